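"""Seeded generator of Daphnet-like fixture recordings.

Emulates the schema of the freezing-of-gait accelerometer corpus — 64 Hz
sampling, nine milli-g channels with gravity-projection offsets, and
annotation segments alternating among 0 (outside the experiment),
1 (walk/stand/turn) and 2 (freeze) — so the whole pipeline can be
exercised without the real download.

Signal model (a caricature, not biomechanics):

* every channel carries its baseline offset plus white Gaussian sensor
  noise;
* walk segments add a coherent ~2 Hz locomotion sinusoid, strongest on
  the horizontal-forward channels, attenuated on vertical and lateral
  ones, with one gait phase shared across the body;
* freeze segments add band-limited 3-8 Hz "trembling in place", strongest
  on vertical channels and strongly attenuated in the forward direction,
  independent across channels.

The two regimes are spectrally disjoint (1-3 Hz vs 3-8 Hz bands) and
differ in cross-channel coherence, so both a discriminative classifier
and the distribution diagnostics have genuine structure to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import N_CHANNELS, Recording, RecordingCollection, combine_recordings

__all__ = ["SimParams", "simulate_recording", "make_fixture_dataset"]

# Gravity projections of the three mounted sensors, milli-g.
DEFAULT_OFFSETS = (0.0, 980.0, -20.0, 5.0, 970.0, -10.0, 0.0, 990.0, 5.0)

# Channel attenuation per regime: (forward, vertical, lateral) factors.
_WALK_FACTORS = (1.0, 0.6, 0.3)
_FREEZE_FACTORS = (0.35, 1.0, 0.6)

_FORWARD = (0, 3, 6)
_VERTICAL = (1, 4, 7)
_LATERAL = (2, 5, 8)


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated recording.

    ``segments`` is the annotation plan: ``(annotation, duration_s)`` pairs
    rendered in order.  Amplitudes are milli-g deviations around the
    per-channel baseline offsets.
    """

    segments: tuple[tuple[int, float], ...]
    sampling_rate: float = 64.0
    baseline_offsets: tuple[float, ...] = DEFAULT_OFFSETS
    walk_freq_hz: float = 2.0
    walk_amplitude: float = 100.0
    freeze_band_hz: tuple[float, float] = (3.0, 8.0)
    freeze_amplitude: float = 60.0
    noise_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "segments", tuple((int(a), float(d)) for a, d in self.segments)
        )
        if not self.segments:
            raise ValueError("segment plan may not be empty")
        if any(a not in (0, 1, 2) for a, _ in self.segments):
            raise ValueError("segment annotations must be in {0, 1, 2}")
        if any(d <= 0 for _, d in self.segments):
            raise ValueError("segment durations must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.baseline_offsets) != N_CHANNELS:
            raise ValueError(f"need {N_CHANNELS} baseline offsets")
        if self.walk_amplitude < 0 or self.freeze_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise SD must be non-negative")
        lo, hi = self.freeze_band_hz
        if not 0 < lo < hi <= self.sampling_rate / 2:
            raise ValueError("freeze band must satisfy 0 < lo < hi <= Nyquist")


def _bandlimited_noise(
    n: int, fs: float, band: tuple[float, float], rms: float, rng: np.random.Generator
) -> np.ndarray:
    """White noise FFT-masked to ``band`` and rescaled to the requested RMS."""
    white = rng.standard_normal(n)
    if n < 8:
        return white * rms
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    sig = np.fft.irfft(spec, n=n)
    cur = sig.std()
    return sig * (rms / cur) if cur > 0 else sig


def simulate_recording(p: SimParams, source_name: str = "simulated.txt") -> Recording:
    """Render the segment plan into a :class:`Recording`; seeded, deterministic."""
    fs = p.sampling_rate
    seg_rows = [int(round(fs * d)) for _, d in p.segments]
    total = int(sum(seg_rows))
    rng = np.random.default_rng(p.seed)

    channels = np.tile(np.asarray(p.baseline_offsets, dtype=float), (total, 1))
    channels += rng.normal(0.0, p.noise_sd, size=(total, N_CHANNELS))
    annotation = np.empty(total, dtype=np.int64)

    # One gait phase per recording keeps walk oscillation coherent across
    # the body, as with a single walking subject.
    gait_phase = rng.uniform(0.0, 2.0 * np.pi)

    start = 0
    for (ann, _), n in zip(p.segments, seg_rows):
        stop = start + n
        annotation[start:stop] = ann
        t = np.arange(start, stop) / fs
        if ann == 1 and p.walk_amplitude > 0:
            carrier = np.sin(2.0 * np.pi * p.walk_freq_hz * t + gait_phase)
            for chans, fac in zip((_FORWARD, _VERTICAL, _LATERAL), _WALK_FACTORS):
                for c in chans:
                    channels[start:stop, c] += p.walk_amplitude * fac * carrier
        elif ann == 2 and p.freeze_amplitude > 0:
            rms = p.freeze_amplitude / np.sqrt(2.0)  # match a sinusoid's RMS
            for chans, fac in zip((_FORWARD, _VERTICAL, _LATERAL), _FREEZE_FACTORS):
                for c in chans:
                    channels[start:stop, c] += _bandlimited_noise(
                        n, fs, p.freeze_band_hz, rms * fac, rng
                    )
        start = stop

    time = (np.arange(total) * 1000.0 / fs).astype(np.int64)
    return Recording(time=time, channels=channels, annotation=annotation,
                     source_name=source_name)


def _recording_plan(
    rows: int, freeze_rows: int, ann0_rows: int, fs: float
) -> tuple[tuple[int, float], ...]:
    """Row-exact segment plan: ann-0 head/tail, walk with interleaved freeze bursts."""
    head = ann0_rows // 2
    tail = ann0_rows - head
    exp_rows = rows - ann0_rows
    walk_rows = exp_rows - freeze_rows

    # Freeze episodes last a few seconds; split the freeze budget into
    # ~3 s bursts spread through the walking bout.
    burst = max(1, int(round(3.0 * fs)))
    n_bursts = max(1, int(round(freeze_rows / burst))) if freeze_rows else 0

    plan: list[tuple[int, float]] = []
    if head:
        plan.append((0, head / fs))
    if n_bursts == 0:
        if walk_rows:
            plan.append((1, walk_rows / fs))
    else:
        f_sizes = [freeze_rows // n_bursts] * n_bursts
        for i in range(freeze_rows - sum(f_sizes)):
            f_sizes[i] += 1
        w_sizes = [walk_rows // (n_bursts + 1)] * (n_bursts + 1)
        for i in range(walk_rows - sum(w_sizes)):
            w_sizes[i] += 1
        for i in range(n_bursts):
            if w_sizes[i]:
                plan.append((1, w_sizes[i] / fs))
            if f_sizes[i]:
                plan.append((2, f_sizes[i] / fs))
        if w_sizes[-1]:
            plan.append((1, w_sizes[-1] / fs))
    if tail:
        plan.append((0, tail / fs))
    return tuple(plan)


def make_fixture_dataset(
    n_recordings: int,
    freeze_prevalence: float,
    total_rows_target: int,
    seed: int,
    **param_overrides,
) -> RecordingCollection:
    """Generate a multi-recording fixture corpus with a planned freeze share.

    ``freeze_prevalence`` is the target fraction of freeze rows among
    experiment (annotation != 0) rows, i.e. the freeze-label share after
    preprocessing.  A small annotation-0 margin (6% of rows) books-ends
    each recording so the class-0 exclusion step has something to remove.
    Extra keyword arguments override :class:`SimParams` fields such as
    amplitudes or ``noise_sd``.
    """
    if not 0.0 < freeze_prevalence < 1.0:
        raise ValueError("freeze_prevalence must be in (0, 1)")
    if n_recordings < 1:
        raise ValueError("n_recordings must be >= 1")
    if total_rows_target < n_recordings:
        raise ValueError(
            f"infeasible target: {total_rows_target} rows over {n_recordings} recordings"
        )
    fs = float(param_overrides.get("sampling_rate", 64.0))
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.generate_state(n_recordings)

    rows_each = total_rows_target // n_recordings
    row_counts = [rows_each] * n_recordings
    for i in range(total_rows_target - rows_each * n_recordings):
        row_counts[i] += 1

    recordings = []
    for i, rows in enumerate(row_counts):
        ann0 = int(round(0.06 * rows))
        exp_rows = rows - ann0
        freeze = int(round(freeze_prevalence * exp_rows))
        plan = _recording_plan(rows, freeze, ann0, fs)
        params = SimParams(
            segments=plan, seed=int(child_seeds[i] % 2**31), **param_overrides
        )
        recordings.append(simulate_recording(params, source_name=f"sim_{i:03d}.txt"))
    return combine_recordings(recordings)
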