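"""Seeded synthetic peri-event datasets for testing and demonstration.

The generator emulates an event-aligned, baseline z-scored photometry
recording: each animal/trial is i.i.d. Gaussian noise plus, from the event
row onward, a peak-normalized double-exponential transient

    k(t) = (1 - exp(-t / rise)) * exp(-t / decay)

scaled by the group's response amplitude plus a per-subject random offset.
Defaults match a conventional peri-event layout: 813 rows spanning -20 s
to +60 s at ~10 Hz (event at row 213), 3 groups of 7 subjects.  White
noise is a deliberate simplification — real recordings carry 1/f noise,
bleaching drift and motion artifacts that this generator does not model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GroupMatrix, PeriEventDataset

__all__ = ["SyntheticSpec", "generate_event_dataset", "generate_null_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic peri-event experiment.

    amplitudes are per-group response sizes in z-units (one entry per
    group); rise_s / decay_s are the transient kernel time constants in
    seconds; subject_sd is the SD of the random per-subject amplitude
    offset; paired=True draws those offsets once per subject index and
    shares them across groups, giving the correlated columns a
    within-subjects design needs.
    """

    n_groups: int = 3
    n_subjects: int = 7
    n_timepoints: int = 813
    sampling_hz: float = 10.0
    event_row: int = 213
    amplitudes: tuple[float, ...] = (0.0, 1.0, 3.0)
    rise_s: float = 0.08
    decay_s: float = 0.5
    noise_sd: float = 1.0
    subject_sd: float = 0.3
    paired: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_subjects < 1 or self.n_timepoints < 2:
            raise ValueError("counts must be positive (and at least 2 timepoints)")
        if not 0 <= self.event_row < self.n_timepoints:
            raise ValueError("event_row must lie inside the peri-event window")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise_sd and subject_sd must be non-negative")
        if len(self.amplitudes) != self.n_groups:
            raise ValueError(
                f"{len(self.amplitudes)} amplitudes for {self.n_groups} groups"
            )
        if self.rise_s < 0 or self.decay_s <= 0:
            raise ValueError("kernel time constants must be positive")


def _transient_kernel(spec: SyntheticSpec) -> np.ndarray:
    """Peak-normalized response kernel over the full window (0 pre-event)."""
    kernel = np.zeros(spec.n_timepoints)
    t = np.arange(spec.n_timepoints - spec.event_row) / spec.sampling_hz
    rise = max(spec.rise_s, 1e-9)
    shape = (1.0 - np.exp(-t / rise)) * np.exp(-t / spec.decay_s)
    peak = shape.max()
    if peak > 0:
        shape = shape / peak
    kernel[spec.event_row:] = shape
    return kernel


def generate_event_dataset(spec: SyntheticSpec) -> PeriEventDataset:
    """Generate one peri-event dataset; bit-identical for a given spec."""
    rng = np.random.default_rng(spec.seed)
    kernel = _transient_kernel(spec)
    shared_offsets = rng.normal(0.0, spec.subject_sd, spec.n_subjects)
    groups = []
    for gi in range(spec.n_groups):
        offsets = (
            shared_offsets
            if spec.paired
            else rng.normal(0.0, spec.subject_sd, spec.n_subjects)
        )
        noise = rng.normal(0.0, spec.noise_sd, (spec.n_timepoints, spec.n_subjects))
        response = kernel[:, None] * (spec.amplitudes[gi] + offsets)[None, :]
        groups.append(GroupMatrix(f"group{gi}", noise + response))
    return PeriEventDataset(tuple(groups), source_path="synthetic")


def generate_null_dataset(
    n_groups: int = 3,
    n_subjects: int = 7,
    n_timepoints: int = 813,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> PeriEventDataset:
    """Pure-noise dataset: all group amplitudes zero, no subject effects."""
    spec = SyntheticSpec(
        n_groups=n_groups,
        n_subjects=n_subjects,
        n_timepoints=n_timepoints,
        event_row=n_timepoints // 2,
        amplitudes=(0.0,) * n_groups,
        noise_sd=noise_sd,
        subject_sd=0.0,
        seed=seed,
    )
    return generate_event_dataset(spec)
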