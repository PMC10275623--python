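"""Simulated subjects: ideal and random observers, and the repeated-
experiment harness used to bound human performance.

The *ideal* observer knows the target's binned spectrum ``s`` exactly and
answers "yes" to the trials whose similarity (Psi s) reaches the median
similarity of the session — a median-thresholding rule that fixes its
yes-rate at one half.  The *random* observer answers +/-1 uniformly at
random, ignoring the stimulus, and calibrates the chance floor of the
accuracy distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .binning import BinPartition
from .reconstruction import as_stimulus_matrix, reconstruct
from .stats import pearson_r
from .stimulus import generate_stimulus_batch
from .targets import TargetSound

__all__ = [
    "SimulatedExperimentResult",
    "ideal_responses",
    "random_responses",
    "run_simulated_experiment",
]


@dataclass
class SimulatedExperimentResult:
    """Accuracy distribution of a simulated observer over repetitions."""

    subject_kind: str
    target_label: str
    r_values: np.ndarray
    p: int
    reps: int

    def __post_init__(self):
        r = np.asarray(self.r_values, dtype=float)
        if r.shape != (self.reps,):
            raise ValueError(f"expected {self.reps} r values, got {r.shape}")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        self.r_values = r

    @property
    def mean_r(self) -> float:
        return float(self.r_values.mean())

    @property
    def sd_r(self) -> float:
        return float(self.r_values.std(ddof=1))


def ideal_responses(psi, s) -> np.ndarray:
    """Median-thresholded responses of the ideal observer.

    y_i = +1 iff (Psi s)_i >= median(Psi s), else -1.  The median uses
    linear interpolation between central order statistics; with
    continuous similarities this is almost surely tie-free and the
    yes-rate is half the trials (ties at the threshold answer +1).
    """
    psi = as_stimulus_matrix(psi)
    if psi.shape[0] < 2:
        raise ValueError("ideal observer needs at least 2 trials")
    s = np.asarray(s, dtype=float)
    if s.shape != (psi.shape[1],):
        raise ValueError(
            f"s has shape {s.shape}, expected ({psi.shape[1]},) to match Psi"
        )
    similarity = psi @ s
    return np.where(similarity >= np.median(similarity), 1, -1)


def random_responses(p: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. uniform +/-1 responses, ignoring the stimulus entirely."""
    if p < 1:
        raise ValueError("need at least 1 trial")
    return rng.integers(0, 2, size=p) * 2 - 1


def run_simulated_experiment(
    subject_kind: str,
    target: TargetSound,
    partition: BinPartition | None = None,
    p: int = 200,
    reps: int = 1000,
    rng: np.random.Generator | int | None = None,
    min_filled: int = 2,
    max_filled: int = 7,
) -> SimulatedExperimentResult:
    """Repeat a full simulated session ``reps`` times and collect accuracy.

    Each repetition draws ``p`` fresh random stimuli, obtains responses
    from the chosen observer, reconstructs via the reverse-correlation
    estimator, and scores Pearson r against the target's binned spectrum.
    Repetitions use independent child streams spawned from the master
    seed, so they are reproducible and order-independent.
    """
    if subject_kind not in ("ideal", "random"):
        raise ValueError(f"unknown subject kind {subject_kind!r}")
    if reps < 1:
        raise ValueError("need at least 1 repetition")
    partition = partition or target.binned.partition
    if p < partition.b:
        warnings.warn(
            f"p={p} trials < b={partition.b} bins: reconstruction is "
            "underdetermined",
            stacklevel=2,
        )
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    streams = rng.spawn(reps)
    s = target.binned.power_db
    r_values = np.empty(reps)
    for i, stream in enumerate(streams):
        psi, _ = generate_stimulus_batch(
            partition, p, stream, min_filled=min_filled, max_filled=max_filled
        )
        if subject_kind == "ideal":
            y = ideal_responses(psi, s)
        else:
            y = random_responses(p, stream)
        rec = reconstruct(psi, y)
        r_values[i] = pearson_r(rec.x_hat, s)
    return SimulatedExperimentResult(
        subject_kind=subject_kind,
        target_label=target.label,
        r_values=r_values,
        p=p,
        reps=reps,
    )
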