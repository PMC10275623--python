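"""Mel-spaced frequency bin partitions and bin-domain <-> dense-domain maps.

The stimulus space is a coarse spectral representation: the audible band
(by default 100–13000 Hz) is divided into ``b`` contiguous rectangular
bins of equal width on the mel scale, and a spectrum is summarized by one
power value (dB) per bin.  This module owns the partition, the projection
of a densely sampled spectrum onto the bins (per-bin mean power), and the
piecewise-constant expansion back to a dense frequency grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinPartition",
    "BinnedSpectrum",
    "DenseSpectrum",
    "mel_from_hz",
    "hz_from_mel",
    "make_mel_partition",
    "bin_dense_spectrum",
    "unbin",
]

#: Name of the mel convention used for partition edges, recorded in configs
#: so an alternate formula can be swapped in without ambiguity.
MEL_FORMULA = "oshaughnessy"


def mel_from_hz(f):
    """Map frequency in Hz to mel, m(f) = 2595 log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def hz_from_mel(m):
    """Inverse mel map, f(m) = 700 (10^(m/2595) - 1)."""
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


@dataclass(frozen=True)
class BinPartition:
    """A partition of [f_lo, f_hi] Hz into ``b`` contiguous bins.

    ``edges`` holds the ``b + 1`` bin boundaries in Hz, strictly
    increasing, with ``edges[0] == f_lo`` and ``edges[-1] == f_hi``.
    Bins are half-open ``[edges[k], edges[k+1])`` except the last,
    which is closed on the right, so every in-range frequency belongs
    to exactly one bin.
    """

    f_lo: float
    f_hi: float
    b: int
    edges: np.ndarray = field(repr=False)

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        if edges.shape != (self.b + 1,):
            raise ValueError(f"expected {self.b + 1} edges, got {edges.shape}")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    def bin_index(self, freqs) -> np.ndarray:
        """Bin index for each frequency; -1 for out-of-range samples."""
        f = np.asarray(freqs, dtype=float)
        idx = np.searchsorted(self.edges, f, side="right") - 1
        idx = np.where(f == self.edges[-1], self.b - 1, idx)  # last bin closed
        out_of_range = (f < self.edges[0]) | (f > self.edges[-1])
        return np.where(out_of_range, -1, idx)

    def widths_hz(self) -> np.ndarray:
        return np.diff(self.edges)

    def to_config(self) -> dict:
        """Small serializable description (inverse of ``from_config``)."""
        return {
            "f_lo": self.f_lo,
            "f_hi": self.f_hi,
            "b": self.b,
            "mel_formula": MEL_FORMULA,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "BinPartition":
        formula = cfg.get("mel_formula", MEL_FORMULA)
        if formula != MEL_FORMULA:
            raise ValueError(f"unknown mel formula {formula!r}")
        return make_mel_partition(cfg["f_lo"], cfg["f_hi"], cfg["b"])


@dataclass
class BinnedSpectrum:
    """Power spectrum summarized as one dB value per bin."""

    partition: BinPartition
    power_db: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.power_db, dtype=float)
        if p.shape != (self.partition.b,):
            raise ValueError(
                f"power_db length {p.shape} does not match b={self.partition.b}"
            )
        if not np.all(np.isfinite(p)):
            raise ValueError("binned power must be finite")
        self.power_db = p


@dataclass
class DenseSpectrum:
    """Power spectrum sampled on a uniform ascending frequency grid (dB)."""

    freqs: np.ndarray
    power_db: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power_db, dtype=float)
        if f.ndim != 1 or f.shape != p.shape:
            raise ValueError("freqs and power_db must be 1-D and equal length")
        df = np.diff(f)
        if f.size > 1 and (np.any(df <= 0) or not np.allclose(df, df[0])):
            raise ValueError("freqs must be a uniform ascending grid")
        self.freqs = f
        self.power_db = p


def make_mel_partition(f_lo: float, f_hi: float, b: int) -> BinPartition:
    """Build ``b`` mel-spaced bins covering [f_lo, f_hi] Hz.

    Edges are the inverse-mel images of ``b + 1`` equally spaced points
    between mel(f_lo) and mel(f_hi); the outer edges are pinned to
    f_lo / f_hi exactly.
    """
    if not (0 < f_lo < f_hi):
        raise ValueError(f"need 0 < f_lo < f_hi, got [{f_lo}, {f_hi}]")
    if b < 1:
        raise ValueError(f"bin count must be >= 1, got {b}")
    mels = np.linspace(mel_from_hz(f_lo), mel_from_hz(f_hi), b + 1)
    edges = hz_from_mel(mels)
    edges[0] = f_lo
    edges[-1] = f_hi
    return BinPartition(f_lo=float(f_lo), f_hi=float(f_hi), b=int(b), edges=edges)


def bin_dense_spectrum(spec: DenseSpectrum, partition: BinPartition) -> BinnedSpectrum:
    """Project a dense spectrum onto the partition by per-bin mean power.

    Each bin's value is the mean of ``spec.power_db`` over the frequency
    samples it contains (averaging done in the dB domain); samples outside
    [f_lo, f_hi] are ignored.  Raises if the grid is too coarse to place
    at least one sample in every bin.
    """
    if spec.freqs[0] > partition.f_lo or spec.freqs[-1] < partition.f_hi:
        raise ValueError(
            f"dense grid [{spec.freqs[0]}, {spec.freqs[-1]}] does not cover "
            f"the partition range [{partition.f_lo}, {partition.f_hi}]"
        )
    idx = partition.bin_index(spec.freqs)
    in_range = idx >= 0
    counts = np.bincount(idx[in_range], minlength=partition.b)
    if np.any(counts == 0):
        empty = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(
            f"bin {empty} contains no frequency samples; "
            "increase the dense grid resolution"
        )
    sums = np.bincount(idx[in_range], weights=spec.power_db[in_range],
                       minlength=partition.b)
    return BinnedSpectrum(partition=partition, power_db=sums / counts)


def unbin(binned: BinnedSpectrum, n_freqs: int) -> DenseSpectrum:
    """Expand a binned spectrum to a piecewise-constant dense spectrum.

    The dense grid is ``n_freqs`` uniform samples spanning [f_lo, f_hi];
    each sample takes the power of the bin containing it, so
    ``bin_dense_spectrum(unbin(x, n), partition)`` round-trips to ``x``.
    """
    part = binned.partition
    if n_freqs < part.b:
        raise ValueError(f"n_freqs={n_freqs} must be >= b={part.b}")
    freqs = np.linspace(part.f_lo, part.f_hi, int(n_freqs))
    idx = part.bin_index(freqs)
    return DenseSpectrum(freqs=freqs, power_db=binned.power_db[idx])
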