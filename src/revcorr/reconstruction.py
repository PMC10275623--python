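"""The linear sign-observer model and the reverse-correlation estimator.

A session of ``p`` trials over ``b`` bins is a stimulus matrix
``Psi`` (p x b; row k is trial k's binned power vector, dB) and a
response vector ``y`` in {+1, -1}^p (+1 = "yes").  The classical
response model is

    y = sign(Psi x)

for an internal representation ``x`` in R^b, and inverting it under the
assumption of uncorrelated stimulus dimensions gives the
reverse-correlation estimate

    x_hat = (1/p) Psi^T y,

the response-weighted mean stimulus (a restricted normal equation).
The 1/p scale is immaterial to Pearson-r validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Reconstruction",
    "as_stimulus_matrix",
    "as_response_vector",
    "simulate_responses",
    "reconstruct",
]


@dataclass
class Reconstruction:
    """A reverse-correlation estimate of an internal representation."""

    x_hat: np.ndarray
    trials_used: int
    subject_id: str | None = None
    target_label: str | None = None

    def __post_init__(self):
        x = np.asarray(self.x_hat, dtype=float)
        if x.ndim != 1 or not np.all(np.isfinite(x)):
            raise ValueError("x_hat must be a finite 1-D vector")
        self.x_hat = x


def as_stimulus_matrix(psi) -> np.ndarray:
    """Validate and return a (p, b) float stimulus matrix."""
    psi = np.asarray(psi, dtype=float)
    if psi.ndim != 2 or psi.shape[0] < 1:
        raise ValueError(f"stimulus matrix must be 2-D with >=1 row, got {psi.shape}")
    if not np.all(np.isfinite(psi)):
        raise ValueError("stimulus matrix must be finite")
    return psi


def as_response_vector(y, p: int | None = None) -> np.ndarray:
    """Validate and return a length-p response vector with entries +/-1."""
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValueError("response vector must be 1-D")
    if not np.all(np.isin(y, (1, -1))):
        raise ValueError("responses must be +1 or -1")
    if p is not None and y.size != p:
        raise ValueError(f"expected {p} responses, got {y.size}")
    return y.astype(float)


def simulate_responses(psi, x) -> np.ndarray:
    """Responses of the linear sign observer, y = sign(Psi x).

    Exact zeros of the similarity map to +1 (fixed tie rule; zeros have
    measure zero for random stimuli but arise in degenerate tests).
    """
    psi = as_stimulus_matrix(psi)
    x = np.asarray(x, dtype=float)
    if x.shape != (psi.shape[1],):
        raise ValueError(
            f"x has shape {x.shape}, expected ({psi.shape[1]},) to match Psi"
        )
    return np.where(psi @ x >= 0, 1, -1)


def reconstruct(
    psi,
    y,
    subject_id: str | None = None,
    target_label: str | None = None,
    center: bool = False,
) -> Reconstruction:
    """Reverse-correlation estimate x_hat = (1/p) Psi^T y.

    ``center=True`` subtracts the column means of Psi before the product
    (off by default: the estimator is implemented verbatim, and binary
    dB-coded stimuli have nonzero column means).
    """
    psi = as_stimulus_matrix(psi)
    if psi.shape[0] == 0:
        raise ValueError("empty session: no trials to reconstruct from")
    y = as_response_vector(y, p=psi.shape[0])
    p = psi.shape[0]
    if center:
        psi = psi - psi.mean(axis=0, keepdims=True)
    x_hat = psi.T @ y / p
    return Reconstruction(
        x_hat=x_hat, trials_used=p, subject_id=subject_id, target_label=target_label
    )
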