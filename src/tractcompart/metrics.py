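"""Diffusivity indices from tensor eigenvalues.

AD = lambda1, RD = (lambda2 + lambda3) / 2, MD = (lambda1 + lambda2 +
lambda3) / 3 and FA = sqrt(3/2) * sqrt(sum((lambda_i - MD)^2) /
sum(lambda_i^2)). Eigenvalues are in 1e-3 mm^2/s; FA is unitless in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ScalarVolume

__all__ = ["EigenTriple", "eigenvalues_to_metrics", "metrics_from_eigen_volumes"]

METRIC_NAMES = ("AD", "RD", "MD", "FA")


@dataclass(frozen=True)
class EigenTriple:
    """Sorted tensor eigenvalues, lambda1 >= lambda2 >= lambda3 >= 0.

    Unsorted input is sorted on construction rather than rejected: upstream
    tensor fits do not guarantee ordering.
    """

    lambda1: float
    lambda2: float
    lambda3: float

    def __post_init__(self):
        vals = sorted((float(self.lambda1), float(self.lambda2),
                       float(self.lambda3)), reverse=True)
        if not all(np.isfinite(vals)):
            raise ValueError("eigenvalues must be finite")
        if vals[2] < 0:
            raise ValueError("eigenvalues must be non-negative")
        object.__setattr__(self, "lambda1", vals[0])
        object.__setattr__(self, "lambda2", vals[1])
        object.__setattr__(self, "lambda3", vals[2])


def eigenvalues_to_metrics(e: EigenTriple) -> dict:
    """AD, RD, MD, FA for one eigenvalue triple.

    The zero tensor has no defined anisotropy; FA is reported as 0 with a
    ``degenerate`` flag so profile arithmetic stays total.
    """
    lam = np.array([e.lambda1, e.lambda2, e.lambda3])
    ad = lam[0]
    rd = (lam[1] + lam[2]) / 2.0
    md = lam.mean()
    ssq = float((lam ** 2).sum())
    degenerate = ssq == 0.0
    fa = 0.0 if degenerate else float(
        np.sqrt(1.5 * ((lam - md) ** 2).sum() / ssq))
    return {"AD": float(ad), "RD": float(rd), "MD": float(md), "FA": fa,
            "degenerate": degenerate}


def metrics_from_eigen_volumes(l1: ScalarVolume, l2: ScalarVolume,
                               l3: ScalarVolume) -> dict:
    """Voxel-wise metric maps from three eigenvalue volumes.

    Returns ``{"AD": ..., "RD": ..., "MD": ..., "FA": ...}`` as
    :class:`ScalarVolume` on the shared grid. Grids and affines must match.
    """
    if not (l1.data.shape == l2.data.shape == l3.data.shape):
        raise ValueError("eigenvalue volumes have mismatched shapes")
    if not (np.allclose(l1.affine, l2.affine) and np.allclose(l1.affine, l3.affine)):
        raise ValueError("eigenvalue volumes have mismatched affines")
    lam = np.sort(np.stack([l1.data, l2.data, l3.data]), axis=0)[::-1]
    ad = lam[0]
    rd = (lam[1] + lam[2]) / 2.0
    md = lam.mean(axis=0)
    ssq = (lam ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * ((lam - md) ** 2).sum(axis=0) / ssq)
    fa = np.where(ssq == 0.0, 0.0, fa)
    return {"AD": l1.like(ad), "RD": l1.like(rd),
            "MD": l1.like(md), "FA": l1.like(fa)}
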