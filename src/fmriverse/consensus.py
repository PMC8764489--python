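"""Correlation-aware consensus meta-analysis across pipelines.

Statistic maps produced by k different analysis pipelines from the *same*
underlying data are strongly correlated, so the naive Stouffer combination
``sqrt(k) * mean(z)`` badly overstates the evidence.  The consensus
statistic used here divides the voxelwise mean of the k z maps by the
standard deviation of a mean of equicorrelated unit-variance variables,

    consensus = mean(z_1..z_k) / sqrt((1 + (k - 1) rho_bar) / k),

with ``rho_bar`` the mean pairwise in-mask correlation between the maps.
Under exchangeable unit-variance nulls with that correlation the consensus
is standard normal, and it degrades gracefully: at rho_bar = 0 it is the
Stouffer combination, at rho_bar = 1 no evidence accumulates.

The correlation estimator is pluggable: by default it is computed over the
whole shared mask, optionally restricted to a presumed-null voxel mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .glm import StatMap
from .group import ThresholdedMap, fdr_threshold

__all__ = [
    "ConsensusResult",
    "mean_pairwise_correlation",
    "consensus_z",
    "consensus_inference",
    "run_consensus",
]

_MIN_MASK = 100


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusResult:
    consensus_z: StatMap
    rho_bar_hat: float
    k: int
    positive_thresholded: ThresholdedMap
    negative_thresholded: ThresholdedMap
    q: float

    def summary(self) -> dict:
        return {
            "k": self.k,
            "rho_bar_hat": self.rho_bar_hat,
            "q": self.q,
            "n_positive_voxels": int(self.positive_thresholded.positive_mask.sum()),
            "n_negative_voxels": int(self.negative_thresholded.negative_mask.sum()),
        }


def _shared_mask(zmaps: Sequence[StatMap]) -> np.ndarray:
    mask = zmaps[0].mask.copy()
    for m in zmaps[1:]:
        if m.values.shape != zmaps[0].values.shape:
            raise ConsensusError("z maps are on different grids")
        mask &= m.mask
    return mask


def mean_pairwise_correlation(
    zmaps: Sequence[StatMap], mask: np.ndarray | None = None
) -> float:
    """Mean of the k(k-1)/2 pairwise in-mask Pearson correlations.

    Clipped below at -1/(k-1) so the equicorrelation variance correction
    stays positive (unreachable in practice for same-data pipelines).
    """
    k = len(zmaps)
    if k < 2:
        raise ConsensusError("need at least two z maps")
    if mask is None:
        mask = _shared_mask(zmaps)
    if int(mask.sum()) < _MIN_MASK:
        raise ConsensusError(f"shared mask has fewer than {_MIN_MASK} voxels")
    data = np.stack([m.values[mask] for m in zmaps])
    sds = data.std(axis=1)
    flat_idx = np.where(sds == 0)[0]
    if flat_idx.size:
        raise ConsensusError(
            f"constant map(s) at position(s) {flat_idx.tolist()}: correlation undefined"
        )
    corr = np.corrcoef(data)
    upper = corr[np.triu_indices(k, 1)]
    rho = float(upper.mean())
    return max(rho, -1.0 / (k - 1) + 1e-12)


def consensus_z(zmaps: Sequence[StatMap], rho_bar_hat: float) -> StatMap:
    """Variance-corrected mean of the k z maps (see module docstring)."""
    k = len(zmaps)
    if k < 2:
        raise ConsensusError("consensus requires at least two z maps")
    mask = _shared_mask(zmaps)
    correction = (1 + (k - 1) * rho_bar_hat) / k
    if correction <= 0:
        raise ConsensusError("variance correction factor must be positive")
    mean = np.mean([m.values for m in zmaps], axis=0)
    z = np.where(mask, mean / np.sqrt(correction), 0.0)
    return StatMap(z, "z", None, mask)


def consensus_inference(
    consensus: StatMap, q: float = 0.05
) -> tuple[ThresholdedMap, ThresholdedMap]:
    """Two independent one-sided BH-FDR inferences on the consensus map.

    Returns (positive-side, negative-side) thresholded maps; either may be
    empty — an empty negative side is the expected outcome when no
    consistent deactivation exists.
    """
    pos = fdr_threshold(consensus, q=q, side="greater")
    neg = fdr_threshold(consensus, q=q, side="less")
    return pos, neg


def run_consensus(
    zmaps: Sequence[StatMap],
    q: float = 0.05,
    null_mask: np.ndarray | None = None,
    correlation_estimator: Callable[[Sequence[StatMap], np.ndarray | None], float]
    | None = None,
) -> ConsensusResult:
    """Full consensus analysis: correlation estimate, corrected z, FDR.

    ``null_mask`` optionally restricts the correlation estimation to
    presumed-null voxels; ``correlation_estimator`` replaces the default
    whole-mask mean-pairwise estimator entirely.
    """
    estimator = correlation_estimator or mean_pairwise_correlation
    rho = float(estimator(zmaps, null_mask))
    cz = consensus_z(zmaps, rho)
    pos, neg = consensus_inference(cz, q=q)
    return ConsensusResult(
        consensus_z=cz,
        rho_bar_hat=rho,
        k=len(zmaps),
        positive_thresholded=pos,
        negative_thresholded=neg,
        q=q,
    )
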