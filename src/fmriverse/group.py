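"""Group-level one-sample inference: t tests, t-to-z conversion, sign-flip
permutation cluster-extent FWE, cluster thresholding, and voxelwise FDR.

Cluster-extent family-wise error is always calibrated against the sign-flip
permutation distribution of the maximum supra-threshold cluster size (for
small samples the full set of sign patterns is enumerated, making the
p-values exact).  The parametric/nonparametric branch distinction of a
workflow is retained as metadata in the thresholding recipe.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, special
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glm import StatMap

__all__ = [
    "ThresholdedMap",
    "PermutationNull",
    "ClusterRecipe",
    "ClusterRecord",
    "PermutationResult",
    "one_sample_ttest",
    "t_to_z",
    "sign_flip_permutation",
    "cluster_threshold",
    "fdr_threshold",
]

logger = logging.getLogger(__name__)


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class ClusterRecipe:
    """Thresholding recipe: cluster-forming p, clusterwise FWE p, voxel
    connectivity, and the inference branch this run belongs to."""

    cluster_forming_p: float = 0.01
    clusterwise_p_fwe: float = 0.05
    connectivity: int = 26
    branch: Literal["parametric", "nonparametric"] = "parametric"
    extent_threshold: int | None = None  # direct extent cutoff, bypassing the null

    def __post_init__(self) -> None:
        if not 0 < self.cluster_forming_p < 1:
            raise InferenceError("cluster_forming_p must be in (0, 1)")
        if not 0 < self.clusterwise_p_fwe < 1:
            raise InferenceError("clusterwise_p_fwe must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise InferenceError("connectivity must be 6, 18 or 26")


@dataclass
class ThresholdedMap:
    """Signed binary activation volumes plus the recipe that produced them."""

    positive_mask: np.ndarray
    negative_mask: np.ndarray
    recipe: dict
    analysis_mask: np.ndarray

    def __post_init__(self) -> None:
        self.positive_mask = np.asarray(self.positive_mask, dtype=bool)
        self.negative_mask = np.asarray(self.negative_mask, dtype=bool)
        self.analysis_mask = np.asarray(self.analysis_mask, dtype=bool)
        if (self.positive_mask & self.negative_mask).any():
            raise InferenceError("positive and negative masks overlap")
        for m in (self.positive_mask, self.negative_mask):
            if (m & ~self.analysis_mask).any():
                raise InferenceError("activation outside the analysis mask")

    @property
    def combined(self) -> np.ndarray:
        return self.positive_mask | self.negative_mask


@dataclass
class PermutationNull:
    """Sampled (or enumerated) maximum-cluster-extent null distribution."""

    max_cluster_sizes: np.ndarray
    n_permutations: int
    seed: int | None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        self.max_cluster_sizes = np.asarray(self.max_cluster_sizes, dtype=int)
        if self.n_permutations < 1:
            raise InferenceError("need at least one permutation")
        if (self.max_cluster_sizes < 0).any():
            raise InferenceError("cluster sizes must be non-negative")

    def fwe_p(self, size: int) -> float:
        """FWE p-value for an observed cluster extent (identity included)."""
        return float((self.max_cluster_sizes >= size).mean())


@dataclass(frozen=True)
class ClusterRecord:
    sign: Literal["positive", "negative"]
    size: int
    peak_stat: float
    peak_index: tuple[int, ...]
    p_fwe: float


@dataclass
class PermutationResult:
    null: PermutationNull
    clusters: list[ClusterRecord]
    tmap: StatMap
    recipe: ClusterRecipe

    def cluster_table(self):
        """Cluster summary (label, sign, size, peak stat, peak index, FWE p)
        as a pandas DataFrame, ordered by extent."""
        import pandas as pd

        rows = [
            {
                "label": i + 1,
                "sign": c.sign,
                "size": c.size,
                "peak_stat": c.peak_stat,
                "peak_index": "{}_{}_{}".format(*c.peak_index),
                "p_fwe": c.p_fwe,
            }
            for i, c in enumerate(
                sorted(self.clusters, key=lambda c: c.size, reverse=True)
            )
        ]
        return pd.DataFrame(
            rows, columns=["label", "sign", "size", "peak_stat", "peak_index", "p_fwe"]
        )


def _connectivity_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def one_sample_ttest(cope_maps: Sequence[np.ndarray]) -> StatMap:
    """Voxelwise one-sample t across subjects; df = n - 1.

    The analysis mask keeps voxels finite in all subjects; zero-variance
    voxels are excluded (and counted in the log).
    """
    data = np.stack([np.asarray(m, dtype=float) for m in cope_maps])
    n = data.shape[0]
    if n < 3:
        raise InferenceError("one-sample t test needs at least 3 subjects")
    mask = np.isfinite(data).all(axis=0)
    safe = np.where(np.isfinite(data), data, 0.0)
    sd = safe.std(axis=0, ddof=1)
    zero_var = mask & ~(sd > 0)
    if zero_var.any():
        logger.warning("excluding %d zero-variance voxels", int(zero_var.sum()))
    mask &= sd > 0
    mean = safe.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(mask, mean / np.where(sd > 0, sd, 1.0) * np.sqrt(n), 0.0)
    return StatMap(t, "t", float(n - 1), mask)


def t_to_z(statmap: StatMap) -> StatMap:
    """Convert a t map to a p-value-preserving z map via the probit of the
    Student cdf, evaluated on the log scale for tail stability."""
    if statmap.stat_kind != "t":
        raise InferenceError("t_to_z requires a t map")
    df = statmap.df
    if df is None or df <= 0:
        raise InferenceError("t map must carry positive degrees of freedom")
    t = statmap.values
    # work on |t| and restore the sign: z = -ndtri(exp(log sf))
    log_sf = stats.t.logsf(np.abs(t), df)
    z_abs = -special.ndtri_exp(log_sf)
    z = np.sign(t) * z_abs
    return StatMap(np.where(statmap.mask, z, 0.0), "z", None, statmap.mask)


def _signed_clusters(
    t: np.ndarray, cutoff: float, structure: np.ndarray, mask: np.ndarray
) -> list[tuple[str, np.ndarray, int]]:
    """Connected components of t >= cutoff and -t >= cutoff inside the mask."""
    out = []
    for sign, field_ in (("positive", t), ("negative", -t)):
        supra = (field_ >= cutoff) & mask
        labels, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            comp = labels == lab
            out.append((sign, comp, int(comp.sum())))
    return out


def sign_flip_permutation(
    cope_maps: Sequence[np.ndarray],
    n_permutations: int = 1000,
    cluster_forming_p: float = 0.01,
    seed: int | None = 0,
    connectivity: int = 26,
    recipe: ClusterRecipe | None = None,
) -> PermutationResult:
    """Sign-flip permutation null of the maximum cluster extent.

    For n <= 12 subjects (or whenever ``n_permutations`` >= 2**n) all 2**n
    sign patterns are enumerated, making the cluster FWE p-values exact; the
    identity permutation is always included, so no p-value can be zero.
    The cluster-forming cutoff is the one-sided Student quantile applied to
    each sign separately; the null maximum is taken over both signs.
    """
    data = np.stack([np.asarray(m, dtype=float) for m in cope_maps])
    n = data.shape[0]
    if n < 3:
        raise InferenceError("sign-flip permutation needs at least 3 subjects")
    if data.ndim != 4:
        raise InferenceError("cope maps must be 3-D volumes")
    if recipe is None:
        recipe = ClusterRecipe(
            cluster_forming_p=cluster_forming_p,
            connectivity=connectivity,
            branch="nonparametric",
        )

    grid = data.shape[1:]
    flat = data.reshape(n, -1)
    mask = np.isfinite(flat).all(axis=0)
    sd0 = flat.std(axis=0, ddof=1)
    mask &= sd0 > 0
    flat = np.where(mask, flat, 0.0)

    exhaustive = n <= 12 or n_permutations >= 2**n
    if exhaustive:
        if n_permutations > 2**n:
            logger.info(
                "requested %d permutations exceeds 2^%d; switching to exhaustive",
                n_permutations,
                n,
            )
        # itertools.product yields the all-ones identity pattern first
        flips = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice((1.0, -1.0), size=(n_permutations - 1, n))
        flips = np.vstack([np.ones(n), flips])
    n_perm = flips.shape[0]

    # sign flips leave sum(x^2) unchanged, so t for all flips is a matmul
    ss = (flat**2).sum(axis=0)
    means = flips @ flat / n
    var = np.maximum(ss - n * means**2, 0.0) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tmat = np.where(mask & (var > 0), means / np.sqrt(var / n), 0.0)

    df = n - 1
    cutoff = float(stats.t.isf(recipe.cluster_forming_p, df))
    structure = _connectivity_structure(recipe.connectivity)
    mask3 = mask.reshape(grid)

    # one-sided null: maximum extent of *positive* supra-threshold clusters
    # per sign pattern; by sign symmetry of the flip distribution the same
    # null applies to negative clusters (per-sign FWE control, as in the
    # packages' one-sided permutation tools)
    max_sizes = np.zeros(n_perm, dtype=int)
    for i in range(n_perm):
        supra = (tmat[i].reshape(grid) >= cutoff) & mask3
        labels, n_lab = ndimage.label(supra, structure=structure)
        if n_lab:
            max_sizes[i] = int(np.bincount(labels.ravel())[1:].max())
    null = PermutationNull(max_sizes, n_perm, seed, exhaustive=exhaustive)

    t_obs = tmat[0].reshape(grid)
    clusters = []
    for sign, comp, size in _signed_clusters(t_obs, cutoff, structure, mask3):
        vals = np.where(comp, t_obs if sign == "positive" else -t_obs, -np.inf)
        peak = np.unravel_index(int(np.argmax(vals)), grid)
        clusters.append(
            ClusterRecord(
                sign=sign,
                size=size,
                peak_stat=float(t_obs[peak]),
                peak_index=tuple(int(i) for i in peak),
                p_fwe=null.fwe_p(size),
            )
        )
    tmap = StatMap(t_obs, "t", float(df), mask3)
    return PermutationResult(null=null, clusters=clusters, tmap=tmap, recipe=recipe)


def cluster_threshold(
    statmap: StatMap,
    recipe: ClusterRecipe,
    null: PermutationNull | None = None,
) -> ThresholdedMap:
    """Cluster-extent thresholding of a t map.

    Supra-threshold voxels (per sign, one-sided Student cutoff at the
    cluster-forming p) are labelled into connected components; components
    whose extent survives the clusterwise FWE criterion — judged against the
    permutation null, or against ``recipe.extent_threshold`` when given —
    populate the signed masks.  An empty result is valid.
    """
    if statmap.stat_kind != "t" or statmap.df is None:
        raise InferenceError("cluster_threshold requires a t map with df")
    if null is None and recipe.extent_threshold is None:
        raise InferenceError("need a permutation null or an explicit extent threshold")
    cutoff = float(stats.t.isf(recipe.cluster_forming_p, statmap.df))
    structure = _connectivity_structure(recipe.connectivity)
    pos = np.zeros(statmap.values.shape, dtype=bool)
    neg = np.zeros(statmap.values.shape, dtype=bool)
    for sign, comp, size in _signed_clusters(
        statmap.values, cutoff, structure, statmap.mask
    ):
        if recipe.extent_threshold is not None:
            keep = size >= recipe.extent_threshold
        else:
            keep = null.fwe_p(size) <= recipe.clusterwise_p_fwe
        if keep:
            (pos if sign == "positive" else neg)[comp] = True
    recipe_dict = {
        "cluster_forming_p": recipe.cluster_forming_p,
        "clusterwise_p_fwe": recipe.clusterwise_p_fwe,
        "connectivity": recipe.connectivity,
        "branch": recipe.branch,
        "extent_threshold": recipe.extent_threshold,
    }
    return ThresholdedMap(pos, neg, recipe_dict, statmap.mask)


def fdr_threshold(
    zmap: StatMap, q: float = 0.05, side: Literal["greater", "less"] = "greater"
) -> ThresholdedMap:
    """One-sided Benjamini-Hochberg step-up on in-mask voxelwise p-values."""
    if not 0 < q < 1:
        raise InferenceError("q must be in (0, 1)")
    if side not in ("greater", "less"):
        raise InferenceError("side must be 'greater' or 'less'")
    if zmap.stat_kind != "z":
        raise InferenceError("fdr_threshold requires a z map")
    mask = zmap.mask
    if not mask.any():
        raise InferenceError("empty analysis mask")
    z = zmap.values[mask]
    p = stats.norm.sf(z) if side == "greater" else stats.norm.cdf(z)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    surv = np.zeros(zmap.values.shape, dtype=bool)
    surv[mask] = reject
    pos = surv if side == "greater" else np.zeros_like(surv)
    neg = surv if side == "less" else np.zeros_like(surv)
    return ThresholdedMap(pos, neg, {"method": "fdr_bh", "q": q, "side": side}, mask)
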