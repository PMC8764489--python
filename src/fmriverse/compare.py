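"""Pairwise similarity statistics between pipelines' statistic maps.

Three statistics quantify between-pipeline (dis)agreement: Pearson
correlation of the unthresholded maps over the intersection of the two
analysis masks; the Dice overlap of the thresholded activation masks,
computed separately per sign (intersection volume over the mean of the two
activation volumes); and "spill-over", the percentage of one map's
activation falling outside the other pipeline's analysis mask.  Sign-split
Dice makes thresholding amplification visible: near-identical unthresholded
maps can disagree completely after a cluster straddles the extent
criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .glm import StatMap
from .group import ThresholdedMap

__all__ = [
    "ComparisonRecord",
    "ComparisonMatrix",
    "pearson_similarity",
    "dice",
    "spillover",
    "pairwise_matrices",
]

_MIN_OVERLAP = 10


class ComparisonError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonRecord:
    pipeline_a: str
    pipeline_b: str
    pearson_r: float
    dice_positive: float  # nan when both maps empty for that sign
    dice_negative: float
    spillover_a_in_b: float  # percent; nan when a has no activation
    spillover_b_in_a: float

    def swapped(self) -> "ComparisonRecord":
        return ComparisonRecord(
            self.pipeline_b,
            self.pipeline_a,
            self.pearson_r,
            self.dice_positive,
            self.dice_negative,
            self.spillover_b_in_a,
            self.spillover_a_in_b,
        )


@dataclass
class ComparisonMatrix:
    ids: list[str]
    r: np.ndarray
    dice_positive: np.ndarray
    dice_negative: np.ndarray
    records: list[ComparisonRecord] = field(default_factory=list)

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, mat in (
            ("correlation", self.r),
            ("dice_positive", self.dice_positive),
            ("dice_negative", self.dice_negative),
        ):
            pd.DataFrame(mat, index=self.ids, columns=self.ids).to_csv(
                out / f"{name}.csv"
            )
        with open(out / "records.jsonl", "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec.__dict__, default=float) + "\n")

    def plot(self, path: str | Path) -> None:
        """Heatmap panel (correlation and sign-split Dice) as PNG."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(4 * 3, 3.5))
        for ax, (title, mat) in zip(
            axes,
            (
                ("Pearson r", self.r),
                ("Dice (positive)", self.dice_positive),
                ("Dice (negative)", self.dice_negative),
            ),
        ):
            im = ax.imshow(mat, vmin=0, vmax=1, cmap="viridis")
            ax.set_xticks(range(len(self.ids)), self.ids, rotation=90, fontsize=6)
            ax.set_yticks(range(len(self.ids)), self.ids, fontsize=6)
            ax.set_title(title)
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def pearson_similarity(map_a: StatMap, map_b: StatMap) -> float:
    """Pearson r of the two maps over the intersection of their masks."""
    if map_a.values.shape != map_b.values.shape:
        raise ComparisonError("maps are on different grids")
    inter = map_a.mask & map_b.mask
    n = int(inter.sum())
    if n < _MIN_OVERLAP:
        raise ComparisonError(
            f"mask intersection has {n} voxels (< {_MIN_OVERLAP}); "
            f"mask sizes {int(map_a.mask.sum())} and {int(map_b.mask.sum())}"
        )
    a = map_a.values[inter]
    b = map_b.values[inter]
    return float(np.corrcoef(a, b)[0, 1])


def dice(
    map_a: ThresholdedMap,
    map_b: ThresholdedMap,
    sign: Literal["positive", "negative"] = "positive",
) -> float:
    """Sign-split Dice: |A & B| / ((|A| + |B|) / 2).

    Returns 0 when exactly one mask is empty (complete disagreement) and
    NaN (missing) when both are empty.
    """
    a = map_a.positive_mask if sign == "positive" else map_a.negative_mask
    b = map_b.positive_mask if sign == "positive" else map_b.negative_mask
    if a.shape != b.shape:
        raise ComparisonError("maps are on different grids")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return float("nan")
    if na == 0 or nb == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def spillover(map_a: ThresholdedMap, analysis_mask_b: np.ndarray) -> float:
    """Percent of map_a's activation outside the other pipeline's mask.

    NaN (missing) when map_a has no activation of either sign.
    """
    mask_b = np.asarray(analysis_mask_b, dtype=bool)
    act = map_a.combined
    if act.shape != mask_b.shape:
        raise ComparisonError("maps are on different grids")
    total = int(act.sum())
    if total == 0:
        return float("nan")
    outside = int((act & ~mask_b).sum())
    return 100.0 * outside / total


def pairwise_matrices(
    collection: Sequence[tuple[str, StatMap, ThresholdedMap]],
) -> ComparisonMatrix:
    """All-pairs comparison statistics in the given pipeline order.

    The ordering convention follows the workflow-enumeration ladder, so
    entries (i, i+1) expose single-stage interchange effects.
    """
    if len(collection) < 2:
        raise ComparisonError("need at least two pipelines to compare")
    ids = [pid for pid, _, _ in collection]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ComparisonError(f"duplicate pipeline ids: {dup}")
    k = len(ids)
    r = np.eye(k)
    dpos = np.full((k, k), np.nan)
    dneg = np.full((k, k), np.nan)
    records: list[ComparisonRecord] = []
    for i in range(k):
        dpos[i, i] = dice(collection[i][2], collection[i][2], "positive")
        dneg[i, i] = dice(collection[i][2], collection[i][2], "negative")
    for i in range(k):
        for j in range(i + 1, k):
            _, stat_i, thr_i = collection[i]
            _, stat_j, thr_j = collection[j]
            rec = ComparisonRecord(
                pipeline_a=ids[i],
                pipeline_b=ids[j],
                pearson_r=pearson_similarity(stat_i, stat_j),
                dice_positive=dice(thr_i, thr_j, "positive"),
                dice_negative=dice(thr_i, thr_j, "negative"),
                spillover_a_in_b=spillover(thr_i, thr_j.analysis_mask),
                spillover_b_in_a=spillover(thr_j, thr_i.analysis_mask),
            )
            records.append(rec)
            r[i, j] = r[j, i] = rec.pearson_r
            dpos[i, j] = dpos[j, i] = rec.dice_positive
            dneg[i, j] = dneg[j, i] = rec.dice_negative
    return ComparisonMatrix(ids, r, dpos, dneg, records)
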