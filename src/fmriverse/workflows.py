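"""Enumeration and execution of the hybrid-pipeline space.

The pipeline space is organised as "ladders": for each dataset kind a
reference package sits at one end and, for each secondary package, a
seven-rung ladder walks from the all-secondary workflow to the
all-reference workflow changing exactly one analysis procedure between
adjacent rungs — preprocessing to a common surrogate, then the group,
noise, drift and signal models one at a time, then preprocessing again.
The two event-related/block dataset kinds carry two secondary-package
ladders in both a parametric and a nonparametric inference branch
(13 workflows per branch, the all-reference endpoint shared); the
repeated-measures kind carries a single parametric ladder (7 workflows).
The default scheme totals 59 distinct workflows.

Because one package's noise model cannot run inside another package, the
noise style of a spec is also the "executing package" of its subject-level
fit; signal and drift blocks from other styles are obtained by exchanging
design-matrix columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import design as dsg
from .compare import ComparisonMatrix, dice, pairwise_matrices
from .consensus import ConsensusResult, run_consensus
from .glm import NoiseSpec, StatMap, compute_contrast, fit_glm
from .group import (
    ClusterRecipe,
    ThresholdedMap,
    cluster_threshold,
    sign_flip_permutation,
    t_to_z,
)
from .synthetic import DatasetBundle

__all__ = [
    "PipelineSpec",
    "DatasetLadder",
    "LadderScheme",
    "WorkflowResult",
    "VariabilityReport",
    "UnsupportedGroupModelError",
    "enumerate_workflows",
    "run_workflow",
    "variability_report",
    "DATASET_RECIPES",
]

logger = logging.getLogger(__name__)

DatasetKind = Literal["ds1_like", "ds109_like", "ds120_like"]

#: per-dataset-kind group-inference settings (cluster-forming p, FWE p)
DATASET_RECIPES: dict[str, ClusterRecipe] = {
    "ds1_like": ClusterRecipe(cluster_forming_p=0.01, clusterwise_p_fwe=0.05),
    "ds109_like": ClusterRecipe(cluster_forming_p=0.005, clusterwise_p_fwe=0.05),
    "ds120_like": ClusterRecipe(cluster_forming_p=0.001, clusterwise_p_fwe=0.05),
}

#: spatial smoothing (voxels) of the preprocessing surrogate per style;
#: distinct values keep preprocessing rungs non-degenerate at toy scale
PREPROCESSING_SIGMA: dict[str, float] = {
    "fmriprep": 0.0,
    "A": 0.3,
    "S": 0.5,
    "F": 0.7,
}


class WorkflowError(ValueError):
    pass


class UnsupportedGroupModelError(WorkflowError):
    """The repeated-measures group model is not implemented."""


@dataclass(frozen=True)
class PipelineSpec:
    """A complete workflow description in the ladder scheme.

    ``label`` follows the ladder naming convention: rung number, then the
    secondary package letter, then (for hybrid rungs) the reference letter —
    e.g. ``1A``, ``4AF``, ``7F``.
    """

    dataset: DatasetKind
    preprocessing: str  # A/F/S/fmriprep
    signal_style: str
    drift_style: str
    noise_style: str
    group_style: str
    inference_branch: Literal["parametric", "nonparametric"] = "parametric"
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("signal_style", "drift_style", "noise_style", "group_style"):
            if getattr(self, name) not in ("A", "F", "S"):
                raise WorkflowError(f"{name} must be one of A/F/S")
        if self.preprocessing not in ("A", "F", "S", "fmriprep"):
            raise WorkflowError("preprocessing must be A/F/S/fmriprep")
        if self.dataset == "ds120_like":
            styles = {
                self.signal_style,
                self.drift_style,
                self.noise_style,
                self.group_style,
            }
            if "F" in styles or self.preprocessing == "F":
                raise WorkflowError("ds120_like workflows cannot use the F style")
            if self.inference_branch == "nonparametric":
                raise WorkflowError("ds120_like supports parametric inference only")

    @property
    def executing_package(self) -> str:
        """The package running the subject-level fit is fixed by the noise model."""
        return self.noise_style

    @property
    def id(self) -> str:
        suffix = "" if self.inference_branch == "parametric" else "-np"
        return self.label + suffix

    def stage_values(self) -> dict[str, str]:
        return {
            "preprocessing": self.preprocessing,
            "signal": self.signal_style,
            "drift": self.drift_style,
            "noise": self.noise_style,
            "group": self.group_style,
        }


@dataclass(frozen=True)
class DatasetLadder:
    """One dataset kind's ladder descriptor: the reference package, the
    secondary packages, the inference branches, and which stage each of the
    six rung transitions interchanges."""

    dataset: DatasetKind
    reference: str
    secondaries: tuple[str, ...]
    branches: tuple[str, ...] = ("parametric", "nonparametric")
    rung_stages: tuple[str, ...] = (
        "preprocessing",  # 1 -> 2: package preprocessing -> common surrogate
        "group",  # 2 -> 3
        "noise",  # 3 -> 4
        "drift",  # 4 -> 5
        "signal",  # 5 -> 6
        "preprocessing",  # 6 -> 7: common surrogate -> reference package
    )

    def __post_init__(self) -> None:
        if len(self.rung_stages) != 6:
            raise WorkflowError("a ladder has exactly six rung transitions")
        for stage in ("group", "noise", "drift", "signal"):
            if self.rung_stages.count(stage) != 1:
                raise WorkflowError(f"rung transitions must interchange {stage} exactly once")
        if self.rung_stages.count("preprocessing") != 2:
            raise WorkflowError("rung transitions must change preprocessing exactly twice")


DEFAULT_SCHEME: tuple[DatasetLadder, ...] = (
    DatasetLadder("ds1_like", reference="F", secondaries=("A", "S")),
    DatasetLadder("ds109_like", reference="F", secondaries=("A", "S")),
    DatasetLadder(
        "ds120_like", reference="S", secondaries=("A",), branches=("parametric",)
    ),
)


@dataclass(frozen=True)
class LadderScheme:
    ladders: tuple[DatasetLadder, ...] = DEFAULT_SCHEME


def _ladder_specs(
    ladder: DatasetLadder, secondary: str, branch: str
) -> list[PipelineSpec]:
    ref = ladder.reference
    stages = {
        "preprocessing": secondary,
        "signal": secondary,
        "drift": secondary,
        "noise": secondary,
        "group": secondary,
    }
    specs = []
    prep_flips = 0
    for rung in range(1, 8):
        if rung > 1:
            stage = ladder.rung_stages[rung - 2]
            if stage == "preprocessing":
                prep_flips += 1
                stages["preprocessing"] = "fmriprep" if prep_flips == 1 else ref
            else:
                stages[stage] = ref
        if rung == 1:
            label = f"1{secondary}"
        elif rung == 7:
            label = f"7{ref}"
        else:
            label = f"{rung}{secondary}{ref}"
        specs.append(
            PipelineSpec(
                dataset=ladder.dataset,
                preprocessing=stages["preprocessing"],
                signal_style=stages["signal"],
                drift_style=stages["drift"],
                noise_style=stages["noise"],
                group_style=stages["group"],
                inference_branch=branch,
                label=label,
            )
        )
    return specs


def enumerate_workflows(scheme: LadderScheme | None = None) -> list[PipelineSpec]:
    """Enumerate all distinct workflow specifications of the scheme.

    Within each dataset kind and branch, the ladders of the different
    secondary packages share their all-reference endpoint, which is emitted
    once; every other rung is distinct.  The default scheme yields 59
    workflows: 26 for each of the two ladder dataset kinds (13 per
    inference branch) and 7 for the repeated-measures kind.
    """
    scheme = scheme or LadderScheme()
    seen: dict[tuple[str, str, str], PipelineSpec] = {}
    out: list[PipelineSpec] = []
    for ladder in scheme.ladders:
        if not ladder.secondaries:
            raise WorkflowError("ladder needs at least one secondary package")
        for branch in ladder.branches:
            for secondary in ladder.secondaries:
                for spec in _ladder_specs(ladder, secondary, branch):
                    key = (spec.dataset, spec.label, spec.inference_branch)
                    if key not in seen:
                        seen[key] = spec
                        out.append(spec)
    return out


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

_ORTHO_BY_STYLE = {
    "A": dsg.OrthoScheme(style="none"),
    "S": dsg.OrthoScheme(style="serial_preceding"),
    # F-style pairs are filled in per event table (modulated -> average)
}

# the three drift emulations share an effective ~128 s high-pass scale
# (drift-model results are insensitive to this choice); they differ in
# basis family and in mechanism (columns vs residualization of data+design)
_DRIFT_BY_STYLE = {
    "A": dsg.DriftSpec(style="polynomial_basis", max_degree=4),
    "F": dsg.DriftSpec(style="highpass_residualization", cutoff=128.0),
    "S": dsg.DriftSpec(style="dct_basis", cutoff=128.0),
}

_NOISE_BY_STYLE = {
    "A": NoiseSpec(style="arma11_voxelwise"),
    "F": NoiseSpec(style="ar1_voxelwise"),
    "S": NoiseSpec(style="ar1_pooled"),
}


@dataclass
class WorkflowResult:
    spec: PipelineSpec
    tmap: StatMap
    zmap: StatMap
    thresholded: ThresholdedMap
    permutation: "object | None" = None  # PermutationResult of the group stage


def _ortho_scheme(style: str, events) -> dsg.OrthoScheme:
    if style == "F":
        pairs = []
        conds = events.conditions
        for c in conds:
            if c.endswith("_modulated") and c.replace("_modulated", "_average") in conds:
                pairs.append((c, c.replace("_modulated", "_average")))
        return dsg.OrthoScheme(style="pairwise_explicit", pairs=tuple(pairs))
    return _ORTHO_BY_STYLE[style]


def _preprocess_surrogate(vol: np.ndarray, style: str) -> np.ndarray:
    """Desk-scale preprocessing surrogate: per-style spatial smoothing of the
    generator's single preprocessed output."""
    sigma = PREPROCESSING_SIGMA[style]
    if sigma == 0:
        return vol
    return ndimage.gaussian_filter(vol, sigma=(sigma, sigma, sigma, 0))


def _build_design(
    spec: PipelineSpec, bundle: DatasetBundle, motion: np.ndarray
) -> dsg.DesignMatrix:
    frame_times = bundle.frame_times
    hrf = dsg.HrfSpec.preset(spec.signal_style)
    signal_cols = dsg.build_signal_regressors(bundle.events, hrf, frame_times)
    signal = dsg.RegressorBlock(signal_cols, spec.signal_style)
    drift_spec = _DRIFT_BY_STYLE[spec.drift_style]
    drift = dsg.drift_regressors(drift_spec, frame_times, bundle.tr)
    if isinstance(drift, dsg.DriftProjection):
        drift = replace(drift, style=spec.drift_style)
        drift_block: dsg.RegressorBlock | dsg.DriftProjection = drift
    else:
        drift_block = dsg.RegressorBlock(drift, spec.drift_style)
    motion_block = dsg.RegressorBlock(pd.DataFrame(motion), "fmriprep")
    dm = dsg.assemble_design(signal, drift_block, motion_block, frame_times)
    return dsg.apply_orthogonalization(dm, _ortho_scheme(spec.signal_style, bundle.events))


def run_workflow(
    spec: PipelineSpec,
    bundle: DatasetBundle,
    n_permutations: int = 200,
    seed: int = 0,
) -> WorkflowResult:
    """Execute one workflow on a bundle, deterministically given the seed.

    Per subject: preprocessing surrogate, hybrid design under the spec's
    signal/drift styles, prewhitened GLM under the noise style's executing
    package, contrast on the bundle's truth condition.  Group stage:
    one-sample sign-flip permutation t test and cluster-extent FWE
    thresholding under the dataset kind's inference settings; the cluster
    FWE calibration always comes from the permutation null, the spec's
    branch is recorded in the recipe.
    """
    if spec.dataset == "ds120_like" or bundle.kind == "ds120_like":
        raise UnsupportedGroupModelError(
            "unsupported group model: the repeated-measures group stage is not implemented"
        )
    if spec.dataset != bundle.kind:
        raise WorkflowError(f"spec is for {spec.dataset} but bundle is {bundle.kind}")

    truth_condition = bundle.ground_truth["truth_condition"]
    noise_spec = _NOISE_BY_STYLE[spec.noise_style]
    copes = []
    for vol, motion in zip(bundle.subjects, bundle.motion_params):
        vol = _preprocess_surrogate(vol, spec.preprocessing)
        dm = _build_design(spec, bundle, motion)
        fit = fit_glm(vol, dm, noise_spec)
        weights = np.zeros(len(fit.columns))
        weights[fit.columns.index(truth_condition)] = 1.0
        copes.append(compute_contrast(fit, weights).effect)
        logger.debug("pipeline %s: subject fitted", spec.id)

    base = DATASET_RECIPES[spec.dataset]
    recipe = ClusterRecipe(
        cluster_forming_p=base.cluster_forming_p,
        clusterwise_p_fwe=base.clusterwise_p_fwe,
        connectivity=base.connectivity,
        branch=spec.inference_branch,
    )
    perm = sign_flip_permutation(
        copes, n_permutations=n_permutations, seed=seed, recipe=recipe
    )
    thresholded = cluster_threshold(perm.tmap, recipe, perm.null)
    zmap = t_to_z(perm.tmap)
    logger.info(
        "pipeline %s: %d clusters, %d surviving voxels",
        spec.id,
        len(perm.clusters),
        int(thresholded.combined.sum()),
    )
    return WorkflowResult(
        spec=spec, tmap=perm.tmap, zmap=zmap, thresholded=thresholded, permutation=perm
    )


@dataclass
class VariabilityReport:
    comparison: ComparisonMatrix
    adjacent_deltas: list[dict]
    consensus: ConsensusResult | None

    def write(self, out_dir: str | Path) -> None:
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.comparison.to_csv(out / "comparison")
        self.comparison.plot(out / "comparison_heatmaps.png")
        (out / "adjacent_deltas.json").write_text(
            json.dumps(self.adjacent_deltas, indent=1, default=float)
        )
        if self.consensus is not None:
            (out / "consensus_summary.json").write_text(
                json.dumps(self.consensus.summary(), indent=1)
            )


def _changed_stages(a: PipelineSpec, b: PipelineSpec) -> list[str]:
    va, vb = a.stage_values(), b.stage_values()
    return [k for k in va if va[k] != vb[k]]


def variability_report(results: Sequence[WorkflowResult]) -> VariabilityReport:
    """Comparison matrices, adjacent-pair stage attributions, and the
    consensus meta-analysis over all completed workflows of one bundle."""
    if len(results) < 2:
        raise WorkflowError("need at least two completed workflows")
    shapes = {r.zmap.values.shape for r in results}
    if len(shapes) != 1:
        raise WorkflowError("workflow results are on mixed grids")
    collection = [(r.spec.id, r.zmap, r.thresholded) for r in results]
    comparison = pairwise_matrices(collection)
    adjacent = []
    for a, b in zip(results, results[1:]):
        stages = _changed_stages(a.spec, b.spec)
        adjacent.append(
            {
                "pair": (a.spec.id, b.spec.id),
                "stages_changed": stages,
                "pearson_r": comparison.r[
                    comparison.ids.index(a.spec.id), comparison.ids.index(b.spec.id)
                ],
                "dice_positive": dice(a.thresholded, b.thresholded, "positive"),
                "dice_negative": dice(a.thresholded, b.thresholded, "negative"),
            }
        )
    consensus = run_consensus([r.zmap for r in results]) if len(results) >= 2 else None
    return VariabilityReport(
        comparison=comparison, adjacent_deltas=adjacent, consensus=consensus
    )
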