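"""First-level design-matrix construction with interchangeable components.

Task-fMRI software packages differ in three first-level modelling choices
that can be swapped between packages by exchanging columns of the design
matrix: the hemodynamic signal model (HRF shape, parametric modulation,
orthogonalization convention), the low-frequency drift model, and —
indirectly, because it fixes the package executing the fit — the noise
model.  This module builds each block separately so that "hybrid" designs
mixing styles are first-class objects.

Three named HRF presets emulate the canonical difference-of-gammas shapes
of the major packages (``A``/``F``/``S`` styles).  They are emulations
parameterized here, not bit-reproductions of any package's code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EventTable",
    "HrfSpec",
    "DriftSpec",
    "DriftProjection",
    "OrthoScheme",
    "RegressorBlock",
    "DesignMatrix",
    "hrf_kernel",
    "build_signal_regressors",
    "apply_orthogonalization",
    "drift_regressors",
    "assemble_design",
]

Style = Literal["A", "F", "S"]

#: difference-of-gammas parameters per package-style preset:
#: (peak_delay, undershoot_delay, peak_disp, undershoot_disp, undershoot_ratio)
_HRF_PRESETS: dict[str, tuple[float, float, float, float, float]] = {
    # SPM-like canonical: gamma pdf shape 6/1, undershoot at 16, ratio 1/6
    "S": (6.0, 16.0, 1.0, 1.0, 1.0 / 6.0),
    # FSL-like: gammas matched to mean 6 / sd 3 and mean 16 / sd 3
    "F": (6.0, 16.0, 1.5, 0.5625, 1.0 / 6.0),
    # AFNI-like: earlier, tighter peak and a weak undershoot
    "A": (5.6, 12.2, 0.9, 0.9, 0.08),
}


class DesignError(ValueError):
    """Raised for invalid design-construction requests."""


@dataclass(frozen=True)
class HrfSpec:
    """Parameters of a difference-of-gammas hemodynamic response kernel.

    The kernel is ``g(t; peak) - undershoot_ratio * g(t; undershoot)`` with
    each ``g`` a gamma density of shape ``delay/disp`` and scale ``disp``
    (so ``delay`` is the gamma mean in seconds), normalized to unit peak.
    """

    style: Style = "S"
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    include_temporal_derivative: bool = False

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_disp", "undershoot_disp"):
            if getattr(self, name) <= 0:
                raise DesignError(f"HrfSpec.{name} must be positive")
        if self.undershoot_ratio <= 0:
            raise DesignError("HrfSpec.undershoot_ratio must be positive")

    @classmethod
    def preset(cls, style: Style, include_temporal_derivative: bool = False) -> "HrfSpec":
        """Return the named package-style preset."""
        try:
            pd_, ud, pdis, udis, ratio = _HRF_PRESETS[style]
        except KeyError:
            raise DesignError(f"unknown HRF style {style!r}; expected one of {sorted(_HRF_PRESETS)}")
        return cls(
            style=style,
            peak_delay=pd_,
            undershoot_delay=ud,
            peak_disp=pdis,
            undershoot_disp=udis,
            undershoot_ratio=ratio,
            include_temporal_derivative=include_temporal_derivative,
        )


@dataclass(frozen=True)
class DriftSpec:
    """Low-frequency drift model: DCT basis, orthogonal polynomials, or a
    high-pass residualization recipe applied to data and design alike."""

    style: Literal["dct_basis", "polynomial_basis", "highpass_residualization"] = "dct_basis"
    cutoff: float = 128.0  # seconds; dct/highpass styles
    max_degree: int = 2  # polynomial style

    def __post_init__(self) -> None:
        if self.style not in ("dct_basis", "polynomial_basis", "highpass_residualization"):
            raise DesignError(f"unknown drift style {self.style!r}")
        if self.style != "polynomial_basis" and self.cutoff <= 0:
            raise DesignError("cutoff must be positive")
        if self.style == "polynomial_basis" and self.max_degree < 0:
            raise DesignError("max_degree must be >= 0")


@dataclass(frozen=True)
class OrthoScheme:
    """Regressor orthogonalization convention.

    ``serial_preceding`` residualizes each signal column on all preceding
    signal columns in order (the automatic SPM-style behaviour);
    ``pairwise_explicit`` residualizes each named target on one named
    reference (FSL-style user-specified orthogonalization); ``none`` leaves
    the design untouched (AFNI-style default).
    """

    style: Literal["none", "serial_preceding", "pairwise_explicit"] = "none"
    pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for target, ref in self.pairs:
            if target == ref:
                raise DesignError(f"self-orthogonalization pair {target!r}")


@dataclass
class EventTable:
    """Task events: onset/duration in seconds, a condition label, and an
    optional parametric modulation value per event."""

    table: pd.DataFrame

    REQUIRED = ("onset", "duration", "condition")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise DesignError(f"event table missing columns {missing}")
        if "modulation" not in df.columns:
            df = df.assign(modulation=np.nan)
        df = df.reset_index(drop=True)
        if (df["onset"] < 0).any():
            raise DesignError("event onsets must be >= 0")
        if (df["duration"] < 0).any():
            raise DesignError("event durations must be >= 0")
        if df["condition"].astype(str).str.len().eq(0).any():
            raise DesignError("condition labels must be non-empty")
        self.table = df

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        return list(dict.fromkeys(self.table["condition"]))

    @property
    def end_time(self) -> float:
        return float((self.table["onset"] + self.table["duration"]).max())

    def to_tsv(self, path: str | Path) -> None:
        """Write as BIDS-style events TSV (condition stored as trial_type)."""
        out = self.table.rename(columns={"condition": "trial_type"})
        out.to_csv(path, sep="\t", index=False, na_rep="n/a")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EventTable":
        df = pd.read_csv(path, sep="\t", na_values=["n/a"])
        return cls(df.rename(columns={"trial_type": "condition"}))


@dataclass(frozen=True)
class RegressorBlock:
    """A named set of regressor columns plus the package style they came from."""

    columns: pd.DataFrame
    style: str


@dataclass(frozen=True)
class DriftProjection:
    """High-pass drift handling as a residualization recipe.

    Instead of adding basis columns to the model, the fit projects both the
    data and the other design columns onto the orthogonal complement of this
    basis before estimation (span-equivalent to including the columns)."""

    basis: np.ndarray  # (n_frames, n_basis)
    cutoff: float
    style: str = "F"

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Residualize the rows-first array/matrix ``x`` on the basis."""
        b = self.basis
        coef, *_ = np.linalg.lstsq(b, x, rcond=None)
        return x - b @ coef


@dataclass
class DesignMatrix:
    """Assembled first-level design with per-column provenance.

    ``provenance`` maps each column name to ``(block, style)`` where block is
    one of signal/drift/motion.
    """

    frame_times: np.ndarray
    data: pd.DataFrame
    provenance: dict[str, tuple[str, str]]
    drift_projection: DriftProjection | None = None

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.frame_times) != len(self.data):
            raise DesignError("frame_times length does not match design rows")
        if self.data.shape[1] >= len(self.data):
            raise DesignError("design has at least as many columns as frames")
        norms = np.linalg.norm(self.data.to_numpy(), axis=0)
        zero = [c for c, nz in zip(self.data.columns, norms) if nz == 0]
        if zero:
            raise DesignError(f"all-zero design columns: {zero}")
        extra = set(self.data.columns) - set(self.provenance)
        if extra:
            raise DesignError(f"columns without provenance: {sorted(extra)}")

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def columns_in(self, block: str) -> list[str]:
        return [c for c in self.data.columns if self.provenance[c][0] == block]

    def block_styles(self) -> dict[str, str]:
        """Style per provenance block (signal/drift/motion)."""
        styles: dict[str, str] = {}
        for col, (block, style) in self.provenance.items():
            styles.setdefault(block, style)
        return styles

    def hat_matrix(self) -> np.ndarray:
        """Projection matrix onto the design column span (for diagnostics)."""
        x = self.matrix
        return x @ np.linalg.pinv(x)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "frame_times", self.frame_times)
        out.to_csv(path, sep="\t", index=False)
        sidecar = {c: {"block": b, "style": s} for c, (b, s) in self.provenance.items()}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DesignMatrix":
        df = pd.read_csv(path, sep="\t")
        frame_times = df.pop("frame_times").to_numpy()
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        prov = {c: (v["block"], v["style"]) for c, v in sidecar.items()}
        return cls(frame_times, df, prov)


def hrf_kernel(spec: HrfSpec, dt: float, length: float = 32.0) -> np.ndarray:
    """Sample the difference-of-gammas kernel on ``[0, length]`` at step dt.

    The kernel is zero at t=0 (gamma shapes exceed one), rises to a single
    positive peak, undershoots, and is normalized to unit peak amplitude.
    """
    if dt <= 0:
        raise DesignError("dt must be positive")
    if length < spec.peak_delay:
        raise DesignError(
            f"kernel length {length}s too short to contain the peak at ~{spec.peak_delay}s"
        )
    t = np.arange(0, length + dt / 2, dt)
    peak = stats.gamma.pdf(t, spec.peak_delay / spec.peak_disp, scale=spec.peak_disp)
    under = stats.gamma.pdf(
        t, spec.undershoot_delay / spec.undershoot_disp, scale=spec.undershoot_disp
    )
    kernel = peak - spec.undershoot_ratio * under
    return kernel / kernel.max()


def _boxcar(
    events: pd.DataFrame, hi_times: np.ndarray, dt: float, heights: np.ndarray
) -> np.ndarray:
    box = np.zeros_like(hi_times)
    for (onset, duration), h in zip(events[["onset", "duration"]].to_numpy(), heights):
        if duration <= 0:
            box[int(round(onset / dt))] += h
        else:
            box[(hi_times >= onset) & (hi_times < onset + duration)] += h
    return box


def build_signal_regressors(
    events: EventTable,
    hrf: HrfSpec,
    frame_times: np.ndarray,
    oversampling: int = 16,
    kernel: np.ndarray | None = None,
) -> pd.DataFrame:
    """Convolve per-condition (modulated) boxcars with the HRF kernel.

    One column per condition; conditions carrying modulation values use the
    mean-centered values as boxcar heights.  Temporal-derivative columns
    (numerical derivative of the convolved regressor) are appended when the
    spec requests them.  ``kernel`` overrides the HRF kernel (unit-tested
    identity convolutions); it must be sampled at the oversampled step.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if len(frame_times) < 2:
        raise DesignError("need at least two frames")
    tr = float(frame_times[1] - frame_times[0])
    if events.end_time > frame_times[-1] + tr:
        raise DesignError(
            f"events extend to {events.end_time:.1f}s beyond the scan "
            f"({frame_times[-1] + tr:.1f}s)"
        )
    dt = tr / oversampling
    hi_times = np.arange(0.0, frame_times[-1] + tr, dt)
    if kernel is None:
        kernel = hrf_kernel(hrf, dt)

    cols: dict[str, np.ndarray] = {}
    for cond in events.conditions:
        rows = events.table[events.table["condition"] == cond]
        mod = rows["modulation"].to_numpy(dtype=float)
        if np.isfinite(mod).all() and len(mod) > 0:
            heights = mod - mod.mean()
            if np.allclose(heights, 0):
                raise DesignError(
                    f"condition {cond!r}: modulation values are constant; the "
                    "mean-centered regressor would be all zero"
                )
        else:
            heights = np.ones(len(rows))
        conv = np.convolve(_boxcar(rows, hi_times, dt, heights), kernel)[: len(hi_times)]
        cols[cond] = np.interp(frame_times, hi_times, conv)
        if hrf.include_temporal_derivative:
            cols[f"{cond}_derivative"] = np.interp(
                frame_times, hi_times, np.gradient(conv, dt)
            )
    return pd.DataFrame(cols)


def _residualize(target: np.ndarray, reference: np.ndarray) -> np.ndarray:
    denom = reference.T @ reference if reference.ndim == 1 else None
    if reference.ndim == 1:
        if denom < 1e-12:
            raise DesignError("reference column is numerically zero")
        return target - reference * (reference @ target / denom)
    coef, *_ = np.linalg.lstsq(reference, target, rcond=None)
    return target - reference @ coef


def apply_orthogonalization(design: DesignMatrix, scheme: OrthoScheme) -> DesignMatrix:
    """Orthogonalize signal columns per the scheme; the design span is unchanged."""
    if scheme.style == "none":
        return design
    data = design.data.copy()
    signal_cols = design.columns_in("signal")
    if scheme.style == "pairwise_explicit":
        for target, ref in scheme.pairs:
            for name in (target, ref):
                if name not in data.columns:
                    raise DesignError(f"orthogonalization references missing column {name!r}")
            data[target] = _residualize(
                data[target].to_numpy(), data[ref].to_numpy()
            )
    elif scheme.style == "serial_preceding":
        for i, col in enumerate(signal_cols[1:], start=1):
            preceding = data[signal_cols[:i]].to_numpy()
            if np.linalg.norm(preceding) < 1e-12:
                raise DesignError("preceding columns numerically zero")
            data[col] = _residualize(data[col].to_numpy(), preceding)
    else:  # pragma: no cover - validated in OrthoScheme
        raise DesignError(f"unknown orthogonalization style {scheme.style!r}")
    return replace(design, data=data)


def drift_regressors(
    spec: DriftSpec, frame_times: np.ndarray, tr: float
) -> pd.DataFrame | DriftProjection:
    """Build the drift block for one style.

    dct_basis returns ``floor(2 T / cutoff)`` cosine columns (periods >=
    cutoff); polynomial_basis returns discretely orthonormalized polynomials
    up to ``max_degree`` (degree 0 is the constant direction);
    highpass_residualization returns a :class:`DriftProjection` recipe over
    the same DCT basis instead of columns.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    n = len(frame_times)
    if n < 2:
        raise DesignError("need at least two frames for drift modelling")
    if spec.style in ("dct_basis", "highpass_residualization"):
        if spec.cutoff <= 2 * tr:
            raise DesignError(
                f"drift cutoff {spec.cutoff}s must exceed twice the TR ({2 * tr}s)"
            )
        total = n * tr
        k_max = int(np.floor(2 * total / spec.cutoff))
        idx = np.arange(n)
        basis = np.column_stack(
            [np.cos(np.pi * k * (2 * idx + 1) / (2 * n)) for k in range(1, k_max + 1)]
        ) if k_max else np.empty((n, 0))
        basis /= np.sqrt((basis**2).sum(axis=0)) if k_max else 1.0
        if spec.style == "highpass_residualization":
            return DriftProjection(basis=basis, cutoff=spec.cutoff)
        return pd.DataFrame(
            {f"drift_cos_{k}": basis[:, k - 1] for k in range(1, k_max + 1)}
        )
    # polynomial_basis: QR-orthonormalized Vandermonde on [-1, 1]
    x = np.linspace(-1.0, 1.0, n)
    vand = np.column_stack([x**d for d in range(spec.max_degree + 1)])
    q, _ = np.linalg.qr(vand)
    q *= np.sign(q[-1, :])  # fix sign convention (increasing at the end)
    return pd.DataFrame({f"drift_poly_{d}": q[:, d] for d in range(spec.max_degree + 1)})


def _collinear_columns(x: np.ndarray, names: Sequence[str]) -> list[str]:
    _, r = np.linalg.qr(x)
    small = np.abs(np.diag(r)) < 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    return [n for n, s in zip(names, small) if s]


def assemble_design(
    signal: RegressorBlock,
    drift: RegressorBlock | DriftProjection,
    motion: RegressorBlock,
    frame_times: np.ndarray,
    hybrid_overrides: Mapping[str, RegressorBlock] | None = None,
) -> DesignMatrix:
    """Assemble signal + drift + motion blocks into one design matrix.

    ``hybrid_overrides`` replaces the signal and/or drift block with columns
    built under a different package style; the overriding style is recorded
    in the column provenance.  The motion block must contain exactly six
    nuisance series.  Column order is signal, drift, motion; a constant
    column is appended to the drift block when no constant direction is
    present.
    """
    overrides = dict(hybrid_overrides or {})
    unknown = set(overrides) - {"signal", "drift"}
    if unknown:
        raise DesignError(f"hybrid overrides for unknown blocks: {sorted(unknown)}")
    signal = overrides.get("signal", signal)
    drift = overrides.get("drift", drift)

    if motion is None:
        raise DesignError("motion block is required (six nuisance regressors)")
    if motion.columns.shape[1] != 6:
        raise DesignError(
            f"motion block must have exactly 6 columns, got {motion.columns.shape[1]}"
        )

    frame_times = np.asarray(frame_times, dtype=float)
    n = len(frame_times)
    projection: DriftProjection | None = None
    if isinstance(drift, DriftProjection):
        projection = drift
        drift_cols = pd.DataFrame(index=range(n))
        drift_style = drift.style
    else:
        drift_cols = drift.columns.reset_index(drop=True)
        drift_style = drift.style

    data = pd.concat(
        [signal.columns.reset_index(drop=True), drift_cols],
        axis=1,
    )
    has_constant = any(
        np.ptp(data[c].to_numpy()) < 1e-12 and abs(data[c].iloc[0]) > 0
        for c in data.columns
    )
    prov: dict[str, tuple[str, str]] = {}
    for c in signal.columns.columns:
        prov[c] = ("signal", signal.style)
    for c in drift_cols.columns:
        prov[c] = ("drift", drift_style)
    if not has_constant:
        data["constant"] = 1.0
        prov["constant"] = ("drift", drift_style)
    mot = motion.columns.reset_index(drop=True)
    mot.columns = [f"motion_{i}" for i in range(6)]
    for c in mot.columns:
        prov[c] = ("motion", motion.style)
    data = pd.concat([data, mot], axis=1)

    x = data.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x, list(data.columns))
        raise DesignError(f"assembled design is rank deficient; collinear columns: {bad}")
    return DesignMatrix(frame_times, data, prov, drift_projection=projection)
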