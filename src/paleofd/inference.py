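"""Exhaustive SAR-error multimodel inference with Akaike weighting.

Every predictor can enter a model as *absent*, *linear*, or *unimodal*
(linear + quadratic term of the standardized predictor; the quadratic never
appears alone). The full model set is the 3^p factorial over those shapes,
fitted by maximum likelihood with shared spatial machinery, then summarized
by:

* Akaike weights w_i = exp(−Δ_i/2) / Σ exp(−Δ_j/2);
* variable importance W = Σ w_i over models containing the predictor;
* conditional model-averaged standardized coefficients
  Σ w_i β_i / Σ w_i over models containing the term;
* single-predictor unimodal Nagelkerke pseudo-R² per predictor;
* partial residuals r + b·x for effect displays.

Run once per imputed trait replicate and pooled across replicates (mean and
2.5/97.5 percentile interval).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial import SARFit, SpatialWeights, fit_sar_error, nagelkerke_r2

__all__ = [
    "SHAPE_ABSENT",
    "SHAPE_LINEAR",
    "SHAPE_UNIMODAL",
    "ModelSpec",
    "ModelSetResult",
    "InferenceConfig",
    "InferenceResult",
    "enumerate_models",
    "akaike_weights",
    "variable_importance",
    "model_average_coefficients",
    "partial_residuals",
    "fit_model_set",
    "run_inference",
]

SHAPE_ABSENT, SHAPE_LINEAR, SHAPE_UNIMODAL = 0, 1, 2
_SHAPE_NAMES = {SHAPE_ABSENT: "absent", SHAPE_LINEAR: "linear", SHAPE_UNIMODAL: "unimodal"}

LOW_SUPPORT_THRESHOLD = 0.1


@dataclass(frozen=True)
class ModelSpec:
    """Shape assignment per predictor; hashable, deterministic ordering."""

    shapes: tuple[int, ...]

    def includes(self, j: int) -> bool:
        return self.shapes[j] != SHAPE_ABSENT

    @property
    def n_included(self) -> int:
        return sum(s != SHAPE_ABSENT for s in self.shapes)

    def describe(self, names: list[str]) -> str:
        parts = [
            f"{names[j]}:{_SHAPE_NAMES[s]}"
            for j, s in enumerate(self.shapes)
            if s != SHAPE_ABSENT
        ]
        return "+".join(parts) if parts else "intercept-only"


def enumerate_models(
    predictors: list[str], max_predictors: int | None = None
) -> list[ModelSpec]:
    """Full factorial over {absent, linear, unimodal} per predictor.

    3^p specs including the intercept-only model, lexicographic in
    (predictor index, shape); optionally truncated to models with at most
    ``max_predictors`` included predictors.
    """
    p = len(predictors)
    if p < 1:
        raise ValueError("need at least one predictor")
    if p > 12 and max_predictors is None:
        warnings.warn(f"enumerating 3^{p} = {3**p} models; consider max_predictors")
    specs = [ModelSpec(shapes) for shapes in itertools.product((0, 1, 2), repeat=p)]
    if max_predictors is not None:
        specs = [s for s in specs if s.n_included <= max_predictors]
    return specs


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    """w_i = exp(−Δ_i/2) normalized; Δ_i = AIC_i − min AIC."""
    aics = np.asarray(aics, dtype=float)
    if not np.all(np.isfinite(aics)):
        raise ValueError("AIC values must be finite")
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelSetResult:
    """All fits of one exhaustive enumeration on one response."""

    predictor_names: list[str]
    specs: list[ModelSpec]
    fits: list[SARFit]
    weights: np.ndarray
    replicate: int = 0
    seed: int | None = None

    def model_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [s.describe(self.predictor_names) for s in self.specs],
                "n_predictors": [s.n_included for s in self.specs],
                "k": [f.k for f in self.fits],
                "log_likelihood": [f.log_likelihood for f in self.fits],
                "aic": [f.aic for f in self.fits],
                "weight": self.weights,
                "lambda": [f.lambda_ for f in self.fits],
            }
        )


def variable_importance(result: ModelSetResult, predictor: str | int) -> float:
    """W = summed Akaike weight of every model including the predictor."""
    j = (
        predictor
        if isinstance(predictor, int)
        else result.predictor_names.index(predictor)
    )
    return float(sum(w for s, w in zip(result.specs, result.weights) if s.includes(j)))


def model_average_coefficients(result: ModelSetResult) -> pd.DataFrame:
    """Conditional (renormalized) weighted average of standardized terms.

    For each term — linear ``b`` or quadratic ``b2`` of each predictor —
    the average is Σ w_i β_i / Σ w_i over the models that contain the term.
    Terms with total containing weight below ``LOW_SUPPORT_THRESHOLD`` are
    kept but flagged; a term contained nowhere gets NaN.
    """
    rows = []
    for j, name in enumerate(result.predictor_names):
        for term, needed in ((f"{name}:b", (1, 2)), (f"{name}:b2", (2,))):
            wsum = 0.0
            acc = 0.0
            for spec, fit, w in zip(result.specs, result.fits, result.weights):
                if spec.shapes[j] in needed:
                    col = name if term.endswith(":b") else f"{name}^2"
                    acc += w * fit.coef(col)
                    wsum += w
            rows.append(
                {
                    "term": term,
                    "coefficient": acc / wsum if wsum > 0 else np.nan,
                    "support": wsum,
                    "low_support": wsum < LOW_SUPPORT_THRESHOLD,
                }
            )
    return pd.DataFrame(rows)


def partial_residuals(
    fit: SARFit, X: np.ndarray, y: np.ndarray, term: str
) -> np.ndarray:
    """r + b·x for one term of a multi-predictor fit.

    r are the fit's response-scale residuals y − Xβ̂ and b the term's
    coefficient, so plotting against x shows the term's effect with every
    other modeled variable statistically controlled.
    """
    j = fit.term_names.index(term)
    resid = y - np.asarray(X, dtype=float) @ fit.beta
    return resid + fit.beta[j] * np.asarray(X, dtype=float)[:, j]


def _design_for(spec: ModelSpec, names, lin_cols, quad_cols):
    cols = [np.ones(lin_cols.shape[0])]
    col_names = ["intercept"]
    for j, s in enumerate(spec.shapes):
        if s >= SHAPE_LINEAR:
            cols.append(lin_cols[:, j])
            col_names.append(names[j])
        if s == SHAPE_UNIMODAL:
            cols.append(quad_cols[:, j])
            col_names.append(f"{names[j]}^2")
    return np.column_stack(cols), col_names


def fit_model_set(
    y: np.ndarray,
    predictors: pd.DataFrame,
    W: SpatialWeights,
    max_predictors: int | None = None,
    replicate: int = 0,
) -> ModelSetResult:
    """Fit the exhaustive model set on one (already standardized) response.

    The response and each predictor column are z-scored here so all
    reported coefficients are standardized; quadratic columns are squares
    of the standardized predictors. Sparse products Wy / WX are shared
    across the whole enumeration.
    """
    names = list(predictors.columns)
    yz = _zscore(np.asarray(y, dtype=float))
    lin = np.column_stack(
        [_zscore(predictors[c].to_numpy(dtype=float)) for c in names]
    )
    quad = lin**2
    specs = enumerate_models(names, max_predictors)
    Wy = W.W @ yz
    Wlin = W.W @ lin
    Wquad = W.W @ quad
    Wones = W.W @ np.ones(len(yz))  # = 1 for row-standardized W
    fits: list[SARFit] = []
    for spec in specs:
        X, col_names = _design_for(spec, names, lin, quad)
        WX_cols = [Wones[:, None]]
        for j, s in enumerate(spec.shapes):
            if s >= SHAPE_LINEAR:
                WX_cols.append(Wlin[:, j : j + 1])
            if s == SHAPE_UNIMODAL:
                WX_cols.append(Wquad[:, j : j + 1])
        WX = np.column_stack([c.ravel() for c in WX_cols]) if len(WX_cols) > 1 else Wones[:, None]
        fits.append(
            fit_sar_error(X, yz, W, term_names=col_names, Wy=Wy, WX=WX)
        )
    weights = akaike_weights(np.array([f.aic for f in fits]))
    return ModelSetResult(
        predictor_names=names, specs=specs, fits=fits,
        weights=weights, replicate=replicate,
    )


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("constant column cannot be standardized")
    return (v - v.mean()) / sd


@dataclass
class InferenceConfig:
    """Knobs for a full multimodel-inference run."""

    log10_predictors: list[str] = field(default_factory=list)
    max_predictors: int | None = None
    response: str = "f_rich"


@dataclass
class InferenceResult:
    per_replicate: list[ModelSetResult]
    importance: pd.DataFrame          # pooled W per predictor
    averaged_coefficients: pd.DataFrame
    single_predictor_r2: pd.DataFrame
    response: str


def run_inference(
    pred: pd.DataFrame,
    fd_per_replicate: list[pd.Series],
    W: SpatialWeights,
    config: InferenceConfig | None = None,
) -> InferenceResult:
    """Exhaustive inference per imputation replicate, pooled across them.

    ``pred`` holds one row per cell (aligned with the weights); configured
    skewed predictors are log10-transformed before z-scoring. Cells whose
    response is NaN in *any* replicate (species-poor cells with undefined
    hull volume) are dropped from every replicate so the model sets stay
    comparable; the weights matrix is rebuilt on the retained cells.

    Pooled importance and pseudo-R² report the replicate mean with the
    empirical 2.5–97.5 percentile interval.
    """
    from .spatial import build_weights  # local to avoid cycle at import time

    config = config or InferenceConfig()
    pred_t = pred.copy()
    for col in config.log10_predictors:
        vals = pred_t[col].to_numpy(dtype=float)
        if (vals <= 0).any():
            floor = np.min(vals[vals > 0]) / 10.0 if (vals > 0).any() else 1e-6
            vals = np.maximum(vals, floor)
        pred_t[col] = np.log10(vals)

    responses = [s.to_numpy(dtype=float) for s in fd_per_replicate]
    keep = np.all([np.isfinite(r) for r in responses], axis=0)
    if not keep.all():
        pred_t = pred_t.loc[keep]
        responses = [r[keep] for r in responses]
        W = build_weights(W.coords[keep], rule=W.rule)
    for s in fd_per_replicate:
        if len(s) != keep.size:
            raise ValueError("FD replicate not aligned with predictor table")

    names = list(pred_t.columns)
    per_rep: list[ModelSetResult] = []
    imp_rows, r2_rows, coef_frames = [], [], []
    for r_idx, y in enumerate(responses):
        res = fit_model_set(y, pred_t, W, config.max_predictors, replicate=r_idx)
        per_rep.append(res)
        imp_rows.append([variable_importance(res, j) for j in range(len(names))])
        coef_frames.append(model_average_coefficients(res).set_index("term"))
        # single-predictor unimodal explained variance
        null = _fit_single(None, pred_t, y, W)
        r2s = []
        for name in names:
            fit1 = _fit_single(name, pred_t, y, W)
            r2s.append(nagelkerke_r2(fit1, null))
        r2_rows.append(r2s)

    imp = np.array(imp_rows)
    r2 = np.array(r2_rows)
    importance = pd.DataFrame(
        {
            "predictor": names,
            "importance_mean": imp.mean(axis=0),
            "importance_lo": np.percentile(imp, 2.5, axis=0),
            "importance_hi": np.percentile(imp, 97.5, axis=0),
        }
    )
    single_r2 = pd.DataFrame(
        {
            "predictor": names,
            "pseudo_r2_mean": r2.mean(axis=0),
            "pseudo_r2_lo": np.percentile(r2, 2.5, axis=0),
            "pseudo_r2_hi": np.percentile(r2, 97.5, axis=0),
        }
    )
    coef_stack = pd.concat(coef_frames, keys=range(len(coef_frames)), names=["replicate"])
    averaged = (
        coef_stack.groupby("term", sort=False)
        .agg(
            coefficient_mean=("coefficient", "mean"),
            support_mean=("support", "mean"),
        )
        .reset_index()
    )
    averaged["low_support"] = averaged["support_mean"] < LOW_SUPPORT_THRESHOLD
    return InferenceResult(
        per_replicate=per_rep,
        importance=importance,
        averaged_coefficients=averaged,
        single_predictor_r2=single_r2,
        response=config.response,
    )


def _fit_single(name: str | None, pred: pd.DataFrame, y, W) -> SARFit:
    yz = _zscore(np.asarray(y, dtype=float))
    if name is None:
        X = np.ones((len(yz), 1))
        return fit_sar_error(X, yz, W, term_names=["intercept"])
    xz = _zscore(pred[name].to_numpy(dtype=float))
    X = np.column_stack([np.ones(len(yz)), xz, xz**2])
    return fit_sar_error(X, yz, W, term_names=["intercept", name, f"{name}^2"])
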