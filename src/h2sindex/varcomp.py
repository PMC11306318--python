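"""Variance-components mixed model on daily index values.

The exposure index for person *i* on day *j* is modelled (by default on the
log scale) as

    y_ij = mu + seg_i + season_j + b_i + e_ij,     b_i ~ N(0, sB²),
                                                   e_ij ~ N(0, sW²)

with fixed effects for similar-exposure group (SEG) and season and a random
intercept per worker, estimated by restricted maximum likelihood.  The
quantity of interest is the decomposition of the residual variance into the
between-worker component sB² and the within-worker component sW²; highly
task-driven exposures such as H₂S are dominated by the within-worker part.

Also here: model comparison by −2·log-likelihood, cell-mean prediction with
95% confidence intervals (back-transformed when the response is logged),
and the seeded split-half robustness procedure (random bipartition with
50% ± 2.5% of datapoints in each half overall and 50% ± 3.5% within every
SEG).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf

from .cohort import StudyDataset, dataset_to_frame
from .errors import ConfigError, ModelError

__all__ = [
    "ModelSpec",
    "VarCompResult",
    "SplitResult",
    "fit_varcomp",
    "compare_models",
    "predict_cell_mean",
    "robustness_split",
    "verify_split",
]


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response transform, fixed factors, random grouping."""

    fixed: tuple[str, ...] = ("seg", "season")
    random: str = "person_id"
    log_response: bool = True
    reml: bool = True

    def __post_init__(self) -> None:
        if not self.fixed:
            raise ConfigError("at least one fixed factor is required")

    @property
    def formula(self) -> str:
        rhs = " + ".join(f"C({f})" for f in self.fixed)
        return f"_y ~ {rhs}"


@dataclass
class VarCompResult:
    """Fitted fixed effects, variance components and fit metadata."""

    fixed_effects: pd.DataFrame
    var_between_person: float
    var_within_person: float
    neg2_loglik: float
    n_obs: int
    n_persons: int
    spec: ModelSpec
    converged: bool = True
    _design_info: object = field(default=None, repr=False)
    _params: np.ndarray = field(default=None, repr=False)
    _cov_params: np.ndarray = field(default=None, repr=False)
    _response_digest: str = field(default="", repr=False)

    @property
    def within_fraction(self) -> float:
        """Share of total random variance that is within-worker."""
        total = self.var_between_person + self.var_within_person
        return self.var_within_person / total if total > 0 else float("nan")


@dataclass
class SplitResult:
    """A verified random bipartition of the model frame."""

    part1: pd.DataFrame
    part2: pd.DataFrame
    n_iterations: int
    seed: int
    overall_tol: float = 0.025
    seg_tol: float = 0.035


def _prepare_frame(data, spec: ModelSpec) -> pd.DataFrame:
    if isinstance(data, StudyDataset):
        df = data.model_frame()
    else:
        df = data.copy()
    needed = set(spec.fixed) | {spec.random, "index"}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigError(f"model frame lacks columns: {sorted(missing)}")
    # days without factor metadata (e.g. no logbook -> no SEG) cannot enter
    cols = sorted(needed)
    complete = df[cols].notna().all(axis=1) & (df[cols].astype(str) != "").all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logging.getLogger(__name__).warning(
            "dropping %d rows with missing model metadata", n_dropped
        )
        df = df[complete].copy()
    if df.empty:
        raise ModelError("no rows with complete model metadata")
    df = df.reset_index(drop=True)
    if spec.log_response:
        if (df["index"] <= 0).any():
            n_bad = int((df["index"] <= 0).sum())
            raise ModelError(
                f"log response requires positive index values; {n_bad} rows are <= 0 "
                "(impute censored days first, exclude real zeros)"
            )
        df["_y"] = np.log(df["index"].astype(float))
    else:
        df["_y"] = df["index"].astype(float)
    return df


def fit_varcomp(data, spec: ModelSpec = ModelSpec()) -> VarCompResult:
    """Fit the worker-random-intercept model by REML (statsmodels MixedLM).

    ``data`` is a StudyDataset (its measured-day model frame is used) or a
    DataFrame with columns ``index``, the fixed factors, and the random
    grouping.  Deterministic given data and spec.  A fixed factor with a
    single observed level triggers an informative error naming the factor.
    """
    df = _prepare_frame(data, spec)
    n_persons = df[spec.random].nunique()
    if n_persons < 2:
        raise ModelError("need at least 2 persons to separate variance components")
    if not (df.groupby(spec.random).size() >= 2).any():
        raise ModelError("need repeated days for at least one person")
    for f in spec.fixed:
        levels = df[f].dropna().unique()
        if len(levels) < 2:
            raise ModelError(
                f"fixed factor {f!r} has a single observed level ({levels.tolist()}); "
                "drop it from the spec or supply richer data"
            )
    model = smf.mixedlm(spec.formula, df, groups=df[spec.random].to_numpy())
    try:
        fit = model.fit(reml=spec.reml)
    except np.linalg.LinAlgError:
        # boundary optimum (between-person variance ~ 0) can make the
        # gradient path singular; a derivative-free pass is robust there
        try:
            fit = model.fit(reml=spec.reml, method="powell")
        except Exception as exc:
            raise ModelError(f"mixed-model fit failed: {exc}") from exc
    except Exception as exc:  # singular designs surface here
        raise ModelError(f"mixed-model fit failed: {exc}") from exc
    k_fe = model.k_fe
    fe = pd.DataFrame(
        {
            "coef": fit.params[:k_fe],
            "se": fit.bse[:k_fe],
            "z": fit.tvalues[:k_fe],
            "p": fit.pvalues[:k_fe],
        }
    )
    var_between = float(fit.cov_re.iloc[0, 0])
    var_within = float(fit.scale)
    digest = hashlib.sha256(np.ascontiguousarray(df["_y"].to_numpy()).tobytes()).hexdigest()
    return VarCompResult(
        fixed_effects=fe,
        var_between_person=var_between,
        var_within_person=var_within,
        neg2_loglik=float(-2.0 * fit.llf),
        n_obs=int(len(df)),
        n_persons=int(n_persons),
        spec=spec,
        converged=bool(fit.converged),
        _design_info=model.data.design_info,
        _params=fit.params[:k_fe].to_numpy(),
        _cov_params=np.asarray(fit.cov_params())[:k_fe, :k_fe],
        _response_digest=digest,
    )


def compare_models(r1: VarCompResult, r2: VarCompResult) -> dict:
    """Compare two fits of the same response by −2·log-likelihood.

    A decrease means a better fit, so the model with the smaller value
    wins.  Fits on different responses (different n or values) are not
    comparable and raise.
    """
    if r1.n_obs != r2.n_obs:
        raise ModelError(f"models fit different n_obs ({r1.n_obs} vs {r2.n_obs})")
    if r1._response_digest and r2._response_digest and r1._response_digest != r2._response_digest:
        raise ModelError("models were fit to different response vectors")
    delta = r1.neg2_loglik - r2.neg2_loglik
    better = "model2" if delta > 0 else ("model1" if delta < 0 else "tie")
    return {
        "neg2_loglik_1": r1.neg2_loglik,
        "neg2_loglik_2": r2.neg2_loglik,
        "delta": delta,
        "better": better,
    }


def predict_cell_mean(result: VarCompResult, cell: dict[str, str]) -> tuple[float, tuple[float, float]]:
    """Estimated mean index for one factor cell, with a 95% CI.

    The estimate is the fixed-effect linear combination for the cell; the
    CI is Wald-type and symmetric on the model scale.  When the response
    was log-transformed, point and CI are exponentiated (hence asymmetric
    on the index scale).
    """
    missing = [f for f in result.spec.fixed if f not in cell]
    if missing:
        raise ConfigError(f"cell must specify levels for {missing}")
    row = pd.DataFrame({k: [v] for k, v in cell.items()})
    try:
        X = np.asarray(patsy.dmatrix(result._design_info, row))
    except Exception as exc:
        raise ModelError(f"cell {cell} uses a level unseen in the fit: {exc}") from exc
    est = float(np.squeeze(X @ result._params))
    var = float(np.squeeze(X @ result._cov_params @ X.T))
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    lo, hi = est - half, est + half
    if result.spec.log_response:
        return math.exp(est), (math.exp(lo), math.exp(hi))
    return est, (lo, hi)


# ---------------------------------------------------------------------------
# Split-half robustness


def verify_split(
    part1: pd.DataFrame,
    part2: pd.DataFrame,
    *,
    seg_col: str = "seg",
    overall_tol: float = 0.025,
    seg_tol: float = 0.035,
) -> bool:
    """Independent check of the split-half constraints.

    Each part must hold 50% ± overall_tol of all datapoints and
    50% ± seg_tol within every SEG.
    """
    n = len(part1) + len(part2)
    if n == 0:
        return False
    if abs(len(part1) / n - 0.5) > overall_tol + 1e-12:
        return False
    segs = set(part1[seg_col]) | set(part2[seg_col])
    for s in segs:
        n1 = int((part1[seg_col] == s).sum())
        n2 = int((part2[seg_col] == s).sum())
        if n1 + n2 == 0 or abs(n1 / (n1 + n2) - 0.5) > seg_tol + 1e-12:
            return False
    return True


def robustness_split(
    data,
    seed: int,
    max_iter: int = 100_000,
    *,
    seg_col: str = "seg",
    overall_tol: float = 0.025,
    seg_tol: float = 0.035,
) -> SplitResult:
    """Random bipartition of the positive-measurement frame for robustness.

    Datapoints are assigned to the halves by independent fair coin flips,
    re-drawn until each half holds 50% ± 2.5% of all datapoints and
    50% ± 3.5% within every SEG.  Reproducible from ``seed``; the number of
    draws needed is reported.  A SEG too small to split within tolerance
    (e.g. a single datapoint) is detected up front and named.
    """
    df = data.model_frame() if isinstance(data, StudyDataset) else data.reset_index(drop=True)
    if len(df) < 2:
        raise ModelError("need at least 2 datapoints to split")
    for s, cnt in df[seg_col].value_counts().items():
        lo = math.ceil(cnt * (0.5 - seg_tol) - 1e-9)
        hi = math.floor(cnt * (0.5 + seg_tol) + 1e-9)
        if lo > hi:
            raise ModelError(
                f"SEG {s!r} with {cnt} datapoint(s) cannot be split within ±{seg_tol:.1%}"
            )
    rng = np.random.default_rng(seed)
    for iteration in range(1, max_iter + 1):
        assign = rng.random(len(df)) < 0.5
        p1, p2 = df[assign], df[~assign]
        if verify_split(p1, p2, seg_col=seg_col, overall_tol=overall_tol, seg_tol=seg_tol):
            return SplitResult(
                part1=p1.reset_index(drop=True),
                part2=p2.reset_index(drop=True),
                n_iterations=iteration,
                seed=seed,
                overall_tol=overall_tol,
                seg_tol=seg_tol,
            )
    raise ModelError(f"no admissible split found in {max_iter} iterations")
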