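"""Linear epigenetic-age predictors ("clocks") and age acceleration.

A clock is a linear map from beta-values at a fixed CpG set to predicted
age in years. The module ships the published Illumina-retrained 3-CpG
predictor

    predicted age = 111.83 - 64.57 b(cg02228185)
                           - 42.57 b(cg25809905)
                           + 75.15 b(cg17861230)

and provides training of new multi-CpG clocks (OLS or elastic net) with
leave-one-out cross-validation for honest error reporting, single-CpG
clocks, and the evaluation metrics used throughout: Pearson correlation of
predicted with chronological age, median absolute error, and the mean/SD of
the age acceleration delta_age = predicted - chronological (positive values
mean the sample looks epigenetically older than its chronological age).

Predictions are deliberately not clamped to plausible ages so the linearity
invariants of the predictor hold exactly.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import warnings

import numpy as np
import pandas as pd

from .io import ClockModel, MethylationMatrix, read_clock

__all__ = [
    "three_cpg_clock",
    "predict_age",
    "compute_delta_age",
    "train_clock_loocv",
    "train_single_cpg",
    "evaluate_predictions",
    "EvaluationMetrics",
]


@dataclasses.dataclass
class EvaluationMetrics:
    """Agreement between predicted and chronological age.

    ``median_abs_error`` is the median of |delta_age| in years; a pure
    offset between predicted and chronological age inflates it without
    reducing ``pearson_r``.
    """

    pearson_r: float
    median_abs_error: float
    mean_delta: float
    sd_delta: float
    n: int


def three_cpg_clock() -> ClockModel:
    """The published 3-CpG age predictor retrained for Illumina 450K data.

    CpGs are associated with the genes ASPA (cg02228185), ITGA2B
    (cg25809905) and PDE4C (cg17861230).
    """
    path = importlib.resources.files("methclock").joinpath("data/clock_3cpg.tsv")
    with importlib.resources.as_file(path) as p:
        return read_clock(p, name="3-CpG")


def predict_age(
    clock: ClockModel,
    matrix: MethylationMatrix,
    missing: str = "error",
) -> pd.Series:
    """Predict age (years) for every sample of a beta matrix.

    Parameters
    ----------
    missing
        Policy when a clock CpG is absent from the matrix or has missing
        beta-values: ``"error"`` (default) raises listing the absent
        probes; ``"impute_mean"`` fills each missing beta with the probe's
        mean over the supplied cohort (absent probes use the mean of the
        clock's own probes present, a last-resort fallback).
    """
    if missing not in {"error", "impute_mean"}:
        raise ValueError(f"missing policy must be 'error' or 'impute_mean', got {missing!r}")
    absent = clock.cpg_ids.difference(matrix.probe_ids)
    if len(absent) and missing == "error":
        raise KeyError(
            f"matrix lacks clock CpG(s) {sorted(absent)} required by model "
            f"{clock.name!r}; pass missing='impute_mean' to impute"
        )
    betas = matrix.values.reindex(clock.cpg_ids)
    if missing == "impute_mean":
        row_means = betas.mean(axis=1)
        if row_means.isna().any():  # probe entirely absent
            row_means = row_means.fillna(row_means.mean())
        betas = betas.T.fillna(row_means).T
    elif betas.isna().any().any():
        bad = betas.index[betas.isna().any(axis=1)].tolist()
        raise ValueError(
            f"missing beta-values at clock CpG(s) {bad}; pass "
            f"missing='impute_mean' to impute"
        )
    pred = clock.intercept + betas.T.to_numpy() @ clock.coefficients.to_numpy()
    return pd.Series(pred, index=matrix.sample_ids, name="predicted_age")


def compute_delta_age(
    predicted: pd.Series,
    chronological: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Age acceleration per sample: delta_age = predicted - chronological.

    Returns a DataFrame with columns ``sample_id``, ``predicted_age``,
    ``chronological_age``, ``delta_age``. Positive delta_age means
    epigenetic age acceleration.
    """
    predicted = pd.Series(predicted)
    chron = np.asarray(chronological, dtype=float)
    if len(predicted) != len(chron):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(chron)} ages"
        )
    return pd.DataFrame(
        {
            "sample_id": predicted.index.astype(str),
            "predicted_age": predicted.to_numpy(float),
            "chronological_age": chron,
            "delta_age": predicted.to_numpy(float) - chron,
        }
    )


def _ols_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares fit with an explicit rank check on the design."""
    design = np.column_stack([np.ones(len(X)), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient design (constant or collinear CpG beta-values); "
            "use method='elastic_net' or drop degenerate probes"
        )
    return coef


def train_clock_loocv(
    matrix: MethylationMatrix,
    ages: pd.Series | np.ndarray,
    cpg_ids: list[str] | None = None,
    method: str = "ols",
    alpha: float = 0.01,
    l1_ratio: float = 0.5,
    name: str | None = None,
) -> tuple[ClockModel, pd.Series]:
    """Train a multi-CpG clock with leave-one-out cross-validation.

    The returned model is fit on all samples; the returned per-sample LOOCV
    predictions (each sample predicted by a model refit without it) give an
    honest error estimate. ``method="ols"`` is ordinary least squares with a
    rank check; ``method="elastic_net"`` uses a penalized fit (scikit-learn)
    for wide or collinear CpG sets.
    """
    if method not in {"ols", "elastic_net"}:
        raise ValueError(f"method must be 'ols' or 'elastic_net', got {method!r}")
    cpg_ids = list(cpg_ids) if cpg_ids is not None else matrix.probe_ids.tolist()
    sub = matrix.subset_probes(cpg_ids)
    X = sub.values.T.to_numpy(float)  # samples x CpGs
    if np.isnan(X).any():
        raise ValueError("missing beta-values in training matrix; impute or drop first")
    y = np.asarray(ages, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError(f"length mismatch: {X.shape[0]} samples vs {len(y)} ages")
    n, p = X.shape
    if method == "ols" and n < p + 2:
        raise ValueError(f"need at least {p + 2} samples to fit and cross-validate {p} CpGs")

    if method == "ols":
        def fit(Xf: np.ndarray, yf: np.ndarray):
            coef = _ols_fit(Xf, yf)
            return coef[0], coef[1:]
    else:
        from sklearn.linear_model import ElasticNet

        def fit(Xf: np.ndarray, yf: np.ndarray):
            est = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=50_000)
            est.fit(Xf, yf)
            return float(est.intercept_), est.coef_.copy()

    intercept, coefs = fit(X, y)
    loo = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        b0, b = fit(X[mask], y[mask])
        loo[i] = b0 + X[i] @ b
        mask[i] = True
    model = ClockModel(
        name or f"retrained-{p}CpG-{method}",
        intercept,
        pd.Series(coefs, index=pd.Index(cpg_ids)),
    )
    return model, pd.Series(loo, index=sub.sample_ids, name="loocv_predicted_age")


def train_single_cpg(
    matrix: MethylationMatrix,
    ages: pd.Series | np.ndarray,
    cpg_id: str,
) -> ClockModel:
    """Univariate least-squares age predictor from a single CpG.

    Fits age ~ beta and returns the line as a 1-CpG clock.
    """
    if cpg_id not in matrix.probe_ids:
        raise KeyError(f"probe {cpg_id!r} not in matrix")
    beta = matrix.values.loc[cpg_id].to_numpy(float)
    y = np.asarray(ages, dtype=float)
    if len(y) != len(beta):
        raise ValueError(f"length mismatch: {len(beta)} samples vs {len(y)} ages")
    if len(y) < 3:
        raise ValueError("need at least 3 samples to train a single-CpG clock")
    if np.ptp(beta) == 0:
        raise ValueError(f"probe {cpg_id!r} has zero beta variance; cannot fit age ~ beta")
    coef = _ols_fit(beta[:, None], y)
    return ClockModel(
        f"single:{cpg_id}", coef[0], pd.Series([coef[1]], index=pd.Index([cpg_id]))
    )


def evaluate_predictions(predictions: pd.DataFrame) -> EvaluationMetrics:
    """Summarize prediction quality from a ``compute_delta_age`` table."""
    pred = predictions["predicted_age"].to_numpy(float)
    chron = predictions["chronological_age"].to_numpy(float)
    delta = predictions["delta_age"].to_numpy(float)
    if len(pred) < 2:
        raise ValueError("need at least 2 samples to evaluate predictions")
    if np.std(pred) == 0 or np.std(chron) == 0:
        warnings.warn(
            "zero variance in predicted or chronological age; Pearson r undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        r = float("nan")
    else:
        r = float(np.corrcoef(pred, chron)[0, 1])
    return EvaluationMetrics(
        pearson_r=r,
        median_abs_error=float(np.median(np.abs(delta))),
        mean_delta=float(np.mean(delta)),
        sd_delta=float(np.std(delta, ddof=1)),
        n=len(pred),
    )
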