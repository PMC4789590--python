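"""End-to-end study orchestration: train on one cohort, test on another.

The canonical design mirrors how epigenetic-clock mortality studies are
run: a clock is taken as published or (re)trained on a reference cohort,
applied to an independent test cohort, the age acceleration delta_age is
computed there, and its association with all-cause mortality is tested by
Cox regression (adjusted for chronological age and sex, hazard ratio per 5
years of delta_age, deaths in the first 2 years of follow-up excluded) and
visualized by Kaplan-Meier curves of the extreme delta_age quartiles. A
per-CpG screen repeats the analysis with single-CpG clocks across a CpG
family and controls the FDR by Benjamini-Hochberg within that family.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clocks import (
    compute_delta_age,
    evaluate_predictions,
    predict_age,
    three_cpg_clock,
    train_clock_loocv,
    train_single_cpg,
)
from .io import ClockModel, MethylationMatrix, read_clock
from .simulate import SyntheticCohort
from .survival import (
    bh_adjust,
    cox_fit,
    km_estimate,
    logrank_test,
    prepare_survival,
    quartile_stratify,
)

__all__ = [
    "resolve_clock",
    "run_clock_mortality",
    "run_cpg_screen",
    "run_cross_cohort_check",
    "config_hash",
    "save_report",
]

logger = logging.getLogger("methclock")

Cohort = "SyntheticCohort | tuple[MethylationMatrix, pd.DataFrame]"


def _unpack(cohort) -> tuple[MethylationMatrix, pd.DataFrame]:
    if isinstance(cohort, SyntheticCohort):
        return cohort.matrix, cohort.annotation
    matrix, annotation = cohort
    return matrix, annotation


def resolve_clock(
    clock: str | ClockModel | tuple,
    train: "Cohort | None" = None,
) -> tuple[ClockModel, pd.Series | None]:
    """Resolve a clock choice into a fitted ClockModel.

    Choices: ``"three_cpg"``; ``"file:<path>"``; ``("retrain", cpg_ids)``
    to refit on the training cohort by LOOCV-backed OLS; ``("single",
    cpg_id)`` for a univariate clock; or a ready ClockModel. Returns the
    model and, for retrained clocks, the LOOCV predictions on the training
    cohort (None otherwise).
    """
    if isinstance(clock, ClockModel):
        return clock, None
    if clock == "three_cpg":
        return three_cpg_clock(), None
    if isinstance(clock, str) and clock.startswith("file:"):
        return read_clock(clock[5:]), None
    if isinstance(clock, tuple) and len(clock) == 2:
        kind, arg = clock
        if train is None:
            raise ValueError(f"clock choice {kind!r} requires a training cohort")
        matrix, annotation = _unpack(train)
        ages = annotation["age"].to_numpy(float)
        if kind == "retrain":
            model, loo = train_clock_loocv(matrix, ages, cpg_ids=arg)
            return model, loo
        if kind == "single":
            return train_single_cpg(matrix, ages, arg), None
    raise ValueError(f"unrecognized clock choice: {clock!r}")


def run_clock_mortality(
    train,
    test,
    clock: str | ClockModel | tuple = "three_cpg",
    exclude_years: float = 2.0,
    scale_years: float = 5.0,
    ties: str = "efron",
    seed: int | None = None,
) -> dict[str, Any]:
    """Full clock-vs-mortality analysis; returns a JSON-serializable report.

    Stages: resolve/train the clock, predict epigenetic age on the test
    cohort, compute delta_age, Cox regression of mortality on delta_age /
    ``scale_years`` adjusted for age and sex (early deaths excluded), and
    Kaplan-Meier curves with a log-rank test for the lowest (Q1) vs highest
    (Q4) delta_age quartiles.
    """
    train_matrix, train_ann = _unpack(train)
    test_matrix, test_ann = _unpack(test)
    model, loo = resolve_clock(clock, train)
    absent = model.cpg_ids.difference(test_matrix.probe_ids)
    if len(absent):
        raise KeyError(f"test cohort lacks clock CpG(s): {sorted(absent)[:5]}")

    report: dict[str, Any] = {
        "clock": {
            "name": model.name,
            "intercept": model.intercept,
            "n_cpgs": int(len(model.cpg_ids)),
        },
        "evaluation": {},
    }

    if loo is not None:
        loo_pred = compute_delta_age(loo, train_ann["age"].to_numpy(float))
        report["evaluation"]["train_loocv"] = vars(evaluate_predictions(loo_pred))

    pred = predict_age(model, test_matrix)
    delta = compute_delta_age(pred, test_ann["age"].to_numpy(float))
    report["evaluation"]["test"] = vars(evaluate_predictions(delta))

    table = prepare_survival(
        test_ann, delta["delta_age"].to_numpy(), exclude_years=exclude_years,
        scale_years=scale_years,
    )
    n_excluded = len(test_ann) - len(table)
    logger.info(
        "survival table: %d samples (%d early deaths excluded), %d events",
        len(table), n_excluded, int(table["event"].sum()),
    )
    cox = cox_fit(table, ["delta_scaled", "age", "sex_male"], ties=ties)
    report["cox"] = {
        "summary": cox.summary.reset_index().to_dict(orient="records"),
        "n_used": cox.n_used,
        "n_events": cox.n_events,
        "n_excluded_early_deaths": int(n_excluded),
        "ties": cox.ties,
        "loglik": cox.loglik,
    }

    quartiles = quartile_stratify(delta["delta_age"])
    report["quartiles"] = {"counts": quartiles.value_counts().sort_index().to_dict()}
    km_report = {}
    for q in ("Q1", "Q4"):
        in_q = (quartiles == q).to_numpy()
        curve = km_estimate(
            test_ann.loc[in_q, "surv_time"].to_numpy(),
            test_ann.loc[in_q, "event"].to_numpy(),
        )
        km_report[q] = curve.to_frame().to_dict(orient="list")
    extreme = quartiles.isin(["Q1", "Q4"]).to_numpy()
    chi2, p = logrank_test(
        test_ann.loc[extreme, "surv_time"].to_numpy(),
        test_ann.loc[extreme, "event"].to_numpy(),
        quartiles[extreme].to_numpy(),
    )
    report["km"] = km_report
    report["logrank_q1_vs_q4"] = {"chi2": chi2, "p": p}

    params = {
        "clock": model.name,
        "exclude_years": exclude_years,
        "scale_years": scale_years,
        "ties": ties,
        "seed": seed,
    }
    report["provenance"] = {
        "config_hash": config_hash(params),
        "seed": seed,
        "version": __version__,
    }
    return report


def run_cpg_screen(
    train,
    test,
    cpg_ids: Sequence[str],
    covariate: str = "delta",
    exclude_years: float = 2.0,
    scale_years: float = 5.0,
    ties: str = "efron",
) -> pd.DataFrame:
    """Per-CpG mortality screen with BH correction across the CpG family.

    For each CpG: train a single-CpG clock on the training cohort, predict
    epigenetic age on the test cohort, and fit a Cox model of mortality on
    delta_age / ``scale_years`` adjusted for age and sex
    (``covariate="beta"`` instead enters the raw test-cohort beta-value).
    q-values are BH-adjusted within the screened set; the table is sorted
    by q then p. CpGs whose fit is impossible (zero beta variance) are
    reported as NA with a warning.
    """
    if covariate not in {"delta", "beta"}:
        raise ValueError(f"covariate must be 'delta' or 'beta', got {covariate!r}")
    cpg_ids = list(cpg_ids)
    if not cpg_ids:
        raise ValueError("empty CpG screen set")
    train_matrix, train_ann = _unpack(train)
    test_matrix, test_ann = _unpack(test)
    for label, matrix in (("training", train_matrix), ("test", test_matrix)):
        missing = pd.Index(cpg_ids).difference(matrix.probe_ids)
        if len(missing):
            raise KeyError(f"{label} cohort lacks screen CpG(s): {sorted(missing)[:5]}")
    train_ages = train_ann["age"].to_numpy(float)

    rows = []
    for cpg in cpg_ids:
        try:
            if covariate == "delta":
                model = train_single_cpg(train_matrix, train_ages, cpg)
                pred = predict_age(model, test_matrix)
                values = pred.to_numpy(float) - test_ann["age"].to_numpy(float)
                scale = scale_years
            else:
                values = test_matrix.values.loc[cpg].to_numpy(float)
                scale = 1.0
            table = prepare_survival(
                test_ann, values, exclude_years=exclude_years, scale_years=scale
            )
            cox = cox_fit(table, ["delta_scaled", "age", "sex_male"], ties=ties)
            row = cox.summary.loc["delta_scaled"]
            rows.append(
                {
                    "cpg_id": cpg,
                    "coef": row["coef"],
                    "hr": row["hr"],
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "p": row["p"],
                    "n_used": cox.n_used,
                    "n_events": cox.n_events,
                }
            )
        except ValueError as err:
            warnings.warn(f"screen skipped CpG {cpg}: {err}", RuntimeWarning, stacklevel=2)
            logger.warning("screen skipped CpG %s: %s", cpg, err)
            rows.append(
                {
                    "cpg_id": cpg, "coef": np.nan, "hr": np.nan, "ci_low": np.nan,
                    "ci_high": np.nan, "p": np.nan, "n_used": 0, "n_events": 0,
                }
            )
    result = pd.DataFrame(rows)
    result["q"] = bh_adjust(result["p"].to_numpy())
    result = result.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
    n_sig = int((result["q"] < 0.05).sum())
    logger.info("screen: %d/%d CpGs significant at q<0.05", n_sig, len(result))
    return result


def run_cross_cohort_check(
    train,
    test_a,
    test_b,
    cpg_ids: Sequence[str],
    q_threshold: float = 0.05,
    **screen_kwargs: Any,
) -> dict[str, Any]:
    """Run the per-CpG screen in two test cohorts and summarize replication.

    A CpG *replicates* when it is significant (q < ``q_threshold``) in both
    cohorts with the same direction of effect — the pattern a robust
    mortality-associated CpG shows across independent cohorts.
    """
    screen_a = run_cpg_screen(train, test_a, cpg_ids, **screen_kwargs)
    screen_b = run_cpg_screen(train, test_b, cpg_ids, **screen_kwargs)
    merged = screen_a.set_index("cpg_id")[["coef", "q"]].join(
        screen_b.set_index("cpg_id")[["coef", "q"]],
        lsuffix="_a", rsuffix="_b", how="inner",
    )
    if merged.empty:
        raise ValueError("the two screens share no CpGs")
    merged["sig_a"] = merged["q_a"] < q_threshold
    merged["sig_b"] = merged["q_b"] < q_threshold
    merged["direction_agree"] = np.sign(merged["coef_a"]) == np.sign(merged["coef_b"])
    merged["replicated"] = merged["sig_a"] & merged["sig_b"] & merged["direction_agree"]
    summary = {
        "n_cpgs": int(len(merged)),
        "n_sig_a": int(merged["sig_a"].sum()),
        "n_sig_b": int(merged["sig_b"].sum()),
        "n_both_significant": int((merged["sig_a"] & merged["sig_b"]).sum()),
        "n_replicated": int(merged["replicated"].sum()),
    }
    logger.info("cross-cohort check: %s", summary)
    return {
        "screen_a": screen_a,
        "screen_b": screen_b,
        "overlap": merged.reset_index(),
        "summary": summary,
    }


def config_hash(params: dict[str, Any]) -> str:
    """Stable short hash of a parameter mapping, for provenance records."""
    canonical = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def save_report(report: dict[str, Any], path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
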