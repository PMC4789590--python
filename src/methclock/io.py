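"""Reading, writing and probe-level QC of methylation study artifacts.

Three on-disk artifacts are supported, all delimited text (TSV by default,
CSV accepted by file extension):

* **beta matrix** — CpG probes x samples, values are methylation
  beta-values in [0, 1] (fraction of methylated signal); missing cells
  allowed. Probes-as-rows is the canonical layout (GEO series-matrix
  convention); the loader accepts the transposed layout via ``orientation``.
* **sample annotation** — one row per sample: chronological age (years),
  sex, survival time (years from sampling), event indicator, plus any
  additional clinical covariates.
* **clock coefficient file** — a named linear age predictor: one
  ``(Intercept)`` row plus one row per CpG with its coefficient in years
  per unit beta. The same format carries the packaged 3-CpG model or any
  user-supplied table (e.g. a 99-CpG, Hannum-71 or Horvath-353 predictor).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "ClockModel",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_annotation",
    "write_annotation",
    "validate_annotation",
    "apply_detection_filter",
    "read_clock",
    "write_clock",
]

INTERCEPT_LABEL = "(Intercept)"

ANNOTATION_COLUMNS = ["sample_id", "age", "sex", "surv_time", "event"]

_SEX_ALIASES = {
    "male": "male", "m": "male", "1": "male",
    "female": "female", "f": "female", "0": "female",
}
_EVENT_ALIASES = {
    "1": 1, "death": 1, "dead": 1, "true": 1,
    "0": 0, "censored": 0, "alive": 0, "false": 0,
}


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclasses.dataclass
class MethylationMatrix:
    """CpG x sample table of beta-values with optional detection p-values.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample. Values
        must lie in [0, 1]; NaN marks a missing measurement.
    detection_pvalues
        Optional DataFrame of per-probe, per-sample detection p-values,
        aligned to ``values`` (same index and columns).
    """

    values: pd.DataFrame
    detection_pvalues: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        values = self.values.astype(float)
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        bad = (values < 0) | (values > 1)
        if bad.any().any():
            probe = values.index[bad.any(axis=1)][0]
            sample = values.columns[bad.loc[probe]][0]
            raise ValueError(
                f"beta-value out of [0, 1] at probe {probe!r}, sample "
                f"{sample!r}: {values.loc[probe, sample]}"
            )
        self.values = values
        if self.detection_pvalues is not None:
            pvals = self.detection_pvalues.astype(float)
            if not pvals.index.equals(values.index) or not pvals.columns.equals(values.columns):
                raise ValueError("detection p-values are not aligned with the beta matrix")
            self.detection_pvalues = pvals

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probe_ids: Iterable[str]) -> "MethylationMatrix":
        probe_ids = pd.Index(probe_ids)
        missing = probe_ids.difference(self.probe_ids)
        if len(missing):
            raise KeyError(f"probes not in matrix: {missing.tolist()[:5]}")
        det = None
        if self.detection_pvalues is not None:
            det = self.detection_pvalues.loc[probe_ids]
        return MethylationMatrix(self.values.loc[probe_ids], det)


@dataclasses.dataclass
class ClockModel:
    """A named linear epigenetic-age predictor.

    ``predicted age = intercept + sum_j coefficients[j] * beta[j]`` with the
    intercept in years and coefficients in years per unit beta.
    """

    name: str
    intercept: float
    coefficients: pd.Series  # index: CpG ids, values: years per unit beta

    def __post_init__(self) -> None:
        coef = pd.Series(self.coefficients, dtype=float)
        if len(coef) < 1:
            raise ValueError("a clock needs at least one CpG coefficient")
        if coef.index.has_duplicates:
            dups = coef.index[coef.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate CpG ids in clock: {dups}")
        self.coefficients = coef
        self.intercept = float(self.intercept)

    @property
    def cpg_ids(self) -> pd.Index:
        return self.coefficients.index


def read_beta_matrix(
    path: str | Path,
    orientation: str = "probes",
    detection_pvalues_path: str | Path | None = None,
) -> MethylationMatrix:
    """Load a beta matrix from delimited text.

    ``orientation="probes"`` (default) expects probes as rows and samples as
    columns; ``"samples"`` expects the transposed layout and transposes it
    back to the canonical probes-as-rows form.
    """
    if orientation not in {"probes", "samples"}:
        raise ValueError(f"orientation must be 'probes' or 'samples', got {orientation!r}")
    values = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "samples":
        values = values.T
    det = None
    if detection_pvalues_path is not None:
        det = pd.read_csv(detection_pvalues_path, sep=_sep_for(detection_pvalues_path), index_col=0)
        if orientation == "samples":
            det = det.T
        det = det.loc[values.index, values.columns]
    return MethylationMatrix(values, det)


def write_beta_matrix(
    matrix: MethylationMatrix,
    path: str | Path,
    detection_pvalues_path: str | Path | None = None,
) -> None:
    """Write a beta matrix (probes as rows) and optionally its p-values."""
    matrix.values.rename_axis("probe_id").to_csv(path, sep=_sep_for(path))
    if detection_pvalues_path is not None:
        if matrix.detection_pvalues is None:
            raise ValueError("matrix carries no detection p-values to write")
        matrix.detection_pvalues.rename_axis("probe_id").to_csv(
            detection_pvalues_path, sep=_sep_for(detection_pvalues_path)
        )


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Normalize and validate a sample annotation table.

    Returns a copy with ``sex`` normalized to {"male", "female"} and
    ``event`` to {0, 1} (1 = death observed, 0 = censored). Extra covariate
    columns are preserved untouched.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation is missing required columns: {missing}")
    ann = annotation.copy()
    if ann["sample_id"].duplicated().any():
        dups = ann.loc[ann["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in annotation: {dups[:5]}")
    ann["sample_id"] = ann["sample_id"].astype(str)
    ann["age"] = ann["age"].astype(float)
    if (ann["age"] <= 0).any():
        raise ValueError("chronological age must be > 0 years")
    ann["surv_time"] = ann["surv_time"].astype(float)
    if (ann["surv_time"] < 0).any():
        raise ValueError("survival time must be >= 0 years")

    def norm_sex(v: object) -> str:
        key = str(v).strip().lower()
        if key not in _SEX_ALIASES:
            raise ValueError(f"unrecognized sex value: {v!r}")
        return _SEX_ALIASES[key]

    def norm_event(v: object) -> int:
        key = str(v).strip().lower()
        if key not in _EVENT_ALIASES:
            raise ValueError(f"unrecognized event value: {v!r}")
        return _EVENT_ALIASES[key]

    ann["sex"] = ann["sex"].map(norm_sex)
    ann["event"] = ann["event"].map(norm_event).astype(int)
    return ann


def read_annotation(path: str | Path) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, sep=_sep_for(path)))


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(annotation).to_csv(path, sep=_sep_for(path), index=False)


def apply_detection_filter(
    matrix: MethylationMatrix,
    p_threshold: float = 0.01,
    min_rate: float = 0.95,
) -> MethylationMatrix:
    """Remove probes with a low detection rate across samples.

    A probe is *detected* in a sample when its detection p-value is strictly
    below ``p_threshold``; probes detected in fewer than ``min_rate`` of the
    samples are removed (a rate of exactly ``min_rate`` is kept). The sample
    set is unchanged, and the filter is idempotent.
    """
    if matrix.detection_pvalues is None:
        raise ValueError(
            "matrix has no detection p-values; load them alongside the beta "
            "matrix or skip QC explicitly"
        )
    detected = matrix.detection_pvalues.lt(p_threshold)  # NaN counts as undetected
    rate = detected.mean(axis=1)
    keep = matrix.probe_ids[rate >= min_rate]
    return matrix.subset_probes(keep)


def read_clock(path: str | Path, name: str | None = None) -> ClockModel:
    """Read a clock coefficient file (term, coefficient)."""
    table = pd.read_csv(path, sep=_sep_for(path))
    if table.shape[1] != 2:
        raise ValueError(
            f"clock file must have exactly two columns (term, coefficient); "
            f"got {table.shape[1]}"
        )
    table.columns = ["term", "coefficient"]
    table["term"] = table["term"].astype(str)
    coef = pd.to_numeric(table["coefficient"], errors="coerce")
    if coef.isna().any():
        bad = table.loc[coef.isna(), "term"].tolist()
        raise ValueError(f"non-numeric coefficient for term(s): {bad[:5]}")
    if table["term"].duplicated().any():
        dups = table.loc[table["term"].duplicated(), "term"].tolist()
        raise ValueError(f"duplicate term(s) in clock file: {dups[:5]}")
    is_intercept = table["term"] == INTERCEPT_LABEL
    if not is_intercept.any():
        raise ValueError(f"clock file is missing the required {INTERCEPT_LABEL!r} row")
    intercept = float(coef[is_intercept].iloc[0])
    cpgs = pd.Series(
        coef[~is_intercept].to_numpy(float),
        index=pd.Index(table.loc[~is_intercept, "term"]),
    )
    return ClockModel(name or Path(path).stem, intercept, cpgs)


def write_clock(clock: ClockModel, path: str | Path) -> None:
    rows = pd.DataFrame(
        {
            "term": [INTERCEPT_LABEL, *clock.cpg_ids],
            "coefficient": [clock.intercept, *clock.coefficients.to_numpy()],
        }
    )
    rows.to_csv(path, sep=_sep_for(path), index=False)
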