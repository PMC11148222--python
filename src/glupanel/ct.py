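"""Ct-table I/O and ΔCt quantification.

Raw qPCR output is a long table of threshold-cycle (Ct) measurements, one row
per technical replicate of one gene in one sample.  Relative quantification
normalises each target gene against a housekeeping gene measured in the same
sample:

    ΔCt = Ct_target − Ct_housekeeping

and reports relative expression on an arbitrary-unit scale as

    relative expression = 10³ · 2^(−ΔCt)

so one cycle less of ΔCt means twice the template.  The housekeeping default
is TBP (TATA-box binding protein), a reference gene with stable expression in
glioblastoma tissue.

Missing-data convention: non-numeric Ct entries ("Undetermined", blanks) and
Ct values beyond the 40-cycle detection limit are recorded as missing — no
Ct=40 imputation, which would fabricate an expression level for an
undetected transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CtFormatError",
    "CtIntegrityError",
    "CtTable",
    "ExpressionMatrix",
    "read_ct_table",
    "write_ct_table",
    "read_clinical_table",
    "write_clinical_table",
    "collapse_replicates",
    "compute_delta_ct",
    "relative_expression",
    "write_expression_matrix",
]

log = logging.getLogger(__name__)

#: hard validity bound for a threshold cycle (cycles)
CT_MAX_VALID = 45.0
#: cycles actually run; a Ct beyond this is "not detected", treated as missing
CT_DETECTION_LIMIT = 40.0

REQUIRED_CT_COLUMNS = ("sample_id", "gene", "replicate", "ct")
CLINICAL_COLUMNS = ("sample_id", "cohort", "age", "sex", "seizures")
COHORTS = ("HGG", "MET")


class CtFormatError(ValueError):
    """A Ct/clinical file does not have the expected layout."""


class CtIntegrityError(ValueError):
    """A Ct table violates a uniqueness or consistency constraint."""


@dataclass
class CtTable:
    """Long-format Ct measurements plus the housekeeping gene they refer to.

    ``measurements`` has columns sample_id, gene, replicate, ct; ``ct`` is a
    float with NaN for missing. (sample_id, gene, replicate) is unique.
    """

    measurements: pd.DataFrame
    housekeeping_gene: str = "TBP"

    def __post_init__(self) -> None:
        df = self.measurements
        missing = [c for c in REQUIRED_CT_COLUMNS if c not in df.columns]
        if missing:
            raise CtFormatError(f"Ct table lacks required columns: {missing}")
        dup = df.duplicated(subset=["sample_id", "gene", "replicate"])
        if dup.any():
            rows = df.loc[dup, ["sample_id", "gene", "replicate"]].head(5)
            raise CtIntegrityError(
                f"duplicate (sample, gene, replicate) measurements, e.g.\n{rows}"
            )
        ct = df["ct"]
        bad = ct.notna() & ((ct <= 0) | (ct > CT_MAX_VALID))
        if bad.any():
            log.warning(
                "%d Ct values outside (0, %.0f] recorded as missing",
                int(bad.sum()),
                CT_MAX_VALID,
            )
            df = df.copy()
            df.loc[bad, "ct"] = np.nan
            self.measurements = df

    @property
    def samples(self) -> list[str]:
        return sorted(self.measurements["sample_id"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.measurements["gene"].unique())

    def usable_samples(self) -> list[str]:
        """Samples having at least one non-missing housekeeping Ct."""
        df = self.measurements
        hk = df[(df["gene"] == self.housekeeping_gene) & df["ct"].notna()]
        return sorted(hk["sample_id"].unique())


@dataclass
class ExpressionMatrix:
    """Genes × samples ΔCt values normalised to a housekeeping gene.

    ``delta_ct`` is a DataFrame indexed by gene symbol with sample ids as
    columns; NaN marks missing entries.  The housekeeping gene itself is not
    a row.
    """

    delta_ct: pd.DataFrame
    housekeeping_gene: str = "TBP"

    @property
    def genes(self) -> list[str]:
        return list(self.delta_ct.index)

    @property
    def samples(self) -> list[str]:
        return list(self.delta_ct.columns)

    def relative(self) -> pd.DataFrame:
        """Relative expression 10³·2^(−ΔCt), NaN where ΔCt is missing."""
        return relative_expression(self.delta_ct)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.delta_ct.loc[:, list(sample_ids)], self.housekeeping_gene
        )


def _parse_ct(value) -> float:
    """One Ct cell → float or NaN.  Non-numeric and >40-cycle values are missing."""
    if value is None:
        return np.nan
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return np.nan
        try:
            value = float(value)
        except ValueError:
            return np.nan  # e.g. "Undetermined"
    value = float(value)
    if not np.isfinite(value) or value <= 0 or value > CT_DETECTION_LIMIT:
        return np.nan
    return value


def read_ct_table(path: str | Path, housekeeping: str = "TBP") -> CtTable:
    """Read a long-format Ct CSV (columns sample_id, gene, replicate, ct).

    Unparseable cells ("Undetermined", blanks) and Ct values beyond the
    40-cycle detection limit become missing, with a logged warning; they are
    never silently dropped.  A ``cohort`` column, if present, is ignored here
    (clinical metadata travels in its own file).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype={"sample_id": str, "gene": str})
    missing_cols = [c for c in REQUIRED_CT_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise CtFormatError(f"{path}: missing required columns {missing_cols}")
    parsed = raw["ct"].map(_parse_ct)
    n_lost = int((parsed.isna() & raw["ct"].notna()).sum())
    if n_lost:
        log.warning(
            "%s: %d Ct entries unparseable or beyond the %g-cycle detection "
            "limit; recorded as missing",
            path.name,
            n_lost,
            CT_DETECTION_LIMIT,
        )
    df = pd.DataFrame(
        {
            "sample_id": raw["sample_id"].astype(str),
            "gene": raw["gene"].astype(str),
            "replicate": raw["replicate"].astype(int),
            "ct": parsed.astype(float),
        }
    )
    table = CtTable(df, housekeeping_gene=housekeeping)
    unusable = set(table.samples) - set(table.usable_samples())
    if unusable:
        log.warning(
            "%s: %d sample(s) lack a %s measurement and are unusable: %s",
            path.name,
            len(unusable),
            housekeeping,
            sorted(unusable),
        )
    return table


def write_ct_table(table: CtTable, path: str | Path) -> None:
    """Write the long-format Ct CSV (period decimal, UTF-8, missing as empty)."""
    table.measurements.to_csv(path, index=False, na_rep="")


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the clinical CSV: sample_id, cohort, and optional age/sex/seizures.

    ``cohort`` must be HGG or MET where present; ``sex`` is f/m; ``seizures``
    is true/false with blanks kept as missing (the study had one HGG patient
    without seizure documentation).
    """
    df = pd.read_csv(Path(path), dtype={"sample_id": str})
    if "sample_id" not in df.columns or "cohort" not in df.columns:
        raise CtFormatError(f"{path}: clinical table needs sample_id and cohort")
    bad = df["cohort"].dropna()[~df["cohort"].dropna().isin(COHORTS)]
    if len(bad):
        raise CtFormatError(f"{path}: unknown cohort labels {sorted(set(bad))}")
    for col in ("age", "sex", "seizures"):
        if col not in df.columns:
            df[col] = np.nan
    if df["seizures"].dtype == object:
        df["seizures"] = df["seizures"].map(
            lambda v: np.nan
            if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == ""
            else str(v).strip().lower() in ("true", "yes", "1")
        )
    dup = df.duplicated(subset=["sample_id"])
    if dup.any():
        raise CtIntegrityError(f"{path}: duplicate sample ids")
    return df


def write_clinical_table(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, index=False, na_rep="")


def collapse_replicates(table: CtTable) -> CtTable:
    """Average technical replicates: one Ct per (sample, gene).

    The arithmetic mean of the present replicate Ct values (standard ΔCt
    practice: average on the cycle scale, before exponentiation).  All
    replicates missing → missing.
    """
    df = table.measurements
    collapsed = (
        df.groupby(["sample_id", "gene"], sort=True)["ct"]
        .mean()  # skips NaN; all-NaN group -> NaN
        .reset_index()
    )
    collapsed["replicate"] = 0
    collapsed = collapsed[["sample_id", "gene", "replicate", "ct"]]
    return CtTable(collapsed, housekeeping_gene=table.housekeeping_gene)


def compute_delta_ct(table: CtTable) -> ExpressionMatrix:
    """ΔCt = Ct_target − Ct_housekeeping per (gene, sample).

    Replicates are collapsed first if needed.  A sample without a housekeeping
    Ct gets all entries missing (with a warning); the housekeeping gene is
    excluded from the target rows.
    """
    if table.measurements.duplicated(subset=["sample_id", "gene"]).any():
        table = collapse_replicates(table)
    wide = table.measurements.pivot(index="gene", columns="sample_id", values="ct")
    hk = table.housekeeping_gene
    if hk not in wide.index:
        raise CtIntegrityError(f"housekeeping gene {hk!r} absent from Ct table")
    hk_ct = wide.loc[hk]
    no_hk = hk_ct.index[hk_ct.isna()].tolist()
    if no_hk:
        log.warning(
            "%d sample(s) lack a usable %s Ct; their ΔCt values are missing: %s",
            len(no_hk),
            hk,
            no_hk,
        )
    targets = wide.drop(index=hk)
    delta = targets.sub(hk_ct, axis=1)
    delta = delta.sort_index()
    delta.index.name = "gene"
    delta.columns.name = "sample_id"
    return ExpressionMatrix(delta, housekeeping_gene=hk)


def relative_expression(delta_ct):
    """Relative expression 10³·2^(−ΔCt); accepts scalars, arrays or frames.

    Strictly positive wherever ΔCt is defined; NaN propagates.
    """
    if isinstance(delta_ct, (pd.DataFrame, pd.Series)):
        return 1000.0 * 2.0 ** (-delta_ct)
    out = 1000.0 * np.exp2(-np.asarray(delta_ct, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def write_expression_matrix(
    matrix: ExpressionMatrix,
    delta_path: str | Path,
    relative_path: str | Path | None = None,
) -> None:
    """Write genes × samples TSVs: ΔCt, and optionally relative expression.

    Missing entries are empty cells.
    """
    matrix.delta_ct.to_csv(delta_path, sep="\t", na_rep="")
    if relative_path is not None:
        matrix.relative().to_csv(relative_path, sep="\t", na_rep="")
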