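"""Secondary clinical associations: seizure screen and Pearson correlations.

Within the high-grade glioma cohort, roughly half the patients present with
tumour-associated epilepsy; the screen asks whether any gene's expression
separates seizure-positive from seizure-negative patients, reusing the
Mann–Whitney machinery of the cohort screen.  Clinical covariates (age, sex)
are related to seizure occurrence by Pearson correlation, with binary
variables coded 0/1 (point-biserial as Pearson on coded values): sex f=0/m=1,
seizures no=0/yes=1.  Missing clinical fields are handled by pairwise-complete
deletion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ct import ExpressionMatrix, relative_expression
from .screen import Mode, mann_whitney_u

__all__ = [
    "AssociationResult",
    "pearson_correlation",
    "seizure_expression_screen",
    "clinical_seizure_associations",
    "write_associations",
]

log = logging.getLogger(__name__)

SEX_CODES = {"f": 0.0, "m": 1.0}


@dataclass
class AssociationResult:
    """One association test: a U statistic or a Pearson r with its p-value."""

    variable: str
    n: int
    statistic: float
    p_value: float
    kind: str  # mann_whitney | pearson
    note: str = ""

    @property
    def defined(self) -> bool:
        return math.isfinite(self.statistic)


def pearson_correlation(x, y, variable: str = "x~y") -> AssociationResult:
    """Product-moment r with a two-sided t-based p-value.

    Pairs with a missing member are dropped (pairwise-complete); at least
    three complete pairs are required.  Zero variance in either variable
    leaves r undefined, flagged in ``note``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("pearson_correlation: unequal lengths")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("pearson_correlation needs at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return AssociationResult(variable, n, math.nan, math.nan, "pearson",
                                 note="zero variance: r undefined")
    r, p = stats.pearsonr(x, y)
    return AssociationResult(variable, n, float(r), float(p), "pearson")


def seizure_expression_screen(
    matrix: ExpressionMatrix,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    cohort: str = "HGG",
    mode: Mode = "auto",
) -> list[AssociationResult]:
    """Per-gene Mann–Whitney U between seizure-positive and -negative patients.

    Restricted to one cohort (default HGG, where the epilepsy phenotype was
    recorded); samples without a seizure label are dropped.  Each stratum
    must contain at least two samples, otherwise the screen aborts.
    """
    cl = clinical[clinical["cohort"] == cohort].dropna(subset=["seizures"])
    ids = [s for s in cl["sample_id"] if s in matrix.samples]
    cl = cl.set_index("sample_id").loc[ids]
    pos_ids = cl.index[cl["seizures"].astype(bool)].tolist()
    neg_ids = cl.index[~cl["seizures"].astype(bool)].tolist()
    if len(pos_ids) < 2 or len(neg_ids) < 2:
        raise ValueError(
            f"seizure screen aborted: strata too small "
            f"(seizure n={len(pos_ids)}, no-seizure n={len(neg_ids)})"
        )
    results = []
    for gene in matrix.genes:
        expr = relative_expression(matrix.delta_ct.loc[gene])
        a = expr[pos_ids].dropna().to_numpy()
        b = expr[neg_ids].dropna().to_numpy()
        if len(a) == 0 or len(b) == 0:
            results.append(
                AssociationResult(gene, len(a) + len(b), math.nan, math.nan,
                                  "mann_whitney", note="a stratum entirely missing")
            )
            continue
        u, p = mann_whitney_u(a, b, mode=mode)
        results.append(AssociationResult(gene, len(a) + len(b), u, p, "mann_whitney"))
    n_sig = sum(1 for r in results if r.defined and r.p_value < alpha)
    log.info("seizure screen: %d/%d genes below alpha=%.3g", n_sig, len(results), alpha)
    return results


def clinical_seizure_associations(clinical: pd.DataFrame) -> list[AssociationResult]:
    """Age and sex versus seizure occurrence within HGG (point-biserial).

    Sex is coded f=0/m=1 and seizures no=0/yes=1, so the sign of r is
    reproducible; missing fields are dropped pairwise.
    """
    cl = clinical[clinical["cohort"] == "HGG"]
    seiz = cl["seizures"].map(lambda v: float(v) if v in (0, 1, True, False) else np.nan)
    out = []
    age = pd.to_numeric(cl["age"], errors="coerce")
    out.append(pearson_correlation(age, seiz, variable="age~seizures"))
    sex = cl["sex"].map(SEX_CODES)
    out.append(pearson_correlation(sex, seiz, variable="sex~seizures"))
    return out


def write_associations(results: list[AssociationResult], path) -> None:
    """Write association.tsv: variable, n, statistic, p, kind."""
    pd.DataFrame(
        [
            {"variable": r.variable, "n": r.n, "statistic": r.statistic,
             "p": r.p_value, "kind": r.kind}
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, na_rep="")
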