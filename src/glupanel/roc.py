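"""Empirical ROC curves, Youden cut-points and the threshold-vote gene panel.

Each candidate gene gets an empirical ROC curve over its ΔCt values with
high-grade glioma (HGG) as the positive class.  Orientation is fixed per gene
from the training fold-difference direction: a gene more expressed in HGG has
*lower* ΔCt in HGG (``HGG_low_delta_ct``), one more expressed in metastases
the opposite.  Candidate thresholds are midpoints between adjacent distinct
observed ΔCt values plus the degenerate ±∞ ends, so no training value can sit
exactly on a threshold.  Tied ΔCt values contribute half-counts, which makes
the trapezoidal area equal U/(n₁·n₂) of the Mann–Whitney comparison.

The optimal cut-point maximises the Youden index J = sensitivity +
specificity − 1; ties are broken towards higher specificity, then lower
sensitivity.  Genes whose AUC exceeds the gate (default 0.8) form the panel;
each panel gene classifies a sample on its own threshold, and panel accuracy
is the unweighted mean of per-gene accuracies.  The per-sample concordance
histogram counts, for every sample, how many panel genes voted its true
entity.

The bootstrap confidence interval for total accuracy resamples samples within
cohort (stratified) with the cut-points held fixed — apparent-accuracy
semantics; pass ``reselect=True`` to re-derive cut-points inside every
resample for an optimism assessment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ct import ExpressionMatrix

__all__ = [
    "ROCCurve",
    "GeneCutpoint",
    "PanelModel",
    "PanelReport",
    "empirical_roc",
    "youden_cutpoint",
    "classify_sample",
    "build_panel",
    "evaluate_panel",
    "report_from_counts",
    "bootstrap_accuracy_ci",
    "panel_to_frame",
    "panel_from_frame",
]

log = logging.getLogger(__name__)

HGG_LOW = "HGG_low_delta_ct"
HGG_HIGH = "HGG_high_delta_ct"


@dataclass
class ROCCurve:
    """Empirical ROC of one gene's ΔCt values, HGG as positive class.

    Points run from (sens=0, spec=1) to (sens=1, spec=0); ``thresholds`` are
    the matching ΔCt cut values (±∞ at the ends, midpoints between adjacent
    distinct observed values elsewhere).
    """

    gene: str
    thresholds: np.ndarray  # ΔCt cycles
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    orientation: str  # HGG_low_delta_ct | HGG_high_delta_ct
    n_pos: int
    n_neg: int
    positive_class: str = "HGG"

    @property
    def n_points(self) -> int:
        return len(self.thresholds)


@dataclass
class GeneCutpoint:
    """A gene's Youden-optimal ΔCt threshold and its operating point."""

    gene: str
    threshold: float  # ΔCt cycles
    orientation: str
    youden_j: float
    sensitivity: float
    specificity: float
    auc: float = math.nan


@dataclass
class PanelModel:
    """The AUC-gated set of per-gene cut-points."""

    cutpoints: list[GeneCutpoint]
    auc_gate: float = 0.8
    #: per-candidate AUC bookkeeping (gene, auc, n_points, in_panel)
    candidates: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def genes(self) -> list[str]:
        return [c.gene for c in self.cutpoints]


@dataclass
class PanelReport:
    """Per-gene and panel-level performance on a labelled expression matrix."""

    per_gene: pd.DataFrame  # gene, correct_hgg, n_hgg, correct_met, n_met, accuracy_pct
    total_accuracy_pct: float
    concordance: dict[int, int]  # k panel genes correct -> sample count
    predictions: pd.DataFrame  # sample_id, gene, delta_ct, prediction, correct
    ci95: tuple[float, float] | None = None


def _oriented_scores(delta_ct: np.ndarray, orientation: str) -> np.ndarray:
    """Score increasing with evidence for HGG."""
    return -delta_ct if orientation == HGG_LOW else delta_ct


def empirical_roc(
    delta_ct_values: Sequence[float],
    labels: Sequence[str],
    gene: str = "",
    orientation: str | None = None,
    positive: str = "HGG",
) -> ROCCurve:
    """Empirical ROC over per-sample ΔCt values with cohort labels.

    ``orientation=None`` picks the direction giving AUC ≥ 0.5; passing an
    orientation (as :func:`build_panel` does, from the screen's fold
    direction) fixes it regardless of the resulting AUC.  Missing values are
    dropped; both cohorts must be represented among the rest.
    """
    d = np.asarray(delta_ct_values, dtype=float)
    lab = np.asarray(labels)
    keep = np.isfinite(d)
    d, lab = d[keep], lab[keep]
    pos, neg = d[lab == positive], d[lab != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("empirical_roc: both cohorts must have non-missing values")

    if orientation is None:
        # HGG-high expression (low ΔCt) is the common case; flip if AUC < 0.5
        auc_low = _pairwise_auc(-pos, -neg)
        orientation = HGG_LOW if auc_low >= 0.5 else HGG_HIGH

    s_pos = _oriented_scores(pos, orientation)
    s_neg = _oriented_scores(neg, orientation)
    scores = np.concatenate([s_pos, s_neg])
    is_pos = np.concatenate([np.ones(len(s_pos), bool), np.zeros(len(s_neg), bool)])

    order = np.argsort(-scores, kind="mergesort")
    scores, is_pos = scores[order], is_pos[order]
    distinct, idx = np.unique(-scores, return_index=True)  # ascending on -score
    distinct = -distinct  # descending distinct scores
    idx = np.sort(idx)

    tp = np.concatenate([[0], np.cumsum(is_pos)])  # at the block boundaries
    fp = np.concatenate([[0], np.cumsum(~is_pos)])
    boundaries = np.concatenate([idx[1:], [len(scores)]])
    tpr = np.concatenate([[0.0], tp[boundaries] / len(s_pos)])
    fpr = np.concatenate([[0.0], fp[boundaries] / len(s_neg)])

    # score threshold after including distinct value v_k: midpoint to the next
    # lower distinct value; +inf before any, -inf after all
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    score_thr = np.concatenate([[np.inf], mids, [-np.inf]])
    thr_delta = -score_thr if orientation == HGG_LOW else score_thr

    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(
        gene=gene,
        thresholds=thr_delta,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        orientation=orientation,
        n_pos=len(s_pos),
        n_neg=len(s_neg),
        positive_class=positive,
    )


def _pairwise_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """U/(n1·n2) with ties half-weighted (rank formulation)."""
    from scipy.stats import rankdata

    combined = np.concatenate([pos_scores, neg_scores])
    ranks = rankdata(combined)
    n1, n2 = len(pos_scores), len(neg_scores)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def youden_cutpoint(curve: ROCCurve) -> GeneCutpoint:
    """Operating point maximising J = sensitivity + specificity − 1.

    Ties are broken in favour of higher specificity, then lower sensitivity
    (the most conservative of the equally informative thresholds).
    """
    j = curve.sensitivity + curve.specificity - 1.0
    # sens/spec are small-integer ratios; equal J values can differ in the
    # last float bit, so the tie set needs a tolerance before tie-breaking
    tied = np.flatnonzero(j >= j.max() - 1e-9)
    best = max(tied, key=lambda i: (curve.specificity[i], -curve.sensitivity[i]))
    return GeneCutpoint(
        gene=curve.gene,
        threshold=float(curve.thresholds[best]),
        orientation=curve.orientation,
        youden_j=float(j[best]),
        sensitivity=float(curve.sensitivity[best]),
        specificity=float(curve.specificity[best]),
        auc=curve.auc,
    )


def classify_sample(delta_ct: float, cutpoint: GeneCutpoint) -> str | None:
    """Predict the entity from one gene's ΔCt; missing ΔCt abstains (None).

    With ``HGG_low_delta_ct`` orientation the rule is HGG iff ΔCt ≤ threshold
    (values exactly at a midpoint threshold cannot occur on training data);
    the flipped orientation uses ΔCt ≥ threshold.
    """
    if delta_ct is None or not np.isfinite(delta_ct):
        return None
    if cutpoint.orientation == HGG_LOW:
        return "HGG" if delta_ct <= cutpoint.threshold else "MET"
    return "HGG" if delta_ct >= cutpoint.threshold else "MET"


def _orientation_from_direction(direction: str) -> str | None:
    if direction == "HGG_high":
        return HGG_LOW  # higher expression = lower ΔCt
    if direction == "MET_high":
        return HGG_HIGH
    return None


def build_panel(
    matrix: ExpressionMatrix,
    clinical: pd.DataFrame,
    screen: pd.DataFrame,
    auc_gate: float = 0.8,
) -> PanelModel:
    """Gate the screen-significant genes by AUC and attach Youden cut-points.

    Candidates are the screen's significant, evaluable genes; each gets an
    ROC with orientation fixed from its fold-difference direction, and those
    with AUC strictly above ``auc_gate`` enter the panel.
    """
    cohort = clinical.set_index("sample_id")["cohort"]
    samples = [s for s in matrix.samples if s in cohort.index]
    labels = cohort[samples].to_numpy()

    candidates = screen[screen["significant"] & screen.get("evaluable", True)]
    cutpoints: list[GeneCutpoint] = []
    rows = []
    for _, cand in candidates.iterrows():
        gene = cand["gene"]
        orientation = _orientation_from_direction(cand["direction"])
        curve = empirical_roc(
            matrix.delta_ct.loc[gene, samples].to_numpy(),
            labels,
            gene=gene,
            orientation=orientation,
        )
        in_panel = curve.auc > auc_gate
        rows.append(
            {"gene": gene, "auc": curve.auc, "n_points": curve.n_points, "in_panel": in_panel}
        )
        if in_panel:
            cutpoints.append(youden_cutpoint(curve))
    if not cutpoints:
        log.warning("no candidate gene exceeded the AUC gate %.2f; panel is empty", auc_gate)
    return PanelModel(
        cutpoints=cutpoints,
        auc_gate=auc_gate,
        candidates=pd.DataFrame(rows, columns=["gene", "auc", "n_points", "in_panel"]),
    )


def evaluate_panel(
    panel: PanelModel,
    matrix: ExpressionMatrix,
    clinical: pd.DataFrame,
) -> PanelReport:
    """Per-gene confusion counts, panel accuracy and concordance histogram.

    A gene's accuracy is (correct HGG + correct MET)/(evaluated HGG +
    evaluated MET) in %; abstentions (missing ΔCt) are excluded from that
    gene's denominator.  Total accuracy is the unweighted mean of per-gene
    accuracies.  The concordance histogram counts, per labelled sample, how
    many panel genes predicted its true cohort.
    """
    cohort = clinical.set_index("sample_id")["cohort"]
    samples = [s for s in matrix.samples if s in cohort.index]

    pred_rows = []
    per_gene_rows = []
    correct_per_sample = {s: 0 for s in samples}
    for cut in panel.cutpoints:
        counts = {"HGG": [0, 0], "MET": [0, 0]}  # cohort -> [correct, evaluated]
        for s in samples:
            d = float(matrix.delta_ct.at[cut.gene, s])
            pred = classify_sample(d, cut)
            truth = cohort[s]
            correct = pred == truth if pred is not None else False
            pred_rows.append(
                {
                    "sample_id": s,
                    "gene": cut.gene,
                    "delta_ct": d,
                    "prediction": pred if pred is not None else "abstain",
                    "correct": correct if pred is not None else "",
                }
            )
            if pred is not None:
                counts[truth][1] += 1
                if correct:
                    counts[truth][0] += 1
                    correct_per_sample[s] += 1
        n_eval = counts["HGG"][1] + counts["MET"][1]
        acc = 100.0 * (counts["HGG"][0] + counts["MET"][0]) / n_eval if n_eval else math.nan
        per_gene_rows.append(
            {
                "gene": cut.gene,
                "correct_hgg": counts["HGG"][0],
                "n_hgg": counts["HGG"][1],
                "correct_met": counts["MET"][0],
                "n_met": counts["MET"][1],
                "accuracy_pct": acc,
            }
        )

    per_gene = pd.DataFrame(
        per_gene_rows,
        columns=["gene", "correct_hgg", "n_hgg", "correct_met", "n_met", "accuracy_pct"],
    )
    total = float(per_gene["accuracy_pct"].mean()) if len(per_gene) else math.nan
    concordance: dict[int, int] = {}
    for s in samples:
        k = correct_per_sample[s]
        concordance[k] = concordance.get(k, 0) + 1
    predictions = pd.DataFrame(
        pred_rows, columns=["sample_id", "gene", "delta_ct", "prediction", "correct"]
    )
    return PanelReport(
        per_gene=per_gene,
        total_accuracy_pct=total,
        concordance=dict(sorted(concordance.items(), reverse=True)),
        predictions=predictions,
    )


def report_from_counts(
    counts: Mapping[str, tuple[int, int, int, int]],
) -> tuple[pd.DataFrame, float]:
    """Panel accuracy arithmetic from per-gene confusion counts.

    ``counts`` maps gene → (correct_hgg, n_hgg, correct_met, n_met) — e.g. a
    published table of per-cohort correct predictions.  Returns the per-gene
    frame (accuracy in %) and the total accuracy (unweighted mean of the
    per-gene accuracies).
    """
    rows = []
    for gene, (ch, nh, cm, nm) in counts.items():
        rows.append(
            {
                "gene": gene,
                "correct_hgg": ch,
                "n_hgg": nh,
                "correct_met": cm,
                "n_met": nm,
                "sensitivity": ch / nh,
                "specificity": cm / nm,
                "youden_j": ch / nh + cm / nm - 1.0,
                "accuracy_pct": 100.0 * (ch + cm) / (nh + nm),
            }
        )
    per_gene = pd.DataFrame(rows)
    return per_gene, float(per_gene["accuracy_pct"].mean())


def _gene_accuracy_pct(
    delta_hgg: np.ndarray, delta_met: np.ndarray, cut: GeneCutpoint
) -> float:
    """Vectorised per-gene accuracy (%) with abstentions excluded."""
    dh = delta_hgg[np.isfinite(delta_hgg)]
    dm = delta_met[np.isfinite(delta_met)]
    if cut.orientation == HGG_LOW:
        correct = (dh <= cut.threshold).sum() + (dm > cut.threshold).sum()
    else:
        correct = (dh >= cut.threshold).sum() + (dm < cut.threshold).sum()
    n = len(dh) + len(dm)
    return 100.0 * correct / n if n else math.nan


def bootstrap_accuracy_ci(
    panel: PanelModel,
    matrix: ExpressionMatrix,
    clinical: pd.DataFrame,
    n_boot: int = 2000,
    seed: int | None = None,
    reselect: bool = False,
) -> tuple[float, float]:
    """95% percentile bootstrap CI for the panel's total accuracy (in %).

    Samples are resampled with replacement within each cohort (stratified, so
    no resample can lose a cohort).  Cut-points are held fixed by default;
    ``reselect=True`` re-derives each gene's Youden cut-point inside every
    resample, which quantifies the optimism of apparent accuracy.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    if not panel.cutpoints:
        raise ValueError("cannot bootstrap an empty panel")
    rng = np.random.default_rng(seed)
    cohort = clinical.set_index("sample_id")["cohort"]
    samples = [s for s in matrix.samples if s in cohort.index]
    hgg_ids = [s for s in samples if cohort[s] == "HGG"]
    met_ids = [s for s in samples if cohort[s] == "MET"]
    delta_h = matrix.delta_ct[hgg_ids].to_numpy()  # genes x n_hgg
    delta_m = matrix.delta_ct[met_ids].to_numpy()
    gene_idx = {g: i for i, g in enumerate(matrix.genes)}

    totals = np.empty(n_boot)
    for b in range(n_boot):
        ih = rng.integers(0, len(hgg_ids), len(hgg_ids))
        im = rng.integers(0, len(met_ids), len(met_ids))
        accs = []
        for cut in panel.cutpoints:
            gi = gene_idx[cut.gene]
            dh, dm = delta_h[gi, ih], delta_m[gi, im]
            use = cut
            if reselect:
                vals = np.concatenate([dh, dm])
                labs = np.array(["HGG"] * len(dh) + ["MET"] * len(dm))
                if np.isfinite(dh).any() and np.isfinite(dm).any():
                    curve = empirical_roc(vals, labs, gene=cut.gene,
                                          orientation=cut.orientation)
                    use = youden_cutpoint(curve)
            accs.append(_gene_accuracy_pct(dh, dm, use))
        totals[b] = float(np.nanmean(accs))
    low, high = np.percentile(totals, [2.5, 97.5])
    return float(low), float(high)


def panel_to_frame(panel: PanelModel) -> pd.DataFrame:
    """Serialisable view of a panel model (one row per gene cut-point)."""
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "orientation": c.orientation,
                "delta_ct_cutpoint": c.threshold,
                "youden_index": c.youden_j,
                "sensitivity": c.sensitivity,
                "specificity": c.specificity,
                "auc": c.auc,
            }
            for c in panel.cutpoints
        ],
        columns=["gene", "orientation", "delta_ct_cutpoint", "youden_index",
                 "sensitivity", "specificity", "auc"],
    )


def panel_from_frame(frame: pd.DataFrame, auc_gate: float = 0.8) -> PanelModel:
    """Rebuild a :class:`PanelModel` from :func:`panel_to_frame` output."""
    cutpoints = [
        GeneCutpoint(
            gene=row["gene"],
            threshold=float(row["delta_ct_cutpoint"]),
            orientation=row["orientation"],
            youden_j=float(row["youden_index"]),
            sensitivity=float(row["sensitivity"]),
            specificity=float(row["specificity"]),
            auc=float(row.get("auc", math.nan)),
        )
        for _, row in frame.iterrows()
    ]
    return PanelModel(cutpoints=cutpoints, auc_gate=auc_gate)
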