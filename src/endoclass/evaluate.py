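"""Discrimination of pathogenicity by effect size and threshold characteristics.

The variant-level classifier asks whether a rare variant's estimated
endophenotype effect size separates ClinVar-asserted pathogenic variants
from non-pathogenic ones (likely benign and benign). Discrimination is
summarized by an unadjusted logistic regression of the pathogenic label on
the effect size and by the ROC curve / AUC of the effect size itself (the
fitted score is monotone in the effect size, so the two AUCs coincide);
the AUC confidence interval uses the DeLong variance estimate.

A "large effect size" threshold -- by default 0.5 SD of the trait
distribution in the analysis cohort -- converts the effect size into a
screening test: sensitivity, specificity, PPV and NPV are tabulated over a
grid of SD multiples, and VUS / conflicting / unreported variants whose
effect size reaches the threshold are nominated as having pathogenic
potential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

__all__ = [
    "DiscriminationResult",
    "ThresholdCharacteristics",
    "rank_auc",
    "delong_auc_ci",
    "fit_discrimination",
    "threshold_characteristics",
    "sd_threshold_sweep",
    "nominate_variants",
    "carrier_fraction_large_effect",
    "summarize_by_consequence",
]

NEGATIVE_CATEGORIES = ("likely_benign", "benign")
NOMINATION_CATEGORIES = ("vus", "conflicting", "absent")

LOF_CONSEQUENCES = {"frameshift", "stop_gained", "splice_altering"}
MISSENSE_INDEL_CONSEQUENCES = {"missense", "inframe_deletion", "inframe_insertion"}


@dataclass
class DiscriminationResult:
    positive_set: str
    auc: float
    ci_low: float
    ci_high: float
    n_variants: int
    n_positive: int
    roc_points: np.ndarray  # (k, 2) array of (FPR, TPR)
    logit_intercept: float
    logit_slope: float


@dataclass
class ThresholdCharacteristics:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    tp: int
    fn: int
    fp: int
    tn: int
    notes: list[str] = field(default_factory=list)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def rank_auc(scores, labels) -> float:
    """Mann-Whitney AUC of ``scores`` for binary ``labels`` (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    m = int(labels.sum())
    n = int((~labels).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = _midranks(scores)
    return float((ranks[labels].sum() - m * (m + 1) / 2) / (m * n))


def delong_auc_ci(scores, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC with a DeLong-variance normal CI, clipped to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    all_ranks = _midranks(scores)
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[labels].sum() - m * (m + 1) / 2) / (m * n)
    # structural components
    v10 = (all_ranks[labels] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[~labels] - neg_ranks) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def _merge_asserted(effects: pd.DataFrame, assertions: pd.DataFrame) -> pd.DataFrame:
    merged = effects.merge(assertions, on="variant_key", how="left")
    merged["category"] = merged["category"].fillna("absent")
    return merged


def fit_discrimination(
    effects: pd.DataFrame,
    assertions: pd.DataFrame,
    positive_set: str = "pathogenic_only",
) -> DiscriminationResult:
    """Discriminate pathogenic from likely-benign/benign variants by effect size.

    Only variants with an assertion are included; positives are pathogenic
    variants (or pathogenic + likely pathogenic for
    ``positive_set="pathogenic_plus_likely"``), negatives are likely benign
    and benign. An unadjusted logistic regression of the label on the
    effect size provides the score; the reported AUC is the rank-based AUC
    of the effect size, which the monotone logistic score shares.
    """
    if positive_set not in ("pathogenic_only", "pathogenic_plus_likely"):
        raise ValueError(f"unknown positive_set: {positive_set!r}")
    positives = {"pathogenic"}
    if positive_set == "pathogenic_plus_likely":
        positives.add("likely_pathogenic")

    merged = _merge_asserted(effects, assertions)
    keep = merged["category"].isin(positives | set(NEGATIVE_CATEGORIES))
    sub = merged.loc[keep]
    labels = sub["category"].isin(positives).to_numpy()
    betas = sub["beta"].to_numpy(dtype=float)
    if labels.sum() == 0 or (~labels).sum() == 0:
        raise ValueError(
            "discrimination needs at least one positive and one negative variant")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # unpenalized fit; under perfect separation the slope diverges but
        # the rank-based AUC below is unaffected
        logit = LogisticRegression(C=np.inf, max_iter=2000)
        logit.fit(betas[:, None], labels.astype(int))
    auc, lo, hi = delong_auc_ci(betas, labels)
    fpr, tpr, _ = roc_curve(labels.astype(int), betas)
    return DiscriminationResult(
        positive_set=positive_set,
        auc=auc, ci_low=lo, ci_high=hi,
        n_variants=int(len(sub)), n_positive=int(labels.sum()),
        roc_points=np.column_stack([fpr, tpr]),
        logit_intercept=float(logit.intercept_[0]),
        logit_slope=float(logit.coef_[0, 0]),
    )


def _wald_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    p = k / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def threshold_characteristics(
    effects: pd.DataFrame,
    assertions: pd.DataFrame,
    threshold: float,
    positive_set: str = "pathogenic_only",
) -> ThresholdCharacteristics:
    """Test characteristics of "effect size >= threshold" as a pathogenicity screen.

    The asserted positive class is pathogenic (optionally plus likely
    pathogenic); negatives are likely benign and benign. Proportion CIs are
    normal (Wald) binomial intervals. An empty margin leaves the affected
    statistic NaN with a note.
    """
    positives = {"pathogenic"}
    if positive_set == "pathogenic_plus_likely":
        positives.add("likely_pathogenic")
    merged = _merge_asserted(effects, assertions)
    sub = merged.loc[merged["category"].isin(positives | set(NEGATIVE_CATEGORIES))]
    is_pos = sub["category"].isin(positives).to_numpy()
    test_pos = sub["beta"].to_numpy(dtype=float) >= threshold

    tp = int((is_pos & test_pos).sum())
    fn = int((is_pos & ~test_pos).sum())
    fp = int((~is_pos & test_pos).sum())
    tn = int((~is_pos & ~test_pos).sum())

    notes = []

    def _prop(k, n, name):
        if n == 0:
            notes.append(f"{name} undefined: empty margin")
            return np.nan
        return k / n

    sens = _prop(tp, tp + fn, "sensitivity")
    spec = _prop(tn, tn + fp, "specificity")
    ppv = _prop(tp, tp + fp, "ppv")
    npv = _prop(tn, tn + fn, "npv")
    return ThresholdCharacteristics(
        threshold=float(threshold),
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        sensitivity_ci=_wald_ci(tp, tp + fn),
        specificity_ci=_wald_ci(tn, tn + fp),
        ppv_ci=_wald_ci(tp, tp + fp),
        npv_ci=_wald_ci(tn, tn + fn),
        tp=tp, fn=fn, fp=fp, tn=tn, notes=notes,
    )


def nominate_variants(
    effects: pd.DataFrame,
    assertions: pd.DataFrame,
    threshold: float,
) -> pd.DataFrame:
    """Label VUS / conflicting / unreported variants by the large-effect rule.

    Each such variant is marked ``evidence_pathogenic`` when its effect
    size reaches the threshold, else ``evidence_benign``.
    """
    merged = _merge_asserted(effects, assertions)
    sub = merged.loc[merged["category"].isin(NOMINATION_CATEGORIES)].copy()
    sub["nominated"] = sub["beta"].to_numpy(dtype=float) >= threshold
    sub["evidence"] = np.where(sub["nominated"], "evidence_pathogenic", "evidence_benign")
    return sub[["variant_key", "category", "beta", "nominated", "evidence"]]


def nominated_fractions(nominations: pd.DataFrame) -> dict[str, float]:
    """Per-category fraction of nominated variants among VUS/conflicting/absent."""
    out = {}
    for category in NOMINATION_CATEGORIES:
        sub = nominations.loc[nominations["category"] == category]
        if len(sub):
            out[category] = float(sub["nominated"].mean())
    return out


def carrier_fraction_large_effect(
    genotypes: pd.DataFrame,
    effects: pd.DataFrame,
    assertions: pd.DataFrame,
    threshold: float,
    categories: tuple[str, ...] = ("vus", "conflicting"),
) -> float:
    """Fraction of VUS/conflicting carriers who carry a large-effect variant.

    Numerator: samples carrying >= 1 variant in ``categories`` with effect
    size >= threshold. Denominator: samples carrying >= 1 variant in
    ``categories``. Returns NaN (logged by the caller) when the denominator
    is zero.
    """
    merged = _merge_asserted(effects, assertions)
    keys = merged.loc[merged["category"].isin(categories), "variant_key"]
    keys = [k for k in keys if k in genotypes.columns]
    if not keys:
        return float("nan")
    carrier_any = (genotypes[keys].fillna(0) > 0).any(axis=1)
    large_keys = merged.loc[
        merged["category"].isin(categories)
        & (merged["beta"] >= threshold), "variant_key"]
    large_keys = [k for k in large_keys if k in genotypes.columns]
    if carrier_any.sum() == 0:
        return float("nan")
    if not large_keys:
        return 0.0
    carrier_large = (genotypes[large_keys].fillna(0) > 0).any(axis=1)
    return float((carrier_large & carrier_any).sum() / carrier_any.sum())


def sd_threshold_sweep(
    effects: pd.DataFrame,
    assertions: pd.DataFrame,
    trait_sd_value: float,
    sd_grid=(0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0),
    genotypes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tabulate test characteristics across SD-multiple thresholds.

    One row per SD multiple: threshold in trait units (multiple x trait SD),
    sensitivity / specificity / PPV / NPV with 95% CIs, per-category
    nomination fractions, and -- when genotypes are supplied -- the fraction
    of VUS/conflicting carriers with a large-effect variant.
    """
    sd_grid = list(sd_grid)
    if not sd_grid or any(m <= 0 for m in sd_grid):
        raise ValueError("sd_grid must be non-empty with positive multiples")
    rows = []
    for multiple in sd_grid:
        thr = multiple * trait_sd_value
        ch = threshold_characteristics(effects, assertions, thr)
        noms = nominate_variants(effects, assertions, thr)
        fracs = nominated_fractions(noms)
        row = {
            "sd_multiple": multiple,
            "threshold": thr,
            "sensitivity": ch.sensitivity,
            "sensitivity_ci_low": ch.sensitivity_ci[0],
            "sensitivity_ci_high": ch.sensitivity_ci[1],
            "specificity": ch.specificity,
            "specificity_ci_low": ch.specificity_ci[0],
            "specificity_ci_high": ch.specificity_ci[1],
            "ppv": ch.ppv,
            "npv": ch.npv,
            "nominated_fraction_vus": fracs.get("vus", np.nan),
            "nominated_fraction_conflicting": fracs.get("conflicting", np.nan),
            "nominated_fraction_absent": fracs.get("absent", np.nan),
        }
        if genotypes is not None:
            row["carrier_fraction_large_effect"] = carrier_fraction_large_effect(
                genotypes, effects, assertions, thr)
        rows.append(row)
    return pd.DataFrame(rows)


def consequence_class(consequence: str) -> str:
    if consequence in LOF_CONSEQUENCES:
        return "lof"
    if consequence in MISSENSE_INDEL_CONSEQUENCES:
        return "missense_indel"
    if consequence == "synonymous":
        return "synonymous"
    warnings.warn(f"unknown consequence label {consequence!r}; classed as 'other'")
    return "other"


def summarize_by_consequence(
    effects: pd.DataFrame,
    variants: pd.DataFrame,
    threshold: float,
    second_threshold: float | None = None,
) -> pd.DataFrame:
    """Large-effect proportions by consequence class.

    Classes: loss of function (frameshift, stop-gained, splice-altering),
    missense / in-frame indels, synonymous. ``second_threshold`` (e.g. the
    1-SD threshold) adds a second proportion column.
    """
    merged = effects.merge(
        variants[["variant_key", "consequence"]], on="variant_key", how="left")
    merged["class"] = merged["consequence"].map(consequence_class)
    rows = []
    for klass, sub in merged.groupby("class"):
        betas = sub["beta"].to_numpy(dtype=float)
        row = {
            "class": klass,
            "n": len(sub),
            "large_effect_proportion": float((betas >= threshold).mean()),
        }
        if second_threshold is not None:
            row["large_effect_proportion_2"] = float(
                (betas >= second_threshold).mean())
        rows.append(row)
    return pd.DataFrame(rows)
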