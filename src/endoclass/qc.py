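"""Genotype-, variant- and sample-level quality control.

Genotype-level rules (per call, by genotype class):

* any call: total depth > 200 or < 10 removed;
* hom-ref: genotype quality < 20 removed;
* hom-alt: removed if phred-scaled genotype likelihood < 20, if
  (ref depth + alt depth) / total depth < 0.9, or if
  alt depth / total depth < 0.9;
* het: removed if genotype likelihood < 20, if
  (ref depth + alt depth) / total depth < 0.9, or if
  alt depth / total depth < 0.2.

Rules are evaluated depth -> GQ/PL -> allele balance; the removal log
records the first failing rule. Removed calls become missing genotypes.

Variant-level: removed if in a low-complexity region, call rate < 90%,
Hardy-Weinberg exact test P <= 1e-15, or monomorphic after call filtering.

Sample-level: removed on duplicate flag, reported/genetic sex mismatch, or
any QC metric (het/hom ratio, Ti/Tv, SNP/indel ratio, singleton count)
more than 8 SD from the cohort mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "filter_genotype_calls",
    "hwe_exact_test",
    "filter_variants",
    "filter_samples",
    "genotype_counts",
]

DEPTH_MIN = 10
DEPTH_MAX = 200
GQ_MIN = 20
PL_MIN = 20
AB_TOTAL_MIN = 0.9     # (A1 + A2 depth) / total depth, het and hom-alt
AB_ALT_HOM_MIN = 0.9   # A2 depth / total depth, hom-alt
AB_ALT_HET_MIN = 0.2   # A2 depth / total depth, het
CALL_RATE_MIN = 0.90
HWE_P_CUTOFF = 1.0e-15
SAMPLE_OUTLIER_SD = 8.0

SAMPLE_METRICS = ["het_hom_ratio", "ti_tv_ratio", "snp_indel_ratio", "n_singletons"]


def _validate_calls(calls: pd.DataFrame) -> None:
    required = ["sample_id", "variant_key", "genotype", "total_depth",
                "ref_depth", "alt_depth", "genotype_quality", "genotype_likelihood"]
    missing = [c for c in required if c not in calls.columns]
    if missing:
        raise KeyError(f"call table missing columns: {missing}")
    depths = calls[["total_depth", "ref_depth", "alt_depth"]].to_numpy(dtype=float)
    neg = np.nanmin(depths) < 0 if depths.size else False
    if neg:
        bad = calls.index[(depths < 0).any(axis=1)][0]
        raise ValueError(f"negative depth in call {calls.loc[bad, 'sample_id']}:"
                         f"{calls.loc[bad, 'variant_key']}")
    over = calls["ref_depth"].to_numpy(float) + calls["alt_depth"].to_numpy(float) \
        > calls["total_depth"].to_numpy(float) + 1e-9
    if over.any():
        bad = calls.index[over][0]
        raise ValueError(
            f"ref_depth + alt_depth exceeds total_depth in call "
            f"{calls.loc[bad, 'sample_id']}:{calls.loc[bad, 'variant_key']}")


def filter_genotype_calls(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the per-call genotype filters.

    Returns ``(kept calls, removal log)``; the log holds one row per removed
    call with the first failing rule (order: depth, genotype quality /
    likelihood, allele balance). Calls with genotype ``missing`` pass
    through untouched.
    """
    _validate_calls(calls)
    gt = calls["genotype"].to_numpy()
    dp = calls["total_depth"].to_numpy(float)
    ref = calls["ref_depth"].to_numpy(float)
    alt = calls["alt_depth"].to_numpy(float)
    gq = calls["genotype_quality"].to_numpy(float)
    pl = calls["genotype_likelihood"].to_numpy(float)

    reason = np.full(len(calls), "", dtype=object)
    active = gt != "missing"

    bad_depth = active & ((dp > DEPTH_MAX) | (dp < DEPTH_MIN))
    reason[bad_depth & (reason == "")] = "depth"

    hom_ref = active & (gt == "hom_ref")
    bad_gq = hom_ref & (gq < GQ_MIN)
    reason[bad_gq & (reason == "")] = "genotype_quality"

    non_ref = active & ((gt == "het") | (gt == "hom_alt"))
    bad_pl = non_ref & (pl < PL_MIN)
    reason[bad_pl & (reason == "")] = "genotype_likelihood"

    with np.errstate(divide="ignore", invalid="ignore"):
        ab_total = np.where(dp > 0, (ref + alt) / dp, np.nan)
        ab_alt = np.where(dp > 0, alt / dp, np.nan)
    het = active & (gt == "het")
    hom_alt = active & (gt == "hom_alt")
    bad_ab = (non_ref & (ab_total < AB_TOTAL_MIN)) \
        | (hom_alt & (ab_alt < AB_ALT_HOM_MIN)) \
        | (het & (ab_alt < AB_ALT_HET_MIN))
    reason[bad_ab & (reason == "")] = "allele_balance"

    removed = reason != ""
    log = pd.DataFrame({
        "sample_id": calls["sample_id"].to_numpy()[removed],
        "variant_key": calls["variant_key"].to_numpy()[removed],
        "reason": reason[removed],
    })
    return calls.loc[~removed].copy(), log


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Computes the probability, given the observed allele counts, of a
    heterozygote count whose conditional probability does not exceed that
    of the observed configuration (the standard exact formulation, no
    mid-P adjustment).

    Returns a P value in (0, 1].
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # minor allele count
    obs_het = n_het

    # log-probabilities of every heterozygote count with the observed
    # allele counts (same parity as the minor allele count)
    from scipy.special import gammaln

    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    n_rare_hom = (n_rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    log_p = (
        gammaln(n + 1)
        - gammaln(hets + 1) - gammaln(n_rare_hom + 1) - gammaln(n_common_hom + 1)
        + hets * np.log(2.0)
        - (gammaln(2 * n + 1) - gammaln(n_rare + 1) - gammaln(2 * n - n_rare + 1))
    )
    log_p -= np.logaddexp.reduce(log_p)  # normalize within the conditional support
    probs = np.exp(log_p)
    p_obs = probs[hets == obs_het]
    if p_obs.size == 0:
        raise ValueError(
            f"heterozygote count {obs_het} impossible with minor allele count {n_rare}")
    p_value = probs[probs <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(p_value, 1.0))


def genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    """Count (hom-ref, het, hom-alt) among non-missing dosages."""
    d = np.asarray(dosage, dtype=float)
    d = d[~np.isnan(d)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def filter_variants(
    genotypes: pd.DataFrame,
    low_complexity: pd.Series | None = None,
    call_rate_min: float = CALL_RATE_MIN,
    hwe_p_cutoff: float = HWE_P_CUTOFF,
) -> pd.DataFrame:
    """Variant-level QC over a dosage matrix (samples x variants, NaN = missing).

    A variant passes iff call rate >= ``call_rate_min``, the HWE exact test
    P exceeds ``hwe_p_cutoff``, it is polymorphic among non-missing calls,
    and it is not flagged low-complexity.
    """
    if genotypes.size == 0:
        raise ValueError("genotype matrix is empty")
    n = len(genotypes)
    records = []
    for key in genotypes.columns:
        dosage = genotypes[key].to_numpy(dtype=float)
        n_called = int((~np.isnan(dosage)).sum())
        call_rate = n_called / n
        aa, ab, bb = genotype_counts(dosage)
        monomorphic = n_called == 0 or (ab == 0 and (aa == 0 or bb == 0))
        hwe_p = hwe_exact_test(aa, ab, bb) if n_called > 0 else 1.0
        lc = bool(low_complexity.get(key, False)) if low_complexity is not None else False
        reasons = []
        if lc:
            reasons.append("low_complexity")
        if call_rate < call_rate_min:
            reasons.append("call_rate")
        if hwe_p <= hwe_p_cutoff:
            reasons.append("hwe")
        if monomorphic:
            reasons.append("monomorphic")
        records.append({
            "variant_key": key,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "monomorphic": monomorphic,
            "low_complexity": lc,
            "pass": not reasons,
            "fail_reasons": ",".join(reasons),
        })
    return pd.DataFrame(records)


def filter_samples(
    metrics: pd.DataFrame, n_sd: float = SAMPLE_OUTLIER_SD
) -> tuple[list, pd.DataFrame]:
    """Sample-level QC: duplicates, sex mismatches, 8-SD metric outliers.

    ``metrics`` needs ``sample_id`` plus any subset of the four QC metrics
    (het/hom ratio, Ti/Tv ratio, SNP/indel ratio, singleton count), and
    optionally ``reported_sex`` / ``genetic_sex`` and ``duplicate_flag``.
    Metric means and SDs are computed once on the input table; a metric
    with zero SD yields no outliers; undefined (NaN) metric values are not
    outliers. The log records every triggered reason per removed sample.
    """
    if len(metrics) < 2:
        raise ValueError("sample QC needs at least 2 samples to compute an SD")
    reasons: list[tuple[object, str]] = []
    removed = pd.Series(False, index=metrics.index)

    if "duplicate_flag" in metrics.columns:
        dup = metrics["duplicate_flag"].fillna(False).astype(bool)
        removed |= dup
        reasons += [(i, "duplicate") for i in metrics.index[dup]]

    if {"reported_sex", "genetic_sex"} <= set(metrics.columns):
        mismatch = (
            metrics["reported_sex"].notna()
            & metrics["genetic_sex"].notna()
            & (metrics["reported_sex"] != metrics["genetic_sex"])
        )
        removed |= mismatch
        reasons += [(i, "sex_mismatch") for i in metrics.index[mismatch]]

    for metric in SAMPLE_METRICS:
        if metric not in metrics.columns:
            continue
        vals = metrics[metric].astype(float)
        mu = vals.mean()
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        outlier = ((vals - mu).abs() > n_sd * sd).fillna(False)
        removed |= outlier
        reasons += [(i, f"outlier_{metric}") for i in metrics.index[outlier]]

    log = pd.DataFrame(
        [(metrics.loc[i, "sample_id"], r) for i, r in reasons],
        columns=["sample_id", "reason"],
    )
    kept = metrics.loc[~removed, "sample_id"].tolist()
    return kept, log
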