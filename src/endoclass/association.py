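"""Single-variant association models and carrier-category contrasts.

Per-variant effect sizes come from an additive model: the endophenotype is
regressed on the alternate-allele dosage, adjusting for age, sex, the
trait's clinical covariates and the leading principal components of
ancestry. By default the model is ordinary least squares; a single
variance component proportional to a kinship matrix can be added, in which
case variance parameters are estimated by restricted maximum likelihood
(profiled over the genetic-to-residual variance ratio after an
eigendecomposition of the kinship matrix) and the fixed effects by
generalized least squares. With an identity kinship matrix the mixed model
collapses exactly to OLS.

Carrier-level contrasts regress individual endophenotype values on
indicators of carrying a variant in each pathogenicity category (with the
same covariate adjustment) and report each category's difference from
benign-variant carriers with a 95% CI and the unadjusted two-sided P from
the model t-statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from endoclass.phenotypes import AnalysisCohort

__all__ = [
    "EffectEstimate",
    "MonomorphicError",
    "CollinearityError",
    "estimate_variant_effect",
    "estimate_all_effects",
    "carrier_category_contrasts",
    "trait_sd",
    "CATEGORY_SEVERITY",
]


class MonomorphicError(ValueError):
    """Dosage is constant among non-missing samples; no effect is estimable."""


class CollinearityError(ValueError):
    """The design matrix is rank-deficient."""


@dataclass
class EffectEstimate:
    """Per-variant effect size in trait units per alternate allele."""

    variant_key: str
    beta: float
    se: float
    p_value: float
    carrier_count: int
    n: int
    model: str  # "ols" or "mixed"


def _design(dosage, covariates):
    cols = ["intercept", "dosage"]
    X = [np.ones_like(dosage), dosage]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        names = (list(covariates.columns) if isinstance(covariates, pd.DataFrame)
                 else [f"x{i}" for i in range(cov.shape[1])])
        cols += names
        X += [cov[:, i] for i in range(cov.shape[1])]
    X = np.column_stack(X)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy rank check
        bad = []
        kept = np.empty((X.shape[0], 0))
        for j, name in enumerate(cols):
            trial = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(trial) > kept.shape[1]:
                kept = trial
            else:
                bad.append(name)
        raise CollinearityError(f"design matrix rank-deficient; collinear columns: {bad}")
    return X, cols


def _ols_fit(X, y):
    n, p = X.shape
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(XtX)
    return beta, cov, dof


def _reml_mixed_fit(X, y, kinship):
    """Single variance component LMM: y ~ N(Xb, sg2*K + se2*I).

    Profiles the REML log-likelihood over log(lambda) with
    lambda = sg2/se2, using the eigendecomposition of K.
    """
    n, p = X.shape
    w, U = np.linalg.eigh(np.asarray(kinship, dtype=float))
    w = np.clip(w, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_reml(log_lam):
        lam = np.exp(log_lam)
        d = lam * w + 1.0  # V = se2 * diag(d) in rotated coordinates
        Xd = Xt / d[:, None]
        XtVX = Xt.T @ Xd
        try:
            beta = np.linalg.solve(XtVX, Xd.T @ yt)
        except np.linalg.LinAlgError:
            return np.inf
        r = yt - Xt @ beta
        rss = float(np.sum(r * r / d))
        dof = n - p
        se2 = rss / dof
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        if sign <= 0 or se2 <= 0:
            return np.inf
        ll = -0.5 * (dof * np.log(2 * np.pi * se2) + np.sum(np.log(d))
                     + logdet_XtVX + dof)
        return -ll

    res = optimize.minimize_scalar(neg_reml, bounds=(-10.0, 10.0), method="bounded")
    lam = float(np.exp(res.x))
    # when the genetic component is not supported, collapse to OLS exactly
    if neg_reml(np.log(1e-10)) <= res.fun + 1e-10:
        lam = 0.0
    d = lam * w + 1.0
    Xd = Xt / d[:, None]
    XtVX = Xt.T @ Xd
    beta = np.linalg.solve(XtVX, Xd.T @ yt)
    r = yt - Xt @ beta
    dof = n - p
    se2 = float(np.sum(r * r / d)) / dof
    cov = se2 * np.linalg.inv(XtVX)
    return beta, cov, dof


def _t_inference(estimate, var, dof):
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0:
        p = 0.0 if estimate != 0 else 1.0
        return se, p
    t = estimate / se
    p = 2 * stats.t.sf(abs(t), dof) if dof > 0 else np.nan
    return se, float(p)


def estimate_variant_effect(
    dosage,
    phenotype,
    covariates=None,
    kinship=None,
    variant_key: str = "",
) -> EffectEstimate:
    """Estimate one variant's effect on the endophenotype.

    Samples with missing dosage are dropped for this variant. Raises
    :class:`MonomorphicError` when the dosage is constant among remaining
    samples and :class:`CollinearityError` when the design is
    rank-deficient (the offending columns are named).
    """
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    keep = ~np.isnan(dosage)
    dosage, y = dosage[keep], y[keep]
    if covariates is not None:
        covariates = (covariates.loc[keep] if isinstance(covariates, pd.DataFrame)
                      else np.asarray(covariates, dtype=float)[keep])
    if kinship is not None:
        kinship = np.asarray(kinship, dtype=float)[np.ix_(keep, keep)]
    if dosage.size == 0 or np.all(dosage == dosage[0]):
        raise MonomorphicError(
            f"variant {variant_key or '<unnamed>'}: dosage constant among "
            "non-missing samples")

    X, _cols = _design(dosage, covariates)
    if kinship is None:
        beta, cov, dof = _ols_fit(X, y)
        model = "ols"
    else:
        beta, cov, dof = _reml_mixed_fit(X, y, kinship)
        model = "mixed"
    se, p = _t_inference(beta[1], cov[1, 1], dof)
    return EffectEstimate(
        variant_key=variant_key,
        beta=float(beta[1]),
        se=se,
        p_value=p,
        carrier_count=int((dosage > 0).sum()),
        n=int(len(y)),
        model=model,
    )


def estimate_all_effects(
    genotypes: pd.DataFrame,
    cohort: AnalysisCohort,
    kinship=None,
) -> tuple[pd.DataFrame, list[str]]:
    """Estimate effects for every variant in the dosage matrix.

    Returns ``(effects table, log)``. Monomorphic or failing variants are
    omitted from the table and recorded in the log. Only samples in the
    analysis cohort enter the models.
    """
    log: list[str] = []
    records = []
    ids = cohort.sample_ids
    geno = genotypes.loc[genotypes.index.intersection(ids)]
    geno = geno.reindex(ids)
    y = cohort.phenotype.to_numpy()
    cov = cohort.covariates
    if len(geno.columns) == 0:
        log.append("empty panel: no variants to test")
    for key in geno.columns:
        try:
            est = estimate_variant_effect(
                geno[key].to_numpy(), y, covariates=cov,
                kinship=kinship, variant_key=key,
            )
        except MonomorphicError:
            log.append(f"{key}: monomorphic, skipped")
            continue
        except CollinearityError as exc:
            log.append(f"{key}: {exc}")
            continue
        records.append({
            "variant_key": est.variant_key, "beta": est.beta, "se": est.se,
            "p_value": est.p_value, "carrier_count": est.carrier_count,
            "n": est.n, "model": est.model,
        })
    effects = pd.DataFrame(
        records, columns=["variant_key", "beta", "se", "p_value",
                          "carrier_count", "n", "model"])
    return effects, log


# most-severe-first precedence for samples carrying variants in several categories
CATEGORY_SEVERITY = [
    "pathogenic", "likely_pathogenic", "conflicting", "vus",
    "likely_benign", "benign",
]


def assign_carrier_categories(
    genotypes: pd.DataFrame, assertions: pd.DataFrame
) -> pd.Series:
    """Assign each sample its most severe carried assertion category.

    Samples carrying no asserted variant get the label ``non_carrier``.
    Variants labelled ``absent`` do not contribute.
    """
    cat = assertions.set_index("variant_key")["category"]
    labels = pd.Series("non_carrier", index=genotypes.index, dtype=object)
    for category in reversed(CATEGORY_SEVERITY):  # severe last so it wins
        keys = [k for k in genotypes.columns
                if cat.get(k, "absent") == category]
        if not keys:
            continue
        carrier = (genotypes[keys].fillna(0) > 0).any(axis=1)
        labels[carrier] = category
    return labels


def carrier_category_contrasts(
    cohort: AnalysisCohort,
    genotypes: pd.DataFrame,
    assertions: pd.DataFrame,
) -> pd.DataFrame:
    """Endophenotype differences of category carriers vs benign carriers.

    Fits one linear model with a carrier indicator per category
    (non-carriers as the implicit baseline) plus the cohort covariates,
    then contrasts each non-benign category against benign carriers.
    Returns one row per category with carriers: difference, 95% CI and
    unadjusted two-sided P. Raises when no benign carriers exist.
    """
    labels = assign_carrier_categories(genotypes.reindex(cohort.sample_ids), assertions)
    present = [c for c in CATEGORY_SEVERITY if (labels == c).any()]
    if "benign" not in present:
        raise ValueError("no benign-variant carriers: reference group empty")

    y = cohort.phenotype.to_numpy()
    cov = cohort.covariates.to_numpy(dtype=float)
    indicators = np.column_stack([(labels == c).to_numpy(float) for c in present])
    X = np.column_stack([np.ones(len(y)), indicators, cov])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise CollinearityError("carrier-contrast design matrix rank-deficient")
    beta, covmat, dof = _ols_fit(X, y)

    ref = 1 + present.index("benign")
    rows = []
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.nan
    for j, category in enumerate(present):
        if category == "benign":
            continue
        idx = 1 + j
        diff = beta[idx] - beta[ref]
        var = covmat[idx, idx] + covmat[ref, ref] - 2 * covmat[idx, ref]
        se, p = _t_inference(diff, var, dof)
        half = tcrit * se if se > 0 else 0.0
        rows.append({
            "category": category,
            "difference": float(diff),
            "ci_low": float(diff - half),
            "ci_high": float(diff + half),
            "p_value": p,
            "n_carriers": int((labels == category).sum()),
        })
    return pd.DataFrame(rows, columns=["category", "difference", "ci_low",
                                       "ci_high", "p_value", "n_carriers"])


def trait_sd(cohort: AnalysisCohort) -> float:
    """Sample SD of the raw endophenotype in the analysis cohort.

    This anchors SD-multiple effect-size thresholds (e.g. the 0.5-SD
    large-effect rule) in trait units.
    """
    y = cohort.phenotype.to_numpy(dtype=float)
    if y.size < 2:
        raise ValueError("trait SD needs at least 2 samples")
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise ValueError("phenotype is degenerate (SD = 0)")
    return sd
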