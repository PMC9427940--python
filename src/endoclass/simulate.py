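"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a population-scale sequencing study of rare coding
variation in monogenic-disease gene panels:

* rare variants (within-sample MAF strictly below a ceiling, default 0.1%)
  placed in gene panels, with per-variant true effects drawn by true
  pathogenicity category (pathogenic largest, benign centered at zero);
* an endophenotype built additively from covariates, variant dosages and
  Gaussian noise;
* ClinVar-style assertion labels with configurable misclassification plus
  VUS / conflicting / absent masking;
* call-level records with injected QC failures (depth, genotype quality,
  allele balance, genotype likelihood);
* a 31-tool in-silico predictor matrix whose damaging-call probability
  rises with the magnitude of the true effect.

Every output is a deterministic function of the config (including its seed).
True effects are specified in trait-SD units and converted to trait units
with the noise SD standing in for the trait SD (rare variants contribute
negligibly to the trait variance); the conversion factor is recorded in the
returned metadata.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from endoclass.pfi import QUALITATIVE_TOOLS, QUANTITATIVE_TOOLS, MUTATION_ASSESSOR_SLOT

__all__ = [
    "GenePanel",
    "SimulationConfig",
    "FH_PANEL",
    "LQTS_PANEL",
    "MODY_PANEL",
    "generate_cohort",
    "generate_assertions",
    "generate_predictor_matrix",
    "generate_raw_calls",
]

TRUE_CATEGORIES = [
    "pathogenic",
    "likely_pathogenic",
    "vus_like",
    "conflicting_like",
    "likely_benign",
    "benign",
]

# chromosome per panel gene, for synthetic loci / VCF output
GENE_CHROM = {
    "LDLR": "19", "APOB": "2", "PCSK9": "1",
    "KCNQ1": "11", "KCNH2": "7", "SCN5A": "3",
    "GCK": "7", "HNF1A": "12", "HNF1B": "17", "HNF4A": "20",
}

# draw probabilities of consequence class by true category: pathogenic
# variants are enriched for loss of function, benign for synonymous
_CONSEQUENCE_PROBS = {
    "pathogenic": {"lof": 0.45, "missense": 0.50, "synonymous": 0.05},
    "likely_pathogenic": {"lof": 0.30, "missense": 0.60, "synonymous": 0.10},
    "vus_like": {"lof": 0.05, "missense": 0.75, "synonymous": 0.20},
    "conflicting_like": {"lof": 0.05, "missense": 0.75, "synonymous": 0.20},
    "likely_benign": {"lof": 0.02, "missense": 0.48, "synonymous": 0.50},
    "benign": {"lof": 0.02, "missense": 0.38, "synonymous": 0.60},
}

_CONSEQUENCE_TERMS = {
    "lof": ["frameshift", "stop_gained", "splice_altering"],
    "missense": ["missense"],
    "synonymous": ["synonymous"],
}


@dataclass(frozen=True)
class GenePanel:
    """One gene with the number of variants to generate per true category."""

    gene: str
    n_variants: dict[str, int]

    def total(self) -> int:
        return sum(self.n_variants.values())


def _panel(genes: list[str], per_gene: dict[str, int]) -> list[GenePanel]:
    return [GenePanel(g, dict(per_gene)) for g in genes]


_DEFAULT_PER_GENE = {
    "pathogenic": 5,
    "likely_pathogenic": 5,
    "vus_like": 15,
    "conflicting_like": 5,
    "likely_benign": 5,
    "benign": 5,
}

FH_PANEL = _panel(["LDLR", "APOB", "PCSK9"], _DEFAULT_PER_GENE)
LQTS_PANEL = _panel(["KCNQ1", "KCNH2", "SCN5A"], _DEFAULT_PER_GENE)
MODY_PANEL = _panel(["GCK", "HNF1A", "HNF1B", "HNF4A"], _DEFAULT_PER_GENE)

# baseline covariate distributions per trait: (intercept, clinical covariate
# generator specs). Age/sex/PCs are shared across traits.
_TRAIT_BASELINES = {
    "ldl_c": {
        "intercept": 136.0,
        "noise_sd": 33.4,
        "continuous": {"hdl": (56.0, 13.0)},
        "binary": {"mi_history": 0.016, "statin_use": 0.168},
        "covariate_effects": {"age": 0.3, "sex": -5.0, "hdl": -0.2,
                              "mi_history": -10.0, "statin_use": -30.0},
    },
    "qtc": {
        "intercept": 411.0,
        "noise_sd": 23.8,
        "continuous": {},
        "binary": {"beta_blocker_use": 0.051, "calcium_channel_blocker_use": 0.073,
                   "mi_history": 0.014, "heart_failure": 0.002},
        "covariate_effects": {"age": 0.2, "sex": -8.0, "beta_blocker_use": 5.0,
                              "calcium_channel_blocker_use": 2.0,
                              "mi_history": 4.0, "heart_failure": 6.0},
    },
    "hba1c": {
        "intercept": 5.4,
        "noise_sd": 0.62,
        "continuous": {"mcv": (91.2, 4.5)},
        "binary": {"diabetes_medication_use": 0.037},
        "covariate_effects": {"age": 0.005, "sex": 0.02, "mcv": -0.005,
                              "diabetes_medication_use": 1.0},
    },
}

_DEFAULT_EFFECT_MEANS = {
    "pathogenic": 0.9,
    "likely_pathogenic": 0.5,
    "vus_like": 0.15,
    "conflicting_like": 0.1,
    "likely_benign": 0.0,
    "benign": 0.0,
}

_DEFAULT_EFFECT_SDS = {
    "pathogenic": 0.2,
    "likely_pathogenic": 0.15,
    "vus_like": 0.25,
    "conflicting_like": 0.2,
    "likely_benign": 0.05,
    "benign": 0.05,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, including the seed.

    True effects (``category_effect_means`` / ``_sds``) are in trait-SD
    units; ``noise_sd`` is in trait units and doubles as the SD-to-trait
    conversion factor. ``maf_ceiling`` is a strict upper bound on the
    within-sample minor allele frequency.
    """

    n_samples: int = 5000
    trait: str = "ldl_c"
    panels: list[GenePanel] = field(default_factory=lambda: list(FH_PANEL))
    category_effect_means: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECT_MEANS))
    category_effect_sds: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECT_SDS))
    maf_ceiling: float = 0.001
    covariate_effects: dict[str, float] | None = None  # None -> trait baseline
    noise_sd: float | None = None  # None -> trait baseline
    sd_to_trait_units: float | None = None  # None -> noise_sd (1.0 when noise-free)
    intercept: float | None = None  # None -> trait baseline
    n_pcs: int = 12
    pc_sd: float = 0.02
    pc_confounding: dict[str, float] = field(default_factory=dict)  # pc name -> trait loading
    hom_alt_fraction: float = 0.0
    assertion_error_rate: float = 0.0
    vus_fraction: float = 0.0
    conflicting_fraction: float = 0.0
    absent_fraction: float = 0.0
    predictor_slope: float = 3.0
    predictor_intercept: float = -1.5
    predictor_na_rate: float = 0.1
    qc_failure_rates: dict[str, float] = field(default_factory=dict)
    mean_depth: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        base = _TRAIT_BASELINES.get(self.trait)
        if base is None:
            raise ValueError(f"unknown trait: {self.trait!r}")
        if self.noise_sd is None:
            self.noise_sd = base["noise_sd"]
        if self.intercept is None:
            self.intercept = base["intercept"]
        if self.covariate_effects is None:
            self.covariate_effects = dict(base["covariate_effects"])
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not (0 < self.maf_ceiling <= 0.001):
            raise ValueError(
                "maf_ceiling must lie in (0, 0.001]: the analysis targets rare "
                "variants with within-sample MAF < 0.1%")
        fractions = {
            "assertion_error_rate": self.assertion_error_rate,
            "vus_fraction": self.vus_fraction,
            "conflicting_fraction": self.conflicting_fraction,
            "absent_fraction": self.absent_fraction,
            "hom_alt_fraction": self.hom_alt_fraction,
            "predictor_na_rate": self.predictor_na_rate,
            **{f"qc_failure_rates[{k}]": v for k, v in self.qc_failure_rates.items()},
        }
        for name, frac in fractions.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        mask_total = self.vus_fraction + self.conflicting_fraction + self.absent_fraction
        if mask_total > 1.0 + 1e-12:
            raise ValueError(
                "vus_fraction + conflicting_fraction + absent_fraction must not exceed 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.max_minor_allele_count() < 1:
            raise ValueError(
                f"n_samples={self.n_samples} too small to place any carrier "
                f"under maf_ceiling={self.maf_ceiling} (strict MAF bound: need "
                f"maf_ceiling * 2 * n_samples > 1)")
        missing = set(TRUE_CATEGORIES) - set(self.category_effect_means)
        if missing:
            raise ValueError(f"category_effect_means missing categories: {sorted(missing)}")

    def effect_scale(self) -> float:
        """Trait units per SD unit for true effects.

        Defaults to the noise SD (rare variants contribute negligibly to
        the trait variance); a noise-free config falls back to 1.0 so that
        SD-unit effects are read directly as trait units.
        """
        if self.sd_to_trait_units is not None:
            return self.sd_to_trait_units
        return self.noise_sd if self.noise_sd > 0 else 1.0

    def max_minor_allele_count(self) -> int:
        """Largest minor allele count with MAF strictly below the ceiling."""
        bound = self.maf_ceiling * 2 * self.n_samples
        mac = int(np.floor(bound))
        if mac == bound:  # strict inequality
            mac -= 1
        return mac

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the config seed."""
        digest = zlib.crc32(stream.encode()) % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, digest]))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["panels"] = [{"gene": p.gene, "n_variants": dict(p.n_variants)} for p in self.panels]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "panels" in d:
            d["panels"] = [GenePanel(p["gene"], dict(p["n_variants"])) for p in d["panels"]]
        return cls(**d)


def _draw_variants(config: SimulationConfig, rng: np.random.Generator):
    """Lay out variant records and their true categories/effects."""
    rows = []
    pos_counter: dict[str, int] = {}
    for panel in config.panels:
        chrom = GENE_CHROM.get(panel.gene, "1")
        for category in TRUE_CATEGORIES:
            n = panel.n_variants.get(category, 0)
            for _ in range(n):
                pos_counter[panel.gene] = pos_counter.get(panel.gene, 0) + 1
                idx = pos_counter[panel.gene]
                pos = 1_000_000 + idx * 100
                ref, alt = "A", "G"
                key = f"{chrom}:{pos}:{ref}:{alt}:{panel.gene}"
                probs = _CONSEQUENCE_PROBS[category]
                klass = rng.choice(list(probs), p=list(probs.values()))
                consequence = rng.choice(_CONSEQUENCE_TERMS[klass])
                effect_sd = rng.normal(
                    config.category_effect_means[category],
                    config.category_effect_sds[category],
                )
                rows.append(
                    (key, panel.gene, chrom, pos, ref, alt, consequence,
                     category, effect_sd)
                )
    variants = pd.DataFrame(
        rows,
        columns=["variant_key", "gene", "chrom", "pos", "ref", "alt",
                 "consequence", "true_category", "true_effect_sd_units"],
    )
    return variants


def generate_cohort(config: SimulationConfig):
    """Generate genotypes, variants, samples and ground truth for one cohort.

    Returns
    -------
    genotypes : DataFrame (n_samples x n_variants)
        Dosage of the alternate allele (0/1/2), float.
    variants : DataFrame
        One row per variant: locus, gene, consequence, true category,
        minor allele count.
    samples : DataFrame
        Phenotype (column named after the trait), age, sex, clinical
        covariates, PCs, and for the QTc trait the raw ECG columns.
    truth : DataFrame
        variant_key, true_category, true_effect (trait units),
        true_effect_sd_units.
    meta : dict
        Conversion factor from SD units to trait units and config echo.
    """
    config.validate()
    rng = config.rng("cohort")
    n = config.n_samples
    base = _TRAIT_BASELINES[config.trait]

    variants = _draw_variants(config, rng)
    n_var = len(variants)

    # covariates
    sample_ids = [f"S{i:06d}" for i in range(n)]
    samples = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    samples["age"] = rng.normal(57.0, 8.1, size=n)
    samples["sex"] = rng.integers(0, 2, size=n).astype(float)
    for col, (mu, sd) in base["continuous"].items():
        samples[col] = rng.normal(mu, sd, size=n)
    for col, p in base["binary"].items():
        samples[col] = (rng.random(n) < p).astype(float)
    for i in range(1, config.n_pcs + 1):
        samples[f"pc{i}"] = rng.normal(0.0, config.pc_sd, size=n)

    # genotypes: per-variant carrier placement under the strict MAF ceiling
    max_mac = config.max_minor_allele_count()
    dosage = np.zeros((n, n_var), dtype=float)
    macs = np.empty(n_var, dtype=int)
    for j in range(n_var):
        mac = int(rng.integers(1, max_mac + 1))
        n_hom = 0
        if config.hom_alt_fraction > 0 and mac >= 2:
            n_hom = int(rng.binomial(mac // 2, config.hom_alt_fraction))
        n_het = mac - 2 * n_hom
        carriers = rng.choice(n, size=n_het + n_hom, replace=False)
        dosage[carriers[:n_het], j] = 1.0
        dosage[carriers[n_het:], j] = 2.0
        macs[j] = mac
    variants["minor_allele_count"] = macs
    variants["maf"] = macs / (2 * n)

    # phenotype: intercept + covariates + genetic effects + noise
    effect_trait_units = variants["true_effect_sd_units"].to_numpy() * config.effect_scale()
    pheno = np.full(n, float(config.intercept))
    for col, eff in config.covariate_effects.items():
        if col in samples.columns:
            pheno += eff * samples[col].to_numpy()
    for pc_col, loading in config.pc_confounding.items():
        if pc_col in samples.columns:
            pheno += loading * samples[pc_col].to_numpy()
    pheno += dosage @ effect_trait_units
    if config.noise_sd > 0:
        pheno += rng.normal(0.0, config.noise_sd, size=n)
    samples[config.trait] = pheno

    if config.trait == "qtc":
        # raw ECG columns consistent with the phenotype and non-excluding
        rr = np.clip(rng.normal(1.0, 0.1, size=n), 0.6, 1.4)
        samples["rr_interval"] = rr
        samples["heart_rate"] = 60.0 / rr
        samples["qrs_duration"] = np.clip(rng.normal(90.0, 10.0, size=n), 60.0, 119.0)
        samples["qt_interval"] = samples["qtc"] * np.sqrt(rr)
        for flag in TRAITS_EXCLUSION_FLAGS:
            samples[flag] = False

    genotypes = pd.DataFrame(
        dosage, index=samples.index, columns=variants["variant_key"].to_list()
    )

    truth = variants[["variant_key", "true_category", "true_effect_sd_units"]].copy()
    truth["true_effect"] = truth["true_effect_sd_units"] * config.effect_scale()

    meta = {
        "trait": config.trait,
        "trait_sd_trait_units": config.noise_sd,
        "sd_to_trait_units": config.effect_scale(),
        "max_minor_allele_count": max_mac,
        "seed": config.seed,
    }
    return genotypes, variants, samples, truth, meta


# participant-level QTc exclusion flags, mirrored from the trait spec
TRAITS_EXCLUSION_FLAGS = [
    "wpw", "pacemaker", "av_block_2_3", "class_i_iii_antiarrhythmic", "digoxin_use",
]

ASSERTION_LABELS = [
    "pathogenic", "likely_pathogenic", "vus", "conflicting",
    "likely_benign", "benign", "absent",
]

_TRUE_TO_ASSERTED = {
    "pathogenic": "pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "vus_like": "vus",
    "conflicting_like": "conflicting",
    "likely_benign": "likely_benign",
    "benign": "benign",
}

_ERROR_FLIP = {
    "pathogenic": "benign",
    "likely_pathogenic": "likely_benign",
    "vus": "vus",
    "conflicting": "conflicting",
    "likely_benign": "likely_pathogenic",
    "benign": "pathogenic",
}


def generate_assertions(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Assign an observed ClinVar-style category to each variant.

    Masking (vus / conflicting / absent) is applied first at the configured
    fractions; surviving variants receive their true label, flipped across
    the pathogenic/benign axis with probability ``assertion_error_rate``.
    """
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    config.validate()
    rng = config.rng("assertions")
    u = rng.random(len(truth))
    err = rng.random(len(truth))
    v, c, a = config.vus_fraction, config.conflicting_fraction, config.absent_fraction

    observed = []
    for i, row in enumerate(truth.itertuples(index=False)):
        if u[i] < a:
            observed.append("absent")
        elif u[i] < a + v:
            observed.append("vus")
        elif u[i] < a + v + c:
            observed.append("conflicting")
        else:
            label = _TRUE_TO_ASSERTED[row.true_category]
            if err[i] < config.assertion_error_rate:
                label = _ERROR_FLIP[label]
            observed.append(label)
    return pd.DataFrame(
        {"variant_key": truth["variant_key"].to_numpy(), "category": observed}
    )


def generate_predictor_matrix(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Emulate a 31-tool in-silico predictor table (dbNSFP-style).

    Each tool independently calls the variant damaging with probability
    sigmoid(intercept + slope * |true effect in SD units|); qualitative
    tools emit "D"/"T" ("H"/"M"/"L" for the MutationAssessor-style slot),
    quantitative tools emit rank scores in [0, 1] with damaging calls
    placed above 0.9. NA entries are injected at ``predictor_na_rate``.
    """
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    config.validate()
    rng = config.rng("predictors")
    eff = np.abs(truth["true_effect_sd_units"].to_numpy())
    p_damaging = 1.0 / (1.0 + np.exp(-(config.predictor_intercept
                                       + config.predictor_slope * eff)))
    n_var = len(truth)
    out = pd.DataFrame({"variant_key": truth["variant_key"].to_numpy()})
    for tool in QUALITATIVE_TOOLS:
        na = rng.random(n_var) < config.predictor_na_rate
        dmg = rng.random(n_var) < p_damaging
        if tool == MUTATION_ASSESSOR_SLOT:
            benign_letter = rng.choice(["M", "L"], size=n_var)
            col = np.where(dmg, "H", benign_letter)
        else:
            col = np.where(dmg, "D", "T")
        out[tool] = pd.array(np.where(na, None, col), dtype="string")
    for tool in QUANTITATIVE_TOOLS:
        na = rng.random(n_var) < config.predictor_na_rate
        dmg = rng.random(n_var) < p_damaging
        score = np.where(dmg,
                         0.9 + 0.1 * rng.random(n_var),
                         0.9 * rng.random(n_var))
        score = np.round(score, 6)
        out[tool] = np.where(na, np.nan, score)
    return out


GENOTYPE_CODES = {0.0: "hom_ref", 1.0: "het", 2.0: "hom_alt"}

QC_FAILURE_MODES = ["low_depth", "high_depth", "low_gq", "low_pl", "allele_balance"]


def generate_raw_calls(genotypes: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Expand a dosage matrix into per-call records with injected QC failures.

    Clean calls are drawn to pass every downstream genotype filter
    (depth in [10, 200], GQ/PL >= 20, allele balance consistent with the
    genotype). Failure modes are then injected independently at the rates
    in ``config.qc_failure_rates``; the ``corrupted`` column records which
    calls were touched and by which mode (first applied).
    """
    if genotypes.size == 0:
        raise ValueError("genotype matrix is empty")
    config.validate()
    rng = config.rng("raw_calls")
    rates = {m: config.qc_failure_rates.get(m, 0.0) for m in QC_FAILURE_MODES}

    sample_ids = np.repeat(genotypes.index.to_numpy(), genotypes.shape[1])
    variant_keys = np.tile(np.asarray(genotypes.columns), genotypes.shape[0])
    dosage = genotypes.to_numpy().ravel()
    n_calls = dosage.size

    depth = np.clip(rng.poisson(config.mean_depth, size=n_calls), 10, 200).astype(float)
    gq = rng.integers(30, 100, size=n_calls).astype(float)
    pl = rng.integers(30, 100, size=n_calls).astype(float)

    # allele depths consistent with the genotype
    alt_frac = np.where(dosage == 0.0, 0.0, np.where(dosage == 1.0, 0.5, 1.0))
    # clean het calls: alt fraction in [0.3, 0.7] keeps balance filters happy
    jitter = rng.uniform(-0.15, 0.15, size=n_calls)
    alt_frac = np.where(dosage == 1.0, 0.5 + jitter, alt_frac)
    alt_depth = np.rint(depth * alt_frac)
    ref_depth = depth - alt_depth

    corrupted = np.full(n_calls, "", dtype=object)
    for mode in QC_FAILURE_MODES:
        rate = rates[mode]
        if rate <= 0:
            continue
        hit = (rng.random(n_calls) < rate) & (corrupted == "")
        if mode == "low_depth":
            depth[hit] = rng.integers(0, 10, size=hit.sum()).astype(float)
        elif mode == "high_depth":
            depth[hit] = rng.integers(201, 400, size=hit.sum()).astype(float)
        elif mode == "low_gq":
            gq[hit] = rng.integers(0, 20, size=hit.sum()).astype(float)
        elif mode == "low_pl":
            pl[hit] = rng.integers(0, 20, size=hit.sum()).astype(float)
        elif mode == "allele_balance":
            # push alt fraction below every balance cutoff
            frac = rng.uniform(0.0, 0.15, size=hit.sum())
            alt_depth[hit] = np.rint(depth[hit] * frac)
        corrupted[hit] = mode
    ref_depth = np.minimum(depth - alt_depth, depth)
    alt_depth = np.minimum(alt_depth, depth)

    calls = pd.DataFrame({
        "sample_id": sample_ids,
        "variant_key": variant_keys,
        "genotype": pd.Series(dosage).map(GENOTYPE_CODES).to_numpy(),
        "total_depth": depth,
        "ref_depth": ref_depth,
        "alt_depth": alt_depth,
        "genotype_quality": gq,
        "genotype_likelihood": pl,
        "corrupted": corrupted,
    })
    return calls
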