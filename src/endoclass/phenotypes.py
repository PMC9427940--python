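"""Endophenotype construction: trait definitions, QTc correction, exclusions, imputation.

Each of the three endophenotypes carries its own clinical covariate set and
exclusion rules:

* ``ldl_c`` (mg/dL): covariates HDL, history of myocardial infarction,
  statin use; continuous covariates imputed to the observed median, binary
  histories to "no history".
* ``qtc`` (ms): QT corrected by the Bazett formula QTc = QT / sqrt(RR);
  ECG-level exclusions (QRS > 120 ms, heart rate < 40 or > 120 bpm) and
  participant-level exclusions (WPW, pacemaker, 2nd/3rd degree AV block,
  class I/III antiarrhythmics, digoxin); covariates beta blocker use,
  calcium channel blocker use, MI history, heart failure history.
* ``hba1c`` (%): covariates mean corpuscular volume (MCV) and diabetes
  medication use; MCV imputed to the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "TRAITS",
    "AnalysisCohort",
    "bazett_qtc",
    "apply_ecg_exclusions",
    "impute_covariates",
    "build_analysis_cohort",
]


@dataclass(frozen=True)
class TraitSpec:
    """Definition of one endophenotype and its adjustment set.

    Parameters
    ----------
    trait : str
        One of ``ldl_c``, ``qtc``, ``hba1c``.
    units : str
        Trait units (mg/dL, ms, %).
    continuous_covariates : list of str
        Clinical covariates imputed to the observed median when missing.
    binary_covariates : list of str
        History/medication flags imputed to False ("no history") when missing.
    exclusion_flags : list of str
        Participant-level condition/medication flags any of which excludes
        the sample (QTc only).
    ecg_exclusions : bool
        Whether ECG-level QRS / heart-rate exclusions apply.
    """

    trait: str
    units: str
    continuous_covariates: list[str] = field(default_factory=list)
    binary_covariates: list[str] = field(default_factory=list)
    exclusion_flags: list[str] = field(default_factory=list)
    ecg_exclusions: bool = False

    @property
    def covariates(self) -> list[str]:
        return list(self.continuous_covariates) + list(self.binary_covariates)


TRAITS: dict[str, TraitSpec] = {
    "ldl_c": TraitSpec(
        trait="ldl_c",
        units="mg/dL",
        continuous_covariates=["hdl"],
        binary_covariates=["mi_history", "statin_use"],
    ),
    "qtc": TraitSpec(
        trait="qtc",
        units="ms",
        continuous_covariates=[],
        binary_covariates=[
            "beta_blocker_use",
            "calcium_channel_blocker_use",
            "mi_history",
            "heart_failure",
        ],
        exclusion_flags=[
            "wpw",
            "pacemaker",
            "av_block_2_3",
            "class_i_iii_antiarrhythmic",
            "digoxin_use",
        ],
        ecg_exclusions=True,
    ),
    "hba1c": TraitSpec(
        trait="hba1c",
        units="%",
        continuous_covariates=["mcv"],
        binary_covariates=["diabetes_medication_use"],
    ),
}


@dataclass
class AnalysisCohort:
    """An analysis-ready cohort: phenotype, covariates, and the exclusion trail."""

    trait: str
    phenotype: pd.Series
    covariates: pd.DataFrame
    exclusion_log: pd.DataFrame
    n_input: int
    n_final: int

    @property
    def sample_ids(self) -> pd.Index:
        return self.phenotype.index


def bazett_qtc(qt, rr):
    """Heart-rate correct the QT interval: QTc = QT / sqrt(RR).

    Parameters
    ----------
    qt : float or array-like
        QT interval in milliseconds, > 0.
    rr : float or array-like
        RR interval in seconds, > 0.

    Returns
    -------
    float or ndarray
        Corrected QT in milliseconds.
    """
    qt_arr = np.asarray(qt, dtype=float)
    rr_arr = np.asarray(rr, dtype=float)
    if np.any(qt_arr <= 0) or np.any(rr_arr <= 0):
        raise ValueError("bazett_qtc requires strictly positive QT and RR")
    out = qt_arr / np.sqrt(rr_arr)
    if np.isscalar(qt) and np.isscalar(rr):
        return float(out)
    return out


_ECG_REASONS = {
    "qrs_duration": "qrs_gt_120",
    "heart_rate": "heart_rate_out_of_range",
}


def apply_ecg_exclusions(
    samples: pd.DataFrame, exclusion_flags: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply ECG- and participant-level exclusions for the QTc analysis.

    ECGs with QRS duration > 120 ms or heart rate < 40 or > 120 bpm are
    excluded, as is any sample with a true condition/medication flag
    (WPW, pacemaker, high-grade AV block, class I/III antiarrhythmic use,
    digoxin use). Heart rate may be given directly (``heart_rate``, bpm) or
    as an RR interval in seconds (``rr_interval``), in which case
    HR = 60 / RR. Missing flag values are treated as false.

    Returns ``(kept samples, exclusion log)``; the log has one row per
    (sample, triggered reason).
    """
    if exclusion_flags is None:
        exclusion_flags = TRAITS["qtc"].exclusion_flags
    if "qrs_duration" not in samples.columns:
        raise KeyError("apply_ecg_exclusions requires a 'qrs_duration' column")
    if "heart_rate" in samples.columns:
        hr = samples["heart_rate"].astype(float)
    elif "rr_interval" in samples.columns:
        hr = 60.0 / samples["rr_interval"].astype(float)
    else:
        raise KeyError(
            "apply_ecg_exclusions requires a 'heart_rate' or 'rr_interval' column"
        )

    reasons: list[tuple[object, str]] = []
    qrs = samples["qrs_duration"].astype(float)
    excluded = pd.Series(False, index=samples.index)

    mask = qrs > 120
    excluded |= mask.fillna(False)
    reasons += [(i, "qrs_gt_120") for i in samples.index[mask.fillna(False)]]

    mask = (hr < 40) | (hr > 120)
    excluded |= mask.fillna(False)
    reasons += [(i, "heart_rate_out_of_range") for i in samples.index[mask.fillna(False)]]

    for flag in exclusion_flags:
        if flag not in samples.columns:
            continue
        mask = samples[flag].map(lambda v: bool(v) if pd.notna(v) else False)
        excluded |= mask
        reasons += [(i, flag) for i in samples.index[mask]]

    log = pd.DataFrame(reasons, columns=["sample_id", "reason"])
    return samples.loc[~excluded], log


def impute_covariates(samples: pd.DataFrame, spec: TraitSpec) -> pd.DataFrame:
    """Fill missing clinical covariates per the trait's imputation rules.

    Continuous covariates (HDL, MCV) go to the median of observed values;
    binary history/medication covariates go to False. Observed values are
    never altered.
    """
    out = samples.copy()
    for col in spec.continuous_covariates:
        if col not in out.columns:
            raise KeyError(f"missing covariate column: {col}")
        vals = out[col].astype(float)
        if vals.isna().all():
            raise ValueError(f"covariate {col!r} is entirely missing; median undefined")
        out[col] = vals.fillna(vals.median())
    for col in spec.binary_covariates:
        if col not in out.columns:
            raise KeyError(f"missing covariate column: {col}")
        out[col] = out[col].map(lambda v: bool(v) if pd.notna(v) else False).astype(bool)
    return out


def build_analysis_cohort(
    samples: pd.DataFrame,
    spec: TraitSpec,
    n_pcs: int = 12,
) -> AnalysisCohort:
    """Apply exclusions then imputation and assemble the analysis cohort.

    ``samples`` must carry the phenotype column named after the trait, an
    ``age`` and ``sex`` column, the trait's clinical covariates, and pc1..pcK
    principal-component columns. Samples with a missing phenotype are
    dropped (logged as ``phenotype_missing``).
    """
    n_input = len(samples)
    logs = []

    kept = samples
    if spec.ecg_exclusions:
        kept, ecg_log = apply_ecg_exclusions(kept, spec.exclusion_flags)
        logs.append(ecg_log)

    pheno_missing = kept[spec.trait].isna()
    if pheno_missing.any():
        logs.append(
            pd.DataFrame(
                {"sample_id": kept.index[pheno_missing], "reason": "phenotype_missing"}
            )
        )
        kept = kept.loc[~pheno_missing]

    if len(kept) == 0:
        raise ValueError("all samples excluded; analysis cohort is empty")

    kept = impute_covariates(kept, spec)

    pc_cols = [f"pc{i}" for i in range(1, n_pcs + 1) if f"pc{i}" in kept.columns]
    cov_cols = ["age", "sex"] + spec.covariates + pc_cols
    missing = [c for c in cov_cols if c not in kept.columns]
    if missing:
        raise KeyError(f"missing covariate columns: {missing}")

    log = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame(columns=["sample_id", "reason"])
    )
    return AnalysisCohort(
        trait=spec.trait,
        phenotype=kept[spec.trait].astype(float),
        covariates=kept[cov_cols].astype(float),
        exclusion_log=log,
        n_input=n_input,
        n_final=len(kept),
    )
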