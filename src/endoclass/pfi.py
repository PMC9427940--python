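"""Predicted functional impact (PFI): aggregation of 31 in-silico predictors.

PFI is the fraction of available prediction tools that call a variant
damaging. A tool counts as a hit when its qualitative prediction is "D"
("H" for the MutationAssessor-style slot) or its quantitative rank score
exceeds 0.90. Tools with no prediction (NA) are excluded from the
denominator; a variant with no available tool has an undefined PFI.

The tool roster follows the dbNSFP v4 convention: 22 qualitative tools
(SIFT, SIFT4G, Polyphen2 HDIV/HVAR, LRT, MutationTaster, FATHMM, PROVEAN,
MetaSVM, MetaLR, MetaRNN, M-CAP, PrimateAI, DEOGEN2, BayesDel addAF/noAF,
ClinPred, LIST-S2, fathmm-MKL, fathmm-XF, MutationAssessor, ALoFT) and 9
quantitative rank-score tools (VEST4, REVEL, MutPred, MVP, MPC, DANN,
CADD, Eigen, Eigen-PC).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "QUALITATIVE_TOOLS",
    "QUANTITATIVE_TOOLS",
    "ALL_TOOLS",
    "MUTATION_ASSESSOR_SLOT",
    "compute_pfi",
    "compute_pfi_table",
    "summarize_pfi",
]

MUTATION_ASSESSOR_SLOT = "MutationAssessor"

QUALITATIVE_TOOLS: tuple[str, ...] = (
    "SIFT", "SIFT4G", "Polyphen2_HDIV", "Polyphen2_HVAR", "LRT",
    "MutationTaster", "FATHMM", "PROVEAN", "MetaSVM", "MetaLR", "MetaRNN",
    "M-CAP", "PrimateAI", "DEOGEN2", "BayesDel_addAF", "BayesDel_noAF",
    "ClinPred", "LIST-S2", "fathmm-MKL", "fathmm-XF",
    MUTATION_ASSESSOR_SLOT, "ALoFT",
)

QUANTITATIVE_TOOLS: tuple[str, ...] = (
    "VEST4", "REVEL", "MutPred", "MVP", "MPC", "DANN", "CADD",
    "Eigen", "Eigen-PC",
)

ALL_TOOLS: tuple[str, ...] = QUALITATIVE_TOOLS + QUANTITATIVE_TOOLS

RANK_SCORE_CUTOFF = 0.90  # quantitative hit iff rank score strictly above


def _is_na(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str):
        return value.strip() in {"", ".", "NA", "nan"}
    return pd.isna(value)


def _qualitative_hit(tool: str, value: str) -> bool:
    # multi-transcript entries like "D;T" count as a hit if any sub-prediction hits
    letters = {part.strip() for part in str(value).split(";")}
    hit_letter = "H" if tool == MUTATION_ASSESSOR_SLOT else "D"
    return hit_letter in letters


def compute_pfi(profile) -> tuple[float, int]:
    """Compute the PFI score for one variant's predictor profile.

    Parameters
    ----------
    profile : mapping or pandas Series
        Tool name -> prediction. Qualitative tools hold letters (possibly
        ";"-joined across transcripts), quantitative tools hold rank scores
        in [0, 1]. Missing predictions may be None, NaN, "", "." or "NA".
        Tools absent from the mapping are treated as NA.

    Returns
    -------
    (pfi, n_available)
        ``pfi`` is hits / available in [0, 1], or NaN when no tool has a
        prediction; ``n_available`` counts tools with a prediction.
    """
    hits = 0
    available = 0
    for tool in QUALITATIVE_TOOLS:
        value = profile.get(tool) if hasattr(profile, "get") else profile[tool]
        if _is_na(value):
            continue
        available += 1
        if _qualitative_hit(tool, value):
            hits += 1
    for tool in QUANTITATIVE_TOOLS:
        value = profile.get(tool) if hasattr(profile, "get") else profile[tool]
        if _is_na(value):
            continue
        score = float(value)
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"rank score for {tool} outside [0, 1]: {score}")
        available += 1
        if score > RANK_SCORE_CUTOFF:
            hits += 1
    if available == 0:
        return float("nan"), 0
    return hits / available, available


def compute_pfi_table(predictors: pd.DataFrame) -> pd.DataFrame:
    """Score every variant in a dbNSFP-style table (one row per variant).

    Returns a frame with ``variant_key`` (if present), ``pfi`` and
    ``n_available``; variants with no available tool get PFI NaN and are
    flagged in ``status``.
    """
    records = []
    for _, row in predictors.iterrows():
        pfi, n_avail = compute_pfi(row)
        records.append((pfi, n_avail))
    out = pd.DataFrame(records, columns=["pfi", "n_available"])
    out.index = predictors.index
    if "variant_key" in predictors.columns:
        out.insert(0, "variant_key", predictors["variant_key"].to_numpy())
    out["status"] = np.where(out["n_available"] > 0, "ok", "no_prediction")
    return out


def summarize_pfi(pfi_table: pd.DataFrame, by: str | pd.Series) -> pd.DataFrame:
    """Median and quartiles of defined PFI scores per group.

    ``by`` is a column name in ``pfi_table`` or an aligned Series of group
    labels. Undefined PFIs are excluded (their counts reported); groups
    with no defined PFI are omitted.
    """
    groups = pfi_table[by] if isinstance(by, str) else by
    rows = []
    for name, sub in pfi_table.groupby(groups):
        defined = sub["pfi"].dropna()
        if defined.empty:
            continue
        rows.append({
            "group": name,
            "n": len(defined),
            "n_undefined": int(sub["pfi"].isna().sum()),
            "median_pfi": float(defined.median()),
            "q1_pfi": float(defined.quantile(0.25)),
            "q3_pfi": float(defined.quantile(0.75)),
        })
    return pd.DataFrame(rows, columns=["group", "n", "n_undefined",
                                       "median_pfi", "q1_pfi", "q3_pfi"])
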