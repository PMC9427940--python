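"""End-to-end orchestration: simulate -> QC -> phenotype prep -> association -> evaluation -> PFI.

Every stage reads and writes declared files under one output directory and
the run is summarized in a JSON manifest (config snapshot, seed, per-stage
row counts, output digests). All randomness flows from the single config
seed, so a rerun with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from endoclass import io
from endoclass.association import (
    carrier_category_contrasts,
    estimate_all_effects,
    trait_sd,
)
from endoclass.evaluate import (
    fit_discrimination,
    nominate_variants,
    nominated_fractions,
    sd_threshold_sweep,
    summarize_by_consequence,
    carrier_fraction_large_effect,
)
from endoclass.pfi import compute_pfi_table, summarize_pfi
from endoclass.phenotypes import TRAITS, build_analysis_cohort
from endoclass.qc import filter_variants
from endoclass.simulate import (
    SimulationConfig,
    generate_assertions,
    generate_cohort,
    generate_predictor_matrix,
)

__all__ = ["run_pipeline"]


def run_pipeline(
    config: SimulationConfig,
    outdir,
    sd_multiple: float = 0.5,
    sd_grid=(0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0),
) -> dict:
    """Run the full synthetic pipeline and write all tables plus a manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = TRAITS[config.trait]
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "trait": config.trait,
        "stages": {},
        "outputs": {},
        "warnings": [],
    }

    # simulate
    genotypes, variants, samples, truth, meta = generate_cohort(config)
    assertions = generate_assertions(truth, config)
    predictors = generate_predictor_matrix(truth, config)
    io.write_dosage_tsv(genotypes, outdir / "dosages.tsv")
    io.write_vcf(genotypes, variants, outdir / "genotypes.vcf")
    io.write_table(variants, outdir / "variants.tsv")
    io.write_table(samples.reset_index(), outdir / "samples.tsv")
    io.write_table(truth, outdir / "truth.tsv")
    io.write_table(assertions, outdir / "assertions.tsv")
    io.write_table(predictors, outdir / "predictors.tsv")
    io.write_config(config, outdir / "config.yaml")
    manifest["stages"]["simulate"] = {
        "n_samples": len(samples), "n_variants": len(variants)}

    # variant QC (calls are clean by construction here; call-level filtering
    # is exercised through the qc stage of the CLI on raw call tables)
    vqc = filter_variants(genotypes)
    io.write_table(vqc, outdir / "variant_qc.tsv")
    passing = vqc.loc[vqc["pass"], "variant_key"].tolist()
    genotypes_qc = genotypes[passing]
    manifest["stages"]["qc"] = {
        "n_variants_in": len(vqc), "n_variants_pass": len(passing)}

    # phenotype prep
    cohort = build_analysis_cohort(samples, spec, n_pcs=config.n_pcs)
    io.write_table(cohort.exclusion_log, outdir / "exclusions.tsv")
    manifest["stages"]["prep"] = {
        "n_input": cohort.n_input, "n_final": cohort.n_final}

    # association
    effects, assoc_log = estimate_all_effects(genotypes_qc, cohort)
    io.write_table(effects, outdir / "effects.tsv")
    manifest["stages"]["associate"] = {
        "n_effects": len(effects), "log": assoc_log}
    contrasts = carrier_category_contrasts(cohort, genotypes_qc, assertions)
    io.write_table(contrasts, outdir / "category_contrasts.tsv")

    # evaluation
    sd = trait_sd(cohort)
    threshold = sd_multiple * sd
    disc = fit_discrimination(effects, assertions, "pathogenic_only")
    disc_pl = fit_discrimination(effects, assertions, "pathogenic_plus_likely")
    sweep = sd_threshold_sweep(effects, assertions, sd, sd_grid, genotypes=genotypes_qc)
    noms = nominate_variants(effects, assertions, threshold)
    fracs = nominated_fractions(noms)
    conseq = summarize_by_consequence(effects, variants, threshold,
                                      second_threshold=1.0 * sd)
    io.write_table(sweep, outdir / "threshold_sweep.tsv")
    io.write_table(noms, outdir / "nominations.tsv")
    io.write_table(conseq, outdir / "consequence_summary.tsv")
    io.write_table(
        pd.DataFrame(disc.roc_points, columns=["fpr", "tpr"]),
        outdir / "roc_points.tsv")
    manifest["stages"]["evaluate"] = {
        "trait_sd": sd,
        "threshold": threshold,
        "sd_multiple": sd_multiple,
        "auc_pathogenic": disc.auc,
        "auc_pathogenic_ci": [disc.ci_low, disc.ci_high],
        "auc_pathogenic_plus_likely": disc_pl.auc,
        "n_discrimination_variants": disc.n_variants,
        "nominated_fractions": fracs,
        "carrier_fraction_large_effect": _none_if_nan(
            carrier_fraction_large_effect(genotypes_qc, effects, assertions, threshold)),
    }

    # PFI
    pfi = compute_pfi_table(predictors)
    gene_map = variants.set_index("variant_key")["gene"]
    missense = variants.loc[variants["consequence"] == "missense", "variant_key"]
    pfi_missense = pfi.loc[pfi["variant_key"].isin(missense)]
    pfi_summary = summarize_pfi(
        pfi_missense, pfi_missense["variant_key"].map(gene_map))
    io.write_table(pfi, outdir / "pfi.tsv")
    io.write_table(pfi_summary, outdir / "pfi_by_gene.tsv")
    manifest["stages"]["pfi"] = {
        "n_scored": int(pfi["pfi"].notna().sum()),
        "n_undefined": int(pfi["pfi"].isna().sum()),
    }

    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = io.file_digest(f)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n")
    return manifest


def _none_if_nan(x: float):
    return None if (x is None or (isinstance(x, float) and np.isnan(x))) else x


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
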