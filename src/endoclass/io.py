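"""Reading and writing the pipeline's file formats.

Genotypes travel either as a minimal VCF (FORMAT GT:DP:AD:GQ:PL) or as a
rectangular dosage TSV (samples x variants); all other tables are TSV with
the documented headers, and the simulation config round-trips through YAML.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from endoclass.simulate import SimulationConfig

__all__ = [
    "write_dosage_tsv", "read_dosage_tsv",
    "write_vcf", "read_vcf_dosages",
    "write_table", "read_table",
    "write_config", "read_config",
    "file_digest",
]

_FLOAT_FORMAT = "%.10g"  # fixed formatting keeps reruns byte-identical


def write_dosage_tsv(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT,
                     index_label="sample_id")


def read_dosage_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id").astype(float)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT, index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">
##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene">
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    path,
    calls: pd.DataFrame | None = None,
) -> None:
    """Write dosages as a minimal VCF.

    Without a call table, per-call DP/AD/GQ/PL are filled with clean
    placeholder values consistent with the genotype; with one, the recorded
    call-level fields are used.
    """
    call_lookup = None
    if calls is not None:
        call_lookup = calls.set_index(["sample_id", "variant_key"])

    samples = list(genotypes.index)
    var = variants.set_index("variant_key")
    lines = [_VCF_HEADER.rstrip("\n")]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in samples))
    order = var.assign(_pos=var["pos"].astype(int)).sort_values(["chrom", "_pos"]).index
    for key in order:
        row = var.loc[key]
        fields = [str(row["chrom"]), str(int(row["pos"])), key,
                  str(row["ref"]), str(row["alt"]), ".", "PASS",
                  f"GENE={row['gene']}", "GT:DP:AD:GQ:PL"]
        for s in samples:
            dosage = genotypes.at[s, key]
            if np.isnan(dosage):
                fields.append("./.:.:.:.:.")
                continue
            d = int(dosage)
            if call_lookup is not None and (s, key) in call_lookup.index:
                c = call_lookup.loc[(s, key)]
                dp = int(c["total_depth"])
                ad = f"{int(c['ref_depth'])},{int(c['alt_depth'])}"
                gq = int(c["genotype_quality"])
                pl = int(c["genotype_likelihood"])
            else:
                dp, gq, pl = 50, 99, 99
                ad = {0: "50,0", 1: "25,25", 2: "0,50"}[d]
            fields.append(f"{_GT_STRINGS[d]}:{dp}:{ad}:{gq}:{pl}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_dosages(path) -> pd.DataFrame:
    """Read a VCF back into a dosage matrix (NaN for missing genotypes)."""
    header = None
    rows = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header = line.lstrip("#").split("\t")
                continue
            parts = line.split("\t")
            key = parts[2]
            dosages = []
            for entry in parts[9:]:
                gt = entry.split(":", 1)[0]
                if "." in gt:
                    dosages.append(np.nan)
                else:
                    dosages.append(float(sum(int(a) for a in gt.replace("|", "/").split("/"))))
            rows[key] = dosages
    samples = header[9:]
    return pd.DataFrame(rows, index=pd.Index(samples, name="sample_id"))


def write_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def read_config(path) -> SimulationConfig:
    return SimulationConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
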