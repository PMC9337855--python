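"""Tabular readers and writers for the pipeline's file formats.

All tables are UTF-8 CSV/TSV (delimiter chosen by extension) with "NA" as
the missing token and a comment header recording the package version, the
RNG seed, and a configuration hash, so every output is traceable to the run
that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .series import PlantSeries, TREATMENT_START_DAS, clean_series

NA_TOKEN = "NA"

PHENOTYPE_COLUMNS = ["plant_id", "accession", "experiment", "temperature_C", "time_dap", "area"]


def _sep(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".txt") else ","


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed=None, cfg_hash=None, index=False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# thermogrowth {__version__}"
    if seed is not None:
        header += f"; seed={seed}"
    if cfg_hash is not None:
        header += f"; config={cfg_hash}"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep=_sep(path), na_rep=NA_TOKEN, index=index)
    return path


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=_sep(Path(path)), comment="#", na_values=NA_TOKEN, index_col=index_col
    )


# ---------------------------------------------------------------------------
# phenotypes

def read_phenotypes(path) -> pd.DataFrame:
    df = read_table(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    return df


def phenotypes_to_series(df: pd.DataFrame, clean: bool = True) -> list[PlantSeries]:
    """Long-format phenotype table -> per-plant series on the model clock.

    Times are shifted from days-after-stratification to days since treatment
    start; series are running-maximum cleaned unless ``clean=False``.
    """
    out = []
    for pid, g in df.groupby("plant_id", sort=True):
        g = g.sort_values("time_dap")
        s = PlantSeries(
            plant_id=str(pid),
            accession=str(g["accession"].iloc[0]),
            experiment=str(g["experiment"].iloc[0]),
            temperature=str(g["temperature_C"].iloc[0]),
            times=g["time_dap"].to_numpy(float) - TREATMENT_START_DAS,
            areas=g["area"].to_numpy(float),
        )
        out.append(clean_series(s) if clean else s)
    return out


# ---------------------------------------------------------------------------
# genotypes

def write_genotypes(G: pd.DataFrame, path, seed=None, cfg_hash=None) -> Path:
    out = G.copy()
    out.index.name = "accession"
    return write_table(out, path, seed=seed, cfg_hash=cfg_hash, index=True)


def read_genotypes(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz"):
        return read_vcf(path)
    return read_table(path, index_col="accession")


def write_vcf(G: pd.DataFrame, path, positions: pd.DataFrame | None = None) -> Path:
    """Minimal haploid VCF for an accessions x SNPs {0,1} matrix.

    SNP ids of the form ``chrom:pos`` are used for coordinates; otherwise
    SNPs are laid out consecutively on chromosome 1.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    samples = list(G.index)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=thermogrowth {__version__}\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, snp in enumerate(G.columns):
            parts = str(snp).split(":")
            if len(parts) == 2 and parts[1].isdigit():
                chrom, pos = parts[0], int(parts[1])
            else:
                chrom, pos = "1", j + 1
            calls = "\t".join(str(int(v)) for v in G[snp].to_numpy())
            fh.write(f"{chrom}\t{pos}\t{snp}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")
    return path


def read_vcf(path) -> pd.DataFrame:
    """Read a (haploid or homozygous-diploid) biallelic VCF into {0,1} counts."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, data = [], []
    for var in vcf:
        gts = var.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        alleles = np.where(gts == 3, 1.0, np.where(gts == 0, 0.0, np.nan))
        name = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
        cols.append(name)
        data.append(alleles)
    G = pd.DataFrame(np.array(data).T, index=samples, columns=cols)
    G.index.name = "accession"
    return G


# ---------------------------------------------------------------------------
# kinship

def write_kinship(K: np.ndarray, ids, path, seed=None, cfg_hash=None) -> Path:
    df = pd.DataFrame(K, index=ids, columns=ids)
    df.index.name = "accession"
    return write_table(df, path, seed=seed, cfg_hash=cfg_hash, index=True)


def read_kinship(path):
    df = read_table(path, index_col="accession")
    return df.to_numpy(float), list(df.index)


# ---------------------------------------------------------------------------
# JSON helpers

def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
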