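"""Readers and writers for the plain-text formats the pipeline exchanges.

Genotypes travel as VCF (unphased GT, ``./.`` for missing) or as a TSV dosage
matrix (rows = lines, header = marker ids, ``NA`` missing); phenotypes, BLUEs,
GEBVs and selection reports as CSV; the GRM as TSV with an id column; variance
components and run manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .qc import GRM
from .sim import GenotypeMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_grm_tsv",
    "read_grm_tsv",
    "write_trial_csv",
    "read_trial_csv",
    "write_components_json",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Minimal biallelic VCF with unphased GT calls (synthetic coordinates)."""
    if geno.continuous:
        raise ValueError("cannot write imputed continuous dosages as VCF genotypes")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.line_ids) + "\n")
        for j, mid in enumerate(geno.marker_ids):
            calls = [
                "./." if geno.missing_mask[i, j] else _GT[int(geno.dosages[i, j])]
                for i in range(geno.n_lines)
            ]
            fh.write(f"1\t{j + 1}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes; dosage = count of the ALT allele.

    Multiallelic records are rejected with an explicit error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids: list[str] = []
    rows = []
    masks = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic site {var.CHROM}:{var.POS} not supported; "
                "split or drop it first"
            )
        gts = var.genotype.array()[:, :2]
        miss = (gts < 0).any(axis=1)
        dos = np.clip(gts, 0, None).sum(axis=1)
        rows.append(np.where(miss, -1, dos).astype(np.int8))
        masks.append(miss)
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    return GenotypeMatrix(
        line_ids, marker_ids, np.array(rows).T, np.array(masks).T
    )


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    X = geno.dosages.astype(float if geno.continuous else object)
    df = pd.DataFrame(
        np.where(geno.missing_mask, np.nan, X),
        index=pd.Index(geno.line_ids, name="line"),
        columns=geno.marker_ids,
    )
    df.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    vals = df.to_numpy(float)
    mask = np.isnan(vals)
    continuous = bool(np.nanmax(np.abs(vals - np.round(vals))) > 0) if vals.size else False
    dos = np.where(mask, -1, vals)
    if not continuous:
        dos = dos.astype(np.int8)
    return GenotypeMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], dos, mask,
        continuous=continuous,
    )


def write_grm_tsv(grm: GRM, path: str | Path) -> None:
    pd.DataFrame(
        grm.values, index=pd.Index(grm.line_ids, name="line"), columns=grm.line_ids
    ).to_csv(path, sep="\t", float_format="%.10g")


def read_grm_tsv(path: str | Path) -> GRM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GRM([str(i) for i in df.index], df.to_numpy(float))


def write_trial_csv(trial: pd.DataFrame, path: str | Path) -> None:
    trial.to_csv(path, index=False)


def read_trial_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"site", "rep", "row", "col", "accession"}
    if not need.issubset(df.columns):
        raise ValueError(f"trial table must have columns {sorted(need)}")
    return df


def write_components_json(components, path: str | Path) -> None:
    def enc(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items()}
        raise TypeError(f"cannot serialize {type(o)}")

    with Path(path).open("w") as fh:
        json.dump(components, fh, default=enc, indent=1)
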