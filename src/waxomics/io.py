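"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as minimal VCF 4.2 (GT fields, INFO DR2) or as a TSV dosage
matrix (lines as rows, SNP ids as columns); gene models as GFF3 (1-based
inclusive, type=gene); plot tables, trait panels and association tables as
TSV; truth records, QC reports and prediction reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import GenomeLayout, GenotypeMatrix, TruthRecord

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DR2,Number=1,Type=Float,Description="Imputation dosage r-squared">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.line_ids) + "\n")
        for j, row in enumerate(gm.snp_meta.itertuples(index=False)):
            gts = "\t".join(_GT[int(d)] for d in gm.dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\tA\tT\t.\tPASS\tDR2={row.dr2:g}\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a (plain-text) VCF into a dosage matrix via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    rows, dosage_cols = [], []
    for var in vcf:
        dr2 = var.INFO.get("DR2", 1.0)
        gts = var.gt_types  # 0=hom ref, 1=het, 2=hom alt (gts012=False: 3=hom alt)
        dos = np.array([{0: 0, 1: 1, 2: 2, 3: 2}[int(g)] for g in gts], dtype=np.int8)
        dosage_cols.append(dos)
        rows.append((var.ID, var.CHROM, var.POS, float(dr2)))
    dosages = np.column_stack(dosage_cols)
    meta = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "dr2"])
    f = dosages.mean(axis=0) / 2.0
    meta.insert(3, "maf", np.minimum(f, 1 - f))
    return GenotypeMatrix(dosages=dosages, snp_meta=meta, line_ids=line_ids)


def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.dosages, index=gm.line_ids, columns=gm.snp_meta["snp_id"])
    df.to_csv(path, sep="\t", index_label="line_id")


def read_dosage_tsv(path, snp_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="line_id")
    dos = df.to_numpy(np.int8)
    if snp_meta is None:
        # fall back to ids of the form snp_<chrom>_<pos>
        parts = [c.split("_") for c in df.columns]
        snp_meta = pd.DataFrame(
            {
                "snp_id": df.columns,
                "chrom": [p[1] if len(p) >= 3 else "1" for p in parts],
                "pos": [int(p[2]) if len(p) >= 3 else i for i, p in enumerate(parts)],
            }
        )
        snp_meta["dr2"] = 1.0
    f = dos.mean(axis=0) / 2.0
    snp_meta = snp_meta.copy()
    snp_meta["maf"] = np.minimum(f, 1 - f)
    return GenotypeMatrix(dosages=dos, snp_meta=snp_meta, line_ids=list(df.index))


def write_gff3(layout: GenomeLayout, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, L in layout.chrom_lengths:
            fh.write(f"##sequence-region {chrom} 1 {L}\n")
        for r in layout.genes.itertuples(index=False):
            fh.write(
                f"{r.chrom}\twaxomics\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\tID={r.gene_id}\n"
            )


def read_gff3(path) -> GenomeLayout:
    chrom_lengths, rows = [], []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()
                chrom_lengths.append((chrom, int(end)))
                continue
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append((attrs.get("ID", f"{f[0]}:{f[3]}"), f[0], int(f[3]), int(f[4]), f[6]))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    genes = genes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if not chrom_lengths:
        chrom_lengths = [
            (c, int(sub["end"].max())) for c, sub in genes.groupby("chrom", sort=False)
        ]
    return GenomeLayout(chrom_lengths=chrom_lengths, genes=genes)


def write_plot_table(pt: pd.DataFrame, path) -> None:
    pt.to_csv(path, sep="\t", index=False)


def read_plot_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: TruthRecord, path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=1))


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, set):
        return sorted(x)
    raise TypeError(f"cannot serialize {type(x)}")
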