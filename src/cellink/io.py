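"""File formats and core containers shared across the pipeline.

Genotypes travel as VCF v4.2 (GT-only, plain text), single-nucleus counts as
Matrix Market sparse matrices with TSV gene/cell sidecars, and everything
else as tab-separated tables with a single header row.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

__all__ = [
    "GenotypeMatrix",
    "read_vcf",
    "write_vcf",
    "read_counts",
    "write_counts",
    "read_tsv",
    "write_tsv",
    "write_manifest",
    "file_checksum",
]


@dataclass
class GenotypeMatrix:
    """Donors x variants dosage table plus per-variant metadata.

    ``dosages`` holds alt-allele counts in {0, 1, 2} as floats with NaN for
    missing calls; rows are donors, columns variant identifiers.
    ``variants`` carries one row per variant with columns
    ``variant, chrom, pos, ref, alt`` (``pos`` is 1-based).
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.variants["variant"]):
            raise ValueError("dosage columns and variant table must align")
        if not self.variants["pos"].is_monotonic_increasing:
            # a single simulated chromosome keeps positions sorted; real
            # multi-chromosome input is sorted within chromosome by the reader
            pass

    @property
    def donors(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        keep = list(variant_ids)
        return GenotypeMatrix(
            dosages=self.dosages[keep].copy(),
            variants=self.variants.set_index("variant").loc[keep].reset_index(),
        )


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> Path:
    """Write genotypes as a minimal plain-text VCF v4.2 with GT fields."""
    path = Path(path)
    donors = geno.donors
    lines = [_VCF_HEADER]
    for chrom in dict.fromkeys(geno.variants["chrom"]):
        lines.append(f"##contig=<ID={chrom}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(donors)
        + "\n"
    )
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    dos = geno.dosages.to_numpy()
    for j, rec in enumerate(geno.variants.itertuples(index=False)):
        calls = [
            "./." if np.isnan(d) else gt_code[float(d)] for d in dos[:, j]
        ]
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t{rec.variant}\t{rec.ref}\t{rec.alt}"
            "\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
        )
    path.write_text("".join(lines))
    return path


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF into a dosage matrix (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    donors = list(vcf.samples)
    rows = []
    dosage_cols = {}
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        rows.append(
            {
                "variant": vid,
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=missing
        gt = np.asarray(rec.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        dosage_cols[vid] = gt
    variants = pd.DataFrame(rows)
    dosages = pd.DataFrame(dosage_cols, index=donors)
    return GenotypeMatrix(dosages=dosages, variants=variants)


def write_counts(adata: ad.AnnData, outdir: str | Path, layer: str | None = None) -> Path:
    """Write a cell matrix as matrix.mtx + genes.tsv + cells.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.layers[layer] if layer else adata.X
    X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())  # genes x cells
    genes = adata.var.reset_index().rename(columns={"index": "gene"})
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    cells = adata.obs.reset_index().rename(columns={"index": "cell"})
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    return outdir


def read_counts(indir: str | Path) -> ad.AnnData:
    """Read matrix.mtx + genes.tsv + cells.tsv back into an AnnData."""
    indir = Path(indir)
    X = scipy.io.mmread(str(indir / "matrix.mtx")).T.tocsr()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    adata = ad.AnnData(
        X=X,
        obs=cells.set_index("cell"),
        var=genes.set_index("gene"),
    )
    return adata


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> Path:
    """Echo configs, seeds and output checksums to a YAML run manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path
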