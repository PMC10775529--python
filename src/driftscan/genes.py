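"""Candidate-gene windowing: map significant SNPs to annotated genes.

A gene is a candidate for a SNP when the SNP lies within the gene span
inflated by a window (default 2 kb on each side, i.e. "around 4 kb" of
annotation per SNP), strand-agnostically and on closed 1-based intervals.
The output is deduplicated by gene, retaining the supporting SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
import pandas as pd

from .errors import ValidationError

__all__ = ["GeneRecord", "read_gff", "genes_near_snps"]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    description: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


def read_gff(path) -> list[GeneRecord]:
    """Read gene-type features from a GFF3 file.

    Only features of type ``gene`` are retained; the ``ID`` attribute names
    the gene and ``description`` or ``Note`` (first present) fills the
    description field.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils wraps line-level parse errors
        raise ValidationError(f"malformed GFF3 {path}: {exc}") from exc
    records = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        desc = ""
        for key in ("description", "Note"):
            if key in feat.attributes:
                desc = feat.attributes[key][0]
                break
        records.append(
            GeneRecord(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
                description=desc,
            )
        )
    return records


def genes_near_snps(
    snps: pd.DataFrame, genes: list[GeneRecord], window_bp: int = 2000
) -> pd.DataFrame:
    """Candidate genes within ``window_bp`` of significant SNPs.

    ``snps`` needs columns ``chrom`` and ``pos`` (1-based).  A SNP supports a
    gene iff gene.start - window <= pos <= gene.end + window.  One row per
    gene (deduplicated), with the count and sorted list of supporting SNPs.
    """
    if window_bp < 0:
        raise ValidationError("window_bp must be >= 0")
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    hits: dict[str, set] = {}
    meta: dict[str, GeneRecord] = {}
    for row in snps[["chrom", "pos"]].drop_duplicates().itertuples(index=False):
        for g in by_chrom.get(row.chrom, ()):
            if g.start - window_bp <= row.pos <= g.end + window_bp:
                hits.setdefault(g.gene_id, set()).add((row.chrom, int(row.pos)))
                meta[g.gene_id] = g
    rows = []
    for gene_id in sorted(hits):
        g = meta[gene_id]
        supporting = sorted(hits[gene_id])
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "description": g.description,
                "n_snps": len(supporting),
                "snp_list": ";".join(f"{c}:{p}" for c, p in supporting),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "chrom",
            "start",
            "end",
            "strand",
            "description",
            "n_snps",
            "snp_list",
        ],
    )
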