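"""Chromosome-order nomenclature, exon counts, promoter extraction.

Family members are named by genomic position (prefix + rank + suffix,
e.g. OsAGP1P..OsAGP43P), chromosomes sorted in natural order so Chr2
precedes Chr10. Promoters are the fixed window (default 2000 bp)
immediately upstream of the start codon, strand-aware and clipped at
contig boundaries.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from .seqio import GeneModel

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterRecord:
    """An upstream promoter window; ``truncated`` marks contig clipping."""

    gene_id: str
    seq: str
    truncated: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key treating digit runs numerically, so Chr2 < Chr10."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def assign_family_names(
    genes: Iterable[GeneModel], prefix: str = "OsAGP", suffix: str = "P"
) -> dict[str, str]:
    """Name genes prefix+rank+suffix by (chromosome, start) order.

    Rank 1 is the gene earliest on the naturally-first chromosome. Exact
    (chrom, start) ties are broken by gene_id lexicographically, with a
    warning.
    """
    genes = list(genes)
    by_pos: dict[tuple[str, int], list[str]] = {}
    for g in genes:
        by_pos.setdefault((g.chrom, g.start), []).append(g.gene_id)
    for (chrom, start), ids in by_pos.items():
        if len(ids) > 1:
            warnings.warn(
                f"tie at {chrom}:{start} between {', '.join(sorted(ids))}; "
                "broken by gene_id"
            )
    ordered = sorted(
        genes, key=lambda g: (natural_chrom_key(g.chrom), g.start, g.gene_id)
    )
    return {g.gene_id: f"{prefix}{i}{suffix}" for i, g in enumerate(ordered, 1)}


def count_exons(gene: GeneModel) -> int:
    return len(gene.exons)


def extract_promoter(
    genome: Mapping[str, str], gene: GeneModel, window: int = 2000
) -> PromoterRecord:
    """The ``window`` bases immediately upstream of the start codon.

    The anchor is the CDS start when the annotation provides one, else
    the gene start. On the + strand this is bases
    [anchor-window, anchor-1] (1-based inclusive); on the - strand, the
    reverse complement of [anchor+1, anchor+window]. Windows running off
    the contig are clipped and flagged ``truncated``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} not in genome")
    contig = genome[gene.chrom]
    if gene.strand == "+":
        anchor = gene.cds_start if gene.cds_start is not None else gene.start
        lo = max(1, anchor - window)
        seq = contig[lo - 1 : anchor - 1]
        truncated = anchor - window < 1
    else:
        anchor = gene.cds_end if gene.cds_end is not None else gene.end
        hi = min(len(contig), anchor + window)
        seq = revcomp(contig[anchor : hi])
        truncated = anchor + window > len(contig)
    return PromoterRecord(gene_id=gene.gene_id, seq=seq, truncated=truncated)


def extract_promoters(
    genome: Mapping[str, str], genes: Iterable[GeneModel], window: int = 2000
) -> list[PromoterRecord]:
    return [extract_promoter(genome, g, window) for g in genes]


def promoter_fasta_header(gene: GeneModel, window: int = 2000) -> str:
    return f"{gene.gene_id} promoter:-{window}..-1 strand={gene.strand}"
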