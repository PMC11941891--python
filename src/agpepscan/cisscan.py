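"""Table-driven promoter cis-element census.

Scans promoter windows for IUPAC-degenerate element consensi (G-box,
ABRE, MBS, ...) on both strands, reporting every overlapping occurrence,
and summarizes hits per gene by functional category (light / stress /
growth / hormone). The bundled default table is a curated approximation
of common PlantCARE consensi and is meant to be edited; a census run
against a different table or database version will differ.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from ._tables import default_motif_rows
from .genomics import PromoterRecord, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

CATEGORIES = ("light", "stress", "growth", "hormone")


@dataclass(frozen=True)
class MotifDef:
    name: str
    consensus: str
    category: str

    def __post_init__(self) -> None:
        if len(self.consensus) < 4:
            raise ValueError(f"{self.name}: consensus shorter than 4")
        for c in self.consensus:
            if c not in IUPAC:
                raise ValueError(f"{self.name}: illegal IUPAC character {c!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    offset: int  # 1-based position of the match start in the promoter
    strand: str  # '+' or '-'


def compile_motif(consensus: str) -> re.Pattern:
    """Compile an IUPAC consensus into a regex matching exactly its expansion."""
    parts = []
    for c in consensus.upper():
        if c not in IUPAC:
            raise ValueError(f"illegal IUPAC character {c!r}")
        bases = IUPAC[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def load_motif_table(path: str | Path | None = None) -> list[MotifDef]:
    """Load a motif table TSV (name, consensus, category); None = bundled default."""
    if path is None:
        rows = default_motif_rows()
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        rows = list(df[["name", "consensus", "category"]].itertuples(index=False))
    return [MotifDef(str(n), str(c).upper(), str(cat)) for n, c, cat in rows]


def scan_promoter(
    promoter: PromoterRecord,
    motifs: Iterable[MotifDef],
    both_strands: bool = True,
) -> list[MotifHit]:
    """All (overlapping) occurrences of each motif in one promoter.

    Minus-strand hits are found by scanning the reverse complement; their
    ``offset`` is the 1-based start of the occupied segment on the
    promoter's own (+) coordinates. Hits are sorted by offset, then
    strand, then motif name.
    """
    seq = promoter.seq.upper()
    hits: list[MotifHit] = []
    for motif in motifs:
        pat = compile_motif(motif.consensus)
        m = len(motif.consensus)
        for match in _overlapping(pat, seq):
            hits.append(MotifHit(promoter.gene_id, motif.name, match + 1, "+"))
        if both_strands:
            rc = revcomp(seq)
            for match in _overlapping(pat, rc):
                # map back to + coordinates of the occupied segment
                offset = len(seq) - match - m + 1
                hits.append(MotifHit(promoter.gene_id, motif.name, offset, "-"))
    hits.sort(key=lambda h: (h.offset, h.strand, h.motif))
    return hits


def _overlapping(pat: re.Pattern, seq: str) -> list[int]:
    out = []
    i = 0
    while True:
        m = pat.search(seq, i)
        if m is None:
            return out
        out.append(m.start())
        i = m.start() + 1


def scan_promoters(
    promoters: Iterable[PromoterRecord],
    motifs: Iterable[MotifDef],
    both_strands: bool = True,
) -> list[MotifHit]:
    motifs = list(motifs)
    out: list[MotifHit] = []
    for p in promoters:
        out.extend(scan_promoter(p, motifs, both_strands))
    return out


def summarize_categories(
    hits: Iterable[MotifHit], motifs: Iterable[MotifDef]
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Census tables from a hit list.

    Returns ``(per_gene, per_motif, per_category)``: a gene x category
    count table, total hits per motif, and grand totals per category.
    Category totals conserve the per-motif totals by construction.
    """
    motifs = list(motifs)
    cat_of = {m.name: m.category for m in motifs}
    df = pd.DataFrame(
        [(h.gene_id, h.motif, cat_of[h.motif]) for h in hits],
        columns=["gene_id", "motif", "category"],
    )
    if df.empty:
        per_gene = pd.DataFrame(columns=list(CATEGORIES))
        per_gene.index.name = "gene_id"
        return (
            per_gene,
            pd.Series(0, index=[m.name for m in motifs], name="hits"),
            pd.Series(0, index=list(CATEGORIES), name="hits"),
        )
    per_gene = (
        df.pivot_table(index="gene_id", columns="category", aggfunc="size", fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
    )
    per_motif = (
        df.groupby("motif").size().reindex([m.name for m in motifs], fill_value=0)
    )
    per_motif.name = "hits"
    per_category = (
        df.groupby("category").size().reindex(list(CATEGORIES), fill_value=0)
    )
    per_category.name = "hits"
    return per_gene, per_motif, per_category


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.gene_id, h.motif, h.offset, h.strand) for h in hits],
        columns=["gene_id", "motif", "offset", "strand"],
    )
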