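"""FASTA / GFF3 / report-table input and output.

Coordinates are 1-based inclusive everywhere in the toolkit (the GFF3
convention); conversion to Python's 0-based slicing happens only inside
sequence extraction code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Literal, Optional

from Bio import SeqIO

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTNX")


class ParseError(ValueError):
    """Raised on malformed input files."""


@dataclass
class ProteinRecord:
    """A protein (or nucleotide) sequence with its FASTA identity.

    ``id`` is the first whitespace-delimited token of the header; the
    remainder is kept as ``description``.
    """

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass
class GeneModel:
    """A gene feature with its exon structure.

    ``start``/``end`` are 1-based inclusive. ``exons`` is sorted,
    non-overlapping and contained in the gene span. When the annotation
    carries CDS features, ``cds_start``/``cds_end`` record the translated
    span so promoters can be anchored at the start codon rather than the
    transcript start.
    """

    gene_id: str
    chrom: str
    strand: Literal["+", "-"]
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ParseError(
                f"gene {self.gene_id}: invalid span {self.start}..{self.end}"
            )
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted(self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ParseError(f"gene {self.gene_id}: exon {s}..{e} reversed")
            if s <= prev_end:
                raise ParseError(f"gene {self.gene_id}: overlapping exons")
            if s < self.start or e > self.end:
                raise ParseError(f"gene {self.gene_id}: exon outside gene span")
            prev_end = e


def read_fasta(
    path: str | Path,
    alphabet: Literal["protein", "nucleotide"] = "protein",
    lenient: bool = False,
) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and line wraps joined; a single trailing
    ``*`` (translated stop) is stripped from protein records. Characters
    outside the alphabet raise :class:`ParseError` unless ``lenient``,
    in which case they are mapped to ``X`` (protein) / ``N`` (nucleotide).
    Duplicate ids and empty sequences are always errors.
    """
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else NUCLEOTIDE_ALPHABET
    unknown = "X" if alphabet == "protein" else "N"
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "protein" and seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ParseError(f"record {rec.id!r}: empty sequence")
        bad = sorted(set(seq) - allowed)
        if bad:
            if not lenient:
                raise ParseError(
                    f"record {rec.id!r}: illegal characters {''.join(bad)!r}"
                )
            seq = "".join(c if c in allowed else unknown for c in seq)
        desc = rec.description.split(None, 1)
        records.append(
            ProteinRecord(
                id=rec.id, seq=seq, description=desc[1] if len(desc) > 1 else ""
            )
        )
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise ParseError(f"duplicate ids: {', '.join(dups)}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_genome_fasta(path: str | Path, lenient: bool = True) -> dict[str, str]:
    """Read a genome FASTA as a ``chrom -> sequence`` map."""
    return {r.id: r.seq for r in read_fasta(path, alphabet="nucleotide", lenient=lenient)}


# --- GFF3 ---------------------------------------------------------------

def _gff_attributes(raw: str) -> dict[str, str]:
    out = {}
    for item in raw.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models (with exon structure) from a GFF3 file.

    One :class:`GeneModel` per ``gene`` feature, in file order. Exons are
    attached through their ``Parent`` chain (typically gene -> mRNA ->
    exon); when a gene has no exon features its CDS features are used
    instead, and a gene with neither gets a single exon spanning the gene.
    Exon/CDS features whose parent cannot be resolved to a gene are
    skipped with a warning; a feature with start > end is an error.
    """
    gene_rows: dict[str, tuple[str, str, int, int]] = {}  # gid -> (chrom, strand, start, end)
    order: list[str] = []
    # feature id -> owning gene id, for resolving Parent chains
    owner: dict[str, str] = {}
    pending: list[tuple[str, str, int, int]] = []  # (type, parent, start, end)

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"line {lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = parts
            start, end = int(start_s), int(end_s)
            if start > end:
                raise ParseError(f"line {lineno}: start {start} > end {end}")
            attrs = _gff_attributes(attrs_s)
            fid = attrs.get("ID")
            if ftype == "gene":
                gid = fid or attrs.get("Name") or f"gene_{lineno}"
                gene_rows[gid] = (chrom, strand if strand in "+-" else "+", start, end)
                order.append(gid)
                owner[gid] = gid
            elif ftype in ("mRNA", "transcript"):
                parent = attrs.get("Parent", "")
                if fid and parent in owner:
                    owner[fid] = owner[parent]
            elif ftype in ("exon", "CDS"):
                pending.append((ftype, attrs.get("Parent", ""), start, end))

    exon_lists: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_rows}
    cds_lists: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_rows}
    for ftype, parent, start, end in pending:
        gid = None
        for p in parent.split(","):
            if p in owner:
                gid = owner[p]
                break
        if gid is None:
            warnings.warn(f"{ftype} with unresolvable parent {parent!r} skipped")
            continue
        (exon_lists if ftype == "exon" else cds_lists)[gid].append((start, end))

    out: list[GeneModel] = []
    for gid in order:
        chrom, strand, start, end = gene_rows[gid]
        cds = sorted(cds_lists[gid])
        exons = sorted(exon_lists[gid]) or cds
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,  # type: ignore[arg-type]
                start=start,
                end=end,
                exons=exons,
                cds_start=cds[0][0] if cds else None,
                cds_end=cds[-1][1] if cds else None,
            )
        )
    return out


# --- report table -------------------------------------------------------

REPORT_COLUMNS = [
    "gene_id",
    "locus_id",
    "name",
    "past_pct",
    "sp",
    "gpi",
    "repeats_ap_pa_sp_tp",
    "aa_size",
    "mw_kda",
    "pi",
    "instability",
]


def round2(x: float) -> str:
    """Round half-up to two decimals, as printed in reports."""
    return str(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def write_report_tsv(rows, path: str | Path, header_comment: str | None = None) -> None:
    """Write screened candidates as the tab-delimited report table.

    One line per candidate with PAST%, the signal-peptide / GPI evidence
    printed Yes/No, the four dipeptide-repeat counts joined ``a/b/c/d``,
    and the physicochemical profile.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no rows")
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in rows:
            p = r.physchem
            fh.write(
                "\t".join(
                    [
                        r.protein.id,
                        r.locus_id or "None",
                        r.name or "",
                        round2(r.past_pct),
                        "Yes" if r.sp else "No",
                        "Yes" if r.gpi else "No",
                        "/".join(str(c) for c in r.repeats),
                        str(r.aa_size),
                        round2(p.mw_kda) if p else "",
                        round2(p.pi) if p else "",
                        round2(p.instability) if p else "",
                    ]
                )
                + "\n"
            )
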