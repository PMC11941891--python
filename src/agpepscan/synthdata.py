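"""Seeded synthetic-data generators with recorded ground truth.

Every input the toolkit consumes can be generated here: proteomes with
planted AG peptides among guaranteed-failing decoys, a toy genome +
GFF3 with planted promoter motifs, and clustered TPM matrices. Each
generator is a pure function of its parameters and seed, and every
truth table is *recomputed from the emitted artifact* rather than from
the construction intent, so incidental extra repeats or motifs are
recorded honestly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exprcluster import ExpressionMatrix
from .genomics import revcomp
from .screen import CandidateRow, count_dipeptide_repeats, past_fraction, past_pct_2dp
from .seqio import GeneModel, ProteinRecord

_HYDROPHOBIC = "LVIA"
_PAST_FILLER = "SAT"
_NONPAST_FILLER = "GEVNQKD"
_REJECTION_CAP = 100_000


@dataclass
class PlantedPeptideSpec:
    """Recipe for one planted AG peptide."""

    length: int = 69
    target_past_pct: float = 45.0
    repeat_targets: tuple[int, int, int, int] = (2, 1, 1, 0)
    with_sp_prefix: bool = True
    with_gpi_tail: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (30 <= self.length <= 200):
            raise ValueError("length must be within [30, 200]")
        if not (0 <= self.target_past_pct <= 100):
            raise ValueError("target_past_pct must be in [0, 100]")


# Fixed flanks with known PAST content, so target composition is solvable.
# SP prefix: Met + basic residue + 10-residue hydrophobic run (mean
# Kyte-Doolittle 3.8 > 1.6), satisfying the heuristic signal-peptide rule.
SP_PREFIX = "MKLLVILLVILA"
# GPI tail: small-residue omega window 18-28 from the C-terminus plus a
# 15-residue hydrophobic tail (mean KD 3.3 > 1.0).
GPI_TAIL = "SAGSAGSAGG" + "LAVLAVLAVLAVLAV"


def _past_count(seq: str) -> int:
    return sum(1 for c in seq if c in "PAST")


def _repeat_block(ap: int, pa: int, sp: int, tp: int) -> str:
    parts = []
    for unit, n in zip(("AP", "PA", "SP", "TP"), (ap, pa, sp, tp)):
        if n:
            parts.append(unit * n)
    return "G".join(parts)


def gen_ag_peptide(spec: PlantedPeptideSpec) -> tuple[ProteinRecord, CandidateRow]:
    """Generate one PAST-rich peptide and its ground-truth screen row.

    The sequence is assembled from an optional signal-peptide-like
    prefix, a PAST-rich core with embedded AP/PA/SP/TP repeats, and an
    optional GPI-like tail; the composition filler is chosen so the PAST
    percentage lands within +/-2 points of the target. The truth row is
    recounted from the final sequence.
    """
    rng = np.random.default_rng(spec.seed)
    prefix = SP_PREFIX if spec.with_sp_prefix else ""
    tail = GPI_TAIL if spec.with_gpi_tail else ""
    block = _repeat_block(*spec.repeat_targets)
    filler_len = spec.length - len(prefix) - len(tail) - len(block)
    if filler_len < 0:
        raise ValueError(
            f"infeasible spec: prefix+repeats+tail need "
            f"{spec.length - filler_len} residues but length is {spec.length}"
        )
    fixed = prefix + block + tail
    past_needed = round(spec.target_past_pct * spec.length / 100.0)
    past_now = _past_count(fixed)
    n_past_filler = min(max(past_needed - past_now, 0), filler_len)
    achieved = 100.0 * (past_now + n_past_filler) / spec.length
    if abs(achieved - spec.target_past_pct) > 2.0:
        raise ValueError(
            f"infeasible spec: closest achievable PAST {achieved:.1f}% is more "
            f"than 2 points from target {spec.target_past_pct}%"
        )
    filler = list(rng.choice(list(_PAST_FILLER), size=n_past_filler)) + list(
        rng.choice(list(_NONPAST_FILLER), size=filler_len - n_past_filler)
    )
    rng.shuffle(filler)
    split = int(rng.integers(0, len(filler) + 1))
    core = "".join(filler[:split]) + block + "".join(filler[split:])
    seq = prefix + core + tail
    assert len(seq) == spec.length
    rec = ProteinRecord(id=f"planted_{spec.seed}", seq=seq)
    truth = CandidateRow(
        protein=rec,
        past_pct=past_pct_2dp(seq),
        sp=spec.with_sp_prefix,
        gpi=spec.with_gpi_tail,
        repeats=count_dipeptide_repeats(seq),
    )
    return rec, truth


def gen_proteome(
    n_planted: int, n_decoys: int, seed: int = 0
) -> tuple[list[ProteinRecord], list[CandidateRow]]:
    """A proteome of planted AG peptides plus guaranteed-failing decoys.

    Planted peptides pass the default screen (length 50-75, PAST >= 35%,
    heuristic signal peptide, >= 1 repeat). Decoys are rejection-sampled
    uniform-composition proteins constrained to fail it outright:
    length outside [50, 75] or PAST below 30%.
    """
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truths: list[CandidateRow] = []
    for i in range(n_planted):
        repeats = tuple(int(x) for x in rng.integers(0, 4, size=4))
        if sum(repeats) == 0:
            repeats = (1, 1, 0, 0)
        length = int(rng.integers(55, 76))
        with_gpi = bool(rng.random() < 0.3)
        fixed = SP_PREFIX + _repeat_block(*repeats) + (GPI_TAIL if with_gpi else "")
        if length < len(fixed) + 4:  # recipe too crowded for a tail
            with_gpi = False
            fixed = SP_PREFIX + _repeat_block(*repeats)
        # clamp the sampled PAST target into this recipe's feasible band
        lo = 100.0 * _past_count(fixed) / length
        hi = 100.0 * (_past_count(fixed) + (length - len(fixed))) / length
        target = float(min(max(float(rng.integers(40, 56)), lo + 1.0), hi - 1.0))
        spec = PlantedPeptideSpec(
            length=length,
            target_past_pct=target,
            repeat_targets=repeats,  # type: ignore[arg-type]
            with_sp_prefix=True,
            with_gpi_tail=with_gpi,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, truth = gen_ag_peptide(spec)
        rec.id = f"AGpep{i + 1:03d}"
        truth.protein = rec
        records.append(rec)
        truths.append(truth)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for i in range(n_decoys):
        for _ in range(_REJECTION_CAP):
            length = int(rng.integers(30, 121))
            seq = "".join(rng.choice(aas, size=length))
            if not (50 <= length <= 75) or past_fraction(seq) < 30.0:
                break
        else:
            raise RuntimeError("decoy rejection sampling exhausted")
        records.append(ProteinRecord(id=f"decoy{i + 1:03d}", seq=seq))
    order = rng.permutation(len(records))
    records = [records[int(k)] for k in order]
    return records, truths


@dataclass
class GenomeTruth:
    """Ground truth emitted alongside a toy genome."""

    rank_order: list[str]  # gene ids sorted by (natural chrom, start)
    exon_counts: dict[str, int]
    promoters: dict[str, str]  # promoter sequence per gene (window 2000)
    planted_hits: list[tuple[str, str, int]]  # (gene_id, motif name, offset)
    truncated: dict[str, bool]


def gen_genome_gff(
    n_genes: int,
    n_chroms: int = 2,
    seed: int = 0,
    window: int = 2000,
    plant_motif: tuple[str, str] = ("G-box", "CACGTG"),
    motif_genes: int = 3,
    copies_per_gene: int = 3,
    truncate_first: bool = False,
) -> tuple[dict[str, str], list[GeneModel], GenomeTruth]:
    """A toy genome + gene models with planted promoter motifs.

    Genes are spaced so every promoter window fits (except, optionally,
    the first gene, placed 100 bp into its contig to exercise clipping).
    ``motif_genes`` genes receive ``copies_per_gene`` planted copies of
    ``plant_motif`` in their promoter at recorded offsets; accidental
    background occurrences of the motif (either strand) are mutated away
    first, so the recorded hits are exhaustive.
    """
    rng = np.random.default_rng(seed)
    name, consensus = plant_motif
    genes: list[GeneModel] = []
    contigs: dict[str, list[str]] = {}
    # a minus-strand promoter extends `window` downstream of its gene end,
    # so 2*window+ spacing keeps every pair of promoter windows disjoint
    spacing = 2 * window + 500
    per_chrom = [n_genes // n_chroms + (1 if c < n_genes % n_chroms else 0)
                 for c in range(n_chroms)]
    gi = 0
    for c in range(n_chroms):
        chrom = f"Chr{c + 1}"
        pos = window + 200
        for k in range(per_chrom[c]):
            near_start = truncate_first and gi == 0
            if near_start:
                pos = 101
            length = int(rng.integers(300, 1501))
            start, end = pos, pos + length - 1
            # the clipping demo gene sits on + so its window hits the contig edge
            strand = "+" if near_start or rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 4))
            exons = _partition_exons(rng, start, end, n_ex)
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi + 1:03d}", chrom=chrom, strand=strand,
                    start=start, end=end, exons=exons,
                )
            )
            pos = end + spacing + int(rng.integers(0, 400))
            gi += 1
        total_len = (genes[-1].end if per_chrom[c] else 0) + spacing
        contigs[chrom] = list("".join(rng.choice(list("ACGT"), size=total_len)))

    # scrub accidental motif occurrences (both strands) near every promoter,
    # then plant recorded copies
    from .cisscan import compile_motif

    pat_f = compile_motif(consensus)
    pat_r = compile_motif(revcomp(consensus))
    for g in genes:
        lo, hi = _promoter_span(g, window, len(contigs[g.chrom]))
        _scrub(rng, contigs[g.chrom], lo, hi, (pat_f, pat_r))

    chosen = genes[: max(motif_genes, 0)]
    planted: list[tuple[str, str, int]] = []
    for g in chosen:
        lo, hi = _promoter_span(g, window, len(contigs[g.chrom]))
        plen = hi - lo + 1
        if plen < copies_per_gene * (len(consensus) + 2):
            continue
        slots = sorted(
            rng.choice(
                np.arange(1, plen - len(consensus) + 2, len(consensus) + 2),
                size=copies_per_gene,
                replace=False,
            ).tolist()
        )
        for off in slots:
            _write_promoter_motif(contigs[g.chrom], g, lo, hi, int(off), consensus)
            planted.append((g.gene_id, name, int(off)))

    genome = {c: "".join(s) for c, s in contigs.items()}
    rank = sorted(genes, key=lambda g: (_nat(g.chrom), g.start, g.gene_id))
    promoters = {}
    truncated = {}
    for g in genes:
        lo, hi = _promoter_span(g, window, len(genome[g.chrom]))
        raw = genome[g.chrom][lo - 1 : hi]
        promoters[g.gene_id] = raw if g.strand == "+" else revcomp(raw)
        truncated[g.gene_id] = (hi - lo + 1) < window
    truth = GenomeTruth(
        rank_order=[g.gene_id for g in rank],
        exon_counts={g.gene_id: len(g.exons) for g in genes},
        promoters=promoters,
        planted_hits=planted,
        truncated=truncated,
    )
    return genome, genes, truth


def _nat(chrom: str):
    from .genomics import natural_chrom_key

    return natural_chrom_key(chrom)


def _partition_exons(
    rng: np.random.Generator, start: int, end: int, n_ex: int
) -> list[tuple[int, int]]:
    length = end - start + 1
    if n_ex == 1 or length < 4 * n_ex:
        return [(start, end)]
    cuts = sorted(rng.choice(np.arange(1, length - 1), size=2 * (n_ex - 1),
                             replace=False).tolist())
    bounds = [0] + cuts + [length - 1]
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        exons.append((start + bounds[i] + (1 if i else 0), start + bounds[i + 1]))
    exons[0] = (start, exons[0][1])
    exons[-1] = (exons[-1][0], end)
    return exons


def _promoter_span(g: GeneModel, window: int, contig_len: int) -> tuple[int, int]:
    """1-based inclusive genome span of the promoter window."""
    if g.strand == "+":
        return max(1, g.start - window), g.start - 1
    return g.end + 1, min(contig_len, g.end + window)


def _scrub(rng, contig: list[str], lo: int, hi: int, patterns) -> None:
    """Mutate bases until the span contains no occurrence of any pattern."""
    for _ in range(_REJECTION_CAP):
        text = "".join(contig[lo - 1 : hi])
        hit = None
        for pat in patterns:
            m = pat.search(text)
            if m:
                hit = m
                break
        if hit is None:
            return
        pos = lo - 1 + hit.start() + int(rng.integers(0, hit.end() - hit.start()))
        old = contig[pos]
        contig[pos] = str(rng.choice([b for b in "ACGT" if b != old]))
    raise RuntimeError("motif scrubbing did not converge")


def _write_promoter_motif(
    contig: list[str], g: GeneModel, lo: int, hi: int, offset: int, consensus: str
) -> None:
    """Write a motif at a 1-based promoter offset (promoter-sense coordinates)."""
    if g.strand == "+":
        gpos = lo + offset - 1
        contig[gpos - 1 : gpos - 1 + len(consensus)] = list(consensus)
    else:
        # promoter sense is the revcomp of the genomic span
        gend = hi - offset + 1  # genomic position of the motif's first promoter base
        rc = revcomp(consensus)
        contig[gend - len(consensus) : gend] = list(rc)


def gen_additive_tree(
    n_taxa: int, seed: int = 0, min_branch: float = 0.1, max_branch: float = 1.0
) -> tuple[list[str], np.ndarray, set[frozenset]]:
    """A random unrooted binary tree with its additive distance matrix.

    Built by repeatedly subdividing a random edge and attaching a new
    leaf. Returns (leaf ids, leaf-to-leaf path-length matrix, the set of
    non-trivial leaf bipartitions). Neighbor joining is consistent, so
    it must recover exactly these bipartitions and path lengths.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    edges: dict[tuple[int, int], float] = {(0, 1): float(rng.uniform(min_branch, max_branch))}
    elist: list[tuple[int, int]] = [(0, 1)]
    leaves = [0, 1]
    next_id = 2
    for _ in range(n_taxa - 2):
        a, b = elist.pop(int(rng.integers(0, len(elist))))
        length = edges.pop((a, b))
        mid, new_leaf = next_id, next_id + 1
        next_id += 2
        f = float(rng.uniform(0.2, 0.8))
        edges[(a, mid)] = length * f
        edges[(mid, b)] = length * (1 - f)
        edges[(mid, new_leaf)] = float(rng.uniform(min_branch, max_branch))
        elist += [(a, mid), (mid, b), (mid, new_leaf)]
        leaves.append(new_leaf)

    adj: dict[int, list[tuple[int, float]]] = {}
    for (a, b), length in edges.items():
        adj.setdefault(a, []).append((b, length))
        adj.setdefault(b, []).append((a, length))

    def dist_from(src: int) -> dict[int, float]:
        d = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, length in adj[u]:
                if v not in d:
                    d[v] = d[u] + length
                    stack.append(v)
        return d

    ids = [f"t{l}" for l in leaves]
    D = np.zeros((n_taxa, n_taxa))
    for i, li in enumerate(leaves):
        dd = dist_from(li)
        for j, lj in enumerate(leaves):
            D[i, j] = dd[lj]
    D = 0.5 * (D + D.T)

    leafset = set(leaves)
    bps: set[frozenset] = set()
    for (a, b) in edges:
        seen = {a}
        stack = [a]
        while stack:
            u = stack.pop()
            for v, _ in adj[u]:
                if (u, v) != (a, b) and (v, u) != (a, b) and v not in seen:
                    seen.add(v)
                    stack.append(v)
        side = frozenset(f"t{x}" for x in seen & leafset)
        other = frozenset(f"t{x}" for x in leafset - {x for x in seen if x in leafset})
        if len(side) > 1 and len(other) > 1:
            bps.add(frozenset([side, other]))
    return ids, D, bps


def gen_tpm_matrix(
    k_clusters: int,
    genes_per_cluster: int,
    n_samples: int,
    sep: float = 8.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """A clustered TPM matrix with known gene-to-cluster truth.

    Cluster mean profiles live in log2(TPM+1) space, drawn uniform on
    [0, 8] per sample and redrawn until every pair is at least ``sep``
    apart in L2. Gene rows add Gaussian noise (sd ``noise_sd``) to their
    cluster mean; TPM = 2^v - 1 clipped at zero. Rows are shuffled; the
    returned truth maps gene id -> planted cluster (1-based).
    """
    if sep <= 0:
        raise ValueError("sep must be positive")
    rng = np.random.default_rng(seed)
    for _ in range(_REJECTION_CAP):
        means = rng.uniform(0.0, 8.0, size=(k_clusters, n_samples))
        if k_clusters == 1:
            break
        d = np.sqrt(((means[:, None, :] - means[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() >= sep:
            break
    else:
        raise RuntimeError("could not draw separated cluster means")
    n = k_clusters * genes_per_cluster
    labels = np.repeat(np.arange(k_clusters), genes_per_cluster)
    v = means[labels] + rng.normal(0.0, noise_sd, size=(n, n_samples))
    tpm = np.clip(2.0**v - 1.0, 0.0, None)
    order = rng.permutation(n)
    gene_ids = [f"g{i + 1:03d}" for i in range(n)]
    M = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[f"tissue{j + 1:02d}" for j in range(n_samples)],
        values=tpm[order],
    )
    truth = {gene_ids[i]: int(labels[order[i]]) + 1 for i in range(n)}
    return M, truth
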