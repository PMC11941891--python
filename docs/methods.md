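# Methods

This note records the models, conventions and numerical choices behind
`agpepscan`, and what the synthetic-data tests do and do not demonstrate.

## The identification screen

AG peptides are defined compositionally: length 50–75 aa (inclusive on
both ends) and PAST% ≥ 35 (inclusive), where PAST% is computed on the full
primary sequence — initiator Met and signal peptide included — because the
reported lengths of known family members are full precursor lengths. The
length window default follows the stricter of the two definitions in
circulation; `ScreenParams.relaxed_length()` gives the 50–90 preset found
in the broader AGP literature. Filtering compares the *unrounded* PAST
fraction; the two-decimal, half-up-rounded value is a display convention
of the report only.

Dipeptide repeats (AP, PA, SP, TP — Pro standing proxy for Hyp) are counted
over every adjacent residue pair, so occurrences overlap ("APA" = one AP +
one PA). No published counting rule exists for this family; overlapping
counting is the maximal deterministic choice and is what the brute-force
oracle in the tests enumerates.

Signal-peptide and GPI evidence comes from predictor output files. The GPI
anchor is **recorded, not required, by default**: published family tables
retain a large majority of members without a predicted anchor, while the
workflow prose asks for both signals. `require_gpi=True` serves readers of
the stricter definition. Multiple GPI predictors are combined by logical OR
by default (`--gpi-consensus=and` available); missing predictor calls are
treated as negative with a warning (`missing_policy="error"` for strict
runs). The minimum repeat total defaults to 1; every published family
member totals ≥ 2, so `ScreenParams.strict_repeats()` offers that preset.
With no domain annotations supplied, nothing is domain-excluded; with
annotations, any domain outside the allowlist excludes.

The bundled heuristic predictors are hydropathy rules (Kyte–Doolittle
table shipped as data): a signal peptide needs a K/R within the first five
residues and an ≥8-residue window of mean hydropathy > 1.6 within the
first 30; a GPI signal needs a C-terminal 15-mer of mean hydropathy > 1.0
and a small residue 18–28 positions from the C-terminus. They exist so the
pipeline runs with zero external binaries and are labelled
`source="heuristic"` everywhere; they are deliberately coarse and are not
a substitute for SignalP/big-PI when characterizing real proteomes.

## Physicochemical profiles

Molecular weight uses **average** isotopic residue masses plus one water
(18.0153 Da) — the convention behind the kDa figures usually quoted for
these proteins. Net charge is the Henderson–Hasselbalch sum over the
termini and K/R/H/D/E/C/Y side chains; pI is found by bisection on
[0, 14] (the charge is strictly decreasing in pH, so the root is unique)
to |charge| < 1e-4 or 100 halvings. Two pKa sets ship as data:
`expasy` (Bjellqvist convention, single N-terminal value; the default,
since the tools typically used for such tables track it) and `emboss`.
The choice is printed into the report header; extreme pI values can differ
by several tenths between sets, which is why both are provided rather than
one being forced. The instability index is the Guruprasad dipeptide-weight
sum, 10/L · Σ DIWV(i, i+1), with the published 20×20 table bundled as TSV.
Unknown residues (X) contribute zero to every computation.

## Genomics conventions

Coordinates are 1-based inclusive throughout (the GFF3 convention);
0-based arithmetic exists only inside sequence slicing. Family names are
assigned by sorting on (chromosome in natural order — Chr2 before
Chr10 — then start, then gene id on exact ties, with a warning). The
promoter is the `window` (default 2000) bases upstream of the start codon:
anchored at the CDS start when the annotation carries CDS features,
otherwise at the gene start; minus-strand promoters are the reverse
complement of the downstream window; windows are clipped at contig bounds
and flagged truncated. For multi-isoform loci the exon/CDS union over the
gene's transcripts defines the anchor, i.e. the outermost translated
coordinate.

## Cis-element census

Motifs are IUPAC-degenerate consensi compiled to exact-expansion matchers;
both strands are scanned (minus-strand hits reported at the 1-based plus
coordinate of the occupied segment) and overlapping occurrences all count,
since reference cis-element databases report all sites. The bundled table
is an editable, curated approximation of common PlantCARE-style elements
grouped into light / stress / growth / hormone categories; counts from it
are not comparable to any specific server version, and the census of a
real promoter set should be read as table-relative.

## Phylogeny

Distances are p-distances with pairwise gap deletion (Poisson correction
−ln(1−p) available). Neighbor joining follows Saitou–Nei with the
Studier–Keppler Q criterion; ties in Q are broken by the lowest index pair
in the current node list, so trees are deterministic. Negative branch
lengths are clamped to zero with the deficit transferred to the sister
edge, preserving the joined pair's distance; the root is trifurcating
(unrooted tree). Bootstrap resamples alignment columns with replacement,
rebuilds the tree per replicate, and reports for each internal edge the
percentage of replicates containing the same leaf bipartition; a fixed
seed gives bit-identical supports. Groups are obtained by deleting the
k−1 longest internal edges (traversal order breaks ties; leaf edges are
used only if internal edges run out, in which degenerate regime fewer
than k leaf groups can result). The alignment itself is an external
input — bundling an aligner would fake precision the method does not
have — and a no-gap equal-length "aligner" is provided for fixtures only.

## Expression clustering

TPM values are transformed log₂(TPM+1) — the +1 pseudocount makes zero
expression well-defined and is configurable — then row z-scored with the
population (n) standard deviation; zero-variance rows map to zeros.
Clustering is agglomerative with Euclidean distance and complete linkage,
ties broken by the lexicographically smallest cluster-index pair; heights
cannot invert under complete linkage and the merge history uses the SciPy
numbering convention. Distances are computed on the normalized matrix by
default (`on="raw"` available), matching the convention of row-normalized
expression heatmaps. The cluster count k is a user parameter; cluster
profiles are means of **raw** TPM, and abundance is strict TPM > 20.

## Synthetic data: what it shows and what it does not

Generators are pure functions of (parameters, seed), and truth tables are
recomputed from the emitted artifact, never from intent — a planted
peptide's repeat counts are re-counted from its final sequence, so
incidental extra repeats are recorded honestly.

Planted peptides are assembled from a fixed signal-peptide-like prefix
(`MK` + 10 hydrophobic residues), a PAST-rich core with embedded repeat
blocks, and optionally a fixed GPI-like tail; the composition filler is
solved so PAST% lands within ±2 points of target. Decoys are
uniform-composition proteins rejection-sampled to fail the default screen
outright (length outside 50–75 or PAST < 30%). The toy genome spaces genes
at least 2·window + 500 apart so promoter windows never overlap on any
strand combination; background occurrences of the planted motif are
mutated away before planting, making the recorded hit list exhaustive.
TPM matrices draw cluster means in log space, uniform [0, 8] per sample,
redrawn until all pairs are ≥ `sep` apart in L2 (defaults sep=8,
noise sd=0.5 in 18 samples — comfortably separated but noisy).

These fixtures validate the *machinery*: exact parsing and arithmetic,
algorithmic correctness (NJ consistency, linkage oracle equivalence),
determinism, and recovery under controlled noise. They do not emulate
real proteome composition biases, predictor error profiles, isoform
complexity, splice structure, or count-noise in expression data — so
passing tests demonstrate correct implementation, not expected recall on
a real genome, which depends chiefly on the external predictors.

## Problem sizes

Test and verification runs use desk-scale sizes chosen to exercise every
code path thoroughly: 1000 random sequences for the repeat-count oracle,
5 planted + 20 decoy proteins for screen recovery, 200 random additive
trees (4–8 taxa) for NJ consistency, 100 random matrices (n ≤ 12) for the
linkage oracle, a 40-gene × 18-sample TPM matrix for cluster recovery,
and a 10-gene toy genome for promoter/motif checks.
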