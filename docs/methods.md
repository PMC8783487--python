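# Methods

This note documents the models, conventions and numerical choices behind
`taxg`, in the order the pipeline runs.

## Assemblies, annotations, translation

Coordinates are 1-based inclusive everywhere (GFF3 convention); conversion
to half-open slices happens only inside alignment kernels. Sequences are
uppercased on read and validated against the IUPAC nucleotide alphabet;
ambiguity codes other than N are accepted but treated as N wherever
identity or G+C is counted, because draft assemblies routinely carry rare
ambiguity codes. Digital G+C is `100·(G+C)/(A+C+G+T)` — ambiguous bases
are excluded from the denominator, a convention this package fixes because
genome tables rarely state it — and is reported to one decimal to match
the precision such tables print. Minus-strand CDS features are stored
reverse-complemented so translation (NCBI table 11) always reads 5′→3′;
the terminal stop is stripped and an internal stop raises by default
(`internal_stop="X"` maps it to X instead, which the pan-genome pipeline
uses for real draft annotations with frameshifted gene calls).

## Homology kernel

`find_hsps` is a seed-and-extend local aligner built for determinism and
zero external binaries:

- exact k-mer seeds (k = 13) on both strands, hashed over the whole
  subject (contigs concatenated with N spacers that can never seed);
- seeds are clustered into loci (same contig, diagonals within 16,
  query gaps ≤ 120 bp). A single-diagonal locus is extended by the
  *maximal-scoring* ungapped extension (match +2 / mismatch −3), computed
  vectorised as the argmax of the cumulative score in each direction —
  equivalent to an X-drop with unbounded drop, so extension is never
  truncated by an unlucky mismatch run;
- a multi-diagonal locus (indels) gets ungapped flank extension on its
  terminal diagonals and an edlib (unit-cost) re-alignment of the spanned
  region; terminal gap operations are trimmed, internal gap columns count
  toward the alignment length;
- HSPs below the caller's identity/length floors are dropped, overlapping
  HSPs keep the higher-identity one, and all orderings/tie-breaks are
  lexicographic on (subject id, subject start), so output is byte-stable.

Maximal-scoring trimming removes net-negative terminal segments, which
inflates fragment identity by roughly `2p/1020` at substitution rate *p*
(≈ 0.01 percentage points at p = 0.05) — negligible against the 0.5-point
accuracy the estimator is tested to.

## OrthoANI

Fragments are consecutive non-overlapping 1,020-bp windows; trailing
remainders are discarded, as are fragments with > 20% N. A fragment pair
is reciprocal when each is the other's best hit with identity ≥ 0.35 and
aligned coverage ≥ 0.70 of the fragment length; ANI is 100 × the mean
identity over reciprocal pairs, averaging both search directions. All
constants live in `AniConfig`. Zero reciprocal pairs yields an explicit
`undefined` result, never 0. Self-comparison is exact (100.0) because
every fragment's best hit is itself with a full-length perfect extension.

## Digital DDH

Formula-2 distance: both genomes are windowed (1,020 bp), each window's
best HSP against the other assembly (min length 100, min identity 0.30)
contributes identities and columns to `d2 = 1 − Σid/Σlen`. This is the
draft-genome-appropriate distance: it measures identity *within* aligned
regions only, so it saturates near 0.25–0.3 for unalignable genomes rather
than 1.0; no HSPs at all is flagged "no homology" with d2 = 1 by
convention.

The d2 → DDH% map is a pluggable monotone logistic in log distance,
`100/(1 + exp(a + b·ln d2))`, pinned to 100% at d2 = 0. The default
coefficients (a = 3.2663, b = 1.1258) are this package's own calibration
to two anchors of the established genome-to-genome distance scale: the
70% species boundary at d2 = 0.0259, and DDH in the mid-20s for genome
pairs near 80% ANI, the regime of the *Nocardia* study group. Users with
the original GLM coefficients can supply them via `DdhConfig`; only
monotonicity is validated. Species-boundary classification is ANI ≥ 95%
or dDDH ≥ 70% ⇒ same species (both cutoffs in `SpeciesThresholds`).

## Marker similarity

Semi-global alignment (terminal gaps free; match +1 / mismatch −1 /
gap −2). Gap runs touching either end are terminal columns and excluded
from the compared length; internal gap columns stay in the compared
length but count toward neither matches nor differences, so
`similarity = 100·matches/aligned_len` and differences are substitution
columns only. This matches the common identification-server convention;
the calibration check is a 1,523-bp pair with 20 planted substitutions
reporting exactly 20 differences and 98.69%. Neither a full-length nor a
trimmed-overlap denominator is hard-coded: the denominator is whatever
the alignment's non-terminal region is. Sequences under 100 bp and
sequences over 5% ambiguous bases compute with a warning.

## Neighbor joining

Classical NJ with two documented conventions: Q-criterion ties break on
the smallest row-major index, and a negative branch estimate is clamped
to zero with the deficit moved to the sibling branch so the joined pair's
total distance is preserved. The final three nodes are connected through
an unrooted central vertex. On additive matrices the patristic distances
reproduce the input to machine precision; topology recovery is exercised
on 100 random additive matrices per run. Maximum-likelihood inference and
bootstrap support are deliberately out of scope — the distance pipeline
does not retain characters to resample.

## Pan-genome (POGs)

All-vs-all protein search per ordered genome pair: a shared amino-acid
5-mer prefilter (≥ 1 shared 5-mer; two unrelated 200-residue proteins
share one by chance with probability ≈ 0.01) followed by global BLOSUM62
alignment (gap open −11 / extend −1). Identity is matched columns over
all alignment columns; hits below identity 0.30 or query coverage 0.50
are dropped — thresholds the source studies leave unstated, fixed here in
`SearchConfig`. Reciprocal best pairs require bidirectional top hits,
with ties broken by identity then lexicographic gene id. POGs are
connected components of the reciprocal-pair graph (single-linkage; a
`pair-only` mode keeps raw pairs, since the merge rule is a genuine
design freedom). Partial genes are attached greedily, longest first, to
the longest-member centroid of each POG when identity over the *shorter*
sequence reaches 0.95 (inclusive), the documented UCLUST convention.

Core POGs span all genomes (and at least two); strain-specific genes
belong to no POG spanning ≥ 2 genomes; the rest is accessory. Category
profiling counts COG one-letter classes for core members versus all
genes, with unmapped genes under `unassigned` — the published contrast
(≈ 75% of core genes categorised versus < 40% of the pan genome) is a
shape this reproduces on real annotations, not a number the simulator can
generate. The pairwise ortholog matrix counts shared POGs off-diagonal
and POG-member genes on the diagonal.

## Feature table, regression, trait screen

Median CDS length uses the lower median for even counts (the convention
is documented because published tables do not state theirs). The CDS ~
genome-size regression is ordinary least squares; R² = 1 − SSres/SStot,
with constant-response inputs returning 0 by convention and a constant
predictor an error. On the published six-genome table this yields
R² = 0.94 (slope ≈ 910 CDS/Mbp, intercept ≈ 62); only R² is asserted
anywhere, since the printed regression-line coefficients are ambiguous
and not reconstructible from rounded table values.

The trait screen is evidence-logged string matching: a trait is present
iff some gene matches a catalog symbol exactly (lowercased, hyphens
stripped, against the annotation's gene symbol or id) or a
product-description regex. The shipped catalog covers the
plant-growth-promotion inventory of the study group — phosphate genes
(ppx-gppA, pstS, senX3), the tryptophan/auxin pathway (trpA/B/D/E/F,
pdxI, aad), ACC deaminase (acc), antibiotic biosynthesis (fabG, bacC2,
hdhA, auaJ, tcmO) and lytic enzymes (chitinase, glucoamylase). No
profile/HMM homology is attempted; false positives are auditable through
the evidence table.

## Synthetic data: what it does and does not show

Generators draw from one explicitly seeded numpy Generator per call and
are byte-reproducible. Substitution-only evolution is the default because
it gives closed-form expectations (expected identity 1 − p, length
preserved); indel mode exists to exercise gap handling only. Simulated
CDSs are stop-free by construction: mutated codons that would become
internal stops are re-drawn, a repair whose bias on the realised
substitution rate is far below the tolerances tested. Pan-genome
simulations place family copies (independently mutated from a common
ancestor at rate p, i.e. ≈ 2p pairwise nucleotide divergence) and unique
private genes on random strands between random spacers.

Passing recovery tests on these inputs demonstrates the estimators'
correctness under i.i.d. substitution divergence — it does not
demonstrate robustness to repeats, horizontal transfer, contamination or
assembly artefacts, which real *Nocardia* drafts contain. The published
ANI/dDDH values for the real study genomes are therefore checked by a
separate integration test that runs only when those multi-Mbp assemblies
are provided locally.

## Problem sizes and tolerances

Default verification sizes — 100–500-kb genomes for self-comparison,
200-kb pairs for ANI recovery (binomial SE of mean identity ≈ 0.05
points, against a 0.5-point assertion), 4 genomes × 50 families for POG
recovery, 100 NJ trials up to 12 taxa — are chosen so the full suite runs
in a few minutes on one CPU while keeping every statistical assertion
several standard errors wide. Matrix symmetry tolerance is 1e−9; NJ
branch lengths are written to 6 decimals; exact assertions (self-ANI
100.0, self-d2 0.0, planted marker differences) are genuinely exact, not
toleranced.
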