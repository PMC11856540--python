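# Methods

This note documents the models, conventions and numerical choices behind
`numtkit`, what the synthetic-data generator does and does not emulate, and
the known limitations of each stage.

## Gene extraction and the mitochondrial code

All codon logic runs under NCBI translation table 5 (invertebrate
mitochondrial): AGA/AGG encode serine, ATA encodes methionine, and the only
complete stop codons are TAA and TAG. The accepted initiation set defaults
to {ATG, ATA, ATT, ATC, TTG, GTG}; rarer real starts (e.g. ACC, observed
for COX1 in some beetles) are *flagged* (`start_ok = False`,
`nonstandard_start` recorded) rather than rejected, because rejecting them
would silently drop genuine genes. Truncated stop codons — a terminal T or
TA completed to TAA by polyadenylation — are accepted only at the annotated
gene terminus; anywhere else a partial codon is treated as an annotation or
alignment artifact. Coordinates are 0-based half-open internally; GFF3 and
GenBank I/O converts from/to 1-based inclusive at the boundary. Gene names
are normalized through a synonym table (COI→COX1, COB→CYTB, NAD4L→ND4L, …)
because annotation pipelines disagree on naming. Bases outside {A, C, G, T,
N} are rejected at parse time: downstream codon counting assumes this
alphabet. Where two annotation sources disagree, both can be parsed and
compared side by side; the package deliberately does not auto-arbitrate
conflicting annotations, since no defensible algorithmic rule exists —
resolution is left to the analyst.

## Homology search and candidate filtering

The primary route for real data is a BLASTN `outfmt 6` table (query = PCG,
subject = nuclear sequence, optional 13th `sseq` column). The built-in
searcher exists so that simulated genomes need no external aligner: exact
11-mers (2-bit rolling hash) seed diagonals; each diagonal's best ungapped
segment score (Kadane max-subarray over +2/−3 match/mismatch) must reach
80% of the score implied by the E-value threshold before the surrounding
window is refined with an affine-gap Smith–Waterman (match +2, mismatch −3,
gap open −5, extend −2, via Biopython's `PairwiseAligner`). E-values use
ungapped Karlin–Altschul statistics with λ = 0.625, K = 0.41 (the standard
constants for +2/−3 scoring); they approximate, but do not exactly
reproduce, BLASTN's gapped statistics. N bases never count as matches. The
80% pre-filter level keeps random seed extensions (which cannot climb far
under the negative expected score) out of the quadratic alignment step
while leaving headroom for hits split across nearby diagonals by indels.

Filtering follows the screening protocol: hits with E > 10⁻⁴ and hits on
sequences not annotated as assembled chromosomes are dropped (and counted);
candidates shorter than 70% of the longest cohort copy of their source gene
are removed; exact duplicates are collapsed per species and source gene.
The duplicate key is the hit sequence normalized to gene sense, so
byte-identical insertions collapse regardless of which chromosome strand
they landed on; the representative is the lexicographically smallest
(chrom, start) locus and family sizes are retained for distribution
statistics. Overlapping or adjacent hits from the same gene are *not*
merged — counting is per (gene, hit) — and hits from different source genes
overlapping on the nuclear axis are kept separately under each gene. The
70% threshold is interpreted on nucleotide length of the longest per-gene
PCG.

## ORF classification (C1–C5)

Each candidate is globally aligned to its source PCG (EMBOSS-needle-like
scoring: match +5, mismatch −4, gap open −10, extend −0.5; the first
optimal alignment under Biopython's canonical traceback order makes results
deterministic). From the alignment:

* `delta_aa` — realized codon count of the NUMT minus that of the PCG,
  under the frame inherited from the PCG row (floor of nucleotide length
  over 3). Measured on the raw NUMT codon count, not after indel
  projection.
* `frameshift_present` — any gap run with length ≢ 0 (mod 3).
* `internal_stops` — stops in the NUMT translated in the inherited frame,
  excluding a terminal stop.
* start/stop presence — membership of the NUMT's own termini in the
  configurable start/stop sets (including truncated T/TA), *not* equality
  with the parent's specific codons.
* `percent_identity` — matches over all aligned columns, gap columns
  counting as mismatches (close to, but not identical with, BLAST
  `pident`).

The decision tree is applied in a fixed precedence order: internal stops →
C3; |Δaa| > 2 → C2; Δaa = 0 with both termini intact → C1; 1 ≤ |Δaa| ≤ 2
with both termini intact → C4; otherwise C5. Internal stops dominate
because an in-frame stop is the least ambiguous decay signature; a
same-length NUMT with a premature stop is C3, not C1. Frameshifted NUMTs
without internal stops fall through to the length rules and keep
`frameshift = True` for transparency. A NUMT with Δaa = 0 but a missing
start or stop lands in C5 (reading C5's "typically 1–2 amino acids" as
inclusive of 0). Filtering efficiency is reported per gene as
removed/total, with mean ± SD across genes, and the count of species left
with zero C1 NUMTs; genes with no C1 NUMTs report the ≥97%-identity
proportion as undefined rather than zero.

## Distribution statistics

The Wilcoxon signed-rank test drops zero differences, uses the exact null
distribution up to an effective n of 25 and the normal approximation with
continuity correction beyond; all p-values are two-sided, and families of
tests are adjusted with Benjamini–Hochberg (via
`statsmodels.stats.multitest`). The X-vs-autosome comparison pairs on the
13 source genes — for each gene, the density (count per Mb) on X against
the mean density across autosomes — with BH across species. Densities are
the default pairing unit because chromosome lengths differ systematically
(the X is often shorter than the large autosomes, so raw counts build in a
bias); a raw-count mode is available. Species without an annotated X, or
with fewer than 3 autosomes, are reported but excluded from testing. The
ATP8-vs-others comparison pairs across species, 12 comparisons, BH over 12.
Correlation defaults to Pearson with pairwise-complete handling of missing
values; Spearman is available.

Calibration note: a "global null" for the X-vs-autosome test means uniform
per-bp insertion intensity — expected counts proportional to chromosome
length — not identical count distributions on chromosomes of different
lengths (the latter builds a density difference into the simulation and is
not a null for the density pairing). Under the proper null the BH-adjusted
test flags well under 5% of species.

## Codon-position substitution analysis

`build_virtual_cds` reduces a pairwise alignment to a gapless in-frame pair
on the PCG codon grid. The removal granularity is whole PCG codons: any
codon with a gap in either row in any of its three columns is removed;
insertion columns (gaps in the PCG row) are always removed, and a
frame-shifting insertion run additionally removes the codon whose interior
it interrupts. This excises in-frame indels as complete codons, restores
the frame around frame-shifting indels (a 1-nt gap costs its host codon,
i.e. 3 positions), and guarantees the output length is a multiple of 3 with
no gap columns.

`count_codon_mutations` counts mismatching columns per codon position
(columns containing N excluded) and tests uniformity with Pearson's χ²
against expected N/3 per position, df = 2, using the asymptotic
distribution even at small totals — matching the method as practiced.
Profiles with fewer than `min_total = 10` mutations are flagged
`low_power`; the decision is still made, but the flag propagates into
reports because the test demonstrably over-splits events at small counts
(the worked (1, 2, 7) example itself: p ≈ 0.045 calls independence even
though two sequences >99% identical plausibly share one event).

`decide_same_event` declares a pair independent only when p < α (default
0.05) **and** n₃ exceeds both n₁ and n₂ — the directional check — and
treats identical pairs (zero mutations) as same-event.
`estimate_integration_events` aligns each NUMT to the contemporary PCG
once, projects every NUMT onto the PCG codon grid, forms pairwise virtual
CDSs on the shared intact codons, and clusters with single-linkage
connected components over the same-event relation. Single linkage is the
conservative choice — any evidence linking two NUMTs merges their events —
which counteracts the known overestimation bias of the pairwise rule.
NUMTs whose profile against the contemporary PCG shows no independence
signal are annotated "contemporary-lineage origin".

## dN/dS diagnostic and CODEML export

`ng86_dnds` implements Nei–Gojobori (1986) counting: per-codon fractional
synonymous sites (averaged over the two sequences), pathway averaging over
all stop-avoiding mutational orders for multi-hit codons, Jukes–Cantor
correction of both proportions. Mutations *to* stop codons count as
non-synonymous; codons containing a stop or an N in either sequence are
masked out of both site and difference counting; if every pathway for a
codon passes through a stop, its differences count as non-synonymous. ω is
undefined (None) when dS = 0. Under uniform-rate (selectively neutral)
simulation the ω distribution centers near 1; under synonymous-only change
ω = 0 exactly. Branch-model likelihood fitting is out of scope: the package
exports sequential PHYLIP (in-frame stops replaced by `---`), a Newick tree
with `#k` branch labels (class 0 = unlabeled background, per the CODEML
convention) and a control-file template (`icode = 4`, `model = 2` when
labeled classes exist), to be run in PAML externally.

## The synthetic-data generator

`simulate_mitogenome` builds 13 valid PCGs (start codon, stop-free body,
TAA/TAG terminus; TAA twice as frequent) at codon counts matching typical
chrysomelid beetle gene lengths (COX3 263 codons = 789 bp, ATP8 52 = 156
bp, ND5 572 = 1716 bp, …), placing ND1/ND4/ND4L/ND5 on the minus strand as
in the usual insect arrangement, with 30-nt random spacers. Nuclear
background is i.i.d. multinomial at 35% GC — beetle-like AT richness — with
no repeat structure. Each integration event draws a founder from the
contemporary PCG or from a diverged mitochondrial lineage: per-position
substitution rates (r, r, m·r) with r = 3d/(2+m) give mean divergence d
with third-position multiplier m, under a Kimura two-parameter scheme
(transition probability κ/(κ+2), default κ = 2). Family copies are nuclear
duplicates of the founder, optionally with additional uniform-rate
within-family divergence and geometric-length indels (p = 0.5, frame
preserving unless the target class requires otherwise).
`degrade_to_class` engineers each class by inverting the classifier: C1 via
synonymous substitutions only, C2 via an in-frame deletion of ≥3 codons, C3
via one engineered in-frame stop, C4 via a 1–2-codon in-frame indel away
from the termini, C5 via start-codon ablation. Substitutions that would
create unintended stops are resampled with bounded retries. Implants are
placed uniformly without overlap on randomly chosen strands; all randomness
flows through one numpy generator seeded from the config, so identical
configs yield byte-identical FASTA/TSV outputs.

What the generator does *not* emulate: repeats and segmental duplications
(the main source of spurious nuclear self-similarity), pericentromeric
clustering, GC gradients around insertion sites, chimeric NUMTs spanning
gene boundaries, tRNA/rRNA-derived NUMTs, and assembly artifacts. Passing
tests therefore demonstrate correctness of the pipeline's logic on clean
signals, not robustness to repeat-rich real assemblies — for real data the
BLASTN route with the assembly's own repeat annotation remains advisable.

## Problem sizes and reproducibility checks

The test suite and `scripts/acceptance.py` exercise: the (1, 2, 7) worked
example; engineered-class recovery at 5 classes × 100 seeds (expected
100%); event recovery at E ∈ {1, 2, 3} lineages (divergence ≥ 0.10,
third-position multiplier ≥ 5, families as identical duplicates, 100
replicates per E, ≥95% expected — with within-family noise at 0.5% per
copy, checked separately at 20 replicates, occasional false splits reflect
the method's small-count overestimation); Wilcoxon exact p against full
sign-assignment enumeration for all n ≤ 10; BH against the hand-computed
step-up rule; the df = 2 χ² p-value against its closed-form survival
function exp(−χ²/2); NG86 against a brute-force pathway-enumeration oracle
to 1e-9; χ² null calibration at 500 uniform-rate replicates on a 572-codon
gene; X-vs-autosome null calibration over 1007 species-tests; and double
runs of the full pipeline compared byte for byte. A six-species synthetic
cohort (five events per species, ~150 kb per chromosome) stands in for a
full genome cohort; these sizes were chosen so the whole battery completes
in a few minutes on one core while keeping every statistical check at the
replicate counts stated above.

## Known limitations

* Event clustering is single-linkage over pairwise decisions; the pairwise
  rule's power depends on mutation counts, so very recent events merge with
  the contemporary lineage and sparse pairs over-split (flagged, not
  corrected).
* The built-in searcher is for clean or simulated data; it has no repeat
  masking, no gapped E-value statistics and no protein-level search.
* `percent_identity` conventions differ between the discovery (local
  alignment) and classification (global alignment, gaps as mismatches)
  stages; both values are stored where relevant.
* CODEML itself is not run; exported inputs follow its conventions but
  likelihoods are not computed in-package.
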