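# Methods

This note documents the models and procedures implemented in `splicescreen`,
the defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that affect results.

## Motif scanning

A position weight matrix (PWM) over ACGT assigns a window of its width the
sum of its per-position, per-base scores. A window is a hit when its score
reaches the matrix's cutoff. Published SR-protein matrices usually come with
a percentage threshold but without a stated baseline, so two threshold modes
exist:

- **fraction of range** (default): `cutoff = min_score + f · (max_score −
  min_score)` with `f = 0.9` by default, i.e. "90%" is interpreted relative
  to the matrix's own score range;
- **absolute**: a user-supplied per-matrix cutoff, for users holding
  published thresholds.

Raising the fraction can only shrink the hit set (monotonicity, property
tested). Enhancer hexamer sets are scanned for presence/absence with all
overlapping occurrences reported; silencer sets carry per-hexamer scores,
`log2(f_pseudoexon / f_exon)`, positive when a hexamer is enriched in
pseudoexons. Scanning is strand-specific (sense strand only) because
pre-mRNA splicing signals are; no reverse-complement symmetry is assumed.
The strict per-window scorer rejects non-ACGT characters, while the scanner
skips ambiguous windows silently — strict where the caller chose the window,
tolerant where the tool slides over real sequence. Coordinates are 0-based
half-open internally and in BED output, 1-based inclusive in report TSVs.

## Maximum-entropy splice-site model

Donor sites are modelled on a 9-mer window (last 3 exonic + first 6 intronic
nt), acceptors on a 23-mer (last 20 intronic + first 3 exonic nt), the
standard geometries for maximum-entropy splice models; both are configurable
through `SiteWindowSpec`.

Given training windows and a *constraint set* — a list of position subsets —
the signal model is the maximum-entropy distribution over all 4^width
windows whose marginals on each subset equal the empirical marginals.
Fitting is iterative proportional fitting (IPF), cycling marginal updates
until the largest marginal discrepancy falls below `tol` (default 1e-6) or
`max_iter` (500) is reached; non-convergence is reported in `fit_meta` with
a warning, never an exception. Three exact engines cover the practical
cases:

- **table** — the full 4^width joint for width ≤ 10; supports arbitrary
  subsets.
- **chain** — when the constraints are the adjacent pairs (i, i+1), the
  model factorises over the chain and all marginals, the normaliser and
  window probabilities are computed exactly by scaled forward–backward
  (transfer-matrix) recursions, so the acceptor's width-23 model never
  materialises 4^23 states. IPF on a chain converges in one ordered sweep.
  This is the default constraint set.
- **product** — singleton-only constraints at widths beyond the table limit
  collapse to the closed-form per-position product.

A pseudocount (default 0.5 per cell) is added to each *maximal* constraint
subset's empirical table; nested subsets take their targets by marginalising
the superset's pseudocounted table. Deriving nested targets rather than
pseudocounting them separately keeps redundant constraints mutually
consistent, so IPF has an exact fixed point (separately pseudocounted
singleton and pair tables imply slightly different singleton marginals and
IPF would oscillate at the inconsistency's amplitude). The pseudocount also
guarantees every window has positive probability, so log-odds scores are
always finite.

A window's strength is `log2 P_signal(w) / P_background(w)` in bits. The
background defaults to uniform — it keeps the tool self-contained and makes
scores read as "bits of departure from random sequence" — and can instead be
trained from user decoy windows with the same machinery. With singleton
constraints the score equals the classical weight-matrix log-odds exactly
(tested). Strength labels are explicit: weak below one cutoff, strong at or
above another, intermediate between; the defaults (3 and 6 bits) are
package conventions, and screening runs require them as explicit parameters
so no hidden thresholds enter a published analysis.

## Codon-aware paralog alignment

Exon coding regions are compared at the protein level: translate (standard
code, stops as `*`, ambiguous codons as `X`; `phase` leading nucleotides and
any trailing partial codon excluded), globally align the peptides with
affine gaps (BLOSUM62, open −10, extend −0.5, terminal gaps penalised), then
thread each member's codons back through its gapped peptide row. Protein
alignment is the right level because paralog families are conserved at the
domain level while nucleotide rows carry synonymous noise. The pairwise
aligner is Biopython's `PairwiseAligner`; its first-optimal alignment is
deterministic, which is what downstream reproducibility needs (score
equality against an independent Gotoh dynamic program is property-tested).
Families with more than two members are aligned progressively against the
first member as anchor, expanding columns for insertions — adequate for the
≥ 90%-identical families the screen targets, and documented as not a general
multiple aligner.

`diff_columns` classifies each differing column as synonymous (codons
differ, amino acids agree), nonsynonymous, or gap. Every produced alignment
satisfies the round-trip invariant: the degapped nucleotide row re-translates
to the degapped protein row.

## The candidate screen

For each ordered orientation of a pair and each site type screened (acceptor
and donor by default; the motivating biology is the acceptor), a candidate
requires all of:

1. the weak member's site labelled *weak* and the strong member's *strong*
   under the explicit cutoffs, with contrast ≥ `min_delta` bits
   (`min_delta` has no default — it is a required parameter);
2. at least one ESE hit in the weak member whose projected alignment columns
   carry no hit *from the same motif set* in the strong member (set-level,
   not identical-hexamer, judgement: a different member of the same enhancer
   set at the same columns still counts as "element present");
3. a non-synonymous difference within `adjacency_window` codons (default 1)
   of such a hit — one codon of slack because a residue immediately adjacent
   to a predicted enhancer can be functionally part of the element.

Silencer hits overlapping the enhancer span are attached to the report as
context only. Hit projection maps exon nucleotide positions through the
codon alignment to nucleotide-column intervals, retaining gap columns that
fall inside. Family-level screening unions all pairs and deduplicates by
(weak member, strong member, site, hit spans); output order is
deterministic. Structural filters (e.g. proximity to a catalytic site) are
deliberately out of scope — users can restrict the screened region
upstream.

## Ancestral-alignment scanning

Ancestral sequence reconstruction is an external step; the scanner consumes
any aligned FASTA whose records include internal-node labels plus a matching
newick tree. Trimming takes the reference exon ± flank (default 30 nt) in
ungapped reference coordinates and maps it through the reference row's gaps;
a flank running off the reference truncates with a `short_flank` flag, and
trimming is idempotent. Exon boundaries in non-reference rows are projected
through alignment columns from the reference; a node with a gap (or an
ambiguous base) inside a site window gets a flag and a missing score rather
than a guessed boundary. A one-row alignment reproduces exactly what the
motif scanner and splice-site scorer return on the raw sequence (consistency
tested). Tree annotation writes per-node scores as newick comment fields
plus a companion TSV; unmatched labels warn and are left unannotated.

## Michaelis–Menten kinetics

`fit_mm` minimises Σ(v − Vmax·S/(Km+S))² with `scipy.optimize.curve_fit`
under positivity bounds, with tight solver tolerances (1e-14) so noiseless
data is recovered to well beyond print precision. Initialisation is
`Vmax₀ = max(v)`, `Km₀ =` the S whose velocity is nearest Vmax₀/2, with two
seeded jittered restarts on failure; standard errors come from the Jacobian
covariance. kcat is either supplied (kinetics tables usually print it) or
derived as Vmax/[E] when the enzyme molar concentration is known — no hidden
mass-to-molar conversion is attempted. Catalytic efficiency is
kcat/(Km·1000) in s⁻¹·µM⁻¹ (Km held in mM). Enzymes with activity below the
assay background are represented by an explicit `below_detection` flag,
never as zero parameters. Replicate fits are compared with an
equal-variance two-sample Student's *t*-test (type-I error checked against
nominal by simulation). Velocity tables accept both decimal commas and dots
on input and always write dots.

## Synthetic data: what it emulates and what it does not

`gen_splice_training` samples i.i.d. windows from a stated product or
first-order chain distribution. The built-in acceptor/donor generating
distributions encode the canonical biology (polypyrimidine tract + near
invariant AG; exonic MAG + GTAAGT-like intron start) at "strong" sites and a
degraded-but-plausible version at "weak" ones.

`gen_family` builds a paralog exon family: a shared ancestral coding
sequence; synonymous-first background divergence towards the identity
target (so spontaneous non-synonymous noise does not contaminate the
screen's signal); planted hexamers written in-frame at stated codons; those
loci ablated in the other members with deliberately non-synonymous codon
choices that also remove the motif from the local neighbourhood (the
ablation mode is recorded in the returned truth ledger — a synonymous
ablation would leave no amino-acid contrast and hence, by the screen's own
criteria, nothing to find); acceptor windows rejection-sampled until the
supplied model actually labels them as requested, so weak/strong is defined
in-model rather than by magic strings; and a single donor flank shared by
all members (with first/last codons frozen) so the donor side can never
produce a spurious contrast. Every generator is a pure function of its
spec + seed.

What the generators do **not** emulate: indels and rate heterogeneity along
a phylogeny, codon-usage bias, GC isochores, realistic intron composition,
overlapping enhancer landscapes, or measurement structure in kinetics beyond
multiplicative Gaussian noise. Passing tests on generated data therefore
demonstrate correctness of the screen's logic and calibration of its
statistics under the stated generative assumptions — not performance on real
genomes, where motif predictions carry well-known false-positive rates.

## Problem sizes and determinism

Test and acceptance runs use deliberately modest sizes chosen to exercise
every code path: maximum-entropy corpora of 300–5000 windows, reference
models trained on 1500 windows, 50 planted + 50 null families of 40-codon
exons, 100-case alignment-oracle batches, 12-point kinetics grids with 6
replicates, and 1000-repetition t-test calibration. All randomness flows
through `numpy.random.default_rng` seeds fixed in the tests or supplied via
`--seed`; identical inputs give byte-identical outputs.

## Known limitations

- The progressive multiple alignment assumes high family identity; distant
  paralogs should be aligned externally and screened pairwise.
- The chain maximum-entropy engine covers singleton/adjacent-pair
  constraints; richer dependence structures (non-adjacent pairs at acceptor
  width) would require a junction-tree extension.
- Packaged motif files are synthetic stand-ins shaped like the published
  SR-protein matrices and enhancer/silencer hexamer sets; real analyses
  should load the published files in the same formats.
- The screen's verdict is purely sequence-computational: splice-site
  strength contrast, enhancer presence/absence, and coincident coding
  differences. Enzymatic-property differences between family members are an
  experimental criterion outside its scope.
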