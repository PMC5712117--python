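# Methods

This note documents the models and procedures the toolkit implements,
the parameters that matter, the synthetic data it is validated on, and
the design choices made where the design was genuinely open. No number
stated here is asserted anywhere except where the tests or
`scripts/acceptance.py` compute it at run time.

## Iterative reciprocal best hits

Given directional alignment tables A→B and B→A, hits are first
restricted to E ≤ `evalue_max` (default 1e-05) and reduced to at most
one row per (query, subject), ranked by bit score (desc), E-value
(asc), percent identity (desc) and finally subject id. The first three
keys are the fields practitioners rank BLAST hits by; the lexicographic
subject id is our own final arbiter, added solely so that runs are
deterministic and invariant to input row order (a property test pins
this). Each round fixes the classical RBHs of the surviving tables,
then removes every anchored gene from *all* remaining rows of both
tables — as query or subject — before re-ranking at the start of the
next round. Iteration stops at convergence or after `max_iterations`
(default 25, configurable). The invariant that rounds-after-removal
equal classical RBH is exactly what the acceptance oracle checks on
random bipartite tables.

Removal timing was an open choice: anchored ids could be purged within
the same round before re-ranking, or between rounds. We remove between
rounds (rank → match → remove), which matches the natural reading of
the three-step cycle; the oracle is defined accordingly.

An `AnchorPair` stores the *worse* of the two directional E-values and
the worse bit score — the conservative summary, since the direction of
published per-anchor statistics is ambiguous. Concordance is
`involves_chrUkn` whenever either side sits on the unplaced-scaffold
bin, because "different chromosome" is not a meaningful call against a
bin of unplaced sequence. The quality ratio is bit score divided by the
legacy (B-side) model length in nt; class means are reported for the
two placed classes only. The rescue pass is a single, non-iterative
RBH restricted to the unanchored legacy ids (optionally also to the
unsupported new-annotation ids) at the same E threshold.

## lncRNA pipeline

Stage order: clustering → expression → protein-homology binning (each
per accession) → cross-accession consensus → Rfam purge → minimum
length → ORF flag. Defaults: cluster identity 0.90, FPKM ≥ 1.50
(inclusive), protein E ≤ 1e-20 (inclusive; only the no-hit bin
continues), consensus alignment ≥ 200 nt, Rfam E ≤ 0.01 (inclusive),
minimum length 200 nt, ORF flag at 100 codons.

Decisions worth recording:

* **Disposal of homology bins.** Both the plant and non-plant bins are
  removed; only transcripts without a qualifying protein hit continue.
  The monotonically shrinking stage counts of the published pipeline
  imply this, though it is not stated explicitly for the non-plant bin.
* **Clustering stand-in.** The greedy scheme visits sequences
  longest-first; a sequence joins the first cluster whose *founder* it
  matches at ≥ identity over the shorter sequence, else founds a
  cluster. Identity is 1 − (infix edit distance)/len(shorter), computed
  exactly by dynamic programming (edlib), so a truncated fragment
  scores ~1 against its source while unrelated random sequences score
  ≈ 0.5–0.6 — safely below the 0.90 threshold. This reproduces
  cd-hit-est's behaviour at desk scale; exact CD-HIT parity is a
  non-goal, and an externally produced `.clstr` file can be supplied
  instead.
* **Consensus direction.** Accession A is the query side (top hit per
  A-transcript); the direction is a config switch. Ties in transcript
  length go to the query side; emitted ids are de-duplicated.
* **Minimum length placement.** The ≥ 200 nt operational definition is
  enforced as an explicit stage after the Rfam purge. In practice the
  ≥ 200 nt consensus-alignment requirement already implies it, so the
  stage usually removes nothing, but it makes the definition a checked
  contract rather than a side effect.
* **ORF flag.** The final coding-potential check is a deliberately
  simple surrogate for a full coding-potential classifier: the longest
  complete ORF (ATG..stop) over all six frames, flagged at ≥ 100
  codons. Flagged transcripts are excluded from the final set but
  reported separately — never silently dropped — mirroring how the
  published pipeline's final validation step trimmed a handful of
  candidates.
* **Inclusive thresholds.** All boundaries are inclusive on the side
  their wording implies ("FPKM ≥ 1.50", "E ≤ 0.01", "at least
  200 nt"); the synthetic bundle plants a probe on each side of every
  boundary so the inclusivity is pinned by tests, not convention.

## Gene duplication

Pairs come from a self-comparison table with self-matches dropped and
directions merged (keeping the better E/bit). Arrangement classes use
gene *rank* — the 0-based order index along the chromosome assigned on
GFF3 load (sorted by start, ties by id) — not base-pair distance:
tandem means |Δrank| = 1, proximal 2..10 (window configurable, default
10, the convention of the standard collinearity toolchain), else
dispersed. A gene's class is its highest-precedence kind
(tandem > proximal > dispersed); the whole-genome/segmental class is
deliberately omitted because it requires collinear-block chaining,
which is external scope — per-class gene totals from the full
classifier are therefore not comparable and are not targets. TAG
arrays are connected components of the tandem-pair graph (networkx),
checked in tests against a hand-rolled union-find.

## Statistics

Welch's t = (m₁−m₂)/√(s₁²/n₁+s₂²/n₂) with Welch–Satterthwaite
df = (s₁²/n₁+s₂²/n₂)² / [(s₁²/n₁)²/(n₁−1)+(s₂²/n₂)²/(n₂−1)]; the raw-
sample overload computes summaries first and is tested to agree with
the summary route to 1e-12 relative. The effect size is d = 2·|t|/√df,
reported as a magnitude (invariant to group order). The two-sample KS
statistic is the exact sup of ECDF differences over the pooled values;
its p-value uses the asymptotic Kolmogorov distribution at effective
n = n₁n₂/(n₁+n₂). Exact small-sample KS p-values are out of scope: at
the group sizes this comparison targets (thousands per side) the
asymptotic form is accurate, and the statistic itself is exact at any
n. Note that library reference implementations often apply small-sample
corrections to the asymptotic p; our tests therefore check the p-value
against the textbook series directly and the statistic against both a
reference implementation and brute-force counting.

Stratified sampling draws uniformly without replacement per chromosome
with numpy's seeded generator; identical seeds give identical samples.
Bit-compatibility with any other environment's generator is not
promised — reproducibility within the toolkit is.

`nussinov_fold` is a maximum base-pairing dynamic program (Watson–Crick
plus G·U wobble, hairpin loop ≥ 3 by default, no pseudoknots) with a
deterministic traceback and a pseudo-energy of −1 per pair. It exists
so folding-dependent code paths are testable without an external
thermodynamic folder; it makes no claim to thermodynamic accuracy, and
real MFE values enter through the RNAfold output parser.

## Synthetic data: what it emulates and what it does not

The generator plants, per class: coding transcripts (log-normal
lengths, median ≈ 900 nt; GC 0.45; an embedded complete ORF of ≥ 120
codons drawn at the class GC; strong plant-protein hits, ~15%
non-plant), noncoding transcripts (median ≈ 450 nt, floored at 250 nt;
GC 0.38; rejection-sampled to be ORF-free; cross-accession partners
aligning ≥ 200 nt, one side 30 nt longer so the consensus winner is
unambiguous), housekeeping structural ncRNAs (GC 0.55; Rfam hits at
E ≤ 0.01), redundant 80%-length fragments at 2% mutation, and the
mandatory boundary probes (FPKM 1.49/1.50, alignment 199/200 nt, Rfam
E 0.01/0.011, protein E 1e-20/just above, a long-ORF survivor, a
record-less transcript). Planted per-nucleotide fold energies are
normal with the published group parameters (−0.276 ± 0.026 coding,
−0.210 ± 0.041 noncoding, kcal/mol/nt), truncated below zero. Default
counts (40 coding, 24 noncoding pairs, 6 housekeeping pairs, 4
fragments per bundle side) keep a full pipeline run around a second
while leaving every stage with real work; the gene-model universe (36
genes over 4 chromosomes plus `chrUkn` cases) plants a one-to-one
ortholog map, a masked paralog family that only the iterative pass can
resolve, dominated decoy hits, a 3-gene tandem chain, a 2-gene array,
a proximal pair, a dispersed pair and a sub-threshold pair.

Evidence tables are *ordinally* consistent (better homology → better
score) but no alignment engine is simulated: E-values and bit scores
are draws, alignment lengths are set by construction, and fold records
carry planted energies with unpaired placeholder structures. Passing
tests therefore demonstrate that the decision logic implements its
contracts exactly — thresholds inclusive, order-stable, conservation
at every stage, planted truth recovered — not that the toolkit would
reproduce any particular biological dataset, where assembly artifacts,
chimeras and genuine borderline cases blur every boundary the decoys
pin cleanly.

## Numerical and degenerate-input choices

GC counts G+C over the full length with N in the denominator only.
U and T are equivalent on read. Zero-length models, empty metric
groups, degenerate (both-zero) variances, missing gene models and
unknown organism codes raise typed errors rather than propagating
NaNs. Means over empty concordance classes are reported as absent, not
zero. The Kolmogorov survival value is clamped to [0, 1]. Problem
sizes in tests and the acceptance script (200 random anchor tables of
≤ 30 genes/side, 500 folding sequences of ≤ 12 nt, 100 statistic
sample pairs, 100 random tandem layouts of ≤ 50 genes, 20 recovery
seeds at n = 3049 per group) were chosen so the whole validation runs
in seconds at full coverage of each contract.

## Known limitations

The clustering, folding and coding-potential components are explicit
desk-scale stand-ins, not re-implementations of CD-HIT, RNAfold or a
trained coding-potential classifier. Orthology is strictly one-to-one
RBH-based — no trees, no synteny, no many-to-many families — and the
duplicate classifier omits the whole-genome-duplication class.
Expression enters only as a precomputed FPKM table; no quantification
is performed. The KS p-value is asymptotic.
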