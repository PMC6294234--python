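# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `hgtscreen`, in the order the pipeline runs them.

## The detection problem

An HGT gene in an obligate parasite leaves two signatures: its gene tree
places it inside the host family rather than with the parasite's own
relatives, and its synonymous divergence to the closest sampled host gene
is far below what vertical descent since the host/parasite split would
produce. Both signatures need careful filtering, because ordinary
conserved genes also align well across families, and gene trees of
diverged loci are noisy. The cascade therefore combines local-identity
screening, a conservation contrast against a close outgroup, distance-based
trees, explicit branch-length and Ks rules, and a topology test, each of
which is a named, configurable threshold in `PipelineConfig`.

## Homology screen

`find_hits` seeds on exact 12-mers shared between query and subject
(both strands) and runs an affine local alignment (match +2, mismatch −3,
gap open 5, gap extend 2 — BLASTN-style scoring, via
`Bio.Align.PairwiseAligner`). A hit qualifies only if identity is
strictly above 75 % over strictly more than 300 alignment columns; gap
columns count against identity. Two shared seeds are required before a
candidate is aligned, and candidates whose optimal local score falls
below a provable lower bound for any qualifying alignment
((7·f − 5)·(min_len+1) at identity fraction f) are skipped without
traceback; neither shortcut can discard a qualifying hit at the default
thresholds. The bit-like score is a fixed affine transform of the raw
score (0.5 bits per score unit); it is used only for comparisons within
one run, never across scoring schemes.

The conservation filter compares best host vs. best outgroup score: ties
go to the vertical explanation (the quantitative form of "much higher
homology to the outgroup" had to be fixed somewhere; a score comparison
with a configurable margin, default 0, is the simplest monotone choice).
The multi-host rule counts distinct host *species* with qualifying hits,
not hits.

## Ka/Ks

`ng86_counts` implements Nei–Gojobori (1986) counting: per-codon
synonymous site fractions (changes to stop codons count as nonsynonymous,
so S + N = 3 per codon), pathway-averaged difference counts over all
minimal mutational paths with stop-crossing paths excluded, gap and
ambiguous codons removed pairwise. All 61×61 pair quantities are
precomputed into tables at import, so alignment-scale work is integer
indexing. Distances are Jukes–Cantor corrected, d = −¾ ln(1 − 4p/3);
p ≥ 0.75 is reported as a saturation flag with an infinite sentinel, and
Ka/Ks is undefined (NaN) when Ks = 0. NG86 was chosen because it is the
classical counting estimator consistent with a JC correction of pS/pN;
ML pairwise estimators are out of scope.

Codon alignment is protein-level center-star progressive alignment
(Needleman–Wunsch, BLOSUM62, affine gaps; the center is the sequence with
the highest mean shared-k-mer similarity), back-translated so gaps occupy
whole codons. Internal stop codons are an error; trailing partial codons
are trimmed with a warning.

## Trees and the phylogenetic screen

`neighbor_joining` is the standard Saitou–Nei agglomeration with the
Q-criterion; negative branch-length estimates are clamped to zero with
the deficit moved to the sister branch. It is exact on additive matrices
(property-tested, and part of the acceptance oracles). Bootstrap support
resamples codon columns; replicates whose resampled distance matrix
contains a saturated pair are dropped from the denominator. The default
100 replicates is a convention; the replicate count behind the original
supports is not recoverable.

The branch-length rule fails a locus when the parasite's external branch
exceeds twice the longest *single edge* of the host-induced subtree.
"Longest branch between host species" could also be read as the patristic
diameter; the single-edge reading is implemented because the comparison
is against one branch in the tree display, and the factor (2) and the
mode are both configurable. The Ks rule takes the minimum-Ks host
(tie-break: more compared codons, then lexicographic id) and requires
Ks < 1, roughly the divergence horizon of a host family.

The placement test roots the gene tree on the outgroup (when the input
tree is already rooted, its root is respected) and accepts when the
smallest clade containing the parasite and at least one host contains no
outgroup tip. Sister-to-the-whole-host-clade counts as the transfer
pattern; with a single outgroup such a tree is topologically ambiguous
with the vertical pattern, which is exactly why the conservation and Ks
filters sit upstream. When no outgroup homolog can be aligned at all,
the placement stage passes vacuously and the Ks evidence stands alone
(mirroring loci whose homologs are found only within the host family).
For gene trees the outgroup homolog is recovered at relaxed thresholds
(50 % / 100 bp), since a genuinely distant outgroup rarely clears the
screening cutoffs themselves.

`verify_homolog_tree` builds confirmatory ML trees: HKY85 with
4-category discrete gamma (category means; shape α optimized by golden
section), Felsenstein pruning over site patterns, branch lengths by
L-BFGS-B on log-lengths, topology by NJ start plus
nearest-neighbor-interchange hill climbing. Homolog sets are pre-filtered
by the half-bit-score rule against the best host hit. These trees are
confirmatory; the accept/reject decision of the cascade is defined by the
NJ stages, which is why `run_screen` does not invoke the ML search by
default.

## Branch-model ω test

For each accepted locus the trio (transferred gene, closest donor
homolog, outgroup homolog) is fitted on a trifurcation under a GY94
codon model: single-nucleotide codon changes at rate proportional to the
target codon frequency, ×κ for transitions, ×ω for nonsynonymous
changes; F3x4 frequencies estimated from the data (codeml's default
parameterization; uniform frequencies are switchable). Each branch's
rate matrix is normalized to unit mean flux, so branch lengths are
expected substitutions per codon. The null model shares one ω across the
three branches; the alternative gives the transferred branch its own ω.
Likelihoods use a symmetrized eigendecomposition of the reversible rate
matrix and site-pattern compression. The alternative fit is seeded at
the null optimum (guaranteeing a non-negative LRT up to optimizer
tolerance) and refitted from ω ∈ {0.1, 0.5, 1.5} whenever the seeded fit
fails to converge or degrades. The LRT statistic is referred to χ²₁ with
no boundary-mixture correction, matching the test as originally applied;
ω and κ are bounded to [1e-4, 99] and branch lengths to [1e-7, 50].
Calibration is part of the acceptance suite: the 5 %-level null rejection
rate over 200 replicates (500 codons, ω = 0.2, branch lengths 0.2) must
lie in [2.5 %, 8.5 %], and the median ω̂ on the transferred branch under
ω = 1.5 must land within ±30 % of truth; a recent run measured 6.0 % and
1.47 respectively.

## Genomic reconstruction

`fill_gap` anchors a contig on each exon flanking an intron and extends
the two contigs toward each other: reads (either orientation) overlapping
a contig end by at least 30 nt with zero mismatches (both configurable)
vote base-by-base; extension stops at a branch point where the
second-most-supported base reaches half the top support, which leaves the
gap open with an ambiguity flag — this is how duplicated loci (e.g. after
a WGD) surface. The gap closes when the two contigs overlap exactly by
the minimum overlap. Extension candidates are processed in sorted order,
so the result is deterministic for a given read set.

`splice_check` counts mRNA reads containing the exon–exon junction with
10 exact nucleotides on each side; one read suffices to call an intron
spliced. `orf_integrity` aligns the transferred CDS globally to the donor
CDS at the DNA level with steep gap penalties (open 16, extend 4), counts
gap runs of length not divisible by 3 as frameshifts and parasite codons
reading as stops in the donor-anchored frame (before the donor's final
codon) as premature stops; amino-acid-changing substitutions are not
counted as damage. The steep penalties matter: at Ks ≈ 0.5 a permissive
aligner invents gap pairs in substitution-diverged regions and
fabricates frameshifts. Intron-position conservation maps each intron's
CDS offset through the codon alignment and counts positions interrupted
at the same aligned nucleotide (phase-aware).

The coverage check places each genomic read once (best placement over
all candidate genes, sliding exact 15-mer seeds; identity =
matches/read length) and accumulates per-base depth at the 100 %
(exact), > 95 % and > 90 % tiers. Contamination is flagged when the
median depth of transfer candidates falls below half the median
background depth at the 100 % tier. With a 5–10 %-diverged WGD copy the
relaxed tiers roughly double in depth (the duplicate's reads map to the
original above 90 % identity but not at 100 %): at 7 % divergence the
expected inflation is 1 + P[Binom(90, 0.067) ≤ 8] ≈ 1.85, and the
acceptance suite requires ≥ 1.7.

## Origins and transfer events

`assign_origin` roots the gene tree on the outgroup, takes the host
species of the parasite gene's sister group, and maps that set onto the
host species tree: a monophyletic sister group gives the stem edge of
the matching clade (a single species gives its terminal edge), the upper
time bound is the speciation at the top of that edge, and the lower
bound is always "the present" — the true donor may be an unsampled
relative of the sampled sister, so the sister's own age never bounds the
event from below. Assignments are flagged ambiguous when the sister
group is non-monophyletic, when the supporting bipartition's bootstrap
is below 75 %, or when the minimum-Ks host falls outside the tree-derived
sister group (two lines of evidence disagreeing); candidates are the
branches of the smallest clade covering the conflict (one level up for a
pure support failure). Deep donors near the host-family root are the
hard case — a 300-codon gene can mis-resolve the sister side with high
bootstrap — and the Ks-consistency flag is what catches it.

`detect_clusters` single-links donor-homolog coordinates along each
chromosome: genes join one event when their interval gap is ≤ 100 kb
(configurable) or their donor-annotation gene ranks are adjacent. The
event count is monotonically non-increasing in the gap threshold, and
the worked acceptance example (11 genes, one adjacent pair → 10 events)
runs on exactly this function. Whether several nearby clusters are one
event or several is reported, not decided: the span of merged clusters
is available at any threshold.

## Synthetic data

The generator emulates the study regime, not any particular dataset:

- **Species tree.** 8 host taxa (balanced, pairwise Ks 0.1–0.6), one
  outgroup and the parasite sister to it (parasite–outgroup Ks ≈ 0.56),
  host family vs. parasite side Ks ≈ 1.2. Branch lengths are *expected
  synonymous substitutions per synonymous site*.
- **Clock calibration.** Codons evolve under GY94 (κ = 2, ω = 0.2,
  uniform codon frequencies). Because the NG86/JC estimator is not
  exactly unbiased under κ ≠ 1, model time is stretched by a constant
  (≈ 0.986) chosen so the analytic expectation of the estimated Ks
  equals the nominal branch length at a reference divergence of 0.3;
  the residual nonlinearity across Ks 0.05–0.6 is below Monte-Carlo
  error at 200 families (measured mean 0.197 ± 0.002 at nominal 0.2).
- **Rate heterogeneity.** Vertical families draw a rate multiplier
  uniform on [0.35, 1.2]; slow families are the conserved loci that pass
  the identity screen and must be removed by the conservation filter
  (without heterogeneity that filter would never fire). Families
  carrying an injected event evolve at rate 1 so nominal donor
  divergences are realized.
- **Transfers.** An event names a donor branch and an age fraction along
  it; the donor branch is evolved in two segments split at the transfer
  point, so the transferred copy shares the donor lineage's realized
  history up to the event and then evolves independently for the
  wall-clock time back to the present (age fraction 0 on a terminal
  branch reproduces the donor tip exactly). DNA mode copies exons and
  introns with positions preserved; mRNA mode copies the spliced CDS
  with a 15 nt poly-A tract. The default scenario injects 10 events with
  donor Ks 0.05–0.5 (7 DNA, 3 mRNA), two of them one linked two-gene
  donor segment; transfer points sit strictly inside donor branches so
  sister groups remain identifiable. The parasite's vertical homolog is
  always retained as its own locus.
- **Introns.** 2–5 per gene, 80–300 nt, GT…AG ends, evolving under
  neutral Jukes–Cantor at a configurable multiple (default 1×) of the
  synonymous rate; positions leave every exon at least 35 nt so each
  exon anchors reconstruction. Intron turnover and exon indels are not
  modeled (an indel switch exists only through the integrity tests'
  engineered inputs).
- **Reads.** 90 bp paired ends, nominal inserts 500 bp (genomic) and
  200 bp (mRNA) with 10 % insert-size dispersion (a fixed insert would
  leave unsequenced dead zones on templates barely longer than the
  insert), uniform fragment starts, optional uniform substitution
  errors (default 0; the pipeline is quality-agnostic and qualities are
  placeholders).
- **Annotation coordinates.** Donor homolog coordinates space unlinked
  families ~150 kb apart with non-adjacent annotation ranks (unsampled
  genes lie between families); linked families sit on consecutive ranks
  within tens of kb, like a real co-transferred segment.
- **Determinism.** Every artifact derives from `numpy` SeedSequences
  keyed by (seed, family, stream); identical configs emit byte-identical
  files.

What passing tests on this generator do *not* show: robustness to
assembly fragmentation and chimeric transcripts (transcripts are emitted
full-length), alignment error under real indel processes, base-quality
artifacts, paralog-rich gene families beyond the single WGD switch, and
codon-usage or GC heterogeneity across the genome.

## Problem sizes

The shipped analysis and test configurations use 110-family scenarios
(300 codons per gene), 100-replicate bootstraps, 200 + 100 LRT
replicates at 500 codons, and 8-taxon / 800 nt ML-recovery replicates;
these sizes were chosen so each analysis completes in minutes on one
core while keeping Monte-Carlo error well inside every tested tolerance.

## Known limitations

- The conservation rule is a score comparison with margin 0; the
  original operation was qualitative, so absolute agreement with any
  particular external implementation is not expected.
- Agreement with codeml on the ω LRT is qualitative (frequency model and
  convergence settings of the original runs are unknown); the test's
  validity is established by its own calibration instead.
- `run_reverse_direction` screens each host species against the
  parasite-side family with the remaining hosts as the conservation
  reference; with very few host species the conservation contrast
  weakens.
- Stage results are not cached across runs; determinism under a fixed
  seed is the reproducibility mechanism.
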