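# Methods

This note documents the models, thresholds and numerical conventions behind
`ssrgbs`, the design choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Read preparation

**Quality trimming** removes the maximal 3' suffix of bases below Phred 20.
Only the 3' end is touched: the 5' end carries the PCR primer that anchors
locus assignment, so 5' trimming would destroy demultiplexing.

**Pair merging** reverse-complements read 2 and enumerates *every* ungapped
suffix–prefix overlap exactly (via anti-diagonal sums of the base-equality
matrix). Among overlaps of ≥ `min_overlap` (default 10 bp) with a mismatch
fraction ≤ `max_mismatch_frac` (default 0.1), the overlap maximizing the
number of matched bases wins, ties going to the longer overlap.
Disagreements are resolved toward the higher-Phred base (ties toward
read 1). The 10 bp floor preserves the standard credible-overlap contract of
amplicon mergers; the mismatch-fraction cap replaces merger-specific
alignment-score significance tests with a transparent, configurable
criterion. Unmerged pairs are discarded and counted. Overlaps longer than
either read (one read engulfing the other) are not considered; the
simulator enforces amplicons longer than one read and shorter than the
mergeable span.

**Primer demultiplexing** requires the forward primer at the start and the
reverse-complemented reverse primer at the end of the merged read, testing
both orientations. The default tolerates zero mismatches per primer — the
strictest reading of exact motif identification — and is configurable
(`max_primer_mismatch`) for degraded samples; at the default, a read with a
sequencing error inside a primer is simply discarded and counted, which at
0.1% base error costs ~4% of reads and no genotypes. A read matching two
markers' primer pairs is counted as ambiguous and rejected (it indicates a
panel design flaw and is logged). Accounting is conservative by
construction: every input pair ends in exactly one category.

## Length-based calling

Lengths are **raw merged-amplicon lengths, primers included**, the same
scale on which the 300 bp minimum-length filter is defined (amplicons are
designed > 400 bp, so shorter products are off-target artifacts). Tallies
below `min_depth` (default 20 reads) give a missing genotype — a floor the
workflow adds so that a handful of reads can never produce a confident
call; every trigger is logged.

The decision tree (README) applies the homozygote threshold inclusively
(f(L1) ≥ 0.90) and the heterozygote joint threshold strictly
(f(L1)+f(L2) > 0.90); exactly-at-threshold profiles are therefore
homozygous-callable but not het-callable, an edge case the verbal form of
the rules leaves open; both thresholds are parameters. The
20-point balance rule is interpreted in **percentage points of all retained
reads** (f(L1) − f(L2) ≤ 0.20), not relative to f(L1), because both
surrounding thresholds are phrased against all reads; the alternative
relative reading is available by adjusting `het_balance`. L1/L2 ranking
ties break toward the longer length (slippage predominantly shortens, so
the longer of two equal peaks is likelier the parent); the case-III ratio
boundary (count(short) = 0.75 × count(long)) counts as passing.

Length differences that are **not a multiple of the repeat unit** and
smaller than one unit cannot arise from repeat slippage; such pairs are
called heterozygous (flank indel) with a warning rather than fed to the
stutter cases, which are defined in whole repeat units.

Profiles failing every rule are flagged ambiguous and exported with their
full histogram record for manual review; curator decisions re-enter through
an override table and are marked `manual` with provenance logged. This
mirrors how chromatogram-based genotyping operates in practice: the
automatic rules handle the clean majority, the curator handles ladders the
rules refuse to guess about (with heavy dinucleotide-type stutter, that is
most of the dataset — see *Simulator*, below).

## Sequence-based calling

Reads of a called length class all share one length, so positions are
directly comparable without alignment — indels within a class are
impossible by construction. The consensus threshold is applied as
f(b1) ≥ 0.70 → homozygous column (the exactly-70% boundary is assigned to homozygous and is
configurable). Reads carrying N at any flagged position are excluded from
combination counting to avoid phantom haplotypes. Multi-SNP columns are
treated as linked and phased by the rank of observed combinations — top two
for a length-homozygote, top one for a length-heterozygote — relying on the
assumption that errors and PCR chimeras are rarer than reads from real
alleles. Ties at the decisive rank (strict count equality by default;
`tie_margin` widens it) flag the genotype for manual resolution instead of
guessing. SNP detection is per length class; flanking positions are not
pooled across classes.

Allele codes are small integers assigned per locus in first-seen order over
samples in sheet order, then frozen; identical sequences always share a
code, so registries and matrices are deterministic. Mapping each sequence
allele to its parent amplicon length yields the parallel length-coded
matrix; since this mapping only merges codes, the sequence partition
refines the length partition and Na/He/PIC cannot decrease under sequence
coding — the refinement direction the statistics module also asserts in
tests.

## Marker screening

The SSR screen reports maximal perfect tandem runs of primitive 2–5 bp
motifs (canonical form: lexicographically smallest rotation over both
strands), resolving overlapping calls to the longest run. Acceptance
thresholds: ≥ 40 bp flank on both sides; minimum repeat counts 10 / 8 / 6 /
6 for di/tri/tetra/penta motifs; reads with mononucleotide stretches > 6 bp
or interrupted copies of the candidate motif are excluded unless
`allow_interrupted` — the documented fallback for motif classes that would
otherwise yield too few loci. The mononucleotide screen is evaluated on the
whole read (the unit of manual exclusion during marker design); a
flank-only variant would be a trivial change and is noted as such. Primer
design itself (thermodynamics, adapter tails) is out of scope; candidates
carry flank coordinates for any external primer tool.

## Population-genetic statistics

He uses the uncorrected 1 − Σp² form (the GenAlEx default); the unbiased
2n/(2n−1) correction sits behind a flag. PIC ≤ He holds algebraically
(PIC = He − Σᵢ<ⱼ2pᵢ²pⱼ²). Pairwise distances count, per co-typed locus,
2 minus the shared allele copies (multiset intersection), reported both as
totals and as per-locus means; pairs are compared over co-typed loci only
(pairwise deletion), with no-overlap pairs left missing. PCoA is Gower
double-centering plus eigendecomposition (via scikit-bio); negative
eigenvalues are reported and their axes dropped. The Mantel test permutes
rows/columns of the second matrix with a seeded generator; the one-tailed
p-value includes the identity permutation in numerator and denominator, so
the smallest attainable p is 1/permutations. Geographic distances are
haversine great circles (R = 6371.0088 km); sample coordinates are treated
as point locations, including for animals whose collection site is only
known to a radius.

## Simulator

The generator emulates the data structure the caller assumes: per-sample
paired 250 bp reads from multiplexed amplicons (~380–440 bp, so pairs
overlap by well over the 10 bp floor), with

* **stutter** — per read, probability `stutter_rate` of losing repeat
  units (geometric number of steps, decay 0.75), expansions at one tenth of
  that rate: the usual contraction bias of polymerase slippage;
* **errors** — i.i.d. base substitutions at `per_base_error`;
* **chimeras** — in heterozygotes, probability `chimera_rate` that a read's
  template is the two alleles spliced at a uniform breakpoint (such
  products carry one allele's flank haplotype on the other's repeat tract,
  the artifact the rank-based phasing must survive);
* **coverage** — locus coverage is gamma-Poisson (shape 50 around a 500×
  mean); reads split binomially between a heterozygote's two alleles,
  because both alleles co-amplify in one reaction.

Defaults are the study conditions used throughout the tests: 20 samples ×
10 tetra/pentanucleotide markers, coverage 500×, base error 0.001, chimera
rate 0.02, stutter rate 0.05, two populations with Dirichlet allele
frequencies, one effectively private allele per marker, and a same-length /
different-haplotype (homoplasic) allele pair at four of the ten markers.
The 5% slip probability is the well-behaved tetra/penta regime: in
practice, tetra- and pentanucleotide loci need almost no manual correction
under the 90% thresholds, which arithmetically requires the parent allele
to keep ≳ 90% of reads. A homozygote at slip probability *q*
shows f(L1) ≈ 1 − 1.1·q, so q ≈ 0.05 auto-calls cleanly (the threshold sits
> 4σ away at 500×), while by q ≈ 0.25 — let alone the 0.4 used in the
dinucleotide demonstration — f(L1) ≈ 0.72–0.77 and the balance rule pushes
profiles to manual review: the tree flags rather than guesses. The test
suite exercises both regimes and treats flagged cells as *non-concordant*
when scoring, so the ≥ 99% recovery claim is strict, not
"among calls only" (that laxer rate is reported separately).

Deliberately **not** modeled: platform quality-score profiles (qualities
are N(37, 2) and errors are drawn independently of them), GC/efficiency
amplification bias, allelic amplification imbalance beyond binomial
sampling, adapter read-through, index hopping, and "plus-A" tailing — the
last is a fragment-sizing artifact with no effect on sequence-defined
alleles. Passing tests therefore demonstrate correctness of the calling
logic under a realistic artifact mix, not robustness to pathological
allelic imbalance or to stutter far outside the auto-call regime; those
data land in the manual-review queue by design.

## Problem sizes used in validation

The decision-tree equivalence check runs an exhaustive grid of ~55,000
count profiles (motifs 2–5; 2–4 length classes; counts 0–1000). End-to-end
recovery runs the full default study (200 genotypes from ~100,000 read
pairs) plus a 6 × 4 and a 4 × 3 run at 300×/200× for integration tests —
sizes chosen to keep the whole suite around a minute while leaving every
code path exercised at realistic coverage. Distance and screening oracles
use 1,000 random 5 × 4 matrices and 200 random 1 kb reads respectively.

## Known limitations

* Multi-copy (duplicated) loci are not deconvolved; suspect markers should
  be excluded upstream.
* No parametric stutter/genotype likelihood model: the tree is rule-based
  by design, trading statistical power for auditability and manual control.
* Dinucleotide panels with heavy stutter genuinely require a curator; the
  package surfaces them rather than resolving them.
* The GenAlEx/STRUCTURE writers target the codominant text layouts those
  tools ingest; exotic dialect variations are not round-tripped.
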