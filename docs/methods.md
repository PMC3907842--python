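# Methods

This note documents the models, rules and numerical choices behind
`mirtally`, and what the synthetic experiments its tests run on do and do
not establish about real data.

## The experiment being modelled

Two small-RNA libraries from the same tissue — an untreated control (CK)
and a stress treatment (TR) — are deep-sequenced, and the question is which
conserved miRNAs change abundance between them. There are no biological
replicates; inference rests on an exact test for a pair of counts given the
two library sizes, which is why the calling rule combines a fold-change
threshold with the test rather than relying on either alone.

## Preprocessing

Reads are uppercased and U→T normalised on ingest, so the whole pipeline
works on a single DNA alphabet. The 3′ adapter is located at the leftmost
position where either the full adapter matches with at most one
substitution, or the read suffix (≥ 6 nt) exactly matches a prefix of the
adapter. Reads containing ambiguous bases and reads whose insert falls
outside 15–32 nt (the sequenced insert range) are discarded; survivors are
the *mappable* reads. "Impurity" removal is deliberately operationalised as
exactly these three concrete filters — adapter trimming, N exclusion,
length gating — because further chemistry-specific artefact filters are
sequencer-dependent and not reproducible from a description alone. Reads
with no detectable adapter are kept when their full length is within the
insert range, since long inserts legitimately push the adapter out of the
read.

Collapsing produces one tag per distinct sequence with exact per-library
multiplicities, sorted by total count (descending) then sequence, so output
is byte-stable. Per-library tag-count sums equal the mappable read counts
by construction, and this conservation is asserted throughout the tests.

## Annotation cascade

Each tag gets exactly one category, with precedence
miRNA > mRNA > RFam > Repbase > genome > no-hit (configurable). The
miRNA-first order is used because published per-category fractions quote
miRNA reads as a share of all mappable reads; the order is a config option
for users who prefer contaminant-first removal.

Conserved-miRNA homology is a shifted ungapped alignment: the tag may start
or end up to 3 nt away from the mature's terminus, overhanging bases are
unaligned, the aligned overlap must cover ≥ 16 nt, and at most 2
substitutions are allowed ("fewer than three mismatches", read strictly).
Indels are not modelled separately; terminal shifts absorb the common
length heterogeneity of real miRNA reads. The best hit minimises
mismatches, then maximises overlap, then takes the lexicographically
smallest name — a total order, so annotation is deterministic. A tag that
fails against every mature but aligns, by the same rule, to a precursor
region disjoint from that precursor's mature locus is a star
(passenger-strand) hit. The minimum overlap of 16 nt guards against
spurious short-overlap hits; the source analyses do not state a value.

mRNA/RFam/Repbase membership is exact substring matching, and genome
membership is exact substring on either strand: no mismatch allowance is
stated for these classes, and exact matching keeps the cascade
unambiguous. The matcher is vectorised (per-length window comparisons over
uint8-encoded sequences) but implements exactly the rule above; tests pin
it to a naive nested-loop scan.

Profiles sum member tags per (reference miRNA, arm) and are kept when
either library shows ≥ 6 reads — the "more than five reads" error filter,
applied to raw counts because the filter precedes normalization in the
workflow being modelled. Families strip the species prefix and trailing
variant letters (`sli-miR166a` → `miR166`).

## Normalization and differential expression

Size factors are median-of-ratios against a per-tag geometric-mean
pseudo-reference; tags with a zero in any library are excluded because
their pseudo-reference is zero, and the median of an even-length list is
the mean of the central pair. Factors from a two-sample geometric-mean
reference are defined only up to a common scalar: multiplying the TR counts
by c moves the pseudo-reference by √c, hence s_TR by √c and s_CK by 1/√c,
and only the ratio s_TR/s_CK is c-equivariant. Everything downstream (fold
changes, filters relative to both libraries, calls) depends on the factors
only through that ratio; the scale-equivariance tests assert the ratio
form. By default factors are computed from the miRNA profile table (the
table being compared); the function accepts any two-column count table.

The exact test: given x counts in N₁ reads, the count K in a library of N₂
reads follows p(k|x) = (N₂/N₁)^k (x+k)! / (x! k! (1+N₂/N₁)^(x+k+1)), the
negative-binomial law NB(x+1, N₁/(N₁+N₂)). The default two-sided p doubles
the smaller of the two conditional lower tails, P(K ≤ y | x; N₂/N₁) and
P(J ≤ x | y; N₁/N₂), capped at 1. These two tails are complementary, so the
construction equals doubling the smaller of the lower tail and the strict
upper tail, and it is exactly exchangeable under swapping (x, N₁) with
(y, N₂) — the property a two-directional call from a single p column
requires. A construction that includes the observed point in both tails is
not exchangeable (verified against exact rational arithmetic), which is why
this one was chosen; one-sided lower/upper variants remain available via
`sided=`. Tails are summed in log space with the log-gamma function; the
open upper tail is accumulated forward from k = y until terms drop below
10⁻¹⁶ of the running sum. Under a paired-Poisson null (λ = 100, N₁ = N₂)
the empirical rejection rate at α = 0.05 is ≈ 0.047 over 10,000 pairs —
slightly conservative, as expected for a doubled discrete tail.

The test runs on raw counts with the per-library mappable-read totals as
N₁, N₂ (the test models sampling from the full library); fold changes are
computed on normalized counts, with a 0.5 pseudo-count substituted for a
zero side for reporting only — never inside the test. Profiles outside
18–24 nt or with normalized counts ≤ 10 in both libraries are excluded
before testing. All calling inequalities are strict, following the wording
of the thresholds ("over 10", "> 1", "< 0.05"). No multiple-testing
correction is applied, matching the modelled workflow.

## Target scoring

The scorer is a transparent stand-in for plant target-prediction servers,
whose exact internals are not published alongside the analyses being
modelled: Watson–Crick 0, G:U wobble 0.5, mismatch 1.0, single-nucleotide
bulge 2.0, penalties doubled at miRNA positions 2–13 from the 5′ end,
default cutoff 3.0. At most one bulge per site (on either strand) bounds
the alignment search while still exercising the gap penalty; only the
transcript sense strand is searched, since targets are mRNAs. The scanner
computes all window scores with prefix/suffix sums (O(L·n) per bulge
variant) and collapses overlapping hits of a miRNA on a transcript to the
best-scoring site, breaking ties by position. It is not intended to be
bit-identical with any external server.

## Reporting

Percentages are count/mappable×100, rounded half-up to two decimals;
composite percentages (e.g. "repeats + mRNA + other RNAs") are sums of the
already-rounded addends — this is the arithmetic that reproduces published
composite values exactly, where raw-count arithmetic can differ in the last
digit. Relative expression from qPCR uses the standard 2^−ΔΔCt form with
arithmetic replicate means, the replicate scatter propagated as the root
sum of the four means' standard errors, and U6 as the default reference;
the computation is invariant to adding a constant to every Ct within a
sample. Concordance compares the sign of the sequencing log₂ fold change
with the sign of the log₂ qPCR fold change per miRNA.

## Synthetic data

The generator emulates the modelled experiment: miRBase-style families
(`sli-miRNNN[letter]`) whose mature sequences are embedded in precursors
with a star arm (approximately the reverse complement of the mature) on the
opposite side of a loop; contaminant, mRNA, repeat and genome references;
and two libraries of 3′-adapter-ligated reads, 40 nt long, with constant
'I' quality and independent per-base substitution errors.

Key design choices:

* **Abundances.** Expected per-miRNA reads are drawn log-uniformly over
  (2, 1000) per 50,000-read library, scaled linearly with depth — roughly
  the four-decade spread observed in real root libraries, scaled down.
  The log-uniform choice guarantees both the ≥ 6-read and > 10-normalized
  filters see passing and failing cases.
* **Planted regulation.** A fraction (default 20%) of miRNAs whose control
  expectation is at least 50 reads receive a fold change of 2^±2
  (alternating directions). A "random filler" read source absorbs the
  difference in expected totals, so the expected TR/CK ratio of a planted
  miRNA is exactly 2^lfc, the ratio of every other source exactly 1, and
  each library still totals exactly its configured depth (counts are one
  multinomial draw per library).
* **Star arms.** Star reads are emitted at 5% of the mature's control
  abundance in both libraries and are not scaled by the planted fold
  change: the passenger strand is degraded after duplex loading and its
  steady-state level need not track mature regulation. Stars therefore act
  as nulls in recovery studies.
* **Adapter-seed masking.** References and filler inserts are rewritten so
  that no 6-mer of the adapter occurs inside an insert. Real inserts can
  contain adapter-like sequence; the simulator excludes this to make
  adapter detection unambiguous, so that at error_rate = 0 the mappable
  read count equals the ground-truth count of reads with inserts in the
  15–32 nt window exactly. read_length defaults to 40 nt so even a 32-nt
  insert leaves ≥ 6 adapter bases visible.
* **Determinism.** All draws flow from one seed through numpy's PCG64
  streams; identical configuration yields byte-identical FASTA/FASTQ.

What the generator does **not** emulate: position-dependent Illumina error
profiles, indels, quality-score variation, adapter dimers, ligation bias,
isomiR length heterogeneity beyond the fixed mature sequences, genuine
hairpin thermodynamics, or complementarity target sites inside the mRNA
references (random transcripts essentially never score below the target
cutoff, so end-to-end target output on synthetic data is expectedly empty
and the scanner is validated on planted-site fixtures instead). Passing
tests on this data therefore demonstrate the correctness of the
implemented rules and the statistical behaviour of the test under clean
sampling noise — not robustness to real-library artefacts.

## Problem sizes used in the test-suite studies

The recovery study runs at 50,000 reads per library with 40 miRNAs in 15
families, every miRNA at ≥ 50 expected control reads, 20% planted at
|log₂fc| = 2 (seed 7): all eight planted miRNAs are recalled with the
correct direction, with at most one false call among the null profiles —
the residual false call, when it occurs, is a star profile, whose
abundance (5% of the mature) sits below the 50-read floor by design.
Unit and oracle tests use 3,000-read libraries with 20 miRNAs, where
exhaustive nested-loop scans are affordable; the matching rules being
checked are size-independent. The null-calibration study uses 10,000
Poisson pairs at λ = 100.

## Known limitations

* No replicate-aware dispersion modelling; the exact test treats all
  variation as sampling noise, so real biological variability inflates
  significance. This mirrors the modelled workflow.
* Exact-substring matching for mRNA/RFam/Repbase/genome misses variant
  reads of those classes (they fall through to no-hit), which is the main
  reason the synthetic no-hit fraction exceeds naive expectation when the
  error rate is nonzero.
* The target scorer's penalties are field-typical defaults, not a
  reimplementation of any specific server.
* Novel-miRNA discovery and hairpin secondary-structure prediction are out
  of scope.
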