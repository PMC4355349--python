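# Methods

This note records the models behind `probecap`, the parameters that matter,
the numerical choices made where the design was genuinely open, and what
the synthetic benchmarks do and do not demonstrate.

## Problem setting

Given a set of target nucleotide sequences (typically gene-family members
collected for a targeted metagenomics study), produce a set of fixed-length
oligonucleotide capture probes such that (a) every cluster of related
targets is covered by a few probes, (b) probes designed for one cluster do
not hybridize-match any other cluster's sequences, (c) every probe is
synthesizable (no ambiguity codes) and falls inside user GC and melting
temperature windows, and (d) the synthesis cost is quantifiable per probe.

## Clustering and the identity measure

Clustering is greedy-incremental in the CD-HIT style: sequences sorted by
decreasing length (ties by input order); each is compared against existing
cluster representatives in creation order and joins the first (or, with
`best_cluster`, the best) whose identity reaches the threshold, else founds
a new cluster. This is deterministic and order-stable.

**Identity definition.** identity(a, b) = M / min(|a|, |b|), where M is the
maximum number of identical aligned bases under a global alignment with
*free gaps*, restricted to a diagonal band (offsets j − i in
[−b, (|b|−|a|) + b], default half-width b = 20). Free-gap match
maximization is the banded longest-common-subsequence count, which has an
exact unbanded dynamic-programming oracle; the test suite exploits this to
verify the banded kernel and the whole greedy pass against brute force.
Two consequences are documented rather than hidden:

- Since gaps are free, local and global identity coincide; the
  `global_identity` flag is accepted for interface compatibility but does
  not change the value.
- For pairs of very different lengths the measure is generous: a short
  sequence can reach "identity" 0.9 against a long random sequence by
  scattering its matches. With the genomic-length filter in place, targets
  are single genes of comparable scale and the regime does not arise in the
  intended use; the word prescreen explicitly abstains there (below).

**Word prescreen.** Before aligning, a pair is rejected if provably hopeless:
the per-letter composition bound min-counts(a, b) is a true upper bound on M
for any alignment, so `bound < ceil(t·m)` is a sound rejection for every
length combination. A shared-word check (no common `word_size`-mer, default
8) additionally rejects pairs, but only when the sequences are comparable
(shorter ≥ 4·word_size and longer ≤ 2·shorter); outside that regime word
statistics carry no signal against a free-gap identity and the filter
abstains. Under substitution-dominated divergence at threshold 0.9, match
runs average ≈ t/(1−t) = 9 > 8 bases, so qualifying pairs share 8-mers with
overwhelming probability; the equivalence of prescreened and
prescreen-free clustering is asserted on randomized datasets in the test
suite rather than claimed as a theorem.

**Defaults** (`identity_threshold` 0.9, `word_size` 8, strands forward-only,
`band_width` 20, first-fit assignment) approximate common CD-HIT practice;
all six parameters are exposed. Reverse-complement members (when
`both_strands` is on) are stored with strand "−" and re-oriented to the
representative's forward strand before any probe work.

## Spaced-seed matching and primary design

A spaced seed is a care/don't-care pattern: `n_words` care runs of
`word_length` bases separated by gap runs of `gap_length` < 3 (the
group-specific design constraint). Default: 4 words of 10 with gaps of 2,
pattern length 46 ≤ probe length 50. A probe candidate matches a target
when, for some anchor inside the candidate and some offset in the target,
all care positions agree. Matching is implemented exactly (not
heuristically) via an inverted index of care-position projections: every
anchoring position of every input sequence contributes one key, so
specificity (no key shared with a foreign cluster) and coverage (bitmask
union over own-cluster members) are dictionary lookups. The brute-force
scan over all offsets and anchors is kept in the tests as the oracle.

Candidate enumeration, ranking and selection are deterministic:
windows → GC/Tm filter → de-duplication by sequence → specificity →
coverage → selection. Selection is greedy: the top candidate by
(coverage desc, offset asc, sequence lex); thereafter the candidate
maximizing the minimum distance to already-chosen offsets (farthest-point
spread, so probes cover both conserved and variable regions), with
coverage/offset/sequence tie-breaks. An empty result is legitimate and
routes the cluster to the rescue stage.

## Rescue stage

Multi-member probe-less clusters: center-star multiple alignment — center =
member maximizing summed pairwise identity; others aligned to it by global
Needleman–Wunsch (match +1, mismatch −1, gap −2); merged under
once-a-gap-always-a-gap. The method is deliberately simple and
deterministic so each sub-step has an independent oracle; an external
aligner could be substituted behind the same contract. Consensus: per
column, the most frequent non-gap character (ties alphabetical) is emitted
if its frequency among non-gap characters reaches the column threshold
(default 0.9, i.e. "consensus at 90 %"), else N; columns that are majority
gap are dropped. Tiling: windows at offsets 0, step, 2·step, … (default
step = probe length, i.e. end-to-end) plus a 3'-anchored terminal window.
Windows containing N are discarded — probes must be synthesizable — and
survivors face the same GC/Tm filter, possibly with a user-relaxed
rescue parameter set. Singletons skip alignment and are tiled directly.

A practical consequence worth knowing: at column threshold 0.9, clusters
with many moderately diverged members produce N-dense consensi, so few
50-mer windows survive. That is intended behavior (ambiguity should not be
synthesized), and it is why relaxing the rescue parameters, not the
consensus threshold, is the recommended lever.

## Thermodynamics

Nearest-neighbor Tm uses the unified dinucleotide ΔH/ΔS parameter set with
terminal initiation terms, the monovalent-salt entropy correction
0.368·(N−1)·ln[Na⁺], and Tm = 1000·ΔH/(ΔS + R·ln(C_T/4)) − 273.15
(R = 1.9872 cal mol⁻¹ K⁻¹; self-complementary oligos get ΔS −= 1.4 and C_T
instead of C_T/4). Defaults: 50 mM Na⁺, 0.25 µM total oligo. The
implementation is a cumulative-sum walk over the stack table so that all
windows of a sequence are scored in one vectorized pass; it is verified
against two independent implementations (a per-dinucleotide loop written
from the published table, and Biopython's `Tm_NN` with the same table and
salt correction) to within 0.01 °C. The GC-rule formula
64.9 + 41·(GC − 16.4)/N is retained as a fast alternative. The
nearest-neighbor method is the default because, for 50-mers, a 55–65 °C
window is only consistent with a thermodynamic model (the GC rule maps
that window to implausibly low GC); the method in force is recorded in the
run manifest. GC and Tm bounds are inclusive on both ends.

## Synthesis cycles

Cost model: cyclic single-base delivery in a fixed order (default A, C, G,
T repeating); each coupled base waits for its next delivery round; the
cost is the 1-based index of the last round used. Bounds length ≤ cycles ≤
4·length hold by construction and are asserted over random probes.
`synthesis_cycles` consumes its argument in coupling order;
`probe_cycles` reverses the conventional 5'→3' probe string first because
array synthesis couples 3'→5' (the direction is a flag, and the convention
is recorded in the run manifest, since platforms differ on whether the
probe or its synthesis-strand complement is counted).

## Synthetic data

The generator plants gene families: each family draws an independent
random ancestor (optionally GC-biased) and derives members by per-site
substitution (uniform different base) and rare 1–3-base indels. Record ids
are assigned after shuffling so they encode nothing about membership; the
truth map is returned separately. Defaults — 10 families × 20 members,
1 kb ancestors, 3 % divergence, indel rate 10⁻³, balanced GC — model a
moderately diverged family collection in which a 0.9 clustering threshold
should recover the planted partition exactly (between-family identity for
same-length random sequences sits near 0.65 under the free-gap measure,
far below threshold). The GC-skewed preset (bias 0.8) exists to force
primary-filter failure and exercise the rescue stage; mixed datasets add
skewed singletons so the direct-tiling path is always exercised too.

What passing on synthetic data does **not** show: real gene families are
not star phylogenies with i.i.d. substitutions; real inputs contain
fragments, chimeras and annotation noise; and between-family identity in
real data can sit near the clustering threshold, where greedy clustering
is order-sensitive. The probe-level guarantees (specificity against the
input, filter compliance, determinism, cost bounds) are input-agnostic;
the clustering-recovery results are statements about the generator's
regime.

## Problem sizes and degenerate inputs

The bundled end-to-end benchmark uses 1,000 sequences (50 families × 20
members, 600 nt) and completes in well under a minute on one CPU; the
alignment and DP kernels are JIT-compiled (numba). Degenerate inputs are
defined, not special-cased: empty record list after the length filter is a
hard pipeline error; a sequence shorter than the probe length contributes
no windows; tiling a sequence shorter than the probe returns nothing; a
cluster can legitimately end with zero probes in both stages and is then
visible in the run-2 summary histogram at count 0. N bases are accepted on
input, matched exactly (never wildcarded) during seed matching, and
excluded from every emitted probe.
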