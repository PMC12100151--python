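# Methods

## The assay model

`tandemtally` models a surrogate assay for tandem-array instability: the
array under study (by default two head-to-tail copies of a 2 kb unit, the
scale of the yeast *CUP1* repeat) is cloned on a centromeric plasmid that
replicates like a miniature chromosome. After growth, plasmid DNA is
linearized at a single restriction site in the vector (PmlI by default), so
each molecule becomes

```
left arm (L) + unit × k + right arm (R)
```

with arm lengths independent of the copy number *k*. Long reads that span
the whole molecule report *k* for one molecule each; the distribution of *k*
over reads is the array-length distribution, and contraction/expansion
frequencies are its tail masses. Two purification protocols are represented
compositionally: the first sequences everything (target plasmid plus
2-micron plasmid, rDNA/mtDNA fragments); the second removes linear
background molecules — modelled simply as filtering linear entries from the
background pool, the computational consequence of linearizing the 2-micron
plasmid (BsoBI + SphI) and degrading linear DNA with exonuclease V.

Assumptions: molecules are independent; the linearization site is unique in
the vector and absent from the unit (validated at construction); the unit is
not internally repetitive at the seeding k-mer scale; reads are single
molecules (no chimeras).

## Target-read selection

Anchors are the innermost `anchor_len` bases of each arm (default 500),
adjacent to the array, so the inter-anchor interval tightly bounds the array
region. Each anchor is located by exact 15-mer seeding, clustering of seeds
by diagonal (offset = read position − arm position; gap threshold =
`band_width`, default 100), and verification of the best clusters with
edlib infix alignment inside the seeded window. Identity is defined as
matches / alignment columns with indels counted as non-matches; a hit
requires identity ≥ `min_identity` (default 0.80). Tie-breaks are
deterministic: higher score (matches − edits), then leftmost, then forward
strand.

A read is **target** iff both anchors are found on the same strand in
template order (canonicalizing reverse-strand reads); one anchor or
inconsistent geometry ⇒ **non-target**; overlapping anchors ⇒ **ambiguous**
(excluded from copy statistics by default). Requiring both anchors is the
clipping defence: a truncated molecule loses an anchor and drops out of
selection instead of contributing a short count.

## Unit counting

Within the inter-anchor region (± one `band_width` of slack, default 150)
the unit is seeded and clustered the same way; clusters recur at the unit
period. Each candidate is verified by edlib alignment of the portion of the
unit expected inside the region; the alignment window is floored at the end
of the previous hit, since template copies abut exactly — this prevents
1–2 base boundary jitter from manufacturing overlaps between adjacent
copies. A placement is **accepted** at identity ≥ 0.80 and unit span ≥ 0.90
(`min_span_frac`); placements spanning ≥ 0.30 (`partial_span_frac`) but
< 0.90 are **partial**. The copy number is the size of the largest set of
pairwise non-overlapping accepted hits, computed by exact interval
scheduling with ties broken by total score then leftmost placement; hits are
few per read, so the exact optimum is as cheap as a greedy pass and, unlike
greedy, provably matches exhaustive enumeration, including the case of one
high-scoring hit straddling two genuine copies. Reads with any partial hit
are flagged `has_partial` and excluded from the headline distribution by
default — a broken or rearranged unit should be visible, not silently
counted as a shorter array.

`oracle_scan` is a deliberately independent reference: iterated best local
alignment (Biopython `PairwiseAligner`, BLAST-like scores 2/−3/−5/−2) with
masking of each accepted hit, no seeding heuristics. It shares no code path
with the scanner and is used only in tests and the acceptance script.

## Simulator

The simulator emulates sequencing of the linearized pool, not the
sequencer: per-base substitution/insertion/deletion errors (defaults
0.01/0.005/0.01, a crude stand-in for current nanopore chemistry with
high-accuracy basecalling; flat Phred 20 qualities), optional end clipping
(each end independently truncated with probability `clip_prob` by a
geometric length, default mean 300 bases — clipping precedes errors, as
truncated capture precedes the error process), uniform strand, and a
background pool. The default copy mixture is {1: 7.32%, 2: 92.32%,
3: 0.36%}, the contraction/expansion frequencies observed for a
yeast-passaged two-unit array; the default background molecules are
synthetic surrogates with the right architecture (a circular 6.3 kb
2-micron-like plasmid carrying BsoBI/SphI sites but no PmlI site; linear
9.1 kb rDNA-like and 7.5 kb mtDNA-like fragments). One master seed governs
everything; the stream for read *i* is derived from `(seed, i)` so read *i*
is identical regardless of the total read count.

What the simulator does **not** model: signal-level errors, homopolymer
bias, chimeric reads, length-dependent capture, or quality-score structure.
Passing tests therefore demonstrate the correctness of the selection and
counting logic under realistic error magnitudes, not calibrated performance
on any particular flowcell.

All construct sequences shipped with the package are synthetic: no public
sequence exists for the real construct, so `constructs.py` generates
deterministic random sequences with the correct architecture (unique
linearization site in the vector, site-free unit, junction-safe assembly
verified for 0–6 copies).

## Statistics and reporting

Per replicate, proportions of each copy number are computed over clean
target reads; percentages are 100 × proportions. The unit of analysis for
group comparison is the per-replicate percentage, compared with Welch's
unequal-variance t-test (Welch–Satterthwaite df); with 2–6 replicates per
group, the unequal-variance form is the robust default, and a degenerate
comparison (both groups constant and equal) reports t = 0, p = 1. No
multiple-testing correction is applied — the report makes single pairwise
comparisons. Enrichment mass is total DNA mass × target read fraction
(valid when target and background molecules have similar lengths); its
display value is *truncated*, not rounded, to 3 decimals (1.73 × 0.056 →
0.096), and protocol comparisons chain from the displayed values, matching
how such figures are quoted. Full precision is retained internally.

Coverage tracks accumulate read placements projected from the anchor/unit
hits onto a chosen reference template (two-copy by default) — a reuse of
existing evidence for sanity plots, not an independent mapping. Both
mean-per-base and total-aligned-bases normalizations are available (mean is
the default); bedGraph output merges equal-value runs and round-trips
exactly.

## Problem sizes and numerical choices

The test-suite and acceptance-script scales are: 1,000 reads for the
zero-error exactness check; 10,000 reads for mixture recovery at 2.5% total
error with moderate clipping; 3,000 reads for selection-fraction recovery at
40% target molecules; 200 reads (copy numbers 0–5, total error 0–5%) for
scanner-vs-oracle agreement. The oracle comparison runs on a miniature
construct (1.4 kb vector, 250 bp unit, 150 bp anchors) because the oracle is
deliberately quadratic; the check is algorithmic and scale-free, so the
miniature preserves its meaning while keeping the run to seconds. Stochastic
recovery checks use 3-standard-error binomial bands around the simulated
truth.

Degenerate inputs: empty regions count zero units; reads shorter than the
k-mer yield no anchors (not an error); an all-zero coverage track refuses
normalization; a zero reference mass refuses a yield-reduction ratio.

## Limitations

- Thresholds (identity 0.80, span 0.90/0.30, anchor length 500) are design
  choices exposed in config, not values fitted to data.
- Concatemeric reads (two plasmid molecules ligated in one read) fall into
  `ambiguous` rather than being resolved.
- Inverted or rearranged units appear as `partial` hits; the package flags
  them but does not reconstruct the rearrangement.
- The enrichment-mass estimate inherits the similar-fragment-length
  assumption; pools with very different background lengths would need a
  length-weighted correction.
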