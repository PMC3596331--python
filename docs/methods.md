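# Methods

## RING-finger model

A C3HC4 RING finger is modelled purely positionally: eight metal-ligand
positions with residues C,C,C,H,C,C,C,C and spacing constraints, no
profile or structure scoring. "n residues between ligands i and j" is
counted *strictly between* the two positions, with intervening ligands
included — so the 7 residues between ligands 3 and 6 include ligands 4
and 5. This is the only reading consistent with the canonical C3HC4
sub-spacings (C-x(1–3)-H-x(2–3)-C-x-C): with 1 residue before the His and
2 after it, 1 + 1 + 2 + 1 + 2 = 7. The family constants are
`d12 = d78 = 2`, `d23 = 11`, `d36 = 7`; `d67` ranges over [11, 24].

The scanner (`ring_domain.scan_ring`) enumerates candidate 8-tuples by
walking Cys anchors left to right and expanding the admissible sub-spacing
and `d67` windows, then resolves overlaps greedily by (start, end) —
leftmost first, shorter domain on ties. A brute-force test oracle
enumerates *all* position 8-tuples independently and must agree on every
sequence up to 120 residues.

Two strictness levels: `strict` additionally requires the family-wide
signature residues (Pro after ligand 7, Arg after ligand 8, Val/Ile
before ligand 2); `signature-tolerant` records them as flags without
vetoing, so rare family members that break one signature are still found
but flagged.

Group assignment is a decision list: `d67 = 11` → III; `d67 ∈ {19, 20}` →
I; `d67 = 24` → II; `d67 ∈ 21–23` (the I/II window overlap) is resolved by
the before-ligand-8 residue (Leu → I, Phe → II); anything else →
`unassigned` with a rule trace listing the tests applied. The
before-ligand-8 residue is used as tie-breaker because it is the only
signature position that differs across all three groups.

## ANK repeat detection

Detection is consensus scoring, not an HMM: each 33-residue window is
scored column-wise against a packaged 33-residue ankyrin consensus
(idealised-repeat style, cysteine-free by design) with BLOSUM62. Candidate
windows at or above the threshold are accepted greedily by descending
score (ties leftmost), discarding overlaps. Greedy resolution was chosen
over dynamic programming for transparency; the generator-ground-truth
tests guard its correctness.

Threshold units are BLOSUM62 half-bits summed over 33 columns. The
consensus self-score is 168; repeats carrying 4 random point mutations
still score ≳ 130, while the best window in 1000 random 400-residue
sequences scores ~30. The default threshold 80 sits in the wide gap
between those distributions; `calibrate_threshold` re-derives a threshold
for any target false-positive rate (smallest threshold whose empirical
FPR on negative sequences, scored by their maximum window, is at or below
target).

Repeat counts 2–7 map to classes A–F. Membership itself does not cap the
count: a protein with 8+ repeats and a valid RING is still a member,
merely `unclassified` for A–F. There is no inter-repeat gap constraint and
no requirement that repeats precede the RING.

## Membership and report

XB3-like ⇔ at least 2 accepted ANK repeats and at least one accepted
C3HC4 RING. When several RINGs are accepted the leftmost classifies the
protein; all are retained. Per-record failures are logged and skipped so
one malformed protein never aborts a proteome run. The TSV report is
byte-deterministic for a given input and configuration (a config hash is
written in the provenance comment).

Molecular weight is the sum of packaged average residue masses plus one
water (18.0153 Da). The isoelectric point is the unique root of the net
charge — a Henderson–Hasselbalch sum over the termini and D, E, C, Y, H,
K, R side chains with the Bjellqvist pK set (the table behind the common
pI/MW web calculators; packaged as a versioned data file) — found by
bisection on [0, 14] to 1e-4 pH, comfortably beyond the 2-decimal
precision pI values are conventionally reported at. Net charge is
strictly decreasing in pH, so the root is unique.

## Phylogeny

Inputs are already-aligned FASTA; alignment heuristics are deliberately
not reimplemented. Complete deletion drops any column with a gap in any
row (erroring if nothing survives — pairwise deletion is unsupported).
p-distance is the raw fraction of differing sites. Neighbour joining uses
the standard Saitou–Nei Q-criterion with two documented conventions:
Q-ties resolve to the lowest index pair (determinism), and negative
branch lengths are clamped to zero with the deficit moved to the sibling
edge so the joined pair's path length is preserved. On additive matrices
the output reproduces the generating tree's topology and path lengths to
1e-9.

Bootstrap resamples alignment columns with replacement, reruns the whole
complete-deletion → p-distance → NJ chain per replicate, and reports, for
each internal bipartition of the full-data tree, the percentage of
replicates containing it. Supports are stored as internal node labels;
Newick output carries 6-decimal branch lengths. Topology recovery between
two trees is the fraction of the true tree's internal bipartitions present
in the inferred tree (1.0 = identical unrooted topology).

## qPCR expression

ΔCt is computed per replicate against the mean of the declared reference
genes in the same condition and replicate; relative expression is
2^(−ΔCt), i.e. 100% amplification efficiency is assumed throughout. Fold
change between conditions is computed from mean ΔCt (not per-replicate
ratios averaged — the alternative convention — because the mean-ΔCt form
is the direct two-sample contrast the t-test uses). Significance is the
classic two-sample, two-sided Student t on replicate ΔCt values, without
Welch correction. No multiple-testing adjustment is applied by default;
Benjamini–Hochberg can be switched on for the call decision (reported
p-values stay raw).

Calls: up/down at >1.2-fold with P < 0.05 for treatments; a tissue is
preferential only when it beats *every* other tissue at >2-fold with
P < 0.05 — the strictest reading of "compared to other tissues", and one
that makes the winner provably unique. Zero-variance replicate sets
(possible only in noise-free synthetic data) get the limiting p-value
(0 for unequal means, 1 for equal) instead of an undefined t statistic.

## Synthetic data: what it emulates and what it does not

`make_member` concatenates: random N-flank (default 30 aa), n tandem
copies of the ANK consensus with a configurable number of point mutations
each, a random linker (20 aa), a RING region built from the chosen
group's rules (sub-spacings 1/2/2 around the His and ligand 5, `d67`
drawn from the group window unless fixed), and a C-flank. Filler inside
the RING region excludes Cys and His so the embedded ligand set is
unambiguous; flanks are unrestricted, so decoy Cys/His in flanks remain
legitimate hard cases. Background composition is uniform over the 20
residues — no claim of realistic proteome composition is made. Decoys
cover the four failure modes the membership rule must reject: RING
without repeats, a single repeat, a C3H2C3 (His-at-ligand-5) near-miss,
and a shuffled member.

`make_family` evolves the root sequence down a given tree with per-site
substitution probability 1 − exp(−rate·branch length), uniform over the
19 alternative residues, and no indels — alignments are exact by
construction, which is precisely what makes tree-recovery ground truth
checkable, but means gap handling is only exercised by explicit gapped
fixtures, not by the evolver.

`make_ct_table` holds reference genes at Ct 20 and targets at
20 + 5 − (log2 effect), adding Gaussian replicate noise (default σ = 0.1
cycles, a typical technical-replicate spread). Because all genes on one
simulated plate share the same reference-gene measurements, their tests
are correlated; null-calibration checks therefore average over many
independent simulated plates (200 plates × 10 genes for the 2000-gene
type-I check). PCR efficiency variation, pipetting outliers and
plate effects are not modelled.

Consequently, passing tests demonstrate that the scanners, classifiers
and statistics implement their rules exactly and recover programmed
ground truth under clean conditions — not that detection thresholds match
any external curated-profile scan on real proteomes, nor that real
qPCR data meet the t-test's assumptions.

## Problem sizes and determinism

Default test problem sizes — 120-residue sequences for the brute-force
RING oracle, 3 groups × 50 seeds for classification accuracy, repeat
counts 2–7 × 25 seeds for ANK recovery, 6–8 taxon trees with ≤ 200
bootstrap replicates, 2000 null genes — keep the whole suite and the
acceptance script in the tens of seconds on one CPU while leaving each
check statistically meaningful. All randomness flows through
`numpy.random.default_rng` seeds; every generator is a pure function of
(spec, seed).

## Known limitations

- Modified RING subtypes (RING-V/D/S-T/G/C2, C3H2C3) are rejected, not
  classified.
- The ANK consensus is a single fixed 33-mer; divergent repeats that a
  profile HMM would catch can fall below threshold, and repeat boundaries
  are never refined away from the 33-column frame.
- NJ only; no model-based distances (Poisson, JTT) or likelihood trees.
- Expression analysis assumes perfect doubling per cycle and equal
  replicate counts per gene × condition.
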