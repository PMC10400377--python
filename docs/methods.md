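# Methods

## Model

`pualign` treats a flexible structural alignment as a set of rigid
sub-alignments. One chain (the *peeled* chain) is decomposed into contiguous
Protein Units (PUs); each PU receives its own rotation + translation onto the
other chain (the *target*), under the constraint that no target residue is
used by more than one PU. The assumptions this encodes:

- conserved structure is rearranged, duplicated or hinged at the level of
  compact fragments, so PUs are the right rigid bodies;
- within one PU the residue correspondence is sequential (order-preserving);
  non-sequentiality — circular permutations in particular — arises only from
  the order in which whole PUs land on the target;
- alignment quality is measured by the TM-score normalized by the shorter
  chain, with every residue pair evaluated under its own PU's transform
  (a "flexible TM").

Because which chain is peeled matters (peeling the shorter chain of a
permuted pair often fails while peeling the longer one succeeds), the
procedure always runs in both directions and keeps the better score; the
per-level difference between directions is reported as `swap_delta`.

## Peeling

Contact probabilities are a logistic transform of Cα distances,
p(i,j) = σ((d0_contact − d_ij)/slope). The literature this construction comes
from does not fix the constants in print, so we default to
**d0_contact = 8.0 Å** (a conventional Cα contact midpoint) and
**slope = 1.5 Å**; both are CLI-configurable. The diagonal is set to 1 by
convention.

The partition index of a split A|B is PI = 1 − K(A,B)²/(K(A,A)·K(B,B)) with
K the block sum of contact probabilities (for 3-way splits, the minimum
pairwise PI). This normalized squared-cross-contact form is our documented
substitute for the unprinted criterion of the original peeling method; it is
1 for perfectly contact-disjoint sub-units and 0 when cross contacts are as
dense as internal ones. Block sums use an integral image, so a full cut scan
is O(N) for 2-way and O(N²) for 3-way splits.

Splitting is greedy top-down: at each step the unit × cut combination with
the highest PI is applied (3-way attempted only when the parent is ≥
3·min_pu_size and the unit budget allows; ties prefer 2-way, then the cut
nearest the unit midpoint). Splitting stops at **max_units = 7**, or when the
best available PI falls below **pi_min = 0.2** — our stop-rule stand-in for
the original method's statistical dissection criterion. **min_pu_size = 15**
residues: smaller fragments carry too little shape to align rigidly with any
confidence.

Exploration levels map to admitted PU counts {2,3}, {4,5}, {6}, {7}. If
peeling stalls before the requested count, the deepest partition is used with
a warning. A count can also be jumped over by a 3-way split (e.g. 5 → 7); in
that case the level simply contributes no candidates, which is harmless
because reporting is cumulative over levels 1..n.

## Inner rigid aligner

Each PU is fitted to the unconsumed target by an iterative
threading/DP/Kabsch scheme (the published experiments used an external rigid
aligner for this step; ours keeps the repository self-contained, at the price
of not being bit-comparable to published scores):

1. **Seeds.** Gapless threading of the PU over contiguous unmasked target
   windows plus 8-residue fragment seeds; every window is scored by Kabsch
   RMSD and the best-fitting windows are kept together with a strided
   coverage subset. Keeping the lowest-RMSD windows is what catches exact
   registers in periodic structures (helices), where a 3–4 residue register
   shift is a strong local optimum.
2. **Refinement.** Alternate (a) affine-gap dynamic programming between the
   transformed PU and the target with pair score 1/(1+(d_ij/d0_dp)²), where
   d0_dp is the TM d0 of min(PU length, unmasked count) floored at 0.5 Å, and
   (b) Kabsch re-superposition on the matched pairs; stop when the local TM
   stops improving (≤ 30 iterations). Gap penalties are open 0.6 / extend
   0.05 in pair-score units; end gaps are free. Masked target columns cannot
   be matched and cost nothing to skip, so one PU may bridge across a region
   consumed by another.
3. The best seed's result wins (ties to the earliest seed). Fewer than
   min_pu_size unmasked target residues ⇒ an empty result (local TM 0),
   which tells the order explorer the branch is dead.

The DP recurrence is jit-compiled (numba); everything else is numpy.

## Order exploration

All |PUs|! orders are searched depth-first. Alignments are memoized on
(PU id, exact target mask), so orders sharing a prefix reuse work. The prune
bound assumes every remaining PU residue could land at distance 0
(min(remaining residues, unmasked residues) / L_norm extra TM); it is
admissible, so pruned search provably returns the enumeration optimum — the
test suite checks equality against a plain enumeration oracle. Ties keep the
first completed strategy in lexicographic PU-id order, making results
deterministic. The pipeline contains no randomness anywhere; only the
synthetic generators take seeds.

## Scoring

d0(L) = 1.24(L−15)^⅓ − 1.8, clamped to ≥ 0.5 Å (the clamp engages for
L ≤ 21). The single-transform TM optimizer used for rigid baselines and
final polishing seeds on mapping fragments of lengths {L, L/2, L/4, 4} and
refines by distance-cutoff re-superposition (keep pairs with d < d0·f,
f ∈ {1, 1.5, 2, 3, 4}); the all-pair Kabsch fit is among the candidates, so
its TM is a guaranteed lower bound. Reference-alignment agreement counts
exact residue pairs (a ±k shift tolerance is available but off by default,
since benchmark conventions differ on this).

## Synthetic fixtures

Generators produce single-chain Cα traces with exact ground truth:

- *globule*: a 3.8 Å-step random walk biased back inside a radius
  ∝ n^⅓ — compact, contact-rich, peelable;
- *two_domain*: two globules joined end to end with centroids ≥ 16 Å apart
  (twice the contact midpoint) so the junction is the natural first cut;
- *circular_permutation*: halves swapped, independently re-oriented,
  re-joined at one Cα step; ground truth is the index permutation;
- *hinge_bend*: residues past the hinge rotated about an axis through the
  hinge Cα (both parts stay internally rigid, chain stays connected);
- *insertion* and *repeat* variants for the remaining difficulty classes.

Default coordinate noise is **0.3 Å** — well under d0, so ground truth
remains the optimum and recovery failures indicate algorithmic, not
statistical, error. What these fixtures do *not* emulate: real secondary
structure packing, sequence-dependent geometry, excluded volume, or the
partial conservation of genuine homologs. Passing the recovery suite
therefore demonstrates the machinery (peeling finds the junctions, the
explorer finds the permutation, transforms are recovered), not benchmark
performance on curated datasets, which additionally depends on the inner
aligner's behaviour on approximate matches.

Problem sizes in the test and acceptance runs — 80-residue chains (two
40-residue domains), exploration levels 1–2, 3–6 replicate fixtures per
family — were chosen as the smallest sizes at which every structural event
(two domains, a permutation point, a hinge) is unambiguous at
min_pu_size = 15.

## Degenerate inputs and numerical choices

- Chains shorter than 2·min_pu_size cannot be peeled: the aligner falls back
  to a single rigid alignment with a warning (only one side needs to be
  peelable for the full procedure to run in that direction).
- Kabsch on near-collinear point sets keeps the SVD sign correction and
  flags the transform `degenerate`.
- Strict-improvement comparisons use a 1e-12 epsilon so that floating-point
  ties fall to the deterministic tie-break.
- PDB output rounds to the format's 3-decimal precision; round-trip tests
  allow 1.5e-3 Å.

## Known limitations

- Single chains only; no multi-chain assemblies.
- The inner aligner is order-preserving within a PU, so non-sequentiality
  finer than the PU decomposition is invisible.
- PUs come from one peeling level at a time; units from different levels are
  never mixed within one strategy.
- Published benchmark numbers for this family of methods were obtained with
  a different (external) inner rigid aligner; scores here are comparable in
  kind but not bit-identical.
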