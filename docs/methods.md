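# Methods

## Model and assumptions

`ismkit` implements classical interpretive structural modeling over a
finite factor set 1..n. The object of study is a binary "leads to"
relation elicited from experts; the method assumes (i) the relation is
meaningful as a reachability statement, so transitivity may be imposed,
(ii) every factor reaches itself (diagonal fixed to 1), and (iii) the
expert panel is exchangeable — judgments are aggregated per pair with no
expert weighting.

The pipeline is: ratify the factor roster from inclusion votes → aggregate
per-expert V/A/X/O pair judgments into one SSIM → decode to the initial
reachability matrix → apply transitivity → compute driving/dependence
powers → partition into levels → conical matrix and level-layered digraph
→ MICMAC quadrants and net influence.

## Aggregation semantics

"Majority rule" is under-determined for a four-symbol alphabet, so
aggregation is plurality-wins, annotated per pair as *absolute* (count >
E/2), *plurality*, or *tie*. Ties are always flagged and resolved by a
configurable policy; the default priority order X > V > A > O prefers any
asserted relation over "no relation" and the mutual relation over the
directional ones. Ratification includes a factor iff yes votes exceed no
votes; the tie policy defaults to *include*, matching how expert panels in
this literature typically resolve a split vote by deliberation.

## Transitivity modes

Three explicit modes, never mixed silently:

- `full` — reflexive-transitive closure by Warshall's algorithm
  (O(n³) boolean updates); the default for new analyses because level
  partitioning is only guaranteed to terminate on a closed matrix.
- `one_pass` — adds exactly the length-2 compositions (M ∨ M·M), the
  single sweep most hand-worked studies perform.
- `as_given` — trusts a supplied final matrix verbatim.

Cells added by closure are marked transitive (`1*` in CSV); direct cells
are never downgraded, so elicited provenance survives every mode.

The packaged case study ships its published final matrix `as_given`
because that matrix is *not* reproducible by closure: it contains one cell,
(7,1), with no supporting length-2 path in the initial matrix, and the full
closure of the initial matrix is strictly larger (it flattens the model
from four levels to two, with factor 1 alone at the bottom).
`audit_closure_consistency` quantifies both discrepancies and reports the
level structure under every mode side by side; published data are
documented, never corrected.

## Level partitioning and degenerate inputs

Each iteration computes, within the remaining factors, reachability,
antecedent and intersection sets per factor and removes those with
reachability = intersection (the current top elements). On a transitively
closed matrix every iteration removes at least one SCC, so the loop ends
in ≤ n iterations; on a non-closed matrix it can stall, in which case a
`StallError` names the unleveled residual rather than looping forever.
Iteration order is ascending factor code everywhere; the engine contains
no randomness.

The conical matrix orders factors by (level ascending, code ascending).
The model digraph condenses SCCs (transitive reduction is ill-defined on
cyclic graphs), transitively reduces the condensation via networkx, and
keeps intra-SCC mutual pairs as bidirectional decorations. The pipeline
builds the digraph from the *direct* (initial) relation when one is
available: closure cells merge whole levels into one SCC and would erase
the layered structure. An SCC that straddles partition levels — possible
on as-given data — is ranked at its topmost member's level.

## MICMAC

Quadrants follow the scale-centric convention: boundary n/2, "high" means
strictly greater. For the case study (n = 11, boundary 5.5) this
reproduces all published labels; (n+1)/2 would too, and the boundary is
configurable for users who prefer it. Net influence is driving −
dependence; the published summary's "effectiveness" column is never
defined in words by its source, but equals this difference in all 11 rows,
so the toolkit computes it as such. Since Σ driving = Σ dependence for any
square matrix, net influences always sum to zero — a conservation check
the tests assert. The "key factor" flag marks every deepest-level factor
classified independent (the case study has exactly one; the flag
generalizes to several).

## Synthetic data generator

`generate_hierarchy` draws a ground-truthed study: n factors over L
non-empty levels (defaults n = 11, L = 4, E = 10 experts, mirroring the
case study's scale); every factor below the top gets one direct edge to
the level above, guaranteeing the recorded strata; extra cross-level edges
appear with probability 0.25 and within-level adjacent mutual pairs with
probability 0.2 (modest values that keep generated SSIMs sparse, like
elicited ones). Ground-truth levels are *defined* as the
longest-path-to-sink strata of the SCC condensation — exactly what level
partitioning computes on a closed matrix — so noise-free end-to-end
recovery is a theorem the tests verify, not a tuned outcome. Expert noise
is symmetric symbol replacement: the true symbol with probability p, else
one of the three wrong symbols uniformly; simple and analytically
comparable to the binomial plurality bound. The generator does not model
expert bias, correlated errors, or systematic over-assertion of relations,
so recovery results say nothing about panels with shared blind spots.

All generators are deterministic given the spec seed;
`recovery_experiment` derives per-replicate seeds from it.

## Problem sizes and numerical choices

Everything is exact integer/boolean arithmetic; there are no tolerances.
Property tests run closures and partitions against independent oracles
(boolean matrix powers, networkx closure, condensation longest-path
strata) on random matrices up to n = 8, 100–200 cases each, and the
recovery experiments use n ≤ 8 with 40–100 replicates — sizes at which the
brute-force oracles are instant while still exercising every structural
case (cycles, multi-SCC levels, stalls). The case-study matrices are 11×11
and run in milliseconds.

## Known limitations

- Classical binary ISM only: no fuzzy or total-ISM variants, no DEMATEL,
  no weighted relations, and MICMAC uses direct powers, not Godet's
  iterated-multiplication ranking.
- Aggregation assumes a complete judgment triangle per expert; missing
  judgments are rejected, not imputed.
- The level structure of as-given matrices is taken at face value; if such
  a matrix is not closed and stalls, the user must choose a closure mode —
  the toolkit will not choose silently.
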