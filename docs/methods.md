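# Methods

## Input model and assumptions

The pipeline consumes a residue × mutant matrix of combined ¹H-¹³C
methyl chemical-shift perturbations (CSPs, Hz).  Each column is one
conservative point mutant measured against the same wildtype reference
under identical conditions; each row is one methyl group, with
stereo-specific pairs (Leu δ1/δ2, Val γ1/γ2) kept as separate
observables.  Three data conventions matter downstream:

- **Combined shift.**  Δν = √((Δδ_H·f)² + (Δδ_C·f·r)²) with
  r = 188.8/750, so that at a 750 MHz spectrometer the carbon term uses
  the conventional 188.8 Hz/ppm; other fields scale linearly.
- **Masking, not zero-filling.**  A peak missing in either spectrum
  (overlap, unassigned, exchange-broadened) is a *missing observation*;
  writing 0 would fabricate a "no perturbation" measurement.  The
  mutated residue's own methyls are likewise masked in that mutant's
  column: their shifts reflect the covalent change, not network
  propagation.
- **Common residue set.**  By default the matrix is restricted to
  methyls observed in the wildtype and every mutant, mirroring the
  common-set convention used when several protein states are compared
  (a union-with-mask mode exists for exploratory work).

The statistical model assumes only that perturbations co-vary
monotonically along communication pathways.  Ranking within each
residue row removes the (large, local) magnitude scale near each
mutation site and damps measurement error; all downstream statistics
are rank-based.

## Pairwise statistics

Spearman correlations are computed as Pearson correlations of rank
rows over the mutants jointly observed by each pair; significance uses
t = R√((n−2)/(1−R²)) with df = n−2, two-sided, *uncorrected* — the
network stage is designed to tolerate a calibrated false-positive rate
rather than maximize per-pair purity.  Pairs with fewer than
`min_overlap` (default 10) joint observations are dropped: below ~10
points the t-test is unstable and a single outlying mutant can
dominate.

At n = 20 mutants the t approximation to the discrete Spearman null
passes p < 0.02 at a measured rate of ≈ 0.0214 rather than 0.0200.
This +0.0014 excess is a property of the approximation itself (scipy's
`spearmanr` produces identical p-values) and is well inside the
binomial uncertainty of a 3003-pair experiment
(3·SE ≈ 0.0077); exact permutation nulls would remove it at
considerable cost and are not used.

Soft-thresholding maps correlations to weights max(R, 0)^β.  β = 8 is
the fixed default, chosen so weak/noisy links decay smoothly to zero
while strong links survive — negative correlations carry no flow.  An
opt-in scale-free criterion (smallest β whose binned log-log degree
distribution fits a line with R² ≥ 0.8) is provided; binning is
equal-width over the connectivity range, since equal-count bins make
the binned frequency constant by construction and the fit undefined.

## Mediation and directionality

An ordered triple A→B→C is accepted as a communication path when

1. p(R_AB) < p_cutoff and R_AB > 0,
2. p(ρ_bc) < p_cutoff and ρ_bc > 0, where ρ_bc is the partial
   correlation of B and C given A — identical to the coefficient t-test
   of B in the regression of C's ranks on A's and B's (df = n−3),
3. ρ_ac < R_AC with R_AC > 0 (the direct effect shrinks when B is
   accounted for), and
4. the path strength, the mediated effect R_AB·ρ_bc, is then in (0, 1].

R_AB, R_AC and p(R_AB) come from the pairwise-complete correlation set;
the partial correlations are recomputed on the triple's jointly
observed mutants.  The positivity filter is applied to R_AB, ρ_bc and
R_AC — the three quantities that enter the criteria and the weights.
Degenerate triples are handled deterministically: |R_AB| = 1 makes the
predictors collinear and the triple is skipped; if one predictor
explains C perfectly (|r| = 1) the other's partial correlation is 0 by
convention.  Ordered triples are evaluated in both directions, since
flow is directional in the memory network.  Enumeration is vectorized
per ordered significant pair over all candidate C's (exact, not
approximate: all moments are accumulated on the triple-joint masks) and
is deterministic given the input matrix.

Default significance cutoffs are state-specific (0.02 inactive apo,
0.03 ATP-bound, 0.03 BIRB796-bound, 0.04 active), chosen for enrichment
in positive correlations; they are ordinary parameters and can be
overridden.

## Second-order memory network

Memory nodes are ordered residue pairs; the edge (A,B) → (B,C) carries
the mediated effect of the triple.  The stationary distribution of the
teleported walk is computed by power iteration,

p ← (1−τ)(p·W_row + dangling mass · t) + τ·t,

where t is the teleport distribution ∝ soft-thresholded pair
correlation of each state's residue pair (normalized; uniform fallback
if all weights vanish), and dangling states redistribute their mass
through t.  τ defaults to 0.15, the standard PageRank/Infomap
convention — the source experiments do not state a rate.  Convergence
is declared at L1 change < 1e−12; visit rates sum to 1 within 1e−10.

Teleporting onto *state nodes weighted by their pair correlation* is
the most direct reading of "two-point correlations as teleportation
probabilities"; a physical-node or uniform teleport would discard the
pair-strength information.

## Map equation and communities

The two-level map equation

L(M) = q·H(Q) + Σ_m (q_m + p_m)·H(P_m)   [bits, log₂]

is evaluated from the factorized flow decomposition: real link steps
(1−τ)·p_α·W_row plus restart steps p_α·(τ + (1−τ)·[α dangling]) landing
on t.  Two accountings are supported: `recorded` (default) counts
restart steps in the module exit flows, `unrecorded` counts only link
and dangling steps.  In both, a one-module partition reduces exactly to
the entropy of the visit distribution.

Optimization is a seeded multi-trial greedy search: from singleton
modules (even trials) or a random coarse partition (odd trials), sweep
the state nodes in random order moving each to the module that most
decreases L (O(degree) incremental evaluation; when ≤ 64 modules remain
every module is a candidate, so teleport-coupled groupings are
reachable), then greedily merge whole modules, repeating until no move
helps; the best partition across trials is kept, ties resolved by first
discovery and equal-codelength single moves by staying put — all of
which makes the result a deterministic function of the seed.  The
default trial count in the model facade is 100; on the tiny networks
used for validation the optimizer provably reaches the exhaustive
minimum (checked against full partition enumeration up to 7 states).
Very large trial counts buy little here: the greedy landscape on these
problem sizes is explored within tens of restarts.

Physical communities are the current residues of each module's state
nodes.  Because a residue's incoming flows may fall in several modules,
communities *overlap*; the non-overlapping "core" assignment (residue →
its highest-flow module) is used only for scoring against planted
truth.  Communities with more than `min_community_size` (default 5)
residues form the main report, smaller ones are listed separately;
inter-module flow sums the link flow crossing each module pair.

On second-order networks the map equation genuinely prefers
fine-grained path communities — mediated flow is confined to narrow
3-residue relays, so dozens of small overlapping modules on ~80
residues is the expected regime, not a failure of optimization (we
verified on study-scale synthetic data that the optimized fine
partition has substantially shorter codelength than the planted
two-block partition polished to a local optimum).

## Synthetic data: what it emulates, what it does not

`generate()` plants a weighted residue graph W (two lobes by default:
ring, clique or hub-and-spoke topology, joined by bridge residues
either in a chain or straddling the lobe hubs), normalizes it to unit
spectral radius, and models the noise-free response of residue j to a
mutation at site i as the resolvent kernel [(I−αW)⁻¹]_ij — the sum of
all damped walks from the mutation site, the simplest linear-response
model of perturbations decaying along a spatially structured network.
Responses are scaled to a realistic Hz range (strongest response
`hz_scale` = 60 Hz), multiplied by lognormal noise (σ = 0.3) and
overlaid with an additive measurement floor (σ = 1.5 Hz, matching the
~1 Hz smallest usable shift differences in practice); cells are masked
at the mutated site plus a random 5 % missing fraction.

Study-scale defaults (78 methyls × 20 mutants, decay α = 0.8, ring
lobes with 15 % extra edge density) yield a few hundred significant
pairs and a few thousand mediated triples at p < 0.02 — the same order
of magnitude as a real methyl-mutagenesis panel.  The additive floor is
essential: multiplicative noise alone cannot decorrelate the
decade-spanning diffusion responses, and without it virtually every
pair correlates.

Two designed validation scenarios are exposed:

- `two_lobe_scenario()`: two 10-residue *clique* lobes plus two bridge
  residues between the lobe hubs, full mutant panel, low noise
  (σ = 0.05, floor 0.1 Hz, no missingness).  Equicorrelated cliques
  drive every within-lobe partial correlation to ≈ r/(1+r), so at the
  small panel size a p < 0.1 cutoff is the appropriate setting; the
  resulting dense state graph makes each lobe a single flow module.
  Expected outcomes: core-assignment adjusted Rand ≥ 0.9 against the
  planted lobes and bridge residues appearing in both lobe communities.
- `chain_scenario()`: one strong 10-residue chain among 8 residues that
  feel only noise — a dominant planted pathway.  Expected outcome: the
  top 5 % of memory nodes by flow lie on the chain.

These scenarios are deliberately *easy*: they verify that the machinery
recovers structure that is recoverable.  Passing them does not imply
comparable accuracy on real spectra, where assignment errors, exchange
broadening, correlated missingness and non-monotone responses all
violate the generator's assumptions.

`subsample_mutants()` reruns the full pipeline on random k-column
subsets and scores the community core assignment against the full-panel
result (adjusted Rand over shared residues).  The joint-observation
floor is reduced alongside k (max(4, min(10, k−2))), as an analyst with
8 mutants would do; a single fit seed is shared so the k = full point
scores exactly 1.  On the 26-residue two-lobe panel the curve rises
from ≈ 0.15 at k = 8 to ≈ 1 by k = 20 — qualitatively, small panels
cannot reproduce the network and agreement saturates well before the
full panel, the robustness behaviour expected of the method.  The exact
panel size needed depends on the data's correlation strength.

## Numerical choices and degenerate inputs

- Logarithms base 2 throughout the map equation; 0·log 0 = 0.
- Rank ties averaged (standard Spearman fractional ranks) — with
  continuous shifts ties are rare and this keeps results deterministic.
- |R| = 1 ⇒ p = 0 by convention; zero-variance rank rows invalidate
  their pairs with a warning.
- Power iteration from the uniform vector; non-convergence raises with
  the residual (never observed at τ ≥ 0.05 on tested networks).
- Text outputs serialize floats with repr/%.17g and are read back with
  round-trip parsing, so write→read→write is byte-identical.
- Degenerate pipelines fail loudly: a cutoff that admits no triples
  raises an empty-network error (CLI exit code 3).

## Problem sizes used in validation

The test suite and acceptance script run on scaled problem sizes chosen
to exercise every code path while remaining desk-runnable: oracle
checks on 1000 random vectors/triples and 200 small state networks,
exhaustive partition search up to 7 states (Bell(7) = 877 partitions),
null calibration at the full 78 × 20 study scale (200 replicates), the
two validation scenarios above, and a 26 × 26 subsampling panel with
3 replicates per k.

## Known limitations

- Mediation is restricted to 3-residue relays; longer chains appear
  only as compositions of overlapping triples.
- No uncertainty is attached to the mediated effect (no Sobel or
  bootstrap errors); p-values are uncorrected by design.
- The two-level (flat) map equation is used; hierarchical community
  structure is out of scope.
- The teleportation rate and the exact teleport target convention are
  not identifiable from data; both are parameters (`tau`,
  `teleport_mode`) and results at very low τ can depend on them.
- The generator's diffusion kernel is a stand-in for real shift
  propagation physics; it preserves monotone decay along the planted
  graph but nothing about actual ring-current or packing effects.
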