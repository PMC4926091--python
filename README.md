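# methylflow

Infer intramolecular communication networks in proteins from NMR methyl
chemical-shift perturbations.

A panel of conservative methyl point mutants (L→V, V→A, I→V, …) mildly
perturbs a protein at known sites; the perturbation propagates through
the packed interior and shifts the ¹H-¹³C resonances of distant methyl
groups.  `methylflow` turns a residue × mutant table of these combined
shift perturbations into a directed information-flow network and asks:
which residues talk to which, along which 3-residue relays, and how do
the residues organize into (possibly overlapping) communication
communities?

It is aimed at NMR spectroscopists and computational structural
biologists studying allostery — kinases, and MAP kinases in particular,
are the motivating system — but nothing in the pipeline is
protein-specific.

## The method

1. **Combined CSPs.**  For each methyl and mutant,
   Δν = √((Δδ_H·f)² + (Δδ_C·f·188.8/750)²) in Hz at ¹H frequency
   f (default 750 MHz, where the ¹³C factor is the conventional
   188.8 Hz/ppm).
2. **Rank correlation.**  Within each residue row the mutants are ranked
   by perturbation magnitude; Spearman correlations R_AB between rank
   profiles (over jointly observed mutants) quantify co-perturbation,
   with two-sided t-test p-values, uncorrected.
3. **Mediation.**  An ordered triple A→B→C is a communication path when
   (i) R_AB is significant, (ii) the partial correlation ρ_bc of B and C
   given A (from the joint regression of C on A and B) is significant,
   (iii) the direct effect is reduced, ρ_ac < R_AC, and (iv) all the
   correlations involved are positive.  The path strength is the
   mediated effect R_AB·ρ_bc.  State-specific cutoffs follow the
   kinase-state convention (p < 0.02 inactive apo, 0.03 ATP-bound,
   0.03 inhibitor-bound, 0.04 active).
4. **Second-order memory network.**  Every path A→B→C becomes a directed
   edge between *memory nodes* (A,B) → (B,C), weighted by the mediated
   effect; a random walk on this state graph is a second-order walk over
   residues, so where flow goes next depends on where it came from.
   Soft-thresholded pair correlations max(R,0)^β (β = 8) serve as
   teleportation probabilities; visit rates come from power iteration.
5. **Map-equation communities.**  A two-level map equation
   L(M) = q·H(Q) + Σ_m (q_m + p_m)·H(P_m) (bits) is minimized over
   partitions of the state nodes by a seeded multi-trial greedy search.
   Projecting modules back to residues yields *overlapping* communities,
   with inter-module flow quantifying how strongly they communicate.
6. **Critical nodes.**  Memory nodes are ranked by stationary flow (each
   with its itemized 3-residue in/out paths), residues by the number of
   significant correlations, and pathway neighborhoods can be exported
   as JSON/DOT diagrams.

A synthetic-data module generates CSP matrices from planted weighted
graphs (diffusion-kernel propagation + lognormal noise + a Hz-scale
measurement floor + missing peaks) so the whole pipeline is testable
against ground truth, and runs the mutant-subsampling robustness
experiment.

## Worked example

Fit the model on a synthetic two-community panel with known truth:

```python
import methylflow as mf

csp, truth = mf.two_lobe_scenario(seed=0)          # 22 residues, 22 mutants
model = mf.CSPNetworkModel(csp, p_cutoff=0.1)
results = model.fit(n_trials=30, seed=5)
print(results.summary())
print("recovery vs planted truth:",
      round(mf.recovery_score(results.community_report, truth), 3))
```

prints

```
CSP information-flow network
============================================================
state:                 apo-inactive (p < 0.1)
residues x mutants:    22 x 22
soft threshold beta:   8.0
teleportation tau:     0.15 (recorded)
significant pairs:     110
mediated 3-res paths:  1136
memory nodes:          220
map codelength:        6.6860 bits (4 modules, 30 trials)
communities > 5 res:  3

top memory nodes (visit rate):
    1. 13:d1->18:d1       0.0170
    2. 9:d1->2:d1         0.0164
    ...

recovery vs planted truth: 0.913
```

110 significant positive pairwise correlations support 1136 mediated
3-residue paths; the map equation compresses the second-order walk to
6.69 bits with 4 modules, and the residue-level core assignment matches
the planted two-lobe structure (adjusted Rand 0.91, with the two bridge
residues appearing in both lobe communities).  `results.save(outdir)`
writes every intermediate (CSP matrix, correlation and triple tables, an
Infomap-style state-network file, community JSON, rankings, provenance).

The same pipeline is available from the shell:

```sh
methylflow simulate --seed 1 --out csp.csv
methylflow run --input csp.csv --p-cutoff 0.1 --trials 50 --seed 1 --out out/
methylflow subsample --input csp.csv --ks 8,11,14,17,20 --out curve.csv
```

## Layout

| module | role |
|---|---|
| `methylflow.shift_io` | shift tables (CSV/TSV/Sparky), CSP matrix assembly and round-trip I/O |
| `methylflow.rank_stats` | rank transform, Spearman + p-values, soft-thresholding |
| `methylflow.mediation` | partial correlations, 3-residue path tests, vectorized enumeration |
| `methylflow.memory_network` | state-node graph, teleportation, stationary flow, state-file export |
| `methylflow.mapeq` | two-level map equation, optimizer, overlapping communities |
| `methylflow.flow_ranking` | memory-node and connectivity rankings, pathway reports |
| `methylflow.synthetic` | planted-network generator, recovery scoring, subsampling |
| `methylflow.model` | `CSPNetworkModel` / `CSPNetworkResults` facade |
| `methylflow.cli` | `methylflow` command-line driver |

See `docs/methods.md` for the model details, parameter choices, and
limitations.
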