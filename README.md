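# kinmotif

Kinase substrate-motif profiling from oriented peptide library screens
(OPLS): spot-grid normalization, motif clustering across a kinase family,
Scansite-style substrate prediction, and phosphorylation-rate estimation.

## The problem

Protein kinases recognize their substrates largely through the residues
flanking the phospho-acceptor (the Ser/Thr/Tyr that receives the
phosphate). An oriented peptide library screen measures this preference
directly: the kinase phosphorylates pools of degenerate peptides, each pool
fixing one residue *Z* at one position from −5 to +4 relative to the
central acceptor. With 9 positions × 22 fixed residues (20 amino acids plus
phospho-Thr and phospho-Tyr) the screen has 198 pools, plus three fully
degenerate pools with fixed S, T or Y acceptors that report the
acceptor preference itself. Spot intensities, read off a dot blot, encode
the kinase's position-specific scoring matrix (PSSM).

`kinmotif` implements the full computational path from raw spot
intensities to biology, for anyone analyzing OPLS data for a kinase family:

1. **Normalization** (`kinmotif.opls`) — each spot is divided by the mean
   intensity of its position, so every position profile has mean 1 and
   per-blot exposure cancels; replicates are averaged; fixed Ser/Thr spots
   (fixed Tyr in the Tyr library) are capped at 1 where they exceed 1,
   because such pools carry a second acceptor site; values are
   log2-transformed for heatmaps and logos.
2. **Motif comparison** (`kinmotif.compare`) — kinases are clustered by
   average linkage on the one-minus-Pearson distance between their capped
   linear motif vectors (198 cells, optionally + 3 acceptor cells);
   percent-identity matrices of aligned kinase domains, signed logo heights,
   and residues at fixed offsets from the conserved HRD/APE/DFG anchors
   (HRD+2, APE−4, DFG+1) round out the comparison toolkit.
3. **Substrate scoring** (`kinmotif.scoring`) — a PSSM built from the
   capped matrix scores candidate phosphosite windows with the mean
   per-position log2 deviation from the column optimum: lower is better and
   0 is a perfect match. Targets are selected as the top scoring fraction
   (e.g. 10%), and multi-kinase target lists are compared by exact Venn
   region counts and score–score correlation.
4. **Kinetics** (`kinmotif.kinetics`) — peptide phosphorylation rates are
   the OLS slopes of scintillation counts (CPM) versus time; substrate
   groups are compared by t-test or ANOVA + Tukey HSD on per-replicate
   slopes.
5. **Synthetic ground truth** (`kinmotif.synthetic`) — generators for true
   motifs, noisy replicate blots (lognormal spot noise × per-blot scale),
   site databases with implanted motif matches, and assay time courses, so
   the whole pipeline is testable with known answers.

## Worked example

```python
import numpy as np
import kinmotif as km
from kinmotif.synthetic import SiteDatabaseSpec

# ground truth: 6 selective positions, 10x preferred residues
truth = km.make_true_motif("NekSim", n_selective_positions=6,
                           preference_strength=10, seed=42)
grids = km.simulate_spot_grids(truth, km.NoiseModel(sigma_log=0.1, seed=43),
                               n_replicates=3)
capped, log2 = km.run_motif_pipeline(grids)

truth_capped = km.cap_acceptor_like_residues(truth.as_motif_matrix())
r = np.corrcoef(capped.values.to_numpy().ravel(),
                truth_capped.values.to_numpy().ravel())[0, 1]
print(f"motif recovery Pearson r = {r:.4f}")
print(km.acceptor_preference(capped).round(3))

pssm = km.build_scoring_matrix(capped)
sites = km.simulate_site_database(SiteDatabaseSpec(seed=44), [truth])
scores = km.score_sites(pssm, km.filter_sites(sites, pssm))
top = km.percentile_select(scores, 0.10)
implanted = sum(s.protein_id.startswith("IMP") for s in top)
print(f"top-10% selection: {len(top)} of {len(scores)} sites, "
      f"{implanted} implanted ({implanted/len(top):.1%} vs 5.0% base rate)")
```

prints

```
motif recovery Pearson r = 0.9979
          normalized  fraction
acceptor
S              1.289     0.430
T              1.402     0.467
Y              0.309     0.103
top-10% selection: 200 of 2000 sites, 67 implanted (33.5% vs 5.0% base rate)
```

Three noisy replicates recover the planted motif almost perfectly
(r ≈ 0.998), the acceptor pools recover the simulated S/T-over-Y
preference, and sites implanted to match the motif (5% of the database) make
up a third of the top-10% prediction — a 6.7-fold enrichment.

The same pipeline is available from the shell:

```sh
kinmotif run-all --seed 42 --out-dir out/
# per-kinase motif TSVs, a PSSM, score and selection TSVs, a Newick
# dendrogram, a Venn-region JSON and a rate-comparison JSON land in out/
```

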