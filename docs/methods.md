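# Methods

## Normalization model

An OPLS readout for one replicate is a 9 × 22 grid of nonnegative spot
intensities `raw(p, z)` — flank position `p ∈ {−5..−1, +1..+4}`, fixed
residue `z` among the 20 amino acids plus phospho-Thr/phospho-Tyr — plus
optionally three fully degenerate acceptor pools (fixed S/T/Y). The model
behind the pipeline is multiplicative: the intensity of a spot is
(kinase preference) × (per-blot exposure) × noise. The pipeline therefore:

1. normalizes each replicate per position:
   `norm(p, z) = raw(p, z) / mean_z raw(p, z)` — each position's profile
   has mean exactly 1 and the blot exposure factor cancels;
2. averages normalized replicates element-wise (unweighted arithmetic
   mean; the protocol expects n ≥ 2 and a single replicate only warns);
3. caps acceptor-like fixed residues at 1 where they exceed 1 — a fixed
   Ser/Thr spot (fixed Tyr in the Tyr library) carries a second acceptor
   besides the central one, so intensity above the position mean there
   does not prove flank preference. Cells can be exempted explicitly
   (e.g. a +1 Tyr when the kinase demonstrably favors aromatics at +1);
   the operation records which cells it modified and is idempotent;
4. log2-transforms for display, flooring at 2⁻⁶ first so zero spots map to
   −6 rather than −∞.

Order matters and is fixed as normalize → average → cap → log2: averaging
{1.4, 0.8} then capping yields 1.0, whereas capping first would yield 0.9.
The capped **linear** matrix feeds clustering and scoring; the **log2**
matrix feeds heatmaps and logos.

Missing spots (failed pools) are permitted as NaN: position means are taken
over present cells, averaging skips missing replicates per cell, and the
matrix reports its completeness. Correlations between motifs are computed
pairwise-complete with a minimum-overlap threshold (default 150 of 198
cells) below which comparison is refused.

Acceptor pools are normalized by the mean of the present pools (mirroring
the per-position flank normalization, so the zero-noise round trip is
exact) and reported both as mean-1 normalized values and as fractions
summing to 1. At least two pools are required.

## Motif comparison

Motif vectors flatten the capped linear matrix in fixed order (positions
ascending, residues in grid-alphabet order), optionally appending the three
acceptor values; the phospho-residue (pT/pY) columns are included by
default since they are part of the 198-cell grid, with a flag to exclude
the acceptor block. Similarity is the Pearson correlation; clustering is
average-linkage (UPGMA) on the distance 1 − r.

UPGMA is implemented in-package rather than via `scipy.cluster.hierarchy`
for one reason: the determinism contract. Exact ties in the merge queue are
broken lexicographically by the candidate clusters' smallest member ids, so
the tree is a pure function of the input. The test suite cross-checks merge
heights against scipy's average linkage on random tie-free matrices and
against a hand-worked 4-leaf example. Trees export to Newick with branch
lengths `parent_height − child_height` (leaves at height 0), which makes
the tree ultrametric: every leaf's root-to-tip depth equals the root's
merge height.

Sequence identity between aligned kinase domains is
`matches / mutually-ungapped columns × 100`; alignment itself is an input
(any aligner; read as aligned FASTA).

Logo heights are the log2 motif values themselves: positive = favored,
negative = disfavored, 0 = indifferent, with a favored-only variant that
zeroes negatives. This is a deliberate presentation-level simplification
relative to information-theoretic (Kullback–Leibler) logo weighting: it
preserves the favored/disfavored semantics without reimplementing a logo
server, and any monotone rescaling of heights leaves the visual ranking of
residues within a position unchanged.

Anchor-offset extraction locates the conserved HRD, APE or DFG tripeptide
in an unaligned kinase-domain sequence (a search window is required when
the tripeptide occurs more than once). Negative offsets count N-terminal
with the anchor's first residue as −1 (APE−4 of `…TIYAPE…` is the T);
positive offsets count C-terminal from the anchor's last residue (HRD+2 is
two residues past the catalytic aspartate, the position whose lysine
predicts Ser/Thr specificity; DFG+1 likewise). Residue frequencies over a
set of kinases are simple fractions summing to 1.

## Substrate scoring

The scoring matrix keeps the 20 amino-acid columns of the capped linear
motif (clamped below at 2⁻⁶ to stay positive; missing cells get the neutral
value 1), moves pT/pY to a modified-residue table, and carries the set of
acceptor residues the kinase can phosphorylate. A candidate site is a
9-residue window (−5..−1, +1..+4) around its acceptor, `_`-padded past
protein termini, with lowercase `t`/`y` marking phosphorylated flank
residues.

The score is

    score(w) = (1/N) Σ_p [ log2 max_z M(p, z) − log2 M(p, w_p) ]

over the N non-padding positions: nonnegative, 0 iff the window is
column-optimal everywhere, invariant to any per-position positive rescaling
of the matrix (only within-position ratios matter). Padding positions are
excluded from the mean so truncated windows remain comparable to full
ones. Modified residues consult the pT/pY table when present and the
neutral value otherwise; their per-position contribution is clamped at ≥ 0
so the score invariant survives a modified value above the plain-amino-acid
column maximum. Because downstream selection is purely percentile-based,
any strictly monotone transform of this score would select identical
targets — the scale is a convention, the ordering is the content.

Selection takes the `⌈fraction · n⌉` lowest scores and includes every site
tied with the boundary score (selection is therefore monotone in the
fraction and order-independent). Acceptor gating is a hard filter before
scoring, not a score term. Overlap analysis counts every nonempty
membership pattern among 2–6 selected-site sets exactly, plus the fraction
of a designated reference kinase's targets shared with any other set.

## Kinetics

The phosphorylation rate of a peptide is the OLS slope of CPM versus time;
each replicate time course yields one slope, and inference runs on the
per-replicate slopes (matching how rate panels report mean ± SEM, n = 3):
two groups → two-sample t-test (paired by flag; unpaired default), more →
one-way ANOVA with Tukey HSD pairwise comparisons, with slope ratios as
effect sizes. Groups of zero within-group variance take a flagged
degenerate path (t = 0/p = 1 when equal, p = 0 otherwise) rather than
dividing by zero. Regression is unconstrained (no forcing through a
measured t = 0 background).

## Synthetic data: what it emulates, what it does not

`make_true_motif` builds ground truth directly in the normalized space the
pipeline recovers: a handful of selective positions each favor one residue
by a factor `preference_strength` over the position median (defaults: 4
selective positions, strength 5 — mid-range for a selective Ser/Thr
kinase), remaining positions flat, positions renormalized to mean 1, and
an S/T/Y acceptor preference (default 0.45/0.45/0.10, a Ser/Thr kinase
with minor Tyr activity).

`simulate_spot_grids` emulates replicate dot blots: per replicate one
global exposure scale drawn uniformly from (0.5, 2), then per spot
multiplicative lognormal noise `exp(N(0, σ))` with σ = 0.1 by default. The
replicate count defaults to the protocol's n ≥ 2; σ is stipulated, not
fitted — no replicate-variability estimates exist to fit it to. The
generator does **not** emulate scanner saturation, spatial blot gradients,
peptide-synthesis failures, or correlated noise between neighboring spots,
so passing recovery tests demonstrate correctness of the normalization
algebra under the stated noise model, not robustness to every artifact of
real blots.

`simulate_site_database` draws background windows i.i.d. from a
configurable background composition (default uniform over the 20 amino
acids — real proteomes are non-uniform, so absolute enrichment numbers on
real site databases will differ) and implants motif-matching sites by
sampling each flank residue from the motif's position profile renormalized
to probabilities, the simplest generative reading of "better match ⇒ more
efficiently phosphorylated". Defaults: 1900 background + 100 implanted
sites per kinase (5% implant rate). Implants are identifiable by id prefix
so enrichment is measurable.

All generators are pure functions of (parameters, seed).

## Numerical and design choices

- Position profiles must contain a strictly positive value; an all-zero
  position raises an error naming the position rather than producing NaNs.
- The log2 floor (2⁻⁶) is configurable; it bounds logo heights and PSSM
  log-deviations at 6 per position.
- TSV output uses 6 significant digits; reading a written file and
  rewriting it is byte-identical, which golden tests rely on.
- Test problem sizes: stochastic recovery/power checks run 100 seeds at
  small n (one kinase, 3 replicates; two 3-kinase groups; 2×3 time
  courses), completing the full suite in well under a minute while putting
  the pass-rate thresholds (≥ 95/100) on solid footing.

## Known limitations

- The score scale is this package's convention (mean log2 deviation), not
  a reimplementation of any particular web server's calibration against a
  vertebrate proteome; only percentile selections are comparable across
  scoring conventions.
- Logo heights are not information-content weighted.
- The Tyr-library grid is handled by the same 22-residue layout with
  capping applied to fixed-Tyr cells; library-specific degenerate-position
  composition (e.g. Cys/Ser/Thr excluded from X mixtures) is a property of
  the physical library, not modeled by the simulator.
- Class-I-style confidence filtering of site lists requires caller-supplied
  labels; no mass-spectrometry localization scoring is performed.
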