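# Methods

This note records the models, estimators and numerical choices behind
`trajnet`, in the spirit of the methods documentation of established
scientific packages: what is computed, under which assumptions, and where
the genuinely open design choices were settled.

## Scope and data model

All analyses operate on Cα coordinates only. "Backbone RMSD" is
approximated at the Cα level, and the cross-correlation map is defined on
Cα positions; using one consistent atom selection everywhere keeps RMSD
profiles, correlation maps and networks defined on the same residue set.
Residue numbers from the source structure (e.g. 267–520 for a kinase
domain) are carried as labels through every interface; internal indexing is
0-based and contiguous. Only the first chain is read from a PDB file;
altloc `A` (or blank) is kept and insertion codes are ignored with a
warning.

## Superposition and RMSD

Rigid-body fits use least-squares (Kabsch) superposition via the SVD of
the cross-covariance of centred coordinates, with the determinant
constraint that forbids reflections. Fitted RMSD is therefore never larger
than unfitted RMSD, is symmetric in its arguments, and is invariant under
a common rigid transform of both inputs — all asserted by tests.
Selections with fewer than two atoms, or with all atoms coincident, raise
a degenerate-selection error; rank-deficient but non-trivial selections
(e.g. two atoms, or collinear atoms) are allowed and return one of the
minimisers — the two-atom case has the closed-form check
RMSD = |d₁ − d₂|/2.

Per-domain RMSD profiles support two alignment modes because published
domain-RMSD figures rarely state which was used: `per-domain` (default)
superposes each domain independently before measuring it, `global`
superposes on all Cα and measures domains without refitting. For a
noise-free linear morph between pre-aligned conformations the global-mode
profile reproduces the linear set-point schedule exactly (see below).

## Dynamical cross-correlation map

C_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩), with fluctuations taken
about the window mean and the dot product over the three Cartesian
components (the standard 3-D vector convention; a scalar-projection
reading of the formula is not offered). Windows are half-open frame
intervals; the default window set of the pipeline is the four quarters of
the trajectory plus the full range.

Superposition before the correlation measurement is exposed as a switch
and **defaults to on** (each frame fitted to the mean structure of the
window): a trajectory with net displacement otherwise yields spurious
all-positive correlations from the shared rigid-body motion. The switch
matters, and cuts both ways: the fit also *redistributes* genuine
correlations, because subtracting a fitted rigid-body component couples
all residues weakly (a large coherent block drags the fit and induces
compensating anti-correlations elsewhere — with three 8-residue coherent
blocks in a 60-residue chain these reach ≈ −0.2). For synthetic data whose
fluctuations are generated in a fixed laboratory frame the raw
(`superpose=False`) reading is the one that matches the planted matrix,
and the planted-structure studies therefore use it; for real trajectory
data, which arrives in an arbitrary and drifting frame, the superposed
reading is the meaningful one.

A residue with zero positional variance gets its row and column set to 0
(diagonal 1) with a logged warning rather than an exception; |C| is
clipped to 1 against roundoff.

## Correlation network

Edge weights are w_ij = −log|C_ij| in natural log. The log base is a pure
rescaling of all distances: shortest-path trees, degree, betweenness,
communities and every ranking are unchanged (asserted by a test), and
closeness rescales by the same constant. Two threshold semantics exist
because the magnitude-based weight and a signed threshold rule are both
defensible: `magnitude` (default) removes edges with |C_ij| < C_thr,
consistent with the weight using |C|; `signed` removes edges with
C_ij < C_thr, which additionally deletes all anti-correlated pairs. The
mode is recorded in the graph metadata. Pairs with C_ij = 0 are never
connected (infinite distance); |C_ij| = 1 gives a legal zero-weight edge.
Raising C_thr can only remove edges (monotonicity, tested).

## Centralities

Degree is the adjacency row sum. Closeness is the inverse mean weighted
shortest-path distance, scaled by (n_reach − 1)/(n − 1) on disconnected
graphs (Wasserman–Faust) so values are comparable across components;
isolated nodes get 0. Betweenness uses Brandes' dependency accumulation
over a Dijkstra shortest-path DAG with *fractional counting* of tied
paths; ties in path weight are declared with relative tolerance 1e−9, and
a zero-weight edge joining two equidistant nodes is oriented by Dijkstra
settle order so the path count stays finite, acyclic and deterministic.
Two normalisations of the pair sum Σ g_i^st/n_st are offered: `all-pairs`
(default) divides by ½n(n−1) — all unordered pairs — and `standard` by
½(n−1)(n−2). They differ only by the constant (n−1)/(n−... ) factor, so
rankings are identical; the default follows the convention used in the
protein-network literature this package targets. The implementation is
validated against exhaustive enumeration of all simple paths on random
weighted graphs (exact agreement at n ≤ 8) and against networkx's
Brandes implementation.

Rank ties (common: many residues share betweenness 0) break by ascending
residue number, which makes every top-k listing deterministic.

## Communities

Divisive Girvan–Newman clustering: repeatedly remove the edge of highest
weighted edge-betweenness (information distance as the path metric) and
cut the resulting dendrogram at maximum modularity. Modularity is
evaluated on the **unweighted** adjacency — the edge weights are
distances, and feeding them to a modularity score (which expects
affinities) inverts their meaning. The trivial connected-component
partition is included as a candidate, isolated nodes are singleton
communities, and an edgeless graph yields all singletons with modularity
0. Because modularity along the divisive sequence is near-unimodal in
practice, the descent stops after 10 consecutive levels without
improvement (`patience`; `None` explores the full dendrogram — used
nowhere by default but available for small graphs).

## Suboptimal paths

Yen's algorithm (via `networkx.shortest_simple_paths`) returns the k
lowest-total-weight loopless paths between two residues; the first is a
weighted shortest path and weights are non-decreasing. Fewer than k paths
(or none) is a valid result, not an error.

## Power-law characterisation

The betweenness distribution is modelled as a continuous power law
p(x) = C x^(−α), x ≥ xmin, C = (α−1) xmin^(α−1). Two estimators are
labelled in output:

* **MLE** (default): α̂ = 1 + n/Σ ln(x_i/xmin), SE = (α̂−1)/√n. xmin is
  either fixed by the caller or selected by minimising the KS distance
  between the fitted tail and the empirical tail over candidate cutoffs
  (distinct data values, thinned to ≤ 100 quantiles). The raw MLE is
  reported without small-sample correction; its expectation is inflated
  by ≈ n/(n−1), i.e. below 0.02 in α at tail size 50 for α ≈ 1.85, well
  inside the reported SE (a test tracks this bound).
* **log–log regression**: least-squares slope of log density vs log bin
  centre on a histogram (geometric bin centres for logarithmic binning),
  the graphical fit traditionally read off published log–log plots. Its
  SE is the regression slope standard error.

Betweenness values of exactly 0 cannot enter either fit (log undefined);
they are excluded and their count reported. When a published exponent is
quoted as α ± u without defining u, this package's SE is the comparable
quantity only under the MLE reading; the ambiguity is inherent to the
source and simply documented here.

## Synthetic data: what it emulates and what it does not

The generator emulates a *targeted* conformational transition at the level
of its observable schedule: the noise-free mean path interpolates linearly
between a start and an end conformation, so its RMSD to the target
decreases linearly from RMSD(start, end) to 0 — the set-point schedule a
targeted-MD restraint imposes. The restraint force, spring constant and
any physics (force field, solvent, thermostat) are deliberately absent.
Per-frame fluctuations are zero-mean Gaussian with a user-specified
residue–residue correlation matrix applied identically and independently
to x, y and z — the simplest model whose 3-D DCCM converges to the
specified matrix (verified entrywise to < 0.05 at 10⁴ frames). Start/end
fixtures are built internally (ideal α-helix with one rigid-body-displaced
block, centred and pre-aligned), so no structure download is ever needed;
pre-alignment makes the linear schedule hold exactly *after* optimal
superposition too, because the shortest-path of cross-covariances stays
symmetric positive semi-definite along the morph.

Planted correlation matrices are repaired to the PSD cone by eigenvalue
clipping and diagonal renormalisation when a block/hub specification is
indefinite; realised correlations then deviate from the planted numbers,
which matters for study design (below). Passing tests on this generator
shows the *analysis machinery* is correct on data with known ground truth;
it does not show that real MD data satisfies the Gaussian, isotropic,
frame-independent noise model — anharmonicity, mass effects and
time-correlated noise are all absent.

### Canonical study conditions

Two frozen configurations drive the end-to-end tests and the acceptance
script; their defaults are the study conditions, not tuning knobs.

* `hub_study` — 60 residues, 400 frames, fluctuation amplitude 1 Å; three
  8-residue blocks with intra-block correlation 0.7, mutually
  uncorrelated; one hub residue carrying half its variance from the first
  block's coherent mode and a quarter from each of the others, hence
  correlated √(0.5·0.7) ≈ 0.59 with the first block and √(0.25·0.7) ≈ 0.42
  with the other two. This factor structure is exactly PSD (no repair
  distortion), places the hub firmly inside the first block's community,
  and makes it the sole bridge between blocks — so the hub must dominate
  betweenness, and deleting its correlations (`mutant=True`, the
  point-mutation analogue) must isolate it and raise the community count.
  Note a hard feasibility bound uncovered during design: a hub bridging
  k mutually uncorrelated blocks cannot exceed √(ρ_block/k) correlation
  per link, ≈ 0.48 for k = 3 — planted values above the bound are silently
  eroded by PSD repair.
* `bridge_study` — the two-block variant (blocks of 10 at ρ = 0.8, hub
  correlated 0.6 with every member of both) used for threshold-robustness
  checks: with k = 2 the links sit well above both conventional thresholds
  (0.3 and 0.5), so the same residue must top the betweenness ranking
  under either.

The trajectory length (400 frames) puts the sampling noise of a true-zero
correlation at σ ≈ 0.05, far from the 0.3 threshold; 60 residues keeps a
full pipeline run (including divisive community detection) at a few
seconds, so 20-replicate studies run comfortably on one CPU.

## Pipeline

A run is driven by a plain INI config, hashed (SHA-256) into the run
metadata; identical config and seed give byte-identical outputs (asserted
by test). Every stage logs its boundaries to a per-run log file, failures
carry the stage name, and the manifest is verified against the disk after
the run. The wild-type-vs-mutant recipe is two configs plus `compare`,
which diffs centralities, ranks, edges and community counts node-by-node
on the whole-trajectory networks and pairs the RMSD profiles.

## Known limitations

* The Gaussian generator cannot produce the heavy-tailed betweenness
  distributions of real large proteins at n = 60; the power-law estimators
  are therefore calibrated on directly sampled Pareto data, not on network
  output.
* Closeness in a component connected entirely by zero-weight edges is
  reported as 0 (the distance sum vanishes); such components only arise
  from |C| = 1 pairs, i.e. duplicated coordinates.
* Community detection above a few hundred edges becomes slow (each
  removed edge costs one weighted edge-betweenness pass); the patience
  bound helps but the algorithm is inherently O(E²·V log V) in the worst
  case.
* The mutant analogue deletes planted hub correlations only; it does not
  model any structural consequence of a real substitution.
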