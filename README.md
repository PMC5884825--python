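# trajnet

Correlation-network analysis of protein conformational-transition
trajectories.

Protein conformational transitions — a kinase switching between its
inactive and active forms, for example — are coordinated by networks of
residues whose motions are dynamically coupled. `trajnet` takes a Cα
trajectory of such a transition and characterises that communication
structure: which residues relay correlated motion between structural
units ("hubs"), how concentrated the path traffic is, and how a point
mutation reshapes the network. It is aimed at structural bioinformaticians
and molecular-modelling practitioners who have a trajectory (from biased or
unbiased simulation, or a morph) and want a reproducible, scriptable
version of the standard DCCM → network → centrality workflow.

## The method

1. **Per-domain RMSD profiles.** Each frame is least-squares (Kabsch)
   superposed onto a target conformation, per named residue-range domain
   (SH3, SH2, linker, kinase domain, …) or globally, giving RMSD(t) curves
   that track the progress of the transition per domain.

2. **Dynamical cross-correlation map (DCCM).** For residues *i*, *j* over a
   frame window,

   C<sub>ij</sub> = ⟨Δr<sub>i</sub>·Δr<sub>j</sub>⟩ /
   √(⟨|Δr<sub>i</sub>|²⟩⟨|Δr<sub>j</sub>|²⟩),  Δr<sub>i</sub>(t) = r<sub>i</sub>(t) − ⟨r<sub>i</sub>⟩,

   with the dot product over x, y, z; C ∈ [−1, 1].

3. **Correlation network.** Residues are nodes; pairs passing a threshold
   C<sub>thr</sub> (default 0.3) are joined by an edge with the information
   distance **w<sub>ij</sub> = −log|C<sub>ij</sub>|**, so weighted shortest
   paths follow chains of strong correlation.

4. **Centralities.** Degree d<sub>i</sub> = Σ<sub>j</sub> A<sub>ij</sub>;
   closeness C<sub>C</sub>(v) = (n−1)/Σ<sub>j</sub> g(v, v<sub>j</sub>) with
   weighted shortest-path distances g; betweenness
   b<sub>i</sub> = [Σ<sub>s&lt;t</sub> g<sub>i</sub><sup>st</sup>/n<sub>st</sub>] / [½n(n−1)]
   with fractional counting over tied shortest paths (the ½(n−1)(n−2)
   textbook normalisation is also available).

5. **Power-law fit.** The betweenness distribution is fitted to
   p(x) = C x<sup>−α</sup> by continuous maximum likelihood
   (α̂ = 1 + n/Σ ln(x<sub>i</sub>/x<sub>min</sub>), SE = (α̂−1)/√n, with
   optional KS-based x<sub>min</sub> selection) or by log–log histogram
   regression; α < 2 signals extreme concentration of path traffic on a
   few residues.

6. **Communities, suboptimal paths, differential comparison.**
   Girvan–Newman edge-betweenness decomposition cut at maximum modularity;
   Yen's k-shortest loopless paths between chosen residues; and a node-wise
   centrality/rank/edge diff of two networks (e.g. wild type vs mutant).

Because real transition trajectories are rarely shareable, the
`synthetic` module generates morphing trajectories with *planted*
correlation structure (coherent blocks, bridge hubs, a linear RMSD
schedule) so every stage is testable against known ground truth.

## Worked example

```python
import trajnet as tn

# canonical planted-hub conditions: three coherent blocks bridged by one hub
spec, sched, hub = tn.hub_study(seed=1)          # hub is residue 49
traj = tn.generate_morph_trajectory(spec, sched)  # 400 frames, 60 residues

dccm = tn.compute_dccm(traj, superpose=False)
net = tn.build_network(dccm, c_thr=0.3)
report = tn.centrality_report(net)
print(tn.top_residues(report, "betweenness", 5))

part = tn.detect_communities(net)
print(f"communities: {part.n_communities} (modularity {part.modularity:.3f})")

s = tn.sample_power_law(tn.PowerLawSampleConfig(alpha=1.85, xmin=1.0,
                                                n=100_000, seed=1))
fit = tn.fit_power_law_mle(s, xmin=1.0)
print(f"alpha = {fit.alpha:.3f} +/- {fit.alpha_se:.3f}")
```

Output:

```
 residue  betweenness  rank_betweenness
      49     0.108475                 1
       1     0.000000                 2
       2     0.000000                 3
       3     0.000000                 4
       4     0.000000                 5
communities: 38 (modularity 0.510)
alpha = 1.850 +/- 0.003
```

The planted hub (residue 49) carries all inter-block shortest paths — its
betweenness dwarfs everything else (ties at zero are broken by ascending
residue number) — and the exponent estimator recovers the generating α to
three decimals at this sample size.

The same pipeline is scriptable from the shell:

```bash
trajnet simulate --n-residues 60 --n-frames 400 --block 0:8:0.7 \
        --hub 48:0+1+2:0.6 --seed 1 --out-prefix scratch/demo
trajnet dccm --trajectory scratch/demo_traj.csv --no-superpose --out scratch/d.csv
trajnet centrality --dccm scratch/d.csv --out scratch/centrality.csv
trajnet run --config analysis.ini        # full pipeline from a config file
```

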