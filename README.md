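# superstruct

Parameter-free cluster-connectivity analysis for single-molecule
localization microscopy (SMLM) point clouds.

SMLM experiments (dSTORM, PALM, …) produce tables of emitter coordinates
rather than images. Standard cluster algorithms such as DBSCAN describe
isolated clusters well, but many biological systems — nuclear
ribonucleoproteins, splicing-factor speckles, cytoskeletal meshes — organize
as *super-structures*: clusters bridged by sparse strands of localizations.
`superstruct` quantifies both levels at once by sweeping the DBSCAN
neighborhood radius ε (with the minimum-neighbor threshold fixed at
Nmin = 0) and analyzing how the number of detected clusters Nc decays.

## The model

With Nmin = 0, clusters at radius ε are exactly the connected components of
the ε-neighborhood graph, and the curve Nc(ε) is computed in a single pass
from the Euclidean minimum spanning tree: Nc(ε) = N − #{MST edges ≤ ε}.
Three regimes of the normalized curve Nc/Nloc carry the physics:

1. **Intra-cluster** (small ε): points inside clusters merge at a rate set
   by the internal emitter density ρem. The normalized count follows a
   truncated Poisson avoidance function

       Nc(ε)/Nloc = Σ_{k=0..m} [1/(k+1)] · xᵏ/k! · e^(−x),   x = π ρem ε²,

   with m = 2. The regime ends near ε* = 3/√(π ρem).
2. **Super-cluster, connected**: when clusters are bridged, whole clusters
   merge exponentially, Nc(ε)/Nloc = g·e^(−ε/λ). The decay length λ
   shortens with more connections, denser connections, and denser clusters
   (λ ~ ρcl^(−1/2)); the dimensionless λ* = λ·√ρcl isolates the
   connectivity contribution.
3. **Super-cluster, unconnected**: free clusters merge only by random
   proximity and follow the same Poisson form with the cluster density ρcl
   (m = 1, free prefactor); added uniform noise shifts the fitted density to
   ρcl + ρn. The functional form — exponential versus Poissonian —
   is therefore a signature of the presence or absence of connectivity.

The package includes a ground-truth simulator of connected Gaussian
clusters (centers uniform in an L×L box, Nem emitters per cluster at sd
σem, pairwise bridges drawn within reach b and populated with jittered
connection points), fixed-ε cluster analysis with gyration-tensor shape
descriptors (Rg, circularity), curve/label file I/O, and a batch pipeline
with Student's t comparisons between conditions.

## Worked example

```python
from superstruct import *

cfg = SimulationConfig(pr_nominal=0.004, seed=7)   # standard conditions
res = simulate_dataset(cfg)
grid = build_epsilon_grid([(0, 10, 0.25), (10, 400, 2)])
curve = superstructure_curve(res.table, grid, engine="mst")

intra = fit_regime(curve, (0, 3), "poisson_intra")
exp = fit_regime(curve, (15, 60), "exponential")
cs = clusters_at_scale(res.table, 15.0, min_size=30)
d = cluster_density(cs, CircleROI(1750.0, 1750.0, 1500.0))
nd = normalize_lambda(exp.params["lam"], d.density_um2)
```

prints, step by step:

```
simulated 8680 localizations, realized pr = 0.0042
intra-cluster fit on [0, 3] nm: rho_em = 15647 um^-2 (constructed 15915)
epsilon* = 13.5 nm
super-cluster fit on [15, 60] nm: lambda = 17.0 nm
cluster density at eps=15 nm: 7.4 um^-2 (52 clusters in 7.07 um^2)
lambda* = 0.046
```

The intra-cluster fit recovers the constructed emitter density within ~2%;
ε* ≈ 13.5 nm marks where the intra-cluster regime ends; the exponential
decay length λ = 17 nm quantifies the (weak, pr ≈ 0.004) connectivity; and
λ* removes the cluster-density contribution so conditions with different
cluster densities can be compared.

The same workflow is available from the shell:

```
superstruct simulate --out-dir sim --replicas 20 --seed 1 --pr 0.004
superstruct curve --input sim/replica_000.csv --eps 0:10:0.25,10:400:2 --out curve.tsv
superstruct fit --curve curve.tsv --model exp --window 15:60 --rho-cl 8.2 --out fit.json
superstruct clusters --input sim/replica_000.csv --eps 40 --min-size 30 --out clusters.tsv
```

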