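# topolearn

Topological analysis of molecular representation spaces, and
meta-prediction of machine-learning generalization error from that
topology.

## The problem

QSAR/molecular-property models are trained on many possible feature
representations of the same molecules — binary substructure
fingerprints, hand-crafted descriptor blocks, learned embeddings — and
no representation wins universally. Choosing one today means training
and benchmarking them all. This package implements an alternative: the
*geometry of the representation's feature space itself* carries
information about how well models will generalize on it. It is aimed at
cheminformaticians and ML practitioners who want a label-free,
training-free signal for representation selection, and at anyone
studying the link between data topology and learnability.

## What it computes

**Persistent homology of the feature cloud.** For an n-molecule cloud
under a metric ρ (Jaccard for fingerprints, Euclidean/Manhattan/cosine
otherwise), the Vietoris–Rips filtration VR_ε = {σ : ρ(x, y) ≤ ε ∀ x ≠
y ∈ σ} yields persistence diagrams PH_i for homological dimensions
i ∈ {0, 1}. Each finite interval (b, d) has lifetime Δ = d − b and
midlife μ = (b + d)/2; the diagram is summarized by Betti numbers β_i,
aggregated raw and sum-normalized lifetime/midlife statistics, and the
persistence entropy E_i = −Σ p log p with p = Δ/ΣΔ. Dimension 0 is
computed from the minimum spanning tree; dimension 1 by exact mod-2
matrix reduction of the clique 2-skeleton (anti-transposed order with
clearing), verified against an in-repo brute-force reduction oracle.

**Intrinsic dimension.** The PH-dimension α/(1 − m), where m is the
log–log slope of total persistence E^α = Σ Δ^α over subsample sizes
(α = 1); the TwoNN estimator from nearest-neighbor distance ratios; and
local-PCA dimension from neighborhood covariance eigenvalues.

**Landscape-roughness baselines.** SALI_ij = |A_i − A_j| / (1 − sim),
SARI = ½(score_cont + (1 − score_disc)), RMODI (fraction of molecules
whose nearest neighbor has similar activity), and ROGI / ROGI-XD
(integrated dispersion loss 2(σ0 − σt) under complete-linkage
coarse-graining).

**Benchmarking + meta-model.** Random-forest and neural-network
regressors are tuned by 5-fold grid-search CV per (dataset,
representation, sample size, split) configuration; RMSE/MAE are min–max
normalized within each dataset (E_rel = (E − E_min)/(E_max − E_min)). A
random-forest meta-model is then fit to predict E_rel from the
topological descriptors alone, with predictions clipped to [0, 1], and
evaluated by leave-one-dataset-out (LODO) and
leave-one-representation-out (LORO) cross-validation, reporting the
per-fold correlation mean r_cv and the aggregated-prediction
correlation r_a.

Everything runs on synthetic data with planted ground truth (clouds of
known topology/dimension, landscapes with planted activity cliffs, a
full planted benchmark grid); see `docs/methods.md` for the models,
defaults and limitations.

## Worked example

```python
import topolearn as tl

# a noisy circle: one persistent 1-cycle expected
cloud = tl.make_point_cloud(
    tl.SyntheticSpec(shape="circle", n=100, noise_sd=0.01, seed=0)
)
D = tl.pairwise_distances(cloud, "euclidean")
diagram = tl.vr_persistence(D, max_hom_dim=1)
desc = tl.compute_descriptors(diagram)
print(f"betti_0 = {desc['betti_0']:.0f}")
print(f"betti_1 = {desc['betti_1']:.0f}")
print(f"longest H1 lifetime = {desc['lifetime_1_max']:.3f}")
print(f"H0 persistence entropy = {desc['entropy_0']:.3f}")
print(f"TwoNN intrinsic dimension = {tl.twonn_dimension(cloud):.2f}")

# landscape roughness: smooth vs 30% planted activity cliffs
land_smooth = tl.make_landscape(cloud, cliff_fraction=0.0, seed=0)
land_cliff = tl.make_landscape(cloud, cliff_fraction=0.3, seed=0)
for name, d in [("smooth", land_smooth), ("cliffed", land_cliff)]:
    print(f"{name}: RMODI = {tl.rmodi(d):.2f}, ROGI = {tl.rogi(d):.3f}")
```

prints

```
betti_0 = 99
betti_1 = 1
longest H1 lifetime = 1.527
H0 persistence entropy = 4.324
TwoNN intrinsic dimension = 1.23
smooth: RMODI = 0.89, ROGI = 0.008
cliffed: RMODI = 0.61, ROGI = 0.422
```

The full filtration always yields n − 1 = 99 dimension-0 bars; the
single dominant dimension-1 bar is the circle's cycle; TwoNN sees a
cloud concentrated near a 1-manifold. Planting cliffs leaves the
feature-space topology untouched but degrades both roughness indices:
fewer molecules have activity-consistent neighbors (RMODI 0.89 → 0.61)
and label dispersion is lost much earlier under coarse-graining (ROGI
0.008 → 0.422).

The same pipeline is scriptable from the shell:

```bash
topolearn synth --shape circle --n 100 --noise-sd 0.01 --outdir out
topolearn describe out/features.csv --outdir out
topolearn modelability out/features.csv out/labels.csv --outdir out
topolearn meta-eval --lodo --outdir out
```

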