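# epiderk

Spatial analysis and steady-state modeling of ERK-MAPK signaling across
human interfollicular epidermis.

Keratinocytes take about two weeks to traverse the epidermis while they
terminally differentiate, so a cell's depth within the tissue proxies its
differentiation stage. `epiderk` is a library (plus a thin `epiderm-erk`
command line) for asking, from depth-resolved immunofluorescence samples
of phospho-Raf-1, phospho-MEK-1/2, phospho-ERK-1/2 and calmodulin, whether
ERK-MAPK activation is coordinated along that differentiation gradient and
whether a cell-autonomous cascade driven by calcium signaling can maintain
the observed spatial profile.

## What it computes

**Spatial conditioning.** Each sampled region carries a tissue-layer index
i<sub>layer</sub> ∈ {0, 1, 2} (basal, spinous/granular, transitional) and
distances d₁, d₂ to its layer's deep and superficial boundaries. Samples
are placed on the layer-normalized ordinate

> u = i<sub>layer</sub> + d₁ / (d₁ + d₂) ∈ [0, 3],

z-scored per patient/target/compartment, loess-smoothed per layer, and
binned into 7 coarse or 28 fine spatial partitions sized 1 : 4 : 2 to
match the relative cell numbers per layer (model depth d ∈ [0, 7]).

**Association statistics.** For every pair of partition profiles, Pearson
correlation and plug-in mutual information (bits, equal-width 2-D
histogram) are compared to null distributions built by scrambling one
profile along the spatial axis (default 100,000 permutations); two-sided
(Pearson) and one-sided (MI) 99 % thresholds and (b+1)/(n+1) permutation
p-values decide which associations depend on spatial conditioning.

**Cascade model.** A normalized-Hill ODE model of
Ca²⁺ → Raf-1 → MEK-1/2 → ERK-1/2 with plasma-membrane calmodulin
inhibiting Raf-1, cytoplasm/nucleus compartments for MEK and ERK with
first-order shuttling scaled by the depth-dependent cytoplasm-to-nucleus
volume ratio r(d) (linear, 2 deep → 5 superficial), negative feedback
ERKc ⊣ Rafc, and ERKn-induced self-dephosphorylation. Every activation is
the normalized Hill function f(x) = B·xⁿ/(Kⁿ + xⁿ) with f(0) = 0,
f(EC₅₀) = ½, f(1) = 1 (defaults n = 1.4, EC₅₀ = 0.5). The model is
integrated to steady state at 15 depths (half-partition grid) under the
piecewise-linear Ca²⁺ input (peak at d = 5) and the piecewise CaM input
(peak at d = 1, exponential decay, baseline beyond d = 5).

**Input fitting.** Only four parameters are free: baseline b and amplitude
a of each input profile. They are recovered from cytoplasmic and nuclear
phospho-ERK partition profiles by bounded multi-start nonlinear least
squares with nested per-species affine scaling (model shape vs z-scored
data). Defaults are the fitted values b_Ca = 0.754, a_Ca = 0.092,
b_CaM = 0.363, a_CaM = 0.485.

**Synthetic data.** The original confocal images were never deposited, so
`epiderk.synth` generates ROI tables (3 patients, the study's
target/compartment panel, depth trends + patient offsets + noise) and
model-forward phospho-ERK profiles with known ground truth.

## Worked example

```python
>>> import numpy as np
>>> from epiderk import CascadeParameters, knockout_cam, spatial_profile
>>> base = spatial_profile(CascadeParameters())
>>> base.depths.size
15
>>> np.round(base.species("erkc"), 3)
array([0.052, 0.005, 0.   , 0.039, 0.107, 0.153, 0.184, 0.204, 0.218,
       0.228, 0.242, 0.23 , 0.219, 0.207, 0.195])
>>> ko = spatial_profile(knockout_cam(CascadeParameters()))
>>> bool(np.all(ko.species("erkc") >= base.species("erkc")))
True
```

Cytoplasmic phospho-ERK activation is near zero in the basal partitions
(where membrane calmodulin cancels the calcium drive), rises steadily
across the spinous/granular depths to its maximum near the Ca²⁺ peak at
d = 5, and declines slightly in the transitional layer. Removing
CaM-mediated Raf-1 inhibition (`knockout_cam`) increases activation at
every depth.

The scripts in `examples/` walk through each capability end to end:
conditioning, association testing, steady-state simulation, input fitting,
and the full CLI pipeline with its manifest-based reproducibility.

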