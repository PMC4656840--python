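# fosmap

Statistical toolkit for mapping how retinal input activates the dorsal
lateral geniculate nucleus (dLGN), the image-forming visual thalamus. It is
aimed at labs combining c-Fos immunolabeling of brain sections with retinal
electrophysiology and visual evoked potentials (VEPs): given cell point
patterns, spike trains, confocal fields, count tables and VEP sweeps, it
answers whether activated neurons are spatially random, whether they hug the
lateral (retinorecipient) edge of the dLGN, how pharmacology (4-AP, L-AP4)
reshapes retinal ganglion cell firing, and whether GABAergic interneurons are
preferentially recruited.

## What it computes

**Spike trains** (per cell, on the superimposition of 30 sweeps):
autocorrelogram over ±2 s with 100 ms bins (lag-zero normalized to 1), its
unit-power spectrum, and a Periodicity Index

    PI = peak height / peak base length,

with a peak-detection threshold of 0.008 and a non-periodic cutoff of 0.003;
a Discrimination Index `D = (A1 − A2)/(A1 + A2)` where A1 counts spikes
during the 1 s light pulse and A2 the second right after (D > 0 ⇒ ON cell,
D < 0 ⇒ OFF cell); the standardized inter-spike-interval entropy
`Hs = −Σ pᵢ ln pᵢ / ln n` with `pᵢ = ISIᵢ/Σ ISIⱼ`; and a binomial logistic
mixed model (rat and cell random intercepts) of stimulus-locked "successes"
versus condition.

**Spatial statistics** (per section): Voronoi entropy of the activated
pattern,

    H = −Σ (Aᵢ/ΣA) ln(Aᵢ/ΣA),

with cells clipped to the section polygon; a Monte Carlo null from N_sim
(default 50 000) random NeuN subsamples of size n_cFos with
`p = #(H_sim < H_obs)/N_sim`; stripe partitions parallel to the lateral edge
with an area-normalized G-test `G = 2 Σ Oᵢ ln(Oᵢ/Eᵢ)`, `Eᵢ = (Sᵢ/ΣS)·n`,
referred to χ²(k−1); a Monte Carlo test of whether the activated cells'
median lateral distance is smaller than random; and Holm step-down
adjustment across sections.

**GAD-cell scoring**: mean c-Fos fluorescence in a 20-pixel-radius disc per
GAD cell, a background distribution from 1000 random disc placements that
avoid putative c-Fos-positive regions, positivity when the cell mean exceeds
background mean + 2 SD, then logistic regressions (treatment, medio-lateral
position) and a Poisson homogeneity test across the 3×3 field grid.

**Count model**: section counts as Poisson with
`ln λ = (α₀ + α₁ I_t) + (α₂ + α₃ I_t)·area` plus a Gaussian rat random
intercept; treatment tested by a likelihood ratio whose p-value comes from a
parametric bootstrap under the fitted null.

**VEP**: ON (0–150 ms) and OFF (300–450 ms) window metrics — first positive
peak height over a 50 ms pre-stimulus baseline and window-RMS × 0.15 s —
compared across conditions with two-sided permutation tests on a t-type
statistic.

**Synthetic data**: seeded generators for every input (crescent-shaped
sections at 1704 NeuN and 278 GAD cells/mm², laterally biased activation,
paired control/4-AP spike trains with a 6.2-fold rate increase and periodic
firing at 3.52 ± 0.86 Hz, confocal fields with planted effects, damped-
sinusoid VEPs, mixed-model count tables), each with a ground-truth record.

## Worked example

```python
import numpy as np
from fosmap import spatial, synthetic

params = synthetic.SectionParams(
    outer_radius=225, inner_radius=275, inner_offset=375,
    lateral_bias_scale=30.0,   # activation decays away from the lateral edge
)
section = synthetic.make_section(params, seed=11)
ent = spatial.mc_entropy_test(section, N_sim=2000, seed=1)
med = spatial.median_lateralization_test(section, N_sim=2000, seed=2)
print(f"H_obs = {ent.H_obs:.3f} nats (n_cFos = {ent.n_cfos}), p = {ent.p_label}")
print(f"median lateral distance = {med.median_obs:.1f} um, p = {med.p_label}")
```

prints

```
H_obs = 2.789 nats (n_cFos = 36), p = < 0.0005
median lateral distance = 28.0 um, p = < 0.0005
```

The activated pattern has lower Voronoi entropy than all 2000 random NeuN
subsamples (it is clustered; the Monte Carlo p is reported as a bound
rather than exactly zero), and its median distance to the lateral edge
(28 µm) is smaller than in every random subsample — the activation is
laterally biased, as built into the generator.

The same analyses run from the shell:

```bash
fosmap simulate section --seed 11 --bias-scale 30 --out data/
fosmap analyze spatial --points data/points.csv --geometry data/geometry.json \
    --nsim 2000 --seed 1 --out results/
```

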