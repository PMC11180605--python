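# riscbleach

Modeling and quantification of **reduced fluorescent-protein photobleaching
under near-infrared (NIR) co-illumination**.

Photobleaching of fluorescent proteins (FPs) under visible excitation largely
proceeds through the triplet manifold: the emissive singlet S₁ crosses to the
long-lived triplet T₁, which is the gateway to irreversibly bleached states.
Co-illuminating the sample with NIR light (~700–1000 nm, resonant with the
triplet–triplet absorption band that peaks near 900 nm for EGFP) promotes T₁
to an upper triplet Tₙ, from which the molecule returns to the singlet
manifold by **reverse intersystem crossing (RISC)**. This shortcut drains the
bleaching-prone triplet and stretches the photon budget of the fluorophore.
The strength of the effect is summarized by the **reduced-photobleaching (RP)
ratio**: the time-integrated emission with NIR co-illumination divided by
that without, at identical visible excitation.

The package is for microscopists and photophysicists who want to (i) simulate
and fit the five-state kinetics behind this effect, (ii) quantify RP from
time-lapse image stacks the way it is measured at the microscope, and (iii)
evaluate the downstream biological readouts (replisome-style foci counting,
cell-track MSD, colony growth) on synthetic data with known ground truth.

## The model

States S₀, S₁, T₁, Tₙ, B (bleached) evolve by the linear master equation
`dp/dt = Q p` with transitions

| transition | rate |
|---|---|
| S₀ → S₁ | k_exc = σ_S Φ_vis |
| S₁ → S₀ / S₁ → T₁ | (1−Φ_isc)/τ_S1 and Φ_isc/τ_S1 |
| T₁ → S₀ | 1/τ_T1 |
| T₁ → B | k_b1 |
| T₁ → Tₙ | k_up = σ_T(λ_vis) Φ_vis + σ_T(λ_NIR) Φ_NIR |
| Tₙ → S₁ / B / T₁ | Φ_risc, Φ_bn, (1−Φ_risc−Φ_bn), each × 1/τ_Tn |

where Φ denotes photon flux (I·λ/hc) and σ cross-sections. Fluorescence is
proportional to Φ_f·p_S1(t)/τ_S1; the infinite-horizon emission integral is
computed exactly from the transient linear system, and
`RP = ∫emission(dual) / ∫emission(vis only)`. Two features beyond the
classical RISC scheme — non-zero triplet absorption at the visible line, and
a second bleaching channel out of Tₙ — produce the two observed regime
boundaries: RP saturates above ~2 kW/cm² NIR and declines above
~100 W/cm² visible.

The shipped EGFP parameter file (`riscbleach/data/egfp_default.json`) is
**reconstructed by calibration**, not transcribed: fixed fields are textbook
EGFP photophysics (τ_S1 = 2.6 ns, Φ_f = 0.60, σ_S from ε(488) =
55,900 M⁻¹cm⁻¹ → 2.14×10⁻¹⁶ cm²), and the NIR-sensitive fields (σ_T scale,
Φ_risc, Φ_bn, k_b1, τ_T1) are fitted to the printed EGFP anchors: RP = 3.5
at (32 W/cm² @ 470 nm, 2 kW/cm² @ 900 nm), the NIR plateau, the visible
turnover, the RP ≥ 3 regime, and minutes-scale bleaching kinetics.

## Worked example

```python
import numpy as np
from riscbleach import egfp_default_params, Illumination, rp_model, simulate_trace, scan_rp

params = egfp_default_params()
ref = Illumination(lambda_vis=470, I_vis=32, lambda_nir=900, I_nir=2000)

print(rp_model(params, ref).rp)          # 3.502 — emission gain from NIR co-illumination

t = np.linspace(0, 300, 7)
with_nir, _ = simulate_trace(params, ref, t)
without, _ = simulate_trace(params, ref.without_nir(), t)
print(with_nir.signal.round(3))          # [1. 0.872 0.755 0.654 0.566 0.491 0.425]
print(without.signal.round(3))           # [1. 0.372 0.294 0.232 0.184 0.145 0.115]

print(scan_rp(params, I_nir_values=[0, 500, 2000, 5000], base=ref))
#  I_vis_W_cm2  I_nir_W_cm2  lambda_nir_nm        rp
#         32.0            0          900.0  1.000000
#         32.0          500          900.0  3.423055
#         32.0         2000          900.0  3.501730
#         32.0         5000          900.0  3.518083
```

The traces are normalized fluorescence (1 at the first, singlet-equilibrated
sample): without NIR the signal collapses within minutes, with 2 kW/cm² of
900-nm light it survives roughly 3.5× longer in integrated photons, and the
scan shows RP rising from 1 (NIR off) to its plateau.

The same numbers are reachable from the shell:

```bash
riscbleach simulate --i-vis 32 --i-nir 2000 --out traces.csv
riscbleach synth --kind bleach-stack --seed 7 --out-dir demo/
riscbleach quantify-rp --stack demo/stack.tif --rois demo/rois.tif \
    --with-rois 1,2 --without-rois 5,6 --out demo/traces.csv
```

Other subcommands: `calibrate`, `fit`, `temperature`, `spots`, `track-msd`,
`colony` (see `riscbleach --help`).

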