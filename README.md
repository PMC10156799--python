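# fontanflow

4D flow MRI hemodynamics of the Fontan total cavopulmonary connection
(TCPC), implemented end to end on synthetic phantoms with known ground
truth.

In a Fontan circulation the systemic venous return (inferior and superior
vena cava, IVC/SVC) is routed directly into the left and right pulmonary
arteries (LPA/RPA) without a sub-pulmonary ventricle, so viscous energy
losses and unbalanced caval flow routing in the TCPC matter clinically.
4D flow MRI measures all three velocity components over a volume through
the cardiac cycle, and this package implements the quantitative analysis
chain that turns those velocity fields into hemodynamic metrics:

1. **phantom** — synthetic 4D flow generators: uniform flow, Poiseuille
   tube and solid-body rotation (closed-form oracles), and a streamfunction
   TCPC junction whose caval flow split to each pulmonary artery is exact
   by construction; plus an MRI corruption model (Gaussian velocity noise,
   spatial polynomial phase offsets, venc wrap-around).
2. **preprocess** — static-tissue detection, least-squares polynomial
   phase-offset correction, neighborhood-median velocity anti-aliasing,
   noise masking, and the PC-MRA used for lumen segmentation.
3. **geometry** — vessel centerlines (distance-weighted medial paths),
   perpendicular analysis planes, and the five-region partition
   (IVC, SVC, connection, LPA, RPA).
4. **flowdist** — pathline-based caval flow distribution: emitters seeded
   at 30/cm³ in each caval vein, RK4 advection through the time-resolved
   field, and first-crossing counts at the pulmonary entrance planes,

       FD_LPA = n_LPA / (n_LPA + n_RPA),    FD_RPA = n_RPA / (n_LPA + n_RPA),

   with FD_LPA < 30% or > 70% classified as *unequal* flow distribution.
5. **voxelmaps** — after 1 mm³ isotropic resampling and cardiac-cycle
   fraction truncation, five voxel-wise metrics: peak velocity (98th
   percentile per region), stasis (% of frames with speed < 0.1 m/s),
   kinetic energy KE = ½ ρ V_voxel |v|² summed over time, and viscous
   energy loss from the dissipation function

       ϕ_v = ½ Σᵢ Σⱼ [ (∂vⱼ/∂xᵢ + ∂vᵢ/∂xⱼ) − ⅔ (∇·V) δᵢⱼ ]²,

   with EL rate = μ V_voxel ϕ_v (ρ = 1060 kg/m³, μ = 3.2 cP, Newtonian),
   integrated (EL_tot, J) and averaged (EL_mean, W) over the covered cycle.
6. **longstats** — longitudinal statistics for a two-timepoint cohort:
   annualized changes, exact small-sample Wilcoxon rank-sum and signed-rank
   tests, Spearman correlation with permutation p-values, OLS regression of
   ΔEL on Δpeak velocity, and Monte-Carlo post-hoc power.

## Worked example

```python
from fontanflow import (make_tcpc_phantom, measure_flow_distribution,
                        resample_isotropic, compute_hemodynamic_maps,
                        regional_summary, RegionModel)

series, truth, region = make_tcpc_phantom(split_ivc_to_lpa=0.8, pulsatility=0.3)
res, paths = measure_flow_distribution(series, region, "IVC", density=30.0, seed=1)
print(f"IVC flow distribution: {res.fraction_lpa:.3f} LPA / {res.fraction_rpa:.3f} RPA "
      f"({res.classification}); truth {truth.split_fraction_lpa_from_ivc}")
print(f"pathlines counted: {res.n_lpa} LPA, {res.n_rpa} RPA of {res.n_pathlines}; "
      f"validity {res.validity_fraction:.2f}")

iso = resample_isotropic(series, 1.0)
maps = compute_hemodynamic_maps(iso)
iso_region = RegionModel(labels=iso.mask, spacing=iso.grid.spacing,
                         origin=iso.grid.origin)
for s in regional_summary(maps, iso_region):
    print(f"{s.region:11s} peak_v98={s.peak_velocity_p98:.3f} m/s  "
          f"stasis={s.stasis_mean:5.1f}%  KE={s.ke_mean:.2e} J  "
          f"EL_tot={s.el_tot_mean:.2e} J  EL_mean={s.el_mean_mean:.2e} W")
```

prints

```
IVC flow distribution: 0.783 LPA / 0.217 RPA (unequal); truth 0.8
pathlines counted: 605 LPA, 168 RPA of 849; validity 0.92
IVC         peak_v98=0.390 m/s  stasis=  7.0%  KE=7.07e-07 J  EL_tot=7.62e-09 J  EL_mean=9.53e-09 W
SVC         peak_v98=0.260 m/s  stasis= 14.4%  KE=3.20e-07 J  EL_tot=1.79e-09 J  EL_mean=2.24e-09 W
connection  peak_v98=0.475 m/s  stasis= 17.0%  KE=5.31e-07 J  EL_tot=4.92e-09 J  EL_mean=6.15e-09 W
LPA         peak_v98=0.442 m/s  stasis=  3.1%  KE=9.53e-07 J  EL_tot=7.44e-09 J  EL_mean=9.30e-09 W
RPA         peak_v98=0.208 m/s  stasis= 20.6%  KE=2.12e-07 J  EL_tot=1.28e-09 J  EL_mean=1.60e-09 W
```

The pathline counter recovers the phantom's exact 0.80 IVC→LPA split to
within sampling error and classifies it unequal; the junction (shear) and
the artery carrying 80% of the flow dominate the energy-loss maps.

A CLI mirrors the stages for shell use:

```sh
fontanflow phantom --kind tcpc --split-ivc-lpa 0.7 --out ds/
fontanflow flowdist --in ds/ --regions ds/ --source ivc --out out/
fontanflow maps --in ds/ --regions ds/ --iso 1.0 --out out/
```

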