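# airwaymorph

Three-dimensional morphometry of the upper airway and mandibular kinematics
from CBCT-derived data. `airwaymorph` is aimed at craniofacial imaging
researchers comparing airway-directed treatments — e.g. a mandibular
advancement device (MAD) versus maxillomandibular advancement surgery (MMA)
— between a pre-treatment (T0) and post-treatment (T1) scan.

The package takes binary upper-airway segmentations (NIfTI), 3D cephalometric
landmark sets (3D Slicer FCSV or markups JSON) and a cohort manifest (CSV),
and produces per-patient measurements plus the full two-group statistical
report. Because clinical CBCT data cannot ship with the code, every
quantitative behaviour is validated end-to-end on synthetic phantoms whose
volumes, areas and rigid motions are known in closed form.

## What it computes

**Oriented head frame.** From porion (Po) and orbitale (Or) landmarks the
scans are placed in a standard frame: Frankfurt horizontal ⟂ +Z, midsagittal
plane at X = 0, transporionic axis ∥ +X, origin at the mid-transporionic
point. T1 is mapped onto oriented T0 either by a least-squares rigid fit
over cranial-base landmarks (deterministic default) or by masked rigid voxel
registration (SimpleITK, normalized correlation, multi-resolution).

**Plane-delimited oropharynx volumetrics.** Three parallel planes — through
basion–posterior nasal spine (Ba–PNS, completed to a unique plane by
requiring perpendicularity to the midsagittal plane), through C2I, and
through C4S — delimit the airway:

- total oropharynx: Ba–PNS plane → C4S plane,
- superior oropharynx: Ba–PNS plane → C2I plane,
- inferior oropharynx: C2I plane → C4S plane.

Volumes count foreground voxel centres in half-open slabs `[lower, upper)`
times the voxel volume, so `V_sup + V_inf = V_total` holds *exactly*.
Surface areas sum marching-cubes triangle areas assigned to slabs by
centroid; the artificial planar cut faces are not counted.

**Mandibular kinematics.** B-point displacement Δap (+ anterior) and Δsi
(+ superior), and signed pitch rotations of the ramus line (Co→Go) and the
anterior line (Co→B), per side and averaged. Pitch is the change in the
orientation angle θ = atan2(Δz, Δy) of the line's sagittal-plane projection:
positive = counterclockwise seen from the patient's right; a bite-opening
appliance produces negative (clockwise) pitch.

**Reliability.** For repeated measurements m₁ᵢ, m₂ᵢ of n cases: Dahlberg's
casual error d = √(Σ(m₁ᵢ−m₂ᵢ)²/2n), the relative error 100·d/mean, and the
intraclass correlation ICC(3,1) = (MS_subjects − MS_error)/(MS_subjects +
MS_error) for k = 2 sessions (ICC(2,1) available).

**Cohort statistics.** Pooled-variance Student t between groups, paired t
within group, Kolmogorov–Smirnov normality with seeded Monte-Carlo
Lilliefors p, age-adjusted ANCOVA (`y ~ group + age`, Type II F), Pearson
correlation, 2×2 Pearson χ² (no continuity correction), the
apnea–hypopnea-index success rule (success iff AHI_T1 < 10 events/h or
≤ 50% of baseline), and the paired-design sample size: the smallest n with
noncentral-t power ≥ target at effect d = |μ_diff|/σ_diff, ncp = d·√n,
df = n − 1.

## Worked example

```python
import airwaymorph as am
from airwaymorph.stats import PowerSpec

# cylinder phantom, r = 10 mm, 25 mm superior + 25 mm inferior, 0.4 mm voxels
mask, lm, truth = am.make_airway_phantom(am.AirwayPhantomSpec(spacing=0.4))
m = am.measure_airway(mask, lm)
print(f"superior volume: {m.superior_volume:.1f} mm^3 (analytic {truth.superior_volume:.1f})")
print(f"inferior volume: {m.inferior_volume:.1f} mm^3 (analytic {truth.inferior_volume:.1f})")
print(f"superior area:   {m.superior_area:.1f} mm^2 (analytic {truth.superior_area:.1f})")

# a MAD-like mandibular motion: -4 deg pitch, 2.75 mm advancement, 9.29 mm drop
t0, t1, _ = am.make_mandible_case(
    am.MandibleCaseSpec(pitch_deg=-4.0, advance_mm=2.75, raise_mm=-9.29))
ch = am.measure_mandible(t0, t1)
print(f"ramus pitch {ch.ramus_pitch_mean:.2f} deg, anterior pitch {ch.anterior_pitch_mean:.2f} deg")

print("n =", am.sample_size_paired_t(PowerSpec(1261.6, 1476.2, 0.05, 0.90)))
r = am.chi_square_2x2([[9, 8], [7, 10]])
print(f"chi2 = {r.statistic:.3f}, p = {r.p:.3f}")
```

prints

```
superior volume: 7789.2 mm^3 (analytic 7854.0)
inferior volume: 7914.8 mm^3 (analytic 7854.0)
superior area:   1577.7 mm^2 (analytic 1570.8)
ramus pitch -4.00 deg, anterior pitch -4.00 deg
n = 17
chi2 = 0.472, p = 0.492
```

The phantom volumes land within 1% of the analytic πr²h (the residual is
voxel-centre discretization at 0.4 mm), the programmed pitch is recovered to
machine precision, the sample-size calculation says 17 subjects per
timepoint suffice for 90% power at the stated effect, and the 2×2 sex-split
test reproduces p = 0.492.

A command-line interface mirrors the library: `airwaymorph measure`,
`airwaymorph study`, `airwaymorph simulate`, `airwaymorph reliability`.

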