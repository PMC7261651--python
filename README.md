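# shuttlesim

Design models for rigid insertion shuttles that deliver flexible neural
electrode arrays through dura mater and epineurium.

A shuttle must satisfy two opposing constraints: it has to be stiff enough
not to buckle while piercing tough collagenous membranes, yet as small as
possible to spare the microvasculature and the surrounding tissue. This
package implements the computational side of that trade-off for arbitrary
rectangular and T-shaped cross-sections:

- **Cross-section geometry** — exact area, centroid and second moment of
  area *I* for rectangles and T-beams (a planar portion with a trapezoidal
  vertical fin), with an independent polygon-integration oracle.
- **Buckling mechanics** — Euler critical loads
  *P*<sub>cr</sub> = π²*EI*/(*KL*)², effective-length factors for the
  fixed-pinned (*K* = 0.699), fixed-guided (*K* = 1) and fixed-free
  (*K* = 2) tip boundary conditions, and thickness design-space sweeps.
- **Vascular damage Monte Carlo** — a 3-D microvascular network (read from
  file or synthesised as an isotropic Poisson stick process) is projected
  onto the insertion plane; the probe footprint is dropped 1000 times at
  random positions and rotations and transected vessel segments are counted
  under two documented criteria (centreline crossing and full-width
  severing). Count distributions are summarised by a Gaussian fit and
  geometries compared by relative mean-damage reduction.
- **Insertion kinematics** — closed-form trajectories, peak speed
  *v* + π*f·A*<sub>pp</sub> and peak acceleration (2π*f*)²·*A*<sub>pp</sub>/2
  for linear drive with superimposed axial oscillation.
- **Recording metrics** — the Vrms noise floor of five concatenated 100 ms
  spike-free snippets and unit SNR = Vpp / (3·Vrms).

## Worked example

The study's T-shaped diamond shuttle — 65 × 11 µm planar portion with a
27.5 µm-deep fin tapering 16 → 2 µm, ultrananocrystalline diamond at
E = 800 GPa — against conventional silicon rectangles (E = 169 GPa):

```python
>>> from shuttlesim import TBeamSection, RectangularSection, area_reduction_percent
>>> from shuttlesim import second_moment, buckling_load, ShuttleBeam, BoundaryCondition
>>> from shuttlesim.geometry import UNCD, SILICON
>>> tbeam, si34 = TBeamSection(65, 11, 27.5, 16, 2), RectangularSection(65, 34)
>>> second_moment(tbeam)            # µm^4
64895.49305555555
>>> area_reduction_percent(tbeam, si34)   # % area saved at matched stiffness
56.44796380090498
>>> beam = ShuttleBeam(tbeam, UNCD, 1.5, BoundaryCondition.named("fixed-pinned"))
>>> buckling_load(beam)             # mN, 1.5 mm shank
466.0873669152354
```

The T-beam matches the bending stiffness of a ~38 µm-thick silicon
rectangle while carrying 56% less cross-sectional area. Running the damage
model on a synthetic cortical-style network
(`analysis/03_vascular_network.py` then `analysis/04_damage_simulation.py`)
prints:

```
T-UNCD   [centerline]  mean  2.67  deviation 1.67
Si-34    [centerline]  mean  3.48  deviation 1.96
-> T-beam reduces mean vessel damage by 23.5% (centerline criterion)

T-UNCD   [full-width]  mean  2.19  deviation 1.54
Si-34    [full-width]  mean  3.07  deviation 1.80
-> T-beam reduces mean vessel damage by 28.6% (full-width criterion)
```

i.e. per insertion the T-beam transects a quarter to a third fewer
microvessels than the silicon rectangle of equal buckling strength; on the
real network, whose vessel density is higher, both the means and the
reduction are larger.

## Analysis pipeline

Numbered drivers under `analysis/` run the full study sequence and write
tables to `results/`:

| script | output |
|---|---|
| `01_cross_sections.py` | section properties, equivalent silicon thickness, area savings |
| `02_buckling.py` | buckling loads per boundary condition, 5–52 µm thickness sweep |
| `03_vascular_network.py` | network statistics (+ canonical CSV copy) |
| `04_damage_simulation.py` | 1000-trial damage distributions, both criteria |
| `05_kinematics.py` | peak speed/acceleration per motor condition |
| `06_ephys_snr.py` | noise floor and unit SNR on a synthetic trace |

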