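# osteoremod

Mechanobiological simulation of cortical bone remodeling in a rodent tibia
under different running regimes.

Bone continuously adapts its density to mechanical demand: osteoblasts
deposit matrix where the tissue is moderately overloaded, osteoclasts
resorb it where the overload is excessive or the stimulus absent.
`osteoremod` models a tibial diaphysis as an axisymmetric elastic cylinder
whose dimensionless bone density ρ(r) rises from the marrow (ρ ≈ 0.15) to
the cortex (ρ ≈ 1) through an arctangent interface, with stiffness
E = E₀·ρ² (E₀ = 20.3 GPa, ν = 0.3). The cylinder is loaded in simple
compression by body weight (350 g), and the elastic energy W developed in
the structure drives a four-parameter cell-activity law

    A_ob(W) = min(k₁·(W − W₀), A₁),    A_oc(W) = max(k₂·(W − W₀), A₂),

zero at the homeostatic energy W₀, with k₁ > 0 > k₂ and caps A₁ = k₁(W₁−W₀),
A₂ = k₂(W₃−W₀). Net formation occurs for W₀ < W < W₂ and net resorption
above W₂. A density-dependent activation factor (α − ρ)ⁿ (α ≈ 1; n
interpolated between 13.6 at W₁ and 5 at W₃) concentrates cell activity on
the marrow side of the cortical-trabecular interface, where remodeling
cells actually live. The density field is integrated in time (explicit
Euler, staggered re-solves of the elasticity problem) over the 8-week
protocol:

* **sedentary** — energy held at W₀: exact homeostasis, no change;
* **intermittent running** — energy W₁: net formation, the mid-density
  interface moves inward (thicker cortex);
* **continuous running** — energy W₃: net resorption, the interface moves
  outward (thinner cortex); optionally with a first-order activation delay
  ("slow"/"low") that spreads the density loss over weeks instead of days.

A calibration module reproduces the parameter identification: normalized
cortical-thickness ratios of the three animal groups, the balance energy
W₂ from A₁ + k₂(W − W₀) = 0, and the slopes/caps from thickness changes
read as an annular shift of the interface.

## Worked example

```bash
$ osteoremod run --scenario intermittent --out demo_run
running scenario 'intermittent': W = 3.7000e-04 mJ, 56 days, energy mode global, delay none
mean density change: +2.004% | front radius: 0.49101321586460916 mm | outputs in demo_run

$ osteoremod profile --radii 0,0.45,0.5,0.55,1.5
radius_mm,density
0,0.146574
0.45,0.401053
0.5,0.560000
0.55,0.718947
1.5,0.997546
```

The run writes `timeseries.csv` (per-day volume-averaged density,
mid-density front radius and global cell activities), `final_profile.csv`,
a legacy-VTK field snapshot and a JSON manifest:

```
time_days,mean_density,front_radius_mm,global_ob_activity,global_oc_activity
0,0.8815257072,0.5,0,0
1,0.8850417406,0.4997364977,2.841680979,-2.711244877
2,0.8868052184,0.4994832296,1.744628609,-1.663452087
```

Reading: the volume-averaged density climbs from 0.8815 by about 2% over
8 weeks while the 0.56-density interface moves from 0.50 mm toward
0.45 mm — the cortex thickens, with formation concentrated on the
trabecular side of the interface. Activities are in mg·mm⁻³·(56 d)⁻¹;
the osteoblast term slightly outweighs the osteoclast term at W₁, and both
relax as the stiffened bone lowers the developed energy back toward
homeostasis. `osteoremod calibrate` prints the thickness-derived parameter
report (normalized ratios 1.00 / 0.74 / 1.07 and derived vs printed
k₁, k₂, A₁, A₂), and `osteoremod compare` diffs two runs.

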