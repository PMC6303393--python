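# rdpattern

Reaction–diffusion modeling and quantification for a synthetic Nodal–Lefty
activator–inhibitor circuit.

## The problem

A short-range activator ligand (Nodal) that induces both its own production
and that of a long-range inhibitor (Lefty) is the textbook recipe for
spontaneous periodic patterning. Deciding whether an engineered mammalian
cell circuit actually patterns by this mechanism requires four linked
computations:

1. **Model the circuit** as two coupled PDEs — two variants, depending on
   whether the inhibitor only competes for receptors or additionally binds
   the activator directly — and **simulate** them in 1-D and 2-D.
2. **Test the mechanism**: find homogeneous steady states and evaluate the
   four diffusion-driven-instability inequalities at them, then compare the
   parameter region that passes with the region that actually patterns in
   simulation.
3. **Measure the physical ingredients**: fit exponential ligand gradients
   from boundary assays for the characteristic decay length λ, degradation
   rates γ from protein-synthesis-chase courses, and combine them into
   effective diffusivities D = λ²γ — the measured inputs that decide whether
   the inhibitor really outranges the activator.
4. **Quantify the resulting images**: pattern period from the second peak of
   the radial autocorrelation, temporal stability from frame-to-frame SSIM,
   and domain sizes from connected components.

`rdpattern` implements all four, plus seeded synthetic-data generators with
recorded ground truth so each analysis stage can be validated end to end.
Formal definitions of every computation are in
[docs/methods.md](docs/methods.md). Units everywhere: nM, min, µm.

## Worked example

Check the instability conditions at a production-rate combination, then watch
the same parameters form a pattern from two initial pulses:

```python
from rdpattern import (ModelKind, ModelParameters, SimulationConfig,
                       find_fixed_points, select_fixed_point, turing_condition,
                       make_initial_condition, integrate, range_ratios)

p = ModelParameters().replace(alpha_N=0.8, alpha_L=4.0)
fp = select_fixed_point(find_fixed_points(p, ModelKind.COMPETITIVE))
print(f"fixed point: N* = {fp.N_star:.3f} nM, L* = {fp.L_star:.3f} nM")
tc = turing_condition(fp, p, ModelKind.COMPETITIVE)
print(f"diffusion ratio d = {tc.d:.2f}; instability conditions: "
      f"{tc.cond1}, {tc.cond2}, {tc.cond3}, {tc.cond4} -> {tc.satisfied}")

cfg = SimulationConfig()  # 2000 um, dx 10 um, dt 0.4 min, 42000 min
init = make_initial_condition("two_pulses", cfg)
res = integrate(init, p, ModelKind.COMPETITIVE, cfg)
N = res.final.N_field
print(f"outcome: {res.outcome}; final N in [{N.min():.3g}, {N.max():.3g}] nM, "
      f"{(N > N.max() / 2).sum()} of {N.size} grid points above half maximum")

r, dg, eq, full = range_ratios(28.7, 99.8, 2.37e-3, 5.65e-3)
print(f"range ratio {r:.2f}, degradation ratio {dg:.2f}, "
      f"diffusivity ratio {full:.1f}")
```

Output:

```
fixed point: N* = 64.571 nM, L* = 135.427 nM
diffusion ratio d = 28.77; instability conditions: True, True, True, True -> True
outcome: pattern; final N in [22.2, 109] nM, 116 of 200 grid points above half maximum
range ratio 3.48, degradation ratio 2.38, diffusivity ratio 28.8
```

The last line uses measured decay lengths (28.7 and 99.8 µm) and degradation
rates (2.37×10⁻³ and 5.65×10⁻³ min⁻¹) for activator and inhibitor: the
inhibitor reaches ≈3.5× farther and diffuses ≈29× faster — the long-range
inhibition that the instability test requires.

The same operations are available from the command line:

```
rdpattern ratios --lambda-n 28.7 --lambda-l 99.8 --gamma-n 2.37e-3 --gamma-l 5.65e-3
rdpattern simulate --out-tiff run.tiff --out-csv run.csv
rdpattern phase-diagram --alpha-n 0.25:8:9 --alpha-l 0.25:8:9 --out-csv pd.csv
rdpattern turing-scan  --alpha-n 0.25:8:9 --alpha-l 0.25:8:9 --out-csv turing.csv
rdpattern synth profiles --lambda-true 50 --out-csv profiles.csv
rdpattern fit-gradient profiles.csv --gamma 2.37e-3
rdpattern correlate image.tiff --pixel-size 8
```

## What to expect from the models

Two findings from this implementation are worth knowing before reading any
phase diagram (details and evidence in
[docs/methods.md](docs/methods.md#observed-regimes)):

- The simulated pattern region is a strict **superset** of the
  linear-instability region: outside the instability band the two-pulse
  initial state can ignite stable localized spikes (solitary-type patterns),
  so simulation-vs-theory overlap is ≈0.6–0.7, not ≈1, on the default grid.
- The direct-inhibition model (k₊ = 0.03) has a small genuine instability
  region near α_N = α_L ≈ 3–4; elsewhere it patterns without satisfying the
  test, and its final pattern depends on the initial pulse placement
  (SSIM ≈ 0.45 between placements) — the solitary-pattern signature.

## Reproduction

```
pip install --no-build-isolation -e .
python -m pytest -o addopts= -p no:cacheprovider -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite (≈10 min, one CPU; most of it the three 9×9 phase-diagram
scans and two 2-D runs in `tests/test_acceptance.py`) contains unit and
property-based tests plus seven end-to-end acceptance checks. Three of the
acceptance checks encode idealized expectations that the
implementation reproducibly does **not** meet, for the model-behavior reasons
above plus one resolution limit (λ = 20 µm decay-length recovery bias is
+5.8% against a 5% bound, set by integer-pixel boundary detection at 1.6 µm
pixels); they fail with diagnostic messages and are left failing
deliberately. The 117 unit/property tests and the remaining four acceptance
checks pass.

`scripts/acceptance.py` (≈10 min) recomputes the headline quantities —
gradient-derived ratios, the reference-point instability check, scan
concordance, the equal-diffusivity null, solitary-regime statistics,
parameter-recovery biases and metric invariants — and writes them to JSON
with sample sizes.
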