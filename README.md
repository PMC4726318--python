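# oligokin

Analysis toolkit for the kinetics of G protein-coupled receptor (GPCR)
oligomerisation in model membranes, and for how the membrane's omega-3
fatty-acid (DHA, C22:6) content shapes it.

Membranes of healthy brain tissue are rich in phospholipids carrying a
docosahexaenoyl chain (SDPC/SDPE); several neuropsychiatric disorders
show depleted DHA. Adenosine A2A and dopamine D2 receptors form dimers
and higher-order oligomers, and DHA levels modulate how fast those
complexes assemble. `oligokin` implements the quantitative machinery of
that comparison for membrane-plane (2D) trajectories:

- **Contact/oligomer kinetics** — two receptors are in contact when
  their lateral centre-of-mass distance is `< 4.2 nm`; oligomers are
  connected components of the contact graph; aggregation is summarised
  as mean contacts per protomer over a late analysis window, with
  healthy-vs-diseased comparison (relative difference + Welch t test).
- **Lipid environment** — 2D radial distribution functions `g(r)` of
  lipids around receptors, first-solvation-shell detection and
  occupancy, receptor-bound lipid fractions, and the
  saturated–unsaturated demixing contact fraction
  `f_AB = (A–B contacts)/(all lipid–lipid contacts)` against its
  random-mixing expectation `2·x_A·x_B`.
- **Diffusion** — translational D from `MSD(Δ) = 4DΔ + b` (weighted
  least squares over an intermediate lag window) and rotational Dr from
  the planar-rotor autocorrelation `C(Δ) = ⟨cos Δθ⟩ = exp(−Dr·Δ)`,
  with exact unit conversion (1 nm²/μs = 10⁻⁸ cm²/s).
- **Composition accounting** — phospholipid-% tables ↔ fatty-acyl tail
  censuses (each phospholipid contributes two tails, cholesterol none),
  DHA tail shares, and integer particle apportionment.
- **BRET titrations** — ratio computation in mBU, the saturation
  hyperbola `BRET(x) = BRETmax·x/(BRET50 + x)`, hyperbolic-vs-bystander
  model selection by extra-sum-of-squares F test, and paired t
  comparison of fitted parameters across experiments.
- **Synthetic membrane generator** — a seeded 2D overdamped-Langevin
  simulator (soft-core + Gaussian-well pair interactions, periodic box)
  whose presets emulate the healthy-like / diseased-like / high-DHA
  ternary membranes with known ground-truth parameters, standing in for
  coarse-grained MD trajectories that are not publicly deposited.

## Layout

```
src/oligokin/      library: geometry, trajectory IO, composition,
                   simulate, contacts, lipids, diffusion, bret, pipeline
analysis/          numbered narrative drivers (01–06); write results/
tests/             pytest suite incl. acceptance checks
scripts/           acceptance.py (see below)
```

## Worked example

```python
import oligokin as ok

runs = {}
for condition in ("healthy", "diseased"):
    runs[condition] = [
        ok.simulate(ok.study_config(condition, seed=s))[0] for s in range(3)
    ]
out = ok.compare_aggregation(runs["healthy"], runs["diseased"])
print(f"{out['mean_a']:.3f} vs {out['mean_b']:.3f} contacts/protomer "
      f"-> +{out['relative_difference_pct']:.1f}% (p = {out['p']:.3f})")
```

prints (seeds 0–2, 18 receptors + 400 lipids, 16 μs effective per run):

```
0.522 vs 0.342 contacts/protomer -> +52.5% (p = 0.235)
```

i.e. receptors in the DHA-rich membrane consolidate about half a
contact per protomer within 16 μs effective, ~50% more than in the
DHA-poor membrane at these desk-scale settings (three replicas do not
give significance; the seed-wise ordering is stable). The same
comparison, the lipid-shell metrics and the diffusion table are run end
to end by `analysis/06_full_study.py`, and `analysis/01…05` walk the
individual analyses with their printed findings.

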