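# cuttlecamo

Simulation and analysis of **camouflage during movement** in the European
cuttlefish (*Sepia officinalis*).

A cuttlefish swimming over a patchy seabed must decide which substrate
features are worth matching. Responding to every small, transient patch
would cost processing effort and — worse — produce conspicuous flickering.
The behavioral hypothesis implemented here is that a moving animal applies
a size filter: a high-contrast substrate patch elicits an intensity-matching
response only if its estimated width exceeds a **Camouflage Eliciting Patch
Size (CEPS)** threshold on the order of the animal's own mantle length
(≈ 10 cm). Above the threshold, the animal matches the mean reflectance of
a forward-skewed oval subregion of its visual field, the **Camouflage
Sampling Area (CSA)**, producing a smooth, sigmoid-like reflectance ramp
rather than a step.

The package is aimed at researchers who want to explore or extend this
decision model, and at anyone needing a fully synthetic, calibrated
test bed for reflectance-trace pipelines (tracking, photometric
balancing, transition detection, nonparametric group comparison).

## The model

At every step of a crossing, with self-reflectance `SR` (percent of a
white standard; 18 = background gray, 3 = patch black):

1. **PSE** — estimate the width `w` of any patch within the visual
   surroundings (forward lookahead of 30 cm plus the CSA's rear extent).
2. **CEPS gate** — if a patch is identified and `w < CEPS`, do nothing.
3. **CSA** — otherwise average background reflectance over the oval
   sampling area (default rasterization: exactly 4530 px, forward skew
   20 px).
4. **Delta gate** — if `|SR − CSA| ≤ δ` (default 0.5), the animal is
   already cryptic; do nothing.
5. **Update** — otherwise `SR ← SR + g·((CSA + η) − SR)` with gain
   `g ∈ [0, 1]` and a uniform ±3% stochastic behavior factor `η` on the
   perceived average.

The synthetic-data generator reproduces the original study design — 8
animals (mantle length ~ Normal(10.2, 1.2) cm truncated to [7.2, 12.3]),
one crossing over a uniform 18%-gray control tank (200 × 40 cm) and over
six dichromic backgrounds (black patch widths 3, 7, 10, 19, 29, 60 cm),
sampled at 0.1 s — with response magnitudes calibrated so the per-width
mean crossing change follows the linear law `0.12·w + 1.72` above the
gate and the control mean 1.69% below it.

## Worked example

```python
from cuttlecamo import generate_experiment, analyze_records, experiment_statistics

animals, records = generate_experiment(n_animals=8, seed=42)
per_crossing, summary = analyze_records(records)
st = experiment_statistics(per_crossing)

print(f"control mean change   : {st['mean_control_change_pct']:.2f} %")
print(f"treatment mean change : {st['mean_treatment_change_pct']:.2f} %")
print(f"first significant patch: {st['first_significant_patch_cm']:g} cm")
print(f"Kruskal-Wallis H = {st['kruskal']['H']:.1f}, df = {st['kruskal']['df']}")
```

prints (seed 42):

```
control mean change   : 1.87 %
treatment mean change : 3.97 %
first significant patch: 19 cm
Kruskal-Wallis H = 36.3, df = 6
```

One synthetic cohort of 8 animals crossed all seven backgrounds (56
crossings). Control crossings show only baseline wander (≈ 1.9% mean
range); dichromic crossings average ≈ 4% because small patches are
filtered out by the CEPS gate while large ones elicit strong matching.
The smallest patch width whose per-crossing changes differ significantly
from control (omnibus Kruskal-Wallis, then pairwise two-sided rank-sum
tests vs control in increasing width order, α = 0.05) is 19 cm — the
camouflage-eliciting threshold falls between 10 and 19 cm, bracketing
the animals' mantle lengths.

A command-line interface covers the same pipeline end to end:

```sh
cuttlecamo generate --seed 3 --outdir ds      # synthetic dataset (CSV + JSON)
cuttlecamo analyze ds --outdir results        # per-crossing CSV, summary, stats
cuttlecamo report results/stats.json --outdir results
cuttlecamo simulate --outdir model            # pure model traces per width
```

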