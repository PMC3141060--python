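# trialcea

Trial-based cost-effectiveness analysis of pulmonary artery catheter (PAC)
versus central venous catheter (CVC) monitoring in acute lung injury (ALI),
built as a reusable, tested Python pipeline. Because the underlying
patient-level trial data are not publicly available, the package ships a
first-class synthetic cohort generator calibrated to the published summary
statistics, so every stage of the analysis is reproducible and testable.

## What it computes

For each patient the pipeline constructs:

1. a **first-year cost stream** in 2010 US dollars — hospital cost (billed
   charges × department cost-to-charge ratios), post-discharge direct
   medical costs from unit cost weights × resource-use counts, and lost
   wages;
2. a **one-year effect stream** — quality-adjusted survival as the area
   under the interpolated utility curve, `QA-days = ∫₀^min(death,365) u(t) dt`,
   from interview utilities at 2, 6, 9 and 12 months;
3. a **lifetime projection** (the reference case) — survivors at one year
   accrue their remaining life-table expectancy at utility 0.6/year and a
   fixed annual cost, discounted at 3%/year.

At the cohort level, a bootstrap Monte Carlo probabilistic sensitivity
analysis (default 5000 trials, costs winsorized at the in-arm 95th
percentile) produces the incremental cloud (ΔC, ΔE), from which it derives
dominance-quadrant probabilities, P(ICER above a willingness-to-pay λ) via
net monetary benefit `NMB = λ·ΔE − ΔC`, the cost-effectiveness
acceptability curve, the 95% confidence ellipse, pre-specified subgroup
re-runs and one-way sensitivity scenarios. A parametric mode draws arm
means from normal distributions to reconstruct summary-level analyses.

## Worked example

```bash
trialcea run -o demo_run --n-trials 5000
```

generates the default synthetic cohort (300 patients/arm, seeded), runs the
full reference case, and prints:

```
incremental cost: +25.6 $k
incremental effect: -0.19 QALYs
classification: dominated
P(dominated): 64.0%
P(exceeds $50k/QALY): 93.9%
P(exceeds $100k/QALY): 82.2%
artifacts written to demo_run
```

Reading this output: on this synthetic cohort PAC monitoring costs on
average $25.6k more per patient over a lifetime and yields 0.19 fewer
QALYs, so it is *dominated* (costlier and less effective — no ICER is
reported for a dominated strategy); 64% of bootstrap trials land in the
dominated quadrant, and 94% of trials are worse than a $50k/QALY
willingness-to-pay threshold. `demo_run/` contains the per-patient
streams, the PSA cloud, the CEAC, survival curves, subgroup and
sensitivity tables, and a manifest that makes the run byte-for-byte
reproducible.

The same analysis is available as a library:

```python
from trialcea import RunConfig, run_reference_case
bundle = run_reference_case(RunConfig(n_per_arm=300, n_trials=5000))
bundle.icer, bundle.quadrants, bundle.ceac.to_frame()
```

## Layout

- `trialcea.cohort` — synthetic two-arm cohort generator and CSV/JSON I/O
- `trialcea.costing` — cost weights, hospital cost-to-charge, CPI indexing
- `trialcea.outcomes` — Kaplan-Meier survival, utility AUC, one-year effects
- `trialcea.projection` — life tables, discounted annuities, lifetime streams
- `trialcea.cea` — bootstrap/parametric PSA, quadrants, CEAC, ellipse
- `trialcea.scenarios` — subgroup strata and one-way sensitivity re-runs
- `trialcea.pipeline` / `trialcea.cli` — end-to-end runs and the `trialcea` CLI

See `docs/methods.md` for the modelling assumptions and numerical choices.
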