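# mrp

A toolkit for massive-report patch-discrimination experiments: participants
briefly view a natural scene and then judge, probe by probe, whether small
image patches were part of it, answering on an 8-option decision x confidence
scale. The package covers the full desk-scale workflow:

- **`mrp.sdt`** — decision x confidence encoding (dxc, tdxc), criterion-sweep
  Type 1 (7 criteria) and Type 2 (3 criteria) ROC curves, non-parametric
  trapezoidal AUC, and an independent rank-statistic oracle.
- **`mrp.design`** — 3x3 grid geometry (location tags, eccentricity strata and
  degrees of visual angle), probe schedules for the in-lab (`exp1`: 80 trials,
  21/20 probes) and online (`exp2`: 34 trials, 6 probes, 13 catch trials)
  layouts, disjoint null-patch allocation, and the exact-binomial catch-trial
  exclusion threshold (with a Monte-Carlo cross-check).
- **`mrp.simulate`** — a rating signal-detection simulator (Gaussian evidence,
  7 shared criteria, eccentricity gain, congruence effect, lapses) with
  closed-form ground-truth AUC for parameter-recovery testing, plus
  attentive/random agent profiles for catch-trial behaviour.
- **`mrp.images`** — changed-region size and grid location from thresholded
  RGB differences, Weibull scale/shape of gradient-magnitude (contrast)
  distributions, and synthetic image-pair fixtures with known ground truth.
- **`mrp.analysis`** — per-participant AUC summaries by eccentricity stratum,
  per-dxc proportion curves with bin-wise tests, per-image-pair delta-tdxc
  classification (grey/blue/red/black + ANOVA interaction flag), and
  likelihood-ratio plumbing for externally fitted mixed models.
- **`mrp.io`** — canonical CSV response schema with validation, catch-trial
  exclusion filtering, run configuration, and a deterministic
  simulate -> exclude -> score -> report pipeline.

Everything is generated programmatically; no data downloads are required.

## Command line

```bash
mrp simulate --experiment exp2 --n-participants 8 --n-pairs 34 --seed 1 --out resp.csv
mrp score --responses resp.csv --task present_vs_null --out auc.csv
mrp report --responses resp.csv --out-dir report/
mrp design --experiment exp2 --seed 1 --out design.csv
mrp image-stats --pair a.png b.png --out stats.csv
mrp run --out out/            # full pipeline with default config
```

`mrp run --config cfg.yaml` accepts a YAML file with the fields of
`mrp.io.RunConfig` (experiment, preset, seeds, alpha levels, catch-trial
parameters, image thresholds). Outputs are byte-identical across reruns of
the same config.

## Python quick start

```python
from mrp import design, simulate, analysis

plan = design.build_design("exp2", n_participants=8, seed=1, n_pairs=34)
responses = simulate.simulate_responses(plan, simulate.get_preset("exp2-default"), seed=1)
per_participant = analysis.auc_summary(responses, "present_vs_null")
print(analysis.summarize_auc(per_participant))
```
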