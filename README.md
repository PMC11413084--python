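# tauconcord

Concordance analysis between tau-PET imaging and quantitative tau
neuropathology, with a fully synthetic ground-truth data generator.

## The scientific problem

[18F]flortaucipir PET visualizes aggregated tau in the living brain, but its
validity rests on post-mortem comparison with the actual pathology: AT8
immunohistochemistry (IHC), where antibody-positive structures are stained
brown by the DAB chromogen against a blue-purple hematoxylin counterstain.
Such validation studies ask, per brain region and per subject:

- How well does the PET signal (SUVR, the regional activity divided by an
  inferior-cerebellar reference activity) track the **% AT8-positive area**
  measured on digitized slides?
- At what pathology burden does a composite PET measure become positive at
  the standard cut-offs (temporal meta-ROI SUVR ≥ 1.36, cortical meta-ROI
  SUVR ≥ 1.19)?
- How concordant are binary PET and pathology calls, with exact small-sample
  confidence intervals?
- Is the SUVR-pathology relationship linear in ordinal stage codings (Braak
  I–VI) versus rank-based sextiles of burden?

Real post-mortem cohorts are small and unavailable; `tauconcord` implements
the full measurement-and-inference chain and pairs it with a synthetic cohort
and histology-image generator whose ground truth is exact, so every stage can
be validated quantitatively.

## What is in the package

| module | contents |
| --- | --- |
| `tauconcord.synthetic` | cohort generator (latent severity → regional burden → Braak/Thal/ADNC staging → SUVR with gamma test-retest noise) and histology-field renderer with exact planted % positive area |
| `tauconcord.ihc` | % AT8-positive area by (a) per-subject stain-score thresholding of s = max(0, R−G) and (b) graph-cut MRF segmentation solved exactly by s–t min cut |
| `tauconcord.graphcut` | binary MRF solver: E(L) = Σ U_p(L_p) + λ Σ exp(−(I_p−I_q)²/2σ²)[L_p≠L_q], globally minimized via `scipy` max-flow |
| `tauconcord.pet` | SUVR, temporal (4-member) and cortical (13-member) meta-ROI composition, positivity calls |
| `tauconcord.stats` | Spearman mid-rank correlation (exact permutation p for n ≤ 10), Youden-index detection thresholds, Clopper–Pearson exact binomial CIs, nested linear-vs-polynomial F/AIC comparison, gamma GLM (IRLS), PART classification, subgroup queries |
| `tauconcord.pipeline` / `tauconcord.cli` | reproducible simulate → quantify → petcalc → analyze → report runs driven by one YAML-serializable config and one seed |

## Worked example

Rendering a 512×512 field with a planted 0.85 % positive area and
quantifying it both ways (`examples/01_quantify_field.py`):

```text
planted truth: 0.8499% AT8-positive area
threshold method: t = 29.24, estimate = 0.8507%
graph-cut method: estimate = 0.8499%, Dice vs truth = 1.000
```

Running the full pipeline on a simulated 63-subject cohort
(`examples/02_cohort_pipeline.py`):

```text
region:entorhinal  rho = +0.943  p = 6.53e-31  n = 63
meta:temporal      rho = +0.957  p = 2.14e-34  n = 63
meta:cortical      rho = +0.950  p = 1.93e-32  n = 63

temporal  detection threshold = 0.710% (J = 0.951)
cortical  detection threshold = 0.388% (J = 0.976)

temporal  concordance = 0.968 (95% CI 0.890-0.996, n = 63)
cortical  concordance = 0.984 (95% CI 0.915-1.000, n = 63)
```

Exact concordance intervals at n = 63 (`examples/03_concordance_interval.py`):

```text
temporal: 53/63 concordant -> accuracy 0.841 (95% CI 0.727-0.921)
cortical: 59/63 concordant -> accuracy 0.937 (95% CI 0.845-0.982)
```

The same pipeline is available as a CLI:

```sh
tauconcord simulate --seed 4 --out fixtures_dir
tauconcord analyze --cohort fixtures_dir/fixtures --out results_dir
tauconcord all --seed 4 --out results_dir
```

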