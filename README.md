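# mcqcpm

Connectome-based predictive modeling (CPM) of maladaptive metacognition and
its consequences for emotional distress.

Maladaptive metacognition — measured by the 30-item Metacognition
Questionnaire (MCQ-30) with its five subdimensions CC (cognitive
confidence), POS (positive beliefs about worry), CSC (cognitive
self-consciousness), NEG (negative beliefs about uncontrollability and
danger of worry) and NC (need to control thoughts) — is linked to anxiety
and depression. This package provides a tested, reusable pipeline for
asking which resting-state functional-connectivity (FC) networks predict
each subdimension, whether the subdimension score mediates the path from
network strength to emotional distress (PANAS positive/negative affect,
BAI anxiety, BDI depression), and whether the baseline network predicts
longitudinal *change* in those outcomes.

It is aimed at researchers with per-subject ROI time series (or precomputed
FC matrices), an atlas node table, and a behavioral table. Because such
cohorts are rarely shareable, the package ships a synthetic-cohort
generator with planted ground truth (known predictive edges, known
mediation paths, known longitudinal coupling) so that every stage of the
pipeline is verifiable end-to-end without any scanner data.

## The method

For each subject, FC edges are Fisher-z-transformed Pearson correlations
between ROI mean BOLD series, `z_ij = atanh(r_ij)`, optionally after
scrubbing frames with framewise displacement above 0.5 mm. For a behavior
`y`, CPM proceeds per cross-validation fold:

1. **Edge selection.** For every edge `k`, compute the partial correlation
   `r_k` between edge and behavior across training subjects, controlling
   for age, gender and head motion; keep edges with two-tailed `p < 0.01`
   (`t = r√(df/(1−r²))`, `df = n − 2 − k`), split by sign into a
   positively and a negatively correlated network.
2. **Summed strength.** Per training subject, `S = Σ_{k ∈ mask} z_k`
   (edge signs retained).
3. **Linear model.** Fit `y = β₀ + β₁ S` on the training subjects, apply
   it to the held-out subject's strength.

Model quality is the Pearson correlation between observed and predicted
scores over held-out subjects (leave-one-out by default; repeated tenfold
with averaged predictions as an alternative). Significance is a one-tailed
permutation test — behavior labels shuffled, the *entire* pipeline
(selection included) rerun — with the plus-one estimator
`p = (#{r_null ≥ r_obs} + 1)/(n_perm + 1)`, and Benjamini–Hochberg FDR
across the five subdimensions within each tail. Selected networks are then
described anatomically (intra/inter-network edge counts, node degrees,
pairwise edge intersections between dimensions), fed into a single-mediator
model (network mean FC → subdimension score → outcome; percentile
bootstrap CI for the indirect effect `a·b`), and used as a restricted edge
universe for predicting annualized outcome change,
`((t2 − t1)/interval_days) × 365`.

## Worked example

```bash
mcqcpm run --out results/demo --seed 1
```

simulates a 120-subject, 60-node cohort in which 50 edges are coupled to
the CSC score at population correlation 0.5, runs CPM for all six
behavioral measures and both tails (200 permutations), and prints:

```
dimension     tail         r   p_perm  n_selected_full  n_consensus   q
    MCQ30 positive -0.213581 0.786070                3            1 NaN
      ...
      CSC positive  0.446151 0.009950               54           52 0.049751
      ...
       NC negative  0.052844 0.407960                9            2 0.616915
```

Only the planted CSC-positive network predicts its score (observed-vs-
predicted r = 0.45, permutation p = 0.01, surviving FDR with q = 0.0498);
the 52-edge consensus mask recovers the 50 planted edges. The mediation
stage then finds exactly the planted CSC → BAI path significant (indirect
effect 0.232, bootstrap 95% CI [0.117, 0.363]) while the unplanted paths'
CIs cover zero, and the longitudinal stage shows the planted baseline
network predicting annualized change in the coupled outcomes (e.g. BAI:
r = 0.30, p = 0.01 across the 106 subjects with follow-up).

The same stages are available piecewise: `mcqcpm simulate`, `mcqcpm cpm`,
`mcqcpm networks`, `mcqcpm mediate`, `mcqcpm longitudinal` and
`mcqcpm describe` (descriptives plus the covariate-adjusted correlation
matrix). Equivalent library calls are `generate_cohort`, `cpm_loocv` /
`cpm_kfold`, `permutation_test`, `count_by_network` / `node_degree` /
`coincidence`, `mediate`, and `predict_change`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full demonstration analysis from scratch — simulation, CPM
with permutation significance for every dimension and tail, FDR, network
anatomy, mediation and longitudinal prediction — writes the result bundle
next to the JSON output, and prints the summary tables. All randomness
derives from `--seed`.

## Repository layout

- `src/mcqcpm/connectome.py` — scrubbing, Fisher-z FC, edge vectorization, atlas I/O
- `src/mcqcpm/synthetic.py` — cohort generator with planted ground truth
- `src/mcqcpm/cpm.py` — edge selection, LOOCV / k-fold CPM, permutation test, FDR
- `src/mcqcpm/anatomy.py` — network edge counts, node degree, coincidence
- `src/mcqcpm/mediation.py` — bootstrap single-mediator model
- `src/mcqcpm/longitudinal.py` — annualized change, restricted-universe CPM
- `src/mcqcpm/behavior.py` — reliability, paired tests, partial correlations
- `src/mcqcpm/pipeline.py`, `cli.py` — orchestration and the `mcqcpm` CLI
- `docs/methods.md` — the model, its assumptions and numerical choices
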