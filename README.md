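# stressbci

A tested re-implementation of an EEG-based mental-stress classification
pipeline for adolescents with and without autism spectrum disorder (ASD).
Participants alternate between timed mental-arithmetic stress induction and
slow-breathing recovery (unguided, or guided at ~6 breaths/min) while
16-channel 10–20-montage EEG is recorded at 125 Hz; classifiers decode the
current condition — *baseline*, *stressor*, *unguided breathing*, *guided
breathing* — from 1 s EEG windows. The pipeline covers:

* **Synthetic sessions** — the study's raw EEG was never released, so a
  first-class generator produces labeled sessions with the protocol's
  schedule (120 s baseline; 4 blocks of 90 s stressor + 200 s breathing),
  condition-dependent theta/alpha/beta band power with state-specific scalp
  topographies, 1/f background, sub-1 Hz drift, 60 Hz mains, and 5-point
  stress self-reports.
* **Preprocessing** — zero-phase 1–50 Hz band-pass (≥ 20 dB down at 0.5 and
  60 Hz, ≤ 1 dB ripple in 2–45 Hz), impedance-style recording rejection,
  cropped window extraction, stratified seeded splits (80:20 SVM, 70:30
  deep).
* **FBCSP-SVM** — nine 4 Hz bands over 4–40 Hz, per-band common spatial
  patterns (generalized eigenvectors of the class covariances, m = 2
  pairs), normalized log-variance features, binary RBF-SVM (γ = 1/360,
  C = 1.6) on four condition pairs.
* **Seven deep architectures** — 1/2/3-layer LSTM stacks (50/40/40 units),
  Deep ConvNet, Shallow ConvNet, EEGNet and LSTM-FCN, built on a compact
  in-package numpy NN engine (hand-derived backprop, Adam, categorical
  cross-entropy; fully seeded and deterministic on CPU).
* **Evaluation & statistics** — confusion matrices, class-wise
  sensitivity/specificity/precision, precision–recall curves; Wilcoxon
  signed-rank, Mann–Whitney U and Spearman correlation with documented tie
  conventions; exact recomputation of the published result tables, which
  ship as CSV fixtures.

At its core, CSP solves, per frequency band and class pair, the
generalized eigenproblem C₁ w = λ (C₁ + C₂) w for spatial filters w that
maximize the class variance ratio; the deep models instead learn the
discrimination end-to-end from the filtered multichannel time series. See
`docs/methods.md` for the full model description and its assumptions.

## Worked example

```
$ python examples/02_fbcsp_condition_pairs.py
window counts: {'baseline': 120, 'stressor': 360, 'unguided': 400, 'guided': 400}
guided_vs_stressor           holdout accuracy = 1.000
baseline_vs_stressor         holdout accuracy = 1.000
unguided_vs_guided           holdout accuracy = 1.000
unguided_vs_stressor         holdout accuracy = 1.000
```

One synthetic session yields 120/360/400/400 labeled windows per class
(the same imbalance direction as the study: breathing periods are longer
than stressors). Under the generator's strong default condition contrasts
the filter-bank CSP + SVM stage separates every pair essentially
perfectly; chance is 0.5 per pair.

```
$ python examples/05_published_table_statistics.py
...
ASD mean accuracy          93.33%
neurotypical mean accuracy 93.16%
Mann-Whitney U = 17.0, two-sided p = 0.566 (no group difference)
Spearman rho (accuracy vs STAI-C trait anxiety) = 0.0393 (virtually no correlation)
```

These are the published per-participant two-layer-LSTM accuracies and
trait-anxiety scores, recomputed from the packaged table fixtures: model
performance does not differ between the ASD and neurotypical groups and is
uncorrelated with trait anxiety. The script also lists the printed table
averages that disagree with the mean of their own printed cells (flagged,
never silently corrected).

Other examples: `01_simulate_session.py` (session structure and band
power), `03_train_lstm.py` (two-layer LSTM training, confusion matrix,
class-wise rates), `04_behavioral_statistics.py` (pre/post-stressor
Wilcoxon tests on a simulated cohort).

A thin CLI wraps the same library: `stressbci simulate | preprocess |
fbcsp | train | stats | run-all` (see `stressbci --help`); `run-all`
executes the full simulate → reject → window → classify → report chain
and writes a manifest with per-stage seeds and output checksums.

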