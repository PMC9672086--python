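# bedmot

Sentiment-based motivation analysis for online binge-eating-disorder (BED)
treatment cohorts.

Patients entering guided internet-based CBT for BED write free-text answers
to two questions — what they want from therapy, and why they chose an online
programme. Clinicians code each answer onto the ordered
self-determination-theory (SDT) spectrum of extrinsic motivation,

```
external < introjection < identification < integration
```

(controlled → autonomous). `bedmot` provides the quantitative machinery to
ask whether the *emotional tone* of those answers tracks that ordering, and
whether either predicts treatment outcome or adherence:

* **Sentiment scoring** — a hybrid lexicon/rule polarity scorer in the
  Sentida family: word valences in [−5, 5], adjusted for intensity
  modifiers, non-interrogative negation and exclamations, pooled per
  document by sum, arithmetic mean, or a *partitioned signed geometric
  mean* defined for any mix of positive, zero and negative valences:
  with P the positives, N the negatives and n the total count,
  g⁺ = gmean(P), g⁻ = gmean(|N|), score = (|P|·g⁺ − |N|·g⁻)/n.
* **Instruments** — BED-Q (9-item BED severity screen, items 1–7 sum to
  0–35 with six bands), the Major Depression Inventory (cut-offs
  21/26/31), screening eligibility (severe BED or MDI > 40 excludes),
  and programme-completion categories (Low < 6 sessions, Full = 10 plus
  follow-up, High otherwise).
* **Ordinal inference** — for each motivation-grouped variable: the
  signed Jonckheere–Terpstra trend test T_JT (tie-corrected normal
  approximation or exact/Monte-Carlo permutation), Brown–Forsythe
  homoscedasticity F_BF, tie-aware Kendall τ_B with a seeded bootstrap
  95% CI, and the dual significance rule: a cell counts only if
  p(T_JT) ≤ 0.05 **and** |τ_B| exceeds the recommended minimal practical
  effect size (RMPE = 0.2) with the CI not reaching both −0.2 and +0.2.
  Pre/post outcomes get a two-way mixed ANOVA (time × motivation
  interaction).
* **Synthetic cohorts** — real patient statements are not shareable, so a
  seeded generator emits cohorts with the structure the analysis assumes
  (printed motivation-label distributions, a polarity–motivation link
  calibrated to population τ_B ≈ 0.31, treatment effects with no
  motivation effect on outcomes, a negative young-adult
  polarity–adherence link), making every stage testable end to end.

## Worked example

`examples/04_simulate_and_analyze.py` generates the default synthetic
cohort (n = 148, 19 young adults) and runs the full pipeline:

```
cohort: n = 148, 10.1% male, 19 young adults

polarity trend cells (the study's headline analysis):
  therapy_aims         all: T_JT = +4.95 (p = 7.7e-07), tau_b = +0.32 (+0.21, +0.42) overall: True
  therapy_aims       adult: T_JT = +4.46 (p = 8.2e-06), tau_b = +0.31 (+0.17, +0.42) overall: True
  ...
young-adult polarity vs completion (why-online):
  tau_b = -0.34 (-0.64, +0.01), n = 19

time x motivation ANOVA interactions (null by construction):
  therapy_aims bedq: F(2,126) = 2.64, p = 0.08
  ...
```

Reading this: sentiment polarity rises with motivation autonomy
(positive T_JT, τ_B ≈ 0.3 clearing the dual rule), young adults show a
negative polarity–completion association, and the outcome ANOVAs stay
null — exactly the effect structure the generator was configured with.

The same pipeline runs on real data from the shell:

```bash
bedmot simulate --seed 1 --out sim/                      # or bring your own cohort.csv
bedmot score   --lexicon sim/lexicon --pooling gmean --in statements.csv --out polarity.csv
bedmot analyze --cohort sim/cohort.csv --lexicon sim/lexicon --seed 1 --out results/
```

`analyze` writes `trend_grid.csv`, `correlation_grid.csv`,
`anova_grid.csv`, `completion.csv`, a JSON bundle and a run log.

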