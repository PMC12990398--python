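# ppdnet

Sleep-quality trajectories across pregnancy and the postpartum period,
and the depressive-symptom networks that go with them.

`ppdnet` is a Python re-implementation, as a tested and reusable
library, of a perinatal-epidemiology analysis pipeline:

1. **Group-based trajectory modelling (GBTM).** Repeated Pittsburgh
   Sleep Quality Index (PSQI) totals (0–21, four waves from the first
   trimester to 42 days postpartum) are modelled as a finite mixture of
   polynomial mean trajectories with a censored-normal outcome,

   y<sub>it</sub> = Σ<sub>d</sub> β<sub>jd</sub> t<sup>d</sup> + ε<sub>it</sub>,  ε<sub>it</sub> ~ N(0, σ²),

   censored to [0, 21], with within-group growth variance fixed at
   zero.  Subjects contribute only their observed waves (full-
   information maximum likelihood).  Model choice uses BIC/AIC on the
   log-likelihood scale, entropy, a 5% minimum group share, and the
   adequacy diagnostics AvePP (> 0.7), OCC (≥ 5) and |EP − P| (< 0.05).
2. **Association statistics.** A Jeffreys–Zellner–Siow Bayes-factor
   t-test on Edinburgh Postnatal Depression Scale (EPDS) totals between
   trajectory groups; logistic regression of probable depression
   (EPDS ≥ 13) on the trajectory indicator, crude and covariate-
   adjusted; and the item-7 sensitivity analysis with
   z = (B₁ − B₂)/√(SE₁² + SE₂²).
3. **Ising symptom networks (eLasso).** EPDS items binarized
   (0 = absent, 1–3 = present), one L1-penalized logistic regression
   per node with extended-BIC penalty selection (γ = 0.25), AND-rule
   symmetrization, strength centrality, case-dropping bootstrap with
   the CS coefficient, and a permutation network-comparison test on
   the maximum edge difference (M) and global-strength difference (S).
4. **Simulated interventions (NodeIdentifyR-style).** Gibbs sampling
   from the estimated Ising networks; each symptom's threshold is
   shifted by ±2·SD(τ) (aggravating/alleviating) and the projected
   change in the expected symptom sum score ranks intervention targets.

The original cohort is not publicly deposited, so the package ships a
synthetic-cohort generator (`ppdnet.datasets`) with the same design:
two to four latent trajectory groups over four waves, censored-normal
sleep scores, missing-completely-at-random follow-up, group-specific
Ising-distributed symptom items, and realistic demographic covariates.
Every estimator is validated against this generator's known truth.

## Worked example

```python
import ppdnet

cfg = ppdnet.default_two_group_config(n_subjects=372, missing_rate=0.1,
                                      seed=11)
data = ppdnet.generate_cohort(cfg)

report = ppdnet.select_model(data, k_range=(2, 3, 4), seed=0)
print(report.candidates[["n_groups", "orders", "bic_subjects",
                         "entropy", "min_share"]])
```

```
   n_groups orders  bic_subjects   entropy  min_share
0         2     11  -2769.892162  0.943529   0.454495
1         3    110  -2774.527385  0.847614   0.048340
2         4   1031  -2781.476520  0.909980   0.016931
```

The two-group linear model ("11") has the best (closest-to-zero) BIC;
the four-group candidate is excluded by the 5% minimum-share rule.  The
recovered shares (45.4%/54.6%) match the generating truth
(41.4%/58.6%) to within sampling error, and entropy 0.94 indicates a
crisp classification.

```python
fit = report.chosen
post = ppdnet.posterior_matrix(fit, data)
labels = ppdnet.assign_groups(post)
X = ppdnet.binarize_items(data.item_table[labels == 0])
net = ppdnet.fit_elasso(X)
print(ppdnet.strength_centrality(net).attrs["core_symptom"])
```

which prints the maximal-strength node of the poor-trajectory
network (`item5` for this seed).

The command-line interface mirrors the library
(`ppdnet run-all --seed 1 --out results/`, plus per-stage subcommands
`simulate`, `fit-gbtm`, `select`, `associate`, `network`, `stability`,
`nct`, `nira`).

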