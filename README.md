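# adaptrial

Simulation and evaluation of **Bayesian adaptive two-arm trials with binary
outcomes**, aimed at quality-improvement (QI) work in high-throughput health
services: settings where two low-cost, low-risk variants of a programmatic
change (a reminder-message wording, a referral-card image, ...) are compared
on a binary endpoint such as clinic attendance, and even a 1-point
improvement is worth detecting quickly.

Classical fixed-size RCTs are awkward here — effect sizes are small and
uncertain, so power calculations either overshoot or undershoot.
`adaptrial` lets you configure an adaptive design and *stress-test it by
simulation* before running it: error rates, sample-size distributions,
coverage, bias, and the probability of adopting the better variant.

## The model and design

Outcomes per arm are binomial, parameterised on the log-odds scale:

    X_A ~ Binomial(n_A, p_A),   X_B ~ Binomial(n_B, p_B)
    logit(p_A) ~ N(0, precision 0.3)          # ≈ logit of uniform(0,1)
    log(OR)    ~ N(0, σ²)                     # the only substantive belief
    p_B = expit(logit(p_A) + log(OR))         # derived, no prior of its own

Three named priors on the odds ratio: **neutral** (95% CrI 1/30–30),
**moderate sceptical** (0.82–1.22, i.e. differences beyond ~5 points
unlikely) and **extreme sceptical** (0.92–1.08, ~2 points).

A design is an interim schedule (first look and batch size per arm), two
posterior-probability thresholds and a cap:

* **efficacy**: stop when `max(Pr(Δ>0), Pr(Δ<0)) ≥ S`, declaring the arm
  with the higher posterior mean success probability superior
  (Δ = p_B − p_A);
* **equivalence**: stop when `Pr(|Δ| < 0.01) ≥ E` (±1-point indifference
  zone); equivalence takes precedence if both fire;
* otherwise continue to the next look, up to a total cap (100,000 by
  default) at which the trial is *inconclusive*.

Simulated trials are classified against the truth as true/partial
efficacy, true/spurious equivalence, false efficacy, or inconclusive, and
aggregated into operating characteristics. A fixed-size RCT comparator
(adopt whichever arm looks better at the end, no prior, no interims) is
included for head-to-head adoption-probability comparisons.

## Worked example

```python
import adaptrial as at

design = at.reference_design()            # neutral prior, looks every 50/arm, S=E=95%
scenario = at.ScenarioSpec(0.50, 0.51)    # arm B truly 1 point better
results = at.run_replicates(design, scenario, n_reps=500, master_seed=11)
oc = at.operating_characteristics(results, scenario, design.indifference_halfwidth)
print({k: round(v, 3) for k, v in oc.rates.items() if v})
print(oc.sample_size_median, (oc.sample_size_q1, oc.sample_size_q3))
```

prints

```
{'true_efficacy': 0.81, 'false_efficacy': 0.164, 'spurious_equivalence': 0.026}
2800.0 (500.0, 13325.0)
```

i.e. with a true 1-point improvement this design finds the right arm 81% of
the time, is fooled into declaring the *wrong* arm superior 16% of the
time, and typically finishes after ~2,800 participants (but the upper
quartile runs past 13,000). The same sweep over designs and scenarios is
available from the shell:

```bash
adaptrial simulate --design II --scenario 0.5,0.51 --reps 500 --seed 11
adaptrial sweep --designs reference,II --reps 1000 --seed 1 --out results/
adaptrial report results/
adaptrial rct --total-n 10000 --scenario 0.5,0.52 --reps 1000 --seed 1
```

`sweep` writes one trial-level CSV per (design, scenario), an aggregated
operating-characteristics CSV and a seed manifest; `report` turns a sweep
directory into summary tables and plots. Designs can also be given as flat
YAML/JSON configs (see `adaptrial.design.load_config`).

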