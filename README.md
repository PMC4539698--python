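# copdce

A Markov cohort cost-effectiveness model of long-acting bronchodilator
therapy in moderate-to-very-severe COPD, built for a Swedish setting.  The
package compares adding tiotropium (TIO, a LAMA) to usual non-LAMA care (UC)
against usual care alone, and tiotropium against glycopyrronium (GLY,
another LAMA), over the cohort's remaining lifetime.  It is aimed at health
economists and modellers who want a fully scripted, testable version of this
class of analysis: every input is a plain configuration file, every result
is recomputed from it, and the mortality synthesis is calibrated rather than
copied from an external life table.

## Model

Patients occupy one of four states — GOLD II, GOLD III, GOLD IV (moderate,
severe, very severe airflow limitation) and death — and move between them in
three-month cycles from age 65 until death or age 100.  Within each cycle a
patient experiences exactly one of: no exacerbation, a non-severe
exacerbation, or a severe (hospitalisation-requiring) exacerbation, with
state- and arm-specific probabilities.  Each state–event combination carries
a direct cost c(s, e) (SEK 2014, maintenance plus event cost) and an annual
utility weight u(s, e).  Per cycle of length L = 0.25 y with discount rate
r = 3 %/y, an arm accrues

    cost_k = Σ_s π_k(s) [ Σ_e P(e|s) c(s,e) + d·1{on treatment} ] (1+r)^-(k-1)L
    QALY_k = Σ_s π_k(s)   Σ_e P(e|s) u(s,e) L                     (1+r)^-(k-1)L

where π_k is the alive-state occupancy and d the drug cost per cycle
(price/day × 365.25 × L).  After the events, state- and age-specific death
probabilities apply — with an additive per-event excess for the severe
fraction — and survivors transition by a phase-specific matrix (first cycle,
on treatment, off treatment).  Treatment lasts 4 years; afterwards both
transition and event probabilities revert to usual-care values.  Arms are
compared by the incremental cost-effectiveness ratio ICER = ΔC/ΔQALY and by
net monetary benefit NMB(λ) = λ·ΔQALY − ΔC.

Mortality is synthesised, not tabulated: a Gompertz–Makeham law fitted to
Swedish-type all-cause mortality (COPD-attributed deaths removed) carries a
GOLD-state relative risk applied on the hazard scale and a per-event severe-
exacerbation excess, each with a per-decade age gradient.  The two free
scales of that excess structure are calibrated by nested root-finding so
that the UC and GLY arms reproduce published discounted life-expectancy
anchors (10.18 and 9.93 years); the TIO arm is left out of the fit and
serves as an out-of-sample prediction.

Uncertainty is handled twice: a one-way deterministic scenario table
(discounting, horizon, treatment duration, start age, initial GOLD mix,
mortality structure, the severe-exacerbation relative risk, costs, utility
decrements) and a 10,000-iteration Monte Carlo PSA (lognormal relative risk
parameterised from its 95 % CI; every cost and utility cell uniform ±20 %)
summarised as cost-effectiveness acceptability curves.

## Worked example

```python
from copdce import economics, engine, fixtures, mortality

params = fixtures.base_case_parameters()          # packaged published inputs
cal = mortality.calibrate(params.anchors, params) # pin the two mortality scales
params = mortality.apply_scales(params, cal.state_scale, cal.sevex_scale)

results = {arm: engine.run_cohort(arm, params) for arm in ("UC", "TIO", "GLY")}
inc = economics.incremental_analysis(results["UC"], results["TIO"])
print(f"TIO vs UC: dC={inc.delta_cost:.0f} SEK, dQ={inc.delta_qalys:.3f} QALY, "
      f"ICER={inc.icer:.0f} SEK/QALY")
```

prints

```
TIO vs UC: dC=13789 SEK, dQ=0.045 QALY, ICER=307514 SEK/QALY
```

meaning: over the cohort's lifetime, adding tiotropium costs an extra
SEK 13,789 per patient (drug costs of SEK 16,534 partly offset by
SEK 2,746 of avoided exacerbation and maintenance costs), buys 0.045
quality-adjusted life years, and therefore costs about SEK 308,000 per QALY
gained — below the implicit Swedish willingness-to-pay threshold of roughly
SEK 600,000 per QALY.  The same workflow with `results["GLY"]` as reference
gives the LAMA head-to-head comparison (ICER ≈ SEK 8,600 per QALY, driven
by glycopyrronium's higher severe-exacerbation risk).  The equivalent shell
workflow is `copdce run`, with `copdce dsa` and `copdce psa` for the
sensitivity analyses.

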