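# Base-case inputs for the Swedish COPD cost-effectiveness model.
#
# Sources: three-month GOLD-state transition probabilities and baseline
# exacerbation risks derived from the UPLIFT trial by Hettle et al. (UK
# cohort model); the severe-exacerbation relative risk of glycopyrronium vs
# tiotropium from the SPARK head-to-head trial; Swedish maintenance costs by
# GOLD state from Jansson et al.; exacerbation event costs from Andersson et
# al. (mild and moderate merged into "non-severe"); utility weights from
# Ståhl et al. with exacerbation decrements from Hoogendoorn et al.
# (non-severe -1.66%, severe -4.82%, applied to the annual weights).
# All costs in SEK 2014. State order everywhere: [GOLD II, GOLD III, GOLD IV].

settings:
  discount_rate_annual: 0.03       # both costs and effects
  cycle_length_years: 0.25
  start_age_years: 65              # UPLIFT mean age; Swedish retirement age
  max_age_years: 100
  treatment_duration_years: 4      # observed UPLIFT treatment duration
  initial_distribution: [0.48, 0.44, 0.08]   # UPLIFT GOLD distribution

drug_cost_per_day:                 # SEK/day, Swedish list prices
  UC: 0.0
  TIO: 12.77                       # tiotropium 18 ug (Spiriva HandiHaler)
  GLY: 10.48                       # glycopyrronium 44 ug (Seebri Breezhaler)

# Three-month transition probabilities between alive GOLD states,
# conditional on survival (death handled by the separate Swedish mortality
# schedule).  Rows: from-state [II, III, IV]; columns: to-state [II, III, IV].
# The first cycle has its own matrix capturing the initial 30-day
# bronchodilator response; glycopyrronium shares the tiotropium matrices
# (equivalent effect on lung function in GLOW1-2, SPARK and network
# meta-analyses), and all arms revert to usual-care subsequent-cycle
# probabilities once treatment stops.
transitions:
  UC:
    first_cycle:
      - [0.86, 0.13, 0.01]
      - [0.13, 0.81, 0.06]
      - [0.02, 0.22, 0.76]
    subsequent:
      - [0.91, 0.09, 0.00]
      - [0.08, 0.88, 0.04]
      - [0.00, 0.13, 0.87]
  TIO:
    first_cycle:
      - [0.92, 0.08, 0.00]
      - [0.17, 0.80, 0.03]
      - [0.03, 0.28, 0.69]
    subsequent:
      - [0.92, 0.08, 0.00]
      - [0.08, 0.88, 0.04]
      - [0.00, 0.12, 0.88]
  GLY:
    first_cycle:
      - [0.92, 0.08, 0.00]
      - [0.17, 0.80, 0.03]
      - [0.03, 0.28, 0.69]
    subsequent:
      - [0.92, 0.08, 0.00]
      - [0.08, 0.88, 0.04]
      - [0.00, 0.12, 0.88]

# Three-month probabilities of exacerbation events per GOLD state
# [II, III, IV].  The no-exacerbation probability is the residual
# complement (published rounded rows need not sum to one).  The
# glycopyrronium column is the published table (tiotropium baseline with
# the SPARK severe RR applied, as printed).
exacerbations:
  UC:
    nonsevere: [0.14, 0.17, 0.18]
    severe: [0.02, 0.05, 0.08]
  TIO:
    nonsevere: [0.11, 0.14, 0.15]
    severe: [0.02, 0.05, 0.08]
  GLY:
    nonsevere: [0.11, 0.14, 0.14]
    severe: [0.03, 0.07, 0.12]

# Direct cost (SEK 2014) per three-month cycle by state [II, III, IV] and
# event: GOLD-state maintenance cost plus the event cost, merged.
costs_sek_per_cycle:
  no_exacerbation: [1284, 3032, 4297]
  nonsevere_exacerbation: [4423, 6170, 7436]
  severe_exacerbation: [27817, 29564, 30830]

# Annual utility weights by state [II, III, IV] and event (baseline GOLD
# weights with the annual exacerbation decrements applied; kept exactly as
# published, including GOLD III printing above GOLD II).
utility_weights_annual:
  no_exacerbation: [0.73, 0.74, 0.52]
  nonsevere_exacerbation: [0.72, 0.73, 0.51]
  severe_exacerbation: [0.69, 0.70, 0.49]

# SPARK: severe-exacerbation relative risk, glycopyrronium vs tiotropium.
relative_risk_severe_gly_vs_tio:
  point: 1.43
  ci_low: 1.05
  ci_high: 1.97

mortality:
  background:
    # Gompertz-Makeham annual hazard a + b*exp(c*age), least-squares fitted
    # to Swedish-type all-cause one-year death probabilities (total
    # population, circa 2012); a parametric stand-in for the national life
    # table, with residual level error absorbed by the calibration scales.
    makeham_a: 1.618574e-3
    gompertz_b: 1.581215e-6
    gompertz_c: 0.129355
    # Share of all-cause deaths with COPD (ICD-10 J44) as underlying cause,
    # removed from the baseline so the GOLD-state excess is not counted twice.
    copd_death_fraction: 0.03
  excess:
    # Mortality relative risk vs the corrected background per GOLD state at
    # the reference age; literature-class point estimates
    # (Garcia-Aymerich / Hoogendoorn-type), free defaults pinned by
    # calibration to the published discounted life-year anchors.
    state_rr: [1.3, 2.0, 3.3]
    state_age_gradient: 0.85     # (RR - 1) multiplier per decade of age
    # Additional death probability per severe exacerbation event at the
    # reference age, growing with age.
    sevex_base_excess: 0.10
    sevex_age_gradient: 1.3      # per-event excess multiplier per decade
    reference_age: 65
    # Calibration degrees of freedom (overwritten by calibrate()).
    state_scale: 1.0
    sevex_scale: 1.0

options:
  # After treatment stops, exacerbation risks revert to usual-care values,
  # mirroring the stated reversion of transition probabilities (little
  # persistence of LAMA effect); set false to keep arm-specific risks for
  # life.
  revert_event_risks_off_treatment: true

# Published discounted life-year anchors used to calibrate the two
# excess-mortality scales; the tiotropium arm is left out and serves as an
# out-of-sample check.
calibration_anchors:
  uc_discounted_ly: 10.18
  gly_discounted_ly: 9.93
  discount_rate_annual: 0.03
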