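# Methods

## Risk model

The package projects the lifetime attributable risk (LAR) of
radiation-induced cancer after an internal exposure. For one cancer site,
sex, absorbed organ dose D (Gy) and age at exposure e:

    LAR(D, e) = Σ_{a = e+L}^{109}  M(D, e, a) · S(a) / S(e+L)

* **Latency L** — no excess risk is attributed for L years after exposure:
  5 years for solid cancers, 2 for leukaemia. The cutoff is hard (no
  phase-in ramp).
* **Survival weighting** — S(a) is the survivorship l(a) from a sex-specific
  annual life table on integer ages 0–110. Normalising by S(e+L) makes the
  result the risk conditional on being alive when risk expression begins.
* **Excess rate** — M combines excess relative risk (ERR, multiplying the
  baseline rate λ(a)) and excess absolute risk (EAR, events per 10⁴
  person-years) additively with a transport weight w ∈ [0, 1]:

      M = f(D)/DDREF · [ w · ERR(e,a) · λ(a) + (1−w) · EAR(e,a)/10⁴ ]

  Both ERR and EAR share the standard age profile
  β · exp(γ e*) · (a/60)^η with e* = (min(e,30) − 30)/10: risk per unit
  dose declines log-linearly per decade of age at exposure up to a cap at
  30, and follows a power of attained age pivoted at 60. f(D) = D for solid
  cancers (with DDREF, default 1.5, for low-dose extrapolation) and
  D(1 + θD) for leukaemia (θ configurable, DDREF 1). Coefficients are
  consumed as configuration — the package does not refit epidemiological
  data, and any transport already applied upstream is expressed through w.

Fifteen sites are tracked (14 specific + an aggregate residual category);
breast, uterus and ovary apply to females only, prostate to males only, so
a male total sums 12 sites and a female total 14. Mortality LAR uses the
same machinery with mortality baseline rates. Per-sex results are never
implicitly averaged.

## Cohort survival modification

A patient cohort with a published k-year survival fraction gets a constant
annual survival probability ASP = fraction^(1/k). From exposure age e the
modified survivorship is

    l*(a) = l*(a−1) · min( l(a)/l(a−1), ASP )      for a in (e, e+window]
    l*(a) = l*(e+window) · l(a)/l(e+window)        beyond the window

The min keeps the cohort from ever being healthier than the general
population; after the window the cohort resumes population conditional
survival. The window defaults to max(k, 5) so that it reaches the start of
the solid-cancer integration, and is configurable per cohort.

**Interaction with normalisation.** Both the numerator S(a) and the
denominator S(e+L) use the modified table. A consequence worth stating
plainly: when the window ends exactly at e+L (the default for solid
cancers, window = L = 5), the modification cancels out of the solid-cancer
LAR — conditioning on surviving the latency period absorbs the entire
excess mortality, which all falls inside it. The cohort effect on the total
then flows through leukaemia, whose 2-year latency ends inside the window:
ages e+2 … e+5 carry reduced conditional survival, and the deficit
accumulated between e+2 and the window end persists in every later term.
Cohorts whose excess mortality genuinely persists beyond the published
horizon can be modelled with a longer `window_years`, which depresses solid
LAR as well; the published 2-year figures for the metastasis cohorts say
nothing about later years, so the default stops at the window.

Presets: Paget's disease (0.93 over 5 y, ASP ≈ 0.98559), prostate cancer
with one bone lesion (0.68 over 2 y, ASP ≈ 0.82462) and with multiple
lesions (0.22 over 2 y, ASP ≈ 0.46904), each applied over a 5-year window.

## Dosimetry

Dose coefficients (mGy/MBq) are tabulated at phantom ages 1, 5, 10, 15 and
adult. Interpolation is linear in age between anchors — the simplest
monotone convention and the one standard in dosimetry practice — with the
adult anchor at 25 years for bone seekers (the reference phantom is a
20-year-old except for bone composition) and 20 years otherwise; values are
held constant below age 1 and above the adult anchor. Organ dose is
activity × coefficient × 10⁻³ Gy, linear in administered activity by
construction. Biokinetics behind the coefficients are out of scope; tables
are consumed from CSV.

## Equal-risk protocol

With an all-linear configuration LAR is exactly proportional to
administered activity, so the activity giving a target risk is
A = A_ref · target/LAR(A_ref). The target is the unweighted mean of
LAR(A_ref) over an integer age grid (default 0–90), per sex by default
(`target_scope = "combined"` pools sexes). Acquisition time follows from
count conservation, t = t_ref · A_ref / A around the 500 MBq / 4 min
reference, clamped to the 3–5 min clinical window; a clamped point reports
the boundary time plus the unclamped value and recomputes its activity from
the clamped time, so A·t = A_ref·t_ref holds for every point. The
equal-risk property itself (one shared LAR across ages) is exercised with
the window released, because risk at the reference administration spans
roughly two orders of magnitude between newborns and the elderly and the
clinical window is far narrower. The leukaemia curvature θ must be zero for
the proportionality to be exact; at diagnostic doses (~mGy) the deviation
with the default θ is of order 10⁻⁴ relative, which matters only against
the very tight equalisation tolerances used in the tests.

## Quadrature and numerics

* Annual left-endpoint rectangles on integer attained ages, matching the
  native resolution of life tables and registry rates; the upper limit is
  fixed at age 110. A finer internal step exists for convergence checks.
  Against the constant-hazard closed form m(1−e^(−h(110−e−L)))/h the
  1-year-step relative error is ≈ h/2 (1.0% at h = 0.02, the magnitude of
  mid-life all-cause hazard; 2.5% at an extreme constant h = 0.05), and
  shrinks linearly with the step.
* Fractional ages interpolate survivorship linearly (error ≤ h²/8 per unit
  step on a constant-hazard table); baseline rates interpolate linearly
  between tabulated ages and hold the last value beyond.
* Degenerate inputs: zero dose gives zero LAR; a population extinct before
  e+L is an error ("cohort extinct"); e+L ≥ 110 returns 0 with a warning;
  a total LAR ≥ 1 is rejected as non-probabilistic.
* "1 in N" renderings round N to two significant figures.

## Synthetic generator

Real inputs (national life tables, registry incidence/mortality,
dose-coefficient compendia, fitted risk coefficients) are not
redistributable, so a seeded generator emulates their structure:

* **Mortality** — Gompertz–Makeham, h(u) = c + α·e^(βu), with β = 0.09,
  c = 5×10⁻⁴ and α = 3.2×10⁻⁵ (male) / 2.0×10⁻⁵ (female), giving life
  expectancies of ≈ 80.6 and 85.6 years and l(110) < 0.05 — chosen once as
  a plausible contemporary northern-European population.
* **Incidence** — per-site power law base·max(0, a−onset)^p per 10⁵
  person-years, with bases 0.02–0.08, exponents 1.5–2.5 and onsets 20–40 y
  (leukaemia: flatter, from birth), giving all-site lifetime baseline risks
  of ≈ 28% (male) and ≈ 51% (female) — the right order for lifetime cancer
  incidence. Mortality = incidence × per-site lethality in 0.15–0.9.
* **Dose coefficients** — adult values 0.0008–0.008 mGy/MBq with an
  age-1/adult ratio of 2–10 interpolated geometrically, strictly decreasing
  with phantom age.
* **Risk coefficients** — β_ERR 0.1–1.0 /Gy, β_EAR 0.5–5 per 10⁴ PY/Gy,
  γ −0.4…−0.1, η −1.5…0.5, w 0.3–0.7, drawn once per site with the truth
  recorded for recovery tests.

Draws use independent seeded streams per generator, so outputs are
bit-reproducible and independent of call order. What the generator does
*not* emulate: cohort-vs-period life-table effects, registry noise and
secular trends, correlated site rates, sex-specific risk coefficients, or
any calibration to actual national statistics — so passing tests demonstrate
the correctness of the machinery on structurally realistic inputs, not
agreement with any particular country's published risk values. Reproducing
published population results requires assembling the real inputs in the
documented CSV/TOML formats.

## Problem sizes

Default analyses use the full integer age-at-exposure grid 0–90 for curves
and protocol tables, 1-year quadrature steps to age 110, and 12–14 sites
per sex; coefficient recovery uses exposure ages 5–60 in 5-year steps.
These sizes run in seconds and match the resolution of the underlying
annual tables.

## Known limitations

* No uncertainty propagation on risk coefficients or doses.
* No risk-of-exposure-induced-death feedback of the dose on survival; the
  survival function is the baseline (or cohort) one.
* ERR and EAR share one (γ, η) age profile per site; sources that fit
  separate profiles per scale must be mapped onto w or supplied as two
  parameter sets.
* The cohort ASP is constant over its window; time-varying relative
  survival is not modelled.
* Hereditary effects and tissue reactions are out of scope.
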