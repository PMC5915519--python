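# Methods

## Radionuclide model

²¹¹At decays by two paths that each yield one alpha particle: a direct
alpha branch (41.8 %, 5.867 MeV) and electron capture to ²¹¹Po (58.2 %),
whose 7.450 MeV alpha follows within ~0.5 s. At the hour-scale sampling of
biodistribution studies the daughter is treated as decaying in place
instantaneously, so the scheme is summarised by a half-life (7.214 h) and
the two alpha branches; the branch-weighted mean energy per decay is
6.788 MeV ≈ 1.088·10⁻¹² J. Electron-capture photon/electron emissions and
the long-lived ²⁰⁷Bi granddaughter are excluded — the dose model counts
only locally deposited alpha energy. These constants are configurable
(YAML decay-scheme files), not hard-wired; the shipped values are standard
nuclear data and the published coefficient set is reproduced with them to
within a few percent, though the third digit of the energy constant may
differ from any individual author's choice.

## Dosimetry

Biodistribution tables are assumed **decay-corrected** %ID/g unless flagged
otherwise — the universal reporting convention. Treating the packaged table
as physical instead would inflate the tumor coefficient roughly threefold,
far outside the published value, which empirically confirms the assumption.

The physical activity concentration per unit injected activity is
a(t) = (%ID/g)/100 · e^(−λt). Its time integral Ã (fraction·h/g) is:

* **body** — trapezoid over the sampled interval;
* **head** (unobserved [0, t_first]) — one of three policies:
  `start-at-first-sample` (add nothing; the default), `zero-origin`
  (triangle from (0, 0)), `plateau-back-extrapolation` (rectangle at the
  first sample's value);
* **tail** (beyond t_last) — `physical-decay` (a(t_last)/λ, exact value
  a(t_last)·t½/ln2; the default) or `fitted-effective-decay` (log-linear
  fit to the last k samples; falls back to physical decay with a warning
  when the terminal samples do not decay).

The default head policy was chosen by calibration against the published
coefficient table: integrating from the first sample reproduces tumor and
adrenals within 0.6 %, liver within 3.2 %, blood within 6.5 %, and rounds
the brain coefficient to the printed two decimals (0.02 Gy/MBq), whereas
adding a zero-origin head triangle biases every organ high (liver +9 %)
and rounds brain to 0.03. The original study's exact integration scheme is
described only in supplementary material that is not available, so the
convention that best matches the published table across all organs was
fixed as the default and the alternatives kept selectable.

Two published values are known not to be reproducible from the printed
inputs and are documented rather than targeted: the **heart** (printed
4.08 Gy/MBq; every tested convention gives 3.0–3.6, suggesting the authors
fitted a curve shape the printed five samples do not constrain) and the
**thyroid** (reported per whole organ; a dose requires the organ mass,
which is not printed, so per-organ rows are skipped unless a mass is
supplied).

Dose is linear in everything: table values, administered activity and mean
alpha energy. No cross-organ or remainder-body terms are included
(sub-100-μm alpha range), and no uncertainty is propagated from the SD
columns — the published table is a point estimate and the SDs are carried
only for calibrating the synthetic generator.

## Monitoring and endpoints

Tumor volume is the standard caliper formula length·width²/2 (mm³) with
axes canonicalised so length ≥ width, since raw data-entry order is
unknowable. Relative series are percent of the animal's own day-0 value;
group summaries average per-animal ratios (mean of ratios), the convention
behind reported relative tumor volumes, and linearly interpolate between
flanking observations when the summary day was not measured (no
extrapolation beyond the observed range).

Endpoint rules: analysis events fire at tumor volume ≥ 500 mm³ or
body-weight loss **strictly greater** than 20 % of baseline; husbandry uses
800 mm³. The weight comparison is strict because the defining phrase is
"more than 20 %" — an animal reaching exactly 20 % is not an event, which
is load-bearing for the MTD: the MTD rule returns the highest tested
activity at which no animal exceeded the weight-loss limit, and the
published outcome pattern (one animal at exactly 20 % in the 1.11 MBq
group) yields 1.11 MBq only under the strict comparison. Volume thresholds
are inclusive (≥) for determinism at the printed bound. Records that never
trigger are censored at the earlier of last observation and study end
(day 56); euthanasia for other recorded reasons (e.g. moribund state, which
is not operationalised beyond a recorded fate) censors at its day.

## Survival statistics

Kaplan–Meier uses the product-limit estimator with the standard tie
convention (events before censorings, so same-day censored subjects remain
in the risk set). The log-rank statistic accumulates observed minus
hypergeometric-expected events over distinct event times and is referred to
χ²(1); a configuration with no events returns an undefined marker. The
Dunnett many-to-one adjustment simulates the null max-|t| distribution
(shared control, pooled χ² variance) with a seeded generator — default
100 000 draws — instead of quantile tables, and floors each adjusted
p-value at its unadjusted t-test p-value, the analytic lower bound. Tests
cross-check all three against lifelines, scipy.stats.dunnett, hand-computed
hypergeometric moments and a 10 000-shuffle permutation null.

## Synthetic-data generators

All generators are pure functions of (spec, seed) and return their ground
truth; they emulate statistical structure, not biology.

**Biodistribution**: decay-corrected biexponential organ curves
u(t) = A₀(e^(−λ_clear t) − e^(−λ_up t)) with unit-mean lognormal
inter-animal scatter (default CV 0.4, n = 5 per time point, sampling at
1/3/6/12/24 h). Default tumor kinetics (A₀ = 41.7 %ID/g, λ_up = 1.2 /h,
λ_clear = 0.039 /h) track the reported tumor time-course: peak ≈ 36 %ID/g
near 3 h, ≈ 16 %ID/g at 24 h. The analytic time-integrated activity of the
physical curve is returned as truth; the dosimetry pipeline recovers it
within 2 % on a dense noise-free grid.

**Therapy cohorts**: log-kill response — a fraction f = e^(−αD) of the
tumor survives the absorbed dose D = coefficient × activity and regrows
exponentially after a growth-arrest delay proportional to D·(1 − f) (so
α = 0 reproduces the control exactly), while the killed fraction regresses
exponentially. Defaults: control growth rate g = ln(591.8/48.9)/21 ≈
0.119 /day (the reported day-0 → 21 control means), baseline volume
48.9 ± 7.7 mm³, α = 1.0 /Gy, regression rate 0.15 /day, delay 0.4 d/Gy —
which places the treated-volume nadir near day 21 at 0.56–1.11 MBq. Weight
loss is a pulse depth·(t/τ)e^(1−t/τ) with nadir day τ = 3 and depth
0.42·D_wb^1.75 of a whole-body surrogate dose D_wb = 0.5 Gy/MBq × activity.
The superlinear exponent is forced by the printed day-3 pattern (< 5 % loss
at 0.28–0.56 MBq, 10–20 % at 1.11 MBq, > 20 % at ≥ 1.85 MBq with recovery
by ~day 10 at tolerated activities); a linear per-Gy slope cannot satisfy
all three simultaneously. Multiplicative lognormal measurement noise
(volume CV 0.12, weight CV 0.01) is applied, calipers are back-solved from
volume with a fixed 0.7 width/length aspect ratio, and animals are
truncated at the husbandry endpoint as in study conduct. Lognormal noise is
used throughout for strictly positive quantities.

One known discrepancy in the published summaries is deliberately *not*
reconciled: the reported day-21 control relative volume (509.2 %, mean of
ratios) is inconsistent with the reported group mean volumes
(591.8/48.9 ≈ 1210 %) under any homogeneous growth model. The generator
follows the group-mean calibration, so its control mean-of-ratios is near
1200 %, not 509 %; the summary *convention* (mean of ratios) is what the
package implements and tests.

**In-vitro plates**: readouts ∝ e^(−kc) with lognormal replicate noise at
the reported concentration ladder (0–20 kBq/mL); the monoexponential fit
recovers k exactly at CV = 0 and within 10 % in the mean over 50 seeds at
CV = 0.1.

What passing these tests does **not** show about real data: real
biodistributions are not exactly biexponential, real tumor regrowth is not
a clean two-compartment exponential, and real weight dynamics include
growth and husbandry variation; the recovery tests validate the pipeline's
arithmetic and statistical behaviour, not the biological model.

## Problem sizes and numerics

The test suite uses the packaged 15 × 5 table, dense synthetic grids of
~290 points for integration checks, 10 000 permutations for the log-rank
null, 2 000 simulated experiments (2 000 Monte-Carlo draws each) for the
Dunnett family-wise-error calibration, and 20–50 seeds for the recovery
studies — sizes at which Monte-Carlo error is comfortably below the
asserted tolerances while the whole suite runs in well under a minute.
Degenerate inputs (empty curves/tables, zero baselines, zero pooled
variance, non-decaying tails) raise explicit errors or warned fallbacks as
documented above; round-half-even rounding is used wherever a printed
two-decimal value is compared.
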