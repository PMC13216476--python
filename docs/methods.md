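# Methods

This document records the model, the default parameters and their
rationale, what the synthetic generator does and does not emulate, the
numerical choices, and known limitations.

## 1. Two-compartment kinetic model

State variables (mg/dL equivalents):

- `S(t)` — intravascular (serum) bilirubin;
- `K(t)` — extravascular cutaneous depot (the skin residual, SRBV, is its
  optical contribution `g·K`).

```
dS/dt = p(t) − (c_ser + c_ph(t))·S − k_sk·max(S − S_thr, 0) + k_ks·K
dK/dt =              k_sk·max(S − S_thr, 0) − k_ks·K
p(t)  = p0 · exp(−λ t)
```

- `p(t)` — endogenous production, decaying with postnatal time as the
  haemolytic load resolves.
- `c_ser` — natural (hepatic) serum clearance, always active.
- `c_ph` — additional phototherapy clearance, active only during light
  sessions. It acts on serum only: the measurement site (forehead) is
  shielded by the eye patch, so light does not bleach the depot being
  measured.
- `k_sk`, `k_ks` — serum→skin and skin→serum exchange rates.
- `S_thr` — diffusion threshold (default 3 mg/dL): serum→skin flux is
  proportional to `max(S − S_thr, 0)`. Below ~3 mg/dL bilirubin stays
  intravascular, so the device reads serum directly (the low-bilirubin
  regime exploited for calibration). A purely linear exchange cannot
  produce this regime — `K` would be a fixed fraction of `S` at all
  levels — so the threshold is a structural part of the model, not a
  numerical device.

Observation model:

```
TBL_true = S + g·K                      0 < g ≤ 1 optical gain
TBL_raw  = γ_site · TBL_true · ε_tcb    γ_site: centre device bias
TSB_obs  = S · ε_tsb
```

`ε` are mean-one multiplicative lognormal noises
(`σ² = log(1 + cv²)`), default `cv` 0.05 (TcB) and 0.03 (TSB).

### Why the flip needs the production transient

With constant production the system under a periodic light/break schedule
settles into a periodic steady state in which the break-time delta
(TBL-return − TBL-out) has a fixed, positive sign — the rebound never
reverses. The observed single positive→negative reversal (the recovery
value flip) requires the production transient: early on, `p > c_ser·S`
and the break rebounds; once production has decayed below the clearance
balance, the composite keeps falling during breaks too. The post-flip
delta magnitude is bounded by `break_duration · (c_ser·S − p)`, i.e. a
fraction of a mg/dL — which is why the flip is a subtle signature and
why detection operationalises "consistently lower" as a run of at least
two consecutive negative deltas (or a terminal negative).

## 2. Default parameters

Defaults were frozen after an a-priori design exploration targeting the
qualitative dynamics documented for the field cohort, before any test was
written (see the project decisions ledger).

| Parameter | Default | Units | Rationale |
| --- | --- | --- | --- |
| `serum_clearance` (`c_ser`) | 0.10 × rate_scale | 1/h | dominant clearance post-flip; sets post-flip decline |
| `photo_clearance` (`c_ph`) | 0.05 × rate_scale | 1/h | modest on top of natural clearance; keeps post-flip deltas negative |
| `production_rate` (`p0`) | 2.5 · c_ser · S₀ | mg/dL/h | initial production ≈ 2.5× the clearance balance → early positive deltas |
| `production_decay` (`λ`) | 0.10 | 1/h | places the flip at cycle ~3 of 7 for a ~13 mg/dL baseline |
| `serum_to_skin` (`k_sk`) | 0.25 | 1/h | with `k_ks` sets equilibrium skin partition |
| `skin_to_serum` (`k_ks`) | 0.90 | 1/h | slow drain relative to light clearance → rebound during breaks |
| `optical_gain` (`g`) | 0.9 | — | equilibrium SRBV fraction ≈ 15–20% of the composite |
| `diffusion_threshold` (`S_thr`) | 3.0 | mg/dL | low-bilirubin serum-equivalence regime |
| schedule | 3 h light + 20 min break × 7 | — | study protocol |
| `tcb_cv` / `tsb_cv` | 0.05 / 0.03 | — | typical device/laboratory repeatability |

`rate_scale` is a per-subject (and per-site) multiplier on both
clearances; site values are derived from the published per-site mean
decline rates relative to the rate the default kinetics produce at that
site's baseline, clipped to [0.45, 1.6] so the flip dynamic survives.

## 3. The synthetic cohort

`default_site_specs()` mirrors the published six-site structure: patient
counts (23/23/10/20/13/13 = 102), postnatal-age means/SDs, baseline
composite means and ranges (pooled 6.8–30.4 mg/dL). Baselines are drawn
from range-truncated normals whose parent location is solved (Brent root
finding on the truncated-normal mean) so the *truncated* mean hits the
published site mean. Baselines are specified on the composite scale and
converted to serum by inverting the equilibrium partition.

Centre-specific device gains (0.88–1.15) are invented — the study reports
no device biases — and exist to give the calibration stage something real
to correct. Calibration pairs are drawn from a separate, independently
keyed RNG stream of non-jaundiced neonates (TSB uniform on 0.5–2.9
mg/dL), where the true composite equals serum.

What the generator emulates: site structure, baseline severity
distributions, decline-rate ordering across sites, flip timing and
prevalence, band-stratified SRBV fractions of plausible magnitude, device
bias and measurement noise.

What it does not emulate: individual covariates (gestational age, weight,
feeding), haemolytic aetiology mix, exchange-transfusion cases, missed or
irregular measurements (the I/O layer accepts them; the generator samples
the full protocol), and any between-cycle operational variability in
session length.

## 4. Numerical choices

- Integration: `scipy.integrate.solve_ivp` (LSODA, `rtol = atol = 1e-8`)
  piecewise per light/break segment, so the discontinuous `c_ph(t)` never
  crosses an integration step. Dense output is sampled on a 0.01 h grid
  plus the exact segment boundaries.
- Independent oracle: `euler_reference` re-integrates the same RHS with a
  plain fixed-step forward Euler loop (`dt = 0.001 h`), sharing no code
  with the adaptive path; agreement is asserted to < 0.5% (measured
  ~4 × 10⁻⁵ max relative error over a full course).
- RNG discipline: every stochastic draw comes from
  `SeedSequence([seed, crc32(stream_id)])` with per-subject and
  per-purpose stream ids, so courses are independent, reproducible, and
  insensitive to sampling order.
- Determinism: all pipeline data outputs (CSVs, `provenance.json`) are
  byte-identical under a fixed configuration and seed; the wall-clock
  timestamp appears only in `run_log.txt`.
- Display rounding is half-up (`floor(x + 0.5)`), matching the printed
  summaries; all stored values keep full precision.

## 5. Analysis conventions

- **Calibration**: per-centre regression through the origin
  (`c = Σ tbl·tsb / Σ tbl²`) on pairs with TSB strictly below 3 mg/dL;
  a ratio-of-means alternative is provided. Pooling across centres is
  deliberately impossible in the API.
- **Severity bands** on the composite reading: [0, 9), [9, 11.5],
  (11.5, 15], (15, ∞) mg/dL. Field readings are recorded to 0.1 mg/dL, so
  the closed/open split at 11.5 is lossless there.
- **SRBV records** with negative residuals (device below laboratory) are
  retained and flagged but excluded from fraction summaries, with an
  audit count.
- **Across-site averages** are unweighted means of per-site mean
  percentages — this, not n-weighted pooling, reproduces the published
  across-site row.
- **Flip detection**: first cycle `j ≥ 2` whose predecessor delta is
  non-negative and whose negative delta opens a run of ≥ 2 consecutive
  negatives or is terminal. Courses with baseline ≤ 9 mg/dL are
  classified ineligible (attenuated depot), and < 3 paired cycles is
  insufficient data.
- **Interpretation** is a first-match-wins cascade ordered
  most-conservative first: serum-equivalent (< 3 mg/dL) → persistent
  rebound → flip reached but trend unresolved / still above the discharge
  threshold (default 11 mg/dL) → recovery confirmed → composite
  unresolved (safe upper bound). Every decision carries a full rationale
  trace.

## 6. Deliberate deviations and documented discrepancies

- The published *pre-treatment* across-site cells (20%, 11%) are not
  reproducible under any single rounding rule: the printed site cells
  average to exactly 20.5 and 10.5, and half-up gives 21/11, half-down
  20/10. The acceptance suite documents this instead of forcing it.
- Flip-timing robustness to measurement noise is property-tested at
  `tcb_cv = 0.002`. At the field noise level (cv 0.05) the single-cycle
  noise on a delta (~0.85 mg/dL on ~12 mg/dL readings) exceeds the
  physical post-flip delta scale (~0.1–0.3 mg/dL), so ±1-cycle
  localisation in ≥ 90% of replicates is information-theoretically
  unattainable for any detector; measured: 41% at cv 0.05 versus 97.7% at
  cv 0.002. The default generator noise remains 0.05.
- The diffusion threshold (§1) replaces a purely linear exchange, which
  cannot satisfy the documented low-bilirubin serum-equivalence regime.

## 7. Limitations

- The kinetic model is a deliberately minimal two-compartment caricature:
  no enterohepatic recirculation, no albumin-binding saturation, no
  site-of-measurement heterogeneity.
- Parameter defaults are design choices reproducing qualitative field
  dynamics, not fitted estimates; per-site decline-rate emulation is
  approximate (clipped scaling).
- The flip detector is a rule, not an estimator: it reports cycle indices,
  not a continuous flip time, and inherits the sampling schedule's
  resolution.
- The interpretation cascade encodes the study's monitoring protocol; the
  thresholds (3, 9, 11 mg/dL) are configurable but their defaults are
  protocol-specific, not universal clinical cut-offs.
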