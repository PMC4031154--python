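# Methods

This note documents the models, estimators, numerical choices and known
limitations of `copsway`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external data.

## 1. Trial-level sway parameters

A trial is a uniformly sampled planar COP trajectory, laterolateral `x` and
anteroposterior `y` in mm. The container enforces ≥ 2 samples, strictly
increasing time, and uniform spacing to 1e-9 relative tolerance.

* **Path length** `L = Σ √(Δx² + Δy²)` over consecutive samples. Removing
  intermediate samples can only shorten the path (triangle inequality),
  which the property suite asserts.
* **Velocities** `V = L / T`; `V_AP = Σ|Δy| / T`; `V_LL = Σ|Δx| / T` with
  `T` the trial duration. These obey `max(V_AP, V_LL) ≤ V ≤ V_AP + V_LL`.
* **Mean position** `X, Y`: arithmetic means. Because quiet-stance
  coordinates are centred near zero, no coefficient of variation is ever
  computed for `X` or `Y` (a CV at mean ≈ 0 is undefined), and their %MDC
  values are numerically huge and should not be over-interpreted.
* **90 % prediction ellipse.** The "ellipse containing 90 % of samples" is
  implemented as the covariance-based prediction ellipse: sample covariance
  with the n−1 denominator, eigenvalues λ₁ ≥ λ₂, semiaxes `√(q λᵢ)` with
  `q = χ²(2)` quantile at the requested coverage (4.60517 at 0.90), area
  `π·SA1·SA2`. For Gaussian sway with per-axis SD σ the expected area is
  `π q σ²`; with σ = 10 mm this is 14.47 cm², and the empirical coverage of
  the fitted ellipse on 10⁵ Gaussian points is 0.90 ± 0.01 — both are
  asserted by tests. An exact minimal-area ellipse over 90 % of the points
  is deliberately *not* implemented: the covariance construction is the
  standard in posturography and has a testable closed form.
* **Semiaxis semantics.** SA1/SA2 are principal-axis aligned (major/minor),
  not platform-axis aligned: the tables they feed treat them as magnitude
  summaries, and principal axes make SA1 ≥ SA2 an invariant. The ellipse
  orientation (major-axis angle in (−π/2, π/2]) is returned for users who
  need platform-frame information.
* Units: coordinates stay in mm throughout; the single mm→cm conversion
  happens at the ellipse stage (semiaxes cm, area cm²).
* Degenerate inputs: < 3 samples is an error for the ellipse; collinear
  samples give SA2 = 0, A = 0 with a logged warning rather than an error.

`compute_metrics_batch` evaluates all nine parameters on a stack of trials
sharing a time base; a test asserts bit-level-close equality with the
per-trial path.

## 2. Psychometric estimators

* **CV** (test-retest repeatability within a session): sample SD (n−1) of
  the repeated trials as a percentage of their mean; error if the mean is
  numerically zero.
* **ICC(3,1)** (intrarater across-session reliability): two-way mean
  squares; `ICC = (BMS − EMS) / (BMS + (k−1) EMS)`. The 95 % CI uses the
  F-bounds for this form: `F_L = F_obs / F_{0.975}(n−1, (n−1)(k−1))`,
  `F_U = F_obs · F_{0.975}((n−1)(k−1), n−1)`, each mapped through
  `(F−1)/(F+k−1)`. Complete cases only: subjects missing an occasion are
  listwise-deleted and counted in the exclusion ledger. The implementation
  is verified to 1e-9 against a brute-force ANOVA-decomposition oracle and
  cross-checked (point estimate and CI) against pingouin's ICC(C,1).
* **SEM** `= SD·√(1−ICC)` with SD the pooled SD of *all* values entering
  the ICC (both occasions) — the common convention when the source of the
  SD is unspecified. A negative ICC is clamped to 0 with a warning (SEM
  then equals the pooled SD); ICC > 1 is rejected.
* **MDC95** `= z·√2·SEM` with `z = 1.959964` by default. The z is
  configurable (`--mdc-factor`), e.g. 1.65 for an MDC90-style bound.
  `%MDC = 100·MDC95 / baseline mean`, where the baseline is the cohort mean
  of first-occasion values.
* **Effect size** (responsiveness): `|mean(second − first)| / SD(first)`,
  absolute value so that measures that *decrease* with improvement register
  positive responsiveness.
* **Correlations**: scipy Spearman/Pearson with two-sided p-values, classed
  on Munro's magnitude bands. The conventional band edges are printed at
  two decimals (0.00–0.25 little, 0.26–0.49 low, 0.50–0.69 moderate,
  0.70–0.89 high, 0.90–1.00 very high), which leaves gaps; the midpoints
  0.255/0.495/0.695/0.895 close them, the boundary belonging to the higher
  band.
* **Two-way ANOVA** (vision × support on V): statsmodels OLS with type II
  sums of squares, appropriate for the unbalanced cell counts that
  condition dropout produces; for balanced two-level designs type II equals
  type I (asserted). Both degrees of freedom are always reported
  explicitly.
* Multiple testing: no correction is applied to the validity tables by
  default (matching common practice in clinimetric studies), but a
  Holm-adjusted p-value column is emitted alongside the raw values.
* Significance stars: * p<0.05, ** p<0.01, *** p<0.001.

## 3. Study pipeline

One *record* is a subject × session × condition observation: the arithmetic
mean of the (default 3) trial values per parameter, plus per-parameter trial
CVs, the session's scale scores, and heel distance (feet-apart conditions
only). Groups with < 2 trials are excluded and logged.

* **Condition codes**: vision OE/CE × support OF (feet apart) / CF (feet
  together); FA/FT are accepted as input aliases of OF/CF.
* **Session pairing**: for reliability and responsiveness, each subject
  contributes their *first* pair of consecutive sessions no more than
  `max_gap_days` (default 15) apart; subjects without such a pair are
  excluded and logged. All-pairs averaging was considered and rejected to
  keep the paired sample independent across subjects.
* **Reliability tables**: CV per parameter × condition averaged over all
  records; ICC/SEM/MDC95/%MDC on the paired sessions' trial-averaged
  values; the same bundle for the clinical scales (one value per session).
  Conditions with < 3 eligible paired subjects are skipped and logged.
* **Validity**: Spearman (default) correlations of each parameter against
  the five scales over all records of a condition; mean |ρ| per row over
  the scales with defined correlations; criterion-validity flag at
  |ρ| > 0.70 vs BBS.
* **Heel distance**: cross-sectional Spearman *and* Pearson vs BBS/TS/TS_E/
  TS_L (Spearman is the default report for ordinal scales); longitudinal
  per-subject Pearson correlation and least-squares slope of HD vs calendar
  day for subjects with ≥ 3 HD sessions, summarised by the cohort means.
* **Demographic screen**: first-session records only; Spearman vs age,
  height, weight; point-biserial vs sex; a single-sex cohort leaves the sex
  column undefined and flagged.
* Exclusion accounting holds everywhere:
  `records_in = records_used + records_excluded` per analysis, emitted with
  the report and asserted by tests.
* Emitted cell tables carry recomputable margins (`row_mean`, `row_sd`,
  `col_mean`, `col_sd` are plain means/SDs of the finite cells).
* The pipeline is a pure function of (study table, options); determinism is
  asserted byte-for-byte on written reports.

## 4. Synthetic cohort generator

No public COP dataset exists for this population, so the generator is a
first-class module whose defaults emulate the target study conditions:

| parameter | default | meaning |
|---|---|---|
| n_subjects | 23 | cohort size |
| sessions | drawn | ~26 % single-session; rest 2–12 (geometric, capped), totalling ≈ 111 |
| intersession_days | 14 | fixed spacing |
| trials_per_condition | 3 | repeated recordings |
| trial_duration / rate | 51.2 s / 50 Hz | sampling grid (rate configurable; platform rates are vendor-specific) |
| subject/session/trial SD of log sway | 0.50 / 0.15 / 0.10 | multiplicative variance components |
| ce_multiplier / cf_multiplier | 1.6 / 1.0 | condition effects on sway scale (vision large, support null) |
| dropout_prob_ce / _cf | 0.13 / 0.35 | fraction of the cohort unable to perform CE / CF conditions |

**Sway process.** Each axis is an exactly discretised stationary
Ornstein–Uhlenbeck process: `x_{t+Δ} = a x_t + s√(1−a²) ε`,
`a = e^{−θΔ}`, stationary SD `s = σ/√(2θ)`; defaults θ = (1.0, 0.8) 1/s and
σ = (5.0, 5.7) mm/√s give ~3.5/4.5 mm stationary sway SD, i.e. ellipse
areas of a few cm². OU sway is stationary, bounded and autocorrelated with
closed-form stationary variance — ideal for oracle tests — but it is *not*
a physiological sway model: it has no rambling–trembling structure, no
fractal scaling, and its path length grows with the sampling rate, so
absolute velocities are higher than typical platform recordings. All
velocity comparisons in tests are therefore relative (ratios, correlations,
ICCs), never absolute mm/s values.

**Variance structure.** A trial's sway scale is
`exp(b_i + s_ij + t_ijk) · ce^[CE] · cf^[CF]` with independent normal
`b_i ~ N(0, τ²)`, `s_ij ~ N(0, σ_s²)`, `t_ijk ~ N(0, σ_t²)` on the log
scale, multiplying the OU σ. This makes the design-implied ICC of
log-sway across sessions `τ²/(τ² + σ_s²)` (exact as trial noise → 0),
which the recovery tests exploit.

**Scales.** Each ordinal scale is
`clip(round(center − slope·(b_i + s_ij) + e_subj + e_sess))` with a stable
per-subject deviation and per-session administration noise. Slopes and
total noise SDs set the expected validity correlations (design target for
BBS ≈ −0.73 Spearman with session-mean sway via the bivariate-normal
relation ρ_S = (6/π)·asin(r/2)); the subject/session noise split makes the
scales highly reliable across a two-week gap, as expected for clinically
stable cohorts. TS = TS_E + TS_L by construction, so all bounds
(BBS ≤ 56, TS ≤ 40, TS_E ≤ 24, TS_L ≤ 16, WISCI ≤ 20) hold.

**Heel distance** (feet-apart stance width): per-subject baseline
~N(20, 3²) cm weakly coupled to sway magnitude (+2 cm per subject log-sway
SD, giving the negative HD–BBS correlation), linear time trend with mean
slope −0.02 cm/day (≈ 3 cm over 150 days) and session noise 0.5 cm,
floored at zero.

**Dropout** is subject-level, fixed across sessions, and monotone in
latent ability: the lowest-ability fractions of the cohort (by the normal
CDF of the ability score) drop CE and/or CF conditions; CF–CE requires
both. Because dropout_prob_cf ≥ dropout_prob_ce, anyone unable to close
their eyes is also within the feet-together dropout tail.

**Demographics** (age, height, weight, sex) are generated independent of
sway, so the demographic screen is a true null and its rejection rate
calibrates the nominal α.

**Determinism**: one `numpy` Generator seeded from `StudyDesign.seed`
drives everything in a fixed order; identical designs give bit-identical
study tables, and the CLI exposes no other entropy source.

## 5. Known limitations

* **Selection confound in the condition ANOVA.** With ability-linked
  dropout, feet-together records come from better-balancing subjects, so
  the marginal vision × support ANOVA shows a spurious *support* effect
  even when `cf_multiplier = 1`. This is a property of the unadjusted
  two-way analysis on observational dropout, not a bug; the ANOVA
  power/level calibration tests therefore run with dropout disabled, and
  default-cohort outputs should read the support p-value with this in
  mind (a mixed model with subject effects would deconfound it, but is out
  of scope here).
* **No recovery trend.** Sessions differ only by random session-level
  variation, so simulated responsiveness effect sizes are small; the ES
  estimator itself is validated by forced-arithmetic and Monte-Carlo
  recovery tests.
* Passing tests on OU sway demonstrate correctness of the *estimators and
  pipeline*, not physiological realism of the simulated trajectories; see
  the sway-process caveats above.
* No filtering or resampling is applied to trajectories (vendor-software
  preprocessing is intentionally not emulated).

## 6. Problem sizes used in tests

Unit tests run on reduced designs (6–8 subjects, 10.24 s trials) for
brevity; calibration and recovery tests use the sizes their statistics
need — 10⁵ points for ellipse coverage, 200 replicates of 50 × 2 matrices
per design ICC, 100 full-size cohorts for the ANOVA power check, and
120–250-subject single studies for correlation/ICC recovery. The full
default cohort (23 subjects, ≈ 111 sessions) is exercised end-to-end by the
pipeline tests and `scripts/acceptance.py`.

## 7. Worked-example snippet

The README output is produced by:

```python
from copsway import StudyDesign, simulate_study, evaluate_study

design = StudyDesign(seed=1)
sim = simulate_study(design)
report = evaluate_study(sim.study, sim.subjects)

rel = report.reliability_table.set_index(["parameter", "condition"])
v = rel.loc[("V", "OF-OE")]
print(f"cohort: {sim.subjects.shape[0]} subjects, "
      f"{sim.study[['subject_id','session_index']].drop_duplicates().shape[0]} sessions, "
      f"{len(sim.study)} recorded trials")
print(f"V, OF-OE: ICC(3,1) = {v['icc']:.2f} "
      f"[{v['icc_ci_low']:.2f}, {v['icc_ci_high']:.2f}], "
      f"SEM = {v['sem']:.2f} mm/s, MDC95 = {v['mdc95']:.2f} mm/s "
      f"({v['pct_mdc']:.1f}% of baseline)")
val = report.validity_table.set_index(["parameter", "condition", "scale"])
r = val.loc[("V", "OF-OE", "bbs")]
print(f"V vs BBS (OF-OE): Spearman rho = {r['r']:.2f} (p = {r['p']:.1e}, {r['munro_class']})")
a = report.condition_effects.anova
print(f"ANOVA on V: vision F({a.df_vision:.0f},{a.df_residual:.0f}) = {a.f_vision:.1f}, "
      f"p = {a.p_vision:.1e}; support p = {a.p_support:.3f}")
hd = report.hd_results
print(f"heel distance: mean slope = {hd.mean_slope_cm_per_day:.3f} cm/day "
      f"over {hd.n_subjects_longitudinal} subjects")
```
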