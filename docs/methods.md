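# Methods

## Scope and model

`bph_persistence` measures *persistence* — the time from therapy initiation
to first discontinuation — for drugs treating benign prostatic
hyperplasia/benign prostatic obstruction (BPH/BPO)-associated lower urinary
tract symptoms, from administrative pharmacy-dispensing records. Seven
drugs are covered: five α1-adrenoceptor antagonists (ABs: alfuzosin,
doxazosin, silodosin, tamsulosin, terazosin) and two 5α-reductase
inhibitors (5ARIs: finasteride, dutasteride). The pipeline has five stages:

1. **Record I/O.** One row per dispensation (patient id, birth date, sex,
   dispensation date, ATC code, drug name, packages, DDDs per package).
   Under the once-daily regimens of all study drugs, the DDD count of a
   package equals its days of supply, so the supply duration of a
   dispensation is `n_packages × ddd_per_package` days. Malformed rows are
   collected into a rejects report, never silently dropped.
2. **Cohort selection** (new-user design). Eligible subjects are men aged
   ≥ 40 completed years at the reference date (2018-04-01) with an index
   fill in the index period, no study-drug fill in the wash-out window
   (2018-01-01 to 2018-04-01), at least one year of database history before
   the index date, and ≥ 2 distinct study-drug dispensation dates in the
   365-day follow-up (chronic use). Deaths during follow-up are retained:
   death counts as a cause of non-persistence.
3. **Treatment episodes.** Dispensations are scanned in date order per drug
   (or per class). A refill continues the current episode iff it arrives
   within the *grace period* — 1.5 × the previous dispensation's own supply
   duration (per-dispensation, because products with different pack sizes
   coexist). Early refills carry over: overlapping supply is shifted
   forward (stockpiling), uncapped by default. Discontinuation is placed at
   the supply end of the episode's last span; an episode whose supply end
   plus its final grace period reaches past the follow-up horizon cannot be
   observed to discontinue and is censored at 365 days.
4. **Drug survival.** Kaplan–Meier product-limit curves with Greenwood
   variance, pointwise 95% intervals on the complementary log-log scale,
   median survival with confidence bounds by inverting the pointwise band
   at S = 0.5, fixed-time persistence at 365 days, the k-group log-rank
   test, and a Wilcoxon rank-sum comparison of ages between classes. All
   four statistics are implemented in this package; `lifelines` and
   exact-permutation enumeration serve purely as independent oracles in the
   test suite.
5. **Networks.** The drug-prescription network joins two drugs when the
   same man received both during follow-up (21 possible pairs for 7 drugs);
   polypharmacy tables give class-count and drug-count distributions per
   age group, plus the young/old (< 70 / ≥ 70) aggregation both as an
   arithmetic mean of per-group percentages and pooled.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `reference_date` | 2018-04-01 | date | age gate anchor |
| `min_age_years` | 40 | years | adult male BPH/BPO population |
| `washout_window` | [2018-01-01, 2018-04-01) | dates | prevalent-user exclusion |
| `index_period` | [2018-04-01, 2018-07-01) | dates | see "Open choices" |
| `min_history_days` | 365 | days | new-user look-back |
| `followup_days` | 365 | days | persistence horizon |
| `min_prescriptions` | 2 | fills | chronic-use filter |
| `grace_multiplier` | 1.5 | × supply | refill-gap tolerance |
| `young_old_cut` | 70 | years | age-stratified comparisons |

All intervals are half-open `[start, end)`; durations are integer day
counts; age is completed years at the reference date.

## Synthetic-data generator

The generator emulates a Local-Health-Authority claims extract with known
ground truth. Each simulated chronic user carries, per drug, a latent
intended treatment span drawn from the drug's time-to-discontinuation
distribution (exponential by default, parameterised by its median;
Weibull optional); refills are one package each, spaced one supply duration
apart plus zero-mean Gaussian jitter clipped inside the grace bound, so the
episode rules can always reconstruct the span. Within-class switching
(probability 0.25 per episode) draws a different drug of the same class and
a fresh span, starting a uniform 0–2 supply durations after the previous
supply end — so some switches preserve the class-level episode and some
break it, as in real data. Death (annual probability 0.032) truncates all
refill sequences. Chronic users always receive at least two fills of their
chain-initial drug: single-fill behaviour is modelled by the separate
"occasional" subpopulation, not by short latent spans, so the chronic-use
filter removes exactly the intended patients.

Default conditions: 5000 patients; age distribution 2.3 / 12.2 / 28.5 /
35.6 / 19.4 / 1.9 % over the decades 40–49 … 90–100; class mix
0.666 / 0.222 / 0.112 for AB-only / 5ARI-only / both; per-drug medians
278 / 81 / 120 / 101 / 28 days for alfuzosin / doxazosin / silodosin /
tamsulosin / terazosin and 272 / 97 for dutasteride / finasteride, with
within-class market shares proportional to the exposure pattern of the
study population (tamsulosin dominant); 30-DDD packages, 3-day refill
jitter. Contaminant fractions: 12% occasional, 5% under-age, 8% wash-out
users, 5% short-history.

**What the generator does not emulate.** Age and drug class are drawn
independently, so the AB-vs-5ARI age comparison is null by construction in
synthetic data (the rank-sum machinery is exercised, its significance is
not meaningful there). There is no seasonality, no dose titration, no
re-initiation after a true discontinuation, no cross-class switching, and
latent spans are memoryless by default. Passing tests therefore demonstrate
correctness of the *measurement* pipeline, not fidelity of any behavioural
model of real prescribing.

## Numerical choices

- Supply ends are `start + ceil(duration)` calendar days; same-day fills of
  one key merge with summed durations.
- Ties in the product-limit estimator: events precede censorings.
- Percentages print at one decimal, rounded half away from zero; p-values
  display at three decimals with a `<0.001` floor.
- Log-rank uses the hypergeometric covariance over the first k−1 groups,
  with a pseudo-inverse fallback for singular covariance.
- Median confidence bounds: smallest event time at which the pointwise
  lower/upper confidence curve crosses 0.5; unbounded sides report as
  not reached.
- All-censored inputs yield S ≡ 1 with an undefined median (not an error);
  an empty eligible cohort yields a ledger-only report with a warning.

## Open choices resolved

- **Gap anchor.** Whether refill gaps are measured from the previous
  dispensation date or from supply exhaustion is ambiguous in persistence
  work; both are implemented (`gap_anchor`), dispensation-date anchoring is
  the default (a "new dispensation within the grace period" reading).
- **Discontinuation time** is the supply end of the last span, not the last
  fill date: the patient is medicated until supply exhaustion.
- **Stockpiling** carries over uncapped by default (conservative for
  persistence); `stockpile_cap_days` can cap it.
- **Index period end** (not fixed by the design constants) defaults to one
  quarter after the reference date, keeping all follow-up windows inside a
  single year of data.
- **Chronic-use threshold** counts distinct dispensation dates for any study
  drug at the subject level; a per-drug variant is a config flag.
- **Drug-level curves do not censor at switch**: each drug's curve uses that
  drug's own fills, so a switcher discontinues drug A and contributes to
  drug B from B's first fill (per-drug Ns then sum to more than the
  cohort, as in the exposure tables).
- **Exclusion order** is fixed (not-male → under-age → wash-out →
  short-history → no-index-fill → occasional) so ledger counts are
  reproducible; a `not_male` status was added so the ledger partitions
  every patient with a study-drug record.
- **Doxazosin** is coded C02CA04 (WHO ATC, cardiovascular chapter) and the
  default class map carries `C02CA → AB` so the seven-drug set is complete.

## Problem sizes

The shipped analysis and the acceptance script simulate 5000 patients
(≈ 42 000 dispensations, ≈ 3500 eligible men); the parameter-recovery check
uses 2000 patients with 10-day packages and no jitter (discretisation error
of the supply-end convention is one package duration, so the fine grid lets
a ± 10-day tolerance around the true 100-day median be meaningful); the
log-rank calibration uses 2000 replicates of two 100-subject groups.

## Known limitations

- Supply duration assumes the DDD equals the prescribed daily dose; dose
  tapering and proportion-of-days-covered adherence metrics are out of
  scope (persistence only).
- Reported descriptive denominators in published tables of this study
  design can disagree by small margins (e.g. an overall N printed as 4380
  against a cohort of 4309, and a both-classes share printed as 10.8%
  where the count/denominator arithmetic gives 10.9%); this package always
  uses the single cohort denominator.
- Re-initiation after the first discontinuation is deliberately not
  measured.
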