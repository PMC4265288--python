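# vaxsignal

Signal detection on spontaneous reports of adverse events following
immunisation. The package implements and benchmarks two complementary
screening algorithms over a database of vaccine–event report mentions:

* **MGPS** — the multi-item gamma Poisson shrinker, an empirical-Bayes
  disproportionality method. For each reported vaccine–event pair with
  observed count *N* and Mantel–Haenszel stratified expected count *E*, the
  relative reporting ratio λ carries a two-component gamma mixture prior
  λ ~ P·Γ(α₁, β₁) + (1−P)·Γ(α₂, β₂) fitted by marginal maximum likelihood
  over all pairs in the database. The signal score is the posterior
  geometric mean EBGM = exp E[ln λ | N] with its 90% credibility interval
  (EB05, EB95); a pair is flagged when EB05 exceeds a threshold. The
  benchmark grid crosses 16 stratification-factor subsets of
  {(S)ex, (A)ge, (R)egion, (Y)ear} with 21 thresholds (0 to 4 by 0.2) —
  336 detectors, labelled e.g. `0.8-SARY`.

* **TTO screening** — a time-to-onset method. The distribution of onset
  delays (days from immunisation to event onset, within a window [0, T]) of
  a pair is compared by two-sample Kolmogorov–Smirnov tests against two
  backgrounds from the same database: the same vaccine with all other
  events ("between events") and the same event with all other vaccines
  ("between vaccines"). A pair is flagged when both p-values fall below α.
  The grid crosses α ∈ {0.01, 0.05, 0.10, 0.20, 0.50, 0.99} with
  T ∈ {30, 60, 90} days — 18 detectors, labelled e.g. `TTO-01-60`.

The two methods are structurally complementary: disproportionality sees
pairs with missing or long onset delays that the TTO screen cannot test,
while the TTO screen can flag pairs whose excess reporting is too small to
stand out but whose onsets cluster tightly after immunisation.

The package also ships the full performance-comparison protocol (gold-
standard classification into TP/FP/TN/FN, per-vaccine PPV ranking with
median-rank aggregation, ROC sweeps, chronological time-to-detection
replay) and a synthetic spontaneous-report generator with injected
ground-truth signals, so every stage is testable without proprietary data.

## Worked example

```python
from vaxsignal import MGPS, StratumSpec, TTOConfig, classify
from vaxsignal.tto import TTOScreen
from vaxsignal.simulate import SimConfig, TTOSignalSpec, simulate_database

config = SimConfig(
    n_vaccines=10, n_events=40, n_reports=20_000, seed=42,
    injected_dpa_signals=(("V02", "E030", 10.0), ("V06", "E035", 10.0)),
    injected_tto_signals=(
        ("V01", "E028", TTOSignalSpec(mode_days=3.0, relative_rate=8.0)),
        ("V04", "E032", TTOSignalSpec(mode_days=2.0, relative_rate=8.0))),
)
db = simulate_database(config)
universe = {tuple(p) for p in db.frame.groupby(["vaccine", "event"]).size().index}

mgps = MGPS(db.frame, StratumSpec("SARY")).fit()
print(mgps.summary())
print(mgps.table.sort_values("EB05", ascending=False).head(4).round(2).to_string(index=False))

tto = TTOScreen(db.frame, TTOConfig(alpha=0.01, window_days=60)).fit()
print(tto.summary())

m_t = classify(tto.flagged(), universe, db.truth)
m_g = classify(mgps.flagged(0.8), universe, db.truth)
print(f"TTO-01-60 : TP={m_t.tp} FP={m_t.fp} PPV={m_t.ppv:.3f}")
print(f"0.8-SARY  : TP={m_g.tp} FP={m_g.fp} PPV={m_g.ppv:.3f}")
```

prints

```
MGPS (multi-item gamma Poisson shrinker)
  stratification : SARY
  pairs scored   : 400
  reports        : 20839
  prior          : alpha1=1.667 beta1=1.763 alpha2=2.435e+08 beta2=2.444e+08 P=0.07299
  log-likelihood : -1237.0286 (converged=True)
  EBGM range     : [0.195, 3.49]
vaccine event   N      E  EBGM  EB05  EB95    Q
    V04  E032  91  24.63  3.49  2.93  4.13 1.00
    V06  E035  84  23.47  3.38  2.81  4.02 1.00
    V02  E030 266 120.16  2.19  1.98  2.42 1.00
    V01  E028 454 279.85  1.62  1.50  1.74 1.00
TTO screen (dual-background two-sample Kolmogorov-Smirnov)
  configuration : TTO-01-60 (alpha=0.01, window=[0,60] days)
  pairs         : 400 (396 testable, 4 without usable TTO)
  flagged       : 3
TTO-01-60 : TP=2 FP=1 PPV=0.667
0.8-SARY  : TP=4 FP=366 PPV=0.011
```

All four injected signals surface at the top of the MGPS table (N well
above E, EB05 ≫ 1), and the TTO screen flags the clustered-onset pairs
with very high precision while ignoring pairs that are merely
over-reported. The extreme false-positive count of `0.8-SARY` here is a
property of this simulated null — see `docs/methods.md` — but the
direction of the precision gap (TTO ≫ MGPS at top operating points)
mirrors what the detectors do on real spontaneous-report data.

## Command line

```sh
vaxsignal simulate --seed 13 --config sim.yaml --out sim/
vaxsignal mgps --reports sim/reports.csv --stratification SARY --threshold 0.8 --out runs/
vaxsignal tto  --reports sim/reports.csv --grid --out runs/
vaxsignal evaluate --results runs/ --gold sim/gold.csv --reports sim/reports.csv --roc --out eval/
```

`evaluate` writes one row per detector — median PPV rank, overall PPV/NPV,
TP/FP/TN/FN, sensitivity, specificity — sorted by median rank, plus the
ROC point sweeps.

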