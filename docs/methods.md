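# Methods

## The data model

One row of a reports table is one vaccine–event *mention*: report id,
receipt date, vaccine code, event code (a MedDRA-preferred-term-like
string), sex (F/M/unknown), age in years, region code, and time-to-onset
(TTO) in whole days, possibly missing. A case report listing k suspected
events yields k rows sharing a report id; each row contributes exactly once
to exactly one pair/stratum cell. Unknown demographic values form a real
"UNK" level within each stratification factor rather than being dropped, so
the total count is conserved between stratified and unstratified analyses,
and pair totals are identical under every stratification.

The evaluation universe is always the set of *reported* pairs (N ≥ 1).
Unreported pairs are not enumerated: "true negative" means reported but
neither labelled nor flagged.

## MGPS

For a pair with observed count N and expected count E, the model is
N | λ ~ Poisson(λE) with λ ~ P·Γ(α₁, β₁) + (1−P)·Γ(α₂, β₂) (shape/rate).

**Expected counts.** E is Mantel–Haenszel stratified:
E(v,e) = Σₛ row(v,s)·col(e,s)/total(s) over strata with positive totals.
Strata are the cross-classification of the chosen factors among sex, age
group, region and reporting year. Default age bins [0,2), [2,12), [12,18),
[18,46), [46,66), [66,∞) separate the paediatric, adolescent and adult
vaccine populations; they are configurable, as is everything else about the
stratification (the field reports no canonical binning).

**Prior fit.** Marginally N is a two-component negative-binomial mixture;
the five prior parameters maximise Σ log marginal pmf over pairs. The
search runs on log/logit-transformed parameters from the classical starting
values (0.2, 0.1, 2.0, 4.0, 1/3): restarted Nelder–Mead followed by an
L-BFGS-B polish. Degenerate optima are real and legitimate — on data with
no dispersion in λ the prior collapses toward a point mass at 1 (huge
shapes, or one component's weight → 0) and the likelihood becomes flat
along a ridge; convergence is therefore declared either by optimizer
success or when a restart improves the log-likelihood by less than the
tolerance (1e-8). Transformed parameters are clipped to ±60 so ridge walks
cannot overflow. Pairs entering the fit are the observed pairs (N ≥ 1),
the convention of production disproportionality systems; the
parameter-recovery experiment, being a generative check, fits on all
simulated pairs including N = 0.

The prior is refitted for each stratification (E changes with the strata),
never per threshold. A caller-supplied prior can be reused instead —
`MGPS(...).fit(prior=...)` — which is also the switch for running one
database-wide prior across stratifications.

**Posterior summaries.** The posterior is Q·Γ(α₁+N, β₁+E) +
(1−Q)·Γ(α₂+N, β₂+E) with Q the posterior weight of component 1. EBGM =
exp(Q·(ψ(α₁+N) − ln(β₁+E)) + (1−Q)·(ψ(α₂+N) − ln(β₂+E))). EB05/EB95 solve
mixture-CDF(x) = 0.05/0.95 by Brent root-finding bracketed by the component
quantiles (the mixture quantile always lies between them), with the bracket
padded against floating-point ties; the achieved CDF error is ~1e-12,
verified against independent quadrature of the posterior density.

**Flagging.** EB05 strictly greater than the threshold (a tie is not a
flag). The grid is 16 stratifications × thresholds 0, 0.2, …, 4; labels
render the threshold with minimal digits then the factor letters in fixed
SARY order ("0.8-SARY", "2-SARY", "0-U").

A note on shrinkage: EBGM sits strictly between the prior geometric mean
and the raw ratio N/E whenever N/E exceeds every component's prior mean.
Between the two component means, posterior reweighting toward the
higher component can push EBGM marginally past N/E; this is a property of
mixture posteriors, not an implementation artefact, and the tests assert
the bracketing exactly in the regime where it is a theorem.

## TTO screening

For a pair, the target sample is its reports' TTO values within [0, T]
(inclusive both ends; missing TTO excluded). Two backgrounds come from the
same window: same vaccine/other events, and same event/other vaccines (the
vaccine of interest entirely excluded from the latter; the target pair's
own reports are in neither). The pair is flagged when both two-sample KS
p-values are below α — two tests each at level α (an AND rule), not a
combined statistic, matching the single α parameter of the screening rule.

TTO values are integer days, so ties are heavy. D is the exact supremum of
the ECDF difference over the pooled observed values. The default p-value is
the asymptotic Kolmogorov tail at D·√(nm/(n+m)), which is conservative
under ties — acceptable for a screening rule where anti-conservatism, not
conservatism, is the failure mode. An exact small-sample null distribution
is available (`method="exact"`, used when n·m ≤ 10 000). No multiplicity
correction is applied across pairs: the benchmark sweeps raw α levels, and
false-discovery control is the evaluation layer's concern.

Pairs with an empty target sample (or below the optional `min_target`
guard, default 1) or an empty background are reported with a status code
and can never be flagged. This is the method's structural blind spot:
events with mostly missing TTO, or onsets beyond the window (e.g.
lack-of-efficacy-like events reported months later), are invisible to it.

## Evaluation protocol

**Classification.** Against a gold standard mapping each vaccine to its set
of labelled events, every reported pair is TP/FP/TN/FN; pairs of vaccines
the gold standard does not cover are excluded and counted. PPV, NPV,
sensitivity and specificity follow from the cells.

**Ranking.** Within each vaccine, detectors are ranked by descending PPV
with midranks for ties (the only assignment that produces the fractional
median ranks seen with eight vaccines); the aggregate is the median rank
across vaccines with its standard deviation. A detector that flags nothing
for some vaccine has no PPV there; that cell is dropped from its rank
vector rather than imputed, since imputation would fabricate an ordering.

**ROC.** Threshold sweeps reuse per-pair scores: EB05 (flag if > t, t from
0 to 10 by 0.1) for MGPS; max of the two KS p-values (flag if < t, t from
0 to 1 by 0.01) for TTO, so score < α is exactly the dual-significance
rule. Pairs without a usable score are never flagged, which caps the TTO
detector's attainable sensitivity below 1 — a deliberate, faithful ceiling.

**Time-to-detection.** The database is replayed in receipt-date order
(ties broken by report id); after each arrival the detector is re-run from
scratch, and the first flagging date yields two counts: reports received
(all rows so far) and reports used — for MGPS all rows, for the TTO screen
only in-window non-missing-TTO rows, by default across target and both
backgrounds (configurable to target-only, since the method's data-economy
argument is usually made about the target sample). A coarse mode
re-evaluates only when the target pair itself gains a report; its
equivalence to the full replay on first-detection counts is asserted by
test, not assumed.

## The synthetic generator

Pair counts are Poisson with mean = database size × vaccine propensity ×
event propensity × stratum composition × stratum effect × injected relative
rate. Propensities are Zipf-like (few common codes, long tail). Each
vaccine carries a demographic profile (paediatric / adolescent / adult age
mixture, female fraction) so stratification genuinely moves expected
counts; regions and reporting years have fixed mixtures with reporting
volume growing over years. Default database size is 50 000 expected
reports over 20 vaccines × 60 events.

TTO background is geometric with mean 10 days truncated at 365 — a
reporting-bias decay (the later the onset, the less likely the report)
that keeps most mass inside even the 30-day window. Injected TTO signals
draw from a discretised log-normal with configurable mode (default 3 days,
σ = 0.35) and an elevated reporting rate, since a causal signal produces
excess reports as well as clustered onsets. An optional long-onset event
class (uniform 91–365 days) emulates lack-of-efficacy-like reporting and
exercises the TTO blind spot. TTO missingness is per vaccine, default
evenly spread over 12%–52%. The ground truth is emitted as a gold-standard
object/file covering every simulated vaccine, so evaluation consumes
simulation output unchanged.

**What the generator does not emulate.** Null pairs have relative reporting
ratio exactly 1: there is no between-pair dispersion, duplicate reporting,
event co-occurrence structure, seasonality, or MedDRA-style vocabulary. Two
consequences matter for interpretation. First, the empirical-Bayes prior
correctly collapses toward a point mass at λ = 1 on such data, so EB05 for
unremarkable pairs sits near 1 and *low* MGPS thresholds (e.g. 0.8) flag
liberally — on real databases the fitted prior is dispersed and the same
thresholds are far more selective. Second, passing null-calibration and
recovery tests here demonstrates correctness of the machinery under the
stated conditions, not field performance on any real safety database.

## Benchmark scenarios and problem sizes

The reference scenarios in `vaxsignal.benchmark` (shared by the test suite
and `scripts/acceptance.py`) use: 50 000 (N, E) pairs for prior recovery
(E log-normal, median 2, σ = 1; true prior (0.2, 0.1, 2, 4, 1/3); component
label switching resolved before computing relative errors); one
50 000-report null database for calibration (TTO flag rate at α = 0.05
compared against 0.05 + 3 binomial s.e. over testable pairs, MGPS at
EB05 > 2 against 1%); and one 50 000-report database with 17
disproportionality signals (relative rate 10), 20 clustered-TTO signals
(mode 3 days, rate 8), three long-onset signals and three signals on a
vaccine with 95% missing TTO, measuring recall at the `0.8-SARY` and
`TTO-01-60` operating points and the blind-spot miss rate. These sizes
give stable results across seeds while each scenario completes in seconds.

## Known limitations

* The MGPS here scores pairs only; higher-order itemsets are out of scope.
* The exact KS option delegates to the standard path-counting null, which
  ignores ties (as all standard implementations do); the default
  asymptotic path handles ties conservatively.
* The chronological replay refits the prior on every prefix, so very early
  prefixes can sit on degenerate likelihood ridges; the replay adapter
  keeps the best-so-far prior instead of failing.
* The gold-standard format cannot express "covered vaccine with zero
  labelled events" on disk (a two-column file has no row to carry it);
  in-memory gold standards from the simulator do cover such vaccines.
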