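"""Multi-item gamma Poisson shrinker (MGPS) for vaccine-event pairs.

The model: for a vaccine-event pair with expected count E (from Mantel-
Haenszel stratified margins under independence), the observed count N is
Poisson(lambda * E) where the relative reporting ratio lambda carries a
two-component gamma mixture prior

    lambda ~ P * Gamma(alpha1, beta1) + (1 - P) * Gamma(alpha2, beta2)

(shape/rate).  Marginally N is a mixture of negative binomials; the five
prior parameters are fitted by maximising that marginal likelihood over all
pairs in the database (empirical Bayes).  The posterior of lambda given
(N, E) is again a two-component gamma mixture, and the signal statistics are

    EBGM = exp(E[ln lambda | N])   (the shrunk reporting ratio)
    EB05, EB95 = 5th / 95th posterior percentiles of lambda.

A pair is flagged when EB05 exceeds a threshold; the benchmarking grid
crosses 16 stratifications with 21 thresholds (0 to 4 by 0.2), 336 detectors.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .reports import (
    ALL_STRATIFICATIONS,
    PairCountTable,
    PairKey,
    StratumSpec,
    build_pair_counts,
    reports_to_frame,
)

__all__ = [
    "GPSPrior",
    "GPSResult",
    "MGPSConfig",
    "PriorFit",
    "PriorFitError",
    "DEFAULT_PRIOR_START",
    "expected_counts",
    "marginal_loglik",
    "fit_prior",
    "posterior_summaries",
    "mgps_grid",
    "run_mgps",
    "MGPS",
    "MGPSResults",
]

#: DuMouchel's published starting values for the prior search
DEFAULT_PRIOR_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)

#: EB05 thresholds of the detection grid: 0 to 4 by 0.2
THRESHOLDS = tuple(i / 5.0 for i in range(21))


@dataclass(frozen=True)
class GPSPrior:
    """Two-component gamma mixture prior on the relative reporting ratio.

    ``alpha`` are shapes, ``beta`` rates, ``p`` the weight of component 1.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes and rates must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.alpha1, self.beta1, self.alpha2, self.beta2, self.p)

    @property
    def geometric_mean(self) -> float:
        """Prior geometric mean of lambda, exp(E[ln lambda])."""
        g1 = special.digamma(self.alpha1) - np.log(self.beta1)
        g2 = special.digamma(self.alpha2) - np.log(self.beta2)
        return float(np.exp(self.p * g1 + (1.0 - self.p) * g2))


@dataclass(frozen=True)
class GPSResult:
    """Posterior signal summaries for one vaccine-event pair."""

    pair: PairKey
    n: int
    e: float
    ebgm: float
    eb05: float
    eb95: float
    q: float  # posterior weight of prior component 1


@dataclass(frozen=True)
class MGPSConfig:
    """A labelled point on the MGPS grid: stratification x EB05 threshold."""

    stratification: StratumSpec
    threshold: float

    @property
    def label(self) -> str:
        return f"{format_threshold(self.threshold)}-{self.stratification.label}"


def format_threshold(t: float) -> str:
    """Render a grid threshold with minimal digits ("0.8", "2", not "2.0")."""
    return f"{round(float(t), 10):g}"


def mgps_grid(age_edges: Sequence[float] | None = None) -> list[MGPSConfig]:
    """The full detection grid: 16 stratifications x 21 EB05 thresholds."""
    strats = (ALL_STRATIFICATIONS if age_edges is None
              else tuple(StratumSpec(s.factors, tuple(age_edges)) for s in ALL_STRATIFICATIONS))
    return [MGPSConfig(s, t) for s in strats for t in THRESHOLDS]


# ---------------------------------------------------------------------------
# expected counts


def expected_counts(counts: PairCountTable) -> pd.Series:
    """Mantel-Haenszel stratified expected counts for every observed pair.

    E(v, e) = sum over strata s of rowtotal(v, s) * coltotal(e, s) / total(s);
    strata with zero grand total contribute nothing.  Returned as a Series
    indexed by (vaccine, event) for the pairs present in ``counts``.
    """
    R = counts.vaccine_totals.unstack(fill_value=0)   # vaccines x strata
    C = counts.event_totals.unstack(fill_value=0)     # events x strata
    strata = counts.stratum_totals.index
    R = R.reindex(columns=strata, fill_value=0)
    C = C.reindex(columns=strata, fill_value=0)
    g = counts.stratum_totals.to_numpy(dtype=float)
    inv_g = np.where(g > 0, 1.0 / g, 0.0)
    E = (R.to_numpy(dtype=float) * inv_g) @ C.to_numpy(dtype=float).T
    Edf = pd.DataFrame(E, index=R.index, columns=C.index)
    pairs = counts.pair_totals().index
    vi = Edf.index.get_indexer(pairs.get_level_values("vaccine"))
    ei = Edf.columns.get_indexer(pairs.get_level_values("event"))
    return pd.Series(Edf.to_numpy()[vi, ei], index=pairs, name="E")


# ---------------------------------------------------------------------------
# prior fitting


def _mixture_logpmf(n: np.ndarray, e: np.ndarray, theta: Sequence[float]) -> np.ndarray:
    """Log marginal pmf of N under the negative-binomial mixture."""
    a1, b1, a2, b2, p = theta
    # NB parameterisation: N | component j ~ NegBin(shape a_j, success prob b_j/(b_j+E))
    l1 = stats.nbinom.logpmf(n, a1, b1 / (b1 + e))
    l2 = stats.nbinom.logpmf(n, a2, b2 / (b2 + e))
    p = min(max(p, 1e-12), 1 - 1e-12)
    return np.logaddexp(np.log(p) + l1, np.log1p(-p) + l2)


def marginal_loglik(prior: GPSPrior | Sequence[float],
                    n: np.ndarray, e: np.ndarray) -> float:
    """Marginal log-likelihood of the (N, E) pairs under the mixture prior."""
    theta = prior.as_tuple() if isinstance(prior, GPSPrior) else tuple(prior)
    return float(np.sum(_mixture_logpmf(np.asarray(n), np.asarray(e, dtype=float), theta)))


@dataclass
class PriorFit:
    prior: GPSPrior
    loglik: float
    converged: bool
    n_iter: int
    start_loglik: float


class PriorFitError(RuntimeError):
    """Prior optimisation failed to converge; carries the best fit so far."""

    def __init__(self, message: str, best: PriorFit):
        super().__init__(message)
        self.best = best


def _to_unconstrained(theta):
    a1, b1, a2, b2, p = theta
    return np.array([np.log(a1), np.log(b1), np.log(a2), np.log(b2),
                     np.log(p) - np.log1p(-p)])


def _from_unconstrained(z):
    # clip keeps shapes/rates in [e-60, e60] so degenerate ridges (a point-
    # mass prior, an empty component) cannot overflow the likelihood
    z = np.clip(z, -60.0, 60.0)
    return (float(np.exp(z[0])), float(np.exp(z[1])),
            float(np.exp(z[2])), float(np.exp(z[3])),
            float(special.expit(z[4])))


def fit_prior(n: Iterable[float], e: Iterable[float],
              start: Sequence[float] = DEFAULT_PRIOR_START,
              tol: float = 1e-8, maxiter: int = 4000,
              raise_on_failure: bool = True) -> PriorFit:
    """Fit the 5-parameter mixture prior by marginal maximum likelihood.

    The search runs on log/logit-transformed parameters (positivity and the
    [0,1] weight are enforced by construction): a Nelder-Mead pass from the
    DuMouchel starting values followed by an L-BFGS-B polish.  Convergence is
    declared when the log-likelihood improves by less than ``tol`` per step.
    """
    n = np.asarray(list(n), dtype=float)
    e = np.asarray(list(e), dtype=float)
    if n.shape != e.shape or n.size < 2:
        raise ValueError("need at least two (N, E) pairs of equal length")
    if np.any(e <= 0):
        raise ValueError("all expected counts must be positive")

    def nll(z):
        theta = _from_unconstrained(z)
        val = -np.sum(_mixture_logpmf(n, e, theta))
        return np.inf if not np.isfinite(val) else val

    z0 = _to_unconstrained(start)
    start_ll = -nll(z0)
    # restarted Nelder-Mead: degenerate optima (an empty mixture component,
    # a point-mass prior) sit on flat ridges where a single pass exhausts its
    # budget without tripping the success flag; convergence is declared when
    # a restart no longer improves the log-likelihood beyond tolerance
    z, prev_fun, n_iter, stationary, success = z0, np.inf, 0, False, False
    for _ in range(6):
        res = optimize.minimize(nll, z, method="Nelder-Mead",
                                options={"fatol": tol, "xatol": 1e-6,
                                         "maxiter": maxiter, "maxfev": maxiter})
        z, n_iter = res.x, n_iter + res.nit
        success = success or bool(res.success)
        if prev_fun - res.fun <= max(tol, 1e-9 * abs(res.fun)):
            stationary = True
            break
        prev_fun = res.fun
    polish = optimize.minimize(nll, z, method="L-BFGS-B",
                               options={"ftol": 1e-12, "maxiter": 500})
    best = polish if polish.fun <= res.fun else res
    prior = GPSPrior(*_from_unconstrained(best.x))
    fit = PriorFit(prior=prior, loglik=float(-best.fun),
                   converged=bool(success or polish.success or stationary),
                   n_iter=int(n_iter + getattr(polish, "nit", 0)),
                   start_loglik=float(start_ll))
    if not fit.converged and raise_on_failure:
        raise PriorFitError("prior fit did not converge", fit)
    return fit


# ---------------------------------------------------------------------------
# posterior summaries


def _posterior_params(n: float, e: float, prior: GPSPrior):
    """Posterior mixture: Q * Gamma(a1+N, b1+E) + (1-Q) * Gamma(a2+N, b2+E)."""
    a1, b1, a2, b2, p = prior.as_tuple()
    l1 = stats.nbinom.logpmf(n, a1, b1 / (b1 + e))
    l2 = stats.nbinom.logpmf(n, a2, b2 / (b2 + e))
    if p >= 1.0:
        q = 1.0
    elif p <= 0.0:
        q = 0.0
    else:
        q = float(special.expit(np.log(p) - np.log1p(-p) + l1 - l2))
    return q, (a1 + n, b1 + e), (a2 + n, b2 + e)


def _mixture_cdf(x, q, g1, g2):
    return (q * stats.gamma.cdf(x, g1[0], scale=1.0 / g1[1])
            + (1.0 - q) * stats.gamma.cdf(x, g2[0], scale=1.0 / g2[1]))


def posterior_quantile(n: float, e: float, prior: GPSPrior, prob: float) -> float:
    """Quantile of the posterior gamma mixture by root-finding on its CDF."""
    q, g1, g2 = _posterior_params(n, e, prior)
    q1 = stats.gamma.ppf(prob, g1[0], scale=1.0 / g1[1])
    q2 = stats.gamma.ppf(prob, g2[0], scale=1.0 / g2[1])
    # the mixture quantile lies between the component quantiles; pad the
    # bracket against floating error when the two nearly coincide
    lo, hi = min(q1, q2), max(q1, q2)
    f = lambda x: _mixture_cdf(x, q, g1, g2) - prob
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return float(lo)
    if fhi == 0.0:
        return float(hi)
    while flo > 0.0:
        lo *= 0.5
        flo = f(lo)
    while fhi < 0.0:
        hi = hi * 2.0 + 1e-300
        fhi = f(hi)
    if hi - lo < 1e-14 * max(1.0, hi):
        return float(0.5 * (lo + hi))
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12, maxiter=200))


def posterior_summaries(n: int, e: float, prior: GPSPrior,
                        pair: PairKey | None = None) -> GPSResult:
    """EBGM and the 90% credibility bounds (EB05, EB95) for one pair.

    EBGM = exp(Q*(psi(a1+N) - ln(b1+E)) + (1-Q)*(psi(a2+N) - ln(b2+E))) with
    psi the digamma function; EB05/EB95 solve mixture-CDF(x) = 0.05 / 0.95.
    """
    if e <= 0:
        raise ValueError("expected count must be positive")
    q, g1, g2 = _posterior_params(n, e, prior)
    ebln = q * (special.digamma(g1[0]) - np.log(g1[1])) \
        + (1.0 - q) * (special.digamma(g2[0]) - np.log(g2[1]))
    return GPSResult(
        pair=pair if pair is not None else PairKey("", ""),
        n=int(n), e=float(e),
        ebgm=float(np.exp(ebln)),
        eb05=posterior_quantile(n, e, prior, 0.05),
        eb95=posterior_quantile(n, e, prior, 0.95),
        q=q,
    )


# ---------------------------------------------------------------------------
# model / results objects


class MGPS:
    """Empirical-Bayes gamma-Poisson model over a spontaneous-report database.

    Parameters
    ----------
    reports : list of Report or DataFrame
        The full report stream; the background is all vaccines present.
    stratification : StratumSpec
        Factors used for the Mantel-Haenszel expected counts.
    min_count : int
        Pairs entering the prior fit and the results table need N >= this
        (default 1: only observed pairs are enumerated).
    """

    def __init__(self, reports, stratification: StratumSpec = StratumSpec("SARY"),
                 min_count: int = 1):
        self.frame = reports_to_frame(reports)
        self.stratification = stratification
        self.min_count = int(min_count)
        self.counts = build_pair_counts(self.frame, stratification)
        ntab = self.counts.pair_totals()
        etab = expected_counts(self.counts)
        keep = ntab >= self.min_count
        self.n_ = ntab[keep]
        self.e_ = etab.reindex(self.n_.index)

    def fit(self, prior: GPSPrior | None = None,
            start: Sequence[float] = DEFAULT_PRIOR_START,
            tol: float = 1e-8, strict: bool = True) -> "MGPSResults":
        """Fit the prior (unless one is supplied) and score every pair.

        ``strict=False`` keeps the best-so-far prior instead of raising when
        the optimizer fails to converge (useful in chronological replay on
        very small prefixes).
        """
        if prior is None:
            pf = fit_prior(self.n_.to_numpy(), self.e_.to_numpy(),
                           start=start, tol=tol, raise_on_failure=strict)
            prior, loglik, converged = pf.prior, pf.loglik, pf.converged
        else:
            loglik = marginal_loglik(prior, self.n_.to_numpy(), self.e_.to_numpy())
            converged = True
        rows = []
        for (v, ev), n in self.n_.items():
            e = self.e_[(v, ev)]
            r = posterior_summaries(int(n), float(e), prior, PairKey(v, ev))
            rows.append((v, ev, r.n, r.e, r.ebgm, r.eb05, r.eb95, r.q))
        table = pd.DataFrame(rows, columns=["vaccine", "event", "N", "E",
                                            "EBGM", "EB05", "EB95", "Q"])
        return MGPSResults(self, prior, table, loglik, converged)


class MGPSResults:
    """Fitted MGPS: the prior, per-pair posterior summaries, flagging."""

    def __init__(self, model: MGPS, prior: GPSPrior, table: pd.DataFrame,
                 loglik: float, converged: bool):
        self.model = model
        self.prior = prior
        self.table = table
        self.loglik = loglik
        self.converged = converged

    def scores(self) -> dict[PairKey, float]:
        """EB05 per pair (the flagging score)."""
        return {PairKey(v, e): s for v, e, s in
                zip(self.table["vaccine"], self.table["event"], self.table["EB05"])}

    def flagged(self, threshold: float) -> set[PairKey]:
        """Pairs with EB05 strictly above the threshold."""
        m = self.table["EB05"] > threshold
        return {PairKey(v, e) for v, e in
                zip(self.table.loc[m, "vaccine"], self.table.loc[m, "event"])}

    def flag_table(self, threshold: float) -> pd.DataFrame:
        out = self.table.copy()
        out["flagged"] = out["EB05"] > threshold
        return out

    def summary(self) -> str:
        p = self.prior
        lines = [
            "MGPS (multi-item gamma Poisson shrinker)",
            f"  stratification : {self.model.stratification.label}",
            f"  pairs scored   : {len(self.table)}",
            f"  reports        : {self.model.counts.total}",
            f"  prior          : alpha1={p.alpha1:.4g} beta1={p.beta1:.4g} "
            f"alpha2={p.alpha2:.4g} beta2={p.beta2:.4g} P={p.p:.4g}",
            f"  log-likelihood : {self.loglik:.4f} (converged={self.converged})",
            f"  EBGM range     : [{self.table['EBGM'].min():.3g}, "
            f"{self.table['EBGM'].max():.3g}]",
        ]
        return "\n".join(lines)


def run_mgps(reports, config: MGPSConfig,
             prior: GPSPrior | None = None) -> tuple[set[PairKey], pd.DataFrame]:
    """Run one grid point: fit (or reuse) the prior, flag pairs by EB05.

    Returns the flagged pair set and the per-pair table with a ``flagged``
    column (vaccine, event, N, E, EBGM, EB05, EB95, flagged).
    """
    res = MGPS(reports, config.stratification).fit(prior=prior)
    table = res.flag_table(config.threshold)
    return res.flagged(config.threshold), table
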