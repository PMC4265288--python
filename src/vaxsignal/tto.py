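"""Time-to-onset (TTO) signal detection via two-sample Kolmogorov-Smirnov tests.

A vaccine-event pair is flagged when the distribution of its reported
times-to-onset (days from immunisation to event onset, restricted to a time
window [0, T]) differs significantly from BOTH of two background
distributions built from the same database:

* "between events"   — same vaccine, all other events;
* "between vaccines" — same event, all other vaccines (the vaccine of
  interest excluded).

Each comparison is a two-sample KS test; the pair is a signal when both
p-values fall below the significance level alpha.  The benchmarking grid
crosses six alpha levels (0.01, 0.05, 0.10, 0.20, 0.50, 0.99) with three
windows (30, 60, 90 days): 18 detectors, labelled e.g. "TTO-01-60".

TTO data are integer days, so ties are heavy; the KS statistic is the sup of
the ECDF difference over the pooled support, and the default p-value is the
asymptotic Kolmogorov tail at D * sqrt(n*m/(n+m)) (conservative under ties,
appropriate for a screening rule).  An exact-distribution option exists for
small samples.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .reports import PairKey, reports_to_frame

__all__ = [
    "ALPHA_LEVELS",
    "WINDOWS",
    "TTOConfig",
    "TTOResult",
    "TTOStatus",
    "tto_grid",
    "tto_sample",
    "background_samples",
    "ks_two_sample",
    "flag_pair",
    "TTOScreen",
    "TTOScreenResults",
]

ALPHA_LEVELS = (0.01, 0.05, 0.10, 0.20, 0.50, 0.99)
WINDOWS = (30, 60, 90)


class TTOStatus(str, Enum):
    OK = "OK"
    INSUFFICIENT_TARGET = "INSUFFICIENT_TARGET"
    INSUFFICIENT_BACKGROUND = "INSUFFICIENT_BACKGROUND"


@dataclass(frozen=True)
class TTOConfig:
    """One point of the TTO grid: significance level x time window.

    ``min_target`` is an optional guard on the target sample size (default 1:
    no guard beyond non-emptiness).
    """

    alpha: float
    window_days: int
    min_target: int = 1

    @property
    def label(self) -> str:
        return f"TTO-{int(round(self.alpha * 100)):02d}-{self.window_days}"


def tto_grid(min_target: int = 1) -> list[TTOConfig]:
    """The full TTO grid: 6 alpha levels x 3 windows = 18 detectors."""
    return [TTOConfig(a, w, min_target) for a in ALPHA_LEVELS for w in WINDOWS]


@dataclass(frozen=True)
class TTOResult:
    """KS screening outcome for one pair under one configuration."""

    pair: PairKey
    n_target: int
    n_bg_events: int
    n_bg_vaccines: int
    d_events: float
    p_events: float
    d_vaccines: float
    p_vaccines: float
    status: TTOStatus
    flagged: bool


# ---------------------------------------------------------------------------
# sample construction


def _window_frame(df: pd.DataFrame, window_days: int) -> pd.DataFrame:
    tto = pd.to_numeric(df["tto_days"], errors="coerce")
    keep = tto.notna() & (tto >= 0) & (tto <= window_days)
    out = df.loc[keep, ["vaccine", "event"]].copy()
    out["tto"] = tto[keep].astype(int)
    return out


def tto_sample(reports, pair: PairKey | tuple[str, str], window_days: int) -> np.ndarray:
    """In-window TTO values (integer days) of the pair's own reports.

    The window is inclusive on both ends, [0, window_days]; reports with
    missing or out-of-window TTO are excluded.
    """
    v, e = pair
    w = _window_frame(reports_to_frame(reports), window_days)
    return w.loc[(w["vaccine"] == v) & (w["event"] == e), "tto"].to_numpy()


def background_samples(reports, pair: PairKey | tuple[str, str],
                       window_days: int) -> tuple[np.ndarray, np.ndarray]:
    """The two background TTO samples for a pair.

    between-events: same vaccine, any other event; between-vaccines: same
    event, any other vaccine.  The target pair's own reports are in neither.
    """
    v, e = pair
    w = _window_frame(reports_to_frame(reports), window_days)
    be = w.loc[(w["vaccine"] == v) & (w["event"] != e), "tto"].to_numpy()
    bv = w.loc[(w["event"] == e) & (w["vaccine"] != v), "tto"].to_numpy()
    return be, bv


# ---------------------------------------------------------------------------
# the KS test


def _ks_d(x: np.ndarray, y: np.ndarray) -> float:
    """sup_t |ECDF_x(t) - ECDF_y(t)| over the pooled observed values."""
    xs = np.sort(x)
    ys = np.sort(y)
    support = np.union1d(xs, ys)
    fx = np.searchsorted(xs, support, side="right") / xs.size
    fy = np.searchsorted(ys, support, side="right") / ys.size
    return float(np.max(np.abs(fx - fy)))


def ks_two_sample(x: Iterable[float], y: Iterable[float],
                  method: str = "asymp") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test with ties allowed.

    Returns (D, p).  D is the exact sup of the ECDF difference evaluated at
    all pooled observed values.  ``method="asymp"`` (default) takes p as the
    Kolmogorov distribution tail at D * sqrt(n*m/(n+m)); ``method="exact"``
    uses the exact small-sample null distribution (only when n*m <= 10000,
    otherwise it falls back to the asymptotic tail).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    d = _ks_d(x, y)
    n, m = x.size, y.size
    if method == "exact" and n * m <= 10_000:
        # exact two-sample null distribution (path-counting), via scipy
        p = float(stats.ks_2samp(x, y, method="exact").pvalue)
    else:
        p = float(special.kolmogorov(d * np.sqrt(n * m / (n + m))))
    return d, min(max(p, 0.0), 1.0)


# ---------------------------------------------------------------------------
# flagging


def flag_pair(reports, pair: PairKey | tuple[str, str], config: TTOConfig,
              method: str = "asymp") -> TTOResult:
    """Run the dual-background KS rule for one pair.

    Flagged iff the target sample has at least ``min_target`` in-window TTO
    values, both backgrounds are non-empty, and both KS p-values < alpha.
    """
    pair = PairKey(*pair)
    target = tto_sample(reports, pair, config.window_days)
    be, bv = background_samples(reports, pair, config.window_days)
    return _flag_from_samples(pair, target, be, bv, config, method)


def _flag_from_samples(pair: PairKey, target: np.ndarray, be: np.ndarray,
                       bv: np.ndarray, config: TTOConfig,
                       method: str = "asymp") -> TTOResult:
    nt, nbe, nbv = target.size, be.size, bv.size
    if nt < max(1, config.min_target):
        status = TTOStatus.INSUFFICIENT_TARGET
        d_e = p_e = d_v = p_v = float("nan")
    elif nbe == 0 or nbv == 0:
        status = TTOStatus.INSUFFICIENT_BACKGROUND
        d_e = p_e = d_v = p_v = float("nan")
    else:
        status = TTOStatus.OK
        d_e, p_e = ks_two_sample(target, be, method=method)
        d_v, p_v = ks_two_sample(target, bv, method=method)
    flagged = (status is TTOStatus.OK
               and p_e < config.alpha and p_v < config.alpha)
    return TTOResult(pair=pair, n_target=nt, n_bg_events=nbe, n_bg_vaccines=nbv,
                     d_events=d_e, p_events=p_e, d_vaccines=d_v, p_vaccines=p_v,
                     status=status, flagged=bool(flagged))


# ---------------------------------------------------------------------------
# model / results objects


class TTOScreen:
    """Database-wide TTO screen: the dual-background KS rule for every pair.

    Parameters
    ----------
    reports : list of Report or DataFrame
    config : TTOConfig, or pass alpha / window_days / min_target directly.
    method : "asymp" (default) or "exact" p-values.

    The evaluation universe is every reported vaccine-event pair, including
    pairs with no usable TTO data (they are scored INSUFFICIENT_* and are
    never flagged — the detector's structural blind spot).
    """

    def __init__(self, reports, config: TTOConfig | None = None, *,
                 alpha: float = 0.05, window_days: int = 60,
                 min_target: int = 1, method: str = "asymp"):
        self.frame = reports_to_frame(reports)
        self.config = config or TTOConfig(alpha, window_days, min_target)
        self.method = method

    def fit(self) -> "TTOScreenResults":
        cfg = self.config
        df = self.frame
        pairs = df.groupby(["vaccine", "event"]).size()
        w = _window_frame(df, cfg.window_days)

        # in-window TTO arrays per vaccine (with event codes) and per event
        # (with vaccine codes), so each pair's backgrounds are one mask away
        by_vac = {v: (g["tto"].to_numpy(), g["event"].to_numpy())
                  for v, g in w.groupby("vaccine")}
        by_eve = {e: (g["tto"].to_numpy(), g["vaccine"].to_numpy())
                  for e, g in w.groupby("event")}
        empty = np.empty(0, dtype=int)

        results = []
        for (v, e) in pairs.index:
            vac_tto, vac_eve = by_vac.get(v, (empty, empty))
            eve_tto, eve_vac = by_eve.get(e, (empty, empty))
            target = vac_tto[vac_eve == e]
            be = vac_tto[vac_eve != e]
            bv = eve_tto[eve_vac != v]
            results.append(_flag_from_samples(PairKey(v, e), target, be, bv,
                                              cfg, self.method))
        return TTOScreenResults(self, results)


class TTOScreenResults:
    """Per-pair KS outcomes for one TTO configuration."""

    def __init__(self, model: TTOScreen, results: list[TTOResult]):
        self.model = model
        self.results = results

    @property
    def config(self) -> TTOConfig:
        return self.model.config

    @property
    def table(self) -> pd.DataFrame:
        rows = [(r.pair.vaccine, r.pair.event, r.n_target, r.n_bg_events,
                 r.n_bg_vaccines, r.d_events, r.p_events, r.d_vaccines,
                 r.p_vaccines, r.status.value, r.flagged) for r in self.results]
        return pd.DataFrame(rows, columns=[
            "vaccine", "event", "n_target", "n_bg_events", "n_bg_vaccines",
            "D_events", "p_events", "D_vaccines", "p_vaccines",
            "status", "flagged"])

    def flagged(self, alpha: float | None = None) -> set[PairKey]:
        """Flagged pairs; pass ``alpha`` to re-threshold the stored p-values."""
        if alpha is None:
            return {r.pair for r in self.results if r.flagged}
        return {r.pair for r in self.results
                if r.status is TTOStatus.OK
                and r.p_events < alpha and r.p_vaccines < alpha}

    def scores(self) -> dict[PairKey, float]:
        """max(p_events, p_vaccines) per OK pair — flag iff score < alpha."""
        return {r.pair: max(r.p_events, r.p_vaccines)
                for r in self.results if r.status is TTOStatus.OK}

    def summary(self) -> str:
        n_ok = sum(r.status is TTOStatus.OK for r in self.results)
        n_fl = sum(r.flagged for r in self.results)
        lines = [
            "TTO screen (dual-background two-sample Kolmogorov-Smirnov)",
            f"  configuration : {self.config.label} "
            f"(alpha={self.config.alpha}, window=[0,{self.config.window_days}] days)",
            f"  pairs         : {len(self.results)} "
            f"({n_ok} testable, {len(self.results) - n_ok} without usable TTO)",
            f"  flagged       : {n_fl}",
        ]
        return "\n".join(lines)
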