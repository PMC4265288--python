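"""Synthetic spontaneous-report databases with known injected signals.

The generator emulates the statistical structure the two detectors assume:

* multi-vaccine, multi-event report streams whose pair counts are Poisson
  with mean = baseline (vaccine propensity x event propensity x database
  size) x stratum effect x injected relative rate;
* stratum-dependent reporting: each vaccine has a demographic profile
  (paediatric / adolescent / adult age mix, female fraction), region and
  reporting-year mixes, so stratification genuinely changes expected counts;
* a reporting-bias time-to-onset background — geometric decay (default mean
  10 days, truncated at 365): the later an event occurs after immunisation,
  the less likely it is reported;
* per-vaccine TTO missingness (default evenly spread over 12%-52%);
* injected disproportionality signals (relative reporting rate >= 1 on a
  pair, background TTO) and injected TTO signals (clustered discretised
  log-normal onset), plus an optional "lack-of-efficacy-like" event class
  with uniform TTO on 91..365 days — the TTO detector's structural blind
  spot.

The ground truth is emitted as a gold standard so the evaluation module
consumes simulation output unchanged.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reports import GoldStandard, PairKey, Report, UNKNOWN

__all__ = [
    "TTOSignalSpec",
    "GeometricTTO",
    "SimConfig",
    "SimulatedDatabase",
    "simulate_database",
    "expected_pair_counts",
    "table_like_fixture",
]

_PROFILES = {
    # age-group mix over the default bins [0,2) [2,12) [12,18) [18,46) [46,66) 66+
    "paediatric": {"age": (0.60, 0.30, 0.05, 0.03, 0.01, 0.01), "female": 0.46},
    "adolescent": {"age": (0.02, 0.18, 0.60, 0.15, 0.03, 0.02), "female": 0.85},
    "adult": {"age": (0.01, 0.04, 0.10, 0.45, 0.25, 0.15), "female": 0.60},
}
_AGE_BOUNDS = ((0.0, 2.0), (2.0, 12.0), (12.0, 18.0),
               (18.0, 46.0), (46.0, 66.0), (66.0, 90.0))
_REGIONS = ("EU", "NAM", "ROW")
_REGION_P = (0.5, 0.3, 0.2)
_UNKNOWN_SEX_P = 0.05   # fraction of reports with unrecorded sex
_UNKNOWN_AGE_P = 0.08   # fraction with unrecorded age


@dataclass(frozen=True)
class GeometricTTO:
    """Geometric-decay background TTO on integer days, truncated."""

    mean_days: float = 10.0
    truncate: int = 365

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = 1.0 / (self.mean_days + 1.0)
        x = rng.geometric(p, size=size) - 1  # support 0, 1, 2, ...
        return np.minimum(x, self.truncate)


@dataclass(frozen=True)
class TTOSignalSpec:
    """Clustered onset for an injected TTO signal: discretised log-normal.

    ``relative_rate`` multiplies the pair's reporting rate — a genuine
    causal signal produces excess reports as well as a clustered onset.
    """

    mode_days: float = 3.0
    sigma: float = 0.35
    truncate: int = 365
    relative_rate: float = 1.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        mu = np.log(self.mode_days) + self.sigma ** 2  # log-normal mode = mode_days
        x = np.rint(rng.lognormal(mu, self.sigma, size=size)).astype(int)
        return np.clip(x, 0, self.truncate)


@dataclass
class SimConfig:
    """Study conditions of a simulated spontaneous-report database.

    ``n_reports`` is the expected database size; realised size is Poisson.
    ``baseline_rates`` (vaccines x events) overrides the default product-of-
    propensities baseline.  ``strata_effects`` maps a factor ("sex", "age",
    "region", "year") to per-level rate multipliers.  Injected signals list
    (vaccine, event, relative rate) for disproportionality and
    (vaccine, event, TTOSignalSpec) for clustered onset; ``long_tto_events``
    names events whose TTO is uniform on 91..365 days for every vaccine.
    ``tto_missingness`` is per vaccine; by default evenly spread over
    [0.12, 0.52].  The seed fully determines the output.
    """

    n_vaccines: int = 20
    n_events: int = 60
    n_reports: int = 50_000
    baseline_rates: np.ndarray | None = None
    strata_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    injected_dpa_signals: Sequence[tuple[str, str, float]] = ()
    injected_tto_signals: Sequence[tuple[str, str, TTOSignalSpec]] = ()
    long_tto_events: Sequence[str] = ()
    tto_missingness: Sequence[float] | None = None
    background_tto: GeometricTTO = GeometricTTO()
    date_range: tuple[str, str] = ("2005-01-01", "2009-12-31")
    seed: int = 0

    def vaccine_names(self) -> list[str]:
        return [f"V{i + 1:02d}" for i in range(self.n_vaccines)]

    def event_names(self) -> list[str]:
        return [f"E{j + 1:03d}" for j in range(self.n_events)]

    def profiles(self) -> list[str]:
        keys = list(_PROFILES)
        return [keys[i % len(keys)] for i in range(self.n_vaccines)]

    def missingness(self) -> np.ndarray:
        if self.tto_missingness is not None:
            m = np.asarray(self.tto_missingness, dtype=float)
            if m.size != self.n_vaccines:
                raise ValueError("tto_missingness needs one value per vaccine")
            return m
        if self.n_vaccines == 1:
            return np.array([0.32])
        return np.linspace(0.12, 0.52, self.n_vaccines)

    def years(self) -> list[int]:
        y0 = int(self.date_range[0][:4])
        y1 = int(self.date_range[1][:4])
        return list(range(y0, y1 + 1))


def _marginal_propensities(k: int) -> np.ndarray:
    w = 1.0 / np.arange(1, k + 1)  # Zipf-like: few common codes, a long tail
    return w / w.sum()


def _mean_tensor(config: SimConfig) -> np.ndarray:
    """Expected counts per (vaccine, event, sex, agegrp, region, year) cell."""
    nv, ne = config.n_vaccines, config.n_events
    if config.baseline_rates is not None:
        base = np.asarray(config.baseline_rates, dtype=float)
        if base.shape != (nv, ne):
            raise ValueError("baseline_rates must be (n_vaccines, n_events)")
    else:
        base = config.n_reports * np.outer(_marginal_propensities(nv),
                                           _marginal_propensities(ne))

    vnames, enames = config.vaccine_names(), config.event_names()
    vidx = {v: i for i, v in enumerate(vnames)}
    eidx = {e: j for j, e in enumerate(enames)}
    rr = np.ones((nv, ne))
    for v, e, rate in config.injected_dpa_signals:
        if rate < 1:
            raise ValueError("injected relative rates must be >= 1")
        rr[vidx[v], eidx[e]] *= rate
    for v, e, spec in config.injected_tto_signals:
        if spec.relative_rate < 1:
            raise ValueError("injected relative rates must be >= 1")
        rr[vidx[v], eidx[e]] *= spec.relative_rate

    profiles = config.profiles()
    sex_p = np.empty((nv, 3))   # F, M, UNKNOWN
    age_p = np.empty((nv, 7))   # 6 bins + UNKNOWN
    for i, prof in enumerate(profiles):
        f = _PROFILES[prof]["female"]
        sex_p[i] = ((1 - _UNKNOWN_SEX_P) * f,
                    (1 - _UNKNOWN_SEX_P) * (1 - f),
                    _UNKNOWN_SEX_P)
        age = np.asarray(_PROFILES[prof]["age"])
        age_p[i, :6] = (1 - _UNKNOWN_AGE_P) * age
        age_p[i, 6] = _UNKNOWN_AGE_P

    years = config.years()
    year_w = np.arange(1, len(years) + 1, dtype=float)  # reporting grows
    year_p = year_w / year_w.sum()
    region_p = np.asarray(_REGION_P)

    eff = config.strata_effects
    sex_eff = np.array([eff.get("sex", {}).get(s, 1.0) for s in ("F", "M", UNKNOWN)])
    age_eff = np.array([eff.get("age", {}).get(str(a), 1.0) for a in range(7)])
    region_eff = np.array([eff.get("region", {}).get(r, 1.0) for r in _REGIONS])
    year_eff = np.array([eff.get("year", {}).get(str(y), 1.0) for y in years])

    mean = (base * rr)[:, :, None, None, None, None] \
        * (sex_p * sex_eff)[:, None, :, None, None, None] \
        * (age_p * age_eff)[:, None, None, :, None, None] \
        * (region_p * region_eff)[None, None, None, None, :, None] \
        * (year_p * year_eff)[None, None, None, None, None, :]
    return mean


def expected_pair_counts(config: SimConfig) -> pd.DataFrame:
    """Configured expected report count per vaccine-event pair."""
    mean = _mean_tensor(config).sum(axis=(2, 3, 4, 5))
    return pd.DataFrame(mean, index=config.vaccine_names(),
                        columns=config.event_names())


@dataclass
class SimulatedDatabase:
    """A generated database plus its ground truth."""

    config: SimConfig
    frame: pd.DataFrame          # canonical reports frame
    truth: GoldStandard          # injected signals, every vaccine covered
    truth_pairs: frozenset[PairKey]

    @property
    def reports(self) -> list[Report]:
        from .reports import frame_to_reports

        return frame_to_reports(self.frame.drop(columns=["report_year"]))


def simulate_database(config: SimConfig) -> SimulatedDatabase:
    """Draw one database from the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    mean = _mean_tensor(config)
    counts = rng.poisson(mean)
    nv, ne = config.n_vaccines, config.n_events
    vnames, enames = config.vaccine_names(), config.event_names()
    years = config.years()

    # expand cells to one row per report mention
    flat = counts.reshape(-1)
    nz = np.nonzero(flat)[0]
    reps = flat[nz]
    cell_idx = np.repeat(nz, reps)
    shape = counts.shape
    vi, ei, si, ai, ri, yi = np.unravel_index(cell_idx, shape)
    n = vi.size

    sex = np.array(["F", "M", UNKNOWN], dtype=object)[si]
    region = np.array(_REGIONS, dtype=object)[ri]
    year = np.asarray(years)[yi]

    # age: uniform within bin; UNKNOWN level (index 6) -> NaN
    age = np.full(n, np.nan)
    for b, (lo, hi) in enumerate(_AGE_BOUNDS):
        m = ai == b
        if m.any():
            age[m] = rng.uniform(lo, hi, size=int(m.sum()))

    # receipt date: uniform within the report's year, clipped to date_range
    start = np.datetime64(config.date_range[0])
    end = np.datetime64(config.date_range[1])
    y0 = np.array([np.datetime64(f"{y}-01-01") for y in years])
    y1 = np.array([np.datetime64(f"{y}-12-31") for y in years])
    ystart = np.maximum(y0[yi], start)
    yend = np.minimum(y1[yi], end)
    span = (yend - ystart).astype(int) + 1
    date = ystart + rng.integers(0, span).astype("timedelta64[D]")

    # time to onset: background decay, overridden per injected TTO signal and
    # per long-TTO event class, then masked by per-vaccine missingness
    tto = config.background_tto.sample(rng, n).astype(float)
    eidx = {e: j for j, e in enumerate(enames)}
    vidx = {v: i for i, v in enumerate(vnames)}
    for ev in config.long_tto_events:
        m = ei == eidx[ev]
        if m.any():
            tto[m] = rng.integers(91, 366, size=int(m.sum()))
    for v, e, spec in config.injected_tto_signals:
        m = (vi == vidx[v]) & (ei == eidx[e])
        if m.any():
            tto[m] = spec.sample(rng, int(m.sum()))
    miss_p = config.missingness()[vi]
    tto[rng.uniform(size=n) < miss_p] = np.nan

    frame = pd.DataFrame({
        "vaccine": np.array(vnames, dtype=object)[vi],
        "event": np.array(enames, dtype=object)[ei],
        "sex": sex,
        "age_years": age,
        "region": region,
        "tto_days": tto,
        "receipt_date": date.astype("datetime64[ns]"),
        "report_year": year,
    })
    frame = frame.sort_values("receipt_date", kind="stable").reset_index(drop=True)
    frame.insert(0, "report_id", [f"R{i + 1:07d}" for i in range(n)])
    frame["receipt_date"] = frame["receipt_date"].dt.date

    truth_map: dict[str, set[str]] = {v: set() for v in vnames}
    pairs = set()
    for v, e, _ in list(config.injected_dpa_signals) + list(config.injected_tto_signals):
        truth_map[v].add(e)
        pairs.add(PairKey(v, e))
    truth = GoldStandard(truth_map)
    return SimulatedDatabase(config=config, frame=frame, truth=truth,
                             truth_pairs=frozenset(pairs))


def table_like_fixture(seed: int = 20130909) -> SimulatedDatabase:
    """The standard small test database: 8 heterogeneous vaccines, ~2000 rows.

    Deterministic for a given seed; vaccines span paediatric, adolescent and
    adult demographic profiles with per-vaccine TTO missingness spread over
    [0.12, 0.52], and it carries a handful of injected signals of both kinds
    so end-to-end runs produce true positives.
    """
    config = SimConfig(
        n_vaccines=8,
        n_events=30,
        n_reports=2000,
        injected_dpa_signals=(("V02", "E025", 8.0), ("V05", "E028", 10.0)),
        injected_tto_signals=(
            ("V01", "E020", TTOSignalSpec(mode_days=2.0, relative_rate=6.0)),
            ("V03", "E022", TTOSignalSpec(mode_days=4.0, relative_rate=15.0))),
        long_tto_events=("E030",),
        tto_missingness=(0.12, 0.18, 0.22, 0.28, 0.33, 0.39, 0.45, 0.52),
        seed=seed,
    )
    return simulate_database(config)
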