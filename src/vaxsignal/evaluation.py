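"""Benchmarking protocol: confusion metrics, PPV median-rank, ROC, timing.

The evaluation universe is the set of *reported* vaccine-event pairs (N >= 1),
never the full vaccine x event cross product.  Against a gold standard of
labelled (product-information) events, each reported pair is a true/false
positive/negative; the headline comparison ranks detectors per vaccine by
descending PPV and aggregates by the median rank across vaccines.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mgps import MGPS, MGPSConfig
from .reports import GoldStandard, PairKey, reports_to_frame
from .tto import TTOConfig, TTOScreen, TTOStatus

__all__ = [
    "ConfusionMetrics",
    "RankSummary",
    "ROCCurve",
    "DetectionTiming",
    "classify",
    "rank_algorithms",
    "per_vaccine_ppv",
    "roc_curve",
    "time_to_detection",
    "MGPSDetector",
    "TTODetector",
    "plot_roc",
]


@dataclass(frozen=True)
class ConfusionMetrics:
    """TP/FP/TN/FN cells and the derived rates over the evaluable universe."""

    tp: int
    fp: int
    tn: int
    fn: int
    excluded: int = 0  # pairs whose vaccine the gold standard does not cover

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else float("nan")

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def n_evaluable(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def classify(flagged: Iterable[PairKey | tuple[str, str]],
             universe: Iterable[PairKey | tuple[str, str]],
             gold: GoldStandard) -> ConfusionMetrics:
    """Classify every reported pair as TP/FP/TN/FN against the gold standard.

    ``flagged`` must be a subset of ``universe``; pairs of vaccines the gold
    standard does not cover are excluded (counted in ``excluded``).
    """
    universe = {PairKey(*p) for p in universe}
    flagged = {PairKey(*p) for p in flagged}
    stray = flagged - universe
    if stray:
        raise ValueError(f"{len(stray)} flagged pairs outside the universe")
    tp = fp = tn = fn = excluded = 0
    for pair in universe:
        status = gold.lookup(pair.vaccine, pair.event)
        if status is None:
            excluded += 1
        elif pair in flagged:
            tp, fp = (tp + 1, fp) if status else (tp, fp + 1)
        else:
            fn, tn = (fn + 1, tn) if status else (fn, tn + 1)
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn, excluded=excluded)


# ---------------------------------------------------------------------------
# PPV ranking


@dataclass
class RankSummary:
    """One detector's per-vaccine PPV ranks and their aggregate."""

    label: str
    ranks: dict[str, float]       # vaccine -> midrank (missing PPVs dropped)
    median_rank: float
    rank_sd: float


def per_vaccine_ppv(flagged: Iterable[PairKey], universe: Iterable[PairKey],
                    gold: GoldStandard) -> dict[str, float]:
    """PPV restricted to each vaccine's reported pairs (NaN when unflagged)."""
    universe = {PairKey(*p) for p in universe}
    flagged = {PairKey(*p) for p in flagged}
    out: dict[str, float] = {}
    for v in sorted({p.vaccine for p in universe} & set(gold.vaccines)):
        uv = {p for p in universe if p.vaccine == v}
        fv = flagged & uv
        m = classify(fv, uv, gold)
        out[v] = m.ppv
    return out


def rank_algorithms(ppv: pd.DataFrame | Mapping[str, Mapping[str, float]]
                    ) -> list[RankSummary]:
    """Rank detectors by descending PPV within each vaccine; aggregate medians.

    ``ppv`` is detectors x vaccines (rows x columns when a DataFrame).  Rank 1
    is the highest PPV; ties receive midranks.  A NaN PPV (the detector
    flagged nothing for that vaccine) drops that detector from that vaccine's
    rank vector rather than being imputed.  Output is sorted by ascending
    median rank (best first), ties broken by label.
    """
    df = pd.DataFrame(ppv).T if not isinstance(ppv, pd.DataFrame) else ppv.copy()
    if df.shape[0] < 2 or df.shape[1] < 1:
        raise ValueError("need at least 2 algorithms and 1 vaccine")
    ranks = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for v in df.columns:
        col = df[v]
        ok = col.notna()
        if ok.any():
            ranks.loc[ok, v] = stats.rankdata(-col[ok].to_numpy(), method="average")
    out = []
    for label in df.index:
        r = ranks.loc[label].dropna()
        out.append(RankSummary(
            label=str(label),
            ranks={str(v): float(x) for v, x in r.items()},
            median_rank=float(np.median(r)) if len(r) else float("nan"),
            rank_sd=float(np.std(r, ddof=1)) if len(r) > 1 else float("nan"),
        ))
    out.sort(key=lambda s: (np.inf if np.isnan(s.median_rank) else s.median_rank,
                            s.label))
    return out


# ---------------------------------------------------------------------------
# ROC


@dataclass
class ROCCurve:
    """(threshold, sensitivity, 1 - specificity) points for one score sweep."""

    label: str
    points: pd.DataFrame  # columns threshold, sensitivity, one_minus_specificity

    @property
    def auc(self) -> float:
        """Trapezoidal area under the (FPR, TPR) polyline, endpoints appended."""
        fpr = self.points["one_minus_specificity"].to_numpy()
        tpr = self.points["sensitivity"].to_numpy()
        order = np.argsort(fpr, kind="stable")
        fpr = np.concatenate(([0.0], fpr[order], [1.0]))
        tpr = np.concatenate(([0.0], tpr[order], [1.0]))
        return float(np.trapezoid(tpr, fpr))


def roc_curve(scores: Mapping[PairKey, float], universe: Iterable[PairKey],
              gold: GoldStandard, thresholds: Sequence[float],
              direction: str = "greater", label: str = "") -> ROCCurve:
    """Sweep a flagging threshold over per-pair scores and classify each time.

    ``direction="greater"`` flags score > t (MGPS: score = EB05);
    ``direction="less"`` flags score < t (TTO: score = max of the two KS
    p-values, so score < alpha is exactly the dual-significance rule).
    Pairs absent from ``scores`` (no usable TTO data) are never flagged —
    they cap the attainable sensitivity.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    universe = [PairKey(*p) for p in universe]
    rows = []
    for t in thresholds:
        if direction == "greater":
            flagged = {p for p in universe if p in scores and scores[p] > t}
        else:
            flagged = {p for p in universe if p in scores and scores[p] < t}
        m = classify(flagged, universe, gold)
        rows.append((float(t), m.sensitivity, 1.0 - m.specificity))
    pts = pd.DataFrame(rows, columns=["threshold", "sensitivity",
                                      "one_minus_specificity"])
    return ROCCurve(label=label, points=pts)


def plot_roc(curves: Iterable[ROCCurve], ax=None):
    """Render ROC curves (matplotlib); returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for c in curves:
        pts = c.points.sort_values("one_minus_specificity")
        ax.plot(pts["one_minus_specificity"], pts["sensitivity"],
                label=f"{c.label} (AUC={c.auc:.2f})")
    ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    return ax


# ---------------------------------------------------------------------------
# time-to-detection replay


@dataclass(frozen=True)
class DetectionTiming:
    """Report counts at the first chronological detection of a pair."""

    pair: PairKey
    label: str
    reports_received: int  # all reports in the database at first detection
    reports_used: int      # reports the detector actually consumed


class MGPSDetector:
    """Replay adapter: does one MGPS grid point flag the pair on a prefix?"""

    def __init__(self, config: MGPSConfig):
        self.config = config
        self.label = config.label

    def __call__(self, prefix: pd.DataFrame, pair: PairKey) -> tuple[bool, int]:
        if not ((prefix["vaccine"] == pair.vaccine)
                & (prefix["event"] == pair.event)).any():
            return False, len(prefix)
        try:
            res = MGPS(prefix, self.config.stratification).fit(strict=False)
        except ValueError:
            return False, len(prefix)
        return pair in res.flagged(self.config.threshold), len(prefix)


class TTODetector:
    """Replay adapter for a TTO grid point.

    ``used_scope`` controls what counts as a consumed report: "target"
    (in-window non-missing TTO reports of the pair itself) or
    "target+background" (default; adds both backgrounds' in-window reports).
    """

    def __init__(self, config: TTOConfig, used_scope: str = "target+background",
                 method: str = "asymp"):
        if used_scope not in ("target", "target+background"):
            raise ValueError("used_scope must be 'target' or 'target+background'")
        self.config = config
        self.used_scope = used_scope
        self.method = method
        self.label = config.label

    def __call__(self, prefix: pd.DataFrame, pair: PairKey) -> tuple[bool, int]:
        from .tto import background_samples, flag_pair, tto_sample

        res = flag_pair(prefix, pair, self.config, method=self.method)
        used = res.n_target
        if self.used_scope == "target+background":
            used += res.n_bg_events + res.n_bg_vaccines
        return res.flagged, used


def time_to_detection(reports, pair: PairKey | tuple[str, str],
                      detector: Callable[[pd.DataFrame, PairKey], tuple[bool, int]],
                      mode: str = "full") -> DetectionTiming | None:
    """Replay the database in receipt-date order until the pair is flagged.

    ``mode="full"`` re-runs the detector after every incoming report (the
    reference behaviour); ``mode="coarse"`` re-evaluates only when the target
    pair itself gains a report (much cheaper; first-detection counts agree
    on databases where intermediate arrivals cannot un-flag the pair, which
    is checked by test rather than assumed).  Returns None when the pair is
    never flagged on the full database.
    """
    if mode not in ("full", "coarse"):
        raise ValueError("mode must be 'full' or 'coarse'")
    pair = PairKey(*pair)
    df = reports_to_frame(reports)
    df = df.sort_values(["receipt_date", "report_id"], kind="stable").reset_index(drop=True)

    if mode == "coarse":
        hits = df.index[(df["vaccine"] == pair.vaccine)
                        & (df["event"] == pair.event)].tolist()
        checkpoints = [i + 1 for i in hits]
    else:
        checkpoints = list(range(1, len(df) + 1))

    for k in checkpoints:
        flagged, used = detector(df.iloc[:k], pair)
        if flagged:
            label = getattr(detector, "label", "")
            return DetectionTiming(pair=pair, label=label,
                                   reports_received=k, reports_used=used)
    return None
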