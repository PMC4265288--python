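"""Benchmark protocol: classification, ranking, ROC sweeps, detection timing."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vaxsignal.evaluation import (
    ConfusionMetrics,
    MGPSDetector,
    TTODetector,
    classify,
    per_vaccine_ppv,
    rank_algorithms,
    roc_curve,
    time_to_detection,
)
from vaxsignal.mgps import MGPS, MGPSConfig, run_mgps
from vaxsignal.reports import GoldStandard, PairKey, StratumSpec
from vaxsignal.simulate import SimConfig, TTOSignalSpec, simulate_database
from vaxsignal.tto import TTOConfig, TTOScreen

from conftest import make_report


class TestClassify:
    @pytest.mark.parametrize("cells,rates", [
        # (TP, FP, TN, FN) -> (ppv, npv, sensitivity, specificity)
        ((77, 53, 8791, 722), (0.592, 0.924, 0.09637, 0.994)),
        ((195, 763, 8081, 604), (0.204, 0.930, 0.24406, 0.914)),
    ])
    def test_rate_formulas(self, cells, rates):
        m = ConfusionMetrics(*cells)
        ppv, npv, sens, spec = rates
        assert round(m.ppv, 3) == ppv
        assert round(m.npv, 3) == npv
        assert round(m.sensitivity, 5) == sens
        assert round(m.specificity, 3) == spec

    def test_set_classification(self):
        gold = GoldStandard({"V1": {"E1"}, "V2": {"E2"}})
        universe = {("V1", "E1"), ("V1", "E2"), ("V2", "E1"), ("V2", "E2")}
        flagged = {("V1", "E1"), ("V2", "E1")}
        m = classify(flagged, universe, gold)
        assert (m.tp, m.fp, m.tn, m.fn) == (1, 1, 1, 1)

    def test_flag_everything_degenerate(self):
        gold = GoldStandard({"V1": {"E1"}})
        universe = {("V1", "E1"), ("V1", "E2"), ("V1", "E3")}
        m = classify(universe, universe, gold)
        assert m.fn == 0 and m.tn == 0
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_uncovered_vaccine_excluded_and_conserved(self):
        gold = GoldStandard({"V1": {"E1"}})
        universe = {("V1", "E1"), ("V2", "E1"), ("V2", "E2")}
        m = classify({("V1", "E1")}, universe, gold)
        assert m.excluded == 2
        assert m.n_evaluable + m.excluded == len(universe)

    def test_flagged_must_be_subset(self):
        gold = GoldStandard({"V1": {"E1"}})
        with pytest.raises(ValueError):
            classify({("V1", "E9")}, {("V1", "E1")}, gold)


class TestRanking:
    def test_total_order(self):
        ppv = pd.DataFrame({"v1": [0.6, 0.2], "v2": [0.6, 0.2], "v3": [0.6, 0.2]},
                           index=["A", "B"])
        ranks = rank_algorithms(ppv)
        assert ranks[0].label == "A" and ranks[0].median_rank == 1.0
        assert ranks[1].label == "B" and ranks[1].median_rank == 2.0

    def test_midrank_ties(self):
        ppv = pd.DataFrame({"v1": [0.5, 0.5]}, index=["A", "B"])
        ranks = rank_algorithms(ppv)
        assert all(r.ranks["v1"] == 1.5 for r in ranks)

    def test_missing_ppv_dropped_not_imputed(self):
        ppv = pd.DataFrame({"v1": [0.5, np.nan], "v2": [0.2, 0.4]}, index=["A", "B"])
        ranks = {r.label: r for r in rank_algorithms(ppv)}
        assert set(ranks["B"].ranks) == {"v2"}
        assert ranks["B"].ranks["v2"] == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        ppv = pd.DataFrame(rng.uniform(size=(5, 4)),
                           index=list("ABCDE"), columns=list("wxyz"))
        got = {r.label: r for r in rank_algorithms(ppv)}
        for v in ppv.columns:
            # brute force: sort descending, assign midranks by value groups
            vals = ppv[v]
            for alg in ppv.index:
                better = (vals > vals[alg]).sum()
                equal = (vals == vals[alg]).sum()
                midrank = better + (equal + 1) / 2
                assert got[alg].ranks[v] == pytest.approx(midrank)
        for alg in ppv.index:
            assert got[alg].median_rank == pytest.approx(
                np.median(list(got[alg].ranks.values())))
            assert got[alg].rank_sd == pytest.approx(
                np.std(list(got[alg].ranks.values()), ddof=1))

    def test_midranks_sum_per_vaccine(self):
        rng = np.random.default_rng(3)
        vals = rng.choice([0.1, 0.2, 0.2, 0.5], size=(6, 3))
        ppv = pd.DataFrame(vals, index=list("ABCDEF"), columns=list("uvw"))
        ranks = rank_algorithms(ppv)
        n = len(ppv.index)
        for v in ppv.columns:
            assert sum(r.ranks[v] for r in ranks) == pytest.approx(n * (n + 1) / 2)


class TestROC:
    def _setup(self):
        rng = np.random.default_rng(8)
        universe = [(f"V{i%4+1}", f"E{j}") for i, j in
                    enumerate(rng.integers(0, 40, 100))]
        universe = sorted(set(universe))
        gold = GoldStandard({f"V{k}": {f"E{j}" for j in range(0, 40, 5)}
                             for k in range(1, 5)})
        scores = {PairKey(*p): float(rng.lognormal(0, 1)) for p in universe}
        return universe, gold, scores

    def test_threshold_zero_flags_all_scored(self):
        universe, gold, scores = self._setup()
        curve = roc_curve(scores, universe, gold, [0.0], direction="greater")
        m = classify({p for p in scores if scores[p] > 0}, universe, gold)
        assert curve.points["sensitivity"][0] == pytest.approx(m.sensitivity)

    def test_unscored_pairs_cap_sensitivity(self):
        universe, gold, scores = self._setup()
        labelled = [p for p in universe if gold.lookup(*p)]
        dropped = {PairKey(*p) for p in labelled[:3]}
        partial = {p: s for p, s in scores.items() if p not in dropped}
        curve = roc_curve(partial, universe, gold, [0.0], direction="greater")
        ceiling = 1.0 - len(dropped) / len(labelled)
        assert curve.points["sensitivity"][0] <= ceiling

    def test_matches_per_threshold_brute_force(self):
        universe, gold, scores = self._setup()
        thresholds = np.linspace(0, 5, 26)
        curve = roc_curve(scores, universe, gold, thresholds, direction="greater")
        for i, t in enumerate(thresholds):
            flagged = {p for p, s in scores.items() if s > t}
            m = classify(flagged, universe, gold)
            assert curve.points["sensitivity"][i] == pytest.approx(m.sensitivity)
            assert curve.points["one_minus_specificity"][i] == pytest.approx(
                1 - m.specificity)

    def test_monotone_under_tightening(self):
        universe, gold, scores = self._setup()
        curve = roc_curve(scores, universe, gold, np.linspace(0, 8, 40),
                          direction="greater")
        sens = curve.points["sensitivity"].to_numpy()
        fpr = curve.points["one_minus_specificity"].to_numpy()
        assert (np.diff(sens) <= 1e-12).all()
        assert (np.diff(fpr) <= 1e-12).all()


def test_plot_roc_renders():
    import matplotlib

    matplotlib.use("Agg")
    from vaxsignal.evaluation import ROCCurve, plot_roc

    pts = pd.DataFrame({"threshold": [0.0, 0.5, 1.0],
                        "sensitivity": [1.0, 0.6, 0.0],
                        "one_minus_specificity": [1.0, 0.3, 0.0]})
    ax = plot_roc([ROCCurve("demo", pts)])
    assert ax.get_xlabel() == "1 - specificity"


class TestDetectorROCDominance:
    def test_auc_above_diagonal_with_bootstrap(self):
        """Injected signals with both strong disproportionality and clustered
        TTO must lift both detectors' ROC curves above the diagonal."""
        sig = [(f"V{i%8+1:02d}", f"E{18+i:03d}",
                TTOSignalSpec(mode_days=3.0, relative_rate=10.0)) for i in range(12)]
        db = simulate_database(SimConfig(
            n_vaccines=8, n_events=30, n_reports=8000, seed=21,
            injected_tto_signals=tuple(sig)))
        universe = {PairKey(v, e) for v, e in
                    db.frame.groupby(["vaccine", "event"]).size().index}
        labels = {p: db.truth.lookup(*p) for p in universe}

        mg = MGPS(db.frame, StratumSpec("SA")).fit()
        tt = TTOScreen(db.frame, TTOConfig(0.05, 60)).fit()
        mg_curve = roc_curve(mg.scores(), universe, db.truth,
                             np.arange(0, 10.01, 0.1), "greater", "MGPS")
        tt_curve = roc_curve(tt.scores(), universe, db.truth,
                             np.arange(0, 1.01, 0.01), "less", "TTO")
        assert mg_curve.auc > 0.5 and tt_curve.auc > 0.5

        def rank_auc(scores, higher_flags):
            s = np.array([scores.get(p, -np.inf if higher_flags else np.inf)
                          for p in sorted(universe)])
            y = np.array([labels[p] for p in sorted(universe)])
            if not higher_flags:
                s = -s
            return s, y

        rng = np.random.default_rng(0)
        for scores, higher in ((mg.scores(), True), (tt.scores(), False)):
            s, y = rank_auc(scores, higher)
            aucs = []
            for _ in range(199):
                idx = rng.integers(0, len(s), len(s))
                sb, yb = s[idx], y[idx]
                if yb.any() and (~yb).any():
                    r = stats.rankdata(sb)
                    aucs.append((r[yb].mean() - (yb.sum() + 1) / 2) / (~yb).sum())
            lo = np.percentile(aucs, 2.5)
            assert lo > 0.5


class TestTimeToDetection:
    def _tto_db(self):
        rows = []
        day = dt.date(2009, 1, 1)
        rng = np.random.default_rng(2)
        # background arrives first
        for i in range(60):
            rows.append(make_report("V2", "E1", rid=f"B{i:03d}",
                                    date=day + dt.timedelta(days=i),
                                    tto=int(rng.integers(0, 61))))
            rows.append(make_report("V1", "E2", rid=f"C{i:03d}",
                                    date=day + dt.timedelta(days=i),
                                    tto=int(rng.integers(0, 61))))
        # target pair accumulates clustered-onset reports afterwards
        for i in range(10):
            rows.append(make_report("V1", "E1", rid=f"T{i:03d}",
                                    date=day + dt.timedelta(days=100 + i),
                                    tto=2 if i % 3 else None))
        return rows

    def test_full_replay_matches_prefix_oracle(self):
        rows = self._tto_db()
        det = TTODetector(TTOConfig(0.05, 60), used_scope="target")
        timing = time_to_detection(rows, ("V1", "E1"), det, mode="full")
        assert timing is not None
        # oracle: independent chronological prefix scan with flag_pair
        from vaxsignal.reports import reports_to_frame
        from vaxsignal.tto import flag_pair

        ordered = sorted(rows, key=lambda r: (r.receipt_date, r.report_id))
        first = None
        for k in range(1, len(ordered) + 1):
            res = flag_pair(ordered[:k], ("V1", "E1"), TTOConfig(0.05, 60))
            if res.flagged:
                first = k
                break
        assert timing.reports_received == first
        used = sum(1 for r in ordered[:first]
                   if r.vaccine == "V1" and r.event == "E1"
                   and r.tto_days is not None and r.tto_days <= 60)
        assert timing.reports_used == used

    def test_used_scope_includes_backgrounds(self):
        rows = self._tto_db()
        both = time_to_detection(rows, ("V1", "E1"),
                                 TTODetector(TTOConfig(0.05, 60)), mode="full")
        target_only = time_to_detection(rows, ("V1", "E1"),
                                        TTODetector(TTOConfig(0.05, 60),
                                                    used_scope="target"),
                                        mode="full")
        assert both.reports_received == target_only.reports_received
        assert both.reports_used > target_only.reports_used
        assert both.reports_used <= both.reports_received

    def test_coarse_equals_full_first_detection(self):
        rows = self._tto_db()
        det = TTODetector(TTOConfig(0.05, 60))
        full = time_to_detection(rows, ("V1", "E1"), det, mode="full")
        coarse = time_to_detection(rows, ("V1", "E1"), det, mode="coarse")
        assert full.reports_received == coarse.reports_received
        assert full.reports_used == coarse.reports_used

    def test_never_flagged_returns_none(self):
        rows = self._tto_db()
        det = TTODetector(TTOConfig(0.05, 60, min_target=1000))
        assert time_to_detection(rows, ("V1", "E1"), det, mode="coarse") is None

    def test_endpoint_detection_at_final_report(self):
        rows = self._tto_db()
        # guard equal to the pair's total usable TTO count: only the complete
        # database can flag, so first detection is the last target arrival
        ordered = sorted(rows, key=lambda r: (r.receipt_date, r.report_id))
        n_usable = sum(1 for r in rows if r.vaccine == "V1" and r.event == "E1"
                       and r.tto_days is not None and r.tto_days <= 60)
        det = TTODetector(TTOConfig(0.05, 60, min_target=n_usable))
        timing = time_to_detection(rows, ("V1", "E1"), det, mode="full")
        assert timing is not None
        last_target = max(i for i, r in enumerate(ordered)
                          if r.vaccine == "V1" and r.event == "E1"
                          and r.tto_days is not None)
        assert timing.reports_received == last_target + 1

    def test_mgps_replay_coarse_matches_oracle(self, fixture_db):
        """Coarse MGPS replay reproduces an independent prefix scan over the
        dates where the target pair gains a report."""
        df = fixture_db.frame.head(400)
        pair = ("V05", "E028")  # injected disproportionality signal
        cfg = MGPSConfig(StratumSpec(""), 0.8)
        det = MGPSDetector(cfg)
        timing = time_to_detection(df, pair, det, mode="coarse")
        assert timing is not None
        ordered = df.sort_values(["receipt_date", "report_id"], kind="stable")
        hits = np.flatnonzero((ordered["vaccine"] == pair[0]).to_numpy()
                              & (ordered["event"] == pair[1]).to_numpy())
        first = None
        for i in hits:
            flagged, _ = run_mgps(ordered.iloc[:i + 1], cfg)
            if PairKey(*pair) in flagged:
                first = i + 1
                break
        assert first is not None and timing.reports_received == first
        assert timing.reports_used == first
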