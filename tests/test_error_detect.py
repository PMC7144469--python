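"""Suspect-record flagging against percentile oracles; neighbor context."""

import numpy as np
import pytest

from uqscreen.data_prep import CuratedCompound
from uqscreen.error_detect import (
    flag_suspects,
    neighbor_context,
    nearest_rank_percentile,
)
from uqscreen.featurize import FingerprintMatrix
from uqscreen.mc_model import PredictionSet


def make_pred(y_mc, unc, y_det=None):
    n = len(y_mc)
    ids = [f"C{i:03d}" for i in range(n)]
    y_mc = np.asarray(y_mc, float)
    return PredictionSet(ids, y_det if y_det is not None else y_mc, y_mc, np.asarray(unc, float))


class TestNearestRankPercentile:
    def test_matches_definition_on_distinct_sample(self, rng):
        vals = rng.permutation(100).astype(float)
        # nearest rank: ceil(p/100 * n)-th order statistic
        for p in (5, 50, 95, 100):
            k = int(np.ceil(p / 100 * 100))
            assert nearest_rank_percentile(vals, p) == np.sort(vals)[k - 1]

    def test_zero_percentile_is_minimum(self):
        assert nearest_rank_percentile(np.array([3.0, 1.0, 2.0]), 0) == 1.0


class TestFlagSuspects:
    def test_top_five_largest_errors_flagged(self, rng):
        """100 distinct errors, error_pctl=95, unc_pctl=0: exactly the 5
        largest-error compounds pass (brute-force percentile oracle)."""
        y_true = np.zeros(100)
        errs = rng.permutation(100).astype(float) + 1  # distinct
        y_mc = np.sqrt(errs)  # squared error == errs
        unc = rng.uniform(0.1, 1.0, 100)
        report = flag_suspects(make_pred(y_mc, unc), y_true, error_pctl=95, unc_pctl=0)
        expected = {f"C{i:03d}" for i in np.argsort(errs)[-5:]}
        assert set(report.flagged_ids) == expected

    def test_all_errors_identical_flags_nobody(self):
        """Strict-below percentile ranks: a constant error sample gives every
        compound rank 0, so none passes a positive error percentile — the
        documented tie outcome."""
        y_true = np.zeros(30)
        pred = make_pred(np.ones(30), np.linspace(0.1, 1.0, 30))
        report = flag_suspects(pred, y_true, error_pctl=95, unc_pctl=0)
        assert len(report.flagged) == 0
        # at percentile 0 the criterion is vacuous: everyone passes
        report0 = flag_suspects(pred, y_true, error_pctl=0, unc_pctl=0)
        assert len(report0.flagged) == 30

    def test_monotone_in_error_percentile(self, rng):
        y_true = np.zeros(200)
        pred = make_pred(rng.standard_normal(200), rng.uniform(0, 1, 200))
        prev = None
        for pctl in (90, 95, 99):
            ids = set(flag_suspects(pred, y_true, error_pctl=pctl, unc_pctl=0).flagged_ids)
            if prev is not None:
                assert ids <= prev
            prev = ids

    def test_direction_at_most_selects_low_uncertainty(self, rng):
        y_true = np.zeros(100)
        errs = np.ones(100)
        unc = np.linspace(0.0, 1.0, 100)
        pred = make_pred(np.sqrt(errs), unc)
        lo = flag_suspects(pred, y_true, error_pctl=0, unc_pctl=5, unc_direction="at_most")
        hi = flag_suspects(pred, y_true, error_pctl=0, unc_pctl=5, unc_direction="at_least")
        assert len(lo.flagged) == 5  # the 5 least-uncertain
        assert len(hi.flagged) == 95  # everyone with rank >= the 5th percentile
        assert max(r.uncertainty for r in lo.flagged) <= min(r.uncertainty for r in hi.flagged)

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            flag_suspects(make_pred(np.arange(10.0), np.ones(10)), np.zeros(10))

    def test_percentiles_validated(self):
        pred = make_pred(np.zeros(25), np.ones(25))
        with pytest.raises(ValueError):
            flag_suspects(pred, np.zeros(25), error_pctl=120)
        with pytest.raises(ValueError):
            flag_suspects(pred, np.zeros(25), unc_direction="sideways")

    def test_reported_activities_attached_from_curated(self):
        y_true = np.zeros(25)
        pred = make_pred(np.full(25, 2.0), np.ones(25))
        curated = [
            CuratedCompound(f"C{i:03d}", None, [0.5, 1.0], 2, 0.75, 0.25, 10.0, 0.75)
            for i in range(25)
        ]
        report = flag_suspects(pred, y_true, error_pctl=0, unc_pctl=0, curated=curated)
        assert all(r.reported_activities == [0.5, 1.0] for r in report.flagged)


class TestNeighborContext:
    @pytest.fixture
    def training(self, rng):
        bits = rng.integers(0, 2, size=(15, 32)).astype(np.uint8)
        bits[:, 0] = 1
        ids = [f"T{i:02d}" for i in range(15)]
        fps = FingerprintMatrix(ids, bits, "synthetic")
        curated = [
            CuratedCompound(cid, None, [float(i)], 1, float(i), 0.0, 1.0, float(i))
            for i, cid in enumerate(ids)
        ]
        return fps, curated

    def test_identical_training_compound_first_with_similarity_one(self, training):
        fps_train, curated = training
        flagged = FingerprintMatrix(["Q0"], fps_train.bits[[3]], "synthetic")
        ctx = neighbor_context(["Q0"], flagged, fps_train, curated, N=5)
        assert ctx["Q0"][0]["compound_id"] == "T03"
        assert ctx["Q0"][0]["tanimoto"] == 1.0
        assert ctx["Q0"][0]["label"] == 3.0

    def test_order_matches_brute_force_sorted_similarity(self, training, rng):
        from uqscreen.featurize import Fingerprint, tanimoto

        fps_train, curated = training
        qbits = rng.integers(0, 2, size=(1, 32)).astype(np.uint8)
        qbits[0, 0] = 1
        flagged = FingerprintMatrix(["Q0"], qbits, "synthetic")
        ctx = neighbor_context(["Q0"], flagged, fps_train, curated, N=15)
        q = Fingerprint(qbits[0], "synthetic")
        brute = sorted(
            ((tanimoto(q, fps_train.row(i)), fps_train.compound_ids[i]) for i in range(15)),
            key=lambda t: (-t[0], t[1]),
        )
        assert [r["compound_id"] for r in ctx["Q0"]] == [cid for _, cid in brute]

    def test_n_exceeding_training_size_warns_and_returns_all(self, training):
        fps_train, curated = training
        flagged = FingerprintMatrix(["Q0"], fps_train.bits[[0]], "synthetic")
        with pytest.warns(UserWarning, match="returning all"):
            ctx = neighbor_context(["Q0"], flagged, fps_train, curated, N=50)
        assert len(ctx["Q0"]) == 15

    def test_missing_fingerprint_raises(self, training):
        fps_train, curated = training
        flagged = FingerprintMatrix(["Q0"], fps_train.bits[[0]], "synthetic")
        with pytest.raises(ValueError, match="QX"):
            neighbor_context(["QX"], flagged, fps_train, curated)
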