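import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methylancestry import (
    ValidationError,
    background_correct,
    compute_beta,
    detection_pvalues,
    filter_probes_qc,
    impute_knn,
    mask_failed_detections,
    quantile_normalize,
)
from conftest import make_signalset


def df(values, probe_ids=None, sample_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return pd.DataFrame(
        values,
        index=probe_ids or [f"cg{i}" for i in range(values.shape[0])],
        columns=sample_ids or [f"s{j}" for j in range(values.shape[1])],
    )


class TestBackgroundCorrect:
    def test_subtracts_channel_background_and_floors(self):
        # constant negative controls of 100 → background exactly 100
        sig = make_signalset([[500.0], [50.0]], [[300.0], [250.0]], ["grn", "grn"])
        sig.neg_controls["intensity"] = 100.0
        out = background_correct(sig)
        assert out.meth.iloc[0, 0] == 400.0
        assert out.meth.iloc[1, 0] == 1.0  # floored
        assert out.unmeth.iloc[0, 0] == 200.0

    def test_type_ii_routes_meth_grn_unmeth_red(self):
        sig = make_signalset([[500.0]], [[500.0]], ["both"])
        neg = sig.neg_controls
        neg.loc[neg["channel"] == "grn", "intensity"] = 100.0
        neg.loc[neg["channel"] == "red", "intensity"] = 50.0
        out = background_correct(sig)
        assert out.meth.iloc[0, 0] == 400.0
        assert out.unmeth.iloc[0, 0] == 450.0

    def test_missing_controls_rejected(self):
        sig = make_signalset([[500.0]], [[500.0]], ["both"])
        sig.neg_controls = sig.neg_controls[sig.neg_controls["channel"] == "grn"]
        with pytest.raises(ValidationError, match="negative controls"):
            background_correct(sig)


class TestDetectionP:
    def test_total_equal_to_background_mean_gives_half(self):
        sig = make_signalset([[50.0]], [[50.0]], ["grn"])
        sig.neg_controls.loc[sig.neg_controls["channel"] == "grn", "intensity"] = [90.0, 100.0, 110.0]
        p = detection_pvalues(sig)
        assert p.iloc[0, 0] == pytest.approx(0.5)

    def test_large_signal_vanishing_p(self):
        sig = make_signalset([[1e6]], [[1e6]], ["both"])
        assert detection_pvalues(sig).iloc[0, 0] < 1e-300

    def test_normal_tail_oracle(self):
        # grn controls with mean 100, sd 10 exactly; total 119.6 → sf(1.96)
        a = 10.0 / np.sqrt(2.0)
        sig = make_signalset([[60.0]], [[59.6]], ["grn"])
        sig.neg_controls = pd.DataFrame({
            "sample_id": ["s0"] * 4,
            "channel": ["grn", "grn", "red", "red"],
            "intensity": [100 - a, 100 + a, 100 - a, 100 + a],
        })
        p = detection_pvalues(sig).iloc[0, 0]
        assert p == pytest.approx(stats.norm.sf(1.96), rel=1e-6)
        assert p == pytest.approx(0.025, abs=1e-4)

    def test_too_few_controls_rejected(self):
        sig = make_signalset([[500.0]], [[500.0]], ["grn"])
        sig.neg_controls = sig.neg_controls.groupby("channel").head(1)
        with pytest.raises(ValidationError):
            detection_pvalues(sig)


class TestMasking:
    def test_threshold_boundary(self):
        vals = df([[1.0, 2.0, 3.0]])
        p = df([[1e-17, 1e-10, 1e-16]])
        out = mask_failed_detections(vals, p, threshold=1e-16)
        assert out.iloc[0, 0] == 1.0          # below threshold: kept
        assert np.isnan(out.iloc[0, 1])       # above: masked
        assert out.iloc[0, 2] == 3.0          # equal: kept (strict >)

    def test_threshold_one_masks_nothing(self):
        vals = df(np.random.default_rng(0).uniform(size=(4, 3)))
        p = df(np.random.default_rng(1).uniform(size=(4, 3)))
        assert not mask_failed_detections(vals, p, threshold=1.0).isna().any().any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mask_failed_detections(df([[1.0]]), df([[0.5, 0.5]]))

    @given(st.floats(1e-20, 1e-5), st.floats(1e-20, 1e-5))
    @settings(max_examples=25, deadline=None)
    def test_lower_threshold_never_unmasks(self, t1, t2):
        rng = np.random.default_rng(9)
        vals = df(rng.uniform(size=(5, 4)))
        p = df(10.0 ** rng.uniform(-20, 0, size=(5, 4)))
        lo, hi = sorted([t1, t2])
        masked_hi = mask_failed_detections(vals, p, hi).isna()
        masked_lo = mask_failed_detections(vals, p, lo).isna()
        assert (masked_hi <= masked_lo).all().all()


class TestQCFilter:
    def make(self, n=100, low_bead=0, n_missing=0):
        bead = np.full((1, n), 10.0)
        bead[0, :low_bead] = 2
        miss = np.zeros((1, n), dtype=bool)
        miss[0, :n_missing] = True
        return df(miss), df(bead)

    @pytest.mark.parametrize(
        "low_bead,n_missing,kept",
        [
            (6, 0, False),   # 6% low-bead > 5% → removed
            (5, 0, True),    # exactly 5% retained (strict inequality)
            (0, 11, False),  # 11% missing → removed
            (0, 10, True),   # exactly 10% retained
        ],
    )
    def test_strict_fraction_boundaries(self, low_bead, n_missing, kept):
        miss, bead = self.make(low_bead=low_bead, n_missing=n_missing)
        retained = filter_probes_qc(miss, bead)
        assert (len(retained) == 1) is kept

    def test_zero_samples_rejected(self):
        with pytest.raises(ValidationError):
            filter_probes_qc(pd.DataFrame(index=["cg0"]), pd.DataFrame(index=["cg0"]))


class TestQuantileNormalize:
    def test_mean_of_order_statistics_oracle(self):
        x = df(np.array([[1.0, 2.0], [3.0, 4.0]]))
        out = quantile_normalize(x)
        expected = np.array([[1.5, 1.5], [3.5, 3.5]])
        np.testing.assert_allclose(out.to_numpy(), expected)

    def test_identical_columns_unchanged(self):
        col = np.array([0.3, 0.9, 0.1, 0.5])
        x = df(np.column_stack([col, col, col]))
        np.testing.assert_allclose(quantile_normalize(x).to_numpy(), x.to_numpy())

    def test_columns_share_sorted_multiset_and_ranks(self):
        rng = np.random.default_rng(2)
        x = df(rng.normal(size=(30, 5)))
        out = quantile_normalize(x).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)
            assert (np.argsort(out[:, j]) == np.argsort(x.to_numpy()[:, j])).all()

    def test_missing_entries_preserved_as_missing(self):
        x = df([[1.0, 2.0], [np.nan, 4.0], [3.0, 6.0]])
        out = quantile_normalize(x)
        assert np.isnan(out.iloc[1, 0]) and out.notna().sum().sum() == 5

    def test_fully_missing_column_rejected(self):
        x = df([[np.nan, 1.0], [np.nan, 2.0]])
        with pytest.raises(ValidationError):
            quantile_normalize(x)


class TestComputeBeta:
    @pytest.mark.parametrize(
        "m,u,expected",
        [(1000.0, 1000.0, 1000.0 / 2100.0), (0.0, 0.0, 0.0), (200.0, 0.0, 200.0 / 300.0)],
    )
    def test_arithmetic(self, m, u, expected):
        out = compute_beta(df([[m]]), df([[u]]))
        assert out.iloc[0, 0] == pytest.approx(expected)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValidationError):
            compute_beta(df([[-1.0]]), df([[1.0]]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_beta_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        m = df(rng.uniform(0, 1e5, size=(6, 4)))
        u = df(rng.uniform(0, 1e5, size=(6, 4)))
        b = compute_beta(m, u).to_numpy()
        assert (b >= 0).all() and (b <= 1).all()


def knn_impute_oracle(x, k):
    """Direct re-statement of the imputation rule with explicit loops."""
    x = x.copy()
    n = x.shape[0]
    obs = ~np.isnan(x)
    for i in range(n):
        for j in range(x.shape[1]):
            if obs[i, j]:
                continue
            dists = []
            for other in range(n):
                if other == i:
                    continue
                joint = obs[i] & obs[other]
                if not joint.any():
                    continue
                d = np.sqrt(np.mean((x[i, joint] - x[other, joint]) ** 2))
                dists.append((d, other))
            usable = [(d, o) for d, o in dists if obs[o, j]]
            if len(usable) < k:
                x[i, j] = np.nanmean(x[i])
                continue
            usable.sort(key=lambda t: t[0])
            nearest = usable[:k]
            if any(d == 0 for d, _ in nearest):
                x[i, j] = np.mean([x[o, j] for d, o in nearest if d == 0])
            else:
                w = np.array([1.0 / d for d, _ in nearest])
                v = np.array([x[o, j] for _, o in nearest])
                x[i, j] = float(w @ v / w.sum())
    return np.clip(x, 0, 1)


class TestImputeKnn:
    def test_complete_matrix_unchanged(self):
        x = df(np.random.default_rng(1).uniform(size=(5, 4)))
        pd.testing.assert_frame_equal(impute_knn(x), x)

    def test_twin_probe_fills_exact_value(self):
        row = np.array([0.2, 0.4, 0.6, 0.8])
        x = np.array([row, row, [0.9, 0.1, 0.9, 0.1]])
        x[0, 2] = np.nan
        out = impute_knn(df(x), k=1)
        assert out.iloc[0, 2] == pytest.approx(0.6, abs=1e-9)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(size=(10, 6))
        x[rng.choice(10, 3, replace=False), rng.choice(6, 3)] = np.nan
        out = impute_knn(df(x), k=2).to_numpy()
        np.testing.assert_allclose(out, knn_impute_oracle(x.copy(), k=2), atol=1e-10)

    def test_all_missing_probe_rejected(self):
        x = df([[np.nan, np.nan], [0.1, 0.2]])
        with pytest.raises(ValidationError):
            impute_knn(x)

    def test_output_complete_and_bounded(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(20, 8))
        x[rng.random(x.shape) < 0.1] = np.nan
        out = impute_knn(df(x)).to_numpy()
        assert not np.isnan(out).any()
        assert (out >= 0).all() and (out <= 1).all()


def test_pipeline_stage_determinism(small_cohort):
    """Identical signals in → bit-identical betas out."""
    sig = small_cohort.signals
    def run():
        p = detection_pvalues(sig)
        c = background_correct(sig)
        meth = mask_failed_detections(c.meth, p)
        unmeth = mask_failed_detections(c.unmeth, p)
        return compute_beta(quantile_normalize(meth), quantile_normalize(unmeth))
    b1, b2 = run(), run()
    assert b1.equals(b2)
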