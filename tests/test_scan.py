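import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import qpss
from qpss import (
    CarrierPartition,
    GenotypeMatrix,
    NoCarriersError,
    Region,
    WindowSpec,
    carrier_partition,
    scan,
    signed_lr,
    window_statistic,
)
from qpss.genotypes import MISSING


def two_group_gaussian_lr_oracle(y, plus_mask):
    """ln LR via explicit normal log-likelihoods at the two fits.

    Maximizes the one-mean and two-mean shared-variance Gaussian
    likelihoods (ML estimates: group means, mean squared residual) and
    evaluates both log-likelihoods with scipy's normal density -- a
    route independent of the variance-ratio closed form.
    """
    y = np.asarray(y, float)
    plus = np.asarray(plus_mask, bool)
    resid2 = np.concatenate([y[plus] - y[plus].mean(), y[~plus] - y[~plus].mean()])
    s2_2 = np.mean(resid2**2)
    l2 = (
        sps.norm.logpdf(y[plus], y[plus].mean(), np.sqrt(s2_2)).sum()
        + sps.norm.logpdf(y[~plus], y[~plus].mean(), np.sqrt(s2_2)).sum()
    )
    s2_1 = np.mean((y - y.mean()) ** 2)
    l1 = sps.norm.logpdf(y, y.mean(), np.sqrt(s2_1)).sum()
    return l2 - l1


class TestWindowStatistic:
    def test_hand_worked_toy(self):
        """y = [1,2,3,4] split 2/2 gives the textbook values."""
        part = CarrierPartition(np.array([0, 1]), np.array([2, 3]))
        ws = window_statistic(np.array([1.0, 2, 3, 4]), part)
        assert ws.mu_plus == pytest.approx(1.5)
        assert ws.mu_minus == pytest.approx(3.5)
        assert ws.mu_0 == pytest.approx(2.5)
        assert ws.sigma2_w == pytest.approx(0.25)
        assert ws.sigma2_0 == pytest.approx(1.25)
        assert ws.ln_lr == pytest.approx(2 * np.log(5))
        assert ws.sign == -1
        assert ws.signed_stat == pytest.approx(-2 * np.log(5))

    def test_null_identity_when_groups_equal(self):
        y = np.array([1.0, 3, 1, 3])  # same mean and spread in both groups
        part = CarrierPartition(np.array([0, 1]), np.array([2, 3]))
        ws = window_statistic(y, part)
        assert ws.ln_lr == 0.0
        assert ws.sign == 0
        assert ws.signed_stat == 0.0

    def test_matches_likelihood_oracle_on_random_inputs(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 31))
            k = int(rng.integers(1, n))
            y = rng.standard_normal(n) * rng.uniform(0.5, 3) + rng.uniform(-5, 5)
            mask = np.zeros(n, bool)
            mask[rng.choice(n, size=k, replace=False)] = True
            ln_lr, _, _ = signed_lr(y, mask)
            assert ln_lr == pytest.approx(
                two_group_gaussian_lr_oracle(y, mask), abs=1e-9
            )

    def test_group_label_permutation_invariance(self, rng):
        y = rng.standard_normal(12)
        part = CarrierPartition(np.arange(5), np.arange(5, 12))
        ws = window_statistic(y, part)
        shuffled = CarrierPartition(
            rng.permutation(np.arange(5)), rng.permutation(np.arange(5, 12))
        )
        assert window_statistic(y, shuffled).signed_stat == pytest.approx(
            ws.signed_stat
        )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=20),
        st.integers(1, 10),
        st.floats(-100, 100),
        st.floats(0.1, 10),
    )
    def test_shift_scale_invariance_and_nonnegativity(self, vals, k, shift, scale):
        y = np.asarray(vals)
        k = min(k, len(y) - 1)
        mask = np.zeros(len(y), bool)
        mask[:k] = True
        ln_lr, sign, _ = signed_lr(y, mask)
        assert ln_lr >= 0.0 or np.isinf(ln_lr)
        ln2, sign2, _ = signed_lr(y * scale + shift, mask)
        if np.isfinite(ln_lr):
            assert ln2 == pytest.approx(ln_lr, abs=1e-6)
            assert sign2 == sign  # positive scaling keeps direction

    def test_zero_within_variance_flagged_as_sentinel(self):
        y = np.array([1.0, 1, 2, 2])  # groups internally constant, means differ
        part = CarrierPartition(np.array([0, 1]), np.array([2, 3]))
        ws = window_statistic(y, part)
        assert np.isinf(ws.ln_lr)
        assert ws.flag == "zero_within_variance"

    def test_all_identical_phenotypes_give_zero(self):
        y = np.full(6, 2.5)
        part = CarrierPartition(np.arange(3), np.arange(3, 6))
        ws = window_statistic(y, part)
        assert ws.ln_lr == 0.0
        assert ws.sign == 0

    def test_degenerate_partition_rejected(self):
        part = CarrierPartition(np.arange(4), np.array([], dtype=int))
        with pytest.raises(ValueError, match="degenerate"):
            window_statistic(np.ones(4), part)


class TestCarrierPartition:
    def test_window_covering_region_is_degenerate(self, toy_genotypes):
        region_mask = np.ones(10, bool)
        part = carrier_partition(toy_genotypes, region_mask, region_mask)
        assert part.n_minus == 0
        assert part.degenerate

    def test_simple_split(self, toy_genotypes):
        region_mask = np.ones(10, bool)
        window_mask = np.zeros(10, bool)
        window_mask[:4] = True  # positions 100..400: carriers are samples 0,1,2
        part = carrier_partition(toy_genotypes, region_mask, window_mask)
        assert sorted(part.w_plus_ids) == [0, 1, 2]
        assert sorted(part.w_minus_ids) == [3, 4, 5]
        assert part.n_carriers == 6

    def test_missing_in_window_assigns_to_w_minus(self):
        d = np.array([[MISSING, 1], [1, 0]], dtype=np.int8)
        gm = GenotypeMatrix(np.array(["a", "b"]), np.array([10, 20]), d)
        part = carrier_partition(gm, np.ones(2, bool), np.array([True, False]))
        # sample a: missing in window, carrier outside -> W-
        assert part.w_minus_ids.tolist() == [0]
        assert part.w_plus_ids.tolist() == [1]

    def test_no_carriers_raises(self):
        gm = GenotypeMatrix(
            np.array(["a", "b"]), np.array([10]), np.zeros((2, 1), np.int8)
        )
        with pytest.raises(NoCarriersError):
            carrier_partition(gm, np.ones(1, bool), np.ones(1, bool))

    def test_window_must_be_subset_of_region(self, toy_genotypes):
        region_mask = np.zeros(10, bool)
        region_mask[:5] = True
        window_mask = np.zeros(10, bool)
        window_mask[6] = True
        with pytest.raises(ValueError):
            carrier_partition(toy_genotypes, region_mask, window_mask)


class TestScan:
    def _toy_scan(self, toy_genotypes, toy_region, y=None, rng=None):
        if y is None:
            y = (rng or np.random.default_rng(0)).standard_normal(8)
        return y, scan(
            y, toy_genotypes, toy_region, [WindowSpec(400, 200)], rare_threshold=0.5
        )

    def test_matches_independent_window_evaluations(self, toy_genotypes, toy_region, rng):
        y, res = self._toy_scan(toy_genotypes, toy_region, rng=rng)
        region_mask = np.ones(10, bool)
        for _, row in res.table.iterrows():
            in_win = (toy_genotypes.positions >= row["window_start"]) & (
                toy_genotypes.positions <= row["window_end"]
            )
            if row["flags"] == "degenerate":
                continue
            part = carrier_partition(toy_genotypes, region_mask, in_win)
            carriers = np.sort(np.concatenate([part.w_plus_ids, part.w_minus_ids]))
            remap = {s: i for i, s in enumerate(carriers)}
            part2 = CarrierPartition(
                np.array([remap[s] for s in part.w_plus_ids], dtype=int),
                np.array([remap[s] for s in part.w_minus_ids], dtype=int),
            )
            ws = window_statistic(y[carriers], part2)
            assert row["signed_stat"] == pytest.approx(ws.signed_stat, abs=1e-9)
            assert row["n_wplus"] == ws.n_plus

    def test_best_window_attains_maximum(self, toy_genotypes, toy_region, rng):
        _, res = self._toy_scan(toy_genotypes, toy_region, rng=rng)
        t = res.table
        finite = t["signed_stat"].abs().dropna()
        for label, idx in res.best.items():
            spec_stats = t.loc[t["spec"] == label, "signed_stat"].abs().dropna()
            assert abs(t.at[idx, "signed_stat"]) == pytest.approx(spec_stats.max())

    def test_constant_phenotype_all_zero_and_first_window_wins(
        self, toy_genotypes, toy_region
    ):
        y = np.full(8, 1.0)
        _, res = self._toy_scan(toy_genotypes, toy_region, y=y)
        stats = res.table.loc[res.table["flags"] == "", "signed_stat"]
        assert (stats == 0).all()
        # argmax tie: first non-degenerate window in genomic order
        first_ok = res.table.index[res.table["flags"] == ""][0]
        assert res.best["400/200"] == first_ok

    def test_m_counts_include_degenerate_windows(self, toy_genotypes, toy_region):
        _, res = self._toy_scan(toy_genotypes, toy_region)
        assert res.m_per_spec["400/200"] == -(-1000 // 200)
        assert res.m_total == 5

    def test_bonferroni_levels(self, toy_genotypes, toy_region):
        _, res = self._toy_scan(toy_genotypes, toy_region)
        assert res.bonferroni_alpha(0.05, "combined")["400/200"] == pytest.approx(
            0.05 / res.m_total
        )
        assert res.bonferroni_alpha(0.05, "per-spec")["400/200"] == pytest.approx(
            0.05 / 5
        )

    def test_samples_without_phenotype_dropped(self, toy_genotypes, toy_region):
        import pandas as pd

        y = pd.Series(
            np.arange(6, dtype=float), index=[f"s{i}" for i in range(6)]
        )  # s6, s7 missing
        res = scan(
            y, toy_genotypes, toy_region, [WindowSpec(400, 200)], rare_threshold=0.5
        )
        assert res.n_dropped_samples == 2
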