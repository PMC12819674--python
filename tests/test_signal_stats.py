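"""The four disproportionality statistics against hand-derived oracles."""

import math

import numpy as np
import pytest
from scipy import special, stats

from pvsignals.meddra import default_mapping
from pvsignals.signal_stats import (
    ContingencyTable,
    DEFAULT_PRIOR_START,
    GammaMixturePrior,
    Thresholds,
    bcpnn_ic,
    build_all_tables,
    build_pair_tables,
    build_table,
    ebgm,
    evaluate_signal,
    fit_prior,
    prr,
    ror,
)

T = ContingencyTable(5, 10, 20, 100)  # hand-checked running example


class TestContingency:
    def test_margins_and_expected(self):
        assert T.N == 135
        assert T.E == pytest.approx(15 * 25 / 135)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError, match="cell"):
            ContingencyTable(-1, 2, 3, 4)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


class TestBuildTable:
    class R:
        def __init__(self, is_target, pts):
            self.is_target = is_target
            self.pts = set(pts)
            self.drugs = []

    def test_enumerable_corpus(self):
        corpus = [self.R(True, {"X"}), self.R(True, {"Y"}),
                  self.R(False, {"X"}), self.R(False, {"Z"})]
        t = build_table(corpus, "X", "PT")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_multiple_pts_in_one_soc_count_once(self):
        m = default_mapping()
        corpus = [self.R(True, {"Headache", "Migraine"}), self.R(False, {"Rash"})]
        t = build_table(corpus, "Nervous system disorders", "SOC", m)
        assert t.a == 1

    def test_absent_term_gives_zero_a(self):
        corpus = [self.R(True, {"X"}), self.R(False, {"X"})]
        t = build_table(corpus, "NOT PRESENT", "PT")
        assert t.a == 0 and t.N == 2

    def test_build_all_matches_per_term_scan(self, reports):
        tables = build_all_tables(reports, "PT")
        for term in list(tables)[:10]:
            single = build_table(reports, term, "PT")
            t = tables[term]
            assert (t.a, t.b, t.c, t.d) == (single.a, single.b, single.c, single.d)


class TestROR:
    def test_symmetric_table_is_unity(self):
        est, lo, hi = ror(ContingencyTable(10, 10, 10, 10))
        assert est == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_hand_value(self):
        est, lo, hi = ror(T)
        assert est == pytest.approx(2.5)
        assert lo == pytest.approx(0.771, abs=1e-3)
        assert hi == pytest.approx(8.104, abs=1e-2)

    def test_zero_cell_haldane_correction(self):
        est, lo, hi = ror(ContingencyTable(0, 10, 10, 100))
        exp = (0.5 * 100.5) / (10.5 * 10.5)
        assert est == pytest.approx(exp)
        assert 0 < lo < est < hi < math.inf


class TestPRR:
    def test_symmetric_table(self):
        est, chi2 = prr(ContingencyTable(10, 10, 10, 10))
        assert est == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    def test_hand_value(self):
        est, chi2 = prr(T)
        assert est == pytest.approx(2.0)
        assert chi2 == pytest.approx(2.4545, abs=1e-4)

    def test_zero_margin_not_evaluable(self):
        est, chi2 = prr(ContingencyTable(3, 0, 0, 10))
        assert math.isnan(est) and math.isnan(chi2)

    def test_chi2_equals_observed_expected_sum(self):
        """Product formula vs the textbook sum over 50 random tables."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 200, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            _, chi2 = prr(t)
            obs = np.array([a, b, c, d], float)
            rows = np.array([a + b, a + b, c + d, c + d], float)
            cols = np.array([a + c, b + d, a + c, b + d], float)
            exp = rows * cols / t.N
            assert chi2 == pytest.approx(float(np.sum((obs - exp) ** 2 / exp)),
                                         abs=1e-8)


class TestBCPNN:
    def test_independence_gives_zero_ic(self):
        ic, _ = bcpnn_ic(ContingencyTable(4, 16, 16, 64))
        assert ic == pytest.approx(0.0)

    def test_hand_value(self):
        ic, ic025 = bcpnn_ic(T)
        assert ic == pytest.approx(0.747, abs=1e-3)
        assert ic025 == pytest.approx(-0.816, abs=1e-3)

    def test_large_count_limit(self):
        # a -> inf with a/E fixed at r: IC -> log2(r)
        a, r = 10**6, 4.0
        b = a  # a+b = 2a
        # choose c,d so E = a/r: E=(a+b)(a+c)/N
        # simple construction: scale a 2x2 with known ratio
        t = ContingencyTable(a, 3 * a, a, 29 * a)  # E=(4a)(2a)/(34a)=4a/17
        ratio = a / t.E
        ic, _ = bcpnn_ic(t)
        assert ic == pytest.approx(math.log2(ratio), rel=1e-4)


class TestMGPS:
    def degenerate_prior(self):
        # both components identical -> effectively a single Gamma(2,2)
        return GammaMixturePrior(w=0.5, alpha1=2.0, beta1=2.0,
                                 alpha2=2.0, beta2=2.0)

    def test_ebgm_closed_form_digamma(self):
        est, _ = ebgm(T, self.degenerate_prior())
        # posterior Gamma(2+5, 2+E) with E=25*15/135
        rate = 2 + T.E
        assert est == pytest.approx(math.exp(special.digamma(7) - math.log(rate)),
                                    rel=1e-10)
        assert est == pytest.approx(1.3618, abs=2e-4)

    def test_ebgm05_closed_form_quantile(self):
        _, q05 = ebgm(T, self.degenerate_prior())
        rate = 2 + T.E
        assert q05 == pytest.approx(stats.gamma.ppf(0.05, 7) / rate, rel=1e-8)
        assert q05 == pytest.approx(0.687, abs=1e-3)

    def test_ebgm_zero_expected_not_evaluable(self):
        t = ContingencyTable(0, 0, 5, 5)
        est, q05 = ebgm(t, self.degenerate_prior())
        assert math.isnan(est) and math.isnan(q05)

    def test_ebgm_large_count_limit(self):
        a = 10**6
        t = ContingencyTable(a, 3 * a, a, 29 * a)
        est, _ = ebgm(t, DEFAULT_PRIOR_START)
        assert est == pytest.approx(a / t.E, rel=1e-2)

    def test_ebgm_between_shrunk_and_unshrunk(self):
        """Under a mean-1 prior the posterior mean of lambda lies between
        1 and a/E; the geometric mean sits below it by at most the
        digamma-log gap exp(-1/shape), so EBGM obeys the sandwich up to
        that factor."""
        prior = GammaMixturePrior(w=0.5, alpha1=2.0, beta1=2.0, alpha2=5.0, beta2=5.0)
        rng = np.random.default_rng(2)
        for _ in range(30):
            a, b, c, d = (int(v) for v in rng.integers(1, 100, size=4))
            t = ContingencyTable(a, b, c, d)
            est, _ = ebgm(t, prior)
            r = t.a / t.E
            s_min = prior.alpha1 + t.a  # smallest posterior shape
            assert min(1, r) * math.exp(-1.0 / s_min) - 1e-9 <= est <= max(1, r) + 1e-9

    def test_fit_prior_requires_enough_tables(self):
        with pytest.raises(ValueError, match="50"):
            fit_prior([T] * 10)

    def _null_tables(self, n=400, seed=3):
        rng = np.random.default_rng(seed)
        tables = []
        for _ in range(n):
            n_drug = int(rng.integers(50, 500))
            n_term = int(rng.integers(50, 500))
            total = 20000
            # under independence a ~ Binomial ~ Poisson(E)
            e = n_drug * n_term / total
            a = int(rng.poisson(e))
            a = min(a, n_drug, n_term)
            tables.append(ContingencyTable(a, n_drug - a, n_term - a,
                                           total - n_drug - n_term + a))
        return tables

    def test_fit_prior_null_data_recovers_unit_mean(self):
        prior = fit_prior(self._null_tables())
        assert 0.8 <= prior.mean <= 1.25

    def test_fit_prior_improves_on_start(self):
        tables = self._null_tables()
        prior = fit_prior(tables)
        from pvsignals.signal_stats import _mixture_loglik, _theta
        a = np.array([t.a for t in tables], float)
        e = np.array([t.E for t in tables], float)
        assert prior.loglik >= _mixture_loglik(_theta(DEFAULT_PRIOR_START), a, e)

    def test_fit_prior_multi_start_stability(self):
        tables = self._null_tables()
        starts = [
            DEFAULT_PRIOR_START,
            GammaMixturePrior(w=0.5, alpha1=1.0, beta1=1.0, alpha2=1.0, beta2=0.5),
            GammaMixturePrior(w=0.1, alpha1=0.5, beta1=0.5, alpha2=3.0, beta2=3.0),
        ]
        lls = [fit_prior(tables, start=s).loglik for s in starts]
        assert max(lls) - min(lls) < 1e-3


class TestMonotonicityAndOrdering:
    def test_increasing_a_increases_all_statistics(self):
        prior = GammaMixturePrior(w=0.5, alpha1=2.0, beta1=2.0, alpha2=5.0, beta2=5.0)
        prev = None
        for a in (2, 5, 10, 20, 40):
            t = ContingencyTable(a, 30, 50, 400)
            vals = (ror(t)[0], prr(t)[0], bcpnn_ic(t)[0], ebgm(t, prior)[0])
            if prev is not None:
                assert all(v > p for v, p in zip(vals, prev))
            prev = vals

    def test_ror_dominates_prr_on_positive_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(1, 300, size=4))
            r = ror(ContingencyTable(a, b, c, d))[0]
            p = prr(ContingencyTable(a, b, c, d))[0]
            if r >= 1:
                assert r >= p - 1e-12
            else:
                assert r <= p + 1e-12


class TestCombinedCriterion:
    def test_count_floor_blocks_tiny_a(self):
        res = evaluate_signal(ContingencyTable(2, 1, 1, 1000), "X",
                              prior=GammaMixturePrior(0.5, 2, 2, 2, 2))
        assert res.ror > 100 and not res.ror_pos and not res.combined_pos

    def test_independence_table_all_flags_false(self):
        res = evaluate_signal(ContingencyTable(4, 16, 16, 64), "X",
                              prior=GammaMixturePrior(0.5, 2, 2, 2, 2))
        assert not any([res.ror_pos, res.prr_pos, res.bcpnn_pos, res.mgps_pos,
                        res.combined_pos])

    def test_combined_is_conjunction(self):
        rng = np.random.default_rng(5)
        prior = GammaMixturePrior(0.5, 2, 2, 2, 2)
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(1, 200, size=4))
            res = evaluate_signal(ContingencyTable(a, b, c, d), "X", prior=prior)
            assert res.combined_pos == (res.ror_pos and res.prr_pos
                                        and res.bcpnn_pos and res.mgps_pos)

    def test_thresholds_are_overridable(self):
        res = evaluate_signal(T, "X", prior=GammaMixturePrior(0.5, 2, 2, 2, 2),
                              thresholds=Thresholds(min_count=1, prr_min=1.5,
                                                    chi2_min=1.0, ic025_min=-1.0,
                                                    ebgm05_min=0.5))
        assert res.prr_pos and res.bcpnn_pos and res.mgps_pos


def test_pair_tables_share_corpus_size(reports):
    tables = build_pair_tables(reports)
    sizes = {t.N for t in tables.values()}
    assert sizes == {len(reports)}
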