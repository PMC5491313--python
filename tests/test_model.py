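"""Model density, likelihood, MLE, confidence intervals, diagnostics."""

import numpy as np
import pytest
from scipy.stats import norm

import overlapmodel as om
from overlapmodel.errors import IdentifiabilityError, InputError
from overlapmodel.partition import term_design

from conftest import brute_cells, brute_log_normalizer, random_layout_and_sets


@pytest.fixture(scope="module")
def two_ref_spec():
    return om.ModelSpec(2, [[1], [2], [1, 2]])


class TestEnrichment:
    def test_worked_two_reference_example(self, two_ref_spec):
        """theta = (0.5, 0.7, -0.2): overlap-R1-only is e^0.5 = 1.65-fold
        enriched, both-sets is e^1.0 = 2.72-fold despite the negative
        interaction."""
        theta = np.array([0.5, 0.7, -0.2])
        assert om.enrichment(theta, two_ref_spec, (1, 0)) == pytest.approx(0.5)
        assert om.enrichment(theta, two_ref_spec, (0, 1)) == pytest.approx(0.7)
        assert om.enrichment(theta, two_ref_spec, (1, 1)) == pytest.approx(1.0)
        assert np.exp(0.5) == pytest.approx(1.65, abs=0.005)
        assert np.exp(1.0) == pytest.approx(2.72, abs=0.005)

    def test_background_is_zero(self, two_ref_spec):
        theta = np.array([3.0, -2.0, 1.0])
        assert om.enrichment(theta, two_ref_spec, (0, 0)) == 0.0

    def test_nine_set_selected_model_arithmetic(self):
        """Only the terms fully contained in the overlap pattern activate:
        for a pattern overlapping sets 2,4,6,9 only, terms {6}, {9} and
        {2,4,6,9} contribute."""
        terms = [[5], [6], [8], [9], [2, 7], [5, 8, 9], [6, 7, 8], [2, 4, 6, 9],
                 [2, 3, 4, 5, 6]]
        theta_by_term = {
            (5,): 0.7654, (6,): 0.3780, (8,): 0.4929, (9,): 0.4968,
            (2, 7): 0.2528, (5, 8, 9): -0.4497, (6, 7, 8): -0.2907,
            (2, 4, 6, 9): -1.668, (2, 3, 4, 5, 6): -1.985,
        }
        spec = om.ModelSpec(9, terms)
        theta = np.array([theta_by_term[tuple(sorted(t))] for t in spec.terms])
        v = tuple(1 if i in {2, 4, 6, 9} else 0 for i in range(1, 10))
        h = om.enrichment(theta, spec, v)
        assert h == pytest.approx(0.3780 + 0.4968 - 1.668, abs=1e-12)
        v5 = tuple(1 if i == 5 else 0 for i in range(1, 10))
        assert om.enrichment(theta, spec, v5) == pytest.approx(0.7654)

    def test_shape_errors(self, two_ref_spec):
        with pytest.raises(InputError):
            om.enrichment(np.zeros(2), two_ref_spec, (1, 0))
        with pytest.raises(InputError):
            om.enrichment(np.zeros(3), two_ref_spec, (1, 0, 1))


class TestNormalizer:
    def test_zero_theta_gives_zero(self, toy1):
        layout, r1, r2, mappable = toy1
        part = om.build_partition([r1, r2], mappable, 3, layout)
        des = term_design([[1], [2], [1, 2]], part.masks)
        assert om.log_normalizer(np.zeros(3), part, des) == pytest.approx(0.0, abs=1e-14)

    def test_toy1_single_term_closed_form(self, toy1):
        """Cells 20/80 at ln 2 tilt: c^-1 = (20*2 + 80)/100 = 1.2."""
        layout, r1, _, mappable = toy1
        part = om.build_partition([r1], mappable, 1, layout)
        des = term_design([[1]], part.masks)
        lc = om.log_normalizer(np.array([np.log(2.0)]), part, des)
        assert lc == pytest.approx(-np.log(1.2), abs=1e-12)

    def test_strong_negative_tilt_limit(self, toy1):
        """theta -> -inf: mass concentrates off the term's cells, so
        c -> |G0| / (size of the non-overlapping cells)."""
        layout, r1, _, mappable = toy1
        part = om.build_partition([r1], mappable, 1, layout)
        des = term_design([[1]], part.masks)
        lc = om.log_normalizer(np.array([-40.0]), part, des)
        assert lc == pytest.approx(np.log(100 / 80), abs=1e-6)

    @pytest.mark.parametrize("case_seed", range(4))
    def test_matches_per_base_oracle(self, case_seed):
        rng = np.random.default_rng(6000 + case_seed)
        layout, refs = random_layout_and_sets(rng, n_refs=2, n_chroms=1)
        mappable = om.IntervalSet.whole_genome(layout)
        y = int(rng.integers(1, 6))
        spec = om.ModelSpec(2, [[1], [2], [1, 2]])
        theta = rng.normal(0, 1.2, size=3)
        part = om.build_partition(refs, mappable, y, layout)
        des = term_design(spec.terms, part.masks)
        ours = om.log_normalizer(theta, part, des)
        brute = brute_log_normalizer(theta, spec, refs, mappable, y, layout)
        assert ours == pytest.approx(brute, rel=1e-10)

    def test_density_sums_to_one(self, toy1):
        """sum_x f(x|y) = 1 by per-base enumeration for random theta."""
        layout, r1, r2, mappable = toy1
        spec = om.ModelSpec(2, [[1], [2], [1, 2]])
        rng = np.random.default_rng(42)
        for y in (1, 4):
            part = om.build_partition([r1, r2], mappable, y, layout)
            des = term_design(spec.terms, part.masks)
            theta = rng.normal(0, 1.5, size=3)
            lc = om.log_normalizer(theta, part, des)
            dil = [om.dilate_left(r1, y), om.dilate_left(r2, y)]
            total = 0.0
            for x in range(1, part.g0_size + 1):
                v = om.pattern_of(om.Query("chr1", x, y), dil)
                h = om.enrichment(theta, spec, v)
                total += np.exp(lc) * (1.0 / part.g0_size) * np.exp(h)
            assert total == pytest.approx(1.0, abs=1e-10)


def _toy_single_parts(toy1_single_fit):
    layout, r1, mappable, queries = toy1_single_fit
    part = om.build_partition([r1], mappable, 1, layout)
    spec = om.ModelSpec(1, [[1]])
    stats = om.sufficient_statistics(queries, spec.terms, [r1], layout)
    return spec, stats, {1: (part, queries.n)}


class TestLikelihood:
    def test_zero_theta_zero_loglik(self, toy1_single_fit):
        spec, stats, parts = _toy_single_parts(toy1_single_fit)
        assert om.log_likelihood(np.zeros(1), stats, parts, spec) == pytest.approx(0.0, abs=1e-12)

    def test_toy1_closed_form(self, toy1_single_fit):
        """l(ln 4) = 5 ln 4 - 10 log 1.6 with cells 20/80, t=5, n=10."""
        spec, stats, parts = _toy_single_parts(toy1_single_fit)
        ll = om.log_likelihood(np.array([np.log(4.0)]), stats, parts, spec)
        assert ll == pytest.approx(2.23143, abs=1e-5)
        assert ll == pytest.approx(5 * np.log(4) - 10 * np.log(1.6), rel=1e-12)

    def test_duplicating_queries_doubles_loglik(self, toy1_single_fit):
        layout, r1, mappable, queries = toy1_single_fit
        spec = om.ModelSpec(1, [[1]])
        part = om.build_partition([r1], mappable, 1, layout)
        stats = om.sufficient_statistics(queries, spec.terms, [r1], layout)
        doubled = om.QueryCollection(list(queries) + list(queries))
        stats2 = om.sufficient_statistics(doubled, spec.terms, [r1], layout)
        theta = np.array([0.7])
        l1 = om.log_likelihood(theta, stats, {1: (part, queries.n)}, spec)
        l2 = om.log_likelihood(theta, stats2, {1: (part, doubled.n)}, spec)
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    @pytest.mark.parametrize("case_seed", range(3))
    def test_concave_along_random_segments(self, toy1, case_seed):
        layout, r1, r2, mappable = toy1
        spec = om.ModelSpec(2, [[1], [2], [1, 2]])
        part = om.build_partition([r1, r2], mappable, 1, layout)
        rng = np.random.default_rng(7000 + case_seed)
        xs = rng.integers(1, 101, size=30)
        qs = om.QueryCollection([om.Query("chr1", int(x), 1) for x in xs])
        stats = om.sufficient_statistics(qs, spec.terms, [r1, r2], layout)
        parts = {1: (part, qs.n)}
        a = rng.normal(0, 2, size=3)
        b = rng.normal(0, 2, size=3)
        ts = np.linspace(0, 1, 9)
        vals = [om.log_likelihood(a + t * (b - a), stats, parts, spec) for t in ts]
        second_diff = np.diff(vals, 2)
        assert np.all(second_diff <= 1e-9)


class TestScoreInformation:
    def test_null_gradient_toy1(self, toy1_single_fit):
        """At theta=0, gradient = t - n * m_1/|G0| = 5 - 10*0.2 = 3."""
        spec, stats, parts = _toy_single_parts(toy1_single_fit)
        g, info = om.score_and_information(np.zeros(1), stats, parts, spec)
        assert g[0] == pytest.approx(3.0, abs=1e-12)
        assert info[0, 0] == pytest.approx(10 * 0.2 * 0.8, abs=1e-12)

    def test_matches_finite_differences(self, toy1):
        layout, r1, r2, mappable = toy1
        spec = om.ModelSpec(2, [[1], [2], [1, 2]])
        part = om.build_partition([r1, r2], mappable, 2, layout)
        rng = np.random.default_rng(8)
        xs = rng.integers(1, 99, size=25)
        qs = om.QueryCollection([om.Query("chr1", int(x), 2) for x in xs])
        stats = om.sufficient_statistics(qs, spec.terms, [r1, r2], layout)
        parts = {2: (part, qs.n)}
        theta = rng.normal(0, 1, size=3)
        g, info = om.score_and_information(theta, stats, parts, spec)
        eps = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = eps
            fd = (
                om.log_likelihood(theta + e, stats, parts, spec)
                - om.log_likelihood(theta - e, stats, parts, spec)
            ) / (2 * eps)
            assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-5)
        # information: symmetric PSD
        assert np.allclose(info, info.T)
        assert np.all(np.linalg.eigvalsh(info) > -1e-10)


class TestFitMLE:
    def test_toy1_closed_form_mle(self, toy1_single_fit):
        """Single term, cells a=20 / b=80, t=5, n=10: e^theta_hat = tb/((n-t)a) = 4."""
        spec, stats, parts = _toy_single_parts(toy1_single_fit)
        fit = om.fit_mle(stats, parts, spec)
        assert fit.converged
        assert fit.theta_hat[0] == pytest.approx(np.log(4.0), abs=1e-8)
        assert fit.score_norm <= 1e-5
        # observed information at the MLE: n p (1-p) = 2.5 at p = 0.5
        assert fit.observed_information[0, 0] == pytest.approx(2.5, abs=1e-6)

    def test_moment_matching_at_mle(self, toy1):
        layout, r1, r2, mappable = toy1
        spec = om.ModelSpec(2, [[1], [2], [1, 2]])
        part = om.build_partition([r1, r2], mappable, 1, layout)
        xs = [12, 13, 18, 19, 25, 26, 44, 70, 71, 72, 90, 95]
        qs = om.QueryCollection([om.Query("chr1", x, 1) for x in xs])
        stats = om.sufficient_statistics(qs, spec.terms, [r1, r2], layout)
        parts = {1: (part, qs.n)}
        fit = om.fit_mle(stats, parts, spec)
        assert fit.converged
        g, _ = om.score_and_information(fit.theta_hat, stats, parts, spec)
        # gradient zero <=> fitted expected per-term counts match T
        assert np.max(np.abs(g)) <= 1e-5

    def test_zero_count_flags_divergence(self, toy1):
        """t_pi = 0 sends theta_pi to -infinity; the fit must say so."""
        layout, r1, _, mappable = toy1
        spec = om.ModelSpec(1, [[1]])
        part = om.build_partition([r1], mappable, 1, layout)
        qs = om.QueryCollection([om.Query("chr1", x, 1) for x in (1, 2, 3)])
        stats = om.sufficient_statistics(qs, spec.terms, [r1], layout)
        fit = om.fit_mle(stats, {1: (part, qs.n)}, spec)
        assert not fit.converged
        assert (1,) in fit.diverged_terms
        assert fit.theta_hat[0] <= -5

    def test_parameter_recovery_within_three_se(self):
        """Fit of the true model to simulated data recovers theta."""
        layout = om.GenomeLayout([("chr1", 200_000)])
        refs = om.synth_references(layout, 2, 60, 400.0, seed=3)
        mappable = om.IntervalSet.whole_genome(layout)
        spec = om.ModelSpec(2, [[1], [2], [1, 2]])
        theta = np.array([0.8, -0.5, 0.4])
        qs = om.sample_queries(
            theta, spec, refs, mappable, layout, om.SimOptions(seed=9, n=4000)
        )
        data = om.OverlapDataset.from_queries(qs, refs, mappable, layout)
        fit = data.fit(spec, with_ci=True)
        assert fit.converged
        cov = np.linalg.inv(fit.observed_information)
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(fit.theta_hat - theta) <= 3 * se)

    def test_empty_model_fits_trivially(self, toy1_single_fit):
        layout, r1, mappable, queries = toy1_single_fit
        data = om.OverlapDataset.from_queries(queries, [r1], mappable, layout)
        fit = data.fit(om.ModelSpec(1, []))
        assert fit.converged and fit.loglik == 0.0


class TestWaldCI:
    def test_closed_form_interval(self, toy1_single_fit):
        spec, stats, parts = _toy_single_parts(toy1_single_fit)
        fit = om.fit_mle(stats, parts, spec)
        lo, hi = om.wald_ci(fit, 0.05)[(1,)]
        z = norm.ppf(0.975)
        assert lo == pytest.approx(np.log(4) - z / np.sqrt(2.5), abs=1e-6)
        assert hi == pytest.approx(np.log(4) + z / np.sqrt(2.5), abs=1e-6)
        assert (lo, hi) == pytest.approx((0.14668, 2.62590), abs=2e-4)

    def test_alpha_one_zero_width(self, toy1_single_fit):
        spec, stats, parts = _toy_single_parts(toy1_single_fit)
        fit = om.fit_mle(stats, parts, spec)
        lo, hi = om.wald_ci(fit, 1.0)[(1,)]
        assert lo == pytest.approx(hi)
        assert lo == pytest.approx(fit.theta_hat[0])

    def test_doubling_data_shrinks_width_by_sqrt2(self, toy1_single_fit):
        layout, r1, mappable, queries = toy1_single_fit
        spec = om.ModelSpec(1, [[1]])
        part = om.build_partition([r1], mappable, 1, layout)
        stats1 = om.sufficient_statistics(queries, spec.terms, [r1], layout)
        doubled = om.QueryCollection(list(queries) + list(queries))
        stats2 = om.sufficient_statistics(doubled, spec.terms, [r1], layout)
        f1 = om.fit_mle(stats1, {1: (part, queries.n)}, spec)
        f2 = om.fit_mle(stats2, {1: (part, doubled.n)}, spec)
        w1 = np.diff(om.wald_ci(f1)[(1,)])[0]
        w2 = np.diff(om.wald_ci(f2)[(1,)])[0]
        assert w1 / w2 == pytest.approx(np.sqrt(2), rel=1e-6)


class TestIdentifiability:
    def test_toy1_full_model_identifiable(self, toy1):
        layout, r1, r2, mappable = toy1
        part = om.build_partition([r1, r2], mappable, 1, layout)
        rep = om.check_identifiability(om.ModelSpec(2, [[1], [2], [1, 2]]), [part])
        assert rep.identifiable and rep.rank == 3 and not rep.missing_patterns

    def test_nested_reference_not_identifiable(self):
        """R2 entirely inside R1 leaves the (0,1) cell empty."""
        layout = om.GenomeLayout([("chr1", 100)])
        r1 = om.merge_normalize({"chr1": [(10, 50)]}, layout)
        r2 = om.merge_normalize({"chr1": [(20, 30)]}, layout)
        mappable = om.IntervalSet.whole_genome(layout)
        part = om.build_partition([r1, r2], mappable, 1, layout)
        rep = om.check_identifiability(om.ModelSpec(2, [[1], [2], [1, 2]]), [part])
        assert not rep.identifiable
        assert (0, 1) in rep.missing_patterns
        assert rep.rank < 3

    def test_empty_model_trivially_identifiable(self, toy1):
        layout, r1, r2, mappable = toy1
        part = om.build_partition([r1, r2], mappable, 1, layout)
        assert om.check_identifiability(om.ModelSpec(2, []), [part]).identifiable

    def test_singular_information_raises_on_ci(self):
        layout = om.GenomeLayout([("chr1", 100)])
        r1 = om.merge_normalize({"chr1": [(10, 50)]}, layout)
        r2 = om.merge_normalize({"chr1": [(10, 50)]}, layout)  # identical sets
        mappable = om.IntervalSet.whole_genome(layout)
        spec = om.ModelSpec(2, [[1], [2]])
        qs = om.QueryCollection([om.Query("chr1", x, 1) for x in (12, 20, 60, 70)])
        data = om.OverlapDataset.from_queries(qs, [r1, r2], mappable, layout)
        fit = data.fit(spec)
        with pytest.raises(IdentifiabilityError):
            om.wald_ci(fit)


class TestFeasibility:
    def test_no_warnings_on_strict_nesting(self):
        stats = om.SufficientStats(
            terms=(frozenset({1}), frozenset({2}), frozenset({1, 2})),
            t=np.array([2, 2, 1]),
            n=3,
        )
        assert om.check_feasibility(stats) == []

    def test_nested_equality_warns(self):
        stats = om.SufficientStats(
            terms=(frozenset({1}), frozenset({2}), frozenset({1, 2})),
            t=np.array([5, 3, 3]),
            n=8,
        )
        ws = om.check_feasibility(stats)
        assert any(
            w.kind == "nested_equality" and w.term == (1, 2) and w.other == (2,)
            for w in ws
        )

    def test_zero_count_warns(self):
        stats = om.SufficientStats(
            terms=(frozenset({1}),), t=np.array([0]), n=5
        )
        ws = om.check_feasibility(stats)
        assert len(ws) == 1 and ws[0].kind == "zero_count"
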