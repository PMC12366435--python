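"""Bootstrap moments, p-values, selection, and the structural-level filter."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from sklearn.linear_model import LogisticRegression

from tagdisc import (
    FeatureMatrix,
    SyntheticConfig,
    bootstrap_coefficients,
    filter_structural_level,
    fit_logistic,
    generate_corpus,
    normalize_features,
    pvalue_from_moments,
    read_results_table,
    reference_table,
    select_discriminators,
    write_results_table,
)
from tagdisc.bootstrap import BootstrapResult, SelectedTag


@pytest.fixture(scope="module")
def tiny_features(toy_scheme_factory):
    """12 speakers, 2 tags, balanced groups, real effect on tag00."""
    sch = toy_scheme_factory(2)
    cfg = SyntheticConfig(
        scheme=sch, n_pos=6, n_neg=6, effect=np.array([0.9, 0.0]), seed=4
    )
    return normalize_features(generate_corpus(cfg), sch)


class TestPvalueFromMoments:
    def test_null_center(self):
        assert pvalue_from_moments(0.0, 1.0) == 1.0
        assert pvalue_from_moments(0.0, 1e-9) == 1.0

    @pytest.mark.parametrize(
        "mean, sd, printed",
        [(-0.0741, 0.0214, 0.0005), (-0.0512, 0.0177, 0.0038)],
    )
    def test_published_rows(self, mean, sd, printed):
        """Printed moments reproduce the printed two-sided p-value (4 dp)."""
        assert round(pvalue_from_moments(mean, sd), 4) == printed

    def test_quadrature_oracle(self):
        """Tail probability agrees with numerical integration of the
        standard normal density to 1e-10."""
        for z in (0.3, 1.0, 1.96, 2.7, 4.1):
            tail, _ = quad(
                lambda t: np.exp(-t * t / 2) / np.sqrt(2 * np.pi), z, np.inf
            )
            assert pvalue_from_moments(z, 1.0) == pytest.approx(
                2 * tail, abs=1e-10
            )

    @settings(derandomize=True, max_examples=100)
    @given(
        mean=st.floats(-5, 5, allow_nan=False),
        sd=st.floats(0.01, 10, allow_nan=False),
        c=st.floats(0.01, 100, allow_nan=False),
    )
    def test_scale_invariance(self, mean, sd, c):
        assert pvalue_from_moments(c * mean, c * sd) == pytest.approx(
            pvalue_from_moments(mean, sd), rel=1e-9, abs=1e-12
        )

    def test_monotone_decreasing_in_effect(self):
        zs = np.linspace(0.0, 6.0, 50)
        ps = [pvalue_from_moments(z, 1.0) for z in zs]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            pvalue_from_moments(0.1, 0.0)


class TestBootstrapCoefficients:
    def test_degenerate_single_iteration(self, tiny_features):
        with pytest.warns(UserWarning, match="B=1"):
            res = bootstrap_coefficients(tiny_features, B=1, seed=0)
        # mean equals the single refit on that resample; sd 0; p undefined
        assert np.all(res.sd == 0.0)
        assert np.all(np.isnan(res.p_value))
        assert not res.significant.any()

    def test_seeded_reexecution_oracle(self, tiny_features):
        """Independent re-enumeration of the same seeded resamples
        reproduces mean and SD bit-exactly."""
        B, lam, seed = 200, 1.0, 13
        res = bootstrap_coefficients(tiny_features, B=B, penalty=lam,
                                     seed=seed)
        rng = np.random.default_rng(seed)
        n = tiny_features.n_speakers
        betas = np.empty((B, tiny_features.n_tags))
        n_failed = 0
        for b in range(B):
            while True:
                idx = rng.integers(0, n, size=n)
                if len(np.unique(tiny_features.y[idx])) == 2:
                    break
                n_failed += 1
            fm = FeatureMatrix(
                x=tiny_features.x[idx],
                y=tiny_features.y[idx],
                tag_names=tiny_features.tag_names,
                speaker_ids=tuple(f"r{i}" for i in range(n)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                betas[b] = fit_logistic(fm, lam).coef
        np.testing.assert_array_equal(res.mean, betas.mean(axis=0))
        np.testing.assert_array_equal(res.sd, betas.std(axis=0, ddof=1))
        assert res.n_failed == n_failed

    def test_moments_against_sklearn_refits(self, tiny_features):
        """Same resamples refit with sklearn's ridge logistic give the
        same bootstrap moments to optimizer tolerance."""
        B, lam, seed = 50, 1.0, 3
        res = bootstrap_coefficients(tiny_features, B=B, penalty=lam,
                                     seed=seed)
        rng = np.random.default_rng(seed)
        n = tiny_features.n_speakers
        betas = np.empty((B, tiny_features.n_tags))
        for b in range(B):
            while True:
                idx = rng.integers(0, n, size=n)
                if len(np.unique(tiny_features.y[idx])) == 2:
                    break
            clf = LogisticRegression(
                C=1.0 / lam, solver="lbfgs", tol=1e-12, max_iter=20_000
            ).fit(tiny_features.x[idx], tiny_features.y[idx])
            betas[b] = clf.coef_[0]
        np.testing.assert_allclose(res.mean, betas.mean(axis=0), atol=1e-5)
        np.testing.assert_allclose(res.sd, betas.std(axis=0, ddof=1),
                                   atol=1e-5)

    def test_determinism(self, tiny_features):
        a = bootstrap_coefficients(tiny_features, B=80, seed=7)
        b = bootstrap_coefficients(tiny_features, B=80, seed=7)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.sd, b.sd)
        assert np.array_equal(a.p_value, b.p_value, equal_nan=True)

    def test_internal_consistency_of_p(self, tiny_features):
        """Recomputing p from the result's own moments reproduces p."""
        res = bootstrap_coefficients(tiny_features, B=120, seed=5)
        for j in range(len(res.tag_names)):
            assert res.p_value[j] == pytest.approx(
                pvalue_from_moments(res.mean[j], res.sd[j]), abs=0
            )
            assert res.significant[j] == (res.p_value[j] < res.alpha)

    def test_degenerate_resamples_redrawn_and_counted(self, toy_scheme_factory):
        sch = toy_scheme_factory(1)
        cfg = SyntheticConfig(scheme=sch, n_pos=1, n_neg=7, seed=0)
        fm = normalize_features(generate_corpus(cfg), sch)
        # P(resample misses the one positive) = (7/8)^8 ~ 0.34: redraws occur
        res = bootstrap_coefficients(fm, B=60, seed=2)
        assert res.n_failed > 0

    def test_stratified_never_degenerate(self, toy_scheme_factory):
        sch = toy_scheme_factory(1)
        cfg = SyntheticConfig(scheme=sch, n_pos=1, n_neg=7, seed=0)
        fm = normalize_features(generate_corpus(cfg), sch)
        res = bootstrap_coefficients(fm, B=60, seed=2, stratified=True)
        assert res.n_failed == 0

    def test_invalid_B(self, tiny_features):
        with pytest.raises(ValueError, match="B must be"):
            bootstrap_coefficients(tiny_features, B=0)

    def test_sign_recovery_two_effect_sizes(self, toy_scheme_factory):
        """The bootstrap mean carries the sign of the planted effect, more
        reliably at the larger effect."""
        sch = toy_scheme_factory(2)
        hits = {0.6: 0, 1.4: 0}
        reps = 12
        for d in hits:
            for rep in range(reps):
                cfg = SyntheticConfig(
                    scheme=sch, n_pos=40, n_neg=40,
                    effect=np.array([d, 0.0]), seed=9_000 + rep,
                )
                fm = normalize_features(generate_corpus(cfg), sch)
                res = bootstrap_coefficients(fm, B=60, seed=rep)
                hits[d] += res.mean[0] > 0
        assert hits[1.4] == reps
        assert hits[0.6] >= reps - 2


class TestSelectDiscriminators:
    def _result(self, p_values, tags=None):
        p = np.asarray(p_values, float)
        m = len(p)
        tags = tags or tuple(f"t{j}" for j in range(m))
        from scipy.stats import norm

        mean = norm.isf(p / 2)  # moments consistent with p (sd = 1)
        return BootstrapResult(
            tag_names=tuple(tags), mean=mean, sd=np.ones(m),
            z=mean, p_value=p, significant=p < 0.05, alpha=0.05,
            B=100, n_failed=0, seed=0, penalty=1.0,
        )

    def test_boundary_strictness(self):
        res = self._result([0.0005, 0.05, 0.9])
        out = select_discriminators(res, alpha=0.05)
        assert [s.tag for s in out] == ["t0"]  # 0.05 is not < 0.05

    def test_saturation(self):
        res = self._result([0.2, 0.99, 0.5])
        out = select_discriminators(res, alpha=1 - 1e-12)
        assert len(out) == 3

    def test_sorted_by_p_then_scheme_order(self):
        res = self._result([0.03, 0.01, 0.03, 0.002])
        out = select_discriminators(res, alpha=0.05)
        assert [s.tag for s in out] == ["t3", "t1", "t0", "t2"]

    def test_bh_adjustment_is_more_conservative(self):
        res = self._result([0.001, 0.02, 0.04, 0.8, 0.9, 0.95])
        raw = select_discriminators(res, alpha=0.05)
        bh = select_discriminators(res, alpha=0.05, adjust="bh")
        assert {s.tag for s in bh} <= {s.tag for s in raw}

    def test_alpha_range_checked(self):
        res = self._result([0.5])
        for bad in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ValueError, match="alpha"):
                select_discriminators(res, alpha=bad)


class TestStructuralLevelFilter:
    @pytest.fixture()
    def published_selection(self, scheme):
        df = reference_table()
        return [
            SelectedTag(r.lexicogrammar, r.mean, r.sd, r.p_value)
            for r in df.itertuples()
        ]

    def test_clause_phrase_subset_is_twenty(self, scheme, published_selection):
        out = filter_structural_level(published_selection, scheme,
                                      "clause_phrase")
        assert len(out.selected) == 20
        assert len(out.unclassified) == 0

    def test_all_is_identity(self, scheme, published_selection):
        out = filter_structural_level(published_selection, scheme, "all")
        assert list(out.selected) == published_selection

    def test_empty_selection(self, scheme):
        out = filter_structural_level([], scheme, "clause_phrase")
        assert out.selected == () and out.unclassified == ()

    def test_unannotated_tag_listed_not_dropped(self, toy_scheme_factory):
        sch = toy_scheme_factory(2, level={"tag00": "clause_phrase"})
        sel = [SelectedTag("tag00", 0.1, 0.01, 0.001),
               SelectedTag("tag01", 0.2, 0.01, 0.002)]
        out = filter_structural_level(sel, sch, "clause_phrase")
        assert [s.tag for s in out.selected] == ["tag00"]
        assert [s.tag for s in out.unclassified] == ["tag01"]

    def test_unknown_level_rejected(self, scheme):
        with pytest.raises(ValueError, match="unknown level"):
            filter_structural_level([], scheme, "word")


class TestResultsTable:
    def test_round_trip(self, tmp_path, tiny_features):
        res = bootstrap_coefficients(tiny_features, B=40, seed=1)
        path = tmp_path / "results.csv"
        write_results_table(res, path)
        df = read_results_table(path)
        assert len(df) == 2
        np.testing.assert_allclose(df["mean"], np.round(res.mean, 4),
                                   atol=5e-5)
        assert df["significant"].tolist() == res.significant.tolist()

    def test_four_decimal_layout(self, tmp_path):
        res = BootstrapResult(
            tag_names=("Clause complexes-reported clauses",),
            mean=np.array([-0.07412]), sd=np.array([0.02141]),
            z=np.array([-3.462]), p_value=np.array([0.000535]),
            significant=np.array([True]), alpha=0.05, B=10_000,
            n_failed=0, seed=0, penalty=1.0,
        )
        path = tmp_path / "row.csv"
        write_results_table(res, path)
        line = path.read_text().splitlines()[1]
        assert line == ("Clause complexes-reported clauses,"
                        "-0.0741,0.0214,0.0005,true")

    def test_full_scheme_row_count(self, tmp_path, scheme):
        from tagdisc import generate_corpus, null_preset

        fm = normalize_features(generate_corpus(null_preset(scheme, seed=0)),
                                scheme)
        res = bootstrap_coefficients(fm, B=5, seed=0)
        path = tmp_path / "full.csv"
        write_results_table(res, path)
        assert len(read_results_table(path)) == 135
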