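"""Compositional design, F-tests, Moran's I, and PCA exploration."""

import numpy as np
import pandas as pd
import pytest

from toadtrends.association import (
    DegenerateDesignError,
    DesignSpec,
    MoranResult,
    RankDeficiencyError,
    build_design,
    moran_residuals,
    pca_explore,
    run_association,
)
from toadtrends.association import test_interactions as interaction_ftest
from toadtrends.association import test_omnibus_main as main_effects_ftest
from toadtrends.landscape import MERGED_CLASSES


def synthetic_profiles(n_sites: int, seed: int, radius: float = 500.0) -> pd.DataFrame:
    """Random compositional profiles with structure and change metrics."""
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(np.full(len(MERGED_CLASSES), 2.0), size=n_sites)
    df = pd.DataFrame(props, columns=[f"p_{c}" for c in MERGED_CLASSES])
    df.insert(0, "site_id", [f"s{i:03d}" for i in range(n_sites)])
    df.insert(1, "radius_m", radius)
    df["shannon"] = -(props * np.log(np.clip(props, 1e-12, None))).sum(axis=1)
    df["n_patches"] = rng.integers(5, 80, n_sites)
    df["edge_length_m"] = rng.uniform(100, 5000, n_sites)
    df["bray_curtis_change"] = rng.uniform(0, 0.4, n_sites)
    return df


def synthetic_trends(profiles: pd.DataFrame, seed: int,
                     signal: dict | None = None, sigma: float = 1.0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    n = len(profiles)
    y = rng.normal(0.0, sigma, n)
    if signal:
        for col, beta in signal.items():
            v = profiles[col].to_numpy(float)
            sd = v.std(ddof=1)
            y = y + beta * (v - v.mean()) / sd
    return pd.DataFrame(
        {
            "site_id": profiles.site_id,
            "begin_end": y,
            "x_m": rng.uniform(0, 50_000, n),
            "y_m": rng.uniform(0, 30_000, n),
        }
    )


class TestBuildDesign:
    def test_all_identities_triggers_aliasing_error(self):
        prof = synthetic_profiles(60, 0)
        tr = synthetic_trends(prof, 1)
        spec = DesignSpec(radius_m=500.0, reference_class=None)
        with pytest.raises(RankDeficiencyError, match="aliased"):
            build_design(prof, tr, spec)

    def test_dropping_reference_restores_full_rank(self):
        prof = synthetic_profiles(60, 0)
        tr = synthetic_trends(prof, 1)
        X, y = build_design(prof, tr, DesignSpec(radius_m=500.0))
        assert X.shape == (60, 9)  # 5 identities + 3 structure + 1 change
        assert "p_agricultural land" not in X.columns

    def test_residual_df_bookkeeping_at_reference_study_size(self):
        # 111 sites, 6 identities, 3 structure, 1 change -> residual df 101
        prof = synthetic_profiles(111, 3)
        tr = synthetic_trends(prof, 4)
        X, y = build_design(prof, tr, DesignSpec(radius_m=500.0))
        res = main_effects_ftest(X, y)
        assert res.df == (9, 101)

    def test_known_replacement_effect_recovered(self):
        # response built as a pure woodland-for-agriculture replacement
        # effect; its coefficient should estimate that effect
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            prof = synthetic_profiles(120, 100 + i)
            rng = np.random.default_rng(500 + i)
            beta_w = 2.0
            y = beta_w * prof["p_woodland"].to_numpy() + rng.normal(0, 0.3, 120)
            tr = pd.DataFrame(
                {"site_id": prof.site_id, "begin_end": y,
                 "x_m": rng.uniform(0, 1e4, 120), "y_m": rng.uniform(0, 1e4, 120)}
            )
            X, yv = build_design(prof, tr, DesignSpec(radius_m=500.0))
            res = main_effects_ftest(X, yv)
            est = res.coefficients.loc["p_woodland", "estimate"]
            se = res.coefficients.loc["p_woodland", "se"]
            hits += bool(abs(est - beta_w) <= 2.0 * se)
        assert hits / n_rep >= 0.9


class TestFTests:
    def test_type_one_error_calibrated_under_global_null(self):
        prof = synthetic_profiles(120, 7)
        X, _ = build_design(
            prof, synthetic_trends(prof, 8), DesignSpec(radius_m=500.0)
        )
        spec = DesignSpec(radius_m=500.0)
        rng = np.random.default_rng(9)
        rej_main = rej_int = 0
        n_rep = 500
        for _ in range(n_rep):
            y = pd.Series(rng.normal(0, 1, len(X)), index=X.index)
            rej_main += main_effects_ftest(X, y).p <= 0.05
            rej_int += interaction_ftest(X, y, spec)[2] <= 0.05
        assert 0.03 <= rej_main / n_rep <= 0.08
        assert 0.03 <= rej_int / n_rep <= 0.08

    def test_planted_interaction_detected(self):
        spec = DesignSpec(radius_m=500.0)
        hits = 0
        n_rep = 60
        for i in range(n_rep):
            prof = synthetic_profiles(120, 200 + i)
            rng = np.random.default_rng(300 + i)
            a = prof["p_woodland"].to_numpy()
            b = prof["p_water"].to_numpy()
            inter = a * b
            # project out the main effects so the planted signal is purely
            # interaction-shaped (a raw product is mostly collinear with a, b)
            M = np.column_stack([np.ones(120), a, b])
            resid = inter - M @ np.linalg.lstsq(M, inter, rcond=None)[0]
            y = 0.5 * resid / resid.std(ddof=1) + rng.normal(0, 1, 120)
            tr = pd.DataFrame(
                {"site_id": prof.site_id, "begin_end": y,
                 "x_m": rng.uniform(0, 1e4, 120), "y_m": rng.uniform(0, 1e4, 120)}
            )
            X, yv = build_design(prof, tr, spec)
            hits += interaction_ftest(X, yv, spec)[2] <= 0.05
        assert hits / n_rep >= 0.8

    def test_planted_shannon_effect_found_by_posthoc(self):
        hits_omni = hits_post = 0
        n_rep = 40
        for i in range(n_rep):
            prof = synthetic_profiles(120, 400 + i)
            tr = synthetic_trends(prof, 600 + i, signal={"shannon": 2.0}, sigma=0.5)
            X, y = build_design(prof, tr, DesignSpec(radius_m=500.0))
            res = main_effects_ftest(X, y)
            hits_omni += res.p <= 0.05
            if res.posthoc:
                smallest = min(res.posthoc, key=res.posthoc.get)
                hits_post += smallest == "shannon"
        assert hits_omni / n_rep >= 0.95
        assert hits_post / n_rep >= 0.9

    def test_zero_residual_response_gives_zero_f(self):
        prof = synthetic_profiles(50, 11)
        tr = synthetic_trends(prof, 12)
        X, y = build_design(prof, tr, DesignSpec(radius_m=500.0))
        res = main_effects_ftest(X, pd.Series(np.full(len(y), 3.7), index=y.index))
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_posthoc_gated_on_omnibus(self):
        prof = synthetic_profiles(120, 13)
        X, _ = build_design(
            prof, synthetic_trends(prof, 14), DesignSpec(radius_m=500.0)
        )
        rng = np.random.default_rng(15)
        for _ in range(20):
            y = pd.Series(rng.normal(0, 1, len(X)), index=X.index)
            res = main_effects_ftest(X, y)
            if res.p > 0.05:
                assert res.posthoc == {}

    def test_degenerate_interaction_design_raises(self):
        # constant identity columns: every product is aliased
        prof = synthetic_profiles(40, 16)
        for c in MERGED_CLASSES:
            prof[f"p_{c}"] = 1.0 / len(MERGED_CLASSES)
        tr = synthetic_trends(prof, 17)
        spec = DesignSpec(radius_m=500.0)
        with pytest.raises((DegenerateDesignError, RankDeficiencyError)):
            X, y = build_design(prof, tr, spec)
            interaction_ftest(X, y, spec)

    def test_f_invariant_to_affine_rescaling_of_structure_terms(self):
        prof = synthetic_profiles(90, 18)
        tr = synthetic_trends(prof, 19)
        X1, y = build_design(prof, tr, DesignSpec(radius_m=500.0))
        prof2 = prof.copy()
        prof2["edge_length_m"] = prof2["edge_length_m"] * 1000.0 + 5.0
        prof2["n_patches"] = prof2["n_patches"] * 7
        X2, _ = build_design(prof2, tr, DesignSpec(radius_m=500.0))
        f1 = main_effects_ftest(X1, y).F
        f2 = main_effects_ftest(X2, y).F
        assert f1 == pytest.approx(f2, rel=1e-9)


class TestMoran:
    def test_expected_value_exact(self):
        rng = np.random.default_rng(20)
        for n in (4, 10, 112):
            res = moran_residuals(
                rng.normal(0, 1, n),
                list(zip(rng.uniform(0, 100, n), rng.uniform(0, 100, n))),
            )
            assert res.expected == -1.0 / (n - 1)
        # at the reference 112-site analysis, expected is about -0.009
        assert -1.0 / 111 == pytest.approx(-0.009, abs=5e-4)

    def test_null_coverage_against_permutation_distribution(self):
        rng = np.random.default_rng(21)
        n, n_trials, n_perm = 50, 100, 1000
        xy = np.column_stack([rng.uniform(0, 1000, n), rng.uniform(0, 1000, n)])
        d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        W = 1.0 / d
        W /= W.sum(1, keepdims=True)

        def quick_I(z):
            zc = z - z.mean()
            return (zc @ W @ zc) / (zc @ zc)

        inside = 0
        for _ in range(n_trials):
            z = rng.normal(0, 1, n)
            obs = quick_I(z)
            perms = np.array([quick_I(rng.permutation(z)) for _ in range(n_perm)])
            lo, hi = np.quantile(perms, [0.025, 0.975])
            inside += bool(lo <= obs <= hi)
        assert inside / n_trials >= 0.93

    def test_spatial_gradient_detected(self):
        rng = np.random.default_rng(22)
        n = 80
        xy = np.column_stack([rng.uniform(0, 1000, n), rng.uniform(0, 1000, n)])
        z = xy[:, 0] / 1000.0 + rng.normal(0, 0.05, n)
        res = moran_residuals(z, [tuple(p) for p in xy])
        assert res.p < 0.01
        assert res.observed > res.expected

    def test_duplicate_coordinates_jittered_not_fatal(self):
        rng = np.random.default_rng(23)
        coords = [(0.0, 0.0), (0.0, 0.0), (10.0, 10.0), (20.0, 5.0), (7.0, 3.0)]
        res = moran_residuals(rng.normal(0, 1, 5), coords)
        assert isinstance(res, MoranResult)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            moran_residuals(np.ones(10), [(i, 0.0) for i in range(10)])


class TestPca:
    def test_variance_explained_sums_to_one(self):
        prof = synthetic_profiles(40, 30)
        res = pca_explore(prof)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_perfectly_correlated_columns_share_loading_magnitude(self):
        rng = np.random.default_rng(31)
        v = rng.normal(0, 1, 50)
        df = pd.DataFrame(
            {"site_id": range(50), "p_a": v, "p_b": 2.0 * v,
             "p_c": rng.normal(0, 1, 50)}
        )
        res = pca_explore(df)
        la, lb = res.loadings.loc["p_a", "PC1"], res.loadings.loc["p_b", "PC1"]
        assert abs(la) == pytest.approx(abs(lb), abs=1e-9)

    def test_planted_urban_rural_gradient_separates_on_pc1(self):
        rng = np.random.default_rng(32)
        n = 60
        group = np.repeat([0, 1], n // 2)
        urban = np.where(group == 1, 0.7, 0.1) + rng.normal(0, 0.05, n)
        rural = 1.0 - urban + rng.normal(0, 0.02, n)
        df = pd.DataFrame(
            {"site_id": range(n), "p_urban": urban, "p_rural": rural,
             "p_noise": rng.uniform(0, 1, n)}
        )
        res = pca_explore(df)
        from sklearn.metrics import silhouette_score

        assert silhouette_score(res.scores[["PC1"]], group) > 0.0

    def test_too_few_sites_rejected(self):
        df = pd.DataFrame({"site_id": [1, 2], "p_a": [0.1, 0.9], "p_b": [0.9, 0.1]})
        with pytest.raises(ValueError):
            pca_explore(df)

    def test_sign_convention_deterministic(self):
        prof = synthetic_profiles(30, 33)
        a = pca_explore(prof)
        b = pca_explore(prof)
        assert np.allclose(a.loadings.to_numpy(), b.loadings.to_numpy())
        for col in a.loadings.columns:
            j = a.loadings[col].abs().idxmax()
            assert a.loadings.loc[j, col] > 0


class TestRunAssociation:
    def _inputs(self, seed, n=111, signal=None, radii=(100.0, 500.0, 1000.0)):
        frames = []
        for r in radii:
            p = synthetic_profiles(n, seed, radius=r)
            frames.append(p)
        prof = pd.concat(frames, ignore_index=True)
        tr = synthetic_trends(
            prof[prof.radius_m == radii[0]].reset_index(drop=True),
            seed + 1, signal=signal,
        )
        return prof, tr

    def test_three_radii_three_reports_table_shape(self):
        prof, tr = self._inputs(40)
        reports, table, conclusion = run_association(prof, tr)
        assert len(reports) == 3
        assert list(table.columns) == ["radius_m", "F", "df_model", "df_resid", "p"]
        assert (table.df_resid == 101).all()

    def test_null_data_yields_null_conclusion(self):
        hits = 0
        n_rep = 25
        for i in range(n_rep):
            prof, tr = self._inputs(1000 + 7 * i)
            _, _, conclusion = run_association(prof, tr)
            hits += conclusion == "no significant association at any scale"
        assert hits / n_rep >= 0.8

    def test_scale_specific_signal_found_at_its_scale(self):
        # plant a strong shannon effect at 500 m only
        found_at_500 = 0
        n_rep = 15
        for i in range(n_rep):
            prof, tr = self._inputs(2000 + 11 * i)
            p500 = prof[prof.radius_m == 500.0]
            v = p500["shannon"].to_numpy(float)
            extra = 2.5 * (v - v.mean()) / v.std(ddof=1)
            tr = tr.copy()
            tr["begin_end"] = tr["begin_end"].to_numpy() * 0.3 + extra
            reports, _, _ = run_association(prof, tr)
            by_radius = {r.radius_m: r for r in reports}
            found_at_500 += by_radius[500.0].omnibus_p <= 0.05
        assert found_at_500 / n_rep >= 0.9

    def test_posthoc_never_reported_when_both_omnibus_fail(self):
        prof, tr = self._inputs(3000)
        reports, _, _ = run_association(prof, tr)
        for r in reports:
            if r.omnibus_p > 0.05 and not (r.interaction_p <= 0.05):
                assert r.posthoc == {}
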