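"""Tentative distributions, stratum design, and conditional logistic fits."""

import numpy as np
import pandas as pd
import pytest

from movestate import SimTruth, simulate_tracks
from movestate.issf import (
    TentativeDistributions,
    build_design,
    build_strata,
    clogit_loglik,
    fit_clogit,
    fit_tentative,
    generate_available,
    run_issf,
)
from movestate.synthetic_data import simulate_selection_strata
from movestate.tracks_io import (
    assign_hunting_pressure,
    assign_time_of_day,
    build_steps,
    filter_season,
)


@pytest.fixture(scope="module")
def tentative():
    return TentativeDistributions(k=1.0, theta=300.0, vm_conc=0.5)


class TestTentative:
    def test_mle_recovery(self):
        rng = np.random.default_rng(0)
        l = rng.gamma(2.0, 50.0, 10_000)
        phi = rng.vonmises(0.0, 0.7, 10_000)
        t = fit_tentative(l, phi)
        assert t.k == pytest.approx(2.0, rel=0.05)
        assert t.theta * t.k == pytest.approx(l.mean() + 1.0, rel=0.02)
        assert t.vm_conc == pytest.approx(0.7, rel=0.1)

    def test_zero_lengths_fit_via_offset(self):
        # the +1 m rule: exact-zero steps must not break the gamma MLE
        rng = np.random.default_rng(1)
        l = rng.gamma(2.0, 50.0, 200)
        l[:40] = 0.0  # GPS fixes with no movement
        phi = rng.vonmises(0.0, 0.5, 200)
        t = fit_tentative(l, phi)
        assert np.isfinite(t.k) and t.k > 0
        assert t.mean == pytest.approx(l.mean() + 1.0, rel=0.05)

    def test_constant_lengths_excluded(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_tentative(np.full(100, 50.0), np.zeros(100))

    def test_too_few_steps(self):
        with pytest.raises(ValueError, match="too few"):
            fit_tentative(np.arange(10.0), np.zeros(10))

    def test_negative_cosine_mean_gives_zero_concentration(self):
        rng = np.random.default_rng(2)
        phi = rng.uniform(-np.pi, np.pi, 200)
        phi = np.where(np.abs(phi) < np.pi / 2, phi + np.pi, phi)  # mass near +-pi
        t = fit_tentative(rng.gamma(2, 50, 200), phi)
        assert t.vm_conc == 0.0


class TestGenerateAvailable:
    def test_exactly_n_and_deterministic(self, landscape, tentative):
        out1 = generate_available(
            (1000.0, 1000.0), 0.3, tentative, landscape, np.random.default_rng(5), n=25
        )
        out2 = generate_available(
            (1000.0, 1000.0), 0.3, tentative, landscape, np.random.default_rng(5), n=25
        )
        assert out1 is not None
        l, phi, ex, ey = out1
        assert len(l) == 25
        for a, b in zip(out1, out2):
            np.testing.assert_array_equal(a, b)

    def test_high_concentration_collinear(self, landscape):
        tent = TentativeDistributions(k=2.0, theta=50.0, vm_conc=1e6)
        out = generate_available(
            (1200.0, 1200.0), 0.7, tent, landscape, np.random.default_rng(0), n=25
        )
        _, phi, _, _ = out
        assert np.abs(phi).max() < 0.01  # turns ~0: collinear with prev bearing

    def test_lengths_floored_at_zero(self, landscape):
        tent = TentativeDistributions(k=0.5, theta=0.5, vm_conc=0.1)
        l, _, _, _ = generate_available(
            (1200.0, 1200.0), 0.0, tent, landscape, np.random.default_rng(1), n=200
        )
        assert l.min() >= 0.0


class TestDesign:
    def make_stratum(self, tod="day", hp="none"):
        return pd.DataFrame(
            {
                "dist_forest": [0.5, -0.5],
                "dist_settlement": [1.0, 0.0],
                "dist_road": [-1.0, 1.0],
                "l": [100.0, 200.0],
                "phi": [0.0, np.pi / 2],
                "time_of_day": tod,
                "hunting_pressure": hp,
            }
        )

    def test_reference_levels_zero_interactions(self):
        X = build_design(self.make_stratum("day", "none"))
        inter = [c for c in X.columns if ":" in c]
        assert (X[inter].to_numpy() == 0).all()
        assert X["l"].tolist() == [100.0, 200.0]
        np.testing.assert_allclose(X["log_l"], np.log([101.0, 201.0]))
        np.testing.assert_allclose(X["cos_phi"], [1.0, 0.0], atol=1e-15)

    def test_night_interactions_equal_mains(self):
        X = build_design(self.make_stratum("night", "none"))
        for cov in ("dist_forest", "dist_settlement", "dist_road"):
            np.testing.assert_array_equal(X[f"{cov}:night"], X[cov])
            assert (X[f"{cov}:high"] == 0).all()

    def test_hand_computed_matrix(self):
        X = build_design(self.make_stratum("night", "high"))
        row = X.iloc[0]
        assert row["dist_forest"] == 0.5
        assert row["dist_forest:night"] == 0.5
        assert row["dist_forest:high"] == 0.5
        assert row["dist_forest:low"] == 0.0
        assert row["dist_road:high"] == -1.0
        assert X.shape[1] == 15

    def test_missing_covariate_raises(self):
        st = self.make_stratum().drop(columns=["dist_road"])
        with pytest.raises(ValueError, match="dist_road"):
            build_design(st)


class TestClogit:
    def test_initial_loglik_uniform_choice(self, landscape, tentative):
        st = simulate_selection_strata(landscape, tentative, np.zeros(3), 40, seed=0)
        X = build_design(st)
        starts = np.flatnonzero(
            np.r_[True, st["stratum_id"].to_numpy()[1:] != st["stratum_id"].to_numpy()[:-1]]
        )
        ll0 = clogit_loglik(np.zeros(X.shape[1]), X, st["case"].to_numpy(), starts)
        assert ll0 == pytest.approx(-40 * np.log(26), rel=1e-12)

    def test_single_covariate_grid_search(self):
        # 3 strata, one covariate: Newton solution vs 1-D grid of the likelihood
        rng = np.random.default_rng(3)
        rows = []
        for s in range(3):
            xs = rng.normal(size=5)
            used = int(np.argmax(xs + rng.gumbel(size=5)))
            for j, x in enumerate(xs):
                rows.append({"stratum_id": s, "case": int(j == used), "x": x})
        df = pd.DataFrame(rows)
        X = df[["x"]]
        terms, beta, se, ll, conv, dropped = fit_clogit(
            X, df["case"].to_numpy(), df["stratum_id"].to_numpy()
        )
        starts = np.arange(0, 15, 5)
        grid = np.linspace(-5, 5, 20001)
        lls = [clogit_loglik(np.array([b]), X, df["case"].to_numpy(), starts) for b in grid]
        assert beta[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)

    def test_loglik_at_optimum_beats_null(self, landscape, tentative):
        st = simulate_selection_strata(landscape, tentative, np.array([-0.5, 0.3, 0.0]), 150, seed=1)
        X = build_design(st)
        terms, beta, se, ll, conv, _ = fit_clogit(
            X, st["case"].to_numpy(), st["stratum_id"].to_numpy()
        )
        assert conv
        assert ll >= -150 * np.log(26)

    def test_invariant_to_stratum_constant_shift(self, landscape, tentative):
        st = simulate_selection_strata(landscape, tentative, np.zeros(3), 30, seed=2)
        X = build_design(st)[["dist_forest", "l"]]
        case = st["case"].to_numpy()
        sid = st["stratum_id"].to_numpy()
        starts = np.flatnonzero(np.r_[True, sid[1:] != sid[:-1]])
        beta = np.array([0.4, -0.002])
        eta_shift = X.copy()
        # adding any stratum-constant to all 26 linear predictors is absorbed
        shift = np.repeat(np.random.default_rng(0).normal(size=30), 26)
        ll_a = clogit_loglik(beta, X, case, starts)
        eta = X.to_numpy() @ beta + shift
        mx = np.maximum.reduceat(eta, starts)
        lse = np.log(np.add.reduceat(np.exp(eta - np.repeat(mx, 26)), starts)) + mx
        ll_b = float(eta[case == 1].sum() - lse.sum())
        assert ll_a == pytest.approx(ll_b, abs=1e-9)

    def test_recovery_against_statsmodels(self, landscape, tentative):
        # independent cross-check: statsmodels ConditionalLogit on the same data
        from statsmodels.discrete.conditional_models import ConditionalLogit

        st = simulate_selection_strata(landscape, tentative, np.array([-0.4, 0.2, 0.1]), 120, seed=4)
        X = build_design(st)[["dist_forest", "dist_settlement", "dist_road"]]
        terms, beta, se, ll, conv, _ = fit_clogit(
            X, st["case"].to_numpy(), st["stratum_id"].to_numpy()
        )
        ref = ConditionalLogit(
            st["case"].to_numpy(), X.to_numpy(), groups=st["stratum_id"].to_numpy()
        ).fit(disp=False)
        np.testing.assert_allclose(beta, ref.params, atol=1e-3)
        np.testing.assert_allclose(se, ref.bse, rtol=1e-2)

    def test_mean_recovery_over_replicates(self, landscape, tentative):
        beta_true = np.array([-0.5, 0.3, 0.0])
        est = []
        for rep in range(20):
            st = simulate_selection_strata(landscape, tentative, beta_true, 150, seed=100 + rep)
            X = build_design(st)
            terms, beta, se, ll, conv, _ = fit_clogit(
                X, st["case"].to_numpy(), st["stratum_id"].to_numpy()
            )
            d = dict(zip(terms, beta))
            est.append([d["dist_forest"], d["dist_settlement"], d["dist_road"]])
        est = np.array(est)
        mcse = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0) - beta_true) < 2 * mcse + 1e-12)

    def test_movement_terms_centered_at_zero(self, landscape, tentative):
        # availables drawn from the tentative itself: l, ln l, cos phi have
        # true coefficient 0 (the iSSA identity)
        vals = []
        for rep in range(60):
            st = simulate_selection_strata(landscape, tentative, np.zeros(3), 150, seed=200 + rep)
            X = build_design(st)
            terms, beta, se, ll, conv, _ = fit_clogit(
                X, st["case"].to_numpy(), st["stratum_id"].to_numpy()
            )
            d = dict(zip(terms, beta))
            vals.append([d["l"], d["log_l"], d["cos_phi"]])
        vals = np.array(vals)
        # conditional-MLE small-sample bias is O(1/n_strata) and nonzero, so
        # assert centering at the sampling-noise scale, not to MC precision
        sd = vals.std(axis=0, ddof=1)
        assert np.all(np.abs(vals.mean(axis=0)) < 0.5 * sd + 1e-12)


@pytest.fixture(scope="module")
def small_run(landscape):
    truth = SimTruth()
    fixes, _ = simulate_tracks(
        landscape, truth, n_individual_years=2, fixes_per_track=450,
        seed=8, start_date_rule="three_periods", n_animals=2,
    )
    steps = build_steps(filter_season(fixes))
    steps["time_of_day"] = assign_time_of_day(steps["t_end"]).to_numpy()
    steps["hunting_pressure"] = assign_hunting_pressure(steps["t_end"]).to_numpy()
    # decode with the true labels (segmentation tested elsewhere)
    fx = fixes.copy()
    fx["timestamp"] = pd.to_datetime(fx["timestamp"], utc=True)
    key = fx.set_index(["iy_id", "timestamp"])["true_state"]
    true_state = [
        int(key.loc[(row["iy_id"], row["t_end"])]) for _, row in steps.iterrows()
    ]
    cohort = pd.DataFrame(
        {
            "iy_id": [f"F{i:03d}-2012" for i in (1, 2)],
            "age": [6, 11],
            "calf_fate_prev": ["loss", "no loss"],
        }
    )
    return run_issf(
        steps, np.array(true_state), landscape, cohort, seed=99, min_strata=20
    )


class TestRunISSF:
    def test_one_fit_per_slice(self, small_run):
        fits, records, skipped = small_run
        slices = {(f.iy_id, f.state) for f in fits}
        assert len(fits) == len(slices)
        assert 2 <= len(fits) <= 4

    def test_records_match_estimable_terms(self, small_run):
        fits, records, skipped = small_run
        for f in fits:
            if not f.converged:
                continue
            n_valid = int(
                np.sum(np.isfinite(f.beta) & np.isfinite(f.se) & (f.se > 0))
            )
            got = len(records[(records["iy_id"] == f.iy_id) & (records["state"] == f.state)])
            assert got == n_valid

    def test_records_carry_cohort_annotations(self, small_run):
        fits, records, skipped = small_run
        assert records["age"].notna().all()
        assert records["calf_fate"].isin(["loss", "no loss"]).all()
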