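"""Calibration, dose-response sweep, plateau detection, subgroups."""

from dataclasses import replace

import numpy as np
import pytest

import surgesim as ss
from surgesim.engine import RunResult
from surgesim.experiments import _mean_expected_rate

from conftest import toy_facilities


def small_config(**over):
    kw = dict(batch_size=2_000, n_runs=3, master_seed=5)
    kw.update(over)
    return ss.SimulationConfig(**kw)


def synthetic_curve(doses, means):
    summaries = tuple(
        ss.DoseSummary(dose=d, mean_no_show=m, ui_low=m, ui_high=m, n_runs=2)
        for d, m in zip(doses, means)
    )
    return ss.DoseResponseCurve(summaries=summaries)


class TestDetectPlateau:
    def test_flat_curve_plateaus_at_first_dose(self):
        c = synthetic_curve(np.arange(5) * 10.0, np.full(5, 0.3))
        p = ss.detect_plateau(c, epsilon=0.005)
        assert p.found and p.dose == 0.0 and p.rate == 0.3

    def test_piecewise_drop_then_flat(self):
        k = 6
        means = np.concatenate([0.5 - 0.01 * np.arange(k + 1), np.full(4, 0.5 - 0.01 * k)])
        doses = 10_000.0 * np.arange(len(means))
        p = ss.detect_plateau(synthetic_curve(doses, means), epsilon=0.005)
        assert p.dose == doses[k]

    def test_never_flat_returns_sentinel(self):
        c = synthetic_curve(np.arange(6) * 1.0, 0.9 - 0.1 * np.arange(6))
        p = ss.detect_plateau(c, epsilon=0.005)
        assert not p.found and p.dose is None and p.rate is None

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_plateau_at_max_price_for_random_toy_tables(self, seed):
        """Under the capped money term the curve freezes at the top price."""
        rng = np.random.default_rng(seed)
        step = 50_000.0
        prices = rng.integers(1, 9, size=(4, 4)) * step
        prices[rng.random((4, 4)) < 0.2] = np.nan
        if np.isnan(prices).all(axis=0).any():  # keep every procedure offered
            prices[0] = step
        cfg = small_config(
            facilities=toy_facilities(prices),
            weights=ss.WeightModel(lam=(1.5, 0.3), alpha_home=(0.0, 0.2)),
            n_runs=2,
            batch_size=1_000,
        )
        grid = np.arange(0.0, np.nanmax(prices) + 2.5 * step, step)
        curve = ss.dose_sweep(cfg, grid, statistic="expected")
        p = ss.detect_plateau(curve)
        assert p.dose == np.nanmax(prices)

    def test_requires_at_least_two_points(self):
        c = synthetic_curve([0.0], [0.5])
        assert not ss.detect_plateau(c).found


class TestDoseSweep:
    def test_single_point_grid_equals_run_batch(self):
        cfg = small_config()
        curve = ss.dose_sweep(cfg, [0.0], statistic="expected")
        batch = ss.run_batch(cfg.at_dose(0.0), statistic="expected")
        assert curve.summaries[0] == batch

    def test_shared_seeds_freeze_curve_beyond_cap(self):
        cfg = small_config()
        top = cfg.facilities.max_price
        curve = ss.dose_sweep(cfg, [top, top + 200_000.0, top + 400_000.0])
        assert curve.summaries[0].mean_no_show == curve.summaries[1].mean_no_show
        assert curve.summaries[1].mean_no_show == curve.summaries[2].mean_no_show

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            ss.dose_sweep(small_config(), [0.0, 0.0])


class TestCalibration:
    def test_parameter_recovery_from_known_generator(self):
        """Anchors produced by a known (alpha_home, lambda) are re-fit."""
        cfg = small_config(batch_size=4_000, master_seed=9)
        true = cfg.weights.recalibrated(0.2, 1.5)
        gen = replace(cfg, weights=true, n_runs=2)
        anchors = [
            (d, _mean_expected_rate(gen, d)) for d in (0.0, 280_000.0)
        ]
        res = ss.calibrate(
            anchors, cfg, n_cal_runs=2, cal_batch_size=4_000, tolerance=0.015
        )
        assert res.converged
        for (d, target), achieved in zip(anchors, res.achieved):
            assert achieved == pytest.approx(target, abs=0.015)

    def test_single_anchor_converges(self):
        cfg = small_config(batch_size=2_000)
        res = ss.calibrate(
            [(0.0, 0.5)], cfg, n_cal_runs=2, cal_batch_size=2_000, tolerance=0.015
        )
        assert res.converged and abs(res.achieved[0] - 0.5) <= 0.015

    def test_unreachable_anchor_raises_with_best_found(self):
        cfg = small_config(batch_size=1_000)
        with pytest.raises(RuntimeError) as exc:
            ss.calibrate(
                [(0.0, 0.5), (10_000.0, 0.01)],  # near-flat dose step can't drop 49pp
                cfg,
                n_cal_runs=2,
                cal_batch_size=1_000,
                max_iter=40,
                tolerance=0.001,
            )
        assert isinstance(exc.value.result, ss.CalibrationResult)
        assert not exc.value.result.converged


class TestSubgroups:
    @staticmethod
    def _fake_runs(rate_by_level, n_runs=6, var="gender", levels=("male", "female")):
        runs = []
        rng = np.random.default_rng(0)
        for i in range(n_runs):
            sub = {}
            for var_, levels_, rates in rate_by_level:
                for lvl, rate in zip(levels_, rates):
                    noise = rng.normal(0, 1e-4)
                    sub[(var_, lvl)] = (rate + noise, 100)
            runs.append(
                RunResult(
                    dose=0.0, seed=i, n_agents=200, no_show_rate=0.3,
                    expected_no_show_rate=0.3, subgroup_rates=sub,
                )
            )
        return runs

    def test_identical_strata_not_flagged(self):
        runs = self._fake_runs([("gender", ("male", "female"), (0.3, 0.3))])
        tab = ss.subgroup_analysis(runs, strata=("gender",))
        assert not tab["significant"].any()
        assert tab["diff_vs_reference"].abs().max() < 0.01

    def test_separated_strata_flagged(self):
        runs = self._fake_runs([("gender", ("male", "female"), (0.2, 0.6))])
        tab = ss.subgroup_analysis(runs, strata=("gender",))
        row = tab[tab.level == "female"].iloc[0]
        assert row["significant"]
        assert row["diff_vs_reference"] == pytest.approx(0.4, abs=0.01)

    def test_low_income_stratum_shows_higher_no_show_and_flags(self):
        """Directional check: a 10x poorer stratum no-shows more."""
        from surgesim.choice import choice_probabilities, sample_choice, utility_matrix
        from surgesim.population import generate_population

        cfg = small_config(batch_size=4_000, master_seed=21)
        cfg = replace(cfg, weights=ss.WeightModel(lam=(2.7, 0.5), alpha_home=(-0.4, 0.3)))
        proc_map = {p: i for i, p in enumerate(("laparotomy", "cesarean", "goiter", "mandibulectomy"))}
        runs = []
        for seed in cfg.run_seeds():
            rng = np.random.default_rng(seed)
            pop = generate_population(replace(cfg.population, n_agents=cfg.batch_size), rng=rng)
            poor = (pop["education"] == "primary").to_numpy()
            income = pop["income_gnf"].to_numpy().copy()
            income[poor] /= 10.0
            w = cfg.weights.draw(len(pop), rng)
            V = utility_matrix(
                income,
                pop["procedure"].map(proc_map).to_numpy(),
                pop[["x_km", "y_km"]].to_numpy(float),
                w,
                cfg.facilities,
                0.0,
            )
            home = sample_choice(choice_probabilities(V), rng) == 0
            sub = {}
            for lvl in ("none", "primary", "secondary"):
                mask = (pop["education"] == lvl).to_numpy()
                sub[("education", lvl)] = (float(home[mask].mean()), int(mask.sum()))
            runs.append(
                RunResult(
                    dose=0.0, seed=seed, n_agents=len(pop),
                    no_show_rate=float(home.mean()),
                    expected_no_show_rate=float(home.mean()),
                    subgroup_rates=sub,
                )
            )
        tab = ss.subgroup_analysis(runs, strata=("education",))
        row = tab[tab.level == "primary"].iloc[0]
        assert row["diff_vs_reference"] > 0
        assert row["significant"]

    def test_too_few_runs_rejected(self):
        runs = self._fake_runs([("gender", ("male", "female"), (0.3, 0.3))], n_runs=1)
        with pytest.raises(ValueError):
            ss.subgroup_analysis(runs, strata=("gender",))
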