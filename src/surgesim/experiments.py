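"""Calibration, dose sweep, plateau detection and subgroup analysis.

The two free preference-weight means — the stay-home offset alpha_home and
the money weight lambda — are calibrated so that the simulated no-show
rate hits two published anchor points: the status-quo rate with no
transfer, and the rate observed when transport-sized costs (~280,000 GNF)
are covered. With those fixed, the cash-transfer dose grid (0 to 1,000,000
GNF in 10,000 GNF steps) is swept and the dose-response curve summarized
per dose. Under the capped money term the curve must flatten exactly at
the maximum facility price, which ``detect_plateau`` recovers from the
curve alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .engine import (
    SUBGROUP_VARIABLES,
    DoseSummary,
    SimulationConfig,
    run_batch,
    run_once,
    uncertainty_interval,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ANCHORS",
    "DEFAULT_DOSE_GRID",
    "CalibrationResult",
    "DoseResponseCurve",
    "PlateauResult",
    "calibrate",
    "dose_sweep",
    "detect_plateau",
    "subgroup_analysis",
]

#: published validation anchors: (dose in GNF, target no-show rate)
DEFAULT_ANCHORS = ((0.0, 0.566), (280_000.0, 0.300))

#: 0 to 1,000,000 GNF in increments of 10,000 GNF (101 doses)
DEFAULT_DOSE_GRID = tuple(float(d) for d in range(0, 1_000_001, 10_000))


@dataclass(frozen=True)
class CalibrationResult:
    alpha_home_mean: float
    lam_mean: float
    weights: object  # fitted WeightModel
    anchors: tuple
    achieved: tuple  # no-show rate at each anchor dose under the fit
    converged: bool
    iterations: int
    tolerance: float

    def max_error(self) -> float:
        return max(
            abs(a - t) for (_, t), a in zip(self.anchors, self.achieved)
        )


def _mean_expected_rate(config: SimulationConfig, dose: float) -> float:
    """Expected no-show rate averaged over the config's seed block.

    Uses the stay-home *probability* averaged over agents rather than
    sampled choices, so the objective is a smooth deterministic function
    of the weight means under common random numbers.
    """
    cfg = config.at_dose(dose)
    return float(
        np.mean([run_once(cfg, s).expected_no_show_rate for s in cfg.run_seeds()])
    )


def calibrate(
    anchors=DEFAULT_ANCHORS,
    config: SimulationConfig | None = None,
    tolerance: float = 0.015,
    n_cal_runs: int = 5,
    cal_batch_size: int = 20_000,
    max_iter: int = 300,
    lam_sd_ratio: float = 0.2,
) -> CalibrationResult:
    """Fit (alpha_home mean, lambda mean) to the anchor no-show rates.

    Quality and distance weight means stay at their configured defaults;
    the two free means are found by a coarse grid scan followed by
    Nelder-Mead on the summed squared anchor error, evaluated on a fixed
    seed block (common random numbers). Raises if the best fit misses any
    anchor by more than ``tolerance`` (absolute rate), carrying the
    best-found parameters in the exception.
    """
    if config is None:
        config = SimulationConfig()
    anchors = tuple((float(d), float(r)) for d, r in anchors)
    if not anchors:
        raise ValueError("need at least one anchor")
    cal = replace(config, n_runs=n_cal_runs, batch_size=cal_batch_size)

    def rates(x):
        w = config.weights.recalibrated(x[0], x[1], lam_sd_ratio)
        c = replace(cal, weights=w)
        return [_mean_expected_rate(c, d) for d, _ in anchors]

    def objective(x):
        return sum((a - t) ** 2 for a, (_, t) in zip(rates(x), anchors))

    # coarse scan keeps Nelder-Mead out of flat far-field regions
    grid = [
        (a, l)
        for a in (-1.0, 0.0, 0.5, 1.0, 2.0)
        for l in (0.5, 1.0, 2.0, 4.0, 8.0)
    ]
    x0 = min(grid, key=lambda x: objective(x))
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-4, "fatol": 1e-10},
    )
    achieved = rates(res.x)
    errors = [abs(a - t) for a, (_, t) in zip(achieved, anchors)]
    converged = max(errors) <= tolerance
    result = CalibrationResult(
        alpha_home_mean=float(res.x[0]),
        lam_mean=float(res.x[1]),
        weights=config.weights.recalibrated(res.x[0], res.x[1], lam_sd_ratio),
        anchors=anchors,
        achieved=tuple(achieved),
        converged=converged,
        iterations=int(res.nit),
        tolerance=tolerance,
    )
    if not converged:
        err = RuntimeError(
            f"calibration missed an anchor by {max(errors):.4f} "
            f"(> tolerance {tolerance})"
        )
        err.result = result
        raise err
    return result


@dataclass(frozen=True)
class DoseResponseCurve:
    """Ordered per-dose summaries over a strictly increasing dose grid."""

    summaries: tuple  # of DoseSummary

    def __post_init__(self):
        doses = self.doses
        if len(doses) and np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing")

    @property
    def doses(self) -> np.ndarray:
        return np.array([s.dose for s in self.summaries])

    @property
    def means(self) -> np.ndarray:
        return np.array([s.mean_no_show for s in self.summaries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose_gnf": self.doses,
                "mean_no_show": self.means,
                "ui_low": [s.ui_low for s in self.summaries],
                "ui_high": [s.ui_high for s in self.summaries],
                "n_runs": [s.n_runs for s in self.summaries],
            }
        )


def dose_sweep(
    config: SimulationConfig,
    dose_grid=DEFAULT_DOSE_GRID,
    statistic: str = "expected",
) -> DoseResponseCurve:
    """Sweep the transfer dose grid with common random numbers.

    Every dose reuses the same master seed, hence the same per-run seed
    block, populations and weight draws; only the dose differs. With the
    default "expected" statistic the per-dose means are deterministic
    functions of the dose, so doses at or above the maximum facility price
    produce bit-identical summaries. Pass statistic="sampled" for the
    realized-choice version (one categorical draw per agent per dose).
    """
    summaries = tuple(
        run_batch(config.at_dose(d), statistic=statistic) for d in dose_grid
    )
    return DoseResponseCurve(summaries=summaries)


@dataclass(frozen=True)
class PlateauResult:
    dose: float | None
    rate: float | None

    @property
    def found(self) -> bool:
        return self.dose is not None


def detect_plateau(curve: DoseResponseCurve, epsilon: float = 1e-9) -> PlateauResult:
    """Smallest dose after which the curve stops changing.

    Returns the first grid dose d* such that every subsequent adjacent
    change in the mean no-show rate is below ``epsilon`` in absolute
    value, together with the mean rate at d*. A plateau must span at least
    two grid points; if even the final adjacent change is >= epsilon, no
    plateau exists and the sentinel (None, None) result is returned. The
    default epsilon is a numerical-zero tolerance suited to the
    deterministic "expected" sweep statistic; sampled curves need a larger
    epsilon reflecting their Monte-Carlo noise.
    """
    means = curve.means
    if len(means) < 2:
        return PlateauResult(None, None)
    diffs = np.abs(np.diff(means))
    # suffix running maximum of the adjacent changes
    suffix_max = np.flip(np.maximum.accumulate(np.flip(diffs)))
    quiet = np.nonzero(suffix_max < epsilon)[0]
    if quiet.size == 0:
        return PlateauResult(None, None)
    i = int(quiet[0])
    return PlateauResult(float(curve.doses[i]), float(means[i]))


def subgroup_analysis(
    runs,
    strata=("gender", "education", "age_band"),
    level: float = 0.95,
    reference: dict | None = None,
) -> pd.DataFrame:
    """Across-run subgroup no-show summary with pairwise significance.

    For each stratum variable the first configured level (or
    ``reference[variable]``) is the reference. Each level gets its mean
    no-show rate and across-run percentile UI; non-reference levels also
    get the run-by-run difference from the reference with its own UI. A
    difference is flagged significant when the two strata's 95%
    (``level``) UIs are disjoint — the convention matching how the
    simulation reports all of its uncertainty. Strata empty in every run
    are excluded with a warning.
    """
    runs = list(runs)
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    reference = reference or {}
    rows = []
    for var in strata:
        levels = SUBGROUP_VARIABLES[var]
        ref = reference.get(var, levels[0])
        per_run = {}
        for lvl in levels:
            r = np.array([run.subgroup_rates[(var, lvl)][0] for run in runs])
            n = sum(run.subgroup_rates[(var, lvl)][1] for run in runs)
            if n == 0:
                logger.warning("stratum %s=%r empty in all runs; excluded", var, lvl)
                continue
            per_run[lvl] = r
        if ref not in per_run:
            raise ValueError(f"reference level {ref!r} for {var!r} is empty")
        ref_lo, ref_hi = uncertainty_interval(per_run[ref], level)
        for lvl, r in per_run.items():
            lo, hi = uncertainty_interval(r, level)
            row = {
                "stratum": var,
                "level": lvl,
                "mean_no_show": float(np.nanmean(r)),
                "ui_low": lo,
                "ui_high": hi,
                "is_reference": lvl == ref,
            }
            if lvl != ref:
                d = r - per_run[ref]
                dlo, dhi = uncertainty_interval(d, level)
                row.update(
                    diff_vs_reference=float(d.mean()),
                    diff_ui_low=dlo,
                    diff_ui_high=dhi,
                    significant=bool(lo > ref_hi or hi < ref_lo),
                )
            else:
                row.update(
                    diff_vs_reference=0.0,
                    diff_ui_low=np.nan,
                    diff_ui_high=np.nan,
                    significant=False,
                )
            rows.append(row)
    return pd.DataFrame(rows)
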