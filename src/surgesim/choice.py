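"""Random-utility care-seeking choice model with a cash-transfer term.

Each agent i facing choice set J (the stay-home option plus every hospital
offering their procedure) assigns alternative j the deterministic utility

    V_ij = gamma_i * Q_j - delta_i * D_ij + lambda_i * c(Y_i, P_j, t)

where Q_j is the hospital quality score, D_ij the planar distance in km,
Y_i monthly income, P_j the procedure price, and t the cash-transfer size
(all monetary quantities in GNF). The stay-home alternative has Q = D =
P = 0 plus an agent-specific intercept alpha_home_i, the calibration lever
for the baseline care/home split. Terms shared by every alternative (the
overall intercept and demographic main effects) cancel in the logit ratio
and are omitted. The unobserved utility component is i.i.d. Gumbel, which
is realized implicitly by the multinomial-logit choice probabilities
rather than by adding explicit noise.

The default money term is the capped net-income share

    c(Y, P, t) = min(Y - P + t, Y) / Y,

equal to 1 whenever the transfer covers the price (t >= P, and always at
home where P = 0) and strictly increasing in t below that. The cap is what
flattens the dose-response curve once t reaches the most expensive
procedure on offer. A log-consumption variant is available as an
alternative functional form.

Preference weights (gamma, delta, lambda, alpha_home) are drawn per agent
from independent normal distributions, independent of demographics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MONEY_FORMS",
    "money_term",
    "WeightModel",
    "DrawnWeights",
    "distance",
    "distance_matrix",
    "utility_matrix",
    "choice_probabilities",
    "sample_choice",
]

MONEY_FORMS = ("capped_share", "log_consumption")


def money_term(income, price, transfer, form: str = "capped_share"):
    """Perceived-affordability term c(Y, P, t); vectorized, unitless.

    ``capped_share``: min(Y - P + t, Y) / Y. May be negative when the
    uncovered price exceeds income. ``log_consumption``: log of residual
    consumption (floored at 1 GNF) normalized by log income, sharing the
    same cap at 1.
    """
    Y = np.asarray(income, dtype=float)
    P = np.asarray(price, dtype=float)
    t = np.asarray(transfer, dtype=float)
    if np.any(Y <= 0):
        raise ValueError("income must be strictly positive")
    residual = np.minimum(Y - P + t, Y)
    if form == "capped_share":
        return residual / Y
    if form == "log_consumption":
        return np.log(np.maximum(residual, 1.0)) / np.log(np.maximum(Y, np.e))
    raise ValueError(f"unknown money-term form {form!r}")


@dataclass(frozen=True)
class WeightModel:
    """Means and SDs of the normal preference-weight distributions.

    Units: gamma per unit quality score, delta per km, lambda per unit of
    the (unitless) money term, alpha_home in utility units.
    """

    gamma: tuple[float, float] = (1.5, 0.3)
    delta: tuple[float, float] = (0.06, 0.015)
    lam: tuple[float, float] = (2.0, 0.4)
    alpha_home: tuple[float, float] = (0.5, 0.3)

    def __post_init__(self):
        for name in ("gamma", "delta", "lam", "alpha_home"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} SD must be non-negative")

    def draw(self, n: int, rng: np.random.Generator) -> "DrawnWeights":
        def _d(pair):
            mean, sd = pair
            return rng.normal(mean, sd, n)

        return DrawnWeights(
            gamma=_d(self.gamma),
            delta=_d(self.delta),
            lam=_d(self.lam),
            alpha_home=_d(self.alpha_home),
        )

    def recalibrated(self, alpha_home_mean: float, lam_mean: float,
                     lam_sd_ratio: float = 0.2) -> "WeightModel":
        """New model with fitted home-offset and money-weight means.

        The lambda SD scales with the fitted mean (fixed coefficient of
        variation); the alpha_home SD is kept as-is.
        """
        return WeightModel(
            gamma=self.gamma,
            delta=self.delta,
            lam=(float(lam_mean), abs(float(lam_mean)) * lam_sd_ratio),
            alpha_home=(float(alpha_home_mean), self.alpha_home[1]),
        )


@dataclass(frozen=True)
class DrawnWeights:
    """Per-agent preference-weight realizations (arrays of length n)."""

    gamma: np.ndarray
    delta: np.ndarray
    lam: np.ndarray
    alpha_home: np.ndarray

    @property
    def n(self) -> int:
        return len(self.gamma)


def distance(ax, ay, bx, by):
    """Euclidean distance on the plane, in km."""
    return np.hypot(np.asarray(ax) - bx, np.asarray(ay) - by)


def distance_matrix(agent_xy: np.ndarray, hospital_xy: np.ndarray) -> np.ndarray:
    """(n_agents, n_hospitals) planar distances in km."""
    d = agent_xy[:, None, :] - hospital_xy[None, :, :]
    return np.hypot(d[..., 0], d[..., 1])


def utility_matrix(
    income: np.ndarray,
    procedure_idx: np.ndarray,
    agent_xy: np.ndarray,
    weights: DrawnWeights,
    facilities,
    t: float,
    money_form: str = "capped_share",
) -> np.ndarray:
    """Deterministic utilities, shape (n_agents, 1 + n_hospitals).

    Column 0 is the stay-home alternative; hospitals not offering the
    agent's procedure get -inf (excluded from the choice set). ``t`` is
    the cash-transfer size in GNF.
    """
    income = np.asarray(income, dtype=float)
    n = income.shape[0]
    J = facilities.n_hospitals
    # (n, J) price faced by each agent at each hospital
    P = facilities.prices[:, :].T[procedure_idx]  # (n, J) via procedure row
    offered = facilities.offered.T[procedure_idx]  # (n, J) bool
    D = distance_matrix(agent_xy, facilities.xy)

    c_hosp = money_term(income[:, None], np.where(offered, P, 0.0), t, money_form)
    V = np.empty((n, 1 + J))
    V[:, 0] = weights.alpha_home + weights.lam * money_term(
        income, 0.0, t, money_form
    )
    V[:, 1:] = (
        weights.gamma[:, None] * facilities.quality[None, :]
        - weights.delta[:, None] * D
        + weights.lam[:, None] * c_hosp
    )
    V[:, 1:][~offered] = -np.inf
    return V


def choice_probabilities(V: np.ndarray) -> np.ndarray:
    """Multinomial-logit probabilities from deterministic utilities.

    Row-wise softmax with max-shift for numerical stability; -inf entries
    (unavailable alternatives) get probability exactly 0. Rows sum to 1 to
    within 1e-12.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    vmax = np.max(V, axis=1, keepdims=True)
    if not np.all(np.isfinite(vmax)):
        raise ValueError("each choice set needs at least one finite utility")
    e = np.exp(V - vmax)
    e[~np.isfinite(V)] = 0.0
    return e / e.sum(axis=1, keepdims=True)


def sample_choice(probabilities: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one alternative index per row by inverse-CDF sampling."""
    P = np.atleast_2d(np.asarray(probabilities, dtype=float))
    cdf = np.cumsum(P, axis=1)
    u = rng.random(P.shape[0])
    idx = (u[:, None] >= cdf).sum(axis=1)
    return np.minimum(idx, P.shape[1] - 1)
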