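"""Synthetic agent population for coastal Guinea.

Agents carry the demographic attributes that enter the care-seeking model:
location on a 60 km x 60 km plane centred on the Conakry region, gender,
education, wealth quintile, age band, monthly income in Guinean francs
(GNF), and the surgical procedure they need. Marginal distributions default
to a published demographic survey of the region; income follows a
"quantized" scheme in which a single right-skewed distribution is
partitioned into five bands aligned with the wealth quintiles, and each
agent draws income from their quintile's band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import truncnorm

__all__ = [
    "IncomeModel",
    "DensityModel",
    "PopulationSpec",
    "generate_population",
    "sample_income",
    "place_agents",
    "POPULATION_COLUMNS",
]

EDUCATION_LEVELS = ("none", "primary", "secondary")
AGE_BANDS = ("5-14", "15-21", "22-49", "50+")
WEALTH_QUINTILES = (1, 2, 3, 4, 5)
PROCEDURES = ("laparotomy", "cesarean", "goiter", "mandibulectomy")
#: age bands in which a woman can be assigned a cesarean section
CESAREAN_AGE_BANDS = ("15-21", "22-49")

#: column order of the exported population table
POPULATION_COLUMNS = (
    "x_km",
    "y_km",
    "gender",
    "education",
    "wealth_quintile",
    "age_band",
    "income_gnf",
    "procedure",
)

# Default marginals: exact counts out of 100,000 from the regional survey.
DEFAULT_GENDER_SPLIT = 0.5  # probability male
DEFAULT_EDUCATION_PROBS = (0.53422, 0.16642, 0.29936)
DEFAULT_WEALTH_PROBS = (0.20131, 0.19959, 0.19937, 0.20052, 0.19921)
DEFAULT_AGE_PROBS = (0.33261, 0.08264, 0.17547, 0.40928)

# Income anchors: median and interquartile range, GNF per month.
DEFAULT_INCOME_MEDIAN = 554_986.0
DEFAULT_INCOME_Q25 = 341_936.0
DEFAULT_INCOME_Q75 = 842_990.0

_Z75 = float(ndtri(0.75))  # 0.6744897...


@dataclass(frozen=True)
class IncomeModel:
    """Log-normal monthly income, quantized into five wealth bands.

    ``mu`` and ``sigma`` parameterise income as ``exp(N(mu, sigma^2))``.
    ``band_edges`` are the distribution's own 20/40/60/80% quantiles, so the
    five bands carry equal mass and wealth quintile q draws from band q
    (q=1 poorest). This makes wealth and income consistent by construction:
    pooling draws across equally weighted quintiles recovers the full
    distribution.
    """

    mu: float
    sigma: float

    @classmethod
    def fit(
        cls,
        median: float = DEFAULT_INCOME_MEDIAN,
        q25: float = DEFAULT_INCOME_Q25,
        q75: float = DEFAULT_INCOME_Q75,
    ) -> "IncomeModel":
        """Fit (mu, sigma) to a printed median and interquartile range.

        The median pins mu exactly; sigma is the least-squares fit to the
        two quartiles in log space, which reduces to matching the IQR
        ratio. A two-parameter family cannot match all three quantiles
        exactly; the residual quartile error is ~3% for the default
        anchors.
        """
        if not (0 < q25 < median < q75):
            raise ValueError("require 0 < q25 < median < q75")
        mu = float(np.log(median))
        sigma = float(np.log(q75 / q25) / (2.0 * _Z75))
        return cls(mu=mu, sigma=sigma)

    @property
    def band_edges(self) -> np.ndarray:
        """Interior band edges: the 20/40/60/80% quantiles (4 values)."""
        qs = np.array([0.2, 0.4, 0.6, 0.8])
        return np.exp(self.mu + self.sigma * ndtri(qs))

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))

    def quantile(self, p):
        """Inverse CDF of the unquantized distribution."""
        p = np.asarray(p, dtype=float)
        return np.exp(self.mu + self.sigma * ndtri(p))


def sample_income(
    wealth_quintile, income_model: IncomeModel, rng: np.random.Generator
) -> np.ndarray:
    """Draw incomes for agents given their wealth quintiles.

    Each draw comes from the income distribution restricted to the
    quintile's band (quintile 1 = lowest). Implemented by inverse-CDF
    sampling with the uniform variate confined to ((q-1)/5, q/5), which is
    exact because the band edges are the distribution's own quantiles.
    """
    q = np.asarray(wealth_quintile)
    if np.any((q < 1) | (q > 5)):
        raise ValueError("wealth quintile must be in 1..5")
    u = rng.uniform((q - 1) / 5.0, q / 5.0)
    # keep u strictly inside (0, 1) so incomes stay finite and positive
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return income_model.quantile(u)


@dataclass(frozen=True)
class DensityModel:
    """Two-component spatial mixture on a square plane.

    A dense cluster (independent per-axis truncated normals) stands in for
    the capital's coastal-peninsula conurbation; the remainder of the
    population is spread uniformly over the square. Distances in km.
    """

    side: float = 60.0
    cluster_center: tuple[float, float] = (10.0, 12.0)
    cluster_sigma: float = 6.0
    cluster_weight: float = 0.65

    def __post_init__(self):
        if not (0.0 <= self.cluster_weight <= 1.0):
            raise ValueError("cluster_weight must be in [0, 1]")
        cx, cy = self.cluster_center
        if not (0 <= cx <= self.side and 0 <= cy <= self.side):
            raise ValueError("cluster center must lie inside the square")

    def _axis(self, center: float):
        a = (0.0 - center) / self.cluster_sigma
        b = (self.side - center) / self.cluster_sigma
        return truncnorm(a, b, loc=center, scale=self.cluster_sigma)

    def marginal_cdf_x(self, x) -> np.ndarray:
        """Analytic CDF of the x-coordinate marginal of the mixture."""
        x = np.asarray(x, dtype=float)
        uniform = np.clip(x / self.side, 0.0, 1.0)
        cluster = self._axis(self.cluster_center[0]).cdf(x)
        return self.cluster_weight * cluster + (1 - self.cluster_weight) * uniform


def place_agents(
    n: int, density_model: DensityModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n (x, y) positions in km from the density mixture."""
    if n <= 0:
        raise ValueError("n must be positive")
    m = density_model
    in_cluster = rng.random(n) < m.cluster_weight
    x = rng.uniform(0.0, m.side, n)
    y = rng.uniform(0.0, m.side, n)
    k = int(in_cluster.sum())
    if k and m.cluster_sigma > 0:
        ax = m._axis(m.cluster_center[0])
        ay = m._axis(m.cluster_center[1])
        # inverse-CDF truncated-normal draws keep everything in the square
        x[in_cluster] = ax.ppf(rng.random(k))
        y[in_cluster] = ay.ppf(rng.random(k))
    elif k:
        x[in_cluster] = m.cluster_center[0]
        y[in_cluster] = m.cluster_center[1]
    return x, y


def _check_probs(name: str, probs, n: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.shape != (n,):
        raise ValueError(f"{name} must have {n} entries")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must be non-negative and sum to 1")
    return p


@dataclass(frozen=True)
class PopulationSpec:
    """Everything needed to generate one synthetic population."""

    n_agents: int = 100_000
    gender_split: float = DEFAULT_GENDER_SPLIT  # probability male
    education_probs: tuple = DEFAULT_EDUCATION_PROBS
    wealth_probs: tuple = DEFAULT_WEALTH_PROBS
    age_probs: tuple = DEFAULT_AGE_PROBS
    income_model: IncomeModel = field(default_factory=IncomeModel.fit)
    density_model: DensityModel = field(default_factory=DensityModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_agents <= 0:
            raise ValueError("n_agents must be positive")
        if not (0.0 <= self.gender_split <= 1.0):
            raise ValueError("gender_split must be a probability")
        _check_probs("education_probs", self.education_probs, 3)
        _check_probs("wealth_probs", self.wealth_probs, 5)
        _check_probs("age_probs", self.age_probs, 4)

    def with_seed(self, seed: int) -> "PopulationSpec":
        return replace(self, seed=int(seed))


def _categorical(rng, levels, probs, n):
    idx = rng.choice(len(levels), size=n, p=probs)
    return np.asarray(levels)[idx], idx


def generate_population(
    spec: PopulationSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate a synthetic population as one DataFrame row per agent.

    Attributes are sampled independently from the spec marginals except for
    income (conditional on wealth quintile) and procedure (a cesarean is
    only kept for women in the fertile age bands; ineligible draws are
    reassigned uniformly to the other three procedures). Deterministic
    given ``spec.seed`` unless an explicit ``rng`` is supplied.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_agents

    x, y = place_agents(n, spec.density_model, rng)
    male = rng.random(n) < spec.gender_split
    gender = np.where(male, "male", "female")
    education, _ = _categorical(
        rng, EDUCATION_LEVELS, _check_probs("education_probs", spec.education_probs, 3), n
    )
    wealth = rng.choice(WEALTH_QUINTILES, size=n, p=np.asarray(spec.wealth_probs))
    age_band, _ = _categorical(
        rng, AGE_BANDS, _check_probs("age_probs", spec.age_probs, 4), n
    )
    income = sample_income(wealth, spec.income_model, rng)

    procedure, _ = _categorical(rng, PROCEDURES, np.full(4, 0.25), n)
    eligible = (~male) & np.isin(age_band, CESAREAN_AGE_BANDS)
    reassign = (procedure == "cesarean") & ~eligible
    if reassign.any():
        others = [p for p in PROCEDURES if p != "cesarean"]
        procedure[reassign] = rng.choice(others, size=int(reassign.sum()))

    return pd.DataFrame(
        {
            "x_km": x,
            "y_km": y,
            "gender": gender,
            "education": education,
            "wealth_quintile": wealth,
            "age_band": age_band,
            "income_gnf": income,
            "procedure": procedure,
        },
        columns=list(POPULATION_COLUMNS),
    )
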