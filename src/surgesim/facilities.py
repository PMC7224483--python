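"""Hospital survey table: parsing, imputation, quality scores, prices.

The packaged survey covers the nine coastal hospitals considered surgically
capable, with workforce counts, operating-room (OR) counts, last-month case
volumes, and prices in GNF for four index procedures (laparotomy, cesarean
section, goiter removal, mandibulectomy). Two sentinels appear in the
survey: "—" marks a value the hospital could not report (unknown, to be
imputed) and "NA" marks a procedure the hospital does not offer at all
(never imputed; the hospital is simply absent from that procedure's choice
sets). A price of 0 is a real price — several hospitals offer cesarean
sections for free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .population import PROCEDURES

logger = logging.getLogger(__name__)

__all__ = [
    "QUALITY_DOMAINS",
    "PRICE_COLUMNS",
    "load_hospitals",
    "load_default_coords",
    "impute_missing",
    "quality_scores",
    "cost_summary",
    "procedure_price",
    "price_matrix",
    "place_hospitals",
    "FacilityModel",
    "build_facility_model",
]

# CSV header -> internal column name
_HEADER_MAP = {
    "Hospital ID": "hospital_id",
    "MDs": "mds",
    "Surgeons": "surgeons",
    "Surgical officers": "surgical_officers",
    "Anesthesia MDs": "anesthesia_mds",
    "Anesthetic officers": "anesthetic_officers",
    "Nurses": "nurses",
    "ORs": "ors",
    "Total cases last month": "cases_total",
    "Total general surgery": "cases_general_surgery",
    "Total OB": "cases_obstetric",
    "Total ENT / head and neck": "cases_ent_head_neck",
    "Cost: laparotomy": "price_laparotomy",
    "Cost: CS": "price_cesarean",
    "Cost: Goitre": "price_goiter",
    "Cost: mandibulectomy": "price_mandibulectomy",
}

#: the staffing, OR and volume columns that enter the quality score
#: (prices are excluded: quality and price enter the utility separately)
QUALITY_DOMAINS = (
    "mds",
    "surgeons",
    "surgical_officers",
    "anesthesia_mds",
    "anesthetic_officers",
    "nurses",
    "ors",
    "cases_total",
    "cases_general_surgery",
    "cases_obstetric",
    "cases_ent_head_neck",
)

PRICE_COLUMNS = {p: f"price_{p}" for p in PROCEDURES}

_UNKNOWN = {"—", "-", "--", ""}
_NOT_OFFERED = "NA"


def _data_path(name: str):
    return resources.files("surgesim.data").joinpath(name)


def load_hospitals(table_file=None) -> pd.DataFrame:
    """Parse the hospital survey CSV into a nine-row DataFrame.

    Numeric columns hold floats with NaN for unknown ("—") entries. Each
    price column ``price_<proc>`` is paired with a boolean
    ``offers_<proc>`` column; "NA" cells yield ``offers_<proc> = False``
    and a NaN price that is *never* imputed.
    """
    if table_file is None:
        table_file = _data_path("hospitals.csv")
    raw = pd.read_csv(table_file, dtype=str, keep_default_na=False)
    missing = [h for h in _HEADER_MAP if h not in raw.columns]
    if missing:
        raise ValueError(f"hospital table is missing columns: {missing}")
    raw = raw.rename(columns=_HEADER_MAP)

    out = pd.DataFrame(index=raw["hospital_id"].str.strip())
    out.index.name = "hospital_id"
    for col in list(QUALITY_DOMAINS) + list(PRICE_COLUMNS.values()):
        is_price = col.startswith("price_")
        values, offered = [], []
        for row_label, cell in zip(out.index, raw[col]):
            cell = cell.strip()
            if cell in _UNKNOWN:
                values.append(np.nan)
                offered.append(True)
            elif cell == _NOT_OFFERED:
                if not is_price:
                    raise ValueError(
                        f"row {row_label!r}, column {col!r}: 'NA' is only "
                        "valid in price columns"
                    )
                values.append(np.nan)
                offered.append(False)
            else:
                try:
                    v = float(cell.replace(",", ""))
                except ValueError as err:
                    raise ValueError(
                        f"row {row_label!r}, column {col!r}: "
                        f"cannot parse {cell!r}"
                    ) from err
                if v < 0:
                    raise ValueError(
                        f"row {row_label!r}, column {col!r}: negative value"
                    )
                values.append(v)
                offered.append(True)
        out[col] = values
        if is_price:
            out[col.replace("price_", "offers_")] = offered
    return out


def load_default_coords() -> pd.DataFrame:
    """Fixed synthetic hospital coordinates shipped with the package.

    The survey does not publish facility GPS positions; these defaults
    place a majority of hospitals near the dense coastal-peninsula cluster
    so that the spatial gradient of access is preserved.
    """
    df = pd.read_csv(_data_path("hospital_coords.csv"))
    df = df.rename(columns={"Hospital ID": "hospital_id"})
    return df.set_index("hospital_id")


def impute_missing(records: pd.DataFrame) -> pd.DataFrame:
    """Replace every unknown value with its column mean over known values.

    Known values are left untouched, so each column's mean over the
    originally-known entries is preserved. Prices of procedures a hospital
    does not offer are structural, not missing: they stay NaN and are
    excluded from the column mean.
    """
    out = records.copy()
    for col in QUALITY_DOMAINS:
        known = out[col].dropna()
        if known.empty:
            raise ValueError(f"column {col!r} has no known values to average")
        out[col] = out[col].fillna(known.mean())
    for proc, col in PRICE_COLUMNS.items():
        offered = out[f"offers_{proc}"]
        known = out.loc[offered, col].dropna()
        if known.empty:
            raise ValueError(f"column {col!r} has no known values to average")
        fill = known.mean()
        mask = offered & out[col].isna()
        out.loc[mask, col] = fill
    return out


def quality_scores(records: pd.DataFrame, domains=QUALITY_DOMAINS) -> pd.Series:
    """Composite quality score Q in [0, 1] per hospital.

    Each domain is standardized against the best-performing hospital
    (x / column max) and Q is the unweighted mean of the per-domain scores,
    so the top hospital in every domain would score exactly 1. Expects an
    imputed table. Domains whose maximum is 0 carry no signal and are
    dropped with a warning.
    """
    used = []
    for col in domains:
        if records[col].isna().any():
            raise ValueError(f"column {col!r} contains unknowns; impute first")
        m = records[col].max()
        if m <= 0:
            logger.warning("quality domain %r has max 0; dropped", col)
            continue
        used.append(records[col] / m)
    if not used:
        raise ValueError("no usable quality domains")
    q = pd.concat(used, axis=1).mean(axis=1)
    q.name = "Q"
    return q


def cost_summary(records: pd.DataFrame) -> dict:
    """Summary statistics of the *known* procedure prices (no imputation).

    Returns the pooled mean over all known price entries, the cesarean-only
    mean, and mean/median/min/max over the known non-cesarean entries.
    Printed-style integers follow the survey report's conventions: the
    cesarean mean is truncated toward zero, other means rounded to the
    nearest GNF.
    """
    known = {
        proc: records.loc[records[f"offers_{proc}"], col].dropna()
        for proc, col in PRICE_COLUMNS.items()
    }
    pooled = pd.concat(known.values())
    cs = known["cesarean"]
    non_cs = pd.concat(v for k, v in known.items() if k != "cesarean")
    return {
        "n_known": int(pooled.size),
        "pooled_mean": float(pooled.mean()),
        "cesarean_n": int(cs.size),
        "cesarean_mean": math.trunc(cs.mean()),
        "non_cesarean_n": int(non_cs.size),
        "non_cesarean_mean": round(float(non_cs.mean())),
        "non_cesarean_median": float(non_cs.median()),
        "non_cesarean_min": float(non_cs.min()),
        "non_cesarean_max": float(non_cs.max()),
    }


def procedure_price(records: pd.DataFrame, hospital_id: str, procedure: str):
    """Effective price of one procedure at one hospital, or None.

    Known prices are returned as-is (0 is a valid, free price); unknown
    prices fall back to the column mean over known offered entries; a
    procedure the hospital does not offer returns None.
    """
    col = PRICE_COLUMNS[procedure]
    row = records.loc[hospital_id]
    if not row[f"offers_{procedure}"]:
        return None
    if not np.isnan(row[col]):
        return float(row[col])
    offered = records[f"offers_{procedure}"]
    return float(records.loc[offered, col].dropna().mean())


def price_matrix(records: pd.DataFrame):
    """(prices, offered) DataFrames of shape hospitals x procedures.

    Unknown prices are imputed with the procedure-column mean; entries for
    procedures not offered hold NaN price and False in ``offered``.
    """
    prices = pd.DataFrame(index=records.index, columns=list(PROCEDURES), dtype=float)
    offered = pd.DataFrame(index=records.index, columns=list(PROCEDURES), dtype=bool)
    for proc in PROCEDURES:
        for hid in records.index:
            p = procedure_price(records, hid, proc)
            prices.loc[hid, proc] = np.nan if p is None else p
            offered.loc[hid, proc] = p is not None
    return prices, offered


def place_hospitals(
    records: pd.DataFrame,
    coords: pd.DataFrame | None = None,
    density_model=None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach x_km/y_km coordinates to the hospital table.

    By default the packaged fixed coordinates are used so that every run is
    reproducible. If ``rng`` is given, positions are instead drawn from the
    population density model (hospitals concentrate where people do).
    """
    out = records.copy()
    if rng is not None:
        from .population import DensityModel, place_agents

        model = density_model or DensityModel()
        x, y = place_agents(len(out), model, rng)
        out["x_km"], out["y_km"] = x, y
        return out
    if coords is None:
        coords = load_default_coords()
    out["x_km"] = coords["x_km"].reindex(out.index)
    out["y_km"] = coords["y_km"].reindex(out.index)
    if out[["x_km", "y_km"]].isna().any().any():
        raise ValueError("missing coordinates for some hospitals")
    return out


@dataclass(frozen=True)
class FacilityModel:
    """Array view of the prepared facility table, ready for simulation."""

    hospital_ids: tuple  # length J
    xy: np.ndarray  # (J, 2) km
    quality: np.ndarray  # (J,) in [0, 1]
    prices: np.ndarray  # (J, 4) GNF, NaN where not offered
    offered: np.ndarray  # (J, 4) bool
    procedures: tuple = PROCEDURES

    @property
    def n_hospitals(self) -> int:
        return len(self.hospital_ids)

    @property
    def max_price(self) -> float:
        return float(np.nanmax(self.prices))


def build_facility_model(
    records: pd.DataFrame | None = None,
    coords: pd.DataFrame | None = None,
) -> FacilityModel:
    """Load, impute, score and place hospitals in one step."""
    if records is None:
        records = load_hospitals()
    placed = place_hospitals(records, coords=coords)
    imputed = impute_missing(placed)
    q = quality_scores(imputed)
    prices, offered = price_matrix(records)
    return FacilityModel(
        hospital_ids=tuple(records.index),
        xy=placed[["x_km", "y_km"]].to_numpy(float),
        quality=q.to_numpy(float),
        prices=prices.to_numpy(float),
        offered=offered.to_numpy(bool),
    )
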