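"""Synthetic district-level and child-level survey data.

The generator emulates the statistical structure of the study inputs so the
whole pipeline is testable without any real survey download:

* **District table** — one row per district with stunting and severe-stunting
  prevalence, open-defecation (OD) prevalence, infant mortality rate (IMR),
  urbanization, literacy, expenditure, calorie and household-size controls,
  and a population weight.  Stunting prevalence follows a log-linear
  structural model, ``intercept + beta_od * ln(od_pct) + controls + noise``,
  and the OD percentage is drawn as ``100 * Beta(a, b)`` with a left-skewed
  shape (first shape parameter larger), matching the strong negative skew of
  observed district OD rates.  IMR is generated as a noisy increasing
  function of ln(OD), so it can act as a partial mediator of the OD effect
  when given a nonzero coefficient in ``control_effects``.

* **Child table** — one row per child with a primary-sampling-unit (PSU)
  label, a household OD indicator and a height-for-age z-score (HAZ).  Each
  PSU has an OD rate drawn from a Beta distribution; children's OD status is
  Bernoulli in that rate and HAZ is Gaussian around a mean that declines
  linearly in the PSU OD rate.

Identical seeds produce byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regression_core import ParameterError

logger = logging.getLogger("ecostunt")

__all__ = [
    "DistrictGenParams",
    "DistrictRecord",
    "ChildGenParams",
    "ChildRecord",
    "gen_districts",
    "gen_children",
    "districts_to_frame",
    "children_to_frame",
    "write_districts_csv",
    "write_children_csv",
    "read_districts_csv",
    "read_children_csv",
]

DISTRICT_COLUMNS = [
    "district_id",
    "stunting_pct",
    "severe_stunting_pct",
    "od_pct",
    "imr",
    "urban_pct",
    "literacy_pct",
    "literacy_female_pct",
    "mpce",
    "calories",
    "cereal_calories",
    "household_size",
    "population",
]
CHILD_COLUMNS = ["psu_id", "od_household", "haz"]

#: Controls the district generator knows how to attach a structural effect to.
SUPPORTED_CONTROLS = (
    "urban_pct",
    "literacy_pct",
    "literacy_female_pct",
    "mpce",
    "calories",
    "cereal_calories",
    "household_size",
    "imr",
)


@dataclass(frozen=True)
class DistrictGenParams:
    """Parameters of the district-level generator.

    ``beta_od`` is the structural effect of ln(OD %) on stunting prevalence,
    in percentage points per log-unit.  ``control_effects`` maps a control
    column name to its (linear, raw-scale) coefficient in the structural
    model; it may include ``imr`` to make IMR a partial mediator of the OD
    effect.  ``od_beta_shape`` are the Beta shape parameters of the OD
    distribution on the [0, 1] scale before multiplying by 100; the default
    (2.5, 0.8) gives a left-skewed distribution (skewness near -1) with mean
    near 76% and an occasional low-sanitation-coverage district.
    """

    n_districts: int = 112
    beta_od: float = 7.0
    control_effects: dict[str, float] = field(
        default_factory=lambda: {"literacy_pct": -0.15, "household_size": 1.0}
    )
    noise_sd: float = 4.0
    od_beta_shape: tuple[float, float] = (2.5, 0.8)
    seed: int = 0
    intercept: float = 30.0
    severe_offset: float = -24.0
    n_missing_imr: int = 2
    imr_od_slope: float = 15.0
    imr_noise_sd: float = 10.0

    def validate(self) -> None:
        if self.n_districts < 3:
            raise ParameterError("n_districts must be >= 3")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if min(self.od_beta_shape) <= 0:
            raise ParameterError("od_beta_shape parameters must be > 0")
        if not 0 <= self.n_missing_imr < self.n_districts:
            raise ParameterError("n_missing_imr must be in [0, n_districts)")
        unknown = set(self.control_effects) - set(SUPPORTED_CONTROLS)
        if unknown:
            raise ParameterError(f"unknown control columns in control_effects: {sorted(unknown)}")


@dataclass(frozen=True)
class DistrictRecord:
    """One district's outcome, exposure, controls and population weight."""

    district_id: str
    stunting_pct: float
    severe_stunting_pct: float
    od_pct: float
    imr: float  # NaN when missing
    urban_pct: float
    literacy_pct: float
    literacy_female_pct: float
    mpce: float
    calories: float
    cereal_calories: float
    household_size: float
    population: float


@dataclass(frozen=True)
class ChildGenParams:
    """Parameters of the child-level (PSU-clustered) generator.

    ``delta_haz`` is the change in mean HAZ per unit PSU OD fraction
    (expected negative); ``intercept_haz`` is the mean HAZ at OD = 0.
    PSU OD rates are Beta with mean ``od_mean`` and concentration
    ``od_conc`` (shapes ``od_mean*od_conc`` and ``(1-od_mean)*od_conc``).
    """

    n_psu: int = 2000
    children_per_psu: int | tuple[int, int] = 20
    delta_haz: float = -2.0
    haz_sd: float = 1.2
    intercept_haz: float = -0.8
    od_mean: float = 0.55
    od_conc: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_psu < 2:
            raise ParameterError("n_psu must be >= 2")
        if self.haz_sd <= 0:
            raise ParameterError("haz_sd must be > 0")
        if not 0 < self.od_mean < 1:
            raise ParameterError("od_mean must be in (0, 1)")
        if self.od_conc <= 0:
            raise ParameterError("od_conc must be > 0")
        cpp = self.children_per_psu
        if isinstance(cpp, tuple):
            if cpp[0] < 1 or cpp[1] < cpp[0]:
                raise ParameterError("children_per_psu range must satisfy 1 <= lo <= hi")
        elif cpp < 1:
            raise ParameterError("children_per_psu must be >= 1")


@dataclass(frozen=True)
class ChildRecord:
    """One child: PSU label, household OD indicator, height-for-age z-score."""

    psu_id: str
    od_household: int
    haz: float


def _clip_logged(values: np.ndarray, lo: float, hi: float, name: str) -> np.ndarray:
    out = np.clip(values, lo, hi)
    n_clipped = int((values != out).sum())
    if n_clipped:
        logger.info("clipped %d %s values into [%s, %s]", n_clipped, name, lo, hi)
    return out


def gen_districts(params: DistrictGenParams) -> list[DistrictRecord]:
    """Generate a district table with a known log-linear OD -> stunting effect.

    Controls are drawn independently of OD (IMR excepted: it is a noisy
    function of ln OD so it can mediate).  Stunting and severe-stunting
    percentages are clipped to [0, 100] after noise, with severe additionally
    capped at the stunting value; clip counts are logged.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_districts
    a, b = params.od_beta_shape

    od_pct = _clip_logged(100.0 * rng.beta(a, b, size=n), 0.1, 99.9, "od_pct")
    ln_od = np.log(od_pct)

    urban_pct = _clip_logged(100.0 * rng.beta(1.5, 6.5, size=n), 0.0, 100.0, "urban_pct")
    literacy_pct = _clip_logged(rng.normal(66.4, 8.0, size=n), 20.0, 100.0, "literacy_pct")
    literacy_female_pct = _clip_logged(
        literacy_pct - np.abs(rng.normal(10.6, 2.5, size=n)), 5.0, 100.0, "literacy_female_pct"
    )
    mpce = np.exp(rng.normal(np.log(540.0), 0.30, size=n))
    calories = np.clip(rng.normal(2056.0, 180.0, size=n), 1200.0, None)
    cereal_share = np.clip(rng.normal(0.686, 0.06, size=n), 0.40, 0.95)
    cereal_calories = calories * cereal_share
    household_size = np.clip(rng.normal(6.3, 0.9, size=n), 2.0, None)
    imr = np.clip(
        6.6 + params.imr_od_slope * ln_od + rng.normal(0.0, params.imr_noise_sd, size=n),
        5.0,
        None,
    )
    population = np.exp(rng.normal(np.log(1.8e6), 0.5, size=n))

    controls = {
        "urban_pct": urban_pct,
        "literacy_pct": literacy_pct,
        "literacy_female_pct": literacy_female_pct,
        "mpce": mpce,
        "calories": calories,
        "cereal_calories": cereal_calories,
        "household_size": household_size,
        "imr": imr,
    }
    control_sum = np.zeros(n)
    for name, coef in params.control_effects.items():
        control_sum = control_sum + coef * controls[name]

    structural = params.intercept + params.beta_od * ln_od + control_sum
    stunting = structural + rng.normal(0.0, params.noise_sd, size=n)
    severe = structural + params.severe_offset + rng.normal(0.0, params.noise_sd, size=n)

    stunting = _clip_logged(stunting, 0.0, 100.0, "stunting_pct")
    severe = _clip_logged(severe, 0.0, 100.0, "severe_stunting_pct")
    severe = np.minimum(severe, stunting)

    imr_out = imr.copy()
    if params.n_missing_imr:
        miss = rng.choice(n, size=params.n_missing_imr, replace=False)
        imr_out[miss] = np.nan

    width = len(str(n))
    return [
        DistrictRecord(
            district_id=f"D{i + 1:0{width}d}",
            stunting_pct=float(stunting[i]),
            severe_stunting_pct=float(severe[i]),
            od_pct=float(od_pct[i]),
            imr=float(imr_out[i]),
            urban_pct=float(urban_pct[i]),
            literacy_pct=float(literacy_pct[i]),
            literacy_female_pct=float(literacy_female_pct[i]),
            mpce=float(mpce[i]),
            calories=float(calories[i]),
            cereal_calories=float(cereal_calories[i]),
            household_size=float(household_size[i]),
            population=float(population[i]),
        )
        for i in range(n)
    ]


def gen_children(params: ChildGenParams) -> list[ChildRecord]:
    """Generate PSU-clustered child records.

    Each PSU draws an OD rate from the Beta distribution; each child's
    household OD indicator is Bernoulli in that rate, and HAZ is Gaussian
    with mean ``intercept_haz + delta_haz * rate`` and SD ``haz_sd``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    a = params.od_mean * params.od_conc
    b = (1.0 - params.od_mean) * params.od_conc
    rates = rng.beta(a, b, size=params.n_psu)

    cpp = params.children_per_psu
    if isinstance(cpp, tuple):
        sizes = rng.integers(cpp[0], cpp[1] + 1, size=params.n_psu)
    else:
        sizes = np.full(params.n_psu, cpp, dtype=int)

    width = len(str(params.n_psu))
    records: list[ChildRecord] = []
    for p in range(params.n_psu):
        m = int(sizes[p])
        od = rng.random(m) < rates[p]
        haz = rng.normal(params.intercept_haz + params.delta_haz * rates[p], params.haz_sd, size=m)
        psu = f"P{p + 1:0{width}d}"
        records.extend(
            ChildRecord(psu_id=psu, od_household=int(od[j]), haz=float(haz[j])) for j in range(m)
        )
    return records


def districts_to_frame(records: list[DistrictRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=DISTRICT_COLUMNS)


def children_to_frame(records: list[ChildRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=CHILD_COLUMNS)


def write_districts_csv(records: list[DistrictRecord], path) -> None:
    districts_to_frame(records).to_csv(path, index=False, encoding="utf-8")


def write_children_csv(records: list[ChildRecord], path) -> None:
    children_to_frame(records).to_csv(path, index=False, encoding="utf-8")


def read_districts_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DISTRICT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"district CSV missing columns: {sorted(missing)}")
    return df


def read_children_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CHILD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"child CSV missing columns: {sorted(missing)}")
    return df
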