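"""Compensating income variation (CIV): shadow pricing of affect loss.

Given fitted coefficients for alcohol consumption (``beta_AC``, affect per
gram/day) and log household income (``beta_lnY``, affect per log-pound),
the proportional increase in household income that holds affect constant
after a one gram/day increase in intake is

    tau = exp(-beta_AC / beta_lnY) - 1.

Uncertainty propagates by the delta method: with gradient
``g = [-exp(-r)/beta_lnY, exp(-r) * beta_AC / beta_lnY**2]`` (r = beta_AC /
beta_lnY), ``Var(tau) = g' Cov(beta) g``. The fraction is monetized against
a table of mean pre-tax income and mean tax by age band,
``CIV_pounds = tau * sum_i p_i * (income_i - tax_i)``, and estimates from
the parallel depression/neuroticism and cross-sectional/longitudinal
analyses are pooled by an equal-weight mean with a Student-t interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoefPair",
    "CIVResult",
    "IncomeTaxTable",
    "PooledCIV",
    "civ_fraction",
    "civ_gradient",
    "civ_se",
    "civ_result",
    "monetize_civ",
    "pool_civ",
    "convert_consumption_equivalents",
    "DEFAULT_INCOME_TAX_TABLE",
]

_Z975 = 1.959963984540054


class CovarianceError(ValueError):
    pass


@dataclass(frozen=True)
class CoefPair:
    """(beta_AC, beta_lnY) with their joint 2x2 covariance."""

    beta_AC: float
    beta_lnY: float
    cov: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    def __post_init__(self):
        c = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "cov", c)
        if c.shape != (2, 2):
            raise CovarianceError("cov must be 2x2")
        if not np.allclose(c, c.T, atol=1e-10):
            raise CovarianceError("cov must be symmetric")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise CovarianceError("cov must be positive semi-definite")


@dataclass(frozen=True)
class CIVResult:
    tau: float
    se_tau: float
    ci95: tuple[float, float]
    civ_pounds: float
    se_pounds: float
    source: str = ""

    @property
    def z(self) -> float:
        return self.tau / self.se_tau if self.se_tau > 0 else math.inf


@dataclass(frozen=True)
class PooledCIV:
    components: tuple[float, ...]
    mean: float
    ci95: tuple[float, float]
    method: str = "equal-weight mean, Student-t interval (df = n - 1)"


def civ_fraction(pair: CoefPair) -> float:
    """tau = exp(-beta_AC / beta_lnY) - 1, a fraction of household income."""
    if pair.beta_lnY == 0:
        raise ZeroDivisionError("beta_lnY = 0: compensating variation undefined")
    if pair.beta_lnY > 0:
        import warnings

        warnings.warn(
            "beta_lnY > 0 (income worsening affect): compensating-variation "
            "interpretation is inverted",
            stacklevel=2,
        )
    return float(math.exp(-pair.beta_AC / pair.beta_lnY) - 1.0)


def civ_gradient(pair: CoefPair) -> np.ndarray:
    """Gradient of the transformation w.r.t. (beta_AC, beta_lnY)."""
    if pair.beta_lnY == 0:
        raise ZeroDivisionError("beta_lnY = 0: gradient undefined")
    e = math.exp(-pair.beta_AC / pair.beta_lnY)
    return np.array([-e / pair.beta_lnY, e * pair.beta_AC / pair.beta_lnY**2])


def civ_se(pair: CoefPair) -> float:
    """Delta-method standard error of tau."""
    g = civ_gradient(pair)
    var = float(g @ pair.cov @ g)
    return math.sqrt(max(var, 0.0))


@dataclass(frozen=True)
class IncomeTaxTable:
    """Age-band weights with mean gross income and mean tax (pounds).

    The default shipped table is a synthetic placeholder with plausible
    magnitudes (weighted net income near the cohort's ~30,500 pound mean);
    it is NOT an official statistics release — supply the real figures via
    configuration for substantive use.
    """

    age_bands: tuple[str, ...]
    proportions: tuple[float, ...]
    incomes: tuple[float, ...]
    taxes: tuple[float, ...]

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        inc = np.asarray(self.incomes, dtype=float)
        tax = np.asarray(self.taxes, dtype=float)
        if not (len(self.age_bands) == p.size == inc.size == tax.size):
            raise ValueError("table columns must have equal length")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {p.sum():.12f}")
        if np.any(tax < 0) or np.any(inc < tax):
            raise ValueError("require income_i >= tax_i >= 0")

    @property
    def weighted_net_income(self) -> float:
        p = np.asarray(self.proportions)
        return float(p @ (np.asarray(self.incomes) - np.asarray(self.taxes)))

    @classmethod
    def from_csv(cls, path) -> "IncomeTaxTable":
        df = pd.read_csv(path)
        return cls(
            age_bands=tuple(df["age_band"].astype(str)),
            proportions=tuple(df["p"].astype(float)),
            incomes=tuple(df["income"].astype(float)),
            taxes=tuple(df["tax"].astype(float)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_band": self.age_bands,
                "p": self.proportions,
                "income": self.incomes,
                "tax": self.taxes,
            }
        )


#: Synthetic placeholder (see IncomeTaxTable docstring): eight five-year
#: age bands from 35-39 to 70-74.
DEFAULT_INCOME_TAX_TABLE = IncomeTaxTable(
    age_bands=("35-39", "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74"),
    proportions=(0.06, 0.12, 0.16, 0.18, 0.18, 0.14, 0.10, 0.06),
    incomes=(36_000.0, 38_500.0, 39_500.0, 38_000.0, 36_500.0, 33_500.0, 28_500.0, 25_500.0),
    taxes=(6_200.0, 6_900.0, 7_200.0, 6_800.0, 6_400.0, 5_600.0, 4_300.0, 3_600.0),
)


def monetize_civ(tau: float, table: IncomeTaxTable) -> float:
    """tau times the weighted mean net (post-tax) income across age bands."""
    return tau * table.weighted_net_income


def civ_result(pair: CoefPair, table: IncomeTaxTable, source: str = "") -> CIVResult:
    """Full CIV: fraction, delta-method SE, normal-theory CI, pounds."""
    tau = civ_fraction(pair)
    se = civ_se(pair)
    net = table.weighted_net_income
    return CIVResult(
        tau=tau,
        se_tau=se,
        ci95=(tau - _Z975 * se, tau + _Z975 * se),
        civ_pounds=tau * net,
        se_pounds=se * net,
        source=source,
    )


def pool_civ(values: Sequence[float]) -> PooledCIV:
    """Equal-weight mean of component CIV values with a t(n-1) interval."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("pooling requires at least two component values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = float(stats.t.ppf(0.975, v.size - 1)) * sd / math.sqrt(v.size)
    return PooledCIV(components=tuple(v), mean=mean, ci95=(mean - half, mean + half))


def convert_consumption_equivalents(
    civ_per_gram_day: float, grams_per_serving: float, servings_per_week: float
) -> float:
    """Annual pounds for a weekly serving habit.

    One serving per week adds grams_per_serving / 7 grams/day on average,
    so the annual-income equivalent is civ_per_gram_day * grams_per_serving
    * servings_per_week / 7.
    """
    if grams_per_serving <= 0 or servings_per_week < 0:
        raise ValueError("grams_per_serving must be positive, servings_per_week non-negative")
    return civ_per_gram_day * grams_per_serving * servings_per_week / 7.0


def round_currency(x: float) -> float:
    """Half-even rounding to 2 d.p. — reporting layer only."""
    import decimal

    return float(
        decimal.Decimal(repr(float(x))).quantize(
            decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_EVEN
        )
    )
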