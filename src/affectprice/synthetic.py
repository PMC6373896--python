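"""Seeded synthetic Biobank-like cohorts with known ground truth.

Every downstream stage — eligibility filtering, IRT scoring, the
within-between panel model, and shadow pricing — is testable against this
generator without any restricted data. It emulates, at a configurable desk
scale:

* a baseline cohort of middle-aged and older drinkers with a repeat
  assessment covering a configurable subset, yielding a balanced two-wave
  panel much smaller than the cross-sectional sample;
* band-censored household income (a latent log-normal income observed only
  as one of five bands);
* alcohol intake composed from per-beverage weekly or monthly counts;
* latent affect driven by a within-between linear model with a cluster
  intercept that can be *correlated* with the cluster mean of alcohol
  intake (the heterogeneity that biases a naive random-effects fit);
* item responses for the two affect scales drawn from graded-response and
  two-parameter logistic measurement models;
* refusal codes injected completely at random, and participant-level
  exclusion flags for each analytic-sample rule.

The affect linear predictor is built from the *encoded* exposures the
analysis will observe (grams/day from beverage counts; ln of the assigned
income-band value), so estimator-recovery tests are exact; the latent
log-income is kept in :class:`TrueParameters` to quantify band-censoring
error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .irt import BinaryItemParams, GradedItemParams, category_probabilities
from .prep import (
    BEVERAGE_COLUMNS,
    BeverageTable,
    COVARIATE_COLUMNS,
    DEFAULT_BAND_VALUES,
    NEUROTICISM_COLUMNS,
    PHQ4_COLUMNS,
    REFUSED,
)

__all__ = [
    "SimulationConfig",
    "TrueParameters",
    "ConfigurationError",
    "DEFAULT_GRADED_BANK",
    "DEFAULT_BINARY_BANK",
    "generate_cohort",
    "generate_item_responses",
    "inject_missingness",
    "simulate_panel",
    "write_cohort",
]


class ConfigurationError(ValueError):
    pass


#: Depression (PHQ-4-like) measurement model: four graded 0-3 items with
#: thresholds shifted positive — most respondents endorse the lowest
#: category, as on a screening scale.
DEFAULT_GRADED_BANK: tuple[GradedItemParams, ...] = (
    GradedItemParams(a=1.8, thresholds=(0.2, 1.2, 2.2)),
    GradedItemParams(a=1.4, thresholds=(-0.1, 0.9, 1.9)),
    GradedItemParams(a=2.0, thresholds=(0.4, 1.3, 2.3)),
    GradedItemParams(a=1.6, thresholds=(0.0, 1.0, 2.0)),
)

#: Neuroticism (EPQ-R-like) measurement model: twelve yes/no items spanning
#: the difficulty range.
DEFAULT_BINARY_BANK: tuple[BinaryItemParams, ...] = tuple(
    BinaryItemParams(a=a, b=b)
    for a, b in zip(
        (1.9, 1.4, 1.1, 1.7, 2.1, 1.3, 2.3, 1.6, 1.2, 1.8, 1.0, 1.5),
        (-1.2, -0.8, -0.5, -0.2, 0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4),
    )
)

_INCOME_BAND_EDGES = np.array([18_000.0, 31_000.0, 52_000.0, 100_000.0])
_DRINK_FREQUENCIES = ("daily", "3-4_per_week", "1-2_per_week", "1-3_per_month", "special_occasions")
_FREQ_PROBS = (0.20, 0.25, 0.30, 0.15, 0.10)


@dataclass
class SimulationConfig:
    """Generative truths and nuisance rates for one synthetic cohort.

    ``beta_AC_true`` / ``beta_lnY_true`` are single level-1 truths applied
    to both the within and between components unless ``beta_within`` /
    ``beta_between`` give distinct values per variable. ``mundlak_rho`` is
    the correlation between the cluster intercept and the (standardized)
    cluster mean of alcohol intake.
    """

    n_participants: int = 2000
    n_waves: int = 2
    seed: int = 0
    beta_AC_true: float = 0.02  # affect units per gram/day
    beta_lnY_true: float = -0.15  # affect units per log-pound
    beta_within: Mapping[str, float] | None = None
    beta_between: Mapping[str, float] | None = None
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "sex_male": -0.12,
            "townsend": 0.02,
            "age": -0.005,
            "college_degree": -0.05,
            "longterm_illness": 0.24,
        }
    )
    sigma_v: float = 0.5
    sigma_eps: float = 0.5
    mundlak_rho: float = 0.0
    followup_rate: float = 0.3
    item_bank_graded: tuple[GradedItemParams, ...] = DEFAULT_GRADED_BANK
    item_bank_binary: tuple[BinaryItemParams, ...] = DEFAULT_BINARY_BANK
    missing_rate: float = 0.005
    covariate_missing_rate: float = 0.02
    exclusion_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "non_drinker": 0.14,
            "neurological_condition": 0.02,
            "alcohol_dependence": 0.005,
        }
    )
    band_values: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_BAND_VALUES))
    beverage_table: BeverageTable = field(default_factory=BeverageTable)

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        if self.n_waves < 1:
            raise ConfigurationError("n_waves must be >= 1")
        if self.sigma_v < 0:
            raise ConfigurationError("sigma_v must be non-negative")
        if self.sigma_eps <= 0:
            raise ConfigurationError("sigma_eps must be positive")
        if not -1.0 <= self.mundlak_rho <= 1.0:
            raise ConfigurationError("mundlak_rho must lie in [-1, 1]")
        rates = [
            self.missing_rate,
            self.covariate_missing_rate,
            self.followup_rate,
            *self.exclusion_rates.values(),
        ]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ConfigurationError("all rates must lie in [0, 1]")

    def resolved_betas(self) -> tuple[dict[str, float], dict[str, float]]:
        base = {"alcohol_gday": self.beta_AC_true, "ln_income": self.beta_lnY_true}
        bw = dict(base)
        bb = dict(base)
        if self.beta_within:
            bw.update(self.beta_within)
        if self.beta_between:
            bb.update(self.beta_between)
        return bw, bb


@dataclass
class TrueParameters:
    """Realized ground truth, kept out of the analysis-facing CSV."""

    config: SimulationConfig
    beta_within: dict[str, float]
    beta_between: dict[str, float]
    alpha: float
    tau_between: float  # exp(-beta_b_AC / beta_b_lnY) - 1
    theta: pd.DataFrame  # participant_id, wave, theta_D, theta_N, eta
    cluster: pd.DataFrame  # participant_id, v_D, v_N, latent_ln_income

    def to_json(self, path) -> None:
        payload = {
            "beta_within": self.beta_within,
            "beta_between": self.beta_between,
            "alpha": self.alpha,
            "tau_between": self.tau_between,
            "sigma_v": self.config.sigma_v,
            "sigma_eps": self.config.sigma_eps,
            "mundlak_rho": self.config.mundlak_rho,
            "seed": self.config.seed,
            "n_participants": self.config.n_participants,
            "n_waves": self.config.n_waves,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def generate_item_responses(
    theta: np.ndarray,
    items: Sequence[GradedItemParams | BinaryItemParams],
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw a response matrix from the measurement model at the given thetas.

    Graded items yield categories 0..K-1; binary items 0/1. Category
    probabilities follow the standard graded-response / 2PL forms.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    X = np.empty((theta.size, len(items)), dtype=int)
    for j, item in enumerate(items):
        th = (
            np.array([item.b])
            if isinstance(item, BinaryItemParams)
            else np.asarray(item.thresholds, dtype=float)
        )
        P = category_probabilities(item.a, th, theta)
        cum = np.cumsum(P, axis=1)
        u = rng.random(theta.size)
        X[:, j] = (u[:, None] > cum).sum(axis=1)
    return X


def inject_missingness(
    dataset: pd.DataFrame,
    missing_rate: float,
    seed: np.random.Generator | int,
    columns: Sequence[str] = PHQ4_COLUMNS + NEUROTICISM_COLUMNS,
) -> pd.DataFrame:
    """Mark individual item responses with the refusal sentinel, MCAR."""
    if not 0.0 <= missing_rate <= 1.0:
        raise ConfigurationError("missing_rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = dataset.copy()
    if missing_rate == 0.0:
        return out
    mask = rng.random((len(out), len(columns))) < missing_rate
    block = out[list(columns)].to_numpy().copy()
    block[mask] = REFUSED
    out[list(columns)] = block
    return out


# ---------------------------------------------------------------------------
# Full cohort generation
# ---------------------------------------------------------------------------


def _income_band(income: np.ndarray) -> np.ndarray:
    return 1 + np.searchsorted(_INCOME_BAND_EDGES, income, side="left").astype(int)


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, TrueParameters]:
    """One row per participant per wave; identical seed, identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, W = config.n_participants, config.n_waves
    pid = np.arange(n)

    # --- time-invariant demographics (marginals loosely census-like)
    cov = pd.DataFrame(
        {
            "participant_id": pid,
            "sex_male": rng.binomial(1, 0.5, n),
            "age": np.round(rng.uniform(40, 70, n), 1),
            "townsend": np.round(rng.normal(-1.6, 2.8, n), 3),
            "college_degree": rng.binomial(1, 0.4, n),
            "employed": rng.binomial(1, 0.6, n),
            "smoker": rng.binomial(1, 0.1, n),
            "fruit_veg_5plus": rng.binomial(1, 0.7, n),
            "white_ethnicity": rng.binomial(1, 0.97, n),
            "bmi_class": rng.choice(3, size=n, p=(0.34, 0.44, 0.22)),
            "longterm_illness": rng.binomial(1, 0.28, n),
            "n_children": rng.poisson(1.77, n),
        }
    )

    # --- household income: latent log-normal, observed as bands per wave
    latent_ln_income = rng.normal(np.log(26_000.0), 0.5, n)
    wave_ln_income = latent_ln_income[:, None] + rng.normal(0.0, 0.2, (n, W))
    income = np.exp(wave_ln_income)
    band = _income_band(income)  # (n, W)
    band_values = dict(config.band_values)
    ln_income_obs = np.log(np.vectorize(band_values.get)(band).astype(float))

    # --- drinking: frequency fixed per participant; counts vary by wave
    rates = dict(config.exclusion_rates)
    non_drinker = rng.random(n) < rates.get("non_drinker", 0.0)
    freq = rng.choice(_DRINK_FREQUENCIES, size=n, p=_FREQ_PROBS)
    freq = np.where(non_drinker, "never", freq)
    weekly = np.isin(freq, ("daily", "3-4_per_week", "1-2_per_week"))
    # consumption scale per reporting period: heavier for weekly reporters
    scale = np.where(weekly, rng.gamma(2.0, 3.5, n), rng.gamma(2.0, 6.0, n))
    scale = np.where(non_drinker, 0.0, scale)
    prefs = rng.dirichlet(np.full(len(BEVERAGE_COLUMNS), 0.7), size=n)

    counts = {}
    for b, col in enumerate(BEVERAGE_COLUMNS):
        lam = scale * prefs[:, b]
        counts[col] = rng.poisson(lam[:, None] * np.ones((1, W)))

    grams_per = np.array([getattr(config.beverage_table, c) for c in BEVERAGE_COLUMNS])
    total_g = sum(counts[c] * g for c, g in zip(BEVERAGE_COLUMNS, grams_per))
    divisor = np.where(weekly, 7.0, 30.44)[:, None]
    ac = total_g / divisor  # grams/day, (n, W); zero for non-drinkers

    # --- follow-up subsampling: everyone at baseline, later waves only for
    # a retained subset (the study's repeat assessment covered a small
    # fraction of the baseline cohort)
    obs = np.ones((n, W), dtype=bool)
    if W > 1:
        followed = rng.random(n) < config.followup_rate
        obs[~followed, 1:] = False
    wts = obs / obs.sum(axis=1, keepdims=True)

    # --- affect linear predictor on the encoded exposures; cluster means
    # are taken over the waves the participant actually contributes
    bw, bb = config.resolved_betas()
    x = {"alcohol_gday": ac, "ln_income": ln_income_obs}
    eta = np.zeros((n, W))
    for v in x:
        xbar = (x[v] * wts).sum(axis=1, keepdims=True)
        eta += bw[v] * (x[v] - xbar) + bb[v] * xbar
    for c, beta in config.covariate_effects.items():
        eta += beta * cov[c].to_numpy(dtype=float)[:, None]
    alpha = -float(eta[obs].mean())  # center so most thetas land in the IRT range
    eta += alpha

    # --- cluster intercepts correlated with the cluster mean of alcohol
    ac_bar = (ac * wts).sum(axis=1)
    sd = ac_bar.std()
    z = (ac_bar - ac_bar.mean()) / (sd if sd > 0 else 1.0)
    rho = config.mundlak_rho
    v_D = config.sigma_v * (rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n))
    v_N = config.sigma_v * (rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n))
    theta_D = eta + v_D[:, None] + rng.normal(0.0, config.sigma_eps, (n, W))
    theta_N = eta + v_N[:, None] + rng.normal(0.0, config.sigma_eps, (n, W))

    # --- item responses for observed person-waves only
    mask = obs.ravel()
    phq = generate_item_responses(theta_D.ravel()[mask], config.item_bank_graded, rng)
    neur = generate_item_responses(theta_N.ravel()[mask], config.item_bank_binary, rng)

    rows = pd.DataFrame(
        {
            "participant_id": np.repeat(pid, W)[mask],
            "wave": np.tile(np.arange(W), n)[mask],
            "income_band": band.ravel()[mask],
            "drink_frequency": np.repeat(freq, W)[mask],
        }
    )
    for col in BEVERAGE_COLUMNS:
        rows[col] = counts[col].ravel()[mask]
    for k, col in enumerate(PHQ4_COLUMNS):
        rows[col] = phq[:, k]
    for k, col in enumerate(NEUROTICISM_COLUMNS):
        rows[col] = neur[:, k]
    rows = rows.merge(cov, on="participant_id", how="left")
    rows["neurological_condition"] = np.repeat(
        (rng.random(n) < rates.get("neurological_condition", 0.0)).astype(int), W
    )[mask]
    rows["alcohol_dependence"] = np.repeat(
        (rng.random(n) < rates.get("alcohol_dependence", 0.0)).astype(int), W
    )[mask]

    rows = inject_missingness(rows, config.missing_rate, rng)
    if config.covariate_missing_rate > 0:
        cmask = rng.random((len(rows), len(COVARIATE_COLUMNS))) < config.covariate_missing_rate
        block = rows[list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
        block[cmask] = np.nan
        rows[list(COVARIATE_COLUMNS)] = block

    tau = float(np.exp(-bb["alcohol_gday"] / bb["ln_income"]) - 1.0) if bb["ln_income"] != 0 else np.nan
    truth = TrueParameters(
        config=config,
        beta_within=bw,
        beta_between=bb,
        alpha=alpha,
        tau_between=tau,
        theta=pd.DataFrame(
            {
                "participant_id": np.repeat(pid, W)[mask],
                "wave": np.tile(np.arange(W), n)[mask],
                "theta_D": theta_D.ravel()[mask],
                "theta_N": theta_N.ravel()[mask],
                "eta": eta.ravel()[mask],
            }
        ),
        cluster=pd.DataFrame(
            {"participant_id": pid, "v_D": v_D, "v_N": v_N, "latent_ln_income": latent_ln_income}
        ),
    )
    return rows, truth


def write_cohort(dataset: pd.DataFrame, path, truth: TrueParameters | None = None) -> None:
    """Write the analysis-facing CSV (and optionally the truth side-car)."""
    dataset.to_csv(path, index=False)
    if truth is not None:
        truth.to_json(str(path) + ".truth.json")


# ---------------------------------------------------------------------------
# Direct panel simulation (no measurement layer)
# ---------------------------------------------------------------------------


def simulate_panel(
    n_clusters: int,
    n_waves: int = 2,
    beta_within: Mapping[str, float] | None = None,
    beta_between: Mapping[str, float] | None = None,
    sigma_v: float = 0.5,
    sigma_eps: float = 0.5,
    mundlak_rho: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a panel directly at the affect-equation level.

    The outcome is built from the realized within/between decomposition of
    the simulated exposures, so the supplied coefficients are the exact
    generative truths for the estimators. Used for estimator recovery, bias
    demonstration, Wald-size and coverage studies where no measurement
    model should intervene.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bw = {"alcohol_gday": 0.02, "ln_income": -0.05, **(beta_within or {})}
    bb = {"alcohol_gday": 0.05, "ln_income": -0.15, **(beta_between or {})}

    ac_bar = rng.gamma(2.0, 7.5, n_clusters)
    ac = np.clip(ac_bar[:, None] + rng.normal(0.0, 4.0, (n_clusters, n_waves)), 0.0, None)
    ly = rng.normal(10.2, 0.5, n_clusters)[:, None] + rng.normal(0.0, 0.15, (n_clusters, n_waves))

    eta = np.zeros((n_clusters, n_waves))
    for name, xmat in (("alcohol_gday", ac), ("ln_income", ly)):
        xbar = xmat.mean(axis=1, keepdims=True)
        eta += bw[name] * (xmat - xbar) + bb[name] * xbar

    zbar = ac.mean(axis=1)
    z = (zbar - zbar.mean()) / zbar.std()
    v = sigma_v * (mundlak_rho * z + np.sqrt(1 - mundlak_rho**2) * rng.standard_normal(n_clusters))
    y = eta + v[:, None] + rng.normal(0.0, sigma_eps, (n_clusters, n_waves))

    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n_clusters), n_waves),
            "wave": np.tile(np.arange(n_waves), n_clusters),
            "theta": y.ravel(),
            "alcohol_gday": ac.ravel(),
            "ln_income": ly.ravel(),
        }
    )
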