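"""End-to-end orchestration: simulate -> filter -> score -> fit -> price.

Runs both affect equations (depression from the 4-item graded scale,
neuroticism from the 12 binary items) under both designs (cross-sectional
baseline and two-wave longitudinal), producing a descriptive table, a
regression table with within/between coefficients, Wald tests and CIV
rows, and a pooled shadow price — the same report shapes as the study the
generator emulates. Deterministic given the seed; every stage logs row
counts so exclusion audits reconcile.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import irt, panel, prep, pricing
from .prep import NEUROTICISM_COLUMNS, PHQ4_COLUMNS, BeverageTable
from .synthetic import SimulationConfig, generate_cohort

__all__ = ["RunConfig", "ReportBundle", "PipelineError", "run_pipeline", "descriptive_table"]

logger = logging.getLogger("affectprice")

DEFAULT_COVARIATES = (
    "sex_male",
    "age",
    "townsend",
    "college_degree",
    "smoker",
    "longterm_illness",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    mode: str = "simulate"  # or "from_csv"
    input_csv: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    band_values: dict[int, float] = field(default_factory=lambda: dict(prep.DEFAULT_BAND_VALUES))
    beverage_table: BeverageTable = field(default_factory=BeverageTable)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    income_tax_table: pricing.IncomeTaxTable = field(
        default_factory=lambda: pricing.DEFAULT_INCOME_TAX_TABLE
    )
    outcomes: tuple[str, ...] = ("depression", "neuroticism")
    designs: tuple[str, ...] = ("cross_sectional", "longitudinal")

    def __post_init__(self):
        if self.mode not in ("simulate", "from_csv"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "from_csv" and not self.input_csv:
            raise ValueError("from_csv mode requires input_csv")
        # the run seed governs the simulation
        self.simulation = replace(self.simulation, seed=self.seed)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "mode": self.mode,
            "input_csv": self.input_csv,
            "band_values": {int(k): float(v) for k, v in self.band_values.items()},
            "beverage_table": self.beverage_table.as_dict(),
            "covariates": list(self.covariates),
            "income_tax_table": self.income_tax_table.to_frame().to_dict("list"),
            "outcomes": list(self.outcomes),
            "designs": list(self.designs),
            "simulation": {
                "n_participants": self.simulation.n_participants,
                "n_waves": self.simulation.n_waves,
                "beta_AC_true": self.simulation.beta_AC_true,
                "beta_lnY_true": self.simulation.beta_lnY_true,
                "sigma_v": self.simulation.sigma_v,
                "sigma_eps": self.simulation.sigma_eps,
                "mundlak_rho": self.simulation.mundlak_rho,
                "missing_rate": self.simulation.missing_rate,
                "covariate_missing_rate": self.simulation.covariate_missing_rate,
                "exclusion_rates": dict(self.simulation.exclusion_rates),
            },
        }
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        bev = BeverageTable(**raw.pop("beverage_table", {}))
        itt = raw.pop("income_tax_table", None)
        table = (
            pricing.IncomeTaxTable(
                age_bands=tuple(itt["age_band"]),
                proportions=tuple(itt["p"]),
                incomes=tuple(itt["income"]),
                taxes=tuple(itt["tax"]),
            )
            if itt
            else pricing.DEFAULT_INCOME_TAX_TABLE
        )
        band = {int(k): float(v) for k, v in raw.pop("band_values", prep.DEFAULT_BAND_VALUES).items()}
        for tup in ("covariates", "outcomes", "designs"):
            if tup in raw:
                raw[tup] = tuple(raw[tup])
        return cls(simulation=sim, beverage_table=bev, income_tax_table=table, band_values=band, **raw)


@dataclass
class ReportBundle:
    """Every number here traces back to a ModelFit or CIVResult."""

    descriptive: pd.DataFrame
    model_table: pd.DataFrame
    civ_results: dict[str, pricing.CIVResult]
    pooled: pricing.PooledCIV
    exclusion_logs: dict[str, prep.ExclusionLog]
    fits: dict[str, panel.ModelFit]
    wald: dict[str, panel.WaldResult]
    provenance: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.descriptive.to_csv(out / "descriptive_table.csv", index=False)
        self.model_table.to_csv(out / "model_table.csv", index=False)
        with open(out / "exclusions.json", "w") as fh:
            json.dump(
                {k: json.loads(v.to_json()) for k, v in self.exclusion_logs.items()}, fh, indent=2
            )
        civ = {
            k: {
                "tau": r.tau,
                "se_tau": r.se_tau,
                "ci95": list(r.ci95),
                "civ_pounds": pricing.round_currency(r.civ_pounds),
                "se_pounds": r.se_pounds,
            }
            for k, r in self.civ_results.items()
        }
        civ["pooled"] = {
            "components_pounds": [pricing.round_currency(c) for c in self.pooled.components],
            "mean_pounds": pricing.round_currency(self.pooled.mean),
            "ci95_pounds": [pricing.round_currency(c) for c in self.pooled.ci95],
            "method": self.pooled.method,
        }
        with open(out / "civ.json", "w") as fh:
            json.dump(civ, fh, indent=2)
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2)
        with open(out / "report.md", "w") as fh:
            fh.write(self.to_markdown())

    def to_markdown(self) -> str:
        lines = ["# Affect shadow-pricing run", ""]
        lines += [f"- config hash: `{self.provenance['config_hash']}`",
                  f"- seed: {self.provenance['seed']}", ""]
        lines += ["## Exclusions", ""]
        for k, log in self.exclusion_logs.items():
            lines.append(f"- {k}: raw {log.raw_n} -> eligible {log.eligible_n} ({log.counts})")
        lines += ["", "## Model table", "", self.model_table.to_markdown(index=False), ""]
        lines += ["## Compensating income variation", ""]
        for k, r in self.civ_results.items():
            lines.append(
                f"- {k}: tau = {100 * r.tau:.3f}% (se {100 * r.se_tau:.3f}%), "
                f"CIV = £{r.civ_pounds:.2f}"
            )
        lines.append(
            f"- pooled: £{self.pooled.mean:.2f} "
            f"(95% CI £{self.pooled.ci95[0]:.2f} to £{self.pooled.ci95[1]:.2f})"
        )
        lines.append("")
        return "\n".join(lines)


# ---------------------------------------------------------------------------


def _score_thetas(df: pd.DataFrame, baseline_wave: int, stage: str):
    """Calibrate item parameters on the baseline wave, score every row.

    Holding baseline-calibrated parameters fixed across waves puts both
    waves on a common latent metric.
    """
    base = df.loc[df["wave"] == baseline_wave]
    try:
        grm, diag_d = irt.fit_graded_model(base[list(PHQ4_COLUMNS)].to_numpy(dtype=int))
        twopl, diag_n = irt.fit_2pl(base[list(NEUROTICISM_COLUMNS)].to_numpy(dtype=int))
    except irt.DegenerateItemError as err:
        raise PipelineError(stage, str(err)) from err
    theta_d, _ = irt.eap_scores(grm, df[list(PHQ4_COLUMNS)].to_numpy(dtype=int))
    theta_n, _ = irt.eap_scores(twopl, df[list(NEUROTICISM_COLUMNS)].to_numpy(dtype=int))
    out = df.copy()
    out["theta_D"] = theta_d
    out["theta_N"] = theta_n
    logger.info("%s: IRT calibrated (GRM %d iters, 2PL %d iters), scored %d rows",
                stage, diag_d["n_iter"], diag_n["n_iter"], len(out))
    return out, {"grm": grm, "twopl": twopl}


_OUTCOME_COL = {"depression": "theta_D", "neuroticism": "theta_N"}


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every stage for both outcomes and both designs."""
    if config.mode == "simulate":
        raw, _truth = generate_cohort(config.simulation)
    else:
        raw = pd.read_csv(config.input_csv)
    logger.info("input: %d rows, %d participants", len(raw), raw["participant_id"].nunique())

    exclusion_logs: dict[str, prep.ExclusionLog] = {}
    fits: dict[str, panel.ModelFit] = {}
    wald: dict[str, panel.WaldResult] = {}
    civ_results: dict[str, pricing.CIVResult] = {}
    covs = tuple(config.covariates)

    for design in config.designs:
        stage = f"filter:{design}"
        try:
            elig, log = prep.apply_eligibility_filters(raw, design)
        except (KeyError, ValueError) as err:
            raise PipelineError(stage, str(err)) from err
        exclusion_logs[design] = log
        logger.info("%s: %d -> %d participants %s", stage, log.raw_n, log.eligible_n, log.counts)

        if design == "longitudinal":
            pds = prep.build_balanced_panel(elig)
            df = pds.data
        else:
            df = elig.sort_values(["participant_id", "wave"], kind="mergesort").reset_index(drop=True)

        df = df.copy()
        df["alcohol_gday"] = prep.compute_grams_per_day(df, config.beverage_table)
        df["ln_income"] = prep.encode_income(df["income_band"], config.band_values)

        baseline_wave = int(df["wave"].min())
        df, _banks = _score_thetas(df, baseline_wave, f"score:{design}")
        if design == "longitudinal":
            scored_panel = df

        for outcome in config.outcomes:
            key = f"{design}:{outcome}"
            spec = panel.DesignSpec(
                outcome=_OUTCOME_COL[outcome],
                level1=("alcohol_gday", "ln_income"),
                level2=covs,
            )
            try:
                if design == "cross_sectional":
                    fit = panel.fit_pooled_ols(df, spec)
                else:
                    fit = panel.fit_wb_random(df, spec)
                    fits[f"{key}:fixed"] = panel.fit_fixed_effects(
                        df, replace_spec_level1_only(spec)
                    )
                    fits[f"{key}:random"] = panel.fit_random_effects(df, spec)
                    wald[key] = panel.wald_equal_effects(fit, ["alcohol_gday", "ln_income"])
            except (panel.SpecificationError, panel.RankError) as err:
                raise PipelineError(f"fit:{key}", str(err)) from err
            fits[key] = fit

            b, V = fit.coef_pair("alcohol_gday", "ln_income", component="between")
            pair = pricing.CoefPair(beta_AC=b[0], beta_lnY=b[1], cov=V)
            civ_results[key] = pricing.civ_result(pair, config.income_tax_table, source=key)

    pooled = pricing.pool_civ([r.civ_pounds for r in civ_results.values()])

    desc_df = scored_panel if "longitudinal" in config.designs else df
    descriptive = descriptive_table(desc_df, covariates=covs)
    model_table = _model_table(fits, wald, civ_results, config.outcomes, config.designs)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "n_rows_input": int(len(raw)),
    }
    return ReportBundle(
        descriptive=descriptive,
        model_table=model_table,
        civ_results=civ_results,
        pooled=pooled,
        exclusion_logs=exclusion_logs,
        fits=fits,
        wald=wald,
        provenance=provenance,
    )


def replace_spec_level1_only(spec: panel.DesignSpec) -> panel.DesignSpec:
    return panel.DesignSpec(
        outcome=spec.outcome, level1=spec.level1, level2=(), cluster=spec.cluster,
        intercept=spec.intercept,
    )


_CATEGORICAL = (
    ("income_band", None),
    ("college_degree", {0: "other", 1: "college"}),
    ("sex_male", {0: "female", 1: "male"}),
    ("employed", {0: "other", 1: "employed"}),
    ("smoker", {0: "no", 1: "yes"}),
    ("fruit_veg_5plus", {0: "<5/day", 1: ">=5/day"}),
    ("white_ethnicity", {0: "other", 1: "white"}),
    ("bmi_class", {0: "normal", 1: "overweight", 2: "obese"}),
    ("longterm_illness", {0: "no", 1: "yes"}),
)
_CONTINUOUS = ("age", "townsend", "n_children")


def descriptive_table(
    scored: pd.DataFrame, covariates: Sequence[str] = DEFAULT_COVARIATES
) -> pd.DataFrame:
    """Means/SDs of the two thetas and alcohol intake by demographic group,
    plus joint least-squares associations of each theta with the
    demographics (coefficient and z per variable)."""
    rows = []
    n = len(scored)
    for var, labels in _CATEGORICAL:
        if var not in scored.columns:
            continue
        grouped = scored.groupby(var, dropna=True)
        if len(grouped) == 0:
            logger.warning("descriptive: %s has no non-missing categories, omitted", var)
            continue
        for level, g in grouped:
            label = labels.get(level, str(level)) if labels else str(level)
            rows.append(
                {
                    "variable": var,
                    "category": label,
                    "proportion": len(g) / n,
                    "theta_D_mean": g["theta_D"].mean(),
                    "theta_D_sd": g["theta_D"].std(ddof=1),
                    "theta_N_mean": g["theta_N"].mean(),
                    "theta_N_sd": g["theta_N"].std(ddof=1),
                    "alcohol_mean": g["alcohol_gday"].mean(),
                    "alcohol_sd": g["alcohol_gday"].std(ddof=1),
                }
            )
    for var in _CONTINUOUS:
        if var not in scored.columns:
            continue
        rows.append(
            {
                "variable": var,
                "category": "(continuous)",
                "value_mean": scored[var].mean(),
                "value_sd": scored[var].std(ddof=1),
            }
        )
    table = pd.DataFrame(rows)

    # least-squares association column: theta ~ demographics jointly
    present = [c for c in covariates if c in scored.columns]
    if present:
        X = np.column_stack(
            [np.ones(n)] + [scored[c].to_numpy(dtype=float) for c in present]
        )
        for theta_col, out_col in (("theta_D", "f_theta_D"), ("theta_N", "f_theta_N")):
            y = scored[theta_col].to_numpy(dtype=float)
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            s2 = r @ r / max(n - X.shape[1], 1)
            se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
            assoc = {c: (beta[k + 1], beta[k + 1] / se[k + 1]) for k, c in enumerate(present)}
            table[out_col] = [
                f"{assoc[v][0]:+.3f} (z={assoc[v][1]:.2f})" if v in assoc else ""
                for v in table["variable"]
            ]
    return table


def _model_table(fits, wald, civ_results, outcomes, designs) -> pd.DataFrame:
    """Regression-table-shaped summary: within/between rows per equation,
    Wald p-values, model statistics, CIV rows."""
    rows = []
    for design in designs:
        for outcome in outcomes:
            key = f"{design}:{outcome}"
            fit = fits[key]
            se = fit.se

            def cell(name):
                if name not in fit.params.index:
                    return ""
                return f"{fit.params[name]:+.4f} (z={fit.params[name] / se[name]:.2f})"

            row = {
                "design": design,
                "outcome": outcome,
                "model": fit.model_kind,
                "AC_within": cell("alcohol_gday:within"),
                "lnY_within": cell("ln_income:within"),
                "AC_between": cell("alcohol_gday:between"),
                "lnY_between": cell("ln_income:between"),
                "sigma_v2": f"{fit.sigma_v2:.4f}" if np.isfinite(fit.sigma_v2) else "",
                "sigma_eps2": f"{fit.sigma_eps2:.4f}",
                "loglik": f"{fit.loglik:.2f}" if np.isfinite(fit.loglik) else "",
                "n_obs": fit.n_obs,
                "n_clusters": fit.n_clusters,
            }
            if key in wald:
                row["wald_p_equal_effects"] = f"{wald[key].p_value:.4f}"
            else:
                row["wald_p_equal_effects"] = ""
            r = civ_results[key]
            row["civ_pct"] = f"{100 * r.tau:.3f}"
            row["civ_pounds"] = f"{r.civ_pounds:.2f}"
            rows.append(row)
    return pd.DataFrame(rows)
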