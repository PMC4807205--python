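"""End-to-end pipeline: ingest rates, fit all growth models, assemble a report.

The report ranks models by the derivative-level score: a model can track the
cumulative level curve almost perfectly (the linear trend does, here) while
its implied *growth-rate mechanism* -- the first differences -- has nothing
to do with the observed annual rates, in which case extrapolating it is
unsound.  Level R^2 is always shown alongside, never used for ranking.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fit import (
    ExponentialFit,
    FitResult,
    GridConfig,
    LinearTrendFit,
    derivative_fit_r2,
    fit_cubic,
    fit_exponential,
    fit_linear_trend,
    fit_logistic,
)
from .models import classify_regime, RegimeLabel
from .series import AnnualRateSeries, CumulativeSeries, build_cumulative, read_rate_table, standardize

__all__ = ["PipelineConfig", "PipelineError", "AnalysisReport",
           "run_pipeline", "compare_models"]

logger = logging.getLogger("growthmap")

#: declaration order; used for stable tie-breaking in model ranking
MODEL_ORDER = ("logistic", "cubic", "linear", "exponential")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[stage: {stage}] {original}")


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved pipeline configuration.

    ``base_year``/``end_year`` bound the running summation (defaults: full
    series); the fitted window opens ``fit_offset`` years after the base --
    two, in the study design, so the initial condition sits just after the
    accumulation start -- and both can be pinned explicitly.
    """

    label: str = ""
    year_col: str = "year"
    rate_col: str = "rate"
    delimiter: str | None = None
    base_year: int | None = None
    end_year: int | None = None
    fit_start_year: int | None = None
    fit_end_year: int | None = None
    fit_offset: int = 2
    breakpoints: tuple[int, ...] = ()
    seed: int = 0
    grid: GridConfig = field(default_factory=GridConfig)
    skip_cubic: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        grid_raw = raw.pop("grid", {})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "breakpoints" in raw:
            raw["breakpoints"] = tuple(int(y) for y in raw["breakpoints"])
        grid_known = set(GridConfig.__dataclass_fields__)
        bad = set(grid_raw) - grid_known
        if bad:
            raise ValueError(f"unknown grid config key(s): {sorted(bad)}")
        for key in ("k_range", "x0_range", "k1_range", "k2_range", "k3_range",
                    "cubic_x0_range"):
            if key in grid_raw:
                grid_raw[key] = tuple(grid_raw[key])
        return cls(grid=GridConfig(**grid_raw), **raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, recomputable from input + config."""

    input_path: str
    label: str
    window: tuple[int, int]
    n_obs: int
    target_mean: float
    target_sd: float
    logistic: FitResult
    cubic: FitResult | None
    linear: LinearTrendFit
    exponential: ExponentialFit
    derivative_r2: dict
    regime: RegimeLabel
    breakpoints: tuple[int, ...]
    config_hash: str
    seed: int

    def to_dict(self) -> dict:
        def fit_block(f: FitResult) -> dict:
            d = {
                "family": f.params.family,
                "x0": f.params.x0,
                "r2": f.r2,
                "orbit_mean": f.orbit_mean,
                "orbit_sd": f.orbit_sd,
                "alignment": f.alignment,
                "n_candidates": f.search_log["n_candidates"],
                "n_divergent": f.search_log["n_divergent"],
            }
            if f.params.family == "logistic":
                d["k"] = f.params.k
            else:
                k1, k2, k3 = f.params.poly_coeffs
                d.update(k1=k1, k2=k2, k3=k3,
                         signed_polynomial=list(f.params.signed_polynomial()))
            return d

        out = {
            "provenance": {
                "input": self.input_path,
                "label": self.label,
                "window": list(self.window),
                "n_obs": self.n_obs,
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": __version__,
            },
            "target": {"mean": self.target_mean, "sd": self.target_sd},
            "models": {
                "logistic": fit_block(self.logistic),
                "linear": {"slope": self.linear.slope,
                           "intercept": self.linear.intercept,
                           "r2": self.linear.r2},
                "exponential": {"a": self.exponential.a,
                                "ln_intercept": self.exponential.ln_intercept,
                                "base": self.exponential.base,
                                "r2": self.exponential.r2},
            },
            "derivative_r2": dict(self.derivative_r2),
            "regime": {"regime": self.regime.regime,
                       "k": self.regime.k,
                       "equilibria": list(self.regime.equilibria)},
            "breakpoints": list(self.breakpoints),
        }
        if self.cubic is not None:
            out["models"]["cubic"] = fit_block(self.cubic)
        return out

    def to_json(self) -> str:
        # sorted keys, no timestamps: byte-identical across reruns
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        d = self.to_dict()
        lines = [
            f"growthmap analysis -- {self.label or self.input_path}",
            f"window {self.window[0]}-{self.window[1]}  "
            f"({self.n_obs} obs)  config {self.config_hash}",
            f"target mean {self.target_mean:.3f}  sd {self.target_sd:.3f}",
            "",
            "model        level R2   derivative R2   parameters",
        ]
        ranking = compare_models(self)
        for _, row in ranking.iterrows():
            lines.append(f"{row['model']:<12} {row['level_r2']:>8.2f} "
                         f"{row['derivative_r2']:>15.2f}   {row['parameters']}")
        lines += [
            "",
            "Ranking is by derivative-level R2: a high level R2 with the wrong",
            "growth-rate mechanism extrapolates poorly and is not model evidence.",
            f"regime of winning map: {self.regime.regime} "
            f"(k={self.regime.k:.3f}, equilibria "
            f"{[round(e, 3) for e in self.regime.equilibria]})",
        ]
        if self.breakpoints:
            lines.append(
                f"externally supplied breakpoint years: {list(self.breakpoints)}")
        return "\n".join(lines) + "\n"


def _params_text(report: AnalysisReport, model: str) -> str:
    if model == "logistic":
        p = report.logistic.params
        return f"k={p.k:.3f} x0={p.x0:.6f}"
    if model == "cubic":
        p = report.cubic.params
        k1, k2, k3 = p.poly_coeffs
        return f"k1={k1:.3f} k2={k2:.3f} k3={k3:.3f} x0={p.x0:.6f}"
    if model == "linear":
        return (f"slope={report.linear.slope:.3f} "
                f"intercept={report.linear.intercept:.3f}")
    return (f"a={report.exponential.a:.3f} "
            f"ln_intercept={report.exponential.ln_intercept:.3f} "
            f"base={report.exponential.base:.3f}")


def compare_models(report: AnalysisReport) -> pd.DataFrame:
    """Rank fitted models by derivative-level R^2 (level R^2 shown alongside).

    Ties keep declaration order (logistic, cubic, linear, exponential).
    Level R^2 alone is explicitly not treated as model evidence.
    """
    rows = []
    level = {
        "logistic": report.logistic.r2 if report.logistic else None,
        "cubic": report.cubic.r2 if report.cubic else None,
        "linear": report.linear.r2 if report.linear else None,
        "exponential": report.exponential.r2 if report.exponential else None,
    }
    for model in MODEL_ORDER:
        if level[model] is None or model not in report.derivative_r2:
            continue
        rows.append({"model": model,
                     "derivative_r2": report.derivative_r2[model],
                     "level_r2": level[model],
                     "parameters": _params_text(report, model)})
    if len(rows) < 2:
        raise ValueError("nothing to compare: need at least 2 model fits")
    df = pd.DataFrame(rows)
    # stable sort keeps declaration order on exact ties
    return df.sort_values("derivative_r2", ascending=False,
                          kind="stable").reset_index(drop=True)


def _fit_table(rates: AnnualRateSeries, target: CumulativeSeries,
               fit: FitResult) -> pd.DataFrame:
    """Per-year observed/fitted table mirroring the published layout."""
    tz = standardize(target.values)
    orbit = fit.orbit_series()
    oz = standardize(orbit)
    obs_rates = np.array([rates.rate_at(int(y)) for y in target.years])
    residual = target.values - fit.fitted_values
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(target.values != 0,
                       residual / target.values * 100.0, np.nan)
    fitted_deriv = np.concatenate([[np.nan], fit.fitted_derivatives])
    return pd.DataFrame({
        "year": target.years,
        "observed_rate": obs_rates,
        "observed_S": target.values,
        "z_observed_S": tz.z_values,
        "orbit_value": orbit,
        "z_orbit": oz.z_values,
        "fitted_S": fit.fitted_values,
        "residual": residual,
        "pct_residual": pct,
        "fitted_derivative": fitted_deriv,
    })


def run_pipeline(rates_path, config_path=None, out_dir=None,
                 config: PipelineConfig | None = None) -> AnalysisReport:
    """Execute the full analysis; optionally write artifacts to ``out_dir``.

    Stages: ingest -> accumulate -> window -> logistic fit -> cubic fit ->
    linear fit -> exponential fit -> derivative comparison -> regime.
    Any stage error is re-raised as :class:`PipelineError` naming the stage.
    """
    if config is not None and config_path is not None:
        raise ValueError("pass either config_path or config, not both")
    if config is None:
        config = (PipelineConfig.from_yaml(config_path)
                  if config_path else PipelineConfig())

    def stage(name, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    rates = stage("read_rates", read_rate_table, rates_path,
                  label=config.label, delimiter=config.delimiter,
                  year_col=config.year_col, rate_col=config.rate_col)
    base = config.base_year if config.base_year is not None else int(rates.years[0])
    end = config.end_year if config.end_year is not None else int(rates.years[-1])
    cumulative = stage("build_cumulative", build_cumulative, rates, base, end)
    fit_start = (config.fit_start_year if config.fit_start_year is not None
                 else min(base + config.fit_offset, end))
    fit_end = config.fit_end_year if config.fit_end_year is not None else end
    target = stage("fit_window", cumulative.window, fit_start, fit_end)

    log_fit = stage("fit_logistic", fit_logistic, target, config.grid)
    logger.info("logistic: k=%.5f x0=%.6f R2=%.5f",
                log_fit.params.k, log_fit.params.x0, log_fit.r2)
    cub_fit = None
    if not config.skip_cubic:
        cub_fit = stage("fit_cubic", fit_cubic, target, config.grid)
        logger.info("cubic: %s x0=%.6f R2=%.5f",
                    cub_fit.params.poly_coeffs, cub_fit.params.x0, cub_fit.r2)
    lin_fit = stage("fit_linear_trend", fit_linear_trend, target)
    exp_fit = stage("fit_exponential", fit_exponential, target)

    def deriv_scores():
        scores = {
            "logistic": derivative_fit_r2(rates, log_fit.fitted_values,
                                          target.years),
            "linear": derivative_fit_r2(rates, lin_fit.fitted_values,
                                        target.years),
            "exponential": derivative_fit_r2(rates, exp_fit.fitted_values,
                                             target.years),
        }
        if cub_fit is not None:
            scores["cubic"] = derivative_fit_r2(rates, cub_fit.fitted_values,
                                                target.years)
        return scores

    deriv = stage("derivative_fit_r2", deriv_scores)
    # regime of the winning map family (cubic wins on its leading factor k1)
    best_map = "logistic"
    if cub_fit is not None and deriv["cubic"] > deriv["logistic"]:
        best_map = "cubic"
    k_win = (log_fit.params.k if best_map == "logistic"
             else cub_fit.params.poly_coeffs[0])
    regime = stage("classify_regime", classify_regime, k_win)

    tz = standardize(target.values)
    report = AnalysisReport(
        input_path=str(rates_path), label=config.label or rates.label,
        window=(fit_start, fit_end), n_obs=target.n_obs,
        target_mean=tz.mean, target_sd=tz.sd,
        logistic=log_fit, cubic=cub_fit, linear=lin_fit,
        exponential=exp_fit, derivative_r2=deriv, regime=regime,
        breakpoints=config.breakpoints,
        config_hash=config.config_hash(), seed=config.seed)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _fit_table(rates, target, log_fit).to_csv(
            out / "logistic_fit.csv", index=False, float_format="%.6f")
        if cub_fit is not None:
            _fit_table(rates, target, cub_fit).to_csv(
                out / "cubic_fit.csv", index=False, float_format="%.6f")
        (out / "report.json").write_text(report.to_json())
        (out / "report.txt").write_text(report.to_text())
    return report
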