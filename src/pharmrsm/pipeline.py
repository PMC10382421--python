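"""End-to-end pipeline: design -> fit -> ANOVA -> optimize -> validate (-> NCA).

A :class:`PipelineConfig` (usually parsed from JSON) validates every stage's
preconditions up front; :func:`run_pipeline` then executes the stages and
writes a deterministic report bundle (per-response ANOVA CSVs and model
JSONs, optimization JSON, optional NCA CSV, and a plain-text report).
Outputs are byte-identical across runs with identical config and inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import desirability as des
from . import diagnostics as diag
from .nca import group_summary, nca_table, read_concentration_csv
from . import rsm
from .design import FactorSpec, read_response_table
from .fixtures import TABLE1_FACTORS

__all__ = ["PipelineConfig", "default_config", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and a hint."""


@dataclass
class ResponseConfig:
    name: str
    direction: str  # minimize | maximize | target
    analyze_as_magnitude: bool = False
    lower: float | None = None  # desirability bounds; None -> observed extremes
    upper: float | None = None
    target: float | None = None
    importance: float = 1.0


@dataclass
class PipelineConfig:
    factors: list[FactorSpec]
    responses: list[ResponseConfig]
    n_center: int = 5
    alpha_mode: str = "rotatable"
    region: str = "factorial_box"
    grid_step: float = 0.01
    lambda_points: int = 3
    seed: int = 0
    observed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.factors) < 2:
            raise PipelineError("config: a CCD needs at least 2 factors")
        if not self.responses:
            raise PipelineError("config: at least one response is required")
        if self.n_center < 1:
            raise PipelineError("config: n_center must be >= 1")
        if self.region not in des.REGIONS:
            raise PipelineError(f"config: region must be one of {des.REGIONS}")
        if not 0 < self.grid_step <= 0.5:
            raise PipelineError("config: grid_step must be in (0, 0.5]")
        if self.lambda_points < 2:
            raise PipelineError("config: lambda_points must be >= 2")
        for r in self.responses:
            if r.direction not in des.DIRECTIONS:
                raise PipelineError(
                    f"config: response {r.name!r}: direction must be one of "
                    f"{des.DIRECTIONS}"
                )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        factors = [FactorSpec(**f) for f in raw.pop("factors")]
        responses = [ResponseConfig(**r) for r in raw.pop("responses")]
        return cls(factors=factors, responses=responses, **raw)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "factors": [vars(f) | {} for f in self.factors],
            "responses": [vars(r) for r in self.responses],
            "n_center": self.n_center,
            "alpha_mode": self.alpha_mode,
            "region": self.region,
            "grid_step": self.grid_step,
            "lambda_points": self.lambda_points,
            "seed": self.seed,
            "observed": self.observed,
        }
        payload["factors"] = [
            {"name": f.name, "center": f.center, "half_range": f.half_range, "units": f.units}
            for f in self.factors
        ]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def default_config() -> PipelineConfig:
    """Defaults mirroring the packaged study: PS/PDI minimized, |ZP| maximized."""
    return PipelineConfig(
        factors=list(TABLE1_FACTORS),
        responses=[
            ResponseConfig(name="PS", direction="minimize"),
            ResponseConfig(name="PDI", direction="minimize"),
            ResponseConfig(name="ZP", direction="maximize", analyze_as_magnitude=True),
        ],
    )


def _stage(name: str, hint: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}; {hint}") from exc

        return wrapped

    return deco


def run_pipeline(
    config: PipelineConfig,
    response_csv: str | Path,
    pk_csv: str | Path | None = None,
    out_dir: str | Path = "pharmrsm_out",
) -> dict:
    """Execute the full chain and write the report bundle to ``out_dir``.

    Returns a summary dict (models, anova tables, optimization result,
    validation records, NCA table when ``pk_csv`` is given). Partial outputs
    are retained when a later stage fails.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: list[str] = []

    log.info("reading response table %s", response_csv)
    magnitude = {r.name for r in config.responses if r.analyze_as_magnitude}
    table = _stage("read", "check CSV columns against the documented dialect")(
        read_response_table
    )(response_csv, factors=config.factors, magnitude_responses=magnitude)
    missing = [r.name for r in config.responses if r.name not in table.means]
    if missing:
        raise PipelineError(
            f"stage 'read' failed: response column(s) {missing} not in "
            f"{response_csv}; available: {list(table.response_names)}"
        )
    report.append(
        f"Design: {table.design.n_runs} runs, k={table.design.k}, "
        f"alpha={table.design.alpha:.5f}, {table.design.n_center} center points"
    )

    models = {}
    goals = []
    for rcfg in config.responses:
        model = _stage("fit", "inspect the design matrix for collinearity")(
            rsm.fit_quadratic
        )(table, rcfg.name)
        models[rcfg.name] = model
        log.info("fitted %s: %s", rcfg.name, model.equation())
        report.append(model.equation())
        tbl = _stage("anova", "the design needs replicated center points")(diag.anova)(
            model
        )
        tbl.to_csv(out / f"anova_{rcfg.name}.csv")
        summ = diag.fit_summary(model)
        report.append(tbl.to_text())
        report.append(
            f"R2={summ.r2:.4f}  adj R2={summ.adj_r2:.4f}  pred R2={summ.pred_r2:.4f}  "
            f"PRESS={summ.press:.4g}  adequate precision={summ.adequate_precision:.3f}"
        )
        model.to_json(out / f"model_{rcfg.name}.json")

        y, _ = table.analysis_values(rcfg.name)
        goals.append(
            des.DesirabilityGoal(
                response_name=rcfg.name,
                direction=rcfg.direction,
                lower=float(y.min()) if rcfg.lower is None else rcfg.lower,
                upper=float(y.max()) if rcfg.upper is None else rcfg.upper,
                target=rcfg.target,
                importance=rcfg.importance,
            )
        )

    log.info("optimizing desirability over %s (step %g)", config.region, config.grid_step)
    result = _stage("optimize", "check desirability bounds for feasibility")(
        des.optimize
    )(list(models.values()), goals, region=config.region, grid_step=config.grid_step)
    signed_pred = {
        name: models[name].sign * val for name, val in result.predicted.items()
    }
    opt_payload = {
        "coded_point": list(result.coded_point),
        "actual_point": list(result.actual_point),
        "predicted": signed_pred,
        "individual_desirability": result.individual_d,
        "overall_desirability": result.overall_D,
        "feasible": result.feasible,
        "solutions": [
            {
                "coded_point": list(s.coded_point),
                "actual_point": list(s.actual_point),
                "predicted": {n: models[n].sign * v for n, v in s.predicted.items()},
                "overall_desirability": s.overall_D,
            }
            for s in result.solutions
        ],
    }
    (out / "optimization.json").write_text(
        json.dumps(opt_payload, indent=2, sort_keys=True) + "\n"
    )
    factor_str = ", ".join(
        f"{f.name}={v:.3f}{(' ' + f.units) if f.units else ''}"
        for f, v in zip(config.factors, result.actual_point)
    )
    report.append(
        f"Optimum: {factor_str}  D={result.overall_D:.3f} "
        f"({len(result.solutions)} local solution(s))"
    )
    log.info("optimum D=%.3f at %s", result.overall_D, factor_str)

    if config.observed:
        records = des.validate_predictions(
            {n: signed_pred[n] for n in config.observed}, config.observed
        )
        report.append(f"{'Response':<10}{'Expected':>12}{'Observed':>12}{'%bias':>9}")
        for rec in records:
            report.append(
                f"{rec.response_name:<10}{rec.expected:>12.3f}"
                f"{rec.observed:>12.3f}{rec.percent_bias:>8.2f}%"
            )
    else:
        records = []

    nca_df = None
    if pk_csv is not None:
        log.info("running NCA on %s", pk_csv)
        profiles = _stage("nca", "check the concentration CSV columns")(
            read_concentration_csv
        )(pk_csv)
        nca_df = nca_table(profiles, lambda_points=config.lambda_points)
        summary = group_summary(profiles, lambda_points=config.lambda_points)
        nca_df.to_csv(out / "nca.csv", index=False)
        summary.to_csv(out / "nca_group_summary.csv", index=False)
        report.append("NCA group summary (mean, sem):")
        report.append(summary.to_string(index=False))

    (out / "report.txt").write_text("\n\n".join(report) + "\n")
    return {
        "table": table,
        "models": models,
        "optimization": result,
        "validation": records,
        "nca": nca_df,
        "out_dir": out,
    }
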