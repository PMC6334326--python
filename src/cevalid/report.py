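"""End-to-end validation pipeline and the roll-up report.

`run_full_validation` executes simulate → peak metrology → validation
statistics → robustness under one master seed, and rolls the results into a
`ValidationReport` shaped like a standard method-validation summary table:
content, linearity, precision, accuracy, LOD/LOQ, system suitability and the
robustness verdict.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import robustness as rb
from . import stats
from .config import PipelineConfig, SimulationConfig
from .peaks import measure_run
from .simulate import (
    simulate_calibration_study,
    simulate_electropherogram,
    simulate_sst_study,
    simulate_robustness_study,
)

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage of the validation pipeline failed."""


def config_hash(config: PipelineConfig) -> str:
    """Short stable digest of the full pipeline configuration."""
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:16]


@dataclasses.dataclass
class ValidationReport:
    """Validation summary: every numeric field traces to one stage output."""

    content_percent: float
    content_rsd_percent: float
    linearity: dict  # equation, slope, intercept, r_squared, range_ug_ml
    anova: list[dict]  # five-row partition
    repeatability_rsd_percent: float
    intermediate_precision: dict  # day_means_percent, rsd_percent
    accuracy: dict  # mean_recovery_percent, rsd_percent, levels
    lod_ug_ml: float
    loq_ug_ml: float
    sst: list[dict]
    robustness: dict  # s_statistic, criterion, overall_robust, table
    provenance: dict  # schema_version, config_hash, seed, timestamp

    def to_dict(self, include_timestamp: bool = True) -> dict:
        d = dataclasses.asdict(self)
        if not include_timestamp:
            d["provenance"] = {
                k: v for k, v in d["provenance"].items() if k != "timestamp"
            }
        return d

    def to_json(self, include_timestamp: bool = True) -> str:
        return json.dumps(self.to_dict(include_timestamp), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        d = json.loads(text)
        d.setdefault("provenance", {}).setdefault("timestamp", None)
        return cls(**d)

    def render_text(self) -> str:
        lin = self.linearity
        ip = self.intermediate_precision
        acc = self.accuracy
        lines = [
            "Capillary-electrophoresis method validation",
            "=" * 43,
            f"Content of analyte       {self.content_percent:.2f}%  (RSD {self.content_rsd_percent:.2f}%)",
            f"Linearity                {lin['equation']}  R^2 = {lin['r_squared']:.4f}"
            f"  ({lin['range_ug_ml'][0]:.0f} to {lin['range_ug_ml'][1]:.0f} ug/mL)",
            f"Repeatability            RSD = {self.repeatability_rsd_percent:.2f}%",
            "Intermediate precision   "
            + "; ".join(
                f"day {i + 1}: {m:.2f}%" for i, m in enumerate(ip["day_means_percent"])
            )
            + f" - RSD = {ip['rsd_percent']:.2f}%",
            f"Accuracy                 {acc['mean_recovery_percent']:.2f}%, RSD = {acc['rsd_percent']:.2f}%",
            f"LOD                      {self.lod_ug_ml:.2f} ug/mL",
            f"LOQ                      {self.loq_ug_ml:.2f} ug/mL",
            f"Robustness               {'robust' if self.robustness['overall_robust'] else 'NOT robust'}"
            f"  (criterion +1: {self.robustness['criterion']['1']:.2f};"
            f" -1: {self.robustness['criterion']['-1']:.2f})",
            "",
            "System suitability (RSD %):",
        ]
        for row in self.sst:
            lines.append(
                f"  {row['metric']:<16} mean {row['mean']:>12.2f}  rsd {row['rsd_percent']:.2f}%"
                f"  {'pass' if row['passed'] else 'FAIL'}"
            )
        prov = self.provenance
        lines.append("")
        lines.append(f"config {prov['config_hash']}  seed {prov['seed']}")
        return "\n".join(lines)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reported with stage context
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def _measure_areas(runs, min_height: float) -> list[float]:
    return [measure_run(eg, min_height).corrected_area for eg in runs]


@_stage("calibration")
def _calibration(sim: SimulationConfig, min_height: float, alpha: float):
    runs = simulate_calibration_study(sim)
    x = [eg.metadata["nominal_conc_ug_ml"] for eg in runs]
    y = _measure_areas(runs, min_height)
    data = stats.CalibrationDataset.from_points(x, y)
    fit = stats.fit_calibration(data)
    anova = stats.linearity_anova(data, alpha=alpha)
    limits = stats.lod_loq(fit.residual_sd, fit.slope, "residual-sd")
    return data, fit, anova, limits


def _contents(
    sim: SimulationConfig, seeds, n: int, ref_area: float, min_height: float
) -> list[float]:
    """Assay ``n`` sample determinations at 100 µg/mL against a reference area."""
    out = []
    for i in range(n):
        eg = simulate_electropherogram(sim, 100.0, int(seeds[i]))
        a_s = measure_run(eg, min_height).corrected_area
        out.append(stats.assay_content(a_s, ref_area, 100.0, 100.0).cs_percent)
    return out


def run_full_validation(
    config: PipelineConfig | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> ValidationReport:
    """Run every validation stage and return the roll-up report.

    ``seed`` overrides the master simulation seed; every stage derives its
    own sub-seeds deterministically from it, so identical config + seed
    yields an identical report (up to the timestamp).
    """
    config = config or PipelineConfig()
    master = int(seed if seed is not None else config.simulation.seed)
    ss = np.random.SeedSequence(master)
    stage_seeds = ss.generate_state(8, dtype=np.uint32)
    mh = config.min_peak_height

    def sim_with(seed_val: int) -> SimulationConfig:
        return config.simulation.model_copy(update={"seed": int(seed_val)})

    # 1. calibration: fit, lack-of-fit ANOVA, LOD/LOQ
    data, fit, anova, limits = _calibration(sim_with(stage_seeds[0]), mh, config.alpha)

    # 2. system suitability
    @_stage("system suitability")
    def _sst():
        runs = simulate_sst_study(sim_with(stage_seeds[1]), config.sst_replicates)
        peaks = [measure_run(eg, mh) for eg in runs]
        return stats.sst_summary(peaks, rsd_limit=config.rsd_limit)

    sst_table = _sst()

    # 3. content vs reference standard, in replicate
    @_stage("content")
    def _content():
        ref_seeds = np.random.SeedSequence(int(stage_seeds[2])).generate_state(
            config.content_replicates
        )
        ref_areas = [
            measure_run(
                simulate_electropherogram(sim_with(0), 100.0, int(s)), mh
            ).corrected_area
            for s in ref_seeds
        ]
        ref_area = float(np.mean(ref_areas))
        sample_seeds = np.random.SeedSequence(int(stage_seeds[3])).generate_state(
            config.content_replicates
        )
        contents = _contents(
            sim_with(0), sample_seeds, config.content_replicates, ref_area, mh
        )
        prec = stats.rsd(contents)
        return ref_area, prec

    ref_area, content_prec = _content()

    # 4. repeatability: seven determinations at the median concentration
    @_stage("repeatability")
    def _repeat():
        seeds = np.random.SeedSequence(int(stage_seeds[4])).generate_state(
            config.repeatability_replicates
        )
        vals = _contents(
            sim_with(0), seeds, config.repeatability_replicates, ref_area, mh
        )
        return stats.rsd(vals)

    repeat_prec = _repeat()

    # 5. intermediate precision: triplicate content on separate days
    @_stage("intermediate precision")
    def _interday():
        day_means = []
        day_seed_roots = np.random.SeedSequence(int(stage_seeds[5])).generate_state(
            config.precision_days
        )
        for day_root in day_seed_roots:
            seeds = np.random.SeedSequence(int(day_root)).generate_state(
                config.content_replicates
            )
            vals = _contents(
                sim_with(0), seeds, config.content_replicates, ref_area, mh
            )
            day_means.append(float(np.mean(vals)))
        return day_means, stats.intermediate_precision(day_means)

    day_means, interday_prec = _interday()

    # 6. accuracy by standard-addition recovery
    @_stage("recovery")
    def _recovery():
        level_rows = []
        roots = np.random.SeedSequence(int(stage_seeds[6])).generate_state(
            len(config.recovery_levels) + 1
        )

        def measured_conc(conc: float, root: int) -> float:
            seeds = np.random.SeedSequence(int(root)).generate_state(
                config.content_replicates
            )
            areas = [
                measure_run(
                    simulate_electropherogram(sim_with(0), conc, int(s)), mh
                ).corrected_area
                for s in seeds
            ]
            return (float(np.mean(areas)) - fit.intercept) / fit.slope

        cu_nominal = config.recovery_levels[0].cu
        cu_meas = measured_conc(cu_nominal, int(roots[0]))
        for lvl, root in zip(config.recovery_levels, roots[1:]):
            cf_meas = measured_conc(lvl.cu + lvl.ca, int(root))
            res = stats.recovery(cf_meas, cu_meas, lvl.ca)
            level_rows.append(
                {
                    "label": lvl.label,
                    "cu_ug_ml": lvl.cu,
                    "ca_ug_ml": lvl.ca,
                    "cf_measured_ug_ml": res.cf,
                    "recovery_percent": res.r_percent,
                }
            )
        prec = stats.rsd([r["recovery_percent"] for r in level_rows])
        return level_rows, prec

    recovery_rows, recovery_prec = _recovery()

    # 7. robustness screening
    @_stage("robustness")
    def _robust():
        design = rb.canonical_design()
        spec = config.robustness.model_copy(update={"seed": int(stage_seeds[7])})
        results = simulate_robustness_study(design, spec)
        eff = rb.effects(design, results)
        return results, eff, rb.assess(eff)

    rb_results, rb_effects, rb_assessment = _robust()

    report = ValidationReport(
        content_percent=content_prec.mean,
        content_rsd_percent=content_prec.rsd_percent,
        linearity={
            "equation": fit.equation(),
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "residual_sd": fit.residual_sd,
            "range_ug_ml": [
                float(min(config.simulation.calibration_levels)),
                float(max(config.simulation.calibration_levels)),
            ],
        },
        anova=anova.to_frame().replace({np.nan: None}).to_dict(orient="records"),
        repeatability_rsd_percent=repeat_prec.rsd_percent,
        intermediate_precision={
            "day_means_percent": day_means,
            "rsd_percent": interday_prec.rsd_percent,
        },
        accuracy={
            "mean_recovery_percent": recovery_prec.mean,
            "rsd_percent": recovery_prec.rsd_percent,
            "levels": recovery_rows,
        },
        lod_ug_ml=limits.lod,
        loq_ug_ml=limits.loq,
        sst=sst_table.to_dict(orient="records"),
        robustness={
            "s_statistic": {str(k): v for k, v in rb_assessment.s_statistic.items()},
            "criterion": {str(k): v for k, v in rb_assessment.criterion.items()},
            "overall_robust": rb_assessment.overall_robust,
            "table": rb_assessment.table.to_dict(orient="records"),
        },
        provenance={
            "schema_version": SCHEMA_VERSION,
            "config_hash": config_hash(config),
            "seed": master,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    )

    if outdir is not None:
        _write_outputs(
            Path(outdir), config, report, data, fit, anova, sst_table,
            recovery_rows, rb_results, rb_assessment,
        )
    return report


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)


def _write_outputs(
    outdir: Path,
    config: PipelineConfig,
    report: ValidationReport,
    data: stats.CalibrationDataset,
    fit: stats.LinearFit,
    anova: stats.AnovaPartition,
    sst_table: pd.DataFrame,
    recovery_rows: list[dict],
    rb_results: pd.DataFrame,
    rb_assessment: rb.YoudenAssessment,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    head = f"config_hash={report.provenance['config_hash']} seed={report.provenance['seed']}"
    _write_csv(anova.to_frame(), outdir / "linearity.csv", head)
    with open(outdir / "fit.json", "w") as fh:
        json.dump(
            {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "residual_sd": fit.residual_sd,
                "n": fit.n,
                "config_hash": report.provenance["config_hash"],
            },
            fh,
            indent=1,
        )
    x, y = data.points()
    _write_csv(
        pd.DataFrame({"conc_ug_ml": x, "corrected_area": y}),
        outdir / "calibration_points.csv",
        head,
    )
    _write_csv(
        pd.DataFrame(
            [
                {
                    "content_percent": report.content_percent,
                    "rsd_percent": report.content_rsd_percent,
                }
            ]
        ),
        outdir / "content.csv",
        head,
    )
    _write_csv(pd.DataFrame(recovery_rows), outdir / "recovery.csv", head)
    _write_csv(sst_table, outdir / "sst.csv", head)
    overall = pd.DataFrame(
        [
            {
                "factor": "overall",
                "side": 0,
                "d": np.nan,
                "s_statistic": np.nan,
                "criterion": np.nan,
                "robust": rb_assessment.overall_robust,
            }
        ]
    )
    _write_csv(
        pd.concat([rb_assessment.table, overall], ignore_index=True),
        outdir / "robustness.csv",
        head,
    )
    _write_csv(rb_results, outdir / "robustness_runs.csv", head)
    with open(outdir / "report.json", "w") as fh:
        fh.write(report.to_json())
    with open(outdir / "report.txt", "w") as fh:
        fh.write(report.render_text() + "\n")
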