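"""End-to-end analysis runner.

Reproduces the study shape: ingest or simulate charts, apply the
eligibility screen, compute full-mouth reference diagnoses under both case
definitions, diagnose under each partial recording protocol, and write the
indicator tables, the staging reclassification cross-tab and a
machine-readable run log. All outputs are deterministic functions of
(input, config, seed); the run log deliberately contains no timestamps so
repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .case_definitions import (
    CDC_AAP_2012,
    EFP_AAP_2018,
    Params2012,
    Params2018,
)
from .chart_model import (
    ELIGIBILITY_REASONS,
    EligibilityReport,
    PeriodontalChart,
    check_eligibility,
    read_charts,
)
from .performance import (
    crosstab_to_edges,
    evaluate_protocols,
    reclassification_table,
    tidy_indicator_table,
)
from .prp import diagnose_under_protocol, make_protocol
from .synthetic_data import SyntheticConfig, generate_population, write_population

__all__ = ["RunConfig", "RunResult", "flow_report", "run"]

DEFAULT_PROTOCOLS = ("FULL_MOUTH", "RAMFJORD", "CPITN", "MB_B", "MB_B_DB", "MB_B_DL")

PRESENCE_INDICATORS = (
    "sensitivity", "specificity", "accuracy", "precision", "youden",
    "f1", "mcc", "auc", "dor", "log10_dor",
)
STAGING_INDICATORS = (
    "staging_auc",
    "precision_stage_0", "precision_stage_1",
    "precision_stage_2", "precision_stage_3",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``input_csv`` or ``synthetic`` must be set. ``seed``
    drives all randomness (only the synthetic generator uses any).
    """

    input_csv: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    protocols: tuple[str, ...] = DEFAULT_PROTOCOLS
    definitions: tuple[str, ...] = (EFP_AAP_2018, CDC_AAP_2012)
    ci_level: float = 0.95
    detectable_cal_threshold_mm: int = 1
    min_age: int = 30
    out_dir: str = "perioprp_out"
    seed: int = 0
    dialect: str = "canonical"

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("set exactly one of input_csv or synthetic")
        if not self.protocols or not self.definitions:
            raise ValueError("need at least one protocol and one definition")
        if self.detectable_cal_threshold_mm < 1:
            raise ValueError("detectable CAL threshold must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class RunResult:
    flow: dict[str, int]
    indicator_table: pd.DataFrame   # wide, one row per definition x protocol
    presence_tidy: pd.DataFrame
    staging_tidy: pd.DataFrame
    reclassification: np.ndarray    # 4x4, rows 2012 stage, cols 2018 stage
    charts: list[PeriodontalChart]
    eligible: list[PeriodontalChart]
    out_dir: Optional[Path]


def flow_report(reports: Sequence[EligibilityReport]) -> dict[str, int]:
    """Participant-flow counts; multi-reason exclusions are attributed to
    the first reason in the fixed order (age, medical exclusion, incomplete
    periodontal status, edentulous)."""
    if not reports:
        raise ValueError("need at least one eligibility report")
    counts = {f"excluded_{r}": 0 for r in ELIGIBILITY_REASONS}
    eligible = 0
    for rep in reports:
        if rep.eligible:
            eligible += 1
        else:
            counts[f"excluded_{rep.reasons[0]}"] += 1
    out = {"initial": len(reports)}
    out.update(counts)
    out["excluded_total"] = len(reports) - eligible
    out["final"] = eligible
    return out


def _percent_table(wide: pd.DataFrame) -> pd.DataFrame:
    """Reporting table on the printed scale: proportion indicators as
    percentages rounded to 1 decimal, DOR-scale values to 2 decimals."""
    rows = []
    pct = ("sensitivity", "specificity", "accuracy", "precision", "youden",
           "f1", "mcc", "auc", "staging_auc",
           "precision_stage_0", "precision_stage_1",
           "precision_stage_2", "precision_stage_3")
    for _, r in wide.iterrows():
        row = {"definition": r["definition"], "protocol": r["protocol"]}
        for name in pct:
            v = r.get(name, float("nan"))
            row[name] = round(100 * v, 1) if pd.notna(v) else float("nan")
        for name in ("dor", "log10_dor"):
            v = r.get(name, float("nan"))
            row[name] = round(v, 2) if pd.notna(v) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def _library_versions() -> dict[str, str]:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "perioprp": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def run(config: RunConfig, write: bool = True) -> RunResult:
    """Execute the full analysis and (optionally) write the artifact bundle.

    Artifacts: eligibility_flow.csv, presence_indicators.csv and
    staging_performance.csv (tidy), indicator_table.csv (wide, full
    precision), report_percent.csv (printed scale), reclassification.csv
    (4x4 staging cross-tab 2012 -> 2018) with reclassification_edges.csv,
    and run_log.json.
    """
    if config.synthetic is not None:
        charts, classes = generate_population(config.synthetic, seed=config.seed)
    else:
        charts = read_charts(config.input_csv, dialect=config.dialect)
        classes = None

    reports = [check_eligibility(c, min_age=config.min_age) for c in charts]
    flow = flow_report(reports)
    eligible = [c for c, r in zip(charts, reports) if r.eligible]
    if not eligible:
        raise ValueError("no eligible participants after the eligibility screen")

    params_2018 = Params2018(detectable_cal_mm=config.detectable_cal_threshold_mm)
    params_2012 = Params2012()
    wide = evaluate_protocols(
        eligible,
        definitions=config.definitions,
        protocols=config.protocols,
        ci_level=config.ci_level,
        params_2012=params_2012,
        params_2018=params_2018,
    )
    tidy = tidy_indicator_table(wide)
    presence = tidy[tidy["indicator"].isin(PRESENCE_INDICATORS)].reset_index(drop=True)
    staging = tidy[tidy["indicator"].isin(STAGING_INDICATORS)].reset_index(drop=True)

    full = make_protocol("FULL_MOUTH")
    stages_2012 = [
        diagnose_under_protocol(c, full, CDC_AAP_2012, params_2012, params_2018).stage
        for c in eligible
    ]
    stages_2018 = [
        diagnose_under_protocol(c, full, EFP_AAP_2018, params_2012, params_2018).stage
        for c in eligible
    ]
    recl = reclassification_table(stages_2012, stages_2018)

    out_dir: Optional[Path] = None
    if write:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([flow]).to_csv(out_dir / "eligibility_flow.csv", index=False)
        wide.to_csv(out_dir / "indicator_table.csv", index=False)
        presence.to_csv(out_dir / "presence_indicators.csv", index=False)
        staging.to_csv(out_dir / "staging_performance.csv", index=False)
        _percent_table(wide).to_csv(out_dir / "report_percent.csv", index=False)
        pd.DataFrame(
            recl,
            index=[f"stage_2012_{i}" for i in range(4)],
            columns=[f"stage_2018_{j}" for j in range(4)],
        ).to_csv(out_dir / "reclassification.csv")
        crosstab_to_edges(recl).to_csv(
            out_dir / "reclassification_edges.csv", index=False
        )
        if config.synthetic is not None and classes is not None:
            write_population(
                charts, classes,
                out_dir / "population.csv", out_dir / "latent_classes.csv",
            )
        log = {
            "config": {
                "input_csv": config.input_csv,
                "synthetic": (
                    json.loads(config.synthetic.to_json())
                    if config.synthetic is not None else None
                ),
                "protocols": list(config.protocols),
                "definitions": list(config.definitions),
                "ci_level": config.ci_level,
                "detectable_cal_threshold_mm": config.detectable_cal_threshold_mm,
                "min_age": config.min_age,
                "dialect": config.dialect,
            },
            "seed": config.seed,
            "flow": flow,
            "library_versions": _library_versions(),
        }
        (out_dir / "run_log.json").write_text(
            json.dumps(log, indent=2, sort_keys=True) + "\n"
        )

    return RunResult(
        flow=flow,
        indicator_table=wide,
        presence_tidy=presence,
        staging_tidy=staging,
        reclassification=recl,
        charts=charts,
        eligible=eligible,
        out_dir=out_dir,
    )
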