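"""Synthetic NHANES-like periodontal chart populations.

The generator draws a latent severity class per participant (healthy, mild,
moderate, severe), removes teeth with a class-dependent probability, and
produces integer-mm site measurements from a latent Gaussian liability:

    CAL_site = round(class mean + tooth effect + site noise), floored at 0
    PPD_site = round(shrink * CAL_site + offset noise), in [0, CAL_site + 3]

The tooth effect (shared by the six sites of a tooth) plus independent site
noise gives within-tooth correlation; class means live on the unbounded
liability scale (the healthy mean is negative, so healthy mouths emit mostly
CAL = 0 after rounding and truncation). The latent class only drives
generation — the pipeline's ground truth is always the full-mouth rule-based
diagnosis.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chart_model import (
    ALL_FDI,
    SITE_CODES,
    CoordinateError,
    PeriodontalChart,
    SiteMeasurement,
    ToothRecord,
    write_charts,
)

__all__ = [
    "SEVERITY_CLASSES",
    "SyntheticConfig",
    "generate_population",
    "make_fixture_chart",
    "write_population",
]

SEVERITY_CLASSES: tuple[str, ...] = ("healthy", "mild", "moderate", "severe")

#: Bump when default parameters or generation logic change incompatibly.
CONFIG_SCHEMA_VERSION = 1


def _default_mixture() -> dict[str, float]:
    return {"healthy": 0.45, "mild": 0.20, "moderate": 0.20, "severe": 0.15}


def _default_tooth_loss() -> dict[str, float]:
    return {"healthy": 0.00, "mild": 0.02, "moderate": 0.05, "severe": 0.12}


def _default_cal_means() -> dict[str, float]:
    return {"healthy": -2.5, "mild": 0.2, "moderate": 1.3, "severe": 3.0}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic chart population.

    ``cal_mean_per_class`` is on the latent liability scale in mm (values
    below zero are legal and produce mostly-zero recorded CAL);
    ``within_tooth_corr`` is the correlation between two sites of one tooth
    induced by the shared tooth effect; ``ppd_shrink``/``ppd_offset_*``
    control how pocket depth tracks attachment loss.
    """

    n_participants: int = 2000
    class_mixture: dict[str, float] = field(default_factory=_default_mixture)
    tooth_loss_base: float = 0.02
    tooth_loss_per_class: dict[str, float] = field(default_factory=_default_tooth_loss)
    cal_mean_per_class: dict[str, float] = field(default_factory=_default_cal_means)
    site_sd: float = 1.0
    within_tooth_corr: float = 0.45
    ppd_shrink: float = 0.6
    ppd_offset_mean: float = 1.2
    ppd_offset_sd: float = 0.7
    age_range: tuple[int, int] = (30, 80)
    site_missing_rate: float = 0.0
    max_mm: int = 19
    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if set(self.class_mixture) != set(SEVERITY_CLASSES):
            raise ValueError(f"class_mixture must have keys {SEVERITY_CLASSES}")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mixture must sum to 1, got {total}")
        if any(not 0 <= p <= 1 for p in self.class_mixture.values()):
            raise ValueError("mixture probabilities must be in [0, 1]")
        if self.site_sd < 0 or self.ppd_offset_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.within_tooth_corr < 1:
            raise ValueError("within_tooth_corr must be in [0, 1)")
        if not 0 <= self.site_missing_rate < 1:
            raise ValueError("site_missing_rate must be in [0, 1)")
        for name in ("tooth_loss_base",):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (low, high) with low <= high")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        payload = json.loads(text)
        payload.pop("schema_version", None)
        if "age_range" in payload:
            payload["age_range"] = tuple(payload["age_range"])
        return cls(**payload)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def generate_population(
    cfg: SyntheticConfig, seed: Optional[int] = None
) -> tuple[list[PeriodontalChart], list[str]]:
    """Generate a chart population; returns (charts, latent class labels).

    Fully reproducible from the seed (``cfg.seed`` unless overridden).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_participants
    n_teeth, n_sites = len(ALL_FDI), len(SITE_CODES)

    probs = np.array([cfg.class_mixture[c] for c in SEVERITY_CLASSES])
    class_idx = rng.choice(len(SEVERITY_CLASSES), size=n, p=probs)
    ages = rng.integers(cfg.age_range[0], cfg.age_range[1] + 1, size=n)

    loss_inc = np.array([cfg.tooth_loss_per_class[c] for c in SEVERITY_CLASSES])
    loss_p = np.clip(cfg.tooth_loss_base + loss_inc[class_idx], 0.0, 1.0)
    present = rng.random((n, n_teeth)) >= loss_p[:, None]

    # within-tooth correlation rho from a shared tooth effect:
    # rho = tau^2 / (tau^2 + site_sd^2)
    rho = cfg.within_tooth_corr
    tau = cfg.site_sd * np.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0
    class_mean = np.array([cfg.cal_mean_per_class[c] for c in SEVERITY_CLASSES])
    tooth_effect = rng.normal(0.0, tau, size=(n, n_teeth)) if tau > 0 else np.zeros((n, n_teeth))
    site_noise = rng.normal(0.0, cfg.site_sd, size=(n, n_teeth, n_sites))
    cal_latent = class_mean[class_idx][:, None, None] + tooth_effect[:, :, None] + site_noise
    cal = np.clip(_round_half_up(cal_latent), 0, cfg.max_mm)

    ppd_noise = rng.normal(cfg.ppd_offset_mean, cfg.ppd_offset_sd, size=cal.shape)
    ppd = _round_half_up(cfg.ppd_shrink * cal + ppd_noise)
    ppd = np.clip(ppd, 0, np.minimum(cal + 3, cfg.max_mm))

    if cfg.site_missing_rate > 0:
        missing = rng.random(cal.shape) < cfg.site_missing_rate
    else:
        missing = np.zeros(cal.shape, dtype=bool)

    charts: list[PeriodontalChart] = []
    classes: list[str] = []
    for i in range(n):
        teeth: dict[int, ToothRecord] = {}
        for j, fdi in enumerate(ALL_FDI):
            if not present[i, j]:
                teeth[fdi] = ToothRecord(fdi=fdi, present=False)
                continue
            sites: dict[str, Optional[SiteMeasurement]] = {}
            for k, site in enumerate(SITE_CODES):
                if missing[i, j, k]:
                    sites[site] = None
                else:
                    sites[site] = SiteMeasurement(
                        ppd_mm=int(ppd[i, j, k]),
                        cal_mm=int(cal[i, j, k]),
                        max_mm=cfg.max_mm,
                    )
            teeth[fdi] = ToothRecord(fdi=fdi, present=True, sites=sites)
        charts.append(
            PeriodontalChart(
                participant_id=f"S{i:05d}",
                age_years=int(ages[i]),
                medically_excluded=False,
                teeth=teeth,
            )
        )
        classes.append(SEVERITY_CLASSES[class_idx[i]])
    return charts, classes


def make_fixture_chart(
    spec: Sequence[tuple[int, str, int, int]],
    participant_id: str = "fixture",
    age_years: int = 45,
) -> PeriodontalChart:
    """Deterministic hand-crafted chart: full dentition, all sites 0/0
    except the listed (tooth, site, ppd, cal) entries."""
    overrides: dict[tuple[int, str], SiteMeasurement] = {}
    for fdi, site, ppd, cal in spec:
        if fdi not in ALL_FDI:
            raise CoordinateError(f"invalid or excluded tooth {fdi}")
        if site not in SITE_CODES:
            raise CoordinateError(f"invalid site code {site!r}")
        if (fdi, site) in overrides:
            raise ValueError(f"duplicate position ({fdi}, {site})")
        overrides[(fdi, site)] = SiteMeasurement(ppd_mm=ppd, cal_mm=cal)
    zero = SiteMeasurement(ppd_mm=0, cal_mm=0)
    teeth = {
        fdi: ToothRecord(
            fdi=fdi,
            present=True,
            sites={s: overrides.get((fdi, s), zero) for s in SITE_CODES},
        )
        for fdi in ALL_FDI
    }
    return PeriodontalChart(
        participant_id=participant_id, age_years=age_years, teeth=teeth
    )


def write_population(
    charts: Sequence[PeriodontalChart],
    classes: Sequence[str],
    chart_path,
    classes_path,
) -> None:
    """Emit the canonical chart CSV plus a sidecar CSV of latent classes."""
    import pandas as pd

    if len(charts) != len(classes):
        raise ValueError("charts and classes must align")
    write_charts(charts, chart_path)
    pd.DataFrame(
        {
            "participant_id": [c.participant_id for c in charts],
            "latent_class": list(classes),
        }
    ).to_csv(classes_path, index=False)
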