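"""Periodontal chart data model, tooth/site coordinates, eligibility, and I/O.

A chart holds one participant's full dentition (28 FDI positions, third
molars excluded) with six probing sites per tooth. Each site carries probing
pocket depth (PPD) and clinical attachment loss (CAL) in integer millimetres;
a site may also be unmeasured, which is distinct from 0 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "SITE_CODES",
    "ALL_FDI",
    "THIRD_MOLARS_FDI",
    "SiteMeasurement",
    "ToothRecord",
    "PeriodontalChart",
    "EligibilityReport",
    "ChartError",
    "CoordinateError",
    "ChartParseError",
    "ChartIntegrityError",
    "universal_to_fdi",
    "check_eligibility",
    "read_charts",
    "write_charts",
]

#: The six circumferential probing sites, in conventional charting order.
SITE_CODES: tuple[str, ...] = ("MB", "B", "DB", "ML", "L", "DL")

#: The 28 eligible FDI tooth codes (second molar to second molar, four
#: quadrants). Third molars (x8) are excluded from the model entirely.
ALL_FDI: tuple[int, ...] = tuple(
    q * 10 + p for q in (1, 2, 3, 4) for p in range(1, 8)
)

THIRD_MOLARS_FDI: frozenset[int] = frozenset({18, 28, 38, 48})

#: Sentinel returned by :func:`universal_to_fdi` for third molars.
THIRD_MOLAR = "THIRD_MOLAR"

#: Measurements above this are rejected as implausible (configurable).
DEFAULT_MAX_MM = 19


class ChartError(ValueError):
    """Base class for chart validation problems."""


class CoordinateError(ChartError):
    """Invalid tooth or site coordinate."""


class ChartParseError(ChartError):
    """Malformed row in a chart file."""


class ChartIntegrityError(ChartError):
    """Structurally valid file that violates uniqueness constraints."""


def _check_mm(value: Optional[int], name: str, max_mm: int) -> Optional[int]:
    if value is None:
        return None
    if not isinstance(value, int) or isinstance(value, bool):
        raise ChartError(f"{name} must be an integer number of mm, got {value!r}")
    if value < 0:
        raise ChartError(f"{name} must be >= 0 mm, got {value}")
    if value > max_mm:
        raise ChartError(f"{name} exceeds ceiling of {max_mm} mm: {value}")
    return value


@dataclass(frozen=True)
class SiteMeasurement:
    """PPD/CAL at one probing site, integer mm; ``None`` marks an unmeasured
    quantity (distinct from 0 mm)."""

    ppd_mm: Optional[int] = None
    cal_mm: Optional[int] = None
    max_mm: int = DEFAULT_MAX_MM

    def __post_init__(self) -> None:
        _check_mm(self.ppd_mm, "ppd_mm", self.max_mm)
        _check_mm(self.cal_mm, "cal_mm", self.max_mm)

    @property
    def complete(self) -> bool:
        return self.ppd_mm is not None and self.cal_mm is not None


@dataclass(frozen=True)
class ToothRecord:
    """One tooth position: FDI code, presence flag, and its six sites.

    An absent tooth has all six sites ``None``. The ``sites`` map always has
    exactly the six canonical keys.
    """

    fdi: int
    present: bool
    sites: dict[str, Optional[SiteMeasurement]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fdi in THIRD_MOLARS_FDI:
            raise CoordinateError(f"third molar {self.fdi} cannot be stored")
        if self.fdi not in ALL_FDI:
            raise CoordinateError(f"invalid FDI code {self.fdi}")
        sites = {code: self.sites.get(code) for code in SITE_CODES}
        unknown = set(self.sites) - set(SITE_CODES)
        if unknown:
            raise CoordinateError(f"unknown site codes {sorted(unknown)}")
        if not self.present and any(m is not None for m in sites.values()):
            raise ChartError(f"absent tooth {self.fdi} has measurements")
        object.__setattr__(self, "sites", sites)

    def measurement(self, site: str) -> Optional[SiteMeasurement]:
        if site not in self.sites:
            raise CoordinateError(f"unknown site code {site!r}")
        return self.sites[site]


@dataclass(frozen=True)
class PeriodontalChart:
    """One participant's periodontal chart (28 tooth positions) + metadata."""

    participant_id: str
    age_years: int
    medically_excluded: bool = False
    teeth: dict[int, ToothRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ChartError("participant_id must be non-empty")
        teeth = dict(self.teeth)
        for fdi in ALL_FDI:
            if fdi not in teeth:
                teeth[fdi] = ToothRecord(fdi=fdi, present=False)
        extra = set(teeth) - set(ALL_FDI)
        if extra:
            raise CoordinateError(f"invalid tooth positions {sorted(extra)}")
        object.__setattr__(self, "teeth", {fdi: teeth[fdi] for fdi in ALL_FDI})

    @property
    def present_teeth(self) -> list[int]:
        return [fdi for fdi in ALL_FDI if self.teeth[fdi].present]

    @property
    def is_edentulous(self) -> bool:
        return not any(t.present for t in self.teeth.values())

    @property
    def is_complete(self) -> bool:
        """True when every present tooth has PPD and CAL at all six sites."""
        for tooth in self.teeth.values():
            if not tooth.present:
                continue
            for m in tooth.sites.values():
                if m is None or not m.complete:
                    return False
        return True

    def site(self, fdi: int, site: str) -> Optional[SiteMeasurement]:
        if fdi not in self.teeth:
            raise CoordinateError(f"invalid FDI code {fdi}")
        return self.teeth[fdi].measurement(site)


@dataclass(frozen=True)
class EligibilityReport:
    participant_id: str
    eligible: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.eligible != (len(self.reasons) == 0):
            raise ChartError("eligible must be true iff reasons is empty")


# Reasons in the fixed attribution order used by the flow report.
ELIGIBILITY_REASONS = (
    "age_under_30",
    "medical_exclusion",
    "incomplete_periodontal_status",
    "edentulous",
)


def universal_to_fdi(universal: int) -> int | str:
    """Map Universal (ADA) tooth number 1-32 to an FDI code.

    Universal numbering runs 1-16 across the maxilla from the patient's
    upper-right third molar to the upper-left third molar, then 17-32 across
    the mandible from lower-left third molar to lower-right third molar.
    Third molars (Universal 1, 16, 17, 32) return the ``THIRD_MOLAR`` marker
    because the model excludes them.
    """
    if not isinstance(universal, int) or isinstance(universal, bool):
        raise CoordinateError(f"universal number must be an integer, got {universal!r}")
    if not 1 <= universal <= 32:
        raise CoordinateError(f"universal number out of range 1-32: {universal}")
    if universal <= 8:
        fdi = 10 + (9 - universal)
    elif universal <= 16:
        fdi = 20 + (universal - 8)
    elif universal <= 24:
        fdi = 30 + (25 - universal)
    else:
        fdi = 40 + (universal - 24)
    return THIRD_MOLAR if fdi in THIRD_MOLARS_FDI else fdi


def check_eligibility(chart: PeriodontalChart, min_age: int = 30) -> EligibilityReport:
    """Apply the study's eligibility screen to one chart.

    Participants are excluded when younger than ``min_age``, medically
    excluded from the periodontal exam, with an incomplete periodontal status
    (some present tooth missing a PPD or CAL value at any site), or
    edentulous. All applicable reasons are reported.
    """
    reasons: list[str] = []
    if chart.age_years < min_age:
        reasons.append("age_under_30")
    if chart.medically_excluded:
        reasons.append("medical_exclusion")
    if chart.is_edentulous:
        reasons.append("edentulous")
    elif not chart.is_complete:
        reasons.append("incomplete_periodontal_status")
    reasons.sort(key=ELIGIBILITY_REASONS.index)
    return EligibilityReport(
        participant_id=chart.participant_id,
        eligible=not reasons,
        reasons=tuple(reasons),
    )


# ---------------------------------------------------------------------------
# Long-format CSV I/O
# ---------------------------------------------------------------------------

_CANONICAL_COLUMNS = [
    "participant_id",
    "age_years",
    "medically_excluded",
    "tooth_fdi",
    "present",
    "site",
    "ppd_mm",
    "cal_mm",
]


def _parse_mm(raw, line: int, name: str, strict: bool) -> Optional[int]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ChartParseError(f"line {line}: {name} not numeric: {raw!r}") from None
    if value != int(value):
        if strict:
            raise ChartParseError(
                f"line {line}: {name} must be integer mm in strict mode: {raw!r}"
            )
        value = math.floor(value + 0.5)  # round half up in lenient mode
    return int(value)


def read_charts(
    path,
    dialect: str = "canonical",
    strict: bool = True,
    max_mm: int = DEFAULT_MAX_MM,
) -> list[PeriodontalChart]:
    """Read periodontal charts from a long-format CSV.

    ``dialect='canonical'`` expects a ``tooth_fdi`` column; rows naming third
    molars are a parse error. ``dialect='nhanes_universal'`` expects
    ``tooth_universal`` (1-32) instead and silently drops third-molar rows.
    Duplicate (participant, tooth, site) rows raise ``ChartIntegrityError``.
    """
    if dialect not in ("canonical", "nhanes_universal"):
        raise ValueError(f"unknown dialect {dialect!r}")
    tooth_col = "tooth_fdi" if dialect == "canonical" else "tooth_universal"
    expected = [tooth_col if c == "tooth_fdi" else c for c in _CANONICAL_COLUMNS]

    df = pd.read_csv(path, dtype={"participant_id": str, "site": str})
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise ChartParseError(f"missing columns {missing_cols}")

    charts: list[PeriodontalChart] = []
    seen_participants: set[str] = set()
    # group_keys preserves file order of participants
    order = df["participant_id"].drop_duplicates().tolist()
    grouped = dict(tuple(df.groupby("participant_id", sort=False)))
    for pid in order:
        rows = grouped[pid]
        if pid in seen_participants:  # pragma: no cover - drop_duplicates guards
            raise ChartIntegrityError(f"participant {pid} appears in two blocks")
        seen_participants.add(pid)
        meta = rows.iloc[0]
        try:
            age = int(meta["age_years"])
            med = bool(int(meta["medically_excluded"]))
        except (TypeError, ValueError):
            raise ChartParseError(
                f"line {meta.name + 2}: bad metadata for participant {pid}"
            ) from None

        sites: dict[int, dict[str, Optional[SiteMeasurement]]] = {}
        present: dict[int, bool] = {}
        seen_keys: set[tuple[int, str]] = set()
        for idx, row in rows.iterrows():
            line = idx + 2  # header + 1-based
            raw_tooth = row[tooth_col]
            try:
                tooth = int(raw_tooth)
            except (TypeError, ValueError):
                raise ChartParseError(f"line {line}: bad tooth code {raw_tooth!r}") from None
            if dialect == "nhanes_universal":
                fdi = universal_to_fdi(tooth)
                if fdi == THIRD_MOLAR:
                    continue
            else:
                if tooth in THIRD_MOLARS_FDI:
                    raise ChartParseError(
                        f"line {line}: third molar {tooth} not allowed"
                    )
                if tooth not in ALL_FDI:
                    raise ChartParseError(f"line {line}: invalid FDI code {tooth}")
                fdi = tooth
            site = row["site"]
            if site not in SITE_CODES:
                raise ChartParseError(f"line {line}: unknown site code {site!r}")
            key = (fdi, site)
            if key in seen_keys:
                raise ChartIntegrityError(
                    f"duplicate measurement for participant {pid}, tooth {fdi}, "
                    f"site {site}"
                )
            seen_keys.add(key)
            try:
                tooth_present = bool(int(row["present"]))
            except (TypeError, ValueError):
                raise ChartParseError(f"line {line}: bad present flag") from None
            if fdi in present and present[fdi] != tooth_present:
                raise ChartIntegrityError(
                    f"participant {pid}, tooth {fdi}: inconsistent present flag"
                )
            present[fdi] = tooth_present
            ppd = _parse_mm(row["ppd_mm"], line, "ppd_mm", strict)
            cal = _parse_mm(row["cal_mm"], line, "cal_mm", strict)
            if ppd is None and cal is None:
                measurement = None
            else:
                try:
                    measurement = SiteMeasurement(ppd_mm=ppd, cal_mm=cal, max_mm=max_mm)
                except ChartError as exc:
                    raise ChartParseError(f"line {line}: {exc}") from None
            if not tooth_present and measurement is not None:
                raise ChartParseError(
                    f"line {line}: absent tooth {fdi} has measurements"
                )
            sites.setdefault(fdi, {})[site] = measurement

        teeth = {
            fdi: ToothRecord(fdi=fdi, present=present.get(fdi, False),
                             sites=sites.get(fdi, {}))
            for fdi in ALL_FDI
        }
        charts.append(
            PeriodontalChart(
                participant_id=str(pid),
                age_years=age,
                medically_excluded=med,
                teeth=teeth,
            )
        )
    return charts


def write_charts(charts: Iterable[PeriodontalChart], path) -> None:
    """Write charts as canonical long-format CSV (one row per tooth-site).

    ``read_charts(write_charts(x))`` round-trips exactly: every tooth
    position emits all six sites, with empty cells for unmeasured values.
    """
    records = []
    for chart in charts:
        for fdi in ALL_FDI:
            tooth = chart.teeth[fdi]
            for site in SITE_CODES:
                m = tooth.sites[site]
                records.append(
                    {
                        "participant_id": chart.participant_id,
                        "age_years": chart.age_years,
                        "medically_excluded": int(chart.medically_excluded),
                        "tooth_fdi": fdi,
                        "present": int(tooth.present),
                        "site": site,
                        "ppd_mm": "" if m is None or m.ppd_mm is None else m.ppd_mm,
                        "cal_mm": "" if m is None or m.cal_mm is None else m.cal_mm,
                    }
                )
    df = pd.DataFrame.from_records(records, columns=_CANONICAL_COLUMNS)
    df.to_csv(path, index=False)
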