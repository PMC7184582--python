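"""Rule engines for the 2012 CDC/AAP and 2018 EFP/AAP periodontitis case
definitions, evaluable on any site selection.

Both definitions are predicates over the per-site clinical attachment loss
(CAL) and probing pocket depth (PPD) of a chart, restricted to an arbitrary
set of (tooth, site) positions — so the same engine serves full-mouth
diagnosis and every partial recording protocol. A diagnosis is a case flag
plus an ordinal stage: 0 none, 1 mild, 2 moderate, 3 severe (stages III and
IV of the 2018 scheme are collapsed into "severe").

2012 CDC/AAP (interproximal sites only):
  severe   — >=2 interproximal sites with CAL >= 6 mm on >=2 distinct teeth
             AND >=1 interproximal site with PPD >= 5 mm;
  moderate — >=2 interproximal sites with CAL >= 4 mm on >=2 distinct teeth
             OR >=2 interproximal sites with PPD >= 5 mm on >=2 distinct
             teeth;
  mild     — >=2 interproximal sites with CAL >= 3 mm AND (>=2 interproximal
             sites with PPD >= 4 mm on >=2 distinct teeth OR >=1 site with
             PPD >= 5 mm).

2018 EFP/AAP:
  case if (a) interdental CAL at or above a detectability threshold
  (default 1 mm) at >=2 non-adjacent teeth, or (b) at >=2 teeth a mid
  (buccal/oral) site shows CAL >= 3 mm with PPD > 3 mm at that same site.
  Stage from the maximum interdental CAL over the selected sites:
  1-2 mm -> mild, 3-4 mm -> moderate, >=5 mm -> severe; cases established
  through pathway (b) alone, with no interdental CAL, are staged mild.

Missing measurements never satisfy any criterion and never contribute to the
site of greatest loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, Optional, Tuple

from .chart_model import (
    ALL_FDI,
    SITE_CODES,
    CoordinateError,
    PeriodontalChart,
)

__all__ = [
    "CDC_AAP_2012",
    "EFP_AAP_2018",
    "Diagnosis",
    "SiteSelector",
    "SelectorError",
    "interproximal_sites",
    "mid_sites",
    "non_adjacent",
    "classify_2012",
    "classify_2018",
    "max_interdental_cal",
]

CDC_AAP_2012 = "CDC_AAP_2012"
EFP_AAP_2018 = "EFP_AAP_2018"

STAGE_NONE, STAGE_MILD, STAGE_MODERATE, STAGE_SEVERE = 0, 1, 2, 3


class SelectorError(ValueError):
    """Raised when a classifier is given an unusable site selection."""


def interproximal_sites() -> frozenset[str]:
    """The four mesial/distal (interdental) probing sites."""
    return frozenset({"MB", "DB", "ML", "DL"})


def mid_sites() -> frozenset[str]:
    """The mid-buccal and mid-lingual (oral) probing sites."""
    return frozenset({"B", "L"})


@dataclass(frozen=True)
class SiteSelector:
    """A non-empty subset of the 28x6 (tooth, site) grid."""

    included: FrozenSet[Tuple[int, str]]

    def __post_init__(self) -> None:
        included = frozenset(self.included)
        if not included:
            raise SelectorError("site selector must be non-empty")
        for fdi, site in included:
            if fdi not in ALL_FDI:
                raise CoordinateError(f"invalid FDI code {fdi} in selector")
            if site not in SITE_CODES:
                raise CoordinateError(f"invalid site code {site!r} in selector")
        object.__setattr__(self, "included", included)

    @classmethod
    def from_teeth_and_sites(
        cls, teeth: Iterable[int], sites: Iterable[str]
    ) -> "SiteSelector":
        return cls(frozenset((t, s) for t in teeth for s in sites))

    @classmethod
    def full_mouth(cls) -> "SiteSelector":
        return cls.from_teeth_and_sites(ALL_FDI, SITE_CODES)

    def __contains__(self, position: Tuple[int, str]) -> bool:
        return position in self.included

    def issubset(self, other: "SiteSelector") -> bool:
        return self.included <= other.included


@dataclass(frozen=True)
class Diagnosis:
    definition: str
    is_case: bool
    stage: int

    def __post_init__(self) -> None:
        if self.stage not in (0, 1, 2, 3):
            raise ValueError(f"stage must be in 0..3, got {self.stage}")
        if self.is_case != (self.stage >= 1):
            raise ValueError("is_case must hold exactly when stage >= 1")


# Anatomical arch sequences: right second molar -> ... -> left second molar.
_UPPER_ARCH = (17, 16, 15, 14, 13, 12, 11, 21, 22, 23, 24, 25, 26, 27)
_LOWER_ARCH = (47, 46, 45, 44, 43, 42, 41, 31, 32, 33, 34, 35, 36, 37)
_ARCH_INDEX: dict[int, tuple[int, int]] = {}
for _arch_id, _arch in enumerate((_UPPER_ARCH, _LOWER_ARCH)):
    for _pos, _fdi in enumerate(_arch):
        _ARCH_INDEX[_fdi] = (_arch_id, _pos)


def non_adjacent(a: int, b: int) -> bool:
    """True unless teeth ``a`` and ``b`` occupy consecutive anatomical
    positions in the same arch.

    Adjacency is anatomical, not clinical: intervening missing teeth do not
    make two positions adjacent, and the central incisors across the midline
    (e.g. 11-21) are adjacent. Teeth in different arches are never adjacent.
    """
    if a not in _ARCH_INDEX:
        raise CoordinateError(f"invalid FDI code {a}")
    if b not in _ARCH_INDEX:
        raise CoordinateError(f"invalid FDI code {b}")
    if a == b:
        raise CoordinateError("non_adjacent requires two distinct teeth")
    arch_a, pos_a = _ARCH_INDEX[a]
    arch_b, pos_b = _ARCH_INDEX[b]
    if arch_a != arch_b:
        return True
    return abs(pos_a - pos_b) > 1


def _iter_measured(
    chart: PeriodontalChart, sel: SiteSelector, sites: frozenset[str]
):
    """Yield (fdi, site, cal, ppd) for measured selected sites of the given
    kinds on present teeth; unmeasured quantities come through as None."""
    for fdi, site in sel.included:
        if site not in sites:
            continue
        tooth = chart.teeth[fdi]
        if not tooth.present:
            continue
        m = tooth.sites[site]
        if m is None:
            continue
        yield fdi, site, m.cal_mm, m.ppd_mm


def _count_sites_and_teeth(hits: Iterable[tuple[int, str]]) -> tuple[int, int]:
    sites = set(hits)
    teeth = {fdi for fdi, _ in sites}
    return len(sites), len(teeth)


@dataclass(frozen=True)
class Params2012:
    """Thresholds of the 2012 CDC/AAP surveillance definition (mm)."""

    mild_cal: int = 3
    mild_ppd_pair: int = 4
    mild_ppd_single: int = 5
    moderate_cal: int = 4
    moderate_ppd: int = 5
    severe_cal: int = 6
    severe_ppd: int = 5


def classify_2012(
    chart: PeriodontalChart,
    sel: Optional[SiteSelector] = None,
    params: Params2012 = Params2012(),
) -> Diagnosis:
    """Apply the 2012 CDC/AAP case definition over the selected sites.

    Only interproximal sites are consulted (the definition ignores mid
    sites even when selected). Severity tiers are checked severe, moderate,
    mild; the stage is the first tier satisfied.
    """
    if sel is None:
        sel = SiteSelector.full_mouth()
    inter = interproximal_sites()
    cal_hits: dict[int, list[tuple[int, str]]] = {}  # threshold -> positions
    ppd_hits: dict[int, list[tuple[int, str]]] = {}
    cal_levels = (params.mild_cal, params.moderate_cal, params.severe_cal)
    ppd_levels = (params.mild_ppd_pair, params.mild_ppd_single,
                  params.moderate_ppd, params.severe_ppd)
    for fdi, site, cal, ppd in _iter_measured(chart, sel, inter):
        if cal is not None:
            for level in cal_levels:
                if cal >= level:
                    cal_hits.setdefault(level, []).append((fdi, site))
        if ppd is not None:
            for level in ppd_levels:
                if ppd >= level:
                    ppd_hits.setdefault(level, []).append((fdi, site))

    def sites_teeth(hits, level):
        return _count_sites_and_teeth(hits.get(level, ()))

    sev_cal_sites, sev_cal_teeth = sites_teeth(cal_hits, params.severe_cal)
    sev_ppd_sites, _ = sites_teeth(ppd_hits, params.severe_ppd)
    if sev_cal_sites >= 2 and sev_cal_teeth >= 2 and sev_ppd_sites >= 1:
        return Diagnosis(CDC_AAP_2012, True, STAGE_SEVERE)

    mod_cal_sites, mod_cal_teeth = sites_teeth(cal_hits, params.moderate_cal)
    mod_ppd_sites, mod_ppd_teeth = sites_teeth(ppd_hits, params.moderate_ppd)
    if (mod_cal_sites >= 2 and mod_cal_teeth >= 2) or (
        mod_ppd_sites >= 2 and mod_ppd_teeth >= 2
    ):
        return Diagnosis(CDC_AAP_2012, True, STAGE_MODERATE)

    mild_cal_sites, _ = sites_teeth(cal_hits, params.mild_cal)
    mild_pair_sites, mild_pair_teeth = sites_teeth(ppd_hits, params.mild_ppd_pair)
    mild_single_sites, _ = sites_teeth(ppd_hits, params.mild_ppd_single)
    if mild_cal_sites >= 2 and (
        (mild_pair_sites >= 2 and mild_pair_teeth >= 2) or mild_single_sites >= 1
    ):
        return Diagnosis(CDC_AAP_2012, True, STAGE_MILD)

    return Diagnosis(CDC_AAP_2012, False, STAGE_NONE)


@dataclass(frozen=True)
class Params2018:
    """Tunable thresholds of the 2018 EFP/AAP definition (mm).

    ``detectable_cal_mm`` is the interdental CAL regarded as detectable
    attachment loss in the presence rule; the staging bands start mild at
    ``stage_mild_min``, moderate at ``stage_moderate_min`` and severe at
    ``stage_severe_min``.
    """

    detectable_cal_mm: int = 1
    buccal_oral_cal: int = 3
    buccal_oral_ppd_gt: int = 3
    stage_mild_min: int = 1
    stage_moderate_min: int = 3
    stage_severe_min: int = 5


def max_interdental_cal(
    chart: PeriodontalChart, sel: Optional[SiteSelector] = None
) -> int:
    """Greatest CAL over the selected interproximal sites; 0 if none measured."""
    if sel is None:
        sel = SiteSelector.full_mouth()
    best = 0
    for _, _, cal, _ in _iter_measured(chart, sel, interproximal_sites()):
        if cal is not None and cal > best:
            best = cal
    return best


def classify_2018(
    chart: PeriodontalChart,
    sel: Optional[SiteSelector] = None,
    params: Params2018 = Params2018(),
) -> Diagnosis:
    """Apply the 2018 EFP/AAP case definition over the selected sites."""
    if sel is None:
        sel = SiteSelector.full_mouth()

    # Pathway (a): detectable interdental CAL at >=2 non-adjacent teeth.
    interdental_teeth = sorted(
        {
            fdi
            for fdi, _, cal, _ in _iter_measured(chart, sel, interproximal_sites())
            if cal is not None and cal >= params.detectable_cal_mm
        }
    )
    pathway_a = any(
        non_adjacent(a, b)
        for i, a in enumerate(interdental_teeth)
        for b in interdental_teeth[i + 1 :]
    )

    # Pathway (b): buccal/oral CAL >= 3 mm with PPD > 3 mm at the same site,
    # at >= 2 teeth.
    pathway_b_teeth = {
        fdi
        for fdi, _, cal, ppd in _iter_measured(chart, sel, mid_sites())
        if cal is not None
        and ppd is not None
        and cal >= params.buccal_oral_cal
        and ppd > params.buccal_oral_ppd_gt
    }
    pathway_b = len(pathway_b_teeth) >= 2

    if not (pathway_a or pathway_b):
        return Diagnosis(EFP_AAP_2018, False, STAGE_NONE)

    worst = max_interdental_cal(chart, sel)
    if worst >= params.stage_severe_min:
        stage = STAGE_SEVERE
    elif worst >= params.stage_moderate_min:
        stage = STAGE_MODERATE
    elif worst >= params.stage_mild_min:
        stage = STAGE_MILD
    else:
        stage = STAGE_MILD  # pathway-(b)-only case with no interdental CAL
    return Diagnosis(EFP_AAP_2018, True, stage)
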