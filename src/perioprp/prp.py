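"""The five named full-mouth partial recording protocols (PRPs).

A PRP is a named site selector: either a set of index teeth probed on all
six sites (Ramfjord, CPITN) or all 28 teeth probed on a reduced set of sites
(MB-B, MB-B-DB, MB-B-DL). FULL_MOUTH is the identity protocol and serves as
the reference standard. Missing index teeth contribute no evidence; no
substitution by neighbouring teeth is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

from .chart_model import ALL_FDI, SITE_CODES, PeriodontalChart
from .case_definitions import (
    CDC_AAP_2012,
    EFP_AAP_2018,
    Diagnosis,
    Params2012,
    Params2018,
    SiteSelector,
    classify_2012,
    classify_2018,
)

__all__ = [
    "PRPProtocol",
    "NAMED_PROTOCOLS",
    "RAMFJORD_TEETH",
    "CPITN_TEETH",
    "make_protocol",
    "custom_protocol",
    "diagnose_under_protocol",
    "protocol_to_json",
    "protocol_from_json",
]

#: Ramfjord index teeth: first molars 16/36, central incisors 21/41,
#: first premolars 24/44.
RAMFJORD_TEETH: tuple[int, ...] = (16, 21, 24, 36, 41, 44)

#: CPITN index teeth (adult form): molar pairs in each posterior sextant
#: plus one incisor per arch.
CPITN_TEETH: tuple[int, ...] = (17, 16, 11, 26, 27, 36, 37, 31, 46, 47)

_NAMED_DEFS: dict[str, tuple[tuple[int, ...], tuple[str, ...]]] = {
    "FULL_MOUTH": (ALL_FDI, SITE_CODES),
    "RAMFJORD": (RAMFJORD_TEETH, SITE_CODES),
    "CPITN": (CPITN_TEETH, SITE_CODES),
    "MB_B": (ALL_FDI, ("MB", "B")),
    "MB_B_DB": (ALL_FDI, ("MB", "B", "DB")),
    "MB_B_DL": (ALL_FDI, ("MB", "B", "DL")),
}

NAMED_PROTOCOLS: tuple[str, ...] = tuple(_NAMED_DEFS)


@dataclass(frozen=True)
class PRPProtocol:
    name: str
    selector: SiteSelector


def make_protocol(name: str) -> PRPProtocol:
    """Build one of the named protocols (case-insensitive, '-' == '_')."""
    key = name.strip().upper().replace("-", "_")
    if key not in _NAMED_DEFS:
        raise ValueError(
            f"unknown protocol {name!r}; known: {', '.join(NAMED_PROTOCOLS)}"
        )
    teeth, sites = _NAMED_DEFS[key]
    return PRPProtocol(key, SiteSelector.from_teeth_and_sites(teeth, sites))


def custom_protocol(teeth: Iterable[int], sites: Iterable[str]) -> PRPProtocol:
    """Arbitrary tooth x site protocol, for sensitivity analyses."""
    return PRPProtocol("CUSTOM", SiteSelector.from_teeth_and_sites(teeth, sites))


def diagnose_under_protocol(
    chart: PeriodontalChart,
    protocol: PRPProtocol,
    definition: str,
    params_2012: Params2012 = Params2012(),
    params_2018: Params2018 = Params2018(),
) -> Diagnosis:
    """Diagnose one chart using only the protocol's sites."""
    if definition == CDC_AAP_2012:
        return classify_2012(chart, protocol.selector, params_2012)
    if definition == EFP_AAP_2018:
        return classify_2018(chart, protocol.selector, params_2018)
    raise ValueError(f"unknown case definition {definition!r}")


def protocol_to_json(protocol: PRPProtocol) -> str:
    """Serialize a protocol for audit: {name, teeth, sites or positions}."""
    teeth = sorted({fdi for fdi, _ in protocol.selector.included})
    sites_per_tooth = {
        fdi: sorted(
            s for f, s in protocol.selector.included if f == fdi
        )
        for fdi in teeth
    }
    site_sets = set(map(tuple, sites_per_tooth.values()))
    if len(site_sets) == 1:  # rectangular protocol: compact form
        payload = {
            "name": protocol.name,
            "teeth": teeth,
            "sites": list(next(iter(site_sets))),
        }
    else:
        payload = {
            "name": protocol.name,
            "positions": sorted(
                [fdi, site] for fdi, site in protocol.selector.included
            ),
        }
    return json.dumps(payload, indent=2)


def protocol_from_json(text: str) -> PRPProtocol:
    payload = json.loads(text)
    if "positions" in payload:
        selector = SiteSelector(
            frozenset((int(f), s) for f, s in payload["positions"])
        )
    else:
        selector = SiteSelector.from_teeth_and_sites(
            payload["teeth"], payload["sites"]
        )
    return PRPProtocol(payload["name"], selector)
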