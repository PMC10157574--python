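"""Health-state catalog: the universe of valuation units.

A catalog is a list of :class:`HealthState` records, one per health state
presented to survey respondents.  Each state carries a short label, a lay
description (plain-language text of at most 75 words shown in the
questionnaire), eleven binary symptom-category flags used in the
cross-survey difference regression, a marker for membership in the
population-health-equivalence (PHE) anchor subset, and a marker for
whether a disability weight is estimable for it at all.

The eleven symptom categories, in the fixed column order used throughout
the package, are: mobility, pain, mental symptoms, fatigue, disfigurement,
sensory symptoms, infection/diarrhoea, substance use, activities of daily
living (ADL), cognitive symptoms, and other physical symptoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "SYMPTOM_CATEGORIES",
    "FLAG_COLUMNS",
    "HealthState",
    "CatalogError",
    "load_catalog",
    "write_catalog",
    "load_reference_dws",
    "anchor_states",
    "available_states",
    "packaged_catalog",
    "packaged_survey_dws",
]

#: Fixed order of the eleven symptom categories.
SYMPTOM_CATEGORIES: tuple[str, ...] = (
    "mobility",
    "pain",
    "mental",
    "fatigue",
    "disfigurement",
    "sensory",
    "infection_diarrhoea",
    "substance_use",
    "adl",
    "cognitive",
    "other_physical",
)

#: Catalog file columns holding the flags, in the same fixed order.
FLAG_COLUMNS: tuple[str, ...] = tuple(f"flag_{c}" for c in SYMPTOM_CATEGORIES)

_REQUIRED_COLUMNS = ("state_id", "label", "lay_description") + FLAG_COLUMNS + (
    "is_phe_anchor",
    "dw_available",
)


class CatalogError(ValueError):
    """Raised for structurally invalid catalog or reference-DW files."""


@dataclass(frozen=True)
class HealthState:
    """One health state in the valuation universe."""

    state_id: int
    label: str
    lay_description: str
    symptom_flags: tuple[bool, ...]
    is_phe_anchor: bool = False
    dw_available: bool = True

    def __post_init__(self) -> None:
        if not self.label:
            raise CatalogError(f"state {self.state_id}: empty label")
        if len(self.symptom_flags) != len(SYMPTOM_CATEGORIES):
            raise CatalogError(
                f"state {self.state_id}: expected {len(SYMPTOM_CATEGORIES)} "
                f"symptom flags, got {len(self.symptom_flags)}"
            )

    def with_anchor(self, is_anchor: bool) -> "HealthState":
        return replace(self, is_phe_anchor=is_anchor)


def _parse_bool(value, column: str, state_id) -> bool:
    """Flags are encoded 0/1 in files; accept bools for in-memory frames."""
    if isinstance(value, bool):
        return value
    try:
        iv = int(value)
    except (TypeError, ValueError):
        iv = -1
    if iv not in (0, 1):
        raise CatalogError(
            f"state {state_id}: column {column!r} has non-boolean value {value!r}"
        )
    return bool(iv)


def load_catalog(path) -> list[HealthState]:
    """Load and validate a health-state catalog from a delimited text file.

    The file must be UTF-8 CSV with a header row defining ``state_id``,
    ``label``, ``lay_description``, the eleven ``flag_*`` columns, and
    ``is_phe_anchor``; ``dw_available`` is optional and defaults to 1.
    Column order in the file is irrelevant (headers are honored).  The
    returned list is sorted by ``state_id`` ascending.
    """
    frame = pd.read_csv(path, dtype={"label": str, "lay_description": str})
    return catalog_from_frame(frame)


def catalog_from_frame(frame: pd.DataFrame) -> list[HealthState]:
    if "dw_available" not in frame.columns:
        frame = frame.assign(dw_available=1)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CatalogError(f"catalog is missing required column(s): {missing}")
    ids = frame["state_id"]
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise CatalogError(f"duplicate state_id(s): {sorted(set(dup.tolist()))}")
    states = []
    for row in frame.itertuples(index=False):
        sid = int(row.state_id)
        flags = tuple(
            _parse_bool(getattr(row, col), col, sid) for col in FLAG_COLUMNS
        )
        states.append(
            HealthState(
                state_id=sid,
                label=str(row.label),
                lay_description="" if pd.isna(row.lay_description) else str(row.lay_description),
                symptom_flags=flags,
                is_phe_anchor=_parse_bool(row.is_phe_anchor, "is_phe_anchor", sid),
                dw_available=_parse_bool(row.dw_available, "dw_available", sid),
            )
        )
    states.sort(key=lambda s: s.state_id)
    return states


def catalog_to_frame(catalog: list[HealthState]) -> pd.DataFrame:
    rows = []
    for s in catalog:
        row = {
            "state_id": s.state_id,
            "label": s.label,
            "lay_description": s.lay_description,
        }
        row.update({col: int(f) for col, f in zip(FLAG_COLUMNS, s.symptom_flags)})
        row["is_phe_anchor"] = int(s.is_phe_anchor)
        row["dw_available"] = int(s.dw_available)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS))


def write_catalog(catalog: list[HealthState], path) -> None:
    """Write a catalog back to CSV; round-trips through :func:`load_catalog`."""
    catalog_to_frame(catalog).to_csv(path, index=False)


def anchor_states(catalog: list[HealthState]) -> list[int]:
    """IDs of the PHE anchor subset, ascending."""
    return [s.state_id for s in catalog if s.is_phe_anchor]


def available_states(catalog: list[HealthState]) -> list[int]:
    """IDs of states with an estimable disability weight, ascending."""
    return [s.state_id for s in catalog if s.dw_available]


def load_reference_dws(path, catalog: list[HealthState] | None = None) -> dict[int, float]:
    """Load an external reference disability-weight table.

    Expects two columns ``state_id, dw`` with every DW in [0, 1].  When a
    catalog is given, catalog IDs without a reference value are reported
    in a warning (partial coverage is allowed); a reference DW of exactly
    zero is flagged because it breaks the proportional-difference ratio.
    """
    frame = pd.read_csv(path)
    for col in ("state_id", "dw"):
        if col not in frame.columns:
            raise CatalogError(f"reference table is missing column {col!r}")
    out: dict[int, float] = {}
    for row in frame.itertuples(index=False):
        sid = int(row.state_id)
        dw = float(row.dw)
        if not (0.0 <= dw <= 1.0):
            raise CatalogError(f"reference DW out of [0, 1] for state {sid}: {dw}")
        if dw == 0.0:
            warnings.warn(
                f"reference DW of exactly 0 for state {sid}; "
                "proportional differences are undefined for it",
                stacklevel=2,
            )
        out[sid] = dw
    if catalog is not None:
        missing = sorted(set(s.state_id for s in catalog) - set(out))
        if missing:
            warnings.warn(
                f"reference table covers {len(out)} states; "
                f"{len(missing)} catalog state(s) missing: {missing}",
                stacklevel=2,
            )
    return out


def _data_path(name: str) -> Path:
    return Path(str(resources.files("dwkit").joinpath("data", name)))


def packaged_catalog() -> list[HealthState]:
    """The 206-state catalog shipped with the package.

    Labels are the real published ones.  The lay descriptions, the eleven
    symptom flags, and the 28-state PHE anchor subset are SYNTHETIC
    stand-ins (seeded, with per-category flag counts matched to the
    published per-category lay-description counts), because the survey's
    per-state symptom annotations are not publicly deposited.
    """
    return load_catalog(_data_path("catalog_synthetic_flags.csv"))


def packaged_survey_dws() -> pd.DataFrame:
    """The published Wuhan survey DW table (mean and 95% UI per state).

    205 of the 206 states carry a value; the state with no estimable DW
    has NaN entries.  Columns: state_id, label, dw, ui_low, ui_high.
    """
    return pd.read_csv(_data_path("wuhan_dws.csv"))
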