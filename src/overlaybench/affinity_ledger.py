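"""Activity/affinity ingestion, normalization and ligand efficiency.

Records of type IC50, EC50, Ki (activity) and Kd (affinity) are pooled:
heterogeneous assay values are used only as a common ground to estimate a
conservative, minimum ligand efficiency per ligand.

value normalization:  p(value) = -log10(value in molar)
ligand efficiency:    LE = 1.37 * p(value) / heavy_atom_count
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)

MEASURE_TYPES = ("IC50", "EC50", "Ki", "Kd")

UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


@dataclass(frozen=True)
class ActivityRecord:
    entry_id: str
    residue_name: str
    measure_type: str
    value: float
    unit: str
    source: str = ""


@dataclass(frozen=True)
class EfficiencyResult:
    p_value: float
    ligand_efficiency: float
    n_records: int


class InvalidRecord(ValueError):
    pass


def normalize_value(value: float, unit: str) -> float:
    """Convert a measured value to molar and return -log10 of it."""
    if unit not in UNIT_TO_MOLAR:
        raise InvalidRecord(f"unknown unit {unit!r}")
    if not (value > 0):
        raise InvalidRecord(f"non-positive value {value!r}")
    return -math.log10(value * UNIT_TO_MOLAR[unit])


def ligand_efficiency(p_value: float, hac: int) -> float:
    """LE = 1.37 * p / hac; requires at least one heavy atom."""
    if hac < 1:
        raise ValueError("heavy atom count must be >= 1")
    return 1.37 * p_value / hac


def min_le_for_ligand(
    records, hac: int, value_selection: str = "min_p"
) -> EfficiencyResult | None:
    """Minimum estimated ligand efficiency over a ligand's records.

    ``min_p`` (default) keeps the weakest measurement (smallest p, hence
    most conservative LE); ``min_molar`` keeps the smallest molar value
    (i.e. the most potent measurement) instead.
    Invalid records (bad unit, non-positive value) are dropped with a log
    line; with no valid record the result is absent (``None``).
    """
    if value_selection not in ("min_p", "min_molar"):
        raise ValueError(f"unknown value selection {value_selection!r}")
    p_values = []
    for rec in records:
        try:
            p_values.append(normalize_value(rec.value, rec.unit))
        except InvalidRecord as exc:
            logger.warning("dropping record %s: %s", rec, exc)
    if not p_values:
        return None
    p = min(p_values) if value_selection == "min_p" else max(p_values)
    return EfficiencyResult(
        p_value=p,
        ligand_efficiency=ligand_efficiency(p, hac),
        n_records=len(p_values),
    )


def read_activity_table(path) -> list[ActivityRecord]:
    """Read a TSV with header ``entry_id het type value unit source``."""
    records = []
    lines = Path(path).read_text().splitlines()
    if not lines:
        return records
    header = lines[0].rstrip("\n").split("\t")
    idx = {name: i for i, name in enumerate(header)}
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        records.append(
            ActivityRecord(
                entry_id=fields[idx["entry_id"]].lower(),
                residue_name=fields[idx["het"]],
                measure_type=fields[idx["type"]],
                value=float(fields[idx["value"]]),
                unit=fields[idx["unit"]],
                source=fields[idx["source"]] if "source" in idx and len(fields) > idx["source"] else "",
            )
        )
    return records


def build_ledger(records) -> dict[tuple[str, str], list[ActivityRecord]]:
    """Group records by (entry_id, het code)."""
    ledger: dict[tuple[str, str], list[ActivityRecord]] = {}
    for rec in records:
        ledger.setdefault((rec.entry_id, rec.residue_name), []).append(rec)
    return ledger
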