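"""Reference-interval registry for the 33-item laboratory frailty index.

The FI-Lab counts deficits: measured items (laboratory values, blood-gas
values, urine dipstick results, vital signs) falling outside their normal
reference range. This module defines the item schema, ships a default
registry of 33 items with standard adult reference intervals, and supports
loading user-edited registries from CSV or YAML so that site-specific
intervals can be substituted without code changes. Every analysis records
the registry checksum so results are traceable to the intervals used.
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import yaml

SAMPLE_TYPES = ("venous_blood", "arterial_gas", "urine", "vital_sign")
VALUE_KINDS = ("continuous", "dipstick")

#: expected composition of the registry by sample type
COMPOSITION = {"venous_blood": 20, "arterial_gas": 4, "urine": 6, "vital_sign": 3}


@dataclass(frozen=True)
class ReferenceItem:
    """One FI-Lab item: what is measured and what counts as normal.

    Continuous items carry a reference interval (at least one of
    ``lower``/``upper``); a value strictly beyond a bound is a deficit and
    the bounds themselves are normal. Dipstick items carry the single
    normal category (e.g. ``"negative"``); any other reading is a deficit.
    """

    name: str
    sample_type: str
    value_kind: str
    lower: Optional[float] = None
    upper: Optional[float] = None
    normal_category: Optional[str] = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"{self.name}: unknown sample_type {self.sample_type!r}")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"{self.name}: unknown value_kind {self.value_kind!r}")
        if self.value_kind == "continuous":
            if self.lower is None and self.upper is None:
                raise ValueError(f"{self.name}: continuous item needs lower and/or upper bound")
            if self.lower is not None and self.upper is not None and self.lower >= self.upper:
                raise ValueError(f"{self.name}: lower bound must be below upper bound")
            if self.normal_category is not None:
                raise ValueError(f"{self.name}: continuous item cannot have a normal_category")
        else:
            if self.normal_category is None:
                raise ValueError(f"{self.name}: dipstick item needs a normal_category")
            if self.lower is not None or self.upper is not None:
                raise ValueError(f"{self.name}: dipstick item cannot have numeric bounds")


class ReferenceRegistry:
    """Ordered collection of exactly 33 :class:`ReferenceItem` definitions.

    The composition by sample type is fixed at 20 venous-blood, 4
    arterial-gas, 6 urine and 3 vital-sign items; item names are unique.
    """

    def __init__(self, items: Iterable[ReferenceItem]):
        items = list(items)
        names = [it.name for it in items]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate item names: {dupes}")
        if len(items) != 33:
            raise ValueError(f"registry must have exactly 33 items, got {len(items)}")
        counts = {st: sum(it.sample_type == st for it in items) for st in SAMPLE_TYPES}
        if counts != COMPOSITION:
            raise ValueError(f"registry composition {counts} != required {COMPOSITION}")
        self.items: tuple[ReferenceItem, ...] = tuple(items)
        self._by_name = {it.name: it for it in items}

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, name: str) -> ReferenceItem:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [it.name for it in self.items]

    def checksum(self) -> str:
        """SHA-256 over the canonical CSV serialization (order-sensitive)."""
        return hashlib.sha256(self.to_csv_text().encode()).hexdigest()

    # ---- serialization -------------------------------------------------

    _FIELDS = ("name", "sample_type", "value_kind", "lower", "upper", "normal_category", "units")

    def to_csv_text(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(self._FIELDS)
        for it in self.items:
            w.writerow([
                it.name, it.sample_type, it.value_kind,
                "" if it.lower is None else repr(it.lower),
                "" if it.upper is None else repr(it.upper),
                "" if it.normal_category is None else it.normal_category,
                it.units,
            ])
        return buf.getvalue()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            records = [
                {f: getattr(it, f) for f in self._FIELDS} for it in self.items
            ]
            path.write_text(yaml.safe_dump({"items": records}, sort_keys=False))
        else:
            path.write_text(self.to_csv_text())

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceRegistry":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(path.read_text())
            rows = data["items"] if isinstance(data, dict) else data
        else:
            rows = list(csv.DictReader(io.StringIO(path.read_text())))
        items = []
        for r in rows:
            items.append(ReferenceItem(
                name=r["name"],
                sample_type=r["sample_type"],
                value_kind=r["value_kind"],
                lower=_opt_float(r.get("lower")),
                upper=_opt_float(r.get("upper")),
                normal_category=r.get("normal_category") or None,
                units=r.get("units") or "",
            ))
        return cls(items)


def _opt_float(x) -> Optional[float]:
    if x is None or x == "":
        return None
    return float(x)


# Default registry: standard adult reference intervals. The 33-item panel is
# 20 venous-blood tests, 4 arterial-blood-gas values, 6 urine dipstick
# readings and 3 vital signs, one value per ICU stay. Sites with different
# laboratory conventions should edit a saved copy and pass it back in; the
# registry checksum in each run manifest records which intervals were used.
_V = "venous_blood"
_A = "arterial_gas"
_U = "urine"
_S = "vital_sign"

DEFAULT_ITEMS: tuple[ReferenceItem, ...] = (
    ReferenceItem("white_cell_count", _V, "continuous", 4.5, 11.0, units="10^9/L"),
    ReferenceItem("platelet_count", _V, "continuous", 150.0, 450.0, units="10^9/L"),
    ReferenceItem("hemoglobin", _V, "continuous", 12.0, 17.5, units="g/dL"),
    ReferenceItem("total_bilirubin", _V, "continuous", 0.2, 1.2, units="mg/dL"),
    ReferenceItem("alanine_transaminase", _V, "continuous", 7.0, 56.0, units="U/L"),
    ReferenceItem("albumin", _V, "continuous", 3.5, 5.0, units="g/dL"),
    ReferenceItem("alkaline_phosphatase", _V, "continuous", 44.0, 147.0, units="U/L"),
    ReferenceItem("lactate_dehydrogenase", _V, "continuous", 122.0, 222.0, units="U/L"),
    ReferenceItem("urea_nitrogen", _V, "continuous", 7.0, 20.0, units="mg/dL"),
    ReferenceItem("creatinine", _V, "continuous", 0.6, 1.2, units="mg/dL"),
    ReferenceItem("glucose", _V, "continuous", 70.0, 100.0, units="mg/dL"),
    ReferenceItem("potassium", _V, "continuous", 3.5, 5.0, units="mmol/L"),
    ReferenceItem("sodium", _V, "continuous", 135.0, 145.0, units="mmol/L"),
    ReferenceItem("calcium", _V, "continuous", 8.5, 10.5, units="mg/dL"),
    ReferenceItem("phosphorus", _V, "continuous", 2.5, 4.5, units="mg/dL"),
    ReferenceItem("prothrombin_time", _V, "continuous", 11.0, 13.5, units="s"),
    ReferenceItem("inr", _V, "continuous", 0.8, 1.2, units=""),
    ReferenceItem("aptt", _V, "continuous", 25.0, 35.0, units="s"),
    ReferenceItem("fibrinogen", _V, "continuous", 200.0, 400.0, units="mg/dL"),
    ReferenceItem("troponin_t", _V, "continuous", None, 0.01, units="ng/mL"),
    ReferenceItem("ph", _A, "continuous", 7.35, 7.45, units=""),
    ReferenceItem("po2", _A, "continuous", 75.0, 100.0, units="mmHg"),
    ReferenceItem("pco2", _A, "continuous", 35.0, 45.0, units="mmHg"),
    ReferenceItem("lactate", _A, "continuous", 0.5, 2.0, units="mmol/L"),
    ReferenceItem("urine_leucocytes", _U, "dipstick", normal_category="negative", units=""),
    ReferenceItem("urine_erythrocytes", _U, "dipstick", normal_category="negative", units=""),
    ReferenceItem("urine_protein", _U, "dipstick", normal_category="negative", units=""),
    ReferenceItem("urine_glucose", _U, "dipstick", normal_category="negative", units=""),
    ReferenceItem("urine_ketones", _U, "dipstick", normal_category="negative", units=""),
    ReferenceItem("urine_bilirubin", _U, "dipstick", normal_category="negative", units=""),
    ReferenceItem("systolic_bp", _S, "continuous", 90.0, 140.0, units="mmHg"),
    ReferenceItem("diastolic_bp", _S, "continuous", 60.0, 90.0, units="mmHg"),
    ReferenceItem("heart_rate", _S, "continuous", 60.0, 100.0, units="bpm"),
)


def default_registry() -> ReferenceRegistry:
    """The shipped 33-item registry with standard adult reference intervals."""
    return ReferenceRegistry(DEFAULT_ITEMS)
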