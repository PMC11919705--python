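"""Activity descriptors derived from four-class nucleus fractions.

Two-gene catFISH reads out neuronal activity at two behavioural epochs from a
single brain: Homer-1a transcription foci mark activity during the earlier
test entry and Arc foci the later one (the default mapping, configurable).
From the four nucleus-class fractions of a structure we derive the activity
descriptor set — fraction active during any entry, during each entry, and
exclusively during each entry — plus the co-localisation coefficient

    coloc = f_both / (f_first * f_second),

the double-positive fraction divided by its expectation under independent
activation across the two entries. It equals 1 under independence, falls
below 1 when activation is exclusive to either entry, and exceeds 1 when the
same sub-population re-activates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataError, ParameterError

#: default IEG -> test-entry mapping
DEFAULT_IEG_MAP = {"first_entry": "homer", "second_entry": "arc"}

DESCRIPTOR_NAMES = (
    "any", "first", "second", "first_only", "second_only", "both", "coloc",
)

_FRACTION_TOL = 1e-6


@dataclass
class ActivityRecord:
    """Four-class nucleus fractions for one (animal, structure)."""

    animal_id: str
    structure: str
    f_both: float
    f_arc_only: float
    f_homer_only: float
    f_negative: float
    n_layers_used: int = 0
    n_nuclei: int = 0

    def validate(self) -> None:
        fr = (self.f_both, self.f_arc_only, self.f_homer_only, self.f_negative)
        if any(math.isnan(f) for f in fr):
            raise DataError(
                f"record ({self.animal_id}, {self.structure}) has undefined fractions"
            )
        if any(f < -_FRACTION_TOL or f > 1 + _FRACTION_TOL for f in fr):
            raise DataError(
                f"record ({self.animal_id}, {self.structure}) has fractions outside [0,1]"
            )
        if abs(sum(fr) - 1.0) > 1e-3:
            raise DataError(
                f"record ({self.animal_id}, {self.structure}): class fractions "
                f"sum to {sum(fr):.4f}, not 1"
            )


@dataclass(frozen=True)
class DescriptorVector:
    """Derived activity descriptors for one (animal, structure)."""

    f_any: float
    f_first: float
    f_second: float
    f_first_only: float
    f_second_only: float
    f_both: float
    coloc: float  # NaN when undefined

    def as_dict(self) -> dict[str, float]:
        return {
            "any": self.f_any,
            "first": self.f_first,
            "second": self.f_second,
            "first_only": self.f_first_only,
            "second_only": self.f_second_only,
            "both": self.f_both,
            "coloc": self.coloc,
        }


def coloc_coefficient(f_both: float, f_first: float, f_second: float) -> float:
    """Double-positive fraction over its independence expectation.

    Returns NaN (undefined) when either marginal is zero.
    """
    for name, v in (("f_both", f_both), ("f_first", f_first), ("f_second", f_second)):
        if not (0 - _FRACTION_TOL <= v <= 1 + _FRACTION_TOL):
            raise ParameterError(f"{name}={v} outside [0, 1]")
    if f_both > min(f_first, f_second) + _FRACTION_TOL:
        raise DataError(
            f"inconsistent fractions: f_both={f_both} exceeds "
            f"min(f_first={f_first}, f_second={f_second})"
        )
    denom = f_first * f_second
    if denom <= 0:
        return float("nan")
    return f_both / denom


def to_descriptors(
    rec: ActivityRecord, ieg_map: Mapping[str, str] | None = None
) -> DescriptorVector:
    """Map four-class fractions to entry-labelled descriptors.

    ``ieg_map`` assigns each test entry its IEG; with the default map
    (first -> Homer-1a, second -> Arc): f_first = f_homer_only + f_both and
    f_second = f_arc_only + f_both.
    """
    ieg_map = dict(ieg_map or DEFAULT_IEG_MAP)
    if set(ieg_map.keys()) != {"first_entry", "second_entry"}:
        raise ParameterError("ieg_map needs keys first_entry and second_entry")
    if set(ieg_map.values()) != {"homer", "arc"}:
        raise ParameterError("ieg_map must assign homer and arc to distinct entries")
    rec.validate()
    only = {"homer": rec.f_homer_only, "arc": rec.f_arc_only}
    f_first_only = only[ieg_map["first_entry"]]
    f_second_only = only[ieg_map["second_entry"]]
    f_first = f_first_only + rec.f_both
    f_second = f_second_only + rec.f_both
    return DescriptorVector(
        f_any=1.0 - rec.f_negative,
        f_first=f_first,
        f_second=f_second,
        f_first_only=f_first_only,
        f_second_only=f_second_only,
        f_both=rec.f_both,
        coloc=coloc_coefficient(rec.f_both, f_first, f_second),
    )


# ---------------------------------------------------------------------------
# tabular interfaces


def records_to_frame(records: Iterable[ActivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "structure": r.structure,
                "f_both": r.f_both,
                "f_arc_only": r.f_arc_only,
                "f_homer_only": r.f_homer_only,
                "f_negative": r.f_negative,
                "n_layers_used": r.n_layers_used,
                "n_nuclei": r.n_nuclei,
            }
            for r in records
        ]
    )


def frame_to_records(df: pd.DataFrame) -> list[ActivityRecord]:
    return [
        ActivityRecord(
            animal_id=str(row["animal_id"]),
            structure=str(row["structure"]),
            f_both=float(row["f_both"]),
            f_arc_only=float(row["f_arc_only"]),
            f_homer_only=float(row["f_homer_only"]),
            f_negative=float(row["f_negative"]),
            n_layers_used=int(row.get("n_layers_used", 0)),
            n_nuclei=int(row.get("n_nuclei", 0)),
        )
        for _, row in df.iterrows()
    ]


def feature_matrix(
    records: Iterable[ActivityRecord],
    ieg_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Wide animals x ``<structure>__<descriptor>`` matrix.

    Undefined co-localisation values propagate as missing (NaN), never 0.
    """
    rows: dict[str, dict[str, float]] = {}
    for rec in records:
        vec = to_descriptors(rec, ieg_map)
        row = rows.setdefault(rec.animal_id, {})
        for name, value in vec.as_dict().items():
            row[f"{rec.structure}__{name}"] = value
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "animal_id"
    return df[sorted(df.columns)]
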