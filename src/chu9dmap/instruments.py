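"""Domain types and scoring contracts for KIDSCREEN-10 and CHU9D.

The KIDSCREEN-10 is a 10-item non-preference-based HRQoL profile for
children and adolescents; each item is answered on a 5-point ordinal scale
and the package standardises on *higher = better health* for every item.
The CHU9D is a preference-based instrument whose utilities (under the
Australian adolescent best-worst-scaling tariff) span 0.33 to 1, anchored
at full health = 1.

Everything downstream (mapping, estimation, validation) consumes the types
defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Item metadata

ITEM_LABELS: tuple[str, ...] = tuple(f"ks_i{j}" for j in range(1, 11))

ITEM_DESCRIPTIONS: dict[str, str] = {
    "ks_i1": "felt fit and well",
    "ks_i2": "felt full of energy",
    "ks_i3": "felt sad",
    "ks_i4": "felt lonely",
    "ks_i5": "had enough time for yourself",
    "ks_i6": "able to do the things you want in your free time",
    "ks_i7": "parent(s) treated you fairly",
    "ks_i8": "had fun with friends",
    "ks_i9": "got on well at school",
    "ks_i10": "been able to pay attention",
}

MIN_LEVEL, MAX_LEVEL = 1, 5

#: CHU9D value sets supported by the mapping registry.  Both tariffs anchor
#: full health at 1; the worst describable state is valued at 0.33.
VALUE_SETS: dict[str, dict] = {
    "AU_adolescent_BWS": {"floor": 0.33, "description":
                          "Australian adolescent best-worst scaling tariff"},
    "UK_adult_SG": {"floor": 0.33, "description":
                    "UK adult standard gamble tariff"},
}


class ResponseValidationError(ValueError):
    """An item response is missing or outside the 1-5 ordinal range."""


# ---------------------------------------------------------------------------
# Core types


@dataclass(frozen=True)
class ItemResponseVector:
    """One respondent's 10 KIDSCREEN-10 item levels (each in 1..5)."""

    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != 10:
            raise ResponseValidationError(
                f"expected 10 item levels, got {len(self.levels)}")
        for label, lev in zip(ITEM_LABELS, self.levels):
            if not isinstance(lev, (int, np.integer)) or isinstance(lev, bool):
                raise ResponseValidationError(
                    f"{label.upper()}: level {lev!r} is not an integer")
            if not MIN_LEVEL <= lev <= MAX_LEVEL:
                raise ResponseValidationError(
                    f"{label.upper()}: level {lev} outside [1, 5]")

    def __getitem__(self, label: str) -> int:
        return self.levels[ITEM_LABELS.index(label)]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(ITEM_LABELS, self.levels))


@dataclass(frozen=True)
class KidscreenIndex:
    """KIDSCREEN-10 index on the T-score metric (mean ~50, SD ~10)."""

    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("KIDSCREEN-10 index must be finite")


@dataclass(frozen=True)
class UtilityScore:
    """A CHU9D utility anchored at full health = 1.

    Observed utilities under either tariff lie in [0.33, 1]; model
    predictions may fall outside that range before truncation, so range
    checking happens at ingest, not here.
    """

    value: float
    value_set: str = "AU_adolescent_BWS"

    def __post_init__(self) -> None:
        if self.value_set not in VALUE_SETS:
            raise ValueError(
                f"unknown value set {self.value_set!r}; "
                f"expected one of {sorted(VALUE_SETS)}")


@dataclass(frozen=True)
class Covariates:
    """Optional socio-demographics used as candidate predictors."""

    age: Optional[int] = None
    gender: Optional[int] = None
    age_range: tuple[int, int] = (11, 17)

    def __post_init__(self) -> None:
        if self.age is not None:
            lo, hi = self.age_range
            if not lo <= self.age <= hi:
                raise ValueError(f"age {self.age} outside [{lo}, {hi}]")
        if self.gender is not None and self.gender not in (0, 1):
            raise ValueError("gender must be coded 0/1")


@dataclass
class PairedDataset:
    """Respondent-level records pairing KIDSCREEN-10 responses with
    (optionally) the KIDSCREEN-10 index, covariates and CHU9D utilities.

    ``items`` is an (n, 10) integer array in item order ks_i1..ks_i10.
    All records are complete-case for the fields that are present.
    """

    items: np.ndarray
    utility: Optional[np.ndarray] = None
    index: Optional[np.ndarray] = None
    age: Optional[np.ndarray] = None
    gender: Optional[np.ndarray] = None
    value_set: str = "AU_adolescent_BWS"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=int)
        if self.items.ndim != 2 or self.items.shape[1] != 10:
            raise ValueError("items must be an (n, 10) array")
        n = self.items.shape[0]
        for name in ("utility", "index", "age", "gender"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,):
                    raise ValueError(f"{name} must have length n={n}")
                setattr(self, name, arr)

    @property
    def n(self) -> int:
        return self.items.shape[0]

    def record(self, i: int) -> ItemResponseVector:
        return ItemResponseVector(tuple(int(v) for v in self.items[i]))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.items, columns=list(ITEM_LABELS))
        if self.index is not None:
            df["ks_index"] = self.index
        if self.age is not None:
            df["age"] = self.age
        if self.gender is not None:
            df["gender"] = self.gender.astype(int)
        if self.utility is not None:
            df["chu9d"] = self.utility
        return df

    def subset(self, idx: Sequence[int]) -> "PairedDataset":
        idx = np.asarray(idx)
        pick = lambda a: None if a is None else a[idx]
        return PairedDataset(
            items=self.items[idx], utility=pick(self.utility),
            index=pick(self.index), age=pick(self.age),
            gender=pick(self.gender), value_set=self.value_set,
            provenance=self.provenance)


@dataclass(frozen=True)
class RaschLookupTable:
    """Raw-sum -> Rasch person parameter lookup plus the affine T-transform.

    The official table is published in the KIDSCREEN manual and is not
    bundled; users supply their own (two-column CSV) or use
    :func:`passthrough_table` for moment-level work.  The lookup must be
    strictly increasing and cover every attainable sum (10..50).
    """

    person_parameter: Mapping[int, float]
    t_slope: float = 1.0
    t_intercept: float = 0.0

    def __post_init__(self) -> None:
        sums = sorted(self.person_parameter)
        if sums != list(range(10, 51)):
            missing = sorted(set(range(10, 51)) - set(sums))
            raise ValueError(
                f"lookup must cover raw sums 10..50; missing {missing[:5]}...")
        vals = [self.person_parameter[s] for s in sums]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("person parameters must be strictly increasing "
                             "in the raw sum")


def passthrough_table(t_slope: float = 1.0,
                      t_intercept: float = 0.0) -> RaschLookupTable:
    """Identity lookup (person parameter = raw sum) with an affine transform."""
    return RaschLookupTable({s: float(s) for s in range(10, 51)},
                            t_slope, t_intercept)


# ---------------------------------------------------------------------------
# Operations


def validate_responses(raw_record: Mapping[str, object],
                       reverse_coded: Iterable[str] = ()) -> ItemResponseVector:
    """Validate one raw record into an :class:`ItemResponseVector`.

    Parameters
    ----------
    raw_record
        Mapping with the 10 fields ``ks_i1``..``ks_i10``.
    reverse_coded
        Item labels whose raw coding runs the wrong way (lower = better);
        those levels are re-coded as ``6 - level`` so that higher = better
        HRQoL uniformly.

    Raises
    ------
    ResponseValidationError
        If an item is missing, non-integer or outside [1, 5]; the message
        names the offending item.
    """
    reverse = {lab.lower() for lab in reverse_coded}
    unknown = reverse - set(ITEM_LABELS)
    if unknown:
        raise ValueError(f"reverse_coded names unknown items: {sorted(unknown)}")
    levels = []
    for label in ITEM_LABELS:
        if label not in raw_record or raw_record[label] is None or (
                isinstance(raw_record[label], float) and np.isnan(raw_record[label])):
            raise ResponseValidationError(
                f"{label.upper()}: missing value (complete-case analysis only)")
        value = raw_record[label]
        if isinstance(value, float) and value.is_integer():
            value = int(value)
        if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
            raise ResponseValidationError(
                f"{label.upper()}: level {value!r} is not an integer")
        if not MIN_LEVEL <= value <= MAX_LEVEL:
            raise ResponseValidationError(
                f"{label.upper()}: level {value} outside [{MIN_LEVEL}, {MAX_LEVEL}]")
        if label in reverse:
            value = MIN_LEVEL + MAX_LEVEL - value
        levels.append(int(value))
    return ItemResponseVector(tuple(levels))


def raw_sum(items: ItemResponseVector) -> int:
    """Equal-weight raw overall score: the sum of the 10 item levels (10..50)."""
    return int(sum(items.levels))


def index_from_sum(total: int, table: RaschLookupTable) -> KidscreenIndex:
    """KIDSCREEN-10 index from a raw sum via the supplied Rasch lookup.

    The sum is mapped to a person parameter and then affinely transformed
    onto the T-score metric (mean ~50, SD ~10 under the official table).
    """
    if not isinstance(total, (int, np.integer)):
        raise TypeError("raw sum must be an integer")
    if total not in table.person_parameter:
        raise ValueError(f"raw sum {total} outside the lookup domain [10, 50]")
    theta = table.person_parameter[total]
    return KidscreenIndex(table.t_intercept + table.t_slope * theta)
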