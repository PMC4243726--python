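"""Apply a mapping algorithm to KIDSCREEN-10 responses.

A :class:`MappingModelSpec` is a complete crosswalk algorithm: functional
form (index + index-squared, or a linear combination of selected items),
link (identity or logit for the fractional-logit fit), coefficient set,
target CHU9D value set, and the truncation policy.  Specs come from the
packaged registry of published algorithms or from a fresh
:class:`~chu9dmap.estimators.FitResult`.

Predictions from identity-link algorithms can exceed 1 for respondents in
very good health; the truncation rule caps the reported prediction at 1,
which never worsens pointwise error when observed utilities are <= 1.
Individual-level predictions carry substantial error — the algorithms are
intended for aggregated (sample/group mean) use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .instruments import (ITEM_LABELS, VALUE_SETS, ItemResponseVector,
                          KidscreenIndex, PairedDataset)

_REGISTRY_RESOURCE = "published_algorithms.json"

Record = Union[ItemResponseVector, KidscreenIndex, Mapping[str, float]]


@dataclass(frozen=True)
class MappingModelSpec:
    """A complete KIDSCREEN-10 -> CHU9D mapping algorithm."""

    form: str                                # "index_quadratic" | "item_linear"
    link: str                                # "identity" | "logit"
    intercept: float
    beta1: Optional[float] = None            # index form
    beta2: Optional[float] = None            # index form, may be absent
    gammas: Optional[Mapping[str, float]] = None   # item form
    estimator_label: str = "OLS"
    value_set: str = "AU_adolescent_BWS"
    truncate_upper_at_1: bool = True
    truncate_lower_at_floor: bool = False    # off by default: cap at 1 only
    name: str = ""
    source: str = ""
    robust_se: Optional[Mapping[str, float]] = None
    provenance_note: Optional[str] = None

    def __post_init__(self) -> None:
        if self.form not in ("index_quadratic", "item_linear"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.link not in ("identity", "logit"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.link == "logit" and self.estimator_label != "GLM":
            raise ValueError("logit link is only used by the GLM "
                             "(fractional logit) estimator")
        if self.value_set not in VALUE_SETS:
            raise ValueError(f"unknown value set {self.value_set!r}")
        if self.form == "index_quadratic":
            if self.beta1 is None:
                raise ValueError("index_quadratic form requires beta1")
        else:
            if not self.gammas:
                raise ValueError("item_linear form requires at least one gamma")
            if len(self.gammas) > 10:
                raise ValueError("at most 10 item coefficients")
            bad = set(self.gammas) - set(ITEM_LABELS)
            if bad:
                raise ValueError(f"unknown item labels in gammas: {sorted(bad)}")

    # -- prediction helpers -------------------------------------------------

    def linear_predictor(self, record: Record) -> float:
        """Evaluate alpha + sum(coef * predictor) for one record."""
        if self.form == "index_quadratic":
            if isinstance(record, KidscreenIndex):
                ks = record.value
            elif isinstance(record, Mapping) and "ks_index" in record:
                ks = float(record["ks_index"])
            else:
                raise ValueError(
                    "index_quadratic algorithm needs a KIDSCREEN-10 index "
                    "('ks_index'); got item responses only")
            eta = self.intercept + self.beta1 * ks
            if self.beta2 is not None:
                eta += self.beta2 * ks * ks
            return eta
        # item form
        if isinstance(record, ItemResponseVector):
            values = record.as_dict()
        elif isinstance(record, Mapping):
            values = record
        else:
            raise ValueError(
                "item_linear algorithm needs item responses; got "
                f"{type(record).__name__}")
        eta = self.intercept
        for label, gamma in self.gammas.items():
            if label not in values:
                raise ValueError(f"record is missing item {label.upper()} "
                                 "required by the algorithm")
            eta += gamma * float(values[label])
        return eta

    def to_json_dict(self) -> dict:
        d = {
            "form": self.form, "link": self.link,
            "estimator_label": self.estimator_label,
            "value_set": self.value_set,
            "intercept": repr(self.intercept),
            "truncate_upper_at_1": self.truncate_upper_at_1,
        }
        if self.name:
            d["name"] = self.name
        if self.source:
            d["source"] = self.source
        if self.form == "index_quadratic":
            d["beta1"] = repr(self.beta1)
            d["beta2"] = None if self.beta2 is None else repr(self.beta2)
        else:
            d["gammas"] = {k: repr(v) for k, v in self.gammas.items()}
        if self.robust_se:
            d["robust_se"] = {k: repr(v) for k, v in self.robust_se.items()}
        if self.provenance_note:
            d["provenance_note"] = self.provenance_note
        return d


@dataclass(frozen=True)
class PredictionResult:
    """One prediction, pre- and post-truncation."""

    raw_prediction: float
    truncated_prediction: float
    spec: MappingModelSpec


@dataclass
class BatchPrediction:
    """Element-wise predictions plus the group-level summary.

    Group-level (mean) use is the recommended application; individual
    predictions are returned but carry large error.
    """

    raw: np.ndarray
    truncated: np.ndarray
    spec: MappingModelSpec

    def summary(self) -> dict[str, float]:
        return {
            "mean_raw": float(self.raw.mean()),
            "min_raw": float(self.raw.min()),
            "max_raw": float(self.raw.max()),
            "mean_truncated": float(self.truncated.mean()),
            "min_truncated": float(self.truncated.min()),
            "max_truncated": float(self.truncated.max()),
        }


def _inv_logit(eta):
    return 1.0 / (1.0 + np.exp(-np.asarray(eta, dtype=float)))


def _apply_link_and_truncate(eta: np.ndarray, spec: MappingModelSpec):
    raw = _inv_logit(eta) if spec.link == "logit" else np.asarray(eta, float)
    trunc = raw
    if spec.truncate_upper_at_1:
        trunc = np.minimum(trunc, 1.0)
    if spec.truncate_lower_at_floor:
        trunc = np.maximum(trunc, VALUE_SETS[spec.value_set]["floor"])
    return raw, trunc


def predict_one(record: Record, spec: MappingModelSpec) -> PredictionResult:
    """Predicted CHU9D utility for a single respondent."""
    eta = spec.linear_predictor(record)
    raw, trunc = _apply_link_and_truncate(np.array([eta]), spec)
    return PredictionResult(float(raw[0]), float(trunc[0]), spec)


def predict_batch(data, spec: MappingModelSpec) -> BatchPrediction:
    """Predictions and mean/min/max summaries for a batch of respondents.

    ``data`` may be a :class:`PairedDataset`, a pandas DataFrame with the
    required predictor columns, or a sequence of records.
    """
    etas = _linear_predictors(data, spec)
    if etas.size == 0:
        raise ValueError("cannot predict on an empty batch")
    raw, trunc = _apply_link_and_truncate(etas, spec)
    return BatchPrediction(raw=raw, truncated=trunc, spec=spec)


def _linear_predictors(data, spec: MappingModelSpec) -> np.ndarray:
    if isinstance(data, PairedDataset):
        if spec.form == "index_quadratic":
            if data.index is None:
                raise ValueError("index_quadratic algorithm needs the "
                                 "'ks_index' column")
            ks = data.index
            eta = spec.intercept + spec.beta1 * ks
            if spec.beta2 is not None:
                eta = eta + spec.beta2 * ks * ks
            return np.asarray(eta, float)
        eta = np.full(data.n, spec.intercept, dtype=float)
        for label, gamma in spec.gammas.items():
            eta += gamma * data.items[:, ITEM_LABELS.index(label)]
        return eta
    if hasattr(data, "columns"):                       # DataFrame
        rows = (row for _, row in data.iterrows())
        return np.array([spec.linear_predictor(dict(r)) for r in rows])
    return np.array([spec.linear_predictor(rec) for rec in data])


# ---------------------------------------------------------------------------
# Registry of published algorithms


def _load_registry_raw() -> dict:
    text = (resources.files("chu9dmap") / "data" / _REGISTRY_RESOURCE).read_text()
    return json.loads(text)


def _spec_from_dict(name: str, entry: Mapping, source: str = "registry"
                    ) -> MappingModelSpec:
    def num(x):
        return None if x is None else float(x)
    gammas = entry.get("gammas")
    return MappingModelSpec(
        form=entry["form"], link=entry["link"],
        intercept=float(entry["intercept"]),
        beta1=num(entry.get("beta1")), beta2=num(entry.get("beta2")),
        gammas=None if gammas is None else {k: float(v) for k, v in gammas.items()},
        estimator_label=entry["estimator_label"],
        value_set=entry["value_set"],
        truncate_upper_at_1=bool(entry.get("truncate_upper_at_1", True)),
        name=name, source=entry.get("source", source),
        robust_se=({k: float(v) for k, v in entry["robust_se"].items()}
                   if entry.get("robust_se") else None),
        provenance_note=entry.get("provenance_note"),
    )


def registry_names() -> list[str]:
    """Identifiers of the 16 packaged published algorithms."""
    return sorted(_load_registry_raw())


def registry_load(name: str) -> MappingModelSpec:
    """Load a published algorithm by identifier, e.g. ``"AU/MM/model2"``."""
    raw = _load_registry_raw()
    if name not in raw:
        raise KeyError(
            f"unknown algorithm {name!r}; available: {', '.join(sorted(raw))}")
    return _spec_from_dict(name, raw[name], source="published registry")


def spec_to_json(spec: MappingModelSpec, path=None) -> str:
    """Serialise a spec to the algorithm-spec JSON format."""
    text = json.dumps(spec.to_json_dict(), indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def spec_from_json(source) -> MappingModelSpec:
    """Load a spec from a JSON string or file path."""
    try:
        entry = json.loads(source)
    except (json.JSONDecodeError, TypeError):
        with open(source) as fh:
            entry = json.load(fh)
    return _spec_from_dict(entry.get("name", ""), entry, source="file")
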