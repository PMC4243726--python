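"""Model selection and internal validation for mapping algorithms.

Covers the selection/validation machinery used when estimating a mapping
on a paired dataset: greedy forward stepwise selection on robust Wald
p-values (entry threshold 0.05), bootstrap selection frequencies,
variance-inflation diagnostics, MAE/RMSE goodness of fit with the
truncation adjustment, 5-fold cross-validation with pooled held-out
errors, and random-subsample validation at fixed sizes (100/300/500).

MAE is the headline selection criterion; RMSE is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import (ESTIMATORS, Design, FitResult, build_design,
                         check_full_rank)
from .instruments import ITEM_LABELS, PairedDataset
from .mapping import MappingModelSpec, predict_batch

# ---------------------------------------------------------------------------
# Goodness of fit


@dataclass(frozen=True)
class GOFStats:
    """MAE/RMSE and prediction summaries, raw and after truncation at 1."""

    n: int
    mae: float
    rmse: float
    mean_pred: float
    min_pred: float
    max_pred: float
    mae_truncated: float
    rmse_truncated: float
    mean_pred_truncated: float
    min_pred_truncated: float
    max_pred_truncated: float
    mean_observed: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def gof(observed, predicted) -> GOFStats:
    """MAE = mean |yhat - y|, RMSE = sqrt(mean (yhat - y)^2), plus the
    truncated variants computed with min(yhat, 1)."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: observed {y.shape} vs "
                         f"predicted {yhat.shape}")
    if y.size == 0:
        raise ValueError("gof needs at least one record")
    yt = np.minimum(yhat, 1.0)
    err, errt = yhat - y, yt - y
    return GOFStats(
        n=y.size,
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err ** 2).mean())),
        mean_pred=float(yhat.mean()), min_pred=float(yhat.min()),
        max_pred=float(yhat.max()),
        mae_truncated=float(np.abs(errt).mean()),
        rmse_truncated=float(np.sqrt((errt ** 2).mean())),
        mean_pred_truncated=float(yt.mean()), min_pred_truncated=float(yt.min()),
        max_pred_truncated=float(yt.max()),
        mean_observed=float(y.mean()),
    )


# ---------------------------------------------------------------------------
# Forward stepwise selection


class StepwiseError(RuntimeError):
    """Estimator failure mid-path; carries the partial trace."""

    def __init__(self, message: str, trace: "SelectionTrace"):
        super().__init__(message)
        self.trace = trace


@dataclass
class SelectionTrace:
    """Entry order with entry p-values, plus bootstrap counts if computed."""

    entered: list[tuple[str, float]] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    bootstrap_counts: Optional[dict[str, int]] = None
    bootstrap_replications: Optional[int] = None
    failures: int = 0


def _as_column_mapping(candidates) -> dict[str, np.ndarray]:
    if isinstance(candidates, pd.DataFrame):
        return {str(c): candidates[c].to_numpy(dtype=float)
                for c in candidates.columns}
    return {str(k): np.asarray(v, dtype=float) for k, v in candidates.items()}


def forward_stepwise(y, candidates, estimator: str = "OLS",
                     p_enter: float = 0.05,
                     base: Optional[Mapping[str, np.ndarray]] = None,
                     fit_kwargs: Optional[dict] = None) -> SelectionTrace:
    """Greedy forward selection on robust Wald p-values.

    At each step every remaining candidate is added in turn to the current
    model (intercept + ``base`` columns + already-selected candidates) and
    refitted; the candidate with the smallest robust-Wald p-value enters
    if that p-value is below ``p_enter``; ties break to the
    earliest-listed candidate.  Stops when no candidate qualifies.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; "
                         f"choose from {sorted(ESTIMATORS)}")
    cand = _as_column_mapping(candidates)
    if not cand:
        raise ValueError("no candidate terms supplied")
    y = np.asarray(y, dtype=float)
    base = {} if base is None else _as_column_mapping(base)
    fit_kwargs = dict(fit_kwargs or {})
    fit = ESTIMATORS[estimator]
    trace = SelectionTrace()
    remaining = list(cand)
    while remaining:
        best = None                      # (p, order, term)
        for order, term in enumerate(remaining):
            cols = {**base,
                    **{t: cand[t] for t in trace.selected},
                    term: cand[term]}
            X = np.column_stack([np.ones(len(y))] + list(cols.values()))
            terms = ["const"] + list(cols)
            try:
                check_full_rank(X, terms)
                res = fit(Design(X, y, terms), **fit_kwargs)
            except Exception as exc:     # noqa: BLE001 - surfaced with trace
                if isinstance(exc, (ValueError,)) and "rank deficient" in str(exc):
                    continue             # candidate collinear with current model
                raise StepwiseError(
                    f"estimator {estimator} failed while testing "
                    f"{term!r}: {exc}", trace) from exc
            p = res.p_values[term]
            if np.isnan(p):
                continue
            if best is None or p < best[0] - 1e-15:
                best = (p, order, term)
        if best is None or not best[0] < p_enter:
            break
        _, _, chosen = best
        trace.entered.append((chosen, float(best[0])))
        trace.selected.append(chosen)
        remaining.remove(chosen)
    return trace


def stepwise_items(data: PairedDataset, estimator: str = "OLS",
                   p_enter: float = 0.05,
                   fit_kwargs: Optional[dict] = None) -> SelectionTrace:
    """Forward stepwise over the 10 KIDSCREEN-10 items."""
    if data.utility is None:
        raise ValueError("stepwise selection needs observed utilities")
    cand = {lab: data.items[:, j].astype(float)
            for j, lab in enumerate(ITEM_LABELS)}
    return forward_stepwise(data.utility, cand, estimator=estimator,
                            p_enter=p_enter, fit_kwargs=fit_kwargs)


def bootstrap_stepwise(y, candidates, B: int = 100, seed: int = 0,
                       estimator: str = "OLS", p_enter: float = 0.05,
                       fit_kwargs: Optional[dict] = None) -> SelectionTrace:
    """Selection frequencies over ``B`` seeded bootstrap resamples of the
    records (pairs); fit failures are counted, not fatal."""
    if B < 1:
        raise ValueError("B must be >= 1")
    cand = _as_column_mapping(candidates)
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    counts = {t: 0 for t in cand}
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        boot = {t: v[idx] for t, v in cand.items()}
        try:
            tr = forward_stepwise(y[idx], boot, estimator=estimator,
                                  p_enter=p_enter, fit_kwargs=fit_kwargs)
        except StepwiseError:
            failures += 1
            continue
        for t in tr.selected:
            counts[t] += 1
    trace = SelectionTrace(bootstrap_counts=counts, bootstrap_replications=B,
                           failures=failures)
    trace.selected = sorted(counts, key=lambda t: -counts[t])
    return trace


# ---------------------------------------------------------------------------
# Multicollinearity


def vif(design: Design) -> dict:
    """Variance inflation factors: VIF_j = 1/(1 - R^2_j) from regressing
    each non-intercept term on all the others (with intercept).  Perfect
    collinearity is reported as ``inf``, not raised."""
    idx = [j for j, t in enumerate(design.terms) if t != "const"]
    if len(idx) < 2:
        raise ValueError("VIF needs at least two non-intercept terms")
    out = {}
    for j in idx:
        xj = design.X[:, j]
        others = [design.X[:, k] for k in idx if k != j]
        Z = np.column_stack([np.ones(design.n)] + others)
        coef, *_ = np.linalg.lstsq(Z, xj, rcond=None)
        resid = xj - Z @ coef
        sst = ((xj - xj.mean()) ** 2).sum()
        r2 = 1 - (resid @ resid) / sst if sst > 0 else 1.0
        out[design.terms[j]] = float("inf") if r2 >= 1 - 1e-12 else 1.0 / (1 - r2)
    out["mean_vif"] = float(np.mean([v for v in out.values()]))
    return out


# ---------------------------------------------------------------------------
# Validation I: 5-fold cross-validation


@dataclass(frozen=True)
class FoldPlan:
    """Seeded assignment of each record to one of k folds (sizes within 1)."""

    n: int
    seed: int
    k: int = 5
    assignment: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.assignment is None:
            rng = np.random.default_rng(self.seed)
            perm = rng.permutation(self.n)
            assign = np.empty(self.n, dtype=int)
            for g, chunk in enumerate(np.array_split(perm, self.k)):
                assign[chunk] = g
            object.__setattr__(self, "assignment", assign)

    def fold_indices(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == g)


@dataclass
class CrossValidationResult:
    pooled: GOFStats
    plan: FoldPlan
    per_fold: list[GOFStats]
    observed: np.ndarray
    predicted: np.ndarray


def _predict_from_fit(fit: FitResult, design: Design) -> np.ndarray:
    eta = design.X @ fit.coef_array
    if fit.estimator_label == "GLM":
        return 1.0 / (1.0 + np.exp(-eta))
    return eta


def crossvalidate_5fold(data: PairedDataset, estimator: str = "MM",
                        form: str = "item_linear",
                        items: Optional[Sequence[str]] = None,
                        stepwise: bool = False, p_enter: float = 0.05,
                        seed: int = 0,
                        fit_kwargs: Optional[dict] = None
                        ) -> CrossValidationResult:
    """Validation by 5-fold cross-validation: the sample is split into five
    seeded random groups; each group in turn is held out, the algorithm is
    re-estimated on the remaining 80% and used to predict the held-out
    20%; the n held-out errors are pooled for the goodness-of-fit.
    """
    if data.utility is None:
        raise ValueError("cross-validation needs observed utilities")
    if data.n < 10:
        raise ValueError("cross-validation needs n >= 10")
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    fit_kwargs = dict(fit_kwargs or {})
    plan = FoldPlan(data.n, seed)
    predicted = np.empty(data.n)
    per_fold = []
    for g in range(plan.k):
        test_idx = plan.fold_indices(g)
        train_idx = np.flatnonzero(plan.assignment != g)
        train, test = data.subset(train_idx), data.subset(test_idx)
        use_items = items
        if stepwise and form == "item_linear":
            use_items = stepwise_items(train, estimator=estimator,
                                       p_enter=p_enter,
                                       fit_kwargs=fit_kwargs).selected or None
        design = build_design(train, form, items=use_items)
        fit = ESTIMATORS[estimator](design, **fit_kwargs)
        test_design = Design(
            _design_like(test, design.terms), test.utility, list(design.terms))
        predicted[test_idx] = _predict_from_fit(fit, test_design)
        per_fold.append(gof(test.utility, predicted[test_idx]))
    pooled = gof(data.utility, predicted)
    return CrossValidationResult(pooled=pooled, plan=plan, per_fold=per_fold,
                                 observed=data.utility, predicted=predicted)


def _design_like(data: PairedDataset, terms: Sequence[str]) -> np.ndarray:
    cols = []
    for t in terms:
        if t == "const":
            cols.append(np.ones(data.n))
        elif t == "ks_index":
            cols.append(data.index)
        elif t == "ks_index_sq":
            cols.append(data.index ** 2)
        elif t in ITEM_LABELS:
            cols.append(data.items[:, ITEM_LABELS.index(t)].astype(float))
        elif t == "age":
            cols.append(data.age)
        elif t == "gender":
            cols.append(data.gender)
        else:
            raise ValueError(f"unknown term {t!r}")
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Validation II: random subsamples


def subsample_validation(data: PairedDataset, spec: MappingModelSpec,
                         sizes: Sequence[int] = (100, 300, 500),
                         seed: int = 0) -> dict[int, GOFStats]:
    """Apply a full-sample algorithm to seeded random subsamples (drawn
    without replacement) and report goodness-of-fit per size."""
    if data.utility is None:
        raise ValueError("subsample validation needs observed utilities")
    rng = np.random.default_rng(seed)
    out = {}
    for size in sizes:
        if not 1 <= size <= data.n:
            raise ValueError(f"subsample size {size} outside [1, n={data.n}]")
        idx = rng.choice(data.n, size=size, replace=False)
        sub = data.subset(idx)
        batch = predict_batch(sub, spec)
        out[int(size)] = gof(sub.utility, batch.raw)
    return out


# ---------------------------------------------------------------------------
# Ranking across candidate algorithms


def rank_report(results: Mapping[str, GOFStats],
                truncated: bool = False) -> pd.DataFrame:
    """Rank candidate algorithms by MAE (headline criterion), with RMSE
    ranks alongside."""
    mae_f = "mae_truncated" if truncated else "mae"
    rmse_f = "rmse_truncated" if truncated else "rmse"
    df = pd.DataFrame({
        "name": list(results),
        "mae": [getattr(g, mae_f) for g in results.values()],
        "rmse": [getattr(g, rmse_f) for g in results.values()],
    })
    df["mae_rank"] = df["mae"].rank(method="min").astype(int)
    df["rmse_rank"] = df["rmse"].rank(method="min").astype(int)
    return df.sort_values("mae_rank").reset_index(drop=True)
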