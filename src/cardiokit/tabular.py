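"""Clinical-table preparation: completeness filtering, stepwise feature
selection, and stable attribute identifiers.

Stepwise selection alternates forward entry and backward elimination on
ordinary-least-squares fits. At each step the candidate predictor with the
smallest partial-F p-value enters if it beats the entry tolerance; then any
included predictor whose p-value exceeds the exit tolerance is removed,
worst first. For adding or dropping a single predictor the partial-F test
equals the squared-t test of that coefficient in the larger model, which is
how it is computed here. Defaults p_enter=0.05, p_exit=0.10 (the classical
tolerances); ties in p-values break by attribute name for determinism, so
the result is invariant to predictor column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["ClinicalTable", "StepwiseResult", "drop_incomplete", "stepwise_select", "assign_identifiers"]


@dataclass
class ClinicalTable:
    """A clinical attribute table with a named binary outcome column."""

    frame: pd.DataFrame
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in self.frame.columns:
            raise ValueError(f"outcome column {self.outcome!r} absent")
        if len(self.frame) == 0:
            raise ValueError("zero data rows")

    @property
    def predictors(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.outcome]

    @property
    def complete_mask(self) -> pd.Series:
        return self.frame.notna().all(axis=1)


def drop_incomplete(table: ClinicalTable) -> ClinicalTable:
    """Remove rows with any missing predictor or outcome value."""
    mask = table.complete_mask
    kept = table.frame[mask].reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError("all rows are incomplete")
    return ClinicalTable(kept, table.outcome)


@dataclass(frozen=True)
class StepwiseResult:
    selected: tuple[str, ...]
    trace: tuple[tuple[str, str, float], ...]  # (attribute, enter|remove, p-value)
    p_enter: float
    p_exit: float


def _partial_f_pvalues(X: pd.DataFrame, y: np.ndarray, included: list[str]) -> pd.Series:
    """p-values of each included predictor's coefficient in the OLS fit."""
    design = sm.add_constant(X[included], has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(f"perfectly collinear attributes among {sorted(included)}")
    model = sm.OLS(y, design).fit()
    return model.pvalues.drop("const")


def stepwise_select(
    X: pd.DataFrame, y: pd.Series | np.ndarray, p_enter: float = 0.05, p_exit: float = 0.10
) -> StepwiseResult:
    """Forward-entry / backward-elimination predictor selection on OLS fits.

    Raises
    ------
    ValueError
        If tolerances are inconsistent, the sample is too small, or the
        included predictors become perfectly collinear.
    """
    if not p_enter <= p_exit:
        raise ValueError("p_enter must not exceed p_exit")
    y = np.asarray(y, dtype=float)
    if len(X) <= X.shape[1] + 1:
        raise ValueError("need more rows than predictors + 1")
    X = X[sorted(X.columns)]  # column-order invariance

    included: list[str] = []
    trace: list[tuple[str, str, float]] = []
    max_steps = 10 * max(1, X.shape[1])  # guard against enter/remove cycling
    while len(trace) < max_steps:
        changed = False
        # forward: candidate with the smallest single-term partial-F p-value
        excluded = [c for c in X.columns if c not in included]
        best_p, best_c = np.inf, None
        for c in excluded:
            pvals = _partial_f_pvalues(X, y, included + [c])
            p = float(pvals[c])
            if np.isnan(p):
                raise ValueError(f"perfect collinearity involving column {c!r}")
            if p < best_p:  # sorted columns => ties keep the first name
                best_p, best_c = p, c
        if best_c is not None and best_p < p_enter:
            included.append(best_c)
            trace.append((best_c, "enter", best_p))
            changed = True
        # backward: drop the included attribute with the largest p-value
        while included:
            pvals = _partial_f_pvalues(X, y, included)
            if pvals.isna().any():
                bad = sorted(pvals.index[pvals.isna()])
                raise ValueError(f"perfect collinearity among included columns {bad}")
            ordered = pvals.sort_values(ascending=False, kind="stable")
            worst, worst_p = ordered.index[0], float(ordered.iloc[0])
            if worst_p > p_exit:
                included.remove(worst)
                trace.append((worst, "remove", worst_p))
                changed = True
            else:
                break
        if not changed:
            break
    return StepwiseResult(tuple(included), tuple(trace), p_enter, p_exit)


def assign_identifiers(table: ClinicalTable) -> tuple[ClinicalTable, dict[str, int]]:
    """Map each attribute to a stable integer ID (1-based, sorted name order)."""
    cols = list(table.frame.columns)
    if len(set(cols)) != len(cols):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise ValueError(f"duplicate column names: {dupes}")
    mapping = {name: i + 1 for i, name in enumerate(sorted(cols))}
    return table, mapping
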