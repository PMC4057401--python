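"""Stepwise multiple linear regression for descriptor selection.

Classic forward-entry / backward-removal stepwise MLR with the selection
round as the (numeric) response: at each step the out-of-model descriptor
with the smallest partial-F p-value enters if p < p_enter, then any
in-model descriptor with p > p_remove leaves.  Defaults (0.05 / 0.10) are
the conventional stepwise thresholds.  Deterministic given the table; ties
are broken by column name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: columns this collinear with the in-model set are skipped
COLLINEARITY_R2 = 0.9999


@dataclass
class StepwiseResult:
    selected: list[str]
    steps: list[dict] = field(default_factory=list)

    def __iter__(self):
        return iter(self.selected)


def _candidate_pvalue(y: np.ndarray, X_in: np.ndarray, x_new: np.ndarray) -> float:
    """Partial-F p-value for adding x_new to the model (== its t-test p)."""
    X = sm.add_constant(np.column_stack([X_in, x_new]) if X_in.size else x_new)
    fit = sm.OLS(y, X).fit()
    return float(fit.pvalues[-1])


def stepwise_mlr(
    table: pd.DataFrame,
    response: str = "round",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 100,
) -> StepwiseResult:
    """Select descriptors by stepwise MLR against ``response``.

    ``table`` holds one row per aptamer with descriptor columns plus the
    response column; non-numeric columns (e.g. ``id``) are ignored.
    """
    if not p_enter < p_remove:
        raise ValueError("p_enter must be < p_remove")
    if response not in table.columns:
        raise ValueError(f"response column {response!r} missing")
    y = table[response].to_numpy(dtype=float)
    candidates = [
        c
        for c in table.columns
        if c != response and pd.api.types.is_numeric_dtype(table[c])
    ]
    cols: dict[str, np.ndarray] = {}
    for c in sorted(candidates):
        x = table[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"column {c!r} contains non-finite values")
        if np.ptp(x) == 0:
            logger.warning("excluding constant column %r", c)
            continue
        cols[c] = x

    selected: list[str] = []
    steps: list[dict] = []
    for _ in range(max_steps):
        changed = False
        X_in = (
            np.column_stack([cols[c] for c in selected]) if selected else np.empty((len(y), 0))
        )
        # forward entry
        best_name, best_p = None, np.inf
        for name in sorted(set(cols) - set(selected)):
            x = cols[name]
            if selected:
                r2 = sm.OLS(x, sm.add_constant(X_in)).fit().rsquared
                if r2 > COLLINEARITY_R2:
                    logger.warning("skipping collinear column %r (R²=%.6f)", name, r2)
                    continue
            p = _candidate_pvalue(y, X_in, x)
            if p < best_p:
                best_name, best_p = name, p
        if best_name is not None and best_p < p_enter:
            selected.append(best_name)
            steps.append({"action": "add", "name": best_name, "p": best_p})
            changed = True
        # backward removal
        while len(selected) > 0:
            X = sm.add_constant(np.column_stack([cols[c] for c in selected]))
            fit = sm.OLS(y, X).fit()
            pvals = dict(zip(selected, fit.pvalues[1:]))
            worst = max(sorted(pvals), key=lambda c: pvals[c])
            if pvals[worst] > p_remove:
                selected.remove(worst)
                steps.append({"action": "remove", "name": worst, "p": float(pvals[worst])})
                changed = True
            else:
                break
        if not changed:
            break
    return StepwiseResult(selected, steps)
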