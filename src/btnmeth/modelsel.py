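"""Ordinary least squares with stepwise AIC selection over window covariates.

Used to build minimal predictor models of window-level 5mC and 5hmC from
genomic composition (gene fraction, CpG-island fraction, GC content,
indetermination content, repeat fractions, the other modification channel).
The AIC is the Gaussian profile-likelihood form with the additive constant
dropped: ``AIC = n * ln(RSS / n) + 2 * (k + 1)`` for k slope terms plus an
intercept; only differences matter for selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class OLSFit:
    coefficients: dict          # predictor -> raw-scale coefficient (incl. "intercept")
    rss: float
    aic: float
    n: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.coefficients["intercept"])
        for name, beta in self.coefficients.items():
            if name != "intercept":
                out = out + beta * X[name].to_numpy()
        return out


@dataclass
class StepwiseResult:
    selected: tuple
    coefficients: dict
    signs: dict                       # predictor -> +1 / -1
    standardized: dict                # predictor -> coefficient * sd(x)
    aic_trajectory: tuple             # one AIC per accepted step (strictly decreasing)
    final_aic: float
    fit: OLSFit

    @property
    def strongest_predictor(self) -> str | None:
        if not self.standardized:
            return None
        return max(self.standardized, key=lambda k: abs(self.standardized[k]))


def _design(X: pd.DataFrame, predictors) -> np.ndarray:
    cols = [np.ones(len(X))] + [X[p].to_numpy(dtype=float) for p in predictors]
    return np.column_stack(cols)


def aic_from_rss(rss: float, n: int, k: int) -> float:
    return n * float(np.log(max(rss, 1e-300) / n)) + 2 * (k + 1)


def ols_fit(X: pd.DataFrame, y, predictors=None) -> OLSFit:
    """Least-squares fit of ``y`` on the given predictor columns.

    Raises on rank deficiency, naming the collinear columns.
    """
    predictors = list(predictors if predictors is not None else X.columns)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n <= len(predictors):
        raise ValueError(f"need more rows ({n}) than predictors ({len(predictors)})")
    design = _design(X, predictors)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the offending columns via pivoted QR on the slope columns
        bad = []
        for i, p in enumerate(predictors):
            sub = np.delete(design, i + 1, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(p)
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ beta) ** 2))
    coef = {"intercept": float(beta[0])}
    coef.update({p: float(b) for p, b in zip(predictors, beta[1:])})
    return OLSFit(coefficients=coef, rss=rss, aic=aic_from_rss(rss, n, len(predictors)), n=n)


def stepwise_aic(X: pd.DataFrame, y, candidates=None, direction: str = "both") -> StepwiseResult:
    """Greedy stepwise selection minimising AIC.

    Starting from the intercept-only model, at every step the single add or
    drop move with the lowest AIC is accepted while it strictly improves on
    the current AIC; ties break deterministically by candidate name order.
    Rows with any undefined value among candidates or response are excluded
    listwise before fitting.
    """
    candidates = sorted(candidates if candidates is not None else X.columns)
    if not candidates:
        raise ValueError("at least one candidate predictor is required")
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    for c in candidates:
        keep &= np.isfinite(X[c].to_numpy(dtype=float))
    X = X.loc[keep, candidates].reset_index(drop=True)
    y = y[keep]

    selected: list[str] = []
    current = ols_fit(X, y, [])
    trajectory = [current.aic]
    while True:
        moves = []
        if direction in ("both", "forward"):
            for c in candidates:
                if c not in selected:
                    moves.append(("add", c, sorted(selected + [c])))
        if direction in ("both", "backward"):
            for c in selected:
                moves.append(("drop", c, sorted(s for s in selected if s != c)))
        best = None
        for _, name, preds in sorted(moves, key=lambda m: (m[0], m[1])):
            try:
                fit = ols_fit(X, y, preds)
            except np.linalg.LinAlgError:
                continue
            if best is None or fit.aic < best[0].aic - 1e-12:
                best = (fit, preds)
        if best is None or best[0].aic >= current.aic - 1e-12:
            break
        current, selected = best[0], list(best[1])
        trajectory.append(current.aic)

    slopes = {p: current.coefficients[p] for p in selected}
    standardized = {p: slopes[p] * float(np.std(X[p].to_numpy(dtype=float), ddof=1))
                    for p in selected}
    return StepwiseResult(
        selected=tuple(selected),
        coefficients=dict(current.coefficients),
        signs={p: (1 if b > 0 else -1) for p, b in slopes.items()},
        standardized=standardized,
        aic_trajectory=tuple(trajectory),
        final_aic=current.aic,
        fit=current,
    )
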