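"""Backward stepwise logistic regression for impairment biomarkers.

statsmodels-style: :class:`StepwiseLogit` is built from a cohort table and
``fit()`` returns a :class:`StepwiseResults` carrying the elimination
trace, retained odds ratios with Wald confidence intervals, and ROC AUCs
of the final and single-predictor models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats import roc_auc


class SeparationError(RuntimeError):
    """Raised when the logistic fit diverges (quasi-)separated data."""


@dataclass
class StepwiseResults:
    """Results of a backward stepwise logistic fit."""

    outcome: str
    candidates: tuple[str, ...]
    removal_alpha: float
    trace: pd.DataFrame  # columns: step, removed, p_at_removal
    params: pd.DataFrame  # index: retained terms; B, OR, or_ci_low, or_ci_high, p
    model_auc: float | None
    predictor_auc: dict[str, float]
    n: int

    @property
    def retained(self) -> list[str]:
        return [t for t in self.params.index if t != "const"]

    def summary(self) -> str:
        lines = [
            f"Backward stepwise logistic regression: {self.outcome}",
            f"  n = {self.n}; candidates = {list(self.candidates)}; "
            f"removal alpha = {self.removal_alpha}",
        ]
        if len(self.trace):
            steps = ", ".join(
                f"{r.removed} (p={r.p_at_removal:.3f})" for r in self.trace.itertuples()
            )
            lines.append(f"  removed: {steps}")
        lines.append(self.params.round(4).to_string())
        if self.model_auc is not None:
            lines.append(f"  final-model AUC = {self.model_auc:.3f}")
        for k, v in self.predictor_auc.items():
            lines.append(f"  single-predictor AUC [{k}] = {v:.3f}")
        return "\n".join(lines)


class StepwiseLogit:
    """Backward elimination on Wald p-values.

    Starting from the full maximum-likelihood logistic model of all
    candidates, the term with the largest Wald p is removed while that p
    exceeds ``removal_alpha`` (default 0.05); the intercept is never
    removed.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        outcome: str,
        candidates: Sequence[str],
        removal_alpha: float = 0.05,
    ) -> None:
        if len(candidates) < 1:
            raise ValueError("need at least one candidate variable")
        data = table.loc[:, [outcome] + list(candidates)].dropna()
        y = data[outcome].astype(float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError(f"outcome {outcome!r} must be binary 0/1")
        if (y == 1).sum() < 5 or (y == 0).sum() < 5:
            raise ValueError("need >= 5 subjects in each outcome class")
        self.outcome = outcome
        self.candidates = tuple(candidates)
        self.removal_alpha = removal_alpha
        self._y = y
        self._X = data[list(candidates)].astype(float)

    def _fit_one(self, terms: list[str]):
        X = sm.add_constant(self._X[terms], has_constant="add")
        try:
            res = sm.Logit(self._y, X).fit(disp=0, maxiter=200)
        except Exception as err:  # PerfectSeparationError and friends
            raise SeparationError(f"logistic fit failed for terms {terms}: {err}") from err
        if not res.mle_retvals.get("converged", True) or np.any(
            np.abs(res.params.drop("const", errors="ignore")) > 50
        ):
            raise SeparationError(
                f"diverging coefficients for terms {terms}: separation suspected "
                f"(max |B| = {np.abs(res.params).max():.1f})"
            )
        return res

    def fit(self) -> StepwiseResults:
        terms = list(self.candidates)
        trace_rows = []
        res = self._fit_one(terms)
        step = 0
        while terms:
            pvals = res.pvalues.drop("const", errors="ignore")
            worst = pvals.idxmax()
            if pvals[worst] <= self.removal_alpha:
                break
            step += 1
            trace_rows.append(
                {"step": step, "removed": worst, "p_at_removal": float(pvals[worst])}
            )
            terms.remove(worst)
            if not terms:
                res = None
                break
            res = self._fit_one(terms)

        if res is not None:
            ci = np.exp(res.conf_int(alpha=0.05))
            params = pd.DataFrame(
                {
                    "B": res.params,
                    "OR": np.exp(res.params),
                    "or_ci_low": ci[0],
                    "or_ci_high": ci[1],
                    "p": res.pvalues,
                }
            )
            model_auc = roc_auc(res.predict(), self._y.values)
        else:  # intercept-only: every candidate eliminated
            params = pd.DataFrame(columns=["B", "OR", "or_ci_low", "or_ci_high", "p"])
            model_auc = None
        pred_auc = {
            t: roc_auc(self._X[t].values, self._y.values, orient=True)[0]
            for t in terms
        }
        return StepwiseResults(
            outcome=self.outcome,
            candidates=self.candidates,
            removal_alpha=self.removal_alpha,
            trace=pd.DataFrame(trace_rows, columns=["step", "removed", "p_at_removal"]),
            params=params,
            model_auc=model_auc,
            predictor_auc=pred_auc,
            n=len(self._y),
        )
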