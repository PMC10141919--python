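"""Two-level forward-stepwise logistic regression for feature selection.

The inferential model for the binary full-flow outcome is a fixed-effects
logistic regression in which participant identity is forced into the
model as a factor (reference-cell dummy coding, first participant as
reference) before any physiological feature is considered.  Candidate
features then enter one at a time by a forward stepwise procedure: at
each step every remaining candidate is added to the current model, the
improvement is judged by a likelihood-ratio test, and the candidate with
the smallest LRT p-value enters if p < alpha (default 0.10, i.e. a 90%
confidence entry criterion).  There is no removal step.  Ties are broken
by the larger chi-square, then by feature-name order in the candidate
list.

Maximum-likelihood fitting is delegated to statsmodels' Newton
optimizer; standard errors come from the observed information.  Final
model terms are summarised Wald-style: chi2 = (b / SE)^2 with 1 df, and
the odds ratio exp(b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "SelectionError",
    "LogisticFit",
    "StepwiseResults",
    "StepwiseFlowLogit",
    "fit_logistic_ml",
    "likelihood_ratio_test",
    "forward_stepwise",
    "wald_summary",
    "participant_design",
]


class SelectionError(ValueError):
    pass


@dataclass
class LogisticFit:
    """A maximum-likelihood logistic fit: terms, coefficients, SEs, loglik."""

    terms: list
    params: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool
    n: int
    separation: bool = False

    def coef(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        xm = X[self.terms].to_numpy(dtype=float)
        eta = xm @ self.params
        return 1.0 / (1.0 + np.exp(-eta))


def _check_design(X: pd.DataFrame, y: np.ndarray) -> None:
    arr = X.to_numpy(dtype=float)
    n, k = arr.shape
    if n <= k:
        raise SelectionError(f"n = {n} rows must exceed {k} design columns")
    const = [c for c, col in zip(X.columns, arr.T)
             if np.all(col == 0)]
    if const:
        raise SelectionError(f"constant-zero columns in design: {const}")
    rank = np.linalg.matrix_rank(arr)
    if rank < k:
        # point at the columns that do not add rank
        bad = []
        cols = []
        for j, name in enumerate(X.columns):
            cand = cols + [j]
            if np.linalg.matrix_rank(arr[:, cand]) == len(cols):
                bad.append(name)
            else:
                cols = cand
        raise SelectionError(f"rank-deficient design; collinear columns: {bad}")


def fit_logistic_ml(X: pd.DataFrame, y, tol: float = 1e-8,
                    max_iter: int = 100) -> LogisticFit:
    """Plain maximum-likelihood logistic regression (Newton / IRLS).

    On quasi-separation the optimizer stops at ``max_iter`` and the fit is
    returned with ``separation=True`` and a warning that the standard
    errors are unreliable.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise SelectionError("labels must be binary 0/1")
    _check_design(X, y)
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X.to_numpy(dtype=float)).fit(
                method="newton", maxiter=max_iter, tol=tol, disp=False,
                warn_convergence=False,
            )
        except Exception:
            # Newton can blow up under complete separation; BFGS limps to
            # the boundary instead so we can still report the fit shape.
            res = sm.Logit(y, X.to_numpy(dtype=float)).fit(
                method="bfgs", maxiter=max_iter, disp=False,
            )
            separation = True
        for w in caught:
            if issubclass(w.category, PerfectSeparationWarning):
                separation = True
    fitted = 1.0 / (1.0 + np.exp(-(X.to_numpy(dtype=float) @ res.params)))
    if np.max(np.abs(fitted - y)) < 1e-6 or np.any(np.abs(res.params) > 50):
        separation = True
    if separation:
        warnings.warn(
            "quasi-separation detected: coefficients on the boundary, "
            "standard errors unreliable"
        )
    bse = np.asarray(res.bse, dtype=float)
    return LogisticFit(
        terms=list(X.columns),
        params=np.asarray(res.params, dtype=float),
        bse=bse,
        llf=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)) and not separation,
        n=len(y),
        separation=separation,
    )


def likelihood_ratio_test(null: LogisticFit, alt: LogisticFit):
    """LRT of nested logistic fits: (chi2, df, p).

    chi2 = 2 (ll_alt - ll_null) clipped at 0; df is the difference in term
    counts; p is the upper chi-square tail.
    """
    if not set(null.terms) <= set(alt.terms):
        raise SelectionError("models are not nested (null terms not a subset)")
    if null.n != alt.n:
        raise SelectionError("models were fitted to different numbers of rows")
    df = len(alt.terms) - len(null.terms)
    chi2 = max(2.0 * (alt.llf - null.llf), 0.0)
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def wald_summary(fit: LogisticFit) -> pd.DataFrame:
    """Per-term Wald chi-square (1 df), p-value and odds ratio.

    Terms with non-finite SEs are flagged and carry no test.
    """
    rows = []
    for term, b, se in zip(fit.terms, fit.params, fit.bse):
        odds = float(np.exp(b)) if b < 700 else float("inf")
        if not np.isfinite(se) or se <= 0 or fit.separation:
            rows.append({"term": term, "estimate": b, "se": se,
                         "wald_chi2": np.nan, "p_value": np.nan,
                         "odds_ratio": odds, "flagged": True})
            continue
        chi2 = (b / se) ** 2
        rows.append({
            "term": term, "estimate": b, "se": se,
            "wald_chi2": chi2, "p_value": float(sps.chi2.sf(chi2, 1)),
            "odds_ratio": odds, "flagged": False,
        })
    return pd.DataFrame(rows).set_index("term")


def participant_design(participant_ids: Sequence) -> pd.DataFrame:
    """Intercept + reference-cell participant dummies (first id = reference)."""
    ids = pd.Series(list(participant_ids))
    levels = list(pd.unique(ids))
    if len(levels) < 2:
        raise SelectionError("need at least 2 participants for the forced factor")
    design = {"intercept": np.ones(len(ids))}
    for level in levels[1:]:
        design[f"participant[{level}]"] = (ids == level).astype(float).to_numpy()
    return pd.DataFrame(design)


@dataclass
class StepwiseResults:
    """Entry trace and final fit of the forward stepwise procedure."""

    forced_terms: list
    trace: list  # (feature, lrt_chi2, df, p) per entry, in entry order
    final_fit: LogisticFit
    alpha: float
    screen: pd.DataFrame  # first-step LRT scan over all candidates

    @property
    def selected_features(self) -> list:
        return [t[0] for t in self.trace]

    def wald_summary(self, features_only: bool = True) -> pd.DataFrame:
        table = wald_summary(self.final_fit)
        if features_only:
            table = table.loc[self.selected_features]
        return table

    def summary(self) -> str:
        lines = [
            "Forward stepwise logistic regression "
            f"(participant forced, entry LRT p < {self.alpha:g})",
            "=" * 72,
            f"n = {self.final_fit.n}, forced terms: {len(self.forced_terms)}, "
            f"entered features: {len(self.trace)}",
            "",
            f"{'step':<5}{'feature':<24}{'LRT chi2':>10}{'df':>4}{'p':>10}",
            "-" * 53,
        ]
        for step, (name, chi2, df, p) in enumerate(self.trace, start=1):
            lines.append(f"{step:<5}{name:<24}{chi2:>10.2f}{df:>4}{p:>10.4f}")
        if not self.trace:
            lines.append("(no feature met the entry criterion)")
        lines += ["", "final model (selected features):",
                  self.wald_summary().to_string(float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)


class StepwiseFlowLogit:
    """Two-level stepwise logistic model of flow on physiological features.

    Parameters
    ----------
    features : DataFrame
        Candidate feature columns (numeric).
    labels : sequence of 0/1
        Full-flow outcome per row.
    participants : sequence
        Participant identifier per row; forced into the model as a factor
        before any feature may enter.
    """

    def __init__(self, features: pd.DataFrame, labels, participants):
        self.features = features.reset_index(drop=True).astype(float)
        self.labels = np.asarray(labels, dtype=float)
        self.participants = list(participants)
        if len(self.features) != len(self.labels) or len(self.labels) != len(self.participants):
            raise SelectionError("features, labels and participants disagree in length")

    def fit(self, alpha: float = 0.10) -> StepwiseResults:
        if not 0 < alpha < 1:
            raise SelectionError("alpha must lie in (0, 1)")
        forced = participant_design(self.participants)
        try:
            current = fit_logistic_ml(forced, self.labels)
        except SelectionError as exc:
            raise SelectionError(f"forced participant model is not identifiable: {exc}")
        design = forced.copy()
        remaining = list(self.features.columns)
        trace = []
        screen = None
        while remaining:
            scans = []
            for name in remaining:
                trial = design.copy()
                trial[name] = self.features[name].to_numpy()
                try:
                    # the scan fits dozens of throwaway models; keep their
                    # separation warnings quiet and rely on the winner's flag
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fit = fit_logistic_ml(trial, self.labels)
                except SelectionError:
                    continue
                if fit.separation:
                    # a quasi-separated trial has no ML estimate and an
                    # unreliable (inflated) LRT; it cannot enter
                    continue
                chi2, df, p = likelihood_ratio_test(current, fit)
                scans.append((name, chi2, df, p, fit))
            if screen is None:
                screen = pd.DataFrame(
                    [(n, c, d, p) for n, c, d, p, _ in scans],
                    columns=["feature", "lrt_chi2", "df", "p_value"],
                ).set_index("feature")
            if not scans:
                break
            # smallest p wins; ties -> larger chi2, then candidate order
            order = {n: j for j, n in enumerate(remaining)}
            scans.sort(key=lambda t: (t[3], -t[1], order[t[0]]))
            name, chi2, df, p, fit = scans[0]
            if p >= alpha:
                break
            trace.append((name, chi2, df, p))
            design[name] = self.features[name].to_numpy()
            current = fit
            remaining.remove(name)
        return StepwiseResults(
            forced_terms=list(forced.columns),
            trace=trace,
            final_fit=current,
            alpha=alpha,
            screen=screen if screen is not None else pd.DataFrame(),
        )


def forward_stepwise(features: pd.DataFrame, labels, participants,
                     alpha: float = 0.10) -> StepwiseResults:
    """Functional entry point for :class:`StepwiseFlowLogit`."""
    return StepwiseFlowLogit(features, labels, participants).fit(alpha=alpha)
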