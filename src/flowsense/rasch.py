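"""Rasch Rating Scale Model (RSM) measurement of the Flow State Scale.

The RSM is a polytomous Rasch model: person n responding to item i picks
category k in 0..M with probability

    P(X_ni = k)  proportional to  exp( k (beta_n - delta_i) - sum_{j<=k} tau_j )

where beta_n is the person's flow level, delta_i the difficulty of
endorsing flow element i, and tau_1..tau_M category thresholds shared by
all items.  The scale is identified by mean(delta) = 0 and sum(tau) = 0;
at beta = delta_i the extreme categories are equally likely,
P(X=0) = P(X=M), so delta_i marks the centre of the rating scale for
element i.

Estimation is joint maximum likelihood (JMLE) with alternating damped
Newton steps for the betas, deltas and taus.  Persons or items with
extreme raw scores (all-minimum or all-maximum) carry no information about
their own parameter under ML; they are excluded from estimation and then
assigned a finite measure by solving for the parameter whose expected
score matches the raw score moved 0.25 score points inward -- the
conventional extreme-score adjustment.

Fit assessment follows standard Rasch practice: mean-square infit
(information weighted) and outfit (outlier sensitive) statistics with
expectation 1, values above 1.5 flagged as misfit; a principal components
analysis of the correlation matrix of standardized residuals, where a
first eigenvalue below 2 is read as conformity with unidimensionality;
and separation reliability (variance of measures net of error variance,
over variance of measures).

The binary "full flow" label used downstream is endorsing the
transformation-of-time element -- the hardest element in the flow
hierarchy -- at "agree" or above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ITEM_NAMES",
    "RaschError",
    "RatingScaleModel",
    "RatingScaleResults",
    "FitStats",
    "ResidualPCAResult",
    "rsm_category_probs",
    "rsm_expected_score",
    "fit_rsm",
    "person_item_fit",
    "residual_pca",
    "separation_reliability",
    "wright_map",
    "label_flow",
    "AGREE_THRESHOLD",
]

#: The nine elements of flow, one survey item each.
ITEM_NAMES = (
    "challenge_skill_balance",
    "action_awareness_merging",
    "clear_goals",
    "unambiguous_feedback",
    "concentration",
    "sense_of_control",
    "loss_of_self_consciousness",
    "transformation_of_time",
    "autotelic_experience",
)

FLOW_ITEM = "transformation_of_time"
#: "agree" on the 0..4 coding (strongly disagree = 0 .. strongly agree = 4).
AGREE_THRESHOLD = 3

MISFIT_CUTOFF = 1.5
UNIDIM_EIGENVALUE_CUTOFF = 2.0
EXTREME_SCORE_ADJUSTMENT = 0.25


class RaschError(ValueError):
    pass


# ---------------------------------------------------------------------------
# model probabilities


def _cumulative_tau(tau: np.ndarray) -> np.ndarray:
    """[0, tau_1, tau_1+tau_2, ...]: threshold part of the category logit."""
    tau = np.asarray(tau, dtype=float)
    return np.concatenate([[0.0], np.cumsum(tau)])


def rsm_category_probs(beta, delta, tau) -> np.ndarray:
    """Category probabilities P(X_ni = k), shape (N, I, M+1).

    ``beta`` (N,), ``delta`` (I,), ``tau`` (M,) are broadcast; scalars are
    accepted.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    ctau = _cumulative_tau(tau)  # (M+1,)
    k = np.arange(ctau.size)
    theta = beta[:, None] - delta[None, :]  # (N, I)
    eta = k[None, None, :] * theta[:, :, None] - ctau[None, None, :]
    eta -= eta.max(axis=2, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=2, keepdims=True)
    return p


def rsm_expected_score(beta, delta, tau):
    """Expected item score E[X | beta, delta, tau], shape (N, I)."""
    p = rsm_category_probs(beta, delta, tau)
    k = np.arange(p.shape[2])
    return (p * k).sum(axis=2)


def _expected_and_variance(beta, delta, tau):
    p = rsm_category_probs(beta, delta, tau)
    k = np.arange(p.shape[2])
    e = (p * k).sum(axis=2)
    w = (p * k**2).sum(axis=2) - e**2
    return e, w


def _loglik(x: np.ndarray, beta, delta, tau) -> float:
    p = rsm_category_probs(beta, delta, tau)
    n, i = np.indices(x.shape)
    return float(np.log(np.clip(p[n, i, x], 1e-300, None)).sum())


# ---------------------------------------------------------------------------
# results containers


@dataclass
class FitStats:
    """Expected scores, model variances, standardized residuals and the
    infit/outfit mean squares derived from them (non-extreme cells only)."""

    expected: pd.DataFrame
    variance: pd.DataFrame
    z: pd.DataFrame  # standardized residuals (x - E) / sqrt(W)
    item_infit: pd.Series
    item_outfit: pd.Series
    person_infit: pd.Series
    person_outfit: pd.Series

    @property
    def misfitting_items(self) -> list:
        """Items with infit or outfit mean square above 1.5."""
        bad = (self.item_infit > MISFIT_CUTOFF) | (self.item_outfit > MISFIT_CUTOFF)
        return list(self.item_infit.index[bad])


@dataclass
class ResidualPCAResult:
    """PCA of the item-by-item correlation matrix of standardized residuals."""

    eigenvalues: np.ndarray  # non-increasing; sum = number of retained items
    loadings: pd.Series  # item loadings on the first residual component
    retained_items: list

    @property
    def first_eigenvalue(self) -> float:
        return float(self.eigenvalues[0])

    @property
    def unidimensional(self) -> bool:
        return self.first_eigenvalue < UNIDIM_EIGENVALUE_CUTOFF


class RatingScaleModel:
    """Rating Scale Model for an N x I polytomous response matrix.

    Parameters
    ----------
    responses : DataFrame or array-like of int
        Responses in 0..M.  A DataFrame's columns name the items and its
        index keys the persons (e.g. (participant, task) tuples).
    n_categories : int, optional
        Number of response categories M+1.  Defaults to
        ``max(responses) + 1``.  Categories never observed anywhere are
        collapsed out (with a warning) before estimation.
    """

    def __init__(self, responses, n_categories: Optional[int] = None):
        if isinstance(responses, pd.DataFrame):
            self.data = responses.copy()
        else:
            arr = np.asarray(responses)
            self.data = pd.DataFrame(
                arr, columns=[f"item_{j + 1}" for j in range(arr.shape[1])]
            )
        x = self.data.to_numpy()
        if x.ndim != 2 or x.shape[1] < 2:
            raise RaschError("need an N x I matrix with at least 2 items")
        if not np.issubdtype(x.dtype, np.number) or np.any(x != np.floor(x)):
            raise RaschError("responses must be integers")
        x = x.astype(int)
        if x.min() < 0:
            raise RaschError("responses must be non-negative")
        m = int(x.max()) if n_categories is None else n_categories - 1
        if n_categories is not None and x.max() > m:
            raise RaschError("responses exceed declared number of categories")
        observed = np.array([np.any(x == k) for k in range(m + 1)])
        if not observed.all():
            warnings.warn(
                f"categories {list(np.flatnonzero(~observed))} unobserved; "
                "collapsing to contiguous codes"
            )
            remap = np.cumsum(observed) - 1
            x = remap[x]
            m = int(x.max())
        if m < 1:
            raise RaschError("responses show no variation across categories")
        self.x = x
        self.max_score = m
        self.item_names = list(self.data.columns)
        self.person_keys = list(self.data.index)

    def fit(self, tol: float = 1e-4, max_iter: int = 200,
            extreme_adjustment: float = EXTREME_SCORE_ADJUSTMENT) -> "RatingScaleResults":
        """JMLE fit by alternating damped Newton steps.

        Converged when no parameter moves by more than ``tol`` logits in a
        full sweep.  Raises :class:`RaschError` with the last step sizes on
        non-convergence.
        """
        x, m = self.x, self.max_score
        n_persons, n_items = x.shape
        row_scores = x.sum(axis=1)
        col_scores = x.sum(axis=0)
        extreme_rows = (row_scores == 0) | (row_scores == n_items * m)
        extreme_cols = (col_scores == 0) | (col_scores == n_persons * m)
        keep_r = ~extreme_rows
        keep_c = ~extreme_cols
        if keep_r.sum() < 2 or keep_c.sum() < 2:
            raise RaschError(
                "fewer than 2 non-extreme persons or items; model unidentifiable"
            )
        xs = x[np.ix_(keep_r, keep_c)]
        nr, nc = xs.shape
        r = xs.sum(axis=1).astype(float)
        s = xs.sum(axis=0).astype(float)

        # moderate starting values: centred log-odds of the raw scores
        beta = np.log((r + 0.5) / (nc * m - r + 0.5))
        delta = -np.log((s + 0.5) / (nr * m - s + 0.5))
        delta -= delta.mean()
        tau = np.zeros(m)

        max_step = np.inf
        for iteration in range(1, max_iter + 1):
            beta_old, delta_old, tau_old = beta.copy(), delta.copy(), tau.copy()

            e, w = _expected_and_variance(beta, delta, tau)
            beta = beta + np.clip((r - e.sum(axis=1)) / np.maximum(w.sum(axis=1), 1e-10),
                                  -1.0, 1.0)

            e, w = _expected_and_variance(beta, delta, tau)
            delta = delta + np.clip((e.sum(axis=0) - s) / np.maximum(w.sum(axis=0), 1e-10),
                                    -1.0, 1.0)

            p = rsm_category_probs(beta, delta, tau)
            for j in range(1, m + 1):
                p_ge = p[:, :, j:].sum(axis=2)
                x_ge = (xs >= j).astype(float)
                grad = (p_ge - x_ge).sum()
                info = np.maximum((p_ge * (1.0 - p_ge)).sum(), 1e-10)
                tau[j - 1] += np.clip(grad / info, -1.0, 1.0)

            # re-impose the identification constraints
            c = tau.mean()
            tau -= c
            delta += c
            c = delta.mean()
            delta -= c
            beta -= c

            max_step = max(
                np.abs(beta - beta_old).max(),
                np.abs(delta - delta_old).max(),
                np.abs(tau - tau_old).max(),
            )
            if max_step < tol:
                break
        else:
            raise RaschError(
                f"JMLE did not converge in {max_iter} iterations "
                f"(last max parameter change {max_step:.2e} logits)"
            )

        e, w = _expected_and_variance(beta, delta, tau)
        se_beta = 1.0 / np.sqrt(np.maximum(w.sum(axis=1), 1e-12))
        se_delta = 1.0 / np.sqrt(np.maximum(w.sum(axis=0), 1e-12))
        p = rsm_category_probs(beta, delta, tau)
        se_tau = np.empty(m)
        for j in range(1, m + 1):
            p_ge = p[:, :, j:].sum(axis=2)
            se_tau[j - 1] = 1.0 / np.sqrt(np.maximum((p_ge * (1 - p_ge)).sum(), 1e-12))

        # fill in extreme persons/items via the inward score adjustment
        full_beta = np.full(n_persons, np.nan)
        full_se_beta = np.full(n_persons, np.nan)
        full_beta[keep_r] = beta
        full_se_beta[keep_r] = se_beta
        for idx in np.flatnonzero(extreme_rows):
            raw = row_scores[idx]
            target = (extreme_adjustment if raw == 0
                      else n_items * m - extreme_adjustment)
            # measured against the calibrated (non-extreme) items
            target *= keep_c.sum() / n_items
            full_beta[idx] = _solve_measure(target, delta, tau)
            _, w_ext = _expected_and_variance(np.array([full_beta[idx]]), delta, tau)
            full_se_beta[idx] = 1.0 / np.sqrt(max(w_ext.sum(), 1e-12))

        full_delta = np.full(n_items, np.nan)
        full_se_delta = np.full(n_items, np.nan)
        full_delta[keep_c] = delta
        full_se_delta[keep_c] = se_delta
        for idx in np.flatnonzero(extreme_cols):
            raw = col_scores[idx]
            target = (extreme_adjustment if raw == 0
                      else n_persons * m - extreme_adjustment)
            target *= keep_r.sum() / n_persons
            full_delta[idx] = _solve_difficulty(target, beta, tau)
            _, w_ext = _expected_and_variance(beta, np.array([full_delta[idx]]), tau)
            full_se_delta[idx] = 1.0 / np.sqrt(max(w_ext.sum(), 1e-12))

        loglik = _loglik(xs, beta, delta, tau)
        return RatingScaleResults(
            model=self,
            person_measures=pd.Series(full_beta, index=self.person_keys, name="measure"),
            person_se=pd.Series(full_se_beta, index=self.person_keys, name="se"),
            item_difficulties=pd.Series(full_delta, index=self.item_names, name="difficulty"),
            item_se=pd.Series(full_se_delta, index=self.item_names, name="se"),
            thresholds=tau,
            threshold_se=se_tau,
            loglik=loglik,
            n_iter=iteration,
            converged=True,
            extreme_persons=pd.Series(extreme_rows, index=self.person_keys),
            extreme_items=pd.Series(extreme_cols, index=self.item_names),
        )


def _solve_measure(target_score: float, delta: np.ndarray, tau: np.ndarray,
                   tol: float = 1e-8, max_iter: int = 200) -> float:
    """beta with expected total score over the given items equal to target."""
    beta = 0.0
    for _ in range(max_iter):
        e, w = _expected_and_variance(np.array([beta]), delta, tau)
        step = np.clip((target_score - e.sum()) / max(w.sum(), 1e-10), -2.0, 2.0)
        beta += step
        if abs(step) < tol:
            break
    return float(beta)


def _solve_difficulty(target_score: float, beta: np.ndarray, tau: np.ndarray,
                      tol: float = 1e-8, max_iter: int = 200) -> float:
    delta = 0.0
    for _ in range(max_iter):
        e, w = _expected_and_variance(beta, np.array([delta]), tau)
        step = np.clip((e.sum() - target_score) / max(w.sum(), 1e-10), -2.0, 2.0)
        delta += step
        if abs(step) < tol:
            break
    return float(delta)


@dataclass
class RatingScaleResults:
    """Estimates and diagnostics from :meth:`RatingScaleModel.fit`."""

    model: RatingScaleModel
    person_measures: pd.Series
    person_se: pd.Series
    item_difficulties: pd.Series
    item_se: pd.Series
    thresholds: np.ndarray
    threshold_se: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    extreme_persons: pd.Series
    extreme_items: pd.Series
    _fit_stats: Optional[FitStats] = field(default=None, repr=False)

    # -- diagnostics --------------------------------------------------------

    def fit_statistics(self) -> FitStats:
        """Infit/outfit mean squares plus the residual matrices behind them.

        outfit_i = mean_n z_ni^2      (unweighted, outlier sensitive)
        infit_i  = sum_n (x-E)^2 / sum_n W   (information weighted)

        and symmetrically for persons.  Cells in extreme rows/columns are
        excluded; cells with zero model variance are dropped with a
        warning.
        """
        if self._fit_stats is not None:
            return self._fit_stats
        keep_r = ~self.extreme_persons.to_numpy()
        keep_c = ~self.extreme_items.to_numpy()
        x = self.model.x[np.ix_(keep_r, keep_c)].astype(float)
        beta = self.person_measures.to_numpy()[keep_r]
        delta = self.item_difficulties.to_numpy()[keep_c]
        e, w = _expected_and_variance(beta, delta, self.thresholds)
        ok = w > 1e-12
        if not ok.all():
            warnings.warn("cells with zero model variance excluded from fit statistics")
        resid = x - e
        z = np.where(ok, resid / np.sqrt(np.where(ok, w, 1.0)), np.nan)
        z2 = np.where(ok, z**2, np.nan)
        sq = np.where(ok, resid**2, 0.0)
        wm = np.where(ok, w, 0.0)

        item_idx = self.item_difficulties.index[keep_c]
        person_idx = self.person_measures.index[keep_r]
        item_outfit = pd.Series(np.nanmean(z2, axis=0), index=item_idx)
        item_infit = pd.Series(sq.sum(axis=0) / np.maximum(wm.sum(axis=0), 1e-12),
                               index=item_idx)
        person_outfit = pd.Series(np.nanmean(z2, axis=1), index=person_idx)
        person_infit = pd.Series(sq.sum(axis=1) / np.maximum(wm.sum(axis=1), 1e-12),
                                 index=person_idx)
        self._fit_stats = FitStats(
            expected=pd.DataFrame(e, index=person_idx, columns=item_idx),
            variance=pd.DataFrame(w, index=person_idx, columns=item_idx),
            z=pd.DataFrame(z, index=person_idx, columns=item_idx),
            item_infit=item_infit,
            item_outfit=item_outfit,
            person_infit=person_infit,
            person_outfit=person_outfit,
        )
        return self._fit_stats

    def residual_pca(self) -> ResidualPCAResult:
        """PCA of the correlation matrix of standardized residuals.

        Eigenvalues are in item units (they sum to the number of retained
        items); a first eigenvalue below 2 is read as residuals compatible
        with a unidimensional scale.
        """
        return residual_pca(self.fit_statistics())

    def separation_reliability(self):
        """(person_reliability, item_reliability)."""
        return separation_reliability(self)

    def wright_map(self) -> pd.DataFrame:
        """Person measures and item difficulties on the common logit scale."""
        return wright_map(self)

    def summary(self) -> str:
        fs = self.fit_statistics()
        pca = self.residual_pca()
        person_rel, item_rel = self.separation_reliability()
        lines = [
            "Rating Scale Model (JMLE)",
            "=" * 60,
            f"persons: {len(self.person_measures)} "
            f"({int(self.extreme_persons.sum())} extreme)   "
            f"items: {len(self.item_difficulties)} "
            f"({int(self.extreme_items.sum())} extreme)   "
            f"categories: 0..{self.model.max_score}",
            f"log-likelihood: {self.loglik:.2f}   iterations: {self.n_iter}",
            f"person reliability: {person_rel:.2f}   item reliability: {item_rel:.2f}",
            f"first residual eigenvalue: {pca.first_eigenvalue:.2f} "
            f"({'unidimensional' if pca.unidimensional else 'multidimensional'})",
            "",
            f"{'item':<28}{'difficulty':>11}{'se':>8}{'infit':>8}{'outfit':>8}",
            "-" * 63,
        ]
        order = self.item_difficulties.sort_values().index
        for name in order:
            infit = fs.item_infit.get(name, np.nan)
            outfit = fs.item_outfit.get(name, np.nan)
            flag = " *" if (infit > MISFIT_CUTOFF or outfit > MISFIT_CUTOFF) else ""
            lines.append(
                f"{str(name):<28}{self.item_difficulties[name]:>11.3f}"
                f"{self.item_se[name]:>8.3f}{infit:>8.2f}{outfit:>8.2f}{flag}"
            )
        lines.append("-" * 63)
        taus = ", ".join(f"{t:+.3f}" for t in self.thresholds)
        lines.append(f"thresholds (sum 0): {taus}")
        lines.append("* infit or outfit mean square > 1.5")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# module-level operations


def fit_rsm(data, tol: float = 1e-4, max_iter: int = 200) -> RatingScaleResults:
    """Fit the Rating Scale Model to an N x I response matrix."""
    return RatingScaleModel(data).fit(tol=tol, max_iter=max_iter)


def person_item_fit(fit: RatingScaleResults, data=None) -> FitStats:
    """Infit/outfit mean squares and standardized residuals for a fit."""
    return fit.fit_statistics()


def residual_pca(fitstats: FitStats) -> ResidualPCAResult:
    """Eigen-decomposition of the residual correlation matrix (item units)."""
    z = fitstats.z.to_numpy()
    names = list(fitstats.z.columns)
    keep = []
    for j, name in enumerate(names):
        col = z[:, j]
        col = col[~np.isnan(col)]
        if col.size < 2 or np.std(col) < 1e-12:
            warnings.warn(f"constant residual column {name!r} excluded from PCA")
        else:
            keep.append(j)
    if len(keep) < 2:
        raise RaschError("fewer than 2 non-constant residual columns")
    zk = z[:, keep]
    frame = pd.DataFrame(zk, columns=[names[j] for j in keep])
    corr = frame.corr().to_numpy()
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    first = eigvecs[:, order[0]]
    # orient and scale as correlation loadings on the first component
    if first[np.argmax(np.abs(first))] < 0:
        first = -first
    loadings = pd.Series(first * np.sqrt(max(eigvals[0], 0.0)),
                         index=[names[j] for j in keep])
    return ResidualPCAResult(
        eigenvalues=eigvals,
        loadings=loadings,
        retained_items=[names[j] for j in keep],
    )


def _reliability(measures: np.ndarray, ses: np.ndarray) -> float:
    if measures.size < 2:
        raise RaschError("need at least 2 non-extreme measures for reliability")
    var = float(np.var(measures, ddof=1))
    if var <= 0:
        warnings.warn("zero variance of measures; reliability set to 0")
        return 0.0
    rel = (var - float(np.mean(ses**2))) / var
    return float(np.clip(rel, 0.0, 1.0))


def separation_reliability(fit: RatingScaleResults):
    """Separation reliability for persons and items.

    reliability = (observed variance of measures - mean squared SE)
                  / observed variance, clipped to [0, 1].
    """
    keep_p = ~fit.extreme_persons.to_numpy()
    keep_i = ~fit.extreme_items.to_numpy()
    person = _reliability(fit.person_measures.to_numpy()[keep_p],
                          fit.person_se.to_numpy()[keep_p])
    item = _reliability(fit.item_difficulties.to_numpy()[keep_i],
                        fit.item_se.to_numpy()[keep_i])
    return person, item


def wright_map(fit: RatingScaleResults) -> pd.DataFrame:
    """Long table of measures and difficulties on the common logit scale.

    Items come first, sorted ascending by difficulty; persons follow in
    data order.  Suitable for a person-item map plot.
    """
    items = pd.DataFrame({
        "kind": "item",
        "name": fit.item_difficulties.sort_values().index,
        "measure": fit.item_difficulties.sort_values().to_numpy(),
        "se": fit.item_se.reindex(fit.item_difficulties.sort_values().index).to_numpy(),
        "extreme": fit.extreme_items.reindex(
            fit.item_difficulties.sort_values().index).to_numpy(),
    })
    persons = pd.DataFrame({
        "kind": "person",
        "name": [str(k) for k in fit.person_measures.index],
        "measure": fit.person_measures.to_numpy(),
        "se": fit.person_se.to_numpy(),
        "extreme": fit.extreme_persons.to_numpy(),
    })
    return pd.concat([items, persons], ignore_index=True)


def label_flow(responses: pd.DataFrame) -> pd.Series:
    """Binary full-flow labels from FSS responses.

    1 iff the transformation-of-time item is rated "agree" or
    "strongly agree" (>= 3 on the 0..4 coding), else 0.
    """
    if FLOW_ITEM not in responses.columns:
        raise RaschError(f"responses lack the {FLOW_ITEM!r} item")
    col = responses[FLOW_ITEM]
    if col.isna().any():
        missing = list(responses.index[col.isna()])
        raise RaschError(f"missing {FLOW_ITEM} rating for rows {missing}")
    return (col >= AGREE_THRESHOLD).astype(int).rename("flow")
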