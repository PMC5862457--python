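"""Andrich Rating Scale Model: probabilities and JMLE calibration.

The RSM assigns person *n* on item *i* the category probabilities

    P(X = k) = exp(k(theta_n - beta_i) - ct_k) / sum_m exp(m(theta_n - beta_i) - ct_m)

with ``ct_k = tau_1 + ... + tau_k`` the cumulative category thresholds
(``ct_0 = 0``), shared across items.  ``theta`` and ``beta`` live on a common
logit scale identified by ``mean(beta) = 0`` and ``sum(tau) = 0``.

Calibration is joint maximum likelihood (JMLE): alternating damped Newton
updates of persons, items and thresholds on the non-extreme core of the
data, with a monotone line-search safeguard on the joint log-likelihood.
Extreme (all-minimum / all-maximum) persons and items receive a
fractional-score adjustment and are flagged.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.special import softmax
from sklearn.base import BaseEstimator, TransformerMixin

from .data import ResponseMatrix
from .errors import DegenerateDataError

__all__ = [
    "category_probabilities",
    "expected_score",
    "score_variance",
    "log_likelihood",
    "RatingScaleModel",
    "fit_rsm",
]


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite model parameters")


def _cumulative_thresholds(tau: np.ndarray) -> np.ndarray:
    """ct_k for k = 0..K, with ct_0 = 0."""
    return np.concatenate([[0.0], np.cumsum(tau)])


def category_probabilities(theta, beta, tau) -> np.ndarray:
    """RSM category probabilities, overflow-safe, summing to 1.

    ``theta`` and ``beta`` may be scalars or broadcastable arrays; the
    category axis is appended last.  ``tau`` is the length-K threshold
    vector (tau_0 = 0 is implicit).
    """
    theta = np.asarray(theta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    tau = np.asarray(tau, dtype=float)
    _check_finite(theta, beta, tau)
    ct = _cumulative_thresholds(tau)
    k = np.arange(ct.size)
    logits = np.asarray(theta - beta)[..., None] * k - ct
    return softmax(logits, axis=-1)


def expected_score(theta, beta, tau) -> np.ndarray:
    """Model-expected score E[X] in [0, K]; strictly increasing in theta."""
    p = category_probabilities(theta, beta, tau)
    k = np.arange(p.shape[-1])
    return p @ k


def score_variance(theta, beta, tau) -> np.ndarray:
    """Model score variance W = E[X^2] - E[X]^2 (the item information kernel)."""
    p = category_probabilities(theta, beta, tau)
    k = np.arange(p.shape[-1])
    e = p @ k
    return np.maximum(p @ k**2 - e**2, 0.0)


def log_likelihood(rm: ResponseMatrix, theta, beta, tau) -> float:
    """Joint log-likelihood of the observed responses at the given parameters."""
    theta = np.asarray(theta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    x = rm.responses
    obs = ~np.isnan(x)
    p = category_probabilities(theta[:, None], beta[None, :], tau)
    xi = np.where(obs, x, 0).astype(int)
    logp = np.log(np.take_along_axis(p, xi[..., None], axis=-1)[..., 0])
    return float(logp[obs].sum())


def _solve_theta(
    target: float, betas: np.ndarray, tau: np.ndarray, theta0: float = 0.0,
    tol: float = 1e-8, max_iter: int = 100,
) -> float:
    """Solve E(theta) = target over a fixed item set by safeguarded Newton.

    ``target`` may be fractional (extreme-score adjustment); it must lie
    strictly inside (0, K * n_items).
    """
    theta = theta0
    lo, hi = -50.0, 50.0
    for _ in range(max_iter):
        e = expected_score(theta, betas, tau).sum()
        w = score_variance(theta, betas, tau).sum()
        resid = target - e
        if abs(resid) < tol:
            break
        if resid > 0:
            lo = theta
        else:
            hi = theta
        step = resid / max(w, 1e-12)
        theta_new = theta + np.clip(step, -2.0, 2.0)
        if not lo < theta_new < hi:
            theta_new = 0.5 * (lo + hi)
        theta = theta_new
    return float(theta)


class RatingScaleModel(TransformerMixin, BaseEstimator):
    """Joint maximum likelihood calibration of the Rating Scale Model.

    Parameters
    ----------
    n_categories : int, default=5
        Number of response categories (K + 1).  Ignored when fitting a
        :class:`~rsmkit.data.ResponseMatrix`, which carries its own.
    tol : float, default=1e-3
        Convergence tolerance: maximum absolute parameter change, in logits.
    max_iter : int, default=100
        Maximum JMLE cycles.
    extreme_adjust : float, default=0.3
        Score-point adjustment pulling extreme raw scores toward the
        interior before estimating their measure.
    bias_correction : bool, default=False
        Apply the (L-1)/L shrinkage of item difficulties that compensates
        the well-known JMLE bias, then re-estimate person measures.
    step_limit : float, default=1.0
        Per-cycle cap on any single Newton step, in logits.

    Attributes
    ----------
    theta_, se_theta_ : ndarray of shape (n_persons_,)
        Person measures and standard errors in logits.
    beta_, se_beta_ : ndarray of shape (n_items_,)
        Item difficulties (mean 0 over non-extreme items) and standard errors.
    tau_ : ndarray of shape (K,)
        Shared category thresholds, summing to 0.
    extreme_persons_, extreme_items_ : boolean ndarray
        Flags for units estimated from adjusted extreme scores.
    dropped_persons_, dropped_items_ : list of str
        Units removed before estimation (all missing, or items constant at
        an interior category).
    converged_ : bool
    n_iter_ : int
    max_last_change_ : float
    log_likelihood_ : float
        Joint log-likelihood of the non-extreme core at the solution.
    loglik_path_ : ndarray
        Core log-likelihood after each accepted cycle (non-decreasing).
    """

    def __init__(
        self,
        n_categories: int = 5,
        tol: float = 1e-3,
        max_iter: int = 100,
        extreme_adjust: float = 0.3,
        bias_correction: bool = False,
        step_limit: float = 1.0,
    ):
        self.n_categories = n_categories
        self.tol = tol
        self.max_iter = max_iter
        self.extreme_adjust = extreme_adjust
        self.bias_correction = bias_correction
        self.step_limit = step_limit

    # -- helpers -------------------------------------------------------

    def _coerce(self, X) -> ResponseMatrix:
        if isinstance(X, ResponseMatrix):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("X must be 2-D (persons x items)")
        return ResponseMatrix(
            person_ids=tuple(f"p{i}" for i in range(arr.shape[0])),
            item_ids=tuple(f"i{j}" for j in range(arr.shape[1])),
            responses=arr,
            n_categories=self.n_categories,
        )

    # -- estimation ----------------------------------------------------

    def fit(self, X, y=None) -> "RatingScaleModel":
        """Calibrate person measures, item difficulties and thresholds."""
        rm = self._coerce(X)
        K = rm.max_score
        x = rm.responses.copy()

        # prune units that carry no information
        person_ids = list(rm.person_ids)
        item_ids = list(rm.item_ids)
        self.dropped_persons_: list[str] = []
        self.dropped_items_: list[str] = []

        all_missing_rows = np.isnan(x).all(axis=1)
        if all_missing_rows.any():
            self.dropped_persons_ = [p for p, d in zip(person_ids, all_missing_rows) if d]
            warnings.warn(f"dropping all-missing persons: {self.dropped_persons_}")
            person_ids = [p for p, d in zip(person_ids, all_missing_rows) if not d]
            x = x[~all_missing_rows]

        drop_cols = []
        for j in range(x.shape[1]):
            col = x[:, j][~np.isnan(x[:, j])]
            if col.size == 0:
                drop_cols.append(j)
            elif col.min() == col.max() and 0 < col[0] < K:
                # constant at an interior category: no difficulty information
                drop_cols.append(j)
        if drop_cols:
            self.dropped_items_ = [item_ids[j] for j in drop_cols]
            warnings.warn(
                f"dropping uninformative items (all-missing or single interior "
                f"category): {self.dropped_items_}"
            )
            keep = [j for j in range(x.shape[1]) if j not in drop_cols]
            item_ids = [item_ids[j] for j in keep]
            x = x[:, keep]

        obs = ~np.isnan(x)
        n_persons, n_items = x.shape
        if n_persons < 2 or n_items < 2:
            raise DegenerateDataError("need at least 2 persons and 2 items")

        counts = np.bincount(x[obs].astype(int), minlength=K + 1)
        if (counts == 0).any():
            warnings.warn(
                "some response categories are unobserved; they are retained as "
                "structural categories of the shared rating scale"
            )

        x0 = np.where(obs, x, 0.0)
        item_score = x0.sum(axis=0)
        item_max = K * obs.sum(axis=0)
        person_score = x0.sum(axis=1)
        person_max = K * obs.sum(axis=1)

        extreme_items = (item_score == 0) | (item_score == item_max)
        extreme_persons_raw = (person_score == 0) | (person_score == person_max)

        core_items = ~extreme_items
        if core_items.sum() < 2:
            raise DegenerateDataError("fewer than 2 non-extreme items")
        # extremeness of persons is judged on the core items they answered
        xc_all = x[:, core_items]
        obs_c = ~np.isnan(xc_all)
        p_score = np.where(obs_c, xc_all, 0.0).sum(axis=1)
        p_max = K * obs_c.sum(axis=1)
        extreme_persons = (p_score == 0) | (p_score == p_max) | (p_max == 0)
        core_persons = ~extreme_persons
        if core_persons.sum() < 2:
            raise DegenerateDataError("fewer than 2 non-extreme persons")

        xc = x[np.ix_(core_persons, core_items)]
        theta_c, beta_c, tau = self._jmle(xc, K)

        # assemble full parameter vectors, scoring extremes from adjusted targets
        adj = self.extreme_adjust
        theta = np.empty(n_persons)
        theta[core_persons] = theta_c
        beta = np.empty(n_items)
        beta[core_items] = beta_c

        for n in np.flatnonzero(extreme_persons):
            row = x[n, core_items]
            seen = ~np.isnan(row)
            if not seen.any():
                theta[n] = np.nan
                continue
            r = np.nansum(row)
            target = np.clip(r, adj, K * seen.sum() - adj)
            theta[n] = _solve_theta(target, beta_c[seen], tau)
        for j in np.flatnonzero(extreme_items):
            col = x[core_persons, j]
            seen = ~np.isnan(col)
            s = np.nansum(col)
            target = np.clip(s, adj, K * seen.sum() - adj)
            # item difficulty mirrors person measure: solve on the item margin
            beta[j] = _solve_beta(target, theta_c[seen], tau)

        if self.bias_correction and core_items.sum() > 1:
            L = core_items.sum()
            beta = beta * (L - 1) / L
            tau = tau * (L - 1) / L
            for n in np.flatnonzero(core_persons):
                row = x[n, core_items]
                seen = ~np.isnan(row)
                theta[n] = _solve_theta(
                    float(np.nansum(row)), beta[core_items][seen], tau, theta0=theta[n]
                )

        # standard errors from the model information at the solution
        p = category_probabilities(theta[:, None], beta[None, :], tau)
        kk = np.arange(K + 1)
        e = p @ kk
        w = np.maximum(p @ kk**2 - e**2, 1e-12)
        w_obs = np.where(obs, w, 0.0)
        with np.errstate(divide="ignore"):
            self.se_theta_ = 1.0 / np.sqrt(w_obs.sum(axis=1))
            self.se_beta_ = 1.0 / np.sqrt(w_obs.sum(axis=0))

        self.person_ids_ = tuple(person_ids)
        self.item_ids_ = tuple(item_ids)
        self.theta_ = theta
        self.beta_ = beta
        self.tau_ = tau
        self.extreme_persons_ = extreme_persons
        self.extreme_items_ = extreme_items
        self.n_persons_ = n_persons
        self.n_items_ = n_items
        self.n_categories_ = K + 1
        core_rm = ResponseMatrix(
            person_ids=tuple(np.asarray(person_ids, dtype=object)[core_persons]),
            item_ids=tuple(np.asarray(item_ids, dtype=object)[core_items]),
            responses=xc,
            n_categories=K + 1,
        )
        self.log_likelihood_ = log_likelihood(core_rm, theta_c, beta_c, tau)
        if not self.converged_:
            warnings.warn(
                f"JMLE did not converge in {self.n_iter_} cycles "
                f"(last max change {self.max_last_change_:.4g} logits)"
            )
        return self

    def _jmle(self, x: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Alternating damped Newton on the non-extreme core matrix."""
        obs = ~np.isnan(x)
        n, m = x.shape
        xi = np.where(obs, x, 0.0)
        kk = np.arange(K + 1)

        # PROX-style starting values from log-odds of normalized raw scores
        r = xi.sum(axis=1)
        rmax = K * obs.sum(axis=1)
        pr = np.clip(r / rmax, 0.02, 0.98)
        theta = np.log(pr / (1 - pr))
        s = xi.sum(axis=0)
        smax = K * obs.sum(axis=0)
        ps = np.clip(s / smax, 0.02, 0.98)
        beta = -np.log(ps / (1 - ps))
        beta -= beta.mean()
        counts = np.bincount(x[obs].astype(int), minlength=K + 1).astype(float) + 0.5
        tau = np.log(counts[:-1] / counts[1:])
        tau -= tau.mean()

        # observed threshold-passing indicators for the tau updates
        m_pass = np.stack([(xi >= j) & obs for j in range(1, K + 1)], axis=-1)

        def loglik(th, be, ta):
            ct = _cumulative_thresholds(ta)
            logits = (th[:, None] - be[None, :])[..., None] * kk - ct
            lse = np.log(np.exp(logits - logits.max(-1, keepdims=True)).sum(-1))
            lse += logits.max(-1)
            num = np.take_along_axis(logits, xi.astype(int)[..., None], -1)[..., 0]
            return float(((num - lse) * obs).sum())

        ll = loglik(theta, beta, tau)
        self.loglik_path_ = [ll]
        converged = False
        stall = 0
        it = 0
        for it in range(1, self.max_iter + 1):
            p = category_probabilities(theta[:, None], beta[None, :], tau)
            e = p @ kk
            w = np.maximum(p @ kk**2 - e**2, 1e-12)
            e_o = np.where(obs, e, 0.0)
            w_o = np.where(obs, w, 0.0)

            d_theta = (xi - e_o).sum(axis=1) / w_o.sum(axis=1)
            d_beta = (e_o - xi).sum(axis=0) / w_o.sum(axis=0)
            # thresholds: diagonal Newton on the category-passing margin
            q = np.flip(np.cumsum(np.flip(p, axis=-1), axis=-1), axis=-1)[..., 1:]
            q_o = q * obs[..., None]
            grad_tau = (q_o - m_pass).sum(axis=(0, 1))
            # Newton for a maximum: step = -grad / hess with hess = -sum Q(1-Q)
            hess_tau = np.maximum((q_o * (1 - q)).sum(axis=(0, 1)), 1e-12)
            d_tau = grad_tau / hess_tau

            lim = self.step_limit
            d_theta = np.clip(d_theta, -lim, lim)
            d_beta = np.clip(d_beta, -lim, lim)
            d_tau = np.clip(d_tau, -lim, lim)

            # damped acceptance: joint likelihood must not decrease
            lam = 1.0
            for _ in range(30):
                th_new = theta + lam * d_theta
                be_new = beta + lam * d_beta
                ta_new = tau + lam * d_tau
                # gauge fixing: sum(tau)=0 then mean(beta)=0, probability-preserving
                c_tau = ta_new.mean()
                ta_new = ta_new - c_tau
                be_new = be_new + c_tau
                c_beta = be_new.mean()
                be_new = be_new - c_beta
                th_new = th_new - c_beta
                ll_new = loglik(th_new, be_new, ta_new)
                if ll_new >= ll - 1e-9:
                    break
                lam *= 0.5
            change = max(
                np.max(np.abs(th_new - theta)),
                np.max(np.abs(be_new - beta)),
                np.max(np.abs(ta_new - tau)),
            )
            # the block-diagonal updates can settle into a tiny limit cycle
            # below the likelihood's resolution; a stalled likelihood with a
            # sub-0.001-logit oscillation is a converged solution
            stall = stall + 1 if abs(ll_new - ll) < 1e-10 * max(1.0, abs(ll)) else 0
            theta, beta, tau, ll = th_new, be_new, ta_new, ll_new
            self.loglik_path_.append(ll)
            if change < self.tol or (stall >= 3 and change < 1e-3):
                converged = True
                break

        self.converged_ = converged
        self.n_iter_ = it
        self.max_last_change_ = float(change)
        self.loglik_path_ = np.asarray(self.loglik_path_)
        return theta, beta, tau

    # -- anchored scoring ----------------------------------------------

    def score_persons(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Estimate person measures for new responses at the fitted item anchors.

        Returns ``(theta, se)``; extreme raw scores use the configured
        fractional adjustment.
        """
        rm = self._coerce(X)
        if isinstance(X, ResponseMatrix):
            shared = [i for i in self.item_ids_ if i in rm.item_ids]
            if not shared:
                raise ValueError("no fitted items present in X")
            cols = [rm.item_ids.index(i) for i in shared]
            fitted_pos = {i: j for j, i in enumerate(self.item_ids_)}
            betas = self.beta_[[fitted_pos[i] for i in shared]]
            x = rm.responses[:, cols]
        else:
            if rm.n_items != self.n_items_:
                raise ValueError("column count does not match the fitted items")
            betas, x = self.beta_, rm.responses
        K = self.n_categories_ - 1
        adj = self.extreme_adjust
        theta = np.full(x.shape[0], np.nan)
        se = np.full(x.shape[0], np.nan)
        for nrow in range(x.shape[0]):
            seen = ~np.isnan(x[nrow])
            if not seen.any():
                continue
            target = np.clip(np.nansum(x[nrow]), adj, K * seen.sum() - adj)
            theta[nrow] = _solve_theta(float(target), betas[seen], self.tau_)
            info = score_variance(theta[nrow], betas[seen], self.tau_).sum()
            se[nrow] = 1.0 / np.sqrt(info)
        return theta, se

    def transform(self, X) -> np.ndarray:
        """Anchored person measures as a column vector (sklearn transform)."""
        theta, _ = self.score_persons(X)
        return theta[:, None]

    def expected_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Fitted E and W matrices over all retained persons x items."""
        p = category_probabilities(self.theta_[:, None], self.beta_[None, :], self.tau_)
        kk = np.arange(self.n_categories_)
        e = p @ kk
        w = np.maximum(p @ kk**2 - e**2, 1e-12)
        return e, w


def _solve_beta(
    target: float, thetas: np.ndarray, tau: np.ndarray, tol: float = 1e-8
) -> float:
    """Solve sum_n E(theta_n; beta) = target for beta (decreasing in beta)."""
    lo, hi = -50.0, 50.0
    beta = 0.0
    for _ in range(200):
        e = expected_score(thetas, beta, tau).sum()
        w = score_variance(thetas, beta, tau).sum()
        resid = e - target
        if abs(resid) < tol:
            break
        if resid > 0:
            lo = beta
        else:
            hi = beta
        beta_new = beta + np.clip(resid / max(w, 1e-12), -2.0, 2.0)
        if not lo < beta_new < hi:
            beta_new = 0.5 * (lo + hi)
        beta = beta_new
    return float(beta)


def fit_rsm(rm: ResponseMatrix, **config) -> RatingScaleModel:
    """Fit the Rating Scale Model to a response matrix; returns the fitted estimator."""
    model = RatingScaleModel(n_categories=rm.n_categories, **config)
    return model.fit(rm)
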