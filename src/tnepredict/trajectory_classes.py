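"""Latent class mixed models for BCVA trajectories.

Fits a finite mixture of linear mixed models to longitudinal best-corrected
visual acuity series by EM.  Each latent class g has a quadratic
fixed-effect trajectory in time (months),

    y_ij = b0_g + b1_g t_ij + b2_g t_ij^2 + u_i + e_ij,

with a shared random intercept u_i ~ N(0, tau^2) and residual
e_ij ~ N(0, sigma^2); no covariates enter the mean model.  The random
intercept is integrated out in closed form (the per-eye marginal covariance
sigma^2 I + tau^2 J is inverted via Sherman-Morrison), so the E-step works
with exact Gaussian marginal likelihoods.  The M-step updates the class
proportions exactly, the class coefficients by posterior-weighted
generalized least squares, and the variance components by one EM sweep over
the random effects — an ECM scheme whose observed-data log-likelihood is
non-decreasing at every iteration.

Classes are reported sorted by intercept (b0) descending so that repeated
fits are comparable despite label switching.  Latent classes are merged
into responders / non-responders by thresholding the model-implied
12-month BCVA gain, b1*12 + b2*144.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .errors import ContractError, ConvergenceError

_LOG_2PI = float(np.log(2.0 * np.pi))
SIGMA2_FLOOR = 1e-8


@dataclass
class LcmmSpec:
    """Model and optimisation settings for the latent class mixed model."""

    k_classes: int = 6
    max_iter: int = 500
    tol: float = 1e-6  # relative log-likelihood change
    n_starts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_classes < 1:
            raise ContractError("k_classes must be >= 1")
        if self.tol <= 0:
            raise ContractError("tol must be positive")


@dataclass
class LcmmFit:
    """Fitted mixture: proportions, per-class quadratics, variance components."""

    class_proportions: np.ndarray  # (K,)
    class_coeffs: np.ndarray  # (K, 3): intercept, slope, quadratic (letters/months)
    var_random: float  # tau^2, random-intercept variance
    var_noise: float  # sigma^2, residual variance
    posterior: np.ndarray  # (n, K), rows sum to 1
    log_likelihood: float
    converged: bool
    n_iter: int
    eye_ids: Tuple[str, ...] = ()
    log_likelihood_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def k_classes(self) -> int:
        return len(self.class_proportions)

    @property
    def classes(self) -> np.ndarray:
        """1-based class labels."""
        return np.arange(1, self.k_classes + 1)

    def implied_gain_12m(self) -> np.ndarray:
        """Model-implied BCVA change from baseline to month 12 per class."""
        return self.class_coeffs[:, 1] * 12.0 + self.class_coeffs[:, 2] * 144.0

    def bic(self) -> float:
        n = self.posterior.shape[0]
        k_par = (self.k_classes - 1) + 3 * self.k_classes + 2
        return -2.0 * self.log_likelihood + k_par * np.log(n)

    def to_json(self, path) -> None:
        payload = {
            "class_proportions": self.class_proportions.tolist(),
            "class_coeffs": self.class_coeffs.tolist(),
            "var_random": self.var_random,
            "var_noise": self.var_noise,
            "log_likelihood": self.log_likelihood,
            "bic": self.bic(),
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class ResponderRule:
    """Merge rule: a class responds if its implied 12-month gain >= threshold."""

    threshold: float = 5.0  # letters

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ContractError("threshold must be finite")


def _prepare_series(
    series: pd.DataFrame,
) -> Tuple[List[str], List[np.ndarray], List[np.ndarray]]:
    required = {"eye_id", "t_months", "bcva"}
    if not required.issubset(series.columns):
        raise ContractError(f"series frame needs columns {sorted(required)}")
    ids, Xs, ys = [], [], []
    for eye_id, grp in series.groupby("eye_id", sort=True):
        t = grp["t_months"].to_numpy(dtype=float)
        y = grp["bcva"].to_numpy(dtype=float)
        if len(t) < 3:
            raise ContractError(f"eye {eye_id} has fewer than 3 observations")
        ids.append(str(eye_id))
        Xs.append(np.column_stack([np.ones_like(t), t, t**2]))
        ys.append(y)
    return ids, Xs, ys


def _component_loglik(Xs, ys, beta, tau2, sig2) -> np.ndarray:
    """(n, K) log N(y_i; X_i beta_g, sig2 I + tau2 J) via Sherman-Morrison."""
    n, K = len(ys), beta.shape[0]
    out = np.empty((n, K))
    for i, (X, y) in enumerate(zip(Xs, ys)):
        m = len(y)
        a = sig2 + m * tau2
        r = y[:, None] - X @ beta.T  # (m, K)
        ssq = np.sum(r * r, axis=0)
        s = np.sum(r, axis=0)
        quad = ssq / sig2 - (tau2 / (sig2 * a)) * s * s
        logdet = (m - 1) * np.log(sig2) + np.log(a)
        out[i] = -0.5 * (m * _LOG_2PI + logdet + quad)
    return out


def _em(
    Xs, ys, pi0, beta0, tau2, sig2, max_iter, tol
) -> Tuple[np.ndarray, np.ndarray, float, float, np.ndarray, float, bool, int, np.ndarray]:
    n = len(ys)
    K = len(pi0)
    N_obs = sum(len(y) for y in ys)
    pi, beta = pi0.copy(), beta0.copy()
    XtX = [X.T @ X for X in Xs]
    Xty = [X.T @ y for X, y in zip(Xs, ys)]
    Xt1 = [X.T.sum(axis=1) for X in Xs]
    trace = []
    ll_prev = -np.inf
    converged = False
    it = 0
    W = np.full((n, K), 1.0 / K)
    for it in range(1, max_iter + 1):
        # E-step: class posteriors from the marginal likelihoods
        comp = _component_loglik(Xs, ys, beta, tau2, sig2)
        logw = comp + np.log(np.maximum(pi, 1e-300))[None, :]
        norm = logsumexp(logw, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        W = np.exp(logw - norm[:, None])
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-12):
            converged = True
            break
        ll_prev = ll
        # M-step
        pi = W.mean(axis=0)
        # class coefficients: posterior-weighted GLS with V fixed
        m_i = np.array([len(y) for y in ys], dtype=float)
        a_i = sig2 + m_i * tau2
        for g in range(K):
            A = np.zeros((3, 3))
            b = np.zeros(3)
            for i in range(n):
                w = W[i, g]
                c = tau2 / a_i[i]
                s_y = ys[i].sum()
                # GLS normal equations for V^-1 = (I - c J)/sig2; the common
                # 1/sig2 factor cancels between A and b
                A += w * (XtX[i] - c * np.outer(Xt1[i], Xt1[i]))
                b += w * (Xty[i] - c * s_y * Xt1[i])
            beta[g] = np.linalg.solve(A, b)
        # variance components: one EM sweep over the random intercepts
        tau2_num = 0.0
        sig2_num = 0.0
        v_i = tau2 * sig2 / a_i  # posterior variance of u_i
        for i in range(n):
            X, y = Xs[i], ys[i]
            m = len(y)
            r = y[:, None] - X @ beta.T  # (m, K)
            s = r.sum(axis=0)
            b_hat = tau2 * s / a_i[i]  # (K,)
            tau2_num += float(W[i] @ (b_hat**2)) + v_i[i]
            rc = r - b_hat[None, :]
            sig2_num += float(W[i] @ np.sum(rc * rc, axis=0)) + m * v_i[i]
        tau2 = max(tau2_num / n, 0.0)
        sig2 = max(sig2_num / N_obs, SIGMA2_FLOOR)
    if not converged:
        # evaluate the likelihood at the final parameters so the reported
        # value matches the returned fit
        comp = _component_loglik(Xs, ys, beta, tau2, sig2)
        norm = logsumexp(comp + np.log(np.maximum(pi, 1e-300))[None, :], axis=1)
        trace.append(float(norm.sum()))
        W = np.exp(comp + np.log(np.maximum(pi, 1e-300))[None, :] - norm[:, None])
    return pi, beta, tau2, sig2, W, trace[-1], converged, it, np.asarray(trace)


def _initialise(Xs, ys, K, seed):
    """k-means on per-eye OLS quadratic coefficients."""
    coefs = []
    for X, y in zip(Xs, ys):
        c, *_ = np.linalg.lstsq(X, y, rcond=None)
        coefs.append(c)
    coefs = np.asarray(coefs)
    if K == 1:
        labels = np.zeros(len(ys), dtype=int)
    else:
        km = KMeans(n_clusters=K, n_init=1, random_state=seed % (2**31))
        labels = km.fit_predict(coefs)
    beta0 = np.zeros((K, 3))
    resid_all = []
    for g in range(K):
        idx = np.flatnonzero(labels == g)
        if len(idx) == 0:
            beta0[g] = coefs.mean(axis=0)
            continue
        Xg = np.vstack([Xs[i] for i in idx])
        yg = np.concatenate([ys[i] for i in idx])
        beta0[g], *_ = np.linalg.lstsq(Xg, yg, rcond=None)
        resid_all.append(yg - Xg @ beta0[g])
    pi0 = np.maximum(np.bincount(labels, minlength=K) / len(ys), 1.0 / (4 * K))
    pi0 = pi0 / pi0.sum()
    resid = np.concatenate(resid_all) if resid_all else np.array([1.0])
    var = max(float(np.var(resid)), 1e-3)
    return pi0, beta0, 0.5 * var, 0.5 * var


def _canonical_order(pi, beta, W):
    order = np.argsort(-beta[:, 0], kind="stable")
    return pi[order], beta[order], W[:, order]


def fit_lcmm(series: pd.DataFrame, spec: LcmmSpec) -> LcmmFit:
    """Fit the latent class mixed model to per-eye BCVA series.

    ``series`` has one row per observation with columns ``eye_id``,
    ``t_months`` and ``bcva``.  The best of ``spec.n_starts`` k-means-seeded
    EM runs (by final log-likelihood) is returned, with classes in canonical
    order.  Runs that empty a class (proportion below 1/(10 n)) are
    discarded and retried with fresh seeds; if every start fails a
    :class:`ConvergenceError` is raised.
    """
    ids, Xs, ys = _prepare_series(series)
    n = len(ids)
    K = spec.k_classes
    if n < 5 * K:
        raise ContractError(f"need at least {5 * K} eyes for {K} classes, got {n}")
    best = None
    for s in range(spec.n_starts):
        pi0, beta0, tau0, sig0 = _initialise(Xs, ys, K, spec.seed + s)
        pi, beta, tau2, sig2, W, ll, conv, it, trace = _em(
            Xs, ys, pi0, beta0, tau0, sig0, spec.max_iter, spec.tol
        )
        if np.min(pi) < 1.0 / (10.0 * n):
            continue  # empty class: restart with the next seed
        if best is None or ll > best[5] + 1e-12:
            best = (pi, beta, tau2, sig2, W, ll, conv, it, trace)
    if best is None:
        raise ConvergenceError(
            f"all {spec.n_starts} starts produced an empty class (K={K}, n={n})"
        )
    pi, beta, tau2, sig2, W, ll, conv, it, trace = best
    if not conv:
        warnings.warn("LCMM EM did not converge within max_iter", RuntimeWarning)
    pi, beta, W = _canonical_order(pi, beta, W)
    return LcmmFit(
        class_proportions=pi,
        class_coeffs=beta,
        var_random=float(tau2),
        var_noise=float(sig2),
        posterior=W,
        log_likelihood=float(ll),
        converged=bool(conv),
        n_iter=int(it),
        eye_ids=tuple(ids),
        log_likelihood_trace=trace,
    )


def posterior_assign(fit: LcmmFit) -> np.ndarray:
    """Modal class per eye (1-based); ties break toward the lower index."""
    return np.argmax(fit.posterior, axis=1) + 1


def merge_to_responder(fit: LcmmFit, rule: Optional[ResponderRule] = None) -> Dict[int, bool]:
    """Class -> responder flag by the implied 12-month gain threshold."""
    rule = rule or ResponderRule()
    gains = fit.implied_gain_12m()
    return {int(g + 1): bool(gains[g] >= rule.threshold) for g in range(fit.k_classes)}


def responder_labels(
    fit: LcmmFit, rule: Optional[ResponderRule] = None
) -> pd.Series:
    """Per-eye responder flag via modal class assignment."""
    merge = merge_to_responder(fit, rule)
    classes = posterior_assign(fit)
    return pd.Series(
        [merge[int(c)] for c in classes], index=pd.Index(fit.eye_ids, name="eye_id"),
        name="responder",
    )


def crosstab_by_baseline(
    responder: Sequence[bool], baseline_bcva: Sequence[float], cut: float = 50.0
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """2x2 counts and percentages: baseline High (>=cut) / Low x responder.

    Percentages are of the grand total, rounded to one decimal.
    """
    responder = np.asarray(responder, dtype=bool)
    baseline = np.asarray(baseline_bcva, dtype=float)
    if responder.shape != baseline.shape:
        raise ContractError("responder and baseline_bcva must be aligned")
    high = baseline >= cut
    counts = pd.DataFrame(
        {
            "responder": [int(np.sum(high & responder)), int(np.sum(~high & responder))],
            "non_responder": [int(np.sum(high & ~responder)), int(np.sum(~high & ~responder))],
        },
        index=pd.Index(["high", "low"], name="baseline_bcva"),
    )
    total = counts.to_numpy().sum()
    pct = (counts / total * 100.0).round(1)
    return counts, pct
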