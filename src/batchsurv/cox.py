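"""Cox proportional-hazards fitting.

The model is ``lambda(t|Z) = lambda_0(t) * exp(Z beta)``. ``beta`` is
estimated by maximizing the partial likelihood with the Breslow
approximation for tied event times; the same convention is used for the
Breslow estimator of the cumulative baseline hazard, so that predicted
survival curves ``pi(t|Z) = exp(-Lambda_0(t) * exp(Z beta))`` are internally
consistent.

Penalized variants maximize ``logPL(beta) - lam * sum_j w_j |beta_j|`` on
internally standardized covariates (unit variance), so that a single ``lam``
is comparable across covariates; coefficients are reported back on the
original scale and exact zeros are preserved. ``w_j = 1`` gives the lasso;
``w_j = 1/|beta_ridge_j|`` the adaptive lasso; SCAD is solved by local
linear approximation (iterated weighted lasso with SCAD-derivative weights,
``a = 3.7``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, ValidationError

__all__ = ["CoxPH", "CoxPHResults", "BreslowBaseline"]


class BreslowBaseline:
    """Step estimate of the cumulative baseline hazard Lambda_0(t).

    ``Lambda_0(t) = sum_{event times t_j <= t} d_j / sum_{i at risk} exp(Z_i beta)``.
    Nondecreasing, 0 at t = 0. With ``beta = 0`` this is the Nelson-Aalen
    estimator.
    """

    def __init__(self, event_times: np.ndarray, cumhaz: np.ndarray):
        self.event_times = np.asarray(event_times, dtype=float)
        self.cumhaz = np.asarray(cumhaz, dtype=float)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        out = np.where(idx > 0, self.cumhaz[np.maximum(idx - 1, 0)], 0.0)
        return out if out.ndim else float(out)


def _as_matrix(Z) -> tuple[np.ndarray, list[str]]:
    if isinstance(Z, pd.DataFrame):
        return Z.to_numpy(dtype=float), list(Z.columns)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    return Z, [f"x{i}" for i in range(Z.shape[1])]


class CoxPH:
    """Cox proportional-hazards model for right-censored times.

    Parameters
    ----------
    time : array-like
        Nonnegative follow-up times (days).
    event : array-like
        1 = event observed, 0 = right censored.
    Z : DataFrame or 2-d array, optional
        Candidate covariate matrix (one column per covariate). ``None`` or
        zero columns gives the null model (linear predictor identically 0).
    """

    def __init__(self, time, event, Z=None, names=None):
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        if self.time.ndim != 1 or self.event.shape != self.time.shape:
            raise ValidationError("time and event must be 1-d and equal length")
        if (self.time < 0).any():
            raise ValidationError("negative follow-up time")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicator must be 0/1")
        if self.event.sum() < 1:
            raise ValidationError("at least one event is required")
        if Z is None:
            self.Z = np.empty((len(self.time), 0))
            self.names: list[str] = []
        else:
            self.Z, inferred = _as_matrix(Z)
            self.names = list(names) if names is not None else inferred
            if self.Z.shape[0] != len(self.time):
                raise ValidationError("covariate matrix row count mismatch")
            spans = np.ptp(self.Z, axis=0)
            if (spans == 0).any() and self.Z.shape[1] > 0:
                bad = [self.names[j] for j in np.flatnonzero(spans == 0)]
                raise ValidationError(f"constant covariate column(s): {bad}")
        self._prepare()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, covariates, time_col="time", event_col="event"):
        return cls(df[time_col], df[event_col], df[list(covariates)])

    # -- internals ------------------------------------------------------
    def _prepare(self) -> None:
        order = np.argsort(self.time, kind="stable")
        self._t = self.time[order]
        self._d = self.event[order]
        self._Zs = self.Z[order]
        # tie groups: first sorted index of each unique event time
        ev_mask = self._d == 1
        ev_times = self._t[ev_mask]
        self._uniq_times, first = np.unique(ev_times, return_index=True)
        # index into sorted arrays of the first patient with time >= t_j
        self._risk_start = np.searchsorted(self._t, self._uniq_times, side="left")
        # per-group event count and covariate sum
        self._d_j = np.array(
            [np.sum((self._t == t) & ev_mask) for t in self._uniq_times], dtype=float
        )
        self._s_j = np.stack(
            [self._Zs[(self._t == t) & ev_mask].sum(axis=0) for t in self._uniq_times]
        ) if self.Z.shape[1] else np.empty((len(self._uniq_times), 0))

    def _suffix_sums(self, beta: np.ndarray):
        eta = self._Zs @ beta if len(beta) else np.zeros(len(self._t))
        eta = eta - eta.max()  # overflow guard; cancels in ratios, tracked in logs
        with np.errstate(under="ignore"):
            r = np.exp(eta)
        s0 = np.cumsum(r[::-1])[::-1]
        if len(beta):
            rz = r[:, None] * self._Zs
            s1 = np.cumsum(rz[::-1], axis=0)[::-1]
            rzz = rz[:, :, None] * self._Zs[:, None, :]
            s2 = np.cumsum(rzz[::-1], axis=0)[::-1]
        else:
            s1 = s2 = None
        return eta, s0, s1, s2

    def loglik(self, beta) -> float:
        beta = np.asarray(beta, dtype=float)
        eta, s0, _, _ = self._suffix_sums(beta)
        idx = self._risk_start
        ll = 0.0
        if len(beta):
            ll += float(np.sum(self._s_j @ beta))
        # eta was shifted by max; s_j beta above is unshifted, correct via d_j * shift
        shift = (self._Zs @ beta).max() if len(beta) else 0.0
        ll -= float(np.sum(self._d_j * (np.log(s0[idx]) + shift)))
        return ll

    def score_info(self, beta) -> tuple[float, np.ndarray, np.ndarray]:
        """Partial log-likelihood, score vector, observed information matrix."""
        beta = np.asarray(beta, dtype=float)
        p = len(beta)
        eta, s0, s1, s2 = self._suffix_sums(beta)
        idx = self._risk_start
        shift = (self._Zs @ beta).max() if p else 0.0
        ll = float(np.sum(self._s_j @ beta)) - float(
            np.sum(self._d_j * (np.log(s0[idx]) + shift))
        ) if p else -float(np.sum(self._d_j * np.log(s0[idx])))
        if not p:
            return ll, np.zeros(0), np.zeros((0, 0))
        zbar = s1[idx] / s0[idx, None]
        grad = (self._s_j - self._d_j[:, None] * zbar).sum(axis=0)
        info = np.zeros((p, p))
        for j in range(len(self._uniq_times)):
            v = s2[idx[j]] / s0[idx[j]] - np.outer(zbar[j], zbar[j])
            info += self._d_j[j] * v
        return ll, grad, info

    # -- fitting --------------------------------------------------------
    def fit(self, tol: float = 1e-9, max_iter: int = 200) -> "CoxPHResults":
        """Newton-Raphson maximum partial-likelihood fit.

        Converges to score norm below ``tol`` (sup-norm); step-halving keeps
        the likelihood monotone. Raises :class:`ConvergenceError` on failure
        or when the likelihood is monotone in some direction (separation in
        the risk sets drives a coefficient to infinity).
        """
        p = self.Z.shape[1]
        beta = np.zeros(p)
        if p == 0:
            ll, _, _ = self.score_info(beta)
            return self._results(beta, ll, np.zeros((0, 0)))
        scale = self.Z.std(axis=0)
        ll, grad, info = self.score_info(beta)
        for _ in range(max_iter):
            if not (np.isfinite(ll) and np.isfinite(grad).all()):
                raise ConvergenceError("non-finite partial likelihood", {"beta": beta.tolist()})
            if np.max(np.abs(beta) * scale) > 15:
                raise ConvergenceError(
                    "monotone likelihood: a coefficient diverges (separation)",
                    {"beta": beta.tolist(), "loglik": ll},
                )
            if np.max(np.abs(grad)) < tol:
                break
            try:
                step = np.linalg.solve(info + 1e-12 * np.eye(p), grad)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise ConvergenceError("singular information matrix") from exc
            # step halving
            factor = 1.0
            for _half in range(40):
                cand = beta + factor * step
                ll_new = self.loglik(cand)
                if ll_new >= ll - 1e-12:
                    break
                factor /= 2.0
            else:  # pragma: no cover
                raise ConvergenceError("step halving failed", {"ll": ll})
            beta = cand
            ll, grad, info = self.score_info(beta)
        else:
            raise ConvergenceError(
                "Newton iterations did not converge",
                {"grad_norm": float(np.max(np.abs(grad))), "loglik": ll},
            )
        return self._results(beta, ll, info)

    def fit_regularized(
        self,
        penalty: str = "l1",
        lam: float = 1.0,
        a: float = 3.7,
        ridge_init: float = 0.01,
        tol: float = 1e-8,
        max_iter: int = 500,
    ) -> "CoxPHResults":
        """Penalized fit maximizing ``logPL - lam * sum w_j |beta_j|``.

        ``penalty``: ``l1`` (w = 1), ``adaptive_l1`` (w = 1/|beta~| from a
        ridge fit with penalty ``ridge_init`` on the standardized scale) or
        ``scad`` (local linear approximation, tuning constant ``a``).
        Covariates are standardized internally; reported coefficients are on
        the original scale with exact zeros preserved.
        """
        if penalty not in ("l1", "adaptive_l1", "scad"):
            raise ValidationError(f"unknown penalty {penalty!r}")
        if lam < 0:
            raise ValidationError("lam must be nonnegative")
        p = self.Z.shape[1]
        if p == 0:
            return self.fit()
        sd = self.Z.std(axis=0)
        mu = self.Z.mean(axis=0)
        std_model = CoxPH(self.time, self.event, (self.Z - mu) / sd, names=self.names)

        if penalty == "l1":
            w = np.ones(p)
            beta_std = std_model._weighted_lasso(lam, w, tol, max_iter)
        elif penalty == "adaptive_l1":
            beta_ridge = std_model._ridge(ridge_init)
            w = 1.0 / np.maximum(np.abs(beta_ridge), 1e-4)
            # normalize to mean 1 so lam is commensurate with the plain lasso
            w = w * p / w.sum()
            beta_std = std_model._weighted_lasso(lam, w, tol, max_iter)
        else:  # scad via LLA, warm-started at the lasso solution
            # the SCAD knots live on the coefficient scale: lam/n plays the
            # per-observation penalty level, so shrinkage relaxes for
            # |beta| > a*lam/n while small coefficients see the lasso slope
            mu = lam / len(self.time)
            beta_std = std_model._weighted_lasso(lam, np.ones(p), tol, max_iter)
            for _ in range(3):
                w = _scad_deriv(np.abs(beta_std), mu, a) / max(mu, 1e-300)
                beta_std = std_model._weighted_lasso(lam, w, tol, max_iter)

        beta = beta_std / sd
        ll = self.loglik(beta)
        res = self._results(beta, ll, None)
        res.penalty = penalty
        res.lam = lam
        return res

    def _ridge(self, lam_ridge: float, max_iter: int = 200) -> np.ndarray:
        p = self.Z.shape[1]
        beta = np.zeros(p)
        for _ in range(max_iter):
            ll, grad, info = self.score_info(beta)
            g = grad - 2 * lam_ridge * beta
            H = info + 2 * lam_ridge * np.eye(p)
            step = np.linalg.solve(H, g)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-10:
                break
        return beta

    def _weighted_lasso(
        self, lam: float, w: np.ndarray, tol: float, max_iter: int
    ) -> np.ndarray:
        """Maximize logPL - lam*sum(w|beta|) by iterated quadratic
        approximation with cyclic coordinate descent (exact zeros)."""
        p = self.Z.shape[1]
        beta = np.zeros(p)
        for _outer in range(max_iter):
            _, grad, info = self.score_info(beta)
            # minimize (-grad)'(b-beta) + 0.5 (b-beta)' info (b-beta) + lam*sum(w|b|)
            b = beta.copy()
            diag = np.maximum(np.diag(info), 1e-10)
            for _inner in range(200):
                b_old = b.copy()
                for j in range(p):
                    cj = -grad[j] + info[j] @ (b - beta) - diag[j] * b[j]
                    b[j] = _soft(-cj, lam * w[j]) / diag[j]
                if np.max(np.abs(b - b_old)) < 1e-12:
                    break
            if np.max(np.abs(b - beta)) < tol:
                beta = b
                break
            beta = b
        # snap numerically-dead coordinates to exact zero via KKT check
        _, grad, _ = self.score_info(beta)
        for j in range(p):
            if beta[j] != 0 and abs(beta[j]) < 1e-10 and abs(grad[j]) <= lam * w[j] + 1e-8:
                beta[j] = 0.0
        return beta

    # -- results --------------------------------------------------------
    def _results(self, beta: np.ndarray, ll: float, info: np.ndarray | None) -> "CoxPHResults":
        baseline = self._breslow(beta)
        return CoxPHResults(self, beta, ll, info, baseline)

    def _breslow(self, beta: np.ndarray) -> BreslowBaseline:
        _, s0, _, _ = self._suffix_sums(np.asarray(beta, dtype=float))
        shift = (self._Zs @ beta).max() if len(beta) else 0.0
        idx = self._risk_start
        incr = self._d_j / (s0[idx] * np.exp(shift))
        return BreslowBaseline(self._uniq_times, np.cumsum(incr))


def _soft(x: float, thresh: float) -> float:
    if x > thresh:
        return x - thresh
    if x < -thresh:
        return x + thresh
    return 0.0


def _scad_deriv(theta: np.ndarray, lam: float, a: float) -> np.ndarray:
    """SCAD penalty derivative p'_lam(theta) for theta >= 0."""
    out = np.where(
        theta <= lam, lam, np.maximum(a * lam - theta, 0.0) / (a - 1.0)
    )
    return out


class CoxPHResults:
    """Fitted Cox model: coefficients, uncertainty, baseline hazard.

    Unpenalized fits carry standard errors from the observed information and
    Wald p-values; penalized fits carry exact-zero coefficients and the
    penalty settings instead (``bse`` is NaN there).
    """

    def __init__(self, model: CoxPH, beta, llf, info, baseline: BreslowBaseline):
        self.model = model
        self._beta = np.asarray(beta, dtype=float)
        self.llf = float(llf)
        self.baseline_cumhaz = baseline
        self.penalty: str | None = None
        self.lam: float | None = None
        names = model.names
        self.params = pd.Series(self._beta, index=names, name="coef")
        if info is not None and len(names):
            cov = np.linalg.inv(info + 1e-300 * np.eye(len(names)))
            se = np.sqrt(np.diag(cov))
        else:
            se = np.full(len(names), np.nan)
        self.bse = pd.Series(se, index=names, name="se")
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self._beta / se if len(names) else np.zeros(0)
        self.zvalues = pd.Series(z, index=names, name="z")
        self.pvalues = pd.Series(
            2 * stats.norm.sf(np.abs(z)), index=names, name="p"
        )

    # -- inspection -----------------------------------------------------
    @property
    def selected(self) -> list[str]:
        """Names of covariates with nonzero coefficient."""
        return [n for n, b in self.params.items() if b != 0.0]

    @property
    def n_events(self) -> int:
        return int(self.model.event.sum())

    @property
    def df_model(self) -> int:
        return len(self.selected)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.df_model

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params).rename("HR")

    def summary(self) -> pd.DataFrame:
        """Coefficient table: coef, HR, se, z, p."""
        return pd.DataFrame(
            {
                "coef": self.params,
                "HR": self.hazard_ratios,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )

    # -- prediction -----------------------------------------------------
    def linear_predictor(self, Z) -> np.ndarray:
        """``Z beta`` for new covariate rows (columns matched by name when
        a DataFrame is given)."""
        if len(self.params) == 0:
            n = len(Z) if hasattr(Z, "__len__") else 1
            return np.zeros(n)
        if isinstance(Z, pd.DataFrame):
            missing = [n for n in self.params.index if n not in Z.columns]
            if missing:
                raise ValidationError(f"covariate(s) missing in new data: {missing}")
            M = Z[list(self.params.index)].to_numpy(dtype=float)
        else:
            M = np.asarray(Z, dtype=float)
            if M.ndim == 1:
                M = M[None, :] if M.shape[0] == len(self.params) else M[:, None]
        return M @ self._beta

    def predict_survival(self, Z, times) -> np.ndarray:
        """``pi(t|Z) = exp(-Lambda_0(t) e^{Z beta})``; shape (n, len(times)).

        Equals 1 at t = 0 and is nonincreasing in t.
        """
        lp = self.linear_predictor(Z)
        t = np.atleast_1d(np.asarray(times, dtype=float))
        H = self.baseline_cumhaz(t)
        return np.exp(-np.outer(np.exp(lp), np.atleast_1d(H)))

    def martingale_residuals(self) -> np.ndarray:
        """``m_i = delta_i - Lambda_0(T_i) e^{Z_i beta}`` on the training
        data; sums to zero at the (unpenalized) MLE."""
        lp = self.linear_predictor(
            pd.DataFrame(self.model.Z, columns=self.model.names)
        ) if len(self.params) else np.zeros(len(self.model.time))
        return self.model.event - self.baseline_cumhaz(self.model.time) * np.exp(lp)
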