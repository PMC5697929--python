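"""Multi-event (hidden-Markov) capture-recapture likelihood and fitting.

The data are encounter histories conditioned on first capture.  The shipped
model has two hidden states, {alive, dead}: an individual alive at occasion
t survives the interval leaving t with probability phi(t) (interval rates
carry the season type of the occasion they leave), dead is absorbing, and
an alive individual is detected at an occasion with probability p(t) while
a dead one never is.  Both rates are logit-linear in the design matrices of
:mod:`partmig.design`.

The likelihood is evaluated with the forward algorithm
(:func:`hmm_loglik`); a generic-state forward pass (:func:`forward_loglik`)
is provided for other state/emission structures.  The classical closed-form
Cormack-Jolly-Seber product, including the terminal chi term, is kept as an
independent oracle (:func:`cjs_loglik_oracle`) and must agree with the
forward algorithm to numerical precision.

Fitting is by quasi-Newton maximisation with seeded multistarts; the
coefficient covariance is the inverse observed (finite-difference) Hessian.
:class:`MultiEventCJS` wraps this as a scikit-learn style estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator

from .design import DesignMatrices, build_design
from .formula import ModelSpec, format_model_spec, parse_model_spec
from .prep import EncounterHistory
from .seasons import SeasonCalendar

__all__ = [
    "hmm_loglik",
    "forward_loglik",
    "cjs_loglik_oracle",
    "FitResult",
    "ConvergenceError",
    "MultiEventCJS",
    "fit_model",
    "predict_rates",
]

_TINY = 1e-300
_BOUNDARY_TOL = 1e-4


class ConvergenceError(RuntimeError):
    """Raised when no optimiser start converged; carries the best attempt."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


def _rates_from_beta(beta: np.ndarray, dm: DesignMatrices) -> tuple[np.ndarray, np.ndarray]:
    b_phi = beta[: dm.k_phi]
    b_p = beta[dm.k_phi :]
    eta_phi = dm.x_phi @ b_phi
    eta_p = dm.x_p @ b_p
    if not (np.isfinite(eta_phi).all() and np.isfinite(eta_p).all()):
        raise FloatingPointError("non-finite linear predictor")
    return expit(eta_phi), expit(eta_p)


def hmm_loglik(
    beta: np.ndarray,
    eh: EncounterHistory,
    dm: DesignMatrices,
    weights: np.ndarray | None = None,
) -> float:
    """Forward-algorithm log-likelihood of the two-state model.

    Vectorised over individuals: carries P(data so far, alive) and
    P(data so far, dead) across occasions, conditioning each history on its
    first capture.  ``weights`` multiply per-individual contributions (used
    when identical histories are collapsed).
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != dm.k:
        raise ValueError(f"expected {dm.k} coefficients, got {beta.shape[0]}")
    phi, p = _rates_from_beta(beta, dm)
    y = eh.matrix
    first = eh.first_occasion
    n, T = y.shape
    if n == 0:
        return 0.0
    alive = np.zeros(n)
    dead = np.zeros(n)
    for t in range(T):
        if t > 0:
            entered = first < t
            ph = phi[:, t - 1]
            a_new = alive * ph
            d_new = alive * (1.0 - ph) + dead
            det = y[:, t] == 1
            pt = p[:, t]
            a_new = np.where(det, a_new * pt, a_new * (1.0 - pt))
            d_new = np.where(det, 0.0, d_new)
            alive = np.where(entered, a_new, alive)
            dead = np.where(entered, d_new, dead)
        entering = first == t
        alive = np.where(entering, 1.0, alive)
        dead = np.where(entering, 0.0, dead)
    ll = np.log(np.maximum(alive + dead, _TINY))
    if weights is not None:
        ll = ll * weights
    return float(ll.sum())


def forward_loglik(
    init: np.ndarray,
    transitions: np.ndarray,
    emissions: np.ndarray,
) -> float:
    """Generic forward pass for one sequence over an arbitrary state space.

    Parameters
    ----------
    init : (S,) initial state distribution at the first occasion (after
        conditioning; the first emission is not scored).
    transitions : (T-1, S, S) row-stochastic matrices, ``transitions[t, i, j]``
        = P(state j at t+1 | state i at t).
    emissions : (T, S) probability of the *observed* event at each occasion
        given each state; ``emissions[0]`` is ignored (conditioned on).
    """
    alpha = np.asarray(init, dtype=float).copy()
    T = emissions.shape[0]
    for t in range(1, T):
        alpha = (alpha @ transitions[t - 1]) * emissions[t]
    return float(np.log(max(alpha.sum(), _TINY)))


def cjs_loglik_oracle(
    phi: np.ndarray, p: np.ndarray, eh: EncounterHistory
) -> float:
    """Closed-form Cormack-Jolly-Seber log-likelihood (independent oracle).

    Per history: product of survival and detection/non-detection terms from
    first capture to last detection, times the recursive chi probability of
    never being seen again.  Intended for small instances; agrees with
    :func:`hmm_loglik` to ~1e-10.
    """
    phi = np.asarray(phi, dtype=float)
    p = np.asarray(p, dtype=float)
    y = eh.matrix
    n, T = y.shape
    if phi.ndim == 1:
        phi = np.broadcast_to(phi, (n, T - 1))
    if p.ndim == 1:
        p = np.broadcast_to(p, (n, T))
    total = 0.0
    for i in range(n):
        dets = np.flatnonzero(y[i])
        f, last = dets[0], dets[-1]
        lik = 1.0
        for t in range(f + 1, last + 1):
            lik *= phi[i, t - 1]
            lik *= p[i, t] if y[i, t] else (1.0 - p[i, t])
        chi = 1.0
        for t in range(T - 2, last - 1, -1):
            chi = (1.0 - phi[i, t]) + phi[i, t] * (1.0 - p[i, t + 1]) * chi
        total += np.log(max(lik * chi, _TINY))
    return float(total)


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model."""

    spec: ModelSpec
    beta: np.ndarray  # link-scale coefficients
    cov: np.ndarray  # inverse observed Hessian
    loglik: float
    k: int
    names: list[str]
    k_phi: int
    converged: bool
    n_individuals: int
    boundary: bool = False
    n_starts: int = 1
    start_logliks: list = field(default_factory=list)

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def to_dict(self) -> dict:
        return {
            "model": format_model_spec(self.spec),
            "coefficients": dict(zip(self.names, self.beta.tolist())),
            "covariance": self.cov.tolist(),
            "loglik": self.loglik,
            "deviance": self.deviance,
            "K": self.k,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_individuals": self.n_individuals,
            "start_logliks": list(self.start_logliks),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _fd_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of scalar f at x."""
    k = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            val = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    return H


def _collapse(eh: EncounterHistory, covariates: pd.DataFrame):
    """Merge individuals with identical histories and covariate classes.

    Returns a reduced (eh, covariates, weights) triple; the likelihood is
    unchanged because contributions are exchangeable within a class.
    """
    cov = covariates.reset_index(drop=True)
    keys = pd.DataFrame(
        {
            "strategy": cov["strategy"].astype(str),
            "sex": cov["sex"].astype(str),
            "age": cov["age"].astype(str),
            "h": ["".join(map(str, row)) for row in eh.matrix],
        }
    )
    grouped = keys.groupby(["strategy", "sex", "age", "h"], sort=False).indices
    reps, weights = [], []
    for idx in grouped.values():
        reps.append(idx[0])
        weights.append(len(idx))
    reps = np.asarray(reps)
    eh2 = EncounterHistory(eh.ids[reps], eh.matrix[reps], eh.calendar)
    return eh2, cov.iloc[reps].reset_index(drop=True), np.asarray(weights, dtype=float)


class MultiEventCJS(BaseEstimator):
    """Multi-event Cormack-Jolly-Seber survival model, sklearn-style.

    Parameters
    ----------
    model : str
        Formula in the mini-language, e.g. ``"Phi[season + migr].P[migr]"``.
    n_starts : int
        Seeded quasi-Newton multistarts; the best optimum is kept.
    random_state : int
        Seed for the start-point draws.
    gtol : float
        Gradient-norm convergence tolerance.
    collapse : bool
        Collapse identical (history, covariate-class) rows into weighted
        pseudo-individuals before optimising (pure speed-up).

    Attributes (after :meth:`fit`)
    ------------------------------
    result_ : FitResult
    coef_, cov_, loglik_, deviance_, k_, converged_, boundary_
    """

    def __init__(
        self,
        model: str = "Phi[season + migr].P[migr]",
        n_starts: int = 5,
        random_state: int = 0,
        gtol: float = 1e-8,
        maxiter: int = 1000,
        collapse: bool = True,
    ):
        self.model = model
        self.n_starts = n_starts
        self.random_state = random_state
        self.gtol = gtol
        self.maxiter = maxiter
        self.collapse = collapse

    # get_params / set_params / cloning come from sklearn's BaseEstimator

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        X: EncounterHistory,
        y=None,
        *,
        covariates: pd.DataFrame,
        calendar: SeasonCalendar | None = None,
    ) -> "MultiEventCJS":
        """Maximise the conditional-on-first-capture likelihood.

        ``X`` is an :class:`EncounterHistory`; ``covariates`` must be
        row-aligned with it (columns ``strategy``, ``sex``, ``age``).
        ``y`` is ignored (sklearn signature compatibility).
        """
        spec = self.model if isinstance(self.model, ModelSpec) else parse_model_spec(self.model)
        calendar = calendar or X.calendar
        if X.n_individuals < 1:
            raise ValueError("need at least one individual")
        if not (X.first_occasion < X.n_occasions - 1).any():
            raise ValueError("no individual has any post-entry occasion")
        if len(covariates) != X.n_individuals:
            raise ValueError("covariates not aligned with encounter history")

        eh_fit, cov_fit, w = (X, covariates.reset_index(drop=True), None)
        if self.collapse:
            eh_fit, cov_fit, w = _collapse(X, covariates)
        dm = build_design(spec, cov_fit, calendar, eh=eh_fit)

        def nll(b):
            try:
                return -hmm_loglik(b, eh_fit, dm, weights=w)
            except FloatingPointError:
                return np.inf

        rng = np.random.default_rng(self.random_state)
        starts = [np.zeros(dm.k)]
        for _ in range(max(0, int(self.n_starts) - 1)):
            starts.append(rng.uniform(-2.0, 2.0, size=dm.k))

        best = None
        best_conv = None
        start_lls = []
        # box the link-scale coefficients: |logit| = 15 pins a rate within
        # 3e-7 of the boundary, where the likelihood is flat; this keeps
        # boundary solutions finite instead of aborting the line search
        bounds = [(-15.0, 15.0)] * dm.k
        for x0 in starts:
            res = minimize(
                nll,
                x0,
                method="L-BFGS-B",
                jac="3-point",
                bounds=bounds,
                options={"gtol": self.gtol, "ftol": 1e-13, "maxiter": self.maxiter},
            )
            start_lls.append(-res.fun)

            def better(a, b):
                if b is None:
                    return True
                if a.fun < b.fun - 1e-10:
                    return True
                return abs(a.fun - b.fun) <= 1e-10 and np.linalg.norm(a.x) < np.linalg.norm(b.x)

            if better(res, best):
                best = res
            if res.success and better(res, best_conv):
                best_conv = res
        if best_conv is not None:
            best = best_conv
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("optimiser failed on every start", None)

        H = _fd_hessian(nll, best.x)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        cov = 0.5 * (cov + cov.T)

        phi, p = _rates_from_beta(best.x, dm)
        first = eh_fit.first_occasion
        t_idx = np.arange(eh_fit.n_occasions)
        mask_phi = t_idx[None, : eh_fit.n_occasions - 1] >= first[:, None]
        mask_p = t_idx[None, :] > first[:, None]
        rates = np.concatenate([phi[mask_phi], p[mask_p]])
        # boundary diagnostic: any fitted rate essentially at 0 or 1
        boundary = bool((np.minimum(rates, 1.0 - rates) < _BOUNDARY_TOL).any())

        result = FitResult(
            spec=spec,
            beta=best.x,
            cov=cov,
            loglik=-best.fun,
            k=dm.k,
            names=dm.names,
            k_phi=dm.k_phi,
            converged=bool(best.success),
            n_individuals=X.n_individuals,
            boundary=boundary,
            n_starts=len(starts),
            start_logliks=start_lls,
        )
        if not best.success:
            raise ConvergenceError(
                f"no start converged: {best.message}", result
            )
        self.result_ = result
        self.coef_ = result.beta
        self.cov_ = result.cov
        self.loglik_ = result.loglik
        self.deviance_ = result.deviance
        self.k_ = result.k
        self.converged_ = result.converged
        self.boundary_ = result.boundary
        return self

    def predict_rate(self, cell: dict) -> dict:
        """Back-transformed rate with 95% Wald CI for one covariate cell."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        return predict_rates(self.result_, cell)

    def score(self, X=None, y=None) -> float:
        """Log-likelihood of the fitted model (higher is better)."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        return self.loglik_


_CELL_LEVELS = {
    "season": ("summer", "winter"),
    "migr": ("resident", "migrant"),
    "sex": ("female", "male"),
    "age": ("adult", "juvenile"),
}
_CELL_ALIASES = {"strategy": "migr", "season_type": "season"}


def predict_rates(fit: FitResult, cell: dict) -> dict:
    """Rate and 95% CI for a covariate cell of one sub-model.

    ``cell`` must contain ``"submodel"`` ("phi" or "p"); remaining keys name
    factors in the fitted formula with their level, e.g.
    ``{"submodel": "phi", "season": "winter", "migr": "migrant"}``.  The CI
    is Wald on the logit scale back-transformed through the inverse link,
    hence asymmetric around the estimate.
    """
    cell = dict(cell)
    sub = cell.pop("submodel", "phi")
    if sub not in ("phi", "p"):
        raise ValueError("submodel must be 'phi' or 'p'")
    terms = fit.spec.phi_terms if sub == "phi" else fit.spec.p_terms
    idx = range(fit.k_phi) if sub == "phi" else range(fit.k_phi, fit.k)
    names = [n.split(":", 1)[1] for n in (fit.names[i] for i in idx)]
    x = np.zeros(len(names))
    x[names.index("(Intercept)")] = 1.0
    for key, level in cell.items():
        factor = _CELL_ALIASES.get(key, key)
        if factor not in terms:
            raise ValueError(f"factor {key!r} is not in the fitted model")
        ref, non_ref = _CELL_LEVELS[factor]
        if level not in (ref, non_ref):
            raise ValueError(f"unknown level {level!r} for factor {factor!r}")
        if level == non_ref:
            x[names.index(f"{factor}[{non_ref}]")] = 1.0
    beta = fit.beta[list(idx)]
    sigma = fit.cov[np.ix_(list(idx), list(idx))]
    eta = float(x @ beta)
    var = float(x @ sigma @ x)
    se = np.sqrt(max(var, 0.0))
    lo, hi = expit(eta - 1.96 * se), expit(eta + 1.96 * se)
    return {
        "rate": float(expit(eta)),
        "se_link": float(se),
        "ci_low": float(lo),
        "ci_high": float(hi),
    }


def fit_model(
    model: str | ModelSpec,
    eh: EncounterHistory,
    covariates: pd.DataFrame,
    *,
    calendar: SeasonCalendar | None = None,
    n_starts: int = 5,
    random_state: int = 0,
    **kwargs,
) -> FitResult:
    """Functional wrapper around :class:`MultiEventCJS`."""
    est = MultiEventCJS(
        model=model, n_starts=n_starts, random_state=random_state, **kwargs
    )
    est.fit(eh, covariates=covariates, calendar=calendar)
    return est.result_
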