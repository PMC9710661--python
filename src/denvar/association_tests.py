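"""Association tests linking subject strata or density similarity to outcomes.

Two families of tests are provided.

Label-based tests take a hard subject partition (from any clustering route)
and test it as a fixed effect: a Wald test in ordinary linear regression for
continuous outcomes, and a partial-likelihood ratio test in a Cox
proportional-hazards model for right-censored outcomes.

Similarity-based tests skip the clustering step entirely.  With
G = exp(-JSD) as a subject-by-subject similarity matrix, a continuous outcome
is modeled as Y = C beta + g + eps with g ~ MVN(0, sigma_g^2 G), and the null
H0: sigma_g^2 = 0 is tested by a likelihood-ratio statistic referred to the
Self-Liang 50:50 mixture of a point mass at zero and chi-square(1) (the
variance sits on the boundary of its parameter space under the null).  For
survival outcomes the same random effect enters the Cox log-hazard
(a correlated Gaussian frailty); its integrated partial likelihood is
maximized under a Laplace approximation.  Variance-component estimates from
partial likelihoods are imprecise in small cohorts, so the frailty test warns
below N = 200.

The mixed models are fitted by maximum likelihood (not REML) so that the
likelihood-ratio statistics comparing nested models are coherent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import optimize
from scipy.stats import chi2

from ._errors import CovarianceError, DegenerateInputError, ParameterError
from .cohort_clustering import ClusterLabels
from .density_distance import SimilarityMatrix

logger = logging.getLogger(__name__)

MIXTURE_NULL = "0.5*chi2(0) + 0.5*chi2(1)"

#: ridge added to G before inversion in the frailty fit
_G_RIDGE = 1e-8


@dataclass
class TestResult:
    """Outcome of one association test."""

    test: str
    statistic: float
    null_distribution: str
    p_value: float
    effect: dict = field(default_factory=dict)
    converged: bool = True
    messages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def to_record(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "null": self.null_distribution,
            "p_value": self.p_value,
            "effect": {k: float(v) for k, v in self.effect.items()},
            "converged": self.converged,
            "messages": list(self.messages),
        }


def _mixture_p(stat: float) -> float:
    """P-value under the 50:50 chi2(0)/chi2(1) boundary mixture."""
    if stat <= 0.0:
        return 1.0
    return 0.5 * float(chi2.sf(stat, 1))


def _design(C: np.ndarray | None, n: int) -> np.ndarray:
    """Intercept plus optional covariate columns."""
    cols = [np.ones((n, 1))]
    if C is not None:
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ParameterError("covariate matrix does not match outcome length")
        cols.append(C)
    return np.hstack(cols)


def _dummies(labels: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Treatment-coded dummies for the non-reference groups."""
    groups = np.unique(labels)
    if groups.size < 2:
        raise DegenerateInputError("only one non-empty group; no contrast to test")
    return (
        np.column_stack([(labels == g).astype(float) for g in groups[1:]]),
        list(groups[1:]),
    )


# ---------------------------------------------------------------------------
# label-based tests
# ---------------------------------------------------------------------------


def linear_wald_test(
    y: np.ndarray, Z: ClusterLabels, C: np.ndarray | None = None
) -> TestResult:
    """Wald test of the cluster-label coefficient(s) in an OLS fit of Y."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    n = y.size
    if Z.labels.size != n:
        raise ParameterError("labels and outcome differ in length")
    Zd, groups = _dummies(Z.labels)
    X = np.hstack([_design(C, n), Zd])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateInputError("collinear design matrix (rank deficient)")
    if n < X.shape[1] + 2:
        raise ParameterError("too few subjects for the requested design")
    fit = sm.OLS(y, X).fit()
    k = Zd.shape[1]
    R = np.zeros((k, X.shape[1]))
    R[:, -k:] = np.eye(k)
    wt = fit.wald_test(R, use_f=False, scalar=True)
    stat = float(wt.statistic)
    effect = {f"coef_group_{g}": float(b) for g, b in zip(groups, fit.params[-k:])}
    effect["sigma2"] = float(fit.scale)
    return TestResult(
        test="linear-wald",
        statistic=stat,
        null_distribution=f"chi2({k})",
        p_value=float(wt.pvalue),
        effect=effect,
    )


def _survival_frame(
    time: np.ndarray,
    event: np.ndarray,
    extra: dict[str, np.ndarray],
) -> pd.DataFrame:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time < 0).any():
        raise ParameterError("negative survival times")
    if event.sum() == 0:
        raise DegenerateInputError("no events observed; Cox model undefined")
    df = pd.DataFrame({"time": time, "event": event})
    for k, v in extra.items():
        df[k] = np.asarray(v, dtype=float)
    return df


def coxph_label_lrt(
    time: np.ndarray,
    event: np.ndarray,
    Z: ClusterLabels,
    C: np.ndarray | None = None,
) -> TestResult:
    """Likelihood-ratio test of cluster labels in a Cox PH model (Efron ties).

    The full model has the label dummies (plus covariates); the reduced model
    drops the labels.  The hazard ratio exp(gamma-hat) is reported per
    non-reference group.
    """
    Zd, groups = _dummies(Z.labels)
    messages: list[str] = []
    for g in np.unique(Z.labels):
        if np.asarray(event)[Z.labels == g].sum() == 0:
            messages.append(f"group {g} has no events; estimates may diverge")
            warnings.warn(messages[-1], stacklevel=2)
    extra = {f"z{g}": Zd[:, i] for i, g in enumerate(groups)}
    ncov = 0
    if C is not None:
        Cm = _design(C, len(np.asarray(time)))[:, 1:]
        ncov = Cm.shape[1]
        extra.update({f"c{i}": Cm[:, i] for i in range(ncov)})
    df = _survival_frame(time, event, extra)
    full = CoxPHFitter().fit(df, duration_col="time", event_col="event")
    if ncov:
        red = CoxPHFitter().fit(
            df.drop(columns=[f"z{g}" for g in groups]),
            duration_col="time",
            event_col="event",
        )
        ll0 = float(red.log_likelihood_)
    else:
        ll0 = float(full._ll_null_)
    stat = max(0.0, 2.0 * (float(full.log_likelihood_) - ll0))
    k = len(groups)
    effect = {
        f"hazard_ratio_group_{g}": float(np.exp(full.params_[f"z{g}"])) for g in groups
    }
    converged = bool(np.isfinite(stat))
    return TestResult(
        test="coxph-label-lrt",
        statistic=stat,
        null_distribution=f"chi2({k})",
        p_value=float(chi2.sf(stat, k)),
        effect=effect,
        converged=converged,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# similarity-based tests
# ---------------------------------------------------------------------------


def _check_similarity(G: SimilarityMatrix | np.ndarray, n: int) -> np.ndarray:
    Gm = G.values if isinstance(G, SimilarityMatrix) else np.asarray(G, dtype=float)
    if Gm.shape != (n, n):
        raise CovarianceError("similarity matrix does not match outcome length")
    if not np.allclose(Gm, Gm.T, atol=1e-10):
        raise CovarianceError("similarity matrix must be symmetric")
    min_eig = float(np.linalg.eigvalsh(Gm)[0])
    if min_eig < -1e-8:
        raise CovarianceError(
            f"similarity matrix is not PSD (min eigenvalue {min_eig:.3e}); "
            "apply to_similarity(..., psd_repair=True)"
        )
    return (Gm + Gm.T) / 2.0


def lmm_variance_lrt(
    y: np.ndarray,
    G: SimilarityMatrix | np.ndarray,
    C: np.ndarray | None = None,
) -> TestResult:
    """LRT of H0: sigma_g^2 = 0 in Y = C beta + g + eps, g ~ MVN(0, sigma_g^2 G).

    The model is fitted by maximum likelihood, profiling beta and the residual
    variance and optimizing the variance ratio delta = sigma_g^2 / sigma^2 on
    the log scale.  The statistic is referred to the 50:50 chi2(0)/chi2(1)
    boundary mixture; a boundary estimate sigma_g^2 = 0 yields statistic 0 and
    p = 1.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    Gm = _check_similarity(G, n)
    messages: list[str] = []
    if n < 20:
        messages.append("fewer than 20 subjects; variance-component LRT unreliable")
    offdiag = Gm[~np.eye(n, dtype=bool)]
    if np.abs(offdiag).max(initial=0.0) < 1e-10:
        messages.append(
            "similarity matrix is (near-)identity: the genetic-style random "
            "effect is not separable from residual noise"
        )
        warnings.warn(messages[-1], stacklevel=2)

    X = _design(C, n)
    lam, U = np.linalg.eigh(Gm)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def profile_ll(delta: float) -> float:
        v = delta * lam + 1.0
        Xw = Xt / v[:, None]
        A = Xt.T @ Xw
        beta = np.linalg.solve(A, Xw.T @ yt)
        r = yt - Xt @ beta
        rss = float((r * r / v).sum())
        s2 = rss / n
        return -0.5 * (n * np.log(2.0 * np.pi * s2) + n + np.log(v).sum())

    ll0 = profile_ll(0.0)
    log_deltas = np.linspace(-10.0, 8.0, 37)
    lls = np.array([profile_ll(np.exp(ld)) for ld in log_deltas])
    i_best = int(np.argmax(lls))
    lo = log_deltas[max(i_best - 1, 0)]
    hi = log_deltas[min(i_best + 1, log_deltas.size - 1)]
    res = optimize.minimize_scalar(
        lambda ld: -profile_ll(np.exp(ld)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    ll_best, delta_hat = -float(res.fun), float(np.exp(res.x))
    if ll_best <= ll0 + 1e-10:
        ll_best, delta_hat = ll0, 0.0

    # recover sigma^2 at the optimum
    v = delta_hat * lam + 1.0
    Xw = Xt / v[:, None]
    beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    r = yt - Xt @ beta
    s2 = float((r * r / v).sum()) / n
    sigma2_g = delta_hat * s2

    stat = max(0.0, 2.0 * (ll_best - ll0))
    if stat < 1e-10:
        stat, sigma2_g = 0.0, 0.0
    return TestResult(
        test="lmm-variance-lrt",
        statistic=stat,
        null_distribution=MIXTURE_NULL,
        p_value=_mixture_p(stat),
        effect={"sigma2_g": sigma2_g, "sigma2": s2},
        converged=bool(res.success),
        messages=messages,
    )


# --- Cox partial-likelihood machinery (Breslow risk sets) -------------------


class _CoxParts:
    """Precomputed risk-set structure for Breslow partial likelihood."""

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if event.sum() == 0:
            raise DegenerateInputError("no events observed")
        if np.ptp(time) == 0 and event.all():
            raise DegenerateInputError("all subjects share one event time")
        self.time, self.event = time, event
        self.event_times = np.unique(time[event == 1])
        # at_risk[e, i] = subject i still at risk at event time e
        self.at_risk = time[None, :] >= self.event_times[:, None]
        self.d = np.array(
            [
                int(((time == t) & (event == 1)).sum())
                for t in self.event_times
            ],
            dtype=float,
        )

    def ll(self, eta: np.ndarray) -> float:
        e = np.exp(eta)
        S = self.at_risk @ e
        return float(eta[self.event == 1].sum() - (self.d * np.log(S)).sum())

    def grad_info(self, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gradient of ll w.r.t. eta and observed information (negative Hessian)."""
        e = np.exp(eta)
        S = self.at_risk @ e
        H = self.at_risk.T @ (self.d / S)  # cumulative hazard per subject
        grad = self.event - e * H
        Pi = (np.sqrt(self.d) / S)[:, None] * (self.at_risk * e[None, :])
        info = np.diag(e * H) - Pi.T @ Pi
        return grad, info


def _cox_fixed_ll(
    parts: _CoxParts, C: np.ndarray | None
) -> tuple[float, np.ndarray]:
    """Maximized Breslow partial log-likelihood of the fixed-effects-only model."""
    n = parts.time.size
    if C is None:
        return parts.ll(np.zeros(n)), np.zeros(0)
    Cm = _design(C, n)[:, 1:]  # no intercept in a Cox model
    beta = np.zeros(Cm.shape[1])
    ll_prev = -np.inf
    for _ in range(50):
        eta = Cm @ beta
        ll = parts.ll(eta)
        grad, info = parts.grad_info(eta)
        g = Cm.T @ grad
        Hm = Cm.T @ info @ Cm + 1e-10 * np.eye(Cm.shape[1])
        step = np.linalg.solve(Hm, g)
        t = 1.0
        while parts.ll(Cm @ (beta + t * step)) < ll and t > 1e-6:
            t /= 2.0
        beta = beta + t * step
        if abs(ll - ll_prev) < 1e-10:
            break
        ll_prev = ll
    return parts.ll(Cm @ beta), beta


def cox_frailty_lrt(
    time: np.ndarray,
    event: np.ndarray,
    G: SimilarityMatrix | np.ndarray,
    C: np.ndarray | None = None,
    theta_bounds: tuple[float, float] = (1e-3, 20.0),
) -> TestResult:
    """LRT of a correlated Gaussian frailty with covariance sigma^2 G.

    The hazard is lambda_0(t) exp(C beta + g_j) with g ~ MVN(0, sigma^2 G).
    For each candidate sigma^2 the random effects (and beta) are found by
    Newton iteration on the penalized Breslow partial log-likelihood, and the
    integrated partial likelihood is approximated by Laplace's method at that
    mode.  The LRT against the fixed-effects-only model is referred to the
    50:50 chi2(0)/chi2(1) mixture.  exp(sigma^2-hat) is reported as the
    relative-risk spread interpretation of the frailty variance.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = time.size
    Gm = _check_similarity(G, n)
    messages: list[str] = []
    if n < 200:
        messages.append(
            "frailty variance estimates are imprecise below N=200; "
            "interpret this test with caution"
        )
        warnings.warn(messages[-1], stacklevel=2)
    parts = _CoxParts(time, event)
    Gr = Gm + _G_RIDGE * np.eye(n)
    Ginv = np.linalg.inv(Gr)
    sign, logdet_G = np.linalg.slogdet(Gr)
    if sign <= 0:
        raise CovarianceError("similarity matrix is singular beyond repair")

    Cm = None
    if C is not None:
        Cm = _design(C, n)[:, 1:]
    p = 0 if Cm is None else Cm.shape[1]
    ll_null, _ = _cox_fixed_ll(parts, C)

    state = {"x": np.zeros(p + n)}

    def laplace_ll(theta: float) -> float:
        Q = Ginv / theta
        x = state["x"].copy()

        def pen_ll(xv: np.ndarray) -> float:
            beta, g = xv[:p], xv[p:]
            eta = g if Cm is None else Cm @ beta + g
            return parts.ll(eta) - 0.5 * float(g @ Q @ g)

        f_prev = pen_ll(x)
        for _ in range(60):
            beta, g = x[:p], x[p:]
            eta = g if Cm is None else Cm @ beta + g
            grad_eta, info = parts.grad_info(eta)
            grad = np.empty(p + n)
            hess = np.empty((p + n, p + n))
            if p:
                grad[:p] = Cm.T @ grad_eta
                hess[:p, :p] = Cm.T @ info @ Cm
                hess[:p, p:] = Cm.T @ info
                hess[p:, :p] = hess[:p, p:].T
            grad[p:] = grad_eta - Q @ g
            hess[p:, p:] = info + Q
            try:
                step = np.linalg.solve(
                    hess + 1e-10 * np.eye(p + n), grad
                )
            except np.linalg.LinAlgError:
                return -np.inf
            t = 1.0
            while pen_ll(x + t * step) < f_prev - 1e-12 and t > 1e-8:
                t /= 2.0
            x = x + t * step
            f_new = pen_ll(x)
            if abs(f_new - f_prev) < 1e-9:
                f_prev = f_new
                break
            f_prev = f_new
        state["x"] = x
        beta, g = x[:p], x[p:]
        eta = g if Cm is None else Cm @ beta + g
        _, info = parts.grad_info(eta)
        A = info + Q
        sign_a, logdet_A = np.linalg.slogdet(A)
        if sign_a <= 0:
            return -np.inf
        return (
            f_prev
            - 0.5 * (n * np.log(theta) + logdet_G)
            - 0.5 * logdet_A
        )

    log_lo, log_hi = np.log(theta_bounds[0]), np.log(theta_bounds[1])
    grid = np.linspace(log_lo, log_hi, 12)
    lls = np.array([laplace_ll(np.exp(t)) for t in grid])
    i_best = int(np.argmax(lls))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda lt: -laplace_ll(np.exp(lt)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-4},
    )
    ll_best, theta_hat = -float(res.fun), float(np.exp(res.x))
    converged = bool(np.isfinite(ll_best))
    stat = 2.0 * (ll_best - ll_null)
    if stat < 1e-8 or i_best == 0 and stat < 1e-4:
        stat, theta_hat = 0.0, 0.0
    stat = max(0.0, stat)
    return TestResult(
        test="cox-frailty-lrt",
        statistic=stat,
        null_distribution=MIXTURE_NULL,
        p_value=_mixture_p(stat),
        effect={
            "sigma2": theta_hat,
            "relative_risk_spread": float(np.exp(theta_hat)),
        },
        converged=converged,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier summaries
# ---------------------------------------------------------------------------


def kaplan_meier_by_group(
    time: np.ndarray,
    event: np.ndarray,
    Z: ClusterLabels,
    plot_path: str | None = None,
    annotation: str | None = None,
) -> dict[int, pd.DataFrame]:
    """Product-limit survival curve per cluster, optionally plotted.

    Returns, per group label, a frame with columns ``time`` and ``survival``
    (the step function evaluated at the observed times).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    curves: dict[int, pd.DataFrame] = {}
    fitters: dict[int, KaplanMeierFitter] = {}
    for g in np.unique(Z.labels):
        mask = Z.labels == g
        if mask.sum() == 0:  # pragma: no cover - labels construction forbids this
            warnings.warn(f"group {g} empty; dropped", stacklevel=2)
            continue
        km = KaplanMeierFitter()
        km.fit(time[mask], event[mask], label=f"group {g}")
        fitters[int(g)] = km
        sf = km.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[int(g)] = sf
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4.5))
        for g, km in fitters.items():
            km.plot_survival_function(ax=ax, show_censors=True)
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        if annotation:
            ax.text(
                0.02, 0.05, annotation, transform=ax.transAxes, fontsize=9
            )
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return curves
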