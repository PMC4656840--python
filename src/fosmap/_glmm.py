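"""Mixed-model fitting kernels.

Two small, purpose-built GLMM fitters:

* a Poisson log-linear model with one Gaussian random intercept per group
  (rat), fitted by maximizing the Laplace-approximate marginal likelihood.
  With a single random intercept the marginal likelihood factorizes over
  groups, so the inner mode is a fast 1-D Newton solve per group; the whole
  negative log-likelihood is jit-compiled because the bootstrap likelihood
  ratio test refits the model thousands of times.

* a binomial (logistic) model with nested rat and cell random intercepts,
  fitted by a joint Laplace approximation over all random effects (the
  designs are small: tens of cells, a handful of rats).

Both reduce exactly to the corresponding fixed-effect GLM when the random
effect standard deviations are zero, which the tests exploit as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit

try:  # pragma: no cover
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# ---------------------------------------------------------------------------
# Poisson GLMM, one random intercept per group
# ---------------------------------------------------------------------------


@njit(cache=True)
def _poisson_laplace_nll(params, y, eta_x, group_start, lgamma_y):
    """Negative Laplace marginal log-likelihood.

    ``eta_x`` is the linear predictor without the random effect; groups are
    contiguous slices delimited by ``group_start`` (len = n_groups + 1).
    ``params[-1]`` is the random-intercept standard deviation (abs is taken).
    """
    sigma = abs(params[-1])
    n_groups = group_start.size - 1
    ll = 0.0
    for g in range(n_groups):
        lo = group_start[g]
        hi = group_start[g + 1]
        S = 0.0
        Y = 0.0
        base = 0.0
        for i in range(lo, hi):
            e = eta_x[i]
            S += math.exp(e)
            Y += y[i]
            base += y[i] * e - lgamma_y[i]
        if sigma < 1e-10:
            ll += base - S
            continue
        inv_v = 1.0 / (sigma * sigma)
        # Newton solve for the mode of  Y*b - S*exp(b) - b^2/(2 sigma^2)
        b = math.log((Y + 0.5) / S) if S > 0.0 else 0.0
        if b > 5.0 * sigma:
            b = 5.0 * sigma
        if b < -5.0 * sigma:
            b = -5.0 * sigma
        for _ in range(60):
            eb = math.exp(b)
            g1 = Y - S * eb - b * inv_v
            g2 = -S * eb - inv_v
            step = g1 / g2
            # damped Newton for stability far from the mode
            if step > 1.0:
                step = 1.0
            elif step < -1.0:
                step = -1.0
            b -= step
            if abs(step) < 1e-12:
                break
        eb = math.exp(b)
        h = S * eb + inv_v
        ll += (
            base
            + Y * b
            - S * eb
            - 0.5 * b * b * inv_v
            - math.log(sigma)
            - 0.5 * math.log(h)
        )
    return -ll


@dataclass
class PoissonGlmmFit:
    """Fitted Poisson mixed model ln λ = (α0 + α1·I_t) + (α2 + α3·I_t)·area."""

    alpha: np.ndarray  # (α0, α1, α2, α3); α1 = α3 = 0 in the null model
    sigma_rat: float
    loglik: float
    converged: bool
    null_model: bool
    n_groups: int


def _prepare_groups(group_labels):
    labels, codes = np.unique(np.asarray(group_labels), return_inverse=True)
    order = np.argsort(codes, kind="stable")
    counts = np.bincount(codes)
    starts = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
    return order, starts, len(labels)


def fit_poisson_glmm_arrays(
    y: np.ndarray,
    treatment: np.ndarray,
    area: np.ndarray,
    group_labels,
    null_model: bool = False,
    start: np.ndarray | None = None,
    sigma_fixed: float | None = None,
    refine: bool = True,
) -> PoissonGlmmFit:
    """Maximum (Laplace) likelihood fit of the treatment-by-area count model."""
    y = np.asarray(y, dtype=np.float64)
    It = np.asarray(treatment, dtype=np.float64)
    area = np.asarray(area, dtype=np.float64)
    if np.any(area <= 0):
        raise ValueError("areas must be positive")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    order, starts, n_groups = _prepare_groups(group_labels)
    if n_groups < 2:
        raise ValueError("need at least two rats for the random intercept")
    if not null_model and (It.min() == It.max()):
        raise ValueError("full model needs both treatments present")
    ys = np.ascontiguousarray(y[order])
    Its = np.ascontiguousarray(It[order])
    areas = np.ascontiguousarray(area[order])
    lg = np.array([math.lgamma(v + 1.0) for v in ys])

    if null_model:
        X = np.column_stack([np.ones_like(areas), areas])
    else:
        X = np.column_stack([np.ones_like(areas), Its, areas, Its * areas])

    if sigma_fixed is None:

        def nll(p):
            eta = X @ p[:-1]
            return _poisson_laplace_nll(p, ys, eta, starts, lg)

    else:

        def nll(p):
            full = np.concatenate([p, [sigma_fixed]])
            eta = X @ p
            return _poisson_laplace_nll(full, ys, eta, starts, lg)

    if start is None:
        # crude start: least squares on log(y + 0.5)
        beta0, *_ = np.linalg.lstsq(X, np.log(ys + 0.5), rcond=None)
        start = np.concatenate([beta0, [0.3]])
        if sigma_fixed is not None:
            start = start[:-1]
    bounds = [(None, None)] * (len(start) - (0 if sigma_fixed is not None else 1))
    if sigma_fixed is None:
        bounds = bounds + [(1e-8, None)]  # keep sigma off the |.| kink at 0
    res = optimize.minimize(
        nll, start, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 300},
    )
    if refine:
        # derivative-free polish guards against rare L-BFGS-B stalls
        res2 = optimize.minimize(
            nll,
            res.x,
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-9, "fatol": 1e-12},
        )
        if res2.fun <= res.fun:
            res = res2
    p = res.x
    sigma = abs(p[-1]) if sigma_fixed is None else float(sigma_fixed)
    betas = p[:-1] if sigma_fixed is None else p
    if null_model:
        alpha = np.array([betas[0], 0.0, betas[1], 0.0])
    else:
        alpha = np.asarray(betas[:4], dtype=float).copy()
    return PoissonGlmmFit(
        alpha=alpha,
        sigma_rat=sigma,
        loglik=-res.fun,
        converged=bool(res.success or res.fun < np.inf),
        null_model=null_model,
        n_groups=n_groups,
    )


# ---------------------------------------------------------------------------
# Binomial GLMM, nested rat / cell random intercepts
# ---------------------------------------------------------------------------


def _binom_laplace_ll(beta, sd, X, Z, succ, fail, re_kind):
    """Laplace-approximate marginal log-likelihood.

    ``re_kind`` maps each random-effect column to its variance component
    (0 = rat, 1 = cell).  Components with sd ~ 0 are dropped exactly.
    """
    active = sd[re_kind] > 1e-8
    Za = Z[:, active]
    prior_var = (sd[re_kind][active]) ** 2
    q = Za.shape[1]
    if q == 0:
        eta = X @ beta
        return float(succ @ eta - (succ + fail) @ np.logaddexp(0.0, eta))
    prior_prec = 1.0 / prior_var
    u = np.zeros(q)
    for _ in range(100):  # Newton on the penalized log-likelihood
        eta = X @ beta + Za @ u
        mu = expit(eta)
        w = (succ + fail) * mu * (1.0 - mu)
        grad = Za.T @ (succ - (succ + fail) * mu) - prior_prec * u
        H = (Za.T * w) @ Za + np.diag(prior_prec)
        step = np.linalg.solve(H, grad)
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta + Za @ u
    ll = float(succ @ eta - (succ + fail) @ np.logaddexp(0.0, eta))
    pen = 0.5 * float(u @ (prior_prec * u))
    mu = expit(eta)
    w = (succ + fail) * mu * (1.0 - mu)
    H = (Za.T * w) @ Za + np.diag(prior_prec)
    sign, logdet = np.linalg.slogdet(H)
    return (
        ll
        - pen
        + 0.5 * float(np.sum(np.log(prior_prec)))
        - 0.5 * logdet
    )


@dataclass
class BinomialGlmmFit:
    coef: np.ndarray  # (intercept, condition effect)
    se_condition: float
    p_condition: float
    sigma_rat: float
    sigma_cell: float
    loglik: float
    separation: bool
    converged: bool


def fit_binomial_glmm(
    successes,
    failures,
    condition,
    rat_ids,
    cell_ids,
    fit_variances: bool = True,
) -> BinomialGlmmFit:
    """Logistic mixed model of success probability on condition.

    One row per cell x condition; random intercepts for rat and for cell
    (cells nested in rats).  Returns the Wald test of the condition fixed
    effect.  With ``fit_variances=False`` both variance components are fixed
    at zero and the fit coincides with plain logistic regression.
    """
    succ = np.asarray(successes, dtype=float)
    fail = np.asarray(failures, dtype=float)
    cond = np.asarray(condition, dtype=float)
    if np.any(succ < 0) or np.any(fail < 0):
        raise ValueError("successes and failures must be non-negative")
    tot = succ + fail
    if succ.sum() == 0 or fail.sum() == 0:
        return BinomialGlmmFit(
            coef=np.array([np.nan, np.nan]),
            se_condition=np.nan,
            p_condition=np.nan,
            sigma_rat=np.nan,
            sigma_cell=np.nan,
            loglik=np.nan,
            separation=True,
            converged=False,
        )
    if len(np.unique(cond)) < 2:
        raise ValueError("both conditions must be present")
    rats, rat_code = np.unique(np.asarray(rat_ids), return_inverse=True)
    cells, cell_code = np.unique(np.asarray(cell_ids), return_inverse=True)
    if len(cells) < 2:
        raise ValueError("need at least two cells")
    n = len(succ)
    X = np.column_stack([np.ones(n), cond])
    Zr = np.zeros((n, len(rats)))
    Zr[np.arange(n), rat_code] = 1.0
    Zc = np.zeros((n, len(cells)))
    Zc[np.arange(n), cell_code] = 1.0
    Z = np.hstack([Zr, Zc])
    re_kind = np.concatenate(
        [np.zeros(len(rats), dtype=int), np.ones(len(cells), dtype=int)]
    )

    def nll(p):
        beta = p[:2]
        sd = np.abs(p[2:4]) if fit_variances else np.zeros(2)
        return -_binom_laplace_ll(beta, sd, X, Z, succ, fail, re_kind)

    # start from the pooled empirical logits
    p1 = np.clip(succ.sum() / tot.sum(), 1e-6, 1 - 1e-6)
    start = np.array([math.log(p1 / (1 - p1)), 0.0, 0.3, 0.3])
    if not fit_variances:
        start = start[:2]

        def nll(p):  # noqa: F811 - fixed-variance objective
            return -_binom_laplace_ll(
                p, np.zeros(2), X, Z, succ, fail, re_kind
            )

    res = optimize.minimize(
        nll, start, method="Nelder-Mead",
        options={"maxiter": 6000, "xatol": 1e-8, "fatol": 1e-10},
    )
    res = optimize.minimize(
        nll, res.x, method="Nelder-Mead",
        options={"maxiter": 3000, "xatol": 1e-9, "fatol": 1e-11},
    )
    p = res.x
    beta = p[:2]
    sd = np.abs(p[2:4]) if fit_variances else np.zeros(2)

    # Wald SE for the condition effect from the numerical Hessian of the
    # profile over the fixed effects (variances held at their estimates)
    def nll_beta(b):
        return -_binom_laplace_ll(b, sd, X, Z, succ, fail, re_kind)

    h = 1e-4
    H = np.zeros((2, 2))
    f0 = nll_beta(beta)
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i] = h
            ej[j] = h
            fij = nll_beta(beta + ei + ej)
            fi = nll_beta(beta + ei)
            fj = nll_beta(beta + ej)
            H[i, j] = H[j, i] = (fij - fi - fj + f0) / (h * h)
    try:
        cov = np.linalg.inv(H)
        se = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se = np.nan
    from scipy.stats import norm

    z = beta[1] / se if se and se > 0 else np.nan
    pval = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return BinomialGlmmFit(
        coef=beta,
        se_condition=se,
        p_condition=pval,
        sigma_rat=float(sd[0]),
        sigma_cell=float(sd[1]),
        loglik=-res.fun,
        separation=False,
        converged=bool(res.success),
    )
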