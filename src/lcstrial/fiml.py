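"""Full-information maximum likelihood (FIML) estimation for moment-structured
models over multivariate-normal data with arbitrary missingness.

The casewise likelihood of each record is the normal density of its observed
sub-vector under the corresponding sub-mean and sub-covariance, which is the
correct observed-data likelihood under MAR.  Records are grouped by
missingness pattern so the log-likelihood reduces to pattern-level sufficient
statistics (count, mean, ML scatter) and is cheap to evaluate repeatedly
inside an optimizer.

The module provides:

* :func:`fiml_loglik` — observed-data log-likelihood of a mean/covariance.
* :func:`fit_saturated` — EM estimation of unstructured per-group moments.
* :func:`fit_independence` — free means/variances, zero covariances.
* :func:`fit_model` — quasi-Newton FIML maximization of any
  :class:`MomentModel`, with observed-information standard errors.
* :func:`standardize` — delta-method standardized solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

LOG_2PI = float(np.log(2.0 * np.pi))


class NumericError(RuntimeError):
    """Raised when a likelihood evaluation is numerically impossible."""


# ---------------------------------------------------------------------------
# Missingness patterns
# ---------------------------------------------------------------------------


@dataclass
class MissingnessPattern:
    """One observed-variable pattern with its pattern-level sufficient stats."""

    observed: np.ndarray  # indices of observed variables
    rows: np.ndarray  # row indices of member records
    n: int
    mean: np.ndarray  # pattern mean of the observed sub-vector
    scatter: np.ndarray  # ML covariance (divisor n) of the observed sub-vector


def extract_patterns(y: np.ndarray) -> tuple[list[MissingnessPattern], int]:
    """Partition the rows of ``y`` (NaN = missing) into missingness patterns.

    Returns the patterns and the number of rows with no observed variable at
    all (these carry no likelihood information and are excluded).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError("data must be a 2-D array of shape (n_records, n_variables)")
    mask = ~np.isnan(y)
    n_empty = int(np.sum(~mask.any(axis=1)))
    patterns: list[MissingnessPattern] = []
    # Encode each row's mask as bytes for grouping.
    codes = np.packbits(mask, axis=1)
    order = np.lexsort(codes.T[::-1])
    sorted_codes = codes[order]
    boundaries = np.any(sorted_codes[1:] != sorted_codes[:-1], axis=1)
    starts = np.concatenate([[0], np.nonzero(boundaries)[0] + 1, [len(order)]])
    for a, b in zip(starts[:-1], starts[1:]):
        rows = order[a:b]
        obs = np.nonzero(mask[rows[0]])[0]
        if obs.size == 0:
            continue
        sub = y[np.ix_(rows, obs)]
        mean = sub.mean(axis=0)
        d = sub - mean
        scatter = d.T @ d / len(rows)
        patterns.append(
            MissingnessPattern(
                observed=obs, rows=rows, n=len(rows), mean=mean, scatter=scatter
            )
        )
    return patterns, n_empty


def _pattern_loglik(pat: MissingnessPattern, mean: np.ndarray, cov: np.ndarray) -> float:
    o = pat.observed
    sub_cov = cov[np.ix_(o, o)]
    sign, logdet = np.linalg.slogdet(sub_cov)
    if sign <= 0:
        raise NumericError(
            f"singular observed sub-covariance for pattern {o.tolist()}"
        )
    inv = np.linalg.inv(sub_cov)
    d = pat.mean - mean[o]
    maha = float(d @ inv @ d)
    k = o.size
    return -0.5 * pat.n * (
        k * LOG_2PI + logdet + float(np.sum(inv * pat.scatter)) + maha
    )


def _ll_and_moment_grads(pattern_sets: list, moments: list):
    """Total log-likelihood plus its gradient w.r.t. each group's (mean, cov).

    The closed forms are, per pattern with observed block o,
    d ll / d mu_o = n * S_o^{-1} (ybar - mu_o) and
    d ll / d Sigma_o = n/2 * (S_o^{-1} M S_o^{-1} - S_o^{-1}) with
    M = scatter + dd', scattered back into the full matrices.
    """
    ll = 0.0
    grads = []
    for pats, (mean, cov) in zip(pattern_sets, moments):
        p = mean.size
        gmu = np.zeros(p)
        gcov = np.zeros((p, p))
        for pat in pats:
            o = pat.observed
            ix = np.ix_(o, o)
            sub = cov[ix]
            sign, logdet = np.linalg.slogdet(sub)
            if sign <= 0:
                raise NumericError(
                    f"singular observed sub-covariance for pattern {o.tolist()}"
                )
            inv = np.linalg.inv(sub)
            d = pat.mean - mean[o]
            invd = inv @ d
            m = pat.scatter + np.outer(d, d)
            ll += -0.5 * pat.n * (
                o.size * LOG_2PI + logdet + float(np.sum(inv * m))
            )
            gmu[o] += pat.n * invd
            gcov[ix] += 0.5 * pat.n * (inv @ m @ inv - inv)
        grads.append((gmu, gcov))
    return ll, grads


def fiml_loglik(y, mean: np.ndarray, cov: np.ndarray) -> float:
    """Observed-data log-likelihood of (``mean``, ``cov``) for data ``y``.

    ``y`` is an (n, p) array with NaN marking missing cells, or a list of
    precomputed :class:`MissingnessPattern`.  Records with every variable
    missing contribute zero.  On complete data this equals the ordinary joint
    normal log-likelihood.
    """
    if isinstance(y, list) and (not y or isinstance(y[0], MissingnessPattern)):
        patterns = y
    else:
        patterns, _ = extract_patterns(np.asarray(y, dtype=float))
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    return float(sum(_pattern_loglik(p, mean, cov) for p in patterns))


# ---------------------------------------------------------------------------
# Saturated and independence reference fits
# ---------------------------------------------------------------------------


def em_saturated(
    y: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """EM estimate of the unstructured mean and covariance under missingness.

    Returns ``(mean, cov, loglik, converged, n_iter)``.  Convergence is
    declared when the relative log-likelihood change drops below ``tol``.
    """
    y = np.asarray(y, dtype=float)
    patterns, _ = extract_patterns(y)
    if not patterns:
        raise ValueError("no records with observed data")
    p = y.shape[1]
    n = sum(pat.n for pat in patterns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nan_to_num(np.nanmean(y, axis=0))
        var = np.nanvar(y, axis=0)
    var = np.where(np.isfinite(var) & (var > 1e-12), var, 1.0)
    sigma = np.diag(var)

    last_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for pat in patterns:
            o = pat.observed
            m = np.setdiff1d(np.arange(p), o, assume_unique=True)
            # Second moment of the observed block around zero.
            ex_o = pat.mean
            exx_oo = pat.scatter + np.outer(ex_o, ex_o)
            if m.size == 0:
                s1[o] += pat.n * ex_o
                s2[np.ix_(o, o)] += pat.n * exx_oo
                continue
            s_oo = sigma[np.ix_(o, o)]
            s_mo = sigma[np.ix_(m, o)]
            c, low = linalg.cho_factor(s_oo, lower=True)
            b = linalg.cho_solve((c, low), s_mo.T).T  # regression of missing on obs
            cond_cov = sigma[np.ix_(m, m)] - b @ s_mo.T
            ex_m = mu[m] + b @ (ex_o - mu[o])
            # E[x_m x_o'] = cond mean outer + B * Cov(x_o) pattern-level
            cov_oo = pat.scatter
            exm_xo = np.outer(ex_m, ex_o) + b @ cov_oo
            exm_xm = (
                cond_cov
                + np.outer(ex_m, ex_m)
                + b @ cov_oo @ b.T
            )
            s1[o] += pat.n * ex_o
            s1[m] += pat.n * ex_m
            s2[np.ix_(o, o)] += pat.n * exx_oo
            s2[np.ix_(m, o)] += pat.n * exm_xo
            s2[np.ix_(o, m)] += pat.n * exm_xo.T
            s2[np.ix_(m, m)] += pat.n * exm_xm
        mu = s1 / n
        sigma = s2 / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        ll = fiml_loglik(patterns, mu, sigma)
        if np.isfinite(last_ll) and abs(ll - last_ll) <= tol * (abs(last_ll) + 1.0):
            last_ll = ll
            converged = True
            break
        last_ll = ll
    return mu, sigma, float(last_ll), converged, it


@dataclass
class FitResult:
    """Outcome of a FIML fit.

    ``names``/``estimates``/``se`` describe the natural (interpretable)
    parameter vector; ``param_cov`` is its observed-information covariance.
    """

    model_label: str
    names: list
    estimates: np.ndarray
    se: np.ndarray | None
    loglik: float
    converged: bool
    n_used: list
    n_params: int
    gradient_norm: float
    group_moments: list  # per-group (mean, cov) implied at the optimum
    param_cov: np.ndarray | None = None
    warnings: list = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return int(sum(self.n_used))

    def pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values from the normal reference."""
        if self.se is None:
            raise ValueError("fit has no standard errors")
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.estimates / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def to_dict(self) -> dict:
        out = {
            "model": self.model_label,
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "n_used": [int(n) for n in self.n_used],
            "n_params": int(self.n_params),
            "gradient_norm": float(self.gradient_norm),
            "parameters": [
                {
                    "name": str(nm),
                    "estimate": float(est),
                    "se": (None if self.se is None else float(s)),
                }
                for nm, est, s in zip(
                    self.names,
                    self.estimates,
                    self.se if self.se is not None else np.full(len(self.names), np.nan),
                )
            ],
            "warnings": list(self.warnings),
        }
        if self.se is not None:
            for entry, p in zip(out["parameters"], self.pvalues()):
                entry["p"] = float(p)
        return out


def _group_patterns(groups) -> tuple[list[list[MissingnessPattern]], list[int]]:
    pattern_sets, n_used = [], []
    for y in groups:
        pats, _ = extract_patterns(np.asarray(y, dtype=float))
        pattern_sets.append(pats)
        n_used.append(sum(p.n for p in pats))
    return pattern_sets, n_used


def fit_saturated(groups) -> FitResult:
    """Unstructured FIML means and covariances, one set per group (via EM)."""
    pattern_sets, n_used = _group_patterns(groups)
    moments, total_ll, conv = [], 0.0, True
    names: list[str] = []
    est: list[float] = []
    for g, y in enumerate(groups):
        mu, sigma, ll, ok, _ = em_saturated(np.asarray(y, dtype=float))
        moments.append((mu, sigma))
        total_ll += ll
        conv = conv and ok
        p = mu.size
        names += [f"g{g}.mean[{i}]" for i in range(p)]
        est += list(mu)
        names += [f"g{g}.cov[{i},{j}]" for i in range(p) for j in range(i + 1)]
        est += [sigma[i, j] for i in range(p) for j in range(i + 1)]
    return FitResult(
        model_label="saturated",
        names=names,
        estimates=np.array(est),
        se=None,
        loglik=total_ll,
        converged=conv,
        n_used=n_used,
        n_params=len(est),
        gradient_norm=0.0,
        group_moments=moments,
    )


def fit_independence(groups) -> FitResult:
    """Free per-variable means and variances, all covariances fixed at zero.

    Because the covariance matrix is diagonal the observed-data likelihood
    factorizes by variable, so the MLE is closed form: per-variable mean and
    ML variance over the records where that variable is observed.
    """
    names, est, moments, n_used = [], [], [], []
    total_ll = 0.0
    for g, y in enumerate(groups):
        y = np.asarray(y, dtype=float)
        p = y.shape[1]
        mu = np.empty(p)
        var = np.empty(p)
        for j in range(p):
            xj = y[:, j]
            xj = xj[~np.isnan(xj)]
            if xj.size < 2:
                raise ValueError(f"variable {j} in group {g} has <2 observed values")
            mu[j] = xj.mean()
            var[j] = xj.var()
        sigma = np.diag(var)
        moments.append((mu, sigma))
        pats, _ = extract_patterns(y)
        n_used.append(sum(pt.n for pt in pats))
        total_ll += fiml_loglik(pats, mu, sigma)
        names += [f"g{g}.mean[{i}]" for i in range(p)]
        est += list(mu)
        names += [f"g{g}.var[{i}]" for i in range(p)]
        est += list(var)
    return FitResult(
        model_label="independence",
        names=names,
        estimates=np.array(est),
        se=None,
        loglik=total_ll,
        converged=True,
        n_used=n_used,
        n_params=len(est),
        gradient_norm=0.0,
        group_moments=moments,
    )


# ---------------------------------------------------------------------------
# Structured model fitting
# ---------------------------------------------------------------------------


class MomentModel:
    """Interface a structured model must implement to be FIML-fittable.

    A model owns a *natural* parameter vector (interpretable means,
    variances, covariances, path coefficients) and a bijective *working*
    transformation used by the optimizer (log variances, Cholesky factors
    for free covariance blocks) that keeps implied moments well defined.
    """

    label: str = "model"
    #: True when the working parameterization guarantees evaluable implied
    #: moments everywhere, enabling the analytic moment-space gradient.
    smooth: bool = False

    def param_names(self) -> list:  # pragma: no cover - abstract
        raise NotImplementedError

    def implied(self, theta: np.ndarray) -> list:
        """Per-group (mean, cov) implied by natural parameters ``theta``."""
        raise NotImplementedError  # pragma: no cover

    def start(self, group_moments: list, n_used: list) -> np.ndarray:
        """Moment-based natural starting values from saturated estimates."""
        raise NotImplementedError  # pragma: no cover

    def to_working(self, theta: np.ndarray) -> np.ndarray:
        return np.asarray(theta, dtype=float).copy()

    def to_natural(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float).copy()


_PENALTY = 1e10


def fit_model(
    groups,
    model: MomentModel,
    start: np.ndarray | None = None,
    compute_se: bool = True,
    gtol: float = 1e-7,
    max_iter: int = 1000,
) -> FitResult:
    """Maximize the multigroup FIML likelihood of ``model`` over ``groups``.

    ``groups`` is a sequence of (n_g, p) arrays with NaN for missing cells.
    The objective is the average negative log-likelihood per record, so the
    gradient tolerance is on a per-observation scale.  Non-convergence is
    flagged on the result, not raised.  Standard errors come from the inverse
    of the observed information, differentiated numerically in the natural
    parameterization.
    """
    pattern_sets, n_used = _group_patterns(groups)
    n_total = sum(n_used)
    if n_total == 0:
        raise ValueError("no usable records in any group")

    def total_loglik(theta: np.ndarray) -> float:
        ll = 0.0
        for pats, (mean, cov) in zip(pattern_sets, model.implied(theta)):
            ll += fiml_loglik(pats, mean, cov)
        return ll

    def objective(z: np.ndarray) -> float:
        theta = model.to_natural(z)
        try:
            moments = model.implied(theta)
        except Exception:
            return _PENALTY
        ll = 0.0
        for pats, (mean, cov) in zip(pattern_sets, moments):
            try:
                ll += fiml_loglik(pats, mean, cov)
            except NumericError:
                eigmin = float(np.linalg.eigvalsh(cov).min())
                return _PENALTY * (1.0 + abs(min(eigmin, 0.0)))
        return -ll / n_total

    def _chain_grad(vec: np.ndarray, to_moments, step: float = 1e-6) -> np.ndarray:
        """Gradient of the scaled objective at ``vec`` via the analytic
        moment-space gradient chained with a central-difference Jacobian of
        the (cheap, data-free) implied-moment map."""
        moments = to_moments(vec)
        _, grads = _ll_and_moment_grads(pattern_sets, moments)
        k = vec.size
        out = np.empty(k)
        for i in range(k):
            h = step * max(abs(vec[i]), 1.0)
            vp, vm = vec.copy(), vec.copy()
            vp[i] += h
            vm[i] -= h
            mp, mm = to_moments(vp), to_moments(vm)
            acc = 0.0
            for (gmu, gcov), (mu_p, cov_p), (mu_m, cov_m) in zip(grads, mp, mm):
                acc += float(gmu @ (mu_p - mu_m)) + float(
                    np.sum(gcov * (cov_p - cov_m))
                )
            out[i] = -acc / (2.0 * h) / n_total
        return out

    jac = None
    if model.smooth:
        jac = lambda z: _chain_grad(z, lambda v: model.implied(model.to_natural(v)))  # noqa: E731

    if start is None:
        sat_moments = []
        for y in groups:
            mu, sigma, _, _, _ = em_saturated(np.asarray(y, dtype=float))
            sat_moments.append((mu, sigma))
        theta0 = model.start(sat_moments, n_used)
    else:
        theta0 = np.asarray(start, dtype=float)
    z0 = model.to_working(theta0)

    res = optimize.minimize(
        objective, z0, jac=jac, method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    # One polishing restart helps when BFGS stops on a stale Hessian estimate.
    if not res.success:
        res2 = optimize.minimize(
            objective, res.x, jac=jac, method="BFGS",
            options={"gtol": gtol, "maxiter": max_iter},
        )
        if res2.fun <= res.fun:
            res = res2

    theta_hat = model.to_natural(res.x)
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    converged = bool(res.success or grad_norm < 1e-4)
    ll_hat = total_loglik(theta_hat)
    warn: list[str] = []
    if not converged:
        warn.append(f"optimizer did not converge: {res.message}")

    se = None
    param_cov = None
    if compute_se:
        if model.smooth:
            # Hessian as the finite difference of the analytic gradient,
            # in the natural parameterization.
            grad_nat = lambda t: n_total * _chain_grad(t, model.implied)  # noqa: E731
            hess = _hessian_from_grad(grad_nat, theta_hat)
        else:
            hess = _numerical_hessian(lambda t: -total_loglik(t), theta_hat)
        try:
            param_cov = linalg.inv(hess)
            diag = np.diag(param_cov).copy()
            if np.any(diag < 0):
                warn.append("observed information not positive definite")
                diag[diag < 0] = np.nan
            se = np.sqrt(diag)
        except linalg.LinAlgError:
            warn.append("observed information singular; SEs unavailable")

    names = model.param_names()
    # Boundary variance check: any natural parameter named like a variance
    # that collapsed to ~0 deserves a flag.
    for nm, val in zip(names, theta_hat):
        if ("var" in str(nm)) and val < 1e-8:
            warn.append(f"variance parameter {nm} on the zero boundary")

    return FitResult(
        model_label=model.label,
        names=names,
        estimates=theta_hat,
        se=se,
        loglik=float(ll_hat),
        converged=converged,
        n_used=n_used,
        n_params=len(names),
        gradient_norm=grad_norm,
        group_moments=model.implied(theta_hat),
        param_cov=param_cov,
        warnings=warn,
    )


def _hessian_from_grad(grad, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Jacobian of a gradient function, symmetrized."""
    x = np.asarray(x, dtype=float)
    k = x.size
    hess = np.empty((k, k))
    for i in range(k):
        h = rel_step * max(abs(x[i]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        hess[i] = (grad(xp) - grad(xm)) / (2.0 * h)
    return 0.5 * (hess + hess.T)


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    hess = np.empty((k, k))
    f0 = f(x)
    # Diagonal terms.
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (
                fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm
            ) / (2.0 * h[i] * h[j])
    return hess


def standardize(fit: FitResult, std_map, names: list | None = None):
    """Delta-method standardized solution.

    ``std_map`` maps the natural parameter vector to the standardized
    quantities of interest (an array-valued callable); the Jacobian is taken
    numerically and propagated through ``fit.param_cov``.  Returns
    ``(values, ses)``; ``ses`` is None when the fit carries no covariance.
    """
    theta = fit.estimates
    vals = np.asarray(std_map(theta), dtype=float)
    if fit.param_cov is None:
        return vals, None
    k = theta.size
    jac = np.empty((vals.size, k))
    h = 1e-6 * np.maximum(np.abs(theta), 1.0)
    for i in range(k):
        e = np.zeros(k)
        e[i] = h[i]
        jac[:, i] = (np.asarray(std_map(theta + e)) - np.asarray(std_map(theta - e))) / (
            2.0 * h[i]
        )
    cov = jac @ fit.param_cov @ jac.T
    diag = np.diag(cov).copy()
    diag[diag < 0] = np.nan
    return vals, np.sqrt(diag)
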