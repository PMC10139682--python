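"""Fittable multigroup model classes for the univariate LCS and the 2W-LCS.

Each class maps a flat *natural* parameter vector (the interpretable
estimates a report prints) to per-group model-implied moments, provides
moment-based starting values, and defines the working transformation used by
the optimizer: log scale for variances and Cholesky factors for free
covariance blocks, which keeps every implied covariance positive definite
without constrained optimization.
"""

from __future__ import annotations

import numpy as np

from .fiml import MomentModel
from .lcs import (
    C2C_PAIRS,
    CROSS_LAGGED_PAIRS,
    INSTRUMENTS,
    RESID_COV_PAIRS,
    ConstraintMap,
    LcsParams,
    TwoWaveParams,
    implied_moments_2w,
    implied_moments_univariate,
    two_wave_constraints,
    univariate_constraints,
)

_TRI5 = [(i, j) for i in range(5) for j in range(i + 1)]  # lower-tri order
_TRI5_R = np.array([i for i, _ in _TRI5])
_TRI5_C = np.array([j for _, j in _TRI5])
_CROSS_R = np.array([i for i, _ in CROSS_LAGGED_PAIRS])
_CROSS_C = np.array([j for _, j in CROSS_LAGGED_PAIRS])
_C2C_R = np.array([i for i, _ in C2C_PAIRS])
_C2C_C = np.array([j for _, j in C2C_PAIRS])
_RESID_R = np.array([i for i, _ in RESID_COV_PAIRS])
_RESID_C = np.array([j for _, j in RESID_COV_PAIRS])


class _Layout:
    """Flat-vector layout of multigroup parameter blocks.

    Blocks flagged group-equal get one copy; free blocks get one copy per
    group.  Entries are (block, group index or None, slice into theta).
    """

    def __init__(self, blocks, n_groups: int, group_labels):
        self.n_groups = n_groups
        self.group_labels = list(group_labels)
        self.entries = []
        pos = 0
        for name, size, equal in blocks:
            if equal:
                self.entries.append((name, None, slice(pos, pos + size)))
                pos += size
            else:
                for g in range(n_groups):
                    self.entries.append((name, g, slice(pos, pos + size)))
                    pos += size
        self.size = pos
        self._index = {}
        for name, g, sl in self.entries:
            self._index[(name, g)] = sl

    def get(self, theta: np.ndarray, block: str, g: int) -> np.ndarray:
        sl = self._index.get((block, g), self._index.get((block, None)))
        return theta[sl]

    def slot(self, block: str, g) -> slice:
        return self._index[(block, g)]

    def names(self, element_names: dict) -> list:
        out = []
        for block, g, sl in self.entries:
            suffix = "" if g is None else f"[{self.group_labels[g]}]"
            for el in element_names[block]:
                out.append(f"{block}{'.' if el else ''}{el}{suffix}")
        return out


class UnivariateLcsModel(MomentModel):
    """Multigroup univariate latent change score model.

    Natural parameters: shared baseline mean ``mu0``; per-group baseline
    variance ``var0``; change mean/variance/baseline-covariance
    (``mu_delta``, ``var_delta``, ``cov0_delta``) either shared (constrained
    model) or per group (unconstrained).  With one group all parameters are
    single copies and the model is saturated (5 parameters, 5 moments).
    """

    def __init__(
        self,
        constraints: ConstraintMap | None = None,
        n_groups: int = 2,
        group_labels=None,
        instrument: str = "",
    ):
        if constraints is None:
            constraints = univariate_constraints(False)
        self.constraints = constraints
        self.n_groups = n_groups
        self.instrument = instrument
        labels = group_labels or [f"g{i}" for i in range(n_groups)]
        eq = constraints.is_equal if n_groups > 1 else (lambda b: b == "mu0")
        if n_groups == 1:
            eq = lambda b: True  # noqa: E731 - single group: one copy of everything
        blocks = [
            ("mu0", 1, True),
            ("var0", 1, n_groups == 1),
            ("mu_delta", 1, eq("mu_delta")),
            ("var_delta", 1, eq("var_delta")),
            ("cov0_delta", 1, eq("cov0_delta")),
        ]
        self.layout = _Layout(blocks, n_groups, labels)
        self.label = f"univariate-{constraints.label}" + (
            f"-{instrument}" if instrument else ""
        )

    def param_names(self) -> list:
        return self.layout.names({b: [""] for b, _, _ in [
            ("mu0", 1, 0), ("var0", 1, 0), ("mu_delta", 1, 0),
            ("var_delta", 1, 0), ("cov0_delta", 1, 0)]})

    def group_params(self, theta: np.ndarray, g: int) -> LcsParams:
        lay = self.layout
        return LcsParams(
            mu0=float(lay.get(theta, "mu0", g)[0]),
            var0=float(lay.get(theta, "var0", g)[0]),
            mu_delta=float(lay.get(theta, "mu_delta", g)[0]),
            var_delta=float(lay.get(theta, "var_delta", g)[0]),
            cov0_delta=float(lay.get(theta, "cov0_delta", g)[0]),
        )

    def implied(self, theta: np.ndarray) -> list:
        return [
            implied_moments_univariate(self.group_params(theta, g))
            for g in range(self.n_groups)
        ]

    def start(self, group_moments: list, n_used: list) -> np.ndarray:
        w = np.asarray(n_used, dtype=float)
        w = w / w.sum()
        per_group = []
        for mu, s in group_moments:
            per_group.append(
                {
                    "mu0": mu[0],
                    "var0": s[0, 0],
                    "mu_delta": mu[1] - mu[0],
                    "var_delta": max(s[1, 1] + s[0, 0] - 2.0 * s[0, 1], 1e-6),
                    "cov0_delta": s[0, 1] - s[0, 0],
                }
            )
        theta = np.empty(self.layout.size)
        for block, g, sl in self.layout.entries:
            if g is None:
                theta[sl] = float(sum(wg * pg[block] for wg, pg in zip(w, per_group)))
            else:
                theta[sl] = per_group[g][block]
        return theta

    def _var_mask(self) -> np.ndarray:
        mask = np.zeros(self.layout.size, dtype=bool)
        for block, g, sl in self.layout.entries:
            if block in ("var0", "var_delta"):
                mask[sl] = True
        return mask

    def to_working(self, theta: np.ndarray) -> np.ndarray:
        z = np.asarray(theta, dtype=float).copy()
        m = self._var_mask()
        z[m] = np.log(np.maximum(z[m], 1e-10))
        return z

    def to_natural(self, z: np.ndarray) -> np.ndarray:
        theta = np.asarray(z, dtype=float).copy()
        m = self._var_mask()
        theta[m] = np.exp(theta[m])
        return theta

    def extract(self, fit, block: str, g: int):
        """(estimate, se, p) for one block in one group, honoring sharing."""
        sl = self.layout._index.get((block, g), self.layout._index.get((block, None)))
        est = float(fit.estimates[sl][0])
        se = None if fit.se is None else float(fit.se[sl][0])
        p = None if fit.se is None else float(fit.pvalues()[sl][0])
        return est, se, p


# ---------------------------------------------------------------------------
# Two-wave five-variable model
# ---------------------------------------------------------------------------


_TRIL_CACHE: dict = {}


def _tril_ix(k: int):
    if k not in _TRIL_CACHE:
        r, c = np.tril_indices(k)
        _TRIL_CACHE[k] = (r, c, r == c)
    return _TRIL_CACHE[k]


def _chol_to_flat(L: np.ndarray) -> np.ndarray:
    """Lower-tri Cholesky -> working vector with log diagonal."""
    r, c, diag = _tril_ix(L.shape[0])
    v = L[r, c].copy()
    v[diag] = np.log(v[diag])
    return v


def _flat_to_chol(v: np.ndarray, k: int) -> np.ndarray:
    r, c, diag = _tril_ix(k)
    vals = np.asarray(v, dtype=float).copy()
    vals[diag] = np.exp(vals[diag])
    L = np.zeros((k, k))
    L[r, c] = vals
    return L


def _nearest_pd(a: np.ndarray, floor_frac: float = 1e-4) -> np.ndarray:
    """Clip eigenvalues to a small positive floor (for starting values only)."""
    a = 0.5 * (a + a.T)
    w, v = np.linalg.eigh(a)
    floor = floor_frac * max(float(np.mean(np.abs(np.diag(a)))), 1e-8)
    w = np.maximum(w, floor)
    return v @ np.diag(w) @ v.T


def _psi_to_vec(psi: np.ndarray) -> np.ndarray:
    """Residual-covariance matrix -> natural vector (5 variances, 4 covariances)."""
    return np.concatenate(
        [np.diag(psi), [psi[i, j] for i, j in RESID_COV_PAIRS]]
    )


def _vec_to_psi(v: np.ndarray) -> np.ndarray:
    psi = np.diag(v[:5]).astype(float)
    for (i, j), c in zip(RESID_COV_PAIRS, v[5:]):
        psi[i, j] = psi[j, i] = c
    return psi


class TwoWaveLcsModel(MomentModel):
    """Multigroup five-variable two-wave latent change score model.

    The constraint map is one of the nested sequence A (everything
    group-equal) through D (LCS, cross-lagged and change-to-change blocks all
    free).  Baseline means are always shared across groups; baseline
    covariances always free.
    """

    smooth = True  # Cholesky working parameters keep implied moments PSD

    def __init__(self, constraints: ConstraintMap | str = "D", group_labels=None):
        if isinstance(constraints, str):
            constraints = two_wave_constraints(constraints)
        self.constraints = constraints
        self.n_groups = 2
        labels = group_labels or ["g0", "g1"]
        eq = constraints.is_equal
        if eq("change_resid_var") != eq("change_resid_cov"):
            raise ValueError("residual variances and covariances must share a flag")
        self._blocks = [
            ("baseline_mean", 5, True),
            ("baseline_cov", 15, False),
            ("change_intercepts", 5, eq("change_intercepts")),
            ("gamma_self", 5, eq("gamma_self")),
            ("change_resid", 9, eq("change_resid_var")),  # 5 var + 4 cov
            ("gamma_cross", 12, eq("gamma_cross")),
            ("beta_c2c", 6, eq("beta_c2c")),
        ]
        self.layout = _Layout(self._blocks, 2, labels)
        self.label = f"2wlcs-{constraints.label}"

    def param_names(self) -> list:
        element_names = {
            "baseline_mean": [f"mu0.{v}" for v in INSTRUMENTS],
            "baseline_cov": [
                f"cov0.{INSTRUMENTS[i]}.{INSTRUMENTS[j]}" for i, j in _TRI5
            ],
            "change_intercepts": [f"alpha.{v}" for v in INSTRUMENTS],
            "gamma_self": [f"self.{v}" for v in INSTRUMENTS],
            "change_resid": [f"psi.{v}" for v in INSTRUMENTS]
            + [f"psi.{INSTRUMENTS[i]}.{INSTRUMENTS[j]}" for i, j in RESID_COV_PAIRS],
            "gamma_cross": [
                f"cross.{INSTRUMENTS[j]}0->d{INSTRUMENTS[i]}"
                for i, j in CROSS_LAGGED_PAIRS
            ],
            "beta_c2c": [
                f"c2c.d{INSTRUMENTS[j]}->d{INSTRUMENTS[i]}" for i, j in C2C_PAIRS
            ],
        }
        out = []
        for block, g, sl in self.layout.entries:
            suffix = "" if g is None else f"[{self.layout.group_labels[g]}]"
            for el in element_names[block]:
                out.append(el + suffix)
        return out

    def group_params(self, theta: np.ndarray, g: int) -> TwoWaveParams:
        lay = self.layout
        s0 = np.zeros((5, 5))
        for (i, j), val in zip(_TRI5, lay.get(theta, "baseline_cov", g)):
            s0[i, j] = s0[j, i] = val
        gamma_cross = np.zeros((5, 5))
        for (i, j), val in zip(CROSS_LAGGED_PAIRS, lay.get(theta, "gamma_cross", g)):
            gamma_cross[i, j] = val
        beta = np.zeros((5, 5))
        for (i, j), val in zip(C2C_PAIRS, lay.get(theta, "beta_c2c", g)):
            beta[i, j] = val
        return TwoWaveParams(
            baseline_mean=lay.get(theta, "baseline_mean", g),
            baseline_cov=s0,
            change_intercepts=lay.get(theta, "change_intercepts", g),
            gamma_self=lay.get(theta, "gamma_self", g),
            gamma_cross=gamma_cross,
            beta_c2c=beta,
            change_resid_cov=_vec_to_psi(lay.get(theta, "change_resid", g)),
        )

    def implied(self, theta: np.ndarray) -> list:
        # Hot path: computed directly from indexed slices without the
        # validated dataclass, since the optimizer calls this thousands of
        # times per fit.  group_params() is the checked, user-facing view.
        out = []
        lay = self.layout
        eye = np.eye(5)
        for g in range(2):
            mu0 = lay.get(theta, "baseline_mean", g)
            s0 = np.zeros((5, 5))
            vals = lay.get(theta, "baseline_cov", g)
            s0[_TRI5_R, _TRI5_C] = vals
            s0[_TRI5_C, _TRI5_R] = vals
            G = np.diag(lay.get(theta, "gamma_self", g))
            G[_CROSS_R, _CROSS_C] = lay.get(theta, "gamma_cross", g)
            A = eye.copy()
            A[_C2C_R, _C2C_C] = lay.get(theta, "beta_c2c", g)  # I + B
            resid = lay.get(theta, "change_resid", g)
            psi = np.diag(resid[:5]).astype(float)
            psi[_RESID_R, _RESID_C] = resid[5:]
            psi[_RESID_C, _RESID_R] = resid[5:]
            a = lay.get(theta, "change_intercepts", g)
            mean_d = A @ (a + G @ mu0)
            gs0 = G @ s0
            c0d = gs0.T @ A.T
            cov_d = A @ (gs0 @ G.T + psi) @ A.T
            mean = np.concatenate([mu0, mu0 + mean_d])
            cov = np.empty((10, 10))
            cov[:5, :5] = s0
            cov[:5, 5:] = s0 + c0d
            cov[5:, :5] = cov[:5, 5:].T
            cov[5:, 5:] = s0 + c0d + c0d.T + cov_d
            out.append((mean, cov))
        return out

    def start(self, group_moments: list, n_used: list) -> np.ndarray:
        w = np.asarray(n_used, dtype=float)
        w = w / w.sum()
        per_group = []
        for mu, s in group_moments:
            s0 = _nearest_pd(s[:5, :5])
            c0d = s[:5, 5:] - s0  # Cov(X0, Delta)
            cov_d = s[5:, 5:] + s0 - s[:5, 5:] - s[5:, :5]
            mean_d = mu[5:] - mu[:5]
            g_full = np.linalg.solve(s0, c0d).T  # Delta-on-X0 regression matrix
            gamma_self = np.diag(g_full).copy()
            gamma_cross = np.zeros(12)
            G = np.diag(gamma_self)
            for k, (i, j) in enumerate(CROSS_LAGGED_PAIRS):
                gamma_cross[k] = g_full[i, j]
                G[i, j] = g_full[i, j]
            alpha = mean_d - G @ mu[:5]
            psi_raw = cov_d - G @ s0 @ G.T
            psi = np.zeros((5, 5))
            psi[np.ix_((0, 1), (0, 1))] = _nearest_pd(psi_raw[np.ix_((0, 1), (0, 1))])
            psi[np.ix_((2, 3, 4), (2, 3, 4))] = _nearest_pd(
                psi_raw[np.ix_((2, 3, 4), (2, 3, 4))]
            )
            per_group.append(
                {
                    "baseline_mean": mu[:5],
                    "baseline_cov": np.array([s0[i, j] for i, j in _TRI5]),
                    "change_intercepts": alpha,
                    "gamma_self": gamma_self,
                    "change_resid": _psi_to_vec(psi),
                    "gamma_cross": gamma_cross,
                    "beta_c2c": np.zeros(6),
                }
            )
        theta = np.empty(self.layout.size)
        for block, g, sl in self.layout.entries:
            if g is None:
                theta[sl] = sum(wg * np.asarray(pg[block]) for wg, pg in zip(w, per_group))
            else:
                theta[sl] = per_group[g][block]
        return theta

    # -- working transformation -------------------------------------------
    def to_working(self, theta: np.ndarray) -> np.ndarray:
        z = np.asarray(theta, dtype=float).copy()
        for block, g, sl in self.layout.entries:
            if block == "baseline_cov":
                s0 = np.zeros((5, 5))
                for (i, j), val in zip(_TRI5, theta[sl]):
                    s0[i, j] = s0[j, i] = val
                z[sl] = _chol_to_flat(np.linalg.cholesky(_nearest_pd(s0)))
            elif block == "change_resid":
                psi = _vec_to_psi(theta[sl])
                lo = np.linalg.cholesky(_nearest_pd(psi[np.ix_((0, 1), (0, 1))]))
                lp = np.linalg.cholesky(_nearest_pd(psi[np.ix_((2, 3, 4), (2, 3, 4))]))
                z[sl] = np.concatenate([_chol_to_flat(lo), _chol_to_flat(lp)])
        return z

    def to_natural(self, z: np.ndarray) -> np.ndarray:
        theta = np.asarray(z, dtype=float).copy()
        for block, g, sl in self.layout.entries:
            if block == "baseline_cov":
                L = _flat_to_chol(z[sl], 5)
                s0 = L @ L.T
                theta[sl] = [s0[i, j] for i, j in _TRI5]
            elif block == "change_resid":
                v = z[sl]
                lo = _flat_to_chol(v[:3], 2)
                lp = _flat_to_chol(v[3:], 3)
                psi = np.zeros((5, 5))
                psi[np.ix_((0, 1), (0, 1))] = lo @ lo.T
                psi[np.ix_((2, 3, 4), (2, 3, 4))] = lp @ lp.T
                theta[sl] = _psi_to_vec(psi)
        return theta

    # -- standardized solution --------------------------------------------
    def standardized_map(self):
        """Callable mapping natural theta to the standardized solution.

        Per group, in order: 10 baseline correlations (lower-tri order over
        variable pairs), 12 standardized cross-lagged paths, 3 + 1 change
        correlations (process pairs then EPDS-HADS), 6 standardized
        change-to-change paths.  Standardization uses model-implied SDs:
        baseline SDs for predictors at T0 and implied change-factor SDs.
        """

        def _map(theta: np.ndarray) -> np.ndarray:
            out = []
            for g in range(2):
                p = self.group_params(theta, g)
                s0 = p.baseline_cov
                sd0 = np.sqrt(np.diag(s0))
                _, _, cov_d = p.delta_moments()
                sdd = np.sqrt(np.diag(cov_d))
                for i, j in _TRI5:
                    if i != j:
                        out.append(s0[i, j] / (sd0[i] * sd0[j]))
                for i, j in CROSS_LAGGED_PAIRS:
                    out.append(p.gamma_cross[i, j] * sd0[j] / sdd[i])
                for i, j in RESID_COV_PAIRS:
                    out.append(cov_d[i, j] / (sdd[i] * sdd[j]))
                for i, j in C2C_PAIRS:
                    out.append(p.beta_c2c[i, j] * sdd[j] / sdd[i])
            return np.array(out)

        return _map

    def standardized_names(self) -> list:
        names = []
        for lab in self.layout.group_labels:
            for i, j in _TRI5:
                if i != j:
                    names.append(f"r0.{INSTRUMENTS[j]}.{INSTRUMENTS[i]}[{lab}]")
            for i, j in CROSS_LAGGED_PAIRS:
                names.append(f"std.cross.{INSTRUMENTS[j]}0->d{INSTRUMENTS[i]}[{lab}]")
            for i, j in RESID_COV_PAIRS:
                names.append(f"r.d{INSTRUMENTS[i]}.d{INSTRUMENTS[j]}[{lab}]")
            for i, j in C2C_PAIRS:
                names.append(f"std.c2c.d{INSTRUMENTS[j]}->d{INSTRUMENTS[i]}[{lab}]")
        return names
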