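"""Latent change score (LCS) parameterizations and implied moment structures.

A univariate LCS model for one variable measured at two waves fixes the
wave-2 score to the wave-1 score plus a latent change factor,

    X1 = X0 + Delta,

so the change itself carries a mean (``mu_delta``), a variance
(``var_delta``) and a covariance with the baseline level (``cov0_delta``).
The five-variable two-wave LCS (2W-LCS) couples the five instruments through
directed paths: own-baseline -> own-change (``gamma_self``), cross-lagged
baseline -> other-variable change (``gamma_cross``), and change -> change
paths from the three psychological-process instruments to the two adjustment
outcomes (``beta_c2c``).

Variable order is fixed throughout the package as
(EPDS, HADS_A, DERS_SF, SCS_SF, COMPACT), baselines first, then changes.
EPDS and HADS_A are the adjustment outcomes; the remaining three are the
psychological processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical instrument order used for every 5- or 10-dimensional array.
INSTRUMENTS = ("EPDS", "HADS_A", "DERS_SF", "SCS_SF", "COMPACT")
#: Indices of the adjustment outcomes within :data:`INSTRUMENTS`.
OUTCOME_IDX = (0, 1)
#: Indices of the psychological processes within :data:`INSTRUMENTS`.
PROCESS_IDX = (2, 3, 4)

#: Directed cross-lagged paths: (row = change of, col = baseline of).
#: Process baselines predict outcome changes and vice versa; no
#: outcome<->outcome or process<->process cross-lagged paths exist.
CROSS_LAGGED_PAIRS = tuple(
    [(o, p) for o in OUTCOME_IDX for p in PROCESS_IDX]
    + [(p, o) for p in PROCESS_IDX for o in OUTCOME_IDX]
)

#: Change-to-change paths: process change -> outcome change.
C2C_PAIRS = tuple((o, p) for o in OUTCOME_IDX for p in PROCESS_IDX)

#: Free residual covariance cells among the change factors: the three
#: process-process pairs plus the (EPDS, HADS_A) outcome pair.
RESID_COV_PAIRS = ((2, 3), (2, 4), (3, 4), (0, 1))


class ParameterError(ValueError):
    """Raised when a parameter set implies an invalid (non-PSD) structure."""


@dataclass(frozen=True)
class LcsParams:
    """Univariate LCS parameters for one variable in one group."""

    mu0: float
    var0: float
    mu_delta: float
    var_delta: float
    cov0_delta: float

    def __post_init__(self) -> None:
        if self.var0 <= 0:
            raise ParameterError(f"baseline variance must be > 0, got {self.var0}")
        if self.var_delta < 0:
            raise ParameterError(f"change variance must be >= 0, got {self.var_delta}")


def implied_moments_univariate(p: LcsParams) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean and covariance of (X0, X1) for a univariate LCS.

    With X1 = X0 + Delta the implied moments are

        E[X0] = mu0                 Var(X0)     = var0
        E[X1] = mu0 + mu_delta      Cov(X0, X1) = var0 + cov0_delta
                                    Var(X1)     = var0 + 2*cov0_delta + var_delta

    Raises :class:`ParameterError` if the implied 2x2 covariance is not
    positive semidefinite (equivalently, cov0_delta**2 > var0 * var_delta).
    """
    mean = np.array([p.mu0, p.mu0 + p.mu_delta])
    c01 = p.var0 + p.cov0_delta
    cov = np.array(
        [[p.var0, c01], [c01, p.var0 + 2.0 * p.cov0_delta + p.var_delta]]
    )
    if p.cov0_delta**2 > p.var0 * p.var_delta + 1e-12 * max(1.0, p.var0):
        raise ParameterError(
            "implied (X0, X1) covariance is not PSD: "
            f"cov0_delta^2 = {p.cov0_delta**2:.6g} exceeds "
            f"var0 * var_delta = {p.var0 * p.var_delta:.6g}"
        )
    return mean, cov


@dataclass
class TwoWaveParams:
    """Joint five-variable 2W-LCS parameters for one group.

    Attributes
    ----------
    baseline_mean : (5,) array
        Baseline means in canonical order.
    baseline_cov : (5, 5) array
        Baseline covariance matrix.
    change_intercepts : (5,) array
        Intercepts of the structural equations for the change factors.
    gamma_self : (5,) array
        Own-baseline -> own-change regression coefficients.
    gamma_cross : (5, 5) array
        Cross-lagged coefficients; nonzero only at :data:`CROSS_LAGGED_PAIRS`
        (row = change equation, column = predictor baseline).
    beta_c2c : (5, 5) array
        Change-to-change coefficients; nonzero only at :data:`C2C_PAIRS`.
    change_resid_cov : (5, 5) array
        Residual covariance of the change factors; off-diagonal cells free
        only at :data:`RESID_COV_PAIRS`.
    """

    baseline_mean: np.ndarray
    baseline_cov: np.ndarray
    change_intercepts: np.ndarray
    gamma_self: np.ndarray
    gamma_cross: np.ndarray = field(default_factory=lambda: np.zeros((5, 5)))
    beta_c2c: np.ndarray = field(default_factory=lambda: np.zeros((5, 5)))
    change_resid_cov: np.ndarray = field(default_factory=lambda: np.zeros((5, 5)))

    def __post_init__(self) -> None:
        self.baseline_mean = np.asarray(self.baseline_mean, dtype=float)
        self.baseline_cov = np.asarray(self.baseline_cov, dtype=float)
        self.change_intercepts = np.asarray(self.change_intercepts, dtype=float)
        self.gamma_self = np.asarray(self.gamma_self, dtype=float)
        self.gamma_cross = np.asarray(self.gamma_cross, dtype=float)
        self.beta_c2c = np.asarray(self.beta_c2c, dtype=float)
        self.change_resid_cov = np.asarray(self.change_resid_cov, dtype=float)
        self._validate_structure()

    def _validate_structure(self) -> None:
        allowed_cross = np.zeros((5, 5), dtype=bool)
        for i, j in CROSS_LAGGED_PAIRS:
            allowed_cross[i, j] = True
        if np.any(self.gamma_cross[~allowed_cross] != 0):
            raise ParameterError("gamma_cross has entries outside the cross-lagged path set")
        allowed_b = np.zeros((5, 5), dtype=bool)
        for i, j in C2C_PAIRS:
            allowed_b[i, j] = True
        if np.any(self.beta_c2c[~allowed_b] != 0):
            raise ParameterError(
                "beta_c2c has entries outside process-change -> outcome-change paths"
            )
        allowed_psi = np.eye(5, dtype=bool)
        for i, j in RESID_COV_PAIRS:
            allowed_psi[i, j] = allowed_psi[j, i] = True
        if np.any(self.change_resid_cov[~allowed_psi] != 0):
            raise ParameterError("change_resid_cov has entries outside the free cell set")

    def delta_moments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Mean of Delta, Cov(X0, Delta), Cov(Delta) implied by the structure.

        The structural system is Delta = a + G X0 + B Delta + zeta with
        G = diag(gamma_self) + gamma_cross and B = beta_c2c.  Because B only
        feeds process changes into outcome equations, B @ B = 0 and
        (I - B)^-1 = I + B exactly.
        """
        G = np.diag(self.gamma_self) + self.gamma_cross
        A = np.eye(5) + self.beta_c2c  # (I - B)^-1, exact since B is nilpotent
        mean_d = A @ (self.change_intercepts + G @ self.baseline_mean)
        cov_x0_d = self.baseline_cov @ G.T @ A.T
        cov_d = A @ (G @ self.baseline_cov @ G.T + self.change_resid_cov) @ A.T
        return mean_d, cov_x0_d, cov_d


def implied_moments_2w(p: TwoWaveParams) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean (10,) and covariance (10, 10) of (X0, X1 = X0 + Delta)."""
    mean_d, c0d, cov_d = p.delta_moments()
    s0 = p.baseline_cov
    mean = np.concatenate([p.baseline_mean, p.baseline_mean + mean_d])
    cov = np.empty((10, 10))
    cov[:5, :5] = s0
    cov[:5, 5:] = s0 + c0d
    cov[5:, :5] = cov[:5, 5:].T
    cov[5:, 5:] = s0 + c0d + c0d.T + cov_d
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin < -1e-8 * max(1.0, float(np.abs(cov).max())):
        block = "change_resid_cov" if np.linalg.eigvalsh(cov_d).min() < 0 else "baseline_cov"
        raise ParameterError(
            f"implied 10x10 covariance not PSD (min eigenvalue {eigmin:.3g}); "
            f"offending block likely {block}"
        )
    return mean, cov


# ---------------------------------------------------------------------------
# Constraint maps and degrees-of-freedom accounting
# ---------------------------------------------------------------------------

GROUP_EQUAL = "group_equal"
GROUP_FREE = "group_free"

#: Parameter blocks of the univariate two-group LCS. Baseline means are
#: always equal across groups and baseline variances always free (the
#: published convention for these models).
UNIVARIATE_BLOCKS = ("mu0", "var0", "mu_delta", "var_delta", "cov0_delta")

#: Parameter blocks of the 2W-LCS with their sizes per group.
TWO_WAVE_BLOCKS = {
    "baseline_mean": 5,
    "baseline_cov": 15,
    "change_intercepts": 5,
    "gamma_self": 5,
    "change_resid_var": 5,
    "change_resid_cov": 4,
    "gamma_cross": 12,
    "beta_c2c": 6,
}

#: The three blocks the multigroup sequence A..D successively frees.
LCS_BLOCK = ("change_intercepts", "gamma_self", "change_resid_var", "change_resid_cov")
CROSS_BLOCK = ("gamma_cross",)
C2C_BLOCK = ("beta_c2c",)


@dataclass(frozen=True)
class ConstraintMap:
    """Cross-group equality flags per parameter block for a multigroup model."""

    label: str
    flags: dict  # block name -> GROUP_EQUAL | GROUP_FREE

    def is_equal(self, block: str) -> bool:
        return self.flags[block] == GROUP_EQUAL


def univariate_constraints(constrained: bool) -> ConstraintMap:
    """Constraint map for the two-group univariate LCS.

    The fully constrained model equates (mu_delta, var_delta, cov0_delta)
    across arms; the unconstrained model frees them.  Baseline means are
    equated and baseline variances freed in both.
    """
    flag = GROUP_EQUAL if constrained else GROUP_FREE
    return ConstraintMap(
        label="constrained" if constrained else "unconstrained",
        flags={
            "mu0": GROUP_EQUAL,
            "var0": GROUP_FREE,
            "mu_delta": flag,
            "var_delta": flag,
            "cov0_delta": flag,
        },
    )


def two_wave_constraints(label: str) -> ConstraintMap:
    """Constraint map for the 2W-LCS multigroup sequence.

    A: LCS, cross-lagged and change-to-change blocks all group-equal.
    B: change-to-change free.
    C: cross-lagged and change-to-change free.
    D: all three blocks free.
    Baseline means are always group-equal; baseline covariances always free.
    """
    label = label.upper()
    if label not in "ABCD" or len(label) != 1:
        raise ValueError(f"unknown 2W-LCS model label {label!r}")
    free: set[str] = set()
    if label in "BCD":
        free.update(C2C_BLOCK)
    if label in "CD":
        free.update(CROSS_BLOCK)
    if label == "D":
        free.update(LCS_BLOCK)
    flags = {"baseline_mean": GROUP_EQUAL, "baseline_cov": GROUP_FREE}
    for block in (*LCS_BLOCK, *CROSS_BLOCK, *C2C_BLOCK):
        flags[block] = GROUP_FREE if block in free else GROUP_EQUAL
    return ConstraintMap(label=label, flags=flags)


def count_df(model: ConstraintMap, n_variables: int = 1, n_groups: int = 2):
    """Moment, parameter and df counts for a constraint map.

    ``n_variables`` is the number of instruments (1 for univariate, 5 for
    the 2W-LCS); observed variables per group number ``2 * n_variables``.
    Returns ``(n_moments, n_params, df)``.
    """
    p_obs = 2 * n_variables
    n_moments = n_groups * (p_obs + p_obs * (p_obs + 1) // 2)
    if n_variables == 1:
        sizes = {b: 1 for b in UNIVARIATE_BLOCKS}
    elif n_variables == 5:
        sizes = TWO_WAVE_BLOCKS
    else:
        raise ValueError("df accounting defined for 1 or 5 variables")
    n_params = 0
    for block, size in sizes.items():
        n_params += size if model.is_equal(block) else n_groups * size
    return n_moments, n_params, n_moments - n_params
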