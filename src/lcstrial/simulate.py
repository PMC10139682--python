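"""Synthetic two-arm, two-wave, five-instrument trial generator.

The generator draws, per arm, the joint vector (baseline scores X0, latent
changes Delta) from the multivariate normal whose moments are the
model-implied moments of that arm's :class:`~lcstrial.lcs.TwoWaveParams`,
sets X1 = X0 + Delta, and then applies a wave-2 missingness regime.  This
guarantees internal consistency with the estimator's moment structure, so
parameter recovery is a well-posed test of the fitting machinery.

``default_paper_params`` converts the published trial summaries
(:mod:`lcstrial.reference`) into per-arm structural parameters: baseline
means/SDs and univariate change parameters enter directly; baseline and
change correlations become covariances; standardized cross-lagged and
change-to-change coefficients are mapped to unstandardized paths through the
implied SDs.  What the generator does *not* emulate: integer item-level
responses (scores are joint-normal unless ``discretize`` is set), MNAR
dropout, and any third assessment wave.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import reference as ref
from .lcs import (
    C2C_PAIRS,
    INSTRUMENTS,
    OUTCOME_IDX,
    PROCESS_IDX,
    RESID_COV_PAIRS,
    LcsParams,
    ParameterError,
    TwoWaveParams,
    implied_moments_2w,
)
from .schema import ARMS, DEFAULT_SCHEMA, TrialDataset

_IDX = {name: i for i, name in enumerate(INSTRUMENTS)}


def default_missing_rates() -> dict:
    """Per-instrument wave-2 missingness, interpolated across the published
    endpoint range (0.324 lowest instrument to 0.402 highest) in canonical
    instrument order — only the two endpoints were published."""
    lo, hi = ref.MISSED_ENDPOINT_RANGE
    rates = np.linspace(lo, hi, len(INSTRUMENTS))
    return {inst: float(r) for inst, r in zip(INSTRUMENTS, rates)}


@dataclass
class SimConfig:
    """Settings for one synthetic trial.

    ``params`` maps arm -> :class:`TwoWaveParams`; when omitted the published
    trial parameter set is used.  ``missingness`` has a ``mode`` of
    ``mcar_by_instrument`` (independent per-cell wave-2 MCAR at per-instrument
    rates), ``mcar_by_arm`` (whole wave-2 vector missing per record at
    arm-specific rates, the published completion imbalance), or ``none``, and
    a ``rates`` map.  ``discretize`` rounds scores to integers and clips to
    instrument ranges.  A seed is mandatory: identical configs (including
    seed) give byte-identical datasets.
    """

    n_intervention: int = ref.N_INTERVENTION
    n_control: int = ref.N_CONTROL
    params: dict | None = None
    missingness: dict = field(
        default_factory=lambda: {"mode": "mcar_by_instrument", "rates": None}
    )
    discretize: bool = False
    seed: int = 0
    covariates: bool = True
    equalize_baseline_means: bool = False

    def __post_init__(self):
        if self.n_intervention <= 0 or self.n_control <= 0:
            raise ValueError("per-arm counts must be positive")
        mode = self.missingness.get("mode", "none")
        if mode not in ("none", "mcar_by_instrument", "mcar_by_arm"):
            raise ValueError(f"unknown missingness mode {mode!r}")
        rates = self.missingness.get("rates") or {}
        for k, v in rates.items():
            if not 0.0 <= v < 1.0:
                raise ValueError(f"missingness rate for {k} must be in [0, 1): {v}")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")

    def resolved_params(self) -> dict:
        params = self.params or default_paper_params()
        if self.equalize_baseline_means:
            w = np.array([self.n_intervention, self.n_control], dtype=float)
            w /= w.sum()
            pooled = sum(
                wi * params[arm].baseline_mean for wi, arm in zip(w, ARMS)
            )
            params = {
                arm: TwoWaveParams(
                    baseline_mean=pooled,
                    baseline_cov=p.baseline_cov,
                    change_intercepts=p.change_intercepts,
                    gamma_self=p.gamma_self,
                    gamma_cross=p.gamma_cross,
                    beta_c2c=p.beta_c2c,
                    change_resid_cov=p.change_resid_cov,
                )
                for arm, p in ((a, params[a]) for a in ARMS)
            }
        return params

    def config_hash(self) -> str:
        params = self.resolved_params()
        blob = {
            "n": [self.n_intervention, self.n_control],
            "missingness": {
                "mode": self.missingness.get("mode"),
                "rates": self.missingness.get("rates"),
            },
            "discretize": self.discretize,
            "seed": self.seed,
            "covariates": self.covariates,
            "params": {
                arm: [np.round(arr, 10).tolist() for arr in (
                    p.baseline_mean, p.baseline_cov, p.change_intercepts,
                    p.gamma_self, p.gamma_cross, p.beta_c2c, p.change_resid_cov)]
                for arm, p in params.items()
            },
        }
        return hashlib.sha256(json.dumps(blob, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Published-parameter construction
# ---------------------------------------------------------------------------


def univariate_paper_params(instrument: str, arm: str) -> LcsParams:
    """Published univariate LCS parameters for one instrument in one arm."""
    t0_mean, t0_sd, _, _ = ref.DESCRIPTIVES[instrument][arm]
    est = ref.LCS_ESTIMATES[instrument][arm]
    return LcsParams(
        mu0=t0_mean,
        var0=t0_sd**2,
        mu_delta=est["mu_delta"][0],
        var_delta=est["var_delta"][0],
        cov0_delta=est["cov0_delta"][0],
    )


def _arm_paper_params(arm: str) -> TwoWaveParams:
    k = len(INSTRUMENTS)
    mu0 = np.array([ref.DESCRIPTIVES[i][arm][0] for i in INSTRUMENTS])
    sd0 = np.array([ref.DESCRIPTIVES[i][arm][1] for i in INSTRUMENTS])
    corr0 = np.eye(k)
    for (a, b), vals in ref.BASELINE_CORRELATIONS.items():
        i, j = _IDX[a], _IDX[b]
        corr0[i, j] = corr0[j, i] = vals[arm]
    s0 = corr0 * np.outer(sd0, sd0)

    mu_d = np.array([ref.LCS_ESTIMATES[i][arm]["mu_delta"][0] for i in INSTRUMENTS])
    var_d = np.array([ref.LCS_ESTIMATES[i][arm]["var_delta"][0] for i in INSTRUMENTS])
    cov0_d = np.array([ref.LCS_ESTIMATES[i][arm]["cov0_delta"][0] for i in INSTRUMENTS])
    sd_d = np.sqrt(var_d)

    beta = np.zeros((k, k))
    for (proc, out), vals in ref.C2C_STD.items():
        o, p = _IDX[out], _IDX[proc]
        beta[o, p] = vals[arm] * sd_d[o] / sd_d[p]
    gamma_cross = np.zeros((k, k))
    for (pred, chg), vals in ref.CROSS_LAGGED_STD.items():
        i, j = _IDX[chg], _IDX[pred]
        gamma_cross[i, j] = vals[arm] * sd_d[i] / sd0[j]

    # Own-baseline paths chosen so the implied baseline-change covariance of
    # each variable equals the published cov0_delta, given the cross paths.
    gamma_self = np.zeros(k)
    G = gamma_cross.copy()
    for p in PROCESS_IDX:
        cross_part = sum(s0[p, o] * gamma_cross[p, o] for o in OUTCOME_IDX)
        gamma_self[p] = (cov0_d[p] - cross_part) / s0[p, p]
        G[p, p] = gamma_self[p]
    for o in OUTCOME_IDX:
        cross_part = sum(s0[o, p] * gamma_cross[o, p] for p in PROCESS_IDX)
        c2c_part = sum(beta[o, p] * float(s0[o, :] @ G[p, :]) for p in PROCESS_IDX)
        gamma_self[o] = (cov0_d[o] - cross_part - c2c_part) / s0[o, o]
        G[o, o] = gamma_self[o]

    # Target marginal change covariance: published variances, published
    # change-factor correlations on the free cells.
    t_delta = np.diag(var_d).astype(float)
    for (a, b), vals in ref.CHANGE_CORRELATIONS.items():
        i, j = _IDX[a], _IDX[b]
        t_delta[i, j] = t_delta[j, i] = vals[arm] * sd_d[i] * sd_d[j]

    proc = list(PROCESS_IDX)
    out = list(OUTCOME_IDX)
    psi = np.zeros((k, k))
    g_s0_g = G @ s0 @ G.T
    psi[np.ix_(proc, proc)] = t_delta[np.ix_(proc, proc)] - g_s0_g[np.ix_(proc, proc)]
    g_out = G[out, :]
    b_op = beta[np.ix_(out, proc)]
    c0p = s0 @ G[proc, :].T  # Cov(X0, Delta_process)
    m = (
        g_out @ s0 @ g_out.T
        + b_op @ t_delta[np.ix_(proc, proc)] @ b_op.T
        + g_out @ c0p @ b_op.T
        + (g_out @ c0p @ b_op.T).T
    )
    psi[np.ix_(out, out)] = t_delta[np.ix_(out, out)] - m
    # Zero any numerically non-free cell.
    keep = np.eye(k, dtype=bool)
    for i, j in RESID_COV_PAIRS:
        keep[i, j] = keep[j, i] = True
    psi[~keep] = 0.0
    for block in (out, proc):
        eigmin = float(np.linalg.eigvalsh(psi[np.ix_(block, block)]).min())
        if eigmin <= 0:
            raise ParameterError(
                f"published mapping yields non-PSD change residual block "
                f"{[INSTRUMENTS[i] for i in block]} (min eig {eigmin:.4g})"
            )

    alpha = (np.eye(k) - beta) @ mu_d - G @ mu0
    return TwoWaveParams(
        baseline_mean=mu0,
        baseline_cov=s0,
        change_intercepts=alpha,
        gamma_self=gamma_self,
        gamma_cross=gamma_cross,
        beta_c2c=beta,
        change_resid_cov=psi,
    )


def default_paper_params() -> dict:
    """Per-arm :class:`TwoWaveParams` reproducing the published trial moments.

    The implied univariate moments of each instrument match the published
    baseline means/SDs and change estimates exactly; the implied cross-
    variable structure matches the published correlations and standardized
    paths under the SD mapping described in the module docstring.
    """
    return {arm: _arm_paper_params(arm) for arm in ARMS}


def two_wave_from_univariate(per_instrument: dict, baseline_corr=None) -> TwoWaveParams:
    """Assemble a no-cross-path :class:`TwoWaveParams` from per-instrument
    :class:`LcsParams` (keys = instrument names); optional baseline
    correlation matrix (default: independent baselines)."""
    k = len(INSTRUMENTS)
    p = [per_instrument[i] for i in INSTRUMENTS]
    sd0 = np.array([np.sqrt(x.var0) for x in p])
    corr = np.eye(k) if baseline_corr is None else np.asarray(baseline_corr)
    gamma_self = np.array([x.cov0_delta / x.var0 for x in p])
    psi = np.diag([x.var_delta - x.cov0_delta**2 / x.var0 for x in p])
    mu0 = np.array([x.mu0 for x in p])
    return TwoWaveParams(
        baseline_mean=mu0,
        baseline_cov=corr * np.outer(sd0, sd0),
        change_intercepts=np.array([x.mu_delta for x in p]) - gamma_self * mu0,
        gamma_self=gamma_self,
        change_resid_cov=psi,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _draw_scores(params: TwoWaveParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw (X0, X1) rows: joint-normal (X0, Delta) then X1 = X0 + Delta."""
    implied_moments_2w(params)  # PSD check with block attribution
    mean_d, c0d, cov_d = params.delta_moments()
    k = params.baseline_mean.size
    mean = np.concatenate([params.baseline_mean, mean_d])
    cov = np.block([[params.baseline_cov, c0d], [c0d.T, cov_d]])
    draws = rng.multivariate_normal(mean, cov, size=n, check_valid="ignore",
                                    method="svd")
    x0, delta = draws[:, :k], draws[:, k:]
    return np.hstack([x0, x0 + delta])


def _apply_missingness(
    t1: np.ndarray, arm: str, missingness: dict, rng: np.random.Generator
) -> np.ndarray:
    mode = missingness.get("mode", "none")
    if mode == "none":
        return t1
    if mode == "mcar_by_instrument":
        rates = missingness.get("rates") or default_missing_rates()
        for j, inst in enumerate(INSTRUMENTS):
            drop = rng.random(t1.shape[0]) < rates[inst]
            t1[drop, j] = np.nan
    elif mode == "mcar_by_arm":
        rates = missingness.get("rates") or ref.ARM_MISSING_RATES
        drop = rng.random(t1.shape[0]) < rates[arm]
        t1[drop, :] = np.nan
    return t1


def _draw_covariates(arm: str, n: int, rng: np.random.Generator) -> dict:
    """Baseline covariates matching the published arm-level distributions.

    Numeric covariates are normal (PDPI-R risk truncated at the 5.5
    eligibility cutoff); binary covariates are Bernoulli at the published
    arm proportions.  They do not feed the outcome model."""
    out: dict = {}
    for name, by_arm in ref.BASELINE_NUMERIC.items():
        mean, sd = by_arm[arm]
        if name == "pdpi_r":
            a = (5.5 - mean) / sd
            out[name] = stats.truncnorm.rvs(
                a, np.inf, loc=mean, scale=sd, size=n, random_state=rng
            )
        else:
            out[name] = np.maximum(rng.normal(mean, sd, size=n), 0.0)
    levels = {
        "marital_status": ("married_cohabiting", "other"),
        "parity": ("primiparous", "multiparous"),
        "education": ("higher_education", "other"),
        "employment": ("employed", "other"),
        "income": ("below_1000", "above_1000"),
        "residence": ("urban", "rural"),
        "infant_sex": ("male", "female"),
    }
    for name, by_arm in ref.BASELINE_BINARY.items():
        count, total = by_arm[arm]
        hit = rng.random(n) < count / total
        ref_level, alt_level = levels[name]
        out[name] = np.where(hit, ref_level, alt_level)
    return out


def generate_trial(config: SimConfig) -> TrialDataset:
    """Generate one synthetic trial dataset from ``config``.

    Scores are exact joint-normal draws unless ``discretize`` is set, in
    which case they are rounded and clipped to instrument ranges (large-
    sample means then shift by well under half a scale point).
    """
    rng = np.random.default_rng(config.seed)
    params = config.resolved_params()
    frames = []
    for arm, n in (("intervention", config.n_intervention),
                   ("control", config.n_control)):
        scores = _draw_scores(params[arm], n, rng)
        k = len(INSTRUMENTS)
        t0, t1 = scores[:, :k], scores[:, k:].copy()
        t1 = _apply_missingness(t1, arm, config.missingness, rng)
        if config.discretize:
            for j, spec in enumerate(DEFAULT_SCHEMA):
                t0[:, j] = np.clip(np.round(t0[:, j]), spec.score_min, spec.score_max)
                obs = ~np.isnan(t1[:, j])
                t1[obs, j] = np.clip(
                    np.round(t1[obs, j]), spec.score_min, spec.score_max
                )
        cols = {"id": [f"{arm[0]}{i + 1:05d}" for i in range(n)], "arm": arm}
        if config.covariates:
            cols.update(_draw_covariates(arm, n, rng))
        for j, inst in enumerate(INSTRUMENTS):
            cols[f"{inst}_T0"] = t0[:, j]
            cols[f"{inst}_T1"] = t1[:, j]
        frames.append(pd.DataFrame(cols))
    data = pd.concat(frames, ignore_index=True)
    return TrialDataset(
        data=data,
        schema=DEFAULT_SCHEMA,
        continuous=not config.discretize,
        provenance={
            "source": "synthetic",
            "seed": int(config.seed),
            "config_hash": config.config_hash(),
        },
    )
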