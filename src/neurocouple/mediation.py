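"""Covariate-adjusted simple mediation (X -> M -> Y) with percentile
bootstrap inference on the indirect effect.

Three OLS fits with the same covariate set C give the paths:

    M = i1 + a*X + C            (a: predictor -> mediator)
    Y = i2 + c'*X + b*M + C     (b: mediator -> outcome; c': direct)
    Y = i3 + c*X + C            (c: total)

The OLS identity c = c' + a*b holds exactly.  Significance of the indirect
effect a*b uses a 95% percentile bootstrap over whole subject rows
(default 5,000 resamples): the effect is significant when the interval
excludes zero.  A bias-corrected (BC) interval is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import ValidationError

log = logging.getLogger("neurocouple")

__all__ = ["MediationResult", "fit_mediation", "bootstrap_indirect"]


@dataclass
class MediationResult:
    a: float
    b: float
    c_total: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    significant: bool


def _as_covar(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    covar = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covar.shape[0] != n:
        covar = covar.T
    if covar.shape[0] != n:
        raise ValidationError("covariate rows != number of subjects")
    return covar


def fit_mediation(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> dict[str, float]:
    """OLS path coefficients a, b, c_total, c_prime and the indirect a*b."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    covar = _as_covar(covariates, n)
    if n <= covar.shape[1] + 4:
        raise ValidationError("too few subjects for the covariate count")

    base = np.column_stack([np.ones(n), x, covar])
    if np.linalg.matrix_rank(base) < base.shape[1]:
        raise ValidationError("rank-deficient mediation design")

    a = float(np.linalg.lstsq(base, m, rcond=None)[0][1])
    design_y = np.column_stack([np.ones(n), x, m, covar])
    if np.linalg.matrix_rank(design_y) < design_y.shape[1]:
        raise ValidationError("mediator is collinear with predictor/covariates")
    coef_y = np.linalg.lstsq(design_y, y, rcond=None)[0]
    c_prime, b = float(coef_y[1]), float(coef_y[2])
    c_total = float(np.linalg.lstsq(base, y, rcond=None)[0][1])
    return {
        "a": a,
        "b": b,
        "c_total": c_total,
        "c_prime": c_prime,
        "indirect": a * b,
    }


def _batched_path(
    design: np.ndarray, target: np.ndarray, idx: np.ndarray, col: int
) -> np.ndarray:
    """Coefficient ``col`` of OLS(target ~ design) for every resample row of
    ``idx``; singular resamples yield NaN."""
    d = design[idx]                      # (B, n, p)
    t = target[idx]                      # (B, n)
    g = np.einsum("bnp,bnq->bpq", d, d)
    h = np.einsum("bnp,bn->bp", d, t)
    p = design.shape[1]
    ok = np.abs(np.linalg.det(g)) > 1e-12 * np.abs(np.linalg.det(g)).max()
    coefs = np.full((idx.shape[0], p), np.nan)
    if np.any(ok):
        coefs[ok] = np.linalg.solve(g[ok], h[ok][..., None])[..., 0]
    return coefs[:, col]


def bootstrap_indirect(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 5000,
    seed: int = 0,
    ci: float = 0.95,
    bias_corrected: bool = False,
) -> MediationResult:
    """Percentile-bootstrap CI for the indirect effect a*b.

    Whole subject rows (x, m, y, covariates jointly) are resampled with
    replacement ``n_boot`` times and both path models refit per resample.
    Degenerate resamples (e.g. constant predictor) are redrawn; the number
    redrawn is logged.  ``significant`` is True when the interval excludes
    zero.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    covar = _as_covar(covariates, n)
    point = fit_mediation(x, m, y, covar if covar.size else None)

    rng = np.random.default_rng(seed)
    base = np.column_stack([np.ones(n), x, covar])
    design_y = np.column_stack([np.ones(n), x, m, covar])

    idx = rng.integers(0, n, size=(n_boot, n))
    a_boot = _batched_path(base, m, idx, 1)
    b_boot = _batched_path(design_y, y, idx, 2)
    indirect = a_boot * b_boot

    n_redrawn = 0
    bad = ~np.isfinite(indirect)
    while np.any(bad):
        n_redrawn += int(bad.sum())
        idx_new = rng.integers(0, n, size=(int(bad.sum()), n))
        a_new = _batched_path(base, m, idx_new, 1)
        b_new = _batched_path(design_y, y, idx_new, 2)
        indirect[bad] = a_new * b_new
        bad = ~np.isfinite(indirect)
    if n_redrawn:
        log.info("stage=bootstrap_indirect degenerate_resamples_redrawn=%d", n_redrawn)

    alpha = 1.0 - ci
    if bias_corrected:
        prop = np.mean(indirect < point["indirect"])
        prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
        z0 = stats.norm.ppf(prop)
        lo_q = stats.norm.cdf(2 * z0 + stats.norm.ppf(alpha / 2))
        hi_q = stats.norm.cdf(2 * z0 + stats.norm.ppf(1 - alpha / 2))
        ci_low, ci_high = np.quantile(indirect, [lo_q, hi_q])
    else:
        ci_low, ci_high = np.quantile(indirect, [alpha / 2, 1 - alpha / 2])

    significant = bool(ci_low > 0 or ci_high < 0)
    return MediationResult(
        a=point["a"],
        b=point["b"],
        c_total=point["c_total"],
        c_prime=point["c_prime"],
        indirect=point["indirect"],
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        seed=seed,
        significant=significant,
    )
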