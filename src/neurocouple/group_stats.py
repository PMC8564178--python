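"""Between-group and correlational inference.

Covers the demographics tests (chi-square, Kruskal-Wallis, one-way ANOVA),
cognition z-scoring across the whole cohort, region-wise permutation ANCOVA
with post-hoc contrasts, and covariate-adjusted partial correlation.

The permutation scheme is Freedman-Lane: residuals of the reduced
(covariate-only) model are permuted and added back to its fitted values, so
the null distribution of the group partial F respects the covariates.
Permutation p-values use the add-one convention, p = (1 + #{F_pi >= F_obs})
/ (1 + n_perm), and are therefore never zero.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError

log = logging.getLogger("neurocouple")

__all__ = [
    "RegionStatResult",
    "zscore_cognition",
    "chi_square_test",
    "oneway_anova",
    "oneway_anova_summary",
    "kruskal_wallis",
    "ancova_permutation",
    "regionwise_ancova",
    "partial_correlation",
    "demographics_table",
]

#: Cognitive tests scored in time, where a larger raw value means worse
#: performance; their z-scores are sign-flipped so higher always = better.
TIME_SCORED_TESTS = ("tmt_a", "tmt_b")


@dataclass
class RegionStatResult:
    """Permutation-ANCOVA outcome for one region/measure."""

    region_id: int
    f_obs: float
    p_perm: float
    posthoc: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)


def zscore_cognition(
    raw: pd.DataFrame,
    time_scored: tuple[str, ...] = TIME_SCORED_TESTS,
) -> pd.DataFrame:
    """Standardize raw cognitive scores across the whole cohort.

    Each column is transformed to z = (x - mean) / SD over all subjects;
    columns named in ``time_scored`` (timed tests, larger = worse) are then
    multiplied by -1 so that a higher z always means better performance.
    """
    out = {}
    for col in raw.columns:
        vals = raw[col].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValidationError(f"{col}: need >= 2 subjects to z-score")
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValidationError(f"{col}: zero variance, cannot z-score")
        z = (vals - vals.mean()) / sd
        if col in time_scored:
            z = -z
        out[col] = z
    return pd.DataFrame(out, index=raw.index)


def chi_square_test(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if np.any(table < 0) or np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValidationError("table has an empty row or column")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def oneway_anova(values: np.ndarray, groups: np.ndarray) -> tuple[float, int, int, float]:
    """Textbook one-way ANOVA on raw data; returns (F, df1, df2, p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValidationError("need >= 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValidationError("every group needs n >= 2")
    f, p = stats.f_oneway(*samples)
    df1 = len(levels) - 1
    df2 = values.size - len(levels)
    return float(f), df1, df2, float(p)


def oneway_anova_summary(
    ns: np.ndarray, means: np.ndarray, sds: np.ndarray
) -> tuple[float, float]:
    """One-way ANOVA from per-group n / mean / SD summaries.

    Exactly reproduces the raw-data F when the raw data match the
    summaries: between SS from group means, within SS from (n-1)*SD^2.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if not (ns.shape == means.shape == sds.shape) or ns.size < 2:
        raise ValidationError("need matching n/mean/SD for >= 2 groups")
    if np.any(ns < 2):
        raise ValidationError("every group needs n >= 2")
    k = ns.size
    total_n = ns.sum()
    grand = (ns * means).sum() / total_n
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    f = (ss_between / (k - 1)) / (ss_within / (total_n - k))
    p = float(stats.f.sf(f, k - 1, total_n - k))
    return float(f), p


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; chi-square approximation."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValidationError("need >= 2 groups")
    samples = [values[groups == g] for g in levels]
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def _hat(design: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(design)
    return q @ q.T


def _dummies(groups: np.ndarray) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(groups))
    cols = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    return cols, levels


def _partial_f_matrix(
    y_cols: np.ndarray, resid_full: np.ndarray, resid_red: np.ndarray, df1: int, df2: int
) -> np.ndarray:
    """Partial F of the group factor for each column of ``y_cols``.

    ``resid_full`` / ``resid_red`` are residual-maker matrices (I - H)."""
    rss_full = np.einsum("nk,nk->k", y_cols, resid_full @ y_cols)
    rss_red = np.einsum("nk,nk->k", y_cols, resid_red @ y_cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    return np.maximum(f, 0.0)


def _freedman_lane_p(
    y: np.ndarray,
    covar_design: np.ndarray,
    full_design: np.ndarray,
    df1: int,
    df2: int,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Observed partial F and its Freedman-Lane permutation p-value."""
    n = y.size
    h_red = _hat(covar_design)
    m_red = np.eye(n) - h_red
    m_full = np.eye(n) - _hat(full_design)

    f_obs = float(_partial_f_matrix(y[:, None], m_full, m_red, df1, df2)[0])

    fitted_red = h_red @ y
    resid_red = m_red @ y
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    y_pi = fitted_red[:, None] + resid_red[perms].T  # n x n_perm
    f_pi = _partial_f_matrix(y_pi, m_full, m_red, df1, df2)
    p = (1.0 + np.count_nonzero(f_pi >= f_obs)) / (1.0 + n_perm)
    return f_obs, float(p)


def ancova_permutation(
    region_values: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int | np.random.Generator = 0,
    posthoc: bool = True,
    scheme: str = "freedman-lane",
) -> RegionStatResult:
    """Permutation test of the group factor adjusting for covariates.

    The observed statistic is the partial F of group over the covariates.
    Under ``scheme="freedman-lane"`` (default) the null distribution comes
    from permuting reduced-model residuals; ``scheme="labels"`` permutes the
    raw values (no covariate adjustment under the null).  Post-hoc pairwise
    contrasts are run, analogously, only when the omnibus p is below
    ``alpha``.
    """
    y = np.asarray(region_values, dtype=float)
    groups = np.asarray(groups)
    n = y.size
    if groups.shape != (n,):
        raise ValidationError("groups length != values length")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value", stacklevel=2)
    if scheme not in ("freedman-lane", "labels"):
        raise ValidationError("scheme must be 'freedman-lane' or 'labels'")

    if covariates is None:
        covar = np.empty((n, 0))
    else:
        covar = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covar.shape[0] != n:
            covar = covar.T
        if covar.shape[0] != n:
            raise ValidationError("covariate rows != number of subjects")
        covar = covar - covar.mean(axis=0)  # centering stabilizes conditioning

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dummies, levels = _dummies(groups)
    covar_design = np.column_stack([np.ones(n), covar])
    full_design = np.column_stack([covar_design, dummies])
    if np.linalg.matrix_rank(full_design) < full_design.shape[1]:
        raise ValidationError("rank-deficient ANCOVA design")
    df1 = dummies.shape[1]
    df2 = n - full_design.shape[1]

    if scheme == "labels":
        # permute raw y against the fixed design
        h_red = _hat(covar_design)
        m_red = np.eye(n) - h_red
        m_full = np.eye(n) - _hat(full_design)
        f_obs = float(_partial_f_matrix(y[:, None], m_full, m_red, df1, df2)[0])
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
        f_pi = _partial_f_matrix(y[perms].T, m_full, m_red, df1, df2)
        p = (1.0 + np.count_nonzero(f_pi >= f_obs)) / (1.0 + n_perm)
        f_obs, p_perm = f_obs, float(p)
    else:
        f_obs, p_perm = _freedman_lane_p(
            y, covar_design, full_design, df1, df2, n_perm, rng
        )

    result = RegionStatResult(region_id=-1, f_obs=f_obs, p_perm=p_perm)

    if posthoc and p_perm < alpha:
        for g1, g2 in itertools.combinations(levels, 2):
            sel = (groups == g1) | (groups == g2)
            y2, c2 = y[sel], covar[sel]
            ind = (groups[sel] == g2).astype(float)[:, None]
            cov_d = np.column_stack([np.ones(y2.size), c2])
            full_d = np.column_stack([cov_d, ind])
            f2, p2 = _freedman_lane_p(
                y2, cov_d, full_d, 1, y2.size - full_d.shape[1], n_perm, rng
            )
            # signed direction from the adjusted contrast coefficient
            beta = np.linalg.lstsq(full_d, y2, rcond=None)[0][-1]
            result.posthoc[(str(g1), str(g2))] = {
                "t": float(np.sign(beta) * np.sqrt(f2)),
                "p_perm": p2,
                "direction": float(np.sign(beta)),
            }
    return result


def regionwise_ancova(
    values: pd.DataFrame,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    fdr: bool = False,
) -> pd.DataFrame:
    """Run the permutation ANCOVA for every region column of ``values``.

    Returns one row per region (no region is silently dropped), with the
    omnibus F, permutation p, and significance flag.  No multiple-comparison
    correction is applied by default; ``fdr=True`` adds Benjamini-Hochberg
    adjusted p-values in a ``p_fdr`` column.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(values.shape[1])
    rows = []
    for (col, child) in zip(values.columns, children):
        rng = np.random.default_rng(child)
        res = ancova_permutation(
            values[col].to_numpy(),
            groups,
            covariates,
            n_perm=n_perm,
            alpha=alpha,
            seed=rng,
        )
        row = {
            "region_id": col,
            "f_obs": res.f_obs,
            "p_perm": res.p_perm,
            "significant": res.p_perm < alpha,
        }
        for (g1, g2), stats_ in res.posthoc.items():
            row[f"t_{g1}_vs_{g2}"] = stats_["t"]
            row[f"p_{g1}_vs_{g2}"] = stats_["p_perm"]
        rows.append(row)
    out = pd.DataFrame(rows)
    if fdr:
        p = out["p_perm"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        p_fdr = np.empty_like(p)
        p_fdr[order] = np.minimum(adj, 1.0)
        out["p_fdr"] = p_fdr
    log.info(
        "stage=regionwise_ancova regions=%d n_perm=%d alpha=%g significant=%d",
        len(out),
        n_perm,
        alpha,
        int(out["significant"].sum()),
    )
    return out


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y controlling for covariates.

    Both variables are residualized on [intercept + covariates]; the p-value
    uses a t distribution with df = n - 2 - k.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        covar = np.empty((n, 0))
    else:
        covar = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covar.shape[0] != n:
            covar = covar.T
    k = covar.shape[1]
    if n <= k + 3:
        raise ValidationError("too few subjects for the covariate count")
    design = np.column_stack([np.ones(n), covar])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("rank-deficient covariate design")
    h = _hat(design)
    rx = x - h @ x
    ry = y - h @ y
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def demographics_table(
    cohort: pd.DataFrame,
    continuous_anova: tuple[str, ...] = (),
    continuous_kruskal: tuple[str, ...] = ("age", "education_years"),
    categorical: tuple[str, ...] = ("sex", "hypertension", "diabetes", "smoking", "drinking"),
    group_col: str = "group",
) -> pd.DataFrame:
    """Summarize a cohort frame and test group differences per variable.

    Continuous variables are reported as mean +/- SD per group and tested
    with one-way ANOVA or Kruskal-Wallis (per-variable choice); categorical
    variables as counts with a chi-square test.
    """
    groups = cohort[group_col].to_numpy()
    levels = list(pd.unique(groups))
    rows = []

    def summarize(col: str) -> list[str]:
        out = []
        for g in levels:
            vals = cohort.loc[cohort[group_col] == g, col].to_numpy(dtype=float)
            out.append(f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}")
        return out

    for col in continuous_kruskal:
        if col not in cohort:
            continue
        h, p = kruskal_wallis(cohort[col].to_numpy(dtype=float), groups)
        rows.append([col, *summarize(col), "Kruskal-Wallis", p])
    for col in continuous_anova:
        if col not in cohort:
            continue
        _, _, _, p = oneway_anova(cohort[col].to_numpy(dtype=float), groups)
        rows.append([col, *summarize(col), "ANOVA", p])
    for col in categorical:
        if col not in cohort:
            continue
        cats = pd.unique(cohort[col])
        table = np.array(
            [
                [np.count_nonzero((cohort[group_col] == g) & (cohort[col] == c)) for c in cats]
                for g in levels
            ]
        )
        _, _, p = chi_square_test(table)
        counts = ["/".join(str(v) for v in row) for row in table]
        rows.append([col, *counts, "chi-square", p])

    return pd.DataFrame(rows, columns=["variable", *levels, "test", "p"])
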