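"""Statistical analysis of Navon-task performance and chest-movement counts.

Covers the full subject-level analysis chain:

* shift/nonshift tagging of the mixed Navon phase (a *shift* trial requires a
  different global/local level than its predecessor; the first mixed trial
  has no predecessor and is excluded),
* per-subject condition means (global, local, nonshift, shift reaction
  times over accurate trials; shift-trial accuracy),
* one-way repeated-measures ANOVA with Greenhouse-Geisser (GG) correction
  for sphericity violations,
* pairwise condition comparisons with a pooled error term (Bonferroni and
  Holm adjusted),
* a Pearson correlation matrix with pairwise deletion of missing values, and
* a bootstrap mediation model: movement counts -> shift-trial reaction time
  -> accuracy / stress, with bias-corrected percentile confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "tag_shift_trials",
    "condition_summaries",
    "RmAnovaResult",
    "rm_anova_gg",
    "PairwiseResult",
    "pairwise_comparisons",
    "correlation_matrix",
    "PathEstimate",
    "MediationResult",
    "mediation_bootstrap",
]

CONDITIONS = ("global", "local", "nonshift", "shift")
MEDIATION_PREDICTORS = ("swinging", "rotating", "sitting")
MEDIATION_OUTCOMES = ("accuracy", "stress")
MEDIATOR = "reaction_time"


# ---------------------------------------------------------------------------
# Trial-level processing
# ---------------------------------------------------------------------------

def tag_shift_trials(kinds) -> list[str]:
    """Tag each mixed-phase trial as ``shift``, ``nonshift`` or ``undefined``.

    Trial i (i >= 2) is a shift trial iff its required level differs from
    trial i-1's.  The first trial has no predecessor and is ``undefined``,
    belonging to neither set.
    """
    kinds = list(kinds)
    if not kinds:
        raise ValueError("trial-kind sequence must be non-empty")
    tags = ["undefined"]
    for prev, cur in zip(kinds, kinds[1:]):
        tags.append("shift" if cur != prev else "nonshift")
    return tags


def condition_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject condition means from a trial-level table.

    ``trials`` needs columns ``participant, phase, trial_kind, rt, correct,
    trial_index``.  Reaction times are averaged over *accurate* trials in
    every condition; shift-trial accuracy is correct-shift / all-shift.
    Subjects with no accurate trial in a condition get NaN there (logged).
    """
    required = {"participant", "phase", "trial_kind", "rt", "correct", "trial_index"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")

    rows = []
    for pid, sub in trials.groupby("participant", sort=True):
        rec: dict = {"participant": pid}
        for phase in ("global", "local"):
            ph = sub[(sub["phase"] == phase) & sub["correct"]]
            rec[f"{phase}_rt"] = ph["rt"].mean() if len(ph) else np.nan
        mixed = sub[sub["phase"] == "mixed"].sort_values("trial_index")
        if len(mixed):
            tags = np.array(tag_shift_trials(mixed["trial_kind"].tolist()))
            rt = mixed["rt"].to_numpy()
            ok = mixed["correct"].to_numpy(dtype=bool)
            shift = tags == "shift"
            nonshift = tags == "nonshift"
            rec["nonshift_rt"] = rt[nonshift & ok].mean() if (nonshift & ok).any() else np.nan
            rec["shift_rt"] = rt[shift & ok].mean() if (shift & ok).any() else np.nan
            rec["accuracy"] = ok[shift].mean() if shift.any() else np.nan
            if not (shift & ok).any():
                log.warning("participant %s has no accurate shift trial; shift RT missing", pid)
        else:
            rec.update({"nonshift_rt": np.nan, "shift_rt": np.nan, "accuracy": np.nan})
        rec["reaction_time"] = rec["shift_rt"]
        rows.append(rec)
    return pd.DataFrame(rows).set_index("participant")


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------

@dataclass
class RmAnovaResult:
    """One-way within-subject ANOVA with GG-corrected degrees of freedom."""

    F: float
    df1: float          # GG-corrected, epsilon * (k - 1)
    df2: float          # GG-corrected, epsilon * (k - 1) * (n - 1)
    epsilon: float
    p: float
    eta_sq: float       # partial eta squared: SS_effect / (SS_effect + SS_error)
    ms_error: float
    n: int
    k: int


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centered condition covariance."""
    k = data.shape[1]
    if k == 2:
        return 1.0
    S = np.cov(data, rowvar=False)
    row = S.mean(axis=0, keepdims=True)
    Sd = S - row - row.T + S.mean()
    eps = np.trace(Sd) ** 2 / ((k - 1) * np.sum(Sd**2))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(data: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on an (n subjects x k conditions) matrix.

    The F statistic comes from the standard within-subject decomposition
    (conditions vs subject-by-condition error); the p value is evaluated at
    GG-corrected fractional degrees of freedom.  Missing cells are rejected
    rather than imputed.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D subjects x conditions matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if np.any(np.isnan(data)):
        raise ValueError("missing cells are not allowed; drop incomplete subjects first")

    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    F = ms_cond / ms_err
    eps = _gg_epsilon(data)
    df1 = eps * df_cond
    df2 = eps * df_err
    p = float(stats.f.sf(F, df1, df2))
    eta = ss_cond / (ss_cond + ss_err)
    return RmAnovaResult(F=float(F), df1=float(df1), df2=float(df2), epsilon=eps,
                         p=p, eta_sq=float(eta), ms_error=float(ms_err), n=n, k=k)


# ---------------------------------------------------------------------------
# Pairwise comparisons
# ---------------------------------------------------------------------------

@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    diff: float
    se: float
    t: float
    p_raw: float
    p_bonf: float
    p_holm: float


def pairwise_comparisons(
    data: np.ndarray, condition_names: tuple[str, ...] = CONDITIONS
) -> list[PairwiseResult]:
    """All pairwise condition contrasts with a pooled within-subject error term.

    Every pair shares the common standard error ``sqrt(2 * MS_error / n)``
    from the repeated-measures ANOVA, with ``(n-1)(k-1)`` error degrees of
    freedom; t is exactly diff/SE.  Both Bonferroni (x number of pairs,
    capped at 1) and Holm step-down adjusted p values are reported.
    """
    data = np.asarray(data, dtype=float)
    anova = rm_anova_gg(data)
    n, k = anova.n, anova.k
    if len(condition_names) != k:
        raise ValueError("condition_names length must match the number of columns")
    se = float(np.sqrt(2.0 * anova.ms_error / n))
    df = (n - 1) * (k - 1)
    means = data.mean(axis=0)

    pairs = list(combinations(range(k), 2))
    diffs = [float(means[i] - means[j]) for i, j in pairs]
    ts = [d / se for d in diffs]
    p_raw = [float(2 * stats.t.sf(abs(t), df)) for t in ts]
    m = len(pairs)
    p_bonf = [min(1.0, m * p) for p in p_raw]

    # Holm step-down
    order = np.argsort(p_raw)
    p_holm = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_raw[idx])
        p_holm[idx] = min(1.0, running)

    return [
        PairwiseResult(
            pair=(condition_names[i], condition_names[j]),
            diff=diffs[q], se=se, t=ts[q],
            p_raw=p_raw[q], p_bonf=p_bonf[q], p_holm=float(p_holm[q]),
        )
        for q, (i, j) in enumerate(pairs)
    ]


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def correlation_matrix(table: pd.DataFrame, variables: list[str] | None = None):
    """Pearson r and two-sided p per variable pair, with pairwise deletion.

    Returns ``(r, p, n)`` DataFrames.  p comes from ``t = r sqrt((n-2)/(1-r^2))``
    on n-2 degrees of freedom.  Pairs with fewer than 3 complete observations
    or a zero-variance column are reported as NaN.
    """
    if variables is None:
        variables = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    m = len(variables)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    nmat = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i, m):
            x = table[variables[i]].to_numpy(dtype=float)
            y = table[variables[j]].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            nn = int(ok.sum())
            nmat[i, j] = nmat[j, i] = nn
            if nn < 3:
                continue
            xs, ys = x[ok], y[ok]
            if xs.std() == 0 or ys.std() == 0:
                continue
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            rij, pij = stats.pearsonr(xs, ys)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    idx = pd.Index(variables)
    return (pd.DataFrame(r, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx),
            pd.DataFrame(nmat, index=idx, columns=idx))


# ---------------------------------------------------------------------------
# Mediation
# ---------------------------------------------------------------------------

@dataclass
class PathEstimate:
    """One effect (direct, indirect or total) for one predictor-outcome path."""

    estimate: float
    se: float
    z: float
    p: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    std_estimate: float = np.nan


@dataclass
class MediationResult:
    """Direct/indirect/total path estimates with bootstrap CIs.

    ``effects[(predictor, outcome)]`` maps ``"direct" | "indirect" | "total"``
    to a :class:`PathEstimate`.  ``r_squared`` holds R^2 for the mediator
    equation and each outcome equation; ``n_boot_achieved`` counts the
    bootstrap resamples that produced a non-singular fit.
    """

    effects: dict[tuple[str, str], dict[str, PathEstimate]]
    r_squared: dict[str, float]
    n_boot_requested: int
    n_boot_achieved: int
    n_used: dict[str, int] = field(default_factory=dict)


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares with classical coefficient covariance; None if singular."""
    n, pdim = X.shape
    if n <= pdim:
        return None
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return None
    if np.linalg.cond(XtX) > 1e12:
        return None
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - pdim)
    cov = sigma2 * XtX_inv
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return beta, cov, r2


def _fit_paths(df: pd.DataFrame, standardized: bool = False):
    """Fit the mediator and outcome equations; return per-path effects.

    Mediator equation: RT ~ swinging + rotating + sitting.  Outcome
    equations: accuracy ~ RT + movements (all complete rows) and
    stress ~ RT + movements (rows with stress observed).  Returns None when
    any design matrix is singular.
    """
    preds = list(MEDIATION_PREDICTORS)

    def design(sub: pd.DataFrame, cols: list[str]) -> np.ndarray:
        M = sub[cols].to_numpy(dtype=float)
        if standardized:
            sd = M.std(axis=0, ddof=1)
            sd = np.where(sd == 0, 1.0, sd)
            M = (M - M.mean(axis=0)) / sd
        return np.column_stack([np.ones(len(sub)), M])

    def response(sub: pd.DataFrame, col: str) -> np.ndarray:
        y = sub[col].to_numpy(dtype=float)
        if standardized:
            sd = y.std(ddof=1)
            y = (y - y.mean()) / (sd if sd else 1.0)
        return y

    base = df.dropna(subset=preds + [MEDIATOR, "accuracy"])
    fit_m = _ols(design(base, preds), response(base, MEDIATOR))
    if fit_m is None:
        return None
    a, cov_a, r2_m = fit_m
    out: dict = {"r2": {MEDIATOR: r2_m}, "paths": {}, "n_used": {MEDIATOR: len(base)}}

    for outcome in MEDIATION_OUTCOMES:
        sub = base if outcome == "accuracy" else base.dropna(subset=[outcome])
        fit_y = _ols(design(sub, [MEDIATOR] + preds), response(sub, outcome))
        if fit_y is None:
            return None
        beta, cov_y, r2_y = fit_y
        out["r2"][outcome] = r2_y
        out["n_used"][outcome] = len(sub)
        b = beta[1]  # mediator coefficient
        var_b = cov_y[1, 1]
        for pi, pred in enumerate(preds):
            a_x, var_a = a[1 + pi], cov_a[1 + pi, 1 + pi]
            direct = beta[2 + pi]
            var_dir = cov_y[2 + pi, 2 + pi]
            indirect = a_x * b
            var_ind = b**2 * var_a + a_x**2 * var_b  # Sobel / delta method
            total = direct + indirect
            var_tot = var_dir + var_ind + 2 * a_x * cov_y[1, 2 + pi]
            out["paths"][(pred, outcome)] = {
                "direct": (direct, np.sqrt(var_dir)),
                "indirect": (indirect, np.sqrt(max(var_ind, 0.0))),
                "total": (total, np.sqrt(max(var_tot, 0.0))),
            }
    return out


def _bc_ci(boot: np.ndarray, theta_hat: float, level: float = 0.95):
    """Bias-corrected percentile bootstrap interval."""
    boot = boot[~np.isnan(boot)]
    B = len(boot)
    if B == 0:
        return np.nan, np.nan
    prop = np.mean(boot < theta_hat)
    prop = np.clip(prop, 1.0 / (B + 1), B / (B + 1.0))
    z0 = stats.norm.ppf(prop)
    alpha = (1.0 - level) / 2.0
    zlo, zhi = stats.norm.ppf(alpha), stats.norm.ppf(1 - alpha)
    lo_q = stats.norm.cdf(2 * z0 + zlo)
    hi_q = stats.norm.cdf(2 * z0 + zhi)
    return (float(np.quantile(boot, lo_q)), float(np.quantile(boot, hi_q)))


def mediation_bootstrap(
    table: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Bootstrap mediation analysis: movements -> shift RT -> accuracy / stress.

    All three movement predictors (swinging, rotating, sitting) enter each
    equation jointly.  Point estimates and delta-method standard errors come
    from ordinary least squares on the observed table (identical to ML point
    estimates under normal errors); confidence intervals are bias-corrected
    percentile intervals over case-resampled bootstrap replicates.  Rows
    missing stress are excluded from the stress equations only.  Resamples
    with a singular design are skipped and the achieved count reported.
    """
    needed = list(MEDIATION_PREDICTORS) + [MEDIATOR, "accuracy"]
    missing = set(needed) - set(table.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    if "stress" not in table.columns:
        table = table.assign(stress=np.nan)
    base = table.dropna(subset=needed)
    if len(base) < 10:
        raise ValueError(f"need >= 10 complete rows, got {len(base)}")

    fit = _fit_paths(base)
    if fit is None:
        raise ValueError("singular design matrix on the observed data")
    fit_std = _fit_paths(base, standardized=True)

    rng = np.random.default_rng(seed)
    n = len(base)
    keys = [(pred, outc, eff) for (pred, outc) in fit["paths"] for eff in ("direct", "indirect", "total")]
    boot_vals = {k: np.full(n_boot, np.nan) for k in keys}
    achieved = 0
    for bi in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bfit = _fit_paths(base.iloc[idx])
        if bfit is None:
            continue
        achieved += 1
        for (pred, outc), effs in bfit["paths"].items():
            for eff, (est, _se) in effs.items():
                boot_vals[(pred, outc, eff)][bi] = est
    if achieved < n_boot:
        log.info("CI based on %d of %d bootstrap samples", achieved, n_boot)

    effects: dict[tuple[str, str], dict[str, PathEstimate]] = {}
    for (pred, outc), effs in fit["paths"].items():
        effects[(pred, outc)] = {}
        for eff, (est, se) in effs.items():
            z = est / se if se > 0 else np.nan
            p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
            lo, hi = _bc_ci(boot_vals[(pred, outc, eff)], est, ci_level)
            std_est = fit_std["paths"][(pred, outc)][eff][0] if fit_std else np.nan
            effects[(pred, outc)][eff] = PathEstimate(
                estimate=float(est), se=float(se), z=float(z), p=p,
                ci_low=lo, ci_high=hi, std_estimate=float(std_est),
            )
    return MediationResult(
        effects=effects,
        r_squared={k: float(v) for k, v in fit["r2"].items()},
        n_boot_requested=n_boot,
        n_boot_achieved=achieved,
        n_used=fit["n_used"],
    )
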