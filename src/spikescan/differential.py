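"""Case-vs-control differential abundance testing.

The workhorse is the Mann-Whitney U test averaged over subject-balanced
bootstrap iterations: each iteration draws the same number of samples per
subject, so a heavily-sampled subject cannot dominate the test, and the
iteration p-values are averaged. Benjamini-Hochberg FDR adjustment is
computed against the *total* number of taxa that existed before the
abundance-reliability filter, treating the untested ones as p = 1.

Also here: the logistic age x abundance interaction test (likelihood-ratio
chi-square), grouped LOESS trajectories with pointwise standard errors, and
chi-square covariate balance checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from ._seeds import child_seed


class DifferentialError(ValueError):
    pass


@dataclass(frozen=True)
class BootstrapConfig:
    iterations: int = 100
    per_subject_k: int = 1
    seed: int = 0
    balance_groups: bool = True

    def __post_init__(self):
        if self.iterations < 1:
            raise DifferentialError("iterations must be >= 1")
        if self.per_subject_k < 1:
            raise DifferentialError("per_subject_k must be >= 1")


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _mw_normal_p(values: np.ndarray, n1: int) -> np.ndarray:
    """Two-sided tie-corrected normal-approximation p, row-wise.

    ``values`` is (B, n1+n2); the first ``n1`` columns of each row are group
    one. Continuity-corrected, matching the standard asymptotic test.
    """
    values = np.atleast_2d(values)
    B, n = values.shape
    n2 = n - n1
    ranks = st.rankdata(values, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie_term = np.zeros(B)
    for b in range(B):
        _, counts = np.unique(values[b], return_counts=True)
        tie_term[b] = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(B)
    ok = var > 0
    z = (np.abs(u1[ok] - mu) - 0.5) / np.sqrt(var[ok])
    z = np.maximum(z, 0.0)
    p[ok] = np.minimum(2.0 * st.norm.sf(z), 1.0)
    return p


def mann_whitney(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration (via the exact null distribution of U) when both
    groups have at most 8 observations and no ties are present; otherwise
    the tie-corrected continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DifferentialError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(x) <= 8 and len(y) <= 8 and no_ties:
        return float(st.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    return float(_mw_normal_p(pooled[None, :], len(x))[0])


def bootstrap_balanced_p(
    values: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    subject_ids: np.ndarray | pd.Series,
    cfg: BootstrapConfig,
) -> float:
    """Subject-balanced bootstrap-averaged Mann-Whitney p.

    Each iteration draws ``per_subject_k`` samples from every subject
    (without replacement when the subject has enough samples, with
    replacement otherwise), runs the Mann-Whitney test case-vs-control on
    the drawn values, and the arithmetic mean of iteration p-values is
    returned. Deterministic for a given seed.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    subject_ids = np.asarray(subject_ids)
    case_subj = np.unique(subject_ids[labels == "case"])
    ctrl_subj = np.unique(subject_ids[labels == "control"])
    if len(case_subj) == 0 or len(ctrl_subj) == 0:
        raise DifferentialError("each group needs at least one subject")
    k = cfg.per_subject_k
    rng = np.random.default_rng(cfg.seed)

    by_subject = {s: values[subject_ids == s] for s in np.concatenate([case_subj, ctrl_subj])}
    n1 = len(case_subj) * k
    n2 = len(ctrl_subj) * k
    B = cfg.iterations

    draws = np.empty((B, n1 + n2))
    for j, s in enumerate(np.concatenate([case_subj, ctrl_subj])):
        v = by_subject[s]
        if len(v) == k:
            draws[:, j * k : (j + 1) * k] = np.tile(v, (B, 1))
        elif len(v) > k:
            idx = np.argsort(rng.random((B, len(v))), axis=1)[:, :k]
            draws[:, j * k : (j + 1) * k] = v[idx]
        else:
            idx = rng.integers(0, len(v), size=(B, k))
            draws[:, j * k : (j + 1) * k] = v[idx]

    if n1 <= 8 and n2 <= 8:
        ps = np.array([mann_whitney(row[:n1], row[n1:]) for row in draws])
    else:
        ps = _mw_normal_p(draws, n1)
    return float(ps.mean())


# ---------------------------------------------------------------------------
# FDR


def fdr_adjust(pvalues, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up with an inflated hypothesis count.

    ``m_total`` is the number of hypotheses that existed before filtering
    (the untested ones are treated as p = 1); it must be at least the length
    of ``pvalues``. With ``m_total`` equal to the list length this is
    textbook B-H.
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DifferentialError("p-values must lie in [0, 1]")
    m = len(p) if m_total is None else int(m_total)
    if m < len(p):
        raise DifferentialError(f"m_total={m} smaller than number of p-values ({len(p)})")
    if len(p) == 0:
        return np.array([])
    padded = np.concatenate([p, np.ones(m - len(p))])
    order = np.argsort(padded, kind="stable")
    ranked = padded[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out[: len(p)]


# ---------------------------------------------------------------------------
# per-taxon pipeline


def test_all_taxa(
    rel_table,
    metadata: pd.DataFrame,
    cfg: BootstrapConfig,
    m_total: int,
    alpha: float = 0.001,
    rank: str | None = None,
) -> pd.DataFrame:
    """Bootstrap-balanced Mann-Whitney across all samples, per taxon.

    Returns one row per taxon with the raw all-samples p, the bootstrap-
    averaged p, the FDR-adjusted p (against ``m_total`` hypotheses), group
    medians, direction, and the significance flag at ``alpha``. Per-taxon
    child seeds are derived from the taxon id, so results do not depend on
    taxon iteration order.
    """
    meta = metadata.set_index("sample_id").loc[rel_table.sample_ids]
    labels = meta["group"].to_numpy()
    subjects = meta["subject_id"].to_numpy()
    rows = []
    for taxon in rel_table.taxon_ids:
        vals = rel_table.fractions.loc[taxon].to_numpy(dtype=float)
        x = vals[labels == "case"]
        y = vals[labels == "control"]
        raw_p = mann_whitney(x, y)
        taxon_cfg = BootstrapConfig(
            iterations=cfg.iterations,
            per_subject_k=cfg.per_subject_k,
            seed=child_seed(cfg.seed, "taxon", taxon),
            balance_groups=cfg.balance_groups,
        )
        boot_p = bootstrap_balanced_p(vals, labels, subjects, taxon_cfg)
        case_med = float(np.median(x))
        ctrl_med = float(np.median(y))
        rows.append(
            {
                "taxon": taxon,
                "rank": rank or "",
                "raw_p": raw_p,
                "boot_p": boot_p,
                "case_median": case_med,
                "control_median": ctrl_med,
                "direction": "case-higher" if case_med >= ctrl_med else "control-higher",
            }
        )
    result = pd.DataFrame(rows)
    if not result.empty:
        result["fdr_p"] = fdr_adjust(result["boot_p"].to_numpy(), m_total)
        result["significant"] = result["fdr_p"] < alpha
    return result


# ---------------------------------------------------------------------------
# logistic age x abundance interaction


def age_interaction_test(abundance, age_days, labels, subject_ids=None) -> dict:
    """Likelihood-ratio test for an age x abundance interaction on case status.

    Fits ``case ~ abundance + age + abundance:age`` with a logit link and
    compares against the no-interaction model by a 1-df likelihood-ratio
    chi-square. Perfect separation triggers a weakly ridge-penalised refit,
    flagged in the result.
    """
    a = np.asarray(abundance, dtype=float)
    t = np.asarray(age_days, dtype=float)
    lab = np.asarray(labels)
    y = (lab == "case").astype(float)
    if y.min() == y.max():
        raise DifferentialError("both case and control labels are required")
    if np.ptp(a) == 0:
        raise DifferentialError("constant abundance: interaction inestimable")
    if np.ptp(t) == 0:
        raise DifferentialError("no age variation: interaction inestimable")
    a_s = (a - a.mean()) / a.std()
    t_s = (t - t.mean()) / t.std()
    X_full = np.column_stack([np.ones_like(a_s), a_s, t_s, a_s * t_s])
    X_red = X_full[:, :3]
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.Logit(y, X_full).fit(disp=0, maxiter=200)
            red = sm.Logit(y, X_red).fit(disp=0, maxiter=200)
        llf_full, llf_red = full.llf, red.llf
        if not (np.isfinite(llf_full) and np.isfinite(llf_red)) or np.abs(full.params).max() > 50:
            raise np.linalg.LinAlgError
    except Exception:
        separated = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full_m = sm.Logit(y, X_full)
            red_m = sm.Logit(y, X_red)
            pf = full_m.fit_regularized(alpha=1e-3, L1_wt=0.0, disp=0, maxiter=500).params
            pr = red_m.fit_regularized(alpha=1e-3, L1_wt=0.0, disp=0, maxiter=500).params
        llf_full = full_m.loglike(np.asarray(pf))
        llf_red = red_m.loglike(np.asarray(pr))
    lr = max(0.0, 2.0 * (llf_full - llf_red))
    p = float(st.chi2.sf(lr, df=1))
    return {"p": p, "lr_stat": float(lr), "separated": separated}


# ---------------------------------------------------------------------------
# LOESS trajectories


def _loess_fit(x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float):
    """Local linear regression with tricube weights; fit and pointwise SE."""
    n = len(x)
    q = max(int(np.ceil(span * n)), 3)
    fit = np.empty(len(grid))
    l2 = np.empty(len(grid))  # sum of squared equivalent-kernel weights

    def local(x0):
        d = np.abs(x - x0)
        h = np.sort(d)[q - 1]
        if h == 0:
            h = max(d.max(), 1e-12)
        w = np.clip(1 - (d / h) ** 3, 0, 1) ** 3
        W = w
        X = np.column_stack([np.ones(n), x - x0])
        XtW = X.T * W
        A = XtW @ X
        A += np.eye(2) * 1e-12 * max(A[0, 0], 1.0)
        li = np.linalg.solve(A, XtW)[0]  # row of the smoother matrix
        return li

    rows = [local(g) for g in grid]
    for i, li in enumerate(rows):
        fit[i] = li @ y
        l2[i] = li @ li
    # residual variance from in-sample fits
    resid = y - np.array([local(xi) @ y for xi in x])
    dof = max(n - 2.0, 1.0)
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * l2)
    return fit, se


def loess_trajectory(
    age_days,
    abundance,
    labels,
    span: float = 0.75,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Per-group LOESS curve of abundance over age with pointwise SE.

    Degree-1 local regression with tricube weights on a nearest-neighbour
    bandwidth covering ``span`` of each group's points, evaluated on a
    common age grid spanning [min age, max age] inclusive.
    """
    if not 0 < span <= 1:
        raise DifferentialError("span must lie in (0, 1]")
    t = np.asarray(age_days, dtype=float)
    a = np.asarray(abundance, dtype=float)
    lab = np.asarray(labels)
    grid = np.linspace(t.min(), t.max(), n_grid)
    frames = []
    for g in pd.unique(lab):
        sel = lab == g
        if sel.sum() < 10:
            raise DifferentialError(f"group {g!r} has fewer than 10 points")
        fit, se = _loess_fit(t[sel], a[sel], grid, span)
        frames.append(pd.DataFrame({"group": g, "age_days": grid, "fit": fit, "se": se}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# covariate balance


def covariate_balance(
    covariates: pd.DataFrame,
    group_col: str = "group",
    duration_bins: tuple = (0, 3, 6, 9, 13),
) -> pd.DataFrame:
    """Chi-square balance check of each covariate against case status.

    Numeric covariates (durations, counts) are binned with ``duration_bins``
    before testing. Single-level covariates yield NA; a warning flag is set
    when any expected cell count falls below 5.
    """
    rows = []
    labels = covariates[group_col]
    for col in covariates.columns:
        if col in (group_col, "subject_id", "seroconversion_age_days"):
            continue
        vals = covariates[col]
        if np.issubdtype(vals.dtype, np.number):
            vals = pd.cut(vals, bins=[-np.inf, *duration_bins[1:-1], np.inf])
        tab = pd.crosstab(vals, labels)
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            rows.append({"covariate": col, "chi2": np.nan, "p": np.nan, "low_expected": False})
            continue
        chi2, p, _, expected = st.chi2_contingency(tab)
        rows.append(
            {
                "covariate": col,
                "chi2": float(chi2),
                "p": float(p),
                "low_expected": bool((expected < 5).any()),
            }
        )
    return pd.DataFrame(rows)
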