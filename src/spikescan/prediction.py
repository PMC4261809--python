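"""Subject-aware prediction of future case status from taxon abundance.

One feature per subject — the median relative abundance of the focal taxon
over that subject's samples inside an age window — scored by leave-one-
subject-out cross-validated logistic regression. Accuracy is the AUC over
held-out scores (the probability a random case outranks a random control,
ties counted half); significance is the 1-df likelihood-ratio chi-square of
the full-data logistic fit. No subject ever contributes to the model that
scores it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from .windows import WindowConfig, build_windows


class PredictionError(ValueError):
    pass


@dataclass
class PredictionResult:
    window: tuple  # (start_day, end_day), half-open
    auc: float
    auc_se: float
    p: float
    scores: pd.Series  # subject_id -> predicted case probability
    labels: pd.Series  # subject_id -> case/control
    n_case: int
    n_control: int
    n_excluded: int = 0  # subjects with no in-window sample
    fallback_folds: int = 0  # folds scored by the prior rate


def subject_features(
    rel_table,
    metadata: pd.DataFrame,
    taxon: str,
    window: tuple,
) -> tuple[pd.Series, pd.Series, int]:
    """Median in-window abundance of ``taxon`` per subject.

    Subjects with no sample in ``[start_day, end_day)`` are excluded; the
    exclusion count is returned. Invariant to sample ordering.
    """
    start, end = window
    meta = metadata[metadata["sample_id"].isin(set(rel_table.sample_ids))]
    in_win = meta[(meta["age_days"] >= start) & (meta["age_days"] < end)]
    if in_win.empty:
        raise PredictionError(f"no samples fall in window [{start}, {end})")
    vals = rel_table.fractions.loc[taxon]
    feats = {}
    labs = {}
    for subject_id, sub in in_win.groupby("subject_id", sort=True):
        feats[subject_id] = float(np.median(vals[list(sub["sample_id"])]))
        labs[subject_id] = sub["group"].iloc[0]
    n_excluded = meta["subject_id"].nunique() - len(feats)
    return pd.Series(feats, name="feature"), pd.Series(labs, name="group"), n_excluded


def auc(scores, labels) -> float:
    """Probability a random case outranks a random control (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    case = s[lab == "case"]
    ctrl = s[lab == "control"]
    if len(case) == 0 or len(ctrl) == 0:
        raise PredictionError("both classes required for AUC")
    ranks = st.rankdata(np.concatenate([case, ctrl]))
    r_case = ranks[: len(case)].sum()
    u = r_case - len(case) * (len(case) + 1) / 2.0
    return float(u / (len(case) * len(ctrl)))


def _hanley_mcneil_se(a: float, n1: int, n2: int) -> float:
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n2 - 1) * (q2 - a * a)) / (n1 * n2)
    return float(np.sqrt(max(var, 0.0)))


def _full_data_lrt(x: np.ndarray, y: np.ndarray) -> float:
    """1-df LRT p of the logistic slope on the full data."""
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.Logit(y, X).fit(disp=0, maxiter=200)
            null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0, maxiter=200)
        lr = max(0.0, 2.0 * (full.llf - null.llf))
    except Exception:
        # separation: the slope is unbounded but the LRT statistic is the
        # saturated-vs-null deviance difference, finite
        p1 = y.mean()
        llf_null = len(y) * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1))
        lr = max(0.0, -2.0 * llf_null)
    return float(st.chi2.sf(lr, df=1))


def loso_cv(features: pd.Series, labels: pd.Series, seed: int = 0) -> PredictionResult:
    """Leave-one-subject-out cross-validated logistic prediction.

    For every subject a logistic regression (status ~ feature) is fitted on
    the remaining subjects and the held-out subject's case probability is
    recorded. Training uses balanced class weights: otherwise the training
    prevalence depends on the held-out subject's own label (one fewer case
    when a case is held out), which under the null pushes every case's score
    below every control's and drives the AUC to 0 instead of 0.5. Folds
    whose training labels are single-class fall back to the (balanced) prior
    rate of 0.5, flagged. The reported AUC is :func:`auc` on the pooled
    held-out scores; its SE uses the Hanley-McNeil formula.
    """
    subjects = list(features.index)
    lab = labels.loc[subjects]
    n_case = int((lab == "case").sum())
    n_ctrl = int((lab == "control").sum())
    if n_case < 5 or n_ctrl < 5:
        raise PredictionError("need >= 5 subjects per group for LOSO-CV")
    x = features.to_numpy(dtype=float)
    y = (lab.to_numpy() == "case").astype(int)
    scores = np.empty(len(subjects))
    fallback = 0
    # Standard L2 shrinkage (C=1) keeps folds finite under perfect
    # separation and damps the known mild pessimistic bias of pooled
    # leave-one-out scores (each fold's slope tilts against its excluded
    # subject under the null); ranking under a real effect is unaffected.
    clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000, class_weight="balanced")
    for i in range(len(subjects)):
        mask = np.ones(len(subjects), dtype=bool)
        mask[i] = False
        ytr = y[mask]
        if ytr.min() == ytr.max():
            scores[i] = 0.5
            fallback += 1
            continue
        clf.fit(x[mask, None], ytr)
        scores[i] = float(clf.predict_proba(x[[i], None])[0, 1])
    score_s = pd.Series(scores, index=subjects, name="score")
    a = auc(score_s, lab)
    return PredictionResult(
        window=(np.nan, np.nan),
        auc=a,
        auc_se=_hanley_mcneil_se(a, n_case, n_ctrl),
        p=_full_data_lrt(x, y),
        scores=score_s,
        labels=lab,
        n_case=n_case,
        n_control=n_ctrl,
        fallback_folds=fallback,
    )


def predict_window(
    rel_table,
    metadata: pd.DataFrame,
    taxon: str,
    window: tuple,
    seed: int = 0,
) -> PredictionResult:
    """LOSO-CV prediction from one age window."""
    feats, labs, n_excluded = subject_features(rel_table, metadata, taxon, window)
    res = loso_cv(feats, labs, seed=seed)
    res.window = (window[0], window[1])
    res.n_excluded = n_excluded
    return res


def scan_prediction_windows(
    rel_table,
    metadata: pd.DataFrame,
    taxon: str,
    cfg: WindowConfig,
    seed: int = 0,
    seroconversion_ages=None,
) -> tuple[pd.DataFrame, PredictionResult | None, bool | None]:
    """LOSO-CV in every scan window; report the argmax-AUC window.

    Returns the per-window table, the best window's full result, and —
    when per-case ``seroconversion_ages`` (days) are supplied — whether
    the best window's upper age bound precedes the cohort's median
    seroconversion age, i.e. whether the predictive signal comes from
    before autoimmunity appears.
    """
    meta = metadata[metadata["sample_id"].isin(set(rel_table.sample_ids))]
    wins, _ = build_windows(meta, cfg)
    if not wins:
        raise PredictionError("no valid windows for prediction scan")
    rows = []
    best: PredictionResult | None = None
    for w in wins:
        try:
            res = predict_window(rel_table, meta, taxon, (w.start_day, w.end_day), seed=seed)
        except PredictionError:
            continue
        rows.append(
            {
                "window_index": w.index,
                "start_day": w.start_day,
                "end_day": w.end_day,
                "median_age": w.median_age,
                "auc": res.auc,
                "auc_se": res.auc_se,
                "p": res.p,
                "n_case": res.n_case,
                "n_control": res.n_control,
            }
        )
        if best is None or res.auc > best.auc:
            best = res
    table = pd.DataFrame(rows)
    precedes = None
    if seroconversion_ages is not None and best is not None:
        ages = pd.Series(seroconversion_ages).dropna()
        if len(ages):
            precedes = bool(best.window[1] < float(ages.median()))
    return table, best, precedes
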