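"""Sliding-window temporal scan for case/control abundance differences.

Samples are ordered by age and grouped into overlapping windows. Within a
window each subject is truncated to its samples nearest the window midpoint
(at most ``max_samples_per_subject``) and then collapsed to a single median
profile, so no subject dominates; case and control subject profiles are
compared by a bootstrap-averaged Mann-Whitney test with equal subject draws
per group. Windows lacking the minimum number of case or control subjects
are discarded (and logged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .differential import _mw_normal_p, mann_whitney


class WindowError(ValueError):
    pass


@dataclass(frozen=True)
class WindowConfig:
    target_samples_per_window: int = 98
    max_samples_per_subject: int = 2
    min_cases: int = 20
    min_controls: int = 20
    step: int = 10  # samples to advance between window starts
    bootstrap_iterations: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("target_samples_per_window", "max_samples_per_subject", "min_cases", "min_controls", "step"):
            if getattr(self, name) < 1:
                raise WindowError(f"{name} must be >= 1")


@dataclass
class Window:
    index: int
    start_day: int
    end_day: int  # half-open [start, end)
    median_age: float
    sample_ids: list[str]  # post-truncation
    n_case_subjects: int
    n_control_subjects: int


@dataclass
class WindowScan:
    windows: list[Window]
    results: pd.DataFrame  # window_index, taxon, boot_p, sig05, sig01
    discarded: int = 0

    def window_table(self) -> pd.DataFrame:
        rows = [
            {
                "window_index": w.index,
                "start_day": w.start_day,
                "end_day": w.end_day,
                "median_age": w.median_age,
                "n_case": w.n_case_subjects,
                "n_control": w.n_control_subjects,
                "n_samples": len(w.sample_ids),
            }
            for w in self.windows
        ]
        return pd.DataFrame(rows)


def _truncate_subject(ages: np.ndarray, midpoint: float, keep: int):
    """Indices of the ``keep`` samples nearest the window age midpoint."""
    if len(ages) <= keep:
        return list(range(len(ages)))
    order = np.argsort(np.abs(ages - midpoint), kind="stable")
    return sorted(order[:keep])


def build_windows(metadata: pd.DataFrame, cfg: WindowConfig) -> tuple[list[Window], int]:
    """Construct age-ordered sliding windows of samples.

    Starting from every ``step``-th position of the age-sorted sample
    sequence, samples are added in age order — counting each subject only up
    to ``max_samples_per_subject``, keeping the samples nearest the evolving
    window midpoint — until the post-truncation count reaches
    ``target_samples_per_window``. Windows short of ``min_cases`` /
    ``min_controls`` case/control *subjects* are discarded.

    Returns (retained windows, number discarded by the group-size gate).
    """
    meta = metadata.sort_values(["age_days", "sample_id"], kind="stable").reset_index(drop=True)
    n = len(meta)
    ages = meta["age_days"].to_numpy(dtype=float)
    sample_ids = meta["sample_id"].to_numpy()
    subj_codes, _subj_uniques = pd.factorize(meta["subject_id"])
    is_case = (meta["group"] == "case").to_numpy()
    windows: list[Window] = []
    discarded = 0
    index = 0
    for start in range(0, n, cfg.step):
        # The post-truncation size depends only on per-subject tallies
        # (sum of min(n_subject, max_samples_per_subject)), not on which
        # samples truncation keeps — so the raw extent can be found with a
        # simple counting pass and truncation applied once afterwards.
        tally: dict = {}
        truncated_count = 0
        end = start
        while end < n and truncated_count < cfg.target_samples_per_window:
            s = subj_codes[end]
            c = tally.get(s, 0)
            if c < cfg.max_samples_per_subject:
                truncated_count += 1
            tally[s] = c + 1
            end += 1
        if truncated_count < cfg.target_samples_per_window:
            break  # tail too short for a full window
        mid = 0.5 * (ages[start] + ages[end - 1])
        by_subject: dict = {}
        for i in range(start, end):
            by_subject.setdefault(subj_codes[i], []).append(i)
        kept_idx: list[int] = []
        for idxs in by_subject.values():
            arr = np.asarray(idxs)
            keep = _truncate_subject(ages[arr], mid, cfg.max_samples_per_subject)
            kept_idx.extend(arr[keep])
        kept_idx = sorted(kept_idx)
        kept_ages = ages[kept_idx]
        kept_subj = subj_codes[kept_idx]
        kept_case = is_case[kept_idx]
        n_case = len(set(kept_subj[kept_case]))
        n_ctrl = len(set(kept_subj[~kept_case]))
        if n_case < cfg.min_cases or n_ctrl < cfg.min_controls:
            discarded += 1
            continue
        windows.append(
            Window(
                index=index,
                start_day=int(kept_ages.min()),
                end_day=int(kept_ages.max()) + 1,  # half-open
                median_age=float(np.median(kept_ages)),
                sample_ids=list(sample_ids[kept_idx]),
                n_case_subjects=n_case,
                n_control_subjects=n_ctrl,
            )
        )
        index += 1
    return windows, discarded


def subject_median_profile(fractions: pd.DataFrame) -> pd.Series:
    """Per-taxon median over one subject's in-window samples (taxa x samples)."""
    return fractions.median(axis=1)


def _window_boot_p(case_vals: np.ndarray, ctrl_vals: np.ndarray, iterations: int, seed: int) -> float:
    """Bootstrap-averaged Mann-Whitney over subject profiles for one taxon.

    Each iteration resamples (with replacement) an equal number of subjects
    from each group — the smaller group's size — removing the case/control
    sampling-frequency imbalance.
    """
    rng = np.random.default_rng(seed)
    m = min(len(case_vals), len(ctrl_vals))
    ci = rng.integers(0, len(case_vals), size=(iterations, m))
    ki = rng.integers(0, len(ctrl_vals), size=(iterations, m))
    draws = np.concatenate([case_vals[ci], ctrl_vals[ki]], axis=1)
    if m <= 8:
        from .differential import mann_whitney as _mw

        return float(np.mean([_mw(row[:m], row[m:]) for row in draws]))
    return float(_mw_normal_p(draws, m).mean())


def scan(rel_table, metadata: pd.DataFrame, cfg: WindowConfig, taxa=None) -> WindowScan:
    """Run the sliding-window case/control scan for the given taxa.

    Per window and taxon: subject median profiles -> bootstrap-averaged
    Mann-Whitney p -> significance flags at 0.05 and 0.01 (reported
    unadjusted, as the scan is descriptive of *when* a difference exists).
    Deterministic for a given seed and invariant to input row order.
    """
    meta = metadata[metadata["sample_id"].isin(set(rel_table.sample_ids))]
    windows, discarded = build_windows(meta, cfg)
    taxa = list(taxa) if taxa is not None else list(rel_table.taxon_ids)
    missing = set(taxa) - set(rel_table.taxon_ids)
    if missing:
        raise WindowError(f"taxa absent from table: {sorted(missing)}")
    frac_arr = rel_table.fractions.loc[taxa].to_numpy() if taxa else np.empty((0, 0))
    col_of = {sid: j for j, sid in enumerate(rel_table.sample_ids)}
    subj_of = dict(zip(meta["sample_id"], meta["subject_id"]))
    group_of = dict(zip(meta["subject_id"], meta["group"]))
    rows = []
    for w in windows:
        cols_by_subject: dict = {}
        for sid in w.sample_ids:
            cols_by_subject.setdefault(subj_of[sid], []).append(col_of[sid])
        case_subj = sorted(s for s in cols_by_subject if group_of[s] == "case")
        ctrl_subj = sorted(s for s in cols_by_subject if group_of[s] == "control")
        for ti, taxon in enumerate(taxa):
            row_vals = frac_arr[ti]
            cv = np.array([np.median(row_vals[cols_by_subject[s]]) for s in case_subj])
            kv = np.array([np.median(row_vals[cols_by_subject[s]]) for s in ctrl_subj])
            p = _window_boot_p(
                cv,
                kv,
                cfg.bootstrap_iterations,
                child_seed(cfg.seed, "window", w.index, taxon),
            )
            rows.append(
                {
                    "window_index": w.index,
                    "taxon": taxon,
                    "boot_p": p,
                    "sig05": p < 0.05,
                    "sig01": p < 0.01,
                }
            )
    results = pd.DataFrame(rows, columns=["window_index", "taxon", "boot_p", "sig05", "sig01"])
    return WindowScan(windows=windows, results=results, discarded=discarded)


def locate_peak(scan_result: WindowScan, taxon: str) -> tuple[Window, float, float]:
    """Window minimising the averaged p for ``taxon`` (ties: earliest).

    Returns (window, median subject age in days, averaged p).
    """
    res = scan_result.results
    sub = res[res["taxon"] == taxon]
    if sub.empty:
        raise WindowError(f"no scan results for taxon {taxon!r}")
    best_idx = int(sub.loc[sub["boot_p"].idxmin(), "window_index"])
    # idxmin returns the first minimum; windows are ordered, so ties -> earliest
    best_p = float(sub["boot_p"].min())
    window = next(w for w in scan_result.windows if w.index == best_idx)
    return window, window.median_age, best_p
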