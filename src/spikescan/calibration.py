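"""Cross-platform species calibration and qPCR concordance.

Short amplicon reads resolve only a merged two-species group; a paired
subset re-sequenced with longer reads resolves the two species. A weighted
Poisson regression per species maps group abundance (coarse platform) to
species abundance (fine platform); the fitted models then impute species
abundances for every sample that has only coarse data.

Model: species pseudo-counts (fraction x depth) follow a Poisson GLM with
log link and linear predictor ``a + b * log(group pseudo-count)``,
with observation weights proportional to group abundance (mean-normalised)
— high-abundance samples are measured more reliably and are up-weighted.
In the noiseless proportional case (species = share x group) the fit is
exact: a = log(share), b = 1, deviance R-squared = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


class CalibrationError(ValueError):
    pass


@dataclass
class SpeciesFit:
    intercept: float
    slope: float
    r2_deviance: float
    degenerate: bool = False  # all-zero species on the paired subset


@dataclass
class CalibrationModel:
    species_fits: dict  # species name -> SpeciesFit
    pooled_shares: dict  # species name -> pooled share of the group
    n_pairs: int
    depth: int
    weighting: str = "group-abundance"

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "depth": self.depth,
            "weighting": self.weighting,
            "species": {
                name: {
                    "intercept": f.intercept,
                    "slope": f.slope,
                    "r2_deviance": f.r2_deviance,
                    "degenerate": f.degenerate,
                    "pooled_share": self.pooled_shares[name],
                }
                for name, f in self.species_fits.items()
            },
        }


@dataclass
class AbsoluteAbundanceRecord:
    sample_id: str
    copies: float
    cv: float
    retained: bool


def fit_calibration(
    group_fraction,
    species_fractions: dict,
    depth: int = 10_000,
) -> CalibrationModel:
    """Fit per-species weighted Poisson regressions against group abundance.

    ``species_fractions`` maps species name -> fraction array aligned with
    ``group_fraction``. Requires >= 10 paired samples with the group present
    (> 0) in at least 5. A species observed at zero in every pair gets a
    degenerate fit with share 0.
    """
    g = np.asarray(group_fraction, dtype=float)
    if len(g) < 10:
        raise CalibrationError(f"need >= 10 paired samples, got {len(g)}")
    if (g > 0).sum() < 5:
        raise CalibrationError("group abundance must be positive in >= 5 paired samples")
    pos = g > 0
    g_counts = np.maximum(g[pos] * depth, 1e-9)
    weights = g[pos] / g[pos].mean()
    X = sm.add_constant(np.log(g_counts))
    fits = {}
    shares = {}
    for name, frac in species_fractions.items():
        s = np.asarray(frac, dtype=float)
        if len(s) != len(g):
            raise CalibrationError(f"species {name!r}: length mismatch")
        # unrounded pseudo-counts keep the noiseless proportional case an
        # exact fit (deviance 0); the Poisson family is used quasi-style
        y = s[pos] * depth
        shares[name] = float(s[pos].sum() / g[pos].sum())
        if y.sum() == 0:
            fits[name] = SpeciesFit(-np.inf, 0.0, 0.0, degenerate=True)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=weights).fit()
            null = sm.GLM(
                y, np.ones((len(y), 1)), family=sm.families.Poisson(), var_weights=weights
            ).fit()
        r2 = 1.0 - res.deviance / null.deviance if null.deviance > 0 else 1.0
        fits[name] = SpeciesFit(float(res.params[0]), float(res.params[1]), float(np.clip(r2, 0.0, 1.0)))
    return CalibrationModel(fits, shares, n_pairs=len(g), depth=depth)


def impute_species(model: CalibrationModel, group_fraction) -> pd.DataFrame:
    """Predict species fractions from group fractions, per species.

    Predictions are clipped to [0, group fraction]; a group fraction of 0
    yields 0 for every species.
    """
    if not model.species_fits:
        raise CalibrationError("model has no fitted species")
    g = np.asarray(group_fraction, dtype=float)
    out = {}
    for name, f in model.species_fits.items():
        pred = np.zeros_like(g)
        if not f.degenerate:
            pos = g > 0
            log_counts = np.log(np.maximum(g[pos] * model.depth, 1e-9))
            mu = np.exp(f.intercept + f.slope * log_counts)
            pred[pos] = np.clip(mu / model.depth, 0.0, g[pos])
        out[name] = pred
    return pd.DataFrame(out)


def triplicate_qc(values, cv_threshold: float = 0.3, sample_id: str = "") -> AbsoluteAbundanceRecord:
    """QC one qPCR triplicate: mean copies, CV, and the retained flag."""
    v = np.asarray(values, dtype=float)
    if len(v) != 3:
        raise CalibrationError("exactly 3 triplicate values required")
    if (v <= 0).any():
        raise CalibrationError("copy numbers must be positive")
    mean = float(v.mean())
    cv = float(v.std(ddof=1) / mean)
    return AbsoluteAbundanceRecord(sample_id, mean, cv, retained=cv <= cv_threshold)


def qc_qpcr_table(qpcr: pd.DataFrame, cv_threshold: float = 0.3) -> list[AbsoluteAbundanceRecord]:
    return [
        triplicate_qc([row.rep1, row.rep2, row.rep3], cv_threshold, row.sample_id)
        for row in qpcr.itertuples(index=False)
    ]


def qpcr_concordance(rel_abundance, records) -> dict:
    """Poisson regression of absolute copy number on relative abundance.

    ``rel_abundance`` aligns with ``records`` (QC-failed records are
    dropped). Returns slope (log scale), its Wald p-value, and a verdict:
    concordant when slope > 0 and p < 0.01.
    """
    rel = np.asarray(rel_abundance, dtype=float)
    if len(rel) != len(records):
        raise CalibrationError("rel_abundance and records length mismatch")
    keep = [i for i, r in enumerate(records) if r.retained]
    if len(keep) < 5:
        raise CalibrationError(f"need >= 5 retained qPCR records, got {len(keep)}")
    x = rel[keep]
    y = np.array([records[i].copies for i in keep])
    # rescale copies so the Poisson variance scale is moderate; slope/p are
    # invariant to the response scale up to the dispersion, which the Wald
    # test here absorbs via a quasi-Poisson scale estimate
    X = sm.add_constant(x)
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2")
    slope = float(res.params[1])
    p = float(res.pvalues[1])
    return {
        "slope": slope,
        "p": p,
        "n": len(keep),
        "concordant": bool(slope > 0 and p < 0.01),
    }
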