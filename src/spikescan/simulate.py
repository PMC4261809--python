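"""Synthetic longitudinal case-control cohort generator.

Emulates the data structure of a monthly-sampled infant stool 16S cohort:
76 subjects (29 cases who later seroconvert to islet autoimmunity, 47
controls), samples from roughly 4-6 months until 2.2 years of age, a
dominant *Bacteroides*-like species group whose case/control divergence
peaks in infancy, overdispersed compositional read counts, technical
replicates with abundance-dependent noise, a paired fine-resolution
(long-read) platform subset that resolves the merged species pair, and
qPCR absolute abundances.

The composition model is Dirichlet-multinomial. The spike taxon's expected
fraction follows a Gaussian-in-age bump centred at ``spike_peak_age``
rising from the control level to ``spike_case_level`` in cases; a
per-subject lognormal effect gives samples from the same subject correlated
compositions, as real stool series have.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import child_rng, child_seed
from .tables import TaxonCountTable, write_counts, write_metadata

DAYS_PER_MONTH = 30.44

SPIKE_TAXON = "p__Bacteroidetes;g__Bacteroides;s__dorei_vulgatus"
SPIKE_SPECIES = (
    "p__Bacteroidetes;g__Bacteroides;s__dorei",
    "p__Bacteroidetes;g__Bacteroides;s__vulgatus",
)

# Baseline composition: Bacteroides-dominated infant gut with moderate
# Firmicutes/Actinobacteria/Proteobacteria, 20 taxa at species resolution.
DEFAULT_TAXA: dict[str, float] = {
    SPIKE_TAXON: 0.0,  # governed by the spike levels, not this weight
    "p__Bacteroidetes;g__Bacteroides;s__fragilis": 0.10,
    "p__Bacteroidetes;g__Bacteroides;s__uniformis": 0.12,
    "p__Bacteroidetes;g__Prevotella;s__copri": 0.03,
    "p__Firmicutes;g__Ruminococcus;s__bromii": 0.07,
    "p__Firmicutes;g__Ruminococcus;s__gnavus": 0.03,
    "p__Firmicutes;g__Faecalibacterium;s__prausnitzii": 0.08,
    "p__Firmicutes;g__Blautia;s__wexlerae": 0.05,
    "p__Firmicutes;g__Veillonella;s__parvula": 0.05,
    "p__Firmicutes;g__Coprococcus;s__comes": 0.04,
    "p__Firmicutes;g__Clostridium;s__unclassified": 0.04,
    "p__Firmicutes;g__Lactobacillus;s__rhamnosus": 0.02,
    "p__Firmicutes;g__Streptococcus;s__thermophilus": 0.03,
    "p__Actinobacteria;g__Bifidobacterium;s__longum": 0.09,
    "p__Actinobacteria;g__Bifidobacterium;s__breve": 0.04,
    "p__Actinobacteria;g__Collinsella;s__aerofaciens": 0.02,
    "p__Proteobacteria;g__Escherichia;s__coli": 0.05,
    "p__Proteobacteria;g__Klebsiella;s__pneumoniae": 0.02,
    "p__Proteobacteria;g__Enterobacter;s__unclassified": 0.01,
    "p__Verrucomicrobia;g__Akkermansia;s__muciniphila": 0.03,
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    """Cohort shape: who is sampled, when, and who seroconverts.

    Ages are integer days internally (one month = 30.44 days). The
    seroconversion spread is a subject-level SD: the source cohort reports a
    mean age at first persistent autoantibody of 16.8 months with SE 2.03
    over 29 cases, i.e. an SD of 2.03*sqrt(29) ~= 10.9 months.
    """

    n_cases: int = 29
    n_controls: int = 47
    first_sample_age_mean: float = 150.0  # days (~5 months)
    first_sample_age_sd: float = 18.0
    last_sample_age: float = 803.0  # days (~2.2 years)
    sampling_interval_mean: float = 36.0  # days
    sampling_interval_sd: float = 11.0
    seroconversion_age_mean_months: float = 16.8
    seroconversion_age_sd_months: float = 10.9
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise SimulationError("n_cases and n_controls must each be >= 1")
        if self.sampling_interval_mean <= 0:
            raise SimulationError("sampling interval mean must be positive")


@dataclass(frozen=True)
class CompositionSpec:
    """Compositional model parameters.

    The spike taxon's expected fraction is a logistic ramp in age — the
    group colonises every infant gut as solid food is introduced, reaching
    a group-specific plateau — plus a Gaussian bump pinned so that at the
    bump peak cases sit at ``spike_case_level`` (17.3%) and controls at
    ``spike_control_level`` (0.18%). Cases also ramp earlier and higher
    (``spike_case_plateau``/``spike_case_t50``), making them several-fold
    more abundant than controls across all ages, not only at the peak.

    ``dorei_fraction_of_group`` is the expected share of the first species
    in the merged pair (~75%). ``overdispersion`` is the inverse Dirichlet
    precision (0 = exactly the expected composition); ``subject_effect_sd``
    is the SD of per-subject lognormal effects giving within-subject
    correlation.
    """

    taxa: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TAXA))
    spike_taxon: str = SPIKE_TAXON
    spike_peak_age: float = 231.0  # days (~7.6 months)
    spike_width_days: float = 50.0  # SD of each subject's Gaussian age bump
    spike_timing_sd: float = 30.0  # SD of per-subject bump timing around the peak
    spike_case_level: float = 0.173  # expected case fraction at the peak
    spike_control_level: float = 0.0018  # expected control fraction at the peak
    spike_base: float = 0.001  # pre-colonisation floor
    spike_control_plateau: float = 0.05
    spike_control_t50: float = 500.0  # days at half the control plateau
    spike_case_plateau: float = 0.12
    spike_case_t50: float = 400.0
    spike_ramp_scale: float = 45.0  # logistic steepness, days
    dorei_fraction_of_group: float = 0.75
    overdispersion: float = 0.02
    reads_per_sample_mean: float = 50_000.0
    reads_per_sample_log_sd: float = 0.35
    replicate_noise_scale: float = 0.35
    subject_effect_sd: float = 0.3  # lognormal SD on each subject's ramp level
    spike_subject_sd: float = 1.0  # lognormal SD on each subject's bump amplitude

    def __post_init__(self):
        if any(v < 0 for v in self.taxa.values()):
            raise SimulationError("baseline concentrations must be >= 0")
        for lvl in (self.spike_case_level, self.spike_control_level):
            if not 0 <= lvl <= 1:
                raise SimulationError("spike levels must lie in [0, 1]")
        if not 0 <= self.dorei_fraction_of_group <= 1:
            raise SimulationError("dorei_fraction_of_group must lie in [0, 1]")
        if self.overdispersion < 0:
            raise SimulationError("overdispersion must be >= 0")
        if self.spike_taxon not in self.taxa:
            raise SimulationError(f"spike taxon {self.spike_taxon!r} not in taxon list")


# ---------------------------------------------------------------------------
# metadata / covariates


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate sample metadata and per-subject covariates.

    Every subject follows a monotone-increasing schedule from around
    ``first_sample_age`` to ``last_sample_age`` with jittered intervals;
    cases carry a seroconversion age truncated to lie after their first
    sample. Covariates are drawn from identical distributions for both
    groups (balanced by construction); see :func:`generate_covariates` for
    injecting imbalance.
    """
    rng = child_rng(spec.rng_seed, "cohort")
    rows = []
    subjects = [(f"case{i:03d}", "case") for i in range(1, spec.n_cases + 1)]
    subjects += [(f"ctrl{i:03d}", "control") for i in range(1, spec.n_controls + 1)]
    sero_ages = {}
    for subject_id, group in subjects:
        first = max(60.0, rng.normal(spec.first_sample_age_mean, spec.first_sample_age_sd))
        age = first
        ages = []
        while age <= spec.last_sample_age:
            ages.append(int(round(age)))
            gap = rng.normal(spec.sampling_interval_mean, spec.sampling_interval_sd)
            age += max(7.0, gap)
        if not ages:
            ages = [int(round(first))]
        for k, a in enumerate(ages, start=1):
            rows.append(
                {
                    "sample_id": f"{subject_id}_s{k:02d}",
                    "subject_id": subject_id,
                    "age_days": a,
                    "group": group,
                    "platform": "hiseq",
                    "replicate_group": "",
                }
            )
        if group == "case":
            mean_d = spec.seroconversion_age_mean_months * DAYS_PER_MONTH
            sd_d = spec.seroconversion_age_sd_months * DAYS_PER_MONTH
            sero = rng.normal(mean_d, sd_d)
            while sero <= first:  # truncated: seroconversion follows sampling onset
                sero = rng.normal(mean_d, sd_d)
            sero_ages[subject_id] = int(round(sero))
    metadata = pd.DataFrame(rows)
    covariates = generate_covariates(
        [s for s, _ in subjects],
        {s: g for s, g in subjects},
        sero_ages,
        seed=child_seed(spec.rng_seed, "covariates"),
    )
    return metadata, covariates


def generate_covariates(
    subject_ids: Sequence[str],
    groups: Mapping[str, str],
    sero_ages: Mapping[str, int] | None = None,
    seed: int = 0,
    imbalance: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-subject covariates, identically distributed across groups.

    ``imbalance`` maps a covariate name to a probability shift applied to
    cases only (used to exercise the chi-square balance check):
    ``{"delivery_mode": 0.4}`` raises the caesarean probability by 0.4 in
    cases.
    """
    rng = np.random.default_rng(seed)
    imbalance = imbalance or {}
    rows = []
    for sid in subject_ids:
        case = groups[sid] == "case"
        p_csec = 0.16 + (imbalance.get("delivery_mode", 0.0) if case else 0.0)
        delivery = "csection" if rng.random() < min(p_csec, 1.0) else "vaginal"
        excl_bf = int(rng.integers(0, 7))
        if case and "breastfeeding_exclusive_months" in imbalance:
            excl_bf = min(6, excl_bf + int(round(6 * imbalance["breastfeeding_exclusive_months"])))
        total_bf = excl_bf + int(rng.integers(0, 7))
        abx = int(rng.poisson(1.5 + (imbalance.get("antibiotic_courses", 0.0) if case else 0.0)))
        rows.append(
            {
                "subject_id": sid,
                "group": groups[sid],
                "delivery_mode": delivery,
                "breastfeeding_exclusive_months": excl_bf,
                "breastfeeding_total_months": total_bf,
                "antibiotic_courses": abx,
                "seroconversion_age_days": (sero_ages or {}).get(sid, np.nan),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# counts


def _spike_params(group: str, comp: CompositionSpec):
    if group == "case":
        return comp.spike_case_plateau, comp.spike_case_t50, comp.spike_case_level
    return comp.spike_control_plateau, comp.spike_control_t50, comp.spike_control_level


def _ramp(age, plateau, t50, scale):
    return plateau / (1.0 + np.exp(-(np.asarray(age, dtype=float) - t50) / scale))


def _bump_shrink(comp: CompositionSpec) -> float:
    """Attenuation of the population-mean bump by timing jitter.

    Individual bumps of width w centred at N(peak, timing_sd) average to a
    Gaussian of width sqrt(w^2 + timing_sd^2) whose height at the peak is
    w / sqrt(w^2 + timing_sd^2); amplitudes are divided by this so the
    population mean still passes through the printed peak levels.
    """
    w, st = comp.spike_width_days, comp.spike_timing_sd
    return w / np.sqrt(w * w + st * st)


def _spike_amplitude(group: str, comp: CompositionSpec) -> float:
    """Per-subject bump amplitude (before the subject's lognormal factor)."""
    plateau, t50, level = _spike_params(group, comp)
    ramp_at_peak = float(_ramp(comp.spike_peak_age, plateau, t50, comp.spike_ramp_scale))
    return (level - comp.spike_base - ramp_at_peak) / _bump_shrink(comp)


def spike_fraction(age_days, group, comp: CompositionSpec):
    """Population-mean spike-taxon fraction at an age for a group.

    Logistic colonisation ramp plus the timing-jitter-averaged Gaussian
    bump; passes exactly through the group's peak level at
    ``spike_peak_age``.
    """
    age = np.asarray(age_days, dtype=float)
    plateau, t50, level = _spike_params(group, comp)
    ramp = _ramp(age, plateau, t50, comp.spike_ramp_scale)
    width_eff = np.sqrt(comp.spike_width_days**2 + comp.spike_timing_sd**2)
    pop_bump = np.exp(-0.5 * ((age - comp.spike_peak_age) / width_eff) ** 2)
    ramp_at_peak = float(_ramp(comp.spike_peak_age, plateau, t50, comp.spike_ramp_scale))
    return np.clip(comp.spike_base + ramp + (level - comp.spike_base - ramp_at_peak) * pop_bump, 0.0, 1.0)


def _compose_fractions(f_spike: float, comp: CompositionSpec, taxa: list, i_spike: int) -> np.ndarray:
    """Full composition vector given the spike taxon's fraction."""
    weights = np.array([comp.taxa[t] for t in taxa], dtype=float)
    rest = weights.copy()
    rest[i_spike] = 0.0
    if rest.sum() <= 0:
        f = np.zeros_like(rest)
        f[i_spike] = 1.0
        return f
    f = rest / rest.sum() * (1.0 - f_spike)
    f[i_spike] = f_spike
    return f


def generate_counts(
    metadata: pd.DataFrame,
    comp: CompositionSpec,
    seed: int = 0,
    shallow_sample_ids: Sequence[str] = (),
    shallow_depth: int = 5_000,
) -> TaxonCountTable:
    """Dirichlet-multinomial counts for every sample in ``metadata``.

    Per-subject lognormal multipliers (mean 1) on the spike fraction and on
    the other taxa's weights make repeated samples of one subject
    correlated. ``shallow_sample_ids`` are drawn at ``shallow_depth`` reads
    to exercise the depth filter.
    """
    if metadata.empty:
        raise SimulationError("metadata is empty")
    taxa = list(comp.taxa)
    n_taxa = len(taxa)
    shallow = set(shallow_sample_ids)
    unknown = shallow - set(metadata["sample_id"])
    if unknown:
        raise SimulationError(f"unknown sample ids: {sorted(unknown)}")

    cols = {}
    sd = comp.subject_effect_sd
    bump_sd = comp.spike_subject_sd
    i_spike = taxa.index(comp.spike_taxon)
    for subject_id, sub in metadata.groupby("subject_id", sort=True):
        srng = child_rng(seed, "counts", subject_id)
        # mean-one lognormal subject effects: ramp level, bump amplitude,
        # and background-composition tilts
        ramp_mult = float(np.exp(srng.normal(-0.5 * sd * sd, sd))) if sd > 0 else 1.0
        bump_mult = float(np.exp(srng.normal(-0.5 * bump_sd * bump_sd, bump_sd))) if bump_sd > 0 else 1.0
        peak_age = (
            float(srng.normal(comp.spike_peak_age, comp.spike_timing_sd))
            if comp.spike_timing_sd > 0
            else comp.spike_peak_age
        )
        bg_tilt = np.exp(srng.normal(0.0, sd, size=n_taxa)) if sd > 0 else np.ones(n_taxa)
        bg_tilt[i_spike] = 1.0
        group = sub["group"].iloc[0]
        plateau, t50, _level = _spike_params(group, comp)
        amp = _spike_amplitude(group, comp)
        for row in sub.itertuples(index=False):
            ramp = float(_ramp(row.age_days, plateau, t50, comp.spike_ramp_scale))
            bump = float(np.exp(-0.5 * ((row.age_days - peak_age) / comp.spike_width_days) ** 2))
            f_spike = float(
                np.clip(comp.spike_base + ramp * ramp_mult + amp * bump * bump_mult, 0.0, 0.95)
            )
            f = _compose_fractions(f_spike, comp, taxa, i_spike)
            f_bg = f * bg_tilt
            bg_sum = f_bg.sum() - f_bg[i_spike]
            if bg_sum > 0:
                f_bg *= (1.0 - f_spike) / bg_sum
            f_bg[i_spike] = f_spike
            f = f_bg
            if comp.overdispersion > 0:
                alpha = np.maximum(f / comp.overdispersion, 1e-9)
                p = srng.dirichlet(alpha)
            else:
                p = f
            if row.sample_id in shallow:
                depth = shallow_depth
            else:
                mu = np.log(comp.reads_per_sample_mean) - 0.5 * comp.reads_per_sample_log_sd**2
                depth = int(round(np.exp(srng.normal(mu, comp.reads_per_sample_log_sd))))
                depth = max(depth, 1)
            cols[row.sample_id] = srng.multinomial(depth, p)

    counts = pd.DataFrame(
        {sid: cols[sid] for sid in metadata["sample_id"]}, index=pd.Index(taxa, name="taxon_id")
    )
    lineage = pd.Series(taxa, index=counts.index, name="lineage")
    return TaxonCountTable(counts, lineage)


# ---------------------------------------------------------------------------
# technical replicates


def replicate_noise_sd(fraction: np.ndarray, scale: float) -> np.ndarray:
    """Per-taxon lognormal noise SD; larger at low abundance.

    Calibrated so the SD equals ``scale`` at 1% relative abundance and grows
    as 1/sqrt(abundance) below it, emulating the sharp rise of technical
    variance at low abundance.
    """
    f = np.maximum(fraction, 1e-6)
    return np.minimum(scale * np.sqrt(0.01 / f), 2.0)


def generate_replicates(
    table: TaxonCountTable,
    comp: CompositionSpec,
    k: int = 2,
    sample_ids: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[TaxonCountTable, pd.DataFrame]:
    """Create ``k`` technical replicates per chosen sample.

    Each replicate perturbs the sample's empirical composition with
    abundance-dependent multiplicative lognormal noise, renormalises, and
    redraws reads multinomially at the sample's depth. With
    ``replicate_noise_scale`` 0 the replicates are independent multinomial
    resamples only.

    Returns the replicate-only table and the metadata rows for the new
    columns (replicate_group = the source sample id).
    """
    if k < 2:
        raise SimulationError("k must be >= 2")
    ids = list(sample_ids) if sample_ids is not None else table.sample_ids
    unknown = set(ids) - set(table.sample_ids)
    if unknown:
        raise SimulationError(f"unknown sample ids: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    cols = {}
    meta_rows = []
    for sid in ids:
        base = table.counts[sid].to_numpy()
        depth = int(base.sum())
        p_hat = base / depth if depth > 0 else np.full(len(base), 1.0 / len(base))
        for r in range(1, k + 1):
            if comp.replicate_noise_scale > 0:
                sd = replicate_noise_sd(p_hat, comp.replicate_noise_scale)
                p = p_hat * np.exp(rng.normal(0.0, 1.0, size=len(p_hat)) * sd)
                p = p / p.sum()
            else:
                p = p_hat
            rep_id = f"{sid}_rep{r}"
            cols[rep_id] = rng.multinomial(depth, p)
            meta_rows.append({"sample_id": rep_id, "replicate_group": sid})
    counts = pd.DataFrame(cols, index=table.counts.index)
    return TaxonCountTable(counts, table.lineage.copy()), pd.DataFrame(meta_rows)


# ---------------------------------------------------------------------------
# fine-resolution platform subset


def generate_fine_platform_subset(
    table: TaxonCountTable,
    comp: CompositionSpec,
    n_samples: int = 93,
    seed: int = 0,
) -> TaxonCountTable:
    """Species-resolved re-sequencing of the samples richest in the group.

    Emulates longer-read re-sequencing that splits the merged species pair:
    the ``n_samples`` samples with the highest group abundance get the group
    count split binomially at ``dorei_fraction_of_group`` into two species
    rows; all other taxa are carried over unchanged.
    """
    if comp.spike_taxon not in table.taxon_ids:
        raise SimulationError(f"spike taxon {comp.spike_taxon!r} absent from table")
    if n_samples > len(table.sample_ids):
        raise SimulationError(
            f"n_samples={n_samples} exceeds available samples ({len(table.sample_ids)})"
        )
    rng = np.random.default_rng(seed)
    group_counts = table.counts.loc[comp.spike_taxon]
    chosen = list(group_counts.sort_values(ascending=False).index[:n_samples])
    chosen = [s for s in table.sample_ids if s in set(chosen)]  # stable order
    sub = table.counts.loc[:, chosen]
    group = sub.loc[comp.spike_taxon].to_numpy()
    dorei = rng.binomial(group, comp.dorei_fraction_of_group)
    vulgatus = group - dorei
    out = sub.drop(index=comp.spike_taxon)
    sp1, sp2 = SPIKE_SPECIES
    out = pd.concat(
        [
            out,
            pd.DataFrame([dorei, vulgatus], index=[sp1, sp2], columns=chosen),
        ]
    )
    out.index.name = "taxon_id"
    lineage = pd.Series(out.index, index=out.index, name="lineage")
    return TaxonCountTable(out.astype(np.int64), lineage)


def paired_calibration_frame(
    coarse: TaxonCountTable, fine: TaxonCountTable, spike_taxon: str = SPIKE_TAXON
) -> pd.DataFrame:
    """Pair coarse group fractions with fine species fractions per sample."""
    sp1, sp2 = SPIKE_SPECIES
    shared = [s for s in fine.sample_ids if s in set(coarse.sample_ids)]
    ct = coarse.counts[shared]
    ft = fine.counts[shared]
    rows = []
    for sid in shared:
        rows.append(
            {
                "sample_id": sid,
                "group_fraction": ct.loc[spike_taxon, sid] / ct[sid].sum(),
                "species1_fraction": ft.loc[sp1, sid] / ft[sid].sum(),
                "species2_fraction": ft.loc[sp2, sid] / ft[sid].sum(),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR


def generate_qpcr(
    table: TaxonCountTable,
    taxa: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
    noise: float = 0.3,
    triplicate_noise: float = 0.1,
    n_high_variance: int = 6,
    total_load: float = 1.0e6,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample qPCR copy numbers in triplicate for a taxon set.

    Copies are proportional to the taxa's summed relative abundance times a
    constant total bacterial load, with between-sample lognormal noise
    (``noise``) and within-triplicate lognormal noise (``triplicate_noise``).
    ``n_high_variance`` samples get 8x the triplicate noise, emulating the
    failed reactions a CV filter later discards.
    """
    if noise < 0 or triplicate_noise < 0:
        raise SimulationError("noise must be >= 0")
    taxa = list(taxa) if taxa is not None else [SPIKE_TAXON]
    if not taxa:
        raise SimulationError("empty taxon selection")
    missing = set(taxa) - set(table.taxon_ids)
    if missing:
        raise SimulationError(f"taxa absent from table: {sorted(missing)}")
    ids = list(sample_ids) if sample_ids is not None else table.sample_ids
    rng = np.random.default_rng(seed)
    noisy = set(rng.choice(ids, size=min(n_high_variance, len(ids)), replace=False)) if n_high_variance else set()
    totals = table.counts[ids].sum(axis=0)
    rel = table.counts.loc[taxa, ids].sum(axis=0) / totals
    rows = []
    for sid in ids:
        mean_copies = max(rel[sid], 1e-8) * total_load
        if noise > 0:
            mean_copies *= np.exp(rng.normal(0.0, noise))
        trip_sd = triplicate_noise * (8.0 if sid in noisy else 1.0)
        reps = mean_copies * (np.exp(rng.normal(0.0, trip_sd, size=3)) if trip_sd > 0 else np.ones(3))
        rows.append({"sample_id": sid, "rep1": reps[0], "rep2": reps[1], "rep3": reps[2]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# convenience: full study bundle


def null_composition(comp: CompositionSpec | None = None) -> CompositionSpec:
    """Composition with no case/control difference (case curve = control)."""
    comp = comp or CompositionSpec()
    return replace(
        comp,
        spike_case_level=comp.spike_control_level,
        spike_case_plateau=comp.spike_control_plateau,
        spike_case_t50=comp.spike_control_t50,
    )


def simulate_study(
    spec: CohortSpec | None = None,
    comp: CompositionSpec | None = None,
    n_replicate_samples: int = 30,
    replicate_k: int = 2,
    n_fine_samples: int = 93,
    n_qpcr_samples: int = 28,
    n_shallow: int = 3,
) -> dict:
    """Generate the complete input bundle for one synthetic study."""
    spec = spec or CohortSpec()
    comp = comp or CompositionSpec()
    seed = spec.rng_seed
    metadata, covariates = generate_cohort(spec)
    rng = child_rng(seed, "shallow-pick")
    shallow = list(rng.choice(metadata["sample_id"], size=min(n_shallow, len(metadata)), replace=False)) if n_shallow else []
    table = generate_counts(metadata, comp, seed=child_seed(seed, "counts"), shallow_sample_ids=shallow)
    rep_rng = child_rng(seed, "replicate-pick")
    deep = [s for s in table.sample_ids if s not in set(shallow)]
    rep_ids = list(rep_rng.choice(deep, size=min(n_replicate_samples, len(deep)), replace=False))
    replicates, rep_meta = generate_replicates(
        table, comp, k=replicate_k, sample_ids=rep_ids, seed=child_seed(seed, "replicates")
    )
    fine = generate_fine_platform_subset(
        table.subset_samples(deep), comp, n_samples=min(n_fine_samples, len(deep)), seed=child_seed(seed, "fine")
    )
    qpcr_rng = child_rng(seed, "qpcr-pick")
    mid = metadata[(metadata["age_days"] >= 200) & (metadata["age_days"] <= 350)]
    qpcr_pool = [s for s in mid["sample_id"] if s in set(deep)]
    qpcr_ids = list(qpcr_rng.choice(qpcr_pool, size=min(n_qpcr_samples, len(qpcr_pool)), replace=False))
    qpcr = generate_qpcr(table, sample_ids=qpcr_ids, seed=child_seed(seed, "qpcr"))
    return {
        "spec": spec,
        "comp": comp,
        "metadata": metadata,
        "covariates": covariates,
        "counts": table,
        "replicates": replicates,
        "replicate_metadata": rep_meta,
        "fine_counts": fine,
        "qpcr": qpcr,
        "shallow_sample_ids": shallow,
    }


def write_study(bundle: dict, out_dir: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write a simulated study bundle as TSV files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = list(header_lines)
    write_counts(bundle["counts"], out / "counts.tsv", hdr)
    write_counts(bundle["replicates"], out / "replicates.tsv", hdr)
    write_counts(bundle["fine_counts"], out / "fine_counts.tsv", hdr)
    meta = bundle["metadata"]
    write_metadata(meta, out / "metadata.tsv", hdr)
    rep_meta = bundle["replicate_metadata"]
    if not rep_meta.empty:
        src = meta.set_index("sample_id")
        rep_full = rep_meta.copy()
        origin = rep_full["replicate_group"]
        for col in ("subject_id", "age_days", "group", "platform"):
            rep_full[col] = origin.map(src[col]).to_numpy()
        write_metadata(rep_full[list(meta.columns)], out / "replicate_metadata.tsv", hdr)
    write_metadata(bundle["covariates"], out / "covariates.tsv", hdr)
    write_metadata(bundle["qpcr"], out / "qpcr.tsv", hdr)
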