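"""End-to-end pipeline: simulate -> preprocess -> diff -> windows ->
calibrate -> predict -> report.

One master seed feeds named child streams per stage, so toggling a stage
never perturbs another's randomness and a fixed seed reproduces every
output byte-for-byte. Each output file carries a provenance header (tool
version, config hash, seed); a state file records completed stages so an
interrupted run resumes where it stopped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import child_seed
from .calibration import fit_calibration, impute_species, qc_qpcr_table, qpcr_concordance
from .differential import BootstrapConfig, covariate_balance, test_all_taxa
from .prediction import predict_window
from .simulate import (
    DAYS_PER_MONTH,
    SPIKE_TAXON,
    CohortSpec,
    CompositionSpec,
    null_composition,
    paired_calibration_frame,
    simulate_study,
    write_study,
)
from .tables import (
    RANKS,
    aggregate_rank,
    apply_cutoff,
    filter_low_depth,
    rarefy,
    read_tables,
    to_relative,
    write_counts,
)
from .windows import WindowConfig, locate_peak, scan

log = logging.getLogger("spikescan")

STAGES = ("simulate", "preprocess", "diff", "windows", "calibrate", "predict")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "spikescan_run"
    seed: int = 0
    # simulate
    simulate: bool = True
    n_cases: int = 29
    n_controls: int = 47
    null_mode: bool = False
    spike_peak_days: float = 231.0
    # preprocess
    counts_path: str | None = None
    metadata_path: str | None = None
    rarefaction_depth: int = 10_000
    cutoff: float = 0.01
    derive_cutoff: bool = False  # derive the cutoff from technical replicates
    dispersion_threshold: float = 0.35
    ranks: tuple = RANKS
    # diff
    bootstrap_iterations: int = 100
    per_subject_k: int = 1
    alpha: float = 0.001
    # windows
    window_taxon: str = SPIKE_TAXON
    target_samples_per_window: int = 98
    max_samples_per_subject: int = 2
    min_cases: int = 20
    min_controls: int = 20
    window_step: int = 10
    # predict (defaults: the 6.1-12.1 month window)
    predict_window_start: int = 186
    predict_window_end: int = 368

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # where outputs land is not semantically meaningful
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def header_lines(self) -> list[str]:
        return [
            f"spikescan {__version__}",
            f"config_hash={self.config_hash()}",
            f"seed={self.seed}",
        ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "ranks" in data:
            data["ranks"] = tuple(data["ranks"])
        return cls(**data)


def _state_path(out: Path) -> Path:
    return out / "state.json"


def _load_state(out: Path) -> dict:
    p = _state_path(out)
    return json.loads(p.read_text()) if p.exists() else {"completed": []}


def _mark_done(out: Path, stage: str, state: dict) -> None:
    state["completed"] = sorted(set(state["completed"]) | {stage})
    _state_path(out).write_text(json.dumps(state, indent=2))


def _write_tsv(df: pd.DataFrame, path: Path, header_lines) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_all(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute every stage in fixed order; returns the result bundle.

    A stage failure raises :class:`PipelineError` naming the stage; outputs
    of completed stages remain on disk and ``resume=True`` skips them.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.simulate:
        for label, p in (("counts", config.counts_path), ("metadata", config.metadata_path)):
            if p is None or not Path(p).exists():
                raise PipelineError(f"missing {label} path: {p}")
    state = _load_state(out) if resume else {"completed": []}
    hdr = config.header_lines()
    bundle: dict = {"config": config}

    def stage(name):
        def deco(fn):
            if name in state["completed"]:
                log.info("stage %s: already complete, skipping", name)
                return
            log.info("stage %s: running", name)
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            _mark_done(out, name, state)

        return deco

    sim_dir = out / "inputs"

    @stage("simulate")
    def _simulate():
        if not config.simulate:
            return
        spec = CohortSpec(
            n_cases=config.n_cases,
            n_controls=config.n_controls,
            rng_seed=child_seed(config.seed, "simulate"),
        )
        comp = CompositionSpec(spike_peak_age=config.spike_peak_days)
        if config.null_mode:
            comp = null_composition(comp)
        study = simulate_study(spec, comp)
        write_study(study, sim_dir, hdr)

    counts_path = sim_dir / "counts.tsv" if config.simulate else Path(config.counts_path)
    metadata_path = sim_dir / "metadata.tsv" if config.simulate else Path(config.metadata_path)

    @stage("preprocess")
    def _preprocess():
        table, metadata = read_tables(counts_path, metadata_path)
        # replicate columns inform the cutoff but are excluded from analysis
        analysis_ids = metadata.loc[
            metadata["replicate_group"].isna() | (metadata["replicate_group"].astype(str) == ""),
            "sample_id",
        ]
        table = table.subset_samples(list(analysis_ids))
        cutoff = config.cutoff
        rep_counts = counts_path.parent / "replicates.tsv"
        rep_meta_path = counts_path.parent / "replicate_metadata.tsv"
        if config.derive_cutoff and rep_counts.exists() and rep_meta_path.exists():
            from .tables import derive_cutoff as _derive, read_counts

            reps = read_counts(rep_counts)
            rep_meta = pd.read_csv(rep_meta_path, sep="\t", comment="#")
            report_ = _derive(to_relative(reps), rep_meta, config.dispersion_threshold)
            cutoff = report_.cutoff
            (out / "cutoff_report.json").write_text(
                json.dumps(
                    {
                        "cutoff": report_.cutoff,
                        "dispersion_threshold": report_.dispersion_threshold,
                        "n_replicate_groups": report_.n_groups,
                        "bin_centers": list(report_.bin_centers),
                        "dispersion": [None if np.isnan(v) else v for v in report_.dispersion],
                    },
                    indent=2,
                )
            )
        table, excluded = filter_low_depth(table, config.rarefaction_depth)
        (out / "excluded_samples.txt").write_text("\n".join(excluded) + ("\n" if excluded else ""))
        table = rarefy(table, config.rarefaction_depth, seed=child_seed(config.seed, "rarefy"))
        rel = to_relative(table, config.rarefaction_depth)
        for rank in config.ranks:
            rel_rank = aggregate_rank(rel, rank)
            kept, m_total = apply_cutoff(rel_rank, cutoff)
            frame = kept.fractions.copy()
            frame.insert(0, "lineage", kept.lineage)
            frame.index.name = "taxon_id"
            with open(out / f"rel_{rank}.tsv", "w") as fh:
                for line in hdr + [f"m_total={m_total}", f"rarefaction_depth={config.rarefaction_depth}"]:
                    fh.write(f"# {line}\n")
                frame.to_csv(fh, sep="\t")
        meta_kept = metadata[metadata["sample_id"].isin(set(table.sample_ids))]
        _write_tsv(meta_kept, out / "metadata_kept.tsv", hdr)

    def _load_rank(rank):
        path = out / f"rel_{rank}.tsv"
        m_total = None
        for line in path.read_text().splitlines():
            if line.startswith("# m_total="):
                m_total = int(line.split("=", 1)[1])
            if not line.startswith("#"):
                break
        df = pd.read_csv(path, sep="\t", comment="#").set_index("taxon_id")
        lineage = df.pop("lineage")
        from .tables import RelativeAbundanceTable

        rel = RelativeAbundanceTable.__new__(RelativeAbundanceTable)
        rel.fractions = df
        rel.lineage = lineage
        rel.rarefaction_depth = config.rarefaction_depth
        return rel, m_total

    def _load_meta():
        return pd.read_csv(out / "metadata_kept.tsv", sep="\t", comment="#")

    @stage("diff")
    def _diff():
        from .differential import loess_trajectory

        metadata = _load_meta()
        meta_idx = None
        loess_frames = []
        for rank in config.ranks:
            rel, m_total = _load_rank(rank)
            cfg = BootstrapConfig(
                iterations=config.bootstrap_iterations,
                per_subject_k=config.per_subject_k,
                seed=child_seed(config.seed, "diff", rank),
            )
            res = test_all_taxa(rel, metadata, cfg, m_total, alpha=config.alpha, rank=rank)
            _write_tsv(res, out / f"diff_{rank}.tsv", hdr)
            if meta_idx is None:
                meta_idx = metadata.set_index("sample_id")
            for taxon in res.loc[res.get("significant", False) == True, "taxon"]:  # noqa: E712
                sub = meta_idx.loc[rel.sample_ids]
                curves = loess_trajectory(
                    sub["age_days"], rel.fractions.loc[taxon], sub["group"]
                )
                curves.insert(0, "taxon", taxon)
                curves.insert(0, "rank", rank)
                loess_frames.append(curves)
        if loess_frames:
            _write_tsv(pd.concat(loess_frames, ignore_index=True), out / "loess_curves.tsv", hdr)
        cov_path = sim_dir / "covariates.tsv"
        if cov_path.exists():
            cov = pd.read_csv(cov_path, sep="\t", comment="#")
            _write_tsv(covariate_balance(cov), out / "covariate_balance.tsv", hdr)

    @stage("windows")
    def _windows():
        metadata = _load_meta()
        rel, _ = _load_rank("species")
        taxon = config.window_taxon
        if taxon not in rel.taxon_ids:
            log.warning("window taxon %s not retained; skipping scan", taxon)
            _write_tsv(pd.DataFrame(), out / "window_scan.tsv", hdr)
            return
        cfg = WindowConfig(
            target_samples_per_window=config.target_samples_per_window,
            max_samples_per_subject=config.max_samples_per_subject,
            min_cases=config.min_cases,
            min_controls=config.min_controls,
            step=config.window_step,
            seed=child_seed(config.seed, "windows"),
        )
        sc = scan(rel, metadata, cfg, taxa=[taxon])
        merged = sc.results.merge(sc.window_table(), on="window_index")
        _write_tsv(merged, out / "window_scan.tsv", hdr)
        if not sc.results.empty:
            w, age, p = locate_peak(sc, taxon)
            (out / "window_peak.json").write_text(
                json.dumps(
                    {
                        "taxon": taxon,
                        "window_index": w.index,
                        "start_day": w.start_day,
                        "end_day": w.end_day,
                        "median_age_days": age,
                        "median_age_months": age / DAYS_PER_MONTH,
                        "boot_p": p,
                    },
                    indent=2,
                )
            )

    @stage("calibrate")
    def _calibrate():
        fine_path = sim_dir / "fine_counts.tsv"
        if not fine_path.exists():
            log.info("no fine-platform table; skipping calibration")
            return
        from .tables import read_counts

        coarse = read_counts(counts_path)
        fine = read_counts(fine_path)
        pairs = paired_calibration_frame(coarse, fine)
        model = fit_calibration(
            pairs["group_fraction"],
            {
                "species1": pairs["species1_fraction"],
                "species2": pairs["species2_fraction"],
            },
            depth=config.rarefaction_depth,
        )
        (out / "calibration.json").write_text(json.dumps(model.to_dict(), indent=2))
        totals = coarse.sample_totals()
        group_frac = (coarse.counts.loc[SPIKE_TAXON] / totals).to_numpy()
        imputed = impute_species(model, group_frac)
        imputed.insert(0, "sample_id", coarse.sample_ids)
        _write_tsv(imputed, out / "imputed_species.tsv", hdr)
        qpcr_path = sim_dir / "qpcr.tsv"
        if qpcr_path.exists():
            qpcr = pd.read_csv(qpcr_path, sep="\t", comment="#")
            records = qc_qpcr_table(qpcr)
            rel_map = pd.Series(group_frac, index=coarse.sample_ids)
            rel = rel_map.loc[qpcr["sample_id"]].to_numpy()
            conc = qpcr_concordance(rel, records)
            (out / "qpcr_concordance.json").write_text(json.dumps(conc, indent=2))

    @stage("predict")
    def _predict():
        metadata = _load_meta()
        rel, _ = _load_rank("species")
        taxon = config.window_taxon
        if taxon not in rel.taxon_ids:
            log.warning("prediction taxon %s not retained; skipping", taxon)
            return
        res = predict_window(
            rel,
            metadata,
            taxon,
            (config.predict_window_start, config.predict_window_end),
            seed=child_seed(config.seed, "predict"),
        )
        summary = {
            "window_start_day": res.window[0],
            "window_end_day": res.window[1],
            "auc": res.auc,
            "auc_se": res.auc_se,
            "p": res.p,
            "n_case": res.n_case,
            "n_control": res.n_control,
            "n_excluded": res.n_excluded,
        }
        (out / "prediction.json").write_text(json.dumps(summary, indent=2))
        scores = res.scores.rename_axis("subject_id").reset_index()
        scores["group"] = res.labels.loc[scores["subject_id"]].to_numpy()
        _write_tsv(scores, out / "prediction_scores.tsv", hdr)

    bundle["out_dir"] = str(out)
    return bundle


def report(out_dir: str | Path) -> str:
    """Human-readable summary of a completed run (idempotent)."""
    out = Path(out_dir)
    lines = ["spikescan run summary", "=" * 24]
    missing = []
    for rank in RANKS:
        p = out / f"diff_{rank}.tsv"
        if not p.exists():
            missing.append(f"diff ({rank})")
            continue
        df = pd.read_csv(p, sep="\t", comment="#")
        sig = df[df["significant"]] if "significant" in df else df.iloc[:0]
        lines.append(f"\n[{rank}] significant taxa (FDR-adjusted): {len(sig)}")
        for row in sig.itertuples(index=False):
            lines.append(
                f"  {row.taxon}  adj_p={row.fdr_p:.3g}  {row.direction}"
                f"  (case med {row.case_median:.4f} vs control {row.control_median:.4f})"
            )
    peak = out / "window_peak.json"
    if peak.exists():
        d = json.loads(peak.read_text())
        lines.append(
            f"\nwindow scan: minimum-p window for {d['taxon']} at median age "
            f"{d['median_age_days']:.0f} d ({d['median_age_months']:.1f} mo), p={d['boot_p']:.3g}"
        )
    else:
        missing.append("windows")
    pred = out / "prediction.json"
    if pred.exists():
        d = json.loads(pred.read_text())
        lines.append(
            f"prediction: AUC={d['auc']:.3f} (SE {d['auc_se']:.3f}, p={d['p']:.3g}) "
            f"in window [{d['window_start_day']}, {d['window_end_day']}) days"
        )
    cal = out / "calibration.json"
    if cal.exists():
        d = json.loads(cal.read_text())
        for name, sp in d["species"].items():
            lines.append(
                f"calibration {name}: share={sp['pooled_share']:.3f} R2={sp['r2_deviance']:.3f}"
            )
    if missing:
        lines.append("\nincomplete stages: " + ", ".join(missing))
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
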