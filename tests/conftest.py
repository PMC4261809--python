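"""Shared fixtures: small hand-made tables and one session-scoped synthetic
cohort reused by the module test files (generation at full cohort scale is
cheap but not free)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spikescan._seeds import child_seed
from spikescan.simulate import CohortSpec, CompositionSpec, generate_cohort, generate_counts
from spikescan.tables import (
    TaxonCountTable,
    aggregate_rank,
    filter_low_depth,
    rarefy,
    to_relative,
)


@pytest.fixture
def tiny_table() -> TaxonCountTable:
    counts = pd.DataFrame(
        {
            "s1": [5000, 3000, 2000],
            "s2": [1000, 8000, 1000],
        },
        index=pd.Index(["tA", "tB", "tC"], name="taxon_id"),
    )
    lineage = pd.Series(
        [
            "p__Bacteroidetes;g__Bacteroides;s__dorei",
            "p__Bacteroidetes;g__Bacteroides;s__fragilis",
            "p__Firmicutes;g__Blautia;s__wexlerae",
        ],
        index=counts.index,
        name="lineage",
    )
    return TaxonCountTable(counts, lineage)


@pytest.fixture
def tiny_metadata() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "subject_id": ["subj1", "subj2"],
            "age_days": [200, 300],
            "group": ["case", "control"],
            "platform": ["hiseq", "hiseq"],
            "replicate_group": ["", ""],
        }
    )


@pytest.fixture(scope="session")
def cohort():
    """Default-shape effect cohort: metadata, covariates, raw counts."""
    spec = CohortSpec(rng_seed=101)
    comp = CompositionSpec()
    metadata, covariates = generate_cohort(spec)
    table = generate_counts(metadata, comp, seed=child_seed(spec.rng_seed, "counts"))
    return {"spec": spec, "comp": comp, "metadata": metadata, "covariates": covariates, "table": table}


@pytest.fixture(scope="session")
def processed(cohort):
    """Depth-filtered, rarefied, species-aggregated relative abundances."""
    table, excluded = filter_low_depth(cohort["table"], 10_000)
    table = rarefy(table, 10_000, seed=202)
    rel = to_relative(table, 10_000)
    rel_species = aggregate_rank(rel, "species")
    meta = cohort["metadata"]
    meta_kept = meta[meta["sample_id"].isin(set(table.sample_ids))].reset_index(drop=True)
    return {"rel_species": rel_species, "rel": rel, "metadata": meta_kept, "excluded": excluded}
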