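"""Shared fixtures: one standard and one null synthetic experiment,
analyzed once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sgenrich.io import CountMatrix, SampleDesign
from sgenrich.simulate import SimConfig, simulate_experiment, simulate_sequences
from sgenrich.enrichment import estimate_dispersion, test_enrichment
from sgenrich.differential import run_group_analysis

STANDARD_SEED = 1
NULL_SEED = 11


@pytest.fixture(scope="session")
def standard_sim():
    """Standard four-condition scenario with planted groups (seed-pinned)."""
    cfg = SimConfig(seed=STANDARD_SEED)
    counts, design, annotation, truth = simulate_experiment(cfg)
    return {"config": cfg, "counts": counts, "design": design,
            "annotation": annotation, "truth": truth}


@pytest.fixture(scope="session")
def standard_analysis(standard_sim):
    """Full group analysis of the standard scenario."""
    res = run_group_analysis(standard_sim["counts"], standard_sim["design"],
                             standard_sim["annotation"])
    return {**standard_sim, **res}


@pytest.fixture(scope="session")
def standard_sequences(standard_sim):
    return simulate_sequences(standard_sim["truth"])


@pytest.fixture(scope="session")
def null_analysis():
    """No planted effects: calibration scenario."""
    cfg = SimConfig.null(seed=NULL_SEED)
    counts, design, annotation, truth = simulate_experiment(cfg)
    disp = estimate_dispersion(counts, design)
    tables = {c: test_enrichment(counts, design, c, disp) for c in design.conditions}
    return {"config": cfg, "counts": counts, "design": design, "truth": truth,
            "dispersion": disp, "tables": tables}


def tiny_counts(values, sample_ids=None, gene_ids=None, library_sizes=None) -> CountMatrix:
    """Hand-made CountMatrix from a nested list."""
    arr = np.asarray(values)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(arr.shape[0])]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(gene_ids=np.array(gene_ids, dtype=object), counts=arr,
                       sample_ids=list(sample_ids), library_sizes=library_sizes)


def tiny_design(sample_ids, conditions, fractions, replicates=None) -> SampleDesign:
    if replicates is None:
        replicates = list(range(1, len(sample_ids) + 1))
    return SampleDesign(pd.DataFrame({
        "sample_id": sample_ids, "condition": conditions,
        "fraction": fractions, "replicate": replicates,
    }))
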