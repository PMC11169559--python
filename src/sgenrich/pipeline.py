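"""End-to-end orchestration of the granule-transcriptome analysis.

``run_pipeline`` executes simulate -> enrichment -> differential
enrichment -> group assignment -> convergence -> resampling -> k-mers ->
overlays on synthetic data (or user-supplied counts), writing one TSV per
result table plus a JSON manifest.  Runs are fully seed-pinned: the same
config produces byte-identical outputs, and an unchanged rerun is served
from the cached outputs keyed by the config checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from sgenrich import __version__
from sgenrich.io import FRACTION_INPUT, FRACTION_IP, write_fasta, write_results
from sgenrich.simulate import SimConfig, simulate_experiment, simulate_sequences, evaluate_recovery
from sgenrich.enrichment import compute_fpkm, compute_size_factors, estimate_dispersion, test_enrichment
from sgenrich.differential import (
    apply_dea_filters,
    assign_groups,
    derive_relocated,
    test_contrast,
)
from sgenrich.robustness import DEFAULT_N_GRID, convergence_analysis, resampling_stability
from sgenrich.kmers import cluster_kmers, kmer_fold_change_matrix
from sgenrich.overlays import (
    abundance_fold_changes,
    compare_group_foldchanges,
    methylated_fraction,
    stratify_expression,
    stratum_composition,
)

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed", "simulate", "enrich", "dea", "convergence", "resample", "kmers", "overlay",
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},          # SimConfig overrides
    "enrich": {"lfc_threshold": 1.0, "fdr_threshold": 0.05},
    "dea": {"kd": "P525L_KD", "ctrl": "P525L", "reference": "WT", "fpkm_min": 1.0,
            "fdr_threshold": 0.05},
    "convergence": {"n_grid": list(DEFAULT_N_GRID)},
    "resample": {"reference": "P525L", "reps": 3},
    "kmers": {"k": 4, "n_clusters": 3},
    "overlay": {},
}


def validate_config(config: dict) -> dict:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {k: (dict(DEFAULT_CONFIG[k], **config.get(k, {})) if isinstance(DEFAULT_CONFIG[k], dict)
                  else config.get(k, DEFAULT_CONFIG[k]))
              for k in _KNOWN_KEYS}
    return merged


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _checksum(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: dict | None = None, out_dir: str | Path = "sgenrich_run",
                 force: bool = False) -> dict:
    """Run the full demo pipeline; returns the manifest dict.

    With an unchanged config and existing outputs the cached manifest is
    returned (``force=True`` recomputes).  All randomness derives from
    ``config['seed']``.
    """
    config = json.loads(json.dumps(validate_config(config or {})))
    out_dir = Path(out_dir)
    cfg_sum = _checksum(config)

    manifest_path = out_dir / "run_summary.json"
    if not force and manifest_path.exists():
        cached = json.loads(manifest_path.read_text())
        if cached.get("parameters", {}).get("config_checksum") == cfg_sum and all(
            (out_dir / f).exists() for f in cached.get("tables", [])
        ):
            logger.info("cache hit for config %s; returning cached manifest", cfg_sum[:12])
            return cached

    seed = int(config["seed"])
    sim_cfg = SimConfig(seed=seed, **config["simulate"])
    counts, design, annotation, truth = simulate_experiment(sim_cfg)
    sequences = simulate_sequences(truth)

    sf = compute_size_factors(counts, design=design)
    disp = estimate_dispersion(counts, design)
    fpkm = compute_fpkm(counts, annotation, sf, design=design)

    enrich_kw = config["enrich"]
    tables = {
        cond: test_enrichment(counts, design, cond, disp, annotation=annotation, **enrich_kw)
        for cond in design.conditions
    }

    dea_cfg = config["dea"]
    kd, ctrl, ref = dea_cfg["kd"], dea_cfg["ctrl"], dea_cfg["reference"]
    dea = test_contrast(counts, design, kd, ctrl, disp)
    de_genes = apply_dea_filters(dea, fpkm, tables, design,
                                 fdr_threshold=dea_cfg["fdr_threshold"],
                                 fpkm_min=dea_cfg["fpkm_min"])
    groups = assign_groups(de_genes, tables[kd], tables[ctrl], dea)
    groups.relocated, _, overlap_fraction = derive_relocated(
        groups.delta_enriched, tables[ref].enriched_genes)
    recovery = evaluate_recovery(groups, truth)

    profile = convergence_analysis(tables, tuple(config["convergence"]["n_grid"]))
    stability = resampling_stability(
        counts, design, config["resample"]["reference"], reps=config["resample"]["reps"],
        seed=seed + 1, dispersion=disp, annotation=annotation, **enrich_kw)

    km_cfg = config["kmers"]
    enriched_sets = {c: t.enriched_genes for c, t in tables.items() if t.enriched_genes}
    kmat = kmer_fold_change_matrix(enriched_sets, groups.invariant, sequences, k=km_cfg["k"])
    clusters = cluster_kmers(kmat, n_clusters=km_cfg["n_clusters"], seed=seed + 2)

    flags = truth.table["methylated"]
    meth = methylated_fraction(groups.sets(), flags)
    strata = stratify_expression(fpkm[design.samples(fraction=FRACTION_INPUT)].mean(axis=1))
    strat_comp = stratum_composition(strata, groups.sets())
    fc_by_fraction = {
        frac: abundance_fold_changes(counts, design, kd, ctrl, frac, disp)
        for frac in (FRACTION_IP, FRACTION_INPUT)
    }
    fc_compare = compare_group_foldchanges(groups.relocated, groups.commonly_enriched,
                                           fc_by_fraction)

    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(sequences, out_dir / "transcripts.fa")
    group_frame = groups.group_of().rename("group").to_frame()
    group_frame["relocated"] = group_frame.index.isin(groups.relocated)
    group_frame.index.name = "gene_id"

    result_tables = {
        "counts": counts.to_frame(),
        "design": design.table,
        "truth": truth.table,
        "dea": dea.table,
        "groups": group_frame.sort_index(),
        "recovery": recovery,
        "convergence": profile.table,
        "resampling": stability,
        "kmer_log2fc": kmat.join(clusters),
        "methylation": meth,
        "stratum_composition": strat_comp,
        "foldchange_comparison": fc_compare.drop(columns=["warning"]),
    }
    for cond, t in tables.items():
        result_tables[f"enrichment_{cond}"] = t.table

    params = {
        "config": config,
        "config_checksum": cfg_sum,
        "seed": seed,
        "stage_seeds": {"simulate": seed, "sequences": sim_cfg.seed + 1,
                        "resample": seed + 1, "kmeans": seed + 2},
        "version": __version__,
        "relocated_overlap_fraction": overlap_fraction,
        "group_sizes": {k: len(v) for k, v in groups.sets().items()},
        "size_factors": dict(zip(counts.sample_ids, np.round(sf, 6).tolist())),
    }
    manifest = write_results(result_tables, out_dir, params=params)
    return manifest


def make_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write the tiny well-formed and malformed files the unit tests exercise.

    Counts/design/annotation/FASTA/flags are drawn from a 30-gene
    simulation at the given seed; the malformed variants (negative count,
    duplicated gene id, design missing a sample) are edited copies.
    Returns {name: path}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed, n_genes=30, n_replicates=2, n_common=5,
                    n_delta_enriched=5, n_delta_depleted=5,
                    library_size_range=(2_000, 3_000))
    counts, design, annotation, truth = simulate_experiment(cfg)
    seqs = simulate_sequences(truth)

    paths: dict[str, Path] = {}

    def _save(name: str, writer) -> None:
        paths[name] = out_dir / name
        writer(paths[name])

    _save("counts.tsv", lambda p: counts.to_frame().to_csv(p, sep="\t"))
    _save("design.tsv", lambda p: design.table.to_csv(p, sep="\t", index=False))
    ann = annotation.table.reset_index()[["gene_id", "length", "biotype"]]
    _save("annotation.tsv", lambda p: ann.to_csv(p, sep="\t", index=False))
    _save("transcripts.fa", lambda p: write_fasta(seqs, p))
    flags = truth.table["methylated"].astype(int).rename("flag")
    _save("m6a_flags.tsv", lambda p: flags.to_csv(p, sep="\t"))
    _save("truth.tsv", lambda p: truth.table.to_csv(p, sep="\t"))

    frame = counts.to_frame()
    bad = frame.copy()
    bad.iloc[0, 0] = -3
    _save("counts_negative.tsv", lambda p: bad.to_csv(p, sep="\t"))
    dup = pd.concat([frame, frame.iloc[[0]]])
    _save("counts_duplicate_gene.tsv", lambda p: dup.to_csv(p, sep="\t"))
    short_design = design.table.iloc[:-1]
    _save("design_missing_sample.tsv", lambda p: short_design.to_csv(p, sep="\t", index=False))

    checksums = {name: hashlib.sha256(path.read_bytes()).hexdigest() for name, path in paths.items()}
    with open(out_dir / "fixtures.json", "w") as fh:
        json.dump({"seed": seed, "checksums": checksums}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
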