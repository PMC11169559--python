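"""Robustness analyses: top-N enrichment convergence and count thinning.

Enrichment convergence compares equally sized sets of top-enriched genes
across conditions over a grid of set sizes N, shrinking N to squeeze out
background noise.  Count thinning emulates without-replacement fragment
subsampling at the gene level with multivariate hypergeometric draws, so
resampled libraries hit target sizes exactly; rerunning the enrichment
calls on thinned counts measures how sensitive the classification is to
library-size variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from sgenrich.io import CountMatrix, SampleDesign
from sgenrich.enrichment import DispersionEstimate, EnrichmentTable, estimate_dispersion, test_enrichment

DEFAULT_N_GRID = (5000, 4500, 4000, 3500, 3000, 2500, 2000, 1500, 1000, 500)


@dataclass
class ConvergenceProfile:
    """Pairwise (and all-way) top-N set overlaps over a grid of N."""

    n_values: list[int]
    table: pd.DataFrame  # columns: N, pair, intersection, overlap_fraction


def rank_by_enrichment(table: EnrichmentTable, expressed_only: bool = True,
                       fpkm_min: float = 1.0) -> list[str]:
    """Genes sorted by log2FC descending; ties by ascending p, then gene id.

    With ``expressed_only`` genes are first restricted to those with mean
    FPKM above ``fpkm_min`` in IP or input (skipped when FPKM columns are
    absent/NaN).
    """
    tab = table.table
    if expressed_only and tab[["mean_ip_fpkm", "mean_input_fpkm"]].notna().any().any():
        tab = tab[tab[["mean_ip_fpkm", "mean_input_fpkm"]].max(axis=1) > fpkm_min]
    tab = tab.reset_index().sort_values(
        by=["log2FC", "pvalue", "gene_id"], ascending=[False, True, True], kind="mergesort"
    )
    return list(tab["gene_id"])


def convergence_analysis(tables: dict[str, EnrichmentTable],
                         n_grid: tuple[int, ...] = DEFAULT_N_GRID,
                         expressed_only: bool = True) -> ConvergenceProfile:
    """Top-N overlap profile among the conditions' enrichment rankings.

    For each N the top-N genes per condition are intersected pairwise and
    all-way; overlap fraction is intersection size over N.  N values
    exceeding the shared universe are truncated to it (logged in the
    profile).  Rankings are deterministic, so top-N sets are nested in N.
    """
    if any(n <= 0 for n in n_grid):
        raise ValueError("N values must be positive")
    ranks = {cond: rank_by_enrichment(t, expressed_only) for cond, t in tables.items()}
    universe = min(len(r) for r in ranks.values())
    rows = []
    n_used = []
    for n_req in sorted(set(n_grid), reverse=True):
        n = min(n_req, universe)
        n_used.append(n)
        tops = {cond: set(r[:n]) for cond, r in ranks.items()}
        for a, b in combinations(sorted(tops), 2):
            inter = len(tops[a] & tops[b])
            rows.append({"N": n, "pair": f"{a}|{b}", "intersection": inter,
                         "overlap_fraction": inter / n})
        allway = set.intersection(*tops.values())
        rows.append({"N": n, "pair": "all", "intersection": len(allway),
                     "overlap_fraction": len(allway) / n})
    return ConvergenceProfile(n_values=n_used, table=pd.DataFrame(rows))


def thin_counts(counts: CountMatrix, target_sizes, seed: int) -> CountMatrix:
    """Thin each sample to a target total by multivariate hypergeometric draws.

    Equivalent to sampling ``target`` fragments without replacement from
    the sample's aligned fragments: column sums equal the targets exactly
    and per-gene expectations are ``count * target / total``.  Targets may
    be a sequence aligned with samples or a dict by sample id; a target
    equal to the current total leaves the column untouched.
    """
    rng = np.random.default_rng(seed)
    if isinstance(target_sizes, dict):
        targets = np.array([target_sizes[s] for s in counts.sample_ids], dtype=np.int64)
    else:
        targets = np.asarray(target_sizes, dtype=np.int64)
    totals = counts.counts.sum(axis=0)
    for s, tgt, tot in zip(counts.sample_ids, targets, totals):
        if tgt > tot:
            raise ValueError(f"target {tgt} exceeds current total {tot} for sample {s}")
    new = counts.counts.copy()
    for j in range(counts.n_samples):
        if targets[j] < totals[j]:
            new[:, j] = rng.multivariate_hypergeometric(counts.counts[:, j], int(targets[j]))
    return CountMatrix(gene_ids=counts.gene_ids.copy(), counts=new,
                       sample_ids=list(counts.sample_ids))


def resampling_stability(counts: CountMatrix, design: SampleDesign, reference_condition: str,
                         reps: int = 10, seed: int = 0,
                         dispersion: DispersionEstimate | None = None,
                         annotation=None, **enrich_kw) -> pd.DataFrame:
    """Thin all other conditions to the reference library sizes and re-call.

    Every sample outside the reference condition is thinned to the mean
    IP / input library size of the reference condition (per fraction; no-op
    where the target is not smaller).  Enrichment is re-tested per
    condition for each repetition and compared with the unthinned run:
    the report gives the per-gene status agreement rate and per-status
    Jaccard index, per condition and repetition.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if reference_condition not in design.conditions:
        raise ValueError(f"reference condition {reference_condition!r} not in design")
    if dispersion is None:
        dispersion = estimate_dispersion(counts, design)

    totals = dict(zip(counts.sample_ids, counts.counts.sum(axis=0)))
    ref_target = {}
    for frac in ("IP", "input"):
        s = design.samples(reference_condition, frac)
        ref_target[frac] = int(np.mean([totals[x] for x in s])) if s else None

    targets = {}
    for _, row in design.table.iterrows():
        sid, cond, frac = row["sample_id"], row["condition"], row["fraction"]
        if cond == reference_condition or ref_target[frac] is None:
            targets[sid] = totals[sid]
        else:
            targets[sid] = min(totals[sid], ref_target[frac])

    base = {
        cond: test_enrichment(counts, design, cond, dispersion, annotation=annotation, **enrich_kw)
        for cond in design.conditions
    }
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, reps + 1):
        thinned = thin_counts(counts, targets, seed=int(rng.integers(0, 2**31 - 1)))
        disp_r = estimate_dispersion(thinned, design)
        for cond in design.conditions:
            redo = test_enrichment(thinned, design, cond, disp_r, annotation=annotation, **enrich_kw)
            merged = base[cond].table[["status"]].join(
                redo.table[["status"]], how="inner", lsuffix="_base", rsuffix="_thin")
            agree = float((merged["status_base"] == merged["status_thin"]).mean())
            row = {"rep": rep, "condition": cond, "status_agreement": agree}
            for st in ("enriched", "depleted", "invariant"):
                a = set(merged.index[merged["status_base"] == st])
                b = set(merged.index[merged["status_thin"] == st])
                union = a | b
                row[f"jaccard_{st}"] = len(a & b) / len(union) if union else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
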