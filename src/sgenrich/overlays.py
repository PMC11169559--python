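"""Group-level annotation overlays.

Given the assigned RNA groups, these routines quantify the patterns the
enrichment analysis is meant to expose: the methylated fraction per group
(with Fisher exact tests against the invariant background — an addition;
the underlying percentages are plain ratios), transcript-length
comparisons (Mann-Whitney, exact by full enumeration at small n), a
five-level expression stratification of the transcriptome, knockdown-vs-
control abundance fold-change comparisons per fraction, and a
length-matched resampling control that asks whether a group's excess
methylation survives conditioning on transcript length.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from sgenrich.io import FRACTION_INPUT, CountMatrix, SampleDesign, TranscriptAnnotation
from sgenrich.enrichment import DispersionEstimate, effective_sizes, two_group_nb_test

STRATA = ("low", "medium-low", "medium", "medium-high", "high")


def methylated_fraction(groups: dict[str, set[str]], flags: pd.Series,
                        reference: str = "invariant") -> pd.DataFrame:
    """Methylated percentage per group with a Fisher exact test vs reference.

    ``flags`` is a boolean Series by gene; genes missing from it count as
    unmethylated.  The two-sided Fisher test compares each group's 2x2
    methylated/unmethylated table against the reference group.  Empty
    groups get NA percentage.
    """
    def counts_of(genes: set[str]) -> tuple[int, int]:
        n = len(genes)
        m = int(flags.reindex(list(genes)).astype("boolean").fillna(False).sum())
        return m, n - m

    ref_m, ref_u = counts_of(groups[reference])
    rows = []
    for name, genes in groups.items():
        m, u = counts_of(genes)
        n = m + u
        pct = 100.0 * m / n if n else np.nan
        if n and name != reference:
            _, p = stats.fisher_exact([[m, u], [ref_m, ref_u]], alternative="two-sided")
        elif name == reference:
            p = 1.0
        else:
            p = np.nan
        rows.append({"group": name, "size": n, "methylated": m,
                     "percentage": pct, "fisher_p_vs_reference": p})
    return pd.DataFrame(rows).set_index("group")


def _mannwhitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic for sample a via midranks (ties shared)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    return float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2)


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of assignments."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    center = n * m / 2
    u_obs = _mannwhitney_u(a, b)
    hits = 0
    total = comb(n + m, n)
    idx_all = range(n + m)
    for pick in combinations(idx_all, n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(pick)] = True
        u = _mannwhitney_u(pooled[mask], pooled[~mask])
        if abs(u - center) >= abs(u_obs - center) - 1e-9:
            hits += 1
    return hits / total


def compare_lengths(group_a, group_b, annotation: TranscriptAnnotation,
                    exact_max_n: int = 8) -> dict:
    """Transcript-length comparison between two gene groups.

    Reports median and quartiles per group and a two-sided Mann-Whitney
    p-value: exact (full enumeration, tie-safe) when both groups have at
    most ``exact_max_n`` members, otherwise the normal approximation with
    tie correction.
    """
    a = annotation.lengths([g for g in group_a if g in annotation.gene_ids])
    b = annotation.lengths([g for g in group_b if g in annotation.gene_ids])
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must have annotated lengths")
    if len(a) <= exact_max_n and len(b) <= exact_max_n:
        p = _exact_rank_sum_p(a, b)
        method = "exact"
    else:
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(p)
        method = "asymptotic"
    q = lambda x: np.percentile(x, [25, 50, 75])
    qa, qb = q(a), q(b)
    return {
        "median_a": qa[1], "q1_a": qa[0], "q3_a": qa[2], "n_a": len(a),
        "median_b": qb[1], "q1_b": qb[0], "q3_b": qb[2], "n_b": len(b),
        "pvalue": p, "method": method,
    }


def stratify_expression(mean_fpkm: pd.Series, n_strata: int = 5,
                        expressed_min: float = 0.0) -> pd.Series:
    """Quantile expression strata (low ... high) over expressed genes.

    Bins are equal-count quantiles of the mean input-fraction FPKM of the
    genes above ``expressed_min`` (ties broken by position so counts stay
    balanced).  Genes below the floor get NA.
    """
    expressed = mean_fpkm[mean_fpkm > expressed_min]
    if len(expressed) < n_strata:
        raise ValueError("fewer expressed genes than strata")
    labels = list(STRATA) if n_strata == 5 else list(range(1, n_strata + 1))
    binned = pd.qcut(expressed.rank(method="first"), n_strata, labels=labels)
    return binned.astype(object).reindex(mean_fpkm.index)


def stratum_composition(strata: pd.Series, groups: dict[str, set[str]]) -> pd.DataFrame:
    """Per-group proportion of genes in each expression stratum."""
    order = [s for s in STRATA if s in set(strata.dropna())] or sorted(set(strata.dropna()))
    rows = {}
    for name, genes in groups.items():
        sub = strata.reindex(list(genes)).dropna()
        comp = sub.value_counts(normalize=True)
        rows[name] = [float(comp.get(s, 0.0)) for s in order]
    return pd.DataFrame(rows, index=order).T


def compare_stratum_composition(strata: pd.Series, group_a, group_b) -> tuple[float, float]:
    """Chi-square comparison of two groups' stratum count profiles."""
    counts = []
    for genes in (group_a, group_b):
        sub = strata.reindex(list(genes)).dropna()
        counts.append(sub.value_counts())
    tab = pd.concat(counts, axis=1).fillna(0.0)
    tab = tab.loc[tab.sum(axis=1) > 0]
    if np.array_equal(tab.iloc[:, 0].to_numpy(), tab.iloc[:, 1].to_numpy()):
        return 0.0, 1.0  # identical profiles: no evidence against homogeneity
    chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy().T)
    return float(chi2), float(p)


def abundance_fold_changes(counts: CountMatrix, design: SampleDesign, cond1: str,
                           cond2: str, fraction: str, dispersion: DispersionEstimate,
                           min_total: int = 1) -> pd.Series:
    """Per-gene log2FC of RNA abundance, cond1 vs cond2, within one fraction."""
    s1 = design.samples(cond1, fraction)
    s2 = design.samples(cond2, fraction)
    if not s1 or not s2:
        raise ValueError(f"missing {fraction} samples for {cond1!r} or {cond2!r}")
    samp = s2 + s1
    sub = counts.subset_samples(samp)
    eff = effective_sizes(counts, design=design)[counts.column_index(samp)]
    grp = np.array([0] * len(s2) + [1] * len(s1))
    keep = sub.counts.sum(axis=1) >= min_total
    res = two_group_nb_test(sub.counts[keep], grp, eff, dispersion.for_genes(sub.gene_ids[keep]),
                            wald_dof=dispersion.residual_dof)
    return pd.Series(res["log2FC"].to_numpy(), index=pd.Index(sub.gene_ids[keep], name="gene_id"))


def compare_group_foldchanges(group_a, group_b, fold_changes: dict[str, pd.Series],
                              min_size: int = 3) -> pd.DataFrame:
    """Compare two groups' abundance fold-change distributions per fraction.

    ``fold_changes`` maps fraction label (e.g. 'IP', 'input') to a
    per-gene log2FC Series.  Reports medians and a two-sided rank-sum
    p-value per fraction; groups smaller than ``min_size`` get summaries
    only (NA p, with a warning column).
    """
    rows = []
    for frac, fc in fold_changes.items():
        a = fc.reindex([g for g in group_a if g in fc.index]).dropna().to_numpy()
        b = fc.reindex([g for g in group_b if g in fc.index]).dropna().to_numpy()
        row = {"fraction": frac, "n_a": len(a), "n_b": len(b),
               "median_a": float(np.median(a)) if len(a) else np.nan,
               "median_b": float(np.median(b)) if len(b) else np.nan}
        row["median_diff"] = row["median_a"] - row["median_b"]
        if len(a) >= min_size and len(b) >= min_size:
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            row["pvalue"] = float(p)
            row["warning"] = ""
        else:
            row["pvalue"] = np.nan
            row["warning"] = "group smaller than minimum size; no test"
        rows.append(row)
    return pd.DataFrame(rows).set_index("fraction")


def length_matched_fraction(group, reference, lengths: pd.Series, flags: pd.Series,
                            n_resamples: int = 200, seed: int = 0,
                            n_bins: int = 10) -> dict:
    """Length-matched resampling control for a methylated-fraction excess.

    Reference genes are resampled (with replacement) to match the focal
    group's composition across length deciles (deciles of the pooled
    length distribution); each resample yields a methylated percentage.
    If the focal group's observed percentage falls inside the central 95%
    interval of the matched-resample distribution, its excess methylation
    is explained by length alone.
    """
    rng = np.random.default_rng(seed)
    group = [g for g in group if g in lengths.index]
    reference = [g for g in reference if g in lengths.index]
    pooled = lengths.reindex(group + reference)
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    gbin = np.searchsorted(edges, lengths.reindex(group).to_numpy(), side="right") - 1
    rbin = np.searchsorted(edges, lengths.reindex(reference).to_numpy(), side="right") - 1

    flag_g = flags.reindex(group).astype("boolean").fillna(False).to_numpy(dtype=bool)
    flag_r = flags.reindex(reference).astype("boolean").fillna(False).to_numpy(dtype=bool)
    observed_pct = 100.0 * flag_g.mean()
    reference_pct = 100.0 * flag_r.mean()

    ref_by_bin = {b: np.where(rbin == b)[0] for b in range(n_bins)}
    need = {b: int((gbin == b).sum()) for b in range(n_bins)}
    pcts = np.empty(n_resamples)
    for i in range(n_resamples):
        picked = []
        for b, k in need.items():
            if k == 0:
                continue
            pool = ref_by_bin[b]
            if len(pool) == 0:  # no reference gene this long; borrow nearest bin
                alt = min((bb for bb in ref_by_bin if len(ref_by_bin[bb])), key=lambda bb: abs(bb - b))
                pool = ref_by_bin[alt]
            picked.append(flag_r[rng.choice(pool, size=k, replace=True)])
        draw = np.concatenate(picked) if picked else np.array([], dtype=bool)
        pcts[i] = 100.0 * draw.mean() if len(draw) else np.nan
    lo, hi = np.nanpercentile(pcts, [2.5, 97.5])
    return {
        "group_pct": observed_pct,
        "reference_pct": reference_pct,
        "matched_mean_pct": float(np.nanmean(pcts)),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "within_ci": bool(lo <= observed_pct <= hi),
        "resampled_pcts": pcts,
    }
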