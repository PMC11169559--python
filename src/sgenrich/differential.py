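"""Cross-condition differential enrichment and RNA group assignment.

The differential-enrichment contrast is the interaction term of a
condition x fraction factorial NB GLM, equal to
``(IP1 - INP1) - (IP2 - INP2)`` on the log2 scale: how much more
IP-enriched a gene is in condition 1 than in condition 2.  Differentially
enriched genes must additionally be expressed above an FPKM floor in at
least one of the four sample types and be called enriched in at least one
of the two conditions.  Comparing a knockdown condition against its
control yields four disjoint groups — commonly enriched, KD-enriched
(gained upon knockdown), KD-depleted (lost upon knockdown), invariant —
and, against a reference wild-type enriched set, the derived "relocated"
subset of KD-enriched genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from sgenrich.io import FRACTION_INPUT, FRACTION_IP, CountMatrix, SampleDesign
from sgenrich.enrichment import (
    DispersionEstimate,
    EnrichmentTable,
    STATUS_ENRICHED,
    _wald_pvalues,
    bh_adjust,
    effective_sizes,
    nb_glm_fit,
)

GROUP_COMMON = "commonly_enriched"
GROUP_DELTA_ENRICHED = "delta_enriched"
GROUP_DELTA_DEPLETED = "delta_depleted"
GROUP_INVARIANT = "invariant"
PRIMARY_GROUPS = (GROUP_COMMON, GROUP_DELTA_ENRICHED, GROUP_DELTA_DEPLETED, GROUP_INVARIANT)


@dataclass
class DEAResult:
    """Interaction-contrast result: per-gene delta log2FC, p, FDR.

    ``delta_log2FC`` is positive when the gene is more IP-enriched in
    ``cond1`` (the first-named condition).
    """

    cond1: str
    cond2: str
    table: pd.DataFrame  # index gene_id; delta_log2FC, pvalue, FDR

    def significant(self, fdr_threshold: float = 0.05) -> set[str]:
        return set(self.table.index[self.table["FDR"] < fdr_threshold])


@dataclass
class GroupAssignment:
    """Disjoint gene groups plus the derived relocated subset."""

    commonly_enriched: set[str]
    delta_enriched: set[str]
    delta_depleted: set[str]
    invariant: set[str]
    relocated: set[str] = field(default_factory=set)
    flagged: set[str] = field(default_factory=set)  # DE + enriched in both, assigned by sign

    @property
    def universe(self) -> set[str]:
        return self.commonly_enriched | self.delta_enriched | self.delta_depleted | self.invariant

    def group_of(self) -> pd.Series:
        out = {}
        for name in PRIMARY_GROUPS:
            for g in getattr(self, name):
                out[g] = name
        return pd.Series(out, dtype=object)

    def sets(self) -> dict[str, set[str]]:
        d = {name: getattr(self, name) for name in PRIMARY_GROUPS}
        d["relocated"] = self.relocated
        return d


def test_contrast(counts: CountMatrix, design: SampleDesign, cond1: str, cond2: str,
                  dispersion: DispersionEstimate, min_total: int = 1) -> DEAResult:
    """Wald test on the condition x fraction interaction coefficient.

    The factorial NB GLM ``log mu = b0 + b1*cond1 + b2*IP + b3*cond1*IP +
    log(effective size)`` makes ``b3`` exactly the enrichment difference
    ``(IP1 - INP1) - (IP2 - INP2)``; it is reported on the log2 scale.
    """
    samp = []
    for cond in (cond1, cond2):
        for frac in (FRACTION_INPUT, FRACTION_IP):
            s = design.samples(cond, frac)
            if not s:
                raise ValueError(f"condition {cond!r} lacks {frac} samples")
            samp.extend(s)
    sub = counts.subset_samples(samp)
    eff = effective_sizes(counts, design=design)[counts.column_index(samp)]

    dt = design.table.set_index("sample_id").loc[samp]
    is_c1 = (dt["condition"] == cond1).to_numpy(dtype=float)
    is_ip = (dt["fraction"] == FRACTION_IP).to_numpy(dtype=float)
    # centered +-1/2 coding: the interaction coefficient equals the
    # contrast, and swapping the conditions is an exact sign flip of the
    # design, so estimates negate precisely even in clamped fits
    c = is_c1 - 0.5
    f = is_ip - 0.5
    X = np.column_stack([np.ones(len(samp)), c, f, c * f])

    keep = sub.counts.sum(axis=1) >= min_total
    y = sub.counts[keep]
    genes = sub.gene_ids[keep]
    phi = dispersion.for_genes(genes)

    beta, cov = nb_glm_fit(y, X, np.log(eff), phi)
    se = np.sqrt(np.maximum(cov[:, 3, 3], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta[:, 3] / se
    pvals = _wald_pvalues(z, dispersion.residual_dof)

    est = beta[:, 3] / np.log(2)
    # genes with an all-zero (condition, fraction) cell have an infinite
    # MLE; substitute the pseudo-count-stabilized cell-total contrast,
    # which is exactly antisymmetric under swapping the conditions
    cells = [(c1v, ipv) for c1v in (1.0, 0.0) for ipv in (1.0, 0.0)]
    cell_totals, cell_eff = [], []
    for c1v, ipv in cells:
        mask = (is_c1 == c1v) & (is_ip == ipv)
        cell_totals.append(y[:, mask].sum(axis=1))
        cell_eff.append(eff[mask].sum())
    degenerate = np.zeros(y.shape[0], dtype=bool)
    for t in cell_totals:
        degenerate |= t == 0
    if degenerate.any():
        lt = [np.log2((t + 0.5) / e) for t, e in zip(cell_totals, cell_eff)]
        stabilized = (lt[0] - lt[1]) - (lt[2] - lt[3])  # (IP1-INP1)-(IP2-INP2)
        est = np.where(degenerate, stabilized, est)

    all_zero = y.sum(axis=1) == 0
    pvals = np.where(all_zero, 1.0, pvals)
    est = np.where(all_zero, 0.0, est)

    tab = pd.DataFrame(
        {"delta_log2FC": est, "pvalue": pvals, "FDR": bh_adjust(pvals)},
        index=pd.Index(genes, name="gene_id"),
    )
    return DEAResult(cond1=cond1, cond2=cond2, table=tab)


def sample_type_fpkm(fpkm: pd.DataFrame, design: SampleDesign, conditions: list[str]) -> pd.DataFrame:
    """Mean FPKM per (condition, fraction) sample type, one column each."""
    cols = {}
    for cond in conditions:
        for frac in (FRACTION_IP, FRACTION_INPUT):
            s = [x for x in design.samples(cond, frac) if x in fpkm.columns]
            if s:
                cols[f"{cond}:{frac}"] = fpkm[s].mean(axis=1)
    return pd.DataFrame(cols)


def apply_dea_filters(dea: DEAResult, fpkm: pd.DataFrame, tables: dict[str, EnrichmentTable],
                      design: SampleDesign, fdr_threshold: float = 0.05,
                      fpkm_min: float = 1.0) -> set[str]:
    """Differentially enriched gene set after the expression and status filters.

    A gene qualifies when its contrast FDR is below ``fdr_threshold``, its
    mean FPKM exceeds ``fpkm_min`` in at least one of the four sample
    types (IP or input of either compared condition), and it is called
    enriched in at least one of the two conditions.
    """
    sig = dea.significant(fdr_threshold)
    enriched_somewhere = (
        tables[dea.cond1].enriched_genes | tables[dea.cond2].enriched_genes
    )
    if fpkm is None:  # no annotation: expression filter cannot apply
        return sig & enriched_somewhere
    stype = sample_type_fpkm(fpkm, design, [dea.cond1, dea.cond2])
    fpkm_pass = set(stype.index[stype.max(axis=1) > fpkm_min])
    return sig & fpkm_pass & enriched_somewhere


def assign_groups(de_genes: set[str], table_kd: EnrichmentTable, table_ctrl: EnrichmentTable,
                  dea: DEAResult) -> GroupAssignment:
    """Partition the tested universe into the four enrichment groups.

    ``table_kd`` / ``table_ctrl`` are the knockdown and control
    per-condition enrichment calls of the comparison; ``de_genes`` is the
    filtered differentially enriched set.  Gained genes (enriched upon
    knockdown only, differentially enriched) are ``delta_enriched``; lost
    genes the mirror image; genes enriched in both conditions without a
    significant difference are ``commonly_enriched``; everything else is
    ``invariant``.  A differentially enriched gene called enriched in both
    conditions is assigned by the sign of its contrast (knockdown minus
    control) and flagged.
    """
    universe = set(table_kd.table.index) | set(table_ctrl.table.index)
    enr_kd = table_kd.enriched_genes
    enr_ctrl = table_ctrl.enriched_genes
    sign_kd_minus_ctrl = dea.table["delta_log2FC"]
    if dea.cond1 != table_kd.condition:
        sign_kd_minus_ctrl = -sign_kd_minus_ctrl

    common, gained, lost, flagged = set(), set(), set(), set()
    for g in de_genes:
        in_kd = g in enr_kd
        in_ctrl = g in enr_ctrl
        if in_kd and not in_ctrl:
            gained.add(g)
        elif in_ctrl and not in_kd:
            lost.add(g)
        else:
            flagged.add(g)
            if float(sign_kd_minus_ctrl.get(g, 0.0)) > 0:
                gained.add(g)
            else:
                lost.add(g)
    common = (enr_kd & enr_ctrl) - de_genes
    invariant = universe - common - gained - lost
    return GroupAssignment(
        commonly_enriched=common,
        delta_enriched=gained,
        delta_depleted=lost,
        invariant=invariant,
        flagged=flagged,
    )


def derive_relocated(delta_enriched: set[str], enriched_reference: set[str]) -> tuple[set[str], set[str], float]:
    """Relocated RNAs: knockdown-gained genes already enriched in the reference.

    Returns the relocated set (intersection), the non-overlapping
    remainder, and the overlap fraction of the gained set.
    """
    relocated = delta_enriched & enriched_reference
    remainder = delta_enriched - enriched_reference
    fraction = len(relocated) / len(delta_enriched) if delta_enriched else 0.0
    return relocated, remainder, fraction


def run_group_analysis(counts: CountMatrix, design: SampleDesign, annotation,
                       kd: str = "P525L_KD", ctrl: str = "P525L", reference: str = "WT",
                       dispersion: DispersionEstimate | None = None,
                       fdr_threshold: float = 0.05, fpkm_min: float = 1.0,
                       **enrich_kw) -> dict:
    """Convenience wrapper: enrichment per condition, contrast, filters,
    group assignment, and relocated derivation in one call.

    Returns a dict with keys ``tables`` (per-condition EnrichmentTable),
    ``dea``, ``groups`` (GroupAssignment with relocated filled in),
    ``fpkm``, ``dispersion``, ``relocated_overlap_fraction``.
    """
    from sgenrich.enrichment import compute_fpkm, estimate_dispersion, test_enrichment

    if dispersion is None:
        dispersion = estimate_dispersion(counts, design)
    fpkm = compute_fpkm(counts, annotation, design=design) if annotation is not None else None
    tables = {
        cond: test_enrichment(counts, design, cond, dispersion, annotation=annotation, **enrich_kw)
        for cond in design.conditions
    }
    dea = test_contrast(counts, design, kd, ctrl, dispersion)
    de_genes = apply_dea_filters(dea, fpkm, tables, design,
                                 fdr_threshold=fdr_threshold, fpkm_min=fpkm_min)
    groups = assign_groups(de_genes, tables[kd], tables[ctrl], dea)
    groups.relocated, _, fraction = derive_relocated(
        groups.delta_enriched, tables[reference].enriched_genes)
    return {"tables": tables, "dea": dea, "groups": groups, "fpkm": fpkm,
            "dispersion": dispersion, "relocated_overlap_fraction": fraction}
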