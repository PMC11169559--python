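"""Interaction contrast, filters, group assignment, relocated derivation."""

import numpy as np
import pandas as pd
import pytest

from sgenrich.differential import (
    DEAResult,
    GroupAssignment,
    PRIMARY_GROUPS,
    apply_dea_filters,
    assign_groups,
    derive_relocated,
    run_group_analysis,
)
from sgenrich.differential import test_contrast as run_contrast_test
from sgenrich.enrichment import EnrichmentTable
from sgenrich.simulate import SimConfig, evaluate_recovery, simulate_experiment


def test_contrast_antisymmetry(standard_sim):
    cm, design = standard_sim["counts"], standard_sim["design"]
    disp = None
    from sgenrich.enrichment import estimate_dispersion

    disp = estimate_dispersion(cm, design)
    fwd = run_contrast_test(cm, design, "P525L_KD", "P525L", disp)
    rev = run_contrast_test(cm, design, "P525L", "P525L_KD", disp)
    np.testing.assert_allclose(fwd.table["delta_log2FC"], -rev.table["delta_log2FC"], atol=1e-6)
    np.testing.assert_allclose(fwd.table["pvalue"], rev.table["pvalue"], atol=1e-8)


def test_contrast_null_when_effects_match(standard_analysis):
    """WT_KD and P525L_KD share planted effects for every non-relocated
    gene; restricted to genes with identical effects the contrast is null."""
    truth = standard_analysis["truth"].table
    dea = run_contrast_test(standard_analysis["counts"], standard_analysis["design"],
                        "WT_KD", "P525L_KD", standard_analysis["dispersion"])
    same = truth.index[truth["effect_WT_KD"] == truth["effect_P525L_KD"]]
    sub = dea.table.loc[dea.table.index.intersection(same)]
    assert abs(sub["delta_log2FC"].mean()) < 0.1
    assert (sub["pvalue"] < 0.05).mean() < 0.08


def test_contrast_recovers_planted_difference(standard_analysis):
    truth = standard_analysis["truth"].table
    dea = standard_analysis["dea"]  # P525L_KD vs P525L
    gained = truth.index[(truth["effect_P525L_KD"] - truth["effect_P525L"]) == 2.0]
    est = dea.table.loc[dea.table.index.intersection(gained), "delta_log2FC"]
    assert est.mean() == pytest.approx(2.0, abs=0.15)


def test_contrast_missing_fraction_named():
    cfg = SimConfig(seed=3, n_genes=100, n_common=10, n_delta_enriched=10,
                    n_delta_depleted=10)
    cm, design, _, _ = simulate_experiment(cfg)
    sub_design = design.subset([s for s in design.sample_ids if s != "WT_IP_1"
                                and s != "WT_IP_2" and s != "WT_IP_3"])
    sub = cm.subset_samples(sub_design.sample_ids)
    from sgenrich.enrichment import estimate_dispersion

    disp = estimate_dispersion(sub, sub_design)
    with pytest.raises(ValueError, match="WT"):
        run_contrast_test(sub, sub_design, "WT", "P525L", disp)


def _fake_table(cond, statuses):
    tab = pd.DataFrame({"log2FC": 0.0, "pvalue": 1.0, "FDR": 1.0,
                        "status": pd.Series(statuses)})
    tab.index.name = "gene_id"
    return EnrichmentTable(condition=cond, table=tab)


def _fake_dea(estimates, fdrs, cond1="KD", cond2="CTRL"):
    tab = pd.DataFrame({"delta_log2FC": pd.Series(estimates),
                        "pvalue": pd.Series(fdrs), "FDR": pd.Series(fdrs)})
    tab.index.name = "gene_id"
    return DEAResult(cond1=cond1, cond2=cond2, table=tab)


def test_dea_filter_clauses(standard_sim):
    design = standard_sim["design"].subset(
        standard_sim["design"].samples("P525L") + standard_sim["design"].samples("P525L_KD"))
    genes = ["keep", "lowfpkm", "neverenriched"]
    dea = _fake_dea({g: 2.0 for g in genes}, {g: 0.01 for g in genes},
                    cond1="P525L_KD", cond2="P525L")
    statuses_kd = {"keep": "enriched", "lowfpkm": "enriched", "neverenriched": "invariant"}
    statuses_ctrl = {g: "invariant" for g in genes}
    tables = {"P525L_KD": _fake_table("P525L_KD", statuses_kd),
              "P525L": _fake_table("P525L", statuses_ctrl)}
    fpkm = pd.DataFrame(5.0, index=genes, columns=design.sample_ids)
    fpkm.loc["lowfpkm"] = 0.4
    kept = apply_dea_filters(dea, fpkm, tables, design)
    assert kept == {"keep"}


def test_assign_groups_definitions():
    genes = ["common", "gained", "lost", "quiet", "both_de"]
    kd = _fake_table("KD", {"common": "enriched", "gained": "enriched",
                            "lost": "invariant", "quiet": "invariant",
                            "both_de": "enriched"})
    ctrl = _fake_table("CTRL", {"common": "enriched", "gained": "invariant",
                                "lost": "enriched", "quiet": "invariant",
                                "both_de": "enriched"})
    dea = _fake_dea({g: {"both_de": 1.5}.get(g, 0.0) for g in genes},
                    {g: 0.01 if g in ("gained", "lost", "both_de") else 0.9 for g in genes})
    ga = assign_groups({"gained", "lost", "both_de"}, kd, ctrl, dea)
    assert ga.commonly_enriched == {"common"}
    assert ga.delta_enriched == {"gained", "both_de"}  # both_de by positive sign, flagged
    assert ga.delta_depleted == {"lost"}
    assert ga.invariant == {"quiet"}
    assert ga.flagged == {"both_de"}


def test_group_partition_property(standard_analysis):
    ga = standard_analysis["groups"]
    sets = [getattr(ga, name) for name in PRIMARY_GROUPS]
    total = sum(len(s) for s in sets)
    assert total == len(ga.universe)
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            assert not (sets[i] & sets[j])
    assert ga.relocated <= ga.delta_enriched


def test_group_antisymmetry(standard_analysis):
    """Swapping the compared conditions maps gained <-> lost."""
    cm, design = standard_analysis["counts"], standard_analysis["design"]
    disp = standard_analysis["dispersion"]
    tables = standard_analysis["tables"]
    fpkm = standard_analysis["fpkm"]
    dea_fwd = standard_analysis["dea"]
    dea_rev = run_contrast_test(cm, design, "P525L", "P525L_KD", disp)
    de_fwd = apply_dea_filters(dea_fwd, fpkm, tables, design)
    de_rev = apply_dea_filters(dea_rev, fpkm, tables, design)
    assert de_fwd == de_rev  # the filter is symmetric in the conditions
    ga_fwd = assign_groups(de_fwd, tables["P525L_KD"], tables["P525L"], dea_fwd)
    ga_rev = assign_groups(de_rev, tables["P525L"], tables["P525L_KD"], dea_rev)
    assert ga_fwd.delta_enriched == ga_rev.delta_depleted
    assert ga_fwd.delta_depleted == ga_rev.delta_enriched


def test_derive_relocated_set_arithmetic():
    rel, rem, frac = derive_relocated({"A", "B", "C"}, {"B", "C", "D"})
    assert rel == {"B", "C"} and rem == {"A"} and frac == pytest.approx(2 / 3)
    rel, _, frac = derive_relocated({"A"}, {"B"})
    assert rel == set() and frac == 0.0
    rel, _, frac = derive_relocated({"A", "B"}, {"A", "B", "C"})
    assert rel == {"A", "B"} and frac == 1.0
    assert derive_relocated(set(), {"A"})[2] == 0.0


def test_group_recovery_on_standard_scenario(standard_analysis):
    rec = evaluate_recovery(standard_analysis["groups"], standard_analysis["truth"])
    assert (rec["f1"] >= 0.9).all()
    assert standard_analysis["relocated_overlap_fraction"] == pytest.approx(0.75, abs=0.1)
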