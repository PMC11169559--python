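"""Statistical core: size factors, FPKM, dispersion moments, the NB GLM
Wald test, the exact conditional test, BH, and status classification."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgenrich.enrichment import (
    bh_adjust,
    classify_enrichment,
    compute_fpkm,
    compute_size_factors,
    estimate_dispersion,
    exact_conditional_pvalue,
    two_group_nb_test,
)
from sgenrich.enrichment import test_enrichment as run_enrichment_test
from sgenrich.io import TranscriptAnnotation
from tests.conftest import tiny_counts, tiny_design


# --- size factors ---------------------------------------------------------

def test_size_factors_identical_columns():
    cm = tiny_counts([[10, 10], [3, 3], [7, 7]])
    np.testing.assert_allclose(compute_size_factors(cm), [1.0, 1.0])


def test_size_factors_doubled_column():
    cm = tiny_counts([[10, 20], [4, 8], [30, 60]])
    sf = compute_size_factors(cm)
    assert sf[1] / sf[0] == pytest.approx(2.0)


def test_size_factors_match_median_of_ratios_oracle():
    counts = np.array([[12, 30, 9], [100, 210, 80], [7, 18, 5], [55, 130, 40], [3, 9, 2]])
    cm = tiny_counts(counts)
    # independent brute-force: per-gene geometric mean, per-sample median ratio
    ref = np.array([np.prod(row.astype(float)) ** (1 / 3) for row in counts])
    expected = [np.median(counts[:, j] / ref) for j in range(3)]
    np.testing.assert_allclose(compute_size_factors(cm), expected, rtol=1e-12)


# --- FPKM -----------------------------------------------------------------

def _annotation(lengths: dict) -> TranscriptAnnotation:
    tab = pd.DataFrame({"length": pd.Series(lengths), "biotype": "protein_coding"})
    tab.index.name = "gene_id"
    return TranscriptAnnotation(tab)


def test_fpkm_arithmetic():
    cm = tiny_counts([[100], [0]], library_sizes=[10_000_000])
    ann = _annotation({"g0": 2000, "g1": 500})
    fpkm = compute_fpkm(cm, ann)
    assert fpkm.loc["g0"].iloc[0] == pytest.approx(5.0)
    assert fpkm.loc["g1"].iloc[0] == 0.0


def test_fpkm_halves_when_library_doubles():
    ann = _annotation({"g0": 1000, "g1": 1000})
    a = compute_fpkm(tiny_counts([[100], [50]], library_sizes=[1_000_000]), ann)
    b = compute_fpkm(tiny_counts([[100], [50]], library_sizes=[2_000_000]), ann)
    np.testing.assert_allclose(b.to_numpy(), a.to_numpy() / 2)


def test_fpkm_excludes_unannotated_gene():
    cm = tiny_counts([[100], [50]], library_sizes=[1_000_000])
    fpkm = compute_fpkm(cm, _annotation({"g0": 1000}))
    assert list(fpkm.index) == ["g0"]


# --- dispersion -----------------------------------------------------------

def _one_group_matrix(gene_counts, n_filler=60, filler_value=30):
    """Matrix whose size factors are exactly 1: constant filler genes
    dominate the median of ratios."""
    n = len(gene_counts)
    filler = np.full((n_filler, n), filler_value)
    counts = np.vstack([np.asarray(gene_counts)[None, :], filler])
    cm = tiny_counts(counts, library_sizes=[filler_value * (n_filler + 1)] * n)
    design = tiny_design([f"s{j}" for j in range(n)], ["A"] * n, ["input"] * n)
    return cm, design


def test_moment_dispersion_formula():
    # mean 15, sample variance 50 -> phi = (50 - 15) / 15^2
    cm, design = _one_group_matrix([7, 13, 16, 24])
    est = estimate_dispersion(cm, design, shrinkage=0.0)
    assert est.phi[0] == pytest.approx((50 - 15) / 225, rel=1e-6)


def test_dispersion_poisson_limit():
    rng = np.random.default_rng(0)
    counts = rng.poisson(200, size=(400, 6))
    cm = tiny_counts(counts)
    design = tiny_design([f"s{j}" for j in range(6)], ["A"] * 6, ["input"] * 6)
    est = estimate_dispersion(cm, design, shrinkage=0.0)
    assert np.median(est.phi) < 0.01


def test_full_shrinkage_gives_trend_everywhere():
    rng = np.random.default_rng(1)
    counts = rng.poisson(100, size=(300, 6))
    cm = tiny_counts(counts)
    design = tiny_design([f"s{j}" for j in range(6)], ["A"] * 6, ["input"] * 6)
    full = estimate_dispersion(cm, design, shrinkage=1.0)
    raw = estimate_dispersion(cm, design, shrinkage=0.0)
    # under full shrinkage the per-gene signal collapses onto the smooth
    # abundance trend: the spread across genes shrinks dramatically
    assert np.std(full.phi) < 0.2 * np.std(raw.phi)


def test_all_zero_gene_gets_common_dispersion():
    cm, design = _one_group_matrix([0, 0, 0, 0])
    est = estimate_dispersion(cm, design)
    assert est.flagged_all_zero[0]
    assert est.phi[0] == est.common_phi


# --- exact conditional test ----------------------------------------------

def test_exact_test_example():
    assert exact_conditional_pvalue(8, 2) == pytest.approx(112 / 1024, abs=1e-12)


def test_exact_test_properties():
    assert exact_conditional_pvalue(0, 0) == 1.0
    assert exact_conditional_pvalue(5, 5) == 1.0
    assert exact_conditional_pvalue(8, 2) == exact_conditional_pvalue(2, 8)


def test_exact_mode_through_two_group_interface():
    y = np.array([[8, 2], [5, 5], [0, 0]])
    res = two_group_nb_test(y, np.array([1, 0]), np.ones(2), np.zeros(3), method="exact")
    assert res["pvalue"].iloc[0] == pytest.approx(112 / 1024, abs=1e-12)
    assert res["pvalue"].iloc[1] == 1.0
    assert res["pvalue"].iloc[2] == 1.0 and res["log2FC"].iloc[2] == 0.0


def test_wald_exact_rejection_orderings_agree():
    """Poisson-limit Wald p-values order count pairs like the exact test.

    Splits with a zero cell are excluded: under complete separation the
    Wald statistic degenerates (the exact conditional test is the tool
    for those)."""
    pairs = [(a, b) for tot in range(2, 16) for a in range(1, tot) for b in [tot - a]]
    y = np.array(pairs)
    res = two_group_nb_test(y, np.array([1, 0]), np.ones(2), np.zeros(len(y)))
    exact = np.array([exact_conditional_pvalue(a, b) for a, b in pairs])
    # within each total, more extreme splits must rank no later in both tests
    for tot in range(2, 16):
        idx = [i for i, (a, b) in enumerate(pairs) if a + b == tot]
        if len(idx) < 2:
            continue
        wald_order = np.argsort(res["pvalue"].to_numpy()[idx], kind="stable")
        exact_order = np.argsort(exact[idx], kind="stable")
        ext = lambda order: [abs(2 * pairs[idx[i]][0] - tot) for i in order]
        assert sorted(ext(wald_order), reverse=True) == ext(wald_order)
        assert sorted(ext(exact_order), reverse=True) == ext(exact_order)


# --- Wald GLM test --------------------------------------------------------

def test_null_identity_and_label_swap():
    y = np.array([[10, 10, 10, 10], [40, 37, 22, 61], [3, 0, 9, 1]])
    grp = np.array([0, 0, 1, 1])
    res = two_group_nb_test(y, grp, np.ones(4), np.full(3, 0.05))
    assert res["log2FC"].iloc[0] == pytest.approx(0.0, abs=1e-8)
    swapped = two_group_nb_test(y, 1 - grp, np.ones(4), np.full(3, 0.05))
    np.testing.assert_allclose(res["log2FC"], -swapped["log2FC"], atol=1e-8)
    np.testing.assert_allclose(res["pvalue"], swapped["pvalue"], atol=1e-10)


def test_zero_group_stabilized_fold_change_is_finite():
    y = np.array([[0, 0, 25, 30]])
    res = two_group_nb_test(y, np.array([0, 0, 1, 1]), np.ones(4), np.array([0.05]))
    assert np.isfinite(res["log2FC"].iloc[0])
    assert res["log2FC"].iloc[0] > 3  # ~log2(55.5/0.5) scale


def test_power_increases_with_effect_and_replicates(standard_sim):
    from sgenrich.simulate import SimConfig, simulate_experiment
    from sgenrich.enrichment import estimate_dispersion

    recalls = []
    for effect, reps in ((1.0, 2), (2.0, 2), (2.0, 4)):
        cfg = SimConfig(seed=21, effect_size=effect, n_replicates=reps, n_genes=1000,
                        n_common=150, n_delta_enriched=0, n_delta_depleted=0)
        cm, design, _, truth = simulate_experiment(cfg)
        disp = estimate_dispersion(cm, design)
        table = run_enrichment_test(cm, design, "WT", disp)
        true_set = truth.genes_in("commonly_enriched")
        recalls.append(len(table.enriched_genes & true_set) / len(true_set))
    assert recalls[0] <= recalls[1] <= recalls[2]


# --- BH -------------------------------------------------------------------

def _bh_brute_force(p):
    """O(m^2) step-up: adj_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    adj = np.empty(m)
    for i in range(m):
        candidates = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i] - 1e-300]
        adj[i] = min(1.0, min(c for c in candidates))
    return adj


def test_bh_closed_form_cases():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])


def test_bh_nan_propagation():
    out = bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(out[1])
    np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_matches_brute_force(ps):
    np.testing.assert_allclose(bh_adjust(ps), _bh_brute_force(ps), atol=1e-12)


def test_bh_dominates_raw_p():
    rng = np.random.default_rng(2)
    p = rng.random(500)
    adj = bh_adjust(p)
    assert (adj >= p - 1e-15).all() and (adj <= 1).all()


# --- classification -------------------------------------------------------

def test_classification_rule():
    tab = pd.DataFrame({
        "log2FC": [1.5, -2.0, 3.0, 0.5, 1.0],
        "FDR": [0.01, 0.001, 0.2, 0.01, 0.01],
    }, index=list("abcde"))
    status = classify_enrichment(tab)
    assert status.tolist() == ["enriched", "depleted", "invariant", "invariant", "invariant"]
    # pure function: permuting rows permutes outputs identically
    perm = tab.iloc[[3, 1, 4, 0, 2]]
    assert classify_enrichment(perm).equals(status.loc[perm.index])


def test_enrichment_requires_both_fractions(standard_sim):
    cm, design = standard_sim["counts"], standard_sim["design"]
    from sgenrich.enrichment import estimate_dispersion

    disp = estimate_dispersion(cm, design)
    with pytest.raises(ValueError, match="lacks"):
        run_enrichment_test(cm, design, "NOPE", disp)
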