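"""Synthetic count/sequence generator with planted ground truth.

Emulates a four-condition stress-granule IP experiment: a wild-type and a
mutant genotype, each with and without knockdown of the m6A writer
(conditions ``WT``, ``WT_KD``, ``P525L``, ``P525L_KD``), each condition
with IP and input replicates.  Input counts are negative-binomial around
a log-normal baseline scaled by unequal library sizes; IP counts multiply
the baseline by ``2**effect`` with per-gene, per-condition planted
effects.  Four planted groups mirror the comparison of mutant knockdown
against mutant control:

* ``commonly_enriched`` — granule-enriched in every condition;
* ``delta_enriched`` — gained upon knockdown; a configurable fraction is
  additionally enriched in the wild-type conditions ("relocated": lost in
  the mutant, regained upon knockdown);
* ``delta_depleted`` — enriched in the mutant control only, lost upon
  knockdown;
* ``invariant`` — no enrichment anywhere.

Transcript lengths are log-normal with a heavier tail in the commonly
enriched group (a plantable length confounder); methylation flags are
Bernoulli with a logit linear in log2 length and group membership;
sequences are drawn i.i.d. from per-group nucleotide compositions so a
composition bias can be planted for the k-mer stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sgenrich.io import FRACTION_INPUT, FRACTION_IP, CountMatrix, SampleDesign, TranscriptAnnotation
from sgenrich.differential import (
    GROUP_COMMON,
    GROUP_DELTA_DEPLETED,
    GROUP_DELTA_ENRICHED,
    GROUP_INVARIANT,
    GroupAssignment,
)

CONDITIONS = ("WT", "WT_KD", "P525L", "P525L_KD")
STRATA = ("low", "medium-low", "medium", "medium-high", "high")

BASES = np.array(list("ACGT"))


def _default_effects(effect: float) -> dict[str, dict[str, float]]:
    return {
        GROUP_COMMON: {c: effect for c in CONDITIONS},
        GROUP_DELTA_ENRICHED: {"WT_KD": effect, "P525L_KD": effect},
        GROUP_DELTA_DEPLETED: {"P525L": effect},
        GROUP_INVARIANT: {},
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults define the standard scenario used throughout the test suite:
    2,000 genes, four conditions with 3 IP and 3 input replicates each,
    planted effects of +2 log2 units with 300 genes per non-invariant
    group, library sizes around 2x10^5 fragments (a deep-sequencing
    design scaled down 100-fold), and a methylation model whose defaults
    place the invariant group near 11% methylated, the (longer) commonly
    enriched group near 22%, and the relocated genes near 37%.
    """

    seed: int
    n_genes: int = 2000
    conditions: tuple[str, ...] = CONDITIONS
    n_replicates: int = 3  # per fraction per condition
    # baseline expression: log-normal relative abundances
    baseline_meanlog: float = 0.0
    baseline_sdlog: float = 1.0
    # NB dispersion: per-gene phi log-normal around phi0
    phi0: float = 0.05
    phi_sdlog: float = 0.3
    # planted enrichment
    effect_size: float = 2.0
    n_common: int = 300
    n_delta_enriched: int = 300
    n_delta_depleted: int = 300
    relocated_fraction: float = 0.75
    effects: dict[str, dict[str, float]] | None = None  # group -> condition -> log2 effect
    # libraries
    library_size_range: tuple[int, int] = (150_000, 250_000)
    # transcript lengths (nt), log-normal; commonly enriched shifted longer
    length_meanlog: float = 7.2
    length_sdlog: float = 0.6
    length_shift_common: float = 0.5
    # methylation: logit(p) = logit(base_rate) + length_coef*(log2 len - ref) + group term
    meth_base_rate: float = 0.11
    meth_length_coef: float = 1.1
    meth_group_logodds: dict[str, float] = field(default_factory=lambda: {"relocated": 1.55})
    # sequence composition (A, C, G, T); biased groups draw from the shifted one
    base_composition: tuple[float, ...] = (0.27, 0.23, 0.23, 0.27)
    biased_composition: tuple[float, ...] = (0.22, 0.26, 0.30, 0.22)
    biased_groups: tuple[str, ...] = (GROUP_COMMON, GROUP_DELTA_ENRICHED)
    # separate stream for count noise: same seed + different noise_seed
    # redraws counts for the identical planted truth
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("degenerate config: need >= 1 gene and >= 1 replicate")
        planted = self.n_common + self.n_delta_enriched + self.n_delta_depleted
        if planted > self.n_genes:
            raise ValueError("planted group sizes exceed n_genes")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if self.effects is None:
            self.effects = _default_effects(self.effect_size)

    @classmethod
    def null(cls, seed: int, **kw) -> "SimConfig":
        """No planted effects: every gene invariant (calibration scenario)."""
        kw.setdefault("n_common", 0)
        kw.setdefault("n_delta_enriched", 0)
        kw.setdefault("n_delta_depleted", 0)
        kw.setdefault("length_shift_common", 0.0)
        return cls(seed=seed, effect_size=0.0, **kw)


@dataclass
class SimTruth:
    """Planted per-gene truth: group, effects, length, methylation, stratum."""

    table: pd.DataFrame  # index gene_id; group, relocated, length, methylated,
    #                      expression, stratum, effect_<condition>...
    config: SimConfig

    def genes_in(self, group: str) -> set[str]:
        if group == "relocated":
            return set(self.table.index[self.table["relocated"]])
        return set(self.table.index[self.table["group"] == group])

    def sets(self) -> dict[str, set[str]]:
        out = {g: self.genes_in(g) for g in
               (GROUP_COMMON, GROUP_DELTA_ENRICHED, GROUP_DELTA_DEPLETED, GROUP_INVARIANT)}
        out["relocated"] = self.genes_in("relocated")
        return out


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def simulate_experiment(config: SimConfig) -> tuple[CountMatrix, SampleDesign, TranscriptAnnotation, SimTruth]:
    """Draw one synthetic experiment; identical seeds give identical output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n)], dtype=object)

    # group labels
    group = np.array([GROUP_INVARIANT] * n, dtype=object)
    order = rng.permutation(n)
    i0 = 0
    assign = {}
    for gname, gn in ((GROUP_COMMON, config.n_common),
                      (GROUP_DELTA_ENRICHED, config.n_delta_enriched),
                      (GROUP_DELTA_DEPLETED, config.n_delta_depleted)):
        assign[gname] = order[i0:i0 + gn]
        group[assign[gname]] = gname
        i0 += gn
    relocated = np.zeros(n, dtype=bool)
    de_idx = assign.get(GROUP_DELTA_ENRICHED, np.array([], dtype=int))
    n_rel = int(round(config.relocated_fraction * len(de_idx)))
    relocated[rng.choice(de_idx, size=n_rel, replace=False) if n_rel else []] = True

    # per-condition planted effects (log2)
    effects = np.zeros((n, len(config.conditions)))
    for j, cond in enumerate(config.conditions):
        for gname, per_cond in config.effects.items():
            if cond in per_cond:
                effects[group == gname, j] = per_cond[cond]
        # relocated genes are additionally enriched in the wild-type conditions
        if cond.startswith("WT"):
            effects[relocated, j] = config.effect_size
    # ... and lost in the mutant control
    for j, cond in enumerate(config.conditions):
        if cond == "P525L":
            effects[relocated, j] = 0.0

    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=n)
    baseline /= baseline.sum()
    phi = config.phi0 * rng.lognormal(0.0, config.phi_sdlog, size=n) if config.phi0 > 0 else np.zeros(n)

    # lengths: heavier tail for the commonly enriched group
    mu_len = np.full(n, config.length_meanlog)
    mu_len[group == GROUP_COMMON] += config.length_shift_common
    lengths = np.maximum(rng.lognormal(mu_len, config.length_sdlog).astype(int), 200)

    # methylation flags
    ref_log2len = np.log2(np.exp(config.length_meanlog))
    logits = _logit(config.meth_base_rate) + config.meth_length_coef * (np.log2(lengths) - ref_log2len)
    for gname, lo in config.meth_group_logodds.items():
        mask = relocated if gname == "relocated" else (group == gname)
        logits[mask] += lo
    meth = rng.random(n) < 1.0 / (1.0 + np.exp(-logits))

    # counts
    if config.noise_seed is not None:
        rng = np.random.default_rng(config.noise_seed)
    rows, sample_ids = [], []
    counts = []
    lo, hi = config.library_size_range
    rep_range = range(1, config.n_replicates + 1)
    for j, cond in enumerate(config.conditions):
        for frac in (FRACTION_INPUT, FRACTION_IP):
            rel = baseline * (2.0 ** effects[:, j]) if frac == FRACTION_IP else baseline
            rel = rel / rel.sum()
            for rep in rep_range:
                lib = int(rng.integers(lo, hi + 1))
                mu = rel * lib
                if config.phi0 > 0:
                    nb_n = 1.0 / phi
                    nb_p = nb_n / (nb_n + mu)
                    y = rng.negative_binomial(nb_n, nb_p)
                else:
                    y = rng.poisson(mu)
                sid = f"{cond}_{frac}_{rep}"
                sample_ids.append(sid)
                counts.append(y)
                rows.append({"sample_id": sid, "condition": cond, "fraction": frac, "replicate": rep})

    cm = CountMatrix(gene_ids=gene_ids, counts=np.column_stack(counts), sample_ids=sample_ids)
    design = SampleDesign(pd.DataFrame(rows))
    ann = TranscriptAnnotation(pd.DataFrame(
        {"length": lengths, "biotype": "protein_coding"},
        index=pd.Index(gene_ids, name="gene_id"),
    ))

    stratum = pd.qcut(baseline, 5, labels=list(STRATA)).astype(str)
    truth_tab = pd.DataFrame({
        "group": group, "relocated": relocated, "length": lengths,
        "methylated": meth, "expression": baseline, "stratum": stratum,
    }, index=pd.Index(gene_ids, name="gene_id"))
    for j, cond in enumerate(config.conditions):
        truth_tab[f"effect_{cond}"] = effects[:, j]
    return cm, design, ann, SimTruth(table=truth_tab, config=config)


def group_composition(config: SimConfig, group: str) -> np.ndarray:
    comp = config.biased_composition if group in config.biased_groups else config.base_composition
    return np.asarray(comp, dtype=float)


def simulate_sequences(truth: SimTruth, seed: int | None = None) -> dict[str, str]:
    """Per-gene random sequences of the planted lengths.

    Bases are i.i.d. from the group's nucleotide composition (the biased
    groups use the shifted composition), so per-group k-mer expectations
    are analytic products of base probabilities.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    seqs: dict[str, str] = {}
    for gene_id, row in truth.table.iterrows():
        comp = group_composition(cfg, row["group"])
        comp = comp / comp.sum()
        seqs[gene_id] = "".join(BASES[rng.choice(4, size=int(row["length"]), p=comp)])
    return seqs


def expected_kmer_log2fc(config: SimConfig, k: int = 4) -> pd.Series:
    """Analytic per-k-mer log2 ratio of biased-group vs background frequency
    under the i.i.d. composition model (the planted-bias truth for ranking
    checks)."""
    from sgenrich.kmers import all_kmers

    base = np.asarray(config.base_composition, dtype=float)
    bias = np.asarray(config.biased_composition, dtype=float)
    base, bias = base / base.sum(), bias / bias.sum()
    idx = {b: i for i, b in enumerate("ACGT")}
    out = {}
    for km in all_kmers(k):
        lb = sum(np.log2(bias[idx[c]]) - np.log2(base[idx[c]]) for c in km)
        out[km] = lb
    return pd.Series(out)


def evaluate_recovery(assigned: GroupAssignment, truth: SimTruth) -> pd.DataFrame:
    """Per-group precision/recall/F1 of assigned gene sets against truth.

    Empty truth groups give NA recall; empty assigned groups give NA
    precision; F1 is NA unless both are defined and their sum is nonzero.
    """
    rows = []
    truth_sets = truth.sets()
    for name, assigned_set in assigned.sets().items():
        t = truth_sets.get(name, set())
        tp = len(assigned_set & t)
        prec = tp / len(assigned_set) if assigned_set else np.nan
        rec = tp / len(t) if t else np.nan
        if np.isnan(prec) or np.isnan(rec) or (prec + rec) == 0:
            f1 = np.nan
        else:
            f1 = 2 * prec * rec / (prec + rec)
        rows.append({"group": name, "n_true": len(t), "n_assigned": len(assigned_set),
                     "precision": prec, "recall": rec, "f1": f1})
    return pd.DataFrame(rows).set_index("group")
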