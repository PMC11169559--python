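"""Per-condition IP-vs-input negative-binomial enrichment testing.

The engine is a gene-wise negative-binomial log-link GLM with a
log-effective-library-size offset, fitted by iteratively reweighted least
squares (batched across genes), and a Wald test on the fraction
coefficient.  The NB variance is parameterized as ``var = mu + phi*mu^2``
with a per-gene dispersion ``phi`` estimated by a method-of-moments
estimator shrunk toward a mean-abundance trend.  An exact conditional
(binomial) test is available for the one-vs-one, equal-offset, ``phi -> 0``
case and serves as an independent oracle for the Wald path.

Genes are called ``enriched`` when log2FC > 1 and FDR < 0.05, ``depleted``
when log2FC < -1 and FDR < 0.05, and ``invariant`` otherwise; the
thresholds are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sgenrich.io import FRACTION_INPUT, FRACTION_IP, CountMatrix, SampleDesign, TranscriptAnnotation

logger = logging.getLogger(__name__)

STATUS_ENRICHED = "enriched"
STATUS_DEPLETED = "depleted"
STATUS_INVARIANT = "invariant"

_ETA_MAX = 30.0
_RIDGE = 1e-8


@dataclass
class DispersionEstimate:
    """Per-gene NB dispersion phi (var = mu + phi*mu^2), with a common value
    and a description of the mean-abundance trend used for shrinkage."""

    gene_ids: np.ndarray
    phi: np.ndarray
    common_phi: float
    trend: str
    flagged_all_zero: np.ndarray  # boolean; phi fell back to common_phi
    residual_dof: int = 0  # pooled within-group dof behind the estimate

    def for_genes(self, gene_ids) -> np.ndarray:
        ser = pd.Series(self.phi, index=self.gene_ids)
        return ser.reindex(list(gene_ids)).fillna(self.common_phi).to_numpy()


@dataclass
class EnrichmentTable:
    """Per-gene IP-vs-input enrichment result for one condition.

    ``table`` is indexed by gene id with columns log2FC, pvalue, FDR,
    status, mean_ip_fpkm, mean_input_fpkm.
    """

    condition: str
    table: pd.DataFrame

    @property
    def enriched_genes(self) -> set[str]:
        return set(self.table.index[self.table["status"] == STATUS_ENRICHED])

    @property
    def depleted_genes(self) -> set[str]:
        return set(self.table.index[self.table["status"] == STATUS_DEPLETED])


def compute_size_factors(counts: CountMatrix, design: SampleDesign | None = None) -> np.ndarray:
    """Median-of-ratios sample scale factors (composition correction).

    Each factor is the median over all-nonzero genes of the ratio of the
    sample's count to a per-gene geometric-mean pseudo-reference.  The
    factors multiply library sizes to give effective sizes.  When a
    design is supplied the pseudo-reference is built from the input-
    fraction samples only: in an IP experiment the enriched minority can
    occupy a large share of the IP libraries, and a reference
    contaminated by IP composition would under-correct the resulting
    depression of unenriched genes, so enrichment is measured against the
    transcriptome (input) instead.  When no gene is nonzero in every
    reference sample the factors fall back to centred library-size ratios
    (library-size-only normalization) with a warning.
    """
    y = counts.counts
    ref_cols = np.arange(counts.n_samples)
    if design is not None:
        inputs = design.samples(fraction=FRACTION_INPUT)
        if inputs:
            ref_cols = counts.column_index(inputs)
    nonzero = np.all(y[:, ref_cols] > 0, axis=1) & np.all(y > 0, axis=1)
    if not nonzero.any():
        logger.warning("no gene nonzero in all samples; falling back to library-size normalization")
        lib = counts.library_sizes.astype(float)
        return lib / np.exp(np.mean(np.log(lib)))
    logy = np.log(y[nonzero].astype(float))
    log_geo = logy[:, ref_cols].mean(axis=1, keepdims=True)
    return np.exp(np.median(logy - log_geo, axis=0))


def effective_sizes(counts: CountMatrix, size_factors: np.ndarray | None = None,
                    design: SampleDesign | None = None) -> np.ndarray:
    """Per-sample effective library sizes: the geometric-mean library size
    scaled by the (geometric-mean-centred) size factors.

    Median-of-ratios factors already carry each sample's relative depth,
    so they scale one representative library size rather than each
    sample's own total (which would count depth twice)."""
    if size_factors is None:
        size_factors = compute_size_factors(counts, design=design)
    lib_geo = np.exp(np.mean(np.log(counts.library_sizes.astype(float))))
    return lib_geo * size_factors / np.exp(np.mean(np.log(size_factors)))


def compute_fpkm(counts: CountMatrix, annotation: TranscriptAnnotation,
                 size_factors: np.ndarray | None = None,
                 design: SampleDesign | None = None) -> pd.DataFrame:
    """Fragments per kilobase per million: count / (len_kb * eff_size/1e6).

    Genes absent from the annotation are excluded (logged) — they stay in
    the tested universe but cannot pass FPKM-dependent filters.
    """
    eff = effective_sizes(counts, size_factors, design=design)
    keep = [g for g in counts.gene_ids if g in annotation.gene_ids]
    dropped = counts.n_genes - len(keep)
    if dropped:
        logger.info("compute_fpkm: %d genes lack annotation and are excluded", dropped)
    frame = counts.to_frame().loc[keep]
    len_kb = annotation.lengths(keep) / 1000.0
    return frame.div(eff / 1e6, axis=1).div(len_kb, axis=0)


def estimate_dispersion(counts: CountMatrix, design: SampleDesign,
                        shrinkage: float = 0.3, n_bins: int = 20) -> DispersionEstimate:
    """Method-of-moments per-gene dispersion with trend shrinkage.

    Counts are put on a common scale by dividing by relative effective
    sizes (geometric mean one); within each (condition, fraction) group the
    pooled residual variance is decomposed into its Poisson part and the
    quadratic overdispersion part, giving a raw ``phi`` per gene.  Raw
    values are shrunk toward a binned-median trend over log mean abundance
    with weight ``shrinkage`` and floored at zero.  All-zero genes receive
    the common (median) dispersion and are flagged.
    """
    eff = effective_sizes(counts, design=design)
    r = eff / np.exp(np.mean(np.log(eff)))  # relative sizes, geomean 1
    z = counts.counts / r  # normalized counts

    groups = design.table.groupby(["condition", "fraction"], sort=False).groups
    col_of = {s: i for i, s in enumerate(counts.sample_ids)}

    ss = np.zeros(counts.n_genes)          # pooled residual sum of squares
    dof = 0
    pois = np.zeros(counts.n_genes)        # pooled Poisson variance part
    msq = np.zeros(counts.n_genes)         # pooled squared-mean part
    nsamp = 0
    mean_all = np.zeros(counts.n_genes)
    for _, samp_idx in groups.items():
        cols = np.array([col_of[design.table.loc[i, "sample_id"]] for i in samp_idx])
        if len(cols) < 1:
            continue
        zg = z[:, cols]
        q = zg.mean(axis=1)
        mean_all += q * len(cols)
        nsamp += len(cols)
        if len(cols) >= 2:
            ss += ((zg - q[:, None]) ** 2).sum(axis=1)
            dof += len(cols) - 1
            pois += (len(cols) - 1) * q * np.mean(1.0 / r[cols])
            msq += (len(cols) - 1) * q**2
    mean_all /= max(nsamp, 1)
    if dof < 1:
        raise ValueError("dispersion estimation needs >= 2 samples in at least one group")

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (ss / dof - pois / dof) / (msq / dof)
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.maximum(raw, 0.0)

    expressed = mean_all > 0
    common = float(np.median(raw[expressed])) if expressed.any() else 0.0

    # binned-median trend over log10 mean abundance
    trend_vals = np.full(counts.n_genes, common)
    if expressed.sum() >= n_bins:
        logm = np.log10(mean_all[expressed])
        qs = np.quantile(logm, np.linspace(0, 1, n_bins + 1))
        qs = np.unique(qs)
        which = np.clip(np.searchsorted(qs, logm, side="right") - 1, 0, len(qs) - 2)
        centers, medians = [], []
        for b in range(len(qs) - 1):
            mask = which == b
            if mask.sum() >= 3:
                centers.append(logm[mask].mean())
                medians.append(np.median(raw[expressed][mask]))
        if len(centers) >= 2:
            tv = np.interp(logm, centers, medians)
            trend_vals[expressed] = tv

    phi = np.maximum((1 - shrinkage) * raw + shrinkage * trend_vals, 0.0)
    all_zero = counts.counts.sum(axis=1) == 0
    phi[all_zero] = common
    return DispersionEstimate(
        gene_ids=counts.gene_ids.copy(),
        phi=phi,
        common_phi=common,
        trend=f"binned-median over log10 mean abundance ({n_bins} bins), shrinkage={shrinkage}",
        flagged_all_zero=all_zero,
        residual_dof=dof,
    )


def nb_glm_fit(y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: np.ndarray,
               max_iter: int = 100, tol: float = 1e-10):
    """Batched IRLS fit of gene-wise NB log-link GLMs.

    Parameters
    ----------
    y : (G, n) counts, X : (n, p) design, offset : (n,) log effective
    sizes, phi : (G,) dispersions.

    Returns ``(beta, cov)`` with beta (G, p) and cov (G, p, p), the inverse
    Fisher information at the fit.
    """
    y = np.asarray(y, dtype=float)
    G, n = y.shape
    p = X.shape[1]
    phi = np.asarray(phi, dtype=float)

    mu = np.maximum(y, 0.5)
    eta = np.log(mu)
    beta = np.linalg.lstsq(X, (eta - offset).T, rcond=None)[0].T  # (G, p)

    eye = np.eye(p) * _RIDGE
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        W = mu / (1.0 + phi[:, None] * mu)
        zwork = eta - offset + (y - mu) / mu
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True) + eye
        XtWz = np.einsum("ni,gn->gi", X, W * zwork, optimize=True)
        beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            break
    eta = np.clip(beta @ X.T + offset, -_ETA_MAX, _ETA_MAX)
    mu = np.exp(eta)
    W = mu / (1.0 + phi[:, None] * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True) + eye
    cov = np.linalg.inv(XtWX)
    return beta, cov


def exact_conditional_pvalue(y_ip: int, y_input: int, s_ip: float = 1.0,
                             s_input: float = 1.0) -> float:
    """Exact conditional two-group count test in the Poisson (phi -> 0) limit.

    Conditional on the total ``n = y_ip + y_input`` the IP count is
    binomial with success probability ``s_ip / (s_ip + s_input)``; the
    two-sided p-value sums the probabilities of all outcomes no more
    likely than the observed one.  With equal effective sizes this is the
    symmetric binomial tail (e.g. IP=8 vs input=2 gives 112/1024).
    """
    n = int(y_ip) + int(y_input)
    if n == 0:
        return 1.0
    pr = s_ip / (s_ip + s_input)
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, pr)
    p_obs = pmf[int(y_ip)]
    mask = pmf <= p_obs * (1 + 1e-12)
    if mask.all():
        return 1.0
    return float(min(1.0, pmf[mask].sum()))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the number of tests and propagated.
    Output is monotone non-decreasing in the p-value ranking, capped at 1,
    and elementwise >= the raw p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return out
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def classify_enrichment(table: pd.DataFrame, lfc_threshold: float = 1.0,
                        fdr_threshold: float = 0.05) -> pd.Series:
    """Three-way status per gene: enriched / depleted / invariant.

    ``enriched`` requires log2FC > lfc_threshold and FDR < fdr_threshold;
    ``depleted`` the mirror image; everything else is ``invariant``.
    """
    lfc = table["log2FC"]
    fdr = table["FDR"]
    status = pd.Series(STATUS_INVARIANT, index=table.index, dtype=object)
    status[(lfc > lfc_threshold) & (fdr < fdr_threshold)] = STATUS_ENRICHED
    status[(lfc < -lfc_threshold) & (fdr < fdr_threshold)] = STATUS_DEPLETED
    return status


def _stabilized_log2fc(y: np.ndarray, grp: np.ndarray, eff: np.ndarray) -> np.ndarray:
    """log2 ratio of normalized group totals with a 0.5 pseudo-count.

    Used only for genes where one fraction has zero counts, where the GLM
    coefficient diverges.
    """
    t1 = y[:, grp == 1].sum(axis=1)
    t0 = y[:, grp == 0].sum(axis=1)
    e1 = eff[grp == 1].sum()
    e0 = eff[grp == 0].sum()
    return np.log2((t1 + 0.5) / e1) - np.log2((t0 + 0.5) / e0)


def _wald_pvalues(stat: np.ndarray, dof: int | None) -> np.ndarray:
    """Two-sided Wald p-values; a t reference with the dispersion
    estimator's pooled residual dof accounts for the plug-in dispersion
    (``dof`` None or 0 falls back to the normal reference)."""
    if dof:
        p = 2 * stats.t.sf(np.abs(stat), dof)
    else:
        p = 2 * stats.norm.sf(np.abs(stat))
    return np.where(np.isfinite(p), p, 1.0)


def two_group_nb_test(y: np.ndarray, grp: np.ndarray, eff: np.ndarray,
                      phi: np.ndarray, method: str = "wald",
                      wald_dof: int | None = None) -> pd.DataFrame:
    """NB test of a binary group effect with log-effective-size offsets.

    ``grp`` is 0/1 per sample; the returned log2FC is the group-1 vs
    group-0 coefficient on the log2 scale, with a pseudo-count-stabilized
    estimate substituted for genes where either group is all zero.
    ``method='exact'`` uses the conditional binomial test (one sample per
    group, phi treated as 0).
    """
    y = np.asarray(y)
    G = y.shape[0]
    all_zero = y.sum(axis=1) == 0

    if method == "exact":
        if y.shape[1] != 2 or grp.tolist() not in ([0, 1], [1, 0]):
            raise ValueError("exact method requires exactly one sample per group")
        i1 = int(np.where(grp == 1)[0][0])
        i0 = int(np.where(grp == 0)[0][0])
        pvals = np.array([
            exact_conditional_pvalue(y[g, i1], y[g, i0], eff[i1], eff[i0]) for g in range(G)
        ])
        lfc = np.log2((y[:, i1] + 0.5) / eff[i1]) - np.log2((y[:, i0] + 0.5) / eff[i0])
        exact_zero = (y[:, i1] / eff[i1]) == (y[:, i0] / eff[i0])
        lfc = np.where(exact_zero, 0.0, lfc)
    elif method == "wald":
        X = np.column_stack([np.ones_like(grp, dtype=float), grp.astype(float)])
        beta, cov = nb_glm_fit(y, X, np.log(eff), phi)
        se = np.sqrt(np.maximum(cov[:, 1, 1], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            zstat = beta[:, 1] / se
        pvals = _wald_pvalues(zstat, wald_dof)
        lfc = beta[:, 1] / np.log(2)
        degenerate = (y[:, grp == 1].sum(axis=1) == 0) | (y[:, grp == 0].sum(axis=1) == 0)
        if degenerate.any():
            lfc = np.where(degenerate, _stabilized_log2fc(y, grp, eff), lfc)
    else:
        raise ValueError(f"unknown method {method!r}")

    pvals = np.where(all_zero, 1.0, pvals)
    lfc = np.where(all_zero, 0.0, lfc)
    return pd.DataFrame({"log2FC": lfc, "pvalue": pvals, "flag_all_zero": all_zero})


def test_enrichment(counts: CountMatrix, design: SampleDesign, condition: str,
                    dispersion: DispersionEstimate,
                    annotation: TranscriptAnnotation | None = None,
                    lfc_threshold: float = 1.0, fdr_threshold: float = 0.05,
                    min_total: int = 1, method: str = "wald") -> EnrichmentTable:
    """IP-vs-input NB enrichment test for one condition.

    Genes with fewer than ``min_total`` fragments across the condition's
    samples are excluded from the tested universe.  FDR is Benjamini-
    Hochberg within that universe; status uses ``classify_enrichment``.
    """
    ip = design.samples(condition, FRACTION_IP)
    inp = design.samples(condition, FRACTION_INPUT)
    if not ip or not inp:
        raise ValueError(f"condition {condition!r} lacks an IP or input sample")
    samp = inp + ip
    sub = counts.subset_samples(samp)
    eff = effective_sizes(counts, design=design)[counts.column_index(samp)]
    grp = np.array([0] * len(inp) + [1] * len(ip))

    keep = sub.counts.sum(axis=1) >= min_total
    y = sub.counts[keep]
    genes = sub.gene_ids[keep]
    phi = dispersion.for_genes(genes)

    res = two_group_nb_test(y, grp, eff, phi, method=method,
                            wald_dof=dispersion.residual_dof)
    res.index = pd.Index(genes, name="gene_id")
    res["FDR"] = bh_adjust(res["pvalue"].to_numpy())
    res["status"] = classify_enrichment(res, lfc_threshold, fdr_threshold)

    res["mean_ip_fpkm"] = np.nan
    res["mean_input_fpkm"] = np.nan
    if annotation is not None:
        fpkm = compute_fpkm(counts, annotation, design=design)
        common = [g for g in genes if g in fpkm.index]
        res.loc[common, "mean_ip_fpkm"] = fpkm.loc[common, ip].mean(axis=1)
        res.loc[common, "mean_input_fpkm"] = fpkm.loc[common, inp].mean(axis=1)
    cols = ["log2FC", "pvalue", "FDR", "status", "mean_ip_fpkm", "mean_input_fpkm", "flag_all_zero"]
    return EnrichmentTable(condition=condition, table=res[cols])
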