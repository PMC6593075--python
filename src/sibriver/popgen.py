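"""Population-genetic summaries on the unrelated-founder subset.

Heterozygosities with a paired t-test, Weir & Cockerham (1984) FST with a
locus bootstrap, rarefaction allelic richness, PCA of the call matrix, and
K-means cluster-number selection by BIC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.cluster import KMeans

from .containers import GenotypeTable


def heterozygosity(g: GenotypeTable) -> pd.DataFrame:
    """Per-locus observed and expected heterozygosity per population.

    Hexp = 2p(1-p) from the observed allele frequency; Hobs = fraction of
    heterozygotes among observed calls. Loci with no observed calls in a
    population get NaN.
    """
    rows = []
    for pop, sub in g.per_pop():
        obs = sub.observed_mask()
        n = obs.sum(axis=0)
        p = sub.allele_freq()
        with np.errstate(invalid="ignore", divide="ignore"):
            hobs = np.where(n > 0, ((sub.calls == 1) & obs).sum(axis=0) / n, np.nan)
        hexp = 2.0 * p * (1.0 - p)
        for lid, ho, he in zip(g.locus_ids, hobs, hexp):
            rows.append((pop, lid, ho, he))
    return pd.DataFrame(rows, columns=["pop", "locus_id", "hobs", "hexp"])


def mean_heterozygosity(het: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-population means of the per-locus heterozygosities."""
    return (
        het.groupby("pop", sort=False)[["hobs", "hexp"]].mean().reset_index()
    )


def paired_hobs_hexp_test(hobs: np.ndarray, hexp: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on per-locus Hobs - Hexp differences.

    Degenerate cases are handled explicitly: identical vectors give (0, 1);
    a constant non-zero difference has zero variance and is reported as
    (signed infinity, 0).
    """
    d = np.asarray(hobs, dtype=float) - np.asarray(hexp, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) < 2:
        raise ValueError("need at least two paired observations")
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(np.asarray(hobs, float), np.asarray(hexp, float), nan_policy="omit")
    return float(t), float(p)


# -- Weir & Cockerham FST ----------------------------------------------


def _wc_components(g: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir & Cockerham (1984) components: a and (a + b + c).

    Genotype-based estimator for r populations at each locus: with per-pop
    sample sizes n_i (genotyped individuals), allele frequencies p_i and
    heterozygote frequencies h_i,

        a = (nbar/nc) [s2 - (1/(nbar-1)) (pbar qbar - (r-1)/r s2 - hbar/4)]
        b = (nbar/(nbar-1)) [pbar qbar - (r-1)/r s2 - (2 nbar - 1)/(4 nbar) hbar]
        c = hbar / 2

    Loci where the components are undefined (a population unobserved, or
    nbar <= 1, or nc <= 0) are returned as NaN.
    """
    pops = g.pop_names()
    r = len(pops)
    if r < 2:
        raise ValueError("need at least two populations")
    n_i, p_i, h_i = [], [], []
    for _, sub in g.per_pop():
        obs = sub.observed_mask()
        n = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(obs, sub.calls, 0).sum(axis=0) / (2 * n), np.nan)
            h = np.where(n > 0, ((sub.calls == 1) & obs).sum(axis=0) / n, np.nan)
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)  # (r, L)
    p_i = np.array(p_i)
    h_i = np.array(h_i)
    nsum = n_i.sum(axis=0)
    nbar = nsum / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n_i**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / nsum
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    bad = (
        np.isnan(p_i).any(axis=0)
        | (n_i == 0).any(axis=0)
        | (nbar <= 1)
        | ~(nc > 0)
    )
    a = np.where(bad, np.nan, a)
    abc = np.where(bad, np.nan, a + b + c)
    return a, abc


@dataclass
class FstResult:
    pop1: str
    pop2: str
    fst: float
    ci_low: float
    ci_high: float


def wc_fst(
    g: GenotypeTable,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[pd.DataFrame, float]:
    """Pairwise multi-locus Weir & Cockerham FST with percentile bootstrap CIs.

    The multi-locus estimate is sum(a) / sum(a+b+c) over usable loci; each
    pair uses only the two populations' data. CIs resample loci with
    replacement ``n_boot`` times. Also returns the overall (all-population)
    multi-locus estimate. Negative estimates are reported as computed.
    """
    pops = g.pop_names()
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    for pop, sub in g.per_pop():
        if (sub.observed_mask().sum(axis=0) >= 2).sum() == 0:
            raise ValueError(f"population {pop} has <2 genotyped individuals at every locus")
    rng = np.random.default_rng(seed)
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    rows = []
    for p1, p2 in itertools.combinations(pops, 2):
        sel = [i for i, pp in zip(g.ids, g.pops) if pp in (p1, p2)]
        a, abc = _wc_components(g.subset_individuals(sel))
        use = ~np.isnan(abc) & (abc != 0)
        a, abc = a[use], abc[use]
        if len(a) == 0:
            raise ValueError(f"no usable loci for pair {p1}-{p2}")
        point = a.sum() / abc.sum()
        idx = rng.integers(0, len(a), size=(n_boot, len(a)))
        boots = a[idx].sum(axis=1) / abc[idx].sum(axis=1)
        rows.append(
            FstResult(p1, p2, float(point), float(np.percentile(boots, lo_q)), float(np.percentile(boots, hi_q)))
        )
    a, abc = _wc_components(g)
    use = ~np.isnan(abc) & (abc != 0)
    overall = float(a[use].sum() / abc[use].sum())
    return pd.DataFrame([vars(r) for r in rows]), overall


# -- rarefaction allelic richness ---------------------------------------


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction_richness(
    g: GenotypeTable, g_max: int | None = None, g_values: list[int] | None = None
) -> pd.DataFrame:
    """Expected allele counts in standardized subsamples of gene copies.

    Per locus with N observed gene copies and allele counts N_j, the expected
    number of distinct alleles in a subsample of size ``g`` is
    sum_j (1 - C(N - N_j, g) / C(N, g)); values are averaged over loci within
    each population. ``g`` may not exceed any locus's observed copy count.
    """
    rows = []
    for pop, sub in g.per_pop():
        obs = sub.observed_mask()
        n = obs.sum(axis=0)
        if (n == 0).any():
            raise ValueError(f"population {pop}: locus with no observed calls")
        N = 2 * n
        n_ref = np.where(obs, sub.calls, 0).sum(axis=0)
        n_alt = N - n_ref
        max_g = int(N.min())
        if g_values is None:
            top = g_max if g_max is not None else max_g
            if top > max_g:
                raise ValueError(f"g_max {top} exceeds minimum gene-copy count {max_g}")
            gs = list(range(1, top + 1))
        else:
            gs = sorted(g_values)
            if gs and gs[-1] > max_g:
                raise ValueError(f"g={gs[-1]} exceeds minimum gene-copy count {max_g}")
        for gv in gs:
            expected = np.zeros(sub.n_loci)
            for counts in (n_ref, n_alt):
                with np.errstate(invalid="ignore"):
                    ratio = np.where(
                        counts > 0,
                        np.where(
                            N - counts >= gv,
                            np.exp(_log_comb((N - counts).astype(float), gv) - _log_comb(N.astype(float), gv)),
                            0.0,
                        ),
                        np.nan,
                    )
                expected += np.where(counts > 0, 1.0 - ratio, 0.0)
            rows.append((pop, gv, float(expected.mean())))
    return pd.DataFrame(rows, columns=["pop", "g", "expected_alleles"])


# -- PCA and clustering --------------------------------------------------


def pca(g: GenotypeTable, n_axes: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the mean-imputed, column-centred call matrix.

    Returns (scores, percent variance explained); deterministic up to the
    sign of each axis.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least two individuals")
    X = g.calls.astype(float)
    X[~g.observed_mask()] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    X = np.where(np.isnan(X), col_mean[None, :], X)
    X = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    total = (s**2).sum()
    var_pct = 100.0 * s**2 / total if total > 0 else np.zeros_like(s)
    k = len(s) if n_axes is None else min(n_axes, len(s))
    return U[:, :k] * s[:k], var_pct[:k]


def kmeans_bic(
    scores: np.ndarray, k_max: int = 20, n_start: int = 1000, seed: int = 0
) -> tuple[pd.DataFrame, int]:
    """BIC-based cluster-number selection over K-means solutions.

    For each K in 1..k_max the best-of-``n_start`` K-means solution (by total
    within-cluster sum of squares, WSS) is scored as
    BIC(K) = n ln(WSS/n) + K ln(n); returns the full table and argmin K.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    # K = n saturates the model (WSS = 0, BIC undefined); stop one short
    k_max = min(k_max, n - 1)
    rows = []
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((X - X.mean(axis=0)) ** 2).sum())
        else:
            km = KMeans(
                n_clusters=k, n_init=n_start, random_state=seed, algorithm="lloyd"
            ).fit(X)
            wss = float(km.inertia_)
        bic = n * np.log(wss / n) + k * np.log(n) if wss > 0 else np.inf
        rows.append((k, wss, float(bic)))
    table = pd.DataFrame(rows, columns=["k", "wss", "bic"])
    best_k = int(table.loc[table["bic"].idxmin(), "k"])
    return table, best_k
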