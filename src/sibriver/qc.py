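"""Four-step SNP quality control: MAF/call-rate, fragment dedup, LD pruning, HWE.

The cascade order is fixed. Boundary semantics follow the filtering rules the
pipeline was built around: loci with MAF <= ``maf_max_excl`` or missing rate
>= ``miss_max_excl`` are excluded (boundaries removed); LD pruning iterates
until every pairwise r^2 is <= ``r2_max``; the Hardy–Weinberg filter drops a
locus significant in ANY population after Dunn–Šidák correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeTable

logger = logging.getLogger("sibriver")


@dataclass
class QCReport:
    """Per-filter removal bookkeeping; removals + survivors = input loci."""

    n_input: int
    removed: dict[str, list[str]] = field(default_factory=dict)
    params: dict[str, object] = field(default_factory=dict)
    survivors: list[str] = field(default_factory=list)

    ORDER = ("maf_callrate", "fragment_dedup", "ld_prune", "hwe")

    def counts(self) -> dict[str, int]:
        return {k: len(self.removed.get(k, [])) for k in self.ORDER}

    def check(self) -> None:
        total = sum(self.counts().values()) + len(self.survivors)
        if total != self.n_input:
            raise AssertionError(
                f"QC bookkeeping broken: {total} accounted for, {self.n_input} input"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, len(self.removed.get(k, []))) for k in self.ORDER]
        rows.append(("surviving", len(self.survivors)))
        return pd.DataFrame(rows, columns=["stage", "n_loci"])


def filter_maf_callrate(
    g: GenotypeTable,
    maf_max_excl: float = 0.05,
    miss_max_excl: float = 0.05,
) -> tuple[GenotypeTable, list[str]]:
    """Drop loci with MAF <= ``maf_max_excl`` or missing rate >= ``miss_max_excl``.

    Both statistics are computed over observed calls only; a locus with every
    call missing is removed by the missingness rule (its MAF is undefined).
    """
    if g.n_loci == 0:
        raise ValueError("empty genotype table")
    maf = g.maf()
    miss = g.missing_rate()
    # boundary-inclusive with a float guard so a count-exact MAF of 0.05
    # (e.g. 1 - 19/20) is excluded despite rounding in 1 - p
    eps = 1e-9
    bad_miss = miss >= miss_max_excl - eps
    with np.errstate(invalid="ignore"):
        bad_maf = ~bad_miss & (np.isnan(maf) | (maf <= maf_max_excl + eps))
    keep = ~(bad_maf | bad_miss)
    removed = [lid for lid, b in zip(g.locus_ids, keep) if not b]
    return g.subset_loci(keep), removed


def dedup_fragments(g: GenotypeTable, seed: int) -> tuple[GenotypeTable, list[str]]:
    """Retain one SNP per fragment, chosen uniformly at random (seeded)."""
    rng = np.random.default_rng(seed)
    keep_idx: list[int] = []
    frags = g.loci["fragment_id"].astype(str)
    for _, idx in frags.groupby(frags, sort=False).groups.items():
        idx = list(idx)
        keep_idx.append(idx[rng.integers(len(idx))] if len(idx) > 1 else idx[0])
    keep_idx = sorted(keep_idx)
    keep_set = set(keep_idx)
    removed = [g.locus_ids[i] for i in range(g.n_loci) if i not in keep_set]
    return g.subset_loci(keep_idx), removed


def pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared Pearson correlation of 0/1/2 calls.

    Pairs with fewer than two joint observations, or a zero-variance member
    over the joint observations, get r^2 = 0.
    """
    W = (calls != MISSING).astype(float)
    X = np.where(calls != MISSING, calls, 0).astype(float)
    N = W.T @ W
    Sx = X.T @ W  # sum of locus-i calls over joint observations with locus j
    Sxy = X.T @ X
    Sxx = (X**2).T @ W
    cov = N * Sxy - Sx * Sx.T
    varx = N * Sxx - Sx**2
    denom = varx * varx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where((denom > 0) & (N >= 2), cov**2 / denom, 0.0)
    np.fill_diagonal(r2, 0.0)
    return np.clip(r2, 0.0, 1.0)


def ld_prune(
    g: GenotypeTable, r2_max: float = 0.2, seed: int = 0
) -> tuple[GenotypeTable, list[str]]:
    """Iteratively remove a random SNP from the current highest-r^2 pair.

    Repeats until all remaining pairwise r^2 values are <= ``r2_max``. Ties on
    the maximum are broken by lexicographic (locus_id, locus_id) pair order;
    the removed member of the winning pair is chosen uniformly at random.
    """
    if g.n_loci < 2:
        return g.copy(), []
    rng = np.random.default_rng(seed)
    r2 = pairwise_r2(g.calls)
    lids = np.array(g.locus_ids, dtype=object)
    alive = np.ones(g.n_loci, dtype=bool)
    removed: list[str] = []
    while alive.sum() > 1:
        sub = r2[np.ix_(alive, alive)]
        mx = sub.max()
        if mx <= r2_max:
            break
        ai = np.flatnonzero(alive)
        ii, jj = np.where(sub == mx)
        pairs = [
            tuple(sorted((str(lids[ai[a]]), str(lids[ai[b]]))))
            for a, b in zip(ii, jj)
            if a < b
        ]
        first, second = min(pairs)
        victim = first if rng.integers(2) == 0 else second
        alive[np.flatnonzero(lids == victim)[0]] = False
        removed.append(victim)
    return g.subset_loci(alive), removed


def sidak_alpha(alpha: float, m: int) -> float:
    """Dunn–Šidák family-wise threshold: 1 - (1 - alpha)^(1/m)."""
    if m <= 0:
        raise ValueError("m must be positive")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def hwe_chisq(g: GenotypeTable) -> pd.DataFrame:
    """Classical chi-square HWE test per locus and population (df = 1).

    Expected genotype counts are n*(q^2, 2pq, p^2) from the observed allele
    frequency over non-missing calls. Monomorphic locus-population combinations
    are skipped (the test is undefined) and logged.
    """
    rows = []
    skipped = 0
    for pop, sub in g.per_pop():
        calls = sub.calls
        obs = calls != MISSING
        n0 = ((calls == 0) & obs).sum(axis=0)
        n1 = ((calls == 1) & obs).sum(axis=0)
        n2 = ((calls == 2) & obs).sum(axis=0)
        n = n0 + n1 + n2
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (2.0 * n2 + n1) / (2.0 * n)
        for i, lid in enumerate(g.locus_ids):
            if n[i] == 0 or p[i] in (0.0, 1.0) or np.isnan(p[i]):
                skipped += 1
                continue
            q = 1.0 - p[i]
            exp = n[i] * np.array([q**2, 2 * p[i] * q, p[i] ** 2])
            obs_counts = np.array([n0[i], n1[i], n2[i]], dtype=float)
            chi2 = float(((obs_counts - exp) ** 2 / exp).sum())
            rows.append((lid, pop, int(n[i]), chi2, float(stats.chi2.sf(chi2, df=1))))
    if skipped:
        logger.info("HWE: %d monomorphic locus-population tests skipped", skipped)
    return pd.DataFrame(rows, columns=["locus_id", "pop", "n", "chi2", "p"])


def hwe_filter(
    g: GenotypeTable,
    alpha: float = 0.05,
    test_ids: list[str] | None = None,
    m_mode: str = "global",
) -> tuple[GenotypeTable, list[str], pd.DataFrame]:
    """Remove loci deviating from HWE in any population after Šidák correction.

    ``test_ids`` restricts the individuals the test statistics are computed on
    (e.g. a relative-free subset); removals always apply to the full table.
    ``m_mode``: ``global`` counts all performed tests (loci x populations,
    skipped monomorphic tests excluded); ``per_pop`` corrects within each
    population separately.
    """
    test_table = g.subset_individuals(test_ids) if test_ids is not None else g
    stats_df = hwe_chisq(test_table)
    if stats_df.empty:
        return g.copy(), [], stats_df
    if m_mode == "global":
        thr = sidak_alpha(alpha, len(stats_df))
        stats_df = stats_df.assign(threshold=thr, significant=stats_df["p"] < thr)
    elif m_mode == "per_pop":
        parts = []
        for pop, grp in stats_df.groupby("pop", sort=False):
            thr = sidak_alpha(alpha, len(grp))
            parts.append(grp.assign(threshold=thr, significant=grp["p"] < thr))
        stats_df = pd.concat(parts, ignore_index=True)
    else:
        raise ValueError(f"unknown m_mode {m_mode!r}")
    bad = stats_df.loc[stats_df["significant"], "locus_id"].unique().tolist()
    bad_in_order = [lid for lid in g.locus_ids if lid in set(bad)]
    return g.drop_loci(bad_in_order), bad_in_order, stats_df


def run_qc(
    g: GenotypeTable,
    *,
    seed: int = 0,
    maf_max_excl: float = 0.05,
    miss_max_excl: float = 0.05,
    r2_max: float = 0.2,
    hwe_alpha: float = 0.05,
    hwe_test_ids: list[str] | None = None,
    hwe_m_mode: str = "global",
) -> tuple[GenotypeTable, QCReport]:
    """Run the fixed cascade: MAF/call-rate -> fragment dedup -> LD prune -> HWE."""
    report = QCReport(
        n_input=g.n_loci,
        params=dict(
            maf_max_excl=maf_max_excl,
            miss_max_excl=miss_max_excl,
            r2_max=r2_max,
            hwe_alpha=hwe_alpha,
            hwe_m_mode=hwe_m_mode,
            seed=seed,
        ),
    )
    g1, rem = filter_maf_callrate(g, maf_max_excl, miss_max_excl)
    report.removed["maf_callrate"] = rem
    g2, rem = dedup_fragments(g1, seed=seed)
    report.removed["fragment_dedup"] = rem
    g3, rem = ld_prune(g2, r2_max=r2_max, seed=seed + 1)
    report.removed["ld_prune"] = rem
    g4, rem, _ = hwe_filter(g3, alpha=hwe_alpha, test_ids=hwe_test_ids, m_mode=hwe_m_mode)
    report.removed["hwe"] = rem
    report.survivors = g4.locus_ids
    report.check()
    return g4, report
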