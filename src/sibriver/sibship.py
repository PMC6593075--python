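"""Maximum-likelihood sibship reconstruction from SNP genotypes.

Each pair of individuals is scored under three relationship classes with
standard IBD coefficients (k0, k1, k2): full sibs (0.25, 0.5, 0.25), half
sibs (0.5, 0.5, 0) and unrelated (1, 0, 0). The per-locus joint genotype
probability is P(G1, G2 | R) = k2*P2 + k1*P1 + k0*P0, where P0 is the
product of HWE genotype probabilities, and P1/P2 condition on one/two
alleles shared identical by descent. Genotyping error enters as a mixture:
an observed genotype is the true one with probability 1 - err, otherwise an
independent HWE draw.

Families are assembled from the pairwise calls: full-sib families are the
connected components of the FS graph (audited for strong unrelated pairs),
each receives a fresh dummy sire and dam, and half-sib links merge one
parent slot between families in descending likelihood-ratio order. Founder
pairs then share both dummy parents iff full sibs, exactly one iff half sibs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import MISSING, UNKNOWN_PARENT, GenotypeTable, Pedigree

logger = logging.getLogger("sibriver")

#: IBD coefficients (k0, k1, k2) per relationship class
K_COEFFS = {"FS": (0.25, 0.5, 0.25), "HS": (0.5, 0.5, 0.0), "U": (1.0, 0.0, 0.0)}

CLASSES = ("FS", "HS", "U")


def subset_for_sibship(g: GenotypeTable, maf_min_excl: float = 0.2) -> GenotypeTable:
    """Retain loci with MAF strictly greater than ``maf_min_excl``.

    Intended to be applied to one population's table at a time, before that
    population's sibship run; highly informative markers keep the pairwise
    likelihoods sharp while shrinking the locus set.
    """
    maf = g.maf()
    # strict boundary with a float guard: a count-exact MAF of 0.2 is removed
    with np.errstate(invalid="ignore"):
        keep = ~np.isnan(maf) & (maf > maf_min_excl + 1e-9)
    return g.subset_loci(keep)


def _joint_tables(p: np.ndarray, err: float) -> dict[str, np.ndarray]:
    """(L, 3, 3) joint genotype probability tables per class, genotype = ref-allele count.

    Rows/columns are indexed by the reference-allele count (0, 1, 2) of each
    individual; with error, T = (1-e)^2 * J + (2e - e^2) * HWE x HWE, valid
    because the marginals of J are HWE under every class.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    hwe = np.stack([q**2, 2 * p * q, p**2], axis=1)  # index = ref count
    JU = hwe[:, :, None] * hwe[:, None, :]
    L = len(p)
    J2 = np.zeros((L, 3, 3))
    J2[:, 0, 0] = q**2
    J2[:, 1, 1] = 2 * p * q
    J2[:, 2, 2] = p**2
    J1 = np.zeros((L, 3, 3))
    J1[:, 2, 2] = p**3
    J1[:, 2, 1] = J1[:, 1, 2] = p**2 * q
    J1[:, 1, 1] = p * q
    J1[:, 1, 0] = J1[:, 0, 1] = p * q**2
    J1[:, 0, 0] = q**3
    out = {}
    for cls, (k0, k1, k2) in K_COEFFS.items():
        J = k0 * JU + k1 * J1 + k2 * J2
        out[cls] = (1.0 - err) ** 2 * J + (2.0 * err - err**2) * JU
    return out


@dataclass
class PairLikelihood:
    """Log-likelihoods of one pair under each relationship class."""

    loglik: dict[str, float]
    n_loci: int

    @property
    def best(self) -> str:
        return max(CLASSES, key=lambda c: (self.loglik[c], c == "U"))

    @property
    def llr_vs_u(self) -> float:
        """Log-likelihood ratio of the best class against unrelated."""
        return self.loglik[self.best] - self.loglik["U"]


def pair_loglik(
    g1: np.ndarray, g2: np.ndarray, p: np.ndarray, err: float = 0.0
) -> PairLikelihood:
    """Total log-likelihood of one genotype pair under FS/HS/U.

    Loci with either call missing are skipped; every used locus must have a
    frequency strictly inside (0, 1).
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    p = np.asarray(p, dtype=float)
    used = (g1 != MISSING) & (g2 != MISSING)
    if np.any((p[used] <= 0.0) | (p[used] >= 1.0)):
        raise ValueError("allele frequency outside (0, 1) at a used locus")
    tables = _joint_tables(p[used], err)
    a = g1[used].astype(int)
    b = g2[used].astype(int)
    idx = np.arange(used.sum())
    ll = {cls: float(np.log(tables[cls][idx, a, b]).sum()) for cls in CLASSES}
    return PairLikelihood(loglik=ll, n_loci=int(used.sum()))


_PAIR_COLUMNS = ["id1", "id2", "ll_fs", "ll_hs", "ll_u", "best", "llr", "n_loci"]

#: cap on leave-family-out fixed-point passes in classify_pairs
_LOO_MAX_ITER = 4

#: full-sib seeding threshold on the KING-robust 2x-kinship scale
#: (full sibs ~0.5, half sibs ~0.25; 2^-1.5 sits between them)
_KING_FS_MIN = 2.0 ** -1.5


def king_robust(calls: np.ndarray) -> np.ndarray:
    """Pairwise KING-robust relatedness (2x kinship) without allele frequencies.

    For a pair, 2*phi = (2 N_het,het - 4 N_opp-hom) / (N_het(i) + N_het(j)),
    counted over jointly observed loci. Full sibs center near 0.5, half sibs
    near 0.25, unrelated near 0; the estimator is insensitive to the
    sib-induced allele-frequency distortions of a skewed sample, which makes
    it a reliable seed for full-sib family detection.
    """
    obs = (calls != MISSING).astype(float)
    het = (calls == 1).astype(float)
    hom_alt = (calls == 0).astype(float)
    hom_ref = (calls == 2).astype(float)
    both_het = het @ het.T
    opp = hom_alt @ hom_ref.T + hom_ref @ hom_alt.T
    het_in_joint = het @ obs.T  # het count of i over loci also observed in j
    denom = het_in_joint + het_in_joint.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi2 = np.where(denom > 0, (2.0 * both_het - 4.0 * opp) / denom, 0.0)
    np.fill_diagonal(phi2, 1.0)
    return phi2


def _finish_pair(ids_i, ids_j, ll, n_used, lr_min, rows) -> None:
    best = max(CLASSES, key=lambda c: (ll[c], c == "U"))
    llr = ll[best] - ll["U"]
    if best != "U" and llr < lr_min:
        best = "U"
    rows.append((ids_i, ids_j, ll["FS"], ll["HS"], ll["U"], best, llr, n_used))


def _classify_fixed_freqs(
    g: GenotypeTable, p: np.ndarray, err: float, lr_min: float
) -> pd.DataFrame:
    """One pass over all pairs with a single shared frequency vector."""
    with np.errstate(invalid="ignore"):
        poly = ~np.isnan(p) & (p > 0.0) & (p < 1.0)
    if not poly.all():
        logger.info("classify_pairs: dropping %d monomorphic loci", int((~poly).sum()))
    calls = g.calls[:, poly]
    tables = _joint_tables(p[poly], err)
    logT = {cls: np.log(tables[cls]) for cls in CLASSES}
    rows: list = []
    for i, j in itertools.combinations(range(g.n_individuals), 2):
        a, b = calls[i], calls[j]
        used = (a != MISSING) & (b != MISSING)
        idx = np.flatnonzero(used)
        ll = {cls: float(logT[cls][idx, a[idx], b[idx]].sum()) for cls in CLASSES}
        _finish_pair(g.ids[i], g.ids[j], ll, len(idx), lr_min, rows)
    return pd.DataFrame(rows, columns=_PAIR_COLUMNS)


def _pair_loglik_freqs(a, b, p, err) -> dict[str, float]:
    """Class log-likelihoods for one pair with its own per-locus frequencies."""
    q = 1.0 - p
    r = np.arange(len(p))
    hwe = np.stack([q**2, 2 * p * q, p**2])
    P0 = hwe[a, r] * hwe[b, r]
    P2 = np.where(a == b, hwe[a, r], 0.0)
    one_ibd = np.stack([q**3, p * q**2, p * q, p**2 * q, p**3])
    P1 = np.where(np.abs(a - b) == 2, 0.0, one_ibd[a + b, r])
    keep, mix = (1.0 - err) ** 2, 2.0 * err - err**2
    ll = {}
    for cls, (k0, k1, k2) in K_COEFFS.items():
        J = k0 * P0 + k1 * P1 + k2 * P2
        ll[cls] = float(np.log(keep * J + mix * P0).sum())
    return ll


def classify_pairs(
    g: GenotypeTable,
    err: float = 0.01,
    lr_min: float = 3.0,
    freqs: np.ndarray | None = None,
    freq_mode: str = "loo_family",
) -> pd.DataFrame:
    """Assign every pair its maximum-likelihood class among FS, HS, U.

    Pairs whose best-vs-U log-likelihood ratio falls below ``lr_min`` are
    forced to U to control false family formation. Monomorphic loci carry no
    pairwise information and are dropped.

    Frequency handling (``freq_mode``, ignored when ``freqs`` is supplied):

    ``loo_family`` (default)
        Deterministic fixed-point iteration. Each pass scores every pair
        with family-weighted frequencies (each currently detected full-sib
        family counts as one observation) computed *excluding both members'
        families*; the FS calls of a pass define the families of the next,
        starting from a frequency-free KING-robust seed partition, until
        the family partition stabilizes (at most ``_LOO_MAX_ITER`` passes).
        Sib-laden
        samples otherwise contaminate the frequency estimate with the very
        alleles being scored, which masks sib sharing. When fewer than four
        families are detected, only the pair itself is left out.
    ``sample``
        Single pass with plain observed sample frequencies.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least two individuals")
    if freqs is not None:
        return _classify_fixed_freqs(g, np.asarray(freqs, dtype=float), err, lr_min)
    if freq_mode == "sample":
        return _classify_fixed_freqs(g, g.allele_freq(), err, lr_min)
    if freq_mode != "loo_family":
        raise ValueError(f"unknown freq_mode {freq_mode!r}")

    obs = g.observed_mask()
    gval = np.where(obs, g.calls, 0).astype(float)
    idx = {ind: i for i, ind in enumerate(g.ids)}
    phi2 = king_robust(g.calls)
    seed_graph = nx.Graph()
    seed_graph.add_nodes_from(g.ids)
    for i, j in itertools.combinations(range(g.n_individuals), 2):
        if phi2[i, j] > _KING_FS_MIN:
            seed_graph.add_edge(g.ids[i], g.ids[j])
    fams = [sorted(c) for c in nx.connected_components(seed_graph)]
    prev_partition = None
    pairs = None
    for _ in range(_LOO_MAX_ITER):
        fam_of = {ind: k for k, members in enumerate(fams) for ind in members}
        weights = np.array([1.0 / len(fams[fam_of[ind]]) for ind in g.ids])
        fam_S = np.zeros((len(fams), g.n_loci))
        fam_C = np.zeros((len(fams), g.n_loci))
        for k, members in enumerate(fams):
            rows_k = [idx[m] for m in members]
            fam_S[k] = (weights[rows_k, None] * gval[rows_k]).sum(axis=0)
            fam_C[k] = (weights[rows_k, None] * 2.0 * obs[rows_k]).sum(axis=0)
        tot_S, tot_C = fam_S.sum(axis=0), fam_C.sum(axis=0)
        leave_pair_only = len(fams) < 4
        if leave_pair_only:
            logger.info(
                "classify_pairs: only %d detected families; leave-pair-out "
                "frequencies used",
                len(fams),
            )
        rows: list = []
        for i, j in itertools.combinations(range(g.n_individuals), 2):
            a_full, b_full = g.calls[i], g.calls[j]
            used = (a_full != MISSING) & (b_full != MISSING)
            fi, fj = fam_of[g.ids[i]], fam_of[g.ids[j]]
            if leave_pair_only:
                S = tot_S - weights[i] * gval[i] - weights[j] * gval[j]
                C = tot_C - 2.0 * weights[i] * obs[i] - 2.0 * weights[j] * obs[j]
            elif fi == fj:
                S, C = tot_S - fam_S[fi], tot_C - fam_C[fi]
            else:
                S = tot_S - fam_S[fi] - fam_S[fj]
                C = tot_C - fam_C[fi] - fam_C[fj]
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(C > 0, S / np.maximum(C, 1e-12), 0.5)
            p = np.clip(p, 0.01, 0.99)
            ll = _pair_loglik_freqs(
                a_full[used].astype(int), b_full[used].astype(int), p[used], err
            )
            _finish_pair(g.ids[i], g.ids[j], ll, int(used.sum()), lr_min, rows)
        pairs = pd.DataFrame(rows, columns=_PAIR_COLUMNS)
        fs_graph = nx.Graph()
        fs_graph.add_nodes_from(g.ids)
        for r in pairs.itertuples(index=False):
            if r.best == "FS":
                fs_graph.add_edge(r.id1, r.id2)
        fams = [sorted(c) for c in nx.connected_components(fs_graph)]
        partition = tuple(sorted(tuple(f) for f in fams))
        if partition == prev_partition:
            break
        prev_partition = partition
    return pairs


@dataclass
class SibshipResult:
    """Full-sib partition, dummy-parent assignments and half-sib links."""

    #: columns: individual, pop, family, dummy_sire, dummy_dam
    assignments: pd.DataFrame
    #: unique dummy parents per population
    dummy_parent_counts: dict[str, int] = field(default_factory=dict)
    #: founder pairs sharing >= 1 dummy parent: id1, id2, n_shared
    shared_parent_pairs: pd.DataFrame | None = None


def build_families(
    pairs: pd.DataFrame,
    ids: list[str],
    pop: str = "pop1",
    lr_min: float = 3.0,
) -> SibshipResult:
    """Assemble full-sib families and dummy parents from pairwise calls.

    Full-sib families are connected components of the FS graph. Components
    holding a pair whose unrelated log-likelihood beats full-sib by more than
    ``lr_min`` are split by removing the weakest FS edge, iterated until
    consistent. HS-classified cross-family pairs then merge one parent slot
    between families, processed in descending LR order; a merge is accepted
    only when consistent with every previously merged link and with the
    observed link set (families sharing a parent must pairwise share one,
    and no family keeps more than two parents). Inconsistent links are
    dropped and logged; leftover parent slots get fresh private dummies.
    """
    ids = list(map(str, ids))
    by_pair = {
        tuple(sorted((r.id1, r.id2))): r for r in pairs.itertuples(index=False)
    }
    fs_graph = nx.Graph()
    fs_graph.add_nodes_from(ids)
    for key, r in by_pair.items():
        if r.best == "FS":
            fs_graph.add_edge(*key, llr=r.llr)

    # audit: strong unrelated evidence inside a component splits it
    while True:
        conflict_edge = None
        for comp in nx.connected_components(fs_graph):
            comp = sorted(comp)
            if len(comp) < 2:
                continue
            strong_u = False
            for a, b in itertools.combinations(comp, 2):
                r = by_pair.get((a, b))
                if r is not None and (r.ll_u - r.ll_fs) > lr_min:
                    strong_u = True
                    break
            if strong_u:
                edges = sorted(
                    fs_graph.subgraph(comp).edges(data="llr"),
                    key=lambda e: (e[2], tuple(sorted(e[:2]))),
                )
                conflict_edge = edges[0][:2]
                break
        if conflict_edge is None:
            break
        logger.info("sibship audit: splitting FS edge %s", conflict_edge)
        fs_graph.remove_edge(*conflict_edge)

    comps = sorted(nx.connected_components(fs_graph), key=lambda c: min(c))
    fam_of = {}
    for k, comp in enumerate(comps):
        for ind in comp:
            fam_of[ind] = k

    # shared parents are recovered as "parent groups": sets of families that
    # pairwise share >= 1 parent. Half-sib evidence is aggregated at the
    # family level: if two families truly share a parent, EVERY cross pair
    # between them is a half-sib pair, so the link statistic is the summed
    # log-LR (HS vs U) over all cross pairs — a lone misclassified pair
    # between two large families cannot fabricate a link. A family belongs
    # to at most two groups (its sire and its dam); a family may only join a
    # group if it is linked to every current member (families sharing a
    # parent must form a clique in the link graph) and does not already
    # share a different parent with any member (two families never share
    # both parents).
    agg_llr: dict[tuple[int, int], float] = {}
    for r in by_pair.values():
        fa, fb = fam_of[r.id1], fam_of[r.id2]
        if fa == fb:
            continue
        key = (min(fa, fb), max(fa, fb))
        agg_llr[key] = agg_llr.get(key, 0.0) + (r.ll_hs - r.ll_u)
    hs_links = sorted(
        ((key, total) for key, total in agg_llr.items() if total > lr_min),
        key=lambda kv: (-kv[1], kv[0]),
    )
    adjacency = {key for key, _ in hs_links}

    groups: list[set[int]] = []
    fam_groups: dict[int, list[int]] = {k: [] for k in range(len(comps))}

    def _can_join(guest: int, gi: int) -> bool:
        if len(fam_groups[guest]) >= 2 or gi in fam_groups[guest]:
            return False
        for m in groups[gi]:
            if (min(m, guest), max(m, guest)) not in adjacency:
                return False
            if any(m in groups[gj] for gj in fam_groups[guest]):
                return False  # would share a second parent with m
        return True

    for (fa, fb), total in hs_links:
        if any(fa in groups[gi] for gi in fam_groups[fb]):
            continue  # already share a parent: consistent
        done = False
        for host, guest in ((fa, fb), (fb, fa)):
            for gi in fam_groups[host]:
                if _can_join(guest, gi):
                    groups[gi].add(guest)
                    fam_groups[guest].append(gi)
                    done = True
                    break
            if done:
                break
        if not done:
            if len(fam_groups[fa]) < 2 and len(fam_groups[fb]) < 2:
                groups.append({fa, fb})
                fam_groups[fa].append(len(groups) - 1)
                fam_groups[fb].append(len(groups) - 1)
            else:
                logger.info(
                    "sibship: dropping half-sib link between families %d and %d "
                    "(total log-LR %.1f) inconsistent with prior merges",
                    fa,
                    fb,
                    total,
                )

    # name dummy parents in family order: shared groups first, then private slots
    group_name: dict[int, str] = {}
    n_named = 0
    rows = []
    for k in range(len(comps)):
        names = []
        for gi in fam_groups[k]:
            if gi not in group_name:
                group_name[gi] = f"{pop}_DP{n_named}"
                n_named += 1
            names.append(group_name[gi])
        while len(names) < 2:
            names.append(f"{pop}_DP{n_named}")
            n_named += 1
        for ind in sorted(comps[k]):
            rows.append((ind, pop, f"{pop}_F{k}", names[0], names[1]))
    assignments = (
        pd.DataFrame(
            rows, columns=["individual", "pop", "family", "dummy_sire", "dummy_dam"]
        )
        .set_index("individual")
        .loc[ids]
        .reset_index()
    )

    shared = []
    parent_sets = {
        r.individual: {r.dummy_sire, r.dummy_dam}
        for r in assignments.itertuples(index=False)
    }
    for a, b in itertools.combinations(ids, 2):
        n_shared = len(parent_sets[a] & parent_sets[b])
        if n_shared:
            shared.append((a, b, n_shared))
    return SibshipResult(
        assignments=assignments,
        dummy_parent_counts={pop: n_named},
        shared_parent_pairs=pd.DataFrame(shared, columns=["id1", "id2", "n_shared"]),
    )


def reconstruct_sibship(
    g: GenotypeTable,
    err: float = 0.01,
    lr_min: float = 3.0,
    maf_min_excl: float = 0.2,
) -> SibshipResult:
    """Per-population sibship reconstruction on the MAF-subset marker panel."""
    parts, shared_parts = [], []
    counts: dict[str, int] = {}
    for pop, sub in g.per_pop():
        panel = subset_for_sibship(sub, maf_min_excl)
        pairs = classify_pairs(panel, err=err, lr_min=lr_min)
        res = build_families(pairs, panel.ids, pop=pop, lr_min=lr_min)
        parts.append(res.assignments)
        shared_parts.append(res.shared_parent_pairs)
        counts.update(res.dummy_parent_counts)
    return SibshipResult(
        assignments=pd.concat(parts, ignore_index=True),
        dummy_parent_counts=counts,
        shared_parent_pairs=pd.concat(shared_parts, ignore_index=True),
    )


def sibship_to_pedigree(s: SibshipResult) -> Pedigree:
    """Founder pedigree with dummy parents entered as unrelated founders."""
    rows = []
    seen: set[str] = set()
    for r in s.assignments.itertuples(index=False):
        for parent in (r.dummy_sire, r.dummy_dam):
            if parent not in seen:
                rows.append((parent, UNKNOWN_PARENT, UNKNOWN_PARENT, r.pop))
                seen.add(parent)
    for r in s.assignments.itertuples(index=False):
        rows.append((r.individual, r.dummy_sire, r.dummy_dam, r.pop))
    return Pedigree(
        pd.DataFrame(rows, columns=["individual", "sire", "dam", "pop"])
    )
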