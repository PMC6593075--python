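"""Genomic (VanRaden method 1) and pedigree (tabular) relationship matrices,
relationship categorization, cross-population anomaly flagging, greedy
selection of pairwise-unrelated founders, and the ΔF / Ne closed form.

The G matrix is G = ZZ' / (2 Σ p_i (1 - p_i)) with Z = M - P, where M holds
-1/0/1 for the alternate homozygote / heterozygote / reference homozygote,
P has rows 2(p_i - 0.5) and p_i is the frequency of the reference allele
(the allele whose homozygote codes +1). Missing entries of M are imputed to
the locus mean of observed entries, so they vanish after centering when
observed frequencies are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import UNKNOWN_PARENT, GenotypeTable, Pedigree, RelMatrix

#: relationship-category bounds: < low boundary -> "low",
#: [low, high] -> "mid", > high boundary -> "high"
CATEGORY_BOUNDS = (0.156, 0.370)


def compute_grm(
    g: GenotypeTable,
    freq_source: str = "observed",
    freqs: np.ndarray | None = None,
) -> RelMatrix:
    """VanRaden method-1 genomic relationship matrix with mean imputation.

    Parameters
    ----------
    freq_source
        ``observed`` derives p_i from the table; ``supplied`` centres and
        scales with ``freqs`` (reference-allele frequencies, one per locus).
    """
    if g.n_loci == 0:
        raise ValueError("empty genotype table")
    obs = g.observed_mask()
    M = g.calls.astype(float) - 1.0  # -1/0/1 coding; ref homozygote -> +1
    M[~obs] = np.nan
    if freq_source == "observed":
        p = g.allele_freq()
    elif freq_source == "supplied":
        if freqs is None:
            raise ValueError("freq_source='supplied' requires freqs")
        p = np.asarray(freqs, dtype=float)
        if p.shape != (g.n_loci,):
            raise ValueError("freqs length does not match locus count")
    else:
        raise ValueError(f"unknown freq_source {freq_source!r}")
    if np.any(np.isnan(p)):
        raise ValueError("allele frequency undefined at some locus (all calls missing)")
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0.0:
        raise ValueError("all loci monomorphic: VanRaden denominator is zero")
    # mean of observed M entries per locus (column); imputed entries then
    # contribute 0 to Z when p is the observed frequency
    col_mean = np.nanmean(M, axis=0)
    M = np.where(np.isnan(M), col_mean, M)
    Z = M - 2.0 * (p - 0.5)
    G = (Z @ Z.T) / denom
    G = (G + G.T) / 2.0  # exact numerical symmetry
    return RelMatrix(list(g.ids), G, kind="genomic")


def make_A(p: Pedigree) -> RelMatrix:
    """Additive (numerator) relationship matrix by the tabular method.

    a_ii = 1 + a(sire, dam)/2; a_ij = (a(j, sire_i) + a(j, dam_i))/2 with
    unknown parents contributing zero. Raises on pedigree cycles, listing one.
    """
    rec = p.records
    dag = nx.DiGraph()
    dag.add_nodes_from(rec["individual"])
    for _, row in rec.iterrows():
        for parent in (row["sire"], row["dam"]):
            if parent != UNKNOWN_PARENT:
                dag.add_edge(parent, row["individual"])
    try:
        order = list(nx.topological_sort(dag))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(dag)
        raise ValueError(f"pedigree contains a cycle: {cycle}") from None
    parents = {
        row["individual"]: (row["sire"], row["dam"]) for _, row in rec.iterrows()
    }
    pos = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for ind in order:
        i = pos[ind]
        s, d = parents.get(ind, (UNKNOWN_PARENT, UNKNOWN_PARENT))
        si = pos.get(s) if s != UNKNOWN_PARENT else None
        di = pos.get(d) if d != UNKNOWN_PARENT else None
        row_s = A[si, :i] if si is not None else 0.0
        row_d = A[di, :i] if di is not None else 0.0
        A[i, :i] = 0.5 * (row_s + row_d)
        A[:i, i] = A[i, :i]
        asd = A[si, di] if (si is not None and di is not None) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    # return in pedigree record order
    idx = np.array([pos[ind] for ind in rec["individual"]])
    return RelMatrix(rec["individual"].tolist(), A[np.ix_(idx, idx)], kind="pedigree")


def categorize_relationships(m: RelMatrix) -> np.ndarray:
    """Entrywise category matrix: low (< 0.156), mid (0.156–0.370, closed), high (> 0.370)."""
    lo, hi = CATEGORY_BOUNDS
    return np.select(
        [m.values < lo, m.values > hi], ["low", "high"], default="mid"
    ).astype(object)


def flag_cross_pop_pairs(
    m: RelMatrix, labels: dict[str, str], g_min: float = 0.35
) -> tuple[pd.DataFrame, list[str]]:
    """Pairs from different populations with relationship >= ``g_min``.

    Such pairs indicate labeling or fish-management mistakes (e.g. transfers
    across rivers); the union of implicated individuals is returned for
    optional removal.
    """
    absent = [i for i in m.ids if i not in labels]
    if absent:
        raise ValueError(f"no population label for: {absent[:5]}")
    rows = []
    implicated: list[str] = []
    for i in range(len(m.ids)):
        for j in range(i + 1, len(m.ids)):
            a, b = m.ids[i], m.ids[j]
            if labels[a] != labels[b] and m.values[i, j] >= g_min:
                rows.append((a, b, labels[a], labels[b], m.values[i, j]))
                for x in (a, b):
                    if x not in implicated:
                        implicated.append(x)
    return (
        pd.DataFrame(rows, columns=["id1", "id2", "pop1", "pop2", "relationship"]),
        implicated,
    )


@dataclass
class UnrelatedSet:
    """Ordered selection of pairwise-unrelated individuals plus its audit trace."""

    selected: list[str]
    #: one record per event: (step, appended individual, removed relatives)
    trace: list[dict] = field(default_factory=list)


def select_unrelated(a: RelMatrix) -> UnrelatedSet:
    """Greedy selection of individuals that are pairwise unrelated in A.

    (i) start from the full matrix; (ii) move every individual whose
    off-diagonal entries are all zero to the selected list; (iii) append the
    remaining individual with the lowest mean off-diagonal relationship to
    the remainder (ties by lexicographic ID), then delete it and all its
    relatives (a_ij > 0); (iv) repeat iii until nothing remains.
    """
    n = len(a.ids)
    if n == 0:
        return UnrelatedSet(selected=[], trace=[])
    ids = list(a.ids)
    V = a.values
    alive = np.ones(n, dtype=bool)
    selected: list[str] = []
    trace: list[dict] = []

    off = V.copy()
    np.fill_diagonal(off, 0.0)
    iso = [i for i in range(n) if np.all(off[i, :] == 0.0)]
    for i in iso:  # step ii, input order
        selected.append(ids[i])
        alive[i] = False
    if iso:
        trace.append({"step": "ii", "appended": [ids[i] for i in iso], "removed": []})

    while alive.any():  # steps iii-iv
        live = np.flatnonzero(alive)
        means = []
        for i in live:
            others = live[live != i]
            means.append(off[i, others].mean() if len(others) else 0.0)
        best = min(range(len(live)), key=lambda k: (means[k], ids[live[k]]))
        chosen = live[best]
        selected.append(ids[chosen])
        relatives = [j for j in live if j != chosen and off[chosen, j] > 0.0]
        alive[chosen] = False
        for j in relatives:
            alive[j] = False
        trace.append(
            {"step": "iii", "appended": [ids[chosen]], "removed": [ids[j] for j in relatives]}
        )
    return UnrelatedSet(selected=selected, trace=trace)


@dataclass
class NeEstimate:
    delta_f: float
    ne: float  # math.inf when delta_f == 0
    ne_rounded: int | None


def ne_from_mean_relationship(a_bar: float) -> NeEstimate:
    """ΔF = ā/2 and Ne = 1/(2ΔF) from a mean additive relationship.

    With random mating among individuals of mean relationship ā, the expected
    per-generation increase in inbreeding is ā/2; Ne is unbounded at ā = 0.
    """
    if a_bar < 0:
        raise ValueError("mean relationship must be non-negative")
    delta_f = a_bar / 2.0
    if delta_f == 0.0:
        return NeEstimate(delta_f=0.0, ne=math.inf, ne_rounded=None)
    ne = 1.0 / (2.0 * delta_f)
    return NeEstimate(delta_f=delta_f, ne=ne, ne_rounded=round(ne))


def mean_relationship(m: RelMatrix, mode: str = "full") -> float:
    """Mean of all entries (``full``) or of strictly off-diagonal entries (``offdiag``)."""
    if len(m.ids) == 0:
        raise ValueError("empty matrix")
    if mode == "full":
        return float(m.values.mean())
    if mode == "offdiag":
        if len(m.ids) == 1:
            return 0.0
        mask = ~np.eye(len(m.ids), dtype=bool)
        return float(m.values[mask].mean())
    raise ValueError(f"unknown mode {mode!r}")
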