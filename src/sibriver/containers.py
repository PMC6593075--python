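"""Core in-memory containers shared across the pipeline.

Genotype calls are coded project-wide as counts of the *reference* allele:
2 = reference homozygote, 1 = heterozygote, 0 = alternate homozygote,
:data:`MISSING` (-1) = no call.  The -1/0/1 coding used inside the genomic
relationship matrix is an internal transform, never a file format.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call in the int8 call matrix
MISSING = -1

#: token used in pedigree records for an unknown parent
UNKNOWN_PARENT = "0"

_ALLOWED_CALLS = frozenset({-1, 0, 1, 2})

LOCUS_COLUMNS = ["locus_id", "fragment_id", "ref", "alt"]


def _find_duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in items:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class GenotypeTable:
    """Individuals x biallelic loci call matrix with fragment IDs and population labels.

    Parameters
    ----------
    ids
        Individual identifiers (unique).
    pops
        Population label per individual, aligned with ``ids``.
    loci
        Locus metadata table with columns ``locus_id``, ``fragment_id``,
        ``ref``, ``alt``; one row per locus, in call-matrix column order.
    calls
        ``(n_individuals, n_loci)`` int8 matrix with entries in
        {0, 1, 2, MISSING} counting reference alleles.
    """

    ids: list[str]
    pops: np.ndarray
    loci: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(map(str, self.ids))
        self.pops = np.asarray(self.pops, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.loci.index.size and not isinstance(self.loci.index, pd.RangeIndex):
            self.loci = self.loci.reset_index(drop=True)
        dup = _find_duplicates(self.ids)
        if dup:
            raise ValueError(f"duplicate individual IDs: {dup}")
        dup = _find_duplicates(self.loci["locus_id"].astype(str))
        if dup:
            raise ValueError(f"duplicate locus IDs: {dup}")
        missing_cols = [c for c in LOCUS_COLUMNS if c not in self.loci.columns]
        if missing_cols:
            raise ValueError(f"loci table lacks columns {missing_cols}")
        if self.pops.shape != (len(self.ids),):
            raise ValueError("population labels do not align with individual IDs")
        if self.calls.shape != (len(self.ids), len(self.loci)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.loci)} loci"
            )
        bad = set(np.unique(self.calls)) - _ALLOWED_CALLS
        if bad:
            raise ValueError(f"call matrix holds values outside {{0,1,2,missing}}: {sorted(bad)}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return self.loci["locus_id"].astype(str).tolist()

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            list(self.ids), self.pops.copy(), self.loci.copy(), self.calls.copy()
        )

    # -- per-locus summaries --------------------------------------------
    def observed_mask(self) -> np.ndarray:
        """Boolean matrix, True where a call was made."""
        return self.calls != MISSING

    def allele_freq(self) -> np.ndarray:
        """Observed reference-allele frequency per locus (NaN if never observed)."""
        obs = self.observed_mask()
        n = obs.sum(axis=0)
        tot = np.where(obs, self.calls, 0).sum(axis=0, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        """Observed minor-allele frequency per locus (NaN if never observed)."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    # -- subsetting ------------------------------------------------------
    def subset_loci(self, index: Sequence[int] | np.ndarray) -> "GenotypeTable":
        """Positional or boolean selection of loci, order-preserving."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeTable(
            list(self.ids),
            self.pops.copy(),
            self.loci.iloc[idx].reset_index(drop=True),
            self.calls[:, idx],
        )

    def drop_loci(self, locus_ids: Iterable[str]) -> "GenotypeTable":
        drop = set(map(str, locus_ids))
        keep = [i for i, lid in enumerate(self.locus_ids) if lid not in drop]
        return self.subset_loci(keep)

    def subset_individuals(self, ids: Iterable[str]) -> "GenotypeTable":
        wanted = list(map(str, ids))
        pos = {x: i for i, x in enumerate(self.ids)}
        absent = [x for x in wanted if x not in pos]
        if absent:
            raise KeyError(f"unknown individual IDs: {absent}")
        idx = [pos[x] for x in wanted]
        return GenotypeTable(wanted, self.pops[idx], self.loci.copy(), self.calls[idx])

    def pop_names(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        out: list[str] = []
        for p in self.pops:
            if p not in out:
                out.append(p)
        return out

    def per_pop(self) -> Iterator[tuple[str, "GenotypeTable"]]:
        for pop in self.pop_names():
            sel = [i for i, p in zip(self.ids, self.pops) if p == pop]
            yield pop, self.subset_individuals(sel)


@dataclass
class Pedigree:
    """(individual, sire, dam, population) records; ``"0"`` marks an unknown parent."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["individual", "sire", "dam", "pop"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValueError(f"pedigree lacks columns {missing}")
        self.records = self.records[req].astype(str).reset_index(drop=True)
        dup = _find_duplicates(self.records["individual"])
        if dup:
            raise ValueError(f"duplicate pedigree individuals: {dup}")
        own = self.records[
            (self.records["individual"] == self.records["sire"])
            | (self.records["individual"] == self.records["dam"])
        ]
        if len(own):
            raise ValueError(
                f"individuals listed as their own parent: {own['individual'].tolist()}"
            )

    @property
    def individuals(self) -> list[str]:
        return self.records["individual"].tolist()

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class RelMatrix:
    """Dense symmetric relationship matrix (genomic G or pedigree A) keyed by IDs."""

    ids: list[str]
    values: np.ndarray
    kind: str = "genomic"  # "genomic" | "pedigree"

    def __post_init__(self) -> None:
        self.ids = list(map(str, self.ids))
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("relationship matrix holds non-finite entries")
        if n and np.max(np.abs(self.values - self.values.T)) > 1e-10:
            raise ValueError("relationship matrix is not symmetric within 1e-10")
        if self.kind not in ("genomic", "pedigree"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        dup = _find_duplicates(self.ids)
        if dup:
            raise ValueError(f"duplicate matrix IDs: {dup}")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: Iterable[str]) -> "RelMatrix":
        wanted = list(map(str, ids))
        pos = {x: i for i, x in enumerate(self.ids)}
        absent = [x for x in wanted if x not in pos]
        if absent:
            raise KeyError(f"unknown matrix IDs: {absent}")
        idx = np.array([pos[x] for x in wanted], dtype=int)
        return RelMatrix(wanted, self.values[np.ix_(idx, idx)], self.kind)

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self.ids.index(str(i)), self.ids.index(str(j))])
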