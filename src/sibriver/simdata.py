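"""Synthetic river populations with mass-spawning family structure.

The generator emulates spawn collections from several diverged river
populations. Divergence follows the Balding–Nichols model: each population's
allele frequency at a locus is a Beta draw around the ancestral frequency
with variance governed by a single parameter interpretable as the expected
FST. Within each population a fixed pool of sires and dams mates through a
Dirichlet-weighted sire x dam table, so a small concentration parameter
concentrates offspring into few families — the skewed parental contribution
typical of sampling fertilized spawn. Genotyping error (symmetric miscall),
missing calls, multi-SNP fragments and high-LD partner loci are layered on
afterwards so that every downstream stage (QC, relationship matrices,
sibship reconstruction, popgen summaries) has something real to remove.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MISSING, GenotypeTable


@dataclass
class SimConfig:
    """Parameters of one simulated spawn-collection study."""

    n_pops: int = 3
    fst_target: float = 0.005
    n_sires: int = 25
    n_dams: int = 25
    n_offspring_sampled: int = 75
    #: Dirichlet concentration over sire x dam mating cells; smaller values
    #: concentrate offspring into fewer families (down to a single mating
    #: pair). The default yields spawn collections with a broad family-size
    #: mixture - many singleton matings plus a handful of sizable full-sib
    #: families - so a usable unrelated-founder subset survives selection.
    contribution_alpha: float = 0.04
    n_loci: int = 2000
    #: fraction of base loci that get a second, identical SNP on the same fragment
    frac_dup_fragment: float = 0.1
    #: fraction of base loci duplicated as high-r2 partners on distinct fragments
    frac_ld_pairs: float = 0.05
    maf_floor: float = 0.1
    err_rate: float = 0.01
    miss_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_pops", "n_sires", "n_dams", "n_offspring_sampled", "n_loci"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "frac_dup_fragment",
            "frac_ld_pairs",
            "err_rate",
            "miss_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must lie in [0, 1)")
        if not 0.0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in (0, 0.5)")
        if self.contribution_alpha <= 0:
            raise ValueError("contribution_alpha must be positive")


@dataclass
class SimTruth:
    """Ground truth accompanying one simulated genotype table."""

    #: columns: offspring, sire, dam, pop — exactly one sire and dam per offspring
    pedigree: pd.DataFrame
    #: long table: locus_id, pop, freq (true per-population reference-allele frequency)
    pop_freqs: pd.DataFrame
    #: columns: locus_id, freq (ancestral reference-allele frequency)
    anc_freqs: pd.DataFrame
    #: clean genotypes of the parental pools (no error, no missingness)
    parents: GenotypeTable

    def contributing_parents(self, pop: str | None = None) -> dict[str, int]:
        """True number of distinct parents contributing sampled offspring, per pop."""
        out: dict[str, int] = {}
        for p, grp in self.pedigree.groupby("pop", sort=False):
            out[str(p)] = len(set(grp["sire"]) | set(grp["dam"]))
        if pop is not None:
            return {pop: out[pop]}
        return out


def _hwe_genotypes(rng: np.random.Generator, freqs: np.ndarray, n: int) -> np.ndarray:
    """n individuals drawn in HWE at the given per-locus frequencies."""
    return rng.binomial(2, freqs[None, :].repeat(n, axis=0)).astype(np.int8)


def _transmit(rng: np.random.Generator, parent_calls: np.ndarray) -> np.ndarray:
    """One gamete per (offspring, locus): Bernoulli(genotype / 2)."""
    return rng.binomial(1, parent_calls / 2.0).astype(np.int8)


def simulate_population(config: SimConfig) -> tuple[GenotypeTable, SimTruth]:
    """Simulate spawn collections from diverged river populations.

    Returns the sampled offspring genotype table (with error, missingness and
    duplicated loci applied) plus the ground truth needed for recovery tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.n_loci
    F = config.fst_target

    anc = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=L)
    pop_names = [f"pop{i + 1}" for i in range(config.n_pops)]
    if F > 0.0:
        shape1 = anc * (1.0 - F) / F
        shape2 = (1.0 - anc) * (1.0 - F) / F
        pop_p = {pop: rng.beta(shape1, shape2) for pop in pop_names}
    else:  # no-divergence branch: Beta parameters undefined at F = 0
        pop_p = {pop: anc.copy() for pop in pop_names}

    parent_ids: list[str] = []
    parent_pops: list[str] = []
    parent_calls: list[np.ndarray] = []
    ped_rows: list[tuple[str, str, str, str]] = []
    off_ids: list[str] = []
    off_pops: list[str] = []
    off_calls: list[np.ndarray] = []

    for pop in pop_names:
        p = pop_p[pop]
        sires = [f"{pop}_S{i}" for i in range(config.n_sires)]
        dams = [f"{pop}_D{i}" for i in range(config.n_dams)]
        sire_g = _hwe_genotypes(rng, p, config.n_sires)
        dam_g = _hwe_genotypes(rng, p, config.n_dams)
        parent_ids += sires + dams
        parent_pops += [pop] * (len(sires) + len(dams))
        parent_calls += [sire_g, dam_g]

        n_cells = config.n_sires * config.n_dams
        weights = rng.dirichlet(np.full(n_cells, config.contribution_alpha))
        cells = rng.choice(n_cells, size=config.n_offspring_sampled, p=weights)
        for k, cell in enumerate(cells):
            si, di = divmod(int(cell), config.n_dams)
            oid = f"{pop}_O{k}"
            gam = _transmit(rng, sire_g[si]) + _transmit(rng, dam_g[di])
            off_ids.append(oid)
            off_pops.append(pop)
            off_calls.append(gam)
            ped_rows.append((oid, sires[si], dams[di], pop))

    calls = np.vstack(off_calls).astype(np.int8)

    # symmetric miscall: heterozygote -> random homozygote, homozygote -> heterozygote
    if config.err_rate > 0:
        err = rng.random(calls.shape) < config.err_rate
        flip_to = np.where(
            calls == 1, 2 * rng.integers(0, 2, size=calls.shape), 1
        ).astype(np.int8)
        calls = np.where(err, flip_to, calls)
    if config.miss_rate > 0:
        calls = np.where(rng.random(calls.shape) < config.miss_rate, MISSING, calls)
    calls = calls.astype(np.int8)

    locus_ids = [f"L{i}" for i in range(L)]
    frag_ids = [f"frag{i}" for i in range(L)]
    loci = pd.DataFrame(
        {"locus_id": locus_ids, "fragment_id": frag_ids, "ref": "A", "alt": "B"}
    )

    # multi-SNP fragments: exact copies of their partner, same fragment
    n_dup = int(round(config.frac_dup_fragment * L))
    dup_src = rng.choice(L, size=n_dup, replace=False) if n_dup else np.array([], int)
    # high-LD partners on distinct fragments: copies with 5% of calls re-drawn from HWE
    n_ld = int(round(config.frac_ld_pairs * L))
    ld_src = rng.choice(L, size=n_ld, replace=False) if n_ld else np.array([], int)

    extra_cols = [calls]
    extra_rows = [loci]
    freq_rows = {pop: [pop_p[pop]] for pop in pop_names}

    if n_dup:
        dup_calls = calls[:, dup_src]
        dup_loci = pd.DataFrame(
            {
                "locus_id": [f"L{i}_b" for i in dup_src],
                "fragment_id": [f"frag{i}" for i in dup_src],
                "ref": "A",
                "alt": "B",
            }
        )
        extra_cols.append(dup_calls)
        extra_rows.append(dup_loci)
        for pop in pop_names:
            freq_rows[pop].append(pop_p[pop][dup_src])

    if n_ld:
        ld_calls = calls[:, ld_src].copy()
        pop_index = {pop: np.array([p == pop for p in off_pops]) for pop in pop_names}
        redraw = rng.random(ld_calls.shape) < 0.05
        for pop in pop_names:
            rows = pop_index[pop]
            hwe_draw = rng.binomial(2, pop_p[pop][ld_src][None, :].repeat(rows.sum(), axis=0))
            block = ld_calls[rows]
            block[redraw[rows]] = hwe_draw.astype(np.int8)[redraw[rows]]
            ld_calls[rows] = block
        ld_loci = pd.DataFrame(
            {
                "locus_id": [f"L{i}_ld" for i in ld_src],
                "fragment_id": [f"fragL{i}" for i in ld_src],
                "ref": "A",
                "alt": "B",
            }
        )
        extra_cols.append(ld_calls.astype(np.int8))
        extra_rows.append(ld_loci)
        for pop in pop_names:
            freq_rows[pop].append(pop_p[pop][ld_src])

    all_calls = np.hstack(extra_cols).astype(np.int8)
    all_loci = pd.concat(extra_rows, ignore_index=True)

    table = GenotypeTable(off_ids, np.array(off_pops, dtype=object), all_loci, all_calls)

    parents = GenotypeTable(
        parent_ids,
        np.array(parent_pops, dtype=object),
        all_loci.copy(),
        np.hstack(
            [np.vstack(parent_calls)]
            + ([np.vstack(parent_calls)[:, dup_src]] if n_dup else [])
            + ([np.vstack(parent_calls)[:, ld_src]] if n_ld else [])
        ).astype(np.int8),
    )

    all_locus_ids = all_loci["locus_id"].tolist()
    pop_freqs = pd.concat(
        [
            pd.DataFrame(
                {
                    "locus_id": all_locus_ids,
                    "pop": pop,
                    "freq": np.concatenate(freq_rows[pop]),
                }
            )
            for pop in pop_names
        ],
        ignore_index=True,
    )
    anc_freqs = pd.DataFrame({"locus_id": locus_ids, "freq": anc})
    truth = SimTruth(
        pedigree=pd.DataFrame(ped_rows, columns=["offspring", "sire", "dam", "pop"]),
        pop_freqs=pop_freqs,
        anc_freqs=anc_freqs,
        parents=parents,
    )
    return table, truth


def write_truth(truth: SimTruth, out_dir: str | Path) -> None:
    """Write pedigree and frequency truth as delimited text (lossless round trip)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.pedigree.to_csv(out / "true_pedigree.tsv", sep="\t", index=False)
    truth.pop_freqs.to_csv(
        out / "true_pop_freqs.tsv", sep="\t", index=False, float_format="%.17g"
    )
    truth.anc_freqs.to_csv(
        out / "true_anc_freqs.tsv", sep="\t", index=False, float_format="%.17g"
    )


def read_truth(out_dir: str | Path, parents: GenotypeTable | None = None) -> SimTruth:
    out = Path(out_dir)
    return SimTruth(
        pedigree=pd.read_csv(out / "true_pedigree.tsv", sep="\t", dtype=str),
        pop_freqs=pd.read_csv(
            out / "true_pop_freqs.tsv", sep="\t", dtype={"locus_id": str, "pop": str}
        ),
        anc_freqs=pd.read_csv(out / "true_anc_freqs.tsv", sep="\t", dtype={"locus_id": str}),
        parents=parents,
    )


def write_manifest(config: SimConfig, path: str | Path) -> None:
    """Echo every generator parameter (seed included) to a run-manifest file."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
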