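"""End-to-end founder characterization: qc -> grm -> sibship -> A -> unrelated -> popgen.

The pipeline mirrors a two-pass structure around the Hardy–Weinberg filter:
a preliminary sibship pass flags full-sib pairs, one member of each flagged
pair is set aside, HWE statistics are computed on the relative-free subset,
and removals are applied to the full table. Reports are deterministic given
the config seed (timings go to the logger, never into the report).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geno_io, qc, relatedness, sibship
from . import popgen as pg
from .containers import GenotypeTable
from .qc import QCReport

logger = logging.getLogger("sibriver")


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and its cause."""


@dataclass
class PipelineConfig:
    genotypes: str
    populations: str | None = None
    genotype_format: str = "matrix"
    out_dir: str = "sibriver_out"
    seed: int = 0
    # qc
    maf_max_excl: float = 0.05
    miss_max_excl: float = 0.05
    r2_max: float = 0.2
    hwe_alpha: float = 0.05
    hwe_m_mode: str = "global"
    # sibship
    err_rate: float = 0.01
    lr_min: float = 3.0
    sibship_maf_min: float = 0.2
    # relatedness
    cross_pop_g_min: float = 0.35
    mean_rel_mode: str = "full"
    # popgen
    fst_n_boot: int = 2000
    k_max: int = 20
    kmeans_n_start: int = 1000
    rarefaction_g_max: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.genotypes:
            raise ValueError("config does not name a genotype file")
        if not Path(self.genotypes).exists():
            raise FileNotFoundError(f"genotype file not found: {self.genotypes}")
        if self.populations and not Path(self.populations).exists():
            raise FileNotFoundError(f"population file not found: {self.populations}")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def _prelim_relative_free_ids(g: GenotypeTable, cfg: PipelineConfig) -> list[str]:
    """Preliminary sibship pass: drop one member of each flagged full-sib pair."""
    removed: set[str] = set()
    for pop, sub in g.per_pop():
        panel = sibship.subset_for_sibship(sub, cfg.sibship_maf_min)
        if panel.n_loci == 0 or panel.n_individuals < 2:
            continue
        pairs = sibship.classify_pairs(panel, err=cfg.err_rate, lr_min=cfg.lr_min)
        fs = pairs[pairs["best"] == "FS"].sort_values(["id1", "id2"])
        for r in fs.itertuples(index=False):
            if r.id1 not in removed and r.id2 not in removed:
                removed.add(max(r.id1, r.id2))
    return [i for i in g.ids if i not in removed]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order, writing per-stage outputs and a report.

    Returns the report as a dict; the same content is written to
    ``report.json`` and a human-readable ``report.txt`` under ``out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config)}

    @_stage("read")
    def read() -> GenotypeTable:
        return geno_io.read_genotypes(
            config.genotypes, format=config.genotype_format, pops=config.populations
        )

    g_raw = read()
    report["n_individuals"] = g_raw.n_individuals
    report["n_loci_input"] = g_raw.n_loci

    @_stage("qc")
    def do_qc() -> tuple[GenotypeTable, QCReport]:
        rep = QCReport(n_input=g_raw.n_loci, params={"seed": config.seed})
        g1, rem = qc.filter_maf_callrate(g_raw, config.maf_max_excl, config.miss_max_excl)
        rep.removed["maf_callrate"] = rem
        g2, rem = qc.dedup_fragments(g1, seed=config.seed)
        rep.removed["fragment_dedup"] = rem
        g3, rem = qc.ld_prune(g2, r2_max=config.r2_max, seed=config.seed + 1)
        rep.removed["ld_prune"] = rem
        test_ids = _prelim_relative_free_ids(g3, config)
        g4, rem, _ = qc.hwe_filter(
            g3, alpha=config.hwe_alpha, test_ids=test_ids, m_mode=config.hwe_m_mode
        )
        rep.removed["hwe"] = rem
        rep.survivors = g4.locus_ids
        rep.check()
        return g4, rep

    g_qc, qc_report = do_qc()
    qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    geno_io.write_genotypes(g_qc, out / "genotypes_qc.tsv")
    report["qc"] = {**qc_report.counts(), "surviving": len(qc_report.survivors)}

    @_stage("grm")
    def do_grm():
        return relatedness.compute_grm(g_qc)

    G = do_grm()
    geno_io.write_matrix(G, out / "grm.tsv")

    @_stage("cross_pop")
    def do_flags():
        labels = dict(zip(g_qc.ids, g_qc.pops))
        return relatedness.flag_cross_pop_pairs(G, labels, g_min=config.cross_pop_g_min)

    flags, implicated = do_flags()
    flags.to_csv(out / "cross_pop_flags.tsv", sep="\t", index=False)
    report["cross_pop"] = {"n_pairs": len(flags), "omitted_individuals": implicated}
    g_kept = (
        g_qc.subset_individuals([i for i in g_qc.ids if i not in set(implicated)])
        if implicated
        else g_qc
    )

    @_stage("sibship")
    def do_sibship():
        res = sibship.reconstruct_sibship(
            g_kept,
            err=config.err_rate,
            lr_min=config.lr_min,
            maf_min_excl=config.sibship_maf_min,
        )
        return res, sibship.sibship_to_pedigree(res)

    sib, pedigree = do_sibship()
    sib.assignments.to_csv(out / "sibship_assignments.tsv", sep="\t", index=False)
    geno_io.write_pedigree(pedigree, out / "pedigree.tsv")
    report["sibship"] = {
        "dummy_parents_per_pop": sib.dummy_parent_counts,
        "n_families": int(sib.assignments["family"].nunique()),
    }

    @_stage("amatrix")
    def do_a():
        A_all = relatedness.make_A(pedigree)
        return A_all.subset(sib.assignments["individual"].tolist())

    A = do_a()
    geno_io.write_matrix(A, out / "amatrix.tsv")

    @_stage("unrelated")
    def do_unrelated():
        return relatedness.select_unrelated(A)

    unrelated = do_unrelated()
    (out / "unrelated_founders.txt").write_text("\n".join(unrelated.selected) + "\n")
    pd.DataFrame(unrelated.trace).to_csv(out / "unrelated_trace.tsv", sep="\t", index=False)
    pop_of = dict(zip(g_kept.ids, g_kept.pops))
    per_pop_unrel: dict[str, int] = {}
    for ind in unrelated.selected:
        per_pop_unrel[pop_of[ind]] = per_pop_unrel.get(pop_of[ind], 0) + 1
    report["unrelated"] = {
        "n_selected": len(unrelated.selected),
        "per_pop": per_pop_unrel,
    }
    a_bar_full = relatedness.mean_relationship(A, mode="full")
    a_bar_off = relatedness.mean_relationship(A, mode="offdiag")
    ne = relatedness.ne_from_mean_relationship(
        a_bar_full if config.mean_rel_mode == "full" else a_bar_off
    )
    report["inbreeding"] = {
        "mean_A_full": a_bar_full,
        "mean_A_offdiag": a_bar_off,
        "delta_F": ne.delta_f,
        "Ne": ne.ne if ne.ne != float("inf") else "unbounded",
        "Ne_rounded": ne.ne_rounded,
    }

    @_stage("popgen")
    def do_popgen() -> dict:
        sub = g_kept.subset_individuals(unrelated.selected)
        het = pg.heterozygosity(sub)
        het.to_csv(out / "heterozygosity.tsv", sep="\t", index=False)
        means = pg.mean_heterozygosity(het)
        ttests = {}
        for pop, grp in het.groupby("pop", sort=False):
            t, p = pg.paired_hobs_hexp_test(grp["hobs"].to_numpy(), grp["hexp"].to_numpy())
            ttests[pop] = {"t": t, "p": p}
        section: dict = {
            "heterozygosity": means.to_dict(orient="records"),
            "paired_t": ttests,
        }
        if len(sub.pop_names()) >= 2:
            fst, overall = pg.wc_fst(sub, n_boot=config.fst_n_boot, seed=config.seed + 2)
            fst.to_csv(out / "fst.tsv", sep="\t", index=False)
            section["fst_pairwise"] = fst.to_dict(orient="records")
            section["fst_overall"] = overall
        rar = pg.rarefaction_richness(sub, g_max=config.rarefaction_g_max)
        rar.to_csv(out / "rarefaction.tsv", sep="\t", index=False)
        scores, var_pct = pg.pca(sub)
        pd.DataFrame({"axis": np.arange(1, len(var_pct) + 1), "var_pct": var_pct}).to_csv(
            out / "pca_variance.tsv", sep="\t", index=False
        )
        bic, best_k = pg.kmeans_bic(
            scores,
            k_max=config.k_max,
            n_start=config.kmeans_n_start,
            seed=config.seed + 3,
        )
        bic.to_csv(out / "kmeans_bic.tsv", sep="\t", index=False)
        section["pc1_var_pct"] = float(var_pct[0]) if len(var_pct) else 0.0
        section["best_k"] = best_k
        return section

    report["popgen"] = do_popgen()

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    (out / "report.txt").write_text(_render_report(report))
    return report


def _render_report(report: dict) -> str:
    lines = ["sibriver pipeline report", "=" * 24, ""]
    lines.append(f"individuals: {report['n_individuals']}")
    lines.append(f"input loci: {report['n_loci_input']}")
    lines.append("")
    lines.append("SNP quality control")
    for k, v in report["qc"].items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append("cross-population anomalies")
    lines.append(f"  flagged pairs: {report['cross_pop']['n_pairs']}")
    lines.append(f"  omitted individuals: {len(report['cross_pop']['omitted_individuals'])}")
    lines.append("")
    lines.append("sibship")
    for pop, n in sorted(report["sibship"]["dummy_parents_per_pop"].items()):
        lines.append(f"  dummy parents ({pop}): {n}")
    lines.append(f"  families: {report['sibship']['n_families']}")
    lines.append("")
    lines.append("unrelated founders")
    lines.append(f"  selected: {report['unrelated']['n_selected']}")
    for pop, n in sorted(report["unrelated"]["per_pop"].items()):
        lines.append(f"  {pop}: {n}")
    lines.append("")
    ib = report["inbreeding"]
    lines.append("inbreeding outlook")
    lines.append(f"  mean A (full): {ib['mean_A_full']:.6f}")
    lines.append(f"  mean A (off-diagonal): {ib['mean_A_offdiag']:.6f}")
    lines.append(f"  delta_F: {ib['delta_F']:.6f}")
    lines.append(f"  Ne: {ib['Ne']} (rounded: {ib['Ne_rounded']})")
    lines.append("")
    popg = report["popgen"]
    lines.append("population genetics (unrelated founders)")
    for rec in popg["heterozygosity"]:
        lines.append(
            f"  {rec['pop']}: Hobs={rec['hobs']:.4f} Hexp={rec['hexp']:.4f}"
        )
    for pop, tt in sorted(popg["paired_t"].items()):
        lines.append(f"  paired t ({pop}): t={tt['t']:.3f} p={tt['p']:.3g}")
    if "fst_pairwise" in popg:
        for rec in popg["fst_pairwise"]:
            lines.append(
                f"  FST {rec['pop1']}-{rec['pop2']}: {rec['fst']:.5f} "
                f"[{rec['ci_low']:.5f}, {rec['ci_high']:.5f}]"
            )
        lines.append(f"  FST overall: {popg['fst_overall']:.5f}")
    lines.append(f"  PC1 variance: {popg['pc1_var_pct']:.2f}%")
    lines.append(f"  best K (min BIC): {popg['best_k']}")
    lines.append("")
    return "\n".join(lines)
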