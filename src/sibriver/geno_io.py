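"""Readers and writers for genotype, pedigree, population and matrix files.

All formats are plain delimited text. The genotype matrix layout is one row
per locus: ``locus_id``, ``fragment_id``, ``ref``, ``alt``, then one call per
individual coded 0/1/2 (reference-allele copies) or ``NA``. A two-row DArT-style
dialect (``dart_2row``) and plain VCF are also read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import LOCUS_COLUMNS, MISSING, GenotypeTable, Pedigree, RelMatrix

logger = logging.getLogger("sibriver")

_CALL_TOKENS = {"0": 0, "1": 1, "2": 2}
_MISSING_TOKENS = {"NA", "", "-", ".", "NaN", "nan"}


def _check_rectangular(path: Path, sep: str = "\t") -> None:
    """Reject ragged files up front, naming the offending line."""
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            n = line.count(sep) + 1
            if width is None:
                width = n
            elif n != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} ({n} fields, expected {width})"
                )


def _tokens_to_calls(block: pd.DataFrame, path: str) -> np.ndarray:
    """Map call tokens to int8 {0,1,2,MISSING}; unknown tokens -> missing, logged."""
    raw = block.astype(str).to_numpy()
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    unknown = 0
    for tok, val in _CALL_TOKENS.items():
        calls[raw == tok] = val
    known = np.isin(raw, list(_CALL_TOKENS) + sorted(_MISSING_TOKENS))
    unknown = int((~known).sum())
    if unknown:
        logger.warning("%s: %d unrecognised call tokens treated as missing", path, unknown)
    return calls


def read_populations(path: str | Path) -> dict[str, str]:
    """Read a two-column (id, pop) table into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns id, pop")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_populations(ids: Iterable[str], pops: Iterable[str], path: str | Path) -> None:
    pd.DataFrame({"id": list(ids), "pop": list(pops)}).to_csv(path, sep="\t", index=False)


def _resolve_pops(ids: list[str], pops: Mapping[str, str] | None) -> np.ndarray:
    if pops is None:
        return np.array(["pop1"] * len(ids), dtype=object)
    absent = [i for i in ids if i not in pops]
    if absent:
        raise ValueError(f"no population label for individuals: {absent[:5]}")
    return np.array([pops[i] for i in ids], dtype=object)


def read_genotypes(
    path: str | Path,
    format: str = "matrix",
    pops: Mapping[str, str] | str | Path | None = None,
) -> GenotypeTable:
    """Read a genotype table.

    Parameters
    ----------
    format
        ``matrix`` (one row per locus), ``dart_2row`` (two presence/absence
        rows per SNP, one per allele) or ``vcf``.
    pops
        Mapping of individual ID to population label, or path to a two-column
        file; individuals default to a single population when omitted.
    """
    if isinstance(pops, (str, Path)):
        pops = read_populations(pops)
    path = Path(path)
    if format == "matrix":
        return _read_matrix_format(path, pops)
    if format == "dart_2row":
        return _read_dart_2row(path, pops)
    if format == "vcf":
        return _read_vcf(path, pops)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_matrix_format(path: Path, pops: Mapping[str, str] | None) -> GenotypeTable:
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in LOCUS_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    ids = [c for c in df.columns if c not in LOCUS_COLUMNS]
    loci = df[LOCUS_COLUMNS].copy()
    calls = _tokens_to_calls(df[ids], str(path)).T  # loci-rows -> individuals x loci
    return GenotypeTable(ids, _resolve_pops(ids, pops), loci, calls)


def _read_dart_2row(path: Path, pops: Mapping[str, str] | None) -> GenotypeTable:
    """Collapse two 0/1 presence rows per SNP (ref row then alt row) to 0/1/2.

    Collapse rule per (ref-present, alt-present): (1,0) -> 2, (1,1) -> 1,
    (0,1) -> 0, (0,0) -> missing.
    """
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    req = ["locus_id", "fragment_id", "allele"]
    missing_cols = [c for c in req if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    ids = [c for c in df.columns if c not in req]
    if len(df) % 2:
        raise ValueError(f"{path}: odd number of rows for a two-row-per-SNP file")
    ref_rows = df.iloc[0::2].reset_index(drop=True)
    alt_rows = df.iloc[1::2].reset_index(drop=True)
    if not (ref_rows["locus_id"].values == alt_rows["locus_id"].values).all():
        raise ValueError(f"{path}: allele rows are not paired by locus_id")
    ref = _tokens_to_calls(ref_rows[ids], str(path))
    alt = _tokens_to_calls(alt_rows[ids], str(path))
    calls = np.full(ref.shape, MISSING, dtype=np.int8)
    calls[(ref == 1) & (alt == 0)] = 2
    calls[(ref == 1) & (alt == 1)] = 1
    calls[(ref == 0) & (alt == 1)] = 0
    loci = ref_rows[["locus_id", "fragment_id"]].copy()
    loci["ref"] = "A"
    loci["alt"] = "B"
    return GenotypeTable(ids, _resolve_pops(ids, pops), loci, calls.T)


def _read_vcf(path: Path, pops: Mapping[str, str] | None) -> GenotypeTable:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires cyvcf2 (install sibriver[vcf])") from exc
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, calls = [], []
    # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT; coding counts REF copies
    code = np.array([2, 1, MISSING, 0], dtype=np.int8)
    for var in vcf:
        lid = var.ID or f"{var.CHROM}_{var.POS}"
        frag = var.INFO.get("FRAG", lid)
        rows.append((lid, frag, var.REF, var.ALT[0] if var.ALT else "."))
        calls.append(code[np.asarray(var.gt_types)])
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    mat = np.array(calls, dtype=np.int8).T if calls else np.empty((len(ids), 0), dtype=np.int8)
    return GenotypeTable(ids, _resolve_pops(ids, pops), loci, mat)


def write_genotypes(g: GenotypeTable, path: str | Path) -> None:
    """Write the one-row-per-locus matrix format (calls 0/1/2/NA)."""
    tokens = g.calls.astype(object)
    out = g.loci.copy()
    for j, ind in enumerate(g.ids):
        col = tokens[j].astype(object)
        col[g.calls[j] == MISSING] = "NA"
        out[ind] = col
    out.to_csv(path, sep="\t", index=False)


def write_vcf(g: GenotypeTable, path: str | Path, contig: str = "1") -> None:
    """Emit a minimal GT-only VCF; positions are 1-based locus indices."""
    gt_map = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##INFO=<ID=FRAG,Number=1,Type=String,Description="Fragment ID">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.ids) + "\n")
        for i in range(g.n_loci):
            row = g.loci.iloc[i]
            ref = row["ref"] if str(row["ref"]) in "ACGT" else "A"
            alt = row["alt"] if str(row["alt"]) in "ACGT" else "C"
            gts = "\t".join(gt_map[int(c)] for c in g.calls[:, i])
            fh.write(
                f"{contig}\t{i + 1}\t{row['locus_id']}\t{ref}\t{alt}\t.\t.\t"
                f"FRAG={row['fragment_id']}\tGT\t{gts}\n"
            )


# -- relationship matrices ---------------------------------------------


def write_matrix(m: RelMatrix, path: str | Path) -> None:
    """Round-trip-safe (<=1e-12) symmetric matrix writer."""
    with open(path, "w") as fh:
        fh.write("kind\t" + m.kind + "\n")
        fh.write("id\t" + "\t".join(m.ids) + "\n")
        for i, ind in enumerate(m.ids):
            fh.write(ind + "\t" + "\t".join(format(v, ".17g") for v in m.values[i]) + "\n")


def read_matrix(path: str | Path) -> RelMatrix:
    with open(path) as fh:
        kind_line = fh.readline().rstrip("\n").split("\t")
        header = fh.readline().rstrip("\n").split("\t")
        if kind_line[0] != "kind" or header[0] != "id":
            raise ValueError(f"{path}: not a sibriver matrix file")
        kind = kind_line[1]
        ids = header[1:]
        rows = []
        for lineno, line in enumerate(fh, start=3):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(ids) + 1:
                raise ValueError(f"{path}: ragged row at line {lineno}")
            rows.append((parts[0], [float(x) for x in parts[1:]]))
    if [r[0] for r in rows] != ids:
        raise ValueError(f"{path}: row IDs do not match header IDs")
    values = np.array([r[1] for r in rows], dtype=float)
    return RelMatrix(ids, values, kind)  # symmetry enforced by the container


# -- pedigrees ----------------------------------------------------------


def write_pedigree(p: Pedigree, path: str | Path) -> None:
    p.records.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    _check_rectangular(Path(path))
    return Pedigree(pd.read_csv(path, sep="\t", dtype=str))
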