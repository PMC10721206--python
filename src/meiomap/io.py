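"""Readers and writers for every on-disk format the pipeline touches.

Count matrices travel as a MatrixMarket coordinate triplet (matrix.mtx +
barcodes.tsv + features.tsv, optionally a clusters.tsv sidecar), the 10x
convention with rows = cells and columns = genes.  Tables are headered
TSV/CSV, promoters/genomes are FASTA, TSS lists are BED (0-based
half-open), variant candidates are a VCFv4.2 subset or an equivalent TSV,
and trees are newick.  VCF-like records are 1-based inclusive throughout.

Every reader validates the invariants of the object it builds and raises
:class:`FormatError` / :class:`SchemaError` with enough context to locate
the offending record.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml
from Bio import SeqIO

from .mutload import VariantCandidate

__all__ = [
    "CountMatrix",
    "FormatError",
    "SchemaError",
    "PipelineConfig",
    "read_count_matrix",
    "write_count_matrix",
    "read_table",
    "read_sequences",
    "write_sequences",
    "read_variants",
    "write_variants",
    "read_tss_bed",
    "write_tss_bed",
    "read_pwms",
    "write_pwms",
    "read_newick",
    "write_newick",
    "get_logger",
]


class FormatError(ValueError):
    """A file violates the structural contract of its format."""


class SchemaError(ValueError):
    """A table is missing required columns or carries unparseable values."""


def get_logger(stage: str) -> logging.Logger:
    """Stage-scoped logger; messages carry the stage name for auditability."""
    logger = logging.getLogger(f"meiomap.{stage}")
    if not logger.handlers and not logging.getLogger().handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Sparse cell x gene UMI count matrix with optional cluster labels.

    ``counts`` is CSR with rows in ``cell_ids`` order and columns in
    ``gene_ids`` order; entries are non-negative integers (UMIs).
    """

    cell_ids: list[str]
    gene_ids: list[str]
    counts: sp.csr_matrix
    cluster_of_cell: dict[str, str] | None = None
    dataset_label: str = ""

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene ids")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative counts")
            if not np.all(data == np.round(data)):
                raise FormatError("non-integer counts")
        self.counts = self.counts.astype(np.int64)
        if self.cluster_of_cell is not None:
            unknown = set(self.cluster_of_cell) - set(self.cell_ids)
            if unknown:
                raise FormatError(
                    f"cluster labels for unknown barcodes: {sorted(unknown)[:5]}"
                )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def n_umi(self) -> np.ndarray:
        """Total UMIs per cell (nUMI)."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    @property
    def n_feature(self) -> np.ndarray:
        """Number of detected genes per cell (nFeature)."""
        return np.diff(self.counts.indptr)

    @property
    def clusters(self) -> list[str]:
        """Sorted distinct cluster labels (empty if unlabeled)."""
        if self.cluster_of_cell is None:
            return []
        return sorted(set(self.cluster_of_cell.values()))

    def cluster_labels(self) -> np.ndarray:
        """Per-row cluster label array; raises if any cell is unlabeled."""
        if self.cluster_of_cell is None:
            raise ValueError("matrix carries no cluster labels")
        missing = [c for c in self.cell_ids if c not in self.cluster_of_cell]
        if missing:
            raise ValueError(f"cells without cluster label: {missing[:5]}")
        return np.array([self.cluster_of_cell[c] for c in self.cell_ids])

    def to_frame(self) -> pd.DataFrame:
        """Dense cells x genes DataFrame (small matrices only)."""
        return pd.DataFrame(
            self.counts.toarray(), index=self.cell_ids, columns=self.gene_ids
        )


def _open_text(path: Path | str, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_id_column(path: Path | str) -> list[str]:
    with _open_text(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return ids


def read_count_matrix(
    matrix_path: Path | str,
    barcodes_path: Path | str,
    features_path: Path | str,
    clusters_path: Path | str | None = None,
    dataset_label: str = "",
) -> CountMatrix:
    """Read a MatrixMarket triplet (rows = cells, columns = genes).

    ``clusters_path`` is a two-column TSV mapping barcode -> cluster label.
    """
    with _open_text(matrix_path, "rb") as fh:
        mat = scipy.io.mmread(fh)
    if not np.all(mat.data == np.round(mat.data)):
        raise FormatError(f"{matrix_path}: non-integer matrix values")
    mat = sp.csr_matrix(mat).astype(np.int64)
    cells = _read_id_column(barcodes_path)
    genes = _read_id_column(features_path)
    if len(cells) != mat.shape[0]:
        raise FormatError(
            f"matrix has {mat.shape[0]} rows but {barcodes_path} lists "
            f"{len(cells)} barcodes"
        )
    if len(genes) != mat.shape[1]:
        raise FormatError(
            f"matrix has {mat.shape[1]} columns but {features_path} lists "
            f"{len(genes)} features"
        )
    cluster_of_cell = None
    if clusters_path is not None:
        cluster_of_cell = {}
        known = set(cells)
        with _open_text(clusters_path) as fh:
            for i, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    raise FormatError(f"{clusters_path}:{i}: expected 2 columns")
                barcode, label = parts[0], parts[1]
                if barcode == "barcode" and i == 1:  # optional header
                    continue
                if barcode not in known:
                    raise FormatError(
                        f"{clusters_path}:{i}: barcode {barcode!r} absent from matrix"
                    )
                cluster_of_cell[barcode] = label
    return CountMatrix(cells, genes, mat, cluster_of_cell, dataset_label)


def write_count_matrix(m: CountMatrix, out_dir: Path | str) -> dict[str, Path]:
    """Write the triplet (plus clusters.tsv when labeled); returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "barcodes": out / "barcodes.tsv",
        "features": out / "features.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(m.counts), field="integer")
    paths["barcodes"].write_text("".join(f"{c}\n" for c in m.cell_ids))
    paths["features"].write_text("".join(f"{g}\n" for g in m.gene_ids))
    if m.cluster_of_cell is not None:
        paths["clusters"] = out / "clusters.tsv"
        paths["clusters"].write_text(
            "".join(f"{c}\t{m.cluster_of_cell[c]}\n" for c in m.cell_ids
                    if c in m.cluster_of_cell)
        )
    return paths


# ---------------------------------------------------------------------------
# Generic tables
# ---------------------------------------------------------------------------


def read_table(
    path: Path | str,
    schema: Mapping[str, Callable] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a headered delimited table, enforcing a column schema.

    ``schema`` maps required column names to converter callables (e.g.
    ``float``, ``int``, ``str``); rows whose values a converter rejects are
    reported with their 1-based data row numbers.  Separator defaults to
    comma for ``.csv`` and tab otherwise.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.name.replace(".gz", "").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
        for col, conv in schema.items():
            converted = []
            bad_rows = []
            for i, raw in enumerate(df[col], 1):
                try:
                    converted.append(conv(raw))
                except (ValueError, TypeError):
                    bad_rows.append(i)
                    converted.append(None)
            if bad_rows:
                raise SchemaError(
                    f"{path}: column {col!r} unparseable at rows {bad_rows[:10]}"
                )
            df[col] = converted
    if df.empty:
        warnings.warn(f"{path}: table has a header but no data rows")
    return df


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_DNA = set("ACGTN")


def read_sequences(path: Path | str) -> dict[str, str]:
    """FASTA -> {id: uppercase DNA}; ids are the first header token."""
    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            seq = str(rec.seq).upper()
            bad = set(seq) - _DNA
            if bad:
                raise FormatError(
                    f"{path}: {rec.id}: illegal characters {sorted(bad)}"
                )
            seqs[rec.id] = seq
    return seqs


def write_sequences(seqs: Mapping[str, str], path: Path | str, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Variants (VCFv4.2 subset or equivalent TSV)
# ---------------------------------------------------------------------------

_VARIANT_TSV_COLS = [
    "contig", "pos", "ref", "alt", "qual", "depth",
    "cell_types", "cells", "in_dnaseq_panel", "is_editing_site",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Sequencing depth">
##INFO=<ID=CT,Number=.,Type=String,Description="Cell types with cells supporting the variant">
##INFO=<ID=CELLS,Number=.,Type=String,Description="Cell barcodes supporting the variant">
##INFO=<ID=DNAPANEL,Number=0,Type=Flag,Description="Present in the DNA-seq exclusion panel">
##INFO=<ID=EDIT,Number=0,Type=Flag,Description="Known A-to-I editing site">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _parse_bool(x: str) -> bool:
    s = str(x).strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no", ""}:
        return False
    raise ValueError(f"not a boolean: {x!r}")


def _parse_set(x: str) -> set[str]:
    s = str(x).strip()
    if not s or s == ".":
        return set()
    return {tok for tok in s.replace(";", ",").split(",") if tok}


def read_variants(path: Path | str) -> list[VariantCandidate]:
    """Read variant candidates from a VCFv4.2 subset or a TSV.

    Both dialects carry contig, 1-based position, ref/alt alleles, QUAL,
    depth, the supporting cell types and barcodes, and the two exclusion
    flags (DNA-seq panel membership; known A-to-I editing site).
    """
    path = Path(path)
    if path.name.replace(".gz", "").endswith(".vcf"):
        return _read_variants_vcf(path)
    df = read_table(path, schema={c: str for c in _VARIANT_TSV_COLS})
    out = []
    for i, row in enumerate(df.itertuples(index=False), 1):
        out.append(
            VariantCandidate(
                contig=row.contig,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                qual=float(row.qual),
                depth=int(row.depth),
                cell_types=_parse_set(row.cell_types),
                cells=_parse_set(row.cells),
                in_dnaseq_panel=_parse_bool(row.in_dnaseq_panel),
                is_editing_site=_parse_bool(row.is_editing_site),
            )
        )
    return out


def _read_variants_vcf(path: Path) -> list[VariantCandidate]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            alts = rec.alts or ()
            if len(alts) != 1:
                raise FormatError(f"{path}: multi-allelic record at {rec.pos}")
            ct = info.get("CT", ())
            cells = info.get("CELLS", ())
            out.append(
                VariantCandidate(
                    contig=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alts[0],
                    qual=float(rec.qual if rec.qual is not None else 0.0),
                    depth=int(info.get("DP", 0)),
                    cell_types=set(ct if isinstance(ct, tuple) else (ct,)),
                    cells=set(cells if isinstance(cells, tuple) else (cells,)),
                    in_dnaseq_panel=bool(info.get("DNAPANEL", False)),
                    is_editing_site=bool(info.get("EDIT", False)),
                )
            )
    return out


def write_variants(variants: Sequence[VariantCandidate], path: Path | str) -> None:
    """Write variants as VCFv4.2 subset (``.vcf``) or TSV (anything else)."""
    path = Path(path)
    if path.name.endswith(".vcf"):
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            for v in variants:
                info = [f"DP={v.depth}"]
                if v.cell_types:
                    info.append("CT=" + ",".join(sorted(v.cell_types)))
                if v.cells:
                    info.append("CELLS=" + ",".join(sorted(v.cells)))
                if v.in_dnaseq_panel:
                    info.append("DNAPANEL")
                if v.is_editing_site:
                    info.append("EDIT")
                fh.write(
                    f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{v.qual:.17g}\t.\t"
                    + ";".join(info) + "\n"
                )
        return
    with open(path, "w") as fh:
        fh.write("\t".join(_VARIANT_TSV_COLS) + "\n")
        for v in variants:
            fh.write(
                "\t".join(
                    [
                        v.contig,
                        str(v.pos),
                        v.ref,
                        v.alt,
                        f"{v.qual:.17g}",
                        str(v.depth),
                        ",".join(sorted(v.cell_types)),
                        ",".join(sorted(v.cells)),
                        "1" if v.in_dnaseq_panel else "0",
                        "1" if v.is_editing_site else "0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED (TSS) — 0-based half-open on disk, 1-based TSS in memory
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TssRecord:
    gene: str
    contig: str
    tss: int  # 1-based
    strand: str  # '+' or '-'


def read_tss_bed(path: Path | str) -> list[TssRecord]:
    """BED6 of single-base TSS intervals -> 1-based TSS records.

    A plus-strand TSS at 1-based position p is stored as [p-1, p); a
    minus-strand TSS uses the same single-base interval.
    """
    records = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{i}: BED6 required (got {len(parts)} cols)")
            contig, start, end, name, _score, strand = parts[:6]
            start, end = int(start), int(end)
            if end - start != 1:
                raise FormatError(f"{path}:{i}: TSS interval must be single-base")
            if strand not in "+-":
                raise FormatError(f"{path}:{i}: bad strand {strand!r}")
            records.append(TssRecord(gene=name, contig=contig, tss=start + 1,
                                     strand=strand))
    return records


def write_tss_bed(records: Iterable[TssRecord], path: Path | str) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.contig}\t{r.tss - 1}\t{r.tss}\t{r.gene}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# PWMs (simple block text: '>TF' header then one 4-column probability row
# per motif position, columns ordered A C G T)
# ---------------------------------------------------------------------------


def read_pwms(path: Path | str) -> list["PWM"]:
    from .regnet import PWM

    pwms = []
    name = None
    rows: list[list[float]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms.append(PWM(tf=name, matrix=np.array(rows)))
                name = line[1:].split()[0]
                rows = []
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise FormatError(f"{path}: PWM row needs 4 values, got {len(vals)}")
                rows.append(vals)
    if name is not None:
        pwms.append(PWM(tf=name, matrix=np.array(rows)))
    return pwms


def write_pwms(pwms: Iterable, path: Path | str) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf}\n")
            for row in pwm.matrix:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(path: Path | str):
    """Read one newick tree as an skbio TreeNode."""
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")


def write_newick(tree, path: Path | str) -> None:
    """Write an skbio TreeNode (or newick string) to ``path``."""
    if isinstance(tree, str):
        Path(path).write_text(tree if tree.endswith("\n") else tree + "\n")
    else:
        tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """YAML-backed configuration: stage parameter maps, paths, and the seed.

    Stochastic stages refuse to run without a seed; thresholds are validated
    against their documented domains by the stages that consume them.
    """

    seed: int | None = None
    paths: dict[str, str] = field(default_factory=dict)
    params: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            seed=raw.get("seed"),
            paths=dict(raw.get("paths", {})),
            params={k: dict(v) for k, v in raw.get("params", {}).items()},
        )

    def stage_params(self, stage: str) -> dict:
        return dict(self.params.get(stage, {}))

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("this stage is stochastic: a seed is required")
        return int(self.seed)


def save_json(obj, path: Path | str) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
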