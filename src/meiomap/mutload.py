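"""Somatic/de-novo variant filtering and per-cell-type mutation-load rates.

Variant candidates come pre-tabulated from an scRNA-seq pileup (one record
per substitution candidate, carrying depth, quality, the supporting cell
barcodes and cell types, and two exclusion flags).  The filter cascade
discards, in any order: indels; candidates outside the retained depth band
[depth_min, depth_max]; candidates below the quality floor; candidates seen
in the DNA-seq exclusion panel (germline); known A-to-I editing sites; and
candidates supported by any somatic cell type (hub, cyst, sheath cells or
hemocytes), which cannot be germline de-novo events.  Surviving candidates
within ``max_dist`` bp of each other in the same cells are collapsed into
single substitution events before rates are computed, because a single
mutational or reverse-transcription artefact can leave several adjacent
mismatches.

Rates per cell type: per-cell rate = events / cells; per-base rate =
per-cell rate / (bases covered by >= 10 reads in that cell type).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "VariantCandidate",
    "SubstitutionEvent",
    "MutationLoad",
    "SOMATIC_CELL_TYPES",
    "apply_filter_cascade",
    "collapse_proximal",
    "compute_rates",
    "repair_gene_contrast",
]

#: Testicular somatic support cells plus hemocytes; a candidate supported by
#: any of these cannot be a germline de-novo substitution.
SOMATIC_CELL_TYPES = frozenset({"HC", "CC", "SC", "HMC"})


@dataclass
class VariantCandidate:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    depth: int
    cell_types: set[str] = field(default_factory=set)
    cells: set[str] = field(default_factory=set)
    in_dnaseq_panel: bool = False
    is_editing_site: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref/alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if self.depth < 0:
            raise ValueError("negative depth")
        self.cell_types = set(self.cell_types)
        self.cells = set(self.cells)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or len(self.alt) != 1


@dataclass
class SubstitutionEvent:
    """One or more proximal candidates in the same cells, merged."""

    cell_type: str
    cells: set[str]
    positions: list[tuple[str, int]]  # sorted (contig, pos)

    @property
    def n_variants(self) -> int:
        return len(self.positions)


@dataclass
class MutationLoad:
    cell_type: str
    n_events: int
    n_cells: int
    covered_bases: int
    per_cell_rate: float
    per_base_rate: float


def apply_filter_cascade(
    candidates: Sequence[VariantCandidate],
    somatic_cell_types: Iterable[str] = SOMATIC_CELL_TYPES,
    depth_min: int = 10,
    depth_max: int = 50,
    qual_min: float = 30.0,
    known_cell_types: Iterable[str] | None = None,
) -> list[VariantCandidate]:
    """Conjunctive filter: a candidate survives iff it fails no clause.

    Clauses (order-free): not an indel; qual >= ``qual_min``; depth within
    the inclusive band [``depth_min``, ``depth_max``]; not in the DNA-seq
    exclusion panel; not a known A-to-I editing site; supported by no
    somatic cell type.  Input order is preserved.
    """
    somatic = set(somatic_cell_types)
    if known_cell_types is not None:
        unknown = somatic - set(known_cell_types)
        if unknown:
            raise ValueError(f"unknown somatic cell-type labels: {sorted(unknown)}")
    return [
        v
        for v in candidates
        if not v.is_indel
        and v.qual >= qual_min
        and depth_min <= v.depth <= depth_max
        and not v.in_dnaseq_panel
        and not v.is_editing_site
        and not (v.cell_types & somatic)
    ]


def collapse_proximal(
    candidates: Sequence[VariantCandidate],
    max_dist: int = 10,
) -> list[SubstitutionEvent]:
    """Merge proximal same-cell candidates into single substitution events.

    Within each cell type, two candidates are linked when they sit on the
    same contig within ``max_dist`` bp of each other and their supporting
    barcode sets intersect; single-linkage chaining (connected components
    of the link graph) defines the events.  Candidates supported by
    disjoint cell sets never merge, whatever their distance.
    """
    events: list[SubstitutionEvent] = []
    all_types = sorted({t for v in candidates for t in v.cell_types})
    for cell_type in all_types:
        members = [v for v in candidates if cell_type in v.cell_types]
        members.sort(key=lambda v: (v.contig, v.pos))
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if members[j].contig != members[i].contig:
                    break
                if members[j].pos - members[i].pos > max_dist:
                    break
                if members[i].cells & members[j].cells:
                    parent[find(i)] = find(j)
        groups: dict[int, list[VariantCandidate]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(members[i])
        for grp in groups.values():
            cells: set[str] = set()
            for v in grp:
                cells |= v.cells
            events.append(
                SubstitutionEvent(
                    cell_type=cell_type,
                    cells=cells,
                    positions=sorted((v.contig, v.pos) for v in grp),
                )
            )
    events.sort(key=lambda e: (e.cell_type, e.positions[0]))
    return events


def compute_rates(
    events: Sequence[SubstitutionEvent],
    n_cells_by_type: Mapping[str, int],
    covered_bases_by_type: Mapping[str, int],
) -> list[MutationLoad]:
    """Per-cell and per-base substitution rates for every cell type.

    per_cell = n_events / n_cells; per_base = per_cell / covered_bases,
    where covered_bases counts bases with >= 10 reads in that cell type.
    """
    counts: dict[str, int] = {}
    for e in events:
        counts[e.cell_type] = counts.get(e.cell_type, 0) + 1
    loads = []
    for cell_type in sorted(set(counts) | set(n_cells_by_type)):
        n_events = counts.get(cell_type, 0)
        n_cells = n_cells_by_type.get(cell_type, 0)
        if n_cells <= 0:
            if n_events:
                raise ValueError(f"{cell_type}: events but no cells recorded")
            warnings.warn(f"{cell_type}: zero cells; omitted from rates")
            continue
        if cell_type not in covered_bases_by_type:
            raise ValueError(f"{cell_type}: missing coverage entry")
        covered = covered_bases_by_type[cell_type]
        if covered <= 0:
            raise ValueError(f"{cell_type}: non-positive covered bases")
        per_cell = n_events / n_cells
        loads.append(
            MutationLoad(
                cell_type=cell_type,
                n_events=n_events,
                n_cells=n_cells,
                covered_bases=covered,
                per_cell_rate=per_cell,
                per_base_rate=per_cell / covered,
            )
        )
    return loads


def repair_gene_contrast(
    expr,
    repair_genes: Iterable[str],
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> tuple[float, float, float, float]:
    """Compare mean DNA-repair-gene expression between two cell groups.

    ``expr`` is a cells x genes DataFrame of normalized expression.  Each
    cell is summarized by its mean over the repair-gene set; the two group
    summaries are compared with a two-sided Welch t-test.  Returns
    (mean_a, mean_b, t, p).
    """
    genes = [g for g in repair_genes if g in expr.columns]
    if not genes:
        raise ValueError("no repair gene present in the expression matrix")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("both groups need at least 3 cells")
    a = expr.loc[list(group_a), genes].mean(axis=1).to_numpy(float)
    b = expr.loc[list(group_b), genes].mean(axis=1).to_numpy(float)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(a.mean()), float(b.mean()), float(t), float(p)
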