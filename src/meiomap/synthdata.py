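"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the statistical structure the corresponding
analysis assumes, at desk scale, and returns a :class:`SimulationTruth`
describing exactly what was planted, so recovery can be asserted without
any external data:

* cluster-structured negative-binomial UMI counts with planted marker
  genes (fold-elevated means) and an optional low-library-size cluster,
  mirroring the small-spermatid cluster whose cells have few UMIs but
  high relative marker expression;
* a TF-target expression system with linear effects plus planted PWM
  sites in the true targets' promoters;
* variant candidates of known classes (true de novo, germline
  panel-shared, A-to-I editing, somatic-shared, indels, proximal pairs);
* replicated daily count series following a piecewise-linear plan;
* multi-species bulk expression evolved by Brownian motion on a tree.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from skbio import TreeNode

from .io import CountMatrix
from .mutload import VariantCandidate
from .regnet import PWM

__all__ = [
    "SimulationTruth",
    "simulate_counts",
    "simulate_regnet",
    "simulate_variants",
    "simulate_daily_counts",
    "simulate_species_bulk",
    "DEFAULT_SPECIES_TREE",
]

#: Five-taxon testis bulk RNA-seq topology: fruit fly outgroup, then wasp,
#: ant, and the two bees as sisters.
DEFAULT_SPECIES_TREE = (
    "(Dmel:1.0,(Nvit:0.6,(Sinv:0.4,(Bter:0.2,Amel:0.2):0.25):0.25):0.4);"
)

#: Germline cell types used by the variant generator.
GERMLINE_CELL_TYPES = ("eSPG", "aSPG", "eSPC", "aSPC", "SPT", "sSPT")


@dataclass
class SimulationTruth:
    """What was planted; serialized as JSON next to the data files."""

    true_markers: dict[str, list[str]] = field(default_factory=dict)
    true_cell_types: dict[str, str] = field(default_factory=dict)
    marker_support: dict[str, list[str]] = field(default_factory=dict)
    true_edges: list[tuple[str, str, float]] = field(default_factory=list)
    true_de_novo_variants: list[tuple[str, int]] = field(default_factory=list)
    true_proximal_pairs: list[list[tuple[str, int]]] = field(default_factory=list)
    true_age_groups: dict[str, str] = field(default_factory=dict)
    true_daily_slopes: dict[int, float] = field(default_factory=dict)
    true_species_tree: str = ""
    true_rates: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: Path | str) -> None:
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            raise TypeError(type(o))

        payload = {
            k: v for k, v in self.__dict__.items() if v or isinstance(v, str)
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")


# ---------------------------------------------------------------------------
# Cluster-structured UMI counts
# ---------------------------------------------------------------------------


def simulate_counts(
    n_cells_per_cluster: Mapping[str, int] | None = None,
    n_genes: int = 500,
    marker_plan: Mapping[str, tuple[int, float]] | None = None,
    library_size_plan: Mapping[str, float] | None = None,
    dispersion: float = 0.1,
    seed: int = 0,
    cell_type_of_cluster: Mapping[str, str] | None = None,
) -> tuple[CountMatrix, SimulationTruth]:
    """Negative-binomial UMI counts with planted cluster markers.

    Per cluster, a shared baseline gene-abundance profile is multiplied,
    for that cluster's planted marker genes, by the planned fold; cell
    library sizes scatter (lognormally, CV ~ 0.2) around the cluster's
    planned mean so that at >= 200 cells the empirical cluster mean is
    within 10% of plan.  Counts are NB with variance mu + dispersion*mu^2.
    The low-library cluster convention: give it a smaller library-size
    plan, not different marker folds — its markers stay high *relative*
    to its (small) library.
    """
    if n_cells_per_cluster is None:
        n_cells_per_cluster = {"c1": 200, "c2": 200, "c3": 200}
    clusters = list(n_cells_per_cluster)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    if any(n <= 0 for n in n_cells_per_cluster.values()):
        raise ValueError("non-positive cluster size")
    if marker_plan is None:
        marker_plan = {c: (10, 8.0) for c in clusters}
    if sum(n for n, _ in marker_plan.values()) > n_genes:
        raise ValueError("marker plan exceeds the number of genes")
    for c, (n_mark, fold) in marker_plan.items():
        if fold < 1:
            raise ValueError(f"{c}: marker fold must be >= 1")
    if library_size_plan is None:
        library_size_plan = {c: 5000.0 for c in clusters}
    if cell_type_of_cluster is None:
        cell_type_of_cluster = {
            c: GERMLINE_CELL_TYPES[i % len(GERMLINE_CELL_TYPES)]
            for i, c in enumerate(clusters)
        }
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    truth = SimulationTruth()
    # disjoint marker blocks, assigned in cluster order from the gene list
    cursor = 0
    marker_genes: dict[str, list[str]] = {}
    for c in clusters:
        n_mark, _ = marker_plan.get(c, (0, 1.0))
        marker_genes[c] = genes[cursor : cursor + n_mark]
        cursor += n_mark
    rows = []
    cell_ids = []
    cluster_of_cell = {}
    sigma = 0.2  # lognormal sd of the cell size factor
    for c in clusters:
        profile = baseline.copy()
        n_mark, fold = marker_plan.get(c, (0, 1.0))
        idx = [genes.index(g) for g in marker_genes[c]]
        profile[idx] *= fold
        props = profile / profile.sum()
        n_cells = n_cells_per_cluster[c]
        # mean-1 lognormal size factors keep the cluster mean on plan
        factors = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=n_cells)
        lib = library_size_plan[c] * factors
        mu = lib[:, None] * props[None, :]
        r = 1.0 / dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
        rows.append(counts)
        for i in range(n_cells):
            barcode = f"{c}_cell{i:04d}"
            cell_ids.append(barcode)
            cluster_of_cell[barcode] = c
    counts = sp.csr_matrix(np.vstack(rows))
    matrix = CountMatrix(cell_ids, genes, counts, cluster_of_cell, "synthetic")
    truth.true_markers = {c: list(marker_genes[c]) for c in clusters}
    truth.true_cell_types = dict(cell_type_of_cluster)
    truth.marker_support = {
        g: [cell_type_of_cluster[c]] for c in clusters for g in marker_genes[c]
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# Regulatory-network inputs
# ---------------------------------------------------------------------------


def _random_pwm(rng: np.random.Generator, length: int) -> np.ndarray:
    """Sharp PWM: each position favours one base with probability 0.85."""
    mat = np.full((length, 4), 0.05)
    for i in range(length):
        mat[i, rng.integers(0, 4)] = 0.85
    return mat


def simulate_regnet(
    n_tfs: int = 5,
    n_targets: int = 100,
    edge_density: float = 0.1,
    effect_size: float = 2.0,
    promoter_len: int = 4001,
    pwm_len: int = 8,
    n_cells: int = 200,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], list[PWM], SimulationTruth]:
    """TF-target system with linear effects and planted promoter sites.

    Returns (expression cells x genes, promoters {gene: seq}, PWMs,
    truth).  Each target's expression is ``effect_size`` times the sum of
    its true TFs' expression plus Gaussian noise, clipped at 0; each true
    TF-target promoter carries at least one planted consensus site of
    that TF's PWM inside the window.
    """
    if not (0 < edge_density < 1):
        raise ValueError("edge_density must be in (0, 1)")
    if promoter_len < pwm_len:
        raise ValueError("promoter shorter than the PWM")
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i}" for i in range(n_tfs)]
    targets = [f"t{i:03d}" for i in range(n_targets)]
    pwms = [PWM(tf=tf, matrix=_random_pwm(rng, pwm_len)) for tf in tfs]
    adjacency = rng.random((n_tfs, n_targets)) < edge_density
    tf_expr = rng.gamma(shape=2.0, scale=2.0, size=(n_cells, n_tfs))
    target_expr = np.empty((n_cells, n_targets))
    truth = SimulationTruth()
    for j in range(n_targets):
        signal = np.zeros(n_cells)
        for i in range(n_tfs):
            if adjacency[i, j]:
                signal += effect_size * tf_expr[:, i]
                truth.true_edges.append((tfs[i], targets[j], effect_size))
        target_expr[:, j] = np.maximum(
            signal + rng.normal(0.0, noise_sd, size=n_cells), 0.0
        )
    expr = pd.DataFrame(
        np.hstack([tf_expr, target_expr]), columns=tfs + targets,
        index=[f"cell{i:04d}" for i in range(n_cells)],
    )
    bases = np.array(list("ACGT"))
    promoters: dict[str, str] = {}
    for j, gene in enumerate(targets):
        seq = rng.choice(bases, size=promoter_len)
        for i, pwm in enumerate(pwms):
            if adjacency[i, j]:
                pos = int(rng.integers(0, promoter_len - pwm_len + 1))
                seq[pos : pos + pwm_len] = list(pwm.consensus)
        promoters[gene] = "".join(seq)
    return expr, promoters, pwms, truth


# ---------------------------------------------------------------------------
# Variant candidates
# ---------------------------------------------------------------------------


def simulate_variants(
    n_true: int = 60,
    n_germline: int = 20,
    n_editing: int = 20,
    n_somatic_shared: int = 20,
    n_indels: int = 10,
    n_proximal_pairs: int = 5,
    depth_range: tuple[int, int] = (10, 50),
    cell_types: Sequence[str] = GERMLINE_CELL_TYPES,
    n_cells_per_type: int = 100,
    covered_bases_per_type: int = 100_000,
    seed: int = 0,
) -> tuple[list[VariantCandidate], pd.DataFrame, SimulationTruth]:
    """Variant candidates of known classes on one synthetic contig.

    Classes: true de novo SNVs (pass every filter), germline variants
    (DNA-seq panel flag), A-to-I editing sites (A->G, editing flag),
    somatic-shared variants (supported by a somatic cell type), indels,
    and proximal pairs (two passing SNVs within 10 bp in the same cells,
    which must collapse to one event each).  Also returns a coverage
    summary table (cell_type, n_cells, covered_bases_ge10) and the truth,
    including the implied per-cell/per-base rates per cell type.
    """
    lo, hi = depth_range
    if not (1 <= lo <= hi <= 200):
        raise ValueError("depth_range must lie within [1, 200]")
    rng = np.random.default_rng(seed)
    n_single = n_true + n_germline + n_editing + n_somatic_shared + n_indels
    # widely spaced anchors guarantee no accidental proximity across classes
    anchors = np.arange(1, n_single + n_proximal_pairs + 1) * 1000
    rng.shuffle(anchors)
    anchors = iter(anchors.tolist())
    bases = "ACGT"

    def snv(rng):
        ref = bases[rng.integers(0, 4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(0, 3)) % 4]
        return ref, alt

    def draw_depth():
        return int(rng.integers(lo, hi + 1))

    variants: list[VariantCandidate] = []
    truth = SimulationTruth()
    type_events: dict[str, int] = {t: 0 for t in cell_types}
    for k in range(n_true):
        pos = next(anchors)
        ref, alt = snv(rng)
        cell_type = cell_types[k % len(cell_types)]
        cells = {f"{cell_type}_bc{rng.integers(0, n_cells_per_type)}"}
        variants.append(
            VariantCandidate("chrS", pos, ref, alt, qual=float(rng.integers(35, 61)),
                             depth=draw_depth(), cell_types={cell_type}, cells=cells)
        )
        truth.true_de_novo_variants.append(("chrS", pos))
        type_events[cell_type] += 1
    for k in range(n_proximal_pairs):
        pos = next(anchors)
        offset = int(rng.integers(1, 11))  # within 10 bp
        cell_type = cell_types[k % len(cell_types)]
        cells = {f"{cell_type}_bc{rng.integers(0, n_cells_per_type)}"}
        pair = []
        for p in (pos, pos + offset):
            ref, alt = snv(rng)
            variants.append(
                VariantCandidate("chrS", p, ref, alt,
                                 qual=float(rng.integers(35, 61)),
                                 depth=draw_depth(), cell_types={cell_type},
                                 cells=set(cells))
            )
            pair.append(("chrS", p))
        truth.true_proximal_pairs.append(pair)
        type_events[cell_type] += 1
    for _ in range(n_germline):
        pos = next(anchors)
        ref, alt = snv(rng)
        cell_type = cell_types[int(rng.integers(0, len(cell_types)))]
        variants.append(
            VariantCandidate("chrS", pos, ref, alt, qual=float(rng.integers(35, 61)),
                             depth=draw_depth(), cell_types={cell_type},
                             cells={f"{cell_type}_bc0"}, in_dnaseq_panel=True)
        )
    for _ in range(n_editing):
        pos = next(anchors)
        cell_type = cell_types[int(rng.integers(0, len(cell_types)))]
        variants.append(
            VariantCandidate("chrS", pos, "A", "G", qual=float(rng.integers(35, 61)),
                             depth=draw_depth(), cell_types={cell_type},
                             cells={f"{cell_type}_bc0"}, is_editing_site=True)
        )
    for _ in range(n_somatic_shared):
        pos = next(anchors)
        ref, alt = snv(rng)
        cell_type = cell_types[int(rng.integers(0, len(cell_types)))]
        variants.append(
            VariantCandidate("chrS", pos, ref, alt, qual=float(rng.integers(35, 61)),
                             depth=draw_depth(),
                             cell_types={cell_type, "HC"},
                             cells={f"{cell_type}_bc0", "HC_bc0"})
        )
    for _ in range(n_indels):
        pos = next(anchors)
        ref, _ = snv(rng)
        cell_type = cell_types[int(rng.integers(0, len(cell_types)))]
        variants.append(
            VariantCandidate("chrS", pos, ref, ref + "T",
                             qual=float(rng.integers(35, 61)),
                             depth=draw_depth(), cell_types={cell_type},
                             cells={f"{cell_type}_bc0"})
        )
    order = rng.permutation(len(variants))
    variants = [variants[i] for i in order]
    coverage = pd.DataFrame(
        {
            "cell_type": list(cell_types),
            "n_cells": n_cells_per_type,
            "covered_bases_ge10": covered_bases_per_type,
        }
    )
    truth.true_rates = {
        t: {
            "n_events": type_events[t],
            "per_cell_rate": type_events[t] / n_cells_per_type,
            "per_base_rate": type_events[t]
            / (n_cells_per_type * covered_bases_per_type),
        }
        for t in cell_types
    }
    return variants, coverage, truth


# ---------------------------------------------------------------------------
# Daily counts
# ---------------------------------------------------------------------------


def simulate_daily_counts(
    days: int = 18,
    start_level: float = 50.0,
    slope_by_day: Mapping[int, float] | None = None,
    noise_sd: float = 5.0,
    n_replicates: int = 20,
    seed: int = 0,
    organ: str = "testis",
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Piecewise-linear daily series (millions of spermatozoa) with noise.

    ``slope_by_day[d]`` is the change applied from day d to day d+1
    (default: constant +3/day).  Negative draws are clipped at 0 with a
    warning.  Returns a long table (organ, day, value) with
    ``n_replicates`` values per day, and the truth slopes.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per day")
    if slope_by_day is None:
        slope_by_day = {d: 3.0 for d in range(1, days)}
    rng = np.random.default_rng(seed)
    level = float(start_level)
    levels = {1: level}
    for d in range(1, days):
        level += slope_by_day.get(d, 0.0)
        levels[d + 1] = level
    records = []
    clipped = 0
    for d in range(1, days + 1):
        draws = levels[d] + rng.normal(0.0, noise_sd, size=n_replicates)
        n_neg = int((draws < 0).sum())
        if n_neg:
            clipped += n_neg
            draws = np.maximum(draws, 0.0)
        for v in draws:
            records.append((organ, d, float(v)))
    if clipped:
        import warnings

        warnings.warn(f"{clipped} negative daily values clipped at 0")
    truth = SimulationTruth(true_daily_slopes=dict(slope_by_day))
    return pd.DataFrame(records, columns=["organ", "day", "value"]), truth


# ---------------------------------------------------------------------------
# Multi-species bulk expression
# ---------------------------------------------------------------------------


def simulate_species_bulk(
    tree: str = DEFAULT_SPECIES_TREE,
    n_genes: int = 2000,
    evolution_sd_per_branch: float = 0.5,
    root_mean: float = 3.0,
    root_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Brownian-motion expression divergence along a newick tree.

    Per gene, the root log-expression is Normal(root_mean, root_sd); each
    branch adds Normal(0, sd * sqrt(branch_length)).  Leaf expression is
    exp of the tip value, so expected pairwise log-expression distance
    grows with tree path length.  Returns a genes x taxa table.
    """
    t = TreeNode.read([tree])
    rng = np.random.default_rng(seed)
    values = {id(t): rng.normal(root_mean, root_sd, size=n_genes)}
    leaf_expr = {}
    for node in t.preorder(include_self=False):
        length = node.length or 0.0
        step = (
            rng.normal(0.0, evolution_sd_per_branch * np.sqrt(length), size=n_genes)
            if length > 0
            else 0.0
        )
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            leaf_expr[node.name] = np.exp(values[id(node)])
    bulk = pd.DataFrame(leaf_expr, index=[f"og{i:04d}" for i in range(n_genes)])
    truth = SimulationTruth(true_species_tree=tree)
    return bulk, truth
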