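"""Orthology-guided cluster cell typing and cluster-level summaries.

The annotation strategy transfers cell-type knowledge from a reference
species (fruit fly testis markers) to the analysis species (honeybee)
through one-to-one orthologs.  Candidate markers are filtered with two
expression criteria evaluated per cluster:

1. the gene is expressed in more than ``frac_min`` (default 10%) of the
   cluster's cells, and
2. the cluster's mean log-normalized expression of the gene exceeds
   ``rel_level_min`` (default 50%) of the maximum cluster mean.

Clusters are then labeled by majority vote: each enriched candidate votes
for the cell types its reference ortholog supports, and a cluster takes
the strictly most-voted type (ties and zero votes leave it UNASSIGNED —
this is how one honeybee cluster, later argued to be small spermatids,
remained undefined by the vote).  Finally, markers are pruned iteratively:
a gene marking exactly one assigned cell type must be supported by the
reference knowledge for that type; a gene marking two or more cell types
may have at most two unsupported correspondences.

The module also provides cluster mean-profile Pearson correlation, a
Wilcoxon rank-sum DEG surrogate with BH adjustment, and upper-tail
hypergeometric gene-set enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import rank_sum_test
from .io import CountMatrix

__all__ = [
    "UNASSIGNED",
    "MarkerKnowledge",
    "MarkerCall",
    "CellTypeAssignment",
    "ClusterProfile",
    "normalize_counts",
    "cluster_profiles",
    "filter_candidate_markers",
    "assign_cluster_types",
    "prune_markers",
    "cluster_correlation",
    "rank_sum_deg",
    "hypergeom_enrichment",
]

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class MarkerKnowledge:
    """One-to-one ortholog pair with the cell types it supports."""

    gene_target: str
    gene_ref: str
    supported_cell_types: frozenset[str]

    def __post_init__(self) -> None:
        if not self.supported_cell_types:
            raise ValueError(f"{self.gene_target}: empty supported cell-type set")
        object.__setattr__(
            self, "supported_cell_types", frozenset(self.supported_cell_types)
        )


def validate_knowledge(knowledge: list[MarkerKnowledge]) -> None:
    """Enforce one-to-one orthology: no repeated target or reference gene."""
    for attr in ("gene_target", "gene_ref"):
        ids = [getattr(k, attr) for k in knowledge]
        if len(set(ids)) != len(ids):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"orthology not one-to-one: repeated {attr} {dup[:5]}")


@dataclass
class MarkerCall:
    gene_target: str
    marked_clusters: set[str]
    status: str  # candidate | enriched | retained | pruned

    def __post_init__(self) -> None:
        if self.status == "enriched" and not self.marked_clusters:
            raise ValueError(f"{self.gene_target}: enriched with no marked cluster")


@dataclass
class CellTypeAssignment:
    cluster: str
    cell_type: str
    vote_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class ClusterProfile:
    cluster: str
    mean_expr: pd.Series  # over genes, log-normalized scale
    frac_expressing: pd.Series  # over genes, in [0, 1]
    n_cells: int
    mean_numi: float
    mean_nfeature: float


def normalize_counts(m: CountMatrix, scale_total: float = 1e4):
    """Library-size normalize then log1p, dropping all-zero cells.

    Each cell's counts are scaled so the pre-log values sum to
    ``scale_total``, then transformed with log(1 + x).  Returns
    (cells x genes DataFrame, list of dropped cell ids).
    """
    if scale_total <= 0:
        raise ValueError("scale_total must be positive")
    totals = m.n_umi.astype(float)
    keep = totals > 0
    dropped = [c for c, k in zip(m.cell_ids, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} all-zero cells")
    counts = m.counts[keep]
    scale = sp.diags(scale_total / totals[keep])
    norm = scale @ counts
    values = np.log1p(norm.toarray())
    cells = [c for c, k in zip(m.cell_ids, keep) if k]
    return pd.DataFrame(values, index=cells, columns=m.gene_ids), dropped


def cluster_profiles(
    m: CountMatrix, normalized: pd.DataFrame | None = None
) -> list[ClusterProfile]:
    """Per-cluster mean log-normalized expression and QC summaries."""
    if normalized is None:
        normalized, _ = normalize_counts(m)
    labels = m.cluster_labels()
    numi = m.n_umi
    nfeat = m.n_feature
    raw = m.counts
    cell_index = {c: i for i, c in enumerate(m.cell_ids)}
    profiles = []
    for cluster in m.clusters:
        cells = [c for c, lab in zip(m.cell_ids, labels) if lab == cluster]
        rows = [cell_index[c] for c in cells]
        in_norm = normalized.index.intersection(cells)
        mean_expr = normalized.loc[in_norm].mean(axis=0)
        sub = raw[rows]
        frac = pd.Series(
            np.asarray((sub > 0).sum(axis=0)).ravel() / len(rows), index=m.gene_ids
        )
        profiles.append(
            ClusterProfile(
                cluster=cluster,
                mean_expr=mean_expr,
                frac_expressing=frac,
                n_cells=len(rows),
                mean_numi=float(numi[rows].mean()),
                mean_nfeature=float(nfeat[rows].mean()),
            )
        )
    return profiles


def filter_candidate_markers(
    m: CountMatrix,
    knowledge: list[MarkerKnowledge],
    frac_min: float = 0.10,
    rel_level_min: float = 0.50,
    profiles: list[ClusterProfile] | None = None,
) -> list[MarkerCall]:
    """Apply the two marker criteria to every knowledge gene, per cluster.

    A cluster is marked by a gene iff strictly more than ``frac_min`` of
    its cells express the gene AND the cluster's mean log-normalized
    expression strictly exceeds ``rel_level_min`` times the maximum
    cluster mean.  Genes marking at least one cluster get status
    ``enriched``; the rest stay ``candidate``.
    """
    validate_knowledge(knowledge)
    genes = [k.gene_target for k in knowledge if k.gene_target in set(m.gene_ids)]
    if not genes:
        raise ValueError("no knowledge gene present in the count matrix")
    if profiles is None:
        profiles = cluster_profiles(m)
    mean = pd.DataFrame({p.cluster: p.mean_expr[genes] for p in profiles})
    frac = pd.DataFrame({p.cluster: p.frac_expressing[genes] for p in profiles})
    max_mean = mean.max(axis=1)
    calls = []
    for gene in genes:
        marked = {
            cluster
            for cluster in mean.columns
            if frac.at[gene, cluster] > frac_min
            and mean.at[gene, cluster] > rel_level_min * max_mean[gene]
        }
        calls.append(
            MarkerCall(
                gene_target=gene,
                marked_clusters=marked,
                status="enriched" if marked else "candidate",
            )
        )
    return calls


def assign_cluster_types(
    calls: list[MarkerCall], knowledge: list[MarkerKnowledge]
) -> list[CellTypeAssignment]:
    """Vote-label clusters from enriched marker calls.

    Each enriched gene votes, in every cluster it marks, for each cell
    type its reference ortholog supports.  A cluster is assigned the
    strict argmax of its votes; ties or no votes leave it UNASSIGNED.
    """
    enriched = [c for c in calls if c.status in {"enriched", "retained"}]
    if not enriched:
        raise ValueError("no enriched marker calls to vote with")
    support = {k.gene_target: k.supported_cell_types for k in knowledge}
    votes: dict[str, dict[str, int]] = {}
    clusters = sorted({cl for c in enriched for cl in c.marked_clusters})
    for cluster in clusters:
        votes[cluster] = {}
    for call in enriched:
        for cluster in call.marked_clusters:
            for cell_type in support.get(call.gene_target, ()):
                votes[cluster][cell_type] = votes[cluster].get(cell_type, 0) + 1
    assignments = []
    for cluster in clusters:
        counts = votes[cluster]
        if not counts:
            assignments.append(CellTypeAssignment(cluster, UNASSIGNED, counts))
            continue
        best = max(counts.values())
        winners = [t for t, v in counts.items() if v == best]
        cell_type = winners[0] if len(winners) == 1 else UNASSIGNED
        assignments.append(CellTypeAssignment(cluster, cell_type, counts))
    return assignments


def prune_markers(
    calls: list[MarkerCall],
    assignment: list[CellTypeAssignment],
    knowledge: list[MarkerKnowledge],
    max_unsupported: int = 2,
) -> list[MarkerCall]:
    """Iteratively remove inconsistent or ambiguous markers.

    Each iteration translates every surviving gene's marked clusters into
    assigned cell types and applies two rules against one fixed
    assignment: a gene marking exactly one cell type must be supported by
    the reference knowledge for it; a gene marking two or more may have at
    most ``max_unsupported`` unsupported correspondences.  After each
    round of removals the cluster assignment is recomputed from the
    survivors and the rules re-applied, to a fixed point.  UNASSIGNED
    clusters contribute no cell type to a gene's marked-type set.
    """
    support = {k.gene_target: k.supported_cell_types for k in knowledge}
    surviving = {
        c.gene_target for c in calls if c.status in {"enriched", "retained"}
    }
    call_of = {c.gene_target: c for c in calls}
    type_of: dict[str, str] = {a.cluster: a.cell_type for a in assignment}
    for call in calls:
        if call.gene_target in surviving:
            missing = call.marked_clusters - set(type_of)
            if missing:
                raise ValueError(
                    f"{call.gene_target}: no assignment for clusters {sorted(missing)}"
                )

    for _ in range(max(1, len(calls))):
        removed = set()
        for gene in sorted(surviving):
            marked_types = {
                type_of[cl]
                for cl in call_of[gene].marked_clusters
                if type_of.get(cl, UNASSIGNED) != UNASSIGNED
            }
            supported = support.get(gene, frozenset())
            if len(marked_types) == 1:
                (only,) = marked_types
                keep = only in supported
            elif len(marked_types) >= 2:
                keep = len(marked_types - supported) <= max_unsupported
            else:
                keep = False  # marks no assigned cell type: uninformative
            if not keep:
                removed.add(gene)
        if not removed:
            break
        surviving -= removed
        if surviving:
            remaining = [
                MarkerCall(g, set(call_of[g].marked_clusters), "enriched")
                for g in sorted(surviving)
            ]
            type_of = {
                a.cluster: a.cell_type
                for a in assign_cluster_types(remaining, knowledge)
            }
        else:
            break
    return [
        MarkerCall(
            c.gene_target,
            set(c.marked_clusters),
            "retained" if c.gene_target in surviving else "pruned",
        )
        for c in calls
        if c.status in {"enriched", "retained"}
    ]


def cluster_correlation(profiles: list[ClusterProfile]) -> pd.DataFrame:
    """Pearson correlation between cluster mean-expression profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 cluster profiles")
    mat = pd.DataFrame({p.cluster: p.mean_expr for p in profiles})
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    stds = mat.std(axis=0, ddof=0)
    flat = stds[stds == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance cluster profiles: {flat}")
    corr = np.corrcoef(mat.to_numpy(float).T)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=mat.columns, columns=mat.columns)


def rank_sum_deg(
    m: CountMatrix,
    cluster: str,
    alpha: float = 0.05,
    min_log_fc: float = 0.25,
    normalized: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DEG surrogate: one cluster vs all other cells.

    Genes with no expression anywhere are excluded before testing.  The
    log2 fold-change contrasts the cluster's mean log-normalized
    expression with the complement's (pseudocount 1e-9).  Reported genes
    satisfy BH-adjusted p < ``alpha`` and |log2 FC| >= ``min_log_fc``;
    the returned frame carries all tested genes with a ``significant``
    column.
    """
    if cluster not in m.clusters:
        raise ValueError(f"unknown cluster {cluster!r}")
    if normalized is None:
        normalized, _ = normalize_counts(m)
    labels = pd.Series(
        {c: m.cluster_of_cell.get(c) for c in normalized.index}, dtype=object
    )
    in_mask = (labels == cluster).to_numpy()
    if in_mask.sum() < 3 or (~in_mask).sum() < 3:
        raise ValueError("cluster and complement each need >= 3 cells")
    values = normalized.to_numpy(float)
    nonzero = values.sum(axis=0) > 0
    genes = [g for g, nz in zip(normalized.columns, nonzero) if nz]
    x = values[in_mask][:, nonzero]
    y = values[~in_mask][:, nonzero]
    stats_w = np.empty(len(genes))
    pvals = np.empty(len(genes))
    for j in range(len(genes)):
        stats_w[j], pvals[j] = rank_sum_test(x[:, j], y[:, j])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    eps = 1e-9
    log_fc = np.log2((x.mean(axis=0) + eps) / (y.mean(axis=0) + eps))
    df = pd.DataFrame(
        {
            "gene": genes,
            "statistic": stats_w,
            "p": pvals,
            "q": qvals,
            "log2_fc": log_fc,
        }
    )
    df["significant"] = (df["q"] < alpha) & (df["log2_fc"].abs() >= min_log_fc)
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def hypergeom_enrichment(
    hit_set: set[str], category_set: set[str], background: set[str]
) -> tuple[int, float]:
    """Upper-tail hypergeometric enrichment of ``hit_set`` in ``category_set``.

    Returns (k, p) with k = |hit ∩ category| and
    p = P(X >= k) for X ~ Hypergeom(|background|, |category|, |hit|).
    """
    if not background:
        raise ValueError("empty background")
    if not hit_set <= background or not category_set <= background:
        raise ValueError("hit and category sets must be subsets of the background")
    k = len(hit_set & category_set)
    p = float(
        stats.hypergeom.sf(k - 1, len(background), len(category_set), len(hit_set))
    )
    return k, min(1.0, p)
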