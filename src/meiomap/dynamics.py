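"""Pseudotime summaries, bootstrap change rates, and expression phylogeny.

Three unrelated "dynamics" procedures share this module because they all
summarize trends over an ordered axis:

* pseudotime binning — cells are binned by one pseudotime unit, a gene's
  per-bin mean scaled expression is z-scored across bins, and the
  branch point of a bifurcating trajectory is estimated as the overlap
  of the per-branch pseudotime ranges;
* daily-count change rates — spermatozoon counts measured on successive
  days are bootstrapped (resampling each day's replicates), and the
  change rate at a day is the OLS slope over the 5-day window centred on
  it (two days before, the day, two days after);
* expression phylogeny — taxa are related by neighbor joining on the
  distance 1 - Pearson r between log(1 + expression) profiles, with
  gene-resampling bootstrap supports per internal bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = [
    "BinnedProfile",
    "ChangeRateEstimate",
    "ExpressionTree",
    "BranchWindow",
    "bin_zprofile",
    "branch_overlap_window",
    "bootstrap_change_rates",
    "compare_rates",
    "expression_tree",
]


@dataclass
class BinnedProfile:
    gene: str
    bin_centers: np.ndarray
    z: np.ndarray
    constant: bool = False  # gene flat across bins: z fixed at 0


@dataclass
class BranchWindow:
    t_low: float
    t_high: float
    overlap: bool


@dataclass
class ChangeRateEstimate:
    organ: str
    day: int
    slopes: np.ndarray
    mean: float
    sd: float


@dataclass
class ExpressionTree:
    newick: str
    supports: dict[frozenset, float]  # bipartition (smaller side) -> support
    tree: TreeNode


# ---------------------------------------------------------------------------
# Pseudotime binning
# ---------------------------------------------------------------------------


def bin_zprofile(
    expr: pd.DataFrame,
    pseudotime: pd.DataFrame,
    genes: Iterable[str],
    bin_width: float = 1.0,
) -> list[BinnedProfile]:
    """Bin cells by pseudotime and z-score each gene's bin means.

    ``expr`` is cells x genes scaled expression; ``pseudotime`` has
    columns (cell, t[, branch]).  Bins are [k*w, (k+1)*w); empty bins are
    omitted.  Per gene, the value in a bin is the mean scaled expression
    of the bin's cells, then the bin values are z-scored (ddof 1) across
    bins.  A gene constant across bins cannot be z-scored and is
    reported as an all-zero profile with ``constant=True``.
    """
    pt = pseudotime.set_index("cell")["t"]
    cells = expr.index.intersection(pt.index)
    if len(cells) == 0:
        raise ValueError("no shared cells between expression and pseudotime")
    bins = np.floor(pt.loc[cells].to_numpy(float) / bin_width).astype(int)
    order = np.unique(bins)
    if len(order) < 2:
        raise ValueError("need at least 2 non-empty pseudotime bins")
    centers = (order + 0.5) * bin_width
    values = expr.loc[cells]
    profiles = []
    for gene in genes:
        if gene not in values.columns:
            raise KeyError(f"gene {gene!r} not in the expression matrix")
        v = values[gene].to_numpy(float)
        means = np.array([v[bins == b].mean() for b in order])
        sd = means.std(ddof=1)
        if sd == 0:
            profiles.append(
                BinnedProfile(gene, centers, np.zeros_like(means), constant=True)
            )
        else:
            z = (means - means.mean()) / sd
            profiles.append(BinnedProfile(gene, centers, z))
    return profiles


def branch_overlap_window(pseudotime: pd.DataFrame) -> BranchWindow:
    """Intersection of per-branch pseudotime ranges (branch-point estimate)."""
    if "branch" not in pseudotime.columns:
        raise ValueError("pseudotime table has no 'branch' column")
    groups = pseudotime.groupby("branch")["t"]
    if groups.ngroups < 2:
        raise ValueError("need at least 2 branches")
    lows = groups.min()
    highs = groups.max()
    t_low, t_high = float(lows.max()), float(highs.min())
    return BranchWindow(t_low=t_low, t_high=t_high, overlap=t_low <= t_high)


# ---------------------------------------------------------------------------
# Bootstrap change rates
# ---------------------------------------------------------------------------


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Ordinary least-squares slope of y on x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def bootstrap_change_rates(
    daily: pd.DataFrame,
    n_boot: int = 20,
    seed: int = 0,
    window: int = 2,
) -> list[ChangeRateEstimate]:
    """Bootstrap the daily change rate of replicated count series.

    ``daily`` has columns (organ, day, value), several replicate values
    per day.  For each organ and each day with ``window`` observed days
    on both sides, every bootstrap replicate resamples each window day's
    values with replacement, takes day means, and fits an OLS slope over
    the (2*window + 1)-day span.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for organ, sub in daily.groupby("organ", sort=True):
        by_day = {int(d): g["value"].to_numpy(float)
                  for d, g in sub.groupby("day", sort=True)}
        days = sorted(by_day)
        for i, day in enumerate(days):
            if i < window or i >= len(days) - window:
                continue
            span = days[i - window : i + window + 1]
            if any(len(by_day[d]) < 2 for d in span):
                raise ValueError(
                    f"{organ} day {day}: a window day has < 2 replicate values"
                )
            x = np.array(span, float)
            slopes = np.empty(n_boot)
            for b in range(n_boot):
                means = np.array(
                    [rng.choice(by_day[d], size=len(by_day[d]),
                                replace=True).mean() for d in span]
                )
                slopes[b] = ols_slope(x, means)
            out.append(
                ChangeRateEstimate(
                    organ=organ,
                    day=day,
                    slopes=slopes,
                    mean=float(slopes.mean()),
                    sd=float(slopes.std(ddof=1)) if n_boot > 1 else 0.0,
                )
            )
    return out


def compare_rates(a: ChangeRateEstimate, b: ChangeRateEstimate) -> tuple[float, float]:
    """Two-sided Welch t-test between two bootstrap slope distributions."""
    if len(a.slopes) < 2 or len(b.slopes) < 2:
        raise ValueError("each slope list needs >= 2 bootstrap replicates")
    if np.var(a.slopes) == 0 and np.var(b.slopes) == 0:
        if np.allclose(a.slopes.mean(), b.slopes.mean()):
            return 0.0, 1.0
        raise ValueError("both slope distributions are degenerate")
    t, p = stats.ttest_ind(a.slopes, b.slopes, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Expression phylogeny
# ---------------------------------------------------------------------------


def _correlation_distance(bulk: pd.DataFrame) -> DistanceMatrix:
    """1 - Pearson r between log1p expression profiles of taxa (columns)."""
    logged = np.log1p(bulk.to_numpy(float))
    stds = logged.std(axis=0)
    flat = [t for t, s in zip(bulk.columns, stds) if s == 0]
    if flat:
        raise ValueError(f"constant taxon expression profiles: {flat}")
    corr = np.corrcoef(logged.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    return DistanceMatrix(dist, ids=list(bulk.columns))


def tree_bipartitions(tree: TreeNode, taxa: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions of an (unrooted) tree, as the smaller side."""
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        smaller = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        splits.add(smaller)
    return splits


def expression_tree(
    bulk: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> ExpressionTree:
    """Neighbor-joining expression phylogeny with gene-resampling supports.

    ``bulk`` is genes x taxa expression.  The taxon-taxon distance is
    1 - Pearson r over log(1 + expression); the tree is built by
    neighbor joining.  Supports: genes are resampled with replacement
    ``n_boot`` times and each internal bipartition of the main tree is
    scored by the fraction of replicate trees that contain it.
    """
    if bulk.shape[1] < 4:
        raise ValueError("need >= 4 taxa")
    if bulk.shape[0] < 10:
        raise ValueError("need >= 10 genes")
    taxa = frozenset(bulk.columns)
    main = nj(_correlation_distance(bulk))
    main_splits = tree_bipartitions(main, taxa)
    rng = np.random.default_rng(seed)
    hits = {split: 0 for split in main_splits}
    n_genes = bulk.shape[0]
    values = bulk.to_numpy(float)
    for _ in range(n_boot):
        idx = rng.integers(0, n_genes, size=n_genes)
        rep = pd.DataFrame(values[idx], columns=bulk.columns)
        try:
            rep_tree = nj(_correlation_distance(rep))
        except ValueError:
            continue  # degenerate resample; counts as non-support
        rep_splits = tree_bipartitions(rep_tree, taxa)
        for split in main_splits & rep_splits:
            hits[split] += 1
    supports = {split: hits[split] / n_boot for split in main_splits}
    return ExpressionTree(newick=str(main).strip(), supports=supports, tree=main)
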