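"""Gene evolutionary-age classes and age-stratified statistics.

Genes are placed in four hierarchical age classes by the deepest taxon in
which orthologs are detectable (phylostratigraphy): ``pre-Hymenoptera``
(orthology with non-hymenopteran animals), ``post-Hymenoptera`` (found in
non-Apidae hymenopterans but nowhere deeper), ``post-Apidae`` (found in
other bees only), and ``Novel`` (restricted to the analysis species).
The three younger classes together are the Hymenoptera-restricted genes
(HRGs); the oldest class is the pre-HRGs.

On top of the classification the module provides: two-sided Fisher exact
enrichment of age classes within gene groups, BH-corrected across tests;
the tau expression-specificity index; and a Wilcoxon rank-sum comparison
of expression bias between gene sets, with an optional expression floor
(e.g. RPKM/FPKM > 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._stats import fisher_two_sided, rank_sum_test

__all__ = [
    "AGE_CLASSES",
    "GeneAge",
    "GroupEnrichment",
    "assign_age_class",
    "fisher_age_enrichment",
    "tau",
    "compare_expression_bias",
]

AGE_CLASSES = ("pre-Hymenoptera", "post-Hymenoptera", "post-Apidae", "Novel")


@dataclass(frozen=True)
class GeneAge:
    gene: str
    age_class: str

    def __post_init__(self) -> None:
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"{self.gene}: unknown age class {self.age_class!r}")

    @property
    def is_hrg(self) -> bool:
        """Hymenoptera-restricted: any class younger than pre-Hymenoptera."""
        return self.age_class != "pre-Hymenoptera"


@dataclass
class GroupEnrichment:
    group: str
    age_class: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    q: float
    continuity_corrected: bool = False


def assign_age_class(
    gene: str, orthology_presence: Mapping[str, Mapping[str, bool]]
) -> GeneAge:
    """Deepest-detectable-ortholog classification for one gene.

    ``orthology_presence[gene]`` must carry three boolean flags:
    ``beyond_hymenoptera`` (ortholog in any non-hymenopteran animal),
    ``hymenoptera_outside_apidae`` (ortholog in a non-Apidae
    hymenopteran), and ``apidae_outside_amel`` (ortholog in a bee other
    than the analysis species).  The hierarchy is evaluated deepest
    first; a gene with no flag set is Novel.
    """
    if gene not in orthology_presence:
        raise KeyError(f"gene {gene!r} absent from the presence map")
    flags = orthology_presence[gene]
    required = {"beyond_hymenoptera", "hymenoptera_outside_apidae",
                "apidae_outside_amel"}
    missing = required - set(flags)
    if missing:
        raise ValueError(f"{gene}: missing presence flags {sorted(missing)}")
    if flags["beyond_hymenoptera"]:
        cls = "pre-Hymenoptera"
    elif flags["hymenoptera_outside_apidae"]:
        cls = "post-Hymenoptera"
    elif flags["apidae_outside_amel"]:
        cls = "post-Apidae"
    else:
        cls = "Novel"
    return GeneAge(gene=gene, age_class=cls)


def fisher_age_enrichment(
    group_genes: set[str],
    ages: Sequence[GeneAge],
    background: set[str],
    classes: Iterable[str] = AGE_CLASSES,
    group_label: str = "group",
) -> list[GroupEnrichment]:
    """Two-sided Fisher enrichment of each age class in a gene group.

    For each class the 2x2 table is [[in-group & class, in-group not
    class], [out-group & class, out-group not class]] over the background;
    p-values come from the exact minimum-likelihood two-sided Fisher test
    and are BH-adjusted across the tested classes.  The odds ratio is the
    cross-product ratio, with a 0.5 continuity correction (flagged) only
    when some cell is zero.
    """
    if not group_genes or not background:
        raise ValueError("group and background must be non-empty")
    if not group_genes <= background:
        raise ValueError("group genes must be a subset of the background")
    age_of = {a.gene: a.age_class for a in ages}
    missing = [g for g in background if g not in age_of]
    if missing:
        raise ValueError(f"background genes without an age: {sorted(missing)[:5]}")
    out_genes = background - group_genes
    results = []
    pvals = []
    for cls in classes:
        a = sum(1 for g in group_genes if age_of[g] == cls)
        b = len(group_genes) - a
        c = sum(1 for g in out_genes if age_of[g] == cls)
        d = len(out_genes) - c
        odds, p = fisher_two_sided([[a, b], [c, d]])
        results.append(
            GroupEnrichment(
                group=group_label,
                age_class=cls,
                table=((a, b), (c, d)),
                odds_ratio=odds,
                p=p,
                q=np.nan,
                continuity_corrected=min(a, b, c, d) == 0,
            )
        )
        pvals.append(p)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for res, q in zip(results, qvals):
        res.q = float(q)
    return results


def tau(expr: Sequence[float]) -> float:
    """Expression-specificity index over contexts (castes or tissues).

    tau = sum_i (1 - x_i / x_max) / (n - 1), for non-negative expression
    x over n >= 2 contexts.  tau = 1 iff exactly one context is nonzero;
    tau = 0 iff all contexts are equal and nonzero.  An all-zero vector
    has no defined specificity and returns NaN.
    """
    x = np.asarray(expr, float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a 1-D vector over at least 2 contexts")
    if np.any(x < 0):
        raise ValueError("negative expression value")
    x_max = x.max()
    if x_max == 0:
        return float("nan")
    return float(np.sum(1.0 - x / x_max) / (x.size - 1))


def compare_expression_bias(
    values_a: Sequence[float],
    values_b: Sequence[float],
    min_expression: float | None = None,
) -> dict:
    """Rank-sum comparison of two expression distributions.

    With ``min_expression`` set, both groups are first restricted to
    values strictly above the floor (the RPKM/FPKM > 10 convention for
    comparing well-expressed genes).  Returns the rank-sum statistic, the
    two-sided p (exact for combined n <= 20, tie-corrected normal
    otherwise), the group medians, and the filter state.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if min_expression is not None:
        a = a[a > min_expression]
        b = b[b > min_expression]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 values after filtering")
    w, p = rank_sum_test(a, b)
    return {
        "statistic": w,
        "p": p,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "min_expression": min_expression,
    }
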