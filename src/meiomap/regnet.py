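"""Motif-anchored transcription-regulatory-network construction.

Per cell type the pipeline (a) extracts a promoter window of -3 kb..+1 kb
around each testis-specific TSS, strand-oriented; (b) scores each TF-gene
pair by scanning the window for clusters of PWM matches — a surrogate
scanner that finds log-odds sites on both strands and takes the best
sliding-span sum of non-overlapping site scores (the HMM of the original
cluster-scoring tool is deliberately not reproduced; the surrogate keeps
the same interface: one maximal cluster score per TF-gene pair);
(c) infers expression-importance edges with a per-target random-forest
regression on TF expression (raw UMI counts by default); (d) prunes the
network into regulons by a minimum edge weight (0.02) and, per TF, the
top 5% of candidate targets by motif-cluster score; (e) flags TFs whose
regulons are unusually enriched for Hymenoptera-restricted targets; and
(f) measures a gene's network connectivity as the sum over all other
genes of the sixth power of the Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .agestats import GeneAge
from .io import TssRecord

__all__ = [
    "PWM",
    "PromoterWindow",
    "MotifClusterScore",
    "NetworkEdge",
    "Regulon",
    "TFEnrichment",
    "extract_promoters",
    "scan_motif_clusters",
    "infer_network",
    "build_regulons",
    "flag_hrg_enriched_tfs",
    "connectivity",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position probability matrix over (A, C, G, T), one row per position."""

    tf: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.tf}: PWM must be positions x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError(f"{self.tf}: PWM length must be >= 4")
        if np.any(self.matrix < 0):
            raise ValueError(f"{self.tf}: negative PWM entry")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"{self.tf}: PWM rows must sum to 1")
        if np.any(self.matrix.max(axis=1) == 0):
            raise ValueError(f"{self.tf}: degenerate all-zero PWM column")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.matrix, axis=1))


@dataclass
class PromoterWindow:
    gene: str
    contig: str
    tss: int  # 1-based
    strand: str
    sequence: str  # strand-oriented; position 0 is most upstream
    truncated: bool = False


@dataclass(frozen=True)
class MotifClusterScore:
    tf: str
    gene: str
    score: float


@dataclass(frozen=True)
class NetworkEdge:
    tf: str
    target: str
    weight: float


@dataclass
class Regulon:
    tf: str
    targets: list[tuple[str, float, float]]  # (gene, weight, motif_score)

    @property
    def target_genes(self) -> set[str]:
        return {g for g, _, _ in self.targets}


@dataclass
class TFEnrichment:
    tf: str
    n_hrg: int
    n_pre_hrg: int
    ratio: float
    flagged: bool
    zero_denominator: bool = False


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------


def extract_promoters(
    tss_records: Sequence[TssRecord],
    genome: Mapping[str, str],
    upstream: int = 3000,
    downstream: int = 1000,
) -> list[PromoterWindow]:
    """Strand-oriented promoter windows of -upstream..+downstream around TSS.

    On the plus strand the window covers 1-based positions
    [tss - upstream, tss + downstream]; on the minus strand the
    complementary-strand interval [tss - downstream, tss + upstream] is
    reverse-complemented so that position 0 of the returned sequence is
    the most-upstream base.  Windows clipped by a contig edge are
    truncated and flagged.
    """
    windows = []
    for rec in tss_records:
        if rec.contig not in genome:
            raise KeyError(f"{rec.gene}: unknown contig {rec.contig!r}")
        contig_seq = genome[rec.contig]
        L = len(contig_seq)
        if not (1 <= rec.tss <= L):
            raise ValueError(f"{rec.gene}: TSS {rec.tss} outside contig (len {L})")
        if rec.strand == "+":
            lo, hi = rec.tss - upstream, rec.tss + downstream
        else:
            lo, hi = rec.tss - downstream, rec.tss + upstream
        lo_c, hi_c = max(1, lo), min(L, hi)
        seq = contig_seq[lo_c - 1 : hi_c]
        if rec.strand == "-":
            seq = reverse_complement(seq)
        windows.append(
            PromoterWindow(
                gene=rec.gene,
                contig=rec.contig,
                tss=rec.tss,
                strand=rec.strand,
                sequence=seq,
                truncated=(lo_c != lo or hi_c != hi),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# Motif-cluster scoring (surrogate scanner)
# ---------------------------------------------------------------------------


def _log_odds(pwm: PWM, background: np.ndarray) -> np.ndarray:
    probs = np.maximum(pwm.matrix, 1e-4)
    return np.log2(probs / background[None, :])


def _site_scores(seq_idx: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Score of the motif at every start position; NaN where N intrudes."""
    L = lod.shape[0]
    n = seq_idx.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    ok = np.ones(n, bool)
    for offset in range(L):
        idx = seq_idx[offset : offset + n]
        valid = idx >= 0
        ok &= valid
        scores += np.where(valid, lod[offset, np.clip(idx, 0, 3)], 0.0)
    scores[~ok] = -np.inf
    return scores


def _background_freqs(seq: str, floor: float = 0.01) -> np.ndarray:
    counts = np.array([seq.count(b) for b in "ACGT"], float)
    total = counts.sum()
    freqs = counts / total if total else np.full(4, 0.25)
    # strand-symmetrize (A with T, C with G) so scores are strand-invariant
    freqs = np.array(
        [
            (freqs[0] + freqs[3]) / 2,
            (freqs[1] + freqs[2]) / 2,
            (freqs[1] + freqs[2]) / 2,
            (freqs[0] + freqs[3]) / 2,
        ]
    )
    freqs = np.maximum(freqs, floor)
    return freqs / freqs.sum()


def _best_cluster_score(
    sites: list[tuple[int, float]], motif_len: int, cluster_span: int
) -> float:
    """Best sliding-span sum of non-overlapping site scores.

    Sites are (start, score) on the oriented window, both strands pooled
    (overlap is judged on window coordinates).  For each candidate span
    the non-overlapping subset is chosen greedily by descending score —
    deterministic, and exact whenever sites within a span do not overlap.
    """
    if not sites:
        return 0.0
    sites = sorted(sites)
    starts = np.array([s for s, _ in sites])
    best = 0.0
    for anchor, _ in sites:
        lo, hi = anchor, anchor + cluster_span - motif_len
        in_span = [s for s in sites if lo <= s[0] <= hi]
        in_span.sort(key=lambda s: (-s[1], s[0]))
        chosen: list[tuple[int, float]] = []
        for start, score in in_span:
            if all(abs(start - c) >= motif_len for c, _ in chosen):
                chosen.append((start, score))
        best = max(best, sum(sc for _, sc in chosen))
    return best


def scan_motif_clusters(
    window: PromoterWindow,
    pwms: Sequence[PWM],
    site_threshold_bits: float = 6.0,
    cluster_span: int = 200,
) -> list[MotifClusterScore]:
    """Score motif clusters of each PWM in one promoter window.

    The background is the window's own mononucleotide frequency (floored
    at 0.01).  Sites are positions on either strand whose log2-odds score
    reaches ``site_threshold_bits``; the TF-gene score is the best sum of
    non-overlapping site scores within any sliding span of
    ``cluster_span`` bp, or 0 when no site exists.
    """
    seq = window.sequence
    if not seq:
        raise ValueError(f"{window.gene}: empty promoter sequence")
    background = _background_freqs(seq)
    seq_idx = np.array([_BASE_INDEX.get(b, -1) for b in seq])
    rc_idx = np.array([_BASE_INDEX.get(b, -1) for b in reverse_complement(seq)])
    results = []
    for pwm in pwms:
        L = len(pwm)
        if L > len(seq):
            raise ValueError(f"{pwm.tf}: PWM longer than promoter {window.gene}")
        lod = _log_odds(pwm, background)
        sites: list[tuple[int, float]] = []
        fwd = _site_scores(seq_idx, lod)
        for pos in np.nonzero(fwd >= site_threshold_bits)[0]:
            sites.append((int(pos), float(fwd[pos])))
        rev = _site_scores(rc_idx, lod)
        n = len(seq)
        for pos in np.nonzero(rev >= site_threshold_bits)[0]:
            # map reverse-strand start back to forward-window coordinates
            sites.append((n - L - int(pos), float(rev[pos])))
        score = _best_cluster_score(sites, L, cluster_span)
        results.append(MotifClusterScore(tf=pwm.tf, gene=window.gene, score=score))
    return results


# ---------------------------------------------------------------------------
# Expression-importance network
# ---------------------------------------------------------------------------


def infer_network(
    expr: pd.DataFrame,
    tf_list: Sequence[str],
    n_trees: int = 1000,
    seed: int = 0,
    max_features: str | float = "sqrt",
) -> list[NetworkEdge]:
    """Tree-ensemble network inference (per-target regression on TFs).

    ``expr`` is cells x genes (raw UMI counts by convention; normalized
    input also accepted).  Every gene is regressed on the TFs (excluding
    itself) with a random forest; the edge weight TF -> target is the
    TF's impurity importance, normalized to sum to 1 per target.
    Constant targets yield all-zero weights.  Deterministic given seed.
    """
    if expr.shape[0] < 20:
        raise ValueError("need >= 20 cells for network inference")
    tfs = [t for t in tf_list if t in expr.columns]
    if len(tfs) < 2:
        raise ValueError("need >= 2 TFs present in the expression matrix")
    rng = np.random.SeedSequence(seed)
    target_seeds = {
        gene: int(s.generate_state(1)[0] % (2**31 - 1))
        for gene, s in zip(expr.columns, rng.spawn(expr.shape[1]))
    }
    edges: list[NetworkEdge] = []
    X_full = expr[tfs].to_numpy(float)
    for target in expr.columns:
        predictors = [t for t in tfs if t != target]
        if len(predictors) < 2:
            continue
        y = expr[target].to_numpy(float)
        if np.all(y == y[0]):
            edges.extend(NetworkEdge(tf=t, target=target, weight=0.0)
                         for t in predictors)
            continue
        if len(predictors) == len(tfs):
            X = X_full
        else:
            X = expr[predictors].to_numpy(float)
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=target_seeds[target],
            n_jobs=1,
        )
        forest.fit(X, y)
        importances = forest.feature_importances_
        total = importances.sum()
        if total > 0:
            importances = importances / total
        edges.extend(
            NetworkEdge(tf=t, target=target, weight=float(w))
            for t, w in zip(predictors, importances)
        )
    return edges


# ---------------------------------------------------------------------------
# Regulons, HRG enrichment, connectivity
# ---------------------------------------------------------------------------


def build_regulons(
    edges: Sequence[NetworkEdge],
    motif_scores: Sequence[MotifClusterScore],
    min_weight: float = 0.02,
    top_frac: float = 0.05,
) -> list[Regulon]:
    """Prune edges into regulons by weight floor then motif-score rank.

    Edges below ``min_weight`` are dropped; per TF, the
    ceil(top_frac x candidates) targets with the highest motif-cluster
    scores survive (ties broken by higher edge weight, then gene id).
    TF-gene pairs absent from the motif-score table score 0.
    """
    if not (0 < top_frac <= 1):
        raise ValueError("top_frac must be in (0, 1]")
    score_of = {(s.tf, s.gene): s.score for s in motif_scores}
    by_tf: dict[str, list[tuple[str, float, float]]] = {}
    for e in edges:
        if e.tf == e.target:
            raise ValueError(f"self-edge {e.tf}")
        if e.weight >= min_weight:
            by_tf.setdefault(e.tf, []).append(
                (e.target, e.weight, score_of.get((e.tf, e.target), 0.0))
            )
    regulons = []
    for tf in sorted(by_tf):
        candidates = by_tf[tf]
        n_keep = math.ceil(top_frac * len(candidates))
        candidates.sort(key=lambda t: (-t[2], -t[1], t[0]))
        regulons.append(Regulon(tf=tf, targets=candidates[:n_keep]))
    return regulons


def flag_hrg_enriched_tfs(
    regulons: Sequence[Regulon],
    ages: Sequence[GeneAge],
    ci_level: float = 0.95,
) -> list[TFEnrichment]:
    """Flag TFs whose target HRG/pre-HRG ratio is extreme across TFs.

    The ratio is n_HRG / max(n_preHRG, 1) (zero denominators flagged);
    a TF is flagged when its ratio strictly exceeds the upper
    (1 + ci_level)/2 percentile of the across-TF ratio distribution.
    """
    nonempty = [r for r in regulons if r.targets]
    if not nonempty:
        raise ValueError("all regulons are empty")
    if len(nonempty) < 10:
        raise ValueError("need >= 10 TFs with non-empty regulons")
    age_of = {a.gene: a for a in ages}
    rows = []
    for reg in nonempty:
        n_hrg = sum(
            1 for g in reg.target_genes if g in age_of and age_of[g].is_hrg
        )
        n_pre = sum(
            1 for g in reg.target_genes if g in age_of and not age_of[g].is_hrg
        )
        rows.append((reg.tf, n_hrg, n_pre, n_hrg / max(n_pre, 1), n_pre == 0))
    ratios = np.array([r[3] for r in rows])
    upper = float(np.percentile(ratios, 100 * (1 + ci_level) / 2))
    return [
        TFEnrichment(
            tf=tf,
            n_hrg=n_hrg,
            n_pre_hrg=n_pre,
            ratio=ratio,
            flagged=ratio > upper,
            zero_denominator=zero_den,
        )
        for tf, n_hrg, n_pre, ratio, zero_den in rows
    ]


def connectivity(expr: pd.DataFrame, gene: str) -> float:
    """Network connectivity of ``gene``: sum over other genes of r^6.

    ``expr`` is cells x genes normalized expression.  Zero-variance
    partner genes contribute 0; a zero-variance focal gene is an error.
    """
    if gene not in expr.columns:
        raise KeyError(f"unknown gene {gene!r}")
    if expr.shape[1] < 3 or expr.shape[0] < 3:
        raise ValueError("need >= 3 genes and >= 3 cells")
    values = expr.to_numpy(float)
    j = expr.columns.get_loc(gene)
    g = values[:, j]
    if g.std() == 0:
        raise ValueError(f"{gene}: zero variance")
    gc = g - g.mean()
    centered = values - values.mean(axis=0)
    denom = np.sqrt((centered**2).sum(axis=0)) * np.sqrt((gc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered * gc[:, None]).sum(axis=0) / denom
    r[~np.isfinite(r)] = 0.0  # zero-variance partners
    r[j] = 0.0  # exclude the focal gene
    return float(np.sum(r**6))
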