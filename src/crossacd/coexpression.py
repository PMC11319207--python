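"""Cross-ACD gene-coexpression statistics from single-cell RNA counts.

The statistic chain, per ACD pair (i, j):

1. tied-rank Spearman correlation S[g, h] for every gene pair with g in
   ACD i and h in ACD j, computed across cells (average ranks, then the
   product-moment correlation of the ranks);
2. the pair-level mean S-bar over the gene-pair matrix, per condition;
3. the differential matrix deltaS = S_depleted - S_control;
4. the sign-count coexpression coefficient
   deltaC(i, j) = (n+ - n-) / (n+ + n-), where n+ and n- count positive
   and negative entries of deltaS (zeros and missing values count in
   neither; a pair with empty denominator has no quantifiable value).

Cells are filtered by detected-gene count (strict > threshold) and genes
by mean count, before any correlation is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .acd import acd_distance
from .types import CountMatrix, GenomicInterval, PairStatMatrix

__all__ = [
    "ExpressionFilterReport",
    "CoexpressionResult",
    "filter_expression_matrix",
    "spearman_tied",
    "pairwise_spearman",
    "acd_pair_spearman",
    "differential_spearman",
    "coexpression_coefficient",
    "distance_decay",
    "chromosome_wise_summary",
    "assign_genes_to_acds",
    "coexpression_analysis",
    "pair_distance_matrix",
]


@dataclass(frozen=True)
class ExpressionFilterReport:
    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    min_genes_per_cell: int
    min_mean_count: float


def filter_expression_matrix(
    m: CountMatrix,
    min_genes_per_cell: int = 2_600,
    min_mean_count: float = 1.0,
) -> tuple[CountMatrix, ExpressionFilterReport]:
    """Apply the cell and gene expression filters.

    Cells with strictly more than ``min_genes_per_cell`` detected genes
    (non-zero counts) are retained; then genes whose mean count over the
    retained cells is >= ``min_mean_count`` are retained.
    """
    detected = (m.counts > 0).sum(axis=1)
    cell_mask = detected > min_genes_per_cell
    if not cell_mask.any():
        raise ValueError("expression filter removed every cell")
    kept_cells = m.subset(cells=cell_mask)
    gene_mask = kept_cells.counts.mean(axis=0) >= min_mean_count
    out = kept_cells.subset(features=gene_mask)
    report = ExpressionFilterReport(
        n_cells_in=m.n_cells,
        n_cells_out=out.n_cells,
        n_genes_in=m.n_features,
        n_genes_out=out.n_features,
        min_genes_per_cell=min_genes_per_cell,
        min_mean_count=min_mean_count,
    )
    return out, report


def spearman_tied(x: np.ndarray, y: np.ndarray) -> float:
    """Tied-rank Spearman correlation of two count vectors over cells.

    Average ranks are assigned to ties and the product-moment correlation
    is taken on the ranks.  Returns NaN when either vector is constant
    (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need 1D vectors of length >= 3")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((rxc * ryc).sum() / denom, -1.0, 1.0))


def pairwise_spearman(counts: np.ndarray) -> np.ndarray:
    """Feature x feature tied-rank Spearman matrix of a cells x features
    array, with NaN rows/columns for constant features.

    Vectorised equivalent of calling :func:`spearman_tied` on every
    column pair.
    """
    counts = np.asarray(counts, dtype=float)
    n_cells, n_feat = counts.shape
    ranks = scipy.stats.rankdata(counts, axis=0)
    centered = ranks - ranks.mean(axis=0, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=0))
    constant = norms == 0
    norms_safe = np.where(constant, 1.0, norms)
    rho = (centered.T @ centered) / np.outer(norms_safe, norms_safe)
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    return rho


def acd_pair_spearman(
    m: CountMatrix,
    genes_a: list[str],
    genes_b: list[str],
) -> tuple[np.ndarray, float]:
    """Gene-pair Spearman matrix S for one ACD pair and its mean S-bar.

    S-bar is the mean over defined entries; NaN when no gene pair has a
    defined correlation.
    """
    if not genes_a or not genes_b:
        raise ValueError("both gene sets must be non-empty")
    idx = {g: k for k, g in enumerate(m.feature_ids)}
    ia = [idx[g] for g in genes_a]
    ib = [idx[g] for g in genes_b]
    sub = m.counts[:, ia + ib]
    rho = pairwise_spearman(sub)
    s = rho[: len(ia), len(ia):]
    sbar = float(np.nanmean(s)) if np.isfinite(s).any() else float("nan")
    return s, sbar


def differential_spearman(s_ctrl: np.ndarray, s_dep: np.ndarray) -> np.ndarray:
    """deltaS = S_depleted - S_control, elementwise; NaN propagates."""
    s_ctrl = np.asarray(s_ctrl, dtype=float)
    s_dep = np.asarray(s_dep, dtype=float)
    if s_ctrl.shape != s_dep.shape:
        raise ValueError("condition matrices must have equal shape")
    return s_dep - s_ctrl


def coexpression_coefficient(delta_s: np.ndarray) -> float:
    """Sign-count coefficient deltaC = (n+ - n-) / (n+ + n-).

    Entries equal to zero or missing belong to neither count; when both
    counts are zero the pair has no quantifiable value (NaN).
    """
    delta_s = np.asarray(delta_s, dtype=float)
    n_pos = int(np.sum(delta_s > 0))
    n_neg = int(np.sum(delta_s < 0))
    if n_pos + n_neg == 0:
        return float("nan")
    return (n_pos - n_neg) / (n_pos + n_neg)


def distance_decay(
    distances: np.ndarray,
    values: np.ndarray,
    bin_width_bp: float = 1_000_000.0,
    smooth_window: int = 5,
) -> pd.DataFrame:
    """Distance-decay curve: bin pair values by genomic distance, take the
    per-bin mean and s.e.m., then apply a centred moving average
    (five-point by default, truncated at the edges).

    Only same-chromosome pairs (finite distances, finite values) enter.
    Returns columns ``distance_bp, mean, sem, n, mean_smooth``.
    """
    distances = np.asarray(distances, dtype=float).ravel()
    values = np.asarray(values, dtype=float).ravel()
    ok = np.isfinite(distances) & np.isfinite(values)
    if not ok.any():
        raise ValueError("no same-chromosome pairs with defined values")
    d, v = distances[ok], values[ok]
    bins = np.floor(d / bin_width_bp).astype(int)
    order = np.unique(bins)
    mean = np.array([v[bins == b].mean() for b in order])
    n = np.array([(bins == b).sum() for b in order])
    sem = np.array(
        [
            v[bins == b].std(ddof=1) / np.sqrt(nb) if nb > 1 else np.nan
            for b, nb in zip(order, n)
        ]
    )
    half = smooth_window // 2
    smooth = np.array(
        [
            mean[max(0, k - half): k + half + 1].mean()
            for k in range(len(mean))
        ]
    )
    return pd.DataFrame(
        {
            "distance_bp": (order + 0.5) * bin_width_bp,
            "mean": mean,
            "sem": sem,
            "n": n,
            "mean_smooth": smooth,
        }
    )


def chromosome_wise_summary(
    pairstat: PairStatMatrix,
    acd_chroms: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chromosome x chromosome mean of a pair statistic.

    Diagonal cells are cis means, off-diagonal cells trans means; the
    second frame carries pair counts.  Cells with no quantifiable pair
    are NaN.
    """
    if not pairstat.is_square:
        raise ValueError("chromosome summary requires a square pair matrix")
    chroms = sorted(set(acd_chroms.values()))
    cidx = {c: k for k, c in enumerate(chroms)}
    sums = np.zeros((len(chroms), len(chroms)))
    counts = np.zeros((len(chroms), len(chroms)), dtype=int)
    ii, jj, vals = pairstat.upper_triangle()
    for i, j, v in zip(ii, jj, vals):
        if not np.isfinite(v):
            continue
        ci = cidx[acd_chroms[pairstat.row_ids[i]]]
        cj = cidx[acd_chroms[pairstat.row_ids[j]]]
        a, b = min(ci, cj), max(ci, cj)
        sums[a, b] += v
        counts[a, b] += 1
    sums = sums + np.triu(sums, 1).T
    counts = counts + np.triu(counts, 1).T
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return (
        pd.DataFrame(means, index=chroms, columns=chroms),
        pd.DataFrame(counts, index=chroms, columns=chroms),
    )


def assign_genes_to_acds(
    features: pd.DataFrame, acds: list[GenomicInterval]
) -> dict[str, list[str]]:
    """Map ACD id -> gene ids whose midpoint falls inside the ACD.

    ACDs are assumed disjoint within a chromosome (as produced by the
    caller); genes outside every ACD are dropped.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in acds:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    assignment: dict[str, list[str]] = {iv.id: [] for iv in acds}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        sub = features[features["chrom"] == chrom]
        if sub.empty:
            continue
        mids = ((sub["start"] + sub["end"]) / 2).to_numpy()
        pos = np.searchsorted(starts, mids, side="right") - 1
        for gene, p, mid in zip(sub.index, pos, mids):
            if p >= 0 and mid < ends[p]:
                assignment[ivs[p].id].append(str(gene))
    return assignment


def pair_distance_matrix(acds: list[GenomicInterval]) -> np.ndarray:
    """Matrix of midpoint distances in bp (NaN for trans pairs)."""
    n = len(acds)
    d = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            d[i, j] = acd_distance(acds[i], acds[j])
    return d


@dataclass
class CoexpressionResult:
    """Pair-level coexpression statistics for a control/depleted contrast."""

    acds: list[GenomicInterval]
    sbar_ctrl: PairStatMatrix
    sbar_dep: PairStatMatrix
    delta_c: PairStatMatrix
    n_pos: np.ndarray
    n_neg: np.ndarray
    filter_ctrl: ExpressionFilterReport
    filter_dep: ExpressionFilterReport
    active_acd_ids: list[str]

    @property
    def n_quantifiable_cis(self) -> int:
        """Number of intrachromosomal ACD pairs with a quantifiable deltaC."""
        _, _, vals = self.delta_c.upper_triangle()
        ii, jj, _ = self.delta_c.upper_triangle()
        dist = self.delta_c.distances[ii, jj]
        return int(np.sum(np.isfinite(vals) & np.isfinite(dist)))

    @property
    def n_quantifiable_trans(self) -> int:
        ii, jj, vals = self.delta_c.upper_triangle()
        dist = self.delta_c.distances[ii, jj]
        return int(np.sum(np.isfinite(vals) & ~np.isfinite(dist)))


def coexpression_analysis(
    m_ctrl: CountMatrix,
    m_dep: CountMatrix,
    acds: list[GenomicInterval],
    min_genes_per_cell: int = 2_600,
    min_mean_count: float = 1.0,
) -> CoexpressionResult:
    """Full cross-ACD coexpression contrast between two conditions.

    Both matrices are filtered independently; gene-level Spearman
    matrices are computed per condition over the intersection of
    surviving genes, and the pair-level statistics (S-bar per condition,
    deltaC with sign counts) are assembled for every unordered ACD pair
    among active ACDs (those containing at least one surviving gene).
    """
    f_ctrl, rep_ctrl = filter_expression_matrix(
        m_ctrl, min_genes_per_cell, min_mean_count
    )
    f_dep, rep_dep = filter_expression_matrix(
        m_dep, min_genes_per_cell, min_mean_count
    )
    shared = [g for g in f_ctrl.feature_ids if g in set(f_dep.feature_ids)]
    if not shared:
        raise ValueError("no genes survive the expression filter in both conditions")
    f_ctrl = f_ctrl.subset(
        features=[f_ctrl.feature_ids.index(g) for g in shared]
    )
    f_dep = f_dep.subset(features=[f_dep.feature_ids.index(g) for g in shared])

    gene_map = assign_genes_to_acds(f_ctrl.features, acds)
    active = [iv for iv in acds if gene_map.get(iv.id)]
    active_ids = [iv.id for iv in active]

    rho_ctrl = pairwise_spearman(f_ctrl.counts)
    rho_dep = pairwise_spearman(f_dep.counts)
    delta = differential_spearman(rho_ctrl, rho_dep)

    gidx = {g: k for k, g in enumerate(shared)}
    blocks = [np.array([gidx[g] for g in gene_map[aid]]) for aid in active_ids]

    n = len(active)
    sbar_c = np.full((n, n), np.nan)
    sbar_d = np.full((n, n), np.nan)
    dc = np.full((n, n), np.nan)
    n_pos = np.zeros((n, n), dtype=int)
    n_neg = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            sub_c = rho_ctrl[np.ix_(blocks[i], blocks[j])]
            sub_d = rho_dep[np.ix_(blocks[i], blocks[j])]
            sub_delta = delta[np.ix_(blocks[i], blocks[j])]
            if np.isfinite(sub_c).any():
                sbar_c[i, j] = sbar_c[j, i] = np.nanmean(sub_c)
            if np.isfinite(sub_d).any():
                sbar_d[i, j] = sbar_d[j, i] = np.nanmean(sub_d)
            npos = int(np.sum(sub_delta > 0))
            nneg = int(np.sum(sub_delta < 0))
            n_pos[i, j] = n_pos[j, i] = npos
            n_neg[i, j] = n_neg[j, i] = nneg
            dc[i, j] = dc[j, i] = coexpression_coefficient(sub_delta)

    dist = pair_distance_matrix(active)
    mk = lambda vals, name: PairStatMatrix(  # noqa: E731
        row_ids=active_ids,
        col_ids=active_ids,
        values=vals,
        distances=dist,
        stat_name=name,
    )
    return CoexpressionResult(
        acds=active,
        sbar_ctrl=mk(sbar_c, "S_mean"),
        sbar_dep=mk(sbar_d, "S_mean"),
        delta_c=mk(dc, "deltaC"),
        n_pos=n_pos,
        n_neg=n_neg,
        filter_ctrl=rep_ctrl,
        filter_dep=rep_dep,
        active_acd_ids=active_ids,
    )
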