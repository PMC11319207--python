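"""Cross-ACD chromatin coaccessibility from single-cell ATAC counts.

Fragments are aggregated per cell into ACD-level counts (capped at a
high ceiling), both conditions are binomially downsampled to 50% in
paired repetitions to match read-depth distributions, each repetition is
normalized to the global matrix mean and stripped of poorly sequenced
cells, and per-ACD-pair tied-rank Spearman correlations are computed
across the retained cells.  The repetition-wise Spearman matrices are
averaged and differenced between conditions:

    deltaS_ATAC = S_ATAC,depleted - S_ATAC,control.

Pairs without a defined correlation in either condition carry no
quantifiable value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexpression import pairwise_spearman, pair_distance_matrix
from .types import CountMatrix, GenomicInterval, PairStatMatrix, child_rng

__all__ = [
    "DownsamplePlan",
    "NormalizeFilterReport",
    "CoaccessibilityResult",
    "bin_counts_to_acds",
    "binomial_downsample",
    "normalize_and_filter",
    "coaccessibility_pipeline",
]


@dataclass(frozen=True)
class DownsamplePlan:
    """Matched-downsampling schedule: fraction kept and repetition count.

    Each repetition derives one child seed from the plan seed, shared
    by both conditions (paired thinning), so the ten repetitions are
    reproducible and independent of each other.
    """

    fraction: float = 0.5
    n_reps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def rep_rngs(self, rep: int) -> tuple[np.random.Generator, np.random.Generator]:
        # paired: both conditions share the rep seed, so identical inputs
        # thin identically and deltaS vanishes exactly
        label = f"downsample/rep{rep}"
        return child_rng(self.seed, label), child_rng(self.seed, label)


@dataclass(frozen=True)
class NormalizeFilterReport:
    n_cells_in: int
    n_cells_out: int
    global_mean: float


def bin_counts_to_acds(
    fragments: pd.DataFrame,
    acds: list[GenomicInterval],
    ceiling: int = 1_000,
    condition_label: str = "",
) -> CountMatrix:
    """Aggregate fragments into a cells x ACDs count matrix.

    A fragment is assigned to the ACD containing its midpoint (ACDs are
    disjoint within a chromosome); per-cell per-ACD counts are capped at
    ``ceiling``.  Fragments with an empty/missing cell id are tallied
    into an ``unassigned`` bucket and excluded from the matrix.

    ``fragments`` needs columns ``chrom, start, end, cell``.
    """
    for col in ("chrom", "start", "end", "cell"):
        if col not in fragments.columns:
            raise ValueError(f"fragments table missing column {col!r}")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in acds:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)

    cell_series = fragments["cell"].astype(str)
    known = cell_series.notna() & (cell_series != "") & (cell_series != "nan")
    n_unassigned_cell = int((~known).sum())
    frag = fragments[known.to_numpy()]

    cells = sorted(frag["cell"].astype(str).unique())
    cell_idx = {c: k for k, c in enumerate(cells)}
    acd_idx = {iv.id: k for k, iv in enumerate(acds)}
    counts = np.zeros((len(cells), len(acds)), dtype=np.int64)
    for chrom, ivs in by_chrom.items():
        sub = frag[frag["chrom"] == chrom]
        if sub.empty:
            continue
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        mids = ((sub["start"] + sub["end"]) / 2).to_numpy()
        pos = np.searchsorted(starts, mids, side="right") - 1
        inside = (pos >= 0) & (mids < ends[np.clip(pos, 0, None)])
        for cell, p in zip(sub["cell"].astype(str)[inside], pos[inside]):
            counts[cell_idx[cell], acd_idx[ivs[p].id]] += 1
    np.minimum(counts, ceiling, out=counts)
    features = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in acds],
            "start": [iv.start for iv in acds],
            "end": [iv.end for iv in acds],
        },
        index=pd.Index([iv.id for iv in acds]),
    )
    cm = CountMatrix(
        cells=cells,
        features=features,
        counts=counts,
        condition_label=condition_label,
    )
    cm.n_unassigned = n_unassigned_cell  # logged bucket, outside the matrix
    return cm


def binomial_downsample(
    m: CountMatrix, fraction: float, rng: np.random.Generator
) -> CountMatrix:
    """Thin every count with an independent Binomial(count, fraction) draw."""
    counts = m.counts
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("downsampling requires integer counts")
    if fraction == 1.0:
        thinned = counts.astype(np.int64).copy()
    else:
        thinned = rng.binomial(counts.astype(np.int64), fraction)
    return CountMatrix(
        cells=list(m.cells),
        features=m.features.copy(),
        counts=thinned,
        condition_label=m.condition_label,
    )


def normalize_and_filter(
    m: CountMatrix,
) -> tuple[CountMatrix, NormalizeFilterReport]:
    """Normalize to the global matrix mean and drop poorly sequenced cells.

    N = M / mean(M) with the scalar mean taken over all entries; a cell
    is retained iff the mean of its normalized entries is >= 1
    (equivalently: its mean raw count is >= the global mean).  The
    normalization itself is a no-op for rank correlations but fixes the
    filter threshold.
    """
    mbar = float(m.counts.mean()) if m.counts.size else 0.0
    if mbar <= 0:
        raise ValueError("matrix total must be positive")
    n = m.counts / mbar
    keep = n.mean(axis=1) >= 1.0
    out = CountMatrix(
        cells=[c for c, k in zip(m.cells, keep) if k],
        features=m.features.copy(),
        counts=n[keep],
        condition_label=m.condition_label,
    )
    return out, NormalizeFilterReport(
        n_cells_in=m.n_cells, n_cells_out=out.n_cells, global_mean=mbar
    )


@dataclass
class CoaccessibilityResult:
    acd_ids: list[str]
    s_ctrl: PairStatMatrix
    s_dep: PairStatMatrix
    delta_s: PairStatMatrix
    n_reps_defined: np.ndarray = field(default=None)

    @property
    def n_quantifiable_cis(self) -> int:
        ii, jj, vals = self.delta_s.upper_triangle()
        dist = self.delta_s.distances[ii, jj]
        return int(np.sum(np.isfinite(vals) & np.isfinite(dist)))


def coaccessibility_pipeline(
    m_ctrl: CountMatrix,
    m_dep: CountMatrix,
    acds: list[GenomicInterval],
    plan: DownsamplePlan | None = None,
) -> CoaccessibilityResult:
    """Matched-downsampling Spearman pipeline over ACD pairs.

    For each repetition both condition matrices are thinned with the
    repetition's paired seeds, normalized and cell-filtered, and the
    ACD x ACD tied-rank Spearman matrix is computed across retained
    cells.  Repetition matrices are averaged elementwise over defined
    entries, then differenced (depleted - control).
    """
    if m_ctrl.feature_ids != m_dep.feature_ids:
        raise ValueError("conditions must share the same ACD set")
    plan = plan or DownsamplePlan()
    acd_ids = m_ctrl.feature_ids
    n = len(acd_ids)

    def _rep_spearman(m: CountMatrix, rng: np.random.Generator) -> np.ndarray:
        thinned = binomial_downsample(m, plan.fraction, rng)
        filtered, _ = normalize_and_filter(thinned)
        if filtered.n_cells < 3:
            return np.full((n, n), np.nan)
        return pairwise_spearman(filtered.counts)

    acc_c = np.zeros((n, n))
    acc_d = np.zeros((n, n))
    cnt_c = np.zeros((n, n), dtype=int)
    cnt_d = np.zeros((n, n), dtype=int)
    for rep in range(plan.n_reps):
        rng_c, rng_d = plan.rep_rngs(rep)
        rc = _rep_spearman(m_ctrl, rng_c)
        rd = _rep_spearman(m_dep, rng_d)
        fc, fd = np.isfinite(rc), np.isfinite(rd)
        acc_c[fc] += rc[fc]
        acc_d[fd] += rd[fd]
        cnt_c += fc
        cnt_d += fd

    with np.errstate(invalid="ignore"):
        s_c = np.where(cnt_c > 0, acc_c / np.maximum(cnt_c, 1), np.nan)
        s_d = np.where(cnt_d > 0, acc_d / np.maximum(cnt_d, 1), np.nan)
    delta = s_d - s_c  # NaN wherever either side is undefined
    np.fill_diagonal(s_c, np.nan)
    np.fill_diagonal(s_d, np.nan)
    np.fill_diagonal(delta, np.nan)

    acd_by_id = {iv.id: iv for iv in acds}
    ordered = [acd_by_id[a] for a in acd_ids]
    dist = pair_distance_matrix(ordered)
    mk = lambda vals, name: PairStatMatrix(  # noqa: E731
        row_ids=acd_ids,
        col_ids=acd_ids,
        values=vals,
        distances=dist,
        stat_name=name,
    )
    return CoaccessibilityResult(
        acd_ids=acd_ids,
        s_ctrl=mk(s_c, "S"),
        s_dep=mk(s_d, "S"),
        delta_s=mk(delta, "deltaS"),
        n_reps_defined=np.minimum(cnt_c, cnt_d),
    )
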