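"""Multi-round FISH decoding and transcriptional co-bursting statistics.

Nascent-transcription bursting sites are read out over several
hybridization rounds; each gene carries a pseudocolor barcode (one
pseudocolor per round).  Spots from different rounds that colocalize
within a 1-pixel xyz cutoff are clustered, the cluster's pseudocolor
sequence is matched against the codebook (exactly, or uniquely with one
dropped round), and matched clusters become per-cell bursting calls.

Bursting statistics:

* bursting frequency  F = N_b / N  (bursting sites of a gene per cell,
  may exceed 1 with multiple alleles);
* co-bursting count  N_co: per cell, greedily matched (A, B) site pairs
  within a 1-um 3D gate (selecting same-chromosome events);
* normalized co-bursting  F_co = N_co / (F_A * F_B * N), so that 1 marks
  independent bursting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as _io

__all__ = [
    "Codebook",
    "BurstCall",
    "CoBurstStat",
    "decode_cell",
    "decode_spots",
    "calls_to_frame",
    "bursting_frequency",
    "co_burst_count",
    "normalized_co_burst",
    "burst_statistics",
    "differential_matrices",
    "all_gene_pairs",
]


@dataclass(frozen=True)
class Codebook:
    """Gene -> per-round pseudocolor barcode (pseudocolors in 1..9).

    Valid codebooks have unique barcodes that differ in at least two
    rounds, so a single dropped round still decodes uniquely.
    """

    barcodes: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("codebook is empty")
        lengths = {len(b) for b in self.barcodes.values()}
        if len(lengths) != 1:
            raise ValueError("all barcodes must have the same number of rounds")
        for gene, bc in self.barcodes.items():
            if any(not (1 <= c <= 9) for c in bc):
                raise ValueError(f"{gene}: pseudocolors must lie in 1..9")
        genes = list(self.barcodes)
        for a, b in itertools.combinations(genes, 2):
            diff = sum(
                x != y for x, y in zip(self.barcodes[a], self.barcodes[b])
            )
            if diff < 2:
                raise ValueError(
                    f"barcodes for {a} and {b} differ in {diff} round(s); "
                    "need >= 2 for one-round-dropout decoding"
                )

    @property
    def n_rounds(self) -> int:
        return len(next(iter(self.barcodes.values())))

    @property
    def genes(self) -> list[str]:
        return list(self.barcodes)

    @classmethod
    def from_csv(cls, path) -> "Codebook":
        df = _io.read_codebook_table(path)
        ro_cols = [c for c in df.columns if c != "gene"]
        return cls(
            barcodes={
                str(row["gene"]): tuple(int(row[c]) for c in ro_cols)
                for _, row in df.iterrows()
            }
        )

    def match(self, colors: dict[int, int]) -> tuple[str | None, int]:
        """Match observed {round: pseudocolor} to a gene.

        Full barcodes must match exactly; with one missing round the
        unique consistent barcode (if any) is taken.  Returns
        (gene or None, number of matched rounds).
        """
        if len(colors) < self.n_rounds - 1:
            return None, 0
        candidates = [
            g
            for g, bc in self.barcodes.items()
            if all(bc[r] == c for r, c in colors.items())
        ]
        if len(candidates) == 1:
            return candidates[0], len(colors)
        return None, 0  # unmatched or ambiguous


@dataclass(frozen=True)
class BurstCall:
    cell_id: str
    gene: str
    x_nm: float
    y_nm: float
    z_nm: float
    n_rounds_matched: int


@dataclass(frozen=True)
class CoBurstStat:
    gene_a: str
    gene_b: str
    n_co: int
    f_a: float
    f_b: float
    n_cells: int
    f_co: float
    mean_distance_um: float


def decode_cell(
    spots: pd.DataFrame,
    codebook: Codebook,
    max_round_dist_px: float = 1.0,
    px_nm: float = 100.0,
    cell_id: str = "",
) -> list[BurstCall]:
    """Decode one cell's multi-round spots into bursting calls.

    ``spots`` needs columns ``round, pseudocolor, x_px, y_px, z_px``
    (round indices 0-based).  Spots are clustered greedily in
    (round, position) order: a spot joins the nearest existing cluster
    whose centroid lies within the cutoff and which has no spot from the
    same round yet; clusters covering all rounds, or all but one, are
    matched against the codebook, and ambiguous or unmatched clusters
    are discarded.  Call positions are cluster centroids in nm.
    """
    required = ["round", "pseudocolor", "x_px", "y_px", "z_px"]
    missing = [c for c in required if c not in spots.columns]
    if missing:
        raise ValueError(f"spots table missing column(s): {', '.join(missing)}")
    ordered = spots.sort_values(
        ["round", "x_px", "y_px", "z_px"], kind="mergesort"
    )
    clusters: list[dict] = []  # {rounds: {r: color}, points: [xyz_px]}
    for _, row in ordered.iterrows():
        p = np.array([row["x_px"], row["y_px"], row["z_px"]], dtype=float)
        r = int(row["round"])
        best, best_d = None, np.inf
        for cl in clusters:
            if r in cl["rounds"]:
                continue
            centroid = np.mean(cl["points"], axis=0)
            d = float(np.linalg.norm(p - centroid))
            if d <= max_round_dist_px and d < best_d:
                # adding must keep every member within the cutoff of the
                # new centroid
                new_centroid = (centroid * len(cl["points"]) + p) / (
                    len(cl["points"]) + 1
                )
                dists = np.linalg.norm(
                    np.vstack(cl["points"] + [p]) - new_centroid, axis=1
                )
                if np.all(dists <= max_round_dist_px):
                    best, best_d = cl, d
        if best is None:
            clusters.append({"rounds": {r: int(row["pseudocolor"])}, "points": [p]})
        else:
            best["rounds"][r] = int(row["pseudocolor"])
            best["points"].append(p)

    calls = []
    for cl in clusters:
        gene, n_matched = codebook.match(cl["rounds"])
        if gene is None:
            continue
        centroid = np.mean(cl["points"], axis=0) * px_nm
        calls.append(
            BurstCall(
                cell_id=cell_id,
                gene=gene,
                x_nm=float(centroid[0]),
                y_nm=float(centroid[1]),
                z_nm=float(centroid[2]),
                n_rounds_matched=n_matched,
            )
        )
    return calls


def decode_spots(
    spots: pd.DataFrame,
    codebook: Codebook,
    max_round_dist_px: float = 1.0,
    px_nm: float = 100.0,
) -> pd.DataFrame:
    """Decode a multi-cell spots table (extra ``cell_id`` column)."""
    calls: list[BurstCall] = []
    for cell, grp in spots.groupby("cell_id", sort=True):
        calls.extend(
            decode_cell(
                grp,
                codebook,
                max_round_dist_px=max_round_dist_px,
                px_nm=px_nm,
                cell_id=str(cell),
            )
        )
    return calls_to_frame(calls)


def calls_to_frame(calls: list[BurstCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.cell_id, c.gene, c.x_nm, c.y_nm, c.z_nm, c.n_rounds_matched)
            for c in calls
        ],
        columns=["cell_id", "gene", "x_nm", "y_nm", "z_nm", "n_rounds_matched"],
    )


def bursting_frequency(calls: pd.DataFrame, gene: str, n_cells: int) -> float:
    """F = N_b / N: bursting sites of ``gene`` per cell.

    May exceed 1 when several alleles burst per cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return float((calls["gene"] == gene).sum()) / n_cells


def co_burst_count(
    calls: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    cutoff_um: float = 1.0,
) -> tuple[int, np.ndarray]:
    """Distance-gated co-bursting count over all cells.

    Per cell, (A, B) site pairs with 3D Euclidean distance <= the gate
    are matched greedily nearest-first; each site participates in at
    most one pair.  Returns the total count and the matched distances
    (um).  Symmetric in (gene_a, gene_b).
    """
    n_co = 0
    distances: list[float] = []
    cutoff_nm = cutoff_um * 1_000.0
    for _, grp in calls.groupby("cell_id", sort=False):
        pa = grp.loc[grp["gene"] == gene_a, ["x_nm", "y_nm", "z_nm"]].to_numpy()
        pb = grp.loc[grp["gene"] == gene_b, ["x_nm", "y_nm", "z_nm"]].to_numpy()
        if len(pa) == 0 or len(pb) == 0:
            continue
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        used_a = np.zeros(len(pa), dtype=bool)
        used_b = np.zeros(len(pb), dtype=bool)
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        for i, j in order:
            if d[i, j] > cutoff_nm:
                break
            if used_a[i] or used_b[j]:
                continue
            used_a[i] = used_b[j] = True
            n_co += 1
            distances.append(d[i, j] / 1_000.0)
    return n_co, np.asarray(distances)


def normalized_co_burst(n_co: int, f_a: float, f_b: float, n_cells: int) -> float:
    """F_co = N_co / (F_A * F_B * N); NaN when either marginal is zero."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if f_a <= 0 or f_b <= 0:
        return float("nan")
    return n_co / (f_a * f_b * n_cells)


def all_gene_pairs(genes: list[str]) -> list[tuple[str, str]]:
    """All unordered gene pairs, in codebook order."""
    return list(itertools.combinations(genes, 2))


def burst_statistics(
    calls: pd.DataFrame,
    genes: list[str],
    n_cells: int,
    cutoff_um: float = 1.0,
) -> list[CoBurstStat]:
    """Per-pair co-bursting statistics over all unordered gene pairs."""
    freqs = {g: bursting_frequency(calls, g, n_cells) for g in genes}
    stats = []
    for a, b in all_gene_pairs(genes):
        n_co, dists = co_burst_count(calls, a, b, cutoff_um=cutoff_um)
        stats.append(
            CoBurstStat(
                gene_a=a,
                gene_b=b,
                n_co=n_co,
                f_a=freqs[a],
                f_b=freqs[b],
                n_cells=n_cells,
                f_co=normalized_co_burst(n_co, freqs[a], freqs[b], n_cells),
                mean_distance_um=float(dists.mean()) if len(dists) else float("nan"),
            )
        )
    return stats


def differential_matrices(
    stats_ctrl: list[CoBurstStat],
    stats_dep: list[CoBurstStat],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise depleted-minus-control differences.

    Returns (delta F_co matrix, delta mean-distance matrix) as symmetric
    gene x gene DataFrames; a pair missing on either side stays NaN.
    """
    genes_c = sorted({s.gene_a for s in stats_ctrl} | {s.gene_b for s in stats_ctrl})
    genes_d = sorted({s.gene_a for s in stats_dep} | {s.gene_b for s in stats_dep})
    if genes_c != genes_d:
        raise ValueError("conditions must cover the same gene set")
    genes = genes_c
    idx = {g: k for k, g in enumerate(genes)}
    dfco = np.full((len(genes), len(genes)), np.nan)
    ddist = np.full((len(genes), len(genes)), np.nan)
    ctrl = {(s.gene_a, s.gene_b): s for s in stats_ctrl}
    for s_dep in stats_dep:
        key = (s_dep.gene_a, s_dep.gene_b)
        s_ctrl = ctrl.get(key) or ctrl.get(key[::-1])
        if s_ctrl is None:
            continue
        i, j = idx[s_dep.gene_a], idx[s_dep.gene_b]
        dfco[i, j] = dfco[j, i] = s_dep.f_co - s_ctrl.f_co
        ddist[i, j] = ddist[j, i] = (
            s_dep.mean_distance_um - s_ctrl.mean_distance_um
        )
    return (
        pd.DataFrame(dfco, index=genes, columns=genes),
        pd.DataFrame(ddist, index=genes, columns=genes),
    )
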