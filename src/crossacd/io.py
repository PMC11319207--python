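"""Readers and writers for the plain-text formats the pipeline consumes.

Formats
-------
* BED (3+ tab-separated columns) for intervals / ACDs / fragments.
* MatrixMarket triplet (+ feature and cell list files) or dense TSV for
  count matrices.
* CSV for localizations (``cell_id,channel,x_nm,y_nm,z_nm``), tracks
  (``track_id,frame,x_um,y_um``) and codebooks (``gene,ro1..roK``).
* Tab-separated dumps of pair-statistic matrices.

All writers round-trip losslessly through the matching reader at the
stated float precision.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    CountMatrix,
    GenomicInterval,
    LocalizationCloud,
    PairStatMatrix,
    Track,
    TrackSet,
)

__all__ = [
    "read_intervals",
    "write_intervals",
    "read_count_matrix",
    "read_count_matrix_tsv",
    "write_count_matrix_tsv",
    "read_tracks",
    "write_tracks",
    "read_localizations",
    "write_localizations",
    "read_pairstat",
    "write_pairstat",
    "read_codebook_table",
]


class ParseError(ValueError):
    """Raised for malformed input files, naming the offending line."""


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file into sorted, validated genomic intervals.

    Coordinates are kept 0-based half-open as in the file.  A fourth
    column, if present, becomes the interval id.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"columns, got {len(parts)}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            try:
                iv = GenomicInterval(
                    chrom=parts[0],
                    start=start,
                    end=end,
                    id=parts[3] if len(parts) > 3 else None,
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            intervals.append(iv)
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_intervals(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.id is not None:
                cols.append(iv.id)
            fh.write("\t".join(cols) + "\n")


def _read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.split("\t")[0].strip() for line in fh if line.strip()]


def read_count_matrix(
    matrix_path: str | Path,
    features_path: str | Path,
    cells_path: str | Path,
    condition_label: str = "",
) -> CountMatrix:
    """Read a MatrixMarket triplet count matrix (features x cells on disk).

    ``features_path`` carries one feature per line: either just an id or
    ``id<TAB>chrom<TAB>start<TAB>end``.  The matrix is stored
    features x cells (the single-cell convention) and transposed to
    cells x features in memory.  Total counts are preserved exactly.
    """
    mat = scipy.io.mmread(str(matrix_path))
    dense = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
    )
    if dense.size and dense.min() < 0:
        raise ValueError(f"{matrix_path}: negative count entries")
    features = _read_feature_table(features_path)
    cells = _read_id_list(cells_path)
    if dense.shape != (len(features), len(cells)):
        raise ValueError(
            f"dimension mismatch: matrix {dense.shape} vs "
            f"{len(features)} features x {len(cells)} cells"
        )
    return CountMatrix(
        cells=cells,
        features=features,
        counts=dense.T.copy(),
        condition_label=condition_label,
    )


def _read_feature_table(path: str | Path) -> pd.DataFrame:
    ids, chroms, starts, ends = [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            ids.append(parts[0])
            if len(parts) >= 4:
                chroms.append(parts[1])
                starts.append(int(parts[2]))
                ends.append(int(parts[3]))
            else:
                chroms.append("")
                starts.append(0)
                ends.append(1)
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends}, index=pd.Index(ids)
    )


def read_count_matrix_tsv(
    path: str | Path, condition_label: str = ""
) -> CountMatrix:
    """Read a dense TSV (rows = features with optional position columns,
    columns = cells; header row of cell ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    pos_cols = [c for c in ("chrom", "start", "end") if c in df.columns]
    if len(pos_cols) == 3:
        features = df[pos_cols].copy()
        data = df.drop(columns=pos_cols)
    else:
        features = pd.DataFrame(
            {"chrom": "", "start": 0, "end": 1}, index=df.index
        )
        data = df
    counts = data.to_numpy(dtype=float).T
    if counts.size and counts.min() < 0:
        raise ValueError(f"{path}: negative count entries")
    return CountMatrix(
        cells=list(data.columns),
        features=features,
        counts=counts,
        condition_label=condition_label,
    )


def write_count_matrix_tsv(matrix: CountMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.counts.T, index=matrix.features.index, columns=matrix.cells
    )
    out = pd.concat([matrix.features[["chrom", "start", "end"]], df], axis=1)
    out.to_csv(path, sep="\t")


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_tracks(path: str | Path, dt: float) -> TrackSet:
    """Read a track CSV with columns ``track_id,frame,x_um,y_um``."""
    df = pd.read_csv(path)
    _require_columns(df, ["track_id", "frame", "x_um", "y_um"], path)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                track_id=str(tid),
                frames=grp["frame"].to_numpy(),
                xy=grp[["x_um", "y_um"]].to_numpy(),
                dt=dt,
            )
        )
    return TrackSet(tracks=tracks, dt=dt)


def write_tracks(ts: TrackSet, path: str | Path) -> None:
    rows = []
    for tr in ts.tracks:
        for f, (x, y) in zip(tr.frames, tr.xy):
            rows.append((tr.track_id, int(f), x, y))
    pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"]).to_csv(
        path, index=False
    )


def read_localizations(path: str | Path) -> list[LocalizationCloud]:
    """Read a localization CSV (``cell_id,channel,x_nm,y_nm,z_nm``) into
    one cloud per (cell_id, channel)."""
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "channel", "x_nm", "y_nm", "z_nm"], path)
    clouds = []
    for (cell, chan), grp in df.groupby(["cell_id", "channel"], sort=True):
        clouds.append(
            LocalizationCloud(
                points=grp[["x_nm", "y_nm", "z_nm"]].to_numpy(),
                channel=str(chan),
                cell_id=str(cell),
            )
        )
    return clouds


def write_localizations(clouds: list[LocalizationCloud], path: str | Path) -> None:
    frames = []
    for cloud in clouds:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cloud.cell_id if cloud.cell_id is not None else "",
                    "channel": cloud.channel,
                    "x_nm": cloud.points[:, 0],
                    "y_nm": cloud.points[:, 1],
                    "z_nm": cloud.points[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_pairstat(matrix: PairStatMatrix, path: str | Path) -> None:
    """Write a pair-statistic matrix as TSV with a small header block."""
    with open(path, "w") as fh:
        fh.write(f"# stat_name\t{matrix.stat_name}\n")
        fh.write(f"# has_distances\t{int(matrix.distances is not None)}\n")
        df = pd.DataFrame(
            matrix.values, index=matrix.row_ids, columns=matrix.col_ids
        )
        df.to_csv(fh, sep="\t", float_format="%.12g")
        if matrix.distances is not None:
            fh.write("# distances\n")
            pd.DataFrame(
                matrix.distances, index=matrix.row_ids, columns=matrix.col_ids
            ).to_csv(fh, sep="\t", float_format="%.12g")


def read_pairstat(path: str | Path) -> PairStatMatrix:
    with open(path) as fh:
        lines = fh.readlines()
    stat_name = lines[0].rstrip("\n").split("\t")[1]
    has_dist = bool(int(lines[1].rstrip("\n").split("\t")[1]))
    body = lines[2:]
    if has_dist:
        sep_idx = body.index("# distances\n")
        val_lines, dist_lines = body[:sep_idx], body[sep_idx + 1 :]
    else:
        val_lines, dist_lines = body, None
    vals = pd.read_csv(_io.StringIO("".join(val_lines)), sep="\t", index_col=0)
    distances = None
    if dist_lines:
        distances = (
            pd.read_csv(_io.StringIO("".join(dist_lines)), sep="\t", index_col=0)
            .to_numpy(dtype=float)
        )
    return PairStatMatrix(
        row_ids=[str(i) for i in vals.index],
        col_ids=[str(c) for c in vals.columns],
        values=vals.to_numpy(dtype=float),
        distances=distances,
        stat_name=stat_name,
    )


def read_codebook_table(path: str | Path) -> pd.DataFrame:
    """Read a codebook CSV with columns ``gene,ro1..roK`` (pseudocolors)."""
    df = pd.read_csv(path)
    if "gene" not in df.columns:
        raise ParseError(f"{path}: missing required column(s): gene")
    ro_cols = [c for c in df.columns if c.lower().startswith("ro")]
    if not ro_cols:
        raise ParseError(f"{path}: missing readout-round columns (ro1..roK)")
    return df[["gene"] + sorted(ro_cols, key=lambda c: int(c[2:]))]
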