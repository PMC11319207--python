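"""Shared domain containers.

Every analysis stage exchanges data through the small set of types defined
here: genomic intervals (the accessible chromatin domains, ACDs, over which
all pairwise statistics are computed), binned 1D signals, cells x features
count matrices, symmetric pair-statistic matrices, 3D localization clouds
and 2D single-particle tracks.

Conventions
-----------
* Genomic coordinates are 0-based half-open (BED convention) everywhere.
* Missing statistic values are ``NaN``, never 0 — the sign-count
  coexpression coefficient distinguishes "no value" from "value zero".
* All randomness flows from a single seed through :func:`child_seed`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "BinnedSignal",
    "CountMatrix",
    "PairStatMatrix",
    "LocalizationCloud",
    "Track",
    "TrackSet",
    "Config",
    "child_seed",
    "child_rng",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class BinnedSignal:
    """Fixed-width binned signal along one chromosome.

    Bin ``i`` covers ``[i * bin_size, (i + 1) * bin_size)``.
    """

    chrom: str
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1D array")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("signal values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CountMatrix:
    """Cells x features non-negative count matrix with feature positions.

    ``features`` is a DataFrame indexed by feature id with columns
    ``chrom``, ``start``, ``end``; a feature maps to exactly one
    chromosome. Counts may be float after normalization but are integer
    on ingest.
    """

    cells: list[str]
    features: pd.DataFrame
    counts: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cells), len(self.features)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.features)} features"
            )
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("cell identifiers must be unique")
        if self.features.index.has_duplicates:
            raise ValueError("feature identifiers must be unique")
        for col in ("chrom", "start", "end"):
            if col not in self.features.columns:
                raise ValueError(f"features table missing column {col!r}")
        if self.counts.size and np.nanmin(self.counts) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    def subset(
        self,
        cells: np.ndarray | list | None = None,
        features: np.ndarray | list | None = None,
    ) -> "CountMatrix":
        """Return a copy restricted to boolean/int masks of cells/features."""
        cell_idx = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        if cell_idx.dtype == bool:
            cell_idx = np.flatnonzero(cell_idx)
        feat_idx = (
            np.arange(self.n_features) if features is None else np.asarray(features)
        )
        if feat_idx.dtype == bool:
            feat_idx = np.flatnonzero(feat_idx)
        return CountMatrix(
            cells=[self.cells[i] for i in cell_idx],
            features=self.features.iloc[feat_idx].copy(),
            counts=self.counts[np.ix_(cell_idx, feat_idx)].copy(),
            condition_label=self.condition_label,
        )


# deltaS is a difference of correlations and may lie in [-2, 2]
_CORRELATION_STATS = {"S", "S_mean", "deltaC"}


@dataclass
class PairStatMatrix:
    """Symmetric pair-statistic matrix over ACDs or genes.

    ``values[i, j]`` carries the statistic for the (row_ids[i], col_ids[j])
    pair; ``NaN`` marks pairs without a quantifiable value.  ``distances``
    holds genomic midpoint distances in bp for same-chromosome pairs and
    ``NaN`` for trans pairs.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    distances: np.ndarray | None = None
    stat_name: str = "S"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("values shape does not match id lists")
        if self.distances is not None:
            self.distances = np.asarray(self.distances, dtype=float)
            if self.distances.shape != self.values.shape:
                raise ValueError("distances shape does not match values")
        if self.stat_name in _CORRELATION_STATS:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError(
                    f"{self.stat_name} entries must lie in [-1, 1]"
                )

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    def upper_triangle(self, k: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, value) arrays over the upper triangle (diagonal excluded).

        Only meaningful for square matrices; the diagonal is excluded from
        all summaries by convention.
        """
        if not self.is_square:
            raise ValueError("upper_triangle requires a square matrix")
        i, j = np.triu_indices(len(self.row_ids), k=k)
        return i, j, self.values[i, j]


@dataclass
class LocalizationCloud:
    """3D localization point cloud (nm) from one imaging channel."""

    points: np.ndarray
    channel: str = ""
    cell_id: str | None = None
    bounding_box: np.ndarray | None = None  # shape (3, 2): [min, max] per axis

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.points.size and not np.all(np.isfinite(self.points)):
            raise ValueError("localization coordinates must be finite")
        if self.bounding_box is not None:
            self.bounding_box = np.asarray(self.bounding_box, dtype=float)
            if self.bounding_box.shape != (3, 2):
                raise ValueError("bounding_box must have shape (3, 2)")
            if np.any(self.bounding_box[:, 1] <= self.bounding_box[:, 0]):
                raise ValueError("bounding_box must have positive extent")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def volume(self) -> float:
        """Bounding volume V in nm^3 (explicit box, else axis-aligned hull)."""
        box = self.bounding_box
        if box is None:
            if len(self.points) < 2:
                raise ValueError("cannot derive a volume from < 2 points")
            box = np.stack([self.points.min(0), self.points.max(0)], axis=1)
        extent = box[:, 1] - box[:, 0]
        v = float(np.prod(extent))
        if v <= 0:
            raise ValueError("bounding volume must be positive")
        return v


@dataclass
class Track:
    """One 2D single-particle trajectory.

    Positions are in micrometres; ``frames`` are the (possibly gapped)
    camera frame indices, so time lags are computed from frame differences
    rather than array offsets.
    """

    track_id: str
    frames: np.ndarray
    xy: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and positions must have equal length")
        if len(self.frames) < 2:
            raise ValueError("a track needs at least 2 points")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TrackSet:
    tracks: list[Track]
    dt: float

    def __len__(self) -> int:
        return len(self.tracks)


def child_seed(seed: int, label: str) -> np.random.SeedSequence:
    """Derive a per-stage seed from one global seed.

    The derivation is a :class:`numpy.random.SeedSequence` keyed on
    ``(seed, crc32(label))``, so the same (seed, stage) pair always yields
    the same stream while distinct stages (e.g. the ten downsampling
    repetitions) get independent streams.
    """
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])


def child_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, label))


@dataclass
class Config:
    """Pipeline defaults; the rationale for each value is in docs/methods.md."""

    bin_size: int = 200_000  # 200-kb ATAC binning unit
    prominence_mode: str = "global_mean"
    min_genes_per_cell: int = 2_600  # strict > filter on detected genes
    min_mean_count: float = 1.0  # gene kept iff mean count >= 1
    atac_ceiling: int = 1_000  # per-ACD per-cell count ceiling
    downsample_fraction: float = 0.5
    downsample_reps: int = 10
    decode_max_dist_px: float = 1.0  # cross-round decoding cutoff
    co_burst_cutoff_um: float = 1.0  # same-chromosome co-burst gate
    dr_nm: float = 50.0  # pair-correlation shell width
    n_reference_draws: int = 20
    min_track_len: int = 5
    max_resnorm: float = 1e-5  # squared residual norm cutoff (um^4)
    max_roc_um: float = 0.5  # 500-nm RoC cutoff
    distance_bin_bp: float = 1_000_000.0
    smooth_window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.downsample_fraction <= 1:
            raise ValueError("downsample_fraction must lie in (0, 1]")
        if self.downsample_reps < 1:
            raise ValueError("downsample_reps must be >= 1")
        if self.bin_size <= 0 or self.dr_nm <= 0:
            raise ValueError("bin_size and dr_nm must be positive")

    def rng(self, label: str) -> np.random.Generator:
        return child_rng(self.seed, label)
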