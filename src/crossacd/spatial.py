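"""3D pair cross-correlation between two localization channels.

The raw cross-correlation per radial shell of width dr is

    c0(r) = V / (V_shell(r) * M * N) * sum_ij [r <= r_ij < r + dr],

with V the bounding volume, M and N the channel localization counts and
V_shell(r) = 4*pi/3 * ((r + dr)^3 - r^3) the exact shell volume (r is
the shell lower edge).  The normalized curve C(r) = c0(r) / c_r(r)
divides by the mean c0 of uniform reference draws with the same M, N
and volume, so C(r) = 1 under complete spatial randomness and C(r) > 1
indicates cross-channel clustering at scale r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .types import LocalizationCloud, child_rng

__all__ = [
    "PairCorrelationCurve",
    "shell_pair_counts",
    "pair_correlation_c0",
    "normalized_pair_correlation",
]


@dataclass
class PairCorrelationCurve:
    r_nm: np.ndarray  # shell lower edges
    c0: np.ndarray
    c_ref: np.ndarray
    c_norm: np.ndarray  # C(r) = c0 / c_ref, NaN where c_ref == 0
    n_pairs: np.ndarray
    dr_nm: float


def shell_pair_counts(
    a: LocalizationCloud,
    b: LocalizationCloud,
    dr_nm: float = 50.0,
    r_max_nm: float = 1_000.0,
    exclude_self: bool = False,
) -> np.ndarray:
    """Ordered pair counts per half-open radial shell [k*dr, (k+1)*dr).

    ``exclude_self`` drops i == j pairs for autocorrelation of a cloud
    with itself (cross-channel use has none).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both clouds must be non-empty")
    if r_max_nm < dr_nm:
        raise ValueError("r_max must be at least one shell wide")
    d = cdist(a.points, b.points)
    if exclude_self:
        if len(a) != len(b):
            raise ValueError("self-pair exclusion requires equal-size clouds")
        np.fill_diagonal(d, np.inf)
    edges = np.arange(0.0, r_max_nm + dr_nm * 0.5, dr_nm)
    counts, _ = np.histogram(d.ravel(), bins=edges)
    return counts.astype(np.int64)


def pair_correlation_c0(
    counts: np.ndarray,
    m: int,
    n: int,
    volume_nm3: float,
    dr_nm: float = 50.0,
) -> np.ndarray:
    """Shell-normalized pair correlation from raw shell counts.

    Implements the density normalization with r taken as the shell
    lower edge, so the denominator 4*pi*(3 r^2 dr + 3 r dr^2 + dr^3)/3
    is exactly the shell volume.
    """
    if volume_nm3 <= 0:
        raise ValueError("volume must be positive")
    counts = np.asarray(counts, dtype=float)
    r = np.arange(len(counts)) * dr_nm
    shell_vol = (
        4.0 * np.pi / 3.0 * (3 * r**2 * dr_nm + 3 * r * dr_nm**2 + dr_nm**3)
    )
    return volume_nm3 * counts / (m * n * shell_vol)


def _union_box(a: LocalizationCloud, b: LocalizationCloud) -> np.ndarray:
    if a.bounding_box is not None and b.bounding_box is not None:
        lo = np.minimum(a.bounding_box[:, 0], b.bounding_box[:, 0])
        hi = np.maximum(a.bounding_box[:, 1], b.bounding_box[:, 1])
    else:
        pts = np.vstack([a.points, b.points])
        lo, hi = pts.min(0), pts.max(0)
    box = np.stack([lo, hi], axis=1)
    if np.any(box[:, 1] <= box[:, 0]):
        raise ValueError("degenerate bounding box (zero extent on an axis)")
    return box


def normalized_pair_correlation(
    a: LocalizationCloud,
    b: LocalizationCloud,
    dr_nm: float = 50.0,
    r_max_nm: float = 1_000.0,
    n_reference_draws: int = 20,
    seed: int = 0,
    exclude_self: bool = False,
) -> PairCorrelationCurve:
    """Normalized pair cross-correlation C(r) = c0(r) / c_r(r).

    The reference c_r is the mean c0 over uniform draws with the same
    localization counts in the same bounding volume (explicit boxes if
    both clouds carry one, else the axis-aligned box of the union
    cloud).  Shells where the reference vanishes have no defined C.
    """
    box = _union_box(a, b)
    volume = float(np.prod(box[:, 1] - box[:, 0]))
    counts = shell_pair_counts(a, b, dr_nm, r_max_nm, exclude_self=exclude_self)
    c0 = pair_correlation_c0(counts, len(a), len(b), volume, dr_nm)

    ref = np.zeros_like(c0)
    for k in range(n_reference_draws):
        rng = child_rng(seed, f"paircorr/ref{k}")
        ua = LocalizationCloud(
            points=rng.uniform(box[:, 0], box[:, 1], size=(len(a), 3)),
            channel="ref_a",
            bounding_box=box,
        )
        ub = LocalizationCloud(
            points=rng.uniform(box[:, 0], box[:, 1], size=(len(b), 3)),
            channel="ref_b",
            bounding_box=box,
        )
        rc = shell_pair_counts(ua, ub, dr_nm, r_max_nm, exclude_self=False)
        ref += pair_correlation_c0(rc, len(a), len(b), volume, dr_nm)
    ref /= n_reference_draws

    with np.errstate(divide="ignore", invalid="ignore"):
        c_norm = np.where(ref > 0, c0 / ref, np.nan)
    return PairCorrelationCurve(
        r_nm=np.arange(len(counts)) * dr_nm,
        c0=c0,
        c_ref=ref,
        c_norm=c_norm,
        n_pairs=counts,
        dr_nm=dr_nm,
    )
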