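"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline has a matching generator here:
ACD landscapes for the caller, correlated negative-binomial RNA counts
and Poisson ATAC counts for the coexpression / coaccessibility
statistics, distance-decaying Hi-C contact matrices, two-territory
burst geometries and multi-round readout spots for the FISH decoder,
uniform and Thomas-clustered point clouds for the pair correlation, and
reflected Brownian tracks for the confined-diffusion fit.

The central construction is a per-cell latent activity vector over
ACDs, zero mean and unit variance, with

    corr(a_i, a_j) = rho0 * exp(-d_ij / lambda)   (same chromosome)
    corr(a_i, a_j) = rho_trans                    (different chromosomes)

realized as a multivariate Gaussian (nearest-PSD jitter <= 1e-8 when
needed).  A "cohesin-depleted" condition is emulated simply by raising
rho0, mirroring increased cross-domain cofluctuation; counts are
negative binomial (RNA) or Poisson (ATAC) around ``mean * exp(a)``.
These are fixtures with the statistical structure the analysis assumes,
not claims about the real data-generating process.

All generators are deterministic given their seed and record the
parameters actually used in a :class:`SimTruth` sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    BinnedSignal,
    CountMatrix,
    GenomicInterval,
    LocalizationCloud,
    Track,
    TrackSet,
    child_rng,
)

__all__ = [
    "SimTruth",
    "gen_acd_landscape",
    "gen_expression_counts",
    "gen_accessibility_counts",
    "gen_hic_matrix",
    "gen_burst_cells",
    "gen_readout_spots",
    "gen_point_cloud",
    "gen_confined_tracks",
    "synthetic_acd_table",
]


@dataclass
class SimTruth:
    """Ground-truth parameters actually used by a generator run."""

    seed: int
    acd_layout: list[tuple[str, int, int]] | None = None
    coupling_cis: float | None = None
    decay_length_bp: float | None = None
    coupling_trans: float | None = None
    co_burst_excess: float | None = None
    roc_true_nm: float | None = None
    diffusion_true_um2s: float | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# ACD landscape


def gen_acd_landscape(
    n_chrom: int = 1,
    chrom_len_bp: int = 10_000_000,
    n_acds_per_chrom: int = 2,
    bin_size: int = 200_000,
    peak_height: float = 10.0,
    background: float = 1.0,
    seed: int = 0,
) -> tuple[list[GenomicInterval], dict[str, BinnedSignal]]:
    """Plant contiguous elevated runs (ACDs) in background ATAC signal.

    Each planted domain is 3-12 bins wide (0.6-2.4 Mb at 200-kb bins,
    the reported ACD size scale) with a raised-cosine profile on top of
    the background so that each domain contains exactly one prominent
    local maximum.  Domains are separated by at least one background
    bin.  Raises when the requested layout cannot fit.
    """
    n_bins = chrom_len_bp // bin_size
    if n_acds_per_chrom * 3 > n_bins:
        raise ValueError("overcrowded layout: n_acds * 3 bins exceeds chromosome")
    rng = child_rng(seed, "acd_landscape")
    acds: list[GenomicInterval] = []
    signals: dict[str, BinnedSignal] = {}
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        widths = rng.integers(3, 13, size=n_acds_per_chrom)
        # shrink until domains + single-bin gaps fit
        while widths.sum() + (n_acds_per_chrom + 1) > n_bins and widths.max() > 3:
            widths[np.argmax(widths)] -= 1
        if widths.sum() + (n_acds_per_chrom + 1) > n_bins:
            raise ValueError("overcrowded layout: cannot place domains with gaps")
        slack = n_bins - int(widths.sum()) - (n_acds_per_chrom + 1)
        extra = rng.multinomial(slack, np.ones(n_acds_per_chrom + 1) / (n_acds_per_chrom + 1))
        values = background * (1.0 + 0.05 * rng.standard_normal(n_bins))
        np.clip(values, 0.0, None, out=values)
        cursor = 0
        for k, w in enumerate(widths):
            cursor += 1 + int(extra[k])  # gap before the domain
            profile = 0.7 + 0.3 * np.cos(
                np.pi * (np.arange(w) - (w - 1) / 2) / max(w / 2.0, 1.0)
            )
            values[cursor: cursor + w] = background + peak_height * profile
            acds.append(
                GenomicInterval(
                    chrom=chrom,
                    start=cursor * bin_size,
                    end=(cursor + int(w)) * bin_size,
                    id=f"true_{chrom}_{k}",
                )
            )
            cursor += int(w)
        signals[chrom] = BinnedSignal(chrom=chrom, bin_size=bin_size, values=values)
    return acds, signals


# ---------------------------------------------------------------------------
# Latent ACD activity covariance


def _acd_covariance(
    acds: list[GenomicInterval],
    coupling_cis: float,
    decay_length_bp: float,
    coupling_trans: float,
) -> np.ndarray:
    n = len(acds)
    cov = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                cov[i, j] = 1.0
            elif acds[i].chrom == acds[j].chrom:
                d = abs(acds[i].midpoint - acds[j].midpoint)
                cov[i, j] = coupling_cis * np.exp(-d / decay_length_bp)
            else:
                cov[i, j] = coupling_trans
    return cov


def _cholesky_psd(cov: np.ndarray, jitter: float = 1e-8) -> np.ndarray:
    """Cholesky factor, allowing a documented diagonal jitter <= 1e-8."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        pass
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin < -jitter:
        raise ValueError(
            f"activity covariance is not positive semi-definite "
            f"(min eigenvalue {eigmin:.3g}); check coupling parameters"
        )
    return np.linalg.cholesky(cov + (jitter - min(eigmin, 0.0)) * np.eye(len(cov)))


def _latent_activities(
    acds: list[GenomicInterval],
    n_cells: int,
    coupling_cis: float,
    decay_length_bp: float,
    coupling_trans: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """cells x ACDs latent activity draws, zero mean, unit variance."""
    if not 0 <= coupling_cis < 1:
        raise ValueError("coupling_cis must lie in [0, 1)")
    if not 0 <= coupling_trans < 1:
        raise ValueError("coupling_trans must lie in [0, 1)")
    cov = _acd_covariance(acds, coupling_cis, decay_length_bp, coupling_trans)
    chol = _cholesky_psd(cov)
    z = rng.standard_normal((n_cells, len(acds)))
    return z @ chol.T


def _acd_features(
    acds: list[GenomicInterval], genes_per_acd: int
) -> pd.DataFrame:
    """Gene feature table: genes spread evenly inside their ACD."""
    ids, chroms, starts, ends = [], [], [], []
    for iv in acds:
        step = iv.length // (genes_per_acd + 1)
        for g in range(genes_per_acd):
            pos = iv.start + (g + 1) * step
            ids.append(f"{iv.id}_g{g}")
            chroms.append(iv.chrom)
            starts.append(int(pos))
            ends.append(int(pos) + 1_000)
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends}, index=pd.Index(ids)
    )


def gen_expression_counts(
    acds: list[GenomicInterval],
    genes_per_acd: int = 3,
    n_cells: int = 300,
    baseline_mean: float = 20.0,
    nb_dispersion: float = 5.0,
    coupling_cis: float = 0.0,
    decay_length_bp: float = 20_000_000.0,
    coupling_trans: float = 0.0,
    seed: int = 0,
    condition_label: str = "",
) -> tuple[CountMatrix, SimTruth]:
    """Correlated negative-binomial RNA counts over ACD-resident genes.

    Gene counts in cell c are NB with mean
    ``baseline_mean * exp(a_ACD(g),c - 1/2)`` (the -1/2 keeps the
    expected mean at ``baseline_mean``) and Gamma shape
    ``nb_dispersion``; all genes of an ACD share its latent activity, so
    cross-ACD gene correlations inherit the coupling structure.
    """
    rng = child_rng(seed, f"expression/{condition_label}")
    a = _latent_activities(
        acds, n_cells, coupling_cis, decay_length_bp, coupling_trans, rng
    )
    features = _acd_features(acds, genes_per_acd)
    acd_of_gene = np.repeat(np.arange(len(acds)), genes_per_acd)
    mu = baseline_mean * np.exp(a[:, acd_of_gene] - 0.5)
    lam = rng.gamma(shape=nb_dispersion, scale=mu / nb_dispersion)
    counts = rng.poisson(lam)
    cm = CountMatrix(
        cells=[f"cell{i}" for i in range(n_cells)],
        features=features,
        counts=counts,
        condition_label=condition_label,
    )
    truth = SimTruth(
        seed=seed,
        acd_layout=[(iv.chrom, iv.start, iv.end) for iv in acds],
        coupling_cis=coupling_cis,
        decay_length_bp=decay_length_bp,
        coupling_trans=coupling_trans,
        extra={
            "genes_per_acd": genes_per_acd,
            "n_cells": n_cells,
            "baseline_mean": baseline_mean,
            "nb_dispersion": nb_dispersion,
        },
    )
    return cm, truth


def gen_accessibility_counts(
    acds: list[GenomicInterval],
    n_cells: int = 2_000,
    mean_reads_per_acd: float = 20.0,
    coupling_cis: float = 0.0,
    decay_length_bp: float = 20_000_000.0,
    coupling_trans: float = 0.0,
    low_depth_fraction: float = 0.2,
    low_depth_factor: float = 0.1,
    activity_scale: float = 0.5,
    seed: int = 0,
    condition_label: str = "",
) -> tuple[CountMatrix, SimTruth]:
    """Poisson per-ACD accessibility counts with the same coupling
    structure as the RNA generator.

    ``activity_scale`` damps the latent log-activity (accessibility per
    domain fluctuates less than transcriptional bursting), keeping cell
    totals tight enough that the downstream poorly-sequenced-cell filter
    separates depth classes.  A ``low_depth_fraction`` of cells receives
    ``low_depth_factor`` (10-fold lower by default) sequencing depth,
    exercising that filter.
    """
    rng = child_rng(seed, f"accessibility/{condition_label}")
    a = _latent_activities(
        acds, n_cells, coupling_cis, decay_length_bp, coupling_trans, rng
    )
    depth = np.ones(n_cells)
    n_low = int(round(low_depth_fraction * n_cells))
    if n_low:
        low_idx = rng.choice(n_cells, size=n_low, replace=False)
        depth[low_idx] = low_depth_factor
    s = activity_scale
    mu = mean_reads_per_acd * np.exp(s * a - s**2 / 2.0) * depth[:, None]
    counts = rng.poisson(mu)
    features = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in acds],
            "start": [iv.start for iv in acds],
            "end": [iv.end for iv in acds],
        },
        index=pd.Index([iv.id for iv in acds]),
    )
    cm = CountMatrix(
        cells=[f"cell{i}" for i in range(n_cells)],
        features=features,
        counts=counts,
        condition_label=condition_label,
    )
    truth = SimTruth(
        seed=seed,
        acd_layout=[(iv.chrom, iv.start, iv.end) for iv in acds],
        coupling_cis=coupling_cis,
        decay_length_bp=decay_length_bp,
        coupling_trans=coupling_trans,
        extra={
            "n_cells": n_cells,
            "mean_reads_per_acd": mean_reads_per_acd,
            "low_depth_fraction": low_depth_fraction,
            "low_depth_factor": low_depth_factor,
            "activity_scale": activity_scale,
        },
    )
    return cm, truth


def gen_hic_matrix(
    acds: list[GenomicInterval],
    bin_size: int = 200_000,
    decay_exponent: float = 1.0,
    acd_boost: float = 1.0,
    mean_scale: float = 100.0,
    seed: int = 0,
) -> np.ndarray:
    """Symmetric single-chromosome contact matrix with power-law decay.

    Expected contact between bins i, j is
    ``mean_scale * (1 + |i - j|)^(-decay_exponent)``, multiplied by
    ``acd_boost`` when both bins lie inside planted ACDs; Poisson noise
    is added and the matrix symmetrized.
    """
    chroms = {iv.chrom for iv in acds}
    if len(chroms) != 1:
        raise ValueError("Hi-C fixture covers a single chromosome")
    rng = child_rng(seed, "hic")
    n_bins = int(np.ceil(max(iv.end for iv in acds) / bin_size)) + 2
    in_acd = np.zeros(n_bins, dtype=bool)
    for iv in acds:
        in_acd[iv.start // bin_size: (iv.end - 1) // bin_size + 1] = True
    i, j = np.meshgrid(np.arange(n_bins), np.arange(n_bins), indexing="ij")
    mu = mean_scale * (1.0 + np.abs(i - j)) ** (-decay_exponent)
    mu[np.outer(in_acd, in_acd)] *= acd_boost
    upper = rng.poisson(np.triu(mu))
    return np.triu(upper, 1) + np.triu(upper, 1).T + np.diag(np.diag(upper))


# ---------------------------------------------------------------------------
# FISH fixtures


def _uniform_in_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.uniform(size=n) ** (1 / 3)
    return v * r[:, None]


def gen_burst_cells(
    gene_pairs: list[tuple[str, str]],
    freqs: dict[str, float],
    co_burst_excess: float = 1.0,
    n_cells: int = 300,
    territory_radius_um: float = 1.0,
    territory_separation_um: float = 4.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Two-territory burst geometry with tunable co-bursting excess psi.

    ``freqs`` are cell-level bursting frequencies (sites per cell,
    the N_b/N scale); each of the two chromosome territories bursts a gene
    with probability F/2, and for each listed pair the per-territory
    joint probability is ``F_A * F_B * psi / 2``, so the downstream
    normalized co-bursting frequency recovers psi (psi = 1 is
    independence).  Joint bursts place the partner gene within 0.8 *
    territory_radius of the first gene, keeping true same-chromosome
    co-bursts inside the 1-um gate; independent bursts are uniform in
    the territory sphere.  Feasibility requires
    ``F_A * F_B * psi <= min(F_A, F_B)``.
    """
    psi = co_burst_excess
    if psi < 0:
        raise ValueError("co_burst_excess must be >= 0")
    for a, b in gene_pairs:
        if freqs[a] * freqs[b] * psi > min(freqs[a], freqs[b]) + 1e-12:
            raise ValueError(
                f"infeasible joint probability for pair ({a}, {b}): "
                "need F_A * F_B * psi <= min(F_A, F_B)"
            )
    rng = child_rng(seed, "burst_cells")
    centers = np.array(
        [[0.0, 0.0, 0.0], [territory_separation_um, 0.0, 0.0]]
    )
    rows = []
    pair_genes = {g for pair in gene_pairs for g in pair}
    lone_genes = sorted(set(freqs) - pair_genes)  # burst independently
    offset_radius = 0.8 * territory_radius_um
    for ci in range(n_cells):
        cell = f"cell{ci}"
        for t in range(2):
            placed: dict[str, np.ndarray] = {}
            # pairs first: joint / single / neither per pair
            for a, b in gene_pairs:
                fa, fb = freqs[a] / 2.0, freqs[b] / 2.0
                p11 = freqs[a] * freqs[b] * psi / 2.0
                p10, p01 = fa - p11, fb - p11
                u = rng.uniform()
                if u < p11:
                    pa = centers[t] + _uniform_in_sphere(rng, 1, territory_radius_um)[0]
                    off = _uniform_in_sphere(rng, 1, offset_radius)[0]
                    placed[a], placed[b] = pa, pa + off
                elif u < p11 + p10:
                    placed[a] = (
                        centers[t]
                        + _uniform_in_sphere(rng, 1, territory_radius_um)[0]
                    )
                elif u < p11 + p10 + p01:
                    placed[b] = (
                        centers[t]
                        + _uniform_in_sphere(rng, 1, territory_radius_um)[0]
                    )
            for g in lone_genes:
                if rng.uniform() < freqs[g] / 2.0:
                    placed[g] = (
                        centers[t]
                        + _uniform_in_sphere(rng, 1, territory_radius_um)[0]
                    )
            for g, pos in placed.items():
                rows.append((cell, g, *(pos * 1_000.0)))  # um -> nm
    bursts = pd.DataFrame(
        rows, columns=["cell_id", "gene", "x_nm", "y_nm", "z_nm"]
    )
    truth = SimTruth(
        seed=seed,
        co_burst_excess=psi,
        extra={
            "freqs": dict(freqs),
            "n_cells": n_cells,
            "territory_radius_um": territory_radius_um,
            "territory_separation_um": territory_separation_um,
        },
    )
    return bursts, truth


def gen_readout_spots(
    bursts: pd.DataFrame,
    codebook,
    px_nm: float = 100.0,
    dropout_rate: float = 0.0,
    loc_noise_px: float = 0.0,
    force_single_dropout: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit per-round readout spots for each true burst.

    Each burst produces one spot per readout round carrying the
    codebook pseudocolor, with Gaussian position jitter
    (``loc_noise_px`` per axis) and independent per-round dropout.
    ``force_single_dropout`` drops exactly one randomly chosen round per
    burst instead (for dropout-robustness fixtures).
    """
    rng = child_rng(seed, "readout_spots")
    n_rounds = codebook.n_rounds
    rows = []
    for _, b in bursts.iterrows():
        barcode = codebook.barcodes[b["gene"]]
        pos_px = np.array([b["x_nm"], b["y_nm"], b["z_nm"]]) / px_nm
        if force_single_dropout:
            dropped = {int(rng.integers(n_rounds))}
        else:
            dropped = {
                r for r in range(n_rounds) if rng.uniform() < dropout_rate
            }
        for r in range(n_rounds):
            if r in dropped:
                continue
            jitter = loc_noise_px * rng.standard_normal(3)
            p = pos_px + jitter
            rows.append(
                (b["cell_id"], r, barcode[r], p[0], p[1], p[2])
            )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "round", "pseudocolor", "x_px", "y_px", "z_px"],
    )


# ---------------------------------------------------------------------------
# Point clouds and tracks


def gen_point_cloud(
    process: str = "uniform",
    box_nm: tuple[float, float, float] = (5_000.0, 5_000.0, 5_000.0),
    n_parents: int = 50,
    cluster_sigma_nm: float = 100.0,
    m: int = 2_000,
    n: int = 2_000,
    seed: int = 0,
) -> tuple[LocalizationCloud, LocalizationCloud]:
    """Two-channel 3D point clouds: CSR or shared-parent Thomas process.

    ``uniform`` draws both channels independently homogeneous in the
    box; ``thomas`` draws parent centres uniformly and scatters both
    channels' points as Gaussian offspring around shared parents, so
    the channels are cross-correlated at scales up to ~2 sigma.
    """
    rng = child_rng(seed, "point_cloud")
    box = np.asarray(box_nm, dtype=float)
    bbox = np.stack([np.zeros(3), box], axis=1)
    if process == "uniform":
        pa = rng.uniform(0, box, size=(m, 3))
        pb = rng.uniform(0, box, size=(n, 3))
    elif process == "thomas":
        parents = rng.uniform(0, box, size=(n_parents, 3))
        pa = (
            parents[rng.integers(n_parents, size=m)]
            + cluster_sigma_nm * rng.standard_normal((m, 3))
        )
        pb = (
            parents[rng.integers(n_parents, size=n)]
            + cluster_sigma_nm * rng.standard_normal((n, 3))
        )
    else:
        raise ValueError(f"unknown process {process!r}")
    return (
        LocalizationCloud(points=pa, channel="A", bounding_box=bbox),
        LocalizationCloud(points=pb, channel="B", bounding_box=bbox),
    )


def gen_confined_tracks(
    roc_true_nm: float = 200.0,
    d_um2s: float = 0.05,
    loc_error_nm: float = 30.0,
    dt_s: float = 0.05,
    n_tracks: int = 500,
    len_frames: int = 100,
    seed: int = 0,
) -> tuple[TrackSet, SimTruth]:
    """2D Brownian tracks reflected at a circle, plus localization noise.

    Increments have per-axis std sqrt(2 * D * dt); positions leaving the
    confinement circle of radius ``roc_true_nm`` are reflected radially.
    ``loc_error_nm`` is the radial (2D rms) localization uncertainty, so
    a static emitter has MSD offset 2 * loc_error^2 (per-axis noise std
    is loc_error / sqrt(2)).
    """
    rng = child_rng(seed, "confined_tracks")
    r_um = roc_true_nm / 1_000.0
    step = np.sqrt(2.0 * d_um2s * dt_s)
    noise_axis = loc_error_nm / 1_000.0 / np.sqrt(2.0)
    tracks = []
    for k in range(n_tracks):
        # uniform start in the disc
        theta = rng.uniform(0, 2 * np.pi)
        rad = r_um * np.sqrt(rng.uniform())
        p = np.array([rad * np.cos(theta), rad * np.sin(theta)])
        xy = np.empty((len_frames, 2))
        for f in range(len_frames):
            xy[f] = p
            p = p + step * rng.standard_normal(2)
            norm = np.linalg.norm(p)
            while norm > r_um:
                p = p * (2 * r_um - norm) / norm
                norm = np.linalg.norm(p)
        xy += noise_axis * rng.standard_normal((len_frames, 2))
        tracks.append(
            Track(
                track_id=f"track{k}",
                frames=np.arange(len_frames),
                xy=xy,
                dt=dt_s,
            )
        )
    truth = SimTruth(
        seed=seed,
        roc_true_nm=roc_true_nm,
        diffusion_true_um2s=d_um2s,
        extra={
            "loc_error_nm": loc_error_nm,
            "dt_s": dt_s,
            "n_tracks": n_tracks,
            "len_frames": len_frames,
        },
    )
    return TrackSet(tracks=tracks, dt=dt_s), truth


# ---------------------------------------------------------------------------
# Synthetic reference table


_MM10_CHROM_MB = {
    "chr1": 195, "chr2": 182, "chr3": 160, "chr4": 156, "chr5": 151,
    "chr6": 149, "chr7": 145, "chr8": 129, "chr9": 124, "chr10": 130,
    "chr11": 122, "chr12": 120, "chr13": 120, "chr14": 124, "chr15": 104,
    "chr16": 98, "chr17": 94, "chr18": 90, "chr19": 61, "chrX": 171,
}


def synthetic_acd_table(n_acds: int = 776, seed: int = 0) -> list[GenomicInterval]:
    """SYNTHETIC stand-in for a genome-wide ACD coordinate table.

    Generates ``n_acds`` non-overlapping intervals across the mouse
    (mm10-named) chromosomes with sizes drawn uniformly on the reported
    ~0.5-2.5 Mb ACD scale, allocated to chromosomes proportionally to
    length.  This is a synthetic fixture for exercising the interval
    parser and per-ACD aggregation at realistic scale; it is not derived
    from any real dataset.
    """
    rng = child_rng(seed, "synthetic_acd_table")
    chroms = list(_MM10_CHROM_MB)
    lengths = np.array([_MM10_CHROM_MB[c] for c in chroms], dtype=float)
    alloc = np.floor(n_acds * lengths / lengths.sum()).astype(int)
    while alloc.sum() < n_acds:
        alloc[int(rng.integers(len(chroms)))] += 1
    intervals = []
    for chrom, k in zip(chroms, alloc):
        size_bp = _MM10_CHROM_MB[chrom] * 1_000_000
        sizes = rng.uniform(500_000, 2_500_000, size=k)
        gap = (size_bp - sizes.sum()) / (k + 1)
        if gap <= 0:
            raise ValueError(f"cannot fit {k} domains on {chrom}")
        cursor = 0.0
        for s in sizes:
            cursor += gap
            start = int(cursor)
            intervals.append(
                GenomicInterval(
                    chrom=chrom,
                    start=start,
                    end=start + int(s),
                    id=f"ACD_{chrom}_{start}",
                )
            )
            cursor += s
    return intervals
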