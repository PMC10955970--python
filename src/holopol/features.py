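"""Particle segmentation and per-ROI feature extraction.

Feature groups follow the C1..C8 tagging used throughout the package:

* C1 — NGTDM texture (Coarseness, Contrast, Busyness, Complexity,
  Strength), Amadasun–King definitions with neighbors clipped at the
  ROI mask boundary;
* C2 — Fourier power spectrum: radial-annulus and angular-sector sums of
  the non-DC power, each set normalized to total 1;
* C3 — GLSZM (gray-level size-zone matrix) statistics with 8-connected
  zones;
* C8 — holographic: percentile-robust Michelson fringe contrast over the
  background annulus and in-mask/annulus transparency ratio;
* C4..C7 (DoLP, AoP, retardance, axis orientation summaries) come from
  :mod:`holopol.polarimetry` and are merged in :func:`extract_all`.

All texture features operate on the total-intensity (S0) hologram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy.ndimage import (
    binary_closing,
    binary_dilation,
    binary_fill_holes,
    binary_opening,
    convolve,
    gaussian_filter,
)
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

from holopol.io_core import FeatureSettings, FeatureTable
from holopol.polarimetry import (
    POLARIZATION_FEATURES,
    PolarizationFrame,
    PolarizationMaps,
    StokesMaps,
    polarization_feature_summary,
)

logger = logging.getLogger("holopol.features")

_EPS = 1e-12
_COARSENESS_CAP = 1e6

NGTDM_NAMES = ("ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
               "ngtdm_complexity", "ngtdm_strength")
GLSZM_NAMES = ("glszm_sze", "glszm_lze", "glszm_zsn", "glszm_zse",
               "glszm_lzhge", "glszm_gln")
HOLO_NAMES = ("fringe_contrast", "transparency")


def feature_registry(settings: FeatureSettings | None = None) -> dict[str, str]:
    """Frozen feature-name -> group-tag mapping for one settings object."""
    settings = settings or FeatureSettings()
    reg: dict[str, str] = {name: "C1" for name in NGTDM_NAMES}
    for i in range(settings.radial_bins):
        reg[f"fps_radial_{i + 1}"] = "C2"
    for i in range(settings.angular_bins):
        reg[f"fps_angular_{i + 1}"] = "C2"
    reg.update({name: "C3" for name in GLSZM_NAMES})
    for tag, names in POLARIZATION_FEATURES.items():
        reg.update({name: tag for name in names})
    reg.update({name: "C8" for name in HOLO_NAMES})
    return reg


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


@dataclass
class ROI:
    particle_id: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]  # (rmin, cmin, rmax, cmax), half-open
    annulus: np.ndarray


@dataclass
class ROISet:
    rois: list[ROI]
    frame_id: str = ""

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)


def segment_particles(S0: np.ndarray, settings: FeatureSettings | None = None,
                      detect_sigma: float = 3.0) -> ROISet:
    """Segment particles from the total-intensity hologram.

    Two stages.  Detection: the absolute deviation from the grid-median
    background is low-pass filtered (``detect_sigma`` px Gaussian, which
    averages out the zero-mean holographic fringes around each particle)
    and Otsu-thresholded; 3x3 opening/closing and 8-connected labeling
    yield candidate regions.  Refinement: inside each candidate the
    unsmoothed deviation is Otsu-thresholded again to recover the
    particle body without the fringe halo, then cleaned and hole-filled.
    Components below the minimum area are dropped; each ROI gets a
    background annulus (dilation ring) excluding every particle mask.
    """
    settings = settings or FeatureSettings()
    S0 = np.asarray(S0, dtype=np.float64)
    dev = np.abs(S0 - np.median(S0))
    if np.ptp(dev) <= 0:
        return ROISet([])
    smooth = gaussian_filter(dev, detect_sigma) if detect_sigma > 0 else dev
    thr = threshold_otsu(smooth)
    binary = smooth > thr
    foot = np.ones((3, 3), dtype=bool)
    binary = binary_closing(binary_opening(binary, foot), foot)
    labels = cc_label(binary, connectivity=2)
    all_masks = np.zeros_like(binary)
    keep: list[np.ndarray] = []
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        if region.sum() < settings.min_area:
            continue
        vals = dev[region]
        if np.ptp(vals) > 0:
            core = region & (dev > threshold_otsu(vals))
            core = binary_fill_holes(binary_closing(binary_opening(core, foot), foot))
        else:
            core = region
        mask = core if core.sum() >= settings.min_area else region
        keep.append(mask)
        all_masks |= mask
    rois = []
    ring_foot = disk(settings.annulus_width)
    for pid, mask in enumerate(keep):
        annulus = binary_dilation(mask, ring_foot) & ~all_masks
        rr, cc = np.nonzero(mask)
        bbox = (int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1)
        rois.append(ROI(pid, mask, bbox, annulus))
    logger.info("segmented %d particle ROI(s)", len(rois))
    return ROISet(rois)


# ---------------------------------------------------------------------------
# gray-level quantization
# ---------------------------------------------------------------------------


@dataclass
class QuantizedROI:
    """Integer levels 1..Ng inside the mask; 0 marks out-of-mask pixels."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    edges: np.ndarray


def quantize(grid: np.ndarray, mask: np.ndarray, n_levels: int = 32) -> QuantizedROI:
    """Equal-width quantization of in-mask values into levels 1..Ng.

    A constant ROI maps wholly to level 1.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(grid, dtype=np.float64)[mask]
    lo, hi = float(vals.min()), float(vals.max())
    edges = np.linspace(lo, hi, n_levels + 1)
    if hi <= lo:
        levels_in = np.ones(vals.shape, dtype=np.int32)
    else:
        levels_in = np.minimum(
            np.floor((vals - lo) / (hi - lo) * n_levels).astype(np.int32) + 1, n_levels
        )
    levels = np.zeros(mask.shape, dtype=np.int32)
    levels[mask] = levels_in
    return QuantizedROI(levels=levels, mask=mask, n_levels=n_levels, edges=edges)


# ---------------------------------------------------------------------------
# NGTDM (group C1)
# ---------------------------------------------------------------------------


def ngtdm_matrix(qroi: QuantizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """NGTDM ingredients: per-level counts n_i, sums s_i, valid-pixel total N.

    For each in-mask pixel with at least one in-mask neighbor (3x3
    neighborhood, center excluded, neighbors restricted to the mask) the
    absolute difference between the pixel level and its neighborhood mean
    accumulates into s at the pixel's level.
    """
    mask = qroi.mask
    lv = qroi.levels.astype(np.float64)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nbr_sum = convolve(lv * mask, kernel, mode="constant", cval=0.0)
    nbr_cnt = convolve(mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = mask & (nbr_cnt > 0.5)
    Ng = qroi.n_levels
    n = np.zeros(Ng + 1)
    s = np.zeros(Ng + 1)
    if valid.any():
        levels = qroi.levels[valid]
        diffs = np.abs(levels - nbr_sum[valid] / nbr_cnt[valid])
        n = np.bincount(levels, minlength=Ng + 1).astype(np.float64)
        n[0] = 0.0
        s = np.bincount(levels, weights=diffs, minlength=Ng + 1)
        s[0] = 0.0
    return n[1:], s[1:], int(valid.sum())


def ngtdm_features(qroi: QuantizedROI) -> dict[str, float]:
    """Amadasun–King NGTDM scalars: Coarseness, Contrast, Busyness,
    Complexity, Strength.

    Zero denominators are guarded by 1e-12; Coarseness is capped at 1e6
    for flat ROIs.  A mask too small to form any neighborhood yields NaN.
    """
    n, s, N = ngtdm_matrix(qroi)
    if N == 0:
        return {name: np.nan for name in NGTDM_NAMES}
    p = n / N
    i = np.arange(1, qroi.n_levels + 1, dtype=np.float64)
    present = p > 0
    Ngp = int(present.sum())
    ps = p * s

    coarseness = min(1.0 / (float(ps.sum()) + _EPS), _COARSENESS_CAP)

    if Ngp <= 1:
        contrast = 0.0
    else:
        pi = p[present]
        ii = i[present]
        pair = np.sum(pi[:, None] * pi[None, :] * (ii[:, None] - ii[None, :]) ** 2)
        contrast = pair / (Ngp * (Ngp - 1)) * (float(s.sum()) / N)

    ipi = i * p
    if Ngp <= 1:
        busyness = 0.0
    else:
        denom = np.sum(np.abs(ipi[present][:, None] - ipi[present][None, :]))
        busyness = float(ps.sum()) / (denom + _EPS)

    pi = p[present]
    ii = i[present]
    psi = ps[present]
    dif = np.abs(ii[:, None] - ii[None, :])
    complexity = float(np.sum(dif * (psi[:, None] + psi[None, :]) / (pi[:, None] + pi[None, :]))) / N

    strength = float(np.sum((pi[:, None] + pi[None, :]) * (ii[:, None] - ii[None, :]) ** 2)) / (
        float(s.sum()) + _EPS
    )
    return dict(zip(NGTDM_NAMES, (coarseness, contrast, busyness, complexity, strength)))


# ---------------------------------------------------------------------------
# GLSZM (group C3)
# ---------------------------------------------------------------------------


def glszm_matrix(qroi: QuantizedROI) -> np.ndarray:
    """Zone-count matrix P[g, s]: 8-connected zones of level g+1, size s+1."""
    sizes_per_level: list[np.ndarray] = []
    max_size = 1
    for g in range(1, qroi.n_levels + 1):
        zones = cc_label((qroi.levels == g) & qroi.mask, connectivity=2)
        if zones.max() == 0:
            sizes_per_level.append(np.zeros(0, dtype=np.int64))
            continue
        sizes = np.bincount(zones.ravel())[1:]
        sizes_per_level.append(sizes)
        max_size = max(max_size, int(sizes.max()))
    P = np.zeros((qroi.n_levels, max_size))
    for g, sizes in enumerate(sizes_per_level):
        for sz in sizes:
            P[g, sz - 1] += 1
    return P


def glszm_features(qroi: QuantizedROI) -> dict[str, float]:
    """Standard GLSZM scalars normalized by the total zone count Nz."""
    P = glszm_matrix(qroi)
    Nz = float(P.sum())
    if Nz == 0:
        return {name: np.nan for name in GLSZM_NAMES}
    g = np.arange(1, P.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, P.shape[1] + 1, dtype=np.float64)[None, :]
    p = P / Nz
    sze = float(np.sum(P / s**2)) / Nz
    lze = float(np.sum(P * s**2)) / Nz
    zsn = float(np.sum(P.sum(axis=0) ** 2)) / Nz
    nz = p[p > 0]
    zse = float(-np.sum(nz * np.log2(nz)))
    lzhge = float(np.sum(P * s**2 * g**2)) / Nz
    gln = float(np.sum(P.sum(axis=1) ** 2)) / Nz
    return dict(zip(GLSZM_NAMES, (sze, lze, zsn, zse, lzhge, gln)))


# ---------------------------------------------------------------------------
# Fourier power spectrum (group C2)
# ---------------------------------------------------------------------------


def fps_features(
    grid: np.ndarray,
    mask: np.ndarray,
    n_radial: int = 8,
    n_angular: int = 8,
) -> dict[str, float]:
    """Radial and angular sums of the ROI's Fourier power spectrum.

    The masked ROI is cropped to its bounding box, zero-padded to a
    square power of two, and transformed; DC is excluded and both the
    radial-annulus and angular-sector profiles are restricted to the
    inscribed Nyquist disc (|f| <= 0.5 cycles/px, where every angular
    sector subtends equal spectral area) and normalized by the total
    non-DC in-disc power, so each profile sums to 1.  Angular sectors
    cover the half-plane [0, pi) — the spectrum of a real image is
    point-symmetric.
    """
    mask = np.asarray(mask, dtype=bool)
    rr, cc = np.nonzero(mask)
    if rr.size <= 1:
        raise ValueError("degenerate ROI: need at least 2 pixels")
    crop = np.where(mask, np.asarray(grid, dtype=np.float64), 0.0)[
        rr.min(): rr.max() + 1, cc.min(): cc.max() + 1
    ]
    side = 1 << int(np.ceil(np.log2(max(crop.shape))))
    padded = np.zeros((side, side))
    padded[: crop.shape[0], : crop.shape[1]] = crop
    power = np.abs(sfft.fftshift(sfft.fft2(padded))) ** 2
    f = sfft.fftshift(sfft.fftfreq(side))
    FX, FY = np.meshgrid(f, f)
    radius = np.hypot(FX, FY)
    dc = (np.abs(FX) < 1e-12) & (np.abs(FY) < 1e-12)
    sel = ~dc & (radius <= 0.5)
    total = float(power[sel].sum())
    names_r = [f"fps_radial_{i + 1}" for i in range(n_radial)]
    names_a = [f"fps_angular_{i + 1}" for i in range(n_angular)]
    if total <= 0:
        return {name: np.nan for name in names_r + names_a}
    rbin = np.minimum((radius / 0.5 * n_radial).astype(int), n_radial - 1)
    angle = np.arctan2(FY, FX) % np.pi
    abin = np.minimum((angle / np.pi * n_angular).astype(int), n_angular - 1)
    out: dict[str, float] = {}
    rsum = np.bincount(rbin[sel], weights=power[sel], minlength=n_radial) / total
    asum = np.bincount(abin[sel], weights=power[sel], minlength=n_angular) / total
    out.update(zip(names_r, rsum))
    out.update(zip(names_a, asum))
    return out


# ---------------------------------------------------------------------------
# holographic features (group C8)
# ---------------------------------------------------------------------------


def fringe_contrast(S0: np.ndarray, roi: ROI) -> float:
    """Percentile-robust Michelson contrast (P98-P2)/(P98+P2) over the annulus."""
    vals = np.asarray(S0, dtype=np.float64)[roi.annulus]
    if vals.size == 0:
        raise ValueError("empty annulus")
    p2, p98 = np.percentile(vals, [2, 98])
    if p98 + p2 <= 0:
        return 0.0
    return float(np.clip((p98 - p2) / (p98 + p2), 0.0, 1.0))


def transparency(S0: np.ndarray, roi: ROI) -> float:
    """Mean in-mask intensity over mean annulus intensity, clipped to [0, 1.5]."""
    S0 = np.asarray(S0, dtype=np.float64)
    if not roi.annulus.any():
        raise ValueError("empty annulus")
    bg = float(S0[roi.annulus].mean())
    if bg <= 0:
        return np.nan
    return float(np.clip(S0[roi.mask].mean() / bg, 0.0, 1.5))


# ---------------------------------------------------------------------------
# combined extraction
# ---------------------------------------------------------------------------


def extract_roi_features(
    S0: np.ndarray,
    maps: PolarizationMaps,
    roi: ROI,
    settings: FeatureSettings | None = None,
) -> dict[str, float]:
    """All C1..C8 scalars for one ROI; failed features come back NaN."""
    settings = settings or FeatureSettings()
    out: dict[str, float] = {}
    try:
        qroi = quantize(S0, roi.mask, settings.gray_levels)
        out.update(ngtdm_features(qroi))
        out.update(glszm_features(qroi))
    except ValueError:
        out.update({name: np.nan for name in NGTDM_NAMES + GLSZM_NAMES})
    try:
        out.update(fps_features(S0, roi.mask, settings.radial_bins, settings.angular_bins))
    except ValueError:
        for i in range(settings.radial_bins):
            out[f"fps_radial_{i + 1}"] = np.nan
        for i in range(settings.angular_bins):
            out[f"fps_angular_{i + 1}"] = np.nan
    out.update(polarization_feature_summary(maps, roi.mask))
    try:
        out["fringe_contrast"] = fringe_contrast(S0, roi)
        out["transparency"] = transparency(S0, roi)
    except ValueError:
        out["fringe_contrast"] = np.nan
        out["transparency"] = np.nan
    return out


def extract_all(
    frame: PolarizationFrame,
    stokes: StokesMaps,
    maps: PolarizationMaps,
    roiset: ROISet,
    settings: FeatureSettings | None = None,
    label: str | None = None,
) -> FeatureTable:
    """One feature row per ROI, every group C1..C8 represented."""
    settings = settings or FeatureSettings()
    registry = feature_registry(settings)
    rows = []
    for roi in roiset:
        row: dict[str, object] = {
            "particle_id": f"{roiset.frame_id}:{roi.particle_id}",
            "frame_id": roiset.frame_id,
            "label": label if label is not None else "",
        }
        row.update(extract_roi_features(stokes.S0, maps, roi, settings))
        rows.append(row)
    columns = list(FeatureTable.ID_COLUMNS) + list(registry)
    df = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    return FeatureTable(df, registry)
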