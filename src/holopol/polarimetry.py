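"""Stokes inversion and polarization-map estimation.

A four-state linear analyzer set (0°, 45°, 90°, 135°) determines
(S0, S1, S2); an additional right-circular channel determines S3 and
enables the full-Stokes model.  Under the circularly polarized probe, a
linear retarder with retardance δ and fast axis θ maps the probe Stokes
vector (1, 0, 0, 1) to

    (S1, S2, S3)/S0 = (-sin δ sin 2θ,  sin δ cos 2θ,  cos δ),

so DoLP = sin δ, AoP = θ + 45° (mod 180°) and S3/S0 = cos δ.  Inverting:

* full-Stokes model:  δ = arccos(S3/S0), valid on [0, π];
* linear-only model:  δ = arcsin(DoLP), restricted to [0, π/2] — a
  linear analyzer set cannot distinguish δ from π − δ.  The limitation
  is surfaced in :attr:`PolarizationMaps.retardance_branch`.

Axis orientation is θ = (AoP − 45°) mod 180° in both models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

LINEAR_ANGLES = {"I0": 0.0, "I45": 45.0, "I90": 90.0, "I135": 135.0}
RCP = "IRCP"

#: relative floor under which S0 pixels are masked invalid
S0_EPS_REL = 1e-6


@dataclass
class PolarizationFrame:
    """Co-registered intensity grids for the analyzer states of one shot."""

    grids: Mapping[str, np.ndarray]
    channels: tuple[str, ...] = ("I0", "I45", "I90", "I135")

    def __post_init__(self) -> None:
        shapes = set()
        for ch in self.channels:
            if ch not in self.grids:
                raise ValueError(f"frame missing declared channel {ch!r}")
            g = np.asarray(self.grids[ch], dtype=np.float64)
            if np.any(g < 0):
                raise ValueError(f"channel {ch}: negative intensities")
            shapes.add(g.shape)
        if len(shapes) != 1:
            raise ValueError(f"channel dimension mismatch: {shapes}")

    def __getitem__(self, ch: str) -> np.ndarray:
        return np.asarray(self.grids[ch], dtype=np.float64)

    def __iter__(self) -> Iterator[str]:
        return iter(self.channels)

    @property
    def shape(self) -> tuple[int, int]:
        return self[self.channels[0]].shape

    @property
    def has_circular(self) -> bool:
        return RCP in self.channels

    @property
    def analyzer_model(self) -> str:
        return "full-stokes" if self.has_circular else "linear-only"


@dataclass
class StokesMaps:
    S0: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    S3: np.ndarray | None = None
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            eps = S0_EPS_REL * float(np.max(self.S0)) if self.S0.size else 0.0
            self.valid = self.S0 > eps

    @property
    def model(self) -> str:
        return "full-stokes" if self.S3 is not None else "linear-only"


@dataclass
class PolarizationMaps:
    """Derived per-pixel maps: AoP/axis in degrees [0, 180), δ in radians."""

    aop: np.ndarray
    dolp: np.ndarray
    retardance: np.ndarray
    axis: np.ndarray
    valid: np.ndarray
    axis_valid: np.ndarray
    #: 'full' (δ ∈ [0, π]) or 'folded' (δ ∈ [0, π/2], δ ↔ π−δ ambiguous)
    retardance_branch: str = "full"


def analyzer_stokes_row(channel: str) -> np.ndarray:
    """Stokes analysis row-vector of one analyzer: I = row · S."""
    if channel in LINEAR_ANGLES:
        a = np.deg2rad(LINEAR_ANGLES[channel])
        return 0.5 * np.array([1.0, np.cos(2 * a), np.sin(2 * a), 0.0])
    if channel == RCP:
        return 0.5 * np.array([1.0, 0.0, 0.0, 1.0])
    raise ValueError(f"unknown analyzer channel {channel!r}")


def compute_stokes(frame: PolarizationFrame, model: str | None = None) -> StokesMaps:
    """Invert analyzer intensities to Stokes maps.

    ``model`` defaults to the frame's own analyzer model.  The linear-only
    model uses the closed form S0 = (I0+I45+I90+I135)/2, S1 = I0 − I90,
    S2 = I45 − I135; the full-Stokes model solves the analyzer system
    I = A·S per pixel by least squares.
    """
    model = model or frame.analyzer_model
    if model == "linear-only":
        I0, I45, I90, I135 = (frame[c] for c in ("I0", "I45", "I90", "I135"))
        S0 = (I0 + I45 + I90 + I135) / 2.0
        return StokesMaps(S0=S0, S1=I0 - I90, S2=I45 - I135)
    if model != "full-stokes":
        raise ValueError(f"unknown Stokes model {model!r}")
    if not frame.has_circular:
        raise ValueError("full-stokes model requires the circular (IRCP) channel")
    A = np.stack([analyzer_stokes_row(ch) for ch in frame.channels])
    if np.linalg.matrix_rank(A) < 4:
        raise ValueError("analyzer matrix is singular; cannot solve for S0..S3")
    pinv = np.linalg.pinv(A)  # (4, n_channels)
    meas = np.stack([frame[ch] for ch in frame.channels], axis=-1)
    S = meas @ pinv.T
    return StokesMaps(S0=S[..., 0], S1=S[..., 1], S2=S[..., 2], S3=S[..., 3])


def compute_aop(stokes: StokesMaps) -> tuple[np.ndarray, np.ndarray]:
    """Angle of polarization ½·atan2(S2, S1) in degrees, mapped to [0, 180).

    Returns (aop, valid); pixels with S1 = S2 = 0 are masked invalid.
    """
    aop = np.rad2deg(0.5 * np.arctan2(stokes.S2, stokes.S1)) % 180.0
    defined = (stokes.S1 != 0) | (stokes.S2 != 0)
    return aop, stokes.valid & defined


def compute_dolp(stokes: StokesMaps) -> np.ndarray:
    """Degree of linear polarization sqrt(S1²+S2²)/S0, clipped to [0, 1]."""
    with np.errstate(divide="ignore", invalid="ignore"):
        dolp = np.hypot(stokes.S1, stokes.S2) / stokes.S0
    dolp = np.where(stokes.valid, dolp, 0.0)
    return np.clip(dolp, 0.0, 1.0)


def estimate_retardance_axis(
    stokes: StokesMaps, dolp_floor: float = 0.02
) -> tuple[np.ndarray, np.ndarray, np.ndarray, str]:
    """Estimate per-pixel retardance δ (rad) and fast-axis orientation θ (deg).

    Assumes the circular probe.  Returns (delta, theta, axis_valid, branch):
    under full-Stokes acquisition δ = arccos(S3/S0) on [0, π] and
    ``branch='full'``; under linear-only acquisition δ = arcsin(DoLP) on
    [0, π/2] and ``branch='folded'``.  θ = (AoP − 45°) mod 180°; pixels
    with DoLP below ``dolp_floor`` carry no usable axis signal and are
    masked in ``axis_valid``.
    """
    dolp = compute_dolp(stokes)
    aop, aop_valid = compute_aop(stokes)
    if stokes.S3 is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            cosd = np.where(stokes.valid, stokes.S3 / np.where(stokes.valid, stokes.S0, 1.0), 1.0)
        delta = np.arccos(np.clip(cosd, -1.0, 1.0))
        branch = "full"
    else:
        delta = np.arcsin(np.clip(dolp, 0.0, 1.0))
        branch = "folded"
    theta = (aop - 45.0) % 180.0
    axis_valid = aop_valid & (dolp >= dolp_floor)
    return delta, theta, axis_valid, branch


def compute_polarization_maps(
    frame: PolarizationFrame, model: str | None = None, dolp_floor: float = 0.02
) -> PolarizationMaps:
    """Full inversion: frame -> AoP, DoLP, retardance and axis maps."""
    stokes = compute_stokes(frame, model=model)
    aop, aop_valid = compute_aop(stokes)
    dolp = compute_dolp(stokes)
    delta, theta, axis_valid, branch = estimate_retardance_axis(stokes, dolp_floor=dolp_floor)
    return PolarizationMaps(
        aop=aop,
        dolp=dolp,
        retardance=delta,
        axis=theta,
        valid=stokes.valid & aop_valid,
        axis_valid=axis_valid,
        retardance_branch=branch,
    )


# ---------------------------------------------------------------------------
# circular (axial) statistics and ROI summaries
# ---------------------------------------------------------------------------


def circular_mean_deg(angles_deg: np.ndarray, period: float = 180.0) -> float:
    """Mean direction of axial data by the doubled-angle construction."""
    ang = np.asarray(angles_deg, dtype=np.float64) * (2 * np.pi / period)
    mean = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return float((mean * period / (2 * np.pi)) % period)


def circular_std_deg(angles_deg: np.ndarray, period: float = 180.0) -> float:
    """Circular standard deviation sqrt(-2 ln R), mapped back to degrees."""
    ang = np.asarray(angles_deg, dtype=np.float64) * (2 * np.pi / period)
    R = float(np.hypot(np.mean(np.sin(ang)), np.mean(np.cos(ang))))
    R = min(R, 1.0)
    if R <= 0.0:
        return period / 2.0
    return float(np.sqrt(-2.0 * np.log(R)) * period / (2 * np.pi))


def _circular_iqr_deg(angles_deg: np.ndarray, period: float = 180.0) -> float:
    """IQR of deviations wrapped around the circular mean."""
    mean = circular_mean_deg(angles_deg, period)
    dev = (np.asarray(angles_deg, dtype=np.float64) - mean + period / 2) % period - period / 2
    q1, q3 = np.percentile(dev, [25, 75])
    return float(q3 - q1)


#: registry of the polarization summary scalars (groups C4-C7)
POLARIZATION_FEATURES = {
    "C4": ("dolp_mean", "dolp_sd", "dolp_iqr"),
    "C5": ("aop_cmean", "aop_csd", "aop_iqr"),
    "C6": ("ret_mean", "ret_sd", "ret_iqr"),
    "C7": ("axis_cmean", "axis_csd", "axis_iqr"),
}


def polarization_feature_summary(
    maps: PolarizationMaps, roi_mask: np.ndarray
) -> dict[str, float]:
    """Summarize polarization maps over one ROI (groups C4-C7).

    Linear quantities (DoLP, retardance) get mean/sd/IQR; axial
    quantities (AoP, axis orientation) use circular statistics with a
    180° period.  An ROI with no valid pixels yields NaN features
    (flagged missing, not fabricated).
    """
    out: dict[str, float] = {}
    m = roi_mask & maps.valid
    ma = roi_mask & maps.axis_valid

    def _linear(prefix: str, grid: np.ndarray, mask: np.ndarray) -> None:
        vals = grid[mask]
        if vals.size == 0:
            out[f"{prefix}_mean"] = out[f"{prefix}_sd"] = out[f"{prefix}_iqr"] = np.nan
            return
        q1, q3 = np.percentile(vals, [25, 75])
        out[f"{prefix}_mean"] = float(np.mean(vals))
        out[f"{prefix}_sd"] = float(np.std(vals))
        out[f"{prefix}_iqr"] = float(q3 - q1)

    def _axial(prefix: str, grid: np.ndarray, mask: np.ndarray) -> None:
        vals = grid[mask]
        if vals.size == 0:
            out[f"{prefix}_cmean"] = out[f"{prefix}_csd"] = out[f"{prefix}_iqr"] = np.nan
            return
        out[f"{prefix}_cmean"] = circular_mean_deg(vals)
        out[f"{prefix}_csd"] = circular_std_deg(vals)
        out[f"{prefix}_iqr"] = _circular_iqr_deg(vals)

    _linear("dolp", maps.dolp, m)
    _axial("aop", maps.aop, ma)
    _linear("ret", maps.retardance, m)
    _axial("axis", maps.axis, ma)
    return out
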