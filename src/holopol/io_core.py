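"""Readers/writers for frames, manifests, feature tables and run configuration.

Frames are stored as multi-page TIFF (one page per analyzer state, page
order = declared channel order); a per-channel PNG fallback is accepted on
read.  Manifests and feature tables are delimited text (CSV) so they stay
inspectable without the package.  Intensities are normalized to [0, 1] on
load by dividing by (2**bitdepth - 1); all downstream math operates on real
intensities.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from holopol.polarimetry import PolarizationFrame

logger = logging.getLogger("holopol.io")

#: canonical analyzer channel tags, in acquisition order
LINEAR_CHANNELS = ("I0", "I45", "I90", "I135")
RCP_CHANNEL = "IRCP"
KNOWN_CHANNELS = LINEAR_CHANNELS + (RCP_CHANNEL,)

#: feature group tags (C1 NGTDM, C2 FPS, C3 GLSZM, C4 DoLP, C5 AoP,
#: C6 retardance, C7 axis orientation, C8 holographic)
GROUP_TAGS = ("C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8")


class ConfigError(ValueError):
    """A run-configuration invariant was violated; names the offending field."""


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class OpticalConfig:
    """Bench geometry and sensor model.

    Defaults mirror the reference bench: 532 nm illumination, 3.45 um
    pixel pitch, 1028 x 1232 recorded holograms, 5 mm sample-to-sensor
    distance.  ``bit_depth=None`` keeps frames as real-valued intensities
    (no quantization); ``photon_budget`` is the expected photon count at
    full-scale intensity and ``read_noise`` the Gaussian read-noise sigma
    in counts.  ``full_scale`` is the intensity mapped to the top code.
    """

    wavelength: float = 5.32e-7
    pitch: float = 3.45e-6
    shape: tuple[int, int] = (1028, 1232)
    z: float = 5e-3
    bit_depth: int | None = 16
    photon_budget: float = 50_000.0
    read_noise: float = 2.0
    full_scale: float = 2.0

    def validate(self) -> "OpticalConfig":
        if not self.wavelength > 0:
            raise ConfigError(f"optics.wavelength must be > 0, got {self.wavelength}")
        if not self.pitch > 0:
            raise ConfigError(f"optics.pitch must be > 0, got {self.pitch}")
        if self.z < 0:
            raise ConfigError(f"optics.z must be >= 0, got {self.z}")
        rows, cols = self.shape
        if rows < 16 or cols < 16:
            raise ConfigError(f"optics.shape dims must be >= 16, got {self.shape}")
        if rows % 2 or cols % 2:
            raise ConfigError(f"optics.shape dims must be even, got {self.shape}")
        if self.bit_depth is not None and self.bit_depth not in (8, 12, 16):
            raise ConfigError(f"optics.bit_depth must be 8, 12, 16 or null, got {self.bit_depth}")
        if not self.photon_budget > 0:
            raise ConfigError(f"optics.photon_budget must be > 0, got {self.photon_budget}")
        if self.read_noise < 0:
            raise ConfigError(f"optics.read_noise must be >= 0, got {self.read_noise}")
        return self


@dataclass
class FeatureSettings:
    gray_levels: int = 32
    radial_bins: int = 8
    angular_bins: int = 8
    min_area: int = 30
    annulus_width: int = 10
    dolp_floor: float = 0.02

    def validate(self) -> "FeatureSettings":
        if self.gray_levels < 2:
            raise ConfigError(f"features.gray_levels must be >= 2, got {self.gray_levels}")
        if self.radial_bins < 1 or self.angular_bins < 1:
            raise ConfigError("features.radial_bins and angular_bins must be >= 1")
        if self.min_area < 1:
            raise ConfigError(f"features.min_area must be >= 1, got {self.min_area}")
        return self


@dataclass
class CVSettings:
    folds: int = 5
    repeats: int = 20
    seed: int = 0
    stratified: bool = True

    def validate(self) -> "CVSettings":
        if self.folds < 2:
            raise ConfigError(f"cv.folds must be >= 2, got {self.folds}")
        if self.repeats < 1:
            raise ConfigError(f"cv.repeats must be >= 1, got {self.repeats}")
        return self


@dataclass
class ClassifierSettings:
    kind: str = "SVM"
    standardize: bool = True
    #: polarization : holographic : texture : FPS category weights
    ratio: tuple[float, float, float, float] = (4.0, 2.0, 2.0, 2.0)

    def validate(self) -> "ClassifierSettings":
        if self.kind not in ("ESD", "KNN", "NN", "SVM"):
            raise ConfigError(f"classifier.kind must be one of ESD/KNN/NN/SVM, got {self.kind!r}")
        if len(self.ratio) != 4 or any(r <= 0 for r in self.ratio):
            raise ConfigError(f"classifier.ratio must be 4 positive numbers, got {self.ratio}")
        return self


@dataclass
class RunConfig:
    """Validated top-level configuration for a full pipeline run."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    features: FeatureSettings = field(default_factory=FeatureSettings)
    cv: CVSettings = field(default_factory=CVSettings)
    classifier: ClassifierSettings = field(default_factory=ClassifierSettings)
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.optics.validate()
        self.features.validate()
        self.cv.validate()
        self.classifier.validate()
        return self


def _coerce_section(cls, data: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {name} config field(s): {sorted(unknown)}")
    if "shape" in data and data["shape"] is not None:
        data = {**data, "shape": tuple(data["shape"])}
    if "ratio" in data and data["ratio"] is not None:
        data = {**data, "ratio": tuple(float(r) for r in data["ratio"])}
    return cls(**data)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; unspecified fields take defaults.

    An empty (or absent) file yields the full default configuration:
    532 nm wavelength, 3.45 um pitch, 1028 x 1232 grid.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = loaded
    sections = {
        "optics": OpticalConfig,
        "features": FeatureSettings,
        "cv": CVSettings,
        "classifier": ClassifierSettings,
    }
    unknown = set(raw) - set(sections) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {}
    for key, cls in sections.items():
        kwargs[key] = _coerce_section(cls, dict(raw.get(key, {}) or {}), key)
    cfg = RunConfig(seed=int(raw.get("seed", 0)), **kwargs)
    return cfg.validate()


# ---------------------------------------------------------------------------
# dataset manifest
# ---------------------------------------------------------------------------


@dataclass
class ManifestRecord:
    frame_id: str
    label: str
    #: single multi-page TIFF path, or mapping channel tag -> file path
    path: str | dict[str, str]
    gt_path: str | None = None


@dataclass
class DatasetManifest:
    """Tabular index of a recorded dataset: frames, labels, channel order."""

    records: list[ManifestRecord]
    channels: tuple[str, ...] = LINEAR_CHANNELS
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for ch in self.channels:
            if ch not in KNOWN_CHANNELS:
                raise ValueError(f"unknown channel tag {ch!r}")
        if not self.labels:
            self.labels = tuple(sorted({r.label for r in self.records}))
        for r in self.records:
            if r.label not in self.labels:
                raise ValueError(f"record {r.frame_id}: label {r.label!r} not in declared set")


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    rows = []
    for r in manifest.records:
        p = r.path if isinstance(r.path, str) else "|".join(f"{k}={v}" for k, v in r.path.items())
        rows.append({"frame_id": r.frame_id, "label": r.label, "path": p, "gt_path": r.gt_path or ""})
    df = pd.DataFrame(rows, columns=["frame_id", "label", "path", "gt_path"])
    with open(path, "w") as fh:
        fh.write(f"# channels: {'|'.join(manifest.channels)}\n")
        df.to_csv(fh, index=False)
    logger.info("wrote manifest with %d records to %s", len(rows), path)


def load_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# channels:"):
            raise ValueError(f"{path}: missing '# channels:' header line")
        channels = tuple(first.split(":", 1)[1].strip().split("|"))
        df = pd.read_csv(fh, dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        p: str | dict[str, str] = row.path
        if "=" in row.path:
            p = dict(part.split("=", 1) for part in row.path.split("|"))
        records.append(ManifestRecord(row.frame_id, row.label, p, row.gt_path or None))
    manifest = DatasetManifest(records, channels=channels)
    logger.info("loaded manifest with %d records from %s", len(records), path)
    return manifest


# ---------------------------------------------------------------------------
# frame I/O
# ---------------------------------------------------------------------------

_DTYPE_FOR_DEPTH = {8: np.uint8, 12: np.uint16, 16: np.uint16}


def write_frame(frame: PolarizationFrame, path: str | Path, bit_depth: int | None = 16) -> None:
    """Write a frame as a multi-page TIFF, one page per channel in frame order.

    With a finite ``bit_depth`` the [0, 1] intensities are encoded as
    integer codes ``round(I * (2**bit_depth - 1))``; ``None`` stores
    float32 pages.
    """
    path = Path(path)
    pages = []
    for ch in frame.channels:
        grid = frame[ch]
        if bit_depth is None:
            pages.append(grid.astype(np.float32))
        else:
            top = 2**bit_depth - 1
            codes = np.clip(np.rint(grid * top), 0, top)
            pages.append(codes.astype(_DTYPE_FOR_DEPTH[bit_depth]))
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")


def load_polarization_frame(
    record: ManifestRecord,
    channels: Sequence[str] = LINEAR_CHANNELS,
    base_dir: str | Path | None = None,
) -> PolarizationFrame:
    """Load one manifest record into a :class:`PolarizationFrame`.

    Integer pixel codes are converted to real intensities in [0, 1] by
    dividing by the dtype's full-scale code; float images pass through.
    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` on
    channel-dimension mismatch or an unknown channel tag.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    for ch in channels:
        if ch not in KNOWN_CHANNELS:
            raise ValueError(f"unknown channel tag {ch!r}")
    grids: dict[str, np.ndarray] = {}
    if isinstance(record.path, str):
        fp = _resolve(record.path)
        if not fp.exists():
            raise FileNotFoundError(fp)
        stack = tifffile.imread(fp)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.shape[0] != len(channels):
            raise ValueError(
                f"{fp}: {stack.shape[0]} pages but {len(channels)} channels declared"
            )
        for ch, page in zip(channels, stack):
            grids[ch] = _to_intensity(page)
    else:
        import imageio.v3 as iio

        for ch in channels:
            if ch not in record.path:
                raise ValueError(f"record {record.frame_id}: channel {ch!r} has no file")
            fp = _resolve(record.path[ch])
            if not fp.exists():
                raise FileNotFoundError(fp)
            img = np.asarray(iio.imread(fp))
            if img.ndim == 3:  # collapse RGB(A) gray images
                img = img[..., 0]
            grids[ch] = _to_intensity(img)
    shapes = {g.shape for g in grids.values()}
    if len(shapes) > 1:
        raise ValueError(f"record {record.frame_id}: channel dimension mismatch {shapes}")
    return PolarizationFrame(grids, channels=tuple(channels))


def _to_intensity(img: np.ndarray) -> np.ndarray:
    if np.issubdtype(img.dtype, np.integer):
        top = float(np.iinfo(img.dtype).max)
        return img.astype(np.float64) / top
    return img.astype(np.float64)


def write_ground_truth(maps: dict[str, np.ndarray], path: str | Path) -> None:
    """Side-car ground truth: float32 pages label/delta/theta/transmittance."""
    order = ("label", "delta", "theta", "transmittance")
    pages = [maps[k].astype(np.float32) for k in order]
    tifffile.imwrite(Path(path), np.stack(pages), photometric="minisblack")


def load_ground_truth(path: str | Path) -> dict[str, np.ndarray]:
    stack = tifffile.imread(Path(path)).astype(np.float64)
    order = ("label", "delta", "theta", "transmittance")
    return dict(zip(order, stack))


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Per-particle feature rows plus the feature -> group-tag mapping.

    ``df`` holds identifier columns (particle_id, frame_id, label) followed
    by feature columns; ``groups`` maps each feature column to C1..C8.
    """

    df: pd.DataFrame
    groups: dict[str, str]

    ID_COLUMNS = ("particle_id", "frame_id", "label")

    def __post_init__(self) -> None:
        feature_cols = [c for c in self.df.columns if c not in self.ID_COLUMNS]
        for col in feature_cols:
            tag = self.groups.get(col)
            if tag not in GROUP_TAGS:
                raise ValueError(f"feature column {col!r} has no valid group tag (got {tag!r})")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in self.ID_COLUMNS]

    def features_in_group(self, *tags: str) -> list[str]:
        return [c for c in self.feature_columns if self.groups[c] in tags]

    def matrix(self, columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.feature_columns
        return self.df[cols].to_numpy(dtype=np.float64)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV with a second ``#group`` header row.

    Values round-trip loss-free (17 significant digits).
    """
    if len(table.df) == 0:
        raise ValueError("refusing to write an empty feature table")
    table.__post_init__()  # re-check group tags before writing
    path = Path(path)
    cols = list(table.df.columns)
    group_row = ["#group"] + [
        "" if c in FeatureTable.ID_COLUMNS else table.groups[c] for c in cols[1:]
    ]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        fh.write(",".join(group_row) + "\n")
        table.df.to_csv(fh, index=False, header=False, float_format="%.17g")
    logger.info("wrote feature table (%d rows, %d features) to %s",
                len(table.df), len(table.feature_columns), path)


def load_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        group_row = fh.readline().strip().split(",")
        if not group_row or group_row[0] != "#group":
            raise ValueError(f"{path}: missing '#group' header row")
        df = pd.read_csv(fh, names=header, float_precision="round_trip")
    groups = {
        col: tag
        for col, tag in zip(header, group_row)
        if col not in FeatureTable.ID_COLUMNS and tag
    }
    for col in df.columns:
        if col not in FeatureTable.ID_COLUMNS:
            df[col] = pd.to_numeric(df[col])
    return FeatureTable(df, groups)
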