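"""End-to-end runs: simulate -> invert -> extract -> evaluate.

These functions tie the modules together for the CLI, and run the same
computation in memory for programmatic use (no intermediate files).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from holopol import features as feat
from holopol import io_core, polarimetry, simulator
from holopol.io_core import DatasetManifest, FeatureSettings, FeatureTable, OpticalConfig

logger = logging.getLogger("holopol.pipeline")

DEFAULT_CHANNELS = ("I0", "I45", "I90", "I135", "IRCP")


def extract_frame_features(
    frame: polarimetry.PolarizationFrame,
    settings: FeatureSettings | None = None,
    frame_id: str = "",
    label: str | None = None,
) -> FeatureTable:
    """Invert one frame and extract all feature groups for its ROIs."""
    settings = settings or FeatureSettings()
    stokes = polarimetry.compute_stokes(frame)
    maps = polarimetry.compute_polarization_maps(frame, dolp_floor=settings.dolp_floor)
    roiset = feat.segment_particles(stokes.S0, settings)
    roiset.frame_id = frame_id
    return feat.extract_all(frame, stokes, maps, roiset, settings, label=label)


def concat_tables(tables: Sequence[FeatureTable]) -> FeatureTable:
    nonempty = [t for t in tables if len(t.df)]
    if not nonempty:
        raise ValueError("no feature rows to concatenate")
    groups = dict(nonempty[0].groups)
    df = pd.concat([t.df for t in nonempty], ignore_index=True)
    return FeatureTable(df, groups)


def synthetic_feature_table(
    per_class: int = 50,
    optics: OpticalConfig | None = None,
    seed: int = 1234,
    profiles: Mapping[str, simulator.ClassProfile] | None = None,
    settings: FeatureSettings | None = None,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    noise: bool = True,
) -> FeatureTable:
    """Simulate single-particle frames for every class and extract features.

    The default conditions are the package's reference experiment:
    8 classes x ``per_class`` particles on 256x256 grids, z = 5 mm,
    full-Stokes acquisition, default sensor noise.  Deterministic per seed.
    """
    optics = optics or OpticalConfig(shape=(256, 256))
    profiles = profiles or simulator.builtin_profiles()
    settings = settings or FeatureSettings()
    ss = np.random.SeedSequence(seed)
    frame_seeds = ss.spawn(len(profiles) * per_class)
    tables = []
    i = 0
    for cls in sorted(profiles):
        for _ in range(per_class):
            rng = np.random.default_rng(frame_seeds[i])
            frame, _scene = simulator.simulate_particle_frame(
                profiles[cls], optics, rng, channels=channels, noise=noise
            )
            tables.append(
                extract_frame_features(frame, settings, frame_id=f"{cls}_{i:05d}", label=cls)
            )
            i += 1
    table = concat_tables(tables)
    logger.info("extracted %d feature rows from %d simulated frames", len(table.df), i)
    return table


def manifest_feature_table(
    manifest: DatasetManifest,
    base_dir: str | Path,
    settings: FeatureSettings | None = None,
) -> FeatureTable:
    """Extract features for every frame referenced by a dataset manifest."""
    tables = []
    for record in manifest.records:
        frame = io_core.load_polarization_frame(record, manifest.channels, base_dir=base_dir)
        tables.append(
            extract_frame_features(frame, settings, frame_id=record.frame_id, label=record.label)
        )
    return concat_tables(tables)
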