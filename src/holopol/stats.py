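"""Feature-correlation analysis and per-class distribution summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from holopol.io_core import GROUP_TAGS, FeatureTable

logger = logging.getLogger("holopol.stats")


@dataclass
class CorrelationReport:
    """Pearson correlations between features and aggregated between groups.

    ``full`` is the feature-by-feature matrix (pairwise-complete
    observations); ``group`` holds, for each pair of feature groups, the
    mean correlation over all cross-group feature pairs with sign
    retained; ``dropped`` lists zero-variance columns excluded up front.
    """

    full: pd.DataFrame
    group: pd.DataFrame
    n_samples: int
    dropped: list[str]


def correlation_matrix(table: FeatureTable) -> CorrelationReport:
    """Pearson correlation report over a feature table.

    Requires at least 3 complete rows; zero-variance columns are
    excluded and reported in ``dropped``.
    """
    df = table.df[table.feature_columns].astype(float)
    if len(df) < 3:
        raise ValueError(f"need >= 3 rows for correlations, got {len(df)}")
    variances = df.var(skipna=True)
    dropped = [c for c in df.columns if not variances[c] > 0]
    kept = [c for c in df.columns if c not in dropped]
    full = df[kept].corr(method="pearson", min_periods=2)
    tags = sorted({table.groups[c] for c in kept}, key=GROUP_TAGS.index)
    group = pd.DataFrame(np.nan, index=tags, columns=tags)
    for gi in tags:
        cols_i = [c for c in kept if table.groups[c] == gi]
        for gj in tags:
            cols_j = [c for c in kept if table.groups[c] == gj]
            block = full.loc[cols_i, cols_j].to_numpy()
            if gi == gj:
                # off-diagonal entries only: self-correlations are trivially 1
                m = ~np.eye(len(cols_i), dtype=bool)
                vals = block[m] if len(cols_i) > 1 else np.array([1.0])
            else:
                vals = block.ravel()
            group.loc[gi, gj] = float(np.nanmean(vals)) if vals.size else np.nan
    if dropped:
        logger.info("dropped %d zero-variance feature(s): %s", len(dropped), dropped)
    return CorrelationReport(full=full, group=group, n_samples=len(df), dropped=dropped)


@dataclass
class ClassDistributionSummary:
    """Per (class, feature) summary stats plus violin-density support."""

    stats: pd.DataFrame  # columns: label, feature, n, median, q1, q3, min, max, flagged
    densities: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]


def class_distributions(table: FeatureTable, density_points: int = 64) -> ClassDistributionSummary:
    """Median/quartile/extreme summaries and Gaussian-KDE violin densities.

    KDE uses the Silverman bandwidth on ``density_points`` support
    points.  A class with fewer than 2 finite rows for a feature is
    summarized by its point value and flagged.
    """
    rows = []
    densities: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for label, sub in table.df.groupby("label"):
        for feat in table.feature_columns:
            vals = sub[feat].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            flagged = vals.size < 2
            if vals.size == 0:
                rows.append({"label": label, "feature": feat, "n": 0,
                             "median": np.nan, "q1": np.nan, "q3": np.nan,
                             "min": np.nan, "max": np.nan, "flagged": True})
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({"label": label, "feature": feat, "n": int(vals.size),
                         "median": float(med), "q1": float(q1), "q3": float(q3),
                         "min": float(vals.min()), "max": float(vals.max()),
                         "flagged": bool(flagged)})
            if not flagged and vals.std() > 0:
                kde = gaussian_kde(vals, bw_method="silverman")
                lo, hi = vals.min(), vals.max()
                pad = 0.1 * (hi - lo)
                xs = np.linspace(lo - pad, hi + pad, density_points)
                densities[(str(label), feat)] = (xs, kde(xs))
    return ClassDistributionSummary(stats=pd.DataFrame(rows), densities=densities)
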