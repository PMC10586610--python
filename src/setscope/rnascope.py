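"""Per-cell RNAscope signal quantification.

The input is a table of fluorescent objects (one row per detected object
inside a cell's nucleus + cytoplasm ring) with integral intensities, plus
a no-probe-control table of per-cell maximum intensities.  The control
defines, per channel, a detection threshold (mean maximum intensity plus
three sample standard deviations).  Objects above threshold are resolved
into molecule counts by dividing the background-subtracted integral
intensity by the average intensity of an individual signal; clusters of
merged molecules thereby contribute their full molecule content.

Downstream summaries are the ones used for smFISH group comparisons:
per-channel positivity calls (minimum molecule counts, e.g. Gal 2+,
c-Fos 5+), positive-cell rates per 1000 cells, semi-quantitative H-scores
(weighted bins 0-4 over molecule counts, range 0-400) and class-wise fold
changes of mean molecule counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelThreshold",
    "ClusterResolutionParams",
    "derive_threshold",
    "resolve_cluster",
    "cell_molecule_counts",
    "classify_cells",
    "positives_per_1000",
    "h_score",
    "fold_change",
    "fold_change_classes",
    "estimate_single_signal_intensity",
    "animal_summary",
]

H_SCORE_BIN_EDGES = (1, 4, 10, 16)  # weights 0..4 over {0},{1-3},{4-9},{10-15},{16+}

METADATA_COLUMNS = ["cell_id", "animal_id", "section_id", "condition"]


@dataclass
class ChannelThreshold:
    """Detection threshold for one channel, derived from no-probe controls."""

    channel: str
    threshold: float
    n_control_cells: int
    mean_max: float
    sd_max: float


@dataclass
class ClusterResolutionParams:
    """Calibration for resolving integral intensities into molecule counts."""

    channel: str
    single_signal_mean_intensity: float
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.single_signal_mean_intensity <= 0:
            raise ValueError("single_signal_mean_intensity must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")


def derive_threshold(control: pd.DataFrame, channel: str) -> ChannelThreshold:
    """Threshold = mean + 3 * sample SD of control max intensities.

    The no-probe control cells are a sample of the background process, so
    the SD uses the n-1 denominator; at least two control cells are needed
    for it to exist.
    """
    vals = control.loc[control["channel"] == channel, "max_intensity"]
    vals = vals.to_numpy(dtype=float)
    if vals.size < 2:
        raise ValueError(
            f"channel {channel!r}: need >= 2 control cells, got {vals.size}"
        )
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return ChannelThreshold(
        channel=channel,
        threshold=mean + 3.0 * sd,
        n_control_cells=int(vals.size),
        mean_max=mean,
        sd_max=sd,
    )


def _round_half_up(x: np.ndarray | float):
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def resolve_cluster(
    integral_intensity: float, params: ClusterResolutionParams
) -> int:
    """Resolve one above-threshold object into a molecule count.

    count = round_half_up((integral - background) / single mean), clamped
    to at least 1: the object already passed the detection threshold, so
    it represents at least one molecule even if its background-subtracted
    intensity is small (or negative, which is logged).
    """
    if integral_intensity < params.background:
        logger.warning(
            "object intensity %.3g below background %.3g on channel %s; "
            "clamping to 1 molecule",
            integral_intensity,
            params.background,
            params.channel,
        )
        return 1
    raw = (integral_intensity - params.background) / (
        params.single_signal_mean_intensity
    )
    return int(max(1, _round_half_up(raw)))


def cell_molecule_counts(
    signals: pd.DataFrame,
    thresholds: dict[str, ChannelThreshold],
    params: dict[str, ClusterResolutionParams],
    cells: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Resolve a signal table into per-cell, per-channel molecule counts.

    Objects at or below their channel threshold are discarded; the rest are
    cluster-resolved and summed per (cell, channel).  ``cells`` optionally
    supplies the full cell roster with metadata so cells without any
    above-threshold object appear with count 0 (otherwise the roster is the
    set of cells present in the signal table).  Returns a wide table:
    metadata columns then one integer count column per channel.
    """
    channels = sorted(signals["channel"].unique())
    for ch in channels:
        if ch not in thresholds:
            raise KeyError(f"no threshold for channel {ch!r}")
        if ch not in params:
            raise KeyError(f"no cluster-resolution params for channel {ch!r}")
    all_channels = sorted(set(channels) | set(thresholds))

    if cells is None:
        roster = signals[METADATA_COLUMNS].drop_duplicates("cell_id")
    else:
        missing = set(METADATA_COLUMNS) - set(cells.columns)
        if missing:
            raise ValueError(f"cell roster missing columns: {sorted(missing)}")
        roster = cells[METADATA_COLUMNS].drop_duplicates("cell_id")
    out = roster.reset_index(drop=True).copy()

    for ch in all_channels:
        out[ch] = 0
    for ch in channels:
        thr = thresholds[ch].threshold
        prm = params[ch]
        sub = signals[
            (signals["channel"] == ch)
            & (signals["integral_intensity"] > thr)
        ]
        if sub.empty:
            continue
        counts = sub.groupby("cell_id")["integral_intensity"].agg(
            lambda v: int(sum(resolve_cluster(x, prm) for x in v))
        )
        mapped = out["cell_id"].map(counts).fillna(0).astype(int)
        out[ch] = mapped
    for ch in all_channels:
        out[ch] = out[ch].astype(int)
    return out


def classify_cells(
    counts: pd.DataFrame, rules: dict[str, int]
) -> pd.DataFrame:
    """Per-cell positivity calls from minimum-molecule rules.

    Returns a copy of the metadata columns plus one boolean column
    ``<channel>_pos`` per rule; composite classes are conjunctions of
    these and can be formed by the caller (labels are non-exclusive).
    """
    out = counts[
        [c for c in METADATA_COLUMNS if c in counts.columns]
    ].copy()
    for ch, min_mol in rules.items():
        if min_mol < 1:
            raise ValueError(f"positivity rule for {ch!r} must be >= 1")
        if ch not in counts.columns:
            raise KeyError(f"channel {ch!r} absent from molecule table")
        out[f"{ch}_pos"] = counts[ch] >= min_mol
    return out


def positives_per_1000(n_positive: int, n_total_cells: int) -> float:
    """Positive-cell count normalized to a rate per 1000 cells."""
    if n_total_cells < 1:
        raise ValueError("n_total_cells must be >= 1")
    if not 0 <= n_positive <= n_total_cells:
        raise ValueError("n_positive must lie in [0, n_total_cells]")
    return 1000.0 * n_positive / n_total_cells


def h_score(counts) -> float:
    """Semi-quantitative H-score of a population of molecule counts.

    The percentage of cells with 0 molecules is weighted 0, with 1-3
    molecules weighted 1, 4-9 weighted 2, 10-15 weighted 3 and 16+
    weighted 4; the score is the weighted sum, in [0, 400].
    """
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("h_score needs at least one cell")
    if np.any(arr < 0):
        raise ValueError("molecule counts must be non-negative")
    weights = np.digitize(arr, H_SCORE_BIN_EDGES)
    return float(100.0 * weights.mean())


def fold_change(mean_a: float, mean_b: float) -> float:
    """Ratio of two class means (class a over class b)."""
    if mean_b == 0:
        raise ValueError("denominator class mean is zero")
    return mean_a / mean_b


def fold_change_classes(
    counts: pd.DataFrame, channel: str, class_a, class_b
) -> float:
    """Fold change of mean molecule counts between two cell classes.

    ``class_a`` / ``class_b`` are boolean masks aligned to ``counts`` or
    callables mapping the table to such masks (e.g. Gal/Th cells vs all
    other cells).
    """
    mask_a = np.asarray(class_a(counts) if callable(class_a) else class_a)
    mask_b = np.asarray(class_b(counts) if callable(class_b) else class_b)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both cell classes must be non-empty")
    mean_a = float(counts.loc[mask_a, channel].mean())
    mean_b = float(counts.loc[mask_b, channel].mean())
    return fold_change(mean_a, mean_b)


def estimate_single_signal_intensity(
    signals: pd.DataFrame, channel: str
) -> float:
    """Data-driven guess of the single-molecule intensity for a channel.

    Takes the median of object intensities below the channel's 50th
    percentile — individual signals sit below clusters in the intensity
    distribution.  This helper is advisory: calibration values are always
    supplied explicitly, never silently estimated.
    """
    vals = signals.loc[
        signals["channel"] == channel, "integral_intensity"
    ].to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError(f"no objects on channel {channel!r}")
    half = vals[vals <= np.percentile(vals, 50)]
    return float(np.median(half))


def animal_summary(
    counts: pd.DataFrame, rules: dict[str, int]
) -> pd.DataFrame:
    """Per-animal quantification summary (animal is the experimental unit).

    For each animal: total cells, then per rule channel the positive-cell
    count, the rate per 1000 cells, the mean molecule count and the
    H-score of that channel's counts pooled over the animal's sections.
    """
    classes = classify_cells(counts, rules)
    rows = []
    for animal, idx in counts.groupby("animal_id").groups.items():
        sub = counts.loc[idx]
        cls = classes.loc[idx]
        row: dict = {
            "animal_id": animal,
            "condition": sub["condition"].iloc[0],
            "n_cells": len(sub),
        }
        for ch in rules:
            n_pos = int(cls[f"{ch}_pos"].sum())
            row[f"{ch}_positive"] = n_pos
            row[f"{ch}_per_1000"] = positives_per_1000(n_pos, len(sub))
            row[f"{ch}_mean_molecules"] = float(sub[ch].mean())
            row[f"{ch}_h_score"] = h_score(sub[ch])
        rows.append(row)
    return pd.DataFrame(rows).sort_values("animal_id").reset_index(drop=True)
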