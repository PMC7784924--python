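"""Spike-calibrated OTU abundance estimation.

Read counts per OTU are converted to DNA amounts in two steps: calibration
``a_ij = w_i * r_ij / f_i`` (sample i's total fungal amount w_i = f_i/s_i
spread over its OTUs by relative read abundance among fungal reads), and a
per-method normalization ``â_ij = a_ij / Σ_{i' in method(i)} w_i'`` so that
the air and the soil data each sum to one and the two media can be compared
on equal footing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class AbundanceMatrix:
    """Samples x OTUs abundance in three layers (raw, calibrated, normalized)."""

    raw: pd.DataFrame
    calibrated: pd.DataFrame
    normalized: pd.DataFrame
    samples: pd.DataFrame  # metadata for the retained samples


def calibrate(raw: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    """Calibrated abundance a_ij = w_i * r_ij / f_i; row sums equal w_i.

    ``raw`` is samples x OTUs read counts; ``counts`` the screening tallies.
    Samples with f_i = 0 (or undefined w) are excluded with a log entry;
    a mismatch between the OTU-table row sum and f_i is an error.
    """
    counts = counts.set_index("sample_id")
    missing = [s for s in raw.index if s not in counts.index]
    if missing:
        raise ValueError(f"calibrate: samples missing from counts: {missing[:5]}")
    keep = []
    for sid in raw.index:
        f = counts.at[sid, "f"]
        w = counts.at[sid, "w"]
        if f == 0 or not np.isfinite(w):
            logger.warning("calibrate: excluding sample %s (f=%s, w=%s)", sid, f, w)
            continue
        row_sum = raw.loc[sid].sum()
        if int(row_sum) != int(f):
            raise ValueError(
                f"calibrate: OTU counts for {sid} sum to {row_sum}, screening f={f}"
            )
        keep.append(sid)
    sub = raw.loc[keep]
    w = counts.loc[keep, "w"].to_numpy(dtype=float)
    f = counts.loc[keep, "f"].to_numpy(dtype=float)
    return sub.mul(w / f, axis=0)


def normalize_by_method(calibrated: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample's abundances by its method's summed DNA amount.

    After normalization the grand total within each method equals 1.
    """
    meta = samples.set_index("sample_id").loc[calibrated.index]
    out = calibrated.copy()
    for method, idx in meta.groupby("method").groups.items():
        total = calibrated.loc[idx].to_numpy().sum()
        if total <= 0:
            raise ValueError(f"normalize_by_method: method {method!r} has zero total DNA")
        out.loc[idx] = calibrated.loc[idx] / total
    return out


def build_abundance(raw: pd.DataFrame, counts: pd.DataFrame, samples: pd.DataFrame) -> AbundanceMatrix:
    """Run both layers and package them with the retained metadata."""
    calibrated = calibrate(raw, counts)
    normalized = normalize_by_method(calibrated, samples)
    meta = samples.set_index("sample_id").loc[calibrated.index].reset_index(names="sample_id")
    return AbundanceMatrix(
        raw=raw.loc[calibrated.index],
        calibrated=calibrated,
        normalized=normalized,
        samples=meta,
    )
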