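"""Taxon-level aggregation and predominance/specialist classification.

A taxon is *predominantly air-detectable* when its summed normalized
abundance over air samples is at least ``ratio`` (default 10) times the
soil sum, and vice versa; the natural/urban specialist call works the same
way pooling both media.  Taxa present in fewer than ``min_samples``
(default 5) samples are excluded as unreliable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .levels import LEVELS


def aggregate_to_level(matrix: pd.DataFrame, assignments: pd.DataFrame, level: str) -> pd.DataFrame:
    """Sum a samples x OTUs matrix into samples x taxa at the given rank.

    ``assignments`` maps OTU id -> per-level taxon path (one row per OTU).
    Column sums are conserved at every rank.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    lookup = assignments.drop_duplicates("otu").set_index("otu")[level]
    unknown = [o for o in matrix.columns if o not in lookup.index]
    if unknown:
        raise ValueError(f"aggregate_to_level: unknown OTU ids {unknown[:5]}")
    taxa = lookup.loc[matrix.columns]
    return matrix.T.groupby(taxa.to_numpy()).sum().T


def classify_predominance(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    ratio: float = 10.0,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Medium (air/soil) and habitat (natural/urban) predominance calls.

    ``matrix`` is samples x taxa normalized abundance.  A call is made when
    one side's sum is at least ``ratio`` times the other (inclusive); taxa
    in fewer than ``min_samples`` samples are 'excluded'.  A positive sum
    against a zero sum yields a call; two zero sums yield 'neither'.
    """
    if ratio <= 1:
        raise ValueError("predominance ratio must exceed 1")
    meta = samples.set_index("sample_id").loc[matrix.index]
    prevalence = (matrix > 0).sum(axis=0)

    def _sums(mask):
        return matrix.loc[mask.to_numpy()].sum(axis=0)

    a_air = _sums(meta["method"] == "air")
    a_soil = _sums(meta["method"] == "soil")
    a_nat = _sums(meta["habitat"] == "natural")
    a_urb = _sums(meta["habitat"] == "urban")

    def _call(x, y, name_x, name_y):
        out = np.full(len(x), "neither", dtype=object)
        out[(x >= ratio * y) & (x > 0)] = name_x
        out[(y >= ratio * x) & (y > 0)] = name_y
        return out

    df = pd.DataFrame(
        {
            "taxon": matrix.columns,
            "medium": _call(a_air.to_numpy(), a_soil.to_numpy(), "air", "soil"),
            "habitat": _call(a_nat.to_numpy(), a_urb.to_numpy(), "natural", "urban"),
            "A_air": a_air.to_numpy(),
            "A_soil": a_soil.to_numpy(),
            "A_natural": a_nat.to_numpy(),
            "A_urban": a_urb.to_numpy(),
            "prevalence": prevalence.to_numpy(),
        }
    )
    excluded = df["prevalence"] < min_samples
    df.loc[excluded, ["medium", "habitat"]] = "excluded"
    return df


def euler_counts(matrix: pd.DataFrame, grouping: pd.Series, min_samples: int = 5):
    """Shared/exclusive OTU counts between two sample groups.

    ``grouping`` maps sample id -> group label (exactly two labels).  Over
    OTUs present (abundance > 0) in at least ``min_samples`` samples,
    returns ``{(label_a, label_b): shared, label_a: only_a, label_b: only_b}``.
    """
    groups = pd.unique(grouping.loc[matrix.index])
    if len(groups) != 2:
        raise ValueError("euler_counts needs exactly two groups")
    a, b = sorted(map(str, groups))
    mask_a = (grouping.loc[matrix.index] == a).to_numpy()
    mask_b = (grouping.loc[matrix.index] == b).to_numpy()
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("euler_counts: a group has no samples")
    eligible = (matrix > 0).sum(axis=0) >= min_samples
    sub = matrix.loc[:, eligible]
    in_a = (sub.loc[mask_a] > 0).any(axis=0)
    in_b = (sub.loc[mask_b] > 0).any(axis=0)
    return {
        (a, b): int((in_a & in_b).sum()),
        a: int((in_a & ~in_b).sum()),
        b: int((in_b & ~in_a).sum()),
    }


def filter_prevalence(matrix: pd.DataFrame, min_samples: int) -> pd.DataFrame:
    """Keep OTUs present (abundance > 0) in at least ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    keep = (matrix > 0).sum(axis=0) >= min_samples
    return matrix.loc[:, keep]
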