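"""Read screening: spike identification, reliability, tallies, pre-clustering.

Per sample i the screening stage produces the bookkeeping the quantification
rests on: n_i total reads, s_i spike reads, p_i non-fungal reads,
f_i = n_i - s_i - p_i fungal reads, and w_i = f_i / s_i as the estimate of
total fungal DNA in the sample.  A read counts as fungal only when its
taxonomic placement assigns it to a fungal phylum with probability above
the reliability cut; reliability at deeper ranks additionally requires all
ancestor ranks to be reliable (prefix rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from . import _identity as idt
from .clustering import _SeqView, greedy_cluster
from .levels import LEVELS

logger = logging.getLogger(__name__)

CATEGORY_SPIKE = 0
CATEGORY_FUNGAL = 1
CATEGORY_NONFUNGAL = 2
CATEGORY_NAMES = np.asarray(["spike", "fungal", "nonfungal"], dtype=object)


def deepest_reliable_levels(probs: np.ndarray, cut: float = 0.9) -> np.ndarray:
    """Deepest reliable rank index per row under the prefix rule.

    ``probs`` is (n, 6) placement probabilities phylum..species; a rank is
    reliable iff its probability strictly exceeds ``cut`` *and* every
    ancestor rank is reliable.  Returns int8 indices into LEVELS, -1 when
    not even the phylum is reliable.  NaN probabilities are unreliable.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != len(LEVELS):
        raise ValueError(f"probs must be (n, {len(LEVELS)})")
    with np.errstate(invalid="ignore"):
        if np.nanmax(probs, initial=0.0) > 1.0 or np.nanmin(probs, initial=0.0) < 0.0:
            raise ValueError("placement probabilities must lie in [0, 1]")
    reliable = np.where(np.isnan(probs), False, probs > cut)
    prefix = np.cumprod(reliable, axis=1).astype(bool)
    return prefix.sum(axis=1).astype(np.int8) - 1


def identify_spikes(seqs, spike_refs, threshold: float = 0.95) -> np.ndarray:
    """Flag reads whose best identity to any spike reference is >= threshold."""
    if len(spike_refs) == 0:
        raise ValueError("identify_spikes: no spike references; quantification impossible")
    view = _SeqView(seqs)
    if view.n == 0:
        return np.zeros(0, dtype=bool)
    refs = [str(s).upper() for s in spike_refs]
    if view.codes is not None and len({len(r) for r in refs}) == 1 and len(refs[0]) == view.L:
        try:
            ref_codes = idt.encode(refs)
        except ValueError:
            ref_codes = None
        if ref_codes is not None:
            lim = idt.inclusive_limit(view.L, threshold)
            pos, ham = idt.best_hits(view.packed, idt.pack(ref_codes), max(lim, 0))
            return (pos >= 0) & ((view.L - ham) / view.L >= threshold)
    flags = np.zeros(view.n, dtype=bool)
    for i in range(view.n):
        s = view.seq(i)
        flags[i] = any(idt.dp_identity(s, r) >= threshold for r in refs)
    return flags


def classify_reliability(placements: pd.DataFrame, cut: float = 0.9) -> pd.Series:
    """Deepest reliable rank name per read ('none' when phylum unreliable).

    ``placements`` carries ``p_{level}`` columns for the six ranks; a missing
    phylum column is an error (fungal retention is decided there).
    """
    if "p_phylum" not in placements.columns:
        raise ValueError("placements lack a p_phylum column")
    cols = []
    for lv in LEVELS:
        col = f"p_{lv}"
        cols.append(placements[col] if col in placements.columns else np.nan)
    probs = pd.concat(
        [pd.Series(c, index=placements.index) for c in cols], axis=1
    ).to_numpy(dtype=float)
    deepest = deepest_reliable_levels(probs, cut=cut)
    names = np.asarray(["none", *LEVELS], dtype=object)
    return pd.Series(names[deepest + 1], index=placements.index, name="deepest_level")


@dataclass
class ScreenResult:
    """Per-read categories plus per-sample tallies."""

    categories: np.ndarray  # int8 per read (0 spike, 1 fungal, 2 nonfungal)
    deepest: np.ndarray  # int8 per read, index into LEVELS, -1 none
    counts: pd.DataFrame  # sample_id, n, s, p, f, w, flagged

    def category_names(self) -> np.ndarray:
        return CATEGORY_NAMES[self.categories]


def screen_reads(
    seqs,
    sample_ids,
    spike_refs,
    placement_probs: np.ndarray | None,
    placement_rows: np.ndarray | None = None,
    spike_threshold: float = 0.95,
    reliability_cut: float = 0.9,
) -> ScreenResult:
    """Partition reads into spike / fungal / non-fungal and tally per sample.

    ``placement_probs`` holds (m, 6) probabilities for the reads listed in
    ``placement_rows`` (default: the first m reads); reads without a row are
    unplaced.  Spike status wins over placement; fungal requires a reliable
    phylum; everything else is non-fungal.
    """
    n = len(sample_ids)
    spikes = identify_spikes(seqs, spike_refs, threshold=spike_threshold)
    deepest = np.full(n, -1, dtype=np.int8)
    if placement_probs is not None and len(placement_probs):
        rows = (
            np.arange(len(placement_probs))
            if placement_rows is None
            else np.asarray(placement_rows)
        )
        deepest[rows] = deepest_reliable_levels(placement_probs, cut=reliability_cut)
    categories = np.full(n, CATEGORY_NONFUNGAL, dtype=np.int8)
    categories[deepest >= 0] = CATEGORY_FUNGAL
    categories[spikes] = CATEGORY_SPIKE
    deepest = deepest.copy()
    deepest[categories != CATEGORY_FUNGAL] = -1
    counts = tally_samples(sample_ids, categories)
    return ScreenResult(categories=categories, deepest=deepest, counts=counts)


def tally_samples(sample_ids, categories) -> pd.DataFrame:
    """SampleCounts table: n = s + p + f and w = f/s (NaN, flagged, if s=0)."""
    df = pd.DataFrame({"sample_id": sample_ids, "cat": categories})
    tab = (
        df.groupby("sample_id", sort=True)["cat"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[CATEGORY_SPIKE, CATEGORY_FUNGAL, CATEGORY_NONFUNGAL], fill_value=0)
    )
    out = pd.DataFrame(
        {
            "sample_id": tab.index,
            "n": tab.sum(axis=1).to_numpy(),
            "s": tab[CATEGORY_SPIKE].to_numpy(),
            "p": tab[CATEGORY_NONFUNGAL].to_numpy(),
            "f": tab[CATEGORY_FUNGAL].to_numpy(),
        }
    ).reset_index(drop=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["w"] = np.where(out["s"] > 0, out["f"] / out["s"], np.nan)
    out["flagged"] = out["s"] == 0
    for sid in out.loc[out["flagged"], "sample_id"]:
        logger.warning("sample %s has no spike reads; w undefined, sample flagged", sid)
    return out


def exclude_small_samples(counts: pd.DataFrame, min_reads: int = 10_000):
    """Drop samples with fewer than ``min_reads`` total reads (strict <)."""
    drop = counts["n"] < min_reads
    dropped = counts.loc[drop, "sample_id"].tolist()
    if dropped:
        logger.info("excluding %d samples below %d reads: %s", len(dropped), min_reads, dropped)
    return counts.loc[~drop].reset_index(drop=True), dropped


@dataclass
class PreclusterResult:
    """Weighted representatives of the fungal reads."""

    seqs: "np.ndarray | list[str]"  # representative sequences (codes or strings)
    ids: list  # representative id = lexicographically smallest member read id
    weights: np.ndarray  # member count per representative
    sample_counts: sparse.csr_matrix  # representatives x samples member counts
    sample_index: list  # column order of sample_counts
    placements: pd.DataFrame | None  # inherited placement per representative
    read_labels: np.ndarray | None = None  # representative index per input read

    @property
    def n(self) -> int:
        return len(self.weights)


def precluster(
    seqs,
    read_ids,
    sample_ids,
    threshold: float = 0.995,
    placements: pd.DataFrame | None = None,
) -> PreclusterResult:
    """Collapse near-identical fungal reads into weighted representatives.

    Greedy centroid clustering at ``threshold`` in read-id order (all reads
    weigh 1, so the contract's weight-descending order reduces to the id
    order).  Exact duplicates are dereplicated first; this provably leaves
    the greedy trajectory unchanged.  Each representative inherits the most
    frequent member placement (ties: higher summed placement probability,
    then smallest read id) and per-sample member counts.
    """
    n = len(read_ids)
    if n == 0:
        raise ValueError("precluster: no fungal reads")
    order = np.argsort(np.asarray(read_ids, dtype=object), kind="stable")
    view = _SeqView(seqs)
    if view.codes is not None:
        uniq_codes, first, inverse = _dereplicate(view.codes, order)
        uview = _SeqView(uniq_codes)
        lim = idt.inclusive_limit(uview.L, threshold)
        uorder = np.arange(uview.n, dtype=np.int64)  # already first-occurrence order
        if lim <= 1:
            labels_u, cent_u = (
                idt.greedy_cluster_ham1(uview.codes, uorder)
                if lim == 1
                else (uorder.copy(), uorder.copy())
            )
        else:
            labels_u, cent_u = idt.greedy_assign_packed(uview.packed, lim)
        labels = labels_u[inverse]
        rep_seqs = uview.codes[cent_u]
        rep_member_first = first[cent_u]
    else:
        res = greedy_cluster(seqs, threshold, ids=list(read_ids), order=order)
        labels = res.labels
        rep_seqs = [view.seq(int(i)) for i in res.centroids]
        rep_member_first = res.centroids
    m = int(labels.max()) + 1
    weights = np.bincount(labels, minlength=m).astype(float)
    rep_ids = _min_member_ids(read_ids, labels, m)

    sample_arr = pd.Series(sample_ids)
    sample_cat = sample_arr.astype("category")
    col_index = list(sample_cat.cat.categories)
    mat = sparse.coo_matrix(
        (np.ones(n), (labels, sample_cat.cat.codes.to_numpy())),
        shape=(m, len(col_index)),
    ).tocsr()

    rep_plac = None
    if placements is not None:
        rep_plac = _inherit_placements(placements, labels, read_ids, m, rep_ids)
    return PreclusterResult(
        seqs=rep_seqs,
        ids=rep_ids,
        weights=weights,
        sample_counts=mat,
        sample_index=col_index,
        placements=rep_plac,
        read_labels=labels,
    )


def _dereplicate(codes: np.ndarray, order: np.ndarray):
    """Unique rows, numbered by first occurrence along ``order``.

    Returns (unique codes, first-occurrence row per unique, inverse labels
    per original row).
    """
    n, L = codes.shape
    voided = np.ascontiguousarray(codes).view([("", codes.dtype)] * L).ravel()
    _, inv = np.unique(voided, return_inverse=True)
    pos_in_order = np.empty(n, dtype=np.int64)
    pos_in_order[order] = np.arange(n)
    first_pos = np.full(inv.max() + 1, n, dtype=np.int64)
    np.minimum.at(first_pos, inv, pos_in_order)
    by_first = np.argsort(first_pos, kind="stable")
    rank = np.empty_like(by_first)
    rank[by_first] = np.arange(len(by_first))
    first_rows = order[first_pos[by_first]]
    return codes[first_rows], first_rows, rank[inv]


def _min_member_ids(read_ids, labels, m):
    ser = pd.Series(np.asarray(read_ids, dtype=object))
    return ser.groupby(labels).min().reindex(range(m)).tolist()


def _inherit_placements(placements, labels, read_ids, m, rep_ids):
    """Modal member placement per representative."""
    df = placements.copy()
    df["_rep"] = labels
    df["_rid"] = np.asarray(read_ids, dtype=object)
    prob_cols = [c for c in df.columns if c.startswith("p_")]
    taxa_cols = [lv for lv in LEVELS if lv in df.columns]
    key_cols = taxa_cols + prob_cols
    df["_psum"] = df[prob_cols].sum(axis=1)
    grp = df.groupby(["_rep", *key_cols], sort=False, dropna=False, observed=True)
    agg = grp.agg(_count=("_rid", "size"), _psum=("_psum", "first"), _rid=("_rid", "min"))
    agg = agg.reset_index().sort_values(
        ["_rep", "_count", "_psum", "_rid"], ascending=[True, False, False, True]
    )
    best = agg.drop_duplicates("_rep", keep="first").set_index("_rep")
    best = best.reindex(range(m))
    out = best[key_cols].reset_index(drop=True)
    out.insert(0, "id", rep_ids)
    return out
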