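"""Taxonomy-constrained hierarchical OTU clustering.

The centerpiece of the package: reliably placed sequences form a taxonomic
backbone; per-level similarity thresholds are calibrated from within- vs
among-taxon similarity distributions so that false positives and false
negatives balance; unreliably placed sequences are then either attached to
a backbone taxon or clustered de novo, level by level from class down to
species.  Every sequence ends up in exactly one species-level OTU and no
reliably placed sequence is ever moved off its reliable taxon.

Similarity is global-alignment identity (match +1, mismatch -1, gap -1;
identity = identical aligned positions / alignment length).  For uniform
length collections produced by a substitution process the optimal alignment
is gap-free and the implementation uses fast Hamming kernels; mixed-length
collections fall back to the exact dynamic program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _identity as idt
from .levels import CLUSTER_LEVELS, LEVELS

logger = logging.getLogger(__name__)

PATH_SEP = ";"

__all__ = [
    "pairwise_identity",
    "greedy_cluster",
    "build_representatives",
    "similarity_distributions",
    "optimize_threshold",
    "assign_or_denovo",
    "hierarchical_otu_clustering",
    "GreedyClusters",
    "ThresholdDecision",
    "HierarchicalResult",
]


def pairwise_identity(a: str, b: str) -> float:
    """Identity of the optimal global alignment of ``a`` and ``b``.

    Scoring: match +1, mismatch -1, gap -1; score ties resolved in favour
    of more matches, then a shorter alignment, which makes the result
    symmetric in its arguments.  1.0 for identical sequences.
    """
    if not a or not b:
        raise ValueError("pairwise_identity: empty sequence")
    return idt.dp_identity(a, b)


class _SeqView:
    """Uniform access to a sequence collection: fast packed path or DP path."""

    def __init__(self, seqs):
        if isinstance(seqs, np.ndarray) and seqs.dtype == np.uint8 and seqs.ndim == 2:
            self.codes = seqs
            self.seqs = None
        else:
            seqs = [s.upper() for s in seqs]
            try:
                self.codes = idt.encode(seqs)
            except ValueError:
                self.codes = None
            self.seqs = seqs
        self._packed = None
        self.n = self.codes.shape[0] if self.codes is not None else len(self.seqs)
        self.L = self.codes.shape[1] if self.codes is not None else None

    @property
    def packed(self):
        if self._packed is None:
            self._packed = idt.pack(self.codes)
        return self._packed

    def seq(self, i: int) -> str:
        if self.seqs is not None:
            return self.seqs[i]
        return idt.decode(self.codes[i : i + 1])[0]

    def best_hits(self, query_rows, target_rows, limit_h=None):
        """Best (max-identity) target for each query; ties -> earliest target.

        Returns (pos int64 array into target_rows, identity float array);
        pos -1 where nothing reaches the limit.
        """
        query_rows = np.asarray(query_rows, dtype=np.int64)
        target_rows = np.asarray(target_rows, dtype=np.int64)
        if self.codes is not None:
            lim = self.L if limit_h is None else int(limit_h)
            qp = self.packed[query_rows]
            tp = self.packed[target_rows]
            pos, ham = idt.best_hits(qp, tp, lim)
            ident = np.where(pos >= 0, (self.L - ham) / self.L, -1.0)
            return pos, ident
        pos = np.full(len(query_rows), -1, dtype=np.int64)
        ident = np.full(len(query_rows), -1.0)
        min_ident = None
        for qi, q in enumerate(query_rows):
            best, best_j = -1.0, -1
            for j, t in enumerate(target_rows):
                d = idt.dp_identity(self.seq(int(q)), self.seq(int(t)))
                if d > best:
                    best, best_j = d, j
                    if best == 1.0:
                        break
            pos[qi] = best_j
            ident[qi] = best
        return pos, ident


def _processing_order(weights, ids):
    """Decreasing weight, ties by lexicographic id."""
    n = len(weights)
    return np.asarray(
        sorted(range(n), key=lambda i: (-weights[i], ids[i])), dtype=np.int64
    )


@dataclass
class GreedyClusters:
    """Result of greedy centroid clustering over one input collection."""

    labels: np.ndarray  # cluster index per input sequence
    centroids: np.ndarray  # input index of each cluster's centroid
    weights: np.ndarray  # summed member weight per cluster

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


def _greedy(view: _SeqView, threshold: float, weights, order) -> GreedyClusters:
    n = view.n
    if view.codes is not None:
        lim = idt.inclusive_limit(view.L, threshold)
        if lim <= 1:
            labels_o, cent = idt.greedy_cluster_ham1(view.codes, order)
            # ham1 path is exact only for limits 0 and 1
            if lim < 1:
                labels_o, cent = _greedy_exact_packed(view, 0, order)
            labels = labels_o
        else:
            labels, cent = _greedy_exact_packed(view, lim, order)
    else:
        labels = np.full(n, -1, dtype=np.int64)
        cents: list[int] = []
        for i in order:
            best, best_c = -1.0, -1
            for c, crow in enumerate(cents):
                d = idt.dp_identity(view.seq(int(i)), view.seq(int(crow)))
                if d > best:
                    best, best_c = d, c
            if best_c >= 0 and best >= threshold:
                labels[i] = best_c
            else:
                labels[i] = len(cents)
                cents.append(int(i))
        cent = np.asarray(cents, dtype=np.int64)
    w = np.zeros(len(cent))
    np.add.at(w, labels, weights)
    return GreedyClusters(labels=labels, centroids=cent, weights=w)


def _greedy_exact_packed(view: _SeqView, limit_h: int, order):
    ordered = view.packed[order]
    lab_o, cent_o = idt.greedy_assign_packed(ordered, max(limit_h, 0))
    labels = np.full(view.n, -1, dtype=np.int64)
    labels[order] = lab_o
    cent = order[cent_o]
    return labels, cent


def greedy_cluster(seqs, threshold: float, weights=None, ids=None, order=None) -> GreedyClusters:
    """Greedy centroid clustering (UCLUST-style, deterministic).

    Sequences are processed in decreasing weight (ties by lexicographic id,
    or by an explicit ``order``).  Each sequence joins the existing centroid
    of highest identity if that identity is >= ``threshold`` (identity ties
    go to the earliest-created centroid), otherwise it founds a new cluster.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    view = _SeqView(seqs)
    n = view.n
    weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if ids is None:
        width = len(str(max(n - 1, 0)))
        ids = [str(i).zfill(width) for i in range(n)]
    if order is None:
        order = _processing_order(weights, ids)
    else:
        order = np.asarray(order, dtype=np.int64)
    return _greedy(view, threshold, weights, order)


def build_representatives(seqs, taxa, weights=None, ids=None, threshold: float = 0.995):
    """Cluster reliable sequences within each taxon into representatives.

    Returns ``{taxon: (member_index_of_each_representative, rep_weights)}``.
    Representatives are the greedy-cluster centroids at ``threshold``; each
    carries the summed weight of its members.  Empty taxa are skipped.
    """
    view = _SeqView(seqs)
    n = view.n
    weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if ids is None:
        width = len(str(max(n - 1, 0)))
        ids = [str(i).zfill(width) for i in range(n)]
    taxa = np.asarray(taxa, dtype=object)
    out = {}
    for taxon in pd.unique(taxa):
        rows = np.flatnonzero(taxa == taxon)
        if len(rows) == 0:
            continue
        sub_order = _processing_order(weights[rows], [ids[r] for r in rows])
        res = _greedy_on_rows(view, rows, threshold, weights[rows], sub_order)
        out[taxon] = (rows[res.centroids], res.weights)
    return out


def _greedy_on_rows(view: _SeqView, rows, threshold, weights, order) -> GreedyClusters:
    if view.codes is not None:
        sub = _SeqView(view.codes[rows])
    else:
        sub = _SeqView([view.seq(int(r)) for r in rows])
    return _greedy(sub, threshold, weights, order)


def similarity_distributions(seqs, taxa, reps_by_taxon, parent_of=None, seq_view=None):
    """Within- and among-taxon best-identity distributions at one level.

    For every sequence ``x`` the *within* list records the best identity of
    ``x`` against the representatives of its own taxon, and the *among* list
    the best identity against representatives of sibling taxa (taxa sharing
    the same parent under ``parent_of``; all other taxa when ``parent_of``
    is None).  Sequences whose parent has a single child contribute only to
    *within*.  Returns (within, among) as float arrays.
    """
    view = seq_view if seq_view is not None else _SeqView(seqs)
    taxa = np.asarray(taxa, dtype=object)
    all_taxa = list(reps_by_taxon.keys())
    if parent_of is None:
        parent_of = {t: "" for t in all_taxa}
    within: list[np.ndarray] = []
    among: list[np.ndarray] = []
    children: dict[str, list] = {}
    for t in all_taxa:
        children.setdefault(parent_of[t], []).append(t)
    for t in all_taxa:
        rows = np.flatnonzero(taxa == t)
        if len(rows) == 0:
            continue
        rep_rows, _ = reps_by_taxon[t]
        rep_rows = np.asarray(rep_rows, dtype=np.int64)
        is_rep = np.isin(rows, rep_rows)
        w = np.ones(len(rows))
        if (~is_rep).any():
            _, ident = view.best_hits(rows[~is_rep], rep_rows)
            w[~is_rep] = ident
        within.append(w)
        sibs = [s for s in children[parent_of[t]] if s != t]
        if sibs:
            sib_rows = np.concatenate(
                [np.asarray(reps_by_taxon[s][0], dtype=np.int64) for s in sibs]
            )
            _, ident = view.best_hits(rows, sib_rows)
            among.append(ident)
    w_arr = np.concatenate(within) if within else np.empty(0)
    a_arr = np.concatenate(among) if among else np.empty(0)
    return w_arr, a_arr


@dataclass
class ThresholdDecision:
    """An optimized similarity threshold with its diagnostics."""

    theta: float
    fp: int
    fn: int
    interval: tuple[float, float]
    n_within: int
    n_among: int
    fallback: bool = False


def optimize_threshold(within, among, mode: str = "counts") -> ThresholdDecision:
    """Threshold at which false positives balance false negatives.

    ``FP(t) = #{among >= t}`` (a sequence of a different taxon would be
    attached) and ``FN(t) = #{within < t}`` (a sequence of the taxon would
    be rejected).  Both are constant on the half-open intervals between
    consecutive distinct pooled values; the chosen interval minimizes
    ``|FP - FN|``, then ``FP + FN``, then takes the lowest such interval,
    and theta is its midpoint.  ``mode="rates"`` balances rates instead of
    raw counts (useful when the two distributions differ greatly in size).
    """
    within = np.sort(np.asarray(within, dtype=float))
    among = np.sort(np.asarray(among, dtype=float))
    if within.size == 0:
        raise ValueError("optimize_threshold: empty within-taxon distribution")
    if mode not in ("counts", "rates"):
        raise ValueError("mode must be 'counts' or 'rates'")
    values = np.unique(np.concatenate([within, among]))
    lows = np.concatenate([[0.0], values])
    highs = np.concatenate([values, [1.0]])
    keep = lows < highs  # drop empty intervals (values at 0 or 1)
    lows, highs = lows[keep], highs[keep]
    fp = among.size - np.searchsorted(among, lows, side="right")
    fn = np.searchsorted(within, lows, side="right")
    if mode == "rates":
        fpv = fp / among.size if among.size else np.zeros_like(fp, dtype=float)
        fnv = fn / within.size
    else:
        fpv, fnv = fp, fn
    key = np.abs(fpv - fnv) * 1e9 + (fpv + fnv)
    k = int(np.argmin(key))  # argmin takes the first (lowest-threshold) tie
    lo = float(lows[k])
    hi = float(highs[k])
    theta = (lo + hi) / 2.0
    if not lo < theta <= hi:  # midpoint under/overflow on extreme floats
        theta = hi
    return ThresholdDecision(
        theta=theta,
        fp=int(fp[k]),
        fn=int(fn[k]),
        interval=(lo, hi),
        n_within=int(within.size),
        n_among=int(among.size),
    )


def assign_or_denovo(
    seqs,
    reps,
    theta: float,
    weights=None,
    ids=None,
    parent: str = "",
    level: str = "species",
    seq_view=None,
    rows=None,
):
    """Attach sequences to backbone taxa or cluster them de novo.

    ``reps`` maps taxon label -> (rep sequence rows, rep weights) within the
    same collection as ``seqs``.  A sequence whose best identity against any
    representative strictly exceeds ``theta`` is assigned to the arg-max
    taxon (identity ties -> taxon of the heavier representative, then
    lexicographic taxon label); the remainder are greedy-clustered at
    ``theta`` into de novo taxa labelled ``{parent}.denovo_{level}_{k}``.

    Returns (labels per sequence, list of de novo labels).
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    view = seq_view if seq_view is not None else _SeqView(seqs)
    if rows is None:
        rows = np.arange(view.n, dtype=np.int64)
    rows = np.asarray(rows, dtype=np.int64)
    nq = len(rows)
    weights = np.ones(nq) if weights is None else np.asarray(weights, dtype=float)
    if ids is None:
        width = len(str(max(nq - 1, 0)))
        ids = [str(i).zfill(width) for i in range(nq)]
    labels = np.full(nq, None, dtype=object)
    # Flatten representatives sorted by (weight desc, taxon, position) so the
    # earliest best hit encodes the tie-break.
    flat = []
    for taxon, (rep_rows, rep_w) in reps.items():
        for r, w in zip(np.asarray(rep_rows, dtype=np.int64), np.asarray(rep_w, dtype=float)):
            flat.append((-w, str(taxon), int(r)))
    if flat:
        flat.sort()
        target_rows = np.asarray([f[2] for f in flat], dtype=np.int64)
        target_taxon = [f[1] for f in flat]
        if view.codes is not None:
            lim = idt.strict_limit(view.L, theta)
            pos, ident = view.best_hits(rows, target_rows, limit_h=max(lim, 0))
            hit = (pos >= 0) & (ident > theta)
        else:
            pos, ident = view.best_hits(rows, target_rows)
            hit = (pos >= 0) & (ident > theta)
        for qi in np.flatnonzero(hit):
            labels[qi] = target_taxon[int(pos[qi])]
    else:
        hit = np.zeros(nq, dtype=bool)
    denovo_labels: list[str] = []
    rest = np.flatnonzero(~hit)
    if len(rest):
        rest_rows = rows[rest]
        sub_order = _processing_order(weights[rest], [ids[i] for i in rest])
        res = _greedy_on_rows(view, rest_rows, theta, weights[rest], sub_order)
        prefix = f"{parent}.denovo_{level}_" if parent else f"denovo_{level}_"
        for c in range(res.n_clusters):
            denovo_labels.append(f"{prefix}{c + 1}")
        for qi, lab in zip(rest, res.labels):
            labels[qi] = denovo_labels[int(lab)]
    return labels, denovo_labels


@dataclass
class HierarchicalResult:
    """Outcome of the full taxonomy-constrained clustering."""

    assignments: pd.DataFrame  # per sequence: one column per level, 'otu'
    thresholds: pd.DataFrame  # per level: theta, fp, fn, sizes, fallback
    demoted: dict = field(default_factory=dict)  # level -> n sequences demoted

    def otu_table(self, weights=None) -> pd.DataFrame:
        """OTU id, taxonomic path and member count/weight."""
        df = self.assignments.copy()
        df["weight"] = 1.0 if weights is None else np.asarray(weights, dtype=float)
        g = df.groupby("otu", sort=True)["weight"].agg(["count", "sum"])
        g.columns = ["members", "weight"]
        return g.reset_index()


def hierarchical_otu_clustering(
    seqs,
    placements: pd.DataFrame,
    weights=None,
    ids=None,
    reliability_cut: float = 0.9,
    rep_threshold: float = 0.995,
    first_fallback: float = 0.9,
    calibration_cap: int | None = None,
    fpfn_mode: str = "counts",
) -> HierarchicalResult:
    """Cluster sequences into species-level OTUs against a reliable backbone.

    ``placements`` must be aligned with ``seqs`` (row i describes sequence i)
    and carry ``{level}`` / ``p_{level}`` columns for the six ranks.  Every
    sequence must be reliably placed at phylum (the fungal-retention filter
    guarantees this upstream).  Levels are processed class -> species; at
    each level the backbone is clustered into representatives, a threshold
    is calibrated (falling back to the previous level's threshold when the
    within-taxon distribution is empty), and remaining sequences are
    attached or clustered de novo under their current parent.

    ``calibration_cap`` bounds the number of backbone sequences used to
    estimate the similarity distributions (deterministic stride over the
    weight-ranked backbone); it affects only threshold estimation, never
    membership.
    """
    from .screening import deepest_reliable_levels  # late import, no cycle

    view = _SeqView(seqs)
    n = view.n
    if n == 0:
        logger.warning("hierarchical_otu_clustering: empty input")
        empty = pd.DataFrame(columns=[*LEVELS, "otu"])
        return HierarchicalResult(assignments=empty, thresholds=pd.DataFrame())
    weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if ids is None:
        width = len(str(n - 1))
        ids = [f"seq{str(i).zfill(width)}" for i in range(n)]
    ids = list(ids)
    probs = placements[[f"p_{lv}" for lv in LEVELS]].to_numpy(dtype=float)
    deepest = deepest_reliable_levels(probs, cut=reliability_cut)
    if (deepest < 0).any():
        bad = int((deepest < 0).sum())
        raise ValueError(
            f"{bad} sequences lack a reliable phylum placement; screen reads first"
        )
    taxa_cols = {lv: placements[lv].to_numpy(dtype=object) for lv in LEVELS}

    assign = np.empty((n, len(LEVELS)), dtype=object)
    assign[:, 0] = taxa_cols["phylum"]
    threshold_rows = []
    demoted_log = {}
    theta_prev = None

    for li, level in enumerate(CLUSTER_LEVELS, start=1):
        parent_assign = assign[:, li - 1]
        reliable = deepest >= li
        consistent = np.zeros(n, dtype=bool)
        if reliable.any():
            consistent[reliable] = (
                taxa_cols[LEVELS[li - 1]][reliable] == _leaf_names(parent_assign[reliable])
            )
        backbone = reliable & consistent
        n_demoted = int(reliable.sum() - backbone.sum())
        if n_demoted:
            demoted_log[level] = n_demoted
            logger.info("%s: demoted %d inconsistent reliable sequences", level, n_demoted)
        assign[backbone, li] = _join_paths(parent_assign[backbone], taxa_cols[level][backbone])

        # representatives per backbone taxon
        bb_rows = np.flatnonzero(backbone)
        reps_by_taxon: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        taxon_parent: dict[str, str] = {}
        if len(bb_rows):
            bb_taxa = assign[bb_rows, li]
            for taxon in pd.unique(bb_taxa):
                rows = bb_rows[bb_taxa == taxon]
                sub_order = _processing_order(weights[rows], [ids[r] for r in rows])
                res = _greedy_on_rows(view, rows, rep_threshold, weights[rows], sub_order)
                reps_by_taxon[taxon] = (rows[res.centroids], res.weights)
                taxon_parent[taxon] = _parent_path(taxon)

        # threshold calibration
        if reps_by_taxon:
            cal_rows, cal_taxa = _calibration_subset(
                bb_rows, assign[bb_rows, li], weights, calibration_cap
            )
            within, among = _distributions_on_rows(
                view, cal_rows, cal_taxa, reps_by_taxon, taxon_parent
            )
        else:
            within = np.empty(0)
            among = np.empty(0)
        if within.size == 0:
            theta = theta_prev if theta_prev is not None else first_fallback
            decision = ThresholdDecision(
                theta=theta, fp=0, fn=0, interval=(theta, theta),
                n_within=0, n_among=0, fallback=True,
            )
        else:
            decision = optimize_threshold(within, among, mode=fpfn_mode)
        theta = decision.theta
        threshold_rows.append(
            {
                "level": level,
                "theta": theta,
                "fp": decision.fp,
                "fn": decision.fn,
                "n_within": decision.n_within,
                "n_among": decision.n_among,
                "fallback": decision.fallback,
            }
        )
        theta_prev = theta

        # attach or de novo, per parent node
        todo = np.flatnonzero(~backbone)
        if len(todo):
            todo_parents = parent_assign[todo]
            for parent in pd.unique(todo_parents):
                rows = todo[todo_parents == parent]
                child_reps = {
                    t: r for t, r in reps_by_taxon.items() if _parent_path(t) == parent
                }
                labels, _ = assign_or_denovo(
                    None,
                    child_reps,
                    theta,
                    weights=weights[rows],
                    ids=[ids[r] for r in rows],
                    parent=str(parent),
                    level=level,
                    seq_view=view,
                    rows=rows,
                )
                for r, lab in zip(rows, labels):
                    assign[r, li] = lab

    frame = pd.DataFrame(assign, columns=list(LEVELS))
    frame.insert(0, "id", ids)
    frame["otu"] = assign[:, -1]
    thresholds = pd.DataFrame(threshold_rows)
    return HierarchicalResult(assignments=frame, thresholds=thresholds, demoted=demoted_log)


def _join_paths(parents, names):
    return np.asarray(
        [f"{p}{PATH_SEP}{c}" for p, c in zip(parents, names)], dtype=object
    )


def _leaf_names(paths):
    return np.asarray([str(p).rsplit(PATH_SEP, 1)[-1] for p in paths], dtype=object)


def _parent_path(taxon: str) -> str:
    taxon = str(taxon)
    if f".denovo_" in taxon.rsplit(PATH_SEP, 1)[-1]:
        # de novo labels embed their parent before ".denovo_"
        return taxon.rsplit(".denovo_", 1)[0]
    if PATH_SEP in taxon:
        return taxon.rsplit(PATH_SEP, 1)[0]
    return ""


def _calibration_subset(bb_rows, bb_taxa, weights, cap):
    if cap is None or len(bb_rows) <= cap:
        return bb_rows, bb_taxa
    order = np.argsort(-weights[bb_rows], kind="stable")
    pick = order[np.linspace(0, len(order) - 1, cap).astype(int)]
    pick.sort()
    return bb_rows[pick], bb_taxa[pick]


def _distributions_on_rows(view, rows, taxa, reps_by_taxon, parent_of):
    """similarity_distributions over a subset of rows of a shared view."""
    taxa = np.asarray(taxa, dtype=object)
    children: dict[str, list] = {}
    for t in reps_by_taxon:
        children.setdefault(parent_of[t], []).append(t)
    within: list[np.ndarray] = []
    among: list[np.ndarray] = []
    for t, (rep_rows, _w) in reps_by_taxon.items():
        sel = np.flatnonzero(taxa == t)
        if len(sel) == 0:
            continue
        sub = rows[sel]
        rep_rows = np.asarray(rep_rows, dtype=np.int64)
        is_rep = np.isin(sub, rep_rows)
        w = np.ones(len(sub))
        if (~is_rep).any():
            _, ident = view.best_hits(sub[~is_rep], rep_rows)
            w[~is_rep] = ident
        within.append(w)
        sibs = [s for s in children[parent_of[t]] if s != t]
        if sibs:
            sib_rows = np.concatenate(
                [np.asarray(reps_by_taxon[s][0], dtype=np.int64) for s in sibs]
            )
            _, ident = view.best_hits(sub, sib_rows)
            among.append(ident)
    w_arr = np.concatenate(within) if within else np.empty(0)
    a_arr = np.concatenate(among) if among else np.empty(0)
    return w_arr, a_arr
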