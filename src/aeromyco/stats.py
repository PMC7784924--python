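"""Community-level statistics: transform, distances, ordination, PERMANOVA.

The analysis chain mirrors a standard community-ecology workflow: log(x +
1e-6) transform of the normalized DNA amounts, Euclidean sample distances,
Sammon ordination into two dimensions, and permutational multivariate
ANOVA (PERMANOVA) with sequential (Type-I) sums of squares computed from
the Gower-centered inner-product matrix (the McArdle-Anderson identity
``SS_total = Σ_{i<j} d_ij^2 / n`` is asserted on every run).  Export
helpers produce the model-ready tables for external mixed-model (richness,
DNA amount) and joint species distribution (presence/abundance hurdle)
fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


def log_transform(matrix: pd.DataFrame, pseudo: float = 1e-6) -> pd.DataFrame:
    """Elementwise natural log of (x + pseudo); negative input is an error."""
    vals = matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("log_transform: negative abundance")
    return pd.DataFrame(np.log(vals + pseudo), index=matrix.index, columns=matrix.columns)


def euclidean_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between sample rows."""
    vals = matrix.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("euclidean_distances: missing values")
    d = squareform(pdist(vals, metric="euclidean"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class OrdinationResult:
    """2-D Sammon embedding with its stress trajectory."""

    coordinates: pd.DataFrame  # sample x (axis1, axis2)
    stress: float
    trace: list = field(default_factory=list)  # accepted-step stress values
    n_iter: int = 0


def _classical_scaling(d: np.ndarray, dims: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)[None, :]


def sammon(
    distances: pd.DataFrame,
    dims: int = 2,
    max_iter: int = 500,
    tol: float = 1e-9,
    step: float = 0.3,
) -> OrdinationResult:
    """Sammon mapping by diagonal-Newton descent with step halving.

    Minimizes ``S = (1/Σδ) Σ (δ_ij - d_ij)^2 / δ_ij`` starting from the
    classical metric scaling of the input distances; a proposed step is
    halved until the stress decreases, so the accepted-step stress trace is
    non-increasing.  Duplicate points (zero off-diagonal distance) must be
    collapsed by the caller first.
    """
    ids = list(distances.index)
    delta = distances.to_numpy(dtype=float)
    n = delta.shape[0]
    off = ~np.eye(n, dtype=bool)
    if n > 1 and (delta[off] <= 0).any():
        raise ValueError(
            "sammon: zero off-diagonal distance; collapse duplicate samples first"
        )
    if n <= 2:
        # one or two points embed exactly
        y = np.zeros((n, dims))
        if n == 2:
            y[1, 0] = delta[0, 1]
        coords = pd.DataFrame(y, index=ids, columns=[f"axis{k+1}" for k in range(dims)])
        return OrdinationResult(coordinates=coords, stress=0.0, trace=[0.0], n_iter=0)

    c = delta[off].sum() / 2.0
    y = _classical_scaling(delta, dims)

    def _stress(pos):
        d = squareform(pdist(pos))
        num = (delta - d)[off] ** 2 / np.where(delta[off] > 0, delta[off], 1.0)
        return num.sum() / (2.0 * c)

    cur = _stress(y)
    trace = [cur]
    it = 0
    for it in range(1, max_iter + 1):
        d = squareform(pdist(y))
        np.fill_diagonal(d, 1.0)
        dl = delta.copy()
        np.fill_diagonal(dl, 1.0)
        inv = 1.0 / (d * dl)
        diff = dl - d
        np.fill_diagonal(inv, 0.0)
        np.fill_diagonal(diff, 0.0)
        # gradient and diagonal curvature of the raw (unscaled) stress
        g = np.empty_like(y)
        h = np.empty_like(y)
        for k in range(dims):
            yk = y[:, k][:, None] - y[:, k][None, :]
            g[:, k] = -2.0 * (inv * diff * yk).sum(axis=1)
            h[:, k] = 2.0 * (
                inv * (diff - (yk**2) / d * (1.0 + diff / d))
            ).sum(axis=1)
        denom = np.abs(h)
        denom[denom < 1e-12] = 1e-12
        direction = -g / denom
        accepted = False
        s = step
        for _half in range(30):
            cand = y + s * direction
            new = _stress(cand)
            if new < cur:
                y, cur = cand, new
                accepted = True
                break
            s /= 2.0
        if not accepted:
            break
        trace.append(cur)
        if len(trace) > 1 and trace[-2] - trace[-1] < tol:
            break
    coords = pd.DataFrame(y, index=ids, columns=[f"axis{k+1}" for k in range(dims)])
    return OrdinationResult(coordinates=coords, stress=float(cur), trace=trace, n_iter=it)


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table."""

    table: pd.DataFrame  # term, df, ss, r2, f, p

    def p_value(self, term: str) -> float:
        return float(self.table.set_index("term").at[term, "p"])


def _design_matrix(meta: pd.DataFrame, term: str) -> np.ndarray:
    cols = term.split(":")
    mats = []
    for c in cols:
        if c not in meta.columns:
            raise ValueError(f"permanova: unknown metadata column {c!r}")
        series = meta[c].astype(str)
        if series.nunique() < 2:
            raise ValueError(f"permanova: term {c!r} has a single level")
        mats.append(pd.get_dummies(series, dtype=float).to_numpy())
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(out.shape[0], -1)
    return out


def permanova(
    distances: pd.DataFrame,
    metadata: pd.DataFrame,
    terms: list,
    n_perm: int = 999,
    seed: int = 0,
    strata: str | None = None,
) -> PermanovaResult:
    """PERMANOVA with sequential sums of squares and free row permutation.

    ``terms`` are metadata columns, in model order; two-way interactions are
    written ``"a:b"``.  The permutation p-value uses the
    ``(1 + exceedances) / (1 + n_perm)`` estimator; ``n_perm="exact"``
    enumerates all row permutations instead (small n only).  ``strata``
    names a column within whose levels permutation is confined.
    """
    # canonical (sorted) sample order, so permutation p-values do not depend
    # on the ordering of the input matrix rows
    ids = sorted(distances.index)
    distances = distances.loc[ids, ids]
    meta = metadata.set_index("sample_id").loc[ids] if "sample_id" in metadata.columns else metadata.loc[ids]
    d = distances.to_numpy(dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    ss_total = float(np.trace(g))
    expected_total = float((d**2).sum() / (2 * n))
    if not np.isclose(ss_total, expected_total, rtol=1e-8, atol=1e-8):
        raise AssertionError("total sum-of-squares identity violated")

    hats = []
    dfs = []
    x = np.ones((n, 1))
    rank_prev = 1
    for term in terms:
        x = np.hstack([x, _design_matrix(meta, term)])
        u, sv, _ = np.linalg.svd(x, full_matrices=False)
        rank = int((sv > sv.max() * n * np.finfo(float).eps).sum())
        if rank == rank_prev:
            raise ValueError(f"permanova: term {term!r} is aliased with earlier terms")
        hats.append(u[:, :rank] @ u[:, :rank].T)
        dfs.append(rank - rank_prev)
        rank_prev = rank
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("permanova: saturated design, no residual degrees of freedom")

    def _ss_terms(gm):
        tr = [float(np.sum(h * gm)) for h in hats]
        ss = []
        prev = 0.0
        for t in tr:
            ss.append(t - prev)
            prev = t
        ss_res = float(np.trace(gm)) - prev
        return np.asarray(ss), ss_res

    ss, ss_res = _ss_terms(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss / np.asarray(dfs)) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    if n_perm == "exact":
        from itertools import permutations as _perms

        perms = [np.asarray(p) for p in _perms(range(n))]
        exceed = np.zeros(len(terms))
        for p in perms:
            gp = g[np.ix_(p, p)]
            ssp, ssrp = _ss_terms(gp)
            with np.errstate(divide="ignore", invalid="ignore"):
                fp = (ssp / np.asarray(dfs)) / (ssrp / df_res)
            exceed += fp >= f_obs - 1e-12
        pvals = exceed / len(perms)
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        exceed = np.zeros(len(terms))
        strata_codes = (
            pd.factorize(meta[strata].astype(str))[0] if strata is not None else None
        )
        for _ in range(int(n_perm)):
            p = _permute(n, rng, strata_codes)
            gp = g[np.ix_(p, p)]
            ssp, ssrp = _ss_terms(gp)
            with np.errstate(divide="ignore", invalid="ignore"):
                fp = (ssp / np.asarray(dfs)) / (ssrp / df_res)
            exceed += fp >= f_obs - 1e-12
        pvals = (1.0 + exceed) / (1.0 + int(n_perm))

    rows = []
    for term, dfk, ssk, fk, pk in zip(terms, dfs, ss, f_obs, pvals):
        rows.append(
            {"term": term, "df": dfk, "ss": ssk, "r2": ssk / ss_total, "f": fk, "p": pk}
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "ss": ss_res,
            "r2": ss_res / ss_total,
            "f": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {"term": "Total", "df": n - 1, "ss": ss_total, "r2": 1.0, "f": np.nan, "p": np.nan}
    )
    return PermanovaResult(table=pd.DataFrame(rows))


def _permute(n, rng, strata_codes):
    if strata_codes is None:
        return rng.permutation(n)
    p = np.arange(n)
    for code in np.unique(strata_codes):
        idx = np.flatnonzero(strata_codes == code)
        p[idx] = idx[rng.permutation(len(idx))]
    return p


def export_model_tables(abundance, counts: pd.DataFrame, min_prevalence: int = 20) -> dict:
    """Model-ready exports for external GLMM and joint-SDM fitting.

    Returns ``richness`` (per retained sample: design factors, observed OTU
    richness, w, log sequencing depth) and, per method, presence-absence
    and abundance matrices for species occurring in at least
    ``min_prevalence`` samples of that method.
    """
    counts = counts.set_index("sample_id")
    meta = abundance.samples.set_index("sample_id")
    raw = abundance.raw
    richness = pd.DataFrame(
        {
            "sample_id": raw.index,
            "method": meta.loc[raw.index, "method"].to_numpy(),
            "habitat": meta.loc[raw.index, "habitat"].to_numpy(),
            "position": meta.loc[raw.index, "position"].to_numpy(),
            "site": meta.loc[raw.index, "site"].to_numpy(),
            "plot": meta.loc[raw.index, "plot"].to_numpy(),
            "richness": (raw > 0).sum(axis=1).to_numpy(),
            "w": counts.loc[raw.index, "w"].to_numpy(),
            "log_depth": np.log(counts.loc[raw.index, "n"].to_numpy(dtype=float)),
        }
    )
    out = {"richness": richness}
    for method in pd.unique(meta["method"]):
        rows = meta.index[meta["method"] == method].intersection(raw.index)
        sub = abundance.normalized.loc[rows]
        keep = (sub > 0).sum(axis=0) >= min_prevalence
        out[f"hmsc_{method}_presence"] = (sub.loc[:, keep] > 0).astype(int)
        out[f"hmsc_{method}_abundance"] = sub.loc[:, keep]
    return out
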