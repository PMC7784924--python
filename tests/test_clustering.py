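"""Greedy clustering, representatives, threshold optimizer and the driver."""

import numpy as np
import pandas as pd
import pytest

from aeromyco.clustering import (
    assign_or_denovo,
    build_representatives,
    greedy_cluster,
    hierarchical_otu_clustering,
    optimize_threshold,
    pairwise_identity,
    similarity_distributions,
)
from aeromyco.levels import LEVELS

from oracles import brute_optimize_threshold


def _mutate(seq, positions, rng):
    bases = "ACGT"
    out = list(seq)
    for p in positions:
        out[p] = bases[(bases.index(out[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def _random_seq(rng, L=250):
    return "".join(np.asarray(list("ACGT"))[rng.choice(4, size=L)])


# ---------------------------------------------------------------- greedy


def test_greedy_all_identical_one_cluster():
    res = greedy_cluster(["ACGTACGT"] * 5, threshold=0.9)
    assert res.n_clusters == 1
    assert res.weights[0] == 5


def test_greedy_threshold_below_min_identity_one_cluster(rng):
    ref = _random_seq(rng, 100)
    seqs = [ref] + [_mutate(ref, rng.choice(100, size=5, replace=False), rng) for _ in range(4)]
    min_ident = min(
        pairwise_identity(a, b) for i, a in enumerate(seqs) for b in seqs[i + 1 :]
    )
    res = greedy_cluster(seqs, threshold=min_ident)
    assert res.n_clusters == 1


def test_greedy_two_separated_groups(rng):
    """Two 10-member groups at ~0.7 between-group identity, threshold 0.9:
    exactly two clusters whose centroids are the heaviest member of each."""
    ref_a = _random_seq(rng)
    ref_b = _mutate(ref_a, rng.choice(250, size=75, replace=False), rng)
    seqs, weights, ids = [], [], []
    for gi, ref in enumerate((ref_a, ref_b)):
        for k in range(10):
            pos = rng.choice(250, size=int(rng.integers(0, 3)), replace=False)
            seqs.append(_mutate(ref, pos, rng))
            weights.append(100 - k if k else 1000 + gi)  # first member heaviest
            ids.append(f"g{gi}m{k}")
    # brute-force: verify the construction separates at 0.9
    ident = np.array([[pairwise_identity(a, b) for b in seqs] for a in seqs])
    assert ident[:10, 10:].max() < 0.9
    assert all(ident[i, (i // 10) * 10] >= 0.9 for i in range(20))
    res = greedy_cluster(seqs, threshold=0.9, weights=weights, ids=ids)
    assert res.n_clusters == 2
    cent_ids = {ids[c] for c in res.centroids}
    assert cent_ids == {"g0m0", "g1m0"}
    assert res.weights.sum() == sum(weights)


def test_greedy_partition_and_weight_conservation(rng):
    for _ in range(5):
        n = int(rng.integers(2, 25))
        seqs = [_random_seq(rng, 60) for _ in range(n)]
        w = rng.integers(1, 10, size=n).astype(float)
        res = greedy_cluster(seqs, threshold=float(rng.uniform(0.3, 1.0)), weights=w)
        assert np.all(res.labels >= 0)
        assert res.weights.sum() == pytest.approx(w.sum())
        assert len(np.unique(res.labels)) == res.n_clusters


# ---------------------------------------------------- representatives


def test_build_representatives_identical_members():
    reps = build_representatives(["ACGT" * 60] * 4, ["taxA"] * 4)
    rows, w = reps["taxA"]
    assert len(rows) == 1 and w[0] == 4


def test_build_representatives_two_variant_groups(rng):
    ref = _random_seq(rng)
    var = _mutate(ref, rng.choice(250, size=5, replace=False), rng)  # 0.98 < 0.995
    assert pairwise_identity(ref, var) < 0.995
    reps = build_representatives([ref, ref, var, var], ["t"] * 4)
    rows, w = reps["t"]
    assert len(rows) == 2
    assert sorted(w.tolist()) == [2, 2]


# ----------------------------------------------- similarity distributions


def test_similarity_distributions_single_taxon_no_among(rng):
    seqs = [_random_seq(rng, 100)] * 3
    reps = build_representatives(seqs, ["t"] * 3)
    within, among = similarity_distributions(seqs, ["t"] * 3, reps)
    assert among.size == 0
    assert np.allclose(within, 1.0)


def test_similarity_distributions_match_brute_force(rng):
    """Two sibling taxa at ~0.1 divergence: every within/among value equals
    the directly computed best identity; within ~1, among ~0.8."""
    ref_a = _random_seq(rng)
    ref_b = _mutate(ref_a, rng.choice(250, size=50, replace=False), rng)
    seqs, taxa = [], []
    for ref, t in ((ref_a, "A"), (ref_b, "B")):
        for _ in range(8):
            pos = rng.choice(250, size=int(rng.integers(0, 2)), replace=False)
            seqs.append(_mutate(ref, pos, rng))
            taxa.append(t)
    parent = {"A": "root", "B": "root"}
    reps = build_representatives(seqs, taxa)
    within, among = similarity_distributions(seqs, taxa, reps, parent_of=parent)

    def ungapped(x, y):
        return sum(a == b for a, b in zip(x, y)) / len(x)

    # reconstruct both lists by direct computation, in the same taxon order
    exp_w_ug, exp_a_ug, exp_a_dp = [], [], []
    for t in ("A", "B"):
        rows = [i for i, tx in enumerate(taxa) if tx == t]
        own = [int(r) for r in reps[t][0]]
        sib = [int(r) for r in reps["B" if t == "A" else "A"][0]]
        for i in rows:
            exp_w_ug.append(max(ungapped(seqs[i], seqs[r]) for r in own))
        for i in rows:
            exp_a_ug.append(max(ungapped(seqs[i], seqs[r]) for r in sib))
            exp_a_dp.append(max(pairwise_identity(seqs[i], seqs[r]) for r in sib))
    # uniform-length collections score gap-free: exact agreement there
    assert np.allclose(np.sort(within), np.sort(exp_w_ug), atol=1e-12)
    assert np.allclose(np.sort(among), np.sort(exp_a_ug), atol=1e-12)
    # and the full-alignment values agree to within the small gapped gain
    assert np.allclose(np.sort(among), np.sort(exp_a_dp), atol=0.02)
    assert within.min() > 0.97
    assert 0.75 < among.mean() < 0.85


# ------------------------------------------------------------ optimizer


def test_optimize_threshold_separable_example():
    d = optimize_threshold([0.99, 0.98], [0.80, 0.70])
    assert d.theta == pytest.approx(0.89)
    assert (d.fp, d.fn) == (0, 0)
    assert d.interval == (0.80, 0.98)


def test_optimize_threshold_overlapping_example():
    d = optimize_threshold([0.95, 0.90, 0.85], [0.92, 0.80])
    assert d.theta == pytest.approx(0.875)
    assert (d.fp, d.fn) == (1, 1)


def test_optimize_threshold_empty_among():
    d = optimize_threshold([0.97, 0.99], [])
    assert (d.fp, d.fn) == (0, 0)
    assert 0 < d.theta <= 0.97


def test_optimize_threshold_empty_within_errors():
    with pytest.raises(ValueError):
        optimize_threshold([], [0.5])


def test_optimize_threshold_matches_exhaustive_oracle(rng):
    """>= 1000 random within/among pairs agree exactly with the naive scan."""
    for _ in range(1000):
        nw = int(rng.integers(1, 12))
        na = int(rng.integers(0, 12))
        grid = rng.choice([True, False])
        if grid:  # coarse grid forces heavy ties
            within = np.round(rng.uniform(0.5, 1.0, size=nw), 1)
            among = np.round(rng.uniform(0.3, 0.9, size=na), 1)
        else:
            within = rng.uniform(0.5, 1.0, size=nw)
            among = rng.uniform(0.3, 0.9, size=na)
        d = optimize_threshold(within, among)
        theta, fp, fn, interval = brute_optimize_threshold(within, among)
        assert d.interval == pytest.approx(interval, abs=1e-12)
        assert d.theta == pytest.approx(theta, abs=1e-12)
        assert (d.fp, d.fn) == (fp, fn)


def test_optimize_threshold_sane_interval_when_separable(rng):
    for _ in range(50):
        within = rng.uniform(0.9, 1.0, size=int(rng.integers(1, 10)))
        among = rng.uniform(0.3, 0.8, size=int(rng.integers(1, 10)))
        d = optimize_threshold(within, among)
        assert (d.fp, d.fn) == (0, 0)
        assert among.max() < d.theta <= within.min()


# ------------------------------------------------------ assign/de novo


def test_assign_identical_to_representative(rng):
    ref = _random_seq(rng, 100)
    labels, denovo = assign_or_denovo(
        [ref, ref], {"tax": (np.asarray([0]), np.asarray([5.0]))}, 0.9
    )
    assert list(labels) == ["tax", "tax"]
    assert denovo == []


def test_assign_exact_theta_goes_denovo(rng):
    """Best identity exactly equal to theta is not an assignment."""
    ref = "A" * 250
    query = _mutate(ref, np.arange(25), rng)  # identity exactly 0.9
    assert pairwise_identity(ref, query) == pytest.approx(0.9)
    labels, denovo = assign_or_denovo(
        [ref, query], {"tax": (np.asarray([0]), np.asarray([1.0]))}, 0.9,
        parent="P1", level="species",
    )
    assert labels[0] == "tax"
    assert labels[1] == "P1.denovo_species_1"
    assert denovo == ["P1.denovo_species_1"]


def test_assign_no_representatives_all_denovo(rng):
    a = _random_seq(rng, 100)
    b = _mutate(a, rng.choice(100, size=40, replace=False), rng)
    labels, denovo = assign_or_denovo([a, a, b], {}, 0.9, parent="P1", level="class")
    assert len(denovo) == 2
    assert labels[0] == labels[1] != labels[2]


# ---------------------------------------------------------------- driver


def _placements_for_species(paths: pd.DataFrame, reliable: np.ndarray) -> pd.DataFrame:
    """Placement frame from species paths and a per-seq/level reliability mask."""
    data = {}
    for li, lv in enumerate(LEVELS):
        data[lv] = paths[lv].to_numpy()
        data[f"p_{lv}"] = np.where(reliable[:, li], 0.95, 0.50)
    return pd.DataFrame(data)


def test_driver_all_reliable_recovers_species(small_dataset):
    """With fully reliable placements, OTUs are exactly the true species."""
    tax = small_dataset.taxonomy
    rng = np.random.default_rng(1)
    picks = rng.choice(tax.n_species, size=60)
    seqs = [tax.sequences()[p] for p in picks]
    paths = tax.labels.iloc[picks].reset_index(drop=True)
    plac = _placements_for_species(paths, np.ones((60, 6), dtype=bool))
    res = hierarchical_otu_clustering(seqs, plac)
    otus = res.assignments["otu"]
    assert otus.nunique() == len(set(picks))
    # reliable sequences keep their reliable taxa (hard constraint)
    for li, lv in enumerate(LEVELS):
        leaf = res.assignments[lv].str.rsplit(";", n=1).str[-1]
        assert (leaf == paths[lv]).all()


def test_driver_denovo_lineage_for_alien_read(rng):
    """A single read unreliable below phylum and dissimilar to everything
    becomes a singleton de novo lineage under its phylum."""
    ref = _random_seq(rng)
    alien = _random_seq(rng)
    paths = pd.DataFrame(
        [["P1", "P1C1", "P1C1O1", "P1C1O1F1", "P1C1O1F1G1", "P1C1O1F1G1S1"]] * 2,
        columns=list(LEVELS),
    )
    rel = np.ones((2, 6), dtype=bool)
    rel[1, 1:] = False  # alien: phylum only
    plac = _placements_for_species(paths, rel)
    res = hierarchical_otu_clustering([ref, alien], plac)
    alien_otu = res.assignments.loc[1, "otu"]
    assert "denovo_class_1" in alien_otu
    assert alien_otu.endswith("denovo_species_1")
    assert res.assignments.loc[0, "otu"].endswith("P1C1O1F1G1S1")


def test_driver_unreliable_species_recovered_by_identity():
    """Species-level reliability removed: reads are still grouped into their
    true species de novo, provided species divergence exceeds what the
    genus-level fallback threshold tolerates (no species backbone means
    theta_species := theta_genus)."""
    from aeromyco.synth import TaxonomySpec, build_taxonomy

    tax = build_taxonomy(
        TaxonomySpec(divergences=(0.15, 0.10, 0.08, 0.06, 0.045, 0.08)), seed=21
    )
    rng = np.random.default_rng(5)
    picks = np.repeat(rng.choice(tax.n_species, size=12, replace=False), 6)
    base = tax.codes[picks]
    reads = base.copy()
    mask = rng.random(reads.shape) < 0.002
    reads[mask] = (reads[mask] + rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)) % 4
    paths = tax.labels.iloc[picks].reset_index(drop=True)
    rel = np.ones((len(picks), 6), dtype=bool)
    rel[:, 5] = False  # nothing reliable at species
    plac = _placements_for_species(paths, rel)
    res = hierarchical_otu_clustering(reads, plac)
    from sklearn.metrics import adjusted_rand_score

    ari = adjusted_rand_score(picks, res.assignments["otu"].to_numpy())
    assert ari == pytest.approx(1.0)


def test_driver_empty_input_warns():
    plac = pd.DataFrame(columns=[*LEVELS, *(f"p_{lv}" for lv in LEVELS)])
    res = hierarchical_otu_clustering([], plac)
    assert len(res.assignments) == 0
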