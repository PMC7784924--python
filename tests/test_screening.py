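"""Spike identification, reliability, tallies, exclusion, pre-clustering."""

import numpy as np
import pandas as pd
import pytest

from aeromyco.levels import LEVELS
from aeromyco.screening import (
    classify_reliability,
    deepest_reliable_levels,
    exclude_small_samples,
    identify_spikes,
    precluster,
    screen_reads,
    tally_samples,
)


def _mutated(ref, k, rng):
    out = np.frombuffer(ref.encode(), dtype=np.uint8).copy()
    lut = {65: "CGT", 67: "AGT", 71: "ACT", 84: "ACG"}
    pos = rng.choice(len(ref), size=k, replace=False)
    s = list(ref)
    for p in pos:
        s[p] = lut[out[p]][int(rng.integers(0, 3))]
    return "".join(s)


# ------------------------------------------------------------- spikes


def test_identify_spikes_boundaries(rng):
    ref = "".join(np.asarray(list("ACGT"))[rng.choice(4, size=250)])
    exact = ref
    at_96 = _mutated(ref, 10, rng)  # identity 0.96 >= 0.95 -> spike
    at_90 = _mutated(ref, 25, rng)  # identity 0.90 < 0.95 -> not spike
    flags = identify_spikes([exact, at_96, at_90], [ref], threshold=0.95)
    assert flags.tolist() == [True, True, False]


def test_identify_spikes_empty_refs_error():
    with pytest.raises(ValueError, match="spike"):
        identify_spikes(["ACGT"], [])


def test_identify_spikes_variable_length_path(rng):
    ref = "ACGTACGTACGTACGTACGT"
    flags = identify_spikes([ref, ref + "A", "TTTTTTTTTTTTTTTTTTTT"], [ref])
    assert flags.tolist() == [True, True, False]


# -------------------------------------------------------- reliability


def test_reliability_prefix_rule_examples():
    frame = pd.DataFrame(
        [
            # reliable through genus: ancestors 0.95, genus 0.91
            dict(p_phylum=0.95, p_class=0.95, p_order=0.95, p_family=0.95,
                 p_genus=0.91, p_species=0.5),
            # 0.90 is not > 0.90: stops at family
            dict(p_phylum=0.95, p_class=0.95, p_order=0.95, p_family=0.95,
                 p_genus=0.90, p_species=0.5),
            # broken prefix: class unreliable caps at phylum despite order 0.99
            dict(p_phylum=0.95, p_class=0.50, p_order=0.99, p_family=0.5,
                 p_genus=0.5, p_species=0.5),
            dict(p_phylum=0.50, p_class=0.95, p_order=0.95, p_family=0.5,
                 p_genus=0.5, p_species=0.5),
        ]
    )
    out = classify_reliability(frame)
    assert out.tolist() == ["genus", "family", "phylum", "none"]


def test_reliability_missing_phylum_errors():
    with pytest.raises(ValueError, match="p_phylum"):
        classify_reliability(pd.DataFrame({"p_class": [0.5]}))


def test_reliability_rejects_out_of_range():
    probs = np.full((1, 6), 0.5)
    probs[0, 2] = 1.5
    with pytest.raises(ValueError):
        deepest_reliable_levels(probs)


def test_reliability_monotone_in_probabilities(rng):
    """Raising any probability never makes the deepest level shallower."""
    for _ in range(50):
        p = rng.uniform(0, 1, size=(1, 6))
        d0 = deepest_reliable_levels(p)[0]
        q = p.copy()
        j = int(rng.integers(0, 6))
        q[0, j] = min(1.0, q[0, j] + rng.uniform(0, 1 - q[0, j]))
        assert deepest_reliable_levels(q)[0] >= d0


# ------------------------------------------------------------ tallies


def test_tally_defining_formula():
    cats = np.array([0] * 100 + [2] * 400 + [1] * 500, dtype=np.int8)
    t = tally_samples(["s1"] * 1000, cats)
    row = t.iloc[0]
    assert (row["n"], row["s"], row["p"], row["f"]) == (1000, 100, 400, 500)
    assert row["w"] == pytest.approx(5.0)


def test_tally_all_spike_w_zero():
    t = tally_samples(["s1"] * 10, np.zeros(10, dtype=np.int8))
    assert t.iloc[0]["w"] == 0.0
    assert not t.iloc[0]["flagged"]


def test_tally_no_spikes_flagged():
    t = tally_samples(["s1"] * 10, np.ones(10, dtype=np.int8))
    assert t.iloc[0]["flagged"]
    assert np.isnan(t.iloc[0]["w"])


def test_exclusion_boundaries():
    counts = pd.DataFrame(
        {"sample_id": ["a", "b", "c"], "n": [9_999, 10_000, 20_000],
         "s": [1, 1, 1], "p": [0, 0, 0], "f": [1, 1, 1], "w": [1.0] * 3,
         "flagged": [False] * 3}
    )
    kept, dropped = exclude_small_samples(counts)
    assert dropped == ["a"]
    assert kept["sample_id"].tolist() == ["b", "c"]
    kept2, dropped2 = exclude_small_samples(counts, min_reads=1000)
    assert dropped2 == []


# ------------------------------------------------------- screen_reads


def test_screen_partition_and_truth(small_dataset):
    ds = small_dataset
    sample_ids = ds.samples["sample_id"].to_numpy(dtype=object)[ds.sample_idx]
    res = screen_reads(
        ds.codes, sample_ids, ds.spike_seqs, ds.placement_probs(),
        placement_rows=ds.fungal_rows,
    )
    assert res.counts["n"].sum() == ds.n_reads
    assert (res.counts["n"] == res.counts[["s", "p", "f"]].sum(axis=1)).all()
    # spike recall: every true spike read is flagged (error rate is tiny)
    true_spike = ds.category == 0
    assert (res.categories[true_spike] == 0).mean() > 0.999


def test_screen_error_free_exact_recovery():
    """With rho=1 and no errors, screening reproduces the drawn composition
    exactly and w equals the realized f/s."""
    from conftest import small_config
    from aeromyco.synth import simulate_study

    rho = {lv: 1.0 for lv in LEVELS}
    ds = simulate_study(small_config(seed=3, mean_depth=1000.0, error_rate=0.0,
                                     reliability=rho))
    sample_ids = ds.samples["sample_id"].to_numpy(dtype=object)[ds.sample_idx]
    res = screen_reads(ds.codes, sample_ids, ds.spike_seqs, ds.placement_probs(),
                       placement_rows=ds.fungal_rows)
    assert np.array_equal(res.categories, ds.category)
    truth = ds.sample_truth.set_index("sample_id")
    merged = res.counts.set_index("sample_id")
    assert (merged["s"] == truth.loc[merged.index, "n_spike"]).all()
    assert (merged["f"] == truth.loc[merged.index, "n_fungal"]).all()
    np.testing.assert_allclose(
        merged["w"], truth.loc[merged.index, "n_fungal"] / truth.loc[merged.index, "n_spike"]
    )


# --------------------------------------------------------- precluster


def _plac_frame(read_ids, taxa="T", prob=0.95):
    n = len(read_ids)
    data = {"read_id": read_ids}
    for lv in LEVELS:
        data[lv] = [taxa] * n
        data[f"p_{lv}"] = [prob] * n
    return pd.DataFrame(data)


def test_precluster_all_identical():
    seqs = ["ACGT" * 60] * 7
    ids = [f"s|r{i}" for i in range(7)]
    res = precluster(seqs, ids, ["s"] * 7, placements=_plac_frame(ids))
    assert res.n == 1
    assert res.weights[0] == 7
    assert res.ids[0] == "s|r0"
    assert res.sample_counts.sum() == 7


def test_precluster_threshold_one_is_dereplication(rng):
    a = "".join(np.asarray(list("ACGT"))[rng.choice(4, size=250)])
    b = _mutated(a, 1, rng)
    seqs = [a, b, a, b, a]
    ids = [f"s|r{i}" for i in range(5)]
    res = precluster(seqs, ids, ["s"] * 5, threshold=1.0)
    assert res.n == 2
    assert sorted(res.weights.tolist()) == [2, 3]


def test_precluster_two_species_brute_force_verified(rng):
    """Two species at ~0.90 identity with sub-0.5% errors: exactly two
    representatives, verified by exhaustive pairwise identity."""
    from aeromyco.clustering import pairwise_identity

    ref_a = "".join(np.asarray(list("ACGT"))[rng.choice(4, size=250)])
    ref_b = _mutated(ref_a, 25, rng)
    seqs = [ref_a, ref_b]
    group = [0, 1]
    for g, ref in ((0, ref_a), (1, ref_b)):
        for k in (0, 0, 1):  # at most one error, so within-pairs stay >= 0.995
            seqs.append(_mutated(ref, k, rng) if k else ref)
            group.append(g)
    ident = np.array([[pairwise_identity(x, y) for y in seqs] for x in seqs])
    group = np.asarray(group)
    within = ident[np.ix_(group == 0, group == 0)]
    between = ident[np.ix_(group == 0, group == 1)]
    assert within.min() >= 0.995 and between.max() < 0.995
    ids = [f"s|r{i}" for i in range(len(seqs))]
    res = precluster(seqs, ids, ["s"] * len(seqs))
    assert res.n == 2


def test_precluster_weight_conservation_and_labels(small_dataset):
    ds = small_dataset
    rows = ds.fungal_rows[:5000]
    ids = [f"x|r{i:07d}" for i in range(len(rows))]
    res = precluster(ds.codes[rows], ids, ["x"] * len(rows))
    assert res.weights.sum() == len(rows)
    assert res.read_labels is not None and len(res.read_labels) == len(rows)
    counts = np.bincount(res.read_labels, minlength=res.n)
    assert np.array_equal(counts, res.weights.astype(int))


def test_precluster_inherits_modal_placement():
    seqs = ["ACGT" * 60] * 3
    ids = ["s|r0", "s|r1", "s|r2"]
    plac = _plac_frame(ids)
    for lv in LEVELS:
        plac.loc[2, f"p_{lv}"] = 0.50  # minority pattern
    res = precluster(seqs, ids, ["s"] * 3, placements=plac)
    assert res.n == 1
    assert res.placements.loc[0, "p_species"] == 0.95
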