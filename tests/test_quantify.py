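"""Counting rules, the fixed-dispersion exact test and its enumeration
oracle, KS oracle, and tag matching vs a brute-force matcher."""

import math

import numpy as np
import pandas as pd
import pytest

from molmatch.quantify import (CountMatrix, de_by_platform, ks_length_bias,
                               lognormalize, match_tags, nb_exact_test,
                               pseudo_bulk, pseudobulk_correlation,
                               stratify_by_length_gc)


def _matrix(data, platform="short", meta=None):
    counts = pd.DataFrame(data)
    if meta is None:
        meta = pd.DataFrame({"length": 1000.0, "gc": 0.5, "is_mito": False,
                             "is_ribo": False, "biotype": "protein_coding"},
                            index=counts.index)
    return CountMatrix(counts, meta, platform)


# ---------------------------------------------------------------------------
# counting rules on the pipeline run

def test_umi_semantics_one_count_per_tag(run):
    """Each (gene, cell, tag) contributes at most once: matrix totals never
    exceed the number of counted tags."""
    assert run.cm_short.total <= len(run.short_survivors)
    assert run.cm_long_unfiltered.total <= len(run.long_survivors)


def test_filtered_counts_monotone(run):
    unf = run.cm_long_unfiltered.counts
    flt = run.cm_long_filtered.counts
    assert (flt <= unf).all().all()
    assert flt.to_numpy().sum() < unf.to_numpy().sum()


def test_pseudo_bulk_conservation(run):
    pb = pseudo_bulk(run.cm_short)
    assert int(pb.sum()) == run.cm_short.total
    pb2 = pseudo_bulk(_matrix({"c1": [3], "c2": [4]}))
    assert int(pb2.iloc[0]) == 7


def test_lognormalize_closed_form():
    cm = _matrix({"c1": [1, 99]})
    norm = lognormalize(cm, scale_factor=1e4)
    assert norm.loc[norm.index[0], "c1"] == pytest.approx(math.log(101), rel=1e-9)
    cm0 = _matrix({"c1": [0, 100]})
    assert lognormalize(cm0).iloc[0, 0] == 0.0


def test_lognormalize_depth_invariance():
    a = _matrix({"c1": [5, 15, 30]})
    b = _matrix({"c1": [10, 30, 60]})
    pd.testing.assert_frame_equal(lognormalize(a), lognormalize(b))


# ---------------------------------------------------------------------------
# exact test: enumeration oracle

def _oracle_p(a, b, dispersion):
    """Independent enumeration: lgamma-based NB split probabilities and the
    doubled smaller tail."""
    n = a + b
    if n == 0:
        return 1.0
    r = 1.0 / dispersion
    mu = n / 2.0
    logq = math.log(mu / (mu + r))
    logp_r = r * math.log(r / (mu + r))

    def lpmf(k):
        return (math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
                + logp_r + k * logq)

    probs = [math.exp(lpmf(k) + lpmf(n - k)) for k in range(n + 1)]
    z = sum(probs)
    probs = [p / z for p in probs]
    lower = sum(probs[: a + 1])
    upper = sum(probs[a:])
    return min(1.0, 2.0 * min(lower, upper))


def test_exact_test_symmetric_and_degenerate():
    assert nb_exact_test(5, 5, 100, 100) == 1.0
    assert nb_exact_test(0, 0, 100, 100) == 1.0


def test_exact_test_matches_enumeration_oracle():
    for n in range(0, 201, 1):
        for a in {0, n // 4, n // 2, n}:
            b = n - a
            got = nb_exact_test(a, b, 1000, 1000, 0.1)
            want = _oracle_p(a, b, 0.1)
            assert got == pytest.approx(want, abs=1e-10), (n, a)


def test_exact_test_extreme_split():
    p = nb_exact_test(0, 40, 500, 500, 0.1)
    assert p == pytest.approx(_oracle_p(0, 40, 0.1), abs=1e-10)
    assert p < 0.05


def test_exact_test_null_superuniform():
    """Under the null (equal means, dispersion 0.1) the rejection rate at
    alpha=0.05 stays at or below nominal (plus 3-SD slack)."""
    rng = np.random.default_rng(2024)
    n_genes = 2000
    r = 1 / 0.1
    mu = 50
    ya = rng.negative_binomial(r, r / (r + mu), n_genes)
    yb = rng.negative_binomial(r, r / (r + mu), n_genes)
    lib = float(mu * n_genes)
    rej = sum(nb_exact_test(a, b, lib, lib) < 0.05
              for a, b in zip(ya, yb)) / n_genes
    assert rej <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_genes)


def test_exact_test_validates_inputs():
    with pytest.raises(ValueError):
        nb_exact_test(-1, 5, 10, 10)
    with pytest.raises(ValueError):
        nb_exact_test(1, 5, 0, 10)
    with pytest.raises(ValueError):
        nb_exact_test(1, 5, 10, 10, dispersion=0)


# ---------------------------------------------------------------------------
# platform DE

def test_de_identical_pseudobulks_all_equal():
    pb = pd.Series([100, 50, 10, 0], index=list("abcd"))
    de = de_by_platform(pb, pb)
    assert (de["direction"] == "equal").all()


def test_de_detects_injected_excess():
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(200)]
    base = pd.Series(rng.poisson(200, 200), index=genes, dtype=float)
    boosted = base.copy()
    boosted.iloc[:5] *= 10
    de = de_by_platform(boosted, base)
    assert set(de.index[de["direction"] == "higher_A"]) >= set(genes[:3])
    assert (de["direction"].iloc[5:] == "equal").mean() > 0.95


def test_de_includes_genes_missing_from_one_side():
    a = pd.Series([100], index=["g1"])
    b = pd.Series([100, 80], index=["g1", "g2"])
    de = de_by_platform(a, b)
    assert set(de.index) == {"g1", "g2"}
    assert de.loc["g2", "count_a"] == 0


def test_bh_monotone():
    pb_a = pd.Series(np.arange(1, 50) * 10, index=[f"g{i}" for i in range(49)])
    pb_b = pd.Series(np.arange(49, 0, -1) * 10, index=[f"g{i}" for i in range(49)])
    de = de_by_platform(pb_a, pb_b).sort_values("pvalue")
    assert (np.diff(de["padj"].to_numpy()) >= -1e-12).all()


def test_stratify_means_and_t():
    de = pd.DataFrame({"direction": ["higher_A", "higher_A", "higher_B",
                                     "equal", "equal"]},
                      index=list("abcde"))
    meta = pd.DataFrame({"length": [1000, 2000, 3000, 1500, 2500],
                         "gc": [0.4, 0.6, 0.5, 0.5, 0.5]},
                        index=list("abcde"))
    out = stratify_by_length_gc(de, meta)
    assert out["higher_A"]["mean_length"] == pytest.approx(1500)
    assert out["higher_B"]["mean_length"] == pytest.approx(3000)
    assert out["higher_B"]["t_vs_equal"] is None  # group of one


# ---------------------------------------------------------------------------
# KS length bias

def test_ks_identical_and_disjoint():
    a = list(range(100))
    stat, _ = ks_length_bias(a, a)
    assert stat == 0.0
    stat, p = ks_length_bias(list(range(100)), list(range(200, 300)))
    assert stat == 1.0
    assert p < 1e-6


def test_ks_matches_bruteforce_ecdf():
    rng = np.random.default_rng(11)
    x = rng.exponential(500, 400)
    keep = rng.random(400) < np.clip(x / 1000, 0, 1)  # filter favours long
    filtered = x[keep]
    stat, _ = ks_length_bias(filtered, x)
    # brute-force ECDF scan
    grid = np.sort(np.concatenate([filtered, x]))
    f1 = np.searchsorted(np.sort(filtered), grid, side="right") / len(filtered)
    f2 = np.searchsorted(np.sort(x), grid, side="right") / len(x)
    assert stat == pytest.approx(np.max(np.abs(f1 - f2)), abs=1e-12)


def test_ks_empty_rejected():
    with pytest.raises(ValueError):
        ks_length_bias([], [1, 2, 3])


# ---------------------------------------------------------------------------
# tag matching

def _brute_force_match(short_tags, long_tags, lengths, edges=(7, 8, 9, 10, 11)):
    shared, short_only, long_only = set(), set(), set()
    for t in short_tags:
        if t in long_tags:
            shared.add(t)
        else:
            short_only.add(t)
    for t in long_tags:
        if t not in short_tags:
            long_only.add(t)
    bins = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        n_long = n_shared = 0
        for t in long_tags:
            if t in lengths and lo <= math.log2(max(lengths[t], 1)) < hi:
                n_long += 1
                n_shared += t in shared
        bins[f"{lo}-{hi}"] = (n_long, n_shared)
    return shared, short_only, long_only, bins


def test_match_tags_trivial_cases():
    s = {"A" * 28, "C" * 28}
    out = match_tags(s, s)
    assert out.shared == s and not out.short_only and not out.long_only
    out2 = match_tags({"A" * 28}, {"C" * 28})
    assert not out2.shared
    assert out2.n_union == 2


def test_match_tags_equals_bruteforce(run):
    """The matcher agrees exactly with an independent quadratic matcher."""
    lengths = {m.tag_key: float(m.length) for m in run.molecules}
    short = sorted(run.short_survivors)[:2000]
    long_ = sorted(run.long_survivors)[:2000]
    out = match_tags(short, long_, lengths)
    shared, s_only, l_only, bins = _brute_force_match(short, long_, lengths)
    assert out.shared == shared
    assert out.short_only == s_only
    assert out.long_only == l_only
    for _, row in out.bin_table.iterrows():
        n_long, n_shared = bins[row["bin"]]
        assert (row["n_long"], row["n_shared"]) == (n_long, n_shared)


def test_pearson_identical_matrices_is_one(run):
    cm = run.cm_short
    assert pseudobulk_correlation(cm, cm) == pytest.approx(1.0, abs=1e-12)
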