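"""Co-expression, ceRNA triplet assembly and hypergeometric enrichment."""

import numpy as np
import pandas as pd
import pytest

from circsponge import network as net
from oracles import hypergeom_tail, pearson_direct


# --- Pearson ----------------------------------------------------------------


def test_pearson_affine_relation_is_exactly_one():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    r, p = net.pearson_with_p(x, 2 * x + 3)
    assert r == pytest.approx(1.0)
    assert p < 1e-8


def test_pearson_matches_direct_formula_oracle():
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
    r, p = net.pearson_with_p(x, y)
    r0, p0 = pearson_direct(x, y)
    assert r == pytest.approx(r0, abs=1e-12)
    assert p == pytest.approx(p0, abs=1e-12)


def test_pearson_n3_has_no_power():
    """At n=3 (1 df, a Cauchy reference) even |r| close to 0.997 — the exact
    r whose two-sided p equals 0.05 — is not significant."""
    for r_target in (0.9, 0.99, 0.996):
        # build a 3-point dataset with exactly this correlation
        x = np.array([-1.0, 0.0, 1.0])
        resid = np.array([1.0, -2.0, 1.0])
        resid = resid / np.sqrt((resid**2).sum()) * np.sqrt((x**2).sum())
        y = x * r_target + resid * np.sqrt(1 - r_target**2)
        r, p = net.pearson_with_p(x, y)
        assert r == pytest.approx(r_target, abs=1e-9)
        assert p > 0.05


def test_pearson_zero_variance_returns_nan_marker():
    r, p = net.pearson_with_p([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
    assert np.isnan(r) and np.isnan(p)


def test_pearson_needs_three_points():
    with pytest.raises(ValueError):
        net.pearson_with_p([1.0, 2.0], [2.0, 4.0])


# --- co-expression screen ---------------------------------------------------


def _expr(rows: dict[str, list[float]]) -> pd.DataFrame:
    cols = [f"s{i}" for i in range(len(next(iter(rows.values()))))]
    return pd.DataFrame(rows, index=cols).T


def test_coexpression_finds_planted_pattern_pair():
    pattern = [10, 11, 9, 100, 105, 98, 1000, 990, 1012]
    circ = _expr({"c1": pattern, "c2": [50, 52, 49, 51, 50, 48, 50, 53, 47]})
    mrna = _expr({"g1": [p * 1.1 for p in pattern], "g2": [9, 3, 7, 5, 2, 8, 4, 6, 1]})
    pairs = net.coexpression_pairs(circ, mrna)
    assert ("c1", "g1") in set(zip(pairs["circ"], pairs["mrna"]))
    assert len(pairs) == 1


def test_coexpression_rejects_mismatched_samples():
    circ = _expr({"c1": [1, 2, 3]})
    mrna = _expr({"g1": [1, 2, 3]}).rename(columns={"s2": "sX"})
    with pytest.raises(ValueError, match="not shared"):
        net.coexpression_pairs(circ, mrna)


def test_coexpression_no_thresholds_returns_all_pairs():
    rng = np.random.default_rng(3)
    circ = pd.DataFrame(rng.poisson(50, (4, 9)), index=list("abcd"))
    mrna = pd.DataFrame(rng.poisson(50, (5, 9)), index=list("vwxyz"))
    mrna.columns = circ.columns
    pairs = net.coexpression_pairs(circ, mrna, r_min=0.0, alpha=1.01)
    assert len(pairs) == 20


def test_coexpression_false_pair_rate_under_independent_noise():
    """Independent NB noise, 9 samples: << 1% of random pairs pass the
    |r| >= 0.9, p < 0.01 screen."""
    rng = np.random.default_rng(42)
    n = 100  # 100 x 100 = 10,000 pairs
    lam = rng.gamma(20.0, np.full((n, 9), 5.0))
    circ = pd.DataFrame(rng.poisson(lam), index=[f"c{i}" for i in range(n)])
    lam2 = rng.gamma(20.0, np.full((n, 9), 5.0))
    mrna = pd.DataFrame(rng.poisson(lam2), index=[f"g{i}" for i in range(n)])
    mrna.columns = circ.columns
    pairs = net.coexpression_pairs(circ, mrna)
    assert len(pairs) / (n * n) <= 0.01


def test_positive_only_mode_drops_anticorrelated():
    x = [1, 2, 3, 10, 12, 11, 100, 95, 102]
    circ = _expr({"c1": x})
    mrna = _expr({"g1": x[::-1]})
    assert len(net.coexpression_pairs(circ, mrna)) == 1
    assert len(net.coexpression_pairs(circ, mrna, positive_only=True)) == 0


# --- ceRNA assembly ---------------------------------------------------------


def _sites(rows):
    return pd.DataFrame(rows, columns=["mirna", "target", "kind"])


def test_build_cerna_requires_site_on_both_molecules():
    sites = _sites(
        [("m1", "c1", "circRNA"), ("m1", "g1", "mRNA"), ("m2", "c1", "circRNA")]
    )
    coexpr = pd.DataFrame({"circ": ["c1"], "mrna": ["g1"], "r": [0.95], "p": [1e-4]})
    trips, graph = net.build_cerna(["c1"], ["m1", "m2"], ["g1"], sites, coexpr)
    assert list(map(tuple, trips[["circ", "mirna", "mrna"]].to_numpy())) == [
        ("c1", "m1", "g1")
    ]
    assert graph.nodes["c1"]["node_type"] == "circRNA"
    assert graph.edges[("c1", "g1")]["edge_type"] == "coexpression"


def test_build_cerna_empty_dec_gives_empty_network():
    sites = _sites([("m1", "c1", "circRNA"), ("m1", "g1", "mRNA")])
    coexpr = pd.DataFrame({"circ": ["c1"], "mrna": ["g1"], "r": [0.95], "p": [1e-4]})
    trips, graph = net.build_cerna([], ["m1"], ["g1"], sites, coexpr)
    assert trips.empty and graph.number_of_nodes() == 0


def test_build_cerna_matches_brute_force_enumeration():
    rng = np.random.default_rng(9)
    circs = [f"c{i}" for i in range(20)]
    mirs = [f"m{i}" for i in range(15)]
    genes = [f"g{i}" for i in range(30)]
    dec = [c for c in circs if rng.random() < 0.6]
    dem = [m for m in mirs if rng.random() < 0.6]
    deg = [g for g in genes if rng.random() < 0.6]
    site_rows = []
    for m in mirs:
        for c in circs:
            if rng.random() < 0.15:
                site_rows.append((m, c, "circRNA"))
        for g in genes:
            if rng.random() < 0.15:
                site_rows.append((m, g, "mRNA"))
    coexpr_rows = [
        {"circ": c, "mrna": g, "r": 0.93, "p": 1e-3}
        for c in circs
        for g in genes
        if rng.random() < 0.2
    ]
    sites = _sites(site_rows)
    coexpr = pd.DataFrame(coexpr_rows)
    trips, _ = net.build_cerna(dec, dem, deg, sites, coexpr)
    got = set(map(tuple, trips[["circ", "mirna", "mrna"]].to_numpy()))
    # exhaustive oracle over all (c, m, g) combinations
    site_set = {(r[0], r[1]) for r in site_rows if r[2] == "circRNA"}
    gsite_set = {(r[0], r[1]) for r in site_rows if r[2] == "mRNA"}
    coexpr_set = {(d["circ"], d["mrna"]) for d in coexpr_rows}
    expected = {
        (c, m, g)
        for c in dec
        for m in dem
        for g in deg
        if (m, c) in site_set and (m, g) in gsite_set and (c, g) in coexpr_set
    }
    assert got == expected


def test_network_graphml_round_trip_preserves_types(tmp_path):
    sites = _sites([("m1", "c1", "circRNA"), ("m1", "g1", "mRNA")])
    coexpr = pd.DataFrame({"circ": ["c1"], "mrna": ["g1"], "r": [0.95], "p": [1e-4]})
    _, graph = net.build_cerna(["c1"], ["m1"], ["g1"], sites, coexpr)
    path = tmp_path / "net.graphml"
    net.write_graphml(graph, path)
    back = net.read_graphml(path)
    assert set(back.nodes) == set(graph.nodes)
    assert {n: d["node_type"] for n, d in back.nodes(data=True)} == {
        n: d["node_type"] for n, d in graph.nodes(data=True)
    }
    assert set(map(frozenset, back.edges)) == set(map(frozenset, graph.edges))


# --- enrichment -------------------------------------------------------------


def test_hypergeometric_exact_small_case():
    universe = [f"u{i}" for i in range(10)]
    term = {"T": universe[:5]}
    query = universe[:4]
    res = net.enrich_hypergeometric(query, universe, term)
    assert res.loc[0, "p"] == pytest.approx(5 / 210, abs=1e-12)
    assert res.loc[0, "p"] == pytest.approx(hypergeom_tail(10, 5, 4, 4), abs=1e-12)


def test_hypergeometric_zero_overlap_tail_is_one():
    universe = [f"u{i}" for i in range(10)]
    res = net.enrich_hypergeometric(universe[5:9], universe, {"T": universe[:3]})
    row = res.set_index("term").loc["T"]
    assert row["k"] == 0 and row["p"] == pytest.approx(1.0)


def test_hypergeometric_query_equals_universe_saturates():
    universe = [f"u{i}" for i in range(8)]
    res = net.enrich_hypergeometric(universe, universe, {"T": universe[:4]})
    assert res.loc[0, "p"] == pytest.approx(1.0)


def test_hypergeometric_rejects_query_outside_universe():
    with pytest.raises(ValueError, match="outside"):
        net.enrich_hypergeometric(["x"], ["a", "b"], {"T": ["a"]})


def test_hypergeometric_matches_enumeration_random_cases():
    rng = np.random.default_rng(17)
    universe = [f"u{i}" for i in range(25)]
    for _ in range(20):
        K = int(rng.integers(1, 20))
        nq = int(rng.integers(1, 20))
        term_genes = list(rng.choice(universe, K, replace=False))
        query = list(rng.choice(universe, nq, replace=False))
        res = net.enrich_hypergeometric(query, universe, {"T": term_genes})
        k = len(set(term_genes) & set(query))
        assert res.loc[0, "p"] == pytest.approx(
            hypergeom_tail(25, K, nq, k), abs=1e-12
        )
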