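"""Calling from labeled neighborhoods; coverage/accuracy bookkeeping."""

import numpy as np
import pytest

from hlagraph.graph_labeling import Labeling, SimilarityGraph
from hlagraph.hla_typing import (
    Call,
    EvalMetrics,
    HLACallSet,
    compute_metrics,
    hla_type,
    neighbor_labels,
)


def _graph(w):
    n = w.shape[0]
    vertices = [(f"i{k // 2}", k % 2) for k in range(n)]
    return SimilarityGraph(vertices, w, [])


def test_neighbor_labels_single_and_tied():
    w = np.zeros((4, 4))
    w[0, 2] = w[2, 0] = 0.8
    g = _graph(w)
    lab = Labeling([None, None, "a", None])
    assert neighbor_labels(g, lab, 0) == (0.8, {"a"})
    w[0, 3] = w[3, 0] = 0.8
    lab = Labeling([None, None, "a", "b"])
    wm, labels = neighbor_labels(_graph(w), lab, 0)
    assert wm == 0.8 and labels == {"a", "b"}


def test_neighbor_labels_ignores_unlabeled_and_matches_scan_oracle():
    rng = np.random.default_rng(0)
    for _ in range(30):
        n = 8
        w = rng.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        labels = [rng.choice(["a", "b", None]) for _ in range(n)]
        g = _graph(w)
        v = int(rng.integers(0, n))
        wm, got = neighbor_labels(g, Labeling(list(labels)), v)
        labeled = [u for u in range(n) if labels[u] is not None and u != v]
        if labeled:
            expect_w = max(w[v, u] for u in labeled)
            expect_l = {
                labels[u] for u in labeled if abs(w[v, u] - expect_w) <= 1e-12
            }
        else:
            expect_w, expect_l = 0.0, set()
        assert wm == pytest.approx(expect_w)
        assert got == expect_l


def _typing_graph():
    # i0, i1 labeled references; i2 untyped
    w = np.zeros((6, 6))
    w[4, 0] = w[0, 4] = 1.0  # i2 copy 0 ~ i0 copy 0 ("a")
    w[5, 2] = w[2, 5] = 0.9  # i2 copy 1 ~ i1 copy 0 ("b")
    g = _graph(w)
    lab = Labeling(["a", "a", "b", "c", None, None])
    return g, lab


def test_hla_type_calls_from_unique_neighbors():
    g, lab = _typing_graph()
    calls, final = hla_type(g, lab, ["i2"], t_s=0.65)
    assert calls["i2"].alleles == ("a", "b")
    assert calls["i2"].status == "called"
    assert final.labels[4] == "a" and final.labels[5] == "b"


def test_hla_type_below_threshold_is_no_call():
    g, lab = _typing_graph()
    g.weights[5, 2] = g.weights[2, 5] = 0.5  # w_m(V2) < 0.65
    calls, _ = hla_type(g, lab, ["i2"], t_s=0.65)
    assert calls["i2"].alleles is None
    assert calls["i2"].status == "no_call"
    assert calls["i2"].support == (1.0, 0.5)


def test_hla_type_resolves_ambiguity_over_candidate_pairs():
    # both copies tie between two labels at their maximum weight; every
    # candidate pair then scores w_m(V1) + w_m(V2) under the best-edge
    # pair weight, so the deterministic lexicographic rule decides
    w = np.zeros((8, 8))
    # references: v0="a", v1="b", v2="c"
    w[6, 0] = w[0, 6] = 0.9  # V1 ties to a and b
    w[6, 1] = w[1, 6] = 0.9
    w[7, 1] = w[1, 7] = 0.8  # V2 ties to b and c
    w[7, 2] = w[2, 7] = 0.8
    g = _graph(w)
    lab = Labeling(["a", "b", "c", None, None, None, None, None])
    calls, _ = hla_type(g, lab, ["i3"], t_s=0.65)

    def support(v, x):
        return max(
            (g.weights[v, u] for u in range(8) if lab.labels[u] == x), default=0
        )

    scores = {
        (g1, g2): max(
            support(6, g1) + support(7, g2), support(6, g2) + support(7, g1)
        )
        for g1 in ("a", "b")
        for g2 in ("b", "c")
    }
    assert all(s == pytest.approx(0.9 + 0.8) for s in scores.values())
    assert calls["i3"].alleles == ("a", "b")  # lexicographically first pair
    assert calls["i3"].status == "called"


def test_metrics_direct_ratios():
    m = EvalMetrics(10, 8, 6)
    assert m.coverage == pytest.approx(80.0)
    assert m.accuracy == pytest.approx(75.0)
    assert EvalMetrics(4, 0, 0).accuracy is None


def test_metrics_unordered_pair_comparison():
    truth = {"x": ("0101", "0201"), "y": ("0101", "0201"), "z": ("0101", "0201")}
    calls = HLACallSet(
        {"x": Call("x", ("0201", "0101"), (1, 1), "called")}
    )
    m = compute_metrics(truth, calls, 4, ["x"])
    assert (m.n_analyzed, m.n_called, m.n_correct) == (2, 2, 2)


def test_metrics_exclude_singleton_and_unresolved_alleles():
    truth = {
        "x": ("0101", "2401"),  # 2401 occurs once in the data -> excluded
        "y": ("0101", "02"),  # "02" unresolved at 4 digits -> excluded
    }
    calls = HLACallSet(
        {
            "x": Call("x", ("0101", "2402"), (1, 1), "called"),
            "y": Call("y", ("0101", "0201"), (1, 1), "called"),
        }
    )
    m = compute_metrics(truth, calls, 4, ["x", "y"])
    assert m.n_analyzed == 2  # one chromosome per individual survives
    assert m.n_called == 2
    assert m.n_correct == 2  # the excluded mismatches do not count


def test_metrics_two_digit_resolution():
    truth = {"x": ("0101", "0102"), "y": ("0101", "0102")}
    calls = HLACallSet({"x": Call("x", ("0102", "0101"), (1, 1), "called")})
    m = compute_metrics(truth, calls, 2, ["x"])
    # at 2 digits both truth alleles collapse to "01" (count 4, no singleton)
    assert (m.n_analyzed, m.n_called, m.n_correct) == (2, 2, 2)


def test_metrics_uncalled_individuals_lower_coverage():
    truth = {"x": ("0101", "0201"), "y": ("0101", "0201")}
    calls = HLACallSet({"x": Call("x", None, (0.2, 0.1), "no_call")})
    m = compute_metrics(truth, calls, 4, ["x"])
    assert (m.n_analyzed, m.n_called, m.n_correct) == (2, 0, 0)
    assert m.coverage == 0.0
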