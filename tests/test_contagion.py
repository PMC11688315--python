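"""Copied-visit detection, graph construction and group metrics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cagecontagion as cc
from cagecontagion.contagion import possible_edges
from cagecontagion.events import ValidationError

from conftest import make_visits, random_valid_log
from oracles import copied_visits_bruteforce

WINDOW = (0.0, 1000.0)


class TestDetection:
    def test_single_visit_yields_nothing(self):
        v = make_visits([("A", "K1", 10.0, 20.0, 0, 0.0)])
        assert len(cc.detect_copied_visits(v, WINDOW)) == 0

    def test_latency_boundary_is_strict(self):
        # leader exits at 100; follower at +3.9 copies, at exactly +4.0 does not
        v = make_visits([
            ("A", "K1", 90.0, 100.0, 0, 0.0),
            ("B", "K1", 103.9, 110.0, 0, 0.0),
        ])
        out = cc.detect_copied_visits(v, WINDOW)
        assert len(out) == 1 and out.loc[0, "latency"] == pytest.approx(3.9)
        v2 = make_visits([
            ("A", "K1", 90.0, 100.0, 0, 0.0),
            ("B", "K1", 104.0, 110.0, 0, 0.0),
        ])
        assert len(cc.detect_copied_visits(v2, WINDOW)) == 0

    def test_zero_latency_counts(self):
        v = make_visits([
            ("A", "K1", 0.0, 10.0, 0, 0.0),
            ("B", "K1", 10.0, 15.0, 0, 0.0),
        ])
        out = cc.detect_copied_visits(v, WINDOW)
        assert len(out) == 1 and out.loc[0, "latency"] == 0.0

    def test_chain_yields_one_event_per_link(self):
        # A -> B -> C: every visit re-demonstrates the corner
        v = make_visits([
            ("A", "K1", 0.0, 10.0, 0, 0.0),
            ("B", "K1", 11.0, 20.0, 0, 0.0),
            ("C", "K1", 22.0, 30.0, 0, 0.0),
        ])
        out = cc.detect_copied_visits(v, WINDOW)
        assert list(zip(out["leader"], out["follower"])) == [("A", "B"), ("B", "C")]

    def test_intervening_visit_takes_over_leadership(self):
        # B enters 2 s after A's exit, C enters 3 s after B's exit but 14 s
        # after A's: C copies B, not A
        v = make_visits([
            ("A", "K1", 0.0, 10.0, 0, 0.0),
            ("B", "K1", 12.0, 21.0, 0, 0.0),
            ("C", "K1", 24.0, 30.0, 0, 0.0),
        ])
        out = cc.detect_copied_visits(v, WINDOW)
        assert set(out["leader"]) == {"A", "B"}
        assert out.loc[out["follower"] == "C", "leader"].iloc[0] == "B"

    def test_self_succession_is_never_copied(self):
        v = make_visits([
            ("A", "K1", 0.0, 10.0, 0, 0.0),
            ("A", "K1", 11.0, 20.0, 0, 0.0),
        ])
        assert len(cc.detect_copied_visits(v, WINDOW)) == 0

    def test_different_corner_not_copied(self):
        v = make_visits([
            ("A", "K1", 0.0, 10.0, 0, 0.0),
            ("B", "K2", 11.0, 20.0, 0, 0.0),
        ])
        assert len(cc.detect_copied_visits(v, WINDOW)) == 0

    def test_leader_outside_window_not_counted(self):
        v = make_visits([
            ("A", "K1", 5.0, 10.0, 0, 0.0),
            ("B", "K1", 12.0, 20.0, 0, 0.0),
        ])
        assert len(cc.detect_copied_visits(v, (11.0, 1000.0))) == 0

    def test_entry_reference_variant(self):
        v = make_visits([
            ("A", "K1", 0.0, 10.0, 0, 0.0),
            ("B", "K1", 11.0, 20.0, 0, 0.0),
        ])
        # entry->entry latency is 11 s: no copy under threshold 4
        assert len(cc.detect_copied_visits(v, WINDOW, latency_reference="entry")) == 0
        assert len(cc.detect_copied_visits(v, WINDOW, latency_reference="entry",
                                           latency_threshold=12.0)) == 1

    def test_threshold_zero_yields_empty(self):
        v = make_visits([
            ("A", "K1", 0.0, 10.0, 0, 0.0),
            ("B", "K1", 10.0, 15.0, 0, 0.0),
        ])
        assert len(cc.detect_copied_visits(v, WINDOW, latency_threshold=0.0)) == 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = random_valid_log(rng, mean_gap=float(rng.uniform(2, 10)))
        thr = float(rng.uniform(0.5, 8.0))
        w = (0.0, float(rng.uniform(300, 700)))
        got = cc.detect_copied_visits(v, w, thr)
        got_set = {
            (r.cage, r.leader, r.follower, r.corner, r.follower_entry)
            for r in got.itertuples()
        }
        assert got_set == copied_visits_bruteforce(v, w, thr)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_in_threshold_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        v = random_valid_log(rng)
        counts = [
            len(cc.detect_copied_visits(v, WINDOW, thr))
            for thr in (0.0, 1.0, 2.0, 4.0, 8.0)
        ]
        assert counts == sorted(counts) and counts[0] == 0
        shuffled = v.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            cc.detect_copied_visits(v, WINDOW),
            cc.detect_copied_visits(cc.validate_visits(shuffled), WINDOW),
        )


def _graph_for(rows, roster, window=WINDOW):
    v = make_visits(rows)
    copied = cc.detect_copied_visits(v, window)
    summary = cc.summarize_window(v, roster, window, warn_outside_span=False)
    return cc.build_graph(copied, roster, summary, "C1"), copied


class TestGraph:
    def test_no_observer_visits_all_passive_zero_edges(self, roster5):
        g, _ = _graph_for([("D1", "K1", 0.0, 10.0, 0, 0.0)], roster5)
        acts = nx.get_node_attributes(g, "activation")
        assert g.number_of_edges() == 0
        assert all(acts[o] == "passive" for o in ["O1", "O2", "O3", "O4"])
        assert acts["D1"] == "demonstrator"

    def test_repeated_copying_pair_accumulates_weight(self, roster5):
        rows = []
        t = 0.0
        for _ in range(3):  # one pair copies 3 times -> single edge, weight 3
            rows.append(("D1", "K1", t, t + 5, 0, 0.0))
            rows.append(("O1", "K1", t + 6, t + 12, 0, 0.0))
            t += 400.0
        g, copied = _graph_for(rows, roster5)
        assert len(copied) == 3
        assert g.number_of_edges() == 1
        assert g["D1"]["O1"]["weight"] == 3

    def test_edge_weight_sum_equals_copied_visits_on_simulated_cages(self):
        cfg = cc.SimulationConfig(include_habituation=False)
        for seed in range(20):
            v, r, tl = cc.simulate_cage(cfg, cc.CONTROL_LIKE, seed)
            w = tl.contagion_window
            copied = cc.detect_copied_visits(v, w)
            summary = cc.summarize_window(v, r, w, warn_outside_span=False)
            g = cc.build_graph(copied, r, summary, "C1")
            assert sum(d["weight"] for _, _, d in g.edges(data=True)) == len(copied)

    def test_unknown_animal_in_copied_visits_rejected(self, roster5):
        v = make_visits([("D1", "K1", 0.0, 10.0, 0, 0.0)])
        copied = pd.DataFrame(
            [("C1", "D1", "GHOST", "K1", 10.0, 11.0, 1.0)],
            columns=["cage", "leader", "follower", "corner",
                     "leader_exit", "follower_entry", "latency"],
        )
        summary = cc.summarize_window(v, roster5, WINDOW, warn_outside_span=False)
        with pytest.raises(ValidationError, match="GHOST"):
            cc.build_graph(copied, roster5, summary, "C1")

    def test_normalized_summary_rejected_for_activation(self, roster5):
        v = make_visits([("D1", "K1", 0.0, 10.0, 0, 0.0)])
        summary = cc.summarize_window(v, roster5, WINDOW, normalization_divisor=6,
                                      warn_outside_span=False)
        with pytest.raises(ValidationError, match="un-normalized"):
            cc.build_graph(cc.detect_copied_visits(v, WINDOW), roster5, summary, "C1")


class TestMetrics:
    @pytest.mark.parametrize("n,expected", [(2, 1), (4, 6), (5, 10), (6, 15)])
    def test_possible_edges_closed_form(self, n, expected):
        assert possible_edges(n) == expected

    def test_activation_partition(self, roster5):
        # three of four observers visited
        rows = [("D1", "K1", 0.0, 5.0, 0, 0.0)]
        for i, o in enumerate(["O1", "O2", "O3"]):
            rows.append((o, "K2", 100.0 * (i + 1), 100.0 * (i + 1) + 5, 0, 0.0))
        g, copied = _graph_for(rows, roster5)
        m = cc.compute_group_metrics(g, copied)
        assert (m.n_activated_observers, m.n_passive_observers) == (3, 1)
        assert m.n_activated_observers + m.n_passive_observers == m.n_observers
        assert m.n == 5 and m.possible_edges == 10

    def test_followers_counted_among_observers_only(self, roster5):
        # O1 follows D1; D1 follows O1 back -> only O1 is a follower
        rows = [
            ("D1", "K1", 0.0, 10.0, 0, 0.0),
            ("O1", "K1", 12.0, 20.0, 0, 0.0),
            ("D1", "K1", 22.0, 30.0, 0, 0.0),
        ]
        g, copied = _graph_for(rows, roster5)
        m = cc.compute_group_metrics(g, copied)
        assert len(copied) == 2
        assert m.n_followers == 1
        assert m.n_followers <= m.n_activated_observers

    def test_pooling_sums_and_strain_guard(self):
        cfg = cc.SimulationConfig(n_cages=2, include_habituation=False)
        profiles = {"control-like": cc.CONTROL_LIKE, "model-like": cc.MODEL_LIKE}
        visits, roster, tl = cc.simulate_colony(cfg, profiles, 3)
        w = tl.contagion_window
        copied = cc.detect_copied_visits(visits, w)
        summary = cc.summarize_window(visits, roster, w, warn_outside_span=False)
        metrics = {}
        for cage in sorted(roster["cage"].unique()):
            cr = roster[roster["cage"] == cage]
            cs = summary[summary["animal"].isin(cr["animal"])]
            g = cc.build_graph(copied, roster, cs, cage)
            metrics[cage] = cc.compute_group_metrics(g, copied)
        ctrl = [m for c, m in metrics.items() if c.startswith("control")]
        pooled = cc.pool_metrics(ctrl, roster, "control-like")
        assert pooled.n_followers == sum(m.n_followers for m in ctrl)
        assert pooled.n_observers == sum(m.n_observers for m in ctrl)
        assert pooled.possible_edges == sum(m.possible_edges for m in ctrl)
        with pytest.raises(ValidationError, match="cannot pool"):
            cc.pool_metrics(ctrl, roster, "model-like")


def test_graph_exports_are_readable(tmp_path, roster5):
    rows = [
        ("D1", "K1", 0.0, 10.0, 0, 0.0),
        ("O1", "K1", 12.0, 20.0, 0, 0.0),
    ]
    g, _ = _graph_for(rows, roster5)
    gp = tmp_path / "g.graphml"
    cc.contagion.write_graphml(g, gp)
    g2 = nx.read_graphml(gp)
    assert g2.number_of_nodes() == 5 and g2["D1"]["O1"]["weight"] == 1
    dp = tmp_path / "g.dot"
    cc.contagion.write_dot(g, dp)
    text = dp.read_text()
    assert '"D1" -- "O1" [weight=1];' in text and 'activation="activated"' in text
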