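"""Evaluation metrics: detection matching, trustworthiness, genealogy."""

import itertools

import networkx as nx
import numpy as np
import pytest

from validtrack.evaluate import (
    MatchCounts,
    build_cell_forest,
    classification_counts,
    complete_path_probability,
    degree_of_relation,
    detection_error_rates,
    frame_correspondences,
    genealogy_error_rates,
    match_detections,
    trustworthiness,
)
from validtrack.simulate import SimulationConfig, simulate_movie
from validtrack.tracking import PathFragment


def square(mask, x0, y0, w, label):
    mask[y0 : y0 + w, x0 : x0 + w] = label


class TestMatchDetections:
    def test_identity(self):
        ref = np.zeros((60, 60), dtype=np.uint16)
        square(ref, 5, 5, 10, 1)
        square(ref, 30, 30, 12, 2)
        counts, matches = match_detections(ref, ref)
        assert counts == MatchCounts(tp=2, fp=0, fn=0)
        assert matches == {1: 1, 2: 2}

    def test_one_detected_blob_covering_two_reference_cells(self):
        det = np.zeros((40, 80), dtype=np.uint16)
        ref = np.zeros((40, 80), dtype=np.uint16)
        square(det, 10, 10, 40, 1)  # one big blob
        square(ref, 10, 10, 18, 1)
        square(ref, 32, 10, 18, 2)  # both inside the blob
        counts, _ = match_detections(det, ref)
        assert counts == MatchCounts(tp=0, fp=1, fn=2)

    def test_low_accuracy_detection_counts_both_ways(self):
        det = np.zeros((40, 80), dtype=np.uint16)
        ref = np.zeros((40, 80), dtype=np.uint16)
        square(ref, 10, 10, 20, 1)  # 400 px
        square(det, 25, 10, 20, 1)  # overlap 5x20 = 100 px -> 0.25 < 0.3
        counts, _ = match_detections(det, ref)
        assert counts == MatchCounts(tp=0, fp=1, fn=1)

    def test_symmetry_under_swapping_with_fp_fn_exchange(self):
        rng = np.random.default_rng(0)
        det = np.zeros((80, 80), dtype=np.uint16)
        ref = np.zeros((80, 80), dtype=np.uint16)
        square(det, 5, 5, 12, 1)
        square(ref, 7, 6, 12, 1)
        square(det, 40, 40, 10, 2)
        square(ref, 60, 10, 9, 2)
        a, _ = match_detections(det, ref)
        b, _ = match_detections(ref, det)
        assert (a.tp, a.fp, a.fn) == (b.tp, b.fn, b.fp)


class TestRates:
    def test_arithmetic(self):
        far, frr = detection_error_rates(MatchCounts(tp=95, fp=5, fn=5))
        assert far == pytest.approx(0.05) and frr == pytest.approx(0.05)

    def test_perfect_case(self):
        assert detection_error_rates(MatchCounts(100, 0, 0)) == (0.0, 0.0)

    def test_degenerate_cases(self):
        far, frr = detection_error_rates(MatchCounts(tp=0, fp=3, fn=0))
        assert far == 1.0 and frr is None  # no reference cells: FRR undefined
        far, frr = detection_error_rates(MatchCounts(tp=0, fp=0, fn=0))
        assert far is None and frr is None


class TestTrustworthiness:
    @pytest.mark.parametrize(
        "correct,total,expected",
        [(789, 1400, 56.4), (360, 377, 95.5), (1114, 1283, 86.8), (1644, 3299, 49.8)],
    )
    def test_printed_quotients(self, correct, total, expected):
        assert round(trustworthiness(correct, total), 1) == expected

    def test_identity_and_empty(self):
        assert trustworthiness(7, 7) == 100.0
        assert trustworthiness(0, 0) is None

    def test_contract_violation(self):
        with pytest.raises(ValueError):
            trustworthiness(5, 4)


def test_error_propagation_over_fifty_frames():
    """95% per-frame success compounds to ~7.7% over a 50-frame life."""
    assert complete_path_probability(0.95, 50) == pytest.approx(0.0769, abs=5e-4)


# ---------------------------------------------------------------------------
# genealogy


def three_generation_forest():
    """Two enumerated trees: one 3-generation binary tree plus a lone pair."""
    g = nx.DiGraph()
    # tree 1: root 1 -> 2,3; 2 -> 4,5; 3 -> 6,7
    for p, d in [(1, 2), (1, 3), (2, 4), (2, 5), (3, 6), (3, 7)]:
        g.add_edge(p, d, frame=10 * p)
    # tree 2: root 20 -> 21,22
    for p, d in [(20, 21), (20, 22)]:
        g.add_edge(p, d, frame=5)
    return g


def brute_force_degree(forest: nx.DiGraph, a, b) -> int:
    """Oracle: walk both ancestor chains to the common ancestor and count
    the distinct dividing cells along the connecting path."""
    parent = {d: p for p, d in forest.edges}

    def ancestors(n):
        chain = [n]
        while chain[-1] in parent:
            chain.append(parent[chain[-1]])
        return chain

    ca, cb = ancestors(a), ancestors(b)
    common = [n for n in ca if n in cb]
    if not common:
        return 0
    lca = common[0]
    path_nodes = ca[: ca.index(lca)] + [lca] + cb[: cb.index(lca)][::-1]
    dividers = set()
    for u, v in zip(path_nodes, path_nodes[1:]):
        dividers.add(u if forest.has_edge(u, v) else v)
    return len(dividers)


class TestDegreeOfRelation:
    def test_siblings(self):
        assert degree_of_relation(three_generation_forest(), 4, 5) == 1

    def test_parent_child(self):
        assert degree_of_relation(three_generation_forest(), 2, 4) == 1

    def test_first_cousins(self):
        assert degree_of_relation(three_generation_forest(), 4, 6) == 3

    def test_disjoint_trees_unrelated(self):
        assert degree_of_relation(three_generation_forest(), 4, 21) == 0

    def test_same_cell_rejected(self):
        with pytest.raises(ValueError):
            degree_of_relation(three_generation_forest(), 4, 4)

    def test_symmetry_and_brute_force_oracle(self):
        forest = three_generation_forest()
        for a, b in itertools.combinations(sorted(forest.nodes), 2):
            d_ab = degree_of_relation(forest, a, b)
            assert d_ab == degree_of_relation(forest, b, a)
            assert d_ab == brute_force_degree(forest, a, b)


class TestGenealogyErrorRates:
    def cells(self):
        return [4, 5, 6, 7, 21, 22]  # leaves of both trees

    def test_identity_is_error_free(self):
        f = three_generation_forest()
        corr = {c: c for c in self.cells()}
        assert genealogy_error_rates(f, f, self.cells(), corr) == (0.0, 0.0)

    def test_empty_prediction_misses_everything(self):
        far, frr = genealogy_error_rates(
            nx.DiGraph(), three_generation_forest(), self.cells(), {}
        )
        assert far == 0.0 and frr == 1.0

    def test_one_misassigned_mitosis_matches_pair_enumeration(self):
        ref = three_generation_forest()
        pred = three_generation_forest()
        pred.remove_edge(2, 5)
        pred.add_edge(3, 5)  # cell 5 hung onto the wrong parent
        corr = {c: c for c in self.cells()}
        far, frr = genealogy_error_rates(pred, ref, self.cells(), corr)
        exp_total = exp_fa = exp_fr = 0
        for a, b in itertools.combinations(self.cells(), 2):
            rd = brute_force_degree(ref, a, b)
            if rd == 0:
                continue
            exp_total += 1
            pd = brute_force_degree(pred, a, b)
            if pd == 0:
                exp_fr += 1
            elif pd != rd:
                exp_fa += 1
        assert far == pytest.approx(exp_fa / exp_total)
        assert frr == pytest.approx(exp_fr / exp_total)

    def test_no_reference_relations_is_undefined(self):
        assert genealogy_error_rates(nx.DiGraph(), nx.DiGraph(), [1, 2], {}) == (None, None)


# ---------------------------------------------------------------------------
# classification counts


@pytest.fixture(scope="module")
def truth_as_result():
    """Express the ground truth itself in tracker terms."""
    cfg = SimulationConfig(
        width=360, height=360, n_frames=40, initial_cells=8,
        mean_lifetime_min=240.0, seed=41, gradient_amplitude=0.0, noise_sd=0.0,
    )
    _, truth = simulate_movie(cfg)
    paths = {}
    for cid, cell in truth.cells.items():
        labels = [cid] * (cell.last_frame - cell.first_frame + 1)
        paths[cid] = PathFragment(id=cid, start_frame=cell.first_frame, labels=labels)
    div = {p: f for p, _, f in truth.lineage}
    mitoses = [(f, p) for p, f in div.items()]
    daughters = {d for _, d, _ in truth.lineage}
    complete = {
        cid: (c.first_frame, c.last_frame)
        for cid, c in truth.cells.items()
        if cid in div and cid in daughters
    }
    maps = frame_correspondences(truth.masks, truth)
    return truth, paths, mitoses, complete, maps


class TestClassificationCounts:
    def test_reference_column_pattern(self, truth_as_result):
        truth, paths, mitoses, complete, maps = truth_as_result
        counts = classification_counts(paths, mitoses, complete, maps, truth)
        assert counts["mitosis detection trustworthiness"] == 100.0
        assert counts["tracking trustworthiness"] == 100.0
        assert counts["correctly detected complete paths"] == len(complete) > 0

    def test_zero_complete_paths_gives_undefined_quotient(self, truth_as_result):
        truth, paths, mitoses, _, maps = truth_as_result
        counts = classification_counts(paths, mitoses, {}, maps, truth)
        assert counts["complete paths (mitosis-mitosis)"] == 0
        assert counts["tracking trustworthiness"] is None

    def test_adding_a_wrong_path_lowers_trustworthiness(self, truth_as_result):
        truth, paths, mitoses, complete, maps = truth_as_result
        base = classification_counts(paths, mitoses, complete, maps, truth)
        # a fabricated "complete" path that matches nothing
        bogus_id = max(paths) + 1
        paths2 = dict(paths)
        paths2[bogus_id] = PathFragment(id=bogus_id, start_frame=0, labels=[9999] * 5)
        complete2 = dict(complete)
        complete2[bogus_id] = (0, 4)
        worse = classification_counts(paths2, mitoses, complete2, maps, truth)
        assert worse["tracking trustworthiness"] < base["tracking trustworthiness"]
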