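import math

import numpy as np
import pandas as pd
import pytest

from bonenet.core import DEFAULT_BONES
from bonenet.network import (
    assemble_profiles,
    graph_summary,
    knn_threshold_graph,
    pearson_matrix,
)

# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def pearson_bruteforce(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def knn_edges_bruteforce(r: pd.DataFrame, r_min: float, k: int, rule: str) -> set:
    """O(n^2 k) pairwise re-derivation of the pruning rule."""
    nodes = list(r.index)
    edges = set()
    for a in nodes:
        for b in nodes:
            if a >= b:
                continue
            v = r.loc[a, b]
            if not v > r_min:
                continue

            def rank_ok(src, dst):
                cands = [
                    (-r.loc[src, other], other)
                    for other in nodes
                    if other != src and r.loc[src, other] > r_min
                ]
                cands.sort()
                return dst in [o for _, o in cands[:k]]

            ok_a, ok_b = rank_ok(a, b), rank_ok(b, a)
            keep = (ok_a or ok_b) if rule == "union" else (ok_a and ok_b)
            if keep:
                edges.add((a, b))
    return edges


def random_symmetric_r(rng, labels):
    n = len(labels)
    m = rng.uniform(-1.0, 1.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return pd.DataFrame(m, index=labels, columns=labels)


# ---------------------------------------------------------------------------


class TestAssembleProfiles:
    def test_single_animal_is_identity(self, default_cohort):
        one = assemble_profiles(default_cohort.tacs[:1])
        pd.testing.assert_frame_equal(one, default_cohort.tacs[0].values, check_names=False)

    def test_two_animals_average_framewise(self, default_cohort):
        two = assemble_profiles(default_cohort.tacs[:2])
        expected = (default_cohort.tacs[0].values + default_cohort.tacs[1].values) / 2
        np.testing.assert_allclose(two.to_numpy(), expected.to_numpy())

    def test_cohort_average_shape_is_7x21(self, default_cohort):
        prof = assemble_profiles(default_cohort.tacs)
        assert prof.shape == (7, 21)
        assert list(prof.index) == list(DEFAULT_BONES)

    def test_per_animal_mode_yields_35_rows(self, default_cohort):
        prof = assemble_profiles(default_cohort.tacs, mode="per_animal")
        assert prof.shape == (35, 21)
        assert prof.index.is_unique

    def test_schedule_mismatch_rejected(self, default_cohort):
        from bonenet.core import FrameSchedule, TACTable

        other_sched = FrameSchedule.from_counts([(21, 60)])
        odd = TACTable(
            values=default_cohort.tacs[0].values.copy(),
            schedule=other_sched,
            animal_id="odd",
        )
        with pytest.raises(ValueError, match="schedule"):
            assemble_profiles([default_cohort.tacs[0], odd])


class TestPearsonMatrix:
    def test_self_correlation_is_one(self, default_cohort):
        r = pearson_matrix(assemble_profiles(default_cohort.tacs))
        np.testing.assert_allclose(np.diag(r), 1.0)
        np.testing.assert_allclose(r.to_numpy(), r.to_numpy().T)
        assert (r.to_numpy() <= 1.0).all() and (r.to_numpy() >= -1.0).all()

    def test_negated_row_correlates_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 4.0])
        prof = pd.DataFrame({"up": x, "down": -x}).T
        r = pearson_matrix(prof)
        assert r.loc["up", "down"] == pytest.approx(-1.0)

    def test_matches_bruteforce_formula(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 5.0]
        prof = pd.DataFrame({"x": x, "y": y}).T
        r = pearson_matrix(prof)
        assert r.loc["x", "y"] == pytest.approx(pearson_bruteforce(x, y), rel=1e-12)

    def test_zero_variance_row_error_names_the_bone(self):
        prof = pd.DataFrame({"flat": [2.0, 2.0, 2.0], "ok": [1.0, 2.0, 3.0]}).T
        with pytest.raises(ValueError, match="flat"):
            pearson_matrix(prof)

    def test_too_few_time_points_rejected(self):
        prof = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}).T
        with pytest.raises(ValueError):
            pearson_matrix(prof)

    def test_invariant_under_positive_affine_transforms_per_row(self, default_cohort, rng):
        prof = assemble_profiles(default_cohort.tacs)
        r_base = pearson_matrix(prof)
        scales = rng.uniform(0.1, 10.0, size=len(prof))
        offsets = rng.uniform(-5.0, 5.0, size=len(prof))
        transformed = prof.mul(scales, axis=0).add(offsets, axis=0)
        r_t = pearson_matrix(transformed)
        np.testing.assert_allclose(r_base.to_numpy(), r_t.to_numpy(), atol=1e-12)


class TestKnnThresholdGraph:
    def test_dense_high_correlations_give_complete_graph(self):
        labels = list("abcd")
        r = pd.DataFrame(0.9, index=labels, columns=labels)
        np.fill_diagonal(r.values, 1.0)
        g = knn_threshold_graph(r, r_min=0.7, k=3)
        assert g.number_of_edges() == 6
        assert g.number_of_nodes() == 4

    def test_subthreshold_correlations_give_isolated_nodes(self):
        labels = [f"b{i}" for i in range(7)]
        r = pd.DataFrame(0.5, index=labels, columns=labels)
        np.fill_diagonal(r.values, 1.0)
        g = knn_threshold_graph(r, r_min=0.7, k=3)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 7  # nodes kept despite isolation

    def test_threshold_is_strict(self):
        labels = ["a", "b"]
        r = pd.DataFrame([[1.0, 0.7], [0.7, 1.0]], index=labels, columns=labels)
        assert knn_threshold_graph(r, r_min=0.7, k=3).number_of_edges() == 0

    @pytest.mark.parametrize("rule", ["union", "mutual"])
    def test_agrees_with_bruteforce_oracle_on_random_instances(self, rule, rng):
        labels = [f"bone{i}" for i in range(7)]
        for _ in range(100):
            r = random_symmetric_r(rng, labels)
            k = int(rng.integers(1, 5))
            r_min = float(rng.uniform(-0.5, 0.9))
            g = knn_threshold_graph(r, r_min=r_min, k=k, rule=rule)
            got = {tuple(sorted(e)) for e in g.edges()}
            assert got == knn_edges_bruteforce(r, r_min, k, rule)

    def test_raising_threshold_never_adds_edges(self, rng):
        labels = [f"bone{i}" for i in range(7)]
        r = random_symmetric_r(rng, labels)
        edges = [
            {tuple(sorted(e)) for e in knn_threshold_graph(r, r_min=rm, k=3).edges()}
            for rm in (0.0, 0.3, 0.6, 0.9)
        ]
        for tighter, looser in zip(edges[1:], edges[:-1]):
            assert tighter <= looser

    def test_raising_k_never_removes_edges(self, rng):
        labels = [f"bone{i}" for i in range(7)]
        r = random_symmetric_r(rng, labels)
        edges = [
            {tuple(sorted(e)) for e in knn_threshold_graph(r, r_min=0.2, k=k).edges()}
            for k in (1, 2, 3, 6)
        ]
        for smaller, larger in zip(edges[:-1], edges[1:]):
            assert smaller <= larger

    def test_mutual_rule_is_subset_of_union(self, rng):
        labels = [f"bone{i}" for i in range(7)]
        r = random_symmetric_r(rng, labels)
        union = {tuple(sorted(e)) for e in knn_threshold_graph(r, k=2, r_min=0.0).edges()}
        mutual = {
            tuple(sorted(e))
            for e in knn_threshold_graph(r, k=2, r_min=0.0, rule="mutual").edges()
        }
        assert mutual <= union

    def test_invalid_k_rejected(self):
        r = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            knn_threshold_graph(r, k=0)


class TestGraphSummary:
    def test_edgeless_graph_has_singleton_components(self):
        labels = [f"b{i}" for i in range(7)]
        r = pd.DataFrame(0.0, index=labels, columns=labels)
        np.fill_diagonal(r.values, 1.0)
        s = graph_summary(knn_threshold_graph(r))
        assert len(s.components) == 7
        assert all(d == 0 for d in s.degrees.values())
        assert math.isnan(s.mean_edge_weight)

    def test_complete_graph_summary(self):
        labels = list("abcd")
        r = pd.DataFrame(0.9, index=labels, columns=labels)
        np.fill_diagonal(r.values, 1.0)
        s = graph_summary(knn_threshold_graph(r, k=3))
        assert all(d == 3 for d in s.degrees.values())
        assert len(s.components) == 1
        assert s.mean_edge_weight == pytest.approx(0.9)
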