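import numpy as np
import pytest

import karyomap as km
from karyomap.mapping import (
    MAP_FUNCTIONS,
    MapInconsistencyError,
    TwoPointTable,
    estimate_all_thetas,
    estimate_theta,
    group_markers,
    haldane,
    kosambi,
    order_markers,
)
from karyomap.simulate import Family, PedigreeGenotypes

from oracles import grid_argmax_theta, random_two_marker_instance


def _phase_known_family(n_off=20, recombinants=0):
    """One family: dam doubly het in coupling, sire homozygous 0 at both."""
    individuals, rows = ["s", "d"], [np.array([0, 0], np.int8), np.array([1, 1], np.int8)]
    offspring = []
    for j in range(n_off):
        rec = j < recombinants
        dam = (0, 1) if rec else ((0, 0) if j % 2 else (1, 1))
        rows.append(np.array(dam, np.int8))
        offspring.append(f"o{j}")
    individuals += offspring
    return PedigreeGenotypes(
        individuals, ["mA", "mB"], np.array(rows), [Family("f", "s", "d", offspring)],
        {"s": "M", "d": "F"},
    )


class TestEstimateTheta:
    def test_zero_recombinants(self):
        data = _phase_known_family(20, recombinants=0)
        est = estimate_theta("mA", "mB", data)
        assert est.theta == pytest.approx(0.0, abs=1e-6)
        assert est.lod > 3

    def test_some_recombinants(self):
        data = _phase_known_family(20, recombinants=4)
        est = estimate_theta("mA", "mB", data)
        assert est.theta == pytest.approx(0.2, abs=1e-3)

    def test_symmetry(self, tiny_data):
        _, data = tiny_data
        a, b = data.markers[0], data.markers[3]
        ab = estimate_theta(a, b, data)
        ba = estimate_theta(b, a, data)
        assert ab.theta == pytest.approx(ba.theta, abs=1e-9)
        assert ab.lod == pytest.approx(ba.lod, abs=1e-9)

    def test_unknown_marker(self, tiny_data):
        _, data = tiny_data
        with pytest.raises(KeyError):
            estimate_theta("nope", data.markers[0], data)

    def test_all_missing_uninformative(self):
        data = _phase_known_family(5)
        data.genotypes[2:] = -1
        est = estimate_theta("mA", "mB", data)
        assert est.theta == 0.5
        assert est.lod == 0.0

    def test_em_loglik_monotone(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            data, _ = random_two_marker_instance(rng)
            _, trace = estimate_theta("mA", "mB", data, return_trace=True)
            diffs = np.diff(trace)
            assert np.all(diffs >= -1e-9)

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(25):
            data, _ = random_two_marker_instance(rng)
            est = estimate_theta("mA", "mB", data)
            theta_grid, _ = grid_argmax_theta(data, "mA", "mB")
            assert est.theta == pytest.approx(theta_grid, abs=1e-3)

    def test_unlinked_markers(self, recovery_setup):
        _, query, data, _, _, tp = recovery_setup
        chroms = list(query.chromosomes.values())
        # theta-hat near 0.5 carries an O(1/sqrt(n)) downward phase-mixture
        # bias, so assert on the mean over a panel of cross-chromosome pairs
        thetas, lods = [], []
        for i in range(0, 20, 2):
            a = chroms[0].markers[i]
            b = chroms[1].markers[i]
            k = tp.pair_index(a, b)
            thetas.append(tp.theta[k])
            lods.append(tp.lod[k])
        assert abs(np.mean(thetas) - 0.5) < 0.05
        assert max(lods) < 5


class TestFastScanConsistency:
    def test_fast_vs_exact_on_deterministic_family(self):
        data = _phase_known_family(20, recombinants=3)
        tp = estimate_all_thetas(data)
        exact = estimate_theta("mA", "mB", data)
        assert tp.theta[0] == pytest.approx(exact.theta, abs=1e-4)

    def test_sex_separation(self, tiny_data):
        """Corrupting the male transmission statistics leaves theta_female
        untouched."""
        _, data = tiny_data
        tp = estimate_all_thetas(data)
        pairs = np.arange(5)
        tf_before, _, nf_before, _ = tp.sex_thetas(pairs)
        rng = np.random.default_rng(0)
        male_rows = tp._parent_sex == "M"
        tp._ns[male_rows] = rng.integers(0, 5, tp._ns[male_rows].shape).astype(np.int16)
        tp._nd[male_rows] = rng.integers(0, 5, tp._nd[male_rows].shape).astype(np.int16)
        tf_after, _, nf_after, _ = tp.sex_thetas(pairs)
        assert np.allclose(tf_before, tf_after)
        assert np.array_equal(nf_before, nf_after)


def _toy_table(markers, theta, lod, n=50):
    k = len(theta)
    return TwoPointTable(
        markers=markers,
        theta=np.asarray(theta, float),
        lod=np.asarray(lod, float),
        n_informative=np.full(k, n),
        marker_meioses=np.full(len(markers), n),
        _ns=np.zeros((1, k), np.int16),
        _nd=np.zeros((1, k), np.int16),
        _parent_sex=np.array(["F"]),
    )


class TestGrouping:
    def test_two_markers_one_group(self):
        tp = _toy_table(["a", "b"], [0.1], [10.0])
        groups, singles = group_markers(tp, 5.0)
        assert groups == [["a", "b"]] and singles == []

    def test_empty_input(self):
        tp = _toy_table([], [], [])
        assert group_markers(tp, 5.0) == ([], [])

    def test_threshold_splits(self):
        tp = _toy_table(["a", "b"], [0.1], [3.0])
        groups, singles = group_markers(tp, 5.0)
        assert groups == [] and sorted(singles) == ["a", "b"]

    def test_recovers_simulated_chromosomes(self, recovery_setup):
        _, query, data, _, _, tp = recovery_setup
        groups, _ = group_markers(tp, 10.0)
        assert len(groups) == len(query.chromosomes)
        chrom_of = query.chromosome_of()
        for g in groups:
            assert len({chrom_of[m] for m in g}) == 1


class TestOrdering:
    def test_single_marker(self):
        tp = _toy_table(["a"], [], [])
        assert order_markers(["a"], tp) == ["a"]

    def test_cosegregating_pair_follows_reference(self):
        tp = _toy_table(["A", "B"], [0.0], [10.0])
        assert order_markers(["A", "B"], tp, reference_order=["B", "A"]) == ["B", "A"]
        assert order_markers(["A", "B"], tp, reference_order=["A", "B"]) == ["A", "B"]

    def test_recovers_truth_order(self, recovery_setup):
        ref, query, data, ref_table, table, tp = recovery_setup
        chrom_of = query.chromosome_of()
        for g in table.groups:
            mk = table.group_rows(g)["marker"].tolist()
            truth = query.chromosomes[chrom_of[mk[0]]].markers
            assert mk == truth or mk == truth[::-1]


class TestMapFunctions:
    def test_haldane_closed_form(self):
        assert haldane(0.1) == pytest.approx(11.157, abs=1e-3)
        assert haldane(0.0) == 0.0

    def test_kosambi_closed_form(self):
        assert kosambi(0.1) == pytest.approx(10.137, abs=1e-3)
        assert kosambi(0.0) == 0.0

    def test_registry(self):
        assert set(MAP_FUNCTIONS) == {"haldane", "kosambi"}


class TestBuildMap:
    def test_zero_theta_all_at_origin(self):
        tp = _toy_table(["a", "b", "c"], [0.0, 0.0, 0.0], [10.0] * 3)
        rows = km.build_map(["a", "b", "c"], tp, "haldane")
        assert np.allclose(rows["female_cM"], 0.0)
        assert list(rows["order"]) == [1, 2, 3]

    def test_unlinked_adjacent_raises(self):
        tp = _toy_table(["a", "b"], [0.5], [0.0])
        with pytest.raises(MapInconsistencyError):
            km.build_map(["a", "b"], tp, "haldane")

    def test_unknown_function(self):
        tp = _toy_table(["a", "b"], [0.1], [10.0])
        with pytest.raises(ValueError):
            km.build_map(["a", "b"], tp, "morgan")

    def test_length_recovery_within_10pct(self, recovery_setup):
        _, query, _, _, table, _ = recovery_setup
        truth_total = sum(c.female_length for c in query.chromosomes.values())
        got = km.map_summary(table)["female_length_cM"]
        assert abs(got - truth_total) / truth_total < 0.10


class TestMapSummary:
    def test_empty(self):
        import pandas as pd
        from karyomap.maptable import COLUMNS, LinkageMapTable

        empty = LinkageMapTable(pd.DataFrame(columns=COLUMNS))
        s = km.map_summary(empty)
        assert s["n_markers"] == 0 and s["female_length_cM"] == 0.0

    def test_recovered_counts(self, recovery_setup):
        _, query, _, _, table, _ = recovery_setup
        s = km.map_summary(table)
        assert s["n_markers"] == len(query.marker_ids())
        assert s["n_groups"] == len(query.chromosomes)
        assert s["n_population_specific"] == 0
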