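import dataclasses

import numpy as np
import pandas as pd
import pytest

import karyomap as km
from karyomap.compare import (
    CENTROMERE_TO_CENTROMERE,
    COMPLEX,
    CONSERVED,
    FISSION_EVENT,
    FUSION,
    TANDEM,
    TRANSLOCATION_PLUS_FISSION,
    ComplexEventError,
    DetectedEvent,
    _two_block_split,
    build_correspondence,
    classify_events,
    infer_architecture,
    male_telomere_statistic,
    match_shared_markers,
)
from karyomap.maptable import COLUMNS, LinkageMapTable


def _table(groups: dict[str, list[tuple[str, float, float]]]) -> LinkageMapTable:
    rows = []
    for g, markers in groups.items():
        for i, (m, f, mm) in enumerate(markers):
            rows.append(
                {"marker": m, "group": g, "order": i + 1, "female_cM": f, "male_cM": mm,
                 "n_meioses": 0, "accession": "", "population_specific": False}
            )
    return LinkageMapTable(pd.DataFrame(rows, columns=COLUMNS))


class TestMatchSharedMarkers:
    def test_disjoint(self):
        a = _table({"g1": [("a", 0, 0), ("b", 1, 1)]})
        b = _table({"h1": [("c", 0, 0), ("d", 1, 1)]})
        p = match_shared_markers(a, b)
        assert p.shared == ()
        assert p.only_a == ("a", "b")

    def test_self_comparison(self, planted_setup):
        *_, query_table, _ = planted_setup
        p = match_shared_markers(query_table, query_table)
        assert len(p.shared) == len(query_table)
        assert p.only_a == () and p.only_b == ()

    def test_duplicate_ids_rejected(self):
        df = _table({"g1": [("a", 0, 0), ("b", 1, 1)]}).df.copy()
        df.loc[1, "marker"] = "a"
        dup = LinkageMapTable(df, validate=False)
        with pytest.raises(ValueError, match="duplicate"):
            match_shared_markers(dup, dup)

    def test_population_specific_counts(self, planted_setup):
        _, _, ref, query, ref_table, query_table, _ = planted_setup
        p = match_shared_markers(ref_table, query_table)
        assert len(p.shared) == len(ref.shared_markers(query))


class TestCorrespondence:
    def test_identical_maps(self):
        t = _table({"g1": [("a", 0, 0), ("b", 5, 1), ("c", 9, 2)]})
        g = build_correspondence(match_shared_markers(t, t), t, t, min_shared=3)
        assert len(g.edges) == 1
        assert g.edges[0].correlation_sign == 1

    def test_min_shared_prunes(self):
        a = _table({"g1": [("a", 0, 0), ("b", 5, 1)]})
        b = _table({"h1": [("a", 0, 0), ("b", 5, 1)]})
        g = build_correspondence(match_shared_markers(a, b), a, b, min_shared=3)
        assert g.edges == []

    def test_fused_group_degree_two(self, planted_setup):
        _, _, _, _, ref_table, query_table, _ = planted_setup
        g = build_correspondence(
            match_shared_markers(ref_table, query_table), ref_table, query_table
        ).graph()
        degrees = {n[1]: d for n, d in g.degree() if n[0] == "B"}
        fused = [b for b, d in degrees.items() if d == 2]
        assert len(fused) == 3  # two fusions plus the translocation target


def test_two_block_split_tolerates_one_interloper():
    blk1, blk2, removed = _two_block_split(list("AAABAAABBBB"))
    assert removed == 1
    blk1, blk2, removed = _two_block_split(list("ABABAB"))
    assert removed > 1


class TestClassification:
    def test_self_comparison_conserved(self, planted_setup):
        *_, query_table, _ = planted_setup
        events = km.detect_events(query_table, query_table)
        assert events and all(e.event_type == CONSERVED for e in events)

    def test_planted_robertsonian(self, planted_setup):
        *_, detected = planted_setup
        ev = next(e for e in detected if set(e.groups_a) == {"ssa26", "ssa28"})
        assert ev.event_type == FUSION
        assert ev.orientation_label == "head_to_head"
        assert ev.architecture == CENTROMERE_TO_CENTROMERE
        assert ev.junction is not None

    def test_planted_tandem(self, planted_setup):
        *_, detected = planted_setup
        ev = next(e for e in detected if set(e.groups_a) == {"ssa08", "ssa29"})
        assert ev.event_type == FUSION
        assert ev.groups_a[0] == "ssa08"  # the tail-side (centromere donor) leads
        assert ev.orientation_label == "tail_to_head"
        assert ev.architecture == TANDEM

    def test_planted_translocation(self, planted_setup):
        *_, detected = planted_setup
        ev = next(e for e in detected if e.event_type == TRANSLOCATION_PLUS_FISSION)
        assert set(ev.groups_a) == {"ssa01", "ssa23"}
        assert ev.groups_a[0] == "ssa01"
        assert ev.residue_group is not None
        assert ev.fragment_proximal is True

    def test_exactly_three_non_conserved(self, planted_setup):
        *_, detected = planted_setup
        assert sum(e.event_type != CONSERVED for e in detected) == 3

    def test_fusion_fission_duality(self, planted_setup):
        """A fusion seen with A as reference is a fission with B as reference."""
        panel, events, ref, query, ref_table, _, _ = planted_setup
        query_truth = km.truth_to_map_table(query, ref)
        forward = km.detect_events(ref_table, query_truth)
        backward = km.detect_events(query_truth, ref_table)
        fusions = {frozenset(e.groups_a) for e in forward if e.event_type == FUSION}
        fissions = {frozenset(e.groups_b) for e in backward if e.event_type == FISSION_EVENT}
        assert fusions and fusions <= fissions

    def test_interleaved_blocks_complex(self):
        a = _table({
            "g1": [(f"a{i}", 3.0 * i, 0.1 * i) for i in range(6)],
            "g2": [(f"b{i}", 3.0 * i, 0.1 * i) for i in range(6)],
        })
        interleaved = []
        for i in range(6):
            interleaved.append((f"a{i}", 3.0 * i, 0.1 * i))
            interleaved.append((f"b{i}", 3.0 * i + 1.5, 0.1 * i))
        b = _table({"h1": sorted(interleaved, key=lambda t: t[1])})
        events = classify_events(
            build_correspondence(match_shared_markers(a, b), a, b), a, b
        )
        assert events[0].event_type == COMPLEX


class TestMaleTelomereStatistic:
    def test_all_terminal(self):
        rows = _table({"g": [("a", 0, 0), ("b", 10, 5), ("c", 50, 5), ("d", 90, 5), ("e", 100, 10)]}).df
        assert male_telomere_statistic(rows) == pytest.approx(1.0)

    def test_uniform_limit(self):
        markers = [(f"m{i}", i, float(i)) for i in range(101)]
        rows = _table({"g": markers}).df
        stat = male_telomere_statistic(rows, terminal_fraction=0.1)
        assert stat == pytest.approx(0.2, abs=0.03)

    def test_no_male_length(self):
        rows = _table({"g": [("a", 0, 0), ("b", 10, 0), ("c", 20, 0)]}).df
        assert male_telomere_statistic(rows) is None

    def test_too_few_markers(self):
        rows = _table({"g": [("a", 0, 0), ("b", 10, 1)]}).df
        with pytest.raises(ValueError):
            male_telomere_statistic(rows)

    def test_planted_profile(self, planted_setup):
        *_, query_table, _ = planted_setup
        pooled_term, pooled_tot = 0.0, 0.0
        for g in query_table.groups:
            rows = query_table.group_rows(g)
            stat = male_telomere_statistic(rows, terminal_fraction=0.15)
            male = rows["male_cM"].iloc[-1]
            if stat is not None:
                pooled_term += stat * male
                pooled_tot += male
        # fused groups carry male-cold junction interiors, so the pooled share
        # sits slightly below the single-chromosome expectation
        assert pooled_term / pooled_tot >= 0.7


class TestInferArchitecture:
    def test_junction_at_hotspot_undetermined(self, planted_setup):
        panel, _, _, _, _, query_table, detected = planted_setup
        ev = next(e for e in detected if set(e.groups_a) == {"ssa26", "ssa28"})
        rows = query_table.group_rows(ev.groups_b[0])
        # junction forced next to the telomeric male hotspot
        moved = dataclasses.replace(ev, junction=(0.0, rows["female_cM"].iloc[1]))
        assert infer_architecture(moved, rows, panel) == "undetermined"

    def test_requires_karyotype(self, planted_setup):
        _, _, _, _, _, query_table, detected = planted_setup
        ev = next(e for e in detected if set(e.groups_a) == {"ssa26", "ssa28"})
        rows = query_table.group_rows(ev.groups_b[0])
        assert infer_architecture(ev, rows, None) == "undetermined"


class TestEventsToKaryotype:
    def test_planted_events_reproduce_karyotype(self, planted_setup):
        panel, events, *_ , detected = planted_setup
        predicted, ops = km.events_to_karyotype(detected, panel)
        assert km.summarize(predicted) == km.summarize(km.apply_event_set(panel, events))

    def test_empty_events(self):
        base = km.build_european_reference()
        result, ops = km.events_to_karyotype([], base)
        assert km.summarize(result) == km.summarize(base) and ops == []

    def test_conserved_only(self):
        base = km.build_european_reference()
        events = [DetectedEvent(CONSERVED, ("ssa01",), ("LG01",))]
        result, _ = km.events_to_karyotype(events, base)
        assert km.summarize(result) == km.summarize(base)

    def test_complex_refused(self):
        base = km.build_european_reference()
        events = [DetectedEvent(COMPLEX, ("ssa01", "ssa02"), ("LG01",), note="tangled")]
        with pytest.raises(ComplexEventError, match="tangled"):
            km.events_to_karyotype(events, base)
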