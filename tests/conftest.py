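import numpy as np
import pytest

import karyomap as km


@pytest.fixture(scope="session")
def tiny_data():
    """Small pedigree genotype set for estimator unit tests."""
    _, query = km.simulate_truth_maps(
        n_chromosomes=2,
        female_lengths_cM=50.0,
        male_lengths_cM=15.0,
        markers_per_chromosome=6,
        shared_fraction=1.0,
        seed=7,
    )
    data = km.simulate_pedigree_genotypes(
        query, n_families=12, offspring_per_family=15, half_sib_fraction=0.2, seed=8
    )
    return query, data


@pytest.fixture(scope="session")
def recovery_setup():
    """Moderate-scale simulate -> map run shared across recovery tests."""
    ref, query = km.simulate_truth_maps(
        n_chromosomes=4,
        female_lengths_cM=80.0,
        male_lengths_cM=20.0,
        markers_per_chromosome=20,
        shared_fraction=1.0,
        seed=11,
    )
    data = km.simulate_pedigree_genotypes(
        query, n_families=35, offspring_per_family=30, seed=12
    )
    ref_table = km.truth_to_map_table(ref)
    table, tp = km.build_map_from_genotypes(
        data, lod_threshold=10.0, mapping_function="haldane", reference=ref_table
    )
    return ref, query, data, ref_table, table, tp


@pytest.fixture(scope="session")
def planted_setup():
    """One simulate -> map -> compare run with the three planted events."""
    panel, events = km.demo_rearrangement_panel()
    ref, query = km.simulate_truth_maps(
        female_lengths_cM=40.0,
        male_lengths_cM=10.0,
        markers_per_chromosome=20,
        shared_fraction=0.9,
        seed=3,
        events=events,
        karyotype=panel,
    )
    data = km.simulate_pedigree_genotypes(
        query, n_families=40, offspring_per_family=30, seed=2003
    )
    ref_table = km.truth_to_map_table(ref, query)
    query_table, _ = km.build_map_from_genotypes(
        data, lod_threshold=10.0, mapping_function="haldane", reference=ref_table
    )
    events_detected = km.detect_events(ref_table, query_table, reference_karyotype=panel)
    return panel, events, ref, query, ref_table, query_table, events_detected
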