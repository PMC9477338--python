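"""Cluster-banded key index: construction, five-case search, tier searches."""

import itertools

import numpy as np
import pytest

from cisbrs.edge_buffer import QuerySphere
from cisbrs.orchestrator import BrsSystem
from cisbrs.sequence_model import SimilarityParams, cis_distance, extract_rcis
from cisbrs.synthetic_data import GeneratorParams, generate_dataset
from cisbrs.uecif_index import (
    IndexStretch,
    LeafEntry,
    OrderedIndex,
    build_index,
    cluster_sequences,
    compute_key,
    load_index_snapshot,
    range_search,
    save_index_snapshot,
    search_ranges,
    _kmedoids,
    _pairwise_distances,
)
from conftest import random_sequence


def make_pool(rng, n=12, params=None):
    params = params or SimilarityParams(0.5)
    seqs = [random_sequence(i + 1, rng, n_slices=5) for i in range(n)]
    for s in seqs:
        extract_rcis(s, params)
    return seqs, params


class TestOrderedIndex:
    def test_insert_lookup_range_scan(self, rng):
        idx = OrderedIndex()
        keys = rng.uniform(0, 100, size=40)
        for i, k in enumerate(keys):
            idx.insert(LeafEntry(float(k), i + 1))
        assert len(idx) == 40
        left, right = 20.0, 60.0
        got = {e.seq_ref for e in idx.range_scan(left, right)}
        want = {i + 1 for i, k in enumerate(keys) if left <= k <= right}
        assert got == want
        scanned = [e.key for e in idx.range_scan(left, right)]
        assert scanned == sorted(scanned)

    def test_duplicate_ids_rejected(self):
        idx = OrderedIndex()
        idx.insert(LeafEntry(1.0, 1))
        with pytest.raises(ValueError):
            idx.insert(LeafEntry(2.0, 1))


class TestClustering:
    def test_single_cluster(self, rng):
        seqs, params = make_pool(rng, n=6)
        model = cluster_sequences(seqs, k=1, params=params, seed=0)
        assert model.n_clusters == 1
        D = _pairwise_distances(seqs, params)
        m = next(i for i, s in enumerate(seqs) if s is model.centers[0])
        assert model.radii[0] == pytest.approx(D[:, m].max())

    def test_k_equals_n_gives_zero_radii(self, rng):
        seqs, params = make_pool(rng, n=5)
        model = cluster_sequences(seqs, k=5, params=params, seed=0)
        assert model.n_clusters == 5
        assert all(r == 0.0 for r in model.radii)

    def test_every_sequence_assigned_within_radius(self, rng):
        seqs, params = make_pool(rng, n=10)
        model = cluster_sequences(seqs, k=3, params=params, seed=0)
        assert set(model.assignment) == {s.seq_id for s in seqs}
        for s in seqs:
            j = model.assignment[s.seq_id]
            d = cis_distance(s, model.centers[j - 1], params)
            assert d <= model.radii[j - 1] + 1e-12

    def test_kmedoids_matches_exhaustive_for_k2(self, rng):
        """Medoid objective equals brute force over all center pairs."""
        seqs, params = make_pool(rng, n=10)
        D = _pairwise_distances(seqs, params)
        got = _kmedoids(D, 2, seed=0)
        got_cost = D[:, got].min(axis=1).sum()
        best_cost = min(
            D[:, list(pair)].min(axis=1).sum()
            for pair in itertools.combinations(range(10), 2)
        )
        assert got_cost == pytest.approx(best_cost)

    def test_deterministic_given_seed(self, rng):
        seqs, params = make_pool(rng, n=8)
        m1 = cluster_sequences(seqs, "auto", params, seed=3)
        m2 = cluster_sequences(seqs, "auto", params, seed=3)
        assert m1.assignment == m2.assignment
        assert m1.radii == m2.radii


class TestKeysAndConstruction:
    def test_center_key_is_band_origin(self, rng):
        seqs, params = make_pool(rng, n=8)
        model = cluster_sequences(seqs, k=2, params=params, seed=0)
        stretch = IndexStretch(10.0)
        for j, center in enumerate(model.centers, start=1):
            assert compute_key(center, model, stretch, params) == pytest.approx(
                j * stretch.c1_idx
            )

    def test_member_keys_stay_in_band(self, rng):
        seqs, params = make_pool(rng, n=10)
        model = cluster_sequences(seqs, k=3, params=params, seed=0)
        stretch = IndexStretch(10.0)
        for s in seqs:
            j = model.assignment[s.seq_id]
            key = compute_key(s, model, stretch, params)
            assert j * 10.0 <= key <= j * 10.0 + model.radii[j - 1] + 1e-12

    def test_bands_never_interleave(self, rng):
        seqs, params = make_pool(rng, n=12)
        model = cluster_sequences(seqs, k=4, params=params, seed=0)
        stretch = IndexStretch(10.0)
        keys_by_cluster = {}
        for s in seqs:
            j = model.assignment[s.seq_id]
            keys_by_cluster.setdefault(j, []).append(
                compute_key(s, model, stretch, params)
            )
        spans = sorted(
            (min(v), max(v)) for v in keys_by_cluster.values()
        )
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            assert hi < lo

    def test_fresh_index_flags(self, rng):
        seqs, params = make_pool(rng, n=6)
        model = cluster_sequences(seqs, k=2, params=params, seed=0)
        idx = build_index(seqs, model, IndexStretch(), "edge", params)
        assert len(idx) == 6
        assert all(e.etype == "F" for e in idx.entries())
        assert all(e.ctype == "T" for e in idx.entries())


class TestSearchRanges:
    def test_query_at_center_with_large_radius_gets_full_band(self, rng):
        seqs, params = make_pool(rng, n=8)
        model = cluster_sequences(seqs, k=2, params=params, seed=0)
        stretch = IndexStretch(10.0)
        center = model.centers[0]
        ranges = search_ranges(
            QuerySphere(center, 1.0), model, stretch, params
        )
        r1 = next(r for r in ranges if r.cluster == 1)
        assert r1.left == pytest.approx(10.0)
        assert r1.right == pytest.approx(10.0 + model.radii[0])

    def test_disjoint_clusters_are_pruned(self, rng):
        seqs, params = make_pool(rng, n=8)
        model = cluster_sequences(seqs, k=2, params=params, seed=0)
        query = QuerySphere(model.centers[0], 0.0)
        ranges = search_ranges(query, model, IndexStretch(10.0), params)
        kept = {r.cluster for r in ranges}
        for j in range(1, model.n_clusters + 1):
            D = cis_distance(query.center, model.centers[j - 1], params)
            if D > model.radii[j - 1]:
                assert j not in kept

    @pytest.mark.parametrize("conservative", [True, False])
    def test_true_answers_always_inside_some_range(self, rng, conservative):
        """Linear-scan oracle: every in-radius sequence's key is covered."""
        for trial in range(10):
            seqs, params = make_pool(rng, n=15)
            model = cluster_sequences(seqs, k=3, params=params, seed=trial)
            stretch = IndexStretch(10.0)
            query = QuerySphere(seqs[trial % 15], float(rng.uniform(0, 0.8)))
            ranges = search_ranges(
                query, model, stretch, params, conservative=conservative
            )
            for s in seqs:
                if cis_distance(query.center, s, params) <= query.radius:
                    key = compute_key(s, model, stretch, params)
                    assert any(
                        r.left - 1e-9 <= key <= r.right + 1e-9 for r in ranges
                    ), f"answer {s.seq_id} outside all ranges"


class TestTierSearches:
    """ESearch / CSearch / DSearch against the linear-scan oracle."""

    def _system(self, seed, n=20):
        ds = generate_dataset(
            GeneratorParams(
                n_sequences=n, slices_range=(8, 16), image_size=(32, 32),
                seed=seed,
            )
        )
        return BrsSystem(
            ds.sequences, SimilarityParams(0.65), max_n=6, seed=seed
        )

    def test_cold_edge_returns_nothing(self):
        system = self._system(1)
        q = QuerySphere(system.sequences[1], 0.4)
        assert system.esearch(q) == set()

    def test_cold_start_csearch_is_complete(self):
        system = self._system(2)
        q = QuerySphere(system.sequences[3], 0.4)
        oracle = system.oracle(q)
        assert system.csearch(q) == oracle
        # returned sequences are now buffered at the edge
        for sid in oracle:
            assert system.is_buffered(sid)

    def test_esearch_after_warmup_equals_buffered_oracle(self):
        system = self._system(3)
        q = QuerySphere(system.sequences[5], 0.3)
        system.csearch(q)
        warm = system.esearch(q)
        oracle = system.oracle(q)
        buffered = system.buffered_ids
        assert warm == {sid for sid in oracle if sid in buffered}

    def test_dsearch_radius_one_returns_everything(self):
        system = self._system(4, n=10)
        q = QuerySphere(system.sequences[2], 1.0)
        assert system.dsearch(q) == set(system.sequences)

    def test_union_of_tier_searches_equals_oracle(self, rng):
        for seed in (5, 6):
            system = self._system(seed)
            for _ in range(15):
                sid = int(rng.integers(1, len(system.sequences) + 1))
                q = QuerySphere(
                    system.sequences[sid], float(rng.uniform(0.05, 0.6))
                )
                oracle = system.oracle(q)
                psi_e = system.esearch(q)
                psi_c = system.csearch(q)
                assert psi_e | psi_c == oracle
                assert system.dsearch(q) == oracle
                system._evict_to_capacity()

    def test_flag_conservation(self):
        system = self._system(7)
        all_ids = set(system.sequences)
        for sid in (1, 4, 9):
            system.brs_search(QuerySphere(system.sequences[sid], 0.4))
        for idx in (system.edge_index, system.cloud_index):
            assert {e.seq_ref for e in idx.entries()} == all_ids
            for e in idx.entries():
                assert (e.etype == "T") != (e.ctype == "T")


class TestSnapshot:
    def test_reload_reproduces_search_results(self, tmp_path, rng):
        seqs, params = make_pool(rng, n=10)
        model = cluster_sequences(seqs, k=3, params=params, seed=0)
        stretch = IndexStretch(10.0)
        idx = build_index(seqs, model, stretch, "cloud", params)
        path = tmp_path / "index.jsonl"
        save_index_snapshot(path, idx, model)
        idx2, model2 = load_index_snapshot(path, {s.seq_id: s for s in seqs})
        q = QuerySphere(seqs[0], 0.5)
        got1 = {e.seq_ref for e in range_search(q, idx, model, stretch, params)}
        got2 = {e.seq_ref for e in range_search(q, idx2, model2, stretch, params)}
        assert got1 == got2
        assert [e.key for e in idx.entries()] == [e.key for e in idx2.entries()]
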