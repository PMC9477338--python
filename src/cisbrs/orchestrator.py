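"""End-to-end batch retrieval over a simulated three-layer network.

A user node submits a (sequence, radius) query to an edge node.  The edge
first reuses verified answers from intersecting historical query spheres,
then searches its own buffer through the edge index; the cloud is consulted
through the cloud index for whatever the edge cannot certify.  Every answer
is refined by the exact batch dissimilarity, so the result always equals a
linear scan.  Answer sequences are buffered at the edge, the buffer is
evicted to capacity by the recency/frequency score, and answer blocks are
transmitted lesion-blocks-first after their IDs are decrypted.

Network bandwidths affect only the optional cost report — never the answer
set.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from cisbrs.block_privacy import (
    Block,
    BlockGrid,
    CodingConstants,
    CryptoKeys,
    PathRegion,
    Rect,
    classify_blocks,
    decrypt_block_id,
    encrypt_block_id,
    partition_slice,
)
from cisbrs.edge_buffer import (
    BufferEntry,
    HistoricalSphere,
    QuerySphere,
    evict,
    plan_with_history,
)
from cisbrs.sequence_model import (
    ImageSequence,
    SimilarityParams,
    cis_distance,
    extract_rcis,
)
from cisbrs.uecif_index import (
    ClusterModel,
    IndexStretch,
    OrderedIndex,
    _pairwise_distances,
    build_index,
    cluster_sequences,
    range_search,
)


@dataclass
class Mecn:
    """Mobile edge-cloud network: user, edge and cloud node names plus
    bandwidth-labelled links.  Must be connected with at least one node of
    each role."""

    users: list[str]
    edges: list[str]
    clouds: list[str]
    links: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        if not (self.users and self.edges and self.clouds):
            raise ValueError("need at least one node of each role")
        nodes = set(self.users) | set(self.edges) | set(self.clouds)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b, bw in self.links:
            if a not in nodes or b not in nodes:
                raise ValueError(f"link endpoint {a!r}/{b!r} is not a declared node")
            if bw <= 0:
                raise ValueError("bandwidth must be positive (Mbps)")
            g.add_edge(a, b, bandwidth=bw)
        if not nx.is_connected(g):
            raise ValueError("network graph must be connected")
        self.graph = g


@dataclass
class RetrievalResult:
    """Outcome of one query: the exact answer set, split into the part
    certified at the edge (buffer + history) and the part fetched from the
    cloud, plus the priority-ordered transmission plan."""

    answers: set[int]
    edge_part: set[int]
    cloud_part: set[int]
    transmission: list[Block] = field(default_factory=list)
    stats: dict = field(default_factory=dict)


def schedule_transmission(
    answers: set[int], block_store: dict[int, list[Block]]
) -> list[Block]:
    """Order all blocks of the answer sequences for transmission: priority
    descending (every CIB before every NIB), ties by (SID, IID, rID, cID)."""
    blocks: list[Block] = []
    for sid in sorted(answers):
        if sid not in block_store:
            raise RuntimeError(f"no blocks stored for sequence {sid}")
        blocks.extend(block_store[sid])
    return sorted(
        blocks,
        key=lambda b: (
            -b.priority,
            b.components.SID,
            b.components.IID,
            b.components.rID,
            b.components.cID,
        ),
    )


class BrsSystem:
    """Mutable retrieval state: the paired tier indexes, residency flags,
    edge-buffer access log, and the historical-sphere log.

    ``k_edge`` / ``k_cloud`` are the cluster counts of the edge and cloud
    indexes ('auto' = exemplar-detecting clustering with a sqrt(n) medoid
    fallback); ``max_n`` is the edge-buffer capacity in sequences.
    """

    def __init__(
        self,
        sequences: list[ImageSequence],
        params: SimilarityParams | None = None,
        *,
        k_edge: int | str = "auto",
        k_cloud: int | str = "auto",
        stretch: IndexStretch | None = None,
        max_n: int = 8,
        history_cap: int = 32,
        seed: int = 0,
        conservative: bool = True,
        network: Mecn | None = None,
    ) -> None:
        if not sequences:
            raise ValueError("need at least one sequence")
        ids = [s.seq_id for s in sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids")
        self.params = params or SimilarityParams()
        self.sequences = {s.seq_id: s for s in sequences}
        for s in sequences:
            if s.rcis is None:
                extract_rcis(s, self.params)
        self.stretch = stretch or IndexStretch()
        self.max_n = max_n
        self.conservative = conservative
        self.network = network
        D = _pairwise_distances(sequences, self.params)
        self.edge_model: ClusterModel = cluster_sequences(
            sequences, k_edge, self.params, seed, distances=D
        )
        self.cloud_model: ClusterModel = cluster_sequences(
            sequences, k_cloud, self.params, seed + 1, distances=D
        )
        self.edge_index: OrderedIndex = build_index(
            sequences, self.edge_model, self.stretch, "edge", self.params
        )
        self.cloud_index: OrderedIndex = build_index(
            sequences, self.cloud_model, self.stretch, "cloud", self.params
        )
        self.access_log: dict[int, BufferEntry] = {}
        self.history: deque[HistoricalSphere] = deque(maxlen=history_cap)
        self.clock: int = 0
        self.block_store: dict[int, list[Block]] = {}
        self.keys: CryptoKeys | None = None
        self.coding: CodingConstants | None = None
        self.encrypted_ids: dict[int, list] = {}

    # -- residency flags ----------------------------------------------------

    def is_buffered(self, sid: int) -> bool:
        return self.edge_index.lookup(sid).etype == "T"

    def _set_buffered(self, sid: int, buffered: bool) -> None:
        e = self.edge_index.lookup(sid)
        c = self.cloud_index.lookup(sid)
        e.etype = c.etype = "T" if buffered else "F"
        e.ctype = c.ctype = "F" if buffered else "T"

    def _touch(self, sid: int, touched: set[int]) -> None:
        """Buffer sid and log the access (once per query)."""
        if sid in touched:
            return
        touched.add(sid)
        self._set_buffered(sid, True)
        entry = self.access_log.get(sid)
        if entry is None:
            self.access_log[sid] = BufferEntry(sid, self.clock, 1)
        else:
            entry.access_time = self.clock
            entry.access_freq += 1

    @property
    def buffered_ids(self) -> set[int]:
        return {e.seq_ref for e in self.edge_index.entries() if e.etype == "T"}

    # -- tier searches ------------------------------------------------------

    def _refine(self, query: QuerySphere, candidates) -> set[int]:
        out = set()
        for entry in candidates:
            seq = self.sequences[entry.seq_ref]
            if cis_distance(query.center, seq, self.params) <= query.radius:
                out.add(entry.seq_ref)
        return out

    def esearch(self, query: QuerySphere, touched: set[int] | None = None) -> set[int]:
        """Partial answers among edge-buffered sequences (etype 'T'),
        refined by the exact dissimilarity; answers are re-logged."""
        cands = range_search(
            query, self.edge_index, self.edge_model, self.stretch,
            self.params, {"etype": "T"}, self.conservative,
        )
        answers = self._refine(query, cands)
        touched = touched if touched is not None else set()
        for sid in answers:
            self._touch(sid, touched)
        return answers

    def csearch(self, query: QuerySphere, touched: set[int] | None = None) -> set[int]:
        """Partial answers among cloud-resident sequences (ctype 'T');
        returned sequences become edge-buffered."""
        cands = range_search(
            query, self.cloud_index, self.cloud_model, self.stretch,
            self.params, {"ctype": "T"}, self.conservative,
        )
        answers = self._refine(query, cands)
        touched = touched if touched is not None else set()
        for sid in answers:
            self._touch(sid, touched)
        return answers

    def dsearch(self, query: QuerySphere, touched: set[int] | None = None) -> set[int]:
        """Complete answer set over all indexed sequences."""
        cands = range_search(
            query, self.cloud_index, self.cloud_model, self.stretch,
            self.params, None, self.conservative,
        )
        answers = self._refine(query, cands)
        if touched is not None:
            for sid in answers:
                self._touch(sid, touched)
        return answers

    def oracle(self, query: QuerySphere) -> set[int]:
        """Linear-scan reference answer set (no index)."""
        return {
            sid
            for sid, seq in self.sequences.items()
            if cis_distance(query.center, seq, self.params) <= query.radius
        }

    # -- block preprocessing ------------------------------------------------

    def preprocess_blocks(
        self,
        grid: BlockGrid,
        annotations: dict[int, dict[int, list[tuple[int, int, int, int]]]],
        keys: CryptoKeys,
        coding: CodingConstants | None = None,
        id_offset: int | None = None,
    ) -> None:
        """Partition every slice, classify blocks against its lesion
        rectangles, and encrypt the lesion-block IDs.

        The key constraint (delta_key strictly below every SID and IID)
        cannot hold for 1-based ids, so a public ``id_offset`` (default:
        delta_key itself) is added to SID and IID before encryption and
        subtracted after decryption; it carries no secret."""
        self.keys = keys
        self.coding = coding or CodingConstants()
        self.id_offset = keys.delta_key if id_offset is None else id_offset
        for sid, seq in self.sequences.items():
            blocks = []
            for sl in seq.slices:
                slice_blocks = partition_slice(sl, grid, sid=sid)
                rects = annotations.get(sid, {}).get(sl.slice_id, [])
                regions = [
                    PathRegion(i + 1, Rect(*r)) for i, r in enumerate(rects)
                ]
                classify_blocks(slice_blocks, regions)
                blocks.extend(slice_blocks)
            enc = []
            for b in blocks:
                if b.kind == "CIB":
                    enc_comp, scalar = encrypt_block_id(
                        self._offset_components(b.components),
                        keys,
                        self.coding,
                    )
                    enc.append((b, enc_comp, scalar))
            self.block_store[sid] = blocks
            self.encrypted_ids[sid] = enc

    def _offset_components(self, comp):
        from dataclasses import replace

        off = self.id_offset
        return replace(comp, SID=comp.SID + off, IID=comp.IID + off)

    # -- end-to-end retrieval ----------------------------------------------

    def brs_search(self, query: QuerySphere) -> RetrievalResult:
        """Run one batch retrieval: history reuse, edge search, cloud
        complement (or direct cloud search on a cold edge), buffering,
        eviction, and priority-ordered transmission.

        The returned answer set always equals the linear-scan oracle: every
        candidate from every path is refined by the exact dissimilarity, and
        the cloud is consulted whenever history does not certify completeness.
        """
        self.clock += 1
        touched: set[int] = set()
        verified, complete, usable = plan_with_history(
            query, list(self.history), self.sequences, self.params,
            tri_defect=self.cloud_model.tri_defect,
        )
        psi_edge = self.esearch(query, touched)
        edge_part = psi_edge | verified
        cloud_candidates = 0
        if complete:
            psi = edge_part
        elif psi_edge:
            psi_cloud = self.csearch(query, touched)
            cloud_candidates = len(psi_cloud)
            psi = edge_part | psi_cloud
        else:
            psi = self.dsearch(query, touched) | verified
            cloud_candidates = len(psi)
        for sid in psi:
            self._touch(sid, touched)
        cloud_part = psi - edge_part

        self.history.append(
            HistoricalSphere(query.center, query.radius, frozenset(psi))
        )
        self._evict_to_capacity()

        transmission: list[Block] = []
        if self.block_store and all(sid in self.block_store for sid in psi):
            transmission = schedule_transmission(psi, self.block_store)
            if self.keys is not None:
                for b in transmission:
                    if b.kind == "CIB":
                        # IDs travel encrypted; decryption precedes display
                        enc_comp, _ = encrypt_block_id(
                            self._offset_components(b.components),
                            self.keys,
                            self.coding,
                        )
                        decrypt_block_id(enc_comp, self.keys, self.coding)

        n_cib = sum(1 for b in transmission if b.kind == "CIB")
        return RetrievalResult(
            answers=psi,
            edge_part=edge_part & psi,
            cloud_part=cloud_part,
            transmission=transmission,
            stats={
                "edge_hits": len(edge_part & psi),
                "cloud_candidates": cloud_candidates,
                "complete_from_history": complete,
                "usable_history": len(usable),
                "buffered": len(self.buffered_ids),
                "blocks_cib": n_cib,
                "blocks_nib": len(transmission) - n_cib,
            },
        )

    def _evict_to_capacity(self) -> None:
        entries = [self.access_log[sid] for sid in sorted(self.buffered_ids)
                   if sid in self.access_log]
        kept, removed = evict(entries, self.max_n)
        for e in removed:
            self._set_buffered(e.seq_ref, False)


def simulate_session(
    workload: list[QuerySphere],
    system: BrsSystem,
    cost_model: dict | None = None,
) -> dict:
    """Replay a workload through :meth:`BrsSystem.brs_search`.

    Returns per-query stats plus session aggregates: the edge-hit fraction
    (answers certified at the edge over all answers), the maximum observed
    buffer occupancy, and — when a cost model with 'bytes_per_block' and
    'bandwidth_mbps' is given — a simulated transfer cost.  Costs never
    affect the answer sets.
    """
    per_query = []
    total_answers = 0
    total_edge = 0
    max_buffered = 0
    total_cost = 0.0
    for q in workload:
        res = system.brs_search(q)
        total_answers += len(res.answers)
        total_edge += len(res.edge_part)
        max_buffered = max(max_buffered, len(system.buffered_ids))
        if cost_model and res.transmission:
            total_cost += (
                len(res.transmission)
                * cost_model.get("bytes_per_block", 1024)
                * 8e-6
                / cost_model.get("bandwidth_mbps", 100.0)
            )
        per_query.append(
            {"answers": sorted(res.answers), **res.stats}
        )
    return {
        "n_queries": len(workload),
        "per_query": per_query,
        "total_answers": total_answers,
        "edge_hit_fraction": (total_edge / total_answers) if total_answers else 0.0,
        "max_buffered": max_buffered,
        "transfer_cost_s": total_cost if cost_model else None,
    }
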