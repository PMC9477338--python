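"""Uniform edge-cloud index: cluster-banded one-dimensional keys over CIS
dissimilarity, with residency flags and five-case range search.

Sequences are grouped around medoid exemplars; each sequence maps to the
scalar key ``j * c1 + d(X, center_j)`` where j is its 1-based cluster and d
is the batch dissimilarity.  Because c1 exceeds every cluster radius, the
per-cluster key bands never interleave, so a metric range query reduces to
at most one contiguous key interval per cluster.  Candidate sets from the
key scan are always refined by the exact dissimilarity, so a wider-than-
necessary interval costs time, never correctness.

The dissimilarity is a set-overlap complement and is not provably a metric;
by default each intersecting cluster is therefore scanned over its full key
band (conservative mode) and only the disjointness test prunes clusters.
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cisbrs.edge_buffer import QuerySphere
from cisbrs.sequence_model import ImageSequence, SimilarityParams, cis_distance


@dataclass
class ClusterModel:
    """Medoid clustering of the indexed sequences.

    ``centers[j-1]`` is the exemplar sequence of cluster j (1-based),
    ``radii[j-1]`` the maximum dissimilarity of its members to it, and
    ``assignment`` maps seq_id -> cluster index j.

    ``tri_defect`` is the maximal triangle-inequality defect
    max(0, d(x,z) - d(x,y) - d(y,z)) measured over all indexed triples: the
    batch dissimilarity is not provably metric, and any sphere-geometry
    pruning must be slackened by this amount to stay exact for queries
    centred on indexed sequences.
    """

    centers: list[ImageSequence]
    radii: list[float]
    assignment: dict[int, int]
    tri_defect: float = 0.0

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class IndexStretch:
    """Band stretch constant; must exceed 1 + max cluster radius so that the
    key bands of different clusters cannot overlap.  Dissimilarities live in
    [0, 1], so the default of 10 is always safe."""

    c1_idx: float = 10.0

    def __post_init__(self) -> None:
        if self.c1_idx <= 2.0:
            raise ValueError("c1_idx must exceed 1 + max possible radius (= 2)")


@dataclass
class LeafEntry:
    """One indexed sequence: its key, id, and tier-residency flags.

    Exactly one of etype/ctype is 'T': 'T' etype means buffered at the edge,
    'T' ctype means resident at the cloud.
    """

    key: float
    seq_ref: int
    etype: str = "F"
    ctype: str = "T"


class OrderedIndex:
    """Ordered map over (key, seq_id) supporting insert, point lookup and
    inclusive range scan — the leaf level of the paired tier indexes."""

    def __init__(self) -> None:
        self._keys: list[tuple[float, int]] = []
        self._entries: dict[int, LeafEntry] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def insert(self, entry: LeafEntry) -> None:
        if entry.seq_ref in self._entries:
            raise ValueError(f"duplicate sequence id {entry.seq_ref}")
        pair = (entry.key, entry.seq_ref)
        i = bisect_left(self._keys, pair)
        self._keys.insert(i, pair)
        self._entries[entry.seq_ref] = entry

    def lookup(self, seq_ref: int) -> LeafEntry:
        return self._entries[seq_ref]

    def range_scan(self, left: float, right: float) -> list[LeafEntry]:
        """All entries with left <= key <= right, in key order."""
        lo = bisect_left(self._keys, (left, -1))
        hi = bisect_right(self._keys, (right, float("inf")))
        return [self._entries[sid] for _, sid in self._keys[lo:hi]]

    def entries(self) -> list[LeafEntry]:
        return [self._entries[sid] for _, sid in self._keys]


@dataclass(frozen=True)
class SearchRange:
    """A contiguous key interval to scan inside one cluster's band."""

    cluster: int
    left: float
    right: float


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _pairwise_distances(
    sequences: list[ImageSequence], params: SimilarityParams
) -> np.ndarray:
    n = len(sequences)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = cis_distance(sequences[i], sequences[j], params)
    return D


def triangle_defect(D: np.ndarray) -> float:
    """Largest violation max(0, D[i,k] - D[i,j] - D[j,k]) over all triples."""
    worst = 0.0
    for j in range(D.shape[0]):
        slack = D - (D[:, j][:, None] + D[j, :][None, :])
        worst = max(worst, float(slack.max()))
    return max(0.0, worst)


def _kmedoids(D: np.ndarray, k: int, seed: int) -> list[int]:
    """Deterministic PAM-style k-medoids on a precomputed distance matrix:
    greedy BUILD then SWAP until no improvement."""
    n = D.shape[0]
    rng = np.random.default_rng(seed)  # reserved for tie shuffling; unused now
    del rng
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        best, best_cost = None, np.inf
        current = D[:, medoids].min(axis=1)
        for c in range(n):
            if c in medoids:
                continue
            cost = float(np.minimum(current, D[:, c]).sum())
            if cost < best_cost - 1e-12:
                best, best_cost = c, cost
        medoids.append(best)
    improved = True
    while improved:
        improved = False
        cost = float(D[:, medoids].min(axis=1).sum())
        for mi in range(k):
            for c in range(n):
                if c in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = c
                tcost = float(D[:, trial].min(axis=1).sum())
                if tcost < cost - 1e-12:
                    medoids, cost, improved = trial, tcost, True
    return sorted(medoids)


def cluster_sequences(
    sequences: list[ImageSequence],
    k: int | str = "auto",
    params: SimilarityParams | None = None,
    seed: int = 0,
    distances: np.ndarray | None = None,
) -> ClusterModel:
    """Group sequences around medoid exemplars under the batch dissimilarity.

    ``k='auto'`` tries affinity propagation on the similarity matrix (the
    exemplars it returns are medoids) and falls back to k-medoids with
    k = ceil(sqrt(n)) when it does not converge.  Centers are actual
    sequences; radii are exact maxima over members.  Deterministic for a
    given seed.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    params = params or SimilarityParams()
    n = len(sequences)
    D = distances if distances is not None else _pairwise_distances(sequences, params)

    medoid_idx: list[int] | None = None
    if k == "auto":
        import warnings

        from sklearn.cluster import AffinityPropagation
        from sklearn.exceptions import ConvergenceWarning

        ap = AffinityPropagation(
            affinity="precomputed", random_state=seed, max_iter=400
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            labels = ap.fit_predict(-D)
        degenerate = any(
            issubclass(w.category, (UserWarning, ConvergenceWarning))
            for w in caught
        )
        if (
            not degenerate
            and len(ap.cluster_centers_indices_) > 0
            and not np.any(labels < 0)
        ):
            medoid_idx = sorted(int(i) for i in ap.cluster_centers_indices_)
        else:
            k = min(n, int(np.ceil(np.sqrt(n))))
    if medoid_idx is None:
        k = int(k)
        if k < 1 or k > n:
            raise ValueError(f"k must be in [1, {n}]")
        medoid_idx = _kmedoids(D, k, seed)

    labels = np.argmin(D[:, medoid_idx], axis=1)
    centers = [sequences[m] for m in medoid_idx]
    radii = []
    assignment = {}
    for j in range(len(medoid_idx)):
        members = np.where(labels == j)[0]
        radii.append(float(D[members, medoid_idx[j]].max()) if len(members) else 0.0)
        for m in members:
            assignment[sequences[m].seq_id] = j + 1
    return ClusterModel(centers, radii, assignment, triangle_defect(D))


# ---------------------------------------------------------------------------
# Keys and index construction
# ---------------------------------------------------------------------------

def compute_key(
    X: ImageSequence,
    model: ClusterModel,
    stretch: IndexStretch,
    params: SimilarityParams | None = None,
) -> float:
    """Key of X: j * c1 + d(X, center_j) for its assigned cluster j."""
    params = params or SimilarityParams()
    try:
        j = model.assignment[X.seq_id]
    except KeyError:
        raise RuntimeError(f"sequence {X.seq_id} is not assigned to a cluster")
    return j * stretch.c1_idx + cis_distance(X, model.centers[j - 1], params)


def build_index(
    sequences: list[ImageSequence],
    model: ClusterModel,
    stretch: IndexStretch,
    tier: str,
    params: SimilarityParams | None = None,
) -> OrderedIndex:
    """Build the edge or cloud tier index with one leaf entry per sequence.

    A fresh edge index starts with every etype 'F' (sequences are only
    virtually at the edge); a fresh cloud index starts with every ctype 'T'.
    """
    if tier not in ("edge", "cloud"):
        raise ValueError("tier must be 'edge' or 'cloud'")
    idx = OrderedIndex()
    for X in sequences:
        key = compute_key(X, model, stretch, params)
        idx.insert(LeafEntry(key, X.seq_id, etype="F", ctype="T"))
    return idx


def search_ranges(
    query: QuerySphere,
    model: ClusterModel,
    stretch: IndexStretch,
    params: SimilarityParams | None = None,
    conservative: bool = True,
) -> list[SearchRange]:
    """Key intervals to scan, one per cluster whose sphere can intersect the
    query sphere.

    Per cluster j with D = d(center_j, query center), r = cluster radius,
    rR = query radius:

    * disjoint (D > r + rR): no range;
    * query contains cluster (D + r <= rR): full band [j*c1, j*c1 + r];
    * cluster contains query (D + rR <= r): [j*c1, j*c1 + min(r, D + rR)];
    * center inside query (D < rR): [j*c1, j*c1 + min(r, D + rR)];
    * plain intersection: [j*c1 + D - rR, j*c1 + min(r, D + rR)].

    With ``conservative=True`` (default) every non-pruned cluster gets its
    full band, and the disjointness prune is slackened by the measured
    triangle defect of the indexed set, so a triangle-inequality failure of
    the dissimilarity can never push a true answer outside the scanned
    intervals (for query centers drawn from the indexed set, for which the
    defect bound holds).
    """
    params = params or SimilarityParams()
    rR = query.radius
    slack = model.tri_defect if conservative else 0.0
    out = []
    for j in range(1, model.n_clusters + 1):
        r = model.radii[j - 1]
        D = cis_distance(query.center, model.centers[j - 1], params)
        base = j * stretch.c1_idx
        if D > r + rR + slack:
            continue  # disjoint spheres: no member can answer
        if conservative:
            out.append(SearchRange(j, base, base + r))
            continue
        hi = base + min(r, D + rR)
        if D + r <= rR or D + rR <= r or D < rR:
            out.append(SearchRange(j, base, hi))
        else:
            out.append(SearchRange(j, base + D - rR, hi))
    return out


def range_search(
    query: QuerySphere,
    index: OrderedIndex,
    model: ClusterModel,
    stretch: IndexStretch,
    params: SimilarityParams | None = None,
    flag_filter: dict[str, str] | None = None,
    conservative: bool = True,
) -> list[LeafEntry]:
    """Union of key-band scans over :func:`search_ranges`, restricted to
    entries matching ``flag_filter`` (e.g. {'etype': 'T'}).  Returns
    candidates; exact refinement is the caller's job."""
    seen: dict[int, LeafEntry] = {}
    for rng in search_ranges(query, model, stretch, params, conservative):
        for entry in index.range_scan(rng.left, rng.right):
            if flag_filter and any(
                getattr(entry, attr) != want for attr, want in flag_filter.items()
            ):
                continue
            seen[entry.seq_ref] = entry
    return list(seen.values())


# ---------------------------------------------------------------------------
# Snapshot I/O
# ---------------------------------------------------------------------------

def save_index_snapshot(
    path: str | Path, index: OrderedIndex, model: ClusterModel
) -> None:
    """JSON-lines snapshot of leaf entries plus the cluster model skeleton."""
    path = Path(path)
    with path.open("w") as fh:
        header = {
            "center_ids": [c.seq_id for c in model.centers],
            "radii": model.radii,
            "assignment": {str(k): v for k, v in model.assignment.items()},
        }
        fh.write(json.dumps({"model": header}) + "\n")
        for e in index.entries():
            fh.write(
                json.dumps(
                    {"key": e.key, "seq_ref": e.seq_ref, "etype": e.etype, "ctype": e.ctype}
                )
                + "\n"
            )


def load_index_snapshot(
    path: str | Path, sequences: dict[int, ImageSequence]
) -> tuple[OrderedIndex, ClusterModel]:
    path = Path(path)
    lines = path.read_text().splitlines()
    header = json.loads(lines[0])["model"]
    model = ClusterModel(
        centers=[sequences[i] for i in header["center_ids"]],
        radii=header["radii"],
        assignment={int(k): v for k, v in header["assignment"].items()},
    )
    idx = OrderedIndex()
    for line in lines[1:]:
        rec = json.loads(line)
        idx.insert(LeafEntry(rec["key"], rec["seq_ref"], rec["etype"], rec["ctype"]))
    return idx, model
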