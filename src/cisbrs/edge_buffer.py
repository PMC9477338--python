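"""Edge-buffer ranking, eviction, and historical query-sphere reuse.

Buffered sequences carry an access time (AT) and an access frequency (AF).
Recency ranks (most recent = 1) and frequencies are normalized into a
weighted access time WAT = rank / n and a weighted access frequency
WAF = 1 - AF / (max AF + 1); their sum is the uniform ranking score (URS).
A smaller URS marks a more valuable sequence, so eviction removes the
largest-URS entries first.

Completed queries leave behind historical retrieval spheres — a center
sequence, a radius, and the verified answer set.  A new query can reuse any
answer of an intersecting historical sphere that lies within its own radius,
and can skip the cloud entirely when some historical sphere contains it.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from cisbrs.sequence_model import ImageSequence, SimilarityParams, cis_distance


def parse_timestamp(ts: int | float | str) -> float:
    """Accept numeric ticks or 'H:MM' clock strings (minutes since midnight)."""
    if isinstance(ts, str):
        hh, mm = ts.split(":")
        return float(int(hh) * 60 + int(mm))
    return float(ts)


@dataclass
class BufferEntry:
    """One buffered sequence with its last access time and access count."""

    seq_ref: int
    access_time: int | float | str
    access_freq: int

    def __post_init__(self) -> None:
        if self.access_freq < 1:
            raise ValueError("access_freq must be >= 1")

    @property
    def time_value(self) -> float:
        return parse_timestamp(self.access_time)


@dataclass
class RankedEntry:
    entry: BufferEntry
    at_id: int
    wat: Fraction
    waf: Fraction

    @property
    def urs(self) -> Fraction:
        return self.wat + self.waf


def rank_buffer(entries: list[BufferEntry]) -> list[RankedEntry]:
    """Score entries by recency and frequency.

    The most recently accessed entry gets recency rank 1, the oldest rank n
    (ties share the earlier rank position deterministically by seq id).
    WAT = rank / n, WAF = 1 - AF/(max AF + 1), URS = WAT + WAF, all exact
    fractions.  Output preserves the input order.
    """
    if not entries:
        raise ValueError("need at least one entry")
    ids = [e.seq_ref for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in buffer")
    n = len(entries)
    by_recency = sorted(entries, key=lambda e: (-e.time_value, e.seq_ref))
    rank = {e.seq_ref: i + 1 for i, e in enumerate(by_recency)}
    max_af = max(e.access_freq for e in entries)
    return [
        RankedEntry(
            entry=e,
            at_id=rank[e.seq_ref],
            wat=Fraction(rank[e.seq_ref], n),
            waf=1 - Fraction(e.access_freq, max_af + 1),
        )
        for e in entries
    ]


def evict(
    entries: list[BufferEntry], max_n: int
) -> tuple[list[BufferEntry], list[BufferEntry]]:
    """Shrink the buffer to at most ``max_n`` entries.

    The |entries| - max_n largest-URS entries are removed (largest first;
    URS ties broken by larger seq id).  Returns (kept, removed), kept in
    input order.  Callers owning residency flags flip removed entries back
    to cloud residency.
    """
    if max_n < 0:
        raise ValueError("max_n must be >= 0")
    excess = len(entries) - max_n
    if excess <= 0:
        return list(entries), []
    ranked = rank_buffer(entries)
    doomed = sorted(ranked, key=lambda r: (r.urs, r.entry.seq_ref), reverse=True)
    removed_ids = {r.entry.seq_ref for r in doomed[:excess]}
    kept = [e for e in entries if e.seq_ref not in removed_ids]
    removed = [e for e in entries if e.seq_ref in removed_ids]
    return kept, removed


# ---------------------------------------------------------------------------
# Query spheres and historical reuse
# ---------------------------------------------------------------------------

@dataclass
class QuerySphere:
    """A retrieval request: a center sequence and a dissimilarity radius."""

    center: ImageSequence
    radius: float

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")


@dataclass
class HistoricalSphere:
    """A completed query whose answer set has been verified: every answer id
    satisfies d(center, answer) <= radius."""

    center: ImageSequence
    radius: float
    answers: frozenset[int]


def plan_with_history(
    query: QuerySphere,
    history: list[HistoricalSphere],
    sequences: dict[int, ImageSequence],
    params: SimilarityParams | None = None,
    tri_defect: float = 0.0,
) -> tuple[set[int], bool, list[HistoricalSphere]]:
    """Reuse verified answers from intersecting historical spheres.

    Spheres disjoint from the query (center distance > rR + radius) are
    discarded.  For each remaining sphere, every recorded answer within the
    query radius joins ``verified`` — each candidate is re-checked against
    the query center directly, so reuse is sound by construction.
    ``complete`` is True when some usable sphere contains the query sphere
    (center distance + rR <= historical radius), meaning its answer set
    already covers every possible answer and no cloud search is needed.

    Because the dissimilarity is not provably metric, the containment test
    is slackened by ``tri_defect`` (the indexed set's measured
    triangle-inequality defect); a sphere with the identical center and a
    radius >= rR certifies completeness unconditionally.
    """
    params = params or SimilarityParams()
    verified: set[int] = set()
    usable: list[HistoricalSphere] = []
    complete = False
    for sphere in history:
        d = cis_distance(query.center, sphere.center, params)
        if d > query.radius + sphere.radius:
            continue
        usable.append(sphere)
        if (d == 0.0 and query.radius <= sphere.radius) or (
            d + query.radius + tri_defect <= sphere.radius
        ):
            complete = True
        for sid in sphere.answers:
            if sid in verified:
                continue
            seq = sequences.get(sid)
            if seq is None:
                continue
            if cis_distance(query.center, seq, params) <= query.radius:
                verified.add(sid)
    return verified, complete, usable
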