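# Methods

## Problem setting

A thoracic CT study is an ordered stack of grayscale slices (a *CT image
sequence*, CIS).  Content-based retrieval asks: given a query sequence
`X_R` and a radius `r_R`, return every archived sequence within
dissimilarity `r_R` of `X_R`.  The package simulates the full retrieval
path of a telemedicine deployment — a user node, an edge node that buffers
popular sequences, and a cloud node holding the archive — and adds a
privacy layer that scrambles the identifiers of lesion-bearing image
blocks before they leave the archive.

## Batch similarity over representative slices

Consecutive CT slices are nearly identical, so each sequence is first
reduced to its *representative slices* (RCIs): the first slice is always
kept, and slice *j*+1 is kept whenever the Euclidean distance between the
feature vectors of slices *j* and *j*+1 exceeds a threshold ε.  The
comparison is against the *immediately preceding slice*, not the last kept
representative; both readings are defensible, but the consecutive-slice
reading makes the scan a single pass and matches the initialization of the
extraction procedure.  ε is the one tuning knob of the similarity layer:
larger ε means fewer representatives and cheaper comparisons but a coarser
similarity.  The default is ε = 0.65 in feature-space units.

Two sequences are compared by counting, on both sides, representatives
that have at least one counterpart on the other side within ε:

    sim(Xm, Xn) = (#matched RCIs of Xm + #matched RCIs of Xn)
                  / (||Xm|| + ||Xn||)

with ||X|| the number of representatives.  The denominator uses
representative counts — not slice counts — so that `sim(X, X) = 1` and
`sim ∈ [0, 1]`.  Ties at exactly ε count as similar; a consecutive-slice
distance of exactly ε does *not* open a new representative.  Everywhere a
distance is needed (index keys, query spheres), the package uses
`d = 1 − sim`.

Per-slice features are pluggable.  The default pixel extractor is a
flattened, mean-normalized 16×16 down-sampling of the slice; the synthetic
generator instead attaches its latent vectors (plus observation noise) so
that ground truth is exact.  The active extractor is recorded in the
dataset manifest.

## Block privacy

Each slice is cut into a `rows × cols` grid (default 6×8); remainder
pixels are absorbed by the last row/column so the block count is always
`rows × cols`.  Blocks intersecting an expert-marked lesion rectangle are
*critical* (CIB): full resolution, scrambled IDs, first in transmission
order.  The rest (NIB) may be stored mean-pooled at reduced resolution.

A block ID packs (SID, IID, rID, cID) into the scalar
`SID·c1 + IID·c2 + rID·c3 + cID` with c1 ≫ c2 ≫ c3 (default 1000/100/10,
a ≥10× ratio is enforced).  Encryption shifts SID/IID by an integer key δ
(sign chosen by row parity) and the row by a fractional key ω (sign chosen
by column parity).  Decryption exploits that the column is never touched:
its parity says whether ω was added or subtracted, which recovers the
integer row and hence the branch, making `decrypt ∘ encrypt` the identity.
This is why ω is constrained to (0, 1): it keeps the encrypted row within
one unit of the true row.  The scheme is ID scrambling, not
cryptographic-strength encryption; its point is that neighbouring blocks
stop having consecutive scalars (within-row neighbours move from a gap of
1 to 1 ± 2ω·c3), so an eavesdropper must guess the block order.  For
lesion regions covering `RS_i × CS_i` blocks the chance of a correct
guess is `1 / ∏ (RS_i·CS_i)!`.

The key constraint δ < SID, δ < IID cannot hold for 1-based IDs, so the
orchestrator adds a public integer offset (default: δ itself) to SID and
IID before encryption and strips it after decryption.  The offset carries
no secret; it only places IDs inside the scheme's valid domain.

## The two-tier index

Sequences are grouped around medoid exemplars — by default affinity
propagation on the precomputed similarity matrix (whose exemplars are
medoids), falling back to a deterministic PAM-style k-medoids at
k = ⌈√n⌉ if propagation fails to converge or degenerates.  Each sequence
gets the scalar key `j·c1 + d(X, center_j)` for its cluster j; since
`c1 = 10` exceeds any possible radius, cluster key bands never interleave
and a metric range query touches at most one contiguous interval per
cluster.  The ordered map behind both tiers is a sorted key list with
binary search; its internals are deliberately unremarkable.

Edge and cloud keep separate clusterings (counts K and T) over the same
entries; each entry carries residency flags with the invariant that a
sequence is counted at exactly one tier.  A fresh edge index marks
everything *not* buffered; a fresh cloud index marks everything resident.

**Non-metric caveat and the conservative mode.**  `1 − sim` is a
set-overlap complement and violates the triangle inequality in practice
(defects up to ≈ 0.33 arise in synthetic data).  Sphere-geometry pruning
that assumes the triangle inequality can therefore miss true answers.  The
index measures the maximal triangle defect
`τ = max(0, d(x,z) − d(x,y) − d(y,z))` over all indexed triples at build
time and, in the default conservative mode, (a) scans the full key band of
every candidate cluster and (b) prunes a cluster only when
`D > r + r_R + τ`.  For queries centred on indexed sequences — the
workload contract — this is provably exact; candidates are in any case
refined by the exact dissimilarity, so a loose band costs time, never
correctness.  The non-conservative mode implements the narrowed five-case
ranges for the metric situation.

## Edge buffering and eviction

Buffered sequences log an access time and an access frequency.  Recency
ranks (most recent = 1, ties broken by sequence id) normalize to
`WAT = rank / n`; frequencies to `WAF = 1 − AF/(max AF + 1)`.  The
eviction score is `URS = WAT + WAF`, kept as exact fractions; larger URS
evicts first, down to the capacity `MaxN` (a sequence count, default 8).
The `+1` in the WAF denominator is deliberate: it is the only reading that
reproduces the method's worked six-sequence example cell for cell, and it
keeps WAF strictly positive so a maximally popular sequence still carries
recency information.

## Historical-sphere reuse

Every completed query leaves a *historical retrieval sphere*: its center,
radius, and verified answer set (the last 32 are retained).  A new query
discards spheres it cannot intersect, re-checks every remembered answer of
the remaining spheres against its own center — so reused answers are sound
by construction — and skips the cloud entirely when a sphere *contains*
the query sphere.  The containment test is slackened by the same triangle
defect τ; a sphere with the identical center and a radius ≥ r_R certifies
completeness unconditionally.

## Orchestration

One query proceeds: history reuse → edge search over buffered entries → if
history certified completeness, stop; else if the edge produced answers,
complement from the cloud; else search the cloud directly.  Two readings
of the printed control flow would leave the system incorrect or cold:
consulting the cloud *only* when the edge returns something loses answers
whenever coverage is incomplete, and never buffering on the direct-search
path means an empty buffer stays empty.  The implementation consults the
cloud whenever completeness is not certified, and buffers and logs
answers on every path, after which the buffer is evicted to capacity.
Answer blocks are transmitted in descending priority — every CIB before
any NIB, ties by (SID, IID, rID, cID) — with CIB identifiers decrypted
before reconstruction.  Time is a logical clock incremented per query;
network bandwidths feed only the optional transfer-cost report and can
never change an answer set.

## Synthetic data

The generator emulates the structure the method assumes, at desk scale
(defaults: 30 sequences × 20–60 slices × 64×64 pixels, 6×8 grid, 16
latent dimensions).  Each cluster of sequences shares a set of "anatomy
stages" spaced about `jump_magnitude` (default 1.0) apart; a sequence
drifts around one stage with per-slice noise `drift_sigma` (default 0.01)
and jumps to a sibling stage with probability `jump_prob` (default 0.05)
per transition, logging the event.  Same-cluster sequences therefore share
representative slices and take graded similarities; cross-cluster pairs
sit near distance 1.  Lesion rectangles (0–2 per sequence, 4–12 px sides)
are embedded as elevated-intensity regions with annotations.  Everything
is reproducible from the seed.

What the generator does *not* emulate: lung anatomy, scanner noise
statistics, DICOM metadata, inter-reader annotation variability, or
archive-scale data volumes.  Passing tests demonstrate the correctness of
the retrieval machinery under the assumed similarity structure, not
clinical retrieval quality.

Workloads mix fresh queries (centers drawn without replacement), exact
repeats (probability `repeat_prob`), and optional radius-perturbed
near-repeats; radii default to [0.1, 0.5].

## Problem sizes and numerical choices

Tests and the acceptance script run 10 datasets of 20 sequences (8–16
slices of 32×32 pixels) with 20 queries each — large enough to exercise
cold and warm buffers, cluster pruning, and history reuse, small enough to
keep the whole suite in seconds.  Exact fractions are used wherever the
buffer arithmetic is defined by a worked example; float comparisons use
1e-9–1e-12 guards; the decrypted row is rounded at 12 decimals before the
integrality check to absorb float error in ω arithmetic.  Eviction ties on
URS are broken toward evicting the larger sequence id; recency ties rank
the smaller id as more recent.  Degenerate inputs (empty region lists,
single-entry buffers, radius 0, k = n clustering) are all defined and
tested.

## Known limitations

- Exactness of index pruning and history completeness is guaranteed only
  for query centers drawn from the indexed set; foreign query sequences
  fall back on the same machinery but the measured defect bound does not
  formally cover them.
- The ordered index favors clarity over asymptotics (O(n) insert).
- The privacy layer is obfuscation by design; no formal security claim is
  made or implied.
- Wall-clock performance of a real edge-cloud deployment is out of scope;
  the cost model is a first-order bytes/bandwidth estimate.
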