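# cisbrs

Privacy-preserving batch retrieval of CT image sequences over a simulated
edge-cloud network.

A CT study is an ordered stack of slices retrieved as one unit (a *CIS*).
`cisbrs` implements the full retrieval path for a telemedicine setting:

- **Batch similarity** — each sequence is reduced to its representative
  slices (a slice is kept when its feature distance to the previous slice
  exceeds ε), and two sequences are scored by the fraction of
  representatives on either side with a counterpart within ε on the other:
  `sim(Xm, Xn) = (m↔n matches) / (||Xm|| + ||Xn||) ∈ [0, 1]`, with
  `d = 1 − sim` as the retrieval distance.
- **Block privacy** — slices are cut into a grid; blocks intersecting an
  expert-marked lesion rectangle keep full resolution and get their IDs
  `SID·c1 + IID·c2 + rID·c3 + cID` scrambled by parity-branched key
  offsets (δ, ω).  Decryption with the keys is exact; without them a
  lesion region of b blocks reassembles correctly with probability `1/b!`.
- **Two-tier index** — sequences cluster around medoids and map to
  one-dimensional keys `j·c1 + d(X, center_j)`, held in ordered edge and
  cloud indexes with residency flags; range queries scan at most one key
  interval per cluster, with pruning made robust to the non-metric
  distance by a measured triangle-defect slack.
- **Edge buffering** — buffered sequences are ranked by
  `URS = WAT + WAF` (recency rank / n plus `1 − AF/(max AF + 1)`); the
  largest scores are evicted beyond capacity `MaxN`.  Verified answer sets
  of past queries (historical spheres) are reused, and a sphere containing
  the current query short-circuits the cloud entirely.
- **Orchestration** — a single call runs history reuse, edge search, cloud
  complement and eviction, and schedules block transmission with every
  lesion block ahead of every ordinary block.  Answers always equal a
  linear scan.

## Worked example

```sh
cisbrs generate --out demo_ds --seed 3 --n-sequences 8
cisbrs index demo_ds
cisbrs search demo_ds --query-seq 2 --radius 0.4
```

prints

```
{"dataset": "demo_ds", "n_sequences": 8, "n_slices": 357}
{"n_indexed": 8, "edge_clusters": 2, "cloud_clusters": 3}
{"answers": [2], "edge_part": [], "cloud_part": [2],
 "stats": {"edge_hits": 0, "cloud_candidates": 1,
           "complete_from_history": false, "usable_history": 0,
           "buffered": 1, "blocks_cib": 288, "blocks_nib": 1440}}
```

The cold query found one answer (the query sequence itself at this
radius), fetched from the cloud and now buffered at the edge; its 288
lesion blocks would transmit — encrypted — ahead of the 1440 ordinary
blocks.  Repeating the query is then served from history with zero cloud
candidates.

`cisbrs buffer-report` prints the eviction arithmetic on the six-sequence
reference example, as exact fractions:

```
CIS_1: AT=2:50 AF=1 AT_ID=4 WAT=2/3 WAF=4/5 URS=22/15
CIS_2: AT=3:40 AF=3 AT_ID=2 WAT=1/3 WAF=2/5 URS=11/15
CIS_3: AT=1:48 AF=1 AT_ID=6 WAT=1 WAF=4/5 URS=9/5
CIS_4: AT=4:21 AF=4 AT_ID=1 WAT=1/6 WAF=1/5 URS=11/30
CIS_5: AT=2:32 AF=2 AT_ID=5 WAT=5/6 WAF=3/5 URS=43/30
CIS_6: AT=3:11 AF=3 AT_ID=3 WAT=1/2 WAF=2/5 URS=9/10
```

With capacity 4, the two largest scores (CIS_3, then CIS_1) are evicted.

The same functionality is available as a library:

```python
from cisbrs import SimilarityParams
from cisbrs.edge_buffer import QuerySphere
from cisbrs.orchestrator import BrsSystem
from cisbrs.synthetic_data import GeneratorParams, generate_dataset

ds = generate_dataset(GeneratorParams(n_sequences=20, seed=7))
system = BrsSystem(ds.sequences, SimilarityParams(epsilon=0.65), max_n=8)
result = system.brs_search(QuerySphere(system.sequences[3], radius=0.4))
assert result.answers == system.oracle(QuerySphere(system.sequences[3], 0.4))
```

## Layout

- `src/cisbrs/sequence_model.py` — sequences, representative-slice
  extraction, batch similarity, dataset I/O
- `src/cisbrs/block_privacy.py` — block grid, lesion classification, ID
  encode/encrypt/decrypt, reconstruction probability
- `src/cisbrs/uecif_index.py` — medoid clustering, banded keys, ordered
  tier indexes, range search
- `src/cisbrs/edge_buffer.py` — recency/frequency ranking, eviction,
  historical-sphere reuse
- `src/cisbrs/orchestrator.py` — the network model and end-to-end search
- `src/cisbrs/synthetic_data.py` — dataset and workload generators
- `docs/methods.md` — the model, its assumptions and design choices
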