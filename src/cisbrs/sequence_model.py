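"""CT image sequences, representative-slice extraction, and batch similarity.

A CT image sequence (CIS) is an ordered stack of grayscale slices.
Consecutive slices are usually nearly identical, so the sequence is summarized
by its representative slices (RCIs): a slice is retained whenever its feature
distance to the immediately preceding slice exceeds a threshold ``epsilon``.
Two sequences are then compared by the fraction of RCIs on either side that
have at least one close RCI on the other side — a set-overlap similarity in
[0, 1] whose complement serves as the retrieval distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize


@dataclass
class ImageSlice:
    """One CT slice: a position in its sequence, a pixel grid, and a feature
    vector used for all distance computations."""

    slice_id: int
    pixels: np.ndarray
    feature: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.feature = np.asarray(self.feature, dtype=float).ravel()
        if self.slice_id < 1:
            raise ValueError("slice_id must be >= 1")
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")


@dataclass
class ImageSequence:
    """An ordered list of slices treated as one retrieval unit.

    ``rcis`` is filled by :func:`extract_rcis`; it is an order-preserving
    sublist of ``slices`` and is what batch similarity operates on.
    """

    seq_id: int
    slices: list[ImageSlice]
    rcis: list[ImageSlice] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.seq_id < 1:
            raise ValueError("seq_id must be >= 1")
        if len(self.slices) < 1:
            raise ValueError("a sequence needs at least one slice")
        dims = {s.feature.shape for s in self.slices}
        if len(dims) > 1:
            raise ValueError("feature dimension must be equal across slices")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def n_rcis(self) -> int:
        if self.rcis is None:
            raise RuntimeError("RCIs not extracted; call extract_rcis first")
        return len(self.rcis)


@dataclass
class SimilarityParams:
    """Similarity threshold epsilon: two slices are 'similar' when their
    feature distance is <= epsilon; a new RCI starts when the consecutive
    distance is > epsilon."""

    epsilon: float = 0.65

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


def slice_distance(a: ImageSlice, b: ImageSlice) -> float:
    """Euclidean distance between the feature vectors of two slices."""
    if a.feature.shape != b.feature.shape:
        raise ValueError(
            f"feature dimension mismatch: {a.feature.shape} vs {b.feature.shape}"
        )
    return float(np.linalg.norm(a.feature - b.feature))


def extract_rcis(
    X: ImageSequence, params: SimilarityParams
) -> list[ImageSlice]:
    """Extract representative slices by a single scan over the sequence.

    The first slice is always an RCI.  Scanning j = 1 .. |X|-1, slice j+1 is
    appended as a new RCI whenever its distance to slice j exceeds epsilon.
    The result is stored on ``X.rcis`` and returned.
    """
    rcis = [X.slices[0]]
    for j in range(len(X.slices) - 1):
        if slice_distance(X.slices[j], X.slices[j + 1]) > params.epsilon:
            rcis.append(X.slices[j + 1])
    X.rcis = rcis
    return rcis


def _rci_matrix(X: ImageSequence) -> np.ndarray:
    # cache keyed on the identity of the rcis list: re-extraction invalidates
    cache = getattr(X, "_rci_cache", None)
    if cache is not None and cache[0] == id(X.rcis):
        return cache[1]
    mat = np.stack([r.feature for r in X.rcis])
    X._rci_cache = (id(X.rcis), mat)
    return mat


def batch_similarity(
    Xm: ImageSequence, Xn: ImageSequence, params: SimilarityParams
) -> float:
    """Fraction of RCIs, counted on both sides, that have a match on the
    other side within epsilon.

    sim = (|{RCI in Xm matched in Xn}| + |{RCI in Xn matched in Xm}|)
          / (||Xm|| + ||Xn||)

    Symmetric, in [0, 1], and 1 on identical sequences.
    """
    if Xm.rcis is None or Xn.rcis is None:
        raise RuntimeError("both sequences need extracted RCIs")
    fm = _rci_matrix(Xm)
    fn = _rci_matrix(Xn)
    if fm.shape[1] != fn.shape[1]:
        raise ValueError("feature dimension mismatch between sequences")
    # pairwise distances between the two RCI sets
    d = np.sqrt(
        np.maximum(
            ((fm[:, None, :] - fn[None, :, :]) ** 2).sum(axis=2), 0.0
        )
    )
    matched_m = int(np.count_nonzero((d <= params.epsilon).any(axis=1)))
    matched_n = int(np.count_nonzero((d <= params.epsilon).any(axis=0)))
    return (matched_m + matched_n) / (len(Xm.rcis) + len(Xn.rcis))


def cis_distance(
    Xm: ImageSequence, Xn: ImageSequence, params: SimilarityParams
) -> float:
    """Dissimilarity 1 - batch_similarity, used wherever the index and the
    search-sphere geometry need a distance.  Zero for identical sequences."""
    return 1.0 - batch_similarity(Xm, Xn, params)


# ---------------------------------------------------------------------------
# Feature extractors
# ---------------------------------------------------------------------------

def _feature_downsample(pixels: np.ndarray, size: int = 16) -> np.ndarray:
    """Default pixel feature: flattened, mean-normalized size x size
    down-sampling of the intensity grid."""
    small = resize(
        pixels.astype(float), (size, size), anti_aliasing=True, mode="reflect"
    )
    flat = small.ravel()
    return flat - flat.mean()


FEATURE_EXTRACTORS = {
    "downsample16": lambda px: _feature_downsample(px, 16),
    "downsample8": lambda px: _feature_downsample(px, 8),
}


def compute_features(pixels: np.ndarray, extractor: str = "downsample16") -> np.ndarray:
    try:
        fn = FEATURE_EXTRACTORS[extractor]
    except KeyError:
        raise ValueError(f"unknown feature extractor {extractor!r}") from None
    return fn(pixels)


# ---------------------------------------------------------------------------
# Dataset directory I/O
# ---------------------------------------------------------------------------
#
# Layout:  <root>/manifest.json
#          <root>/seq_<SID>/slice_<IID>.png      (uint8 grayscale pixels)
#          <root>/seq_<SID>/features.csv         (one row per slice)
#          <root>/seq_<SID>/annotations.json     (POA rectangles per slice)


def save_dataset(
    root: str | Path,
    sequences: list[ImageSequence],
    *,
    dataset_id: str = "dataset",
    grid_shape: tuple[int, int] = (6, 8),
    extractor: str = "downsample16",
    extractor_params: dict | None = None,
    annotations: dict[int, dict[int, list[tuple[int, int, int, int]]]] | None = None,
) -> Path:
    """Write a dataset directory: manifest + one subdirectory per sequence.

    ``annotations`` maps seq_id -> slice_id -> list of (r0, c0, r1, c1)
    half-open lesion rectangles.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "dataset_id": dataset_id,
        "grid_shape": list(grid_shape),
        "feature_extractor": {"name": extractor, "params": extractor_params or {}},
        "sequences": [
            {"seq_id": s.seq_id, "n_slices": len(s.slices)} for s in sequences
        ],
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    annotations = annotations or {}
    for seq in sequences:
        sdir = root / f"seq_{seq.seq_id}"
        sdir.mkdir(exist_ok=True)
        feats = []
        for sl in seq.slices:
            px = np.clip(np.rint(sl.pixels), 0, 255).astype(np.uint8)
            Image.fromarray(px, mode="L").save(sdir / f"slice_{sl.slice_id}.png")
            feats.append(sl.feature)
        np.savetxt(sdir / "features.csv", np.stack(feats), delimiter=",")
        ann = annotations.get(seq.seq_id, {})
        (sdir / "annotations.json").write_text(
            json.dumps({str(k): [list(r) for r in v] for k, v in ann.items()})
        )
    return root


def load_dataset(
    root: str | Path,
) -> tuple[list[ImageSequence], dict, dict[int, dict[int, list[tuple[int, int, int, int]]]]]:
    """Load a dataset directory written by :func:`save_dataset`.

    Returns (sequences, manifest, annotations); the stored feature vectors
    are used verbatim so a save/load round trip is bit-exact.
    """
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    sequences = []
    annotations: dict[int, dict[int, list[tuple[int, int, int, int]]]] = {}
    for entry in manifest["sequences"]:
        sid = entry["seq_id"]
        sdir = root / f"seq_{sid}"
        feats = np.loadtxt(sdir / "features.csv", delimiter=",", ndmin=2)
        slices = []
        for iid in range(1, entry["n_slices"] + 1):
            px = np.asarray(Image.open(sdir / f"slice_{iid}.png"), dtype=np.uint8)
            slices.append(ImageSlice(iid, px, feats[iid - 1]))
        sequences.append(ImageSequence(sid, slices))
        ann_file = sdir / "annotations.json"
        if ann_file.exists():
            raw = json.loads(ann_file.read_text())
            if raw:
                annotations[sid] = {
                    int(k): [tuple(r) for r in v] for k, v in raw.items()
                }
    return sequences, manifest, annotations
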