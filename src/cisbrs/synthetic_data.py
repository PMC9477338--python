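"""Synthetic CT-sequence datasets and query workloads at desk scale.

The generator emulates the statistical structure the retrieval method
assumes in a thoracic CT archive: many sequences of consecutive,
visually-similar slices with occasional abrupt anatomical changes (the
boundaries that representative-slice extraction should find), rectangular
lesion annotations inside the slice, and inter-sequence cluster structure.
Each cluster owns a small set of shared "anatomy stages" — latent feature
vectors spaced roughly ``jump_magnitude`` apart around the cluster
prototype.  A sequence starts near one stage and drifts with per-slice
Gaussian noise; with probability ``jump_prob`` per transition it jumps to a
different stage of its cluster.  Sequences of the same cluster therefore
share stages, so their representative slices partially match and the batch
similarity takes graded values in (0, 1]; cross-cluster pairs share nothing
and sit near distance 1.  The jump log is the ground truth for
representative-slice recall.  Pixels are rendered from the latent vector
through a fixed random projection, so the pixel-based feature extractor
sees the same geometry the latent features encode.

No attempt is made at anatomical realism; the generator reproduces the
similarity structure, not the anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from cisbrs.edge_buffer import BufferEntry, QuerySphere
from cisbrs.sequence_model import ImageSequence, ImageSlice, save_dataset


@dataclass
class GeneratorParams:
    """Study conditions for one synthetic dataset.

    Defaults are desk-scale: 30 sequences of 20-60 slices of 64 x 64 pixels
    on a 6 x 8 block grid, 16 latent feature dimensions, drift noise 0.01
    per slice with 5% jump probability of magnitude 1.0 (two orders above
    the drift), 0-2 lesion rectangles per sequence, and 4 sequence clusters.
    """

    n_sequences: int = 30
    slices_range: tuple[int, int] = (20, 60)
    image_size: tuple[int, int] = (64, 64)
    grid: tuple[int, int] = (6, 8)
    feature_dim: int = 16
    drift_sigma: float = 0.01
    jump_prob: float = 0.05
    jump_magnitude: float = 1.0
    poa_count_range: tuple[int, int] = (0, 2)
    poa_size_range: tuple[int, int] = (4, 12)
    cluster_count: int = 4
    cluster_separation: float = 5.0
    stages_per_cluster: int = 6
    within_stage_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jump_magnitude <= self.drift_sigma:
            raise ValueError("jump_magnitude must exceed drift_sigma")
        for lo, hi in (self.slices_range, self.poa_count_range, self.poa_size_range):
            if lo > hi or lo < 0:
                raise ValueError("invalid range")
        if self.n_sequences < 1 or self.cluster_count < 1:
            raise ValueError("counts must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SyntheticDataset:
    """In-memory dataset plus generator ground truth."""

    sequences: list[ImageSequence]
    annotations: dict[int, dict[int, list[tuple[int, int, int, int]]]]
    jump_log: dict[int, list[int]]  # seq_id -> slice positions where jumps occurred
    cluster_truth: dict[int, int]
    params: GeneratorParams = field(repr=False, default=None)


def _render_pixels(
    latent: np.ndarray, proj: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    img = proj @ latent
    img = img.reshape(shape)
    lo, hi = img.min(), img.max()
    scale = (hi - lo) if hi > lo else 1.0
    return np.clip(40 + 160 * (img - lo) / scale, 0, 255)


def generate_dataset(
    params: GeneratorParams, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Generate a dataset; fully reproducible from ``params.seed``.

    Sequence latents start near one of their cluster's shared stages and
    drift slice to slice; with probability ``jump_prob`` per transition the
    sequence jumps to a different stage (a move of order ``jump_magnitude``)
    and the event is logged.  Lesion rectangles are embedded as
    elevated-intensity regions and recorded as annotations.  When
    ``out_dir`` is given, the dataset is also written to disk in the
    manifest layout.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    dim = params.feature_dim
    proj = rng.normal(size=(h * w, dim))
    prototypes = rng.normal(scale=params.cluster_separation,
                            size=(params.cluster_count, dim))
    # shared per-cluster stages, spaced ~jump_magnitude apart
    stages = np.empty((params.cluster_count, params.stages_per_cluster, dim))
    for c in range(params.cluster_count):
        for s in range(params.stages_per_cluster):
            direction = rng.normal(size=dim)
            direction /= np.linalg.norm(direction)
            norm = params.jump_magnitude * float(rng.uniform(1.0, 2.0))
            stages[c, s] = prototypes[c] + (0.0 if s == 0 else norm) * direction
    sequences: list[ImageSequence] = []
    annotations: dict[int, dict[int, list[tuple[int, int, int, int]]]] = {}
    jump_log: dict[int, list[int]] = {}
    cluster_truth: dict[int, int] = {}

    for sid in range(1, params.n_sequences + 1):
        c = int(rng.integers(params.cluster_count))
        cluster_truth[sid] = c
        n_slices = int(rng.integers(params.slices_range[0],
                                    params.slices_range[1] + 1))
        stage = int(rng.integers(params.stages_per_cluster))
        latent = stages[c, stage] + rng.normal(
            scale=params.within_stage_sigma, size=dim
        )
        jumps: list[int] = []
        slices: list[ImageSlice] = []
        seq_ann: dict[int, list[tuple[int, int, int, int]]] = {}

        n_poa = int(rng.integers(params.poa_count_range[0],
                                 params.poa_count_range[1] + 1))
        poa_rects = []
        for _ in range(n_poa):
            ph = int(rng.integers(params.poa_size_range[0],
                                  params.poa_size_range[1] + 1))
            pw = int(rng.integers(params.poa_size_range[0],
                                  params.poa_size_range[1] + 1))
            r0 = int(rng.integers(0, h - ph + 1))
            c0 = int(rng.integers(0, w - pw + 1))
            poa_rects.append((r0, c0, r0 + ph, c0 + pw))

        for iid in range(1, n_slices + 1):
            if iid > 1:
                latent = latent + rng.normal(scale=params.drift_sigma, size=dim)
                if rng.random() < params.jump_prob and params.stages_per_cluster > 1:
                    others = [s for s in range(params.stages_per_cluster)
                              if s != stage]
                    stage = others[int(rng.integers(len(others)))]
                    latent = stages[c, stage] + rng.normal(
                        scale=params.within_stage_sigma, size=dim
                    )
                    jumps.append(iid)
            pixels = _render_pixels(latent, proj, (h, w))
            for (r0, c0, r1, c1) in poa_rects:
                pixels[r0:r1, c0:c1] = np.clip(pixels[r0:r1, c0:c1] + 60, 0, 255)
            feature = latent + rng.normal(scale=params.drift_sigma / 10, size=dim)
            slices.append(ImageSlice(iid, pixels, feature))
            if poa_rects:
                seq_ann[iid] = list(poa_rects)

        sequences.append(ImageSequence(sid, slices))
        annotations[sid] = seq_ann
        jump_log[sid] = jumps

    ds = SyntheticDataset(sequences, annotations, jump_log, cluster_truth, params)
    if out_dir is not None:
        save_dataset(
            out_dir,
            sequences,
            dataset_id=f"synthetic-seed{params.seed}",
            grid_shape=params.grid,
            extractor="latent",
            extractor_params={"feature_dim": dim},
            annotations=annotations,
        )
    return ds


def tables_fixture() -> list[BufferEntry]:
    """The six-sequence edge-buffer example: access times as same-day clock
    strings and access frequencies (1, 3, 1, 4, 2, 3)."""
    ats = ["2:50", "3:40", "1:48", "4:21", "2:32", "3:11"]
    afs = [1, 3, 1, 4, 2, 3]
    return [BufferEntry(i + 1, at, af) for i, (at, af) in enumerate(zip(ats, afs))]


def generate_workload(
    dataset: SyntheticDataset,
    n_queries: int,
    repeat_prob: float = 0.0,
    radius_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    perturb_prob: float = 0.0,
) -> list[QuerySphere]:
    """Build a query workload mixing fresh queries, exact repeats, and
    (optionally) radius-perturbed near-repeats.

    After the first query, each subsequent one is an exact repeat of a
    previous query with probability ``repeat_prob`` (or, with
    ``perturb_prob``, a repeat with a jittered radius); otherwise a fresh
    center is drawn from the not-yet-queried sequences.  Deterministic for
    a given seed.
    """
    if not 0 <= repeat_prob <= 1:
        raise ValueError("repeat_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    seqs = dataset.sequences
    unused = list(range(len(seqs)))
    workload: list[QuerySphere] = []

    def fresh() -> QuerySphere:
        if unused:
            i = unused.pop(int(rng.integers(len(unused))))
        else:
            i = int(rng.integers(len(seqs)))
        radius = float(rng.uniform(*radius_range))
        return QuerySphere(seqs[i], radius)

    for qi in range(n_queries):
        if qi > 0 and rng.random() < repeat_prob:
            prev = workload[int(rng.integers(len(workload)))]
            if rng.random() < perturb_prob:
                radius = float(
                    np.clip(prev.radius * rng.uniform(0.8, 1.2), 0.0, 1.0)
                )
                workload.append(QuerySphere(prev.center, radius))
            else:
                workload.append(QuerySphere(prev.center, prev.radius))
        else:
            workload.append(fresh())
    return workload
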