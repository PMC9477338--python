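"""Block-grid partitioning, lesion-block classification, and ID scrambling.

Each slice is cut into a rows x cols grid of image blocks.  Blocks that
intersect an expert-marked lesion rectangle (pathological object area, POA)
are critical blocks (CIB): they keep full resolution, their identifiers are
scrambled with two secret keys, and they transmit first.  The remaining
blocks (NIB) may be stored down-sampled.

A block identifier packs (sequence, slice, row, column) into one scalar with
strictly decreasing stretch constants.  Encryption shifts the components by
key-dependent, parity-branched offsets, which breaks the spatial continuity
of neighbouring block IDs; decryption with the same keys is exact.  Without
the keys, reassembling a lesion region of b blocks requires guessing one of
b! orderings, so the chance of a correct reconstruction across regions is
1 / prod_i (RS_i * CS_i)!.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from cisbrs.sequence_model import ImageSlice

#: Transmission priorities: lesion blocks go first.
CIB_PRIORITY = 1
NIB_PRIORITY = 0


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [r0, r1) x [c0, c1)."""

    r0: int
    c0: int
    r1: int
    c1: int

    def __post_init__(self) -> None:
        if self.r1 <= self.r0 or self.c1 <= self.c0:
            raise ValueError("rectangle must have positive width and height")

    def intersects(self, other: "Rect") -> bool:
        return (
            self.r0 < other.r1
            and other.r0 < self.r1
            and self.c0 < other.c1
            and other.c0 < self.c1
        )

    @property
    def area(self) -> int:
        return (self.r1 - self.r0) * (self.c1 - self.c0)


@dataclass(frozen=True)
class PathRegion:
    """An expert-marked lesion rectangle (POA) in one slice."""

    region_id: int
    rect: Rect


@dataclass(frozen=True)
class BlockGrid:
    """Partition granularity: the slice is cut into rows x cols blocks."""

    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have positive rows and cols")


@dataclass(frozen=True)
class BlockIdComponents:
    """The four ID components of a block: sequence (SID), slice (IID), row
    (rID) and column (cID), all 1-based.  rID becomes fractional after
    encryption."""

    SID: float
    IID: float
    rID: float
    cID: int

    def is_plain(self) -> bool:
        return all(
            float(v).is_integer() and v >= 1
            for v in (self.SID, self.IID, self.rID, self.cID)
        )


@dataclass
class Block:
    components: BlockIdComponents
    rect: Rect
    pixels: np.ndarray
    kind: str | None = None  # 'CIB' | 'NIB'
    priority: int = NIB_PRIORITY


@dataclass(frozen=True)
class CodingConstants:
    """Stretch constants c1 >> c2 >> c3 for the scalar ID encoding; each must
    dominate the next by at least a factor of 10."""

    c1_blk: float = 1000.0
    c2_blk: float = 100.0
    c3_blk: float = 10.0

    def __post_init__(self) -> None:
        if not (self.c1_blk >= 10 * self.c2_blk >= 100 * self.c3_blk > 0):
            raise ValueError("constants must decrease by a factor >= 10 each")


@dataclass(frozen=True)
class CryptoKeys:
    """Scrambling keys: an integer shift delta_key applied to SID/IID and a
    fractional shift omega applied to the row.

    ``0 < omega < 1`` keeps the integer part of the encrypted row adjacent to
    the original row, which is what makes key-based inversion exact.
    """

    delta_key: int
    omega: float

    def __post_init__(self) -> None:
        if self.delta_key < 1:
            raise ValueError("delta_key must be a positive integer")
        if not (0.0 < self.omega < 1.0):
            raise ValueError("omega must lie strictly between 0 and 1")

    def check_plain(self, c: BlockIdComponents) -> None:
        if not c.is_plain():
            raise ValueError("components must be unencrypted positive integers")
        if not (self.delta_key < c.SID and self.delta_key < c.IID):
            raise ValueError("delta_key must be smaller than SID and IID")
        if not self.omega < c.rID:
            raise ValueError("omega must be smaller than rID")


@dataclass
class Poar:
    """The set of lesion blocks (CIBs) covering one POA."""

    region_id: int
    blocks: list[Block]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) extent of the covering block grid."""
        rids = sorted({int(b.components.rID) for b in self.blocks})
        cids = sorted({int(b.components.cID) for b in self.blocks})
        return len(rids), len(cids)


def partition_slice(
    sl: ImageSlice, grid: BlockGrid, *, sid: int = 1
) -> list[Block]:
    """Cut a slice into a rows x cols tiling of blocks.

    Block heights/widths are the integer quotients; remainder pixels are
    absorbed by the last row/column so the block count is exactly
    rows x cols.  Row/column components are 1-based.
    """
    h, w = sl.pixels.shape
    if grid.rows > h or grid.cols > w:
        raise ValueError("grid does not fit inside the slice")
    bh, bw = h // grid.rows, w // grid.cols
    blocks = []
    for r in range(grid.rows):
        r0 = r * bh
        r1 = (r + 1) * bh if r < grid.rows - 1 else h
        for c in range(grid.cols):
            c0 = c * bw
            c1 = (c + 1) * bw if c < grid.cols - 1 else w
            rect = Rect(r0, c0, r1, c1)
            comp = BlockIdComponents(sid, sl.slice_id, r + 1, c + 1)
            blocks.append(Block(comp, rect, sl.pixels[r0:r1, c0:c1]))
    return blocks


def classify_blocks(
    blocks: list[Block], regions: list[PathRegion]
) -> tuple[list[Block], list[Poar]]:
    """Label each block CIB iff it intersects at least one lesion region.

    Returns the labelled blocks and one POAR per region holding exactly the
    blocks that intersect it.  Labels are independent of region order.
    """
    poars = {reg.region_id: Poar(reg.region_id, []) for reg in regions}
    for b in blocks:
        hit = False
        for reg in regions:
            if b.rect.intersects(reg.rect):
                hit = True
                poars[reg.region_id].blocks.append(b)
        b.kind = "CIB" if hit else "NIB"
        b.priority = CIB_PRIORITY if hit else NIB_PRIORITY
    return blocks, [poars[reg.region_id] for reg in regions]


def encode_block_id(c: BlockIdComponents, k: CodingConstants) -> float:
    """Scalar ID = SID*c1 + IID*c2 + rID*c3 + cID."""
    return c.SID * k.c1_blk + c.IID * k.c2_blk + c.rID * k.c3_blk + c.cID


def encrypt_block_id(
    c: BlockIdComponents, keys: CryptoKeys, k: CodingConstants
) -> tuple[BlockIdComponents, float]:
    """Scramble the ID components by parity-branched key offsets.

    The branch is chosen by the parities of (rID, cID): odd rows add
    delta_key to SID and subtract it from IID, even rows do the opposite;
    odd columns add omega to the row, even columns subtract it.  Returns the
    encrypted components and their scalar encoding.
    """
    keys.check_plain(c)
    r_odd = int(c.rID) % 2 == 1
    c_odd = c.cID % 2 == 1
    if r_odd:
        sid, iid = c.SID + keys.delta_key, c.IID - keys.delta_key
    else:
        sid, iid = c.SID - keys.delta_key, c.IID + keys.delta_key
    rid = c.rID + keys.omega if c_odd else c.rID - keys.omega
    enc = BlockIdComponents(sid, iid, rid, c.cID)
    return enc, encode_block_id(enc, k)


def decrypt_block_id(
    enc: BlockIdComponents, keys: CryptoKeys, k: CodingConstants
) -> BlockIdComponents:
    """Invert :func:`encrypt_block_id` with the same keys.

    The column is never touched, so its parity tells whether omega was added
    (odd column) or subtracted (even column); that recovers the integer row
    and hence the parity branch.  With the right keys decrypt(encrypt(c)) == c
    exactly.
    """
    c_odd = enc.cID % 2 == 1
    rid_int = math.floor(enc.rID) if c_odd else math.floor(enc.rID) + 1
    r_odd = rid_int % 2 == 1
    if r_odd:
        sid, iid = enc.SID - keys.delta_key, enc.IID + keys.delta_key
    else:
        sid, iid = enc.SID + keys.delta_key, enc.IID - keys.delta_key
    rid = enc.rID - keys.omega if c_odd else enc.rID + keys.omega
    rid = round(rid, 12)
    plain = BlockIdComponents(sid, iid, rid, enc.cID)
    if sid < 1 or iid < 1 or rid < 1 or not plain.is_plain():
        raise ValueError("components inconsistent with the supplied keys")
    return replace(plain, rID=float(int(rid)))


def reconstruction_probability(
    poar_shapes: list[tuple[int, int]]
) -> float:
    """Probability that all lesion regions are reassembled correctly by
    guessing block order: 1 / prod_i (RS_i * CS_i)!.

    Each region of RS_i x CS_i blocks admits (RS_i*CS_i)! orderings of which
    exactly one reconstructs the image; regions are independent.  An empty
    list gives 1 (nothing to misplace).
    """
    denom = 1
    for rs, cs in poar_shapes:
        if rs < 1 or cs < 1:
            raise ValueError("POAR row/column counts must be >= 1")
        denom *= math.factorial(rs * cs)
    return 1.0 / denom


def downsample_nib(block: Block, factor: int) -> Block:
    """Reduce a non-lesion block's resolution by mean pooling.

    Each axis shrinks by ``factor`` (ceil division; edge cells average the
    remaining pixels).  Metadata is unchanged.  CIBs keep their original
    resolution, so applying this to one is an error.
    """
    if block.kind != "NIB":
        raise ValueError("only NIBs may be down-sampled; CIBs keep full resolution")
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return block
    px = block.pixels.astype(float)
    h, w = px.shape
    oh, ow = -(-h // factor), -(-w // factor)
    out = np.empty((oh, ow))
    for i in range(oh):
        for j in range(ow):
            out[i, j] = px[
                i * factor : min((i + 1) * factor, h),
                j * factor : min((j + 1) * factor, w),
            ].mean()
    return Block(block.components, block.rect, out, block.kind, block.priority)
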