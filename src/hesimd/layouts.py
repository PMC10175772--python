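"""Slot layouts: row-column flattening, the backward-convolution format, and
spaced vectors.

Three layouts recur throughout the package:

* **RC (row-column)** — a 2D matrix flattened row by row into the slot vector;
  the densest representation and the lingua franca between layer families.
* **SCBF (streamlined backward convolution format)** — the layout left behind
  by chained strided convolutions.  Entry ``(i, j)`` of the current logical
  ``h x w`` matrix lives at slot ``i*w0*Sx + j*Sy``, where ``(h0, w0)`` are the
  dimensions of the first encoded matrix and ``(Sx, Sy)`` the products of all
  previous layers' strides.  Slots not addressed by this map may hold garbage;
  only the result transformation cleans them.
* **Spaced** — a logical vector whose entry ``i`` sits at slot ``i * delta``;
  with ``n * delta = N`` a rotation by ``k * delta`` cycles the logical
  entries, which is what the diagonal dense algorithm exploits.

All indices are 0-based, ranges half-open, matrices row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .backend import HEParams, KeyMaterial, PackedVector, encode_encrypt, make_bitmask
from .errors import CapacityError, LayoutError

__all__ = [
    "RCMatrix",
    "SCBFLayout",
    "SpacedVector",
    "ReplicationPlan",
    "rc_encode",
    "rc_decode",
    "scbf_slot_index",
    "scbf_valid_mask",
    "make_spaced",
    "encode_matrix",
]


@dataclass(frozen=True)
class RCMatrix:
    """A plaintext ``h x w`` real matrix destined for row-column encoding."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise LayoutError("RCMatrix requires a 2D matrix with h, w >= 1")

    @property
    def h(self) -> int:
        return self.values.shape[0]

    @property
    def w(self) -> int:
        return self.values.shape[1]


def rc_encode(m: RCMatrix | np.ndarray) -> np.ndarray:
    """Row-column flattening: rows concatenated in order."""
    values = m.values if isinstance(m, RCMatrix) else np.asarray(m, dtype=np.float64)
    return values.reshape(-1).copy()


def rc_decode(vec: np.ndarray, h: int, w: int) -> np.ndarray:
    """Inverse of :func:`rc_encode` given the matrix dimensions."""
    vec = np.asarray(vec, dtype=np.float64)
    if vec.size < h * w:
        raise LayoutError(f"vector of length {vec.size} cannot hold a {h}x{w} matrix")
    return vec[: h * w].reshape(h, w).copy()


@dataclass(frozen=True)
class SCBFLayout:
    """Where a logical ``h x w`` matrix lives after chained convolution blocks.

    ``Sx``/``Sy`` are the running products of the strides of every previous
    convolution or pooling stage; the first layer has ``Sx = Sy = 1`` and
    ``(h, w) = (h0, w0)``, which makes SCBF coincide with RC.
    """

    h0: int
    w0: int
    Sx: int = 1
    Sy: int = 1
    h: int = 0
    w: int = 0

    def __post_init__(self):
        if min(self.h0, self.w0, self.Sx, self.Sy) < 1:
            raise LayoutError("SCBF dimensions and stride products must be >= 1")
        if self.h == 0:
            object.__setattr__(self, "h", self.h0)
        if self.w == 0:
            object.__setattr__(self, "w", self.w0)

    @classmethod
    def first_layer(cls, h: int, w: int) -> "SCBFLayout":
        return cls(h0=h, w0=w)

    def slot(self, i: int, j: int) -> int:
        return i * self.w0 * self.Sx + j * self.Sy

    @property
    def max_slot(self) -> int:
        return self.slot(self.h - 1, self.w - 1)

    def with_shape(self, h: int, w: int) -> "SCBFLayout":
        return replace(self, h=h, w=w)

    def after_stride(self, sx: int, sy: int, hout: int, wout: int) -> "SCBFLayout":
        return SCBFLayout(self.h0, self.w0, self.Sx * sx, self.Sy * sy, hout, wout)


def scbf_slot_index(layout: SCBFLayout, i: int, j: int) -> int:
    """Slot position of logical entry ``(i, j)``: ``i*w0*Sx + j*Sy``."""
    if not (0 <= i < layout.h and 0 <= j < layout.w):
        raise LayoutError(f"({i}, {j}) outside logical {layout.h}x{layout.w} matrix")
    return layout.slot(i, j)


def scbf_valid_mask(layout: SCBFLayout, params: HEParams,
                    total_slots: int | None = None) -> np.ndarray:
    """Plaintext mask with 1 exactly at every valid SCBF slot of ``layout``.

    ``total_slots`` widens the mask to ``r * N`` for multi-ciphertext inputs.
    """
    total = total_slots or params.N
    if layout.max_slot >= total:
        raise CapacityError(
            f"SCBF layout needs slot {layout.max_slot} but only {total} slots exist")
    mask = np.zeros(total, dtype=np.float64)
    for i in range(layout.h):
        for j in range(layout.w):
            mask[layout.slot(i, j)] = 1.0
    return mask


def encode_matrix(M, params: HEParams, keys: KeyMaterial,
                  grid: tuple[int, int] | None = None
                  ) -> tuple[SCBFLayout, PackedVector]:
    """Encode a matrix in first-layer SCBF (= RC) layout, optionally on an
    enlarged ``(h0, w0)`` grid with the matrix in the top-left corner — the
    encoding a client uses when the server will pad the first layer itself."""
    M = np.asarray(M, dtype=np.float64)
    h, w = M.shape
    h0, w0 = grid or (h, w)
    if h0 < h or w0 < w:
        raise LayoutError(f"grid {h0}x{w0} smaller than matrix {h}x{w}")
    buf = np.zeros((h0, w0))
    buf[:h, :w] = M
    layout = SCBFLayout(h0=h0, w0=w0, h=h, w=w)
    if layout.max_slot >= params.N:
        raise CapacityError(f"matrix needs slot {layout.max_slot} >= N = {params.N}")
    return layout, encode_encrypt(buf.reshape(-1)[: layout.max_slot + 1],
                                  params, keys)


@dataclass(frozen=True)
class SpacedVector:
    """Metadata of a logical vector placed every ``delta`` slots."""

    n: int
    delta: int

    def __post_init__(self):
        if self.delta < 1 or (self.delta & (self.delta - 1)) != 0:
            raise LayoutError(f"spacing must be a power of two, got {self.delta}")
        if self.n < 1:
            raise LayoutError("spaced vector needs n >= 1")


def make_spaced(values, delta: int, params: HEParams,
                keys: KeyMaterial) -> tuple[SpacedVector, PackedVector]:
    """Encode ``values`` with entry ``i`` at slot ``i * delta`` (rest zero)."""
    arr = np.asarray(values, dtype=np.float64).ravel()
    meta = SpacedVector(arr.size, delta)
    if arr.size * delta > params.N:
        raise CapacityError(
            f"spaced vector needs n*delta = {arr.size * delta} <= N = {params.N}")
    buf = np.zeros(params.N, dtype=np.float64)
    buf[:: delta][: arr.size] = arr
    return meta, encode_encrypt(buf, params, keys)


@dataclass(frozen=True)
class ReplicationPlan:
    """Shapes of a matrix-matrix product in the replicated-slot layout."""

    hA: int
    wA: int
    hB: int
    wB: int

    def __post_init__(self):
        if self.wA != self.hB:
            raise LayoutError(f"incompatible shapes: wA={self.wA} != hB={self.hB}")
        if min(self.hA, self.wA, self.hB, self.wB) < 1:
            raise LayoutError("matrix dimensions must be >= 1")

    @property
    def required_slots(self) -> int:
        return max(self.hA * self.wA * self.wB, self.hB * self.wB * self.hA)

    def check_capacity(self, N: int) -> None:
        if self.required_slots > N:
            raise CapacityError(
                f"replicated matrix product needs max(hA*wA*wB, hB*wB*hA) = "
                f"{self.required_slots} <= N = {N}")
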