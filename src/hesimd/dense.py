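"""Dense (fully-connected) layers on packed vectors.

Two schemes are provided, with different capacity/depth trade-offs:

* **Diagonal matrix-vector multiplication** — the input vector is spread out
  with a uniform slot spacing ``delta = N / alpha`` (``alpha`` the larger of
  the weight matrix's dimensions rounded up to a power of two), so that slot
  rotations by multiples of ``delta`` cycle the *logical* entries, wrap-around
  included.  The weight matrix, zero-extended to ``hext x wext``, is then
  consumed as its ``alpha`` generalized diagonals: rotate, multiply by the
  (plaintext, equally spaced) diagonal, accumulate.  Capacity only requires
  ``max(alpha, n) <= N``, which scales to large layers.

* **Replicated matrix-matrix multiplication** — both operands are laid out in
  replicated row-column form (each entry of ``A`` repeated ``wB`` times; the
  whole of ``RC(B)`` tiled ``hA`` times), after which the product needs a
  single elementwise multiplication plus ``wA`` rotate-and-accumulate steps.
  Cheap in depth and multiplications, but the replication factor caps the
  shapes at ``max(hA*wA*wB, hB*wB*hA) <= N``.

For deep-learning inference the weights are cleartext, so the expensive
replication of the left operand can be done on the plaintext side at zero
ciphertext cost (:func:`replicate_plain_a`); the ciphertext-side
:func:`prepare_matrix_a` remains available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .backend import (
    HEParams,
    PackedVector,
    elementwise,
    make_bitmask,
    rotate,
    zeros_like,
)
from .errors import CapacityError, LayoutError
from .layouts import ReplicationPlan, SpacedVector, rc_encode

__all__ = [
    "DenseWeights",
    "DiagonalPlan",
    "switch_spacing",
    "diagonal_matmul",
    "add_bias",
    "prepare_matrix_a",
    "prepare_matrix_b",
    "replicate_plain_a",
    "matmat",
    "result_extraction",
    "dense_layer_diagonal",
    "dense_layer_matmat",
]


@dataclass(frozen=True)
class DenseWeights:
    """Cleartext weights ``W`` (``h x w``) and bias ``b`` of a dense layer."""

    W: np.ndarray
    b: np.ndarray | None = None

    def __post_init__(self):
        W = np.asarray(self.W, dtype=np.float64)
        if W.ndim != 2:
            raise LayoutError("dense weights must be a 2D matrix")
        object.__setattr__(self, "W", W)
        b = (np.zeros(W.shape[0]) if self.b is None
             else np.asarray(self.b, dtype=np.float64))
        if b.shape != (W.shape[0],):
            raise LayoutError(f"bias length {b.shape} != output size {W.shape[0]}")
        object.__setattr__(self, "b", b)

    @property
    def h(self) -> int:
        return self.W.shape[0]

    @property
    def w(self) -> int:
        return self.W.shape[1]


@dataclass(frozen=True)
class DiagonalPlan:
    """Geometry of the diagonal scheme for an ``h x w`` weight matrix at slot
    count ``N``: power-of-two extended dimensions, ``alpha = max(hext, wext)``
    and the slot spacing ``delta = N / alpha`` (an exact power of two)."""

    h: int
    w: int
    N: int

    @property
    def hext(self) -> int:
        return 1 << max(0, math.ceil(math.log2(self.h)))

    @property
    def wext(self) -> int:
        return 1 << max(0, math.ceil(math.log2(self.w)))

    @property
    def alpha(self) -> int:
        return max(self.hext, self.wext)

    @property
    def delta(self) -> int:
        return self.N // self.alpha

    def check_capacity(self) -> None:
        if max(self.alpha, self.w) > self.N:
            raise CapacityError(
                f"diagonal scheme needs max(alpha, n) = {max(self.alpha, self.w)} "
                f"<= N = {self.N}")


def switch_spacing(ct: PackedVector, n: int, delta_i: int, delta_f: int) -> PackedVector:
    """Move logical entry ``i`` from slot ``i*delta_i`` to slot ``i*delta_f``.

    Serves both as the result transformation of one dense layer and the
    initial representation of the next.  One mask, rotation and accumulation
    per logical entry; one multiplicative level.  The geometric capacity
    requirement ``n * max(delta_i, delta_f) <= N`` is enforced.
    """
    N = ct.N
    if n * max(delta_i, delta_f) > N:
        raise CapacityError(
            f"switch_spacing needs n*max(delta_i, delta_f) = "
            f"{n * max(delta_i, delta_f)} <= N = {N}")
    shift = delta_f - delta_i
    acc = zeros_like(ct)
    for i in range(n):
        mask = make_bitmask((i * delta_i,), ct.params)
        term = elementwise("mul", ct, mask, opname="switch_spacing mask")
        rotate(term, -(i * shift), out=term)  # right rotation by i*shift
        elementwise("sum", acc, term, out=acc)
        del term
    return acc


def _spaced_plain(entries, delta: int, N: int) -> np.ndarray:
    buf = np.zeros(N, dtype=np.float64)
    arr = np.asarray(entries, dtype=np.float64)
    buf[:: delta][: arr.size] = arr
    return buf


def diagonal_matmul(ct: PackedVector, weights: DenseWeights,
                    plan: DiagonalPlan) -> PackedVector:
    """``W @ x`` for a spaced input ``x`` (spacing ``plan.delta``).

    The zero-extended matrix is consumed as ``alpha`` generalized diagonals
    ``d_i[j] = Wext[j, (i + j) mod wext]``, each encoded as a plaintext vector
    with the *same* spacing as the input so that rotating the input by
    ``i * delta`` lines logical entries up with their matrix column.
    """
    if (plan.h, plan.w) != (weights.h, weights.w):
        raise LayoutError("plan shape does not match the weight matrix")
    plan.check_capacity()
    if plan.N != ct.N:
        raise LayoutError(f"plan N = {plan.N} != ciphertext N = {ct.N}")
    delta, alpha = plan.delta, plan.alpha
    wext = plan.wext
    Wext = np.zeros((plan.hext, wext), dtype=np.float64)
    Wext[: weights.h, : weights.w] = weights.W

    acc = zeros_like(ct)
    for i in range(alpha):
        diag = [Wext[j, (i + j) % wext] for j in range(plan.hext)]
        rot = rotate(ct, i * delta)
        elementwise("mul", rot, _spaced_plain(diag, delta, ct.N), out=rot,
                    opname="diagonal")
        elementwise("sum", acc, rot, out=acc)
        del rot
    return acc


def add_bias(ct: PackedVector, b, spacing: int = 1) -> PackedVector:
    """Add a plaintext bias to the logical entries (slot ``i*spacing`` gets
    ``b[i]``); a single addition, no depth."""
    arr = np.asarray(b, dtype=np.float64).ravel()
    if arr.size * spacing > ct.N:
        raise CapacityError(f"bias of {arr.size} entries at spacing {spacing} "
                            f"exceeds N = {ct.N}")
    return elementwise("sum", ct, _spaced_plain(arr, spacing, ct.N))


# ---------------------------------------------------------------------------
# replicated matrix-matrix path
# ---------------------------------------------------------------------------


def prepare_matrix_a(ctA: PackedVector, plan: ReplicationPlan) -> PackedVector:
    """Replicated layout of the left operand: slot ``(i*wA + j)*wB + m`` holds
    ``A[i, j]`` for every ``m < wB``.  Ciphertext-side version; for cleartext
    weights use :func:`replicate_plain_a` at zero ciphertext cost."""
    plan.check_capacity(ctA.N)
    hA, wA, wB = plan.hA, plan.wA, plan.wB
    partial = zeros_like(ctA)
    for i in range(hA * wA):
        mask = make_bitmask((i,), ctA.params)
        term = elementwise("mul", ctA, mask, opname="prepare A mask")
        rotate(term, -(i * (wB - 1)), out=term)  # entry i -> slot i*wB
        elementwise("sum", partial, term, out=partial)
        del term
    out = zeros_like(ctA)
    for m in range(wB):
        term = rotate(partial, -m)
        elementwise("sum", out, term, out=out)
        del term
    return out


def replicate_plain_a(A: np.ndarray, wB: int) -> np.ndarray:
    """Plaintext replication of ``A``: each RC entry repeated ``wB`` times."""
    return np.repeat(rc_encode(np.asarray(A, dtype=np.float64)), wB)


def prepare_matrix_b(ctB: PackedVector, plan: ReplicationPlan) -> PackedVector:
    """Replicated layout of the right operand: ``RC(B)`` tiled ``hA`` times.

    Requires all slots beyond the ``hB*wB`` prefix of ``ctB`` to be zero (true
    for freshly encoded vectors and result-transformation outputs).  Costs
    ``hA`` rotations and additions, no multiplication, no depth.
    """
    plan.check_capacity(ctB.N)
    acc = zeros_like(ctB)
    block = plan.hB * plan.wB
    for i in range(plan.hA):
        term = rotate(ctB, -(i * block))
        elementwise("sum", acc, term, out=acc)
        del term
    return acc


def matmat(ctPA, ctPB: PackedVector, plan: ReplicationPlan) -> PackedVector:
    """Product of replicated operands: one elementwise multiplication followed
    by ``wA`` rotate-and-accumulate steps.  Block ``i`` of the result starts at
    slot ``i*wA*wB`` and holds ``C[i, 0..wB)``.

    ``ctPA`` may be a plaintext replicated vector (cleartext weights)."""
    plan.check_capacity(ctPB.N)
    ctC = elementwise("mul", ctPB, ctPA, opname="matmat product") \
        if not isinstance(ctPA, PackedVector) \
        else elementwise("mul", ctPA, ctPB, opname="matmat product")
    acc = zeros_like(ctPB)
    for i in range(plan.wA):
        term = rotate(ctC, i * plan.wB)
        elementwise("sum", acc, term, out=acc)
        del term
    return acc


def result_extraction(ctC: PackedVector, plan: ReplicationPlan) -> PackedVector:
    """Discard the inter-block spacing of the blocked product: mask block ``i``
    (``wB`` slots at ``i*wA*wB``), rotate it down to ``i*wB``, accumulate.
    The decrypted prefix of length ``hA*wB`` is ``RC(C)``; the rest is zero."""
    hA, wA, wB = plan.hA, plan.wA, plan.wB
    if hA * wB > ctC.N:
        raise CapacityError(f"RC result of {hA * wB} entries exceeds N = {ctC.N}")
    acc = zeros_like(ctC)
    for i in range(hA):
        start = i * wA * wB
        mask = make_bitmask(range(start, start + wB), ctC.params)
        term = elementwise("mul", ctC, mask, opname="result extraction mask")
        rotate(term, i * wB * (wA - 1), out=term)  # block i -> slot i*wB
        elementwise("sum", acc, term, out=acc)
        del term
    return acc


# ---------------------------------------------------------------------------
# full dense layers (cleartext weights)
# ---------------------------------------------------------------------------


def dense_layer_diagonal(ct: PackedVector, weights: DenseWeights,
                         spacing_in: int = 1) -> tuple[PackedVector, int]:
    """``W @ x + b`` via the diagonal scheme.

    ``ct`` holds ``x`` at spacing ``spacing_in`` (1 = plain RC prefix).  The
    returned vector is spaced at the plan's ``delta``; the second element of
    the tuple is that spacing, to feed the next layer's initial representation.
    """
    plan = DiagonalPlan(weights.h, weights.w, ct.N)
    plan.check_capacity()
    spaced = switch_spacing(ct, weights.w, spacing_in, plan.delta)
    out = diagonal_matmul(spaced, weights, plan)
    del spaced
    out = add_bias(out, weights.b, spacing=plan.delta)
    return out, plan.delta


def dense_layer_matmat(ct: PackedVector, weights: DenseWeights) -> PackedVector:
    """``W @ x + b`` via the replicated scheme with cleartext weights.

    The weight matrix plays the left operand, replicated on the plaintext
    side; the encrypted input vector is the right operand (``wB = 1``), tiled
    by :func:`prepare_matrix_b`.  Returns a plain RC vector of length ``h``.
    """
    plan = ReplicationPlan(hA=weights.h, wA=weights.w, hB=weights.w, wB=1)
    plan.check_capacity(ct.N)
    ctPB = prepare_matrix_b(ct, plan)
    plainPA = np.concatenate(
        [replicate_plain_a(weights.W, plan.wB),
         np.zeros(ct.N - weights.h * weights.w * plan.wB)])
    prod = matmat(plainPA, ctPB, plan)
    del ctPB
    out = result_extraction(prod, plan)
    del prod
    return add_bias(out, weights.b, spacing=1)
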