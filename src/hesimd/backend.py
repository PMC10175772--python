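"""Packed-vector runtime: encoding, SIMD primitives, and cost instrumentation.

A leveled homomorphic encryption (LHE) scheme with ciphertext packing exposes a
single data type — a vector of ``N`` numeric *slots* — and five SIMD primitives
on it: elementwise sum, subtraction, multiplication, and cyclic left/right
rotation.  Every higher-level routine in this package (convolution, dense
layers, layout transforms) is compiled down to these primitives, so this module
is the contract the rest of the code is written against.

Two interchangeable backends implement the contract:

``sim``
    An exact plaintext simulator over ``float64`` slots.  Arithmetic is
    bit-exact, which makes it the ground truth for oracle tests, while still
    enforcing the leveled-scheme bookkeeping (depth budget, key roles).

``fixed``
    A fixed-point leveled-arithmetic model of CKKS-style encoding: slot values
    are stored as integers at scale ``2**scale_bits``, every multiplication is
    followed by a rescaling (rounding division by the scale), and each
    rescaling consumes one level of a modulus chain sized ``depth_budget + 1``.
    This backend reproduces the *numerical* behaviour of approximate-arithmetic
    HE (quantisation on encode, rounding per multiplication, level exhaustion)
    but performs no encryption and provides no confidentiality.

Rotation convention: a left rotation by ``k`` maps input slot ``(j + k) mod N``
to output slot ``j`` — entries move toward slot 0 and the first entries
overflow cyclically to the end.  Right rotation by ``k`` is left rotation by
``-k``.  All modules share this single convention.
"""

from __future__ import annotations

import random
import weakref
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

from .errors import CapacityError, DecryptionError, LayoutError, LevelExhaustedError

__all__ = [
    "HEParams",
    "KeyMaterial",
    "PackedVector",
    "BigPackedVector",
    "CostReport",
    "keygen",
    "encode_encrypt",
    "decrypt_decode",
    "elementwise",
    "rotate",
    "big_rotate",
    "make_bitmask",
    "invert_mask",
    "poly_eval",
    "zeros_like",
    "counter_scope",
]

BACKENDS = ("sim", "fixed")


@dataclass(frozen=True)
class HEParams:
    """Leveled-scheme parameters shared by both backends.

    Parameters
    ----------
    N:
        Slot count (polynomial degree); must be a power of two >= 2.
    depth_budget:
        Maximum number of consecutive multiplications any single ciphertext
        lineage may undergo.  The ``fixed`` backend models a modulus chain of
        ``depth_budget + 1`` primes, one consumed per rescaling.
    scale_bits:
        Binary exponent of the fixed-point encoding scale (``fixed`` backend
        only).  The scale is kept constant across levels, mirroring the usual
        choice of encoding scale equal to the intermediate chain primes so
        that rescaling leaves the scale invariant.
    backend:
        ``"sim"`` (exact simulator) or ``"fixed"`` (fixed-point model).
    """

    N: int
    depth_budget: int = 16
    scale_bits: int = 40
    backend: str = "sim"

    def __post_init__(self) -> None:
        if self.N < 2 or (self.N & (self.N - 1)) != 0:
            raise ValueError(f"N must be a power of two >= 2, got {self.N}")
        if self.depth_budget < 1:
            raise ValueError("depth_budget must be >= 1")
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}; expected one of {BACKENDS}")
        if self.backend == "fixed" and not (1 <= self.scale_bits <= 60):
            raise ValueError("scale_bits must be in [1, 60] for the fixed backend")

    def as_config(self) -> dict:
        return {
            "N": self.N,
            "depth_budget": self.depth_budget,
            "scale_bits": self.scale_bits,
            "backend": self.backend,
        }


@dataclass(frozen=True)
class KeyMaterial:
    """Opaque key handles with client/server role separation.

    The simulator and fixed-point backends carry no real cryptographic
    material; the handles exist so that key *roles* are enforced: encryption
    needs the public handle, decryption needs the secret handle, and a vector
    can only be decrypted by the key pair that produced it.  ``public_only``
    yields the handle set a server would receive.
    """

    backend: str
    key_id: int
    has_secret: bool = True
    rotation_keys: tuple = ()

    def public_only(self) -> "KeyMaterial":
        return KeyMaterial(self.backend, self.key_id, has_secret=False,
                           rotation_keys=self.rotation_keys)


def keygen(params: HEParams, seed: int | None = None) -> KeyMaterial:
    """Produce a key pair handle for ``params``' backend."""
    rng = random.Random(seed)
    return KeyMaterial(params.backend, key_id=rng.getrandbits(63))


# ---------------------------------------------------------------------------
# cost instrumentation
# ---------------------------------------------------------------------------


@dataclass
class CostReport:
    """Operation ledger of a circuit: depth and per-primitive counts.

    ``dc`` is the multiplicative depth (longest chain of consecutive
    multiplications on one ciphertext lineage), ``osum``/``omul``/``orot`` the
    number of additions-or-subtractions, multiplications, and rotations, and
    ``omem`` the peak number of simultaneously live packed vectors allocated
    inside the measured scope.
    """

    dc: int = 0
    osum: int = 0
    omul: int = 0
    orot: int = 0
    omem: int = 0

    def as_dict(self) -> dict:
        return {"dc": self.dc, "osum": self.osum, "omul": self.omul,
                "orot": self.orot, "omem": self.omem}

    def __add__(self, other: "CostReport") -> "CostReport":
        return CostReport(
            dc=self.dc + other.dc,
            osum=self.osum + other.osum,
            omul=self.omul + other.omul,
            orot=self.orot + other.orot,
            omem=max(self.omem, other.omem),
        )


class _Scope:
    """One open measurement scope; primitives report into every open scope."""

    __slots__ = ("osum", "omul", "orot", "dc", "_live", "_peak", "closed",
                 "__weakref__")

    def __init__(self) -> None:
        self.osum = 0
        self.omul = 0
        self.orot = 0
        self.dc = 0
        self._live = 0
        self._peak = 0
        self.closed = False

    def _vector_created(self) -> None:
        self._live += 1
        self._peak = max(self._peak, self._live)

    def _vector_freed(self) -> None:
        if not self.closed:
            self._live -= 1

    @property
    def report(self) -> CostReport:
        return CostReport(dc=self.dc, osum=self.osum, omul=self.omul,
                          orot=self.orot, omem=self._peak)


_OPEN_SCOPES: list[_Scope] = []


@contextmanager
def counter_scope():
    """Open a measurement scope; yields a handle whose ``.report`` is the
    accumulated :class:`CostReport`.  Nested scopes compose additively into
    their parents (an operation is counted by every open scope)."""
    scope = _Scope()
    _OPEN_SCOPES.append(scope)
    try:
        yield scope
    finally:
        _OPEN_SCOPES.remove(scope)
        scope.closed = True


def _count(kind: str, times: int = 1) -> None:
    for s in _OPEN_SCOPES:
        if kind == "sum":
            s.osum += times
        elif kind == "mul":
            s.omul += times
        elif kind == "rot":
            s.orot += times


def _released(scopes: tuple) -> None:
    for ref in scopes:
        s = ref()
        if s is not None:
            s._vector_freed()


# ---------------------------------------------------------------------------
# slot-level backend arithmetic
# ---------------------------------------------------------------------------


def _fixed_encode_slots(values: np.ndarray, scale_bits: int) -> np.ndarray:
    scale = 1 << scale_bits
    return np.array([int(round(float(v) * scale)) for v in values], dtype=object)

def _fixed_decode_slots(slots: np.ndarray, scale_bits: int) -> np.ndarray:
    scale = float(1 << scale_bits)
    return np.array([int(v) / scale for v in slots], dtype=np.float64)

def _fixed_rescale(slots: np.ndarray, scale_bits: int) -> np.ndarray:
    # rounding division by 2**scale_bits (round half toward +inf)
    half = 1 << (scale_bits - 1)
    return np.array([(int(v) + half) >> scale_bits for v in slots], dtype=object)


def _as_plain_array(values, N: int) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim == 0:
        arr = np.full(N, float(arr))
    if arr.shape != (N,):
        raise LayoutError(f"plaintext operand has {arr.shape[0] if arr.ndim else 1} "
                          f"slots, expected {N}")
    return arr


# ---------------------------------------------------------------------------
# packed vectors
# ---------------------------------------------------------------------------


class PackedVector:
    """One ciphertext-sized slot vector of length ``N``.

    ``level_used`` counts the multiplicative levels this lineage has consumed;
    the runtime refuses multiplications past ``params.depth_budget``.
    Instances should be produced through :func:`encode_encrypt`,
    :func:`zeros_like` or the primitives, never built by hand.
    """

    __slots__ = ("slots", "params", "level_used", "key_id", "_depth",
                 "_finalizer", "__weakref__")

    def __init__(self, slots: np.ndarray, params: HEParams, level_used: int = 0,
                 key_id: int | None = None,
                 _depth: dict | None = None) -> None:
        self.slots = slots
        self.params = params
        self.level_used = level_used
        self.key_id = key_id
        # per-open-scope multiplicative depth of this lineage
        self._depth = dict(_depth) if _depth else {}
        counted = tuple(weakref.ref(s) for s in _OPEN_SCOPES)
        for s in _OPEN_SCOPES:
            s._vector_created()
        self._finalizer = weakref.finalize(self, _released, counted)

    @property
    def N(self) -> int:
        return self.params.N

    def copy(self) -> "PackedVector":
        return PackedVector(self.slots.copy(), self.params, self.level_used,
                            self.key_id, self._depth)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"PackedVector(N={self.N}, backend={self.params.backend!r}, "
                f"level={self.level_used})")


class BigPackedVector:
    """A logical vector of ``n > N`` entries packed across ``r = ceil(n/N)``
    ciphertext-sized parts; slots past index ``n - 1`` are zero after encoding."""

    __slots__ = ("parts", "n")

    def __init__(self, parts: Sequence[PackedVector], n: int) -> None:
        parts = list(parts)
        N = parts[0].N
        if len(parts) != -(-n // N):
            raise LayoutError(f"need ceil({n}/{N}) = {-(-n // N)} parts, got {len(parts)}")
        self.parts = parts
        self.n = n

    @property
    def r(self) -> int:
        return len(self.parts)

    @property
    def params(self) -> HEParams:
        return self.parts[0].params

    @property
    def N(self) -> int:
        return self.parts[0].N

    @property
    def level_used(self) -> int:
        return max(p.level_used for p in self.parts)


AnyPacked = Union[PackedVector, BigPackedVector]


# ---------------------------------------------------------------------------
# encode / decode
# ---------------------------------------------------------------------------


def _encode_one(values: np.ndarray, params: HEParams, key_id: int | None) -> PackedVector:
    buf = np.zeros(params.N, dtype=np.float64)
    buf[: len(values)] = values
    if params.backend == "fixed":
        slots = _fixed_encode_slots(buf, params.scale_bits)
    else:
        slots = buf
    return PackedVector(slots, params, level_used=0, key_id=key_id)


def encode_encrypt(values, params: HEParams, keys: KeyMaterial) -> AnyPacked:
    """Encode (and, in role terms, encrypt) a length-``n`` vector.

    Returns a :class:`PackedVector` when ``n <= N`` (tail slots zero-filled)
    and a :class:`BigPackedVector` with ``r = ceil(n/N)`` parts otherwise.
    """
    if keys.backend != params.backend:
        raise LayoutError(f"key backend {keys.backend!r} != params backend {params.backend!r}")
    arr = np.asarray(values, dtype=np.float64).ravel()
    n = arr.size
    if n == 0:
        raise ValueError("cannot encode an empty vector")
    N = params.N
    if n <= N:
        return _encode_one(arr, params, keys.key_id)
    parts = [_encode_one(arr[i * N:(i + 1) * N], params, keys.key_id)
             for i in range(-(-n // N))]
    return BigPackedVector(parts, n)


def decrypt_decode(v: AnyPacked, keys: KeyMaterial, n: int | None = None) -> np.ndarray:
    """Decode the first ``n`` logical entries of ``v`` (all slots if ``n`` is None).

    Requires the secret-key handle of the pair that encrypted ``v``; the
    server-side role (``public_only`` keys) cannot decrypt.
    """
    if not keys.has_secret:
        raise DecryptionError("decryption requires the secret key (client role)")
    if isinstance(v, BigPackedVector):
        full = np.concatenate([decrypt_decode(p, keys, p.N) for p in v.parts])
        return full[: (v.n if n is None else n)]
    if v.key_id is not None and keys.key_id != v.key_id:
        raise DecryptionError("wrong key for this ciphertext")
    if v.params.backend == "fixed":
        out = _fixed_decode_slots(v.slots, v.params.scale_bits)
    else:
        out = np.asarray(v.slots, dtype=np.float64).copy()
    return out if n is None else out[:n]


def zeros_like(template: PackedVector) -> PackedVector:
    """Fresh all-zero vector sharing ``template``'s parameters and key.

    Used as an accumulator seed; allocation is tracked for Omem but creating
    it costs no homomorphic operation.
    """
    if template.params.backend == "fixed":
        slots = np.array([0] * template.N, dtype=object)
    else:
        slots = np.zeros(template.N, dtype=np.float64)
    return PackedVector(slots, template.params, level_used=0, key_id=template.key_id)


# ---------------------------------------------------------------------------
# SIMD primitives
# ---------------------------------------------------------------------------


def _mul_depth_bookkeeping(result_depth_src: Iterable[PackedVector]) -> dict:
    """Compute the per-scope depth of a multiplication result and update DC."""
    depth = {}
    for s in _OPEN_SCOPES:
        d = 1 + max((v._depth.get(id(s), 0) for v in result_depth_src), default=0)
        depth[id(s)] = d
        s.dc = max(s.dc, d)
    return depth


def _carry_depth(sources: Iterable[PackedVector]) -> dict:
    depth = {}
    for s in _OPEN_SCOPES:
        d = max((v._depth.get(id(s), 0) for v in sources), default=0)
        if d:
            depth[id(s)] = d
    return depth


def elementwise(op: str, a: AnyPacked, b, out: PackedVector | None = None,
                opname: str | None = None) -> AnyPacked:
    """Apply a slotwise primitive: ``op`` in {"sum", "sub", "mul"}.

    ``b`` may be a packed vector on the same backend/key or a plaintext vector
    (length ``N``) / scalar.  Multiplication consumes one level of the depth
    budget — including multiplications by plaintext bitmasks, which is how
    leveled schemes behave and how the cost model counts them.  ``out`` reuses
    an existing vector's storage (no new allocation is tracked).
    """
    if op not in ("sum", "sub", "mul"):
        raise ValueError(f"unknown elementwise op {op!r}")
    if isinstance(a, BigPackedVector):
        return _elementwise_big(op, a, b, opname)
    params = a.params
    b_ct = isinstance(b, PackedVector)
    if b_ct:
        if b.N != a.N or b.params.backend != params.backend:
            raise LayoutError("operand slot counts / backends differ")
        if a.key_id is not None and b.key_id is not None and a.key_id != b.key_id:
            raise LayoutError("operands were encrypted under different keys")

    level = a.level_used if not b_ct else max(a.level_used, b.level_used)
    if op == "mul":
        level += 1
        if level > params.depth_budget:
            raise LevelExhaustedError(
                f"multiplication {opname or ''}".strip()
                + f" would use level {level} > depth budget {params.depth_budget}")

    if params.backend == "fixed":
        b_slots = b.slots if b_ct else _fixed_encode_slots(
            _as_plain_array(b, a.N), params.scale_bits)
        if op == "sum":
            slots = a.slots + b_slots
        elif op == "sub":
            slots = a.slots - b_slots
        else:
            slots = _fixed_rescale(a.slots * b_slots, params.scale_bits)
    else:
        b_slots = b.slots if b_ct else _as_plain_array(b, a.N)
        if op == "sum":
            slots = a.slots + b_slots
        elif op == "sub":
            slots = a.slots - b_slots
        else:
            slots = a.slots * b_slots

    _count("mul" if op == "mul" else "sum")
    srcs = (a, b) if b_ct else (a,)
    depth = _mul_depth_bookkeeping(srcs) if op == "mul" else _carry_depth(srcs)
    key_id = a.key_id if a.key_id is not None else (b.key_id if b_ct else None)
    if out is not None:
        out.slots = slots
        out.level_used = level
        out.key_id = key_id
        out._depth = depth
        return out
    return PackedVector(slots, params, level, key_id, depth)


def _elementwise_big(op: str, a: BigPackedVector, b, opname) -> BigPackedVector:
    if isinstance(b, BigPackedVector):
        if b.r != a.r:
            raise LayoutError("big vectors have different part counts")
        parts = [elementwise(op, pa, pb, opname=opname)
                 for pa, pb in zip(a.parts, b.parts)]
    elif isinstance(b, PackedVector):
        raise LayoutError("cannot combine a BigPackedVector with a single PackedVector")
    else:
        arr = np.asarray(b, dtype=np.float64)
        if arr.ndim == 0:
            parts = [elementwise(op, pa, float(arr), opname=opname) for pa in a.parts]
        else:
            N = a.N
            if arr.size != a.r * N:
                raise LayoutError(f"plaintext operand must cover all {a.r * N} slots")
            parts = [elementwise(op, pa, arr[i * N:(i + 1) * N], opname=opname)
                     for i, pa in enumerate(a.parts)]
    return BigPackedVector(parts, a.n)


def rotate(v: AnyPacked, k: int, out: PackedVector | None = None) -> AnyPacked:
    """Cyclic rotation: ``k > 0`` rotates left (``out[j] = in[(j+k) mod N]``),
    ``k < 0`` right.  Zero-amount rotations are executed and counted, so
    measured ledgers match the closed-form cost model (an optimisation flag in
    the algorithms may elide them, off by default)."""
    if isinstance(v, BigPackedVector):
        return big_rotate(v, k)
    k = k % v.N
    slots = np.roll(v.slots, -k) if k else v.slots.copy()
    _count("rot")
    depth = _carry_depth((v,))
    if out is not None:
        out.slots = slots
        out.level_used = v.level_used
        out.key_id = v.key_id
        out._depth = depth
        return out
    return PackedVector(slots, v.params, v.level_used, v.key_id, depth)


def big_rotate(v: BigPackedVector, k: int) -> BigPackedVector:
    """Cyclic rotation of the logical vector spread over ``r`` ciphertexts.

    The rotation amount is decomposed into a whole-part block offset
    ``q = floor(k / N)`` and an intra-ciphertext amount ``k mod N``.  Each part
    is rotated once, split by a plaintext mask into the slots that stay in
    their block and the slots that overflow into the next block (the overflow
    obtained by subtracting the masked part), and the pieces are recombined
    with the block offset applied.  Per call this costs one level (the mask
    multiplication) and ``Osum = 2r``, ``Omul = r``, ``Orot = r``.

    The logical length must fill the parts exactly (``n = r * N``): cyclic
    rotation over a partially filled final part is not defined by per-part
    rotations.
    """
    r, N = v.r, v.N
    if v.n != r * N:
        raise CapacityError(
            f"big_rotate needs n = r*N (got n={v.n}, r={r}, N={N}); zero-pad the "
            "logical vector to a whole number of ciphertexts")
    k = k % (r * N)
    q, rot = divmod(k, N)
    keep_mask = make_bitmask(range(N - rot), v.params)  # rot=0 -> all-ones, still applied
    kept, overflow = [], []
    for p in v.parts:
        rp = rotate(p, rot)
        kp = elementwise("mul", rp, keep_mask, opname="big_rotate mask")
        overflow.append(elementwise("sub", rp, kp, out=rp))  # reuse rp's storage
        kept.append(kp)
        del rp, kp
    out = [elementwise("sum", kept[(i + q) % r], overflow[(i + q + 1) % r],
                       out=kept[(i + q) % r])
           for i in range(r)]
    return BigPackedVector(out, v.n)


def make_bitmask(indices, params: HEParams) -> np.ndarray:
    """Plaintext 0/1 mask with ones exactly at ``indices`` (subset of [0, N))."""
    mask = np.zeros(params.N, dtype=np.float64)
    for t in indices:
        if not 0 <= t < params.N:
            raise ValueError(f"bitmask index {t} out of range [0, {params.N})")
        mask[t] = 1.0
    return mask


def invert_mask(mask: np.ndarray) -> np.ndarray:
    """Inverted bitmask: zeroes become ones and vice versa (1 - mask)."""
    return 1.0 - np.asarray(mask, dtype=np.float64)


def poly_eval(v: PackedVector, coeffs: Sequence[float]) -> PackedVector:
    """Evaluate a polynomial (coefficients low-to-high) on every slot.

    Powers are built by balanced repeated multiplication, so ``x**d`` costs
    ``ceil(log2 d)`` levels; a further level is spent multiplying a power by
    its coefficient unless the coefficient is exactly 1 (the bare square
    activation ``x**2`` therefore costs a single level).  The constant term is
    a plaintext addition and costs no depth.
    """
    coeffs = list(coeffs)
    while len(coeffs) > 1 and coeffs[-1] == 0:
        coeffs.pop()
    d = len(coeffs) - 1
    if d == 0:
        out = zeros_like(v)
        return elementwise("sum", out, float(coeffs[0]), out=out)

    powers: dict[int, PackedVector] = {1: v}

    def power(i: int) -> PackedVector:
        if i not in powers:
            lo = i // 2
            hi = i - lo
            powers[i] = elementwise("mul", power(hi), power(lo),
                                    opname=f"poly_eval x^{i}")
        return powers[i]

    acc: PackedVector | None = None
    for i in range(1, d + 1):
        c = coeffs[i]
        if c == 0:
            continue
        term = power(i)
        if c != 1:
            term = elementwise("mul", term, float(c), opname="poly_eval coeff")
        acc = term if acc is None else elementwise("sum", acc, term)
    if coeffs[0] != 0:
        acc = elementwise("sum", acc, float(coeffs[0]))
    return acc
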