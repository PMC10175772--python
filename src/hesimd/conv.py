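"""The streamlined convolution block: convolution, padding, average pooling,
and the result transformation back to row-column format.

The streamlined convolution exploits plaintext access to the filter: for each
filter tap ``(i, j)`` the packed input is rotated by the tap's SCBF offset,
scaled by the tap weight, and accumulated.  Because the accumulation lands the
output of coordinate ``(u, v)`` at slot ``u*sx*w0*Sx + v*sy*Sy``, a strided
convolution merely *multiplies the stride into the layout metadata* instead of
moving data — chains of convolution / pooling / activation stages therefore
cost one multiplicative level each, and a single result transformation at the
end of the chain restores the dense row-column layout.

The operation computed is cross-correlation (no filter flip), the deep
learning convention.  Slots outside the SCBF-valid set may hold garbage
between stages; correctness is defined on valid slots only and the result
transformation masks everything else away.

Inputs whose padded grid exceeds ``N`` slots lift transparently to
:class:`~hesimd.backend.BigPackedVector`, with the multi-ciphertext rotation
standing in for the plain one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backend import (
    AnyPacked,
    BigPackedVector,
    PackedVector,
    elementwise,
    make_bitmask,
    invert_mask,
    rotate,
    zeros_like,
)
from .errors import CapacityError, LayoutError
from .layouts import SCBFLayout

__all__ = [
    "Filter",
    "ConvSpec",
    "PoolSpec",
    "ConvResult",
    "streamlined_convolution",
    "streamlined_padding",
    "average_pooling",
    "rt_scbf_to_rc",
]


@dataclass(frozen=True)
class Filter:
    """A plaintext ``fx x fy`` convolution kernel."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise LayoutError("filter must be a 2D matrix with fx, fy >= 1")

    @property
    def fx(self) -> int:
        return self.values.shape[0]

    @property
    def fy(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ConvSpec:
    """Convolution hyper-parameters: kernel, stride ``(sx, sy)``, uniform pad."""

    filter: Filter
    stride: tuple[int, int] = (1, 1)
    padding: int = 0

    def __post_init__(self):
        if min(self.stride) < 1:
            raise LayoutError("strides must be >= 1")
        if self.padding < 0:
            raise LayoutError("padding must be >= 0")


@dataclass(frozen=True)
class PoolSpec:
    """Average-pool window; induces the uniform ``1/(px*py)`` filter."""

    px: int
    py: int

    def __post_init__(self):
        if min(self.px, self.py) < 1:
            raise LayoutError("pool window must be >= 1 in both axes")

    def as_filter(self) -> Filter:
        return Filter(np.full((self.px, self.py), 1.0 / (self.px * self.py)))


@dataclass
class ConvResult:
    """Packed output (SCBF layout), updated layout metadata, and output shape."""

    vector: AnyPacked
    layout: SCBFLayout
    hout: int
    wout: int


def _total_slots(ct: AnyPacked) -> int:
    return ct.r * ct.N if isinstance(ct, BigPackedVector) else ct.N


def _zeros_any(ct: AnyPacked) -> AnyPacked:
    if isinstance(ct, BigPackedVector):
        return BigPackedVector([zeros_like(p) for p in ct.parts], ct.n)
    return zeros_like(ct)


def _mask_for(ct: AnyPacked, indices) -> np.ndarray:
    total = _total_slots(ct)
    mask = np.zeros(total, dtype=np.float64)
    for t in indices:
        if not 0 <= t < total:
            raise CapacityError(f"slot {t} out of the {total} available slots")
        mask[t] = 1.0
    return mask


def streamlined_padding(ct: AnyPacked, p: int,
                        layout: SCBFLayout) -> tuple[AnyPacked, SCBFLayout]:
    """Zero-pad the logical matrix by ``p`` on every side, in SCBF layout.

    One right rotation moves the interior to its padded position
    (``p * (w0*Sx + Sy)`` slots, the offset of logical cell ``(p, p)``), and a
    single multiplication by an inverted border bitmask zeroes the ring of
    padding cells.  ``p = 0`` returns the input unchanged at zero cost.
    """
    if p == 0:
        return ct, layout
    hpad, wpad = layout.h + 2 * p, layout.w + 2 * p
    # column capacity: padded columns must stay within one grid row
    if wpad * layout.Sy > layout.w0 * layout.Sx:
        raise CapacityError(
            f"padded width {wpad} does not fit the SCBF grid "
            f"(wpad*Sy = {wpad * layout.Sy} > w0*Sx = {layout.w0 * layout.Sx})")
    padded_layout = layout.with_shape(hpad, wpad)
    total = _total_slots(ct)
    if padded_layout.max_slot >= total:
        raise CapacityError(
            f"padded matrix needs slot {padded_layout.max_slot} but only "
            f"{total} slots exist")

    shift = p * (layout.w0 * layout.Sx + layout.Sy)
    out = rotate(ct, -shift)  # right rotation

    border = []
    for i in range(hpad):
        for j in range(wpad):
            if i < p or i >= hpad - p or j < p or j >= wpad - p:
                border.append(padded_layout.slot(i, j))
    mask = invert_mask(_mask_for(ct, border))
    if isinstance(out, PackedVector):
        out = elementwise("mul", out, mask, out=out, opname="streamlined_padding mask")
    else:
        out = elementwise("mul", out, mask, opname="streamlined_padding mask")
    return out, padded_layout


def streamlined_convolution(ct: AnyPacked, spec: ConvSpec,
                            layout: SCBFLayout) -> ConvResult:
    """Strided 2D cross-correlation of a packed SCBF matrix with a plaintext
    filter; one rotation, one plaintext multiplication and one addition per
    filter tap, one multiplicative level in total.

    The output of coordinate ``(u, v)`` lives at slot
    ``u*w0*Sx' + v*Sy'`` of the returned vector, where ``Sx' = Sx*sx`` and
    ``Sy' = Sy*sy`` — i.e. the stride is absorbed into the updated layout.
    """
    f = spec.filter
    sx, sy = spec.stride
    if spec.padding > 0:
        ct, layout = streamlined_padding(ct, spec.padding, layout)
    h, w = layout.h, layout.w
    if f.fx > h or f.fy > w:
        raise LayoutError(f"{f.fx}x{f.fy} filter larger than {h}x{w} input")
    hout = (h - f.fx) // sx + 1
    wout = (w - f.fy) // sy + 1
    out_layout = layout.after_stride(sx, sy, hout, wout)
    total = _total_slots(ct)
    if out_layout.max_slot >= total:
        raise CapacityError(
            f"convolution output needs slot {out_layout.max_slot} but only "
            f"{total} slots exist")

    conv = _zeros_any(ct)
    for i in range(f.fx):
        for j in range(f.fy):
            shift = i * layout.w0 * layout.Sx + j * layout.Sy
            rot = rotate(ct, shift)
            if isinstance(rot, PackedVector):
                elementwise("mul", rot, float(f.values[i, j]), out=rot,
                            opname="convolution tap")
                elementwise("sum", conv, rot, out=conv)
            else:
                rot = elementwise("mul", rot, float(f.values[i, j]),
                                  opname="convolution tap")
                conv = elementwise("sum", conv, rot)
            del rot
    return ConvResult(conv, out_layout, hout, wout)


def average_pooling(ct: AnyPacked, pool: PoolSpec, layout: SCBFLayout,
                    stride: tuple[int, int] | None = None) -> ConvResult:
    """Average pooling as a convolution with the uniform ``1/(px*py)`` filter,
    stride ``(px, py)`` by default; delegates entirely to
    :func:`streamlined_convolution`."""
    spec = ConvSpec(pool.as_filter(), stride or (pool.px, pool.py), padding=0)
    return streamlined_convolution(ct, spec, layout)


def rt_scbf_to_rc(ct: AnyPacked, layout: SCBFLayout,
                  hout: int | None = None, wout: int | None = None) -> PackedVector:
    """Result transformation: gather the SCBF-valid slots into a dense
    row-column prefix of length ``hout*wout``; every other slot decodes to 0.

    Per output element: one single-slot mask multiplication, one left rotation
    by the slot's displacement, one accumulation — ``hout*wout`` of each, one
    multiplicative level.
    """
    hout = layout.h if hout is None else hout
    wout = layout.w if wout is None else wout
    N = ct.N
    if hout * wout > N:
        raise CapacityError(f"RC output of {hout * wout} entries exceeds N = {N}")

    big = isinstance(ct, BigPackedVector)
    acc = zeros_like(ct.parts[0]) if big else zeros_like(ct)
    for i in range(hout):
        for j in range(wout):
            t = layout.slot(i, j)
            target = i * wout + j
            mask = _mask_for(ct, (t,))
            term = elementwise("mul", ct, mask, opname="rt mask")
            if big:
                moved = rotate(term, t - target)  # multi-ciphertext rotation
                elementwise("sum", acc, moved.parts[0], out=acc)
            else:
                rotate(term, t - target, out=term)
                elementwise("sum", acc, term, out=acc)
            del term
    return acc
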