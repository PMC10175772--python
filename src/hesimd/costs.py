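"""Closed-form operation costs, depth formulas, and capacity analysis.

Every packed-SIMD routine in this package has an exactly predictable ledger —
its counts of additions (``Osum``), multiplications (``Omul``), rotations
(``Orot``), its multiplicative depth (``DC``) and working-set size (``Omem``)
are fixed functions of the layer dimensions.  This module holds those closed
forms, in two regimes per algorithm: the single-ciphertext regime (the
capacity condition ``Ocon`` holds) and the multi-ciphertext regime, where a
logical vector spans ``r = ceil(required / N)`` ciphertexts and every rotation
becomes a mask-split-recombine sequence.

Baseline (non-streamlined) convolution-family routines are carried as
evaluable formulas only — they have no executable counterpart here — so that
predicted ledgers of the streamlined and baseline designs can be compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .backend import CostReport, HEParams
from .errors import CapacityError

__all__ = [
    "CostFormula",
    "NetworkCounts",
    "predict_cost",
    "algorithm_ids",
    "is_executable",
    "depth_streamlined",
    "depth_base",
    "max_square_matmat",
    "max_dense_vec",
    "recommend_dense",
    "check_ledger",
]


@dataclass(frozen=True)
class CostFormula:
    """One algorithm's cost row: capacity expression and both regimes."""

    name: str
    ocon: str                      # human-readable capacity condition
    required: callable             # dims -> slots that must fit
    fits: callable                 # dims -> CostReport (single ciphertext)
    multi: callable                # (dims, r) -> CostReport
    executable: bool = True        # has an implementation in this package


def _d(dims: dict, *keys: str) -> tuple:
    missing = [k for k in keys if k not in dims]
    if missing:
        raise ValueError(f"missing dimension(s) {missing} for this formula")
    return tuple(dims[k] for k in keys)


def _alpha(dims: dict) -> int:
    h, w = _d(dims, "h", "w")
    hext = 1 << max(0, math.ceil(math.log2(h)))
    wext = 1 << max(0, math.ceil(math.log2(w)))
    return max(hext, wext)


_FORMULAS: dict[str, CostFormula] = {}


def _register(f: CostFormula) -> None:
    _FORMULAS[f.name] = f


_register(CostFormula(
    "streamlined_convolution", "h*w <= N",
    required=lambda d: d["h"] * d["w"],
    fits=lambda d: CostReport(1, d["fx"] * d["fy"], d["fx"] * d["fy"],
                              d["fx"] * d["fy"], 3),
    multi=lambda d, r: CostReport(2, 3 * r * d["fx"] * d["fy"],
                                  2 * r * d["fx"] * d["fy"],
                                  r * d["fx"] * d["fy"], 4 * r)))

_register(CostFormula(
    "baseline_convolution", "h*w <= N",
    required=lambda d: d["h"] * d["w"],
    fits=lambda d: CostReport(1, d["fx"] * d["fy"], d["fx"] * d["fy"],
                              d["fx"] * d["fy"], 3),
    multi=lambda d, r: CostReport(2, 3 * r * d["fx"] * d["fy"],
                                  2 * r * d["fx"] * d["fy"],
                                  r * d["fx"] * d["fy"], 4 * r),
    executable=False))

_register(CostFormula(
    "streamlined_padding", "h0*w0 <= N",
    required=lambda d: d["h0"] * d["w0"],
    fits=lambda d: CostReport(1, 0, 1, 1, 2),
    multi=lambda d, r: CostReport(2, 2 * r, 2 * r, r, 3 * r)))

_register(CostFormula(
    "baseline_private_padding", "h*w <= N",
    required=lambda d: d["h"] * d["w"],
    fits=lambda d: CostReport(1, d["h"], d["h"], d["h"], 3),
    multi=lambda d, r: CostReport(2, 3 * r * d["h"], 2 * r * d["h"],
                                  r * d["h"], 4 * r),
    executable=False))

_register(CostFormula(
    "rt_scbf_to_rc", "h*w <= N",
    required=lambda d: d["h"] * d["w"],
    fits=lambda d: CostReport(1, d["hout"] * d["wout"], d["hout"] * d["wout"],
                              d["hout"] * d["wout"], 3),
    multi=lambda d, r: CostReport(2, 3 * r * d["hout"] * d["wout"],
                                  2 * r * d["hout"] * d["wout"],
                                  r * d["hout"] * d["wout"], 4 * r)))

_register(CostFormula(
    "baseline_rt_crf_to_rc", "h*w <= N",
    required=lambda d: d["h"] * d["w"],
    fits=lambda d: CostReport(1, d["hout"], d["hout"], d["hout"], 3),
    multi=lambda d, r: CostReport(2, 3 * r * d["hout"], 2 * r * d["hout"],
                                  r * d["hout"], 4 * r),
    executable=False))

_register(CostFormula(
    "baseline_rt_scrf_to_rc", "h*w <= N",
    required=lambda d: d["h"] * d["w"],
    fits=lambda d: CostReport(1, d["hout"] * d["wout"], d["hout"] * d["wout"],
                              d["hout"] * d["wout"], 3),
    multi=lambda d, r: CostReport(2, 3 * r * d["hout"] * d["wout"],
                                  2 * r * d["hout"] * d["wout"],
                                  r * d["hout"] * d["wout"], 4 * r),
    executable=False))

# The printed capacity expression n*(delta_f - delta_i + 1) <= N is carried
# here verbatim; the runtime enforces the geometric n*max(delta_i, delta_f).
_register(CostFormula(
    "switch_spacing", "n*(delta_f - delta_i + 1) <= N",
    required=lambda d: d["n"] * (d["delta_f"] - d["delta_i"] + 1),
    fits=lambda d: CostReport(1, d["n"], d["n"], d["n"], 3),
    multi=lambda d, r: CostReport(2, 3 * r * d["n"], 2 * r * d["n"],
                                  r * d["n"], 4 * r)))

_register(CostFormula(
    "diagonal_matmul", "max(alpha, n) <= N",
    required=lambda d: max(_alpha(d), d.get("n", d["w"])),
    fits=lambda d: CostReport(1, _alpha(d), _alpha(d), _alpha(d), 4),
    multi=lambda d, r: CostReport(2, 3 * r * _alpha(d), 2 * r * _alpha(d),
                                  r * _alpha(d), 5 * r)))

_register(CostFormula(
    "prepare_matrix_a", "hA*wA*wB <= N",
    required=lambda d: d["hA"] * d["wA"] * d["wB"],
    fits=lambda d: CostReport(1, d["hA"] * d["wA"] + d["wB"],
                              d["hA"] * d["wA"],
                              d["hA"] * d["wA"] + d["wB"], 3),
    multi=lambda d, r: CostReport(3, 3 * r * d["hA"] * d["wA"] + d["wB"],
                                  r * (2 * d["hA"] * d["wA"] + d["wB"]),
                                  r * (d["hA"] * d["wA"] + d["wB"]), 4 * r)))

_register(CostFormula(
    "prepare_matrix_b", "hB*wB*hA <= N",
    required=lambda d: d["hB"] * d["wB"] * d["hA"],
    fits=lambda d: CostReport(0, d["hA"], 0, d["hA"], 2),
    multi=lambda d, r: CostReport(1, 3 * r * d["hA"], r * d["hA"],
                                  r * d["hA"], 3 * r)))

_register(CostFormula(
    "matmat", "max(hA*wA*wB, hB*wB*hA) <= N",
    required=lambda d: max(d["hA"] * d["wA"] * d["wB"],
                           d["hB"] * d["wB"] * d["hA"]),
    fits=lambda d: CostReport(1, d["wA"], 1, d["wA"], 4),
    multi=lambda d, r: CostReport(2, 3 * r * d["wA"], r * (d["wA"] + 1),
                                  r * d["wA"], 5 * r)))

_register(CostFormula(
    "result_extraction", "hA*wA*wB <= N",
    required=lambda d: d["hA"] * d["wA"] * d["wB"],
    fits=lambda d: CostReport(1, d["hA"], d["hA"], d["hA"], 4),
    multi=lambda d, r: CostReport(2, 3 * r * d["hA"], 2 * r * d["hA"],
                                  r * d["hA"], 3 * r)))

_register(CostFormula(
    "big_rotate", "always (r parts)",
    required=lambda d: d["r"],   # regime is explicit: r given directly
    fits=lambda d: CostReport(1, 2 * d["r"], d["r"], d["r"], 2 * d["r"]),
    multi=lambda d, r: CostReport(1, 2 * r, r, r, 2 * r)))


def algorithm_ids() -> list[str]:
    return sorted(_FORMULAS)


def is_executable(algorithm: str) -> bool:
    return _FORMULAS[algorithm].executable


def predict_cost(algorithm: str, dims: dict, params: HEParams) -> CostReport:
    """Evaluate an algorithm's closed-form ledger at ``dims``.

    The regime is selected by the algorithm's capacity condition against
    ``params.N``; in the multi-ciphertext regime ``r = ceil(required / N)``.
    """
    if algorithm not in _FORMULAS:
        raise ValueError(f"unknown algorithm {algorithm!r}; "
                         f"known: {', '.join(algorithm_ids())}")
    f = _FORMULAS[algorithm]
    if algorithm == "big_rotate":
        return f.fits(dims)
    required = f.required(dims)
    if required <= params.N:
        return f.fits(dims)
    r = -(-required // params.N)
    return f.multi(dims, r)


def check_ledger(algorithm: str, dims: dict, params: HEParams,
                 measured: CostReport) -> dict:
    """Field-by-field comparison of a measured ledger against the prediction.

    DC, Osum, Omul and Orot must match exactly; the measured working set must
    not exceed the predicted Omem.  Returns a dict of mismatches (empty =
    agreement).
    """
    pred = predict_cost(algorithm, dims, params)
    diffs = {}
    for f in ("dc", "osum", "omul", "orot"):
        if getattr(measured, f) != getattr(pred, f):
            diffs[f] = (getattr(measured, f), getattr(pred, f))
    if measured.omem > pred.omem:
        diffs["omem"] = (measured.omem, pred.omem)
    return diffs


# ---------------------------------------------------------------------------
# network depth formulas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkCounts:
    """Layer counts of a convolutional block chain: plain convolutions,
    strided convolutions, paddings, average poolings, activations (with the
    activation's own depth ``dc_act``)."""

    lconv: int = 0
    lstride: int = 0
    lpad: int = 0
    lpool: int = 0
    lact: int = 0
    dc_act: int = 1

    def __post_init__(self):
        if min(self.lconv, self.lstride, self.lpad, self.lpool,
               self.lact, self.dc_act) < 0:
            raise ValueError("layer counts must be non-negative")


def depth_streamlined(c: NetworkCounts) -> int:
    """Depth of a streamlined convolutional chain: one level per stage plus
    one for the single trailing result transformation."""
    return c.lconv + c.lstride + c.lpad + c.lpool + c.lact * c.dc_act + 1


def depth_base(c: NetworkCounts) -> int:
    """Depth of the baseline design, which pays a result transformation after
    every convolution and pooling stage (reporting only; the baseline
    algorithms themselves are not implemented here)."""
    return 2 * c.lconv + 2 * c.lstride + c.lpad + 2 * c.lpool + c.lact * c.dc_act


# ---------------------------------------------------------------------------
# capacity takeaways
# ---------------------------------------------------------------------------


def max_square_matmat(N: int) -> int:
    """Largest ``m`` such that two square ``m x m`` matrices can be multiplied
    in one ciphertext: the replicated layout needs ``m**3 <= N``."""
    if N < 1:
        raise ValueError("N must be >= 1")
    m = 1
    while (m + 1) ** 3 <= N:
        m += 1
    return m


def max_dense_vec(N: int) -> int:
    """Largest input width of a reducing dense layer (``hA <= wA = hB``,
    ``wB = 1``) in one ciphertext: the constraint collapses to ``hB**2 <= N``."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return math.isqrt(N)


def recommend_dense(l: int, dims: dict, N: int) -> tuple[str, str]:
    """Choose between the replicated and diagonal dense schemes for an
    ``l``-layer dense network of the given shapes.

    The replicated scheme wins only when its capacity constraint holds *and*
    the network has a single dense layer; from two layers on the diagonal
    scheme's depth (2l+1 versus the multi-ciphertext 4l+2 <= 5l comparison)
    and larger capacity make it the better default.  Returns
    ``(choice, rationale)``.
    """
    hA, wA = dims["hA"], dims["wA"]
    hB, wB = dims.get("hB", wA), dims.get("wB", 1)
    required = max(hA * wA * wB, hB * wB * hA)
    ocon_ok = required <= N
    diag_favored = (4 * l + 2) <= 5 * l   # true from l = 2 on
    if ocon_ok and (l == 1 or not diag_favored):
        return ("matmat",
                f"replicated capacity max(hA*wA*wB, hB*wB*hA) = {required} <= N = {N} "
                f"and l = {l}: depth 2l beats the diagonal 2l+1")
    if not ocon_ok:
        return ("diagonal",
                f"replicated capacity violated: max(hA*wA*wB, hB*wB*hA) = "
                f"{required} > N = {N}")
    return ("diagonal",
            f"l = {l} >= 2: diagonal depth comparison (4l+2 <= 5l) favors the "
            f"diagonal scheme")
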