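"""Network composition and end-to-end encrypted inference.

A network configuration is an ordered list of layer descriptors plus the
leveled-scheme parameters.  :func:`build_plan` walks the list, negotiates the
packing layout between stages — consecutive convolution / pooling / activation
layers share one backward-convolution-format chain with a *single* trailing
result transformation; dense layers get the spacing or replication initial
representation their scheme needs — and predicts the full operation ledger,
rejecting configurations that exceed the slot capacity or the depth budget
before anything is encrypted.

Execution follows the client/server split of outsourced private inference:
the client generates keys, encodes and (in role terms) encrypts the input and
decrypts the result; the server executes the plan with public handles only
and structurally cannot decrypt (:func:`execute_plan` takes public-only key
material).  Padding of the *first* layer is performed client-side on the
plaintext by default, since the client touches the cleartext anyway; a
``server_padding`` flag forces the streamlined padding algorithm instead,
which requires the input to be encoded on the padded grid.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import costs
from .backend import (
    CostReport,
    HEParams,
    KeyMaterial,
    PackedVector,
    counter_scope,
    decrypt_decode,
    elementwise,
    encode_encrypt,
    keygen,
    poly_eval,
    rotate,
)
from .conv import ConvSpec, Filter, PoolSpec, average_pooling, rt_scbf_to_rc, \
    streamlined_convolution, streamlined_padding
from .dense import DenseWeights, DiagonalPlan, dense_layer_diagonal, \
    dense_layer_matmat, switch_spacing
from .errors import CapacityError, LayoutError, LevelExhaustedError
from .layouts import SCBFLayout

logger = logging.getLogger("hesimd")

__all__ = ["NetworkSpec", "Plan", "InferenceResult", "load_network",
           "build_plan", "execute_plan", "run_inference"]


def _load_array(value, base_dir: str | None):
    if value is None:
        return None
    if isinstance(value, dict):
        path = value["path"]
        if base_dir and not os.path.isabs(path):
            path = os.path.join(base_dir, path)
        flat = np.loadtxt(path, delimiter=",").reshape(-1)
        return flat.reshape(value["shape"])
    return np.asarray(value, dtype=np.float64)


@dataclass
class NetworkSpec:
    """Validated network description with materialised weight arrays."""

    params: HEParams
    input_shape: tuple[int, int]
    channels: int
    layers: list[dict]
    server_padding: bool = False

    @classmethod
    def from_config(cls, config: dict, base_dir: str | None = None) -> "NetworkSpec":
        he = config.get("he", {})
        params = HEParams(
            N=he.get("N", 1024),
            depth_budget=he.get("depth_budget", 16),
            scale_bits=he.get("scale_bits", 40),
            backend=he.get("backend", "sim"),
        )
        inp = config["input"]
        layers = []
        for layer in config["layers"]:
            layer = dict(layer)
            if "weights" in layer:
                layer["weights"] = _load_array(layer["weights"], base_dir)
            if layer.get("bias") is not None:
                layer["bias"] = _load_array(layer["bias"], base_dir)
            layers.append(layer)
        return cls(params=params,
                   input_shape=(inp["h"], inp["w"]),
                   channels=inp.get("channels", 1),
                   layers=layers,
                   server_padding=bool(config.get("server_padding", False)))


def load_network(path: str) -> NetworkSpec:
    """Read a network configuration from YAML or JSON."""
    with open(path) as fh:
        text = fh.read()
    if path.endswith((".yaml", ".yml")):
        import yaml
        config = yaml.safe_load(text)
    else:
        config = json.loads(text)
    return NetworkSpec.from_config(config, base_dir=os.path.dirname(path) or ".")


@dataclass
class PlanStep:
    kind: str
    detail: dict
    predicted: CostReport


@dataclass
class Plan:
    spec: NetworkSpec
    steps: list[PlanStep]
    encode_shape: tuple[int, int]      # per-channel grid the client encodes on
    logical_shape: tuple[int, int]     # matrix shape inside that grid
    client_pad: int                    # plaintext padding applied client-side
    out_features: int
    predicted_total: CostReport

    def as_dict(self) -> dict:
        return {
            "encode_shape": list(self.encode_shape),
            "client_pad": self.client_pad,
            "out_features": self.out_features,
            "steps": [{"kind": s.kind,
                       **{k: v for k, v in s.detail.items()
                          if isinstance(v, (int, float, str, list, tuple))},
                       "predicted": s.predicted.as_dict()} for s in self.steps],
            "predicted_total": self.predicted_total.as_dict(),
        }


def _poly_cost(coeffs) -> CostReport:
    """Predicted ledger of poly_eval, mirroring its evaluation strategy."""
    coeffs = list(coeffs)
    while len(coeffs) > 1 and coeffs[-1] == 0:
        coeffs.pop()
    d = len(coeffs) - 1
    if d == 0:
        return CostReport(0, 1, 0, 0, 1)
    muls = 0
    depth = {1: 0}

    def power(i):
        if i not in depth:
            nonlocal muls
            lo, hi = i // 2, i - i // 2
            depth[i] = 1 + max(power(hi), power(lo))
            muls += 1
        return depth[i]

    dc = 0
    sums = 0
    terms = 0
    for i in range(1, d + 1):
        if coeffs[i] == 0:
            continue
        pd = power(i)
        if coeffs[i] != 1:
            muls += 1
            pd += 1
        dc = max(dc, pd)
        terms += 1
    sums += terms - 1
    if coeffs[0] != 0:
        sums += 1
    return CostReport(dc, sums, muls, 0, d + 1)


def build_plan(spec: NetworkSpec) -> Plan:
    """Validate the layer chain, insert the implicit layout transformations,
    and predict the total ledger.  Raises :class:`CapacityError` or
    :class:`LevelExhaustedError` naming the offending layer when the network
    cannot run at the given parameters."""
    params = spec.params
    N = params.N
    steps: list[PlanStep] = []
    total = CostReport()
    depth_used = 0

    def add(kind: str, detail: dict, predicted: CostReport, depth: int) -> None:
        nonlocal total, depth_used
        steps.append(PlanStep(kind, detail, predicted))
        total = total + predicted
        depth_used += depth
        total.dc = depth_used

    h, w = spec.input_shape
    channels = spec.channels
    client_pad = 0
    first_conv = next((l for l in spec.layers if l["type"] == "conv"), None)
    first_is_first_layer = bool(spec.layers) and spec.layers[0]["type"] == "conv"
    grid = None
    if (first_conv is not None and first_is_first_layer
            and first_conv.get("padding", 0) > 0):
        p0 = int(first_conv["padding"])
        if spec.server_padding:
            # encode on the padded grid so the streamlined padding fits
            grid = (h + 2 * p0, w + 2 * p0)
        else:
            client_pad = p0
            h, w = h + 2 * p0, w + 2 * p0
    encode_shape = grid or (h, w)

    layout = SCBFLayout(h0=encode_shape[0], w0=encode_shape[1], h=h, w=w)
    stage = "scbf"
    vec_n = 0
    spacing = 1

    for li, layer in enumerate(spec.layers):
        kind = layer["type"]
        first = li == 0

        if kind in ("conv", "avgpool") and stage != "scbf":
            raise LayoutError(
                f"layer {li} ({kind}): convolutional stages must precede the "
                "dense block in this pipeline")

        if kind == "conv":
            Wc = np.asarray(layer["weights"], dtype=np.float64)
            if Wc.ndim != 4:
                raise LayoutError(f"layer {li}: conv weights must be "
                                  "(out_channels, in_channels, fx, fy)")
            cout, cin, fx, fy = Wc.shape
            if cin != channels:
                raise LayoutError(f"layer {li}: expects {cin} input channels, "
                                  f"chain provides {channels}")
            p = layer.get("padding", 0)
            if first and client_pad:
                p = 0
            sx, sy = layer.get("stride", (1, 1))
            pred = CostReport()
            depth = 0
            if p > 0:
                pad_pred = costs.predict_cost(
                    "streamlined_padding",
                    {"h0": layout.h0, "w0": layout.w0}, params)
                for _ in range(cin):
                    pred = pred + pad_pred
                depth += 1
                hp, wp = layout.h + 2 * p, layout.w + 2 * p
                if wp * layout.Sy > layout.w0 * layout.Sx:
                    raise CapacityError(
                        f"layer {li}: padded width {wp} exceeds the SCBF grid "
                        f"(wpad*Sy > w0*Sx); pad client-side or enlarge the grid")
            else:
                hp, wp = layout.h, layout.w
            if fx > hp or fy > wp:
                raise LayoutError(f"layer {li}: {fx}x{fy} kernel larger than "
                                  f"{hp}x{wp} input")
            hout = (hp - fx) // sx + 1
            wout = (wp - fy) // sy + 1
            conv_pred = costs.predict_cost(
                "streamlined_convolution",
                {"h": hp, "w": wp, "fx": fx, "fy": fy}, params)
            for _ in range(cout * cin):
                pred = pred + conv_pred
            pred.osum += cout * (cin - 1)      # cross-channel accumulation
            if layer.get("bias") is not None:
                pred.osum += cout
            depth += 1
            new_layout = layout.with_shape(hp, wp).after_stride(sx, sy, hout, wout)
            if new_layout.max_slot >= N * max(1, -(-layout.h0 * layout.w0 // N)):
                raise CapacityError(
                    f"layer {li}: output slot {new_layout.max_slot} exceeds "
                    f"capacity (Ocon h*w <= N, N = {N})")
            pred.dc = depth
            add("conv", {"layer": li, "out_shape": [hout, wout], "cout": cout,
                         "padding": p, "stride": [sx, sy]}, pred, depth)
            layout = new_layout
            channels = cout

        elif kind == "avgpool":
            px, py = layer["pool"]
            if px > layout.h or py > layout.w:
                raise LayoutError(f"layer {li}: pool window exceeds input")
            hout = (layout.h - px) // px + 1
            wout = (layout.w - py) // py + 1
            pool_pred = costs.predict_cost(
                "streamlined_convolution",
                {"h": layout.h, "w": layout.w, "fx": px, "fy": py}, params)
            pred = CostReport()
            for _ in range(channels):
                pred = pred + pool_pred
            pred.dc = 1
            add("avgpool", {"layer": li, "out_shape": [hout, wout]}, pred, 1)
            layout = layout.after_stride(px, py, hout, wout)

        elif kind == "activation":
            act_pred = _poly_cost(layer["coeffs"])
            reps = channels if stage == "scbf" else 1
            pred = CostReport()
            for _ in range(reps):
                pred = pred + act_pred
            depth = act_pred.dc
            if stage == "vec" and layer["coeffs"][0] != 0:
                # a nonzero constant term fills the unused slots; mask the
                # logical entries back out so replication stays sound
                pred.omul += 1
                depth += 1
            pred.dc = depth
            add("activation", {"layer": li, "degree": len(layer["coeffs"]) - 1},
                pred, depth)

        elif kind in ("flatten", "dense"):
            if stage == "scbf":
                m = layout.h * layout.w
                if m > N:
                    raise CapacityError(
                        f"layer {li}: flattened channel of {m} entries "
                        f"exceeds N = {N}")
                rt_pred = costs.predict_cost(
                    "rt_scbf_to_rc",
                    {"h": layout.h, "w": layout.w,
                     "hout": layout.h, "wout": layout.w}, params)
                pred = CostReport()
                for _ in range(channels):
                    pred = pred + rt_pred
                pred.osum += channels - 1      # concat accumulations
                pred.orot += channels          # concat rotations
                if channels * m > N:
                    raise CapacityError(
                        f"layer {li}: flattened vector of {channels * m} "
                        f"entries exceeds N = {N}")
                pred.dc = 1
                add("flatten", {"layer": li, "n": channels * m}, pred, 1)
                stage, vec_n, spacing = "vec", channels * m, 1
            if kind == "flatten":
                continue

            W = np.asarray(layer["weights"], dtype=np.float64)
            hA, wA = W.shape
            if wA != vec_n:
                raise LayoutError(f"layer {li}: dense expects {wA} inputs, "
                                  f"chain provides {vec_n}")
            method = layer.get("method", "auto")
            if method == "auto":
                n_dense = sum(1 for l in spec.layers if l["type"] == "dense")
                method, _ = costs.recommend_dense(
                    n_dense, {"hA": hA, "wA": wA, "hB": wA, "wB": 1}, N)
            if method == "matmat":
                if spacing != 1:
                    ss_pred = costs.predict_cost(
                        "switch_spacing",
                        {"n": vec_n, "delta_i": spacing, "delta_f": 1}, params)
                    add("respace", {"layer": li, "delta": 1}, ss_pred, 1)
                    spacing = 1
                req = hA * wA
                if req > N:
                    raise CapacityError(
                        f"layer {li}: replicated product needs "
                        f"max(hA*wA*wB, hB*wB*hA) = {req} <= N = {N}")
                pred = (costs.predict_cost("prepare_matrix_b",
                                           {"hA": hA, "hB": wA, "wB": 1}, params)
                        + costs.predict_cost("matmat",
                                             {"hA": hA, "wA": wA, "hB": wA,
                                              "wB": 1}, params)
                        + costs.predict_cost("result_extraction",
                                             {"hA": hA, "wA": wA, "wB": 1},
                                             params))
                pred.osum += 1                 # bias
                pred.dc = 2
                add("dense", {"layer": li, "method": "matmat",
                              "out_features": hA}, pred, 2)
                vec_n, spacing = hA, 1
            elif method == "diagonal":
                plan_d = DiagonalPlan(hA, wA, N)
                plan_d.check_capacity()
                if vec_n * max(spacing, plan_d.delta) > N:
                    raise CapacityError(
                        f"layer {li}: spacing IR needs n*max(delta_i, delta_f) "
                        f"= {vec_n * max(spacing, plan_d.delta)} <= N = {N}")
                pred = (costs.predict_cost(
                            "switch_spacing",
                            {"n": vec_n, "delta_i": spacing,
                             "delta_f": plan_d.delta}, params)
                        + costs.predict_cost(
                            "diagonal_matmul",
                            {"h": hA, "w": wA, "n": wA}, params))
                pred.osum += 1                 # bias
                pred.dc = 2
                add("dense", {"layer": li, "method": "diagonal",
                              "out_features": hA, "delta": plan_d.delta},
                    pred, 2)
                vec_n, spacing = hA, plan_d.delta
            else:
                raise LayoutError(f"layer {li}: unknown dense method {method!r}")
        else:
            raise LayoutError(f"layer {li}: unknown layer type {kind!r}")

    if stage == "vec" and spacing != 1:
        pred = costs.predict_cost(
            "switch_spacing", {"n": vec_n, "delta_i": spacing, "delta_f": 1},
            params)
        add("respace", {"layer": "output", "delta": 1}, pred, 1)
        spacing = 1
    if stage == "scbf":
        vec_n = layout.h * layout.w * channels

    if depth_used > params.depth_budget:
        raise LevelExhaustedError(
            f"network needs depth {depth_used} > depth budget "
            f"{params.depth_budget}")

    total.dc = depth_used
    return Plan(spec=spec, steps=steps, encode_shape=encode_shape,
                logical_shape=(h, w) if grid is None else spec.input_shape,
                client_pad=client_pad, out_features=vec_n,
                predicted_total=total)


@dataclass
class InferenceResult:
    logits: np.ndarray
    per_layer: list[dict]
    total: CostReport
    predicted: CostReport
    backend: str


def execute_plan(plan: Plan, cts: list[PackedVector],
                 public_keys: KeyMaterial) -> tuple[PackedVector, list[dict]]:
    """Server-side evaluation: consumes encrypted channels and public key
    handles only; never decrypts.  Returns the output vector (RC prefix of
    length ``plan.out_features``) and per-step measured ledgers."""
    spec = plan.spec
    params = spec.params
    layout = SCBFLayout(h0=plan.encode_shape[0], w0=plan.encode_shape[1],
                        h=plan.logical_shape[0], w=plan.logical_shape[1])
    state: list[PackedVector] | PackedVector = cts
    spacing = 1
    vec_n = 0
    ledgers: list[dict] = []

    for step in plan.steps:
        layer = spec.layers[step.detail["layer"]] \
            if isinstance(step.detail.get("layer"), int) else None
        with counter_scope() as scope:
            if step.kind == "conv":
                Wc = np.asarray(layer["weights"], dtype=np.float64)
                cout, cin, fx, fy = Wc.shape
                p = step.detail["padding"]
                sx, sy = step.detail["stride"]
                inputs = state
                if p > 0:
                    padded = []
                    for ct in inputs:
                        pct, pl = streamlined_padding(ct, p, layout)
                        padded.append(pct)
                    inputs, layout = padded, pl
                outs = []
                new_layout = None
                for co in range(cout):
                    acc = None
                    for ci in range(cin):
                        res = streamlined_convolution(
                            inputs[ci], ConvSpec(Filter(Wc[co, ci]), (sx, sy), 0),
                            layout)
                        new_layout = res.layout
                        acc = res.vector if acc is None else \
                            elementwise("sum", acc, res.vector, out=acc)
                    if layer.get("bias") is not None:
                        acc = elementwise(
                            "sum", acc, float(layer["bias"][co]), out=acc)
                    outs.append(acc)
                layout = new_layout
                state = outs
            elif step.kind == "avgpool":
                px, py = layer["pool"]
                outs = []
                new_layout = None
                for ct in state:
                    res = average_pooling(ct, PoolSpec(px, py), layout)
                    new_layout = res.layout
                    outs.append(res.vector)
                layout = new_layout
                state = outs
            elif step.kind == "activation":
                coeffs = layer["coeffs"]
                if isinstance(state, list):
                    state = [poly_eval(ct, coeffs) for ct in state]
                else:
                    state = poly_eval(state, coeffs)
                    if coeffs[0] != 0:
                        mask = np.zeros(params.N)
                        mask[: vec_n * spacing: spacing] = 1.0
                        state = elementwise("mul", state, mask, out=state,
                                            opname="activation cleanup mask")
            elif step.kind == "flatten":
                m = layout.h * layout.w
                acc = None
                for c, ct in enumerate(state):
                    rc = rt_scbf_to_rc(ct, layout)
                    moved = rotate(rc, -(c * m))
                    acc = moved if acc is None else \
                        elementwise("sum", acc, moved, out=acc)
                state = acc
                vec_n, spacing = step.detail["n"], 1
            elif step.kind == "respace":
                state = switch_spacing(state, vec_n, spacing, 1)
                spacing = 1
            elif step.kind == "dense":
                weights = DenseWeights(np.asarray(layer["weights"]),
                                       None if layer.get("bias") is None
                                       else np.asarray(layer["bias"]))
                if step.detail["method"] == "matmat":
                    if spacing != 1:
                        state = switch_spacing(state, vec_n, spacing, 1)
                        spacing = 1
                    state = dense_layer_matmat(state, weights)
                    vec_n, spacing = weights.h, 1
                else:
                    state, spacing = dense_layer_diagonal(state, weights,
                                                          spacing_in=spacing)
                    vec_n = weights.h
            else:  # pragma: no cover
                raise LayoutError(f"unknown plan step {step.kind!r}")
        entry = {"step": step.kind, "detail": step.detail,
                 "measured": scope.report.as_dict(),
                 "predicted": step.predicted.as_dict(),
                 "level_used": (state.level_used if isinstance(state, PackedVector)
                                else max(s.level_used for s in state))}
        ledgers.append(entry)
        logger.info("%s", json.dumps(entry))

    return state, ledgers


def run_inference(spec_or_plan: NetworkSpec | Plan, image: np.ndarray,
                  keys: KeyMaterial | None = None) -> InferenceResult:
    """End-to-end private inference round trip.

    Client side: key generation, optional plaintext padding of the first
    layer, encoding/encryption of each input channel, and final decryption.
    Server side: :func:`execute_plan` with public-only key handles.
    """
    plan = spec_or_plan if isinstance(spec_or_plan, Plan) \
        else build_plan(spec_or_plan)
    spec = plan.spec
    params = spec.params
    keys = keys or keygen(params)

    image = np.asarray(image, dtype=np.float64)
    chans = [image] if image.ndim == 2 else [image[..., c]
                                             for c in range(image.shape[2])]
    if len(chans) != spec.channels:
        raise LayoutError(f"expected {spec.channels} channels, got {len(chans)}")
    p = plan.client_pad
    if p:
        chans = [np.pad(ch, p) for ch in chans]

    cts = []
    for ch in chans:
        if ch.shape != plan.encode_shape:
            grid = np.zeros(plan.encode_shape)
            grid[: ch.shape[0], : ch.shape[1]] = ch
            ch = grid
        flat = ch.reshape(-1)
        if flat.size > params.N:
            # pad to a whole number of ciphertexts so rotations stay cyclic
            r = -(-flat.size // params.N)
            flat = np.concatenate([flat, np.zeros(r * params.N - flat.size)])
        cts.append(encode_encrypt(flat, params, keys.public_only()))
    out_ct, ledgers = execute_plan(plan, cts, keys.public_only())

    logits = decrypt_decode(out_ct, keys, plan.out_features)
    measured = CostReport()
    dc = 0
    for entry in ledgers:
        m = entry["measured"]
        measured.osum += m["osum"]
        measured.omul += m["omul"]
        measured.orot += m["orot"]
        measured.omem = max(measured.omem, m["omem"])
        dc += m["dc"]
    measured.dc = dc
    return InferenceResult(logits=logits, per_layer=ledgers, total=measured,
                           predicted=plan.predicted_total,
                           backend=params.backend)
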