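"""Seeded synthetic inputs and independent plaintext oracles.

Every SIMD routine in this package is tested against a brute-force reference
implemented here with plain nested loops — no slot arithmetic, no layout
bookkeeping, no code shared with the packed path.  The generators produce
deterministic matrices, filters and whole network configurations (weights
drawn uniformly from [-1, 1] by default, which keeps fixed-point precision
comparisons meaningful at the default encoding scale).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FixtureSpec",
    "gen_matrix",
    "gen_network",
    "write_network",
    "oracle_rotate",
    "oracle_conv",
    "oracle_pool",
    "oracle_dense",
    "oracle_matmat",
    "oracle_poly",
    "oracle_network",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and distribution of one generated fixture."""

    seed: int
    h: int = 4
    w: int = 4
    low: float = -1.0
    high: float = 1.0


def gen_matrix(spec: FixtureSpec | None = None, *, seed: int | None = None,
               h: int = 4, w: int = 4, low: float = -1.0,
               high: float = 1.0) -> np.ndarray:
    """Deterministic ``h x w`` matrix, uniform on [low, high]."""
    if spec is None:
        spec = FixtureSpec(seed=seed if seed is not None else 0,
                           h=h, w=w, low=low, high=high)
    rng = np.random.default_rng(spec.seed)
    return rng.uniform(spec.low, spec.high, size=(spec.h, spec.w))


# ---------------------------------------------------------------------------
# oracles: straightforward reference computations
# ---------------------------------------------------------------------------


def oracle_rotate(v, k: int) -> list:
    """Index-permutation left rotation: out[j] = in[(j + k) mod n]."""
    v = list(v)
    n = len(v)
    return [v[(j + k) % n] for j in range(n)]


def oracle_conv(M, F, stride=(1, 1), padding: int = 0) -> np.ndarray:
    """Nested-loop 2D cross-correlation with zero padding and stride."""
    M = np.asarray(M, dtype=np.float64)
    F = np.asarray(F, dtype=np.float64)
    h, w = M.shape
    fx, fy = F.shape
    sx, sy = stride
    p = padding
    padded = np.zeros((h + 2 * p, w + 2 * p))
    padded[p: p + h, p: p + w] = M
    hout = (h - fx + 2 * p) // sx + 1
    wout = (w - fy + 2 * p) // sy + 1
    out = np.zeros((hout, wout))
    for u in range(hout):
        for v in range(wout):
            s = 0.0
            for i in range(fx):
                for j in range(fy):
                    s += padded[u * sx + i, v * sy + j] * F[i, j]
            out[u, v] = s
    return out


def oracle_pool(M, window) -> np.ndarray:
    """Block means over non-overlapping ``px x py`` windows."""
    M = np.asarray(M, dtype=np.float64)
    px, py = window
    hout = (M.shape[0] - px) // px + 1
    wout = (M.shape[1] - py) // py + 1
    out = np.zeros((hout, wout))
    for u in range(hout):
        for v in range(wout):
            s = 0.0
            for i in range(px):
                for j in range(py):
                    s += M[u * px + i, v * py + j]
            out[u, v] = s / (px * py)
    return out


def oracle_dense(W, x, b=None) -> np.ndarray:
    """Row-by-row weighted sums: z = W x + b."""
    W = np.asarray(W, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    h, w = W.shape
    b = np.zeros(h) if b is None else np.asarray(b, dtype=np.float64)
    out = np.zeros(h)
    for i in range(h):
        s = 0.0
        for j in range(w):
            s += W[i, j] * x[j]
        out[i] = s + b[i]
    return out


def oracle_matmat(A, B) -> np.ndarray:
    """Triple-loop matrix product."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    hA, wA = A.shape
    hB, wB = B.shape
    assert wA == hB
    C = np.zeros((hA, wB))
    for i in range(hA):
        for m in range(wB):
            s = 0.0
            for j in range(wA):
                s += A[i, j] * B[j, m]
            C[i, m] = s
    return C


def oracle_poly(x, coeffs) -> np.ndarray:
    """Scalar per-element polynomial evaluation (low-to-high coefficients)."""
    x = np.asarray(x, dtype=np.float64)
    out = np.zeros_like(x)
    flat = out.reshape(-1)
    for idx, xv in enumerate(np.asarray(x).reshape(-1)):
        acc = 0.0
        for c in reversed(list(coeffs)):
            acc = acc * xv + c
        flat[idx] = acc
    return out


def oracle_network(config: dict, image: np.ndarray) -> np.ndarray:
    """Plaintext reference inference for a network configuration with inline
    weights.  Channel handling and the channel-major flatten order match the
    packed pipeline's conventions; the arithmetic is all loops over the
    oracles above."""
    image = np.asarray(image, dtype=np.float64)
    channels = [image] if image.ndim == 2 else [image[..., c]
                                                for c in range(image.shape[2])]
    state: list[np.ndarray] | np.ndarray = channels
    for layer in config["layers"]:
        kind = layer["type"]
        if kind == "conv":
            W = np.asarray(layer["weights"], dtype=np.float64)  # (cout, cin, fx, fy)
            bias = layer.get("bias")
            outs = []
            for co in range(W.shape[0]):
                acc = None
                for ci in range(W.shape[1]):
                    part = oracle_conv(state[ci], W[co, ci],
                                       tuple(layer.get("stride", (1, 1))),
                                       layer.get("padding", 0))
                    acc = part if acc is None else acc + part
                if bias is not None:
                    acc = acc + bias[co]
                outs.append(acc)
            state = outs
        elif kind == "activation":
            coeffs = layer["coeffs"]
            if isinstance(state, list):
                state = [oracle_poly(ch, coeffs) for ch in state]
            else:
                state = oracle_poly(state, coeffs)
        elif kind == "avgpool":
            state = [oracle_pool(ch, tuple(layer["pool"])) for ch in state]
        elif kind == "flatten":
            state = np.concatenate([ch.reshape(-1) for ch in state])
        elif kind == "dense":
            if isinstance(state, list):
                state = np.concatenate([ch.reshape(-1) for ch in state])
            state = oracle_dense(layer["weights"], state, layer.get("bias"))
        else:
            raise ValueError(f"unknown layer type {kind!r}")
    if isinstance(state, list):
        state = np.concatenate([ch.reshape(-1) for ch in state])
    return np.asarray(state, dtype=np.float64)


# ---------------------------------------------------------------------------
# network generators
# ---------------------------------------------------------------------------


def gen_network(seed: int, style: str = "cryptonets",
                input_shape: tuple[int, int] = (8, 8),
                N: int = 1024, depth_budget: int = 16,
                backend: str = "sim") -> dict:
    """Seeded runnable network configuration with inline weights.

    ``cryptonets`` builds the archetypal HE-friendly CNN — convolution,
    square activation, average pooling, two dense layers with a square
    activation between them.  ``minimal`` is one convolution plus one dense
    layer.  The same seed always yields identical weights.
    """
    rng = np.random.default_rng(seed)
    h, w = input_shape

    def u(*shape):
        return rng.uniform(-1.0, 1.0, size=shape).tolist()

    layers: list[dict]
    if style == "cryptonets":
        n_filters = 5
        fh = fw = 3
        hc, wc = h - fh + 1, w - fw + 1            # conv output (stride 1, no pad)
        hp, wp = hc // 2, wc // 2                  # after 2x2 pooling
        n_flat = n_filters * hp * wp
        hidden = 16
        n_out = 10
        layers = [
            {"type": "conv", "weights": u(n_filters, 1, fh, fw),
             "bias": u(n_filters), "stride": [1, 1], "padding": 0},
            {"type": "activation", "coeffs": [0, 0, 1]},
            {"type": "avgpool", "pool": [2, 2]},
            {"type": "dense", "weights": u(hidden, n_flat), "bias": u(hidden),
             "method": "matmat"},
            {"type": "activation", "coeffs": [0, 0, 1]},
            {"type": "dense", "weights": u(n_out, hidden), "bias": u(n_out),
             "method": "matmat"},
        ]
    elif style == "minimal":
        fh = fw = 3
        hc, wc = h - fh + 1, w - fw + 1
        layers = [
            {"type": "conv", "weights": u(1, 1, fh, fw), "bias": None,
             "stride": [1, 1], "padding": 0},
            {"type": "dense", "weights": u(4, hc * wc), "bias": u(4),
             "method": "diagonal"},
        ]
    else:
        raise ValueError(f"unknown network style {style!r}")

    return {
        "he": {"N": N, "depth_budget": depth_budget, "scale_bits": 40,
               "backend": backend},
        "input": {"h": h, "w": w, "channels": 1},
        "layers": layers,
    }


def write_network(config: dict, outdir: str) -> str:
    """Write a configuration to ``outdir`` with weights externalised to CSV
    files referenced as ``{"path": ..., "shape": ...}``; returns the path of
    the written ``network.json``."""
    os.makedirs(outdir, exist_ok=True)
    cfg = json.loads(json.dumps(config))  # deep copy, plain types
    for idx, layer in enumerate(cfg["layers"]):
        for key in ("weights", "bias"):
            val = layer.get(key)
            if val is None or not isinstance(val, list):
                continue
            arr = np.asarray(val, dtype=np.float64)
            fname = f"layer{idx}_{key}.csv"
            np.savetxt(os.path.join(outdir, fname), arr.reshape(1, -1),
                       delimiter=",")
            layer[key] = {"path": fname, "shape": list(arr.shape)}
    path = os.path.join(outdir, "network.json")
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2)
    return path
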