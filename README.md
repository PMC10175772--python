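# hesimd

Packed-SIMD linear algebra for leveled homomorphic encryption (LHE), aimed at
private convolutional-network inference — the setting where a client sends an
encrypted medical image to an untrusted server and receives encrypted logits
back, with the server learning nothing about the data.

LHE schemes with ciphertext packing expose one data type — a vector of `N`
slots inside a single ciphertext — and five SIMD operations on it:
elementwise sum ⊕, subtraction ⊖, multiplication ⊙, and cyclic rotation
≪ / ≫.  Running a CNN on packed ciphertexts is therefore a *data layout*
problem, and the costs that matter are unusual: the number of
multiplications `Omul` (each forcing a rescaling), rotations `Orot`, and
above all the multiplicative depth `DC` — the longest chain of consecutive
multiplications — which dictates the scheme parameters and the cost of every
single operation.

This package provides:

* the packed-vector runtime with an **exact simulator** backend and a
  **fixed-point CKKS-style** backend (scaled-integer encoding, rescaling and
  level accounting; a numerical model, not encryption), behind one contract
  with role-separated key handles;
* the **streamlined convolution block**: convolution with stride and
  padding, average pooling and polynomial activations chained at one
  multiplicative level per stage with a *single* result transformation at
  the end of the chain (`DC = l_conv + l_stride + l_pad + l_pool +
  l_act·DC_act + 1`);
* two **dense-layer schemes** — diagonal matrix–vector multiplication over
  spaced slots (capacity `max(α, n) ≤ N`, depth `2l+1`) and a replicated
  matrix–matrix product (capacity `max(hA·wA·wB, hB·wB·hA) ≤ N`, depth
  `2l`) — with the spacing/replication transformations that chain them;
* **rotation over multiple ciphertexts** for logical vectors longer than
  `N` (`Osum = 2r`, `Omul = r`, `Orot = r`, one level, for `r` parts);
* a **closed-form cost model** with capacity analysis (e.g. square
  matrix–matrix products cap at `m³ ≤ N`: 10×10 at N=1024, 25×25 at
  N=16384, 32×32 at N=32768) and an instrumented counter that measures the
  real ledger of any circuit, scope by scope;
* a **network pipeline + CLI** that plans, validates and runs whole
  networks under the client/server key split.

## Worked example

Generate a seeded Cryptonets-style network (8×8 input, 5 conv filters 3×3,
square activation, 2×2 average pooling, dense 16, square activation,
dense 10) and plan it:

```
$ hesimd fixtures --seed 3 --outdir demo
$ hesimd plan --config demo/network.json
step          dc    osum    omul    orot    omem
conv           1      50      45      45       3
activation     1       0       5       0       3
avgpool        1      20      20      20       3
flatten        1      49      45      50       3
dense          2      78      17      77       4
activation     1       0       1       0       3
dense          2      37      11      36       4
total          9     234     144     228       4
depth budget: 16  (used 9)  N = 1024
```

Reading the table: the convolution costs `5 filters × 9 taps = 45`
multiplications and rotations but only one level; the single `flatten` step
is the one result transformation the whole convolutional chain needs
(`45 = 5 × 9` mask-rotate-add triples plus the channel concatenation); the
dense layers use the replicated scheme with cleartext weights, so each costs
`hA` rotations to tile the input, one ciphertext product, and `hA`
mask-rotate-adds to extract the result — depth 2.  The whole network needs
depth 9, so a modulus chain of 10 primes suffices.

Run inference (exact simulator):

```
$ hesimd infer --config demo/network.json --input demo/input.csv --seed 1
logits: -12.738199 +10.042248 -7.323074 -112.508347 -42.547123 +6.333231 -94.906580 +30.215272 +3.438915 +43.404069
```

These ten numbers are the dense-10 outputs of the synthetic network on the
seeded input; on the simulator they equal the plaintext reference network's
outputs exactly, and the per-layer measured ledgers (written with
`--out`) equal the planned ones field by field.  Passing
`--backend fixed --N 8192` reruns the same network on the fixed-point
leveled model; logits then agree with the simulator to ~1e-10, far inside
the 1e-3 tolerance that matters at scale 2^40.

The same functionality is available as a library:

```python
import numpy as np
from hesimd import (HEParams, keygen, encode_encrypt, decrypt_decode,
                    ConvSpec, Filter, SCBFLayout, streamlined_convolution,
                    rt_scbf_to_rc, counter_scope)

params = HEParams(N=1024)
keys = keygen(params, seed=0)
image = np.random.default_rng(0).uniform(-1, 1, (8, 8))
ct = encode_encrypt(image.reshape(-1), params, keys)
with counter_scope() as scope:
    res = streamlined_convolution(ct, ConvSpec(Filter(np.full((3, 3), 1/9))),
                                  SCBFLayout.first_layer(8, 8))
    rc = rt_scbf_to_rc(res.vector, res.layout)
print(decrypt_decode(rc, keys, res.hout * res.wout))  # 36 window means
print(scope.report.as_dict())  # {'dc': 2, 'osum': 45, 'omul': 45, 'orot': 45, 'omem': 3}
```

## Layout of the package

| module | contents |
|---|---|
| `hesimd.backend` | packed vectors, both backends, SIMD primitives, multi-ciphertext rotation, polynomial evaluation, cost instrumentation |
| `hesimd.layouts` | row-column flattening, backward-convolution-format indexing, spaced vectors, replication shapes |
| `hesimd.conv` | streamlined convolution, padding, average pooling, result transformation |
| `hesimd.dense` | diagonal and replicated dense schemes with their layout transforms |
| `hesimd.costs` | closed-form ledgers, depth formulas, capacity solvers, scheme recommendation |
| `hesimd.network` | network planning, client/server execution, inference |
| `hesimd.fixtures` | seeded generators and brute-force oracles |
| `hesimd.cli` | `hesimd plan / infer / keygen / fixtures / selftest` |

See `docs/methods.md` for the model, the layout algebra, the counting
conventions and the known limitations.
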