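# Methods

## Setting

Leveled homomorphic encryption (LHE) schemes over rings of the form
`Z_Q[x]/<x^N + 1>` support *ciphertext packing*: one ciphertext carries a
vector of `N` numeric slots, and a single homomorphic operation acts on all
slots at once (SIMD).  The available primitives are elementwise sum (⊕),
subtraction (⊖), multiplication (⊙) and cyclic rotation (≪ / ≫) of the slot
vector.  Running a convolutional neural network privately therefore becomes a
data-layout problem: each layer's linear algebra must be expressed as a short
sequence of these five primitives, and the *output layout* of one layer must
be a valid *input layout* for the next.  The cost drivers are the number of
multiplications (each followed by a rescaling in a leveled scheme), the
number of rotations (each needing Galois key material), and above all the
*multiplicative depth* `DC` — the longest chain of consecutive
multiplications — which dictates the size of the modulus chain and hence of
every ciphertext operation.

This package implements that layout algebra: the primitives with exact cost
instrumentation, the streamlined convolution block, two dense-layer schemes,
the transformations that chain them, a closed-form cost model, and a network
pipeline with a client/server key split.

## Backends

Two backends satisfy one contract (`PackedVector` with the five primitives,
level accounting, and key-role checks):

* **`sim`** — an exact `float64` slot simulator.  It is the ground truth for
  every oracle test: any disagreement between a packed routine and its
  brute-force reference is a logic error, not numerical noise.
* **`fixed`** — a fixed-point model of CKKS-style approximate arithmetic.
  Values are encoded as integers at scale `2**scale_bits` (default 40);
  every multiplication is followed by a rounding division by the scale
  (rescaling) and consumes one level of a modulus chain sized
  `depth_budget + 1`.  Keeping the encoding scale equal to the intermediate
  chain primes makes the scale level-invariant, which is the usual CKKS
  configuration.  This backend reproduces the *numerics* of approximate HE —
  quantisation on encode (error ~2^-41 per value), rounding per product,
  level exhaustion as a hard error — but performs no encryption and provides
  no confidentiality.  Key handles are role-tagged (public/secret, with a
  key identity check on decryption) so that the client/server protocol shape
  is enforced structurally even though no cryptography is present.

Both backends refuse a multiplication past `depth_budget` with an error that
names the offending operation.

## Layouts

* **RC** (row-column): the matrix flattened row-major into the slot prefix.
* **SCBF** (streamlined backward convolution format): after a chain of
  strided convolutions with stride products `(Sx, Sy)` on an initial
  `(h0, w0)` grid, logical entry `(i, j)` lives at slot `i*w0*Sx + j*Sy`.
  The first layer is the special case `Sx = Sy = 1`, i.e. RC.
  Slots outside this index set may hold garbage between stages; only the
  result transformation guarantees clean zeros.
* **Spaced**: logical entry `i` at slot `i*delta` with `delta` a power of
  two.  When the lattice fills the vector (`alpha * delta = N`) a rotation
  by `k*delta` rotates the *logical* entries cyclically — the property the
  diagonal dense scheme builds on.

## The streamlined convolution block

For each filter tap `(i, j)` the packed input is rotated by the tap's SCBF
offset `i*w0*Sx + j*Sy`, multiplied by the plaintext tap weight, and
accumulated: `fx*fy` rotations, multiplications and additions, one level.
The operation is cross-correlation (no filter flip), the deep-learning
convention.  A strided convolution writes its outputs at slots
`u*w0*(Sx*sx) + v*(Sy*sy)` — the stride is *absorbed into the metadata*
instead of being paid in data movement, so convolution, average pooling
(a uniform `1/(px*py)` filter at stride `(px, py)`) and slotwise polynomial
activations chain freely at one level each.  A chain of `c` stages plus the
final transformation measures depth `c + 1`, and in general

    DC = l_conv + l_stride + l_pad + l_pool + l_act * DC_act + 1.

**Padding** is one right rotation by `p*(w0*Sx + Sy)` — the offset of logical
cell `(p, p)` — plus one multiplication by an inverted border mask.  The form
`p*(w0*Sx + Sy)` is the only one consistent with the SCBF index map when
`Sx != Sy` (it reduces to `(w0+1)*Sx*p` when `Sx = Sy`).  Padding needs
column slack: `wpad*Sy <= w0*Sx`.  Mid-chain this slack exists because
strides multiply `Sx`; at the *first* layer it does not, so the pipeline pads
the first layer on the client's plaintext by default (the client touches the
cleartext anyway), or — under the `server_padding` flag — encodes the input
on the enlarged `(h+2p, w+2p)` grid so the streamlined padding applies.

**Result transformation (SCBF→RC)**: per output element, one single-slot
mask, one left rotation by the element's displacement `t - (i*wout + j)`,
one accumulation; `hout*wout` of each, one level.  The target index uses
`wout` (row-major RC).

**Multi-ciphertext lift.**  A logical vector longer than `N` is held as
`r = ceil(n/N)` ciphertexts.  Rotation then decomposes into a block offset
`floor(k/N)` and an intra-ciphertext amount `k mod N`: each part is rotated
once, split by a plaintext mask into in-block and overflow components (the
overflow recovered by subtraction), and recombined — `Osum = 2r`,
`Omul = r`, `Orot = r`, one level, working set `2r`.  It requires
`n = r*N`; partially filled final parts are zero-padded at encode time.
Convolution, padding and the result transformation operate on such vectors
transparently, with this rotation standing in for the plain one.

## Dense layers

**Diagonal scheme.**  The weight matrix `W (h x w)` is zero-extended to
power-of-two dimensions `(hext, wext)`; `alpha = max(hext, wext)` and
`delta = N/alpha`.  The input vector is re-spaced to `delta`
(`switch_spacing`: one mask+rotation+add per logical entry, one level) and
the product accumulates the `alpha` generalized diagonals
`d_i[j] = Wext[j, (i+j) mod wext]`, each encoded as a plaintext vector *with
the same spacing* so that rotating the input by `i*delta` lines entries up
with their column — the only encoding compatible with the spaced lattice,
with wrap-around at `alpha` logical entries doing the work for the final
columns.  Capacity: `max(alpha, n) <= N`.  `switch_spacing` doubles as the
result transformation of one dense layer and the initial representation of
the next, so an `l`-layer diagonal block costs depth `2l + 1` including the
final return to unit spacing.

Because the diagonals accumulate columns in rotated order, results agree
with a reference dot product to reassociation precision (~1e-15), not bit
for bit; all other routines preserve the reference summation order and are
bit-exact on the simulator.

**Replicated (matrix-matrix) scheme.**  `RC(A)` with every entry repeated
`wB` times, against `RC(B)` tiled `hA` times: one elementwise product, then
`wA` rotate-accumulate steps put `C[i, :]` at slot `i*wA*wB`; the extraction
masks each block and rotates it down by `i*wB*(wA-1)` to rebuild `RC(C)`.
The printed extraction in the source material does not reconstruct RC for
`wA > 2` under any literal reading; the amounts here are derived from the
verified blocked layout.  Capacity: `max(hA*wA*wB, hB*wB*hA) <= N` —
replication is the scheme's Achilles heel (square matrices cap at
`m^3 <= N`: 10 at N=1024, 25 at 16384, 32 at 32768; a reducing dense layer
caps at `sqrt(N)` inputs).  For inference the weights are cleartext, so the
expensive left-operand replication is done plaintext-side at zero ciphertext
cost and only the cheap `prepare_matrix_b` (rotations and additions, no
multiplication, no depth) runs on the ciphertext; the ciphertext-side
`prepare_matrix_a` remains implemented and tested.  An `l`-layer replicated
block costs depth `2l`, which is why the recommendation helper picks it for
single-dense-layer networks within capacity and the diagonal scheme
otherwise.

## Cost model and instrumentation

Every routine's ledger `(DC, Osum, Omul, Orot, Omem)` is a closed form of
its dimensions, held in `costs.py` in two regimes (single- and
multi-ciphertext, `r = ceil(required/N)`).  `counter_scope()` measures the
real thing: every primitive reports into all open scopes (nesting composes
additively); depth is tracked per ciphertext *lineage*, so `d` sequential
squarings measure `DC = d` while parallel products on disjoint vectors
measure `DC = 1`.  `Omem` is measured as the peak number of packed vectors
allocated *inside* the scope that are simultaneously alive — the algorithm's
own working set, excluding inputs owned by the caller — and the
implementations reuse buffers so the measured working set never exceeds the
predicted one.  The test suite asserts measured = predicted field by field
(with Omem as an upper bound) across seeded dimension sweeps.

Deliberate counting conventions, chosen so measured ledgers equal the
printed closed forms: zero-amount rotations and multiplications by trivial
all-ones masks are executed and counted (an optimisation pass could elide
them; none is applied by default), and every plaintext-mask multiplication
consumes one level.  Baseline (non-streamlined) convolution-family routines
are carried as evaluable formulas only, for predicted-ledger comparisons;
they have no executable counterpart here.

Two capacity expressions differ between the carried table and the geometry:
`switch_spacing`'s tabulated `n*(Δf - Δi + 1) <= N` versus the geometric
`n*max(Δi, Δf) <= N`.  The runtime enforces the geometric form; the cost
table reports the tabulated one.  The reducing-dense capacity at `N = 32768`
is `isqrt(32768) = 181` exactly.

## Polynomial activations

Activations are assumed already approximated by a polynomial; evaluation is
layout-free (slotwise).  Powers are built by balanced repeated
multiplication (`x^d` costs `ceil(log2 d)` levels) and each power is scaled
by its coefficient unless the coefficient is exactly 1 — so the bare square
activation costs a single level.  In the dense stage, an activation with a
nonzero constant term fills the unused slots with that constant; the
pipeline restores the zeros with one extra mask multiplication, since the
tiling replication relies on a clean tail.

## Pipeline and protocol

`build_plan` walks the layer list, inserts the implicit transformations
(one flatten = per-channel result transformation + rotate-concat before the
first dense layer; spacing or replication representations around dense
layers; a final return to unit spacing), checks every capacity constraint
and the total depth against the budget *before* anything is encrypted, and
emits the predicted ledger.  Execution mirrors the outsourcing protocol:
the client generates keys, encodes (and in role terms encrypts) each input
channel, and decrypts the result; `execute_plan` receives public-only key
handles and cannot decrypt even by mistake.  Multi-filter convolutions use
one packed vector per channel — the simplest layout consistent with the
chaining rules; packing channels into shared ciphertexts is a possible
optimisation, not implemented.

## Synthetic data and what the tests show

The fixture generator draws inputs, filters and weights uniformly from
[-1, 1] (keeping fixed-point comparisons meaningful at scale 2^40) with
seeded, reproducible randomness.  The Cryptonets-style configuration —
8x8 input, 5 filters of 3x3, square activation, 2x2 average pooling, dense
16, square activation, dense 10 — is the archetypal HE-friendly topology at
desk scale; the independent reference implementation (`fixtures.oracle_*`)
is plain nested loops sharing no code with the packed path.  Problem sizes
throughout (N up to 8192, matrices up to ~20x20, 50-case sweeps) were chosen
as the smallest sizes that exercise every regime — strides, padding,
wrap-around, both dense schemes, the multi-ciphertext lift.

What passing tests show: layout correctness, exact ledger/depth accounting,
and the numerical behaviour of fixed-point rescaling.  What they do not
show: real wall-clock performance of ring arithmetic, noise growth of an
actual RLWE scheme, security of any kind (the `fixed` backend is a
numerical model, not encryption), or accuracy on trained models and real
medical images — the synthetic weights are not a trained classifier.

## Known limitations

* The dense stage requires the convolutional stage to come first; arbitrary
  interleavings (dense → conv) are not planned.
* The replicated scheme raises an eager capacity error rather than falling
  back to multi-ciphertext execution (its replication factors explode; the
  diagonal scheme is the intended escape hatch).
* The result transformation requires its RC output to fit one ciphertext.
* Max pooling is out of scope (non-polynomial); average pooling is the
  supported reduction.
* Encryption-side randomness is absent by construction in both backends;
  determinism is a feature for testing, not a security property.
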