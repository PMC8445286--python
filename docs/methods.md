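# Methods

This note documents the models, protocols and numerical choices behind
`mpclasso`, the assumptions under which its security statements hold, and
what the synthetic-data tests do and do not demonstrate.

## Setting and threat model

Three parties: two *data parties* (called `AC` and `EMC` throughout the
code, after the insurer/hospital use-case the package is modelled on) and an
input-less *helper* (`HELPER`). Each data party holds an identifier column
plus numeric/Boolean feature columns for its own set of individuals; one
column of the second party is the regression target. Features are assumed
pre-scaled to [0, 1] — secure pre-processing is out of scope.

All parties are assumed **semi-honest** (they follow the protocol but try to
infer extra information from what they see) and **non-colluding**, and
channels are assumed secure. The package's TCP transport is plaintext over
localhost and exists only for desk-scale integration testing; it is not a
deployment transport. Under these assumptions, a full run reveals exactly:
the intersection cardinality `k` (to everyone, including the helper), the
aggregate `max(XᵀX)` behind the initial step size, the per-iteration
stopping sums `‖Δw‖²` and `‖w‖²`, the final coefficients, and the two sums
behind `R²`. Every such opening is recorded in an append-only reveal ledger
whose labels are checked against this whitelist by `audit_transcript`;
everything else on the wire is keyed digests, ciphertexts under keys the
receiver does not hold, secret shares, or statistically masked openings.

## Secure inner join

Building blocks: SHA-256 keyed by a 128-bit string jointly coin-tossed by
the data parties (XOR of two locally drawn strings — adequate without
commitments in the semi-honest model); textbook Paillier encryption
(`n = pq`, `g = n+1`, decryption via the Carmichael function), implemented
in-package with 2048-bit default keys and a 512-bit fast test mode; and
2-out-of-2 additive sharing modulo the MPC field prime `p`.

Protocol outline: each data party secretly permutes its rows, uploads keyed
digests and own-key ciphertexts of its fixed-point-encoded features to the
helper; the helper pairs equal digests (duplicates within one upload abort
the run), announces `k`, and receives from each party `k` fresh uniform
masks per *other-party* column, encrypted under the other party's key. The
mask for value `α` is encrypted as `p − z`, so the helper only ever
homomorphically **adds**: it forms `[α + p − z]` and routes it to the column
owner, who decrypts and reduces mod `p`. The final holdings are
`AC: (α − z, s)` and `EMC: (z, β − s)` — each party's table column-aligned
and row-aligned by the helper's join order. Because the Paillier plaintext
modulus (≥ 2⁵¹¹) vastly exceeds `2p`, no wrap-around occurs before the
mod-`p` reduction, and each revealed difference is uniform on the field
(the mask is a one-time pad mod `p`).

What the helper learns: `k`, upload sizes, and digest equality under a key
it does not know. What each data party learns: `k` and its own blinded
values. Multi-feature tables and `k > 1` are handled by per-column, per-row
repetition of the masking, with the helper linking all columns of a matched
pair through its join order.

## Shamir engine

(1,3)-Shamir sharing over the prime field `Z_p` with `p` the largest
192-bit prime; party evaluation points are fixed at 1, 2, 3 and Lagrange
constants (3, −3, 1) precomputed. Any single share is uniform regardless of
the secret; any two reconstruct, and reconstruction from three mutually
inconsistent shares raises the ⊥ error. Multiplication follows the standard
reshare-and-interpolate round (local products give a degree-2 sharing that
is immediately re-randomized back to degree 1); inner products and
matrix-vector products reshare once per output element regardless of vector
length. Casting from the join's 2-of-2 sharing is purely linear: each data
party Shamir-shares its additive share and all parties locally add.

**Fixed point.** Reals carry `f = 40` fractional bits inside a signed
embedding of `(−p/2, p/2]`; `k_int = 16` integer bits bound encodable
magnitudes, and `σ = 40` is the statistical masking parameter. The field
size invariant `p > 2^{2(k_int+f)+σ+2}` guarantees that degree-2 products
plus masks never wrap. Products accumulate fractional bits (the gradient
path reaches `3f` before renormalization) and are brought back by
**probabilistic truncation**: a masked shifted value is opened *to the data
parties only* (the helper supplies none of the mask bits it would need to
undo it, and conversely never sees the opening), and the result equals the
exact floor-division plus a carry bit — at most one unit in the last place,
i.e. `2⁻⁴⁰`, per truncation. Exact multiples truncate exactly.

**Comparison.** `(x < 0)` on shares opens `x + 2^m + r` to the data parties,
where `m` bounds `log₂|x|` and `r` is built from `m` jointly random shared
bits (XOR of three per-party bits) plus a `σ`-bit shared high part; the
borrow of the low bits is resolved with a bitwise less-than circuit between
the opened value's bits (re-shared by a data party) and the shared mask
bits, costing about `5m` multiplications. Strict comparisons against public
thresholds and the tournament `max(a,b) = b + (a > b)(a − b)` reduce to this
primitive. These realizations are standard semi-honest constructions chosen
for simplicity; any 1-private three-party comparison/truncation could be
substituted behind the same contracts. The masked openings are excluded
from the reveal ledger because they are statistically independent of the
data (that is their defining property); the audit treats them as a distinct
payload class.

**Shared randomness caveat.** The high masking parts are sums of three
per-party uniform draws rather than exactly uniform; this only smudges a
statistically hidden quantity further and never enters an opened low part,
for which exactly-uniform shared bits are used.

## Lasso by proximal gradient descent

Objective `F(w) = (1/n)‖Xw − y‖² + λ‖w‖₁`, iteration
`w ← Proxy(w − η_t (2/n) Xᵀ(Xw − y), τ)` from `w₀ = 0`. Choices the
underlying description left open, and how this package resolves them:

- **Threshold `τ`.** The literal specification soft-thresholds by `λ`
  itself; canonical ISTA uses `η_t·λ`. Both are implemented
  (`ista_scaling` flag, default off = literal). Note that the literal rule
  with a data-driven `η₀ ≈ 10⁻³` and moderate `λ` can freeze the iteration
  at `w = 0` (every update is smaller than the threshold); this is a
  property of the rule, reproduced identically by both trainers, and kept
  under test. The ISTA-scaled variant is what the fidelity benchmarks use
  because it exercises non-trivial dynamics.
- **Step schedule.** `η_t = η₀/(1+t)` ("harmonic", default — the step must
  decrease every iteration and this schedule is always convergent) or
  constant `η₀` (the textbook ISTA choice; with `η₀ ≤ 1/L`,
  `L = (2/n)σ_max(X)²`, the objective is monotone and the iterates converge
  to the Lasso optimum — used by the parameter-recovery and
  solver-comparison tests).
- **`η₀` rule.** `0.1/max(XᵀX)` with the maximum over *all* entries of the
  Gram matrix, as literally stated. Securely: shared Gram, secure tournament
  maximum, then the single aggregate is revealed and divided publicly —
  one explicitly ledgered leak that avoids secure division.
- **Stopping.** `‖w_new − w_old‖²/‖w_old‖² < tolerance`; with `w₀ = 0` the
  first ratio is 0/0, treated as +∞ so training never stops before moving.
  Securely, numerator and denominator are revealed each iteration and the
  division and comparison are public.
- **`R²`.** Implemented with *squared* residual sums (the standard
  definition); the source description prints the formula without the
  squares, which cannot equal the coefficient of determination it names.
  Securely, `y_pred = Xw` for already-public `w` is a local linear
  combination; only the residual and total sums are revealed. The revealed
  residual sum equals `‖Xw − y‖²`, from which the final objective follows
  publicly — the secure trainer therefore reports its objective only after
  the goodness-of-fit step, avoiding any extra reveal.
- **Intercept.** Optional unpenalized all-ones column excluded from the
  soft threshold; off by default.
- **Divergence guard** (plaintext trainer): abort if the objective exceeds
  10⁶ × its initial value. The secure trainer cannot evaluate the objective
  per iteration without extra reveals and so has no such guard.

Operating-point defaults follow the use-case the package is modelled on:
`λ = 0.001`, `tolerance = 10⁻⁴`.

**Fidelity.** With `f = 40`, per-operation rounding is ~`10⁻¹²`; over tens
of iterations the secure and plaintext trainers agree on every revealed
stopping statistic, stop at the same iteration, and the final objectives
agree to ~`10⁻¹¹` on the 100 × 10 benchmark — well inside the `10⁻⁷`
acceptance bound. Two caveats are inherent: a coefficient landing within
~`2⁻⁴⁰` of a comparison threshold could branch differently in the two
trainers, and a stopping ratio landing within ~`10⁻¹¹` of the tolerance
could shift the stop by one iteration; both are measure-zero events on
generic data.

## Synthetic data

`generate_regression(n, m, noise_sd, sparsity, seed)` draws `X` uniformly on
[0, 1), a Gaussian weight vector with exactly `round(sparsity·m)` zeros, and
`y = Xw + N(0, noise_sd²)`; by default every column including the target is
then min-max scaled to [0, 1], the range the pipeline assumes (`scale=False`
keeps the exact linear relation for recovery oracles).
`vertical_split(full, m_A, overlap, seed)` gives party A the first `m_A`
features and party B the rest plus the target, keeps
`n − ⌈(1−overlap)·n⌉` genuine records at both parties and pads each party
back to `n` rows with filler records whose identifiers are fresh and whose
feature values are bootstrap-resampled from the party's own columns — so
overlap membership is not readable from marginal distributions. Identifiers
are zero-padded 7-digit strings. The default study conditions used by the
acceptance script are `n = 100`, `m = 10`, `noise_sd = 0.01`,
`sparsity = 0.5`, `overlap = 0.8`, with 512-bit test-mode HE keys (the
protocol is key-size agnostic; 2048 bits is the production default).

What these tests do **not** show: behaviour under real-world identifier
noise (typos, format drift — matching is exact-bytes by design), non-linear
signal, unscaled or heavy-tailed features, network latency/failure, or
malicious parties. Wall-clock performance of the in-process simulation says
nothing about a geographically distributed deployment.

## Problem sizes and determinism

The bundled benchmarks run the full secure pipeline at 100 records × 10
features (about 15 s in-process) and the join oracle comparison over 50
random 10-record instances; these sizes were chosen to exercise every
protocol path with comfortably fast test runs, and all results scale with
the published linear communication/computation costs. Every source of
randomness — data generation, key generation, masks, permutations,
resharing polynomials — derives from explicit seeds in deterministic test
mode; without a seed, protocol randomness comes from the OS CSPRNG and the
deterministic mode is flagged insecure.

## Known limitations

- Semi-honest, non-colluding, exactly-three-party model; no fuzzy record
  linkage; `k` is revealed by design.
- Probabilistic truncation adds a one-ulp bias (the carry is always
  non-negative); with `f = 40` this is far below any quantity of interest.
- Secure MSE/MAE, secure pre-processing, λ-path search and more than two
  data parties are out of scope.
- The comparison sub-protocol's cost (~5·57 multiplications per bit vector
  element) dominates training time; batching across coefficients and
  iterations keeps this tractable at desk scale.
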