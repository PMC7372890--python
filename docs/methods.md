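# Methods

This note documents the models and numerical decisions behind `hegwas`:
what is computed, under which assumptions, with which defaults, and what
the synthetic validation does and does not establish.

## 1. The encryption scheme

`hegwas.ckks` implements a leveled approximate HE scheme over the
power-of-two cyclotomic ring R = Z[X]/(Xᴺ+1) with two-power moduli
q_ℓ = 2^ℓ. A message vector of K ≤ N/2 reals (K a power of two) is mapped
through the inverse canonical embedding, scaled by 2^p and rounded; short
vectors are replicated to fill all N/2 slots, so every ciphertext of a
K-vector is simultaneously a ciphertext of its periodic extension — the
packing tricks below lean on this heavily. Slots are indexed by the roots
ζ^(5^j), making the Galois map X → X^(5^r) a cyclic slot shift; rotations
are key-switched back to the original secret with keys modulo q_L².
Multiplication is relinearized with an evaluation key and followed
immediately by rescaling, which divides by the consumed scale and drops
the same number of modulus bits.

**Parameters.** A profile is (log N, L, p, h, σ). Two production-scale
profiles with ring dimension 2^17 and L = 1300/1700, p = 50 bits are
recorded as named configurations (`exp1`, `exp2`); they are configuration
records only — the pure-Python engine is meant for correctness work at
toy profiles (ring 2^9–2^13), where all homomorphic semantics are
identical. Correctness is parameter-independent; performance and formal
security are out of scope. The error and encryption distributions are
discrete Gaussians with σ = 3.2 by default (the standard choice); the
secret is ternary with Hamming weight h.

**Arithmetic.** Coefficients are stored as little-endian base-2^12 limb
matrices. Negacyclic products are computed exactly by a twisted FFT over
the limb matrix: with 12-bit limbs every convolution value stays well
below the float64 integer threshold, and a runtime integrality check
(max deviation from the nearest integer, hard error above 0.25) guards
every product. The engine is validated coefficient-exactly against a
schoolbook big-integer convolution in the tests. Key-switching products
use one fixed transform length per key so key spectra are computed once
and cached.

**Decryption contract.** Decrypting with the wrong key yields garbage
without detection; messages must stay below 2^62 at their scale for the
centered-lift fast path (assured by the pipeline's magnitudes).

## 2. Matrices in ciphertexts

An n×m matrix is zero-padded to powers of two and packed column-major:
slot j·n̄ + i holds entry (i, j); wide matrices split columns across
blocks. On this layout (`hegwas.packing`):

* column rotation = slot rotation by n̄·j; row rotation = two slot
  rotations glued with complementary 0/1 masks. Masks are public encoded
  plaintexts at a reduced scale (default 24 bits; configurable to
  encrypted masks), costing their scale in depth when applied.
* AᵀB (optionally AᵀDB with one extra Hadamard) uses the generalized
  diagonals of A: Expdiag_t(A) broadcasts (a_{i,(i−t) mod k}) to every
  column; summing ρ_t(Expdiag_t(A) ⊙ B) over t and then the full cycle of
  stride-k row sums leaves AᵀB replicated in every k-row band. Row
  reductions use plain power-of-two rotations with a single cleanup mask
  (windowed sums are valid exactly on the rows the mask keeps).
* Sᵀx is computed by one Hadamard and log n̄ rotations, yielding a
  **row-replicated** ciphertext (every row equals Sᵀx). Such outputs no
  longer satisfy the column-major invariants; they carry a flag and every
  column-major operation rejects them rather than computing silently
  wrong results. The same reduction yields diag(AᵀDC), and
  diag(AᵀBA) = Σ_t diag(Aᵀ B_t ρ_t(A)) after decomposing the small
  symmetric B into the cyclic diagonals (b_{i,(i+t) mod k}).
* The k×k adjugate is evaluated from the (k−1)² row/column-rotated copies
  C_{a,b} of U's ciphertext: the cyclic minor of every entry is the same
  polynomial in the copies' entries. A subtlety: the cyclically ordered
  minor equals the true minor times the parity of a (k−1)-element
  rotation, so the checkerboard sign mask [(−1)^(i+j)] is applied exactly
  when k is even; for odd k the parities supply the signs. Cofactor
  polynomials are generated by exact permutation expansion for k ≤ 5,
  with the k = 4 polynomial additionally written out explicitly. The
  implementation returns the cofactor matrix, which equals the adjugate
  for the symmetric U the pipeline produces (and for all test inputs).
  The determinant is the masked first-column product of U with its
  cofactors, summed and broadcast by a full rotation cycle.

Every operation is tested against a brute-force plaintext linear-algebra
oracle on random small instances.

## 3. HE-friendly statistics

Plaintext reference semantics live in `hegwas.approx`; the encrypted
pipeline must (and is tested to) agree with them up to encryption noise.

**Sigmoid.** The degree-7 continuous least-squares fit of σ on [−8, 8] in
t = x/8 has coefficients (0.5, 1.735, −4.194, 5.434, −2.507) and maximal
error ≈ 0.032; `fit_sigmoid_lsq` re-derives them by Legendre projection
with adaptive quadrature. The polynomial diverges outside [−8, 8] and is
deliberately not clamped: keeping fitted logits inside the interval is a
modelling responsibility (see §6). Homomorphic evaluation uses the
odd-polynomial factorization g = 0.5 + t(c₁+c₃t²) + t⁴·t(c₅+c₇t²):
three ciphertext multiplications deep; the division by 8 is free because
power-of-two scalar multiples are pure scale bookkeeping.

**Modified Fisher scoring.** β ← β + α·adj(U)Xᵀ(y − p) is Newton's method
scaled by γ = α·det(U). Defaults: β⁰ = 0, α = 8, 4 iterations. Because
β⁰ = 0 implies p = ½ and W = I/4 exactly, the first encrypted iteration
skips the sigmoid and uses U = XᵀX/4 — an algebraic identity, not an
approximation (toggle `first_iter_shortcut`). After the final update the
analysis quantities (p, W, U, adj U, det U) are recomputed at the
returned coefficients.

**Standardization (γ calibration).** For γ ≈ 1 the update converges
quadratically and the Fisher-score residual Xᵀ(y − p) reaches ~10⁻¹²
within 4 iterations, which is what makes the dropped projection term
SᵀWX U⁻¹Xᵀ(y − p) negligible. `standardize_design` z-scores the
covariates and then scales the whole design (intercept included) by the
constant solving α·det(s²·ZᵀWZ) = 1 at the converged IRLS weights — a
cheap plaintext calibration the data owner runs before encrypting.
Uniform design scaling is an exact reparameterization: p, z² and p-values
are invariant. Calibrating at the starting weights W = I/4 instead
(the fallback when no phenotype is passed) leaves γ ≈ 0.8 and a linear
convergence tail. A guard aborts with a pointer to α if β diverges.

**Association stage.** c = Sᵀ(y − p), V = XᵀWS,
d = det(U)·diag(SᵀWS) − diag(Vᵀ·adj(U)·V), z² = det(U)·c²/d, p-values
from the χ²(1) upper tail (done in clear on the decrypted statistics, as
squared statistics carry exactly the information of p-values). SNPs with
d ≤ 0 (monomorphic or covariate-collinear) are flagged with missing
p-values, never dropped or crashed on.

**Goldschmidt division** (`exp2` mode): with the public bound
B = 2^b ≥ d, the normalized n = 2d/B ∈ (0, 2) gives
1/n = Π_{i<iters}(1 + e^(2^i)), e = 1 − n, with relative error
|e|^(2^iters). Defaults: 8 iterations; b from the closed form
d ≤ n_samples/(4α), which is public because calibration pins
det(U) ≈ 1/α. Normalization by B is free (power of two). α itself must
be a power of two in the encrypted path for the same reason — the default
8 is; other values would cost one scalar multiplication level.

## 4. Depth planning

The pipeline code is written against an evaluator interface with two
backends: the real scheme, and a meter carrying only (level, scale)
bookkeeping. `plan_depth` runs the meter through the identical code path
and reports per-stage modulus consumption, the exact rotation-shift set,
and operation counts; `keygen_for` sizes L as plan + working scale +
margin (default 40 bits) and generates precisely the needed rotation
keys. A test asserts the meter's artifact depths equal the real run's
level ledger. Typical totals at p = 30–34 bits: ~1.2k modulus bits for
two Fisher iterations in `exp1`, ~1.7k with homomorphic division.

## 5. Synthetic data

`hegwas.simulate` emulates the randomized scalability study the method
was profiled on: covariates uniform on [150, 200] × [40, 100] × [20, 80]
(height/weight/age-like), SNPs uniform binary (or Binomial(2, maf) for
additive coding), and a logistic phenotype
y ~ Bernoulli(σ(b₀ + Z₀γ + Sδ)) with γ applied to internally z-scored
covariates and δ nonzero at planted columns. The phenotype mechanism is a
modelling choice (the generating model equals the analysis model) so that
parameter recovery and ranking tests are well-posed. The default
benchmark is n = 245, k = 4, m = 2000, 20 planted effects of |δ| ∈
[0.5, 1.5] with alternating signs, fixed seed — sized for seconds-scale
plaintext runs, with the encrypted toy runs at n = 32.

What passing tests show: algorithmic agreement (modified vs original,
encrypted vs plaintext) and calibration under a correctly specified
logistic model with independent SNPs. What they do not show: behaviour
under linkage disequilibrium, population stratification,
Hardy–Weinberg departures, case-control ascertainment or model
misspecification — none of which the generator models.

## 6. Numerical choices and limitations

* **Working scale** p = 30–38 bits at toy ring sizes keeps per-operation
  relative noise near 10⁻⁵–10⁻⁶; the end-to-end encrypted toy runs agree
  with plaintext to ~10⁻³ relative on z², comfortably inside the 10⁻²
  target, and degrade smoothly as p shrinks.
* **Sigmoid domain.** Fitted logits must stay within [−8, 8] throughout
  the iteration trajectory. Small samples with many covariates (n ≲ 20
  at k = 4) can be near-separated, pushing logits outside and making the
  polynomial diverge — the guard raises rather than returning nonsense.
  This is a limitation of the polynomial surrogate itself.
* **Ties/degeneracies.** Constant covariates are rejected at
  standardization; monomorphic SNPs are flagged downstream. Mode `exp1`
  flags d ≤ 0 after decryption; mode `exp2` can only flag non-finite or
  negative decrypted statistics, since d itself is never decrypted.
* **What `exp1` leaks.** The numerator/denominator pairs carry more
  information than p-values; the trade-off against the extra depth and
  time of `exp2` is the caller's, mirrored by the `mode` switch.
* **Security.** Toy profiles are for correctness only and offer no
  meaningful cryptographic security; the recorded 2^17-dimension
  profiles are the production-scale reference points, and no security
  estimation is performed here (out of scope).
* **Performance.** The engine is vectorized Python; the full-size runs
  behind the recorded profiles are far outside its envelope. The
  end-to-end encrypted validation uses n = 32, m = 64 at ring 2^13 with
  two Fisher iterations, chosen to exercise every pipeline stage at the
  criterion's ring size while keeping the suite's runtime reasonable.
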