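"""Exact arithmetic in the power-of-two cyclotomic ring R_q = Z[X]/(X^N + 1, q).

All moduli in the scheme are powers of two, q = 2^l, with l up to a few
thousand bits, far beyond machine precision.  Elements are therefore stored
as little-endian limb matrices: an ``(N, D)`` int64 array of base-``2^LIMB_BITS``
digits, one row per polynomial coefficient, canonically reduced to
``[0, 2^l)``.  Negacyclic multiplication is carried out exactly by a
twisted complex FFT over the limb matrix; the limb base is chosen small
enough that every convolution value is an integer representable in a double
with slack, and an integrality check (largest deviation from the nearest
integer) guards every product at run time.

The naive O(N^2) big-integer convolution used to validate this engine lives
in :func:`negacyclic_convolve_naive`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.fft as _fft

LIMB_BITS = 12
LIMB_BASE = 1 << LIMB_BITS
LIMB_MASK = LIMB_BASE - 1

#: Largest tolerated deviation of an FFT convolution value from the nearest
#: integer.  Exceeding it means the limb base / operand sizes broke the
#: exactness contract, which is a hard error, never a silent approximation.
FFT_INTEGRALITY_TOL = 0.25


def n_limbs(q_bits: int) -> int:
    """Number of base-2^LIMB_BITS limbs needed for a q_bits-bit value."""
    return -(-q_bits // LIMB_BITS)


def _top_limb_mask(q_bits: int) -> int:
    rem = q_bits - (n_limbs(q_bits) - 1) * LIMB_BITS
    return (1 << rem) - 1


def carry_normalize(arr: np.ndarray, q_bits: int) -> np.ndarray:
    """Reduce a signed limb matrix to canonical form modulo 2^q_bits.

    Input limbs at positions >= D carry weight 2^(LIMB_BITS*D) >= 2^q_bits
    and vanish mod q, so the workspace is truncated to D columns up front.
    Carries are propagated by whole-matrix passes (each pass shrinks carry
    magnitudes by 2^LIMB_BITS); long borrow ripples, which the vector passes
    resolve only one column per pass, fall back to a sequential sweep.
    Correct for negative entries because ``&`` and ``>>`` on int64 follow
    two's-complement semantics.
    """
    D = n_limbs(q_bits)
    work = np.zeros(arr.shape[:-1] + (D,), dtype=np.int64)
    width = min(arr.shape[-1], D)
    work[..., :width] = arr[..., :width]
    for _ in range(8):
        carry = work >> LIMB_BITS
        if not carry.any():
            break
        work &= LIMB_MASK
        work[..., 1:] += carry[..., :-1]
    else:
        # rare: long borrow chain; finish with the exact sequential sweep
        carry = np.zeros(arr.shape[:-1], dtype=np.int64)
        for d in range(D):
            cur = work[..., d] + carry
            work[..., d] = cur & LIMB_MASK
            carry = cur >> LIMB_BITS
    work[..., D - 1] &= _top_limb_mask(q_bits)
    return work


@dataclass
class RingElement:
    """A polynomial in R_q, q = 2^q_bits, as canonical nonnegative limbs."""

    arr: np.ndarray  # (N, D) int64, 0 <= limb < 2^LIMB_BITS
    q_bits: int

    @property
    def n(self) -> int:
        return self.arr.shape[0]

    def copy(self) -> "RingElement":
        return RingElement(self.arr.copy(), self.q_bits)

    # -- conversions ---------------------------------------------------

    @classmethod
    def from_int_coeffs(cls, coeffs, n: int, q_bits: int) -> "RingElement":
        """Build from a sequence of (arbitrary size) Python integers."""
        D = n_limbs(q_bits)
        q = 1 << q_bits
        arr = np.zeros((n, D), dtype=np.int64)
        for i, c in enumerate(coeffs):
            c = int(c) % q
            for d in range(D):
                arr[i, d] = c & LIMB_MASK
                c >>= LIMB_BITS
        return cls(arr, q_bits)

    @classmethod
    def from_int64_coeffs(cls, coeffs: np.ndarray, q_bits: int) -> "RingElement":
        """Build from an int64 vector (|c| < 2^62), vectorized."""
        coeffs = np.asarray(coeffs, dtype=np.int64)
        D = n_limbs(q_bits)
        arr = np.empty((coeffs.shape[0], D), dtype=np.int64)
        c = coeffs.copy()
        for d in range(D):
            arr[:, d] = c & LIMB_MASK
            c >>= LIMB_BITS
        # negative inputs leave an all-ones tail; carry_normalize fixes the top
        return cls(carry_normalize(arr, q_bits), q_bits)

    def to_int_coeffs(self) -> list:
        """Canonical coefficients in [0, q) as Python integers (test path)."""
        vals = []
        for i in range(self.arr.shape[0]):
            c = 0
            for d in range(self.arr.shape[1] - 1, -1, -1):
                c = (c << LIMB_BITS) | int(self.arr[i, d])
            vals.append(c)
        return vals

    def centered_int64(self) -> np.ndarray:
        """Centered representatives mod q = 2^q_bits, assumed to fit in int64.

        Shifts by q/2 so the centered value becomes the canonical value minus
        q/2, then recovers it from the low 64 bits with two's-complement
        wraparound.  Exact whenever the centered magnitude is below 2^62,
        which the scheme's decrypt contract guarantees for valid messages.
        """
        q_bits = self.q_bits
        if q_bits < 63:
            v = np.zeros(self.arr.shape[0], dtype=np.int64)
            for d in range(self.arr.shape[1] - 1, -1, -1):
                v = (v << LIMB_BITS) + self.arr[:, d]
            half = np.int64(1 << (q_bits - 1))
            return v - ((v >= half).astype(np.int64) << q_bits)
        shifted = self.add_pow2(q_bits - 1)  # centered + q/2, in [0, q)
        nl = min(shifted.arr.shape[1], 64 // LIMB_BITS + 1)
        low = np.zeros(self.arr.shape[0], dtype=np.uint64)
        for d in range(nl - 1, -1, -1):
            low = (low << np.uint64(LIMB_BITS)) + shifted.arr[:, d].astype(np.uint64)
        half_low = (1 << (q_bits - 1)) & ((1 << 64) - 1)
        return (low - np.uint64(half_low)).view(np.int64)

    # -- modular structure ---------------------------------------------

    def mod_down(self, new_q_bits: int) -> "RingElement":
        """Reduce to the smaller modulus 2^new_q_bits (limb truncation)."""
        if new_q_bits > self.q_bits:
            raise ValueError("mod_down target must not exceed current modulus")
        D = n_limbs(new_q_bits)
        arr = self.arr[:, :D].copy()
        arr[:, D - 1] &= _top_limb_mask(new_q_bits)
        return RingElement(arr, new_q_bits)

    def add_pow2(self, bit: int) -> "RingElement":
        """Add 2^bit to every coefficient (rounding offsets, centering)."""
        arr = self.arr.copy()
        d, r = divmod(bit, LIMB_BITS)
        arr[:, d] += 1 << r
        return RingElement(carry_normalize(arr, self.q_bits), self.q_bits)

    def shift_left(self, bits: int, new_q_bits: int) -> "RingElement":
        """Multiply by 2^bits, reduced mod 2^new_q_bits (vectorized)."""
        w, r = divmod(bits, LIMB_BITS)
        D_new = n_limbs(new_q_bits)
        arr = np.zeros((self.arr.shape[0], D_new + 1), dtype=np.int64)
        width = min(self.arr.shape[1], D_new + 1 - w)
        arr[:, w : w + width] = self.arr[:, :width] << r
        return RingElement(carry_normalize(arr, new_q_bits), new_q_bits)

    def rescale(self, drop_bits: int) -> "RingElement":
        """Rounded division by 2^drop_bits: floor((v + 2^(t-1)) / 2^t) mod q'."""
        if drop_bits <= 0:
            raise ValueError("drop_bits must be positive")
        if drop_bits >= self.q_bits:
            raise ValueError("cannot rescale past the modulus")
        t = drop_bits
        rounded = self.add_pow2(t - 1).arr
        w, r = divmod(t, LIMB_BITS)
        new_bits = self.q_bits - t
        D = n_limbs(new_bits)
        src = np.zeros((rounded.shape[0], D + w + 1), dtype=np.int64)
        src[:, : rounded.shape[1]] = rounded
        if r == 0:
            arr = src[:, w : w + D].copy()
        else:
            lo = src[:, w : w + D] >> r
            hi = (src[:, w + 1 : w + D + 1] & ((1 << r) - 1)) << (LIMB_BITS - r)
            arr = lo | hi
        arr[:, D - 1] &= _top_limb_mask(new_bits)
        return RingElement(arr, new_bits)


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------


def ring_add(a: RingElement, b: RingElement) -> RingElement:
    assert a.q_bits == b.q_bits
    Dm = max(a.arr.shape[1], b.arr.shape[1])
    s = np.zeros((a.n, Dm), dtype=np.int64)
    s[:, : a.arr.shape[1]] += a.arr
    s[:, : b.arr.shape[1]] += b.arr
    return RingElement(carry_normalize(s, a.q_bits), a.q_bits)


def ring_sub(a: RingElement, b: RingElement) -> RingElement:
    assert a.q_bits == b.q_bits
    Dm = max(a.arr.shape[1], b.arr.shape[1])
    s = np.zeros((a.n, Dm), dtype=np.int64)
    s[:, : a.arr.shape[1]] += a.arr
    s[:, : b.arr.shape[1]] -= b.arr
    return RingElement(carry_normalize(s, a.q_bits), a.q_bits)


def ring_neg(a: RingElement) -> RingElement:
    return RingElement(carry_normalize(-a.arr, a.q_bits), a.q_bits)


@lru_cache(maxsize=8)
def _twist(n: int) -> np.ndarray:
    """exp(i*pi*k/n) for k < n: maps cyclic length-n FFT to negacyclic."""
    return np.exp(1j * np.pi * np.arange(n) / n)


def _fwd_transform(limbs: np.ndarray, n: int, T: int) -> np.ndarray:
    """Forward twisted transform of a signed limb matrix, shape (n, T//2+1)->(n, ...).

    rfft along the limb axis (real input), twist + full fft along the
    coefficient axis.  Returns complex spectrum of shape (n, T//2 + 1).
    """
    spec = _fft.rfft(limbs.astype(np.float64), n=T, axis=1)
    spec *= _twist(n)[:, None]
    return _fft.fft(spec, axis=0)


def _inv_transform(spec: np.ndarray, n: int, T: int) -> np.ndarray:
    out = _fft.ifft(spec, axis=0)
    out *= _twist(n).conj()[:, None]
    vals = _fft.irfft(out, n=T, axis=1)
    # vals accumulated an imaginary part inside ifft; irfft of the complex
    # array keeps only the spectrum's Hermitian part, which is exactly the
    # real convolution values because inputs were real limb matrices.
    return vals


def _check_integral(vals: np.ndarray, d_keep: int | None = None) -> np.ndarray:
    """Round convolution values to int64, guarding exactness.

    ``d_keep`` truncates to the limb columns that survive the subsequent
    modular reduction (higher columns carry weight that vanishes mod q).
    """
    if d_keep is not None and d_keep < vals.shape[-1]:
        vals = vals[..., :d_keep]
    rounded = np.rint(vals)
    err = np.max(np.abs(vals - rounded)) if vals.size else 0.0
    if err > FFT_INTEGRALITY_TOL:
        raise ArithmeticError(
            f"FFT convolution lost exactness (residual {err:.3g}); "
            "operand sizes exceed the engine's integrality budget"
        )
    return rounded.astype(np.int64)


def _as_limbs(x) -> np.ndarray:
    if isinstance(x, RingElement):
        return x.arr
    x = np.asarray(x, dtype=np.int64)
    if x.ndim == 1:
        x = x[:, None]
    return x


def _conv_size(da: int, db: int) -> int:
    # linear convolution along the limb axis: any fast FFT length >= da+db-1
    return _fft.next_fast_len(da + db - 1)


def ring_mult(a, b, out_q_bits: int) -> RingElement:
    """Exact negacyclic product, reduced mod 2^out_q_bits.

    Either operand may be a :class:`RingElement` or a signed int64 coefficient
    vector / (N, D) signed limb matrix of small magnitude (secrets, errors).
    """
    la, lb = _as_limbs(a), _as_limbs(b)
    n = la.shape[0]
    assert lb.shape[0] == n
    T = _conv_size(la.shape[1], lb.shape[1])
    sa = _fwd_transform(la, n, T)
    sb = _fwd_transform(lb, n, T)
    vals = _inv_transform(sa * sb, n, T)
    prod = _check_integral(vals, n_limbs(out_q_bits))
    return RingElement(carry_normalize(prod, out_q_bits), out_q_bits)


class TransformedOperand:
    """A fixed ring operand with its forward spectrum cached per conv size."""

    def __init__(self, elem: RingElement):
        self.elem = elem
        self._spectra: dict[int, np.ndarray] = {}

    def spectrum(self, T: int) -> np.ndarray:
        if T not in self._spectra:
            if len(self._spectra) > 2:  # keep the cache tiny
                self._spectra.clear()
            self._spectra[T] = _fwd_transform(self.elem.arr, self.elem.n, T)
        return self._spectra[T]


def ring_mult_cached(a, cached: TransformedOperand, out_q_bits: int,
                     T: int | None = None) -> RingElement:
    """Product against a fixed operand with a cached forward spectrum.

    Passing an explicit (sufficiently large) ``T`` pins the transform
    length so the cached spectrum is reused across ciphertext levels.
    """
    la = _as_limbs(a)
    n = la.shape[0]
    if T is None:
        T = _conv_size(la.shape[1], cached.elem.arr.shape[1])
    elif T < la.shape[1] + cached.elem.arr.shape[1] - 1:
        raise ValueError("transform length too short for exact convolution")
    sa = _fwd_transform(la, n, T)
    vals = _inv_transform(sa * cached.spectrum(T), n, T)
    prod = _check_integral(vals, n_limbs(out_q_bits))
    return RingElement(carry_normalize(prod, out_q_bits), out_q_bits)


def ring_mult_cached_pair(a, cached0: TransformedOperand,
                          cached1: TransformedOperand, out_q_bits: int,
                          T: int) -> tuple[RingElement, RingElement]:
    """One forward transform of ``a`` against two cached operands."""
    la = _as_limbs(a)
    n = la.shape[0]
    sa = _fwd_transform(la, n, T)
    out = []
    dk = n_limbs(out_q_bits)
    for c in (cached0, cached1):
        vals = _inv_transform(sa * c.spectrum(T), n, T)
        out.append(RingElement(carry_normalize(_check_integral(vals, dk),
                                               out_q_bits), out_q_bits))
    return out[0], out[1]


def ring_mult_many(pairs, out_q_bits: int) -> list[RingElement]:
    """Multiply several operand pairs sharing transforms where repeated.

    ``pairs`` is a list of (a, b); operands compared by identity so that e.g.
    (c0, d0'), (c0, d1'), (c1, d0'), (c1, d1') transform each input once.
    """
    la = [_as_limbs(a) for a, _ in pairs]
    lb = [_as_limbs(b) for _, b in pairs]
    n = la[0].shape[0]
    T = _conv_size(max(x.shape[1] for x in la), max(x.shape[1] for x in lb))
    cache: dict[int, np.ndarray] = {}

    def fwd(limbs):
        key = id(limbs)
        if key not in cache:
            cache[key] = _fwd_transform(limbs, n, T)
        return cache[key]

    dk = n_limbs(out_q_bits)
    out = []
    for xa, xb in zip(la, lb):
        vals = _inv_transform(fwd(xa) * fwd(xb), n, T)
        out.append(RingElement(carry_normalize(_check_integral(vals, dk),
                                               out_q_bits), out_q_bits))
    return out


# ---------------------------------------------------------------------------
# Galois automorphisms X -> X^u (u odd), the slot-rotation workhorse
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _automorphism_tables(n: int, u: int):
    k = np.arange(n, dtype=np.int64)
    t = (k * u) % (2 * n)
    idx = t % n
    sign = np.where(t < n, 1, -1).astype(np.int64)
    return idx, sign


def ring_automorphism(a: RingElement, u: int) -> RingElement:
    """sigma_u(a)(X) = a(X^u) in R_q; u must be odd."""
    if u % 2 == 0:
        raise ValueError("automorphism exponent must be odd")
    n = a.n
    idx, sign = _automorphism_tables(n, u % (2 * n))
    out = np.zeros_like(a.arr)
    out[idx] = a.arr * sign[:, None]
    return RingElement(carry_normalize(out, a.q_bits), a.q_bits)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_uniform(rng: np.random.Generator, n: int, q_bits: int) -> RingElement:
    D = n_limbs(q_bits)
    arr = rng.integers(0, LIMB_BASE, size=(n, D), dtype=np.int64)
    arr[:, D - 1] &= _top_limb_mask(q_bits)
    return RingElement(arr, q_bits)


def sample_gaussian(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """Discrete Gaussian (rounded normal) as a small signed int64 vector."""
    if sigma <= 0:
        return np.zeros(n, dtype=np.int64)
    return np.rint(rng.normal(0.0, sigma, size=n)).astype(np.int64)


def sample_hwt(rng: np.random.Generator, n: int, h: int) -> np.ndarray:
    """Ternary secret with Hamming weight h (uniform support and signs)."""
    if h > n:
        raise ValueError("Hamming weight cannot exceed the ring dimension")
    s = np.zeros(n, dtype=np.int64)
    support = rng.choice(n, size=h, replace=False)
    s[support] = rng.choice(np.array([-1, 1]), size=h)
    return s


# ---------------------------------------------------------------------------
# reference oracle (tests only; exact big-int arithmetic)
# ---------------------------------------------------------------------------


def negacyclic_convolve_naive(a, b, q: int) -> list:
    """Schoolbook negacyclic convolution over Python integers, mod q."""
    n = len(a)
    assert len(b) == n
    out = [0] * n
    for i in range(n):
        ai = int(a[i])
        if ai == 0:
            continue
        for j in range(n):
            k = i + j
            term = ai * int(b[j])
            if k >= n:
                out[k - n] -= term
            else:
                out[k] += term
    return [v % q for v in out]
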