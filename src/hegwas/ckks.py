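"""Leveled approximate homomorphic encryption over real-number slots.

The scheme encrypts vectors of up to N/2 real (or complex) numbers into
polynomials of the ring R = Z[X]/(X^N + 1) taken modulo q_l = 2^l, and
supports slotwise addition, multiplication and cyclic slot rotation on
ciphertexts.  Messages are fixed-point: a vector is scaled by 2^p before
rounding into the ring ("p precision bits"), and every homomorphic
multiplication is followed by a rescaling step that divides the ciphertext
by 2^p and drops p bits of modulus, so the scale stays put while the level
budget l shrinks.  Decryption returns the message plus a small error; all
arithmetic is approximate by design.

Slots live on the canonical embedding: slot j corresponds to evaluation of
the message polynomial at the primitive 2N-th root of unity zeta^(5^j).
With this ordering the Galois automorphism X -> X^(5^r) acts on slots as a
cyclic left shift by r, which is what the rotation operation key-switches
back to the original secret.

Vectors shorter than N/2 (any power-of-two length K) are replicated N/(2K)
times across the slots, so a ciphertext of a length-K vector is equally a
ciphertext of the replicated length-N/2 vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.fft as _fft

from . import ring
from .ring import (
    RingElement,
    TransformedOperand,
    ring_add,
    ring_automorphism,
    ring_mult,
    ring_mult_many,
    ring_neg,
    ring_sub,
)


class LevelBudgetError(RuntimeError):
    """Raised when an operation would exhaust the ciphertext modulus."""


class MissingRotationKeyError(KeyError):
    """Raised when a rotation is requested without its switching key."""


# ---------------------------------------------------------------------------
# parameters and key material
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HEParams:
    """Scheme parameters.

    Parameters
    ----------
    log_n : int
        log2 of the ring dimension N; N/2 slots are available.
    level_bits : int
        Level parameter L; the fresh ciphertext modulus is q_L = 2^L.
    scale_bits : int
        Fixed-point precision p: messages are scaled by 2^p at encoding.
    hamming_weight : int
        Number of nonzero (ternary) secret-key coefficients.
    sigma_err : float
        Standard deviation of the discrete-Gaussian error/encryption noise.
    seed : int
        Seed for all key-generation and encryption randomness.
    """

    log_n: int
    level_bits: int
    scale_bits: int
    hamming_weight: int
    sigma_err: float = 3.2
    seed: int = 0

    def __post_init__(self):
        if self.log_n < 2 or self.log_n > 20:
            raise ValueError("log_n out of supported range")
        if not (1 <= self.scale_bits < self.level_bits):
            raise ValueError("need 1 <= scale_bits < level_bits")
        if not (0 < self.hamming_weight <= self.n):
            raise ValueError("hamming weight must be in (0, N]")
        if self.sigma_err < 0:
            raise ValueError("sigma_err must be nonnegative")

    @property
    def n(self) -> int:
        return 1 << self.log_n

    @property
    def n_slots(self) -> int:
        return self.n // 2


def load_profile(path) -> "HEParams":
    """Read scheme parameters from a YAML (or JSON) profile file.

    Recognized keys: log_n, level_bits, scale_bits, hamming_weight, and
    optionally sigma_err and seed.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return HEParams(**doc)


#: Named parameter profiles.  "exp1"/"exp2" record the 128-bit-secure
#: production parameter sets (ring dimension 2^17); they are far too large to
#: evaluate in this implementation and exist as configuration records.  The
#: toy profiles are for correctness work at matching semantics.
PROFILES: dict[str, HEParams] = {
    "exp1": HEParams(log_n=17, level_bits=1300, scale_bits=50, hamming_weight=56),
    "exp2": HEParams(log_n=17, level_bits=1700, scale_bits=50, hamming_weight=78),
    "toy": HEParams(log_n=13, level_bits=300, scale_bits=30, hamming_weight=64),
    "tiny": HEParams(log_n=9, level_bits=180, scale_bits=26, hamming_weight=32),
}


@dataclass
class PlaintextPoly:
    """Encoded message: an integer polynomial carrying its scale."""

    poly: RingElement
    scale_bits: int
    n_slots: int


@dataclass
class Ciphertext:
    """Pair of ring elements (c0, c1) mod q_level with a tracked scale."""

    c0: RingElement
    c1: RingElement
    level: int  # modulus bits l; q = 2^l
    scale_bits: int
    n_slots: int

    def copy(self) -> "Ciphertext":
        return Ciphertext(self.c0.copy(), self.c1.copy(), self.level,
                          self.scale_bits, self.n_slots)


@dataclass
class KeySet:
    """Secret, public, evaluation and rotation keys for one parameter set."""

    params: HEParams
    sk: np.ndarray  # ternary secret s; the secret key is the pair (1, s)
    pk: tuple[RingElement, RingElement]
    evk: tuple[RingElement, RingElement]
    rot_keys: dict[int, tuple[RingElement, RingElement]] = field(default_factory=dict)

    def public_material(self) -> "PublicKeySet":
        return PublicKeySet(self.params, self.pk, self.evk, self.rot_keys)


@dataclass
class PublicKeySet:
    """Everything an evaluating party holds: no secret key."""

    params: HEParams
    pk: tuple[RingElement, RingElement]
    evk: tuple[RingElement, RingElement]
    rot_keys: dict[int, tuple[RingElement, RingElement]]


# ---------------------------------------------------------------------------
# canonical-embedding encode / decode
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _slot_root_indices(n: int) -> np.ndarray:
    """Odd exponents m_j = 5^j mod 2N addressing the slot roots zeta^(m_j)."""
    idx = np.empty(n // 2, dtype=np.int64)
    m = 1
    for j in range(n // 2):
        idx[j] = m
        m = (m * 5) % (2 * n)
    return idx


def embed_inverse(slots: np.ndarray, n: int) -> np.ndarray:
    """Real coefficient vector whose canonical embedding equals ``slots``.

    ``slots`` has length N/2 (complex allowed); the conjugate half of the
    spectrum is filled in automatically so the result is real.
    """
    m = _slot_root_indices(n)
    spec = np.zeros(2 * n, dtype=np.complex128)
    slots = np.asarray(slots, dtype=np.complex128)
    spec[2 * n - m] = slots
    spec[m] = slots.conj()
    return _fft.fft(spec)[:n].real / n


def embed_forward(coeffs: np.ndarray, n: int) -> np.ndarray:
    """Evaluate a real coefficient vector at the slot roots."""
    m = _slot_root_indices(n)
    spec = _fft.fft(np.asarray(coeffs, dtype=np.float64), n=2 * n)
    return spec[(2 * n - m) % (2 * n)]


def encode(vec, params: HEParams, scale_bits: int | None = None) -> PlaintextPoly:
    """Ecd: scale by 2^p and round the inverse embedding to integers.

    ``vec`` must have power-of-two length K <= N/2; it is replicated to fill
    all

    N/2 slots, so ciphertexts of short vectors behave periodically under
    rotation.
    """
    p = params.scale_bits if scale_bits is None else scale_bits
    v = np.asarray(vec)
    K = v.shape[0]
    half = params.n_slots
    if K > half or K & (K - 1):
        raise ValueError(f"slot count {K} must be a power of two <= {half}")
    full = np.tile(v, half // K)
    coeffs = embed_inverse(full, params.n) * float(2**p)
    if np.max(np.abs(coeffs)) >= 2**62:
        raise OverflowError("encoded coefficients exceed the engine's range")
    ints = np.rint(coeffs).astype(np.int64)
    return PlaintextPoly(RingElement.from_int64_coeffs(ints, params.level_bits),
                         p, K)


def decode(pt: PlaintextPoly, params: HEParams) -> np.ndarray:
    """Dcd: evaluate at the slot roots and undo the 2^p scaling.

    Returns the real parts of the first ``pt.n_slots`` slots (messages in
    this package are real; the imaginary parts carry only noise).
    """
    coeffs = pt.poly.centered_int64().astype(np.float64)
    slots = embed_forward(coeffs, params.n) / float(2**pt.scale_bits)
    return slots[: pt.n_slots].real


# ---------------------------------------------------------------------------
# key generation / encryption (secret-key side)
# ---------------------------------------------------------------------------


def rotation_exponent(n: int, r: int) -> int:
    return pow(5, r % (n // 2), 2 * n)


class CkksContext:
    """Key-owner context: key generation, encryption and decryption."""

    def __init__(self, params: HEParams):
        self.params = params
        self.rng = np.random.default_rng(params.seed)

    def keygen(self, shifts: tuple[int, ...] | list[int] = ()) -> KeySet:
        par = self.params
        n, L = par.n, par.level_bits
        rng = self.rng
        s = ring.sample_hwt(rng, n, par.hamming_weight)
        # public key mod q_L
        a = ring.sample_uniform(rng, n, L)
        e = ring.sample_gaussian(rng, n, par.sigma_err)
        b = ring_add(ring_neg(ring_mult(a, s, L)),
                     RingElement.from_int64_coeffs(e, L))
        # evaluation key mod q_L^2: b' = -a's + e' + q_L * s^2
        s2 = ring_mult(s, s, 2 * L)
        evk = self._switching_key(s, s2)
        ks = KeySet(par, s, (b, a), evk)
        for r in shifts:
            self.add_rotation_key(ks, r)
        return ks

    def _switching_key(self, s: np.ndarray,
                       target: RingElement) -> tuple[RingElement, RingElement]:
        """Key switching from ``target`` to s, modulo q_L^2 = 2^(2L)."""
        par = self.params
        n, L = par.n, par.level_bits
        a = ring.sample_uniform(self.rng, n, 2 * L)
        e = ring.sample_gaussian(self.rng, n, par.sigma_err)
        # q_L * (target mod q_L), lifted to the modulus q_L^2
        up = target.mod_down(L).shift_left(L, 2 * L)
        b = ring_add(ring_add(ring_neg(ring_mult(a, s, 2 * L)),
                              RingElement.from_int64_coeffs(e, 2 * L)), up)
        return (b, a)

    def add_rotation_key(self, ks: KeySet, r: int) -> None:
        par = self.params
        r = r % par.n_slots
        if r in ks.rot_keys or r == 0:
            return
        u = rotation_exponent(par.n, r)
        idx, sign = ring._automorphism_tables(par.n, u % (2 * par.n))
        s_rot = np.zeros_like(ks.sk)
        s_rot[idx] = ks.sk * sign
        ks.rot_keys[r] = self._switching_key(
            ks.sk, RingElement.from_int64_coeffs(s_rot, 2 * par.level_bits))

    # -- encryption ----------------------------------------------------

    def encrypt(self, pk: tuple[RingElement, RingElement],
                pt: PlaintextPoly) -> Ciphertext:
        par = self.params
        n, L = par.n, par.level_bits
        v = ring.sample_gaussian(self.rng, n, par.sigma_err)
        e0 = ring.sample_gaussian(self.rng, n, par.sigma_err)
        e1 = ring.sample_gaussian(self.rng, n, par.sigma_err)
        c0 = ring_add(ring_add(ring_mult(v, pk[0], L),
                               RingElement(pt.poly.arr, L)),
                      RingElement.from_int64_coeffs(e0, L))
        c1 = ring_add(ring_mult(v, pk[1], L),
                      RingElement.from_int64_coeffs(e1, L))
        return Ciphertext(c0, c1, L, pt.scale_bits, pt.n_slots)

    def encrypt_vector(self, pk, vec, scale_bits: int | None = None) -> Ciphertext:
        return self.encrypt(pk, encode(vec, self.params, scale_bits))

    def decrypt(self, sk: np.ndarray, ct: Ciphertext) -> PlaintextPoly:
        m = ring_add(ct.c0, ring_mult(sk, ct.c1, ct.level))
        return PlaintextPoly(m, ct.scale_bits, ct.n_slots)

    def decrypt_vector(self, sk: np.ndarray, ct: Ciphertext) -> np.ndarray:
        return decode(self.decrypt(sk, ct), self.params)


# ---------------------------------------------------------------------------
# homomorphic evaluation (public-key side)
# ---------------------------------------------------------------------------


class Evaluator:
    """Homomorphic operations over public key material.

    The evaluator keeps the canonical working scale at ``params.scale_bits``
    and rescales immediately after every multiplicative operation, so levels
    drop by the multiplier's scale.  It also keeps a running ledger of
    operation counts and the current pipeline stage label, which the
    depth planner and the tests inspect.
    """

    def __init__(self, keys: PublicKeySet, min_level_floor: int | None = None):
        self.keys = keys
        self.params = keys.params
        self._evk_t = (TransformedOperand(keys.evk[0]),
                       TransformedOperand(keys.evk[1]))
        self._rot_t: dict[int, tuple[TransformedOperand, TransformedOperand]] = {}
        # one fixed transform length for all key-switching products, so key
        # spectra are computed once and reused at every ciphertext level
        L = self.params.level_bits
        self._T_ks = ring._conv_size(ring.n_limbs(L), ring.n_limbs(2 * L))
        self.op_counts: dict[str, int] = {}
        self.stage = ""
        # a ciphertext must keep modulus headroom above its scale
        self.min_level_floor = (self.params.scale_bits
                                if min_level_floor is None else min_level_floor)

    # -- bookkeeping ---------------------------------------------------

    def _count(self, op: str) -> None:
        self.op_counts[op] = self.op_counts.get(op, 0) + 1

    def _require_level(self, level: int, drop: int) -> None:
        if level - drop < self.min_level_floor:
            raise LevelBudgetError(
                f"level budget exhausted at stage '{self.stage}': "
                f"level {level} cannot drop {drop} bits "
                f"(floor {self.min_level_floor})")

    # -- plaintext helpers --------------------------------------------

    def encode(self, vec, scale_bits: int | None = None) -> PlaintextPoly:
        return encode(vec, self.params, scale_bits)

    # -- level / scale management -------------------------------------

    def mod_down(self, ct: Ciphertext, level: int) -> Ciphertext:
        if level > ct.level:
            raise ValueError("mod_down cannot raise the level")
        if level == ct.level:
            return ct
        return Ciphertext(ct.c0.mod_down(level), ct.c1.mod_down(level),
                          level, ct.scale_bits, ct.n_slots)

    def rescale(self, ct: Ciphertext, drop_bits: int) -> Ciphertext:
        """RS: divide by 2^drop_bits, dropping that much modulus and scale."""
        if drop_bits <= 0:
            raise ValueError("rescale must drop a positive number of bits")
        self._require_level(ct.level, drop_bits)
        self._count("rescale")
        return Ciphertext(ct.c0.rescale(drop_bits), ct.c1.rescale(drop_bits),
                          ct.level - drop_bits, ct.scale_bits - drop_bits,
                          ct.n_slots)

    def align(self, a: Ciphertext, b: Ciphertext) -> tuple[Ciphertext, Ciphertext]:
        lvl = min(a.level, b.level)
        return self.mod_down(a, lvl), self.mod_down(b, lvl)

    # -- linear ops ----------------------------------------------------

    def add(self, a: Ciphertext, b: Ciphertext) -> Ciphertext:
        a, b = self.align(a, b)
        if a.scale_bits != b.scale_bits:
            raise ValueError(
                f"scale mismatch in add: {a.scale_bits} vs {b.scale_bits} "
                f"(stage '{self.stage}'); rescale/align first")
        self._count("add")
        return Ciphertext(ring_add(a.c0, b.c0), ring_add(a.c1, b.c1),
                          a.level, a.scale_bits, max(a.n_slots, b.n_slots))

    def sub(self, a: Ciphertext, b: Ciphertext) -> Ciphertext:
        a, b = self.align(a, b)
        if a.scale_bits != b.scale_bits:
            raise ValueError(
                f"scale mismatch in sub: {a.scale_bits} vs {b.scale_bits} "
                f"(stage '{self.stage}')")
        self._count("add")
        return Ciphertext(ring_sub(a.c0, b.c0), ring_sub(a.c1, b.c1),
                          a.level, a.scale_bits, max(a.n_slots, b.n_slots))

    def neg(self, a: Ciphertext) -> Ciphertext:
        return Ciphertext(ring_neg(a.c0), ring_neg(a.c1), a.level,
                          a.scale_bits, a.n_slots)

    def add_const(self, a: Ciphertext, c: float) -> Ciphertext:
        """Add the same constant to every slot (exact, scale-matched)."""
        val = int(round(c * 2**a.scale_bits))
        pt = RingElement.from_int_coeffs([val] + [0] * (a.c0.n - 1),
                                         a.c0.n, a.level)
        self._count("add")
        return Ciphertext(ring_add(a.c0, pt), a.c1, a.level, a.scale_bits,
                          a.n_slots)

    def mult_pow2(self, a: Ciphertext, k: int) -> Ciphertext:
        """Multiply every slot by 2^k exactly, free of noise and depth.

        Implemented as pure scale bookkeeping: the ciphertext is unchanged,
        only the claimed fixed-point scale moves by -k.
        """
        if a.scale_bits - k < 1:
            raise ValueError("scale would underflow")
        return Ciphertext(a.c0, a.c1, a.level, a.scale_bits - k, a.n_slots)

    # -- multiplicative ops --------------------------------------------

    def mult(self, a: Ciphertext, b: Ciphertext,
             rescale_to: int | None = None) -> Ciphertext:
        """Relinearized slotwise product; rescaled back to one scale.

        By default the result is rescaled so its scale equals
        ``max(a.scale, b.scale)`` (i.e. the smaller scale is consumed as
        depth), matching the rescale-after-every-multiplication policy.
        """
        a, b = self.align(a, b)
        lvl, L = a.level, self.params.level_bits
        d0, x, y, d2 = ring_mult_many(
            [(a.c0, b.c0), (a.c0, b.c1), (a.c1, b.c0), (a.c1, b.c1)], lvl)
        d1 = ring_add(x, y)
        # relinearize: (d0, d1) + round(q_L^-1 * d2 * evk) mod q_l
        k0, k1 = ring.ring_mult_cached_pair(d2, self._evk_t[0],
                                            self._evk_t[1], L + lvl,
                                            self._T_ks)
        k0, k1 = k0.rescale(L), k1.rescale(L)
        ct = Ciphertext(ring_add(d0, k0), ring_add(d1, k1), lvl,
                        a.scale_bits + b.scale_bits,
                        max(a.n_slots, b.n_slots))
        self._count("mult")
        target = max(a.scale_bits, b.scale_bits) if rescale_to is None else rescale_to
        drop = ct.scale_bits - target
        return self.rescale(ct, drop) if drop else ct

    def mult_plain(self, a: Ciphertext, pt: PlaintextPoly,
                   rescale_to: int | None = None) -> Ciphertext:
        """Slotwise product with an encoded (public) plaintext."""
        if pt.poly.q_bits < a.level:
            raise ValueError("plaintext encoded at too small a modulus")
        ptq = pt.poly.mod_down(a.level)
        c0, c1 = ring_mult_many([(a.c0, ptq), (a.c1, ptq)], a.level)
        ct = Ciphertext(c0, c1, a.level, a.scale_bits + pt.scale_bits,
                        max(a.n_slots, pt.n_slots))
        self._count("mult_plain")
        target = a.scale_bits if rescale_to is None else rescale_to
        drop = ct.scale_bits - target
        return self.rescale(ct, drop) if drop else ct

    def zero(self, n_slots: int) -> Ciphertext:
        """A trivial (noiseless, transparent) encryption of the zero vector."""
        n, L = self.params.n, self.params.level_bits
        z = RingElement(np.zeros((n, ring.n_limbs(L)), dtype=np.int64), L)
        return Ciphertext(z, z.copy(), L, self.params.scale_bits, n_slots)

    def mult_const(self, a: Ciphertext, c: float,
                   const_bits: int = 24) -> Ciphertext:
        """Multiply every slot by a scalar constant (one rescale level).

        The constant polynomial round(c * 2^const_bits) is exact, so unlike
        a general plaintext mask this costs no encoding error -- only the
        scalar's own rounding at ``const_bits`` precision.
        """
        val = int(round(c * 2**const_bits))
        pt = RingElement.from_int_coeffs([val] + [0] * (a.c0.n - 1),
                                         a.c0.n, a.level)
        c0, c1 = ring_mult_many([(a.c0, pt), (a.c1, pt)], a.level)
        ct = Ciphertext(c0, c1, a.level, a.scale_bits + const_bits, a.n_slots)
        self._count("mult_const")
        return self.rescale(ct, const_bits)

    def square(self, a: Ciphertext) -> Ciphertext:
        return self.mult(a, a)

    # -- rotation ------------------------------------------------------

    def rotate(self, a: Ciphertext, r: int) -> Ciphertext:
        """Cyclic left slot shift by r (right for negative r)."""
        par = self.params
        r = r % par.n_slots
        if r == 0:
            return a
        if r not in self.keys.rot_keys:
            raise MissingRotationKeyError(
                f"no rotation key for shift {r} (stage '{self.stage}')")
        u = rotation_exponent(par.n, r)
        c0g = ring_automorphism(a.c0, u)
        c1g = ring_automorphism(a.c1, u)
        if r not in self._rot_t:
            rk = self.keys.rot_keys[r]
            self._rot_t[r] = (TransformedOperand(rk[0]),
                              TransformedOperand(rk[1]))
        L, lvl = par.level_bits, a.level
        k0, k1 = ring.ring_mult_cached_pair(c1g, *self._rot_t[r], L + lvl,
                                            self._T_ks)
        self._count("rotate")
        return Ciphertext(ring_add(c0g, k0.rescale(L).mod_down(lvl)),
                          k1.rescale(L).mod_down(lvl),
                          lvl, a.scale_bits, a.n_slots)


# ---------------------------------------------------------------------------
# serialization (JSON container with a params header)
# ---------------------------------------------------------------------------


def _elem_to_hex(e: RingElement) -> dict:
    return {"q_bits": e.q_bits,
            "coeffs": [format(c, "x") for c in e.to_int_coeffs()]}


def _elem_from_hex(d: dict, n: int) -> RingElement:
    return RingElement.from_int_coeffs([int(c, 16) for c in d["coeffs"]],
                                       n, d["q_bits"])


def keyset_to_json(ks: KeySet) -> str:
    par = ks.params
    doc = {
        "params": {"log_n": par.log_n, "level_bits": par.level_bits,
                   "scale_bits": par.scale_bits,
                   "hamming_weight": par.hamming_weight,
                   "sigma_err": par.sigma_err, "seed": par.seed},
        "sk": ks.sk.tolist(),
        "pk": [_elem_to_hex(ks.pk[0]), _elem_to_hex(ks.pk[1])],
        "evk": [_elem_to_hex(ks.evk[0]), _elem_to_hex(ks.evk[1])],
        "rot_keys": {str(r): [_elem_to_hex(k[0]), _elem_to_hex(k[1])]
                     for r, k in ks.rot_keys.items()},
    }
    return json.dumps(doc)


def ciphertext_to_dict(ct: Ciphertext) -> dict:
    return {"c0": _elem_to_hex(ct.c0), "c1": _elem_to_hex(ct.c1),
            "level": ct.level, "scale_bits": ct.scale_bits,
            "n_slots": ct.n_slots}


def ciphertext_from_dict(d: dict, n: int) -> Ciphertext:
    return Ciphertext(_elem_from_hex(d["c0"], n), _elem_from_hex(d["c1"], n),
                      d["level"], d["scale_bits"], d["n_slots"])


def keyset_from_json(text: str) -> KeySet:
    doc = json.loads(text)
    par = HEParams(**doc["params"])
    n = par.n
    return KeySet(
        par,
        np.asarray(doc["sk"], dtype=np.int64),
        tuple(_elem_from_hex(d, n) for d in doc["pk"]),
        tuple(_elem_from_hex(d, n) for d in doc["evk"]),
        {int(r): tuple(_elem_from_hex(d, n) for d in k)
         for r, k in doc["rot_keys"].items()},
    )
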