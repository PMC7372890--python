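"""Scheme-level behaviour: encoding, encryption, homomorphic ops, rotation."""

import numpy as np
import pytest

from hegwas import ckks
from hegwas.ckks import HEParams

from conftest import TINY_PARAMS


def test_params_validation():
    with pytest.raises(ValueError):
        HEParams(log_n=9, level_bits=100, scale_bits=100, hamming_weight=8)
    with pytest.raises(ValueError):
        HEParams(log_n=9, level_bits=100, scale_bits=30, hamming_weight=0)
    with pytest.raises(ValueError):
        HEParams(log_n=1, level_bits=100, scale_bits=30, hamming_weight=2)


def test_encode_decode_roundtrip_bound():
    """decode(encode(v)) recovers v within the rounding bound; error
    shrinks monotonically as the precision p grows."""
    rng = np.random.default_rng(0)
    v = rng.normal(size=TINY_PARAMS.n_slots)
    errs = []
    for p in (20, 30, 40):
        pt = ckks.encode(v, TINY_PARAMS, scale_bits=p)
        errs.append(np.max(np.abs(ckks.decode(pt, TINY_PARAMS) - v)))
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 1e-9


def test_encode_all_ones_is_constant_polynomial():
    pt = ckks.encode(np.ones(8), TINY_PARAMS, scale_bits=30)
    coeffs = pt.poly.centered_int64()
    assert coeffs[0] == 2**30
    assert np.all(coeffs[1:] == 0)


def test_encode_replication_rule():
    """Encoding v equals encoding v||v: short vectors are replicated."""
    rng = np.random.default_rng(1)
    v = rng.normal(size=TINY_PARAMS.n_slots // 4)
    a = ckks.encode(v, TINY_PARAMS)
    b = ckks.encode(np.tile(v, 2), TINY_PARAMS)
    assert np.array_equal(a.poly.arr, b.poly.arr)


def test_encode_rejects_bad_slot_counts():
    with pytest.raises(ValueError):
        ckks.encode(np.ones(3), TINY_PARAMS)
    with pytest.raises(ValueError):
        ckks.encode(np.ones(TINY_PARAMS.n_slots * 2), TINY_PARAMS)


def test_encrypt_decrypt_roundtrip(tiny_keys):
    ctx, keys, _ = tiny_keys
    ct = ctx.encrypt_vector(keys.pk, np.array([1.0, 2.0, 3.0, 4.0]))
    out = ctx.decrypt_vector(keys.sk, ct)
    assert np.allclose(out[:4], [1, 2, 3, 4], atol=1e-4)
    zero = ctx.decrypt_vector(keys.sk, ctx.encrypt_vector(keys.pk,
                                                          np.zeros(4)))
    assert np.max(np.abs(zero)) < 1e-4


def test_encryption_is_randomized_but_decrypts_equal(tiny_keys):
    ctx, keys, _ = tiny_keys
    v = np.array([0.5, -1.5, 2.0, 0.0])
    c1 = ctx.encrypt_vector(keys.pk, v)
    c2 = ctx.encrypt_vector(keys.pk, v)
    assert not np.array_equal(c1.c0.arr, c2.c0.arr)
    d1 = ctx.decrypt_vector(keys.sk, c1)[:4]
    d2 = ctx.decrypt_vector(keys.sk, c2)[:4]
    assert np.allclose(d1, d2, atol=1e-4)


def test_keygen_deterministic_under_seed():
    k1 = ckks.CkksContext(TINY_PARAMS).keygen(shifts=[1])
    k2 = ckks.CkksContext(TINY_PARAMS).keygen(shifts=[1])
    assert np.array_equal(k1.sk, k2.sk)
    assert np.array_equal(k1.pk[0].arr, k2.pk[0].arr)
    assert np.array_equal(k1.evk[1].arr, k2.evk[1].arr)
    assert np.array_equal(k1.rot_keys[1][0].arr, k2.rot_keys[1][0].arr)


def test_key_identities(tiny_keys):
    """pk and evk satisfy their defining near-identities with small error."""
    from hegwas import ring

    ctx, keys, _ = tiny_keys
    L = TINY_PARAMS.level_bits
    b, a = keys.pk
    e = ring.ring_add(b, ring.ring_mult(a, keys.sk, L)).centered_int64()
    assert np.max(np.abs(e)) < 64  # a few noise standard deviations
    bp, ap = keys.evk
    s2 = ring.ring_mult(keys.sk, keys.sk, 2 * L)
    lhs = ring.ring_add(bp, ring.ring_mult(ap, keys.sk, 2 * L))
    rhs = s2.shift_left(L, 2 * L)
    err = ring.ring_sub(lhs, rhs).centered_int64()
    assert np.max(np.abs(err)) < 64


def test_hom_add_sub_identities(tiny_keys):
    ctx, keys, ev = tiny_keys
    rng = np.random.default_rng(2)
    u, v = rng.uniform(-1, 1, 8), rng.uniform(-1, 1, 8)
    cu, cv = (ctx.encrypt_vector(keys.pk, x) for x in (u, v))
    assert np.allclose(ctx.decrypt_vector(keys.sk, ev.add(cu, cv))[:8],
                       u + v, atol=1e-4)
    diff = ctx.decrypt_vector(keys.sk, ev.sub(cu, cu))[:8]
    assert np.max(np.abs(diff)) < 1e-4
    ident = ev.add(cu, ctx.encrypt_vector(keys.pk, np.zeros(8)))
    assert np.allclose(ctx.decrypt_vector(keys.sk, ident)[:8], u, atol=1e-4)


def test_hom_mult_matches_slotwise_product(tiny_keys):
    """Random u, v: decrypted product within 1e-6 relative of u * v."""
    ctx, keys, ev = tiny_keys
    rng = np.random.default_rng(3)
    u = rng.uniform(0.5, 1.5, 8)
    v = rng.uniform(0.5, 1.5, 8)
    cu = ctx.encrypt_vector(keys.pk, u, scale_bits=40)
    cv = ctx.encrypt_vector(keys.pk, v, scale_bits=40)
    out = ctx.decrypt_vector(keys.sk, ev.mult(cu, cv))[:8]
    assert np.max(np.abs(out - u * v) / np.abs(u * v)) < 1e-6
    # identity: multiply by an encryption of ones
    ones = ctx.encrypt_vector(keys.pk, np.ones(8), scale_bits=40)
    out = ctx.decrypt_vector(keys.sk, ev.mult(cu, ones))[:8]
    assert np.allclose(out, u, atol=1e-6)


def test_mult_plain_matches_slotwise_product(tiny_keys):
    ctx, keys, ev = tiny_keys
    rng = np.random.default_rng(4)
    u = rng.uniform(-1, 1, 8)
    mask = rng.integers(0, 2, 8).astype(float)
    cu = ctx.encrypt_vector(keys.pk, u, scale_bits=35)
    pt = ev.encode(mask, scale_bits=30)
    out = ctx.decrypt_vector(keys.sk, ev.mult_plain(cu, pt))[:8]
    assert np.allclose(out, u * mask, atol=1e-5)
    zeros = ctx.decrypt_vector(keys.sk,
                               ev.mult_plain(cu, ev.encode(np.zeros(8),
                                                           scale_bits=30)))
    assert np.max(np.abs(zeros[:8])) < 1e-5


def test_rescale_semantics(tiny_keys):
    """Rescaling preserves slots while trading modulus for scale; two
    successive rescales equal one combined rescale."""
    ctx, keys, ev = tiny_keys
    ct = ctx.encrypt_vector(keys.pk, np.full(4, 6.0), scale_bits=55)
    a = ev.rescale(ev.rescale(ct, 10), 10)
    b = ev.rescale(ct, 20)
    assert a.level == b.level and a.scale_bits == b.scale_bits
    va = ctx.decrypt_vector(keys.sk, a)[:4]
    vb = ctx.decrypt_vector(keys.sk, b)[:4]
    assert np.allclose(va, 6.0, atol=1e-4)
    assert np.allclose(va, vb, atol=1e-6)


def test_level_accounting(tiny_keys):
    """Each product consumes exactly the rescaled bits of modulus."""
    ctx, keys, ev = tiny_keys
    p = TINY_PARAMS.scale_bits
    ct = ctx.encrypt_vector(keys.pk, np.full(4, 1.1))
    before = ct.level
    ct = ev.mult(ct, ct)
    assert ct.level == before - p and ct.scale_bits == p
    with pytest.raises(ckks.LevelBudgetError):
        deep = ct
        for _ in range(100):
            deep = ev.mult(deep, deep)


def test_rotation_shifts_slots(tiny_keys):
    ctx, keys, ev = tiny_keys
    u = np.arange(8.0)
    cu = ctx.encrypt_vector(keys.pk, u)
    got = ctx.decrypt_vector(keys.sk, ev.rotate(cu, 1))[:8]
    assert np.allclose(got, np.roll(u, -1), atol=1e-4)
    assert ev.rotate(cu, 0) is cu
    inv = ev.rotate(ev.rotate(cu, 3), -3)
    assert np.allclose(ctx.decrypt_vector(keys.sk, inv)[:8], u, atol=1e-4)


def test_missing_rotation_key_raises():
    ctx = ckks.CkksContext(TINY_PARAMS)
    keys = ctx.keygen(shifts=[1])
    ev = ckks.Evaluator(keys.public_material())
    ct = ctx.encrypt_vector(keys.pk, np.arange(4.0))
    with pytest.raises(ckks.MissingRotationKeyError, match="7"):
        ev.rotate(ct, 7)


def test_homomorphic_composition_matches_plaintext(tiny_keys):
    """A mixed add/mult/rotate circuit tracks its plaintext evaluation."""
    ctx, keys, ev = tiny_keys
    rng = np.random.default_rng(5)
    u = rng.uniform(-1, 1, 8)
    v = rng.uniform(-1, 1, 8)
    cu = ctx.encrypt_vector(keys.pk, u)
    cv = ctx.encrypt_vector(keys.pk, v)
    ct = ev.mult(ev.add(cu, cv), ev.rotate(cu, 2))
    ct = ev.add(ct, ev.mult(cv, cv))
    ct = ev.mult(ct, ev.rotate(cv, -1))
    ref = ((u + v) * np.roll(u, -2) + v * v) * np.roll(v, 1)
    got = ctx.decrypt_vector(keys.sk, ct)[:8]
    assert np.max(np.abs(got - ref)) < 1e-3


def test_profile_file_roundtrip(tmp_path):
    import yaml

    doc = {"log_n": 9, "level_bits": 200, "scale_bits": 30,
           "hamming_weight": 16, "sigma_err": 3.2, "seed": 5}
    p = tmp_path / "profile.yaml"
    p.write_text(yaml.safe_dump(doc))
    par = ckks.load_profile(p)
    assert par == ckks.HEParams(**doc)
    assert "exp1" in ckks.PROFILES and ckks.PROFILES["exp1"].log_n == 17


def test_keyset_json_roundtrip():
    par = ckks.HEParams(log_n=5, level_bits=120, scale_bits=25,
                        hamming_weight=8, seed=3)
    ctx = ckks.CkksContext(par)
    ks = ctx.keygen(shifts=[1, 2])
    ks2 = ckks.keyset_from_json(ckks.keyset_to_json(ks))
    assert ks2.params == par
    assert np.array_equal(ks.sk, ks2.sk)
    assert np.array_equal(ks.pk[1].arr, ks2.pk[1].arr)
    assert np.array_equal(ks.rot_keys[2][0].arr, ks2.rot_keys[2][0].arr)
    # the deserialized keys still decrypt
    ct = ctx.encrypt_vector(ks.pk, np.array([1.0, -2.0]))
    out = ckks.CkksContext(par).decrypt_vector(ks2.sk, ct)
    assert np.allclose(out[:2], [1, -2], atol=1e-3)
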