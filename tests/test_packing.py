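"""Packed-matrix operations versus brute-force plaintext linear algebra."""

import numpy as np
import pytest

from hegwas import ckks, packing as pk

TOL = 5e-3  # entrywise tolerance at toy parameters (25-bit scale)


@pytest.fixture()
def masks_for(tiny_keys):
    _, _, ev = tiny_keys

    def make(pm, scale_bits=18):
        return pk.MaskSet(ev, pm.n_pad, pm.cols_per_block, scale_bits)

    return make


def test_matrix_roundtrip_layout(tiny_keys):
    """A 3x3 matrix pads to 4x4 with slot j*4+i holding z_ij; zero and
    random matrices round-trip entrywise."""
    ctx, keys, _ = tiny_keys
    Z = np.arange(9.0).reshape(3, 3)
    pm = pk.encrypt_matrix(ctx, keys.pk, Z)
    assert (pm.n_pad, pm.m_pad) == (4, 4)
    slots = ctx.decrypt_vector(keys.sk, pm.cts[0])
    assert abs(slots[1 * 4 + 2] - Z[2, 1]) < TOL  # column-major check
    assert np.max(np.abs(pk.decrypt_matrix(ctx, keys.sk, pm) - Z)) < TOL

    zero = pk.encrypt_matrix(ctx, keys.pk, np.zeros((4, 4)))
    assert np.max(np.abs(pk.decrypt_matrix(ctx, keys.sk, zero))) < TOL

    rng = np.random.default_rng(0)
    R = rng.normal(size=(8, 16))
    pm = pk.encrypt_matrix(ctx, keys.pk, R)
    assert np.max(np.abs(pk.decrypt_matrix(ctx, keys.sk, pm) - R)) < TOL


def test_matrix_too_tall_rejected(tiny_keys):
    ctx, keys, _ = tiny_keys
    with pytest.raises(ValueError, match="does not fit"):
        pk.encrypt_matrix(ctx, keys.pk, np.zeros((1024, 2)))


def test_column_rotation_matches_roll(tiny_keys, masks_for):
    ctx, keys, ev = tiny_keys
    rng = np.random.default_rng(1)
    Z = rng.normal(size=(8, 8))
    pm = pk.encrypt_matrix(ctx, keys.pk, Z)
    assert pk.column_rot(ev, pm, 0) is pm
    for j in (1, 3):
        got = pk.decrypt_matrix(ctx, keys.sk, pk.column_rot(ev, pm, j))
        assert np.max(np.abs(got - np.roll(Z, -j, axis=1))) < TOL
    # identity matrix, one column left: subdiagonal permutation
    I4 = np.eye(4)
    pmi = pk.encrypt_matrix(ctx, keys.pk, I4)
    got = pk.decrypt_matrix(ctx, keys.sk, pk.column_rot(ev, pmi, 1))
    assert np.max(np.abs(got - np.roll(I4, -1, axis=1))) < TOL


def test_row_rotation_matches_roll(tiny_keys, masks_for):
    ctx, keys, ev = tiny_keys
    rng = np.random.default_rng(2)
    Z = rng.normal(size=(8, 8))
    pm = pk.encrypt_matrix(ctx, keys.pk, Z)
    masks = masks_for(pm)
    assert pk.row_rot(ev, masks, pm, 0) is pm
    assert pk.row_rot(ev, masks, pm, 8) is pm  # full cycle
    for i in (1, 5):
        got = pk.decrypt_matrix(ctx, keys.sk, pk.row_rot(ev, masks, pm, i))
        assert np.max(np.abs(got - np.roll(Z, -i, axis=0))) < TOL


def test_row_and_column_rotations_commute(tiny_keys, masks_for):
    ctx, keys, ev = tiny_keys
    rng = np.random.default_rng(3)
    Z = rng.normal(size=(8, 8))
    pm = pk.encrypt_matrix(ctx, keys.pk, Z)
    masks = masks_for(pm)
    a = pk.row_rot(ev, masks, pk.column_rot(ev, pm, 2), 3)
    b = pk.column_rot(ev, pk.row_rot(ev, masks, pm, 3), 2)
    da = pk.decrypt_matrix(ctx, keys.sk, a)
    db = pk.decrypt_matrix(ctx, keys.sk, b)
    assert np.max(np.abs(da - db)) < 2 * TOL


def test_expdiag_broadcasts_generalized_diagonal(tiny_keys, masks_for):
    ctx, keys, ev = tiny_keys
    rng = np.random.default_rng(4)
    A = rng.normal(size=(8, 4))
    pm = pk.encrypt_matrix(ctx, keys.pk, A)
    masks = masks_for(pm)
    for t in range(4):
        got = pk.decrypt_matrix(ctx, keys.sk, pk.expdiag(ev, masks, pm, t, 4))
        want = A[np.arange(8), (np.arange(8) - t) % 4][:, None] * np.ones(4)
        assert np.max(np.abs(got - want)) < TOL


def test_matmul_AtB_example_and_random(tiny_keys, masks_for):
    ctx, keys, ev = tiny_keys
    # worked 2x2 example
    A = np.array([[1.0, 2.0], [3.0, 4.0]])
    B = np.array([[5.0, 6.0], [7.0, 8.0]])
    pa = pk.encrypt_matrix(ctx, keys.pk, A)
    pb = pk.encrypt_matrix(ctx, keys.pk, B)
    out = pk.matmul_AtB(ev, masks_for(pa), pa, pb, k=2)
    got = pk.decrypt_matrix(ctx, keys.sk, out)
    assert np.allclose(got, [[26, 30], [38, 44]], atol=2e-2)

    # identity A: A^T B = B
    rng = np.random.default_rng(5)
    B = rng.normal(size=(4, 4))
    pa = pk.encrypt_matrix(ctx, keys.pk, np.eye(4))
    pb = pk.encrypt_matrix(ctx, keys.pk, B)
    got = pk.decrypt_matrix(ctx, keys.sk,
                            pk.matmul_AtB(ev, masks_for(pa), pa, pb, k=4))
    assert np.max(np.abs(got - B)) < TOL

    # random weighted product A^T D B
    A = rng.normal(size=(8, 4))
    B = rng.normal(size=(8, 8))
    d = rng.uniform(0.5, 1.5, 8)
    pa = pk.encrypt_matrix(ctx, keys.pk, A)
    pb = pk.encrypt_matrix(ctx, keys.pk, B)
    dv = ctx.encrypt_vector(keys.pk, d)
    ed = [pk.expdiag(ev, masks_for(pa), pa, t, 4) for t in range(4)]
    out = pk.matmul_AtB(ev, masks_for(pb), pa, pb, k=4, weight_vec=dv,
                        expdiags=ed)
    got = pk.decrypt_matrix(ctx, keys.sk, out)[:4, :]
    assert np.max(np.abs(got - A.T @ np.diag(d) @ B)) < 2e-2


def test_matvec_Xbeta(tiny_keys, masks_for):
    ctx, keys, ev = tiny_keys
    rng = np.random.default_rng(6)
    X = rng.normal(size=(8, 4))
    px = pk.encrypt_matrix(ctx, keys.pk, X)
    masks = masks_for(px)
    ed = [pk.expdiag(ev, masks, px, t, 4) for t in range(4)]
    # zero vector in, zero out
    zero = ctx.encrypt_vector(keys.pk, np.zeros(4))
    out = ctx.decrypt_vector(keys.sk, pk.matvec_Xbeta(ev, masks, ed, zero, 4))
    assert np.max(np.abs(out[:8])) < TOL
    # identity X reproduces beta; random X matches the clear product
    beta = rng.normal(size=4)
    bv = ctx.encrypt_vector(keys.pk, beta)
    got = ctx.decrypt_vector(keys.sk, pk.matvec_Xbeta(ev, masks, ed, bv, 4))
    assert np.max(np.abs(got[:8] - X @ beta)) < TOL
    pi = pk.encrypt_matrix(ctx, keys.pk, np.eye(4))
    edi = [pk.expdiag(ev, masks_for(pi), pi, t, 4) for t in range(4)]
    got = ctx.decrypt_vector(keys.sk,
                             pk.matvec_Xbeta(ev, masks, edi, bv, 4))
    assert np.max(np.abs(got[:4] - beta)) < TOL


def test_matvec_Stx_row_replication_and_guard(tiny_keys, masks_for):
    ctx, keys, ev = tiny_keys
    rng = np.random.default_rng(7)
    S = rng.integers(0, 2, size=(8, 8)).astype(float)
    x = rng.normal(size=8)
    ps = pk.encrypt_matrix(ctx, keys.pk, S)
    masks = masks_for(ps)
    xv = ctx.encrypt_vector(keys.pk, x)
    rr = pk.matvec_Stx(ev, masks, ps, xv)
    assert rr.row_replicated
    got = pk.decrypt_row_vector(ctx, keys.sk, rr)
    assert np.max(np.abs(got - S.T @ x)) < TOL
    # every decrypted row equals the vector
    full = np.hstack([ctx.decrypt_vector(keys.sk, rr.cts[0])[:64]
                      .reshape(8, 8).T])
    assert np.max(np.abs(full - np.tile(S.T @ x, (8, 1)))) < TOL
    # all-ones S with unit x gives the row count; zero x gives zero
    ones = pk.encrypt_matrix(ctx, keys.pk, np.ones((8, 8)))
    got = pk.decrypt_row_vector(
        ctx, keys.sk, pk.matvec_Stx(ev, masks, ones,
                                    ctx.encrypt_vector(keys.pk, np.ones(8))))
    assert np.allclose(got, 8.0, atol=1e-2)
    # layout safety: row-replicated output refuses column-major ops
    with pytest.raises(pk.LayoutError):
        pk.column_rot(ev, rr, 1)
    with pytest.raises(pk.LayoutError):
        pk.matmul_AtB(ev, masks, rr, ps, k=4)


def test_diag_AtDC(tiny_keys, masks_for):
    ctx, keys, ev = tiny_keys
    rng = np.random.default_rng(8)
    A = rng.normal(size=(8, 8))
    C = rng.normal(size=(8, 8))
    d = rng.uniform(0.2, 1.0, 8)
    pa = pk.encrypt_matrix(ctx, keys.pk, A)
    pc = pk.encrypt_matrix(ctx, keys.pk, C)
    masks = masks_for(pa)
    dv = ctx.encrypt_vector(keys.pk, d)
    got = pk.decrypt_row_vector(ctx, keys.sk,
                                pk.diag_AtDC(ev, masks, pa, dv, pc))
    assert np.max(np.abs(got - np.diag(A.T @ np.diag(d) @ C))) < TOL
    # D = I, C = A: column squared norms
    got = pk.decrypt_row_vector(
        ctx, keys.sk,
        pk.diag_AtDC(ev, masks, pa, ctx.encrypt_vector(keys.pk, np.ones(8)),
                     pa))
    assert np.max(np.abs(got - (A * A).sum(axis=0))) < 2 * TOL


def test_diag_AtBA(tiny_keys, masks_for):
    ctx, keys, ev = tiny_keys
    rng = np.random.default_rng(9)
    k = 4
    V = np.zeros((8, 8))
    V[:k, :] = rng.normal(size=(k, 8))
    B = rng.normal(size=(k, k))
    B = B + B.T
    pv = pk.encrypt_matrix(ctx, keys.pk, V)
    pb = pk.encrypt_matrix(ctx, keys.pk, np.vstack([B, np.zeros((4, 4))]))
    got = pk.decrypt_row_vector(
        ctx, keys.sk,
        pk.diag_AtBA(ev, masks_for(pv), pv, pb, k, b_masks=masks_for(pb)))
    assert np.max(np.abs(got - np.diag(V[:k].T @ B @ V[:k]))) < 2 * TOL
    # B = I: diag(A^T A)
    pb = pk.encrypt_matrix(ctx, keys.pk, np.vstack([np.eye(4),
                                                    np.zeros((4, 4))]))
    got = pk.decrypt_row_vector(
        ctx, keys.sk,
        pk.diag_AtBA(ev, masks_for(pv), pv, pb, k, b_masks=masks_for(pb)))
    assert np.max(np.abs(got - (V * V).sum(axis=0))) < 2 * TOL


def test_cofactor_polynomial_generation():
    """Cyclic-minor monomials reproduce determinants; the hardcoded k=4
    polynomial equals the generated one."""
    rng = np.random.default_rng(10)
    for k in (2, 3, 4, 5):
        U = rng.normal(size=(k, k))
        val = 0.0
        for sign, factors in pk.cyclic_minor_monomials(k):
            term = sign
            for a, b in factors:
                term = term * U[a, b]
            val += term
        assert np.isclose(val, np.linalg.det(U[1:, 1:]))
    norm = lambda monos: sorted((s, tuple(sorted(f))) for s, f in monos)
    assert norm(pk.hardcoded_f_k4()) == norm(pk.cyclic_minor_monomials(4))


@pytest.mark.parametrize("k", [2, 3, 4])
def test_adjoint_det_matches_cofactor_oracle(tiny_keys, masks_for, k):
    """Encrypted adjugate/determinant of random SPD matrices vs numpy."""
    ctx, keys, ev = tiny_keys
    rng = np.random.default_rng(20 + k)
    M = rng.normal(size=(k, k))
    U = M @ M.T + k * np.eye(k)
    pu = pk.encrypt_matrix(ctx, keys.pk, U)
    adj_pm, det_ct = pk.adjoint_det(ev, masks_for(pu), pu, k)
    adj = pk.decrypt_matrix(ctx, keys.sk, adj_pm)
    det = ctx.decrypt_vector(keys.sk, det_ct)[0]
    exp_det = np.linalg.det(U)
    exp_adj = exp_det * np.linalg.inv(U)
    assert np.max(np.abs(adj - exp_adj)) / np.max(np.abs(exp_adj)) < 1e-3
    assert abs(det - exp_det) / abs(exp_det) < 1e-3


def test_adjoint_closed_forms(tiny_keys, masks_for):
    ctx, keys, ev = tiny_keys
    U = np.array([[2.0, 1.0], [1.0, 2.0]])
    pu = pk.encrypt_matrix(ctx, keys.pk, U)
    adj_pm, det_ct = pk.adjoint_det(ev, masks_for(pu), pu, 2)
    assert np.allclose(pk.decrypt_matrix(ctx, keys.sk, adj_pm),
                       [[2, -1], [-1, 2]], atol=1e-2)
    assert abs(ctx.decrypt_vector(keys.sk, det_ct)[0] - 3.0) < 1e-2
    pu = pk.encrypt_matrix(ctx, keys.pk, np.eye(4))
    adj_pm, det_ct = pk.adjoint_det(ev, masks_for(pu), pu, 4)
    assert np.allclose(pk.decrypt_matrix(ctx, keys.sk, adj_pm), np.eye(4),
                       atol=1e-2)
    assert abs(ctx.decrypt_vector(keys.sk, det_ct)[0] - 1.0) < 1e-2


def test_encrypted_masks_match_plain_masks(tiny_keys):
    """The encrypted-mask switch reproduces the plain-mask row rotation
    (at the cost of ciphertext-ciphertext multiplications)."""
    ctx, keys, ev = tiny_keys
    rng = np.random.default_rng(30)
    Z = rng.normal(size=(8, 8))
    pm = pk.encrypt_matrix(ctx, keys.pk, Z)
    # encrypted masks carry encryption noise, not just rounding, so they
    # need the full working scale where a plain mask gets by with less
    plain = pk.MaskSet(ev, 8, 8, 18)
    encm = pk.MaskSet(ev, 8, 8, 30, encrypted=True,
                      encryptor=lambda pat, s: ctx.encrypt_vector(
                          keys.pk, pat, s))
    a = pk.decrypt_matrix(ctx, keys.sk, pk.row_rot(ev, plain, pm, 3))
    b = pk.decrypt_matrix(ctx, keys.sk, pk.row_rot(ev, encm, pm, 3))
    assert np.max(np.abs(a - b)) < 2 * TOL


def test_adjoint_rejects_bad_k(tiny_keys, masks_for):
    ctx, keys, ev = tiny_keys
    pu = pk.encrypt_matrix(ctx, keys.pk, np.eye(4))
    with pytest.raises(ValueError):
        pk.adjoint_det(ev, masks_for(pu), pu, 1)
    with pytest.raises(ValueError):
        pk.adjoint_det(ev, masks_for(pu), pu, pk.KMAX_ADJOINT + 2)
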