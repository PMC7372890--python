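"""Matrices inside ciphertexts: packing, rotation and the linear algebra
the association pipeline needs.

An n x m matrix is zero-padded to power-of-two dimensions (n_pad, m_pad)
and packed column by column into the slots of one ciphertext -- slot
``j * n_pad + i`` holds entry (i, j) -- replicated to fill all N/2 slots.
When a matrix is too wide for one ciphertext its columns are split across
blocks.  On this layout:

* rotating by ``n_pad * j`` cycles columns ("column rotation");
* rotating by ``i`` plus a pair of complementary row masks cycles rows
  ("row rotation", the masking approach);
* summing the full cycle of strided rotations reduces rows, which yields
  the transposed products A^T B, matrix-vector products, and row-replicated
  diagonal vectors diag(A^T D C) / diag(A^T B A) without ever forming a
  transpose.

The adjugate of a small k x k matrix is evaluated from (k-1)^2 cyclically
rotated copies of its ciphertext: the cofactor of every entry is the *same*
polynomial in the rotated copies' entries (the index-shifting property of
cyclic minors), so one polynomial evaluation produces the whole cofactor
matrix at once.  A final [(-1)^(i+j)] sign mask is needed exactly when k is
even -- for odd k the parity of the cyclic reordering supplies the signs.

Every operation here is tested against a brute-force plaintext
linear-algebra oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .ckks import Ciphertext


class LayoutError(RuntimeError):
    """A row-replicated ciphertext was fed to a column-major operation."""


KMAX_ADJOINT = 5


def next_pow2(x: int) -> int:
    p = 1
    while p < x:
        p <<= 1
    return p


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PackedMatrix:
    """One or more ciphertexts holding a zero-padded column-major matrix."""

    cts: list  # one ciphertext per column block
    n: int
    m: int
    n_pad: int
    m_pad: int               # total padded columns across blocks
    cols_per_block: int
    row_replicated: bool = False

    @property
    def n_blocks(self) -> int:
        return len(self.cts)

    def require_column_major(self, op: str) -> None:
        if self.row_replicated:
            raise LayoutError(
                f"{op} requires column-major layout, but this matrix is "
                "row-replicated (output of a row-summing operation)")

    def like(self, cts, row_replicated: bool | None = None) -> "PackedMatrix":
        return replace(self, cts=list(cts),
                       row_replicated=self.row_replicated
                       if row_replicated is None else row_replicated)


def plan_blocks(n: int, m: int, n_slots: int) -> tuple[int, int, int]:
    """(n_pad, m_pad, cols_per_block) for an n x m matrix in N/2 slots."""
    n_pad, m_pad = next_pow2(n), next_pow2(m)
    if n_pad > n_slots:
        raise ValueError(f"matrix with {n} rows does not fit {n_slots} slots")
    cols = min(m_pad, n_slots // n_pad)
    return n_pad, m_pad, cols


def encrypt_matrix(ctx, pk, Z: np.ndarray, scale_bits: int | None = None
                   ) -> PackedMatrix:
    """Pack and encrypt a real matrix (zero padding, column-major)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n, m = Z.shape
    n_pad, m_pad, cols = plan_blocks(n, m, ctx.params.n_slots)
    cts = []
    for b in range(0, m_pad, cols):
        block = np.zeros((n_pad, cols))
        width = min(m - b, cols) if b < m else 0
        if width > 0:
            block[:n, :width] = Z[:, b : b + width]
        cts.append(ctx.encrypt_vector(pk, block.T.ravel(), scale_bits))
    return PackedMatrix(cts, n, m, n_pad, m_pad, cols)


def decrypt_matrix(ctx, sk, pm: PackedMatrix) -> np.ndarray:
    """Inverse of :func:`encrypt_matrix`: the logical n x m matrix."""
    cols = []
    for ct in pm.cts:
        v = ctx.decrypt_vector(sk, ct)[: pm.n_pad * pm.cols_per_block]
        cols.append(v.reshape(pm.cols_per_block, pm.n_pad).T)
    full = np.hstack(cols)
    return full[: pm.n, : pm.m]


def decrypt_row_vector(ctx, sk, pm: PackedMatrix) -> np.ndarray:
    """The length-m vector held by a row-replicated matrix (row 0)."""
    if not pm.row_replicated:
        raise LayoutError("matrix is not row-replicated")
    cols = []
    for ct in pm.cts:
        v = ctx.decrypt_vector(sk, ct)[: pm.n_pad * pm.cols_per_block]
        cols.append(v.reshape(pm.cols_per_block, pm.n_pad)[:, 0])
    return np.concatenate(cols)[: pm.m]


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


@dataclass
class MaskSet:
    """Cache of encoded (or encrypted) 0/1 and sign mask patterns.

    Masks are public plaintexts encoded at a reduced scale by default;
    setting ``encrypted=True`` (with an ``encryptor`` callback) restores
    the behaviour where masks are themselves ciphertexts, at the cost of a
    full ciphertext-ciphertext multiplication per masking.
    """

    ev: object
    n_pad: int
    m_pad: int               # columns per block (grid width)
    scale_bits: int = 24
    encrypted: bool = False
    encryptor: object = None
    _cache: dict = field(default_factory=dict)

    def _grid(self, fn) -> np.ndarray:
        i, j = np.meshgrid(np.arange(self.n_pad), np.arange(self.m_pad),
                           indexing="ij")
        return fn(i, j).astype(float).T.ravel()  # column-major flatten

    def get(self, key, fn):
        if key not in self._cache:
            pattern = self._grid(fn)
            if self.encrypted:
                self._cache[key] = self.encryptor(pattern, self.scale_bits)
            else:
                self._cache[key] = self.ev.encode(pattern, self.scale_bits)
        return self._cache[key]

    def apply(self, ct, mask):
        """Multiply a ciphertext by a cached mask (plain or encrypted)."""
        if self.encrypted:
            return self.ev.mult(ct, mask, rescale_to=ct.scale_bits)
        return self.ev.mult_plain(ct, mask)

    # pattern constructors ---------------------------------------------

    def rows_below(self, bound: int):
        """1 on rows i < bound (every column)."""
        return self.get(("rows_below", bound), lambda i, j: i < bound)

    def rows_range(self, lo: int, hi: int):
        return self.get(("rows_range", lo, hi),
                        lambda i, j: (i >= lo) & (i < hi))

    def cols_below(self, bound: int):
        """1 on columns j < bound (every row)."""
        return self.get(("cols_below", bound), lambda i, j: j < bound)

    def cols_range(self, lo: int, hi: int):
        return self.get(("cols_range", lo, hi),
                        lambda i, j: (j >= lo) & (j < hi))

    def diag_select(self, t: int, k: int):
        """dmsk_t: 1 at (i, j) with j = (i - t) mod k -- picks diag_t."""
        return self.get(("dmsk", t, k), lambda i, j: (j % k) == ((i - t) % k))

    def column_zero(self, k: int):
        """1 on column 0, rows i < k."""
        return self.get(("col0", k), lambda i, j: (j == 0) & (i < k))

    def checker_sign(self, k: int):
        """[(-1)^(i+j)] on rows i < k (zero elsewhere keeps padding clean)."""
        return self.get(("sign", k),
                        lambda i, j: np.where(i < k, 1.0, 0.0)
                        * np.where((i + j) % 2 == 0, 1.0, -1.0))


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------


def column_rot(ev, pm: PackedMatrix, j: int) -> PackedMatrix:
    """Cyclic left rotation of the matrix columns by j (single block)."""
    pm.require_column_major("column_rot")
    if pm.n_blocks > 1:
        raise ValueError("column_rot on a multi-block matrix: rotate the "
                         "block list instead")
    j = j % pm.cols_per_block
    if j == 0:
        return pm
    return pm.like([ev.rotate(pm.cts[0], pm.n_pad * j)])


def column_rot_block(ev, masks: MaskSet, pm: PackedMatrix, b: int,
                     block_cols: int) -> PackedMatrix:
    """Cyclic left column rotation within the first ``block_cols`` columns.

    For a logical k x k matrix narrower than its padded grid, a plain slot
    rotation would pull padding columns into the cycle; the masked pair
    (forward rotation on columns j < k-b, wraparound on the rest) restores
    the k-cyclic semantics.  Reduces to :func:`column_rot` when the block
    spans the grid.
    """
    pm.require_column_major("column_rot_block")
    k = block_cols
    b = b % k
    if b == 0:
        return pm
    if k == pm.cols_per_block:
        return column_rot(ev, pm, b)
    if pm.n_blocks > 1:
        raise ValueError("column rotation on a multi-block matrix")
    ct = pm.cts[0]
    fwd = masks.apply(ev.rotate(ct, pm.n_pad * b), masks.cols_below(k - b))
    wrap = masks.apply(ev.rotate(ct, pm.n_pad * (b - k)),
                       masks.cols_range(k - b, k))
    return pm.like([ev.add(fwd, wrap)])


def row_rot(ev, masks: MaskSet, pm: PackedMatrix, i: int,
            block_rows: int | None = None) -> PackedMatrix:
    """Cyclic upward rotation of rows by i, via the masking approach.

    ``block_rows`` restricts the cycle to a logical sub-block occupying
    rows 0..block_rows-1 of the grid (used for small k x k matrices living
    in the top rows of a taller grid); it defaults to the full grid height.
    """
    pm.require_column_major("row_rot")
    q = pm.n_pad if block_rows is None else block_rows
    i = i % q
    if i == 0:
        return pm
    out = []
    for ct in pm.cts:
        up = masks.apply(ev.rotate(ct, i), masks.rows_below(q - i))
        wrap = masks.apply(ev.rotate(ct, i - q), masks.rows_range(q - i, q))
        out.append(ev.add(up, wrap))
    return pm.like(out)


# ---------------------------------------------------------------------------
# diagonal extraction / expansion
# ---------------------------------------------------------------------------


def expdiag(ev, masks: MaskSet, pm: PackedMatrix, t: int, k: int
            ) -> PackedMatrix:
    """Expdiag_t(A): every column holds diag_t(A) = (a_{i,(i-t) mod k}).

    A must be single-block with grid width k.  The selected entries (one
    per row) are spread to all columns by log2(k) column-rotation doublings.
    """
    pm.require_column_major("expdiag")
    if pm.n_blocks > 1 or pm.cols_per_block != k:
        raise ValueError("expdiag expects a single block of width k")
    ct = masks.apply(pm.cts[0], masks.diag_select(t % k, k))
    step = 1
    while step < k:
        ct = ev.add(ct, ev.rotate(ct, pm.n_pad * step))
        step <<= 1
    return pm.like([ct])


def fold_rows_to_period(ev, ct: Ciphertext, n_pad: int, k: int) -> Ciphertext:
    """Fold a grid vector with support on rows < k into a k-periodic vector.

    Input slots: value v_i at rows i < k (zeros elsewhere); output: slot s
    holds v_{s mod k}.  Pure rotate-and-add, no masks (relies on the zeros).
    """
    step = k
    while step < n_pad:
        ct = ev.add(ct, ev.rotate(ct, step))
        step <<= 1
    return ct


# ---------------------------------------------------------------------------
# row reductions
# ---------------------------------------------------------------------------


def sum_rows_strided(ev, masks: MaskSet, pm: PackedMatrix, k: int
                     ) -> PackedMatrix:
    """Per-column sums of every k-th row: rows i < k of the result hold
    sum_s M[i + s*k, j]; other rows are cleaned to zero.

    Uses the full cycle of stride-k rotations (windowed sums are only valid
    on the first k rows, hence the cleanup mask)."""
    pm.require_column_major("sum_rows_strided")
    out = []
    for ct in pm.cts:
        acc = ct
        step = k
        while step < pm.n_pad:
            acc = ev.add(acc, ev.rotate(acc, step))
            step <<= 1
        out.append(masks.apply(acc, masks.rows_below(k)))
    return pm.like(out)


def sum_rows_replicate(ev, masks: MaskSet, pm: PackedMatrix) -> PackedMatrix:
    """Column sums, replicated down every row (Alg-8-style reduction).

    The result is *row-replicated*: each decrypted row equals the vector of
    column sums, and the column-major invariants no longer hold, so the
    output is flagged and refused by column-major operations.
    """
    pm.require_column_major("sum_rows_replicate")
    out = []
    for ct in pm.cts:
        acc = ct
        step = 1
        while step < pm.n_pad:
            acc = ev.add(acc, ev.rotate(acc, step))
            step <<= 1
        acc = masks.apply(acc, masks.rows_below(1))  # row 0 holds the sums
        step = 1
        while step < pm.n_pad:
            acc = ev.add(acc, ev.rotate(acc, -step))
            step <<= 1
        out.append(acc)
    return pm.like(out, row_replicated=True)


# ---------------------------------------------------------------------------
# elementwise helpers (legal on any layout)
# ---------------------------------------------------------------------------


def pm_mult(ev, a: PackedMatrix, b: PackedMatrix) -> PackedMatrix:
    return a.like([ev.mult(x, y) for x, y in zip(a.cts, b.cts)],
                  row_replicated=a.row_replicated or b.row_replicated)


def pm_mult_vec(ev, a: PackedMatrix, v: Ciphertext) -> PackedMatrix:
    """Hadamard with a broadcast vector ciphertext (same for each block)."""
    return a.like([ev.mult(x, v) for x in a.cts])


def pm_sub(ev, a: PackedMatrix, b: PackedMatrix) -> PackedMatrix:
    return a.like([ev.sub(x, y) for x, y in zip(a.cts, b.cts)],
                  row_replicated=a.row_replicated or b.row_replicated)


# ---------------------------------------------------------------------------
# products
# ---------------------------------------------------------------------------


def matmul_AtB(ev, masks: MaskSet, pmA: PackedMatrix, pmB: PackedMatrix,
               k: int, weight_vec: Ciphertext | None = None,
               expdiags: list | None = None) -> PackedMatrix:
    """A^T B (or A^T D B with a diagonal weight) on packed matrices.

    A is n x k (single block, grid width k); B is n x m and may span
    blocks.  ``weight_vec`` is an optional n_pad-periodic slot vector
    holding diag(D): weighting costs one extra Hadamard multiplication.
    ``expdiags`` lets callers reuse precomputed Expdiag_t(A).

    Result: k x m, column-major, rows k.. cleaned to zero.
    """
    pmA.require_column_major("matmul_AtB")
    pmB.require_column_major("matmul_AtB")
    if pmA.n_pad != pmB.n_pad:
        raise ValueError("operands must share the row grid")
    if expdiags is None:
        expdiags = [expdiag(ev, masks, pmA, t, k) for t in range(k)]
    out_blocks = []
    for ct_b in pmB.cts:
        b_eff = ev.mult(ct_b, weight_vec) if weight_vec is not None else ct_b
        acc = None
        for t in range(k):
            prod = ev.mult(expdiags[t].cts[0], b_eff)
            single = pmB.like([prod])
            rotated = row_rot(ev, masks, single, t).cts[0]
            acc = rotated if acc is None else ev.add(acc, rotated)
        out_blocks.append(acc)
    M = pmB.like(out_blocks)
    out = sum_rows_strided(ev, masks, M, k)
    return PackedMatrix(out.cts, k, pmB.m, pmB.n_pad, pmB.m_pad,
                        pmB.cols_per_block)


def matvec_Xbeta(ev, masks: MaskSet, expdiags: list, beta: Ciphertext,
                 k: int) -> Ciphertext:
    """X beta from Expdiag_t(X) and a k-periodic replicated beta.

    Returns an n_pad-periodic slot vector: slot (j, i) holds (X beta)_i for
    every column j, ready for the sigmoid and for weighting S or X.
    """
    acc = None
    for t in range(k):
        rb = ev.rotate(beta, -t)
        term = ev.mult(expdiags[t].cts[0], rb)
        acc = term if acc is None else ev.add(acc, term)
    return acc


def matvec_Stx(ev, masks: MaskSet, pmS: PackedMatrix, x: Ciphertext
               ) -> PackedMatrix:
    """S^T x as a row-replicated matrix (one Hadamard + log n rotations).

    ``x`` is an n_pad-periodic slot vector.  The output encrypts a matrix
    whose every row equals S^T x; it is flagged row-replicated and must not
    be consumed by column-major operations.
    """
    pmS.require_column_major("matvec_Stx")
    prod = pm_mult_vec(ev, pmS, x)
    return sum_rows_replicate(ev, masks, prod)


def diag_AtDC(ev, masks: MaskSet, pmA: PackedMatrix, d_vec: Ciphertext,
              pmC: PackedMatrix) -> PackedMatrix:
    """Row-replicated diag(A^T D C) = (sum_i d_i a_ij c_ij)_j."""
    pmA.require_column_major("diag_AtDC")
    pmC.require_column_major("diag_AtDC")
    if pmA.n_pad != pmC.n_pad or pmA.n_blocks != pmC.n_blocks:
        raise ValueError("operands must share the packing layout")
    prod = pm_mult(ev, pmA, pmC)
    prod = pm_mult_vec(ev, prod, d_vec)
    return sum_rows_replicate(ev, masks, prod)


def diag_AtBA(ev, masks: MaskSet, pmA: PackedMatrix, pmB: PackedMatrix,
              k: int, b_masks: MaskSet | None = None) -> PackedMatrix:
    """Row-replicated diag(A^T B A) for a small k x k symmetric B.

    Decomposes B into its k cyclic diagonals:
    diag(A^T B A) = sum_t diag(A^T B_t rho_t(A)) where B_t carries the
    diagonal (b_{i,(i+t) mod k}) that pairs row i with the upward-rotated
    row i+t; each term needs only Hadamard products with the k-periodic
    broadcast of that diagonal and a row rotation of A within its k-row
    block.  A holds a k x m matrix in rows < k of its grid.
    """
    pmA.require_column_major("diag_AtBA")
    pmB.require_column_major("diag_AtBA")
    bm = b_masks if b_masks is not None else masks
    acc = None
    for t in range(k):
        ed = expdiag(ev, bm, pmB, (-t) % k, k).cts[0]
        ed_k = fold_rows_to_period(ev, ed, pmB.n_pad, k)
        rotA = row_rot(ev, masks, pmA, t, block_rows=k)
        term_blocks = [
            ev.mult(ev.mult(a_ct, ed_k), ra_ct)
            for a_ct, ra_ct in zip(pmA.cts, rotA.cts)
        ]
        term = pmA.like(term_blocks)
        acc = term if acc is None else acc.like(
            [ev.add(x, y) for x, y in zip(acc.cts, term.cts)])
    return sum_rows_replicate(ev, masks, acc)


# ---------------------------------------------------------------------------
# adjugate and determinant of a small k x k matrix
# ---------------------------------------------------------------------------


def cyclic_minor_monomials(k: int) -> list[tuple[int, tuple]]:
    """The cofactor polynomial f in cyclic-offset variables u_{a,b}.

    Returns monomials of M_{0,0} = det [u_{a,b}]_{1<=a,b<=k-1} as
    (sign, ((a_1,b_1), ..., (a_{k-1}, b_{k-1}))) with b_i the column paired
    with row a_i = i.  By the index-shifting property, evaluating f on the
    (a,b)-rotated copies of U's ciphertext yields every cyclic minor at
    once.
    """
    if k < 2:
        raise ValueError("adjugate needs k >= 2")
    rows = list(range(1, k))
    monos = []
    for perm in itertools.permutations(rows):
        inv = sum(1 for a, b in itertools.combinations(range(len(perm)), 2)
                  if perm[a] > perm[b])
        sign = -1 if inv % 2 else 1
        monos.append((sign, tuple(zip(rows, perm))))
    return monos


def hardcoded_f_k4() -> list[tuple[int, tuple]]:
    """The printed k=4 cofactor polynomial (3x3 cyclic minor), explicit.

    f = u11 u22 u33 - u11 u23 u32 - u21 u12 u33 + u21 u13 u32
        + u31 u12 u23 - u31 u13 u22
    """
    return [
        (+1, ((1, 1), (2, 2), (3, 3))),
        (-1, ((1, 1), (2, 3), (3, 2))),
        (-1, ((2, 1), (1, 2), (3, 3))),
        (+1, ((2, 1), (1, 3), (3, 2))),
        (+1, ((3, 1), (1, 2), (2, 3))),
        (-1, ((3, 1), (1, 3), (2, 2))),
    ]


def _product_tree(ev, factors: list) -> Ciphertext:
    while len(factors) > 1:
        nxt = [ev.mult(factors[i], factors[i + 1])
               for i in range(0, len(factors) - 1, 2)]
        if len(factors) % 2:
            nxt.append(factors[-1])
        factors = nxt
    return factors[0]


def adjoint_det(ev, masks: MaskSet, pmU: PackedMatrix, k: int,
                compute_det: bool = True
                ) -> tuple[PackedMatrix, Ciphertext | None]:
    """Adjugate (and determinant) of a symmetric k x k packed matrix.

    U occupies rows < k, columns < k of its (single-block) grid.  From the
    (k-1)^2 row/column-rotated copies C_{a,b} the cofactor polynomial is
    evaluated entrywise, producing the whole cofactor matrix in one go; a
    checkerboard sign mask is applied for even k (see module docstring).
    For the symmetric matrices the pipeline produces, the cofactor matrix
    equals the adjugate.  The determinant is recovered as the sum of
    U[:,0] * adj[:,0] (cofactor expansion along the first column),
    broadcast to every slot.
    """
    pmU.require_column_major("adjoint_det")
    if k < 2:
        raise ValueError("adjugate of a 1x1 matrix is not defined here")
    if k > KMAX_ADJOINT:
        raise ValueError(f"adjugate supported up to k={KMAX_ADJOINT}")
    if pmU.n_blocks > 1:
        raise ValueError("adjoint_det expects a single-block matrix")
    if pmU.cols_per_block != next_pow2(k):
        raise ValueError("adjoint_det expects a grid of width next_pow2(k)")
    monos = hardcoded_f_k4() if k == 4 else cyclic_minor_monomials(k)

    copies: dict[tuple[int, int], Ciphertext] = {}
    for a in range(1, k):
        rowed = row_rot(ev, masks, pmU, a, block_rows=k)
        for b in range(1, k):
            copies[(a, b)] = column_rot_block(ev, masks, rowed, b,
                                              block_cols=k).cts[0]

    pos, negv = None, None
    for sign, factors in monos:
        prod = _product_tree(ev, [copies[f] for f in factors])
        if sign > 0:
            pos = prod if pos is None else ev.add(pos, prod)
        else:
            negv = prod if negv is None else ev.add(negv, prod)
    cof = pos if negv is None else (ev.sub(pos, negv) if pos is not None
                                    else ev.neg(negv))
    if k % 2 == 0:
        cof = masks.apply(cof, masks.checker_sign(k))
    pm_adj = pmU.like([cof])

    det = None
    if compute_det:
        prod = ev.mult(pmU.cts[0], cof)
        prod = masks.apply(prod, masks.column_zero(k))
        period = pmU.n_pad * pmU.cols_per_block
        step = 1
        while step < period:
            prod = ev.add(prod, ev.rotate(prod, step))
            step <<= 1
        det = prod
    return pm_adj, det
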