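"""End-to-end encrypted semi-parallel GWAS.

Flow: the data owner standardizes the design, encrypts X (packed matrix),
y (row-broadcast vector) and S (packed matrix blocks); the evaluating
party runs the modified Fisher scoring homomorphically (degree-7 sigmoid,
adjugate update) followed by the inversion-free association stage; the
data owner decrypts only the declared outputs -- squared statistics in the
"exp2" mode, or the numerator/denominator pairs (det(U) c_i^2, d_i) in the
streamlined "exp1" mode -- and converts them to p-values in clear.

The same evaluation code runs against two backends: the real CKKS
evaluator, and a :class:`LevelMeter` that carries only level/scale
bookkeeping.  Running the meter first *is* the depth plan: it returns the
exact modulus consumption of every stage and the exact set of rotation
shifts key generation must provide, so the level parameter L can be chosen
automatically and key material is provably sufficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import packing as pkg
from .approx import SIGMOID7_COEFFS, standardize_design, zsq_to_pvalue
from .ckks import (
    CkksContext,
    Evaluator,
    HEParams,
    KeySet,
    PROFILES,
)
from .packing import MaskSet, PackedMatrix


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything that determines one encrypted run.

    ``profile`` selects a named HE parameter set; when None, toy parameters
    are derived automatically: ``log_n`` as given (or the smallest ring
    that packs S in one block, capped at 2^13) and the level parameter L
    from the depth plan plus ``level_margin``.  ``d_bound_bits`` is the
    public power-of-two bound on the Wald denominators used by Goldschmidt
    division; with a standardized design det(U) ~ 1/alpha at convergence,
    so d <= n/(4 alpha) gives a closed-form public default.
    """

    profile: str | None = None
    log_n: int | None = None
    scale_bits: int = 36
    mask_scale_bits: int = 24
    hamming_weight: int = 64
    sigma_err: float = 3.2
    alpha: float = 8.0
    fisher_iters: int = 4
    mode: str = "exp1"
    gs_iters: int = 5
    d_bound_bits: int | None = None
    standardize: bool = True
    first_iter_shortcut: bool = True
    encrypted_masks: bool = False
    level_margin: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("exp1", "exp2"):
            raise ValueError("mode must be 'exp1' or 'exp2'")
        if self.fisher_iters < 1:
            raise ValueError("need at least one Fisher iteration")

    def resolved_d_bound_bits(self, n: int) -> int:
        if self.d_bound_bits is not None:
            return self.d_bound_bits
        return max(0, math.ceil(math.log2(n / (4.0 * self.alpha))))

    def alpha_log2(self) -> int:
        a = math.log2(self.alpha)
        if a != int(a):
            raise ValueError(
                "the encrypted pipeline folds alpha into the fixed-point "
                "scale and needs it to be a power of two")
        return int(a)


@dataclass
class EncryptedGWASState:
    """Ciphertext artifacts of one run plus the per-artifact level ledger."""

    config: PipelineConfig
    n: int
    m: int
    k: int
    n_pad: int
    ctX: PackedMatrix = None
    ctY: object = None
    ctS: PackedMatrix = None
    ctBeta: object = None
    ctP: object = None
    ctW: object = None
    ctAdjU: PackedMatrix = None
    ctDetU: object = None
    ctC: PackedMatrix = None
    ctD: PackedMatrix = None
    ctNum: PackedMatrix = None
    ctZsq: PackedMatrix = None
    ledger: dict = field(default_factory=dict)
    op_counts: dict = field(default_factory=dict)

    def log_artifact(self, name: str, obj) -> None:
        ct = obj.cts[0] if isinstance(obj, PackedMatrix) else obj
        self.ledger[name] = (ct.level, ct.scale_bits)


@dataclass
class GWASResult:
    """Decrypted per-SNP output: squared statistic, p-value, flag."""

    table: pd.DataFrame        # snp_id, zsq, pval, flag
    mode: str

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# level-meter backend
# ---------------------------------------------------------------------------


@dataclass
class MeterCt:
    level: int
    scale_bits: int
    n_slots: int


@dataclass
class MeterPlain:
    scale_bits: int
    n_slots: int


@dataclass
class _MeterParams:
    log_n: int
    level_bits: int
    scale_bits: int

    @property
    def n_slots(self) -> int:
        return (1 << self.log_n) // 2


class LevelMeter:
    """Backend that mimics context + evaluator, tracking only bookkeeping.

    Mirrors the scale/level arithmetic of :class:`~hegwas.ckks.Evaluator`
    operation for operation; a pipeline run against it yields the exact
    depth ledger and rotation-shift set of the real run.  The starting
    level is set high enough never to bottom out.
    """

    START_LEVEL = 1 << 20

    def __init__(self, log_n: int, scale_bits: int):
        self.params = _MeterParams(log_n, self.START_LEVEL, scale_bits)
        self.min_level = self.START_LEVEL
        self.shifts: set[int] = set()
        self.op_counts: dict[str, int] = {}
        self.stage = ""
        self.stage_floor: dict[str, int] = {}

    # context-side mimics ----------------------------------------------

    def encrypt_vector(self, pk, vec, scale_bits=None):
        return self._new(self.START_LEVEL,
                         self.params.scale_bits if scale_bits is None
                         else scale_bits, len(vec))

    # shared helpers ----------------------------------------------------

    def _new(self, level, scale, n_slots):
        if level < self.min_level:
            self.min_level = level
        cur = self.stage_floor.get(self.stage, self.START_LEVEL)
        self.stage_floor[self.stage] = min(cur, level)
        return MeterCt(level, scale, n_slots)

    def _count(self, op):
        self.op_counts[op] = self.op_counts.get(op, 0) + 1

    def encode(self, vec, scale_bits=None):
        return MeterPlain(self.params.scale_bits if scale_bits is None
                          else scale_bits, len(vec))

    def mod_down(self, ct, level):
        return self._new(level, ct.scale_bits, ct.n_slots)

    def rescale(self, ct, drop):
        self._count("rescale")
        return self._new(ct.level - drop, ct.scale_bits - drop, ct.n_slots)

    def align(self, a, b):
        lvl = min(a.level, b.level)
        return self.mod_down(a, lvl), self.mod_down(b, lvl)

    def add(self, a, b):
        a, b = self.align(a, b)
        if a.scale_bits != b.scale_bits:
            raise ValueError(f"meter: scale mismatch {a.scale_bits} vs "
                             f"{b.scale_bits} at stage '{self.stage}'")
        self._count("add")
        return self._new(a.level, a.scale_bits, max(a.n_slots, b.n_slots))

    sub = add

    def neg(self, a):
        return self._new(a.level, a.scale_bits, a.n_slots)

    def add_const(self, a, c):
        self._count("add")
        return self._new(a.level, a.scale_bits, a.n_slots)

    def mult_pow2(self, a, k):
        return self._new(a.level, a.scale_bits - k, a.n_slots)

    def mult(self, a, b, rescale_to=None):
        a, b = self.align(a, b)
        self._count("mult")
        s = a.scale_bits + b.scale_bits
        target = max(a.scale_bits, b.scale_bits) if rescale_to is None \
            else rescale_to
        ct = self._new(a.level, s, max(a.n_slots, b.n_slots))
        return self.rescale(ct, s - target) if s != target else ct

    def mult_plain(self, a, pt, rescale_to=None):
        self._count("mult_plain")
        s = a.scale_bits + pt.scale_bits
        target = a.scale_bits if rescale_to is None else rescale_to
        ct = self._new(a.level, s, max(a.n_slots, pt.n_slots))
        return self.rescale(ct, s - target) if s != target else ct

    def mult_const(self, a, c, const_bits):
        self._count("mult_const")
        ct = self._new(a.level, a.scale_bits + const_bits, a.n_slots)
        return self.rescale(ct, const_bits)

    def rotate(self, a, r):
        r = r % self.params.n_slots
        if r:
            self.shifts.add(r)
            self._count("rotate")
        return self._new(a.level, a.scale_bits, a.n_slots)

    def zero(self, n_slots):
        return self._new(self.START_LEVEL, self.params.scale_bits, n_slots)


# ---------------------------------------------------------------------------
# homomorphic building blocks
# ---------------------------------------------------------------------------


def _add_matched(ev, a, b):
    """Add after matching scales: the finer-scaled operand is rescaled."""
    if a.scale_bits > b.scale_bits:
        a = ev.rescale(a, a.scale_bits - b.scale_bits)
    elif b.scale_bits > a.scale_bits:
        b = ev.rescale(b, b.scale_bits - a.scale_bits)
    return ev.add(a, b)


def hom_sigmoid7(ev, x):
    """g(x) = 0.5 + t(c1 + c3 t^2) + t^4 * t(c5 + c7 t^2), t = x/8.

    Three ciphertext-ciphertext multiplications deep; the scalar
    coefficients cost ``cb`` extra bits each.  Input and output are at the
    evaluator's canonical scale.
    """
    cb = 24  # scalar-coefficient precision
    c0, c1, c3, c5, c7 = SIGMOID7_COEFFS
    t = ev.mult_pow2(x, -3)           # x/8, scale p+3
    t2 = ev.mult(t, t)
    t4 = ev.mult(t2, t2)
    a1 = ev.add_const(ev.mult_const(t2, c3, cb), c1)
    a2 = ev.add_const(ev.mult_const(t2, c7, cb), c5)
    w1 = ev.mult(t, a1)
    w2 = ev.mult(t, a2)
    g = ev.add_const(ev.add(w1, ev.mult(t4, w2)), c0)
    return ev.rescale(g, 3)           # back to scale p


def hom_goldschmidt(ev, d, gs_iters: int, bound_bits: int):
    """1/d for 0 < d <= 2^bound_bits, as a product of 1 + e^(2^i) factors."""
    nhat = ev.mult_pow2(d, 1 - bound_bits)          # 2 d / bound in (0, 2)
    e = ev.add_const(ev.neg(nhat), 1.0)
    r = ev.add_const(e, 1.0)
    for _ in range(1, gs_iters):
        e = ev.mult(e, e)
        r = ev.mult(r, ev.add_const(e, 1.0))
    return ev.mult_pow2(r, 1 - bound_bits)          # (2/bound) / nhat


# ---------------------------------------------------------------------------
# the pipeline proper
# ---------------------------------------------------------------------------


def _encrypt_inputs(ctx, pk, X, y, S, config, st: EncryptedGWASState):
    st.ctX = pkg.encrypt_matrix(ctx, pk, X)
    n_pad = st.ctX.n_pad
    y_pad = np.zeros(n_pad)
    y_pad[: len(y)] = y
    st.ctY = ctx.encrypt_vector(pk, y_pad)
    st.ctS = pkg.encrypt_matrix(ctx, pk, S)
    if st.ctS.n_pad != n_pad:
        raise ValueError("X and S must share the sample dimension")
    st.n_pad = n_pad


def _evaluate(ev, st: EncryptedGWASState, config: PipelineConfig):
    """Run the homomorphic algorithm on an encrypted state (any backend)."""
    k, n_pad = st.k, st.n_pad
    # masks are public encoded plaintexts by default; the encrypted-mask
    # switch routes them through the mask encryptor the state carries
    enc = getattr(st, "mask_encryptor", None) if config.encrypted_masks \
        else None
    if config.encrypted_masks and enc is None:
        raise ValueError("encrypted_masks requires a state prepared with a "
                         "mask encryptor (see run_encrypted_gwas)")
    masksX = MaskSet(ev, n_pad, st.ctX.cols_per_block,
                     config.mask_scale_bits, encrypted=enc is not None,
                     encryptor=enc)
    masksS = MaskSet(ev, n_pad, st.ctS.cols_per_block,
                     config.mask_scale_bits, encrypted=enc is not None,
                     encryptor=enc)
    a_log2 = config.alpha_log2()

    ev.stage = "expdiag_X"
    expdiags = [pkg.expdiag(ev, masksX, st.ctX, t, k) for t in range(k)]

    def xt_times(vec_ct):
        """X^T v for a broadcast vector: k-periodic replicated result."""
        wrapped = st.ctX.like([vec_ct])
        prod = pkg.matmul_AtB(ev, masksX, st.ctX, wrapped, k,
                              expdiags=expdiags)
        return pkg.fold_rows_to_period(ev, prod.cts[0], n_pad, k)

    def adj_times(adj_pm, vec_k):
        """adj(U) @ v from Expdiag_t(adjU) and a k-periodic vector."""
        acc = None
        for t in range(k):
            ed = pkg.expdiag(ev, masksX, adj_pm, t, k).cts[0]
            ed_k = pkg.fold_rows_to_period(ev, ed, n_pad, k)
            term = ev.mult(ed_k, ev.rotate(vec_k, -t))
            acc = term if acc is None else ev.add(acc, term)
        return acc

    beta = None if config.first_iter_shortcut else ev.zero(k)
    p_ct = w_ct = U = adjU = None
    start = 0
    if config.first_iter_shortcut:
        # beta^(0) = 0 implies p = 1/2 and W = I/4 exactly (g(0) = 1/2), so
        # the first update needs no sigmoid: U = X^T X / 4 and the residual
        # is X^T (y - 1/2).
        ev.stage = "fisher_0"
        U0 = pkg.matmul_AtB(ev, masksX, st.ctX, st.ctX, k, expdiags=expdiags)
        U0 = U0.like([ev.mult_pow2(U0.cts[0], -2)])
        adj0, _ = pkg.adjoint_det(ev, masksX, U0, k, compute_det=False)
        ymh = ev.add_const(st.ctY, -0.5)
        r = xt_times(ymh)
        beta = ev.mult_pow2(adj_times(adj0, r), a_log2)
        start = 1
    for it in range(start, config.fisher_iters):
        ev.stage = f"fisher_{it}"
        xb = pkg.matvec_Xbeta(ev, masksX, expdiags, beta, k)
        p_ct = hom_sigmoid7(ev, xb)
        w_ct = ev.mult(p_ct, ev.add_const(ev.neg(p_ct), 1.0))
        U = pkg.matmul_AtB(ev, masksX, st.ctX, st.ctX, k, weight_vec=w_ct,
                           expdiags=expdiags)
        adjU, _ = pkg.adjoint_det(ev, masksX, U, k, compute_det=False)
        ymp = ev.sub(ev.mod_down(st.ctY, p_ct.level), p_ct)
        r = xt_times(ymp)
        step = ev.mult_pow2(adj_times(adjU, r), a_log2)
        beta = _add_matched(ev, beta, step)
    st.ctBeta = beta
    st.log_artifact("beta", beta)

    # final analysis at the converged coefficients
    ev.stage = "analysis"
    xb = pkg.matvec_Xbeta(ev, masksX, expdiags, beta, k)
    p_ct = hom_sigmoid7(ev, xb)
    w_ct = ev.mult(p_ct, ev.add_const(ev.neg(p_ct), 1.0))
    U = pkg.matmul_AtB(ev, masksX, st.ctX, st.ctX, k, weight_vec=w_ct,
                       expdiags=expdiags)
    adjU, detU = pkg.adjoint_det(ev, masksX, U, k, compute_det=True)
    ymp = ev.sub(ev.mod_down(st.ctY, p_ct.level), p_ct)
    st.ctP, st.ctW, st.ctAdjU, st.ctDetU = p_ct, w_ct, adjU, detU
    st.log_artifact("p", p_ct)
    st.log_artifact("adjU", adjU)
    st.log_artifact("detU", detU)

    ev.stage = "association"
    V = pkg.matmul_AtB(ev, masksS, st.ctX, st.ctS, k, weight_vec=w_ct,
                       expdiags=expdiags)
    c_rr = pkg.matvec_Stx(ev, masksS, st.ctS, ymp)
    dsws = pkg.diag_AtDC(ev, masksS, st.ctS, w_ct, st.ctS)
    dvav = pkg.diag_AtBA(ev, masksS, V, adjU, k, b_masks=masksX)
    det_sws = pkg.pm_mult_vec(ev, dsws, detU)
    d = pkg.pm_sub(ev, det_sws, dvav)
    csq = c_rr.like([ev.mult(ct, ct) for ct in c_rr.cts])
    num = pkg.pm_mult_vec(ev, csq, detU)
    st.ctC, st.ctD, st.ctNum = c_rr, d, num
    st.log_artifact("c", c_rr)
    st.log_artifact("d", d)
    st.log_artifact("num", num)

    if config.mode == "exp2":
        ev.stage = "goldschmidt"
        bb = config.resolved_d_bound_bits(st.n)
        zsq_cts = []
        for d_ct, n_ct in zip(d.cts, num.cts):
            inv = hom_goldschmidt(ev, d_ct, config.gs_iters, bb)
            zsq_cts.append(ev.mult(ev.mod_down(n_ct, inv.level), inv))
        st.ctZsq = d.like(zsq_cts)
        st.log_artifact("zsq", st.ctZsq)
    st.op_counts = dict(ev.op_counts)
    return st


# ---------------------------------------------------------------------------
# planning and the public entry points
# ---------------------------------------------------------------------------


def choose_log_n(n: int, m: int, cap: int = 13) -> int:
    """Smallest ring packing S in one block (up to the cap)."""
    need = pkg.next_pow2(n) * pkg.next_pow2(m)
    log_n = 4
    while (1 << log_n) // 2 < need and log_n < cap:
        log_n += 1
    return log_n


def plan_depth(config: PipelineConfig, n: int, m: int, k: int) -> dict:
    """Static depth/shift plan: the pipeline run against the level meter.

    Returns the per-stage modulus consumption (bits), the total, the level
    parameter the run needs (total + working scale + margin), the rotation
    shifts, and homomorphic operation counts.  Exact by construction --
    the meter executes the same code path as the real evaluator.
    """
    log_n = config.log_n or choose_log_n(n, m)
    meter = LevelMeter(log_n, config.scale_bits)
    st = EncryptedGWASState(config, n, m, k, pkg.next_pow2(n))
    n_pad, m_pad, cols = pkg.plan_blocks(n, m, meter.params.n_slots)
    st.ctX = PackedMatrix([meter.encrypt_vector(None, np.zeros(n_pad * k))],
                          n, k, n_pad, pkg.next_pow2(k), pkg.next_pow2(k))
    st.ctY = meter.encrypt_vector(None, np.zeros(n_pad))
    st.ctS = PackedMatrix(
        [meter.encrypt_vector(None, np.zeros(n_pad * cols))
         for _ in range(0, m_pad, cols)], n, m, n_pad, m_pad, cols)
    if config.encrypted_masks:
        st.mask_encryptor = lambda pattern, scale_bits: meter.encrypt_vector(
            None, pattern, scale_bits)
    _evaluate(meter, st, config)
    stages = {}
    prev = LevelMeter.START_LEVEL
    for stage, floor in meter.stage_floor.items():
        stages[stage] = max(0, prev - floor)
        prev = min(prev, floor)
    total = LevelMeter.START_LEVEL - meter.min_level
    return {
        "log_n": log_n,
        "stage_bits": stages,
        "total_bits": total,
        "required_level": total + config.scale_bits + config.level_margin,
        "shifts": sorted(meter.shifts),
        "op_counts": dict(meter.op_counts),
        "artifact_levels": {name: LevelMeter.START_LEVEL - lvl
                            for name, (lvl, _) in st.ledger.items()},
    }


def build_params(config: PipelineConfig, n: int, m: int, k: int
                 ) -> tuple[HEParams, dict]:
    """HE parameters for a run: named profile or auto-leveled toy set."""
    plan = plan_depth(config, n, m, k)
    if config.profile is not None:
        return PROFILES[config.profile], plan
    params = HEParams(log_n=plan["log_n"],
                      level_bits=plan["required_level"],
                      scale_bits=config.scale_bits,
                      hamming_weight=config.hamming_weight,
                      sigma_err=config.sigma_err,
                      seed=config.seed)
    return params, plan


def keygen_for(config: PipelineConfig, n: int, m: int, k: int
               ) -> tuple[CkksContext, KeySet, dict]:
    params, plan = build_params(config, n, m, k)
    ctx = CkksContext(params)
    keys = ctx.keygen(shifts=plan["shifts"])
    return ctx, keys, plan


def run_encrypted_gwas(config: PipelineConfig, dataset, ctx: CkksContext,
                       keys: KeySet) -> EncryptedGWASState:
    """Encrypt a dataset and evaluate the full pipeline homomorphically.

    ``dataset`` is a :class:`~hegwas.simulate.GWASDataset`; standardization
    (including the alpha calibration) happens in clear on the data-owner
    side before encryption when ``config.standardize`` is set.
    """
    X = standardize_design(dataset.X, dataset.y, config.alpha) \
        if config.standardize else dataset.X
    st = EncryptedGWASState(config, dataset.n, dataset.m, dataset.k,
                            pkg.next_pow2(dataset.n))
    _encrypt_inputs(ctx, keys.pk, X, dataset.y, dataset.S, config, st)
    if config.encrypted_masks:
        st.mask_encryptor = lambda pattern, scale_bits: ctx.encrypt_vector(
            keys.pk, pattern, scale_bits)
    ev = Evaluator(keys.public_material())
    return _evaluate(ev, st, config)


def decrypt_results(st: EncryptedGWASState, ctx: CkksContext, keys: KeySet,
                    snp_ids=None) -> GWASResult:
    """Decrypt the declared outputs and convert to p-values in clear.

    exp1: decrypts (num, d) and divides in clear; SNPs with d <= 0 are
    flagged.  exp2: decrypts the squared statistics directly; negative or
    non-finite values are flagged.  Flagged SNPs keep their row with a
    missing p-value.
    """
    m = st.m
    ids = snp_ids if snp_ids is not None else [f"snp{j}" for j in range(m)]
    if st.config.mode == "exp1":
        num = pkg.decrypt_row_vector(ctx, keys.sk, st.ctNum)
        den = pkg.decrypt_row_vector(ctx, keys.sk, st.ctD)
        flag = ~(den > 0)
        zsq = np.full(m, np.nan)
        zsq[~flag] = num[~flag] / den[~flag]
    else:
        zsq = pkg.decrypt_row_vector(ctx, keys.sk, st.ctZsq)
        flag = ~np.isfinite(zsq) | (zsq < 0)
    pval = np.full(m, np.nan)
    pval[~flag] = zsq_to_pvalue(np.maximum(zsq[~flag], 0.0))
    table = pd.DataFrame({"snp_id": ids, "zsq": zsq, "pval": pval,
                          "flag": flag.astype(int)})
    return GWASResult(table=table, mode=st.config.mode)
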