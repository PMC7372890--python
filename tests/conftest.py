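"""Shared fixtures: toy-parameter key material and small pipeline runs.

Key generation and encrypted pipeline evaluations are the expensive parts
of the suite, so they are session-scoped and shared; every test reads from
them without mutating ciphertexts in place.
"""

import numpy as np
import pytest

from hegwas import approx, ckks, pipeline, simulate

#: Toy parameters used across unit tests: 512-dimensional ring, 256 slots.
TINY_PARAMS = ckks.HEParams(log_n=9, level_bits=600, scale_bits=30,
                            hamming_weight=32, seed=7)


@pytest.fixture(scope="session")
def tiny_keys():
    """Context, keys (every rotation shift) and evaluator at toy params."""
    ctx = ckks.CkksContext(TINY_PARAMS)
    keys = ctx.keygen(shifts=range(1, TINY_PARAMS.n_slots))
    ev = ckks.Evaluator(keys.public_material())
    return ctx, keys, ev


@pytest.fixture(scope="session")
def bench_dataset():
    """The default synthetic benchmark: n=245, k=4, m=2000, 20 effects."""
    ds, truth = simulate.generate_dataset(simulate.benchmark_spec(seed=1))
    return ds, truth


@pytest.fixture(scope="session")
def small_dataset():
    """A small, well-conditioned study for fast pipeline comparisons."""
    spec = simulate.SimSpec(n=32, m=16, k=4, effect_snps=((5, 0.8),), seed=1)
    ds, _ = simulate.generate_dataset(spec)
    return ds


def _run_tiny_mode(ds, mode, gs_iters=6):
    cfg = pipeline.PipelineConfig(log_n=10, scale_bits=30,
                                  mask_scale_bits=20, hamming_weight=64,
                                  fisher_iters=2, mode=mode,
                                  gs_iters=gs_iters, seed=11)
    ctx, keys, plan = pipeline.keygen_for(cfg, ds.n, ds.m, ds.k)
    st = pipeline.run_encrypted_gwas(cfg, ds, ctx, keys)
    res = pipeline.decrypt_results(st, ctx, keys, ds.snp_ids)
    Xs = approx.standardize_design(ds.X, ds.y, cfg.alpha)
    ref = approx.modified_semiparallel(
        Xs, ds.y, ds.S, alpha=cfg.alpha, iters=cfg.fisher_iters, mode=mode,
        gs_iters=gs_iters, d_bound=2.0 ** cfg.resolved_d_bound_bits(ds.n))
    return {"config": cfg, "ctx": ctx, "keys": keys, "plan": plan,
            "state": st, "result": res, "reference": ref}


@pytest.fixture(scope="session")
def tiny_pipeline_exp1(small_dataset):
    """One encrypted exp1 run (n=32, m=16, ring 2^10) plus its reference."""
    return _run_tiny_mode(small_dataset, "exp1")


@pytest.fixture(scope="session")
def tiny_pipeline_exp2(small_dataset):
    """The matching exp2 run (homomorphic Goldschmidt division)."""
    return _run_tiny_mode(small_dataset, "exp2")
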