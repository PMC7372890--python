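"""Encrypted small-matrix algebra: the adjugate trick, step by step.

Matrix inversion is not polynomial, so the pipeline never inverts U = X^T W X
under encryption; it computes the adjugate and determinant instead, which
are polynomial in the entries, and carries det(U) through the statistics.
This script encrypts a 4x4 SPD matrix, computes adj(U) and det(U)
homomorphically, and checks adj(U) U = det(U) I after decryption.
"""

import numpy as np

from hegwas import ckks, packing as pk

params = ckks.HEParams(log_n=9, level_bits=300, scale_bits=25,
                       hamming_weight=32, seed=1)
ctx = ckks.CkksContext(params)
keys = ctx.keygen(shifts=range(1, params.n_slots))
ev = ckks.Evaluator(keys.public_material())

rng = np.random.default_rng(0)
M = rng.normal(size=(4, 4))
U = M @ M.T + 4 * np.eye(4)
print("U =\n", np.round(U, 3))

pm = pk.encrypt_matrix(ctx, keys.pk, U)
masks = pk.MaskSet(ev, pm.n_pad, pm.cols_per_block, scale_bits=18)
adj_pm, det_ct = pk.adjoint_det(ev, masks, pm, k=4)

adj = pk.decrypt_matrix(ctx, keys.sk, adj_pm)
det = ctx.decrypt_vector(keys.sk, det_ct)[0]
print("\ndecrypted adj(U) =\n", np.round(adj, 3))
print(f"decrypted det(U) = {det:.4f}  (numpy: {np.linalg.det(U):.4f})")
resid = np.max(np.abs(adj @ U - det * np.eye(4)))
print(f"max |adj(U) U - det(U) I| = {resid:.2e}")
print("The identity holds to encryption noise: dividing adj(U) by det(U) "
      "\nwould reproduce U^-1, but the pipeline never needs that division.")
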