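"""Synthetic genotype-phenotype data with planted SNP effects.

The generator emulates the structure of the randomized scalability
experiment the pipeline was profiled on: covariates drawn uniformly from
fixed intervals (height-, weight- and age-like ranges by default), a
uniform-random binary SNP matrix, and a binary phenotype drawn from a
logistic model so that parameter-recovery questions are well-posed.  SNP
effects are planted at chosen columns with chosen sizes and returned as a
ground-truth table; with no planted effects the dataset is an exact null.

Covariates are written raw (their natural ranges); standardization is a
downstream analysis step, not a property of the files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_COVARIATE_RANGES = ((150.0, 200.0), (40.0, 100.0), (20.0, 80.0))
DEFAULT_COVARIATE_NAMES = ("height", "weight", "age")


@dataclass
class GWASDataset:
    """Plaintext inputs: design X (with intercept), phenotype y, SNPs S."""

    X: np.ndarray            # n x k, first column all ones
    y: np.ndarray            # n, binary 0/1
    S: np.ndarray            # n x m, SNP codes
    snp_ids: list[str]
    covariate_names: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def m(self) -> int:
        return self.S.shape[1]


@dataclass
class SimSpec:
    """Specification of one synthetic study.

    ``effect_snps`` maps SNP column indices to log-odds effect sizes (on the
    raw SNP coding); ``covariate_effects`` are log-odds per standard
    deviation of each covariate (applied to internally z-scored covariates
    so the phenotype model is invariant to the raw ranges).
    """

    n: int = 245
    m: int = 2000
    k: int = 4
    covariate_ranges: tuple = DEFAULT_COVARIATE_RANGES
    snp_coding: str = "binary"          # "binary" | "additive012"
    maf_range: tuple = (0.05, 0.5)
    effect_snps: tuple = ()             # ((index, effect_size), ...)
    covariate_effects: tuple = (0.3, -0.2, 0.1)
    intercept: float = 0.0
    seed: int = 1

    def __post_init__(self):
        if min(self.n, self.m, self.k) <= 0:
            raise ValueError("n, m, k must be positive")
        if self.k != len(self.covariate_ranges) + 1:
            raise ValueError("k must equal number of covariates plus intercept")
        if len(self.covariate_effects) != self.k - 1:
            raise ValueError("need one covariate effect per covariate")
        if self.snp_coding not in ("binary", "additive012"):
            raise ValueError("snp_coding must be 'binary' or 'additive012'")
        if any(lo >= hi for lo, hi in self.covariate_ranges):
            raise ValueError("covariate ranges must be nonempty intervals")
        idx = [i for i, _ in self.effect_snps]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate effect SNP indices")
        if len(idx) > self.m:
            raise ValueError("more planted effects than SNPs")
        if any(i < 0 or i >= self.m for i in idx):
            raise ValueError("effect SNP index out of range")


def default_effects(m: int, count: int = 20, lo: float = 0.5,
                    hi: float = 1.5, seed: int = 12345) -> tuple:
    """Evenly spaced planted effects with alternating signs in [lo, hi]."""
    rng = np.random.default_rng(seed)
    idx = np.linspace(0, m - 1, count).astype(int)
    sizes = rng.uniform(lo, hi, size=count) * np.where(np.arange(count) % 2, -1, 1)
    return tuple((int(i), float(s)) for i, s in zip(idx, sizes))


def benchmark_spec(seed: int = 1, n: int = 245, m: int = 2000,
                   n_effects: int = 20) -> SimSpec:
    """The default synthetic benchmark: n=245, k=4, m=2000, 20 effects."""
    return SimSpec(n=n, m=m, effect_snps=default_effects(m, n_effects),
                   seed=seed)


def generate_dataset(spec: SimSpec) -> tuple[GWASDataset, pd.DataFrame]:
    """Draw one dataset; returns it with the ground-truth effect table."""
    rng = np.random.default_rng(spec.seed)
    n, m, k = spec.n, spec.m, spec.k
    X0 = np.column_stack([rng.uniform(lo, hi, size=n)
                          for lo, hi in spec.covariate_ranges])
    if spec.snp_coding == "binary":
        S = rng.integers(0, 2, size=(n, m)).astype(float)
    else:
        maf = rng.uniform(*spec.maf_range, size=m)
        S = rng.binomial(2, maf, size=(n, m)).astype(float)
    Z0 = (X0 - X0.mean(axis=0)) / X0.std(axis=0)
    delta = np.zeros(m)
    for i, eff in spec.effect_snps:
        delta[i] = eff
    eta = spec.intercept + Z0 @ np.asarray(spec.covariate_effects) + S @ delta
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    X = np.column_stack([np.ones(n), X0])
    ids = [f"snp{j}" for j in range(m)]
    truth = pd.DataFrame({"snp_id": ids, "effect": delta,
                          "is_causal": delta != 0.0})
    names = list(DEFAULT_COVARIATE_NAMES[: k - 1])
    if len(names) < k - 1:
        names += [f"cov{j}" for j in range(len(names), k - 1)]
    return GWASDataset(X=X, y=y, S=S, snp_ids=ids,
                       covariate_names=names), truth


# ---------------------------------------------------------------------------
# file round-trip (TSV formats shared with the CLI)
# ---------------------------------------------------------------------------


def write_dataset(ds: GWASDataset, out_dir) -> dict[str, Path]:
    """Write covariates/phenotype/SNPs as TSV; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"covariates": out / "covariates.tsv",
             "phenotype": out / "phenotype.tsv",
             "snps": out / "snps.tsv"}
    pd.DataFrame(ds.X[:, 1:], columns=ds.covariate_names).to_csv(
        paths["covariates"], sep="\t", index=False)
    pd.DataFrame({"phenotype": ds.y.astype(int)}).to_csv(
        paths["phenotype"], sep="\t", index=False)
    pd.DataFrame(ds.S, columns=ds.snp_ids).to_csv(
        paths["snps"], sep="\t", index=False,
        float_format="%g")
    return paths


def read_dataset(covariates, phenotype, snps, header: bool = True
                 ) -> GWASDataset:
    """Read the TSV triple back into a dataset (intercept added here).

    ``header=False`` accepts headerless files with the same layout.
    Row-count mismatches raise with the offending file named.
    """
    hdr = 0 if header else None
    cov = pd.read_csv(covariates, sep="\t", header=hdr)
    phe = pd.read_csv(phenotype, sep="\t", header=hdr)
    snp = pd.read_csv(snps, sep="\t", header=hdr)
    n = len(cov)
    for name, frame in (("phenotype", phe), ("snps", snp)):
        if len(frame) != n:
            raise ValueError(
                f"{name} file has {len(frame)} rows, covariates have {n}")
    if phe.shape[1] != 1:
        raise ValueError("phenotype file must have exactly one column")
    y = phe.iloc[:, 0].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        bad = int(np.flatnonzero(~np.isin(y, (0.0, 1.0)))[0])
        raise ValueError(f"phenotype row {bad} is not binary 0/1")
    X = np.column_stack([np.ones(n), cov.to_numpy(dtype=float)])
    names = [str(c) for c in cov.columns] if header \
        else [f"cov{j}" for j in range(cov.shape[1])]
    ids = [str(c) for c in snp.columns] if header \
        else [f"snp{j}" for j in range(snp.shape[1])]
    return GWASDataset(X=X, y=y, S=snp.to_numpy(dtype=float),
                       snp_ids=ids, covariate_names=names)
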