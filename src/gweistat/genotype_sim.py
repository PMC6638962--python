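"""Genotype simulation under Hardy-Weinberg equilibrium.

Each locus is an i.i.d. dosage vector with ``g ~ Binomial(2, maf)``.  The
allele-frequency spectrum is uniform on [0.05, 0.5] by default (a flat
common-variant spectrum) or a rescaled Beta; linkage disequilibrium is
emulated with a latent AR(1) Gaussian copula per haplotype, which leaves
the per-locus marginal law exactly HWE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

#: Default Beta(a, b) shape for the "rare-skewed" MAF spectrum, rescaled to
#: [0.05, 0.5].  A declared stand-in: configurable per call.
BETA_MAF_SHAPE = (1.0, 3.0)
#: Default AR(1) correlation of the latent haplotype process under LD.
LD_RHO = 0.8

CODINGS = ("additive", "dominant", "recessive")


@dataclass
class GenotypeMatrix:
    """Dosage matrix (n samples x L loci) with its generating MAFs."""

    dosages: np.ndarray
    maf: np.ndarray
    ld_structure: str = "none"
    coding: str = "additive"
    variant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.variant_ids:
            self.variant_ids = [f"snp{j + 1}" for j in range(self.dosages.shape[1])]

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def L(self) -> int:
        return self.dosages.shape[1]


def draw_mafs(
    L: int,
    rng: np.random.Generator,
    dist: str = "uniform",
    low: float = 0.05,
    high: float = 0.5,
    beta_shape: tuple[float, float] = BETA_MAF_SHAPE,
) -> np.ndarray:
    """Allele-frequency spectrum: uniform or rescaled Beta on [low, high]."""
    if not (0.0 < low < high <= 0.5):
        raise ValueError("need 0 < low < high <= 0.5")
    if dist == "uniform":
        return rng.uniform(low, high, size=L)
    if dist == "beta":
        a, b = beta_shape
        return low + (high - low) * rng.beta(a, b, size=L)
    raise ValueError(f"unknown MAF distribution {dist!r}")


def simulate_genotypes(
    n: int,
    L: int,
    seed: int | np.random.Generator,
    maf_dist: str = "uniform",
    maf: np.ndarray | None = None,
    ld: str = "none",
    ld_rho: float = LD_RHO,
    beta_shape: tuple[float, float] = BETA_MAF_SHAPE,
) -> GenotypeMatrix:
    """Simulate an n x L HWE dosage matrix.

    ``ld='none'`` draws every locus independently as Binomial(2, maf_l).
    ``ld='ar1'`` runs two latent standard-normal AR(1) chains (one per
    haplotype) across the loci of each sample and thresholds each at the
    maf-matched normal quantile; dosages are the sum of the two Bernoulli
    alleles, so each locus is marginally HWE but adjacent loci correlate.
    """
    if n < 1 or L < 1:
        raise ValueError("need n >= 1 and L >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if maf is None:
        maf = draw_mafs(L, rng, dist=maf_dist, beta_shape=beta_shape)
    else:
        maf = np.asarray(maf, dtype=float).ravel()
        if maf.shape[0] != L:
            raise ValueError("maf vector length must equal L")
        if np.any((maf <= 0) | (maf > 0.5)):
            raise ValueError("maf values must lie in (0, 0.5]")

    if ld == "none":
        dos = rng.binomial(2, maf[None, :], size=(n, L)).astype(np.int8)
        structure = "none"
    elif ld == "ar1":
        if not (0.0 <= ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        thresh = norm.ppf(maf)  # allele present iff latent < quantile
        dos = np.zeros((n, L), dtype=np.int8)
        scale = np.sqrt(1.0 - ld_rho**2)
        for _hap in range(2):
            z = np.empty((n, L))
            z[:, 0] = rng.standard_normal(n)
            for j in range(1, L):
                z[:, j] = ld_rho * z[:, j - 1] + scale * rng.standard_normal(n)
            dos += (z < thresh[None, :]).astype(np.int8)
        structure = f"ar1(rho={ld_rho})"
    else:
        raise ValueError(f"unknown LD structure {ld!r}")
    return GenotypeMatrix(dosages=dos, maf=maf, ld_structure=structure)


def code_genotype(dosage: np.ndarray, coding: str = "additive") -> np.ndarray:
    """Recode minor-allele counts: additive (0,1,2), dominant (0,1,1),
    recessive (0,0,1)."""
    d = np.asarray(dosage)
    if coding == "additive":
        return d.astype(float)
    if coding == "dominant":
        return (d >= 1).astype(float)
    if coding == "recessive":
        return (d == 2).astype(float)
    raise ValueError(f"unknown coding {coding!r}")
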