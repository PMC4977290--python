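"""Synthetic SNP genotypes and phenotypes for genomic-prediction studies.

Real rice diversity panels used in genomic selection are a few hundred
accessions genotyped at tens of thousands of biallelic SNP after a MAF >
1% filter.  This module emulates that shape without external data:
genotypes are Hardy-Weinberg binomial draws (dosage ~ Binomial(2, q_j)
with marker allele frequency q_j uniform over a MAF window, markers
independent), and phenotypes follow Y = g + eps where the true genetic
value g is

* ``additive``            — a sparse linear combination of causal dosages,
* ``pairwise_epistatic``  — additive plus products of centered dosages at
  random causal marker pairs (first-order epistasis), mixed so a chosen
  fraction of genetic variance is interaction variance,
* ``gp_gaussian_kernel``  — a draw from the Gaussian-kernel Gaussian
  process, i.e. g ~ N(0, K_h) (all interaction orders implicitly).

Residual variance is set from the realized var(g) so that var(g)/var(Y)
matches the target heritability in expectation.  True genetic values and
the causal-effect ledger are returned so true prediction accuracy (TPA)
is computable — something real data never permits.

Everything is reproducible bit-for-bit from ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.distance import pdist, squareform

from .kernels import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_study",
    "tpa",
    "RICE_PRESETS",
]

#: (n accessions, p SNP) shapes matching published rice diversity panels
RICE_PRESETS = {
    "temperate_japonica": (230, 22691),
    "tropical_japonica_small": (167, 16444),
    "tropical_japonica_large": (188, 38390),
}

ARCHITECTURES = ("additive", "pairwise_epistatic", "gp_gaussian_kernel")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n: int = 200
    p: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    architecture: str = "additive"
    n_causal: int = 100
    heritability_target: float = 0.5
    interaction_fraction: float = 0.0
    decay_h: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise SimulationError(
                f"maf_range must lie in (0.01, 0.5] with low > 0.01 "
                f"(the MAF > 1% filter), got {self.maf_range}"
            )
        if self.architecture not in ARCHITECTURES:
            raise SimulationError(f"unknown architecture {self.architecture!r}")
        if not (0.0 < self.heritability_target < 1.0):
            raise SimulationError("heritability_target must be in (0, 1)")
        if not (0.0 <= self.interaction_fraction <= 1.0):
            raise SimulationError("interaction_fraction must be in [0, 1]")
        if self.n < 2 or self.p < 1:
            raise SimulationError("need n >= 2 and p >= 1")
        if self.architecture != "gp_gaussian_kernel" and self.n_causal > self.p:
            raise SimulationError("n_causal cannot exceed the marker count p")
        if self.architecture == "gp_gaussian_kernel" and not (self.decay_h or 0) > 0:
            raise SimulationError("gp_gaussian_kernel needs decay_h > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedStudy:
    genotypes: GenotypeMatrix
    phenotypes: np.ndarray
    true_genetic_values: np.ndarray
    true_effects: dict[str, pd.DataFrame]
    config: SimulationConfig
    realized_h2: float = field(default=float("nan"))


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Hardy-Weinberg dosage matrix with per-marker MAF in ``maf_range``.

    Each marker draws its allele frequency uniformly in ``maf_range`` and
    dosages are i.i.d. Binomial(2, q_j) across accessions (no linkage
    disequilibrium).  Markers whose *realized* frequency falls at or below
    the 1% MAF filter are redrawn, so the returned matrix always passes the
    filter it emulates.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n, config.p
    lo, hi = config.maf_range
    X = np.empty((n, p))
    todo = np.arange(p)
    while todo.size:
        q = rng.uniform(lo, hi, size=todo.size)
        X[:, todo] = rng.binomial(2, q, size=(n, todo.size))
        freq = X[:, todo].mean(axis=0) / 2.0
        realized = np.minimum(freq, 1.0 - freq)
        todo = todo[realized <= 0.01]
    return GenotypeMatrix(
        X,
        coding="raw_012",
        accession_ids=[f"acc{i:04d}" for i in range(n)],
        marker_ids=[f"snp{j:05d}" for j in range(p)],
    )


def _standardize(g: np.ndarray) -> np.ndarray:
    sd = g.std(ddof=1)
    if sd == 0:
        raise SimulationError("degenerate genetic values (zero variance); "
                              "increase n or n_causal")
    return (g - g.mean()) / sd


def _additive_component(Xc: np.ndarray, config: SimulationConfig, rng) -> tuple[np.ndarray, pd.DataFrame]:
    idx = rng.choice(Xc.shape[1], size=config.n_causal, replace=False)
    beta = rng.standard_normal(config.n_causal)
    g = Xc[:, idx] @ beta
    ledger = pd.DataFrame({"marker_index": idx, "effect": beta})
    return g, ledger


def _epistatic_component(Xc: np.ndarray, config: SimulationConfig, rng) -> tuple[np.ndarray, pd.DataFrame]:
    p = Xc.shape[1]
    j = rng.choice(p, size=config.n_causal, replace=False)
    k = rng.choice(p, size=config.n_causal, replace=False)
    clash = j == k
    while clash.any():
        k[clash] = rng.choice(p, size=int(clash.sum()))
        clash = j == k
    w = rng.standard_normal(config.n_causal)
    g = (Xc[:, j] * Xc[:, k]) @ w
    ledger = pd.DataFrame({"marker_index_1": j, "marker_index_2": k, "effect": w})
    return g, ledger


def simulate_phenotypes(X: GenotypeMatrix, config: SimulationConfig) -> SimulatedStudy:
    """Phenotypes Y = g + eps under the configured genetic architecture.

    The genetic value is standardized to unit sample variance (component-
    wise for the epistatic mixture, weighted sqrt(1-f) / sqrt(f) so the
    interaction fraction of genetic variance is ``interaction_fraction``);
    residuals are i.i.d. N(0, var(g) (1 - h2) / h2) so the realized signal
    fraction matches ``heritability_target`` up to Monte-Carlo noise.
    Interactions use centered dosage products, keeping the additive /
    interaction variance partition interpretable.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    Xc = X.values - X.values.mean(axis=0)
    effects: dict[str, pd.DataFrame] = {}

    if config.architecture in ("additive", "pairwise_epistatic"):
        g_add, effects["additive"] = _additive_component(Xc, config, rng)
        g = _standardize(g_add)
        f_int = config.interaction_fraction if config.architecture == "pairwise_epistatic" else 0.0
        if f_int > 0:
            g_epi, effects["interactions"] = _epistatic_component(Xc, config, rng)
            g = np.sqrt(1.0 - f_int) * g + np.sqrt(f_int) * _standardize(g_epi)
    else:  # gp_gaussian_kernel
        D = squareform(pdist(Xc, metric="sqeuclidean"))
        Kh = np.exp(-config.decay_h * D)
        d, Q = scipy.linalg.eigh(Kh)
        d = np.clip(d, 0.0, None)
        g = _standardize(Q @ (np.sqrt(d) * rng.standard_normal(config.n)))
        effects["gp"] = pd.DataFrame({"decay_h": [config.decay_h]})

    var_g = float(np.var(g, ddof=1))
    h2 = config.heritability_target
    sigma2_e = var_g * (1.0 - h2) / h2
    eps = rng.normal(0.0, np.sqrt(sigma2_e), size=config.n)
    y = g + eps
    realized = var_g / float(np.var(y, ddof=1))
    return SimulatedStudy(
        genotypes=X,
        phenotypes=y,
        true_genetic_values=g,
        true_effects=effects,
        config=config,
        realized_h2=realized,
    )


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Convenience: genotypes then phenotypes from one config."""
    return simulate_phenotypes(simulate_genotypes(config), config)


def tpa(predicted: np.ndarray, true_genetic: np.ndarray) -> float:
    """True prediction accuracy: Pearson correlation with true genetic values.

    Only available in simulation — with real data only the noisy relative
    prediction accuracy (correlation with observed phenotypes) can be
    measured, which attenuates differences between methods.
    """
    from .tuning_eval import rpa

    return rpa(predicted, true_genetic)
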