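"""Synthetic arm-based meta-analysis data.

Generates study-level binary data from the same hierarchical process the
model assumes: per study a latent pair of logit event probabilities is
drawn from a bivariate normal with means (mu0, mu1), SDs (sigma0, sigma1)
and between-arm correlation rho, then arm event counts are binomial.  The
default parameter values (mu0 = 0, mu1 = 0.5, sigma0 = sigma1 = 1,
rho = 0.7, 50 studies of 50 + 50 subjects) define the reference simulation
conditions used throughout the tests.

Also ships a frozen five-study fixture (the printed example dataset) so
the small-sample analysis is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data import MetaDataset, StudyRecord

__all__ = ["SimParams", "simulate_meta", "table1_fixture", "nested_subsets"]


@dataclass(frozen=True)
class SimParams:
    """True parameter values for a simulated meta-analysis."""

    mu0: float = 0.0
    mu1: float = 0.5
    sigma0: float = 1.0
    sigma1: float = 1.0
    rho: float = 0.7
    n_studies: int = 50
    arm_size: int | tuple[int, int] = 50
    seed: int = 0

    def __post_init__(self):
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie strictly inside (-1, 1)")
        if self.sigma0 < 0 or self.sigma1 < 0:
            raise ValueError("between-study SDs must be nonnegative")
        if self.n_studies < 1:
            raise ValueError("n_studies must be positive")
        sizes = self.arm_sizes
        if sizes[0] < 1 or sizes[1] < 1:
            raise ValueError("arm sizes must be positive")

    @property
    def arm_sizes(self) -> tuple[int, int]:
        if isinstance(self.arm_size, (tuple, list)):
            return int(self.arm_size[0]), int(self.arm_size[1])
        return int(self.arm_size), int(self.arm_size)


def latent_logits(p: SimParams) -> np.ndarray:
    """The (N, 2) latent logit pairs :func:`simulate_meta` would draw.

    Uses the same generator state and draw order as :func:`simulate_meta`,
    so the returned array matches the latents behind a simulated dataset
    with the same parameters.
    """
    rng = np.random.default_rng(p.seed)
    mean = np.array([p.mu0, p.mu1])
    cov = np.array([
        [p.sigma0 ** 2, p.rho * p.sigma0 * p.sigma1],
        [p.rho * p.sigma0 * p.sigma1, p.sigma1 ** 2],
    ])
    return rng.multivariate_normal(mean, cov, size=p.n_studies, method="svd")


def simulate_meta(p: SimParams, name: str = "simulated") -> MetaDataset:
    """Simulate a two-arm meta-analysis dataset.

    Latent logits come from the bivariate normal random-effects
    distribution; counts are Binomial(n_k, expit(latent)).  The same seed
    reproduces the dataset byte-for-byte (the latent and count streams are
    drawn from one generator in a fixed order).
    """
    rng = np.random.default_rng(p.seed)
    mean = np.array([p.mu0, p.mu1])
    cov = np.array([
        [p.sigma0 ** 2, p.rho * p.sigma0 * p.sigma1],
        [p.rho * p.sigma0 * p.sigma1, p.sigma1 ** 2],
    ])
    theta = rng.multivariate_normal(mean, cov, size=p.n_studies, method="svd")
    probs = expit(theta)
    n0, n1 = p.arm_sizes
    x = rng.binomial([n0, n1], probs)
    studies = tuple(
        StudyRecord(f"Study {i + 1}", x0=int(x[i, 0]), n0=n0,
                    x1=int(x[i, 1]), n1=n1)
        for i in range(p.n_studies))
    return MetaDataset(studies, name=name)


#: (x0, n0, x1, n1) of the frozen five-study example.
_TABLE1 = (
    (21, 50, 17, 50),
    (9, 50, 17, 50),
    (13, 50, 29, 50),
    (9, 50, 15, 50),
    (30, 50, 42, 50),
)


def table1_fixture() -> MetaDataset:
    """The five-study example dataset (50 subjects per arm).

    Generated once from the reference simulation conditions (mu0 = 0,
    mu1 = 0.5, sigma = 1, rho = 0.7) and frozen, so analyses of it are
    exactly reproducible.
    """
    studies = tuple(
        StudyRecord(f"Study {i + 1}", x0=x0, n0=n0, x1=x1, n1=n1)
        for i, (x0, n0, x1, n1) in enumerate(_TABLE1))
    return MetaDataset(studies, name="five-study example")


def nested_subsets(d: MetaDataset, sizes) -> list[MetaDataset]:
    """Prefix subsets of a dataset, e.g. the first 5, 10, ... studies.

    Order is preserved (any randomization of study order happens upstream,
    once).  Sizes exceeding N are rejected.
    """
    sizes = list(sizes)
    if any(s < 1 for s in sizes):
        raise ValueError("subset sizes must be positive")
    if max(sizes) > len(d):
        raise ValueError(f"subset size {max(sizes)} exceeds N = {len(d)}")
    return [MetaDataset(d.studies[:s], name=f"{d.name}[:{s}]") for s in sizes]
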