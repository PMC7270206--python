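"""Synthetic expression data with planted ground truth.

Generates binary-labelled Gaussian expression matrices in which a small
set of informative genes carries a class-mean shift of ``effect_size``
within-class standard deviations while all other genes are pure noise.
Presets mirror the shapes of public benchmark panels used for gene
selection (a 70-gene breast-cancer signature panel, a 22-variable
cardiovascular risk panel, and a high-dimensional toxicogenomics slice).
Everything is deterministic per seed, so tests and simulations can plant
a signal and check it is recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import ExpressionDataset
from .errors import ConfigError

__all__ = ["SyntheticSpec", "generate", "replicate", "preset", "preset_names", "PRESETS"]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    Parameters
    ----------
    m, n
        Sample and gene counts.
    n_informative
        Number of genes carrying class signal.
    effect_size
        Class-mean separation of informative genes, in units of the
        within-class standard deviation (which is 1).
    class_balance
        Fraction of samples in the positive class; the positive count is
        round(m * class_balance), assigned in seeded shuffled order so
        both classes are always present.
    correlation
        Optional equicorrelation among the informative genes' noise
        (block-correlated signal); 0 = independent.
    seed
        Generator seed.
    """

    m: int
    n: int
    n_informative: int = 0
    effect_size: float = 2.0
    class_balance: float = 0.5
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n:
            raise ConfigError(
                f"n_informative={self.n_informative} exceeds n={self.n}"
            )
        if not 0.0 < self.class_balance < 1.0:
            raise ConfigError(f"class_balance must lie in (0, 1), got {self.class_balance}")
        if self.effect_size < 0:
            raise ConfigError(f"effect_size must be >= 0, got {self.effect_size}")
        if not 0.0 <= self.correlation < 1.0:
            raise ConfigError(f"correlation must lie in [0, 1), got {self.correlation}")
        if self.m < 4 or self.n < 1:
            raise ConfigError(f"need m >= 4 samples and n >= 1 genes, got {self.m}x{self.n}")


PRESETS: dict[str, SyntheticSpec] = {
    # 144 samples x 70 genes, like a breast-cancer signature panel
    "nki70-like": SyntheticSpec(m=144, n=70, n_informative=5, effect_size=2.0),
    # 300 samples x 22 genes, like a cardiovascular risk-factor panel
    "regicor-like": SyntheticSpec(m=300, n=22, n_informative=3, effect_size=2.0),
    # 116 samples x 1000 genes, a trimmed high-dimensional microarray slice
    "ratinvitro-like-small": SyntheticSpec(m=116, n=1000, n_informative=10, effect_size=2.0),
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def preset(name: str, **overrides) -> SyntheticSpec:
    """A named preset spec, optionally with fields overridden (e.g. seed)."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; available: {preset_names()}") from None
    return replace(base, **overrides)


def generate(
    spec: SyntheticSpec, noise_seed: int | None = None
) -> tuple[ExpressionDataset, list[str]]:
    """Draw one dataset; returns (dataset, informative gene identifiers).

    Labels: round(m * class_balance) positives in seeded shuffled order.
    Informative genes: Normal(+effect/2, 1) in class 1, Normal(-effect/2, 1)
    in class 0, optionally equicorrelated within the informative block.
    Noise genes: Normal(0, 1) regardless of class.  Informative genes are
    placed at seeded random column positions.

    The generator keeps two independent random streams: a *structure*
    stream (which columns are informative) and a *noise* stream (labels
    and expression values), both derived from ``spec.seed``.  Passing
    `noise_seed` replaces only the noise stream, producing a replicate
    dataset with the same planted structure — see :func:`replicate`.
    """
    struct_ss, noise_ss = np.random.SeedSequence(spec.seed).spawn(2)
    rng_struct = np.random.default_rng(struct_ss)
    rng = np.random.default_rng(
        noise_ss if noise_seed is None else np.random.SeedSequence(noise_seed)
    )

    n_pos = int(round(spec.m * spec.class_balance))
    n_pos = min(max(n_pos, 1), spec.m - 1)  # both classes always present
    labels = np.zeros(spec.m, dtype=int)
    labels[rng.permutation(spec.m)[:n_pos]] = 1

    matrix = rng.standard_normal((spec.m, spec.n))
    informative = np.sort(rng_struct.permutation(spec.n)[: spec.n_informative])
    if spec.n_informative:
        p = spec.n_informative
        if spec.correlation > 0:
            cov = np.full((p, p), spec.correlation)
            np.fill_diagonal(cov, 1.0)
            matrix[:, informative] = rng.multivariate_normal(
                np.zeros(p), cov, size=spec.m, method="cholesky"
            )
        shift = np.where(labels == 1, spec.effect_size / 2.0, -spec.effect_size / 2.0)
        matrix[:, informative] += shift[:, None]

    width = len(str(spec.n))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(spec.n)]
    data = ExpressionDataset(matrix=matrix, labels=labels, gene_ids=gene_ids)
    return data, [gene_ids[i] for i in informative]


def replicate(spec: SyntheticSpec, noise_seed: int) -> tuple[ExpressionDataset, list[str]]:
    """Fresh draw from the same planted structure (new labels and noise).

    The informative columns stay where ``spec`` put them, so a gene subset
    selected on one draw can be validated on a replicate draw.
    """
    return generate(spec, noise_seed=noise_seed)
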