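"""Synthetic groups of expression matrices with shared modular correlation.

Each group owns a template: a partition of the genes into coexpression
modules with per-gene signs.  A replicate draws one latent factor per module
and sets

    x_g = s_g * a * f_{m(g)} + eps_g,      eps_g ~ N(0, sigma^2) i.i.d.

so same-module genes correlate (|r| -> a^2 / (a^2 + sigma^2)) while
cross-module genes are uncorrelated.  Replicates of a group share the
template but draw independent factors and noise, which makes their
coexpression networks topologically similar.

Two finite-sample controls keep the topology of a replicate faithful to its
template rather than to sampling accidents.  The factor matrix is
orthonormalized across samples (QR), so module factors have exactly zero
sample correlation; and each gene's noise vector is projected orthogonal to
the factors (and rescaled), so a spurious cross-module gene correlation can
arise only from noise-noise interaction (sd ~ sigma^2/(a^2+sigma^2)/sqrt(n)),
never from a chance factor alignment.  Without these controls the sample
factor correlations (sd ~ 1/sqrt(n_samples)) dominate the inter-module merge
structure and swamp the group signal at realistic sample counts.

Groups are told apart by a label-free topological summary only through
permutation-invariant structure, so distinct groups must differ in more than
which genes are coassigned: here each group has its own number of modules
(group g gets n_modules + g * module_count_step), emulating stress responses
that engage characteristically different numbers of coexpression modules.
The long-lived component count of a replicate's network is its group's
module count, which is exactly the kind of feature 0-dimensional persistence
detects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "ModuleStructure",
    "generate_group_template",
    "simulate_expression",
    "simulate_study",
]

_TEMPLATE_STREAM = 0
_REPLICATE_STREAM = 1


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for the generator.

    Defaults mirror a four-group stress-response design: 4 groups of 5
    replicate experiments, 200 genes by 40 samples each, factor loading 0.9
    and noise standard deviation 0.3 (so same-module genes reach
    |r| ~ 0.81/0.90 = 0.9).  Group g is partitioned into
    ``n_modules + g * module_count_step`` modules.
    """

    n_groups: int = 4
    networks_per_group: int = 5
    n_genes: int = 200
    n_samples: int = 40
    n_modules: int = 5
    module_count_step: int = 2
    within_module_loading: float = 0.9
    noise_sd: float = 0.3
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_groups", "networks_per_group", "n_genes", "n_samples", "n_modules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.module_count_step < 0:
            raise ValueError("module_count_step must be nonnegative")
        if self.max_modules > self.n_genes:
            raise ValueError("module count cannot exceed n_genes in any group")
        if self.within_module_loading > 0 and self.max_modules >= self.n_samples:
            raise ValueError(
                "need n_samples > module count to draw orthonormal module factors"
            )
        if not 0 <= self.within_module_loading <= 1:
            raise ValueError("within_module_loading must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.within_module_loading == 0 and self.noise_sd == 0:
            raise ValueError(
                "loading and noise cannot both be 0: every gene would be constant"
            )

    def modules_in_group(self, group_index: int) -> int:
        return self.n_modules + group_index * self.module_count_step

    @property
    def max_modules(self) -> int:
        return self.modules_in_group(self.n_groups - 1)

    @property
    def expected_within_module_abs_r(self) -> float:
        """Large-sample |Pearson r| between genes of the same module."""
        a2 = self.within_module_loading**2
        return a2 / (a2 + self.noise_sd**2)


@dataclass(frozen=True)
class ModuleStructure:
    """A group's template: module assignment and sign per gene."""

    assignment: np.ndarray  # (n_genes,) int, module index per gene
    sign: np.ndarray  # (n_genes,) values in {-1, +1}

    def __post_init__(self) -> None:
        if self.assignment.shape != self.sign.shape:
            raise ValueError("assignment and sign must have equal length")
        if not np.all(np.isin(self.sign, (-1, 1))):
            raise ValueError("sign entries must be +1 or -1")

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max()) + 1

    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_modules)


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    # Counter-based derivation: any (seed, stream...) tuple is reproducible
    # on its own, so subsets of the study can be regenerated independently.
    return np.random.default_rng(np.random.SeedSequence((config.seed, *stream)))


def generate_group_template(
    config: SimulationConfig, group_index: int
) -> ModuleStructure:
    """Draw the module partition and gene signs for one group.

    Genes are assigned uniformly at random to the group's modules (every
    module is guaranteed at least one gene) and signs are fair coin flips.
    Deterministic given (seed, group_index); distinct groups draw distinct
    partitions and have distinct module counts.
    """
    if not 0 <= group_index < config.n_groups:
        raise ValueError(
            f"group_index {group_index} out of range [0, {config.n_groups})"
        )
    rng = _rng(config, _TEMPLATE_STREAM, group_index)
    k, n = config.modules_in_group(group_index), config.n_genes
    assignment = rng.integers(0, k, size=n)
    # top up empty modules from the largest one
    for m in range(k):
        if not np.any(assignment == m):
            donor = np.bincount(assignment, minlength=k).argmax()
            assignment[np.flatnonzero(assignment == donor)[0]] = m
    sign = rng.choice((-1, 1), size=n)
    return ModuleStructure(assignment=assignment, sign=sign)


def _orthonormal_factors(
    rng: np.random.Generator, k: int, s: int
) -> np.ndarray:
    """k module factors over s samples with exact zero sample correlation."""
    G = rng.standard_normal((s, k))
    Q, R = np.linalg.qr(G)
    Q = Q * np.where(np.diag(R) >= 0, 1.0, -1.0)  # fix QR sign ambiguity
    return (Q * np.sqrt(s)).T  # rows have unit sample variance


def simulate_expression(
    template: ModuleStructure,
    config: SimulationConfig,
    replicate_seed: "int | np.random.SeedSequence",
) -> ExpressionMatrix:
    """Draw one expression matrix (genes x samples) from a group template.

    Noise is drawn i.i.d. Gaussian, then projected orthogonal to the module
    factors and rescaled to keep its sample variance, so cross-module sample
    correlations carry no factor leakage (see module docstring).  With a
    zero loading there are no factors and the noise is returned as drawn.
    """
    rng = np.random.default_rng(replicate_seed)
    n, s = config.n_genes, config.n_samples
    if len(template.assignment) != n:
        raise ValueError("template gene count does not match config.n_genes")
    k = template.n_modules
    a = config.within_module_loading
    noise = rng.standard_normal((n, s))
    if a > 0:
        F = _orthonormal_factors(rng, k, s)
        # project noise off the factor span; restore its original norm
        coeff = noise @ F.T / s  # (n, k) sample covariances with unit factors
        resid = noise - coeff @ F
        norms = np.linalg.norm(resid, axis=1, keepdims=True)
        scale = np.linalg.norm(noise, axis=1, keepdims=True) / np.where(
            norms > 0, norms, 1.0
        )
        noise = resid * scale
        signal = template.sign[:, None] * a * F[template.assignment]
    else:
        signal = 0.0
    values = signal + config.noise_sd * noise
    width = len(str(n))
    gene_ids = [f"g{i + 1:0{max(4, width)}d}" for i in range(n)]
    sample_ids = [f"s{j + 1:03d}" for j in range(s)]
    return ExpressionMatrix(gene_ids, sample_ids, values)


def simulate_study(
    config: SimulationConfig,
) -> list[tuple[str, ExpressionMatrix]]:
    """Generate the full labeled study: n_groups x networks_per_group matrices.

    Returns (group_label, matrix) tuples in (group, replicate) order; labels
    are "group0" ... "group{n_groups-1}".
    """
    out: list[tuple[str, ExpressionMatrix]] = []
    for g in range(config.n_groups):
        template = generate_group_template(config, g)
        for r in range(config.networks_per_group):
            seed = np.random.SeedSequence((config.seed, _REPLICATE_STREAM, g, r))
            out.append((f"group{g}", simulate_expression(template, config, seed)))
    return out
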