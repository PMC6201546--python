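"""Synthetic expression generators with known statistical structure.

Two generators cover the inference scenarios: a Gaussian block-correlation
matrix (planted co-expression modules, optionally with anti-correlated
nodes, for power / clustering / consensus checks) and cross-sectionally
correlated AR(1) rows (temporal autocorrelation, for the blocked
bootstrap).  Everything is fully determined by (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ExpressionMatrix

__all__ = ["FixtureSpec", "make_block_expression", "make_ar1_series"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted-structure generators.

    within_module_correlation / between_module_correlation are target
    pairwise Pearson correlations of the latent Gaussian; sign_pattern is
    the fraction of nodes whose profile is negated (turning their
    within-module correlations negative); ar_phi is the AR(1) coefficient
    for time-series fixtures.
    """

    n_nodes: int = 60
    n_samples: int = 100
    n_modules: int = 2
    within_module_correlation: float = 0.7
    between_module_correlation: float = 0.0
    sign_pattern: float = 0.0
    ar_phi: float = 0.0
    seed: int = 0

    def module_assignment(self) -> np.ndarray:
        """Planted block labels: nodes split into n_modules contiguous blocks."""
        blocks = np.array_split(np.arange(self.n_nodes), self.n_modules)
        return np.concatenate([np.full(len(b), i) for i, b in enumerate(blocks)])


def _block_correlation(spec: FixtureSpec) -> np.ndarray:
    labels = spec.module_assignment()
    same = labels[:, None] == labels[None, :]
    C = np.where(same, spec.within_module_correlation,
                 spec.between_module_correlation).astype(float)
    np.fill_diagonal(C, 1.0)
    return C


def _check_psd(C: np.ndarray) -> None:
    evals = np.linalg.eigvalsh(C)
    if evals.min() < -1e-8:
        raise ValueError(
            f"implied correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {evals.min():.3e})"
        )


def make_block_expression(spec: FixtureSpec) -> ExpressionMatrix:
    """Multivariate-normal draws with block-structured correlation.

    Each of n_modules equal-sized blocks has pairwise correlation
    within_module_correlation inside and between_module_correlation
    across blocks.  A sign_pattern fraction of nodes is negated,
    exercising signed wTO with genuinely negative correlations.
    """
    C = _block_correlation(spec)
    _check_psd(C)
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(spec.n_nodes))
    X = L @ rng.standard_normal((spec.n_nodes, spec.n_samples))
    if spec.sign_pattern > 0:
        n_flip = int(round(spec.sign_pattern * spec.n_nodes))
        flip = rng.choice(spec.n_nodes, size=n_flip, replace=False)
        X[flip] *= -1.0
    node_ids = tuple(f"N{i:04d}" for i in range(spec.n_nodes))
    sample_ids = tuple(f"S{j:04d}" for j in range(spec.n_samples))
    return ExpressionMatrix(node_ids, sample_ids, X)


def make_ar1_series(spec: FixtureSpec) -> ExpressionMatrix:
    """Stationary AR(1) rows, x_t = phi x_{t-1} + e_t with unit innovations.

    Rows are cross-correlated through the same block structure as
    make_block_expression (applied to the innovations), so the temporal
    and the cross-sectional correlation components coexist as they do in
    replicate-free environmental time series.  Marginal row variance is
    1 / (1 - phi^2).
    """
    phi = spec.ar_phi
    if not abs(phi) < 1:
        raise ValueError(f"AR(1) coefficient must satisfy |phi| < 1, got {phi}")
    C = _block_correlation(spec)
    _check_psd(C)
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(spec.n_nodes))
    innov = L @ rng.standard_normal((spec.n_nodes, spec.n_samples))
    X = np.empty_like(innov)
    scale0 = 1.0 / np.sqrt(1.0 - phi ** 2)  # start in the stationary law
    X[:, 0] = innov[:, 0] * scale0
    for t in range(1, spec.n_samples):
        X[:, t] = phi * X[:, t - 1] + innov[:, t]
    node_ids = tuple(f"N{i:04d}" for i in range(spec.n_nodes))
    sample_ids = tuple(f"T{j:04d}" for j in range(spec.n_samples))
    return ExpressionMatrix(node_ids, sample_ids, X, is_time_series=True)
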