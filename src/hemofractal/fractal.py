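"""Information dimension and multifractal spectrum of blood-flow measures.

The flow distribution of a vascular tree is treated as a measure on the
generation cross-sections of the tree. At generation ``n`` the carry-forward
cross-section carries flow probabilities ``p_i`` over a nominal ``2**n``
cells, and the cross-section entropy is ``S(n) = -sum p_i ln p_i``. The
*flow fractal (information) dimension* ``D_Q`` is the slope of ``S(n)``
against ``ln 2**n = n ln 2``: it is 1 for perfectly even splitting at every
bifurcation and shrinks toward 0 as the flow distribution grows more
heterogeneous.

The multifractal spectrum generalises this: for each moment order ``q`` the
normalised measures ``mu_i(q) = p_i**q / sum_j p_j**q`` weight the
cross-section toward its concentrated (q > 0) or rarefied (q < 0) parts, and

    f(q)     = slope of  -sum mu_i ln mu_i  vs  n ln 2
    alpha(q) = slope of  -sum mu_i ln p_i   vs  n ln 2

trace the singularity spectrum ``f(alpha)``. Its width ``delta_alpha =
alpha_max - alpha_min`` measures the degree of multifractality (flow
heterogeneity); its height ``f_max = f(0)`` depends only on which cells of
the nominal binary grid are occupied, i.e. on tree structure. At ``q = 1``
the measures reduce to the probabilities themselves, so
``f(1) = alpha(1) = D_Q``.

All logarithms are natural; every reported quantity is a ratio of
logarithms, so the base cancels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import linregress

from .errors import DataError, InsufficientDataError, ScaleRangeWarning
from .tree import GenerationFlowTable

LN2 = math.log(2.0)

#: Default moment-order grid: -5 to 5 in steps of 0.25. The spectrum width
#: delta_alpha depends on this grid, so it is always reported alongside.
DEFAULT_Q_GRID = np.linspace(-5.0, 5.0, 41)

__all__ = [
    "DEFAULT_Q_GRID",
    "EntropyScaling",
    "MultifractalSpectrum",
    "generation_entropy",
    "fractal_dimension",
    "analytic_dimension",
    "multifractal_spectrum",
    "spectrum_range",
    "spectrum_max",
]


def generation_entropy(probabilities: np.ndarray) -> float:
    """Shannon entropy ``-sum p_i ln p_i`` in nats, with ``0 ln 0 := 0``.

    Entries must be non-negative and sum to 1 within 1e-9.
    """
    p = np.asarray(probabilities, dtype=float)
    if (p < 0).any():
        raise DataError("probabilities must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise DataError(f"probabilities sum to {total}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass
class EntropyScaling:
    """Entropy-vs-scale regression for the flow information dimension.

    ``log_n[j]`` is ``ln 2**n`` and ``entropy[j]`` the cross-section entropy
    ``S(n)`` for generations n = 1..G. ``dimension`` is the OLS slope
    (the flow fractal dimension ``D_Q``), with ``r_squared`` as the
    linearity diagnostic.
    """

    log_n: np.ndarray
    entropy: np.ndarray
    dimension: float
    intercept: float
    r_squared: float
    fit_generations: int

    def to_frame(self) -> pd.DataFrame:
        gen = np.rint(self.log_n / LN2).astype(int)
        return pd.DataFrame(
            {"generation": gen, "logN": self.log_n, "entropy": self.entropy}
        )


def _check_scale_span(max_generation: int) -> None:
    # 2**G spans three decades only for G >= 10 (G*log10(2) >= 3)
    if max_generation * math.log10(2.0) < 3.0:
        warnings.warn(
            f"scaling range spans {max_generation * math.log10(2.0):.2f} decades "
            "of cell counts (< 3); scale invariance cannot be asserted over "
            "three orders of magnitude",
            ScaleRangeWarning,
            stacklevel=3,
        )


def fractal_dimension(
    table: GenerationFlowTable, active_flow_threshold: float = 0.5
) -> EntropyScaling:
    """Estimate the flow fractal dimension ``D_Q`` from a generation table.

    Ordinary least-squares fit (with intercept) of ``S(n)`` against
    ``n ln 2``. Generation 0 contributes only the trivial point (0, 0) and
    is excluded to avoid weighting the origin. The fit runs over the
    scale-invariant range n = 1..n*, where n* is the last generation at
    which bifurcating segments still carry at least ``active_flow_threshold``
    of the total flow (:meth:`GenerationFlowTable.scaling_generations`):
    beyond it the cross-sections consist almost entirely of carried-forward
    terminals, the entropy saturates at the terminal-flow entropy, and the
    additional generations measure nothing — the analogue of counting boxes
    smaller than the pixels of an image. On a perfect binary tree every
    generation lies on the same line, so the restriction leaves the slope
    untouched. The entropy points of *all* generations are reported.

    Emits :class:`ScaleRangeWarning` when the fitted cell-count span is
    below three orders of magnitude (n* < 10); a diagnostic, never an error.
    """
    G = table.max_generation
    if G < 2:
        raise InsufficientDataError(
            f"need at least 2 generations beyond the root to fit a slope, got {G}"
        )
    gens = np.arange(1, G + 1)
    x = gens * LN2
    y = np.array([generation_entropy(table.probabilities[n]) for n in gens])
    n_fit = table.scaling_generations(active_flow_threshold)
    fit = linregress(x[:n_fit], y[:n_fit])
    _check_scale_span(n_fit)
    return EntropyScaling(
        log_n=x,
        entropy=y,
        dimension=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        fit_generations=n_fit,
    )


def analytic_dimension(r: float) -> float:
    """Closed-form flow fractal dimension of a constant-split perfect tree.

        D_Q(r) = [(1+r) ln(1+r) - r ln r] / [ln 2 * (1+r)]

    Equivalently the binary entropy of the split fractions in bits. Strictly
    increasing on (0, 1] with D_Q(1) = 1; the r -> 0+ limit is 0 and is
    returned for r = 0.
    """
    if not (0.0 <= r <= 1.0):
        raise DataError(f"split ratio must lie in [0, 1], got {r}")
    if r == 0.0:
        return 0.0
    return ((1.0 + r) * math.log1p(r) - r * math.log(r)) / (LN2 * (1.0 + r))


@dataclass
class MultifractalSpectrum:
    """Multifractal spectrum ``f(alpha)`` of a flow measure on a q grid."""

    q: np.ndarray
    alpha: np.ndarray
    f: np.ndarray

    @property
    def delta_alpha(self) -> float:
        """Spectrum width ``alpha_max - alpha_min`` over the q grid."""
        return float(self.alpha.max() - self.alpha.min())

    @property
    def f_max(self) -> float:
        """Spectrum height, attained at q = 0."""
        return float(self.f.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"q": self.q, "alpha": self.alpha, "f": self.f})


def _ols_slopes(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """OLS slopes (with intercept) of each column of Y against x."""
    xc = x - x.mean()
    return (xc @ (Y - Y.mean(axis=0))) / (xc @ xc)


def multifractal_spectrum(
    table: GenerationFlowTable,
    q_grid: np.ndarray | None = None,
    active_flow_threshold: float = 0.5,
) -> MultifractalSpectrum:
    """Estimate the multifractal spectrum of a carry-forward flow table.

    For each moment order q the per-generation sums ``-sum mu_i ln mu_i``
    and ``-sum mu_i ln p_i`` are regressed against ``n ln 2`` over the same
    scale-invariant generation range as :func:`fractal_dimension` (so that
    ``f(1) = alpha(1) = D_Q`` holds by construction). The normalised
    measures are evaluated in the log domain (log-sum-exp), so extreme q
    are handled without overflow; a ``mu_i`` underflowing to zero
    contributes zero to ``mu ln mu``.

    Requires strictly positive probabilities (guaranteed by carry-forward
    tables of positive-flow trees).
    """
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or q.size < 1 or not np.isfinite(q).all():
        raise DataError("q_grid must be a finite 1-D array")
    G = table.max_generation
    if G < 2:
        raise InsufficientDataError(
            f"need at least 2 generations beyond the root, got {G}"
        )

    n_fit = table.scaling_generations(active_flow_threshold)
    gens = np.arange(1, n_fit + 1)
    x = gens * LN2
    A = np.empty((gens.size, q.size))  # -sum mu ln mu, per (generation, q)
    B = np.empty((gens.size, q.size))  # -sum mu ln p
    for j, n in enumerate(gens):
        p = table.probabilities[n]
        if (p <= 0).any():
            raise DataError(
                f"generation {n} contains non-positive probabilities; the "
                "multifractal spectrum requires strictly positive flows"
            )
        lp = np.log(p)
        M = q[:, None] * lp[None, :]  # (n_q, n_cells) log p_i**q
        lse = logsumexp(M, axis=1)
        mu = np.exp(M - lse[:, None])
        # -sum mu ln mu = lse - sum mu * M  (since sum mu = 1)
        A[j] = lse - (mu * M).sum(axis=1)
        B[j] = -(mu @ lp)
    _check_scale_span(n_fit)
    return MultifractalSpectrum(q=q, alpha=_ols_slopes(x, B), f=_ols_slopes(x, A))


def spectrum_range(spectrum: MultifractalSpectrum) -> float:
    """Width ``delta_alpha`` of a computed spectrum (>= 0)."""
    return spectrum.delta_alpha


def spectrum_max(spectrum: MultifractalSpectrum) -> float:
    """Height ``f_max`` of a computed spectrum."""
    return spectrum.f_max
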