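"""Two-condition microarray expression simulator.

Simulates an ``n`` genes by ``m1 + m2`` samples matrix of log2 intensities
(or log2 ratios against a common reference) for a control-versus-test
design, with a known set of differentially expressed (DE) genes.  The
generative model is hierarchical:

1. Per-gene mean log2 levels are drawn from a beta distribution (right
   skewed, so weakly expressed genes dominate) and scaled into the dynamic
   range typical of array platforms.
2. Each gene's per-sample values are uniform around its mean, with a
   relative half-width ``alpha = lambda1 * exp(-lambda1 * mean)`` so that
   weakly expressed genes are noisier than strongly expressed ones.
3. A fraction ``pde`` of genes is flagged DE; their test-sample values are
   shifted up or down by normal draws whose mean is ``mu_de_min`` plus an
   exponential excess.
4. Optional zero-mean Gaussian noise is added to every entry.

All randomness flows through a single :class:`numpy.random.Generator`
seeded from ``rseed`` and consumed in a fixed, documented order, so a given
parameter set always reproduces the same matrix bit for bit.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "BaselineLevels",
    "DEAssignment",
    "SimulatedDataset",
    "alpha_width",
    "draw_base_levels",
    "sample_gene_profile",
    "assign_de",
    "apply_de_shift",
    "add_noise",
    "finalize_output",
    "simulate",
    "sd_de_bound",
]

# Largest relative half-width accepted before the uniform interval of a
# positive-mean gene would cross zero; wider requests are clamped here.
_ALPHA_CLAMP = 0.99


@dataclass(frozen=True)
class ModelParams:
    """User settings of the simulator, with field defaults matching the
    reference two-condition study design (10,000 genes, 7 vs 7 samples,
    2% DE genes split evenly up/down).

    Parameters
    ----------
    n : int
        Number of genes (probes).
    m1, m2 : int
        Number of control and test samples.
    ratio : bool
        ``False`` returns log2 intensities; ``True`` returns log2 ratios
        against a shared reference column.
    shape1, shape2 : float
        Beta shape parameters for the base-level draw.  ``shape1`` is
        conventionally fixed at 2; ``shape2`` in [4, 8] controls skew.
    lb, ub : float
        Scaling of beta draws into log2 space: ``zbar = lb + ub * z``.
        Recommended intervals are [2, 6] for ``lb`` and [8, 16] for ``ub``.
    pde : float
        Fraction of genes that are differentially expressed, in [0, 1].
    sym : float
        Up/down balance among DE genes; each DE gene is up-regulated with
        probability ``1 - sym`` (values below 0.5 give more up-regulated
        genes).
    lambda1 : float
        Decay rate of the uniform half-width with mean level.
    lambda2 : float
        Rate of the exponential excess added to the minimum shift mean
        (mean excess ``1 / lambda2``).
    mu_de_min : float
        Minimum mean of the DE shift, in log2 units.
    sd_de : float
        Standard deviation of the DE shift draws.
    sd_n : float
        Standard deviation of the additive Gaussian noise; 0 disables it.
    rseed : int
        Random generator seed.
    """

    n: int = 10_000
    m1: int = 7
    m2: int = 7
    ratio: bool = False
    shape1: float = 2.0
    shape2: float = 4.0
    lb: float = 4.0
    ub: float = 14.0
    pde: float = 0.02
    sym: float = 0.5
    lambda1: float = 0.13
    lambda2: float = 2.0
    mu_de_min: float = 1.0
    sd_de: float = 0.5
    sd_n: float = 0.4
    rseed: int = 50

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.m1 < 1 or self.m2 < 1:
            raise ValueError(f"m1 and m2 must be >= 1, got m1={self.m1}, m2={self.m2}")
        if not 0.0 <= self.pde <= 1.0:
            raise ValueError(f"pde must lie in [0, 1], got {self.pde}")
        if not 0.0 <= self.sym <= 1.0:
            raise ValueError(f"sym must lie in [0, 1], got {self.sym}")
        if self.shape1 <= 0 or self.shape2 <= 0:
            raise ValueError("beta shape parameters must be positive")
        if self.lambda1 <= 0:
            raise ValueError(f"lambda1 must be positive, got {self.lambda1}")
        if self.lambda2 <= 0:
            raise ValueError(f"lambda2 must be positive, got {self.lambda2}")
        if self.sd_de < 0:
            raise ValueError(f"sd_de must be non-negative, got {self.sd_de}")
        if self.sd_n < 0:
            raise ValueError(f"sd_n must be non-negative, got {self.sd_n}")
        if self.ub <= self.lb:
            raise ValueError(f"ub must exceed lb, got lb={self.lb}, ub={self.ub}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class BaselineLevels:
    """Per-gene base expression levels.

    ``z`` are raw beta draws in (0, 1) (``None`` in seed-data mode),
    ``zbar = lb + ub * z`` are mean log2 levels, and ``alpha`` are the
    relative uniform half-widths ``lambda1 * exp(-lambda1 * zbar)``.
    """

    z: np.ndarray | None
    zbar: np.ndarray
    alpha: np.ndarray


@dataclass(frozen=True)
class DEAssignment:
    """Per-gene DE ground truth.

    ``status`` is -1 (down), 0 (not DE) or +1 (up); ``mu_de`` holds the
    per-gene shift mean and is NaN wherever ``status == 0``.
    """

    status: np.ndarray
    mu_de: np.ndarray


@dataclass(frozen=True)
class SimulatedDataset:
    """Output of one simulation run.

    ``x`` is the returned ``n x (m1 + m2)`` matrix (log2 intensities, or
    log2 ratios if ``params.ratio``); columns ``0..m1-1`` are controls and
    the rest test samples.  ``reference`` is the extra first column used as
    the ratio denominator; ``y_noise_free`` the pre-noise
    ``n x (m1 + m2 + 1)`` matrix including that column.  ``de_status`` is
    the truth vector as in :class:`DEAssignment`.
    """

    x: np.ndarray
    reference: np.ndarray
    y_noise_free: np.ndarray
    de_status: np.ndarray
    params: ModelParams
    mu_de: np.ndarray = field(repr=False, default=None)


def alpha_width(zbar_i, lambda1):
    """Relative half-width of a gene's uniform variation.

    ``alpha = lambda1 * exp(-lambda1 * zbar)``, interpreted as a fraction
    of the mean level: with the default ``lambda1 = 0.13`` a gene with mean
    log2 level 2 varies by about +/-10% and one at level 10 by about
    +/-3.54%.  Accepts scalars or arrays.
    """
    if lambda1 <= 0:
        raise ValueError(f"lambda1 must be positive, got {lambda1}")
    return lambda1 * np.exp(-lambda1 * np.asarray(zbar_i, dtype=float))


def draw_base_levels(params: ModelParams, rng: np.random.Generator) -> BaselineLevels:
    """Draw per-gene mean levels ``zbar = lb + ub * Beta(shape1, shape2)``
    and their uniform half-widths.

    With ``shape2 > shape1`` the beta draw is right-skewed, so weakly
    expressed genes outnumber strongly expressed ones.  All ``zbar`` lie in
    ``[lb, lb + ub]``.
    """
    z = rng.beta(params.shape1, params.shape2, params.n)
    zbar = params.lb + params.ub * z
    alpha = _clamped_alpha(zbar, params.lambda1)
    return BaselineLevels(z=z, zbar=zbar, alpha=alpha)


def _clamped_alpha(zbar: np.ndarray, lambda1: float) -> np.ndarray:
    alpha = alpha_width(zbar, lambda1)
    oversized = alpha >= 1.0
    if np.any(oversized):
        warnings.warn(
            f"{int(np.count_nonzero(oversized))} gene(s) have uniform "
            f"half-width alpha >= 1 (non-positive mean level?); clamping to "
            f"{_ALPHA_CLAMP}",
            stacklevel=3,
        )
        alpha = np.where(oversized, _ALPHA_CLAMP, alpha)
    return alpha


def sample_gene_profile(zbar_i, alpha_i, m1, m2, rng):
    """Draw one gene's ``m1 + m2 + 1`` values from
    ``Uniform((1 - alpha) * zbar, (1 + alpha) * zbar)``.

    The first ``m1 + 1`` entries are the reference plus control samples,
    the last ``m2`` the test samples.
    """
    if alpha_i >= 1.0:
        raise ValueError(f"alpha must be < 1, got {alpha_i}")
    lo = (1.0 - alpha_i) * zbar_i
    hi = (1.0 + alpha_i) * zbar_i
    u = rng.random(m1 + m2 + 1)
    return lo + (hi - lo) * u


def assign_de(params: ModelParams, rng: np.random.Generator) -> DEAssignment:
    """Assign DE status and per-gene shift means.

    Each gene is DE independently with probability ``pde``; a DE gene is
    up-regulated with probability ``1 - sym``.  The shift mean is
    ``mu_de_min`` plus an Exponential(rate=lambda2) excess, so larger
    ``lambda2`` concentrates shifts near the minimum.

    Stream order: one uniform per gene for the DE decision, then one
    uniform per DE gene (gene order) for the direction, then one
    exponential per DE gene for the shift mean.
    """
    n = params.n
    status = np.zeros(n, dtype=np.int8)
    mu_de = np.full(n, np.nan)
    u_de = rng.random(n)
    de_idx = np.flatnonzero(u_de < params.pde)
    if de_idx.size:
        u_sym = rng.random(de_idx.size)
        status[de_idx] = np.where(u_sym > params.sym, 1, -1)
        mu_de[de_idx] = params.mu_de_min + rng.exponential(
            1.0 / params.lambda2, de_idx.size
        )
    return DEAssignment(status=status, mu_de=mu_de)


def apply_de_shift(r2, status_i, mu_de_i, sd_de, rng):
    """Shift one DE gene's test-sample values.

    Adds (``status_i = +1``) or subtracts (``-1``) ``m2`` independent
    ``Normal(mu_de_i, sd_de**2)`` draws; controls and the reference column
    are never shifted.
    """
    if status_i not in (-1, 1):
        raise ValueError(f"status must be -1 or +1, got {status_i}")
    r2 = np.asarray(r2, dtype=float)
    return r2 + status_i * rng.normal(mu_de_i, sd_de, r2.shape[0])


def add_noise(y: np.ndarray, sd_n: float, rng: np.random.Generator) -> np.ndarray:
    """Add independent ``Normal(0, sd_n**2)`` noise to every entry,
    reference column included.  ``sd_n = 0`` returns ``y`` unchanged
    without consuming the stream."""
    if sd_n < 0:
        raise ValueError(f"sd_n must be non-negative, got {sd_n}")
    if sd_n == 0:
        return y
    return y + rng.normal(0.0, sd_n, y.shape)


def finalize_output(ybar: np.ndarray, ratio: bool):
    """Split the ``n x (m1 + m2 + 1)`` matrix into output and reference.

    Intensity mode drops the first column; ratio mode subtracts it from
    every remaining column.  Returns ``(x, reference)``.
    """
    reference = ybar[:, 0].copy()
    if ratio:
        x = ybar[:, 1:] - reference[:, None]
    else:
        x = ybar[:, 1:].copy()
    return x, reference


def simulate(
    params: ModelParams, seed_levels: np.ndarray | None = None
) -> SimulatedDataset:
    """Run the full generative model and return data plus DE ground truth.

    Parameters
    ----------
    params : ModelParams
        Simulator settings.  ``params.rseed`` fully determines the output.
    seed_levels : array-like of float, optional
        Per-gene mean log2 levels (e.g. from a real dataset) used directly
        as ``zbar``, bypassing the beta draw; ``shape2``, ``lb`` and ``ub``
        then have no effect.  Its length defines the number of genes and
        must agree with ``params.n`` when that was set explicitly.

    Notes
    -----
    The random stream is consumed in the fixed order: base levels,
    per-gene profiles (gene order, sample order within gene), DE decisions,
    DE direction draws, shift-mean exponentials, shift normals (gene order,
    sample order), then the noise matrix in row-major order.  The ``ratio``
    flag does not touch the stream, so same-seed ratio output equals
    same-seed intensity output minus the reference column.
    """
    if seed_levels is not None:
        seed_levels = np.asarray(seed_levels, dtype=float).ravel()
        if seed_levels.size == 0:
            raise ValueError("seed_levels is empty")
        default_n = ModelParams().n
        if params.n not in (default_n, seed_levels.size):
            raise ValueError(
                f"seed_levels has {seed_levels.size} genes but params.n="
                f"{params.n}; drop the explicit n or make them agree"
            )
        params = params.replace(n=seed_levels.size)

    rng = np.random.default_rng(params.rseed)
    m1, m2 = params.m1, params.m2

    if seed_levels is None:
        levels = draw_base_levels(params, rng)
    else:
        alpha = _clamped_alpha(seed_levels, params.lambda1)
        levels = BaselineLevels(z=None, zbar=seed_levels, alpha=alpha)

    # Per-gene uniform profiles; the (n, m1+m2+1) fill is row-major, so the
    # stream order matches drawing gene by gene.
    lo = (1.0 - levels.alpha) * levels.zbar
    hi = (1.0 + levels.alpha) * levels.zbar
    u = rng.random((params.n, m1 + m2 + 1))
    y = lo[:, None] + (hi - lo)[:, None] * u

    de = assign_de(params, rng)
    de_idx = np.flatnonzero(de.status)
    if de_idx.size:
        shifts = rng.normal(
            de.mu_de[de_idx][:, None], params.sd_de, (de_idx.size, m2)
        )
        y[de_idx, m1 + 1 :] += de.status[de_idx][:, None] * shifts

    y_noise_free = y.copy()
    ybar = add_noise(y, params.sd_n, rng)
    x, reference = finalize_output(ybar, params.ratio)

    return SimulatedDataset(
        x=x,
        reference=reference,
        y_noise_free=y_noise_free,
        de_status=de.status.astype(int),
        params=params,
        mu_de=de.mu_de,
    )


def sd_de_bound(m2: int, mu_de_min: float) -> float:
    """Largest shift standard deviation keeping the one-sample shift
    statistic ``sqrt(m2) * mu_de_min / sd_de`` above the 5% critical value
    1.96, i.e. ``sqrt(m2) * mu_de_min / 1.96`` (~``0.51 * sqrt(m2) *
    mu_de_min``).  Advisory only: exceeding it makes the minimum shift
    statistically invisible to a one-sample test."""
    if m2 < 1:
        raise ValueError(f"m2 must be >= 1, got {m2}")
    if mu_de_min <= 0:
        raise ValueError(f"mu_de_min must be positive, got {mu_de_min}")
    return np.sqrt(m2) * mu_de_min / 1.96
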