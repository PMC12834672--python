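"""Prior distributions: densities, gradients and samplers.

The sampler needs analytic gradients of every prior log-density, so each
supported family carries its own closed-form ``logpdf`` / ``dlogpdf`` pair in
addition to a scipy-backed sampler. Families are deliberately few: weakly
informative defaults in hierarchical location-scale models need nothing
beyond Gaussians, Student-t (and their half versions for standard
deviations), and an LKJ prior on correlation matrices.

The LKJ prior is handled in its C-vine representation: the canonical partial
correlations (CPCs) ``z_ij`` (row ``i``, column ``j < i`` of the Cholesky
construction) are independent with ``(z_ij + 1)/2 ~ Beta(a_j, a_j)`` where
``a_j = eta + (d - 1 - j)/2`` (1-based column). That representation induces
the usual ``det(R)^(eta - 1)`` density over correlation matrices and keeps
both sampling and gradients elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

__all__ = ["Prior", "PriorSet", "lkj_log_norm", "lkj_logpdf", "cpc_beta_shape"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class Prior:
    """A univariate prior: ``kind`` in {normal, student_t, half_normal, half_student_t}.

    ``loc``/``scale`` follow the usual location-scale convention; ``df`` is
    ignored for the Gaussian kinds. Half distributions live on [0, inf) and
    must have ``loc == 0``.
    """

    kind: str
    loc: float = 0.0
    scale: float = 1.0
    df: float = 3.0

    def __post_init__(self):
        if self.kind not in ("normal", "student_t", "half_normal", "half_student_t"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.scale <= 0:
            raise ValueError("prior scale must be positive")
        if self.kind.startswith("half") and self.loc != 0.0:
            raise ValueError("half distributions must be centred at 0")
        # cache the log normalizing constant (gammaln is costly in hot loops)
        if self.kind == "normal":
            c = -0.5 * _LOG_2PI - np.log(self.scale)
        elif self.kind == "half_normal":
            c = np.log(2.0) - 0.5 * _LOG_2PI - np.log(self.scale)
        else:
            v = self.df
            c = (
                special.gammaln((v + 1) / 2)
                - special.gammaln(v / 2)
                - 0.5 * np.log(v * np.pi)
                - np.log(self.scale)
            )
            if self.kind == "half_student_t":
                c += np.log(2.0)
        object.__setattr__(self, "_log_const", float(c))

    # -- log density -------------------------------------------------------
    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        t = (x - self.loc) / self.scale
        if self.kind == "normal":
            return self._log_const - 0.5 * t * t
        if self.kind == "student_t":
            return self._log_const - 0.5 * (self.df + 1) * np.log1p(t * t / self.df)
        if self.kind == "half_normal":
            return np.where(x < 0, -np.inf, self._log_const - 0.5 * t * t)
        out = self._log_const - 0.5 * (self.df + 1) * np.log1p(t * t / self.df)
        return np.where(x < 0, -np.inf, out)

    def dlogpdf(self, x):
        """d/dx log pdf (for x in the interior of the support)."""
        x = np.asarray(x, dtype=float)
        t = (x - self.loc) / self.scale
        if self.kind in ("normal", "half_normal"):
            return -t / self.scale
        v = self.df
        return -(v + 1) * t / (self.scale * (v + t * t))

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "normal":
            return rng.normal(self.loc, self.scale, size=size)
        if self.kind == "half_normal":
            return np.abs(rng.normal(0.0, self.scale, size=size))
        draws = self.loc + self.scale * rng.standard_t(self.df, size=size)
        if self.kind == "half_student_t":
            draws = np.abs(draws - self.loc)
        return draws

    def mean_sd(self):
        """Approximate (mean, sd) — used only for initialization heuristics."""
        if self.kind == "normal":
            return self.loc, self.scale
        if self.kind == "student_t":
            sd = self.scale * np.sqrt(self.df / (self.df - 2)) if self.df > 2 else 2 * self.scale
            return self.loc, sd
        # half families: crude but adequate for starting points
        return 0.8 * self.scale, 0.6 * self.scale


@dataclass(frozen=True)
class PriorSet:
    """Priors for every free top-level parameter of a model spec.

    One descriptor per structural role; each is applied to every coefficient
    in that role (e.g. ``scale_coef`` covers all per-category scale
    coefficients of the cell-means model). ``lkj_eta`` is the concentration
    of the LKJ prior shared by all correlation blocks. Varying (random)
    effects are standard-normal in the non-centred parameterization and have
    no free prior here.
    """

    loc_intercept: Prior = field(default_factory=lambda: Prior("student_t", 0.0, 2.5, 3.0))
    loc_slope: Prior = field(default_factory=lambda: Prior("normal", 0.0, 1.0))
    scale_coef: Prior = field(default_factory=lambda: Prior("student_t", 0.0, 2.5, 3.0))
    scale_slope: Prior = field(default_factory=lambda: Prior("normal", 0.0, 1.0))
    sd: Prior = field(default_factory=lambda: Prior("half_student_t", 0.0, 2.5, 3.0))
    lkj_eta: float = 1.0

    def centred_on(self, y: np.ndarray) -> "PriorSet":
        """Return a copy with the location intercept centred on the data.

        Centre = median of the response, scale = 2.5 x MAD (floored at 2.5 x
        a small constant so degenerate data keep a proper prior) — the usual
        weakly-informative default for regression intercepts.
        """
        y = np.asarray(y, dtype=float)
        med = float(np.median(y)) if y.size else 0.0
        mad = float(np.median(np.abs(y - med))) * 1.4826 if y.size else 1.0
        scale = 2.5 * max(mad, 0.4)
        return replace(self, loc_intercept=replace(self.loc_intercept, loc=med, scale=scale))


# --------------------------------------------------------------------------
# LKJ correlation prior
# --------------------------------------------------------------------------

def cpc_beta_shape(d: int, col: int, eta: float) -> float:
    """Beta shape for the CPC in 1-based column ``col`` of a d x d matrix."""
    return eta + (d - 1 - col) / 2.0


def lkj_log_norm(d: int, eta: float = 1.0) -> float:
    """log of the LKJ normalizing constant c_d(eta), i.e. log ∫ det(R)^(eta-1) dR.

    Derived from the C-vine: level-k partial correlations (d - k of them)
    contribute ∫_{-1}^{1} (1 - z^2)^{a} dz = 2^{2a+1} B(a+1, a+1) with
    a = eta - 1 + (d - 1 - k)/2. For d = 3, eta = 1 this gives pi^2/2, the
    volume of the 3x3 elliptope.
    """
    if d < 2:
        return 0.0
    total = 0.0
    for k in range(1, d):
        a = eta - 1.0 + (d - 1 - k) / 2.0
        log_int = (2 * a + 1) * np.log(2.0) + special.betaln(a + 1, a + 1)
        total += (d - k) * log_int
    return total


def lkj_logpdf(corr: np.ndarray, eta: float = 1.0) -> float:
    """Normalized LKJ log-density of a correlation matrix."""
    corr = np.asarray(corr, dtype=float)
    d = corr.shape[0]
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0:
        raise ValueError("correlation matrix must be positive definite")
    return (eta - 1.0) * logdet - lkj_log_norm(d, eta)


def sample_lkj(rng: np.random.Generator, d: int, eta: float = 1.0) -> np.ndarray:
    """Draw a correlation matrix from LKJ(eta) via beta-distributed CPCs."""
    z = np.zeros((d, d))
    for i in range(1, d):
        for j in range(i):
            a = cpc_beta_shape(d, j + 1, eta)
            z[i, j] = 2.0 * rng.beta(a, a) - 1.0
    chol = cpc_to_cholesky(z)
    return chol @ chol.T


def cpc_to_cholesky(z: np.ndarray) -> np.ndarray:
    """Build the Cholesky factor of a correlation matrix from CPCs.

    ``z`` is strictly lower triangular with entries in (-1, 1).
    """
    d = z.shape[0]
    chol = np.zeros((d, d))
    chol[0, 0] = 1.0
    for i in range(1, d):
        rem = 1.0
        for j in range(i):
            chol[i, j] = z[i, j] * np.sqrt(rem)
            rem *= 1.0 - z[i, j] ** 2
        chol[i, i] = np.sqrt(rem)
    return chol


def cholesky_to_cpc(chol: np.ndarray) -> np.ndarray:
    """Inverse of :func:`cpc_to_cholesky` (assumes unit-norm rows)."""
    d = chol.shape[0]
    z = np.zeros((d, d))
    for i in range(1, d):
        rem = 1.0
        for j in range(i):
            z[i, j] = chol[i, j] / np.sqrt(rem) if rem > 0 else 0.0
            rem *= 1.0 - z[i, j] ** 2
    return z
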