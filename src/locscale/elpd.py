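"""Pointwise expected log predictive density (elpd) under two prediction tasks.

*Conditional* (within-study) prediction scores a held-out observation using
the fitted study-level effects of its own study: for observation ``i`` and
posterior draws ``theta_s``,

    elpd_i = log( (1/S) * sum_s p(y_i | theta_s) ),

computed with log-sum-exp stabilization. A held-out observation is always a
*new case*, so in models with a nested case-level intercept its variance is
integrated out analytically (the predictive variance gains ``omega^2``).

*Marginal* (new-study) prediction scores observations from studies the
model has never seen: for each posterior draw, new-study varying effects
are sampled from their population multivariate normal (given that draw's
SDs and correlations), the density is averaged over those samples first,
and then across draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import Dataset
from .inference import PosteriorDraws
from .models import ModelSpec, build_design, coord_key

__all__ = ["ElpdVector", "elpd_conditional", "elpd_marginal", "elpd_total"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class ElpdVector:
    """Pointwise elpd for a block of held-out observations."""

    values: np.ndarray
    mode: str                # {"conditional", "marginal"}
    model_id: str
    fold_id: object = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("elpd values must be finite")


def elpd_total(vec: ElpdVector | np.ndarray) -> tuple[float, float]:
    """Total elpd and its standard error, ``SE = sd(values) * sqrt(N)``.

    A single observation has SE 0 by convention.
    """
    values = vec.values if isinstance(vec, ElpdVector) else np.asarray(vec, dtype=float)
    if values.size == 0:
        raise ValueError("elpd_total requires a nonempty vector")
    total = float(np.sum(values))
    if values.size == 1:
        return total, 0.0
    return total, float(np.std(values, ddof=1) * np.sqrt(values.size))


# --------------------------------------------------------------------------
# internals shared by both modes
# --------------------------------------------------------------------------

def _flat_params(draws: PosteriorDraws):
    bl = draws.flat("beta_loc")
    bs = draws.flat("beta_scale")
    sd = draws.flat("sd")
    return bl, bs, sd


def _base_predictors(draws: PosteriorDraws, design):
    """Fixed-effect parts of mu and log sigma: arrays (S, n)."""
    bl, bs, _ = _flat_params(draws)
    mu = bl @ design.X_loc.T
    eta = bs @ design.X_scale.T if design.X_scale.shape[1] else None
    if draws.spec.has_scale and eta is None:
        eta = np.zeros((bl.shape[0], design.n_obs))
    return mu, eta


def _loglik_matrix(spec: ModelSpec, design, mu, eta, sd, draws: PosteriorDraws):
    """log p(y_i | draw) given complete linear predictors; (S, n)."""
    y = design.y[None, :]
    if spec.family == "gaussian_known_variance":
        var = np.broadcast_to(design.v_known[None, :], mu.shape).copy()
        if spec.has_scale:
            var = var + np.exp(2.0 * eta)
        if spec.case_level_intercept:
            omega = sd[:, draws.sd_keys.index("case")]
            var = var + (omega ** 2).reshape((omega.size,) + (1,) * (mu.ndim - 1))
        return -0.5 * (np.log(2.0 * np.pi * var) + (y - mu) ** 2 / var)
    sigma = np.exp(eta)
    return -eta - 0.5 * _LOG_2PI - 0.5 * ((y - mu) / sigma) ** 2 + design.log_jac[None, :]


def elpd_conditional(draws: PosteriorDraws, spec: ModelSpec, heldout: Dataset) -> ElpdVector:
    """Within-study pointwise elpd using the sampled study effects.

    Every held-out study must appear in the training fit; otherwise the
    caller needs :func:`elpd_marginal` for those observations.
    """
    design = build_design(spec, heldout)
    train_idx = {lab: i for i, lab in enumerate(draws.study_labels)}
    unseen = [lab for lab in design.study_labels if lab not in train_idx]
    if unseen:
        raise ValueError(
            f"held-out studies {unseen} were not in the training data; "
            "use elpd_marginal for new-study prediction"
        )
    obs_study = np.array([train_idx[lab] for lab in
                          np.asarray(design.study_labels, dtype=object)[design.study]])
    mu, eta = _base_predictors(draws, design)
    _, _, sd = _flat_params(draws)
    for c in spec.random_coords:
        key = coord_key(c)
        b = draws.flat(f"b_{key}")[:, obs_study]       # (S, n)
        contrib = b * design.coord_x[key][None, :]
        if c[0] == "loc":
            mu = mu + contrib
        else:
            eta = eta + contrib
    ll = _loglik_matrix(spec, design, mu, eta, sd, draws)
    n_draws = ll.shape[0]
    values = logsumexp(ll, axis=0) - np.log(n_draws)
    return ElpdVector(values, "conditional", spec.name)


def elpd_marginal(draws: PosteriorDraws, spec: ModelSpec, heldout: Dataset,
                  re_draws: int = 100, seed: int | np.random.Generator = 0) -> ElpdVector:
    """New-study pointwise elpd, marginalizing over unseen study effects.

    For each posterior draw, ``re_draws`` vectors of study-level effects are
    sampled from the population MVN implied by that draw's SDs and
    correlation matrices; densities are averaged over those samples before
    the across-draw average. With no varying effects this reduces exactly to
    :func:`elpd_conditional`.
    """
    if re_draws < 1:
        raise ValueError("re_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = build_design(spec, heldout)
    train = set(draws.study_labels)
    seen = [lab for lab in design.study_labels if lab in train]
    if seen:
        raise ValueError(f"studies {seen} are in the training data; use elpd_conditional")

    mu0, eta0 = _base_predictors(draws, design)
    _, _, sd = _flat_params(draws)
    S = mu0.shape[0]
    values = np.empty(design.n_obs)

    if not spec.random_coords:
        ll = _loglik_matrix(spec, design, mu0, eta0, sd, draws)
        return ElpdVector(logsumexp(ll, axis=0) - np.log(S), "marginal", spec.name)

    # sampled effects are shared across a study's observations within a
    # replicate but each observation's density is averaged separately
    labels_arr = np.asarray(design.study_labels, dtype=object)
    for si, lab in enumerate(labels_arr):
        rows = np.flatnonzero(labels_arr[design.study] == lab)
        mu = np.repeat(mu0[:, rows][:, None, :], re_draws, axis=1)      # (S, R, nr)
        eta = (np.repeat(eta0[:, rows][:, None, :], re_draws, axis=1)
               if eta0 is not None else None)
        for gi, grp in enumerate(spec.groups):
            d_g = len(grp)
            sd_cols = np.array([draws.sd_keys.index(coord_key(c)) for c in grp])
            sds = sd[:, sd_cols]                                        # (S, d)
            eps = rng.standard_normal((S, re_draws, d_g))
            if d_g == 1:
                b = sds[:, None, :] * eps
            else:
                corr = draws.flat(f"corr{gi}")                          # (S, d, d)
                chol = np.linalg.cholesky(corr)
                b = sds[:, None, :] * np.einsum("sij,srj->sri", chol, eps)
            for k, c in enumerate(grp):
                x_c = design.coord_x[coord_key(c)][rows]
                contrib = b[:, :, k][:, :, None] * x_c[None, None, :]
                if c[0] == "loc":
                    mu = mu + contrib
                else:
                    eta = eta + contrib
        sub = _subdesign(design, rows)
        ll = _loglik_matrix(spec, sub, mu, eta, sd, draws)              # (S, R, nr)
        per_draw = logsumexp(ll, axis=1) - np.log(re_draws)             # (S, nr)
        values[rows] = logsumexp(per_draw, axis=0) - np.log(S)
    return ElpdVector(values, "marginal", spec.name)


class _SubDesign:
    __slots__ = ("y", "v_known", "log_jac", "n_obs")

    def __init__(self, y, v, lj):
        self.y = y
        self.v_known = v
        self.log_jac = lj
        self.n_obs = len(y)


def _subdesign(design, rows):
    sub = _SubDesign(design.y[rows], design.v_known[rows], design.log_jac[rows])
    return sub
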