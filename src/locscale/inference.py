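"""Posterior sampling: a self-contained No-U-Turn sampler over any model spec.

The engine is a dynamic Hamiltonian Monte Carlo sampler (multinomial NUTS
with dual-averaging step-size adaptation and windowed diagonal mass-matrix
estimation) running on the unconstrained, non-centred posterior of
:class:`locscale._posterior.Posterior`, whose gradients are analytic.
Chains are run sequentially with seeds spawned deterministically from the
user seed, so identical configurations reproduce identical draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._posterior import Posterior
from .data import Dataset
from .models import ModelSpec, ParameterSet, coord_key

__all__ = ["McmcConfig", "PosteriorDraws", "fit", "diagnose"]


@dataclass(frozen=True)
class McmcConfig:
    """Sampler configuration; the seed is recorded in every artifact."""

    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    seed: int = 0
    adapt_target: float = 0.95
    max_treedepth: int = 10

    def __post_init__(self):
        if self.chains < 1 or self.warmup < 10 or self.samples < 1:
            raise ValueError("chains >= 1, warmup >= 10, samples >= 1 required")
        if not 0.0 < self.adapt_target < 1.0:
            raise ValueError("adapt_target must lie in (0, 1)")


@dataclass
class PosteriorDraws:
    """Posterior draws addressed by parameter name, with sampler metadata.

    ``params`` maps names to arrays whose first two axes are (chain, draw):
    ``beta_loc`` (c, s, p), ``beta_scale`` (c, s, q), ``sd`` (c, s, n_sd)
    in ``sd_keys`` order, per-group correlation matrices ``corr<g>``
    (c, s, d, d), per-coordinate study effects ``b_<coord>`` (c, s, I) and,
    when present, ``case`` (c, s, n).
    """

    spec: ModelSpec
    params: dict
    sd_keys: list
    scale_colnames: list
    study_labels: list
    config: McmcConfig
    divergences: np.ndarray
    treedepth_hits: np.ndarray
    step_sizes: np.ndarray
    accept_stat: np.ndarray
    diagnostics: Optional[pd.DataFrame] = None
    sbc_meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.params["beta_loc"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.params["beta_loc"].shape[1]

    def flat(self, name: str) -> np.ndarray:
        arr = self.params[name]
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    # -- named scalar views -------------------------------------------------
    def top_level(self) -> dict:
        """Flattened draws of every free top-level scalar, by display name."""
        out = {}
        bl = self.flat("beta_loc")
        for j in range(bl.shape[1]):
            out[f"beta{j}"] = bl[:, j]
        bs = self.flat("beta_scale")
        for j, nm in enumerate(self.scale_colnames):
            out[nm] = bs[:, j]
        sd = self.flat("sd")
        for j, key in enumerate(self.sd_keys):
            out[self.spec.sd_display(key)] = sd[:, j]
        for gi, grp in enumerate(self.spec.groups):
            if len(grp) > 1:
                corr = self.flat(f"corr{gi}")
                names = self.spec.corr_names(gi)
                rows, cols = np.tril_indices(len(grp), k=-1)
                for nm, i, j in zip(names, rows, cols):
                    out[nm] = corr[:, i, j]
        return out

    def scalar_dict(self, include_effects: bool = True) -> dict:
        """Per-chain scalar arrays (chains, draws) for diagnostics."""
        out = dict(self._chainwise_top_level())
        if include_effects:
            for name, arr in self.params.items():
                if name.startswith("b_"):
                    for i, lab in enumerate(self.study_labels):
                        out[f"{name}[{lab}]"] = arr[:, :, i]
        return out

    def _chainwise_top_level(self) -> dict:
        c, s = self.n_chains, self.n_draws
        flat = self.top_level()
        return {k: v.reshape(c, s) for k, v in flat.items()}

    def draw_params(self, chain: int, draw: int) -> ParameterSet:
        """Reassemble one draw as a natural-space ParameterSet."""
        sd = {k: float(self.params["sd"][chain, draw, j]) for j, k in enumerate(self.sd_keys)}
        corr = {}
        effects = {}
        for gi, grp in enumerate(self.spec.groups):
            if len(grp) > 1:
                corr[gi] = self.params[f"corr{gi}"][chain, draw]
            for c_ in grp:
                effects[coord_key(c_)] = self.params[f"b_{coord_key(c_)}"][chain, draw]
        return ParameterSet(
            beta_loc=self.params["beta_loc"][chain, draw],
            beta_scale=self.params["beta_scale"][chain, draw],
            sd=sd, corr=corr,
            study_effects=effects if effects else None,
            case_effects=self.params.get("case", np.empty((1, 1, 0)))[chain, draw]
            if "case" in self.params else None,
        )

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD and 5/50/95% quantiles of top-level scalars."""
        rows = []
        for name, v in self.top_level().items():
            rows.append(
                {"param": name, "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)),
                 "q05": float(np.quantile(v, 0.05)), "q50": float(np.quantile(v, 0.5)),
                 "q95": float(np.quantile(v, 0.95))}
            )
        return pd.DataFrame(rows)

    def to_inference_data(self, include_effects: bool = True):
        """Convert to an ArviZ InferenceData for standard posterior analysis."""
        import arviz as az

        return az.from_dict(posterior=self.scalar_dict(include_effects=include_effects))

    def to_long_frame(self) -> pd.DataFrame:
        """Draws in long format (chain, draw, parameter, value) for CSV export."""
        recs = []
        for name, arr in self._chainwise_top_level().items():
            c, s = arr.shape
            for ci in range(c):
                recs.append(pd.DataFrame({
                    "chain": ci, "draw": np.arange(s), "parameter": name, "value": arr[ci]
                }))
        return pd.concat(recs, ignore_index=True)


# --------------------------------------------------------------------------
# NUTS
# --------------------------------------------------------------------------

_DIVERGENCE_THRESHOLD = 1000.0


class _Tree:
    __slots__ = ("th_m", "r_m", "g_m", "th_p", "r_p", "g_p",
                 "th_prop", "lp_prop", "g_prop", "logw", "rho",
                 "divergent", "turning", "accept_sum", "n_leap")

    def __init__(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)


def _leapfrog(post, th, r, grad, eps, inv_mass):
    r_half = r + 0.5 * eps * grad
    th_new = th + eps * (inv_mass * r_half)
    lp_new, grad_new = post.logpost_grad(th_new)
    r_new = r_half + 0.5 * eps * grad_new
    return th_new, r_new, lp_new, grad_new


def _kinetic(r, inv_mass):
    return 0.5 * float(np.dot(inv_mass * r, r))


def _build_tree(post, depth, th, r, grad, lp, dirn, eps, H0, inv_mass, rng):
    if depth == 0:
        th1, r1, lp1, g1 = _leapfrog(post, th, r, grad, dirn * eps, inv_mass)
        if np.isfinite(lp1):
            dH = H0 - (-lp1 + _kinetic(r1, inv_mass))
        else:
            dH = -np.inf
        divergent = not np.isfinite(dH) or dH < -_DIVERGENCE_THRESHOLD
        accept = float(np.exp(min(0.0, dH))) if np.isfinite(dH) else 0.0
        return _Tree(th_m=th1, r_m=r1, g_m=g1, th_p=th1, r_p=r1, g_p=g1,
                     th_prop=th1, lp_prop=lp1, g_prop=g1,
                     logw=dH if np.isfinite(dH) else -np.inf, rho=r1.copy(),
                     divergent=divergent, turning=False,
                     accept_sum=accept, n_leap=1)

    t1 = _build_tree(post, depth - 1, th, r, grad, lp, dirn, eps, H0, inv_mass, rng)
    if t1.divergent or t1.turning:
        return t1
    if dirn == 1:
        th_e, r_e, g_e = t1.th_p, t1.r_p, t1.g_p
    else:
        th_e, r_e, g_e = t1.th_m, t1.r_m, t1.g_m
    t2 = _build_tree(post, depth - 1, th_e, r_e, g_e, 0.0, dirn, eps, H0, inv_mass, rng)
    logw = np.logaddexp(t1.logw, t2.logw)
    take2 = np.log(rng.random()) < t2.logw - logw if np.isfinite(t2.logw) else False
    prop = t2 if take2 else t1
    rho = t1.rho + t2.rho
    if dirn == 1:
        th_m, r_m, g_m = t1.th_m, t1.r_m, t1.g_m
        th_p, r_p, g_p = t2.th_p, t2.r_p, t2.g_p
    else:
        th_m, r_m, g_m = t2.th_m, t2.r_m, t2.g_m
        th_p, r_p, g_p = t1.th_p, t1.r_p, t1.g_p
    turning = t2.divergent or t2.turning or _uturn(rho, r_m, r_p, inv_mass)
    return _Tree(th_m=th_m, r_m=r_m, g_m=g_m, th_p=th_p, r_p=r_p, g_p=g_p,
                 th_prop=prop.th_prop, lp_prop=prop.lp_prop, g_prop=prop.g_prop,
                 logw=logw, rho=rho,
                 divergent=t2.divergent, turning=turning,
                 accept_sum=t1.accept_sum + t2.accept_sum,
                 n_leap=t1.n_leap + t2.n_leap)


def _uturn(rho, r_m, r_p, inv_mass):
    return (float(np.dot(inv_mass * r_m, rho)) <= 0.0
            or float(np.dot(inv_mass * r_p, rho)) <= 0.0)


def _nuts_draw(post, th, lp, grad, eps, inv_mass, rng, max_depth):
    dim = th.shape[0]
    r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
    H0 = -lp + _kinetic(r0, inv_mass)
    th_prop, lp_prop, g_prop = th, lp, grad
    th_m, r_m, g_m = th, r0, grad
    th_p, r_p, g_p = th, r0, grad
    rho = r0.copy()
    logw_total = 0.0
    accept_sum, n_leap = 0.0, 0
    divergent = False
    depth = 0
    while depth < max_depth:
        dirn = 1 if rng.random() < 0.5 else -1
        if dirn == 1:
            t = _build_tree(post, depth, th_p, r_p, g_p, lp, dirn, eps, H0, inv_mass, rng)
        else:
            t = _build_tree(post, depth, th_m, r_m, g_m, lp, dirn, eps, H0, inv_mass, rng)
        accept_sum += t.accept_sum
        n_leap += t.n_leap
        if t.divergent:
            divergent = True
            break
        if t.turning:
            break
        if np.isfinite(t.logw) and np.log(rng.random()) < t.logw - logw_total:
            th_prop, lp_prop, g_prop = t.th_prop, t.lp_prop, t.g_prop
        logw_total = np.logaddexp(logw_total, t.logw)
        if dirn == 1:
            th_p, r_p, g_p = t.th_p, t.r_p, t.g_p
        else:
            th_m, r_m, g_m = t.th_m, t.r_m, t.g_m
        rho = rho + t.rho
        depth += 1
        if _uturn(rho, r_m, r_p, inv_mass):
            break
    stat = accept_sum / max(n_leap, 1)
    return th_prop, lp_prop, g_prop, stat, divergent, depth


def _find_epsilon(post, th, lp, grad, inv_mass, rng):
    eps = 0.1
    r0 = rng.standard_normal(th.shape[0]) / np.sqrt(inv_mass)
    H0 = -lp + _kinetic(r0, inv_mass)

    def accept_logp(e):
        _, r1, lp1, _ = _leapfrog(post, th, r0, grad, e, inv_mass)
        if not np.isfinite(lp1):
            return -np.inf
        return H0 - (-lp1 + _kinetic(r1, inv_mass))

    a = accept_logp(eps)
    dirn = 1.0 if a > np.log(0.5) else -1.0
    for _ in range(50):
        if dirn * a <= -dirn * np.log(2.0):
            break
        eps *= 2.0 ** dirn
        a = accept_logp(eps)
    return eps


def _adaptation_windows(warmup: int):
    """(start, end) pairs of mass-estimation windows, Stan-like buffers."""
    init_buf = max(int(0.15 * warmup), 10)
    term_buf = max(int(0.10 * warmup), 10)
    middle = warmup - init_buf - term_buf
    if middle < 20:
        return []
    windows = []
    start = init_buf
    size = max(middle // 7, 20)
    while start < warmup - term_buf:
        end = min(start + size, warmup - term_buf)
        if (warmup - term_buf) - end < size:
            end = warmup - term_buf
        windows.append((start, end))
        start = end
        size *= 2
    return windows


def _run_chain(post, config: McmcConfig, rng: np.random.Generator):
    dim = post.dim
    th = None
    for _ in range(10):
        cand = post.init_theta(rng)
        lp, grad = post.logpost_grad(cand)
        if np.isfinite(lp) and np.all(np.isfinite(grad)):
            th = cand
            break
    if th is None:
        raise RuntimeError("initialization failed: non-finite log density after 10 retries")

    inv_mass = np.ones(dim)
    eps = _find_epsilon(post, th, lp, grad, inv_mass, rng)
    gamma, t0, kappa = 0.05, 10.0, 0.75
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar, m_adapt = 0.0, 0.0, 0
    windows = _adaptation_windows(config.warmup)
    window_draws: list[np.ndarray] = []
    win_idx = 0

    draws = np.empty((config.samples, dim))
    divergences = 0
    depth_hits = 0
    accept_stats = []

    for it in range(config.warmup + config.samples):
        warming = it < config.warmup
        th, lp, grad, stat, div, depth = _nuts_draw(
            post, th, lp, grad, eps, inv_mass, rng, config.max_treedepth
        )
        if warming:
            m_adapt += 1
            h_bar = (1 - 1 / (m_adapt + t0)) * h_bar + (config.adapt_target - stat) / (m_adapt + t0)
            log_eps = mu - np.sqrt(m_adapt) / gamma * h_bar
            log_eps_bar = m_adapt ** (-kappa) * log_eps + (1 - m_adapt ** (-kappa)) * log_eps_bar
            eps = float(np.exp(log_eps))
            if win_idx < len(windows):
                w_start, w_end = windows[win_idx]
                if w_start <= it < w_end:
                    window_draws.append(th.copy())
                if it == w_end - 1 and len(window_draws) >= 10:
                    arr = np.asarray(window_draws)
                    nw = arr.shape[0]
                    var = np.var(arr, axis=0, ddof=1)
                    inv_mass = (nw / (nw + 5.0)) * var + 1e-3 * (5.0 / (nw + 5.0))
                    window_draws = []
                    win_idx += 1
                    eps = _find_epsilon(post, th, lp, grad, inv_mass, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, m_adapt = 0.0, 0.0, 0
            if it == config.warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            k = it - config.warmup
            draws[k] = th
            divergences += int(div)
            depth_hits += int(depth >= config.max_treedepth)
            accept_stats.append(stat)

    return draws, divergences, depth_hits, eps, float(np.mean(accept_stats))


def fit(spec: ModelSpec, data: Dataset, config: McmcConfig | None = None,
        priors=None) -> PosteriorDraws:
    """Sample the posterior of ``spec`` given ``data``.

    Returns draws for every parameter (top-level and varying effects) with
    convergence diagnostics attached when at least two chains were run.
    A high divergence fraction is reported in the diagnostics, not raised.
    """
    config = config or McmcConfig()
    post = Posterior(spec, data, priors)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains + 1)
    all_draws = np.empty((config.chains, config.samples, post.dim))
    div = np.zeros(config.chains, dtype=int)
    hits = np.zeros(config.chains, dtype=int)
    steps = np.zeros(config.chains)
    acc = np.zeros(config.chains)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for c in range(config.chains):
            rng = np.random.default_rng(seeds[c])
            all_draws[c], div[c], hits[c], steps[c], acc[c] = _run_chain(post, config, rng)

    flat = all_draws.reshape(config.chains * config.samples, post.dim)
    extracted = post.extract(flat)
    if post.marginal_case:
        extracted["case"] = post.conditional_case_draw(
            extracted, np.random.default_rng(seeds[config.chains])
        )
    params = {
        k: v.reshape(config.chains, config.samples, *v.shape[1:])
        for k, v in extracted.items()
    }
    draws = PosteriorDraws(
        spec=spec, params=params, sd_keys=post.sd_keys,
        scale_colnames=post.design.scale_colnames,
        study_labels=list(post.design.study_labels), config=config,
        divergences=div, treedepth_hits=hits, step_sizes=steps, accept_stat=acc,
    )
    if config.chains >= 2:
        draws.diagnostics = diagnose(draws, include_effects=False)
    return draws


def diagnose(draws: PosteriorDraws, include_effects: bool = True,
             rhat_threshold: float = 1.01) -> pd.DataFrame:
    """Rank-normalized split R-hat and bulk ESS per scalar coordinate.

    With a single chain R-hat is unavailable and flagged as such rather than
    silently reported.
    """
    import arviz as az

    scalars = draws.scalar_dict(include_effects=include_effects)
    single = draws.n_chains < 2
    rows = []
    idata = az.from_dict(posterior={k: v for k, v in scalars.items()})
    ess = az.ess(idata, method="bulk")
    rhat = None if single else az.rhat(idata)
    for name in scalars:
        r = float("nan") if single else float(rhat[name].values)
        e = float(ess[name].values)
        flag = []
        if single:
            flag.append("rhat_unavailable_single_chain")
        elif r > rhat_threshold:
            flag.append("rhat_high")
        rows.append({"param": name, "rhat": r, "ess_bulk": e, "flags": ";".join(flag)})
    out = pd.DataFrame(rows)
    out.attrs["divergences"] = int(np.sum(draws.divergences))
    return out
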