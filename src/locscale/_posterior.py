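"""Unconstrained posterior with analytic gradients.

The sampler works on a flat unconstrained vector ``theta``:

* fixed effects — identity;
* standard deviations — log transform (with Jacobian);
* correlation matrices — canonical partial correlations (CPCs) through
  ``tanh``, combined into a Cholesky factor;
* varying effects — non-centred: standardized draws ``u`` scaled by the SDs
  and correlation Cholesky factor (``b = diag(s) L u``), which removes the
  funnel geometry that otherwise defeats gradient-based samplers in
  hierarchical scale models.

``logpost_grad`` returns the log posterior density over ``theta`` (the
natural-space joint density plus all change-of-variable terms) and its exact
gradient, assembled by hand via the chain rule. Everything is vectorized
over observations and studies; the only Python loops are over the handful
of random-effect blocks and the <= 4 rows of a correlation factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .models import Design, ModelSpec, ParameterSet, build_design, coord_key
from .priors import cholesky_to_cpc, cpc_to_cholesky, lkj_logpdf

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class _GroupInfo:
    coords: tuple
    d: int
    sd_idx: np.ndarray      # indices into the sd vector
    sl_y: slice             # CPC coordinates (empty slice when d == 1)
    sl_u: slice             # standardized effects, reshaped (d, I)
    rows: np.ndarray        # edge row indices (d > 1)
    cols: np.ndarray
    a_edge: np.ndarray      # per-edge Beta shape for the LKJ prior
    edge_const: np.ndarray  # per-edge additive constant of prior + Jacobian


class Posterior:
    """Packed unconstrained posterior for one (spec, dataset) pair.

    With ``marginalize_case=True`` (the default used by the sampler) the
    nested case-level intercepts of the meta family are integrated out
    analytically — the observation variance gains ``omega^2`` — which
    removes one coordinate per observation; the case effects can then be
    recovered exactly per posterior draw from their conjugate Gaussian
    conditional (:meth:`conditional_case_draw`). ``marginalize_case=False``
    keeps them as explicit coordinates (useful for density cross-checks).
    """

    def __init__(self, spec: ModelSpec, data, priors=None, marginalize_case: bool = True):
        self.spec = spec
        self.data = data
        self.design: Design = build_design(spec, data, priors)
        d = self.design
        self.I = d.n_studies
        self.n = d.n_obs
        self.is_meta = spec.family == "gaussian_known_variance"
        self.has_scale = spec.has_scale
        self.marginal_case = bool(marginalize_case and spec.case_level_intercept)
        self.case = spec.case_level_intercept and not self.marginal_case
        self.has_case_sd = spec.case_level_intercept
        self.p = d.X_loc.shape[1]
        self.q = d.X_scale.shape[1]
        self.sd_keys = spec.sd_keys()
        self.n_sd = len(self.sd_keys)

        pos = 0
        self.sl_bl = slice(pos, pos + self.p); pos += self.p
        self.sl_bs = slice(pos, pos + self.q); pos += self.q
        self.sl_sd = slice(pos, pos + self.n_sd); pos += self.n_sd

        eta = d.priors.lkj_eta
        self.group_infos: list[_GroupInfo] = []
        sd_cursor = 0
        y_slices = []
        for grp in spec.groups:
            gd = len(grp)
            m = gd * (gd - 1) // 2
            sl_y = slice(pos, pos + m); pos += m
            rows, cols = np.tril_indices(gd, k=-1)
            a_edge = np.array([eta + (gd - 1 - (j + 1)) / 2.0 for j in cols])
            edge_const = -(2 * a_edge - 1) * np.log(2.0) - special.betaln(a_edge, a_edge)
            self.group_infos.append(
                _GroupInfo(tuple(grp), gd, np.arange(sd_cursor, sd_cursor + gd),
                           sl_y, slice(0, 0), rows, cols, a_edge, edge_const)
            )
            sd_cursor += gd
            y_slices.append(sl_y)
        for gi, grp in enumerate(spec.groups):
            gd = len(grp)
            self.group_infos[gi].sl_u = slice(pos, pos + gd * self.I)
            pos += gd * self.I
        if self.has_case_sd:
            self.case_sd_idx = self.n_sd - 1
        if self.case:
            self.sl_case = slice(pos, pos + self.n); pos += self.n
        self.dim = pos

        self.loc_priors = [getattr(d.priors, r) for r in d.loc_roles]
        self.scale_priors = [getattr(d.priors, r) for r in d.scale_roles]
        self.sd_prior = d.priors.sd
        # vectorized prior tables for the hot path (fixed effects, then SDs)
        fx = self.loc_priors + self.scale_priors
        self._fx_loc = np.array([pr.loc for pr in fx])
        self._fx_scale = np.array([pr.scale for pr in fx])
        # placeholder df for non-t entries keeps the masked branch finite
        self._fx_df = np.array([pr.df if "student" in pr.kind else 10.0 for pr in fx])
        self._fx_is_t = np.array(["student" in pr.kind for pr in fx])
        self._fx_const = np.array([pr._log_const for pr in fx])
        sp = self.sd_prior
        self._sd_is_t = "student" in sp.kind
        self._sd_df = sp.df
        self._sd_scale = sp.scale
        self._sd_const = sp._log_const
        # per-observation multiplier per random coord, in group order
        self.coord_parts = []
        for G in self.group_infos:
            self.coord_parts.append(
                [(c[0], d.coord_x[coord_key(c)]) for c in G.coords]
            )

    # ------------------------------------------------------------------
    def logpost_grad(self, th: np.ndarray):
        d = self.design
        g = np.zeros_like(th)
        lp = 0.0
        bl = th[self.sl_bl]
        bs = th[self.sl_bs]
        ls = th[self.sl_sd]
        s = np.exp(ls)

        chol_list, z_list = [], []
        for G in self.group_infos:
            if G.d == 1:
                chol_list.append(None); z_list.append(None)
                continue
            z = np.tanh(th[G.sl_y])
            zmat = np.zeros((G.d, G.d))
            zmat[G.rows, G.cols] = z
            chol_list.append(cpc_to_cholesky(zmat))
            z_list.append(z)

        mu = d.X_loc @ bl
        eta = d.X_scale @ bs if self.has_scale else None
        U_list, A_list = [], []
        for gi, G in enumerate(self.group_infos):
            U = th[G.sl_u].reshape(G.d, self.I)
            A = U if G.d == 1 else chol_list[gi] @ U
            B = s[G.sd_idx][:, None] * A
            U_list.append(U); A_list.append(A)
            for k, (part, x_c) in enumerate(self.coord_parts[gi]):
                contrib = B[k][d.study] * x_c
                if part == "loc":
                    mu = mu + contrib
                else:
                    eta = eta + contrib
        if self.case:
            u_case = th[self.sl_case]
            s_case = s[self.case_sd_idx]
            mu = mu + s_case * u_case

        # observation terms ------------------------------------------------
        if self.is_meta:
            V = d.v_known
            if self.has_scale:
                sig2 = np.exp(np.minimum(2.0 * eta, 700.0))
                V = V + sig2
            if self.marginal_case:
                s_case2 = s[self.case_sd_idx] ** 2
                V = V + s_case2
            r = d.y - mu
            lp += -0.5 * float((np.log(2.0 * np.pi * V) + r * r / V).sum())
            gmu = r / V
            gv2 = (r * r / (V * V) - 1.0 / V) if (self.has_scale or self.marginal_case) else None
            geta = sig2 * gv2 if self.has_scale else None
            if self.marginal_case:
                g_ls_case = s_case2 * float(gv2.sum())
        else:
            inv_s2 = np.exp(np.minimum(-2.0 * eta, 700.0))
            r = d.y - mu
            lp += float((-eta - 0.5 * _LOG_2PI - 0.5 * r * r * inv_s2 + d.log_jac).sum())
            gmu = r * inv_s2
            geta = -1.0 + r * r * inv_s2

        g[self.sl_bl] += d.X_loc.T @ gmu
        if self.has_scale and self.q:
            g[self.sl_bs] += d.X_scale.T @ geta
        g_ls = np.zeros(self.n_sd)

        # varying-effect blocks --------------------------------------------
        for gi, G in enumerate(self.group_infos):
            gb = np.empty((G.d, self.I))
            for k, (part, x_c) in enumerate(self.coord_parts[gi]):
                w = (gmu if part == "loc" else geta) * x_c
                gb[k] = np.bincount(d.study, weights=w, minlength=self.I)
            sg = s[G.sd_idx]
            g_ls[G.sd_idx] += (A_list[gi] * gb).sum(axis=1) * sg
            GA = sg[:, None] * gb
            U = U_list[gi]
            if G.d == 1:
                gU = GA
            else:
                L = chol_list[gi]
                gU = L.T @ GA
                GL = GA @ U.T
                z = z_list[gi]
                gz = self._chol_backward(GL, z, L, G)
                lp += float((G.a_edge * np.log1p(-z * z) + G.edge_const).sum())
                g[G.sl_y] += gz * (1.0 - z * z) - 2.0 * G.a_edge * z
            g[G.sl_u] += (gU - U).ravel()
            lp += -0.5 * float((U * U).sum()) - 0.5 * G.d * self.I * _LOG_2PI
        if self.marginal_case:
            g_ls[self.case_sd_idx] += g_ls_case
        elif self.case:
            g[self.sl_case] += s_case * gmu - u_case
            g_ls[self.case_sd_idx] += s_case * float((u_case * gmu).sum())
            lp += -0.5 * float((u_case * u_case).sum()) - 0.5 * self.n * _LOG_2PI

        # priors on fixed effects and SDs (vectorized tables) --------------
        if self.p + self.q:
            b_fx = th[: self.p + self.q]
            t = (b_fx - self._fx_loc) / self._fx_scale
            t2 = t * t
            df = self._fx_df
            lp_fx = np.where(
                self._fx_is_t,
                self._fx_const - 0.5 * (df + 1) * np.log1p(t2 / df),
                self._fx_const - 0.5 * t2,
            )
            g_fx = np.where(
                self._fx_is_t,
                -(df + 1) * t / (self._fx_scale * (df + t2)),
                -t / self._fx_scale,
            )
            lp += float(lp_fx.sum())
            g[: self.p + self.q] += g_fx
        if self.n_sd:
            t = s / self._sd_scale
            t2 = t * t
            if self._sd_is_t:
                v = self._sd_df
                lp += float((self._sd_const - 0.5 * (v + 1) * np.log1p(t2 / v)).sum())
                g_ls += -(v + 1) * t / (self._sd_scale * (v + t2)) * s
            else:
                lp += float((self._sd_const - 0.5 * t2).sum())
                g_ls += -t / self._sd_scale * s
            lp += float(ls.sum())
            g_ls += 1.0
            g[self.sl_sd] += g_ls
        return lp, g

    def logpost(self, th: np.ndarray) -> float:
        return self.logpost_grad(th)[0]

    @staticmethod
    def _chol_backward(GL: np.ndarray, z_edges: np.ndarray, L: np.ndarray,
                       G: _GroupInfo) -> np.ndarray:
        """d(logp)/d(CPC z) given d(logp)/dL, for one correlation factor."""
        d = G.d
        zmat = np.zeros((d, d))
        zmat[G.rows, G.cols] = z_edges
        gz = np.zeros_like(z_edges)
        for e, (i, j) in enumerate(zip(G.rows, G.cols)):
            rem = 1.0
            for k in range(j):
                rem *= 1.0 - zmat[i, k] ** 2
            tail = 0.0
            for jp in range(j + 1, i + 1):
                tail += GL[i, jp] * L[i, jp]
            zij = zmat[i, j]
            gz[e] = GL[i, j] * np.sqrt(rem) - zij / (1.0 - zij * zij) * tail
        return gz

    # ------------------------------------------------------------------
    # packing / unpacking
    # ------------------------------------------------------------------
    def unpack(self, th: np.ndarray) -> ParameterSet:
        """Unconstrained vector -> natural-space ParameterSet."""
        s = np.exp(th[self.sl_sd])
        sd = {k: float(s[i]) for i, k in enumerate(self.sd_keys)}
        corr = {}
        effects = {}
        for gi, G in enumerate(self.group_infos):
            U = th[G.sl_u].reshape(G.d, self.I)
            if G.d == 1:
                block = s[G.sd_idx][:, None] * U
            else:
                z = np.tanh(th[G.sl_y])
                zmat = np.zeros((G.d, G.d))
                zmat[G.rows, G.cols] = z
                L = cpc_to_cholesky(zmat)
                corr[gi] = L @ L.T
                block = s[G.sd_idx][:, None] * (L @ U)
            for k, c in enumerate(G.coords):
                effects[coord_key(c)] = block[k].copy()
        case = None
        if self.case:
            case = s[self.case_sd_idx] * th[self.sl_case]
        return ParameterSet(
            beta_loc=th[self.sl_bl].copy(),
            beta_scale=th[self.sl_bs].copy(),
            sd=sd, corr=corr,
            study_effects=effects if effects else None,
            case_effects=case,
        )

    def pack(self, params: ParameterSet) -> np.ndarray:
        """Natural-space ParameterSet -> unconstrained vector (inverse of unpack)."""
        th = np.zeros(self.dim)
        th[self.sl_bl] = np.asarray(params.beta_loc, dtype=float)
        th[self.sl_bs] = np.asarray(params.beta_scale, dtype=float)
        s = np.array([params.sd[k] for k in self.sd_keys], dtype=float)
        if np.any(s <= 0):
            raise ValueError("pack requires strictly positive SDs")
        th[self.sl_sd] = np.log(s)
        for gi, G in enumerate(self.group_infos):
            b = np.vstack([params.study_effects[coord_key(c)] for c in G.coords])
            if G.d == 1:
                U = b / s[G.sd_idx][:, None]
            else:
                corr = np.asarray(params.corr[gi], dtype=float)
                L = np.linalg.cholesky(corr)
                zmat = cholesky_to_cpc(L)
                th[G.sl_y] = np.arctanh(zmat[G.rows, G.cols])
                U = np.linalg.solve(L, b / s[G.sd_idx][:, None])
            th[G.sl_u] = U.ravel()
        if self.case:
            th[self.sl_case] = np.asarray(params.case_effects, dtype=float) / s[self.case_sd_idx]
        return th

    def jacobian_correction(self, th: np.ndarray) -> float:
        """logpost(theta) - log_joint(unpack(theta)) in closed form.

        Collects the log-transform Jacobians of the SDs, the non-centring
        determinant per study, and the CPC-space correlation prior minus the
        natural-space LKJ density.
        """
        ls = th[self.sl_sd]
        s = np.exp(ls)
        total = float(np.sum(ls))
        for gi, G in enumerate(self.group_infos):
            sd_logdet = float(np.sum(np.log(s[G.sd_idx])))
            if G.d == 1:
                total += self.I * sd_logdet
            else:
                z = np.tanh(th[G.sl_y])
                zmat = np.zeros((G.d, G.d))
                zmat[G.rows, G.cols] = z
                L = cpc_to_cholesky(zmat)
                total += self.I * (sd_logdet + float(np.sum(np.log(np.diag(L)))))
                z_prior = float(np.sum(G.a_edge * np.log1p(-z * z) + G.edge_const))
                total += z_prior - lkj_logpdf(L @ L.T, self.design.priors.lkj_eta)
        if self.case:
            total += self.n * float(np.log(s[self.case_sd_idx]))
        return total

    # ------------------------------------------------------------------
    def init_theta(self, rng: np.random.Generator) -> np.ndarray:
        th = np.zeros(self.dim)
        for j, pr in enumerate(self.loc_priors):
            m, sd_ = pr.mean_sd()
            th[self.sl_bl.start + j] = m + 0.1 * sd_ * rng.standard_normal()
        resid0 = max(float(np.std(self.design.y)), 0.05) if self.n else 0.3
        for j, role in enumerate(self.design.scale_roles):
            base = np.log(0.5 * resid0) if role == "scale_coef" else 0.0
            th[self.sl_bs.start + j] = base + 0.1 * rng.standard_normal()
        th[self.sl_sd] = np.log(0.3) + 0.2 * rng.standard_normal(self.n_sd)
        for G in self.group_infos:
            if G.d > 1:
                th[G.sl_y] = 0.1 * rng.standard_normal(G.sl_y.stop - G.sl_y.start)
            th[G.sl_u] = 0.2 * rng.standard_normal(G.d * self.I)
        if self.case:
            th[self.sl_case] = 0.2 * rng.standard_normal(self.n)
        return th

    # ------------------------------------------------------------------
    def extract(self, thetas: np.ndarray) -> dict:
        """Vectorized natural-space extraction for a (N, dim) draw matrix."""
        N = thetas.shape[0]
        out = {
            "beta_loc": thetas[:, self.sl_bl].copy(),
            "beta_scale": thetas[:, self.sl_bs].copy(),
            "sd": np.exp(thetas[:, self.sl_sd]),
        }
        for gi, G in enumerate(self.group_infos):
            U = thetas[:, G.sl_u].reshape(N, G.d, self.I)
            sg = out["sd"][:, G.sd_idx]  # (N, d)
            if G.d == 1:
                block = sg[:, :, None] * U
            else:
                z = np.tanh(thetas[:, G.sl_y])
                L = _chol_batch(z, G)
                out[f"corr{gi}"] = L @ np.swapaxes(L, 1, 2)
                block = sg[:, :, None] * (L @ U)
            for k, c in enumerate(G.coords):
                out[f"b_{coord_key(c)}"] = block[:, k, :]
        if self.case:
            s_case = out["sd"][:, self.case_sd_idx]
            out["case"] = s_case[:, None] * thetas[:, self.sl_case]
        return out

    def conditional_case_draw(self, extracted: dict, rng: np.random.Generator) -> np.ndarray:
        """Exact conjugate draws of marginalized case-level intercepts.

        Given each posterior draw's other parameters, the case intercept of
        observation ``ij`` is Gaussian with precision ``1/omega^2 + 1/v_ij``
        where ``v_ij`` is the remaining observation variance; this recovers
        the joint posterior exactly.
        """
        if not self.marginal_case:
            raise RuntimeError("case effects were sampled explicitly")
        d = self.design
        mu = extracted["beta_loc"] @ d.X_loc.T
        eta = extracted["beta_scale"] @ d.X_scale.T if self.has_scale else None
        for gi, G in enumerate(self.group_infos):
            for k, (part, x_c) in enumerate(self.coord_parts[gi]):
                key = coord_key(G.coords[k])
                contrib = extracted[f"b_{key}"][:, d.study] * x_c[None, :]
                if part == "loc":
                    mu = mu + contrib
                else:
                    eta = eta + contrib
        var_rest = np.broadcast_to(d.v_known[None, :], mu.shape).copy()
        if self.has_scale:
            var_rest = var_rest + np.exp(2.0 * eta)
        w = (extracted["sd"][:, self.case_sd_idx] ** 2)[:, None]
        r = d.y[None, :] - mu
        post_var = w * var_rest / (w + var_rest)
        post_mean = r * w / (w + var_rest)
        return post_mean + np.sqrt(post_var) * rng.standard_normal(mu.shape)


def _chol_batch(z: np.ndarray, G: _GroupInfo) -> np.ndarray:
    N = z.shape[0]
    d = G.d
    zm = np.zeros((N, d, d))
    zm[:, G.rows, G.cols] = z
    L = np.zeros((N, d, d))
    L[:, 0, 0] = 1.0
    for i in range(1, d):
        rem = np.ones(N)
        for j in range(i):
            L[:, i, j] = zm[:, i, j] * np.sqrt(rem)
            rem = rem * (1.0 - zm[:, i, j] ** 2)
        L[:, i, i] = np.sqrt(rem)
    return L
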