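"""Independent brute-force oracles.

Everything here is deliberately naive — per-observation Python loops and
library density calls — and shares no code with the package's vectorized
implementations. It exists to pin those implementations down numerically.
"""

import numpy as np
from scipy import special, stats

from locscale.data import EXTENT_BINS
from locscale.inference import McmcConfig, PosteriorDraws
from locscale.models import ParameterSet, build_design, coord_key
from locscale.priors import PriorSet


def _naive_lkj_log_norm(d, eta):
    total = 0.0
    for k in range(1, d):
        a = eta - 1.0 + (d - 1 - k) / 2.0
        total += (d - k) * ((2 * a + 1) * np.log(2.0) + float(special.betaln(a + 1, a + 1)))
    return total


def _resolve_priors(spec, y):
    if spec.priors is not None:
        return spec.priors
    return PriorSet().centred_on(np.asarray(y, dtype=float))


def _prior_logpdf(pr, x):
    if pr.kind == "normal":
        return float(stats.norm.logpdf(x, pr.loc, pr.scale))
    if pr.kind == "student_t":
        return float(stats.t.logpdf(x, pr.df, pr.loc, pr.scale))
    if pr.kind == "half_normal":
        return float(stats.halfnorm.logpdf(x, 0.0, pr.scale))
    if pr.kind == "half_student_t":
        return float(np.log(2.0) + stats.t.logpdf(x, pr.df, 0.0, pr.scale)) if x >= 0 else -np.inf
    raise ValueError(pr.kind)


def naive_log_joint(spec, params: ParameterSet, data):
    """Per-term summed joint log density with scipy pdf calls."""
    tab = data.table
    study_order = []
    for s in tab["study_id"]:
        if s not in study_order:
            study_order.append(s)
    study_pos = {s: i for i, s in enumerate(study_order)}

    loc_term = spec.location_terms[0] if spec.location_terms else None
    scale_numeric = [t for t in spec.scale_terms if t != "extent_bin"]

    total = 0.0
    y_for_priors = []
    for idx in range(len(tab)):
        row = tab.iloc[idx]
        i = study_pos[row["study_id"]]
        mu = float(params.beta_loc[0])
        if loc_term is not None:
            mu += float(params.beta_loc[1]) * float(row[loc_term])
        for grp in spec.groups:
            for c in grp:
                if c[0] != "loc":
                    continue
                b = float(params.study_effects[coord_key(c)][i])
                mult = 1.0 if c[1] == "icpt" else float(row[loc_term])
                mu += b * mult
        if spec.case_level_intercept:
            mu += float(params.case_effects[idx])

        if spec.has_scale:
            eta = 0.0
            col = 0
            if spec.scale_intercept:
                eta += float(params.beta_scale[col])
                col += 1
            for t in spec.scale_terms:
                if t == "extent_bin":
                    for b_lab in EXTENT_BINS:
                        if str(row["extent_bin"]) == b_lab:
                            eta += float(params.beta_scale[col])
                        col += 1
                else:
                    eta += float(params.beta_scale[col]) * float(row[t])
                    col += 1
            for grp in spec.groups:
                for c in grp:
                    if c[0] != "scale":
                        continue
                    b = float(params.study_effects[coord_key(c)][i])
                    mult = 1.0 if c[1] == "icpt" else float(row[scale_numeric[0]])
                    eta += b * mult
            sigma = np.exp(eta)
        if spec.family == "gaussian_known_variance":
            var = float(row["var_z"])
            if spec.has_scale:
                var += sigma ** 2
            total += float(stats.norm.logpdf(float(row["z"]), mu, np.sqrt(var)))
            y_for_priors.append(float(row["z"]))
        else:
            s_val = float(row["richness"])
            # lognormal density of S with log-mean mu and log-sd sigma
            total += float(stats.lognorm.logpdf(s_val, s=sigma, scale=np.exp(mu)))
            y_for_priors.append(np.log(s_val))

    # varying-effect densities
    n_studies = len(study_order)
    for gi, grp in enumerate(spec.groups):
        sds = [float(params.sd[coord_key(c)]) for c in grp]
        if len(grp) == 1:
            for i in range(n_studies):
                b = float(params.study_effects[coord_key(grp[0])][i])
                total += float(stats.norm.logpdf(b, 0.0, sds[0]))
        else:
            corr = np.asarray(params.corr[gi], dtype=float)
            cov = np.diag(sds) @ corr @ np.diag(sds)
            mvn = stats.multivariate_normal(mean=np.zeros(len(grp)), cov=cov)
            for i in range(n_studies):
                b = np.array([params.study_effects[coord_key(c)][i] for c in grp])
                total += float(mvn.logpdf(b))
    if spec.case_level_intercept:
        for idx in range(len(tab)):
            total += float(stats.norm.logpdf(float(params.case_effects[idx]),
                                             0.0, float(params.sd["case"])))

    # priors
    priors = _resolve_priors(spec, y_for_priors)
    total += _prior_logpdf(priors.loc_intercept, float(params.beta_loc[0]))
    if loc_term is not None:
        total += _prior_logpdf(priors.loc_slope, float(params.beta_loc[1]))
    if spec.has_scale:
        col = 0
        if spec.scale_intercept:
            total += _prior_logpdf(priors.scale_coef, float(params.beta_scale[col]))
            col += 1
        for t in spec.scale_terms:
            if t == "extent_bin":
                for _ in EXTENT_BINS:
                    total += _prior_logpdf(priors.scale_coef, float(params.beta_scale[col]))
                    col += 1
            else:
                total += _prior_logpdf(priors.scale_slope, float(params.beta_scale[col]))
                col += 1
    for key in spec.sd_keys():
        total += _prior_logpdf(priors.sd, float(params.sd[key]))
    for gi, grp in enumerate(spec.groups):
        if len(grp) > 1:
            corr = np.asarray(params.corr[gi], dtype=float)
            sign, logdet = np.linalg.slogdet(corr)
            total += (priors.lkj_eta - 1.0) * logdet - _naive_lkj_log_norm(len(grp), priors.lkj_eta)
    return total


def random_params(spec, data, rng) -> ParameterSet:
    """A random natural-space parameter set conforming to (spec, data)."""
    design = build_design(spec, data)
    p = design.X_loc.shape[1]
    q = design.X_scale.shape[1]
    n_studies = data.n_studies
    sd = {k: float(np.abs(rng.normal(0, 0.5)) + 0.05) for k in spec.sd_keys()}
    corr = {}
    effects = {}
    for gi, grp in enumerate(spec.groups):
        d = len(grp)
        if d > 1:
            a = rng.normal(size=(d, d + 2))
            c = a @ a.T
            dd = np.sqrt(np.diag(c))
            corr[gi] = c / np.outer(dd, dd)
        for c_ in grp:
            effects[coord_key(c_)] = rng.normal(0, 0.4, size=n_studies)
    return ParameterSet(
        beta_loc=rng.normal(0, 0.5, size=p),
        beta_scale=rng.normal(-0.5, 0.5, size=q),
        sd=sd, corr=corr, study_effects=effects if effects else None,
        case_effects=rng.normal(0, 0.3, size=data.n_obs)
        if spec.case_level_intercept else None,
    )


def draws_from_params(spec, data, param_list) -> PosteriorDraws:
    """Assemble a PosteriorDraws object from explicit parameter sets (1 chain)."""
    design = build_design(spec, data)
    S = len(param_list)
    params = {
        "beta_loc": np.stack([p.beta_loc for p in param_list])[None],
        "beta_scale": np.stack([np.asarray(p.beta_scale, dtype=float).reshape(-1)
                                for p in param_list])[None],
        "sd": np.stack([[p.sd[k] for k in spec.sd_keys()] for p in param_list])[None],
    }
    for gi, grp in enumerate(spec.groups):
        if len(grp) > 1:
            params[f"corr{gi}"] = np.stack([p.corr[gi] for p in param_list])[None]
        for c in grp:
            key = coord_key(c)
            params[f"b_{key}"] = np.stack([p.study_effects[key] for p in param_list])[None]
    if spec.case_level_intercept:
        params["case"] = np.stack([p.case_effects for p in param_list])[None]
    cfg = McmcConfig(chains=1, warmup=10, samples=S, seed=0)
    return PosteriorDraws(
        spec=spec, params=params, sd_keys=spec.sd_keys(),
        scale_colnames=design.scale_colnames,
        study_labels=list(design.study_labels), config=cfg,
        divergences=np.zeros(1, dtype=int), treedepth_hits=np.zeros(1, dtype=int),
        step_sizes=np.zeros(1), accept_stat=np.zeros(1),
    )
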