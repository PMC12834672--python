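"""Declarative location-scale model specifications and their densities.

The grammar covers two response families used in quantitative evidence
synthesis:

* ``gaussian_known_variance`` — meta-analytic effect sizes: each observation
  ``z_ij`` (case ``j`` in study ``i``) is normal around a location linear
  predictor with variance ``s_ij^2 + sigma_ij^2``, where ``s_ij^2`` is the
  known sampling variance and ``sigma_ij`` (when a scale submodel is
  present) is modelled on the log scale.
* ``lognormal`` — strictly positive responses (standardized species
  richness): ``S_ij ~ lognormal(mu_ij, sigma_ij^2)``.

Both the location (``mu``) and the log residual SD (``log sigma``) are
linear predictors with optional study-level varying effects; varying effects
can be grouped into a single multivariate normal so that location and scale
departures correlate (a double hierarchical model). The nine named presets
(m1_1..m1_4 for the meta case study, m2_1..m2_5 for the fragmentation case
study) are instances of this grammar, and arbitrary user compositions within
it are legal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular

from .data import EXTENT_BINS, Dataset, dataset_from_frame
from .priors import Prior, PriorSet, lkj_logpdf

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "ParameterSet",
    "Design",
    "spec_model",
    "build_design",
    "log_joint",
    "pointwise_log_lik",
    "simulate_response",
]

Coord = tuple  # ("loc" | "scale", "icpt" | "slope")

MODEL_NAMES = ("m1_1", "m1_2", "m1_3", "m1_4", "m2_1", "m2_2", "m2_3", "m2_4", "m2_5")


def coord_key(coord: Coord) -> str:
    return f"{coord[0]}_{coord[1]}"


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one location-scale hierarchical model.

    Attributes
    ----------
    family : str
        ``gaussian_known_variance`` or ``lognormal``.
    location_terms : tuple of str
        Covariate columns entering the location linear predictor (an
        intercept is always implicit).
    scale_terms : tuple of str
        Covariate columns for ``log sigma``. The special term
        ``"extent_bin"`` expands to cell-means indicator columns over the
        fixed extent label set.
    scale_intercept : bool
        Whether ``log sigma`` has a free intercept (suppressed for
        cell-means coding).
    has_scale : bool
        False only for the known-variance model without any estimated
        residual component (Model 1.1 style).
    groups : tuple of tuple of Coord
        Correlation groups of study-level varying effects. Each group is one
        multivariate normal; a singleton group is an independent normal.
        A group mixing ``loc`` and ``scale`` coords realizes cross-block
        correlation.
    case_level_intercept : bool
        Nested case-level intercept (one per observation row) in the
        location predictor.
    priors : PriorSet or None
        None means the weakly-informative defaults, with the location
        intercept centred on the observed response at build time.
    complexity_rank : int
        Count of free top-level parameters; used by the one-SE rule.
    order : int
        Position in the canonical model numbering; breaks complexity ties
        toward the earlier model.
    """

    name: str
    family: str
    location_terms: tuple = ()
    scale_terms: tuple = ()
    scale_intercept: bool = True
    has_scale: bool = True
    groups: tuple = ()
    case_level_intercept: bool = False
    priors: Optional[PriorSet] = None
    complexity_rank: int = 0
    order: int = 99

    def __post_init__(self):
        if self.family not in ("gaussian_known_variance", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "lognormal" and not self.has_scale:
            raise ValueError("lognormal family requires a residual scale component")
        flat = [c for g in self.groups for c in g]
        if len(set(flat)) != len(flat):
            raise ValueError("a varying coordinate may appear in only one group")
        for grp in self.groups:
            if len(grp) > 1 and not self.has_scale and any(c[0] == "scale" for c in grp):
                raise ValueError("scale varying effects require a scale component")
        if any(c[0] == "scale" for c in flat) and not self.has_scale:
            raise ValueError("scale varying effects require a scale component")
        if self.case_level_intercept and self.family != "gaussian_known_variance":
            raise ValueError("case-level intercept is defined for the meta family only")

    # -- structural helpers ------------------------------------------------
    @property
    def random_coords(self) -> list:
        return [c for g in self.groups for c in g]

    def sd_keys(self) -> list:
        keys = [coord_key(c) for c in self.random_coords]
        if self.case_level_intercept:
            keys.append("case")
        return keys

    def sd_display(self, key: str) -> str:
        gaussian = self.family == "gaussian_known_variance"
        table = {
            "loc_icpt": "tau" if gaussian else "sd_icpt",
            "loc_slope": "sd_slope",
            "scale_icpt": "zeta" if gaussian else "sd_icpt_sigma",
            "scale_slope": "sd_slope_sigma",
            "case": "omega",
        }
        return table[key]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        """Plain-data form suitable for YAML/JSON round-tripping."""
        out = {
            "name": self.name, "family": self.family,
            "location_terms": list(self.location_terms),
            "scale_terms": list(self.scale_terms),
            "scale_intercept": self.scale_intercept, "has_scale": self.has_scale,
            "groups": [[list(c) for c in grp] for grp in self.groups],
            "case_level_intercept": self.case_level_intercept,
            "complexity_rank": self.complexity_rank, "order": self.order,
        }
        if self.priors is not None:
            out["priors"] = {
                role: {"kind": pr.kind, "loc": pr.loc, "scale": pr.scale, "df": pr.df}
                for role, pr in (
                    ("loc_intercept", self.priors.loc_intercept),
                    ("loc_slope", self.priors.loc_slope),
                    ("scale_coef", self.priors.scale_coef),
                    ("scale_slope", self.priors.scale_slope),
                    ("sd", self.priors.sd),
                )
            }
            out["priors"]["lkj_eta"] = self.priors.lkj_eta
        return out

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelSpec":
        payload = dict(payload)
        priors = None
        if "priors" in payload:
            raw = dict(payload.pop("priors"))
            eta = raw.pop("lkj_eta", 1.0)
            priors = PriorSet(**{role: Prior(**kw) for role, kw in raw.items()},
                              lkj_eta=eta)
        payload["location_terms"] = tuple(payload.get("location_terms", ()))
        payload["scale_terms"] = tuple(payload.get("scale_terms", ()))
        payload["groups"] = tuple(
            tuple(tuple(c) for c in grp) for grp in payload.get("groups", ())
        )
        return cls(priors=priors, **payload)

    def corr_names(self, group_idx: int) -> list:
        short = {"loc_icpt": "icpt", "loc_slope": "slope",
                 "scale_icpt": "icpt_sigma", "scale_slope": "slope_sigma"}
        grp = self.groups[group_idx]
        names = []
        for i in range(1, len(grp)):
            for j in range(i):
                names.append(f"rho[{short[coord_key(grp[j])]},{short[coord_key(grp[i])]}]")
        return names


@dataclass
class ParameterSet:
    """Natural-space parameters conforming to a :class:`ModelSpec`.

    ``beta_loc`` stacks the location intercept then slopes; ``beta_scale``
    follows the scale design column order. ``sd`` maps each varying
    coordinate key (plus ``"case"``) to its standard deviation; ``corr``
    maps a group index to that group's correlation matrix (groups of size
    one need no entry). ``study_effects`` maps coordinate keys to per-study
    departures; ``case_effects`` holds the per-observation nested intercepts.
    """

    beta_loc: np.ndarray
    beta_scale: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sd: dict = field(default_factory=dict)
    corr: dict = field(default_factory=dict)
    study_effects: Optional[dict] = None
    case_effects: Optional[np.ndarray] = None

    # familiar aliases ------------------------------------------------------
    @property
    def beta0(self) -> float:
        return float(self.beta_loc[0])

    @property
    def beta1(self) -> float:
        return float(self.beta_loc[1])

    @property
    def tau(self) -> float:
        return float(self.sd["loc_icpt"])

    @property
    def omega(self) -> float:
        return float(self.sd["case"])

    @property
    def zeta(self) -> float:
        return float(self.sd["scale_icpt"])

    @property
    def beta0_sigma(self) -> float:
        return float(self.beta_scale[0])

    @property
    def beta1_sigma(self) -> float:
        return float(self.beta_scale[1])

    @property
    def sigma_resid(self) -> float:
        """Residual SD implied by an intercept-only scale model."""
        return float(np.exp(self.beta_scale[0]))


# --------------------------------------------------------------------------
# Named presets
# --------------------------------------------------------------------------

def spec_model(name: str) -> ModelSpec:
    """Return one of the nine named location-scale model specifications.

    Meta-analytic family (responses are Fisher-z effect sizes with known
    sampling variances; ``X`` is log grain size):

    * ``m1_1`` — homoscedastic meta-regression: study and nested case
      intercepts, constant between-study variance, no scale submodel.
    * ``m1_2`` — ``log sigma_ij = beta0^s + beta1^s X_ij``; the case-level
      intercept is dropped (sigma and omega describe the same level).
    * ``m1_3`` — scale cell-means over spatial-extent bins (no scale
      intercept); location part identical to m1_2.
    * ``m1_4`` — study-varying scale intercepts with SD zeta.

    Lognormal family (responses are standardized richness; ``X`` is centred
    log fragment size):

    * ``m2_1`` — correlated study intercept + slope for the location,
      constant residual SD.
    * ``m2_2`` — adds independent study-varying log-sigma intercepts.
    * ``m2_3`` — adds a fragment-size slope for log sigma; scale-block
      intercept/slope correlate with each other, independently of the
      location block.
    * ``m2_4`` — one 3x3 MVN over (location icpt, location slope, scale
      icpt).
    * ``m2_5`` — one 4x4 MVN over all four varying effects.
    """
    G = "gaussian_known_variance"
    L = "lognormal"
    li, lsl = ("loc", "icpt"), ("loc", "slope")
    si, ssl = ("scale", "icpt"), ("scale", "slope")
    presets = {
        "m1_1": ModelSpec("m1_1", G, ("log_grain",), (), scale_intercept=False,
                          has_scale=False, groups=((li,),), case_level_intercept=True,
                          complexity_rank=4, order=0),
        "m1_2": ModelSpec("m1_2", G, ("log_grain",), ("log_grain",),
                          groups=((li,),), complexity_rank=5, order=1),
        "m1_3": ModelSpec("m1_3", G, ("log_grain",), ("extent_bin",),
                          scale_intercept=False, groups=((li,),),
                          complexity_rank=3 + len(EXTENT_BINS), order=2),
        "m1_4": ModelSpec("m1_4", G, ("log_grain",), (),
                          groups=((li,), (si,)), complexity_rank=5, order=3),
        "m2_1": ModelSpec("m2_1", L, ("log_frag_size",), (),
                          groups=((li, lsl),), complexity_rank=6, order=4),
        "m2_2": ModelSpec("m2_2", L, ("log_frag_size",), (),
                          groups=((li, lsl), (si,)), complexity_rank=7, order=5),
        "m2_3": ModelSpec("m2_3", L, ("log_frag_size",), ("log_frag_size",),
                          groups=((li, lsl), (si, ssl)), complexity_rank=10, order=6),
        "m2_4": ModelSpec("m2_4", L, ("log_frag_size",), (),
                          groups=((li, lsl, si),), complexity_rank=9, order=7),
        "m2_5": ModelSpec("m2_5", L, ("log_frag_size",), ("log_frag_size",),
                          groups=((li, lsl, si, ssl),), complexity_rank=14, order=8),
    }
    if name not in presets:
        raise ValueError(f"unknown model name {name!r}; choose from {MODEL_NAMES}")
    return presets[name]


# --------------------------------------------------------------------------
# Design construction
# --------------------------------------------------------------------------

@dataclass
class Design:
    """Numeric arrays realizing a spec on a concrete dataset."""

    y: np.ndarray            # response on the modelling scale (z, or log S)
    log_jac: np.ndarray      # -log S for lognormal (0 for meta): data-scale density
    v_known: np.ndarray      # known sampling variances (zeros for lognormal)
    X_loc: np.ndarray        # (n, p) location design
    X_scale: np.ndarray      # (n, q) scale design (q = 0 when has_scale is False)
    loc_roles: list          # prior role per location column
    scale_roles: list        # prior role per scale column
    scale_colnames: list
    coord_x: dict            # coord key -> per-observation multiplier
    study: np.ndarray        # integer study codes per observation
    n_studies: int
    study_labels: list
    priors: PriorSet

    @property
    def n_obs(self) -> int:
        return len(self.y)


def build_design(spec: ModelSpec, data: Dataset, priors: Optional[PriorSet] = None) -> Design:
    """Materialize the design matrices and resolved priors for (spec, data)."""
    tab = data.table
    n = data.n_obs
    if spec.family == "gaussian_known_variance":
        if data.kind != "meta":
            raise ValueError("gaussian_known_variance requires a meta dataset")
        y = tab["z"].to_numpy(dtype=float)
        v = tab["var_z"].to_numpy(dtype=float)
        if np.any(v <= 0):
            raise ValueError("var_z must be positive for every observation")
        log_jac = np.zeros(n)
    else:
        if data.kind != "fragment":
            raise ValueError("lognormal family requires a fragment dataset")
        s_resp = tab["richness"].to_numpy(dtype=float)
        if np.any(s_resp <= 0):
            raise ValueError("richness must be strictly positive")
        y = np.log(s_resp)
        v = np.zeros(n)
        log_jac = -y  # d(log S)/dS: lognormal density of S vs normal density of log S

    cols = [np.ones(n)]
    loc_roles = ["loc_intercept"]
    for term in spec.location_terms:
        cols.append(tab[term].to_numpy(dtype=float))
        loc_roles.append("loc_slope")
    X_loc = np.column_stack(cols)

    s_cols, scale_roles, scale_names = [], [], []
    if spec.has_scale:
        if spec.scale_intercept:
            s_cols.append(np.ones(n))
            scale_roles.append("scale_coef")
            scale_names.append("beta0_sigma")
        for term in spec.scale_terms:
            if term == "extent_bin":
                labels = tab["extent_bin"].astype(str).to_numpy()
                unknown = set(labels) - set(EXTENT_BINS)
                if unknown:
                    raise ValueError(f"extent labels outside the fixed set: {sorted(unknown)}")
                for b in EXTENT_BINS:
                    s_cols.append((labels == b).astype(float))
                    scale_roles.append("scale_coef")
                    scale_names.append(f"beta_sigma[{b}]")
            else:
                s_cols.append(tab[term].to_numpy(dtype=float))
                scale_roles.append("scale_slope")
                scale_names.append("beta1_sigma")
    X_scale = np.column_stack(s_cols) if s_cols else np.zeros((n, 0))

    coord_x = {}
    for c in spec.random_coords:
        if c[1] == "icpt":
            coord_x[coord_key(c)] = np.ones(n)
        else:
            term = spec.location_terms[0] if c[0] == "loc" else _numeric_scale_term(spec)
            coord_x[coord_key(c)] = tab[term].to_numpy(dtype=float)

    if priors is not None:
        resolved = priors
    elif spec.priors is not None:
        resolved = spec.priors
    else:
        resolved = PriorSet().centred_on(y)
    return Design(
        y=y, log_jac=log_jac, v_known=v, X_loc=X_loc, X_scale=X_scale,
        loc_roles=loc_roles, scale_roles=scale_roles, scale_colnames=scale_names,
        coord_x=coord_x, study=data.study_codes(), n_studies=data.n_studies,
        study_labels=data.study_labels, priors=resolved,
    )


def _numeric_scale_term(spec: ModelSpec) -> str:
    numeric = [t for t in spec.scale_terms if t != "extent_bin"]
    if not numeric:
        raise ValueError("a scale slope varying effect needs a numeric scale term")
    return numeric[0]


def _prior_for(priors: PriorSet, role: str) -> Prior:
    return getattr(priors, role)


# --------------------------------------------------------------------------
# Densities
# --------------------------------------------------------------------------

def _linear_predictors(spec, params: ParameterSet, design: Design):
    """(mu, log_sigma) per observation from natural-space parameters."""
    if params.study_effects is None and spec.random_coords:
        raise ValueError("ParameterSet.study_effects required (draw them or fit first)")
    mu = design.X_loc @ np.asarray(params.beta_loc, dtype=float)
    eta = design.X_scale @ np.asarray(params.beta_scale, dtype=float) if spec.has_scale else None
    for c in spec.random_coords:
        key = coord_key(c)
        b = np.asarray(params.study_effects[key], dtype=float)
        if b.shape[0] != design.n_studies:
            raise ValueError(f"study effects for {key} have length {b.shape[0]}, expected {design.n_studies}")
        contrib = b[design.study] * design.coord_x[key]
        if c[0] == "loc":
            mu = mu + contrib
        else:
            eta = eta + contrib
    if spec.case_level_intercept:
        if params.case_effects is None:
            raise ValueError("case_effects required for a case-level intercept model")
        mu = mu + np.asarray(params.case_effects, dtype=float)
    return mu, eta


def pointwise_log_lik(spec: ModelSpec, params: ParameterSet, data: Dataset) -> np.ndarray:
    """Observation-level log densities, in dataset row order.

    For the meta family this is ``Normal(z; mu, s^2 + sigma^2)``; for the
    lognormal family it is the lognormal density of the response itself
    (i.e. the normal density of ``log S`` plus the ``-log S`` Jacobian).
    """
    design = build_design(spec, data)
    mu, eta = _linear_predictors(spec, params, design)
    if spec.family == "gaussian_known_variance":
        var = design.v_known + (np.exp(2.0 * eta) if spec.has_scale else 0.0)
        return stats.norm.logpdf(design.y, loc=mu, scale=np.sqrt(var))
    sigma = np.exp(eta)
    return stats.norm.logpdf(design.y, loc=mu, scale=sigma) + design.log_jac


def log_joint(spec: ModelSpec, params: ParameterSet, data: Dataset) -> float:
    """Joint log density: observations + varying effects + priors.

    Natural-space (centred) parameterization: study effects contribute their
    (multivariate) normal log densities given the SDs and correlation
    matrices, and every free top-level parameter contributes its prior.
    """
    design = build_design(spec, data)
    total = float(np.sum(pointwise_log_lik(spec, params, data)))

    # varying-effect densities
    for gi, grp in enumerate(spec.groups):
        d = len(grp)
        sds = np.array([params.sd[coord_key(c)] for c in grp], dtype=float)
        if np.any(sds < 0):
            raise ValueError("standard deviations must be non-negative")
        b = np.column_stack([params.study_effects[coord_key(c)] for c in grp])  # (I, d)
        if d == 1:
            total += float(np.sum(stats.norm.logpdf(b[:, 0], scale=sds[0])))
        else:
            corr = np.asarray(params.corr[gi], dtype=float)
            if corr.shape != (d, d) or not np.allclose(corr, corr.T):
                raise ValueError("corr_block must be a symmetric d x d matrix")
            cov = np.outer(sds, sds) * corr
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as err:
                raise ValueError("corr_block is not positive definite") from err
            w = solve_triangular(chol, b.T, lower=True)
            logdet = float(np.sum(np.log(np.diag(chol))))
            total += float(
                -0.5 * np.sum(w * w)
                - b.shape[0] * (logdet + 0.5 * d * np.log(2.0 * np.pi))
            )
    if spec.case_level_intercept:
        total += float(np.sum(stats.norm.logpdf(params.case_effects, scale=params.sd["case"])))

    # priors
    for j, role in enumerate(design.loc_roles):
        total += float(_prior_for(design.priors, role).logpdf(params.beta_loc[j]))
    for j, role in enumerate(design.scale_roles):
        total += float(_prior_for(design.priors, role).logpdf(params.beta_scale[j]))
    for key in spec.sd_keys():
        total += float(design.priors.sd.logpdf(params.sd[key]))
    for gi, grp in enumerate(spec.groups):
        if len(grp) > 1:
            total += lkj_logpdf(np.asarray(params.corr[gi], dtype=float), design.priors.lkj_eta)
    return total


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def draw_study_effects(spec: ModelSpec, params: ParameterSet, n_studies: int,
                       rng: np.random.Generator) -> dict:
    """Sample study-level varying effects from their population distribution."""
    effects = {}
    for gi, grp in enumerate(spec.groups):
        d = len(grp)
        sds = np.array([params.sd[coord_key(c)] for c in grp], dtype=float)
        eps = rng.standard_normal((d, n_studies))
        if d == 1:
            block = sds[0] * eps
        else:
            corr = np.asarray(params.corr[gi], dtype=float)
            chol = np.linalg.cholesky(corr)
            block = sds[:, None] * (chol @ eps)
        for k, c in enumerate(grp):
            effects[coord_key(c)] = block[k]
    return effects


def simulate_response(spec: ModelSpec, params: ParameterSet, design_data: Dataset,
                      seed=None) -> tuple:
    """Draw responses from the spec's generative process on a given design.

    ``design_data`` supplies covariates, study structure and (meta kind) the
    known sampling variances; any response column is ignored. Missing
    ``study_effects``/``case_effects`` in ``params`` are drawn from their
    population distributions. Returns ``(dataset, params_used)`` where
    ``params_used`` includes the realized effects, and the same seed always
    reproduces the same dataset.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tab = design_data.table.copy()
    n = len(tab)
    work = ParameterSet(
        beta_loc=np.asarray(params.beta_loc, dtype=float),
        beta_scale=np.asarray(params.beta_scale, dtype=float),
        sd=dict(params.sd),
        corr={k: np.asarray(v, dtype=float) for k, v in params.corr.items()},
        study_effects=None if params.study_effects is None else dict(params.study_effects),
        case_effects=None if params.case_effects is None else np.asarray(params.case_effects),
    )
    if work.study_effects is None and spec.random_coords:
        work.study_effects = draw_study_effects(spec, work, design_data.n_studies, rng)
    if spec.case_level_intercept and work.case_effects is None:
        work.case_effects = work.sd["case"] * rng.standard_normal(n)

    if spec.family == "gaussian_known_variance":
        probe = tab.assign(z=0.0)
        probe_ds = dataset_from_frame(probe, "meta")
    else:
        probe = tab.assign(richness=1.0)
        probe_ds = dataset_from_frame(probe, "fragment", design_data.center_log_size)
    design = build_design(spec, probe_ds)
    mu, eta = _linear_predictors(spec, work, design)
    if spec.family == "gaussian_known_variance":
        var = design.v_known + (np.exp(2.0 * eta) if spec.has_scale else 0.0)
        tab["z"] = mu + np.sqrt(var) * rng.standard_normal(n)
        out = dataset_from_frame(tab, "meta")
    else:
        sigma = np.exp(eta)
        tab["richness"] = np.exp(mu + sigma * rng.standard_normal(n))
        out = dataset_from_frame(tab, "fragment", design_data.center_log_size)
    return out, work
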