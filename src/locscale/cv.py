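"""Cross-validation schemes, model comparison and the modified one-SE rule.

Two data-splitting schemes mirror two prediction goals:

* **stratified k-fold** approximates leave-one-out for *within-study*
  prediction: each study's cases are spread across folds as evenly as
  arithmetic allows (fold counts per study differ by at most one), so the
  relative study frequencies are maintained in every training fold;
* **leave-one-group-out (LOGO)** tests *new-study* transferability: whole
  studies are held out one at a time and scored marginally.

Model comparison uses total elpd; the standard error of a difference uses
the pointwise paired differences (not independent SEs). The modified
one-standard-error rule selects the least complex model whose total elpd is
within one SE (of the pairwise difference) of the best model's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset
from .elpd import elpd_conditional, elpd_marginal, elpd_total
from .inference import McmcConfig, fit
from .models import ModelSpec

__all__ = [
    "FoldAssignment",
    "CVReport",
    "assign_stratified_kfold",
    "run_kfold",
    "run_logo",
    "compare",
]


@dataclass
class FoldAssignment:
    """Fold id per observation under one splitting scheme."""

    scheme: str
    k: int
    labels: np.ndarray
    seed: int

    def folds(self):
        for f in range(self.k):
            yield f, np.flatnonzero(self.labels == f)


@dataclass
class CVReport:
    """Per-model elpd totals, pairwise difference SEs and one-SE selection."""

    scheme: str
    table: pd.DataFrame
    pointwise: dict
    selected_model: str
    best_model: str
    scheme_meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def meta(self) -> dict:
        return {"scheme": self.scheme, "selected_model": self.selected_model,
                "best_model": self.best_model, **self.scheme_meta}


# --------------------------------------------------------------------------
# fold assignment
# --------------------------------------------------------------------------

def assign_stratified_kfold(data: Dataset, k: int, seed: int = 0) -> FoldAssignment:
    """Study-stratified fold assignment with seeded within-study shuffling.

    Within each study the (shuffled) cases go to cyclically consecutive
    folds from a random starting fold, so per-study fold counts differ by at
    most one and a study with ``m < k`` cases lands in ``m`` distinct folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > data.n_obs:
        raise ValueError("k cannot exceed the number of observations")
    rng = np.random.default_rng(seed)
    labels = np.empty(data.n_obs, dtype=int)
    study = data.study_codes()
    for si in range(data.n_studies):
        rows = np.flatnonzero(study == si)
        rows = rng.permutation(rows)
        start = int(rng.integers(k))
        labels[rows] = (start + np.arange(rows.size)) % k
    return FoldAssignment("stratified_kfold", k, labels, seed)


def _categorical_scale_columns(spec: ModelSpec) -> bool:
    return "extent_bin" in spec.scale_terms


def _folds_cover_levels(data: Dataset, assignment: FoldAssignment) -> bool:
    """Every training fold must contain every extent bin present in the data."""
    levels = data.table["extent_bin"].astype(str).to_numpy()
    for _, heldout_rows in assignment.folds():
        mask = np.ones(data.n_obs, dtype=bool)
        mask[heldout_rows] = False
        if set(np.unique(levels)) - set(np.unique(levels[mask])):
            return False
    return True


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def run_kfold(specs: list[ModelSpec], data: Dataset, k: int = 10,
              config: McmcConfig | None = None, seed: int = 0,
              re_draws: int = 100) -> CVReport:
    """Stratified k-fold CV: refit every model per fold, score held-out cases.

    Held-out observations whose study appears in the training fold are
    scored conditionally; observations from studies entirely held out
    (single-case studies) are scored marginally. Folds are shared across
    models so pointwise differences stay paired. If a model uses extent-bin
    cell means, the assignment is re-drawn (up to 20 sub-seeds) until every
    training fold covers every bin; failing that, the model is fit anyway
    and an uncovered bin's coefficient simply follows its prior.
    """
    if not specs:
        raise ValueError("specs must be nonempty")
    config = config or McmcConfig()
    assignment = assign_stratified_kfold(data, k, seed)
    if any(_categorical_scale_columns(s) for s in specs) and "extent_bin" in data.table:
        for attempt in range(1, 21):
            if _folds_cover_levels(data, assignment):
                break
            assignment = assign_stratified_kfold(data, k, seed + 1000 * attempt)

    pointwise = {spec.name: np.full(data.n_obs, np.nan) for spec in specs}
    fold_seeds = np.random.SeedSequence(seed).spawn(k)
    for f, heldout_rows in assignment.folds():
        train_rows = np.setdiff1d(np.arange(data.n_obs), heldout_rows)
        train = data.subset(train_rows)
        heldout = data.subset(heldout_rows)
        fit_seed = int(fold_seeds[f].generate_state(1)[0] % (2 ** 31))
        train_studies = set(train.study_labels)
        seen_mask = np.array([s in train_studies for s in heldout.study_ids])
        for spec in specs:
            draws = fit(spec, train, _with_seed(config, fit_seed))
            vals = np.empty(heldout.n_obs)
            if seen_mask.any():
                sub = heldout.subset(np.flatnonzero(seen_mask))
                vals[seen_mask] = elpd_conditional(draws, spec, sub).values
            if (~seen_mask).any():
                sub = heldout.subset(np.flatnonzero(~seen_mask))
                vals[~seen_mask] = elpd_marginal(
                    draws, spec, sub, re_draws=re_draws, seed=fit_seed
                ).values
            pointwise[spec.name][heldout_rows] = vals
    report = compare(pointwise, specs)
    report.scheme = "stratified_kfold"
    report.scheme_meta.update({"k": k, "seed": seed, "mode": "conditional"})
    return report


def run_logo(specs: list[ModelSpec], data: Dataset,
             config: McmcConfig | None = None, seed: int = 0,
             re_draws: int = 100, max_heldout: int | None = None) -> CVReport:
    """Leave-one-group-out CV: hold out whole studies, score marginally.

    ``max_heldout`` optionally scores a seeded random subset of studies
    (the same subset for every model, keeping differences paired) — a
    computational-budget option for simulation studies; by default every
    study is held out once.
    """
    if not specs:
        raise ValueError("specs must be nonempty")
    if data.n_studies < 2:
        raise ValueError("leave-one-group-out requires at least 2 studies")
    config = config or McmcConfig()
    rng = np.random.default_rng(seed)
    labels = list(data.study_labels)
    if max_heldout is not None and max_heldout < len(labels):
        chosen = sorted(rng.choice(len(labels), size=max_heldout, replace=False))
        labels = [labels[i] for i in chosen]

    study = data.study_ids
    scored_rows = np.flatnonzero(np.isin(study, labels))
    pointwise = {spec.name: np.full(data.n_obs, np.nan) for spec in specs}
    fold_seeds = np.random.SeedSequence(seed).spawn(len(labels))
    for f, lab in enumerate(labels):
        heldout_rows = np.flatnonzero(study == lab)
        train_rows = np.flatnonzero(study != lab)
        train = data.subset(train_rows)
        heldout = data.subset(heldout_rows)
        fit_seed = int(fold_seeds[f].generate_state(1)[0] % (2 ** 31))
        for spec in specs:
            draws = fit(spec, train, _with_seed(config, fit_seed))
            vals = elpd_marginal(draws, spec, heldout, re_draws=re_draws, seed=fit_seed)
            pointwise[spec.name][heldout_rows] = vals.values
    trimmed = {name: v[scored_rows] for name, v in pointwise.items()}
    report = compare(trimmed, specs)
    report.scheme = "logo"
    report.scheme_meta.update(
        {"n_heldout_studies": len(labels), "n_studies": data.n_studies,
         "seed": seed, "mode": "marginal"}
    )
    return report


def _with_seed(config: McmcConfig, seed: int) -> McmcConfig:
    return McmcConfig(chains=config.chains, warmup=config.warmup,
                      samples=config.samples, seed=seed,
                      adapt_target=config.adapt_target,
                      max_treedepth=config.max_treedepth)


# --------------------------------------------------------------------------
# comparison and the one-SE rule
# --------------------------------------------------------------------------

def compare(pointwise: dict, specs: list[ModelSpec]) -> CVReport:
    """Assemble a CV report from aligned pointwise elpd vectors.

    The best model maximizes total elpd. For every other model the
    difference SE is ``sd(pointwise differences) * sqrt(N)``. The selected
    model is the least complex one whose difference from the best is at most
    one difference-SE (the best always qualifies); complexity ties break
    toward the earlier model in the canonical numbering, then by name.
    """
    by_name = {s.name: s for s in specs}
    if set(pointwise) != set(by_name):
        raise ValueError("pointwise vectors and specs name different models")
    lengths = {len(np.asarray(v)) for v in pointwise.values()}
    if len(lengths) != 1:
        raise ValueError("pointwise elpd vectors are misaligned")
    n = lengths.pop()
    if n == 0:
        raise ValueError("empty pointwise vectors")
    arrays = {m: np.asarray(v, dtype=float) for m, v in pointwise.items()}
    for m, v in arrays.items():
        if np.any(~np.isfinite(v)):
            raise ValueError(f"non-finite pointwise elpd for model {m}")

    totals = {m: elpd_total(v) for m, v in arrays.items()}
    best = max(totals, key=lambda m: totals[m][0])

    rows = []
    qualifying = []
    for m, (total, se) in totals.items():
        diff = totals[best][0] - total
        d_vec = arrays[best] - arrays[m]
        se_diff = 0.0 if m == best or n == 1 else float(np.std(d_vec, ddof=1) * np.sqrt(n))
        spec = by_name[m]
        rows.append({"model": m, "elpd": total, "se": se,
                     "elpd_diff": diff, "se_diff": se_diff,
                     "complexity_rank": spec.complexity_rank})
        if m == best or diff <= se_diff:
            qualifying.append(spec)
    selected = min(qualifying, key=lambda s: (s.complexity_rank, s.order, s.name)).name

    table = pd.DataFrame(rows).sort_values("elpd", ascending=False).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["selected"] = table["model"] == selected
    return CVReport(scheme="", table=table, pointwise=arrays,
                    selected_model=selected, best_model=best)
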