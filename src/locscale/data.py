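"""Shared data containers and tabular I/O for the two dataset schemas.

Two kinds of tables flow through the package:

* **meta** — one row per meta-analytic *case* (an effect size): a Fisher-z
  transformed correlation with its known sampling variance, nested in a
  *study*, with log grain size and a spatial-extent category as moderators.
* **fragment** — one row per habitat fragment: effort-standardized species
  richness with the fragment's (natural-log, mean-centred) size, nested in a
  study, with a taxon-group covariate.

Column names in deposited files are resolved through an explicit
``schema_map`` (canonical name -> file column); presets for the two public
deposits are in :data:`SCHEMA_PRESETS`. Reports are written as CSV plus a
JSON sidecar carrying a checksum of the canonical serialization so silent
corruption is detectable on re-read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .effects import fisher_z, fisher_z_variance

__all__ = [
    "EXTENT_BINS",
    "SCHEMA_PRESETS",
    "EffectSizeRecord",
    "FragmentRecord",
    "Dataset",
    "SchemaError",
    "ValidationError",
    "read_effect_sizes",
    "read_fragments",
    "dataset_from_frame",
    "write_report",
    "read_report",
]

#: Ordered spatial-extent categories (km^2), one order of magnitude per bin.
EXTENT_BINS = (
    "(0,10)",
    "[10,100)",
    "[1e2,1e3)",
    "[1e3,1e4)",
    "[1e4,1e5)",
    "[1e5,1e6)",
    "[1e6,inf)",
)

#: Best-effort column-name presets for the two public deposits. Deposited
#: files vary; override any entry with an explicit schema_map when needed.
SCHEMA_PRESETS: dict[str, dict[str, str]] = {
    "native-exotic-meta": {
        "study_id": "study_id",
        "case_id": "case_id",
        "r": "r",
        "n": "n",
        "log_grain": "log_grain",
        "extent_bin": "extent_bin",
    },
    "fragmentation-richness": {
        "study_id": "study_id",
        "fragment_id": "fragment_id",
        "richness": "richness",
        "frag_size": "frag_size",
        "taxon_group": "taxon_group",
    },
}


class SchemaError(ValueError):
    """A required column could not be resolved through the schema map."""


class ValidationError(ValueError):
    """A row violates the dataset invariants (named row in the message)."""


@dataclass(frozen=True)
class EffectSizeRecord:
    """One meta-analytic case: Fisher-z effect size with known sampling variance."""

    study_id: str
    case_id: str
    z: float
    var_z: float
    log_grain: float
    extent_bin: str | None = None
    r: float | None = None
    n: int | None = None


@dataclass(frozen=True)
class FragmentRecord:
    """One habitat fragment's standardized richness with study membership."""

    study_id: str
    fragment_id: str
    richness: float
    log_frag_size: float
    taxon_group: str | None = None
    extra_covariates: dict = field(default_factory=dict)


@dataclass
class Dataset:
    """An ordered collection of records of one kind with a stable row order.

    ``table`` holds the canonical columns; its positional order *is* the
    observation order used by every pointwise output. ``study_index`` maps
    each study label to 0..I-1 in order of first appearance.
    ``center_log_size`` stores the constant subtracted from log fragment
    sizes (fragment kind only) so back-transformation and out-of-fold
    centring reuse the full-dataset constant.
    """

    table: pd.DataFrame
    kind: str  # {"meta", "fragment"}
    center_log_size: float | None = None

    def __post_init__(self):
        if self.kind not in ("meta", "fragment"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        self.table = self.table.reset_index(drop=True)

    # -- structure ---------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return len(self.table)

    @property
    def study_ids(self) -> np.ndarray:
        return self.table["study_id"].to_numpy()

    @property
    def study_labels(self) -> list:
        seen: dict = {}
        for s in self.table["study_id"]:
            seen.setdefault(s, None)
        return list(seen)

    @property
    def study_index(self) -> dict:
        return {s: i for i, s in enumerate(self.study_labels)}

    @property
    def n_studies(self) -> int:
        return len(self.study_index)

    def study_codes(self) -> np.ndarray:
        """Integer study membership per observation (order of first appearance)."""
        idx = self.study_index
        return np.fromiter((idx[s] for s in self.table["study_id"]), dtype=int, count=self.n_obs)

    def subset(self, rows: Iterable[int]) -> "Dataset":
        rows = np.asarray(list(rows), dtype=int)
        return Dataset(self.table.iloc[rows].copy(), self.kind, self.center_log_size)

    def records(self) -> list:
        out = []
        if self.kind == "meta":
            for row in self.table.itertuples(index=False):
                out.append(
                    EffectSizeRecord(
                        study_id=row.study_id,
                        case_id=row.case_id,
                        z=row.z,
                        var_z=row.var_z,
                        log_grain=row.log_grain,
                        extent_bin=getattr(row, "extent_bin", None),
                        r=getattr(row, "r", None),
                        n=getattr(row, "n", None),
                    )
                )
        else:
            known = {"study_id", "fragment_id", "richness", "log_frag_size", "taxon_group"}
            extras = [c for c in self.table.columns if c not in known]
            for _, row in self.table.iterrows():
                out.append(
                    FragmentRecord(
                        study_id=row["study_id"],
                        fragment_id=row["fragment_id"],
                        richness=row["richness"],
                        log_frag_size=row["log_frag_size"],
                        taxon_group=row.get("taxon_group"),
                        extra_covariates={c: row[c] for c in extras},
                    )
                )
        return out


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------

def _resolve(frame: pd.DataFrame, schema_map: Mapping[str, str], name: str, required: bool = True):
    col = schema_map.get(name, name)
    if col not in frame.columns:
        if required:
            raise SchemaError(f"column {col!r} (for field {name!r}) not found in file")
        return None
    return frame[col]


def read_effect_sizes(path, schema_map: Mapping[str, str] | None = None) -> Dataset:
    """Read a meta-analytic effect-size table.

    Each row must supply either ``(r, n)`` — in which case ``z`` and
    ``var_z`` are computed via the Fisher transform — or ``(z, var_z)``
    directly. Row order in the file is the dataset's observation order.
    """
    schema_map = dict(schema_map or {})
    raw = pd.read_csv(path)
    study = _resolve(raw, schema_map, "study_id")
    case = _resolve(raw, schema_map, "case_id", required=False)
    r = _resolve(raw, schema_map, "r", required=False)
    n = _resolve(raw, schema_map, "n", required=False)
    z = _resolve(raw, schema_map, "z", required=False)
    var_z = _resolve(raw, schema_map, "var_z", required=False)
    grain = _resolve(raw, schema_map, "log_grain")
    extent = _resolve(raw, schema_map, "extent_bin", required=False)

    if z is None and r is None:
        raise SchemaError("need either an 'r' column or a 'z' column")
    if z is not None and var_z is None and n is None:
        raise SchemaError("'z' given without 'var_z' or 'n'")

    n_rows = len(raw)
    out = pd.DataFrame(
        {
            "study_id": study.astype(str),
            "case_id": (case.astype(str) if case is not None else pd.Series(np.arange(n_rows)).astype(str)),
            "log_grain": pd.to_numeric(grain),
        }
    )
    if r is not None:
        r_vals = pd.to_numeric(r).to_numpy(dtype=float)
    if n is not None:
        n_vals = pd.to_numeric(n).to_numpy()

    z_out = np.empty(n_rows)
    v_out = np.empty(n_rows)
    for i in range(n_rows):
        have_z = z is not None and np.isfinite(pd.to_numeric(z.iloc[i], errors="coerce"))
        if have_z:
            z_out[i] = float(z.iloc[i])
            if var_z is not None and np.isfinite(pd.to_numeric(var_z.iloc[i], errors="coerce")):
                v_out[i] = float(var_z.iloc[i])
            else:
                _check_n(n_vals[i], i)
                v_out[i] = fisher_z_variance(int(n_vals[i]))
        else:
            if r is None or not np.isfinite(r_vals[i]):
                raise ValidationError(f"row {i}: neither z nor r available")
            if abs(r_vals[i]) >= 1:
                raise ValidationError(f"row {i}: |r| >= 1 (Fisher z undefined); refusing to clamp")
            _check_n(n_vals[i], i)
            z_out[i] = fisher_z(r_vals[i])
            v_out[i] = fisher_z_variance(int(n_vals[i]))
        if not np.isfinite(z_out[i]):
            raise ValidationError(f"row {i}: non-finite effect size")
        if v_out[i] <= 0:
            raise ValidationError(f"row {i}: var_z must be > 0")

    out["z"] = z_out
    out["var_z"] = v_out
    if r is not None:
        out["r"] = r_vals
    if n is not None:
        out["n"] = n_vals
    if extent is not None:
        labels = extent.astype(str)
        bad = ~labels.isin(EXTENT_BINS) & labels.notna() & (labels != "nan")
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValidationError(
                f"row {i}: extent_bin {labels.iloc[i]!r} not in the fixed label set {EXTENT_BINS}"
            )
        out["extent_bin"] = labels
    return Dataset(out, "meta")


def _check_n(n_val, row: int):
    if not np.isfinite(float(n_val)):
        raise ValidationError(f"row {row}: sample size missing")
    if float(n_val) <= 3:
        raise ValidationError(f"row {row}: n <= 3, sampling variance 1/(n-3) undefined")


def read_fragments(path, schema_map: Mapping[str, str] | None = None) -> Dataset:
    """Read a fragment-richness table; log sizes are mean-centred over all rows."""
    schema_map = dict(schema_map or {})
    raw = pd.read_csv(path)
    study = _resolve(raw, schema_map, "study_id")
    frag = _resolve(raw, schema_map, "fragment_id", required=False)
    rich = pd.to_numeric(_resolve(raw, schema_map, "richness"))
    size = pd.to_numeric(_resolve(raw, schema_map, "frag_size"))
    taxon = _resolve(raw, schema_map, "taxon_group", required=False)

    rich_v = rich.to_numpy(dtype=float)
    size_v = size.to_numpy(dtype=float)
    for i in range(len(raw)):
        if not rich_v[i] > 0:
            raise ValidationError(f"row {i}: richness must be > 0 (lognormal support)")
        if not size_v[i] > 0:
            raise ValidationError(f"row {i}: fragment size must be > 0")
    log_size = np.log(size_v)
    center = float(np.mean(log_size)) if len(raw) else 0.0
    out = pd.DataFrame(
        {
            "study_id": study.astype(str),
            "fragment_id": (frag.astype(str) if frag is not None else pd.Series(np.arange(len(raw))).astype(str)),
            "richness": rich_v,
            "frag_size": size_v,
            "log_frag_size": log_size - center,
        }
    )
    if taxon is not None:
        out["taxon_group"] = taxon.astype(str)
    return Dataset(out, "fragment", center_log_size=center)


def dataset_from_frame(frame: pd.DataFrame, kind: str, center_log_size: float | None = None) -> Dataset:
    """Wrap an already-canonical DataFrame (used by the simulators)."""
    return Dataset(frame.copy(), kind, center_log_size)


# --------------------------------------------------------------------------
# Report round-tripping
# --------------------------------------------------------------------------

def _canonical_csv(frame: pd.DataFrame) -> str:
    return frame.to_csv(index=False, float_format="%.17g", lineterminator="\n")


def write_report(report, path) -> None:
    """Write a report as CSV (+ JSON sidecar with metadata and checksum).

    ``report`` is either an object with ``to_frame()``/``meta()`` methods
    (e.g. :class:`locscale.cv.CVReport`) or a plain DataFrame. Floats
    round-trip to 1e-12; a checksum over the canonical CSV serialization is
    stored so that any later perturbation of the table is detected.
    """
    path = Path(path)
    if hasattr(report, "to_frame"):
        frame = report.to_frame()
        meta = report.meta() if hasattr(report, "meta") else {}
    else:
        frame = pd.DataFrame(report)
        meta = {}
    text = _canonical_csv(frame)
    path.write_text(text, encoding="utf-8")
    sidecar = {
        "checksum_sha256": hashlib.sha256(text.encode("utf-8")).hexdigest(),
        "n_rows": int(len(frame)),
        "columns": list(map(str, frame.columns)),
        "meta": _jsonable(meta),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True), encoding="utf-8"
    )


def read_report(path, verify: bool = True) -> pd.DataFrame:
    """Re-read a report written by :func:`write_report`, verifying its checksum."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if verify and sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
        digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
        if digest != sidecar.get("checksum_sha256"):
            raise ValidationError(f"checksum mismatch for {path}: file was modified after writing")
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
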