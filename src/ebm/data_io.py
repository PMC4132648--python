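"""Reading, validation, preprocessing and subsetting of biomarker tables.

The central container is :class:`BiomarkerDataset`: a subjects x biomarkers
matrix of continuous measurements with per-subject diagnostic labels
(CN / MCI / AD), optional covariates and optional visit labels.  Every other
module in the package consumes this object.

Column roles are declared in a schema (a dict, or a YAML/JSON file)::

    id: RID
    diagnosis: DX
    visit: VISCODE            # optional
    covariates: [age, apoe4, amyloid_beta]   # optional
    biomarkers:
      ABETA: decrease         # abnormality direction per biomarker
      TAU: increase

Reserved covariate names used by subgroup selection: ``amyloid_beta`` is the
raw CSF amyloid-beta 1-42 value in pg/ml, ``apoe4`` is a 0/1 (or boolean)
APOE4 carrier flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import DataValidationError, SchemaError

logger = logging.getLogger(__name__)

DIAGNOSIS_LABELS = ("CN", "MCI", "AD")

#: Reserved visit label for the first time point.
BASELINE_VISIT = "baseline"

#: Raw CSF amyloid-beta 1-42 threshold (pg/ml) defining the amyloid-positive
#: subgroup; subjects strictly below it are amyloid+.
AMYLOID_POSITIVE_CUTOFF = 192.0


@dataclass
class BiomarkerDataset:
    """Cross-sectional (or per-visit) table of continuous biomarker values.

    Parameters
    ----------
    subject_ids
        Opaque per-row subject identifiers (strings).
    biomarker_names
        Names of the N biomarkers; unique.
    values
        J x N float matrix, no missing entries (missing data is unsupported).
    diagnosis
        Per-row label, one of ``CN``, ``MCI``, ``AD``.
    direction
        Map biomarker name -> ``"increase"`` or ``"decrease"``: whether
        abnormality raises or lowers the measured value (e.g. CSF tau
        increases, hippocampal volume decreases).
    covariates
        Optional per-row covariate table (age, sex, education, ``apoe4``
        carrier flag, raw ``amyloid_beta`` in pg/ml, total intracranial
        volume, ...); row-aligned with ``values``.
    visit
        Optional per-row visit label; ``"baseline"`` is the reserved default.
    """

    subject_ids: list
    biomarker_names: list
    values: np.ndarray
    diagnosis: np.ndarray
    direction: dict
    covariates: pd.DataFrame | None = None
    visit: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.diagnosis = np.asarray(self.diagnosis, dtype=object)
        j, n = self.values.shape
        if j < 1 or n < 1:
            raise DataValidationError("dataset must have at least one subject and one biomarker")
        if len(self.subject_ids) != j or len(self.diagnosis) != j:
            raise DataValidationError("subject_ids/diagnosis length must match the value matrix")
        if len(self.biomarker_names) != n:
            raise DataValidationError("biomarker_names length must match the value matrix")
        if len(set(self.biomarker_names)) != n:
            raise DataValidationError("biomarker names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("value matrix contains missing or non-finite entries")
        bad = sorted(set(self.diagnosis) - set(DIAGNOSIS_LABELS))
        if bad:
            raise SchemaError(f"unknown diagnosis label(s): {bad}; expected one of {DIAGNOSIS_LABELS}")
        for name in self.biomarker_names:
            if self.direction.get(name) not in ("increase", "decrease"):
                raise SchemaError(f"biomarker {name!r} needs a direction ('increase'/'decrease')")
        if self.visit is not None:
            self.visit = np.asarray(self.visit, dtype=object)
            if len(self.visit) != j:
                raise DataValidationError("visit length must match the value matrix")
            pairs = list(zip(self.subject_ids, self.visit))
            if len(set(pairs)) != len(pairs):
                raise DataValidationError("duplicate (subject, visit) pair")
        elif len(set(self.subject_ids)) != j:
            raise DataValidationError("duplicate subject id without visit labels")
        if self.covariates is not None and len(self.covariates) != j:
            raise DataValidationError("covariates must be row-aligned with the value matrix")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_biomarkers(self) -> int:
        return self.values.shape[1]

    def subset(self, mask) -> "BiomarkerDataset":
        """Return the row subset selected by a boolean mask or index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return BiomarkerDataset(
            subject_ids=[self.subject_ids[i] for i in idx],
            biomarker_names=list(self.biomarker_names),
            values=self.values[idx],
            diagnosis=self.diagnosis[idx],
            direction=dict(self.direction),
            covariates=None if self.covariates is None else self.covariates.iloc[idx].reset_index(drop=True),
            visit=None if self.visit is None else self.visit[idx],
        )

    def diagnosis_mask(self, label: str) -> np.ndarray:
        return self.diagnosis == label

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a single table (id, dx, [visit], covariates, biomarkers)."""
        out = pd.DataFrame({"id": self.subject_ids, "dx": self.diagnosis})
        if self.visit is not None:
            out["visit"] = self.visit
        if self.covariates is not None:
            for c in self.covariates.columns:
                out[c] = self.covariates[c].to_numpy()
        for i, name in enumerate(self.biomarker_names):
            out[name] = self.values[:, i]
        return out

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def schema_dict(self) -> dict:
        """Schema describing :meth:`to_frame`'s column layout (round-trip aid)."""
        sc = {"id": "id", "diagnosis": "dx", "biomarkers": dict(self.direction)}
        if self.visit is not None:
            sc["visit"] = "visit"
        if self.covariates is not None:
            sc["covariates"] = list(self.covariates.columns)
        return sc


def load_schema(path) -> dict:
    """Load a column-role schema from a YAML or JSON file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def read_biomarker_table(path, schema, mode: str = "strict") -> BiomarkerDataset:
    """Read a CSV biomarker table into a validated :class:`BiomarkerDataset`.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Column-role map (dict, or path to YAML/JSON): keys ``id``,
        ``diagnosis``, optional ``visit``, optional ``covariates`` (list of
        column names) and ``biomarkers`` (map column name -> direction).
    mode
        ``"strict"`` (default) rejects any row with a missing or non-numeric
        biomarker cell; ``"lenient"`` drops such rows with a logged count.
    """
    if isinstance(schema, (str, Path)):
        schema = load_schema(schema)
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    df = pd.read_csv(path)
    for key in ("id", "diagnosis"):
        if key not in schema:
            raise SchemaError(f"schema missing required role {key!r}")
    biomarkers = schema.get("biomarkers")
    if not biomarkers:
        raise SchemaError("schema declares no biomarkers")
    needed = [schema["id"], schema["diagnosis"], *biomarkers]
    if "visit" in schema:
        needed.append(schema["visit"])
    needed += list(schema.get("covariates", []))
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"CSV is missing columns required by the schema: {missing_cols}")

    bio_cols = list(biomarkers)
    numeric = df[bio_cols].apply(pd.to_numeric, errors="coerce")
    bad_rows = numeric.isna().any(axis=1)
    if bad_rows.any():
        if mode == "strict":
            first = int(np.flatnonzero(bad_rows.to_numpy())[0])
            raise SchemaError(
                f"row {first} has a missing or non-numeric biomarker value (strict mode)"
            )
        logger.warning("dropping %d row(s) with missing biomarker values", int(bad_rows.sum()))
        df = df.loc[~bad_rows].reset_index(drop=True)
        numeric = numeric.loc[~bad_rows].reset_index(drop=True)

    dx = df[schema["diagnosis"]].astype(str).to_numpy()
    bad_dx = ~np.isin(dx, DIAGNOSIS_LABELS)
    if bad_dx.any():
        first = int(np.flatnonzero(bad_dx)[0])
        raise SchemaError(
            f"row {first}: unknown diagnosis label {dx[first]!r} (expected one of {DIAGNOSIS_LABELS})"
        )

    ids = df[schema["id"]].astype(str).tolist()
    visit = df[schema["visit"]].astype(str).to_numpy() if "visit" in schema else None
    key = list(zip(ids, visit)) if visit is not None else ids
    if len(set(key)) != len(key):
        raise DataValidationError("duplicate (subject, visit) row in input table")

    cov_cols = list(schema.get("covariates", []))
    covariates = df[cov_cols].reset_index(drop=True) if cov_cols else None
    return BiomarkerDataset(
        subject_ids=ids,
        biomarker_names=bio_cols,
        values=numeric.to_numpy(dtype=float),
        diagnosis=dx,
        direction=dict(biomarkers),
        covariates=covariates,
        visit=visit,
    )


def preprocess(ds: BiomarkerDataset, log_transform=(), tiv_normalize=None) -> BiomarkerDataset:
    """Apply the standard per-biomarker transforms.

    ``log_transform`` names biomarkers replaced by their natural logarithm
    (CSF tau measures, to improve normality).  ``tiv_normalize`` maps a volume
    biomarker name to the covariate column holding total intracranial volume;
    the volume is replaced by ``100 * volume / TIV`` (percent of TIV).
    Untouched columns are returned bit-identical.
    """
    log_transform = set(log_transform)
    tiv_normalize = dict(tiv_normalize or {})
    for name in log_transform | set(tiv_normalize):
        if name not in ds.biomarker_names:
            raise SchemaError(f"unknown biomarker {name!r} scheduled for preprocessing")
    values = ds.values.copy()
    for name in log_transform:
        i = ds.biomarker_names.index(name)
        if np.any(values[:, i] <= 0):
            raise DataValidationError(f"non-positive value in {name!r}: cannot log transform")
        values[:, i] = np.log(values[:, i])
    for name, tiv_col in tiv_normalize.items():
        if ds.covariates is None or tiv_col not in ds.covariates.columns:
            raise SchemaError(f"TIV column {tiv_col!r} not found in covariates")
        tiv = ds.covariates[tiv_col].to_numpy(dtype=float)
        if np.any(~np.isfinite(tiv)) or np.any(tiv <= 0):
            raise DataValidationError(f"TIV column {tiv_col!r} must be strictly positive")
        i = ds.biomarker_names.index(name)
        values[:, i] = 100.0 * values[:, i] / tiv
    if not log_transform and not tiv_normalize:
        return replace(ds)
    return replace(ds, values=values)


SUBGROUP_RULES = ("whole", "amyloid+", "apoe+", "amyloid+apoe+")


def select_subgroup(ds: BiomarkerDataset, rule: str) -> BiomarkerDataset:
    """Select the population subgroup defined by ``rule``.

    ``amyloid+`` keeps subjects with raw CSF amyloid-beta 1-42 strictly below
    192 pg/ml (``amyloid_beta`` covariate); ``apoe+`` keeps APOE4 carriers
    (``apoe4`` covariate truthy); ``amyloid+apoe+`` is their intersection;
    ``whole`` returns the input unchanged.
    """
    rule = rule.lower()
    if rule not in SUBGROUP_RULES:
        raise ValueError(f"unknown subgroup rule {rule!r}; expected one of {SUBGROUP_RULES}")
    if rule == "whole":
        return ds
    mask = np.ones(ds.n_subjects, dtype=bool)
    if "amyloid+" in rule:
        if ds.covariates is None or "amyloid_beta" not in ds.covariates.columns:
            raise SchemaError("amyloid+ subgrouping needs the raw 'amyloid_beta' covariate (pg/ml)")
        ab = ds.covariates["amyloid_beta"].to_numpy(dtype=float)
        mask &= ab < AMYLOID_POSITIVE_CUTOFF
    if "apoe+" in rule:
        if ds.covariates is None or "apoe4" not in ds.covariates.columns:
            raise SchemaError("apoe+ subgrouping needs the 'apoe4' carrier covariate")
        mask &= ds.covariates["apoe4"].astype(bool).to_numpy()
    return ds.subset(mask)
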