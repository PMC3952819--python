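"""Core data containers for the county-level bivariate Poisson model.

The analysis operates on four tabular objects — a state/county hierarchy
with gender-stratified populations, a per-county covariate table, an
incidence panel of disease counts, and (for the comorbidity analysis) a
patient-level flag table — plus the model-side containers: a model
specification, a parameter set (fixed-effect weights and two 2x2
random-effect covariance matrices), realised random effects, and the
assembled regression design.

All tabular containers are thin, validated wrappers around pandas
DataFrames so they round-trip losslessly through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "POLICY_COLUMNS",
    "COVARIATE_COLUMNS",
    "DEFAULT_COVARIATES",
    "GeoHierarchy",
    "CovariateTable",
    "IncidencePanel",
    "PatientTable",
    "ModelSpec",
    "ParameterSet",
    "RandomEffects",
    "DesignBundle",
]

#: Hand-coded state special-education policy variables and their code sets.
#: CFR/DSM/ASDcrit are two-level (+/-1); Eval has four ordered rigor levels.
POLICY_COLUMNS: dict[str, frozenset] = {
    "CFR": frozenset({-1, 1}),
    "DSM": frozenset({-1, 1}),
    "ASDcrit": frozenset({-1, 1}),
    "Eval": frozenset({-2, -1, 1, 2}),
}

#: County-level covariates: ethnic proportions, socioeconomics, and
#: population-normalised environmental indicator rates (all in percent
#: except Income, which is in thousands of dollars).
COVARIATE_COLUMNS: tuple[str, ...] = (
    "Income",
    "Poor",
    "Urban",
    "Insured",
    "AmInd",
    "Asian",
    "WHisp",
    "W",
    "BHisp",
    "B",
    "Pacific",
    "ConGenM",
    "ConGenF",
    "CongMrepM",
    "CongMrepF",
    "Viral_M",
    "Viral_F",
    "ect_pr",
    "abnormal_concept",
    "spont_abort",
    "mult_gest",
)

ETHNIC_COLUMNS: tuple[str, ...] = (
    "AmInd", "Asian", "WHisp", "W", "BHisp", "B", "Pacific",
)

#: Default per-disease fixed-effect covariate list (21 columns; an intercept
#: is added per disease, giving 22 weights per disease, 44 in total).
#: Eval enters as three indicator contrasts against a reference level.
DEFAULT_COVARIATES: tuple[str, ...] = (
    "Gender",
    "Income",
    "Poor",
    "Urban",
    "Insured",
    "AmInd",
    "Asian",
    "WHisp",
    "W",
    "BHisp",
    "B",
    "Pacific",
    "ConGenM",
    "CongMrepM",
    "Viral_M",
    "CFR",
    "DSM",
    "ASDcrit",
    "Eval1",
    "Eval2",
    "Eval-1",
)

_EVAL_INDICATORS = {"Eval1": 1, "Eval2": 2, "Eval-1": -1, "Eval-2": -2}


class SchemaError(ValueError):
    """A table does not match its documented column schema."""


class ValidationError(ValueError):
    """A table or parameter object violates a structural invariant."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


@dataclass
class GeoHierarchy:
    """States containing counties, with gender-stratified populations.

    ``states``: one row per state — ``state_id`` plus the four policy code
    columns (constant within a state).  ``counties``: one row per county —
    ``county_id``, parent ``state_id``, ``pop_male``, ``pop_female``.
    Identifiers are opaque strings and never parsed for meaning.
    """

    states: pd.DataFrame
    counties: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require_columns(self.states, ["state_id", *POLICY_COLUMNS], "states")
        _require_columns(
            self.counties, ["county_id", "state_id", "pop_male", "pop_female"],
            "counties",
        )
        if self.states["state_id"].duplicated().any():
            raise ValidationError("duplicate state_id")
        if self.counties["county_id"].duplicated().any():
            raise ValidationError("duplicate county_id")
        known = set(self.states["state_id"])
        orphans = set(self.counties["state_id"]) - known
        if orphans:
            raise ValidationError(f"counties reference unknown states: {sorted(orphans)}")
        for col in ("pop_male", "pop_female"):
            if (self.counties[col] < 0).any():
                raise ValidationError(f"negative population in {col}")
        for col, allowed in POLICY_COLUMNS.items():
            bad = ~self.states[col].isin(allowed)
            if bad.any():
                raise ValidationError(
                    f"policy column {col} has values outside {sorted(allowed)}"
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_counties(self) -> int:
        return len(self.counties)


@dataclass
class CovariateTable:
    """Per-county fixed-effect covariates (percent scales; Income in $1000)."""

    data: pd.DataFrame  # indexed or keyed by county_id

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require_columns(self.data, ["county_id", *COVARIATE_COLUMNS], "covariates")
        if self.data["county_id"].duplicated().any():
            raise ValidationError("duplicate county_id in covariates")
        if self.data[list(COVARIATE_COLUMNS)].isna().any().any():
            raise ValidationError("missing covariate values")
        pct = [c for c in COVARIATE_COLUMNS if c != "Income"]
        vals = self.data[pct].to_numpy(float)
        if (vals < 0).any() or (vals > 100).any():
            raise ValidationError("percent covariate outside [0, 100]")
        eth = self.data[list(ETHNIC_COLUMNS)].to_numpy(float).sum(axis=1)
        if (eth > 100 + 1e-9).any():
            raise ValidationError("ethnic proportions sum above 100")


@dataclass
class IncidencePanel:
    """Observed counts per (county, disease, gender) with population offsets."""

    data: pd.DataFrame  # columns county_id, disease, gender, y, N

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require_columns(self.data, ["county_id", "disease", "gender", "y", "N"], "panel")
        dup = self.data.duplicated(subset=["county_id", "disease", "gender"])
        if dup.any():
            raise ValidationError("duplicate (county, disease, gender) key")
        y = self.data["y"].to_numpy()
        n = self.data["N"].to_numpy()
        if (y < 0).any():
            rows = np.flatnonzero(y < 0)
            raise ValidationError(f"negative count at row(s) {rows[:5].tolist()}")
        if (y > n).any():
            rows = np.flatnonzero(y > n)
            raise ValidationError(f"count exceeds population at row(s) {rows[:5].tolist()}")


@dataclass
class PatientTable:
    """Patient-level disease/malformation flags for the comorbidity analysis."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _require_columns(
            self.data,
            ["patient_id", "county_id", "gender", "flag_ASD", "flag_ID", "flag_ConGen"],
            "patients",
        )
        if self.data["patient_id"].duplicated().any():
            raise ValidationError("duplicate patient_id")


@dataclass
class ModelSpec:
    """Which covariates enter each disease's fixed-effect block, and how.

    ``covariates`` maps disease label to its covariate name list (an
    intercept is always prepended).  ``Gender`` is the level-1 indicator
    (0 = ``gender_reference``, 1 = other); ``Eval1``/``Eval2``/``Eval-1``
    are indicator contrasts of the four-level Eval policy code against
    ``eval_reference``.  With ``center=True`` every non-intercept column is
    mean-centered (unweighted over design rows within its disease block).
    """

    diseases: tuple[str, ...] = ("ASD", "ID")
    covariates: Mapping[str, tuple[str, ...]] | None = None
    center: bool = True
    gender_reference: str = "M"
    eval_reference: int = -2
    offset_column: str = "N"

    def __post_init__(self) -> None:
        if self.covariates is None:
            self.covariates = {d: tuple(DEFAULT_COVARIATES) for d in self.diseases}
        self.covariates = {d: tuple(v) for d, v in self.covariates.items()}
        if set(self.covariates) != set(self.diseases):
            raise ValidationError("covariates must be given for exactly the model diseases")
        for d, names in self.covariates.items():
            if not names:
                raise ValidationError(f"empty covariate list for {d}")
        if self.eval_reference not in POLICY_COLUMNS["Eval"]:
            raise ValidationError("eval_reference must be one of the Eval levels")

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    def column_labels(self) -> list[str]:
        labels = []
        for d in self.diseases:
            labels.append(f"{d}:Intercept")
            labels.extend(f"{d}:{name}" for name in self.covariates[d])
        return labels

    @property
    def n_fixed_effects(self) -> int:
        return sum(1 + len(self.covariates[d]) for d in self.diseases)

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "diseases": list(self.diseases),
            "covariates": {d: list(v) for d, v in self.covariates.items()},
            "center": self.center,
            "gender_reference": self.gender_reference,
            "eval_reference": self.eval_reference,
            "offset_column": self.offset_column,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            diseases=tuple(d.get("diseases", ("ASD", "ID"))),
            covariates={k: tuple(v) for k, v in d["covariates"].items()}
            if "covariates" in d and d["covariates"] is not None
            else None,
            center=bool(d.get("center", True)),
            gender_reference=d.get("gender_reference", "M"),
            eval_reference=int(d.get("eval_reference", -2)),
            offset_column=d.get("offset_column", "N"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _check_psd(sigma: np.ndarray, name: str, strict: bool = False) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValidationError(f"{name} must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-10):
        raise ValidationError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(sigma)
    lo = eig.min()
    if strict and lo <= 0:
        raise ValidationError(f"{name} must be positive definite (min eig {lo:.3g})")
    if not strict and lo < -1e-10:
        raise ValidationError(f"{name} must be positive semi-definite (min eig {lo:.3g})")
    return sigma


@dataclass
class ParameterSet:
    """Fixed-effect weights plus the two random-effect covariance matrices.

    ``b`` is a Series indexed by design column labels (``"ASD:Income"`` ...);
    ``sigma_state`` / ``sigma_county`` are d x d covariance matrices of the
    zero-mean random effects across the d diseases, at the state and county
    level respectively.
    """

    b: pd.Series
    sigma_state: np.ndarray
    sigma_county: np.ndarray

    def __post_init__(self) -> None:
        self.b = pd.Series(self.b, dtype=float)
        self.sigma_state = _check_psd(np.asarray(self.sigma_state, float), "sigma_state")
        self.sigma_county = _check_psd(np.asarray(self.sigma_county, float), "sigma_county")
        if self.sigma_state.shape != self.sigma_county.shape:
            raise ValidationError("state/county covariance dimensions differ")
        for lvl, sig in (("state", self.sigma_state), ("county", self.sigma_county)):
            d = sig.shape[0]
            for i in range(d):
                for j in range(i):
                    denom = np.sqrt(sig[i, i] * sig[j, j])
                    if denom > 0 and abs(sig[i, j] / denom) > 1 + 1e-9:
                        raise ValidationError(f"implied {lvl} correlation outside [-1, 1]")

    @property
    def n_diseases(self) -> int:
        return self.sigma_state.shape[0]


@dataclass
class RandomEffects:
    """Realised (or estimated) random effects per state and county.

    Both frames have one column per disease; ``v_state`` is indexed by
    state_id, ``v_county`` by county_id.
    """

    v_state: pd.DataFrame
    v_county: pd.DataFrame

    def __post_init__(self) -> None:
        for frame, what in ((self.v_state, "v_state"), (self.v_county, "v_county")):
            if not np.isfinite(frame.to_numpy(float)).all():
                raise ValidationError(f"non-finite values in {what}")


@dataclass
class DesignBundle:
    """The assembled regression design in canonical row order.

    Rows are county-major (counties sorted by state then county id); within
    a county the (disease, gender) cells appear in disease-major order with
    genders reference-first.  ``X`` is the block-diagonal centered
    fixed-effect matrix; ``row_state`` / ``row_county`` / ``row_disease``
    are the random-effect incidence maps (the z matrix in sparse index
    form).  Zero-offset rows have been dropped before construction.
    """

    y: np.ndarray
    N: np.ndarray
    X: np.ndarray
    col_labels: list[str]
    col_disease: np.ndarray  # disease index of each design column
    row_state: np.ndarray
    row_county: np.ndarray
    row_disease: np.ndarray
    row_gender: np.ndarray  # 0 = reference gender, 1 = other
    state_ids: np.ndarray  # state_id per state index
    county_ids: np.ndarray  # county_id per county index
    county_state: np.ndarray  # state index per county index
    spec: ModelSpec
    col_means: np.ndarray = field(default=None)  # pre-centering column means

    @property
    def n_rows(self) -> int:
        return self.y.shape[0]

    @property
    def n_counties(self) -> int:
        return len(self.county_ids)

    @property
    def n_states(self) -> int:
        return len(self.state_ids)

    @property
    def n_diseases(self) -> int:
        return self.spec.n_diseases

    def b_vector(self, params: ParameterSet) -> np.ndarray:
        """Align a ParameterSet's weights with this design's columns."""
        try:
            return params.b.loc[self.col_labels].to_numpy(float)
        except KeyError as exc:
            raise SchemaError(f"parameter vector missing design columns: {exc}") from exc

    def raneff_arrays(self, raneff: RandomEffects) -> tuple[np.ndarray, np.ndarray]:
        """Align RandomEffects frames to (n_states, d), (n_counties, d) arrays."""
        cols = list(self.spec.diseases)
        vs = raneff.v_state.loc[list(self.state_ids), cols].to_numpy(float)
        vc = raneff.v_county.loc[list(self.county_ids), cols].to_numpy(float)
        return vs, vc

    def to_frame(self) -> pd.DataFrame:
        """Export the design as a flat DataFrame (for external cross-checks)."""
        df = pd.DataFrame(self.X, columns=self.col_labels)
        df.insert(0, "gender_code", self.row_gender)
        df.insert(0, "disease", [self.spec.diseases[k] for k in self.row_disease])
        df.insert(0, "county_id", self.county_ids[self.row_county])
        df.insert(0, "state_id", self.state_ids[self.row_state])
        df["y"] = self.y
        df["N"] = self.N
        return df

    def subset_params(self, params: ParameterSet) -> None:
        """Validate a ParameterSet against this design (dimension contract)."""
        if params.n_diseases != self.n_diseases:
            raise ValidationError("parameter covariance dimension != number of diseases")
        self.b_vector(params)
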