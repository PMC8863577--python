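"""Core data containers shared across the pipeline.

The analysis operates on two aligned tables: a subjects-by-features
abundance matrix (taxa, functional modules, serum/urine metabolites) and a
subject metadata table carrying the disease-stage group label, treatment
and host covariates, and optionally the fecal microbial load (cells per
gram measured by flow cytometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Closed vocabulary of disease-stage group labels:
#: HC   healthy control
#: UMMC untreated metabolically matched control (dysmetabolic, drug-naive)
#: MMC  treated metabolically matched control (dysmetabolic, on medication)
#: IHD  ischemic heart disease (diagnosed, treated)
GROUPS = ("HC", "UMMC", "MMC", "IHD")

#: IHD clinical subtypes: acute coronary syndrome, chronic IHD, and heart
#: failure secondary to chronic IHD.
SUBTYPES = ("ACS", "CIHD", "HF")

FEATURE_KINDS = ("taxon", "module", "metabolite_serum", "metabolite_urine")

#: The five pairwise group comparisons spanning the two disease stages:
#: stage 1 (dysmetabolism) = HC vs MMC/UMMC; stage 2 (overt disease) =
#: MMC/UMMC vs IHD.  HC:IHD spans both.
COMPARISONS = ("HC:MMC", "HC:UMMC", "HC:IHD", "MMC:IHD", "UMMC:IHD")

STAGE1_COMPARISONS = ("HC:MMC", "HC:UMMC")
STAGE2_COMPARISONS = ("MMC:IHD", "UMMC:IHD")

COVARIATE_TYPES = ("binary", "continuous", "ordinal", "dosage")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class CohortMatrix:
    """Subjects x features abundance table with per-feature kind tags.

    Parameters
    ----------
    values
        DataFrame indexed by subject ID with one column per feature ID.
        All values non-negative; NaN marks a missing measurement.
    kinds
        Series mapping feature ID -> kind tag (one of ``FEATURE_KINDS``).
    """

    values: pd.DataFrame
    kinds: pd.Series

    def __post_init__(self) -> None:
        self.kinds = pd.Series(self.kinds).reindex(self.values.columns)
        self.validate()

    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate subject IDs: {dups[:5]}")
        cols = self.values.columns
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dups[:5]}")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            bad = self.values.columns[(self.values < 0).any(axis=0)]
            raise ValidationError(f"negative abundances in features: {list(bad[:5])}")
        missing_kind = self.kinds.isna()
        if missing_kind.any():
            bad = list(self.kinds.index[missing_kind][:5])
            raise ValidationError(f"features without kind tag: {bad}")
        unknown = set(self.kinds.unique()) - set(FEATURE_KINDS)
        if unknown:
            raise ValidationError(f"unknown feature kinds: {sorted(unknown)}")

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def features(self) -> pd.Index:
        return self.values.columns

    def features_of_kind(self, kind: str) -> pd.Index:
        return self.kinds.index[self.kinds == kind]


@dataclass
class SubjectMetadata:
    """Per-subject group labels, covariates, and optional microbial load.

    ``table`` is indexed by subject ID and must contain a ``group`` column
    drawn from the closed group vocabulary; IHD subjects may carry a
    ``subtype``.  Covariate columns are typed via ``covariate_types``
    (binary / continuous / ordinal / dosage) which governs the test used
    when associating them with features (Mann-Whitney for binary,
    Spearman otherwise).
    """

    table: pd.DataFrame
    covariate_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate subject IDs in metadata")
        if "group" not in self.table.columns:
            raise ValidationError("metadata must contain a 'group' column")
        bad = set(self.table["group"].dropna().unique()) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        if "subtype" in self.table.columns:
            sub = self.table["subtype"].dropna()
            sub = sub[sub != ""]
            unknown = set(sub.unique()) - set(SUBTYPES)
            if unknown:
                raise ValidationError(f"unknown IHD subtypes: {sorted(unknown)}")
        for cov, typ in self.covariate_types.items():
            if typ not in COVARIATE_TYPES:
                raise ValidationError(f"covariate {cov!r}: unknown type {typ!r}")
            if cov not in self.table.columns:
                raise ValidationError(f"declared covariate {cov!r} missing from table")

    @property
    def subjects(self) -> pd.Index:
        return self.table.index

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def covariates(self) -> list[str]:
        return list(self.covariate_types)

    @property
    def microbial_load(self) -> pd.Series | None:
        if "microbial_load" in self.table.columns:
            return self.table["microbial_load"]
        return None

    def subjects_in(self, label: str) -> pd.Index:
        """Subject IDs in a group or an IHD subtype."""
        if label in GROUPS:
            return self.table.index[self.table["group"] == label]
        if label in SUBTYPES:
            if "subtype" not in self.table.columns:
                raise ValidationError("metadata has no 'subtype' column")
            return self.table.index[self.table["subtype"] == label]
        raise ValidationError(f"unknown group or subtype label {label!r}")


def align(matrix: CohortMatrix, metadata: SubjectMetadata) -> None:
    """Check that matrix and metadata cover the same subjects."""
    missing = matrix.subjects.difference(metadata.subjects)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} subjects in matrix missing from metadata: "
            f"{list(missing[:5])}"
        )
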