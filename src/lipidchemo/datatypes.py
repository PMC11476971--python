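"""Core tabular containers for untargeted lipidomics peak data.

A study is represented as a :class:`FeatureTable`: an (samples x features)
intensity matrix together with per-sample metadata (individual, replicate,
class, gender, acquisition batch) and per-feature descriptors (m/z,
retention time, ion mode).  Technical replicates (repeated LC-HRMS
injections of the same serum extract) are first-class: every sample row
carries an ``individual_id`` and a ``replicate_index``, and downstream
resampling / cross-validation code treats the replicate group as the unit
that must never be split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CLASS_LABELS = ("SCH", "C")
GENDERS = ("M", "F")

SAMPLE_COLUMNS = ["individual_id", "replicate_index", "class_label", "gender", "batch"]
FEATURE_COLUMNS = ["mz", "rt", "ion_mode"]


@dataclass(frozen=True)
class SampleMetadata:
    """Metadata for one chromatogram (one injection of one individual)."""

    sample_id: str
    individual_id: str
    replicate_index: int
    class_label: str
    gender: str
    batch: int

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}")
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.replicate_index < 1:
            raise ValueError("replicate_index is 1-based and must be >= 1")


@dataclass(frozen=True)
class FeatureDescriptor:
    """Descriptor of one m/z (rt) variable."""

    feature_id: str
    mz: float
    rt: float
    ion_mode: str

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"mz must be > 0, got {self.mz}")
        if self.rt < 0:
            raise ValueError(f"rt must be >= 0, got {self.rt}")
        if self.ion_mode not in ("positive", "negative"):
            raise ValueError(f"ion_mode must be 'positive' or 'negative', got {self.ion_mode!r}")


@dataclass
class FeatureTable:
    """Samples x features intensity matrix plus sample/feature annotations.

    ``intensities`` is a DataFrame indexed by sample_id with feature_id
    columns; NaN encodes a missing peak.  ``samples`` is indexed by
    sample_id, ``features`` by feature_id.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.features is None:
            self.features = pd.DataFrame(
                {"mz": np.nan, "rt": np.nan, "ion_mode": "positive"},
                index=self.intensities.columns,
            )
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if not self.intensities.index.equals(self.samples.index):
            raise ValueError("intensities rows and sample metadata index differ")
        if not self.intensities.columns.equals(self.features.index):
            raise ValueError("intensities columns and feature descriptor index differ")
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise ValueError(f"sample metadata lacks columns {missing_cols}")
        dup = self.samples.duplicated(subset=["individual_id", "replicate_index"])
        if dup.any():
            raise ValueError(
                "duplicate (individual_id, replicate_index) pairs: "
                f"{self.samples.index[dup].tolist()}"
            )
        per_ind = self.samples.groupby("individual_id")[["class_label", "gender"]].nunique()
        bad = per_ind[(per_ind > 1).any(axis=1)]
        if len(bad):
            raise ValueError(
                f"individuals with inconsistent class/gender across replicates: {bad.index.tolist()}"
            )
        with np.errstate(invalid="ignore"):
            if (self.intensities.to_numpy() < 0).any():
                raise ValueError("intensities must be non-negative")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def class_labels(self) -> pd.Series:
        return self.samples["class_label"]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.samples.copy(), self.features.copy()
        )

    def subset_samples(self, sample_ids) -> "FeatureTable":
        sample_ids = list(sample_ids)
        return FeatureTable(
            self.intensities.loc[sample_ids],
            self.samples.loc[sample_ids],
            self.features.copy(),
        )

    def subset_features(self, feature_ids) -> "FeatureTable":
        feature_ids = list(feature_ids)
        return FeatureTable(
            self.intensities[feature_ids],
            self.samples.copy(),
            self.features.loc[feature_ids],
        )

    # -- delimited-text round trip ---------------------------------------
    def write(self, out_dir) -> None:
        """Write intensities.csv / samples.csv / features.csv (missing = empty cell)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.intensities.to_csv(out / "intensities.csv", index_label="sample_id")
        self.samples.to_csv(out / "samples.csv", index_label="sample_id")
        self.features.to_csv(out / "features.csv", index_label="feature_id")

    @classmethod
    def read(cls, in_dir) -> "FeatureTable":
        p = Path(in_dir)
        intensities = pd.read_csv(p / "intensities.csv", index_col="sample_id")
        samples = pd.read_csv(p / "samples.csv", index_col="sample_id")
        fpath = p / "features.csv"
        features = pd.read_csv(fpath, index_col="feature_id") if fpath.exists() else None
        return cls(intensities, samples, features)


def stratify_by_gender(table: FeatureTable) -> tuple[FeatureTable, FeatureTable]:
    """Split a table into (male, female) sub-tables, keeping class labels.

    The split is disjoint and exhaustive; a single-gender input yields one
    empty subset with a warning.
    """
    gender = table.samples["gender"]
    if gender.isna().any():
        bad = table.samples.index[gender.isna()].tolist()
        raise ValueError(f"samples without gender annotation: {bad}")
    male_ids = table.samples.index[gender == "M"]
    female_ids = table.samples.index[gender == "F"]
    if len(male_ids) == 0 or len(female_ids) == 0:
        warnings.warn("single-gender table: one gender subset is empty", stacklevel=2)
    male = FeatureTable(
        table.intensities.loc[male_ids], table.samples.loc[male_ids], table.features.copy()
    )
    female = FeatureTable(
        table.intensities.loc[female_ids], table.samples.loc[female_ids], table.features.copy()
    )
    return male, female
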