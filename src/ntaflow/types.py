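"""Core data containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import chem

ION_MODES = ("positive", "negative")
MATRICES = ("serum", "urine", "blank")
OUTCOMES = ("preterm", "term")

#: The five source/use categories carried by library entries and annotations.
SOURCE_CATEGORIES = (
    "endogenous_metabolite",
    "natural_product",
    "drug",
    "personal_care_product",
    "exogenous_contaminant",
)
UNKNOWN_SOURCE = "unknown"

#: Orbitrap background noise floor: areas at or below this are not "detected".
NOISE_FLOOR = 10_000.0


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


class ParseError(ValueError):
    """An external file could not be parsed; the message names the location."""


class ConfigError(ValueError):
    """A configuration object is internally inconsistent."""


@dataclass
class Spectrum:
    """An MS2 fragment spectrum for a single precursor."""

    precursor_mz: float
    ion_mode: str
    fragments: np.ndarray  # shape (n, 2): columns m/z, intensity

    def __post_init__(self) -> None:
        frags = np.asarray(self.fragments, dtype=float)
        if frags.ndim != 2 or frags.shape[1] != 2:
            raise ValidationError("fragments must be an (n, 2) array of (mz, intensity)")
        if len(frags) and np.any(frags[:, 1] <= 0):
            raise ValidationError("fragment intensities must be > 0")
        order = np.argsort(frags[:, 0], kind="stable")
        self.fragments = frags[order]
        if self.ion_mode not in ION_MODES:
            raise ValidationError(f"unknown ion mode {self.ion_mode!r}")

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


@dataclass
class SpectralLibraryEntry:
    """A reference spectrum with compound identity and source categories."""

    name: str
    spectrum: Spectrum
    neutral_mass: float
    formula: Optional[str] = None
    rt: Optional[float] = None
    sources: frozenset = frozenset()
    is_authentic_standard: bool = False

    def __post_init__(self) -> None:
        self.sources = frozenset(self.sources)
        bad = self.sources - set(SOURCE_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown source categories {sorted(bad)}")
        if self.formula:
            expected = chem.formula_monoisotopic_mass(self.formula)
            if chem.ppm_difference(expected, self.neutral_mass) > 5.0:
                raise ValidationError(
                    f"entry {self.name!r}: neutral mass {self.neutral_mass} "
                    f"disagrees with formula {self.formula} ({expected:.5f}) by >5 ppm"
                )

    def effective_sources(self) -> frozenset:
        """The category set, with an empty set collapsed to 'unknown'."""
        return self.sources if self.sources else frozenset({UNKNOWN_SOURCE})


@dataclass
class Annotation:
    """A candidate compound assigned to a feature, with confidence evidence."""

    feature_id: Optional[str]
    compound_name: Optional[str]
    level: int
    score: float = 0.0
    formula: Optional[str] = None
    sources: frozenset = frozenset({UNKNOWN_SOURCE})
    precursor_mz: Optional[float] = None
    rt: Optional[float] = None
    precursor_ppm_error: Optional[float] = None
    rt_error_min: Optional[float] = None
    n_matched_fragments: int = 0

    def __post_init__(self) -> None:
        self.sources = frozenset(self.sources)
        if self.level not in (1, 2, 3, 4, 5):
            raise ValidationError(f"level must be 1-5, got {self.level}")
        if not (0.0 <= self.score <= 100.0):
            raise ValidationError(f"score must be in [0, 100], got {self.score}")


@dataclass(frozen=True)
class MergeRecord:
    """A matched [M+H]+/[M-H]- pair sharing one neutral molecule."""

    pos_feature_id: str
    neg_feature_id: str
    neutral_mass_pos: float
    neutral_mass_neg: float
    mass_error_ppm: float
    delta_rt: float


FEATURE_COLUMNS = ("mz", "rt", "ion_mode", "adduct_link")
SAMPLE_COLUMNS = ("matrix", "batch", "outcome", "creatinine")


@dataclass
class FeatureTable:
    """Feature abundance matrix plus per-feature and per-sample metadata.

    ``abundance`` is features x samples with NaN encoding "missing"
    (below-MDL), which is distinct from a literal zero area.
    """

    features: pd.DataFrame   # index: feature_id
    abundance: pd.DataFrame  # index: feature_id, columns: sample_id
    samples: pd.DataFrame    # index: sample_id

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.features.copy(), self.abundance.copy(), self.samples.copy()
        )

    def validate(self) -> "FeatureTable":
        feats, ab, samp = self.features, self.abundance, self.samples
        if feats.index.has_duplicates:
            dupes = feats.index[feats.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dupes[:5]}")
        if samp.index.has_duplicates:
            dupes = samp.index[samp.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        if not feats.index.equals(ab.index):
            raise ValidationError("abundance rows do not match feature records")
        if list(ab.columns) != list(samp.index):
            raise ValidationError("abundance columns do not match sample records")
        for col in ("mz", "rt", "ion_mode"):
            if col not in feats.columns:
                raise ValidationError(f"feature metadata missing column {col!r}")
        if (feats["mz"] <= 0).any():
            bad = feats.index[feats["mz"] <= 0][0]
            raise ValidationError(f"feature {bad!r} has non-positive m/z")
        if (feats["rt"] < 0).any():
            bad = feats.index[feats["rt"] < 0][0]
            raise ValidationError(f"feature {bad!r} has negative RT")
        unknown_modes = set(feats["ion_mode"]) - set(ION_MODES)
        if unknown_modes:
            raise ValidationError(f"unknown ion modes {sorted(unknown_modes)}")
        vals = ab.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValidationError("negative peak areas present")
        for col in ("matrix", "batch"):
            if col not in samp.columns:
                raise ValidationError(f"sample metadata missing column {col!r}")
        unknown_matrix = set(samp["matrix"]) - set(MATRICES)
        if unknown_matrix:
            raise ValidationError(f"unknown matrix values {sorted(unknown_matrix)}")
        if "creatinine" in samp.columns:
            urine = samp["matrix"] == "urine"
            creat = pd.to_numeric(samp.loc[urine, "creatinine"], errors="coerce")
            if creat.isna().any() or (creat <= 0).any():
                bad = creat.index[creat.isna() | (creat <= 0)][0]
                raise ValidationError(
                    f"urine sample {bad!r} lacks a positive creatinine value"
                )
        return self

    # -- convenience views -------------------------------------------------

    def detected(self, noise_floor: float = NOISE_FLOOR) -> pd.DataFrame:
        """Boolean mask of detection: non-missing and above the noise floor."""
        return self.abundance.notna() & (self.abundance > noise_floor)

    def detection_frequency(self, noise_floor: float = NOISE_FLOOR) -> pd.Series:
        return self.detected(noise_floor).mean(axis=1)

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(
            self.features.loc[ids].copy(),
            self.abundance.loc[ids].copy(),
            self.samples.copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        ids = list(sample_ids)
        return FeatureTable(
            self.features.copy(),
            self.abundance[ids].copy(),
            self.samples.loc[ids].copy(),
        )

    def log10_abundance(self) -> pd.DataFrame:
        vals = self.abundance.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) <= 0:
            raise ValidationError("cannot log-transform non-positive areas")
        return pd.DataFrame(
            np.log10(vals), index=self.abundance.index, columns=self.abundance.columns
        )


def make_feature_table(
    feature_records: pd.DataFrame,
    abundance: pd.DataFrame,
    sample_records: pd.DataFrame,
) -> FeatureTable:
    """Assemble and validate a :class:`FeatureTable` in one call."""
    table = FeatureTable(feature_records, abundance, sample_records)
    return table.validate()
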