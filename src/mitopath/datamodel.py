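"""Core domain types: variants, feature tables, labeled datasets, residue sites.

Feature values live in a pandas DataFrame (rows = variant ids, columns =
feature names, NaN = missing). Each feature belongs to one of four groups
(evolutionary, predictor, structural, positional); features that are 3D
coordinates (X, Y, Z) carry an additional *spatial* flag so that the spatial
autocorrelation analysis can exclude base learners trained on them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MT_GENOME_LENGTH = 16_569  # NC_012920.1 (rCRS)

_NUCLEOTIDES = frozenset("ACGT")


class Status(str, enum.Enum):
    """Literature-curation status of an mtDNA variant."""

    confirmed = "confirmed"
    reported = "reported"
    general = "general"
    none = "none"


class FeatureGroup(str, enum.Enum):
    evolutionary = "evolutionary"
    predictor = "predictor"
    structural = "structural"
    positional = "positional"


@dataclass(frozen=True)
class VariantRecord:
    """A single mtDNA single-nucleotide variant with curation annotations.

    Parameters
    ----------
    mt_position : int
        1-based position on the revised Cambridge reference sequence.
    ref_allele, alt_allele : str
        Nucleotides; must differ.
    gene : str
        Gene symbol (e.g. ``MT-ND1``).
    protein_change : str
        Amino-acid substitution, e.g. ``p.Thr35Pro`` (1-based residue index).
    status : Status
        Curation status (confirmed / reported / general / none).
    clingen_codes : frozenset of str
        ACMG/AMP criteria codes attached by curators (e.g. ``PM2``, ``BA1``).
    synergistic_or_conflicting : bool
        Noted in the literature as synergistic or with conflicting reports.
    af : mapping
        source name -> (homoplasmic fraction, heteroplasmic fraction),
        both in [0, 1].
    """

    mt_position: int
    ref_allele: str
    alt_allele: str
    gene: str = ""
    protein_change: str = ""
    status: Status = Status.none
    clingen_codes: frozenset = frozenset()
    synergistic_or_conflicting: bool = False
    af: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.mt_position <= MT_GENOME_LENGTH):
            raise ValueError(
                f"mt_position {self.mt_position} outside [1, {MT_GENOME_LENGTH}]"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele equals alt_allele")
        for source, (hom, het) in self.af.items():
            if not (0.0 <= hom <= 1.0 and 0.0 <= het <= 1.0):
                raise ValueError(f"allele fractions for {source!r} outside [0, 1]")

    @property
    def key(self) -> tuple[int, str, str]:
        """Nucleotide-level variant identity: (position, ref, alt)."""
        return (self.mt_position, self.ref_allele, self.alt_allele)

    @property
    def variant_id(self) -> str:
        return f"m.{self.mt_position}{self.ref_allele}>{self.alt_allele}"


class FeatureTable:
    """Variants x features matrix with explicit missing values and metadata.

    Wraps a float DataFrame (NaN marks missing) together with a feature ->
    group mapping and the set of features flagged as spatial coordinates.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        feature_groups: Mapping[str, FeatureGroup] | None = None,
        spatial_flags: Iterable[str] = (),
    ) -> None:
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate variant ids: {dupes}")
        if values.columns.has_duplicates:
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        self.values = values.astype(float)
        groups = dict(feature_groups or {})
        for name in self.values.columns:
            groups.setdefault(name, FeatureGroup.predictor)
        self.feature_groups = groups
        self.spatial_flags = frozenset(spatial_flags)
        unknown = self.spatial_flags - set(self.values.columns)
        if unknown:
            raise ValueError(f"spatial_flags not among features: {sorted(unknown)}")

    # -- basic views ------------------------------------------------------

    @property
    def variant_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    # -- derived tables ---------------------------------------------------

    def subset_rows(self, ids: Iterable[str]) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(self.values.loc[ids], self.feature_groups, self.spatial_flags)

    def subset_features(self, names: Iterable[str]) -> "FeatureTable":
        names = list(names)
        return FeatureTable(
            self.values.loc[:, names],
            {n: self.feature_groups[n] for n in names},
            self.spatial_flags & set(names),
        )

    def with_values(self, values: pd.DataFrame) -> "FeatureTable":
        """Same metadata, new value matrix (must keep index/columns)."""
        if not values.index.equals(self.values.index) or not values.columns.equals(
            self.values.columns
        ):
            raise ValueError("with_values requires identical index and columns")
        return FeatureTable(values, self.feature_groups, self.spatial_flags)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.feature_groups, self.spatial_flags)

    def __repr__(self) -> str:  # pragma: no cover
        n, f = self.shape
        return f"FeatureTable({n} variants x {f} features, {self.n_missing()} missing)"


@dataclass
class LabeledDataset:
    """A feature table with aligned binary class labels (1 = pathogenic)."""

    table: FeatureTable
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.table.values.index)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()
            raise ValueError(f"labels missing for variants: {missing[:5]}")
        self.labels = self.labels.astype(int)
        if not set(self.labels.unique()) <= {0, 1}:
            raise ValueError("labels must be 0 (neutral) or 1 (pathogenic)")

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    @property
    def n_pathogenic(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neutral(self) -> int:
        return int((self.labels == 0).sum())

    def require_both_classes(self) -> None:
        if self.n_pathogenic == 0 or self.n_neutral == 0:
            raise ValueError(
                "training requires both classes; got "
                f"{self.n_pathogenic} pathogenic / {self.n_neutral} neutral"
            )

    def subset_rows(self, ids: Iterable[str]) -> "LabeledDataset":
        ids = list(ids)
        return LabeledDataset(self.table.subset_rows(ids), self.labels.loc[ids])


@dataclass
class ResidueSite:
    """One residue of one chain of one protein complex, located by its CA atom."""

    complex_id: str
    chain: str
    residue_index: int
    ca_coord: tuple[float, float, float]
    mean_score: float | None = None

    def __post_init__(self) -> None:
        if not all(np.isfinite(c) for c in self.ca_coord):
            raise ValueError(
                f"non-finite CA coordinate at {self.complex_id}/{self.chain}/"
                f"{self.residue_index}"
            )

    @property
    def site_key(self) -> tuple[str, str, int]:
        return (self.complex_id, self.chain, self.residue_index)
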