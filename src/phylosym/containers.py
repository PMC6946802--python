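"""Core in-memory containers: the ASV count table and the sample metadata.

Both are thin, validating wrappers around pandas DataFrames.  Distance
matrices use :class:`skbio.DistanceMatrix` and phylogenies use
:class:`skbio.TreeNode`; no bespoke containers are introduced for those.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "SampleMetadata", "REQUIRED_METADATA_COLUMNS", "DIET_PREFIX"]

#: metadata columns that must be present (diet columns carry the DIET_PREFIX)
REQUIRED_METADATA_COLUMNS = ("host_species", "host_order", "host_class", "flight")

#: prefix marking diet-composition columns (percentages summing to 100)
DIET_PREFIX = "diet_"


def _check_unique(labels, kind: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dupes = sorted(idx[idx.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {kind} IDs: {dupes}")


@dataclass
class FeatureTable:
    """ASV-by-sample table of non-negative integer counts.

    ``data`` is indexed by ASV ID with one column per sample ID.  Counts are
    validated to be non-negative integers and IDs to be unique on
    construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "ASV")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                # accept float inputs only when exactly integral
                rounded = np.rint(values)
                bad = ~np.isfinite(values) | (values != rounded)
                if bad.any():
                    r, c = np.argwhere(bad)[0]
                    raise ValueError(
                        "non-integer count at "
                        f"(asv={self.data.index[r]!r}, sample={self.data.columns[c]!r}): "
                        f"{values[r, c]!r}"
                    )
                self.data = self.data.astype(np.int64)
                values = self.data.to_numpy()
            if (values < 0).any():
                r, c = np.argwhere(values < 0)[0]
                raise ValueError(
                    "negative count at "
                    f"(asv={self.data.index[r]!r}, sample={self.data.columns[c]!r}): "
                    f"{values[r, c]}"
                )
        else:
            self.data = self.data.astype(np.int64)

    # -- construction -------------------------------------------------------
    @classmethod
    def from_arrays(cls, counts, asv_ids, sample_ids) -> "FeatureTable":
        return cls(pd.DataFrame(np.asarray(counts), index=list(asv_ids), columns=list(sample_ids)))

    # -- views ---------------------------------------------------------------
    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """(n_asvs, n_samples) int array view of the counts."""
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def presence(self) -> np.ndarray:
        """Boolean (n_asvs, n_samples) presence matrix (count > 0)."""
        return self.counts > 0

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def asv_prevalence(self) -> pd.Series:
        """Number of samples in which each ASV is present."""
        return (self.data > 0).sum(axis=1)

    # -- subsetting ----------------------------------------------------------
    def select_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(sample_ids)])

    def select_asvs(self, asv_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(asv_ids), :])

    def __eq__(self, other) -> bool:  # count-and-label equality
        return isinstance(other, FeatureTable) and self.data.equals(other.data)


@dataclass
class SampleMetadata:
    """Per-sample host annotations, indexed by sample ID.

    Required columns: host_species, host_order, host_class, flight.  Diet
    composition lives in ``diet_*`` columns (percentages summing to 100 per
    sample); any other columns are carried through untouched.
    """

    frame: pd.DataFrame
    diet_tolerance: float = field(default=1e-6, repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "sample")
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing required metadata column(s): {missing}")
        diet = self.diet
        if diet.shape[1]:
            if (diet.to_numpy() < 0).any():
                raise ValueError("negative diet percentage")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def diet_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith(DIET_PREFIX)]

    @property
    def diet(self) -> pd.DataFrame:
        """Diet composition (samples x categories), in percent."""
        return self.frame[self.diet_columns].astype(float)

    def check_diet_sums(self) -> pd.Series:
        """Per-sample deviation of the diet sum from 100."""
        return (self.diet.sum(axis=1) - 100.0).abs()

    def species_of(self, sample_ids=None) -> pd.Series:
        ids = self.frame.index if sample_ids is None else list(sample_ids)
        return self.frame.loc[ids, "host_species"]

    def samples_of_class(self, class_name: str) -> list[str]:
        return list(self.frame.index[self.frame["host_class"] == class_name])

    def select(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)], self.diet_tolerance)

    def species_diet(self) -> pd.DataFrame:
        """Diet composition per species (mean over its samples)."""
        return self.diet.groupby(self.frame["host_species"]).mean()
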