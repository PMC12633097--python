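"""Core containers shared by every pipeline stage.

An :class:`AbundanceMatrix` is a proteins x samples table with explicit
missingness (NaN) and a ``scale_tag`` recording how far along the
normalisation chain the values are.  A :class:`SampleManifest` carries the
per-sample metadata (batch, GIS flag, traits, covariates) that drives batch
correction, regression and the trait-association scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# Ordered normalisation states; transitions only move right.
SCALE_TAGS = ("raw", "sum_scaled", "log2", "tampor_corrected", "regressed")

# Manifest columns understood by the pipeline.  ``caa_severity`` is the
# ordinal 0-3 amyloid-angiopathy score; ``wmh`` a continuous white-matter
# hyperintensity burden; ``microbleeds``/``infarcts`` binary lesion flags.
TRAIT_COLUMNS = ("group", "caa_severity", "cerad", "braak", "wmh",
                 "microbleeds", "infarcts")
COVARIATE_COLUMNS = ("age", "pmi", "sex", "apoe4", "cell_proportion")


class ScaleTagError(ValueError):
    """Raised when an operation is applied at the wrong normalisation state."""


@dataclass
class AbundanceMatrix:
    """Proteins x samples abundance table with explicit missing values.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with sample ids as columns.  Missing
        cells are NaN; raw/sum_scaled values must be strictly positive where
        present.
    scale_tag
        One of ``raw``, ``sum_scaled``, ``log2``, ``tampor_corrected``,
        ``regressed``.
    """

    values: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate protein ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.values = self.values.astype(float)
        if self.scale_tag in ("raw", "sum_scaled"):
            vals = self.values.to_numpy()
            # raw zeros are legal placeholders for "not quantified"; they are
            # converted to explicit missing by sum_scale
            floor = 0.0 if self.scale_tag == "raw" else None
            present = vals[np.isfinite(vals)]
            bad = np.any(present < 0) if floor == 0.0 else np.any(present <= 0)
            if bad:
                raise ValueError(
                    f"{self.scale_tag} values must be positive where present")

    # -- convenience ------------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the cell is missing."""
        return self.values.isna()

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_tag(self, *tags: str) -> None:
        if self.scale_tag not in tags:
            raise ScaleTagError(
                f"operation requires scale_tag in {tags}, got {self.scale_tag!r}")

    def with_values(self, values: pd.DataFrame, scale_tag: str | None = None) -> "AbundanceMatrix":
        """Copy with new values (and optionally a new tag), validating the
        tag transition only moves forward along the normalisation chain."""
        tag = self.scale_tag if scale_tag is None else scale_tag
        if SCALE_TAGS.index(tag) < SCALE_TAGS.index(self.scale_tag):
            raise ScaleTagError(
                f"cannot move scale_tag backwards: {self.scale_tag} -> {tag}")
        return AbundanceMatrix(values=values, scale_tag=tag)

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        return replace(self, values=self.values.loc[:, list(sample_ids)])

    def subset_proteins(self, protein_ids) -> "AbundanceMatrix":
        return replace(self, values=self.values.loc[list(protein_ids), :])


@dataclass
class SampleManifest:
    """Per-sample metadata table indexed by sample id.

    Required columns: ``batch`` and ``is_gis``.  Trait and covariate columns
    (see :data:`TRAIT_COLUMNS`, :data:`COVARIATE_COLUMNS`) are optional and
    may contain NaN for GIS channels.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in manifest")
        for col in ("batch", "is_gis"):
            if col not in self.table.columns:
                raise ValueError(f"manifest missing required column {col!r}")
        self.table = self.table.copy()
        self.table["is_gis"] = self.table["is_gis"].astype(bool)

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def batches(self) -> pd.Series:
        return self.table["batch"]

    @property
    def is_gis(self) -> pd.Series:
        return self.table["is_gis"]

    def gis_samples(self, batch=None) -> pd.Index:
        t = self.table
        sel = t["is_gis"]
        if batch is not None:
            sel = sel & (t["batch"] == batch)
        return t.index[sel]

    def non_gis_samples(self, batch=None) -> pd.Index:
        t = self.table
        sel = ~t["is_gis"]
        if batch is not None:
            sel = sel & (t["batch"] == batch)
        return t.index[sel]

    def check_against(self, X: AbundanceMatrix, require_gis: bool = False) -> None:
        """Validate that every matrix sample appears exactly once, and
        (optionally) that every batch with matrix samples has a GIS channel."""
        missing = X.sample_ids.difference(self.table.index)
        if len(missing):
            raise ValueError(f"samples absent from manifest: {list(missing)[:5]}")
        if require_gis:
            sub = self.table.loc[X.sample_ids]
            for b, grp in sub.groupby("batch", sort=False):
                if not grp["is_gis"].any():
                    raise ValueError(f"batch {b!r} has no GIS sample")

    def subset(self, sample_ids) -> "SampleManifest":
        return SampleManifest(self.table.loc[list(sample_ids)])
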