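"""Reading, validation and preprocessing of site-by-taxon community tables.

The central container is :class:`CommunityMatrix`, a validated samples × taxa
abundance table (counts or densities in ind/m²). Preprocessing mirrors common
practice in benthic bioassessment: replicate pooling to site level, log(x+1)
transformation ahead of ordination/clustering, and exclusion of rare taxa
(those occurring at fewer than a minimum number of sites).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FFG_CATEGORIES",
    "FFG_UNKNOWN",
    "CommunityMatrix",
    "TaxonTable",
    "SiteTable",
    "read_community_matrix",
    "read_taxon_table",
    "read_site_table",
    "pool_replicates",
    "log_transform",
    "inverse_log_transform",
    "drop_rare_taxa",
]

#: Closed functional-feeding-group vocabulary used throughout the package.
FFG_CATEGORIES = (
    "predator",
    "parasite",
    "scraper",
    "collector_filterer",
    "collector_gatherer",
    "shredder",
)
#: Sentinel for taxa without an FFG assignment.
FFG_UNKNOWN = "unknown"


def _check_unique(ids, kind: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {kind} identifier(s): {dup}")


@dataclass(frozen=True)
class CommunityMatrix:
    """Samples × taxa abundance matrix, the universal currency of the pipeline.

    Parameters
    ----------
    data
        DataFrame with sample identifiers as the index and taxon identifiers
        as columns; non-negative numeric body.
    transformed
        Whether ``log_b(x + 1)`` has been applied (see :func:`log_transform`).
    log_base
        The base ``b`` of the transform, when ``transformed`` is True.
    dropped_taxa
        Taxa removed by :func:`drop_rare_taxa`, recorded for provenance.
    """

    data: pd.DataFrame
    transformed: bool = False
    log_base: float | None = None
    dropped_taxa: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "taxon")
        body = df.to_numpy()
        if not np.issubdtype(np.asarray(body).dtype, np.number):
            bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-numeric cell at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )
        if np.isnan(body).any():
            r, c = np.argwhere(np.isnan(body))[0]
            raise ValueError(
                f"missing cell at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )
        if (body < 0).any():
            r, c = np.argwhere(body < 0)[0]
            raise ValueError(
                f"negative abundance {body[r, c]} at sample {df.index[r]!r}, "
                f"taxon {df.columns[c]!r}"
            )
        object.__setattr__(self, "data", df.astype(float))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Abundance matrix as a float array (samples × taxa)."""
        return self.data.to_numpy(copy=True)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        """Abundance vector of one sample."""
        return self.data.loc[sample_id]


@dataclass(frozen=True)
class TaxonTable:
    """Per-taxon order/family and functional-feeding-group labels."""

    data: pd.DataFrame  # index taxon_id; columns order_name, family_name, ffg

    def __post_init__(self) -> None:
        df = self.data.copy()
        _check_unique(df.index, "taxon")
        for col in ("order_name", "family_name", "ffg"):
            if col not in df.columns:
                df[col] = FFG_UNKNOWN if col == "ffg" else ""
        df["ffg"] = df["ffg"].fillna(FFG_UNKNOWN)
        bad = ~df["ffg"].isin(FFG_CATEGORIES + (FFG_UNKNOWN,))
        if bad.any():
            raise ValueError(
                f"unrecognized FFG label(s): {sorted(df.loc[bad, 'ffg'].unique())}; "
                f"expected one of {FFG_CATEGORIES} or {FFG_UNKNOWN!r}"
            )
        object.__setattr__(self, "data", df)

    def ffg_of(self, taxa) -> pd.Series:
        """FFG label per taxon; taxa missing from the table map to ``unknown``."""
        out = self.data["ffg"].reindex(taxa).fillna(FFG_UNKNOWN)
        missing = [t for t in taxa if t not in self.data.index]
        if missing:
            warnings.warn(
                f"{len(missing)} taxa lack trait rows; assigned FFG "
                f"{FFG_UNKNOWN!r}: {missing[:5]}...",
                stacklevel=2,
            )
        return out

    def order_of(self, taxa) -> pd.Series:
        return self.data["order_name"].reindex(taxa).fillna("")


@dataclass(frozen=True)
class SiteTable:
    """Per-sample stream membership and environmental covariates."""

    data: pd.DataFrame  # index sample_id; column stream_id + covariates

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")

    def check_samples(self, matrix: CommunityMatrix) -> None:
        extra = set(self.data.index) - set(matrix.sample_ids)
        if extra:
            raise ValueError(f"site table samples not in matrix: {sorted(extra)}")


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_community_matrix(path, orientation: str = "rows_are_samples") -> CommunityMatrix:
    """Read a delimited site-by-taxon table (CSV or TSV, sniffed).

    ``orientation`` is normalized so samples are rows in the returned matrix.
    """
    if orientation not in ("rows_are_samples", "rows_are_taxa"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}"
            )
        df[col] = coerced
    if orientation == "rows_are_taxa":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CommunityMatrix(df)


def read_taxon_table(path) -> TaxonTable:
    return TaxonTable(_read_table(path))


def read_site_table(path) -> SiteTable:
    return SiteTable(_read_table(path))


def pool_replicates(
    m: CommunityMatrix,
    replicate_map: Mapping[str, str],
    area_m2: float | None = None,
) -> CommunityMatrix:
    """Pool replicate samples to site level by summation.

    With ``area_m2`` (total sampled area per site, e.g. 0.27 m² for three
    30 × 30 cm Surber grabs) counts become densities in ind/m²; otherwise raw
    sums are returned. Totals are conserved: site total × area = sum of the
    replicate totals.
    """
    if m.transformed:
        raise ValueError("pool replicates on raw counts, before log transform")
    unmapped = [s for s in m.sample_ids if s not in replicate_map]
    if unmapped:
        raise ValueError(f"samples without a site mapping: {unmapped}")
    if area_m2 is not None and area_m2 <= 0:
        raise ValueError("area_m2 must be positive")
    sites = pd.Series({s: replicate_map[s] for s in m.sample_ids})
    # preserve order of first appearance
    order = sites.drop_duplicates().tolist()
    pooled = m.data.groupby(sites, sort=False).sum().loc[order]
    if area_m2 is not None:
        pooled = pooled / area_m2
    return CommunityMatrix(pooled, dropped_taxa=m.dropped_taxa)


def log_transform(m: CommunityMatrix, base: float = 10.0) -> CommunityMatrix:
    """Apply ``x -> log_base(x + 1)`` cellwise and set the transformed flag."""
    if m.transformed:
        raise ValueError("matrix is already log-transformed")
    if base <= 0 or base == 1:
        raise ValueError("log base must be positive and != 1")
    out = np.log1p(m.data) / math.log(base)
    return CommunityMatrix(
        out, transformed=True, log_base=base, dropped_taxa=m.dropped_taxa
    )


def inverse_log_transform(m: CommunityMatrix) -> CommunityMatrix:
    """Undo :func:`log_transform`, recovering raw abundances."""
    if not m.transformed:
        raise ValueError("matrix is not transformed")
    raw = np.expm1(m.data * math.log(m.log_base))
    # clip tiny negative float noise
    raw = raw.clip(lower=0.0)
    return CommunityMatrix(raw, dropped_taxa=m.dropped_taxa)


def drop_rare_taxa(m: CommunityMatrix, min_occurrences: int = 2) -> CommunityMatrix:
    """Exclude taxa occurring at fewer than ``min_occurrences`` samples.

    Occurrence counts samples with abundance > 0. With the default of 2,
    singleton taxa (present at exactly one site) are removed — the standard
    rare-taxon filter applied before ordination. The removed taxa are
    recorded on the returned matrix.
    """
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be >= 1")
    occ = (m.data > 0).sum(axis=0)
    keep = occ[occ >= min_occurrences].index
    dropped = tuple(t for t in m.taxon_ids if t not in set(keep))
    if len(keep) == 0:
        warnings.warn("all taxa removed by rare-taxon filter", stacklevel=2)
    return CommunityMatrix(
        m.data[list(keep)],
        transformed=m.transformed,
        log_base=m.log_base,
        dropped_taxa=m.dropped_taxa + dropped,
    )
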