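"""Community indices and functional-feeding-group (FFG) profiles.

Per-sample descriptors standard in freshwater bioassessment:

* richness S, abundance N
* Shannon diversity H = −Σ pᵢ ln pᵢ (natural log)
* McNaughton dominance DI = (n₁ + n₂)/N (two most abundant taxa)
* Margalef richness index R = (S − 1)/ln N
* Pielou evenness E = H/ln S
* EPT (Ephemeroptera + Plecoptera + Trichoptera) richness and abundance,
  per-order breakdowns, and non-insect / other-insect tallies
* FFG percentages of abundance and of richness over trait-classified taxa

All indices are computed on raw (untransformed) abundances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import FFG_CATEGORIES, FFG_UNKNOWN, CommunityMatrix, TaxonTable

__all__ = [
    "EPT_ORDERS",
    "INSECT_ORDERS",
    "CommunityIndices",
    "indices",
    "indices_table",
    "ffg_profile",
    "ffg_table",
]

EPT_ORDERS = ("Ephemeroptera", "Plecoptera", "Trichoptera")
INSECT_ORDERS = EPT_ORDERS + (
    "Diptera",
    "Coleoptera",
    "Odonata",
    "Hemiptera",
    "Megaloptera",
    "Lepidoptera",
    "Neuroptera",
    "Collembola",
)


@dataclass(frozen=True)
class CommunityIndices:
    richness: int
    abundance: float
    shannon: float
    dominance: float
    richness_index: float
    evenness: float
    ept_richness: int
    ept_abundance: float
    ephemeroptera_richness: int
    ephemeroptera_abundance: float
    plecoptera_richness: int
    plecoptera_abundance: float
    trichoptera_richness: int
    trichoptera_abundance: float
    other_insect_richness: int
    other_insect_abundance: float
    non_insect_richness: int
    non_insect_abundance: float


def indices(sample: pd.Series, traits: TaxonTable | None = None) -> CommunityIndices:
    """Community indices for one sample (a row of the community matrix).

    Degenerate cases: an empty sample (N = 0) yields all-zero indices with a
    warning; a single-taxon sample has H = 0 and evenness defined as 0.
    """
    x = sample.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    N = float(x.sum())
    S = int((x > 0).sum())

    orders = (
        traits.order_of(sample.index)
        if traits is not None
        else pd.Series("", index=sample.index)
    )

    def order_stats(mask: np.ndarray) -> tuple[int, float]:
        return int(((x > 0) & mask).sum()), float(x[mask].sum())

    is_order = {o: (orders == o).to_numpy() for o in EPT_ORDERS}
    ept_mask = orders.isin(EPT_ORDERS).to_numpy()
    insect_mask = orders.isin(INSECT_ORDERS).to_numpy()
    other_insect = insect_mask & ~ept_mask
    non_insect = ~insect_mask

    if N == 0:
        warnings.warn("empty sample: all indices set to 0", stacklevel=2)
        return CommunityIndices(
            0, 0.0, 0.0, 0.0, 0.0, 0.0, 0, 0.0, 0, 0.0, 0, 0.0, 0, 0.0,
            0, 0.0, 0, 0.0,
        )

    p = x[x > 0] / N
    H = float(-(p * np.log(p)).sum())
    top2 = np.sort(x)[::-1][:2]
    DI = float(top2.sum() / N)
    R = (S - 1) / math.log(N) if N > 1 else 0.0
    E = H / math.log(S) if S > 1 else 0.0

    e_r, e_a = order_stats(is_order["Ephemeroptera"])
    p_r, p_a = order_stats(is_order["Plecoptera"])
    t_r, t_a = order_stats(is_order["Trichoptera"])
    ept_r, ept_a = order_stats(ept_mask)
    oi_r, oi_a = order_stats(other_insect)
    ni_r, ni_a = order_stats(non_insect)

    return CommunityIndices(
        richness=S,
        abundance=N,
        shannon=H,
        dominance=DI,
        richness_index=R,
        evenness=E,
        ept_richness=ept_r,
        ept_abundance=ept_a,
        ephemeroptera_richness=e_r,
        ephemeroptera_abundance=e_a,
        plecoptera_richness=p_r,
        plecoptera_abundance=p_a,
        trichoptera_richness=t_r,
        trichoptera_abundance=t_a,
        other_insect_richness=oi_r,
        other_insect_abundance=oi_a,
        non_insect_richness=ni_r,
        non_insect_abundance=ni_a,
    )


def indices_table(m: CommunityMatrix, traits: TaxonTable | None = None) -> pd.DataFrame:
    """One row of :func:`indices` per sample."""
    if m.transformed:
        raise ValueError("indices require raw (untransformed) abundances")
    rows = {s: asdict(indices(m.data.loc[s], traits)) for s in m.sample_ids}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def ffg_profile(sample: pd.Series, traits: TaxonTable) -> pd.DataFrame:
    """FFG percentages of abundance and of richness for one sample.

    Percentages are taken over trait-classified present taxa only (taxa with
    FFG ``unknown`` are excluded from both denominators), so each column sums
    to 100 whenever any classified taxon is present.
    """
    ffg = traits.ffg_of(sample.index)
    x = sample.to_numpy(dtype=float)
    classified = (ffg != FFG_UNKNOWN).to_numpy() & (x > 0)
    out = pd.DataFrame(
        0.0, index=list(FFG_CATEGORIES), columns=["pct_abundance", "pct_richness"]
    )
    out.index.name = "ffg"
    total_ab = x[classified].sum()
    total_ri = classified.sum()
    if total_ri == 0:
        warnings.warn("no classified taxa present; empty FFG profile", stacklevel=2)
        return out
    for g in FFG_CATEGORIES:
        mask = classified & (ffg == g).to_numpy()
        out.loc[g, "pct_abundance"] = 100.0 * x[mask].sum() / total_ab
        out.loc[g, "pct_richness"] = 100.0 * mask.sum() / total_ri
    return out


def ffg_table(m: CommunityMatrix, traits: TaxonTable) -> pd.DataFrame:
    """Long-format FFG profile (sample_id, ffg, pct_abundance, pct_richness)."""
    if m.transformed:
        raise ValueError("FFG profiles require raw abundances")
    frames = []
    for s in m.sample_ids:
        prof = ffg_profile(m.data.loc[s], traits).reset_index()
        prof.insert(0, "sample_id", s)
        frames.append(prof)
    return pd.concat(frames, ignore_index=True)
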