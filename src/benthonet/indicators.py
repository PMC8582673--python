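"""Dufrêne–Legendre indicator species analysis (IndVal).

For taxon t and cluster c:

* specificity  A(t,c) = mean abundance of t in c / Σ over clusters of the
  mean abundance of t (group-equalized means, so unequal cluster sizes do
  not bias A);
* fidelity     B(t,c) = fraction of cluster-c samples where t is present;
* IndVal(t,c) = 100 · A · B, ranging 0–100, with 100 meaning the taxon
  occurs at every sample of one cluster and nowhere else.

Significance is assessed by permuting sample labels and comparing each
taxon's maximum-over-clusters IndVal to its permutation null. A taxon is
selected as an indicator of its maximizing cluster when IndVal > 25 and
p < 0.05 (both thresholds configurable; the IndVal inequality is strict).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import CommunityMatrix

__all__ = ["indval", "indval_significance", "select_indicators", "indicator_analysis"]


def _as_arrays(m: CommunityMatrix | np.ndarray, labels):
    if isinstance(m, CommunityMatrix):
        if m.transformed:
            raise ValueError("IndVal requires raw (untransformed) abundances")
        X = m.counts
        taxa = list(m.taxon_ids)
        if isinstance(labels, (pd.Series, dict)):
            lab = np.asarray([labels[s] for s in m.sample_ids])
        else:
            lab = np.asarray(labels)
    else:
        X = np.asarray(m, dtype=float)
        taxa = [f"t{j}" for j in range(X.shape[1])]
        lab = np.asarray(labels)
    if lab.shape[0] != X.shape[0]:
        raise ValueError("labels must cover every sample")
    return X, taxa, lab


def _indval_components(X: np.ndarray, codes: np.ndarray, k: int):
    """Return (A, B, IV) arrays of shape clusters × taxa."""
    means = np.stack([X[codes == c].mean(axis=0) for c in range(k)])
    col = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(col > 0, means / np.where(col > 0, col, 1.0), 0.0)
    B = np.stack([(X[codes == c] > 0).mean(axis=0) for c in range(k)])
    return A, B, 100.0 * A * B


def indval(m: CommunityMatrix | np.ndarray, labels) -> pd.DataFrame:
    """Per taxon × cluster IndVal table (columns: taxon, cluster, A, B,
    indval, is_max).

    ``is_max`` flags each taxon's maximizing cluster (ties broken toward the
    lowest cluster index). Taxa absent everywhere get all-zero rows with a
    warning.
    """
    X, taxa, lab = _as_arrays(m, labels)
    uniq, codes = np.unique(lab, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("IndVal needs at least 2 clusters")
    A, B, IV = _indval_components(X, codes, len(uniq))

    absent = X.sum(axis=0) == 0
    if absent.any():
        warnings.warn(
            f"{absent.sum()} taxa absent from every sample have all-zero IndVal",
            stacklevel=2,
        )

    best = IV.argmax(axis=0)  # argmax returns the first (lowest) on ties
    rows = []
    for j, t in enumerate(taxa):
        for c, cname in enumerate(uniq):
            rows.append(
                {
                    "taxon": t,
                    "cluster": cname,
                    "A": float(A[c, j]),
                    "B": float(B[c, j]),
                    "indval": float(IV[c, j]),
                    "is_max": bool(c == best[j]) and not absent[j],
                }
            )
    return pd.DataFrame(rows)


def indval_significance(
    m: CommunityMatrix | np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.Series:
    """Permutation p-value per taxon for its maximum-over-clusters IndVal.

    p = (1 + #{max IndVal under permuted labels ≥ observed max}) /
    (n_perm + 1); one shared label permutation per iteration for all taxa.
    """
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is small for stable p-values", stacklevel=2)
    X, taxa, lab = _as_arrays(m, labels)
    uniq, codes = np.unique(lab, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("IndVal needs at least 2 clusters")
    _, _, IV = _indval_components(X, codes, k)
    obs = IV.max(axis=0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(X.shape[1], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        _, _, IVp = _indval_components(X, perm, k)
        exceed += IVp.max(axis=0) >= obs - 1e-12
    p = (1 + exceed) / (n_perm + 1)
    return pd.Series(p, index=taxa, name="p")


def select_indicators(
    table: pd.DataFrame,
    p: pd.Series,
    threshold: float = 25.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the indicator selection rule: IndVal strictly above ``threshold``
    and permutation p below ``alpha``, evaluated only at each taxon's
    maximizing cluster."""
    out = table.copy()
    out["p"] = out["taxon"].map(p)
    out["selected"] = (
        out["is_max"] & (out["indval"] > threshold) & (out["p"] < alpha)
    )
    return out


def indicator_analysis(
    m: CommunityMatrix | np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int = 0,
    threshold: float = 25.0,
    alpha: float = 0.05,
    traits=None,
) -> pd.DataFrame:
    """Full IndVal workflow; returns the selected-indicator table ordered by
    cluster then descending IndVal, with order/family columns when traits
    are given."""
    table = indval(m, labels)
    p = indval_significance(m, labels, n_perm=n_perm, seed=seed)
    table = select_indicators(table, p, threshold=threshold, alpha=alpha)
    if traits is not None:
        table["order_name"] = traits.order_of(table["taxon"]).to_numpy()
        table["family_name"] = (
            traits.data["family_name"].reindex(table["taxon"]).fillna("").to_numpy()
        )
    return table.sort_values(
        ["cluster", "indval"], ascending=[True, False]
    ).reset_index(drop=True)
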