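"""Between-cluster tests: MRPP, Kruskal–Wallis and Dunn's posthoc.

MRPP (multi-response permutation procedure) tests whether community
composition differs among a priori groups. The observed statistic is the
group-size-weighted mean within-group pairwise distance
δ = Σᵢ (nᵢ/N)·ξᵢ; significance comes from permuting group labels, and the
chance-corrected within-group agreement is A = 1 − δ/E(δ), with E(δ) the
permutation mean. A = 1 means all within-group distances are zero; A ≈ 0
means the grouping is no tighter than chance.

Univariate index/covariate comparisons use the tie-corrected Kruskal–Wallis
test followed by Dunn's pairwise z tests, summarized with a compact letter
display (groups sharing no letter differ significantly).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .io import CommunityMatrix

__all__ = [
    "MrppResult",
    "KwDunnResult",
    "mrpp",
    "kruskal_wallis",
    "dunn_posthoc",
    "compare_variables",
]

_DISTANCES = {"euclidean": "euclidean", "bray_curtis": "braycurtis"}


@dataclass(frozen=True)
class MrppResult:
    A: float
    delta_obs: float
    expected_delta: float
    p: float
    n_perm: int
    distance_name: str


def _weighted_delta(D: np.ndarray, codes: np.ndarray, group_sizes: np.ndarray) -> float:
    """δ = Σ (nᵢ/N)·(mean pairwise within-group distance)."""
    total = 0.0
    N = codes.shape[0]
    for g, n_g in enumerate(group_sizes):
        idx = np.nonzero(codes == g)[0]
        sub = D[np.ix_(idx, idx)]
        xi = sub[np.triu_indices(n_g, k=1)].mean()
        total += (n_g / N) * xi
    return total


def mrpp(
    m: CommunityMatrix | np.ndarray,
    labels,
    distance: str = "euclidean",
    n_perm: int = 999,
    seed: int = 0,
) -> MrppResult:
    """Multi-response permutation procedure with Cᵢ = nᵢ/N group weights.

    p = (1 + #{δ_perm ≤ δ_obs}) / (n_perm + 1). Requires ≥2 groups of ≥2
    samples each.
    """
    if distance not in _DISTANCES:
        raise ValueError(f"unknown distance {distance!r}; use {sorted(_DISTANCES)}")
    X = m.counts if isinstance(m, CommunityMatrix) else np.asarray(m, dtype=float)
    lab = np.asarray(
        [labels[s] for s in m.sample_ids] if isinstance(m, CommunityMatrix)
        and not isinstance(labels, (np.ndarray, list, tuple))
        else labels
    )
    uniq, codes = np.unique(lab, return_inverse=True)
    sizes = np.bincount(codes)
    if len(uniq) < 2:
        raise ValueError("MRPP needs at least 2 groups")
    if (sizes < 2).any():
        small = [str(uniq[i]) for i in np.nonzero(sizes < 2)[0]]
        raise ValueError(f"singleton group(s) not allowed: {small}")

    D = squareform(pdist(X, metric=_DISTANCES[distance]))
    delta_obs = _weighted_delta(D, codes, sizes)

    rng = np.random.default_rng(seed)
    perm_deltas = np.empty(n_perm)
    for i in range(n_perm):
        perm_deltas[i] = _weighted_delta(D, rng.permutation(codes), sizes)
    expected = float(perm_deltas.mean())
    p = float((1 + (perm_deltas <= delta_obs + 1e-12).sum()) / (n_perm + 1))
    A = 1.0 - delta_obs / expected if expected > 0 else 0.0
    return MrppResult(
        A=float(A),
        delta_obs=float(delta_obs),
        expected_delta=expected,
        p=p,
        n_perm=n_perm,
        distance_name=distance,
    )


def _groups(values, labels):
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if v.shape[0] != lab.shape[0]:
        raise ValueError("values and labels must have equal length")
    uniq = np.unique(lab)
    return v, lab, uniq


def kruskal_wallis(values, labels) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H with its chi-square p (df = k − 1).

    All-tied input yields H = 0, p = 1 with a warning.
    """
    v, lab, uniq = _groups(values, labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if np.all(v == v[0]):
        warnings.warn("all values identical; H = 0, p = 1", stacklevel=2)
        return 0.0, len(uniq) - 1, 1.0
    groups = [v[lab == u] for u in uniq]
    H, p = stats.kruskal(*groups)
    return float(H), len(uniq) - 1, float(p)


@dataclass(frozen=True)
class KwDunnResult:
    H: float
    df: int
    p: float
    pairwise: pd.DataFrame          # group_i, group_j, z, p, p_adj
    letters: dict = field(default_factory=dict)
    alpha: float = 0.05


def _compact_letters(groups, sig_pairs: set, alpha: float) -> dict:
    """Letters via maximal cliques of the non-significance graph.

    Two groups share a letter iff they are NOT significantly different, which
    holds exactly when they co-occur in some maximal clique of the graph
    whose edges are the non-significant pairs.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for a, b in itertools.combinations(groups, 2):
        if frozenset((a, b)) not in sig_pairs:
            g.add_edge(a, b)
    order = {grp: i for i, grp in enumerate(groups)}
    cliques = sorted(
        (sorted(c, key=order.get) for c in nx.find_cliques(g)),
        key=lambda c: [order[x] for x in c],
    )
    letters = {grp: "" for grp in groups}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i) if i < 26 else f"z{i}"
        for grp in clique:
            letters[grp] += ch
    return letters


def dunn_posthoc(
    values,
    labels,
    alpha: float = 0.05,
    adjust: str = "none",
) -> KwDunnResult:
    """Dunn's pairwise rank comparisons after Kruskal–Wallis.

    z_ij = (R̄ᵢ − R̄ⱼ) / √[(N(N+1)/12 − T/(12(N−1)))·(1/nᵢ + 1/nⱼ)] with the
    tie term T = Σ(t³ − t); two-sided normal p-values, optionally Holm- or
    Bonferroni-adjusted. Letters summarize the adjusted significance graph.
    """
    if adjust not in ("none", "holm", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    H, df, p_global = kruskal_wallis(values, labels)
    v, lab, uniq = _groups(values, labels)
    N = len(v)
    r = stats.rankdata(v)
    mean_rank = {u: r[lab == u].mean() for u in uniq}
    n = {u: int((lab == u).sum()) for u in uniq}
    _, t_counts = np.unique(v, return_counts=True)
    tie_term = float(((t_counts**3 - t_counts).sum()) / (12.0 * (N - 1)))
    var_base = N * (N + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(uniq, 2):
        se = np.sqrt(var_base * (1.0 / n[a] + 1.0 / n[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        pz = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, float(z), float(pz)))
    pw = pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p"])
    if adjust == "none" or pw.empty:
        pw["p_adj"] = pw["p"]
    else:
        pw["p_adj"] = multipletests(pw["p"].to_numpy(), method=adjust)[1]

    sig = {
        frozenset((a, b))
        for a, b, padj in zip(pw["group_i"], pw["group_j"], pw["p_adj"])
        if padj < alpha
    }
    letters = _compact_letters(list(uniq), sig, alpha)
    return KwDunnResult(
        H=H, df=df, p=p_global, pairwise=pw, letters=letters, alpha=alpha
    )


def compare_variables(
    table: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    adjust: str = "none",
) -> pd.DataFrame:
    """KW + Dunn letters for every numeric column of ``table``.

    Returns a long-format frame (variable, cluster, mean, sd, letter, kw_H,
    kw_p) mirroring the mean (sd) + letter presentation used in
    bioassessment cluster comparisons. Constant variables get H = 0, p = 1
    and a shared letter.
    """
    lab = labels.reindex(table.index)
    if lab.isna().any():
        raise ValueError("labels missing for some samples")
    rows = []
    for var in table.columns:
        vals = table[var].to_numpy(dtype=float)
        res = dunn_posthoc(vals, lab.to_numpy(), alpha=alpha, adjust=adjust)
        for grp in np.unique(lab.to_numpy()):
            sel = (lab == grp).to_numpy()
            rows.append(
                {
                    "variable": var,
                    "cluster": grp,
                    "mean": float(vals[sel].mean()),
                    "sd": float(vals[sel].std(ddof=1)) if sel.sum() > 1 else 0.0,
                    "letter": res.letters[grp],
                    "kw_H": res.H,
                    "kw_p": res.p,
                }
            )
    return pd.DataFrame(rows)
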