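"""End-to-end orchestration: ingest → preprocess → metrics → network →
SOM/clusters → MRPP/KW/Dunn → IndVal, as one reproducible, seeded run.

A single global seed fans out to per-stage child seeds (stage name hashed
into the seed), so each stage is independently reproducible and inserting a
stage never silently changes another stage's random stream.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from . import metrics as bmetrics
from . import network as bnet
from . import som as bsom
from . import group_tests as bgt
from . import indicators as bind
from .synthetic import SyntheticDataset, generate_mining_gradient

__all__ = ["RunConfig", "ReportBundle", "validate_config", "run_pipeline", "child_seed"]


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Every knob of a pipeline run, serializable for provenance."""

    matrix_path: str | None = None
    traits_path: str | None = None
    sites_path: str | None = None
    orientation: str = "rows_are_samples"
    replicate_map_path: str | None = None
    area_m2: float | None = None
    # demo fallback when no matrix_path is given
    demo_n_sites: int = 8
    # preprocessing
    log_base: float = 10.0
    min_occurrences: int = 2
    # network edge rule
    alpha: float = 0.05
    min_abs_rho: float = 0.0
    signed: str = "both"
    # SOM / clustering
    grid_rows: int | None = None
    grid_cols: int | None = None
    lattice: str = "hexagonal"
    k_min: int = 2
    k_max: int = 10
    kmeans_restarts: int = 100
    # tests
    mrpp_distance: str = "euclidean"
    n_perm: int = 999
    dunn_adjust: str = "none"
    test_alpha: float = 0.05
    # indicators
    indval_threshold: float = 25.0
    indval_alpha: float = 0.05
    seed: int = 0


@dataclass
class ReportBundle:
    """All pipeline outputs plus a provenance block."""

    indices: pd.DataFrame
    ffg: pd.DataFrame
    network_summary: pd.DataFrame
    cluster_assignments: pd.DataFrame
    db_by_k: pd.DataFrame
    mrpp: bgt.MrppResult
    comparisons: pd.DataFrame
    indicators: pd.DataFrame
    provenance: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "indices": self.indices,
            "ffg": self.ffg,
            "network_summary": self.network_summary,
            "cluster_assignments": self.cluster_assignments,
            "db_by_k": self.db_by_k,
            "comparisons": self.comparisons,
            "indicators": self.indicators,
        }

    def content_hash(self) -> str:
        """Stable hash over every numeric table (for determinism checks)."""
        h = 0
        for name in sorted(self.tables()):
            df = self.tables()[name]
            h ^= int(
                pd.util.hash_pandas_object(
                    df.round(12).astype(str), index=True
                ).sum()
            )
        return f"{h & 0xFFFFFFFFFFFFFFFF:016x}"

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(out / f"{name}.csv", index=True)
        prov = dict(self.provenance)
        prov["mrpp"] = asdict(self.mrpp)
        (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of human-readable problems; empty iff runnable."""
    problems = []
    if not 0 < config.alpha <= 1:
        problems.append("alpha must lie in (0, 1]")
    if not 0 < config.test_alpha < 1:
        problems.append("test_alpha must lie in (0, 1)")
    if not 0 < config.indval_alpha < 1:
        problems.append("indval_alpha must lie in (0, 1)")
    if config.log_base <= 0 or config.log_base == 1:
        problems.append("log_base must be positive and != 1")
    if config.min_occurrences < 1:
        problems.append("min_occurrences must be >= 1")
    if config.k_min < 2:
        problems.append("k_min must be >= 2")
    if config.k_max < config.k_min:
        problems.append("k_max must be >= k_min")
    if (config.grid_rows is None) != (config.grid_cols is None):
        problems.append("grid_rows and grid_cols must be given together")
    if config.grid_rows is not None:
        units = config.grid_rows * config.grid_cols
        if units < 2:
            problems.append("grid must have at least 2 units")
        if config.k_max >= units:
            problems.append("k_max must be smaller than the number of grid units")
    if config.n_perm < 1:
        problems.append("n_perm must be >= 1")
    if config.signed not in ("both", "positive_only"):
        problems.append("signed must be 'both' or 'positive_only'")
    if config.mrpp_distance not in ("euclidean", "bray_curtis"):
        problems.append("mrpp_distance must be 'euclidean' or 'bray_curtis'")
    if config.dunn_adjust not in ("none", "holm", "bonferroni"):
        problems.append("dunn_adjust must be 'none', 'holm' or 'bonferroni'")
    if config.orientation not in ("rows_are_samples", "rows_are_taxa"):
        problems.append("orientation must be 'rows_are_samples' or 'rows_are_taxa'")
    if config.indval_threshold < 0 or config.indval_threshold >= 100:
        problems.append("indval_threshold must lie in [0, 100)")
    if config.demo_n_sites < 6:
        problems.append("demo_n_sites must be >= 6")
    return problems


def _ingest(config: RunConfig) -> tuple[bio.CommunityMatrix, bio.TaxonTable | None, dict]:
    if config.matrix_path is not None:
        m = bio.read_community_matrix(config.matrix_path, config.orientation)
        traits = (
            bio.read_taxon_table(config.traits_path) if config.traits_path else None
        )
        if config.replicate_map_path:
            rep = pd.read_csv(config.replicate_map_path, index_col=0).iloc[:, 0]
            m = bio.pool_replicates(m, rep.to_dict(), area_m2=config.area_m2)
        src = {"source": "file", "matrix_path": str(config.matrix_path)}
    else:
        ds = generate_mining_gradient(
            n_sites=config.demo_n_sites, seed=child_seed(config.seed, "simulate")
        )
        m, traits = ds.matrix, ds.traits
        src = {"source": "demo_mining_gradient", "n_sites": config.demo_n_sites}
    return m, traits, src


def run_pipeline(
    config: RunConfig,
    dataset: SyntheticDataset | None = None,
) -> ReportBundle:
    """Execute all stages in order; identical config + seed gives an
    identical bundle. ``dataset`` (an in-memory synthetic dataset) bypasses
    file ingestion."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    log: list[dict] = []

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 4), **info})

        return done

    try:
        d = stage("ingest")
        if dataset is not None:
            raw, traits, src = dataset.matrix, dataset.traits, {"source": "in_memory"}
        else:
            raw, traits, src = _ingest(config)
        d(samples=raw.n_samples, taxa=raw.n_taxa, **src)

        d = stage("preprocess")
        filtered = bio.drop_rare_taxa(raw, config.min_occurrences)
        transformed = bio.log_transform(filtered, base=config.log_base)
        d(taxa_dropped=len(filtered.dropped_taxa), taxa_kept=filtered.n_taxa,
          log_base=config.log_base)

        d = stage("metrics")
        idx_table = bmetrics.indices_table(filtered, traits)
        ffg_tab = (
            bmetrics.ffg_table(filtered, traits) if traits is not None
            else pd.DataFrame()
        )
        d(index_columns=idx_table.shape[1])

        d = stage("network")
        corr = bnet.spearman_matrix(filtered)
        net = bnet.build_network(
            corr, alpha=config.alpha, min_abs_rho=config.min_abs_rho,
            signed=config.signed,
        )
        net_summary = pd.DataFrame(
            [bnet.network_summary(net).as_dict()], index=["all_samples"]
        )
        net_summary.index.name = "group"
        d(edges=int(net_summary["n_edges"].iloc[0]), **net.edge_rule)

        d = stage("som")
        if config.grid_rows is not None:
            grid = bsom.GridSpec(config.grid_rows, config.grid_cols, config.lattice)
        else:
            grid = bsom.map_size(filtered.n_samples, data=transformed)
            grid = bsom.GridSpec(grid.n_rows, grid.n_cols, config.lattice)
        model = bsom.train_som(
            transformed, grid, seed=child_seed(config.seed, "som")
        )
        k_max = min(config.k_max, grid.n_units - 1)
        part = bsom.cluster_units(
            model,
            k_range=range(config.k_min, k_max + 1),
            restarts=config.kmeans_restarts,
            seed=child_seed(config.seed, "kmeans"),
        )
        assignments = pd.DataFrame(
            {
                "cluster": part.sample_labels,
                "bmu": model.bmu,
            }
        )
        assignments.index.name = "sample_id"
        db_tab = pd.DataFrame(
            sorted(part.db_by_k.items()), columns=["k", "davies_bouldin"]
        ).set_index("k")
        d(grid=f"{grid.n_rows}x{grid.n_cols}", chosen_k=part.k,
          qe=round(bsom.quantization_error(model, transformed), 6))

        d = stage("group_tests")
        sizes = part.sample_labels.value_counts()
        if (sizes < 2).any():
            # MRPP is undefined with singleton clusters; report NaN, keep going
            mrpp_res = bgt.MrppResult(
                A=float("nan"), delta_obs=float("nan"),
                expected_delta=float("nan"), p=float("nan"),
                n_perm=0, distance_name=config.mrpp_distance,
            )
        else:
            mrpp_res = bgt.mrpp(
                transformed,
                part.sample_labels,
                distance=config.mrpp_distance,
                n_perm=config.n_perm,
                seed=child_seed(config.seed, "mrpp"),
            )
        comparisons = bgt.compare_variables(
            idx_table,
            part.sample_labels,
            alpha=config.test_alpha,
            adjust=config.dunn_adjust,
        )
        d(mrpp_A=round(mrpp_res.A, 4), mrpp_p=mrpp_res.p)

        d = stage("indicators")
        ind_table = bind.indicator_analysis(
            filtered,
            part.sample_labels,
            n_perm=config.n_perm,
            seed=child_seed(config.seed, "indval"),
            threshold=config.indval_threshold,
            alpha=config.indval_alpha,
            traits=traits,
        )
        d(selected=int(ind_table["selected"].sum()))
    except Exception as exc:  # annotate which stage failed
        failed = "ingest" if not log else f"after {log[-1]['stage']}"
        raise RuntimeError(f"[pipeline stage {failed}] {exc}") from exc

    provenance = {
        "config": asdict(config),
        "seed": config.seed,
        "dropped_taxa": list(filtered.dropped_taxa),
        "n_taxa_dropped": len(filtered.dropped_taxa),
        "edge_rule": net.edge_rule,
        "grid": {"rows": grid.n_rows, "cols": grid.n_cols, "lattice": grid.lattice},
        "chosen_k": part.k,
        "index_formulas": {
            "shannon": "H = -sum p_i ln p_i (natural log)",
            "dominance": "McNaughton (n1+n2)/N",
            "richness_index": "Margalef (S-1)/ln N",
            "evenness": "Pielou H/ln S",
        },
        "stages": log,
    }
    return ReportBundle(
        indices=idx_table,
        ffg=ffg_tab,
        network_summary=net_summary,
        cluster_assignments=assignments,
        db_by_k=db_tab,
        mrpp=mrpp_res,
        comparisons=comparisons,
        indicators=ind_table,
        provenance=provenance,
    )
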