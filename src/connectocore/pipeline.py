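"""One-command orchestration of the full analysis with a structured report.

``run_pipeline`` executes io -> nulls -> global topology -> communities ->
hubs -> motifs -> homology on a single input matrix and writes a JSON
summary plus per-stage CSV outputs.  All stochastic stages are seeded
deterministically from one master seed, so the same config reproduces the
same bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import communities, global_topology, homology, hubs, motifs, nulls
from .io import ConnectomeGraph, load_connectome, weight_to_length

__all__ = ["AnalysisConfig", "run_pipeline", "PipelineError"]

SUMMARY_SCHEMA_VERSION = 1

log = logging.getLogger("connectocore.pipeline")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class AnalysisConfig:
    """Configuration for one pipeline run; round-trips losslessly via JSON."""

    weights_path: str
    coords_path: Optional[str] = None
    pairwise_complete: bool = True
    n_nulls_global: int = 1000
    n_nulls_motifs: int = 100
    n_nulls_homology: int = 100
    swaps_per_edge: int = 10
    gamma_grid: Sequence[float] = field(
        default_factory=lambda: [round(g, 2) for g in np.arange(0.5, 2.2001, 0.1)]
    )
    louvain_runs: int = 1000
    consensus_tau: float = 0.4
    rich_club_keep_geq: bool = False
    homology_max_dim: int = 3
    homology_top_m: int = 5
    path_mean_rule: str = "arithmetic"
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))


def _stage_seeds(master: int) -> dict:
    names = ["nulls_global", "nulls_motifs", "nulls_homology", "communities"]
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0]) for n, c in zip(names, children)}


def run_pipeline(config: AnalysisConfig, out_dir) -> dict:
    """Run every analysis stage and write the report bundle to ``out_dir``.

    Returns the summary dictionary (also written to ``summary.json``).  A
    stage failure raises :class:`PipelineError`; outputs of completed
    stages remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION, "seed": config.seed}

    def _write_summary() -> None:
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    stage = "io"
    try:
        g = load_connectome(
            config.weights_path, config.coords_path, config.pairwise_complete
        )
        summary["n_nodes"] = g.n_nodes
        summary["n_edges"] = g.n_edges
        log.info("loaded %d nodes, %d edges", g.n_nodes, g.n_edges)

        stage = "nulls"
        ens_global = nulls.build_ensemble(
            g, config.n_nulls_global, config.swaps_per_edge, seeds["nulls_global"]
        )
        ens_motifs = nulls.build_ensemble(
            g, config.n_nulls_motifs, config.swaps_per_edge, seeds["nulls_motifs"]
        )
        ens_homology = nulls.build_ensemble(
            g, config.n_nulls_homology, config.swaps_per_edge, seeds["nulls_homology"]
        )
        log.info("null ensembles built (%d/%d/%d members)",
                 ens_global.n_members, ens_motifs.n_members, ens_homology.n_members)

        stage = "global_topology"
        gm = global_topology.global_metrics(g, config.path_mean_rule)
        sw = global_topology.small_world(g, ens_global, config.path_mean_rule)
        summary["global"] = {
            "density_directed": gm.density_directed,
            "density_undirected": gm.density_undirected,
            "reciprocity": gm.reciprocity,
            "assortativity_degree": gm.assortativity_degree,
            "assortativity_strength": gm.assortativity_strength,
            "clustering_mean": gm.clustering_mean,
            "char_path_length": gm.char_path_length,
            "gamma_norm": sw.gamma_norm,
            "lambda_norm": sw.lambda_norm,
            "sigma": sw.sigma,
        }
        pd.DataFrame(
            {"null_clustering": sw.null_clustering, "null_path_length": sw.null_path_length}
        ).to_csv(out / "null_global_distributions.csv", index=False)
        _write_summary()

        stage = "communities"
        sweep = communities.resolution_sweep(
            g,
            config.gamma_grid,
            n_runs=config.louvain_runs,
            tau=config.consensus_tau,
            seed=seeds["communities"],
        )
        labels_df = pd.DataFrame(
            {f"gamma_{gam:g}": res.partition.labels for gam, res in zip(sweep.gammas, sweep.results)},
            index=g.labels,
        )
        labels_df.to_csv(out / "community_labels.csv")
        pd.DataFrame(sweep.nmi_matrix, index=sweep.gammas, columns=sweep.gammas).to_csv(
            out / "community_nmi.csv"
        )
        summary["communities"] = {
            "gammas": sweep.gammas.tolist(),
            "n_communities": [r.partition.n_communities for r in sweep.results],
            "quality": [r.partition.quality for r in sweep.results],
            "selected_gammas": sweep.selected_gammas,
            "selected_n_communities": [
                sweep.results[i].partition.n_communities for i in sweep.selected_indices
            ],
        }
        _write_summary()

        stage = "hubs"
        partitions = [r.partition.labels for r in sweep.results]
        rank_in, rank_out = hubs.participation_rank_profile(g, partitions)
        ratio, total, ratio_corr, valid = hubs.strength_ratio(g)
        rc = hubs.rich_club(g, ens_global, config.rich_club_keep_geq)
        node_df = pd.DataFrame(
            {
                "label": g.labels,
                "mean_rank_participation_in": rank_in,
                "mean_rank_participation_out": rank_out,
                "out_in_strength_ratio": ratio,
                "total_strength": total,
            }
        )
        node_df.to_csv(out / "node_hub_profile.csv", index=False)
        pd.DataFrame(
            {
                "k": rc.k_levels,
                "phi": rc.phi,
                "phi_norm": rc.phi_norm,
                "p_value": rc.p_values,
                "survivors": rc.survivors,
            }
        ).to_csv(out / "rich_club_curve.csv", index=False)
        regime = rc.significant_regime
        summary["hubs"] = {
            "strength_ratio_corr": ratio_corr,
            "rich_club_regime": None if regime is None else list(regime),
        }
        _write_summary()

        stage = "motifs"
        spec = motifs.motif_significance(g, ens_motifs)
        pd.DataFrame(
            {
                "motif_class": np.arange(1, motifs.N_MOTIF3_CLASSES + 1),
                "count": spec.class_count,
                "null_median": np.median(spec.null_counts, axis=1),
                "p_two_tailed": spec.p_two_tailed,
                "direction": spec.direction,
            }
        ).to_csv(out / "motif_spectrum.csv", index=False)
        summary["motifs"] = {
            "counts": spec.class_count.tolist(),
            "p_two_tailed": spec.p_two_tailed.tolist(),
            "enriched": [i + 1 for i, d in enumerate(spec.direction) if d == "enriched"],
            "depleted": [i + 1 for i, d in enumerate(spec.direction) if d == "depleted"],
        }
        _write_summary()

        stage = "homology"
        cav = homology.cavity_significance(
            g,
            ens_homology,
            top_m=config.homology_top_m,
            max_dim=config.homology_max_dim,
        )
        rows = []
        for dim, rep in cav.items():
            for bar in rep.top_bars:
                rows.append({**bar, "nodes": "|".join(bar["nodes"])})
        pd.DataFrame(rows).to_csv(out / "cavity_top_bars.csv", index=False)
        summary["homology"] = {
            str(dim): {
                "n_bars": rep.n_bars,
                "n_long_bars": rep.n_long_bars,
                "p_count": rep.p_count,
                "p_longest": rep.p_longest,
                "longest_lifetime": rep.longest_lifetime,
                "top_bars": rep.top_bars,
            }
            for dim, rep in cav.items()
        }
        _write_summary()
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - tag stage and re-raise
        _write_summary()
        raise PipelineError(stage, exc) from exc

    return summary
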