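"""End-to-end orchestration: simulate -> preprocess -> FPCA -> cluster.

Every stochastic stage draws its own child seed from one pipeline seed
(via numpy SeedSequence), so a fixed configuration reproduces the whole
run bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from engagetraj import clustering, fpca, preprocess, synth

logger = logging.getLogger("engagetraj")


@dataclass
class PipelineConfig:
    """Tunable knobs of the clustering pipeline, with published defaults:
    7-day presmoothing, 90% FPCA variance, candidate k in {2, 3} (the set
    the published analysis examined), prediction-strength threshold 0.6,
    minimum group share 5%."""

    seed: int = 0
    window: int = 7
    fpca_threshold: float = 0.90
    fpca_bandwidth: float = 7.0
    k_min: int = 2
    k_max: int = 3
    ps_threshold: float = 0.6
    min_group_frac: float = 0.05
    n_splits: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.fpca_threshold <= 1:
            raise ValueError("fpca_threshold must lie in (0, 1]")
        if not 0 <= self.ps_threshold <= 1:
            raise ValueError("ps_threshold must lie in [0, 1]")
        if not 0 <= self.min_group_frac < 1:
            raise ValueError("min_group_frac must lie in [0, 1)")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    matrix: preprocess.DailyEngagementMatrix
    smoothed: preprocess.SmoothedTrajectoryMatrix
    fpc: fpca.FPCModel
    selection: clustering.SelectKResult
    solution: clustering.ClusterSolution

    def group_shares_by_persistence(self) -> np.ndarray:
        """Group shares ordered least -> most persistent."""
        order = self.solution.groups_by_persistence()
        return self.solution.group_sizes[order] / self.solution.n


def run_cluster_pipeline(
    matrix: preprocess.DailyEngagementMatrix, config: PipelineConfig
) -> PipelineResult:
    """binarized matrix -> presmooth -> FPCA -> select k -> CLARA -> name."""
    ss = np.random.SeedSequence(config.seed)
    seed_select, seed_final = [int(s.generate_state(1)[0] % (2**31 - 1))
                               for s in ss.spawn(2)]
    logger.info("clustering %d participants (%d excluded as zero-log-in)",
                matrix.n, len(matrix.excluded_ids))
    smoothed = preprocess.presmooth(matrix, config.window)
    fpc = fpca.fit_fpca(smoothed, config.fpca_threshold, config.fpca_bandwidth)
    logger.info("FPCA retained %d components (%.1f%% variance)",
                fpc.n_components, 100 * fpc.pct_variance.sum())
    selection = clustering.select_k(
        fpc.scores,
        k_range=range(config.k_min, config.k_max + 1),
        ps_threshold=config.ps_threshold,
        min_group_frac=config.min_group_frac,
        n_splits=config.n_splits,
        rng=seed_select,
    )
    logger.info("selected k=%d (prediction strengths: %s)",
                selection.chosen_k,
                {k: round(v, 3) for k, v in selection.prediction_strengths.items()})
    solution = clustering.solve(fpc.scores, selection.chosen_k, rng=seed_final)
    solution.prediction_strength = selection.prediction_strengths[selection.chosen_k]
    clustering.name_groups(solution, matrix)
    return PipelineResult(matrix, smoothed, fpc, selection, solution)


def run_preset_pipeline(
    preset: str, n: int, seed: int, config: PipelineConfig | None = None
) -> tuple[list[synth.ParticipantRecord], PipelineResult]:
    """Simulate a preset cohort and cluster it (convenience wrapper)."""
    cohort_cfg = synth.CohortConfig(
        n=n, seed=seed, archetypes=synth.archetype_library(preset), arm_label=preset
    )
    records = synth.generate_cohort(cohort_cfg)
    matrix = preprocess.matrix_from_records(records)
    config = config or PipelineConfig(seed=seed + 1)
    return records, run_cluster_pipeline(matrix, config)


def _header(config_hash: str) -> str:
    return f"# engagetraj config_hash={config_hash}\n"


def write_csv_with_header(df: pd.DataFrame, path: str | Path, config_hash: str) -> None:
    """CSV with a one-line config-hash comment header (audit trail)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        df.to_csv(fh, index=False)


def write_cluster_outputs(
    result: PipelineResult, outdir: str | Path, config: PipelineConfig
) -> None:
    """Persist assignments, group summaries and the FPC bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    sol = result.solution
    assignments = pd.DataFrame(
        {
            "participant_id": result.matrix.participant_ids,
            "group_index": sol.labels,
            "group_name": [sol.group_names[g] for g in sol.labels],
        }
    )
    write_csv_with_header(assignments, outdir / "assignments.csv", h)
    summary = pd.DataFrame(
        sol.group_weekly_means,
        columns=[f"week{w}" for w in range(1, synth.N_WEEKS + 1)],
    )
    summary.insert(0, "group_name", sol.group_names)
    summary.insert(1, "size", sol.group_sizes)
    summary.insert(2, "share", sol.group_sizes / sol.n)
    write_csv_with_header(summary, outdir / "group_summary.csv", h)
    result.fpc.save(outdir / "fpc_model")
    diag = pd.DataFrame(
        {
            "k": list(result.selection.prediction_strengths),
            "prediction_strength": list(result.selection.prediction_strengths.values()),
            "min_group_size": [int(result.selection.group_sizes[k].min())
                               for k in result.selection.prediction_strengths],
            "separation": [result.selection.separations[k]
                           for k in result.selection.prediction_strengths],
        }
    )
    diag["chosen"] = diag["k"] == result.selection.chosen_k
    write_csv_with_header(diag, outdir / "k_selection.csv", h)


def load_assignments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
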