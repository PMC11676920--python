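"""End-to-end orchestration: configuration, scenario dispatch, results.

``run_pipeline`` executes the whole analysis on a prepared study:
embeddings (one per dendrogram depth), the stratification sweep, bootstrap
stability filtering, Jaccard grouping, and representative selection. All
randomness is derived from ``RunConfig.seed`` through per-task seed
streams, so the result is identical for any worker count.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .consensus import (
    build_jaccard_matrix,
    filter_robust,
    group_and_represent,
    make_embedding_reclusterer,
)
from .engine import run_stratification_process
from .imputation import make_consensus_reclusterer, run_missing_pipeline
from .reduction import build_variable_dendrogram, compute_embeddings, standardize

__all__ = ["RunConfig", "RunResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Hyper-parameters of one run (defaults follow the method's contract)."""

    k_min: int = 2
    k_max: int = 6
    max_depth: int | None = None  # None -> V - 2
    depths: list | None = None  # subset of depths for exploratory runs
    combos: str = "abcd"
    stability_threshold: float = 0.85
    jaccard_threshold: float = 0.7
    n_boot: int = 100
    kmeans_restarts: int = 25
    var_target: float | None = None  # None -> 1 PC per variable group
    stability_summary: str = "min"
    min_group_size: int = 2
    workers: int = 1
    seed: int = 0

    def validate(self):
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        for name in ("stability_threshold", "jaccard_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


@dataclass
class RunResult:
    """Everything a run produced, re-groupable without re-clustering."""

    config: RunConfig
    scenario: str
    samples: list
    n_embeddings: int
    candidates: list  # all candidates, stability filled in where scored
    robust_names: list
    jaccard: object | None  # JaccardMatrix over robust candidates
    groups: list  # StratificationGroup, multi-member by default
    stability: pd.DataFrame | None

    # -- tables -----------------------------------------------------------
    def candidates_table(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            rows.append(
                {
                    "name": c.name,
                    "depth": c.depth,
                    "combo": c.code,
                    "distance": c.distance,
                    "method": c.method,
                    "k": c.k,
                    "stability": c.stability,
                    "robust": c.name in self.robust_names,
                    "error": c.error,
                }
            )
        return pd.DataFrame(rows)

    def assignments_table(self) -> pd.DataFrame:
        data = {
            c.name: np.asarray(c.assignment) + 1
            for c in self.candidates
            if not c.failed
        }
        return pd.DataFrame(data, index=self.samples)

    def candidate(self, name: str):
        for c in self.candidates:
            if c.name == name:
                return c
        raise KeyError(f"unknown stratification {name!r}")

    # -- regrouping -------------------------------------------------------
    def regroup(self, threshold: float, min_size: int | None = None) -> list:
        """Re-run only the Jaccard grouping at a new threshold."""
        if self.jaccard is None:
            return []
        if min_size is None:
            min_size = self.config.min_group_size
        return group_and_represent(self.jaccard, threshold=threshold, min_size=min_size)

    # -- reproducibility --------------------------------------------------
    def digest(self) -> str:
        """SHA-256 over the canonical serialisation of the run outcome."""
        payload = {
            "scenario": self.scenario,
            "candidates": {
                c.name: {
                    "k": c.k,
                    "assignment": None if c.failed else np.asarray(c.assignment).tolist(),
                    "stability": None if c.stability is None else round(c.stability, 12),
                    "error": c.error,
                }
                for c in sorted(self.candidates, key=lambda c: c.name)
            },
            "robust": sorted(self.robust_names),
            "groups": [
                {"members": g.members, "representative": g.representative}
                for g in self.groups
            ],
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    # -- persistence ------------------------------------------------------
    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.candidates_table().to_csv(out / "candidates.csv", index=False)
        self.assignments_table().to_csv(out / "assignments.csv", index_label="sample")
        if self.stability is not None:
            self.stability.to_csv(out / "stability.csv", index=False)
        if self.jaccard is not None:
            self.jaccard.to_frame().to_csv(out / "jaccard.csv", index_label="name")
            self.jaccard.annotations.to_csv(out / "annotations.csv", index_label="name")
        with open(out / "groups.json", "w") as fh:
            json.dump(
                [
                    {"group": i + 1, "members": g.members, "representative": g.representative}
                    for i, g in enumerate(self.groups)
                ],
                fh,
                indent=2,
            )
        provenance = {
            "config": asdict(self.config),
            "scenario": self.scenario,
            "n_samples": len(self.samples),
            "n_embeddings": self.n_embeddings,
            "n_candidates": len(self.candidates),
            "n_robust": len(self.robust_names),
            "digest": self.digest(),
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)


def run_pipeline(study, stack=None, config: RunConfig | None = None) -> RunResult:
    """Execute the scenario-appropriate pipeline end to end."""
    config = config or RunConfig()
    config.validate()
    k_range = (config.k_min, config.k_max)

    if study.scenario == "complete":
        std = standardize(study.encoded)
        dendrogram = build_variable_dendrogram(study.encoded, max_depth=config.max_depth)
        depths = config.depths
        embeddings = compute_embeddings(
            dendrogram, std, depths=depths, var_target=config.var_target
        )
        candidates = run_stratification_process(
            embeddings,
            combos=config.combos,
            k_range=k_range,
            seed=config.seed,
            restarts=config.kmeans_restarts,
            n_jobs=config.workers,
        )
        emb_by_depth = {e.depth: e for e in embeddings}

        def recluster_factory(cand):
            return make_embedding_reclusterer(
                emb_by_depth[cand.depth].matrix.to_numpy(dtype=float),
                cand.code,
                cand.k,
                restarts=config.kmeans_restarts,
            )

        n_embeddings = len(embeddings)
    else:
        candidates, consensus_matrices, dendrogram = run_missing_pipeline(
            study,
            stack,
            combos=config.combos,
            k_range=k_range,
            depths=config.depths,
            max_depth=config.max_depth,
            var_target=config.var_target,
            seed=config.seed,
            restarts=config.kmeans_restarts,
            n_jobs=config.workers,
        )

        def recluster_factory(cand):
            return make_consensus_reclusterer(consensus_matrices[cand.name], cand.k)

        n_embeddings = (
            len(config.depths) if config.depths is not None else dendrogram.max_depth
        )

    robust, stability_table = filter_robust(
        candidates,
        recluster_factory,
        n_boot=config.n_boot,
        threshold=config.stability_threshold,
        seed=config.seed,
        summary=config.stability_summary,
        n_jobs=config.workers,
    )
    if robust:
        jaccard = build_jaccard_matrix(robust)
        groups = group_and_represent(
            jaccard, threshold=config.jaccard_threshold, min_size=config.min_group_size
        )
    else:
        jaccard, groups = None, []

    return RunResult(
        config=config,
        scenario=study.scenario,
        samples=list(study.samples),
        n_embeddings=n_embeddings,
        candidates=candidates,
        robust_names=[c.name for c in robust],
        jaccard=jaccard,
        groups=groups,
        stability=stability_table,
    )
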