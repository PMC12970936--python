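"""End-to-end orchestration of the analysis stages.

Stage order: simulate/load -> detection filter -> left-censored imputation ->
log2 transform + normality report -> covariate-adjusted group comparisons ->
per-group correlation networks and overlap (raw concentrations, per cohort)
-> control merging + batch adjustment -> subset-wise group-mean clustering ->
pairwise Mahalanobis similarity + permutation test.  Every intermediate
table is written as RFC-4180 CSV and hashed into a run manifest.

One global seed expands into per-stage seeds through a fixed splitting rule:
``numpy.random.SeedSequence(seed)`` generates one 32-bit state word per
stage, taken modulo 2**31, in the order (simulate, impute, permutation).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sputumpanel.batch import combat_adjust, merge_controls
from sputumpanel.containers import DEFAULT_COVARIATES, MediatorMatrix, validate_participants
from sputumpanel.correlations import build_network, membership_table, pair_overlap
from sputumpanel.group_stats import compare_all
from sputumpanel.preprocess import (
    assess_normality,
    detection_filter,
    impute_left_censored,
    log2_transform,
)
from sputumpanel.similarity import (
    DEFAULT_SUBSETS,
    MediatorSubset,
    group_means,
    hierarchical_cluster,
    permutation_test,
    scale_rows,
)
from sputumpanel.synthetic import SimConfig, default_config, generate_cohort

logger = logging.getLogger(__name__)


def stage_seeds(seed: int) -> dict[str, int]:
    """Expand one global seed into per-stage seeds (documented splitting rule)."""
    words = np.random.SeedSequence(seed).generate_state(3, dtype=np.uint32)
    names = ("simulate", "impute", "permutation")
    return {name: int(w % (2**31)) for name, w in zip(names, words)}


@dataclass
class PipelineConfig:
    """Thresholds, inputs, and seeds for one pipeline run."""

    simulate: SimConfig | None = None
    mediators_csv: str | None = None
    lods_csv: str | None = None
    participants_csv: str | None = None
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    control_labels: list[str] = field(default_factory=lambda: ["Control_COPD", "Control_EC"])
    min_detection: float = 0.75
    r_threshold: float = 0.6
    p_threshold: float = 0.01
    alpha: float = 0.05
    n_permutations: int = 10_000
    far_percentile: float = 95.0
    close_percentile: float = 5.0
    impute_iterations: int = 10
    subsets: tuple[MediatorSubset, ...] = DEFAULT_SUBSETS
    seed: int = 0
    outdir: str = "pipeline_out"

    def validate(self) -> None:
        if self.simulate is None and self.mediators_csv is None:
            raise ValueError("config needs either a simulate block or input CSV paths")
        if not (0 < self.min_detection <= 1):
            raise ValueError(f"min_detection {self.min_detection} outside (0, 1]")
        if not (0 <= self.r_threshold <= 1):
            raise ValueError(f"r_threshold {self.r_threshold} outside [0, 1]")
        for name in ("p_threshold", "alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} {v} outside (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 <= self.close_percentile < self.far_percentile <= 100):
            raise ValueError("need 0 <= close_percentile < far_percentile <= 100")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            if sim == "default" or sim is True:
                cfg.simulate = default_config(seed=cfg.seed)
            else:
                from sputumpanel.synthetic import GroupSpec

                groups = [GroupSpec(g["name"], g["n"], g.get("shifts", {})) for g in sim.pop("groups")]
                cfg.simulate = SimConfig(group_specs=groups, **sim)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resolve_subsets(
    subsets: tuple[MediatorSubset, ...], measured: list[str]
) -> list[MediatorSubset]:
    out = []
    for s in subsets:
        if s.name == "all":
            out.append(MediatorSubset("all", tuple(measured)))
            continue
        members = tuple(m for m in s.members if m in measured)
        if len(members) < 2:
            warnings.warn(f"subset {s.name!r}: fewer than 2 measured members; skipped")
            continue
        if len(members) < len(s.members):
            warnings.warn(f"subset {s.name!r}: dropped unmeasured members")
        out.append(MediatorSubset(s.name, members))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; write artifacts; return the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, index: bool = False) -> Path:
        path = outdir / name
        df.to_csv(path, index=index, na_rep="")
        written.append(path)
        return path

    stage = "simulate/load"
    try:
        if config.simulate is not None:
            sim = config.simulate
            sim.seed = seeds["simulate"] if sim.seed == 0 else sim.seed
            matrix, participants, truth = generate_cohort(sim)
            truth.group_log2_means.rename_axis("group").to_csv(
                outdir / "truth_group_means.csv"
            )
            written.append(outdir / "truth_group_means.csv")
        else:
            lods = (
                MediatorMatrix.lod_from_csv(config.lods_csv)
                if config.lods_csv
                else None
            )
            matrix = MediatorMatrix.from_csv(config.mediators_csv, lod=lods)
            participants = pd.read_csv(config.participants_csv, index_col="participant_id")
        validate_participants(participants, matrix)
        matrix.to_csv(outdir / "mediators_raw.csv")
        written.append(outdir / "mediators_raw.csv")
        matrix.lod_to_csv(outdir / "lods.csv")
        written.append(outdir / "lods.csv")
        participants.rename_axis("participant_id").to_csv(outdir / "participants.csv")
        written.append(outdir / "participants.csv")

        stage = "detection_filter"
        matrix = detection_filter(matrix, config.min_detection)

        stage = "impute"
        matrix = impute_left_censored(
            matrix, n_iterations=config.impute_iterations, seed=seeds["impute"]
        )
        matrix.to_csv(outdir / "mediators_imputed.csv")
        written.append(outdir / "mediators_imputed.csv")

        stage = "normality"
        save(assess_normality(matrix), "normality.csv")

        stage = "log2"
        log2_matrix = log2_transform(matrix)
        log2_matrix.to_csv(outdir / "mediators_log2.csv")
        written.append(outdir / "mediators_log2.csv")

        stage = "compare"
        comparison = compare_all(
            log2_matrix, participants, covariates=config.covariates, alpha=config.alpha
        )
        save(comparison.overall, "ancova_overall.csv")
        save(comparison.contrasts, "emm_contrasts.csv")
        save(comparison.covariates, "covariate_effects.csv")

        stage = "correlate"
        networks = []
        for grp in sorted(participants["group"].astype(str).unique()):
            nw = build_network(
                matrix, participants, grp, config.r_threshold, config.p_threshold
            )
            networks.append(nw)
            edge = nw.edge_list()
            edge.insert(0, "group", grp)
            save(edge, f"correlations_{grp}.csv")
        overlap = pair_overlap(networks)
        save(overlap.exclusive, "correlation_overlap.csv")
        save(membership_table(networks), "correlation_membership.csv")

        stage = "merge_controls"
        merged = merge_controls(participants, config.control_labels)

        stage = "combat_adjust"
        adjusted, model = combat_adjust(log2_matrix, merged, protected=["group", "age"])
        adjusted.to_csv(outdir / "mediators_adjusted.csv")
        written.append(outdir / "mediators_adjusted.csv")
        if model is not None:
            save(model.to_frame(), "batch_model.csv")

        subsets = _resolve_subsets(config.subsets, adjusted.mediators)
        stage = "cluster"
        for s in subsets:
            means = group_means(adjusted, merged, s)
            scaled = scale_rows(means.T)  # mediators as rows, row-scaled
            dendro = hierarchical_cluster(scaled)
            save(
                pd.DataFrame(
                    {"axis": ["row"] * len(dendro.row_order) + ["col"] * len(dendro.col_order),
                     "label": dendro.row_order + dendro.col_order}
                ),
                f"cluster_order_{s.name}.csv",
            )
            (outdir / f"cluster_{s.name}.nwk").write_text(
                dendro.col_newick() + "\n" + dendro.row_newick() + "\n"
            )
            written.append(outdir / f"cluster_{s.name}.nwk")

        stage = "similarity"
        for s in subsets:
            report = permutation_test(
                adjusted,
                merged,
                s,
                n_permutations=config.n_permutations,
                seed=seeds["permutation"],
                far_percentile=config.far_percentile,
                close_percentile=config.close_percentile,
            )
            tab = report.table.copy()
            tab.insert(0, "subset", s.name)
            tab["n_permutations"] = report.n_permutations
            tab["seed"] = report.seed
            save(tab, f"similarity_{s.name}.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    from importlib.metadata import version as _pkg_version

    manifest = {
        "version": _pkg_version("sputumpanel"),
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_participants": int(len(participants)),
        "n_mediators": int(len(matrix.mediators)),
        "subsets": [s.name for s in subsets],
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
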