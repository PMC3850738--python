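"""End-to-end pipeline orchestration with YAML configuration.

The pipeline walks a directory layout of one native PDB plus a decoy
directory per case, computes quality tables, scores (from contact
matrices and/or externally supplied score TSVs), ranked cluster
representatives, benchmark success statistics and the pairwise synergy
matrices, writing everything as TSV/Newick under an output directory
together with a JSON run manifest (config hash + seeds).  Per-case
failures are logged and skipped rather than aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .evaluation import CaseResult, conditional_table, stratified_success_tables, success_table
from .potentials import MetricSpec, contact_potential_metric, load_contact_matrix, read_score_table, score_decoy_set, write_score_table
from .quality import QualityClass, evaluate_decoy_set, write_quality_table
from .ranking import rank_case, write_ranked_list
from .structures import DecoySet, partition_complex, read_pdb, validate_decoy_set
from .synergy import synergy_matrices

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    cases: list[dict]                      # each: case_id, native, decoy_dir,
                                           # optional receptor_chains, difficulty,
                                           # optional score_table
    output_dir: str
    matrices: list[str] = field(default_factory=list)
    top_n: list[int] = field(default_factory=lambda: [1, 10, 100])
    quality_threshold: str = "acceptable"
    cluster_threshold: float = 3.0
    contact_cutoff: float = 5.0
    interface_cutoff: float = 10.0
    found_top_n: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        config = cls(**raw)
        config.validate()
        return config

    def validate(self) -> None:
        if not self.cases:
            raise ValueError("config lists no cases")
        for case in self.cases:
            native = Path(case["native"])
            if not native.exists():
                raise FileNotFoundError(native)
            decoy_dir = Path(case["decoy_dir"])
            if not decoy_dir.is_dir():
                raise FileNotFoundError(decoy_dir)
        for m in self.matrices:
            if not Path(m).exists():
                raise FileNotFoundError(m)
        if any(n <= 0 for n in self.top_n):
            raise ValueError("top_n values must be positive")

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_case(case: dict, config: PipelineConfig) -> DecoySet:
    """Read one case's native and decoys; corrupt decoys are skipped."""
    native = read_pdb(case["native"])
    partition = partition_complex(native, case.get("receptor_chains"))
    decoys = []
    for path in sorted(Path(case["decoy_dir"]).glob("*.pdb")):
        try:
            decoys.append((path.stem, read_pdb(path)))
        except Exception as exc:  # noqa: BLE001 - skip, log, continue
            logger.warning("case %s: decoy %s unreadable (%s); skipped",
                           case["case_id"], path.name, exc)
    if not decoys:
        raise ValueError(f"case {case['case_id']}: no readable decoys")
    return DecoySet(case["case_id"], native, decoys, partition)


def run_full(config: PipelineConfig) -> Path:
    """Run every stage and write the output tree; returns the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    partial = False

    metrics: list[MetricSpec] = []
    for matrix_path in config.matrices:
        matrix = load_contact_matrix(matrix_path)
        metrics.append(contact_potential_metric(matrix))

    results: list[CaseResult] = []
    metric_names: list[str] = [m.name for m in metrics]
    q = QualityClass.from_label(config.quality_threshold)

    for case in config.cases:
        case_id = case["case_id"]
        case_dir = out / "cases" / case_id
        case_dir.mkdir(parents=True, exist_ok=True)
        try:
            decoy_set = load_case(case, config)
        except Exception as exc:  # noqa: BLE001
            logger.error("case %s failed to load: %s; skipped", case_id, exc)
            partial = True
            continue
        report = validate_decoy_set(decoy_set)
        if report:
            pd.DataFrame(report).to_csv(case_dir / "validation.tsv", sep="\t", index=False)
        quality = evaluate_decoy_set(decoy_set, config.contact_cutoff, config.interface_cutoff)
        write_quality_table(quality, case_dir / "quality.tsv")

        scores = score_decoy_set(decoy_set, metrics) if metrics else pd.DataFrame(index=quality.index)
        if "score_table" in case:
            external = read_score_table(case["score_table"])
            scores = scores.join(external, how="outer")
        write_score_table(scores, case_dir / "scores.tsv")

        directions = {m.name: m.direction for m in metrics}
        ranked = {}
        for name in scores.columns:
            direction = directions.get(name, "ascending_better")
            ranked_list = rank_case(decoy_set, scores, quality, name, direction,
                                    config.cluster_threshold)
            write_ranked_list(ranked_list, quality, case_dir / f"ranked_{name}.tsv")
            ranked[name] = ranked_list
            if name not in metric_names:
                metric_names.append(name)
        best = QualityClass(int(quality["class"].map(int).max()))
        results.append(CaseResult(case_id, case.get("difficulty", "rigid_body"),
                                  ranked, best))

    if metric_names:
        eval_dir = out / "evaluation"
        eval_dir.mkdir(exist_ok=True)
        table = success_table(results, metric_names, config.top_n)
        table.to_csv(eval_dir / "success.tsv", sep="\t", index=False)
        conditional_table(results, metric_names, config.found_top_n).to_csv(
            eval_dir / "conditional.tsv", sep="\t")
        for name, strat_table in stratified_success_tables(results, metric_names,
                                                           top_n=config.top_n).items():
            strat_table.to_csv(eval_dir / f"success_{name}.tsv", sep="\t", index=False)

    if len(metric_names) >= 2:
        syn = synergy_matrices(results, metric_names, config.found_top_n, q)
        syn_dir = out / "synergy"
        syn_dir.mkdir(exist_ok=True)
        syn.symmetric_difference.to_csv(syn_dir / "symmetric_difference.tsv", sep="\t")
        syn.union.to_csv(syn_dir / "union.tsv", sep="\t")
        syn.relative_complement.to_csv(syn_dir / "relative_complement.tsv", sep="\t")
        (syn_dir / "dendrogram.nwk").write_text(syn.dendrogram.to_newick() + "\n")

    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_cases": len(results),
        "metrics": metric_names,
        "partial": partial,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
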