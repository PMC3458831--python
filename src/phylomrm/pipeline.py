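"""Configuration-driven end-to-end analysis runner.

Ties the stages together: pool posterior runs, compute the node-distance
response from a summary tree, build the model matrices from metadata, run
the matrix regression with permutation tests, and evaluate the topology
hypotheses against the pooled posterior.  The JSON report records input
checksums, every result, the seed and the software version; rerunning the
same configuration byte-reproduces the report body.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .matrix_regression import mrm_permutation_test
from .model_matrices import TaxonTable, geographic_matrix, habitat_matrix, taxonomy_matrix
from .phylo_distance import node_distance_matrix
from .topology_tests import Constraint, posterior_frequency
from .trees_io import (
    McmcSamplingSpec,
    TreeIOError,
    pool_posterior,
    read_newick_trees,
    read_nexus_trees,
    write_newick_trees,
)

__all__ = ["PipelineError", "AnalysisConfig", "run_pipeline"]

logger = logging.getLogger("phylomrm")

_PREDICTORS = ("taxonomy", "geography", "habitat")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its inputs."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Validated analysis configuration (YAML-loadable)."""

    tree_files: tuple[str, ...]
    summary_tree: str
    metadata: str
    output_dir: str
    constraints: tuple[str, ...] = ()
    sampling: Optional[McmcSamplingSpec] = None
    unroot: bool = False
    predictor_order: tuple[str, ...] = _PREDICTORS
    permutations: int = 9999
    seed: int = 0
    geography_units: str = "meters"

    def __post_init__(self) -> None:
        if sorted(self.predictor_order) != sorted(_PREDICTORS):
            raise PipelineError(
                f"predictor_order must be a permutation of {_PREDICTORS}"
            )
        for path in (*self.tree_files, self.summary_tree, self.metadata, *self.constraints):
            if not Path(path).exists():
                raise PipelineError(f"configured path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        base = Path(path).parent

        def _resolve(p: str) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        sampling = None
        if "sampling" in doc:
            s = doc["sampling"]
            sampling = McmcSamplingSpec(
                generations=int(s["generations"]),
                interval=int(s["interval"]),
                burnin=int(s.get("burnin", 0)),
                n_runs=int(s.get("n_runs", len(doc.get("tree_files", [])) or 1)),
            )
        return cls(
            tree_files=tuple(_resolve(p) for p in doc.get("tree_files", [])),
            summary_tree=_resolve(doc["summary_tree"]),
            metadata=_resolve(doc["metadata"]),
            output_dir=_resolve(doc.get("output_dir", "out")),
            constraints=tuple(_resolve(p) for p in doc.get("constraints", [])),
            sampling=sampling,
            unroot=bool(doc.get("unroot", False)),
            predictor_order=tuple(doc.get("predictor_order", _PREDICTORS)),
            permutations=int(doc.get("permutations", 9999)),
            seed=int(doc.get("seed", 0)),
            geography_units=str(doc.get("geography_units", "meters")),
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_trees(path: str):
    text = Path(path).read_text(encoding="utf-8", errors="ignore")
    if "#NEXUS" in text[:200].upper():
        return read_nexus_trees(path)
    return read_newick_trees(path)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns (and writes) the JSON-able report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "permutations": config.permutations,
        "predictor_order": list(config.predictor_order),
        "unroot": config.unroot,
        "inputs": {},
    }
    for path in (*config.tree_files, config.summary_tree, config.metadata, *config.constraints):
        report["inputs"][str(path)] = _sha256(path)

    # stage 1: pool posterior runs
    pooled = None
    if config.tree_files:
        try:
            runs = [_read_trees(p) for p in config.tree_files]
            if config.sampling is not None:
                pooled = pool_posterior(runs, config.sampling)
            else:
                if len(runs) > 1:
                    raise TreeIOError("multiple runs require a sampling spec")
                pooled = runs[0]
        except Exception as exc:
            raise PipelineError(f"pooling stage failed on {config.tree_files}: {exc}") from exc
        pooled_path = outdir / "pooled.nwk"
        write_newick_trees(pooled, pooled_path)
        report["pooled"] = {
            "count": pooled.count,
            "path": str(pooled_path),
            "sha256": _sha256(pooled_path),
        }
        logger.info("pooled %d trees from %d run(s)", pooled.count, len(config.tree_files))

    # stage 2: node-distance response from the summary tree
    try:
        summary = _read_trees(config.summary_tree).samples[0].tree
        table = TaxonTable.from_csv(config.metadata)
        response = node_distance_matrix(
            summary, label_order=table.labels, unroot=config.unroot
        )
    except Exception as exc:
        raise PipelineError(
            f"node-distance stage failed on {config.summary_tree}: {exc}"
        ) from exc
    nodedist_path = outdir / "nodedist.tsv"
    response.write_tsv(nodedist_path)
    report["node_distance"] = {"path": str(nodedist_path), "sha256": _sha256(nodedist_path)}
    logger.info("node-distance matrix on %d taxa", response.n)

    # stage 3: model matrices
    try:
        builders = {
            "taxonomy": lambda: taxonomy_matrix(table),
            "geography": lambda: geographic_matrix(table, units=config.geography_units),
            "habitat": lambda: habitat_matrix(table),
        }
        predictors = {name: builders[name]() for name in config.predictor_order}
    except Exception as exc:
        raise PipelineError(f"model-matrix stage failed on {config.metadata}: {exc}") from exc
    report["model_matrices"] = {}
    for name, matrix in predictors.items():
        path = outdir / f"{name}.tsv"
        matrix.write_tsv(path)
        report["model_matrices"][name] = {"path": str(path), "sha256": _sha256(path)}

    # stage 4: matrix regression with permutation tests
    try:
        mrm = mrm_permutation_test(
            response,
            [predictors[name] for name in config.predictor_order],
            permutations=config.permutations,
            seed=config.seed,
            names=list(config.predictor_order),
        )
    except Exception as exc:
        raise PipelineError(f"regression stage failed: {exc}") from exc
    report["mrm"] = mrm.to_dict()
    logger.info(
        "MRM: %.2f%% variance explained over %d pairs", mrm.percent_variance, mrm.n_pairs
    )

    # stage 5: topology tests against the pooled posterior
    report["topology_tests"] = []
    if config.constraints:
        if pooled is None:
            raise PipelineError("topology tests require tree_files for the posterior")
        for cpath in config.constraints:
            try:
                constraint = Constraint.from_yaml(cpath)
                result = posterior_frequency(pooled, constraint)
            except Exception as exc:
                raise PipelineError(f"topology-test stage failed on {cpath}: {exc}") from exc
            report["topology_tests"].append(result.to_dict())
            logger.info(
                "hypothesis %s: pP = %s%% (%d/%d)",
                result.hypothesis,
                result.pp_display,
                result.n_consistent,
                result.total,
            )

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
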