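"""End-to-end orchestration: simulate/load -> select -> cluster -> evaluate.

A run takes either a pair of input files (expression matrix +
annotations) or a simulation config, applies the signature-selection
procedure, clusters the samples on the signature, evaluates the
two-group cut as a diagnostic test against the LVSI labels, and writes
the clinicopathological association report.  Every output file carries
the seed and a hash of the run configuration; identical config + seed
gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import cluster as _cluster
from . import diagnostics as _diag
from . import io as _io
from .clinstats import table1_report
from .select import SelectionParams, select_signature, write_selection, write_signature
from .simulate import SimulationConfig, SyntheticDataset, generate_dataset

logger = logging.getLogger("lvsig")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of (``matrix_path`` + ``samples_path``) or ``simulation``
    must be given.
    """

    outdir: str | Path
    matrix_path: str | Path | None = None
    samples_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    selection: SelectionParams = dataclasses.field(default_factory=SelectionParams)
    linkage: str = "average"
    seed: int = 0
    heatmap: bool = False

    def __post_init__(self) -> None:
        have_files = self.matrix_path is not None and self.samples_path is not None
        if have_files == (self.simulation is not None):
            raise ValueError(
                "exactly one of input paths or a simulation config is required")

    def config_hash(self) -> str:
        payload = {
            "matrix_path": str(self.matrix_path),
            "samples_path": str(self.samples_path),
            "simulation": (dataclasses.asdict(self.simulation)
                           if self.simulation else None),
            "selection": dataclasses.asdict(self.selection),
            "linkage": self.linkage,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("load")
def _load(config: RunConfig):
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        ds = generate_dataset(sim)
        return ds.expression, ds.samples, ds.truth
    matrix = _io.read_matrix(config.matrix_path)
    samples = _io.read_samples(config.samples_path)
    missing = set(matrix.sample_ids) - set(samples["sample_id"])
    if missing:
        raise ValueError(f"samples missing annotations: {sorted(missing)[:5]}")
    samples = (samples.set_index("sample_id").loc[matrix.sample_ids]
               .reset_index())
    return matrix, samples, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write artifacts into ``outdir``, return the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"seed={config.seed} config_hash={config.config_hash()}"
    logger.info("run start: %s", tag)

    matrix, samples, truth = _load(config)
    labels = samples.set_index("sample_id")["lvsi"] == "positive"

    selection = _stage("select")(select_signature)(
        matrix, labels, config.selection)
    write_selection(selection, outdir / "selection_table.tsv", tag)
    write_signature(selection, outdir / "signature.txt", tag)
    logger.info("selected %d genes", len(selection.signature))
    if not selection.signature:
        raise PipelineError("stage 'select' failed: empty signature, "
                            "cannot cluster")

    sig_matrix = matrix.restrict_genes(selection.signature)
    assignment = _stage("cluster")(_cluster.cluster_samples)(
        sig_matrix, config.linkage)
    assignment = _cluster.label_groups(assignment, labels)
    (outdir / "dendrogram.nwk").write_text(
        f"# {tag}\n" + _cluster.to_newick(assignment) + "\n")
    pd.DataFrame({"sample_id": assignment.sample_ids,
                  "group": assignment.group_of.to_numpy()}).to_csv(
        outdir / "assignment.tsv", sep="\t", index=False)
    if config.heatmap:
        _cluster.plot_heatmap(sig_matrix, assignment, outdir / "heatmap.png")

    predicted = _cluster.predict(assignment)
    metrics = _stage("evaluate")(_diag.confusion)(predicted, labels)
    _diag.write_report(metrics, outdir / "confusion_report.tsv", tag)

    clin = _stage("clinstats")(table1_report)(samples)
    with open(outdir / "clinical_report.tsv", "w") as fh:
        fh.write(f"# {tag}\n")
        clin.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    summary = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_samples": matrix.n_samples,
        "n_genes": matrix.n_genes,
        "n_selected": len(selection.signature),
        "linkage": config.linkage,
        "group_A_size": int((assignment.group_of == "A").sum()),
        "group_B_size": int((assignment.group_of == "B").sum()),
        "confusion": metrics.as_dict(),
    }
    if truth is not None:
        truth_set = set(truth)
        sel_set = set(selection.signature)
        summary["n_planted"] = len(truth_set)
        summary["planted_recall"] = (len(sel_set & truth_set) / len(truth_set)
                                     if truth_set else None)
        summary["false_positive_genes"] = len(sel_set - truth_set)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    flat = _flatten(summary)
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write(f"# {tag}\n")
        for k, v in flat.items():
            fh.write(f"{k}\t{v}\n")
    logger.info("run complete: %s", outdir)
    return summary


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out
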