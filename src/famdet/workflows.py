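"""End-to-end analysis workflows with manifests and TSV/JSON reports.

Two pipelines mirror the study designs this package supports:

* **family workflow** — read an alignment, remove fragments and >70%
  redundant sequences, build the reference map, profile conservation,
  detect coevolved sets, and classify sequences against residue
  signatures; every stage logs input/kept/removed counts so the
  "filtering resulted in N sequences" narrative is reproducible on any
  input.
* **coverage workflow** — pairwise distances, OTU clustering at the 97%
  identity cutoff, Good's coverage.

Both write their reports plus a run manifest (inputs, parameters,
versions, per-stage counts) into an output directory and are byte-stable
for a fixed configuration.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .alignment import (
    Alignment,
    ReferenceMap,
    build_reference_map,
    read_alignment,
    read_fasta_sequences,
    remove_fragments,
    remove_redundant,
    write_alignment,
)
from .conservation import conserved_positions
from .coevolution import assemble_sets, detect_correlated_pairs
from .coverage import cluster_otus, goods_coverage
from .signatures import MappedPeptide, Signature, builtin_signatures, classify

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A workflow stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Parameters of one workflow run; defaults are the analysis defaults."""

    input_path: str = ""
    output_dir: str = "famdet_out"
    reference_id: str | None = None
    first_residue_number: int = 1
    min_occupancy: float = 0.5
    max_identity: float = 0.70
    conservation_threshold: float = 0.80
    min_presence: float = 0.20
    min_increase: float = 0.80
    max_p: float = 1e-10
    set_mode: str = "component"
    signature_family: str | None = "arsc"
    otu_cutoff: float = 0.03
    linkage: str = "furthest"
    n_definition: str = "singleton_otus"
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_occupancy", "max_identity", "conservation_threshold",
                     "min_presence", "min_increase", "otu_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 and name != "min_increase":
                raise ValueError(f"{name} must be within [0, 1], got {v}")
        if not 0.0 < self.max_p < 1.0:
            raise ValueError("max_p must lie in (0, 1)")

    def to_dict(self) -> dict[str, Any]:
        return dict(self.__dict__)


def _write_manifest(outdir: Path, config: RunConfig, stages: list[dict]) -> None:
    manifest = {
        "tool": "famdet",
        "version": __version__,
        "config": config.to_dict(),
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _peptides_from_alignment(
    aln: Alignment, refmap: ReferenceMap
) -> list[MappedPeptide]:
    """Express every alignment row as reference-position residue states."""
    peptides = []
    for rid, seq in aln.records:
        states = {
            ref: seq[col]
            for col, ref in refmap.col_to_ref.items()
            if seq[col] != "-"
        }
        if states:
            peptides.append(MappedPeptide(rid, states))
    return peptides


def run_family_workflow(
    config: RunConfig, signatures: list[Signature] | None = None
) -> dict[str, Any]:
    """read -> filter -> reference map -> conservation -> coevolution -> classify.

    Returns a result bundle (in-memory objects plus report paths); all
    reports and a manifest land in ``config.output_dir``.  On a stage
    failure, partial outputs are removed and a :class:`StageError` names
    the stage.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    try:
        stage = "read_alignment"
        aln = read_alignment(config.input_path)
        stages.append({"stage": stage, "n_in": aln.n_sequences, "n_out": aln.n_sequences})

        stage = "remove_fragments"
        n_in = aln.n_sequences
        aln, frag_report = remove_fragments(aln, config.min_occupancy)
        if not aln.records:
            raise ValueError("all sequences removed as fragments")
        stages.append({"stage": stage, "n_in": n_in, "n_out": aln.n_sequences,
                       "n_removed": len(frag_report)})

        stage = "remove_redundant"
        n_in = aln.n_sequences
        aln, red_report = remove_redundant(aln, config.max_identity)
        stages.append({"stage": stage, "n_in": n_in, "n_out": aln.n_sequences,
                       "n_removed": len(red_report)})
        pd.DataFrame(frag_report + red_report,
                     columns=["id", "reason", "statistic"]).to_csv(
            outdir / "filter_report.tsv", sep="\t", index=False)
        write_alignment(aln, outdir / "filtered_alignment.fasta")

        stage = "reference_map"
        ref_id = config.reference_id or aln.records[0][0]
        refmap = build_reference_map(aln, ref_id, config.first_residue_number)
        stages.append({"stage": stage, "reference_id": ref_id,
                       "n_mapped_columns": len(refmap.col_to_ref)})

        stage = "conservation"
        conserved = conserved_positions(aln, refmap, config.conservation_threshold)
        pd.DataFrame(conserved, columns=["ref_position", "residue", "frequency"]
                     ).assign(conserved=True).to_csv(
            outdir / "conserved_positions.tsv", sep="\t", index=False)
        stages.append({"stage": stage, "n_conserved": len(conserved)})

        stage = "coevolution"
        pairs = detect_correlated_pairs(
            aln, config.min_presence, config.min_increase, config.max_p,
            refmap=refmap)
        sets = assemble_sets(pairs, mode=config.set_mode)
        pd.DataFrame(
            [
                {
                    "a": p.event_a.label(), "b": p.event_b.label(),
                    "f_a": p.f_a, "f_b": p.f_b,
                    "f_b_given_a": p.f_b_given_a, "f_a_given_b": p.f_a_given_b,
                    "increase_ab": p.relative_increase_ab,
                    "increase_ba": p.relative_increase_ba,
                    "p_value": p.p_value, "direction": p.direction,
                }
                for p in pairs
            ],
            columns=["a", "b", "f_a", "f_b", "f_b_given_a", "f_a_given_b",
                     "increase_ab", "increase_ba", "p_value", "direction"],
        ).to_csv(outdir / "correlated_pairs.tsv", sep="\t", index=False)
        (outdir / "coevolved_sets.json").write_text(json.dumps(
            [{"events": s.labels(),
              "n_supporting_pairs": len(s.supporting_pairs)} for s in sets],
            indent=2) + "\n")
        stages.append({"stage": stage, "n_pairs": len(pairs), "n_sets": len(sets)})

        stage = "classification"
        if signatures is None and config.signature_family:
            signatures = builtin_signatures(config.signature_family)
        report = None
        if signatures:
            peptides = _peptides_from_alignment(aln, refmap)
            report = classify(peptides, signatures)
            rows = [
                {"id": rid, **calls} for rid, calls in report.statuses.items()
            ]
            pd.DataFrame(rows).to_csv(
                outdir / "classification.tsv", sep="\t", index=False)
            (outdir / "classification_aggregate.json").write_text(json.dumps(
                {"fraction_present": report.aggregate,
                 "n_assessable": report.n_assessable}, indent=2) + "\n")
        stages.append({"stage": stage,
                       "n_signatures": len(signatures) if signatures else 0})

        _write_manifest(outdir, config, stages)
    except Exception as exc:
        failed = stage
        shutil.rmtree(outdir, ignore_errors=True)
        raise StageError(failed, exc) from exc
    return {
        "alignment": aln, "refmap": refmap, "conserved": conserved,
        "pairs": pairs, "sets": sets, "classification": report,
        "output_dir": str(outdir), "stages": stages,
    }


def run_coverage_workflow(config: RunConfig) -> dict[str, Any]:
    """distance -> OTU clustering (97%) -> Good's coverage, with reports."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    try:
        stage = "read_sequences"
        seqs = read_fasta_sequences(config.input_path)
        if not seqs:
            raise ValueError("no sequences in input")
        stages.append({"stage": stage, "n_in": len(seqs)})

        stage = "cluster_otus"
        table = cluster_otus(seqs, cutoff=config.otu_cutoff, method=config.linkage)
        pd.DataFrame(
            [{"otu": i, "id": rid, "otu_size": len(cluster)}
             for i, cluster in enumerate(table.clusters) for rid in cluster]
        ).to_csv(outdir / "otu_membership.tsv", sep="\t", index=False)
        stages.append({"stage": stage, "n_otus": table.n_otus,
                       "n_singletons": table.n_singletons})

        stage = "goods_coverage"
        cov = goods_coverage(table, config.n_definition)
        pd.DataFrame([{"C_percent": cov.C, "n": cov.n, "N": cov.N,
                       "n_definition": cov.n_definition,
                       "cutoff": table.cutoff}]).to_csv(
            outdir / "coverage.tsv", sep="\t", index=False)
        stages.append({"stage": stage, "C_percent": cov.C})

        _write_manifest(outdir, config, stages)
    except Exception as exc:
        failed = stage
        shutil.rmtree(outdir, ignore_errors=True)
        raise StageError(failed, exc) from exc
    return {"otu_table": table, "coverage": cov,
            "output_dir": str(outdir), "stages": stages}
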