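"""End-to-end orchestration: simulate -> filter -> subsample -> quantify -> report.

One config (YAML/JSON-equivalent) drives the whole experiment; all
randomness derives from a single base seed, and a second run with the
same config reproduces every TSV byte-identically. Each stage's outputs
are written under the run directory with a systematic
(sample, depth, replicate) naming scheme, and a run manifest records
every seed, parameter and per-stage read count.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .filtering import FilterPolicy, filter_reads
from .quantify import (
    GeneLengthTable,
    assign_reads,
    average_profiles,
    build_index,
    compute_rpkm,
)
from .sampling import SubsamplePlan, derive_seed, make_replicates
from .saturation import (
    assign_quartiles,
    depth_correlation,
    detection_report,
    percentile_summary,
    replicate_correlations,
)
from .simulate import SimulationConfig, generate_transcriptome, simulate_reads


class PipelineError(RuntimeError):
    """Stage failure; the message names the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Full experiment configuration (YAML round-trippable)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterPolicy = field(default_factory=FilterPolicy)
    depths: list[int] = field(default_factory=lambda: [100_000, 150_000, 200_000])
    n_replicates: int = 4
    k: int = 31
    sample: str = "sample1"
    output_dir: str = "seqsat_run"
    write_fastq: bool = False
    base_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "simulation": dataclasses.asdict(self.simulation),
            "filter": dataclasses.asdict(self.filter),
            "depths": list(self.depths),
            "n_replicates": self.n_replicates,
            "k": self.k,
            "sample": self.sample,
            "output_dir": self.output_dir,
            "write_fastq": self.write_fastq,
            "base_seed": self.base_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = SimulationConfig(**d.pop("simulation", {}))
        flt = FilterPolicy(**d.pop("filter", {}))
        return cls(simulation=sim, filter=flt, **d)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def run_pipeline(config: PipelineConfig) -> str:
    """Run the full experiment; returns the report directory path.

    Layout of the run directory::

        transcriptome.{fasta,lengths.tsv,truth.tsv}
        filter_stats.tsv
        counts/<sample>.depth<d>.rep<r>.counts.tsv     (+ reference)
        expression/<sample>.depth<d>.rep<r>.expr.tsv   (+ per-depth means)
        reports/{detection,percentiles,correlation,replicate_correlation}.tsv
        manifest.yaml
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    for sub in ("counts", "expression", "reports"):
        os.makedirs(os.path.join(out, sub), exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    # stage: simulate
    try:
        sim_cfg = dataclasses.replace(config.simulation, seed=config.base_seed)
        model = generate_transcriptome(sim_cfg)
        model.write(out)
        reads = simulate_reads(model, sim_cfg)
    except ValueError as e:
        raise PipelineError("simulate", str(e)) from e
    manifest["stages"]["simulate"] = {"n_genes": model.n_genes, "n_reads": len(reads)}

    # stage: filter
    reads, fstats = filter_reads(reads, config.filter)
    with open(os.path.join(out, "filter_stats.tsv"), "w") as fh:
        fh.write(fstats.to_tsv())
    manifest["stages"]["filter"] = dataclasses.asdict(fstats)

    # stage: subsample
    plan = SubsamplePlan(
        depths=config.depths, n_replicates=config.n_replicates, base_seed=config.base_seed
    )
    if max(plan.depths) > len(reads):
        raise PipelineError(
            "subsample",
            f"requested depth {max(plan.depths)} exceeds the {len(reads)} "
            "reads surviving the filter",
        )
    cells = make_replicates(
        reads,
        plan,
        out_dir=os.path.join(out, "fastq") if config.write_fastq else None,
        sample=config.sample,
    )
    manifest["stages"]["subsample"] = {
        "cells": [
            {
                "depth": d,
                "replicate": r,
                "n_reads": len(rs),
                "seed": derive_seed(config.base_seed, d, r),
            }
            for (d, r), rs in cells.items()
        ]
    }

    # stage: quantify
    try:
        index = build_index(dict(zip(model.gene_ids, model.sequences)), k=config.k)
        lengths = GeneLengthTable(dict(zip(model.gene_ids, (int(x) for x in model.lengths_bp))))
        ref_counts = assign_reads(reads, index)
        reference = compute_rpkm(
            ref_counts, lengths, sample=config.sample, depth=len(reads), replicate="reference"
        )
    except ValueError as e:
        raise PipelineError("quantify", str(e)) from e
    ref_counts.to_tsv(os.path.join(out, "counts", f"{config.sample}.reference.counts.tsv"))
    reference.to_tsv(os.path.join(out, "expression", f"{config.sample}.reference.expr.tsv"))

    profiles: dict[tuple[int, int], object] = {}
    assignment_stats = []
    for (d, r), rs in cells.items():
        ct = assign_reads(rs, index)
        prof = compute_rpkm(ct, lengths, sample=config.sample, depth=d, replicate=r)
        ct.to_tsv(os.path.join(out, "counts", f"{config.sample}.depth{d}.rep{r}.counts.tsv"))
        prof.to_tsv(os.path.join(out, "expression", f"{config.sample}.depth{d}.rep{r}.expr.tsv"))
        profiles[(d, r)] = prof
        assignment_stats.append(
            {
                "depth": d,
                "replicate": r,
                "total_assigned": ct.total_assigned,
                "n_unassigned": ct.n_unassigned,
                "n_ambiguous": ct.n_ambiguous,
            }
        )
    manifest["stages"]["quantify"] = {
        "k": config.k,
        "reference_assigned": ref_counts.total_assigned,
        "cells": assignment_stats,
    }

    # stage: saturate
    means = {}
    for d in config.depths:
        reps = [profiles[(d, r)] for r in range(config.n_replicates)]
        means[d] = average_profiles(reps)
        means[d].to_tsv(
            os.path.join(out, "expression", f"{config.sample}.depth{d}.mean.expr.tsv")
        )

    det = detection_report(list(profiles.values()) + [reference], model.n_genes)
    det = det.sort_values(["sample", "depth"]).reset_index(drop=True)

    quart = assign_quartiles(reference)
    corr = pd.concat(
        [depth_correlation(means[d], reference, quart) for d in config.depths],
        ignore_index=True,
    )

    repcorr_rows = []
    for d in config.depths:
        reps = [profiles[(d, r)] for r in range(config.n_replicates)]
        rc = replicate_correlations(reps)
        rc.insert(0, "depth", d)
        repcorr_rows.append(rc)
    repcorr = pd.concat(repcorr_rows, ignore_index=True)

    pct = pd.concat(
        [percentile_summary(means[d]) for d in config.depths]
        + [percentile_summary(reference)],
        ignore_index=True,
    )

    reports = os.path.join(out, "reports")
    kw = dict(sep="\t", index=False, float_format="%.6f")
    det.to_csv(os.path.join(reports, "detection.tsv"), **kw)
    corr.to_csv(os.path.join(reports, "correlation.tsv"), **kw)
    repcorr.to_csv(os.path.join(reports, "replicate_correlation.tsv"), **kw)
    pct.to_csv(os.path.join(reports, "percentiles.tsv"), **kw)

    with open(os.path.join(out, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out
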