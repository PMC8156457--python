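"""End-to-end pipeline orchestration: simulate/ingest -> QC -> call -> filter ->
classify -> haplogroup -> annotate -> cohort tables.

All randomness flows from the single configured seed; every output carries
the seed and a config hash in its header so a rerun with the same
configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import clinvar as clinvar_mod
from . import io as io_mod
from .cohort import CohortTable, frequency_spectrum, genome_bins, top_variants
from .haplogroup import HaploTree, assign_haplogroup, packaged_tree
from .qc import classify_mt_content, compute_qc, qc_table
from .reference import MtReference, find_homopolymers, packaged_reference
from .simulate import SimConfig, SimulatedCohort, simulate_cohort
from .variants import build_pileup, call_variants, classify_heteroplasmy, run_cascade

log = logging.getLogger("cfmito")


@dataclass
class PipelineConfig:
    """Thresholds and run parameters; defaults follow the screening protocol."""

    seed: int = 0
    out_dir: str | Path = "cfmito_out"
    min_depth: int = 5
    homopolymer_snv_minlen: int = 4
    homopolymer_indel_minlen: int = 4  # 3 for the stricter indel-reporting mode
    min_alt: int = 4
    min_alt_call: int = 2
    approximate_homoplasmy: bool = False
    discard_score: float = 0.5
    sim: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> None:
        for name in ("min_depth", "homopolymer_snv_minlen", "homopolymer_indel_minlen", "min_alt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (paths excluded)."""
        payload = {
            k: repr(v) for k, v in vars(self).items() if k != "out_dir"
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(
    config: PipelineConfig,
    ref: MtReference | None = None,
    tree: HaploTree | None = None,
    cohort: SimulatedCohort | None = None,
    write_outputs: bool = True,
) -> dict:
    """Execute all stages on a simulated cohort and write the run artefacts.

    Returns a dict with the in-memory results (qc table, kept variants per
    sample, filter reports, haplogroup calls, annotation and cohort tables).
    """
    config.validate()
    ref = ref or packaged_reference()
    tree = tree or packaged_tree()
    out_dir = Path(config.out_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
    stamp = [f"# cfmito seed={config.seed} config={config.digest()}"]

    def timed(stage):
        log.info("stage %s", stage)
        return time.time()

    t0 = timed("simulate")
    if cohort is None:
        config.sim.seed = config.seed
        cohort = simulate_cohort(config.sim, ref, tree)
    snv_track = find_homopolymers(ref, config.homopolymer_snv_minlen)
    indel_track = find_homopolymers(ref, config.homopolymer_indel_minlen)

    timed("qc")
    qcs = [
        compute_qc(s.fragments, s.truth.total_reads, ref, truth=s.truth)
        for s in cohort.samples
    ]
    classify_mt_content(qcs)

    timed("call/filter/classify")
    kept_by_sample, reports, calls = {}, {}, []
    for s in cohort.samples:
        sites, _ = build_pileup(s.fragments, ref)
        variants = call_variants(sites, min_alt_call=config.min_alt_call)
        kept, report = run_cascade(
            variants, snv_track, indel_track,
            min_depth=config.min_depth, min_alt=config.min_alt,
            ref_length=ref.length,
        )
        for v in kept:
            classify_heteroplasmy(v, approximate=config.approximate_homoplasmy)
        kept_by_sample[s.truth.sample_id] = kept
        reports[s.truth.sample_id] = report
        calls.append(
            assign_haplogroup(kept, tree, sample_id=s.truth.sample_id,
                              discard_threshold=config.discard_score)
        )

    timed("annotate")
    table = clinvar_mod.packaged_clinvar_table()
    ann_frames = []
    for sid, kept in kept_by_sample.items():
        ann = clinvar_mod.annotate_variants(kept, table)
        ann.insert(0, "sample_id", sid)
        ann_frames.append(ann)
    annotation = (
        pd.concat(ann_frames, ignore_index=True)
        if ann_frames
        else pd.DataFrame()
    )

    timed("cohort")
    metadata = pd.DataFrame(
        {
            "region": [s.truth.region_label for s in cohort.samples],
            "tube_type": [s.truth.tube_type for s in cohort.samples],
            "transport_days": [s.truth.transport_days for s in cohort.samples],
            "mt_content": [q.mt_content for q in qcs],
        },
        index=[s.truth.sample_id for s in cohort.samples],
    )
    cohort_table = CohortTable.from_calls(kept_by_sample, metadata)
    spectrum = frequency_spectrum(cohort_table)
    bins = genome_bins(list(cohort_table.presence.columns))

    if write_outputs:
        qdf = qc_table(qcs)
        _write_tsv(qdf, out_dir / "qc.tsv", stamp)
        haplo_df = pd.DataFrame(
            [(c.sample_id, c.best_haplogroup, c.superclade, c.confidence, c.discarded)
             for c in calls],
            columns=["sample_id", "haplogroup", "superclade", "confidence", "discarded"],
        ).set_index("sample_id")
        _write_tsv(haplo_df, out_dir / "haplogroups.tsv", stamp)
        for sid, kept in kept_by_sample.items():
            io_mod.write_vcf(kept, ref, out_dir / f"{sid}.filtered.vcf", extra_headers=stamp)
        report_df = pd.concat(
            {sid: r.to_frame() for sid, r in reports.items()}, names=["sample_id"]
        )
        _write_tsv(report_df.reset_index().set_index("sample_id"),
                   out_dir / "filter_report.tsv", stamp)
        if len(annotation):
            _write_tsv(annotation.set_index("sample_id"), out_dir / "annotation.tsv", stamp)
        pres = cohort_table.presence.copy()
        pres.columns = [_vname(k) for k in pres.columns]
        _write_tsv(pres.astype(int), out_dir / "cohort_matrix.tsv", stamp)
        _write_tsv(spectrum.rename("frequency").to_frame().set_axis(
            [_vname(k) for k in spectrum.index]), out_dir / "spectrum.tsv", stamp)
        _write_tsv(bins.rename("n_variants").to_frame(), out_dir / "genome_bins.tsv", stamp)
        _write_tsv(top_variants(cohort_table, k=10).set_index("variant"),
                   out_dir / "top_variants.tsv", stamp)
        io_mod.write_manifest([s.truth for s in cohort.samples], out_dir / "manifest.tsv")
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return {
        "qc": qcs,
        "kept": kept_by_sample,
        "reports": reports,
        "haplogroup_calls": calls,
        "annotation": annotation,
        "cohort_table": cohort_table,
        "spectrum": spectrum,
        "genome_bins": bins,
    }


def _vname(key) -> str:
    from .variants import hgvs_name

    return hgvs_name(key)


def _write_tsv(df: pd.DataFrame, path: Path, stamp: list[str]) -> None:
    with open(path, "w") as fh:
        for line in stamp:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t")
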