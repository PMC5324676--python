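"""End-to-end orchestration: simulate -> demux -> phase -> variants -> call.

Each stage reads the previous stage's on-disk artifacts and writes its own,
so stages are independently runnable and the whole pipeline is idempotent
and deterministic for a given seed.  ``run_all`` chains them and produces a
per-sample JSON report plus a summary TSV with one row per sample
(haplogroups, coverage ratio, SUB-INS-DEL tallies, het/hom counts, genotype
and metabolizer group).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from amplistar import io_utils
from amplistar.demux import DemuxConfig, Read, demultiplex, length_filter, orient_and_trim
from amplistar.layout import AdornmentLayout
from amplistar.phasing import (
    PhasingConfig,
    cluster_reads,
    clusters_to_haplogroups,
    coverage_ratio,
    filter_haplogroups,
)
from amplistar.starcall import (
    PhenotypeCutpoints,
    call_diplotype,
    match_haplotype,
    predict_phenotype,
)
from amplistar.synthetic import apply_allele
from amplistar.variants import (
    align_to_reference,
    class_counts,
    classify_zygosity,
    extract_and_normalize,
    write_vcf,
)

log = logging.getLogger("amplistar")


class PipelineError(RuntimeError):
    """A stage failure, carrying stage and sample context in its message."""


@dataclass
class PipelineConfig:
    reads: str = "reads.fastq"
    sample_sheet: str = "sample_sheet.tsv"
    reference: str = "reference.fasta"
    table: str = "table.tsv"
    evidence: Optional[str] = None
    outdir: str = "out"
    demux: DemuxConfig = field(default_factory=DemuxConfig)
    phasing: PhasingConfig = field(default_factory=PhasingConfig)
    cutpoints: PhenotypeCutpoints = field(default_factory=PhenotypeCutpoints)
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["demux"] = DemuxConfig(**raw.get("demux", {}))
        raw["phasing"] = PhasingConfig(**raw.get("phasing", {}))
        raw["cutpoints"] = PhenotypeCutpoints(**raw.get("cutpoints", {}))
        return cls(**raw)


def _sample_seed(master_seed: int, index: int) -> int:
    return (master_seed * 100003 + 7919 * index + 1) % (2**31)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(
    outdir: str,
    depth: int = 120,
    seed: int = 0,
    scenarios=None,
) -> PipelineConfig:
    """Write the packaged synthetic cohort to ``outdir``; returns its config.

    ``scenarios`` defaults to the 20-sample packaged cohort; pass a subset
    of :data:`amplistar.fixtures.COHORT_SCENARIOS` to scale down.
    """
    from amplistar import fixtures
    from amplistar.synthetic import ReadErrorModel, simulate_reads

    os.makedirs(outdir, exist_ok=True)
    reference = fixtures.fixture_reference()
    table = fixtures.fixture_table()
    truths, evidence, expected = fixtures.packaged_cohort(depth=depth, scenarios=scenarios)
    reads, truth_df = simulate_reads(
        reference,
        table.alleles,
        truths,
        ReadErrorModel(seed=seed),
        fixtures.fixture_layout(),
    )
    io_utils.write_fasta({"locus": reference}, os.path.join(outdir, "reference.fasta"))
    io_utils.write_translation_table(table, os.path.join(outdir, "table.tsv"))
    io_utils.write_sample_sheet(
        {t.sample_id: t.barcode for t in truths}, os.path.join(outdir, "sample_sheet.tsv")
    )
    io_utils.write_evidence(evidence, os.path.join(outdir, "evidence.tsv"))
    io_utils.write_fastq(reads, os.path.join(outdir, "reads.fastq"))
    truth_df.assign(expected_genotype=truth_df["sample_id"].map(expected)).to_csv(
        os.path.join(outdir, "truth.tsv"), sep="\t", index=False
    )
    config = PipelineConfig(
        reads=os.path.join(outdir, "reads.fastq"),
        sample_sheet=os.path.join(outdir, "sample_sheet.tsv"),
        reference=os.path.join(outdir, "reference.fasta"),
        table=os.path.join(outdir, "table.tsv"),
        evidence=os.path.join(outdir, "evidence.tsv"),
        outdir=os.path.join(outdir, "out"),
        seed=seed,
    )
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    return config


def stage_demux(config: PipelineConfig, layout: Optional[AdornmentLayout] = None) -> dict[str, str]:
    """Split the input FASTQ by sample; returns sample -> per-sample FASTQ."""
    layout = layout or AdornmentLayout()
    reads = io_utils.read_fastq(config.reads)
    sheet = io_utils.read_sample_sheet(config.sample_sheet)
    result = demultiplex(reads, sheet, config.demux, layout)
    demux_dir = os.path.join(config.outdir, "demux")
    os.makedirs(demux_dir, exist_ok=True)
    paths: dict[str, str] = {}
    rows = []
    for sid in sorted(sheet):
        path = os.path.join(demux_dir, f"{sid}.fastq")
        io_utils.write_fastq(result.assigned[sid], path)
        paths[sid] = path
        rows.append({"sample_id": sid, "n_assigned": len(result.assigned[sid])})
    reasons = pd.Series([reason for _, reason in result.unassigned]).value_counts()
    rows.append(
        {
            "sample_id": "__unassigned__",
            "n_assigned": len(result.unassigned),
            "reasons": ";".join(f"{k}={v}" for k, v in sorted(reasons.items())),
        }
    )
    pd.DataFrame(rows).to_csv(os.path.join(demux_dir, "demux_report.tsv"), sep="\t", index=False)
    io_utils.write_fastq(
        [r for r, _ in result.unassigned], os.path.join(demux_dir, "unassigned.fastq")
    )
    log.info("demux: %d assigned, %d unassigned", result.n_assigned, len(result.unassigned))
    return paths


def _phase_sample(
    sample_id: str,
    reads: list[Read],
    config: PipelineConfig,
    layout: AdornmentLayout,
    sample_index: int,
):
    trimmed = []
    for r in reads:
        t, reason = orient_and_trim(r, layout, config.demux)
        if t is None:
            log.info("phase[%s]: dropped %s (%s)", sample_id, r.id, reason)
        else:
            trimmed.append(t)
    usable, short = length_filter(trimmed, config.demux)
    if short:
        log.info("phase[%s]: %d reads below minimum length", sample_id, len(short))
    phasing_cfg = dataclasses.replace(
        config.phasing, seed=_sample_seed(config.seed, sample_index)
    )
    try:
        clusters = cluster_reads(usable, phasing_cfg)
        raw = clusters_to_haplogroups(sample_id, clusters)
        return filter_haplogroups(raw, phasing_cfg)
    except ValueError as exc:
        raise PipelineError(f"phase[{sample_id}]: {exc}") from exc


def stage_phase(
    config: PipelineConfig,
    sample_fastqs: Optional[dict[str, str]] = None,
    layout: Optional[AdornmentLayout] = None,
) -> dict[str, list]:
    """Cluster each sample's reads into filtered haplogroup consensuses."""
    layout = layout or AdornmentLayout()
    if sample_fastqs is None:
        demux_dir = os.path.join(config.outdir, "demux")
        sheet = io_utils.read_sample_sheet(config.sample_sheet)
        sample_fastqs = {sid: os.path.join(demux_dir, f"{sid}.fastq") for sid in sorted(sheet)}
    phase_dir = os.path.join(config.outdir, "phase")
    os.makedirs(phase_dir, exist_ok=True)
    all_haps: dict[str, list] = {}
    rows = []
    for i, (sid, path) in enumerate(sorted(sample_fastqs.items())):
        reads = io_utils.read_fastq(path)
        haps = _phase_sample(sid, reads, config, layout, i)
        all_haps[sid] = haps
        ratio = coverage_ratio(haps, config.phasing.duplication_threshold)
        io_utils.write_haplogroup_fasta(haps, os.path.join(phase_dir, f"{sid}.haplogroups.fasta"))
        rows.append(
            {
                "sample_id": sid,
                "n_haplogroups": len(haps),
                "supports": ",".join(str(h.support) for h in haps),
                "coverage_ratio": round(ratio.ratio, 3),
                "classification": ratio.classification,
            }
        )
        log.info("phase[%s]: %d haplogroup(s), %s", sid, len(haps), ratio.classification)
    pd.DataFrame(rows).to_csv(os.path.join(phase_dir, "phasing_report.tsv"), sep="\t", index=False)
    return all_haps


def stage_variants(
    config: PipelineConfig,
    all_haps: Optional[dict[str, list]] = None,
) -> dict[str, list[list]]:
    """Align consensuses to the reference and emit normalized variants + VCF."""
    reference = list(io_utils.read_fasta(config.reference).values())[0]
    if all_haps is None:
        phase_dir = os.path.join(config.outdir, "phase")
        all_haps = {}
        for name in sorted(os.listdir(phase_dir)):
            if name.endswith(".haplogroups.fasta"):
                haps = io_utils.read_haplogroup_fasta(os.path.join(phase_dir, name))
                all_haps[name.split(".")[0]] = haps
    var_dir = os.path.join(config.outdir, "variants")
    os.makedirs(var_dir, exist_ok=True)
    per_sample: dict[str, list[list]] = {}
    rows = []
    for sid, haps in sorted(all_haps.items()):
        hap_sets = []
        for h in sorted(haps, key=lambda h: h.index):
            aln = align_to_reference(h.sequence, reference)
            variants = extract_and_normalize(
                aln, reference, masked_ends=config.demux.trim_end_bases
            )
            hap_sets.append(variants)
            for v in variants:
                rows.append(
                    {
                        "sample_id": sid,
                        "haplogroup": h.index,
                        "position": v.position,
                        "class": v.vclass,
                        "hgvs": v.hgvs(),
                        "low_confidence": v.low_confidence,
                    }
                )
        per_sample[sid] = hap_sets
        write_vcf(
            os.path.join(var_dir, f"{sid}.vcf"), sid, reference, hap_sets, contig="locus"
        )
    pd.DataFrame(rows).to_csv(os.path.join(var_dir, "variants.tsv"), sep="\t", index=False)
    return per_sample


def stage_call(
    config: PipelineConfig,
    all_haps: dict[str, list],
    per_sample_variants: dict[str, list[list]],
) -> pd.DataFrame:
    """Star-allele diplotype + phenotype per sample; summary table + JSON."""
    table = io_utils.read_translation_table(config.table)
    evidence = io_utils.read_evidence(config.evidence) if config.evidence else {}
    activities = table.activities()
    report_dir = os.path.join(config.outdir, "reports")
    os.makedirs(report_dir, exist_ok=True)
    rows = []
    for sid in sorted(all_haps):
        haps = all_haps[sid]
        hap_sets = per_sample_variants[sid]
        ratio = coverage_ratio(haps, config.phasing.duplication_threshold)
        calls = [match_haplotype(variants, table) for variants in hap_sets]
        diplo = call_diplotype(calls, ratio, evidence.get(sid))
        diplo = predict_phenotype(diplo, activities, config.cutpoints)
        if len(hap_sets) == 2:
            zyg = classify_zygosity(hap_sets[0], hap_sets[1])
        else:
            zyg = classify_zygosity(hap_sets[0], None)
        sub_ins_del = ";".join(
            "-".join(map(str, class_counts(vs))) for vs in hap_sets
        )
        report = {
            "sample_id": sid,
            "haplogroups": [
                {"index": h.index, "support": h.support, "length": len(h.sequence)}
                for h in haps
            ],
            "coverage_ratio": ratio.ratio,
            "classification": ratio.classification,
            "haplotype_calls": [
                {
                    "allele": c.allele,
                    "exact": c.exact,
                    "n_extra_variants": len(c.extra_variants),
                    "extra_variants": sorted(v.hgvs() for v in c.extra_variants),
                }
                for c in calls
            ],
            "variants": [
                [
                    {"hgvs": v.hgvs(), "class": v.vclass, "zygosity": zyg.per_variant[v],
                     "low_confidence": v.low_confidence}
                    for v in vs
                ]
                for vs in hap_sets
            ],
            "genotype": diplo.genotype_string,
            "copies": [diplo.copies1, diplo.copies2],
            "activity_score": diplo.activity_score,
            "phenotype": diplo.phenotype,
            "caveats": diplo.caveats,
        }
        with open(os.path.join(report_dir, f"{sid}.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        rows.append(
            {
                "sample_id": sid,
                "n_haplogroups": len(haps),
                "supports": ",".join(str(h.support) for h in haps),
                "coverage_ratio": round(ratio.ratio, 3),
                "classification": ratio.classification,
                "sub_ins_del": sub_ins_del,
                "n_het": zyg.n_het,
                "n_hom": zyg.n_hom,
                "genotype": diplo.genotype_string,
                "activity_score": diplo.activity_score,
                "phenotype": diplo.phenotype,
                "caveats": ";".join(diplo.caveats),
            }
        )
        log.info("call[%s]: %s -> %s", sid, diplo.genotype_string, diplo.phenotype)
    summary = pd.DataFrame(rows)
    summary.to_csv(os.path.join(config.outdir, "summary.tsv"), sep="\t", index=False)
    return summary


def run_all(config: PipelineConfig, layout: Optional[AdornmentLayout] = None) -> pd.DataFrame:
    """Demultiplex, phase, call variants and diplotypes for a whole run."""
    os.makedirs(config.outdir, exist_ok=True)
    sample_fastqs = stage_demux(config, layout)
    all_haps = stage_phase(config, sample_fastqs, layout)
    per_sample = stage_variants(config, all_haps)
    return stage_call(config, all_haps, per_sample)


# ---------------------------------------------------------------------------
# validation


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Machine-readable diagnostics for a run configuration; empty == valid."""
    diagnostics: list[dict] = []

    def diag(code: str, message: str) -> None:
        diagnostics.append({"level": "error", "code": code, "message": message})

    for attr in ("reads", "sample_sheet", "reference", "table"):
        path = getattr(config, attr)
        if not os.path.exists(path):
            diag("missing_file", f"{attr} file not found: {path}")
    if config.evidence and not os.path.exists(config.evidence):
        diag("missing_file", f"evidence file not found: {config.evidence}")
    if diagnostics:
        return diagnostics

    sheet = io_utils.read_sample_sheet(config.sample_sheet)
    if not sheet:
        diag("empty_sample_sheet", "sample sheet contains no samples")
    if len(set(sheet.values())) != len(sheet):
        diag("duplicate_barcodes", "sample sheet barcodes are not unique")
    if len({len(b) for b in sheet.values()}) > 1:
        diag("barcode_lengths", "sample sheet barcodes differ in length")

    reference = list(io_utils.read_fasta(config.reference).values())[0]
    try:
        table = io_utils.read_translation_table(config.table)
    except ValueError as exc:
        if "default allele" in str(exc):
            diag("multiple_default_alleles", str(exc))
        else:
            diag("table_invalid", str(exc))
        return diagnostics
    for allele in table.alleles.values():
        try:
            apply_allele(reference, allele)
        except ValueError as exc:
            diag("reference_mismatch", str(exc))
    return diagnostics
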