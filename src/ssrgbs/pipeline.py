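"""End-to-end orchestration of the genotyping pipeline.

Chains demultiplexing, length calling, sequence calling, matrix building and
summary statistics into a single programmatic entry point shared by the CLI
and by validation scripts. All tunable thresholds are carried in
:class:`CallParams`; defaults are the calling thresholds documented in
``length_caller`` and ``sequence_caller``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import config_io, popgen
from .config_io import GenotypeMatrix, MarkerDef, SampleSheet
from .errors import ConfigError
from .length_caller import (LengthGenotype, LengthProfile, call_by_length,
                            render_histogram, tally_lengths)
from .read_prep import ReadAccounting, demultiplex_run
from .sequence_caller import (SequenceAllele, SequenceCall,
                              build_registry_and_matrix, call_sequences,
                              length_matrix_from_registry)


@dataclass
class CallParams:
    """Every tunable threshold of the calling cascade, in one place."""

    trim_threshold: int = 20
    min_overlap: int = 10
    max_mismatch_frac: float = 0.1
    max_primer_mismatch: int = 0
    hom_frac: float = 0.90
    het_joint_frac: float = 0.90
    het_balance: float = 0.20
    min_depth: int = 20
    stutter_ratio: float = 0.75
    hom_base_frac: float = 0.70
    tie_margin: int = 0
    max_missing: float = 0.50

    def validate(self) -> None:
        for name in ("hom_frac", "het_joint_frac", "het_balance",
                     "stutter_ratio", "hom_base_frac", "max_missing",
                     "max_mismatch_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0 and name not in ("het_balance", "max_missing",
                                                   "max_mismatch_frac"):
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass
class PipelineResult:
    accounting: ReadAccounting
    profiles: dict[tuple[str, str], LengthProfile]
    length_genotypes: dict[tuple[str, str], LengthGenotype]
    sequence_calls: dict[tuple[str, str], SequenceCall]
    registry: dict[str, list[SequenceAllele]]
    sequence_matrix: GenotypeMatrix
    length_matrix: GenotypeMatrix  # derived from the registry (refined coding)
    histogram_records: list[dict] = field(default_factory=list)


def run_length_calls(
    files: Mapping[tuple[str, str], Path],
    panel: Sequence[MarkerDef],
    sample_ids: Sequence[str],
    params: CallParams,
) -> tuple[dict[tuple[str, str], LengthProfile],
           dict[tuple[str, str], LengthGenotype], list[dict]]:
    by_name = {m.name: m for m in panel}
    profiles: dict[tuple[str, str], LengthProfile] = {}
    genotypes: dict[tuple[str, str], LengthGenotype] = {}
    records: list[dict] = []
    for sample in sample_ids:
        for marker in panel:
            key = (sample, marker.name)
            seqs = [seq for _, seq in config_io.read_fasta(files[key])] \
                if key in files else []
            profile = tally_lengths(seqs, by_name[marker.name], sample)
            genotype = call_by_length(
                profile, motif_len=marker.motif_len,
                hom_frac=params.hom_frac, het_joint_frac=params.het_joint_frac,
                het_balance=params.het_balance, min_depth=params.min_depth,
                stutter_ratio=params.stutter_ratio,
            )
            profiles[key] = profile
            genotypes[key] = genotype
            records.append(render_histogram(profile, genotype))
    return profiles, genotypes, records


def run_sequence_calls(
    files: Mapping[tuple[str, str], Path],
    panel: Sequence[MarkerDef],
    genotypes: Mapping[tuple[str, str], LengthGenotype],
    params: CallParams,
) -> dict[tuple[str, str], SequenceCall]:
    by_name = {m.name: m for m in panel}
    calls: dict[tuple[str, str], SequenceCall] = {}
    for key, genotype in genotypes.items():
        sample, marker_name = key
        if not genotype.is_called:
            calls[key] = SequenceCall(sample, marker_name, None,
                                      needs_manual=genotype.status.value == "ambiguous",
                                      reason=f"length status {genotype.status.value}")
            continue
        seqs = [seq for _, seq in config_io.read_fasta(files[key])]
        calls[key] = call_sequences(seqs, genotype, by_name[marker_name],
                                    hom_base_frac=params.hom_base_frac,
                                    tie_margin=params.tie_margin)
    return calls


def run_pipeline(sheet: SampleSheet, panel: Sequence[MarkerDef],
                 workdir: str | Path,
                 params: CallParams | None = None) -> PipelineResult:
    """demux -> length calls -> sequence calls -> registry and matrices."""
    params = params or CallParams()
    params.validate()
    workdir = Path(workdir)
    accounting, files = demultiplex_run(
        sheet, panel, workdir / "demux",
        trim_threshold=params.trim_threshold,
        min_overlap=params.min_overlap,
        max_mismatch_frac=params.max_mismatch_frac,
        max_primer_mismatch=params.max_primer_mismatch,
    )
    profiles, genotypes, records = run_length_calls(
        files, panel, sheet.sample_ids, params)
    seq_calls = run_sequence_calls(files, panel, genotypes, params)
    registry, seq_matrix = build_registry_and_matrix(
        seq_calls, sheet.sample_ids, [m.name for m in panel])
    length_matrix = length_matrix_from_registry(registry, seq_matrix)
    return PipelineResult(
        accounting=accounting, profiles=profiles, length_genotypes=genotypes,
        sequence_calls=seq_calls, registry=registry,
        sequence_matrix=seq_matrix, length_matrix=length_matrix,
        histogram_records=records,
    )


def write_outputs(result: PipelineResult, outdir: str | Path,
                  sheet: SampleSheet | None = None) -> dict[str, str]:
    """Write the standard output set; returns {artifact name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    acct_path = outdir / "read_accounting.tsv"
    pd.DataFrame(result.accounting.to_rows()).to_csv(acct_path, sep="\t", index=False)
    outputs["read_accounting"] = str(acct_path)

    hist_path = outdir / "length_histograms.tsv"
    rows = []
    for rec in result.histogram_records:
        rows.append({
            "sample": rec["sample"], "marker": rec["marker"],
            "total": rec["total"],
            "lengths": ",".join(map(str, rec["lengths"])),
            "counts": ",".join(map(str, rec["counts"])),
            "alleles": ",".join(map(str, rec["alleles"])),
            "status": rec["status"],
        })
    pd.DataFrame(rows).to_csv(hist_path, sep="\t", index=False)
    outputs["length_histograms"] = str(hist_path)

    geno_path = outdir / "length_genotypes.tsv"
    rows = []
    for (sample, marker), g in sorted(result.length_genotypes.items()):
        rows.append({
            "sample": sample, "marker": marker,
            "allele1": g.alleles[0] if g.alleles else ".",
            "allele2": g.alleles[1] if len(g.alleles) > 1 else ".",
            "status": g.status.value,
        })
    pd.DataFrame(rows).to_csv(geno_path, sep="\t", index=False)
    outputs["length_genotypes"] = str(geno_path)

    manual_path = outdir / "manual_review_queue.tsv"
    rows = [
        {"sample": c.sample_id, "marker": c.marker, "reason": c.reason}
        for c in sorted(result.sequence_calls.values(),
                        key=lambda c: (c.sample_id, c.marker))
        if c.needs_manual
    ]
    pd.DataFrame(rows, columns=["sample", "marker", "reason"]).to_csv(
        manual_path, sep="\t", index=False)
    outputs["manual_review_queue"] = str(manual_path)

    if any(result.registry.values()):
        fasta_path = outdir / "allele_registry.fasta"
        config_io.write_allele_fasta(result.registry, fasta_path)
        outputs["allele_registry"] = str(fasta_path)

    seq_path = outdir / "matrix_sequence.tsv"
    config_io.write_matrix_tsv(result.sequence_matrix, seq_path)
    outputs["matrix_sequence"] = str(seq_path)
    len_path = outdir / "matrix_length.tsv"
    config_io.write_matrix_tsv(result.length_matrix, len_path)
    outputs["matrix_length"] = str(len_path)

    populations = None
    if sheet is not None:
        populations = {e.sample_id: (e.site_label or e.species_label or "pop1")
                       for e in sheet}
    for coding, matrix in (("sequence", result.sequence_matrix),
                           ("length", result.length_matrix)):
        gpath = outdir / f"genalex_{coding}.txt"
        config_io.export_genalex(matrix, gpath, populations)
        outputs[f"genalex_{coding}"] = str(gpath)
        spath = outdir / f"structure_{coding}.txt"
        config_io.export_structure(matrix, spath, populations)
        outputs[f"structure_{coding}"] = str(spath)
    return outputs


def run_stats(result: PipelineResult, outdir: str | Path,
              max_missing: float = 0.50) -> dict[str, str]:
    """Marker filter, per-locus statistics and distances on both codings."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    for coding, matrix in (("length", result.length_matrix),
                           ("sequence", result.sequence_matrix)):
        filtered, removed = popgen.filter_markers_by_missing(matrix, max_missing)
        stats = popgen.locus_stats_table(filtered)
        stats_path = outdir / f"locus_stats_{coding}.tsv"
        stats.to_csv(stats_path, sep="\t", index=False)
        outputs[f"locus_stats_{coding}"] = str(stats_path)
        if removed:
            pd.Series(removed).to_csv(outdir / f"removed_markers_{coding}.tsv",
                                      index=False, header=["marker"])
        total, mean = popgen.pairwise_allele_distance(filtered)
        dist_path = outdir / f"distance_mean_{coding}.csv"
        mean.to_dataframe().to_csv(dist_path)
        outputs[f"distance_mean_{coding}"] = str(dist_path)
    return outputs
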