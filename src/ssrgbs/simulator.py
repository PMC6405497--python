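"""Synthetic multiplexed SSR amplicon runs with known truth.

Generates a marker panel, a two-population diploid cohort, and per-sample
paired FASTQ files whose reads carry the artifacts the caller must survive:

* PCR stutter — with probability ``stutter_rate`` a read's repeat tract
  loses repeat units (a geometric number of steps, one being most likely);
  expansions by one unit occur at a tenth of that rate, the usual
  contraction bias of slippage;
* i.i.d. per-base substitution errors at ``per_base_error``;
* PCR chimeras — in heterozygotes, with probability ``chimera_rate`` a read
  derives from a template spliced from the two alleles at a uniform
  breakpoint;
* variable per-allele coverage (gamma-Poisson around half the locus mean).

The default parameter set represents a well-behaved tetra/pentanucleotide
amplicon panel: 20 samples x 10 markers, 500x locus coverage, 0.1% base
error, 2% chimeras and a 5% per-read slip probability — the stutter regime
in which the 90%-frequency calling thresholds keep tetra- and
pentanucleotide loci almost entirely in the automatic path, matching how
such panels behave in practice (dinucleotides, simulated with a higher slip
probability, land in manual review instead). Flanking-SNP haplotypes are
shared or private between the two populations, and selected markers carry
homoplasic allele pairs (same length, different flanking sequence).

Everything is driven by one seeded generator: the same config yields
byte-identical FASTQ files.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config_io import (GenotypeMatrix, MarkerDef, SampleEntry, SampleSheet,
                        revcomp, write_marker_panel, write_sample_sheet)
from .errors import ConfigError
from .length_caller import LengthGenotype
from .sequence_caller import SequenceCall

BASES = np.array(list("ACGT"))

TETRA_PENTA_MOTIFS = ("ATCT", "AGAT", "AAAG", "ATGG", "AGGT",
                      "AAGAT", "ATCTG", "AATGG", "ACTCT", "AGATG")
DI_MOTIFS = ("AT", "AC", "AG")


@dataclass
class SimConfig:
    """Study-condition knobs of the synthetic run. ``seed`` is mandatory."""

    seed: int
    n_samples: int = 20
    n_markers: int = 10
    motifs: Sequence[str] = TETRA_PENTA_MOTIFS
    n_populations: int = 2
    repeat_count_range: tuple[int, int] = (8, 14)
    alleles_per_marker: tuple[int, int] = (3, 5)
    n_homoplasy_markers: int = 4  # markers guaranteed a same-length allele pair
    coverage_mean: float = 500.0  # reads per locus per sample
    coverage_shape: float = 50.0  # gamma shape of locus coverage; larger = tighter
    stutter_rate: float = 0.05  # per-read probability of repeat contraction
    stutter_decay: float = 0.75  # geometric P(stop) per extra slipped unit
    expansion_fraction: float = 0.1  # expansion rate = stutter_rate * this
    per_base_error: float = 0.001
    chimera_rate: float = 0.02
    read_length: int = 250
    min_overlap: int = 10
    flank5_range: tuple[int, int] = (120, 150)
    flank3_range: tuple[int, int] = (140, 170)
    primer_length: int = 20
    quality_mean: float = 37.0
    quality_sd: float = 2.0

    def validate(self) -> None:
        for name in ("stutter_rate", "per_base_error", "chimera_rate",
                     "expansion_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.coverage_mean < 1:
            raise ConfigError("coverage_mean must be >= 1")
        if self.n_samples < 1 or self.n_markers < 1:
            raise ConfigError("need at least one sample and one marker")
        if self.seed is None:
            raise ConfigError("seed is mandatory for reproducibility")


@dataclass(frozen=True)
class SimAllele:
    repeat_count: int
    insert: str  # primer-stripped insert sequence
    amplicon: str  # full amplicon including both primer copies

    @property
    def raw_length(self) -> int:
        return len(self.amplicon)


@dataclass
class SimMarker:
    definition: MarkerDef
    flank5: str
    flank3: str
    alleles: list[SimAllele]
    freqs: np.ndarray  # populations x alleles


@dataclass
class TruthRecord:
    sample_id: str
    marker: str
    population: int
    allele1: SimAllele
    allele2: SimAllele


@dataclass
class TruthTable:
    records: dict[tuple[str, str], TruthRecord] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records.values():
            rows.append({
                "sample": rec.sample_id, "marker": rec.marker,
                "population": rec.population,
                "repeat_count_1": rec.allele1.repeat_count,
                "repeat_count_2": rec.allele2.repeat_count,
                "length_1": rec.allele1.raw_length,
                "length_2": rec.allele2.raw_length,
                "insert_1": rec.allele1.insert,
                "insert_2": rec.allele2.insert,
            })
        return pd.DataFrame(rows)

    def length_pair(self, sample: str, marker: str) -> tuple[int, int]:
        rec = self.records[(sample, marker)]
        return tuple(sorted((rec.allele1.raw_length, rec.allele2.raw_length)))

    def insert_pair(self, sample: str, marker: str) -> tuple[str, str]:
        rec = self.records[(sample, marker)]
        return tuple(sorted((rec.allele1.insert, rec.allele2.insert)))


@dataclass
class SimRun:
    config: SimConfig
    panel: list[MarkerDef]
    sample_sheet: SampleSheet
    truth: TruthTable
    outdir: Path
    panel_path: Path
    sample_sheet_path: Path
    truth_path: Path


# ---------------------------------------------------------------------------
# Construction helpers
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int, max_mono: int = 3) -> str:
    """Random sequence with no homopolymer longer than ``max_mono`` (keeps
    flanks from mimicking mononucleotide repeats)."""
    out: list[str] = []
    run = 0
    for _ in range(length):
        choices = BASES if run < max_mono or not out else BASES[BASES != out[-1]]
        base = str(rng.choice(choices))
        run = run + 1 if out and base == out[-1] else 1
        out.append(base)
    return "".join(out)


def _build_marker(rng: np.random.Generator, cfg: SimConfig, index: int,
                  motif: str, with_homoplasy: bool) -> SimMarker:
    name = f"M{index + 1:02d}_{motif}"
    flank5 = _random_dna(rng, int(rng.integers(*cfg.flank5_range)))
    flank3 = _random_dna(rng, int(rng.integers(*cfg.flank3_range)))
    fwd = _random_dna(rng, cfg.primer_length)
    rev = _random_dna(rng, cfg.primer_length)
    definition = MarkerDef(name=name, motif=motif, fwd_primer=fwd, rev_primer=rev,
                           source_species="synthetic")

    n_alleles = int(rng.integers(cfg.alleles_per_marker[0],
                                 cfg.alleles_per_marker[1] + 1))
    lo, hi = cfg.repeat_count_range
    counts = sorted(rng.choice(np.arange(lo, hi + 1), size=n_alleles,
                               replace=False))
    # one or two flanking SNP positions, placed away from flank edges
    n_snps = int(rng.integers(1, 3))
    snp_pos = sorted(rng.choice(np.arange(10, len(flank3) - 10), size=n_snps,
                                replace=False))

    def make_allele(repeat_count: int, hap: tuple[str, ...]) -> SimAllele:
        f3 = list(flank3)
        for pos, base in zip(snp_pos, hap):
            f3[pos] = base
        insert = flank5 + motif * repeat_count + "".join(f3)
        amplicon = fwd + insert + revcomp(rev)
        return SimAllele(repeat_count=repeat_count, insert=insert, amplicon=amplicon)

    ref_hap = tuple(flank3[p] for p in snp_pos)
    alleles: list[SimAllele] = []
    for i, rc in enumerate(counts):
        hap = ref_hap
        if i % 2 == 1:  # alternate haplotypes across the allele series
            hap = tuple(_mutate_base(rng, b) for b in ref_hap)
        alleles.append(make_allele(int(rc), hap))
    if with_homoplasy:
        # a second allele with the same repeat count as the first but a
        # different flanking haplotype: identical length, different sequence
        alt_hap = tuple(_mutate_base(rng, b) for b in ref_hap)
        twin = make_allele(int(counts[0]), alt_hap)
        if twin.insert == alleles[0].insert:  # pragma: no cover - defensive
            raise ConfigError("homoplasy construction failed")
        alleles.append(twin)

    n = len(alleles)
    freqs = rng.dirichlet(np.full(n, 5.0), size=cfg.n_populations)
    if n >= 2 and cfg.n_populations >= 2:
        # make one allele effectively private to population 2
        freqs[0, -1] *= 0.05
        freqs = freqs / freqs.sum(axis=1, keepdims=True)
    return SimMarker(definition=definition, flank5=flank5, flank3=flank3,
                     alleles=alleles, freqs=freqs)


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    return str(rng.choice(BASES[BASES != base]))


def build_panel(cfg: SimConfig, rng: np.random.Generator) -> list[SimMarker]:
    motifs = [cfg.motifs[i % len(cfg.motifs)] for i in range(cfg.n_markers)]
    markers = [
        _build_marker(rng, cfg, i, motifs[i], with_homoplasy=i < cfg.n_homoplasy_markers)
        for i in range(cfg.n_markers)
    ]
    for m in markers:
        for allele in m.alleles:
            if allele.raw_length < m.definition.min_amplicon_len:
                raise ConfigError(
                    f"{m.definition.name}: amplicon {allele.raw_length} bp below "
                    f"the {m.definition.min_amplicon_len} bp length floor"
                )
            if allele.raw_length > 2 * cfg.read_length - cfg.min_overlap:
                raise ConfigError(
                    f"{m.definition.name}: allele amplicon {allele.raw_length} bp "
                    f"exceeds the mergeable span of two {cfg.read_length} bp reads"
                )
            if allele.raw_length < cfg.read_length:
                raise ConfigError(
                    f"{m.definition.name}: amplicon shorter than one read"
                )
    return markers


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

def _apply_stutter(rng: np.random.Generator, cfg: SimConfig, marker: SimMarker,
                   allele: SimAllele) -> str:
    """Template for one read: possibly a slipped copy of the allele."""
    u = rng.random()
    count = allele.repeat_count
    if u < cfg.stutter_rate:
        steps = int(rng.geometric(cfg.stutter_decay))
        count = max(1, count - steps)
    elif u < cfg.stutter_rate * (1.0 + cfg.expansion_fraction):
        count = count + 1
    if count == allele.repeat_count:
        return allele.amplicon
    motif = marker.definition.motif
    insert = marker.flank5 + motif * count + allele.insert[len(marker.flank5) + motif_span(allele, marker):]
    return (marker.definition.fwd_primer + insert
            + revcomp(marker.definition.rev_primer))


def motif_span(allele: SimAllele, marker: SimMarker) -> int:
    return len(marker.definition.motif) * allele.repeat_count


def _chimera_template(rng: np.random.Generator, a: SimAllele, b: SimAllele) -> str:
    span = min(len(a.amplicon), len(b.amplicon))
    breakpoint = int(rng.integers(1, span))
    return a.amplicon[:breakpoint] + b.amplicon[breakpoint:]


def _read_pair(rng: np.random.Generator, cfg: SimConfig,
               template: str) -> tuple[str, list[int], str, list[int]]:
    r1 = template[: cfg.read_length]
    r2 = revcomp(template)[: cfg.read_length]
    reads = []
    for seq in (r1, r2):
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        n_err = rng.binomial(len(arr), cfg.per_base_error)
        if n_err:
            pos = rng.choice(len(arr), size=n_err, replace=False)
            for p in pos:
                current = chr(arr[p])
                arr[p] = ord(_mutate_base(rng, current))
        quals = np.clip(np.rint(rng.normal(cfg.quality_mean, cfg.quality_sd,
                                           size=len(arr))), 2, 40).astype(int)
        reads.append((arr.tobytes().decode("ascii"), quals.tolist()))
    return reads[0][0], reads[0][1], reads[1][0], reads[1][1]


def simulate_run(cfg: SimConfig, outdir: str | Path) -> SimRun:
    """Generate the panel, cohort, paired FASTQ files and truth table."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)

    markers = build_panel(cfg, rng)
    panel = [m.definition for m in markers]
    truth = TruthTable()
    entries: list[SampleEntry] = []

    # two geographic clusters matching the two populations (for Mantel demos)
    pop_centers = [(14.3, 48.3), (16.4, 48.2), (13.0, 47.5), (15.5, 46.9)]

    for i in range(cfg.n_samples):
        sample_id = f"S{i + 1:03d}"
        pop = i * cfg.n_populations // cfg.n_samples
        center = pop_centers[pop % len(pop_centers)]
        lon_lat = (center[0] + float(rng.normal(0, 0.4)),
                   center[1] + float(rng.normal(0, 0.3)))
        r1_path = outdir / "reads" / f"{sample_id}_R1.fastq"
        r2_path = outdir / "reads" / f"{sample_id}_R2.fastq"
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            read_no = 0
            for marker in markers:
                n_alleles = len(marker.alleles)
                picks = rng.choice(n_alleles, size=2, p=marker.freqs[pop])
                a1, a2 = marker.alleles[picks[0]], marker.alleles[picks[1]]
                truth.records[(sample_id, marker.definition.name)] = TruthRecord(
                    sample_id=sample_id, marker=marker.definition.name,
                    population=pop, allele1=a1, allele2=a2,
                )
                # locus coverage is gamma-Poisson; the two alleles of a
                # diploid amplify in the same reaction, so reads split
                # binomially between them rather than varying independently
                lam = rng.gamma(cfg.coverage_shape,
                                cfg.coverage_mean / cfg.coverage_shape)
                n_total = int(rng.poisson(lam))
                n_first = int(rng.binomial(n_total, 0.5))
                for allele, n_reads in ((a1, n_first), (a2, n_total - n_first)):
                    for _ in range(n_reads):
                        if a1.insert != a2.insert and rng.random() < cfg.chimera_rate:
                            other = a2 if allele is a1 else a1
                            template = _chimera_template(rng, allele, other)
                        else:
                            template = _apply_stutter(rng, cfg, marker, allele)
                        s1, q1, s2, q2 = _read_pair(rng, cfg, template)
                        read_no += 1
                        rid = f"{sample_id}.{read_no}"
                        f1.write(f"@{rid}/1\n{s1}\n+\n"
                                 f"{''.join(chr(q + 33) for q in q1)}\n")
                        f2.write(f"@{rid}/2\n{s2}\n+\n"
                                 f"{''.join(chr(q + 33) for q in q2)}\n")
        entries.append(SampleEntry(
            sample_id=sample_id, files=(str(r1_path), str(r2_path)),
            tissue_type="tissue", species_label=f"pop{pop + 1}",
            site_label=f"site{pop + 1}", lon_lat=lon_lat,
        ))

    sheet = SampleSheet(entries)
    panel_path = outdir / "panel.tsv"
    sheet_path = outdir / "samples.tsv"
    truth_path = outdir / "truth.tsv"
    write_marker_panel(panel, panel_path)
    write_sample_sheet(sheet, sheet_path)
    truth.to_dataframe().to_csv(truth_path, sep="\t", index=False)
    return SimRun(config=cfg, panel=panel, sample_sheet=sheet, truth=truth,
                  outdir=outdir, panel_path=panel_path,
                  sample_sheet_path=sheet_path, truth_path=truth_path)


# ---------------------------------------------------------------------------
# Scoring against truth
# ---------------------------------------------------------------------------

@dataclass
class ScoreReport:
    """Strict concordance accounting: ambiguous/flagged and missing cells
    count as non-concordant."""

    n_cells: int = 0
    length_concordant: int = 0
    length_called: int = 0
    length_ambiguous: int = 0
    length_missing: int = 0
    false_het: int = 0  # called het, truth hom
    allele_dropout: int = 0  # called hom, truth het
    n_truth_het: int = 0
    n_truth_hom: int = 0
    seq_cells: int = 0
    seq_concordant: int = 0
    seq_called: int = 0

    @property
    def length_concordance(self) -> float:
        return self.length_concordant / self.n_cells if self.n_cells else 0.0

    @property
    def length_concordance_called(self) -> float:
        return self.length_concordant / self.length_called if self.length_called else 0.0

    @property
    def sequence_concordance(self) -> float:
        return self.seq_concordant / self.seq_cells if self.seq_cells else 0.0

    @property
    def false_het_rate(self) -> float:
        return self.false_het / self.n_truth_hom if self.n_truth_hom else 0.0

    @property
    def allele_dropout_rate(self) -> float:
        return self.allele_dropout / self.n_truth_het if self.n_truth_het else 0.0

    def as_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "length_concordance": self.length_concordance,
            "length_concordance_called": self.length_concordance_called,
            "length_called": self.length_called,
            "length_ambiguous": self.length_ambiguous,
            "length_missing": self.length_missing,
            "sequence_concordance": self.sequence_concordance,
            "sequence_called": self.seq_called,
            "false_het_rate": self.false_het_rate,
            "allele_dropout_rate": self.allele_dropout_rate,
        }


def score_against_truth(
    truth: TruthTable,
    length_genotypes: dict[tuple[str, str], LengthGenotype] | None = None,
    sequence_calls: dict[tuple[str, str], SequenceCall] | None = None,
) -> ScoreReport:
    """Compare called genotypes with the simulated truth, cell by cell."""
    report = ScoreReport()
    for (sample, marker), rec in sorted(truth.records.items()):
        true_lengths = truth.length_pair(sample, marker)
        true_het = true_lengths[0] != true_lengths[1] or rec.allele1.insert != rec.allele2.insert
        report.n_cells += 1
        if true_lengths[0] != true_lengths[1]:
            report.n_truth_het += 1
        else:
            report.n_truth_hom += 1

        if length_genotypes is not None:
            geno = length_genotypes.get((sample, marker))
            if geno is None or geno.status.value == "missing":
                report.length_missing += 1
            elif not geno.is_called:
                report.length_ambiguous += 1
            else:
                report.length_called += 1
                called = tuple(sorted(geno.alleles))
                if called == true_lengths:
                    report.length_concordant += 1
                called_het = called[0] != called[1]
                if called_het and true_lengths[0] == true_lengths[1]:
                    report.false_het += 1
                if not called_het and true_lengths[0] != true_lengths[1]:
                    report.allele_dropout += 1

        if sequence_calls is not None:
            report.seq_cells += 1
            call = sequence_calls.get((sample, marker))
            if call is not None and call.alleles is not None:
                report.seq_called += 1
                if tuple(sorted(call.alleles)) == truth.insert_pair(sample, marker):
                    report.seq_concordant += 1
    return report
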