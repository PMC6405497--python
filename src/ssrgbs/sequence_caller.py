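"""Sequence-based allele definition within called length classes.

Once a length genotype is accepted, reads are partitioned by exact length
into one set per called allele. Because every read in a set has the same
length, positions are directly comparable without alignment: per column the
base frequencies f(b1) >= f(b2) >= f(b3) are computed, a column whose top
base falls below 70% is flagged as a potential SNP, and flagged columns are
phased from the joint base combinations observed on individual reads — the
two most frequent combinations for a length-homozygous sample (which may be
heterozygous at the SNPs), the single most frequent one for a sample already
heterozygous for length. Each unique full sequence per marker then becomes a
numbered allele in a registry, from which the codominant sequence matrix and
its derived length matrix are built.

The ranking approach rests on the assumption that sequencing errors and PCR
chimeras are rarer than reads from real alleles, so true haplotypes win the
count ranking.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .config_io import GenotypeMatrix, MarkerDef
from .errors import ConfigError, PipelineError
from .length_caller import LengthGenotype

IUPAC_TWO_BASE = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


@dataclass(frozen=True)
class BaseColumn:
    """Base tally for one position of a length class (N excluded)."""

    position: int
    base_counts: dict[str, int]
    f_b1: float
    f_b2: float
    f_b3: float

    @property
    def top_bases(self) -> list[str]:
        return sorted(self.base_counts, key=lambda b: (-self.base_counts[b], b))


@dataclass(frozen=True)
class SequenceAllele:
    marker: str
    code: int
    sequence: str  # primer-stripped insert
    length: int  # insert length, bp
    parent_length_allele: int  # raw amplicon length, bp (length-coding scale)


@dataclass
class PhaseResult:
    alleles: list[str]
    needs_manual: bool = False
    reason: str = ""
    snp_positions: list[int] = field(default_factory=list)
    combo_counts: dict[tuple[str, ...], int] = field(default_factory=dict)


def split_by_length(sequences: Sequence[str], genotype: LengthGenotype,
                    marker: MarkerDef) -> dict[int, list[str]]:
    """Partition primer-stripped reads by exact match to the called allele
    lengths (raw-amplicon scale); other lengths are dropped for this step."""
    if not genotype.is_called:
        raise ConfigError("split_by_length needs a called length genotype")
    wanted = {raw: raw - marker.primer_len for raw in genotype.distinct_alleles}
    classes: dict[int, list[str]] = {raw: [] for raw in wanted}
    for seq in sequences:
        for raw, insert_len in wanted.items():
            if len(seq) == insert_len:
                classes[raw].append(seq)
                break
    for raw, seqs in classes.items():
        if not seqs:
            raise PipelineError(
                f"{genotype.sample_id}/{genotype.marker}: called allele {raw} bp "
                "has no exact-length reads (inconsistent upstream tally)"
            )
    return classes


def column_consensus(sequences: Sequence[str],
                     hom_base_frac: float = 0.70) -> tuple[str, list[BaseColumn], list[int]]:
    """Column-wise consensus of an equal-length read set.

    A column whose most frequent base reaches ``hom_base_frac`` (inclusive)
    contributes that base; below the threshold the column is a potential SNP
    and contributes the IUPAC two-base code of its two top bases. Returns
    ``(consensus, columns, flagged_positions)``.
    """
    if not sequences:
        raise ConfigError("column_consensus: empty sequence set")
    width = len(sequences[0])
    if any(len(s) != width for s in sequences):
        raise ConfigError("column_consensus requires equal-length sequences")
    consensus: list[str] = []
    columns: list[BaseColumn] = []
    flagged: list[int] = []
    for pos in range(width):
        counter = Counter(s[pos] for s in sequences)
        counter.pop("N", None)
        total_acgt = sum(counter.values())
        ranked = sorted(counter, key=lambda b: (-counter[b], b))
        freqs = [counter[b] / total_acgt if total_acgt else 0.0 for b in ranked]
        col = BaseColumn(
            position=pos,
            base_counts=dict(counter),
            f_b1=freqs[0] if len(freqs) > 0 else 0.0,
            f_b2=freqs[1] if len(freqs) > 1 else 0.0,
            f_b3=freqs[2] if len(freqs) > 2 else 0.0,
        )
        columns.append(col)
        if total_acgt == 0:
            consensus.append("N")
            continue
        if col.f_b1 >= hom_base_frac or len(ranked) == 1:
            consensus.append(ranked[0])
        else:
            flagged.append(pos)
            pair = frozenset(ranked[:2])
            consensus.append(IUPAC_TWO_BASE.get(pair, "N"))
    return "".join(consensus), columns, flagged


def _substitute(consensus: str, positions: Sequence[int], bases: Sequence[str]) -> str:
    chars = list(consensus)
    for pos, base in zip(positions, bases):
        chars[pos] = base
    return "".join(chars)


def phase_snps(sequences: Sequence[str], flagged_positions: Sequence[int],
               consensus: str, length_het: bool,
               tie_margin: int = 0) -> PhaseResult:
    """Resolve flagged SNP columns into one or two allele sequences.

    Combinations are counted only over reads carrying an unambiguous base at
    every flagged position (linked-SNP haplotypes). A length-heterozygous
    sample contributes a single allele per length class (the most frequent
    combination); a length-homozygous sample takes the two most frequent
    combinations. A tie between the second and third ranked combinations
    (within ``tie_margin`` counts, default strict equality) cannot be
    resolved automatically and flags the genotype for manual resolution.
    """
    positions = sorted(flagged_positions)
    if not positions:
        return PhaseResult(alleles=[consensus])
    combos = Counter()
    for seq in sequences:
        bases = tuple(seq[p] for p in positions)
        if all(b in "ACGT" for b in bases):
            combos[bases] += 1
    if not combos:
        return PhaseResult(alleles=[], needs_manual=True,
                           reason="no read spans all flagged positions",
                           snp_positions=positions)
    ranked = sorted(combos.items(), key=lambda kv: (-kv[1], kv[0]))
    counts = [c for _, c in ranked]

    if length_het:
        if len(ranked) > 1 and counts[0] - counts[1] <= tie_margin:
            return PhaseResult(alleles=[], needs_manual=True,
                               reason="tied top combinations in a length-het class",
                               snp_positions=positions, combo_counts=dict(combos))
        return PhaseResult(
            alleles=[_substitute(consensus, positions, ranked[0][0])],
            snp_positions=positions, combo_counts=dict(combos),
        )

    if len(ranked) == 1:
        # flag arose from N-excluded reads; only one real haplotype observed
        return PhaseResult(alleles=[_substitute(consensus, positions, ranked[0][0])],
                           snp_positions=positions, combo_counts=dict(combos))
    if len(ranked) > 2 and counts[1] - counts[2] <= tie_margin:
        return PhaseResult(alleles=[], needs_manual=True,
                           reason="more than two equally frequent combinations",
                           snp_positions=positions, combo_counts=dict(combos))
    return PhaseResult(
        alleles=[_substitute(consensus, positions, ranked[0][0]),
                 _substitute(consensus, positions, ranked[1][0])],
        snp_positions=positions, combo_counts=dict(combos),
    )


@dataclass
class SequenceCall:
    """Outcome of sequence-level calling for one sample x marker."""

    sample_id: str
    marker: str
    alleles: tuple[str, str] | None  # insert sequences, sorted; None if not called
    parent_lengths: tuple[int, int] | None = None  # raw lengths, aligned to alleles
    needs_manual: bool = False
    reason: str = ""


def call_sequences(sequences: Sequence[str], genotype: LengthGenotype,
                   marker: MarkerDef, hom_base_frac: float = 0.70,
                   tie_margin: int = 0) -> SequenceCall:
    """Run the full per-sample sequence-calling cascade for one marker."""
    if not genotype.is_called:
        return SequenceCall(genotype.sample_id, genotype.marker, None,
                            needs_manual=genotype.status.value == "ambiguous",
                            reason=f"length status {genotype.status.value}")
    classes = split_by_length(sequences, genotype, marker)
    length_het = len(genotype.distinct_alleles) == 2
    alleles: list[str] = []
    parents: list[int] = []
    for raw in genotype.distinct_alleles:
        consensus, _, flagged = column_consensus(classes[raw], hom_base_frac)
        result = phase_snps(classes[raw], flagged, consensus, length_het, tie_margin)
        if result.needs_manual:
            return SequenceCall(genotype.sample_id, genotype.marker, None,
                                needs_manual=True, reason=result.reason)
        alleles.extend(result.alleles)
        parents.extend([raw] * len(result.alleles))
    if len(alleles) == 1:
        alleles *= 2
        parents *= 2
    if len(alleles) != 2:
        raise PipelineError(
            f"{genotype.sample_id}/{genotype.marker}: expected 2 allele sequences, "
            f"got {len(alleles)}"
        )
    order = sorted(range(2), key=lambda i: (parents[i], alleles[i]))
    return SequenceCall(
        genotype.sample_id, genotype.marker,
        alleles=(alleles[order[0]], alleles[order[1]]),
        parent_lengths=(parents[order[0]], parents[order[1]]),
    )


def build_registry_and_matrix(
    calls: Mapping[tuple[str, str], SequenceCall],
    samples: Sequence[str],
    markers: Sequence[str],
) -> tuple[dict[str, list[SequenceAllele]], GenotypeMatrix]:
    """Assign integer codes to unique sequences and build the codominant
    sequence matrix.

    Codes are assigned per marker in first-seen order, scanning samples in
    the given order, so identical inputs always yield identical registries.
    """
    registry: dict[str, list[SequenceAllele]] = {m: [] for m in markers}
    index: dict[str, dict[str, SequenceAllele]] = {m: {} for m in markers}
    matrix = GenotypeMatrix(samples=list(samples), loci=list(markers),
                            coding="sequence")
    for marker in markers:
        for sample in samples:
            call = calls.get((sample, marker))
            if call is None or call.alleles is None:
                continue
            codes = []
            for seq, parent in zip(call.alleles, call.parent_lengths):
                allele = index[marker].get(seq)
                if allele is None:
                    allele = SequenceAllele(
                        marker=marker, code=len(registry[marker]) + 1,
                        sequence=seq, length=len(seq), parent_length_allele=parent,
                    )
                    registry[marker].append(allele)
                    index[marker][seq] = allele
                codes.append(allele.code)
            matrix.set_call(sample, marker, (codes[0], codes[1]))
    return registry, matrix


def length_matrix_from_registry(registry: Mapping[str, Sequence[SequenceAllele]],
                                matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Map each sequence allele to its parent amplicon length, producing the
    parallel length-coded matrix (the sequence partition refines it)."""
    if matrix.coding != "sequence":
        raise ConfigError("expected a sequence-coded matrix")
    lookup = {
        (marker, allele.code): allele.parent_length_allele
        for marker, alleles in registry.items()
        for allele in alleles
    }
    out = GenotypeMatrix(samples=list(matrix.samples), loci=list(matrix.loci),
                         coding="length")
    for (sample, marker), call in matrix.calls.items():
        out.set_call(sample, marker,
                     (lookup[(marker, call[0])], lookup[(marker, call[1])]))
    return out
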