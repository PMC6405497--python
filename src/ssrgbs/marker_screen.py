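"""Screening sequence sets for SSR-containing candidate loci.

Finds maximal perfect tandem repeats of 2-5 bp primitive motifs and applies
the acceptance thresholds used for amplicon marker design: at least 40 bp of
flank on both sides and motif-size-specific minimum repeat counts (10 for
di-, 8 for tri-, 6 for tetra- and pentanucleotides); reads carrying
mononucleotide stretches longer than 6 bp, or interrupted copies of the
candidate motif, are excluded unless explicitly allowed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

DEFAULT_MIN_REPEATS = {2: 10, 3: 8, 4: 6, 5: 6}


@dataclass(frozen=True)
class SsrCandidate:
    read_id: str
    motif: str  # canonical: lexicographically smallest rotation, strand-normalized
    motif_len: int
    repeat_count: int
    start: int  # 0-based half-open run interval within the read
    end: int
    flank5_len: int
    flank3_len: int
    interrupted: bool = False
    max_mononucleotide_run: int = 0

    @property
    def run_length(self) -> int:
        return self.end - self.start


def canonical_motif(unit: str) -> str:
    """Smallest rotation over the unit and its reverse complement."""
    from .config_io import revcomp

    rotations = {unit[i:] + unit[:i] for i in range(len(unit))}
    rc = revcomp(unit)
    rotations |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return min(rotations)


def _is_primitive(unit: str) -> bool:
    m = len(unit)
    for d in range(1, m):
        if m % d == 0 and unit == unit[:d] * (m // d):
            return False
    return True


def max_mono_run(sequence: str) -> int:
    best = run = 0
    prev = ""
    for ch in sequence:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


def _resolve_overlaps(candidates: list[SsrCandidate]) -> list[SsrCandidate]:
    """Keep the longest run among overlapping calls (ties: earlier start,
    then smaller motif)."""
    kept: list[SsrCandidate] = []
    for cand in sorted(candidates,
                       key=lambda c: (-c.run_length, c.start, c.motif_len)):
        if all(cand.end <= k.start or cand.start >= k.end for k in kept):
            kept.append(cand)
    return sorted(kept, key=lambda c: c.start)


def _mark_interrupted(candidates: list[SsrCandidate]) -> list[SsrCandidate]:
    # two nearby runs of the same canonical motif = one interrupted motif
    out = list(candidates)
    for i, a in enumerate(out):
        for j, b in enumerate(out):
            if i == j or a.motif != b.motif:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if 0 <= gap <= a.motif_len:
                out[i] = replace(a, interrupted=True)
                break
    return out


def find_ssrs(sequence: str, read_id: str = "",
              motif_lengths: Iterable[int] = (2, 3, 4, 5),
              min_report: int = 3) -> list[SsrCandidate]:
    """All maximal perfect repeat runs of primitive 2-5 bp motifs.

    A run is maximal when it cannot be extended by a full motif copy on
    either side; only full copies count toward ``repeat_count``. Runs of at
    least ``min_report`` copies are reported, with overlapping calls of
    different motifs resolved to the longest run.
    """
    sequence = sequence.upper()
    n = len(sequence)
    mono = max_mono_run(sequence)
    raw: list[SsrCandidate] = []
    for m in motif_lengths:
        i = 0
        while i + 2 * m <= n:
            if sequence[i + m] != sequence[i]:
                i += 1
                continue
            # leftmost phase of a periodic stretch: count matched positions
            unit = sequence[i: i + m]
            if not _is_primitive(unit) or not set(unit) <= set("ACGT"):
                i += 1
                continue
            j = i + m
            while j < n and sequence[j] == sequence[j - m]:
                j += 1
            copies = (j - i) // m
            if copies >= min_report:
                end = i + copies * m
                raw.append(SsrCandidate(
                    read_id=read_id, motif=canonical_motif(unit), motif_len=m,
                    repeat_count=copies, start=i, end=end,
                    flank5_len=i, flank3_len=n - end,
                    max_mononucleotide_run=mono,
                ))
            # restart after the periodic stretch (any run starting inside it
            # is a sub-run of the same stretch)
            i = j - m + 1
    return _resolve_overlaps(_mark_interrupted(raw))


def filter_candidates(candidates: Sequence[SsrCandidate], min_flank: int = 40,
                      min_repeats: dict[int, int] | None = None,
                      max_mono_run_len: int = 6,
                      allow_interrupted: bool = False) -> list[SsrCandidate]:
    """Apply the marker-design acceptance thresholds.

    The mononucleotide-run screen is evaluated on the whole candidate read
    (the unit of manual exclusion during marker design); ``allow_interrupted``
    relaxes both the interruption and the mononucleotide screens, the
    fallback used when a motif class would otherwise yield too few loci.
    """
    min_repeats = dict(DEFAULT_MIN_REPEATS if min_repeats is None else min_repeats)
    accepted = []
    for c in candidates:
        if c.repeat_count < min_repeats.get(c.motif_len, 6):
            continue
        if c.flank5_len < min_flank or c.flank3_len < min_flank:
            continue
        if not allow_interrupted and (c.interrupted or
                                      c.max_mononucleotide_run > max_mono_run_len):
            continue
        accepted.append(c)
    return accepted


def screen_reads(reads: Iterable[tuple[str, str]], **filter_kwargs) -> list[SsrCandidate]:
    """Convenience wrapper: scan and filter a stream of (read_id, sequence)."""
    out: list[SsrCandidate] = []
    for read_id, seq in reads:
        out.extend(filter_candidates(find_ssrs(seq, read_id), **filter_kwargs))
    return out
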