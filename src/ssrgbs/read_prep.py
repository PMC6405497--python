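"""Quality trimming, read-pair merging and per-locus primer demultiplexing.

The stages mirror the standard amplicon workflow: trim low-quality 3' tails,
merge each read pair over its best ungapped overlap, then assign every merged
read to a marker by requiring the forward primer at the start and the
reverse-complemented reverse primer at the end, in either orientation of the
merged read.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np

from .config_io import MarkerDef, SampleSheet, read_fastq, revcomp, write_fasta
from .errors import ConfigError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Quality trimming
# ---------------------------------------------------------------------------

def quality_trim(sequence: str, qualities: Sequence[int],
                 threshold: int = 20) -> tuple[str, list[int]]:
    """Remove the maximal 3' suffix of bases below ``threshold`` Phred.

    Only the 3' end is trimmed: the 5' end is anchored by the PCR primer and
    must stay intact for primer recognition. May return an empty read.
    """
    if len(sequence) != len(qualities):
        raise ConfigError("sequence and quality lengths differ")
    keep = len(qualities)
    while keep > 0 and qualities[keep - 1] < threshold:
        keep -= 1
    return sequence[:keep], list(qualities[:keep])


# ---------------------------------------------------------------------------
# Pair merging
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _diag_bins(l1: int, l2: int) -> np.ndarray:
    """Flattened anti-diagonal index for an (l1, l2) comparison matrix."""
    i = np.arange(l1)[:, None]
    j = np.arange(l2)[None, :]
    return (j - i + l1 - 1).ravel()


def _overlap_match_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """matches[v-1] = matched bases when the last v of ``a`` align to the
    first v of ``b``, for every overlap v in 1..min(len(a), len(b))."""
    l1, l2 = len(a), len(b)
    eq = (a[:, None] == b[None, :]).ravel()
    sums = np.bincount(_diag_bins(l1, l2), weights=eq, minlength=l1 + l2 - 1)
    return sums[: min(l1, l2)]


def merge_pair(seq1: str, qual1: Sequence[int], seq2: str, qual2: Sequence[int],
               min_overlap: int = 10,
               max_mismatch_frac: float = 0.1) -> tuple[str, list[int]] | None:
    """Merge a read pair over its best ungapped suffix-prefix overlap.

    ``seq2`` is supplied in sequencer orientation and reverse-complemented
    internally. All candidate overlaps are enumerated exactly; among overlaps
    of at least ``min_overlap`` bases with a mismatch fraction of at most
    ``max_mismatch_frac``, the one maximizing the number of matched bases is
    chosen (ties broken toward the longer overlap). Disagreeing bases are
    resolved toward the higher-Phred read (ties toward read 1). Returns
    ``None`` when no overlap qualifies; rejection is a counted outcome, not
    an error.
    """
    rc2 = revcomp(seq2)
    q2 = list(qual2)[::-1]
    l1, l2 = len(seq1), len(rc2)
    if min(l1, l2) < min_overlap or min_overlap < 1:
        return None

    a = np.frombuffer(seq1.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(rc2.encode("ascii"), dtype=np.uint8)
    matches = _overlap_match_counts(a, b)
    v = np.arange(1, len(matches) + 1)
    mismatches = v - matches
    ok = (v >= min_overlap) & (mismatches <= max_mismatch_frac * v)
    if not ok.any():
        return None
    # maximize matched bases, ties toward longer overlap: v is ascending so
    # argmax of (matches, v) lexicographically == last index of max matches.
    cand = np.flatnonzero(ok)
    best = cand[np.argmax(matches[cand] * (len(matches) + 1) + v[cand])]
    bv = int(v[best])

    head = seq1[: l1 - bv]
    qhead = list(qual1[: l1 - bv])
    tail = rc2[bv:]
    qtail = q2[bv:]
    mid_chars: list[str] = []
    mid_quals: list[int] = []
    for t in range(bv):
        c1, c2 = seq1[l1 - bv + t], rc2[t]
        p1, p2 = qual1[l1 - bv + t], q2[t]
        if c1 == c2:
            mid_chars.append(c1)
            mid_quals.append(max(p1, p2))
        elif p2 > p1:
            mid_chars.append(c2)
            mid_quals.append(p2)
        else:
            mid_chars.append(c1)
            mid_quals.append(p1)
    return head + "".join(mid_chars) + tail, qhead + mid_quals + qtail


# ---------------------------------------------------------------------------
# Primer identification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergedRead:
    """A primer-stripped merged amplicon assigned to a marker."""

    sequence: str  # insert, forward-primer orientation, primers removed
    raw_length: int  # bp including both primers
    marker: MarkerDef

    @property
    def insert_length(self) -> int:
        return len(self.sequence)


def _hamming_at_most(a: str, b: str, limit: int) -> bool:
    if len(a) != len(b):
        return False
    if limit == 0:
        return a == b
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def find_primer_matches(sequence: str, panel: Sequence[MarkerDef],
                        max_primer_mismatch: int = 0) -> list[MergedRead]:
    """All (marker, insert) interpretations of a merged read, testing both
    orientations. More than one element signals an ambiguous panel design."""
    out: list[MergedRead] = []
    for oriented in (sequence, revcomp(sequence)):
        for marker in panel:
            fwd = marker.fwd_primer
            tail = revcomp(marker.rev_primer)
            if len(oriented) < len(fwd) + len(tail) + 1:
                continue
            if not _hamming_at_most(oriented[: len(fwd)], fwd, max_primer_mismatch):
                continue
            if not _hamming_at_most(oriented[len(oriented) - len(tail):], tail,
                                    max_primer_mismatch):
                continue
            out.append(MergedRead(sequence=oriented[len(fwd): len(oriented) - len(tail)],
                                  raw_length=len(oriented), marker=marker))
        if out:
            # a palindromic-ish read matching in both orientations is still a
            # single marker assignment when the matches agree
            break
    return out


def assign_to_marker(sequence: str, panel: Sequence[MarkerDef],
                     max_primer_mismatch: int = 0) -> MergedRead | None:
    """Assign a merged read to the unique marker whose primer pair frames it.

    Returns ``None`` on no match or on an ambiguous (multi-marker) match;
    ambiguity is logged because it points at a panel design flaw.
    """
    matches = find_primer_matches(sequence, panel, max_primer_mismatch)
    if len(matches) == 1:
        return matches[0]
    if len(matches) > 1:
        logger.warning(
            "read matches primer pairs of %d markers (%s); rejected as ambiguous",
            len(matches), ",".join(m.marker.name for m in matches),
        )
    return None


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

@dataclass
class SampleAccounting:
    total_pairs: int = 0
    merged: int = 0
    unmerged_discarded: int = 0
    no_primer_discarded: int = 0  # includes ambiguous matches
    ambiguous: int = 0
    per_marker: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        assert self.total_pairs == self.merged + self.unmerged_discarded
        assert self.merged == self.no_primer_discarded + sum(self.per_marker.values())


@dataclass
class ReadAccounting:
    """Read conservation bookkeeping: every input pair ends in exactly one
    category (merged+assigned, merged+no-primer, or unmerged)."""

    samples: dict[str, SampleAccounting] = field(default_factory=dict)

    def check(self) -> None:
        for acct in self.samples.values():
            acct.check()

    def to_rows(self) -> list[dict]:
        rows = []
        for sample, a in self.samples.items():
            row = {
                "sample": sample,
                "total_pairs": a.total_pairs,
                "merged": a.merged,
                "unmerged_discarded": a.unmerged_discarded,
                "no_primer_discarded": a.no_primer_discarded,
                "ambiguous": a.ambiguous,
            }
            row.update({f"assigned_{m}": n for m, n in sorted(a.per_marker.items())})
            rows.append(row)
        return rows


def demultiplex_run(sheet: SampleSheet, panel: Sequence[MarkerDef],
                    outdir: str | Path, *,
                    trim_threshold: int = 20,
                    min_overlap: int = 10,
                    max_mismatch_frac: float = 0.1,
                    max_primer_mismatch: int = 0) -> tuple[ReadAccounting, dict]:
    """Trim, merge and split every sample's reads into per-sample x per-marker
    FASTA files named ``{sample}__{marker}.fasta`` under ``outdir``.

    Samples with a single read file are taken as pre-merged and skip the
    merging stage. Returns the accounting plus a mapping
    ``(sample_id, marker_name) -> file path``; every marker file exists even
    when empty so downstream tallies see explicit zero counts.
    """
    sheet.check_files()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    accounting = ReadAccounting()
    files: dict[tuple[str, str], Path] = {}

    for entry in sheet:
        acct = accounting.samples.setdefault(entry.sample_id, SampleAccounting())
        acct.per_marker = {m.name: 0 for m in panel}
        buffers: dict[str, list[tuple[str, str]]] = {m.name: [] for m in panel}

        paired = len(entry.files) == 2
        stream1 = read_fastq(entry.files[0])
        stream2 = read_fastq(entry.files[1]) if paired else None

        for rec1 in stream1:
            rid, s1, q1 = rec1
            acct.total_pairs += 1
            if paired:
                try:
                    _, s2, q2 = next(stream2)  # type: ignore[arg-type]
                except StopIteration:
                    raise ConfigError(
                        f"sample {entry.sample_id!r}: R2 file shorter than R1"
                    ) from None
                s1, q1 = quality_trim(s1, q1, trim_threshold)
                s2, q2 = quality_trim(s2, q2, trim_threshold)
                merged = merge_pair(s1, q1, s2, q2, min_overlap, max_mismatch_frac)
                if merged is None:
                    acct.unmerged_discarded += 1
                    continue
                mseq = merged[0]
            else:
                mseq, _ = quality_trim(s1, q1, trim_threshold)
            acct.merged += 1
            matches = find_primer_matches(mseq, panel, max_primer_mismatch)
            if len(matches) == 1:
                read = matches[0]
                acct.per_marker[read.marker.name] += 1
                buffers[read.marker.name].append(
                    (f"{entry.sample_id}:{read.marker.name}:{acct.per_marker[read.marker.name]}",
                     read.sequence)
                )
            else:
                acct.no_primer_discarded += 1
                if len(matches) > 1:
                    acct.ambiguous += 1
                    logger.warning(
                        "sample %s read %s matches %d markers; rejected",
                        entry.sample_id, rid, len(matches),
                    )
        if paired and stream2 is not None:
            if next(stream2, None) is not None:
                raise ConfigError(f"sample {entry.sample_id!r}: R2 file longer than R1")

        for marker in panel:
            path = outdir / f"{entry.sample_id}__{marker.name}.fasta"
            write_fasta(buffers[marker.name], path)
            files[(entry.sample_id, marker.name)] = path

    accounting.check()
    return accounting, files
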