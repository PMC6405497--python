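"""Quality trimming, pair merging, primer assignment and demultiplexing."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssrgbs.config_io import MarkerDef, revcomp
from ssrgbs.read_prep import (assign_to_marker, demultiplex_run,
                              find_primer_matches, merge_pair, quality_trim)
from ssrgbs.simulator import SimConfig, simulate_run

# -- quality trimming -------------------------------------------------------


@pytest.mark.parametrize(
    "quals, threshold, kept",
    [
        ([40, 40, 40, 10, 8], 20, 3),   # low-quality suffix removed
        ([40, 40, 40, 40], 20, 4),      # identity when all pass
        ([10, 12, 5], 20, 0),           # everything below threshold
        ([40, 10, 40, 8], 20, 3),       # internal dip kept, suffix trimmed
    ],
)
def test_quality_trim_removes_maximal_low_quality_suffix(quals, threshold, kept):
    seq = "ACGTACGT"[: len(quals)]
    trimmed_seq, trimmed_quals = quality_trim(seq, quals, threshold)
    assert trimmed_seq == seq[:kept]
    assert trimmed_quals == quals[:kept]


@given(st.lists(st.integers(min_value=0, max_value=41), min_size=0, max_size=50))
@settings(deadline=None, max_examples=50)
def test_quality_trim_never_lengthens_and_ends_high(quals):
    seq = "A" * len(quals)
    out_seq, out_quals = quality_trim(seq, quals, 20)
    assert len(out_seq) <= len(seq)
    if out_quals:
        assert out_quals[-1] >= 20


# -- pair merging -----------------------------------------------------------


def _exact_pair(x: str, s: str, y: str, read_len: int | None = None):
    """Construct (read1, read2) covering amplicon x+s+y with overlap s."""
    amplicon = x + s + y
    r1 = x + s
    r2 = revcomp(s + y)
    return r1, [35] * len(r1), r2, [35] * len(r2), amplicon


def test_merge_reconstructs_exact_overlap(rng):
    bases = np.array(list("ACGT"))
    x = "".join(rng.choice(bases, 60))
    s = "".join(rng.choice(bases, 30))
    y = "".join(rng.choice(bases, 55))
    r1, q1, r2, q2, amplicon = _exact_pair(x, s, y)
    merged = merge_pair(r1, q1, r2, q2)
    assert merged is not None
    assert merged[0] == amplicon


def test_merge_rejects_below_min_overlap(rng):
    bases = np.array(list("ACGT"))
    x = "".join(rng.choice(bases, 40))
    s = "".join(rng.choice(bases, 9))  # one short of the 10 bp floor
    y = "".join(rng.choice(bases, 40))
    r1, q1, r2, q2, _ = _exact_pair(x, s, y)
    assert merge_pair(r1, q1, r2, q2) is None
    assert merge_pair(r1, q1, r2, q2, min_overlap=9) is not None


def test_merge_resolves_mismatches_toward_higher_phred():
    x, s, y = "ACGTACGTAC", "AACCGGTTAACCGGTTAACCGGTTAACCGG", "GTCAGTCAGT"
    r1 = x + s
    # mutate two overlap positions on read2, but give read1 higher quality
    s_mut = list(s)
    s_mut[5] = "T" if s[5] != "T" else "G"
    s_mut[20] = "C" if s[20] != "C" else "A"
    r2 = revcomp("".join(s_mut) + y)
    q1 = [38] * len(r1)
    q2 = [15] * len(r2)
    merged = merge_pair(r1, q1, r2, q2)
    assert merged is not None
    assert merged[0] == x + s + y  # read1's bases won at both disagreements


def _enumerate_best_overlap(r1, r2, min_overlap, max_mismatch_frac):
    """Independent oracle: try every overlap, score by matched bases."""
    rc2 = revcomp(r2)
    best = None
    for v in range(min_overlap, min(len(r1), len(rc2)) + 1):
        tail, head = r1[len(r1) - v:], rc2[:v]
        mism = sum(1 for a, b in zip(tail, head) if a != b)
        if mism > max_mismatch_frac * v:
            continue
        score = (v - mism, v)
        if best is None or score > best[0]:
            best = (score, v)
    return best


def test_merge_choice_matches_exhaustive_enumeration(rng):
    """The chosen overlap maximizes matched length among qualifying overlaps,
    including with mismatches present."""
    bases = np.array(list("ACGT"))
    for trial in range(50):
        x = "".join(rng.choice(bases, int(rng.integers(20, 60))))
        s = "".join(rng.choice(bases, int(rng.integers(12, 40))))
        y = "".join(rng.choice(bases, int(rng.integers(20, 60))))
        r1 = x + s
        s_noisy = list(s)
        for pos in rng.choice(len(s), size=rng.integers(0, 3), replace=False):
            s_noisy[pos] = str(rng.choice(bases[bases != s[pos]]))
        r2 = revcomp("".join(s_noisy) + y)
        q1, q2 = [30] * len(r1), [30] * len(r2)
        merged = merge_pair(r1, q1, r2, q2)
        best = _enumerate_best_overlap(r1, r2, 10, 0.1)
        if best is None:
            assert merged is None
        else:
            assert merged is not None
            v = best[1]
            assert len(merged[0]) == len(r1) + len(r2) - v


# -- primer assignment ------------------------------------------------------


@pytest.fixture()
def panel() -> list[MarkerDef]:
    return [
        MarkerDef(name="M1", motif="ATCT", fwd_primer="ACGTACGTACGTACGTACGT",
                  rev_primer="TGCATGCATGCATGCATGCA", min_amplicon_len=0),
        MarkerDef(name="M2", motif="AAT", fwd_primer="GGTTCCAAGGTTCCAAGGTT",
                  rev_primer="CCAATTGGCCAATTGGCCAA", min_amplicon_len=0),
    ]


def _amplicon(marker: MarkerDef, insert: str) -> str:
    return marker.fwd_primer + insert + revcomp(marker.rev_primer)


def test_assign_identifies_marker_and_strips_primers(panel):
    insert = "AATTGGCC" * 5
    read = assign_to_marker(_amplicon(panel[0], insert), panel)
    assert read is not None
    assert read.marker.name == "M1"
    assert read.sequence == insert
    assert read.raw_length == len(insert) + panel[0].primer_len


def test_assign_rejects_wrong_tail(panel):
    seq = panel[0].fwd_primer + "AATTGGCC" * 5 + "TTTTTTTTTTTTTTTTTTTT"
    assert assign_to_marker(seq, panel) is None


def test_assign_orientation_invariant(panel, rng):
    """Reverse-complementing a merged amplicon never changes its assignment."""
    bases = np.array(list("ACGT"))
    for marker in panel:
        for _ in range(20):
            insert = "".join(rng.choice(bases, int(rng.integers(30, 80))))
            fwd = assign_to_marker(_amplicon(marker, insert), panel)
            rev = assign_to_marker(revcomp(_amplicon(marker, insert)), panel)
            assert fwd is not None and rev is not None
            assert fwd.marker.name == rev.marker.name == marker.name
            assert fwd.sequence == rev.sequence == insert


def test_ambiguous_panel_match_rejected(panel):
    # a read framed by M1's forward and M2's... build a true dual match:
    # same primer pair on two markers
    twin = MarkerDef(name="M1b", motif="AT", fwd_primer=panel[0].fwd_primer,
                     rev_primer=panel[0].rev_primer)
    dual_panel = [panel[0], twin]
    seq = _amplicon(panel[0], "AATTGGCC" * 4)
    assert len(find_primer_matches(seq, dual_panel)) == 2
    assert assign_to_marker(seq, dual_panel) is None


def test_primer_mismatch_tolerance(panel):
    seq = _amplicon(panel[0], "AATTGGCC" * 4)
    mutated = "T" + seq[1:]
    assert assign_to_marker(mutated, panel) is None
    read = assign_to_marker(mutated, panel, max_primer_mismatch=1)
    assert read is not None and read.marker.name == "M1"


# -- demultiplexing ---------------------------------------------------------


def test_demultiplex_conservation_and_zero_error_assignment(tmp_path):
    """With the noise model off, every simulated pair is merged and assigned
    to its true marker; the accounting identity holds exactly."""
    cfg = SimConfig(seed=3, n_samples=2, n_markers=2, coverage_mean=60,
                    stutter_rate=0.0, per_base_error=0.0, chimera_rate=0.0)
    run = simulate_run(cfg, tmp_path / "sim")
    accounting, files = demultiplex_run(run.sample_sheet, run.panel,
                                        tmp_path / "demux")
    for sample_id, acct in accounting.samples.items():
        acct.check()
        assert acct.unmerged_discarded == 0
        assert acct.no_primer_discarded == 0
        assert acct.total_pairs == sum(acct.per_marker.values())
        for m in run.panel:
            assert (sample_id, m.name) in files


def test_demultiplex_empty_sample_has_all_marker_files(tmp_path, panel):
    from ssrgbs.config_io import SampleEntry, SampleSheet

    empty = tmp_path / "empty.fastq"
    empty.write_text("")
    sheet = SampleSheet([SampleEntry(sample_id="s1", files=(str(empty),))])
    accounting, files = demultiplex_run(sheet, panel, tmp_path / "out")
    acct = accounting.samples["s1"]
    assert acct.total_pairs == 0
    assert set(acct.per_marker) == {"M1", "M2"}
    assert all(path.exists() for path in files.values())
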