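"""Length-based allele calling with explicit PCR-stutter control.

Per sample and marker, the raw merged-amplicon lengths are tallied and a
genotype is called from the two most frequent lengths (L1, L2) and their
read-count fractions f(L1), f(L2):

* one length holding at least 90% of all retained reads -> homozygote;
* two lengths jointly above 90% whose fractions differ by at most 20
  percentage points -> provisional heterozygote, which is then screened
  against stutter (slippage products one repeat unit short of the template);
* anything else is flagged ambiguous for manual review, mirroring how
  chromatogram-based scoring falls back to a human curator.

The stutter screen distinguishes three cases: (I) the candidate alleles
differ by more than one repeat unit, so neither can be the other's one-step
stutter; (II) they differ by exactly one unit but the shorter is the more
frequent, which a stutter ladder of the longer allele cannot produce alone;
(III) they differ by one unit with the shorter less frequent, in which case
the shorter is accepted as a real allele only when it reaches 75% of the
longer's count — below that it is treated as stutter and the genotype is a
corrected homozygote for the longer allele.

All thresholds are parameters; lengths are raw merged-amplicon lengths with
both primers included, on the same scale as the 300 bp minimum-length filter.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config_io import MarkerDef
from .errors import ConfigError
from .read_prep import MergedRead

logger = logging.getLogger(__name__)


class CallStatus(str, enum.Enum):
    AUTO_HOM = "auto_hom"
    AUTO_HET = "auto_het"
    STUTTER_CORRECTED_HOM = "stutter_corrected_hom"
    AMBIGUOUS = "ambiguous"
    MANUAL = "manual"
    MISSING = "missing"


CALLED_STATUSES = frozenset(
    {CallStatus.AUTO_HOM, CallStatus.AUTO_HET, CallStatus.STUTTER_CORRECTED_HOM,
     CallStatus.MANUAL}
)


@dataclass(frozen=True)
class LengthProfile:
    """Read-count tally by amplicon length for one sample x marker.

    ``counts`` holds only lengths at or above the marker's minimum amplicon
    length. L1/L2 are the two most frequent lengths (ties broken toward the
    longer length), with f_L1/f_L2 their fractions of the retained total.
    """

    sample_id: str
    marker: str
    counts: dict[int, int]
    total: int
    L1: int | None = None
    L2: int | None = None
    f_L1: float = 0.0
    f_L2: float = 0.0


@dataclass(frozen=True)
class LengthGenotype:
    sample_id: str
    marker: str
    alleles: tuple[int, ...]  # () or (a, a) or (short, long)
    status: CallStatus
    support: tuple[int, ...] = ()  # read counts of the called alleles

    @property
    def is_called(self) -> bool:
        return self.status in CALLED_STATUSES

    @property
    def distinct_alleles(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.alleles)))


def profile_from_counts(sample_id: str, marker_name: str,
                        counts: Mapping[int, int],
                        min_len: int = 300) -> LengthProfile:
    """Build a :class:`LengthProfile` from a length -> read-count mapping.

    Lengths below ``min_len`` and zero counts are dropped; L1/L2 ties are
    broken toward the longer length.
    """
    kept = {int(l): int(c) for l, c in counts.items()
            if l >= min_len and c > 0}
    total = sum(kept.values())
    ranked = sorted(kept, key=lambda l: (kept[l], l), reverse=True)
    L1 = ranked[0] if ranked else None
    L2 = ranked[1] if len(ranked) > 1 else None
    return LengthProfile(
        sample_id=sample_id,
        marker=marker_name,
        counts=kept,
        total=total,
        L1=L1,
        L2=L2,
        f_L1=kept[L1] / total if L1 is not None else 0.0,
        f_L2=kept[L2] / total if L2 is not None else 0.0,
    )


def tally_lengths(sequences: Iterable[str | MergedRead], marker: MarkerDef,
                  sample_id: str = "", *,
                  lengths: Iterable[int] | None = None) -> LengthProfile:
    """Tally raw merged-amplicon lengths (primers included).

    ``sequences`` are primer-stripped inserts; both primer lengths are added
    back so lengths are on the raw-amplicon scale. Precomputed raw lengths
    may be passed via ``lengths`` instead. Lengths below
    ``marker.min_amplicon_len`` are excluded before any frequency is formed.
    """
    counts: dict[int, int] = {}
    if lengths is None:
        lengths = (
            (s.raw_length if isinstance(s, MergedRead) else len(s) + marker.primer_len)
            for s in sequences
        )
    for length in lengths:
        counts[length] = counts.get(length, 0) + 1
    return profile_from_counts(sample_id, marker.name, counts,
                               marker.min_amplicon_len)


def stutter_control(profile_or_sample, marker: str | None = None, *,
                    shorter: int, longer: int, count_shorter: int,
                    count_longer: int, motif_len: int,
                    stutter_ratio: float = 0.75) -> LengthGenotype:
    """Screen a provisional two-length heterozygote against stutter.

    See the module docstring for cases I-III. Length differences that are
    not a multiple of the motif but smaller than one unit cannot arise from
    repeat slippage and are accepted as genuine (flank indel) alleles with a
    warning.
    """
    sample_id = profile_or_sample.sample_id if isinstance(profile_or_sample, LengthProfile) else str(profile_or_sample)
    if isinstance(profile_or_sample, LengthProfile):
        marker = profile_or_sample.marker
    if shorter >= longer:
        raise ConfigError("stutter_control requires shorter < longer")
    delta = longer - shorter
    het = LengthGenotype(sample_id, marker, (shorter, longer), CallStatus.AUTO_HET,
                         (count_shorter, count_longer))
    if delta > motif_len:
        return het  # case I: not a one-step stutter relationship
    if delta < motif_len or delta % motif_len != 0:
        logger.warning(
            "%s/%s: allele length difference %d bp is not a motif multiple; "
            "treated as a flanking indel heterozygote", sample_id, marker, delta,
        )
        return het
    if count_shorter > count_longer:
        return het  # case II: stutter of the longer allele cannot dominate it
    if count_shorter >= stutter_ratio * count_longer:
        return het  # case III, at/above the ratio: real allele overlaid by stutter
    return LengthGenotype(sample_id, marker, (longer, longer),
                          CallStatus.STUTTER_CORRECTED_HOM, (count_longer,))


def call_by_length(profile: LengthProfile, *, motif_len: int,
                   hom_frac: float = 0.90, het_joint_frac: float = 0.90,
                   het_balance: float = 0.20, min_depth: int = 20,
                   stutter_ratio: float = 0.75) -> LengthGenotype:
    """Call a length genotype from a tally, chaining the stutter screen.

    The balance rule compares f(L1) - f(L2) in fractions of all retained
    reads (percentage points). The homozygote threshold is inclusive
    (>= hom_frac); the joint heterozygote threshold is strict (> het_joint_frac).
    Profiles below ``min_depth`` retained reads are missing.
    """
    if profile.total < min_depth or profile.L1 is None:
        if 0 < profile.total < min_depth:
            logger.info("%s/%s: %d reads below min_depth=%d -> missing",
                        profile.sample_id, profile.marker, profile.total, min_depth)
        return LengthGenotype(profile.sample_id, profile.marker, (), CallStatus.MISSING)
    if profile.f_L1 >= hom_frac:
        return LengthGenotype(profile.sample_id, profile.marker,
                              (profile.L1, profile.L1), CallStatus.AUTO_HOM,
                              (profile.counts[profile.L1],))
    if (profile.L2 is not None
            and profile.f_L1 + profile.f_L2 > het_joint_frac
            and profile.f_L1 - profile.f_L2 <= het_balance):
        shorter, longer = sorted((profile.L1, profile.L2))
        return stutter_control(
            profile,
            shorter=shorter, longer=longer,
            count_shorter=profile.counts[shorter],
            count_longer=profile.counts[longer],
            motif_len=motif_len, stutter_ratio=stutter_ratio,
        )
    return LengthGenotype(profile.sample_id, profile.marker, (), CallStatus.AMBIGUOUS)


# ---------------------------------------------------------------------------
# Reporting and manual overrides
# ---------------------------------------------------------------------------

def render_histogram(profile: LengthProfile, genotype: LengthGenotype,
                     plot_path: str | Path | None = None) -> dict:
    """Machine-readable histogram record (and optional bar-plot image).

    The record is the curator-facing analogue of a chromatogram trace:
    lengths, counts, the called alleles and the call status.
    """
    record = {
        "sample": profile.sample_id,
        "marker": profile.marker,
        "total": profile.total,
        "lengths": sorted(profile.counts),
        "counts": [profile.counts[l] for l in sorted(profile.counts)],
        "alleles": list(genotype.alleles),
        "status": genotype.status.value,
    }
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3))
        lengths = record["lengths"]
        colors = ["tab:green" if l in genotype.alleles else "tab:gray" for l in lengths]
        ax.bar(lengths, record["counts"], color=colors)
        ax.set_xlabel("amplicon length (bp)")
        ax.set_ylabel("reads")
        ax.set_title(f"{profile.sample_id} / {profile.marker} [{genotype.status.value}]")
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return record


def apply_manual_overrides(
    genotypes: Mapping[tuple[str, str], LengthGenotype],
    overrides: str | Path | pd.DataFrame,
) -> dict[tuple[str, str], LengthGenotype]:
    """Apply a curator's override table (sample, marker, allele1, allele2).

    Overridden calls get status ``manual``; all others are untouched. An
    override naming an unknown sample x marker is a configuration error.
    """
    if not isinstance(overrides, pd.DataFrame):
        overrides = pd.read_csv(overrides, sep=None, engine="python", dtype=str,
                                comment="#")
    out = dict(genotypes)
    for _, row in overrides.iterrows():
        key = (str(row["sample"]).strip(), str(row["marker"]).strip())
        if key not in out:
            raise ConfigError(f"override references unknown sample/marker {key}")
        alleles = tuple(sorted((int(row["allele1"]), int(row["allele2"]))))
        out[key] = LengthGenotype(key[0], key[1], alleles, CallStatus.MANUAL)
        logger.info("manual override for %s/%s -> %s", key[0], key[1], alleles)
    return out
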