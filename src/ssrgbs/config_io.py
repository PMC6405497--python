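"""Readers and writers for every external artifact of the pipeline.

Covers marker panels (TSV/CSV), per-sample FASTQ(.gz), allele FASTA, the
native codominant genotype-matrix TSV, and GenAlEx / STRUCTURE exports.
All writers are deterministic: identical inputs produce byte-identical files.
"""
from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, FormatError

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Marker panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerDef:
    """One amplicon locus: primers, repeat motif and length bookkeeping.

    ``rev_primer`` is stored as synthesized, i.e. in reverse-complement
    orientation relative to the top strand, so a valid merged amplicon reads
    ``fwd_primer + insert + revcomp(rev_primer)``.
    """

    name: str
    motif: str
    fwd_primer: str
    rev_primer: str
    min_amplicon_len: int = 300
    source_species: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("marker name must be non-empty")
        if not (2 <= len(self.motif) <= 5) or not set(self.motif) <= DNA_ALPHABET:
            raise ConfigError(
                f"marker {self.name!r}: motif must be 2-5 bp of A/C/G/T, got {self.motif!r}"
            )
        for label, primer in (("fwd_primer", self.fwd_primer), ("rev_primer", self.rev_primer)):
            if not primer or not set(primer) <= DNA_ALPHABET:
                raise ConfigError(
                    f"marker {self.name!r}: {label} must be non-empty A/C/G/T "
                    f"(IUPAC ambiguity codes are not supported), got {primer!r}"
                )

    @property
    def motif_len(self) -> int:
        return len(self.motif)

    @property
    def primer_len(self) -> int:
        """Total bases contributed by both primers to the raw amplicon length."""
        return len(self.fwd_primer) + len(self.rev_primer)


def load_marker_panel(path: str | Path) -> list[MarkerDef]:
    """Read a tab- or comma-separated marker panel with a header row.

    Required columns: ``name, motif, fwd_primer, rev_primer``. Optional:
    ``min_amplicon_len`` (default 300) and ``source_species``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#",
                         skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse marker panel {path}: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"name", "motif", "fwd_primer", "rev_primer"}
    if missing := required - set(df.columns):
        raise ConfigError(f"marker panel {path} missing columns: {sorted(missing)}")

    markers: list[MarkerDef] = []
    seen: dict[str, int] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        name = str(row["name"]).strip()
        if name in seen:
            raise ConfigError(
                f"duplicate marker name {name!r} (lines {seen[name]} and {line_no})"
            )
        seen[name] = line_no
        kwargs = {}
        if "min_amplicon_len" in df.columns and pd.notna(row.get("min_amplicon_len")):
            kwargs["min_amplicon_len"] = int(row["min_amplicon_len"])
        if "source_species" in df.columns and pd.notna(row.get("source_species")):
            kwargs["source_species"] = str(row["source_species"]).strip()
        try:
            markers.append(
                MarkerDef(
                    name=name,
                    motif=str(row["motif"]).strip().upper(),
                    fwd_primer=str(row["fwd_primer"]).strip().upper(),
                    rev_primer=str(row["rev_primer"]).strip().upper(),
                    **kwargs,
                )
            )
        except ConfigError as exc:
            raise ConfigError(f"marker panel {path} line {line_no}: {exc}") from exc
    if not markers:
        raise ConfigError(f"marker panel {path} contains no markers")
    return markers


def write_marker_panel(markers: Sequence[MarkerDef], path: str | Path) -> None:
    rows = [
        {
            "name": m.name,
            "motif": m.motif,
            "fwd_primer": m.fwd_primer,
            "rev_primer": m.rev_primer,
            "min_amplicon_len": m.min_amplicon_len,
            "source_species": m.source_species,
        }
        for m in markers
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

TISSUE_TYPES = ("tissue", "swab", "other")


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    files: tuple[str, ...]  # one (pre-merged) or two (paired) read files
    tissue_type: str = "other"
    species_label: str | None = None
    site_label: str | None = None
    lon_lat: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ConfigError("sample_id must be non-empty")
        if len(self.files) not in (1, 2):
            raise ConfigError(f"sample {self.sample_id!r}: expected 1 or 2 read files")
        if self.tissue_type not in TISSUE_TYPES:
            raise ConfigError(
                f"sample {self.sample_id!r}: tissue_type must be one of {TISSUE_TYPES}"
            )


@dataclass
class SampleSheet:
    entries: list[SampleEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        if dupes:
            raise ConfigError(f"duplicate sample ids: {dupes}")

    def __iter__(self) -> Iterator[SampleEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def check_files(self) -> None:
        for e in self.entries:
            for f in e.files:
                if not Path(f).is_file():
                    raise ConfigError(f"sample {e.sample_id!r}: missing read file {f}")


def load_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV/CSV sample sheet with columns ``sample_id, file1[, file2,
    tissue_type, species_label, site_label, lon, lat]``."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample_id" not in df.columns or "file1" not in df.columns:
        raise ConfigError(f"sample sheet {path} needs at least sample_id and file1 columns")
    entries = []
    for _, row in df.iterrows():
        files = [str(row["file1"]).strip()]
        if "file2" in df.columns and pd.notna(row.get("file2")) and str(row["file2"]).strip():
            files.append(str(row["file2"]).strip())
        lon_lat = None
        if "lon" in df.columns and "lat" in df.columns and pd.notna(row.get("lon")) and pd.notna(row.get("lat")):
            lon_lat = (float(row["lon"]), float(row["lat"]))
        entries.append(
            SampleEntry(
                sample_id=str(row["sample_id"]).strip(),
                files=tuple(files),
                tissue_type=str(row["tissue_type"]).strip() if "tissue_type" in df.columns and pd.notna(row.get("tissue_type")) else "other",
                species_label=str(row["species_label"]).strip() if "species_label" in df.columns and pd.notna(row.get("species_label")) else None,
                site_label=str(row["site_label"]).strip() if "site_label" in df.columns and pd.notna(row.get("site_label")) else None,
                lon_lat=lon_lat,
            )
        )
    return SampleSheet(entries)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    rows = []
    for e in sheet:
        rows.append(
            {
                "sample_id": e.sample_id,
                "file1": e.files[0],
                "file2": e.files[1] if len(e.files) > 1 else "",
                "tissue_type": e.tissue_type,
                "species_label": e.species_label or "",
                "site_label": e.site_label or "",
                "lon": e.lon_lat[0] if e.lon_lat else "",
                "lat": e.lon_lat[1] if e.lon_lat else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    """Stream ``(read_id, sequence, phred_qualities)`` from a FASTQ(.gz) file.

    Qualities are Sanger Phred+33 integers. A truncated record or a
    sequence/quality length mismatch raises :class:`FormatError` naming the
    record index (0-based).
    """
    path = Path(path)
    index = 0
    with _open_text(path) as handle:
        parser = SeqIO.parse(handle, "fastq")
        while True:
            try:
                record = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(f"{path}: bad FASTQ record at index {index}: {exc}") from exc
            yield record.id, str(record.seq).upper(), record.letter_annotations["phred_quality"]
            index += 1


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write ``(header, sequence)`` pairs as FASTA; returns the record count."""
    n = 0
    with open(path, "w") as out:
        for header, seq in records:
            out.write(f">{header}\n{seq}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    for record in SeqIO.parse(str(path), "fasta"):
        yield record.description, str(record.seq).upper()


def write_allele_fasta(registry: Mapping[str, Sequence], path: str | Path) -> int:
    """Write the per-marker allele registry as FASTA.

    ``registry`` maps marker name to a sequence of objects with ``code``,
    ``sequence`` and ``length`` attributes (see
    :class:`ssrgbs.sequence_caller.SequenceAllele`). Records are emitted in
    (marker name, allele code) order with headers ``{marker}|allele_{code}|len_{bp}``.
    """
    records = []
    for marker in sorted(registry):
        for allele in sorted(registry[marker], key=lambda a: a.code):
            records.append((f"{marker}|allele_{allele.code}|len_{allele.length}", allele.sequence))
    if not records:
        raise ConfigError("nothing to write: allele registry is empty")
    return write_fasta(records, path)


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

Call = tuple[int, int]


@dataclass
class GenotypeMatrix:
    """Codominant samples x loci genotype matrix.

    ``calls`` maps ``(sample_id, locus)`` to an unordered pair of integer
    allele codes (homozygote = same code twice); absent keys are missing
    data. ``coding`` records whether codes are amplicon lengths in bp
    (``"length"``) or registry codes for full sequences (``"sequence"``).
    """

    samples: list[str]
    loci: list[str]
    calls: dict[tuple[str, str], Call] = field(default_factory=dict)
    coding: str = "length"

    def __post_init__(self) -> None:
        if self.coding not in ("length", "sequence"):
            raise ConfigError(f"unknown coding {self.coding!r}")
        for key, call in self.calls.items():
            self._check_call(key, call)

    def _check_call(self, key, call) -> None:
        sample, locus = key
        if sample not in self.samples or locus not in self.loci:
            raise ConfigError(f"call for unknown sample/locus {key}")
        if len(call) != 2:
            raise ConfigError(f"call at {key} must have exactly 2 allele codes")

    def set_call(self, sample: str, locus: str, call: Call | None) -> None:
        if call is None:
            self.calls.pop((sample, locus), None)
            return
        call = tuple(sorted(int(a) for a in call))  # type: ignore[assignment]
        self._check_call((sample, locus), call)
        self.calls[(sample, locus)] = call  # type: ignore[assignment]

    def get(self, sample: str, locus: str) -> Call | None:
        return self.calls.get((sample, locus))

    def missing_fraction(self, locus: str) -> float:
        if not self.samples:
            return 0.0
        n_missing = sum(1 for s in self.samples if (s, locus) not in self.calls)
        return n_missing / len(self.samples)

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeMatrix":
        keep = set(loci)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[l for l in self.loci if l in keep],
            calls={k: v for k, v in self.calls.items() if k[1] in keep},
            coding=self.coding,
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, list] = {}
        for locus in self.loci:
            a1, a2 = [], []
            for s in self.samples:
                call = self.get(s, locus)
                a1.append(call[0] if call else pd.NA)
                a2.append(call[1] if call else pd.NA)
            cols[f"{locus}_1"] = a1
            cols[f"{locus}_2"] = a2
        return pd.DataFrame(cols, index=pd.Index(self.samples, name="sample"))


def write_matrix_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Native matrix format: one row per sample, two columns per locus,
    ``.`` for missing, with the coding recorded on a comment line."""
    with open(path, "w") as out:
        out.write(f"# coding={matrix.coding}\n")
        header = ["sample"]
        for locus in matrix.loci:
            header += [f"{locus}_1", f"{locus}_2"]
        out.write("\t".join(header) + "\n")
        for s in matrix.samples:
            row = [s]
            for locus in matrix.loci:
                call = matrix.get(s, locus)
                row += [str(call[0]), str(call[1])] if call else [".", "."]
            out.write("\t".join(row) + "\n")


def read_matrix_tsv(path: str | Path) -> GenotypeMatrix:
    with open(path) as handle:
        first = handle.readline().strip()
        coding = "length"
        if first.startswith("# coding="):
            coding = first.split("=", 1)[1]
            header = handle.readline().strip().split("\t")
        else:
            header = first.split("\t")
        loci = []
        for col in header[1::2]:
            if not col.endswith("_1"):
                raise FormatError(f"{path}: malformed matrix header column {col!r}")
            loci.append(col[:-2])
        samples, calls = [], {}
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            sample = parts[0]
            samples.append(sample)
            for i, locus in enumerate(loci):
                a1, a2 = parts[1 + 2 * i], parts[2 + 2 * i]
                if a1 != "." and a2 != ".":
                    calls[(sample, locus)] = tuple(sorted((int(a1), int(a2))))
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls, coding=coding)


# ---------------------------------------------------------------------------
# GenAlEx / STRUCTURE exports
# ---------------------------------------------------------------------------

DEFAULT_POP = "pop1"


def _populations_for(matrix: GenotypeMatrix,
                     populations: Mapping[str, str] | None) -> dict[str, str]:
    pops = {}
    for s in matrix.samples:
        pops[s] = (populations or {}).get(s) or DEFAULT_POP
    return pops


def export_genalex(matrix: GenotypeMatrix, path: str | Path,
                   populations: Mapping[str, str] | None = None,
                   title: str = "ssrgbs export") -> None:
    """Write the codominant GenAlEx text layout (missing allele = 0).

    Samples without a population label are assigned to a single default
    population. Population blocks preserve the matrix sample order.
    """
    pops = _populations_for(matrix, populations)
    pop_order = list(dict.fromkeys(pops[s] for s in matrix.samples))
    pop_sizes = {p: sum(1 for s in matrix.samples if pops[s] == p) for p in pop_order}

    with open(path, "w") as out:
        head = [str(len(matrix.loci)), str(len(matrix.samples)), str(len(pop_order))]
        head += [str(pop_sizes[p]) for p in pop_order]
        out.write("\t".join(head) + "\n")
        out.write("\t".join([title, "", ""] + pop_order) + "\n")
        header = ["Sample", "Pop"]
        for locus in matrix.loci:
            header += [locus, ""]
        out.write("\t".join(header) + "\n")
        for pop in pop_order:
            for s in matrix.samples:
                if pops[s] != pop:
                    continue
                row = [s, pop]
                for locus in matrix.loci:
                    call = matrix.get(s, locus)
                    row += [str(call[0]), str(call[1])] if call else ["0", "0"]
                out.write("\t".join(row) + "\n")


def import_genalex(path: str | Path, coding: str = "length") -> GenotypeMatrix:
    """Parse a file written by :func:`export_genalex` (round-trip support)."""
    with open(path) as handle:
        handle.readline()
        handle.readline()
        header = handle.readline().rstrip("\n").split("\t")
        loci = [c for c in header[2:] if c]
        samples, calls = [], {}
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 + 2 * len(loci):
                raise FormatError(f"{path}: truncated GenAlEx row {parts[:2]}")
            sample = parts[0]
            samples.append(sample)
            for i, locus in enumerate(loci):
                a1, a2 = int(parts[2 + 2 * i]), int(parts[3 + 2 * i])
                if a1 != 0 and a2 != 0:
                    calls[(sample, locus)] = tuple(sorted((a1, a2)))
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls, coding=coding)


def export_structure(matrix: GenotypeMatrix, path: str | Path,
                     populations: Mapping[str, str] | None = None) -> None:
    """Write STRUCTURE two-rows-per-individual format (missing allele = -9).

    Populations are encoded as 1-based integers in the second column.
    """
    pops = _populations_for(matrix, populations)
    pop_order = list(dict.fromkeys(pops[s] for s in matrix.samples))
    pop_index = {p: i + 1 for i, p in enumerate(pop_order)}
    with open(path, "w") as out:
        out.write("\t".join(["", ""] + list(matrix.loci)) + "\n")
        for s in matrix.samples:
            for slot in (0, 1):
                row = [s, str(pop_index[pops[s]])]
                for locus in matrix.loci:
                    call = matrix.get(s, locus)
                    row.append(str(call[slot]) if call else "-9")
                out.write("\t".join(row) + "\n")
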