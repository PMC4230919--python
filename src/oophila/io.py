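"""Survey manifest, aligned FASTA, and Newick input/output.

The manifest mirrors the collection-details table of an egg-capsule clone
library survey: one row per sampling event (site/date/host) carrying the
list of sequence accessions obtained from it.  Accession accounting on this
table drives the detection-power stage (per-host clone counts ``n``).
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import dendropy
from Bio import SeqIO

__all__ = [
    "SampleRow",
    "SampleManifest",
    "AlignedSeqSet",
    "ManifestError",
    "AlignmentError",
    "DEFAULT_HOST_VOCABULARY",
    "read_manifest",
    "write_manifest",
    "count_accessions",
    "load_reference_manifest",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "read_newick",
    "write_newick",
]

#: IUPAC nucleotide codes plus the gap symbol; U is normalized to T on ingest.
ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

#: Hosts known to carry egg-capsule algal symbionts in this system, plus the
#: label used for free-living reference strains.  Unknown hosts warn, not fail.
DEFAULT_HOST_VOCABULARY = frozenset(
    {"A. maculatum", "A. gracile", "L. sylvatica", "L. aurora", "Free-living"}
)

# en-dash / unicode-minus normalisation for coordinates and dates
_DASHES = str.maketrans({"−": "-", "–": "-", "—": "-"})


class ManifestError(ValueError):
    """Raised when a survey manifest violates its invariants."""


class AlignmentError(ValueError):
    """Raised on malformed aligned-sequence input."""


@dataclass(frozen=True)
class SampleRow:
    location: str
    code: str
    lon: float
    lat: float
    date: str  # stored verbatim: source tables mix day-first and month-first
    sample_type: str  # "ES" (environmental sequence) or "CI" (cultured isolate)
    host: str
    accessions: tuple[str, ...]


@dataclass
class SampleManifest:
    """Validated survey metadata table; rows preserve input order."""

    rows: list[SampleRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        codes: set[str] = set()
        seen_acc: set[str] = set()
        for i, row in enumerate(self.rows, start=1):
            if row.code in codes:
                raise ManifestError(f"duplicate sample code {row.code!r}")
            codes.add(row.code)
            if not -180.0 <= row.lon <= 180.0:
                raise ManifestError(f"row {i}: longitude {row.lon} out of range")
            if not -90.0 <= row.lat <= 90.0:
                raise ManifestError(f"row {i}: latitude {row.lat} out of range")
            if row.sample_type not in ("ES", "CI"):
                raise ManifestError(
                    f"row {i}: sample type must be ES or CI, got {row.sample_type!r}"
                )
            if not row.accessions:
                raise ManifestError(f"row {i} ({row.code}): empty accession list")
            for acc in row.accessions:
                if not acc:
                    raise ManifestError(f"row {i} ({row.code}): blank accession")
                if acc in seen_acc:
                    raise ManifestError(f"accession {acc!r} listed more than once")
                seen_acc.add(acc)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def hosts(self) -> list[str]:
        return sorted({r.host for r in self.rows})

    def per_host_accession_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for row in self.rows:
            counts[row.host] = counts.get(row.host, 0) + len(row.accessions)
        return counts


#: Default column mapping of the tab-separated manifest dialect.
DEFAULT_DIALECT: dict[str, str] = {
    "location": "Location",
    "code": "Code",
    "lon": "Lon",
    "lat": "Lat",
    "date": "Date",
    "sample_type": "SampleType",
    "host": "Host",
    "accessions": "Accessions",
}

_ACCESSION_SPLIT = re.compile(r"[;,\s]+")


def read_manifest(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    host_vocabulary: Iterable[str] | None = DEFAULT_HOST_VOCABULARY,
) -> SampleManifest:
    """Read a tab-separated survey manifest.

    ``dialect`` maps the canonical field names (location, code, lon, lat,
    date, sample_type, host, accessions) to the file's column headers.
    Accession fields may be separated by semicolons, commas or whitespace;
    accession ranges are never expanded.  Unicode dashes in coordinate and
    date fields are normalised to ASCII hyphens.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    vocab = frozenset(host_vocabulary) if host_vocabulary is not None else None

    rows: list[SampleRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return SampleManifest(rows=[])
        missing = [c for c in cols.values() if c not in reader.fieldnames]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        for lineno, rec in enumerate(reader, start=2):
            def get(key: str) -> str:
                return (rec.get(cols[key]) or "").strip().translate(_DASHES)

            try:
                lon = float(get("lon"))
                lat = float(get("lat"))
            except ValueError as exc:
                raise ManifestError(
                    f"line {lineno}: malformed coordinate ({exc})"
                ) from None
            accessions = tuple(a for a in _ACCESSION_SPLIT.split(get("accessions")) if a)
            host = get("host")
            if vocab is not None and host not in vocab:
                warnings.warn(
                    f"line {lineno}: host {host!r} not in configured vocabulary",
                    stacklevel=2,
                )
            rows.append(
                SampleRow(
                    location=get("location"),
                    code=get("code"),
                    lon=lon,
                    lat=lat,
                    date=get("date"),
                    sample_type=get("sample_type"),
                    host=host,
                    accessions=accessions,
                )
            )
    return SampleManifest(rows=rows)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    """Write a manifest in the default tab-separated dialect (semicolon-joined accessions)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(DEFAULT_DIALECT.values()))
        for row in manifest.rows:
            writer.writerow(
                [
                    row.location,
                    row.code,
                    f"{row.lon:.3f}",
                    f"{row.lat:.3f}",
                    row.date,
                    row.sample_type,
                    row.host,
                    ";".join(row.accessions),
                ]
            )


def count_accessions(
    manifest: SampleManifest,
    predicate: Callable[[SampleRow], bool] | None = None,
) -> int:
    """Number of accessions across rows satisfying ``predicate`` (all rows if None).

    Additive over disjoint predicates: summing counts over a partition of the
    rows reproduces the unfiltered total.
    """
    return sum(
        len(row.accessions)
        for row in manifest.rows
        if predicate is None or predicate(row)
    )


def load_reference_manifest() -> SampleManifest:
    """The packaged transcription of the survey's collection-details table.

    32 rows, 129 accessions: 126 amphibian-derived clone sequences plus three
    culture-collection strains (codes starting with SAG or CCAP).
    """
    res = resources.files("oophila").joinpath("data/amphibian_survey_manifest.tsv")
    with resources.as_file(res) as path:
        return read_manifest(path)


def is_culture_collection(row: SampleRow) -> bool:
    """True for rows of long-term culture-collection strains (SAG/CCAP codes)."""
    return row.code.startswith(("SAG", "CCAP"))


# ---------------------------------------------------------------------------
# aligned FASTA
# ---------------------------------------------------------------------------


@dataclass
class AlignedSeqSet:
    """Equal-length nucleotide rows keyed by unique identifiers."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows must have equal count")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        if self.rows:
            ref_len = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != ref_len:
                    raise AlignmentError(
                        f"ragged alignment: sequence {sid!r} has length "
                        f"{len(row)}, expected {ref_len}"
                    )

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.rows))


def _normalize_residues(sid: str, seq: str) -> str:
    out = seq.upper().replace("U", "T")
    for pos, ch in enumerate(out):
        if ch not in ALPHABET:
            raise AlignmentError(
                f"sequence {sid!r}: illegal character {ch!r} at column {pos + 1}"
            )
    return out


def read_aligned_fasta(path: str | Path) -> AlignedSeqSet:
    """Read an aligned multi-FASTA; uppercases, normalizes U to T, rejects ragged rows."""
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(_normalize_residues(rec.id, str(rec.seq)))
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")
    return AlignedSeqSet(ids=ids, rows=rows)


def write_aligned_fasta(aln: AlignedSeqSet, path: str | Path, width: int = 80) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, row in aln:
            fh.write(f">{sid}\n")
            for start in range(0, len(row), width):
                fh.write(row[start : start + width] + "\n")


def write_phylip(aln: AlignedSeqSet, path: str | Path) -> None:
    """Relaxed sequential PHYLIP export (for external ML/MP tools)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(aln)} {aln.length}\n")
        for sid, row in aln:
            fh.write(f"{sid}  {row}\n")


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)
# ---------------------------------------------------------------------------


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write standard Newick; bootstrap supports appear as internal node labels."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
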