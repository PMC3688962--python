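"""Data model and readers/writers for CNV tables, chromosome sizes and gene tracks.

Internal coordinate convention
------------------------------
Every object in this package uses **0-based, half-open** coordinates.
Published CNV tables are almost always 1-based inclusive, so that is the
default on-disk dialect; :class:`TableDialect` declares the column mapping
and the coordinate convention of a file, and the readers convert on entry.

Chromosome names are normalised to the UCSC ``chr``-prefixed form.
Categorical fields (CNV type, inheritance, sex, diagnosis, discovery
method) are parsed case-insensitively through explicit synonym maps;
unrecognised tokens degrade to ``not_reported``/``unknown`` with a logged
warning rather than failing the load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# -- categorical vocabularies -------------------------------------------------

DUPLICATION = "duplication"
DELETION = "deletion"

INHERITED = "inherited"
DE_NOVO = "de_novo"
NOT_REPORTED = "not_reported"

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

ASD = "ASD"
OTHER = "other"
CONTROL = "control"

GENOME_WIDE = "genome_wide"
TARGETED = "targeted"

_TYPE_SYNONYMS = {
    "duplication": DUPLICATION, "dup": DUPLICATION, "gain": DUPLICATION,
    "amplification": DUPLICATION,
    "deletion": DELETION, "del": DELETION, "loss": DELETION,
}
_INHERITANCE_SYNONYMS = {
    "inherited": INHERITED, "inh": INHERITED, "maternal": INHERITED,
    "paternal": INHERITED, "transmitted": INHERITED,
    "de_novo": DE_NOVO, "de novo": DE_NOVO, "denovo": DE_NOVO, "dn": DE_NOVO,
    "not_reported": NOT_REPORTED, "nr": NOT_REPORTED, "": NOT_REPORTED,
    "na": NOT_REPORTED, "unknown": NOT_REPORTED,
}
_SEX_SYNONYMS = {
    "male": MALE, "m": MALE,
    "female": FEMALE, "f": FEMALE,
    "unknown": UNKNOWN, "": UNKNOWN, "na": UNKNOWN, "nr": UNKNOWN,
}
_DIAGNOSIS_SYNONYMS = {
    "asd": ASD, "autism": ASD, "autistic": ASD, "case": ASD,
    "control": CONTROL, "unaffected": CONTROL, "sibling": CONTROL,
    "other": OTHER,
}
_METHOD_SYNONYMS = {
    "genome_wide": GENOME_WIDE, "genome-wide": GENOME_WIDE,
    "array-cgh": GENOME_WIDE, "snp array": GENOME_WIDE, "snp_array": GENOME_WIDE,
    "targeted": TARGETED, "fish": TARGETED, "qpcr": TARGETED,
}

PROTEIN_CODING = "protein_coding"
NCRNA = "ncRNA"
PSEUDOGENE = "pseudogene"
_BIOTYPE_SYNONYMS = {
    "protein_coding": PROTEIN_CODING, "coding": PROTEIN_CODING,
    "ncrna": NCRNA, "noncoding": NCRNA, "non_coding": NCRNA, "lncrna": NCRNA,
    "pseudogene": PSEUDOGENE, "pseudo": PSEUDOGENE,
}


class CNVFormatError(ValueError):
    """A file-level problem: missing mandatory column, malformed sizes file."""


class CNVValidationError(ValueError):
    """A row-level problem: invalid coordinates, unknown chromosome."""


def normalize_chrom(name: str) -> str:
    """Canonical ``chr``-prefixed chromosome name ('1' and 'chr1' both -> 'chr1')."""
    name = str(name).strip()
    if not name.lower().startswith("chr"):
        return "chr" + name
    return "chr" + name[3:]


def _parse_categorical(value, synonyms: dict, default: str, what: str) -> str:
    token = str(value).strip().lower() if value is not None and not pd.isna(value) else ""
    if token in synonyms:
        return synonyms[token]
    logger.warning("unrecognised %s token %r mapped to %r", what, value, default)
    return default


# -- domain types -------------------------------------------------------------

@dataclass
class CNVRecord:
    """One CNV call: a duplication or deletion in one subject, from one study.

    ``start``/``end`` are internal 0-based half-open; they are ``None`` when
    the source row lacked breakpoints, in which case ``breakpoints_defined``
    is False and the record is dropped by the breakpoint filter downstream.
    """

    record_id: str
    subject_id: str
    study_id: str
    chrom: str
    start: Optional[int]
    end: Optional[int]
    cnv_type: str = DELETION
    inheritance: str = NOT_REPORTED
    sex: str = UNKNOWN
    diagnosis: str = ASD
    discovery_method: str = GENOME_WIDE
    breakpoints_defined: bool = True

    @property
    def length(self) -> Optional[int]:
        if self.start is None or self.end is None:
            return None
        return self.end - self.start

    def replace(self, **kw) -> "CNVRecord":
        return replace(self, **kw)


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes with their lengths in bp."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.names) == 0:
            raise CNVFormatError("no chromosomes in genome build")
        if len(set(self.names)) != len(self.names):
            raise CNVFormatError("duplicate chromosome names in genome build")
        if any(l <= 0 for l in self.lengths):
            raise CNVFormatError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeBuild":
        names = tuple(normalize_chrom(n) for n in sizes)
        return cls(names=names, lengths=tuple(int(v) for v in sizes.values()))

    @property
    def total_length(self) -> int:
        return sum(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[self.names.index(chrom)]
        except ValueError:
            raise CNVValidationError(f"chromosome {chrom!r} not in genome build") from None

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    chrom: str
    start: int
    end: int
    biotype: str = PROTEIN_CODING


@dataclass
class GeneTrack:
    """A flat gene annotation track (no merging of overlapping genes)."""

    genes: list[GeneRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


# -- table dialect ------------------------------------------------------------

#: canonical column names used on disk
CANONICAL_COLUMNS = {
    "record": "record_id", "subject": "subject_id", "study": "study_id",
    "chrom": "chrom", "start": "start", "end": "end", "type": "cnv_type",
    "inheritance": "inheritance", "sex": "sex", "diagnosis": "diagnosis",
    "method": "discovery_method",
}

MANDATORY = ("subject", "study", "chrom", "start", "end", "type")


@dataclass
class TableDialect:
    """Column mapping and coordinate convention of an on-disk CNV table.

    ``columns`` maps the canonical keys (``subject``, ``study``, ``chrom``,
    ``start``, ``end``, ``type``, and optionally ``record``, ``inheritance``,
    ``sex``, ``diagnosis``, ``method``) to the file's column headers.
    ``coords`` is ``"1-based-inclusive"`` (the published-table default) or
    ``"0-based-half-open"``.
    """

    columns: dict[str, str] = field(
        default_factory=lambda: {k: k for k in CANONICAL_COLUMNS})
    coords: str = "1-based-inclusive"

    def __post_init__(self):
        if self.coords not in ("1-based-inclusive", "0-based-half-open"):
            raise CNVFormatError(f"unknown coordinate convention {self.coords!r}")

    @classmethod
    def from_yaml(cls, path) -> "TableDialect":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = {k: k for k in CANONICAL_COLUMNS}
        base.update(raw.get("columns", {}))
        return cls(columns=base, coords=raw.get("coords", "1-based-inclusive"))


# -- readers ------------------------------------------------------------------

def read_cnv_table(path, dialect: TableDialect | None = None) -> list[CNVRecord]:
    """Read a tab-separated CNV table into validated :class:`CNVRecord` s.

    Rows with an empty start or end are retained with
    ``breakpoints_defined=False``; rows whose converted coordinates violate
    ``start < end`` raise :class:`CNVValidationError` naming the rows.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [dialect.columns[c] for c in MANDATORY
               if dialect.columns.get(c, c) not in df.columns]
    if missing:
        raise CNVFormatError(
            f"{path}: missing mandatory column(s) {', '.join(missing)}")

    one_based = dialect.coords == "1-based-inclusive"
    records: list[CNVRecord] = []
    bad_rows: list[int] = []
    col = dialect.columns.get
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))

        def cell(key, default=None):
            name = col(key, key)
            if name in row and not pd.isna(row[name]) and str(row[name]).strip() != "":
                return str(row[name]).strip()
            return default

        start_raw, end_raw = cell("start"), cell("end")
        if start_raw is None or end_raw is None:
            start = end = None
            defined = False
        else:
            start, end = int(float(start_raw)), int(float(end_raw))
            if one_based:
                start -= 1
            defined = True
            if not start < end:
                bad_rows.append(i)

        records.append(CNVRecord(
            record_id=cell("record", f"cnv{i:06d}"),
            subject_id=cell("subject", ""),
            study_id=cell("study", ""),
            chrom=normalize_chrom(cell("chrom", "")),
            start=start, end=end,
            cnv_type=_parse_categorical(cell("type"), _TYPE_SYNONYMS, DELETION, "cnv_type"),
            inheritance=_parse_categorical(
                cell("inheritance", ""), _INHERITANCE_SYNONYMS, NOT_REPORTED, "inheritance"),
            sex=_parse_categorical(cell("sex", ""), _SEX_SYNONYMS, UNKNOWN, "sex"),
            diagnosis=_parse_categorical(
                cell("diagnosis", "asd"), _DIAGNOSIS_SYNONYMS, OTHER, "diagnosis"),
            discovery_method=_parse_categorical(
                cell("method", "genome_wide"), _METHOD_SYNONYMS, GENOME_WIDE, "method"),
            breakpoints_defined=defined,
        ))
    if bad_rows:
        raise CNVValidationError(
            f"{path}: start >= end after coordinate conversion in row(s) "
            + ", ".join(map(str, bad_rows)))
    return records


def write_cnv_table(records: Iterable[CNVRecord], path,
                    dialect: TableDialect | None = None) -> None:
    """Write records as a tab-separated table in the dialect's convention."""
    dialect = dialect or TableDialect()
    one_based = dialect.coords == "1-based-inclusive"
    rows = []
    for r in records:
        start = "" if r.start is None else (r.start + 1 if one_based else r.start)
        end = "" if r.end is None else r.end
        rows.append({
            dialect.columns.get("record", "record"): r.record_id,
            dialect.columns.get("subject", "subject"): r.subject_id,
            dialect.columns.get("study", "study"): r.study_id,
            dialect.columns.get("chrom", "chrom"): r.chrom,
            dialect.columns.get("start", "start"): start,
            dialect.columns.get("end", "end"): end,
            dialect.columns.get("type", "type"): r.cnv_type,
            dialect.columns.get("inheritance", "inheritance"): r.inheritance,
            dialect.columns.get("sex", "sex"): r.sex,
            dialect.columns.get("diagnosis", "diagnosis"): r.diagnosis,
            dialect.columns.get("method", "method"): r.discovery_method,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def records_to_frame(records: Iterable[CNVRecord]) -> pd.DataFrame:
    """Internal-coordinate DataFrame view of a record collection."""
    return pd.DataFrame([r.__dict__ for r in records])


def read_chrom_sizes(path) -> GenomeBuild:
    """Read a two-column UCSC ``chrom.sizes`` file into a :class:`GenomeBuild`."""
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise CNVFormatError(f"{path}:{lineno}: expected two columns")
            try:
                length = int(parts[1])
            except ValueError:
                raise CNVFormatError(
                    f"{path}:{lineno}: non-numeric chromosome length {parts[1]!r}") from None
            if length <= 0:
                raise CNVFormatError(f"{path}:{lineno}: non-positive length {length}")
            names.append(normalize_chrom(parts[0]))
            lengths.append(length)
    return GenomeBuild(names=tuple(names), lengths=tuple(lengths))


def write_chrom_sizes(genome: GenomeBuild, path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(genome.names, genome.lengths):
            fh.write(f"{name}\t{length}\n")


def read_gene_track(path, genome: GenomeBuild | None = None) -> GeneTrack:
    """Read a BED4+ gene track (chrom, start, end, name[, biotype]).

    BED coordinates are already 0-based half-open.  Biotype defaults to
    ``protein_coding`` when the fifth column is absent.  When a genome is
    supplied, coordinates are validated against it.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise CNVFormatError(f"{path}:{lineno}: BED4+ needs >= 4 columns")
            chrom = normalize_chrom(parts[0])
            start, end = int(parts[1]), int(parts[2])
            symbol = parts[3].strip()
            if not symbol:
                raise CNVValidationError(f"{path}:{lineno}: empty gene symbol")
            biotype = PROTEIN_CODING
            if len(parts) >= 5 and parts[4].strip():
                biotype = _parse_categorical(
                    parts[4], _BIOTYPE_SYNONYMS, PROTEIN_CODING, "biotype")
            if genome is not None:
                if chrom not in genome or not (0 <= start < end <= genome.length(chrom)):
                    raise CNVValidationError(
                        f"{path}:{lineno}: coordinates {chrom}:{start}-{end} "
                        "outside genome build")
            genes.append(GeneRecord(symbol, chrom, start, end, biotype))
    return GeneTrack(genes)


def write_gene_track(track: GeneTrack, path) -> None:
    with open(path, "w") as fh:
        for g in track:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}\t{g.biotype}\n")
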