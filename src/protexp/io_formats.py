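"""Readers and writers for the on-disk formats the pipeline consumes.

Supported formats:

* PaxDB-style abundance tables — tab-separated, ``#`` comment header, either
  2 columns (protein id, abundance in ppm) or 3 columns (internal id,
  external string id, abundance), auto-detected by column count.
* FASTA sequence files (via Biopython).
* AAindex1 flat-format physicochemical property files.
* Two-column amino-acid cost tables (a default table ships with the package).

All readers validate eagerly and raise :class:`ParseError` /
:class:`ValidationError` with the offending line number where applicable.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter order.
STANDARD_AA: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Residue order used by the AAindex1 ``I`` block (two rows of ten).
AAINDEX_ORDER: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")

#: Tokens that may appear in sequences but are not standard residues.
NONSTANDARD_AA: frozenset[str] = frozenset("UOBZX")


class ParseError(ValueError):
    """A file could not be parsed in its declared format."""


class ValidationError(ValueError):
    """A file parsed, but its content violates an invariant."""


@dataclass(frozen=True)
class AbundanceRecord:
    """One protein abundance measurement (ppm) for one species."""

    protein_id: str
    abundance: float
    species_id: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be nonempty")
        if self.abundance < 0:
            raise ValidationError(
                f"abundance must be >= 0, got {self.abundance} for {self.protein_id}"
            )


@dataclass(frozen=True)
class PropertyIndex:
    """One AAindex1 entry: 20 numerical values, one per standard residue.

    Entries whose ``I`` block contains ``NA`` are kept for bookkeeping but
    flagged unusable via :attr:`has_missing`; downstream analyses skip them.
    """

    accession: str
    description: str
    values: Mapping[str, float | None]

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("accession must be nonempty")
        if set(self.values) != set(STANDARD_AA):
            raise ValidationError(
                f"{self.accession}: property must cover exactly the 20 standard residues"
            )

    @property
    def has_missing(self) -> bool:
        return any(v is None for v in self.values.values())


@dataclass(frozen=True)
class CostTable:
    """Per-residue biosynthetic cost in high-energy phosphate bonds (~P)."""

    costs: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(STANDARD_AA) - set(self.costs)
        extra = set(self.costs) - set(STANDARD_AA)
        if missing:
            raise ValidationError(f"cost table missing residues: {sorted(missing)}")
        if extra:
            raise ValidationError(f"cost table has non-standard residues: {sorted(extra)}")
        for aa, c in self.costs.items():
            if not c > 0:
                raise ValidationError(f"cost for {aa} must be > 0, got {c}")

    def __getitem__(self, aa: str) -> float:
        return self.costs[aa]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def read_abundance_table(path: str | Path, species_id: str) -> list[AbundanceRecord]:
    """Read a PaxDB-dialect abundance table.

    Lines starting with ``#`` are comments.  Data lines are tab-separated
    with either 2 columns (id, abundance) or 3 columns (internal id,
    external id, abundance); the layout is auto-detected per line by column
    count.  A leading ``taxid.`` prefix on the id is stripped so ids join
    cleanly against FASTA headers.
    """
    records: list[AbundanceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                pid, abund_str = fields
            elif len(fields) == 3:
                _, pid, abund_str = fields
            else:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated columns, got {len(fields)}"
                )
            try:
                abundance = float(abund_str)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric abundance {abund_str!r}"
                ) from exc
            pid = strip_taxid_prefix(pid.strip())
            if pid in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate protein_id {pid!r}")
            seen.add(pid)
            records.append(AbundanceRecord(pid, abundance, species_id))
    return records


def strip_taxid_prefix(protein_id: str) -> str:
    """Drop a leading ``<digits>.`` taxon prefix from a PaxDB protein id."""
    head, sep, tail = protein_id.partition(".")
    if sep and head.isdigit() and tail:
        return tail
    return protein_id


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> upper-cased sequence mapping.

    The id is the header token up to the first whitespace.  Nonstandard
    residues (U/O/B/Z/X) are retained but logged; duplicate ids and empty
    sequences are errors.
    """
    sequences: dict[str, str] = {}
    n_nonstandard = 0
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise ValidationError(f"{path}: empty sequence for id {rec.id!r}")
            if rec.id in sequences:
                raise ValidationError(f"{path}: duplicate id {rec.id!r}")
            bad = set(seq) - set(STANDARD_AA) - NONSTANDARD_AA
            if bad:
                raise ValidationError(
                    f"{path}: id {rec.id!r} contains invalid characters {sorted(bad)}"
                )
            if set(seq) & NONSTANDARD_AA:
                n_nonstandard += 1
            sequences[rec.id] = seq
    if n_nonstandard:
        logger.info("%s: %d sequences contain nonstandard residues", path, n_nonstandard)
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write an id -> sequence mapping as FASTA (UTF-8, ``\\n`` endings)."""
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_aaindex1(path: str | Path) -> list[PropertyIndex]:
    """Parse an AAindex1 flat-format file into :class:`PropertyIndex` entries.

    Each record starts with ``H <accession>``, carries its 20 values in the
    ``I`` block (two rows of ten, residue order ``ARNDCQEGHILKMFPSTWYV``)
    and ends with ``//``.  ``NA`` values are recorded as missing.
    """
    entries: list[PropertyIndex] = []
    accession: str | None = None
    description = ""
    values: list[float | None] = []
    in_i_block = False
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("H "):
                accession = line[2:].strip()
                description = ""
                values = []
                in_i_block = False
            elif line.startswith("D "):
                description = line[2:].strip()
                in_i_block = False
            elif line.startswith("I "):
                in_i_block = True
            elif line.startswith("//"):
                if accession is None:
                    raise ParseError(f"{path}:{lineno}: record terminator before header")
                if len(values) != 20:
                    raise ParseError(
                        f"{path}:{lineno}: record {accession} I block has "
                        f"{len(values)} values, expected 20"
                    )
                entries.append(
                    PropertyIndex(accession, description, dict(zip(AAINDEX_ORDER, values)))
                )
                accession = None
                in_i_block = False
            elif in_i_block and line.strip():
                for tok in line.split():
                    if tok == "NA":
                        values.append(None)
                    else:
                        try:
                            values.append(float(tok))
                        except ValueError as exc:
                            raise ParseError(
                                f"{path}:{lineno}: bad value {tok!r} in I block"
                            ) from exc
            elif line.startswith(("R ", "A ", "T ", "J ", "C ", "* ")):
                in_i_block = False
    if accession is not None:
        raise ParseError(f"{path}: record {accession} missing '//' terminator")
    return entries


def read_cost_table(path: str | Path | None = None) -> CostTable:
    """Read a two-column amino-acid/cost TSV; ``None`` loads the packaged default."""
    if path is None:
        ref = resources.files("protexp.data").joinpath("biosynthetic_cost.tsv")
        text = ref.read_text(encoding="utf-8")
    else:
        with _open_text(path) as fh:
            text = fh.read()
    costs: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"cost table line {lineno}: expected 2 columns")
        aa, cost_str = fields[0].strip(), fields[1].strip()
        try:
            cost = float(cost_str)
        except ValueError as exc:
            raise ParseError(f"cost table line {lineno}: bad cost {cost_str!r}") from exc
        if aa in costs:
            raise ValidationError(f"cost table line {lineno}: duplicate residue {aa!r}")
        costs[aa] = cost
    return CostTable(costs)
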