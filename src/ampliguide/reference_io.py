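"""Reading, writing and partitioning SSU rRNA reference sequences.

Reference sets arrive as FASTA with taxonomy-bearing headers, either in the
SILVA export convention (``accession<space>path;separated;by;semicolons``) or
as plain headers.  On input, sequences are uppercased and the RNA alphabet is
normalized to DNA (U -> T), since curated SSU databases commonly ship RNA.

The host/microeukaryote split used downstream — metazoan and land-plant
("host") clades on one side, protistan and fungal eukaryotes on the other —
is a keyword partition over the taxonomy path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import reverse_complement as _bio_revcomp

logger = logging.getLogger(__name__)

#: IUPAC nucleotide code -> set of concrete bases it stands for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_CODES)

#: Default labels that mark a record as belonging to the host-side clade
#: (metazoa / land plants); SILVA releases differ in spelling, so this is
#: configurable everywhere it is used.
DEFAULT_HOST_KEYWORDS: tuple[str, ...] = ("Metazoa", "Animalia", "Embryophyta")


class FastaParseError(ValueError):
    """A FASTA record could not be parsed into accession + taxonomy."""


class SequenceAlphabetError(ValueError):
    """A sequence contains characters outside the IUPAC DNA alphabet."""


@dataclass(frozen=True)
class TaxonomyPath:
    """An ordered lineage from the root rank down to the deepest label."""

    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("taxonomy path must have at least one level")
        if any(not lvl for lvl in self.levels):
            raise ValueError(f"taxonomy path contains an empty level: {self.levels!r}")
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def species_name(self) -> str:
        """The deepest label in the path, used as the taxon identity."""
        return self.levels[-1]

    @property
    def root(self) -> str:
        return self.levels[0]

    @classmethod
    def from_string(cls, text: str, sep: str = ";") -> "TaxonomyPath":
        levels = tuple(part.strip() for part in text.split(sep) if part.strip())
        return cls(levels)

    def __str__(self) -> str:
        return ";".join(self.levels)


@dataclass(frozen=True)
class ReferenceRecord:
    """One SSU reference sequence together with its taxonomy path."""

    accession: str
    taxonomy: TaxonomyPath
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.accession!r} has an empty sequence")
        bad = set(self.sequence) - IUPAC_ALPHABET
        if bad:
            raise SequenceAlphabetError(
                f"record {self.accession!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    @property
    def species_name(self) -> str:
        return self.taxonomy.species_name


@dataclass
class CladePartition:
    """Host-clade vs microeukaryote split of a reference set."""

    host_records: list[ReferenceRecord]
    micro_records: list[ReferenceRecord]
    selector: list[str] = field(default_factory=list)
    n_dropped: int = 0

    @property
    def host_species(self) -> set[str]:
        return {r.species_name for r in self.host_records}

    @property
    def micro_species(self) -> set[str]:
        return {r.species_name for r in self.micro_records}


def normalize_sequence(seq: str, accession: str = "<unknown>") -> str:
    """Uppercase and convert RNA (U) to DNA (T); validate the alphabet."""
    norm = seq.upper().replace("U", "T")
    bad = set(norm) - IUPAC_ALPHABET
    if bad:
        raise SequenceAlphabetError(
            f"record {accession!r} contains non-IUPAC characters: {sorted(bad)}"
        )
    return norm


def revcomp(seq: str) -> str:
    """Reverse complement with full IUPAC degenerate-code support.

    An involution: ``revcomp(revcomp(s)) == s`` for any IUPAC string.
    """
    s = seq.upper()
    bad = set(s) - IUPAC_ALPHABET
    if bad:
        raise SequenceAlphabetError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return _bio_revcomp(s)


def iupac_match(pattern: str, text: str) -> int:
    """Number of positions where ``text`` falls outside ``pattern``'s code set.

    The pattern may carry degenerate IUPAC codes; a position matches iff the
    text base is one of the concrete bases the pattern code stands for.
    Ambiguity codes in the text therefore never match (conservative).
    """
    if len(pattern) != len(text):
        raise ValueError(
            f"pattern length {len(pattern)} != text length {len(text)}"
        )
    mismatches = 0
    for p, t in zip(pattern, text):
        try:
            allowed = IUPAC_CODES[p]
        except KeyError:
            raise SequenceAlphabetError(f"non-IUPAC code in pattern: {p!r}") from None
        if t not in allowed:
            mismatches += 1
    return mismatches


def read_reference_fasta(path: str | Path, dialect: str = "silva") -> list[ReferenceRecord]:
    """Read a reference FASTA into records, in file order.

    dialect="silva" expects headers ``accession<space>tax;path;...`` and
    raises :class:`FastaParseError` naming the header when the taxonomy part
    is missing; dialect="plain" treats the whole header as a single-level
    taxonomy.
    """
    if dialect not in ("silva", "plain"):
        raise ValueError(f"unknown FASTA dialect: {dialect!r}")
    records: list[ReferenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        if dialect == "silva":
            parts = header.split(None, 1)
            if len(parts) < 2 or not parts[1].strip():
                raise FastaParseError(
                    f"SILVA-dialect header {header!r} lacks a taxonomy path"
                )
            accession = parts[0]
            taxonomy = TaxonomyPath.from_string(parts[1])
        else:
            accession = rec.id
            taxonomy = TaxonomyPath((header,))
        sequence = normalize_sequence(str(rec.seq), accession)
        records.append(ReferenceRecord(accession, taxonomy, sequence))
    return records


def write_reference_fasta(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    """Write records as SILVA-dialect FASTA (one unwrapped line per sequence).

    Deterministic byte-for-byte for a given record list, and a lossless
    round-trip partner of :func:`read_reference_fasta`.
    """
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession} {rec.taxonomy}\n{rec.sequence}\n")


def clade_partition(
    records: Sequence[ReferenceRecord],
    host_keywords: Sequence[str] = DEFAULT_HOST_KEYWORDS,
) -> CladePartition:
    """Split records into host-clade vs microeukaryote sets.

    A record is host-side iff any taxonomy level equals (case-insensitively)
    one of ``host_keywords``; it is microeukaryote-side iff its root level
    indicates Eukaryota and no host keyword matched.  Non-eukaryotes are
    dropped with a logged count.
    """
    if not host_keywords:
        raise ValueError("host_keywords must be non-empty")
    keys = {k.lower() for k in host_keywords}
    host: list[ReferenceRecord] = []
    micro: list[ReferenceRecord] = []
    dropped = 0
    for rec in records:
        levels_lower = [lvl.lower() for lvl in rec.taxonomy.levels]
        if any(lvl in keys for lvl in levels_lower):
            host.append(rec)
        elif "eukaryota" in levels_lower[0]:
            micro.append(rec)
        else:
            dropped += 1
    if dropped:
        logger.info("clade_partition dropped %d non-eukaryote records", dropped)
    return CladePartition(host, micro, selector=list(host_keywords), n_dropped=dropped)
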