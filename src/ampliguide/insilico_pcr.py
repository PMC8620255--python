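"""In-silico PCR: degenerate primer matching and amplicon extraction.

The guide-design search space is the segment a "universal" primer pair would
amplify — for the default pair, the ~380-450 bp V4 region of the 18S rRNA
gene.  Primers may carry IUPAC degenerate codes; matching is exact within
the code sets by default (degeneracy only, no mismatches), with a mismatch
tolerance exposed for sensitivity analysis.

Amplicons are always returned oriented forward-primer -> reverse-primer,
whichever genomic strand carried the forward-primer match, so downstream
site enumeration is strand-closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

from .reference_io import (
    IUPAC_ALPHABET,
    ReferenceRecord,
    TaxonomyPath,
    iupac_match,
    revcomp,
)


@dataclass(frozen=True)
class PrimerPair:
    """A named primer pair, both primers written 5'->3' as synthesized.

    The reverse primer is the reverse complement of its footprint on the
    template plus strand (the usual synthesis convention).
    """

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if len(seq) < 10:
                raise ValueError(f"{label} primer shorter than 10 nt: {seq!r}")
            bad = set(seq.upper()) - IUPAC_ALPHABET
            if bad:
                raise ValueError(f"{label} primer has non-IUPAC codes: {sorted(bad)}")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class AmpliconConstraints:
    """Length window and primer-mismatch tolerance for extraction.

    The window default is deliberately loose ([50, 2000]) so the machinery
    works for arbitrary genes; with the default V4 primer pair, products are
    expected to land around 380-450 bp.
    """

    min_len: int = 50
    max_len: int = 2000
    max_mismatch: int = 0


class PrimerHit(NamedTuple):
    offset: int
    strand: str  # "+" primer matched the given sequence; "-" its revcomp did
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A primer-flanked segment, oriented forward-primer -> reverse-primer.

    ``start``/``end`` are 0-based half-open coordinates on the source plus
    strand; ``source_strand`` is the strand that carried the forward-primer
    match.  ``interior`` is the sub-interval of the amplicon (in amplicon
    coordinates) excluding both primer footprints.
    """

    source_accession: str
    start: int
    end: int
    source_strand: str
    sequence: str
    interior: tuple[int, int]
    taxonomy: TaxonomyPath | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError("amplicon sequence length != interval length")
        lo, hi = self.interior
        if not (0 <= lo <= hi <= len(self.sequence)):
            raise ValueError(f"interior {self.interior} outside [0, {len(self.sequence)})")

    @property
    def source_taxon(self) -> str:
        return self.taxonomy.species_name if self.taxonomy else self.source_accession

    @property
    def interior_sequence(self) -> str:
        lo, hi = self.interior
        return self.sequence[lo:hi]

    @classmethod
    def from_sequence(
        cls,
        sequence: str,
        accession: str = "seq",
        taxonomy: TaxonomyPath | None = None,
    ) -> "Amplicon":
        """Wrap a bare sequence as a full-interior amplicon (no footprints)."""
        return cls(
            source_accession=accession,
            start=0,
            end=len(sequence),
            source_strand="+",
            sequence=sequence.upper(),
            interior=(0, len(sequence)),
            taxonomy=taxonomy,
        )


def find_primer_matches(seq: str, primer: str, max_mismatch: int = 0) -> list[PrimerHit]:
    """All binding offsets of a degenerate primer on both strands of ``seq``.

    Plus-strand hits are direct matches of the primer pattern; minus-strand
    hits are matches of its reverse complement.  Offsets are plus-strand,
    0-based, sorted.  Ambiguity codes in the subject never count as matches.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq = seq.upper()
    n, k = len(seq), len(primer)
    if k > n:
        return []
    patterns = (("+", primer.upper()), ("-", revcomp(primer)))
    hits: list[PrimerHit] = []
    for off in range(n - k + 1):
        window = seq[off : off + k]
        for strand, pat in patterns:
            mm = iupac_match(pat, window)
            if mm <= max_mismatch:
                hits.append(PrimerHit(off, strand, mm))
    return hits


def _plus_strand_amplicons(
    seq: str, primers: PrimerPair, constraints: AmpliconConstraints
) -> list[tuple[int, int]]:
    """Intervals [start, end) of products on the plus orientation of ``seq``.

    The forward primer matches the plus strand directly; the reverse-primer
    footprint on the plus strand is the reverse complement of the reverse
    primer.  Each forward hit is paired with the nearest downstream reverse
    footprint whose product length falls inside the window (innermost
    product — the shortest product dominates PCR).
    """
    mm = constraints.max_mismatch
    fwd = primers.forward
    rev_fp = revcomp(primers.reverse)
    fwd_offsets = [
        h.offset for h in find_primer_matches(seq, fwd, mm) if h.strand == "+"
    ]
    # revcomp(rev_fp) == reverse primer, so "+" hits of rev_fp are the footprint.
    rev_offsets = [
        h.offset for h in find_primer_matches(seq, rev_fp, mm) if h.strand == "+"
    ]
    out: list[tuple[int, int]] = []
    for f in fwd_offsets:
        for r in rev_offsets:
            if r < f + len(fwd):
                continue
            length = r + len(rev_fp) - f
            if length < constraints.min_len:
                continue
            if length <= constraints.max_len:
                out.append((f, r + len(rev_fp)))
            break  # nearest candidate reached the window or overshot it
    return out


def extract_amplicons(
    record: ReferenceRecord,
    primers: PrimerPair,
    constraints: AmpliconConstraints | None = None,
) -> list[Amplicon]:
    """Extract all primer-flanked products from a reference record.

    Both template orientations are scanned; products from minus-strand
    templates are reverse-complemented so every returned sequence reads
    forward-primer -> reverse-primer.  Coordinates stay on the source plus
    strand.  No pairing -> empty list (never an error).
    """
    constraints = constraints or AmpliconConstraints()
    if constraints.min_len < len(primers.forward) + len(primers.reverse):
        raise ValueError("min_len must cover both primer footprints")
    seq = record.sequence
    n = len(seq)
    out: list[Amplicon] = []
    for strand, template in (("+", seq), ("-", revcomp(seq))):
        for s, e in _plus_strand_amplicons(template, primers, constraints):
            if strand == "+":
                start, end = s, e
            else:
                start, end = n - e, n - s
            product = template[s:e]
            out.append(
                Amplicon(
                    source_accession=record.accession,
                    start=start,
                    end=end,
                    source_strand=strand,
                    sequence=product,
                    interior=(len(primers.forward), len(product) - len(primers.reverse)),
                    taxonomy=record.taxonomy,
                )
            )
    out.sort(key=lambda a: (a.start, a.source_strand))
    return out
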