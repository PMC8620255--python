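"""Cas9 guide-site enumeration, off-target screening, and sgRNA templates.

A Cas9-compatible target site is a 20-nt protospacer immediately followed
3' by an NGG PAM, on either strand of the search region.  A site is
*taxon-specific* when its 20-mer occurs (on either strand, exact match by
default) in no microeukaryote reference sequence — PAM context in the
off-target is deliberately not required, the conservative direction for a
depletion assay where cutting the wrong template is the failure mode.

The designers compose amplicon extraction, site enumeration, and k-mer
screening; ranking of the surviving sites (by 1-mismatch near-hit count,
GC balance, then 5'-most position) is a stable, deterministic convenience
ordering, not a cutting-activity model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .insilico_pcr import (
    Amplicon,
    AmpliconConstraints,
    PrimerPair,
    extract_amplicons,
)
from .reference_io import CladePartition, ReferenceRecord, revcomp

_ACGT = frozenset("ACGT")
GUIDE_LEN = 20
PAM_LEN = 3
SITE_LEN = GUIDE_LEN + PAM_LEN


class NoAmpliconError(ValueError):
    """The primer pair does not amplify the supplied host sequences."""


@dataclass(frozen=True)
class GuideSite:
    """One protospacer+PAM occurrence within an amplicon.

    Coordinates are on the amplicon plus strand (the forward-primer
    orientation).  For strand "+" the PAM occupies [end, end+3); for
    strand "-" it occupies [start-3, start) and the protospacer string is
    the minus-strand read.
    """

    protospacer: str
    pam: str
    strand: str
    start: int
    end: int
    source_accession: str
    source_taxon: str

    def __post_init__(self) -> None:
        if len(self.protospacer) != GUIDE_LEN:
            raise ValueError("protospacer must be 20 nt")
        if set(self.protospacer) - _ACGT:
            raise ValueError("protospacer must be unambiguous A/C/G/T")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise ValueError(f"PAM must match NGG, got {self.pam!r}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.end - self.start != GUIDE_LEN:
            raise ValueError("protospacer interval must span 20 nt")

    @property
    def gc_fraction(self) -> float:
        return sum(b in "GC" for b in self.protospacer) / GUIDE_LEN


def enumerate_guide_sites(amplicon: Amplicon, region: str = "interior") -> list[GuideSite]:
    """Every Cas9-compatible 20-nt site in the chosen region, both strands.

    The full 23-nt protospacer+PAM window must lie inside the region;
    windows containing ambiguity codes are skipped (an ambiguous guide is
    not synthesizable).  Sorted by plus-strand coordinate, then strand.
    """
    if region not in ("interior", "full"):
        raise ValueError(f"region must be 'interior' or 'full', got {region!r}")
    s = amplicon.sequence
    lo, hi = amplicon.interior if region == "interior" else (0, len(s))
    sites: list[GuideSite] = []
    for w in range(lo, hi - SITE_LEN + 1):
        window = s[w : w + SITE_LEN]
        if set(window) - _ACGT:
            continue
        # plus strand: protospacer [w, w+20), PAM NGG at [w+20, w+23)
        if window[21:23] == "GG":
            sites.append(
                GuideSite(
                    protospacer=window[:GUIDE_LEN],
                    pam=window[GUIDE_LEN:],
                    strand="+",
                    start=w,
                    end=w + GUIDE_LEN,
                    source_accession=amplicon.source_accession,
                    source_taxon=amplicon.source_taxon,
                )
            )
        # minus strand: PAM on plus coords at [w, w+3) reading CCN,
        # protospacer is the revcomp of [w+3, w+23)
        if window[0:2] == "CC":
            sites.append(
                GuideSite(
                    protospacer=revcomp(window[PAM_LEN:]),
                    pam=revcomp(window[:PAM_LEN]),
                    strand="-",
                    start=w + PAM_LEN,
                    end=w + SITE_LEN,
                    source_accession=amplicon.source_accession,
                    source_taxon=amplicon.source_taxon,
                )
            )
    sites.sort(key=lambda g: (g.start, g.strand))
    return sites


class KmerIndex:
    """Exact-match 20-mer index over a sequence set, both strands.

    Maps every unambiguous 20-mer of every sequence and of its reverse
    complement to the set of ``(accession, species_name, strand)`` sources.
    The raw sequences are retained for exhaustive mismatch scans.
    """

    K = GUIDE_LEN

    def __init__(self) -> None:
        self._map: dict[str, set[tuple[str, str, str]]] = {}
        self._sequences: list[tuple[str, str, str]] = []  # (seq, accession, taxon)

    def __len__(self) -> int:
        return len(self._map)

    def add_sequence(self, seq: str, accession: str, taxon: str) -> None:
        self._sequences.append((seq, accession, taxon))
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for i in range(len(s) - self.K + 1):
                kmer = s[i : i + self.K]
                if set(kmer) - _ACGT:
                    continue
                self._map.setdefault(kmer, set()).add((accession, taxon, strand))

    @classmethod
    def from_sequences(cls, items: Iterable[tuple[str, str, str]]) -> "KmerIndex":
        idx = cls()
        for seq, accession, taxon in items:
            idx.add_sequence(seq, accession, taxon)
        return idx

    @classmethod
    def from_amplicons(cls, amplicons: Iterable[Amplicon]) -> "KmerIndex":
        return cls.from_sequences(
            (a.sequence, a.source_accession, a.source_taxon) for a in amplicons
        )

    @classmethod
    def from_records(cls, records: Iterable[ReferenceRecord]) -> "KmerIndex":
        return cls.from_sequences(
            (r.sequence, r.accession, r.species_name) for r in records
        )

    def query(self, kmer: str) -> set[tuple[str, str, str]]:
        return set(self._map.get(kmer.upper(), ()))

    def scan_with_mismatches(self, kmer: str, max_mismatch: int) -> set[tuple[str, str, str]]:
        """Exhaustive Hamming-distance scan over the stored sequences."""
        kmer = kmer.upper()
        hits: set[tuple[str, str, str]] = set()
        for seq, accession, taxon in self._sequences:
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                for i in range(len(s) - self.K + 1):
                    window = s[i : i + self.K]
                    mm = sum(a != b for a, b in zip(kmer, window))
                    if mm <= max_mismatch:
                        hits.add((accession, taxon, strand))
                        break
        return hits


def build_kmer_index(amplicons: Sequence[Amplicon]) -> KmerIndex:
    """Index every 20-mer (both strands) of the given amplicons."""
    return KmerIndex.from_amplicons(amplicons)


@dataclass(frozen=True)
class SpecificityResult:
    """Outcome of screening one protospacer against an off-target index."""

    protospacer: str
    host_hits: frozenset[str]
    micro_hits: frozenset[tuple[str, str]]  # (species_name, accession)
    verdict: str
    max_mismatch_used: int

    @property
    def is_specific(self) -> bool:
        return self.verdict == "taxon_specific"


def screen_guide(
    protospacer: str,
    micro_index: KmerIndex,
    max_mismatch: int = 0,
    host_index: KmerIndex | None = None,
) -> SpecificityResult:
    """Is this 20-mer absent from every microeukaryote sequence?

    Occurrence on either strand counts as a hit (dsDNA is cut regardless of
    which strand carries the protospacer) and no PAM is required in the
    off-target.  ``max_mismatch > 0`` switches to an exhaustive scan.
    """
    protospacer = protospacer.upper()
    if len(protospacer) != GUIDE_LEN or set(protospacer) - _ACGT:
        raise ValueError(f"protospacer must be 20 nt of A/C/G/T, got {protospacer!r}")
    if max_mismatch == 0:
        raw = micro_index.query(protospacer)
    else:
        raw = micro_index.scan_with_mismatches(protospacer, max_mismatch)
    micro_hits = frozenset((taxon, accession) for accession, taxon, _ in raw)
    host_hits: frozenset[str] = frozenset()
    if host_index is not None:
        host_hits = frozenset(t for _, t, _ in host_index.query(protospacer))
    verdict = "taxon_specific" if not micro_hits else "off_target_micro"
    return SpecificityResult(protospacer, host_hits, micro_hits, verdict, max_mismatch)


def count_near_hits(protospacer: str, index: KmerIndex, distance: int = 1) -> int:
    """Distinct off-target taxa with a Hamming-1 neighbour of the guide.

    Implemented by querying all single-base variants against the exact
    index, so it stays cheap even on large references.  Exact hits are
    excluded (a specific guide has none anyway).
    """
    protospacer = protospacer.upper()
    if distance != 1:
        hits = index.scan_with_mismatches(protospacer, distance)
        exact = index.query(protospacer)
        return len({t for _, t, _ in hits - exact})
    taxa: set[str] = set()
    for i, orig in enumerate(protospacer):
        for base in "ACGT":
            if base == orig:
                continue
            variant = protospacer[:i] + base + protospacer[i + 1 :]
            for _, taxon, _ in index.query(variant):
                taxa.add(taxon)
    return len(taxa)


@dataclass(frozen=True)
class SgRNAScheme:
    """Promoter + scaffold-overlap scheme for sgRNA template assembly."""

    promoter: str
    overlap: str
    require_leading_g: bool = False


@dataclass(frozen=True)
class SgRNATemplateOligo:
    """A synthesizable sgRNA transcription template.

    ``oligo`` decomposes exactly as promoter + [G] + protospacer + overlap,
    the optional G being prepended when the scheme requires a leading G for
    T7 transcription and the protospacer does not start with one.
    """

    protospacer: str
    promoter: str
    overlap: str
    oligo: str
    leading_g_added: bool


def build_sgrna_template(
    protospacer: str, scheme: SgRNAScheme | None = None
) -> SgRNATemplateOligo:
    """Assemble the transcription-template oligo for a 20-nt target site."""
    if scheme is None:
        from .config import get_sgrna_scheme

        scheme = get_sgrna_scheme()
    protospacer = protospacer.upper()
    if len(protospacer) != GUIDE_LEN:
        raise ValueError(f"protospacer must be {GUIDE_LEN} nt, got {len(protospacer)}")
    if set(protospacer) - _ACGT:
        raise ValueError("protospacer must be unambiguous A/C/G/T")
    insert = protospacer
    leading_g = False
    if scheme.require_leading_g and not protospacer.startswith("G"):
        insert = "G" + protospacer
        leading_g = True
    return SgRNATemplateOligo(
        protospacer=protospacer,
        promoter=scheme.promoter,
        overlap=scheme.overlap,
        oligo=scheme.promoter + insert + scheme.overlap,
        leading_g_added=leading_g,
    )


@dataclass(frozen=True)
class DesignHit:
    """One ranked designer output: a deduplicated specific site.

    ``accessions`` aggregates every host record in which the protospacer was
    found; ``site`` is the occurrence in the first such record.
    """

    site: GuideSite
    specificity: SpecificityResult
    accessions: tuple[str, ...]
    near_hits_1mm: int
    gc: float

    @property
    def protospacer(self) -> str:
        return self.site.protospacer


@dataclass(frozen=True)
class DesignParams:
    """Knobs shared by the host and generic-gene designers."""

    region: str = "interior"
    max_mismatch: int = 0
    screen_scope: str = "amplicon"  # or "full_sequence"
    constraints: AmpliconConstraints = field(default_factory=AmpliconConstraints)


def _rank_and_dedup(
    sites: Sequence[GuideSite],
    results: dict[str, SpecificityResult],
    off_index: KmerIndex,
) -> list[DesignHit]:
    """Deduplicate by protospacer (aggregating accessions), then rank.

    Order: fewest 1-mismatch off-target near-hits, GC fraction closest to
    0.5, 5'-most first occurrence, protospacer string as the final
    deterministic tie-break.
    """
    by_proto: dict[str, list[GuideSite]] = {}
    for site in sites:
        by_proto.setdefault(site.protospacer, []).append(site)
    hits: list[DesignHit] = []
    for proto, occurrences in by_proto.items():
        res = results[proto]
        if not res.is_specific:
            continue
        first = occurrences[0]
        accs = tuple(dict.fromkeys(o.source_accession for o in occurrences))
        hits.append(
            DesignHit(
                site=first,
                specificity=res,
                accessions=accs,
                near_hits_1mm=count_near_hits(proto, off_index),
                gc=first.gc_fraction,
            )
        )
    hits.sort(
        key=lambda h: (h.near_hits_1mm, abs(h.gc - 0.5), h.site.start, h.protospacer)
    )
    return hits


def design_for_host(
    host_records: Sequence[ReferenceRecord],
    reference: CladePartition,
    primers: PrimerPair,
    params: DesignParams | None = None,
) -> list[DesignHit]:
    """Design taxon-specific guides for a host against a reference partition.

    Pipeline: extract host amplicons with the primer pair, enumerate
    Cas9-compatible sites in the chosen region, screen each distinct
    protospacer against the microeukaryote side, keep the specific ones,
    deduplicate and rank.  Zero specific sites is a valid (empty) outcome;
    primers that amplify nothing raise :class:`NoAmpliconError`.
    """
    params = params or DesignParams()
    host_amplicons: list[Amplicon] = []
    for rec in host_records:
        host_amplicons.extend(extract_amplicons(rec, primers, params.constraints))
    if not host_amplicons:
        raise NoAmpliconError(
            f"primers {primers.name!r} do not amplify any supplied host sequence"
        )
    micro_index = _micro_index(reference, primers, params)
    sites: list[GuideSite] = []
    for amp in host_amplicons:
        sites.extend(enumerate_guide_sites(amp, region=params.region))
    results = {
        proto: screen_guide(proto, micro_index, params.max_mismatch)
        for proto in dict.fromkeys(s.protospacer for s in sites)
    }
    return _rank_and_dedup(sites, results, micro_index)


def _micro_index(
    reference: CladePartition, primers: PrimerPair, params: DesignParams
) -> KmerIndex:
    if params.screen_scope == "full_sequence":
        return KmerIndex.from_records(reference.micro_records)
    micro_amplicons: list[Amplicon] = []
    for rec in reference.micro_records:
        micro_amplicons.extend(extract_amplicons(rec, primers, params.constraints))
    return KmerIndex.from_amplicons(micro_amplicons)


def design_for_gene(
    target: ReferenceRecord,
    background: Sequence[ReferenceRecord],
    params: DesignParams | None = None,
) -> list[DesignHit]:
    """Design guides for an arbitrary gene against a background sequence set.

    No primer step: the whole target sequence is the search region, and the
    background records are indexed in full.  Useful for depleting any
    dominant sequence (other rRNA genes, COX1, ...) given a reference set
    to certify specificity against.
    """
    params = params or DesignParams(region="full")
    amplicon = Amplicon.from_sequence(
        target.sequence, accession=target.accession, taxonomy=target.taxonomy
    )
    background_index = KmerIndex.from_records(background)
    sites = enumerate_guide_sites(amplicon, region="full")
    results = {
        proto: screen_guide(proto, background_index, params.max_mismatch)
        for proto in dict.fromkeys(s.protospacer for s in sites)
    }
    return _rank_and_dedup(sites, results, background_index)
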