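"""Two-step cut / PCR / size-selection depletion simulation and fixtures.

Models the selective-depletion workflow as a per-molecule process: in each
round, every intact molecule whose amplicon carries at least one guide
match is cut independently with a fixed per-round efficiency; a cut
molecule loses one primer footprint on each fragment, cannot re-amplify,
and is removed at the size-selection step.  Molecules with no guide match
are never touched.  Under this model the expected residual host fraction
after r rounds is (1 - efficiency)^r, the closed form the observed counts
are reported against.

The module also houses the synthetic reference generator: seeded host and
microeukaryote record sets whose amplicon interiors are built over a
PAM-free backbone alphabet, with known taxon-specific and shared
protospacers planted at known positions.  The planted truth table makes
exact-recovery tests of the whole design pipeline possible without any
external database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .guide_design import GuideSite
from .insilico_pcr import AmpliconConstraints, PrimerPair, extract_amplicons
from .reference_io import IUPAC_CODES, ReferenceRecord, TaxonomyPath, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CutModel:
    """Parameters of the cut / size-selection process.

    ``efficiency`` is the per-round, per-molecule probability that a
    guide-bearing molecule is cut.  ``cut_offset`` is where the blunt cut
    falls, in nt 5' of the PAM (3 for SpCas9).  ``size_threshold`` is the
    bead-cleanup cutoff in bp; fragments shorter are discarded.
    """

    efficiency: float = 0.97
    rounds: int = 2
    cut_offset: int = 3
    size_threshold: int = 300

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must be in [0, 1]")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not 1 <= self.cut_offset <= 19:
            raise ValueError("cut_offset must be in [1, 19]")
        if self.size_threshold < 0:
            raise ValueError("size_threshold must be >= 0")

    @property
    def expected_residual(self) -> float:
        return (1.0 - self.efficiency) ** self.rounds


@dataclass(frozen=True)
class CommunityMember:
    template: str
    molecules: int
    is_host: bool = False

    def __post_init__(self) -> None:
        if self.molecules <= 0:
            raise ValueError("molecules must be positive")


@dataclass(frozen=True)
class MockCommunity:
    """Named templates at known molecule counts, hosts flagged."""

    members: Mapping[str, CommunityMember]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("community must have at least one member")
        object.__setattr__(self, "members", dict(self.members))


@dataclass
class DepletionReport:
    """Per-taxon molecule trajectories through the cut/selection rounds."""

    counts: dict[str, list[int]]  # taxon -> [initial, after round 1, ...]
    matched: dict[str, bool]
    excluded: list[str]
    residual_host_fraction: float
    expected_residual: float
    library_composition: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "matched": self.matched,
            "excluded": self.excluded,
            "residual_host_fraction": self.residual_host_fraction,
            "expected_residual": self.expected_residual,
            "library_composition": self.library_composition,
        }


def cut_positions(
    amplicon_seq: str, sites: Sequence[GuideSite], cut_offset: int = 3
) -> list[int]:
    """Plus-strand blunt-cut coordinates for the given sites.

    A "+" site with protospacer [i, i+20) is cut ``cut_offset`` nt 5' of
    its PAM, i.e. at i + 20 - cut_offset; the mirror "-" site at plus
    interval [j, j+20) is cut at j + cut_offset.  Duplicates collapse.
    """
    seq = amplicon_seq.upper()
    positions: set[int] = set()
    for site in sites:
        observed = seq[site.start : site.end]
        expected = site.protospacer if site.strand == "+" else revcomp(site.protospacer)
        if observed != expected:
            raise ValueError(
                f"site {site.protospacer} ({site.strand}) at [{site.start}, {site.end}) "
                "is inconsistent with the amplicon sequence"
            )
        if site.strand == "+":
            positions.add(site.end - cut_offset)
        else:
            positions.add(site.start + cut_offset)
    return sorted(positions)


def fragmentize(length: int, cuts: Sequence[int]) -> list[int]:
    """Fragment lengths from cutting a molecule of ``length`` at ``cuts``.

    Lengths always sum to the parent length.
    """
    prev = None
    for c in cuts:
        if not 0 < c < length:
            raise ValueError(f"cut {c} outside (0, {length})")
        if prev is not None and c < prev:
            raise ValueError("cuts must be sorted ascending")
        prev = c
    bounds = [0, *cuts, length]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def size_select(fragments: Sequence[int], threshold: int) -> list[int]:
    """Bead-cleanup model: keep fragments >= threshold, stable order."""
    return [f for f in fragments if f >= threshold]


def _guide_strings(guides: Sequence) -> list[str]:
    out = []
    for g in guides:
        out.append(g.protospacer if isinstance(g, GuideSite) else str(g).upper())
    return out


def simulate_ccsas(
    community: MockCommunity,
    guides: Sequence,
    model: CutModel,
    primers: PrimerPair,
    seed: int,
    constraints: AmpliconConstraints | None = None,
) -> DepletionReport:
    """Simulate rounds of guide-directed cutting over a mock community.

    Each member's template is amplified in silico first; members the primer
    pair does not amplify are excluded with a warning.  A member is
    cuttable iff any guide 20-mer occurs (either strand) in its amplicon.
    Per round, each intact cuttable molecule is cut with probability
    ``model.efficiency``; cut molecules are unamplifiable and removed.
    Identical seeds give identical reports.
    """
    rng = np.random.default_rng(seed)
    protos = _guide_strings(guides)
    rcs = [revcomp(p) for p in protos]

    counts: dict[str, list[int]] = {}
    matched: dict[str, bool] = {}
    excluded: list[str] = []
    for name, member in community.members.items():
        rec = ReferenceRecord(
            accession=name,
            taxonomy=TaxonomyPath((name,)),
            sequence=member.template,
        )
        amps = extract_amplicons(rec, primers, constraints)
        if not amps:
            logger.warning("community member %r is not amplified by %s; excluded",
                           name, primers.name)
            excluded.append(name)
            continue
        seqs = [a.sequence for a in amps]
        matched[name] = any(
            p in s or r in s for s in seqs for p, r in zip(protos, rcs)
        )
        counts[name] = [member.molecules]

    for _ in range(model.rounds):
        for name, trajectory in counts.items():
            intact = trajectory[-1]
            if matched[name] and intact > 0:
                survivors = int(rng.binomial(intact, 1.0 - model.efficiency))
            else:
                survivors = intact
            trajectory.append(survivors)

    host_names = [
        n for n in counts if community.members[n].is_host
    ]
    host_initial = sum(counts[n][0] for n in host_names)
    host_final = sum(counts[n][-1] for n in host_names)
    residual = host_final / host_initial if host_initial else 0.0
    total_final = sum(t[-1] for t in counts.values())
    composition = {
        n: (t[-1] / total_final if total_final else 0.0) for n, t in counts.items()
    }
    return DepletionReport(
        counts=counts,
        matched=matched,
        excluded=excluded,
        residual_host_fraction=residual,
        expected_residual=model.expected_residual,
        library_composition=composition,
    )


# ---------------------------------------------------------------------------
# Synthetic reference generator
# ---------------------------------------------------------------------------

#: Backbone alphabet for synthetic interiors.  Strings over {A, C, T} with
#: no "CC" dinucleotide contain no NGG PAM on either strand (plus needs GG,
#: minus needs CC on the plus strand), so the only Cas9-compatible windows
#: in a synthetic interior are the planted ones.
_BACKBONE = "ACT"


def _backbone_string(rng: np.random.Generator, n: int, prev: str = "") -> str:
    out: list[str] = []
    for _ in range(n):
        choices = "AT" if prev == "C" else _BACKBONE
        c = choices[int(rng.integers(len(choices)))]
        out.append(c)
        prev = c
    return "".join(out)


def _concretize(primer: str, rng: np.random.Generator) -> str:
    """Replace degenerate codes by a seeded concrete choice."""
    return "".join(
        sorted(IUPAC_CODES[c])[int(rng.integers(len(IUPAC_CODES[c])))] for c in primer
    )


def _planted_protospacer(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        p = _backbone_string(rng, 20)
        if p not in taken and revcomp(p) not in taken:
            taken.add(p)
            return p


@dataclass
class SyntheticReference:
    """Generated host + microeukaryote records with the planted truth table."""

    host_records: list[ReferenceRecord]
    micro_records: list[ReferenceRecord]
    truth: dict[str, set[str]]  # host species -> planted specific protospacers
    shared: dict[str, set[str]]  # host species -> planted shared protospacers
    primers: PrimerPair


def generate_synthetic_reference(
    n_host: int = 5,
    n_micro: int = 20,
    seq_len: int = 400,
    n_specific_per_host: int = 2,
    n_shared: int = 2,
    seed: int = 0,
    primers: PrimerPair | None = None,
) -> SyntheticReference:
    """Emit seeded host/micro reference sets with planted guide sites.

    Every record amplifies with the primer pair (one product).  Each host
    interior carries ``n_specific_per_host`` planted protospacer+TGG sites
    absent from every micro record (verified by substring scan, both
    strands) and ``n_shared`` sites whose 20-mer is copied into at least
    one micro record.  Interiors use a PAM-free backbone alphabet, so the
    planted sites are provably the only compatible windows and the truth
    table is exact.  Identical seeds give byte-identical records.
    """
    if primers is None:
        from .config import get_primer_pair

        primers = get_primer_pair()
    rng = np.random.default_rng(seed)
    fwd_fp = _concretize(primers.forward, rng)
    rev_fp = revcomp(_concretize(primers.reverse, rng))
    interior_len = seq_len - len(fwd_fp) - len(rev_fp)
    n_blocks = n_specific_per_host + n_shared
    # each planted block: 'A' spacer + 20-mer + TGG + 'A' spacer
    needed = n_blocks * 25 + (n_blocks + 1)
    if interior_len < needed:
        raise ValueError(
            f"seq_len {seq_len} too short for {n_blocks} planted sites "
            f"(need interior >= {needed}, have {interior_len})"
        )

    taken: set[str] = set()
    truth: dict[str, set[str]] = {}
    shared_map: dict[str, set[str]] = {}
    host_records: list[ReferenceRecord] = []
    micro_payload: dict[int, list[str]] = {i: [] for i in range(n_micro)}
    micro_slot = 0

    for h in range(n_host):
        species = f"Hostgenus species{h + 1}"
        specific = [_planted_protospacer(rng, taken) for _ in range(n_specific_per_host)]
        shared = [_planted_protospacer(rng, taken) for _ in range(n_shared)]
        truth[species] = set(specific)
        shared_map[species] = set(shared)
        if n_micro:
            for p in shared:
                micro_payload[micro_slot % n_micro].append(p)
                micro_slot += 1
        blocks = ["A" + p + "TGG" + "A" for p in specific + shared]
        order = rng.permutation(len(blocks))
        blocks = [blocks[i] for i in order]
        slack = interior_len - sum(len(b) for b in blocks)
        seg_lens = _split_lengths(rng, slack, len(blocks) + 1)
        parts: list[str] = []
        prev = ""
        for i, block in enumerate(blocks):
            seg = _backbone_string(rng, seg_lens[i], prev)
            parts.extend([seg, block])
            prev = block[-1]
        parts.append(_backbone_string(rng, seg_lens[-1], prev))
        interior = "".join(parts)
        host_records.append(
            ReferenceRecord(
                accession=f"HOST{h + 1:03d}",
                taxonomy=TaxonomyPath(
                    ("Eukaryota", "Metazoa", "Hostphylum", species)
                ),
                sequence=fwd_fp + interior + rev_fp,
            )
        )

    micro_records: list[ReferenceRecord] = []
    for m in range(n_micro):
        species = f"Microgenus species{m + 1}"
        payload = micro_payload[m]
        blocks = ["A" + p + "A" for p in payload]  # no PAM needed off-target
        slack = interior_len - sum(len(b) for b in blocks)
        seg_lens = _split_lengths(rng, slack, len(blocks) + 1)
        parts = []
        prev = ""
        for i, block in enumerate(blocks):
            seg = _backbone_string(rng, seg_lens[i], prev)
            parts.extend([seg, block])
            prev = block[-1]
        parts.append(_backbone_string(rng, seg_lens[-1], prev))
        interior = "".join(parts)
        micro_records.append(
            ReferenceRecord(
                accession=f"MICRO{m + 1:03d}",
                taxonomy=TaxonomyPath(
                    ("Eukaryota", "Protistclade", "Microphylum", species)
                ),
                sequence=fwd_fp + interior + rev_fp,
            )
        )

    _verify_construction(host_records, micro_records, truth, shared_map, primers)
    return SyntheticReference(host_records, micro_records, truth, shared_map, primers)


def _split_lengths(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    """Split ``total`` into ``parts`` non-negative segments, each >= 1."""
    if total < parts:
        raise ValueError("not enough slack for separator segments")
    extra = rng.multinomial(total - parts, [1.0 / parts] * parts)
    return [1 + int(e) for e in extra]


def _verify_construction(
    host_records: Sequence[ReferenceRecord],
    micro_records: Sequence[ReferenceRecord],
    truth: Mapping[str, set[str]],
    shared_map: Mapping[str, set[str]],
    primers: PrimerPair,
) -> None:
    """Construction scan: planted truth holds and every record amplifies once.

    Independent of the design pipeline — plain substring checks on the raw
    record sequences.
    """
    micro_seqs = [r.sequence for r in micro_records]
    for species, protos in truth.items():
        for p in protos:
            rc = revcomp(p)
            for s in micro_seqs:
                if p in s or rc in s:
                    raise AssertionError(
                        f"planted specific protospacer {p} for {species} leaked "
                        "into a micro record"
                    )
    if micro_records:
        for species, protos in shared_map.items():
            for p in protos:
                rc = revcomp(p)
                if not any(p in s or rc in s for s in micro_seqs):
                    raise AssertionError(
                        f"planted shared protospacer {p} for {species} missing "
                        "from all micro records"
                    )
    for rec in list(host_records) + list(micro_records):
        n_amps = len(extract_amplicons(rec, primers))
        if n_amps != 1:
            raise AssertionError(
                f"synthetic record {rec.accession} yields {n_amps} amplicons "
                "(expected exactly 1)"
            )


def community_from_reference(
    ref: SyntheticReference,
    host_molecules: int = 100_000,
    micro_molecules: int = 10_000,
) -> MockCommunity:
    """Mock community over the synthetic templates, hosts flagged."""
    members: dict[str, CommunityMember] = {}
    for rec in ref.host_records:
        members[rec.species_name] = CommunityMember(
            template=rec.sequence, molecules=host_molecules, is_host=True
        )
    for rec in ref.micro_records:
        members[rec.species_name] = CommunityMember(
            template=rec.sequence, molecules=micro_molecules, is_host=False
        )
    return MockCommunity(members)
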