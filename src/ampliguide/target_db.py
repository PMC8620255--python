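"""Per-taxon guide-site database: build, serialize, query, summarize.

The database catalogs, for every host-clade species in a reference set, the
Cas9-compatible sites its amplicons carry and which of those are
taxon-specific (absent from all microeukaryote sequences).  Species are
keyed by name — the deepest taxonomy label — with accession provenance per
entry, so a protospacer shared by several species is listed under each.

Serialization is a TSV (one row per guide entry) plus a JSON sidecar that
records the design parameters and per-species bookkeeping, making the
round-trip lossless.
"""

from __future__ import annotations

import csv
import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .guide_design import (
    GUIDE_LEN,
    DesignParams,
    KmerIndex,
    enumerate_guide_sites,
    screen_guide,
)
from .insilico_pcr import Amplicon, PrimerPair, extract_amplicons
from .reference_io import CladePartition, ReferenceRecord, revcomp

SCHEMA_VERSION = 1
_TSV_COLUMNS = [
    "species",
    "protospacer",
    "pam",
    "strand",
    "source_accessions",
    "compatible",
    "taxon_specific",
]


class DatabaseSchemaError(ValueError):
    """A serialized database does not match the expected schema/version."""


@dataclass
class GuideEntry:
    """One catalogued site for one species."""

    protospacer: str
    pam: str
    strand: str
    source_accessions: tuple[str, ...]
    compatible: bool = True
    taxon_specific: bool = False

    def __post_init__(self) -> None:
        if self.taxon_specific and not self.compatible:
            raise ValueError("a taxon-specific entry must also be compatible")
        self.source_accessions = tuple(self.source_accessions)


@dataclass
class GuideDatabase:
    """Per-species catalog of guide sites with the parameters that built it."""

    entries: dict[str, list[GuideEntry]]
    params: dict
    reference_label: str = ""
    no_amplicon: frozenset[str] = frozenset()

    @property
    def species(self) -> list[str]:
        return list(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GuideDatabase):
            return NotImplemented
        return (
            self.entries == other.entries
            and self.params == other.params
            and self.reference_label == other.reference_label
            and self.no_amplicon == other.no_amplicon
        )


@dataclass(frozen=True)
class BreadthSummary:
    """How broadly one protospacer cuts across the host clade.

    ``per_level`` maps taxonomy depth (``D0`` root, ``D1``, ...) to the
    number of distinct labels at that depth among species whose amplicons
    contain the site.  Counts need not decrease toward the root, since
    label sets differ per level.
    """

    protospacer: str
    per_level: dict[str, int]
    species_count: int


def build_database(
    partition: CladePartition,
    primers: PrimerPair,
    params: DesignParams | None = None,
) -> GuideDatabase:
    """Catalog compatible and taxon-specific sites for every host species.

    The microeukaryote index is built once and shared across species.
    Species whose records yield no amplicon with the primer pair are
    recorded under ``no_amplicon`` rather than silently dropped.
    """
    if not partition.host_records:
        raise ValueError("partition has no host records")
    params = params or DesignParams()
    if params.screen_scope == "full_sequence":
        micro_index = KmerIndex.from_records(partition.micro_records)
    else:
        micro_amps: list[Amplicon] = []
        for rec in partition.micro_records:
            micro_amps.extend(extract_amplicons(rec, primers, params.constraints))
        micro_index = KmerIndex.from_amplicons(micro_amps)

    by_species: dict[str, list[ReferenceRecord]] = {}
    for rec in partition.host_records:
        by_species.setdefault(rec.species_name, []).append(rec)

    entries: dict[str, list[GuideEntry]] = {}
    no_amplicon: set[str] = set()
    for species, records in by_species.items():
        amplicons: list[Amplicon] = []
        for rec in records:
            amplicons.extend(extract_amplicons(rec, primers, params.constraints))
        if not amplicons:
            no_amplicon.add(species)
            entries[species] = []
            continue
        per_proto: dict[str, GuideEntry] = {}
        for amp in amplicons:
            for site in enumerate_guide_sites(amp, region=params.region):
                entry = per_proto.get(site.protospacer)
                if entry is None:
                    res = screen_guide(site.protospacer, micro_index, params.max_mismatch)
                    per_proto[site.protospacer] = GuideEntry(
                        protospacer=site.protospacer,
                        pam=site.pam,
                        strand=site.strand,
                        source_accessions=(site.source_accession,),
                        compatible=True,
                        taxon_specific=res.is_specific,
                    )
                elif site.source_accession not in entry.source_accessions:
                    entry.source_accessions = entry.source_accessions + (
                        site.source_accession,
                    )
        entries[species] = list(per_proto.values())

    return GuideDatabase(
        entries=entries,
        params=_params_to_dict(params, primers),
        reference_label=f"{len(partition.host_records)} host / "
        f"{len(partition.micro_records)} micro records",
        no_amplicon=frozenset(no_amplicon),
    )


def _params_to_dict(params: DesignParams, primers: PrimerPair) -> dict:
    return {
        "primer_set": primers.name,
        "forward": primers.forward,
        "reverse": primers.reverse,
        "region": params.region,
        "max_mismatch": params.max_mismatch,
        "screen_scope": params.screen_scope,
        "min_len": params.constraints.min_len,
        "max_len": params.constraints.max_len,
        "primer_max_mismatch": params.constraints.max_mismatch,
    }


def coverage_stats(db: GuideDatabase) -> dict:
    """Summary of how much of the host clade the database covers.

    Uniqueness is reported in both senses — distinct specific protospacer
    strings, and specific (species, protospacer) pairs — since broad guides
    are cross-listed under every species they cut.
    """
    if not db.entries:
        raise ValueError("cannot summarize an empty database")
    n_taxa = len(db.entries)
    with_amplicon = [sp for sp in db.entries if sp not in db.no_amplicon]
    specific_counts = {
        sp: sum(e.taxon_specific for e in db.entries[sp]) for sp in with_amplicon
    }
    compatible_counts = {sp: len(db.entries[sp]) for sp in with_amplicon}
    n_specific = sum(1 for c in specific_counts.values() if c > 0)
    unique_specific = {
        e.protospacer
        for entries in db.entries.values()
        for e in entries
        if e.taxon_specific
    }

    def _mmm(counts: dict[str, int]) -> dict:
        vals = list(counts.values())
        if not vals:
            return {"min": 0, "mean": 0.0, "max": 0}
        return {
            "min": min(vals),
            "mean": round(statistics.mean(vals), 1),
            "max": max(vals),
        }

    return {
        "n_taxa": n_taxa,
        "n_with_amplicon": len(with_amplicon),
        "n_with_specific_site": n_specific,
        "fraction_with_specific_site": n_specific / n_taxa,
        "compatible_sites_per_taxon": _mmm(compatible_counts),
        "specific_sites_per_taxon": _mmm(specific_counts),
        "n_unique_specific_protospacers": len(unique_specific),
        "n_specific_taxon_site_pairs": sum(specific_counts.values()),
    }


def breadth_summary(
    protospacer: str,
    partition: CladePartition,
    primers: PrimerPair,
    constraints=None,
) -> BreadthSummary:
    """Count, per taxonomy level, the host labels whose amplicons carry a site.

    Matching is exact, either strand, over freshly extracted amplicons of
    every host record.
    """
    protospacer = protospacer.upper()
    if len(protospacer) != GUIDE_LEN:
        raise ValueError("protospacer must be 20 nt")
    rc = revcomp(protospacer)
    matched: list[ReferenceRecord] = []
    for rec in partition.host_records:
        for amp in extract_amplicons(rec, primers, constraints):
            if protospacer in amp.sequence or rc in amp.sequence:
                matched.append(rec)
                break
    per_level: dict[str, set[str]] = {}
    species: set[str] = set()
    for rec in matched:
        species.add(rec.species_name)
        for depth, label in enumerate(rec.taxonomy.levels):
            per_level.setdefault(f"D{depth}", set()).add(label)
    return BreadthSummary(
        protospacer=protospacer,
        per_level={lvl: len(labels) for lvl, labels in sorted(per_level.items())},
        species_count=len(species),
    )


@dataclass(frozen=True)
class LookupResult:
    """search_by_name outcome; distinguishes absent species from zero sites."""

    name: str
    status: str  # "found" | "not_in_database"
    entries: tuple[GuideEntry, ...] = ()


def search_by_name(db: GuideDatabase, name: str, substring: bool = False) -> LookupResult:
    """Case-insensitive species lookup; optional substring mode."""
    needle = name.strip().lower()
    matches: list[GuideEntry] = []
    found = False
    for species, entries in db.entries.items():
        hay = species.lower()
        if (substring and needle in hay) or hay == needle:
            found = True
            matches.extend(entries)
    status = "found" if found else "not_in_database"
    return LookupResult(name=name, status=status, entries=tuple(matches))


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".params.json")


def write_database(db: GuideDatabase, path: str | Path) -> None:
    """Serialize as TSV (one row per guide) + JSON parameter sidecar."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for species, entries in db.entries.items():
            for e in entries:
                writer.writerow(
                    [
                        species,
                        e.protospacer,
                        e.pam,
                        e.strand,
                        ",".join(e.source_accessions),
                        str(e.compatible).lower(),
                        str(e.taxon_specific).lower(),
                    ]
                )
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "params": db.params,
        "reference_label": db.reference_label,
        "species": list(db.entries),
        "no_amplicon": sorted(db.no_amplicon),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_database(path: str | Path) -> GuideDatabase:
    """Inverse of :func:`write_database`; errors name what is wrong."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise DatabaseSchemaError(f"missing parameter sidecar: {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    version = sidecar.get("schema_version")
    if version != SCHEMA_VERSION:
        raise DatabaseSchemaError(
            f"database schema version {version!r} != supported {SCHEMA_VERSION}"
        )
    entries: dict[str, list[GuideEntry]] = {sp: [] for sp in sidecar["species"]}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _TSV_COLUMNS:
            raise DatabaseSchemaError(
                f"unexpected TSV columns {header!r}; expected {_TSV_COLUMNS}"
            )
        for row in reader:
            species, proto, pam, strand, accs, compatible, specific = row
            entries.setdefault(species, []).append(
                GuideEntry(
                    protospacer=proto,
                    pam=pam,
                    strand=strand,
                    source_accessions=tuple(accs.split(",")) if accs else (),
                    compatible=compatible == "true",
                    taxon_specific=specific == "true",
                )
            )
    return GuideDatabase(
        entries=entries,
        params=sidecar["params"],
        reference_label=sidecar["reference_label"],
        no_amplicon=frozenset(sidecar["no_amplicon"]),
    )
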