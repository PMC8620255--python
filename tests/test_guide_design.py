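"""Guide-site enumeration, k-mer screening, designers, template oligos."""

import numpy as np
import pytest

from ampliguide import (
    Amplicon,
    CladePartition,
    KmerIndex,
    NoAmpliconError,
    ReferenceRecord,
    SgRNAScheme,
    TaxonomyPath,
    build_kmer_index,
    build_sgrna_template,
    design_for_gene,
    design_for_host,
    enumerate_guide_sites,
    revcomp,
    screen_guide,
)
from ampliguide.guide_design import count_near_hits


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_sites(seq):
    """Sliding 23-nt window oracle, both strands, as (protospacer, strand, start)."""
    out = set()
    for i in range(len(seq) - 22):
        window = seq[i : i + 23]
        if set(window) - set("ACGT"):
            continue
        if window[21:23] == "GG":
            out.add((window[:20], "+", i))
        if window[0:2] == "CC":
            out.add((revcomp(window[3:]), "-", i + 3))
    return out


class TestEnumerateGuideSites:
    def test_plus_strand_forced_site(self):
        amp = Amplicon.from_sequence("A" * 20 + "TGG")
        (site,) = enumerate_guide_sites(amp, region="full")
        assert site.strand == "+"
        assert site.protospacer == "A" * 20
        assert site.pam == "TGG"
        assert (site.start, site.end) == (0, 20)

    def test_minus_strand_forced_site(self):
        amp = Amplicon.from_sequence("CCA" + "T" * 20)
        (site,) = enumerate_guide_sites(amp, region="full")
        assert site.strand == "-"
        assert site.protospacer == "A" * 20
        assert site.pam == "TGG"
        assert (site.start, site.end) == (3, 23)

    def test_no_gg_or_cc_dinucleotide_means_no_sites(self):
        amp = Amplicon.from_sequence("A" * 100)
        assert enumerate_guide_sites(amp, region="full") == []

    def test_ambiguous_windows_are_skipped(self):
        amp = Amplicon.from_sequence("A" * 10 + "N" + "A" * 9 + "TGG")
        assert enumerate_guide_sites(amp, region="full") == []

    def test_short_amplicon_yields_nothing(self):
        assert enumerate_guide_sites(Amplicon.from_sequence("ACGTGG"), "full") == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        amp = Amplicon.from_sequence(_random_seq(rng, 400))
        got = {
            (s.protospacer, s.strand, s.start)
            for s in enumerate_guide_sites(amp, region="full")
        }
        assert got == brute_force_sites(amp.sequence)

    def test_interior_region_excludes_footprint_windows(self):
        seq = "A" * 20 + "TGG" + "C" * 30
        amp = Amplicon(
            source_accession="x", start=0, end=len(seq), source_strand="+",
            sequence=seq, interior=(5, len(seq) - 5),
        )
        full = enumerate_guide_sites(amp, region="full")
        interior = enumerate_guide_sites(amp, region="interior")
        assert any(s.start == 0 for s in full)
        assert all(s.start >= 5 for s in interior)

    def test_sites_reextract_from_sequence(self, synthetic_ref, primers):
        from ampliguide import extract_amplicons

        for rec in synthetic_ref.host_records:
            (amp,) = extract_amplicons(rec, primers)
            for s in enumerate_guide_sites(amp, region="full"):
                segment = amp.sequence[s.start : s.end]
                if s.strand == "+":
                    assert segment == s.protospacer
                    assert amp.sequence[s.end : s.end + 3] == s.pam
                else:
                    assert revcomp(segment) == s.protospacer
                    assert revcomp(amp.sequence[s.start - 3 : s.start]) == s.pam


class TestKmerIndex:
    def test_window_count_on_single_amplicon(self):
        rng = np.random.default_rng(9)
        seq = _random_seq(rng, 23)
        idx = build_kmer_index([Amplicon.from_sequence(seq)])
        plus = {seq[i : i + 20] for i in range(4)}
        minus = {revcomp(k) for k in plus}
        assert set(idx._map) == plus | minus

    def test_empty_index(self):
        idx = build_kmer_index([])
        assert len(idx) == 0
        assert idx.query("A" * 20) == set()

    def test_strand_mirror_invariant(self):
        rng = np.random.default_rng(10)
        seq = _random_seq(rng, 60)
        idx = build_kmer_index([Amplicon.from_sequence(seq, accession="a1")])
        probe = seq[10:30]
        fwd = {(acc, strand) for acc, _, strand in idx.query(probe)}
        rev = {(acc, strand) for acc, _, strand in idx.query(revcomp(probe))}
        assert fwd == {(a, "+-"["+-".index(s) ^ 1]) for a, s in rev}

    @pytest.mark.parametrize("seed", range(3))
    def test_membership_matches_substring_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        seqs = [_random_seq(rng, 150) for _ in range(5)]
        amps = [Amplicon.from_sequence(s, accession=f"a{i}") for i, s in enumerate(seqs)]
        idx = build_kmer_index(amps)
        for _ in range(100):
            if rng.random() < 0.5:
                j = int(rng.integers(5))
                pos = int(rng.integers(131))
                probe = seqs[j][pos : pos + 20]
            else:
                probe = _random_seq(rng, 20)
            hit = bool(idx.query(probe))
            oracle = any(probe in s or revcomp(probe) in s for s in seqs)
            assert hit == oracle


class TestScreenGuide:
    def test_empty_index_is_specific(self):
        res = screen_guide("A" * 10 + "C" * 10, KmerIndex())
        assert res.verdict == "taxon_specific"
        assert res.is_specific

    def test_verbatim_off_target(self):
        rng = np.random.default_rng(4)
        proto = _random_seq(rng, 20)
        idx = KmerIndex.from_sequences(
            [("TTT" + proto + "TTT", "m1", "Protist sp1")]
        )
        res = screen_guide(proto, idx)
        assert res.verdict == "off_target_micro"
        assert ("Protist sp1", "m1") in res.micro_hits

    def test_revcomp_only_occurrence_still_hits(self):
        rng = np.random.default_rng(5)
        proto = _random_seq(rng, 20)
        idx = KmerIndex.from_sequences(
            [("TTT" + revcomp(proto) + "TTT", "m1", "Protist sp1")]
        )
        assert screen_guide(proto, idx).verdict == "off_target_micro"

    def test_mismatch_tolerance_widens_hits(self):
        rng = np.random.default_rng(6)
        proto = _random_seq(rng, 20)
        variant = ("T" if proto[0] != "T" else "G") + proto[1:]
        idx = KmerIndex.from_sequences([("AAA" + variant + "AAA", "m1", "P sp")])
        assert screen_guide(proto, idx, max_mismatch=0).is_specific
        assert not screen_guide(proto, idx, max_mismatch=1).is_specific

    def test_malformed_protospacer_rejected(self):
        with pytest.raises(ValueError):
            screen_guide("ACGT", KmerIndex())
        with pytest.raises(ValueError):
            screen_guide("N" * 20, KmerIndex())

    def test_near_hit_count_matches_scan(self):
        rng = np.random.default_rng(7)
        proto = _random_seq(rng, 20)
        variant = ("T" if proto[3] != "T" else "G").join([proto[:3], proto[4:]])
        idx = KmerIndex.from_sequences([("AA" + variant + "AA", "m1", "P sp")])
        scan = idx.scan_with_mismatches(proto, 1) - idx.query(proto)
        assert count_near_hits(proto, idx) == len({t for _, t, _ in scan}) == 1


class TestDesignForHost:
    def test_recovers_planted_sites_per_host(self, synthetic_ref, partition, primers):
        for rec in synthetic_ref.host_records:
            hits = design_for_host([rec], partition, primers)
            assert {h.protospacer for h in hits} == synthetic_ref.truth[rec.species_name]

    def test_host_identical_to_micro_yields_nothing(self, synthetic_ref, primers):
        clone = synthetic_ref.micro_records[0]
        host_twin = ReferenceRecord(
            "H_TWIN",
            TaxonomyPath(("Eukaryota", "Metazoa", "Twin sp")),
            clone.sequence,
        )
        part = CladePartition([host_twin], list(synthetic_ref.micro_records))
        assert design_for_host([host_twin], part, primers) == []

    def test_shared_site_across_variants_is_aggregated(
        self, synthetic_ref, partition, primers
    ):
        rec = synthetic_ref.host_records[0]
        variant = ReferenceRecord("HOST001b", rec.taxonomy, rec.sequence)
        hits = design_for_host([rec, variant], partition, primers)
        assert {h.protospacer for h in hits} == synthetic_ref.truth[rec.species_name]
        for h in hits:
            assert h.accessions == ("HOST001", "HOST001b")

    def test_no_amplicon_raises(self, partition, primers):
        rec = ReferenceRecord(
            "noamp", TaxonomyPath(("Eukaryota", "Metazoa", "No sp")), "ACGT" * 100
        )
        with pytest.raises(NoAmpliconError):
            design_for_host([rec], partition, primers)

    def test_ranking_is_deterministic(self, synthetic_ref, partition, primers):
        a = design_for_host(synthetic_ref.host_records, partition, primers)
        b = design_for_host(synthetic_ref.host_records, partition, primers)
        assert [h.protospacer for h in a] == [h.protospacer for h in b]


class TestDesignForGene:
    def _target(self, seed=11, n=1000):
        rng = np.random.default_rng(seed)
        return ReferenceRecord(
            "gene1", TaxonomyPath(("target gene",)), _random_seq(rng, n)
        )

    def test_self_background_removes_everything(self):
        target = self._target()
        assert design_for_gene(target, [target]) == []

    def test_empty_background_returns_all_sites(self):
        target = self._target()
        hits = design_for_gene(target, [])
        expected = {p for p, _, _ in brute_force_sites(target.sequence)}
        assert {h.protospacer for h in hits} == expected

    @pytest.mark.parametrize("seed", [21, 22])
    def test_matches_bruteforce_pipeline_oracle(self, seed):
        rng = np.random.default_rng(seed)
        target = self._target(seed)
        background = [
            ReferenceRecord(f"bg{i}", TaxonomyPath((f"bg taxon {i}",)),
                            _random_seq(rng, 500))
            for i in range(10)
        ]
        hits = design_for_gene(target, background)
        expected = set()
        for proto, _, _ in brute_force_sites(target.sequence):
            rc = revcomp(proto)
            if not any(proto in b.sequence or rc in b.sequence for b in background):
                expected.add(proto)
        assert {h.protospacer for h in hits} == expected


class TestSgRNATemplate:
    SCHEME = SgRNAScheme(promoter="TTCTAATACGACTCACTATAG", overlap="GTTTTAGAGCTAGA")

    def test_length_contract_without_leading_g(self):
        oligo = build_sgrna_template("G" + "A" * 19, self.SCHEME)
        assert len(oligo.oligo) == len(self.SCHEME.promoter) + 34
        assert not oligo.leading_g_added

    def test_leading_g_prepended_when_required(self):
        scheme = SgRNAScheme(
            promoter=self.SCHEME.promoter, overlap=self.SCHEME.overlap,
            require_leading_g=True,
        )
        oligo = build_sgrna_template("A" * 20, scheme)
        assert oligo.leading_g_added
        assert oligo.oligo == scheme.promoter + "G" + "A" * 20 + scheme.overlap

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            build_sgrna_template("A" * 19, self.SCHEME)

    def test_default_scheme_decomposes(self):
        oligo = build_sgrna_template("ACGT" * 5)
        assert oligo.oligo.startswith(oligo.promoter)
        assert oligo.oligo.endswith(oligo.overlap)
        core = oligo.oligo[len(oligo.promoter) : -len(oligo.overlap)]
        assert core.endswith(oligo.protospacer)


def test_strand_closure_of_design(synthetic_ref, partition, primers):
    """Designing on reverse-complemented host records finds the same guides."""
    from collections import Counter

    rc_records = [
        ReferenceRecord(r.accession, r.taxonomy, revcomp(r.sequence))
        for r in synthetic_ref.host_records
    ]
    fwd = design_for_host(synthetic_ref.host_records, partition, primers)
    rev = design_for_host(rc_records, partition, primers)
    assert Counter(h.protospacer for h in fwd) == Counter(h.protospacer for h in rev)
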