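"""Site scanning geometry, digestion conservation, and one-pot assembly."""

from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from srnaforge import (
    AssemblyError,
    BBSI,
    SAPI,
    DesignError,
    SeedRegion,
    SeqRecordX,
    TypeIISFragment,
    anneal,
    check_overhang_scheme,
    default_scheme,
    design_part_primers,
    design_seed_oligos,
    digest,
    enumerate_products,
    revcomp,
    scan_type_iis,
    simulate_one_pot,
    simulate_pcr,
)
from srnaforge.goldengate import OverhangScheme, _canonical_circle


class TestScan:
    def test_top_strand_geometry(self):
        rec = SeqRecordX(id="x", sequence="TTGAAGACAAACGTCCTG")
        (site,) = scan_type_iis(rec, BBSI)
        assert (site.position, site.strand) == (3, 1)
        assert site.overhang_interval == (11, 14)
        assert rec.sequence[site.overhang_interval[0] - 1 : site.overhang_interval[1]] == "ACGT"

    def test_bottom_strand_mirror(self):
        rec = SeqRecordX(id="x", sequence=revcomp("TTGAAGACAAACGTCCTG"))
        (site,) = scan_type_iis(rec, BBSI)
        assert site.strand == -1
        a, b = site.overhang_interval
        assert rec.sequence[a - 1 : b] == "ACGT"  # same overhang on the sense strand

    def test_no_sites_empty(self):
        rec = SeqRecordX(id="x", sequence="ACGTACGTACGTACGT")
        assert scan_type_iis(rec, BBSI) == []

    def test_circular_seam_site_found(self):
        linear = "AGACAAACGTCCTGTTGA"  # GAAGAC split across the origin
        rec = SeqRecordX(id="x", sequence=linear, circular=True)
        sites = scan_type_iis(rec, BBSI)
        assert any(s.position == 17 for s in sites)

    def test_sapi_constants(self):
        assert (SAPI.recognition, SAPI.spacer, SAPI.overhang_len) == ("GCTCTTC", 1, 3)


class TestDigest:
    def test_acceptor_two_fragments_cassette_carries_sites(self, acceptor):
        frags = digest(acceptor, BBSI)
        assert len(frags) == 2
        by_labels = {("ccdB" in f.labels): f for f in frags}
        cassette, backbone = by_labels[True], by_labels[False]
        assert {"mCherry", "ccdB"} <= set(cassette.labels)
        # re-scan: backbone clean, cassette keeps both recognition sites
        assert scan_type_iis(SeqRecordX(id="b", sequence=backbone.seq), BBSI) == []
        assert len(scan_type_iis(SeqRecordX(id="c", sequence=cassette.seq), BBSI)) == 2

    def test_length_conservation(self, acceptor):
        frags = digest(acceptor, BBSI)
        assert sum(len(f.seq) - f.rov for f in frags) == len(acceptor)
        assert sum(f.duplex_len for f in frags) + len(frags) * BBSI.overhang_len == len(acceptor)

    def test_single_site_gives_self_religating_fragment(self):
        seq = "GG" + "GAAGAC" + "AA" + "ACGT" + "C" * 40
        rec = SeqRecordX(id="one", sequence=seq, circular=True)
        (frag,) = digest(rec, BBSI)
        assert frag.left_overhang == frag.right_overhang
        products, _ = enumerate_products([frag])
        assert len(products) == 1
        assert len(products[0].record) == len(rec)

    def test_zero_sites_errors(self):
        rec = SeqRecordX(id="x", sequence="ACGT" * 20, circular=True)
        with pytest.raises(AssemblyError, match="nothing to digest"):
            digest(rec, BBSI)


class TestEnumeration:
    def test_religation_reproduces_plasmid(self, acceptor):
        frags = digest(acceptor, BBSI)
        products, _ = enumerate_products(frags)
        canon = {_canonical_circle(p.record.sequence) for p in products}
        assert _canonical_circle(acceptor.sequence) in canon

    def test_religation_redigests_to_same_fragments(self, acceptor):
        frags = digest(acceptor, BBSI)
        products, _ = enumerate_products(frags)
        rebuilt = next(
            p for p in products
            if _canonical_circle(p.record.sequence) == _canonical_circle(acceptor.sequence)
        )
        again = digest(rebuilt.record, BBSI)
        assert Counter(f.seq for f in again) == Counter(f.seq for f in frags)

    def test_two_node_unique_cycle(self):
        a = TypeIISFragment(seq="AGGT" + "C" * 30 + "CGCT", lov=4, rov=4, name="bb")
        b = TypeIISFragment(seq="CGCT" + "G" * 20 + "AGGT", lov=4, rov=4, name="ins")
        products, _ = enumerate_products([a, b])
        assert len(products) == 1
        assert len(products[0].record) == 30 + 20 + 8

    def test_mismatched_overhang_no_products(self):
        a = TypeIISFragment(seq="AGGT" + "C" * 30 + "CGCT", lov=4, rov=4, name="bb")
        b = TypeIISFragment(seq="TTTT" + "G" * 20 + "AGGT", lov=4, rov=4, name="ins")
        products, _ = enumerate_products([a, b])
        assert products == []

    def test_duplicate_overhangs_flagged_and_ambiguous(self):
        bb = TypeIISFragment(seq="AGGT" + "C" * 30 + "CGCT", lov=4, rov=4, name="bb")
        i1 = TypeIISFragment(seq="CGCT" + "G" * 20 + "AGGT", lov=4, rov=4, name="i1")
        i2 = TypeIISFragment(seq="CGCT" + "GA" * 10 + "AGGT", lov=4, rov=4, name="i2")
        products, diags = enumerate_products([bb, i1, i2])
        assert len(products) > 1
        assert any("collision" in d for d in diags)


class TestOnePot:
    def _seed_insert(self, panel, cfg, sid="s8"):
        seed = next(s for s in panel if s.sid == sid)
        pair = design_seed_oligos(seed, cfg.scheme, BBSI)
        return anneal(pair.fwd, pair.rev, BBSI.overhang_len, name=f"seed_{sid}")

    def test_low_complexity_cloning(self, acceptor, panel, cfg):
        insert = self._seed_insert(panel, cfg)
        result = simulate_one_pot(acceptor, [insert], BBSI)
        assert result.intended_ok
        (product,) = result.products
        assert product.circular
        assert scan_type_iis(product, BBSI) == []
        assert insert.seq[4:-4] in product.sequence  # the seed is in the product

    def test_religated_acceptor_not_terminal(self, acceptor, panel, cfg):
        insert = self._seed_insert(panel, cfg)
        result = simulate_one_pot(acceptor, [insert], BBSI)
        assert any("not terminal" in d for d in result.diagnostics)

    def test_medium_complexity_two_inserts(self, cfg):
        from srnaforge import gen_multi_acceptor

        scheme = default_scheme(2)
        acc = gen_multi_acceptor(cfg, 2)
        rng = np.random.default_rng(3)

        def part(i, name, n=40):
            core = "".join(rng.choice(list("ACGT"), size=n))
            while "GAAGAC" in core or "GTCTTC" in core:
                core = "".join(rng.choice(list("ACGT"), size=n))
            return TypeIISFragment(
                seq=scheme.junctions[i] + core + scheme.junctions[i + 1],
                lov=4, rov=4, name=name,
            )

        promoter, seed = part(0, "promoter"), part(1, "seed")
        result = simulate_one_pot(acc, [promoter, seed], BBSI)
        assert result.intended_ok
        (product,) = result.products
        assert promoter.seq[4:-4] in product.sequence
        assert seed.seq[4:-4] in product.sequence

    def test_random_seed_battery_round_trip(self, acceptor, annotation, cfg):
        """Oligo design -> annealing -> one-pot succeeds across random seeds."""
        from srnaforge import make_seed

        rng = np.random.default_rng(9)
        n_ok = 0
        for i in range(25):
            a = int(rng.integers(1, len(annotation.mrna) - 16))
            seed = make_seed((a, a + 15), annotation, f"r{i}")
            if "GAAGAC" in seed.seq or "GTCTTC" in seed.seq:
                continue
            pair = design_seed_oligos(seed, cfg.scheme, BBSI)
            insert = anneal(pair.fwd, pair.rev, 4, name=f"seed_r{i}")
            assert simulate_one_pot(acceptor, [insert], BBSI).intended_ok
            n_ok += 1
        assert n_ok >= 20


class TestOligoAndPrimerDesign:
    def test_oligo_lengths_and_annealing(self, panel, cfg):
        seed = next(s for s in panel if s.sid == "s2")
        pair = design_seed_oligos(seed, cfg.scheme, BBSI)
        assert len(pair.fwd) == 20 and len(pair.rev) == 20
        frag = anneal(pair.fwd, pair.rev, 4)
        assert frag.duplex_len == 16
        assert frag.seq == pair.fragment.seq
        assert pair.phosphorylated

    def test_seed_with_internal_site_rejected(self, cfg):
        bad = SeedRegion(sid="bad", seq="AAAGAAGACAAAAAAA", region_label="TIR")
        with pytest.raises(DesignError, match="recognition site"):
            design_seed_oligos(bad, cfg.scheme, BBSI)

    def test_part_primer_amplicon_arithmetic(self):
        rng = np.random.default_rng(17)
        part = "".join(rng.choice(list("ACGT"), size=80))
        while "GAAGAC" in part or "GTCTTC" in part:
            part = "".join(rng.choice(list("ACGT"), size=80))
        fwd, rev = design_part_primers(part, BBSI, "AGGT", "CGCT")
        amplicon = simulate_pcr(part, fwd, rev)
        assert len(amplicon) == 80 + 2 * (2 + 6 + 2 + 4)
        frags = digest(amplicon, BBSI)
        middle = next(f for f in frags if f.lov and f.rov)
        assert middle.left_overhang == "AGGT"
        assert middle.right_overhang == "CGCT"

    def test_part_with_internal_site_advises_domestication(self):
        part = "ACGT" * 10 + "GAAGAC" + "ACGT" * 10
        with pytest.raises(DesignError, match="domestication"):
            design_part_primers(part, BBSI, "AGGT", "CGCT")


class TestSchemeQC:
    def test_palindrome_flagged(self):
        diags = check_overhang_scheme(OverhangScheme(junctions=("AATT", "CGCT")))
        assert any("palindromic" in d and "AATT" in d for d in diags)

    def test_duplicate_flagged(self):
        diags = check_overhang_scheme(OverhangScheme(junctions=("ACGG", "ACGG")))
        assert any("duplicate" in d for d in diags)

    def test_revcomp_collision_flagged(self):
        diags = check_overhang_scheme(OverhangScheme(junctions=("AAAC", "GTTT")))
        assert any("reverse-complement" in d for d in diags)

    def test_default_scheme_clean(self):
        diags = check_overhang_scheme(default_scheme(6))
        assert not any("palindromic" in d or "duplicate" in d or "collision" in d
                       for d in diags)
        assert all("hamming" in d for d in diags if "=" in d)
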