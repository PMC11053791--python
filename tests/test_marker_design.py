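import itertools
import re

import numpy as np
import pytest
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from introtrace.io_formats import CallSet, VariantRecord
from introtrace.marker_design import (
    ENZYMES,
    KASP_TAIL_FAM,
    KASP_TAIL_HEX,
    KaspPrimerSet,
    annotate_cds_variant,
    design_caps,
    design_indel_marker,
    design_kasp,
    find_linked_indels,
    insilico_digest,
    insilico_pcr,
)
from introtrace.synthetic_data import simulate_amplicons

BASES = "ACGT"


def _make_cds(codons_at: dict[int, str], n_codons: int = 645) -> str:
    """CDS of n_codons Ala codons with specific codons substituted."""
    codons = ["GCT"] * n_codons
    for num, codon in codons_at.items():
        codons[num - 1] = codon
    return "".join(codons)


class TestAnnotateCds:
    def test_ser_to_asn_at_codon_627(self):
        # codon 627 spans CDS 1879-1881; its middle base is position 1880
        cds = _make_cds({627: "AGC"})
        ann = annotate_cds_variant(cds, 1880, "G", "A")
        assert (ann.codon_number, ann.ref_aa, ann.alt_aa) == (627, "S", "N")
        assert ann.effect == "missense"
        assert ann.protein_change == "S627N"

    def test_val_to_met_at_codon_643(self):
        cds = _make_cds({643: "GTG"})
        ann = annotate_cds_variant(cds, 1927, "G", "A")
        assert ann.protein_change == "V643M"
        assert ann.effect == "missense"

    def test_wobble_synonymous(self):
        cds = _make_cds({2: "CTG"})
        ann = annotate_cds_variant(cds, 6, "G", "A")  # CTG -> CTA, both Leu
        assert ann.effect == "synonymous"
        assert ann.ref_aa == ann.alt_aa == "L"

    def test_nonsense(self):
        cds = _make_cds({2: "TGG"})
        ann = annotate_cds_variant(cds, 6, "G", "A")  # TGG -> TGA stop
        assert ann.effect == "nonsense"

    def test_ref_mismatch_names_observed_base(self):
        cds = _make_cds({})
        with pytest.raises(ValueError, match="observed G"):
            annotate_cds_variant(cds, 1, "A", "T")

    def test_length_not_multiple_of_three(self):
        with pytest.raises(ValueError, match="divisible"):
            annotate_cds_variant("GCTA", 1, "G", "A")

    def test_all_substitutions_match_codon_table(self):
        """Every single-base substitution of every codon agrees with an
        independent standard-table lookup."""
        table = unambiguous_dna_by_id[1]

        def aa(codon):
            return "*" if codon in table.stop_codons else table.forward_table[codon]

        for codon in ("".join(c) for c in itertools.product(BASES, repeat=3)):
            cds = codon + "GCTGCT"  # pad to length 9
            for pic in range(3):
                for alt in BASES:
                    if alt == codon[pic]:
                        continue
                    ann = annotate_cds_variant(cds, pic + 1, codon[pic], alt)
                    alt_codon = codon[:pic] + alt + codon[pic + 1:]
                    assert ann.ref_aa == aa(codon)
                    assert ann.alt_aa == aa(alt_codon)
                    expected = (
                        "synonymous" if aa(codon) == aa(alt_codon)
                        else "nonsense" if aa(alt_codon) == "*"
                        else "missense"
                    )
                    assert ann.effect == expected


class TestDigest:
    def test_no_site_single_fragment(self):
        assert insilico_digest("A" * 50, "HinfI") == [50]

    def test_cut_offset_arithmetic(self):
        amplicon = "A" * 100 + "GAATC" + "A" * 115
        assert insilico_digest(amplicon, "HinfI") == [101, 119]

    def test_unknown_enzyme_lists_builtins(self):
        with pytest.raises(KeyError, match="HinfI"):
            insilico_digest("AAAA", "NotAnEnzyme")

    def test_random_sequences_match_sequential_digestion_oracle(self):
        """Fragment multisets equal a brute-force oracle that literally
        re-digests fragments until no intact site remains."""

        def oracle(seq, motif_re, offset):
            frags = [seq]
            done = []
            while frags:
                f = frags.pop()
                m = motif_re.search(f)
                cut = m.start() + offset if m else None
                if m is None or cut == 0 or cut >= len(f):
                    done.append(len(f))
                else:
                    frags.extend([f[:cut], f[cut:]])
            return sorted(done)

        motif_re = re.compile("GA[ACGT]TC")
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(20, 400))
            seq = "".join(BASES[i] for i in rng.integers(0, 4, size=n))
            got = insilico_digest(seq, "HinfI")
            assert sum(got) == n
            assert sorted(got) == oracle(seq, motif_re, 1)

    def test_fragments_sum_to_length_many_random(self):
        rng = np.random.default_rng(11)
        for name in ENZYMES:
            for _ in range(50):
                n = int(rng.integers(10, 500))
                seq = "".join(BASES[i] for i in rng.integers(0, 4, size=n))
                assert sum(insilico_digest(seq, name)) == n


class TestInsilicoPcr:
    def test_planted_deletion_product_lengths(self):
        pair = simulate_amplicons(1, [49], seed=2, amplicon_len=191)[0]
        fwd = pair.ref_seq[:20]
        rev = str(Seq(pair.ref_seq[-20:]).reverse_complement())
        ref_product = insilico_pcr(pair.ref_seq, fwd, rev)
        donor_product = insilico_pcr(pair.donor_seq, fwd, rev)
        assert ref_product.ok and donor_product.ok
        assert (ref_product.length, donor_product.length) == (191, 142)

    def test_no_forward_match(self):
        res = insilico_pcr("A" * 100, "GATTACAGATTACAG", "TTTTTTTTTTTTTTT")
        assert res.status == "no_forward_site"

    def test_multiple_binding_sites_flagged(self):
        fwd = "GATTACAGATTACAG"
        template = fwd + "CCCC" + fwd + "CCCC" + "AAAAAAAAAAAAAAA"
        rev = str(Seq("AAAAAAAAAAAAAAA").reverse_complement())
        assert insilico_pcr(template, fwd, rev).status == "multiple_sites"

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError, match="15"):
            insilico_pcr("A" * 50, "ACGT", "ACGTACGTACGTACG")

    def test_matches_brute_force_scan_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(80, 300))
            template = "".join(BASES[i] for i in rng.integers(0, 4, size=n))
            f0 = int(rng.integers(0, n - 60))
            r1 = int(rng.integers(f0 + 45, n - 15))
            fwd = template[f0 : f0 + 18]
            rev = str(Seq(template[r1 : r1 + 15]).reverse_complement())
            res = insilico_pcr(template, fwd, rev)
            # oracle: exhaustive scan for both primer sites
            f_sites = [m.start() for m in re.finditer(f"(?={re.escape(fwd)})", template)]
            rc = str(Seq(rev).reverse_complement())
            r_sites = [m.start() for m in re.finditer(f"(?={re.escape(rc)})", template)]
            if len(f_sites) == 1 and len(r_sites) == 1:
                expected = r_sites[0] + len(rc) - f_sites[0]
                if expected > len(fwd):
                    assert res.ok and res.length == expected
                else:
                    assert not res.ok
            else:
                assert not res.ok


class TestFindLinkedIndels:
    def _cs(self, records):
        return CallSet("d", "ref", records)

    def test_empty_window(self):
        cs = self._cs([VariantRecord("chr2", 100, "A", "T", "hom_alt")])
        assert find_linked_indels(cs, ("chr2", 100), 50) == []

    def test_closed_interval_boundaries(self):
        edge = VariantRecord("chr2", 150, "A" * 31, "A", "hom_alt")
        out = VariantRecord("chr2", 151, "A" * 31, "A", "hom_alt")
        cs = self._cs([edge, out])
        hits = find_linked_indels(cs, ("chr2", 100), 50)
        assert [r.pos for r in hits] == [150]

    def test_size_selection_and_distance_sort(self):
        recs = [
            VariantRecord("chr2", 90, "A" * 50, "A", "hom_alt"),   # qualifies
            VariantRecord("chr2", 105, "A", "A" * 25, "hom_alt"),  # qualifies
            VariantRecord("chr2", 120, "A" * 10, "A", "hom_alt"),  # too small
            VariantRecord("chr2", 500, "A" * 50, "A", "hom_alt"),  # out of window
        ]
        cs = self._cs(recs)
        hits = find_linked_indels(cs, ("chr2", 100), 100, min_len=20, max_len=80)
        assert [r.pos for r in hits] == [105, 90]

    def test_flank_validation(self):
        with pytest.raises(ValueError):
            find_linked_indels(self._cs([]), ("chr2", 100), 0)


class TestDesignCaps:
    def test_both_alleles_cut_no_candidate(self):
        # GAGTC and GACTC both match GANTC: the SNP does not discriminate
        base = "ATTGCGCATTGCATCCGGAT"
        tail = "GGTACCAGTTGACCGGATCC"
        ref = base + "GAGTC" + tail
        alt = base + "GACTC" + tail
        assert design_caps(ref, alt, enzymes={"HinfI": ENZYMES["HinfI"]}) is None

    def test_site_loss_two_vs_one_fragments(self):
        base = "ATTGCGCATTGCATCCGGAT"
        tail = "GGTACCAGTTGACCGGATCC"
        ref = base + "GATTC" + tail
        alt = base + "GCTTC" + tail
        cand = design_caps(ref, alt, enzymes={"HinfI": ENZYMES["HinfI"]})
        assert cand is not None and cand.enzyme == "HinfI"
        assert len(cand.fragment_lengths["ref"]) == 2
        assert len(cand.fragment_lengths["alt"]) == 1
        assert sum(cand.fragment_lengths["ref"]) == len(ref)

    def test_simulated_site_altering_snps_detected(self):
        for pair in simulate_amplicons(4, [], enzyme_site="GANTC", seed=19):
            cand = design_caps(pair.ref_seq, pair.donor_seq,
                               enzymes={"HinfI": ENZYMES["HinfI"]})
            assert cand is not None
            assert cand.position == pair.snp_pos
            # the donor allele lost the site: one fragment vs two
            assert len(cand.fragment_lengths["alt"]) < len(cand.fragment_lengths["ref"])

    def test_requires_single_difference(self):
        with pytest.raises(ValueError, match="one differing"):
            design_caps("AAAA", "TTTT")


class TestDesignIndelMarker:
    def test_rediscovers_every_planted_indel(self):
        sizes = [49, 24, 41, 33, 46]
        for pair in simulate_amplicons(5, sizes, seed=29, amplicon_len=220):
            cand = design_indel_marker(
                pair.ref_seq, pair.donor_seq, pair.indel_start, pair.indel_len
            )
            assert cand is not None
            diff = cand.product_lengths["ref"] - cand.product_lengths["alt"]
            assert diff == pair.indel_len

    def test_size_outside_gel_range_rejected(self):
        pair = simulate_amplicons(1, [5], seed=1)[0]
        assert design_indel_marker(
            pair.ref_seq, pair.donor_seq, pair.indel_start, pair.indel_len
        ) is None


class TestDesignKasp:
    def test_table_style_forwards_differ_only_at_terminus(self):
        # published-style allele-specific forwards for a Ser->Asn site
        f1 = KASP_TAIL_FAM + "ATCATGTCCTTGAATGCGCCCCCAT"
        f2 = KASP_TAIL_HEX + "ATCATGTCCTTGAATGCGCCCCCAC"
        ps = KaspPrimerSet(
            allele1_forward=f1, allele2_forward=f2,
            common_reverse="CAGTCCGTGTAACAAAGAAGAGTGAAGTCC",
            tail1=KASP_TAIL_FAM, tail2=KASP_TAIL_HEX,
            chrom=None, pos=25, ref="T", alt="C",
        )
        u1, u2 = ps.untailed()
        assert u1[:-1] == u2[:-1] and u1[-1] != u2[-1]

    def test_mismatched_cores_rejected(self):
        with pytest.raises(ValueError, match="terminal"):
            KaspPrimerSet(
                allele1_forward=KASP_TAIL_FAM + "AAAAAAAAAAAAAAAAAAAAAAAAT",
                allele2_forward=KASP_TAIL_HEX + "AAAAAAAAAAAAAAACAAAAAAAAC",
                common_reverse="X" * 20,
                tail1=KASP_TAIL_FAM, tail2=KASP_TAIL_HEX,
                chrom=None, pos=1, ref="T", alt="C",
            )

    def test_design_on_random_variants_satisfies_invariants(self):
        rng = np.random.default_rng(37)
        for _ in range(100):
            n = 160
            flank = "".join(BASES[i] for i in rng.integers(0, 4, size=n))
            pos = int(rng.integers(30, n - 40))
            ref = flank[pos - 1]
            alt = rng.choice([b for b in BASES if b != ref])
            ps = design_kasp(flank, pos, ref, alt)
            u1, u2 = ps.untailed()
            assert u1[-1] == ref and u2[-1] == alt
            assert u1[:-1] == u2[:-1]
            assert ps.allele1_forward.startswith(KASP_TAIL_FAM)
            assert ps.allele2_forward.startswith(KASP_TAIL_HEX)
            # forward core anneals right up to the SNP on the template
            assert flank[pos - len(u1) : pos] == u1

    def test_palindromic_context_still_single_difference(self):
        flank = ("AT" * 40) + "G" + ("TA" * 40)
        pos = 81
        ps = design_kasp(flank, pos, "G", "C")
        u1, u2 = ps.untailed()
        diffs = [i for i, (a, b) in enumerate(zip(u1, u2)) if a != b]
        assert diffs == [len(u1) - 1]

    def test_short_flank_rejected(self):
        with pytest.raises(ValueError, match="flank"):
            design_kasp("ACGTACGTAA", 5, "A", "T")
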