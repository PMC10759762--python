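"""Anchor chaining, collinear variant calling and SSR scanning."""

import re

import numpy as np
import pytest

import karyohybrid as kh
from karyohybrid.cp_structure import PlastomeRecord
from karyohybrid.cp_variation import (
    SSRLocus,
    _left_align_deletion,
    _left_align_insertion,
    diff_ssr_catalogs,
    variant_set_symmetric_difference,
)
from karyohybrid.errors import InsufficientHomologyError, ReferenceMismatchError
from karyohybrid.simulate import (
    PlastomeSimSpec,
    derive_maternal_offspring,
    simulate_plastome,
)


def random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def regex_ssr_oracle(seq, thresholds):
    """Brute-force regex oracle: leftmost maximal primitive-motif runs.

    A non-primitive match (e.g. AA counted as a dinucleotide) does not
    consume the sequence, so phase-shifted runs behind it are still found.
    """
    def primitive(m):
        return all(
            m != m[:p] * (len(m) // p)
            for p in range(1, len(m))
            if len(m) % p == 0
        )

    loci = []
    for u, minrep in thresholds.items():
        pat = re.compile(rf"(.{{{u}}})\1{{{minrep - 1},}}")
        pos = 0
        while True:
            m = pat.search(seq, pos)
            if not m:
                break
            motif = m.group(1)
            if "N" not in motif and primitive(motif):
                loci.append(
                    (m.start() + 1, motif, (m.end() - m.start()) // u)
                )
                pos = m.end()
            else:
                pos = m.start() + 1
    return sorted(loci)


class TestAnchorChain:
    def test_identical_sequences_tile(self):
        s = random_seq(600, 0)
        chain = kh.anchor_chain(s, s, k=31)
        assert chain[0] == (0, 0)
        assert chain[-1] == (600 - 31, 600 - 31)
        assert all(r == q for r, q in chain)

    def test_single_substitution_opens_2k_gap(self):
        ref = random_seq(500, 1)
        p = 250
        alt = "A" if ref[p] != "A" else "C"
        qry = ref[:p] + alt + ref[p + 1 :]
        chain = kh.anchor_chain(qry, ref, k=31)
        rs = [r for r, _ in chain]
        gaps = [b - a for a, b in zip(rs, rs[1:])]
        # the k 31-mers covering p are destroyed, so the surviving anchors
        # flanking the site start k+1 positions apart
        assert max(gaps) == 31 + 1

    def test_unrelated_sequences_rejected(self):
        with pytest.raises(InsufficientHomologyError):
            kh.anchor_chain(random_seq(500, 2), random_seq(500, 3), k=31)


class TestCallVariants:
    def test_identity_is_empty(self):
        s = random_seq(2000, 4)
        assert kh.call_variants(s, s).calls == []

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_edit_recovery(self, seed):
        rec, _ = simulate_plastome(PlastomeSimSpec(seed=seed, ssr_plants=()))
        child, edits = derive_maternal_offspring(rec, n_subs=5, n_indels=2, seed=seed)
        calls = kh.call_variants(child, rec).calls
        assert [c.key() for c in calls] == [e.key() for e in edits]

    def test_planted_ca_insertion_pattern(self):
        ref = random_seq(3000, 9)
        p = 1500
        # avoid an ambiguous (shiftable) placement
        while ref[p - 1] == "A":
            p += 1
        qry = ref[:p] + "CA" + ref[p:]
        calls = kh.call_variants(qry, ref).calls
        assert len(calls) == 1
        assert calls[0].kind == "insertion"
        assert calls[0].alt_allele == "CA"
        assert calls[0].ref_pos == p

    def test_gene_annotation_on_reference_features(self):
        rec, _ = simulate_plastome(PlastomeSimSpec(seed=12, ssr_plants=()))
        seq = rec.sequence
        p = 1500  # inside the matK stub (1200-1800)
        alt = "A" if seq[p - 1] != "A" else "G"
        qry = seq[: p - 1] + alt + seq[p:]
        calls = kh.call_variants(PlastomeRecord("q", qry), rec).calls
        assert [c.gene for c in calls if c.kind == "substitution"] == ["matK"]


class TestIndelNormalization:
    def test_deletion_left_aligned_in_homopolymer(self):
        #            123456789
        ref = "GGGAAAATCC"
        assert _left_align_deletion(6, "A", ref) == (4, "A")

    def test_insertion_left_aligned_in_repeat(self):
        ref = "GGCACACATT"
        # inserting CA after position 8 is the same event as after position 2
        assert _left_align_insertion(8, "CA", ref) == (2, "CA")

    def test_caller_emits_left_aligned_deletion(self):
        ref = random_seq(1000, 5)
        ref = ref[:500] + "AAAAA" + ref[505:]
        qry = ref[:503] + ref[504:]  # delete one A mid-run
        calls = kh.call_variants(qry, ref).calls
        assert len(calls) == 1
        c = calls[0]
        assert (c.kind, c.ref_allele) == ("deletion", "A")
        assert ref[c.ref_pos - 2] != "A"  # leftmost representation


class TestSharedSites:
    def _vset(self, subs, ref="R", query="Q"):
        calls = [kh.VariantCall(p, "substitution", r, a) for p, r, a in subs]
        return kh.VariantSet(reference_id=ref, query_id=query, calls=calls)

    def test_self_and_disjoint(self):
        a = self._vset([(10, "A", "G"), (20, "C", "T")])
        assert kh.shared_snp_sites(a, a) == 2
        b = self._vset([(30, "A", "G")])
        assert kh.shared_snp_sites(a, b) == 0

    def test_bounded_and_symmetric(self):
        a = self._vset([(10, "A", "G"), (20, "C", "T"), (30, "G", "A")])
        b = self._vset([(20, "C", "T"), (40, "T", "C")])
        n = kh.shared_snp_sites(a, b)
        assert n == kh.shared_snp_sites(b, a) == 1
        assert n <= min(len(a.substitutions), len(b.substitutions))

    def test_reference_mismatch_rejected(self):
        a = self._vset([(10, "A", "G")], ref="R1")
        b = self._vset([(10, "A", "G")], ref="R2")
        with pytest.raises(ReferenceMismatchError):
            kh.shared_snp_sites(a, b)

    def test_maternal_trio_sharing(self):
        rec, _ = simulate_plastome(PlastomeSimSpec(seed=21, ssr_plants=()))
        parent, _ = derive_maternal_offspring(rec, n_subs=6, n_indels=0, seed=1)
        parent.id = "parent"
        hybrid, _ = derive_maternal_offspring(parent, n_subs=3, n_indels=0, seed=2)
        pv = kh.call_variants(parent, rec)
        hv = kh.call_variants(hybrid, rec)
        assert kh.shared_snp_sites(pv, hv) == len(pv.substitutions) == 6


class TestSSRScanner:
    def test_planted_mononucleotide_run(self):
        rec, truth = simulate_plastome(PlastomeSimSpec(seed=30544))
        loci = {(l.start, l.motif, l.repeats) for l in kh.find_ssrs(rec) if not l.compound}
        assert set(truth["ssrs"]) <= loci

    def test_penta_repeat_threshold(self):
        seq = random_seq(200, 6) + "C" + "GGAAA" * 3 + "C" + random_seq(200, 7)
        hits = [l for l in kh.find_ssrs(seq) if l.motif == "GGAAA"]
        assert len(hits) == 1 and hits[0].repeats == 3
        assert not [
            l for l in kh.find_ssrs(seq, thresholds={5: 4}) if l.motif == "GGAAA"
        ]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_regex_oracle(self, seed):
        seq = random_seq(2000, 1000 + seed)
        found = kh.find_ssrs(seq, compound_gap=-1)
        got = sorted((l.start, l.motif, l.repeats) for l in found)
        assert got == regex_ssr_oracle(seq, kh.DEFAULT_SSR_THRESHOLDS)

    def test_threshold_monotonicity(self):
        seq = random_seq(5000, 77) + "TTTTTTTTTT" + random_seq(100, 78)
        base = {(l.start, l.motif) for l in kh.find_ssrs(seq, compound_gap=-1)}
        lower = {t: max(1, v - 1) for t, v in kh.DEFAULT_SSR_THRESHOLDS.items()}
        relaxed = {
            (l.start, l.motif)
            for l in kh.find_ssrs(seq, thresholds=lower, compound_gap=-1)
        }
        assert base <= relaxed

    def test_compound_merging(self):
        gap20 = "GCTAGGCTGACGGATCCGTG"  # aperiodic spacer, no A/T runs
        seq = "C" + "A" * 10 + gap20 + "T" * 12 + "G" + random_seq(300, 9)
        merged = kh.find_ssrs(seq, compound_gap=100)
        assert any(l.compound and len(l.components) == 2 for l in merged)
        unmerged = kh.find_ssrs(seq, compound_gap=5)
        assert not any(l.compound for l in unmerged)


class TestSSRDiff:
    def _locus(self, start, motif, repeats):
        return SSRLocus(start=start, motif=motif, repeats=repeats, unit_size=len(motif))

    def test_identical_catalogs(self):
        cat = [self._locus(100, "A", 10), self._locus(400, "AT", 6)]
        diff = diff_ssr_catalogs(cat, list(cat))
        assert len(diff["identical"]) == 2
        assert not diff["private_a"] and not diff["private_b"]

    def test_repeat_count_change(self):
        a = [self._locus(30544, "A", 10)]
        b = [self._locus(30544, "A", 11)]
        diff = diff_ssr_catalogs(a, b)
        assert len(diff["repeat_changed"]) == 1

    def test_motif_change_same_site(self):
        a = [self._locus(111168, "GGAAA", 3)]
        b = [self._locus(111168, "CGAAA", 3)]
        diff = diff_ssr_catalogs(a, b)
        assert len(diff["motif_changed"]) == 1

    def test_versus_empty_catalog(self):
        a = [self._locus(10, "T", 12)]
        diff = diff_ssr_catalogs(a, [])
        assert diff["private_a"] == a and not diff["identical"]


class TestVCF:
    def test_minimal_vcf_output(self, tmp_path):
        ref = random_seq(300, 11)
        p = 150
        alt = "A" if ref[p - 1] != "A" else "C"
        qry = ref[: p - 1] + alt + ref[p:]
        vset = kh.call_variants(qry, ref)
        out = tmp_path / "v.vcf"
        kh.write_vcf(vset, ref, out)
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 1
        chrom, pos, _, r, a, _, filt, info = lines[0].split("\t")
        assert (int(pos), r, a, filt) == (p, ref[p - 1], alt, "PASS")
        assert "TYPE=substitution" in info


def test_symmetric_difference_counts_all_kinds():
    a = kh.VariantSet("R", "q1", [kh.VariantCall(5, "substitution", "A", "G")])
    b = kh.VariantSet("R", "q2", [
        kh.VariantCall(5, "substitution", "A", "G"),
        kh.VariantCall(9, "deletion", "TT", ""),
    ])
    assert variant_set_symmetric_difference(a, b) == 1
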