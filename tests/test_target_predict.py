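import numpy as np
import pytest
from Bio.Seq import Seq

from mirprog.io_formats import GeneList, read_fasta, read_gene_list
from mirprog.quantify import ExpressionMatrix
from mirprog.target_predict import (
    MatureMiRNA,
    PredictionSet,
    SITE_CLASSES,
    consensus_targets,
    derive_seed_matches,
    downstream_intersection,
    intersect_upregulated,
    rank_candidates,
    scan_utr,
    seed_filter,
)

_SPEC = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 1, "6mer": 0}


def oracle_scan(utr: str, mirna: MatureMiRNA):
    """Exhaustive position-by-position scanner, independent of scan_utr.

    Uses Biopython's reverse complement to derive the match strings and
    checks every substring window; then drops any match contained in a
    strictly more specific retained match (resolving equal-interval
    duplicates by specificity).
    """
    seq = mirna.sequence
    matches = {
        "6mer": str(Seq(seq[1:7]).reverse_complement()),
        "7mer-m8": str(Seq(seq[1:8]).reverse_complement()),
        "7mer-A1": str(Seq(seq[1:7]).reverse_complement()) + "A",
        "8mer": str(Seq(seq[1:8]).reverse_complement()) + "A",
    }
    utr = utr.upper().replace("U", "T")
    found = []
    for cls, pat in matches.items():
        for start in range(len(utr) - len(pat) + 1):
            if utr[start : start + len(pat)] == pat:
                found.append((start + 1, start + len(pat), cls, pat))
    kept = []
    for site in sorted(found, key=lambda s: (-_SPEC[s[2]], s[0])):
        covered = any(
            k[0] <= site[0] and site[1] <= k[1] and _SPEC[k[2]] > _SPEC[site[2]]
            for k in kept
        )
        same_span = any((k[0], k[1]) == (site[0], site[1]) for k in kept)
        if not covered and not same_span:
            kept.append(site)
    return sorted(kept)


class TestSeedMatches:
    def test_mir375_seven_mer_a1_matches_reported_site(self, mir375):
        assert derive_seed_matches(mir375)["7mer-A1"] == "GAACAAA"

    def test_mir375_other_classes(self, mir375):
        matches = derive_seed_matches(mir375)
        assert matches["6mer"] == "GAACAA"
        assert matches["7mer-m8"] == "CGAACAA"
        assert matches["8mer"] == "CGAACAAA"

    def test_matches_agree_with_independent_revcomp(self, mir375):
        matches = derive_seed_matches(mir375)
        assert matches["6mer"] == str(Seq(mir375.sequence[1:7]).reverse_complement())
        assert matches["7mer-m8"] == str(Seq(mir375.sequence[1:8]).reverse_complement())

    def test_homopolymer(self):
        matches = derive_seed_matches(MatureMiRNA("u8", "UUUUUUUU"))
        assert matches["6mer"] == "AAAAAA"
        assert matches["8mer"] == "AAAAAAAA"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="8 nt"):
            MatureMiRNA("short", "UUUU")

    def test_packaged_fixture_is_the_same_mirna(self, mir375, mir375_fasta):
        seqs = read_fasta(mir375_fasta)
        assert next(iter(seqs.values())) == mir375.sequence


class TestScanUTR:
    def test_planted_7mer_a1_located(self, mir375):
        sites = scan_utr("u", "TTT" + "GAACAAA" + "TTT", mir375)
        assert len(sites) == 1
        s = sites[0]
        assert (s.start, s.end, s.site_class) == (4, 10, "7mer-A1")
        assert s.matched_seq == "GAACAAA"

    def test_no_complement_no_sites(self, mir375):
        assert scan_utr("u", "TTTTTTTTTTTT", mir375) == []

    def test_nested_classes_collapse_to_8mer(self, mir375):
        sites = scan_utr("u", "CGAACAAA", mir375)
        assert len(sites) == 1
        assert (sites[0].start, sites[0].end, sites[0].site_class) == (1, 8, "8mer")

    def test_empty_utr(self, mir375):
        assert scan_utr("u", "", mir375) == []

    def test_matched_seq_equals_utr_substring(self, mir375):
        utr = "ACGTGAACAAATTTCGAACAATT"
        for s in scan_utr("u", utr, mir375):
            assert utr[s.start - 1 : s.end] == s.matched_seq

    def test_agrees_with_exhaustive_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for case in range(300):
            mirna = MatureMiRNA(f"m{case}", "".join(rng.choice(bases, size=21)))
            utr = "".join(rng.choice(bases, size=int(rng.integers(30, 400))))
            got = [(s.start, s.end, s.site_class, s.matched_seq)
                   for s in scan_utr("u", utr, mirna)]
            assert sorted(got) == oracle_scan(utr, mirna)

    def test_reverse_complement_strand_is_not_searched(self, mir375):
        utr = "TTT" + "GAACAAA" + "TTTT"
        rc = str(Seq(utr).reverse_complement())
        assert len(scan_utr("u", utr, mir375)) == 1
        assert scan_utr("u", rc, mir375) == []


class TestConsensus:
    def _sets(self, memberships):
        return [
            PredictionSet(f"tool{i}", "miR-x", GeneList.from_iterable(f"tool{i}", genes))
            for i, genes in enumerate(memberships)
        ]

    def test_three_of_six_kept_at_k3(self):
        sets = self._sets([["g"], ["g"], ["g"], [], [], []])
        assert consensus_targets(sets, 3).genes == {"G"}

    def test_two_of_six_dropped_at_k3(self):
        sets = self._sets([["g"], ["g"], [], [], [], []])
        assert consensus_targets(sets, 3).genes == set()

    def test_k1_is_the_union(self):
        sets = self._sets([["a"], ["b"], ["c"]])
        assert consensus_targets(sets, 1).genes == {"A", "B", "C"}

    def test_monotone_decreasing_in_k(self, rng):
        genes = [f"g{i}" for i in range(30)]
        sets = self._sets(
            [[g for g in genes if rng.random() < 0.4] for _ in range(6)]
        )
        previous = None
        for k in range(1, 7):
            current = consensus_targets(sets, k).genes
            if previous is not None:
                assert current <= previous
            previous = current

    def test_mixed_mirnas_rejected(self):
        sets = [
            PredictionSet("t1", "miR-a", GeneList.from_iterable("t1", ["g"])),
            PredictionSet("t2", "miR-b", GeneList.from_iterable("t2", ["g"])),
        ]
        with pytest.raises(ValueError, match="mix"):
            consensus_targets(sets, 1)


class TestIntersections:
    def test_plain_intersection(self):
        a = GeneList.from_iterable("a", ["A", "B", "C"])
        b = GeneList.from_iterable("b", ["B", "C", "D"])
        assert intersect_upregulated(a, b).genes == {"B", "C"}

    def test_disjoint(self):
        a = GeneList.from_iterable("a", ["A"])
        b = GeneList.from_iterable("b", ["B"])
        assert intersect_upregulated(a, b).genes == set()

    def test_case_insensitive(self):
        a = GeneList.from_iterable("a", ["KLF5"])
        b = GeneList.from_iterable("b", ["klf5"])
        assert intersect_upregulated(a, b).genes == {"KLF5"}

    def test_regulator_target_narrowing_on_packaged_list(self):
        from importlib.resources import files

        regulator = read_gene_list(
            files("mirprog.data") / "klf5_ipa_targets_synthetic.tsv"
        )
        assert len(regulator) == 50
        upregulated = GeneList.from_iterable("up", ["KLF5", "BIRC5", "NOVELX"])
        hit = downstream_intersection(upregulated, regulator)
        assert hit.genes == {"KLF5", "BIRC5"}

    def test_empty_regulator_list(self):
        up = GeneList.from_iterable("up", ["KLF5"])
        assert downstream_intersection(up, GeneList("empty")).genes == set()

    def test_self_intersection_is_identity(self):
        up = GeneList.from_iterable("up", ["A", "B"])
        assert downstream_intersection(up, up).genes == up.genes


class TestSeedFilter:
    def test_seven_mer_kept_six_mer_dropped(self, mir375):
        genes = GeneList.from_iterable("g", ["HAS7", "HAS6"])
        utrs = {"HAS7": "TTGAACAAATT", "HAS6": "TTGAACAATT"}  # 7mer-A1 vs 6mer only
        kept = seed_filter(genes, utrs, mir375, "7mer")
        assert kept.genes == {"HAS7"}

    def test_min_class_6mer_keeps_both(self, mir375):
        genes = GeneList.from_iterable("g", ["HAS7", "HAS6"])
        utrs = {"HAS7": "TTGAACAAATT", "HAS6": "TTGAACAATT"}
        assert seed_filter(genes, utrs, mir375, "6mer").genes == {"HAS7", "HAS6"}

    def test_missing_utr_dropped_with_warning(self, mir375):
        genes = GeneList.from_iterable("g", ["LOST"])
        with pytest.warns(UserWarning, match="LOST"):
            kept = seed_filter(genes, {}, mir375)
        assert len(kept) == 0


def _expr(manifest, assay, per_stage_values, feature_ids):
    """ExpressionMatrix with the same per-stage values in every patient."""
    sub = manifest.subset(assay)
    sample_ids = sub.sample_ids
    rows = []
    for fid in feature_ids:
        row = []
        for s in sample_ids:
            stage = sub.samples.set_index("sample_id").loc[s, "stage"]
            row.append(per_stage_values[fid][("normal", "OLP", "OSCC").index(stage)])
        rows.append(row)
    return ExpressionMatrix(list(feature_ids), sample_ids, np.array(rows, float),
                            "RPKM" if assay == "mRNA" else "per_million")


class TestRanking:
    def test_opposed_profiles_give_anticorr_minus_one(self, manifest_two_patients):
        mirna_expr = _expr(manifest_two_patients, "miRNA", {"miR-x": (4, 2, 1)}, ["miR-x"])
        mrna_expr = _expr(manifest_two_patients, "mRNA", {"RISER": (1, 2, 4)}, ["RISER"])
        ranked = rank_candidates(
            GeneList.from_iterable("g", ["RISER"]),
            mrna_expr, mirna_expr,
            MatureMiRNA("miR-x", "UUUGUUCGUUCGGCUCGCGUGA"),
            manifest_two_patients,
        )
        assert ranked[0].anticorr == pytest.approx(-1.0)

    def test_flat_gene_has_undefined_anticorr_and_ranks_last(self, manifest_two_patients):
        mirna_expr = _expr(manifest_two_patients, "miRNA", {"miR-x": (4, 2, 1)}, ["miR-x"])
        mrna_expr = _expr(
            manifest_two_patients, "mRNA",
            {"FLAT": (3, 3, 3), "RISER": (1, 2, 4)}, ["FLAT", "RISER"],
        )
        ranked = rank_candidates(
            GeneList.from_iterable("g", ["FLAT", "RISER"]),
            mrna_expr, mirna_expr,
            MatureMiRNA("miR-x", "UUUGUUCGUUCGGCUCGCGUGA"),
            manifest_two_patients,
        )
        # same peak expression (4 vs 3): RISER peaks higher and leads anyway;
        # check the degenerate gene reports nan
        flat = next(c for c in ranked if c.gene == "FLAT")
        assert np.isnan(flat.anticorr)
        assert ranked[0].gene == "RISER"

    def test_highest_abundance_ranks_first(self, manifest_two_patients):
        mirna_expr = _expr(manifest_two_patients, "miRNA", {"miR-x": (4, 2, 1)}, ["miR-x"])
        mrna_expr = _expr(
            manifest_two_patients, "mRNA",
            {"BIG": (10, 20, 40), "SMALL": (1, 2, 4)}, ["BIG", "SMALL"],
        )
        ranked = rank_candidates(
            GeneList.from_iterable("g", ["SMALL", "BIG"]),
            mrna_expr, mirna_expr,
            MatureMiRNA("miR-x", "UUUGUUCGUUCGGCUCGCGUGA"),
            manifest_two_patients,
        )
        assert [c.gene for c in ranked] == ["BIG", "SMALL"]
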