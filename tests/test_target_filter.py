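"""Prioritization funnel set algebra, shortlist ranking, seed-site scanning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirhts.target_filter import (
    SeedSite,
    annotate_and_shortlist,
    apply_site_deletion,
    build_sets,
    filter_targets,
    find_seed_sites,
    sites_to_frame,
)

HITS = ["miR-509-5p", "miR-509-3p"]
NON_HITS = ["miR-381", "miR-550a", "miR-873", "miR-432"]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_scan(utr: str, mir: str):
    """Character-level scan straight from the seed-pairing definitions:
    UTR position i+j pairs the complement of miR seed bases in antiparallel
    order; the A1 classes require an adenine opposite miR position 1.
    Longest class wins at a locus."""
    utr = utr.upper().replace("U", "T")
    mir = mir.upper().replace("U", "T")

    def pairs(i, mir_pos):  # mir_pos is 1-based
        return utr[i] == _COMP[mir[mir_pos - 1]]

    hits8, hits7 = [], []
    for i in range(len(utr) - 7):
        # positions i..i+6 pair miR 8..2; i+7 is the A1 adenine
        if all(pairs(i + j, 8 - j) for j in range(7)) and utr[i + 7] == "A":
            hits8.append((i + 1, i + 8, "8mer-A1"))
    for i in range(len(utr) - 6):
        if all(pairs(i + j, 8 - j) for j in range(7)):
            hits7.append((i + 1, i + 7, "7mer-m8"))
        elif all(pairs(i + j, 7 - j) for j in range(6)) and utr[i + 6] == "A":
            hits7.append((i + 1, i + 7, "7mer-A1"))
    out = list(hits8)
    for a, b, cls in hits7:
        if not any(a >= s and b <= e for s, e, _ in hits8):
            out.append((a, b, cls))
    return sorted(out)


class TestBuildSets:
    def predictions(self):
        rows = [
            ("G1", "miR-509-5p", "predictorA", -0.4),
            ("G2", "miR-509-3p", "predictorB", 80.0),
            ("G2", "miR-381", "predictorA", -0.2),
            ("G3", "miR-550a", "predictorB", 60.0),
            ("G4", "miR-136", "predictorA", -0.3),  # excluded miR: in no group
        ]
        return pd.DataFrame(rows, columns=["gene", "mir", "source", "score"])

    def expression(self):
        return pd.DataFrame(
            {"gene": ["G1", "G2", "G3", "G4"], "call": ["present", "marginal", "absent", "present"]}
        )

    def test_excluded_mir_contributes_to_no_set(self):
        set1, set2, set3 = build_sets(self.predictions(), HITS, NON_HITS, self.expression())
        assert set1 == {"G1", "G2"}
        assert set2 == {"G2", "G3"}  # only the 4 non-hit miRs, never miR-136
        assert set3 == {"G1", "G2", "G4"}

    def test_empty_predictions_give_empty_sets(self):
        empty = pd.DataFrame(columns=["gene", "mir", "source", "score"])
        set1, set2, set3 = build_sets(empty, HITS, NON_HITS, self.expression())
        assert set1 == set() and set2 == set()

    def test_overlapping_mir_groups_rejected(self):
        with pytest.raises(ValueError):
            build_sets(self.predictions(), HITS, HITS[:1] + NON_HITS, self.expression())

    def test_symbol_matching_is_case_insensitive(self):
        preds = self.predictions()
        preds.loc[0, "gene"] = "g1"
        set1, _, _ = build_sets(preds, HITS, NON_HITS, self.expression())
        assert "G1" in set1


class TestFilterTargets:
    def test_worked_example(self):
        out = filter_targets({"A", "B", "C", "D"}, {"B"}, {"A", "B", "C"})
        assert out == {"A", "C"}

    def test_dominating_exclusion_empties_output(self):
        assert filter_targets({"A", "B"}, {"A", "B", "C"}, {"A", "B"}) == set()

    @given(
        st.sets(st.integers(0, 30)),
        st.sets(st.integers(0, 30)),
        st.sets(st.integers(0, 30)),
    )
    def test_equals_per_gene_membership_oracle(self, s1, s2, s3):
        out = filter_targets(s1, s2, s3)
        oracle = {g for g in s1 | s2 | s3 if g in s1 and g in s3 and g not in s2}
        assert out == oracle
        # idempotence and bound
        assert filter_targets(out, s2, s3) == out & s3
        assert out <= s1

    def test_monotone_in_exclusion_set(self, rng):
        for _ in range(100):
            s1 = set(rng.choice(50, size=rng.integers(0, 30), replace=False).tolist())
            s2 = set(rng.choice(50, size=rng.integers(0, 30), replace=False).tolist())
            s3 = set(rng.choice(50, size=rng.integers(0, 30), replace=False).tolist())
            bigger = filter_targets(s1, s2, s3)
            smaller_s2 = s2 - {next(iter(s2))} if s2 else s2
            assert filter_targets(s1, smaller_s2, s3) >= bigger


class TestAnnotateAndShortlist:
    def fixture(self):
        preds = pd.DataFrame(
            [
                ("RAB", "miR-509-3p", "predictorA", -0.65),
                ("RAB", "miR-509-3p", "predictorB", 91.0),
                ("OTH", "miR-509-3p", "predictorA", -0.30),
                ("OTH", "miR-509-3p", "predictorB", 80.0),
                ("LIT", "miR-509-5p", "predictorA", -0.10),
                ("NOG", "miR-509-5p", "predictorB", 95.0),
            ],
            columns=["gene", "mir", "source", "score"],
        )
        ann = pd.DataFrame(
            {
                "gene": ["RAB", "OTH", "LIT", "NOG"],
                "growth_related": [True, True, True, False],
                "leukemia_oncogenesis_literature": [False, False, True, False],
            }
        )
        return preds, ann

    def test_strong_dual_source_gene_ranks_first(self):
        preds, ann = self.fixture()
        out = annotate_and_shortlist({"RAB", "OTH", "LIT", "NOG"}, ann, preds, HITS)
        shortlisted = out[out["shortlisted"]]["gene"].tolist()
        assert shortlisted[0] == "RAB"  # (-0.65, 91) outranks (-0.30, 80)
        assert "NOG" not in out["gene"].tolist()  # not growth-related

    def test_literature_only_gene_is_shortlisted(self):
        preds, ann = self.fixture()
        out = annotate_and_shortlist({"LIT"}, ann, preds, HITS)
        assert out.loc[out["gene"] == "LIT", "shortlisted"].item()
        assert not out.loc[out["gene"] == "LIT", "both_sources"].item()

    def test_missing_annotation_counts_as_not_growth_related(self):
        preds, ann = self.fixture()
        out = annotate_and_shortlist({"RAB", "UNSEEN"}, ann, preds, HITS)
        assert "UNSEEN" not in out["gene"].tolist()

    def test_no_growth_related_genes_gives_empty_shortlist(self):
        preds, ann = self.fixture()
        out = annotate_and_shortlist({"NOG"}, ann, preds, HITS)
        assert out.empty

    def test_ranking_matches_brute_force_sort(self, rng):
        genes = [f"G{i}" for i in range(20)]
        rows = []
        for g in genes:
            rows.append((g, "miR-509-3p", "predictorA", float(rng.uniform(-0.9, -0.1))))
            rows.append((g, "miR-509-3p", "predictorB", float(rng.uniform(50, 99))))
        preds = pd.DataFrame(rows, columns=["gene", "mir", "source", "score"])
        ann = pd.DataFrame(
            {
                "gene": genes,
                "growth_related": True,
                "leukemia_oncogenesis_literature": False,
            }
        )
        out = annotate_and_shortlist(set(genes), ann, preds, HITS)
        scores = {
            g: (
                preds[(preds.gene == g) & (preds.source == "predictorA")].score.min(),
                -preds[(preds.gene == g) & (preds.source == "predictorB")].score.max(),
                g,
            )
            for g in genes
        }
        expected = sorted(genes, key=lambda g: scores[g])
        assert out["gene"].tolist() == expected


class TestFindSeedSites:
    def test_agrees_with_naive_scan_on_random_sequences(self, rng, mir_seq):
        """1,000 random 120-nt sequences: scanner == definition-level scan."""
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            seq = "".join(bases[rng.integers(0, 4, size=120)])
            got = [(s.start, s.end, s.site_class) for s in find_seed_sites(seq, mir_seq)]
            assert sorted(got) == naive_scan(seq, mir_seq)

    def test_empty_on_matchless_sequence(self, mir_seq):
        assert find_seed_sites("ACGT" * 30, mir_seq) == []

    def test_sliding_a_site_shifts_coordinates(self, mir_seq):
        from mirhts.simulate import plant_utr_sites

        for k in (0, 5, 13):
            rec = plant_utr_sites(150, mir_seq, [40 + k], ["7mer-m8"], rng_seed=31)
            (site,) = find_seed_sites(str(rec.seq), mir_seq)
            assert (site.start, site.end) == (40 + k, 46 + k)

    def test_ambiguous_bases_warn_and_skip(self, mir_seq):
        from mirhts.target_filter import site_sequences

        seq = "N" * 10 + site_sequences(mir_seq)["7mer-m8"] + "N" * 10
        with pytest.warns(UserWarning):
            sites = find_seed_sites(seq, mir_seq)
        assert [(s.start, s.end) for s in sites] == [(11, 17)]

    def test_rna_and_dna_utrs_equivalent(self, planted_utr, mir_seq):
        dna = str(planted_utr.seq)
        rna = dna.replace("T", "U")
        assert find_seed_sites(dna, mir_seq) == find_seed_sites(rna, mir_seq)


class TestSiteDeletion:
    def test_deleting_one_site_leaves_the_other(self, planted_utr, mir_seq):
        sites = find_seed_sites(str(planted_utr.seq), mir_seq)
        d1 = apply_site_deletion(str(planted_utr.seq), sites[0])
        remaining = find_seed_sites(d1, mir_seq)
        assert len(remaining) == 1
        assert remaining[0].site_class == "8mer-A1"
        # downstream coordinates shift left by the excised length
        assert remaining[0].start == sites[1].start - (sites[0].end - sites[0].start + 1)

    def test_deleting_both_sites_silences_the_utr(self, planted_utr, mir_seq):
        seq = str(planted_utr.seq)
        sites = find_seed_sites(seq, mir_seq)
        # delete 3'-most first so the 5' coordinates stay valid
        for site in sorted(sites, key=lambda s: -s.start):
            seq = apply_site_deletion(seq, site)
        assert find_seed_sites(seq, mir_seq) == []

    def test_deleting_a_non_site_span_preserves_sites(self, planted_utr, mir_seq):
        seq = str(planted_utr.seq)
        out = apply_site_deletion(seq, SeedSite(200, 207, "8mer-A1"))
        sites = find_seed_sites(out, mir_seq)
        assert [(s.start, s.end) for s in sites] == [(66, 72), (751, 758)]

    def test_out_of_bounds_deletion_rejected(self):
        with pytest.raises(ValueError):
            apply_site_deletion("ACGTACGT", SeedSite(5, 12, "8mer-A1"))

    def test_sites_frame_columns(self, planted_utr, mir_seq):
        frame = sites_to_frame(find_seed_sites(str(planted_utr.seq), mir_seq), gene="X")
        assert list(frame.columns) == ["gene", "mir", "start", "end", "site_class"]
        assert len(frame) == 2
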