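import pytest

from gdrep.core import ChainJunction, Cohort, SingleCellRecord
from gdrep.junctions import decompose
from gdrep.publicity import (
    convergence_report,
    dominant_clone_fraction,
    overlap_matrix,
    pseudoclonotype_report,
    sharing_fraction,
    top_shared_hierarchy,
)
from gdrep.simulate import RecombinationModel, simulate_cohort

from conftest import GERMLINE_AA, VARIANTS_N, cohort_from_aa_sets


class TestSharingFraction:
    def test_private_repertoire_shares_nothing(self):
        cohort = cohort_from_aa_sets([{"CAAF", "CTTF"}, {"CGGF", "CHHF"}])
        assert sharing_fraction(cohort, "d1").fraction == 0.0

    def test_identical_repertoires_share_everything(self):
        cohort = cohort_from_aa_sets([{"CAAF", "CTTF"}, {"CAAF", "CTTF"}])
        assert sharing_fraction(cohort, "d1").fraction == 1.0

    def test_three_donor_worked_example(self):
        # donor A = {x, y, z}: x in B only, y in B and C, z nowhere
        cohort = cohort_from_aa_sets(
            [
                {"CIAF", "CKAF", "CLAF"},
                {"CIAF", "CKAF"},
                {"CKAF", "CQAF"},
            ]
        )
        assert sharing_fraction(cohort, "d1", min_other_donors=1).fraction == (
            pytest.approx(2 / 3)
        )
        assert sharing_fraction(cohort, "d1", min_other_donors=2).fraction == (
            pytest.approx(1 / 3)
        )

    def test_monotone_non_increasing_in_min_other_donors(self):
        cohort = cohort_from_aa_sets(
            [
                {"CAAF", "CCCF", "CDDF", "CEEF"},
                {"CAAF", "CCCF"},
                {"CAAF", "CDDF"},
                {"CAAF"},
            ]
        )
        fractions = [
            sharing_fraction(cohort, "d1", min_other_donors=k).fraction
            for k in (1, 2, 3)
        ]
        assert fractions == sorted(fractions, reverse=True)


class TestOverlapMatrix:
    def test_disjoint_repertoires(self):
        cohort = cohort_from_aa_sets([{"CAAF"}, {"CGGF"}])
        assert overlap_matrix(cohort).pair("d1", "d2") == 0.0

    def test_subset_saturates_min_normalised_overlap(self):
        cohort = cohort_from_aa_sets([{"CAAF", "CGGF", "CDDF"}, {"CAAF", "CGGF"}])
        assert overlap_matrix(cohort).pair("d1", "d2") == 1.0

    def test_min_normalisation(self):
        a = {"CAAF", "CGGF", "CDDF", "CEEF"}
        b = {"CAAF", "CGGF", "CHHF", "CIIF", "CKKF", "CLLF"}
        cohort = cohort_from_aa_sets([a, b])
        assert overlap_matrix(cohort).pair("d1", "d2") == pytest.approx(0.5)

    def test_symmetric_with_unit_diagonal_and_relabelling_invariance(self):
        sets = [{"CAAF", "CGGF"}, {"CAAF"}, {"CDDF", "CGGF"}]
        om = overlap_matrix(cohort_from_aa_sets(sets))
        assert (om.values == om.values.T).all()
        assert (om.values.diagonal() == 1).all()
        om2 = overlap_matrix(cohort_from_aa_sets(sets[::-1]))
        assert om.pair("d1", "d3") == om2.pair("d3", "d1")


class TestTopSharedHierarchy:
    def test_shared_dominant_sequence_ranks_first(self):
        cohort = cohort_from_aa_sets(
            [{"CAAF", "CGGF"}, {"CAAF", "CDDF"}, {"CAAF", "CEEF"}]
        )
        table = top_shared_hierarchy(cohort, n=1, share_threshold_donors=2)
        assert table.entries[0].junction_aa == "CAAF"
        assert [e.junction_aa for e in table.entries if e.inclusion == "top10"] == [
            "CAAF"
        ]

    def test_exactly_two_donors_fails_strict_threshold(self):
        cohort = cohort_from_aa_sets([{"CAAF"}, {"CAAF"}, {"CGGF"}])
        table = top_shared_hierarchy(cohort, n=5, share_threshold_donors=2)
        assert all(e.junction_aa != "CAAF" or e.inclusion == "amplified"
                   for e in table.entries)

    def test_amplified_exception_included_and_flagged(self):
        # CDDF is outside every donor's top-1 but hugely expanded in d3
        cohort = cohort_from_aa_sets(
            [{"CAAF", "CGGF"}, {"CAAF", "CGGF"}, {"CAAF", "CGGF"}]
        )
        from gdrep.core import Chain, ClonotypeRecord, Repertoire

        extra = Repertoire.from_records(
            "d4",
            [
                ClonotypeRecord("TGTGCTGCTTTT", "CAAF", "TRGV9", "TRGJP", 60, Chain.gamma),
                ClonotypeRecord("TGTGATGATTTT", "CDDF", "TRGV9", "TRGJP", 40, Chain.gamma),
            ],
            Chain.gamma,
        )
        cohort = Cohort(cohort.repertoires + [extra], ["g"] * 4)
        table = top_shared_hierarchy(cohort, n=1, amplified_min_freq=0.10)
        flagged = {e.junction_aa: e.inclusion for e in table.entries}
        assert flagged.get("CDDF") == "amplified"

    def test_recovers_seeded_public_clonotypes(self):
        model = RecombinationModel(p_public=0.5, n_public_seeds=3)
        result = simulate_cohort(model, 5, 150, rng=19)
        table = top_shared_hierarchy(result.gamma, n=10)
        found = {e.junction_aa for e in table.entries}
        seeded = {s.junction_aa for s in result.truth.public_seeds}
        assert seeded <= found


class TestConvergenceReport:
    def test_printed_variant_group_has_one_germline_label(self, reference):
        """The four printed nucleotide variants of the public γ9 sequence
        form one group in which exactly one variant is a germline joint."""
        variants = {
            nt: n
            for nt, n in [
                VARIANTS_N["donor3_germline"],
                VARIANTS_N["donor28_T"],
                VARIANTS_N["donor35_G"],
                VARIANTS_N["donor231_A"],
            ]
        }
        from gdrep.core import Chain, ClonotypeRecord, Repertoire

        recs = [
            ClonotypeRecord(nt, GERMLINE_AA, "TRGV9", "TRGJP", 1, Chain.gamma)
            for nt in variants
        ]
        cohort = Cohort(
            [Repertoire.from_records("d1", recs, Chain.gamma)], ["g"]
        )
        decomps = {
            nt: decompose(nt, "TRGV9", "TRGJP", reference) for nt in variants
        }
        report = convergence_report(cohort, decomps)
        group = report.groups[GERMLINE_AA]
        assert len(group.variants) == 4
        assert group.is_convergent
        assert group.n_germline == 1

    def test_single_variant_group_is_not_convergent(self, reference):
        from gdrep.core import Chain, ClonotypeRecord, Repertoire

        nt = VARIANTS_N["donor3_germline"][0]
        rec = ClonotypeRecord(nt, GERMLINE_AA, "TRGV9", "TRGJP", 1, Chain.gamma)
        cohort = Cohort([Repertoire.from_records("d1", [rec], Chain.gamma)], ["g"])
        report = convergence_report(
            cohort, {nt: decompose(nt, "TRGV9", "TRGJP", reference)}
        )
        assert not report.groups[GERMLINE_AA].is_convergent


_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def _nt(aa):
    return "".join(_CODON[a] for a in aa)


def _cell(cid, donor, gamma_aa, delta_aa):
    return SingleCellRecord(
        cell_id=cid,
        donor_id=donor,
        gamma=ChainJunction(_nt(gamma_aa), gamma_aa, "TRGV9", "TRGJP"),
        delta=ChainJunction(_nt(delta_aa), delta_aa, "TRDV2", "TRDJ1"),
    )


class TestPseudoclonotypes:
    def test_two_delta_partners_flagged(self):
        cells = [
            _cell("c1", "donor3", GERMLINE_AA, "CACDSLLGDTPNFDKLIF"),
            _cell("c2", "donor3", GERMLINE_AA, "CACDTGGAQSWDTRQMFF"),
        ]
        report = pseudoclonotype_report(cells)
        entry = report.get("donor3", GERMLINE_AA)
        assert entry.partner_count == 2
        assert entry.is_pseudoclonotype

    def test_single_cell_not_flagged(self):
        report = pseudoclonotype_report(
            [_cell("c1", "d1", GERMLINE_AA, "CACDSLLGDTPNFDKLIF")]
        )
        assert not report.entries[0].is_pseudoclonotype

    def test_cells_missing_delta_are_tallied(self):
        cells = [
            _cell("c1", "d1", GERMLINE_AA, "CACDSLLGDTPNFDKLIF"),
            SingleCellRecord(
                "c2", "d1", gamma=ChainJunction("TGTTTT", GERMLINE_AA, "TRGV9", "TRGJP")
            ),
        ]
        report = pseudoclonotype_report(cells)
        assert report.n_cells_missing_delta == 1

    def test_dominant_clone_fraction_35_of_36(self):
        cells = [_cell(f"c{i}", "dX", "CAAF", "CACGSWWGTYTDKLIF") for i in range(35)]
        cells.append(_cell("c35", "dX", "CGGF", "CACDSLLGDTPNFDKLIF"))
        assert dominant_clone_fraction(cells) == pytest.approx(35 / 36)
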