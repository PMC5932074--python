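import numpy as np
import pytest

from gdrep.core import Chain, GermlineReference, GermlineSegment, reverse_complement
from gdrep.junctions import (
    DecomposeOptions,
    DecompositionError,
    NonCanonicalJunctionError,
    cdr3_core_length,
    classify_recombination,
    decompose,
    n_count_by_affix,
    position5,
    translate,
)
from gdrep.simulate import RecombinationModel, sample_rearrangement, simulate_cohort

from conftest import GERMLINE_AA, GERMLINE_JUNCTION, VARIANTS_N
from _oracle import brute_force_decompose


@pytest.mark.parametrize(
    "nt,aa",
    [
        (GERMLINE_JUNCTION, GERMLINE_AA),
        ("TGT", "C"),
        ("TGA", "*"),
    ],
)
def test_translation_standard_code(nt, aa):
    assert translate(nt) == aa


def test_translation_rejects_out_of_frame():
    from gdrep.core import FormatError

    with pytest.raises(FormatError):
        translate("TGTG")


@pytest.mark.parametrize(
    "aa,length",
    [
        ("CACGSWWGTYTDKLIF", 14),
        ("CACDTRFRPGRSARVVRLTAQLFF", 22),
        ("CALWEVQELGKKIKVF", 14),
        ("CACDSLLGDTPNFDKLIF", 16),
        ("CF", 0),
    ],
)
def test_core_length_counts_residues_between_anchors(aa, length):
    assert cdr3_core_length(aa) == length


def test_core_length_requires_anchors():
    with pytest.raises(NonCanonicalJunctionError):
        cdr3_core_length("AACGSWWGTYTDKLIA")


@pytest.mark.parametrize(
    "aa,residue,klass",
    [
        ("CACGSWWGTYTDKLIF", "W", "hydrophobic"),
        ("CACDSLLGDTPNFDKLIF", "L", "hydrophobic"),
        ("CACDTGGAQSWDTRQMFF", "G", "neutral"),
    ],
)
def test_position5_residue_and_class(aa, residue, klass):
    assert position5(aa) == (residue, klass)


def test_position5_undefined_for_short_cores():
    with pytest.raises(NonCanonicalJunctionError):
        position5("CACDF")


class TestAffixNCount:
    @pytest.mark.parametrize("name", sorted(VARIANTS_N))
    def test_printed_variants_reproduce_printed_n_counts(self, name):
        nt, expected = VARIANTS_N[name]
        assert n_count_by_affix(nt, GERMLINE_JUNCTION) == expected

    def test_identity_gives_zero(self):
        assert n_count_by_affix("ACGTACGT", "ACGTACGT") == 0

    def test_affix_overlap_is_capped(self):
        # prefix and suffix overlap inside a repeat-rich junction
        assert n_count_by_affix("AAAA", "AAAAAA") == 0


@pytest.fixture(scope="module")
def gamma_ref():
    """Toy γ reference whose germline V–J joint is the printed junction."""
    return GermlineReference(
        segments={
            "TRGV9": GermlineSegment(
                "TRGV9", "V", "GGA" + GERMLINE_JUNCTION[:18], anchor_offset=3
            ),
            "TRGJP": GermlineSegment(
                "TRGJP", "J", GERMLINE_JUNCTION[18:] + "GGT",
                anchor_offset=len(GERMLINE_JUNCTION) - 18 - 3,
            ),
        }
    )


class TestDecompose:
    def test_germline_joint_has_no_n_no_p_no_trims(self, gamma_ref):
        d = decompose(GERMLINE_JUNCTION, "TRGV9", "TRGJP", gamma_ref)
        assert (d.n_total, d.p_total, d.is_germline) == (0, 0, True)
        assert classify_recombination(d) == "germline"

    def test_inserted_non_germline_dinucleotide_with_j_trim(self, gamma_ref):
        v = gamma_ref["TRGV9"].junction_region
        j = gamma_ref["TRGJP"].junction_region
        junction = v + "AT" + j[2:]
        d = decompose(junction, "TRGV9", "TRGJP", gamma_ref)
        assert d.reconstruct() == junction
        assert (d.n_total, d.j_trim, d.v_trim) == (2, 2, 0)
        oracle = brute_force_decompose(junction, "TRGV9", "TRGJP", gamma_ref)
        assert oracle[:2] == (d.v_contrib, d.j_contrib)

    def test_palindromic_extension_classified_as_p_not_n(self, gamma_ref):
        v = gamma_ref["TRGV9"].junction_region
        j = gamma_ref["TRGJP"].junction_region
        p = reverse_complement(v[-1])  # 1-nt palindromic extension of V end
        # spacer chosen to neither extend the palindrome nor match J
        junction = v + p + "GG" + j[2:]
        d = decompose(junction, "TRGV9", "TRGJP", gamma_ref)
        assert d.reconstruct() == junction
        assert d.p_v == p
        assert d.p_total >= 1

    def test_incompatible_anchor_prefix_rejected(self, gamma_ref):
        with pytest.raises(DecompositionError):
            decompose("GGG" + GERMLINE_JUNCTION[3:], "TRGV9", "TRGJP", gamma_ref)

    def test_trimmed_variant_is_convergent_candidate(self, gamma_ref):
        nt = VARIANTS_N["donor28_T"][0]
        d = decompose(nt, "TRGV9", "TRGJP", gamma_ref)
        assert classify_recombination(d) == "convergent_candidate"


class TestDecomposeProperties:
    def test_reconstruction_identity_on_simulated_cohort(self, reference, sim_small):
        for clone in sim_small.truth.clones:
            for t in (clone.gamma, clone.delta):
                d = decompose(t.junction_nt, t.v_name, t.j_name, reference)
                assert d.reconstruct() == t.junction_nt

    def test_recovered_n_never_exceeds_true_nontemplated_total(
        self, reference, sim_small
    ):
        """Coverage maximisation guarantees recovered templated nt >= true
        templated nt, so recovered N can never exceed the true count of
        non-templated bases (N plus P)."""
        for clone in sim_small.truth.clones:
            for t in (clone.gamma, clone.delta):
                d = decompose(t.junction_nt, t.v_name, t.j_name, reference)
                true_nontemplated = t.n_total + len(t.p_v) + len(t.p_j) + sum(
                    len(p) for p in t.d_p5 + t.d_p3
                )
                assert d.n_total <= true_nontemplated

    def test_affix_count_matches_decompose_for_d_less_germline_variants(
        self, reference
    ):
        """For γ (D-less) junctions with a unique optimum, the affix count
        against the zero-trim germline junction equals decompose's N."""
        v = reference["TRGV9"].junction_region
        j = reference["TRGJP"].junction_region
        germ = v + j
        for insert, pos in [("A", 18), ("CAG", 18), ("T", 20)]:
            junction = germ[:pos] + insert + germ[pos + len(insert) :]
            d = decompose(junction, "TRGV9", "TRGJP", reference)
            assert d.n_total == n_count_by_affix(junction, germ)

    def test_p_strings_are_palindromic(self, reference, sim_small):
        for clone in sim_small.truth.clones:
            t = clone.gamma
            d = decompose(t.junction_nt, t.v_name, t.j_name, reference)
            v = reference[t.v_name].junction_region
            j = reference[t.j_name].junction_region
            if d.p_v:
                assert d.p_v == reverse_complement(v[-len(d.p_v) :])
            if d.p_j:
                assert d.p_j == reverse_complement(j[: len(d.p_j)])

    def test_matches_brute_force_oracle_on_random_single_d_junctions(
        self, reference
    ):
        """Spot-check against the independent oracle (the full ≥1000-case
        audit runs in the acceptance suite)."""
        model = RecombinationModel(d_count_probs={1: 1.0})
        rng = np.random.default_rng(23)
        opts = DecomposeOptions(max_d_segments=1)
        checked = 0
        while checked < 60:
            t = sample_rearrangement(model, rng, Chain.delta)
            if len(t.junction_nt) > 60:
                continue
            d = decompose(t.junction_nt, t.v_name, t.j_name, reference, opts)
            v, j, sel = brute_force_decompose(
                t.junction_nt, t.v_name, t.j_name, reference
            )
            assert (d.v_contrib, d.j_contrib) == (v, j)
            got = tuple(
                (p.d_name, p.d5_trim, p.d_contrib) for p in d.d_parts
            )
            want = tuple((s[0], s[2], s[3]) for s in sel)
            assert got == want, t.junction_nt
            checked += 1
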