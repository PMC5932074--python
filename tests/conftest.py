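import pytest

from gdrep.core import Chain, ClonotypeRecord, Cohort, Repertoire
from gdrep.simulate import RecombinationModel, default_reference, simulate_cohort

# Printed worked examples: the public germline CALWEVQELGKKIKVF junction and
# its convergent nucleotide variants, keyed by the donor they were seen in.
GERMLINE_JUNCTION = "TGTGCCTTGTGGGAGGTGCAAGAGTTGGGCAAAAAAATCAAGGTATTT"
GERMLINE_AA = "CALWEVQELGKKIKVF"
VARIANTS_N = {
    "donor3_germline": ("TGTGCCTTGTGGGAGGTGCAAGAGTTGGGCAAAAAAATCAAGGTATTT", 0),
    "donor28_T": ("TGTGCCTTGTGGGAGGTTCAAGAGTTGGGCAAAAAAATCAAGGTATTT", 1),
    "donor35_G": ("TGTGCCTTGTGGGAGGTGCAGGAGTTGGGCAAAAAAATCAAGGTATTT", 1),
    "donor231_A": ("TGTGCCTTGTGGGAGGTACAAGAGTTGGGCAAAAAAATCAAGGTATTT", 1),
    "donor261_CAG": ("TGTGCCTTGTGGGAGGTCAGAGAGTTGGGCAAAAAAATCAAGGTATTT", 3),
}


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def sim_small():
    """Small deterministic cohort shared across tests."""
    model = RecombinationModel()
    return simulate_cohort(model, n_donors=3, clones_per_donor=120, rng=11)


def make_repertoire(counts_by_nt, donor_id="d1", chain=Chain.gamma, v_call="TRGV9", j_call="TRGJP"):
    """Repertoire from {junction_nt: count}; aa derived by translation."""
    from gdrep.core import translate_nt

    records = [
        ClonotypeRecord(
            junction_nt=nt,
            junction_aa=translate_nt(nt),
            v_call=v_call,
            j_call=j_call,
            read_count=count,
            chain=chain,
        )
        for nt, count in counts_by_nt.items()
    ]
    return Repertoire.from_records(donor_id, records, chain)


@pytest.fixture
def uniform100():
    """100 distinct clonotypes with one read each."""
    bases = "ACGT"
    counts = {}
    for i in range(100):
        # two variable codons with a fixed middle C (never a stop codon)
        c3 = bases[i % 4] + "C" + bases[(i // 4) % 4]
        c4 = bases[(i // 16) % 4] + "C" + bases[(i // 64) % 4]
        counts["TGTGCC" + c3 + c4 + "GGGTTT"] = 1
    assert len(counts) == 100
    return make_repertoire(counts)


def cohort_from_aa_sets(aa_sets, chain=Chain.gamma):
    """Cohort where donor i holds the given aa sequences (count 1 each).

    Nucleotide junctions are synthesised per aa via a trivial reverse
    translation table, so translation consistency holds.
    """
    from gdrep.core import translate_nt

    codon = {
        "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
        "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
        "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
        "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    }
    reps = []
    for i, aa_set in enumerate(aa_sets):
        records = []
        for aa in sorted(aa_set):
            nt = "".join(codon[a] for a in aa)
            assert translate_nt(nt) == aa
            records.append(
                ClonotypeRecord(
                    junction_nt=nt, junction_aa=aa, v_call="TRGV9",
                    j_call="TRGJP", read_count=1, chain=chain,
                )
            )
        reps.append(Repertoire.from_records(f"d{i + 1}", records, chain))
    return Cohort(reps, ["g"] * len(reps))
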