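# gdrep — γδ T-cell receptor repertoire analysis

`gdrep` analyses clonotype repertoires of human γδ T cells, with a focus on
the Vγ9⁺Vδ2⁺ compartment whose γ-chain repertoire is dominated by *public*
CDR3 sequences — amino-acid sequences found in many unrelated donors. It is
aimed at immunologists working with AIRR-style clonotype tables (bulk TCR-seq)
and paired-chain single-cell TCR sequences.

The package answers three families of questions:

**Where does a junction come from?** Each CDR3 junction (the nucleotide
sequence spanning both anchor codons, the conserved V-region Cys and J-region
Phe) is decomposed into V-, D- and J-templated parts, palindromic P
nucleotides and non-templated N nucleotides. The decomposition maximises the
germline-templated contribution, then prefers fewer D segments, less
trimming, and the V-proximal placement:

    junction = V(trimmed) · P · N · D(trimmed) · P · N · P · J(trimmed)

A junction with zero trimming and zero N nucleotides is a *germline* joint —
one that recombination can produce deterministically, and therefore in any
donor. Distinct nucleotide junctions translating to the same amino-acid
sequence mark *convergent recombination*, the second route to publicity.

**How diverse and how shared is a repertoire?** Diversity is summarised by
D75 (the percentage of unique clonotypes needed to account for 75% of reads;
lower = more focused), the accumulated frequency of the top-N clonotypes,
CDR3 length spectratypes, segment usage, and squarified treemap layouts.
Sharing is quantified per donor (fraction of amino-acid clonotypes seen in
≥ k other donors), pairwise (|A∩B| / min(|A|,|B|), "relative publicity"), and
through a top-10 shared-clonotype hierarchy with amplified-expansion
exceptions. Single-cell tables yield *pseudoclonotype* reports: one public
γ-chain CDR3 paired with several distinct δ chains in one donor, the
signature of independent generation rather than clonal expansion.

**What would a repertoire with known ground truth look like?** A generative
V(D)J simulator draws segments, geometric exonuclease trims, palindromic P
additions and Poisson-length N insertions, rejects out-of-frame or
stop-containing joints, and emits per-donor AIRR tables together with the
exact truth for every clone — so every analysis stage can be validated
against known answers.

Shannon sequence logos (information `I_p = log2 20 + Σ f_a log2 f_a`, bar
heights `f_a·I_p`, no pseudocounts) with the standard four-class residue
colouring complete the per-position CDR3 analysis, including the
position-5 hydrophobicity check associated with phosphoantigen reactivity.

## Worked example

```python
from gdrep import (RecombinationModel, simulate_cohort, rank_clonotypes, d75,
                   accumulated_top_n, sharing_fraction, decompose,
                   default_reference, classify_recombination)

ref = default_reference()
germline = "TGTGCCTTGTGGGAGGTGCAAGAGTTGGGCAAAAAAATCAAGGTATTT"  # CALWEVQELGKKIKVF
variant  = "TGTGCCTTGTGGGAGGTTCAAGAGTTGGGCAAAAAAATCAAGGTATTT"  # same protein
for nt in (germline, variant):
    dec = decompose(nt, "TRGV9", "TRGJP", ref)
    print(nt[:24] + "...", "N =", dec.n_total, "P =", dec.p_total,
          "->", classify_recombination(dec))

model = RecombinationModel()
result = simulate_cohort(model, n_donors=3, clones_per_donor=500, rng=1)
for rep in result.gamma.repertoires:
    ranked = rank_clonotypes(rep)
    share = sharing_fraction(result.gamma, rep.donor_id)
    print(f"{rep.donor_id}: richness={ranked.richness:4d}  D75={d75(ranked):5.2f}%  "
          f"top10={accumulated_top_n(ranked, 10):5.2f}%  shared={share.fraction:.3f}")
```

prints

```
TGTGCCTTGTGGGAGGTGCAAGAG... N = 0 P = 0 -> germline
TGTGCCTTGTGGGAGGTTCAAGAG... N = 1 P = 0 -> convergent_candidate
sim01: richness= 303  D75= 7.59%  top10=40.17%  shared=0.445
sim02: richness= 313  D75= 6.39%  top10=53.28%  shared=0.416
sim03: richness= 294  D75= 7.14%  top10=49.38%  shared=0.450
```

The two junctions differ by one substitution: the first is a pure Vγ9–JγP
germline joint (no trimming, no added nucleotides), the second needs one N
nucleotide — two independent recombinations converging on one public protein
sequence. In the simulated cohort, each donor needs only ~7% of its
clonotypes to cover 75% of reads, the ten most prevalent clonotypes hold
40–53% of the repertoire, and ~44% of each donor's γ amino-acid clonotypes
recur in another donor.

The same analyses are available from the shell:

```sh
gdrep simulate --donors 3 --clones 500 --cells 100 --seed 1 --out cohort/
gdrep run --input cohort/ --out cohort/analysis/
gdrep junction --input cohort/sim01_gamma.tsv --germline cohort/germline.fasta \
               --chain gamma --out junctions.tsv
```

`gdrep run` writes one TSV per stage (junctions, stats, treemap, sharing,
overlap, hierarchy, convergence, logo) plus a manifest recording the config,
seed and per-stage record counts.

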