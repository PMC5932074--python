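# Methods

## Scope and data model

`gdrep` operates on pre-called clonotypes: per-donor tables in the AIRR
Rearrangement TSV dialect (`junction`, `junction_aa`, `v_call`, `d_call`,
`j_call`, `duplicate_count`; other dialects via a column map), paired-chain
single-cell tables (one row per chain, shared `cell_id`), and a germline
segment FASTA whose headers carry the anchor annotation
(`>NAME|V|anchor=N`, `>NAME|D|order=K`). Raw-read processing, UMI handling
and sequencing-error correction are out of scope.

Conventions, stated once: all coordinates are 0-based half-open on the top
strand; a *junction* includes both anchor codons (conserved V-region Cys,
J-region Phe), so a 48-nt junction is a 16-aa sequence whose *core length*
(used for spectratypes and the position-5 analysis) is 16 − 2 = 14.
Position 5 is 1-based within the core. Clonotype identity is
(`junction`, `v_call`, `j_call`); amino-acid-level analyses re-aggregate on
`junction_aa`. Records whose junction contains ambiguity codes, does not
translate to the stated protein, or lacks the C…F anchors are excluded
from analysis but always counted in an ingest report. Repertoire
frequencies are read-weighted and sum to 1 within 1e-9.

The residue classes used for logos and position-5 calls are acidic `DE`,
basic `RKH`, hydrophobic `ACFILMPVW` and neutral `NQSGTY`. Glutamine is
assigned to the neutral class so the four classes partition the 20-letter
alphabet exactly (2 + 3 + 9 + 6).

## Junction decomposition

The decomposer splits a junction into V-templated, P, N, D-templated and
J-templated parts. The V contribution is a prefix of the V segment from its
anchor codon (the first three junction bases must match the anchor;
`max_anchor_mismatch`, default 0); the J contribution is a suffix of the J
segment through its anchor codon; D segments (δ chains only) contribute
0–2 non-overlapping blocks in genomic order, each at least `min_d_match`
(default 3) contiguous nucleotides — shorter matches are statistically
indistinguishable from chance.

Among all consistent assignments the decomposer selects, in order:
(1) maximal total templated nucleotides; (2) fewest D segments;
(3) least total trimming; (4) the V-proximal D placement; remaining ties
prefer the placement with less D 5′ trimming, then less V trimming, then
the lexicographically smallest segment names. This ordering is a package
convention chosen for determinism — junction-analysis tools do not publish
tie-breaking at this granularity — and is enforced by an independent
brute-force oracle test over the same objective.

After segment assignment, unassigned bases flanking an *untrimmed* segment
end are classified as P if they extend the palindrome (each P base is the
complement of the corresponding terminal base, read outward), greedily up
to `max_p` (default 3) per end, left end of a gap first. Everything still
unassigned is N. A joint is *germline* iff it has zero trims and zero N.
The concatenation of the parts always reproduces the input junction; this
reconstruction identity is tested on every simulated junction.

Because P bases are non-templated, a maximal-coverage parse may label true
P bases as N (or absorb chance palindromes into P); recovered N is
therefore guaranteed to be bounded by the true non-templated total (N + P),
not by true N alone. P totals are consequently reported but not treated as
recoverable ground truth; only the palindrome contract is.

The affix counter `n_count_by_affix(junction, germline_junction)` provides
the complementary route used for γ chains when a designated zero-N
reference junction is known: `len − LCP − LCS` (capped at zero), with
LCP/LCS the longest common prefix/suffix against the reference. For D-less
junctions with a unique optimum it agrees with the full decomposer.

## Diversity, sharing and layout statistics

* **D75**: clonotypes are ranked by descending count (ties by sequence);
  `k` is the first rank whose cumulative frequency reaches the threshold
  (default 0.75, inclusive ≥); D75 = 100·k / richness. Computed at a
  declared aggregation level, nucleotide by default; both levels are
  supported and labelled because clonotype tables resolve nucleotide
  variants.
* **Accumulated top-N**: 100 × cumulative frequency at rank min(N, richness).
* **Spectratype**: distribution of core lengths over canonical records,
  read-weighted by default, unique-clonotype weighting on request.
* **Segment usage**: read-weighted fractions within a V or J family;
  multi-valued calls (e.g. `TRDD1,TRDD3`) are excluded from usage.
* **Sharing**: fraction of a donor's amino-acid clonotypes present in at
  least `min_other_donors` (default 1) other repertoires; unique-clonotype
  weighting by default, read weighting on request. Pairwise overlap uses
  |A∩B| / min(|A|,|B|) on unique amino-acid sets (Jaccard available); the
  min-normalisation is recorded in the output since "relative publicity"
  admits several normalisations.
* **Top-shared hierarchy**: the union of every donor's top-N (default 10)
  amino-acid clonotypes, kept when present in more than
  `share_threshold_donors` (default 2) donors, ordered by mean frequency
  over possessing donors; sequences outside this set whose frequency
  exceeds `amplified_min_freq` (default 0.10) in some donor are appended as
  flagged amplified exceptions. The 0.10 floor captures expansions in the
  tens of percent while ignoring ordinary clones; it is configurable.
* **Treemap**: squarified layout; the canvas is first partitioned by V
  segment (area ∝ summed read share), clonotype rectangles nest inside.
  Area proportionality holds to 1e-6 relative and rectangles tile without
  overlap; only coordinates are produced, rendering is out of scope.

## Sequence logos

Strata are selected as the top-k (default 10) most abundant amino-acid
clonotypes with a given J segment and core-length range; the length range
is a required parameter rather than a default. Frequencies count each
selected clonotype once, without pseudocounts. Information content is
`I_p = log2 20 + Σ_a f_a log2 f_a` and bar heights `f_a·I_p`, so a
monomorphic column reaches log2 20 ≈ 4.32 bits and a uniform column 0.
Mixed lengths are handled per exact length by default (no alignment); an
`anchor_split` policy (left-align the first ⌈L/2⌉ columns, right-align the
rest) is available for cross-length display and labelled as such. A
progressive multiple alignment of mixed-length strata is deliberately not
re-implemented; per-length logos preserve the left-anchored position-5
analysis.

## The cohort simulator

`RecombinationModel` holds the generative parameters; all randomness flows
through one seeded NumPy generator, and identical model + seed give
byte-identical cohort tables.

Per clone and chain: segments are drawn from per-family probabilities;
each segment end is trimmed by a geometric(`p_trim`, default 0.35) draw,
truncated so every retained segment keeps at least `min_keep` = 3 nt (the
anchor codons, and a D core no shorter than the decomposer's detection
floor — fully eroded D segments would otherwise masquerade as N);
untrimmed ends gain a palindromic P extension with probability `p_p` = 0.3
(geometric length, capped at `max_p` = 3); each inter-segment gap receives
an N string of Poisson(`λ_n` = 2) length with a mildly G/C-biased
composition {A 0.2, C 0.3, G 0.3, T 0.2} mimicking terminal transferase.
Out-of-frame or stop-containing joints, and joints without C…F anchors,
are rejected and redrawn (bounded at 1000 retries; exhaustion raises an
error naming the parameter regime). δ chains use 1–2 D segments
(probabilities 0.85/0.15, matching the observation that junctions with two
D contributions occur but are the minority). No published quantitative
trim/N-length statistics exist for γδ chains, so these defaults are
documented placeholders, not literature values.

Publicity enters through cohort-wide seed clonotypes: a list of
`n_public_seeds` = 5 distinct γ joints is drawn once per cohort (pure
germline joints first — the biologically grounded channel — topping up
with ordinary draws if the germline combination space is exhausted); each
clone's γ chain is replaced by a uniformly chosen seed with probability
`p_public` = 0.2. δ chains are always drawn independently, so public γ
sequences pair with diverse δ partners and pseudoclonotypes arise
naturally. Clone sizes are Zipf(α = 1.5), truncated at the clone count; α
is a free, documented knob since no clone-size law is published for this
compartment.

The default germline reference is **synthetic** (3 Vγ, 3 Jγ, 1 Vδ, 3 Dδ,
4 Jδ, with anchors; every V/J junction region stop-free and a codon
multiple). Its Vγ9–JγP germline joint reproduces the canonical public
CALWEVQELGKKIKVF junction, so the publicity mechanism of the real locus is
represented. Real IMGT segments can be substituted through the same FASTA
interface. What the simulator does *not* model: thymic selection, allele
variation, somatic hypermutation, sequencing error, and realistic
junction-length or publicity spectra — passing tests demonstrate the
correctness of the analysis machinery on data with known structure, not
quantitative agreement with any real repertoire.

Single cells are drawn without replacement from the pool of cells implied
by clone sizes, so drawing a 35:1 pair exhaustively yields a 35/36
dominant fraction exactly.

## Validation experiments and their scales

The test battery (under `tests/`, including `test_acceptance.py`) uses
problem sizes chosen to make sampling error negligible at the stated
tolerances while keeping the whole suite around two minutes:

* printed worked examples (core lengths, N counts, position-5 calls,
  35/36 dominance) verified exactly;
* decomposer vs brute-force oracle on 1000 random ≤ 60-nt single-D
  junctions;
* reconstruction identity on 5000 simulated junctions, truth round-trip
  exact;
* parameter recovery on 5000 clones: segment-choice frequencies within
  ±0.02 (binomial SE ≈ 0.006); N-length recovery on 2000 γ junctions from
  a {G,T}-alphabet germline with {A,C} insertions and P disabled — the
  disjoint alphabets make N recovery exact, and the recovered mean falls
  within 15% of λ_n;
* publicity dose-response over p_public ∈ {0, 0.2, 0.5} in a 7-donor ×
  1000-clone cohort with fixed seeds, measured with **read-weighted**
  sharing. Unique-clonotype sharing is the wrong instrument for this
  check: seed draws displace private draws, the small synthetic germline
  space gives a high baseline of chance (convergent) sharing, and once
  every seed is present in a donor further copies cannot move a set-based
  metric — measured unique-weighted means are flat-to-decreasing in
  p_public, while read-weighted means increase strictly with wide margins
  (the seeding dose acts on repertoire mass, which read weighting
  measures).

## Numerical and degenerate-input choices

Cumulative-threshold comparisons use ≥ with a 1e-12 slack; frequency and
height sums are asserted to 1e-9. Ranking ties break lexicographically for
reproducibility. Empty repertoires, empty strata, all-non-canonical
spectratypes and non-positive canvases raise typed signals rather than
returning silent empties. The pipeline writes a manifest on both success
and failure; a failed stage leaves a `FAILED` marker naming the stage and
offending input, and partial outputs are retained.
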