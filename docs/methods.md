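# Methods

## Scope and model

`igmrep` annotates heavy-chain nucleotide reads (one per cell, presented in
V→J orientation) against a germline V/D/J reference, decomposes each
junction, and summarizes repertoires the way B-1 subset comparisons are
done: junctional N-addition categories and means, gene-family usage, and
replicate-CDR-H3 clonality, with χ², Mann–Whitney and Fisher/BH tests
between repertoires. Light chains, isotype switching, lineage trees and
novel-allele inference are out of scope.

## Germline references

A reference is a plain ungapped FASTA plus an anchors TSV (`name`,
`anchor_0based`) giving the conserved Cys codon offset for each V and the
conserved Trp/Phe codon (of the W/F-G-x-G motif) for each J. IMGT gap dots
are stripped on load with anchors recomputed. Family labels derive from the
allele name: V and J keep the token up to the first hyphen or asterisk
(`IGHV12-3*01 → VH12`, `IGHJ1*03 → JH1`); D keeps the whole gene token up
to the asterisk (`IGHD1-1*01 → DH1-1`) because D genes within a numeric
family are tabulated separately on usage axes.

The bundled reference (10 V, 4 D, 4 J) is synthetic: segment bodies are
random nucleotides; only the anchor regions and the junction-facing termini
are designed. All D lengths are multiples of three and every V tail and J
head is codon-aligned and stop-free, so every zero-trim/zero-N join is
productive — including the fully germline-encoded VH12+DH2+JH1 join, whose
CDR-H3 (`AGDYDGYWYFDV`) reproduces the canonical dominant peritoneal B-1a
clonotype. Real (e.g. IMGT) references can be supplied as ordinary inputs;
nothing needs to be downloaded to use or test the package.

## Annotation

**Segment assignment.** Every V is aligned locally with affine gaps
(defaults: match +2, mismatch −2, gap open −5, gap extend −1; a gap of
length L costs open + (L−1)·extend). An ungapped seed-and-extend fast path
(11-mer seeds, best contiguous-scoring diagonal run) resolves near-germline
reads; when any segment reaches ungapped identity ≥ 0.9, segments without
a seeded hit are pruned (they cannot outscore a near-perfect match), and
otherwise a full Smith–Waterman fallback (biotite) runs. Ties across
segments break by score, then aligned length, then earlier query start,
then name. The V call requires identity ≥ 0.85 (same for J); the J is
aligned against the read suffix downstream of the accepted V. If no V is
found forward, a single reverse-complement rescue pass is attempted. The D
is called by the longest contiguous exact match (≥ 5 nt by default)
between any D segment and the insert between the templated V end and J
start; ties go to the lexicographically smaller name, then the leftmost
position. Failures are carried as flagged rows (`no_v_call`, `no_j_call`,
`invalid_sequence`, `anchor_unaligned`, `v_j_overlap`), never dropped.

**Junction boundaries (maximal-templated convention).** Templated V and J
contributions inside the junction window are delimited by exact
base-by-base walks outward from the anchors: forward from the V Cys codon
while the read matches V germline, backward from the end of the J Trp/Phe
codon while it matches J germline (capped so the walks cannot cross; V
greedy first). A junction base matching the adjacent germline terminus is
therefore always counted as templated, never as an N-addition — the
conservative choice for any claim about N-addition burden. The remaining
insert is split by the exact D placement into `n1` (V–D N-additions) and
`n2` (D–J). With no D call the whole insert is `n1` and `np2` is
undefined; such reads are excluded from two-junction statistics and
counted separately. The decomposition concatenation reproduces the read's
junction window exactly (asserted for every annotated read in the tests).

Because boundaries come from exact walks anchored at the conserved codons,
a point mutation adjacent to the junction stops the walk and its germline
bases are counted as N. No somatic-hypermutation correction is attempted;
natural IgM is near-germline and the simulator's default mutation rate is
zero. This is the main known limitation for data with appreciable SHM.

**P-nucleotides.** When enabled (`call_p_nucleotides`, default off), up to
`max_p_len` (default 2, ≤ 3) bases are classified as P at an end only if
that segment end is untrimmed (the walk reached the germline terminus) and
the bases are the reverse complement of the terminus. By default
palindromic bases count as N-additions, matching how N burden is usually
reported; the option preserves the mechanistic distinction.

**CDR-H3 and productivity.** The junction runs from the V Cys codon
through the J Trp/Phe codon inclusive and is translated in the V reading
frame; `cdr3_aa` strips the two anchor residues (printed clonotypes begin
after the Cys). Productive means junction length divisible by three and
stop-free. Out-of-frame junctions still report a translation in the V
frame.

## Repertoire statistics

Eligibility for all junction statistics defaults to *productive AND
D-called*; both filters are exposed as switches (`include_unproductive`,
`include_no_d`) because published percentages rarely state their filter.
Category frequencies are percentages of eligible sequences and sum to
100%. Usage tables are fractions over eligible sequences (D usage over
D-called only), zero-filled from the germline vocabulary. The replicate
fraction is the share of eligible sequences whose exact `cdr3_aa` occurs
at least twice within the same repertoire (equivalently 1 − singletons/n);
cross-repertoire sharing is not folded in. `cdr3_hamming` compares
equal-length clonotypes only; no alignment is attempted.

## Between-repertoire tests

* 2×K Pearson χ² without continuity correction on category counts;
  categories empty in both groups are dropped with df reduced.
* Mann–Whitney U, two-sided: exact enumeration when n₁+n₂ ≤ 16 with no
  ties, else the tie-corrected normal approximation with continuity
  correction. (Figure legends sometimes call this a "Mann-Whitney t-test";
  it is the standard U test.)
* Per-family usage: 2×2 Fisher exact (uses vs non-uses per group), BH
  step-up adjustment across the families of one segment type; raw and
  adjusted p are both reported since the choice of per-family test and
  adjustment is an explicit package decision, not something the source
  analyses specify.

## Simulator

The generative model draws V, D, J by categorical usage; trims each
junction-facing end by a capped geometric (`trim_p` = 0.45, caps 4/3/3/4
for V 3', D 5', D 3', J 5'); optionally adds P-nucleotides at untrimmed
ends (`p_prob`, 0 in all presets); draws N lengths per junction from an
explicit distribution with uniform base composition (TdT's G-bias is not
modelled); assembles V'+P+N1+D'+N2+P+J'; and applies per-base substitution
noise (default 0). Clone sizes are geometric (`clone_p`); all cells of a
clone share one recombination event. A single integer seed drives one RNG
stream in a fixed draw order, so outputs are platform-stable; a repertoire
is reproducible byte-for-byte from its seed.

Presets model sorted surface-IgM⁺ cells, which carry productive
rearrangements, by resampling junction draws until the junction is
in-frame and stop-free (`require_inframe`); the plain model leaves frame
unconstrained. Preset N-length distributions and usage skews encode the
characteristic contrasts between the four compartment × subset conditions:
near-zero N and >80% VH12/DH2/JH1 usage for peritoneal B-1a, progressively
heavier N burden and broader usage for peritoneal B-1b, splenic B-1a and
splenic B-1b, the last with mean ≈ 3 N per junction. Clone-size parameters
(0.42/0.63/0.68/0.79) were calibrated once so the realized replicate
fraction at n = 500 — which includes germline-convergent CDR-H3 collisions
across clones, a real phenomenon — lands near 92/65/56/39% across the four
conditions. Exact percentages vary between animals and datasets, so
validation asserts the *ordering* of the four conditions, not point
values; the default problem size everywhere is 500 cells per condition.

What the simulator does not emulate: somatic hypermutation beyond uniform
substitution noise, selection and affinity maturation, TdT base bias,
sequencing error profiles, primer artefacts, and allele-level germline
variation. Passing recovery tests therefore demonstrates correctness of
the annotation logic under clean single-cell Sanger-like reads, not
robustness to heavily mutated or noisy data.

**Ground-truth recovery.** Every simulated read stores its generative
record; `recovery_report` measures per-field agreement and computes, from
truth alone, the *accidental-extension set*: reads where a generated N
base happens to continue a trimmed germline terminus (or a generated P is
reported as N, or the true D core is shorter than the call threshold or
ambiguous in the insert), so that the maximal-templated convention must
report fewer N than were generated. Off this set, N counts are recovered
exactly; on or off it, annotated np never exceeds generated np. Both
properties are asserted in the test suite.

## Numerical and degenerate-input conventions

Percentages are reported to one decimal in tidy CSV outputs, full
precision in JSON. Probability vectors must sum to 1 within 1e-9. Empty
repertoires summarize to zero counts with absent means rather than
raising. Usage tables on empty input are all-zero. Trim draws that would
exhaust a segment are redrawn (bounded; error after 200 failures). The
χ² requires a positive total per group and at least two non-empty
categories.
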