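# Methods

## The design problem

A combinatorial protein library is encoded by a degenerate DNA template: an
ordered list of degenerate codons, each written in IUPAC ambiguity letters and
synthesized as an equimolar blend of its concrete expansions. Under the
standard genetic code, an equimolar degenerate codon translates to a known
expected amino-acid distribution, and — because positions are synthesized
independently — the library's mean composition is the position-average of the
per-codon distributions.

Given a residue alphabet `A` and a target composition `t` (a probability
vector over the 20 canonical letters, zero outside `A`), the design task is to
pick `n` codons from the *stop-free pool* of `A` — the subset of the 3375
degenerate codons whose expansions code only residues of `A` and never a stop
codon — minimizing

    RMSE(p, t) = sqrt( (1/20) Σ_a (p_a − t_a)² )

where `p` is the template's expected profile. Evaluating the RMSE over all 20
letters (not just the alphabet) penalizes any off-alphabet leakage; drawing
moves from the stop-free pool makes the expected stop mass exactly zero by
construction.

Two bundled design conditions mirror the two libraries this package is built
around: the full 20-letter alphabet with UniProtKB/Swiss-Prot average
frequencies as the target ("20F"), and the 10-letter early/prebiotic alphabet
ASDGLIPTEV with the same frequencies restricted and renormalized ("10E").
Both use 84 variable codons inside a 105-residue construct.

## Optimizer

Simulated annealing over the codon multiset:

- state: `n` pool indices; the expected profile is maintained as a running
  sum, so a move costs O(20);
- move: replace the codon at a uniformly random position by a uniformly
  random pool codon;
- schedule: geometric cooling, `T0 = 0.1`, `α = 0.995`, 20,000 iterations by
  default;
- start: the single pool codon with the lowest uniform-template RMSE, used at
  every position. The best state ever visited is returned, so the result is
  never worse than this baseline;
- determinism: one `numpy` generator seeded by the caller; identical spec +
  seed ⇒ identical template.

The problem is soft: with 84 positions and hundreds to thousands of pool
codons, typical achieved RMSE is below 0.001 for both bundled targets —
far below the ≈0.06 deviation measured when such libraries are actually
synthesized and sequenced, so design residual is never the binding
constraint. On instances small enough to enumerate (≤4 positions, small
alphabets), the annealer reaches the brute-force optimum to 1e-9; this is
pinned by tests.

## Construct layout

The default construct is FLAG tag (DYKDDDDK) — 42 variable residues —
thrombin cassette (ALVPRGS) — 42 variable residues — His6, i.e. 21 fixed + 84
variable = 105 residues. The cassette contains one LVPRGS motif; thrombin
cuts between R and G, and `locate_cleavage` returns the index of the G of the
first occurrence. Fixed residues are reverse-translated with the most common
E. coli K-12 codon per residue; all downstream analyses are protein-level, so
this table only needs to be stop-free and deterministic.

## Synthetic libraries and the error model

`sample_sequences` draws each degenerate position independently and uniformly
over its base set (the equimolar-mix assumption), fixed positions verbatim.
`apply_errors` then applies:

1. substitutions — each base flips with probability ε, uniformly to one of
   the other three bases. Default ε = 0.0015/nt, a typical order of magnitude
   for long-oligo synthesis plus sequencing substitutions;
2. duplication — in read order, a read is replaced with probability `d`
   (default 0.02) by a copy of a uniformly chosen earlier read, the simplest
   mechanism consistent with PCR/optical duplicates. Each duplication event
   makes ~2 reads non-unique, so `d = 0.02` leaves ≈96% of reads unique.

Indels are deliberately not modeled: substitutions alone reproduce the
appearance of in-frame stop codons in a stop-free design while keeping reads
frame-aligned, which is what the QC statistics assume. The stop-containing
read fraction implied by the model is available in closed form
(`expected_stop_fraction`: per expansion codon, a mutation to stop codon `s`
at Hamming distance `d` has probability `(ε/3)^d (1−ε)^{3−d}`; positions are
independent), and `calibrate_sub_rate` inverts it by bisection — e.g. a ~12%
stop incidence over 84 codons corresponds to ε ≈ 0.019/nt.

What the generator does *not* emulate: positional error profiles, indels and
frameshifts, chimeric reads, paired-end merging artifacts, and base-quality
structure. Tests passing on these libraries therefore validate the statistics
and the model arithmetic, not the behaviour of any particular sequencing
chemistry.

## QC statistics

- per-position composition: column frequencies over equal-length translated
  variable regions (no alignment; ragged input is an error);
- RMSE to target: the design metric applied to the position-averaged
  composition. Stop-containing sequences are excluded from composition
  statistics — they truncate during translation — and accounted separately;
- uniqueness: fraction of sequences whose exact string occurs exactly once;
  measured on DNA by default (the stricter level), protein optionally;
- stop fraction: share of sequences with ≥1 stop symbol;
- misincorporation: off-alphabet residues over all residues of stop-free
  sequences, plus per-letter relative deviation |obs − designed| / designed;
- information content: `R_i = log2(20) − H_i` bits per position, stop mass
  excluded and the column renormalized, matching sequence-logo conventions.

## Charge, pI, hydropathy, aggregation, consensus structure

Net charge at pH x sums Henderson–Hasselbalch fractional charges of side
chains and termini: basic groups contribute `N/(1+10^(x−pKa))`, acidic groups
`−N/(1+10^(pKa−x))`. The curve is strictly decreasing in pH, so the
isoelectric point is the unique zero; it is found by bisection on [0, 14] to
1e-3 pH (41 halvings), vectorized across sequences. The default pKa constants
are the EMBOSS set (D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5, K 10.8, R 12.5,
N-term 8.6, C-term 3.6). pKa conventions differ between tools by a few tenths
of a pH unit and propagate directly into pI, which is why the mean-pI check
carries a ±0.3 tolerance. Under these constants the mean pI of 10,000 sampled
10E constructs computes to ≈3.92.

GRAVY is the mean Kyte–Doolittle index (table taken from Biopython). The
aggregation score is the fraction of residues flagged aggregation-prone by a
per-residue classifier; the *score* (flags/length) is the fixed part, the
classifier is pluggable. The bundled default flags residue i when its
centered width-7 window (truncated at the ends) has mean hydropathy ≥ 1.0 and
contains no D/E/K/R — a transparent heuristic standing in for trained
aggregation predictors, which are outside this package's scope. Consensus
secondary structure is the per-position plurality vote over k ≥ 1 external
3-state (H/E/C) predictions, ties resolved to C; helix/sheet content are
fractions of the consensus string. Solubility categorization applies the
published scaled-solubility cutoff: soluble iff score > 0.45 (strict).

## Mass envelope

Construct mass is the sum of independent per-position residue masses plus the
fixed-region mass and one water, so

    mean = m_fixed + Σ_i E[m_i] + m_H2O,   var = Σ_i Var[m_i]

in closed form. The full envelope is the convolution of per-position mass
distributions on a uniform grid (default 1 Da, matching linear-mode MALDI
resolution for ~11 kDa products; average masses by default, monoisotopic by
flag). Discretization uses the lever rule — each point mass is split between
the two adjacent bins in proportion to its fractional offset — which
preserves the mean exactly and inflates variance by at most `f(1−f) ≤ 1/4`
bin² per position, keeping grid moments within half a bin of the closed form
even at 84 positions. Stop-coding expansions are excluded (truncation
products are not full-length molecules); the final envelope is truncated at
mean ± 6 sd and renormalized. Charge state +1, no adducts, no isotopic fine
structure.

## Fraction accounting

Densitometry rows carry four intensities: `total`, `soluble`,
`total_uncleaved`, `soluble_uncleaved`. The partition of total expressed
material is

    insoluble %          = 100 − 100·soluble/total
    soluble_resistant %  = 100·soluble_uncleaved/total
    soluble_degradable % = the remainder of the soluble share

using the *undigested* band for resistance (cleavage fragments transfer
poorly and may be re-cleaved). The three components sum to 100 exactly and
are invariant to rescaling a row (arbitrary units). Rows with
soluble > total or soluble_uncleaved > soluble are flagged, never clipped.
Replicate summaries report mean ± sample sd per fraction; the default
averages per-replicate percentages (mean of ratios), with ratio-of-means
available because published bar values can be computed either way. The same
arithmetic applies unchanged to post-heat-shock tables.

## Problem sizes and numerical choices

Default sizes: 20,000 annealing iterations per design; 10,000 constructs for
mean-pI estimation; 50,000 reads for composition-recovery checks; 100,000
Monte-Carlo draws for moment cross-checks. Distribution invariants are held
to 1e-12 (normalization), bisection to 1e-3 pH, convolution moment drift to
half a bin. Ties: consensus votes fall to C; the first LVPRGS motif wins;
annealing returns the best-ever state, so equal-objective moves cannot
degrade the result.

## Known limitations

- Equimolar base mixes only; spiked or trimer-phosphoramidite synthesis is
  out of scope.
- Substitution-only error model; real synthesis error spectra include indels
  that this package does not represent.
- The default aggregation flagger is a labelled heuristic stand-in, not a
  trained predictor; use the pluggable interface for production scoring.
- Secondary-structure prediction itself is external; only the consensus vote
  is implemented.
- Mass envelopes ignore ionization bias, adducts and truncation products, so
  they are comparison targets for spectra, not simulated spectra.
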