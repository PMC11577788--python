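# Methods

## Barcode model

The degenerate repair oligo is an 80-nt single-stranded DNA written
antisense to the *cat* coding strand. Its six N positions are arranged
`N xxxxx NNNN xx N`: one wobble base, the three bases replacing the
engineered stop codon plus a second wobble, and a third wobble (the
wobbles sit in codons A138, S140 and S142 of Cat). `parse_template`
enforces exactly this arrangement and derives 12-nt constant flank anchors
immediately outside the degenerate block; both flanks must be unique
within the template.

Functionality is a pure sense/stop decision: the replacement codon is the
reverse complement of barcode positions 2–4 (the published restored barcodes
all yield sense codons only under this strand convention), and a barcode
is functional iff that codon is not TAA/TAG/TGA under the standard genetic
code (via Biopython's table). Wobble positions impose no constraint —
matching the 4³ × 61 = 3,904 arithmetic — although non-synonymous wobble
changes are biologically conceivable; restricting them was considered and
rejected because the enumeration is meant to count *selectable* tags, and
selection acts on the replacement codon. An optional sense-codon whitelist
narrows the admissible replacement codons (e.g. 24 codons → 4³ × 24 =
1,536 tags) for scenarios where only some amino acids restore enzyme
function.

Barcode extraction locates both flanks by exact match (a mismatch
tolerance is available but defaults to 0 — the amplicon is short and reads
are expected-error filtered first), requires the template's exact spacing,
searches both strands, and returns "unassigned" unless exactly one
placement exists. Diversity statistics report per-position base counts,
information content 2 − *H* bits (log base 2, no small-sample correction
by default; Miller–Madow correction behind a flag), the amino-acid
spectrum of replacement codons, and the occupancy expectation
*N*(1 − (1 − 1/*N*)^*k*) with a seeded Monte-Carlo companion.

## Knockout oligo and MAMA design

Knockout oligos carry exactly one contiguous block of five mismatching
bases — the block size that fully evades mismatch repair in *L. reuteri* —
flanked by 38-nt homology arms (~81-nt oligos, matching the published
designs; configurable). The search enumerates every 5-nt window touching a
target codon and all 3⁵ all-mismatch replacements, scores by the number of
requested residues converted to stops, and breaks ties toward the 5′-most
placement on the oligo, then toward fewer collateral amino-acid changes.
The annotation (`K150*V151Q`-style strings) lists *every* residue changed
by the block; `annotate_oligo_mutations` recovers it from an oligo/wild-
type alignment given a frame anchor, and rejects scattered or >5-nt
mismatch patterns. Lagging-strand identity is caller-supplied (replichore
layout is genome-specific); when the gene is on the lagging strand the
oligo reads in gene orientation, otherwise it is reverse-complemented.

MAMA PCR screening uses outer primers whose 5′ ends sit exactly
`outer_offset` (default 500) bp up- and downstream of the edited site and
a forward allele-specific primer (default 26 nt) whose 3′ terminus is the
last base of the mismatch block, so it extends only on the recombinant
allele. Predicted bands are primer-5′-to-primer-5′ amplicon spans: the
wild-type diagnostic band is 2 × offset + 1 (~1 kb at defaults) and the
recombinant band ~offset + primer length (~0.5 kb). No melting-temperature
optimisation or deliberate extra destabilising mismatch is applied — the
design is coordinate arithmetic only, and primer lengths are configurable.

## Demultiplexing pipeline

Pair merging is a self-contained overlap-consensus merger rather than a
wrapper around an external tool: mate 2 is reverse-complemented, all
overlaps ≥ 10 nt are scored by matches − mismatches, and the best-scoring
overlap with identity ≥ 0.9 wins (ties to the longer overlap). Consensus
takes the higher-quality base; agreeing positions get min(q₁+q₂, 41),
disagreeing positions max − min floored at Q2. These parameters are
explicit choices; they are deterministic and adequate for a short, fully
overlapping amplicon. Quality encoding is fixed to Phred+33 (Phred+64 is
rejected, not auto-detected).

Merged reads are filtered on expected errors E = Σ 10^(−Q/10) with
Emax = 1 (filtering after merging, in that order). Note the consensus
rule makes the filter sensitive to mate disagreements: a disagreeing
position floors near Q2 (error probability 0.63), so reads with two or
more disagreements are typically discarded — which is the desired
behaviour for a consensus-based error filter.

Assignment is extraction plus exact whitelist lookup: structurally valid
but unlisted barcodes count as "offlist", extraction failures as
"unassigned"; both are excluded from relative percentages, which are
computed over whitelist reads only. Conservation (whitelist + offlist +
unassigned = filtered) is enforced by construction and tested. Sample
indexing is assumed done upstream; 6-N diversity spacers at read starts
are tolerated by the flank search rather than trimmed.

## Competition and persistence statistics

Δ%(T_F − T_0) is the per-strain difference of relative percentages between
a timepoint pair; deltas sum to zero within a pair and are invariant under
read-depth rescaling. Replicates are summarised as mean ± sd/√n. The
washed-vs-unwashed comparison uses a two-tailed unpaired t-test, Welch by
default (the variance assumption is not otherwise constrained; Student's
is available), with the degenerate equal-constant case defined as t = 0,
p = 1. P-values are unadjusted by design, with an optional
Benjamini–Hochberg column.

Because percentages are compositional, a deficit in one strain necessarily
spills small positive shifts onto the others (one of nine strains losing
2.5 points lifts each other strain ~+0.3). At high read depth such
spillover can reach two-sided significance without any adhesion biology
behind it. The screen therefore flags `reduced_adhesion` only when the
washed mean is significantly *below* the unwashed control — a one-
directional reading of the two-sided test that matches how the assay is
interpreted (strains that drift upward are not adhesion-defective).

Clearance rate is the absolute OLS slope of log₁₀(CFU/100 mg) on days
within a 0–5-day window. Below-detection points inside the window are
substituted with LOD/2 by default (or dropped); a trailing run of
consecutive censored days is always excluded, since once the organism is
cleared further censored days carry no slope information. Growth rate is
the OLS slope of log₂(OD₆₀₀) against hours inside a user-chosen window,
i.e. doublings per hour; OD must be positive inside the window.

## Synthetic data

Generators are pure functions of their configuration including the seed
(byte-identical reruns). The sequenced amplicon is the 80-nt template
region plus constant 50-nt pads on each side (the real enrichment-primer
coordinates are internal to *cat*; 180 nt is representative and keeps
150-nt mates overlapping by ≥ 100 nt). Reads carry a 6-base random
diversity spacer at their 5′ end, a fixed quality profile (Q25 first/last
10 cycles, Q35 elsewhere) or a constant profile implied by an explicit
per-base error rate, and substitution errors drawn at the quality-implied
probability. No indels are generated by default: the assignment is
flank-anchored on a short amplicon, and indel robustness is not what the
round-trip tests probe.

The competition generator mirrors the assay design: per experiment one
shared T0 mixture sample plus washed and unwashed TF wells in technical
triplicate, across three experiments. Unwashed TF proportions equal T0;
washed TF proportions are the configured per-strain percentage-point
effects applied and renormalised (default: nine ~1:1 strains with dcmbA at
−2.5). Replicate noise is logistic-normal with 5% CV at both the
biological (per-experiment) and technical (per-sample) level — chosen once
to reproduce the scatter seen in real control mixtures, where per-strain
deltas on ~11% baselines stay within a few tenths of a percentage point to
~±0.7. CFU series are log-linear decays (default slope 0.8 log₁₀/day from
10⁸ CFU/100 mg, Gaussian noise sd 0.2, six subjects, days 0–7) censored at
an LOD of 100 CFU/100 mg, recorded at the limit with a censoring flag.
Growth curves are logistic (inoculum OD 0.02, capacity 2.0, 1-h lag,
default 1.0 doublings/h, 2% multiplicative noise); fits restricted to the
early window (OD ≪ capacity) recover the generating rate to within ~4%,
the residual being genuine logistic damping rather than estimator bias.

What passing tests show — and don't: the generators emulate multinomial
sampling, quality-driven substitution error and replicate-level proportion
noise, but not PCR amplification bias, index hopping, chimeras, indels, or
strain-specific growth during the assay. Agreement on synthetic data
validates the arithmetic and the statistical behaviour of the pipeline,
not robustness to those artefacts.

## Problem sizes and numerical choices

Simulation-backed tests and examples run the competition at 10⁴ read
pairs per sample (21 samples); the configuration default is 10⁵. Replicate
noise dominates multinomial noise at both depths, so conclusions are
unchanged; the smaller size keeps the full suite around a minute of
simulation time. Enumeration is exhaustive (4,096 barcodes, well under a
second). Monte-Carlo checks use ≥ 2,000 trials with fixed seeds and
3-standard-error tolerances. Case handling is canonical-uppercase
throughout; all intervals are 0-based half-open except 1-based residue
indices in mutation strings, which follow the field's convention.

## Known limitations

- The merger is not a drop-in reimplementation of any external tool's
  scoring; it implements the documented consensus rules above.
- MAMA design performs no thermodynamics; predicted band sizes are
  coordinate arithmetic.
- The 1,536-tag restricted space requires the user to supply the 24-codon
  whitelist; the admissible amino-acid set is an experimental observation,
  not derivable from the model.
- Extraction requires both 12-nt flanks exactly once; heavily degraded
  reads are dropped as unassigned rather than rescued.
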