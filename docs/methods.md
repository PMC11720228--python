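# Methods

This note records the models, conventions and numerical choices behind
`ringkit`, and what its synthetic validation does and does not show.

## RING domain grammar and scanning

A RING type is encoded as eight allowed-residue sets over {C, H, S, T, G}
at the metal-ligand positions ml1..ml8 and seven finite sets of allowed
spacer lengths g1..g7 between them.  The default grammar:

| Type | ml1..ml8 | g1..g7 |
|---|---|---|
| RING-H2 | C C C H H C C C | 2, 11–28, 1, 2, 2, 7–45, 2 |
| RING-HCa | C C C H C C C C | 2, 9–20, 1, {2,3}, 2, 6–29, {1,2} |
| RING-HCb | C C C H C C C C | 2, 11–13, 1, 2, 2, 11–18, 4 |
| RING-v | C C C C H C C C | 2, 11–27, 1, 7, 2, 12–15, 4 |
| RING-C2 | C C C C C C C C | 2, 13–15, 1, 4, 2, 10–36, 2 |
| RING-S/T | C {S,T} C H C {C,S} C C | 2, 10–14, 1, {2,3}, 2, {6,13}, 2 |
| RING-D | C C C H C C C C | 2, 12, 1, 2, 2, 10, 2 |
| RING-G | C C C H G C C C | 2, 16, 1, 2, 2, 13, 2 |

Two deliberate choices:

* **RING-HCb g7 = 4.**  Published consensus tables for this family are
  inconsistent between the HCb row (printing X_2) and the observation
  that every HCb domain carries a four-residue ml7–ml8 spacer.  With
  g7 = 2 the HCb row is a strict subset of HCa and the four-residue
  observation is unsatisfiable, so we fix g7 = {4}.  Anyone preferring
  the tabulated value can override the grammar from JSON.
* **RING-D as printed.**  The RING-D consensus row contains no aspartate;
  we encode it exactly as printed, which makes it a fixed-gap special
  case inside RING-HCa's ranges.  Precedence, not residue content,
  separates them.

**Precedence** orders types most-specific-first (RING-G, RING-D,
RING-S/T, RING-C2, RING-v, RING-HCb, RING-H2, RING-HCa) so that broad
ranged types cannot absorb the fixed-gap special cases they contain.

**Scanning** is exhaustive: the scanner walks candidate ligand positions
depth-first per type and emits every position 8-tuple satisfying the
constraints, equivalent to brute-force enumeration of all increasing
8-tuples (the test suite asserts this equivalence against an
independent enumerator on random sequences).  Spacer residues are
unconstrained — real domain loops contain Cys/His — and nonstandard
letters (X/B/Z/U/*) never satisfy an ml constraint but are legal in
spacers.  A domain may touch either sequence end.

**Overlap resolution** partitions a protein's hits into transitive
overlap clusters and keeps one hit per cluster by (type precedence,
leftmost ml1, smallest span).  The policy `all` returns raw matches.

## Spacing profiles

Spacer-length counts are tabulated per (type, gap index) stratum and for
an `ALL` stratum aggregating all types, with fractions relative to the
stratum's hit count (both denominators are always available to the
caller).  The modal spacing breaks count ties toward the smaller length;
no biological claim is attached to the tie-break, it is just
deterministic.

## Molecular weight and isoelectric point

MW is the sum of average residue masses (ExPASy-style table, water
18.0153 Da added once).  Nonstandard residues raise an error by default;
permissive mode substitutes the mean residue mass.

The pI model puts Henderson–Hasselbalch charges on the free termini
(pK 7.5 / 3.55) and the D, E, C, Y, H, K, R side chains with
Bjellqvist-style pK values.  Terminal pKs are residue-independent: the
residue-specific terminal adjustments used by some calculators shift pI
by a few tenths of a unit for short acidic peptides and, more
importantly, break the monotone response of pI to composition (appending
aspartate would *raise* the C-terminal pK and can raise the pI of an
acidic peptide).  With the constant-terminal model, appending K/R never
lowers and appending D/E never raises the pI, which the tests assert.

The pI is located by bisection on [0, 14].  Because the charge slope at
the zero crossing grows with the number of ionizable groups, a fixed pH
tolerance alone would leave long proteins visibly charged at the
reported pI; bisection therefore refines the interval below 0.001 pH
*and* continues until the residual net charge is below 1e−6.  Agreement
with an independent Bjellqvist implementation is asserted to 0.02 pH on
sequences where both models share the same pK set.  Bit-equality with
any particular web service is not claimed.

## Ka/Ks (NG86 with Jukes–Cantor correction)

Site counts: per codon position, the synonymous fraction is the share of
the single-base changes that preserve the amino acid, with changes to
stop codons removed from the denominator, so S + N = 3 for every sense
codon.  Sites are averaged over the two sequences.

Differences: codons differing at k positions are scored by averaging the
per-step synonymous/nonsynonymous classification over all k! orderings
of the single-step pathways; orderings passing through a stop codon are
excluded (if every ordering is blocked — possible only for 2–3-hit
codons — the average falls back to all orderings).  All 61×61 codon-pair
scores are precomputed, so pairs are scored by table lookup.

Correction and classification: ps = Sd/S and pn = Nd/N are corrected
with d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 raises a saturation error.
Ka/Ks < 1 is purifying, > 1 positive (equality within 1e−12 is
neutral); Ks = 0 with Ka > 0 yields an infinite ratio scored positive,
and an identical pair is undefined.  Codons containing an ambiguous
base, a gap, or a stop in either sequence are skipped pairwise and
counted.

This is the equal-weight counting estimator; model-averaged or
maximum-likelihood tools will produce different values on the same
pairs, so published Ka/Ks ranges obtained with unstated tools are not
exact targets for this implementation.  Codon alignment is assumed
given: duplicate-pair CDS from one genome are typically near-identical,
and alignment construction is out of scope.

## Duplicates and expression logic

* **Tandem calls**: a pair is tandem when both genes share a chromosome
  and their gene-order ranks differ by at most `max_gap + 1`
  (default adjacent, `max_gap = 0`).  Everything else is a
  nontandem/segmental candidate; true segmental assignment requires
  collinearity blocks computed externally and supplied as input.
* **DEG calls**: inclusive thresholds exactly as stated
  (log2FC ≥ 1 / ≤ −1, adjusted p ≤ 0.05); direction by sign; records
  with missing values are excluded and counted.  log2FC and adjusted p
  are consumed from input tables (they normally come from a dedicated
  differential-expression model whose shrinkage we do not reimplement);
  Benjamini–Hochberg adjustment is available for raw p-values.
* **Set logic**: a gene is in the ≥ k set when DE at ≥ k time points in
  any direction (mixed-direction genes included); the directional
  all-time-point sets require the same direction at every configured
  time point, so mixed genes belong to neither.
* **Pair concordance**: concordant iff directions match at every time
  point where both genes are DEGs and at least one such time point
  exists; opposite directions anywhere make the pair discordant; pairs
  with no shared DEG time point are vacuously concordant and flagged
  `untested`.
* **qPCR**: Livak relative expression
  2^−((Ct_tgt,t − Ct_ref,t) − (Ct_tgt,0 − Ct_ref,0)).

## Synthetic data

The generators produce the study's data *structures* with known truth;
they are deliberately not realistic in composition:

* **Protein cohorts** plant domains drawn from the grammar between
  random flanks.  In the default non-ligand mode, spacers and flanks use
  the 15 residues that can never satisfy an ml constraint, so the
  planted hits are provably the only matches; two further guarantees
  keep ground truth exact: inter-domain linkers are longer than the
  widest grammar gap (45), so no chimeric match can bridge two planted
  domains, and spacer draws that would also satisfy a higher-precedence
  type (e.g. an HCa drawn exactly at RING-D's gaps) are redrawn.  The
  full-alphabet mode drops these guarantees and guarantees recovery only
  as a superset.  Amino-acid composition is uniform, so recovery rates
  say nothing about false-positive rates on real proteomes.
* **Codon pairs** evolve two descendants independently from a
  uniform-sense-codon ancestor: each site mutates with probability p
  (validated < 0.1 to stay in the regime where the Jukes–Cantor
  correction is accurate), stop-creating changes are rejected and
  redrawn, nonsynonymous proposals are accepted with probability
  min(1, ω) and synonymous with min(1, 1/ω) so the realized rate ratio
  equals ω on both sides of 1.  No transition/transversion bias or codon
  usage bias is modelled.
* **Expression fixtures** plant exact per-time-point DEG counts, a
  configurable number of ≥2-time-point genes (split between two- and
  three-time-point memberships to meet the event total), all-time-point
  up/down genes, and duplicate pairs whose members share identical DEG
  time-point sets (so concordance is non-vacuous).  Time points are
  allocated by a capacity-greedy assignment that raises an error on
  infeasible targets.  DEG cells get |log2FC| in [1.5, 4] and adjusted
  p < 0.05; every other cell violates at least one threshold.  Values
  are drawn directly in effect-size space — no count model, library
  sizes or dispersion, so these fixtures validate set logic, not
  differential-expression inference.

Every generator seeds one private RNG stream from its integer seed;
equal seeds give byte-identical output.

Default study-shaped parameters: 914 genes over time points 1/3/12/48 h
with 107/153/273/90 planted DEGs, 393 DEGs overall, 144 genes at ≥ 2
time points, 13 all-time-point genes (10 up / 3 down) and 45 concordant
duplicate pairs.

## Validation problem sizes

The test suite and `scripts/acceptance.py` exercise: scanner/brute-force
equivalence on 1,000 random 300-aa sequences; exact recovery of 800
planted domains spanning all eight types (including two- and
three-domain proteins); dN/dS recovery on 200 pairs × 10,000 codons at
2% per-site divergence for ω = 1 (mean within [0.9, 1.1]) and ω = 0.2
(mean within [0.15, 0.25]); exact recovery of the planted expression
structure above; and |net charge at pI| < 1e−3 over 1,000 random
proteins.  These sizes give tight means at interactive runtimes.

## Known limitations

* The scanner is a grammar matcher, not a profile HMM: it has no notion
  of E-values and will not find degenerate domains that violate the
  consensus spacing.
* Genome-scale headline numbers from real proteomes (family sizes,
  per-type census, DEG totals) depend on the upstream homology search
  and on real transcriptome data; they are inputs to this package, not
  outputs.
* NG86 equal pathway weighting slightly biases Ka/Ks for deeply
  diverged pairs; the simulator validates the low-divergence regime the
  method is intended for.
* GFF reading is restricted to gene/mRNA/exon rows; the exon count is
  taken from the first-listed mRNA per gene (multi-isoform handling is
  out of scope).
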