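# Methods

This note documents the models, conventions and numerical choices behind
`crossfam`, what the synthetic-data generator does and does not emulate, and
the known limitations of the simplified quantifier.

## Coordinates and site model

All coordinates are 0-based, half-open, on the forward strand of an amplicon.
A protospacer site is identified by the leftmost forward-strand base of its
20-mer window regardless of strand: a `+` site has its PAM in the three bases
immediately right of the window, a `-` site appears on the forward strand as
the reverse-complemented PAM immediately left of the window.  Under
reverse-complementation of an amplicon of length L, a site at position p maps
to L − 20 − p with flipped strand; this protospacer-leftmost convention keeps
scan, enumeration and on-target validation coordinates interchangeable.

The protospacer length is fixed at 20 nt (the designed guides are 20-mers);
the PAM is a configurable 3-letter IUPAC motif, default NGG (SpCas9).  An `N`
in the pattern matches anything, including an ambiguous `N` in the amplicon;
every other IUPAC code accepts only its literal expansion, so an amplicon `N`
never satisfies the `G` of NGG.  Amplicon `N`s likewise never match a guide
base: in alignment and edit distance they count as a fifth symbol
(mismatch cost applies), which tolerates reference ambiguity without
inventing degenerate-base semantics for guides.

The predicted cut is the blunt SpCas9 cut 3 nt 5′ of the PAM, i.e. between
protospacer positions 17 and 18 (1-based).  On the minus strand this mirrors
to forward junction `window_start + 3`.

## Candidate enumeration

For every ordered (guide, sibling amplicon) pair the scanner collects all
PAM-adjacent 20-mer windows on both strands (overlapping windows are all
retained; nothing is merged) and filters by two criteria against the guide:

* **Alignment score** — optimal pairwise score under a configurable scheme.
  Default: match 1, mismatch 0, free gaps, global mode, so the score is the
  number of matched bases (equivalently the LCS length); a perfect site
  scores 20.  Default threshold 10.  Computed with Biopython's
  `PairwiseAligner`; an independent full-matrix Gotoh implementation in the
  test suite verifies scores exactly, including affine and local variants.
* **Edit distance** — unit-cost Levenshtein distance, computed with edlib
  and verified against a full-matrix DP oracle.  Default threshold 12.

The defaults are deliberately permissive: cross-reactive sites at edit
distances of 9–10 from the guide are biologically real in paralog families,
so the admission region must reach at least that far.  Both thresholds are
monotone (loosening either only ever adds sites), a property the test suite
checks on randomized families.

Candidate lists are sorted by (score desc, edit distance asc, position asc,
`+` before `-`), which makes selection and labelling deterministic.
`select_reported_sites` truncates each list to its top-k and labels the
survivors α, β, γ…, mirroring the convention of carrying a handful of
"selected potential off-target sites" per sibling into quantification.  A
sibling's own on-target window is a legitimate cross-reactivity candidate
and is retained by default; `exclude_sibling_on_target` removes it for
analyses where the sibling guide is also being delivered (its own editing
would otherwise appear as cross-activity).

## Configuration tables

One table per target guide: one on-target row (the target's amplicon with
its designed guide in the gRNA cell) plus one off-target row per retained
candidate (the putative recognition sequence in the gRNA cell).  The native
CSV dialect round-trips every field; the minimal three-column dialect
(`SiteName,AmpliconReference,gRNA`, remappable headers) matches the public
convention of external amplicon-analysis configuration files.

## Read quantification

**Assignment.**  Each read (or its reverse complement, whichever is closer)
is compared against every family amplicon by global edit distance; the
minimum wins, ties broken by reference order, and reads whose best distance
exceeds 30% of the reference length are set aside.  Reads shorter than half
the shortest reference are discarded as fragments before assignment.  Full
amplicon-length reads make this assignment essentially unambiguous at ≥5%
paralog divergence (≥99% accuracy in simulation at 1% read error); the
implementation uses banded alignments capped at the current best distance
for speed.

**Edit calling.**  The assigned read is globally aligned to its reference
and called *edited* at a site when any alignment gap (insertion or deletion,
length ≥ 1) overlaps the window cut ± 10 nt.  Substitutions never count —
NHEJ signatures are indel-dominated and substitution errors would otherwise
dominate the background.  A read is *discarded* at a site when its anchored
coverage does not span the window; coverage is the reference span between
the outermost exact-match runs of ≥ 15 bases, so a truncated read cannot
fake window coverage with a spurious few-base end match.  The default
alignment for calling is the unit-cost (Levenshtein) global alignment via
edlib: it is two orders of magnitude faster per kilobase read than an affine
aligner, and with a ±10 nt window the two produce identical calls on clean
NHEJ indels (asserted in the test suite).  An affine-gap mode
(match 2, mismatch −2, open −4, extend −1, preferring one contiguous indel)
is available as `method="affine"` for users who want gap placement
consistent with classical amplicon tools.

**Estimation.**  Per (site, sample): the raw edited proportion
p̂ = n_edited/n_reads with a Wilson score 0.95 interval (stable at
sub-percent rates, verified against the closed form to 1e-9), threshold
flags at 1%, 0.3%, 0.1% and 0.01%, and a one-sided Fisher exact test
(treatment > mock) at α = 0.05, verified against full hypergeometric
enumeration.  No multiple-testing correction is applied by default (a
configured analysis quantifies a handful of sites); Benjamini–Hochberg is
available for large configurations.

**Background correction.**  Any indel sequencing error inside the call
window is counted as an edit, so the raw proportion estimates
r + b(1 − r), where r is the true edited fraction and b the background
call rate — with CCS-like per-base indel error of 0.7% and a 21-position
window, b ≈ 1 − 0.993²¹ ≈ 13%.  The raw rate is therefore reported as-is
(it is the directly observed quantity) but, whenever a mock is present, the
package also reports the corrected activity
(p̂_t − p̂_m)/(1 − p̂_m), which is unbiased for r, with a Newcombe hybrid
score interval rescaled by 1/(1 − p̂_m).  The corrected point estimate is
not clipped at zero: small negative values are downward background
fluctuations, and clipping would bias replicate averages upward at exactly
the sub-percent rates this analysis targets.  When a mock is available the
corrected estimate is the package's headline activity number; the raw rate
and the mock rate are always reported beside it.  Parameter-recovery
simulations (2000 reads, 1% total per-base error, 20 independent
treated/mock pairs per rate) show the corrected 0.95 interval covering true
rates of 0, 0.1%, 1% and 10% at nominal frequency, while the raw interval
is centred on r + b and covers none of them — the quantitative reason the
corrected estimate is the reported one.

## Synthetic data

`simulate_family` draws a random ancestral sequence (default 1000 nt,
matching the ~0.9–1.1 kb amplicons the design targets), derives each member
by i.i.d. substitutions (default 5% per base, the low end of recently
duplicated paralog divergence) plus sparse short indels (0.2% per base,
1–3 nt), then splices in one random 20-mer guide with an NGG PAM per member
at a random interior position ≥ 100 nt from the ends (amplicons extend
several hundred bases beyond the target site in the emulated design) and,
for each requested off-target, a 20-mer at exactly the requested Levenshtein
distance d from the source guide, with its own PAM, strand chosen at random.
Planted variants are constructed by substitution-only edit scripts and
re-verified with the same edit-distance routine the enumerator uses, so the
planted window's measured distance equals d exactly (an indel-containing
script would shift the PAM-adjacent window and break that identity).
Planted features are kept ≥ 25 nt apart.  The truth table records position,
strand, protospacer, PAM, distance and cut position for every planted site.

`simulate_reads` emits, per sample and amplicon, n copies of the reference
(default 2000), each independently edited at every truth site it hosts with
that site's configured rate (always 0 in the mock), then passed through an
i.i.d. per-base error channel (substitution/insertion/deletion
0.003/0.003/0.004 — a conservative CCS-like ~1% total) and flipped to the
reverse strand with probability 1/2.  Edits are cut-site indels from a
deletion(1–10 nt, 70%)/insertion(1–3 nt, 30%) mixture, deletions centred on
the cut junction.  The exact realized edited count per (sample, site) is
recorded.  Samples follow the emulated design: several treated replicates
plus one mock control.  All randomness derives from one integer seed via
spawned generator streams; identical specs produce byte-identical FASTA and
FASTQ output.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: homopolymer-dependent indel error (CCS error is
not i.i.d.), chimeric/primer-dimer reads, barcode hopping, amplification
bias between alleles, polyploid allele mixtures, microhomology-biased repair
spectra, and translocations.  Real analyses should treat the mock-corrected
estimates as conditional on the mock capturing the same error process as
the treatment arms, which the multiplexed single-pool design encourages but
does not guarantee.

## Numerical and design choices

* Window half-width default 10 nt: wide enough to absorb alignment wobble of
  left- or right-shifted indels near the cut, narrow enough to keep the
  error background proportional to ~21 positions.  Monotone: widening never
  un-calls an edited read.
* Insertions are located at their reference junction; an insertion exactly
  on the window boundary counts as inside (inclusive on both edges).
* Degenerate inputs: amplicons shorter than 23 nt are rejected at load;
  empty candidate lists propagate to a config table with only the on-target
  row; a site×sample cell with zero evaluable reads yields a NaN rate with
  a warning rather than an abort; a missing mock downgrades to no-mock mode
  (no significance calls) with a warning.
* Site naming: `{amplicon}_{label}` for selected sites, `{amplicon}_{position}`
  otherwise, with a strand suffix only when two strands share a window
  position.
* The pipeline driver writes a manifest (tool version, full configuration,
  stages) next to its outputs; CSV payloads are byte-stable for a fixed
  configuration and seed.

## Problem sizes used in the shipped experiments

The randomized verification suites run at sizes chosen to exercise the code
thoroughly on a single CPU: 200 random families (2–3 amplicons, 300–1000 nt)
for enumeration-vs-oracle equivalence, 1000 random pairs for the DP oracles,
50 planted-site recovery families across d = 0…14, and 20 independent
treated/mock pairs of 2000 reads at each of four true rates for parameter
recovery.  The acceptance script quantifies six 2000-read replicates plus
mock for the strong-site arm and a 200 000-read pool for the weak (0.36%)
site, whose signal sits an order of magnitude below per-replicate binomial
background noise at 2000 reads.

## Known limitations

The quantifier is a deliberately transparent stand-in for richer Bayesian
read-classification models: it does not model per-read quality, does not
separate true edits from errors at the read level (only in aggregate via the
mock), does not detect translocations or large structural outcomes, and
treats every indel in the window equally regardless of size or
microhomology.  Absolute sensitivity at a given depth is limited by the
error background; with ~13% background per 21-position window, sub-0.1%
activities require either very deep pools or an error model, not more
replicates.
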