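# Methods

## Model and pipeline

`sscall` models targeted cfDNA sequencing as a three-stage error-reduction
cascade.  Every original single-stranded cfDNA molecule is labelled with a
random molecular tag before amplification; all reads carrying the same
(tag, alignment start, strand) key are treated as copies of one molecule.
PCR and sequencing errors are then suppressed twice:

1. **Within-family majority vote.**  The consensus allele at a reference
   position is the allele carried by strictly more than `majority_threshold`
   (default 0.70) of the family members covering that position; otherwise
   the consensus is `N`.  The vote is implemented in exact rational
   arithmetic, so a family with exactly 70.0% support yields `N` (7/10 is
   not > 7/10) regardless of float rounding.  Insertions and deletions are
   voted by the same rule; deletions are carried per deleted position, with
   the event (anchor, length) kept separately for indel-length filtering.
   Members whose alignment does not cover a position do not dilute its vote.
2. **Background-profile testing.**  Errors that survive consensus (mostly
   first-cycle PCR artifacts) recur at characteristic positions, so a
   per-(position, alternative-allele) background profile is estimated from
   mutation-free control samples and each candidate in a test sample is
   required to exceed it statistically.

### The conservative error bound

Tag-based consensus leaves most panel positions with zero observed errors
even across dozens of controls; the maximum-likelihood rate k/n = 0 would
make any single alt molecule "significant".  The profile therefore stores
an upper confidence bound ε_up at per-entry confidence δ (default 0.01).
The default construction inverts the Chernoff–Kullback–Leibler binomial
tail bound,

    ε_up = sup { ε ≥ k/n : n · KL(k/n ‖ ε) ≤ ln(1/δ) },

solved by bisection; at k = 0 it has the closed form 1 − δ^(1/n) ≈ ln(1/δ)/n.
Two alternatives are selectable through `ProfileConfig.method`: the exact
binomial (Clopper–Pearson) limit, which is numerically indistinguishable
from the KL inversion at small rates, and the additive Hoeffding-type bound
k/n + sqrt(ln(1/δ)/(2n)).  The additive form is *not* the default because
its floor scales as n^(-1/2): at a pooled control coverage of n = 120,000 it
cannot certify any rate below ~0.4%, which would make a 0.5% variant
untestable — inconsistent with the assay's demonstrated sensitivity.  The
KL bound's floor scales as 1/n (~4e-5 at the same n), matching the
operating point at which the assay detects 0.5% variants reproducibly.
All three constructions satisfy ε_up ≥ k/n, monotonicity in k and n, and
the coverage guarantee P(ε_up < true rate) ≤ δ (checked by Monte Carlo in
the test suite).

### The caller

For every non-SNP panel position with SSCS coverage ≥ `min_sscs_coverage`
(default 100), each of the three non-reference bases with a profile entry
is a hypothesis; m is the count of all such hypotheses in the sample,
whether or not any alt molecule was observed — the stringent reading of
controlling the global false-positive rate over everything that could have
been called.  A candidate with a alt molecules at coverage N is scored with
the one-sided binomial survival probability P(X ≥ a), X ~ Bin(N, ε_up),
and adjusted as p_adj = min(1, m·p).  Candidates with p_adj < α (strict;
ties are not called) are emitted, carrying the labels of any failed filter:

* `single_strand` — no alt support on one of the strands;
* `strand_bias` — two-sided exact (Fisher) test of alt proportion between
  strands below `strand_bias_p_floor` (default 0.001);
* `indel_too_short` — indel length < `min_indel_length` (default 3, i.e.
  only indels longer than 2 bp are considered);
* `low_coverage` / `snp_masked` are structural: such positions are not
  tested at all and contribute nothing to m.

A call with an empty label set is PASS.  Indel hypotheses are keyed by
length class (`del:3`, `ins:2`); an indel class never seen in the controls
falls back to the k = 0 bound at the position's pooled control coverage and
is added to m when tested.  The Bonferroni universe is counted per sample
(recorded in the run metadata), not per cohort.

## Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `majority_threshold` | 0.70 | fraction | strict within-family vote threshold |
| `min_family_size` | 1 | reads | no minimum is imposed upstream; configurable |
| `tag_merge_hamming` | 1 | mismatches | directional merge absorbs 1-error tags |
| `delta` | 0.01 | — | per-entry confidence of ε_up |
| `alpha` | 0.05 | — | family-wise false-positive level per sample |
| `min_sscs_coverage` | 100 | molecules | positions below are not considered |
| `strand_bias_p_floor` | 0.001 | — | exact-test floor; statistic and floor exposed |
| `min_indel_length` | 3 | bp | indels of 1–2 bp are dominated by platform noise |
| `tag_length` | 10 | nt | collision probability negligible at panel scale |
| `fragment_length` | 160 ± 20 | bp | mononucleosomal cfDNA fragment size |
| `recovery` | 0.22 | fraction | typical molecular recovery of the assay |
| `family_size_mean` | 30 | reads | raw:SSCS coverage ratio ~67,000:2,200 |
| `raw_substitution_rate` | 1e-3 | per base | realistic raw semiconductor-sequencing error |

Molecular recovery uses 3.3 pg per haploid genome and 2 single strands per
genome equivalent; both constants are recorded in every report since the
denominator convention is a choice.

## What the simulator does and does not emulate

The read-level generator draws molecules (count = 2 × mass/3.3 pg ×
recovery, or an explicit override), assigns each a random tag, locus,
strand and ~160 bp fragment, allocates spike-in alt alleles per molecule as
Bernoulli(vaf), draws family sizes geometrically, and injects independent
per-base substitution errors, occasional 1–3 bp indels, and tag errors.  A
consensus-level shortcut (`simulate_sscs_pileup`) draws SSCS pileups
directly at a stated coverage and error rate with independent positions;
the large-cohort specificity/sensitivity experiments use it because they
exercise only the profile/caller stages.

Deliberately not modelled: flow-space/homopolymer error structure of
semiconductor sequencing, position- and context-dependent error spectra
(available as an opt-in hotspot hook is *not* provided; error injection is
homogeneous), double-strand (duplex) consensus, GC-dependent capture bias,
and real family-size distributions, which are unpublished for this
chemistry.  A green specificity test therefore establishes that the
statistics control errors in the stated world — homogeneous, independent
errors at the stated rates — not that the pipeline is robust to hotspot
artifacts; the per-position profile exists precisely to absorb those in
real data, but the simulation does not stress it.

## Numerical choices

* Consensus votes compare integer counts against the threshold as an exact
  `Fraction`; no float comparison touches the 70% boundary.
* The KL bound is solved with Brent's method on [k/n, 1−1e-12] at xtol
  1e-15; the binomial tail uses the scipy survival function (asserted
  against direct pmf summation to 1e-12 for n ≤ 50 in the tests).
* Tag merging is directional and deterministic: candidates sorted by
  (−size, tag) and absorbed by the first strictly larger neighbour, ties
  broken lexicographically; equal-size neighbours never merge.
* Families, consensus records and pileups are sorted on their keys, so the
  pipeline output is invariant to input read order and bit-identical on
  rerun.  Per-sample seeds derive from the master seed via
  `numpy.random.SeedSequence(master, spawn_key=(index,))`.
* Degenerate inputs: empty read streams yield empty family lists; a family
  of one returns the read verbatim; n = 0 positions are untestable and
  raise `no_coverage`; coverage 0 makes VAF undefined and raises.

## Known limitations

* Insertion events sit between positions and are excluded from per-position
  coverage; insertion VAFs are therefore computed against the anchor
  position's coverage.
* The caller tests substitutions at every profiled position but indels only
  when observed in the sample, so m grows slightly with observed indel
  candidates; with default settings this changes p_adj by < 1%.
* SAM output/input carries the tag in an auxiliary string field (`RX`);
  BAM is supported by pysam transparently but all shipped fixtures are
  plain text.
* Specificity experiments at desk scale use a 300-position panel; the
  real assay's panel is two orders of magnitude larger, which scales m and
  the Bonferroni threshold proportionally but does not change the
  per-hypothesis guarantee.
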