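# Methods

## Coordinate frame and regions

All coordinates are 0-based, half-open, in transcript space, running 5′→3′.
Strand is resolved once, at annotation load time (minus-strand transcripts
are reverse-complemented during GTF flattening), and never reappears
downstream. T and U are equivalent; sequences are stored in the DNA
alphabet.

The normal termination codon (NTC) is counted **inside** the CDS:
`cds_end` is one past the last nucleotide of the stop codon. This puts
"density at the stop codon" and "CDS density" in a single frame and makes
the RRTS denominator include the NTC. The alternative convention (NTC
outside the CDS) changes the RRTS denominator by at most 3 nt out of a
whole CDS and the pause-score denominator not at all (the body excludes the
last 12 nt anyway); the choice is recorded in provenance rather than
surfaced as a switch.

Four regions drive every metric:

| region | interval | role |
|---|---|---|
| CDS | `[cds_start, cds_end)` | RRTS denominator |
| CDS body | `[cds_start+15, cds_end−12)` | pause-score denominator |
| stop codon | `[cds_end−3, cds_end)` | pause-score numerator |
| extension | `[cds_end, next in-frame stop)` | RRTS numerator |

The body exclusion removes initiation- and termination-proximal pile-ups
from the elongation baseline; a CDS shorter than 30 nt leaves no room for a
body codon and is flagged pause-ineligible. The extension scan walks
codon-by-codon in the CDS frame from `cds_end`; a stop immediately after
the NTC yields a present-but-empty extension whose density is defined as 0
(the transcript stays in the RRTS population with RRTS 0) — excluding such
transcripts would bias the RRTS distribution upward. Transcripts with no
in-frame 3′ stop at all are excluded from RRTS (the score is undefined)
but retained for pause scores.

## Footprint processing

PCR duplicates are collapsed on the key (transcript, 5′ position, length,
UMI); records with no UMI are never collapsed. Deduplication is idempotent,
order-independent (output sorted by key), and commutes with the length
filter. Size selection keeps 15–35 nt inclusive, matching gel-based
selection bounds read as a closed interval.

P-sites are assigned by a length-dependent offset added to the 5′ end.
The default table maps lengths 25–31 nt to +12 (the conventional mammalian
P-site offset) and drops other lengths; both the table and the drop policy
are configuration, stamped into output provenance. Density tracks hold raw
per-nucleotide P-site counts — all normalization happens in the metrics
layer, so "density" has exactly one definition.

## Scores

* pause score = mean counts/nt over the 3 NTC positions ÷ mean counts/nt
  over the CDS body;
* RRTS = mean counts/nt over the extension ÷ mean counts/nt over the full
  CDS.

No pseudocounts anywhere: a zero denominator (or an absent extension)
makes the score ineligible with a machine-readable reason code, and
ineligible rows still report their densities. A pseudocount would silently
pull RRTS toward 0 for shallow transcripts, which is exactly the regime
where readthrough effects are measured. The default eligibility threshold
is ≥ 32 CDS reads; below a few dozen reads the ratio estimates are
shot-noise dominated. Both scores are invariant to scaling all counts on a
transcript, and strictly monotone in reads added to their numerator
regions.

## Metagene

Transcripts are aligned at the first NTC nucleotide (position 0, window
100 nt up/down by default). Each eligible transcript's counts are divided
by its own mean CDS density and the normalized tracks are averaged with
equal weight per transcript; transcripts shorter than the window contribute
only to the positions they cover, with per-position contributor counts
reported. This normalization makes a uniform track the exact fixed point
(profile ≡ 1), which the tests assert to 1e-12.

## Hypothesis tests

Paired pause scores (same transcripts, two conditions) are compared with a
Wilcoxon signed-rank test; RRTS distributions with a Mann–Whitney U test.
Both are implemented directly:

* **exact mode** (n ≤ 12, or n1+n2 ≤ 12): full enumeration of all 2ⁿ sign
  vectors / all C(n1+n2, n1) labelings over the observed (average-tie)
  ranks, giving rational p-values; enumeration at this cutoff is
  effectively instant and doubles as an oracle at the mode boundary;
* **approximate mode**: normal approximation with tie-corrected variance
  and a 0.5 continuity correction toward the mean.

Zero differences in the signed-rank test are dropped and counted
(Wilcoxon's original convention). Two-sided p-values are
`min(1, 2·min(p_less, p_greater))`. Both modes agree with an independent
standard implementation to floating precision in the test suite, and the
empirical type-I error at α = 0.05 over 2,000 null replicates sits inside
[0.035, 0.065] for both tests. Comparison directions are never inferred
from file names; the configuration declares ordered
(reference, treatment, alternative) triples.

Descriptive summaries: ECDF steps (right-continuous, final fraction
exactly 1) and notched box statistics — quartiles by linear interpolation
between order statistics, notches median ± 1.57·IQR/√n (McGill's 95%
comparison interval), whiskers at the most extreme data within 1.5·IQR of
the quartiles.

## Generative simulator

The simulator exists so that every pipeline stage, and the qualitative
three-arm signature itself, can be tested against known truth.

* **Transcriptome**: random sequences with a guaranteed NTC, no in-frame
  stop inside the CDS, and (for a configurable fraction, default 0.9) an
  in-frame 3′UTR stop placed uniformly among eligible codon starts, with no
  earlier in-frame stop inside the designated extension. A ≥ 27 nt tail
  after the second stop guarantees simulated footprints never run off the
  3′ end. Default sizes: CDS uniform 120–600 nt (multiples of 3), 5′UTR
  50 nt, 3′UTR uniform 90–240 nt — compact but in realistic proportion for
  mammalian mRNAs, and large enough to hold the default metagene window.
* **Counts**: per transcript λ_t ~ Gamma(shape 2, scale 1) counts/nt
  (mean 2 — a mid-depth ribo-seq experiment), position-level counts
  Poisson(λ_t·m(p)) with m = 1 over the CDS, π at the NTC, r over the
  extension, π2·r at the second stop, 0 elsewhere. Overdispersion thus
  lives between transcripts (negative-binomial marginal), not between
  neighboring positions. Under this model E[pause score] = π and
  E[RRTS] ≈ r up to a CDS-density correction of order 3(π−1)/L ≈ 1%.
* **Records**: each count becomes a footprint whose 5′ position is
  back-computed from the configured offset table (simulator and pipeline
  can never disagree about offsets), with a fresh random 10-nt UMI;
  identical duplicates are injected at the configured PCR duplication
  rate. The duplicate coin is always drawn so runs differing only in the
  duplication rate produce identical underlying records.
* **Arms**: conditions share one transcriptome (pairing transcripts for
  the signed-rank test) with independent count noise. The three-arm preset
  uses π = 1, r = 0.005 (vehicle-like); π = 0.5, r = 0.08
  (readthrough-inducer-like); π = 3, r = 0.005
  (termination-inhibitor-like) — effect sizes chosen for clear signature
  separation, since the real effect sizes behind the published test
  statistics are not identifiable from them.

What the simulator does **not** model: sequence-dependent readthrough
(stop-codon identity, +4 context), within-extension drop-off (a geometric
option exists but defaults off), codon-level elongation kinetics, frame
periodicity of real footprints, ligation/PCR sequence bias, and rRNA or
multimapping contamination. Passing tests therefore demonstrate the
*arithmetic and inferential* correctness of the pipeline and its ability
to separate the two termination signatures under Poisson–gamma noise — not
robustness to every artifact of real libraries.

## Problem sizes

The test suite runs the oracle-equivalence check on 60–100 transcripts,
parameter recovery on 2,000 transcripts at mean 2 counts/nt, the
three-arm signature on 1,000 transcripts per arm, and test calibration on
2,000 null replicates of paired samples of size 50 — sizes at which the
medians and p-values of interest are stable and the whole suite completes
in a couple of minutes on one core.

## Assay metrics

% Activation and % viability are affine normalizations anchored at
per-plate control means (0 = negative/low control, 100 = positive/high
control); both are exactly invertible on their anchors and invariant to
affine transforms of the raw luminescence. The hit threshold is the mean
% Activation of all test wells plus three sample SDs of the negative
controls' % Activation (per-plate or campaign-pooled negatives are the
caller's choice). Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋| with sample SDs (n−1); Z′ ≤ 1
always, with equality iff both control SDs are zero, and runs with
Z′ ≤ 0.5 are flagged. Papp = ΔQ/(Δt·A·C0) expects unit-consistent inputs
(amount/s, cm², amount/cm³) and performs no unit inference; the efflux
ratio is Papp(B→A)/Papp(A→B). All control statistics use the sample-SD
convention, stated here because summary formulas are otherwise ambiguous.

## Determinism

Every stochastic step takes an explicit seed; per-condition seeds are
derived from the experiment seed via a seed sequence and recorded in the
manifest. The full simulate → score → compare chain is byte-reproducible,
and every output file carries a short hash of the full configuration
(excluding the output directory) plus the package version in its `#`
provenance header.
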