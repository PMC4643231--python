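# Methods

## The problem

Targeted 16S rRNA amplicon sequencing of ancient microbiome samples (dental
calculus in particular) systematically distorts taxonomic profiles. Ancient
DNA is fragmented to median lengths well under 100 bp, while the commonly
amplified V3 region requires an intact, primer-inclusive target of 150–194
bp depending on the taxon. Because the V3 region carries clade-structured
length polymorphisms — archaeal targets (*Methanobrevibacter oralis*,
151 bp) are at least 17 bp shorter than any bacterial oral target (168 bp
and up) — random fragmentation does not hit all taxa equally: short-target
taxa amplify from a larger share of surviving molecules and are enriched,
long-target taxa drop out. This package implements the three components of
that argument as a tested pipeline: in-silico primer evaluation, a
random-degradation survival model, and a forward simulator of paired
amplicon/shotgun sequencing on synthetic communities.

## Primer-binding model (`insilico_pcr`)

Primer binding is scored as a weighted penalty over gapped alignments of
the primer against a candidate target window:

| event | penalty |
|---|---|
| non-3' mismatch | 0.40 |
| 3' mismatch (last 5 bases, not final) | 1.00 |
| final-base mismatch | 3.00 |
| non-3' gap | 1.00 |
| 3' gap | 3.00 |

A site passes when the total is ≤ 1.00: two non-3' mismatches, one non-3'
gap, or one non-final 3' mismatch pass; any final-base mismatch fails
alone. Only alignments with at most one gap are enumerated — two gaps or
any 3' gap already exceed the threshold, so the cap cannot lose a passing
site. The "3' window" is the last five bases of the primer in its own
5'→3' orientation; a gap is a 3' gap when fewer than five primer bases lie
3' of it (the same convention for deletions and insertions, and the one the
brute-force oracle in the test suite enumerates independently).

Degenerate IUPAC primer bases match a target base when their base sets
intersect. A target `N` never matches; otherwise databases with masked
stretches would inflate coverage.

Reverse primers are searched as their reverse complement on the sense
strand; the scored window is reverse-complemented back into primer
orientation, so the 3' window maps to the leftmost bases of the sense-strand
site. Among equal-score passing sites the forward primer takes the leftmost
and the reverse primer the rightmost site, which maximizes the canonical
amplicon. Amplicon length is primer-inclusive (first base of the forward
site through last base of the reverse site): a degraded template must
contain the whole interval for PCR to proceed. Amplicons above `max_len`
(default 500 bp, matching the analysis restriction to short-amplicon pairs)
are discarded.

Length summaries use the lower median (an observed, integer value for even
n) and nearest-rank percentiles; the 99% interval bounds are the empirical
0.5% and 99.5% nearest-rank quantiles. These rules are applied everywhere.

Taxonomic resolution uses a greedy incremental centroid clusterer:
sequences sorted by decreasing length then lexicographically, identity
computed as alignment matches divided by the shorter sequence's length
under a unit-cost global alignment (edlib), first centroid at ≥ 97% wins.
This approximates the classic greedy OTU clusterer; reproducing any
specific tool's OTU counts bit-for-bit is explicitly not promised.

## Degradation model (`degradation`)

Each internal phosphodiester bond breaks independently with probability
λ (per-bond scission probability; dimensionless). The packaged per-site
values span 0.0006 (a ~150-year-old temperate-climate site) to 0.0863 (a
~1000-year-old tropical site). The survival of an x-nucleotide target is
modelled as e^(−λx); the discrete process actually gives (1−λ)^(x−1).
The per-bond discrepancy is < 0.5% for λ ≤ 0.09, but it compounds over
x ≈ 150–200 bases, so tests that compare the simulator against the
continuous form carry an explicit slack term where it matters.

The observed-profile prediction reweights a community profile by survival:

    f'_i = f_i e^(−λ x_i) / Σ_j f_j e^(−λ x_j)

computed in log space with max-subtraction (λx reaches ~17 at λ = 0.0863,
x = 194; naive products underflow across many taxa). Renormalization is
over all supplied taxa; zero-frequency taxa stay at zero.

`estimate_lambda` inverts the mean fragment length. The plain
exponential-approximation estimator 1/mean is biased upward by
(1−λ)/L on templates of length L (each template contributes terminal
fragments); at λ = 0.005 and L = 1540 that is +13%. When the template
length is known — always true in simulation — the exact moment inversion
λ̂ = (L/mean − 1)/(L − 1) (from mean = L/((L−1)λ + 1)) is used instead;
parameter-recovery tests use this form.

Empirical fragment-fraction statistics come with a caveat worth stating:
the fraction of *fragments* with length ≥ x is not (1−λ)^x on a finite
template — long fragments have fewer placements, and the exact expectation
E[#fragments ≥ x] = Σ_k≥x [(L−k−1)λ² + 2λ](1−λ)^(k−1) + (1−λ)^(L−1)
deviates from the geometric form by up to ~0.02 at λ = 0.01, L = 1540.
The survival the continuous model describes is the *template* survival of a
fixed x-bp target, which does match (1−λ)^(x−1) exactly and e^(−λx) to
within 0.01 over the V3 length range; tests check each quantity against its
own correct expectation.

## Synthetic data (`synthetic`)

The generator emulates the structure the analysis depends on and nothing
more: conserved primer-binding flanks, clade-specific variable-loop lengths
(so the planted primer-inclusive amplicon length is exact by construction),
within-clade loop divergence, and optional planted primer-site defects
(final-3'-base mismatch, or k non-3' mismatches) for coverage tests.
Templates default to 1540 bp (the full 16S gene) with the forward site at
1-based position 341, reproducing the E. coli V3 anchor.

What it does **not** emulate: sequence variation outside the amplified
loop (real 16S genes vary across all hypervariable regions, so real
amplicon OTU resolution is far below full-length resolution — on synthetic
databases it is an upper bound); 16S copy-number variation (one copy per
organism); cytosine-deamination damage; PCR cycle stochasticity or primer
competition (amplification is exhaustive: every fragment containing the
full amplicon interval yields exactly one amplicon — the bias mechanism
under study is template availability); read-level error models. Passing
tests therefore demonstrate the length-bias mechanism, not a full forward
model of ancient sequencing.

Fragmentation realizes λ as independent Bernoulli scission per bond, walked
with geometric gap sampling in a numba kernel. Recording fragments and
counts-only tallying consume the identical random stream, so the staged
path (`fragment_templates` → `amplify_fragments` → `shotgun_sample`) and
the fused counting path used by `run_end_to_end` agree exactly at matched
seeds (asserted in tests). Shotgun reads are drawn uniformly over surviving
fragments with replacement — realized as the induced multinomial over
per-taxon fragment counts; a length-weighted alternative was considered and
rejected because library molecules are fragments, and with equal-length
templates taxon shares track fragment counts. Fragments shorter than
`min_len` (default 25 bp, mirroring standard read-length filtering) are
discarded; amplification is assessed before that filter since PCR acts on
the extract, not on the sequenced reads.

All stage seeds derive deterministically from one master seed
(`numpy.random.SeedSequence`); identical inputs give bit-identical outputs.

## Community metrics (`community`)

Oral/other classification sums profile frequency over an explicit genus
membership list (exact match after case/whitespace folding; no fuzzy
matching). Fold changes are log base 2 — stated in every report header,
since "log fold change" alone is ambiguous — with a symmetric
pseudo-frequency ε = 1e−6, because amplification dropout produces true
zeros on one side. Rank correlation is Spearman's rho with average ranks
for ties (scipy).

## Problem sizes and numerical choices

Desk-scale defaults were chosen once, by power analysis, and are stated
here as the package's own study conditions:

- Simulator–model agreement runs 1e5 templates per λ at the packaged λ
  values {0, 0.0149, 0.0701, 0.0863}. At the two highest λ the model itself
  predicts a near-total dropout (expected amplicon yield < 1 from 1e5
  templates: survival of a 151-bp target at λ = 0.0701 is (1−λ)^150 ≈
  1.8e−5), so the frequency comparison there is checked over whatever
  amplicons exist; it is sharp at λ ≤ 0.0149.
- The 100-seed direction-of-bias experiment at λ = 0.0701 uses 3e6
  templates per seed on compact 280-nt templates (forward site at position
  51). Target survival is independent of template length and shotgun shares
  are template-proportional, so the compact geometry changes nothing about
  the tested event; 3e6 templates put the expected shortest-clade amplicon
  count at ≈ 18 per seed, making the per-seed failure probability of the
  sign event ≈ 1e−4 (Poisson/binomial calculation), i.e. the ≥ 99/100
  requirement holds with large margin.
- λ-recovery tests run 1e5 templates over λ ∈ {0.005, 0.01, 0.02, 0.05}
  with min_len = 1 (the estimator sees the full fragment pool).

Tolerances: profile normalization to 1e−9; scoring comparisons to 1e−9
(penalties are exact decimals); simulator-vs-model frequency comparisons at
3 binomial standard errors plus an explicit discrete-vs-exponential slack
(0.005–0.012 depending on λ); survival and fragment-fraction checks at
±0.01 absolute. Ties in site search are impossible after the documented
position tie-break; ties in clustering are resolved by centroid creation
order, which the canonical input sort makes deterministic.

## Known limitations

- The greedy clusterer is an approximation; absolute OTU counts on real
  databases will differ from uclust's.
- The scoring scheme considers at most one gap per site; this is lossless
  for pass/fail decisions but reported scores for grossly mismatched
  windows are upper-bounded rather than exact.
- The analytic bias model renormalizes over supplied taxa only; if a
  profile omits taxa that would amplify, predicted frequencies are
  conditional on the supplied set.
- Thermal-age → λ conversion is out of scope; λ values are inputs.
- HOMD rank abundances do not cover archaea (the HOMD assay primers do not
  amplify them), so the thermal-series analysis reports measured-abundance
  taxa by default and a clearly labelled sensitivity variant with
  *M. oralis* assumed at 0.1%.
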