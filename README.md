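# paleo16s

Why does 16S rRNA V3 amplicon sequencing of ancient microbiome samples
(archaeological dental calculus in particular) produce taxonomic profiles
with wildly inflated archaea and missing pathogens? This package implements
the quantitative argument as a tested, reproducible pipeline, for
researchers working on ancient microbiomes, metataxonomics, or
amplicon-bias methodology:

1. **In-silico primer evaluation** — penalty-scored primer binding
   (non-3' mismatch 0.40, 3' mismatch 1.00, final-base mismatch 3.00,
   non-3'/3' gap 1.00/3.00; pass at ≤ 1.00), primer-inclusive amplicon
   extraction, and the three primer-quality metrics: length variation
   (median and 99% nearest-rank interval), per-phylum taxonomic coverage,
   and OTU-based taxonomic resolution (greedy 97% centroid clustering).
2. **Random-degradation survival model** — ancient DNA breaks at each
   internal bond with per-bond probability λ (driven by the sample's
   thermal age); an x-bp primer-inclusive target survives with probability
   e^(−λx), so a starting community f is observed as

       f'_i = f_i e^(−λ x_i) / Σ_j f_j e^(−λ x_j).

   Because the archaeal V3 target (151 bp) is ≥ 17 bp shorter than any
   bacterial oral target, degradation alone predicts progressive archaeal
   enrichment and dropout of long-target taxa — the "Archaea effect".
3. **Forward simulator** — synthetic clade-structured 16S databases with
   planted amplicon lengths, multinomial community sampling, per-bond
   Bernoulli fragmentation (numba-accelerated), an exhaustive-PCR amplicon
   arm, a uniform shotgun arm, and amplicon-vs-shotgun log2 fold-change
   comparison against the analytic prediction.

## Worked example

Simulate paired amplicon/shotgun sequencing of a three-clade community
(planted V3 lengths 151/169/194 bp, equal starting frequencies) degraded at
λ = 0.0149 — the packaged value for a Chalcolithic site:

```python
import paleo16s as p
from paleo16s.datasets import load_primer_pairs

v3 = load_primer_pairs()["U341F/534R"]
spec = p.three_clade_spec()          # archaeal clade 151 bp, bacterial 169/194 bp
profile = p.normalize_profile({"Methanobrevibacter": 1/3,
                               "Anaerolineae G-1": 1/3,
                               "Streptococcus": 1/3})
res = p.run_end_to_end(spec, profile, p.DegradationParams(0.0149),
                       n_templates=100_000, n_reads=10_000, pair=v3, seed=1)
print(res.comparison.table.round(4))
print("analytic prediction:", res.analytic.table["f_prime"].round(4).to_dict())
```

prints

```
                    freq_amplicon  freq_shotgun  log2_fold_change
taxon
Anaerolineae G-1           0.3336        0.3383           -0.0201
Methanobrevibacter         0.4363        0.3321            0.3937
Streptococcus              0.2301        0.3296           -0.5186
analytic prediction: {'Methanobrevibacter': 0.4364, 'Anaerolineae G-1': 0.3337, 'Streptococcus': 0.2299}
```

The shotgun arm recovers the true composition (~1/3 each); the amplicon arm
enriches the shortest-target archaeal clade to 44% and depletes the
longest-target clade to 23%, in quantitative agreement with the analytic
reweighting — taxonomic skew from fragment-length arithmetic alone.

## Analysis scripts

Numbered drivers under `analysis/` run the full study at desk scale and
write TSV tables under `results/`:

- `01_evaluate_primers.py` — V3/V4 primer metrics on a ten-genus synthetic
  database (per-genus length medians 151–194 bp, archaeal clade shortest;
  coverage 100% except a planted final-base-mismatch clade at 0%).
- `02_thermal_age_predictions.py` — predicted community profiles at the
  seven packaged per-site λ values, amplifiable-fraction tables (e.g. at
  λ = 0.0149 only 7–14% of ≥25 bp fragments span the V3 bracket), and an
  archaeal sensitivity variant.
- `03_amplicon_vs_shotgun.py` — end-to-end simulations across λ with
  log2 fold-change tables and a multi-seed bias-direction check.

A `paleo16s` CLI wraps the same stages (`evaluate-primers`, `predict-bias`,
`simulate`, `compare`); every run writes a `run_info.json` provenance
record.

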