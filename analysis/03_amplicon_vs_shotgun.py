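#!/usr/bin/env python
"""Simulated amplicon-vs-shotgun comparison of a degraded community.

Runs the end-to-end simulator (community sampling, random scission at the
per-site lambdas, exhaustive-PCR amplicon arm, uniform shotgun arm) on the
canonical three-clade database (planted V3 lengths 151/169/194 bp) and
summarizes the taxonomic skew: per-taxon log2 fold changes, the archaeal
fraction of each profile, and a multi-seed sign check of the bias direction.
"""

from pathlib import Path

import pandas as pd

import paleo16s as p
from paleo16s.datasets import load_primer_pairs
from paleo16s.synthetic import three_clade_spec

RESULTS = Path(__file__).resolve().parents[1] / "results"

LAMBDAS = [0.0, 0.0006, 0.0045, 0.0149, 0.0701]
N_TEMPLATES = 300_000
N_READS = 20_000


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    v3 = load_primer_pairs()["U341F/534R"]
    spec = three_clade_spec()
    profile = p.normalize_profile(
        {"Methanobrevibacter": 1 / 3, "Anaerolineae G-1": 1 / 3, "Streptococcus": 1 / 3}
    )
    db = p.generate_reference_db(spec, v3)
    lineages = {rec.lineage.genus: rec.lineage for rec in db}

    rows = []
    for lam in LAMBDAS:
        res = p.run_end_to_end(
            spec, profile, p.DegradationParams(lam), N_TEMPLATES, N_READS, v3, seed=2015
        )
        t = res.comparison.table
        amp_prof = dict(t["freq_amplicon"])
        shot_prof = dict(t["freq_shotgun"])
        arch_amp = sum(f for g, f in amp_prof.items() if lineages[g].domain == "Archaea")
        arch_shot = sum(f for g, f in shot_prof.items() if lineages[g].domain == "Archaea")
        for taxon in t.index:
            rows.append({
                "lam": lam, "taxon": taxon,
                "x_bp": res.amplicon_lengths[taxon],
                "freq_amplicon": t.loc[taxon, "freq_amplicon"],
                "freq_shotgun": t.loc[taxon, "freq_shotgun"],
                "log2_fold_change": t.loc[taxon, "log2_fold_change"],
                "analytic_f_prime": res.analytic.frequency(taxon),
            })
        n_amp = sum(res.output.amplicon_counts.values())
        print(f"lam={lam:<7} amplicons={n_amp:>7}  archaeal fraction: "
              f"amplicon {arch_amp:.3f} vs shotgun {arch_shot:.3f}")
    frame = pd.DataFrame(rows)
    frame.to_csv(RESULTS / "amplicon_vs_shotgun.tsv", sep="\t",
                 float_format="%.6g", index=False)

    # bias direction across seeds at a moderate lambda
    wins = 0
    n_seeds = 20
    for seed in range(n_seeds):
        res = p.run_end_to_end(
            spec, profile, p.DegradationParams(0.0149), 100_000, 10_000, v3, seed=seed
        )
        t = res.comparison.table
        wins += bool(
            t.loc["Methanobrevibacter", "log2_fold_change"] > 0
            and t.loc["Streptococcus", "log2_fold_change"] < 0
        )
    print(f"bias direction at lam=0.0149: shortest clade enriched and longest "
          f"depleted in {wins}/{n_seeds} seeds")

    # archaeal amplicon excess grows with lambda (rank correlation over the series)
    arch_series = (
        frame[frame["taxon"] == "Methanobrevibacter"]
        .sort_values("lam")[["lam", "log2_fold_change"]]
    )
    usable = arch_series[arch_series["lam"] > 0]
    rho = p.rank_correlation(usable["lam"], usable["log2_fold_change"])
    print(f"Spearman rho (lambda vs archaeal log2 fold change) = {rho:.2f}")


if __name__ == "__main__":
    main()
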