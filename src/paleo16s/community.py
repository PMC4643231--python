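"""Community-profile classification and amplicon-vs-shotgun comparison.

Three small summaries the bias analysis keeps reaching for: the fraction of
a genus-level profile that belongs to known oral taxa (membership against an
oral-microbiome genus list), the summed archaeal fraction (the quantity that
balloons in degraded amplicon profiles), and per-taxon log2 fold changes
between a targeted-amplicon profile and a shotgun profile of the same
sample. Fold changes use a symmetric pseudo-frequency so that amplification
dropout (a zero on one side) stays finite — dropout is the phenomenon under
study, not an error condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference_io import CommunityProfile, TaxonomyLineage

__all__ = [
    "OralMembershipList",
    "OralClassification",
    "ComparisonTable",
    "classify_oral",
    "archaeal_fraction",
    "compare_amplicon_shotgun",
    "rank_correlation",
]


def _canon(label: str) -> str:
    return " ".join(label.split()).casefold()


class OralMembershipList:
    """Set of genus labels designated oral (exact match after case/space folding)."""

    def __init__(self, genera: Sequence[str]):
        canon = [_canon(g) for g in genera if g and g.strip()]
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate genus labels in membership list")
        self._members = frozenset(canon)
        self.genera = tuple(g.strip() for g in genera if g and g.strip())

    def __contains__(self, genus: str) -> bool:
        return _canon(genus) in self._members

    def __len__(self) -> int:
        return len(self._members)

    @classmethod
    def from_file(cls, path) -> "OralMembershipList":
        with open(path) as fh:
            genera = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
        return cls(genera)


@dataclass(frozen=True)
class OralClassification:
    oral_fraction: float
    other_fraction: float
    flags: dict[str, bool]  # genus -> is oral


def classify_oral(
    profile: CommunityProfile, membership: OralMembershipList
) -> OralClassification:
    """Split a genus-level profile into oral vs other summed frequency.

    Genera absent from the membership list are 'Other' by definition; the two
    fractions always sum to 1.
    """
    flags = {genus: genus in membership for genus in profile}
    oral = sum(profile[g] for g, is_oral in flags.items() if is_oral)
    return OralClassification(
        oral_fraction=oral, other_fraction=1.0 - oral, flags=flags
    )


def archaeal_fraction(
    profile: CommunityProfile,
    lineages: Mapping[str, TaxonomyLineage],
    phylum: str | None = None,
) -> float:
    """Summed frequency of archaeal taxa (optionally one archaeal phylum)."""
    total = 0.0
    for taxon in profile:
        lin = lineages.get(taxon)
        if lin is None or lin.domain != "Archaea":
            continue
        if phylum is not None and lin.phylum != phylum:
            continue
        total += profile[taxon]
    return total


@dataclass(frozen=True)
class ComparisonTable:
    """Per-taxon amplicon-vs-shotgun frequencies and log2 fold changes."""

    table: pd.DataFrame  # index: taxon; columns: freq_amplicon, freq_shotgun, log2_fold_change
    epsilon: float

    def lfc(self, taxon: str) -> float:
        return float(self.table.loc[taxon, "log2_fold_change"])


def compare_amplicon_shotgun(
    p_amp: CommunityProfile | Mapping[str, float],
    p_shot: CommunityProfile | Mapping[str, float],
    epsilon: float = 1e-6,
) -> ComparisonTable:
    """log2((f_amp + eps) / (f_shot + eps)) over the union of taxa.

    Log base 2 throughout; the pseudo-frequency ``epsilon`` is applied
    symmetrically to both profiles.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    fa = dict(p_amp.items() if hasattr(p_amp, "items") else p_amp)
    fs = dict(p_shot.items() if hasattr(p_shot, "items") else p_shot)
    taxa = sorted(set(fa) | set(fs))
    a = np.array([fa.get(t, 0.0) for t in taxa])
    s = np.array([fs.get(t, 0.0) for t in taxa])
    lfc = np.log2((a + epsilon) / (s + epsilon))
    table = pd.DataFrame(
        {"freq_amplicon": a, "freq_shotgun": s, "log2_fold_change": lfc},
        index=pd.Index(taxa, name="taxon"),
    )
    return ComparisonTable(table=table, epsilon=epsilon)


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties); rho only."""
    x_arr, y_arr = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape:
        raise ValueError(f"length mismatch: {x_arr.shape} vs {y_arr.shape}")
    if x_arr.size < 3:
        raise ValueError("need at least 3 paired observations")
    rho = stats.spearmanr(x_arr, y_arr).statistic
    return float(rho)
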