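"""Packaged literature-derived reference tables.

Three small TSVs ship with the package: per-site chain-scission
probabilities (lambda) for seven archaeological dental-calculus sites,
V3 amplicon lengths and HOMD rank abundances for oral taxa of interest, and
default universal primer pairs with their E. coli anchor coordinates. All
are plain TSV and user-replaceable via the corresponding CLI options.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .degradation import DegradationParams
from .insilico_pcr import Primer, PrimerPair

__all__ = [
    "load_site_lambdas",
    "load_oral_taxa",
    "load_primer_pairs",
    "default_primer_pair",
]


def _data_path(name: str):
    return resources.files("paleo16s.data").joinpath(name)


def load_site_lambdas(as_params: bool = False) -> pd.DataFrame | list[DegradationParams]:
    """Per-site lambda values, ordered by increasing thermal age."""
    with resources.as_file(_data_path("site_lambda.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    if as_params:
        return [DegradationParams(lam=row.lam, label=row.site) for row in df.itertuples()]
    return df


def load_oral_taxa() -> pd.DataFrame:
    """V3 amplicon lengths and HOMD rank abundances for oral taxa of interest."""
    with resources.as_file(_data_path("oral_taxa_v3.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_primer_pairs(path=None) -> dict[str, PrimerPair]:
    """Primer pairs keyed by name (packaged defaults, or a user TSV)."""
    if path is None:
        with resources.as_file(_data_path("primer_pairs.tsv")) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    pairs = {}
    for row in df.itertuples():
        pairs[row.name] = PrimerPair(
            name=row.name,
            forward=Primer(row.forward_name, row.forward_seq, "forward"),
            reverse=Primer(row.reverse_name, row.reverse_seq, "reverse"),
            ecoli_start=int(row.ecoli_start),
            ecoli_stop=int(row.ecoli_stop),
        )
    return pairs


def default_primer_pair(region: str = "V3") -> PrimerPair:
    """The packaged default pair for a region ("V3" or "V4")."""
    with resources.as_file(_data_path("primer_pairs.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    sub = df[df["region"] == region]
    if sub.empty:
        raise KeyError(f"no packaged primer pair for region {region!r}")
    return load_primer_pairs()[sub["name"].iloc[0]]
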