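"""Reference 16S databases, taxonomy lineages, and taxon frequency tables.

The data model is deliberately small: a :class:`ReferenceRecord` is one 16S
sequence plus its ranked lineage, a :class:`ReferenceDatabase` is an indexed
collection of records, and a :class:`CommunityProfile` maps taxon labels to
relative frequencies. Sequences are normalized on read (uppercase, RNA ``U``
mapped to ``T``); IUPAC ambiguity codes are preserved because the primer
matcher consumes them.

Taxonomy strings are accepted in two dialects and auto-detected per file:

* plain semicolon-delimited ranks (SILVA style):
  ``Bacteria;Firmicutes;Bacilli;...``
* rank-prefixed (Greengenes style):
  ``k__Bacteria; p__Firmicutes; c__Bacilli; ...``

Both parse to the same :class:`TaxonomyLineage`; unassigned ranks use the
single canonical marker :data:`UNASSIGNED` so grouping is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "RANKS",
    "UNASSIGNED",
    "TaxonomyLineage",
    "ReferenceRecord",
    "ReferenceDatabase",
    "CommunityProfile",
    "FrequencyTable",
    "read_reference_fasta",
    "write_reference_fasta",
    "normalize_profile",
    "read_frequency_table",
    "write_report",
]

#: Rank order, fixed. Any suffix may be unassigned.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Canonical marker for an unassigned rank.
UNASSIGNED = "unassigned"

_GG_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

#: IUPAC nucleotide codes accepted in normalized sequences.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

_PROFILE_TOL = 1e-9


@dataclass(frozen=True)
class TaxonomyLineage:
    """Ranked lineage from domain through species.

    Ranks are stored in the fixed order of :data:`RANKS`; unassigned ranks
    hold :data:`UNASSIGNED`.
    """

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ValueError(
                f"lineage must have {len(RANKS)} ranks, got {len(self.ranks)}"
            )
        for label in self.ranks:
            if not label:
                raise ValueError(
                    "rank labels must be non-empty; use the "
                    f"{UNASSIGNED!r} marker for unassigned ranks"
                )

    @classmethod
    def from_labels(cls, *labels: str) -> "TaxonomyLineage":
        """Build a lineage from up to seven rank labels; the rest are unassigned."""
        if len(labels) > len(RANKS):
            raise ValueError(f"at most {len(RANKS)} ranks, got {len(labels)}")
        filled = [lab.strip() if lab and lab.strip() else UNASSIGNED for lab in labels]
        filled += [UNASSIGNED] * (len(RANKS) - len(filled))
        return cls(tuple(filled))

    @classmethod
    def from_string(cls, lineage: str) -> "TaxonomyLineage":
        """Parse either taxonomy dialect (auto-detected on ``__`` prefixes)."""
        parts = [p.strip() for p in lineage.strip().rstrip(";").split(";")]
        if any(p[:3] in _GG_PREFIXES for p in parts if len(p) >= 3):
            labels = []
            for p in parts:
                if len(p) >= 3 and p[:3] in _GG_PREFIXES:
                    p = p[3:]
                labels.append(p.strip())
        else:
            labels = parts
        return cls.from_labels(*labels)

    def get(self, rank: str) -> str:
        try:
            return self.ranks[RANKS.index(rank)]
        except ValueError:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}") from None

    @property
    def domain(self) -> str:
        return self.ranks[0]

    @property
    def phylum(self) -> str:
        return self.ranks[1]

    @property
    def genus(self) -> str:
        return self.ranks[5]

    def to_string(self, dialect: str = "plain") -> str:
        if dialect == "plain":
            return ";".join(self.ranks)
        if dialect == "greengenes":
            return ";".join(
                f"{pre}{'' if lab == UNASSIGNED else lab}"
                for pre, lab in zip(_GG_PREFIXES, self.ranks)
            )
        raise ValueError(f"unknown dialect {dialect!r}")


def _normalize_sequence(seq: str, record_id: str) -> str:
    out = seq.upper().replace("U", "T")
    bad = set(out) - IUPAC_CODES
    if bad:
        raise ValueError(
            f"record {record_id!r}: non-IUPAC characters {sorted(bad)} in sequence"
        )
    return out


@dataclass(frozen=True)
class ReferenceRecord:
    """One 16S reference sequence with its lineage."""

    record_id: str
    lineage: TaxonomyLineage
    sequence: str

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.record_id!r}: empty sequence")
        object.__setattr__(
            self, "sequence", _normalize_sequence(self.sequence, self.record_id)
        )

    def __len__(self) -> int:
        return len(self.sequence)


class ReferenceDatabase:
    """Indexed collection of :class:`ReferenceRecord`."""

    def __init__(self, records: Iterable[ReferenceRecord]):
        self._records: list[ReferenceRecord] = list(records)
        self._by_id: dict[str, ReferenceRecord] = {}
        for rec in self._records:
            if rec.record_id in self._by_id:
                raise ValueError(f"duplicate record_id {rec.record_id!r}")
            self._by_id[rec.record_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self._records)

    def __getitem__(self, record_id: str) -> ReferenceRecord:
        return self._by_id[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    @property
    def records(self) -> list[ReferenceRecord]:
        return list(self._records)

    def group_by_rank(self, rank: str) -> dict[str, list[ReferenceRecord]]:
        """Records grouped by their label at ``rank`` (insertion order kept)."""
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        groups: dict[str, list[ReferenceRecord]] = {}
        for rec in self._records:
            groups.setdefault(rec.lineage.get(rank), []).append(rec)
        return groups


def read_reference_fasta(path: str | Path, taxonomy_path: str | Path) -> ReferenceDatabase:
    """Read a FASTA reference plus a two-column taxonomy TSV.

    The taxonomy file maps ``record_id <tab> lineage string`` (either
    dialect). Every FASTA id must appear in the taxonomy table.
    """
    path, taxonomy_path = Path(path), Path(taxonomy_path)
    taxonomy: dict[str, TaxonomyLineage] = {}
    with open(taxonomy_path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                rec_id, lineage_str = line.split("\t", 1)
            except ValueError:
                raise ValueError(
                    f"{taxonomy_path}:{line_no}: expected 'id<tab>lineage'"
                ) from None
            taxonomy[rec_id.strip()] = TaxonomyLineage.from_string(lineage_str)
    if not taxonomy:
        raise ValueError(f"empty taxonomy file: {taxonomy_path}")

    records = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        if seq_rec.id not in taxonomy:
            raise KeyError(f"FASTA id {seq_rec.id!r} missing from taxonomy table")
        records.append(
            ReferenceRecord(seq_rec.id, taxonomy[seq_rec.id], str(seq_rec.seq))
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceDatabase(records)


def write_reference_fasta(
    db: ReferenceDatabase, path: str | Path, taxonomy_path: str | Path
) -> None:
    """Inverse of :func:`read_reference_fasta` (exact round trip)."""
    SeqIO.write(
        (SeqRecord(Seq(rec.sequence), id=rec.record_id, description="") for rec in db),
        str(path),
        "fasta",
    )
    with open(taxonomy_path, "w") as fh:
        for rec in db:
            fh.write(f"{rec.record_id}\t{rec.lineage.to_string()}\n")


class CommunityProfile:
    """Taxon label -> relative frequency, summing to 1."""

    def __init__(self, frequencies: Mapping[str, float]):
        freqs = dict(frequencies)
        if not freqs:
            raise ValueError("empty profile")
        for taxon, f in freqs.items():
            if f < 0 or not math.isfinite(f):
                raise ValueError(f"taxon {taxon!r}: invalid frequency {f}")
        total = sum(freqs.values())
        if abs(total - 1.0) > _PROFILE_TOL:
            raise ValueError(
                f"frequencies must sum to 1 (got {total}); use normalize_profile()"
            )
        self._freqs = freqs

    def __getitem__(self, taxon: str) -> float:
        return self._freqs[taxon]

    def __iter__(self) -> Iterator[str]:
        return iter(self._freqs)

    def __len__(self) -> int:
        return len(self._freqs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CommunityProfile) and self._freqs == other._freqs

    def items(self):
        return self._freqs.items()

    @property
    def taxa(self) -> list[str]:
        return list(self._freqs)

    def as_dict(self) -> dict[str, float]:
        return dict(self._freqs)

    def to_series(self) -> pd.Series:
        return pd.Series(self._freqs, name="frequency")


def normalize_profile(raw: Mapping[str, float]) -> CommunityProfile:
    """Normalize non-negative weights to frequencies; zeros are retained."""
    if not raw:
        raise ValueError("empty profile")
    for taxon, w in raw.items():
        if w < 0 or not math.isfinite(w):
            raise ValueError(f"taxon {taxon!r}: invalid weight {w}")
    total = float(sum(raw.values()))
    if total <= 0:
        raise ValueError("all weights are zero; cannot normalize")
    return CommunityProfile({t: float(w) / total for t, w in raw.items()})


@dataclass
class FrequencyTable:
    """Samples x taxa matrix of counts or frequencies (rows are samples)."""

    data: pd.DataFrame
    mode: str = "counts"  # "counts" | "frequencies"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "frequencies"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("negative entries in frequency table")

    def row_normalize(self) -> "FrequencyTable":
        sums = self.data.sum(axis=1)
        if (sums <= 0).any():
            bad = list(sums.index[sums <= 0])
            raise ValueError(f"all-zero rows cannot be normalized: {bad}")
        return FrequencyTable(self.data.div(sums, axis=0), mode="frequencies")

    def profile(self, sample: str) -> CommunityProfile:
        return normalize_profile(self.data.loc[sample].to_dict())


def write_report(table: FrequencyTable | pd.DataFrame, path: str | Path) -> None:
    """Write a TSV report with a header row and >= 6 significant digits."""
    df = table.data if isinstance(table, FrequencyTable) else table
    df.to_csv(path, sep="\t", float_format="%.10g", index_label=df.index.name or "sample")


def read_frequency_table(path: str | Path, mode: str = "frequencies") -> FrequencyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return FrequencyTable(df, mode=mode)
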