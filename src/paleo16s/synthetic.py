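"""Synthetic 16S databases and a forward simulator of degraded sequencing.

The generator builds a clade-structured reference database in which every
record carries an exact forward primer site and an exact reverse-complement
site planted so that the primer-inclusive amplicon length equals the clade's
chosen value — emulating the real situation where hypervariable-region
stem-loops differ in length across clades (archaeal clades shortest) while
the primer-binding flanks are conserved. Optional planted primer-site
defects (a final-3'-base mismatch, or k non-3' mismatches) make coverage
failures constructible.

The forward simulator then models an ancient-sample sequencing experiment:

1. multinomial sampling of intact template molecules from a community
   profile (one 16S copy per organism);
2. random per-bond chain scission at probability ``lam`` (every internal
   bond breaks independently; fragments are maximal unbroken runs; fragments
   shorter than ``min_len`` are discarded, mirroring standard read-length
   filtering);
3. a targeted arm: a fragment yields one amplicon iff it fully contains the
   record's primer-inclusive amplicon interval (PCR modelled as exhaustive —
   the bias mechanism under study is template availability, not polymerase
   kinetics);
4. a non-targeted arm: shotgun reads drawn uniformly over surviving
   fragments, with replacement.

Fragmentation walks breaks with geometric gap sampling in a numba kernel,
which keeps multi-million-template runs tractable; recording fragments and
counting them consume the identical random stream, so the staged and the
counts-only paths agree exactly at matched seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .community import ComparisonTable, compare_amplicon_shotgun
from .degradation import BiasPrediction, DegradationParams, predict_observed_profile
from .insilico_pcr import PrimerPair, extract_amplicon, reverse_complement
from .reference_io import (
    CommunityProfile,
    ReferenceDatabase,
    ReferenceRecord,
    TaxonomyLineage,
    normalize_profile,
)

__all__ = [
    "CladeSpec",
    "SyntheticDbSpec",
    "TemplatePool",
    "FragmentSet",
    "SequencingOutput",
    "EndToEndResult",
    "generate_reference_db",
    "three_clade_spec",
    "clade_amplicon_intervals",
    "sample_community",
    "fragment_templates",
    "amplify_fragments",
    "shotgun_sample",
    "run_end_to_end",
]

_BASES = "ACGT"
_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class CladeSpec:
    """One synthetic clade: lineage through genus, OTU count, planted length.

    ``divergence`` is the per-base substitution probability applied inside
    the variable loop (never inside primer sites). ``primer_site_defect``
    plants mismatches into the forward site of every record:
    ``"none"``, ``"last_base_mismatch"``, or ``"non3prime_mismatches"``
    (with ``defect_mismatches`` bases mutated outside the 3' window).
    """

    lineage: TaxonomyLineage
    n_otus: int
    amplicon_length: int
    divergence: float = 0.02
    primer_site_defect: str = "none"
    defect_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 1:
            raise ValueError("n_otus must be >= 1")
        if not 0 <= self.divergence <= 0.3:
            raise ValueError("divergence must be in [0, 0.3]")
        if self.primer_site_defect not in (
            "none",
            "last_base_mismatch",
            "non3prime_mismatches",
        ):
            raise ValueError(f"unknown defect {self.primer_site_defect!r}")
        if self.primer_site_defect == "non3prime_mismatches" and self.defect_mismatches < 1:
            raise ValueError("defect_mismatches must be >= 1 for non3prime_mismatches")

    @property
    def taxon(self) -> str:
        return self.lineage.genus


@dataclass(frozen=True)
class SyntheticDbSpec:
    """Whole-database recipe: clades, template geometry, and the seed.

    The default template length matches the full 16S rRNA gene
    (approximately 1540 bp); ``forward_site_start`` is the 0-based position
    where the forward primer site is planted (340 reproduces the E. coli
    V3 anchor at 1-based position 341).
    """

    clades: tuple[CladeSpec, ...]
    template_total_length: int = 1540
    forward_site_start: int = 340
    seed: int = 0

    def __post_init__(self) -> None:
        taxa = [c.taxon for c in self.clades]
        if len(set(taxa)) != len(taxa):
            raise ValueError("clade genera must be unique")
        if not self.clades:
            raise ValueError("need at least one clade")


def _concretize(iupac: str, rng: np.random.Generator) -> str:
    """Resolve IUPAC ambiguity codes to concrete bases (seeded, per database)."""
    return "".join(
        b if b in _BASES else _IUPAC_SETS[b][rng.integers(len(_IUPAC_SETS[b]))]
        for b in iupac
    )


def _mismatch_base(iupac: str) -> str:
    """First base (A<C<G<T) not matched by the IUPAC code; error if none exists."""
    allowed = _IUPAC_SETS[iupac]
    for b in _BASES:
        if b not in allowed:
            return b
    raise ValueError(f"cannot plant a mismatch against fully degenerate base {iupac!r}")


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0 or not seq:
        return seq
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        choices = [b for b in _BASES if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def generate_reference_db(spec: SyntheticDbSpec, pair: PrimerPair) -> ReferenceDatabase:
    """Build the synthetic reference database for a primer pair.

    Every record is ``left flank + forward site + variable loop + reverse
    site + conserved filler`` with flanks and filler shared across the
    database (conserved regions) and the loop clade-specific. Identical
    (spec, pair) inputs produce an identical database.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.template_total_length
    fs = spec.forward_site_start
    fwd_site = _concretize(pair.forward.sequence, rng)
    rev_site = reverse_complement(_concretize(pair.reverse.sequence, rng))
    len_f, len_r = len(fwd_site), len(rev_site)

    left_flank = _random_bases(rng, fs)
    filler = _random_bases(rng, L)

    records = []
    for clade in spec.clades:
        x = clade.amplicon_length
        loop_len = x - len_f - len_r
        if loop_len < 0:
            raise ValueError(
                f"clade {clade.taxon!r}: amplicon length {x} shorter than the "
                f"two primers ({len_f} + {len_r})"
            )
        if fs + x > L:
            raise ValueError(
                f"clade {clade.taxon!r}: planted amplicon end {fs + x} exceeds "
                f"template length {L}"
            )
        site = fwd_site
        if clade.primer_site_defect == "last_base_mismatch":
            site = site[:-1] + _mismatch_base(pair.forward.sequence[-1])
        elif clade.primer_site_defect == "non3prime_mismatches":
            k = clade.defect_mismatches
            if k > len_f - 5:
                raise ValueError(
                    f"clade {clade.taxon!r}: {k} non-3' mismatches exceed the "
                    f"{len_f - 5} non-3' positions"
                )
            site = (
                "".join(_mismatch_base(pair.forward.sequence[i]) for i in range(k))
                + site[k:]
            )
        clade_loop = _random_bases(rng, loop_len)
        for i in range(clade.n_otus):
            loop = _mutate(clade_loop, clade.divergence, rng)
            seq = left_flank + site + loop + rev_site + filler[fs + x :]
            ranks = list(clade.lineage.ranks)
            ranks[6] = f"{clade.taxon} sp{i + 1:03d}"
            records.append(
                ReferenceRecord(
                    # FASTA ids must be whitespace-free
                    record_id=f"{clade.taxon.replace(' ', '-')}_{i + 1:03d}",
                    lineage=TaxonomyLineage(tuple(ranks)),
                    sequence=seq,
                )
            )
    return ReferenceDatabase(records)


def three_clade_spec(
    lengths: tuple[int, int, int] = (151, 169, 194),
    n_otus: int = 2,
    template_total_length: int = 1540,
    forward_site_start: int = 340,
    divergence: float = 0.0,
    seed: int = 0,
) -> SyntheticDbSpec:
    """Canonical three-clade database spanning the V3 length range.

    An archaeal clade carries the shortest planted amplicon (the
    *Methanobrevibacter* situation), a Chloroflexi-like clade the
    intermediate one, and a Firmicutes-like clade the longest.
    """
    short, mid, long_ = sorted(lengths)
    clades = (
        CladeSpec(
            TaxonomyLineage.from_labels(
                "Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales",
                "Methanobacteriaceae", "Methanobrevibacter",
            ),
            n_otus=n_otus, amplicon_length=short, divergence=divergence,
        ),
        CladeSpec(
            TaxonomyLineage.from_labels(
                "Bacteria", "Chloroflexi", "Anaerolineae", "Anaerolineales",
                "Anaerolineaceae", "Anaerolineae G-1",
            ),
            n_otus=n_otus, amplicon_length=mid, divergence=divergence,
        ),
        CladeSpec(
            TaxonomyLineage.from_labels(
                "Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
                "Streptococcaceae", "Streptococcus",
            ),
            n_otus=n_otus, amplicon_length=long_, divergence=divergence,
        ),
    )
    return SyntheticDbSpec(
        clades=clades,
        template_total_length=template_total_length,
        forward_site_start=forward_site_start,
        seed=seed,
    )


def clade_amplicon_intervals(
    db: ReferenceDatabase, pair: PrimerPair, max_len: int = 500
) -> dict[str, tuple[int, int] | None]:
    """Per-genus primer-inclusive amplicon interval (from the first record).

    Genera whose representative record yields no amplicon map to ``None``.
    """
    intervals: dict[str, tuple[int, int] | None] = {}
    for genus, records in db.group_by_rank("genus").items():
        amp = extract_amplicon(pair, records[0], max_len=max_len)
        intervals[genus] = None if amp is None else (amp.amp_start, amp.amp_end)
    return intervals


@dataclass(frozen=True)
class TemplatePool:
    """Intact template copies per taxon (one 16S copy per organism)."""

    taxa: tuple[str, ...]
    counts: np.ndarray  # int64, per taxon
    template_length: int

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("negative template counts")
        if self.counts.sum() <= 0:
            raise ValueError("empty template pool")

    @property
    def n_templates(self) -> int:
        return int(self.counts.sum())


def sample_community(
    profile: CommunityProfile,
    n_templates: int,
    seed: int,
    template_length: int = 1540,
) -> TemplatePool:
    """Multinomial draw of intact template copies across taxa."""
    if n_templates < 1:
        raise ValueError("n_templates must be >= 1")
    taxa = tuple(profile.taxa)
    p = np.array([profile[t] for t in taxa], dtype=float)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_templates, p / p.sum())
    return TemplatePool(taxa=taxa, counts=counts.astype(np.int64), template_length=template_length)


@njit(cache=True)
def _fragment_kernel(
    n_copies: int,
    L: int,
    lam: float,
    min_len: int,
    amp_start: int,
    amp_end: int,
    seed: int,
    record: bool,
    starts: np.ndarray,
    ends: np.ndarray,
):  # pragma: no cover - exercised via wrappers
    """Per-copy Bernoulli(lam) scission via geometric gap walking.

    Returns (n_amplified, n_kept): copies whose fragment contains
    [amp_start, amp_end), and fragments of length >= min_len. When
    ``record`` is set, kept fragments are written to ``starts``/``ends``
    (only up to their capacity; n_kept keeps counting regardless, so a
    caller can re-run with larger buffers on the same seed). The random
    stream does not depend on ``record``.
    """
    np.random.seed(seed)
    log1m = np.log(1.0 - lam) if lam > 0.0 else 0.0
    cap = starts.shape[0]
    n_amp = 0
    n_kept = 0
    check_amp = amp_start >= 0
    for _c in range(n_copies):
        prev = 0
        while True:
            if lam > 0.0:
                u = np.random.random()
                gap = int(np.log(u) / log1m) + 1
                brk = prev + gap
                if brk > L:
                    brk = L
            else:
                brk = L
            if check_amp and prev <= amp_start and brk >= amp_end:
                n_amp += 1
            if brk - prev >= min_len:
                if record and n_kept < cap:
                    starts[n_kept] = prev
                    ends[n_kept] = brk
                n_kept += 1
            if brk == L:
                break
            prev = brk
    return n_amp, n_kept


def _per_taxon_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n)


def _expected_fragments(n_copies: int, L: int, lam: float) -> int:
    mean = n_copies * ((L - 1) * lam + 1.0)
    return int(mean + 6.0 * np.sqrt(mean + 1.0) + 16)


@dataclass(frozen=True)
class FragmentSet:
    """Surviving fragments as intervals on their source templates."""

    taxa: tuple[str, ...]
    taxon_idx: np.ndarray  # int32 per fragment
    start: np.ndarray  # int32 per fragment, 0-based on the template
    end: np.ndarray  # int32 per fragment, half-open
    template_length: int
    min_len: int

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def __len__(self) -> int:
        return len(self.start)

    def counts_per_taxon(self) -> dict[str, int]:
        counts = np.bincount(self.taxon_idx, minlength=len(self.taxa))
        return {t: int(c) for t, c in zip(self.taxa, counts)}


def fragment_templates(
    pool: TemplatePool,
    params: DegradationParams,
    min_len: int = 25,
    seed: int = 0,
) -> FragmentSet:
    """Break every template copy at per-bond probability ``lam``.

    Fragments are maximal unbroken runs; fragments shorter than ``min_len``
    are discarded. Identical (pool, params, seed) inputs give bit-identical
    output.
    """
    L = pool.template_length
    seeds = _per_taxon_seeds(seed, len(pool.taxa))
    all_t, all_s, all_e = [], [], []
    for i, taxon in enumerate(pool.taxa):
        n_copies = int(pool.counts[i])
        if n_copies == 0:
            continue
        cap = _expected_fragments(n_copies, L, params.lam)
        while True:
            starts = np.empty(cap, dtype=np.int32)
            ends = np.empty(cap, dtype=np.int32)
            _, n_kept = _fragment_kernel(
                n_copies, L, params.lam, min_len, -1, -1, int(seeds[i]), True, starts, ends
            )
            if n_kept <= cap:
                break
            cap = n_kept  # deterministic re-run with exact capacity
        all_t.append(np.full(n_kept, i, dtype=np.int32))
        all_s.append(starts[:n_kept].copy())
        all_e.append(ends[:n_kept].copy())
    return FragmentSet(
        taxa=pool.taxa,
        taxon_idx=np.concatenate(all_t) if all_t else np.empty(0, np.int32),
        start=np.concatenate(all_s) if all_s else np.empty(0, np.int32),
        end=np.concatenate(all_e) if all_e else np.empty(0, np.int32),
        template_length=L,
        min_len=min_len,
    )


def _simulate_counts(
    pool: TemplatePool,
    intervals: Mapping[str, tuple[int, int] | None],
    params: DegradationParams,
    min_len: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts-only fragmentation: (amplicon counts, kept-fragment counts).

    Shares the kernel and per-taxon seed derivation with
    :func:`fragment_templates`, so the tallies equal what the staged
    fragment/amplify path produces at the same seed.
    """
    L = pool.template_length
    seeds = _per_taxon_seeds(seed, len(pool.taxa))
    empty = np.empty(0, dtype=np.int32)
    amp = np.zeros(len(pool.taxa), dtype=np.int64)
    kept = np.zeros(len(pool.taxa), dtype=np.int64)
    for i, taxon in enumerate(pool.taxa):
        n_copies = int(pool.counts[i])
        if n_copies == 0:
            continue
        interval = intervals.get(taxon)
        a0, a1 = interval if interval is not None else (-1, -1)
        n_amp, n_kept = _fragment_kernel(
            n_copies, L, params.lam, min_len, a0, a1, int(seeds[i]), False, empty, empty
        )
        amp[i], kept[i] = n_amp, n_kept
    return amp, kept


def amplify_fragments(
    frags: FragmentSet,
    pair: PrimerPair,
    db: ReferenceDatabase,
    max_len: int = 500,
) -> dict[str, int]:
    """Amplicon counts per taxon: fragments fully containing the amplicon site.

    A fragment contributes one amplicon iff its interval contains the source
    record's primer-inclusive amplicon interval. Taxa without a predicted
    amplicon (primer-site defects) are counted as zero, with a warning.
    """
    intervals = clade_amplicon_intervals(db, pair, max_len=max_len)
    counts: dict[str, int] = {}
    for i, taxon in enumerate(frags.taxa):
        interval = intervals.get(taxon)
        if interval is None:
            warnings.warn(
                f"taxon {taxon!r} has no predicted amplicon; counting 0", stacklevel=2
            )
            counts[taxon] = 0
            continue
        a0, a1 = interval
        sel = frags.taxon_idx == i
        counts[taxon] = int(((frags.start[sel] <= a0) & (frags.end[sel] >= a1)).sum())
    return counts


def shotgun_sample(
    frags: FragmentSet | Mapping[str, int], n_reads: int, seed: int = 0
) -> dict[str, int]:
    """Shotgun read counts per taxon: reads drawn uniformly over fragments.

    One read per drawn fragment, with replacement; uniform sampling over
    fragments induces a multinomial over taxa weighted by their fragment
    counts, which is how the draw is realized.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if isinstance(frags, FragmentSet):
        per_taxon = frags.counts_per_taxon()
    else:
        per_taxon = dict(frags)
    taxa = list(per_taxon)
    weights = np.array([per_taxon[t] for t in taxa], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no fragments to sample shotgun reads from")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, weights / total)
    return {t: int(c) for t, c in zip(taxa, counts)}


@dataclass(frozen=True)
class SequencingOutput:
    """Paired targeted/non-targeted count tables from one simulated run."""

    amplicon_counts: dict[str, int]
    shotgun_counts: dict[str, int]
    lam: float
    n_templates: int
    n_reads: int
    seed: int
    min_len: int


@dataclass(frozen=True)
class EndToEndResult:
    db: ReferenceDatabase = field(repr=False)
    output: SequencingOutput
    comparison: ComparisonTable
    analytic: BiasPrediction
    amplicon_lengths: dict[str, int]


def run_end_to_end(
    spec: SyntheticDbSpec,
    profile: CommunityProfile,
    params: DegradationParams,
    n_templates: int,
    n_reads: int,
    pair: PrimerPair,
    seed: int = 0,
    min_len: int = 25,
) -> EndToEndResult:
    """generate -> sample -> fragment -> {amplify, shotgun} -> compare.

    Also returns the analytic degradation-bias prediction at the same lambda
    (over the taxa that have a predicted amplicon, renormalized) for
    cross-checking the simulator against the closed-form model.
    """
    db = generate_reference_db(spec, pair)
    intervals = clade_amplicon_intervals(db, pair)
    unknown = set(profile.taxa) - set(intervals)
    if unknown:
        raise KeyError(f"profile taxa missing from the database: {sorted(unknown)}")

    s_sample, s_frag, s_shot = (int(s) for s in np.random.SeedSequence(seed).generate_state(3))
    pool = sample_community(
        profile, n_templates, seed=s_sample, template_length=spec.template_total_length
    )
    amp_counts, kept_counts = _simulate_counts(pool, intervals, params, min_len, s_frag)
    amplicon_counts = {t: int(c) for t, c in zip(pool.taxa, amp_counts)}
    shotgun_counts = shotgun_sample(
        {t: int(c) for t, c in zip(pool.taxa, kept_counts)}, n_reads, seed=s_shot
    )

    amp_total = sum(amplicon_counts.values())
    if amp_total > 0:
        amp_freq = {t: c / amp_total for t, c in amplicon_counts.items()}
    else:
        amp_freq = {t: 0.0 for t in amplicon_counts}
    shot_total = sum(shotgun_counts.values())
    shot_freq = {t: c / shot_total for t, c in shotgun_counts.items()}
    comparison = compare_amplicon_shotgun(amp_freq, shot_freq)

    lengths = {t: iv[1] - iv[0] for t, iv in intervals.items() if iv is not None}
    amplifiable = {t: profile[t] for t in profile.taxa if t in lengths}
    analytic = predict_observed_profile(
        normalize_profile(amplifiable) if amplifiable else profile, lengths, params
    )

    output = SequencingOutput(
        amplicon_counts=amplicon_counts,
        shotgun_counts=shotgun_counts,
        lam=params.lam,
        n_templates=n_templates,
        n_reads=n_reads,
        seed=seed,
        min_len=min_len,
    )
    return EndToEndResult(
        db=db,
        output=output,
        comparison=comparison,
        analytic=analytic,
        amplicon_lengths=lengths,
    )
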