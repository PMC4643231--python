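"""In-silico PCR: primer-binding scoring, amplicon extraction, primer metrics.

Primer binding is scored with a weighted-penalty scheme over gapped
alignments of the primer against a candidate window of the target:

===================================  =======
non-3' mismatch                      0.40
3' mismatch (last 5 bases, not final)  1.00
final-base mismatch                  3.00
non-3' gap                           1.00
3' gap                               3.00
===================================  =======

An alignment *passes* when its total penalty is <= 1.00, so a single non-3'
gap, a non-final 3' mismatch, or two non-3' mismatches pass, while any
final-base mismatch fails on its own. Only alignments with at most one gap
are enumerated: two gaps (>= 2.00) or any 3' gap can never pass, so the cap
loses no passing site.

Degenerate (IUPAC) primer bases match a target base iff their base sets
intersect; a target ``N`` never matches (it would otherwise inflate
coverage).

Amplicon length is primer-inclusive: the amplicon spans the first base of
the forward binding site through the last base of the reverse site, which is
what a degraded template must fully contain for PCR to proceed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .reference_io import ReferenceDatabase, ReferenceRecord

__all__ = [
    "PENALTIES",
    "THREE_PRIME_LEN",
    "PASS_THRESHOLD",
    "Primer",
    "PrimerPair",
    "PrimerMatch",
    "AmpliconResult",
    "LengthSummary",
    "CoverageReport",
    "ResolutionReport",
    "score_primer_alignment",
    "find_best_site",
    "extract_amplicon",
    "amplicon_length_distribution",
    "length_ci",
    "taxonomic_coverage",
    "taxonomic_resolution",
    "reverse_complement",
]

#: Penalty weights, keyed by breakdown class.
PENALTIES = {
    "non3_mismatch": 0.40,
    "three_mismatch": 1.00,
    "last_mismatch": 3.00,
    "non3_gap": 1.00,
    "three_gap": 3.00,
}

#: Number of 3'-terminal primer bases in the high-penalty window.
THREE_PRIME_LEN = 5

#: Maximum total penalty for a site to pass.
PASS_THRESHOLD = 1.00

_EPS = 1e-9

# IUPAC nucleotide codes as bitmasks over {A, C, G, T}.
_IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7,
    "N": 15,
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _primer_masks(seq: str) -> np.ndarray:
    try:
        return np.array([_IUPAC_BITS[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-IUPAC base {exc.args[0]!r} in primer {seq!r}") from None


def _target_masks(seq: str) -> np.ndarray:
    # Target N never matches: mask 0 has empty intersection with everything.
    out = np.fromiter(
        (0 if b == "N" else _IUPAC_BITS.get(b, 0) for b in seq),
        dtype=np.uint8,
        count=len(seq),
    )
    return out


@dataclass(frozen=True)
class Primer:
    """An IUPAC primer, written 5'->3'."""

    name: str
    sequence: str
    role: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"role must be forward/reverse, got {self.role!r}")
        if len(self.sequence) < THREE_PRIME_LEN + 1:
            raise ValueError(
                f"primer {self.name!r} shorter than {THREE_PRIME_LEN + 1} nt"
            )
        _primer_masks(self.sequence)  # validate alphabet

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primer pair with E. coli anchor coordinates (1-based)."""

    name: str
    forward: Primer
    reverse: Primer
    ecoli_start: int
    ecoli_stop: int

    def __post_init__(self) -> None:
        if self.ecoli_start >= self.ecoli_stop:
            raise ValueError("ecoli_start must be < ecoli_stop")

    @property
    def min_amplicon_length(self) -> int:
        return len(self.forward) + len(self.reverse)


@dataclass(frozen=True)
class PrimerMatch:
    """A scored primer binding site on the sense strand (0-based half-open)."""

    target_start: int
    target_end: int
    strand: str  # "sense" | "sense-revcomp"
    score: float
    breakdown: dict
    passed: bool


@dataclass(frozen=True)
class AmpliconResult:
    """A predicted, primer-inclusive amplicon."""

    record_id: str
    amp_start: int
    amp_end: int
    sequence: str
    forward_match: PrimerMatch
    reverse_match: PrimerMatch

    @property
    def length(self) -> int:
        return self.amp_end - self.amp_start


def _mismatch_class(k: int, primer_len: int) -> str:
    """Penalty class of a mismatch at primer index ``k`` (0-based, 5'->3')."""
    if k == primer_len - 1:
        return "last_mismatch"
    if k >= primer_len - THREE_PRIME_LEN:
        return "three_mismatch"
    return "non3_mismatch"


def _gap_class(n_bases_3prime_of_gap: int) -> str:
    """A gap is a 3' gap when fewer than THREE_PRIME_LEN primer bases lie 3' of it."""
    return "three_gap" if n_bases_3prime_of_gap < THREE_PRIME_LEN else "non3_gap"


def _score_columns(pairs: Iterable[tuple[int, int, int]], primer_len: int) -> dict:
    """Score aligned (primer_index, primer_mask, target_mask) columns."""
    counts = {k: 0 for k in PENALTIES}
    for k, pmask, tmask in pairs:
        if not (pmask & tmask):
            counts[_mismatch_class(k, primer_len)] += 1
    return counts


def _total(counts: dict) -> float:
    return sum(PENALTIES[k] * v for k, v in counts.items())


def score_primer_alignment(primer: Primer | str, window: str) -> PrimerMatch:
    """Best (minimum-penalty) alignment of a primer against one window.

    The window must be given in primer orientation (5'->3' of the primer) and
    have length within one of the primer; at most one gap is considered.
    Returns a :class:`PrimerMatch` whose coordinates are window-relative
    (``target_start = 0``).
    """
    seq = primer.sequence if isinstance(primer, Primer) else primer
    L = len(seq)
    wl = len(window)
    if not (L - 1 <= wl <= L + 1):
        raise ValueError(
            f"window length {wl} outside [{L - 1}, {L + 1}] for primer of length {L}"
        )
    pmask = _primer_masks(seq)
    tmask = _target_masks(window.upper().replace("U", "T"))

    best: tuple[float, dict] | None = None

    def consider(counts: dict) -> None:
        nonlocal best
        score = _total(counts)
        if best is None or score < best[0] - _EPS:
            best = (score, counts)

    if wl == L:
        consider(_score_columns(((k, pmask[k], tmask[k]) for k in range(L)), L))
    elif wl == L - 1:
        # One primer base i is deleted (gap in target).
        for i in range(L):
            cols = [(k, pmask[k], tmask[k]) for k in range(i)]
            cols += [(k, pmask[k], tmask[k - 1]) for k in range(i + 1, L)]
            counts = _score_columns(cols, L)
            counts[_gap_class(L - 1 - i)] += 1
            consider(counts)
    else:
        # One target base j is skipped (gap in primer between positions j-1, j).
        for j in range(L + 1):
            cols = [(k, pmask[k], tmask[k]) for k in range(j)]
            cols += [(k, pmask[k], tmask[k + 1]) for k in range(j, L)]
            counts = _score_columns(cols, L)
            counts[_gap_class(L - j)] += 1
            consider(counts)

    score, counts = best
    return PrimerMatch(
        target_start=0,
        target_end=wl,
        strand="sense",
        score=round(score, 10),
        breakdown=counts,
        passed=score <= PASS_THRESHOLD + _EPS,
    )


def _penalty_vector(L: int) -> np.ndarray:
    pen = np.full(L, PENALTIES["non3_mismatch"])
    pen[L - THREE_PRIME_LEN : L - 1] = PENALTIES["three_mismatch"]
    pen[L - 1] = PENALTIES["last_mismatch"]
    return pen


def _scan_scores(
    pmask: np.ndarray, tmask: np.ndarray, max_score: float = np.inf
) -> list[tuple[float, int, int]]:
    """All-site alignment scan; returns [(score, start, window_len), ...].

    Vectorized equivalent of calling :func:`score_primer_alignment` at every
    offset and window length. ``Rp[k, pad + t]`` holds the mismatch penalty of
    primer base ``k`` against target position ``t``; prefix/suffix cumulative
    sums over ``k`` with a +-1 target shift then give every single-gap
    alignment in O(L) vector operations. Only scores <= ``max_score`` are
    returned.
    """
    L, n = len(pmask), len(tmask)
    if n < L - 1:
        return []
    pen = _penalty_vector(L)
    pad = L + 1
    match = (tmask[None, :] & pmask[:, None]) != 0
    Rp = np.full((L, n + 2 * pad), np.inf)
    Rp[:, pad : pad + n] = np.where(match, 0.0, pen[:, None])

    # Offsets s in [0, n); out-of-range columns carry inf and are filtered.
    F = np.zeros((L + 1, n))  # F[i, s] = sum_{k < i} Rp[k, pad + s + k]
    for k in range(L):
        F[k + 1] = F[k] + Rp[k, pad + k : pad + k + n]
    Gm = np.zeros((L + 1, n))  # Gm[i, s] = sum_{k >= i} Rp[k, pad + s + k - 1]
    Gp = np.zeros((L + 1, n))  # Gp[j, s] = sum_{k >= j} Rp[k, pad + s + k + 1]
    for k in range(L - 1, -1, -1):
        Gm[k] = Gm[k + 1] + Rp[k, pad + k - 1 : pad + k - 1 + n]
        Gp[k] = Gp[k + 1] + Rp[k, pad + k + 1 : pad + k + 1 + n]

    out: list[tuple[float, int, int]] = []
    offsets = np.arange(n)

    def collect(scores: np.ndarray, wl: int) -> None:
        ok = (offsets + wl <= n) & (scores <= max_score + _EPS)
        for s in np.flatnonzero(ok):
            out.append((float(scores[s]), int(s), wl))

    # No-gap alignments.
    collect(F[L], L)
    # Deletion of primer base i -> window length L - 1.
    del_scores = np.full(n, np.inf)
    for i in range(L):
        gp = PENALTIES[_gap_class(L - 1 - i)]
        del_scores = np.minimum(del_scores, F[i] + Gm[i + 1] + gp)
    collect(del_scores, L - 1)
    # Insertion before primer base j -> window length L + 1.
    ins_scores = np.full(n, np.inf)
    for j in range(L + 1):
        gp = PENALTIES[_gap_class(L - j)]
        ins_scores = np.minimum(ins_scores, F[j] + Gp[j] + gp)
    collect(ins_scores, L + 1)
    return out


def find_best_site(
    primer: Primer, record: ReferenceRecord | str, orientation: str | None = None
) -> PrimerMatch | None:
    """Best passing binding site of a primer on the sense strand, or ``None``.

    A reverse-role primer is searched as its reverse complement on the sense
    strand (its 3' end maps to the leftmost base of the site). Ties on score
    break toward the lowest ``target_start`` for forward primers and the
    highest for reverse primers, which maximizes the canonical amplicon.
    """
    orientation = orientation or primer.role
    target = record.sequence if isinstance(record, ReferenceRecord) else record
    target = target.upper().replace("U", "T")
    n = len(target)

    if orientation == "forward":
        scan_target = target
    elif orientation == "reverse":
        scan_target = reverse_complement(target)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    pmask = _primer_masks(primer.sequence)
    tmask = _target_masks(scan_target)
    candidates = _scan_scores(pmask, tmask, max_score=PASS_THRESHOLD)
    if not candidates:
        return None
    # Lowest score first; then leftmost scan position; then un-gapped window.
    score, s, wl = min(candidates, key=lambda c: (c[0], c[1], abs(c[2] - len(primer))))
    window = scan_target[s : s + wl]
    rescored = score_primer_alignment(primer, window)
    if orientation == "forward":
        start, end, strand = s, s + wl, "sense"
    else:
        start, end, strand = n - (s + wl), n - s, "sense-revcomp"
    return PrimerMatch(
        target_start=start,
        target_end=end,
        strand=strand,
        score=rescored.score,
        breakdown=rescored.breakdown,
        passed=rescored.passed,
    )


def extract_amplicon(
    pair: PrimerPair,
    record: ReferenceRecord,
    max_len: int = 500,
    scan_revcomp: bool = False,
) -> AmpliconResult | None:
    """Primer-inclusive predicted amplicon, or ``None`` when PCR would fail.

    Requires both primers to pass with the forward site upstream of (and not
    overlapping) the reverse site; amplicons longer than ``max_len`` are
    discarded. With ``scan_revcomp``, a record yielding no amplicon is
    re-scanned as its reverse complement (for antisense-deposited entries).
    """
    fwd = find_best_site(pair.forward, record, "forward")
    rev = find_best_site(pair.reverse, record, "reverse")
    result = None
    if fwd is not None and rev is not None and fwd.target_end <= rev.target_start:
        length = rev.target_end - fwd.target_start
        if length <= max_len:
            result = AmpliconResult(
                record_id=record.record_id,
                amp_start=fwd.target_start,
                amp_end=rev.target_end,
                sequence=record.sequence[fwd.target_start : rev.target_end],
                forward_match=fwd,
                reverse_match=rev,
            )
    if result is None and scan_revcomp:
        flipped = ReferenceRecord(
            record.record_id, record.lineage, reverse_complement(record.sequence)
        )
        return extract_amplicon(pair, flipped, max_len=max_len, scan_revcomp=False)
    return result


def median_lower(values: Sequence[int | float]) -> float:
    """Lower median (exact element for even n); used for all length medians."""
    if len(values) == 0:
        raise ValueError("empty input")
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def length_ci(lengths: Sequence[int | float], level: float = 0.99) -> tuple[float, float]:
    """Nearest-rank empirical percentile bounds at (1-level)/2 and 1-(1-level)/2."""
    n = len(lengths)
    if n == 0:
        raise ValueError("empty input")
    if not 0 < level <= 1:
        raise ValueError(f"level must be in (0, 1], got {level}")
    s = sorted(lengths)
    lo_p, hi_p = (1 - level) / 2, 1 - (1 - level) / 2
    # nearest-rank: value at rank ceil(p*n); the epsilon guards float artifacts
    # like 0.005 * 1000 = 5.000000000000001
    lo = s[max(math.ceil(lo_p * n - 1e-9), 1) - 1]
    hi = s[max(math.ceil(hi_p * n - 1e-9), 1) - 1]
    return lo, hi


@dataclass(frozen=True)
class LengthSummary:
    """Amplicon length distribution within one taxonomic group."""

    group: str
    n: int
    median: float | None
    ci_low: float | None
    ci_high: float | None
    lengths: tuple[int, ...] = field(repr=False)


def amplicon_length_distribution(
    db: ReferenceDatabase, pair: PrimerPair, rank: str, max_len: int = 500
) -> list[LengthSummary]:
    """Per-group (at ``rank``) primer-inclusive amplicon length summaries.

    Groups where no record amplifies are reported with ``n = 0``.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    summaries = []
    for group, records in db.group_by_rank(rank).items():
        lengths = tuple(
            amp.length
            for rec in records
            if (amp := extract_amplicon(pair, rec, max_len=max_len)) is not None
        )
        if lengths:
            lo, hi = length_ci(lengths)
            summaries.append(
                LengthSummary(group, len(lengths), median_lower(lengths), lo, hi, lengths)
            )
        else:
            summaries.append(LengthSummary(group, 0, None, None, None, ()))
    return summaries


@dataclass(frozen=True)
class CoverageReport:
    """Per-phylum predicted amplification coverage."""

    rows: pd.DataFrame  # columns: phylum, n_total, n_amplified, fraction

    def fraction(self, phylum: str) -> float:
        sub = self.rows[self.rows["phylum"] == phylum]
        if sub.empty:
            raise KeyError(phylum)
        return float(sub["fraction"].iloc[0])


def taxonomic_coverage(
    db: ReferenceDatabase, pair: PrimerPair, max_len: int = 500
) -> CoverageReport:
    """Fraction of records per phylum for which amplicon extraction succeeds."""
    if len(db) == 0:
        raise ValueError("empty database")
    rows = []
    for phylum, records in db.group_by_rank("phylum").items():
        n_amp = sum(
            extract_amplicon(pair, rec, max_len=max_len) is not None for rec in records
        )
        rows.append(
            {
                "phylum": phylum,
                "n_total": len(records),
                "n_amplified": n_amp,
                "fraction": n_amp / len(records),
            }
        )
    return CoverageReport(pd.DataFrame(rows))


@dataclass(frozen=True)
class ResolutionReport:
    """OTU-based taxonomic resolution of a set of (amplicon) sequences."""

    n_input: int
    n_otus: int
    threshold: float
    reference_total_otus: int | None = None

    @property
    def resolution_fraction(self) -> float | None:
        if self.reference_total_otus is None:
            return None
        return self.n_otus / self.reference_total_otus


def _global_identity(a: str, b: str) -> float:
    """Matches / length-of-shorter under a unit-cost global alignment."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            if ch == "=":
                matches += int(num)
            num = ""
    return matches / min(len(a), len(b))


def taxonomic_resolution(
    seqs: Sequence[str] | dict[str, str],
    threshold: float = 0.97,
    reference_total_otus: int | None = None,
) -> ResolutionReport:
    """Greedy centroid clustering at a similarity threshold (uclust-style).

    Inputs are sorted by decreasing length then lexicographically (on id when
    given, else on sequence) so the OTU count is invariant to input order. A
    sequence joins the first centroid, in creation order, whose global-alignment
    identity (matches over the shorter length) meets the threshold.
    """
    if isinstance(seqs, dict):
        items = list(seqs.items())
    else:
        items = [(s, s) for s in seqs]
    if not items:
        raise ValueError("empty input")
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    centroids: list[str] = []
    for _sid, seq in items:
        for c in centroids:
            if _global_identity(seq, c) >= threshold:
                break
        else:
            centroids.append(seq)
    return ResolutionReport(
        n_input=len(items),
        n_otus=len(centroids),
        threshold=threshold,
        reference_total_otus=reference_total_otus,
    )
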