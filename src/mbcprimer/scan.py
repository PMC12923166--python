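"""Sliding-window detection and scoring of discriminative primer sites.

A window of the intended primer length slides over the trimmed alignment.
In each window the most abundant target variant (degapped window string)
becomes the primer candidate; every covered sequence in both sets is then
binned by its edit distance to the candidate into mismatch classes
{0, 1, 2, 3, ≥4}, giving one mismatch profile per set.  The two profiles
are folded into a single discriminative score,

    score = (1/mm) * sum_{k=1..mm} ( T(k) - E(k) ),

where T(k) and E(k) are the cumulative fractions of target and exclusion
sequences within k-1 mismatches of the candidate, and mm is the mismatch
threshold (default 2).  A perfectly discriminative window — every target
sequence identical to the candidate, every exclusion sequence at ≥ mm
mismatches — scores exactly 1; identical profiles score 0.  Candidates are
filtered on score, gaps and ambiguity, overlapping survivors are grouped,
and the result is written as a tab-separated report.

Edit distances are global (Levenshtein) distances on the degapped window
strings, computed with edlib.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import edlib

from .errors import ConfigurationError, MbcError
from .msa import EXCLUSION, TARGET, TrimmedAlignment, to_original_position

logger = logging.getLogger(__name__)

#: mismatch classes of a profile: exactly 0, 1, 2, 3, and 4-or-more
PROFILE_BINS = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    window_length
        Primer length in bp the window slides at (default 20).
    mm
        Mismatch threshold of the score: cumulative profile differences are
        averaged over k = 1..mm (default 2).
    min_score
        Score filter floor, inclusive (default 0.5).
    max_gaps / max_ambiguous
        Maximum gap characters / non-ACGT characters tolerated in a
        candidate sequence (both default 0).
    """

    window_length: int = 20
    mm: int = 2
    min_score: float = 0.5
    max_gaps: int = 0
    max_ambiguous: int = 0

    def __post_init__(self) -> None:
        if self.window_length < 10:
            raise ConfigurationError("window_length must be >= 10")
        if not 1 <= self.mm <= 4:
            raise ConfigurationError("mm must be in 1..4")
        if not -1.0 <= self.min_score <= 1.0:
            raise ConfigurationError("min_score must be in [-1, 1]")
        if self.max_gaps < 0 or self.max_ambiguous < 0:
            raise ConfigurationError("max_gaps / max_ambiguous must be >= 0")


@dataclass(frozen=True)
class MismatchProfile:
    """Fractions of a sequence set at exactly 0, 1, 2, 3 and ≥4 mismatches
    from the candidate, abundance-weighted over the set's covered records."""

    fractions: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.fractions) != 5:
            raise ValueError("profile needs exactly five mismatch bins")
        if any(f < -1e-12 or f > 1 + 1e-12 for f in self.fractions):
            raise ValueError(f"profile fractions out of [0,1]: {self.fractions}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"profile fractions must sum to 1: {self.fractions}")

    @classmethod
    def from_counts(cls, counts: dict[int, int] | list[int]) -> "MismatchProfile":
        bins = [0] * 5
        items = counts.items() if isinstance(counts, dict) else enumerate(counts)
        for dist, n in items:
            bins[min(dist, 4)] += n
        total = sum(bins)
        if total == 0:
            raise ValueError("cannot build a profile from zero counts")
        return cls(tuple(b / total for b in bins))

    def cumulative(self, k: int) -> float:
        """Fraction of the set within k-1 mismatches (first k bins)."""
        return sum(self.fractions[:k])


@dataclass
class WindowVariants:
    """Degapped sequence variants of one window, counted per set.

    ``variants[set]`` maps degapped window string → abundance, insertion
    order = first occurrence in the alignment (used for tie-breaking);
    ``covered[set]`` counts records whose terminal mask spans the window.
    """

    start: int
    length: int
    variants: dict[str, dict[str, int]]
    covered: dict[str, int]


@dataclass
class CandidateSite:
    """One scored window: a row of the candidate report."""

    name: str
    start: int  # trimmed coords, half-open
    end: int
    orig_start: int  # original-alignment coords, half-open
    orig_end: int
    sequence: str
    score: float
    target_profile: MismatchProfile
    exclusion_profile: MismatchProfile
    group_id: int | None = None


def count_mismatches(candidate: str, variant: str) -> int:
    """Levenshtein edit distance (unit-cost substitutions and indels)."""
    if not candidate or not variant:
        return max(len(candidate), len(variant))
    return edlib.align(candidate, variant, mode="NW", task="distance")["editDistance"]


def extract_window_variants(
    trimmed: TrimmedAlignment, start: int, length: int
) -> WindowVariants:
    """Count degapped window strings per set over records covering the window.

    Records whose terminal mask does not fully span ``[start, start+length)``
    are excluded from both the variant counts and the covered denominators.
    """
    alignment = trimmed.alignment
    end = start + length
    if end > alignment.n_columns:
        raise IndexError(f"window [{start},{end}) exceeds {alignment.n_columns} columns")
    variants: dict[str, dict[str, int]] = {TARGET: {}, EXCLUSION: {}}
    covered = {TARGET: 0, EXCLUSION: 0}
    for rec in alignment.records:
        if not rec.covers(start, end):
            continue
        covered[rec.set_label] += 1
        window = rec.residues[start:end].replace("-", "")
        bucket = variants[rec.set_label]
        bucket[window] = bucket.get(window, 0) + 1
    return WindowVariants(start=start, length=length, variants=variants, covered=covered)


def select_candidate_variant(wv: WindowVariants) -> str:
    """Most abundant target variant; ties go to the first seen in file order."""
    bucket = wv.variants[TARGET]
    if not bucket:
        raise MbcError(f"window at {wv.start} has no covered target records")
    best, best_n = None, -1
    for seq, n in bucket.items():  # insertion order == first occurrence
        if n > best_n:
            best, best_n = seq, n
    return best


def build_mismatch_profile(
    wv: WindowVariants, candidate: str, set_label: str
) -> MismatchProfile:
    """Abundance-weighted mismatch profile of one set against the candidate."""
    if wv.covered[set_label] == 0:
        raise MbcError(
            f"window at {wv.start}: no covered {set_label} records, profile undefined"
        )
    counts: dict[int, int] = {}
    for seq, n in wv.variants[set_label].items():
        d = count_mismatches(candidate, seq)
        counts[d] = counts.get(d, 0) + n
    return MismatchProfile.from_counts(counts)


def discriminative_score(
    target: MismatchProfile, exclude: MismatchProfile, mm: int = 2
) -> float:
    """Average over k = 1..mm of the cumulative-profile difference T(k) - E(k).

    1 means every target sequence matches the candidate perfectly while
    every exclusion sequence carries at least mm mismatches; 0 means the two
    sets are indistinguishable at the site.  Values are not clamped, so a
    window where the exclusion set matches better than the target set goes
    negative (the default filter removes it).
    """
    if not 1 <= mm <= 4:
        raise ConfigurationError("mm must be in 1..4")
    return sum(target.cumulative(k) - exclude.cumulative(k) for k in range(1, mm + 1)) / mm


def scan_alignment(trimmed: TrimmedAlignment, cfg: ScanConfig) -> list[CandidateSite]:
    """Score every window of the trimmed alignment (unfiltered).

    Windows with no covered target or exclusion records are skipped.
    Deterministic for a fixed input and config.
    """
    n_cols = trimmed.alignment.n_columns
    length = cfg.window_length
    if n_cols < length:
        raise MbcError(
            f"alignment has {n_cols} columns, shorter than the {length} bp window"
        )
    sites: list[CandidateSite] = []
    n_skipped = 0
    for start in range(n_cols - length + 1):
        wv = extract_window_variants(trimmed, start, length)
        if wv.covered[TARGET] == 0 or wv.covered[EXCLUSION] == 0:
            n_skipped += 1
            continue
        candidate = select_candidate_variant(wv)
        tgt = build_mismatch_profile(wv, candidate, TARGET)
        exc = build_mismatch_profile(wv, candidate, EXCLUSION)
        score = discriminative_score(tgt, exc, cfg.mm)
        sites.append(
            CandidateSite(
                name=f"mbc-{start + 1}",
                start=start,
                end=start + length,
                orig_start=to_original_position(trimmed, start),
                orig_end=to_original_position(trimmed, start + length - 1) + 1,
                sequence=candidate,
                score=score,
                target_profile=tgt,
                exclusion_profile=exc,
            )
        )
    logger.info(
        "scanned %d windows: %d scored, %d skipped (no coverage)",
        n_cols - length + 1, len(sites), n_skipped,
    )
    return sites


def filter_candidates(sites: list[CandidateSite], cfg: ScanConfig) -> list[CandidateSite]:
    """Keep sites with score ≥ min_score (inclusive) whose candidate carries
    at most max_gaps gap-shortened positions and max_ambiguous non-ACGT
    characters; order preserved."""
    kept = []
    for site in sites:
        n_gaps = (site.end - site.start) - len(site.sequence)
        n_ambig = sum(1 for c in site.sequence if c not in "ACGT")
        if site.score >= cfg.min_score and n_gaps <= cfg.max_gaps and n_ambig <= cfg.max_ambiguous:
            kept.append(site)
    logger.info("filter: %d of %d sites kept (min_score=%g)", len(kept), len(sites), cfg.min_score)
    return kept


def group_overlapping(sites: list[CandidateSite]) -> list[CandidateSite]:
    """Assign consecutive group ids to connected components of window overlap.

    Windows are half-open, so abutting windows ([0,20) and [20,40)) land in
    different groups.  Sites are returned sorted by start.
    """
    ordered = sorted(sites, key=lambda s: (s.start, s.end))
    group, prev_end = 0, None
    for site in ordered:
        if prev_end is None or site.start >= prev_end:
            group += 1
            prev_end = site.end
        else:
            prev_end = max(prev_end, site.end)
        site.group_id = group
    return ordered


REPORT_COLUMNS = (
    "name", "start", "end", "orig_start", "orig_end", "length", "score",
    "tgt_mm0", "tgt_mm1", "tgt_mm2", "tgt_mm3", "tgt_mm4plus",
    "exc_mm0", "exc_mm1", "exc_mm2", "exc_mm3", "exc_mm4plus",
    "group", "sequence",
)


def write_report(sites: list[CandidateSite], path: str | Path) -> None:
    """Write the candidate table as TSV.

    Coordinates are 1-based inclusive, in both trimmed and original
    alignment frames; scores carry 4 decimals, profile bins are percentages
    with 1 decimal.
    """
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for s in sites:
            row = [
                s.name,
                str(s.start + 1), str(s.end),
                str(s.orig_start + 1), str(s.orig_end),
                str(len(s.sequence)),
                f"{s.score:.4f}",
                *(f"{100 * f:.1f}" for f in s.target_profile.fractions),
                *(f"{100 * f:.1f}" for f in s.exclusion_profile.fractions),
                str(s.group_id if s.group_id is not None else 0),
                s.sequence,
            ]
            fh.write("\t".join(row) + "\n")


def scan_pipeline(
    trimmed: TrimmedAlignment, cfg: ScanConfig | None = None
) -> list[CandidateSite]:
    """scan → filter → group, the default end-to-end candidate search."""
    cfg = cfg or ScanConfig()
    return group_overlapping(filter_candidates(scan_alignment(trimmed, cfg), cfg))
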