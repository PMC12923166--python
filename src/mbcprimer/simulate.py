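"""Seedable synthetic fixtures with planted discriminative sites.

The generator emulates the situation the scanner is built for: a mostly
conserved marker alignment shared by target and exclusion sequences, with
one or more windows where the exclusion (host) set diverges from the
target set by a prescribed number of substitutions.  Because the planted
mismatch counts are known exactly, every generated alignment comes with a
ground-truth record (:class:`PlantedTruth`) holding the expected mismatch
profiles and the analytically expected discriminative score — the basis of
the planted-site recovery tests.

Background columns are drawn once and copied to every row with a small,
set-independent substitution noise (default 2% per cell), so no window
outside the planted sites is systematically discriminative.  Optional
internal gaps and terminal truncations (both kept away from the planted
windows so the ground truth stays exact) exercise the preprocessing path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, GenerationError
from .msa import EXCLUSION, TARGET, AlignedRecord, Alignment, mask_terminal_gaps
from .primers import IUPAC_SETS, approximate_occurrence, reverse_complement
from .scan import MismatchProfile, count_mismatches, discriminative_score

_BASES = "ACGT"
_GAPCODE = 4
_DECODE = np.frombuffer(b"ACGT-", dtype=np.uint8)


@dataclass(frozen=True)
class SiteSpec:
    """One planted discriminative window."""

    start: int
    length: int = 20
    target_fractions: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    exclusion_fractions: Mapping[int, float] = field(default_factory=lambda: {4: 1.0})


@dataclass
class PlantedTruth:
    """Where a site was planted and what the scanner should find there."""

    window_start: int
    window_length: int
    expected_target_profile: MismatchProfile
    expected_exclusion_profile: MismatchProfile
    expected_score: float
    seed: int
    candidate: str
    mm: int = 2

    def to_dict(self) -> dict:
        return {
            "window_start": self.window_start,
            "window_length": self.window_length,
            "expected_target_profile": list(self.expected_target_profile.fractions),
            "expected_exclusion_profile": list(self.expected_exclusion_profile.fractions),
            "expected_score": self.expected_score,
            "seed": self.seed,
            "candidate": self.candidate,
            "mm": self.mm,
        }


def _class_counts(fractions: Mapping[int, float], n: int, length: int) -> dict[int, int]:
    """Largest-remainder apportionment of n rows over mismatch classes."""
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ConfigurationError(f"mismatch fractions must sum to 1: {dict(fractions)}")
    for m in fractions:
        if not 0 <= m <= length:
            raise GenerationError(f"cannot plant {m} substitutions in a {length} bp window")
    floors = {m: int(math.floor(f * n)) for m, f in fractions.items()}
    remainder = n - sum(floors.values())
    order = sorted(fractions, key=lambda m: (-(fractions[m] * n - floors[m]), m))
    for m in order[:remainder]:
        floors[m] += 1
    counts = {m: c for m, c in floors.items() if c > 0}
    for m, c in counts.items():
        if m == 0:
            continue  # class-0 rows all share the candidate itself
        capacity = math.comb(length, m) * 3 ** m
        if c > capacity:
            raise GenerationError(
                f"{c} distinct variants at {m} mismatches requested but only "
                f"{capacity} exist for a {length} bp window"
            )
    return counts


def _mutate(candidate: np.ndarray, m: int, rng: np.random.Generator,
            used: set[bytes]) -> np.ndarray:
    """Candidate window with exactly m substitutions, distinct from `used`,
    verified to sit at edit distance exactly m (substitutions can otherwise
    collapse into cheaper indel alignments)."""
    cand_str = _DECODE[candidate].tobytes().decode()
    for _ in range(200):
        variant = candidate.copy()
        pos = rng.choice(len(candidate), size=m, replace=False)
        variant[pos] = (variant[pos] + rng.integers(1, 4, size=m)) % 4
        key = variant.tobytes()
        if key in used:
            continue
        if count_mismatches(cand_str, _DECODE[variant].tobytes().decode()) != m:
            continue
        used.add(key)
        return variant
    raise GenerationError(f"could not draw a fresh variant at {m} mismatches")


def _plant_set(
    rows: np.ndarray,
    row_idx: np.ndarray,
    site: SiteSpec,
    fractions: Mapping[int, float],
    rng: np.random.Generator,
) -> MismatchProfile:
    """Write planted variants into rows[row_idx, window]; returns the
    realized (= expected) mismatch profile."""
    counts = _class_counts(fractions, len(row_idx), site.length)
    window = slice(site.start, site.start + site.length)
    candidate = rows[row_idx[0], window].copy()  # pre-noise master == candidate
    perm = rng.permutation(len(row_idx))
    classes = np.empty(len(row_idx), dtype=int)
    off = 0
    for m in sorted(counts):
        classes[perm[off : off + counts[m]]] = m
        off += counts[m]
    if counts.get(0, 0) >= 1 and classes[0] != 0:
        swap = int(np.flatnonzero(classes == 0)[0])
        classes[swap], classes[0] = classes[0], 0  # keep the candidate first in file order
    used: set[bytes] = {candidate.tobytes()}
    for local, m in enumerate(classes):
        r = row_idx[local]
        if m == 0:
            rows[r, window] = candidate
        else:
            rows[r, window] = _mutate(candidate, int(m), rng, used)
    bins = [0] * 5
    for m, c in counts.items():
        bins[min(m, 4)] += c
    return MismatchProfile.from_counts(bins)


def generate_multi_planted_alignment(
    n_target: int,
    n_exclusion: int,
    n_columns: int,
    sites: Sequence[SiteSpec],
    gap_rate: float = 0.0,
    terminal_truncation_rate: float = 0.0,
    background_identity: float = 0.98,
    seed: int = 0,
    mm: int = 2,
) -> tuple[Alignment, list[PlantedTruth]]:
    """Alignment with several disjoint planted windows and their truths."""
    ordered = sorted(sites, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if a.start + a.length > b.start:
            raise ConfigurationError("planted windows must not overlap")
    if ordered and ordered[-1].start + ordered[-1].length > n_columns:
        raise ConfigurationError("planted window does not fit in the alignment")
    if n_target < 1 or n_exclusion < 1:
        raise ConfigurationError("need at least one target and one exclusion row")

    rng = np.random.default_rng(seed)
    n_rows = n_target + n_exclusion
    master = rng.integers(0, 4, size=n_columns)
    rows = np.tile(master, (n_rows, 1))

    site_mask = np.zeros(n_columns, dtype=bool)
    for s in ordered:
        site_mask[s.start : s.start + s.length] = True

    # set-independent background noise outside the planted windows
    noise = (rng.random(rows.shape) < (1.0 - background_identity)) & ~site_mask
    rows[noise] = (rows[noise] + rng.integers(1, 4, size=int(noise.sum()))) % 4

    target_idx = np.arange(n_target)
    excl_idx = np.arange(n_target, n_rows)
    truths: list[PlantedTruth] = []
    for s in ordered:
        window = slice(s.start, s.start + s.length)
        rows[:, window] = master[window]  # reset noise inside the window
        tgt_prof = _plant_set(rows, target_idx, s, s.target_fractions, rng)
        exc_prof = _plant_set(rows, excl_idx, s, s.exclusion_fractions, rng)
        truths.append(
            PlantedTruth(
                window_start=s.start,
                window_length=s.length,
                expected_target_profile=tgt_prof,
                expected_exclusion_profile=exc_prof,
                expected_score=discriminative_score(tgt_prof, exc_prof, mm),
                seed=seed,
                candidate=_DECODE[master[window]].tobytes().decode(),
                mm=mm,
            )
        )

    if gap_rate > 0:
        gaps = (rng.random(rows.shape) < gap_rate) & ~site_mask
        rows[gaps] = _GAPCODE

    if terminal_truncation_rate > 0:
        left_max = min((s.start for s in ordered), default=n_columns // 4)
        right_max = n_columns - max((s.start + s.length for s in ordered), default=3 * n_columns // 4)
        for r in range(n_rows):
            if rng.random() < terminal_truncation_rate:
                cut_l = int(rng.integers(0, left_max + 1))
                cut_r = int(rng.integers(0, right_max + 1))
                rows[r, :cut_l] = _GAPCODE
                if cut_r:
                    rows[r, n_columns - cut_r :] = _GAPCODE

    records = []
    for i in range(n_rows):
        label = TARGET if i < n_target else EXCLUSION
        idx = i if i < n_target else i - n_target
        records.append(
            AlignedRecord(
                id=f"{label}_{idx:03d}",
                residues=_DECODE[rows[i]].tobytes().decode(),
                set_label=label,
            )
        )
    alignment = Alignment(records=records, n_columns=n_columns)
    mask_terminal_gaps(alignment)
    return alignment, truths


def generate_planted_alignment(
    n_target: int,
    n_exclusion: int,
    n_columns: int,
    site_start: int,
    site_length: int = 20,
    target_variant_fractions: Mapping[int, float] | None = None,
    exclusion_min_mismatches: int | None = 4,
    exclusion_variant_fractions: Mapping[int, float] | None = None,
    gap_rate: float = 0.0,
    terminal_truncation_rate: float = 0.0,
    background_identity: float = 0.98,
    seed: int = 0,
    mm: int = 2,
) -> tuple[Alignment, PlantedTruth]:
    """Alignment with one planted discriminative window.

    ``target_variant_fractions`` maps planted mismatch count → fraction of
    target rows (default all at 0).  The exclusion side takes either a full
    fraction mapping or, as a shorthand, ``exclusion_min_mismatches`` d
    (every exclusion row planted at exactly d substitutions).
    """
    if exclusion_variant_fractions is None:
        if exclusion_min_mismatches is None:
            raise ConfigurationError("provide exclusion fractions or a minimum mismatch count")
        exclusion_variant_fractions = {exclusion_min_mismatches: 1.0}
    site = SiteSpec(
        start=site_start,
        length=site_length,
        target_fractions=target_variant_fractions or {0: 1.0},
        exclusion_fractions=exclusion_variant_fractions,
    )
    alignment, truths = generate_multi_planted_alignment(
        n_target, n_exclusion, n_columns, [site],
        gap_rate=gap_rate,
        terminal_truncation_rate=terminal_truncation_rate,
        background_identity=background_identity,
        seed=seed,
        mm=mm,
    )
    return alignment, truths[0]


def score_ladder_sites(
    expected_scores: Sequence[float],
    window_length: int = 20,
    first_start: int = 60,
    spacing: int = 60,
) -> list[SiteSpec]:
    """Disjoint sites whose expected scores at mm=2 equal the given values.

    Target rows all match the candidate; a fraction 1-s of the exclusion
    rows also match it while the rest carry ≥4 mismatches, which makes the
    expected score exactly s.
    """
    sites = []
    for i, s in enumerate(expected_scores):
        if not 0.0 <= s <= 1.0:
            raise ConfigurationError("expected scores must lie in [0, 1]")
        excl = {4: 1.0} if s >= 1.0 else ({0: 1.0} if s <= 0.0 else {0: 1.0 - s, 4: s})
        sites.append(
            SiteSpec(
                start=first_start + i * (window_length + spacing),
                length=window_length,
                target_fractions={0: 1.0},
                exclusion_fractions=excl,
            )
        )
    return sites


def generate_reference_set(
    primer: str,
    n_refs: int | None = None,
    mismatch_counts: Sequence[int] = (0,),
    flank_length: int = 30,
    seed: int = 0,
) -> list[SeqRecord]:
    """Unaligned references each embedding the primer with a prescribed
    number of substitutions inside random flanks; every other reference is
    reverse-complemented.  Each record is verified against the IUPAC
    Hamming matcher so the realized best-hit mismatch count equals the
    prescription (counts ≤ 2) or exceeds the 2-mismatch horizon (counts > 2).
    """
    if n_refs is None:
        n_refs = len(mismatch_counts)
    rng = np.random.default_rng(seed)
    primer = primer.upper()
    sets = [IUPAC_SETS[c] for c in primer]
    records = []
    for i in range(n_refs):
        m = mismatch_counts[i % len(mismatch_counts)]
        if m > len(primer):
            raise GenerationError(f"cannot plant {m} mismatches in a {len(primer)} bp primer")
        for _ in range(50):
            core = [rng.choice(sorted(s)) for s in sets]  # one expansion of the primer
            pos = rng.choice(len(primer), size=m, replace=False)
            for p in pos:
                off_bases = sorted(set(_BASES) - sets[p])
                core[p] = off_bases[int(rng.integers(len(off_bases)))]
            flank_l = "".join(rng.choice(list(_BASES), size=flank_length))
            flank_r = "".join(rng.choice(list(_BASES), size=flank_length))
            seq = flank_l + "".join(core) + flank_r
            rc = i % 2 == 1
            if rc:
                seq = reverse_complement(seq)
            occ = approximate_occurrence(primer, seq, max_mm=2)
            if (m <= 2 and occ is not None and occ.mismatches == m) or (m > 2 and occ is None):
                records.append(
                    SeqRecord(Seq(seq), id=f"ref_{i:03d}_mm{m}{'_rc' if rc else ''}",
                              description="")
                )
                break
        else:
            raise GenerationError(f"could not realize a reference at {m} mismatches")
    return records
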