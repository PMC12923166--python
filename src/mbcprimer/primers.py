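"""Downstream primer evaluation.

Once the scanner has proposed discriminative candidate sites, each primer
is judged on practical PCR criteria: GC content, melting temperature,
a mismatch at the 3' terminus against the exclusion set (the position where
polymerase extension is most sensitive), in-silico coverage of reference
sets at 0/1/2 mismatches, and pair compatibility (ΔTm, predicted amplicon
length, and a heterodimer heuristic).  Degenerate IUPAC positions can be
introduced greedily to raise target coverage.

Selection criteria applied here mirror standard discriminative-primer
practice: ≥80% target coverage within one mismatch, at least one 3'-end
mismatch against the exclusion set, GC between 40 and 60%, and a length of
about 20 bp.

Coverage matching is a both-strand Hamming scan with IUPAC-aware base
equality (a reference base matches wherever it lies inside the primer
position's IUPAC set).  Heterodimer likelihood is a longest-complementary-
run heuristic, with 3'-anchored runs reported separately — a documented
simplification of full duplex thermodynamics.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from .errors import AlphabetError, ConfigurationError, DegeneracyError, GeometryError, MbcError
from .msa import TARGET
from .scan import CandidateSite, WindowVariants, select_candidate_variant

logger = logging.getLogger(__name__)

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: reaction conditions assumed by the nearest-neighbor Tm (Biopython defaults)
TM_CONDITIONS = {"Na": 50.0, "dnac1": 25.0, "dnac2": 25.0}


def _sets(sequence: str) -> list[frozenset[str]]:
    try:
        return [IUPAC_SETS[c] for c in sequence.upper()]
    except KeyError as exc:
        raise AlphabetError(f"invalid IUPAC character {exc} in {sequence!r}") from exc


def degeneracy(sequence: str) -> int:
    """Product of per-position IUPAC set sizes."""
    d = 1
    for s in _sets(sequence):
        d *= len(s)
    return d


def gc_content(sequence: str) -> float:
    """Fraction of GC, averaging degenerate positions over their IUPAC set
    (S counts 1.0, Y counts 0.5, N counts 0.5, ...)."""
    sets = _sets(sequence)
    if not sets:
        raise AlphabetError("empty sequence")
    return sum(len(s & {"G", "C"}) / len(s) for s in sets) / len(sets)


def reverse_complement(sequence: str) -> str:
    """IUPAC-aware reverse complement (Y↔R, S↔S, D↔H, N↔N, ...)."""
    _sets(sequence)  # alphabet check
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def expand_degenerate(sequence: str, cap: int = 64) -> list[str]:
    """All plain-base expansions of a degenerate primer, lexicographic."""
    d = degeneracy(sequence)
    if d > cap:
        raise DegeneracyError(
            f"degeneracy {d} exceeds cap {cap}; redesign with fewer degenerate positions"
        )
    choices = [sorted(s) for s in _sets(sequence)]
    return ["".join(p) for p in itertools.product(*choices)]


def collapse_to_iupac(sequences: Sequence[str]) -> str:
    """Minimal IUPAC code per position covering all given equal-length seqs."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise MbcError("can only collapse equal-length sequences")
    out = []
    for pos in range(lengths.pop()):
        bases = frozenset().union(*(IUPAC_SETS[s[pos].upper()] for s in sequences))
        out.append(CODE_FOR_SET[bases])
    return "".join(out)


def melting_temperature(sequence: str, method: str = "nn", cap: int = 64) -> float:
    """Primer melting temperature in °C.

    ``wallace``: 2(A+T) + 4(G+C).  ``nn``: nearest-neighbor model
    (Biopython's Tm_NN with its default Allawi & SantaLucia parameters at
    the conditions in :data:`TM_CONDITIONS`).  Degenerate primers are
    averaged over their expansions; beyond ``cap`` expansions a fixed-seed
    sample of ``cap`` expansions is averaged instead.
    """
    if method not in ("wallace", "nn"):
        raise ConfigurationError(f"unknown Tm method {method!r}")
    if len(sequence) < 8:
        logger.warning("Tm of a %d bp sequence is unreliable", len(sequence))
    d = degeneracy(sequence)
    if d <= cap:
        seqs = expand_degenerate(sequence, cap)
    else:
        rng = np.random.default_rng(0)
        choices = [sorted(s) for s in _sets(sequence)]
        seqs = [
            "".join(c[rng.integers(len(c))] for c in choices) for _ in range(cap)
        ]
    if method == "wallace":
        vals = [_mt.Tm_Wallace(s) for s in seqs]
    else:
        vals = [_mt.Tm_NN(s, **TM_CONDITIONS) for s in seqs]
    return float(np.mean(vals))


@dataclass
class PrimerRecord:
    """An oriented, possibly degenerate primer with its physical properties.

    ``sequence`` is written 5'→3' on the primer strand; a reverse primer
    therefore stores the reverse complement of its alignment-strand site.
    """

    name: str
    sequence: str
    orientation: str = "forward"
    source_site: CandidateSite | None = None
    tm_method: str = "nn"
    gc_fraction: float = field(init=False)
    tm_celsius: float = field(init=False)
    degeneracy: int = field(init=False)
    target_coverage: float | None = None
    coverage_goal_met: bool | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ConfigurationError(f"orientation must be forward|reverse, got {self.orientation!r}")
        self.sequence = self.sequence.upper()
        self.gc_fraction = gc_content(self.sequence)
        self.tm_celsius = melting_temperature(self.sequence, self.tm_method)
        self.degeneracy = degeneracy(self.sequence)

    @classmethod
    def from_site(cls, site: CandidateSite, orientation: str = "forward") -> "PrimerRecord":
        seq = site.sequence if orientation == "forward" else reverse_complement(site.sequence)
        suffix = "F" if orientation == "forward" else "R"
        return cls(name=f"{site.name}-{suffix}", sequence=seq, orientation=orientation,
                   source_site=site)


@dataclass(frozen=True)
class CoverageResult:
    """Cumulative ("summative") fractions of a reference set hit within
    0, 1, and 2 mismatches."""

    fractions: tuple[float, float, float]

    def __post_init__(self) -> None:
        c0, c1, c2 = self.fractions
        if not (0 <= c0 <= c1 <= c2 <= 1 + 1e-12):
            raise ValueError(f"coverage must be cumulative in [0,1]: {self.fractions}")

    def at(self, max_mm: int) -> float:
        return self.fractions[max_mm]


@dataclass(frozen=True)
class Occurrence:
    """Best approximate match of a primer in one reference sequence."""

    position: int  # 0-based start on the forward reference
    mismatches: int
    strand: str  # "+" or "-"


@dataclass(frozen=True)
class ThreePrimeReport:
    """Per-position exclusion mismatch fractions at the primer's 3' end.

    ``fractions[j]`` is the abundance-weighted fraction of exclusion
    sequences mismatching the primer at the j-th position from the 3'
    terminus (j = 0 is the terminal base).
    """

    fractions: tuple[float, ...]
    passes: bool
    refused_variants: int = 0

    @property
    def terminal_fraction(self) -> float:
        return self.fractions[0]


@dataclass
class SelectionVerdict:
    """The four practical selection criteria, plus their conjunction."""

    coverage_ok: bool
    three_prime_ok: bool
    gc_ok: bool
    length_ok: bool

    @property
    def passed(self) -> bool:
        return self.coverage_ok and self.three_prime_ok and self.gc_ok and self.length_ok


@dataclass
class PairReport:
    """Compatibility summary for a forward/reverse primer pair."""

    forward: PrimerRecord
    reverse: PrimerRecord
    delta_tm: float
    predicted_amplicon_bp: int
    heterodimer_score: int  # longest complementary run anywhere
    three_prime_anchored: int  # longest 3'-anchored complementary run
    passes: bool


def propose_degenerate_consensus(
    wv: WindowVariants,
    coverage_goal: float = 0.9,
    degeneracy_cap: int = 64,
    name: str = "consensus",
) -> PrimerRecord:
    """Greedily add degenerate positions to the candidate variant until the
    exact-match target coverage goal is reached or the degeneracy cap hit.

    At each step the single-base addition giving the largest coverage gain
    per unit of added degeneracy is applied; ties break to the leftmost
    position, then alphabetically.  Positions where all target variants
    agree are never altered.  If the goal is unreachable, the best-effort
    primer is returned with ``coverage_goal_met`` False.
    """
    candidate = select_candidate_variant(wv)
    variants = wv.variants[TARGET]
    total = sum(variants.values())
    pattern = [IUPAC_SETS[c] for c in candidate]

    def coverage(pat: list[frozenset[str]]) -> float:
        hit = 0
        for seq, n in variants.items():
            if len(seq) == len(pat) and all(c in s for c, s in zip(seq, pat)):
                hit += n
        return hit / total

    cov = coverage(pattern)
    while cov < coverage_goal - 1e-12:
        deg = 1
        for s in pattern:
            deg *= len(s)
        # scan leftmost-first, A<C<G<T; keeping only strictly larger gains
        # makes ties resolve to the leftmost position / alphabetic base
        best = None  # (gain_per_degeneracy, pos, base, new_cov)
        for pos in range(len(pattern)):
            extra = len(pattern[pos])
            new_deg = deg // extra * (extra + 1)
            if new_deg > degeneracy_cap:
                continue
            for base in "ACGT":
                if base in pattern[pos]:
                    continue
                new_pat = list(pattern)
                new_pat[pos] = pattern[pos] | {base}
                new_cov = coverage(new_pat)
                if new_cov <= cov + 1e-12:
                    continue
                gain = (new_cov - cov) / (new_deg - deg)
                if best is None or gain > best[0] + 1e-15:
                    best = (gain, pos, base, new_cov)
        if best is None:
            break
        _, pos, base, cov = best
        pattern[pos] = pattern[pos] | {base}
    sequence = "".join(CODE_FOR_SET[s] for s in pattern)
    rec = PrimerRecord(name=name, sequence=sequence, orientation="forward")
    rec.target_coverage = cov
    rec.coverage_goal_met = cov >= coverage_goal - 1e-12
    if not rec.coverage_goal_met:
        logger.warning(
            "degenerate consensus reached %.3f coverage, goal %.3f unreachable under cap %d",
            cov, coverage_goal, degeneracy_cap,
        )
    return rec


def _variant_items(variants: Mapping[str, int] | Iterable[str]) -> list[tuple[str, int]]:
    if isinstance(variants, Mapping):
        return list(variants.items())
    return [(v, 1) for v in variants]


def three_prime_mismatch_check(
    primer: PrimerRecord | str,
    exclusion_variants: Mapping[str, int] | Iterable[str],
    k: int = 3,
    required_fraction: float = 1.0,
) -> ThreePrimeReport:
    """Fraction of exclusion sequences mismatching each of the primer's last
    ``k`` 3'-end positions; passes iff the terminal base mismatches at least
    ``required_fraction`` of them.

    Exclusion variants are the degapped window strings on the alignment
    strand; for a reverse :class:`PrimerRecord` they are reverse-complemented
    onto the primer strand first.  Variants whose length differs from the
    primer by more than 2 cannot be compared positionally (edit ambiguity)
    and are excluded, counted in ``refused_variants``.
    """
    if isinstance(primer, PrimerRecord):
        seq = primer.sequence
        reverse = primer.orientation == "reverse"
    else:
        seq, reverse = primer.upper(), False
    primer_sets = _sets(seq)
    items = _variant_items(exclusion_variants)
    if reverse:
        items = [(reverse_complement(v), n) for v, n in items]
    mism = [0.0] * k
    total = 0
    refused = 0
    for variant, n in items:
        if abs(len(variant) - len(seq)) > 2:
            refused += 1
            logger.warning(
                "3'-check: variant length %d vs primer %d differs by >2; skipped",
                len(variant), len(seq),
            )
            continue
        total += n
        vsets = _sets(variant)
        for j in range(k):
            if j >= len(vsets):
                mism[j] += n  # no base to pair: counts as a mismatch
            elif not (primer_sets[-1 - j] & vsets[-1 - j]):
                mism[j] += n
    if total == 0:
        raise MbcError("no comparable exclusion variants for the 3'-end check")
    fractions = tuple(m / total for m in mism)
    return ThreePrimeReport(
        fractions=fractions,
        passes=fractions[0] >= required_fraction - 1e-12,
        refused_variants=refused,
    )


_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_BITS = {
    code: sum(_BITS[b] for b in bases) for code, bases in IUPAC_SETS.items()
}


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_CODE_BITS[c] for c in sequence.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise AlphabetError(f"invalid character {exc} in sequence") from exc


def _hamming_scan(primer_bits: np.ndarray, ref_bits: np.ndarray) -> np.ndarray | None:
    n, L = len(ref_bits), len(primer_bits)
    if n < L:
        return None
    w = n - L + 1
    mism = np.zeros(w, dtype=np.int32)
    for p in range(L):
        mism += (ref_bits[p : p + w] & primer_bits[p]) == 0
    return mism


def approximate_occurrence(
    primer: str, reference: str, max_mm: int = 2
) -> Occurrence | None:
    """Best Hamming-with-IUPAC hit of the primer (either strand) in a
    reference, or None if every placement exceeds ``max_mm`` mismatches.

    A reference base matches wherever the primer position's IUPAC set and
    the reference base's IUPAC set intersect.  Ties break to the forward
    strand, then to the leftmost position.
    """
    pseq = primer if isinstance(primer, str) else primer.sequence
    ref_bits = _encode(reference)
    best: Occurrence | None = None
    for strand, seq in (("+", pseq), ("-", reverse_complement(pseq))):
        mism = _hamming_scan(_encode(seq), ref_bits)
        if mism is None:
            continue
        idx = int(np.argmin(mism))  # leftmost minimum
        if mism[idx] <= max_mm and (best is None or mism[idx] < best.mismatches):
            best = Occurrence(position=idx, mismatches=int(mism[idx]), strand=strand)
    return best


def coverage_profile(
    primer: PrimerRecord | str, references: Iterable[str]
) -> CoverageResult:
    """Cumulative fraction of references containing a primer binding site
    within 0, 1, and 2 mismatches (both strands)."""
    pseq = primer.sequence if isinstance(primer, PrimerRecord) else primer
    refs = [str(getattr(r, "seq", r)) for r in references]
    if not refs:
        raise MbcError("reference set is empty")
    hits = [0, 0, 0]
    for ref in refs:
        occ = approximate_occurrence(pseq, ref, max_mm=2)
        if occ is not None:
            for kk in range(occ.mismatches, 3):
                hits[kk] += 1
    n = len(refs)
    return CoverageResult(fractions=(hits[0] / n, hits[1] / n, hits[2] / n))


def apply_selection_criteria(
    primer: PrimerRecord,
    coverage: CoverageResult,
    three_prime_pass: bool,
    min_coverage_1mm: float = 0.80,
    gc_bounds: tuple[float, float] = (0.40, 0.60),
    target_length: int = 20,
    length_tolerance: int = 3,
) -> SelectionVerdict:
    """Apply the four selection criteria (all bounds inclusive):
    ≥80% reference coverage within one mismatch, a 3'-end mismatch against
    the exclusion set, GC in 40–60%, and length of 20 ± 3 bp."""
    return SelectionVerdict(
        coverage_ok=coverage.at(1) >= min_coverage_1mm - 1e-12,
        three_prime_ok=bool(three_prime_pass),
        gc_ok=gc_bounds[0] - 1e-12 <= primer.gc_fraction <= gc_bounds[1] + 1e-12,
        length_ok=abs(len(primer.sequence) - target_length) <= length_tolerance,
    )


def _complementary_run_matrix(a: str, b: str) -> np.ndarray:
    """DP matrix of longest complementary runs ending at (a[i], b[j]).

    a and b are both 5'→3'; complementarity is IUPAC-aware (sets of a[i] and
    of the complement of b[j] intersect).
    """
    rb = reverse_complement(b)  # run of a matching rb == complementary duplex
    sa, sb = _sets(a), _sets(rb)
    n, m = len(sa), len(sb)
    dp = np.zeros((n, m), dtype=np.int32)
    for i in range(n):
        for j in range(m):
            if sa[i] & sb[j]:
                dp[i, j] = (dp[i - 1, j - 1] if i and j else 0) + 1
    return dp


def longest_complementary_run(a: str, b: str) -> int:
    """Length of the longest perfect complementary duplex between any
    substring of ``a`` and any substring of ``b``."""
    dp = _complementary_run_matrix(a, b)
    return int(dp.max()) if dp.size else 0


def three_prime_anchored_run(a: str, b: str) -> int:
    """Longest complementary run that ends at ``a``'s 3' terminus."""
    dp = _complementary_run_matrix(a, b)
    return int(dp[-1].max()) if dp.size else 0


def pair_compatibility(
    fw: PrimerRecord,
    rv: PrimerRecord,
    fw_site_start: int,
    rv_site_end: int,
    max_delta_tm: float = 5.0,
    max_three_prime_run: int = 5,
) -> PairReport:
    """Evaluate a forward/reverse pair.

    ``fw_site_start`` and ``rv_site_end`` are 1-based coordinates on the
    ungapped target consensus: the 5'-most position of the forward binding
    site and the 3'-most position of the reverse binding site, so the
    predicted amplicon is their inclusive span.  The pair passes if
    |ΔTm| ≤ ``max_delta_tm`` and the longest 3'-anchored complementary run
    between the two primers is below ``max_three_prime_run``.
    """
    amplicon = rv_site_end - fw_site_start + 1
    if amplicon <= 0:
        raise GeometryError(
            f"reverse site end ({rv_site_end}) must lie downstream of the "
            f"forward site start ({fw_site_start})"
        )
    delta_tm = abs(fw.tm_celsius - rv.tm_celsius)
    hetero = longest_complementary_run(fw.sequence, rv.sequence)
    anchored = max(
        three_prime_anchored_run(fw.sequence, rv.sequence),
        three_prime_anchored_run(rv.sequence, fw.sequence),
    )
    return PairReport(
        forward=fw,
        reverse=rv,
        delta_tm=delta_tm,
        predicted_amplicon_bp=amplicon,
        heterodimer_score=hetero,
        three_prime_anchored=anchored,
        passes=delta_tm <= max_delta_tm and anchored < max_three_prime_run,
    )
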