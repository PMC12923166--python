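# Methods

## Model and procedure

The package searches a labeled multiple sequence alignment for windows
where a single primer sequence separates a target taxon set from an
exclusion (host) set. The unit of comparison is the *degapped window
string*: for each window of the configured primer length, the aligned
slice of every covering sequence is taken and its gap characters removed,
so an internal indel shortens that sequence's variant rather than
invalidating the comparison. The most abundant target variant is the
primer candidate; ties break to the variant first seen in record order,
which makes the whole scan deterministic.

Distances between candidate and variants are global Levenshtein edit
distances (unit-cost substitutions and indels), computed with edlib. Each
set's variants are binned at exactly 0, 1, 2, 3 and ≥4 mismatches, with
abundance weighting: the profile describes fractions of *sequences*, not
of unique variants, because downstream coverage claims ("80% of fungi")
are about sequences. A flagless switch to variant weighting was considered
and rejected to keep the report's semantics aligned with coverage
percentages.

The discriminative score averages the cumulative profile difference over
the first *mm* mismatch classes:

    score = (1/mm) * sum_{k=1..mm} ( T(k) - E(k) ),

T(k) and E(k) being the fractions of target and exclusion sequences within
k−1 mismatches of the candidate. The indexing is anchored by the perfect
case: an all-identical target set against an all-≥mm exclusion set must
score exactly 1. The score is mathematically confined to [−1, 1]; it is
reported unclamped, so a window where the host matches the candidate
better than the target set goes negative and is removed by the default
filter (score ≥ 0.5, inclusive). The practical range of *filtered* output
is therefore [0.5, 1].

## Preprocessing

Terminal gap runs — artifacts of partial database records — are masked per
sequence as everything outside the (first, last) non-gap column. A masked
position neither contributes a gap to column statistics nor counts in the
denominator, so a handful of partial sequences cannot delete a conserved
column; this coverage-aware reading of the 20% trim rule is a design
choice of this package. Columns whose internal-gap plus ambiguity fraction
exceeds the threshold (default 0.20, strictly greater) are removed, and a
trimmed→original column map is kept; reports carry both coordinate frames,
1-based inclusive. Trimming is idempotent: removing a column can only turn
former internal gaps of a record into terminal ones, which lowers, never
raises, the badness of the remaining columns.

A window only counts sequences whose mask spans it entirely; windows with
zero covered target or exclusion sequences are skipped and logged.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `window_length` | 20 bp | primer length the window slides at; one length per run |
| `mm` | 2 | depth of the cumulative score average |
| `min_score` | 0.5 | filter floor, inclusive |
| `max_gap_col_frac` | 0.20 | column trim threshold (strict >) |
| `max_gaps`, `max_ambiguous` | 0 | tolerated gaps / non-ACGT in a candidate |
| Tm conditions | 50 mM Na⁺, 25 nM each strand | nearest-neighbor model conditions |
| ΔTm / 3′-run pair thresholds | 5 °C / 5 bp | pair compatibility limits |

## Primer evaluation

GC content of degenerate primers is the expectation over the IUPAC set at
each position (S counts 1, Y counts 0.5). Melting temperatures use the
nearest-neighbor model via Biopython (Allawi & SantaLucia parameters) at
the conditions above; degenerate primers are averaged over their
expansions up to a cap of 64, beyond which a fixed-seed sample of 64
expansions is averaged. The Wallace rule is available for quick screens.

Coverage of a reference set is a both-strand sliding Hamming match with
IUPAC-aware equality (a reference base matches where it lies inside the
primer position's set), reported cumulatively at 0/1/2 mismatches. This
matcher is a from-scratch in-silico probe implementation; indels are
deliberately excluded from it (unlike the scanner's edit distance) because
probe-style binding-site counts are positional.

The 3′-end check compares the primer's last k positions (default 3)
against the exclusion variants right-aligned, and passes when the terminal
base mismatches a configurable fraction (default all) of them; variants
whose length differs by more than 2 cannot be compared positionally and
are excluded with a flag. Degenerate consensus proposal is greedy: the
single-base IUPAC addition with the best exact-match coverage gain per
unit of added degeneracy is applied until the goal or the cap is reached;
the greedy search only takes strictly improving steps, so it can stall
below the goal when no single addition helps (e.g. variants differing at
many positions at once), in which case the best effort is returned
flagged.

Heterodimer likelihood is a longest-perfect-complementary-run heuristic
(longest common substring between one primer and the reverse complement
of the other, IUPAC-aware), with the 3′-anchored run reported separately
since 3′-anchored duplexes are the ones that prime. This is a documented
simplification of full duplex thermodynamics; thresholds are configurable
and the score is a length in bp, not an energy.

## Synthetic data generator

The generator emulates a conserved marker alignment shared by both sets: a
single master sequence copied to every row with 2% per-cell substitution
noise (default `background_identity` 0.98, chosen so that no background
window is systematically discriminative while rows are not artificially
identical), plus planted windows where each row carries an exactly
prescribed number of substitutions against a known candidate 20-mer.
Mismatch-class counts are apportioned by largest remainder, so the
recorded expected profiles are the *realized* fractions — with 50
exclusion rows a requested 0.95 site realizes 48/50 and an expected score
of 0.94 — and every planted variant is verified with the same edit
distance the scanner uses, since k substitutions can otherwise collapse
into a cheaper indel alignment. Random internal gaps and terminal
truncations are kept outside the planted windows so the ground truth stays
exact.

What the generator does not emulate: phylogenetic correlation between
rows, substitution-model heterogeneity, alignment errors, and chimeric or
low-quality database records. Passing the planted-site recovery tests
therefore shows the scanner computes its own model correctly on clean
planted signal, not that real SSU/LSU alignments will yield primers of any
particular score.

Reference sets for coverage testing embed a primer mutated at prescribed
positions inside random flanks, half of the records reverse-complemented,
each verified against the coverage matcher.

## Numerical choices and problem sizes

Profiles must sum to 1 within 1e-9; scores are exact rational arithmetic
in floating point with no clamping. Candidate names are `mbc-<1-based
trimmed start>`; reports round scores to 4 decimals and profile bins to
0.1 percentage points, and identical inputs reproduce byte-identical
reports. The bundled reproduction script uses a 150-sequence, 600-column
alignment with five planted windows and 10,000 random Dirichlet profile
pairs — sizes at which the full pipeline completes in seconds while
leaving the planted fractions exactly representable or within one row of
exact.

## Known limitations

- One window length per run; scanning several lengths means several runs.
- The degenerate-consensus search is greedy and can miss multi-position
  generalizations.
- The heterodimer heuristic ignores mismatched and bulged duplexes.
- The coverage matcher is Hamming-based; a reference with an indel inside
  the binding site is scored as a heavy mismatch rather than a shifted hit.
- Negative and zero scores are meaningful internally but are not reported
  under default filtering.
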