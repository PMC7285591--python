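"""Secondary-structure screening for negative-set construction.

Aptamers fold into stable stem-loop structures; random sequences that do
not share those structural signatures make good negative examples for
aptamer prediction.  This module parses dot-bracket structures into loop
and stem statistics, provides an internal maximum-base-pairing (Nussinov)
folder as a fallback folding engine, classifies records as aptamer-like or
not, and generates screened negative sets whose length distribution and
base composition match a positive aptamer set.

The external folding-engine contract is RNAfold-style text output (name,
sequence, dot-bracket with an energy in kcal/mol); the internal fallback
reports a pseudo-energy of minus the base-pair count, which is on a
different scale from a thermodynamic minimum free energy (see
ScreeningThresholds for how the defaults account for that).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from aptapred.seqio import SequenceRecord

#: allowed base pairs (T treated as U): Watson-Crick plus G-U wobble
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _can_pair(a: str, b: str) -> bool:
    a = "U" if a == "T" else a
    b = "U" if b == "T" else b
    return (a, b) in _PAIRS


@dataclass(frozen=True)
class StructureStats:
    pair_count: int
    hairpin_count: int
    bulge_count: int
    internal_loop_count: int
    multiloop_count: int
    stem_count: int
    longest_stem: int
    unpaired_fraction: float
    energy_density: float


@dataclass(frozen=True)
class StructureRecord:
    """A sequence with its (nested) secondary structure and derived statistics."""

    sequence: SequenceRecord
    dotbracket: str
    energy: float
    stats: StructureStats


def _pair_table(db: str) -> dict[int, int]:
    """Stack-parse a dot-bracket string into an i->j pair map (both directions)."""
    if re.search(r"[^().]", db):
        raise ValueError("dot-bracket may contain only '(', ')' and '.'")
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket: unmatched ')' at {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
    if stack:
        raise ValueError(
            f"unbalanced dot-bracket: unmatched '(' at {stack[-1]}"
        )
    return pairs


def parse_dotbracket(
    seq: SequenceRecord, db_string: str, energy: float
) -> StructureRecord:
    """Parse a dot-bracket structure into loop/stem statistics.

    Loops enclosed by a pair (i, j) are classified by their directly nested
    pairs: none -> hairpin; one nested pair flush on both sides -> stack
    (part of a stem); one nested pair with a gap on exactly one side ->
    bulge; gaps on both sides -> internal loop; two or more nested pairs ->
    multiloop.
    """
    if len(db_string) != len(seq.residues):
        raise ValueError(
            f"structure length {len(db_string)} != sequence length {len(seq)}"
        )
    pairs = _pair_table(db_string)
    n = len(db_string)
    opening = sorted(i for i, j in pairs.items() if i < j)

    hairpins = bulges = internal = multi = 0
    for i in opening:
        j = pairs[i]
        # directly nested opening pairs inside (i, j)
        children = []
        k = i + 1
        while k < j:
            if db_string[k] == "(":
                children.append(k)
                k = pairs[k] + 1
            else:
                k += 1
        if not children:
            hairpins += 1
        elif len(children) == 1:
            k = children[0]
            l = pairs[k]
            left_gap = k - i - 1
            right_gap = j - l - 1
            if left_gap == 0 and right_gap == 0:
                pass  # stacked pair, part of a stem
            elif left_gap == 0 or right_gap == 0:
                bulges += 1
            else:
                internal += 1
        else:
            multi += 1

    # stems: maximal runs of directly stacked pairs
    stem_count = 0
    longest = 0
    run = 0
    prev_stacked = False
    for i in opening:
        j = pairs[i]
        if prev_stacked and pairs.get(i - 1) == j + 1:
            run += 1
        else:
            if run:
                stem_count += 1
                longest = max(longest, run)
            run = 1
        prev_stacked = True
    if run:
        stem_count += 1
        longest = max(longest, run)

    pair_count = len(opening)
    unpaired = n - 2 * pair_count
    stats = StructureStats(
        pair_count=pair_count,
        hairpin_count=hairpins,
        bulge_count=bulges,
        internal_loop_count=internal,
        multiloop_count=multi,
        stem_count=stem_count,
        longest_stem=longest,
        unpaired_fraction=unpaired / n,
        energy_density=energy / n,
    )
    return StructureRecord(seq, db_string, float(energy), stats)


def nussinov_fold(
    seq: SequenceRecord | str, min_loop: int = 3
) -> tuple[str, int, float]:
    """Maximum base-pairing fold (Nussinov dynamic program).

    Returns (dot-bracket, pair count, pseudo-energy), where the
    pseudo-energy is minus the pair count — a structural score, not a
    thermodynamic minimum free energy.  Hairpin loops must contain at
    least ``min_loop`` unpaired bases; allowed pairs are A-U/T, G-C and
    the G-U wobble.
    """
    s = seq.residues if isinstance(seq, SequenceRecord) else seq.upper()
    if re.search(r"[^ACGTU]", s):
        raise ValueError("nussinov_fold: sequence has letters outside ACGTU")
    n = len(s)
    # best[i][j] = max pairs in s[i..j] inclusive; fill by increasing span
    best = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            # j unpaired
            score = best[i][j - 1]
            # j pairs with k in [i, j-min_loop-1]
            for k in range(i, j - min_loop):
                if _can_pair(s[k], s[j]):
                    left = best[i][k - 1] if k > i else 0
                    inner = best[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    cand = left + inner + 1
                    if cand > score:
                        score = cand
            best[i][j] = score

    db = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        if best[i][j] == best[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_loop):
            if _can_pair(s[k], s[j]):
                left = best[i][k - 1] if k > i else 0
                inner = best[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if left + inner + 1 == best[i][j]:
                    db[k] = "("
                    db[j] = ")"
                    if k > i:
                        stack.append((i, k - 1))
                    if k + 1 <= j - 1:
                        stack.append((k + 1, j - 1))
                    break
    pair_count = int(best[0][n - 1]) if n > 0 else 0
    return "".join(db), pair_count, float(-pair_count)


def fold_record(seq: SequenceRecord, min_loop: int = 3) -> StructureRecord:
    """Fold with the internal engine and parse into a StructureRecord."""
    db, _, energy = nussinov_fold(seq, min_loop=min_loop)
    return parse_dotbracket(seq, db, energy)


@dataclass(frozen=True)
class ScreeningThresholds:
    """Cut-offs defining "aptamer-like" structure.

    A record is aptamer-like iff

        energy_density <= max_energy_density
        AND unpaired_fraction <= max_unpaired_fraction
        AND hairpin_count >= min_hairpins
        AND longest_stem >= min_longest_stem

    The defaults are calibrated to the internal fallback's pseudo-energy
    scale (-pair_count / length, so energy density is -0.5 * paired
    fraction): a canonical stable hairpin passes, while poorly pairing or
    weakly stacked sequences fail.  When using a thermodynamic external
    engine, supply kcal/mol-scale cut-offs instead.
    """

    max_energy_density: float = -0.37
    max_unpaired_fraction: float = 0.26
    min_hairpins: int = 1
    min_longest_stem: int = 4

    def __post_init__(self) -> None:
        for v in (self.max_energy_density, self.max_unpaired_fraction):
            if not np.isfinite(v):
                raise ValueError("thresholds must be finite")


APTAMER_LIKE = "aptamer-like"
NOT_APTAMER_LIKE = "not-aptamer-like"


def aptamer_likeness(
    record: StructureRecord, thresholds: ScreeningThresholds | None = None
) -> str:
    """Classify a structure as aptamer-like or not under the thresholds."""
    t = thresholds or ScreeningThresholds()
    st = record.stats
    ok = (
        st.energy_density <= t.max_energy_density
        and st.unpaired_fraction <= t.max_unpaired_fraction
        and st.hairpin_count >= t.min_hairpins
        and st.longest_stem >= t.min_longest_stem
    )
    return APTAMER_LIKE if ok else NOT_APTAMER_LIKE


def read_structure_file(
    path, molecule: str
) -> list[StructureRecord]:
    """Parse RNAfold-style text output: per record a '>name' line, the
    sequence line, and a dot-bracket line ending in '(energy)'."""
    records = []
    lines = [ln.rstrip("\n") for ln in Path(path).open() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected '>' header at line {i + 1}")
        name = lines[i][1:].split()[0]
        seq = SequenceRecord(name, lines[i + 1].strip(), molecule)
        m = re.match(r"^([().]+)\s+\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$", lines[i + 2])
        if not m:
            raise ValueError(f"malformed structure line {i + 3}: {lines[i + 2]!r}")
        records.append(parse_dotbracket(seq, m.group(1), float(m.group(2))))
        i += 3
    return records


def length_stats(
    seqs: Sequence[SequenceRecord], lo: int = 30, hi: int = 80
) -> tuple[int, float, dict[int, int]]:
    """(modal length, fraction of lengths within [lo, hi], length histogram).

    The mode breaks ties toward the smallest length.
    """
    if not seqs:
        raise ValueError("empty sequence list")
    lengths = [len(s) for s in seqs]
    hist = Counter(lengths)
    top = max(hist.values())
    mode = min(length for length, c in hist.items() if c == top)
    frac = sum(1 for L in lengths if lo <= L <= hi) / len(lengths)
    return mode, frac, dict(sorted(hist.items()))


def generate_negatives(
    positives: Sequence[SequenceRecord],
    n: int,
    thresholds: ScreeningThresholds | None = None,
    seed: int = 0,
    min_loop: int = 3,
    max_attempts: int | None = None,
    min_acceptance: float = 0.01,
    fold: Callable[[SequenceRecord], StructureRecord] | None = None,
) -> tuple[list[SequenceRecord], dict]:
    """Generate ``n`` structurally screened negative sequences.

    Candidate lengths (and molecule kinds) are drawn from the positive
    set's empirical distribution; candidate bases are i.i.d. draws from
    the positive set's per-molecule mononucleotide frequencies.  A
    candidate is kept iff its fold is NOT aptamer-like under
    ``thresholds``.  Returns the accepted records plus rejection
    statistics.  Raises if the acceptance rate stays below
    ``min_acceptance`` after a bounded number of attempts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not positives:
        raise ValueError("positives must be non-empty")
    thresholds = thresholds or ScreeningThresholds()
    fold = fold or (lambda rec: fold_record(rec, min_loop=min_loop))
    if max_attempts is None:
        max_attempts = max(50 * n, 2000)

    rng = np.random.default_rng(seed)
    base_freqs: dict[str, np.ndarray] = {}
    for mol in {p.molecule for p in positives}:
        counts = np.zeros(4)
        for p in positives:
            if p.molecule == mol:
                canon = p.residues.replace("U", "T")
                for i, b in enumerate("ACGT"):
                    counts[i] += canon.count(b)
        base_freqs[mol] = counts / counts.sum()

    # candidate lengths follow the positives' length assignment: templates
    # are consumed in permuted order, cycling if n exceeds the positive count
    order = rng.permutation(len(positives))
    accepted: list[SequenceRecord] = []
    attempts = 0
    rejected = 0
    per_template_cap = 200
    for slot in range(n):
        template = positives[order[slot % len(positives)]]
        mol = template.molecule
        letters = list("ACGU" if mol == "RNA" else "ACGT")
        for _ in range(per_template_cap):
            if attempts >= max_attempts:
                rate = len(accepted) / max(attempts, 1)
                raise RuntimeError(
                    f"negative generation acceptance rate {rate:.3f} below "
                    f"floor {min_acceptance} after {attempts} attempts; "
                    "thresholds are too aptamer-permissive"
                )
            bases = rng.choice(letters, size=len(template), p=base_freqs[mol])
            candidate = SequenceRecord(
                f"negative_{len(accepted) + 1}", "".join(bases), mol
            )
            attempts += 1
            record = fold(candidate)
            if aptamer_likeness(record, thresholds) == NOT_APTAMER_LIKE:
                accepted.append(candidate)
                break
            rejected += 1
            if attempts >= 200 and len(accepted) / attempts < min_acceptance:
                raise RuntimeError(
                    f"negative generation acceptance rate "
                    f"{len(accepted) / attempts:.3f} below floor "
                    f"{min_acceptance} after {attempts} attempts; thresholds "
                    "are too aptamer-permissive"
                )
        else:
            raise RuntimeError(
                f"could not generate a screen-failing sequence of length "
                f"{len(template)} within {per_template_cap} attempts"
            )
    log = {"attempts": attempts, "accepted": n, "rejected": rejected,
           "acceptance_rate": n / attempts}
    return accepted, log
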