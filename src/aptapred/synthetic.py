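"""Synthetic fixture generation.

Produces data with the shapes of the real study inputs so that every
pipeline stage can be exercised end-to-end without the original tables:

* random valid protein / DNA / RNA sequences,
* an aptamer-like length sampler (modal length 40 nt, secondary peaks at
  30, 50 and 80 nt, ~80% of lengths inside [30, 80] nt),
* stem-loop structured "aptamer" sequences that pass the secondary
  structure screen (real aptamers fold into stable stems; the generator
  builds the stem explicitly: left arm + loop + reverse-complement arm,
  embedded in random flanks),
* planted-signal protein-aptamer pair tables: interacting and
  non-interacting pairs whose sequences are drawn from class-specific
  residue/base frequency profiles separated by a configurable logit shift
  (shift 0 -> no signal, AUC ~ 0.5 by construction),
* emulated interaction tables at the published partition sizes
  (561/1682 training and 143/421 test pairs after the problematic-sequence
  filter, with injected problematic rows for the filter to remove; 704
  positive aptamers and 700 screened negatives).

All draws are reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from aptapred.seqio import PairRecord, SequenceRecord, write_fasta
from aptapred.structure_screen import (
    ScreeningThresholds,
    aptamer_likeness,
    fold_record,
    generate_negatives,
)

AA = "ACDEFGHIKLMNPQRSTVWY"

#: published dataset shape: pair partitions after filtering
PAIR_TRAIN_POS, PAIR_TRAIN_NEG = 561, 1682
PAIR_TEST_POS, PAIR_TEST_NEG = 143, 421
#: published dataset shape: aptamer prediction set
N_APTAMER_POS, N_APTAMER_NEG = 704, 700

#: default planted composition shift (logit scale) between interacting and
#: non-interacting pair classes; chosen to give clear feature-space
#: separation, the fixture's purpose
DEFAULT_SHIFT = 1.0


def _length_distribution() -> tuple[np.ndarray, np.ndarray]:
    """Aptamer length distribution: support 15-120 nt, mode 40, peaks at
    30/50/80, 80% of mass in [30, 80]."""
    lengths = np.arange(15, 121)
    p = np.zeros(len(lengths), dtype=float)
    idx = {L: i for i, L in enumerate(lengths)}
    p[idx[40]] = 0.16
    p[idx[30]] = 0.10
    p[idx[50]] = 0.10
    p[idx[80]] = 0.08
    bulk = [L for L in range(31, 80) if L not in (40, 50)]
    p[[idx[L] for L in bulk]] = 0.36 / len(bulk)
    low = list(range(15, 30))
    p[[idx[L] for L in low]] = 0.10 / len(low)
    high = list(range(81, 121))
    p[[idx[L] for L in high]] = 0.10 / len(high)
    return lengths, p / p.sum()


def sample_aptamer_lengths(n: int, rng: np.random.Generator) -> np.ndarray:
    lengths, p = _length_distribution()
    return rng.choice(lengths, size=n, p=p)


def _shifted_freqs(
    base: np.ndarray, direction: np.ndarray, shift: float
) -> np.ndarray:
    logits = np.log(base) + shift * direction
    w = np.exp(logits - logits.max())
    return w / w.sum()


def _random_seq(
    rng: np.random.Generator, alphabet: str, length: int, freqs: np.ndarray
) -> str:
    return "".join(rng.choice(list(alphabet), size=length, p=freqs))


@dataclass(frozen=True)
class PairSignalProfiles:
    """Class-conditional residue/base frequency profiles for pair fixtures."""

    protein_pos: np.ndarray
    protein_neg: np.ndarray
    base_pos: np.ndarray
    base_neg: np.ndarray

    @staticmethod
    def build(shift: float, rng: np.random.Generator) -> "PairSignalProfiles":
        aa_base = np.full(20, 1 / 20)
        nt_base = np.full(4, 1 / 4)
        aa_dir = rng.standard_normal(20)
        aa_dir /= np.abs(aa_dir).max()
        nt_dir = rng.standard_normal(4)
        nt_dir /= np.abs(nt_dir).max()
        return PairSignalProfiles(
            protein_pos=_shifted_freqs(aa_base, aa_dir, +shift / 2),
            protein_neg=_shifted_freqs(aa_base, aa_dir, -shift / 2),
            base_pos=_shifted_freqs(nt_base, nt_dir, +shift / 2),
            base_neg=_shifted_freqs(nt_base, nt_dir, -shift / 2),
        )


def random_proteins(
    n: int,
    rng: np.random.Generator,
    min_len: int = 60,
    max_len: int = 300,
    freqs: np.ndarray | None = None,
    prefix: str = "prot",
) -> list[SequenceRecord]:
    freqs = np.full(20, 1 / 20) if freqs is None else freqs
    out = []
    for i in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        out.append(SequenceRecord(f"{prefix}_{i + 1}", _random_seq(rng, AA, L, freqs), "protein"))
    return out


def random_nucleotides(
    n: int,
    rng: np.random.Generator,
    molecule: str = "DNA",
    min_len: int = 20,
    max_len: int = 100,
    freqs: np.ndarray | None = None,
    prefix: str = "nt",
) -> list[SequenceRecord]:
    alphabet = "ACGU" if molecule == "RNA" else "ACGT"
    freqs = np.full(4, 1 / 4) if freqs is None else freqs
    out = []
    for i in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        out.append(
            SequenceRecord(f"{prefix}_{i + 1}", _random_seq(rng, alphabet, L, freqs), molecule)
        )
    return out


_COMPLEMENT = {"A": "T", "T": "A", "U": "A", "C": "G", "G": "C"}

#: first-order base-step bias in synthetic stems: probability that the next
#: stem base is the preferred strong-stacking partner of the current one
#: (G<->C alternation); emulates the enrichment of strong G:C stacking
#: steps in selected aptamer stems
STEM_STEP_BIAS = 0.55


def _revcomp(s: str, molecule: str) -> str:
    comp = "".join(_COMPLEMENT[c] for c in reversed(s))
    return comp.replace("T", "U") if molecule == "RNA" else comp


def _markov_arm(length: int, rng: np.random.Generator, bias: float) -> str:
    """Stem arm with enriched strong base steps: from each base the
    preferred next base (G->C, C->G, A->C, T->G) has probability ``bias``."""
    bases = "ACGT"
    prefer = {"G": "C", "C": "G", "A": "C", "T": "G"}
    trans = {}
    for b in bases:
        p = np.full(4, (1.0 - bias) / 3.0)
        p[bases.index(prefer[b])] = bias
        trans[b] = p
    out = [str(rng.choice(list("GC")))]
    for _ in range(length - 1):
        out.append(bases[int(rng.choice(4, p=trans[out[-1]]))])
    return "".join(out)


def stem_loop_sequence(
    length: int,
    molecule: str,
    rng: np.random.Generator,
    loop_len: int = 4,
    step_bias: float = STEM_STEP_BIAS,
) -> str:
    """A sequence folding into a long hairpin: flank + arm + loop +
    reverse-complement(arm) + flank, with step-biased arms."""
    alphabet = "ACGU" if molecule == "RNA" else "ACGT"
    flank_total = max(0, int(rng.integers(0, max(1, length // 6))))
    arm = (length - loop_len - flank_total) // 2
    arm = max(6, arm)
    loop = length - 2 * arm - flank_total
    if loop < 3:
        flank_total = max(0, length - 2 * arm - 3)
        loop = length - 2 * arm - flank_total
    left_flank = flank_total // 2
    right_flank = flank_total - left_flank
    uniform = np.full(4, 1 / 4)
    armseq = _markov_arm(arm, rng, step_bias)
    if molecule == "RNA":
        armseq = armseq.replace("T", "U")
    parts = [
        _random_seq(rng, alphabet, left_flank, uniform),
        armseq,
        _random_seq(rng, alphabet, max(loop, 3), uniform),
        _revcomp(armseq, molecule),
        _random_seq(rng, alphabet, right_flank, uniform),
    ]
    return "".join(parts)


def synthesize_aptamers(
    n: int,
    rng: np.random.Generator,
    molecules: tuple[str, ...] = ("DNA", "RNA"),
    thresholds: ScreeningThresholds | None = None,
    prefix: str = "aptamer",
) -> list[SequenceRecord]:
    """Stem-loop structured sequences that pass the aptamer-likeness screen.

    Lengths follow the aptamer length distribution; molecule kinds
    alternate through ``molecules``.  Each sequence is verified
    aptamer-like (re-drawn if the random flanks spoil the structure).
    """
    thresholds = thresholds or ScreeningThresholds()
    lengths = sample_aptamer_lengths(n, rng)
    out: list[SequenceRecord] = []
    for i, L in enumerate(lengths):
        mol = molecules[i % len(molecules)]
        L = max(int(L), 20)
        for _ in range(100):
            seq = stem_loop_sequence(L, mol, rng)
            rec = SequenceRecord(f"{prefix}_{i + 1}", seq, mol)
            if aptamer_likeness(fold_record(rec), thresholds) == "aptamer-like":
                out.append(rec)
                break
        else:  # pragma: no cover - the hairpin construction essentially always passes
            raise RuntimeError(f"failed to synthesize aptamer-like sequence of length {L}")
    return out


def make_pair_records(
    n_pos: int,
    n_neg: int,
    rng: np.random.Generator,
    profiles: PairSignalProfiles,
    molecule: str = "DNA",
    name_prefix: str = "train",
) -> list[PairRecord]:
    """Planted-signal pair records: sequence composition depends on the label."""
    pairs: list[PairRecord] = []
    labels = [1] * n_pos + [0] * n_neg
    for i, label in enumerate(labels):
        p_freq = profiles.protein_pos if label else profiles.protein_neg
        b_freq = profiles.base_pos if label else profiles.base_neg
        protein = random_proteins(
            1, rng, freqs=p_freq, prefix=f"{name_prefix}_prot{i + 1}"
        )[0]
        L = max(15, int(sample_aptamer_lengths(1, rng)[0]))
        alphabet = "ACGU" if molecule == "RNA" else "ACGT"
        aptamer = SequenceRecord(
            f"{name_prefix}_apt{i + 1}", _random_seq(rng, alphabet, L, b_freq), molecule
        )
        pairs.append(PairRecord(protein, aptamer, label))
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


def _inject_problematic(
    pairs: list[PairRecord], n_bad: int, rng: np.random.Generator, name_prefix: str
) -> list[PairRecord]:
    """Append rows whose aptamer the problematic-sequence filter must remove."""
    out = list(pairs)
    kinds = ["N", "B", "UT"]
    for i in range(n_bad):
        template = pairs[int(rng.integers(0, len(pairs)))]
        s = list(template.aptamer.residues)
        kind = kinds[i % 3]
        pos = int(rng.integers(0, len(s)))
        if kind == "UT":
            # ensure both U and T appear
            s[pos] = "U"
            if "T" not in s:
                s[(pos + 1) % len(s)] = "T"
        else:
            s[pos] = kind
        bad = SequenceRecord(
            f"{name_prefix}_bad{i + 1}", "".join(s), template.aptamer.molecule
        )
        out.append(PairRecord(template.protein, bad, template.label))
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def pairs_to_frame(pairs: list[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [p.protein.name for p in pairs],
            "protein_seq": [p.protein.residues for p in pairs],
            "aptamer_id": [p.aptamer.name for p in pairs],
            "aptamer_seq": [p.aptamer.residues for p in pairs],
            "label": [p.label for p in pairs],
        }
    )


@dataclass(frozen=True)
class FixtureSizes:
    """Problem sizes for the fixture bundle; defaults are the published
    dataset shapes."""

    train_pos: int = PAIR_TRAIN_POS
    train_neg: int = PAIR_TRAIN_NEG
    test_pos: int = PAIR_TEST_POS
    test_neg: int = PAIR_TEST_NEG
    aptamer_pos: int = N_APTAMER_POS
    aptamer_neg: int = N_APTAMER_NEG
    problematic_fraction: float = 0.03


@dataclass(frozen=True)
class FixtureBundle:
    pairs_train: list[PairRecord]  # includes problematic rows, pre-filter
    pairs_test: list[PairRecord]
    aptamer_positives: list[SequenceRecord]
    aptamer_negatives: list[SequenceRecord]
    negatives_log: dict


def make_fixtures(
    seed: int = 0,
    sizes: FixtureSizes | None = None,
    shift: float = DEFAULT_SHIFT,
    thresholds: ScreeningThresholds | None = None,
    molecule: str = "DNA",
    aptamer_molecules: tuple[str, ...] = ("DNA", "RNA"),
) -> FixtureBundle:
    """Generate the full fixture bundle (pair tables + aptamer sets)."""
    sizes = sizes or FixtureSizes()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2024]))
    profiles = PairSignalProfiles.build(shift, rng)

    train = make_pair_records(
        sizes.train_pos, sizes.train_neg, rng, profiles, molecule, "train"
    )
    test = make_pair_records(
        sizes.test_pos, sizes.test_neg, rng, profiles, molecule, "test"
    )
    n_bad_train = int(round(sizes.problematic_fraction * len(train)))
    n_bad_test = int(round(sizes.problematic_fraction * len(test)))
    train = _inject_problematic(train, n_bad_train, rng, "train")
    test = _inject_problematic(test, n_bad_test, rng, "test")

    positives = synthesize_aptamers(
        sizes.aptamer_pos, rng, molecules=aptamer_molecules, thresholds=thresholds
    )
    negatives, log = generate_negatives(
        positives, sizes.aptamer_neg, thresholds=thresholds,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return FixtureBundle(train, test, positives, negatives, log)


def write_fixture_bundle(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as FASTA + TSV files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pairs_train": outdir / "pairs_train.tsv",
        "pairs_test": outdir / "pairs_test.tsv",
        "aptamer_positives": outdir / "aptamer_positives.fasta",
        "aptamer_negatives": outdir / "aptamer_negatives.fasta",
    }
    pairs_to_frame(bundle.pairs_train).to_csv(paths["pairs_train"], sep="\t", index=False)
    pairs_to_frame(bundle.pairs_test).to_csv(paths["pairs_test"], sep="\t", index=False)
    write_fasta(bundle.aptamer_positives, paths["aptamer_positives"])
    write_fasta(bundle.aptamer_negatives, paths["aptamer_negatives"])
    return paths
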