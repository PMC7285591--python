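"""Nucleotide (DNA/RNA) sequence encoders.

Three encodings with molecule-specific dinucleotide property tables:

* NAC — nucleotide composition: four frequencies (A, C, G, T/U),
* PseKNC — pseudo k-tuple nucleotide composition: normalized k-mer
  frequencies plus ``lam`` sequence-order correlation factors computed from
  the mean squared difference of the 11 standardized dinucleotide
  properties, jointly normalized to sum to 1,
* NMBAC — normalized Moreau-Broto autocorrelation: for each property and
  lag d, the average product of the standardized property profile with its
  d-shifted self over the sequence's L-1 dinucleotide positions.

DNA and RNA use separate property tables; a record's spelling (U vs T) is
canonicalized internally so encoding depends only on the base order and
the declared molecule kind.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from aptapred import _resources as res
from aptapred.features import FeatureVector
from aptapred.seqio import SequenceRecord

_BASES = "ACGT"  # canonical internal 4-letter index; U maps to the T slot
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _check_nucleotide(seq: SequenceRecord) -> str:
    if not seq.is_nucleotide:
        raise ValueError(f"record {seq.name!r} is not a nucleotide sequence")
    seq.validate()
    return seq.residues.replace("U", "T")


def encode_nac(seq: SequenceRecord) -> FeatureVector:
    """Nucleotide composition: frequencies of A, C, G and T/U."""
    s = _check_nucleotide(seq)
    counts = np.array([s.count(b) for b in _BASES], dtype=float)
    return FeatureVector(
        ("NAC_A", "NAC_C", "NAC_G", "NAC_TU"), counts / len(s)
    )


def _dinuc_profile(s: str, molecule: str) -> np.ndarray:
    """Standardized property values per dinucleotide position, shape (L-1, 11)."""
    table = res.dinucleotide_properties(molecule).to_numpy()  # (16, 11)
    idx = np.array(
        [4 * _BASE_INDEX[s[i]] + _BASE_INDEX[s[i + 1]] for i in range(len(s) - 1)]
    )
    return table[idx]


def encode_pseknc(
    seq: SequenceRecord,
    k: int = 2,
    lam: int = 10,
    w: float = 0.05,
    molecule: str | None = None,
) -> FeatureVector:
    """Pseudo k-tuple nucleotide composition (4^k + lam components)."""
    if molecule is not None and molecule != seq.molecule:
        raise ValueError(
            f"encoder configured for {molecule} but record {seq.name!r} is "
            f"{seq.molecule}; DNA and RNA use different property tables"
        )
    s = _check_nucleotide(seq)
    L = len(s)
    if k < 1 or lam < 1 or w <= 0:
        raise ValueError("require k >= 1, lam >= 1, w > 0")
    if L < k or L - 1 <= lam:
        raise ValueError(
            f"sequence {seq.name!r} (length {L}) too short for PseKNC with "
            f"k={k}, lam={lam}: need L >= k and L - 1 > lam"
        )
    # k-tuple frequencies over the canonical ACGT alphabet
    kmers = ["".join(p) for p in product(_BASES, repeat=k)]
    kmer_index = {m: i for i, m in enumerate(kmers)}
    counts = np.zeros(len(kmers))
    for i in range(L - k + 1):
        counts[kmer_index[s[i : i + k]]] += 1
    freqs = counts / counts.sum()

    profile = _dinuc_profile(s, seq.molecule)  # (L-1, 11)
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        diff = profile[: L - 1 - j] - profile[j:]
        thetas[j - 1] = np.mean((diff**2).mean(axis=1))

    denom = freqs.sum() + w * thetas.sum()
    values = np.concatenate([freqs, w * thetas]) / denom
    names = tuple(f"PseKNC_{m}" for m in kmers) + tuple(
        f"PseKNC_theta{j}" for j in range(1, lam + 1)
    )
    return FeatureVector(names, values)


def encode_nmbac(
    seq: SequenceRecord, max_lag: int = 10, molecule: str | None = None
) -> FeatureVector:
    """Normalized Moreau-Broto autocorrelation over the 11 dinucleotide properties.

    AC(p, d) = mean_i Pz_p(i) * Pz_p(i+d) over the L-1 dinucleotide
    positions, with Pz the per-table standardized property profile.
    """
    if molecule is not None and molecule != seq.molecule:
        raise ValueError(
            f"encoder configured for {molecule} but record {seq.name!r} is "
            f"{seq.molecule}"
        )
    s = _check_nucleotide(seq)
    L = len(s)
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if L - 1 <= max_lag:
        raise ValueError(
            f"sequence {seq.name!r} (length {L}) too short for NMBAC with "
            f"max_lag={max_lag}: need L - 1 > max_lag"
        )
    profile = _dinuc_profile(s, seq.molecule)  # (L-1, n_props)
    m = L - 1
    names, values = [], []
    for p_i, prop in enumerate(res.PROPERTY_NAMES):
        col = profile[:, p_i]
        for d in range(1, max_lag + 1):
            ac = float(np.mean(col[: m - d] * col[d:]))
            names.append(f"NMBAC_{prop}_lag{d}")
            values.append(ac)
    return FeatureVector(tuple(names), np.array(values))


@dataclass(frozen=True)
class NucleotideEncoderConfig:
    """Which nucleotide encoders to run, with parameters and molecule kind.

    The default runs NAC, PseKNC(k=2, lam=10, w=0.05) and NMBAC(11
    properties, max lag 10): 4 + 26 + 110 = 140 components.
    """

    encoders: tuple[str, ...] = ("nac", "pseknc", "nmbac")
    molecule: str = "DNA"
    pseknc_k: int = 2
    pseknc_lam: int = 10
    pseknc_w: float = 0.05
    nmbac_max_lag: int = 10

    def __post_init__(self) -> None:
        known = {"nac", "pseknc", "nmbac"}
        if not self.encoders:
            raise ValueError("empty nucleotide encoder config")
        bad = set(self.encoders) - known
        if bad:
            raise ValueError(f"unknown nucleotide encoders: {sorted(bad)}")
        if self.molecule not in ("DNA", "RNA"):
            raise ValueError("molecule must be DNA or RNA")

    @property
    def min_length(self) -> int:
        need = 1
        if "pseknc" in self.encoders:
            need = max(need, self.pseknc_k, self.pseknc_lam + 2)
        if "nmbac" in self.encoders:
            need = max(need, self.nmbac_max_lag + 2)
        return need


def encode_nucleotide(
    seq: SequenceRecord, config: NucleotideEncoderConfig | None = None
) -> FeatureVector:
    """Concatenate the configured encoders in fixed order."""
    config = config or NucleotideEncoderConfig()
    if seq.molecule != config.molecule:
        raise ValueError(
            f"config is for {config.molecule} but record {seq.name!r} is "
            f"{seq.molecule}; DNA and RNA must be encoded separately"
        )
    parts = []
    for enc in config.encoders:
        if enc == "nac":
            parts.append(encode_nac(seq))
        elif enc == "pseknc":
            parts.append(
                encode_pseknc(
                    seq, config.pseknc_k, config.pseknc_lam, config.pseknc_w,
                    molecule=config.molecule,
                )
            )
        elif enc == "nmbac":
            parts.append(
                encode_nmbac(seq, config.nmbac_max_lag, molecule=config.molecule)
            )
    return FeatureVector.concat(parts)
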