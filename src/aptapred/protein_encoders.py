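"""Protein sequence encoders.

Five encodings over the 20-letter amino-acid alphabet:

* AAC — amino-acid composition (20 frequencies),
* GAAC — grouped amino-acid composition over five physicochemical groups,
* PseAAC — Chou's type-1 pseudo amino-acid composition: the 20 residue
  frequencies augmented with ``lam`` sequence-order correlation factors
  built from standardized hydrophobicity, hydrophilicity and side-chain
  mass, jointly normalized so all 20+lam components sum to 1,
* CTDC — the composition part of the C/T/D descriptors: for each of seven
  physicochemical attributes, the frequencies of its three residue classes,
* SOCN — sequence-order-coupling numbers: for each distance d = 1..lam,
  the sum of squared pairwise distances d(R_i, R_{i+d}) under an
  amino-acid distance matrix (two matrices by default).

``encode_protein`` concatenates any subset in a fixed declared order with
encoder-prefixed component names.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from aptapred import _resources as res
from aptapred.features import FeatureVector
from aptapred.seqio import SequenceRecord

AA = res.AA_ORDER
_AA_INDEX = {a: i for i, a in enumerate(AA)}


def _check_protein(seq: SequenceRecord) -> str:
    if seq.molecule != "protein":
        raise ValueError(f"record {seq.name!r} is not a protein")
    seq.validate()
    return seq.residues


def _counts(residues: str) -> np.ndarray:
    counts = np.zeros(20)
    for ch in residues:
        counts[_AA_INDEX[ch]] += 1
    return counts


def encode_aac(seq: SequenceRecord) -> FeatureVector:
    """Amino-acid composition: count(a)/N for each of the 20 residues."""
    residues = _check_protein(seq)
    freqs = _counts(residues) / len(residues)
    return FeatureVector(tuple(f"AAC_{a}" for a in AA), freqs)


def encode_gaac(seq: SequenceRecord) -> FeatureVector:
    """Grouped composition over the five physicochemical groups, f(g) = N(g)/N."""
    residues = _check_protein(seq)
    groups = res.group_schemes()["gaac"]
    n = len(residues)
    names, values = [], []
    for gname, letters in groups.items():
        names.append(f"GAAC_{gname}")
        values.append(sum(residues.count(ch) for ch in letters) / n)
    return FeatureVector(tuple(names), np.array(values))


def encode_ctdc(seq: SequenceRecord) -> FeatureVector:
    """C/T/D composition: three class frequencies per physicochemical attribute."""
    residues = _check_protein(seq)
    n = len(residues)
    names, values = [], []
    for scheme, groups in res.group_schemes().items():
        if not scheme.startswith("ctd_"):
            continue
        prop = scheme[len("ctd_"):]
        for gname, letters in groups.items():
            names.append(f"CTDC_{prop}_{gname}")
            values.append(sum(residues.count(ch) for ch in letters) / n)
    return FeatureVector(tuple(names), np.array(values))


def encode_ctdt(seq: SequenceRecord) -> FeatureVector:
    """C/T/D transition: per attribute, frequencies of adjacent residue
    pairs that cross between each pair of classes, over N-1 adjacencies.

    Off the default feature set; enable via the encoder config.
    """
    residues = _check_protein(seq)
    n = len(residues)
    names, values = [], []
    for scheme, groups in res.group_schemes().items():
        if not scheme.startswith("ctd_"):
            continue
        prop = scheme[len("ctd_"):]
        gnames = list(groups)
        cls = {ch: g for g, letters in groups.items() for ch in letters}
        pair_counts = {}
        for a, b in zip(residues, residues[1:]):
            ga, gb = cls[a], cls[b]
            if ga != gb:
                key = tuple(sorted((ga, gb), key=gnames.index))
                pair_counts[key] = pair_counts.get(key, 0) + 1
        for i in range(3):
            for j in range(i + 1, 3):
                key = (gnames[i], gnames[j])
                names.append(f"CTDT_{prop}_{gnames[i]}.{gnames[j]}")
                values.append(
                    pair_counts.get(key, 0) / (n - 1) if n > 1 else 0.0
                )
    return FeatureVector(tuple(names), np.array(values))


#: quantiles of the distribution descriptor: first residue, then the
#: 25/50/75/100% occurrence positions
_CTDD_FRACTIONS = (0.0, 0.25, 0.50, 0.75, 1.00)


def encode_ctdd(seq: SequenceRecord) -> FeatureVector:
    """C/T/D distribution: per attribute and class, the relative sequence
    positions (percent of N) of the first, 25%, 50%, 75% and last
    occurrence; 0 for an absent class.

    Off the default feature set; enable via the encoder config.
    """
    residues = _check_protein(seq)
    n = len(residues)
    names, values = [], []
    for scheme, groups in res.group_schemes().items():
        if not scheme.startswith("ctd_"):
            continue
        prop = scheme[len("ctd_"):]
        for gname, letters in groups.items():
            positions = [i + 1 for i, ch in enumerate(residues) if ch in letters]
            for frac in _CTDD_FRACTIONS:
                names.append(f"CTDD_{prop}_{gname}_{int(frac * 100):03d}")
                if not positions:
                    values.append(0.0)
                    continue
                k = max(1, int(np.ceil(frac * len(positions))))
                values.append(100.0 * positions[k - 1] / n)
    return FeatureVector(tuple(names), np.array(values))


def _paac_theta(residues: str, lam: int) -> np.ndarray:
    """Sequence-order correlation factors theta_1..theta_lam.

    theta_j averages Theta(R_i, R_{i+j}) over i, where Theta is the mean
    squared difference of the three standardized property scales.
    """
    scales = res.paac_scales().to_numpy()  # (20, 3), standardized
    profile = scales[[_AA_INDEX[ch] for ch in residues]]  # (N, 3)
    n = len(residues)
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        diff = profile[: n - j] - profile[j:]
        thetas[j - 1] = np.mean((diff**2).mean(axis=1))
    return thetas


def encode_paac(seq: SequenceRecord, lam: int = 30, w: float = 0.05) -> FeatureVector:
    """Chou's type-1 pseudo amino-acid composition (20 + lam components)."""
    residues = _check_protein(seq)
    if lam < 1:
        raise ValueError("lam must be >= 1")
    if w <= 0:
        raise ValueError("w must be positive")
    if len(residues) <= lam:
        raise ValueError(
            f"sequence {seq.name!r} has length {len(residues)}; PseAAC with "
            f"lam={lam} requires length >= {lam + 1}"
        )
    freqs = _counts(residues) / len(residues)
    thetas = _paac_theta(residues, lam)
    denom = freqs.sum() + w * thetas.sum()
    values = np.concatenate([freqs, w * thetas]) / denom
    names = tuple(f"PseAAC_{a}" for a in AA) + tuple(
        f"PseAAC_theta{j}" for j in range(1, lam + 1)
    )
    return FeatureVector(names, values)


def encode_socn(
    seq: SequenceRecord,
    lam: int = 30,
    matrices: tuple[str, ...] = ("physchem", "grantham"),
) -> FeatureVector:
    """Sequence-order-coupling numbers f_d = sum_i d(R_i, R_{i+d})^2, d=1..lam.

    One block of lam values per distance matrix, physicochemical block
    first, then Grantham.
    """
    residues = _check_protein(seq)
    n = len(residues)
    if n <= lam:
        raise ValueError(
            f"sequence {seq.name!r} has length {n}; SOCN with lam={lam} "
            f"requires length >= {lam + 1}"
        )
    idx = np.array([_AA_INDEX[ch] for ch in residues])
    names, values = [], []
    for mat_name in matrices:
        mat = res.distance_matrix(mat_name).to_numpy()
        for d in range(1, lam + 1):
            fd = float((mat[idx[: n - d], idx[d:]] ** 2).sum())
            names.append(f"SOCN_{mat_name}_d{d}")
            values.append(fd)
    return FeatureVector(tuple(names), np.array(values))


@dataclass(frozen=True)
class ProteinEncoderConfig:
    """Which protein encoders to run, with their parameters.

    The default runs all five in the declared order AAC, PseAAC, GAAC,
    CTDC, SOCN, giving 20 + (20+30) + 5 + 21 + 60 = 156 components.
    """

    encoders: tuple[str, ...] = ("aac", "paac", "gaac", "ctdc", "socn")
    paac_lam: int = 30
    paac_w: float = 0.05
    socn_lam: int = 30
    socn_matrices: tuple[str, ...] = ("physchem", "grantham")

    def __post_init__(self) -> None:
        # ctdt / ctdd are available but off the default feature set
        known = {"aac", "paac", "gaac", "ctdc", "socn", "ctdt", "ctdd"}
        if not self.encoders:
            raise ValueError("empty protein encoder config")
        bad = set(self.encoders) - known
        if bad:
            raise ValueError(f"unknown protein encoders: {sorted(bad)}")

    @property
    def min_length(self) -> int:
        need = 1
        if "paac" in self.encoders:
            need = max(need, self.paac_lam + 1)
        if "socn" in self.encoders:
            need = max(need, self.socn_lam + 1)
        return need


def encode_protein(
    seq: SequenceRecord, config: ProteinEncoderConfig | None = None
) -> FeatureVector:
    """Concatenate the configured encoders in fixed order."""
    config = config or ProteinEncoderConfig()
    parts = []
    for enc in config.encoders:
        if enc == "aac":
            parts.append(encode_aac(seq))
        elif enc == "paac":
            parts.append(encode_paac(seq, config.paac_lam, config.paac_w))
        elif enc == "gaac":
            parts.append(encode_gaac(seq))
        elif enc == "ctdc":
            parts.append(encode_ctdc(seq))
        elif enc == "ctdt":
            parts.append(encode_ctdt(seq))
        elif enc == "ctdd":
            parts.append(encode_ctdd(seq))
        elif enc == "socn":
            parts.append(encode_socn(seq, config.socn_lam, config.socn_matrices))
    return FeatureVector.concat(parts)
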