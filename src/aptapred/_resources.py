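"""Loaders for the plain-text data resources shipped with the package.

All tables live in ``aptapred/data`` as TSV with ``#`` comment headers
documenting provenance; see those headers and docs/methods.md.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
DNA_BASES = "ACGT"
RNA_BASES = "ACGU"


def _read(name: str) -> pd.DataFrame:
    with resources.files("aptapred.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


@lru_cache(maxsize=None)
def distance_matrix(which: str) -> pd.DataFrame:
    """20x20 amino-acid distance matrix.

    ``which`` is "grantham" (recomputed from Grantham's published formula)
    or "physchem" (a synthetic constructed matrix standing in for the
    Schneider-Wrede physicochemical distance matrix; see the data file
    header).  d(a,a) = 0 for both.
    """
    fname = {
        "grantham": "grantham.tsv",
        "physchem": "physchem_distance_synthetic.tsv",
    }[which]
    df = _read(fname).set_index("aa")
    df = df.loc[list(AA_ORDER), list(AA_ORDER)].astype(float)
    return df


@lru_cache(maxsize=None)
def paac_scales() -> pd.DataFrame:
    """Standardized hydrophobicity / hydrophilicity / side-chain mass scales.

    Each scale is standardized to zero mean and unit (population) variance
    across the 20 residues, the convention of Chou's pseudo-composition.
    """
    df = _read("paac_scales.tsv").set_index("aa").loc[list(AA_ORDER)].astype(float)
    return (df - df.mean()) / df.std(ddof=0)


@lru_cache(maxsize=None)
def group_schemes() -> dict[str, dict[str, str]]:
    """Amino-acid group schemes: scheme -> {group name -> letter set}."""
    df = _read("protein_groups.tsv")
    schemes: dict[str, dict[str, str]] = {}
    for scheme, sub in df.groupby("scheme", sort=False):
        schemes[scheme] = dict(zip(sub["group"], sub["letters"]))
    for scheme, groups in schemes.items():
        letters = "".join(groups.values())
        if sorted(letters) != sorted(AA_ORDER):
            raise AssertionError(f"scheme {scheme} is not a partition of the 20 residues")
    return schemes


@lru_cache(maxsize=None)
def dinucleotide_properties(molecule: str, standardized: bool = True) -> pd.DataFrame:
    """16-dinucleotide x 11-property table for DNA or RNA.

    The standardized view (default) has zero mean and unit population
    variance per property across the 16 dinucleotides.
    """
    fname = {"DNA": "dinucleotide_dna.tsv", "RNA": "dinucleotide_rna.tsv"}[molecule]
    df = _read(fname).set_index("dinucleotide").astype(float)
    letters = DNA_BASES if molecule == "DNA" else RNA_BASES
    order = [a + b for a in letters for b in letters]
    df = df.loc[order]
    if standardized:
        df = (df - df.mean()) / df.std(ddof=0)
    return df


PROPERTY_NAMES = (
    "shift", "slide", "rise", "tilt", "roll", "twist",
    "stacking_energy", "enthalpy", "entropy", "free_energy", "hydrophilicity",
)
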