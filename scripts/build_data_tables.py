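"""Regenerate the two 20x20 amino-acid distance matrices shipped in
``src/aptapred/data``.

``grantham.tsv`` is computed from Grantham's chemical-distance formula

    D(i,j) = rho * sqrt(alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2 + gamma*(v_i-v_j)^2)

with the published composition (c), polarity (p) and side-chain volume (v)
values and alpha=1.833, beta=0.1018, gamma=0.000399; rho scales the mean of
the 190 pairwise distances to 100, which is how the printed table was
normalized.

``physchem_distance_synthetic.tsv`` is a SYNTHETIC stand-in for the
Schneider-Wrede physicochemical distance matrix (whose printed values are
not redistributable here): Euclidean distance in the standardized
(hydrophobicity, hydrophilicity, side-chain mass) property space, rescaled
to [0, 1].  It plays the same structural role (a non-negative amino-acid
dissimilarity with zero diagonal) in the sequence-order-coupling encoder.

Run from the repository root:  python scripts/build_data_tables.py
"""

from pathlib import Path

import numpy as np

DATA = Path(__file__).resolve().parent.parent / "src" / "aptapred" / "data"

AA = "ACDEFGHIKLMNPQRSTVWY"

# Grantham (1974): composition, polarity, molecular volume.
GRANTHAM_PROPS = {
    "A": (0.00, 8.1, 31.0),
    "C": (2.75, 5.5, 55.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "F": (0.00, 5.2, 132.0),
    "G": (0.74, 9.0, 3.0),
    "H": (0.58, 10.4, 96.0),
    "I": (0.00, 5.2, 111.0),
    "K": (0.33, 11.3, 119.0),
    "L": (0.00, 4.9, 111.0),
    "M": (0.00, 5.7, 105.0),
    "N": (1.33, 11.6, 56.0),
    "P": (0.39, 8.0, 32.5),
    "Q": (0.89, 10.5, 85.0),
    "R": (0.65, 10.5, 124.0),
    "S": (1.42, 9.2, 32.0),
    "T": (0.71, 8.6, 61.0),
    "V": (0.00, 5.9, 84.0),
    "W": (0.13, 5.4, 170.0),
    "Y": (0.20, 6.2, 136.0),
}
ALPHA, BETA, GAMMA = 1.833, 0.1018, 0.000399

# Amino-acid property scales used by the pseudo-composition encoder
# (hydrophobicity, hydrophilicity, side-chain mass) — the same scales the
# synthetic distance matrix is built from.
PAAC_SCALES = {
    "A": (0.62, -0.5, 15.0),
    "C": (0.29, -1.0, 47.0),
    "D": (-0.90, 3.0, 59.0),
    "E": (-0.74, 3.0, 73.0),
    "F": (1.19, -2.5, 91.0),
    "G": (0.48, 0.0, 1.0),
    "H": (-0.40, -0.5, 82.0),
    "I": (1.38, -1.8, 57.0),
    "K": (-1.50, 3.0, 73.0),
    "L": (1.06, -1.8, 57.0),
    "M": (0.64, -1.3, 75.0),
    "N": (-0.78, 0.2, 58.0),
    "P": (0.12, 0.0, 42.0),
    "Q": (-0.85, 0.2, 72.0),
    "R": (-2.53, 3.0, 101.0),
    "S": (-0.18, 0.3, 31.0),
    "T": (-0.05, -0.4, 45.0),
    "V": (1.08, -1.5, 43.0),
    "W": (0.81, -3.4, 130.0),
    "Y": (0.26, -2.3, 107.0),
}


def write_matrix(path: Path, mat: np.ndarray, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("aa\t" + "\t".join(AA) + "\n")
        for i, a in enumerate(AA):
            fh.write(a + "\t" + "\t".join(f"{x:.6g}" for x in mat[i]) + "\n")


def build_grantham() -> np.ndarray:
    props = np.array([GRANTHAM_PROPS[a] for a in AA])
    c, p, v = props[:, 0], props[:, 1], props[:, 2]
    d2 = (
        ALPHA * (c[:, None] - c[None, :]) ** 2
        + BETA * (p[:, None] - p[None, :]) ** 2
        + GAMMA * (v[:, None] - v[None, :]) ** 2
    )
    d = np.sqrt(d2)
    iu = np.triu_indices(20, k=1)
    rho = 100.0 / d[iu].mean()
    return np.round(rho * d, 3)


def build_synthetic_physchem() -> np.ndarray:
    scales = np.array([PAAC_SCALES[a] for a in AA])
    z = (scales - scales.mean(axis=0)) / scales.std(axis=0)
    diff = z[:, None, :] - z[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return np.round(d / d.max(), 6)


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    write_matrix(
        DATA / "grantham.tsv",
        build_grantham(),
        [
            "Grantham chemical distance matrix, recomputed from the published",
            "formula D = rho*sqrt(1.833*dc^2 + 0.1018*dp^2 + 0.000399*dv^2)",
            "with Grantham (1974) composition/polarity/volume values;",
            "rho scales the mean pairwise distance to 100.",
        ],
    )
    write_matrix(
        DATA / "physchem_distance_synthetic.tsv",
        build_synthetic_physchem(),
        [
            "SYNTHETIC physicochemical distance matrix: Euclidean distance in",
            "standardized (hydrophobicity, hydrophilicity, side-chain mass)",
            "space, rescaled to [0,1].  A constructed stand-in playing the",
            "structural role of the Schneider-Wrede distance matrix in the",
            "sequence-order-coupling encoder; not the published matrix.",
        ],
    )
    # Sanity prints for well-known Grantham entries.
    g = build_grantham()
    idx = {a: i for i, a in enumerate(AA)}
    print("d(L,I) =", g[idx["L"], idx["I"]], "(published: 5)")
    print("d(W,C) =", g[idx["W"], idx["C"]], "(published: 215)")
    print("d(S,R) =", g[idx["S"], idx["R"]], "(published: 110)")


if __name__ == "__main__":
    main()
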