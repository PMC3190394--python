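"""Amino-acid biochemical property scales used to weight substitution events.

Four scales are provided: side-chain charge, Grantham polarity, Grantham
volume, and the full Grantham pairwise distance matrix.  The scalar scales
weight a substitution x->y by ``value(y) - value(x)`` (signed, "compensatory"
mode) or its absolute value ("correlated" mode); the Grantham matrix weights
it directly by the tabulated pairwise distance and therefore only supports
the correlated mode.

The Grantham distance matrix is computed at import time from the published
composition/polarity/volume scales with the published formula

    D_ij = rho * sqrt(1.833 c^2 + 0.1018 p^2 + 0.000399 v^2)

where the differences c, p, v are taken between residues i and j and rho
scales the mean over the 190 unordered pairs to 100, then rounded to
integers.  This reproduces the printed 1974 table including its extremes
(Leu-Ile = 5, Cys-Trp = 215); a handful of printed entries (I-V, M-L, E-K)
differ by one unit because the original table is not internally consistent
with any single scaling constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 20 amino acids in alphabetical one-letter order (used for all
#: user-facing tables and matrices).
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Side-chain charge at physiological pH.  Histidine is treated as neutral.
CHARGE = {aa: 0.0 for aa in AMINO_ACIDS}
CHARGE.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0, "H": 0.0})

#: Grantham (1974) polarity scale.
POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}

#: Grantham (1974) side-chain volume scale.
VOLUME = {
    "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0, "Q": 85.0,
    "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0, "L": 111.0, "K": 119.0,
    "M": 105.0, "F": 132.0, "P": 32.5, "S": 32.0, "T": 61.0, "W": 170.0,
    "Y": 136.0, "V": 84.0,
}

#: Grantham (1974) composition scale (atomic-weight ratio of non-C atoms in
#: the side chain); only used to build the distance matrix.
COMPOSITION = {
    "A": 0.0, "R": 0.65, "N": 1.33, "D": 1.38, "C": 2.75, "Q": 0.89,
    "E": 0.92, "G": 0.74, "H": 0.58, "I": 0.0, "L": 0.0, "K": 0.33,
    "M": 0.0, "F": 0.0, "P": 0.39, "S": 1.42, "T": 0.71, "W": 0.13,
    "Y": 0.20, "V": 0.0,
}


def _build_grantham() -> np.ndarray:
    a, b, g = 1.833, 0.1018, 0.000399
    n = len(AMINO_ACIDS)
    raw = np.zeros((n, n))
    for i, x in enumerate(AMINO_ACIDS):
        for j, y in enumerate(AMINO_ACIDS):
            if i == j:
                continue
            raw[i, j] = np.sqrt(
                a * (COMPOSITION[x] - COMPOSITION[y]) ** 2
                + b * (POLARITY[x] - POLARITY[y]) ** 2
                + g * (VOLUME[x] - VOLUME[y]) ** 2
            )
    iu = np.triu_indices(n, 1)
    rho = 100.0 / raw[iu].mean()
    return np.round(raw * rho)


#: 20x20 symmetric integer Grantham distance matrix, rows/columns ordered as
#: :data:`AMINO_ACIDS`.  Range 5..215, zero diagonal.
GRANTHAM_MATRIX = _build_grantham()

SCALAR_SCALES = {"charge": CHARGE, "polarity": POLARITY, "volume": VOLUME}
PROPERTY_NAMES = ("charge", "polarity", "volume", "grantham")


def grantham_distance(aa1: str, aa2: str) -> float:
    """Grantham distance between two amino acids (one-letter codes)."""
    return float(GRANTHAM_MATRIX[AA_INDEX[aa1], AA_INDEX[aa2]])


@dataclass(frozen=True)
class PropertyScale:
    """A biochemical property used to weight amino-acid substitutions.

    ``kind`` is "scalar" for charge/polarity/volume and "matrix" for the
    Grantham pairwise distance.
    """

    name: str
    kind: str
    values: np.ndarray = field(repr=False)  # (20,) scalar or (20, 20) matrix

    @classmethod
    def get(cls, name: str) -> "PropertyScale":
        name = name.lower()
        if name in SCALAR_SCALES:
            vals = np.array([SCALAR_SCALES[name][aa] for aa in AMINO_ACIDS])
            return cls(name=name, kind="scalar", values=vals)
        if name == "grantham":
            return cls(name=name, kind="matrix", values=GRANTHAM_MATRIX)
        raise ValueError(
            f"unknown property {name!r}; expected one of {PROPERTY_NAMES}"
        )

    def event_weights(
        self, frm: np.ndarray, to: np.ndarray, mode: str = "correlated"
    ) -> np.ndarray:
        """Weights of substitution events given integer amino-acid indices.

        Correlated mode: absolute property change (Grantham: matrix entry).
        Compensatory mode: signed property change; undefined for the
        Grantham matrix.
        """
        if mode not in ("correlated", "compensatory"):
            raise ValueError(f"unknown mode {mode!r}")
        if self.kind == "matrix":
            if mode == "compensatory":
                raise ValueError(
                    "the Grantham distance is unsigned and cannot be used "
                    "in compensatory mode"
                )
            return self.values[frm, to]
        delta = self.values[to] - self.values[frm]
        return np.abs(delta) if mode == "correlated" else delta

    def event_weight(self, frm: str, to: str, mode: str = "correlated") -> float:
        """Weight of a single substitution given one-letter codes."""
        w = self.event_weights(
            np.array([AA_INDEX[frm]]), np.array([AA_INDEX[to]]), mode
        )
        return float(w[0])
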