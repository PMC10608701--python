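"""Physical constants: monoisotopic atomic masses and isotope mass shifts.

All masses in Da (unified atomic mass units), CODATA/IUPAC values.
12C is exactly 12 by definition of the scale.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Monoisotopic atomic masses of the CHNOPS alphabet (Da).
MONOISOTOPIC: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

#: Fixed Hill-order element alphabet for this package (water-soluble
#: primary metabolites are CHNOPS).
ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "P", "S")

MASS_13C = 13.0033548378
MASS_15N = 15.0001088989

PROTON = 1.007276466812
ELECTRON = 0.00054857990907


@dataclass(frozen=True)
class IsotopeDeltas:
    """Mass differences driving the four-condition labeling shifts.

    d13c: 13C - 12C; d15n: 15N - 14N. A compound with c carbons and n
    nitrogens, fully labeled, shifts by c*d13c (+13C medium), n*d15n
    (+15N medium) and c*d13c + n*d15n (dual medium).
    """

    d13c: float = MASS_13C - MONOISOTOPIC["C"]
    d15n: float = MASS_15N - MONOISOTOPIC["N"]
    proton: float = PROTON
    electron: float = ELECTRON

    def __post_init__(self) -> None:
        if not (1.0030 < self.d13c < 1.0040):
            raise ValueError(f"d13c out of physical range: {self.d13c}")
        if not (0.9965 < self.d15n < 0.9975):
            raise ValueError(f"d15n out of physical range: {self.d15n}")


#: Default deltas used throughout; immutable.
DELTAS = IsotopeDeltas()
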