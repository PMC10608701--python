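import numpy as np
import pytest

from isocred.constants import DELTAS, PROTON
from isocred.formula import monoisotopic_mass, parse_formula
from isocred.peaks_io import PeakSet, ReferenceEntry

GLUTAMATE = "C5H9NO4"
GLUTAMATE_MASS = monoisotopic_mass(parse_formula(GLUTAMATE))  # 147.05316 Da
GLUTAMATE_RT = 7.9


def make_peakset(condition, rows, polarity="negative", source="ESI"):
    """rows: list of (mz, rt, intensity[, snr])."""
    rows = [tuple(r) + (50.0,) * (4 - len(r)) for r in rows]
    return PeakSet(
        condition, polarity, source,
        mz=np.array([r[0] for r in rows]),
        rt=np.array([r[1] for r in rows]),
        intensity=np.array([r[2] for r in rows]),
        snr=np.array([r[3] for r in rows]),
    )


@pytest.fixture
def glutamate_quartet_sets():
    """Noiseless four-condition sets containing exactly one planted
    glutamate quartet (c=5, n=1) in negative mode."""
    mz = GLUTAMATE_MASS - PROTON  # [M-H]-
    inten = 1e6
    u = make_peakset("U", [(mz, GLUTAMATE_RT, inten)])
    c13 = make_peakset("C13", [(mz + 5 * DELTAS.d13c, GLUTAMATE_RT, inten)])
    n15 = make_peakset("N15", [(mz + DELTAS.d15n, GLUTAMATE_RT, inten)])
    dual = make_peakset("C13N15", [(mz + 5 * DELTAS.d13c + DELTAS.d15n, GLUTAMATE_RT, inten)])
    return u, c13, n15, dual


@pytest.fixture
def tiny_library():
    glu_ms2 = ((85.03, 100.0), (101.02, 50.0), (128.03, 30.0))
    return [
        ReferenceEntry("Glutamate", parse_formula(GLUTAMATE),
                       monoisotopic_mass(parse_formula(GLUTAMATE)),
                       rt=GLUTAMATE_RT, ms2=glu_ms2),
        ReferenceEntry("Glucose", parse_formula("C6H12O6"),
                       monoisotopic_mass(parse_formula("C6H12O6")), rt=11.2),
        ReferenceEntry("Urea", parse_formula("CH4N2O"),
                       monoisotopic_mass(parse_formula("CH4N2O"))),
    ]
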