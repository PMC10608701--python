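"""Molecular-formula arithmetic and mass-shift-constrained formula prediction.

The central operation is :func:`decompose`: given a neutral monoisotopic
mass and the carbon and nitrogen counts inferred from isotope labeling,
enumerate all CHNOPS formulas consistent with the mass within a ppm
tolerance and with standard chemical-plausibility filters (RDBE range and
integrality, H/C ratio). Fixing (C, N) from the labeling shifts is what
collapses the usual combinatorial ambiguity of formula assignment.

Hydrogen is solved from the mass residual instead of looped over, which
reduces the enumeration from O(H*O*P*S) to O(O*P*S); equivalence with the
exhaustive enumeration is covered by the oracle tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .constants import ELEMENTS, MONOISOTOPIC

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(s: str) -> dict[str, int]:
    """Parse a Hill-notation CHNOPS formula string into element counts.

    No charges, no isotope markers, no parentheses. Raises ``ValueError``
    naming the first invalid token.
    """
    s = s.strip()
    if not s:
        raise ValueError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(s):
        if m.start() != pos:
            raise ValueError(f"invalid token {s[pos:m.start()]!r} in formula {s!r}")
        pos = m.end()
        elem, num = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC:
            raise ValueError(f"invalid token {elem!r} in formula {s!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(s):
        raise ValueError(f"invalid token {s[pos:]!r} in formula {s!r}")
    return counts


def hill_formula(counts: dict[str, int]) -> str:
    """Format element counts as a Hill-order formula string (C, H, then
    remaining elements alphabetically); zero counts are omitted."""
    out = []
    for el in ELEMENTS:  # ELEMENTS is already Hill order for CHNOPS
        k = counts.get(el, 0)
        if k < 0:
            raise ValueError(f"negative count for {el}")
        if k == 0:
            continue
        out.append(el if k == 1 else f"{el}{k}")
    return "".join(out)


def monoisotopic_mass(counts: dict[str, int]) -> float:
    """Neutral monoisotopic mass (Da) of an element-count vector."""
    mass = 0.0
    for el, k in counts.items():
        if el not in MONOISOTOPIC:
            raise ValueError(f"unknown element {el!r}")
        if k < 0:
            raise ValueError(f"negative count for {el}")
        mass += k * MONOISOTOPIC[el]
    return mass


def rdbe(counts: dict[str, int]) -> float:
    """Ring-plus-double-bond equivalents: C + 1 + (N+P)/2 - H/2.

    O and S are divalent and contribute nothing. Integer-valued for
    neutral even-electron molecules.
    """
    c = counts.get("C", 0)
    h = counts.get("H", 0)
    n = counts.get("N", 0)
    p = counts.get("P", 0)
    return c + 1.0 + (n + p) / 2.0 - h / 2.0


@dataclass(frozen=True)
class ElementBounds:
    """Plausibility box for formula enumeration.

    Per-element (min, max) counts plus an allowed RDBE interval and H/C
    ratio interval. Defaults follow common small-molecule heuristics for
    metabolites under 1000 Da; every bound is config-exposed.
    """

    c: tuple[int, int] = (0, 50)
    h: tuple[int, int] = (0, 80)
    n: tuple[int, int] = (0, 20)
    o: tuple[int, int] = (0, 20)
    p: tuple[int, int] = (0, 4)
    s: tuple[int, int] = (0, 4)
    rdbe_range: tuple[float, float] = (0.0, 25.0)
    hc_ratio_range: tuple[float, float] = (0.1, 6.0)

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "p", "s"):
            lo, hi = getattr(self, name)
            if lo < 0 or lo > hi:
                raise ValueError(f"bad bounds for {name}: ({lo}, {hi})")
        if self.rdbe_range[0] < 0:
            raise ValueError("rdbe lower bound must be >= 0")


@dataclass(frozen=True)
class FormulaCandidate:
    counts: dict[str, int]
    neutral_mass: float
    ppm_error: float  # signed, (candidate - query)/query * 1e6
    rdbe: float

    @property
    def formula(self) -> str:
        return hill_formula(self.counts)

    def heteroatoms(self) -> int:
        return sum(v for k, v in self.counts.items() if k not in ("C", "H"))


_M_H = MONOISOTOPIC["H"]


def _enumerate(
    neutral_mass_q: float,
    c_range: range,
    n_range: range,
    tol_ppm: float,
    bounds: ElementBounds,
) -> list[FormulaCandidate]:
    """Vectorized enumeration over (c, n, o, p, s) with h solved from the
    mass residual."""
    mo, mp, ms = MONOISOTOPIC["O"], MONOISOTOPIC["P"], MONOISOTOPIC["S"]
    mc, mn = MONOISOTOPIC["C"], MONOISOTOPIC["N"]
    cs = np.asarray(c_range)
    ns = np.asarray(n_range)
    os_ = np.arange(bounds.o[0], bounds.o[1] + 1)
    ps = np.arange(bounds.p[0], bounds.p[1] + 1)
    ss = np.arange(bounds.s[0], bounds.s[1] + 1)
    if min(len(cs), len(ns), len(os_), len(ps), len(ss)) == 0:
        return []

    C, N, O, P, S = np.meshgrid(cs, ns, os_, ps, ss, indexing="ij")
    C, N, O, P, S = (a.ravel() for a in (C, N, O, P, S))
    base = C * mc + N * mn + O * mo + P * mp + S * ms
    residual = neutral_mass_q - base
    H = np.rint(residual / _M_H).astype(np.int64)

    mass = base + H * _M_H
    ppm = (mass - neutral_mass_q) / neutral_mass_q * 1e6
    rdbe_v = C + 1.0 + (N + P) / 2.0 - H / 2.0

    ok = (H >= bounds.h[0]) & (H <= bounds.h[1])
    ok &= np.abs(ppm) <= tol_ppm
    ok &= (rdbe_v >= bounds.rdbe_range[0]) & (rdbe_v <= bounds.rdbe_range[1])
    # neutral even-electron molecules have integer RDBE, i.e. H+N+P even
    ok &= (H + N + P) % 2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        hc = np.where(C > 0, H / np.maximum(C, 1), np.nan)
    ok &= (C == 0) | ((hc >= bounds.hc_ratio_range[0]) & (hc <= bounds.hc_ratio_range[1]))

    out = []
    for i in np.flatnonzero(ok):
        counts = {
            "C": int(C[i]), "H": int(H[i]), "N": int(N[i]),
            "O": int(O[i]), "P": int(P[i]), "S": int(S[i]),
        }
        counts = {k: v for k, v in counts.items() if v > 0}
        out.append(
            FormulaCandidate(
                counts=counts,
                neutral_mass=float(mass[i]),
                ppm_error=float(ppm[i]),
                rdbe=float(rdbe_v[i]),
            )
        )
    out.sort(key=lambda f: (abs(f.ppm_error), f.heteroatoms(), f.formula))
    return out


def decompose(
    neutral_mass_q: float,
    c: int,
    n: int,
    tol_ppm: float = 5.0,
    bounds: ElementBounds | None = None,
) -> list[FormulaCandidate]:
    """Enumerate formula candidates for a neutral mass with C and N fixed.

    Parameters
    ----------
    neutral_mass_q:
        Query neutral monoisotopic mass (Da), e.g. from a credentialed
        quartet's unlabeled ion.
    c, n:
        Carbon and nitrogen counts inferred from the labeling mass shifts;
        every returned candidate has exactly these counts.
    tol_ppm:
        Mass tolerance in ppm (> 0).
    bounds:
        Plausibility box; defaults to :class:`ElementBounds`.

    Returns candidates sorted by |ppm error| ascending, ties broken by
    fewer heteroatoms then Hill string.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if neutral_mass_q <= 0:
        raise ValueError("neutral mass must be > 0")
    if c < 0 or n < 0:
        raise ValueError("atom counts must be >= 0")
    bounds = bounds or ElementBounds()
    return _enumerate(neutral_mass_q, range(c, c + 1), range(n, n + 1), tol_ppm, bounds)


def decompose_unconstrained(
    neutral_mass_q: float,
    tol_ppm: float = 5.0,
    bounds: ElementBounds | None = None,
) -> list[FormulaCandidate]:
    """Enumerate candidates with C and N free over ``bounds`` (the
    conventional, label-free formula search used as the comparison point
    for the labeling constraint)."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    bounds = bounds or ElementBounds()
    c_hi = min(bounds.c[1], int(neutral_mass_q // MONOISOTOPIC["C"]))
    n_hi = min(bounds.n[1], int(neutral_mass_q // MONOISOTOPIC["N"]))
    return _enumerate(
        neutral_mass_q,
        range(bounds.c[0], c_hi + 1),
        range(bounds.n[0], n_hi + 1),
        tol_ppm,
        bounds,
    )


def constrained_gain(
    neutral_mass_q: float,
    c: int,
    n: int,
    tol_ppm: float = 5.0,
    bounds: ElementBounds | None = None,
) -> tuple[int, int]:
    """Candidate-set sizes with (c, n) fixed vs free.

    Returns ``(n_constrained, n_unconstrained)``; the constrained set is a
    subset of the unconstrained one, so the first number never exceeds the
    second.
    """
    con = decompose(neutral_mass_q, c, n, tol_ppm, bounds)
    unc = decompose_unconstrained(neutral_mass_q, tol_ppm, bounds)
    return len(con), len(unc)
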