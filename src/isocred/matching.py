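"""Quartet matching across the four labeling conditions.

A metabolite grown in unlabeled, U-13C, U-15N and U-13C+15N media appears
as four ions whose m/z values differ by exact multiples of the 13C-12C and
15N-14N mass differences: +c*d13C, +n*d15N and +c*d13C+n*d15N for a
compound with c carbons and n nitrogens. Matching an unlabeled peak to
co-eluting partners at those predicted shifts both *credentials* the peak
as biological (media contaminants and other background ions have no
labeled partners) and reads the carbon and nitrogen counts directly off
the spectrum.

Matching contract
-----------------
For each unlabeled peak, candidate (c, n) assignments are enumerated over
c in [0, min(c_max, floor(M/12))] and n in [0, min(n_max, floor(M/14))].
A candidate requires each atom count to be evidenced by at least one
observed partner: c by the 13C or dual peak, n by the 15N or dual peak.
Support levels: ``full`` = all three partners, ``triad`` = two, ``pair``
= dual only. Candidates are ranked (support desc, worst-partner ppm asc);
an exact tie between distinct (c, n) at the top flags the quartet
ambiguous. Unlabeled peaks are processed in descending intensity; each
labeled peak may be claimed by one quartet only — later quartets wanting
an already-claimed partner are emitted but demoted from credentialing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import DELTAS, IsotopeDeltas
from .peaks_io import Peak, PeakSet

SUPPORT_FULL = "full"
SUPPORT_TRIAD = "triad"
SUPPORT_PAIR = "pair"
_SUPPORT_RANK = {SUPPORT_FULL: 0, SUPPORT_TRIAD: 1, SUPPORT_PAIR: 2}


@dataclass(frozen=True)
class MatchConfig:
    """Tolerances and search bounds for quartet matching.

    mz_tol_ppm and rt_tol are the partner mass-match and co-elution
    windows; intensity_ratio_bounds constrain labeled/unlabeled intensity
    (fully labeled cultures should express partners at comparable
    abundance). c_max/n_max cap the atom-count search.
    """

    mz_tol_ppm: float = 5.0
    rt_tol: float = 0.5
    intensity_ratio_bounds: tuple[float, float] = (0.2, 5.0)
    c_max: int = 40
    n_max: int = 10

    def __post_init__(self) -> None:
        if self.mz_tol_ppm <= 0 or self.rt_tol <= 0:
            raise ValueError("tolerances must be > 0")
        lo, hi = self.intensity_ratio_bounds
        if not (0 < lo < 1 < hi):
            raise ValueError("intensity ratio bounds must satisfy 0 < lo < 1 < hi")
        if self.c_max < 0 or self.n_max < 0:
            raise ValueError("search bounds must be >= 0")


def expected_shift(c: int, n: int, deltas: IsotopeDeltas = DELTAS) -> float:
    """Predicted mass shift (Da) of the dual-labeled form of a compound
    with ``c`` carbons and ``n`` nitrogens: c*d13C + n*d15N."""
    if c < 0 or n < 0:
        raise ValueError("atom counts must be >= 0")
    return c * deltas.d13c + n * deltas.d15n


def neutral_mass(p: Peak, deltas: IsotopeDeltas = DELTAS) -> float:
    """Neutral monoisotopic mass from an observed ion m/z.

    Assumes [M-H]- in negative mode and [M+H]+ in positive mode; the
    proton mass (= H atom minus electron) carries the electron correction,
    which is not negligible at 5 ppm near the bottom of the scan range.
    """
    if p.polarity == "negative":
        return p.mz + deltas.proton
    if p.polarity == "positive":
        return p.mz - deltas.proton
    raise ValueError(f"unknown polarity {p.polarity!r}")


@dataclass
class LabelQuartet:
    """An unlabeled peak with its matched labeled partners and the
    inferred atom counts."""

    u: Peak
    p13c: Optional[Peak]
    p15n: Optional[Peak]
    pdual: Optional[Peak]
    c: int
    n: int
    support: str
    ppm_residual: float
    ambiguous: bool = False
    conflict: bool = False  # a partner was already claimed by a stronger quartet

    @property
    def credentialed(self) -> bool:
        return self.support == SUPPORT_FULL and not self.ambiguous and not self.conflict


def _window(ps: PeakSet, target_mz: float, tol_ppm: float) -> np.ndarray:
    tol = target_mz * tol_ppm * 1e-6
    lo = np.searchsorted(ps.mz, target_mz - tol, side="left")
    hi = np.searchsorted(ps.mz, target_mz + tol, side="right")
    return np.arange(lo, hi)


def _partner_candidates(
    ps: PeakSet, u: Peak, target_mz: float, cfg: MatchConfig
) -> list[tuple[float, int]]:
    """Indices of peaks in ps matching target_mz under all constraints,
    as (|ppm|, index), best first."""
    idx = _window(ps, target_mz, cfg.mz_tol_ppm)
    out = []
    rlo, rhi = cfg.intensity_ratio_bounds
    for i in idx:
        if abs(ps.rt[i] - u.rt) > cfg.rt_tol:
            continue
        ratio = ps.intensity[i] / u.intensity
        if not (rlo <= ratio <= rhi):
            continue
        ppm = abs(ps.mz[i] - target_mz) / target_mz * 1e6
        out.append((float(ppm), int(i)))
    out.sort()
    return out


def _check_sets(u: PeakSet, c13: PeakSet, n15: PeakSet, dual: PeakSet) -> None:
    sets = {"U": u, "C13": c13, "N15": n15, "C13N15": dual}
    pol = {s.polarity for s in sets.values()}
    src = {s.source for s in sets.values()}
    if len(pol) != 1 or len(src) != 1:
        raise ValueError("all four peak sets must share polarity and ion source")
    for cond, s in sets.items():
        if s.condition != cond:
            raise ValueError(f"peak set for condition {cond} has condition={s.condition!r}")


def match_quartets(
    u: PeakSet,
    c13: PeakSet,
    n15: PeakSet,
    dual: PeakSet,
    cfg: MatchConfig = MatchConfig(),
    deltas: IsotopeDeltas = DELTAS,
) -> list[LabelQuartet]:
    """Match every unlabeled peak against the three labeled conditions.

    Returns one quartet per unlabeled peak that has an admissible (c, n)
    candidate (see module docstring for the contract), ordered by
    descending unlabeled intensity (the claiming order). Deterministic for
    identical inputs and config.
    """
    _check_sets(u, c13, n15, dual)
    results: list[LabelQuartet] = []
    claimed_c13: set[int] = set()
    claimed_n15: set[int] = set()
    claimed_dual: set[int] = set()

    order = sorted(range(len(u)), key=lambda i: (-u.intensity[i], u.mz[i], i))
    for ui in order:
        up = u[ui]
        m = neutral_mass(up, deltas)
        if m <= 0:
            continue
        cmax = min(cfg.c_max, int(m // 12))
        nmax = min(cfg.n_max, int(m // 14))

        # best 13C partner per carbon count, 15N per nitrogen count
        best13: dict[int, tuple[float, int]] = {}
        for c in range(cmax + 1):
            cand = _partner_candidates(c13, up, up.mz + c * deltas.d13c, cfg)
            if cand:
                best13[c] = cand[0]
        best15: dict[int, tuple[float, int]] = {}
        for n in range(nmax + 1):
            cand = _partner_candidates(n15, up, up.mz + n * deltas.d15n, cfg)
            if cand:
                best15[n] = cand[0]

        candidates: list[tuple[int, float, int, int, object]] = []
        for c in range(cmax + 1):
            for n in range(nmax + 1):
                t13 = best13.get(c)
                t15 = best15.get(n)
                dcand = _partner_candidates(
                    dual, up, up.mz + c * deltas.d13c + n * deltas.d15n, cfg
                )
                td = dcand[0] if dcand else None
                if (t13 is None and td is None) or (t15 is None and td is None):
                    continue  # an atom count would be unevidenced
                present = [t for t in (t13, t15, td) if t is not None]
                support = {3: SUPPORT_FULL, 2: SUPPORT_TRIAD, 1: SUPPORT_PAIR}[len(present)]
                worst = max(t[0] for t in present)
                candidates.append(
                    (_SUPPORT_RANK[support], worst, c, n, (t13, t15, td, support))
                )
        if not candidates:
            continue
        candidates.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
        rank0, worst0, c0, n0, (t13, t15, td, support) = candidates[0]
        ambiguous = len(candidates) > 1 and (
            candidates[1][0] == rank0 and candidates[1][1] == worst0
        )

        conflict = (
            (t13 is not None and t13[1] in claimed_c13)
            or (t15 is not None and t15[1] in claimed_n15)
            or (td is not None and td[1] in claimed_dual)
        )
        if not conflict and not ambiguous:
            if t13 is not None:
                claimed_c13.add(t13[1])
            if t15 is not None:
                claimed_n15.add(t15[1])
            if td is not None:
                claimed_dual.add(td[1])

        results.append(
            LabelQuartet(
                u=up,
                p13c=c13[t13[1]] if t13 is not None else None,
                p15n=n15[t15[1]] if t15 is not None else None,
                pdual=dual[td[1]] if td is not None else None,
                c=c0,
                n=n0,
                support=support,
                ppm_residual=worst0,
                ambiguous=ambiguous,
                conflict=conflict,
            )
        )
    return results


def credential(quartets: Sequence[LabelQuartet]) -> list[LabelQuartet]:
    """Keep only credentialed quartets: present in all four conditions
    (support=full), unambiguous (c, n), and with unshared partners.

    This is the pseudo-metabolite set passed to formula prediction.
    """
    return [q for q in quartets if q.credentialed]


def quartets_to_frame(quartets: Sequence[LabelQuartet]) -> pd.DataFrame:
    """Flatten quartets into the output table schema."""
    rows = []
    for q in quartets:
        rows.append(
            {
                "u_mz": q.u.mz,
                "rt": q.u.rt,
                "intensity": q.u.intensity,
                "c": q.c,
                "n": q.n,
                "support": q.support,
                "ppm_residual": q.ppm_residual,
                "mz_13c": q.p13c.mz if q.p13c else np.nan,
                "mz_15n": q.p15n.mz if q.p15n else np.nan,
                "mz_dual": q.pdual.mz if q.pdual else np.nan,
                "ambiguous": q.ambiguous,
                "conflict": q.conflict,
                "credentialed": q.credentialed,
                "u_id": q.u.id,
            }
        )
    cols = [
        "u_mz", "rt", "intensity", "c", "n", "support", "ppm_residual",
        "mz_13c", "mz_15n", "mz_dual", "ambiguous", "conflict", "credentialed", "u_id",
    ]
    return pd.DataFrame(rows, columns=cols)
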