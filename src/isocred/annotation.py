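"""Identity assignment and confidence tiers for credentialed quartets.

A quartet carries a neutral mass and labeling-inferred (c, n) atom counts;
a library entry matches only if its formula has exactly those counts and
its neutral mass agrees within tolerance. Evidence then sets the tier:

- ``standard_confirmed`` — mass match plus retention time within tolerance
  of an authenticated standard's RT;
- ``ms2_matched``        — mass match plus MS2 cosine above threshold;
- ``putative_formula``   — mass/formula evidence only;
- ``unannotated``        — no admissible formula candidate at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import math

import numpy as np
import pandas as pd

from .formula import FormulaCandidate
from .matching import LabelQuartet, neutral_mass
from .peaks_io import ReferenceEntry

TIER_STANDARD = "standard_confirmed"
TIER_MS2 = "ms2_matched"
TIER_FORMULA = "putative_formula"
TIER_NONE = "unannotated"
#: Best-to-worst ordering of identification confidence.
TIER_ORDER = (TIER_STANDARD, TIER_MS2, TIER_FORMULA, TIER_NONE)
_TIER_RANK = {t: i for i, t in enumerate(TIER_ORDER)}


def best_tier(tiers: Sequence[str]) -> str:
    if not tiers:
        return TIER_NONE
    return min(tiers, key=lambda t: _TIER_RANK[t])


def ms2_cosine(
    spec_a: Sequence[tuple[float, float]],
    spec_b: Sequence[tuple[float, float]],
    frag_tol_mz: float = 0.01,
) -> float:
    """Greedy one-to-one fragment-matched cosine with square-root
    intensity scaling.

    Fragment pairs within ``frag_tol_mz`` are matched closest-m/z first,
    each fragment used at most once; the score is the cosine of the two
    sqrt-scaled intensity vectors (unmatched fragments contribute to the
    norms only). Symmetric; 1.0 iff the spectra coincide within tolerance
    up to a global intensity scale.
    """
    if len(spec_a) == 0 or len(spec_b) == 0:
        raise ValueError("MS2 spectra must be non-empty")
    a = np.asarray(spec_a, dtype=float)
    b = np.asarray(spec_b, dtype=float)
    if np.any(a[:, 1] <= 0) or np.any(b[:, 1] <= 0):
        raise ValueError("fragment intensities must be > 0")
    wa = np.sqrt(a[:, 1])
    wb = np.sqrt(b[:, 1])

    pairs = [
        (abs(a[i, 0] - b[j, 0]), i, j)
        for i in range(len(a))
        for j in range(len(b))
        if abs(a[i, 0] - b[j, 0]) <= frag_tol_mz
    ]
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += wa[i] * wb[j]
    denom = math.sqrt(float(np.sum(wa**2)) * float(np.sum(wb**2)))
    return dot / denom


@dataclass
class Annotation:
    """A quartet with its formula candidates and library matches."""

    quartet: LabelQuartet
    candidates: list[FormulaCandidate]
    matches: list[tuple[ReferenceEntry, str, float]] = field(default_factory=list)
    tier: str = TIER_NONE

    @property
    def best_name(self) -> Optional[str]:
        return self.matches[0][0].name if self.matches else None

    @property
    def best_formula(self) -> Optional[str]:
        if self.matches:
            return self.matches[0][0].formula_str
        if self.candidates:
            return self.candidates[0].formula
        return None

    @property
    def identity(self) -> Optional[str]:
        """Merging key: name when identified, otherwise top formula."""
        return self.best_name or self.best_formula

    @property
    def score(self) -> float:
        return self.matches[0][2] if self.matches else float("nan")


def match_library(
    quartet: LabelQuartet,
    candidates: Sequence[FormulaCandidate],
    library: Sequence[ReferenceEntry],
    mass_tol_ppm: float = 5.0,
    rt_tol: float = 0.5,
    ms2_threshold: float = 0.7,
    frag_tol_mz: float = 0.01,
    query_ms2: Optional[Sequence[tuple[float, float]]] = None,
) -> Annotation:
    """Annotate one credentialed quartet against the reference library.

    Library entries are admissible when their formula's C and N counts
    equal the quartet's labeling-inferred (c, n) and their neutral mass is
    within ``mass_tol_ppm`` of the quartet's. Admissible entries start at
    ``putative_formula``; RT agreement upgrades to ``standard_confirmed``,
    an MS2 cosine >= ``ms2_threshold`` (when both spectra exist) to
    ``ms2_matched``. The annotation's tier is the best over all matches,
    or ``putative_formula``/``unannotated`` depending on whether any
    formula candidate survived.
    """
    m = neutral_mass(quartet.u)
    matches: list[tuple[ReferenceEntry, str, float]] = []
    for entry in library:
        if entry.formula.get("C", 0) != quartet.c or entry.formula.get("N", 0) != quartet.n:
            continue
        ppm = abs(entry.neutral_mass - m) / entry.neutral_mass * 1e6
        if ppm > mass_tol_ppm:
            continue
        tier = TIER_FORMULA
        score = float("nan")
        if query_ms2 is not None and entry.ms2:
            cos = ms2_cosine(query_ms2, entry.ms2, frag_tol_mz)
            if cos >= ms2_threshold:
                tier = TIER_MS2
                score = cos
        if entry.rt is not None and abs(entry.rt - quartet.u.rt) <= rt_tol:
            tier = TIER_STANDARD
        matches.append((entry, tier, score))

    matches.sort(key=lambda t: (_TIER_RANK[t[1]], -(t[2] if t[2] == t[2] else -1.0), t[0].name))
    if matches:
        tier = matches[0][1]
    elif candidates:
        tier = TIER_FORMULA
    else:
        tier = TIER_NONE
    return Annotation(quartet=quartet, candidates=list(candidates), matches=matches, tier=tier)


def annotations_to_frame(
    annotations: Sequence[Annotation], source: str, polarity: str
) -> pd.DataFrame:
    """Flatten annotations into the per-run output table schema."""
    rows = []
    for a in annotations:
        q = a.quartet
        rows.append(
            {
                "u_mz": q.u.mz,
                "rt": q.u.rt,
                "intensity": q.u.intensity,
                "neutral_mass": neutral_mass(q.u),
                "c": q.c,
                "n": q.n,
                "formula": a.best_formula or "",
                "name": a.best_name or "",
                "tier": a.tier,
                "score": a.score,
                "source": source,
                "polarity": polarity,
                "u_id": q.u.id,
            }
        )
    cols = [
        "u_mz", "rt", "intensity", "neutral_mass", "c", "n",
        "formula", "name", "tier", "score", "source", "polarity", "u_id",
    ]
    return pd.DataFrame(rows, columns=cols)
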