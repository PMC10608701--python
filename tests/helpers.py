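"""Independent oracles used by the test suite.

These deliberately avoid the package's search machinery: the matcher
oracle scans every peak for every (u, c, n) combination, and the
decomposition oracle runs the full nested loop over H, O, P and S.
"""

from __future__ import annotations

import numpy as np

from isocred.constants import DELTAS
from isocred.formula import ElementBounds
from isocred.matching import MatchConfig, neutral_mass
from isocred.peaks_io import PeakSet

# independent IUPAC values (CIAAW), not imported from the package
IUPAC = {
    "e": 0.000548579909,
    "1H": 1.00782503207,
    "12C": 12.0,
    "13C": 13.00335483507,
    "14N": 14.00307400443,
    "15N": 15.00010889888,
    "16O": 15.99491461957,
    "31P": 30.97376199842,
    "32S": 31.9720711744,
}


def iupac_mass(counts: dict[str, int]) -> float:
    key = {"C": "12C", "H": "1H", "N": "14N", "O": "16O", "P": "31P", "S": "32S"}
    return sum(k * IUPAC[key[el]] for el, k in counts.items())


def brute_decompose(mass: float, c: int, n: int, tol_ppm: float,
                    bounds: ElementBounds | None = None) -> set[tuple[int, ...]]:
    """Full nested-loop enumeration over (h, o, p, s) with c, n fixed.

    Returns the set of accepted (c, h, n, o, p, s) tuples; no closed-form
    hydrogen solve, no vectorization.
    """
    b = bounds or ElementBounds()
    out = set()
    masses = {"C": 12.0, "H": IUPAC["1H"], "N": IUPAC["14N"],
              "O": IUPAC["16O"], "P": IUPAC["31P"], "S": IUPAC["32S"]}
    for h in range(b.h[0], b.h[1] + 1):
        for o in range(b.o[0], b.o[1] + 1):
            for p in range(b.p[0], b.p[1] + 1):
                for s in range(b.s[0], b.s[1] + 1):
                    m = (c * masses["C"] + h * masses["H"] + n * masses["N"]
                         + o * masses["O"] + p * masses["P"] + s * masses["S"])
                    if abs(m - mass) / mass * 1e6 > tol_ppm:
                        continue
                    r = c + 1 + (n + p) / 2 - h / 2
                    if not (b.rdbe_range[0] <= r <= b.rdbe_range[1]):
                        continue
                    if (h + n + p) % 2 != 0:
                        continue
                    if c > 0 and not (b.hc_ratio_range[0] <= h / c <= b.hc_ratio_range[1]):
                        continue
                    out.add((c, h, n, o, p, s))
    return out


def counts_tuple(counts: dict[str, int]) -> tuple[int, ...]:
    return tuple(counts.get(e, 0) for e in ("C", "H", "N", "O", "P", "S"))


def _scan(ps: PeakSet, u_mz: float, u_rt: float, u_int: float,
          target: float, cfg: MatchConfig):
    """Best matching peak in ps for a target m/z, by full linear scan."""
    best = None
    for i in range(len(ps)):
        if abs(ps.mz[i] - target) > target * cfg.mz_tol_ppm * 1e-6:
            continue
        if abs(ps.rt[i] - u_rt) > cfg.rt_tol:
            continue
        ratio = ps.intensity[i] / u_int
        lo, hi = cfg.intensity_ratio_bounds
        if not (lo <= ratio <= hi):
            continue
        ppm = abs(ps.mz[i] - target) / target * 1e6
        if best is None or (ppm, i) < best:
            best = (float(ppm), i)
    return best


def brute_match(u: PeakSet, c13: PeakSet, n15: PeakSet, dual: PeakSet,
                cfg: MatchConfig = MatchConfig()):
    """Exhaustive reference matcher over all (u, c13, n15, dual, c, n).

    Implements the documented contract (both atom counts evidenced,
    support/ppm ranking, intensity-greedy claiming) by direct enumeration.
    Returns comparable tuples:
    (u index, c, n, support, i13, i15, idual, ambiguous, conflict).
    """
    d = DELTAS
    support_rank = {"full": 0, "triad": 1, "pair": 2}
    results = []
    claimed = {"c13": set(), "n15": set(), "dual": set()}
    order = sorted(range(len(u)), key=lambda i: (-u.intensity[i], u.mz[i], i))
    for ui in order:
        u_mz, u_rt, u_int = float(u.mz[ui]), float(u.rt[ui]), float(u.intensity[ui])
        m = neutral_mass(u[ui])
        cmax = min(cfg.c_max, int(m // 12))
        nmax = min(cfg.n_max, int(m // 14))
        cands = []
        for c in range(cmax + 1):
            for n in range(nmax + 1):
                t13 = _scan(c13, u_mz, u_rt, u_int, u_mz + c * d.d13c, cfg)
                t15 = _scan(n15, u_mz, u_rt, u_int, u_mz + n * d.d15n, cfg)
                td = _scan(dual, u_mz, u_rt, u_int, u_mz + c * d.d13c + n * d.d15n, cfg)
                if (t13 is None and td is None) or (t15 is None and td is None):
                    continue
                present = [t for t in (t13, t15, td) if t is not None]
                support = {3: "full", 2: "triad", 1: "pair"}[len(present)]
                worst = max(t[0] for t in present)
                cands.append((support_rank[support], worst, c, n, (t13, t15, td, support)))
        if not cands:
            continue
        cands.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
        rank0, worst0, c0, n0, (t13, t15, td, support) = cands[0]
        ambiguous = len(cands) > 1 and cands[1][0] == rank0 and cands[1][1] == worst0
        conflict = (
            (t13 is not None and t13[1] in claimed["c13"])
            or (t15 is not None and t15[1] in claimed["n15"])
            or (td is not None and td[1] in claimed["dual"])
        )
        if not conflict and not ambiguous:
            if t13 is not None:
                claimed["c13"].add(t13[1])
            if t15 is not None:
                claimed["n15"].add(t15[1])
            if td is not None:
                claimed["dual"].add(td[1])
        results.append(
            (ui, c0, n0, support,
             t13[1] if t13 else None, t15[1] if t15 else None, td[1] if td else None,
             ambiguous, conflict)
        )
    return results


def quartets_as_tuples(u: PeakSet, c13: PeakSet, n15: PeakSet, dual: PeakSet, quartets):
    """Project package quartets onto the oracle's tuple form (peak ids
    mapped back to set indices)."""
    def index_of(ps, peak):
        if peak is None:
            return None
        hits = np.flatnonzero(ps.ids == peak.id)
        assert len(hits) == 1
        return int(hits[0])

    out = []
    for q in quartets:
        out.append(
            (index_of(u, q.u), q.c, q.n, q.support,
             index_of(c13, q.p13c), index_of(n15, q.p15n), index_of(dual, q.pdual),
             q.ambiguous, q.conflict)
        )
    return out


def random_instance(rng: np.random.Generator, max_per_set: int = 5):
    """A small random four-set instance mixing true quartets, partial
    quartets and junk peaks (<= max_per_set peaks per labeled set)."""
    d = DELTAS
    n_true = int(rng.integers(1, 4))
    sets = {"U": [], "C13": [], "N15": [], "C13N15": []}
    for _ in range(n_true):
        mz = float(rng.uniform(80, 900))
        rt = float(rng.uniform(1, 20))
        c = int(rng.integers(0, 12))
        n = int(rng.integers(0, 4))
        inten = float(rng.lognormal(13, 1))
        noise = lambda x: x * (1 + rng.normal(0, 2) * 1e-6)
        sets["U"].append((noise(mz), rt + rng.normal(0, 0.05), inten))
        for cond, shift in (("C13", c * d.d13c), ("N15", n * d.d15n),
                            ("C13N15", c * d.d13c + n * d.d15n)):
            if rng.random() < 0.8:  # partner present
                sets[cond].append(
                    (noise(mz + shift), rt + rng.normal(0, 0.05),
                     inten * float(np.clip(rng.lognormal(0, 0.3), 0.25, 4)))
                )
    # junk peaks everywhere
    for cond in sets:
        for _ in range(int(rng.integers(0, 3))):
            sets[cond].append(
                (float(rng.uniform(75, 950)), float(rng.uniform(1, 20)),
                 float(rng.lognormal(13, 1)))
            )
    out = {}
    for cond, rows in sets.items():
        rows = rows[:max_per_set]
        out[cond] = PeakSet(
            cond, "negative", "ESI",
            mz=np.array([r[0] for r in rows]),
            rt=np.array([r[1] for r in rows]),
            intensity=np.array([r[2] for r in rows]),
            snr=np.full(len(rows), 50.0),
        )
    return out["U"], out["C13"], out["N15"], out["C13N15"]
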