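"""Ground-truthed synthetic four-condition LC-MS peak sets.

The generator emulates the labeled-reference design: a yeast culture grown
to full isotopic enrichment in unlabeled, U-13C, U-15N and U-13C+15N
media, measured by HILIC LC-MS with ESI and APCI sources in both
polarities. Each synthetic compound plants an unlabeled ion plus partners
at exactly +c*d13C, +n*d15N and +c*d13C+n*d15N (full enrichment, no
partial isotopologue envelopes), perturbed by multiplicative ppm mass
noise and additive RT jitter; labeled partners drop out independently
with a configurable probability. Decoy peaks appear in the unlabeled
condition only — they model media/background ions, exactly the artifact
class credentialing is designed to remove.

Every random draw flows from ``SimConfig.seed``; identical configs yield
byte-identical peak tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DELTAS, PROTON
from .formula import ElementBounds, hill_formula, monoisotopic_mass
from .matching import LabelQuartet
from .peaks_io import PeakSet, ReferenceEntry

RT_RANGE = (1.0, 20.0)  # usable window of the 25-min HILIC gradient
_MASS_RANGE = (72.0, 980.0)  # keeps both ion polarities inside scan range


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults reflect a 1000-compound library measured on a
    120,000-resolution instrument: 2 ppm mass noise, 0.05 min RT jitter,
    10% per-condition partner dropout, one background decoy per compound.
    The source design (fractions of compounds seen only by ESI, only by
    APCI, or by both, and the negative-mode fraction) mirrors the strong
    source/polarity exclusivity of HILIC metabolite coverage.
    """

    n_compounds: int = 1000
    ppm_noise_sd: float = 2.0
    rt_jitter_sd: float = 0.05
    dropout: float = 0.10
    decoy_density: float = 1.0
    neg_frac: float = 0.67
    esi_only_frac: float = 0.55
    apci_only_frac: float = 0.35
    lib_rt_frac: float = 0.6
    lib_ms2_frac: float = 0.6
    query_ms2_frac: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout", "decoy_density", "neg_frac", "esi_only_frac",
                     "apci_only_frac", "lib_rt_frac", "lib_ms2_frac", "query_ms2_frac"):
            v = getattr(self, name)
            if name != "decoy_density" and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.esi_only_frac + self.apci_only_frac > 1.0 + 1e-9:
            raise ValueError("source-exclusive fractions exceed 1")
        if self.ppm_noise_sd < 0 or self.rt_jitter_sd < 0 or self.decoy_density < 0:
            raise ValueError("noise/decoy parameters must be >= 0")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")


@dataclass
class GroundTruth:
    """What was planted: per-compound design and per-peak provenance.

    ``compounds`` — one row per compound: name, formula, c, n, rt,
    polarity, sources (';'-joined).
    ``planted`` — one row per planted peak: name, source, polarity,
    condition, peak_id, mz, rt (decoys have name='').
    """

    compounds: pd.DataFrame
    planted: pd.DataFrame

    @property
    def decoy_ids(self) -> set[int]:
        return set(self.planted.loc[self.planted["name"] == "", "peak_id"])

    def u_id_to_name(self) -> dict[int, str]:
        mask = (self.planted["condition"] == "U") & (self.planted["name"] != "")
        return dict(zip(self.planted.loc[mask, "peak_id"], self.planted.loc[mask, "name"]))

    def fully_planted_names(self) -> set[str]:
        """Compounds with all four peaks planted in at least one run."""
        sub = self.planted[self.planted["name"] != ""]
        counts = sub.groupby(["name", "source", "polarity"])["condition"].nunique()
        return set(counts[counts == 4].index.get_level_values("name"))


def sample_library(n: int, seed: int) -> list[ReferenceEntry]:
    """Draw ``n`` distinct plausible CHNOPS metabolites.

    Formulas are rejection-sampled inside the default plausibility box
    (RDBE in [0, 25], H/C in [0.1, 6.0], neutral mass inside the scan
    range for both ion polarities); RTs are uniform over the LC gradient
    and each entry gets a synthetic MS2 spectrum. Formulas are unique
    within one library.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    bounds = ElementBounds()
    entries: list[ReferenceEntry] = []
    seen: set[str] = set()
    while len(entries) < n:
        c = int(rng.integers(2, 36))
        nn = int(rng.choice([0, 1, 2, 3, 4, 5, 6], p=[0.30, 0.25, 0.18, 0.12, 0.08, 0.04, 0.03]))
        o = int(rng.integers(0, 13))
        p = int(rng.choice([0, 1, 2], p=[0.88, 0.10, 0.02]))
        s = int(rng.choice([0, 1, 2], p=[0.90, 0.08, 0.02]))
        rdbe_hi = int(min(bounds.rdbe_range[1], c + 1 + (nn + p) / 2))
        r = int(rng.integers(0, rdbe_hi + 1))
        h = 2 * (c + 1) + nn + p - 2 * r
        counts = {"C": c, "H": h, "N": nn, "O": o, "P": p, "S": s}
        counts = {k: v for k, v in counts.items() if v > 0}
        if h < bounds.h[0] or h > bounds.h[1] or h <= 0:
            continue
        if not (bounds.hc_ratio_range[0] <= h / c <= bounds.hc_ratio_range[1]):
            continue
        mass = monoisotopic_mass(counts)
        if not (_MASS_RANGE[0] <= mass <= _MASS_RANGE[1]):
            continue
        formula = hill_formula(counts)
        if formula in seen:
            continue
        seen.add(formula)
        rt = float(rng.uniform(*RT_RANGE))
        n_frag = int(rng.integers(5, 13))
        frag_mz = np.sort(rng.uniform(50.0, max(51.0, mass - 1.0), n_frag))
        frag_int = rng.uniform(5.0, 100.0, n_frag)
        frag_int[int(rng.integers(0, n_frag))] = 100.0
        ms2 = tuple((float(m), float(i)) for m, i in zip(frag_mz, frag_int))
        entries.append(
            ReferenceEntry(
                name=f"SYN-{len(entries) + 1:04d}",
                formula=counts,
                neutral_mass=mass,
                rt=rt,
                ms2=ms2,
            )
        )
    return entries


def _ion_mz(neutral: float, polarity: str) -> float:
    return neutral - PROTON if polarity == "negative" else neutral + PROTON


def simulate_quartets(
    library: Sequence[ReferenceEntry], cfg: SimConfig
) -> tuple[dict[tuple[str, str], dict[str, PeakSet]], GroundTruth]:
    """Plant four-condition peak sets for every compound in ``library``.

    Returns ``(runs, truth)`` where ``runs`` maps (source, polarity) to
    the four condition PeakSets. Peak ids are globally unique and recorded
    in ``truth.planted`` so recovered quartets can be traced back.
    """
    if not library:
        raise ValueError("library must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    deltas = DELTAS

    comp_rows = []
    buckets: dict[tuple[str, str, str], dict[str, list]] = {}

    def bucket(source: str, polarity: str, condition: str) -> dict[str, list]:
        key = (source, polarity, condition)
        if key not in buckets:
            buckets[key] = {"mz": [], "rt": [], "intensity": [], "snr": [], "id": []}
        return buckets[key]

    planted_rows = []
    next_id = 0

    def plant(source, polarity, condition, mz, rt, intensity, name):
        nonlocal next_id
        b = bucket(source, polarity, condition)
        b["mz"].append(mz)
        b["rt"].append(rt)
        b["intensity"].append(intensity)
        b["snr"].append(5.0 + float(rng.lognormal(math.log(40.0), 0.8)))
        b["id"].append(next_id)
        planted_rows.append(
            {"name": name, "source": source, "polarity": polarity,
             "condition": condition, "peak_id": next_id, "mz": mz, "rt": rt}
        )
        next_id += 1

    for entry in library:
        polarity = "negative" if rng.random() < cfg.neg_frac else "positive"
        u01 = rng.random()
        if u01 < cfg.esi_only_frac:
            sources = ["ESI"]
        elif u01 < cfg.esi_only_frac + cfg.apci_only_frac:
            sources = ["APCI"]
        else:
            sources = ["ESI", "APCI"]
        c = entry.formula.get("C", 0)
        n = entry.formula.get("N", 0)
        base_intensity = float(rng.lognormal(math.log(1e6), 1.0))
        ion = _ion_mz(entry.neutral_mass, polarity)
        shifts = {
            "U": 0.0,
            "C13": c * deltas.d13c,
            "N15": n * deltas.d15n,
            "C13N15": c * deltas.d13c + n * deltas.d15n,
        }
        comp_rows.append(
            {"name": entry.name, "formula": entry.formula_str, "c": c, "n": n,
             "rt": entry.rt, "polarity": polarity, "sources": ";".join(sources)}
        )
        for source in sources:
            u_int = base_intensity * float(rng.lognormal(0.0, 0.2))
            for cond, shift in shifts.items():
                if cond != "U" and rng.random() < cfg.dropout:
                    continue
                mz = (ion + shift) * (1.0 + rng.normal(0.0, cfg.ppm_noise_sd) * 1e-6)
                rt = entry.rt + float(rng.normal(0.0, cfg.rt_jitter_sd))
                if cond == "U":
                    intensity = u_int
                else:
                    intensity = u_int * float(np.clip(rng.lognormal(0.0, 0.3), 0.25, 4.0))
                plant(source, polarity, cond, float(mz), rt, intensity, entry.name)

    # unlabeled-only background decoys, per run, proportional to the
    # number of compounds the run sees
    per_run_compounds: dict[tuple[str, str], int] = {}
    for row in comp_rows:
        for source in row["sources"].split(";"):
            key = (source, row["polarity"])
            per_run_compounds[key] = per_run_compounds.get(key, 0) + 1
    for (source, polarity), n_comp in sorted(per_run_compounds.items()):
        n_decoys = int(round(cfg.decoy_density * n_comp))
        for _ in range(n_decoys):
            mz = float(rng.uniform(70.5, 999.0))
            rt = float(rng.uniform(*RT_RANGE))
            intensity = float(rng.lognormal(math.log(3e5), 1.0))
            plant(source, polarity, "U", mz, rt, intensity, "")

    runs: dict[tuple[str, str], dict[str, PeakSet]] = {}
    for (source, polarity) in sorted(per_run_compounds.keys()):
        conds = {}
        for cond in ("U", "C13", "N15", "C13N15"):
            b = buckets.get((source, polarity, cond),
                            {"mz": [], "rt": [], "intensity": [], "snr": [], "id": []})
            conds[cond] = PeakSet(
                cond, polarity, source,
                mz=np.array(b["mz"]), rt=np.array(b["rt"]),
                intensity=np.array(b["intensity"]), snr=np.array(b["snr"]),
                ids=np.array(b["id"], dtype=np.int64),
            )
        runs[(source, polarity)] = conds

    truth = GroundTruth(
        compounds=pd.DataFrame(comp_rows),
        planted=pd.DataFrame(
            planted_rows,
            columns=["name", "source", "polarity", "condition", "peak_id", "mz", "rt"],
        ),
    )
    return runs, truth


def degrade_library(
    library: Sequence[ReferenceEntry], cfg: SimConfig
) -> tuple[list[ReferenceEntry], dict[str, tuple[float, list[tuple[float, float]]]]]:
    """Split simulator knowledge into annotation inputs.

    Returns (annotation library, query MS2 spectra). The annotation
    library keeps each entry's RT with probability ``lib_rt_frac`` and its
    MS2 spectrum with probability ``lib_ms2_frac`` (modeling incomplete
    standards/spectral coverage). Query spectra — what the instrument
    would have acquired — exist for ``query_ms2_frac`` of compounds, with
    10% multiplicative intensity noise, keyed by compound name with the
    neutral mass as precursor.
    """
    rng = np.random.default_rng(cfg.seed + 104729)  # decoupled stream
    lib_out: list[ReferenceEntry] = []
    queries: dict[str, tuple[float, list[tuple[float, float]]]] = {}
    for entry in library:
        rt = entry.rt if rng.random() < cfg.lib_rt_frac else None
        ms2 = entry.ms2 if rng.random() < cfg.lib_ms2_frac else None
        lib_out.append(replace(entry, rt=rt, ms2=ms2))
        if entry.ms2 and rng.random() < cfg.query_ms2_frac:
            noisy = [
                (mz, max(1e-3, i * float(rng.lognormal(0.0, 0.1))))
                for mz, i in entry.ms2
            ]
            queries[entry.name] = (entry.neutral_mass, noisy)
    return lib_out, queries


def write_dataset(cfg: SimConfig, out_dir: str) -> GroundTruth:
    """Generate and write a full synthetic dataset.

    Writes ``{source}_{polarity}_{condition}.csv`` peak tables, the
    annotation library (``library.tsv`` + ``library.msp``), the acquired
    query spectra (``queries.msp``) and the ground truth
    (``ground_truth_compounds.tsv``, ``ground_truth_peaks.tsv``).
    """
    import os

    from .peaks_io import write_library, write_msp, write_peak_table

    os.makedirs(out_dir, exist_ok=True)
    library = sample_library(cfg.n_compounds, cfg.seed)
    runs, truth = simulate_quartets(library, cfg)
    ann_library, queries = degrade_library(library, cfg)
    for (source, polarity), conds in runs.items():
        for cond, ps in conds.items():
            write_peak_table(ps, os.path.join(out_dir, f"{source}_{polarity}_{cond}.csv"))
    write_library(
        ann_library,
        os.path.join(out_dir, "library.tsv"),
        os.path.join(out_dir, "library.msp"),
    )
    if queries:
        write_msp(queries, os.path.join(out_dir, "queries.msp"))
    truth.compounds.to_csv(
        os.path.join(out_dir, "ground_truth_compounds.tsv"), sep="\t", index=False
    )
    truth.planted.to_csv(
        os.path.join(out_dir, "ground_truth_peaks.tsv"), sep="\t", index=False
    )
    return truth


def recovery_report(
    quartets_by_run: dict[tuple[str, str], list[LabelQuartet]],
    truth: GroundTruth,
) -> dict[str, float]:
    """Compare matched quartets with the planted design.

    A compound counts as *recovered* when, in at least one run where its
    unlabeled ion was planted, the quartet emitted for that ion carries
    the true (c, n). ``credentialed_correct`` restricts to credentialed
    quartets, over compounds with a fully planted quartet somewhere.
    Decoys are evaluated against the credentialed set.
    """
    u_map = truth.u_id_to_name()
    true_cn = {
        row["name"]: (int(row["c"]), int(row["n"]))
        for _, row in truth.compounds.iterrows()
    }
    decoys = truth.decoy_ids

    recovered: set[str] = set()
    cred_correct: set[str] = set()
    decoys_credentialed = 0
    for quartets in quartets_by_run.values():
        for q in quartets:
            name = u_map.get(q.u.id)
            if name is None:
                if q.u.id in decoys and q.credentialed:
                    decoys_credentialed += 1
                continue
            if (q.c, q.n) == true_cn[name]:
                recovered.add(name)
                if q.credentialed:
                    cred_correct.add(name)

    n_compounds = len(true_cn)
    fully = truth.fully_planted_names()
    return {
        "n_compounds": n_compounds,
        "n_fully_planted": len(fully),
        "n_recovered": len(recovered),
        "recovery_rate": len(recovered) / n_compounds,
        "n_credentialed_correct": len(cred_correct),
        "credentialed_recovery_rate": (
            len(cred_correct & fully) / len(fully) if fully else float("nan")
        ),
        "n_decoys": len(decoys),
        "n_decoys_credentialed": decoys_credentialed,
        "decoy_credential_rate": (
            decoys_credentialed / len(decoys) if decoys else 0.0
        ),
    }
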