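"""Merge per-source/polarity annotations into one metabolite database.

ESI and APCI ionize complementary compound classes, and each polarity sees
a different ion of the same neutral metabolite, so the same compound can
surface in up to four runs (ESI+, ESI-, APCI+, APCI-). Entries sharing an
identity (best-tier name, else Hill formula) whose retention times fall in
the same cluster collapse into one database row that records the union of
detecting runs, the best tier, and the per-run intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import TIER_NONE, _TIER_RANK

#: Canonical run labels, e.g. "ESI-" = electrospray, negative mode.
RUN_LABELS = ("ESI+", "ESI-", "APCI+", "APCI-")


def run_label(source: str, polarity: str) -> str:
    sign = "+" if polarity == "positive" else "-"
    return f"{source}{sign}"


@dataclass
class DatabaseEntry:
    identity: str
    neutral_mass: float
    rt: float
    tier: str
    detected_in: frozenset[str]
    intensity_by_run: dict[str, float] = field(default_factory=dict)


def merge_annotations(
    ann_tables: Sequence[pd.DataFrame], rt_tol: float = 0.5
) -> list[DatabaseEntry]:
    """Merge annotation tables (one per source/polarity run) into a
    deduplicated database.

    Rows with the same identity and RT within ``rt_tol`` of a cluster seed
    collapse to one entry (union of runs, best tier, mean mass/RT).
    Distinct identities at the same mass/RT stay separate. Order of the
    input tables does not affect the result: rows are canonically sorted
    before clustering and the output is sorted by (identity, rt).
    """
    if not ann_tables:
        raise ValueError("need at least one annotation table")
    df = pd.concat(ann_tables, ignore_index=True)
    df = df[df["tier"] != TIER_NONE]
    df = df[(df["formula"] != "") | (df["name"] != "")]
    if df.empty:
        return []
    df["identity"] = np.where(df["name"] != "", df["name"], df["formula"])
    df["run"] = [run_label(s, p) for s, p in zip(df["source"], df["polarity"])]
    df = df.sort_values(["identity", "rt", "run", "u_mz"], kind="stable")

    entries: list[DatabaseEntry] = []
    for identity, grp in df.groupby("identity", sort=True):
        # greedy RT clustering: a row joins the current cluster while it is
        # within rt_tol of the cluster's first (seed) RT
        seed_rt = None
        cluster: list[pd.Series] = []
        clusters: list[list[pd.Series]] = []
        for _, row in grp.iterrows():
            if seed_rt is None or abs(row["rt"] - seed_rt) > rt_tol:
                cluster = []
                clusters.append(cluster)
                seed_rt = row["rt"]
            cluster.append(row)
        for cl in clusters:
            runs = frozenset(r["run"] for r in cl)
            tier = min((r["tier"] for r in cl), key=lambda t: _TIER_RANK[t])
            intensity = {}
            for r in cl:
                intensity[r["run"]] = intensity.get(r["run"], 0.0) + float(r["intensity"])
            entries.append(
                DatabaseEntry(
                    identity=str(identity),
                    neutral_mass=float(np.mean([r["neutral_mass"] for r in cl])),
                    rt=float(np.mean([r["rt"] for r in cl])),
                    tier=tier,
                    detected_in=runs,
                    intensity_by_run=intensity,
                )
            )
    entries.sort(key=lambda e: (e.identity, e.rt))
    return entries


def count_by_source(db: Sequence[DatabaseEntry]) -> pd.DataFrame:
    """Per-run detection counts plus the distinct-entry total.

    An entry detected in several runs counts once per run and once in the
    total, so the total is at most the sum of the per-run counts.
    """
    counts = {label: 0 for label in RUN_LABELS}
    for e in db:
        for label in e.detected_in:
            counts[label] += 1
    rows = [{"run": label, "n_metabolites": counts[label]} for label in RUN_LABELS]
    rows.append({"run": "total_distinct", "n_metabolites": len(db)})
    return pd.DataFrame(rows)


def database_to_frame(db: Sequence[DatabaseEntry]) -> pd.DataFrame:
    rows = []
    for e in db:
        row = {
            "identity": e.identity,
            "neutral_mass": e.neutral_mass,
            "rt": e.rt,
            "tier": e.tier,
            "detected_in": ";".join(sorted(e.detected_in)),
        }
        for label in RUN_LABELS:
            row[f"intensity_{label}"] = e.intensity_by_run.get(label, np.nan)
        rows.append(row)
    cols = ["identity", "neutral_mass", "rt", "tier", "detected_in"] + [
        f"intensity_{label}" for label in RUN_LABELS
    ]
    return pd.DataFrame(rows, columns=cols)
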