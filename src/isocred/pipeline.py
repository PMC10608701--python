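"""End-to-end orchestration: filter -> match -> credential -> decompose
-> annotate -> merge -> count, with all intermediate tables on disk."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from .annotation import Annotation, annotations_to_frame, match_library
from .config import ADDUCT_SHIFTS, element_bounds, match_config
from .dbbuild import count_by_source, database_to_frame, merge_annotations
from .formula import decompose
from .matching import LabelQuartet, credential, match_quartets, quartets_to_frame
from .peaks_io import (
    CONDITIONS,
    PeakSet,
    filter_peaks,
    read_library,
    read_msp,
    read_peak_table,
)
log = logging.getLogger("isocred")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in ``stage``."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


def run_key(source: str, polarity: str) -> str:
    return f"{source}_{polarity}"


def discover_runs(input_dir: str) -> list[tuple[str, str]]:
    """Runs present in a directory of ``{source}_{polarity}_{condition}.csv``
    peak tables (a run needs at least the unlabeled table)."""
    runs = []
    for source in ("ESI", "APCI"):
        for polarity in ("negative", "positive"):
            if os.path.exists(os.path.join(input_dir, f"{source}_{polarity}_U.csv")):
                runs.append((source, polarity))
    return runs


def load_run(input_dir: str, source: str, polarity: str) -> dict[str, PeakSet]:
    sets = {}
    for cond in CONDITIONS:
        path = os.path.join(input_dir, f"{source}_{polarity}_{cond}.csv")
        if not os.path.exists(path):
            raise StageError("read", f"missing peak table {path}")
        sets[cond] = read_peak_table(path, cond, polarity, source)
    return sets


def annotate_quartets(
    quartets: Sequence[LabelQuartet],
    library,
    cfg: dict[str, Any],
    query_ms2: Optional[dict[str, tuple[float, list[tuple[float, float]]]]] = None,
) -> list[Annotation]:
    """Decompose and library-match a list of credentialed quartets.

    ``query_ms2`` maps names to (precursor neutral mass, spectrum);
    a query spectrum is attached to a quartet when its precursor mass is
    within the decomposition tolerance of the quartet's neutral mass.
    """
    bounds = element_bounds(cfg)
    tol = float(cfg["decompose"]["tol_ppm"])
    a = cfg["annotation"]
    adduct = cfg["match"]["adduct_neg"], cfg["match"]["adduct_pos"]

    precursors = []
    if query_ms2:
        precursors = sorted((prec, spec) for prec, spec in query_ms2.values())
    prec_mz = np.array([p for p, _ in precursors])

    out = []
    for q in quartets:
        shift = ADDUCT_SHIFTS[adduct[0] if q.u.polarity == "negative" else adduct[1]]
        m = q.u.mz + shift
        candidates = decompose(m, q.c, q.n, tol, bounds)
        spec = None
        if len(prec_mz):
            i = int(np.searchsorted(prec_mz, m))
            best, best_d = None, np.inf
            for j in (i - 1, i):
                if 0 <= j < len(prec_mz):
                    d = abs(prec_mz[j] - m)
                    if d < best_d:
                        best, best_d = j, d
            if best is not None and best_d / m * 1e6 <= a["mass_tol_ppm"]:
                spec = precursors[best][1]
        out.append(
            match_library(
                q, candidates, library,
                mass_tol_ppm=float(a["mass_tol_ppm"]),
                rt_tol=float(a["rt_tol_min"]),
                ms2_threshold=float(a["ms2_threshold"]),
                frag_tol_mz=float(a["frag_tol_mz"]),
                query_ms2=spec,
            )
        )
    return out


@dataclass
class PipelineResult:
    stage_counts: pd.DataFrame
    database: pd.DataFrame
    summary: pd.DataFrame
    quartets_by_run: dict[tuple[str, str], list[LabelQuartet]]


def run_pipeline(
    cfg: dict[str, Any],
    input_dir: str,
    library_path: str,
    out_dir: str,
    msp_path: Optional[str] = None,
    query_msp_path: Optional[str] = None,
) -> PipelineResult:
    """Execute the full chain on a directory of four-condition peak tables.

    Writes per-run quartet and annotation tables plus ``database.tsv`` and
    ``summary.tsv`` into ``out_dir``; logs peak/quartet/entry counts at
    every stage. Raises :class:`StageError` naming the failing stage
    (partial outputs written so far are retained).
    """
    os.makedirs(out_dir, exist_ok=True)
    mcfg = match_config(cfg)
    f = cfg["filter"]

    try:
        library = read_library(library_path, msp_path)
    except Exception as e:
        raise StageError("read_library", str(e)) from e
    query_ms2 = None
    if query_msp_path:
        raw = read_msp(query_msp_path)
        # precursor mass is carried per spectrum name in the companion
        # library-style MSP written by the simulator
        from matchms.importing import load_from_msp

        query_ms2 = {}
        for spec in load_from_msp(str(query_msp_path), metadata_harmonization=False):
            name = str(spec.metadata.get("compound_name") or spec.metadata.get("name"))
            prec = spec.metadata.get("precursor_mz")
            if prec is None:
                continue
            query_ms2[name] = (float(prec), raw[name])

    runs = discover_runs(input_dir)
    if not runs:
        log.warning("no peak tables found in %s; writing empty database", input_dir)

    stage_rows = []
    ann_tables = []
    quartets_by_run: dict[tuple[str, str], list[LabelQuartet]] = {}
    for source, polarity in runs:
        key = run_key(source, polarity)
        try:
            sets = load_run(input_dir, source, polarity)
        except StageError:
            raise
        except Exception as e:
            raise StageError("read", str(e)) from e
        try:
            filtered = {
                cond: filter_peaks(ps, float(f["min_snr"]), (float(f["mz_min"]), float(f["mz_max"])))
                for cond, ps in sets.items()
            }
            quartets = match_quartets(
                filtered["U"], filtered["C13"], filtered["N15"], filtered["C13N15"], mcfg
            )
        except Exception as e:
            raise StageError("match", str(e)) from e
        quartets_by_run[(source, polarity)] = quartets
        credentialed = credential(quartets)
        quartets_to_frame(quartets).to_csv(
            os.path.join(out_dir, f"quartets_{key}.tsv"), sep="\t", index=False
        )
        try:
            annotations = annotate_quartets(credentialed, library, cfg, query_ms2)
        except Exception as e:
            raise StageError("annotate", str(e)) from e
        table = annotations_to_frame(annotations, source, polarity)
        table.to_csv(os.path.join(out_dir, f"annotations_{key}.tsv"), sep="\t", index=False)
        ann_tables.append(table)
        n_ann = int((table["tier"] != ann_mod.TIER_NONE).sum())
        stage_rows.append(
            {
                "run": key,
                "peaks_unlabeled": len(filtered["U"]),
                "quartets": len(quartets),
                "credentialed": len(credentialed),
                "annotated": n_ann,
            }
        )
        log.info(
            "%s: %d unlabeled peaks -> %d quartets -> %d credentialed -> %d annotated",
            key, len(filtered["U"]), len(quartets), len(credentialed), n_ann,
        )

    try:
        db = merge_annotations(ann_tables, float(cfg["merge"]["rt_tol_min"])) if ann_tables else []
    except Exception as e:
        raise StageError("merge", str(e)) from e
    db_frame = database_to_frame(db)
    db_frame.to_csv(os.path.join(out_dir, "database.tsv"), sep="\t", index=False)
    summary = count_by_source(db) if db else count_by_source([])
    summary.to_csv(os.path.join(out_dir, "summary.tsv"), sep="\t", index=False)
    log.info("database: %d distinct entries", len(db))

    stage_counts = pd.DataFrame(
        stage_rows, columns=["run", "peaks_unlabeled", "quartets", "credentialed", "annotated"]
    )
    stage_counts.to_csv(os.path.join(out_dir, "stage_counts.tsv"), sep="\t", index=False)
    return PipelineResult(
        stage_counts=stage_counts,
        database=db_frame,
        summary=summary,
        quartets_by_run=quartets_by_run,
    )
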