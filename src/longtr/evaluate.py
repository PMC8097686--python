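"""Benchmark evaluation: unit recovery, length error, sensitivity tables.

A predicted unit counts as correct when some cyclic rotation of it reaches
the required global-alignment identity against the planted unit (a cycle
has no canonical start, so rotation-equivalent units are the same unit).
tau = 1.0 demands exact recovery; tau = 0.95 tolerates e.g. five errors in
a 100 nt unit.  Sensitivity of a run is the fraction of reads whose
planted unit is recovered by at least one reported call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .chaining import RepeatCall
from .pipeline import PipelineConfig, find_repeats
from .simulate import BenchmarkSpec, ErrorModel, ReadTruth, simulate_read

__all__ = [
    "rotation_identity",
    "unit_match",
    "length_error",
    "evaluate_read",
    "run_benchmark",
]


def rotation_identity(pred: str, truth: str) -> float:
    """Best global-alignment identity of any rotation of ``pred`` vs
    ``truth``: 1 - distance / mean(length)."""
    if not pred or not truth:
        return 0.0
    doubled = pred + pred
    best = None
    for i in range(len(pred)):
        rot = doubled[i : i + len(pred)]
        d = edlib.align(rot, truth, mode="NW", task="distance")["editDistance"]
        if best is None or d < best:
            best = d
            if best == 0:
                break
    return 1.0 - best / ((len(pred) + len(truth)) / 2.0)


def unit_match(pred: str, truth: str, tau: float = 1.0) -> bool:
    """True when some rotation of ``pred`` is tau-identical to ``truth``."""
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    if not pred or not truth:
        return False
    return rotation_identity(pred, truth) >= tau


def length_error(pred_len: int, true_len: int) -> float:
    """|len_pred - len_true| / len_true."""
    if true_len <= 0:
        raise ValueError("true_len must be positive")
    return abs(pred_len - true_len) / true_len


@dataclass
class ReadEvaluation:
    matched: bool
    best_identity: float
    best_call: RepeatCall | None
    len_err: float | None


def evaluate_read(
    truth: ReadTruth,
    calls: list[RepeatCall],
    tau: float = 1.0,
    length_error_bound: float | None = None,
) -> ReadEvaluation:
    """Score one read: does any call recover the planted unit (and, when
    requested, the repeat length within the bound)?"""
    best_id, best_call = 0.0, None
    for c in calls:
        ident = rotation_identity(c.unit, truth.true_unit)
        if ident > best_id or best_call is None:
            best_id, best_call = ident, c
    matched = best_call is not None and best_id >= tau
    len_err = None
    if best_call is not None:
        len_err = length_error(best_call.span, truth.true_len)
        if matched and length_error_bound is not None:
            matched = len_err <= length_error_bound
    return ReadEvaluation(matched, best_id, best_call, len_err)


def run_benchmark(
    unit_lengths: list[int],
    copy_numbers: list[int],
    error: ErrorModel,
    n_reads: int,
    seed: int,
    cfg: PipelineConfig | None = None,
    tau: float = 1.0,
    length_error_bound: float | None = None,
) -> pd.DataFrame:
    """Sensitivity per (unit_len, copies) cell over seeded synthetic reads.

    Returns a table with one row per cell: unit_len, copies, n_reads,
    detected, sensitivity, mean length error of matched reads.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    root = np.random.SeedSequence(seed)
    cells = [(u, c) for u in unit_lengths for c in copy_numbers]
    for (unit_len, copies), cell_ss in zip(cells, root.spawn(len(cells))):
        spec = BenchmarkSpec(unit_len=unit_len, copies=copies, error=error)
        hits = 0
        len_errs = []
        for child in cell_ss.spawn(n_reads):
            rt = simulate_read(spec, np.random.default_rng(child))
            calls = find_repeats(rt.read, cfg)
            ev = evaluate_read(rt, calls, tau, length_error_bound)
            if ev.matched:
                hits += 1
                if ev.len_err is not None:
                    len_errs.append(ev.len_err)
        rows.append(
            {
                "unit_len": unit_len,
                "copies": copies,
                "n_reads": n_reads,
                "detected": hits,
                "sensitivity": hits / n_reads if n_reads else float("nan"),
                "mean_length_error": float(np.mean(len_errs)) if len_errs else float("nan"),
            }
        )
    return pd.DataFrame(rows)
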