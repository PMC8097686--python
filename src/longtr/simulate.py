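"""Synthetic reads with planted tandem repeats and an i.i.d. error channel.

Each benchmark read is built as flank + unit^copies + flank where the unit
is a uniformly random primitive string and each flank is a random string
of the same length as the repeat, so boundary prediction is genuinely
tested on both sides.  The read then passes through a per-base channel
that substitutes, deletes, or inserts with fixed rates; presets emulate a
Nanopore-like raw read (10% substitution / 5% insertion / 5% deletion), a
PacBio CLR-like insertion-dominated profile, and a highly accurate mode
(1% / 0.5% / 0.5%).

Because the channel is applied i.i.d., errors can be drawn independently
per segment, which keeps the post-error repeat boundaries exact in the
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kmers import BASES, Read

__all__ = [
    "ErrorModel",
    "ERROR_PRESETS",
    "BenchmarkSpec",
    "ReadTruth",
    "random_primitive_unit",
    "make_truth",
    "apply_errors",
    "simulate_read",
    "write_benchmark",
    "UNIT_LENGTHS",
    "COPY_NUMBERS",
]

UNIT_LENGTHS = (2, 5, 10, 20, 50, 100, 200)
COPY_NUMBERS = (10, 20, 50, 100, 200)


@dataclass(frozen=True)
class ErrorModel:
    """Per-base substitution / insertion / deletion rates."""

    sub: float
    ins: float
    dele: float

    def __post_init__(self) -> None:
        if min(self.sub, self.ins, self.dele) < 0 or self.sub + self.ins + self.dele >= 1:
            raise ValueError("rates must be non-negative with sub+ins+del < 1")

    @property
    def total(self) -> float:
        return self.sub + self.ins + self.dele


ERROR_PRESETS: dict[str, ErrorModel] = {
    "none": ErrorModel(0.0, 0.0, 0.0),
    "nanopore_like": ErrorModel(0.10, 0.05, 0.05),
    "pacbio_like": ErrorModel(0.015, 0.09, 0.045),
    "accurate": ErrorModel(0.01, 0.005, 0.005),
}


@dataclass
class BenchmarkSpec:
    unit_len: int = 20
    copies: int = 100
    error: ErrorModel = field(default_factory=lambda: ERROR_PRESETS["nanopore_like"])
    n_reads: int = 1
    seed: int = 0


@dataclass
class ReadTruth:
    """A synthetic read with its planted-repeat ground truth."""

    read: Read
    true_start: int
    true_end: int
    true_unit: str
    true_copies: int
    template_len: int

    @property
    def true_len(self) -> int:
        return self.true_end - self.true_start


def _is_primitive(u: str) -> bool:
    n = len(u)
    for p in range(1, n):
        if n % p == 0 and u == u[:p] * (n // p):
            return False
    return True


def random_primitive_unit(unit_len: int, rng: np.random.Generator) -> str:
    """Uniform random unit that is not itself a perfect tandem of a
    shorter unit."""
    while True:
        u = "".join(np.array(list(BASES))[rng.integers(0, 4, unit_len)])
        if _is_primitive(u):
            return u


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, n)])


def _extends_array(flank: str, unit: str) -> bool:
    """Does the flank's start continue the cyclic unit phase?

    True when some prefix at least one unit long matches the tandem
    continuation at >= 75% positional identity: such a flank would
    extend the planted repeat and leave its true boundary ill-defined.
    """
    limit = min(len(flank), 4 * len(unit))
    cont = (unit * (limit // len(unit) + 1))[:limit]
    matches = 0
    for i in range(limit):
        matches += flank[i] == cont[i]
        if i + 1 >= len(unit) and matches >= 0.75 * (i + 1):
            return True
    return False


def make_truth(spec: BenchmarkSpec, rng: np.random.Generator) -> tuple[str, str, str, str]:
    """Pre-error template: (flank_left, repeat, flank_right, unit).

    Flanks are resampled when they would continue the tandem array
    (see :func:`_extends_array`), so the planted boundary is the true
    boundary of the repeat in the string.
    """
    unit = random_primitive_unit(spec.unit_len, rng)
    repeat = unit * spec.copies
    fl = _random_seq(len(repeat), rng)
    while _extends_array(fl[::-1], unit[::-1]):
        fl = _random_seq(len(repeat), rng)
    fr = _random_seq(len(repeat), rng)
    while _extends_array(fr, unit):
        fr = _random_seq(len(repeat), rng)
    return fl, repeat, fr, unit


def apply_errors(s: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """Pass a string through the i.i.d. error channel.

    Per input base: delete with probability del; else substitute to a
    uniformly chosen different base with probability sub; independently
    insert one uniform random base after it with probability ins.
    """
    if not s or model.total == 0.0:
        return s
    n = len(s)
    r = rng.random(n)
    subs = rng.integers(1, 4, n)  # offset to a *different* base
    ins_mask = rng.random(n) < model.ins
    ins_bases = rng.integers(0, 4, n)
    base_idx = {b: i for i, b in enumerate(BASES)}
    out: list[str] = []
    for i, ch in enumerate(s):
        if r[i] < model.dele:
            pass
        elif r[i] < model.dele + model.sub:
            out.append(BASES[(base_idx[ch] + subs[i]) % 4])
        else:
            out.append(ch)
        if ins_mask[i]:
            out.append(BASES[ins_bases[i]])
    return "".join(out)


def simulate_read(
    spec: BenchmarkSpec, seed: int | np.random.Generator, read_id: str = "sim"
) -> ReadTruth:
    """One synthetic read with exact post-error repeat boundaries."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fl, repeat, fr, unit = make_truth(spec, rng)
    fl_e = apply_errors(fl, spec.error, rng)
    rep_e = apply_errors(repeat, spec.error, rng)
    fr_e = apply_errors(fr, spec.error, rng)
    seq = fl_e + rep_e + fr_e
    return ReadTruth(
        read=Read(read_id, seq),
        true_start=len(fl_e),
        true_end=len(fl_e) + len(rep_e),
        true_unit=unit,
        true_copies=spec.copies,
        template_len=3 * len(repeat),
    )


def write_benchmark(
    specs: list[BenchmarkSpec], out_prefix: str | Path, seed: int
) -> tuple[Path, Path]:
    """Write benchmark reads as FASTA with a truth TSV sidecar.

    Deterministic: identical specs and seed give byte-identical files.
    Returns (fasta_path, truth_path).
    """
    out_prefix = Path(out_prefix)
    fasta = out_prefix.with_suffix(".fasta")
    truth = out_prefix.with_suffix(".truth.tsv")
    root = np.random.SeedSequence(seed)
    with open(fasta, "w") as fa, open(truth, "w") as tr:
        tr.write("read_id\tstart\tend\tunit\tcopies\n")
        idx = 0
        for spec, ss in zip(specs, root.spawn(len(specs))):
            for child in ss.spawn(spec.n_reads):
                rid = f"sim_{spec.unit_len}x{spec.copies}_{idx}"
                rt = simulate_read(spec, np.random.default_rng(child), rid)
                fa.write(f">{rid}\n{rt.read.seq}\n")
                tr.write(
                    f"{rid}\t{rt.true_start}\t{rt.true_end}\t{rt.true_unit}\t{rt.true_copies}\n"
                )
                idx += 1
    return fasta, truth
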