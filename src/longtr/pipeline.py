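"""End-to-end tandem repeat calling on a single read.

Stages: (1) scan the read with the (k, w) grid for candidate ranges;
(2) cluster near-identical ranges from different patterns; (3) for each
range, sweep k over a de Bruijn graph of the padded range, build greedy
cycle units, repair them, and keep the unit with the best wraparound
score; (4) refine the repeat boundaries from the alignment, growing the
aligned region outward while the repeat continues, so a seed detected in
the middle of a long repeat still recovers its full extent; (5) chain
calls into a disjoint report; (6) polish the surviving units against
their intervals.

Boundary refinement reduces the per-base match profile of the alignment
to the maximum-scoring segment around the candidate core, under a match
threshold t placed between the observed in-repeat identity and a
random-sequence baseline: the segment extends over the repeat and stops
where the alignment degrades to flank-like identity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .align import suffix_sigma, wraparound_align
from .assembly import DEFAULT_K_RANGE, build_graph, candidate_units, canonical_rotation
from .boundaries import (
    DEFAULT_THETA_B,
    CandidateRange,
    GridPattern,
    scan_read,
)
from .chaining import ChainConfig, RepeatCall, chain, finalize
from .kmers import Read, SimilarityMeasure
from .refine import ma_polish, transition_repair

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "find_repeats"]

RANDOM_MATCH_BASELINE = 0.55  # match fraction of random DNA vs an unrelated cyclic unit


@dataclass
class PipelineConfig:
    """Tunable parameters of the caller; defaults follow the method."""

    measure: SimilarityMeasure = SimilarityMeasure.MANHATTAN
    theta_b: float = DEFAULT_THETA_B
    k_range: range | list[int] = field(default_factory=lambda: DEFAULT_K_RANGE)
    chain: ChainConfig = field(default_factory=ChainConfig)
    grid: list[GridPattern] | None = None
    eval_window: int = 3000  # subregion length for cross-k sigma ranking
    max_candidates: int = 4000  # cluster representatives per read
    min_copies: float = 3.0  # fewer copies cannot be told from chance repetition
    enforce_span: bool = True  # candidate and final span must reach 2w
    polish: bool = True

    def describe(self) -> dict:
        return {
            "measure": self.measure.value,
            "theta_b": self.theta_b,
            "k_range": [min(self.k_range), max(self.k_range)],
            "overlap_limit": self.chain.overlap_limit,
            "min_sigma_frac": self.chain.min_sigma_frac,
            "eval_window": self.eval_window,
        }


def _cluster_candidates(
    cands: list[CandidateRange], max_keep: int
) -> list[CandidateRange]:
    """One representative per group of near-identical ranges.

    Ranges from different patterns that reciprocally overlap by >= 75%
    describe the same repeat; the member with the smallest window (and
    best start peak on ties) represents the group, as the smallest
    detecting window carries the tightest boundary estimate.
    """
    order = sorted(cands, key=lambda c: (-(c.e - c.b), -c.peak_b))
    clusters: list[list[CandidateRange]] = []
    fb = np.empty(len(order), dtype=np.int64)  # founder bounds, vectorized overlap
    fe = np.empty(len(order), dtype=np.int64)
    fl = np.empty(len(order), dtype=np.int64)
    nc = 0
    for c in order:
        ln = c.e - c.b
        if nc:
            ov = np.minimum(c.e, fe[:nc]) - np.maximum(c.b, fb[:nc])
            hit = np.nonzero(ov >= 0.75 * np.maximum(ln, fl[:nc]))[0]
        else:
            hit = ()
        if len(hit):
            clusters[int(hit[0])].append(c)
        elif nc < max_keep:
            clusters.append([c])
            fb[nc], fe[nc], fl[nc] = c.b, c.e, ln
            nc += 1
    reps = [min(cl, key=lambda c: (c.w, -c.peak_b)) for cl in clusters]
    # widest candidates first: later seeds inside an accepted call are skipped
    reps.sort(key=lambda c: (-(c.e - c.b), c.b))
    return reps


def _region_k_range(cfg_range: range | list[int], region_len: int) -> list[int]:
    """Clip the k sweep to values useful for the range at hand.

    A unit fits at most half the range and its k-mers should be mostly
    unique within the unit (expected self-collisions < ~1), which needs
    4^k on the order of the squared unit length.
    """
    max_unit = max(2, region_len // 2)
    kmax = math.ceil(math.log(2.0 * max_unit * max_unit, 4.0))
    return [k for k in cfg_range if k <= max(3, kmax)]


def _max_segment(scores: np.ndarray) -> tuple[int, int, float]:
    """Maximum-sum contiguous segment [a, b) of a score array."""
    cum = np.concatenate([[0.0], np.cumsum(scores)])
    run_min = np.minimum.accumulate(cum[:-1])
    gains = cum[1:] - run_min
    b = int(np.argmax(gains)) + 1
    a = int(np.argmin(cum[:b]))
    return a, b, float(gains[b - 1])


def _refine_boundaries(
    match_flags: np.ndarray, core_lo: int, core_hi: int
) -> tuple[int, int]:
    """Maximum-scoring segment of the per-base match profile.

    Scores are (1 - t) for a match and -t otherwise, with the threshold t
    midway between an estimate of the in-repeat identity and the
    random-sequence baseline.  t is seeded from the candidate core and
    re-estimated from the found segment, so a candidate whose range was
    off (e.g. mostly flank) still converges onto the repeat itself.
    """
    m = len(match_flags)
    core_lo = max(0, min(core_lo, m - 1))
    core_hi = max(core_lo + 1, min(core_hi, m))
    core = match_flags[core_lo:core_hi]
    m_est = float(core.mean()) if len(core) else 1.0
    a, b = core_lo, core_hi
    for _ in range(3):
        t = float(np.clip((m_est + RANDOM_MATCH_BASELINE) / 2.0, 0.60, 0.93))
        scores = np.where(match_flags > 0, 1.0 - t, -t)
        a2, b2, gain = _max_segment(scores)
        if gain <= 0 or b2 <= a2:
            break
        a, b = a2, b2
        new_est = float(match_flags[a:b].mean())
        if abs(new_est - m_est) < 0.01:
            break
        m_est = new_est
    return a, b


def _finish_call(
    read: Read,
    unit: str,
    k_used: int,
    w_used: int,
    ps: int,
    pe: int,
    core: tuple[int, int],
    cfg: PipelineConfig,
    min_span: int = 0,
) -> RepeatCall | None:
    """Boundary refinement and final alignment of one unit.

    The aligned region grows outward (doubling steps) whenever the
    refined boundary touches the region edge, so a repeat much longer
    than the seeding candidate range is still recovered whole.
    """
    n = len(read)
    if not unit:
        return None
    grow = max(2 * len(unit), w_used, 32)
    for _ in range(40):
        region = read.seq[ps:pe]
        if not region:
            return None
        full = wraparound_align(unit, region)
        a, b = _refine_boundaries(full.match_flags, core[0] - ps, core[1] - ps)
        grow_left = a <= 1 and ps > 0
        grow_right = b >= len(region) - 1 and pe < n
        if not grow_left and not grow_right:
            break
        if grow_left:
            ps = max(0, ps - grow)
        if grow_right:
            pe = min(n, pe + grow)
        grow *= 2
    s, e = ps + a, ps + b
    if e - s < max(4, 2 * len(unit) - 1, min_span):
        return None
    trimmed = read.seq[s:e]
    unit = canonical_rotation(unit)
    res = wraparound_align(unit, trimmed)
    if res.copies < cfg.min_copies:
        return None
    return RepeatCall(
        read_id=read.id,
        s=s,
        e=e,
        unit=unit,
        sigma=res.sigma,
        copies=res.copies,
        identity=res.identity,
        k_used=k_used,
        w_used=w_used,
        prefix_sigma=res.prefix_sigma,
        suffix_sigma=suffix_sigma(unit, trimmed),
    )


PERIODICITY_SCREEN_LEN = 300
PERIODICITY_MIN_FRACTION = 0.52


def _best_period_fraction(region: str, max_period: int) -> float:
    """Best positional self-match fraction over small shift periods.

    A genuine tandem repeat keeps a high fraction even under sequencing
    error at the period of its unit; random sequence stays near 1/4 for
    every shift.  Used as a cheap screen before the unit sweep on short
    candidate ranges, where chance window-similarity peaks abound.
    """
    from .kmers import seq_to_digits

    d = seq_to_digits(region)
    best = 0.0
    for p in range(1, min(max_period, len(d) - 1) + 1):
        frac = float(np.mean(d[:-p] == d[p:]))
        if frac > best:
            best = frac
    return best


def _call_candidate(
    read: Read, cand: CandidateRange, cfg: PipelineConfig
) -> RepeatCall | None:
    n = len(read)
    pad = cand.w // 2
    ps, pe = max(0, cand.b - pad), min(n, cand.e + pad)
    region = read.seq[ps:pe]
    if len(region) < 4:
        return None
    if len(region) <= PERIODICITY_SCREEN_LEN:
        core = read.seq[cand.b : cand.e]
        if (
            _best_period_fraction(core, len(core) // 2)
            < PERIODICITY_MIN_FRACTION
        ):
            return None
    # unit sweep over k, transition repair, sigma ranking on a capped window
    units = candidate_units(region, _region_k_range(cfg.k_range, len(region)))
    if not units:
        return None
    ew = cfg.eval_window
    if len(region) > ew:
        off = (len(region) - ew) // 2
        eval_region = region[off : off + ew]
    else:
        eval_region = region
    best = None
    for uc in units:
        g = build_graph(region, uc.k_used)
        unit = transition_repair(uc.unit, g)
        if not unit or len(unit) > len(region) // 2:
            continue
        target = eval_region if 3 * len(unit) <= len(eval_region) else region
        res = wraparound_align(unit, target)
        key = (res.sigma, -len(unit), unit)
        if best is None or key > best[0]:
            best = (key, unit, uc.k_used)
    if best is None:
        return None
    _, unit, k_used = best
    # a repeat detectable at window w spans at least 2w
    min_span = 2 * cand.w if cfg.enforce_span else 0
    return _finish_call(
        read, unit, k_used, cand.w, ps, pe, (cand.b, cand.e), cfg, min_span
    )


def _merge_same_unit(
    calls: list[RepeatCall], read: Read, cfg: PipelineConfig
) -> list[RepeatCall]:
    """Reunite neighboring calls that report the same unit.

    Distinct repeats of the same unit stay separate: the gap must be
    small relative to the combined span to merge."""
    if len(calls) < 2:
        return calls
    calls = sorted(calls, key=lambda c: (c.s, c.e))
    groups: list[list[RepeatCall]] = [[calls[0]]]
    for c in calls[1:]:
        g = groups[-1]
        gap = c.s - max(m.e for m in g)
        if c.unit == g[0].unit and gap <= 0.3 * (c.span + sum(m.span for m in g)):
            g.append(c)
        else:
            groups.append([c])
    out: list[RepeatCall] = []
    for g in groups:
        if len(g) == 1:
            out.append(g[0])
            continue
        lead = max(g, key=lambda c: c.sigma)
        lo, hi = min(c.s for c in g), max(c.e for c in g)
        pad = len(lead.unit) + 10
        merged = _finish_call(
            read,
            lead.unit,
            lead.k_used,
            lead.w_used,
            max(0, lo - pad),
            min(len(read), hi + pad),
            (lo, hi),
            cfg,
        )
        out.append(merged if merged is not None else lead)
    return out


def _polish_final(calls: list[RepeatCall], read: Read) -> list[RepeatCall]:
    """Multiple-alignment polish of the units that survived chaining."""
    for c in calls:
        region = read.seq[c.s : c.e]
        polished = ma_polish(c.unit, region)
        if polished and polished != c.unit:
            unit = canonical_rotation(polished)
            res = wraparound_align(unit, region)
            c.unit = unit
            c.sigma = res.sigma
            c.copies = res.copies
            c.identity = res.identity
            c.prefix_sigma = res.prefix_sigma
            c.suffix_sigma = suffix_sigma(unit, region)
        else:
            c.unit = canonical_rotation(c.unit)
    return calls


def find_repeats(read: Read, cfg: PipelineConfig | None = None) -> list[RepeatCall]:
    """All disjoint tandem repeat calls on one read, sorted by start."""
    cfg = cfg or PipelineConfig()
    cands = scan_read(read, cfg.measure, cfg.theta_b, cfg.grid)
    if not cands:
        return []
    if cfg.enforce_span:
        cands = [c for c in cands if c.e - c.b >= 2 * c.w] or cands
    reps = _cluster_candidates(cands, cfg.max_candidates)
    logger.debug(
        "read %s: %d raw candidates, %d after clustering", read.id, len(cands), len(reps)
    )
    calls: list[RepeatCall] = []
    for cand in reps:
        # a seed already explained by an accepted call adds nothing
        span = cand.e - cand.b
        covered = sum(
            max(0, min(cand.e, c.e) - max(cand.b, c.s)) for c in calls
        )
        if span > 0 and covered >= 0.8 * span:
            continue
        call = _call_candidate(read, cand, cfg)
        if call is not None:
            calls.append(call)
    if not calls:
        return []
    calls = _merge_same_unit(calls, read, cfg)
    chained = chain(calls, cfg.chain)
    final = finalize(chained, read.seq)
    if cfg.polish:
        final = _polish_final(final, read)
    return final
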