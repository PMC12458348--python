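"""Upstream ORF extraction and the translated-uORF frame test.

Candidate uORFs are every AUG in the 5'UTR paired with its first in-frame
stop codon (which may lie inside the CDS: "overlapping" uORFs). Translation
is called from 3-nt periodicity of P-site anchored footprints: within each
candidate, per-codon in-frame counts are compared against each of the two
off-frame positions by a one-sided Wilcoxon signed-rank test, the two
p-values are combined by Stouffer's method, and candidates are selected at
a Benjamini-Hochberg FDR below alpha.

The signed-rank null distribution is computed exactly (by dynamic
programming over doubled midranks, which handles tied absolute differences)
for n <= 25 pairs, and by a normal approximation with tie correction and
continuity correction above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import STOP_CODONS, CoverageProfile, TranscriptModel

EXACT_MAX_N = 25
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_CODONS = 2
DEFAULT_MIN_READS = 8


@dataclass(frozen=True)
class UorfCandidate:
    """An AUG-initiated ORF starting in the 5'UTR."""

    transcript_id: str
    start: int  # first nt of the AUG
    stop: int  # first nt of the in-frame stop codon
    n_codons: int  # coding codons, excluding the stop codon
    kind: Literal["contained", "overlapping"]


@dataclass
class UorfCall:
    candidate: UorfCandidate
    p_frame1: Optional[float]
    p_frame2: Optional[float]
    z1: Optional[float]
    z2: Optional[float]
    p_combined: Optional[float]
    q_value: Optional[float] = None
    robust: bool = False


def extract_candidate_uorfs(transcript: TranscriptModel) -> list[UorfCandidate]:
    """All AUGs in the 5'UTR paired with their first in-frame stop codon.

    The stop search continues into the CDS ("overlapping" candidates);
    AUGs with no in-frame stop before the transcript end are dropped.
    Nested and overlapping candidates are all retained.
    """
    seq = transcript.sequence
    out = []
    for start in range(transcript.cds_start):
        if seq[start : start + 3] != "ATG":
            continue
        for stop in range(start + 3, transcript.length - 2, 3):
            if seq[stop : stop + 3] in STOP_CODONS:
                kind = "contained" if stop < transcript.cds_start else "overlapping"
                out.append(
                    UorfCandidate(
                        transcript.transcript_id,
                        start,
                        stop,
                        (stop - start) // 3,
                        kind,
                    )
                )
                break
    return out


# ---------------------------------------------------------------------------
# One-sided exact Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank_greater(
    x: Sequence[float], y: Sequence[float]
) -> float:
    """One-sided P(W+ >= observed) for paired differences x - y.

    Zero differences are dropped before ranking (all-zero input gives
    p = 1). Absolute differences are midranked, so tied magnitudes are
    handled exactly; the null distribution is exact for n <= 25 pairs
    (dynamic programming over doubled ranks, equivalent to enumerating all
    2^n sign assignments) and a tie-corrected normal approximation with
    continuity correction beyond.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))  # midranks; multiples of 0.5
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        return _exact_sf(ranks, w_plus)
    mean = n * (n + 1) / 4
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - ((tie_counts**3 - tie_counts).sum()) / 48
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))


def _exact_sf(ranks: np.ndarray, w_plus: float) -> float:
    """P(W+ >= w_plus) under random signs, exactly, for midranked data.

    Doubling the ranks makes them integers; ``counts[s]`` tallies the sign
    assignments whose positive-rank (doubled) sum is s.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = doubled.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[: total + 1 - r].copy()
    threshold = int(np.ceil(np.rint(2 * w_plus)))
    return float(counts[threshold:].sum() / 2 ** len(doubled))


def uorf_frame_test(
    candidate: UorfCandidate,
    profile: CoverageProfile,
    unit: Literal["codon"] = "codon",
) -> tuple[Optional[float], Optional[float]]:
    """Per-codon frame comparison on a P-site anchored profile.

    For codon j of the candidate, the in-frame count at ``start + 3j`` is
    paired with the counts at ``start + 3j + 1`` (p_frame1) and
    ``start + 3j + 2`` (p_frame2); each comparison is a one-sided
    signed-rank test of "in-frame greater". Candidates with fewer than 2
    codons are untestable and return (None, None).
    """
    if candidate.n_codons < 2:
        return None, None
    counts = profile.counts
    idx = candidate.start + 3 * np.arange(candidate.n_codons)
    if idx[-1] + 2 >= counts.size:
        return None, None
    x = counts[idx]
    p1 = wilcoxon_signed_rank_greater(x, counts[idx + 1])
    p2 = wilcoxon_signed_rank_greater(x, counts[idx + 2])
    return p1, p2


# ---------------------------------------------------------------------------
# P-value combination and FDR
# ---------------------------------------------------------------------------

_P_CLIP = 1e-300


def stouffer_combine(p1: float, p2: float) -> float:
    """Combine two one-sided p-values by Stouffer's method (equal weights).

    z_i = Phi^{-1}(1 - p_i); p = 1 - Phi((z1 + z2) / sqrt(2)). Inputs of
    exactly 1 are clipped just below 1 so z stays finite.
    """
    for p in (p1, p2):
        if not 0 < p <= 1:
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    eps = np.finfo(float).epsneg
    z1 = stats.norm.isf(min(max(p1, _P_CLIP), 1 - eps))
    z2 = stats.norm.isf(min(max(p2, _P_CLIP), 1 - eps))
    return float(stats.norm.sf((z1 + z2) / np.sqrt(2)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def call_uorfs(
    transcripts: dict[str, TranscriptModel],
    profiles: dict[str, CoverageProfile],
    alpha: float = DEFAULT_ALPHA,
    min_codons: int = DEFAULT_MIN_CODONS,
    min_reads: int = DEFAULT_MIN_READS,
) -> list[UorfCall]:
    """Extract, test, combine, and FDR-adjust uORF candidates jointly.

    Candidates need at least ``min_codons`` codons and ``min_reads``
    anchored reads within [start, stop) of their (P-site anchored) profile
    to be testable; BH adjustment runs across all testable candidates from
    all transcripts, and ``robust`` flags q < alpha.
    """
    calls: list[UorfCall] = []
    for tid, profile in profiles.items():
        if tid not in transcripts:
            continue
        tx = transcripts[tid]
        for cand in extract_candidate_uorfs(tx):
            if cand.n_codons < min_codons:
                continue
            if profile.counts[cand.start : cand.stop].sum() < min_reads:
                continue
            p1, p2 = uorf_frame_test(cand, profile)
            if p1 is None or p2 is None:
                calls.append(UorfCall(cand, p1, p2, None, None, None))
                continue
            eps = np.finfo(float).epsneg
            z1 = float(stats.norm.isf(min(max(p1, _P_CLIP), 1 - eps)))
            z2 = float(stats.norm.isf(min(max(p2, _P_CLIP), 1 - eps)))
            calls.append(UorfCall(cand, p1, p2, z1, z2, stouffer_combine(p1, p2)))
    testable = [c for c in calls if c.p_combined is not None]
    if testable:
        q = bh_adjust([c.p_combined for c in testable])
        for call, qv in zip(testable, q):
            call.q_value = float(qv)
            call.robust = qv < alpha
    return calls


def calls_to_frame(calls: Sequence[UorfCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [c.candidate.transcript_id for c in calls],
            "start": [c.candidate.start for c in calls],
            "stop": [c.candidate.stop for c in calls],
            "n_codons": [c.candidate.n_codons for c in calls],
            "kind": [c.candidate.kind for c in calls],
            "p_frame1": [c.p_frame1 for c in calls],
            "p_frame2": [c.p_frame2 for c in calls],
            "p_combined": [c.p_combined for c in calls],
            "q_value": [c.q_value for c in calls],
            "robust": [c.robust for c in calls],
        }
    )
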