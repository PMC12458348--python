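"""Per-mRNA stop-codon pausing index, 3'UTR relative density, and
stop-context (GA-rich / C-rich) stratification.

The pausing index normalizes footprint density in the stop-codon window by
the mean CDS occupancy, factoring out mRNA abundance and overall
translation efficiency: on 5'-end coordinates terminating ribosomes leave
peaks at -15 (stop codon in the A-site) and -12 (forward-shifted,
post-termination) nt from the stop codon's first nt, so the default
window is [-15, -12] inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .io import CoverageProfile, TranscriptModel
from .profiles import MetageneResult, cds_counts, metagene_aggregate

DEFAULT_STOP_WINDOW = (-15, -12)  # inclusive, 5'-end offsets from stop codon
DEFAULT_CONTEXT_WINDOW = 9  # nt immediately upstream of the stop codon
DEFAULT_GA_THRESHOLD = 7 / 9
DEFAULT_C_THRESHOLD = 5 / 9

ContextLabel = Literal["GA_rich", "C_rich", "other"]


@dataclass
class PausingRecord:
    """Per-transcript termination-pausing summary."""

    transcript_id: str
    pausing_index: float
    stop_window: tuple[int, int]
    cds_mean_density: float
    utr3_relative_density: Optional[float]
    context_label: ContextLabel
    ga_fraction: float
    c_fraction: float


def _stop_window_positions(
    transcript: TranscriptModel, stop_window: tuple[int, int]
) -> np.ndarray:
    lo, hi = stop_window
    if lo > hi:
        raise ValueError(f"invalid stop window {stop_window}")
    return transcript.stop_start + np.arange(lo, hi + 1)


def stop_pausing_index(
    profile: CoverageProfile,
    transcript: TranscriptModel,
    stop_window: tuple[int, int] = DEFAULT_STOP_WINDOW,
) -> float:
    """Mean stop-window density over mean CDS density (5'-end coordinates).

    A uniform profile gives exactly 1; the index is invariant to uniform
    scaling of the counts, and a zeroed window gives exactly 0. No
    pseudocounts are applied.
    """
    cds = cds_counts(profile, transcript)
    cds_mean = cds.sum() / transcript.cds_length
    if cds_mean == 0:
        raise ValueError(
            f"{transcript.transcript_id}: zero CDS counts; pausing index undefined"
        )
    positions = _stop_window_positions(transcript, stop_window)
    in_range = (positions >= 0) & (positions < transcript.length)
    window = profile.counts[positions[in_range]]
    return float(window.sum() / positions.size / cds_mean)


def utr3_relative_density(
    profile: CoverageProfile,
    transcript: TranscriptModel,
    stop_window: tuple[int, int] = DEFAULT_STOP_WINDOW,
) -> Optional[float]:
    """Per-nt 3'UTR density over per-nt CDS density.

    Positions inside the stop window are excluded from the 3'UTR tally
    (relevant only if the window reaches past the stop codon). Returns
    None when the transcript has no 3'UTR.
    """
    if transcript.utr3_length < 1:
        return None
    cds = cds_counts(profile, transcript)
    cds_mean = cds.sum() / transcript.cds_length
    if cds_mean == 0:
        raise ValueError(
            f"{transcript.transcript_id}: zero CDS counts; relative density undefined"
        )
    window = set(_stop_window_positions(transcript, stop_window).tolist())
    positions = [
        p for p in range(transcript.cds_end, transcript.length) if p not in window
    ]
    if not positions:
        return None
    utr3_mean = profile.counts[positions].sum() / len(positions)
    return float(utr3_mean / cds_mean)


def classify_stop_context(
    transcript: TranscriptModel,
    upstream_window_nt: int = DEFAULT_CONTEXT_WINDOW,
    ga_threshold: float = DEFAULT_GA_THRESHOLD,
    c_threshold: float = DEFAULT_C_THRESHOLD,
) -> tuple[ContextLabel, float, float]:
    """Classify the sequence immediately 5' of the stop codon by composition.

    ``ga_fraction`` counts G+A and ``c_fraction`` counts C over the window;
    GA_rich takes precedence when both thresholds fire. The thresholds are
    declared interpretations (composition cutoffs), not measured constants.
    """
    stop_start = transcript.stop_start
    lo = stop_start - upstream_window_nt
    if lo < transcript.cds_start:
        raise ValueError(
            f"{transcript.transcript_id}: {upstream_window_nt}-nt context window "
            "extends past the start codon"
        )
    window = transcript.sequence[lo:stop_start]
    ga = (window.count("G") + window.count("A")) / upstream_window_nt
    c = window.count("C") / upstream_window_nt
    if ga >= ga_threshold:
        return "GA_rich", ga, c
    if c >= c_threshold:
        return "C_rich", ga, c
    return "other", ga, c


def pausing_table(
    profiles: dict[str, CoverageProfile],
    transcripts: dict[str, TranscriptModel],
    stop_window: tuple[int, int] = DEFAULT_STOP_WINDOW,
    upstream_window_nt: int = DEFAULT_CONTEXT_WINDOW,
    ga_threshold: float = DEFAULT_GA_THRESHOLD,
    c_threshold: float = DEFAULT_C_THRESHOLD,
) -> list[PausingRecord]:
    """One PausingRecord per (filter-passing) profiled transcript."""
    records = []
    for tid, profile in profiles.items():
        tx = transcripts[tid]
        label, ga, c = classify_stop_context(
            tx, upstream_window_nt, ga_threshold, c_threshold
        )
        cds = cds_counts(profile, tx)
        records.append(
            PausingRecord(
                transcript_id=tid,
                pausing_index=stop_pausing_index(profile, tx, stop_window),
                stop_window=stop_window,
                cds_mean_density=float(cds.sum() / tx.cds_length),
                utr3_relative_density=utr3_relative_density(
                    profile, tx, stop_window
                ),
                context_label=label,
                ga_fraction=ga,
                c_fraction=c,
            )
        )
    return records


def records_to_frame(records: Sequence[PausingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "pausing_index": [r.pausing_index for r in records],
            "cds_mean_density": [r.cds_mean_density for r in records],
            "utr3_relative_density": [r.utr3_relative_density for r in records],
            "context_label": [r.context_label for r in records],
            "ga_fraction": [r.ga_fraction for r in records],
            "c_fraction": [r.c_fraction for r in records],
        }
    )


@dataclass
class StratifiedPausingSummary:
    """Per-context metagenes, index quartiles, and High/Low classes."""

    metagenes: dict[str, MetageneResult]
    index_summary: pd.DataFrame  # quartiles of the pausing index per label
    high_transcripts: list[str]  # top quartile of the index distribution
    low_transcripts: list[str]  # bottom quartile


def stratified_pausing_summary(
    records: Sequence[PausingRecord],
    profiles: dict[str, CoverageProfile],
    transcripts: dict[str, TranscriptModel],
    offsets: range = range(-50, 51),
) -> StratifiedPausingSummary:
    """Stratify the metagene and index distribution by stop-codon context.

    High/Low pausing classes (for 3'UTR-density contrasts) are the top and
    bottom quartiles of the pausing-index distribution across all records.
    Labels with no transcripts after filtering are omitted.
    """
    frame = records_to_frame(list(records))
    metagenes: dict[str, MetageneResult] = {}
    rows = []
    for label, group in frame.groupby("context_label", sort=True):
        tids = [t for t in group.transcript_id if t in profiles]
        if not tids:
            continue
        metagenes[str(label)] = metagene_aggregate(
            [profiles[t] for t in tids], transcripts, align_to="stop", offsets=offsets
        )
        q = group.pausing_index.quantile([0.25, 0.5, 0.75])
        rows.append(
            {
                "context_label": label,
                "n": len(group),
                "mean_index": group.pausing_index.mean(),
                "q25": q.loc[0.25],
                "median": q.loc[0.5],
                "q75": q.loc[0.75],
            }
        )
    if not rows:
        raise ValueError("no context label has any transcripts")
    lo_cut = frame.pausing_index.quantile(0.25)
    hi_cut = frame.pausing_index.quantile(0.75)
    return StratifiedPausingSummary(
        metagenes=metagenes,
        index_summary=pd.DataFrame(rows),
        high_transcripts=list(
            frame.loc[frame.pausing_index >= hi_cut, "transcript_id"]
        ),
        low_transcripts=list(
            frame.loc[frame.pausing_index <= lo_cut, "transcript_id"]
        ),
    )
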