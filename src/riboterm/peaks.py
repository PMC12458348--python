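"""eRF1-seq termination-peak calling and annotation.

A termination peak is a transcript site whose eRF1 footprint count exceeds
``fold_threshold`` times the mean count of a centered sliding window
(default 120 nt), on transcripts with at least ``min_total_reads`` eRF1
reads. Called peaks are annotated with mRNA region, reading frame, A-site
codon, shifted-stop status (a stop codon one nt either side of the A-site
codon), agreement with the annotated stop or a uORF stop, and optionally
the downstream/upstream Ribo-seq density drop that distinguishes true
termination from eRF1 sampling of paused elongation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import STOP_CODONS, CoverageProfile, TranscriptModel, frame_of, region_of


@dataclass(frozen=True)
class PeakParams:
    """Sliding-window peak-calling parameters."""

    window_nt: int = 120
    fold_threshold: float = 10.0
    min_total_reads: int = 10
    min_site_count: float = 1.0
    flank_nt: int = 60  # for the Ribo-seq density drop ratio
    collapse_nt: int = 2  # adjacent candidates within this gap are merged

    def __post_init__(self) -> None:
        if self.window_nt < 3:
            raise ValueError("window_nt must be >= 3")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if self.min_total_reads < 0:
            raise ValueError("min_total_reads must be >= 0")


@dataclass
class TerminationPeak:
    """A called eRF1 peak; annotation fields are filled by annotate_peak."""

    transcript_id: str
    five_prime_pos: int  # the peak's 5'-end site
    fold_enrichment: float
    site_count: float
    asite_pos: int = -1  # five_prime_pos + 15
    asite_codon: str = ""
    region: str = ""
    frame: int = -1
    in_frame: bool = False
    shifted_stop: str = "none"  # stop codon at asite_pos-1 / +1
    shifted_stop_offset: int = 0  # raw positional offset of that stop codon
    at_annotated_stop: bool = False
    at_uorf_stop: bool = False
    drop_ratio: Optional[float] = None
    annotatable: bool = True


ASITE_OFFSET = 15


def window_mean(counts: np.ndarray, site: int, window_nt: int) -> float:
    """Mean count of the centered window at ``site``, clipped to bounds.

    The window covers [site - window_nt//2, site + window_nt//2), includes
    the candidate site itself, and averages over the positions actually in
    range near transcript edges.
    """
    half = window_nt // 2
    lo = max(0, site - half)
    hi = min(len(counts), site + half)
    return float(counts[lo:hi].mean())


def call_termination_peaks(
    profile: CoverageProfile,
    transcript: TranscriptModel,
    params: PeakParams = PeakParams(),
) -> list[TerminationPeak]:
    """Call termination peaks on a 5'-end anchored eRF1 profile.

    Transcripts with fewer than ``min_total_reads`` total eRF1 reads return
    no peaks. A site is a candidate iff its count is at least
    ``min_site_count`` and *strictly* greater than ``fold_threshold`` times
    the centered window mean (which includes the site). Runs of candidates
    within ``collapse_nt`` of each other collapse to the maximal-count site
    (ties resolved to the 5'-most); the -15/-12 terminating doublet, 3 nt
    apart, is deliberately not collapsed. Peaks come back annotated and
    sorted by position.
    """
    counts = profile.counts
    if transcript.length < 3:
        raise ValueError(f"{transcript.transcript_id}: transcript shorter than 3 nt")
    if counts.sum() < params.min_total_reads:
        return []
    # cumulative sums make every centered window mean O(1)
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    half = params.window_nt // 2
    n = len(counts)
    sites = np.nonzero(counts >= params.min_site_count)[0]
    candidates = []
    for i in sites:
        lo = max(0, i - half)
        hi = min(n, i + half)
        mean = (csum[hi] - csum[lo]) / (hi - lo)
        if counts[i] > params.fold_threshold * mean:
            candidates.append((int(i), mean))
    peaks: list[TerminationPeak] = []
    for i, mean in _collapse(candidates, counts, params.collapse_nt):
        peaks.append(
            TerminationPeak(
                transcript_id=transcript.transcript_id,
                five_prime_pos=i,
                fold_enrichment=float(counts[i] / mean) if mean > 0 else float("inf"),
                site_count=float(counts[i]),
            )
        )
    return [annotate_peak(p, transcript) for p in peaks]


def _collapse(
    candidates: list[tuple[int, float]], counts: np.ndarray, collapse_nt: int
) -> list[tuple[int, float]]:
    """Merge candidate runs whose neighbours are within ``collapse_nt`` nt.

    Each run keeps its maximal-count site; ties go to the 5'-most member.
    """
    out: list[tuple[int, float]] = []
    run: list[tuple[int, float]] = []
    for cand in candidates:
        if run and cand[0] - run[-1][0] > collapse_nt:
            out.append(max(run, key=lambda c: (counts[c[0]], -c[0])))
            run = []
        run.append(cand)
    if run:
        out.append(max(run, key=lambda c: (counts[c[0]], -c[0])))
    return out


def annotate_peak(
    peak: TerminationPeak,
    transcript: TranscriptModel,
    uorf_stops: Optional[Iterable[int]] = None,
) -> TerminationPeak:
    """Fill region / frame / A-site codon / shifted-stop annotation.

    The A-site codon starts 15 nt downstream of the peak's 5'-end site.
    ``shifted_stop`` records a stop codon starting one nt 5' (``minus1``,
    checked first) or one nt 3' (``plus1``) of the A-site codon; note the
    ribosome-frameshift vocabulary is the negation of this positional
    offset (a stop at +1 is reached by a -1 frameshift of the ribosome),
    so the raw offset is emitted alongside the label. Peaks whose A-site
    codon would extend past the transcript end are flagged unannotatable.
    """
    asite_pos = peak.five_prime_pos + ASITE_OFFSET
    peak = replace(peak, asite_pos=asite_pos)
    if asite_pos + 3 > transcript.length:
        return replace(peak, annotatable=False)
    seq = transcript.sequence
    region = region_of(transcript, asite_pos)
    frame = frame_of(transcript, asite_pos)
    at_stop = asite_pos == transcript.cds_end - 3
    shifted, offset = "none", 0
    if asite_pos - 1 >= 0 and seq[asite_pos - 1 : asite_pos + 2] in STOP_CODONS:
        shifted, offset = "minus1", -1
    elif asite_pos + 4 <= transcript.length and seq[
        asite_pos + 1 : asite_pos + 4
    ] in STOP_CODONS:
        shifted, offset = "plus1", +1
    stops = set(uorf_stops) if uorf_stops is not None else set()
    return replace(
        peak,
        asite_codon=seq[asite_pos : asite_pos + 3],
        region=region,
        frame=frame,
        in_frame=(frame == 0 and region == "cds") or at_stop,
        shifted_stop=shifted,
        shifted_stop_offset=offset,
        at_annotated_stop=at_stop,
        at_uorf_stop=asite_pos in stops,
    )


def termination_drop_ratio(
    peak: TerminationPeak,
    ribo_profile: CoverageProfile,
    transcript: TranscriptModel,
    flank_nt: int = 60,
) -> Optional[float]:
    """Downstream/upstream Ribo-seq density ratio around a peak's A-site.

    True termination leaves lowered ribosome density downstream of the
    terminating codon, so a ratio well below 1 corroborates a peak. The
    A-site codon itself is excluded from both flanks; flanks are clipped
    to transcript bounds. Returns None when the upstream flank has zero
    density (ratio undefined); raises when both flanks are empty.
    """
    asite = peak.asite_pos
    up = ribo_profile.counts[max(0, asite - flank_nt) : asite]
    down = ribo_profile.counts[asite + 3 : min(transcript.length, asite + 3 + flank_nt)]
    if up.size == 0 and down.size == 0:
        raise ValueError("both flanks empty; drop ratio undefined")
    if up.size == 0 or up.mean() == 0:
        return None
    if down.size == 0:
        return None
    return float(down.mean() / up.mean())


def match_peaks_to_uorf_stops(
    utr5_peaks: Sequence[TerminationPeak],
    uorf_stops_by_tx: dict[str, Iterable[int]],
    slop_nt: int = 0,
) -> tuple[Optional[float], list[tuple[TerminationPeak, int]]]:
    """Fraction of 5'UTR peaks whose A-site is a (called or true) uORF stop.

    A peak matches when its A-site position equals a uORF stop-codon start
    exactly, or within ``slop_nt`` when a slop is configured. With no
    5'UTR peaks the fraction is undefined (None).
    """
    matched: list[tuple[TerminationPeak, int]] = []
    n_utr5 = 0
    for peak in utr5_peaks:
        if peak.region != "utr5":
            continue
        n_utr5 += 1
        stops = uorf_stops_by_tx.get(peak.transcript_id, ())
        for stop in stops:
            if abs(peak.asite_pos - stop) <= slop_nt:
                matched.append((peak, stop))
                break
    if n_utr5 == 0:
        return None, []
    return len(matched) / n_utr5, matched


def peak_position_histogram(
    peaks: Sequence[TerminationPeak],
    transcripts: dict[str, TranscriptModel],
    bin_nt: int = 30,
) -> pd.DataFrame:
    """Distances of (out-of-frame CDS) peak A-sites to the annotated stop.

    Distance = asite_pos - (cds_end - 3); negative upstream. Returns a
    table of bin left edges and counts (empty for an empty peak set).
    """
    distances = [
        p.asite_pos - (transcripts[p.transcript_id].cds_end - 3) for p in peaks
    ]
    if not distances:
        return pd.DataFrame({"bin_start": [], "count": []})
    arr = np.asarray(distances)
    bins = np.floor_divide(arr, bin_nt) * bin_nt
    uniq, counts = np.unique(bins, return_counts=True)
    return pd.DataFrame({"bin_start": uniq, "count": counts})


def peaks_to_frame(peaks: Sequence[TerminationPeak]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in peaks])


def write_asite_bed(
    peaks: Sequence[TerminationPeak], path: str
) -> None:
    """Write peak A-site codons as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for p in peaks:
            if not p.annotatable:
                continue
            fh.write(
                f"{p.transcript_id}\t{p.asite_pos}\t{p.asite_pos + 3}\t"
                f"{p.asite_codon}\t{p.fold_enrichment:.3f}\t+\n"
            )
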