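"""Anchor assignment, per-transcript coverage, transcript filters, CDS
normalization, and metagene aggregation.

A footprint contributes to a profile at a single anchored position derived
from its 5' end: the 5' end itself, the first nt of the P-site codon
(5' end + 12), the first nt of the A-site codon (5' end + 15), or the 3'
end (5' end + length - 1). Transcript-level inclusion follows the standard
coverage gate (CDS reads >= 16 and >= 10% of CDS positions covered), and
per-site values are normalized by the mean CDS count before metagene
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .io import (
    AnchorConfig,
    CoverageProfile,
    FootprintRead,
    TranscriptModel,
    frame_of,
    read_passes_filters,
)

MIN_CDS_READS = 16
MIN_CDS_COVERED_FRACTION = 0.10


@dataclass
class MetageneResult:
    """Mean normalized density by distance from the start or stop codon.

    ``offsets[i]`` is the distance (nt) from the anchor codon's first nt;
    ``mean_density[i]`` averages the normalized density at that distance
    over the ``n_transcripts_at_offset[i]`` transcripts whose bounds
    contain it.
    """

    align_to: Literal["start", "stop"]
    offsets: np.ndarray
    mean_density: np.ndarray
    n_transcripts_at_offset: np.ndarray
    n_transcripts: int
    anchor: str
    length_range: Optional[tuple[int, int]] = None

    def density_at(self, offset: int) -> float:
        idx = int(np.searchsorted(self.offsets, offset))
        if idx >= len(self.offsets) or self.offsets[idx] != offset:
            raise KeyError(f"offset {offset} not in metagene range")
        return float(self.mean_density[idx])


def assign_anchor(read: FootprintRead, anchor: AnchorConfig) -> int:
    """Map a footprint to its anchored transcript position.

    Returns a coordinate that may lie beyond the transcript end; callers
    drop out-of-range anchors (see :func:`build_profile`).
    """
    if anchor.mode == "five_prime":
        return read.five_prime
    if anchor.mode == "three_prime":
        return read.five_prime + read.length - 1
    if anchor.mode == "psite":
        return read.five_prime + anchor.psite_offset
    if anchor.mode == "asite":
        return read.five_prime + anchor.asite_offset
    raise ValueError(f"unknown anchor mode {anchor.mode!r}")


def build_profile(
    reads: Iterable[FootprintRead],
    transcript: TranscriptModel,
    anchor: AnchorConfig = AnchorConfig(),
    length_range: Optional[tuple[int, int]] = None,
    apply_read_filters: bool = True,
) -> CoverageProfile:
    """Count anchored reads per transcript position.

    Reads failing the alignment-quality gate (when ``apply_read_filters``),
    outside ``length_range`` (when given), or whose anchor falls outside
    the transcript are excluded; everything else increments exactly one
    position.
    """
    counts = np.zeros(transcript.length, dtype=float)
    for read in reads:
        if read.transcript_id != transcript.transcript_id:
            raise ValueError(
                f"read on {read.transcript_id} passed to profile of "
                f"{transcript.transcript_id}"
            )
        if apply_read_filters and not read_passes_filters(read):
            continue
        if length_range is not None and not (
            length_range[0] <= read.length <= length_range[1]
        ):
            continue
        pos = assign_anchor(read, anchor)
        if 0 <= pos < transcript.length:
            counts[pos] += 1
    return CoverageProfile(transcript.transcript_id, anchor.mode, counts, length_range)


def group_reads_by_transcript(
    reads: Iterable[FootprintRead],
) -> dict[str, list[FootprintRead]]:
    by_tx: dict[str, list[FootprintRead]] = {}
    for read in reads:
        by_tx.setdefault(read.transcript_id, []).append(read)
    return by_tx


def cds_counts(profile: CoverageProfile, transcript: TranscriptModel) -> np.ndarray:
    return profile.counts[transcript.cds_start : transcript.cds_end]


def passes_cds_filters(profile: CoverageProfile, transcript: TranscriptModel) -> bool:
    """Transcript inclusion gate: CDS reads >= 16 and coverage >= 10%.

    Both thresholds are inclusive (a transcript at exactly 16 reads and
    exactly 10% covered positions passes).
    """
    cds = cds_counts(profile, transcript)
    if cds.sum() < MIN_CDS_READS:
        return False
    covered = float((cds > 0).sum()) / transcript.cds_length
    return covered >= MIN_CDS_COVERED_FRACTION


def normalize_by_cds(
    profile: CoverageProfile, transcript: TranscriptModel
) -> CoverageProfile:
    """Divide every position by the mean CDS count.

    After normalization the mean over CDS positions is exactly 1, so
    metagene averages are in units of "fold of mean CDS occupancy".
    Normalization is idempotent up to floating error.
    """
    cds = cds_counts(profile, transcript)
    mean = cds.sum() / transcript.cds_length
    if mean == 0:
        raise ValueError(
            f"{transcript.transcript_id}: zero CDS counts; cannot normalize"
        )
    return CoverageProfile(
        profile.transcript_id, profile.anchor, profile.counts / mean,
        profile.length_range,
    )


def metagene_aggregate(
    profiles: Sequence[CoverageProfile],
    transcripts: dict[str, TranscriptModel],
    align_to: Literal["start", "stop"] = "stop",
    offsets: range = range(-50, 51),
) -> MetageneResult:
    """Average normalized density at fixed distances from the anchor codon.

    The anchor codon's first nt is ``cds_start`` (align_to="start") or
    ``cds_end - 3`` (align_to="stop"). A transcript contributes at offset
    ``d`` only when ``anchor + d`` lies inside its bounds, so per-offset
    denominators differ near the edges of the window.
    """
    if not profiles:
        raise ValueError("metagene_aggregate needs at least one profile")
    offs = np.asarray(list(offsets), dtype=int)
    total = np.zeros(offs.size)
    n_at = np.zeros(offs.size, dtype=int)
    anchor_mode = profiles[0].anchor
    for profile in profiles:
        tx = transcripts[profile.transcript_id]
        anchor = tx.cds_start if align_to == "start" else tx.stop_start
        positions = anchor + offs
        in_range = (positions >= 0) & (positions < tx.length)
        total[in_range] += profile.counts[positions[in_range]]
        n_at[in_range] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(n_at > 0, total / np.maximum(n_at, 1), np.nan)
    return MetageneResult(
        align_to=align_to,
        offsets=offs,
        mean_density=mean,
        n_transcripts_at_offset=n_at,
        n_transcripts=len(profiles),
        anchor=anchor_mode,
        length_range=profiles[0].length_range,
    )


def frame_fractions(
    profile: CoverageProfile,
    transcript: TranscriptModel,
    region: Literal["cds", "utr3"] = "cds",
) -> tuple[float, float, float]:
    """Fraction of region counts in each reading frame relative to the start.

    CDS reads from a well-phased library concentrate in one frame; 3'UTR
    reads from non-canonical ribosome populations approach (1/3, 1/3, 1/3).
    """
    if region == "cds":
        lo, hi = transcript.cds_start, transcript.cds_end
    elif region == "utr3":
        lo, hi = transcript.cds_end, transcript.length
    else:
        raise ValueError(f"unknown region {region!r}")
    counts = profile.counts[lo:hi]
    total = counts.sum()
    if total == 0:
        raise ValueError(f"no counts in {region} of {transcript.transcript_id}")
    positions = np.arange(lo, hi)
    frames = (positions - transcript.cds_start) % 3
    return tuple(float(counts[frames == f].sum() / total) for f in range(3))


def build_filtered_normalized_profiles(
    reads_by_tx: dict[str, list[FootprintRead]],
    transcripts: dict[str, TranscriptModel],
    anchor: AnchorConfig = AnchorConfig(),
    length_range: Optional[tuple[int, int]] = None,
) -> dict[str, CoverageProfile]:
    """Convenience pipeline: profile, gate, normalize every transcript.

    The CDS filters are evaluated on the unstratified profile; a supplied
    ``length_range`` then stratifies the profile of transcripts that passed.
    """
    out: dict[str, CoverageProfile] = {}
    for tid, reads in reads_by_tx.items():
        if tid not in transcripts:
            continue
        tx = transcripts[tid]
        full = build_profile(reads, tx, anchor)
        if not passes_cds_filters(full, tx):
            continue
        profile = (
            full
            if length_range is None
            else build_profile(reads, tx, anchor, length_range)
        )
        if cds_counts(profile, tx).sum() == 0:
            continue  # stratum empty on a transcript that passed unstratified
        out[tid] = normalize_by_cds(profile, tx)
    return out
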