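"""Domain types, coordinate conventions, and readers/writers.

Coordinate conventions used throughout the package:

* All coordinates are 0-based, half-open, in *transcript* space.
* ``cds_start`` is the first nt of the start codon; ``cds_end`` is the
  half-open end of the CDS *including* the stop codon, so the stop codon
  is ``sequence[cds_end - 3 : cds_end]``.
* 5'UTR = ``[0, cds_start)``, CDS = ``[cds_start, cds_end)``,
  3'UTR = ``[cds_end, len(sequence))``.
* A footprint's ``five_prime`` is the transcript coordinate of its 5'-most
  aligned base ("position 0" of the read).

Sequences are normalized to the DNA alphabet (U -> T, upper-cased) at load
time; all downstream codon logic works on {A, C, G, T}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("riboterm")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

Region = Literal["utr5", "cds", "utr3"]
AnchorMode = Literal["five_prime", "three_prime", "psite", "asite"]


class TranscriptLoadError(ValueError):
    """A transcript failed validation at load time."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's sequence plus its CDS annotation.

    The CDS interval includes the stop codon, so a valid model always has a
    stop codon at ``sequence[cds_end - 3 : cds_end]`` (unless constructed
    with ``validate=False`` through :func:`load_transcriptome`'s permissive
    mode).
    """

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def stop_start(self) -> int:
        """Transcript coordinate of the stop codon's first nt."""
        return self.cds_end - 3

    @property
    def stop_codon(self) -> str:
        return self.sequence[self.cds_end - 3 : self.cds_end]

    @property
    def utr5_length(self) -> int:
        return self.cds_start

    @property
    def utr3_length(self) -> int:
        return self.length - self.cds_end

    def validate(self, require_stop: bool = True) -> None:
        """Raise :class:`TranscriptLoadError` if any invariant is violated."""
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            raise TranscriptLoadError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"out of bounds for length {self.length}"
            )
        if self.cds_length % 3 != 0:
            raise TranscriptLoadError(
                f"{self.transcript_id}: CDS length {self.cds_length} not a multiple of 3"
            )
        if self.cds_length < 6:
            raise TranscriptLoadError(
                f"{self.transcript_id}: CDS length {self.cds_length} < 6 nt"
            )
        if require_stop and self.stop_codon not in STOP_CODONS:
            raise TranscriptLoadError(
                f"{self.transcript_id}: no stop codon at CDS end "
                f"(found {self.stop_codon!r})"
            )


@dataclass(frozen=True)
class FootprintRead:
    """One aligned footprint in transcriptome coordinates."""

    transcript_id: str
    five_prime: int
    length: int
    n_mismatches: int = 0
    n_hits: int = 1

    def __post_init__(self) -> None:
        if self.five_prime < 0:
            raise ValueError(f"five_prime must be >= 0, got {self.five_prime}")
        if self.length < 15:
            raise ValueError(f"footprint length must be >= 15 nt, got {self.length}")
        if self.n_mismatches < 0 or self.n_hits < 1:
            raise ValueError("n_mismatches must be >= 0 and n_hits >= 1")


@dataclass(frozen=True)
class AnchorConfig:
    """How a footprint's 5' end maps to a single transcript position.

    The P-site codon starts 12 nt downstream of the read 5' end and the
    A-site codon 15 nt downstream; ``five_prime`` leaves reads anchored at
    their 5' ends and ``three_prime`` anchors at the last aligned base.
    """

    mode: AnchorMode = "five_prime"
    psite_offset: int = 12
    asite_offset: int = 15

    def __post_init__(self) -> None:
        if self.psite_offset < 0 or self.asite_offset < 0:
            raise ValueError("anchor offsets must be >= 0")


@dataclass
class CoverageProfile:
    """Per-nucleotide anchored read counts on one transcript."""

    transcript_id: str
    anchor: AnchorMode
    counts: np.ndarray
    length_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("coverage counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


# ---------------------------------------------------------------------------
# Sequence / coordinate helpers
# ---------------------------------------------------------------------------


def normalize_sequence(seq: str) -> str:
    """Upper-case and map U -> T (RNA input accepted, DNA used internally)."""
    return seq.upper().replace("U", "T")


def region_of(transcript: TranscriptModel, position: int) -> Region:
    """Classify a transcript position into 5'UTR, CDS or 3'UTR.

    The partition is exhaustive and disjoint under the half-open convention.
    """
    if not 0 <= position < transcript.length:
        raise ValueError(
            f"position {position} out of range [0, {transcript.length}) "
            f"on {transcript.transcript_id}"
        )
    if position < transcript.cds_start:
        return "utr5"
    if position < transcript.cds_end:
        return "cds"
    return "utr3"


def frame_of(transcript: TranscriptModel, position: int) -> int:
    """Reading frame of a position relative to the annotated start codon.

    Python's modulo already maps negative operands into {0, 1, 2}, so
    positions upstream of the start codon get mathematically consistent
    frames (e.g. 3 nt upstream of the start is frame 0).
    """
    return (position - transcript.cds_start) % 3


def read_passes_filters(read: FootprintRead) -> bool:
    """Alignment-quality gate: unique mappers with at most 2 mismatches."""
    return read.n_hits == 1 and read.n_mismatches <= 2


# ---------------------------------------------------------------------------
# Transcriptome loading
# ---------------------------------------------------------------------------


def _read_annotation(annotation_path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a CDS annotation as {transcript_id: (cds_start, cds_end)}.

    Accepts the 3-column TSV (transcript_id, cds_start, cds_end; 0-based,
    half-open, stop-inclusive) or a GTF subset whose CDS + stop_codon
    features are in transcript coordinates (1-based, closed, per GTF).
    """
    path = Path(annotation_path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        return _read_gtf_annotation(path)
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"transcript_id", "cds_start", "cds_end"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"annotation {path} must have columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    return {
        str(row.transcript_id): (int(row.cds_start), int(row.cds_end))
        for row in table.itertuples()
    }


def _read_gtf_annotation(path: Path) -> dict[str, tuple[int, int]]:
    cds_lo: dict[str, int] = {}
    stop_hi: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line")
            seqname, _, feature, start, end = fields[0], fields[1], fields[2], fields[3], fields[4]
            if feature == "CDS":
                lo = int(start) - 1
                cds_lo[seqname] = min(cds_lo.get(seqname, lo), lo)
                stop_hi.setdefault(seqname, int(end))
                stop_hi[seqname] = max(stop_hi[seqname], int(end))
            elif feature == "stop_codon":
                stop_hi[seqname] = max(stop_hi.get(seqname, 0), int(end))
    return {tid: (cds_lo[tid], stop_hi[tid]) for tid in cds_lo}


def load_transcriptome(
    fasta_path: str | Path,
    annotation_path: str | Path,
    permissive: bool = False,
) -> dict[str, TranscriptModel]:
    """Load and validate a transcript set from FASTA + CDS annotation.

    Returns validated :class:`TranscriptModel` objects keyed by id. FASTA
    records without an annotation are skipped with a warning. Records that
    violate the CDS invariants raise :class:`TranscriptLoadError`, or are
    skipped with a logged reason when ``permissive`` is set.
    """
    from Bio import SeqIO

    annotation = _read_annotation(annotation_path)
    models: dict[str, TranscriptModel] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        tid = record.id
        if tid not in annotation:
            logger.warning("transcript %s has no annotation; skipped", tid)
            continue
        cds_start, cds_end = annotation[tid]
        model = TranscriptModel(tid, str(record.seq), cds_start, cds_end)
        try:
            model.validate()
        except TranscriptLoadError as err:
            if permissive:
                logger.warning("transcript rejected: %s", err)
                continue
            raise
        models[tid] = model
    return models


def write_transcriptome(
    models: Iterable[TranscriptModel],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Write FASTA + 3-column annotation TSV for a transcript set."""
    models = list(models)
    with open(fasta_path, "w") as fa:
        for m in models:
            fa.write(f">{m.transcript_id}\n")
            for i in range(0, len(m.sequence), 70):
                fa.write(m.sequence[i : i + 70] + "\n")
    pd.DataFrame(
        {
            "transcript_id": [m.transcript_id for m in models],
            "cds_start": [m.cds_start for m in models],
            "cds_end": [m.cds_end for m in models],
        }
    ).to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignment loading
# ---------------------------------------------------------------------------

READ_TSV_COLUMNS = ["transcript_id", "five_prime", "length", "n_mismatches", "n_hits"]


def load_alignments(
    path: str | Path,
    format: Optional[Literal["sam", "bam", "tsv"]] = None,
    known_transcripts: Optional[set[str]] = None,
    stats: Optional[dict[str, int]] = None,
) -> Iterator[FootprintRead]:
    """Stream footprint reads from SAM/BAM or the 5-column read TSV.

    For SAM/BAM, ``five_prime`` is the leftmost aligned base (transcriptome
    alignments are sense-strand by construction, so reverse-strand records
    are dropped and counted), ``n_mismatches`` comes from the NM tag
    (missing -> 0 with a warning) and ``n_hits`` from NH (missing -> 1).
    Reads on transcripts absent from ``known_transcripts`` (when given) are
    dropped and counted. Drop counters accumulate into ``stats`` if a dict
    is supplied.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = suffix if suffix in {"sam", "bam", "tsv"} else "tsv"
    counters = stats if stats is not None else {}
    for key in ("reverse_strand", "unknown_transcript", "unmapped"):
        counters.setdefault(key, 0)
    if format == "tsv":
        yield from _load_alignments_tsv(path, known_transcripts, counters)
    else:
        yield from _load_alignments_sam(path, format, known_transcripts, counters)


def _load_alignments_tsv(path, known_transcripts, counters):
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != READ_TSV_COLUMNS:
            raise ValueError(
                f"{path}: expected header {READ_TSV_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                tid = fields[0]
                read = FootprintRead(
                    tid, int(fields[1]), int(fields[2]), int(fields[3]), int(fields[4])
                )
            except (IndexError, ValueError) as err:
                raise ValueError(f"{path}:{lineno}: unparseable read line: {err}")
            if known_transcripts is not None and tid not in known_transcripts:
                counters["unknown_transcript"] += 1
                continue
            yield read


def _load_alignments_sam(path, format, known_transcripts, counters):
    import pysam

    mode = "rb" if format == "bam" else "r"
    warned_nm = False
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                counters["unmapped"] += 1
                continue
            if rec.is_reverse:
                counters["reverse_strand"] += 1
                continue
            tid = rec.reference_name
            if known_transcripts is not None and tid not in known_transcripts:
                counters["unknown_transcript"] += 1
                continue
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            else:
                if not warned_nm:
                    logger.warning("%s: NM tag missing; assuming 0 mismatches", path)
                    warned_nm = True
                nm = 0
            nh = int(rec.get_tag("NH")) if rec.has_tag("NH") else 1
            yield FootprintRead(
                tid, rec.reference_start, rec.query_length or rec.infer_read_length(), nm, nh
            )


def write_alignments_tsv(reads: Iterable[FootprintRead], path: str | Path) -> None:
    """Write footprint reads as the 5-column TSV consumed by load_alignments."""
    with open(path, "w") as fh:
        fh.write("\t".join(READ_TSV_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                f"{r.transcript_id}\t{r.five_prime}\t{r.length}\t"
                f"{r.n_mismatches}\t{r.n_hits}\n"
            )


# ---------------------------------------------------------------------------
# Coverage / table serialization
# ---------------------------------------------------------------------------


def write_coverage(
    profile: CoverageProfile, path: str | Path, keep_zeros: bool = False
) -> None:
    """Write a coverage profile as bedGraph (runs of equal value merged).

    The transcript id serves as the chrom column; intervals are 0-based,
    half-open. Zero runs are omitted unless ``keep_zeros`` is set.
    """
    counts = profile.counts
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{profile.transcript_id}:{profile.anchor}"\n')
        start = 0
        for i in range(1, len(counts) + 1):
            if i == len(counts) or counts[i] != counts[start]:
                value = counts[start]
                if keep_zeros or value != 0:
                    fh.write(
                        f"{profile.transcript_id}\t{start}\t{i}\t{_fmt_value(value)}\n"
                    )
                start = i


def _fmt_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def read_coverage(
    path: str | Path, transcript_length: int, anchor: AnchorMode = "five_prime"
) -> CoverageProfile:
    """Read a single-transcript bedGraph back into a CoverageProfile."""
    counts = np.zeros(transcript_length, dtype=float)
    transcript_id = None
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, end, value = line.rstrip("\n").split("\t")
            if transcript_id is None:
                transcript_id = chrom
            elif chrom != transcript_id:
                raise ValueError(f"{path}: multiple transcripts in one bedGraph")
            counts[int(start) : int(end)] = float(value)
    if transcript_id is None:
        raise ValueError(f"{path}: empty bedGraph")
    return CoverageProfile(transcript_id, anchor, counts)


def write_table(records: pd.DataFrame | Sequence, path: str | Path) -> None:
    """Write tabular results as TSV with a header line."""
    frame = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
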