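"""Synthetic transcriptomes, Ribo-seq / eRF1-seq footprints, and MPRA libraries.

The generators emulate the statistical structure that the downstream
analyses assume, with a ground-truth table for every planted signal:

* Ribo-seq: uniform Poisson elongation coverage over the CDS; a
  terminating-ribosome component whose 5' ends sit at -15 and -12 nt from
  the stop codon's first nt (the pre- and post-termination peaks) with a
  bimodal footprint-length mixture (long 30-31 nt, short 20-23 nt); a
  sequence-dependent pausing multiplier tied to the G+A fraction of the
  9 nt upstream of the stop codon; and 3'UTR "leak" reads whose intensity
  decreases with the pausing multiplier and whose 5' ends are placed
  frame-uniformly (degraded 3-nt periodicity).
* eRF1-seq: reads concentrated at termination sites (annotated stops,
  planted uORF stops, planted out-of-frame stops, orphan 5'UTR stops) with
  the A-site on the terminating codon (5' end at site - 15), over a low
  uniform CDS background.
* MPRA: a library of distinct random 9-nt inserts partitioned between
  monosome and polysome fractions as a function of in-frame stop-codon
  presence (and optionally insert G+A content).

Every generator is byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import STOP_CODONS, FootprintRead, TranscriptModel

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class LengthDistributions:
    """Footprint-length models for elongating and terminating ribosomes."""

    elongating: tuple[int, int] = (28, 31)
    terminating_long: tuple[int, int] = (30, 31)
    terminating_short: tuple[int, int] = (20, 23)
    terminating_short_fraction: float = 0.5


@dataclass
class PausingModel:
    """Stop-codon pausing multiplier model.

    ``context`` mode ties the multiplier to the G+A fraction of the 9 nt
    upstream of the stop codon (multiplier = base + slope * ga_fraction);
    ``loguniform`` samples multipliers log-uniformly from ``range`` for
    parameter-recovery experiments.
    """

    mode: str = "context"  # "context" | "loguniform"
    base: float = 1.0
    slope: float = 20.0
    range: tuple[float, float] = (1.0, 50.0)


@dataclass
class Utr3LeakModel:
    """3'UTR read intensity as a decreasing function of the pausing multiplier.

    Per-nt 3'UTR read rate = scale * depth / multiplier: transcripts whose
    terminating ribosomes do not pause shed more ribosomes into the 3'UTR.
    """

    scale: float = 0.5


@dataclass
class UorfSpec:
    probability: float = 0.3
    n_codons_range: tuple[int, int] = (3, 10)
    enrichment: float = 4.0  # in-frame mean = enrichment * local background


@dataclass
class Erf1Spec:
    reads_per_site: float = 50.0
    background_rate: float = 0.1  # per CDS nt
    out_of_frame_prob: float = 0.3  # planted out-of-frame CDS stop per transcript
    orphan_utr5_prob: float = 0.7  # planted non-uORF 5'UTR stop per transcript


@dataclass
class MpraSpec:
    n_variants: int = 10_000
    reads_per_fraction: int = 1_000_000
    p_stop: float = 0.9  # P(monosome | in-frame stop in insert)
    p_base: float = 0.18  # P(monosome | no in-frame stop); p_stop / p_base = 5
    ga_coef: float = 0.0  # optional additive modulation by insert G+A fraction


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data generators."""

    n_transcripts: int = 200
    utr5_length: tuple[int, int] = (60, 120)
    cds_length: tuple[int, int] = (150, 450)  # forced to a multiple of 3
    utr3_length: tuple[int, int] = (60, 180)
    depth: float = 5.0  # mean elongation footprints per CDS nt
    utr5_depth_factor: float = 1.0  # 5'UTR background relative to CDS depth
    pausing_model: PausingModel = field(default_factory=PausingModel)
    utr3_leak_model: Utr3LeakModel = field(default_factory=Utr3LeakModel)
    stop_window_split: float = 0.7  # fraction of terminating 5' ends at -15
    stop_peak_smear: int = 0  # smearing half-width around -15/-12 (nt)
    length_distributions: LengthDistributions = field(default_factory=LengthDistributions)
    context_fraction: float = 0.5  # transcripts with a designed upstream 9-mer
    uorf_spec: UorfSpec = field(default_factory=UorfSpec)
    erf1_spec: Erf1Spec = field(default_factory=Erf1Spec)
    mpra_spec: MpraSpec = field(default_factory=MpraSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 0 or self.utr5_depth_factor < 0:
            raise ValueError("depths must be >= 0")
        if not 0 <= self.stop_window_split <= 1:
            raise ValueError("stop_window_split must be in [0, 1]")
        if not 0 <= self.context_fraction <= 1:
            raise ValueError("context_fraction must be in [0, 1]")
        if not 0 <= self.uorf_spec.probability <= 1:
            raise ValueError("uORF probability must be in [0, 1]")
        lo, hi = self.uorf_spec.n_codons_range
        if 3 * (hi + 1) + 18 > self.utr5_length[0]:
            raise ValueError(
                "largest uORF does not fit in the shortest 5'UTR; "
                "shrink uorf_spec.n_codons_range or grow utr5_length"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(self.to_dict(), sort_keys=False)


@dataclass
class GroundTruth:
    """Planted signals, joinable to generated outputs on transcript_id."""

    transcripts: pd.DataFrame  # multiplier, ga_fraction, context, leak rate
    uorfs: pd.DataFrame  # planted uORF intervals and enrichment
    erf1_sites: pd.DataFrame  # A-site positions of planted termination sites


# ---------------------------------------------------------------------------
# Transcriptome generation
# ---------------------------------------------------------------------------


def _rand_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, n)])


def _sample_range(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def _ga_fraction(seq: list[str] | str) -> float:
    s = "".join(seq) if not isinstance(seq, str) else seq
    return (s.count("G") + s.count("A")) / len(s) if s else 0.0


def _designed_9mer(rng: np.random.Generator, kind: str) -> list[str]:
    """A GA-rich or C-rich 9-mer free of in-frame stop codons."""
    while True:
        if kind == "GA":
            mer = list(np.array(list("GA"))[rng.integers(0, 2, 9)])
        else:  # C-rich: mostly C with occasional other bases
            mer = [
                "C" if rng.random() < 0.8 else "AGT"[rng.integers(0, 3)]
                for _ in range(9)
            ]
        if all("".join(mer[i : i + 3]) not in STOP_CODONS for i in (0, 3, 6)):
            return mer


def generate_transcriptome(
    config: SimulationConfig, seed: Optional[int] = None
) -> tuple[dict[str, TranscriptModel], GroundTruth]:
    """Generate random transcripts with planted sequence features.

    Each transcript has ATG at ``cds_start``, a stop codon at
    ``cds_end - 3``, no accidental in-frame stop inside the CDS, and
    (depending on the config) a designed GA-rich or C-rich 9-mer
    immediately upstream of the stop codon, a planted AUG-initiated uORF
    contained in the 5'UTR, a planted out-of-frame stop inside the CDS and
    an orphan stop codon in the 5'UTR (extra eRF1 termination sites).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    models: dict[str, TranscriptModel] = {}
    tx_rows, uorf_rows, site_rows = [], [], []

    n_context = int(round(config.n_transcripts * config.context_fraction))
    context_kinds = ["GA"] * (n_context - n_context // 2) + ["C"] * (n_context // 2)
    context_kinds += ["none"] * (config.n_transcripts - n_context)
    rng.shuffle(context_kinds)

    for idx in range(config.n_transcripts):
        tid = f"tx{idx:05d}"
        utr5_len = _sample_range(rng, config.utr5_length)
        cds_len = 3 * max(2, _sample_range(rng, config.cds_length) // 3)
        utr3_len = _sample_range(rng, config.utr3_length)
        cds_start = utr5_len
        cds_end = cds_start + cds_len
        stop_start = cds_end - 3

        seq = _rand_seq(rng, utr5_len)
        n_codons = cds_len // 3 - 2  # between start and stop
        seq += list("ATG")
        body = rng.choice(len(_SENSE_CODONS), n_codons)
        for ci in body:
            seq += list(_SENSE_CODONS[ci])
        stop = _STOPS[rng.integers(0, 3)]
        seq += list(stop)
        seq += _rand_seq(rng, utr3_len)

        # designed stop-context 9-mer (3 in-frame sense codons)
        kind = context_kinds[idx]
        if kind != "none" and stop_start - 9 >= cds_start + 3:
            seq[stop_start - 9 : stop_start] = _designed_9mer(rng, kind)

        # planted uORF, fully contained in the 5'UTR
        uorf = None
        if rng.random() < config.uorf_spec.probability:
            n_uc = _sample_range(rng, config.uorf_spec.n_codons_range)
            span = 3 * (n_uc + 1)
            if utr5_len - span >= 15:
                start = int(rng.integers(15, utr5_len - span + 1))
                u_stop = start + 3 * n_uc
                seq[start : start + 3] = list("ATG")
                for j in range(1, n_uc):
                    seq[start + 3 * j : start + 3 * j + 3] = list(
                        _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))]
                    )
                seq[u_stop : u_stop + 3] = list(_STOPS[rng.integers(0, 3)])
                uorf = (start, u_stop, n_uc)
                uorf_rows.append(
                    {
                        "transcript_id": tid,
                        "start": start,
                        "stop": u_stop,
                        "n_codons": n_uc,
                        "enrichment": config.uorf_spec.enrichment,
                    }
                )
                site_rows.append(
                    {"transcript_id": tid, "position": u_stop, "kind": "uorf_stop"}
                )

        # orphan 5'UTR termination site (a stop codon not tied to a planted uORF)
        if rng.random() < config.erf1_spec.orphan_utr5_prob:
            pos = _place_orphan_stop(rng, seq, utr5_len, uorf)
            if pos is not None:
                site_rows.append(
                    {"transcript_id": tid, "position": pos, "kind": "utr5_orphan"}
                )

        # planted out-of-frame stop codon inside the CDS
        if rng.random() < config.erf1_spec.out_of_frame_prob:
            pos = _place_out_of_frame_stop(rng, seq, cds_start, stop_start)
            if pos is not None:
                site_rows.append(
                    {"transcript_id": tid, "position": pos, "kind": "out_of_frame"}
                )

        site_rows.append(
            {"transcript_id": tid, "position": stop_start, "kind": "annotated_stop"}
        )

        model = TranscriptModel(tid, "".join(seq), cds_start, cds_end)
        model.validate()
        models[tid] = model

        ga = _ga_fraction(seq[stop_start - 9 : stop_start])
        if config.pausing_model.mode == "loguniform":
            lo, hi = config.pausing_model.range
            multiplier = float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
        else:
            multiplier = config.pausing_model.base + config.pausing_model.slope * ga
        leak_rate = config.utr3_leak_model.scale * config.depth / max(multiplier, 1e-9)
        tx_rows.append(
            {
                "transcript_id": tid,
                "multiplier": multiplier,
                "ga_fraction": ga,
                "context": kind,
                "utr3_leak_rate": leak_rate,
                "has_uorf": uorf is not None,
            }
        )

    truth = GroundTruth(
        transcripts=pd.DataFrame(
            tx_rows,
            columns=[
                "transcript_id", "multiplier", "ga_fraction", "context",
                "utr3_leak_rate", "has_uorf",
            ],
        ),
        uorfs=pd.DataFrame(
            uorf_rows,
            columns=["transcript_id", "start", "stop", "n_codons", "enrichment"],
        ),
        erf1_sites=pd.DataFrame(
            site_rows, columns=["transcript_id", "position", "kind"]
        ),
    )
    return models, truth


def _place_orphan_stop(rng, seq, utr5_len, uorf) -> Optional[int]:
    """Plant a stop codon in the 5'UTR outside any planted uORF interval."""
    for _ in range(50):
        if utr5_len < 19:
            return None
        pos = int(rng.integers(15, utr5_len - 3))
        if uorf is not None and not (pos + 3 <= uorf[0] or pos >= uorf[1] + 3):
            continue
        seq[pos : pos + 3] = list(_STOPS[rng.integers(0, 3)])
        return pos
    return None


def _place_out_of_frame_stop(rng, seq, cds_start, stop_start) -> Optional[int]:
    """Plant a stop codon at an out-of-frame CDS position.

    Overwriting three nt at an out-of-frame position touches two in-frame
    codons; placements that would create an in-frame stop (or clobber the
    designed context 9-mer) are resampled.
    """
    lo, hi = cds_start + 16, stop_start - 15  # keep clear of start and context
    if hi <= lo:
        return None
    for _ in range(100):
        pos = int(rng.integers(lo, hi))
        if (pos - cds_start) % 3 == 0:
            continue
        stop = _STOPS[rng.integers(0, 3)]
        saved = seq[pos : pos + 3]
        seq[pos : pos + 3] = list(stop)
        frame_off = (pos - cds_start) % 3
        ok = True
        for cpos in (pos - frame_off, pos - frame_off + 3):
            if cds_start <= cpos and cpos + 3 <= stop_start:
                if "".join(seq[cpos : cpos + 3]) in STOP_CODONS:
                    ok = False
        if ok:
            return pos
        seq[pos : pos + 3] = saved
    return None


# ---------------------------------------------------------------------------
# Footprint simulation
# ---------------------------------------------------------------------------


def _lengths(rng, lohi: tuple[int, int], n: int) -> np.ndarray:
    return rng.integers(lohi[0], lohi[1] + 1, n)


def _terminating_lengths(rng, dist: LengthDistributions, n: int) -> np.ndarray:
    short = rng.random(n) < dist.terminating_short_fraction
    out = np.empty(n, dtype=int)
    out[short] = _lengths(rng, dist.terminating_short, int(short.sum()))
    out[~short] = _lengths(rng, dist.terminating_long, int((~short).sum()))
    return out


def simulate_ribo_reads(
    transcripts: dict[str, TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> list[FootprintRead]:
    """Simulate Ribo-seq footprints for a generated transcript set.

    Components per transcript: Poisson(depth) elongation 5' ends at every
    CDS position; Poisson(depth * utr5_depth_factor) background at every
    5'UTR position, with planted uORFs boosting in-frame (P-site anchored)
    positions to enrichment * background; a terminating component with
    total mean depth * multiplier at 5'-end offsets -15 / -12 from the
    stop codon; and frame-uniform 3'UTR leak reads at the truth leak rate.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dist = config.length_distributions
    tx_truth = truth.transcripts.set_index("transcript_id")
    uorfs_by_tx: dict[str, list] = {}
    if len(truth.uorfs):
        for row in truth.uorfs.itertuples():
            uorfs_by_tx.setdefault(row.transcript_id, []).append(row)

    reads: list[FootprintRead] = []
    for tid, tx in transcripts.items():
        stop_start = tx.stop_start
        # elongation: one Poisson draw per CDS 5'-end position
        positions = np.arange(tx.cds_start, tx.cds_end)
        counts = rng.poisson(config.depth, positions.size)
        _emit(reads, rng, tid, positions, counts, dist.elongating)

        # 5'UTR background (frame-uniform scanning/elongation mixture)
        u_depth = config.depth * config.utr5_depth_factor
        if tx.cds_start > 0 and u_depth > 0:
            upos = np.arange(0, tx.cds_start)
            urates = np.full(upos.size, u_depth)
            for u in uorfs_by_tx.get(tid, []):
                # extra in-frame reads: P-site anchored => 5' end at codon - 12
                enrich = (u.enrichment - 1.0) * u_depth
                for j in range(u.n_codons):
                    fp = u.start + 3 * j - 12
                    if 0 <= fp < tx.cds_start:
                        urates[fp] += enrich
            ucounts = rng.poisson(urates)
            _emit(reads, rng, tid, upos, ucounts, dist.elongating)

        # terminating component at -15 / -12
        mult = float(tx_truth.at[tid, "multiplier"])
        n_term = rng.poisson(config.depth * mult)
        if n_term > 0:
            at15 = rng.random(n_term) < config.stop_window_split
            fp = np.where(at15, stop_start - 15, stop_start - 12)
            if config.stop_peak_smear > 0:
                fp = fp + rng.integers(
                    -config.stop_peak_smear, config.stop_peak_smear + 1, n_term
                )
            fp = np.clip(fp, 0, tx.length - 1)
            lens = _terminating_lengths(rng, dist, n_term)
            for p, ln in zip(fp, lens):
                reads.append(FootprintRead(tid, int(p), int(ln)))

        # 3'UTR leak, frame-uniform 5' ends
        leak = float(tx_truth.at[tid, "utr3_leak_rate"])
        if tx.utr3_length > 0 and leak > 0:
            lpos = np.arange(tx.cds_end, tx.length)
            lcounts = rng.poisson(leak, lpos.size)
            _emit(reads, rng, tid, lpos, lcounts, dist.elongating)
    return reads


def _emit(reads, rng, tid, positions, counts, length_range) -> None:
    total = int(counts.sum())
    if total == 0:
        return
    fps = np.repeat(positions, counts)
    lens = _lengths(rng, length_range, total)
    for p, ln in zip(fps, lens):
        reads.append(FootprintRead(tid, int(p), int(ln)))


def simulate_erf1_reads(
    transcripts: dict[str, TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> list[FootprintRead]:
    """Simulate eRF1-selective footprints.

    Each planted termination site (annotated stop, uORF stop, orphan 5'UTR
    stop, out-of-frame CDS stop) receives Poisson(reads_per_site) reads
    whose 5' ends sit at site - 15 (A-site on the terminating codon), over
    a uniform Poisson(background_rate) CDS background.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    spec = config.erf1_spec
    dist = config.length_distributions
    reads: list[FootprintRead] = []
    sites_by_tx: dict[str, list[int]] = {}
    for row in truth.erf1_sites.itertuples():
        sites_by_tx.setdefault(row.transcript_id, []).append(int(row.position))
    for tid, tx in transcripts.items():
        if spec.background_rate > 0:
            positions = np.arange(tx.cds_start, tx.cds_end)
            counts = rng.poisson(spec.background_rate, positions.size)
            _emit(reads, rng, tid, positions, counts, dist.terminating_long)
        for site in sites_by_tx.get(tid, []):
            fp = site - 15
            if fp < 0:
                continue
            n = rng.poisson(spec.reads_per_site)
            lens = _terminating_lengths(rng, dist, n)
            for ln in lens:
                reads.append(FootprintRead(tid, fp, int(ln)))
    return reads


# ---------------------------------------------------------------------------
# MPRA library simulation
# ---------------------------------------------------------------------------


@dataclass
class MpraLibrary:
    mono_reads: np.ndarray  # insert sequence per read, monosome fraction
    poly_reads: np.ndarray
    truth: pd.DataFrame  # per variant: p_monosome, has_inframe_stop, ga_fraction


def _decode_9mers(codes: np.ndarray) -> np.ndarray:
    """Vectorized base-4 decoding of insert codes to 9-nt strings."""
    out = np.full(codes.shape, "", dtype="<U9")
    for k in range(9):
        out = np.char.add(out, _BASES[(codes // 4 ** (8 - k)) % 4])
    return out


def has_inframe_stop(insert: str) -> bool:
    """True if a stop codon starts at insert offset 0, 3 or 6."""
    return any(insert[i : i + 3] in STOP_CODONS for i in (0, 3, 6))


def simulate_mpra_library(
    config: SimulationConfig, seed: Optional[int] = None
) -> MpraLibrary:
    """Simulate monosome/polysome reads for a random 9-nt insert library.

    Each of ``n_variants`` distinct inserts gets a Poisson total read count
    (2 * reads_per_fraction / n_variants on average) split binomially
    between fractions with P(monosome) = p_stop when the insert carries an
    in-frame stop codon and p_base otherwise, optionally shifted by
    ga_coef * (G+A fraction - 0.5) and clipped to [0, 1].
    """
    spec = config.mpra_spec
    if spec.n_variants > 4 ** 9:
        raise ValueError(f"cannot draw {spec.n_variants} distinct 9-mers (max 4^9)")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    codes = rng.choice(4 ** 9, size=spec.n_variants, replace=False)
    inserts = _decode_9mers(codes)

    stop_flags = np.array([has_inframe_stop(s) for s in inserts])
    ga = np.array([(s.count("G") + s.count("A")) / 9 for s in inserts])
    p_mono = np.where(stop_flags, spec.p_stop, spec.p_base)
    if spec.ga_coef != 0.0:
        p_mono = p_mono + spec.ga_coef * (ga - 0.5)
    p_mono = np.clip(p_mono, 0.0, 1.0)

    mean_reads = 2.0 * spec.reads_per_fraction / spec.n_variants
    totals = rng.poisson(mean_reads, spec.n_variants)
    mono_counts = rng.binomial(totals, p_mono)
    poly_counts = totals - mono_counts

    truth = pd.DataFrame(
        {
            "insert": inserts,
            "p_monosome": p_mono,
            "has_inframe_stop": stop_flags,
            "ga_fraction": ga,
            "true_total_reads": totals,
        }
    )
    return MpraLibrary(
        mono_reads=np.repeat(inserts, mono_counts),
        poly_reads=np.repeat(inserts, poly_counts),
        truth=truth,
    )
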