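"""Monosome/polysome MPRA analysis of 9-nt random inserts.

Raw insert reads are gated to exact 9-nt sequences over {A,C,G,T}, counted
per fraction, normalized to reads per million (RPM), and summarized per
variant as the monosome/polysome ratio M/P = (rpm_mono + pc) /
(rpm_poly + pc) with a small RPM pseudocount. Positional codon matrices
average M/P over variants carrying a given 3-mer at a given insert offset
(all seven 3-mer start offsets 0..6), from which per-codon means, stop-codon
ranks, and frame-0 enrichment derive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import STOP_CODONS

INSERT_LENGTH = 9
ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
N_OFFSETS = INSERT_LENGTH - 3 + 1  # 3-mer start offsets 0..6
DEFAULT_PSEUDOCOUNT_RPM = 0.5


@dataclass
class GateStats:
    """Rejection tally from insert gating."""

    n_kept: int = 0
    n_wrong_length: int = 0
    n_ambiguous: int = 0


def gate_inserts(
    raw_inserts: Iterable[str] | np.ndarray,
    stats: Optional[GateStats] = None,
    flank5: str = "",
    flank3: str = "",
) -> np.ndarray:
    """Keep exact 9-nt inserts over {A,C,G,T}; count rejections by reason.

    When flanks are configured, the insert is first extracted by exact
    flank matching (reads without both flanks count as wrong-length).
    Sequences of the wrong length and sequences containing ambiguous bases
    are dropped and tallied separately in ``stats``.
    """
    arr = np.asarray(raw_inserts, dtype="U")
    if arr.size and (flank5 or flank3):
        extracted = []
        for s in arr:
            if flank5 and not s.startswith(flank5):
                extracted.append("")
                continue
            s = s[len(flank5):]
            if flank3:
                if not s.endswith(flank3):
                    extracted.append("")
                    continue
                s = s[: len(s) - len(flank3)]
            extracted.append(s)
        arr = np.asarray(extracted, dtype="U")
    lengths = np.char.str_len(arr)
    right_len = lengths == INSERT_LENGTH
    clean = np.zeros(arr.shape, dtype=bool)
    if right_len.any():
        sub = arr[right_len]
        ok = np.ones(sub.shape, dtype=bool)
        stripped = sub
        for base in "ACGT":
            stripped = np.char.replace(stripped, base, "")
        ok = np.char.str_len(stripped) == 0
        clean[np.nonzero(right_len)[0][ok]] = True
    if stats is not None:
        stats.n_kept += int(clean.sum())
        stats.n_wrong_length += int((~right_len).sum())
        stats.n_ambiguous += int(right_len.sum() - clean[right_len].sum())
    return arr[clean]


def count_and_rpm(inserts: np.ndarray | Sequence[str]) -> pd.DataFrame:
    """Count gated inserts and normalize to reads per million.

    Returns a frame indexed by insert with ``count`` and ``rpm`` columns;
    RPM sums to 1e6 over the fraction. Raises on an empty fraction.
    """
    arr = np.asarray(inserts, dtype="U")
    if arr.size == 0:
        raise ValueError("no passing reads in this fraction; cannot compute RPM")
    variants, counts = np.unique(arr, return_counts=True)
    total = counts.sum()
    return pd.DataFrame(
        {"count": counts, "rpm": counts / total * 1e6}, index=pd.Index(variants, name="insert")
    )


def has_inframe_stop(insert: str) -> bool:
    """True if a stop codon starts at insert offset 0, 3 or 6."""
    return any(insert[i : i + 3] in STOP_CODONS for i in (0, 3, 6))


def mp_ratio(
    table_mono: pd.DataFrame,
    table_poly: pd.DataFrame,
    pseudocount_rpm: float = DEFAULT_PSEUDOCOUNT_RPM,
) -> pd.DataFrame:
    """Per-variant monosome/polysome ratio over the union of variants.

    M/P = (rpm_mono + pc) / (rpm_poly + pc). With pseudocount 0, variants
    absent from either fraction get a missing (NaN) ratio rather than 0 or
    infinity.
    """
    if pseudocount_rpm < 0:
        raise ValueError("pseudocount must be >= 0")
    merged = pd.DataFrame(
        {
            "count_mono": table_mono["count"],
            "rpm_mono": table_mono["rpm"],
            "count_poly": table_poly["count"],
            "rpm_poly": table_poly["rpm"],
        }
    )
    merged = merged.fillna(
        {"count_mono": 0, "rpm_mono": 0.0, "count_poly": 0, "rpm_poly": 0.0}
    )
    if pseudocount_rpm == 0:
        present = (merged.rpm_mono > 0) & (merged.rpm_poly > 0)
        mp = np.where(present, merged.rpm_mono / merged.rpm_poly.replace(0, np.nan), np.nan)
    else:
        mp = (merged.rpm_mono + pseudocount_rpm) / (merged.rpm_poly + pseudocount_rpm)
    merged["mp_ratio"] = mp
    merged["has_inframe_stop"] = [has_inframe_stop(s) for s in merged.index]
    merged.index.name = "insert"
    return merged


@dataclass
class PositionalCodonMatrix:
    """Mean M/P of each 3-mer at each insert offset, with support counts."""

    values: pd.DataFrame  # 64 codons x 7 offsets; NaN where n == 0
    n: pd.DataFrame
    per_codon_mean: pd.Series  # mean of defined offset entries per codon
    stop_codon_ranks: pd.Series  # rank of each stop codon among per-codon means

    def rank_of(self, codon: str) -> int:
        ordered = self.per_codon_mean.sort_values(ascending=False)
        return int(np.nonzero(ordered.index == codon)[0][0]) + 1


def positional_codon_matrix(variants: pd.DataFrame) -> PositionalCodonMatrix:
    """Average M/P over variants carrying codon c at insert offset p.

    ``variants`` is the mp_ratio output (indexed by insert, with an
    ``mp_ratio`` column). Cells with no supporting variant are NaN, not 0.
    Per-codon means average each codon's defined offset entries; ranks of
    the three stop codons among the 64 per-codon means (1 = largest) are
    reported for the planted-partition check.
    """
    if len(variants) == 0:
        raise ValueError("positional_codon_matrix needs at least one variant")
    inserts = variants.index.to_numpy(dtype="U9")
    mp = variants["mp_ratio"].to_numpy(dtype=float)
    valid = ~np.isnan(mp)
    codon_index = {c: i for i, c in enumerate(ALL_CODONS)}
    sums = np.zeros((64, N_OFFSETS))
    ns = np.zeros((64, N_OFFSETS), dtype=int)
    for insert, ratio, ok in zip(inserts, mp, valid):
        if not ok:
            continue
        for p in range(N_OFFSETS):
            ci = codon_index[insert[p : p + 3]]
            sums[ci, p] += ratio
            ns[ci, p] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    values = pd.DataFrame(means, index=ALL_CODONS, columns=range(N_OFFSETS))
    n = pd.DataFrame(ns, index=ALL_CODONS, columns=range(N_OFFSETS))
    per_codon = values.mean(axis=1, skipna=True)
    ranks = per_codon.rank(ascending=False, method="min")
    stop_ranks = ranks.loc[sorted(STOP_CODONS)].astype("Int64")  # NA if unobserved
    return PositionalCodonMatrix(values, n, per_codon, stop_ranks)


def frame_enrichment(matrix: PositionalCodonMatrix) -> pd.DataFrame:
    """Per-frame mean M/P per codon and frame-0 / off-frame enrichment.

    Insert offsets are grouped by offset mod 3; frame 0 (offsets 0, 3, 6)
    is in-frame with the upstream ORF by construct design. Enrichment is
    the frame-0 mean over the mean of frames 1-2.
    """
    values = matrix.values
    frames = {
        f: values[[p for p in values.columns if p % 3 == f]].mean(axis=1, skipna=True)
        for f in range(3)
    }
    out = pd.DataFrame(
        {
            "frame0_mean": frames[0],
            "frame1_mean": frames[1],
            "frame2_mean": frames[2],
        }
    )
    off = out[["frame1_mean", "frame2_mean"]].mean(axis=1)
    out["enrichment"] = out["frame0_mean"] / off
    return out
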