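"""Ribosome-profiling stage: footprint classes, region ratios, metagenes.

Footprints from a 15-34 nt size selection mix two populations: full-length
25-34 nt footprints of elongating ribosomes ("28-mers") and 15-18 nt
footprints ("16-mers") of ribosomes stalled with a cleaved mRNA 3' end in
their decoding center, plus a minor 19-24 nt class from empty-A-site
ribosomes. A single 5' base is trimmed from every read before mapping to
remove untemplated additions, but lengths are always reported pre-trim.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    Alignment,
    Region,
    Transcript,
    TranscriptomeModel,
    region_of,
    to_dna,
    to_rna,
)
from .fragments import ALL_DINUCLEOTIDES
from .simulate import SPIKE_INS

logger = logging.getLogger(__name__)

#: (inclusive) reported-length bounds of the named footprint classes
CLASS_BOUNDS = {
    "SHORT16": (15, 18),
    "MID21": (19, 24),
    "LONG28": (25, 34),
}

DEFAULT_P_SITE_SHIFT = 12
DEFAULT_MIN_RAW = 5


class FootprintClass(str, Enum):
    SHORT16 = "SHORT16"
    MID21 = "MID21"
    LONG28 = "LONG28"
    OTHER = "OTHER"


def classify_footprint(reported_len: int) -> FootprintClass:
    """Assign a pre-trim read length to a footprint class."""
    if reported_len < 1:
        raise ValueError(f"invalid read length {reported_len}")
    for name, (lo, hi) in CLASS_BOUNDS.items():
        if lo <= reported_len <= hi:
            return FootprintClass(name)
    return FootprintClass.OTHER


def class_counts(alignments: Iterable[Alignment]) -> Counter:
    """Footprint-class tally over mapped alignments (pre-trim lengths)."""
    counts: Counter = Counter()
    for aln in alignments:
        if aln.mapped:
            counts[classify_footprint(aln.read_len)] += 1
    return counts


def short_long_ratio(counts: Counter | dict) -> float:
    """16-mer / 28-mer count ratio, the headline stalling statistic."""
    long_n = counts.get(FootprintClass.LONG28, 0) or counts.get("LONG28", 0)
    short_n = counts.get(FootprintClass.SHORT16, 0) or counts.get("SHORT16", 0)
    if long_n == 0:
        raise ValueError("no LONG28 footprints: 16/28 ratio undefined")
    return short_n / long_n


# ---------------------------------------------------------------------------
# read preprocessing

def preprocess_reads(
    reads: Iterable[tuple[str, str]], trim5: bool = True
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Trim one 5' base per read (untemplated-base removal).

    Returns trimmed ``(read_id, sequence)`` pairs plus a map of read id to
    the original pre-trim length, which is what all length classification
    and plots use. Reads empty after trimming are dropped and counted.
    """
    out: list[tuple[str, str]] = []
    lengths: dict[str, int] = {}
    n_dropped = 0
    for read_id, seq in reads:
        lengths[read_id] = len(seq)
        trimmed = seq[1:] if trim5 else seq
        if not trimmed:
            n_dropped += 1
            continue
        out.append((read_id, trimmed))
    if n_dropped:
        logger.info("dropped %d reads empty after 5' trimming", n_dropped)
    return out, lengths


# ---------------------------------------------------------------------------
# region occupancy

def _assigned_position(aln: Alignment, assignment: str) -> int:
    if assignment == "p_site_shift12":
        return aln.ref_start + DEFAULT_P_SITE_SHIFT
    if assignment == "five_prime":
        return aln.ref_start
    if assignment == "three_prime":
        return aln.ref_end - 1
    raise ValueError(f"unknown assignment {assignment!r}")


def region_counts(
    alignments: Sequence[Alignment],
    model: TranscriptomeModel,
    assignment: str = "p_site_shift12",
) -> pd.DataFrame:
    """Per-transcript raw and rpm read counts by region.

    Each mapped read contributes a single position (P site by default, i.e.
    5' end + 12) classified as 5'UTR/CDS/3'UTR. Reads whose assigned
    position falls off the transcript are dropped and counted in the
    DataFrame ``attrs``. rpm is reads per million mapped reads in the sample.
    """
    mapped = [a for a in alignments if a.mapped]
    total_mapped = len(mapped)
    raw: dict[str, dict[Region, int]] = {}
    n_dropped = 0
    for aln in mapped:
        tx = model[aln.transcript_id]
        pos = _assigned_position(aln, assignment)
        if not 0 <= pos < tx.annotated_len:
            n_dropped += 1
            continue
        region = region_of(pos, tx)
        raw.setdefault(tx.id, {r: 0 for r in Region})[region] += 1
    rows = []
    for tx_id in sorted(raw):
        row = {"transcript_id": tx_id}
        for region in Region:
            row[f"{region.value}_raw"] = raw[tx_id][region]
            row[f"{region.value}_rpm"] = (
                raw[tx_id][region] * 1e6 / total_mapped if total_mapped else 0.0
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["total_mapped"] = total_mapped
    df.attrs["n_dropped_off_transcript"] = n_dropped
    return df


def utr_cds_ratios(
    counts: pd.DataFrame,
    min_raw: int = DEFAULT_MIN_RAW,
    region: str = "UTR3",
) -> tuple[pd.DataFrame, float]:
    """Per-transcript and pooled region:CDS rpm ratios.

    Transcripts are kept only when their raw CDS + region reads strictly
    exceed ``min_raw``; transcripts with zero CDS rpm but nonzero region rpm
    are excluded and counted. The pooled ratio sums rpm over included
    transcripts before dividing.
    """
    if region not in ("UTR3", "UTR5"):
        raise ValueError(f"region must be UTR3 or UTR5, got {region!r}")
    raw_sum = counts[f"{region}_raw"] + counts["CDS_raw"]
    keep = raw_sum > min_raw
    zero_cds = keep & (counts["CDS_rpm"] == 0) & (counts[f"{region}_rpm"] > 0)
    keep &= ~zero_cds
    kept = counts[keep].copy()
    if kept.empty:
        raise ValueError("no transcript passes the minimum-read filter")
    kept["ratio"] = kept[f"{region}_rpm"] / kept["CDS_rpm"]
    pooled = kept[f"{region}_rpm"].sum() / kept["CDS_rpm"].sum()
    kept.attrs["n_excluded_zero_cds"] = int(zero_cds.sum())
    return kept[["transcript_id", f"{region}_rpm", "CDS_rpm", "ratio"]], pooled


# ---------------------------------------------------------------------------
# metagenes

@dataclass
class MetageneProfile:
    """Offset-indexed normalized mean occupancy around a shared landmark."""

    offsets: np.ndarray
    value: np.ndarray
    n_transcripts: int
    n_per_offset: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "value": self.value, "n": self.n_per_offset}
        )


def _average_anchor_profiles(
    per_anchor: list[tuple[np.ndarray, np.ndarray]],
    offsets: np.ndarray,
) -> MetageneProfile:
    """Mean-normalize each contributor, then average per offset.

    ``per_anchor`` holds (counts, valid-mask) vectors over ``offsets``;
    offsets outside a transcript contribute nothing (no phantom zeros). Each
    vector is divided by its own mean over valid offsets before averaging.
    """
    total = np.zeros(len(offsets))
    n_cover = np.zeros(len(offsets), dtype=int)
    n_used = 0
    for vec, valid in per_anchor:
        if not valid.any():
            continue
        mean = vec[valid].mean()
        if mean == 0:
            continue
        normed = np.where(valid, vec / mean, 0.0)
        total += normed
        n_cover += valid.astype(int)
        n_used += 1
    if n_used == 0:
        raise ValueError("no contributor with reads in the metagene window")
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(n_cover > 0, total / np.maximum(n_cover, 1), np.nan)
    return MetageneProfile(offsets, value, n_used, n_cover)


def _counts_around(
    anchor: int,
    tx_len: int,
    positions: np.ndarray,
    window: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    abs_pos = anchor + offsets
    valid = (abs_pos >= 0) & (abs_pos < tx_len)
    vec = np.zeros(len(offsets))
    if len(positions):
        binc = np.bincount(positions, minlength=tx_len)
        vec[valid] = binc[abs_pos[valid]]
    return vec, valid


def _positions_by_transcript(
    alignments: Sequence[Alignment],
    model: TranscriptomeModel,
    assignment: str,
    shift: int | None = None,
    cls: Optional[FootprintClass] = None,
) -> dict[str, np.ndarray]:
    by_tx: dict[str, list[int]] = {}
    for aln in alignments:
        if not aln.mapped:
            continue
        if cls is not None and classify_footprint(aln.read_len) != cls:
            continue
        tx = model[aln.transcript_id]
        if shift is not None:
            pos = aln.ref_start + shift
        else:
            pos = _assigned_position(aln, assignment)
        if 0 <= pos < tx.annotated_len:
            by_tx.setdefault(aln.transcript_id, []).append(pos)
    return {k: np.asarray(v, dtype=int) for k, v in by_tx.items()}


def metagene_stop(
    alignments: Sequence[Alignment],
    model: TranscriptomeModel,
    window: tuple[int, int] = (-50, 50),
    assignment: str = "five_prime",
    min_reads: int = DEFAULT_MIN_RAW,
) -> MetageneProfile:
    """Normalized average occupancy around the stop codon.

    Offset 0 is the first nucleotide of the stop codon; reads contribute
    their unshifted 5' end by default. Each transcript's window vector is
    divided by its own mean before transcripts are averaged equally;
    transcripts with fewer than ``min_reads`` reads in the window are
    excluded.
    """
    by_tx = _positions_by_transcript(alignments, model, assignment)
    per_anchor = []
    offsets = np.arange(window[0], window[1] + 1)
    for tx_id, positions in sorted(by_tx.items()):
        tx = model[tx_id]
        anchor = tx.cds_end - 3  # first nt of the stop codon
        vec, valid = _counts_around(anchor, tx.annotated_len, positions, window)
        if vec[valid].sum() < min_reads:
            continue
        per_anchor.append((vec, valid))
    return _average_anchor_profiles(per_anchor, offsets)


# ---------------------------------------------------------------------------
# altORFs

@dataclass(frozen=True)
class AltORF:
    """AUG-initiated reading frame in a 3'UTR.

    ``stop`` is the first nucleotide of the in-frame stop codon, or ``None``
    when the frame runs off the annotated 3' end (toward the poly(A) tail).
    """

    transcript_id: str
    start: int
    stop: Optional[int]


_STOPS = {"TAA", "TAG", "TGA"}


def find_altorfs(tx: Transcript, min_codons: int = 2) -> list[AltORF]:
    """Scan the 3'UTR for AUG-initiated ORFs.

    Every AUG opens an ORF (overlapping ORFs are all kept). An ORF with an
    in-frame stop is discarded when it has fewer than ``min_codons`` codons
    (AUG included) before the stop; ORFs that never meet a stop before the
    transcript end are kept regardless.
    """
    orfs: list[AltORF] = []
    seq = tx.seq
    for start in range(tx.cds_end, tx.annotated_len - 2):
        if seq[start:start + 3] != "ATG":
            continue
        stop = None
        for pos in range(start + 3, tx.annotated_len - 2, 3):
            if seq[pos:pos + 3] in _STOPS:
                stop = pos
                break
        if stop is not None and (stop - start) // 3 < min_codons:
            continue
        orfs.append(AltORF(tx.id, start, stop))
    return orfs


def metagene_altorf(
    alignments: Sequence[Alignment],
    altorfs: Sequence[AltORF],
    model: TranscriptomeModel,
    shift: int = DEFAULT_P_SITE_SHIFT,
    window: tuple[int, int] = (-18, 60),
    min_reads: int = 1,
) -> tuple[MetageneProfile, dict[int, float]]:
    """Occupancy around altORF start codons plus reading-frame fractions.

    Reads are assigned their 5' end + ``shift`` (approximate P site). The
    profile is anchored at each altORF's AUG; frame fractions count assigned
    positions inside each altORF (start up to its stop, or the last complete
    codon when the stop is absent) by ``(position - start) mod 3``.
    """
    by_tx = _positions_by_transcript(alignments, model, "five_prime", shift=shift)
    offsets = np.arange(window[0], window[1] + 1)
    per_anchor = []
    frame_tally = {0: 0, 1: 0, 2: 0}
    for orf in altorfs:
        if orf.transcript_id not in by_tx:
            continue
        tx = model[orf.transcript_id]
        positions = by_tx[orf.transcript_id]
        vec, valid = _counts_around(orf.start, tx.annotated_len, positions, window)
        if vec[valid].sum() >= min_reads:
            per_anchor.append((vec, valid))
        end = orf.stop if orf.stop is not None else (
            orf.start + 3 * ((tx.annotated_len - orf.start) // 3)
        )
        inside = positions[(positions >= orf.start) & (positions < end)]
        for pos in inside:
            frame_tally[(pos - orf.start) % 3] += 1
    profile = _average_anchor_profiles(per_anchor, offsets)
    total = sum(frame_tally.values())
    if total == 0:
        raise ValueError("no reads assigned inside any altORF")
    frame_fractions = {f: c / total for f, c in frame_tally.items()}
    return profile, frame_fractions


# ---------------------------------------------------------------------------
# motif-anchored 3'-end averaging

def _motif_occurrences(tx: Transcript, motif: str, region: Region) -> list[int]:
    """0-based positions of the *last* base of each motif occurrence in region."""
    if region == Region.CDS:
        lo, hi = tx.cds_start, tx.cds_end
    elif region == Region.UTR3:
        lo, hi = tx.cds_end, tx.annotated_len
    else:
        lo, hi = 0, tx.cds_start
    hits = []
    m = len(motif)
    for i in range(lo, hi - m + 1):
        if tx.seq[i:i + m] == motif:
            hits.append(i + m - 1)
    return hits


def motif_anchored_average(
    alignments: Sequence[Alignment],
    model: TranscriptomeModel,
    motif: str = "UU",
    cls: FootprintClass = FootprintClass.SHORT16,
    region: Region = Region.CDS,
    window: tuple[int, int] = (-25, 25),
) -> MetageneProfile:
    """Average 3'-end occupancy of one footprint class around a motif.

    Offset 0 is the 3'-most base of each motif occurrence (for UU, the
    second U — where a cleavage-stalled footprint's 3' end terminates).
    Reads contribute their 3'-terminal base (``ref_end - 1``). Occurrences
    closer than the window to the region edges are skipped. Occurrence
    counts are summed per transcript, mean-normalized, and averaged across
    transcripts as in :func:`metagene_stop`.
    """
    motif_dna = to_dna(motif)
    if len(motif_dna) < 2:
        raise ValueError("motif must be at least 2 nt")
    by_tx = _positions_by_transcript(
        alignments, model, "three_prime", cls=cls
    )
    offsets = np.arange(window[0], window[1] + 1)
    per_tx: list[tuple[np.ndarray, np.ndarray]] = []
    n_occurrences = 0
    for tx_id in sorted(model.transcripts):
        tx = model[tx_id]
        if region == Region.CDS:
            lo_edge, hi_edge = tx.cds_start, tx.cds_end
        elif region == Region.UTR3:
            lo_edge, hi_edge = tx.cds_end, tx.annotated_len
        else:
            lo_edge, hi_edge = 0, tx.cds_start
        anchors = [
            a for a in _motif_occurrences(tx, motif_dna, region)
            if a + window[0] >= lo_edge and a + window[1] < hi_edge
        ]
        if not anchors:
            continue
        n_occurrences += len(anchors)
        positions = by_tx.get(tx_id, np.array([], dtype=int))
        vec_sum = np.zeros(len(offsets))
        valid_any = np.zeros(len(offsets), dtype=bool)
        for anchor in anchors:
            vec, valid = _counts_around(anchor, tx.annotated_len, positions, window)
            vec_sum += vec
            valid_any |= valid
        per_tx.append((vec_sum, valid_any))
    if n_occurrences == 0:
        raise ValueError(f"no {motif!r} occurrence fits the window in any {region.value}")
    return _average_anchor_profiles(per_tx, offsets)


# ---------------------------------------------------------------------------
# 3' dinucleotides, poly(A) reads, spike-ins, length distribution

def three_prime_dinucleotide(
    alignments: Sequence[Alignment],
    model: TranscriptomeModel,
    cls: FootprintClass = FootprintClass.SHORT16,
) -> dict[str, float]:
    """Reference dinucleotide at the 3' terminus of one footprint class.

    For cleavage-stalled 16-mers this reads out the cut motif directly:
    the bases at ``(ref_end - 2, ref_end - 1)``. RNA-alphabet fractions over
    all 16 dinucleotides, summing to 1.
    """
    tallies = {d: 0 for d in ALL_DINUCLEOTIDES}
    n = 0
    for aln in alignments:
        if not aln.mapped or classify_footprint(aln.read_len) != cls:
            continue
        if aln.ref_end < 2:
            continue
        tx = model[aln.transcript_id]
        tallies[tx.seq[aln.ref_end - 2:aln.ref_end]] += 1
        n += 1
    if n == 0:
        raise ValueError(f"no mapped {cls.value} footprints")
    return {to_rna(d): c / n for d, c in tallies.items()}


def _trailing_a_run(seq: str) -> int:
    return len(seq) - len(seq.rstrip("A"))


def count_polyA_tail_reads(
    unmapped_seqs: Iterable[str],
    min_run: int = 8,
    max_run: int = 18,
    open_ended: bool = False,
) -> dict[str, float]:
    """Fraction of unmapped reads ending in a bounded poly(A) run.

    A read counts when its maximal 3'-terminal run of A has length within
    ``[min_run, max_run]`` (or ``>= min_run`` with ``open_ended``). These are
    footprints of ribosomes that advanced into the poly(A) tail.
    """
    n_polyA = n_unmapped = 0
    for seq in unmapped_seqs:
        n_unmapped += 1
        run = _trailing_a_run(to_dna(seq))
        if run >= min_run and (open_ended or run <= max_run):
            n_polyA += 1
    if n_unmapped == 0:
        raise ValueError("no unmapped reads supplied")
    return {
        "n_polyA": n_polyA,
        "n_unmapped": n_unmapped,
        "percent": 100.0 * n_polyA / n_unmapped,
    }


def spike_in_ratio(
    seqs: Iterable[str],
    spikes: Optional[Sequence[tuple[str, str]]] = None,
) -> dict:
    """Count spike-in oligos and the 18-mer/30-mer recovery-bias ratio.

    Matching is exact against post-trim sequences, allowing for the one
    trimmed 5' base (a read matches a spike either in full or missing its
    first base). No deduplication is applied to spike matches.
    """
    spikes = SPIKE_INS if spikes is None else spikes
    spike_dna = [(name, to_dna(seq)) for name, seq in spikes]
    lookup: dict[str, str] = {}
    for name, seq in spike_dna:
        lookup[seq] = name
        lookup[seq[1:]] = name
    counts = {name: 0 for name, _ in spike_dna}
    for seq in seqs:
        name = lookup.get(to_dna(seq))
        if name is not None:
            counts[name] += 1
    n18 = sum(counts[name] for name, s in spike_dna if len(s) == 18)
    n30 = sum(counts[name] for name, s in spike_dna if len(s) == 30)
    ratio = n18 / n30 if n30 else None
    if n30 == 0:
        logger.warning("no 30-mer spike-in matches: 18/30 ratio undefined")
    return {"per_spike": counts, "n_18": n18, "n_30": n30, "ratio_18_to_30": ratio}


def footprint_length_distribution(
    alignments: Sequence[Alignment],
    len_range: tuple[int, int] = (15, 34),
) -> pd.Series:
    """Normalized pre-trim length histogram of mapped footprints (15-34 nt)."""
    lengths = [a.read_len for a in alignments
               if a.mapped and len_range[0] <= a.read_len <= len_range[1]]
    if not lengths:
        raise ValueError("no mapped footprints in length range")
    idx = np.arange(len_range[0], len_range[1] + 1)
    counts = pd.Series(0, index=idx, dtype=float)
    vc = pd.Series(lengths).value_counts()
    counts.loc[vc.index] = vc.values
    return counts / counts.sum()
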