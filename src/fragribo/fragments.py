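"""Nanopore-stage analysis of 3' mRNA cleavage fragments.

Reads from poly(A)-selected direct RNA sequencing are classified as 3'
fragments when they are shorter than one third of their annotated transcript
and anchored at its 3' end. Because the pore loses the last ~10-15 nt of a
read's 5' end, the cleavage dinucleotide is sought in the reference sequence
a fixed window upstream of the mapped 5' end, where per-position Shannon
information content and the dinucleotide spectrum (classically peaking at
offsets -12/-11) reveal the endonuclease's U-N preference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Alignment, Transcript, TranscriptomeModel, to_rna

logger = logging.getLogger(__name__)

DEFAULT_END_TOL = 30  # nt of 3'-end slack when requiring 3' anchoring
DEFAULT_LEN_BOUNDS = (50, 10_000)  # nt, min/max aligned span for a fragment
DEFAULT_WINDOW = 15  # nt of reference sequence upstream of the mapped 5' end

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
ALL_DINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=2)]


@dataclass(frozen=True)
class FragmentCall:
    """Per-read fragment classification."""

    read_id: str
    transcript_id: str
    is_fragment: bool
    norm_len: float
    cleavage_window: Optional[str] = None  # reference bases, 5'->3', length W


@dataclass
class MotifProfile:
    """Per-position base counts and information content upstream of 5' ends.

    ``offsets`` are negative positions relative to the mapped 5' end (offset
    -1 is the base immediately upstream). ``ic_bits`` is the Shannon
    information content 2 + sum_b f_b log2 f_b, in [0, 2] bits.
    """

    offsets: list[int]
    counts: pd.DataFrame  # index = offsets, columns = A,C,G,T
    n_windows: int
    ic_bits: pd.Series  # index = offsets

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out["ic_bits"] = self.ic_bits
        out.index.name = "offset"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class RankTestResult:
    u_stat: float
    p_value: float
    n_a: int
    n_b: int


@dataclass
class LengthDistribution:
    """Raw and transcript-normalized read-length histograms."""

    raw_edges: np.ndarray
    raw_counts: np.ndarray
    norm_edges: np.ndarray
    norm_counts: np.ndarray
    raw_lengths: np.ndarray
    norm_lengths: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "raw_bin_left": self.raw_edges[:-1],
                "raw_bin_right": self.raw_edges[1:],
                "raw_count": self.raw_counts,
            }
        )


def normalized_length(aln: Alignment, tx: Transcript) -> float:
    """Aligned span divided by the annotated transcript length, capped at 1."""
    if not aln.mapped:
        raise ValueError(f"read {aln.read_id} is unmapped")
    return min(1.0, (aln.ref_end - aln.ref_start) / tx.annotated_len)


def classify_fragment(
    aln: Alignment,
    tx: Transcript,
    end_tol: int = DEFAULT_END_TOL,
    len_bounds: tuple[int, int] = DEFAULT_LEN_BOUNDS,
    window: int = DEFAULT_WINDOW,
) -> FragmentCall:
    """Call a mapped read as a 3' fragment or not.

    A fragment must satisfy all of: aligned span strictly shorter than one
    third of the annotated length; 3'-anchored (``ref_end`` within
    ``end_tol`` of the transcript end); span within ``len_bounds``. The
    upstream reference window is attached only when the mapped 5' end leaves
    room for it.
    """
    span = aln.ref_end - aln.ref_start
    norm = normalized_length(aln, tx)
    is_fragment = (
        span * 3 < tx.annotated_len
        and aln.ref_end >= tx.annotated_len - end_tol
        and len_bounds[0] <= span <= len_bounds[1]
    )
    cleavage_window = None
    if is_fragment and aln.ref_start >= window:
        cleavage_window = tx.seq[aln.ref_start - window:aln.ref_start]
    return FragmentCall(aln.read_id, tx.id, is_fragment, norm, cleavage_window)


def extract_cleavage_context(
    call: FragmentCall, model: TranscriptomeModel, window: int = DEFAULT_WINDOW
) -> Optional[str]:
    """Reference bases ``[p - window, p)`` upstream of a fragment's 5' end.

    Returns ``None`` (read excluded) when the 5' end is closer than
    ``window`` to the transcript start. The window comes from the reference
    transcript, not the read: the read is unsequenced there by definition.
    """
    if not call.is_fragment:
        raise ValueError(f"read {call.read_id} is not a fragment call")
    if call.cleavage_window is not None and len(call.cleavage_window) == window:
        return call.cleavage_window
    return None


def position_information_content(windows: Sequence[str]) -> MotifProfile:
    """Per-position base counts and Shannon information content (bits).

    All windows must share one length W; positions are reported as offsets
    -W..-1 relative to the mapped 5' end. No small-sample correction is
    applied.
    """
    if not windows:
        raise ValueError("no windows supplied")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("windows differ in length")
    counts = np.zeros((width, 4), dtype=int)
    for w in windows:
        for j, base in enumerate(w):
            counts[j, _BASE_INDEX[base]] += 1
    n = len(windows)
    freqs = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    offsets = list(range(-width, 0))
    counts_df = pd.DataFrame(counts, index=offsets, columns=list("ACGT"))
    return MotifProfile(
        offsets=offsets,
        counts=counts_df,
        n_windows=n,
        ic_bits=pd.Series(ic, index=offsets),
    )


def dinucleotide_distribution(
    windows: Sequence[str],
    pos_pair: tuple[int, int] = (-12, -11),
) -> dict[str, dict[str, float]]:
    """Dinucleotide spectrum at a fixed offset pair upstream of 5' ends.

    Returns RNA-alphabet fractions over all 16 dinucleotides (summing to 1)
    plus the {UU, UA, UG, UC} breakdown renormalized among windows whose
    first base is U — the endonuclease's second-base preference.
    """
    if not windows:
        raise ValueError("no windows supplied")
    width = len(windows[0])
    i, j = (width + pos_pair[0], width + pos_pair[1])
    if not (0 <= i < width and 0 <= j < width):
        raise ValueError(f"offsets {pos_pair} outside window of width {width}")
    tallies: dict[str, int] = {d: 0 for d in ALL_DINUCLEOTIDES}
    for w in windows:
        tallies[w[i] + w[j]] += 1
    n = len(windows)
    all_frac = {to_rna(d): c / n for d, c in tallies.items()}
    u_first = {d: tallies[d] for d in ("TT", "TA", "TG", "TC")}
    u_total = sum(u_first.values())
    u_frac = {
        to_rna(d): (c / u_total if u_total else 0.0) for d, c in u_first.items()
    }
    return {"all": all_frac, "u_first": u_frac}


def compare_length_distributions(
    a: Sequence[float], b: Sequence[float]
) -> RankTestResult:
    """Two-sided Mann-Whitney U test between two length samples.

    Uses exact enumeration for small samples (both n <= 20, no ties across
    groups) and the tie-corrected normal approximation otherwise. Two fully
    degenerate samples (every value identical) give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return RankTestResult(len(a) * len(b) / 2.0, 1.0, len(a), len(b))
    method = "exact" if (len(a) <= 20 and len(b) <= 20
                         and len(np.unique(combined)) == len(combined)) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankTestResult(float(res.statistic), float(res.pvalue), len(a), len(b))


def length_density_summary(
    alignments: Iterable[Alignment],
    model: TranscriptomeModel,
    raw_bins: int = 50,
    norm_bins: int = 50,
) -> LengthDistribution:
    """Raw (nt) and normalized (span / annotated length) length histograms."""
    raw, norm = [], []
    for aln in alignments:
        if not aln.mapped:
            continue
        tx = model[aln.transcript_id]
        raw.append(aln.ref_end - aln.ref_start)
        norm.append(normalized_length(aln, tx))
    if not raw:
        raise ValueError("no mapped alignments")
    raw = np.asarray(raw)
    norm = np.asarray(norm)
    raw_counts, raw_edges = np.histogram(raw, bins=raw_bins)
    norm_counts, norm_edges = np.histogram(norm, bins=norm_bins, range=(0.0, 1.0))
    return LengthDistribution(raw_edges, raw_counts, norm_edges, norm_counts, raw, norm)


@dataclass
class FragmentAnalysis:
    """Bundle of all nanopore-stage results for one sample."""

    calls: pd.DataFrame
    motif: Optional[MotifProfile]
    dinucleotides: Optional[dict[str, dict[str, float]]]
    lengths: LengthDistribution
    n_fragments: int
    n_windows: int
    n_excluded_short_utr5: int


def analyze_fragments(
    alignments: Sequence[Alignment],
    model: TranscriptomeModel,
    end_tol: int = DEFAULT_END_TOL,
    len_bounds: tuple[int, int] = DEFAULT_LEN_BOUNDS,
    window: int = DEFAULT_WINDOW,
    pos_pair: tuple[int, int] = (-12, -11),
) -> FragmentAnalysis:
    """Run the full nanopore-stage pipeline on mapped alignments.

    Classifies every mapped read, collects upstream reference windows from
    fragment calls, and computes the motif profile and dinucleotide spectrum.
    """
    rows = []
    windows = []
    n_fragments = n_excluded = 0
    mapped = [a for a in alignments if a.mapped]
    for aln in mapped:
        tx = model[aln.transcript_id]
        call = classify_fragment(aln, tx, end_tol, len_bounds, window)
        rows.append(
            dict(
                read_id=call.read_id,
                transcript_id=call.transcript_id,
                is_fragment=call.is_fragment,
                norm_len=call.norm_len,
                has_window=call.cleavage_window is not None,
            )
        )
        if call.is_fragment:
            n_fragments += 1
            if call.cleavage_window is not None:
                windows.append(call.cleavage_window)
            else:
                n_excluded += 1
    motif = position_information_content(windows) if windows else None
    dinucs = dinucleotide_distribution(windows, pos_pair) if windows else None
    lengths = length_density_summary(mapped, model)
    logger.info(
        "%d mapped reads: %d fragments, %d motif windows (%d excluded near 5' end)",
        len(mapped), n_fragments, len(windows), n_excluded,
    )
    return FragmentAnalysis(
        calls=pd.DataFrame(rows),
        motif=motif,
        dinucleotides=dinucs,
        lengths=lengths,
        n_fragments=n_fragments,
        n_windows=len(windows),
        n_excluded_short_utr5=n_excluded,
    )
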