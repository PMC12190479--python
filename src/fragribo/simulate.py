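"""Ground-truth read simulator.

Emulates the two sequencing assays around RNase L activation:

* **Direct RNA nanopore reads** of poly(A)-selected RNA: intact mRNAs and the
  poly(A)-bearing 3' products of endonucleolytic UN^N cleavage, with the
  characteristic ~10-15 nt of 5' sequence lost in the pore, plus a
  configurable share of motif-free background fragments.
* **Ribosome-profiling footprints** (15-34 nt size selection): elongating
  25-34 nt footprints with 3-nt periodicity, a minor 19-24 nt class, 15-18 nt
  footprints whose 3' end sits exactly at a cleavage site, unmappable reads
  ending in a poly(A) run, and fixed-sequence spike-in oligos.

Cleavage geometry
-----------------
A cut at a U-N dinucleotide is placed *after* the second base (UN^N):
``cleave_pos`` is the first nucleotide of the 3' fragment, so the cleavage
dinucleotide occupies ``cleave_pos - 2`` and ``cleave_pos - 1``. One
convention therefore produces both hallmark observations: the motif appears
10-15 nt upstream of nanopore 5' ends (pore truncation), and short-footprint
3' ends terminate on the second base of the motif.

Every emitted read carries one extra 5' base (an untemplated base with
probability ``untemplated5_prob``, otherwise the genuine upstream transcript
base); the analysis trims a single 5' base, so the recorded truth alignment
is what the trimmed read would map to. Reported read lengths are pre-trim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    STOP_CODONS,
    Transcript,
    TranscriptomeModel,
    to_dna,
    to_rna,
)

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

#: Spike-in oligos co-selected with footprints to monitor length bias
#: (three 18-mers and three 30-mers; stored as RNA).
SPIKE_INS: tuple[tuple[str, str], ...] = (
    ("18-mer-1", "UCGAACCUUAAGGUUAAU"),
    ("18-mer-2", "AACUACCGACUCAUCCCA"),
    ("18-mer-3", "CUAAUACUUACGAACCAG"),
    ("30-mer-1", "AAUACCACCCCCAUGAACGCUGCACACACG"),
    ("30-mer-2", "AACUACCGACUCAUCCCAUCUUGCCAGUAC"),
    ("30-mer-3", "CUAAUACUUACGAACCAGACGAAUCCCUUG"),
)

FOOTPRINT_CLASSES = ("long28", "mid21", "short16", "polyA_tail", "spike_in")


@dataclass
class SimConfig:
    """All simulator knobs, shared by the nanopore and footprint stages.

    Fractions are probabilities in [0, 1]; ``trunc_dist`` and
    ``footprint_mix`` must each sum to 1. ``motif_weights`` gives the
    relative cleavage propensity of a U-N site by its second base.
    """

    seed: int = 0
    n_transcripts: int = 30
    len_range: tuple[int, int] = (600, 2000)
    utr_fracs: tuple[float, float] = (0.15, 0.35)
    cleave_prob: float = 0.8
    motif_weights: dict[str, float] = field(
        default_factory=lambda: {"UU": 0.4, "UA": 0.3, "UG": 0.2, "UC": 0.1}
    )
    trunc_dist: dict[int, float] = field(
        default_factory=lambda: {9: 0.25, 10: 0.5, 11: 0.25}
    )
    bg_frag_frac: float = 0.05
    n_reads: int = 10_000
    footprint_mix: dict[str, float] = field(
        default_factory=lambda: {
            "long28": 0.60,
            "mid21": 0.10,
            "short16": 0.20,
            "polyA_tail": 0.05,
            "spike_in": 0.05,
        }
    )
    frame0_prob: float = 0.7
    polyA_run_range: tuple[int, int] = (8, 18)
    untemplated5_prob: float = 0.5
    polyA_len: int = 30  # poly(A) appended to nanopore reads
    spike18_frac: float = 0.5  # share of spike-in reads that are 18-mers

    def validate(self) -> None:
        for name in ("cleave_prob", "bg_frag_frac", "frame0_prob",
                     "untemplated5_prob", "spike18_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if abs(sum(self.trunc_dist.values()) - 1.0) > 1e-9:
            raise ValueError("trunc_dist must sum to 1")
        if abs(sum(self.footprint_mix.values()) - 1.0) > 1e-9:
            raise ValueError("footprint_mix must sum to 1")
        if set(self.footprint_mix) - set(FOOTPRINT_CLASSES):
            raise ValueError(f"footprint_mix keys must be in {FOOTPRINT_CLASSES}")
        if not any(w > 0 for w in self.motif_weights.values()):
            raise ValueError("motif_weights must not be all zero")
        if any(w < 0 for w in self.motif_weights.values()):
            raise ValueError("motif_weights must be nonnegative")
        if self.len_range[0] > self.len_range[1] or self.len_range[0] < 30:
            raise ValueError(f"bad len_range {self.len_range}")
        if self.polyA_run_range[0] > self.polyA_run_range[1] or self.polyA_run_range[0] < 1:
            raise ValueError(f"bad polyA_run_range {self.polyA_run_range}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{
            k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()
        })
        # YAML maps may carry string keys for the truncation offsets
        cfg.trunc_dist = {int(k): float(v) for k, v in cfg.trunc_dist.items()}
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass(frozen=True)
class Molecule:
    """One mRNA molecule, possibly cleaved.

    For an RNase L cut, ``cleave_pos`` is the first nucleotide of the 3'
    fragment; the U-N dinucleotide sits at ``cleave_pos - 2 .. cleave_pos - 1``.
    """

    transcript_id: str
    cleave_pos: Optional[int]
    origin: str  # "rnasel" | "background" | "intact"


@dataclass
class SimReads:
    """Simulator output: reads plus per-read ground truth.

    ``truth`` has one row per read; ``truth_alignments`` holds the alignment
    each (trimmed, where applicable) read would produce, in the documented
    truth-TSV column layout.
    """

    reads: list[tuple[str, str, str]]  # (read_id, sequence, quality)
    truth: pd.DataFrame
    truth_alignments: pd.DataFrame

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for read_id, seq, qual in self.reads:
                fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def write_truth_alignments(self, path: str | Path) -> None:
        self.truth_alignments.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transcriptome generation

def generate_transcriptome(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> TranscriptomeModel:
    """Generate random transcripts with valid UTR5/CDS/UTR3 structure.

    Base composition is i.i.d. uniform; each CDS starts with ATG, ends with a
    stop codon, and has triplet length (any length remainder is pushed into
    the 3'UTR). Deterministic for a fixed ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    f5, f3 = cfg.utr_fracs
    transcripts: dict[str, Transcript] = {}
    for i in range(cfg.n_transcripts):
        length = int(rng.integers(cfg.len_range[0], cfg.len_range[1] + 1))
        utr5 = int(round(length * f5))
        cds = length - utr5 - int(round(length * f3))
        cds -= cds % 3
        if cds < 6:
            raise ValueError(
                f"utr_fracs {cfg.utr_fracs} leave a CDS of {cds} nt "
                f"(< 2 codons) on a {length} nt transcript"
            )
        seq = rng.choice(BASES, size=length)
        seq[utr5:utr5 + 3] = list("ATG")
        stop = STOP_CODONS[int(rng.integers(3))]
        seq[utr5 + cds - 3:utr5 + cds] = list(stop)
        tx = Transcript(
            id=f"tx{i:04d}",
            seq="".join(seq),
            cds_start=utr5,
            cds_end=utr5 + cds,
        )
        tx.validate()
        transcripts[tx.id] = tx
    return TranscriptomeModel(transcripts)


# ---------------------------------------------------------------------------
# cleavage

def _cleavage_sites(tx: Transcript, weights: dict[str, float]):
    """Candidate U-N site indices and their weights on one transcript.

    A site index ``i`` is the U of the dinucleotide; the cut falls after
    ``i + 1``, so only sites leaving a non-empty 3' fragment are kept.
    """
    seq = tx.seq
    sites, w = [], []
    wt = {to_dna(k)[1]: float(v) for k, v in weights.items()}  # second base -> weight
    for i in range(len(seq) - 2):
        if seq[i] == "T":
            weight = wt.get(seq[i + 1], 0.0)
            if weight > 0:
                sites.append(i)
                w.append(weight)
    return np.array(sites, dtype=int), np.array(w, dtype=float)


def simulate_cleavage(
    model: TranscriptomeModel,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    n_molecules: Optional[int] = None,
) -> list[Molecule]:
    """Draw molecules and cleave each with probability ``cleave_prob``.

    A cleaved molecule picks a U-N site with probability proportional to the
    motif weight of the second base; molecules on transcripts without any
    positively-weighted site stay intact.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_reads if n_molecules is None else n_molecules
    tx_ids = sorted(model.transcripts)
    site_cache = {
        tx_id: _cleavage_sites(model[tx_id], cfg.motif_weights) for tx_id in tx_ids
    }
    prob_cache = {
        tx_id: (w / w.sum() if w.sum() > 0 else None)
        for tx_id, (s, w) in site_cache.items()
    }
    molecules: list[Molecule] = []
    choices = rng.integers(0, len(tx_ids), size=n)
    cleaved = rng.random(n) < cfg.cleave_prob
    for idx, do_cleave in zip(choices, cleaved):
        tx_id = tx_ids[idx]
        sites, _ = site_cache[tx_id]
        probs = prob_cache[tx_id]
        if do_cleave and probs is not None and len(sites):
            site = int(sites[rng.choice(len(sites), p=probs)])
            molecules.append(Molecule(tx_id, site + 2, "rnasel"))
        else:
            molecules.append(Molecule(tx_id, None, "intact"))
    return molecules


# ---------------------------------------------------------------------------
# nanopore 3'-fragment reads

def _sample_trunc(cfg: SimConfig, rng: np.random.Generator) -> int:
    offsets = sorted(cfg.trunc_dist)
    probs = np.array([cfg.trunc_dist[o] for o in offsets], dtype=float)
    return int(offsets[rng.choice(len(offsets), p=probs / probs.sum())])


def simulate_nanopore_reads(
    molecules: Sequence[Molecule],
    model: TranscriptomeModel,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> SimReads:
    """Emit poly(A)-selected direct-RNA reads for a set of molecules.

    Only poly(A)-bearing species appear: the 3' fragment of a cleaved
    molecule or the whole transcript of an intact one (5' fragments are never
    emitted). The observed 5' end is the true fragment start plus a pore
    truncation offset drawn from ``trunc_dist``. A ``bg_frag_frac`` share of
    reads is replaced by motif-free background fragments with a uniform 5'
    start. Sequences are RNA with a poly(A) tail appended; the tail is not
    part of the recorded alignment span.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    reads, truth_rows, aln_rows = [], [], []
    for i, mol in enumerate(molecules):
        tx = model[mol.transcript_id]
        read_id = f"np{i:06d}"
        is_bg = rng.random() < cfg.bg_frag_frac
        if is_bg:
            ref_start = int(rng.integers(0, tx.annotated_len))
            origin, cleave_pos, k = "background", None, None
            cls = "fragment3p"
        elif mol.origin == "rnasel":
            k = _sample_trunc(cfg, rng)
            ref_start = min(mol.cleave_pos + k, tx.annotated_len - 1)
            origin, cleave_pos, cls = "rnasel", mol.cleave_pos, "fragment3p"
        else:
            k = _sample_trunc(cfg, rng)
            ref_start = min(k, tx.annotated_len - 1)
            origin, cleave_pos, cls = "intact", None, "full_length"
        ref_end = tx.annotated_len
        body = to_rna(tx.seq[ref_start:ref_end])
        seq = body + "A" * cfg.polyA_len
        reads.append((read_id, seq, "I" * len(seq)))
        read_len = len(seq)
        truth_rows.append(
            dict(
                read_id=read_id,
                transcript_id=tx.id,
                true_class=cls,
                origin=origin,
                cleave_pos=-1 if cleave_pos is None else cleave_pos,
                trunc_offset=-1 if k is None else k,
                ref_start=ref_start,
                ref_end=ref_end,
                read_len=read_len,
                mapped=True,
            )
        )
        aln_rows.append(
            dict(
                read_id=read_id,
                transcript_id=tx.id,
                ref_start=ref_start,
                ref_end=ref_end,
                mapped=True,
                **{"class": cls},
                read_len=read_len,
            )
        )
    return SimReads(reads, pd.DataFrame(truth_rows), pd.DataFrame(aln_rows))


# ---------------------------------------------------------------------------
# ribosome footprints

def _frame_positions(start: int, end: int, frame: int) -> np.ndarray:
    """Positions in [start, end) congruent to ``frame`` modulo 3 from start."""
    first = start + frame
    if first >= end:
        return np.array([], dtype=int)
    return np.arange(first, end, 3)


def _emit_first_base(
    tx_seq: str, ref_start: int, cfg: SimConfig, rng: np.random.Generator
) -> str:
    """The sacrificial 5' base removed by trimming: untemplated or genuine."""
    if ref_start == 0 or rng.random() < cfg.untemplated5_prob:
        return str(rng.choice(BASES))
    return tx_seq[ref_start - 1]


def simulate_footprints(
    molecules: Sequence[Molecule],
    model: TranscriptomeModel,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    orf_targets: Optional[Sequence[tuple[str, int, int]]] = None,
) -> SimReads:
    """Emit a 15-34 nt footprint mixture with ground truth.

    Classes per ``footprint_mix``:

    * ``long28`` — reported length 25-34 nt; the P site (trimmed 5' end + 12)
      falls inside an ORF, in frame 0 relative to the ORF start with
      probability ``frame0_prob`` (else frames 1/2 equally). ``orf_targets``
      (``(transcript_id, start, end)`` triplets) defaults to the annotated
      CDSs; pass altORF intervals to simulate 3'UTR translation.
    * ``mid21`` — reported length 19-24 nt, 5' end uniform in the CDS.
    * ``short16`` — reported length 15-18 nt, 3' end exactly at
      ``cleave_pos - 1`` of a cleaved molecule (the second base of the
      cleavage dinucleotide).
    * ``polyA_tail`` — unmappable read ending in a maximal run of 8-18 A's.
    * ``spike_in`` — one of the six fixed spike-in oligos.

    Reported lengths are pre-trim (aligned span + the sacrificial 5' base).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng

    tx_ids = sorted(model.transcripts)
    if orf_targets is None:
        orf_targets = [
            (tx_id, model[tx_id].cds_start, model[tx_id].cds_end) for tx_id in tx_ids
        ]
    cleaved = [
        m for m in molecules
        if m.origin == "rnasel" and m.cleave_pos is not None and m.cleave_pos >= 17
    ]
    mix_classes = [c for c in FOOTPRINT_CLASSES if cfg.footprint_mix.get(c, 0.0) > 0]
    mix_probs = np.array([cfg.footprint_mix[c] for c in mix_classes])
    mix_probs = mix_probs / mix_probs.sum()
    if "short16" in mix_classes and not cleaved:
        raise ValueError(
            "short16 footprints requested but no cleaved molecule provides a "
            "3' end at least 17 nt into its transcript"
        )
    spike_dna = [(name, to_dna(seq)) for name, seq in SPIKE_INS]
    spike18 = [s for s in spike_dna if len(s[1]) == 18]
    spike30 = [s for s in spike_dna if len(s[1]) == 30]

    reads, truth_rows, aln_rows = [], [], []
    class_draws = rng.choice(len(mix_classes), size=cfg.n_reads, p=mix_probs)
    for i, ci in enumerate(class_draws):
        cls = mix_classes[ci]
        read_id = f"fp{i:06d}"
        row = dict(
            read_id=read_id, transcript_id="", true_class=cls, origin="",
            cleave_pos=-1, trunc_offset=-1, ref_start=-1, ref_end=-1,
            read_len=0, mapped=False,
        )
        if cls == "long28":
            reported = int(rng.integers(25, 35))
            span = reported - 1
            for _ in range(200):
                tid, ostart, oend = orf_targets[int(rng.integers(len(orf_targets)))]
                tx = model[tid]
                u = rng.random()
                if u < cfg.frame0_prob:
                    frame = 0
                else:
                    frame = 1 if u < cfg.frame0_prob + (1 - cfg.frame0_prob) / 2 else 2
                cand = _frame_positions(ostart, oend, frame)
                # P site = ref_start + 12 must keep the read on-transcript
                cand = cand[(cand >= 12) & (cand - 12 + span <= tx.annotated_len)]
                if len(cand):
                    p_site = int(cand[rng.integers(len(cand))])
                    ref_start = p_site - 12
                    break
            else:  # pragma: no cover - pathological config
                continue
            ref_end = ref_start + span
            row.update(transcript_id=tid, ref_start=ref_start, ref_end=ref_end,
                       read_len=reported, mapped=True, origin="elongating")
            body = model[tid].seq[ref_start:ref_end]
            seq = _emit_first_base(model[tid].seq, ref_start, cfg, rng) + body
        elif cls == "mid21":
            reported = int(rng.integers(19, 25))
            span = reported - 1
            for _ in range(200):
                tid = tx_ids[int(rng.integers(len(tx_ids)))]
                tx = model[tid]
                hi = min(tx.cds_end, tx.annotated_len - span)
                if hi > tx.cds_start:
                    ref_start = int(rng.integers(tx.cds_start, hi))
                    break
            else:  # pragma: no cover
                continue
            ref_end = ref_start + span
            row.update(transcript_id=tid, ref_start=ref_start, ref_end=ref_end,
                       read_len=reported, mapped=True, origin="empty_a_site")
            seq = _emit_first_base(tx.seq, ref_start, cfg, rng) + tx.seq[ref_start:ref_end]
        elif cls == "short16":
            reported = int(rng.integers(15, 19))
            span = reported - 1
            mol = cleaved[int(rng.integers(len(cleaved)))]
            tx = model[mol.transcript_id]
            ref_end = mol.cleave_pos  # 3' base = second nt of the motif
            ref_start = ref_end - span
            row.update(transcript_id=tx.id, ref_start=ref_start, ref_end=ref_end,
                       read_len=reported, mapped=True, origin="rnasel",
                       cleave_pos=mol.cleave_pos)
            seq = _emit_first_base(tx.seq, ref_start, cfg, rng) + tx.seq[ref_start:ref_end]
        elif cls == "polyA_tail":
            run = int(rng.integers(cfg.polyA_run_range[0], cfg.polyA_run_range[1] + 1))
            prefix_len = int(rng.integers(6, 13))
            prefix = "".join(rng.choice(BASES, size=prefix_len))
            prefix = prefix[:-1] + str(rng.choice(np.array(list("CGT"))))
            seq = str(rng.choice(BASES)) + prefix + "A" * run
            row.update(read_len=len(seq), mapped=False, origin="polyA_stall")
        else:  # spike_in
            pool = spike18 if rng.random() < cfg.spike18_frac else spike30
            name, spike_seq = pool[int(rng.integers(len(pool)))]
            if rng.random() < cfg.untemplated5_prob:
                seq = str(rng.choice(BASES)) + spike_seq
            else:
                seq = spike_seq
            row.update(read_len=len(seq), mapped=False, origin=name)
        reads.append((read_id, seq, "I" * len(seq)))
        if row["read_len"] == 0:
            row["read_len"] = len(seq)
        truth_rows.append(row)
        aln_rows.append(
            dict(
                read_id=read_id,
                transcript_id=row["transcript_id"] or ".",
                ref_start=row["ref_start"],
                ref_end=row["ref_end"],
                mapped=row["mapped"],
                **{"class": cls},
                read_len=row["read_len"],
            )
        )
    return SimReads(reads, pd.DataFrame(truth_rows), pd.DataFrame(aln_rows))


# ---------------------------------------------------------------------------
# auxiliary generators used for calibration experiments

def simulate_uniform_region_reads(
    model: TranscriptomeModel,
    n_reads: int,
    utr3_density: float,
    rng: np.random.Generator,
    p_site_offset: int = 12,
    span: int = 16,
) -> pd.DataFrame:
    """Reads whose P sites are uniform within CDS and 3'UTR at fixed densities.

    Per-nucleotide density is 1 in the CDS and ``utr3_density`` in the 3'UTR;
    only P-site positions for which the implied read fits on the transcript
    are eligible, so the expected pooled 3'UTR:CDS rpm ratio is exactly
    ``utr3_density * (total eligible UTR3 positions) / (total eligible CDS
    positions)``. Returns a truth-alignment-style DataFrame.
    """
    positions: list[tuple[str, int]] = []
    weights: list[float] = []
    for tx in model:
        lo = max(tx.cds_start, p_site_offset)
        hi_cds = min(tx.cds_end, tx.annotated_len - span + p_site_offset)
        for p in range(lo, hi_cds):
            positions.append((tx.id, p))
            weights.append(1.0)
        hi_utr = min(tx.annotated_len, tx.annotated_len - span + p_site_offset)
        for p in range(tx.cds_end, hi_utr):
            positions.append((tx.id, p))
            weights.append(utr3_density)
    w = np.array(weights)
    idx = rng.choice(len(positions), size=n_reads, p=w / w.sum())
    rows = []
    for i, j in enumerate(idx):
        tid, p = positions[j]
        rows.append(
            dict(
                read_id=f"ur{i:06d}",
                transcript_id=tid,
                ref_start=p - p_site_offset,
                ref_end=p - p_site_offset + span,
                mapped=True,
                **{"class": "uniform"},
                read_len=span + 1,
            )
        )
    return pd.DataFrame(rows)


def expected_uniform_region_ratio(
    model: TranscriptomeModel,
    utr3_density: float,
    p_site_offset: int = 12,
    span: int = 16,
) -> float:
    """Closed-form expected pooled 3'UTR:CDS rpm ratio for the generator above."""
    n_cds = n_utr3 = 0
    for tx in model:
        lo = max(tx.cds_start, p_site_offset)
        hi_cds = min(tx.cds_end, tx.annotated_len - span + p_site_offset)
        n_cds += max(0, hi_cds - lo)
        hi_utr = min(tx.annotated_len, tx.annotated_len - span + p_site_offset)
        n_utr3 += max(0, hi_utr - tx.cds_end)
    return utr3_density * n_utr3 / n_cds
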