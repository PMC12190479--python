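"""Transcript-space data model and I/O shared by all analysis stages.

Conventions
-----------
* All coordinates are 0-based, half-open, in transcript space (sense strand).
* The internal nucleotide alphabet is DNA (``ACGT``); ``U`` is converted to
  ``T`` on input and back to ``U`` where RNA output is expected.
* ``annotated_len`` is the length of the annotated transcript body and never
  includes the poly(A) tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
STOP_CODONS = ("TAA", "TAG", "TGA")


def to_dna(seq: str) -> str:
    """Uppercase and convert RNA ``U`` to the internal ``T`` alphabet."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Convert an internal DNA string back to RNA for output."""
    return seq.upper().replace("T", "U")


class Region(str, Enum):
    """Functional region of a transcript position."""

    UTR5 = "UTR5"
    CDS = "CDS"
    UTR3 = "UTR3"


@dataclass(frozen=True)
class Transcript:
    """A single annotated transcript.

    ``cds_start``/``cds_end`` delimit the coding sequence (half-open); the
    5'UTR is ``[0, cds_start)`` and the 3'UTR is ``[cds_end, annotated_len)``.
    """

    id: str
    seq: str
    cds_start: int
    cds_end: int

    @property
    def annotated_len(self) -> int:
        return len(self.seq)

    @property
    def utr3_len(self) -> int:
        return self.annotated_len - self.cds_end

    @property
    def utr5_len(self) -> int:
        return self.cds_start

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    def validate(self) -> None:
        """Raise ``ValueError`` if the transcript violates its invariants."""
        if not (0 <= self.cds_start < self.cds_end <= self.annotated_len):
            raise ValueError(
                f"{self.id}: CDS [{self.cds_start},{self.cds_end}) outside "
                f"[0,{self.annotated_len})"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(
                f"{self.id}: CDS length {self.cds_end - self.cds_start} not a "
                "multiple of 3"
            )
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: non-ACGT characters {sorted(bad)}")


@dataclass
class TranscriptomeModel:
    """Container mapping transcript id to :class:`Transcript`."""

    transcripts: dict[str, Transcript]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError("transcriptome model is empty")

    def __len__(self) -> int:
        return len(self.transcripts)

    def __getitem__(self, tx_id: str) -> Transcript:
        return self.transcripts[tx_id]

    def __contains__(self, tx_id: str) -> bool:
        return tx_id in self.transcripts

    def __iter__(self):
        return iter(self.transcripts.values())


@dataclass(frozen=True)
class Alignment:
    """A read placed on a transcript (transcript coordinates, half-open).

    ``read_len`` is the reported read length *before* any 5' trimming and may
    exceed the aligned span (soft clips, poly(A) tail). For unmapped records
    ``seq`` retains the read sequence so downstream poly(A)/spike-in analyses
    can use it.
    """

    read_id: str
    transcript_id: str
    ref_start: int
    ref_end: int
    read_len: int
    mapped: bool
    sample: str = ""
    seq: Optional[str] = None

    @property
    def span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class SampleMeta:
    """Experimental labels for one library."""

    sample: str
    condition: str  # "minus_25A" | "plus_25A"
    genotype: str  # "WT" | "XRN1_KO" | "PELO_KD" | "PELO_KO"
    fraction: str = "none"  # "total" | "monosome_80S" | "polysome" | "none"

    CONDITIONS = ("minus_25A", "plus_25A")
    GENOTYPES = ("WT", "XRN1_KO", "PELO_KD", "PELO_KO")
    FRACTIONS = ("total", "monosome_80S", "polysome", "none")

    def __post_init__(self) -> None:
        if self.condition not in self.CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.genotype not in self.GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.fraction not in self.FRACTIONS:
            raise ValueError(f"unknown fraction {self.fraction!r}")


def region_of(position: int, transcript: Transcript) -> Region:
    """Classify a transcript position as 5'UTR, CDS, or 3'UTR.

    Regions partition ``[0, annotated_len)``: the CDS is half-open, so the
    first nucleotide after the stop codon is already 3'UTR.
    """
    if not 0 <= position < transcript.annotated_len:
        raise ValueError(
            f"position {position} outside [0,{transcript.annotated_len}) "
            f"on {transcript.id}"
        )
    if position < transcript.cds_start:
        return Region.UTR5
    if position < transcript.cds_end:
        return Region.CDS
    return Region.UTR3


def load_transcriptome(fasta_path: str | Path, annotation_path: str | Path) -> TranscriptomeModel:
    """Load transcript sequences plus CDS annotations.

    The annotation is a tab-separated file with a header line and columns
    ``transcript_id``, ``cds_start``, ``cds_end`` (0-based half-open).
    Transcripts violating the :class:`Transcript` invariants (non-triplet CDS,
    out-of-range CDS, non-ACGT bases) are skipped with a logged warning;
    loading fails only if no valid transcript remains.
    """
    fasta_path = Path(fasta_path)
    annotation_path = Path(annotation_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    if not annotation_path.exists():
        raise FileNotFoundError(annotation_path)

    ann = pd.read_csv(annotation_path, sep="\t")
    required = {"transcript_id", "cds_start", "cds_end"}
    if not required.issubset(ann.columns):
        raise ValueError(
            f"annotation must have columns {sorted(required)}, got {list(ann.columns)}"
        )
    ann = ann.set_index("transcript_id")

    transcripts: dict[str, Transcript] = {}
    n_skipped = 0
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id not in ann.index:
            logger.warning("no annotation for %s; skipped", record.id)
            n_skipped += 1
            continue
        row = ann.loc[record.id]
        tx = Transcript(
            id=record.id,
            seq=to_dna(str(record.seq)),
            cds_start=int(row["cds_start"]),
            cds_end=int(row["cds_end"]),
        )
        try:
            tx.validate()
        except ValueError as exc:
            logger.warning("skipping %s: %s", record.id, exc)
            n_skipped += 1
            continue
        transcripts[tx.id] = tx

    if not transcripts:
        raise ValueError("no valid transcripts loaded")
    logger.info("loaded %d transcripts (%d skipped)", len(transcripts), n_skipped)
    return TranscriptomeModel(transcripts)


@dataclass
class IngestStats:
    """Counters accumulated while ingesting alignment records."""

    n_records: int = 0
    n_mapped: int = 0
    n_unmapped: int = 0
    n_skipped_secondary: int = 0
    n_skipped_unknown_ref: int = 0


def ingest_alignments(
    path: str | Path,
    fmt: str,
    sample: str,
    model: Optional[TranscriptomeModel] = None,
) -> tuple[list[Alignment], IngestStats]:
    """Read transcript-space alignments from SAM/BAM or a truth table.

    ``fmt`` is ``"sam_bam"`` or ``"truth_tsv"`` (the simulator's
    truth-alignment table). Secondary and supplementary SAM records are
    skipped; records whose reference is absent from ``model`` (when given)
    are skipped and counted. Unmapped records are retained with
    ``mapped=False`` and the read sequence attached.
    """
    stats = IngestStats()
    alignments: list[Alignment] = []
    if fmt == "sam_bam":
        with pysam.AlignmentFile(str(path), check_sq=False) as handle:
            for rec in handle:
                if rec.is_secondary or rec.is_supplementary:
                    stats.n_skipped_secondary += 1
                    continue
                stats.n_records += 1
                if rec.is_unmapped:
                    stats.n_unmapped += 1
                    alignments.append(
                        Alignment(
                            read_id=rec.query_name,
                            transcript_id="",
                            ref_start=-1,
                            ref_end=-1,
                            read_len=rec.query_length,
                            mapped=False,
                            sample=sample,
                            seq=to_dna(rec.query_sequence or ""),
                        )
                    )
                    continue
                if model is not None and rec.reference_name not in model:
                    stats.n_skipped_unknown_ref += 1
                    continue
                stats.n_mapped += 1
                alignments.append(
                    Alignment(
                        read_id=rec.query_name,
                        transcript_id=rec.reference_name,
                        ref_start=rec.reference_start,
                        ref_end=rec.reference_end,
                        read_len=rec.query_length or rec.infer_read_length() or 0,
                        mapped=True,
                        sample=sample,
                    )
                )
    elif fmt == "truth_tsv":
        table = pd.read_csv(path, sep="\t")
        for row in table.itertuples(index=False):
            stats.n_records += 1
            mapped = bool(row.mapped) if not isinstance(row.mapped, str) else row.mapped == "True"
            if not mapped:
                stats.n_unmapped += 1
                alignments.append(
                    Alignment(
                        read_id=str(row.read_id),
                        transcript_id="",
                        ref_start=-1,
                        ref_end=-1,
                        read_len=int(row.read_len),
                        mapped=False,
                        sample=sample,
                    )
                )
                continue
            if model is not None and str(row.transcript_id) not in model:
                stats.n_skipped_unknown_ref += 1
                continue
            stats.n_mapped += 1
            alignments.append(
                Alignment(
                    read_id=str(row.read_id),
                    transcript_id=str(row.transcript_id),
                    ref_start=int(row.ref_start),
                    ref_end=int(row.ref_end),
                    read_len=int(row.read_len),
                    mapped=True,
                    sample=sample,
                )
            )
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")

    logger.info(
        "%s: %d records (%d mapped, %d unmapped, %d secondary/supplementary "
        "skipped, %d unknown reference)",
        path,
        stats.n_records,
        stats.n_mapped,
        stats.n_unmapped,
        stats.n_skipped_secondary,
        stats.n_skipped_unknown_ref,
    )
    return alignments, stats


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTQ file into ``(read_id, DNA sequence)`` tuples."""
    return [
        (rec.id, to_dna(str(rec.seq))) for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fasta(model: TranscriptomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tx in model:
            fh.write(f">{tx.id}\n{tx.seq}\n")


def write_annotation(model: TranscriptomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tcds_start\tcds_end\n")
        for tx in model:
            fh.write(f"{tx.id}\t{tx.cds_start}\t{tx.cds_end}\n")
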