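"""Readers/writers and run configuration shared by the pipeline stages.

Conventions
-----------
* All reference coordinates are 0-based, half-open. SAM input (1-based) is
  converted on read via pysam; 1-based numbers appear only in display output.
* Reference sequences are uppercased on read and restricted to {A,C,G,T,N}.
* Subsampling is reservoir-based so alignment streams need not be materialized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO

logger = logging.getLogger("ripseq")

_REFERENCE_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file (message carries the offending line when known)."""


class ConfigurationError(ValueError):
    """Inconsistent run configuration or inputs (e.g. missing reference)."""


@dataclass(frozen=True)
class ReferenceRecord:
    """A named nucleotide reference sequence (uppercase, A/C/G/T/N only)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"reference {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - _REFERENCE_ALPHABET
        if bad:
            raise FormatError(
                f"reference {self.id!r}: invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read; orientation records the strand it was emitted from."""

    id: str
    sequence: str
    qualities: Optional[Sequence[int]] = None
    orientation: str = "unknown"  # {"forward", "reverse", "unknown"}

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"read {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(f"read {self.id!r}: quality/sequence length mismatch")
        if self.orientation not in ("forward", "reverse", "unknown"):
            raise ValueError(f"read {self.id!r}: bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class AlignmentRecord:
    """One primary alignment against a single reference.

    ``aligned_pairs`` follows pysam's ``get_aligned_pairs``: a list of
    (read_pos | None, ref_pos | None) tuples, monotone in both coordinates;
    None marks a gap on that side. ``sequence`` is the read sequence as
    aligned (reference sense). ``edit_fraction`` is mismatches / aligned
    length when an NM tag was present, else NaN (recomputed downstream
    against the reference).
    """

    read_id: str
    reference_id: str
    reference_start: int
    aligned_pairs: tuple
    is_reverse: bool
    sequence: Optional[str] = None
    edit_fraction: Optional[float] = None


@dataclass
class RunConfig:
    """Thresholds and seed for a pipeline run; echoed to the log on use.

    min_reads_per_replicate: replicates with fewer retained reads at the
        target site are flagged and excluded from group tests (default 10).
    max_mismatch_fraction: per-read mismatch cap for alignment-mode read
        retention, target column exempt (default 0.02).
    subsample_reads: optional cap on reads considered per sample (uniform
        without replacement), for very deep rRNA libraries.
    lfc_min / fdr_max: differential-expression call thresholds.
    delta / epsilon: z-score separation / similarity thresholds for the
        expression-pattern classifiers.
    """

    seed: int = 0
    min_reads_per_replicate: int = 10
    max_mismatch_fraction: float = 0.02
    subsample_reads: Optional[int] = None
    lfc_min: float = 0.58
    fdr_max: float = 0.05
    delta: float = 0.5
    epsilon: float = 0.75
    prior_scale: float = 2.5
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if self.min_reads_per_replicate < 0 or self.max_mismatch_fraction < 0:
            raise ConfigurationError("thresholds must be non-negative")
        for name in ("lfc_min", "fdr_max", "delta", "epsilon", "prior_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.subsample_reads is not None and self.subsample_reads < 0:
            raise ConfigurationError("subsample_reads must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def log_echo(self) -> None:
        logger.info("run config: %s", asdict(self))


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ReferenceRecord]:
    """Read a FASTA file into ReferenceRecords (uppercased, validated).

    Raises FormatError naming the offending line for empty sequences or
    headerless content; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    records: list[ReferenceRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: content before any '>' header"
                    )
                break
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython signals structural problems
        raise FormatError(f"{path}: {exc}") from exc
    if not parsed:
        logger.warning("%s: empty FASTA file", path)
        return []
    for rec in parsed:
        if len(rec.seq) == 0:
            lineno = _find_header_line(path, rec.id)
            raise FormatError(f"{path}: line {lineno}: record {rec.id!r} has empty sequence")
        records.append(ReferenceRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def _find_header_line(path: Path, record_id: str) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[0:1] == [record_id]:
                return lineno
    return 0


def write_fasta(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read FASTQ into ReadRecords; orientation is 'unknown' (not encoded)."""
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        records.append(
            ReadRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return records


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = (
                "".join(chr(q + 33) for q in rec.qualities)
                if rec.qualities is not None
                else "I" * len(rec.sequence)
            )
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM / BAM
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path, reference_id: str) -> list[AlignmentRecord]:
    """Read primary mapped alignments to ``reference_id`` from SAM or BAM.

    Unmapped, secondary and supplementary records, and records mapped to
    other references, are skipped; the skip tally is logged.
    """
    path = Path(path)
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    records: list[AlignmentRecord] = []
    skipped = {"unmapped": 0, "secondary": 0, "other_reference": 0}
    with pysam.AlignmentFile(str(path), mode) as fh:
        if reference_id not in fh.references:
            raise ConfigurationError(
                f"{path}: reference {reference_id!r} not in header "
                f"(has {list(fh.references)})"
            )
        for aln in fh:
            if aln.is_unmapped:
                skipped["unmapped"] += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                skipped["secondary"] += 1
                continue
            if aln.reference_name != reference_id:
                skipped["other_reference"] += 1
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else None
            alen = aln.query_alignment_length or 0
            edit = nm / alen if (nm is not None and alen) else None
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    reference_id=aln.reference_name,
                    reference_start=aln.reference_start,
                    aligned_pairs=tuple(aln.get_aligned_pairs()),
                    is_reverse=aln.is_reverse,
                    sequence=aln.query_sequence,
                    edit_fraction=edit,
                )
            )
    logger.info("read_alignments(%s, %s): kept %d, skipped %s", path, reference_id,
                len(records), skipped)
    return records


# ---------------------------------------------------------------------------
# Subsampling
# ---------------------------------------------------------------------------

def subsample_reads(records: Iterable, n: int, seed: int) -> list:
    """Uniform sample of ``min(n, total)`` records without replacement.

    Single-pass reservoir sampling; the returned records keep their input
    order, and the selection is reproducible for a fixed seed.
    """
    if n < 0:
        raise ValueError(f"subsample size must be non-negative, got {n}")
    rng = np.random.default_rng(seed)
    reservoir: list[tuple[int, object]] = []
    for i, rec in enumerate(records):
        if len(reservoir) < n:
            reservoir.append((i, rec))
        else:
            j = rng.integers(0, i + 1)
            if j < n:
                reservoir[j] = (i, rec)
    reservoir.sort(key=lambda pair: pair[0])
    return [rec for _, rec in reservoir]


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    # default float formatting is shortest round-trip repr: bit-identical reload
    frame.to_csv(path, sep="\t", index=index)
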