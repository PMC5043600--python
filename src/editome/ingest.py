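"""Read-level ingest: trimming, cell QC, pileup construction, background rate.

Every transcriptome gets its own per-base background mismatch rate, the
null error probability for the downstream binomial test. Bases only count
toward a pileup column when their quality passes ``min_base_quality``.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .io import BASES, PILEUP_COLUMNS

logger = logging.getLogger(__name__)

STAGES = ("oocyte", "pronucleus", "zygote", "2cell", "4cell", "8cell", "morula")

#: read-end window sizes (bases), per the position-bias definition
END_3PRIME = 10
END_5PRIME = 5

DEFAULT_MIN_BASE_QUALITY = 20
DEFAULT_TRIM_3PRIME_SINGLE_END = 15
DEFAULT_MIN_UNIQUELY_MAPPED_BASES = 5e8


@dataclasses.dataclass(frozen=True)
class CellLibrary:
    """Identity and sequencing metadata of one single-cell library."""

    cell_id: str
    embryo_id: str
    stage: str
    layout: str = "single_end"
    uniquely_mapped_bases: int = 0

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.layout not in ("single_end", "paired_end"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if not self.embryo_id:
            raise ValueError("embryo_id must be non-empty (needed by the recurrence filter)")
        if self.uniquely_mapped_bases < 0:
            raise ValueError("uniquely_mapped_bases must be >= 0")


@dataclasses.dataclass(frozen=True)
class PileupColumn:
    """Per-site tally of quality-passing base calls for one cell.

    base_counts maps base -> (sense, antisense) counts on the alignment
    strand; end_counts holds (read_end, read_middle) counts for variant
    (non-reference) and reference bases.
    """

    chrom: str
    pos: int  # 1-based
    ref_base: str
    base_counts: dict[str, tuple[int, int]]
    end_counts: dict[str, tuple[int, int]]  # keys 'variant', 'reference'

    @property
    def depth(self) -> int:
        return sum(f + r for f, r in self.base_counts.values())

    def to_row(self) -> dict:
        row = {"chrom": self.chrom, "pos": self.pos, "ref": self.ref_base,
               "depth": self.depth}
        for b in BASES:
            f, r = self.base_counts.get(b, (0, 0))
            row[f"{b}_f"], row[f"{b}_r"] = f, r
        ve, vm = self.end_counts.get("variant", (0, 0))
        re_, rm = self.end_counts.get("reference", (0, 0))
        row.update(var_end=ve, var_mid=vm, ref_end=re_, ref_mid=rm)
        return row


@dataclasses.dataclass(frozen=True)
class BackgroundRate:
    """Per-transcriptome background mismatch probability."""

    cell_id: str
    p: float
    mismatch_bases: int
    aligned_bases: int


def trim_read(sequence: str, qualities: str | None, layout: str,
              trim_3prime: int = DEFAULT_TRIM_3PRIME_SINGLE_END):
    """Trim the 3' end of single-end reads; paired-end reads pass unchanged.

    Returns (sequence, qualities) or None when the read is dropped because
    nothing would remain after trimming.
    """
    if len(sequence) == 0:
        raise ValueError("empty read")
    if layout == "paired_end":
        return sequence, qualities
    if len(sequence) <= trim_3prime:
        logger.warning("dropping %d-base single-end read (<= trim length %d)",
                       len(sequence), trim_3prime)
        return None
    seq = sequence[:-trim_3prime]
    quals = qualities[:-trim_3prime] if qualities is not None else None
    return seq, quals


def qc_cell(library: CellLibrary,
            threshold: float = DEFAULT_MIN_UNIQUELY_MAPPED_BASES) -> bool:
    """Keep a cell only if it has more than ``threshold`` uniquely mapped bases."""
    return library.uniquely_mapped_bases > threshold


def _is_end_offset(offset_5p: int, offset_3p: int) -> bool:
    return offset_3p < END_3PRIME or offset_5p < END_5PRIME


def iter_pileup_columns(alignments: str | Path | pysam.AlignmentFile,
                        reference: str | Path | Fasta,
                        min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
                        ) -> Iterator[PileupColumn]:
    """Build pileup columns from coordinate-sorted SAM alignments.

    Skips unmapped, secondary, supplementary and duplicate-flagged records
    (duplicate marking is assumed done upstream). The strand of a base is
    the alignment strand of its read; read-end status is measured on the
    read as sequenced (after any trimming), each mate independently.
    """
    if not isinstance(reference, Fasta):
        reference = Fasta(str(reference))
    close = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), "r")
        close = True
    # tally[(chrom, pos)] = {'ref': base, 'counts': {base: [f, r]}, 'ends': {...}}
    tally: dict[tuple[str, int], dict] = {}
    try:
        for read in alignments:
            if (read.is_unmapped or read.is_secondary or
                    read.is_supplementary or read.is_duplicate):
                continue
            chrom = read.reference_name
            if chrom not in reference:
                raise KeyError(f"chromosome {chrom!r} absent from reference")
            seq = read.query_sequence
            quals = read.query_qualities
            rlen = read.query_length
            chrom_seq = reference[chrom]
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                base = seq[qpos].upper()
                if base not in BASES:
                    continue
                # qpos indexes the forward-genome-strand sequence; map back
                # to the as-sequenced read to measure end distances
                if read.is_reverse:
                    off5, off3 = rlen - 1 - qpos, qpos
                else:
                    off5, off3 = qpos, rlen - 1 - qpos
                pos1 = rpos + 1
                key = (chrom, pos1)
                col = tally.get(key)
                if col is None:
                    ref_base = chrom_seq[rpos:rpos + 1].seq.upper()
                    col = tally[key] = {
                        "ref": ref_base,
                        "counts": {b: [0, 0] for b in BASES},
                        "ends": {"variant": [0, 0], "reference": [0, 0]},
                    }
                strand_idx = 1 if read.is_reverse else 0
                col["counts"][base][strand_idx] += 1
                kind = "reference" if base == col["ref"] else "variant"
                end_idx = 0 if _is_end_offset(off5, off3) else 1
                col["ends"][kind][end_idx] += 1
    finally:
        if close:
            alignments.close()
    for (chrom, pos), col in sorted(tally.items()):
        if col["ref"] not in BASES:
            continue
        yield PileupColumn(
            chrom=chrom, pos=pos, ref_base=col["ref"],
            base_counts={b: tuple(v) for b, v in col["counts"].items()},
            end_counts={k: tuple(v) for k, v in col["ends"].items()},
        )


def build_pileup(alignments, reference,
                 min_base_quality: int = DEFAULT_MIN_BASE_QUALITY) -> pd.DataFrame:
    """Pileup columns as a DataFrame in the package's pileup dialect."""
    rows = [c.to_row() for c in
            iter_pileup_columns(alignments, reference, min_base_quality)]
    if not rows:
        return pd.DataFrame(columns=PILEUP_COLUMNS)
    return pd.DataFrame(rows)[PILEUP_COLUMNS]


def variant_depth(df: pd.DataFrame) -> pd.Series:
    """Non-reference base count per pileup row."""
    totals = {b: df[f"{b}_f"].to_numpy() + df[f"{b}_r"].to_numpy() for b in BASES}
    ref = df["ref"].to_numpy()
    k = np.zeros(len(df), dtype=np.int64)
    for b in BASES:
        k += np.where(ref == b, 0, totals[b])
    return pd.Series(k, index=df.index)


def estimate_background_rate(pileup: pd.DataFrame, cell_id: str,
                             total_aligned_bases: int | None = None,
                             exclude_high_freq: bool = False,
                             high_freq_threshold: float = 0.1) -> BackgroundRate:
    """Estimate the per-base mismatch probability of one transcriptome.

    p = non-reference quality-passing bases / aligned quality-passing bases,
    over all columns of the cell. For sparse pileups that only record
    mismatch-bearing columns, pass ``total_aligned_bases`` (the cell's
    quality-passing aligned base count) as the denominator.

    With ``exclude_high_freq``, columns whose mismatch frequency reaches
    ``high_freq_threshold`` are left out of the numerator (and, for full
    pileups, the denominator) — a two-pass refinement that keeps true
    variant sites from inflating the error-rate estimate.
    """
    if len(pileup) == 0 and total_aligned_bases is None:
        raise ValueError("no pileup columns and no total_aligned_bases")
    k = variant_depth(pileup).to_numpy() if len(pileup) else np.array([], dtype=int)
    n = pileup["depth"].to_numpy() if len(pileup) else np.array([], dtype=int)
    keep = np.ones(len(pileup), dtype=bool)
    if exclude_high_freq and len(pileup):
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n > 0, k / np.maximum(n, 1), 0.0)
        keep = freq < high_freq_threshold
    mismatch = int(k[keep].sum())
    if total_aligned_bases is not None:
        aligned = int(total_aligned_bases)
        if exclude_high_freq:
            aligned -= int(n[~keep].sum())
    else:
        aligned = int(n[keep].sum())
    if aligned <= 0:
        raise ValueError(f"cell {cell_id}: zero aligned bases")
    return BackgroundRate(cell_id=cell_id, p=mismatch / aligned,
                          mismatch_bases=mismatch, aligned_bases=aligned)
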