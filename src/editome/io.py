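"""Readers and writers for the flat-text formats the pipeline consumes.

Internal coordinates are 1-based, fully closed. BED inputs are 0-based,
half-open and converted on read; everything written by this package that is
not BED uses the internal convention.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd
from intervaltree import IntervalTree

#: column order of the pileup TSV dialect
PILEUP_COLUMNS = [
    "chrom", "pos", "ref", "depth",
    "A_f", "A_r", "C_f", "C_r", "G_f", "G_r", "T_f", "T_r",
    "var_end", "var_mid", "ref_end", "ref_mid",
]

BASES = ("A", "C", "G", "T")


def read_pileup(path: str | Path) -> pd.DataFrame:
    """Read a per-cell pileup table (one row per covered site).

    The dialect stores, per site: reference base, quality-passing depth,
    per-base counts split by alignment strand (``_f`` sense / ``_r``
    antisense of the reference) and read-end/middle counts for variant
    (non-reference) and reference bases.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pileup file {path} lacks columns {missing}")
    return df[PILEUP_COLUMNS]


def write_pileup(df: pd.DataFrame, path: str | Path) -> None:
    df[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Per-cell metadata: cell_id, embryo_id, stage, layout, uniquely_mapped_bases."""
    meta = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "embryo_id": str})
    required = {"cell_id", "embryo_id", "stage", "uniquely_mapped_bases"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks columns {sorted(missing)}")
    if "layout" not in meta.columns:
        meta["layout"] = "single_end"
    return meta


def read_bed_intervals(path: str | Path) -> dict[str, IntervalTree]:
    """Load a BED file into per-chromosome interval trees.

    BED is 0-based half-open; the trees are queried with 1-based positions,
    so each interval is stored as [start+1, end+1) which makes ``tree[pos]``
    a closed-interval containment test on 1-based coordinates.
    """
    trees: dict[str, IntervalTree] = {}
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"],
                      dtype={0: str})
    for chrom, grp in bed.groupby("chrom"):
        tree = IntervalTree()
        for s, e in zip(grp["start"], grp["end"]):
            if e > s:
                tree.addi(int(s) + 1, int(e) + 1)
        trees[str(chrom)] = tree
    return trees


def in_intervals(trees: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
    tree = trees.get(chrom)
    return bool(tree is not None and tree[pos])


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    """Write 1-based closed intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def read_site_list(path: str | Path) -> pd.DataFrame:
    """Read a site TSV with columns chrom, pos and optionally strand/ref/alt.

    Used for both the known-editing-site catalogue (chrom, pos[, strand])
    and SNP lists (chrom, pos[, ref, alt]).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos"} <= set(df.columns):
        raise ValueError(f"site list {path} needs chrom and pos columns")
    return df


@dataclasses.dataclass(frozen=True)
class Transcript:
    """A transcript from the gene-model input (1-based closed intervals)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    transcript_type: str  # 'protein_coding' or a non-coding label
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    def splice_positions(self) -> list[int]:
        """Internal exon-intron boundary positions (genomic, inclusive)."""
        if len(self.exons) < 2:
            return []
        exons = sorted(self.exons)
        pos: list[int] = []
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            pos.extend([e1, s2])
        return pos


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for field in attr.strip().strip(";").split(";"):
        field = field.strip()
        if not field:
            continue
        key, _, value = field.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gene_models(path: str | Path) -> list[Transcript]:
    """Read a GTF-like gene model file into Transcript records.

    Recognised feature rows: exon, CDS. transcript_type defaults to
    protein_coding when a transcript has CDS rows, ncRNA otherwise, unless
    the attribute column says so explicitly.
    """
    cols = ["chrom", "source", "feature", "start", "end",
            "score", "strand", "frame", "attributes"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=cols,
                     dtype={"chrom": str})
    records: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        if row.feature not in ("exon", "CDS"):
            continue
        attrs = _parse_gtf_attributes(row.attributes)
        tid = attrs.get("transcript_id")
        if tid is None:
            raise ValueError(f"gene-model row without transcript_id: {row}")
        rec = records.setdefault(tid, {
            "gene_id": attrs.get("gene_id", tid),
            "chrom": row.chrom, "strand": row.strand,
            "transcript_type": attrs.get("transcript_type"),
            "exons": [], "cds": [],
        })
        if rec["chrom"] != row.chrom or rec["strand"] != row.strand:
            raise ValueError(f"inconsistent rows for transcript {tid}")
        key = "exons" if row.feature == "exon" else "cds"
        rec[key].append((int(row.start), int(row.end)))
    out = []
    for tid, rec in records.items():
        if not rec["exons"]:
            raise ValueError(f"transcript {tid} has no exon rows")
        ttype = rec["transcript_type"]
        if ttype is None:
            ttype = "protein_coding" if rec["cds"] else "ncRNA"
        out.append(Transcript(
            transcript_id=tid, gene_id=rec["gene_id"], chrom=rec["chrom"],
            strand=rec["strand"], transcript_type=ttype,
            exons=tuple(sorted(rec["exons"])), cds=tuple(sorted(rec["cds"])),
        ))
    return out


def write_gene_models(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                     f'transcript_type "{t.transcript_type}";')
            for s, e in t.exons:
                fh.write(f"{t.chrom}\tsim\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n")
            for s, e in t.cds:
                fh.write(f"{t.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n")
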