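"""Editome annotation: mismatch spectrum, Alu/non-Alu classing, the A-to-I
retention rule, genic features, coding effects, neighbor-base preferences,
and miRNA-target overlap.

Because inosine pairs like guanosine, true A-to-I events appear as A-to-G
mismatches on the transcribed strand. With non-strand-specific libraries a
genomic T-to-C mismatch over a minus-strand gene is the same event seen
from the other strand; the default mode records such sites in transcript
sense, a strict mode drops all T-to-C.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .io import BASES, Transcript, in_intervals

FEATURES = ("CDS", "5UTR", "3UTR", "ncRNA", "intronic", "intergenic")
#: annotation precedence when a site overlaps several transcripts
FEATURE_PRECEDENCE = {f: i for i, f in enumerate(FEATURES)}

MISMATCH_TYPES = tuple(f"{a}-to-{b}" for a in BASES for b in BASES if a != b)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclasses.dataclass(frozen=True)
class EditingSite:
    """A retained A-to-I editing site with its annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    region_class: str  # 'Alu' or 'non-Alu'
    in_catalogue: bool
    feature: str
    coding_effect: str = "not_applicable"
    mirna_target: bool = False
    gene_id: str | None = None
    strand_of_gene: str = "none"


def classify_mismatch(chrom: str, pos: int, ref: str, alt: str,
                      alu: dict[str, IntervalTree],
                      catalogue: set) -> tuple[str, str, bool]:
    """(region_class, mismatch_type, in_catalogue) for one mismatch site.

    region_class is by Alu-interval overlap (closed 1-based intervals
    after BED conversion); mismatch_type is ref->alt on the reference
    strand; catalogue membership is positional, or position+strand-sense
    when the catalogue entries carry strand (an entry on '-' matches a
    genomic T-to-C, on '+' an A-to-G).
    """
    region = "Alu" if in_intervals(alu, chrom, pos) else "non-Alu"
    mtype = f"{ref}-to-{alt}"
    in_cat = ((chrom, pos) in catalogue or (chrom, pos, "+") in catalogue
              or (chrom, pos, "-") in catalogue)
    return region, mtype, in_cat


def catalogue_from_frame(df: pd.DataFrame) -> set:
    """Known-editing-site catalogue as a membership set.

    Entries with a strand column are stored as (chrom, pos, strand),
    otherwise (chrom, pos).
    """
    cat: set = set()
    has_strand = "strand" in df.columns
    for row in df.itertuples(index=False):
        if has_strand and isinstance(row.strand, str) and row.strand in "+-":
            cat.add((str(row.chrom), int(row.pos), row.strand))
        else:
            cat.add((str(row.chrom), int(row.pos)))
    return cat


def retain_a2i(region_class: str, ref: str, alt: str, in_catalogue: bool,
               gene_strand: str = "none",
               t2c_mode: str = "transcript_sense") -> bool:
    """The A-to-I retention rule.

    Alu A-to-G mismatches are retained outright; non-Alu A-to-G only when
    present in the known-site catalogue. In the default
    ``transcript_sense`` mode a genomic T-to-C is treated as A-to-G seen
    from the antisense strand when an overlapping gene lies on '-',
    subject to the same Alu/catalogue rule; ``strict`` drops all T-to-C.
    Everything else stays in the mismatch spectrum but out of the editome.
    """
    if t2c_mode not in ("transcript_sense", "strict"):
        raise ValueError(f"unknown t2c_mode {t2c_mode!r}")
    a2g = ref == "A" and alt == "G"
    if not a2g and t2c_mode == "transcript_sense":
        a2g = ref == "T" and alt == "C" and gene_strand == "-"
    if not a2g:
        return False
    return region_class == "Alu" or in_catalogue


def mismatch_spectrum(candidates: pd.DataFrame) -> pd.DataFrame:
    """Per-cell counts and fractions of the 12 substitution types."""
    rows = []
    for cell_id, grp in candidates.groupby("cell_id"):
        counts = Counter(f"{r}-to-{a}" for r, a in zip(grp["ref"], grp["alt"]))
        total = sum(counts.values())
        for mtype in MISMATCH_TYPES:
            c = counts.get(mtype, 0)
            rows.append({"cell_id": cell_id, "mismatch_type": mtype,
                         "count": c, "fraction": c / total if total else 0.0})
    return pd.DataFrame(rows)


def neighbor_preference(sites: pd.DataFrame,
                        reference_fetch: Callable[[str, int, int], str],
                        contig_lengths: dict[str, int]) -> dict[str, float]:
    """G fraction at the -1 and +1 neighbors of edited adenosines.

    A-to-G sites are read on the reference strand; T-to-C sites on its
    reverse complement (so their genomic +1 neighbor, complemented, is
    the editing-strand -1 neighbor). Sites at contig edges are skipped.
    Returns g_minus1, g_plus1, c_minus1, c_plus1 fractions and n_sites.
    """
    minus, plus = [], []
    for row in sites.itertuples(index=False):
        chrom, pos = str(row.chrom), int(row.pos)
        L = contig_lengths.get(chrom)
        if L is None or pos <= 1 or pos >= L:
            continue
        trio = reference_fetch(chrom, pos - 1, pos + 1).upper()
        if row.ref == "A":
            minus.append(trio[0])
            plus.append(trio[2])
        elif row.ref == "T":  # editing strand is the reverse complement
            minus.append(trio[2].translate(_COMPLEMENT))
            plus.append(trio[0].translate(_COMPLEMENT))
    if not minus:
        raise ValueError("no usable sites (all at contig edges?)")
    n = len(minus)
    return {
        "g_minus1": minus.count("G") / n, "g_plus1": plus.count("G") / n,
        "c_minus1": minus.count("C") / n, "c_plus1": plus.count("C") / n,
        "n_sites": n,
    }


def _feature_in_transcript(t: Transcript, pos: int) -> str | None:
    if not (t.start <= pos <= t.end):
        return None
    in_exon = any(s <= pos <= e for s, e in t.exons)
    if not in_exon:
        return "intronic"
    if not t.cds or t.transcript_type != "protein_coding":
        return "ncRNA"
    if any(s <= pos <= e for s, e in t.cds):
        return "CDS"
    cds_start = min(s for s, _ in t.cds)
    cds_end = max(e for _, e in t.cds)
    if pos < cds_start:
        return "5UTR" if t.strand == "+" else "3UTR"
    if pos > cds_end:
        return "3UTR" if t.strand == "+" else "5UTR"
    return "intronic"  # exonic gap inside the CDS span should not occur


def assign_feature(chrom: str, pos: int,
                   transcripts: Sequence[Transcript]) -> tuple[str, str | None, str]:
    """(feature, gene_id, gene_strand) with precedence
    CDS > 5UTR > 3UTR > ncRNA > intronic > intergenic across all
    overlapping transcripts."""
    best = ("intergenic", None, "none")
    best_rank = FEATURE_PRECEDENCE["intergenic"]
    for t in transcripts:
        if t.chrom != chrom:
            continue
        f = _feature_in_transcript(t, pos)
        if f is None:
            continue
        rank = FEATURE_PRECEDENCE[f]
        if rank < best_rank:
            best = (f, t.gene_id, t.strand)
            best_rank = rank
    return best


def gene_strand_at(chrom: str, pos: int,
                   transcripts: Sequence[Transcript]) -> str:
    """Strand of a gene overlapping the position ('none' if intergenic)."""
    for t in transcripts:
        if t.chrom == chrom and t.start <= pos <= t.end:
            return t.strand
    return "none"


def coding_effect(chrom: str, pos: int, ref: str, alt: str,
                  transcript: Transcript,
                  reference_fetch: Callable[[str, int, int], str]
                  ) -> tuple[str, str]:
    """(effect, amino-acid change) of an edit inside a CDS.

    The codon is built in transcript orientation: a genomic A-to-G on a
    '+' gene and a genomic T-to-C on a '-' gene both read as A-to-G on
    the transcript. Effect is 'synonymous' or 'nonsynonymous'.
    """
    cds = sorted(transcript.cds)
    if not any(s <= pos <= e for s, e in cds):
        raise ValueError(f"position {chrom}:{pos} is not in the CDS of "
                         f"{transcript.transcript_id}")
    cds_len = sum(e - s + 1 for s, e in cds)
    if cds_len % 3 != 0:
        raise ValueError(f"CDS of {transcript.transcript_id} has length "
                         f"{cds_len}, not divisible by 3")
    genomic = "".join(reference_fetch(chrom, s, e).upper() for s, e in cds)
    offset = 0  # 0-based position within the genomic-order CDS sequence
    for s, e in cds:
        if s <= pos <= e:
            offset += pos - s
            break
        offset += e - s + 1
    edited = genomic[:offset] + alt + genomic[offset + 1:]
    if transcript.strand == "-":
        genomic = str(Seq(genomic).reverse_complement())
        edited = str(Seq(edited).reverse_complement())
        offset = cds_len - 1 - offset
    codon_i = offset // 3
    ref_codon = genomic[codon_i * 3: codon_i * 3 + 3]
    alt_codon = edited[codon_i * 3: codon_i * 3 + 3]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
    return effect, f"{aa_ref}{codon_i + 1}{aa_alt}"


def mirna_target_overlap(chrom: str, pos: int, feature: str,
                         target_intervals: dict[str, IntervalTree]) -> bool:
    """True iff the site lies in a miRNA seed-match interval inside a 3'UTR."""
    return feature == "3UTR" and in_intervals(target_intervals, chrom, pos)


def splice_positions_from_models(transcripts: Iterable[Transcript]
                                 ) -> dict[str, np.ndarray]:
    """Per-chromosome sorted arrays of exon-intron boundary positions."""
    acc: dict[str, set[int]] = {}
    for t in transcripts:
        acc.setdefault(t.chrom, set()).update(t.splice_positions())
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in acc.items()}


def annotate_candidates(filtered: pd.DataFrame,
                        alu: dict[str, IntervalTree],
                        catalogue: set,
                        transcripts: Sequence[Transcript],
                        mirna_targets: dict[str, IntervalTree],
                        reference_fetch: Callable[[str, int, int], str],
                        t2c_mode: str = "transcript_sense") -> pd.DataFrame:
    """Annotate filter-retained candidates and apply the A-to-I retention
    rule. Adds region_class, in_catalogue, feature, gene_id, gene_strand,
    coding_effect, mirna_target and ``retained`` columns."""
    df = filtered.copy()
    if len(df) == 0:
        for c in ("region_class", "in_catalogue", "feature", "gene_id",
                  "gene_strand", "coding_effect", "mirna_target", "retained"):
            df[c] = pd.Series(dtype=object)
        return df
    regions, in_cats, feats, genes, strands = [], [], [], [], []
    effects, targets, retained = [], [], []
    ann_cache: dict[tuple[str, int, str, str], tuple] = {}
    for row in df.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), row.ref, row.alt)
        if key not in ann_cache:
            chrom, pos, ref, alt = key
            region, _, in_cat = classify_mismatch(chrom, pos, ref, alt,
                                                  alu, catalogue)
            feature, gene_id, gstrand = assign_feature(chrom, pos, transcripts)
            if gstrand == "none":
                gstrand = gene_strand_at(chrom, pos, transcripts)
            keep = retain_a2i(region, ref, alt, in_cat, gstrand, t2c_mode)
            effect = "not_applicable"
            if keep and feature == "CDS":
                for t in transcripts:
                    if (t.chrom == chrom and t.cds and t.gene_id == gene_id
                            and any(s <= pos <= e for s, e in t.cds)):
                        effect, _ = coding_effect(chrom, pos, ref, alt, t,
                                                  reference_fetch)
                        break
            mirna = mirna_target_overlap(chrom, pos, feature, mirna_targets)
            ann_cache[key] = (region, in_cat, feature, gene_id, gstrand,
                              keep, effect, mirna)
        region, in_cat, feature, gene_id, gstrand, keep, effect, mirna = \
            ann_cache[key]
        regions.append(region)
        in_cats.append(in_cat)
        feats.append(feature)
        genes.append(gene_id)
        strands.append(gstrand)
        effects.append(effect)
        targets.append(mirna)
        retained.append(keep)
    df["region_class"] = regions
    df["in_catalogue"] = in_cats
    df["feature"] = feats
    df["gene_id"] = genes
    df["gene_strand"] = strands
    df["coding_effect"] = effects
    df["mirna_target"] = targets
    df["retained"] = np.asarray(retained) & df["retained_by_filters"].to_numpy()
    return df
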