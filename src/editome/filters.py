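"""The artifact-filter cascade applied to detected variant candidates.

Each filter is a pure predicate on a candidate plus its annotations, so
the retained set does not depend on the order the filters run in. A
verdict records pass/fail/not_applied together with the statistics that
explain a failure.

Filters: strand bias, read-position bias, realignment support, region
masks (simple repeats, homopolymer runs, splice-site proximity for
non-Alu sites), known-SNP membership, single-embryo recurrence, and the
0.95 mismatch-frequency cap.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from Bio import Align
from intervaltree import IntervalTree

from .io import in_intervals

DEFAULT_STRAND_FET_ALPHA = 0.005
DEFAULT_POSITION_FET_ALPHA = 0.05
DEFAULT_REALIGN_FRACTION = 0.9
DEFAULT_HOMOPOLYMER_RUN = 5
DEFAULT_SPLICE_WINDOW = 5
DEFAULT_FREQ_CAP = 0.95

PASS, FAIL, NOT_APPLIED = "pass", "fail", "not_applied"


@dataclasses.dataclass(frozen=True)
class FilterVerdict:
    filter_name: str
    decision: str
    statistics: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.decision == FAIL and not self.statistics:
            raise ValueError("a fail verdict must record at least one statistic")


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher's exact P for a 2x2 count table.

    Sums hypergeometric probabilities no larger than the observed table's,
    at fixed margins. A zero margin admits a single table and returns 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def strand_bias_filter(variant_sense: int, variant_antisense: int,
                       reference_sense: int, reference_antisense: int,
                       fet_alpha: float = DEFAULT_STRAND_FET_ALPHA) -> FilterVerdict:
    """Flag variants whose support is skewed to one alignment strand.

    Fails when the strand table is significant (FET P < alpha) and the
    variant's strand preference |v - 0.5| exceeds the reference's, or when
    the variant strand frequency v leaves (0.1, 0.9).
    """
    k = variant_sense + variant_antisense
    if k == 0:
        raise ValueError("no variant-supporting reads to assess")
    v = variant_sense / k
    nref = reference_sense + reference_antisense
    r = reference_sense / nref if nref else 0.5
    p = fisher_exact_2x2([[variant_sense, reference_sense],
                          [variant_antisense, reference_antisense]])
    biased = (p < fet_alpha and abs(v - 0.5) > abs(r - 0.5)) or v > 0.9 or v < 0.1
    return FilterVerdict("strand_bias", FAIL if biased else PASS,
                         {"fet_p": p, "variant_strand_freq": v,
                          "reference_strand_freq": r})


def position_bias_filter(variant_end: int, variant_middle: int,
                         reference_end: int, reference_middle: int,
                         fet_alpha: float = DEFAULT_POSITION_FET_ALPHA) -> FilterVerdict:
    """Flag variants whose support concentrates in read ends.

    Read end = 10 bases at the 3' end or 5 bases at the 5' end. Fails when
    the end/middle table is significant (FET P < alpha) and the variant's
    read-end frequency exceeds its read-middle frequency, or when the
    read-end frequency exceeds 0.9.
    """
    k = variant_end + variant_middle
    if k == 0:
        raise ValueError("no variant-supporting bases to assess")
    e = variant_end / k
    p = fisher_exact_2x2([[variant_end, reference_end],
                          [variant_middle, reference_middle]])
    biased = (p < fet_alpha and e > 1 - e) or e > 0.9
    return FilterVerdict("position_bias", FAIL if biased else PASS,
                         {"fet_p": p, "read_end_freq": e})


class PairwiseRealigner:
    """Default realignment backend: local alignment against every
    reference sequence (genome contigs + transcript sequences).

    Scoring: match +1, mismatch -3, gap open -5, gap extend -2. A read
    supports the site when a best-scoring placement lies on the site's
    chromosome and its reference span covers the site (with
    ``count_ties``, any tied best placement covering the site counts).
    """

    def __init__(self, references: dict[str, str], count_ties: bool = True):
        if not references or all(len(s) == 0 for s in references.values()):
            raise ValueError("empty combined reference")
        self.references = references
        self.count_ties = count_ties
        self._aligner = Align.PairwiseAligner(
            mode="local", match_score=1, mismatch_score=-3,
            open_gap_score=-5, extend_gap_score=-2)

    def best_placements(self, read: str) -> list[tuple[str, int, int, float]]:
        """(name, start_1based, end_1based, score) of the best-scoring placements."""
        results = []
        best = -np.inf
        for name, seq in self.references.items():
            if not seq:
                continue
            score = self._aligner.score(seq, read)
            results.append((name, score))
            best = max(best, score)
        placements = []
        for name, score in results:
            if score < best:
                continue
            alns = self._aligner.align(self.references[name], read)
            take = len(alns) if self.count_ties else 1
            for aln in list(alns)[:min(take, 8)]:
                start = int(aln.aligned[0][0][0])
                end = int(aln.aligned[0][-1][1])
                placements.append((name, start + 1, end, float(aln.score)))
                if not self.count_ties:
                    break
        return placements


def realignment_filter(chrom: str, pos: int, variant_reads: Sequence[str],
                       realigner: PairwiseRealigner,
                       min_support_frac: float = DEFAULT_REALIGN_FRACTION
                       ) -> FilterVerdict:
    """Require >= 90% of variant-supporting reads to realign over the site
    when mapped against the combined genome + transcript reference."""
    if not variant_reads:
        return FilterVerdict("realignment", NOT_APPLIED)
    supporting = 0
    for read in variant_reads:
        placements = realigner.best_placements(read)
        if any(name == chrom and start <= pos <= end
               for name, start, end, _ in placements):
            supporting += 1
    frac = supporting / len(variant_reads)
    ok = frac >= min_support_frac
    return FilterVerdict("realignment", PASS if ok else FAIL,
                         {"realigned_frac": frac})


def homopolymer_run_at(sequence: str, pos0: int) -> int:
    """Longest same-base run that includes or is adjacent to position pos0
    (0-based within ``sequence``)."""
    n = len(sequence)
    best = 0
    for anchor in (pos0 - 1, pos0, pos0 + 1):
        if not 0 <= anchor < n:
            continue
        base = sequence[anchor]
        i = anchor
        while i > 0 and sequence[i - 1] == base:
            i -= 1
        j = anchor
        while j + 1 < n and sequence[j + 1] == base:
            j += 1
        best = max(best, j - i + 1)
    return best


def region_mask_filter(chrom: str, pos: int, is_alu: bool,
                       reference_window: str, window_offset: int,
                       simple_repeats: dict[str, IntervalTree],
                       splice_positions: dict[str, np.ndarray],
                       homopolymer_min_run: int = DEFAULT_HOMOPOLYMER_RUN,
                       splice_window: int = DEFAULT_SPLICE_WINDOW) -> FilterVerdict:
    """Mask simple repeats, homopolymer runs (>= 5 bases, measured on the
    reference strand), and — for non-Alu sites only — positions within 5
    bases of an annotated splice site.

    ``reference_window`` is reference sequence containing the site;
    ``window_offset`` is the 1-based genomic position of its first base.
    """
    stats_: dict[str, float] = {}
    if in_intervals(simple_repeats, chrom, pos):
        return FilterVerdict("region_mask", FAIL, {"simple_repeat": 1.0})
    run = homopolymer_run_at(reference_window, pos - window_offset)
    stats_["homopolymer_run"] = run
    if run >= homopolymer_min_run:
        return FilterVerdict("region_mask", FAIL, stats_)
    if not is_alu:
        sp = splice_positions.get(chrom)
        if sp is not None and len(sp):
            d = int(np.min(np.abs(sp - pos)))
            stats_["splice_distance"] = d
            if d <= splice_window:
                return FilterVerdict("region_mask", FAIL, stats_)
    return FilterVerdict("region_mask", PASS, stats_)


def known_snp_filter(chrom: str, pos: int, alt: str | None,
                     snp_catalogues: Iterable[dict]) -> FilterVerdict:
    """Remove sites present in any provided DNA-SNP catalogue.

    Each catalogue maps (chrom, pos) -> set of alt alleles (empty set =
    positional entry). Matching is alt-aware when both the candidate and
    the entry carry an alt allele.
    """
    for cat in snp_catalogues:
        alts = cat.get((chrom, pos))
        if alts is None:
            continue
        if not alts or alt is None or alt in alts:
            return FilterVerdict("known_snp", FAIL, {"in_snp_catalogue": 1.0})
    return FilterVerdict("known_snp", PASS)


def recurrence_filter(embryos_detected: set[str]) -> FilterVerdict:
    """Remove variants detected in cells of exactly one embryo; true
    editing recurs across individuals, rare SNPs do not."""
    if not embryos_detected:
        raise ValueError("site has no embryo detections; metadata missing?")
    n = len(embryos_detected)
    return FilterVerdict("recurrence", PASS if n >= 2 else FAIL,
                         {"n_embryos": float(n)})


def frequency_cap_filter(freq: float,
                         cap: float = DEFAULT_FREQ_CAP) -> FilterVerdict:
    """Remove candidates with mismatch frequency above 0.95 (likely
    homozygous genomic variants)."""
    ok = freq <= cap
    return FilterVerdict("frequency_cap", PASS if ok else FAIL,
                         {"freq": freq})


def snp_catalogue_from_frame(df: pd.DataFrame) -> dict:
    """Build a (chrom, pos) -> {alt, ...} lookup from a site-list frame."""
    cat: dict[tuple[str, int], set] = {}
    has_alt = "alt" in df.columns
    for row in df.itertuples(index=False):
        key = (str(row.chrom), int(row.pos))
        entry = cat.setdefault(key, set())
        if has_alt and isinstance(row.alt, str):
            entry.add(row.alt)
    return cat


def apply_filters(candidates: pd.DataFrame,
                  alu: dict[str, IntervalTree],
                  simple_repeats: dict[str, IntervalTree],
                  splice_positions: dict[str, np.ndarray],
                  snp_catalogues: Sequence[dict],
                  reference_fetch: Callable[[str, int, int], str],
                  strand_fet_alpha: float = DEFAULT_STRAND_FET_ALPHA,
                  position_fet_alpha: float = DEFAULT_POSITION_FET_ALPHA,
                  homopolymer_min_run: int = DEFAULT_HOMOPOLYMER_RUN,
                  splice_window: int = DEFAULT_SPLICE_WINDOW,
                  freq_cap: float = DEFAULT_FREQ_CAP,
                  realigner: PairwiseRealigner | None = None,
                  variant_reads: dict | None = None,
                  realign_fraction: float = DEFAULT_REALIGN_FRACTION
                  ) -> pd.DataFrame:
    """Compute every filter verdict for each detected candidate.

    ``candidates`` is the detect-module output restricted to detected
    rows, for the whole cohort (recurrence needs all cells). Adds one
    column per filter with 'pass'/'fail'/'not_applied' plus key statistics,
    and ``retained_by_filters`` = all applied filters pass.

    ``reference_fetch(chrom, start, end)`` returns 1-based closed
    reference sequence. ``variant_reads`` optionally maps
    (cell_id, chrom, pos) -> list of variant-supporting read sequences for
    the realignment filter; without it (pileup-only input) that filter is
    recorded as not_applied.
    """
    df = candidates.copy()
    n_rows = len(df)
    if n_rows == 0:
        for name in ("strand_bias", "position_bias", "realignment",
                     "region_mask", "known_snp", "recurrence", "frequency_cap"):
            df[name] = pd.Series(dtype=object)
        df["retained_by_filters"] = pd.Series(dtype=bool)
        return df

    # recurrence: embryos with a detection per site, over the whole cohort
    site_embryos = (df.groupby(["chrom", "pos", "alt"])["embryo_id"]
                    .agg(lambda s: frozenset(s)))

    # cache FET results; many candidates share small tables
    fet_cache: dict[tuple, float] = {}

    def cached_fet(a, b, c, d):
        key = (a, b, c, d)
        if key not in fet_cache:
            fet_cache[key] = fisher_exact_2x2([[a, b], [c, d]])
        return fet_cache[key]

    strand_v, position_v, realign_v = [], [], []
    region_v, snp_v, recur_v, cap_v = [], [], [], []
    is_alu_col = []
    win = max(homopolymer_min_run + 2, 8)
    for row in df.itertuples(index=False):
        chrom, pos = str(row.chrom), int(row.pos)
        # strand bias
        p = cached_fet(row.alt_f, row.ref_f, row.alt_r, row.ref_r)
        k = row.alt_f + row.alt_r
        v = row.alt_f / k if k else 0.0
        nref = row.ref_f + row.ref_r
        r = row.ref_f / nref if nref else 0.5
        sb = (p < strand_fet_alpha and abs(v - 0.5) > abs(r - 0.5)) \
            or v > 0.9 or v < 0.1
        strand_v.append(FAIL if sb else PASS)
        # position bias
        kv = row.var_end + row.var_mid
        e = row.var_end / kv if kv else 0.0
        p = cached_fet(row.var_end, row.ref_end, row.var_mid, row.ref_mid)
        pb = (p < position_fet_alpha and e > 1 - e) or e > 0.9
        position_v.append(FAIL if pb else PASS)
        # realignment
        reads = None if variant_reads is None else \
            variant_reads.get((row.cell_id, chrom, pos))
        if realigner is None or reads is None:
            realign_v.append(NOT_APPLIED)
        else:
            realign_v.append(realignment_filter(
                chrom, pos, reads, realigner, realign_fraction).decision)
        # region masks
        is_alu = in_intervals(alu, chrom, pos)
        is_alu_col.append(is_alu)
        seq = reference_fetch(chrom, max(1, pos - win), pos + win)
        offset = max(1, pos - win)
        region_v.append(region_mask_filter(
            chrom, pos, is_alu, seq, offset, simple_repeats, splice_positions,
            homopolymer_min_run, splice_window).decision)
        # known SNPs
        snp_v.append(known_snp_filter(chrom, pos, row.alt, snp_catalogues).decision)
        # recurrence
        embryos = site_embryos.loc[(chrom, int(row.pos), row.alt)]
        recur_v.append(PASS if len(embryos) >= 2 else FAIL)
        # frequency cap
        cap_v.append(PASS if row.freq <= freq_cap else FAIL)

    df["is_alu"] = is_alu_col
    df["strand_bias"] = strand_v
    df["position_bias"] = position_v
    df["realignment"] = realign_v
    df["region_mask"] = region_v
    df["known_snp"] = snp_v
    df["recurrence"] = recur_v
    df["frequency_cap"] = cap_v
    verdict_cols = ["strand_bias", "position_bias", "realignment",
                    "region_mask", "known_snp", "recurrence", "frequency_cap"]
    df["retained_by_filters"] = np.logical_and.reduce(
        [(df[c] != FAIL).to_numpy() for c in verdict_cols])
    return df
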