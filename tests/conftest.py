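"""Shared fixtures: a hand-built 12-site filter-cascade cohort and
module-scoped simulated cohorts."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from intervaltree import IntervalTree

from editome import annotate as ann
from editome import filters as flt
from editome import pipeline as pl
from editome.io import PILEUP_COLUMNS, Transcript
from editome.simulate import SimulationConfig, simulate


def trees_from(intervals: list[tuple[int, int]], chrom: str
               ) -> dict[str, IntervalTree]:
    t = IntervalTree()
    for s, e in intervals:
        t.addi(s, e + 1)
    return {chrom: t}


def pileup_row(pos, ref, alt, n, k, *, alt_f=None, var_end=None,
               chrom="chrF"):
    """One pileup column with given variant counts; strand and end splits
    default to balanced (half sense) and ~1/6 read-end."""
    if alt_f is None:
        alt_f = k // 2
    if var_end is None:
        var_end = k // 6
    ref_n = n - k
    ref_f = ref_n // 2
    ref_end = ref_n // 6
    row = {"chrom": chrom, "pos": pos, "ref": ref, "depth": n}
    for b in "ACGT":
        row[f"{b}_f"] = row[f"{b}_r"] = 0
    row[f"{ref}_f"], row[f"{ref}_r"] = ref_f, ref_n - ref_f
    row[f"{alt}_f"], row[f"{alt}_r"] = alt_f, k - alt_f
    row.update(var_end=var_end, var_mid=k - var_end,
               ref_end=ref_end, ref_mid=ref_n - ref_end)
    return row


@dataclasses.dataclass
class CascadeFixture:
    """Twelve hand-placed sites, each designed to trip one specific rule."""

    chrom: str
    sequence: str
    pileups: dict[str, pd.DataFrame]
    meta: pd.DataFrame
    alu: dict[str, IntervalTree]
    simple_repeats: dict[str, IntervalTree]
    transcripts: list[Transcript]
    catalogue: set
    snp_catalogues: list[dict]
    mirna_targets: dict[str, IntervalTree]
    expected: dict[int, str]  # pos -> expected failure attribution

    def fetch(self, chrom, start, end):
        return self.sequence[start - 1:end]

    def run(self, **param_overrides) -> pl.PipelineResult:
        params = pl.PipelineParams(**param_overrides)
        return pl.run_from_tables(
            self.pileups, self.meta, self.fetch,
            {self.chrom: len(self.sequence)}, self.alu, self.simple_repeats,
            self.transcripts, self.catalogue, self.snp_catalogues,
            self.mirna_targets, params=params)


@pytest.fixture(scope="session")
def cascade() -> CascadeFixture:
    chrom = "chrF"
    L = 3000
    rng = np.random.default_rng(42)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, L))

    def set_window(pos, ref, minus1="T", plus1="G", minus2="C", plus2="T"):
        i = pos - 1
        seq[i - 2], seq[i - 1], seq[i] = minus2, minus1, ref
        seq[i + 1], seq[i + 2] = plus1, plus2

    # annotations
    alu_iv = [(1001, 1400)]
    reps_iv = [(2501, 2560)]
    tx = Transcript("txF", "geneF", chrom, "+", "protein_coding",
                    exons=((1501, 1700), (1901, 2300)),
                    cds=((1951, 2250),))
    # splice boundaries at 1700 and 1901

    # the twelve sites
    S_PASS, S_DEPTH, S_FREQ, S_STRAND, S_END = 1050, 1060, 1070, 1080, 1090
    S_SNP, S_ONEEMB, S_CAP, S_CT = 1200, 1250, 1300, 1350
    S_HOMO, S_SPLICE, S_NOCAT = 1803, 1903, 2600
    for p in (S_PASS, S_DEPTH, S_FREQ, S_STRAND, S_END, S_SNP, S_ONEEMB,
              S_CAP, S_SPLICE, S_NOCAT):
        set_window(p, "A")
    set_window(S_CT, "C")
    seq[S_HOMO - 3:S_HOMO + 3] = list("AAAAAA")  # run of 6 containing S_HOMO
    sequence = "".join(seq)

    shared = [
        pileup_row(S_PASS, "A", "G", 20, 8),
        pileup_row(S_DEPTH, "A", "G", 3, 3),
        pileup_row(S_FREQ, "A", "G", 100, 9),
        pileup_row(S_STRAND, "A", "G", 20, 8, alt_f=8),
        pileup_row(S_END, "A", "G", 20, 8, var_end=8),
        pileup_row(S_HOMO, "A", "G", 20, 8),
        pileup_row(S_SPLICE, "A", "G", 20, 8),
        pileup_row(S_SNP, "A", "G", 20, 8),
        pileup_row(S_CAP, "A", "G", 100, 96),
        pileup_row(S_NOCAT, "A", "G", 20, 8),
        pileup_row(S_CT, "C", "T", 20, 8),
    ]
    one_embryo = pileup_row(S_ONEEMB, "A", "G", 20, 8)
    pileups, meta_rows = {}, []
    for cell, embryo in [("c1", "E1"), ("c2", "E1"), ("c3", "E2"), ("c4", "E2")]:
        rows = list(shared) + ([one_embryo] if embryo == "E1" else [])
        pileups[cell] = pd.DataFrame(rows)[PILEUP_COLUMNS]
        meta_rows.append({"cell_id": cell, "embryo_id": embryo,
                          "stage": "4cell", "layout": "single_end",
                          "uniquely_mapped_bases": 1_000_000})

    catalogue = {(chrom, S_SPLICE), (chrom, S_HOMO)}
    snp_cat = {(chrom, S_SNP): {"G"}}
    expected = {
        S_PASS: "retained",
        S_DEPTH: "detection", S_FREQ: "detection",
        S_STRAND: "strand_bias", S_END: "position_bias",
        S_HOMO: "region_mask", S_SPLICE: "region_mask",
        S_SNP: "known_snp", S_ONEEMB: "recurrence",
        S_CAP: "frequency_cap",
        S_NOCAT: "a2i_retention", S_CT: "a2i_retention",
    }
    return CascadeFixture(
        chrom=chrom, sequence=sequence, pileups=pileups,
        meta=pd.DataFrame(meta_rows), alu=trees_from(alu_iv, chrom),
        simple_repeats=trees_from(reps_iv, chrom), transcripts=[tx],
        catalogue=catalogue, snp_catalogues=[snp_cat],
        mirna_targets=trees_from([], chrom), expected=expected)


def run_cohort(cohort, **param_overrides) -> pl.PipelineResult:
    return pl.run_simulated(cohort, params=pl.PipelineParams(**param_overrides))


SMALL = dict(genome_length=200_000, n_true_edits=120, n_snps=40,
             n_strand_artifacts=10, n_end_artifacts=10,
             n_simple_repeats=5, n_homopolymers=5)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate(SimulationConfig(seed=11, **SMALL))


@pytest.fixture(scope="session")
def small_result(small_cohort):
    return run_cohort(small_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 1 Mb genome, 24 cells / 6 stages,
    500 edits, 200 SNPs, 50+50 artifacts, p_err 1e-3, depth ~20."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_result(default_cohort):
    return run_cohort(default_cohort)


@pytest.fixture(scope="session")
def staged_cohort():
    """A deeper cohort (10 cells/stage) for stage-trajectory, clustering
    and stage-specificity checks."""
    return simulate(SimulationConfig(seed=13, cells_per_stage=10))


@pytest.fixture(scope="session")
def staged_result(staged_cohort):
    return run_cohort(staged_cohort)
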