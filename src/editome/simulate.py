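"""Synthetic editome generator with known ground truth.

Builds a toy genome with Alu intervals, simple repeats, homopolymer runs
and multi-exon genes on both strands, then per-cell pileups carrying:

* true A-to-G edits, concentrated in Alu, with G enrichment at +1 and
  depletion at -1 of the edited adenosine, base frequencies uniform in
  [0.1, 0.95] scaled by a per-cell editing activity;
* a stage-dependent activity trajectory (stable through the 4-cell
  stage, sharp drop at 8-cell, further drop at morula) that co-varies
  with a simulated ADAR expression value;
* germline SNPs shared by all cells of one embryo (half heterozygous at
  frequency 0.5, half homozygous at 1.0);
* strand-biased and read-end-biased artifact sites present in every cell;
* uniform per-base sequencing errors.

Pileup-level emission is the default; a small SAM emitter is provided to
exercise the read-level ingest and realignment paths.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import (BASES, Transcript, write_bed, write_gene_models,
                 write_pileup, PILEUP_COLUMNS)
from .ingest import STAGES

_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_IDX_BASE = np.array(list(BASES))

#: per-cell realized frequency ceiling for true edits; keeps genuine
#: editing clear of the 0.95 homozygote-removal cap, which binomial
#: sampling would otherwise straddle at the boundary
REALIZED_FREQ_CAP = 0.9

DEFAULT_STAGE_ACTIVITY = {
    "oocyte": 1.0, "pronucleus": 1.0, "zygote": 1.0,
    "2cell": 1.0, "4cell": 1.0, "8cell": 0.32, "morula": 0.19,
}


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort."""

    seed: int = 0
    stages: tuple[str, ...] = ("oocyte", "zygote", "2cell",
                               "4cell", "8cell", "morula")
    cells_per_stage: int = 4
    embryos_per_stage: int = 2
    genome_length: int = 1_000_000
    n_genes: int = 40
    n_ncrna_genes: int = 4
    n_alu: int = 40
    alu_length: int = 280
    n_simple_repeats: int = 20
    simple_repeat_length: int = 60
    n_homopolymers: int = 30
    p_err: float = 1e-3
    n_true_edits: int = 500
    edit_freq_range: tuple[float, float] = (0.1, 0.95)
    alu_edit_fraction: float = 0.8
    catalogue_fraction: float = 0.9
    n_catalogue_decoys: int = 200
    context_g_plus1_prob: float = 0.7
    context_g_minus1_prob: float = 0.1
    n_snps: int = 200
    snp_known_fraction: float = 0.5
    n_strand_artifacts: int = 50
    n_end_artifacts: int = 50
    artifact_freq: float = 0.3
    stage_activity: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_STAGE_ACTIVITY))
    activity_noise_sd: float = 0.1
    adar_coupling: float = 50.0
    adar_noise_sd: float = 0.15
    mean_depth: float = 20.0
    depth_jitter: tuple[float, float] = (0.75, 1.25)
    read_length: int = 90
    n_stage_specific_genes: int = 6
    n_two_stage_genes: int = 3
    n_null_mirna_genes: int = 8
    n_coupled_genes: int = 4
    edits_per_mirna_gene: int = 3
    chrom: str = "chrS"

    def __post_init__(self):
        for p in (self.p_err, self.context_g_plus1_prob,
                  self.context_g_minus1_prob, self.alu_edit_fraction,
                  self.catalogue_fraction, self.snp_known_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if any(v <= 0 for v in self.stage_activity.values()):
            raise ValueError("activity multipliers must be positive")
        lo, hi = self.edit_freq_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("invalid edit_freq_range")


@dataclasses.dataclass
class GenomeBundle:
    """The reference side of a simulation: sequence plus annotations."""

    chrom: str
    sequence: str
    alu_intervals: list[tuple[int, int]]        # 1-based closed
    simple_repeats: list[tuple[int, int]]
    transcripts: list[Transcript]
    catalogue: pd.DataFrame                     # chrom, pos, strand
    known_snps: pd.DataFrame                    # chrom, pos, ref, alt
    mirna_targets: list[tuple[int, int]]
    sites: pd.DataFrame                         # planted-site truth

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom != self.chrom:
            raise KeyError(f"chromosome {chrom!r} absent from reference")
        return self.sequence[start - 1:end]


@dataclasses.dataclass
class SimulatedCohort:
    config: SimulationConfig
    genome: GenomeBundle
    pileups: dict[str, pd.DataFrame]
    meta: pd.DataFrame
    expression: pd.DataFrame                    # gene x cell RPKM
    cells: pd.DataFrame                         # per-cell truth


class _SitePlacer:
    """Places planted sites with >= 8 bp spacing, clear of simple
    repeats, splice windows and contig edges, and rewrites a 5-base
    window so no homopolymer run can include or adjoin the site."""

    def __init__(self, genome: np.ndarray, rng: np.random.Generator,
                 forbidden: set[int], splice: np.ndarray):
        self.genome = genome
        self.rng = rng
        self.occupied: set[int] = set()
        self.forbidden = forbidden
        self.splice = splice

    def ok(self, pos: int) -> bool:
        L = len(self.genome)
        if pos < 10 or pos > L - 10:
            return False
        if pos in self.forbidden:
            return False
        if len(self.splice) and np.min(np.abs(self.splice - pos)) <= 8:
            return False
        return all(pos + d not in self.occupied for d in range(-8, 9))

    def place(self, pos: int, ref: str, minus1: str, plus1: str) -> None:
        g = self.genome
        i = pos - 1
        g[i] = ref
        g[i - 1] = minus1
        g[i + 1] = plus1
        flank = [b for b in ("C", "T") if b != minus1] or ["T"]
        g[i - 2] = flank[0]
        flank = [b for b in ("C", "T") if b != plus1] or ["T"]
        g[i + 2] = flank[0]
        self.occupied.add(pos)

    def sample_in(self, lo: int, hi: int, max_tries: int = 200) -> int:
        for _ in range(max_tries):
            pos = int(self.rng.integers(lo, hi + 1))
            if self.ok(pos):
                return pos
        raise RuntimeError(f"could not place a site in [{lo}, {hi}]")


def _edit_context(rng, g_minus1_p, g_plus1_p) -> tuple[str, str]:
    minus1 = "G" if rng.random() < g_minus1_p else rng.choice(["C", "T"])
    plus1 = "G" if rng.random() < g_plus1_p else rng.choice(["C", "T"])
    return str(minus1), str(plus1)


def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> GenomeBundle:
    """Generate the reference genome, annotations and planted-site truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.genome_length
    genome = _IDX_BASE[rng.integers(0, 4, L)].astype("<U1")

    margin = 2000
    gene_span = 3200
    slot = (L - 2 * margin) // max(config.n_genes, 1)
    if slot < gene_span + 600:
        raise ValueError("genome too short for the requested gene count")

    transcripts: list[Transcript] = []
    utr3_by_gene: dict[str, tuple[int, int]] = {}
    n_coding = config.n_genes - config.n_ncrna_genes
    for i in range(config.n_genes):
        g0 = margin + i * slot + 100
        strand = "+" if i % 2 == 0 else "-"
        gid = f"gene{i:03d}"
        tid = f"tx{i:03d}"
        if i >= n_coding:  # non-coding, single exon
            exons = ((g0, g0 + 799),)
            transcripts.append(Transcript(tid, gid, config.chrom, strand,
                                          "ncRNA", exons))
            continue
        if strand == "+":
            exons = ((g0, g0 + 199), (g0 + 600, g0 + 899),
                     (g0 + 1300, g0 + 1599), (g0 + 2000, g0 + 3199))
            cds = ((g0 + 600, g0 + 899), (g0 + 1300, g0 + 1599))
            utr3 = (g0 + 2000, g0 + 3199)
        else:
            exons = ((g0, g0 + 1199), (g0 + 1600, g0 + 1899),
                     (g0 + 2300, g0 + 2599), (g0 + 3000, g0 + 3199))
            cds = ((g0 + 1600, g0 + 1899), (g0 + 2300, g0 + 2599))
            utr3 = (g0, g0 + 1199)
        transcripts.append(Transcript(tid, gid, config.chrom, strand,
                                      "protein_coding", exons, cds))
        utr3_by_gene[gid] = utr3

    splice = np.array(sorted({p for t in transcripts
                              for p in t.splice_positions()}), dtype=np.int64)

    # simple repeats and homopolymers in the gaps between gene slots
    simple_repeats: list[tuple[int, int]] = []
    forbidden: set[int] = set()
    free_start = margin + (config.n_genes - 1) * slot + gene_span + 400
    free_end = L - margin
    spots = np.linspace(free_start, free_end - 200,
                        config.n_simple_repeats + config.n_homopolymers,
                        dtype=int)
    for j in range(config.n_simple_repeats):
        s = int(spots[j])
        unit = "AC"
        rep = (unit * (config.simple_repeat_length // 2))
        genome[s - 1:s - 1 + len(rep)] = list(rep)
        simple_repeats.append((s, s + len(rep) - 1))
        forbidden.update(range(s - 8, s + len(rep) + 8))
    for j in range(config.n_homopolymers):
        s = int(spots[config.n_simple_repeats + j])
        run = 5 + int(rng.integers(0, 4))
        base = str(rng.choice(list(BASES)))
        genome[s - 1:s - 1 + run] = base
        forbidden.update(range(s - 8, s + run + 8))

    # Alu intervals: inside 3'UTRs of coding genes first, rest intergenic
    alu_intervals: list[tuple[int, int]] = []
    coding_gids = [t.gene_id for t in transcripts
                   if t.transcript_type == "protein_coding"]
    n_mirna_genes = (config.n_stage_specific_genes + config.n_two_stage_genes
                     + config.n_null_mirna_genes + config.n_coupled_genes)
    n_in_gene = min(len(coding_gids),
                    max(config.n_alu * 3 // 5, n_mirna_genes))
    alu_gids = coding_gids[:n_in_gene]
    for gid in alu_gids:
        u3s, u3e = utr3_by_gene[gid]
        start = u3s + 100
        alu_intervals.append((start, start + config.alu_length - 1))
    n_intergenic = config.n_alu - len(alu_intervals)
    for j in range(max(n_intergenic, 0)):
        g0 = margin + (j % config.n_genes) * slot + gene_span + 500
        start = g0 + 40 * (j // config.n_genes)
        alu_intervals.append((start, start + config.alu_length - 1))

    placer = _SitePlacer(genome, rng, forbidden, splice)

    site_rows: list[dict] = []

    def add_site(pos, ref, alt, kind, **extra):
        row = {"chrom": config.chrom, "pos": pos, "ref": ref, "alt": alt,
               "kind": kind, "base_freq": np.nan, "gene_id": None,
               "stage_window": "", "embryo_id": "", "in_known_snp_list": False,
               "in_catalogue": False}
        row.update(extra)
        site_rows.append(row)

    lo_f, hi_f = config.edit_freq_range

    # miRNA-target genes: stage-specific, two-stage, null, then coupled
    mirna_targets: list[tuple[int, int]] = []
    n_mirna = (config.n_stage_specific_genes + config.n_two_stage_genes
               + config.n_null_mirna_genes)
    need = n_mirna + config.n_coupled_genes
    if need > len(alu_gids):
        raise ValueError("not enough Alu-bearing genes for the requested "
                         "miRNA-target and coupled genes")
    testable = list(config.stages)
    windows: list[tuple[str, ...]] = []
    for j in range(config.n_stage_specific_genes):
        windows.append((testable[j % len(testable)],))
    seq_pairs = [(a, b) for a, b in zip(testable, testable[1:])]
    if seq_pairs:  # a single-stage cohort has no sequential pairs
        for j in range(config.n_two_stage_genes):
            windows.append(seq_pairs[j % len(seq_pairs)])
    windows.extend(() for _ in range(config.n_null_mirna_genes))

    for j, window in enumerate(windows):
        gid = alu_gids[j]
        a_s, a_e = alu_intervals[j]
        t_s = a_s + 40
        t_e = t_s + 79
        mirna_targets.append((t_s, t_e))
        for _ in range(config.edits_per_mirna_gene):
            pos = placer.sample_in(t_s, t_e)
            m1, p1 = _edit_context(rng, config.context_g_minus1_prob,
                                   config.context_g_plus1_prob)
            placer.place(pos, "A", m1, p1)
            # genes with a stage window carry stage-restricted edits; the
            # remaining miRNA-target genes get stage-uniform frequencies
            # so they act as true nulls for the stage-specificity test
            kind = "uniform_edit" if not window else "stage_edit"
            f = float(rng.uniform(max(lo_f, 0.35), hi_f)) if window else \
                float(rng.uniform(lo_f, hi_f))
            add_site(pos, "A", "G", kind, base_freq=f, gene_id=gid,
                     stage_window="+".join(window))

    # keep later bulk edits out of the miRNA-target windows so planted
    # stage patterns (and nulls) stay uncontaminated
    for t_s, t_e in mirna_targets:
        placer.forbidden.update(range(t_s, t_e + 1))

    coupled_gids = []
    for j in range(config.n_coupled_genes):
        gid = alu_gids[n_mirna + j]
        a_s, a_e = alu_intervals[n_mirna + j]
        pos = placer.sample_in(a_s, a_s + 35)
        m1, p1 = _edit_context(rng, config.context_g_minus1_prob,
                               config.context_g_plus1_prob)
        placer.place(pos, "A", m1, p1)
        add_site(pos, "A", "G", "coupled_edit", base_freq=np.nan, gene_id=gid)
        coupled_gids.append(gid)

    # bulk Alu edits
    n_special = sum(1 for r in site_rows)
    n_alu_edits = max(int(round(config.alu_edit_fraction
                                * config.n_true_edits)) - n_special, 0)
    for j in range(n_alu_edits):
        a_s, a_e = alu_intervals[int(rng.integers(0, len(alu_intervals)))]
        try:
            pos = placer.sample_in(a_s, a_e, max_tries=60)
        except RuntimeError:
            continue
        m1, p1 = _edit_context(rng, config.context_g_minus1_prob,
                               config.context_g_plus1_prob)
        placer.place(pos, "A", m1, p1)
        gid = next((t.gene_id for t in transcripts
                    if t.start <= pos <= t.end), None)
        add_site(pos, "A", "G", "edit",
                 base_freq=float(rng.uniform(lo_f, hi_f)), gene_id=gid)

    # non-Alu edits (mostly catalogue-listed)
    alu_arr = np.array(alu_intervals)
    n_non_alu = config.n_true_edits - sum(1 for r in site_rows)
    for j in range(max(n_non_alu, 0)):
        for _ in range(200):
            pos = int(rng.integers(margin, L - margin))
            in_alu = bool(np.any((alu_arr[:, 0] <= pos)
                                 & (pos <= alu_arr[:, 1])))
            if not in_alu and placer.ok(pos):
                break
        else:
            continue
        m1, p1 = _edit_context(rng, config.context_g_minus1_prob,
                               config.context_g_plus1_prob)
        placer.place(pos, "A", m1, p1)
        add_site(pos, "A", "G", "edit",
                 base_freq=float(rng.uniform(lo_f, hi_f)),
                 in_catalogue=bool(rng.random() < config.catalogue_fraction))

    # germline SNPs, each confined to one embryo
    embryo_ids = [f"E{stage}{k}" for stage in config.stages
                  for k in range(config.embryos_per_stage)]
    for j in range(config.n_snps):
        for _ in range(200):
            pos = int(rng.integers(margin, L - margin))
            if placer.ok(pos):
                break
        else:
            continue
        ref = str(rng.choice(list(BASES)))
        alt = str(rng.choice([b for b in BASES if b != ref]))
        m1 = str(rng.choice([b for b in BASES if b != ref]))
        p1 = str(rng.choice([b for b in BASES if b != ref and b != m1]))
        placer.place(pos, ref, m1, p1)
        add_site(pos, ref, alt, "snp",
                 base_freq=0.5 if j % 2 == 0 else 1.0,
                 embryo_id=embryo_ids[j % len(embryo_ids)],
                 in_known_snp_list=bool(rng.random()
                                        < config.snp_known_fraction))

    # systematic artifact sites, present in every cell
    for kind, count in (("strand_artifact", config.n_strand_artifacts),
                        ("end_artifact", config.n_end_artifacts)):
        for _ in range(count):
            for _ in range(200):
                pos = int(rng.integers(margin, L - margin))
                if placer.ok(pos):
                    break
            else:
                continue
            placer.place(pos, "A", str(rng.choice(["C", "T"])),
                         str(rng.choice(["C", "T"])))
            add_site(pos, "A", "G", kind, base_freq=config.artifact_freq)

    site_columns = ["chrom", "pos", "ref", "alt", "kind", "base_freq",
                    "gene_id", "stage_window", "embryo_id",
                    "in_known_snp_list", "in_catalogue"]
    sites = (pd.DataFrame(site_rows, columns=site_columns)
             .sort_values("pos").reset_index(drop=True))

    # catalogue: listed non-Alu edits + all stage/coupled edits + decoys
    cat_pos = list(sites.loc[sites["in_catalogue"], "pos"])
    for _ in range(config.n_catalogue_decoys):
        pos = int(rng.integers(margin, L - margin))
        if pos not in placer.occupied:
            cat_pos.append(pos)
    catalogue = pd.DataFrame({"chrom": config.chrom,
                              "pos": sorted(set(cat_pos)), "strand": "+"})

    snp_mask = sites["in_known_snp_list"]
    known_snps = sites.loc[snp_mask, ["chrom", "pos", "ref", "alt"]].copy()

    return GenomeBundle(
        chrom=config.chrom, sequence="".join(genome),
        alu_intervals=alu_intervals, simple_repeats=simple_repeats,
        transcripts=transcripts, catalogue=catalogue, known_snps=known_snps,
        mirna_targets=mirna_targets, sites=sites)


def _split_counts(rng, k: np.ndarray, p: float, forced: np.ndarray
                  ) -> np.ndarray:
    """Binomial split of k with probability p, except where ``forced``
    (all counts land on the first side)."""
    out = rng.binomial(k, p)
    return np.where(forced, k, out)


def simulate_cells(config: SimulationConfig, genome: GenomeBundle,
                   rng: np.random.Generator | None = None) -> SimulatedCohort:
    """Simulate per-cell pileups, metadata, expression and truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    L = config.genome_length
    sites = genome.sites
    n_sites = len(sites)
    pos_arr = sites["pos"].to_numpy()
    ref_arr = sites["ref"].to_numpy()
    alt_arr = sites["alt"].to_numpy()
    kind = sites["kind"].to_numpy()
    base_f = sites["base_freq"].to_numpy(dtype=float)
    strand_forced = kind == "strand_artifact"
    end_forced = kind == "end_artifact"
    end_frac = 15.0 / config.read_length

    # cohort roster
    cells = []
    for stage in config.stages:
        for k in range(config.cells_per_stage):
            embryo = f"E{stage}{k % config.embryos_per_stage}"
            cells.append({"cell_id": f"{stage}_c{k}", "embryo_id": embryo,
                          "stage": stage})
    cells = pd.DataFrame(cells)
    n_cells = len(cells)

    act_mult = np.array([config.stage_activity[s] for s in cells["stage"]])
    activity = act_mult * rng.lognormal(0.0, config.activity_noise_sd, n_cells)
    depth_c = config.mean_depth * rng.uniform(*config.depth_jitter, n_cells)
    mapped = np.round(L * depth_c).astype(np.int64)

    # expression (gene x cell RPKM); ADAR tracks activity
    gene_ids = sorted({t.gene_id for t in genome.transcripts})
    base_expr = rng.lognormal(2.0, 1.0, len(gene_ids))
    expr = base_expr[:, None] * rng.lognormal(0.0, 0.3, (len(gene_ids), n_cells))
    expression = pd.DataFrame(expr, index=gene_ids,
                              columns=cells["cell_id"])
    coupled_rows = sites["kind"] == "coupled_edit"
    coupled_gids = list(sites.loc[coupled_rows, "gene_id"].dropna().unique())
    for gid in coupled_gids:
        expression.loc[gid] = base_expr[gene_ids.index(gid)] * \
            rng.lognormal(0.0, 0.8, n_cells)
    expression.loc["ADAR"] = config.adar_coupling * activity * \
        rng.lognormal(0.0, config.adar_noise_sd, n_cells)

    # per-cell frequency at coupled sites: decreasing in expression rank
    coupled_freq = {}
    for idx in np.flatnonzero(coupled_rows):
        gid = sites.loc[idx, "gene_id"]
        e = expression.loc[gid].to_numpy(dtype=float)
        ranks = rankdata(e)
        f = 0.9 - 0.75 * (ranks - 1) / max(n_cells - 1, 1) \
            + rng.normal(0.0, 0.04, n_cells)
        coupled_freq[idx] = np.clip(f, 0.1, 0.92)

    stage_windows = [set(w.split("+")) if w else set()
                     for w in sites["stage_window"]]

    pileups: dict[str, pd.DataFrame] = {}
    base_code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_IDX.items():
        base_code[ord(b)] = i
    genome_code = base_code[np.frombuffer(genome.sequence.encode(),
                                          dtype=np.uint8)]

    for ci, cell in enumerate(cells.itertuples(index=False)):
        freq = np.zeros(n_sites)
        is_edit = kind == "edit"
        freq[is_edit] = base_f[is_edit] * activity[ci]
        uniform = kind == "uniform_edit"
        freq[uniform] = base_f[uniform]
        for idx in np.flatnonzero(kind == "stage_edit"):
            freq[idx] = base_f[idx] if cell.stage in stage_windows[idx] else 0.0
        snp_rows = kind == "snp"
        freq[snp_rows] = np.where(
            sites.loc[snp_rows, "embryo_id"].to_numpy() == cell.embryo_id,
            base_f[snp_rows], 0.0)
        art = strand_forced | end_forced
        freq[art] = base_f[art]
        for idx, f in coupled_freq.items():
            freq[idx] = f[ci]
        # true edits stay clear of the homozygote-removal boundary: a
        # genuine editing event never reaches fixation, so its per-cell
        # frequency is held below 0.9 and only SNP-like signals (planted
        # homozygous SNPs) straddle the 0.95 cap
        true_edit = ~(snp_rows | art)
        freq[true_edit] = np.minimum(freq[true_edit], REALIZED_FREQ_CAP)

        n = rng.poisson(depth_c[ci], n_sites)
        k = rng.binomial(n, freq)
        keep = n > 0
        alt_f = _split_counts(rng, k, 0.5, strand_forced)
        ref_n = n - k
        ref_f = rng.binomial(ref_n, 0.5)
        var_end = _split_counts(rng, k, end_frac, end_forced)
        ref_end = rng.binomial(ref_n, end_frac)

        # sequencing errors at random positions
        n_err = rng.poisson(L * depth_c[ci] * config.p_err)
        epos = rng.integers(1, L + 1, n_err)
        epos = epos[~np.isin(epos, pos_arr)]
        epos_u, ek = np.unique(epos, return_counts=True)
        e_ref_idx = genome_code[epos_u - 1]
        e_alt_idx = (e_ref_idx + rng.integers(1, 4, len(epos_u))) % 4
        en = np.maximum(rng.poisson(depth_c[ci], len(epos_u)), ek)
        e_alt_f = rng.binomial(ek, 0.5)
        e_ref_n = en - ek
        e_ref_f = rng.binomial(e_ref_n, 0.5)
        e_var_end = rng.binomial(ek, end_frac)
        e_ref_end = rng.binomial(e_ref_n, end_frac)

        all_pos = np.concatenate([pos_arr[keep], epos_u])
        all_ref_idx = np.concatenate(
            [np.array([_BASE_IDX[b] for b in ref_arr[keep]], dtype=np.int64),
             e_ref_idx]).astype(np.int64)
        all_alt_idx = np.concatenate(
            [np.array([_BASE_IDX[b] for b in alt_arr[keep]], dtype=np.int64),
             e_alt_idx]).astype(np.int64)
        all_n = np.concatenate([n[keep], en])
        all_k = np.concatenate([k[keep], ek])
        all_alt_f = np.concatenate([alt_f[keep], e_alt_f])
        all_ref_f = np.concatenate([ref_f[keep], e_ref_f])
        all_var_end = np.concatenate([var_end[keep], e_var_end])
        all_ref_end = np.concatenate([ref_end[keep], e_ref_end])
        ref_count = all_n - all_k

        cols = {c: np.zeros(len(all_pos), dtype=np.int64)
                for c in PILEUP_COLUMNS[4:]}
        for bi, b in enumerate(BASES):
            at_ref = all_ref_idx == bi
            at_alt = all_alt_idx == bi
            cols[f"{b}_f"] = np.where(at_ref, all_ref_f, 0) + \
                np.where(at_alt, all_alt_f, 0)
            cols[f"{b}_r"] = (np.where(at_ref, ref_count - all_ref_f, 0)
                              + np.where(at_alt, all_k - all_alt_f, 0))
        cols["var_end"] = all_var_end
        cols["var_mid"] = all_k - all_var_end
        cols["ref_end"] = all_ref_end
        cols["ref_mid"] = ref_count - all_ref_end
        df = pd.DataFrame({"chrom": config.chrom, "pos": all_pos,
                           "ref": _IDX_BASE[all_ref_idx],
                           "depth": all_n, **cols})
        pileups[cell.cell_id] = df.sort_values("pos").reset_index(drop=True)

    meta = cells.assign(layout="single_end",
                        uniquely_mapped_bases=mapped,
                        stage=cells["stage"])
    cell_truth = cells.assign(
        activity=activity, mean_depth=depth_c,
        adar_rpkm=expression.loc["ADAR"].to_numpy(),
        uniquely_mapped_bases=mapped)
    return SimulatedCohort(config=config, genome=genome, pileups=pileups,
                           meta=meta, expression=expression,
                           cells=cell_truth)


def simulate(config: SimulationConfig) -> SimulatedCohort:
    """Genome + cohort in one call, fully determined by config.seed."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    return simulate_cells(config, genome, rng)


def score_against_truth(annotated: pd.DataFrame,
                        cohort: SimulatedCohort) -> dict:
    """Precision/recall on planted edits and per-kind artifact leakage.

    Recall is restricted to recoverable edits (depth >= 4 in at least one
    cell). Precision is NA (None) when nothing was detected. Also reports
    the fraction of single-embryo SNP candidates removed by the
    recurrence or known-SNP filters.
    """
    sites = cohort.genome.sites
    edits = sites.loc[sites["kind"].isin(["edit", "uniform_edit",
                                          "stage_edit", "coupled_edit"])]
    max_depth = {}
    for df in cohort.pileups.values():
        d = df.set_index("pos")["depth"]
        for p, v in d.items():
            if v > max_depth.get(p, 0):
                max_depth[p] = v
    recoverable = {p for p in edits["pos"] if max_depth.get(p, 0) >= 4}

    detected = set(annotated.loc[annotated["retained"], "pos"])
    edit_pos = set(edits["pos"])
    tp = len(detected & edit_pos)
    precision = tp / len(detected) if detected else None
    recall = (len(detected & recoverable) / len(recoverable)
              if recoverable else None)

    out = {"precision": precision, "recall": recall,
           "n_detected": len(detected), "n_recoverable": len(recoverable)}
    for akind in ("strand_artifact", "end_artifact"):
        apos = set(sites.loc[sites["kind"] == akind, "pos"])
        out[f"{akind}_leakage"] = (len(detected & apos) / len(apos)
                                   if apos else 0.0)
    snp_pos = set(sites.loc[sites["kind"] == "snp", "pos"])
    snp_cand = annotated.loc[annotated["pos"].isin(snp_pos)]
    if len(snp_cand):
        removed = ((snp_cand["recurrence"] == "fail")
                   | (snp_cand["known_snp"] == "fail"))
        out["snp_removed_frac"] = float(removed.mean())
        out["n_snp_candidates"] = int(len(snp_cand))
    else:
        out["snp_removed_frac"] = None
        out["n_snp_candidates"] = 0
    return out


def write_bundle(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write the simulated inputs as the plain-text bundle the pipeline
    and CLI consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    g = cohort.genome
    with open(out / "genome.fa", "w") as fh:
        fh.write(f">{g.chrom}\n")
        for i in range(0, len(g.sequence), 80):
            fh.write(g.sequence[i:i + 80] + "\n")
    write_bed(((g.chrom, s, e) for s, e in g.alu_intervals), out / "alu.bed")
    write_bed(((g.chrom, s, e) for s, e in g.simple_repeats),
              out / "simple_repeats.bed")
    write_bed(((g.chrom, s, e) for s, e in g.mirna_targets),
              out / "mirna_targets.bed")
    write_gene_models(g.transcripts, out / "genes.gtf")
    g.catalogue.to_csv(out / "catalogue.tsv", sep="\t", index=False)
    g.known_snps.to_csv(out / "known_snps.tsv", sep="\t", index=False)
    g.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    cohort.cells.to_csv(out / "truth_cells.tsv", sep="\t", index=False)
    cohort.meta.to_csv(out / "meta.tsv", sep="\t", index=False)
    cohort.expression.rename_axis("gene_id").to_csv(
        out / "expression.tsv", sep="\t")
    pdir = out / "pileups"
    pdir.mkdir(exist_ok=True)
    for cell_id, df in cohort.pileups.items():
        write_pileup(df, pdir / f"{cell_id}.pileup.tsv")


def emit_sam(genome: GenomeBundle, site_reads: list[dict],
             path: str | Path, read_length: int = 90) -> None:
    """Write a small single-end SAM file of reads over the toy genome.

    ``site_reads`` entries: {pos (1-based alignment start), variants:
    {read_offset: base}, reverse: bool, qual: int}. Intended for
    exercising the read-level ingest path at small scale.
    """
    import pysam
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": genome.chrom, "LN": len(genome.sequence)}]}
    site_reads = sorted(site_reads, key=lambda r: r["pos"])
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for i, spec in enumerate(site_reads):
            start = spec["pos"]
            seq = list(genome.sequence[start - 1:start - 1 + read_length])
            for off, base in spec.get("variants", {}).items():
                seq[off] = base
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"read{i}"
            a.query_sequence = "".join(seq)
            a.flag = 16 if spec.get("reverse") else 0
            a.reference_id = 0
            a.reference_start = start - 1
            a.mapping_quality = 50
            a.cigarstring = f"{len(seq)}M"
            a.query_qualities = pysam.qualitystring_to_array(
                chr(spec.get("qual", 30) + 33) * len(seq))
            fh.write(a)
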