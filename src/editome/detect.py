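"""Binomial error test, Benjamini-Hochberg adjustment, detection thresholds.

A mismatch with k variant-supporting reads among n mapped reads is tested
against the cell's background error rate p: the binomial upper tail
P(X >= k), X ~ B(n, p), is the probability that all k mismatches are
sequencing errors. Adjusted per transcriptome (BH), candidates must then
clear hard thresholds: adjusted P < 0.01, depth >= 4, variant reads >= 3,
frequency >= 0.1.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BASES

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_DEPTH = 4
DEFAULT_MIN_ALT = 3
DEFAULT_MIN_FREQ = 0.1


@dataclasses.dataclass
class VariantCandidate:
    """A mismatch site in one cell with its test results and filter verdicts."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    cell_id: str
    n: int
    k: int
    p_binomial: float = np.nan
    p_adjusted: float = np.nan
    verdicts: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.k <= self.n):
            raise ValueError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base must differ from ref_base")

    @property
    def freq(self) -> float:
        return self.k / self.n if self.n else 0.0


def binomial_error_test(k, n, p):
    """Upper-tail binomial probability P(X >= k) for X ~ B(n, p).

    Vectorised over k and n. Computed through the survival function
    (regularised incomplete beta), which is numerically stable for the
    tiny tail probabilities this test produces.
    """
    k_arr = np.asarray(k)
    n_arr = np.asarray(n)
    if np.any(k_arr < 0) or np.any(n_arr < 0) or np.any(k_arr > n_arr):
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= float(p) <= 1.0:
        raise ValueError("need 0 <= p <= 1")
    out = stats.binom.sf(k_arr - 1, n_arr, p)
    if np.isscalar(k) and np.isscalar(n):
        return float(out)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_detection_thresholds(n: int, k: int, p_adjusted: float,
                               alpha: float = DEFAULT_ALPHA,
                               min_depth: int = DEFAULT_MIN_DEPTH,
                               min_alt: int = DEFAULT_MIN_ALT,
                               min_freq: float = DEFAULT_MIN_FREQ) -> bool:
    """Hard detection gate on one candidate."""
    freq = k / n if n else 0.0
    return (p_adjusted < alpha and n >= min_depth
            and k >= min_alt and freq >= min_freq)


def detect_cell(pileup: pd.DataFrame, background_p: float, cell_id: str,
                alpha: float = DEFAULT_ALPHA,
                min_depth: int = DEFAULT_MIN_DEPTH,
                min_alt: int = DEFAULT_MIN_ALT,
                min_freq: float = DEFAULT_MIN_FREQ,
                p_adjusted: np.ndarray | None = None) -> pd.DataFrame:
    """Run detection over one cell's pileup table.

    At multi-allelic columns only the majority alt (ties broken
    alphabetically, logged) is carried forward and tested against the
    full depth n. The BH family is the cell's mismatch columns unless
    pre-computed adjusted values for a pooled family are supplied via
    ``p_adjusted``.

    Returns a candidate table with columns cell_id, chrom, pos, ref, alt,
    n, k, freq, p, p_adj, detected, plus the strand/end split of the
    majority alt and the reference base (inputs to the bias filters).
    """
    df = pileup
    ref = df["ref"].to_numpy()
    totals = {b: df[f"{b}_f"].to_numpy() + df[f"{b}_r"].to_numpy() for b in BASES}

    alt_count = np.zeros(len(df), dtype=np.int64)
    alt_base = np.full(len(df), "N", dtype="<U1")
    for b in BASES:  # alphabetical order => ties keep the earlier base
        cnt = np.where(ref == b, -1, totals[b])
        better = cnt > alt_count
        alt_count = np.where(better, cnt, alt_count)
        alt_base = np.where(better, b, alt_base)
    is_mismatch = alt_count > 0
    ties = np.zeros(len(df), dtype=bool)
    for b in BASES:
        ties |= (np.asarray(totals[b]) == alt_count) & (ref != b) & \
                (np.char.not_equal(alt_base, b))
    n_tied = int((ties & is_mismatch).sum())
    if n_tied:
        logger.info("cell %s: %d multi-allelic columns with tied alts; "
                    "kept the alphabetically first alt", cell_id, n_tied)

    sub = df.loc[is_mismatch].copy()
    alt = alt_base[is_mismatch]
    k = alt_count[is_mismatch]
    n = sub["depth"].to_numpy()
    p_raw = binomial_error_test(k, n, background_p)
    p_adj = bh_adjust(p_raw) if p_adjusted is None else np.asarray(p_adjusted)

    freq = k / n
    out = pd.DataFrame({
        "cell_id": cell_id,
        "chrom": sub["chrom"].to_numpy(),
        "pos": sub["pos"].to_numpy(),
        "ref": sub["ref"].to_numpy(),
        "alt": alt,
        "n": n,
        "k": k,
        "freq": freq,
        "p": p_raw,
        "p_adj": p_adj,
    })
    out["detected"] = ((out["p_adj"] < alpha) & (out["n"] >= min_depth)
                       & (out["k"] >= min_alt) & (out["freq"] >= min_freq))
    # strand / end splits needed by the bias filters
    alt_f = np.zeros(len(sub), dtype=np.int64)
    alt_r = np.zeros(len(sub), dtype=np.int64)
    ref_f = np.zeros(len(sub), dtype=np.int64)
    ref_r = np.zeros(len(sub), dtype=np.int64)
    for b in BASES:
        bf = sub[f"{b}_f"].to_numpy()
        br = sub[f"{b}_r"].to_numpy()
        alt_f = np.where(alt == b, bf, alt_f)
        alt_r = np.where(alt == b, br, alt_r)
        ref_f = np.where(out["ref"].to_numpy() == b, bf, ref_f)
        ref_r = np.where(out["ref"].to_numpy() == b, br, ref_r)
    out["alt_f"], out["alt_r"] = alt_f, alt_r
    out["ref_f"], out["ref_r"] = ref_f, ref_r
    for c in ("var_end", "var_mid", "ref_end", "ref_mid"):
        out[c] = sub[c].to_numpy()
    return out


def detect_cohort(pileups: dict[str, pd.DataFrame],
                  background: dict[str, float],
                  bh_family: str = "per_cell", **thresholds) -> pd.DataFrame:
    """Detection across a cohort of cells.

    bh_family 'per_cell' adjusts within each transcriptome (default);
    'global' pools every mismatch column of every cell into one family.
    """
    if bh_family not in ("per_cell", "global"):
        raise ValueError("bh_family must be 'per_cell' or 'global'")
    parts = [detect_cell(pileup, background[cid], cid, **thresholds)
             for cid, pileup in pileups.items()]
    cand = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    if bh_family == "global" and len(cand):
        alpha = thresholds.get("alpha", DEFAULT_ALPHA)
        min_depth = thresholds.get("min_depth", DEFAULT_MIN_DEPTH)
        min_alt = thresholds.get("min_alt", DEFAULT_MIN_ALT)
        min_freq = thresholds.get("min_freq", DEFAULT_MIN_FREQ)
        cand["p_adj"] = bh_adjust(cand["p"].to_numpy())
        cand["detected"] = ((cand["p_adj"] < alpha) & (cand["n"] >= min_depth)
                            & (cand["k"] >= min_alt) & (cand["freq"] >= min_freq))
    return cand
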