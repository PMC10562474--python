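"""Pre- and post-analysis utilities for allele-specific expression.

Covers SNP-to-gene aggregation of allele-specific counts (phased and
unphased/pseudo-phased), monoallelic-expression and coverage QC filters,
classification of dynamic-ASE trajectories, an exact Fisher test for 2x3
contingency tables, and chromatin-state recoding with the associated
regression of chromatin change on D-ASE status.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
import statsmodels.api as sm

logger = logging.getLogger(__name__)

SNP_COLUMNS = ["snp", "gene", "donor", "cell", "ref_count", "alt_count",
               "hap_of_alt"]


# --------------------------------------------------------------------------
# SNP -> gene aggregation
# --------------------------------------------------------------------------

def aggregate_phased(records: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Sum phased SNP-level counts to haplotype-level gene counts.

    ``hap_of_alt`` (1 or 2) names the haplotype carrying each tSNP's
    alternative allele; per (gene, donor, cell) the allele counts are
    routed to their haplotypes and summed. The gene's alternative
    haplotype is anchored at the top tSNP (largest total allele-specific
    count across donors); donors homozygous at the top tSNP (no records
    for it) get a seeded random anchor.

    Returns a long-format frame with ``alt_count`` = alternative-haplotype
    count and ``total_count`` = hap1 + hap2.
    """
    _check_snp_columns(records)
    out = []
    rng = np.random.default_rng(seed)
    for gene, sub in records.groupby("gene", sort=True):
        if (sub["hap_of_alt"].astype(str) == "unknown").any():
            known = (sub["hap_of_alt"].astype(str) != "unknown").any()
            if known:
                raise ValueError(
                    f"{gene}: mixed known/unknown phase; use "
                    "aggregate_unphased for unphased data")
            raise ValueError(
                f"{gene}: phase unknown; use aggregate_unphased")
        sub = sub.copy()
        sub["hap_of_alt"] = sub["hap_of_alt"].astype(int)
        # counts routed to haplotypes: alt allele lives on hap_of_alt
        sub["hap1"] = np.where(sub["hap_of_alt"] == 1, sub["alt_count"],
                               sub["ref_count"])
        sub["hap2"] = np.where(sub["hap_of_alt"] == 2, sub["alt_count"],
                               sub["ref_count"])
        per_cell = (sub.groupby(["donor", "cell"], sort=True)[["hap1", "hap2"]]
                    .sum().reset_index())
        snp_tot = sub.groupby("snp")[["ref_count", "alt_count"]].sum().sum(axis=1)
        top = snp_tot.idxmax()
        # per donor: which haplotype is the gene's alternative haplotype
        top_rec = sub[sub["snp"] == top].groupby("donor")["hap_of_alt"].first()
        anchors = {}
        for donor in per_cell["donor"].unique():
            if donor in top_rec.index:
                anchors[donor] = int(top_rec.loc[donor])
            else:  # homozygous at the top tSNP: random, seeded
                anchors[donor] = int(rng.integers(1, 3))
                logger.info("%s/%s: top tSNP homozygous; random haplotype "
                            "anchor %d", gene, donor, anchors[donor])
        anchor = per_cell["donor"].map(anchors)
        alt = np.where(anchor == 1, per_cell["hap1"], per_cell["hap2"])
        tot = per_cell["hap1"] + per_cell["hap2"]
        out.append(pd.DataFrame({
            "gene": gene, "donor": per_cell["donor"],
            "cell": per_cell["cell"], "alt_count": alt,
            "total_count": tot,
        }))
    return pd.concat(out, ignore_index=True)


def aggregate_unphased(records: pd.DataFrame) -> pd.DataFrame:
    """Pseudo-phased aggregation for data without genotype phase.

    Per tSNP and donor, counts are pooled across cells and the expression
    minor allele (the one with the lower pooled count) is designated the
    alternative haplotype; the gene-level alternative count per cell is
    the sum of minor-allele counts over tSNPs, the total the sum of all
    allele-specific counts. Exact ties go to the alternative allele (a
    deterministic tie-break, logged).
    """
    _check_snp_columns(records, require_phase=False)
    pooled = (records.groupby(["gene", "snp", "donor"], sort=True)
              [["ref_count", "alt_count"]].sum())
    minor_is_alt = pooled["alt_count"] <= pooled["ref_count"]
    ties = pooled["alt_count"] == pooled["ref_count"]
    if ties.any():
        for key in pooled.index[ties]:
            logger.info("tie at %s: alternative allele chosen", (key,))
    lookup = minor_is_alt.to_dict()
    rec = records.copy()
    keys = list(zip(rec["gene"], rec["snp"], rec["donor"]))
    use_alt = np.array([lookup[k] for k in keys])
    rec["minor"] = np.where(use_alt, rec["alt_count"], rec["ref_count"])
    rec["total"] = rec["alt_count"] + rec["ref_count"]
    per_cell = (rec.groupby(["gene", "donor", "cell"], sort=True)
                [["minor", "total"]].sum().reset_index())
    return per_cell.rename(columns={"minor": "alt_count",
                                    "total": "total_count"})


def _check_snp_columns(records: pd.DataFrame, require_phase: bool = True):
    need = SNP_COLUMNS if require_phase else SNP_COLUMNS[:-1]
    missing = [c for c in need if c not in records.columns]
    if missing:
        raise ValueError(f"SNP-level table missing columns {missing}")
    if (records[["ref_count", "alt_count"]] < 0).any().any():
        raise ValueError("negative counts in SNP-level table")


# --------------------------------------------------------------------------
# QC filters
# --------------------------------------------------------------------------

def filter_monoallelic(records: pd.DataFrame, low: float = 0.02,
                       high: float = 0.98) -> pd.DataFrame:
    """Drop (SNP, donor) pairs with near-monoallelic pseudobulk expression.

    The pseudobulk fraction sums alt and total counts over a donor's
    cells; the pair is removed when fraction < ``low`` or > ``high``
    (strict inequalities, so a fraction exactly at a threshold is kept).
    Zero-total pairs are removed and counted. The default 0.02/0.98
    thresholds suit deep phased data; 0.05/0.95 is the usual preset for
    sparser unphased data.
    """
    if not (0.0 < low < high < 1.0):
        raise ValueError("need 0 < low < high < 1")
    _check_snp_columns(records, require_phase=False)
    pooled = (records.groupby(["snp", "donor"], sort=False)
              [["ref_count", "alt_count"]].sum())
    total = pooled["ref_count"] + pooled["alt_count"]
    with np.errstate(invalid="ignore"):
        frac = pooled["alt_count"] / total
    keep = (total > 0) & (frac >= low) & (frac <= high)
    n_zero = int((total == 0).sum())
    if n_zero:
        logger.info("filter_monoallelic: removed %d zero-coverage "
                    "(snp, donor) pairs", n_zero)
    keep_keys = set(pooled.index[keep])
    mask = [(s, d) in keep_keys
            for s, d in zip(records["snp"], records["donor"])]
    return records[np.asarray(mask)].reset_index(drop=True)


def filter_coverage(gene_table: pd.DataFrame, preset: str,
                    condition: pd.Series | dict | None = None):
    """Gene-level coverage filters.

    ``preset='endoderm'``: remove genes with non-zero allele-specific
    counts in <= 20% of all cells.

    ``preset='pancreatic'``: per gene, first remove donors contributing
    < 3 cells or < 5 reads; then drop the gene if < 50 cells remain, or
    < 2 case donors, or < 2 control donors (``condition`` maps donor ->
    0/1 case status and is required).

    Returns (filtered table, per-rule removal tally).
    """
    need = ["gene", "donor", "cell", "alt_count", "total_count"]
    missing = [c for c in need if c not in gene_table.columns]
    if missing:
        raise ValueError(f"gene table missing columns {missing}")
    tally: dict[str, int] = {}
    if preset == "endoderm":
        n_cells = gene_table.groupby("gene")["cell"].transform("size")
        nz = (gene_table["total_count"] > 0).groupby(
            gene_table["gene"]).transform("sum")
        frac = nz / n_cells
        bad_genes = set(gene_table.loc[frac <= 0.20, "gene"])
        tally["nonzero<=20%-of-cells"] = len(bad_genes)
        out = gene_table[~gene_table["gene"].isin(bad_genes)]
        return out.reset_index(drop=True), tally
    if preset == "pancreatic":
        if condition is None:
            raise ValueError("pancreatic preset requires case/control labels")
        cond = dict(condition) if not isinstance(condition, dict) \
            else condition
        keep_frames = []
        tally = {"donor<3cells-or<5reads": 0, "gene<50cells": 0,
                 "gene<2cases": 0, "gene<2controls": 0}
        for gene, sub in gene_table.groupby("gene", sort=True):
            per_donor = sub.groupby("donor").agg(
                cells=("cell", "size"), reads=("total_count", "sum"))
            ok_donors = per_donor.index[(per_donor["cells"] >= 3)
                                        & (per_donor["reads"] >= 5)]
            tally["donor<3cells-or<5reads"] += (
                len(per_donor) - len(ok_donors))
            sub = sub[sub["donor"].isin(ok_donors)]
            if len(sub) < 50:
                tally["gene<50cells"] += 1
                continue
            status = [cond.get(d, None) for d in sub["donor"].unique()]
            if any(s is None for s in status):
                raise ValueError(f"{gene}: donor without case/control label")
            n_cases = sum(1 for s in status if s)
            n_controls = sum(1 for s in status if not s)
            if n_cases < 2:
                tally["gene<2cases"] += 1
                continue
            if n_controls < 2:
                tally["gene<2controls"] += 1
                continue
            keep_frames.append(sub)
        out = (pd.concat(keep_frames, ignore_index=True)
               if keep_frames else gene_table.iloc[0:0].copy())
        return out, tally
    raise ValueError(f"unknown preset {preset!r}")


# --------------------------------------------------------------------------
# Dynamic-ASE classification
# --------------------------------------------------------------------------

def allelic_ratio(beta0: float, beta1: float, t) -> float | np.ndarray:
    """Model-implied allelic ratio 1 / (1 + exp(-(beta0 + beta1 t)))."""
    val = special.expit(beta0 + beta1 * np.asarray(t, dtype=float))
    return float(val) if np.ndim(t) == 0 else val


@dataclass(frozen=True)
class DASEClassInput:
    """Endpoint allelic ratios derived from a mixture-model fit."""
    beta0: float
    beta1: float
    t_start: float
    t_end: float

    def endpoints(self) -> tuple[float, float]:
        return (allelic_ratio(self.beta0, self.beta1, self.t_start),
                allelic_ratio(self.beta0, self.beta1, self.t_end))


def classify_dase(inp: DASEClassInput) -> str:
    """Classify a dynamic-ASE trajectory by its endpoint allelic ratios.

    With p_start and p_end the allelic ratios at the two endpoints
    (thresholds 0.47 / 0.53 around balance, dead zone half-width 0.03):

    - increasing: imbalance grows away from 0.5 on one side
      (p_end < p_start < 0.47 or p_end > p_start > 0.53);
    - decreasing: imbalance shrinks (p_start < p_end < 0.47 or
      p_start > p_end > 0.53);
    - late: balanced at start (|p_start - 0.5| < 0.03) and imbalanced at
      the end (|p_end - 0.5| > 0.03);
    - early: the reverse;
    - switching: the imbalance changes side (p_start < 0.47 and
      p_end > 0.53, or vice versa);
    - unspecified: anything else. The five named rules are mutually
      exclusive; 'increasing' here means the *magnitude* of imbalance
      increases along the trajectory.
    """
    p_start, p_end = inp.endpoints()
    matches = _matching_rules(p_start, p_end)
    assert len(matches) <= 1, f"rules overlap at {(p_start, p_end)}"
    return matches[0] if matches else "unspecified"


def _matching_rules(p_start: float, p_end: float) -> list[str]:
    rules = []
    if (p_end < p_start < 0.47) or (p_end > p_start > 0.53):
        rules.append("increasing")
    if (p_start < p_end < 0.47) or (p_start > p_end > 0.53):
        rules.append("decreasing")
    if abs(p_start - 0.5) < 0.03 and abs(p_end - 0.5) > 0.03:
        rules.append("late")
    if abs(p_start - 0.5) > 0.03 and abs(p_end - 0.5) < 0.03:
        rules.append("early")
    if (p_start < 0.47 and p_end > 0.53) or (p_end < 0.47 and p_start > 0.53):
        rules.append("switching")
    return rules


def classify_table(results: pd.DataFrame, t_start: float,
                   t_end: float) -> pd.DataFrame:
    """Classify every gene in a results frame with beta0/beta1 columns."""
    for col in ("gene", "beta0", "beta1"):
        if col not in results.columns:
            raise ValueError(f"results frame missing column {col!r}")
    rows = []
    for _, r in results.sort_values("gene").iterrows():
        inp = DASEClassInput(float(r["beta0"]), float(r["beta1"]),
                             t_start, t_end)
        p_start, p_end = inp.endpoints()
        rows.append({"gene": r["gene"], "p_start": p_start, "p_end": p_end,
                     "category": classify_dase(inp)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Exact Fisher test for 2x3 tables
# --------------------------------------------------------------------------

def fisher_exact_2x3(table, seed: int = 0, n_mc: int = 100_000):
    """Two-sided exact conditional test of independence in a 2x3 table.

    The p-value sums the hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed that of the
    observed table (probability-ordering two-sided rule). Exhaustive
    enumeration is used when the grand total is <= 500; beyond that a
    seeded Monte Carlo estimate over ``n_mc`` margin-preserving draws is
    returned (flagged via the second return value).

    Zero row/column margins are collapsed; a fully degenerate table has
    p = 1. Returns (pvalue, exact_flag).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("table must be a non-negative 2-D count array")
    if t.size:
        t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.size == 0 or min(t.shape) < 2:
        return 1.0, True
    total = int(t.sum())
    if total <= 500:
        return _fisher_enumerate(t), True
    return _fisher_montecarlo(t, seed=seed, n_mc=n_mc), False


def _log_table_prob(t, row_sums, col_sums, log_denom):
    return (np.sum(special.gammaln(row_sums + 1))
            + np.sum(special.gammaln(col_sums + 1))
            - log_denom - np.sum(special.gammaln(t + 1)))


def _fisher_enumerate(t: np.ndarray) -> float:
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())
    log_denom = special.gammaln(n + 1)
    obs = _log_table_prob(t, rows, cols, log_denom)
    p = 0.0
    r1 = int(rows[0])
    ncols = len(cols)

    def rec(j, remaining_r1, used):
        nonlocal p
        if j == ncols - 1:
            last = remaining_r1
            if 0 <= last <= cols[-1]:
                cand_top = used + [last]
                cand = np.array([cand_top, (cols - np.array(cand_top))])
                if np.all(cand >= 0):
                    lp = _log_table_prob(cand, rows, cols, log_denom)
                    if lp <= obs + 1e-9:
                        p += np.exp(lp)
            return
        for v in range(0, min(int(cols[j]), remaining_r1) + 1):
            rec(j + 1, remaining_r1 - v, used + [v])

    rec(0, r1, [])
    return float(min(p, 1.0))


def _fisher_montecarlo(t: np.ndarray, seed: int, n_mc: int) -> float:
    from scipy.stats import random_table

    rows, cols = t.sum(axis=1), t.sum(axis=0)
    log_denom = special.gammaln(t.sum() + 1)
    obs = _log_table_prob(t, rows, cols, log_denom)
    rng = np.random.default_rng(seed)
    draws = random_table(rows, cols).rvs(n_mc, random_state=rng)
    lp = (np.sum(special.gammaln(rows + 1))
          + np.sum(special.gammaln(cols + 1)) - log_denom
          - special.gammaln(draws + 1).sum(axis=(1, 2)))
    count = int(np.sum(lp <= obs + 1e-9))
    return float((count + 1) / (n_mc + 1))


def fisher_2x3_bruteforce(table) -> float:
    """Independent brute-force oracle: enumerate all tables with the same
    margins via nested loops. Only for small totals."""
    t = np.asarray(table, dtype=np.int64)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = int(t.sum())
    log_denom = special.gammaln(n + 1)
    obs = _log_table_prob(t, rows, cols, log_denom)
    p = 0.0
    for top in itertools.product(*(range(c + 1) for c in cols)):
        if sum(top) != rows[0]:
            continue
        cand = np.array([list(top), list(cols - np.array(top))])
        if np.any(cand < 0):
            continue
        lp = _log_table_prob(cand, rows, cols, log_denom)
        if lp <= obs + 1e-9:
            p += np.exp(lp)
    return float(min(p, 1.0))


# --------------------------------------------------------------------------
# Chromatin state recoding and association
# --------------------------------------------------------------------------

@dataclass
class ChromatinStateTrack:
    """Integer chromatin-state codes (1..15) at a gene's TSS: several
    start-condition epigenomes and one end-condition state."""
    gene_id: str
    states_start: np.ndarray
    state_end: int

    def __post_init__(self):
        self.states_start = np.asarray(self.states_start, dtype=np.int64)
        codes = np.append(self.states_start, self.state_end)
        if np.any((codes < 1) | (codes > 15)):
            raise ValueError("state codes must be in 1..15")


def recode_chromatin(track: ChromatinStateTrack) -> float:
    """Absolute activity change between conditions.

    States <= 7 (promoter/transcription/enhancer classes) are active (1),
    the rest inactive (0). The start condition averages its epigenomes;
    the change is |mean(start activity) - end activity| in [0, 1].
    """
    active_start = (track.states_start <= 7).astype(float)
    active_end = float(track.state_end <= 7)
    return float(abs(active_start.mean() - active_end))


def chromatin_assoc(change, is_dase, depth):
    """OLS of chromatin change on D-ASE status, adjusting for read depth.

    Fits change ~ I(D-ASE) + depth; returns (D, pvalue, group_means)
    where D is the adjusted D-ASE coefficient and group_means the raw
    means for (D-ASE, non-D-ASE) genes.
    """
    change = np.asarray(change, dtype=float)
    flag = np.asarray(is_dase, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if not (len(change) == len(flag) == len(depth)):
        raise ValueError("inputs must be aligned per gene")
    if (flag == 1).sum() < 3 or (flag == 0).sum() < 3:
        raise ValueError("need >= 3 genes in each group")
    X = sm.add_constant(np.column_stack([flag, depth]))
    fit = sm.OLS(change, X).fit()
    if np.ptp(change) == 0:
        return 0.0, 1.0, (float(change[flag == 1].mean()),
                          float(change[flag == 0].mean()))
    return (float(fit.params[1]), float(fit.pvalues[1]),
            (float(change[flag == 1].mean()), float(change[flag == 0].mean())))
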