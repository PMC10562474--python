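"""Benchmark harness: type-I error, power, precision-recall, and
phasing-concordance evaluation of differential-ASE methods on simulated
genes with known ground truth."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .downstream import fisher_exact_2x3
from .model import DASETestResult, DAESCMix, MixResults, test_gene
from .simulate import SimScenario, SimulatedGene, simulate_dataset

logger = logging.getLogger(__name__)


def evaluate_rejections(results: pd.DataFrame, truth: pd.DataFrame,
                        alpha: float = 0.05) -> dict:
    """Type-I error and power at a nominal p-value threshold.

    ``results`` needs columns gene/pvalue; ``truth`` gene/is_null (one
    row per gene suffices; per-donor truth frames are reduced). NA
    p-values count as non-rejections and are tallied separately. Power is
    NaN when no non-null genes are present.
    """
    gene_truth = truth.groupby("gene")["is_null"].first()
    missing = set(results["gene"]) - set(gene_truth.index)
    if missing:
        raise ValueError(f"genes without truth rows: {sorted(missing)[:5]}")
    merged = results.merge(gene_truth.rename("is_null"), on="gene")
    rej = merged["pvalue"] < alpha  # NA -> False
    null_mask = merged["is_null"].astype(bool)
    n_null = int(null_mask.sum())
    n_alt = int((~null_mask).sum())
    out = {
        "alpha": alpha,
        "n_null": n_null, "n_alt": n_alt,
        "n_na": int(merged["pvalue"].isna().sum()),
        "rejections_null": int(rej[null_mask].sum()),
        "rejections_alt": int(rej[~null_mask].sum()),
    }
    out["type1_error"] = out["rejections_null"] / n_null if n_null else np.nan
    out["power"] = out["rejections_alt"] / n_alt if n_alt else np.nan
    return out


def precision_recall(results: pd.DataFrame,
                     truth: pd.DataFrame) -> pd.DataFrame:
    """Precision/recall over the sweep of p-value thresholds.

    One curve point per distinct p-value; recall is monotone
    non-decreasing as the threshold loosens.
    """
    gene_truth = truth.groupby("gene")["is_null"].first()
    merged = results.merge(gene_truth.rename("is_null"), on="gene")
    merged = merged.dropna(subset=["pvalue"])
    n_pos = int((~merged["is_null"].astype(bool)).sum())
    if n_pos == 0:
        raise ValueError("no non-null genes: precision-recall undefined")
    pts = []
    for thr in np.sort(merged["pvalue"].unique()):
        called = merged["pvalue"] <= thr
        tp = int((called & ~merged["is_null"].astype(bool)).sum())
        pts.append({"threshold": float(thr),
                    "precision": tp / int(called.sum()),
                    "recall": tp / n_pos,
                    "n_called": int(called.sum())})
    return pd.DataFrame(pts)


def phasing_concordance(fit: MixResults, truth: SimulatedGene,
                        seed: int = 0):
    """Fisher exact association between mixture labels and true z.

    Donors are hard-assigned to mixture groups by responsibility > 0.5;
    the 2 x 3 table crosses assignment with z_true in {-1, +1, 0}.
    Returns (pvalue, table).
    """
    if len(fit.donors) != len(truth.z_true):
        raise ValueError("fit and truth must share donors")
    group = (fit.resp > 0.5).astype(int)
    table = np.zeros((2, 3), dtype=np.int64)
    zcol = {-1: 0, 1: 1, 0: 2}
    for g, z in zip(group, truth.z_true):
        table[g, zcol[int(np.sign(z))]] += 1
    pval, _ = fisher_exact_2x3(table, seed=seed)
    return pval, table


def run_scenario(scenario: SimScenario, methods=("daesc-bb",),
                 generator: str = "betabin",
                 library: pd.DataFrame | None = None,
                 tol: float = 1e-6, max_iter: int = 200,
                 alpha: float = 0.05):
    """Simulate one scenario and test every gene with every method.

    Returns (metrics frame, results frame, genes). The metrics frame has
    one row per method carrying rejection counts and denominators, not
    only fractions.
    """
    counts, truth, genes = simulate_dataset(scenario, library=library,
                                            generator=generator)
    from .data import iter_genes
    from .glmm import glmm_test

    all_rows = []
    for gene_data in iter_genes(counts):
        for method in methods:
            if method == "glmm":
                res = glmm_test(gene_data)
            else:
                res = test_gene(gene_data, method=method, tol=tol,
                                max_iter=max_iter)
            row = res.to_row()
            all_rows.append(row)
    results = pd.DataFrame(all_rows)
    metrics = []
    for method in methods:
        sub = results[results["method"] == method]
        m = evaluate_rejections(sub, truth, alpha=alpha)
        m.update({"method": method, "r2": scenario.r2,
                  "n_donors": scenario.n_donors,
                  "covariate": scenario.covariate})
        metrics.append(m)
    return pd.DataFrame(metrics), results, genes


def grid_study(seed: int = 0, n_null: int = 30, n_alt: int = 6,
               cells_per_donor=(15, 2.0), depth=(15, 0.8),
               r2_values=(0.0, 0.1, 0.9), n_values=(10, 50, 100),
               include_glmm: bool = True, tol: float = 1e-5,
               max_iter: int = 100):
    """Run the full r^2 x N benchmark grid with the mixture model (and
    optionally the GLMM), reusing each full mixture fit for the
    label-vs-truth Fisher concordance check.

    Returns (pvalue frame, fisher frame). The pvalue frame has one row
    per gene per method with scenario annotations; the fisher frame has
    the 2x3 exact-test p-value of mixture labels against the true
    haplotype configuration for every gene.
    """
    from .glmm import glmm_test
    from .model import lrt_pvalue

    rows, fisher = [], []
    idx = 0
    for r2 in r2_values:
        for N in n_values:
            idx += 1
            sc = SimScenario(n_donors=N, cells_per_donor=cells_per_donor,
                             depth=depth, r2=r2, n_null=n_null,
                             n_alt=n_alt,
                             seed=(seed * 97 + idx * 1009) % (2 ** 31))
            _, _, genes = simulate_dataset(sc)
            for g in genes:
                tag = dict(r2=r2, n_donors=N, gene=g.data.gene_id,
                           is_null=g.is_null)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    res, full, _ = DAESCMix(g.data).lr_test(
                        tol=tol, max_iter=max_iter, return_fits=True)
                rows.append({**tag, "method": "daesc-mix",
                             "pvalue": res.pvalue})
                fp, _ = phasing_concordance(full, g, seed=seed + idx)
                fisher.append({**tag, "fisher_p": fp})
                if include_glmm:
                    gres = glmm_test(g.data)
                    rows.append({**tag, "method": "glmm",
                                 "pvalue": gres.pvalue})
    return pd.DataFrame(rows), pd.DataFrame(fisher)


def mean_type1_error(pframe: pd.DataFrame, method: str,
                     alpha: float = 0.05) -> float:
    """Type-I error averaged over scenarios (equal scenario weights)."""
    sub = pframe[(pframe["method"] == method) & pframe["is_null"]]
    per = sub.groupby(["r2", "n_donors"]).apply(
        lambda d: float((d["pvalue"] < alpha).mean()),
        include_groups=False)
    return float(per.mean())


def phasing_effectiveness(genes, tol: float = 1e-5, max_iter: int = 100,
                          alpha: float = 0.05, seed: int = 0) -> dict:
    """Fraction of simulated genes whose mixture labels associate with the
    true haplotype configuration (Fisher 2x3 p < alpha)."""
    n_sig = n_tested = 0
    for k, gene in enumerate(genes):
        if gene.data.n_donors < 4:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                fit = DAESCMix(gene.data).fit(tol=tol, max_iter=max_iter)
            pval, _ = phasing_concordance(fit, gene, seed=seed + k)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("%s: concordance failed (%s)", gene.data.gene_id,
                           exc)
            continue
        n_tested += 1
        n_sig += pval < alpha
    return {"n_tested": n_tested, "n_significant": int(n_sig),
            "fraction_significant": n_sig / n_tested if n_tested else np.nan}
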