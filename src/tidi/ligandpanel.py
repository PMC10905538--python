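"""NK receptor-ligand panel summaries over annotated expression matrices.

Joins phenotypic response labels (responder / nonresponder, from the trap
assay) to a processed, log-normalized gene-by-cell expression matrix and
summarizes a packaged panel of NK-92 receptor-ligand pairs per response
group.  The packaged default panel has 22 receptor entries (11 inhibiting,
10 activating, 1 signalling both ways) covering the MHC-I/HLA-E inhibitory
axis, NKG2D/ULBP and other activating ligands, and adhesion molecules.

Group differences are ranked with a two-sided Wilcoxon rank-sum test,
Benjamini-Hochberg adjusted across panel genes; the test choice is this
package's own addition for reproducible ranking.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SIGNAL_CLASSES = {"inhibiting", "activating", "both", "adhesion-associated"}
REQUIRED_ANNOTATIONS = ("line_id", "patient", "site", "response")


def load_panel(path=None, signal_class: str | None = None) -> pd.DataFrame:
    """Load the receptor-ligand panel (packaged default if no path).

    Columns: nk_receptor, alias, signal_class, ligand_genes (list of gene
    symbols), reported_expression_level.
    """
    if path is None:
        ref = importlib.resources.files("tidi").joinpath(
            "data/table2_panel.csv")
        with importlib.resources.as_file(ref) as p:
            panel = pd.read_csv(p)
    else:
        panel = pd.read_csv(path)
    if len(panel) == 0:
        raise ValueError("empty panel file")
    bad = set(panel["signal_class"]) - SIGNAL_CLASSES
    if bad:
        raise ValueError(f"unknown signal_class values: {sorted(bad)}")
    panel = panel.copy()
    panel["ligand_genes"] = panel["ligand_genes"].map(
        lambda s: [g for g in str(s).split(";") if g])
    if (panel["ligand_genes"].map(len) == 0).any():
        raise ValueError("entry with no ligand genes")
    if signal_class is not None:
        panel = panel[panel["signal_class"] == signal_class].reset_index(
            drop=True)
    return panel


def panel_genes(panel: pd.DataFrame) -> list[str]:
    """Unique gene symbols across the panel, in first-appearance order."""
    seen, out = set(), []
    for genes in panel["ligand_genes"]:
        for g in genes:
            if g not in seen:
                seen.add(g)
                out.append(g)
    return out


def _as_matrix(expr):
    """Accept an AnnData (cells x genes) or a genes-by-cells DataFrame plus
    obs annotations; return (values cells x genes, var_names, obs)."""
    try:
        import anndata
        if isinstance(expr, anndata.AnnData):
            X = expr.X
            X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
            return X, list(expr.var_names), expr.obs
    except ImportError:          # pragma: no cover
        pass
    raise TypeError("expr must be an AnnData with per-cell annotations")


def summarize_by_group(expr, panel: pd.DataFrame,
                       group_key: str = "response") -> dict:
    """Per-gene, per-group expression summaries for the panel genes.

    Returns ``{"summary": DataFrame, "missing_genes": [..]}``; summary
    columns: gene, group, mean, median, frac_positive, n_cells.  Panel
    genes absent from the matrix are reported, not fatal.
    """
    X, var_names, obs = _as_matrix(expr)
    for key in REQUIRED_ANNOTATIONS:
        if key not in obs.columns:
            raise ValueError(f"missing cell annotation: {key}")
    genes = panel_genes(panel)
    pos = {g: i for i, g in enumerate(var_names)}
    missing = [g for g in genes if g not in pos]
    found = [g for g in genes if g in pos]
    rows = []
    for group in sorted(obs[group_key].unique()):
        mask = (obs[group_key] == group).to_numpy()
        sub = X[mask]
        for g in found:
            v = sub[:, pos[g]]
            rows.append((g, group, float(v.mean()), float(np.median(v)),
                         float((v > 0).mean()), int(mask.sum())))
    summary = pd.DataFrame(rows, columns=["gene", "group", "mean", "median",
                                          "frac_positive", "n_cells"])
    return {"summary": summary, "missing_genes": missing}


def rank_group_differences(expr, panel: pd.DataFrame,
                           group_key: str = "response",
                           test: str = "wilcoxon") -> pd.DataFrame:
    """Rank panel genes by between-group shift with a rank-sum test.

    Requires exactly two groups.  Output columns: gene, delta_median
    (group2 - group1 in sorted group order), p_value, p_adj (BH across
    panel genes), sorted by |delta_median| descending then adjusted p.
    """
    if test != "wilcoxon":
        raise ValueError("only the wilcoxon rank-sum test is supported")
    X, var_names, obs = _as_matrix(expr)
    groups = sorted(obs[group_key].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    mask1 = (obs[group_key] == groups[0]).to_numpy()
    mask2 = (obs[group_key] == groups[1]).to_numpy()
    pos = {g: i for i, g in enumerate(var_names)}
    rows = []
    for g in panel_genes(panel):
        if g not in pos:
            continue
        a, b = X[mask1, pos[g]], X[mask2, pos[g]]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(stats.ranksums(a, b).pvalue)
        rows.append((g, float(np.median(b) - np.median(a)), p))
    out = pd.DataFrame(rows, columns=["gene", "delta_median", "p_value"])
    out["p_adj"] = _bh_adjust(out["p_value"].to_numpy())
    out = out.sort_values(["delta_median", "p_adj"],
                          key=lambda s: -s.abs() if s.name == "delta_median"
                          else s, kind="stable")
    return out.reset_index(drop=True)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out
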