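"""Expression-side statistics for the parent/parent/hybrid trio.

Covers actively expressed genes (FPKM >= 1), specifically expressed genes
(SEGs), replicate/sample correlation, trio DEG categories (Up / Down /
B2P, where B2P means the hybrid sits strictly between the two parental
means), mid-parent and high-parent heterosis (MPH / HPH), and a simple
Welch + Benjamini-Hochberg two-group test for synthetic data. The simple
test is not equivalent to a negative-binomial DE model fitted on counts;
real differential-expression tables can be supplied as inputs instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SAMPLES",
    "ExpressionTable",
    "TrioDEGReport",
    "active_genes",
    "specific_genes",
    "sample_correlation",
    "simple_de_test",
    "classify_trio_degs",
    "heterosis_stats",
    "percent_breakdown",
]

SAMPLES = ("P1", "P2", "F1")


@dataclass
class ExpressionTable:
    """FPKM per gene per sample replicate.

    Columns are ``{sample}_{replicate}`` (e.g. ``F1_2``); the index is the
    gene id. All values must be finite and non-negative, with every gene
    measured in every sample replicate.
    """

    data: pd.DataFrame
    samples: tuple[str, ...] = SAMPLES
    n_reps: int = 3

    def __post_init__(self) -> None:
        expected = [f"{s}_{r}" for s in self.samples for r in range(1, self.n_reps + 1)]
        missing = [c for c in expected if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing replicate columns: {missing}")
        vals = self.data[expected].to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("FPKM values must be finite and >= 0")
        self.data = self.data[expected]

    def sample_columns(self, sample: str) -> list[str]:
        return [f"{sample}_{r}" for r in range(1, self.n_reps + 1)]

    def sample_mean(self, sample: str) -> pd.Series:
        return self.data[self.sample_columns(sample)].mean(axis=1)

    @classmethod
    def read_tsv(cls, path: str | Path, **kw) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0), **kw)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


def active_genes(expr: ExpressionTable, sample: str) -> pd.Index:
    """Genes actively expressed in a sample: mean FPKM >= 1 (inclusive)."""
    mean = expr.sample_mean(sample)
    return mean.index[mean >= 1.0]


def specific_genes(expr: ExpressionTable) -> tuple[dict[str, pd.Index], pd.DataFrame]:
    """Per-sample SEG sets and pairwise common/specific Venn counts.

    A SEG of a sample is active in that sample and in neither of the other
    two samples.
    """
    active = {s: set(active_genes(expr, s)) for s in expr.samples}
    segs = {}
    for s in expr.samples:
        others = set().union(*(active[o] for o in expr.samples if o != s))
        segs[s] = pd.Index(sorted(active[s] - others))
    rows = []
    for i, a in enumerate(expr.samples):
        for b in expr.samples[i + 1:]:
            common = active[a] & active[b]
            rows.append(
                (a, b, len(common), len(active[a] - active[b]), len(active[b] - active[a]))
            )
    venn = pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "common", "a_specific", "b_specific"]
    )
    return segs, venn


def sample_correlation(expr: ExpressionTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Squared Pearson correlation (R^2) on log2(FPKM + 1).

    Returns the replicate-level 9x9 matrix and the sample-level 3x3 matrix
    of mean replicate profiles. Zero-variance columns yield NaN with a
    warning.
    """
    logv = np.log2(expr.data + 1.0)
    zero_var = logv.std(axis=0) == 0
    if zero_var.any():
        warnings.warn(f"zero-variance replicates: {list(logv.columns[zero_var])}")
    rep_r2 = logv.corr() ** 2
    means = pd.DataFrame({s: logv[expr.sample_columns(s)].mean(axis=1) for s in expr.samples})
    sample_r2 = means.corr() ** 2
    return rep_r2, sample_r2


def simple_de_test(
    expr: ExpressionTable, group_a: str, group_b: str
) -> pd.DataFrame:
    """Welch two-sample test per gene on log2(FPKM + 1), BH-adjusted.

    ``log2fc`` is log2((mean_a + 1) / (mean_b + 1)) so positive values mean
    higher expression in ``group_a``; a gene is a DEG iff padj < 0.05 and
    |log2fc| > 1 (strict). Genes with zero variance in both groups get
    p = 1 when the means agree and p = 0 otherwise.
    """
    la = np.log2(expr.data[expr.sample_columns(group_a)].to_numpy() + 1.0)
    lb = np.log2(expr.data[expr.sample_columns(group_b)].to_numpy() + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    mean_a = expr.sample_mean(group_a).to_numpy()
    mean_b = expr.sample_mean(group_b).to_numpy()
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate & np.isclose(la.mean(1), lb.mean(1)), 1.0, p)
    p = np.where(~np.isfinite(p), 0.0, p)
    padj = multipletests(p, method="fdr_bh")[1]
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    out = pd.DataFrame(
        {
            "gene_id": expr.data.index,
            "log2fc": log2fc,
            "pvalue": p,
            "padj": padj,
        }
    )
    out["is_deg"] = (out["padj"] < 0.05) & (out["log2fc"].abs() > 1.0)
    return out


@dataclass
class TrioDEGReport:
    """Up/Down(/B2P) counts and percentages per contrast and for the trio set."""

    table: pd.DataFrame  # contrast, up, down, b2p, total, up_pct, down_pct, b2p_pct
    trio_genes: pd.DataFrame  # gene_id, category


def percent_breakdown(counts: Sequence[int]) -> list[float]:
    """Percentages of a count vector, rounded to 2 decimal places."""
    total = sum(counts)
    if total == 0:
        return [0.0 for _ in counts]
    return [round(100.0 * c / total, 2) for c in counts]


def classify_trio_degs(
    degs: Mapping[str, pd.DataFrame], expr: ExpressionTable
) -> TrioDEGReport:
    """Tabulate DEG direction per contrast and the trio Up/Down/B2P split.

    ``degs`` maps contrast names 'P1vsP2', 'F1vsP1', 'F1vsP2' to tables
    with gene_id, log2fc (first sample over the reference after "vs.") and
    is_deg. Trio DEGs are genes significant in both F1 contrasts: Up if the
    F1 mean exceeds both parent means, Down if below both, B2P if strictly
    between. With equal parent means a trio DEG is Up or Down relative to
    that common value (B2P impossible).
    """
    rows = []
    for contrast in ("P1vsP2", "F1vsP1", "F1vsP2"):
        d = degs[contrast]
        sig = d[d["is_deg"]]
        up = int((sig["log2fc"] > 0).sum())
        down = int((sig["log2fc"] < 0).sum())
        pct = percent_breakdown([up, down])
        rows.append((contrast, up, down, 0, up + down, pct[0], pct[1], 0.0))

    f1p1 = degs["F1vsP1"].set_index("gene_id")
    f1p2 = degs["F1vsP2"].set_index("gene_id")
    trio_ids = f1p1.index[f1p1["is_deg"]].intersection(f1p2.index[f1p2["is_deg"]])
    mean_f1 = expr.sample_mean("F1")
    mean_p1 = expr.sample_mean("P1")
    mean_p2 = expr.sample_mean("P2")
    cats = []
    for g in trio_ids:
        f1, p1, p2 = mean_f1[g], mean_p1[g], mean_p2[g]
        if f1 >= max(p1, p2):
            cats.append("Up")
        elif f1 <= min(p1, p2):
            cats.append("Down")
        else:
            cats.append("B2P")
    trio = pd.DataFrame({"gene_id": trio_ids, "category": cats})
    up = int((trio["category"] == "Up").sum())
    down = int((trio["category"] == "Down").sum())
    b2p = int((trio["category"] == "B2P").sum())
    pct = percent_breakdown([up, down, b2p])
    rows.append(("F1vsBoth", up, down, b2p, up + down + b2p, pct[0], pct[1], pct[2]))
    table = pd.DataFrame(
        rows,
        columns=["contrast", "up", "down", "b2p", "total", "up_pct", "down_pct", "b2p_pct"],
    )
    return TrioDEGReport(table=table, trio_genes=trio)


def heterosis_stats(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Mid-parent and high-parent heterosis per trait, in percent.

    ``phenotypes`` has columns trait, sample (P1/P2/F1), value — one row
    per replicate. MPH = (F1 mean - mid-parent mean) / mid-parent mean x
    100; HPH uses the better (larger-mean) parent. Non-positive parent
    means are an error. Both statistics are invariant under rescaling all
    values by a positive constant.
    """
    rows = []
    for trait, grp in phenotypes.groupby("trait", sort=False):
        means = grp.groupby("sample")["value"].mean()
        for s in SAMPLES:
            if s not in means:
                raise ValueError(f"trait {trait}: missing sample {s}")
        p1, p2, f1 = means["P1"], means["P2"], means["F1"]
        if p1 <= 0 or p2 <= 0:
            raise ValueError(f"trait {trait}: non-positive parent mean")
        mid = (p1 + p2) / 2.0
        best = max(p1, p2)
        rows.append(
            (trait, 100.0 * (f1 - mid) / mid, 100.0 * (f1 - best) / best)
        )
    return pd.DataFrame(rows, columns=["trait", "mph_percent", "hph_percent"])
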