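"""A/B compartment calling and parent/parent/hybrid shift classification.

Compartments are called per chromosome at coarse (typically 100 kb)
resolution: the balanced cis matrix is turned into an observed/expected
matrix, its Pearson correlation matrix is computed over unmasked bins, and
the first principal component of that correlation matrix scores every bin.
The sign is oriented per chromosome so that the positive (A) side has the
higher mean gene density — A compartments are the gene-dense, transcrip-
tionally active fraction of the genome.

Trio states are written parent-first: ``P1-to-P2-to-F1`` (e.g. a bin that
is B in both parents and A in the hybrid reads ``B-to-B-to-A``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .matrix_ops import BinTable, ContactMatrix, assign_genes_to_bins, expected_by_distance

__all__ = [
    "CompartmentTrack",
    "ShiftTable",
    "ShiftReport",
    "CompartmentExpression",
    "ALL_TRIO_STATES",
    "call_compartments",
    "compartment_expression_contrast",
    "classify_shifts",
    "aggregate_shift_percentages",
    "pairwise_shift_genes",
]

ALL_TRIO_STATES = tuple(
    f"{a}-to-{b}-to-{c}" for a in "AB" for b in "AB" for c in "AB"
)


@dataclass
class CompartmentTrack:
    """Per-bin PC1 score and A/B label for one sample.

    ``label`` is ``A`` iff ``pc1 > 0`` after gene-density orientation;
    masked bins carry the label ``masked`` and a NaN score.
    """

    sample: str
    df: pd.DataFrame  # chrom, start, end, bin_id, pc1, label

    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()


@dataclass
class ShiftTable:
    """Per-bin compartment state of all three samples plus the trio state."""

    df: pd.DataFrame  # chrom, start, end, bin_id, state_P1, state_P2, state_F1, trio_state


@dataclass
class ShiftReport:
    """Percentages of unmasked bins in each of the 8 trio states (2 dp)."""

    n_bins: int
    state_percent: dict[str, float]
    aggregates: dict[str, float]


@dataclass
class CompartmentExpression:
    """Gene counts and expression summary per compartment label."""

    n_a: int
    n_b: int
    mean_log2_a: float
    mean_log2_b: float
    pvalue: float


def call_compartments(
    m: ContactMatrix,
    genes: pd.DataFrame,
    sample: str = "",
    min_bins: int = 10,
) -> CompartmentTrack:
    """Call A/B compartments on a balanced matrix by O/E correlation PCA.

    Chromosomes with fewer than ``min_bins`` usable bins, or with a
    degenerate (zero-variance) correlation matrix, are fully masked with a
    warning. Orientation ties (equal mean gene density on both sides) keep
    the PCA's native sign, with a warning.
    """
    if m.state != "balanced":
        raise ValueError("call_compartments expects a balanced matrix")
    gene_bins = assign_genes_to_bins(genes, m.bins)
    density = np.bincount(gene_bins[gene_bins >= 0], minlength=m.bins.n_bins)
    decay = expected_by_distance(m)

    pc1 = np.full(m.bins.n_bins, np.nan)
    label = np.full(m.bins.n_bins, "masked", dtype=object)
    for chrom, sl in m.bins.chrom_slices().items():
        W = m.counts[sl, sl]
        mk = m.mask[sl].copy()
        idx = np.where(mk)[0]
        if idx.size < min_bins:
            warnings.warn(f"{chrom}: fewer than {min_bins} unmasked bins; masked")
            continue
        exp = decay.values[chrom]
        dist = np.abs(idx[:, None] - idx[None, :])
        E = exp[dist]
        O = W[np.ix_(idx, idx)]
        with np.errstate(divide="ignore", invalid="ignore"):
            OE = np.where(E > 0, O / np.where(E > 0, E, 1.0), 0.0)
        keep = OE.std(axis=1) > 0
        idx = idx[keep]
        if idx.size < min_bins:
            warnings.warn(f"{chrom}: fewer than {min_bins} informative bins; masked")
            continue
        corr = np.corrcoef(OE[np.ix_(keep, keep)])
        pca = PCA(n_components=1, svd_solver="full")
        scores = pca.fit_transform(corr)[:, 0]
        if pca.explained_variance_[0] <= 1e-12:
            warnings.warn(f"{chrom}: degenerate correlation matrix; masked")
            continue
        scores = _orient_by_gene_density(scores, density[sl][idx], chrom)
        pc1[sl.start + idx] = scores
        label[sl.start + idx] = np.where(scores > 0, "A", "B")

    df = m.bins.df.copy()
    df["pc1"] = pc1
    df["label"] = label
    return CompartmentTrack(sample=sample, df=df)


def _orient_by_gene_density(scores: np.ndarray, density: np.ndarray, chrom: str) -> np.ndarray:
    pos = scores > 0
    neg = scores < 0
    if not pos.any() or not neg.any():
        warnings.warn(f"{chrom}: one-sided PC1; orientation left as computed")
        return scores
    mean_pos = density[pos].mean()
    mean_neg = density[neg].mean()
    if np.isclose(mean_pos, mean_neg):
        warnings.warn(f"{chrom}: gene-density tie; orientation left as computed")
        return scores
    return -scores if mean_pos < mean_neg else scores


def compartment_expression_contrast(
    track: CompartmentTrack,
    genes: pd.DataFrame,
    expr,
    sample: str | None = None,
    bins: BinTable | None = None,
) -> CompartmentExpression:
    """Contrast gene expression between A and B bins of one sample.

    Genes are assigned to bins by midpoint; expression is the per-sample
    mean FPKM on the log2(FPKM + 1) scale, compared with a two-sided
    rank-sum (Mann-Whitney) test.
    """
    if sample is None:
        sample = track.sample
    if bins is None:
        res = int((track.df["end"] - track.df["start"]).max())
        bins = BinTable(track.df[["chrom", "start", "end", "bin_id"]].copy(), res)
    gene_bins = assign_genes_to_bins(genes, bins)
    labels = track.labels()
    mean_fpkm = expr.sample_mean(sample)
    vals = np.log2(mean_fpkm.reindex(genes["gene_id"]).to_numpy() + 1.0)
    ok = gene_bins >= 0
    gl = np.where(ok, labels[np.clip(gene_bins, 0, None)], "masked")
    a_vals = vals[(gl == "A") & np.isfinite(vals)]
    b_vals = vals[(gl == "B") & np.isfinite(vals)]
    if a_vals.size == 0 or b_vals.size == 0:
        return CompartmentExpression(a_vals.size, b_vals.size, np.nan, np.nan, np.nan)
    pooled = np.concatenate([a_vals, b_vals])
    if np.all(pooled == pooled[0]):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a_vals, b_vals, alternative="two-sided").pvalue)
    return CompartmentExpression(
        n_a=int(a_vals.size),
        n_b=int(b_vals.size),
        mean_log2_a=float(a_vals.mean()),
        mean_log2_b=float(b_vals.mean()),
        pvalue=p,
    )


def classify_shifts(
    p1: CompartmentTrack, p2: CompartmentTrack, f1: CompartmentTrack
) -> tuple[ShiftTable, ShiftReport]:
    """Per-bin trio state over bins unmasked in all three samples.

    Percentages are reported to 2 decimal places over the common unmasked
    bins; aggregate categories are sums of the corresponding state
    percentages (see :func:`aggregate_shift_percentages`).
    """
    bt = BinTable(p1.df[["chrom", "start", "end", "bin_id"]].copy(),
                  int((p1.df["end"] - p1.df["start"]).max()))
    for other in (p2, f1):
        ob = BinTable(other.df[["chrom", "start", "end", "bin_id"]].copy(), bt.resolution)
        if not bt.same_bins(ob):
            raise ValueError("compartment tracks are on different bin tables")
    s1, s2, sf = p1.labels(), p2.labels(), f1.labels()
    unmasked = (s1 != "masked") & (s2 != "masked") & (sf != "masked")
    trio = np.full(len(s1), "masked", dtype=object)
    trio[unmasked] = [
        f"{a}-to-{b}-to-{c}"
        for a, b, c in zip(s1[unmasked], s2[unmasked], sf[unmasked])
    ]
    df = p1.df[["chrom", "start", "end", "bin_id"]].copy()
    df["state_P1"] = s1
    df["state_P2"] = s2
    df["state_F1"] = sf
    df["trio_state"] = trio

    n = int(unmasked.sum())
    pct = {}
    for state in ALL_TRIO_STATES:
        count = int((trio == state).sum())
        pct[state] = round(100.0 * count / n, 2) if n else 0.0
    report = ShiftReport(n_bins=n, state_percent=pct,
                         aggregates=aggregate_shift_percentages(pct))
    return ShiftTable(df), report


def aggregate_shift_percentages(state_percent: Mapping[str, float]) -> dict[str, float]:
    """Sum printed per-state percentages into the standard aggregates.

    States read parent-first (P1-to-P2-to-F1). ``f1_a_gain_parents_disagree``
    totals the two states where the parents disagree and the hybrid resolves
    to A; ``f1_a_gain_any`` additionally counts the rarer state where the
    hybrid turns A against both parents.
    """
    g = lambda k: state_percent.get(k, 0.0)
    return {
        "unchanged": round(g("A-to-A-to-A") + g("B-to-B-to-B"), 2),
        "f1_a_gain_parents_disagree": round(g("A-to-B-to-A") + g("B-to-A-to-A"), 2),
        "f1_b_gain_parents_disagree": round(g("A-to-B-to-B") + g("B-to-A-to-B"), 2),
        "f1_differs_from_both_a": round(g("B-to-B-to-A"), 2),
        "f1_differs_from_both_b": round(g("A-to-A-to-B"), 2),
        "f1_a_gain_any": round(
            g("A-to-B-to-A") + g("B-to-A-to-A") + g("B-to-B-to-A"), 2
        ),
    }


def pairwise_shift_genes(
    parent: CompartmentTrack, f1: CompartmentTrack, genes: pd.DataFrame
) -> pd.DataFrame:
    """Genes whose midpoint bin shifts compartment between a parent and F1.

    Returns one row per gene in an ``A-to-B`` or ``B-to-A`` bin (parent
    state first), over bins unmasked in both samples.
    """
    res = int((parent.df["end"] - parent.df["start"]).max())
    bins = BinTable(parent.df[["chrom", "start", "end", "bin_id"]].copy(), res)
    gene_bins = assign_genes_to_bins(genes, bins)
    sp, sf = parent.labels(), f1.labels()
    rows = []
    for k, b in enumerate(gene_bins):
        if b < 0:
            continue
        a, c = sp[b], sf[b]
        if "masked" in (a, c) or a == c:
            continue
        rows.append((genes["gene_id"].iloc[k], genes["chrom"].iloc[k], int(b), f"{a}-to-{c}"))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "bin_id", "shift"])
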