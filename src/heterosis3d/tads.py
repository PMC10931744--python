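"""Directionality-index TAD calling and cross-sample TAD comparison.

The directionality index (DI) contrasts each bin's upstream and downstream
contact sums within a fixed window: with A the upstream sum, B the
downstream sum and E = (A + B) / 2,

    DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E)

DI is 0 when A == B or E == 0. Boundaries are placed where a smoothed DI
track switches from a sustained-negative run (domain end) to a
sustained-positive run (next domain start); the intervals between
consecutive boundaries are the domains.

Conserved vs specific domains, the 10%-tail activated/repressed
classification by mean fold change of member genes, and DI-window boundary
correlation follow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix_ops import BinTable, ContactMatrix

__all__ = [
    "DITrack",
    "TADSet",
    "TADComparison",
    "directionality_index",
    "call_tads",
    "tad_boundaries",
    "compare_tads",
    "classify_tad_activity",
    "boundary_specificity",
    "tad_length_stats",
    "assign_genes_to_tads",
]


@dataclass
class DITrack:
    """Per-bin directionality index for one sample.

    ``truncated`` flags bins whose window runs past a chromosome end; they
    are computed with the truncated window but excluded from boundary
    correlation.
    """

    sample: str
    window_bp: int
    df: pd.DataFrame  # chrom, start, end, bin_id, di, truncated


@dataclass
class TADSet:
    """Non-overlapping, sorted domains for one sample at bin granularity."""

    sample: str
    df: pd.DataFrame  # chrom, start, end (bp)
    resolution: int


@dataclass
class TADComparison:
    """Reference-sample domains vs one other sample.

    ``status`` is conserved iff some domain of the other sample matches both
    boundaries within the tolerance; ``activity`` (activated / repressed /
    other / NA) is assigned only to conserved domains with expressed genes.
    """

    ref_sample: str
    other_sample: str
    tol_bins: int
    df: pd.DataFrame  # chrom, start, end, status, activity, fc_fraction, mean_log2fc, n_genes
    counts: dict = field(default_factory=dict)


def directionality_index(m: ContactMatrix, window_bp: int) -> DITrack:
    """Compute the DI track on a balanced cis matrix."""
    res = m.bins.resolution
    w = window_bp // res
    if w < 1:
        raise ValueError("DI window must cover at least one bin")
    di = np.full(m.bins.n_bins, np.nan)
    trunc = np.zeros(m.bins.n_bins, dtype=bool)
    for chrom, sl in m.bins.chrom_slices().items():
        W = m.counts[sl, sl]
        mk = m.mask[sl]
        n = W.shape[0]
        for i in range(n):
            if not mk[i]:
                continue
            lo = max(0, i - w)
            hi = min(n, i + w + 1)
            trunc[sl.start + i] = (i - w < 0) or (i + w + 1 > n)
            a = float(W[i, lo:i].sum())
            b = float(W[i, i + 1:hi].sum())
            e = (a + b) / 2.0
            if a == b or e == 0:
                di[sl.start + i] = 0.0
            else:
                di[sl.start + i] = math.copysign(
                    (a - e) ** 2 / e + (b - e) ** 2 / e, b - a
                )
    df = m.bins.df.copy()
    df["di"] = di
    df["truncated"] = trunc
    return DITrack(sample="", window_bp=window_bp, df=df)


def _running_mean(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return x.astype(float)
    num = np.convolve(x, np.ones(k), mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), np.ones(k), mode="same")
    return num / den


def _sign_runs(signs: np.ndarray) -> list[tuple[int, int, int]]:
    """Compress a sign vector into (sign, start, length) runs."""
    runs = []
    start = 0
    for i in range(1, len(signs) + 1):
        if i == len(signs) or signs[i] != signs[start]:
            runs.append((int(signs[start]), start, i - start))
            start = i
    return runs


def call_tads(
    di: DITrack,
    min_tad_bins: int = 5,
    persistence: int = 3,
    smooth_bins: int = 3,
) -> TADSet:
    """Call domains from DI sign changes.

    A boundary is the first bin of a sustained-positive run (length >=
    ``persistence``) that follows a sustained-negative run of the same
    minimum length, intervening zero-DI bins permitted. Domains shorter
    than ``min_tad_bins`` are dropped. Deterministic for fixed parameters
    and invariant to positive scaling of the matrix.
    """
    rows = []
    for chrom, grp in di.df.groupby("chrom", sort=False):
        x = np.nan_to_num(grp["di"].to_numpy(), nan=0.0)
        n = len(x)
        signs = np.sign(_running_mean(x, smooth_bins))
        boundaries = []
        last_sig: tuple[int, int] | None = None  # (sign, length)
        for sgn, start, length in _sign_runs(signs):
            if sgn == 0:
                continue
            if (
                sgn > 0
                and length >= persistence
                and last_sig is not None
                and last_sig[0] < 0
                and last_sig[1] >= persistence
            ):
                boundaries.append(start)
            last_sig = (sgn, length)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        edges = [0] + boundaries + [n]
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a >= min_tad_bins:
                rows.append((chrom, int(starts[a]), int(ends[b - 1])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return TADSet(sample=di.sample, df=df, resolution=int(di.df["end"].sub(di.df["start"]).max()))


def tad_boundaries(t: TADSet, internal_only: bool = True) -> pd.DataFrame:
    """Domain start positions as (chrom, chrom-local bin index).

    With ``internal_only`` the boundary at each chromosome start is dropped.
    """
    rows = []
    for chrom, grp in t.df.groupby("chrom", sort=False):
        for s in grp["start"]:
            b = int(s) // t.resolution
            if internal_only and b == 0:
                continue
            rows.append((chrom, b))
    return pd.DataFrame(rows, columns=["chrom", "bin"])


def compare_tads(ref: TADSet, other: TADSet, tol_bins: int = 1) -> TADComparison:
    """Conserved/specific status of every reference domain.

    A reference domain is conserved iff some domain of the other sample has
    both boundaries within ``tol_bins`` bins; symmetric counts for the Venn
    are reported in ``counts``.
    """
    tol = tol_bins * ref.resolution

    def status(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
        out = np.empty(len(a), dtype=object)
        for i, (chrom, s, e) in enumerate(zip(a["chrom"], a["start"], a["end"])):
            cand = b[b["chrom"] == chrom]
            hit = (
                (np.abs(cand["start"].to_numpy() - s) <= tol)
                & (np.abs(cand["end"].to_numpy() - e) <= tol)
            ).any()
            out[i] = "conserved" if hit else "specific"
        return out

    df = ref.df.copy()
    df["status"] = status(ref.df, other.df)
    df["activity"] = "NA"
    df["fc_fraction"] = np.nan
    df["mean_log2fc"] = np.nan
    df["n_genes"] = 0
    other_status = status(other.df, ref.df)
    counts = {
        "ref_conserved": int((df["status"] == "conserved").sum()),
        "ref_specific": int((df["status"] == "specific").sum()),
        "other_conserved": int((other_status == "conserved").sum()),
        "other_specific": int((other_status == "specific").sum()),
    }
    return TADComparison(ref.sample, other.sample, tol_bins, df, counts)


def assign_genes_to_tads(domains: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    """Row index in ``domains`` containing each gene midpoint (-1 if none)."""
    out = np.full(len(genes), -1, dtype=int)
    mid = (genes["start"].to_numpy() + genes["end"].to_numpy()) // 2
    for chrom, grp in domains.groupby("chrom", sort=False):
        sel = np.where(genes["chrom"].to_numpy() == chrom)[0]
        if sel.size == 0:
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        ridx = grp.index.to_numpy()[order]
        pos = np.searchsorted(starts, mid[sel], side="right") - 1
        ok = (pos >= 0) & (mid[sel] < ends[np.clip(pos, 0, None)])
        out[sel[ok]] = ridx[pos[ok]]
    return out


def classify_tad_activity(
    cmp: TADComparison,
    deg: pd.DataFrame,
    genes: pd.DataFrame,
    top_frac: float = 0.10,
) -> TADComparison:
    """Fill activated/repressed/other classes on conserved domains.

    ``deg`` carries ``gene_id`` and ``log2fc`` for the parent-vs-F1 contrast
    with F1 as reference (fold change = parent / F1). Conserved domains with
    at least one gene in ``deg`` are ranked by mean log2 fold change,
    descending, ties broken by genomic order; the top floor(top_frac * n)
    are activated, the bottom the same number repressed, the rest other.
    Domains without genes stay NA. Fewer than 10 rankable domains leaves
    everything "other" with a warning.
    """
    df = cmp.df.copy()
    lfc = deg.set_index("gene_id")["log2fc"]
    gidx = assign_genes_to_tads(df, genes)
    gene_lfc = lfc.reindex(genes["gene_id"]).to_numpy()
    for row in df.index:
        member = np.isfinite(gene_lfc) & (gidx == row)
        df.loc[row, "n_genes"] = int(member.sum())
        if member.any():
            vals = gene_lfc[member]
            df.loc[row, "mean_log2fc"] = float(vals.mean())
            df.loc[row, "fc_fraction"] = float((vals > 0).mean())
    rankable = df[(df["status"] == "conserved") & (df["n_genes"] > 0)]
    n = len(rankable)
    k = int(np.floor(top_frac * n))
    if n < 10:
        warnings.warn(f"only {n} rankable conserved TADs; all classed 'other'")
    order = rankable.sort_values(
        by=["mean_log2fc", "chrom", "start"],
        ascending=[False, True, True],
        kind="mergesort",
    ).index
    df.loc[order, "activity"] = "other"
    if k > 0:
        df.loc[order[:k], "activity"] = "activated"
        df.loc[order[n - k:], "activity"] = "repressed"
    return TADComparison(cmp.ref_sample, cmp.other_sample, cmp.tol_bins, df, dict(cmp.counts))


def boundary_specificity(
    di_ref: DITrack,
    di_other: DITrack,
    boundaries: pd.DataFrame,
    window_bins: int = 12,
    r_min: float = 0.75,
) -> tuple[pd.DataFrame, dict]:
    """Shared/specific call per boundary by DI-window Pearson correlation.

    The two samples' DI vectors over boundary +/- ``window_bins`` are
    correlated; a boundary is shared iff r >= ``r_min``. Windows that leave
    the chromosome, contain truncated-window or masked bins, or have zero
    variance in either track are unclassifiable and flagged.
    """
    ref_by_chrom = {c: g for c, g in di_ref.df.groupby("chrom", sort=False)}
    oth_by_chrom = {c: g for c, g in di_other.df.groupby("chrom", sort=False)}
    rows = []
    for chrom, b in zip(boundaries["chrom"], boundaries["bin"]):
        gr = ref_by_chrom.get(chrom)
        go = oth_by_chrom.get(chrom)
        if gr is None or go is None:
            rows.append((chrom, int(b), np.nan, "unclassified", "unknown chromosome"))
            continue
        n = len(gr)
        lo, hi = b - window_bins, b + window_bins + 1
        if lo < 0 or hi > n:
            rows.append((chrom, int(b), np.nan, "unclassified", "window outside chromosome"))
            continue
        x = gr["di"].to_numpy()[lo:hi]
        y = go["di"].to_numpy()[lo:hi]
        tr = gr["truncated"].to_numpy()[lo:hi] | go["truncated"].to_numpy()[lo:hi]
        if tr.any() or not (np.isfinite(x).all() and np.isfinite(y).all()):
            rows.append((chrom, int(b), np.nan, "unclassified", "truncated or masked bins"))
            continue
        if x.std() == 0 or y.std() == 0:
            rows.append((chrom, int(b), np.nan, "unclassified", "zero variance"))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append((chrom, int(b), r, "shared" if r >= r_min else "specific", ""))
    out = pd.DataFrame(rows, columns=["chrom", "bin", "r", "status", "note"])
    n_shared = int((out["status"] == "shared").sum())
    n_specific = int((out["status"] == "specific").sum())
    classified = n_shared + n_specific
    summary = {
        "n_shared": n_shared,
        "n_specific": n_specific,
        "n_unclassified": int((out["status"] == "unclassified").sum()),
        "frac_specific": (n_specific / classified) if classified else float("nan"),
    }
    return out, summary


def tad_length_stats(t: TADSet) -> dict:
    """Per-sample domain count, mean length (bp) and genome length covered."""
    lengths = (t.df["end"] - t.df["start"]).to_numpy()
    if lengths.size == 0:
        return {"count": 0, "mean_length_bp": float("nan"), "covered_bp": 0}
    return {
        "count": int(lengths.size),
        "mean_length_bp": float(lengths.mean()),
        "covered_bp": int(lengths.sum()),
    }
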