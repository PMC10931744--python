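"""Contact-matrix data model, I/O, balancing and distance-decay summaries.

All genomic coordinates are 0-based, half-open. Contact matrices are kept
dense in memory (whole-genome matrices at 40-100 kb for a small plant
genome fit comfortably); on disk they are sparse upper-triangle triplet
text files next to a BED4 bin table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "InputError",
    "BinTable",
    "ContactMatrix",
    "ContactSummary",
    "ExpectedDecay",
    "read_contact_matrix",
    "write_contact_matrix",
    "balance_matrix",
    "expected_by_distance",
    "contact_summary",
    "assign_genes_to_bins",
]


class InputError(ValueError):
    """An input file violates the format contract."""


@dataclass(frozen=True)
class BinTable:
    """Fixed-resolution genomic bins: the coordinate system for all tracks.

    Bins tile each chromosome without gaps or overlaps; every bin spans
    ``resolution`` bp except possibly the last bin of a chromosome.
    ``bin_id`` is dense and ordered by (chrom, start).
    """

    df: pd.DataFrame  # columns: chrom, start, end, bin_id
    resolution: int

    def __post_init__(self) -> None:
        df = self.df
        required = {"chrom", "start", "end", "bin_id"}
        if not required.issubset(df.columns):
            raise InputError(f"bin table needs columns {sorted(required)}")
        if not np.array_equal(df["bin_id"].to_numpy(), np.arange(len(df))):
            raise InputError("bin_id must be dense and ordered by (chrom, start)")
        for chrom, grp in df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if starts[0] != 0 or np.any(starts[1:] != ends[:-1]):
                raise InputError(f"bins on {chrom} do not tile the chromosome")
            widths = ends - starts
            if np.any(widths[:-1] != self.resolution) or not (
                0 < widths[-1] <= self.resolution
            ):
                raise InputError(f"bin widths on {chrom} inconsistent with resolution")

    @classmethod
    def from_chrom_sizes(cls, chrom_sizes: Mapping[str, int], resolution: int) -> "BinTable":
        rows = []
        bin_id = 0
        for chrom, size in chrom_sizes.items():
            for start in range(0, size, resolution):
                rows.append((chrom, start, min(start + resolution, size), bin_id))
                bin_id += 1
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "bin_id"])
        return cls(df, resolution)

    @classmethod
    def read_bed(cls, path: str | Path, resolution: int | None = None) -> "BinTable":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "bin_id"]
        )
        if resolution is None:
            resolution = int((df["end"] - df["start"]).max())
        return cls(df, resolution)

    def to_bed(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous bin_id slice per chromosome."""
        out: dict[str, slice] = {}
        for chrom, grp in self.df.groupby("chrom", sort=False):
            ids = grp["bin_id"].to_numpy()
            out[chrom] = slice(int(ids[0]), int(ids[-1]) + 1)
        return out

    def chrom_index(self) -> np.ndarray:
        """Integer chromosome index per bin (for cis/trans bookkeeping)."""
        codes = {c: i for i, c in enumerate(self.chroms)}
        return self.df["chrom"].map(codes).to_numpy()

    def same_bins(self, other: "BinTable") -> bool:
        a = self.df[["chrom", "start", "end", "bin_id"]].reset_index(drop=True)
        b = other.df[["chrom", "start", "end", "bin_id"]].reset_index(drop=True)
        return a.equals(b)


@dataclass
class ContactMatrix:
    """Symmetric whole-genome contact counts over a :class:`BinTable`.

    ``mask`` marks bins that survive balancing (zero-marginal bins are
    excluded from every downstream statistic); for raw matrices it marks
    bins with a positive marginal.
    """

    bins: BinTable
    counts: np.ndarray
    state: str = "raw"  # "raw" | "balanced"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    converged: bool = True

    def __post_init__(self) -> None:
        n = self.bins.n_bins
        if self.counts.shape != (n, n):
            raise InputError("matrix dimension does not match the bin table")
        if np.any(self.counts < 0):
            raise InputError("contact counts must be non-negative")
        if not np.allclose(self.counts, self.counts.T):
            raise InputError("contact matrix must be symmetric")
        if self.mask is None:
            self.mask = self.counts.sum(axis=1) > 0


@dataclass(frozen=True)
class ContactSummary:
    """cis/trans contact totals and the trans/cis ratio for one sample."""

    cis_total: float
    trans_total: float
    trans_cis_ratio: float


@dataclass(frozen=True)
class ExpectedDecay:
    """Per-chromosome expected contact value at each diagonal offset.

    ``empty[chrom][d]`` is True when diagonal ``d`` had no unmasked pairs or
    only zeros; its expected value is defined as 0.
    """

    values: dict[str, np.ndarray]
    empty: dict[str, np.ndarray]


def read_contact_matrix(
    triplet_path: str | Path, bins_path: str | Path | None = None, bins: BinTable | None = None
) -> ContactMatrix:
    """Read a sparse triplet TSV (bin1_id, bin2_id, count) into a raw matrix.

    Unlisted pairs are zero. A pair listed twice — including once as (i, j)
    and once as (j, i) — is rejected rather than summed.
    """
    if bins is None:
        if bins_path is None:
            raise InputError("either bins or bins_path is required")
        bins = BinTable.read_bed(bins_path)
    n = bins.n_bins
    try:
        trip = pd.read_csv(
            triplet_path, sep="\t", header=None, names=["bin1", "bin2", "count"]
        )
    except pd.errors.EmptyDataError:
        trip = pd.DataFrame(columns=["bin1", "bin2", "count"])
    counts = np.zeros((n, n), dtype=float)
    if len(trip):
        i = trip["bin1"].to_numpy(dtype=int)
        j = trip["bin2"].to_numpy(dtype=int)
        c = trip["count"].to_numpy(dtype=float)
        if np.any((i < 0) | (i >= n) | (j < 0) | (j >= n)):
            raise InputError("bin id out of range in triplet file")
        if np.any(c < 0):
            raise InputError("negative count in triplet file")
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        key = lo.astype(np.int64) * n + hi
        if len(np.unique(key)) != len(key):
            raise InputError("duplicate (i, j)/(j, i) pair in triplet file")
        counts[i, j] = c
        counts[j, i] = c
    return ContactMatrix(bins, counts, state="raw")


def write_contact_matrix(m: ContactMatrix, path: str | Path) -> None:
    """Write the non-zero upper triangle (incl. diagonal) as triplet TSV."""
    iu = np.triu_indices(m.bins.n_bins)
    vals = m.counts[iu]
    nz = vals != 0
    out = pd.DataFrame({"bin1": iu[0][nz], "bin2": iu[1][nz], "count": vals[nz]})
    if m.state == "raw":
        out["count"] = out["count"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


def balance_matrix(m: ContactMatrix, tol: float = 1e-5, max_iter: int = 200) -> ContactMatrix:
    """ICE-style iterative correction: equalize non-masked bin marginals.

    Bins with a zero raw marginal are masked and zeroed. Convergence is
    declared when the maximum relative deviation of non-masked row sums
    from their mean drops below ``tol``; otherwise the best iterate is
    returned with ``converged=False`` and a warning.
    """
    if m.state != "raw":
        raise ValueError("balance_matrix expects a raw matrix")
    W = m.counts.astype(float).copy()
    mask = W.sum(axis=1) > 0
    W[~mask, :] = 0.0
    W[:, ~mask] = 0.0
    converged = False
    if not mask.any():
        converged = True
    for _ in range(max_iter):
        s = W.sum(axis=1)
        sv = s[mask]
        mean = sv.mean()
        if mean == 0:
            converged = True
            break
        if np.abs(sv / mean - 1.0).max() < tol:
            converged = True
            break
        b = np.where(mask, s / mean, 1.0)
        W /= np.outer(b, b)
    if not converged:
        warnings.warn(
            f"matrix balancing did not converge within {max_iter} iterations; "
            "returning best iterate",
            RuntimeWarning,
        )
    return ContactMatrix(m.bins, W, state="balanced", mask=mask, converged=converged)


def expected_by_distance(m: ContactMatrix) -> ExpectedDecay:
    """Per-chromosome mean contact at each diagonal offset over unmasked bins."""
    values: dict[str, np.ndarray] = {}
    empty: dict[str, np.ndarray] = {}
    for chrom, sl in m.bins.chrom_slices().items():
        W = m.counts[sl, sl]
        mk = m.mask[sl]
        n = W.shape[0]
        exp = np.zeros(n)
        emp = np.zeros(n, dtype=bool)
        for d in range(n):
            i = np.arange(n - d)
            valid = mk[i] & mk[i + d]
            if not valid.any():
                emp[d] = True
                continue
            exp[d] = W[i[valid], i[valid] + d].mean()
            if exp[d] == 0:
                emp[d] = True
        values[chrom] = exp
        empty[chrom] = emp
    return ExpectedDecay(values, empty)


def contact_summary(m: ContactMatrix) -> ContactSummary:
    """cis/trans totals over the upper triangle (diagonal counts once, to cis)."""
    n = m.bins.n_bins
    ci = m.bins.chrom_index()
    iu = np.triu_indices(n)
    same = ci[iu[0]] == ci[iu[1]]
    vals = m.counts[iu]
    cis = float(vals[same].sum())
    trans = float(vals[~same].sum())
    if cis == 0:
        raise ValueError("cis total is zero; trans/cis ratio undefined")
    return ContactSummary(cis, trans, trans / cis)


def assign_genes_to_bins(genes: pd.DataFrame, bins: BinTable) -> np.ndarray:
    """Map each gene to the bin containing its midpoint.

    A midpoint that falls exactly on a bin boundary is assigned to the
    lower (left) bin. Genes on chromosomes absent from the bin table get -1.
    """
    res = bins.resolution
    slices = bins.chrom_slices()
    nbins_per = {c: sl.stop - sl.start for c, sl in slices.items()}
    mid = (genes["start"].to_numpy() + genes["end"].to_numpy()) // 2
    local = mid // res
    on_border = (mid % res == 0) & (mid > 0)
    local = np.where(on_border, local - 1, local)
    out = np.full(len(genes), -1, dtype=int)
    for k, chrom in enumerate(genes["chrom"]):
        if chrom not in slices:
            continue
        lb = min(int(local[k]), nbins_per[chrom] - 1)
        out[k] = slices[chrom].start + lb
    return out
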