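import numpy as np
import pandas as pd
import pytest

from heterosis3d.matrix_ops import ContactMatrix
from heterosis3d.tads import (
    DITrack,
    TADComparison,
    TADSet,
    boundary_specificity,
    call_tads,
    classify_tad_activity,
    compare_tads,
    directionality_index,
    tad_boundaries,
    tad_length_stats,
)

from conftest import single_chrom_bins, symmetric_matrix

RES = 100_000


def di_track_from_values(values, resolution=RES, chrom="chr1", truncated=None):
    n = len(values)
    if truncated is None:
        truncated = np.zeros(n, bool)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * resolution,
            "end": (np.arange(n) + 1) * resolution,
            "bin_id": np.arange(n),
            "di": np.asarray(values, dtype=float),
            "truncated": truncated,
        }
    )
    return DITrack(sample="x", window_bp=resolution, df=df)


def tadset(domains, resolution=RES, sample="x"):
    df = pd.DataFrame(domains, columns=["chrom", "start", "end"])
    return TADSet(sample=sample, df=df, resolution=resolution)


class TestDirectionalityIndex:
    def test_hand_evaluation(self):
        # bin 1: upstream sum A = 10, downstream B = 30, E = 20 -> DI = +10
        bins = single_chrom_bins(3)
        counts = np.array([[0.0, 10, 0], [10, 0, 30], [0, 30, 0]])
        m = ContactMatrix(bins, counts, state="balanced", mask=np.ones(3, bool))
        di = directionality_index(m, RES)
        assert di.df["di"].iloc[1] == pytest.approx(10.0)

    def test_zero_when_windows_balance(self):
        bins = single_chrom_bins(3)
        counts = np.array([[0.0, 7, 0], [7, 0, 7], [0, 7, 0]])
        m = ContactMatrix(bins, counts, state="balanced", mask=np.ones(3, bool))
        di = directionality_index(m, RES)
        assert di.df["di"].iloc[1] == 0.0

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(2)
        n = 15
        bins = single_chrom_bins(n)
        m = symmetric_matrix(bins, rng)
        mirrored = ContactMatrix(bins, m.counts[::-1, ::-1].copy())
        di = directionality_index(m, 3 * RES).df["di"].to_numpy()
        dim = directionality_index(mirrored, 3 * RES).df["di"].to_numpy()
        assert np.allclose(dim, -di[::-1])

    def test_window_smaller_than_bin_rejected(self):
        rng = np.random.default_rng(0)
        m = symmetric_matrix(single_chrom_bins(5), rng)
        with pytest.raises(ValueError, match="window"):
            directionality_index(m, RES // 2)


class TestCallTads:
    def test_hand_trace_single_boundary(self):
        di = di_track_from_values([1, 1, 1, -1, -1, -1, 1, 1, 1])
        out = call_tads(di, min_tad_bins=2, persistence=2, smooth_bins=1)
        assert len(out.df) == 2
        assert out.df["end"].iloc[0] == 6 * RES
        assert out.df["start"].iloc[1] == 6 * RES

    def test_all_positive_gives_whole_chromosome_domain(self):
        di = di_track_from_values([2, 3, 1, 4, 2, 3])
        out = call_tads(di, min_tad_bins=2, persistence=2, smooth_bins=1)
        assert len(out.df) == 1
        assert (out.df["start"].iloc[0], out.df["end"].iloc[0]) == (0, 6 * RES)

    def test_short_domains_dropped(self):
        di = di_track_from_values([1, 1, -1, -1, 1, 1, 1, 1, 1, 1])
        out = call_tads(di, min_tad_bins=5, persistence=2, smooth_bins=1)
        # boundary at bin 4 leaves a 4-bin left domain, below the minimum
        assert len(out.df) == 1
        assert out.df["start"].iloc[0] == 4 * RES

    def test_scaling_invariance(self):
        rng = np.random.default_rng(9)
        bins = single_chrom_bins(60)
        m = symmetric_matrix(bins, rng)
        bal = ContactMatrix(bins, m.counts.astype(float), state="balanced",
                            mask=np.ones(60, bool))
        scaled = ContactMatrix(bins, 3.7 * m.counts, state="balanced",
                               mask=np.ones(60, bool))
        a = call_tads(directionality_index(bal, 5 * RES))
        b = call_tads(directionality_index(scaled, 5 * RES))
        assert a.df.equals(b.df)


class TestCompareTads:
    def test_identical_sets_all_conserved(self):
        t = tadset([("chr1", 0, 10 * RES), ("chr1", 10 * RES, 25 * RES)])
        cmp = compare_tads(t, t, tol_bins=1)
        assert (cmp.df["status"] == "conserved").all()

    def test_tolerance_edge(self):
        ref = tadset([("chr1", 0, 10 * RES)])
        within = tadset([("chr1", 0, 11 * RES)])
        beyond = tadset([("chr1", 0, 12 * RES)])
        assert compare_tads(ref, within, tol_bins=1).df["status"].iloc[0] == "conserved"
        assert compare_tads(ref, beyond, tol_bins=1).df["status"].iloc[0] == "specific"

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(4)
        def random_set(rng):
            doms, pos = [], 0
            while pos < 180:
                size = int(rng.integers(5, 15))
                doms.append(("chr1", pos * RES, min(pos + size, 200) * RES))
                pos += size
            return tadset(doms)

        ref, other = random_set(rng), random_set(rng)
        cmp = compare_tads(ref, other, tol_bins=1)
        tol = RES
        for k, row in ref.df.iterrows():
            hit = any(
                o["chrom"] == row["chrom"]
                and abs(o["start"] - row["start"]) <= tol
                and abs(o["end"] - row["end"]) <= tol
                for _, o in other.df.iterrows()
            )
            assert cmp.df["status"].iloc[k] == ("conserved" if hit else "specific")


def comparison_with_domains(n_domains, genes_per=2, status="conserved"):
    doms = [("chr1", k * 10 * RES, (k + 1) * 10 * RES) for k in range(n_domains)]
    df = pd.DataFrame(doms, columns=["chrom", "start", "end"])
    df["status"] = status
    df["activity"] = "NA"
    df["fc_fraction"] = np.nan
    df["mean_log2fc"] = np.nan
    df["n_genes"] = 0
    cmp = TADComparison("F1", "P1", 1, df, {})
    rows = []
    for k in range(n_domains):
        for g in range(genes_per):
            start = k * 10 * RES + 1000 + g * 5000
            rows.append(("chr1", start, start + 2000, f"g{k}_{g}"))
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    return cmp, genes


class TestActivityClasses:
    def test_twenty_rankable_gives_two_per_tail(self):
        cmp, genes = comparison_with_domains(20)
        lfc = {g: (k - 10) * 0.3 for k, g in enumerate(genes["gene_id"])}
        deg = pd.DataFrame({"gene_id": list(lfc), "log2fc": list(lfc.values())})
        out = classify_tad_activity(cmp, deg, genes)
        counts = out.df["activity"].value_counts()
        assert counts["activated"] == 2 and counts["repressed"] == 2
        assert counts["other"] == 16
        act = out.df[out.df["activity"] == "activated"]["mean_log2fc"]
        rep = out.df[out.df["activity"] == "repressed"]["mean_log2fc"]
        assert act.min() > rep.max()

    def test_ties_broken_by_genomic_order(self):
        cmp, genes = comparison_with_domains(20)
        deg = pd.DataFrame({"gene_id": genes["gene_id"], "log2fc": 0.0})
        out = classify_tad_activity(cmp, deg, genes)
        assert list(out.df["activity"].iloc[:2]) == ["activated", "activated"]
        assert list(out.df["activity"].iloc[-2:]) == ["repressed", "repressed"]
        assert (out.df["mean_log2fc"] == 0).all()

    def test_fewer_than_ten_rankable_warns_all_other(self):
        cmp, genes = comparison_with_domains(6)
        deg = pd.DataFrame({"gene_id": genes["gene_id"], "log2fc": 1.0})
        with pytest.warns(UserWarning, match="rankable"):
            out = classify_tad_activity(cmp, deg, genes)
        assert (out.df["activity"] == "other").all()

    def test_domains_without_genes_stay_na(self):
        cmp, genes = comparison_with_domains(12)
        # only the first 11 domains have scored genes
        keep = genes[~genes["gene_id"].str.startswith("g11")]
        deg = pd.DataFrame({"gene_id": keep["gene_id"],
                            "log2fc": np.linspace(-1, 1, len(keep))})
        out = classify_tad_activity(cmp, deg, genes)
        assert out.df["activity"].iloc[11] == "NA"
        assert (out.df["activity"].iloc[:11] != "NA").all()


class TestBoundarySpecificity:
    def test_identical_tracks_are_shared(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=30)
        di = di_track_from_values(vals)
        bounds = pd.DataFrame({"chrom": ["chr1"], "bin": [15]})
        out, summary = boundary_specificity(di, di, bounds, window_bins=5)
        assert out["status"].iloc[0] == "shared"
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert summary["frac_specific"] == 0.0

    def test_anticorrelated_tracks_are_specific(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=30)
        di = di_track_from_values(vals)
        neg = di_track_from_values(-vals)
        bounds = pd.DataFrame({"chrom": ["chr1"], "bin": [15]})
        out, _ = boundary_specificity(di, neg, bounds, window_bins=5)
        assert out["status"].iloc[0] == "specific"
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_window_flagged(self):
        di = di_track_from_values(np.zeros(30))
        other = di_track_from_values(np.arange(30, dtype=float))
        bounds = pd.DataFrame({"chrom": ["chr1"], "bin": [15]})
        out, summary = boundary_specificity(di, other, bounds, window_bins=5)
        assert out["status"].iloc[0] == "unclassified"
        assert summary["n_unclassified"] == 1

    def test_window_outside_chromosome_flagged(self):
        rng = np.random.default_rng(0)
        di = di_track_from_values(rng.normal(size=10))
        bounds = pd.DataFrame({"chrom": ["chr1"], "bin": [1]})
        out, _ = boundary_specificity(di, di, bounds, window_bins=5)
        assert out["status"].iloc[0] == "unclassified"


class TestLengthStats:
    def test_hand_arithmetic(self):
        t = tadset([("chr1", 0, 400_000), ("chr1", 400_000, 1_000_000)])
        s = tad_length_stats(t)
        assert s == {"count": 2, "mean_length_bp": 500_000.0, "covered_bp": 1_000_000}

    def test_empty_set(self):
        s = tad_length_stats(tadset([]))
        assert s["count"] == 0 and np.isnan(s["mean_length_bp"])

    def test_boundaries_exclude_chromosome_start(self):
        t = tadset([("chr1", 0, 400_000), ("chr1", 400_000, 1_000_000)])
        b = tad_boundaries(t)
        assert list(b["bin"]) == [4]
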