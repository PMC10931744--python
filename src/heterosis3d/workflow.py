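"""End-to-end trio analysis: one call from raw matrices + expression to
compartment shifts, TAD classes and candidate genes.

This is thin glue over the stage modules, used by the command line, the
test suite and the reproduction script; every step can also be driven
individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import compartments as comp
from . import expression as xp
from . import integration as ig
from . import matrix_ops as mo
from . import tads as td
from .simulate import TrioBundle

__all__ = ["TrioResults", "analyze_trio"]

SAMPLES = ("P1", "P2", "F1")


@dataclass
class TrioResults:
    """Everything the pipeline derives from one trio."""

    balanced: dict[str, mo.ContactMatrix]
    summaries: dict[str, mo.ContactSummary]
    tracks: dict[str, comp.CompartmentTrack]
    shift_table: comp.ShiftTable
    shift_report: comp.ShiftReport
    shift_genes: dict[str, pd.DataFrame]  # parent -> gene-level shift list
    di: dict[str, td.DITrack]
    tadsets: dict[str, td.TADSet]
    tad_stats: dict[str, dict]
    tad_comparisons: dict[str, td.TADComparison]  # parent -> F1-referenced comparison
    boundary_reports: dict[str, dict]  # pair label -> summary
    degs: dict[str, pd.DataFrame]
    trio_report: xp.TrioDEGReport
    segs: dict[str, pd.Index]
    venn: pd.DataFrame
    sample_r2: pd.DataFrame
    heterosis: pd.DataFrame
    candidates: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    candidate_summary: dict = field(default_factory=dict)


def analyze_trio(
    bundle: TrioBundle,
    di_window_bp: int | None = None,
    boundary_window_bins: int = 4,
    boundary_r_min: float = 0.75,
    tad_tol_bins: int = 1,
    min_tad_bins: int = 5,
) -> TrioResults:
    """Run the full analysis on a trio bundle.

    ``di_window_bp`` defaults to five bins of the bundle's resolution, a
    window suited to the simulated domain sizes; pass an explicit value
    (classically 2 Mb at 40 kb) for other regimes.
    """
    res = bundle.bins.resolution
    if di_window_bp is None:
        di_window_bp = 5 * res
    genes = bundle.genes

    balanced, summaries, tracks, di, tadsets, tad_stats = {}, {}, {}, {}, {}, {}
    for s in SAMPLES:
        raw = bundle.matrices[s]
        summaries[s] = mo.contact_summary(raw)
        bal = mo.balance_matrix(raw)
        balanced[s] = bal
        tr = comp.call_compartments(bal, genes, sample=s)
        tracks[s] = tr
        dt = td.directionality_index(bal, di_window_bp)
        dt.sample = s
        di[s] = dt
        tadsets[s] = td.call_tads(dt, min_tad_bins=min_tad_bins)
        tad_stats[s] = td.tad_length_stats(tadsets[s])

    shift_table, shift_report = comp.classify_shifts(tracks["P1"], tracks["P2"], tracks["F1"])
    shift_genes = {
        p: comp.pairwise_shift_genes(tracks[p], tracks["F1"], genes) for p in ("P1", "P2")
    }

    degs = {
        "P1vsP2": xp.simple_de_test(bundle.expr, "P1", "P2"),
        "F1vsP1": xp.simple_de_test(bundle.expr, "F1", "P1"),
        "F1vsP2": xp.simple_de_test(bundle.expr, "F1", "P2"),
    }
    trio_report = xp.classify_trio_degs(degs, bundle.expr)
    segs, venn = xp.specific_genes(bundle.expr)
    _, sample_r2 = xp.sample_correlation(bundle.expr)
    heterosis = xp.heterosis_stats(bundle.phenotypes)

    tad_comparisons = {}
    comp_rows, tad_rows = [], []
    for p in ("P1", "P2"):
        cmpo = td.compare_tads(tadsets["F1"], tadsets[p], tol_bins=tad_tol_bins)
        # activity ranks by parent-over-F1 fold change, F1 as reference
        parent_over_f1 = degs[f"F1vs{p}"].copy()
        parent_over_f1["log2fc"] = -parent_over_f1["log2fc"]
        cmpo = td.classify_tad_activity(cmpo, parent_over_f1, genes)
        tad_comparisons[p] = cmpo
        comp_rows.append(
            ig.integrate_shifts(degs[f"F1vs{p}"], shift_genes[p], contrast=f"F1vs{p}")
        )
        tad_rows.append(
            ig.integrate_tads(degs[f"F1vs{p}"], cmpo, genes, contrast=f"F1vs{p}")
        )
    comp_list = pd.concat(comp_rows, ignore_index=True)
    tad_list = pd.concat(tad_rows, ignore_index=True)
    candidates, candidate_summary = ig.final_candidates(comp_list, tad_list)

    # Boundaries come from the first sample of each pair, so hybrid-specific
    # (e.g. split-TAD) boundaries are probed directly in the parent contrasts.
    boundary_reports = {}
    pairs = [("F1", "P1"), ("F1", "P2"), ("P1", "P2")]
    for a, b in pairs:
        bounds = td.tad_boundaries(tadsets[a])
        _, summ = td.boundary_specificity(
            di[a], di[b], bounds, window_bins=boundary_window_bins, r_min=boundary_r_min
        )
        boundary_reports[f"{a}_vs_{b}"] = summ

    return TrioResults(
        balanced=balanced,
        summaries=summaries,
        tracks=tracks,
        shift_table=shift_table,
        shift_report=shift_report,
        shift_genes=shift_genes,
        di=di,
        tadsets=tadsets,
        tad_stats=tad_stats,
        tad_comparisons=tad_comparisons,
        boundary_reports=boundary_reports,
        degs=degs,
        trio_report=trio_report,
        segs=segs,
        venn=venn,
        sample_r2=sample_r2,
        heterosis=heterosis,
        candidates=candidates,
        candidate_summary=candidate_summary,
    )
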