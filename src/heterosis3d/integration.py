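"""Candidate-gene selection: DEGs intersected with structural changes.

Two evidence tracks feed the candidate list: genes in compartment-shift
bins (parent -> F1, A-to-B or B-to-A) and genes inside activated or
repressed conserved TADs. Expression direction is taken from the F1-over-
parent contrast; a candidate is concordant when the direction matches the
structure: B-to-A with up-regulation in F1, A-to-B with down-regulation,
an activated TAD (parent-high by the parent/F1 ranking) with
down-regulation in F1 and a repressed TAD with up-regulation. Discordant
genes are retained and flagged.
"""

from __future__ import annotations

import pandas as pd

from .tads import TADComparison, assign_genes_to_tads

__all__ = ["integrate_shifts", "integrate_tads", "final_candidates"]

_COLUMNS = [
    "gene_id",
    "source",
    "contrast",
    "structure_change",
    "log2fc",
    "padj",
    "expression_direction",
    "concordant",
]


def _direction(log2fc: float) -> str:
    return "up_in_F1" if log2fc > 0 else "down_in_F1"


def integrate_shifts(
    deg: pd.DataFrame, shift_genes: pd.DataFrame, contrast: str = ""
) -> pd.DataFrame:
    """Compartment-shift candidates: DEGs whose bin shifts between a parent and F1.

    ``deg`` holds gene_id, log2fc (F1 over the parent), padj, is_deg for
    the matching parent contrast; ``shift_genes`` is the gene-level
    pairwise shift list (gene_id, shift).
    """
    d = deg.set_index("gene_id")
    rows = []
    for g, shift in zip(shift_genes["gene_id"], shift_genes["shift"]):
        if g not in d.index or not bool(d.loc[g, "is_deg"]):
            continue
        lfc = float(d.loc[g, "log2fc"])
        direction = _direction(lfc)
        concordant = (shift == "B-to-A" and direction == "up_in_F1") or (
            shift == "A-to-B" and direction == "down_in_F1"
        )
        rows.append(
            (g, "compartment_shift", contrast, shift, lfc, float(d.loc[g, "padj"]),
             direction, concordant)
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def integrate_tads(
    deg: pd.DataFrame,
    cmp: TADComparison,
    genes: pd.DataFrame,
    contrast: str = "",
) -> pd.DataFrame:
    """TAD-activity candidates: DEGs inside activated or repressed TADs.

    DEGs in "other" or unclassified TADs are excluded. ``deg`` log2fc is
    F1 over the parent, so an activated TAD (high parent/F1 fold change)
    is concordant with down-regulation in F1 and a repressed TAD with
    up-regulation in F1.
    """
    d = deg.set_index("gene_id")
    gidx = assign_genes_to_tads(cmp.df, genes)
    activity = cmp.df["activity"]
    rows = []
    for k, g in enumerate(genes["gene_id"]):
        if gidx[k] < 0 or g not in d.index or not bool(d.loc[g, "is_deg"]):
            continue
        act = activity.loc[gidx[k]]
        if act not in ("activated", "repressed"):
            continue
        lfc = float(d.loc[g, "log2fc"])
        direction = _direction(lfc)
        concordant = (act == "activated" and direction == "down_in_F1") or (
            act == "repressed" and direction == "up_in_F1"
        )
        rows.append(
            (g, "tad_activity", contrast, f"{act}_TAD", lfc, float(d.loc[g, "padj"]),
             direction, concordant)
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def final_candidates(
    comp_list: pd.DataFrame, tad_list: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Deduplicated union of both evidence tracks plus summary bookkeeping.

    Genes appearing in both tracks get source "both" (per-evidence rows are
    kept, one per record). The summary satisfies
    |compartment-only| + |TAD-only| + |both| = |unique candidates|.
    """
    comp_genes = set(comp_list["gene_id"])
    tad_genes = set(tad_list["gene_id"])
    both = comp_genes & tad_genes
    out = pd.concat([comp_list, tad_list], ignore_index=True)
    out.loc[out["gene_id"].isin(both), "source"] = "both"
    unique = comp_genes | tad_genes
    concordant_genes = set(out.loc[out["concordant"], "gene_id"])
    summary = {
        "n_candidates": len(unique),
        "n_compartment_only": len(comp_genes - tad_genes),
        "n_tad_only": len(tad_genes - comp_genes),
        "n_both": len(both),
        "n_concordant": len(concordant_genes),
    }
    return out, summary
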