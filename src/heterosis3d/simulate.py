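"""Synthetic parent/parent/hybrid trio generator with recorded ground truth.

Every pipeline stage is verifiable against planted structure: contact
matrices carry a power-law distance decay in cis, a compartment
checkerboard (same-label bins interact more), nested TAD blocks and a
uniform trans background; genes are placed preferentially in A bins;
expression is log-normal with a compartment-dependent mean plus planted
differential effects; phenotypes show hybrid vigour. Counts are Poisson
draws around the expected intensity, the simplest noise model that still
exercises every caller.

Trio compartment states are written parent-first (P1-to-P2-to-F1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionTable
from .matrix_ops import BinTable, ContactMatrix, write_contact_matrix

__all__ = [
    "PlantedShift",
    "SimulationConfig",
    "TruthTables",
    "TrioBundle",
    "default_planted_shifts",
    "simulate_trio",
    "make_heterosis_trio",
]

SAMPLES = ("P1", "P2", "F1")


@dataclass(frozen=True)
class PlantedShift:
    """A planted compartment pattern over a chrom-local bin range.

    ``states`` gives the (P1, P2, F1) labels imposed on bins
    [start_bin, end_bin) of ``chrom``.
    """

    chrom: str
    start_bin: int
    end_bin: int
    states: tuple[str, str, str]


@dataclass
class SimulationConfig:
    """Knobs of the trio simulator; defaults give the standard study layout.

    Two 20 Mb chromosomes at 100 kb (2 x 200 bins), alternating 20-bin
    compartment blocks with a 2x same-label contact boost, 10-20-bin TAD
    blocks with a 2.5x within-domain boost, power-law decay with exponent
    1.0, a uniform trans background, and ~5% of bins carrying planted trio
    compartment shifts. Expression plants a +2 log2 A-compartment effect.
    """

    n_chroms: int = 2
    bins_per_chrom: int = 200
    resolution_bp: int = 100_000
    base_intensity: float = 50.0
    decay_exponent: float = 1.0
    compartment_block_bins: int = 20
    compartment_contrast: float = 2.0
    tad_min_bins: int = 10
    tad_max_bins: int = 20
    tad_contrast: float = 2.5
    trans_weight: Mapping[str, float] = field(
        default_factory=lambda: {"P1": 0.02, "P2": 0.02, "F1": 0.02}
    )
    planted_shifts: tuple[PlantedShift, ...] | None = None  # None -> default set
    f1_split_tads: bool = False
    n_genes: int = 2000
    gene_length_bp: int = 2000
    a_density_ratio: float = 2.0
    expr_log2_mean_a: float = 5.0
    expr_log2_mean_b: float = 3.0
    expr_log2_sd: float = 1.0
    noise_log2_sd: float = 0.25
    n_reps: int = 3
    planted_degs: tuple[tuple[str, str, float], ...] = ()  # (gene_id, sample, log2fc)
    shift_deg_log2fc: float = 0.0  # plant F1 effects concordant with its label changes
    # sample-specific genes: low baseline everywhere, boosted in one sample
    specific_genes_per_sample: Mapping[str, int] = field(
        default_factory=lambda: {"P1": 0, "P2": 0, "F1": 0}
    )
    # genes pushed apart in the parents with the hybrid left at mid-parent
    n_parent_divergent: int = 0
    parent_divergent_log2fc: float = 3.0
    pheno_means: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "fresh_weight": (1.8585, 2.0, 5.0022),
            "dry_weight": (0.12, 0.13, 0.25),
        }
    )
    pheno_cv: float = 0.03
    seed: int = 0


@dataclass
class TruthTables:
    """Planted structure recorded alongside the generated files."""

    compartments: pd.DataFrame  # per bin: labels per sample + trio_state
    tad_boundaries: dict[str, dict[str, list[int]]]  # sample -> chrom -> internal bins
    genes: pd.DataFrame  # gene_id, chrom, start, end, bin_id, base_label
    deg_effects: pd.DataFrame  # gene_id, sample, log2fc
    seg_genes: dict[str, list[str]]  # sample -> planted sample-specific genes
    trans_weight: dict[str, float]


@dataclass
class TrioBundle:
    """In-memory simulation output: inputs for every pipeline stage + truth."""

    config: SimulationConfig
    bins: BinTable
    matrices: dict[str, ContactMatrix]
    genes: pd.DataFrame
    expr: ExpressionTable
    phenotypes: pd.DataFrame
    truth: TruthTables

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.bins.to_bed(out / "bins.bed")
        for s, m in self.matrices.items():
            write_contact_matrix(m, out / f"{s}_matrix.tsv")
        self.genes.to_csv(out / "genes.bed", sep="\t", header=False, index=False,
                          columns=["chrom", "start", "end", "gene_id"])
        self.expr.to_tsv(out / "expression_fpkm.tsv")
        self.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        self.truth.compartments.to_csv(truth_dir / "compartments.tsv", sep="\t", index=False)
        rows = [
            (s, c, b)
            for s, per_chrom in self.truth.tad_boundaries.items()
            for c, bl in per_chrom.items()
            for b in bl
        ]
        pd.DataFrame(rows, columns=["sample", "chrom", "bin"]).to_csv(
            truth_dir / "tad_boundaries.tsv", sep="\t", index=False
        )
        self.truth.genes.to_csv(truth_dir / "genes.tsv", sep="\t", index=False)
        self.truth.deg_effects.to_csv(truth_dir / "deg_effects.tsv", sep="\t", index=False)
        seg_rows = [(s, g) for s, gl in self.truth.seg_genes.items() for g in gl]
        pd.DataFrame(seg_rows, columns=["sample", "gene_id"]).to_csv(
            truth_dir / "seg_genes.tsv", sep="\t", index=False
        )
        cfg = asdict(self.config)
        cfg["trans_weight"] = dict(cfg["trans_weight"])
        cfg["pheno_means"] = {k: list(v) for k, v in dict(cfg["pheno_means"]).items()}
        cfg["planted_shifts"] = [
            [s["chrom"], s["start_bin"], s["end_bin"], list(s["states"])]
            for s in (cfg["planted_shifts"] or [])
        ]
        cfg["planted_degs"] = [list(t) for t in cfg["planted_degs"]]
        cfg["specific_genes_per_sample"] = dict(cfg["specific_genes_per_sample"])
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump({"config": cfg}, fh, sort_keys=False)


def default_planted_shifts(cfg: SimulationConfig) -> tuple[PlantedShift, ...]:
    """Standard planted trio shifts: ~5% of bins, mostly hybrid A-gains.

    Requires at least 2 chromosomes of 160 bins; smaller layouts get no
    planted shifts.
    """
    if cfg.n_chroms < 2 or cfg.bins_per_chrom < 160:
        return ()
    return (
        PlantedShift("chr1", 44, 50, ("A", "B", "A")),
        PlantedShift("chr1", 100, 105, ("B", "A", "A")),
        PlantedShift("chr2", 24, 29, ("B", "B", "A")),
        PlantedShift("chr2", 64, 68, ("B", "A", "B")),
        PlantedShift("chr2", 150, 153, ("A", "A", "B")),
    )


def _base_labels(cfg: SimulationConfig) -> np.ndarray:
    """Alternating A/B blocks along one chromosome."""
    blocks = np.arange(cfg.bins_per_chrom) // cfg.compartment_block_bins
    return np.where(blocks % 2 == 0, "A", "B").astype(object)


def _tad_partition(cfg: SimulationConfig, rng: np.random.Generator) -> list[int]:
    """Internal TAD boundary bins for one chromosome (base layout)."""
    if cfg.tad_max_bins > cfg.bins_per_chrom:
        raise ValueError("TAD size exceeds chromosome length; infeasible config")
    bounds = []
    pos = 0
    while True:
        size = int(rng.integers(cfg.tad_min_bins, cfg.tad_max_bins + 1))
        if pos + size >= cfg.bins_per_chrom:
            break
        pos += size
        bounds.append(pos)
    return bounds


def _domain_ids(n: int, internal_bounds: list[int]) -> np.ndarray:
    ids = np.zeros(n, dtype=int)
    for b in internal_bounds:
        ids[b:] += 1
    return ids


def simulate_trio(cfg: SimulationConfig) -> TrioBundle:
    """Generate the trio file bundle and its truth tables.

    Expected cis intensity: base x (1 + |i - j|)^(-decay) x compartment
    factor (x contrast for same-label pairs) x TAD factor (x contrast
    within a domain); trans intensity: base x trans_weight. Counts are
    Poisson. A fixed seed yields byte-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.compartment_contrast < 1 or cfg.tad_contrast < 1:
        raise ValueError("contrasts must be >= 1")
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    bins = BinTable.from_chrom_sizes(
        {c: cfg.bins_per_chrom * cfg.resolution_bp for c in chroms}, cfg.resolution_bp
    )
    n = bins.n_bins
    npc = cfg.bins_per_chrom

    shifts = cfg.planted_shifts
    if shifts is None:
        shifts = default_planted_shifts(cfg)
    base = np.concatenate([_base_labels(cfg) for _ in chroms])
    labels = {s: base.copy() for s in SAMPLES}
    offsets = {c: i * npc for i, c in enumerate(chroms)}
    for sh in shifts:
        if sh.chrom not in offsets or not (0 <= sh.start_bin < sh.end_bin <= npc):
            raise ValueError(f"planted shift outside the genome: {sh}")
        o = offsets[sh.chrom]
        for s, st in zip(SAMPLES, sh.states):
            labels[s][o + sh.start_bin:o + sh.end_bin] = st

    base_bounds = {c: _tad_partition(cfg, rng) for c in chroms}
    tad_bounds: dict[str, dict[str, list[int]]] = {}
    for s in SAMPLES:
        tad_bounds[s] = {c: list(b) for c, b in base_bounds.items()}
    if cfg.f1_split_tads:
        min_split = 10  # only split domains whose halves stay callable
        for c in chroms:
            edges = [0] + base_bounds[c] + [npc]
            extra = []
            for k in range(0, len(edges) - 1, 2):
                a, b = edges[k], edges[k + 1]
                if b - a >= min_split:
                    extra.append((a + b) // 2)
            tad_bounds["F1"][c] = sorted(base_bounds[c] + extra)

    matrices: dict[str, ContactMatrix] = {}
    ci = bins.chrom_index()
    dist = np.abs(np.arange(npc)[:, None] - np.arange(npc)[None, :])
    decay = cfg.base_intensity * (1.0 + dist) ** (-cfg.decay_exponent)
    for s in SAMPLES:
        lam = np.full((n, n), cfg.base_intensity * cfg.trans_weight[s])
        for c in chroms:
            o = offsets[c]
            sl = slice(o, o + npc)
            lab = labels[s][sl]
            same_comp = lab[:, None] == lab[None, :]
            dom = _domain_ids(npc, tad_bounds[s][c])
            same_tad = dom[:, None] == dom[None, :]
            block = decay.copy()
            block[same_comp] *= cfg.compartment_contrast
            block[same_tad] *= cfg.tad_contrast
            lam[sl, sl] = block
        iu = np.triu_indices(n)
        counts = np.zeros((n, n))
        draws = rng.poisson(lam[iu]).astype(float)
        counts[iu] = draws
        counts.T[iu] = draws
        matrices[s] = ContactMatrix(bins, counts, state="raw")

    # Genes: density ratio a_density_ratio in base-A bins, fixed genome-wide.
    w = np.where(base == "A", cfg.a_density_ratio, 1.0)
    gene_bins = np.sort(rng.choice(n, size=cfg.n_genes, p=w / w.sum()))
    bin_starts = bins.df["start"].to_numpy()
    bin_chroms = bins.df["chrom"].to_numpy()
    jitter = rng.integers(0, cfg.resolution_bp - cfg.gene_length_bp, size=cfg.n_genes)
    g_start = bin_starts[gene_bins] + jitter
    genes = pd.DataFrame(
        {
            "chrom": bin_chroms[gene_bins],
            "start": g_start,
            "end": g_start + cfg.gene_length_bp,
            "gene_id": [f"G{k:05d}" for k in range(cfg.n_genes)],
        }
    )

    base_log2 = rng.normal(
        np.where(base[gene_bins] == "A", cfg.expr_log2_mean_a, cfg.expr_log2_mean_b),
        cfg.expr_log2_sd,
    )
    effects = {s: np.zeros(cfg.n_genes) for s in SAMPLES}
    deg_rows = []
    gene_index = {g: k for k, g in enumerate(genes["gene_id"])}
    for gid, sample, lfc in cfg.planted_degs:
        effects[sample][gene_index[gid]] += lfc
        deg_rows.append((gid, sample, lfc))
    if cfg.shift_deg_log2fc > 0:
        for k, b in enumerate(gene_bins):
            lf1 = labels["F1"][b]
            parents = (labels["P1"][b], labels["P2"][b])
            if lf1 == "A" and "B" in parents:
                effects["F1"][k] += cfg.shift_deg_log2fc
                deg_rows.append((genes["gene_id"].iloc[k], "F1", cfg.shift_deg_log2fc))
            elif lf1 == "B" and "A" in parents:
                effects["F1"][k] -= cfg.shift_deg_log2fc
                deg_rows.append((genes["gene_id"].iloc[k], "F1", -cfg.shift_deg_log2fc))

    # SEG and parent-divergence planting draws from structurally quiet genes
    # (no compartment change between samples, no effect planted so far).
    planted_mask = np.zeros(cfg.n_genes, dtype=bool)
    for s in SAMPLES:
        planted_mask |= effects[s] != 0
    quiet = np.array(
        [
            labels["P1"][b] == labels["P2"][b] == labels["F1"][b]
            for b in gene_bins
        ]
    ) & ~planted_mask
    pool = rng.permutation(np.where(quiet)[0])
    cursor = 0
    seg_truth: dict[str, list[str]] = {}
    for s in SAMPLES:
        k = cfg.specific_genes_per_sample.get(s, 0)
        idx = pool[cursor:cursor + k]
        cursor += k
        base_log2[idx] = rng.normal(-2.5, 0.5, size=len(idx))
        effects[s][idx] += 5.5
        seg_truth[s] = [genes["gene_id"].iloc[i] for i in idx]
    div_idx = pool[cursor:cursor + cfg.n_parent_divergent]
    for j, k in enumerate(div_idx):
        up, down = ("P1", "P2") if j % 2 == 0 else ("P2", "P1")
        effects[up][k] += cfg.parent_divergent_log2fc
        effects[down][k] -= cfg.parent_divergent_log2fc
        deg_rows.append((genes["gene_id"].iloc[k], up, cfg.parent_divergent_log2fc))
        deg_rows.append((genes["gene_id"].iloc[k], down, -cfg.parent_divergent_log2fc))
    data = {}
    for s in SAMPLES:
        for r in range(1, cfg.n_reps + 1):
            noise = rng.normal(0.0, cfg.noise_log2_sd, size=cfg.n_genes)
            data[f"{s}_{r}"] = 2.0 ** (base_log2 + effects[s] + noise)
    expr = ExpressionTable(pd.DataFrame(data, index=genes["gene_id"]), n_reps=cfg.n_reps)

    ph_rows = []
    for trait, (p1, p2, f1) in cfg.pheno_means.items():
        for s, mu in zip(SAMPLES, (p1, p2, f1)):
            for v in rng.normal(mu, cfg.pheno_cv * mu, size=cfg.n_reps):
                ph_rows.append((trait, s, max(float(v), 1e-9)))
    phenotypes = pd.DataFrame(ph_rows, columns=["trait", "sample", "value"])

    comp_truth = bins.df.copy()
    for s in SAMPLES:
        comp_truth[f"label_{s}"] = labels[s]
    comp_truth["trio_state"] = [
        f"{a}-to-{b}-to-{c}"
        for a, b, c in zip(labels["P1"], labels["P2"], labels["F1"])
    ]
    truth_genes = genes.copy()
    truth_genes["bin_id"] = gene_bins
    truth_genes["base_label"] = base[gene_bins]
    truth = TruthTables(
        compartments=comp_truth,
        tad_boundaries=tad_bounds,
        genes=truth_genes,
        deg_effects=pd.DataFrame(deg_rows, columns=["gene_id", "sample", "log2fc"]),
        seg_genes=seg_truth,
        trans_weight=dict(cfg.trans_weight),
    )
    return TrioBundle(cfg, bins, matrices, genes, expr, phenotypes, truth)


def make_heterosis_trio(seed: int = 0, **overrides) -> TrioBundle:
    """Preset trio reproducing the study's qualitative genome-wide findings.

    The hybrid gets a boosted trans background (higher trans/cis ratio than
    either parent), split TADs (more and smaller domains), net B-to-A
    planted compartment shifts, planted F1 expression effects concordant
    with its compartment changes, planted sample-specific genes (fewest in
    the hybrid) and parent-divergent genes whose hybrid expression sits at
    mid-parent; ~95% of bins keep an unchanged trio state.
    """
    cfg = SimulationConfig(
        trans_weight={"P1": 0.02, "P2": 0.02, "F1": 0.045},
        f1_split_tads=True,
        shift_deg_log2fc=4.0,
        specific_genes_per_sample={"P1": 80, "P2": 75, "F1": 50},
        n_parent_divergent=120,
        seed=seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return simulate_trio(cfg)
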