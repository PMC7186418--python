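"""Synthetic cohort generator with ground truth.

The study this package targets profiled 1107 single cells from regenerating
alveolar ducts (207 littermate controls, 169 surgical controls, 265 day-1,
261 day-3 and 205 day-7 post-pneumonectomy cells) on a 96-assay qPCR panel,
plus 73 flow-sorted bulk samples sharing an 18-gene overlap subset with the
panel.  The raw cohort is not deposited, so every analysis stage here is
exercised against synthetic cohorts that emulate that design: K latent cell
populations with log2-scale expression programs, Bernoulli detection dropout
per reaction, and timepoint-dependent composition in which one population
(the "emergent" population, the analogue of the study's Cluster 2) is
near-absent before pneumonectomy (~0.5% of control cells) and prominent
after (mean 27% across days 1/3/7).

Generative model, per cell i in group g:
    z_i ~ Categorical(composition[g])                 (latent population)
    per gene j:  detect ~ Bernoulli(detect_prob[z_i, j])
        if detect:  Ct = clamp(LOD - Normal(mean_et[z_i, j], sd_et[z_i, j]), (0, 40])
        else:       Ct = sentinel (999)

Draw order is fixed (populations per group in declared group order, then one
uniform detection matrix, then one normal noise matrix, all from a single
seeded PCG64 generator), so output is bit-reproducible for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ct_io import (
    CT_MAX,
    DEFAULT_LOD,
    GROUPS,
    NONDETECT_CODE,
    CellMeta,
    CtMatrix,
    GenePanel,
)

__all__ = [
    "OVERLAP_GENES",
    "PAPER_GROUP_SIZES",
    "PopulationProgram",
    "StudyDesign",
    "GroundTruth",
    "BulkPanel",
    "generate_cohort",
    "generate_bulk",
    "default_study_design",
    "scaled_study_design",
    "write_bulk_panel",
    "write_ground_truth",
]

#: The 18-gene overlap subset shared by the single-cell panel and the sorted
#: bulk profiles, used by the bulk-matching algorithm.
OVERLAP_GENES = (
    "Col18a1", "Col4a3", "Csf3", "Ctgf", "Eng", "Ephb4", "Ereg", "Fgf1",
    "Igf1", "Lep", "Mapk14", "Npr1", "Pecam1", "S1pr1", "Sphk1", "Tgfa",
    "Tnf", "Vegfa",
)

#: Study cohort: cells per group, 1107 in total.
PAPER_GROUP_SIZES: dict[str, int] = {
    "littermate_control": 207,
    "surgical_control": 169,
    "day1": 265,
    "day3": 261,
    "day7": 205,
}

# Panel gene symbols named in figures and methods beyond the overlap subset
# (lung repair, matrix and angiogenesis genes); the full 96-assay list is not
# published, so the panel is padded with synthetic placeholder assays.
_EXTRA_NAMED_GENES = (
    "Eln", "Lox", "Fbn1", "Mapk3", "Fbln1", "Fbln5", "Ltbp2", "Ltbp4",
    "Fn1", "Mmp2", "Mmp14", "Tgfb1", "Pdgfra", "Pdgfrb", "Flt1", "Flt4",
    "Acta2",
)


@dataclass(frozen=True)
class PopulationProgram:
    """Expression program of one latent cell population.

    mean_et / sd_et are per-gene Gaussian parameters on the log2 (Et) scale;
    detect_prob is the per-gene probability that a reaction yields signal.
    """

    pop_id: int
    mean_et: np.ndarray
    sd_et: np.ndarray
    detect_prob: np.ndarray

    def __post_init__(self) -> None:
        for name in ("mean_et", "sd_et", "detect_prob"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if (self.mean_et < 0).any() or (self.sd_et < 0).any():
            raise ValueError("mean_et and sd_et must be >= 0")
        if ((self.detect_prob < 0) | (self.detect_prob > 1)).any():
            raise ValueError("detect_prob must be in [0, 1]")
        if not (self.mean_et.shape == self.sd_et.shape == self.detect_prob.shape):
            raise ValueError("program arrays must share one shape")


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: group sizes, per-group population composition, panel,
    overlap genes and the bulk sampling plan."""

    group_sizes: Mapping[str, int]
    composition: Mapping[str, Sequence[float]]
    panel: GenePanel
    overlap_genes: tuple[str, ...]
    #: (cell-type label, source population id, replicate count)
    bulk_design: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
        for g, comp in self.composition.items():
            comp = np.asarray(comp, dtype=float)
            if not np.isclose(comp.sum(), 1.0, atol=1e-9):
                raise ValueError(f"composition for {g!r} sums to {comp.sum()}, not 1")
            if (comp < 0).any():
                raise ValueError(f"composition for {g!r} has negative entries")
        missing = set(self.overlap_genes) - set(self.panel.gene_names)
        if missing:
            raise ValueError(f"overlap genes absent from panel: {sorted(missing)}")

    @property
    def n_populations(self) -> int:
        return len(next(iter(self.composition.values())))

    @property
    def n_cells(self) -> int:
        return sum(self.group_sizes.values())

    @property
    def n_bulk(self) -> int:
        return sum(n for _, _, n in self.bulk_design)


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth: latent population per cell (or per bulk sample)."""

    populations: np.ndarray  # int, per cell / per bulk sample
    seed: int
    design: StudyDesign

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", np.asarray(self.populations, dtype=int))


@dataclass(frozen=True)
class BulkPanel:
    """Sorted-population bulk expression profiles on the overlap genes."""

    sample_ids: tuple[str, ...]
    cell_types: tuple[str, ...]
    genes: tuple[str, ...]
    profiles: np.ndarray  # [n_bulk x n_genes], log2 units

    def __post_init__(self) -> None:
        profiles = np.asarray(self.profiles, dtype=float)
        if profiles.shape != (len(self.sample_ids), len(self.genes)):
            raise ValueError("profiles shape does not match samples x genes")
        if len(self.sample_ids) != len(self.cell_types):
            raise ValueError("sample_ids and cell_types must align")
        object.__setattr__(self, "profiles", profiles)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _programs_by_id(programs: Sequence[PopulationProgram]) -> dict[int, PopulationProgram]:
    return {p.pop_id: p for p in programs}


def generate_cohort(
    design: StudyDesign,
    programs: Sequence[PopulationProgram],
    seed: int,
    lod: float = DEFAULT_LOD,
) -> tuple[CtMatrix, GroundTruth]:
    """Draw a single-cell Ct cohort from the design's mixture model."""
    progs = _programs_by_id(programs)
    n_pops = design.n_populations
    if set(progs) != set(range(1, n_pops + 1)):
        raise ValueError(
            f"programs must cover population ids 1..{n_pops}, got {sorted(progs)}"
        )
    rng = np.random.default_rng(seed)

    group_order = [g for g in GROUPS if g in design.group_sizes]
    cells: list[CellMeta] = []
    pops: list[np.ndarray] = []
    for g in group_order:
        n = design.group_sizes[g]
        comp = np.asarray(design.composition[g], dtype=float)
        pops.append(rng.choice(np.arange(1, n_pops + 1), size=n, p=comp))
        cells.extend(CellMeta(cell_id=f"{g}_c{i:04d}", group=g) for i in range(n))
    populations = np.concatenate(pops) if pops else np.empty(0, dtype=int)

    n_cells, n_genes = len(cells), design.panel.size
    mean = np.stack([progs[p].mean_et for p in populations]) if n_cells else np.empty((0, n_genes))
    sd = np.stack([progs[p].sd_et for p in populations]) if n_cells else np.empty((0, n_genes))
    pdet = np.stack([progs[p].detect_prob for p in populations]) if n_cells else np.empty((0, n_genes))

    detected = rng.random((n_cells, n_genes)) < pdet
    et_latent = mean + sd * rng.standard_normal((n_cells, n_genes))
    ct = np.clip(lod - et_latent, 1e-2, CT_MAX)
    ct[~detected] = NONDETECT_CODE

    matrix = CtMatrix(cells=tuple(cells), panel=design.panel, ct=ct)
    return matrix, GroundTruth(populations=populations, seed=seed, design=design)


def generate_bulk(
    design: StudyDesign,
    programs: Sequence[PopulationProgram],
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[BulkPanel, GroundTruth]:
    """Draw sorted-population bulk profiles on the overlap genes.

    Each replicate is its source population's mean program restricted to the
    overlap genes plus i.i.d. Gaussian noise (log2 units).  Bulk measurements
    average thousands of cells, so no dropout is simulated.
    """
    if not design.bulk_design:
        raise ValueError("bulk_design is empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    progs = _programs_by_id(programs)
    overlap_idx = design.panel.index_of(design.overlap_genes)
    rng = np.random.default_rng(seed)

    sample_ids, cell_types, rows, src = [], [], [], []
    for label, pop, n_rep in design.bulk_design:
        if pop not in progs:
            raise ValueError(f"bulk cell-type {label!r} references unknown population {pop}")
        base = progs[pop].mean_et[overlap_idx]
        for r in range(n_rep):
            sample_ids.append(f"{label}_r{r + 1:02d}")
            cell_types.append(label)
            rows.append(base + noise_sd * rng.standard_normal(base.shape))
            src.append(pop)

    panel = BulkPanel(
        sample_ids=tuple(sample_ids),
        cell_types=tuple(cell_types),
        genes=tuple(design.overlap_genes),
        profiles=np.array(rows),
    )
    return panel, GroundTruth(populations=np.array(src), seed=seed, design=design)


# ---------------------------------------------------------------------------
# Default design emulating the study
# ---------------------------------------------------------------------------

def _default_panel() -> GenePanel:
    names = list(OVERLAP_GENES) + list(_EXTRA_NAMED_GENES)
    pad = [f"Syn{i:02d}" for i in range(1, 97 - len(names))]
    return GenePanel(tuple(names + pad))


def _default_composition(emergent_control: float, emergent_days: tuple[float, float, float]):
    # Non-emergent populations split the remaining mass in fixed proportions.
    base = {1: 0.30, 3: 0.22, 4: 0.18, 5: 0.17, 6: 0.13}  # sums to 1

    def comp(emergent: float) -> list[float]:
        rest = 1.0 - emergent
        vec = [0.0] * 6
        vec[1] = emergent  # population 2
        for p, w in base.items():
            vec[p - 1] = w * rest
        return vec

    d1, d3, d7 = emergent_days
    return {
        "littermate_control": comp(emergent_control),
        "surgical_control": comp(emergent_control),  # indistinguishable from littermates
        "day1": comp(d1),
        "day3": comp(d3),
        "day7": comp(d7),
    }


def default_study_design(
    separability: float = 7.0,
    sd_et: float = 1.0,
    emergent_control: float = 0.005,
    emergent_days: tuple[float, float, float] = (0.24, 0.30, 0.27),
    group_sizes: Mapping[str, int] | None = None,
) -> tuple[StudyDesign, list[PopulationProgram]]:
    """The default synthetic design emulating the study cohort.

    Six latent populations on a 96-gene panel; population 2 is the emergent
    one, at ``emergent_control`` frequency in both control groups and at
    ``emergent_days`` frequencies on post-pneumonectomy days 1/3/7 (default
    mean 0.27).  Each population over-expresses a distinct signature block —
    3 overlap genes plus 10 panel genes — by ``separability`` log2 units over
    a baseline of 2, so between-population distance well exceeds the
    within-population spread ``sd_et``.
    """
    panel = _default_panel()
    composition = _default_composition(emergent_control, emergent_days)
    sizes = dict(PAPER_GROUP_SIZES if group_sizes is None else group_sizes)
    n_genes = panel.size

    programs = []
    overlap_idx = panel.index_of(OVERLAP_GENES)
    non_overlap_idx = np.array([i for i in range(n_genes) if i not in set(overlap_idx)])
    for p in range(1, 7):
        mean = np.full(n_genes, 2.0)
        detect = np.full(n_genes, 0.5)
        sig = np.concatenate(
            [overlap_idx[3 * (p - 1): 3 * p], non_overlap_idx[10 * (p - 1): 10 * p]]
        )
        mean[sig] = 2.0 + separability
        detect[sig] = 0.95
        programs.append(
            PopulationProgram(
                pop_id=p,
                mean_et=mean,
                sd_et=np.full(n_genes, sd_et),
                detect_prob=detect,
            )
        )

    # 8 sorted cell-types over 73 bulk samples; three types source from
    # population 1 and two from population 2, mirroring the multi-identity
    # clusters reported for the study's bulk projections.
    bulk_design = (
        ("myofibroblast", 1, 10),
        ("type2_cell", 1, 9),
        ("epc_cd34", 1, 9),
        ("alveolar_macrophage", 2, 9),
        ("monocyte_cd11b", 2, 9),
        ("endothelial_cd31", 3, 9),
        ("type1_cell", 4, 9),
        ("mesothelial", 5, 9),
    )
    design = StudyDesign(
        group_sizes=sizes,
        composition=composition,
        panel=panel,
        overlap_genes=OVERLAP_GENES,
        bulk_design=bulk_design,
    )
    return design, programs


def scaled_study_design(
    n_cells: int = 400, **kwargs
) -> tuple[StudyDesign, list[PopulationProgram]]:
    """Default design with group sizes scaled proportionally to ``n_cells``.

    Useful for desk-scale runs; composition, panel and bulk plan unchanged.
    Largest-remainder rounding keeps the total exactly ``n_cells``.
    """
    total = sum(PAPER_GROUP_SIZES.values())
    raw = {g: n * n_cells / total for g, n in PAPER_GROUP_SIZES.items()}
    sizes = {g: int(np.floor(v)) for g, v in raw.items()}
    remainder = n_cells - sum(sizes.values())
    for g in sorted(raw, key=lambda g: raw[g] - np.floor(raw[g]), reverse=True)[:remainder]:
        sizes[g] += 1
    return default_study_design(group_sizes=sizes, **kwargs)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_bulk_panel(bulk: BulkPanel, path: str | Path) -> None:
    """Write bulk profiles as CSV: sample_id, cell_type, one column per gene."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "cell_type", *bulk.genes])
        for sid, ct_label, row in zip(bulk.sample_ids, bulk.cell_types, bulk.profiles):
            writer.writerow([sid, ct_label, *[f"{v:.4f}" for v in row]])


def load_bulk_panel(path: str | Path) -> BulkPanel:
    """Read a bulk CSV written by :func:`write_bulk_panel`."""
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["sample_id", "cell_type"]:
            raise ValueError(f"{path}: expected columns sample_id, cell_type, <genes>")
        genes = tuple(header[2:])
        sids, ctypes, rows = [], [], []
        for row in reader:
            sids.append(row[0])
            ctypes.append(row[1])
            rows.append([float(v) for v in row[2:]])
    return BulkPanel(
        sample_ids=tuple(sids), cell_types=tuple(ctypes), genes=genes, profiles=np.array(rows)
    )


def write_ground_truth(truth: GroundTruth, ids: Sequence[str], path: str | Path) -> None:
    """Dump per-sample latent populations and a design echo as JSON."""
    payload = {
        "seed": truth.seed,
        "populations": {i: int(p) for i, p in zip(ids, truth.populations)},
        "design": {
            "group_sizes": dict(truth.design.group_sizes),
            "composition": {g: list(map(float, c)) for g, c in truth.design.composition.items()},
            "overlap_genes": list(truth.design.overlap_genes),
            "bulk_design": [list(b) for b in truth.design.bulk_design],
            "n_genes": truth.design.panel.size,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))
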