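"""Synthetic screens, reagent libraries, and expression tables.

The generator emulates the statistical structure of cell-based RNAi
high-throughput screens run on 384-well plates:

* a reagent library with 1-4 dsRNAs per gene, a set of true-hit genes, and
  per-reagent defects — an *ineffective* reagent on a hit gene (probability
  ``reagent_fn_rate``) produces no phenotype, an *off-target-active* reagent
  (probability ``reagent_fp_rate``) produces one regardless of its target;
* plates with an empty outer perimeter, interior wells filled row-major;
* per-well Gaussian noise, and a per-screen response weight that scales the
  phenotypic effect — different assays respond to the same perturbation with
  different strength, which is what gives a reagent a *profile* across
  screens rather than a single number;
* log-normal FPKM values for expressed genes, sub-threshold uniform values
  for unexpressed ones.

Ground truth (which genes are hits, which reagents are defective) is returned
alongside, so downstream estimators can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .normalize import PLATE_COLUMNS

__all__ = [
    "SimulationParams",
    "ExpressionSimParams",
    "generate_library",
    "generate_screen_plates",
    "generate_expression_table",
    "hit_annotation",
]


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of a simulated multi-screen experiment.

    Defaults describe a focused sub-library screened across many assays: a
    1,000-gene library with two dsRNAs per gene, 50 genes carrying a genuine
    broad phenotype, 8% of reagents ineffective, 1% off-target-active, a
    -5 Z-unit effect against unit well noise, observed in 16 screens.
    """

    n_genes: int = 1000
    reagents_per_gene: int | Sequence[int] = 2
    n_true_hits: int = 50
    reagent_fn_rate: float = 0.08
    reagent_fp_rate: float = 0.01
    effect_size: float = -5.0
    noise_sd: float = 1.0
    n_screens: int = 16
    n_replicates_per_screen: int = 2
    plate_rows: int = 16
    plate_cols: int = 24
    perimeter_empty: bool = True
    #: Per-screen response weights are drawn uniformly from this interval and
    #: multiply effect_size; (1, 1) makes every screen respond identically.
    #: The wide default reflects how differently unrelated assays respond to
    #: the same broad perturbation, and is what gives signature clusters
    #: their across-screen profile after Z-scoring.
    screen_effect_range: tuple[float, float] = (0.2, 1.8)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("reagent_fn_rate", "reagent_fp_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_true_hits > self.n_genes:
            raise ValueError("n_true_hits cannot exceed n_genes")
        if isinstance(self.reagents_per_gene, int):
            counts = [self.reagents_per_gene] * self.n_genes
        else:
            counts = list(self.reagents_per_gene)
            if len(counts) != self.n_genes:
                raise ValueError("per-gene reagent counts must have length n_genes")
        if any(c < 1 or c > 4 for c in counts):
            raise ValueError("reagents per gene must be between 1 and 4")
        lo, hi = self.screen_effect_range
        if not (0 <= lo <= hi):
            raise ValueError("screen_effect_range must satisfy 0 <= low <= high")

    @property
    def reagent_counts(self) -> list[int]:
        if isinstance(self.reagents_per_gene, int):
            return [self.reagents_per_gene] * self.n_genes
        return list(self.reagents_per_gene)

    @property
    def wells_per_plate(self) -> int:
        if self.perimeter_empty:
            return (self.plate_rows - 2) * (self.plate_cols - 2)
        return self.plate_rows * self.plate_cols


@dataclass(frozen=True)
class ExpressionSimParams:
    """Parameters of a simulated gene x cell-line FPKM table.

    Expressed genes draw FPKM log-normally (``exp(Normal(mu, sigma))`` on the
    natural-log scale); unexpressed genes draw uniformly below
    ``unexpressed_fpkm_max``.  Expression status is independent across cell
    lines.  The default expressed fraction mirrors cultured cell lines that
    express roughly half of protein-coding genes.
    """

    cell_lines: tuple[str, ...] = ("S2R+", "Kc167", "S2", "BG3", "Clone8")
    expressed_fraction: float = 0.53
    lognormal_mu: float = 3.0
    lognormal_sigma: float = 1.5
    unexpressed_fpkm_max: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.expressed_fraction <= 1.0:
            raise ValueError("expressed_fraction must be in [0, 1]")
        if self.unexpressed_fpkm_max < 0:
            raise ValueError("unexpressed_fpkm_max must be >= 0")
        if not self.cell_lines:
            raise ValueError("at least one cell line required")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_library(params: SimulationParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a reagent library and its ground truth.

    Returns
    -------
    reagent_map : DataFrame
        Columns ``reagent_id``, ``gene_id`` (many reagents to one gene).
    truth : DataFrame
        Columns ``reagent_id``, ``gene_id``, ``gene_is_hit``, ``effective``,
        ``off_target``.  Exactly ``n_true_hits`` genes are flagged hits;
        effectiveness and off-target activity are i.i.d. Bernoulli draws with
        P(ineffective) = reagent_fn_rate, P(off-target) = reagent_fp_rate.
    """
    rng = np.random.default_rng(params.seed)
    genes = _gene_ids(params.n_genes)
    counts = params.reagent_counts

    capacity_needed = sum(counts)
    # capacity is checked against a generous plate budget at generation time;
    # generate_screen_plates allocates exactly ceil(n_reagents / wells) plates
    if params.wells_per_plate < 1:
        raise ValueError("plate has no usable wells")

    hit_idx = rng.choice(params.n_genes, size=params.n_true_hits, replace=False)
    is_hit = np.zeros(params.n_genes, dtype=bool)
    is_hit[hit_idx] = True

    reagent_ids: list[str] = []
    gene_col: list[str] = []
    hit_col: list[bool] = []
    for g, gene in enumerate(genes):
        for j in range(counts[g]):
            reagent_ids.append(f"{gene}_ds{j + 1}")
            gene_col.append(gene)
            hit_col.append(bool(is_hit[g]))
    n_reagents = len(reagent_ids)
    assert n_reagents == capacity_needed

    effective = rng.random(n_reagents) >= params.reagent_fn_rate
    off_target = rng.random(n_reagents) < params.reagent_fp_rate

    reagent_map = pd.DataFrame({"reagent_id": reagent_ids, "gene_id": gene_col})
    truth = pd.DataFrame(
        {
            "reagent_id": reagent_ids,
            "gene_id": gene_col,
            "gene_is_hit": hit_col,
            "effective": effective,
            "off_target": off_target,
        }
    )
    return reagent_map, truth


def _plate_layout(params: SimulationParams, n_reagents: int) -> pd.DataFrame:
    """Assign each reagent index a (plate, row, col); emit perimeter wells as empty."""
    rows, cols = params.plate_rows, params.plate_cols
    if params.perimeter_empty:
        interior = [
            (r, c) for r in range(2, rows) for c in range(2, cols)
        ]  # 1-based coords; perimeter = row/col 1 and rows/cols
        interior = [(r, c) for r, c in interior if r < rows and c < cols]
    else:
        interior = [(r, c) for r in range(1, rows + 1) for c in range(1, cols + 1)]
    per_plate = len(interior)
    n_plates = -(-n_reagents // per_plate)

    records = []
    idx = 0
    for p in range(1, n_plates + 1):
        plate_id = f"P{p:03d}"
        taken = set()
        for r, c in interior:
            if idx < n_reagents:
                records.append((plate_id, r, c, "sample", idx))
                taken.add((r, c))
                idx += 1
        if params.perimeter_empty:
            for r in range(1, rows + 1):
                for c in range(1, cols + 1):
                    if (r, c) not in interior:
                        records.append((plate_id, r, c, "empty", -1))
    return pd.DataFrame(
        records, columns=["plate_id", "row", "col", "well_role", "reagent_idx"]
    )


def generate_screen_plates(
    library: pd.DataFrame,
    truth: pd.DataFrame,
    params: SimulationParams,
) -> pd.DataFrame:
    """Simulate raw plate readings for every screen and replicate.

    A reagent is *active* when (its gene is a hit AND the reagent is
    effective) OR the reagent is off-target-active; activity flags are fixed
    across screens.  The raw value of a sample well in screen ``s`` is

        baseline(0) + effect_size * w_s * active + Normal(0, noise_sd)

    with ``w_s`` the screen's response weight.  Perimeter wells are emitted
    with role ``empty`` and a blank reagent id.  The layout is identical
    across screens and replicates; output is deterministic under the seed.
    """
    if not library["reagent_id"].equals(truth["reagent_id"]):
        raise ValueError("library and truth tables disagree on reagents")
    rng = np.random.default_rng((params.seed, 1))

    n_reagents = len(library)
    layout = _plate_layout(params, n_reagents)
    active = (truth["gene_is_hit"].to_numpy() & truth["effective"].to_numpy()) | truth[
        "off_target"
    ].to_numpy()

    lo, hi = params.screen_effect_range
    weights = rng.uniform(lo, hi, size=params.n_screens)

    sample = layout[layout["well_role"] == "sample"]
    empty = layout[layout["well_role"] != "sample"]
    reagent_ids = library["reagent_id"].to_numpy()[sample["reagent_idx"].to_numpy()]
    act = active[sample["reagent_idx"].to_numpy()].astype(float)

    frames = []
    for s in range(params.n_screens):
        screen_id = f"screen{s + 1:02d}"
        for rep in range(1, params.n_replicates_per_screen + 1):
            noise = rng.normal(0.0, params.noise_sd, size=len(sample)) if params.noise_sd > 0 else 0.0
            values = params.effect_size * weights[s] * act + noise
            frames.append(
                pd.DataFrame(
                    {
                        "screen_id": screen_id,
                        "replicate": rep,
                        "plate_id": sample["plate_id"].to_numpy(),
                        "row": sample["row"].to_numpy(),
                        "col": sample["col"].to_numpy(),
                        "well_role": "sample",
                        "reagent_id": reagent_ids,
                        "value": values,
                    }
                )
            )
            if len(empty):
                frames.append(
                    pd.DataFrame(
                        {
                            "screen_id": screen_id,
                            "replicate": rep,
                            "plate_id": empty["plate_id"].to_numpy(),
                            "row": empty["row"].to_numpy(),
                            "col": empty["col"].to_numpy(),
                            "well_role": "empty",
                            "reagent_id": "",
                            "value": 0.0,
                        }
                    )
                )
    out = pd.concat(frames, ignore_index=True)
    return out[PLATE_COLUMNS]


def generate_expression_table(
    genes: Sequence[str], params: ExpressionSimParams
) -> pd.DataFrame:
    """Draw a gene x cell-line FPKM table.

    Per cell line, each gene is expressed with probability
    ``expressed_fraction``; expressed genes draw log-normal FPKM, unexpressed
    genes draw uniformly on [0, unexpressed_fpkm_max).
    """
    if len(genes) == 0:
        raise ValueError("empty gene list")
    rng = np.random.default_rng(params.seed)
    n = len(genes)
    data = {}
    for line in params.cell_lines:
        expressed = rng.random(n) < params.expressed_fraction
        fpkm = rng.uniform(0.0, params.unexpressed_fpkm_max, size=n)
        n_expr = int(expressed.sum())
        fpkm[expressed] = np.exp(
            rng.normal(params.lognormal_mu, params.lognormal_sigma, size=n_expr)
        )
        data[line] = fpkm
    out = pd.DataFrame(data, index=pd.Index(list(genes), name="gene_id"))
    return out


def hit_annotation(truth: pd.DataFrame, label: str = "signature") -> pd.DataFrame:
    """Gene-set annotation table marking every true-hit gene with ``label``.

    Mirrors selecting a functionally coherent gene set (e.g. a protein
    complex) whose members are expected to share a screen signature.
    """
    hits = truth.loc[truth["gene_is_hit"], "gene_id"].drop_duplicates()
    return pd.DataFrame({"gene_id": hits.to_numpy(), "set_label": label})
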