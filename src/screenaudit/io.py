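"""File formats, configuration, and the end-to-end audit pipeline.

All tabular formats are UTF-8 TSV ('.' decimal separator, missing = empty
field); dendrograms are written as Newick with branch lengths; the pipeline
report is JSON with a versioned schema.  Every writer has a paired reader
that round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import categorize, errormodel, normalize, signatures, simdata

logger = logging.getLogger(__name__)

__all__ = [
    "REPORT_SCHEMA_VERSION",
    "read_plate_table",
    "write_plate_table",
    "read_zmatrix",
    "write_zmatrix",
    "read_reagent_map",
    "write_reagent_map",
    "read_truth",
    "write_truth",
    "read_annotation",
    "write_annotation",
    "read_fpkm",
    "write_fpkm",
    "read_table2_fixture",
    "dendrogram_to_newick",
    "PipelineConfig",
    "stage_seed",
    "run_pipeline",
]

REPORT_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# readers / writers

def read_plate_table(path, plate_rows: int = 16, plate_cols: int = 24) -> pd.DataFrame:
    """Read and validate a plate-readings TSV.

    Raises ValueError naming the offending line for missing columns,
    non-numeric values, duplicate wells, or out-of-range coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in normalize.PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("row", "col", "replicate"):
        try:
            df[col] = df[col].astype(int)
        except ValueError as exc:
            bad = df.index[~df[col].str.fullmatch(r"-?\d+")][0]
            raise ValueError(f"{path}: non-integer {col!r} at line {bad + 2}") from exc
    numeric = pd.to_numeric(df["value"], errors="coerce")
    if numeric.isna().any():
        bad = int(df.index[numeric.isna()][0])
        raise ValueError(f"{path}: non-numeric value at line {bad + 2}")
    df["value"] = numeric
    out_of_range = (
        (df["row"] < 1) | (df["row"] > plate_rows) | (df["col"] < 1) | (df["col"] > plate_cols)
    )
    if out_of_range.any():
        bad = int(df.index[out_of_range][0])
        raise ValueError(f"{path}: well coordinates out of range at line {bad + 2}")
    dup = df.duplicated(subset=["screen_id", "replicate", "plate_id", "row", "col"])
    if dup.any():
        bad = int(df.index[dup][0])
        raise ValueError(f"{path}: duplicate well at line {bad + 2}")
    bad_role = ~df["well_role"].isin(sorted(normalize.WELL_ROLES))
    if bad_role.any():
        bad = int(df.index[bad_role][0])
        raise ValueError(f"{path}: unknown well_role at line {bad + 2}")
    no_reagent = (df["well_role"] == "sample") & (df["reagent_id"] == "")
    if no_reagent.any():
        bad = int(df.index[no_reagent][0])
        raise ValueError(f"{path}: sample well without reagent_id at line {bad + 2}")
    return df[normalize.PLATE_COLUMNS]


def write_plate_table(readings: pd.DataFrame, path) -> None:
    readings.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_zmatrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="reagent_id")
    return df.astype(float)


def write_zmatrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="reagent_id", float_format="%.12g")


def read_reagent_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("reagent_id", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def write_reagent_map(reagent_map: pd.DataFrame, path) -> None:
    reagent_map.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"reagent_id": str, "gene_id": str})
    for col in ("gene_is_hit", "effective", "off_target"):
        df[col] = df[col].astype(bool)
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "set_label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_fpkm(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id").astype(float)


def write_fpkm(fpkm: pd.DataFrame, path) -> None:
    fpkm.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_table2_fixture() -> pd.DataFrame:
    """The packaged worked-example table: per-gene reagent counts, category,
    and S2R+ expression status for the 24 hit genes of a focused
    kinase/phosphatase screen."""
    path = Path(__file__).parent / "data" / "table2_fixture.tsv"
    df = pd.read_csv(path, sep="\t")
    df["expressed"] = df["expressed"] == "Yes"
    return df


def dendrogram_to_newick(dendrogram: signatures.Dendrogram) -> str:
    """Render a dendrogram as a Newick string with branch lengths.

    Branch length of a node is (parent merge height - own merge height);
    leaves sit at height 0.
    """
    Z = dendrogram.linkage
    leaves = dendrogram.leaves
    n = len(leaves)
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for i, (a, b, h, _) in enumerate(Z):
        node = n + i
        height[node] = float(h)
        children[node] = (int(a), int(b))
    root = n + len(Z) - 1

    # iterative post-order rendering (deep dendrograms overflow recursion)
    rendered: dict[int, str] = {}
    stack = [root]
    while stack:
        node = stack.pop()
        if node < n:
            rendered[node] = leaves[node]
            continue
        a, b = children[node]
        if a in rendered and b in rendered:
            ha = height[node] - height[a]
            hb = height[node] - height[b]
            rendered[node] = f"({rendered[a]}:{ha:.10g},{rendered[b]}:{hb:.10g})"
        else:
            stack.extend([node, a, b])
    return rendered[root] + ";"


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """End-to-end audit configuration; defaults match the documented stage defaults."""

    # simulation
    simulate: bool = True
    sim: simdata.SimulationParams = field(default_factory=simdata.SimulationParams)
    expression: simdata.ExpressionSimParams = field(
        default_factory=simdata.ExpressionSimParams
    )
    # normalization
    sd_ddof: int = 1
    include_controls: bool = False
    # clustering / concordance
    cut_height: float = 0.5
    r_threshold: float = 0.5
    min_cluster_size: int = 3
    # hit calling / categories
    z_threshold: float = 2.0
    require_sign_consistency: bool = True
    categorize_screen: str | None = None
    cell_line: str | None = None
    fpkm_expressed: float = 1.0
    fpkm_elevated: float = 5.0
    # error model
    model_r_fn: float = 0.10
    model_r_fp: float = 0.01
    model_hits: int = 100
    model_genes: int = 13735
    model_k: int = 3
    model_rule: str = "majority"
    model_n_reps: int = 0  # 0 disables the Monte-Carlo check
    # paths (used when simulate=False)
    plates_path: str | None = None
    reagent_map_path: str | None = None
    annotation_path: str | None = None
    fpkm_path: str | None = None
    # master seed; every stochastic stage derives its own stream from it
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in data and isinstance(data["sim"], dict):
            sim_known = {f.name for f in dataclasses.fields(simdata.SimulationParams)}
            bad = set(data["sim"]) - sim_known
            if bad:
                raise ValueError(f"unknown sim config keys: {sorted(bad)}")
            if "screen_effect_range" in data["sim"]:
                data["sim"]["screen_effect_range"] = tuple(
                    data["sim"]["screen_effect_range"]
                )
            if "reagents_per_gene" in data["sim"] and not isinstance(
                data["sim"]["reagents_per_gene"], int
            ):
                data["sim"]["reagents_per_gene"] = list(data["sim"]["reagents_per_gene"])
            data["sim"] = simdata.SimulationParams(**data["sim"])
        if "expression" in data and isinstance(data["expression"], dict):
            expr_known = {
                f.name for f in dataclasses.fields(simdata.ExpressionSimParams)
            }
            bad = set(data["expression"]) - expr_known
            if bad:
                raise ValueError(f"unknown expression config keys: {sorted(bad)}")
            if "cell_lines" in data["expression"]:
                data["expression"]["cell_lines"] = tuple(data["expression"]["cell_lines"])
            data["expression"] = simdata.ExpressionSimParams(**data["expression"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["screen_effect_range"] = list(d["sim"]["screen_effect_range"])
        if not isinstance(d["sim"]["reagents_per_gene"], int):
            d["sim"]["reagents_per_gene"] = list(d["sim"]["reagents_per_gene"])
        d["expression"]["cell_lines"] = list(d["expression"]["cell_lines"])
        return d


def stage_seed(master_seed: int, stage: int) -> int:
    """Derive a per-stage integer seed (< 2**31) from the master seed.

    Stages are numbered: 0 = library/plates simulation, 1 = expression table,
    2 = error-model Monte-Carlo.  Partial reruns of any stage are therefore
    reproducible from the master seed alone.
    """
    ss = np.random.SeedSequence([int(master_seed), int(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# end-to-end pipeline

def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run simulate -> normalize -> cluster -> categorize -> model; return the JSON-ready report.

    When ``out_dir`` is given, all intermediate tables (plates, Z matrix,
    concordance calls, categories, Newick dendrogram) and the report are
    written there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: inputs -------------------------------------------------
    if config.simulate:
        logger.info("simulate: %s (seed %d)", config.sim, config.seed)
        sim = dataclasses.replace(config.sim, seed=stage_seed(config.seed, 0))
        expr = dataclasses.replace(config.expression, seed=stage_seed(config.seed, 1))
        reagent_map, truth = simdata.generate_library(sim)
        readings = simdata.generate_screen_plates(reagent_map, truth, sim)
        genes = reagent_map["gene_id"].drop_duplicates().tolist()
        fpkm = simdata.generate_expression_table(genes, expr)
        annotation = simdata.hit_annotation(truth)
    else:
        if not (config.plates_path and config.reagent_map_path and config.annotation_path):
            raise ValueError("simulate=False requires plates/reagent-map/annotation paths")
        readings = read_plate_table(config.plates_path)
        reagent_map = read_reagent_map(config.reagent_map_path)
        annotation = read_annotation(config.annotation_path)
        fpkm = read_fpkm(config.fpkm_path) if config.fpkm_path else None
        truth = None

    # --- stage 2: normalization ------------------------------------------
    logger.info("normalize: ddof=%d include_controls=%s", config.sd_ddof, config.include_controls)
    normalized = normalize.normalize_plates(
        readings, ddof=config.sd_ddof, include_controls=config.include_controls
    )
    zmat = normalize.assemble_profile_matrix(normalized)

    # per-screen matrix for clustering: replicate columns averaged
    screens = normalized["screen_id"].astype(str).unique().tolist()
    per_screen = {}
    col_screen = {
        col: col.split(":", 1)[0] for col in zmat.columns
    }
    for s in screens:
        cols = [c for c in zmat.columns if col_screen[c] == s]
        per_screen[s] = zmat[cols].mean(axis=1, skipna=True)
    screen_matrix = pd.DataFrame(per_screen)

    # --- stage 3: clustering + concordance --------------------------------
    logger.info(
        "cluster: cut=%.3g r_threshold=%.3g", config.cut_height, config.r_threshold
    )
    conc = signatures.concordance_pipeline(
        screen_matrix,
        reagent_map,
        annotation,
        cut_height=config.cut_height,
        r_threshold=config.r_threshold,
        min_cluster_size=config.min_cluster_size,
        z_active_threshold=config.z_threshold,
    )

    # --- stage 4: hit calling + categories + expression filter ------------
    # default to the most responsive screen (largest Z spread): in a
    # simulated panel no screen is privileged, and a flat assay would
    # trivially call nothing
    screen_for_cat = config.categorize_screen or screen_matrix.std().idxmax()
    rep_cols = [c for c in zmat.columns if col_screen[c] == screen_for_cat]
    logger.info("categorize: screen=%s zcut=%.3g", screen_for_cat, config.z_threshold)
    hits = categorize.call_reagent_hits(
        zmat[rep_cols],
        threshold=config.z_threshold,
        require_sign_consistency=config.require_sign_consistency,
    )
    cats = categorize.assign_gene_categories(hits, reagent_map)
    if fpkm is not None:
        line = config.cell_line or fpkm.columns[0]
        cats = categorize.apply_expression_filter(
            cats,
            fpkm,
            line,
            threshold=config.fpkm_expressed,
            elevated_threshold=config.fpkm_elevated,
        )
    if cats["category"].isin([1, 2, 3]).any():
        rates = categorize.estimate_screen_rates(cats, library_size=len(reagent_map))
    else:
        # a screen with no hit genes has nothing to attribute
        rates = categorize.RateEstimates(
            0.0, 0.0, 0.0, 0, 0, 0, 0, len(reagent_map), 0, 0
        )

    # --- stage 5: error model ---------------------------------------------
    rule = errormodel.DisambiguationRule.from_name(config.model_rule, config.model_k)
    rates_em = errormodel.ErrorRates(config.model_r_fn, config.model_r_fp)
    scenario = errormodel.LibraryScenario(
        config.model_hits, config.model_genes - config.model_hits, config.model_k
    )
    outcome = errormodel.expected_error_counts(rates_em, scenario, rule)
    model_report = {
        "rule": config.model_rule,
        "k": config.model_k,
        "m": rule.m,
        "expected_fn": outcome.expected_fn,
        "expected_fp": outcome.expected_fp,
    }
    if config.model_n_reps > 0:
        sim_summary = errormodel.simulate_disambiguation(
            rates_em,
            scenario,
            rule,
            n_reps=config.model_n_reps,
            seed=stage_seed(config.seed, 2),
        )
        model_report["simulation"] = dataclasses.asdict(sim_summary)

    classification_counts = (
        conc.calls["classification"].value_counts().to_dict() if len(conc.calls) else {}
    )
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config": config.to_dict(),
        "concordance": {
            "n_multireagent_genes": int(len(conc.calls)),
            "classification_counts": {
                k: int(v) for k, v in sorted(classification_counts.items())
            },
            "n_false_negative_reagents": conc.estimate.n_false_negative,
            "total_signature_reagents": conc.estimate.total_reagents,
            "fn_rate": conc.estimate.rate,
            "degenerate_mode": conc.degenerate,
        },
        "categories": {
            "n_category1": rates.n_category1,
            "n_category2": rates.n_category2,
            "n_category3": rates.n_category3,
            "n_hit_genes": rates.n_hit_genes,
        },
        "screen_rates": {
            "fp_reagent_rate": rates.fp_reagent_rate,
            "fp_hit_fraction": rates.fp_hit_fraction,
            "fn_reagent_rate": rates.fn_reagent_rate,
            "library_size": rates.library_size,
        },
        "error_model": model_report,
    }

    if out is not None:
        write_plate_table(readings, out / "plates.tsv")
        write_reagent_map(reagent_map, out / "reagent_map.tsv")
        write_annotation(annotation, out / "annotation.tsv")
        if truth is not None:
            write_truth(truth, out / "truth.tsv")
        if fpkm is not None:
            write_fpkm(fpkm, out / "fpkm.tsv")
        write_zmatrix(zmat, out / "zmatrix.tsv")
        conc.calls.to_csv(out / "concordance.tsv", sep="\t", index=False)
        cats.to_csv(out / "categories.tsv", sep="\t", index=False)
        if conc.dendrogram is not None:
            (out / "dendrogram.nwk").write_text(dendrogram_to_newick(conc.dendrogram))
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
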