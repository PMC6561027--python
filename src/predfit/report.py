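"""End-to-end orchestration and summary reproduction.

``run_screen`` drives the whole synthetic pipeline — genome, library,
competitive expansion per condition, fitness estimation, essential calls,
pool-sorting scores — from one YAML-able configuration and returns a
:class:`ScreenSummary`.  ``reproduce_supplementary`` recomputes the same
headline numbers (threshold counts, collective control scores, pairwise
Spearman correlations, killing categories) from supplementary-format
tables rather than raw counts, re-deriving every number from values, never
from spreadsheet formatting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .fitness import ExpansionFitnessModel, condition_correlation, threshold_bins
from .io import find_column, read_table
from .phenotype import killing_category
from .pools import PoolEnrichmentModel

log = logging.getLogger("predfit")

DEFAULT_THRESHOLDS = {
    "fitness_defective": 0.1,
    "fitness_borderline": 0.5,
    "fitness_high": 2.0,
    "fitness_improved": 3.0,
    "attachment": [0.5, 0.3],
    "rounding": [0.4, 0.2],
    "survival_no_kill": 50.0,
    "survival_kills": 1.0,
}


@dataclass
class ScreenSummary:
    """Headline numbers for one screen (or one reproduced table set)."""

    conditions: list[str]
    n_genes_scored: dict[str, int]
    bin_counts: dict[str, dict[str, int]]
    essential_counts: dict[str, int] = field(default_factory=dict)
    collective_control_scores: dict[str, float] = field(default_factory=dict)
    pool_threshold_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    spearman_rho: dict[str, float] = field(default_factory=dict)
    killing_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _require(config: dict, key: str):
    if key not in config:
        raise KeyError(f"config is missing required field {key!r}")
    return config[key]


def run_screen(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute simulate -> count -> fitness -> scores -> summarise.

    ``config`` keys (all sizes overridable): ``seed``, ``genome_length``,
    ``n_genes``, ``n_insertions``, ``read_depth``, ``n_replicates``,
    ``conditions`` (mapping condition name -> expansion factor ``d``;
    required), optional ``landscape`` (counts of essential/defective/dead/
    improved genes), optional ``pools`` (depth/replicates/mutants for the
    sorting assays), ``thresholds``.

    Returns a dict with the summary and every stage output; writes TSVs
    under ``outdir`` when given.  Deterministic for a fixed seed.
    """
    seed = int(config.get("seed", 0))
    conditions = _require(config, "conditions")
    if not isinstance(conditions, dict) or not conditions:
        raise KeyError("config 'conditions' must map condition name -> expansion factor d")
    for name, d in conditions.items():
        if d is None:
            raise KeyError(f"condition {name!r} is missing its expansion factor d")

    land = config.get("landscape", {})
    sim = simulate.SimConfig(
        genome_length=int(config.get("genome_length", 300_000)),
        n_genes=int(config.get("n_genes", 200)),
        n_insertions=int(config.get("n_insertions", 2000)),
        read_depth=int(config.get("read_depth", 2_000_000)),
        n_replicates=int(config.get("n_replicates", 3)),
        ta_enrichment=float(config.get("ta_enrichment", 0.04)),
        expansion_factor=float(next(iter(conditions.values()))),
        seed=seed,
    )
    log.info("stage=genome seed=%d length=%d genes=%d", seed, sim.genome_length, sim.n_genes)
    genome, genes = simulate.gen_genome(sim)
    fitness_map, essential = simulate.fitness_landscape(
        genes["gene_id"],
        n_essential=int(land.get("essential", 10)),
        n_defective=int(land.get("defective", 15)),
        n_dead=int(land.get("dead", 5)),
        n_improved=int(land.get("improved", 10)),
        seed=seed,
    )
    sim = dataclasses.replace(sim, true_fitness=fitness_map, essential_genes=essential)
    log.info("stage=library insertions=%d essential=%d", sim.n_insertions, len(essential))
    sites, truth = simulate.gen_library(genome, genes, sim)

    results: dict[str, object] = {
        "genes": genes,
        "truth": truth,
        "sites": sites,
        "essential_genes": essential,
        "true_fitness": fitness_map,
    }
    n_scored, bin_counts, ess_counts, rhos = {}, {}, {}, {}
    fitness_results = {}
    for name, d in conditions.items():
        log.info("stage=expansion condition=%s d=%s", name, d)
        table = simulate.simulate_expansion(
            truth,
            d=float(d),
            depth=sim.read_depth,
            n_replicates=sim.n_replicates,
            seed=seed + zlib.crc32(name.encode()) % 10_000,
            condition=name,
        )
        res = ExpansionFitnessModel(
            table, d=float(d), genes=genes["gene_id"], condition=name
        ).fit()
        fitness_results[name] = res
        n_scored[name] = len(res.gene_table)
        _, bin_counts[name] = res.bins()
        ess = res.essentials["category"].value_counts()
        ess_counts[name] = int(ess.get("essential_zero", 0))
    for a in conditions:
        for b in conditions:
            if a < b:
                rhos[f"{a}:{b}"] = condition_correlation(
                    fitness_results[a].W, fitness_results[b].W
                )
    results["fitness"] = fitness_results

    pools_cfg = config.get("pools", {})
    ctrl_scores, pool_counts = {}, {}
    pool_results = {}
    if pools_cfg:
        depth = int(pools_cfg.get("depth", 1_000_000))
        n_rep = int(pools_cfg.get("replicates", 6))
        n_mut = int(pools_cfg.get("mutants", 100))
        n_ctrl = int(pools_cfg.get("controls", 10))
        for which, score_type, simulate_fn in (
            ("attach", "attachment", simulate.simulate_sorting),
            ("round", "rounding", simulate.simulate_bdelloplast),
        ):
            pool_truth = simulate.make_pool_truth(
                n_mut, n_ctrl, which=which, seed=seed
            )
            if which == "attach":
                table = simulate_fn(pool_truth, depth=depth, seed=seed, n_replicates=n_rep)
            else:
                table = simulate_fn(
                    pool_truth,
                    contamination=float(pools_cfg.get("contamination", 0.02)),
                    depth=depth,
                    seed=seed,
                    n_replicates=n_rep,
                )
            log.info("stage=pool type=%s depth=%d replicates=%d", score_type, depth, n_rep)
            pres = PoolEnrichmentModel(table, score_type=score_type).fit()
            pool_results[score_type] = (pool_truth, pres)
            ctrl_scores[score_type] = pres.collective_control_score
            pool_counts[score_type] = pres.classify()
    results["pools"] = pool_results

    summary = ScreenSummary(
        conditions=list(conditions),
        n_genes_scored=n_scored,
        bin_counts=bin_counts,
        essential_counts=ess_counts,
        collective_control_scores=ctrl_scores,
        pool_threshold_counts=pool_counts,
        spearman_rho=rhos,
    )
    results["summary"] = summary

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import write_fasta, write_genes_gff

        write_fasta(genome, outdir / "genome.fasta")
        write_genes_gff(genes, outdir / "genes.gff")
        truth.to_csv(outdir / "truth.tsv", sep="\t")
        for name, res in fitness_results.items():
            res.to_tsv(outdir / f"fitness_{name}.tsv")
            res.essentials.to_csv(outdir / f"essentials_{name}.tsv", sep="\t")
        for score_type, (_, pres) in pool_results.items():
            pres.to_tsv(outdir / f"scores_{score_type}.tsv")
        summary.to_json(outdir / "summary.json")
    return results


# ---------------------------------------------------------------------------
# supplementary-table reproduction
# ---------------------------------------------------------------------------

def summarize_fitness_table(
    df: pd.DataFrame, thresholds: dict | None = None
) -> dict:
    """Threshold counts and pairwise rank correlations from a fitness table.

    Detects every fitness column (headers containing ``w``/``fitness``,
    excluding SD columns) and reports, per column, the number of genes
    below the defective/borderline cuts and above the high/improved cuts,
    plus pairwise Spearman rho between the fitness columns.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    w_cols = [
        c
        for c in df.columns
        if ("fitness" in c.lower() or c.lower() == "w" or c.lower().startswith("w "))
        and "sd" not in c.lower()
        and "std" not in c.lower()
    ]
    if not w_cols:
        raise KeyError(
            "no fitness columns found (expected headers containing 'W' or 'fitness'); "
            f"table has {list(df.columns)}"
        )
    counts = {}
    for c in w_cols:
        w = pd.to_numeric(df[c], errors="coerce").dropna()
        counts[c] = {
            "scored": int(len(w)),
            "below_defective": int((w < th["fitness_defective"]).sum()),
            "below_borderline": int((w < th["fitness_borderline"]).sum()),
            "above_high": int((w > th["fitness_high"]).sum()),
            "above_improved": int((w > th["fitness_improved"]).sum()),
        }
    rho = {}
    for i, a in enumerate(w_cols):
        for b in w_cols[i + 1 :]:
            pair = df[[a, b]].apply(pd.to_numeric, errors="coerce").dropna()
            if len(pair) >= 3:
                rho[f"{a}:{b}"] = condition_correlation(pair[a], pair[b])
    return {"columns": w_cols, "counts": counts, "spearman_rho": rho}


def summarize_score_table(
    df: pd.DataFrame,
    score_type: str = "attachment",
    thresholds: dict | None = None,
) -> dict:
    """Threshold counts and the collective control score from a score table.

    Control rows are recognised from an ``is_control`` column or from
    ``intergenic`` appearing in the gene/mutant id.  When per-pool count
    columns (``selected_reads``/``reference_reads``) are present the
    collective control score is recomputed exactly from the pooled counts;
    otherwise it falls back to the mean of the control rows' scores.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    score_col = find_column(df, f"{score_type} score", "score", score_type)
    scores = pd.to_numeric(df[score_col], errors="coerce")
    if "is_control" in df.columns:
        is_ctrl = df["is_control"].astype(bool)
    else:
        try:
            idcol = find_column(df, "gene", "mutant", "id")
            is_ctrl = df[idcol].astype(str).str.contains("intergenic", case=False)
        except KeyError:
            is_ctrl = pd.Series(False, index=df.index)
    hi, lo = max(th[score_type]), min(th[score_type])
    tested = scores[~is_ctrl].dropna()
    if {"selected_reads", "reference_reads"} <= set(df.columns) and is_ctrl.any():
        sel = df.loc[is_ctrl, "selected_reads"].sum() / df["selected_reads"].sum()
        ref = df.loc[is_ctrl, "reference_reads"].sum() / df["reference_reads"].sum()
        control = float(sel / ref)
    else:
        control = float(scores[is_ctrl].mean()) if is_ctrl.any() else float("nan")
    return {
        "score_column": score_col,
        "tested": int(len(tested)),
        f"below_{hi}": int((tested < hi).sum()),
        f"below_{lo}": int((tested < lo).sum()),
        "collective_control_score": control,
    }


def summarize_survival_table(df: pd.DataFrame) -> dict:
    """Killing-category counts from a survival-percentage column."""
    col = find_column(df, "survival", "survival_pct", "% survival")
    s = pd.to_numeric(df[col], errors="coerce").dropna()
    cats = s.map(killing_category).value_counts()
    return {
        "tested": int(len(s)),
        "no_kill": int(cats.get("no_kill", 0)),
        "kills": int(cats.get("kills", 0)),
        "intermediate": int(cats.get("intermediate", 0)),
    }


def reproduce_supplementary(
    fitness_tables: dict[str, object] | None = None,
    attachment_table=None,
    rounding_table=None,
    survival_table=None,
    thresholds: dict | None = None,
) -> dict:
    """Recompute headline summary statistics from supplementary-format tables.

    Every argument accepts a path (.xlsx/.tsv/.csv) or an in-memory
    DataFrame.  Returns a nested dict of recomputed counts, collective
    control scores and Spearman correlations.
    """
    def _load(obj):
        return obj if isinstance(obj, pd.DataFrame) else read_table(obj)

    out: dict[str, object] = {}
    if fitness_tables:
        out["fitness"] = {
            name: summarize_fitness_table(_load(t), thresholds)
            for name, t in fitness_tables.items()
        }
    if attachment_table is not None:
        out["attachment"] = summarize_score_table(
            _load(attachment_table), "attachment", thresholds
        )
    if rounding_table is not None:
        out["rounding"] = summarize_score_table(
            _load(rounding_table), "rounding", thresholds
        )
    if survival_table is not None:
        out["survival"] = summarize_survival_table(_load(survival_table))
    if not out:
        raise ValueError("no tables supplied")
    return out
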