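"""Expansion-fitness estimation, essential-gene calling and fitness binning.

The fitness statistic *W* compares a mutant's frequency before (``f1``) and
after (``f2``) a competitive expansion in which the whole population grew
``d``-fold::

    W = ln(f2 * d / f1) / ln((1 - f2) * d / (1 - f1))

*W* = 1 means the disruption is neutral (the mutant expanded like the bulk),
*W* < 1 a predation/growth defect, and *W* = 0 a dead lineage (the
``f2 = 0`` convention; no pseudocount by default).  Gene-level fitness is
the read-weighted mean over a gene's insertions within each biological
replicate, then the unweighted mean (with sample SD) across replicates.

The module is organised statsmodels-style: build an
:class:`ExpansionFitnessModel` from a :class:`~predfit.tables.CountTable`,
call :meth:`~ExpansionFitnessModel.fit`, and read estimates off the
returned :class:`FitnessResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CountTable

DEFAULT_CUTS = {"defective": 0.1, "borderline": 0.5, "high": 2.0, "improved": 3.0}

BIN_ORDER = ["defective", "borderline", "neutral", "high", "improved"]


# ---------------------------------------------------------------------------
# elemental operations
# ---------------------------------------------------------------------------

def expansion_fitness(f1, f2, d):
    """Per-insertion fitness W from input/output frequencies.

    Vectorised over ``f1``/``f2``.  Requires ``0 < f1 < 1``,
    ``0 <= f2 < 1`` and ``d > 1``; returns exactly 0 where ``f2 == 0``
    (dead-mutant convention) and exactly 1 where ``f2 == f1``.
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if d <= 1:
        raise ValueError("expansion factor d must be > 1")
    if np.any((f1 <= 0) | (f1 >= 1)):
        raise ValueError("input frequency f1 must lie in (0, 1): mutant absent from input")
    if np.any((f2 < 0) | (f2 >= 1)):
        raise ValueError("output frequency f2 must lie in [0, 1)")
    with np.errstate(divide="ignore"):
        num = np.log(f2 * d / f1)
        den = np.log((1.0 - f2) * d / (1.0 - f1))
        w = np.where(f2 == 0, 0.0, num / den)
    # mutants depleted below a d-fold absolute decline would score negative;
    # the dead-mutant convention floors them at 0
    w = np.maximum(w, 0.0)
    return w if w.ndim else float(w)


def gene_fitness(
    insertion_fitness: pd.DataFrame,
    weighted: bool = True,
) -> pd.DataFrame:
    """Aggregate per-insertion W values to per-gene records.

    ``insertion_fitness`` columns: ``gene_id``, ``replicate``, ``W``,
    ``weight`` (input reads).  Per replicate the gene W is the
    weight-averaged (or plain, if ``weighted=False``) mean over the gene's
    insertions with non-zero input reads; the reported W is the unweighted
    mean over replicates and ``sd`` the sample standard deviation
    (0 when a single replicate is available).
    """
    df = insertion_fitness[insertion_fitness["weight"] > 0]
    records = []
    for gene, sub in df.groupby("gene_id", sort=True):
        per_rep = []
        for _, rep_rows in sub.groupby("replicate"):
            w = rep_rows["W"].to_numpy()
            wt = rep_rows["weight"].to_numpy() if weighted else np.ones(len(rep_rows))
            per_rep.append(float(np.average(w, weights=wt)))
        per_rep = np.asarray(per_rep)
        records.append(
            {
                "gene_id": gene,
                "W": float(per_rep.mean()),
                "sd": float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0,
                "n_insertions": int(sub.index.nunique()),
                "n_replicates": len(per_rep),
            }
        )
    return pd.DataFrame(records).set_index("gene_id")


def call_essentials(
    insertions_per_replicate: pd.DataFrame, pooled: pd.Series | None = None
) -> pd.DataFrame:
    """Classify genes by observed insertion support.

    ``insertions_per_replicate``: genes x replicates frame of the number of
    distinct insertion sites with at least one input read.  Genes with zero
    insertions in every replicate are called ``essential_zero``; genes
    averaging less than one insertion are ``putative_lt1``; the rest are
    ``nonessential``.  Both the per-replicate mean and the pooled unique
    count (union over replicates; defaults to the per-replicate maximum
    when no union is supplied) are reported, since the two conventions can
    disagree for sparsely covered genes.
    """
    mean_ins = insertions_per_replicate.mean(axis=1)
    if pooled is None:
        pooled = insertions_per_replicate.max(axis=1)
    pooled = pooled.reindex(insertions_per_replicate.index, fill_value=0)
    category = np.where(
        (insertions_per_replicate == 0).all(axis=1),
        "essential_zero",
        np.where(mean_ins < 1, "putative_lt1", "nonessential"),
    )
    return pd.DataFrame(
        {
            "category": category,
            "mean_insertions": mean_ins,
            "pooled_insertions": pooled,
        },
        index=insertions_per_replicate.index,
    )


def threshold_bins(w: pd.Series, cuts: dict[str, float] | None = None):
    """Bin genes by fitness thresholds.

    Primary bins partition the scored genes: ``defective`` (W < 0.1),
    ``borderline`` (0.1 <= W < 0.5), ``neutral`` (0.5 <= W <= 2.0),
    ``high`` (2.0 < W <= 3.0) and ``improved`` (W > 3.0).  The returned
    counts additionally report ``high_total`` (every W > 2.0, i.e. the
    high/improved overlap made explicit).
    """
    c = {**DEFAULT_CUTS, **(cuts or {})}
    w = w.astype(float)
    bins = pd.Series("neutral", index=w.index, dtype=object)
    bins[w < c["borderline"]] = "borderline"
    bins[w < c["defective"]] = "defective"
    bins[w > c["high"]] = "high"
    bins[w > c["improved"]] = "improved"
    counts = {name: int((bins == name).sum()) for name in BIN_ORDER}
    counts["high_total"] = int((w > c["high"]).sum())
    counts["total"] = int(len(w))
    return bins, counts


def condition_correlation(w_a: pd.Series, w_b: pd.Series) -> float:
    """Spearman rank correlation of gene fitness between two conditions.

    Computed over the genes shared by both vectors, with average ranks for
    ties.  Requires at least three shared genes.
    """
    shared = w_a.index.intersection(w_b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    rho = stats.spearmanr(w_a.loc[shared], w_b.loc[shared]).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ExpansionFitnessModel:
    """Per-gene expansion-fitness model over a paired input/output screen.

    Parameters
    ----------
    table : CountTable
        Must contain, for every replicate, one ``pool_role == "reference"``
        (input) and one ``pool_role == "selected"`` (output) sample.
    d : float
        Population expansion factor for the condition (output CFU / input
        CFU); supplied, never estimated from counts.
    site_gene : pandas.Series, optional
        site_id -> gene_id mapping (e.g. from
        :func:`predfit.counts.assign_genes`); defaults to the table's own
        ``gene_id`` column.
    genes : sequence of str, optional
        Full annotated gene list, so zero-insertion genes flow into
        essential calling.  Defaults to the genes seen in the table.
    weighted : bool
        Weight insertions by input reads within a replicate (default) or
        average unweighted.
    pseudocount : bool
        When True, add one read to every zero output count before
        frequency calculation instead of applying the W = 0 convention.
    """

    def __init__(
        self,
        table: CountTable,
        d: float,
        site_gene: pd.Series | None = None,
        genes=None,
        weighted: bool = True,
        pseudocount: bool = False,
        condition: str | None = None,
    ):
        if d <= 1:
            raise ValueError("expansion factor d must be > 1")
        self.table = table
        self.d = float(d)
        self.weighted = weighted
        self.pseudocount = pseudocount
        self.condition = condition
        if site_gene is None:
            if "gene_id" not in table.sites.columns:
                raise ValueError("no gene assignment: pass site_gene or a gene_id column")
            site_gene = table.sites["gene_id"]
        self.site_gene = site_gene.reindex(table.counts.index)
        self.genes = (
            pd.Index(genes)
            if genes is not None
            else pd.Index(sorted(set(self.site_gene) - {"intergenic"}))
        )

    def _pairs(self) -> list[tuple[int, str, str]]:
        out = []
        for rep in self.table.replicates():
            ref = self.table.select_samples(pool_role="reference", replicate=rep)
            sel = self.table.select_samples(pool_role="selected", replicate=rep)
            if self.condition is not None:
                sel = [
                    s
                    for s in sel
                    if self.table.samples.loc[s, "condition"] == self.condition
                ]
            if len(ref) != 1 or len(sel) != 1:
                raise ValueError(
                    f"replicate {rep}: need exactly one reference and one "
                    f"selected sample, found {len(ref)}/{len(sel)}"
                )
            out.append((rep, ref[0], sel[0]))
        return out

    def fit(self) -> "FitnessResults":
        rows = []
        support = {}
        for rep, ref, sel in self._pairs():
            in_counts = self.table.counts[ref].astype(float)
            out_counts = self.table.counts[sel].astype(float)
            if self.pseudocount:
                out_counts = out_counts.where(out_counts > 0, 1.0)
            with_input = in_counts > 0
            f1 = in_counts[with_input] / in_counts.sum()
            f2 = out_counts[with_input] / out_counts.sum()
            w = expansion_fitness(f1.to_numpy(), f2.to_numpy(), self.d)
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": self.site_gene[with_input].to_numpy(),
                        "replicate": rep,
                        "W": w,
                        "weight": in_counts[with_input].to_numpy(),
                    },
                    index=f1.index,
                )
            )
            support[rep] = (
                pd.Series(self.site_gene[with_input].to_numpy())
                .value_counts()
                .reindex(self.genes, fill_value=0)
            )
        per_insertion = pd.concat(rows)
        per_insertion = per_insertion[per_insertion["gene_id"] != "intergenic"]
        gene_table = gene_fitness(per_insertion, weighted=self.weighted)
        # correct n_insertions to pooled unique sites per gene
        pooled_sites = (
            per_insertion.reset_index()
            .drop_duplicates(subset=["site_id", "gene_id"])
            .groupby("gene_id")
            .size()
        )
        gene_table["n_insertions"] = pooled_sites.reindex(gene_table.index).astype(int)
        insertions_per_rep = pd.DataFrame(support)
        pooled_union = (
            pd.concat(rows)
            .reset_index()
            .drop_duplicates(subset=["site_id", "gene_id"])
            .groupby("gene_id")
            .size()
            .reindex(self.genes, fill_value=0)
        )
        essentials = call_essentials(insertions_per_rep, pooled=pooled_union)
        return FitnessResults(
            model=self,
            per_insertion=per_insertion,
            gene_table=gene_table,
            insertions_per_replicate=insertions_per_rep,
            essentials=essentials,
        )


@dataclass
class FitnessResults:
    """Estimates from :class:`ExpansionFitnessModel.fit`.

    Attributes
    ----------
    per_insertion : frame of per-site, per-replicate W values and weights.
    gene_table : per-gene W, sd over replicates, insertion support.
    essentials : per-gene essentiality category over the full gene list.
    """

    model: ExpansionFitnessModel
    per_insertion: pd.DataFrame
    gene_table: pd.DataFrame
    insertions_per_replicate: pd.DataFrame
    essentials: pd.DataFrame
    _bins: tuple | None = field(default=None, repr=False)

    @property
    def W(self) -> pd.Series:
        return self.gene_table["W"]

    def bins(self, cuts: dict[str, float] | None = None):
        return threshold_bins(self.gene_table["W"], cuts)

    def correlate(self, other: "FitnessResults") -> float:
        return condition_correlation(self.W, other.W)

    def summary(self) -> str:
        _, counts = self.bins()
        ess = self.essentials["category"].value_counts()
        lines = [
            "Expansion fitness results",
            "=" * 34,
            f"condition:        {self.model.condition or 'unnamed'}",
            f"expansion d:      {self.model.d:g}",
            f"genes scored:     {len(self.gene_table)}",
            f"replicates:       {self.insertions_per_replicate.shape[1]}",
            f"essential (zero insertions):   {ess.get('essential_zero', 0)}",
            f"putative (<1 insertion/rep):   {ess.get('putative_lt1', 0)}",
            "fitness bins: "
            + ", ".join(f"{k}={counts[k]}" for k in BIN_ORDER),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.gene_table.to_csv(path, sep="\t")
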