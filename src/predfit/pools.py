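"""Pool-abundance ratio scores: Tn-FACSeq attachment and Tn-SphereSeq rounding.

Both assays sort a mutant pool into a phenotype-positive ("selected") and a
reference pool, sequence both, and score each mutant by the ratio of its
frequencies::

    score = freq(selected pool) / freq(reference pool)

For attachment the selected pool holds predators attached to prey and the
reference pool the unattached ones; for rounding the selected pool is the
bdelloplast band and the reference the unsorted input.  A score near 1
means the mutant partitions like the bulk population — no defect; defective
mutants score low.  Intergenic-insertion controls are aggregated into a
*collective* control score computed on their summed counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CountTable

ATTACHMENT_CUTS = (0.5, 0.3)
ROUNDING_CUTS = (0.4, 0.2)


def pool_frequencies(table: CountTable) -> pd.DataFrame:
    """Per-mutant frequencies in the selected and reference pools per replicate.

    Returns a frame indexed like the table with columns
    ``(replicate, 'selected'|'reference')``.  Raises when a replicate lacks
    one of the two pools or a pool has zero total reads.
    """
    cols = {}
    for rep in table.replicates():
        for role in ("selected", "reference"):
            samples = table.select_samples(pool_role=role, replicate=rep)
            if len(samples) != 1:
                raise ValueError(
                    f"replicate {rep}: expected one {role} pool, found {len(samples)}"
                )
            cols[(rep, role)] = table.frequencies(samples[0])
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["replicate", "pool"])
    return out


def abundance_score(f_selected, f_reference, floor: float = 0.0):
    """Frequency-ratio score with a finite-floor rule for empty references.

    ``score = f_selected / max(f_reference, floor)`` where ``floor`` is
    normally the frequency equivalent of half a read in the reference pool.
    Returns ``(score, flag)`` arrays; flags are ``"floored"`` where the
    reference frequency was zero and ``"undefined"`` (score NaN) where both
    frequencies were zero.
    """
    f_sel = np.asarray(f_selected, dtype=float)
    f_ref = np.asarray(f_reference, dtype=float)
    if np.any(f_ref < 0) or np.any(f_sel < 0):
        raise ValueError("frequencies must be non-negative")
    denom = np.where(f_ref > 0, f_ref, floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(denom > 0, f_sel / denom, np.nan)
    flag = np.full(f_sel.shape, "", dtype=object)
    flag[(f_ref == 0) & (f_sel > 0)] = "floored"
    flag[(f_ref == 0) & (f_sel == 0)] = "undefined"
    score = np.where(flag == "undefined", np.nan, score)
    return score, flag


def aggregate_replicates(
    per_replicate: pd.DataFrame,
    control_scores: pd.Series | None = None,
    normalize: bool = False,
) -> pd.DataFrame:
    """Mean/SD of per-replicate scores, optionally control-normalised.

    ``per_replicate``: mutants x replicates score frame.  When
    ``normalize`` is set, each replicate's scores are divided by that
    replicate's collective control score first.  With a single replicate
    the SD is reported as 0.
    """
    scores = per_replicate.copy()
    if normalize:
        if control_scores is None:
            raise ValueError("normalize=True requires per-replicate control scores")
        scores = scores.div(control_scores, axis=1)
    n = scores.notna().sum(axis=1)
    out = pd.DataFrame(
        {
            "score": scores.mean(axis=1),
            "sd": scores.std(axis=1, ddof=1).where(n > 1, 0.0),
            "n_replicates": n,
        }
    )
    return out


class PoolEnrichmentModel:
    """Ratio-score model for one binary-sorting experiment.

    Parameters
    ----------
    table : CountTable
        Mutant (or site) level counts with, per replicate, one
        ``selected`` and one ``reference`` pool.
    score_type : {"attachment", "rounding"}
        Labels the output and picks the default classification cuts.
    controls : sequence of mutant ids, optional
        Neutral (e.g. intergenic-insertion) mutants; defaults to the
        table's ``is_control`` column, else to ids whose ``gene_id`` is
        ``"intergenic"``.
    normalize : bool
        Divide every score by the replicate's collective control score
        (default off: the published scores are reported unnormalised, with
        the collective control value quoted alongside).
    """

    def __init__(
        self,
        table: CountTable,
        score_type: str = "attachment",
        controls=None,
        normalize: bool = False,
    ):
        if score_type not in ("attachment", "rounding"):
            raise ValueError("score_type must be 'attachment' or 'rounding'")
        self.table = table
        self.score_type = score_type
        self.normalize = normalize
        if controls is None:
            if "is_control" in table.sites.columns:
                controls = table.sites.index[table.sites["is_control"].astype(bool)]
            elif "gene_id" in table.sites.columns:
                controls = table.sites.index[table.sites["gene_id"] == "intergenic"]
            else:
                controls = []
        self.controls = pd.Index(controls)

    def fit(self) -> "PoolScoreResults":
        freqs = pool_frequencies(self.table)
        reps = self.table.replicates()
        per_rep = {}
        flags = pd.Series("", index=self.table.counts.index, dtype=object)
        control_scores = {}
        for rep in reps:
            f_sel = freqs[(rep, "selected")]
            f_ref = freqs[(rep, "reference")]
            ref_total = self.table.counts[
                self.table.select_samples(pool_role="reference", replicate=rep)[0]
            ].sum()
            floor = 0.5 / ref_total  # half a read in the reference pool
            score, flag = abundance_score(f_sel.to_numpy(), f_ref.to_numpy(), floor)
            per_rep[rep] = pd.Series(score, index=freqs.index)
            newly = (flags == "") & (flag != "")
            flags[newly] = flag[newly.to_numpy()]
            control_scores[rep] = self._collective_control(rep)
        per_rep = pd.DataFrame(per_rep)
        control_scores = pd.Series(control_scores)
        agg = aggregate_replicates(per_rep, control_scores, self.normalize)
        agg["is_control"] = agg.index.isin(self.controls)
        agg["flag"] = flags
        return PoolScoreResults(
            model=self,
            scores=agg,
            per_replicate=per_rep,
            control_scores_per_replicate=control_scores,
        )

    def _collective_control(self, rep: int) -> float:
        """Control score on summed control counts (pooled, not averaged)."""
        if len(self.controls) == 0:
            return np.nan
        sel = self.table.select_samples(pool_role="selected", replicate=rep)[0]
        ref = self.table.select_samples(pool_role="reference", replicate=rep)[0]
        csel = self.table.counts.loc[self.controls, sel].sum()
        cref = self.table.counts.loc[self.controls, ref].sum()
        f_sel = csel / self.table.counts[sel].sum()
        f_ref = cref / self.table.counts[ref].sum()
        if f_ref == 0:
            return np.nan
        return float(f_sel / f_ref)


@dataclass
class PoolScoreResults:
    """Per-mutant pool scores plus control diagnostics."""

    model: PoolEnrichmentModel
    scores: pd.DataFrame
    per_replicate: pd.DataFrame
    control_scores_per_replicate: pd.Series

    @property
    def collective_control_score(self) -> float:
        return float(self.control_scores_per_replicate.mean())

    def classify(self, cuts: tuple[float, float] | None = None) -> dict[str, int]:
        """Count mutants under the published score cuts (controls excluded)."""
        if cuts is None:
            cuts = (
                ATTACHMENT_CUTS
                if self.model.score_type == "attachment"
                else ROUNDING_CUTS
            )
        hi, lo = max(cuts), min(cuts)
        s = self.scores.loc[~self.scores["is_control"], "score"].dropna()
        return {
            "tested": int(len(s)),
            f"below_{hi}": int((s < hi).sum()),
            f"below_{lo}": int((s < lo).sum()),
        }

    def summary(self) -> str:
        counts = self.classify()
        lines = [
            f"{self.model.score_type.capitalize()} pool scores",
            "=" * 34,
            f"mutants tested:            {counts['tested']}",
            f"replicates:                {self.per_replicate.shape[1]}",
            f"collective control score:  {self.collective_control_score:.2f}",
        ]
        for k, v in counts.items():
            if k.startswith("below"):
                lines.append(f"scores {k.replace('_', ' ')}:          {v}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out.insert(0, "score_type", self.model.score_type)
        out.to_csv(path, sep="\t", index_label="mutant_id")
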