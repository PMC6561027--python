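"""Core tabular containers shared across the pipeline.

The central object is :class:`CountTable`: an insertion-site (or mutant) by
sample matrix of raw read counts, with a small sample-metadata frame carrying
the experimental design (condition, replicate, pool role).  Everything
downstream — fitness estimation, pool enrichment scores, essential-gene
calling — consumes this one container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: pool_role vocabulary: the selected pool carries the phenotype-positive
#: population, the reference pool anchors the denominator of ratio scores.
POOL_ROLES = ("reference", "selected", "none")

SITE_COLUMNS = ["position", "strand", "ta_valid", "gene_id"]


class CountTableError(ValueError):
    """Raised when a count table violates its structural invariants."""


@dataclass
class CountTable:
    """Sites/mutants x samples read-count matrix with sample metadata.

    Parameters
    ----------
    sites : pandas.DataFrame
        One row per insertion site (or per mutant for gene-level pools),
        indexed by a unique ``site_id``.  Typical columns: ``position``
        (1-based first base of the TA), ``strand``, ``ta_valid``,
        ``gene_id``; pool tables may instead carry ``is_control``.
    counts : pandas.DataFrame
        Non-negative integer counts, same index as ``sites``, one column
        per sample.
    samples : pandas.DataFrame
        Indexed by sample id with columns ``condition``, ``replicate``
        (int) and ``pool_role`` in :data:`POOL_ROLES`.
    """

    sites: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(
                {
                    "condition": "unknown",
                    "replicate": 1,
                    "pool_role": "none",
                },
                index=self.counts.columns,
            )
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if not self.sites.index.equals(self.counts.index):
            raise CountTableError("sites and counts must share an identical index")
        if self.sites.index.has_duplicates:
            raise CountTableError("duplicate site ids")
        if "position" in self.sites.columns and self.sites["position"].duplicated().any():
            raise CountTableError("duplicate (strand-collapsed) site positions")
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise CountTableError("negative read counts")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise CountTableError(f"samples metadata missing for: {sorted(missing)}")
        bad = set(self.samples["pool_role"]) - set(POOL_ROLES)
        if bad:
            raise CountTableError(f"unknown pool_role values: {sorted(bad)}")

    # -- convenience ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def replicates(self) -> list[int]:
        return sorted(self.samples["replicate"].unique())

    def select_samples(
        self,
        condition: str | None = None,
        pool_role: str | None = None,
        replicate: int | None = None,
    ) -> list[str]:
        """Sample ids matching the given metadata filters, in column order."""
        meta = self.samples
        keep = pd.Series(True, index=meta.index)
        if condition is not None:
            keep &= meta["condition"] == condition
        if pool_role is not None:
            keep &= meta["pool_role"] == pool_role
        if replicate is not None:
            keep &= meta["replicate"] == replicate
        chosen = set(meta.index[keep])
        return [s for s in self.counts.columns if s in chosen]

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def frequencies(self, sample: str) -> pd.Series:
        """Read frequencies for one sample; zero-count rows get 0."""
        col = self.counts[sample].astype(float)
        total = col.sum()
        if total == 0:
            raise CountTableError(f"sample {sample!r} has zero total reads")
        return col / total

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path, samples_path: str | Path | None = None) -> None:
        """Write ``site columns + one column per sample`` TSV (and metadata)."""
        path = Path(path)
        out = pd.concat([self.sites, self.counts], axis=1)
        out.to_csv(path, sep="\t", index_label="site_id")
        if samples_path is None:
            samples_path = path.with_suffix(".samples.tsv")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(
        cls, path: str | Path, samples_path: str | Path | None = None
    ) -> "CountTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="site_id")
        if samples_path is None:
            candidate = path.with_suffix(".samples.tsv")
            samples_path = candidate if candidate.exists() else None
        if samples_path is not None:
            samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
            sample_cols = [c for c in df.columns if c in set(samples.index)]
            samples = samples.loc[sample_cols]
        else:
            sample_cols = [c for c in df.columns if c not in SITE_COLUMNS]
            samples = None
        site_cols = [c for c in df.columns if c not in sample_cols]
        counts = df[sample_cols].astype(np.int64)
        return cls(sites=df[site_cols], counts=counts, samples=samples)


def make_samples(
    specs: list[tuple[str, str, int, str]],
) -> pd.DataFrame:
    """Build a sample-metadata frame from (sample_id, condition, replicate, role)."""
    idx = [s[0] for s in specs]
    return pd.DataFrame(
        {
            "condition": [s[1] for s in specs],
            "replicate": [s[2] for s in specs],
            "pool_role": [s[3] for s in specs],
        },
        index=pd.Index(idx, name="sample_id"),
    )
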