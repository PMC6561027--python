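"""Junction read processing: tag trimming, exact-match site location, tallying.

Reads are transposon-junction reads: a transposon tag followed by genomic
sequence that starts at the TA dinucleotide the mariner element inserted
into.  Mapping is exact-match on both strands (no indels/mismatches in the
genomic fragment); reads from opposite orientations of the same TA collapse
to a single site keyed by the 1-based position of the TA's first base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .tables import CountTable

MIN_FRAGMENT_LENGTH = 16  # shortest genomic fragment considered mappable
DEFAULT_MAX_MISMATCH = 1


@dataclass(frozen=True)
class InsertionSite:
    """A strand-collapsed transposon insertion site.

    ``position`` is the 1-based coordinate of the first base of the TA
    dinucleotide the junction abuts; ``ta_valid`` is True iff the genome
    actually reads "TA" there.
    """

    position: int
    strand: str
    ta_valid: bool
    gene_id: str = "unassigned"


def trim_tag(read: str, tag: str, max_mismatch: int = DEFAULT_MAX_MISMATCH):
    """Strip the transposon tag off a read prefix.

    Returns ``(fragment, None)`` on success or ``(None, reason)`` when the
    tag does not match within ``max_mismatch`` Hamming errors or the
    remaining fragment is shorter than :data:`MIN_FRAGMENT_LENGTH`.
    """
    if not tag:
        raise ValueError("tag must be non-empty")
    if len(read) <= len(tag):
        return None, "too_short"
    prefix = read[: len(tag)]
    mism = sum(a != b for a, b in zip(prefix, tag))
    if mism > max_mismatch:
        return None, "no_tag"
    fragment = read[len(tag) :]
    if len(fragment) < MIN_FRAGMENT_LENGTH:
        return None, "fragment_too_short"
    return fragment, None


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def locate_insertion(fragment: str, genome: str):
    """Exact-match a genomic fragment on both strands.

    Returns ``("unique", InsertionSite)``, ``("ambiguous", None)`` or
    ``("unmapped", None)``.  The site position is normalised to the TA the
    junction abuts: for a forward hit the fragment starts at the TA; for a
    reverse-strand hit the fragment is the reverse complement of genome
    sequence *ending* at the TA (TA is its own reverse complement, so the
    two orientations share one site).
    """
    if len(fragment) < MIN_FRAGMENT_LENGTH:
        raise ValueError("fragment below minimum mappable length")
    fwd = _find_all(genome, fragment)
    rev = _find_all(genome, reverse_complement(fragment))
    if len(fwd) + len(rev) == 0:
        return "unmapped", None
    if len(fwd) + len(rev) > 1:
        return "ambiguous", None
    if fwd:
        i = fwd[0]
        pos = i + 1
        strand = "+"
    else:
        j = rev[0]
        pos = j + len(fragment) - 1
        strand = "-"
    ta_valid = genome[pos - 1 : pos + 1] == "TA"
    return "unique", InsertionSite(position=pos, strand=strand, ta_valid=ta_valid)


def _iter_reads(reads, fmt: str = "fastq") -> Iterator[tuple[int, str]]:
    """Yield (index, sequence) from a FASTQ path/handle or an iterable of strings."""
    if isinstance(reads, (str, Path)):
        for i, rec in enumerate(SeqIO.parse(str(reads), fmt)):
            yield i, str(rec.seq)
    else:
        for i, r in enumerate(reads):
            yield i, (str(r.seq) if hasattr(r, "seq") else str(r))


def tally(
    reads,
    genome: str,
    tag: str,
    sample_id: str = "sample",
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Tally uniquely mapped junction reads into a count-table column.

    ``reads`` may be a FASTQ path or any iterable of sequences/records.
    Returns ``(table, report)`` where ``table`` has one row per collapsed
    site (position, strand, ta_valid, <sample_id>) and ``report`` satisfies
    the conservation identity
    ``mapped + rejected + ambiguous + unmapped == total``.
    """
    counts: dict[int, int] = {}
    meta: dict[int, InsertionSite] = {}
    cache: dict[str, tuple[str, InsertionSite | None]] = {}
    report = {"total": 0, "mapped": 0, "rejected": 0, "ambiguous": 0, "unmapped": 0}
    for _, seq in _iter_reads(reads):
        report["total"] += 1
        fragment, reason = trim_tag(seq, tag, max_mismatch)
        if fragment is None:
            report["rejected"] += 1
            continue
        if fragment in cache:
            status, site = cache[fragment]
        else:
            status, site = locate_insertion(fragment, genome)
            cache[fragment] = (status, site)
        if status != "unique":
            report[status] += 1
            continue
        report["mapped"] += 1
        counts[site.position] = counts.get(site.position, 0) + 1
        meta.setdefault(site.position, site)
    positions = sorted(counts)
    table = pd.DataFrame(
        {
            "position": positions,
            "strand": [meta[p].strand for p in positions],
            "ta_valid": [meta[p].ta_valid for p in positions],
            sample_id: [counts[p] for p in positions],
        },
        index=pd.Index([f"ta{p:08d}" for p in positions], name="site_id"),
    )
    return table, report


def tally_samples(
    sample_reads: dict[str, Iterable],
    genome: str,
    tag: str,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[CountTable, dict[str, dict[str, int]]]:
    """Tally several samples and align them into one :class:`CountTable`."""
    columns, reports = {}, {}
    site_meta: dict[int, tuple[str, bool]] = {}
    for sample_id, reads in sample_reads.items():
        tbl, rep = tally(reads, genome, tag, sample_id, max_mismatch)
        reports[sample_id] = rep
        columns[sample_id] = tbl.set_index("position")[sample_id]
        for row in tbl.itertuples(index=False):
            site_meta.setdefault(row.position, (row.strand, row.ta_valid))
    positions = sorted(site_meta)
    counts = pd.DataFrame(
        {s: col.reindex(positions).fillna(0).astype(np.int64) for s, col in columns.items()},
    )
    idx = pd.Index([f"ta{p:08d}" for p in positions], name="site_id")
    counts.index = idx
    sites = pd.DataFrame(
        {
            "position": positions,
            "strand": [site_meta[p][0] for p in positions],
            "ta_valid": [site_meta[p][1] for p in positions],
            "gene_id": "unassigned",
        },
        index=idx,
    )
    return CountTable(sites=sites, counts=counts), reports


def assign_genes(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    terminal_exclusion: float = 0.1,
    genome_length: int | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign sites to genes, trimming the 3' terminal fraction of each gene.

    Insertions in the distal ``terminal_exclusion`` fraction of a gene's 3'
    end often leave a functional protein, so they are treated as intergenic.
    Genes must be non-overlapping.  Returns ``(site_gene, per_gene)`` where
    ``site_gene`` maps every site to a gene id or ``"intergenic"`` and
    ``per_gene`` carries unique-site counts (every annotated gene appears,
    zero-site genes included).
    """
    g = genes.sort_values("start").reset_index(drop=True)
    if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
        raise ValueError("gene annotations overlap")
    positions = sites["position"].to_numpy()
    if genome_length is not None and (positions > genome_length).any():
        raise ValueError("site position beyond genome end")
    from .simulate import _gene_lookup

    lookup = _gene_lookup(genes, terminal_exclusion, genome_length or 0)
    assigned = pd.Series(lookup(positions), index=sites.index, name="gene_id")
    per_gene = (
        assigned[assigned != "intergenic"]
        .value_counts()
        .reindex(genes["gene_id"], fill_value=0)
        .rename("n_sites")
        .to_frame()
    )
    return assigned, per_gene


def gene_read_summary(
    table: CountTable, site_gene: pd.Series, genes: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene unique-site counts and summed reads for every sample."""
    df = table.counts.copy()
    df["gene_id"] = site_gene.reindex(df.index)
    grouped = df[df["gene_id"] != "intergenic"].groupby("gene_id")
    reads = grouped.sum().reindex(genes["gene_id"], fill_value=0)
    n_sites = grouped.size().reindex(genes["gene_id"], fill_value=0)
    reads.insert(0, "n_sites", n_sites)
    return reads
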