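"""Synthetic-data generator for the transposon predation screen.

Everything downstream of raw sequencing is testable against this module:
it produces a random genome with a tunable TA-dinucleotide density, a
mariner-style insertion library (strictly at TA sites, never in essential
genes), competitive-expansion count tables under a deterministic
``d**W`` growth model with multinomial read sampling, binary pool-sorting
experiments (attached/unattached for Tn-FACSeq, input/bdelloplast for
Tn-SphereSeq), junction reads, and fluorescence-style images of elliptical
cells with analytically known eccentricity.

The generative growth model is the exact inverse of the expansion-fitness
estimator in :mod:`predfit.fitness` when mutant frequencies are small, so
parameter recovery on simulated data is a meaningful end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement
from scipy import ndimage

from .tables import CountTable, make_samples

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of the simulated screen.

    Defaults mirror the scale of a saturating mariner library in a
    ~3.8 Mb predator genome (90,000 unique insertions over 3,584 genes,
    three biological replicates, low-MOI expansion killing ~99% of prey).
    Desk-scale tests override the size parameters explicitly.
    """

    genome_length: int = 3_800_000
    n_genes: int = 3584
    gene_length_range: tuple[int, int] = (500, 1500)
    ta_enrichment: float = 0.04          # per-position TA planting probability
    n_insertions: int = 90_000
    true_fitness: Mapping[str, float] = field(default_factory=dict)
    essential_genes: frozenset[str] = field(default_factory=frozenset)
    expansion_factor: float = 100.0      # d: output CFU / input CFU
    read_depth: int = 2_000_000
    n_replicates: int = 3
    attach_prob: Mapping[str, float] = field(default_factory=dict)
    round_prob: Mapping[str, float] = field(default_factory=dict)
    pool_contamination: float = 0.02
    terminal_exclusion: float = 0.1      # 3' fraction treated as fitness-neutral
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expansion_factor <= 1:
            raise SimulationError("expansion_factor must be > 1")
        for name in ("ta_enrichment", "pool_contamination", "terminal_exclusion"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must lie in [0, 1], got {v}")
        for m in (self.attach_prob, self.round_prob):
            bad = {k: v for k, v in m.items() if not 0 <= v <= 1}
            if bad:
                raise SimulationError(f"probabilities outside [0, 1]: {bad}")


# ---------------------------------------------------------------------------
# genome & gene model
# ---------------------------------------------------------------------------

def gen_genome(config: SimConfig) -> tuple[str, pd.DataFrame]:
    """Random genome plus a non-overlapping, strand-annotated gene table.

    TA dinucleotides are planted on top of a uniform-base background at
    per-position probability ``config.ta_enrichment``, so raising the
    enrichment (at a fixed seed) monotonically grows the planted set.
    Gene coordinates are 1-based inclusive.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    base_idx = rng.integers(0, 4, size=L)
    # plant TAs at u < enrichment; at a fixed seed a larger enrichment keeps
    # every previous planting and adds new ones
    u = rng.random(L - 1)
    planted = np.flatnonzero(u < config.ta_enrichment)
    last = -2
    for p in planted:
        if p > last + 1:
            base_idx[p] = 3      # T
            base_idx[p + 1] = 0  # A
            last = p
    genome = "".join(_BASES[base_idx])

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    free = L - int(lengths.sum()) - config.n_genes  # >=1 bp gap between genes
    if free < 0:
        raise SimulationError(
            f"{config.n_genes} genes of total length {int(lengths.sum())} "
            f"cannot fit in a {L} bp genome"
        )
    cuts = np.sort(rng.integers(0, free + 1, size=config.n_genes))
    gaps = np.diff(np.concatenate([[0], cuts])) + 1
    starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lengths[:-1])])
    strands = rng.choice(["+", "-"], size=config.n_genes)
    width = len(str(config.n_genes))
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:0{width}d}" for i in range(config.n_genes)],
            "start": starts.astype(int),
            "end": (starts + lengths - 1).astype(int),
            "strand": strands,
        }
    )
    return genome, genes


def ta_positions(genome: str) -> np.ndarray:
    """1-based positions of the first base of every TA dinucleotide."""
    arr = np.frombuffer(genome.encode(), dtype=np.uint8)
    hits = np.flatnonzero((arr[:-1] == ord("T")) & (arr[1:] == ord("A")))
    return hits + 1


def _gene_lookup(genes: pd.DataFrame, terminal_exclusion: float, genome_length: int):
    """Return a vectorised position -> gene_id mapper honouring 3' trimming."""
    body_start = np.empty(len(genes), dtype=int)
    body_end = np.empty(len(genes), dtype=int)
    for i, row in enumerate(genes.itertuples(index=False)):
        length = row.end - row.start + 1
        kept = int(np.floor(length * (1.0 - terminal_exclusion)))
        kept = max(kept, 1)
        if row.strand == "+":
            body_start[i], body_end[i] = row.start, row.start + kept - 1
        else:
            body_start[i], body_end[i] = row.end - kept + 1, row.end
    order = np.argsort(body_start)
    bs, be = body_start[order], body_end[order]
    ids = genes["gene_id"].to_numpy()[order]

    def lookup(positions: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(bs, positions, side="right") - 1
        out = np.full(len(positions), "intergenic", dtype=object)
        ok = idx >= 0
        hit = ok & (positions <= be[np.clip(idx, 0, None)])
        out[hit] = ids[idx[hit]]
        return out

    return lookup


# ---------------------------------------------------------------------------
# library
# ---------------------------------------------------------------------------

def gen_library(
    genome: str, genes: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a mariner insertion library and its ground-truth table.

    Every insertion sits on a TA dinucleotide; essential genes receive
    none (their whole annotated body is excluded).  Input library
    frequencies are symmetric Dirichlet(alpha=1) over insertions.

    Returns ``(sites, truth)``: both indexed by ``site_id``; truth carries
    ``true_W``, ``input_freq`` and (when configured) ``attach_prob`` /
    ``round_prob``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    tas = ta_positions(genome)
    # keep junction reads fully mappable: no sites within a read length of
    # either genome end (where fragments would truncate)
    margin = 60
    tas = tas[(tas > margin) & (tas <= len(genome) - margin)]
    if config.essential_genes:
        ess = genes[genes["gene_id"].isin(config.essential_genes)]
        forbidden = np.zeros(len(tas), dtype=bool)
        for row in ess.itertuples(index=False):
            forbidden |= (tas >= row.start) & (tas <= row.end)
        tas = tas[~forbidden]
    if len(tas) < config.n_insertions:
        raise SimulationError(
            f"only {len(tas)} admissible TA sites for {config.n_insertions} insertions"
        )
    chosen = np.sort(rng.choice(tas, size=config.n_insertions, replace=False))
    strands = rng.choice(["+", "-"], size=config.n_insertions)

    lookup = _gene_lookup(genes, config.terminal_exclusion, len(genome))
    gene_ids = lookup(chosen)
    site_ids = pd.Index([f"ta{p:08d}" for p in chosen], name="site_id")
    sites = pd.DataFrame(
        {
            "position": chosen,
            "strand": strands,
            "ta_valid": True,
            "gene_id": gene_ids,
        },
        index=site_ids,
    )

    freqs = rng.dirichlet(np.ones(config.n_insertions))
    w = np.array([config.true_fitness.get(g, 1.0) for g in gene_ids])
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "position": chosen,
            "strand": strands,
            "true_W": w,
            "input_freq": freqs,
            "attach_prob": [config.attach_prob.get(g, np.nan) for g in gene_ids],
            "round_prob": [config.round_prob.get(g, np.nan) for g in gene_ids],
        },
        index=site_ids,
    )
    return sites, truth


def fitness_landscape(
    gene_ids: Sequence[str],
    n_essential: int = 10,
    n_defective: int = 8,
    n_dead: int = 4,
    n_improved: int = 4,
    seed: int = 0,
) -> tuple[dict[str, float], frozenset[str]]:
    """Assign a mixed true-fitness landscape over the given genes.

    The default split (for 200 genes: 10 essential, 174 neutral W=1,
    8 defective W~U[0,0.5], 4 dead W=0, 4 mildly improved W~U[1.2,1.5])
    keeps >=90% of the library mass neutral.  W is fitness *relative to
    the bulk population*, so the estimator is only the exact generative
    inverse when the bulk is dominated by neutral lineages; improved
    mutants in particular inflate the realised population expansion and
    bias every other estimate downward if they carry appreciable mass.
    """
    rng = np.random.default_rng(seed)
    ids = list(gene_ids)
    n_special = n_essential + n_defective + n_dead + n_improved
    if n_special > len(ids):
        raise SimulationError("more special genes requested than genes available")
    picked = rng.choice(len(ids), size=n_special, replace=False)
    it = iter(picked)
    essential = frozenset(ids[next(it)] for _ in range(n_essential))
    fitness: dict[str, float] = {}
    for _ in range(n_defective):
        fitness[ids[next(it)]] = float(rng.uniform(0.0, 0.5))
    for _ in range(n_dead):
        fitness[ids[next(it)]] = 0.0
    for _ in range(n_improved):
        fitness[ids[next(it)]] = float(rng.uniform(1.2, 1.5))
    return fitness, essential


def realized_expansion(truth: pd.DataFrame, d: float) -> float:
    """Realised population fold-expansion d * sum_j f_j d^{W_j - 1}.

    This is the quantity an output/input CFU ratio would measure; it
    equals the nominal per-neutral-lineage ``d`` only when the library
    mass is entirely neutral.
    """
    f = truth["input_freq"].to_numpy()
    mass = f * d ** truth["true_W"].to_numpy()
    return float(mass.sum() / f.sum())


# ---------------------------------------------------------------------------
# selection / sorting experiments
# ---------------------------------------------------------------------------

def expected_output_frequencies(truth: pd.DataFrame, d: float) -> pd.Series:
    """Deterministic post-expansion frequencies: f_i d^{W_i} / sum_j f_j d^{W_j}."""
    mass = truth["input_freq"].to_numpy() * d ** truth["true_W"].to_numpy()
    return pd.Series(mass / mass.sum(), index=truth.index)


def simulate_expansion(
    truth: pd.DataFrame,
    d: float,
    depth: int,
    n_replicates: int = 3,
    seed: int = 0,
    condition: str = "expansion",
) -> CountTable:
    """Paired input/output count tables for one competitive expansion.

    Each mutant's lineage grows deterministically by ``d**W``; sequencing
    draws exactly ``depth`` reads per sample from a multinomial over the
    resulting frequencies.  Replicates are independent draws from the same
    underlying library.
    """
    if d <= 1:
        raise SimulationError("expansion factor d must be > 1")
    if depth <= 0:
        raise SimulationError("read depth must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    f_in = truth["input_freq"].to_numpy()
    f_out = expected_output_frequencies(truth, d).to_numpy()
    cols, specs = {}, []
    for r in range(1, n_replicates + 1):
        cols[f"input_r{r}"] = rng.multinomial(depth, f_in)
        cols[f"{condition}_r{r}"] = rng.multinomial(depth, f_out)
        specs.append((f"input_r{r}", "input", r, "reference"))
        specs.append((f"{condition}_r{r}", condition, r, "selected"))
    counts = pd.DataFrame(cols, index=truth.index)
    sites = truth[["position", "strand", "gene_id"]].copy()
    sites["ta_valid"] = True
    return CountTable(sites=sites, counts=counts, samples=make_samples(specs))


def _two_pool_table(
    truth: pd.DataFrame,
    sel_weight: np.ndarray,
    ref_weight: np.ndarray,
    depth: int,
    n_replicates: int,
    rng: np.random.Generator,
    sel_name: str,
    ref_name: str,
) -> CountTable:
    f = truth["input_freq"].to_numpy()
    sel_mass = f * sel_weight
    ref_mass = f * ref_weight
    if sel_mass.sum() <= 0 or ref_mass.sum() <= 0:
        raise SimulationError("a pool has zero expected mass")
    f_sel = sel_mass / sel_mass.sum()
    f_ref = ref_mass / ref_mass.sum()
    cols, specs = {}, []
    for r in range(1, n_replicates + 1):
        cols[f"{ref_name}_r{r}"] = rng.multinomial(depth, f_ref)
        cols[f"{sel_name}_r{r}"] = rng.multinomial(depth, f_sel)
        specs.append((f"{ref_name}_r{r}", ref_name, r, "reference"))
        specs.append((f"{sel_name}_r{r}", sel_name, r, "selected"))
    counts = pd.DataFrame(cols, index=truth.index)
    keep = [c for c in ("position", "strand", "gene_id", "is_control") if c in truth.columns]
    sites = truth[keep].copy() if keep else pd.DataFrame(index=truth.index)
    return CountTable(sites=sites, counts=counts, samples=make_samples(specs))


def simulate_sorting(
    truth: pd.DataFrame,
    depth: int,
    seed: int = 0,
    n_replicates: int = 6,
) -> CountTable:
    """FACS-style binary sort into attached vs. unattached pools.

    Each cell of mutant *i* lands in the attached pool with probability
    ``attach_prob[i]``; both pools are then sequenced multinomially at
    ``depth`` reads.
    """
    p = truth["attach_prob"].to_numpy(dtype=float)
    if np.isnan(p).any():
        raise SimulationError("attach_prob missing for some mutants")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    return _two_pool_table(
        truth, p, 1.0 - p, depth, n_replicates, rng, "attached", "unattached"
    )


def simulate_bdelloplast(
    truth: pd.DataFrame,
    contamination: float,
    depth: int,
    seed: int = 0,
    n_replicates: int = 6,
) -> CountTable:
    """Density-gradient bdelloplast enrichment vs. the unsorted input.

    A mutant enters the bdelloplast band with probability
    ``r*(1-contamination) + contamination`` — the contamination term models
    attack-phase cells carried over into the band irrespective of rounding
    ability.  The reference pool is the unselected input itself.
    """
    r = truth["round_prob"].to_numpy(dtype=float)
    if np.isnan(r).any():
        raise SimulationError("round_prob missing for some mutants")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    enter = r * (1.0 - contamination) + contamination
    return _two_pool_table(
        truth, enter, np.ones_like(r), depth, n_replicates, rng, "bdelloplast", "input"
    )


def make_pool_truth(
    n_mutants: int,
    n_controls: int,
    prob_range: tuple[float, float] = (0.0, 0.5),
    which: str = "attach",
    seed: int = 0,
) -> pd.DataFrame:
    """Mutant-level truth table for pool-sorting simulations.

    Mutant probabilities are evenly spaced over ``prob_range``; the
    intergenic controls all receive the library mass-weighted mean
    probability, i.e. they behave like the bulk population, which is what
    anchors the collective control score at ~1.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    probs = np.linspace(*prob_range, n_mutants)
    n = n_mutants + n_controls
    freqs = rng.dirichlet(np.ones(n))
    mean_p = float(np.average(probs, weights=freqs[:n_mutants]))
    all_p = np.concatenate([probs, np.full(n_controls, mean_p)])
    ids = [f"mut{i + 1:04d}" for i in range(n_mutants)] + [
        f"ctrl{i + 1:03d}" for i in range(n_controls)
    ]
    truth = pd.DataFrame(
        {
            "input_freq": freqs,
            "is_control": [False] * n_mutants + [True] * n_controls,
        },
        index=pd.Index(ids, name="site_id"),
    )
    truth[f"{which}_prob"] = all_p
    return truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def gen_reads(
    count_table: CountTable,
    genome: str,
    read_length: int = 50,
    tn_tag: str = "ACAGGTTGGATGA",
) -> dict[str, list[tuple[str, str, bool]]]:
    """Materialise junction reads for every site x sample count.

    Each read is ``tn_tag`` followed by genomic sequence starting at the
    insertion's TA on the recorded strand; multiplicities equal the count
    table exactly.  Returns per-sample lists of ``(read_id, sequence,
    truncated)``; reads running off the genome end are truncated and
    flagged.  Use :func:`write_fastq` to serialise.
    """
    frag_len = read_length - len(tn_tag)
    if frag_len < 1:
        raise SimulationError("read_length must exceed the tag length")
    L = len(genome)
    out: dict[str, list[tuple[str, str, bool]]] = {}
    positions = count_table.sites["position"].to_numpy()
    strands = count_table.sites["strand"].to_numpy()
    for sample in count_table.sample_ids:
        reads: list[tuple[str, str, bool]] = []
        col = count_table.counts[sample].to_numpy()
        for sid, pos, strand, n in zip(
            count_table.sites.index, positions, strands, col
        ):
            if n == 0:
                continue
            if strand == "+":
                frag = genome[pos - 1 : pos - 1 + frag_len]
            else:
                start = max(0, pos + 1 - frag_len)
                frag = reverse_complement(genome[start : pos + 1])
            truncated = len(frag) < frag_len
            seq = tn_tag + frag
            for i in range(int(n)):
                reads.append((f"{sid}|{sample}|{i}", seq, truncated))
        out[sample] = reads
    return out


def write_fastq(reads: Iterable[tuple[str, str, bool]], path) -> None:
    """Write ``(read_id, seq, truncated)`` triples as a FASTQ file."""
    with open(path, "w") as fh:
        for rid, seq, truncated in reads:
            flag = " truncated" if truncated else ""
            fh.write(f"@{rid}{flag}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def gen_images(
    cells: Sequence[tuple[float, float, float, float, float]],
    shape: tuple[int, int] = (512, 512),
    noise_sigma: float = 0.03,
    blur_sigma: float = 1.0,
    foreground: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render elliptical cells into a noisy grayscale image.

    ``cells`` rows are ``(row, col, semi_major, semi_minor, angle_rad)``.
    The truth table records the analytic eccentricity
    ``e = sqrt(1 - (b/a)^2)`` per cell and flags overlapping pairs.
    """
    from skimage.draw import ellipse

    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    img = np.zeros(shape, dtype=float)
    hit_count = np.zeros(shape, dtype=np.int16)
    rows = []
    for i, (r0, c0, a, b, ang) in enumerate(cells):
        if b > a:
            a, b = b, a
        rr, cc = ellipse(r0, c0, a, b, shape=shape, rotation=ang)
        img[rr, cc] = foreground
        hit_count[rr, cc] += 1
        rows.append(
            {
                "cell_id": i,
                "row": r0,
                "col": c0,
                "major": a,
                "minor": b,
                "angle": ang,
                "true_eccentricity": float(np.sqrt(1.0 - (b / a) ** 2)),
            }
        )
    truth = pd.DataFrame(rows).set_index("cell_id") if rows else pd.DataFrame(
        columns=["row", "col", "major", "minor", "angle", "true_eccentricity"]
    )
    overlap_mask = hit_count > 1
    if len(truth):
        flags = []
        for r0, c0, a in zip(truth["row"], truth["col"], truth["major"]):
            rlo = max(0, int(r0 - a - 1))
            rhi = min(shape[0], int(r0 + a + 2))
            clo = max(0, int(c0 - a - 1))
            chi = min(shape[1], int(c0 + a + 2))
            flags.append(bool(overlap_mask[rlo:rhi, clo:chi].any()))
        truth["overlaps"] = flags
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=shape)
    return np.clip(img, 0.0, None), truth


def random_cell_field(
    n_cells: int,
    shape: tuple[int, int] = (512, 512),
    major_range: tuple[float, float] = (8.0, 14.0),
    ecc_range: tuple[float, float] = (0.0, 0.95),
    min_gap: float = 4.0,
    seed: int = 0,
) -> list[tuple[float, float, float, float, float]]:
    """Place non-overlapping random ellipses (rejection sampling on centres)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    cells: list[tuple[float, float, float, float, float]] = []
    attempts = 0
    while len(cells) < n_cells:
        attempts += 1
        if attempts > 100 * n_cells:
            raise SimulationError("could not place non-overlapping cells; enlarge image")
        a = rng.uniform(*major_range)
        e = rng.uniform(*ecc_range)
        b = a * np.sqrt(1.0 - e**2)
        margin = a + min_gap
        r0 = rng.uniform(margin, shape[0] - margin)
        c0 = rng.uniform(margin, shape[1] - margin)
        ok = all(
            np.hypot(r0 - rc, c0 - cc) > a + ac + min_gap
            for rc, cc, ac, _, _ in cells
        )
        if ok:
            cells.append((r0, c0, a, b, float(rng.uniform(0, np.pi))))
    return cells
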