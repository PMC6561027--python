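"""predfit: fitness, enrichment and phenotype analysis for saturating
transposon-insertion screens in predatory bacteria.

The package covers the computational core of a Tn-seq predation screen:
junction-read counting, expansion-fitness estimation with essential-gene
calling, FACS/density-gradient pool enrichment scores, killing-assay and
class I-IV phenotype classification, eccentricity-based prey-rounding image
quantification, and a ground-truthed synthetic-data generator that makes
every stage testable end to end.
"""

from .counts import InsertionSite, assign_genes, locate_insertion, tally, trim_tag
from .fitness import (
    ExpansionFitnessModel,
    FitnessResults,
    call_essentials,
    condition_correlation,
    expansion_fitness,
    gene_fitness,
    threshold_bins,
)
from .imaging import eccentricity, rounded_fraction, segment
from .phenotype import (
    assign_class,
    group_compare,
    killing_category,
    survival_percent,
)
from .pools import PoolEnrichmentModel, PoolScoreResults, abundance_score
from .report import ScreenSummary, reproduce_supplementary, run_screen
from .simulate import SimConfig
from .tables import CountTable

__version__ = "0.1.0"

__all__ = [
    "CountTable",
    "ExpansionFitnessModel",
    "FitnessResults",
    "InsertionSite",
    "PoolEnrichmentModel",
    "PoolScoreResults",
    "ScreenSummary",
    "SimConfig",
    "abundance_score",
    "assign_class",
    "assign_genes",
    "call_essentials",
    "condition_correlation",
    "eccentricity",
    "expansion_fitness",
    "gene_fitness",
    "group_compare",
    "killing_category",
    "locate_insertion",
    "reproduce_supplementary",
    "rounded_fraction",
    "run_screen",
    "segment",
    "survival_percent",
    "tally",
    "threshold_bins",
    "trim_tag",
]
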