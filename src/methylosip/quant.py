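"""Methanol-dehydrogenase gene quantification.

Two routes to gene-clade abundance:

* metagenome hit tables — BLAST hit counts against representative sequences
  of each MDH clade (xoxF1-5, mxaF, mdh2), normalized to reference gene
  length (assembled contigs) or to gene length and library size (unassembled
  reads), and expressed relative to the single-copy housekeeping gene recA as
  the percentage of bacteria carrying an MDH gene;
* qPCR — a log-linear standard curve fitted to a dilution series, absolute
  copy-number quantification of samples, and normalization to 16S rRNA gene
  copies.

Also includes the e-value stringency calibration used when screening mixed
databases: the cutoff is set just below the strongest hit from a wrong clade.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GeneHitTable",
    "NormalizedAbundance",
    "MdhFraction",
    "QpcrStandardCurve",
    "QuantResult",
    "normalize_gene_abundance",
    "mdh_bacterial_fraction",
    "calibrate_evalue_cutoff",
    "apply_evalue_cutoff",
    "fit_standard_curve",
    "quantify_and_normalize",
]

MODES = ("assembled", "unassembled")


@dataclass(frozen=True)
class GeneHitTable:
    """Hit counts per gene clade from a metagenome screen.

    ``mode`` is 'assembled' (hits against assembled contigs) or 'unassembled'
    (hits against raw reads, requiring ``total_reads`` for library-size
    normalization).  Reference lengths are nucleotide bp of the representative
    screening sequence.
    """

    clades: tuple[str, ...]
    lengths_bp: tuple[float, ...]
    hits: tuple[float, ...]
    mode: str = "unassembled"
    total_reads: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not (len(self.clades) == len(self.lengths_bp) == len(self.hits)):
            raise ValueError("clades, lengths_bp and hits must have equal length")
        if any(l <= 0 for l in self.lengths_bp):
            raise ValueError("reference lengths must be positive")
        if any(h < 0 for h in self.hits):
            raise ValueError("hit counts must be non-negative")
        if self.mode == "unassembled" and not self.total_reads:
            raise ValueError("unassembled mode requires total_reads")


@dataclass(frozen=True)
class NormalizedAbundance:
    """Gene abundance in hits/kb (assembled) or hits/kb/Mread (unassembled)."""

    clade: str
    abundance: float
    mode: str


@dataclass(frozen=True)
class MdhFraction:
    """Percentage of bacteria carrying an MDH gene, relative to recA.

    Values above 100 % are legitimate (multiple MDH copies per genome are
    common, notably xoxF5) and are flagged rather than rejected.
    """

    percentage: float
    multi_copy: bool


def normalize_gene_abundance(table: GeneHitTable) -> list[NormalizedAbundance]:
    """Length-normalize hit counts; also read-normalize for unassembled data.

    assembled:    hits / (length/1000)                 -> hits per kb
    unassembled:  hits / ((length/1000) * (reads/1e6)) -> hits per kb per Mread
    """
    out = []
    for clade, length, hits in zip(table.clades, table.lengths_bp, table.hits):
        per_kb = hits / (length / 1000.0)
        if table.mode == "unassembled":
            per_kb /= table.total_reads / 1e6
        out.append(NormalizedAbundance(clade, per_kb, table.mode))
    return out


def mdh_bacterial_fraction(
    mdh_abundances: Sequence[NormalizedAbundance],
    recA_abundance: NormalizedAbundance,
) -> MdhFraction:
    """Sum of normalized MDH-clade abundances as a percentage of recA."""
    modes = {a.mode for a in mdh_abundances} | {recA_abundance.mode}
    if len(modes) != 1:
        raise ValueError(f"mixed normalization modes: {sorted(modes)}")
    if recA_abundance.abundance <= 0:
        raise ValueError("recA abundance is zero; the bacterial fraction is undefined")
    pct = 100.0 * sum(a.abundance for a in mdh_abundances) / recA_abundance.abundance
    return MdhFraction(percentage=pct, multi_copy=pct > 100.0)


def calibrate_evalue_cutoff(
    hits: Sequence[tuple[float, str]], query_clade: str
) -> float:
    """E-value stringency from a labelled hit list.

    The threshold is the e-value of the strongest (lowest-e) hit belonging to
    a clade other than the query's; hits with e-value strictly below it pass.
    With no wrong-clade hits the threshold is +inf (everything passes).  If
    the resulting cutoff passes no correct-clade hit at all, a warning is
    raised and the (empty-passing) threshold still returned.
    """
    if not hits:
        raise ValueError("empty hit list")
    wrong = [e for e, clade in hits if clade != query_clade]
    if not wrong:
        return math.inf
    threshold = min(wrong)
    if not any(e < threshold for e, clade in hits if clade == query_clade):
        warnings.warn(
            f"strongest hit for {query_clade!r} is outranked by a wrong-clade "
            "hit; the calibrated cutoff passes zero hits",
            stacklevel=2,
        )
    return threshold


def apply_evalue_cutoff(
    hits: Sequence[tuple[float, str]], threshold: float
) -> list[tuple[float, str]]:
    """Hits passing a calibrated cutoff (strictly below the threshold)."""
    return [h for h in hits if h[0] < threshold]


@dataclass(frozen=True)
class QpcrStandardCurve:
    """Log-linear qPCR standard curve: Cq = slope * log10(copies) + intercept.

    A valid assay has slope < 0; perfect doubling per cycle gives slope
    -1/log10(2) ~= -3.3219 and efficiency 1.0 (100 %).
    """

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency as a fraction: 10^(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.efficiency

    def quantify(self, cq: float) -> float:
        """Invert the curve: copy number for an observed Cq."""
        return 10.0 ** ((cq - self.intercept) / self.slope)


def fit_standard_curve(
    dilution_series: Sequence[tuple[float, float]]
) -> QpcrStandardCurve:
    """Least-squares fit of Cq on log10(copies) over a dilution series.

    Requires at least 3 distinct copy levels (the usual series spans 10^1 to
    10^8 copies/ul).  A non-negative slope means the assay is invalid.
    """
    if any(c <= 0 for c, _ in dilution_series):
        raise ValueError("copy numbers must be positive")
    levels = {c for c, _ in dilution_series}
    if len(levels) < 3:
        raise ValueError(
            f"need >= 3 distinct copy levels to fit a standard curve, got {len(levels)}"
        )
    x = np.log10([c for c, _ in dilution_series])
    y = np.array([cq for _, cq in dilution_series])
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(
            f"standard-curve slope {fit.slope:.4g} is non-negative; invalid assay"
        )
    return QpcrStandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


@dataclass(frozen=True)
class QuantResult:
    """Absolute copies, reference-normalized ratios and pairwise gene ratios."""

    copies: dict[str, float]
    relative_to_reference: dict[str, float]
    pairwise_ratios: dict[str, float]
    reference_gene: str


def quantify_and_normalize(
    sample_cq: Mapping[str, float],
    curves: Mapping[str, QpcrStandardCurve],
    reference_gene: str,
) -> QuantResult:
    """Copy numbers from per-gene Cq values, normalized to a reference gene.

    Each gene's Cq is inverted through its own standard curve; results are
    reported as copies per reference-gene copy (e.g. per 16S rRNA gene copy)
    plus all pairwise ratios between non-reference genes (e.g. xoxF5:mxaF).
    """
    genes = list(sample_cq)
    missing = [g for g in genes + [reference_gene] if g not in curves]
    if missing:
        raise ValueError(f"no standard curve for gene(s): {missing}")
    if reference_gene not in sample_cq:
        raise ValueError(f"no Cq measured for reference gene {reference_gene!r}")
    copies = {g: curves[g].quantify(cq) for g, cq in sample_cq.items()}
    ref = copies[reference_gene]
    relative = {g: copies[g] / ref for g in genes if g != reference_gene}
    others = [g for g in genes if g != reference_gene]
    pairwise = {
        f"{a}:{b}": copies[a] / copies[b]
        for i, a in enumerate(others)
        for b in others[i + 1:]
    }
    return QuantResult(copies, relative, pairwise, reference_gene)
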