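"""Synthetic DNA-SIP experiments with known ground truth.

The generator emulates the data structure of a fraction-resolved SIP study:
two soil treatments (rhizosphere, unplanted control), two isotopes (13C
substrate, 12C control), heavy and light gradient fraction pools and
replicate incubations, with four planted taxon classes —

* labelled      : primary substrate consumers, enriched in the 13C-heavy
                  fraction of the rhizosphere treatment;
* crossfeeder   : secondary consumers with a weaker 13C-heavy enrichment;
* autotroph     : CO2 fixers, 13C-heavy-enriched in BOTH treatments (the
                  confounder an unplanted control is there to remove);
* unlabelled    : background community, present in heavy fractions only via
                  density leakage; a high-GC subset leaks more in BOTH
                  isotopes (the skew the 12C control criterion removes).

DNA of each taxon is split between the heavy and the light band with
heavy:light odds = background_leakage x enrichment; compositions are then
multinomially resampled at the sequencing depth.  This conserves DNA mass, so
a strongly labelled taxon is simultaneously enriched in the heavy and
depleted from the light fraction, as in real gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .primers import AlignmentMatrix
from .quant import GeneHitTable

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulatedExperiment",
    "simulate_experiment",
    "simulate_alignment",
    "simulate_gene_hits",
]

TREATMENTS = ("rhizosphere", "unplanted")
ISOTOPES = ("13C", "12C")
FRACTIONS = ("heavy", "light")


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of a synthetic SIP experiment.

    Enrichment factors multiply a taxon's heavy:light odds and are drawn
    per taxon and replicate from a log-normal law with the given log-scale
    median and standard deviation.  ``background_leakage`` is the baseline
    heavy:light odds of unlabelled DNA (GC-content and gradient smearing);
    at 1.0 the heavy and light compositions coincide in expectation.
    """

    n_taxa: int = 200
    n_labelled: int = 20
    n_crossfeeders: int = 10
    n_autotrophs: int = 5
    n_high_gc: int = 10
    base_abundance_concentration: float = 1.0
    enrichment_mean: float = 50.0
    enrichment_sd: float = 0.15
    crossfeed_enrichment_mean: float = 5.0
    gc_enrichment_mean: float = 15.0
    background_leakage: float = 0.05
    read_depth: int = 20_000
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_taxa": self.n_taxa,
            "n_labelled": self.n_labelled,
            "n_crossfeeders": self.n_crossfeeders,
            "n_autotrophs": self.n_autotrophs,
            "n_high_gc": self.n_high_gc,
            "read_depth": self.read_depth,
            "n_replicates": self.n_replicates,
        }
        for name, v in counts.items():
            if v < 0 or (name in ("n_taxa", "read_depth", "n_replicates") and v < 1):
                raise ConfigurationError(f"{name}={v} is invalid")
        special = self.n_labelled + self.n_crossfeeders + self.n_autotrophs + self.n_high_gc
        if special > self.n_taxa:
            raise ConfigurationError(
                f"n_labelled + n_crossfeeders + n_autotrophs + n_high_gc = {special} "
                f"exceeds n_taxa = {self.n_taxa}"
            )
        positive = {
            "base_abundance_concentration": self.base_abundance_concentration,
            "enrichment_mean": self.enrichment_mean,
            "enrichment_sd": self.enrichment_sd,
            "crossfeed_enrichment_mean": self.crossfeed_enrichment_mean,
            "gc_enrichment_mean": self.gc_enrichment_mean,
        }
        for name, v in positive.items():
            if v <= 0 and name != "enrichment_sd":
                raise ConfigurationError(f"{name}={v} must be strictly positive")
        if self.enrichment_sd < 0:
            raise ConfigurationError(f"enrichment_sd={self.enrichment_sd} must be >= 0")
        if not 0.0 <= self.background_leakage <= 1.0:
            raise ConfigurationError(
                f"background_leakage={self.background_leakage} must lie in [0, 1]"
            )


@dataclass(frozen=True)
class TruthTable:
    """Ground-truth status per simulated taxon.

    ``status`` maps every taxon to one of labelled / crossfeeder / autotroph /
    unlabelled; ``high_gc`` marks the unlabelled subset with elevated
    heavy-band leakage in both isotopes.
    """

    status: dict[str, str]
    high_gc: frozenset[str]

    def taxa_with(self, status: str) -> list[str]:
        return [t for t, s in self.status.items() if s == status]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon_id": list(self.status),
                "status": list(self.status.values()),
                "high_gc": [t in self.high_gc for t in self.status],
            }
        )


@dataclass(frozen=True)
class SimulatedExperiment:
    """Fraction-resolved relative-abundance tables plus their sample sheet.

    ``abundance`` is taxa x samples (each column sums to 1); ``samples`` maps
    sample_id to (treatment, isotope, fraction_class, replicate, timepoint).
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame
    config: SimulationConfig


def _enrichment_factors(
    cfg: SimulationConfig,
    truth: TruthTable,
    taxa: Sequence[str],
    treatment: str,
    isotope: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-taxon heavy:light odds multipliers for one incubation replicate."""
    e = np.ones(len(taxa))
    idx = {t: i for i, t in enumerate(taxa)}

    def draw(median: float) -> float:
        return float(rng.lognormal(mean=np.log(median), sigma=cfg.enrichment_sd))

    if isotope == "13C":
        for t in truth.taxa_with("autotroph"):
            e[idx[t]] = draw(cfg.enrichment_mean)
        if treatment == "rhizosphere":
            for t in truth.taxa_with("labelled"):
                e[idx[t]] = draw(cfg.enrichment_mean)
            for t in truth.taxa_with("crossfeeder"):
                e[idx[t]] = draw(cfg.crossfeed_enrichment_mean)
    # GC-driven leakage is a physical property of the DNA: same in both isotopes
    for t in truth.high_gc:
        e[idx[t]] *= cfg.gc_enrichment_mean
    return e


def simulate_experiment(config: SimulationConfig) -> tuple[SimulatedExperiment, TruthTable]:
    """Draw one complete synthetic SIP experiment.

    Baseline composition is drawn once per treatment from a symmetric
    Dirichlet; each taxon's DNA is then split between heavy and light bands
    with odds background_leakage x enrichment, enrichment factors are redrawn
    per replicate (incubation-to-incubation jitter), and every fraction sample
    is a multinomial of size read_depth renormalized to relative abundance.
    Identical configs (including seed) reproduce identical tables bit-for-bit.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    width = max(3, len(str(cfg.n_taxa)))
    taxa = [f"t{i + 1:0{width}d}" for i in range(cfg.n_taxa)]

    order = rng.permutation(cfg.n_taxa)
    status = {t: "unlabelled" for t in taxa}
    cursor = 0
    for name, count in (
        ("labelled", cfg.n_labelled),
        ("crossfeeder", cfg.n_crossfeeders),
        ("autotroph", cfg.n_autotrophs),
    ):
        for j in order[cursor:cursor + count]:
            status[taxa[j]] = name
        cursor += count
    high_gc = frozenset(taxa[j] for j in order[cursor:cursor + cfg.n_high_gc])
    truth = TruthTable(status=status, high_gc=high_gc)

    alpha = np.full(cfg.n_taxa, cfg.base_abundance_concentration)
    baseline = {trt: rng.dirichlet(alpha) for trt in TREATMENTS}

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for treatment in TREATMENTS:
        base = baseline[treatment]
        for isotope in ISOTOPES:
            for rep in range(1, cfg.n_replicates + 1):
                e = _enrichment_factors(cfg, truth, taxa, treatment, isotope, rng)
                odds = cfg.background_leakage * e
                share = odds / (1.0 + odds)
                weights = {"heavy": base * share, "light": base * (1.0 - share)}
                for fraction in FRACTIONS:
                    w = weights[fraction]
                    total = w.sum()
                    # an empty band (e.g. leakage 0, nothing labelled) still
                    # yields reads: the residual background composition
                    p = w / total if total > 0 else base
                    counts = rng.multinomial(cfg.read_depth, p)
                    sample_id = f"{treatment}_{isotope}_{fraction}_r{rep}"
                    columns[sample_id] = counts / cfg.read_depth
                    sheet_rows.append(
                        {
                            "sample_id": sample_id,
                            "treatment": treatment,
                            "isotope": isotope,
                            "fraction_class": fraction,
                            "replicate": rep,
                            "timepoint": "T1",
                        }
                    )
    abundance = pd.DataFrame(columns, index=pd.Index(taxa, name="taxon_id"))
    samples = pd.DataFrame(sheet_rows)
    return SimulatedExperiment(abundance=abundance, samples=samples, config=cfg), truth


def simulate_alignment(
    n_seqs: int,
    n_cols: int,
    variable_columns: Sequence[int] | set[int] = (),
    seed: int = 0,
) -> AlignmentMatrix:
    """Gap-free alignment with conserved columns everywhere except the given
    variable columns, each of which is forced to hold >= 2 distinct bases."""
    if n_seqs < 2:
        raise ValueError("conservation is undefined for fewer than 2 sequences")
    variable = set(variable_columns)
    bad = [j for j in variable if not 0 <= j < n_cols]
    if bad:
        raise ValueError(f"variable column indices out of range: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    matrix = np.tile(bases[rng.integers(0, 4, size=n_cols)], (n_seqs, 1))
    for j in sorted(variable):
        col = bases[rng.integers(0, 4, size=n_seqs)]
        if len(set(col)) == 1:  # force >= 2 distinct bases
            row = int(rng.integers(0, n_seqs))
            col[row] = bases[(np.where(bases == col[row])[0][0] + 1) % 4]
        matrix[:, j] = col
    ids = [f"seq{i + 1}" for i in range(n_seqs)]
    return AlignmentMatrix(ids, ["".join(row) for row in matrix])


def simulate_gene_hits(
    clades: Sequence[str],
    lengths_bp: Sequence[float],
    true_abundances: Sequence[float],
    total_reads: int,
    seed: int = 0,
    *,
    mode: str = "unassembled",
    hit_rate: float = 100.0,
    noise: bool = True,
) -> GeneHitTable:
    """Gene-hit counts whose expectation is abundance x length x library size.

    Longer genes intercept proportionally more reads, which is exactly the
    bias the per-kb normalization removes.  ``hit_rate`` sets hits per kb per
    Mread per unit abundance; with ``noise`` the counts are Poisson draws,
    without it they equal their expectations (useful for exact round-trip
    checks).
    """
    if not (len(clades) == len(lengths_bp) == len(true_abundances)):
        raise ValueError("clades, lengths_bp and true_abundances must have equal length")
    if any(l <= 0 for l in lengths_bp):
        raise ValueError("gene lengths must be positive")
    if any(a < 0 for a in true_abundances):
        raise ValueError("abundances must be non-negative")
    if total_reads < 1:
        raise ValueError("total_reads must be positive")
    lengths = np.asarray(lengths_bp, dtype=float)
    abund = np.asarray(true_abundances, dtype=float)
    expected = hit_rate * abund * (lengths / 1000.0) * (total_reads / 1e6)
    if noise:
        rng = np.random.default_rng(seed)
        hits = rng.poisson(expected).astype(float)
    else:
        hits = expected
    return GeneHitTable(
        clades=tuple(clades),
        lengths_bp=tuple(float(l) for l in lengths),
        hits=tuple(float(h) for h in hits),
        mode=mode,
        total_reads=total_reads,
    )
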