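"""Synthetic pooled-screen and survival-cohort generators with known truth.

The screen generator emulates a negative-selection knockout screen run in
parallel in two (or more) genetic backgrounds: a genome-wide library with a
few guides per gene is transduced, the population grows for a fixed number
of cumulative population doublings D, and initial / final samples are
sequenced to a finite depth.

Growth is deterministic exponential on expected abundances: a guide whose
gene carries fitness effect s (log2 abundance change per doubling, in a
given background) ends the screen with relative abundance multiplied by
2**(D*s).  All stochasticity enters at two points — the lognormal spread
of starting abundances (which also produces the low-count guides the read
filter must catch) and multinomial sequencing sampling at finite depth.
This is the simplest generative model with the structure the CS statistic
assumes; cell-level branching noise, transduction bottlenecks and PCR
jackpotting are deliberately not modeled.

Gene classes and their per-background fitness effects are recorded in a
:class:`SimTruth`, so recovery of implanted synthetic-lethal genes by the
dCS ranking can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .screenio import CountTable, SampleMeta, SgRNARecord
from .scoring import DifferentialScoreTable, top_candidates
from .survival import SurvivalRecord

SYNTHETIC_LETHAL = "synthetic_lethal"

_DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "neutral": {},
    "pan_essential": {"WT": -0.25, "KO": -0.25},
    SYNTHETIC_LETHAL: {"KO": -0.4},
}
_DEFAULT_FRACTIONS = {"neutral": 0.9, "pan_essential": 0.09, SYNTHETIC_LETHAL: 0.01}


@dataclass
class SimConfig:
    """Configuration of a simulated screen.

    Defaults describe the reference scenario used throughout the test
    suite: a 1000-gene library at 4 guides per gene, 90% neutral genes,
    9% pan-essential genes (s = -0.25/doubling in every background) and
    1% synthetic-lethal genes (s = -0.4/doubling in the knockout
    background only), screened for 14 doublings at a mean sequencing depth
    of 500 reads per guide, with lognormal sigma 0.5 on starting
    abundances.  Effects absent from ``effect_table`` for a background
    default to 0 (neutral there).
    """

    n_genes: int = 1000
    sgrna_per_gene: int = 4
    doublings: float = 14.0
    depth: float = 500.0
    initial_dispersion: float = 0.5
    backgrounds: tuple[str, ...] = ("WT", "KO")
    effect_table: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_EFFECTS.items()}
    )
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    seed: int = 20221121

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.sgrna_per_gene < 1:
            raise ValueError("n_genes and sgrna_per_gene must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.doublings < 0:
            raise ValueError("doublings must be non-negative")
        if self.initial_dispersion < 0:
            raise ValueError("initial_dispersion must be non-negative")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        unknown = set(self.class_fractions) - set(self.effect_table)
        if unknown:
            raise ValueError(f"class_fractions refer to unknown classes {unknown}")

    def effect(self, gene_class: str, background: str) -> float:
        return float(self.effect_table.get(gene_class, {}).get(background, 0.0))


@dataclass
class SimTruth:
    """Ground truth of a simulated library: class and per-background s per gene."""

    classes: dict[str, str]
    effects: dict[str, dict[str, float]]

    def genes_in_class(self, gene_class: str) -> list[str]:
        return sorted(g for g, c in self.classes.items() if c == gene_class)

    def to_frame(self, backgrounds: Sequence[str]) -> pd.DataFrame:
        rows = {
            gene: [cls] + [self.effects[gene].get(bg, 0.0) for bg in backgrounds]
            for gene, cls in self.classes.items()
        }
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["class"] + [f"s_{bg}" for bg in backgrounds]
        ).rename_axis("gene")


_BASES = np.array(list("ACGT"))


def _largest_remainder(fractions: Sequence[float], total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``fractions``.

    Floors first, then hands the remaining units to the largest fractional
    parts (earlier index wins ties), so counts always sum to ``total``.
    """
    exact = np.asarray(fractions, dtype=float) * total
    base = np.floor(exact).astype(int)
    remainder = exact - base
    short = total - int(base.sum())
    order = np.argsort(-remainder, kind="stable")
    base[order[:short]] += 1
    return base


def build_library(config: SimConfig) -> tuple[list[SgRNARecord], SimTruth]:
    """Deterministically build a guide library and its ground truth.

    Gene ids are GENE0001..; guide ids GENE0001_sg1.. with random 20-nt
    sequences.  Class counts are the exact largest-remainder allocation of
    ``class_fractions`` over ``n_genes`` (so a 0.01 fraction of 1000 genes
    implants exactly 10), and the labels are placed by a seeded shuffle.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    width = max(4, len(str(config.n_genes)))
    genes = [f"GENE{i + 1:0{width}d}" for i in range(config.n_genes)]
    class_names = sorted(config.class_fractions)
    counts = _largest_remainder(
        [config.class_fractions[c] for c in class_names], config.n_genes
    )
    labels = np.repeat(np.arange(len(class_names)), counts)
    assignment = rng.permutation(labels)

    classes = {g: class_names[a] for g, a in zip(genes, assignment)}
    effects = {
        g: {bg: config.effect(classes[g], bg) for bg in config.backgrounds}
        for g in genes
    }
    seqs = _BASES[rng.integers(0, 4, size=(config.n_genes * config.sgrna_per_gene, 20))]
    library = []
    for i, gene in enumerate(genes):
        for j in range(config.sgrna_per_gene):
            seq = "".join(seqs[i * config.sgrna_per_gene + j])
            library.append(SgRNARecord(f"{gene}_sg{j + 1}", gene, seq))
    return library, SimTruth(classes, effects)


def simulate_counts(
    library: Sequence[SgRNARecord],
    truth: SimTruth,
    config: SimConfig,
) -> dict[str, CountTable]:
    """Simulate initial/final raw count tables for every background.

    Per background b: starting relative abundance a0 ~ lognormal(0, sigma)
    per guide; final abundance a1 = a0 * 2**(D * s(gene, b)); each sample's
    counts are a multinomial draw with total = depth * n_guides over the
    normalized abundance vector.
    """
    n_guides = len(library)
    total_reads = int(round(config.depth * n_guides))
    d = config.doublings
    out: dict[str, CountTable] = {}
    for bi, bg in enumerate(config.backgrounds):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, bi]))
        if config.initial_dispersion > 0:
            a0 = rng.lognormal(0.0, config.initial_dispersion, size=n_guides)
        else:
            a0 = np.ones(n_guides)
        s = np.array([truth.effects[g.gene].get(bg, 0.0) for g in library])
        a1 = a0 * np.exp2(d * s)
        counts0 = rng.multinomial(total_reads, a0 / a0.sum())
        counts1 = rng.multinomial(total_reads, a1 / a1.sum())
        samples = [
            SampleMeta(f"{bg}_initial", bg, "initial", 0.0),
            SampleMeta(f"{bg}_final", bg, "final", d),
        ]
        counts = pd.DataFrame(
            {samples[0].sample_id: counts0, samples[1].sample_id: counts1},
            index=pd.Index([g.sgrna_id for g in library], name="sgrna_id"),
            dtype=np.int64,
        )
        out[bg] = CountTable(list(library), samples, counts)
    return out


def evaluate_recovery(
    dcs_table: DifferentialScoreTable,
    truth: SimTruth,
    k: int,
    target_class: str = SYNTHETIC_LETHAL,
) -> tuple[int, float]:
    """How many implanted genes of ``target_class`` rank in the dCS top k.

    Returns (n_recovered, recall).  Implanted genes filtered out before
    scoring still count in the recall denominator — a gene the pipeline
    never scores is a miss.
    """
    implanted = set(truth.genes_in_class(target_class))
    if not implanted:
        raise ValueError(f"truth contains no genes of class {target_class!r}")
    k = min(k, len(dcs_table.table))
    top = set(top_candidates(dcs_table, k))
    n_recovered = len(implanted & top)
    return n_recovered, n_recovered / len(implanted)


@dataclass
class CohortConfig:
    """Configuration of a synthetic survival cohort.

    Groups mirror a tumor-genotype stratification of metastatic
    castration-resistant prostate cancer: patients whose tumors lost both
    PTEN and ATAD1, patients with PTEN loss alone, and patients unaltered
    at both loci.  Defaults encode the reported group medians — overall
    survival of 77 months for the PTEN-null/ATAD1-null group versus 37
    months for the comparison groups — as the medians of exponential
    survival-time distributions, with independent exponential censoring
    tuned to the requested censoring fraction.
    """

    group_medians: Mapping[str, float] = field(
        default_factory=lambda: {
            "PTEN_ATAD1_null": 77.0,
            "PTEN_null": 37.0,
            "unaltered": 37.0,
        }
    )
    n_per_group: int = 150
    censoring_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must be in [0, 1)")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")
        for g, m in self.group_medians.items():
            if m <= 0:
                raise ValueError(f"group {g!r}: median must be positive")


def simulate_cohort(config: CohortConfig) -> list[SurvivalRecord]:
    """Draw a synthetic right-censored survival cohort.

    Survival times are exponential with rate ln(2)/median per group;
    censoring times are exponential with the rate that makes the expected
    censored fraction equal ``censoring_fraction`` (independent censoring,
    under which the product-limit estimator is consistent).
    """
    rng = np.random.default_rng(config.seed)
    records: list[SurvivalRecord] = []
    f = config.censoring_fraction
    for group in sorted(config.group_medians):
        rate = np.log(2.0) / config.group_medians[group]
        t = rng.exponential(1.0 / rate, size=config.n_per_group)
        if f > 0:
            c = rng.exponential((1.0 - f) / (rate * f), size=config.n_per_group)
        else:
            c = np.full(config.n_per_group, np.inf)
        obs = np.minimum(t, c)
        event = (t <= c).astype(int)
        for i in range(config.n_per_group):
            records.append(
                SurvivalRecord(f"{group}_{i + 1:04d}", group, float(obs[i]), int(event[i]))
            )
    return records
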