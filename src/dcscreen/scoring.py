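"""CRISPR score (CS) and differential CRISPR score (dCS) computation.

The scoring model for a pooled knockout screen:

* raw guide counts are given a pseudocount and depth-normalized so that
  every sample has the same total abundance;
* each guide's log2 fold-change (final vs. initial sample of the same
  genetic background) measures its fitness effect over the screen;
* the CRISPR score of a gene is the arithmetic mean log2 fold-change of
  all retained guides targeting it;
* the differential score dCS = CS_test - CS_ref contrasts two genetic
  backgrounds; strongly negative dCS marks genes selectively essential in
  the test background (synthetic-lethal candidates).

Filtering happens on RAW counts, before normalization: guides with fewer
than ``min_reads`` reads in the initial reference sample are removed, and
genes left with fewer than ``min_sgrna`` informative guides are removed.
For a paired two-background comparison a guide must clear the read floor
in every background, so that each retained guide is assessable in both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screenio import CountTable, SgRNARecord

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_MIN_READS = 50
DEFAULT_MIN_SGRNA = 4


@dataclass
class NormalizedTable:
    """Depth-normalized, pseudocounted guide abundances (strictly positive)."""

    guides: list[SgRNARecord]
    samples: list
    values: pd.DataFrame

    def sample(self, sample_id: str):
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"sample {sample_id!r} not found")


@dataclass
class GeneScoreTable:
    """Per-gene CS for one background; ``table`` has columns cs, n_sgrna."""

    background: str
    table: pd.DataFrame


@dataclass
class DifferentialScoreTable:
    """Per-gene dCS between two backgrounds; ``table`` has columns dcs, rank.

    Rank 1 is the most negative dCS, i.e. the strongest synthetic-lethal
    candidate in the test background.
    """

    test_background: str
    ref_background: str
    table: pd.DataFrame


def normalize(table: CountTable, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> NormalizedTable:
    """Pseudocount and depth-normalize a raw count table.

    value[g, s] = (count[g, s] + pseudocount) * T / total_s, where total_s
    is the pseudocounted column sum of sample s and T is the mean of those
    totals across samples.  Any common target yields identical log2
    fold-changes; the mean keeps values on the raw-count scale.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    pc = table.counts.astype(float) + pseudocount
    totals = pc.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(
            f"sample(s) {bad} have zero pseudocounted total; "
            "use a positive pseudocount"
        )
    target = float(totals.mean())
    values = pc * (target / totals)
    return NormalizedTable(table.guides, table.samples, values)


def initial_filter(
    table: CountTable,
    initial_sample: str,
    min_reads: int = DEFAULT_MIN_READS,
    min_sgrna: int = DEFAULT_MIN_SGRNA,
) -> tuple[set[str], dict[str, int]]:
    """Representation filter on the initial reference sample of one background.

    A guide is retained iff its raw count in ``initial_sample`` is at least
    ``min_reads`` and its gene keeps at least ``min_sgrna`` guides after the
    read filter.  Returns the retained guide-id set and the per-gene count
    of read-passing guides (including genes that fail the gene filter).
    """
    meta = table.sample(initial_sample)
    if meta.timepoint != "initial":
        raise ValueError(f"sample {initial_sample!r} is not an initial time point")
    passing = table.counts[initial_sample] >= min_reads
    gene_of = table.gene_of
    per_gene = gene_of[passing].value_counts().to_dict()
    kept_genes = {g for g, n in per_gene.items() if n >= min_sgrna}
    retained = {
        gid for gid, ok in passing.items() if ok and gene_of[gid] in kept_genes
    }
    _log_filter(table, retained, f"initial filter ({initial_sample})")
    return retained, per_gene


def paired_filter(
    tables: Mapping[str, CountTable],
    initial_samples: Mapping[str, str],
    min_reads: int = DEFAULT_MIN_READS,
    min_sgrna: int = DEFAULT_MIN_SGRNA,
) -> set[str]:
    """Representation filter for a paired cross-background comparison.

    A guide is retained only if it has at least ``min_reads`` raw reads at
    the initial time point in EVERY background: a guide that scores in one
    background but cannot be assessed in another would corrupt the paired
    contrast.  The ``min_sgrna`` gene floor is re-applied to the paired
    retained set, since pairing can drop a gene below it.
    """
    if len(tables) < 2:
        raise ValueError("paired_filter requires at least 2 backgrounds")
    guide_sets = [set(t.counts.index) for t in tables.values()]
    common = set.intersection(*guide_sets)
    if not common:
        raise ValueError("backgrounds have disjoint guide sets")

    passing = None
    for bg, table in tables.items():
        init = initial_samples[bg]
        meta = table.sample(init)
        if meta.timepoint != "initial":
            raise ValueError(f"sample {init!r} ({bg}) is not an initial time point")
        ok = set((table.counts[init] >= min_reads).loc[lambda s: s].index) & common
        passing = ok if passing is None else (passing & ok)

    first = next(iter(tables.values()))
    gene_of = first.gene_of
    per_gene = gene_of[gene_of.index.isin(passing)].value_counts()
    kept_genes = set(per_gene[per_gene >= min_sgrna].index)
    retained = {gid for gid in passing if gene_of[gid] in kept_genes}
    _log_filter(first, retained, "paired filter")
    return retained


def log2fc(norm: NormalizedTable, initial_sample: str, final_sample: str) -> pd.Series:
    """Per-guide log2 fold-change of normalized abundance, final vs. initial.

    Both samples must belong to the same genetic background.
    """
    init = norm.sample(initial_sample)
    fin = norm.sample(final_sample)
    if init.background != fin.background:
        raise ValueError(
            f"samples {initial_sample!r} ({init.background}) and "
            f"{final_sample!r} ({fin.background}) are from different backgrounds"
        )
    fc = np.log2(norm.values[final_sample] / norm.values[initial_sample])
    fc.name = "log2fc"
    return fc


def gene_cs(
    fold_changes: Mapping[str, float] | pd.Series,
    library: Sequence[SgRNARecord],
    retained: set[str],
    background: str = "",
) -> GeneScoreTable:
    """Average guide log2 fold-changes into per-gene CRISPR scores.

    CS(gene) is the arithmetic mean log2FC over the gene's retained guides;
    genes with no retained guide are absent from the output.
    """
    if not retained:
        raise ValueError("retained guide set is empty")
    fc = pd.Series(fold_changes)
    missing = retained - set(fc.index)
    if missing:
        raise ValueError(
            f"{len(missing)} retained guide(s) have no fold change, "
            f"e.g. {sorted(missing)[:3]}"
        )
    gene_of = pd.Series(
        [g.gene for g in library], index=[g.sgrna_id for g in library]
    )
    keep = [g.sgrna_id for g in library if g.sgrna_id in retained]
    grouped = fc.loc[keep].groupby(gene_of.loc[keep])
    out = pd.DataFrame({"cs": grouped.mean(), "n_sgrna": grouped.size()})
    out.index.name = "gene"
    if not np.isfinite(out["cs"]).all():
        raise ValueError("non-finite CS; check normalization pseudocount")
    return GeneScoreTable(background, out.sort_index())


def average_clone_cs(tables: Sequence[GeneScoreTable]) -> GeneScoreTable:
    """Average per-gene CS across clonal replicates of the same genotype.

    Restricted to genes scored in every clone; n_sgrna is the minimum
    across clones (the weakest support any clone provides).
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 clone tables to average")
    genes = tables[0].table.index
    for t in tables[1:]:
        genes = genes.intersection(t.table.index)
    if len(genes) == 0:
        raise ValueError("no genes shared across all clone tables")
    cs = np.mean([t.table.loc[genes, "cs"].to_numpy() for t in tables], axis=0)
    n = np.min([t.table.loc[genes, "n_sgrna"].to_numpy() for t in tables], axis=0)
    out = pd.DataFrame({"cs": cs, "n_sgrna": n}, index=genes).sort_index()
    label = "mean(" + ",".join(t.background for t in tables) + ")"
    return GeneScoreTable(label, out)


def dcs(test: GeneScoreTable, ref: GeneScoreTable) -> DifferentialScoreTable:
    """Differential CRISPR score: dCS(gene) = CS_test(gene) - CS_ref(gene).

    Genes are ranked ascending — rank 1 is the most negative dCS, i.e. the
    gene most selectively essential in the test background.  Ties are
    broken lexicographically by gene symbol for determinism.
    """
    genes = test.table.index.intersection(ref.table.index)
    if len(genes) == 0:
        raise ValueError("no genes shared between test and reference tables")
    d = test.table.loc[genes, "cs"] - ref.table.loc[genes, "cs"]
    out = pd.DataFrame({"dcs": d})
    out.index.name = "gene"
    order = out.reset_index().sort_values(["dcs", "gene"]).set_index("gene")
    order["rank"] = np.arange(1, len(order) + 1)
    out = order.sort_index()
    return DifferentialScoreTable(test.background, ref.background, out)


def top_candidates(table: DifferentialScoreTable, k: int) -> list[str]:
    """The k genes with the smallest (most negative) dCS, ascending."""
    n = len(table.table)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} ranked genes")
    if k < 1:
        raise ValueError("k must be positive")
    ordered = table.table.sort_values("rank")
    return list(ordered.index[:k])


def clone_concordance(
    a: DifferentialScoreTable, b: DifferentialScoreTable
) -> tuple[float, float, int]:
    """Pearson correlation of two dCS tables over their shared genes.

    Returns (r, two-sided p from the t distribution with n-2 df, n genes).
    Used to check that independent knockout clones of the same gene rank
    the genome concordantly.
    """
    genes = a.table.index.intersection(b.table.index)
    n = len(genes)
    if n < 3:
        raise ValueError(f"need >= 3 shared genes, got {n}")
    x = a.table.loc[genes, "dcs"].to_numpy()
    y = b.table.loc[genes, "dcs"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the dCS vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def dcs_permutation_null(
    guide_delta: pd.Series,
    gene_of: pd.Series,
    n_perm: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Permutation null for the strongest gene-level |dCS|.

    ``guide_delta`` holds per-guide differences of log2 fold-change between
    two backgrounds for the retained guides; ``gene_of`` maps those guides
    to genes.  Guide-to-gene labels are permuted, gene means recomputed,
    and the per-permutation maximum |dCS| collected — the family-wise null
    against which observed gene scores are compared.
    """
    rng = np.random.default_rng(seed)
    delta = guide_delta.to_numpy(float)
    genes, inverse = np.unique(gene_of.loc[guide_delta.index].to_numpy(), return_inverse=True)
    sizes = np.bincount(inverse)
    maxima = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(delta)
        sums = np.bincount(inverse, weights=perm)
        maxima[i] = np.max(np.abs(sums / sizes))
    return maxima


def _log_filter(table: CountTable, retained: set[str], stage: str) -> None:
    n_guides = len(table.guides)
    genes_all = set(g.gene for g in table.guides)
    genes_kept = set(g.gene for g in table.guides if g.sgrna_id in retained)
    logger.info(
        "%s: retained %d/%d guides, %d/%d genes",
        stage, len(retained), n_guides, len(genes_kept), len(genes_all),
    )
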