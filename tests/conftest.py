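"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (explicit Python loops, closed
forms) and never call the library code paths they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from dcscreen import CountTable, SampleMeta, SgRNARecord


def make_count_table(matrix, genes, samples) -> CountTable:
    """Build a CountTable from a nested list.

    ``genes`` is one gene symbol per guide row; ``samples`` is a list of
    (sample_id, background, timepoint, cpd) tuples.
    """
    guides = [SgRNARecord(f"sg{i + 1:03d}", g) for i, g in enumerate(genes)]
    metas = [SampleMeta(*s) for s in samples]
    counts = pd.DataFrame(
        np.asarray(matrix, dtype=np.int64),
        index=pd.Index([g.sgrna_id for g in guides], name="sgrna_id"),
        columns=[m.sample_id for m in metas],
    )
    return CountTable(guides, metas, counts)


def random_toy_screen(rng: np.random.Generator):
    """A small random two-background screen for oracle comparisons.

    Returns (library, {background: CountTable}).  Counts are Poisson with
    guide-specific rates so some guides fall under the read filter.
    """
    n_genes = int(rng.integers(5, 51))
    library = []
    for i in range(n_genes):
        gene = f"G{i + 1:03d}"
        for j in range(int(rng.integers(4, 6))):
            library.append(SgRNARecord(f"{gene}_sg{j + 1}", gene))
    n = len(library)
    tables = {}
    for bg in ("WT", "KO"):
        rates = rng.lognormal(np.log(120), 0.8, size=n)
        mat = np.column_stack([rng.poisson(rates), rng.poisson(rates)])
        mat[:4, 0] += 500  # anchor gene: always clears the read filter
        samples = [
            SampleMeta(f"{bg}_t0", bg, "initial", 0.0),
            SampleMeta(f"{bg}_t1", bg, "final", 14.0),
        ]
        counts = pd.DataFrame(
            mat.astype(np.int64),
            index=pd.Index([g.sgrna_id for g in library], name="sgrna_id"),
            columns=[s.sample_id for s in samples],
        )
        tables[bg] = CountTable(list(library), samples, counts)
    return library, tables


def naive_screen_scores(tables, pseudocount=1.0, min_reads=50, min_sgrna=4):
    """Loop-and-average re-implementation of paired filter + CS + dCS.

    Operates on raw Python dicts; returns ({bg: {gene: cs}}, {gene: dcs})
    with dCS oriented KO minus WT.
    """
    lib = tables["WT"].guides
    gene_of = {g.sgrna_id: g.gene for g in lib}

    # paired read filter on raw initial counts
    passing = []
    for g in lib:
        ok = True
        for bg, t in tables.items():
            init = [s.sample_id for s in t.samples if s.timepoint == "initial"][0]
            if t.counts.at[g.sgrna_id, init] < min_reads:
                ok = False
        if ok:
            passing.append(g.sgrna_id)
    per_gene: dict[str, int] = {}
    for gid in passing:
        per_gene[gene_of[gid]] = per_gene.get(gene_of[gid], 0) + 1
    retained = [gid for gid in passing if per_gene[gene_of[gid]] >= min_sgrna]

    cs_by_bg: dict[str, dict[str, float]] = {}
    for bg, t in tables.items():
        init = [s.sample_id for s in t.samples if s.timepoint == "initial"][0]
        fin = [s.sample_id for s in t.samples if s.timepoint == "final"][0]
        tot0 = sum(t.counts.at[g.sgrna_id, init] + pseudocount for g in lib)
        tot1 = sum(t.counts.at[g.sgrna_id, fin] + pseudocount for g in lib)
        target = (tot0 + tot1) / 2.0
        sums: dict[str, float] = {}
        ns: dict[str, int] = {}
        for gid in retained:
            v0 = (t.counts.at[gid, init] + pseudocount) * target / tot0
            v1 = (t.counts.at[gid, fin] + pseudocount) * target / tot1
            fc = math.log2(v1 / v0)
            gene = gene_of[gid]
            sums[gene] = sums.get(gene, 0.0) + fc
            ns[gene] = ns.get(gene, 0) + 1
        cs_by_bg[bg] = {gene: sums[gene] / ns[gene] for gene in sums}

    dcs = {
        gene: cs_by_bg["KO"][gene] - cs_by_bg["WT"][gene]
        for gene in cs_by_bg["KO"]
        if gene in cs_by_bg["WT"]
    }
    return cs_by_bg, dcs


def km_oracle(times, events):
    """Closed-form product-limit estimator by explicit iteration.

    Returns (death_times, survival_after_each, at_risk_before_each).
    Deaths at a tied time are processed before censorings at that time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out_t, out_s, out_n = [], [], []
    s = 1.0
    for t in np.unique(times):
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum((times == t) & (events == 1)))
        if d_i > 0:
            s *= 1.0 - d_i / n_i
            out_t.append(t)
            out_s.append(s)
            out_n.append(n_i)
    return np.array(out_t), np.array(out_s), np.array(out_n)


def km_median_oracle(times, events):
    t, s, _ = km_oracle(times, events)
    below = s <= 0.5 * (1 + 1e-9)  # same exact-half convention as the library
    if not below.any():
        return None
    return float(t[np.argmax(below)])


@pytest.fixture
def simple_two_gene_table():
    """Two genes x four guides each, two samples of one background."""
    genes = ["GENE_A"] * 4 + ["GENE_B"] * 4
    matrix = [[100, 200], [100, 50], [100, 100], [100, 400],
              [80, 80], [120, 60], [60, 240], [90, 90]]
    samples = [("t0", "WT", "initial", 0.0), ("t1", "WT", "final", 14.0)]
    return make_count_table(matrix, genes, samples)
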