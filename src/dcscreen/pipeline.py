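"""End-to-end screen analysis runs with a reproducibility manifest.

A run goes: obtain counts (simulated or from files) -> paired
representation filter across backgrounds -> depth normalization -> guide
log2 fold-changes -> per-gene CRISPR scores -> differential scores against
the reference background -> ranked candidate list.  With more than one
test background (e.g. two independent knockout clones), per-clone CS
tables are additionally averaged before the headline comparison and the
per-clone dCS concordance is reported.

Every invocation writes one run directory containing all intermediate
tables, a filter-stage log, and ``manifest.json`` recording the seed and a
hash of the configuration; re-running with an identical configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import scoring
from .screenio import (
    CountTable,
    read_counts,
    read_library,
    read_sample_sheet,
    write_counts,
    write_scores,
)
from .simulate import (
    SYNTHETIC_LETHAL,
    SimConfig,
    build_library,
    evaluate_recovery,
    simulate_counts,
)

logger = logging.getLogger(__name__)


@dataclass
class ScreenRunConfig:
    """Parameters of one end-to-end screen analysis.

    Exactly one of ``sim`` (simulate the screen) or ``counts_paths`` +
    ``library_path`` + ``samples_path`` (load real counts) must be given.
    """

    outdir: Path
    sim: SimConfig | None = None
    counts_paths: Mapping[str, Path] | None = None
    library_path: Path | None = None
    samples_path: Path | None = None
    ref_background: str = "WT"
    pseudocount: float = scoring.DEFAULT_PSEUDOCOUNT
    min_reads: int = scoring.DEFAULT_MIN_READS
    min_sgrna: int = scoring.DEFAULT_MIN_SGRNA
    top_k: int = 20

    def to_jsonable(self) -> dict:
        d: dict = {
            "ref_background": self.ref_background,
            "pseudocount": self.pseudocount,
            "min_reads": self.min_reads,
            "min_sgrna": self.min_sgrna,
            "top_k": self.top_k,
        }
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        if self.counts_paths is not None:
            d["counts_paths"] = {k: str(v) for k, v in self.counts_paths.items()}
            d["library_path"] = str(self.library_path)
            d["samples_path"] = str(self.samples_path)
        return d


def score_screen(
    tables: Mapping[str, CountTable],
    ref_background: str,
    pseudocount: float = scoring.DEFAULT_PSEUDOCOUNT,
    min_reads: int = scoring.DEFAULT_MIN_READS,
    min_sgrna: int = scoring.DEFAULT_MIN_SGRNA,
) -> tuple[set[str], dict[str, scoring.GeneScoreTable]]:
    """Paired-filter, normalize and score every background of a screen.

    Returns the paired retained guide set and one CS table per background.
    """
    if ref_background not in tables:
        raise ValueError(f"reference background {ref_background!r} not among {list(tables)}")
    initial_samples = {}
    sample_pairs = {}
    for bg, table in tables.items():
        init = [s for s in table.samples if s.timepoint == "initial"]
        fin = [s for s in table.samples if s.timepoint == "final"]
        if len(init) != 1 or len(fin) != 1:
            raise ValueError(
                f"background {bg!r} must have exactly one initial and one final sample"
            )
        initial_samples[bg] = init[0].sample_id
        sample_pairs[bg] = (init[0].sample_id, fin[0].sample_id)

    retained = scoring.paired_filter(tables, initial_samples, min_reads, min_sgrna)
    cs_tables = {}
    for bg, table in tables.items():
        norm = scoring.normalize(table, pseudocount)
        fc = scoring.log2fc(norm, *sample_pairs[bg])
        cs_tables[bg] = scoring.gene_cs(fc, table.guides, retained, background=bg)
    return retained, cs_tables


def run_screen_pipeline(config: ScreenRunConfig) -> tuple[scoring.DifferentialScoreTable, dict]:
    """Run a full screen analysis and write all outputs to ``config.outdir``.

    Returns the headline dCS table (averaged across clones when several
    test backgrounds are present) and a report dictionary; both are also
    written to the run directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("dcscreen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: ScreenRunConfig, outdir: Path) -> tuple[scoring.DifferentialScoreTable, dict]:
    truth = None
    if (config.sim is None) == (config.counts_paths is None):
        raise ValueError("exactly one of sim / counts_paths must be configured")
    if config.sim is not None:
        library, truth = build_library(config.sim)
        tables = simulate_counts(library, truth, config.sim)
        truth.to_frame(config.sim.backgrounds).to_csv(outdir / "truth.tsv", sep="\t")
        _write_library(library, outdir / "library.tsv")
        _write_samples(tables, outdir / "samples.tsv")
        for bg, t in tables.items():
            write_counts(t, outdir / f"counts_{bg}.tsv")
    else:
        library = read_library(config.library_path)
        samples = read_sample_sheet(config.samples_path)
        tables = {}
        for bg, path in config.counts_paths.items():
            bg_samples = [s for s in samples if s.background == bg]
            tables[bg] = read_counts(path, library, bg_samples)

    retained, cs_tables = score_screen(
        tables,
        config.ref_background,
        config.pseudocount,
        config.min_reads,
        config.min_sgrna,
    )
    for bg, cs in cs_tables.items():
        write_scores(cs, outdir / f"cs_{bg}.tsv")

    test_bgs = sorted(bg for bg in tables if bg != config.ref_background)
    ref_cs = cs_tables[config.ref_background]
    per_clone_dcs = {bg: scoring.dcs(cs_tables[bg], ref_cs) for bg in test_bgs}
    for bg, d in per_clone_dcs.items():
        write_scores(d, outdir / f"dcs_{bg}.tsv")

    report: dict = {
        "n_guides_retained": len(retained),
        "n_genes_scored": len(ref_cs.table),
        "backgrounds": sorted(tables),
        "ref_background": config.ref_background,
    }
    if len(test_bgs) > 1:
        averaged = scoring.average_clone_cs([cs_tables[bg] for bg in test_bgs])
        headline = scoring.dcs(averaged, ref_cs)
        pairs = [
            (a, b) for i, a in enumerate(test_bgs) for b in test_bgs[i + 1:]
        ]
        report["clone_concordance"] = {
            f"{a}|{b}": dict(
                zip(("r", "p", "n"), scoring.clone_concordance(per_clone_dcs[a], per_clone_dcs[b]))
            )
            for a, b in pairs
        }
    else:
        headline = per_clone_dcs[test_bgs[0]]
    write_scores(headline, outdir / "dcs.tsv")

    k = min(config.top_k, len(headline.table))
    top = scoring.top_candidates(headline, k)
    (outdir / "top_candidates.tsv").write_text(
        "rank\tgene\n" + "".join(f"{i + 1}\t{g}\n" for i, g in enumerate(top)),
        encoding="utf-8",
    )
    report["top_candidates"] = top
    if truth is not None:
        if truth.genes_in_class(SYNTHETIC_LETHAL):
            n_rec, recall = evaluate_recovery(headline, truth, k)
            report["recovery"] = {"k": k, "n_recovered": n_rec, "recall": recall}
        else:
            report["recovery"] = None  # no implanted genes in this draw

    manifest = {
        "config": config.to_jsonable(),
        "config_sha256": _config_hash(config),
        "seed": config.sim.seed if config.sim is not None else None,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return headline, report


def _config_hash(config: ScreenRunConfig) -> str:
    blob = json.dumps(config.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_library(library, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sgrna_id\tgene\tsequence\n")
        for g in library:
            fh.write(f"{g.sgrna_id}\t{g.gene}\t{g.sequence or ''}\n")


def _write_samples(tables: Mapping[str, CountTable], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tbackground\ttimepoint\tcpd\n")
        for bg in sorted(tables):
            for s in tables[bg].samples:
                fh.write(f"{s.sample_id}\t{s.background}\t{s.timepoint}\t{s.cpd:g}\n")
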