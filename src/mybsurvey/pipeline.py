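"""End-to-end orchestration: scan → phylogeny → introns → duplications →
expression, with a census report of the surveyed family.

Each stage writes a TSV (or newick) into the output directory; the
effective configuration is echoed there for provenance.  Stages run only
when their inputs are configured; missing inputs mark the stage skipped,
never silently defaulted.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (duplication, expression, gene_structure, io_formats,
               phylogeny, repeat_scanner)
from .synthetic_data import default_profile


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    Serialized (YAML) into the output directory for provenance.
    """

    out_dir: str
    proteome: str | None = None
    anchors: str | None = None            # anchor repeat alignment FASTA
    subfamily_anchors: str | None = None  # TSV: protein_id, subfamily
    gff: str | None = None
    expression_matrix: str | None = None
    expression_metadata: str | None = None
    blocks: str | None = None
    context: str | None = None            # TSV: gene_id, subgenome, chromosome, rank
    homeology: str | None = None          # TSV: chrom_a, chrom_b
    catalog: str | None = None            # intron pattern catalog YAML
    max_linker: int = 12
    support_floor: float = 70.0
    bootstrap_reps: int = 100
    fold: float = 1.5
    pseudocount: float = 0.1
    column_tolerance: int = 3
    min_sites: int = 20
    seed: int = 0


def _log(fh, msg: str) -> None:
    print(msg, file=sys.stderr)
    fh.write(msg + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all configured stages; returns the report directory.

    A stage failure aborts the run with the stage name in the raised
    error.  The census report aggregates family counts and percentages,
    subfamily and chromosome tables, duplication shares and expression
    group counts for whichever stages ran.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    log = open(out / "run.log", "w")
    report: dict = {"stages": {}}

    assignments = subfamily_of = None
    gene_chrom: dict[str, str] = {}
    try:
        if config.proteome:
            _log(log, "[scan] scanning proteome")
            proteins = io_formats.read_fasta(config.proteome)
            if config.anchors:
                anchor_rows = [r.sequence for r in
                               io_formats.read_fasta(config.anchors)]
                profile = repeat_scanner.build_repeat_profile(anchor_rows)
            else:
                profile = default_profile()
            params = repeat_scanner.ScanParams(max_linker=config.max_linker)
            assignments = [repeat_scanner.assign(p, profile, params)
                           for p in proteins]
            rows = [{
                "protein_id": a.protein_id, "family": a.family,
                "repeat_starts": ",".join(str(r.start) for r in a.repeats),
                "repeat_scores": ",".join(f"{r.score:.2f}" for r in a.repeats),
                "w_matched": ",".join(str(r.w_matched) for r in a.repeats),
            } for a in assignments]
            pd.DataFrame(rows).to_csv(out / "scan.tsv", sep="\t", index=False)
            report["stages"]["scan"] = "ok"
        else:
            report["stages"]["scan"] = "skipped"

        subfamily_calls = None
        if assignments and config.subfamily_anchors:
            _log(log, "[phylo] building NJ tree with bootstrap")
            prot_by_id = {p.id: p for p in proteins}
            aln = phylogeny.induced_domain_alignment(
                [a for a in assignments if a.repeats], prot_by_id, profile)
            tree = phylogeny.bootstrap_support(
                aln, n_replicates=config.bootstrap_reps, seed=config.seed,
                min_sites=config.min_sites)
            io_formats.write_newick(tree, out / "tree.nwk")
            anchors_df = pd.read_csv(config.subfamily_anchors, sep="\t")
            anchor_map = dict(zip(anchors_df["protein_id"],
                                  anchors_df["subfamily"]))
            calls = phylogeny.assign_subfamilies(
                tree, anchor_map, support_floor=config.support_floor)
            subfamily_calls = {c.protein_id: c.label for c in calls}
            pd.DataFrame([{"protein_id": c.protein_id, "subfamily": c.label,
                           "support": c.clade_support} for c in calls]
                         ).to_csv(out / "subfamilies.tsv", sep="\t",
                                  index=False)
            report["stages"]["phylo"] = "ok"
        else:
            report["stages"]["phylo"] = "skipped"

        if config.gff and assignments:
            _log(log, "[introns] typing intron patterns")
            models = io_formats.read_gff3_gene_models(config.gff)
            gene_chrom = {m.protein_id: m.chromosome for m in models}
            by_id = {a.protein_id: a for a in assignments}
            catalog = gene_structure.load_catalog(config.catalog)
            sigs = [gene_structure.domain_signature(m, by_id[m.protein_id])
                    for m in models
                    if m.protein_id in by_id and by_id[m.protein_id].repeats]
            labeled = gene_structure.label_patterns(
                sigs, catalog, tolerance=config.column_tolerance)
            pd.DataFrame([{
                "gene_id": s.gene_id,
                "signature": ";".join(f"{a},{b},{c}" for a, b, c in s.events),
                "pattern_label": s.pattern_label} for s in labeled]
                ).to_csv(out / "introns.tsv", sep="\t", index=False)
            report["stages"]["introns"] = "ok"
        else:
            report["stages"]["introns"] = "skipped"

        dup_summary = None
        if config.blocks and config.context:
            _log(log, "[dupclass] classifying duplication events")
            blocks = io_formats.read_collinearity(config.blocks)
            ctx_df = pd.read_csv(config.context, sep="\t")
            hom_df = (pd.read_csv(config.homeology, sep="\t")
                      if config.homeology else pd.DataFrame(
                          columns=["chrom_a", "chrom_b"]))
            context = duplication.GenomeContext.from_tables(
                ctx_df.to_dict("records"), hom_df.to_dict("records"))
            dup_calls = duplication.classify_duplications(
                blocks, context, subfamily_calls or {})
            pd.DataFrame([{
                "gene_id": c.gene_id,
                "events": ",".join(sorted(c.events)),
                "origin": c.progenitor_origin,
                "colinear": c.colinear} for c in dup_calls]
                ).to_csv(out / "dupclass.tsv", sep="\t", index=False)
            dup_summary = duplication.duplication_summary(dup_calls)
            report["stages"]["dupclass"] = "ok"
        else:
            report["stages"]["dupclass"] = "skipped"

        expr_summary = None
        if config.expression_matrix and config.expression_metadata:
            _log(log, "[expr] profiling hormone responses")
            matrix = io_formats.read_expression_table(
                config.expression_matrix, config.expression_metadata)
            kept, dropped = expression.filter_expressed(matrix)
            ecalls = expression.call_regulation(
                kept, fold=config.fold, pseudocount=config.pseudocount)
            pd.DataFrame([{
                "gene_id": c.gene_id, "expressed": c.expressed,
                "group": c.group,
                **{f"dir_{h}": c.directions[h] for h in io_formats.HORMONES}}
                for c in ecalls]).to_csv(out / "expr_calls.tsv", sep="\t",
                                         index=False)
            transformed = expression.transform(kept.values)
            clustered = expression.cluster_genes(transformed)
            clustered.values.to_csv(out / "expr_clustered.tsv", sep="\t",
                                    index_label="gene_id")
            pd.DataFrame(clustered.linkage,
                         columns=["child_a", "child_b", "height", "size"]
                         ).to_csv(out / "expr_linkage.tsv", sep="\t",
                                  index_label="merge_step")
            expr_summary = expression.group_summary(ecalls)
            expr_summary["n_dropped"] = len(dropped)
            report["stages"]["expr"] = "ok"
        else:
            report["stages"]["expr"] = "skipped"

        if assignments:
            cns = repeat_scanner.census(assignments, subfamily_calls,
                                        gene_chrom or None)
            report["census"] = {
                "total": cns.total, "counts": cns.counts,
                "percentages": cns.percentages,
                "subfamily_counts": cns.subfamily_counts,
                "chromosome_counts": cns.chromosome_counts,
            }
        if dup_summary is not None:
            report["duplication"] = dup_summary
        if expr_summary is not None:
            report["expression"] = expr_summary
        report["seed"] = config.seed
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        _log(log, f"[done] report written to {out}")
    except Exception as exc:
        failed = [k for k, v in report["stages"].items() if v == "ok"]
        _log(log, f"[abort] after stages {failed}: {exc}")
        raise
    finally:
        log.close()
    return out
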