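"""Shared helper: simulate a full input set and run the pipeline on it."""

import numpy as np
import pandas as pd

from mybsurvey import gene_structure as gs
from mybsurvey import io_formats as io
from mybsurvey import synthetic_data as sd
from mybsurvey.pipeline import PipelineConfig, run_pipeline


def simulate_and_run(workdir, seed=17, bootstrap_reps=30):
    workdir.mkdir(parents=True, exist_ok=True)
    recs, truth = sd.make_myb_proteome(
        {"1R": 4, "2R": 10, "3R": 3}, noise_rate=0.0, n_decoys=4, seed=seed)
    io.write_fasta(recs, workdir / "proteome.fasta")
    planted = [r for r in recs if not r.id.startswith("decoy")]
    cat = gs.load_catalog()
    rng = np.random.default_rng(seed)
    tt = truth.table.set_index("protein_id")
    sig_of = {}
    for r in planted:
        n_rep = len(tt.loc[r.id, "repeat_starts"].split(","))
        letters = sorted(l for l in cat
                         if all(s < n_rep for s, _, _ in cat[l]))
        sig_of[r.id] = cat[letters[rng.integers(len(letters))]]
    _, gff, _ = sd.make_gene_models(planted, truth, sig_of, seed=seed)
    (workdir / "genes.gff3").write_text(gff)
    two_r = [r for r in planted if r.id.startswith("syn2R")]
    pd.DataFrame([{"protein_id": r.id, "subfamily": f"S{i + 1}"}
                  for i, r in enumerate(two_r[:3])]
                 ).to_csv(workdir / "anchors.tsv", sep="\t", index=False)
    gene_ids = [r.id for r in planted]
    design = sd.random_expression_design(gene_ids, seed=seed)
    matrix, _ = sd.make_expression(gene_ids, design, seed=seed)
    io.write_expression_table(matrix, workdir / "fpkm.tsv",
                              workdir / "samples.tsv")
    ctx, blocks, subfam, _ = sd.make_collinearity(
        {"TD": 2, "HE": 3, "SE": 2, "SD": 2}, seed=seed)
    io.write_collinearity(blocks, workdir / "blocks.tsv")
    pd.DataFrame([{"gene_id": g, "subgenome": s, "chromosome": c, "rank": r}
                  for g, (s, c, r) in ctx.genes.items()]
                 ).to_csv(workdir / "context.tsv", sep="\t", index=False)
    pd.DataFrame([{"chrom_a": sorted(p)[0], "chrom_b": sorted(p)[1]}
                  for p in sorted(ctx.homeology, key=sorted)]
                 ).to_csv(workdir / "homeology.tsv", sep="\t", index=False)
    config = PipelineConfig(
        out_dir=str(workdir / "report"),
        proteome=str(workdir / "proteome.fasta"),
        subfamily_anchors=str(workdir / "anchors.tsv"),
        gff=str(workdir / "genes.gff3"),
        expression_matrix=str(workdir / "fpkm.tsv"),
        expression_metadata=str(workdir / "samples.tsv"),
        blocks=str(workdir / "blocks.tsv"),
        context=str(workdir / "context.tsv"),
        homeology=str(workdir / "homeology.tsv"),
        bootstrap_reps=bootstrap_reps,
        seed=seed,
    )
    return run_pipeline(config)
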