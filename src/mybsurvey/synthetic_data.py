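"""Seeded synthetic inputs with known truth for every pipeline stage.

The generators emulate the structure of the real inputs — proteomes with
planted 1R–4R MYB repeat architectures and decoys, gene models with
designed intron signatures, collinearity blocks realizing known duplication
events, and hormone-response FPKM matrices — so every consuming stage can
be tested as a closed loop against the planted truth.  They do not attempt
realistic genome composition (repeat content, GC skew) or read-level
RNA-seq noise.

All outputs are byte-stable under a fixed seed.

The anchor repeat set shipped here is synthetic: a hand-designed plant-MYB
style consensus (52 columns, tryptophans at columns 4/24/44, 1-based) with
deterministic per-anchor variation, standing in for curated subfamily
representative repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import (HORMONES, TIME_POINTS_H, CollinearityBlock,
                         ExpressionMatrix, ProteinRecord)
from .repeat_scanner import AA_ALPHABET, RepeatProfile, build_repeat_profile

# 52-residue synthetic consensus of a plant MYB repeat; Ws at 0-based
# columns 3, 23, 43 (the three canonical tryptophans).
REPEAT_CONSENSUS = "KGPWTAEEDELLRKAVEAHGGENWRSVAKRAGLNRCGKSCRLRWANYLRPDI"
CANONICAL_W_COLUMNS = (3, 23, 43)
REPEAT_LENGTH = len(REPEAT_CONSENSUS)

FAMILY_REPEATS = {"1R": 1, "2R": 2, "3R": 3, "4R": 4}

_CODONS = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAC",
    "P": "CCT", "Q": "CAA", "R": "AGA", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAC",
}
_SYNONYMS = {
    "A": ["GCT", "GCC", "GCA"], "R": ["AGA", "AGG", "CGT"],
    "L": ["CTT", "CTC", "TTG"], "S": ["TCT", "TCC", "AGC"],
    "G": ["GGT", "GGA", "GGC"], "V": ["GTT", "GTC", "GTG"],
    "T": ["ACT", "ACC", "ACA"], "P": ["CCT", "CCA", "CCC"],
    "E": ["GAA", "GAG"], "D": ["GAT", "GAC"], "K": ["AAA", "AAG"],
    "N": ["AAC", "AAT"], "Q": ["CAA", "CAG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC"], "F": ["TTC", "TTT"], "Y": ["TAC", "TAT"],
    "C": ["TGC", "TGT"], "W": ["TGG"], "M": ["ATG"],
}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class TruthTable:
    """Planted truth serialized alongside generated outputs."""

    table: pd.DataFrame
    seed: int
    params: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def default_anchor_alignment(n_anchors: int = 8) -> list[str]:
    """Deterministic synthetic anchor repeats: the consensus plus a few
    substitutions per anchor, never at the canonical W columns."""
    rng = np.random.default_rng(20200875)
    anchors = [REPEAT_CONSENSUS]
    mutable = [i for i in range(REPEAT_LENGTH) if i not in CANONICAL_W_COLUMNS]
    for _ in range(n_anchors - 1):
        row = list(REPEAT_CONSENSUS)
        for pos in rng.choice(mutable, size=5, replace=False):
            choices = [a for a in AA_ALPHABET if a != row[pos]]
            row[pos] = choices[rng.integers(len(choices))]
        anchors.append("".join(row))
    return anchors


def default_profile(**kwargs) -> RepeatProfile:
    """Repeat profile built from the synthetic anchor alignment."""
    return build_repeat_profile(default_anchor_alignment(), **kwargs)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA_ALPHABET[i]
                   for i in rng.integers(0, 20, size=length))


def _mutate(seq: str, rng: np.random.Generator, rate: float,
            protected: set[int]) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            choices = [a for a in AA_ALPHABET if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def make_myb_proteome(n_per_family: Mapping[str, int],
                      noise_rate: float = 0.0, n_decoys: int = 0,
                      seed: int = 0) -> tuple[list[ProteinRecord], TruthTable]:
    """Proteome with planted MYB repeat architectures and decoys.

    Each planted protein carries the family's repeat count as consensus
    copies separated by 3–8 residue linkers, flanked by 10–40 random
    residues.  Residues are point-mutated at ``noise_rate`` but never at
    the canonical W columns.  Decoys are random-composition sequences with
    no planted repeat.
    """
    if noise_rate >= 0.5:
        raise ValueError("noise_rate >= 0.5 destroys the planted signal")
    rng = np.random.default_rng(seed)
    records, rows = [], []
    for family in sorted(n_per_family):
        k = FAMILY_REPEATS[family]
        for i in range(n_per_family[family]):
            pid = f"syn{family}_{i:03d}"
            nterm = _random_protein(rng, int(rng.integers(10, 41)))
            parts, starts = [nterm], []
            pos = len(nterm)
            for r in range(k):
                rep = _mutate(REPEAT_CONSENSUS, rng, noise_rate,
                              set(CANONICAL_W_COLUMNS))
                starts.append(pos)
                parts.append(rep)
                pos += REPEAT_LENGTH
                if r < k - 1:
                    linker = _random_protein(rng, int(rng.integers(3, 9)))
                    parts.append(linker)
                    pos += len(linker)
            parts.append(_random_protein(rng, int(rng.integers(10, 41))))
            records.append(ProteinRecord(pid, "".join(parts)))
            rows.append({"protein_id": pid, "family": family,
                         "repeat_starts": ",".join(map(str, starts))})
    for i in range(n_decoys):
        pid = f"decoy_{i:03d}"
        length = int(rng.integers(100, 401))
        records.append(ProteinRecord(pid, _random_protein(rng, length)))
        rows.append({"protein_id": pid, "family": "none", "repeat_starts": ""})
    truth = TruthTable(pd.DataFrame(rows), seed,
                       {"noise_rate": noise_rate, "n_decoys": n_decoys})
    return records, truth


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def make_gene_models(records: Sequence[ProteinRecord], truth: TruthTable,
                     signature_of: Mapping[str, Sequence[tuple[int, int, int]]],
                     seed: int = 0) -> tuple[dict[str, str], str, TruthTable]:
    """Back-translate planted proteins into gene models with designed
    intron signatures.

    ``signature_of`` assigns each protein id an ordered event list
    (repeat_slot, domain_column, phase); introns (canonical GT..AG, length
    80–300 nt) are inserted at the dictated coding positions.  Synonymous
    codons are sampled under the seed.  Each gene sits on its own contig,
    on a random strand.  Returns (contig sequences, GFF3 text, truth).
    """
    rng = np.random.default_rng(seed)
    starts_of = {r["protein_id"]: ([int(x) for x in r["repeat_starts"].split(",")]
                                   if r["repeat_starts"] else [])
                 for _, r in truth.table.iterrows()}
    contigs: dict[str, str] = {}
    gff = ["##gff-version 3"]
    rows = []
    pad = 50
    for rec in records:
        sig = list(signature_of.get(rec.id, ()))
        starts = starts_of.get(rec.id, [])
        cds = "".join(
            _SYNONYMS[aa][rng.integers(len(_SYNONYMS[aa]))]
            for aa in rec.sequence)
        cut_points = []
        for slot, column, phase in sig:
            if slot >= len(starts) or not 0 <= column < REPEAT_LENGTH:
                raise ValueError(
                    f"{rec.id}: signature event (slot {slot}, column "
                    f"{column}) outside the protein's domain span")
            cut = (starts[slot] + column) * 3 + phase
            cut_points.append(cut)
        if sorted(cut_points) != cut_points or len(set(cut_points)) != len(cut_points):
            raise ValueError(f"{rec.id}: signature events out of order")
        pieces, prev = [], 0
        for cut in cut_points:
            pieces.append(cds[prev:cut])
            prev = cut
        pieces.append(cds[prev:])
        introns = []
        for _ in cut_points:
            ln = int(rng.integers(80, 301))
            introns.append("GT" + "".join(
                "ACGT"[i] for i in rng.integers(0, 4, size=ln - 4)) + "AG")
        genic = pieces[0]
        exon_spans = [(0, len(pieces[0]))]          # 0-based half-open in genic
        for intron, piece in zip(introns, pieces[1:]):
            genic += intron
            s = len(genic)
            genic += piece
            exon_spans.append((s, s + len(piece)))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = f"ctg_{rec.id}"
        flank5 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=pad))
        flank3 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=pad))
        if strand == "+":
            contigs[chrom] = flank5 + genic + flank3
            g_exons = [(pad + a + 1, pad + b) for a, b in exon_spans]
        else:
            contigs[chrom] = flank5 + _revcomp(genic) + flank3
            lg = len(genic)
            g_exons = [(pad + lg - b + 1, pad + lg - a) for a, b in exon_spans]
            g_exons = g_exons[::-1]
        gene_id = f"gene_{rec.id}"
        mrna_id = rec.id
        gstart = min(s for s, _ in g_exons)
        gend = max(e for _, e in g_exons)
        gff.append(f"{chrom}\tsynthetic\tgene\t{gstart}\t{gend}\t.\t{strand}"
                   f"\t.\tID={gene_id}")
        gff.append(f"{chrom}\tsynthetic\tmRNA\t{gstart}\t{gend}\t.\t{strand}"
                   f"\t.\tID={mrna_id};Parent={gene_id}")
        for i, (s, e) in enumerate(sorted(g_exons)):
            gff.append(f"{chrom}\tsynthetic\tCDS\t{s}\t{e}\t.\t{strand}\t."
                       f"\tID=cds_{mrna_id}_{i};Parent={mrna_id}")
        rows.append({"gene_id": gene_id, "protein_id": rec.id,
                     "signature": ";".join(f"{s},{c},{p}"
                                           for s, c, p in sig),
                     "strand": strand})
    out_truth = TruthTable(pd.DataFrame(rows), seed, dict(truth.params))
    return contigs, "\n".join(gff) + "\n", out_truth


def make_collinearity(event_mix: Mapping[str, int], seed: int = 0,
                      with_homeology: bool = True):
    """Genome context, blocks and subfamily labels realizing a requested
    mix of duplication events.

    ``event_mix`` keys: TD, HE, SE, SD, origin_rapa, origin_oleracea,
    origin_both.  Chromosomes A01–A10 (subgenome An) and C01–C09 (Cn);
    A0i ~ C0i are declared homeologous.  Requesting HE without a homeology
    map is an error.  Returns (GenomeContext, blocks, subfamily_calls,
    TruthTable).
    """
    from .duplication import GenomeContext

    if event_mix.get("HE", 0) > 0 and not with_homeology:
        raise ValueError("HE events require homeologous chromosome pairs")
    rng = np.random.default_rng(seed)
    an_chroms = [f"A{i:02d}" for i in range(1, 11)]
    cn_chroms = [f"C{i:02d}" for i in range(1, 10)]
    homeology = ({frozenset((f"A{i:02d}", f"C{i:02d}")) for i in range(1, 10)}
                 if with_homeology else set())
    next_rank = {c: 1 for c in an_chroms + cn_chroms}
    genes: dict[str, tuple[str, str, int]] = {}
    subfam: dict[str, str] = {}
    blocks: list[CollinearityBlock] = []
    rows = []
    gid = [0]
    sfid = [0]

    def new_gene(chrom: str, rank: int | None = None) -> str:
        gid[0] += 1
        g = f"BnMYB{gid[0]:03d}"
        sub = "An" if chrom.startswith("A") else "Cn"
        r = next_rank[chrom] if rank is None else rank
        next_rank[chrom] = max(next_rank[chrom], r) + 1
        genes[g] = (sub, chrom, r)
        return g

    def new_subfam() -> str:
        sfid[0] += 1
        return f"S{sfid[0]}"

    def add_block(pair: str, c1: str, c2: str, g1: str, g2: str) -> str:
        bid = f"blk{len(blocks) + 1:03d}"
        blocks.append(CollinearityBlock(bid, pair, (c1, c2), [(g1, g2)]))
        return bid

    def record(g: str, events: str, origin: str = "none") -> None:
        rows.append({"gene_id": g, "events": events, "origin": origin})

    for _ in range(event_mix.get("TD", 0)):
        chrom = an_chroms[rng.integers(len(an_chroms))]
        g1 = new_gene(chrom)
        g2 = new_gene(chrom)
        lab = new_subfam()
        subfam[g1] = subfam[g2] = lab
        record(g1, "TD")
        record(g2, "TD")
    for _ in range(event_mix.get("HE", 0)):
        i = int(rng.integers(1, 10))
        g1 = new_gene(f"A{i:02d}")
        g2 = new_gene(f"C{i:02d}")
        lab = new_subfam()
        subfam[g1] = subfam[g2] = lab
        add_block("An-Cn", f"A{i:02d}", f"C{i:02d}", g1, g2)
        record(g1, "HE")
        record(g2, "HE")
    for _ in range(event_mix.get("SE", 0)):
        if rng.random() < 0.5:                    # within-subgenome variant
            c1, c2 = rng.choice(an_chroms, size=2, replace=False)
            pair = "An-An"
        else:                                     # non-homeologous cross pair
            i, j = rng.choice(range(1, 10), size=2, replace=False)
            c1, c2, pair = f"A{i:02d}", f"C{j:02d}", "An-Cn"
        g1, g2 = new_gene(c1), new_gene(c2)
        lab = new_subfam()
        subfam[g1] = subfam[g2] = lab
        add_block(pair, c1, c2, g1, g2)
        record(g1, "SE")
        record(g2, "SE")
    for _ in range(event_mix.get("SD", 0)):
        chrom = cn_chroms[rng.integers(len(cn_chroms))]
        g1 = new_gene(chrom)
        r2 = next_rank[chrom] + 1                 # leave a rank gap: not tandem
        g2 = new_gene(chrom, rank=r2)
        lab = new_subfam()
        subfam[g1] = subfam[g2] = lab
        add_block("Cn-Cn" if chrom.startswith("C") else "An-An",
                  chrom, chrom, g1, g2)
        record(g1, "SD")
        record(g2, "SD")
    origin_specs = [("origin_rapa", "An-Ar", an_chroms, "Ar", "B.rapa"),
                    ("origin_oleracea", "Cn-Co", cn_chroms, "Co", "B.oleracea")]
    for key, pair, chroms, ptag, origin in origin_specs:
        for _ in range(event_mix.get(key, 0)):
            chrom = chroms[rng.integers(len(chroms))]
            g = new_gene(chrom)
            subfam[g] = new_subfam()
            add_block(pair, chrom, f"{ptag}{chrom[1:]}", g,
                      f"{ptag}MYB{gid[0]:03d}")
            record(g, "", origin)
    for _ in range(event_mix.get("origin_both", 0)):
        chrom = an_chroms[rng.integers(len(an_chroms))]
        g = new_gene(chrom)
        subfam[g] = new_subfam()
        add_block("An-Ar", chrom, f"Ar{chrom[1:]}", g, f"ArMYB{gid[0]:03d}")
        add_block("An-Co", chrom, f"Co{chrom[1:]}", g, f"CoMYB{gid[0]:03d}")
        record(g, "", "both")

    context = GenomeContext(genes=genes, homeology=homeology)
    truth = TruthTable(pd.DataFrame(rows), seed, dict(event_mix))
    return context, blocks, subfam, truth


def random_expression_design(gene_ids: Sequence[str], seed: int = 0,
                             frac_not_expressed: float = 0.2,
                             frac_up_all: float = 0.25,
                             frac_down_all: float = 0.25) -> dict[str, dict]:
    """Planted design: up-all / down-all / mixed / not-expressed genes.

    Mixed genes carry at least one up and one down hormone so the group is
    unambiguous.
    """
    rng = np.random.default_rng(seed)
    ids = list(gene_ids)
    rng.shuffle(ids)
    n = len(ids)
    n_ne = int(frac_not_expressed * n)
    n_up = int(frac_up_all * n)
    n_down = int(frac_down_all * n)
    design = {}
    for i, g in enumerate(ids):
        if i < n_ne:
            design[g] = {"expressed": False, "directions": {}}
        elif i < n_ne + n_up:
            design[g] = {"expressed": True,
                         "directions": {h: "up" for h in HORMONES}}
        elif i < n_ne + n_up + n_down:
            design[g] = {"expressed": True,
                         "directions": {h: "down" for h in HORMONES}}
        else:
            n_up_h = int(rng.integers(1, 5))
            hs = list(HORMONES)
            rng.shuffle(hs)
            dirs = {h: ("up" if k < n_up_h else "down")
                    for k, h in enumerate(hs)}
            design[g] = {"expressed": True, "directions": dirs}
    return design


def make_expression(gene_ids: Sequence[str], design: Mapping[str, dict],
                    seed: int = 0, n_replicates: int = 2,
                    fold_up: float = 2.0, fold_down: float = 0.5,
                    cv: float = 0.1) -> tuple[ExpressionMatrix, TruthTable]:
    """FPKM matrix with planted per-hormone responses.

    Layout: 5 hormones × 6 time points × ``n_replicates``, per-hormone
    time-0 controls.  Expressed genes draw a lognormal baseline (median 8,
    floored at 5 so planted folds stay decisive) and apply their planted
    fold at 2–5 random post-treatment time points; non-expressed genes are
    uniform on [0, 0.9).  Noise is multiplicative lognormal with the given
    coefficient of variation.
    """
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log(1.0 + cv ** 2)))
    samples = [(h, t, r) for h in HORMONES for t in TIME_POINTS_H
               for r in range(1, n_replicates + 1)]
    sample_ids = [f"{h}_{t}h_r{r}" for h, t, r in samples]
    values = np.zeros((len(gene_ids), len(samples)))
    rows = []
    for gi, g in enumerate(gene_ids):
        plan = design[g]
        if not plan["expressed"]:
            values[gi] = rng.uniform(0.0, 0.9, size=len(samples))
            rows.append({"gene_id": g, "group": "not-expressed",
                         "directions": ""})
            continue
        baseline = max(float(rng.lognormal(np.log(8.0), 0.6)), 5.0)
        affected: dict[str, set[int]] = {}
        for h, d in plan["directions"].items():
            if d in ("up", "down"):
                k = int(rng.integers(2, 6))
                affected[h] = set(rng.choice(TIME_POINTS_H[1:], size=k,
                                             replace=False).tolist())
        for si, (h, t, r) in enumerate(samples):
            level = baseline
            d = plan["directions"].get(h, "none")
            if t > 0 and t in affected.get(h, ()):
                level *= fold_up if d == "up" else fold_down
            values[gi, si] = level * rng.lognormal(0.0, sigma)
        dirs = plan["directions"]
        if all(dirs.get(h) == "up" for h in HORMONES):
            group = "up-all"
        elif all(dirs.get(h) == "down" for h in HORMONES):
            group = "down-all"
        else:
            group = "mixed"
        rows.append({"gene_id": g, "group": group,
                     "directions": ";".join(f"{h}:{dirs.get(h, 'none')}"
                                            for h in HORMONES)})
    vdf = pd.DataFrame(values, index=list(gene_ids), columns=sample_ids)
    meta = pd.DataFrame(
        [{"sample_id": sid, "hormone": h, "time_h": t, "replicate": r}
         for sid, (h, t, r) in zip(sample_ids, samples)])
    matrix = ExpressionMatrix(vdf, meta)
    truth = TruthTable(pd.DataFrame(rows), seed,
                       {"n_replicates": n_replicates, "cv": cv})
    return matrix, truth


def random_additive_tree(n_leaves: int, seed: int = 0
                         ) -> tuple[list[str], np.ndarray, set[frozenset]]:
    """Random binary tree with positive branch lengths and its additive
    leaf-to-leaf distance matrix (the neighbor-joining correctness oracle).

    Returns (leaf ids, distance matrix, true non-trivial bipartitions).
    """
    from .phylogeny import bipartitions

    rng = np.random.default_rng(seed)
    ids = [f"t{i:02d}" for i in range(n_leaves)]
    nodes = [TreeNode(name=i) for i in ids]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.05, 0.5))
        b.length = float(rng.uniform(0.05, 0.5))
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    for n in nodes:
        n.length = float(rng.uniform(0.05, 0.5))
    tree = TreeNode(children=nodes)
    dm = tree.tip_tip_distances(endpoints=ids)
    return ids, dm.data.copy(), bipartitions(tree)
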