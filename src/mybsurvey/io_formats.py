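"""Readers/writers for the pipeline's external formats and basic protein annotation.

External conventions follow the respective standards: FASTA and GFF3
(1-based, inclusive coordinates) on the outside; all internal interval
arithmetic is 0-based half-open, converted at the boundary.

Expression tables are TSV with gene ids in the first column and sample ids
in the header; sample metadata is a second TSV with columns
``sample_id, hormone, time_h, replicate``.  Collinearity blocks are TSV with
columns ``block_id, genome_pair, chrom1, chrom2, gene1, gene2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import skbio
from Bio import SeqIO

HORMONES = ("IAA", "GA3", "6-BA", "ABA", "ACC")
TIME_POINTS_H = (0, 1, 3, 6, 12, 24)

GENOME_PAIRS = ("An-An", "Cn-Cn", "An-Cn", "An-Ar", "Cn-Co", "An-Co", "Cn-Ar")

# Average residue (in-chain) masses in Da; free amino acid = residue + water.
_WATER = 18.01528
_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

# EMBOSS iep pKa set (the default table; an alternative may be passed in).
EMBOSS_PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}


@dataclass
class ProteinRecord:
    """One proteome entry: canonical amino acids plus ``X`` for unknowns."""

    id: str
    sequence: str
    species: str = ""
    incomplete: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"protein {self.id!r}: whitespace in sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene's coding structure.

    ``exons`` are CDS segments as 1-based inclusive genomic intervals listed
    in transcription order (descending genomic coordinates on the − strand).
    """

    gene_id: str
    protein_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_length: int = 0
    incomplete: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if not self.cds_length:
            self.cds_length = sum(e - s + 1 for s, e in self.exons)
        if self.cds_length % 3 != 0:
            self.incomplete = True

    @property
    def exon_cds_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]


@dataclass
class CollinearityBlock:
    block_id: str
    genome_pair: str
    chrom_pair: tuple[str, str]
    gene_pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.genome_pair not in GENOME_PAIRS:
            raise ValueError(
                f"block {self.block_id!r}: unknown genome_pair {self.genome_pair!r}"
            )


class ExpressionMatrix:
    """FPKM matrix (genes × samples) with per-sample hormone/time metadata.

    Replicate values are stored raw; averaging per condition is a downstream
    decision.  Time 0 is the untreated control (CK).  Both 60-sample layouts
    (5 hormones × 6 times × 2 replicates, or a shared control) are accepted:
    the control set is either per-hormone or shared, flagged by
    ``shared_control``.
    """

    def __init__(self, values: pd.DataFrame, metadata: pd.DataFrame,
                 shared_control: bool = False):
        if (values.values < 0).any():
            bad = values.index[(values.values < 0).any(axis=1)][0]
            raise ValueError(f"negative FPKM for gene {bad!r}")
        missing = [s for s in values.columns if s not in set(metadata["sample_id"])]
        if missing:
            raise ValueError(f"sample without metadata: {missing[0]!r}")
        meta = metadata.set_index("sample_id").loc[list(values.columns)].reset_index()
        bad_h = set(meta["hormone"]) - set(HORMONES) - {"CK"}
        if bad_h:
            raise ValueError(f"unknown hormone tag(s): {sorted(bad_h)}")
        self.values = values
        self.metadata = meta
        self.shared_control = shared_control

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)],
                                self.metadata, self.shared_control)

    def condition_means(self) -> pd.DataFrame:
        """Mean FPKM per (hormone, time_h) condition, replicates averaged.

        Columns are a MultiIndex (hormone, time_h); the control (time 0)
        appears once per hormone, or under 'CK' if shared.
        """
        meta = self.metadata
        cols = {}
        for (h, t), grp in meta.groupby(["hormone", "time_h"]):
            cols[(h, int(t))] = self.values[grp["sample_id"]].mean(axis=1)
        out = pd.DataFrame(cols)
        out.columns = pd.MultiIndex.from_tuples(out.columns,
                                                names=["hormone", "time_h"])
        return out


def read_fasta(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA: sequences uppercased, terminal ``*`` stripped.

    Duplicate ids raise; an empty file returns an empty list with a warning.
    An internal ``*`` flags the record incomplete (retained).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        incomplete = "*" in seq
        records.append(ProteinRecord(rec.id, seq, species=species,
                                     incomplete=incomplete))
    if not records:
        warnings.warn(f"no records in FASTA {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_gff3_gene_models(gff_path: str | Path,
                          id_map: Mapping[str, str] | None = None,
                          ) -> list[GeneModel]:
    """Parse gene models (gene → mRNA → CDS) from a GFF3 file.

    The first mRNA per gene is used.  ``id_map`` maps mRNA ids to protein
    ids (identity when omitted).  CDS features without a parent mRNA are
    skipped with a warning; a CDS length not divisible by 3 flags the gene
    incomplete but the model is retained.
    """
    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    orphans = [f.id for f in db.features_of_type("CDS")
               if not list(db.parents(f, featuretype="mRNA"))]
    if orphans:
        warnings.warn(f"skipping {len(orphans)} CDS feature(s) without a parent mRNA",
                      stacklevel=2)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            continue
        mrna = mrnas[0]
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            continue
        exons = [(f.start, f.end) for f in cds]
        if mrna.strand == "-":
            exons = exons[::-1]
        protein_id = (id_map or {}).get(mrna.id, mrna.id)
        models.append(GeneModel(gene_id=gene.id, protein_id=protein_id,
                                chromosome=gene.seqid, strand=mrna.strand,
                                exons=exons))
    return models


def read_expression_table(path: str | Path, metadata_path: str | Path,
                          shared_control: bool = False) -> ExpressionMatrix:
    """Load a genes × samples FPKM TSV plus a sample-metadata TSV."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t",
                           dtype={"sample_id": str, "hormone": str})
    return ExpressionMatrix(values, metadata, shared_control=shared_control)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path,
                           metadata_path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    matrix.metadata.to_csv(metadata_path, sep="\t", index=False)


def read_collinearity(path: str | Path) -> list[CollinearityBlock]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    blocks = []
    for (bid, gpair, c1, c2), grp in df.groupby(
            ["block_id", "genome_pair", "chrom1", "chrom2"], sort=False):
        pairs = list(zip(grp["gene1"], grp["gene2"]))
        blocks.append(CollinearityBlock(bid, gpair, (c1, c2), pairs))
    return blocks


def write_collinearity(blocks: Iterable[CollinearityBlock],
                       path: str | Path) -> None:
    rows = []
    for b in blocks:
        for g1, g2 in b.gene_pairs:
            rows.append((b.block_id, b.genome_pair, b.chrom_pair[0],
                         b.chrom_pair[1], g1, g2))
    pd.DataFrame(rows, columns=["block_id", "genome_pair", "chrom1",
                                "chrom2", "gene1", "gene2"]
                 ).to_csv(path, sep="\t", index=False)


def write_newick(tree: skbio.TreeNode, path: str | Path) -> None:
    """Write newick with bootstrap supports as internal labels and branch
    lengths rounded to 6 decimals."""
    out = tree.copy()
    for node in out.traverse():
        if node.length is not None:
            node.length = round(float(node.length), 6)
    out.write(str(path), format="newick")


def read_newick(path: str | Path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick")


def annotate_physicochemical(protein: ProteinRecord,
                             pka: Mapping[str, float] = EMBOSS_PKA,
                             ) -> tuple[float, float]:
    """Theoretical molecular weight (Da) and isoelectric point of a protein.

    MW is the sum of average residue masses plus one water; ``X`` residues
    are excluded from the sum with a warning.  pI is found by bisection of
    the Henderson–Hasselbalch net charge over the EMBOSS pKa table to a
    residual charge below 1e-4.
    """
    seq = protein.sequence.replace("*", "")
    if not seq:
        raise ValueError(f"protein {protein.id!r}: empty sequence")
    n_x = seq.count("X")
    if n_x:
        warnings.warn(f"protein {protein.id!r}: {n_x} X residue(s) excluded "
                      "from molecular weight", stacklevel=2)
    unknown = set(seq) - set(_RESIDUE_MASS) - {"X"}
    if unknown:
        raise ValueError(f"protein {protein.id!r}: non-canonical residues "
                         f"{sorted(unknown)}")
    mw = sum(_RESIDUE_MASS[c] for c in seq if c != "X") + _WATER

    counts = {aa: seq.count(aa) for aa in "CDEHKRY"}

    def net_charge(ph: float) -> float:
        pos = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
        for aa in "HKR":
            pos += counts[aa] / (1.0 + 10 ** (ph - pka[aa]))
        neg = 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
        for aa in "CDEY":
            neg += counts[aa] / (1.0 + 10 ** (pka[aa] - ph))
        return pos - neg

    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(mid)
        if abs(q) < 1e-4:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mw, mid
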