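"""Classify per-gene duplication and origin events from collinearity blocks.

Brassica napus is an allotetraploid (AnAnCnCn) formed from B. rapa (Ar) and
B. oleracea (Co).  Gene pairs in collinear blocks are typed as:

* TD — tandem duplication: two same-subfamily genes adjacent in the gene
  order of one chromosome (no block required);
* HE — homeologous exchange: a cross-subgenome pair on chromosomes declared
  homeologous (An_i ~ Cn_i);
* SE — segmental exchange: a pair on different, non-homeologous
  chromosomes;
* SD — segmental duplication: a duplicated block within one chromosome.

Precedence per pair is TD > HE > SE > SD; a gene in several pairs
accumulates several event tags.  Blocks against the progenitor genomes
(An-Ar, Cn-Co and the exchanged sides An-Co, Cn-Ar) set each gene's
progenitor origin (B.rapa / B.oleracea / both).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import CollinearityBlock

EVENTS = ("TD", "HE", "SE", "SD")
PROGENITOR_PAIRS = {"An-Ar": "B.rapa", "Cn-Ar": "B.rapa",
                    "Cn-Co": "B.oleracea", "An-Co": "B.oleracea"}
INTRA_PAIRS = {"An-An", "Cn-Cn", "An-Cn"}


@dataclass
class GenomeContext:
    """Gene placement (subgenome, chromosome, rank in the chromosome's gene
    order) plus the declared homeologous chromosome pairs."""

    genes: dict[str, tuple[str, str, int]]     # gene -> (subgenome, chrom, rank)
    homeology: set[frozenset]                  # {frozenset({An_chrom, Cn_chrom})}

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        for g, (_, chrom, rank) in self.genes.items():
            key = (chrom, rank)
            if key in seen:
                raise ValueError(
                    f"rank {rank} on {chrom} assigned to both "
                    f"{seen[key]!r} and {g!r}")
            seen[key] = g

    def subgenome(self, gene: str) -> str:
        return self.genes[gene][0]

    def chromosome(self, gene: str) -> str:
        return self.genes[gene][1]

    def rank(self, gene: str) -> int:
        return self.genes[gene][2]

    def homeologous(self, chrom_a: str, chrom_b: str) -> bool:
        return frozenset((chrom_a, chrom_b)) in self.homeology

    @classmethod
    def from_tables(cls, context_rows: Iterable[Mapping],
                    homeology_rows: Iterable[Mapping]) -> "GenomeContext":
        genes = {r["gene_id"]: (r["subgenome"], r["chromosome"], int(r["rank"]))
                 for r in context_rows}
        hom = {frozenset((r["chrom_a"], r["chrom_b"])) for r in homeology_rows}
        return cls(genes=genes, homeology=hom)


@dataclass
class DuplicationCall:
    gene_id: str
    events: set = field(default_factory=set)
    progenitor_origin: str = "none"            # B.rapa / B.oleracea / both / none
    evidence: list = field(default_factory=list)
    colinear: bool = False


def classify_pair(context: GenomeContext, g1: str, g2: str,
                  subfamily_of: Mapping[str, str]) -> str:
    """Event class of one intra-genome colinear pair (TD > HE > SE > SD)."""
    sg1, c1, r1 = context.genes[g1]
    sg2, c2, r2 = context.genes[g2]
    same_sub = (subfamily_of.get(g1) is not None
                and subfamily_of.get(g1) == subfamily_of.get(g2))
    if c1 == c2 and abs(r1 - r2) == 1 and same_sub:
        return "TD"
    if sg1 != sg2 and context.homeologous(c1, c2):
        return "HE"
    if c1 != c2:
        return "SE"
    return "SD"


def classify_duplications(blocks: Sequence[CollinearityBlock],
                          context: GenomeContext,
                          subfamily_calls: Mapping[str, str],
                          ) -> list[DuplicationCall]:
    """Per-gene duplication events and progenitor origins.

    Intra-genome blocks (An-An, Cn-Cn, An-Cn) are typed pair by pair;
    progenitor blocks set origins (the napus-side gene is the first of each
    pair).  Tandem duplications are additionally detected from gene order
    alone: same subfamily, same chromosome, adjacent ranks.
    """
    calls = {g: DuplicationCall(gene_id=g) for g in context.genes}
    origins: dict[str, set] = {g: set() for g in context.genes}

    for block in blocks:
        for g1, g2 in block.gene_pairs:
            if block.genome_pair in INTRA_PAIRS:
                for g in (g1, g2):
                    if g not in context.genes:
                        raise KeyError(
                            f"block {block.block_id!r}: gene {g!r} has no "
                            "genome context (missing rank)")
                ev = classify_pair(context, g1, g2, subfamily_calls)
                for g in (g1, g2):
                    calls[g].events.add(ev)
                    calls[g].colinear = True
                    calls[g].evidence.append((block.block_id, g1, g2, ev))
            elif block.genome_pair in PROGENITOR_PAIRS:
                if g1 not in context.genes:
                    raise KeyError(
                        f"block {block.block_id!r}: napus gene {g1!r} has no "
                        "genome context (missing rank)")
                origins[g1].add(PROGENITOR_PAIRS[block.genome_pair])
                calls[g1].colinear = True
                calls[g1].evidence.append(
                    (block.block_id, g1, g2, block.genome_pair))

    # rank-adjacency tandem duplications (no block required)
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g, (_, chrom, rank) in context.genes.items():
        by_chrom.setdefault(chrom, []).append((rank, g))
    for chrom, ranked in by_chrom.items():
        ranked.sort()
        for (r1, g1), (r2, g2) in zip(ranked, ranked[1:]):
            if r2 - r1 == 1 and subfamily_calls.get(g1) is not None \
                    and subfamily_calls.get(g1) == subfamily_calls.get(g2):
                for g in (g1, g2):
                    calls[g].events.add("TD")
                    calls[g].evidence.append(("rank-adjacency", g1, g2, "TD"))

    for g, orig in origins.items():
        if len(orig) == 2:
            calls[g].progenitor_origin = "both"
        elif orig:
            calls[g].progenitor_origin = orig.pop()
    return [calls[g] for g in sorted(calls)]


def _pct(num: int, den: int) -> int:
    """Integer percentage with round-half-up (as printed in summaries)."""
    if den == 0:
        return 0
    return int(100.0 * num / den + 0.5)


def duplication_summary(calls: Sequence[DuplicationCall],
                        families: Mapping[str, str] | None = None,
                        family_filter: str | None = None) -> dict:
    """Counts and integer-rounded shares per event class and origin.

    Event denominators are genes with at least one colinear relationship;
    origin denominators are genes with any progenitor origin.  A zero
    denominator is flagged.
    """
    if family_filter is not None:
        families = families or {}
        calls = [c for c in calls
                 if families.get(c.gene_id) == family_filter]
    colinear = [c for c in calls if c.colinear]
    den = len(colinear)
    event_counts = {ev: sum(1 for c in colinear if ev in c.events)
                    for ev in EVENTS}
    with_origin = [c for c in colinear if c.progenitor_origin != "none"]
    origin_den = len(with_origin)
    origin_counts = {
        "B.rapa": sum(1 for c in with_origin
                      if c.progenitor_origin in ("B.rapa", "both")),
        "B.oleracea": sum(1 for c in with_origin
                          if c.progenitor_origin in ("B.oleracea", "both")),
    }
    return {
        "n_genes": len(calls),
        "n_colinear": den,
        "colinear_pct": _pct(den, len(calls)),
        "event_counts": event_counts,
        "event_pct": {ev: _pct(n, den) for ev, n in event_counts.items()},
        "origin_counts": origin_counts,
        "origin_den": origin_den,
        "origin_pct": {k: _pct(n, origin_den)
                       for k, n in origin_counts.items()},
        "empty": den == 0,
    }
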