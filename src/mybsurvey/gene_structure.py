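"""Intron positions/phases over the MYB-domain-encoding region and their
typing into lettered patterns.

An intron's phase is the number of coding nucleotides of the interrupted
codon that precede it (0/1/2).  Only introns falling inside a detected MYB
repeat are part of a gene's domain signature; the rest of the gene is too
divergent to compare.  Signatures are matched against a catalog of
canonical lettered patterns (a shipped, editable configuration: the letters
mirror designations from earlier family surveys, but the canonical column
coordinates here are this package's own configuration artifact, not
measured data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import yaml

from .io_formats import GeneModel
from .repeat_scanner import MybAssignment


@dataclass(frozen=True)
class IntronEvent:
    coding_nt_before: int
    phase: int
    residue_index: int
    domain_column: int | None = None
    repeat_slot: int | None = None

    def __post_init__(self) -> None:
        if self.phase != self.coding_nt_before % 3:
            raise ValueError("phase inconsistent with coding_nt_before")


@dataclass
class IntronSignature:
    """Ordered (repeat_slot, domain_column, phase) events inside the MYB
    domain; an intronless or domain-intron-free gene has an empty tuple."""

    gene_id: str
    events: tuple[tuple[int, int, int], ...]
    pattern_label: str | None = None


def extract_intron_events(gene_model: GeneModel) -> list[IntronEvent]:
    """One event per exon junction, in transcription order.

    ``coding_nt_before`` is the cumulative CDS length of the preceding
    exons; phase follows as its value mod 3.  Single-exon genes yield an
    empty list.
    """
    events = []
    cum = 0
    lengths = gene_model.exon_cds_lengths
    for ln in lengths[:-1]:
        cum += ln
        events.append(IntronEvent(coding_nt_before=cum, phase=cum % 3,
                                  residue_index=cum // 3))
    return events


def domain_signature(gene_model: GeneModel, assignment: MybAssignment
                     ) -> IntronSignature:
    """Map a gene's introns onto its MYB repeats.

    Each intron whose interrupted residue is mapped to a profile column of
    some repeat contributes a (repeat_slot, domain_column, phase) event;
    introns outside every repeat are dropped.  Slots are 0-based from the
    N-terminal repeat of the chain.
    """
    if gene_model.protein_id != assignment.protein_id:
        raise ValueError(
            f"gene {gene_model.gene_id!r} links protein "
            f"{gene_model.protein_id!r}, assignment is for "
            f"{assignment.protein_id!r}")
    sig = []
    for ev in extract_intron_events(gene_model):
        for slot, rep in enumerate(assignment.repeats):
            col = rep.column_map.get(ev.residue_index)
            if col is not None:
                sig.append((slot, col, ev.phase))
                break
    sig.sort(key=lambda t: (t[0], t[1]))
    return IntronSignature(gene_id=gene_model.gene_id, events=tuple(sig))


def load_catalog(path: str | None = None) -> dict[str, tuple]:
    """Load the lettered pattern catalog (letter -> canonical events).

    Without a path the catalog shipped with the package is used.
    """
    if path is None:
        text = resources.files("mybsurvey.data").joinpath(
            "intron_patterns.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    catalog = {}
    for letter, events in raw["patterns"].items():
        catalog[str(letter)] = tuple(
            (int(e["slot"]), int(e["column"]), int(e["phase"]))
            for e in (events or []))
    return catalog


def _matches(sig: tuple, canon: tuple, tolerance: int) -> int | None:
    """Total column deviation if ``sig`` matches ``canon`` (same event
    count, same slots and phases, columns within tolerance), else None."""
    if len(sig) != len(canon):
        return None
    dev = 0
    for (s1, c1, p1), (s2, c2, p2) in zip(sig, canon):
        if s1 != s2 or p1 != p2 or abs(c1 - c2) > tolerance:
            return None
        dev += abs(c1 - c2)
    return dev


def label_patterns(signatures: Sequence[IntronSignature],
                   catalog: Mapping[str, tuple] | None = None,
                   tolerance: int = 3) -> list[IntronSignature]:
    """Assign each signature a catalog letter or a ``novel-k`` label.

    A signature matches a letter when event counts, slots and phases agree
    and every column is within ±tolerance of the canonical column.  When
    two letters both match, the smaller total column deviation wins; an
    exact tie is an error.  Unmatched signatures are grouped by exact
    equality and labelled novel-1, novel-2, ... by descending group size
    (ties by smallest gene id).  Labelling is input-order invariant.
    """
    catalog = catalog if catalog is not None else load_catalog()
    labeled = []
    novel_groups: dict[tuple, list[IntronSignature]] = {}
    for s in signatures:
        best: list[tuple[int, str]] = []
        for letter, canon in catalog.items():
            dev = _matches(s.events, canon, tolerance)
            if dev is not None:
                best.append((dev, letter))
        if best:
            best.sort()
            if len(best) > 1 and best[0][0] == best[1][0]:
                raise ValueError(
                    f"gene {s.gene_id!r}: signature matches patterns "
                    f"{best[0][1]!r} and {best[1][1]!r} equally well")
            s = IntronSignature(s.gene_id, s.events, best[0][1])
        else:
            novel_groups.setdefault(s.events, []).append(s)
        labeled.append(s)

    order = sorted(novel_groups,
                   key=lambda ev: (-len(novel_groups[ev]),
                                   min(s.gene_id for s in novel_groups[ev])))
    novel_label = {ev: f"novel-{k}" for k, ev in enumerate(order, start=1)}
    return [
        s if s.pattern_label is not None
        else IntronSignature(s.gene_id, s.events, novel_label[s.events])
        for s in labeled
    ]
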