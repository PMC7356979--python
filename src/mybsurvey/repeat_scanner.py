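"""Detect MYB repeats in protein sequences and type proteins into families.

A MYB repeat is a ~52-residue helix-turn-helix unit carrying three regularly
spaced conserved tryptophans.  Proteins are classified by the number of
adjacent repeats they carry: one (1R / MYB-related), two (2R / R2R3), three
(3R, or 3R-like when one repeat is marginal), or four (4R).

Detection is profile-based: a position-specific log-odds profile is built
from an alignment of anchor repeats, candidate windows are scored along the
protein, and accepted hits must (i) score at least the relaxed profile
threshold, (ii) retain at least two of the three canonical tryptophans, and
(iii) chain with neighbouring hits across short linkers to form a single
domain.  Isolated sub-threshold hits are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import ProteinRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

FAMILIES = ("1R", "2R", "3R", "3R-like", "4R")


@dataclass
class ScanParams:
    """Tunables for repeat scanning and chaining.

    max_linker is the longest residue gap allowed between consecutive
    repeats of one domain (R2–R3 linkers are short).  band is the indel
    tolerance of the window alignment.  min_w is the canonical-tryptophan
    requirement; only exact W is credited.
    """

    max_linker: int = 12
    band: int = 3
    gap_penalty: float = 2.0
    min_w: int = 2
    dp_slack: float = 8.0
    min_chain_column_frac: float = 0.7


@dataclass
class RepeatProfile:
    """Position-specific scoring profile for one MYB repeat."""

    length: int
    frequencies: np.ndarray          # (L, 20), rows sum to 1
    background: np.ndarray           # (20,)
    canonical_w_columns: tuple[int, int, int]
    score_threshold: float
    relaxed_threshold: float
    log_odds: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.log_odds is None:
            with np.errstate(divide="ignore"):
                self.log_odds = np.log2(self.frequencies / self.background)
        if not self.relaxed_threshold < self.score_threshold:
            raise ValueError("relaxed_threshold must be below score_threshold")

    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in self.frequencies.argmax(axis=1))


@dataclass
class MybRepeat:
    """One detected repeat: 0-based half-open protein coordinates."""

    start: int
    end: int
    score: float
    w_matched: int
    column_map: dict[int, int]       # residue index -> profile column
    weak: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty repeat interval")


@dataclass
class MybAssignment:
    protein_id: str
    repeats: list[MybRepeat]
    family: str                      # 1R/2R/3R/3R-like/4R/none
    excluded: bool = False           # long deletion in the MYB domain
    warning: str = ""


@dataclass
class FamilyCensus:
    total: int
    counts: dict[str, int]
    percentages: dict[str, float]
    subfamily_counts: dict[str, int]
    chromosome_counts: dict[str, int]


def _encode(seq: str) -> np.ndarray:
    """Map a protein string to alphabet indices; unknowns (X etc.) -> -1."""
    return np.array([_AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def build_repeat_profile(anchor_alignment: Sequence[str],
                         background: np.ndarray | Mapping[str, float] | None = None,
                         pseudocount: float = 0.5,
                         threshold_factor: float = 0.6,
                         relaxed_factor: float = 0.45) -> RepeatProfile:
    """Build a log-odds repeat profile from a gapped anchor alignment.

    Column frequencies are Laplace-smoothed (pseudocount 0.5 per residue).
    The acceptance threshold defaults to 0.6 × the mean self-score of the
    anchors; the relaxed threshold (marking weak hits) to 0.45 ×.
    The three columns with maximal tryptophan frequency are recorded as the
    canonical W positions.
    """
    if len(anchor_alignment) < 5:
        raise ValueError(f"need >=5 anchor sequences, got {len(anchor_alignment)}")
    lengths = {len(s) for s in anchor_alignment}
    if len(lengths) != 1:
        raise ValueError("anchor alignment rows differ in length")
    L = lengths.pop()

    if background is None:
        bg = np.full(20, 1.0 / 20)
    elif isinstance(background, Mapping):
        bg = np.array([background[a] for a in AA_ALPHABET], dtype=float)
    else:
        bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()

    counts = np.zeros((L, 20))
    for row in anchor_alignment:
        for j, c in enumerate(row.upper()):
            if c == "-":
                continue
            idx = _AA_INDEX.get(c)
            if idx is not None:
                counts[j, idx] += 1
    if (counts.sum(axis=1) == 0).any():
        bad = int(np.where(counts.sum(axis=1) == 0)[0][0])
        raise ValueError(f"alignment column {bad} contains only gaps")
    freqs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True)
                                      + pseudocount * 20)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(freqs / bg)

    w_col = _AA_INDEX["W"]
    canonical = tuple(int(c) for c in np.sort(np.argsort(freqs[:, w_col])[-3:]))

    self_scores = []
    for row in anchor_alignment:
        s = 0.0
        for j, c in enumerate(row.upper()):
            idx = _AA_INDEX.get(c)
            if c != "-" and idx is not None:
                s += log_odds[j, idx]
        self_scores.append(s)
    mean_self = float(np.mean(self_scores))
    return RepeatProfile(
        length=L, frequencies=freqs, background=bg,
        canonical_w_columns=canonical,
        score_threshold=threshold_factor * mean_self,
        relaxed_threshold=relaxed_factor * mean_self,
        log_odds=log_odds,
    )


def _banded_align(idx: np.ndarray, start: int, profile: RepeatProfile,
                  params: ScanParams) -> tuple[float, int, dict[int, int]]:
    """Globally align profile columns to the protein suffix at ``start``
    within an indel band, returning (score, end, residue->column map)."""
    L, band = profile.length, params.band
    lo_m = profile.log_odds
    n_avail = min(L + band, len(idx) - start)
    NEG = -1e18
    # dp[i][j]: best score consuming i residues and j profile columns
    dp = np.full((n_avail + 1, L + 1), NEG)
    dp[0, 0] = 0.0
    back = np.zeros((n_avail + 1, L + 1), dtype=np.int8)  # 1=diag 2=del(col) 3=ins(res)
    gp = params.gap_penalty
    for i in range(0, n_avail + 1):
        j_lo = max(0, i - band)
        j_hi = min(L, i + band)
        for j in range(j_lo, j_hi + 1):
            if i == 0 and j == 0:
                continue
            best, op = NEG, 0
            if i > 0 and j > 0 and dp[i - 1, j - 1] > NEG / 2:
                a = idx[start + i - 1]
                m = lo_m[j - 1, a] if a >= 0 else 0.0
                cand = dp[i - 1, j - 1] + m
                if cand > best:
                    best, op = cand, 1
            if j > 0 and dp[i, j - 1] > NEG / 2:
                cand = dp[i, j - 1] - gp
                if cand > best:
                    best, op = cand, 2
            if i > 0 and dp[i - 1, j] > NEG / 2:
                cand = dp[i - 1, j] - gp
                if cand > best:
                    best, op = cand, 3
            dp[i, j] = best
            back[i, j] = op
    i_best = max(range(max(1, L - band), n_avail + 1), key=lambda i: dp[i, L])
    score = float(dp[i_best, L])
    # traceback for the residue -> column map
    cmap: dict[int, int] = {}
    i, j = i_best, L
    while i > 0 or j > 0:
        op = back[i, j]
        if op == 1:
            cmap[start + i - 1] = j - 1
            i, j = i - 1, j - 1
        elif op == 2:
            j -= 1
        else:
            i -= 1
    return score, start + i_best, cmap


def scan_repeats(protein: ProteinRecord, profile: RepeatProfile,
                 params: ScanParams | None = None) -> list[MybRepeat]:
    """Locate MYB repeats in one protein.

    Ungapped windows of the profile length are scored at every offset; the
    promising ones are refined with a banded (±band) alignment to the
    profile.  Non-overlapping hits are selected greedily by descending score
    (ties: smaller start), hits missing two canonical tryptophans are
    discarded, hits are chained across linkers of at most ``max_linker``
    residues, and isolated weak hits (below the strict threshold) are
    dropped.
    """
    params = params or ScanParams()
    L = profile.length
    idx = _encode(protein.sequence)
    n = len(idx)
    if n < L - params.band:
        return []

    # vectorised ungapped scan
    n_win = n - L + 1
    candidates: list[int] = []
    if n_win > 0:
        scores = np.zeros(n_win)
        for j in range(L):
            col = profile.log_odds[j]
            sl = idx[j:j + n_win]
            valid = sl >= 0
            scores[valid] += col[sl[valid]]
        cutoff = profile.relaxed_threshold - params.dp_slack
        candidates = [int(p) for p in np.where(scores >= cutoff)[0]]
    # short proteins (length in [L-band, L)) still get one aligned attempt
    if not candidates and n >= L - params.band:
        candidates = [0]

    hits: list[MybRepeat] = []
    for p in candidates:
        score, end, cmap = _banded_align(idx, p, profile, params)
        if score < profile.relaxed_threshold or not cmap:
            continue
        res_start = min(cmap)
        w_matched = sum(
            1 for r, c in cmap.items()
            if c in profile.canonical_w_columns and protein.sequence[r] == "W"
        )
        hits.append(MybRepeat(start=res_start, end=end, score=score,
                              w_matched=w_matched, column_map=cmap,
                              weak=score < profile.score_threshold))

    # greedy non-overlapping selection: descending score, ties -> smaller start
    hits.sort(key=lambda h: (-h.score, h.start))
    selected: list[MybRepeat] = []
    for h in hits:
        if all(h.end <= s.start or h.start >= s.end for s in selected):
            selected.append(h)
    selected.sort(key=lambda h: h.start)

    # rule (ii): at least two of the three canonical tryptophans
    selected = [h for h in selected if h.w_matched >= params.min_w]

    # rule (iii): chain across short linkers; isolated weak hits dropped
    kept: list[MybRepeat] = []
    for chain in _chains(selected, params.max_linker):
        if len(chain) == 1 and chain[0].weak:
            continue
        kept.extend(chain)
    return kept


def _chains(hits: list[MybRepeat], max_linker: int) -> list[list[MybRepeat]]:
    """Group start-ordered hits into maximal chains (linker <= max_linker)."""
    chains: list[list[MybRepeat]] = []
    for h in hits:
        if chains and h.start - chains[-1][-1].end <= max_linker:
            chains[-1].append(h)
        else:
            chains.append([h])
    return chains


def classify_family(repeats: list[MybRepeat],
                    params: ScanParams | None = None,
                    profile_length: int | None = None,
                    ) -> tuple[str, list[MybRepeat], bool, str]:
    """Type a protein from its detected repeats.

    The best chain (most repeats, then highest total score) defines the
    domain.  Repeat counts 1–4 map to 1R/2R/3R/4R; a 3-repeat chain with any
    weak member is called 3R-like.  Five or more repeats are reported as 4R
    with a warning.  A chain whose aligned columns cover less than
    ``min_chain_column_frac`` of the expected domain length marks the
    protein excluded (long deletion in the MYB domain).
    Returns (family, chain, excluded, warning).
    """
    params = params or ScanParams()
    chains = _chains(sorted(repeats, key=lambda h: h.start), params.max_linker)
    if not chains:
        return "none", [], False, ""
    chain = max(chains, key=lambda c: (len(c), sum(h.score for h in c)))
    n = len(chain)
    excluded = False
    if profile_length is not None:
        aligned = sum(len(h.column_map) for h in chain)
        if aligned < params.min_chain_column_frac * n * profile_length:
            excluded = True
    warning = ""
    if n == 1:
        family = "1R"
    elif n == 2:
        family = "2R"
    elif n == 3:
        family = "3R-like" if any(h.weak for h in chain) else "3R"
    else:
        family = "4R"
        if n > 4:
            warning = f"{n} chained repeats collapsed to 4R"
    return family, chain, excluded, warning


def assign(protein: ProteinRecord, profile: RepeatProfile,
           params: ScanParams | None = None) -> MybAssignment:
    """Scan one protein and return its family assignment."""
    params = params or ScanParams()
    repeats = scan_repeats(protein, profile, params)
    family, chain, excluded, warning = classify_family(
        repeats, params, profile_length=profile.length)
    if excluded:
        family = "none"
    return MybAssignment(protein_id=protein.id, repeats=chain, family=family,
                         excluded=excluded, warning=warning)


def family_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Shares of the classified total per family, rounded to 1 decimal."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: round(100.0 * v / total, 1) for k, v in counts.items()}


def census(assignments: Sequence[MybAssignment],
           subfamily_calls: Mapping[str, str] | None = None,
           gene_models: Mapping[str, str] | None = None) -> FamilyCensus:
    """Summarise family counts, percentages, subfamilies and chromosomes.

    ``subfamily_calls`` maps protein id -> subfamily label;
    ``gene_models`` maps protein id -> chromosome.
    """
    counts: dict[str, int] = {}
    for a in assignments:
        if a.family == "none":
            continue
        counts[a.family] = counts.get(a.family, 0) + 1
    sub: dict[str, int] = {}
    for lab in (subfamily_calls or {}).values():
        sub[lab] = sub.get(lab, 0) + 1
    chrom: dict[str, int] = {}
    classified = {a.protein_id for a in assignments if a.family != "none"}
    for pid, c in (gene_models or {}).items():
        if pid in classified:
            chrom[c] = chrom.get(c, 0) + 1
    return FamilyCensus(total=sum(counts.values()), counts=counts,
                        percentages=family_percentages(counts),
                        subfamily_counts=sub, chromosome_counts=chrom)
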