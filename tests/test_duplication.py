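import itertools

import numpy as np
import pytest

from mybsurvey import duplication as dup
from mybsurvey import synthetic_data as sd
from mybsurvey.io_formats import CollinearityBlock


def _context(genes, homeology=({"A01", "C01"}, {"A02", "C02"},
                               {"A03", "C03"})):
    return dup.GenomeContext(genes={g: info for g, info in genes.items()},
                             homeology={frozenset(p) for p in homeology})


class TestClassifyPair:
    def test_tandem_adjacency(self):
        ctx = _context({"g1": ("An", "A03", 5), "g2": ("An", "A03", 6)})
        calls = dup.classify_duplications([], ctx, {"g1": "S1", "g2": "S1"})
        assert all(c.events == {"TD"} for c in calls)

    def test_homeologous_pair(self):
        ctx = _context({"g1": ("An", "A01", 1), "g2": ("Cn", "C01", 1)})
        block = CollinearityBlock("b1", "An-Cn", ("A01", "C01"),
                                  [("g1", "g2")])
        calls = dup.classify_duplications([block], ctx, {})
        assert all(c.events == {"HE"} for c in calls)

    def test_unknown_gene_in_block_raises(self):
        ctx = _context({"g1": ("An", "A01", 1)})
        block = CollinearityBlock("b1", "An-Cn", ("A01", "C01"),
                                  [("g1", "gX")])
        with pytest.raises(KeyError, match="gX"):
            dup.classify_duplications([block], ctx, {})

    def test_exhaustive_configurations_match_rule_table(self):
        """Enumerate every pair configuration (subgenome, chromosome,
        homeology, adjacency, subfamily combinations) against an
        independent restatement of the definitions."""
        n_checked = 0
        for same_sub, same_chrom, homeo, adjacent, same_fam in \
                itertools.product([True, False], repeat=5):
            if same_chrom and not same_sub:
                continue            # one chromosome lives in one subgenome
            if same_chrom and homeo:
                continue            # homeology is declared across subgenomes
            if homeo and same_sub:
                continue
            if adjacent and not same_chrom:
                continue
            c1 = "A01"
            c2 = (c1 if same_chrom else
                  "C01" if (homeo and not same_sub) else
                  "A05" if same_sub else "C05")
            sub2 = "An" if same_sub else "Cn"
            r2 = 2 if adjacent else 9
            ctx = _context({"g1": ("An", c1, 1), "g2": (sub2, c2, r2)})
            fams = {"g1": "S1", "g2": "S1" if same_fam else "S2"}
            got = dup.classify_pair(ctx, "g1", "g2", fams)
            # independent rule table, straight from the definitions
            if same_chrom and adjacent and same_fam:
                want = "TD"
            elif not same_sub and homeo:
                want = "HE"
            elif not same_chrom:
                want = "SE"
            else:
                want = "SD"
            assert got == want, (same_sub, same_chrom, homeo, adjacent,
                                 same_fam)
            n_checked += 1
        assert n_checked == 10   # distinct valid pair geometries

    def test_precedence_tandem_beats_segmental(self):
        # adjacent same-subfamily pair that also sits in a block
        ctx = _context({"g1": ("An", "A01", 1), "g2": ("An", "A01", 2)})
        block = CollinearityBlock("b1", "An-An", ("A01", "A01"),
                                  [("g1", "g2")])
        calls = dup.classify_duplications([block], ctx,
                                          {"g1": "S1", "g2": "S1"})
        assert all("TD" in c.events and "SD" not in c.events for c in calls)


class TestProgenitorOrigins:
    def test_origin_sides(self):
        ctx = _context({"g1": ("An", "A01", 1), "g2": ("Cn", "C01", 1),
                        "g3": ("An", "A02", 1)})
        blocks = [
            CollinearityBlock("b1", "An-Ar", ("A01", "Ar01"),
                              [("g1", "BrX")]),
            CollinearityBlock("b2", "Cn-Co", ("C01", "Co01"),
                              [("g2", "BoX")]),
            CollinearityBlock("b3", "An-Ar", ("A02", "Ar02"),
                              [("g3", "BrY")]),
            CollinearityBlock("b4", "An-Co", ("A02", "Co02"),
                              [("g3", "BoY")]),
        ]
        calls = {c.gene_id: c
                 for c in dup.classify_duplications(blocks, ctx, {})}
        assert calls["g1"].progenitor_origin == "B.rapa"
        assert calls["g2"].progenitor_origin == "B.oleracea"
        assert calls["g3"].progenitor_origin == "both"


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", [0, 7, 23])
    def test_generated_events_recovered(self, seed):
        mix = {"TD": 3, "HE": 4, "SE": 3, "SD": 2, "origin_rapa": 3,
               "origin_oleracea": 2, "origin_both": 1}
        ctx, blocks, subfam, truth = sd.make_collinearity(mix, seed=seed)
        calls = dup.classify_duplications(blocks, ctx, subfam)
        tt = truth.table.set_index("gene_id")
        for c in calls:
            want = (set(tt.loc[c.gene_id, "events"].split(","))
                    if tt.loc[c.gene_id, "events"] else set())
            assert c.events == want
            assert c.progenitor_origin == tt.loc[c.gene_id, "origin"]

    def test_he_without_homeology_rejected(self):
        with pytest.raises(ValueError, match="homeolog"):
            sd.make_collinearity({"HE": 1}, seed=0, with_homeology=False)

    def test_event_invariants_hold_on_outputs(self):
        ctx, blocks, subfam, _ = sd.make_collinearity(
            {"TD": 5, "HE": 5, "SE": 5, "SD": 5}, seed=3)
        calls = dup.classify_duplications(blocks, ctx, subfam)
        by_id = {c.gene_id: c for c in calls}
        for c in calls:
            if "TD" in c.events:
                sub, chrom, rank = ctx.genes[c.gene_id]
                partner = any(
                    ctx.genes[o][1] == chrom
                    and abs(ctx.genes[o][2] - rank) == 1
                    and subfam.get(o) == subfam.get(c.gene_id)
                    for o in ctx.genes if o != c.gene_id)
                assert partner
            if "HE" in c.events:
                assert any(ev[3] == "HE" for ev in c.evidence)


class TestSummary:
    def _calls(self, event_counts, denominator, origins=None):
        calls = []
        i = 0
        for ev, n in event_counts.items():
            for _ in range(n):
                calls.append(dup.DuplicationCall(f"g{i}", {ev},
                                                 colinear=True))
                i += 1
        while i < denominator:
            calls.append(dup.DuplicationCall(f"g{i}", set(), colinear=True))
            i += 1
        for origin, n in (origins or {}).items():
            for k in range(n):
                calls[k if origin == "B.rapa" else denominator - 1 - k] \
                    .progenitor_origin = origin
        return calls

    def test_published_2r_shares(self):
        calls = self._calls({"SE": 68, "HE": 109, "SD": 59}, 362)
        s = dup.duplication_summary(calls)
        assert s["event_pct"]["SE"] == 19
        assert s["event_pct"]["HE"] == 30
        assert s["event_pct"]["SD"] == 16

    def test_published_progenitor_shares(self):
        calls = self._calls({}, 126,
                            origins={"B.rapa": 96, "B.oleracea": 30})
        s = dup.duplication_summary(calls)
        assert s["origin_pct"]["B.rapa"] == 76
        assert s["origin_pct"]["B.oleracea"] == 24

    def test_empty_calls_flagged(self):
        s = dup.duplication_summary([])
        assert s["empty"] and s["n_colinear"] == 0

    def test_family_filter(self):
        calls = self._calls({"SE": 2, "HE": 2}, 6)
        fams = {c.gene_id: ("2R" if i < 3 else "1R")
                for i, c in enumerate(calls)}
        s = dup.duplication_summary(calls, families=fams,
                                    family_filter="2R")
        assert s["n_colinear"] == 3
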