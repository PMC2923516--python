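"""Conversion/crossover detection, template direction, merging, rates."""

import numpy as np
import pytest

from matchrom.errors import ValidationError
from matchrom.events import (
    ConversionEvent,
    WindowEvidence,
    allele_affiliation,
    count_events_per_gene,
    detect_conversions,
    detect_crossovers,
    homogenization_rate,
    infer_template_direction,
    merge_ancestral_events,
    rates_table,
)
from matchrom.genealogy import (
    PHASE_SEPARATED,
    PHASE_TOGETHER,
    PHASE_UNRESOLVED,
    PairPhaseCall,
    PhaseMatrix,
    SupportThresholds,
)
from matchrom.io import ChromosomeLayout, GeneAlignmentSet, read_newick_supported
from matchrom.suppression import demarcate_region

from .conftest import make_manifest

THR = SupportThresholds(bootstrap_reps=200)


def call(pair, gene, phase, supported=False):
    return PairPhaseCall(
        pair, gene, phase, separation_supported=supported,
        max_support_on_path=95.0 if supported else 40.0,
    )


def build_phases(layout, pair_phases):
    """pair_phases: {pair: [(phase, supported), ...]} in layout order."""
    pm = PhaseMatrix(genes=list(layout.genes), pair_ids=list(pair_phases))
    for pair, entries in pair_phases.items():
        for gene, (phase, supported) in zip(layout.genes, entries):
            pm.calls[(gene, pair)] = call(pair, gene, phase, supported)
    return pm


T, S, U = PHASE_TOGETHER, PHASE_SEPARATED, PHASE_UNRESOLVED


def maps_for(layout, pair_phases):
    from matchrom.suppression import CLASS_DIVERGED, CLASS_HOMOALLELIC

    maps = {}
    for pair, entries in pair_phases.items():
        classes = [
            CLASS_DIVERGED if phase == S else CLASS_HOMOALLELIC
            for phase, _ in entries
        ]
        maps[pair] = demarcate_region(classes, layout, pair)
    return maps


class TestHomogenizationRate:
    def test_single_event_rate(self):
        est = homogenization_rate(1, 9, 4.6)
        assert est.r_rounded == 0.012
        assert est.K == pytest.approx(1 / 9)

    def test_zero_events(self):
        assert homogenization_rate(0, 9, 4.6).r == 0.0

    def test_direct_arithmetic(self):
        assert homogenization_rate(2, 10, 5.0).r == pytest.approx(0.020)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            homogenization_rate(1, 0, 4.6)
        with pytest.raises(ValidationError):
            homogenization_rate(1, 9, 0.0)
        with pytest.raises(ValidationError):
            homogenization_rate(-1, 9, 4.6)

    def test_linear_in_events_and_inverse_in_time(self):
        base = homogenization_rate(2, 9, 4.6).r
        assert homogenization_rate(4, 9, 4.6).r == pytest.approx(2 * base)
        assert homogenization_rate(2, 9, 9.2).r == pytest.approx(base / 2)


class TestDetectConversions:
    def test_window_rule_fires_between_supported_separations(self):
        layout = ChromosomeLayout(["g0", "g1", "g2"], "g0", "g0")
        phases = build_phases(
            layout, {"L4": [(S, True), (T, False), (S, True)]}
        )
        events = detect_conversions(phases, maps_for(layout, {
            "L4": [(S, True), (T, False), (S, True)]
        }), layout)
        assert len(events) == 1
        ev = events[0]
        assert ev.gene == "g1"
        assert ev.affected_pairs == frozenset({"L4"})
        assert ev.in_region is True
        assert ev.evidence["L4"].left_gene == "g0"

    def test_all_separated_yields_nothing(self):
        layout = ChromosomeLayout(["g0", "g1", "g2"], "g0", "g0")
        pp = {"L4": [(S, True), (S, True), (S, True)]}
        assert detect_conversions(build_phases(layout, pp),
                                  maps_for(layout, pp), layout) == []

    def test_no_together_cells_yields_nothing(self):
        layout = ChromosomeLayout([f"g{i}" for i in range(4)], "g0", "g0")
        pp = {"L4": [(S, True), (U, False), (S, True), (S, False)]}
        assert detect_conversions(build_phases(layout, pp),
                                  maps_for(layout, pp), layout) == []

    def test_terminal_genes_never_fire(self):
        layout = ChromosomeLayout(["g0", "g1"], "g0", "g0")
        pp = {"L4": [(T, False), (S, True)]}
        assert detect_conversions(build_phases(layout, pp),
                                  maps_for(layout, pp), layout) == []

    def test_unresolved_neighbour_extends_window(self):
        layout = ChromosomeLayout([f"g{i}" for i in range(5)], "g0", "g0")
        pp = {"L4": [(S, True), (U, False), (T, False), (U, False), (S, True)]}
        events = detect_conversions(build_phases(layout, pp),
                                    maps_for(layout, pp), layout)
        assert len(events) == 1
        assert events[0].evidence["L4"].left_gene == "g0"
        assert events[0].evidence["L4"].right_gene == "g4"

    def test_strict_adjacency_requires_immediate_neighbours(self):
        layout = ChromosomeLayout([f"g{i}" for i in range(5)], "g0", "g0")
        pp = {"L4": [(S, True), (U, False), (T, False), (U, False), (S, True)]}
        assert detect_conversions(build_phases(layout, pp),
                                  maps_for(layout, pp), layout,
                                  strict_adjacency=True) == []

    def test_unsupported_flanks_do_not_fire(self):
        layout = ChromosomeLayout(["g0", "g1", "g2"], "g0", "g0")
        pp = {"L4": [(S, False), (T, False), (S, False)]}
        assert detect_conversions(build_phases(layout, pp),
                                  maps_for(layout, pp), layout) == []

    def test_layout_mismatch_rejected(self):
        layout = ChromosomeLayout(["g0", "g1", "g2"], "g0", "g0")
        other = ChromosomeLayout(["h0", "h1", "h2"], "h0", "h0")
        pp = {"L4": [(S, True), (T, False), (S, True)]}
        with pytest.raises(ValidationError):
            detect_conversions(build_phases(other, pp), {}, layout)

    def test_evidence_invariant_enforced(self):
        bad = WindowEvidence(
            "g0", "g1", "g2",
            call("L4", "g0", S, supported=False),
            call("L4", "g1", T),
            call("L4", "g2", S, supported=False),
        )
        with pytest.raises(ValidationError):
            ConversionEvent("g1", frozenset({"L4"}), evidence={"L4": bad})


class TestTemplateDirection:
    # converted pair L4 nested inside the mat a clade of three other pairs
    NESTED_IN_A = (
        "((((L4A:0.001,L4a:0.001)100:0.01,L1a:0.02)95:0.02,"
        "(L2a:0.02,L3a:0.02)90:0.02)98:0.05,"
        "((L1A:0.02,L2A:0.02)90:0.02,L3A:0.02)98:0.05);"
    )

    def setup_method(self):
        self.manifest = make_manifest(["L1", "L2", "L3", "L4"])

    def test_nested_in_a_clade(self):
        tree = read_newick_supported(self.NESTED_IN_A)
        assert infer_template_direction(tree, "L4", self.manifest, THR) == "mat_a"

    def test_nested_in_A_clade(self):
        swapped = (
            self.NESTED_IN_A.replace("a:", "+:").replace("A:", "a:")
            .replace("+:", "A:")
        )
        tree = read_newick_supported(swapped)
        assert infer_template_direction(tree, "L4", self.manifest, THR) == "mat_A"

    def test_mixed_neighbourhood_is_unknown(self):
        tree = read_newick_supported(
            "(((L4A:0.001,L4a:0.001)100:0.01,(L1a:0.02,L2A:0.02)95:0.01)95:0.05,"
            "(L1A:0.02,(L2a:0.02,L3a:0.01)90:0.01)90:0.05,L3A:0.05);"
        )
        assert (
            infer_template_direction(tree, "L4", self.manifest, THR)
            == "unknown"
        )

    def test_homogenized_other_pairs_abstain(self):
        # L3's both alleles also sit in the a clade (it converted too):
        # only single-allele pairs vote
        tree = read_newick_supported(
            "((((L4A:0.001,L4a:0.001)100:0.01,(L3A:0.001,L3a:0.001)100:0.01)95:0.02,"
            "(L1a:0.02,L2a:0.02)90:0.02)98:0.05,(L1A:0.02,L2A:0.02)98:0.05);"
        )
        assert infer_template_direction(tree, "L4", self.manifest, THR) == "mat_a"


class TestMerging:
    def _alignment(self, gene, seqs):
        return GeneAlignmentSet(
            gene=gene, sequences=seqs, coding_mask=np.ones(9, dtype=bool)
        )

    def _event(self, gene, pair):
        return ConversionEvent(gene, frozenset({pair}))

    def test_identical_alleles_merge_into_ancestral_event(self):
        manifest = make_manifest(["L3", "L8"], lineages=["3", "8"])
        conv = "ATGAAATTT"
        other = "ATGCCCTTT"
        aln = self._alignment("ser-3", {
            "L3A": conv, "L3a": conv, "L8A": conv, "L8a": conv,
        })
        merged = merge_ancestral_events(
            [self._event("ser-3", "L3"), self._event("ser-3", "L8")],
            {"ser-3": aln}, manifest, merge_max_diffs=0,
        )
        assert len(merged) == 1
        assert merged[0].ancestral
        assert merged[0].lineages == frozenset({"3", "8"})
        assert merged[0].affected_pairs == frozenset({"L3", "L8"})

    def test_divergent_alleles_stay_separate(self):
        manifest = make_manifest(["L2", "L4"], lineages=["2", "4"])
        aln = self._alignment("ser-3", {
            "L2A": "ATGAAATTT", "L2a": "ATGAAATTT",
            "L4A": "ATGCCCTTT", "L4a": "ATGCCCTTT",
        })
        merged = merge_ancestral_events(
            [self._event("ser-3", "L2"), self._event("ser-3", "L4")],
            {"ser-3": aln}, manifest, merge_max_diffs=2,
        )
        assert len(merged) == 2
        assert not any(m.ancestral for m in merged)

    def test_single_pair_event_unchanged(self):
        manifest = make_manifest(["L4"], lineages=["4"])
        aln = self._alignment("lys-4", {"L4A": "ATGAAATTT", "L4a": "ATGAAATTT"})
        merged = merge_ancestral_events(
            [self._event("lys-4", "L4")], {"lys-4": aln}, manifest
        )
        assert len(merged) == 1
        assert not merged[0].ancestral
        assert merged[0].lineages == frozenset({"4"})

    def test_same_lineage_pairs_merge_without_ancestral_flag(self):
        manifest = make_manifest(["L8(1)", "L8(2)"], lineages=["8", "8"])
        conv = "ATGAAATTT"
        aln = self._alignment("ad-9", {
            "L8(1)A": conv, "L8(1)a": conv, "L8(2)A": conv, "L8(2)a": conv,
        })
        merged = merge_ancestral_events(
            [self._event("ad-9", "L8(1)"), self._event("ad-9", "L8(2)")],
            {"ad-9": aln}, manifest,
        )
        assert len(merged) == 1
        assert not merged[0].ancestral  # one lineage, however many pairs
        assert merged[0].lineages == frozenset({"8"})


class TestCrossovers:
    def _trees(self, swapped_from):
        """Per-gene trees for pairs L3, L4, L7; L4 swaps from a given gene."""
        genes = ["g0", "g1", "g2", "g3", "g4"]
        trees = {}
        for gi, gene in enumerate(genes):
            if gi >= swapped_from:
                # L4A with the a alleles, L4a with the A alleles
                nwk = (
                    "(((L3A:0.01,L7A:0.01)90:0.01,L4a:0.01)95:0.05,"
                    "((L3a:0.01,L7a:0.01)90:0.01,L4A:0.01)95:0.05);"
                )
            else:
                nwk = (
                    "(((L3A:0.01,L7A:0.01)90:0.01,L4A:0.01)95:0.05,"
                    "((L3a:0.01,L7a:0.01)90:0.01,L4a:0.01)95:0.05);"
                )
            trees[gene] = read_newick_supported(nwk, gene=gene)
        return ChromosomeLayout(genes, "g1", "g1"), trees

    def setup_method(self):
        self.manifest = make_manifest(["L3", "L4", "L7"])

    def test_affiliation_reads_the_host_clade(self):
        layout, trees = self._trees(swapped_from=2)
        aff = allele_affiliation(
            trees["g0"], "L4A", frozenset({"L4A", "L4a"}), self.manifest, THR
        )
        assert aff == "A"
        aff2 = allele_affiliation(
            trees["g2"], "L4A", frozenset({"L4A", "L4a"}), self.manifest, THR
        )
        assert aff2 == "a"

    def test_persistent_swap_is_placed_between_flanking_genes(self):
        layout, trees = self._trees(swapped_from=2)
        events = detect_crossovers(trees, self.manifest, layout, THR)
        assert [(e.pair_id, e.interval) for e in events] == [
            ("L4", ("g1", "g2"))
        ]

    def test_no_affiliation_changes_yields_nothing(self):
        layout, trees = self._trees(swapped_from=99)
        assert detect_crossovers(trees, self.manifest, layout, THR) == []

    def test_single_gene_blip_is_ignored(self):
        layout, trees = self._trees(swapped_from=2)
        # revert the swap from g3 on: only g2 is swapped
        _, unswapped = self._trees(swapped_from=99)
        trees["g3"] = unswapped["g3"]
        trees["g4"] = unswapped["g4"]
        assert detect_crossovers(trees, self.manifest, layout, THR,
                                 persistence=2) == []

    def test_terminal_swap_counts_as_persistent(self):
        layout, trees = self._trees(swapped_from=4)  # only the last gene
        events = detect_crossovers(trees, self.manifest, layout, THR,
                                   persistence=2)
        assert [(e.pair_id, e.interval) for e in events] == [
            ("L4", ("g3", "g4"))
        ]


class TestRates:
    def _events(self):
        ev_single = [
            ConversionEvent(g, frozenset({"L4"}), in_region=True)
            for g in ("cys-5", "arg-1", "lys-4", "ad-9")
        ]
        ser3 = [
            ConversionEvent("ser-3", frozenset({"L2"}), in_region=True),
            ConversionEvent("ser-3", frozenset({"L4"}), in_region=True),
            ConversionEvent("ser-3", frozenset({"L7"}), in_region=True),
            ConversionEvent(
                "ser-3", frozenset({"L3", "L8(1)", "L8(2)"}),
                ancestral=True, lineages=frozenset({"3", "8"}), in_region=True,
            ),
        ]
        outside = [ConversionEvent("phr", frozenset({"L1"}), in_region=False)]
        return ev_single + ser3 + outside

    def test_counting_conventions(self):
        events = self._events()
        per_event = count_events_per_gene(events, "per_event")
        per_pair = count_events_per_gene(events, "per_pair")
        assert per_event["ser-3"] == 4
        assert per_pair["ser-3"] == 6
        assert "phr" not in per_event  # outside the suppressed span
        assert count_events_per_gene(events, "per_event",
                                     inside_region_only=False)["phr"] == 1

    def test_rates_table_reproduces_published_style_rates(self):
        table = rates_table(self._events(), n_lineages=9, T=4.6).set_index("gene")
        assert table.loc["ser-3", "r_rounded"] == 0.048
        for gene in ("cys-5", "arg-1", "lys-4", "ad-9"):
            assert table.loc[gene, "r_rounded"] == 0.012

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValidationError):
            count_events_per_gene([], "per_gene")
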