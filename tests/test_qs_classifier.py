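"""Domain-architecture rules, pair/solo adjacency, and system summaries."""

import pytest

from qsmine.conservation import ConservationReport
from qsmine.genome_io import DomainHit, GeneFeature, GenomeRecord, KOAssignment, ProteinSeq, Replicon
from qsmine.qs_classifier import (
    ACCEPTED_WITH_FLAGS,
    CANONICAL,
    REJECTED,
    HomologCall,
    call_component_inventory,
    call_system_summary,
    classify_luxI_architecture,
    classify_luxR_architecture,
    dsf_tier,
    pair_or_solo,
    qse_ef_pairing,
)


def hit(pid, ns, dom, e=1e-20):
    return DomainHit(pid, ns, dom, 1, 180, e)


LUXI_FULL = [
    hit("P1", "Pfam", "PF00765", 1e-20),
    hit("P1", "InterPro", "IPR016181"),
    hit("P1", "InterPro", "IPR001690"),
    hit("P1", "InterPro", "IPR018311"),
]
LUXR_FULL = [
    hit("P2", "Pfam", "PF03472", 1e-20),
    hit("P2", "InterPro", "IPR005143"),
    hit("P2", "InterPro", "IPR036388"),
    hit("P2", "InterPro", "IPR016032"),
    hit("P2", "InterPro", "IPR000792"),
]


class TestLuxIArchitecture:
    def test_all_signature_domains_canonical(self):
        call = classify_luxI_architecture("P1", LUXI_FULL)
        assert call.status == CANONICAL and not call.flags

    def test_missing_conserved_site_accepted_with_flag(self):
        hits = [h for h in LUXI_FULL if h.domain_id != "IPR018311"]
        call = classify_luxI_architecture("P1", hits)
        assert call.status == ACCEPTED_WITH_FLAGS
        assert call.flags == {"missing_conserved_site"}

    def test_no_gate_hit_rejected(self):
        call = classify_luxI_architecture("P1", [hit("P1", "InterPro", "IPR001690")])
        assert call.status == REJECTED and "gate_failed" in call.flags

    def test_missing_required_domain_rejected(self):
        hits = [h for h in LUXI_FULL if h.domain_id != "IPR016181"]
        call = classify_luxI_architecture("P1", hits)
        assert call.status == REJECTED and "missing:IPR016181" in call.flags

    def test_purity_hit_order_irrelevant(self):
        a = classify_luxI_architecture("P1", LUXI_FULL)
        b = classify_luxI_architecture("P1", list(reversed(LUXI_FULL)))
        assert a == b

    def test_evidence_chain_retained(self):
        call = classify_luxI_architecture("P1", LUXI_FULL)
        assert sorted(h.domain_id for h in call.evidence) == sorted(
            h.domain_id for h in LUXI_FULL
        )

    def test_foreign_protein_hit_rejected_as_input_error(self):
        with pytest.raises(ValueError):
            classify_luxI_architecture("P9", LUXI_FULL)


class TestLuxRArchitecture:
    def test_four_domains_canonical(self):
        assert classify_luxR_architecture("P2", LUXR_FULL).status == CANONICAL

    def test_any_missing_domain_rejected_with_missing_set(self):
        hits = [h for h in LUXR_FULL if h.domain_id != "IPR005143"]
        call = classify_luxR_architecture("P2", hits)
        assert call.status == REJECTED and call.flags == {"missing:IPR005143"}

    @pytest.mark.parametrize(
        "e_value,expected",
        [(1e-3, REJECTED), (1e-5, REJECTED), (9.9e-6, CANONICAL)],
    )
    def test_gate_threshold_is_strict(self, e_value, expected):
        hits = [hit("P2", "Pfam", "PF03472", e_value)] + LUXR_FULL[1:]
        assert classify_luxR_architecture("P2", hits).status == expected


def genome_with(features, n_rep=1, rep_len=50000):
    proteins = {
        f.protein_id: ProteinSeq(f.protein_id, "MKT") for f in features if f.protein_id
    }
    return GenomeRecord(
        genome_id="G",
        replicons=[Replicon(f"rep{i+1}", rep_len) for i in range(n_rep)],
        features=features,
        proteins=proteins,
    )


def accepted(pid, role):
    return HomologCall(pid, role, CANONICAL)


class TestPairOrSolo:
    def test_adjacent_pair(self):
        g = genome_with([
            GeneFeature("fi", "rep1", 1000, 1600, "+", protein_id="pi"),
            GeneFeature("fr", "rep1", 1751, 2400, "-", protein_id="pr"),
        ])
        calls = pair_or_solo(g, [accepted("pi", "LuxI")], [accepted("pr", "LuxR")])
        assert len(calls) == 1
        assert calls[0].relation == "paired"
        assert calls[0].intergenic_gap == 150
        assert calls[0].intervening_genes == 0

    def test_lone_luxi_is_solo(self):
        g = genome_with([GeneFeature("fi", "rep1", 1000, 1600, "+", protein_id="pi")])
        calls = pair_or_solo(g, [accepted("pi", "LuxI")], [])
        assert [c.relation for c in calls] == ["luxI_solo"]

    def test_different_replicons_both_solo(self):
        g = genome_with(
            [
                GeneFeature("fi", "rep1", 1000, 1600, "+", protein_id="pi"),
                GeneFeature("fr", "rep2", 1000, 1600, "+", protein_id="pr"),
            ],
            n_rep=2,
        )
        calls = pair_or_solo(g, [accepted("pi", "LuxI")], [accepted("pr", "LuxR")])
        assert sorted(c.relation for c in calls) == ["luxI_solo", "luxR_solo"]

    def test_gap_and_intervening_thresholds(self):
        g = genome_with([
            GeneFeature("fi", "rep1", 1000, 1600, "+", protein_id="pi"),
            GeneFeature("fr", "rep1", 4001, 4600, "-", protein_id="pr"),
        ])
        calls = pair_or_solo(g, [accepted("pi", "LuxI")], [accepted("pr", "LuxR")],
                             max_gap=2000)
        assert sorted(c.relation for c in calls) == ["luxI_solo", "luxR_solo"]
        calls = pair_or_solo(g, [accepted("pi", "LuxI")], [accepted("pr", "LuxR")],
                             max_gap=2500)
        assert [c.relation for c in calls] == ["paired"]

    def test_greedy_matching_prefers_smaller_gap_each_feature_used_once(self):
        g = genome_with([
            GeneFeature("fi1", "rep1", 1000, 1600, "+", protein_id="pi1"),
            GeneFeature("fr1", "rep1", 1701, 2300, "+", protein_id="pr1"),
            GeneFeature("fi2", "rep1", 2421, 3020, "+", protein_id="pi2"),
        ])
        calls = pair_or_solo(
            g,
            [accepted("pi1", "LuxI"), accepted("pi2", "LuxI")],
            [accepted("pr1", "LuxR")],
        )
        paired = [c for c in calls if c.relation == "paired"]
        assert len(paired) == 1
        assert paired[0].luxI_feature.feature_id == "fi1"  # gap 100 beats gap 120
        assert sum(c.relation == "luxI_solo" for c in calls) == 1

    def test_rejected_calls_never_pair(self):
        g = genome_with([
            GeneFeature("fi", "rep1", 1000, 1600, "+", protein_id="pi"),
            GeneFeature("fr", "rep1", 1751, 2400, "-", protein_id="pr"),
        ])
        calls = pair_or_solo(
            g, [HomologCall("pi", "LuxI", REJECTED, {"gate_failed"})],
            [accepted("pr", "LuxR")],
        )
        assert [c.relation for c in calls] == ["luxR_solo"]


class TestComponentInventory:
    def test_two_qseef_pairs(self):
        kos = [KOAssignment(f"p{i}", k) for i, k in enumerate(
            ["K07711", "K07711", "K07715", "K07715"])]
        inv = call_component_inventory("g", kos)
        n_pairs, orphans = qse_ef_pairing(inv)
        assert n_pairs == 2 and orphans == []

    def test_qsef_without_kinase_is_orphan(self):
        inv = call_component_inventory("g", [KOAssignment("p1", "K07715")])
        n_pairs, orphans = qse_ef_pairing(inv)
        assert n_pairs == 0 and orphans == ["p1"]

    def test_multiplicity_preserved(self):
        kos = [KOAssignment("a", "K13075"), KOAssignment("b", "K13075")]
        inv = call_component_inventory("g", kos)
        assert inv.count("AhlD") == 2


class TestDsfTier:
    @pytest.mark.parametrize(
        "present,tier,missing",
        [
            ({"RpfF", "RpfC", "RpfG", "RpfB", "Clp"}, "full", []),
            ({"RpfF", "RpfC", "RpfG", "RpfB"}, "missing_clp", ["Clp"]),
            ({"RpfF", "RpfC", "RpfG"}, "core", ["RpfB", "Clp"]),
            ({"RpfC", "RpfG", "RpfB", "Clp"}, "partial", ["RpfF"]),
            (set(), "none", list(("RpfF", "RpfC", "RpfG", "RpfB", "Clp"))),
        ],
    )
    def test_tiers(self, present, tier, missing):
        assert dsf_tier(present) == (tier, missing)


class TestSystemSummary:
    def test_ahld_validity_downgraded_by_conservation_flags(self):
        inv = call_component_inventory(
            "g", [KOAssignment("pa", "K13075"), KOAssignment("pb", "K13075")]
        )
        bad = ConservationReport("pa", "AhlD", flags={"motif_absent", "truncated"})
        good = ConservationReport("pb", "AhlD")
        summary = call_system_summary(inv, [], {"pa": bad, "pb": good})
        assert summary.qq_ahlD_validity == {"pa": "questionable", "pb": "valid"}
        assert summary.qq_ahlD_count == 2

    def test_lsrb_only_flagged_doubtful(self):
        inv = call_component_inventory("g", [KOAssignment("p", "K10555")])
        assert call_system_summary(inv, []).ai2_lsrB_only

    def test_extras_annotations(self):
        inv = call_component_inventory(
            "g",
            [KOAssignment("p1", "K07666"), KOAssignment("p2", "K20334"),
             KOAssignment("p3", "K20249")],
        )
        summary = call_system_summary(inv, [])
        assert set(summary.extras) == {"QseB_only", "CviR", "RaiI"}
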