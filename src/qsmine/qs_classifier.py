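"""Identification rules for QS/QQ systems.

Two evidence tracks, mirroring how these systems are mined in practice:
LuxI/LuxR homologs are authenticated by signature domain architecture (a Pfam
HMM gate plus required InterPro domains), while all other components (QseE/F,
the DSF Rpf set, Clp, AhlD, LsrB, QseB, CviR) are inventoried from KO
assignments. Pair-versus-solo calls for LuxI/LuxR use operon-scale adjacency
on the same replicon, and the per-genome summary rolls everything up into one
system inventory (AI-1, AI-2, AI-3, DSF, QQ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .conservation import ConservationReport
from .genome_io import DomainHit, GeneFeature, GenomeRecord, KOAssignment
from .resources import load_role_catalog

#: Default significance gate for the Pfam HMM hits (strict "<").
PFAM_E_VALUE_GATE = 1e-5

#: Default adjacency thresholds for pair/solo calling.
DEFAULT_MAX_GAP_BP = 2000
DEFAULT_MAX_INTERVENING = 2

DSF_COMPONENTS = ("RpfF", "RpfC", "RpfG", "RpfB", "Clp")


@dataclass(frozen=True)
class ArchitectureRule:
    role: str
    required_domains: frozenset
    optional_domains: frozenset
    pfam_gate_id: str
    pfam_gate_e_value: float = PFAM_E_VALUE_GATE

    def __post_init__(self) -> None:
        if self.required_domains & self.optional_domains:
            raise ValueError("required and optional domain sets must be disjoint")


#: LuxI: acyl-CoA N-acyltransferase + autoinducer synthase domains are
#: mandatory; the autoinducer-synthesis conserved site may be absent in
#: functional homologs (e.g. RaiI) and only downgrades the call to
#: accepted-with-flags.
LUXI_RULE = ArchitectureRule(
    role="LuxI",
    required_domains=frozenset({"IPR016181", "IPR001690"}),
    optional_domains=frozenset({"IPR018311"}),
    pfam_gate_id="PF00765",
)

#: LuxR: all four signature domains (autoinducer binding, winged HTH,
#: response-regulator effector, LuxR C-terminal) are mandatory.
LUXR_RULE = ArchitectureRule(
    role="LuxR",
    required_domains=frozenset(
        {"IPR005143", "IPR036388", "IPR016032", "IPR000792"}
    ),
    optional_domains=frozenset(),
    pfam_gate_id="PF03472",
)

CANONICAL = "canonical"
ACCEPTED_WITH_FLAGS = "accepted_with_flags"
REJECTED = "rejected"


@dataclass
class HomologCall:
    protein_id: str
    role: str
    status: str
    flags: set[str] = field(default_factory=set)
    evidence: list[DomainHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status == CANONICAL and self.flags:
            raise ValueError("canonical calls must carry no flags")

    @property
    def accepted(self) -> bool:
        return self.status in (CANONICAL, ACCEPTED_WITH_FLAGS)

    def to_dict(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "role": self.role,
            "status": self.status,
            "flags": sorted(self.flags),
            "evidence": [
                [h.namespace, h.domain_id, h.hit_start, h.hit_end, h.e_value]
                for h in self.evidence
            ],
        }


def _classify_architecture(
    protein_id: str, hits: Iterable[DomainHit], rule: ArchitectureRule
) -> HomologCall:
    hits = sorted(hits, key=lambda h: (h.namespace, h.domain_id, h.hit_start, h.e_value))
    for h in hits:
        if h.protein_id != protein_id:
            raise ValueError(
                f"hit for {h.protein_id!r} passed while classifying {protein_id!r}"
            )
    gate_hits = [
        h
        for h in hits
        if h.namespace == "Pfam"
        and h.domain_id == rule.pfam_gate_id
        and h.e_value < rule.pfam_gate_e_value
    ]
    interpro = {h.domain_id for h in hits if h.namespace == "InterPro"}

    if not gate_hits:
        return HomologCall(protein_id, rule.role, REJECTED, {"gate_failed"}, list(hits))
    missing_required = rule.required_domains - interpro
    if missing_required:
        flags = {f"missing:{d}" for d in sorted(missing_required)}
        return HomologCall(protein_id, rule.role, REJECTED, flags, list(hits))
    missing_optional = rule.optional_domains - interpro
    if missing_optional:
        return HomologCall(
            protein_id, rule.role, ACCEPTED_WITH_FLAGS,
            {"missing_conserved_site"}, list(hits),
        )
    return HomologCall(protein_id, rule.role, CANONICAL, set(), list(hits))


def classify_luxI_architecture(
    protein_id: str, hits: Iterable[DomainHit], rule: ArchitectureRule = LUXI_RULE
) -> HomologCall:
    """Authenticate a LuxI candidate from its domain architecture.

    The Pfam autoinducer-synthase gate (E < 1e-5) is applied first; both
    required InterPro domains must be present. A candidate missing only the
    autoinducer-synthesis conserved site is accepted with the
    ``missing_conserved_site`` flag rather than rejected.
    """
    return _classify_architecture(protein_id, hits, rule)


def classify_luxR_architecture(
    protein_id: str, hits: Iterable[DomainHit], rule: ArchitectureRule = LUXR_RULE
) -> HomologCall:
    """Authenticate a LuxR candidate: gate plus all four signature domains."""
    return _classify_architecture(protein_id, hits, rule)


# --- Pair / solo calling -----------------------------------------------------


@dataclass
class PairCall:
    relation: str  # "paired", "luxI_solo", "luxR_solo"
    luxI_feature: GeneFeature | None = None
    luxR_feature: GeneFeature | None = None
    intergenic_gap: int | None = None
    intervening_genes: int | None = None

    def to_dict(self) -> dict:
        return {
            "relation": self.relation,
            "luxI_feature": self.luxI_feature.feature_id if self.luxI_feature else None,
            "luxR_feature": self.luxR_feature.feature_id if self.luxR_feature else None,
            "intergenic_gap": self.intergenic_gap,
            "intervening_genes": self.intervening_genes,
        }


def _intergenic_gap(a: GeneFeature, b: GeneFeature) -> int:
    left, right = (a, b) if a.start <= b.start else (b, a)
    return max(0, right.start - left.end - 1)


def _intervening_count(genome: GenomeRecord, a: GeneFeature, b: GeneFeature) -> int:
    left, right = (a, b) if a.start <= b.start else (b, a)
    return sum(
        1
        for f in genome.features_on(a.replicon_id)
        if f.feature_id not in (a.feature_id, b.feature_id)
        and f.start > left.end
        and f.end < right.start
    )


def pair_or_solo(
    genome: GenomeRecord,
    luxi_calls: Sequence[HomologCall],
    luxr_calls: Sequence[HomologCall],
    max_gap: int = DEFAULT_MAX_GAP_BP,
    max_intervening: int = DEFAULT_MAX_INTERVENING,
) -> list[PairCall]:
    """Pair accepted LuxI and LuxR homologs by operon-scale adjacency.

    Greedy nearest-neighbor matching on each replicon: candidate pairs must sit
    on the same replicon within ``max_gap`` bp and ``max_intervening`` genes;
    ties are broken by smaller gap, then lexicographic feature ids. Unmatched
    accepted homologs are reported as solos.
    """
    luxi_feats = [
        genome.feature_for_protein(c.protein_id) for c in luxi_calls if c.accepted
    ]
    luxr_feats = [
        genome.feature_for_protein(c.protein_id) for c in luxr_calls if c.accepted
    ]
    candidates = []
    for fi in luxi_feats:
        for fr in luxr_feats:
            if fi.replicon_id != fr.replicon_id:
                continue
            gap = _intergenic_gap(fi, fr)
            inter = _intervening_count(genome, fi, fr)
            if gap <= max_gap and inter <= max_intervening:
                candidates.append((gap, fi.feature_id, fr.feature_id, fi, fr, inter))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    used_i: set[str] = set()
    used_r: set[str] = set()
    calls: list[PairCall] = []
    for gap, fid_i, fid_r, fi, fr, inter in candidates:
        if fid_i in used_i or fid_r in used_r:
            continue
        used_i.add(fid_i)
        used_r.add(fid_r)
        calls.append(
            PairCall("paired", luxI_feature=fi, luxR_feature=fr,
                     intergenic_gap=gap, intervening_genes=inter)
        )
    for fi in sorted(luxi_feats, key=lambda f: f.feature_id):
        if fi.feature_id not in used_i:
            calls.append(PairCall("luxI_solo", luxI_feature=fi))
    for fr in sorted(luxr_feats, key=lambda f: f.feature_id):
        if fr.feature_id not in used_r:
            calls.append(PairCall("luxR_solo", luxR_feature=fr))
    return calls


# --- Component inventory and system summary ----------------------------------


@dataclass
class ComponentInventory:
    """Per-genome component sets from KO evidence, multiplicity preserved."""

    genome_id: str
    components: dict[str, list[str]]  # component role -> protein ids
    ko_by_protein: dict[str, str] = field(default_factory=dict)

    def count(self, role: str) -> int:
        return len(self.components.get(role, []))

    def proteins(self, role: str) -> list[str]:
        return list(self.components.get(role, []))

    def proteins_with_ko(self, ko_id: str) -> list[str]:
        return sorted(p for p, k in self.ko_by_protein.items() if k == ko_id)


def call_component_inventory(
    genome_id: str,
    ko_assignments: Iterable[KOAssignment],
    catalog=None,
) -> ComponentInventory:
    """Map KO assignments onto QS component roles via the packaged catalog.

    Every matching protein is retained (a genome may carry two AhlDs or two
    QseEF sets); KOs outside the catalog are ignored here — they belong to the
    KO inventory, not the system classifier.
    """
    catalog = catalog if catalog is not None else load_role_catalog()
    by_ko = {e.ko_id: e.component for e in catalog}
    components: dict[str, list[str]] = {}
    ko_by_protein: dict[str, str] = {}
    for a in sorted(ko_assignments, key=lambda a: a.protein_id):
        role = by_ko.get(a.ko_id)
        if role is not None:
            components.setdefault(role, []).append(a.protein_id)
            ko_by_protein[a.protein_id] = a.ko_id
    return ComponentInventory(
        genome_id=genome_id, components=components, ko_by_protein=ko_by_protein
    )


def qse_ef_pairing(inventory: ComponentInventory) -> tuple[int, list[str]]:
    """QseEF pairs are counted as min(#QseE, #QseF); leftovers are orphans."""
    qse_e = inventory.proteins("QseE")
    qse_f = inventory.proteins("QseF")
    n_pairs = min(len(qse_e), len(qse_f))
    orphans = qse_e[n_pairs:] + qse_f[n_pairs:]
    return n_pairs, orphans


def dsf_tier(present: set[str]) -> tuple[str, list[str]]:
    """Completeness tier of the DSF system from its present components.

    full: RpfF+RpfC+RpfG+RpfB+Clp; missing_clp: all but Clp (treated as a
    complete signaling circuit lacking only the downstream regulator);
    core: the RpfF/RpfC/RpfG circuit; partial: any non-empty remainder.
    """
    missing = [c for c in DSF_COMPONENTS if c not in present]
    core = {"RpfF", "RpfC", "RpfG"}
    if not missing:
        return "full", []
    if missing == ["Clp"]:
        return "missing_clp", missing
    if core <= present:
        return "core", missing
    if present & set(DSF_COMPONENTS):
        return "partial", missing
    return "none", missing


@dataclass
class SystemInventory:
    """Per-genome QS/QQ system summary (the cohort-overview object)."""

    genome_id: str
    ai1_status: str  # "pair", "solo_only", "none"
    ai1_pairs: int
    ai1_luxi_solos: list[str]
    ai1_luxr_solos: list[str]
    ai3_qseE: int
    ai3_qseF: int
    ai3_pairs: int
    ai3_orphans: list[str]
    dsf_tier: str
    dsf_missing: list[str]
    qq_ahlD_count: int
    qq_ahlD_validity: dict[str, str]  # protein_id -> "valid" / "questionable"
    ai2_lsrB_only: bool
    extras: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "ai1": {
                "status": self.ai1_status,
                "pairs": self.ai1_pairs,
                "luxI_solos": self.ai1_luxi_solos,
                "luxR_solos": self.ai1_luxr_solos,
            },
            "ai3": {
                "qseE": self.ai3_qseE,
                "qseF": self.ai3_qseF,
                "pairs": self.ai3_pairs,
                "orphans": self.ai3_orphans,
            },
            "dsf": {"tier": self.dsf_tier, "missing": self.dsf_missing},
            "qq_ahlD": {
                "count": self.qq_ahlD_count,
                "validity": self.qq_ahlD_validity,
            },
            "ai2_lsrB_only": self.ai2_lsrB_only,
            "extras": self.extras,
        }


def call_system_summary(
    inventory: ComponentInventory,
    pair_calls: Sequence[PairCall],
    conservation_reports: Mapping[str, ConservationReport] | None = None,
) -> SystemInventory:
    """Roll one genome's evidence into a system inventory.

    AhlD validity is downgraded to "questionable" when its conservation report
    carries a ``motif_absent`` or ``truncated`` flag.
    """
    conservation_reports = conservation_reports or {}

    pairs = [c for c in pair_calls if c.relation == "paired"]
    luxi_solos = [c.luxI_feature.feature_id for c in pair_calls if c.relation == "luxI_solo"]
    luxr_solos = [c.luxR_feature.feature_id for c in pair_calls if c.relation == "luxR_solo"]
    if pairs:
        ai1_status = "pair"
    elif luxi_solos or luxr_solos:
        ai1_status = "solo_only"
    else:
        ai1_status = "none"

    n_qse_pairs, qse_orphans = qse_ef_pairing(inventory)
    tier, missing = dsf_tier(
        {c for c in DSF_COMPONENTS if inventory.count(c) > 0}
    )

    ahld_proteins = inventory.proteins("AhlD")
    validity: dict[str, str] = {}
    for pid in ahld_proteins:
        report = conservation_reports.get(pid)
        if report is not None and report.flags & {"motif_absent", "truncated"}:
            validity[pid] = "questionable"
        else:
            validity[pid] = "valid"

    extras: list[str] = []
    if inventory.count("QseB") > 0 and inventory.count("QseE") == 0:
        extras.append("QseB_only")
    if inventory.proteins_with_ko("K20334"):
        extras.append("CviR")
    if inventory.proteins_with_ko("K20249"):
        extras.append("RaiI")

    return SystemInventory(
        genome_id=inventory.genome_id,
        ai1_status=ai1_status,
        ai1_pairs=len(pairs),
        ai1_luxi_solos=sorted(luxi_solos),
        ai1_luxr_solos=sorted(luxr_solos),
        ai3_qseE=inventory.count("QseE"),
        ai3_qseF=inventory.count("QseF"),
        ai3_pairs=n_qse_pairs,
        ai3_orphans=sorted(qse_orphans),
        dsf_tier=tier,
        dsf_missing=missing,
        qq_ahlD_count=len(ahld_proteins),
        qq_ahlD_validity=validity,
        ai2_lsrB_only=inventory.count("LsrB") > 0,
        extras=extras,
    )


def cohort_summary_frame(inventories: Sequence[SystemInventory]) -> pd.DataFrame:
    """Cohort-level genomes × systems table (one row per genome)."""
    rows = []
    for inv in inventories:
        rows.append(
            {
                "genome_id": inv.genome_id,
                "ai1": inv.ai1_status,
                "ai1_pairs": inv.ai1_pairs,
                "ai1_solos": len(inv.ai1_luxi_solos) + len(inv.ai1_luxr_solos),
                "ai3_qseEF_pairs": inv.ai3_pairs,
                "ai3_orphans": len(inv.ai3_orphans),
                "dsf_tier": inv.dsf_tier,
                "qq_ahlD": inv.qq_ahlD_count,
                "qq_ahlD_questionable": sum(
                    1 for v in inv.qq_ahlD_validity.values() if v == "questionable"
                ),
                "ai2_lsrB_only": inv.ai2_lsrB_only,
                "extras": ";".join(inv.extras),
            }
        )
    return pd.DataFrame(rows)
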