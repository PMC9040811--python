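"""Synthetic annotated genomes with planted QS/QQ cassettes and ground truth.

Two generators live here:

* :func:`simulate_family` — protein-family evolution on a fixed tree under a
  Poisson substitution process (per branch of length b, each site receives a
  Poisson(b) number of events, each replacing the residue uniformly among the
  other 19), with optional single-residue indels and a true homology (column)
  map. This is the substrate for alignment/distance/tree recovery tests.

* :func:`plant_genome` / :func:`make_cohort` — annotated genome bundles
  (protein FASTA + GFF3 + domain-hit TSV + KO TSV) with planted cassettes:
  AI-1 LuxI/LuxR pairs and solos, QseEF sets, DSF component sets, AhlD copies
  (valid, motif-broken, or truncated), LsrB, QseB, CviR, plus neutral filler
  genes and optional mobile-element neighbor genes. Every planted element is
  recorded in a machine-readable :class:`TruthLedger` so pipeline output can
  be compared against ground truth exactly.

Cassette protein sequences derive from the packaged synthetic reference
sequences that satisfy the conservation profiles; at zero divergence the
planted proteins match their profiles exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np

from .conservation import load_profiles
from .genome_io import (
    DomainHit,
    GeneFeature,
    GenomeRecord,
    KOAssignment,
    ProteinSeq,
    Replicon,
    write_domain_hits,
    write_genome_bundle,
    write_ko_assignments,
)
from .phylo import Msa
from .qs_classifier import DSF_COMPONENTS, dsf_tier

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# --- Family evolution --------------------------------------------------------


@dataclass(frozen=True)
class EvolutionSpec:
    root_seq: str
    tree_newick: str  # leaf names + branch lengths (expected substitutions/site)
    indel_rate: float = 0.0  # expected indel events per site per unit branch length
    seed: int = 0


@dataclass
class FamilySimulation:
    leaves: dict[str, str]
    #: per-leaf list of homology column ids, one per residue
    columns: dict[str, list[int]]
    #: master ordering of all homology columns ever created
    master_columns: list[int]
    true_distances: dict[tuple[str, str], float]

    def true_msa(self) -> Msa:
        ids = sorted(self.leaves)
        rows = []
        for leaf in ids:
            res = dict(zip(self.columns[leaf], self.leaves[leaf]))
            rows.append("".join(res.get(c, "-") for c in self.master_columns))
        # prune columns absent everywhere (all-gap)
        keep = [k for k in range(len(self.master_columns))
                if any(r[k] != "-" for r in rows)]
        rows = ["".join(r[k] for k in keep) for r in rows]
        return Msa(ids, rows)


def expected_p_distance(t: float) -> float:
    """Expected fraction of differing sites between two sequences separated by
    total path length t under the uniform-replacement Poisson process."""
    return (19.0 / 20.0) * (1.0 - np.exp(-20.0 * t / 19.0))


def _substitute(residue: str, rng: np.random.Generator) -> str:
    choices = AA20.replace(residue, "")
    return choices[rng.integers(0, len(choices))]


def simulate_family(spec: EvolutionSpec) -> FamilySimulation:
    """Evolve the root sequence down the tree; deterministic under the seed."""
    if set(spec.root_seq) - set(AA20):
        raise ValueError("root sequence must be over the 20-residue alphabet")
    tree = dendropy.Tree.get(data=spec.tree_newick, schema="newick")
    rng = np.random.default_rng(spec.seed)

    master: list[int] = list(range(len(spec.root_seq)))
    next_col = len(spec.root_seq)

    def evolve(residues: list[str], cols: list[int], t: float):
        nonlocal next_col
        residues = list(residues)
        cols = list(cols)
        if t > 0:
            counts = rng.poisson(t, size=len(residues))
            for idx in np.nonzero(counts)[0]:
                for _ in range(counts[idx]):
                    residues[idx] = _substitute(residues[idx], rng)
            if spec.indel_rate > 0:
                n_events = rng.poisson(spec.indel_rate * t * len(residues))
                for _ in range(n_events):
                    pos = int(rng.integers(0, len(residues)))
                    if rng.random() < 0.5 and len(residues) > 1:
                        del residues[pos]
                        del cols[pos]
                    else:
                        new_res = AA20[rng.integers(0, 20)]
                        new_id = next_col
                        next_col += 1
                        anchor = master.index(cols[pos - 1]) + 1 if pos > 0 else 0
                        master.insert(anchor, new_id)
                        residues.insert(pos, new_res)
                        cols.insert(pos, new_id)
        return residues, cols

    states: dict = {}
    root = tree.seed_node
    states[root] = (list(spec.root_seq), list(range(len(spec.root_seq))))
    leaves: dict[str, str] = {}
    columns: dict[str, list[int]] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            pass
        else:
            blen = node.edge.length or 0.0
            states[node] = evolve(*states[node.parent_node], blen)
        if node.is_leaf():
            name = node.taxon.label if node.taxon else str(id(node))
            residues, cols = states[node]
            leaves[name] = "".join(residues)
            columns[name] = list(cols)

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    names = sorted(leaves)
    true_distances = {
        (a, b): float(pdm.distance(taxa[a], taxa[b]))
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    return FamilySimulation(
        leaves=leaves, columns=columns, master_columns=master,
        true_distances=true_distances,
    )


# --- Planted genomes ---------------------------------------------------------


ROLE_KO = {
    "LuxI": "K13061",
    "LuxR": "K19666",
    "AhlD": "K13075",
    "RpfF": "K13816",
    "RpfC": "K10715",
    "RpfG": "K13815",
    "RpfB": "K01897",
    "Clp": "K10914",
    "QseE": "K07711",
    "QseF": "K07715",
    "LsrB": "K10555",
    "QseB": "K07666",
}

ROLE_PRODUCT = {
    "LuxI": "acyl-homoserine lactone synthase",
    "LuxR": "LuxR family transcriptional regulator",
    "AhlD": "N-acyl homoserine lactone hydrolase",
    "RpfF": "DSF synthase",
    "RpfC": "two-component sensor histidine kinase RpfC",
    "RpfG": "two-component response regulator RpfG",
    "RpfB": "long-chain acyl-CoA synthetase",
    "Clp": "CRP/FNR family transcriptional regulator",
    "QseE": "two-component sensor histidine kinase QseE",
    "QseF": "two-component response regulator QseF",
    "LsrB": "AI-2 transport system substrate-binding protein",
    "QseB": "two-component response regulator QseB",
}

# Deterministic seeds for the base sequences of roles without a packaged
# conservation profile.
_ROLE_SEEDS = {
    "RpfC": 211, "RpfG": 212, "Clp": 213, "QseE": 214, "QseF": 215,
    "LsrB": 216, "QseB": 217,
}

FILLER_PRODUCTS = (
    "hypothetical protein",
    "ATP synthase subunit",
    "30S ribosomal protein",
    "elongation factor Tu",
    "DNA polymerase III subunit",
    "molecular chaperone DnaK",
    "NADH dehydrogenase subunit",
)

LUXI_DOMAINS = ("IPR016181", "IPR001690", "IPR018311")
LUXR_DOMAINS = ("IPR005143", "IPR036388", "IPR016032", "IPR000792")


def role_base_sequence(role: str) -> str:
    """Base protein sequence for a component role.

    Roles with a packaged conservation profile use its synthetic reference;
    the rest get a deterministic random 250-mer.
    """
    profiles = load_profiles()
    by_role = {
        "LuxI": "luxi", "LuxR": "luxr", "AhlD": "ahld",
        "RpfF": "rpff", "RpfB": "rpfb",
    }
    if role in by_role:
        return profiles[by_role[role]].reference_seq
    rng = np.random.default_rng(_ROLE_SEEDS[role])
    return "".join(AA20[i] for i in rng.integers(0, 20, size=250))


def _diverge(seq: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence <= 0:
        return seq
    residues = list(seq)
    counts = rng.poisson(divergence, size=len(residues))
    for idx in np.nonzero(counts)[0]:
        for _ in range(counts[idx]):
            if residues[idx] in AA20:
                residues[idx] = _substitute(residues[idx], rng)
    return "".join(residues)


@dataclass(frozen=True)
class Cassette:
    """One planted QS/QQ element (or element set) on a replicon."""

    kind: str  # ai1_pair | luxi_solo | luxr_solo | ahld | dsf | qseef | lsrb | qseb | cvir
    gap_bp: int = 150  # intra-pair intergenic gap for ai1_pair
    luxi_missing_conserved_site: bool = False
    luxi_ko: str = "K13061"
    ahld_variant: str = "valid"  # valid | motif_broken | truncated
    dsf_components: tuple[str, ...] = DSF_COMPONENTS
    n_qse_e: int = 1
    n_qse_f: int = 1
    replicon: int = 0
    neighbor_product: str | None = None  # planted gene upstream of the cassette


@dataclass(frozen=True)
class GenomePlan:
    genome_id: str
    genus: str
    species: str = "sp."
    strain: str = ""
    cassettes: tuple[Cassette, ...] = ()
    n_replicons: int = 1
    circular: tuple[bool, ...] = (False,)
    n_filler: int = 4  # extra filler genes appended after the cassettes
    divergence: float = 0.0  # branch length from role base to this genome's copies
    extra_kos: tuple[str, ...] = ()  # neutral reference KOs planted on fillers


@dataclass(frozen=True)
class CohortSpec:
    genomes: tuple[GenomePlan, ...]
    seed: int = 0


@dataclass
class PlantedGenome:
    record: GenomeRecord
    domain_hits: list[DomainHit]
    ko_table: list[KOAssignment]
    truth: dict


@dataclass
class TruthLedger:
    per_genome: dict[str, dict] = field(default_factory=dict)
    genus_map: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"per_genome": self.per_genome, "genus_map": self.genus_map},
                indent=1,
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        data = json.loads(Path(path).read_text())
        return cls(per_genome=data["per_genome"], genus_map=data["genus_map"])


class _GenomeBuilder:
    """Sequential gene layout with enough spacing between cassettes that
    nothing pairs by accident (inter-cassette gaps exceed the adjacency
    threshold)."""

    INTER_CASSETTE_GAP = 1200
    N_SPACER_FILLERS = 2

    def __init__(self, plan: GenomePlan, rng: np.random.Generator):
        self.plan = plan
        self.rng = rng
        self.cursor = [1000] * plan.n_replicons
        self.features: list[GeneFeature] = []
        self.proteins: dict[str, ProteinSeq] = {}
        self.domain_hits: list[DomainHit] = []
        self.kos: list[KOAssignment] = []
        self.counter = 0

    def _new_ids(self) -> tuple[str, str, str]:
        self.counter += 1
        gid = self.plan.genome_id
        return (
            f"{gid}_G{self.counter:04d}",
            f"{gid}_P{self.counter:04d}",
            f"{gid}_{self.counter:04d}",
        )

    def add_gene(
        self,
        replicon_idx: int,
        protein_seq: str,
        product: str,
        gap_before: int,
        strand: str = "+",
        ko: str | None = None,
        domains: Iterable[tuple[str, str, float]] = (),
    ) -> tuple[GeneFeature, str]:
        feature_id, protein_id, locus = self._new_ids()
        start = self.cursor[replicon_idx] + gap_before
        end = start + 3 * len(protein_seq) + 2
        feat = GeneFeature(
            feature_id=feature_id,
            replicon_id=f"{self.plan.genome_id}_rep{replicon_idx + 1}",
            start=start,
            end=end,
            strand=strand,
            locus_tag=locus,
            product=product,
            protein_id=protein_id,
        )
        self.features.append(feat)
        self.proteins[protein_id] = ProteinSeq(protein_id, protein_seq)
        self.cursor[replicon_idx] = end
        if ko:
            self.kos.append(KOAssignment(protein_id, ko))
        for namespace, domain_id, e_value in domains:
            self.domain_hits.append(
                DomainHit(protein_id, namespace, domain_id, 1,
                          max(1, len(protein_seq) - 5), e_value)
            )
        return feat, protein_id

    def add_filler(self, replicon_idx: int, gap_before: int, ko: str | None = None):
        product = FILLER_PRODUCTS[self.counter % len(FILLER_PRODUCTS)]
        seq = "".join(AA20[i] for i in self.rng.integers(0, 20, size=150))
        return self.add_gene(replicon_idx, seq, product, gap_before, ko=ko)

    def space_out(self, replicon_idx: int):
        for _ in range(self.N_SPACER_FILLERS):
            self.add_filler(replicon_idx, self.INTER_CASSETTE_GAP)


def plant_genome(plan: GenomePlan, seed: int = 0) -> PlantedGenome:
    """Build one annotated genome bundle plus its truth entry."""
    if len(plan.circular) != plan.n_replicons:
        raise ValueError("need one circularity flag per replicon")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    builder = _GenomeBuilder(plan, rng)

    truth: dict = {
        "genome_id": plan.genome_id,
        "homolog_calls": {},
        "pair_relations": [],
        "conservation": {},
        "neighborhood_flags": [],
        "planted_kos": [],
    }
    ai1_pairs = 0
    luxi_solos: list[str] = []
    luxr_solos: list[str] = []
    n_qse_e = n_qse_f = 0
    dsf_present: set[str] = set()
    ahld_validity: dict[str, str] = {}
    lsrb = False
    qseb = False
    extras: list[str] = []
    accepted_feats: list[GeneFeature] = []
    keyword_feats: list[GeneFeature] = []

    def luxi_seq() -> str:
        return _diverge(role_base_sequence("LuxI"), plan.divergence, rng)

    def luxr_seq() -> str:
        return _diverge(role_base_sequence("LuxR"), plan.divergence, rng)

    def luxi_domains(missing_site: bool):
        doms = [("Pfam", "PF00765", 1e-30)]
        ids = LUXI_DOMAINS[:2] if missing_site else LUXI_DOMAINS
        doms += [("InterPro", d, 1e-20) for d in ids]
        return doms

    def luxr_domains():
        return [("Pfam", "PF03472", 1e-28)] + [
            ("InterPro", d, 1e-20) for d in LUXR_DOMAINS
        ]

    def plant_neighbor(cassette: Cassette, rep: int):
        if cassette.neighbor_product is None:
            return None
        seq = "".join(AA20[i] for i in rng.integers(0, 20, size=120))
        feat, _ = builder.add_gene(
            rep, seq, cassette.neighbor_product, gap_before=200
        )
        return feat

    for cassette in plan.cassettes:
        rep = cassette.replicon
        if rep >= plan.n_replicons:
            raise ValueError("cassette placed on a replicon outside the plan")
        neighbor_feat = plant_neighbor(cassette, rep)
        if neighbor_feat is not None:
            keyword_feats.append(neighbor_feat)

        if cassette.kind == "ai1_pair":
            fi, pi = builder.add_gene(
                rep, luxi_seq(), ROLE_PRODUCT["LuxI"], gap_before=200,
                ko=cassette.luxi_ko,
                domains=luxi_domains(cassette.luxi_missing_conserved_site),
            )
            fr, pr = builder.add_gene(
                rep, luxr_seq(), ROLE_PRODUCT["LuxR"],
                gap_before=cassette.gap_bp + 1, ko="K19666",
                domains=luxr_domains(),
            )
            ai1_pairs += 1
            truth["pair_relations"].append(
                {"relation": "paired", "luxI": fi.feature_id, "luxR": fr.feature_id}
            )
            truth["homolog_calls"][pi] = {
                "role": "LuxI",
                "status": "accepted_with_flags"
                if cassette.luxi_missing_conserved_site
                else "canonical",
                "flags": ["missing_conserved_site"]
                if cassette.luxi_missing_conserved_site
                else [],
            }
            truth["homolog_calls"][pr] = {"role": "LuxR", "status": "canonical", "flags": []}
            accepted_feats.extend([fi, fr])
        elif cassette.kind == "luxi_solo":
            fi, pi = builder.add_gene(
                rep, luxi_seq(), ROLE_PRODUCT["LuxI"], gap_before=200,
                ko=cassette.luxi_ko,
                domains=luxi_domains(cassette.luxi_missing_conserved_site),
            )
            luxi_solos.append(fi.feature_id)
            truth["pair_relations"].append(
                {"relation": "luxI_solo", "luxI": fi.feature_id, "luxR": None}
            )
            truth["homolog_calls"][pi] = {
                "role": "LuxI",
                "status": "accepted_with_flags"
                if cassette.luxi_missing_conserved_site
                else "canonical",
                "flags": ["missing_conserved_site"]
                if cassette.luxi_missing_conserved_site
                else [],
            }
            if cassette.luxi_ko == "K20249":
                extras.append("RaiI")
            accepted_feats.append(fi)
        elif cassette.kind in ("luxr_solo", "cvir"):
            ko = "K20334" if cassette.kind == "cvir" else "K19666"
            fr, pr = builder.add_gene(
                rep, luxr_seq(), ROLE_PRODUCT["LuxR"], gap_before=200,
                ko=ko, domains=luxr_domains(),
            )
            luxr_solos.append(fr.feature_id)
            accepted_feats.append(fr)
            truth["pair_relations"].append(
                {"relation": "luxR_solo", "luxI": None, "luxR": fr.feature_id}
            )
            truth["homolog_calls"][pr] = {"role": "LuxR", "status": "canonical", "flags": []}
            if cassette.kind == "cvir":
                extras.append("CviR")
        elif cassette.kind == "ahld":
            base = role_base_sequence("AhlD")
            if cassette.ahld_variant == "valid":
                seq = _diverge(base, plan.divergence, rng)
                flags: list[str] = []
                validity = "valid"
            elif cassette.ahld_variant == "motif_broken":
                seq = base[:200] + "A" + base[201:]  # knock out the distal D anchor
                flags = ["motif_absent"]
                validity = "questionable"
            elif cassette.ahld_variant == "truncated":
                seq = base[:130]  # ends inside the first spacer window
                flags = ["truncated"]
                validity = "questionable"
            else:
                raise ValueError(f"unknown AhlD variant {cassette.ahld_variant!r}")
            _, pid = builder.add_gene(
                rep, seq, ROLE_PRODUCT["AhlD"], gap_before=200, ko="K13075"
            )
            ahld_validity[pid] = validity
            truth["conservation"][pid] = {"flags": sorted(flags)}
        elif cassette.kind == "dsf":
            for comp in cassette.dsf_components:
                seq = _diverge(role_base_sequence(comp), plan.divergence, rng)
                builder.add_gene(
                    rep, seq, ROLE_PRODUCT[comp], gap_before=200, ko=ROLE_KO[comp]
                )
                dsf_present.add(comp)
        elif cassette.kind == "qseef":
            for _ in range(cassette.n_qse_e):
                seq = _diverge(role_base_sequence("QseE"), plan.divergence, rng)
                builder.add_gene(rep, seq, ROLE_PRODUCT["QseE"], 200, ko="K07711")
                n_qse_e += 1
            for _ in range(cassette.n_qse_f):
                seq = _diverge(role_base_sequence("QseF"), plan.divergence, rng)
                builder.add_gene(rep, seq, ROLE_PRODUCT["QseF"], 200, ko="K07715")
                n_qse_f += 1
        elif cassette.kind == "lsrb":
            seq = _diverge(role_base_sequence("LsrB"), plan.divergence, rng)
            builder.add_gene(rep, seq, ROLE_PRODUCT["LsrB"], 200, ko="K10555")
            lsrb = True
        elif cassette.kind == "qseb":
            seq = _diverge(role_base_sequence("QseB"), plan.divergence, rng)
            builder.add_gene(rep, seq, ROLE_PRODUCT["QseB"], 200, ko="K07666")
            qseb = True
        else:
            raise ValueError(f"unknown cassette kind {cassette.kind!r}")
        builder.space_out(rep)

    for i in range(plan.n_filler):
        ko = plan.extra_kos[i] if i < len(plan.extra_kos) else None
        builder.add_filler(i % plan.n_replicons, 500, ko=ko)
    for ko in plan.extra_kos[plan.n_filler:]:
        builder.add_filler(0, 500, ko=ko)

    replicons = [
        Replicon(
            f"{plan.genome_id}_rep{i + 1}",
            length=builder.cursor[i] + 1000,
            circular=plan.circular[i],
        )
        for i in range(plan.n_replicons)
    ]
    record = GenomeRecord(
        genome_id=plan.genome_id,
        genus=plan.genus,
        species=plan.species,
        strain=plan.strain,
        replicons=replicons,
        features=builder.features,
        proteins=builder.proteins,
    )

    if qseb and n_qse_e == 0:
        extras.append("QseB_only")
    tier, missing = dsf_tier(dsf_present)
    if ai1_pairs:
        ai1_status = "pair"
    elif luxi_solos or luxr_solos:
        ai1_status = "solo_only"
    else:
        ai1_status = "none"
    truth["system_inventory"] = {
        "genome_id": plan.genome_id,
        "ai1": {
            "status": ai1_status,
            "pairs": ai1_pairs,
            "luxI_solos": sorted(luxi_solos),
            "luxR_solos": sorted(luxr_solos),
        },
        "ai3": {
            "qseE": n_qse_e,
            "qseF": n_qse_f,
            "pairs": min(n_qse_e, n_qse_f),
            "orphans_count": abs(n_qse_e - n_qse_f),
        },
        "dsf": {"tier": tier, "missing": missing},
        "qq_ahlD": {
            "count": len(ahld_validity),
            "validity": dict(sorted(ahld_validity.items())),
        },
        "ai2_lsrB_only": lsrb,
        "extras": sorted(extras),
    }
    # Expected keyword flags, derived from the final layout: a planted keyword
    # gene is flagged from every accepted homolog whose default 5-kbp context
    # window reaches it (all planted genes are on the + strand).
    for focal in accepted_feats:
        lo, hi = focal.start - 5000, focal.end + 5000
        for kw in keyword_feats:
            if kw.replicon_id != focal.replicon_id:
                continue
            if kw.end < lo or kw.start > hi:
                continue
            side = "upstream" if kw.end < focal.start else "downstream"
            truth["neighborhood_flags"].append(
                {"focal": focal.feature_id, "feature": kw.feature_id, "side": side}
            )
    truth["neighborhood_flags"].sort(key=lambda d: (d["focal"], d["feature"]))
    truth["planted_kos"] = sorted(a.ko_id for a in builder.kos)
    return PlantedGenome(
        record=record,
        domain_hits=builder.domain_hits,
        ko_table=builder.kos,
        truth=truth,
    )


def make_cohort(spec: CohortSpec, out_dir: str | Path) -> TruthLedger:
    """Write a cohort directory; byte-identical for a fixed spec and seed.

    Layout: ``genomes/<id>/{proteins.faa,features.gff3,domain_hits.tsv,ko.tsv}``
    plus ``manifest.tsv`` and ``truth.json`` at the top level.
    """
    if not spec.genomes:
        raise ValueError("cohort needs at least one genome")
    ids = [g.genome_id for g in spec.genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids in cohort")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ledger = TruthLedger()
    manifest_rows = []
    for idx, plan in enumerate(spec.genomes):
        planted = plant_genome(plan, seed=(spec.seed * 100003 + idx) % (2**31))
        gdir = out_dir / "genomes" / plan.genome_id
        gdir.mkdir(parents=True, exist_ok=True)
        fasta = gdir / "proteins.faa"
        gff3 = gdir / "features.gff3"
        write_genome_bundle(planted.record, fasta, gff3)
        write_domain_hits(planted.domain_hits, gdir / "domain_hits.tsv")
        write_ko_assignments(planted.ko_table, gdir / "ko.tsv")
        ledger.per_genome[plan.genome_id] = planted.truth
        ledger.genus_map[plan.genome_id] = plan.genus
        manifest_rows.append(
            "\t".join(
                [
                    plan.genome_id,
                    plan.genus,
                    plan.species,
                    plan.strain,
                    f"genomes/{plan.genome_id}/proteins.faa",
                    f"genomes/{plan.genome_id}/features.gff3",
                    f"genomes/{plan.genome_id}/domain_hits.tsv",
                    f"genomes/{plan.genome_id}/ko.tsv",
                ]
            )
        )
    (out_dir / "manifest.tsv").write_text(
        "# genome_id\tgenus\tspecies\tstrain\tfasta\tgff3\tdomains\tkos\n"
        + "\n".join(manifest_rows)
        + "\n"
    )
    ledger.to_json(out_dir / "truth.json")
    return ledger


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """A 12-genome, 4-genus cohort exercising every call path.

    Planted conditions: AI-1 pairs and solos (including a conserved-site-less
    LuxI solo), two-copy QseEF sets and QseF orphans, DSF sets at every
    completeness tier, and valid / motif-broken / truncated AhlD copies.
    """
    g = [
        GenomePlan(
            "AFE01", "Acidithiobacillus", "ferrooxidans", "T1",
            cassettes=(
                Cassette("ai1_pair", neighbor_product="IS3 family transposase"),
                Cassette("qseef", n_qse_e=2, n_qse_f=2),
                Cassette("dsf"),
            ),
            extra_kos=("K03070",),
        ),
        GenomePlan(
            "ATH02", "Acidithiobacillus", "thiooxidans", "T2",
            cassettes=(
                Cassette("ai1_pair"),
                Cassette("qseef", n_qse_e=2, n_qse_f=3),
                Cassette("dsf", dsf_components=("RpfF", "RpfC", "RpfG", "RpfB")),
            ),
            extra_kos=("K03070",),
        ),
        GenomePlan(
            "ACA03", "Acidithiobacillus", "caldus", "T3",
            cassettes=(
                Cassette("qseef", n_qse_e=0, n_qse_f=1),
                Cassette("dsf", dsf_components=("RpfF", "RpfC", "RpfG")),
            ),
            extra_kos=("K03070",),
        ),
        GenomePlan(
            "AFV04", "Acidithiobacillus", "ferrivorans", "T4",
            cassettes=(
                Cassette("qseef"),
                Cassette("dsf"),
                Cassette("ahld"),
            ),
            extra_kos=("K03070",),
        ),
        GenomePlan(
            "LFO05", "Leptospirillum", "ferrooxidans", "C2-3-like",
            cassettes=(Cassette("cvir"), Cassette("dsf")),
            extra_kos=("K03070",),
        ),
        GenomePlan(
            "LFP06", "Leptospirillum", "ferriphilum", "T6",
            cassettes=(
                Cassette("dsf", dsf_components=("RpfC", "RpfG", "RpfB", "Clp")),
            ),
            extra_kos=("K03070",),
        ),
        GenomePlan(
            "SAC07", "Sulfobacillus", "acidophilus", "T7",
            cassettes=(Cassette("ahld"), Cassette("ahld"), Cassette("qseb")),
            extra_kos=("K03070", "K01580"),
        ),
        GenomePlan(
            "STH08", "Sulfobacillus", "thermosulfidooxidans", "T8",
            cassettes=(Cassette("ahld", ahld_variant="motif_broken"),),
            extra_kos=("K03070", "K01580"),
        ),
        GenomePlan(
            "ACP09", "Acidiphilium", "sp.", "37-67-22-like",
            cassettes=(
                Cassette("luxi_solo", luxi_missing_conserved_site=True,
                         luxi_ko="K20249"),
                Cassette("ahld", ahld_variant="truncated"),
            ),
            extra_kos=("K03070",),
        ),
        GenomePlan(
            "AAN10", "Acidiphilium", "angustum", "T10",
            cassettes=(Cassette("lsrb"),),
            extra_kos=("K03070",),
        ),
        GenomePlan(
            "ARU11", "Acidiphilium", "rubrum", "T11",
            cassettes=(Cassette("ahld"), Cassette("lsrb")),
            extra_kos=("K03070",),
        ),
        GenomePlan(
            "AFE12", "Acidithiobacillus", "ferrooxidans", "BY-3-like",
            cassettes=(
                Cassette("ai1_pair"),
                Cassette("luxi_solo", neighbor_product="transposase"),
            ),
            extra_kos=("K03070",),
        ),
    ]
    return CohortSpec(genomes=tuple(g), seed=seed)
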