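"""End-to-end orchestration: annotate -> trees -> neighborhoods -> report.

Each stage writes its outputs before any downstream stage reads them, so a run
can be restarted at stage granularity. All outputs are plain text (JSON / TSV /
FASTA / Newick) and byte-identical for a fixed config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import conservation as cons
from . import genome_io, ko_inventory, neighborhood, phylo, qs_classifier

STAGES = ("annotate", "tree", "neighborhood", "report")

#: Component families eligible for tree building (KO-evidence roles; LuxI and
#: LuxR members come from domain-architecture calls instead).
TREE_FAMILIES = (
    "LuxI", "LuxR", "QseE", "QseF", "RpfF", "RpfC", "RpfG", "RpfB", "Clp", "AhlD",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the genome and stage."""


@dataclass
class PipelineConfig:
    manifest: Path
    out_dir: Path
    max_gap: int = qs_classifier.DEFAULT_MAX_GAP_BP
    max_intervening: int = qs_classifier.DEFAULT_MAX_INTERVENING
    window_bp: int = neighborhood.DEFAULT_WINDOW_BP
    keywords: tuple[str, ...] = neighborhood.DEFAULT_KEYWORDS
    pfam_gate_e_value: float = qs_classifier.PFAM_E_VALUE_GATE
    bootstrap_replicates: int = 100
    seed: int = 0
    min_family_size: int = 4
    gap_open: float = cons.DEFAULT_GAP_OPEN
    gap_extend: float = cons.DEFAULT_GAP_EXTEND

    def __post_init__(self) -> None:
        self.manifest = Path(self.manifest)
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        if "keywords" in data:
            data["keywords"] = tuple(data["keywords"])
        return cls(**data)


@dataclass
class ManifestEntry:
    genome_id: str
    genus: str
    species: str
    strain: str
    fasta: Path
    gff3: Path
    domains: Path
    kos: Path


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    path = Path(path)
    base = path.parent
    entries: list[ManifestEntry] = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 8:
            raise PipelineError(f"manifest row needs 8 columns: {line!r}")
        entries.append(
            ManifestEntry(
                genome_id=cols[0], genus=cols[1], species=cols[2], strain=cols[3],
                fasta=base / cols[4], gff3=base / cols[5],
                domains=base / cols[6], kos=base / cols[7],
            )
        )
    if not entries:
        raise PipelineError(f"manifest {path} lists no genomes")
    ids = [e.genome_id for e in entries]
    if len(set(ids)) != len(ids):
        raise PipelineError("duplicate genome ids in manifest")
    return entries


def _load_bundle(entry: ManifestEntry):
    record = genome_io.read_genome_bundle(
        entry.fasta, entry.gff3,
        genome_id=entry.genome_id, genus=entry.genus,
        species=entry.species, strain=entry.strain,
    )
    hits = genome_io.read_domain_hits(entry.domains, e_value_threshold=1e-5)
    kos = genome_io.read_ko_assignments(entry.kos)
    return record, hits, kos


def _annotate_genome(entry: ManifestEntry, config: PipelineConfig) -> dict:
    record, hits, kos = _load_bundle(entry)
    by_protein = genome_io.hits_by_protein(hits)
    profiles = cons.load_profiles()

    luxi_calls = []
    luxr_calls = []
    for pid in sorted(by_protein):
        phits = by_protein[pid]
        if any(h.namespace == "Pfam" and h.domain_id == "PF00765" for h in phits):
            luxi_calls.append(qs_classifier.classify_luxI_architecture(pid, phits))
        if any(h.namespace == "Pfam" and h.domain_id == "PF03472" for h in phits):
            luxr_calls.append(qs_classifier.classify_luxR_architecture(pid, phits))

    reports: dict[str, cons.ConservationReport] = {}
    for call in luxi_calls:
        if call.accepted and call.protein_id in record.proteins:
            reports[call.protein_id] = cons.check_key_residues(
                call.protein_id, record.proteins[call.protein_id].residues,
                profiles["luxi"], gap_open=config.gap_open,
                gap_extend=config.gap_extend,
            )
    for call in luxr_calls:
        if call.accepted and call.protein_id in record.proteins:
            reports[call.protein_id] = cons.check_key_residues(
                call.protein_id, record.proteins[call.protein_id].residues,
                profiles["luxr"], gap_open=config.gap_open,
                gap_extend=config.gap_extend,
            )

    inventory = qs_classifier.call_component_inventory(entry.genome_id, kos)
    for pid in inventory.proteins("AhlD"):
        if pid in record.proteins:
            reports[pid] = cons.ahld_conservation_report(
                pid, record.proteins[pid].residues, profiles
            )
    for pid in inventory.proteins("RpfF"):
        if pid in record.proteins:
            reports[pid] = cons.check_key_residues(
                pid, record.proteins[pid].residues, profiles["rpff"]
            )

    pair_calls = qs_classifier.pair_or_solo(
        record, luxi_calls, luxr_calls,
        max_gap=config.max_gap, max_intervening=config.max_intervening,
    )
    inv = qs_classifier.call_system_summary(inventory, pair_calls, reports)

    accepted_features = sorted(
        {
            c.luxI_feature.feature_id
            for c in pair_calls
            if c.luxI_feature is not None
        }
        | {
            c.luxR_feature.feature_id
            for c in pair_calls
            if c.luxR_feature is not None
        }
    )
    return {
        "genome_id": entry.genome_id,
        "homolog_calls": {
            c.protein_id: c.to_dict() for c in luxi_calls + luxr_calls
        },
        "pair_calls": [c.to_dict() for c in pair_calls],
        "component_inventory": {
            role: pids for role, pids in sorted(inventory.components.items())
        },
        "ko_by_protein": dict(sorted(inventory.ko_by_protein.items())),
        "conservation": {pid: r.to_dict() for pid, r in sorted(reports.items())},
        "system_inventory": inv.to_dict(),
        "accepted_features": accepted_features,
    }


def _write_json(path: Path, payload) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def stage_annotate(config: PipelineConfig) -> None:
    for entry in read_manifest(config.manifest):
        try:
            annotations = _annotate_genome(entry, config)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise PipelineError(
                f"genome {entry.genome_id}, stage annotate: {exc}"
            ) from exc
        _write_json(
            config.out_dir / "genomes" / entry.genome_id / "annotations.json",
            annotations,
        )


def _read_annotations(config: PipelineConfig, genome_id: str) -> dict:
    path = config.out_dir / "genomes" / genome_id / "annotations.json"
    if not path.exists():
        raise PipelineError(
            f"genome {genome_id}, stage tree/neighborhood: run annotate first"
        )
    return json.loads(path.read_text())


def stage_tree(config: PipelineConfig) -> None:
    entries = read_manifest(config.manifest)
    families: dict[str, list[tuple[str, str]]] = {f: [] for f in TREE_FAMILIES}
    for entry in entries:
        ann = _read_annotations(config, entry.genome_id)
        record, _, _ = _load_bundle(entry)
        for pid, call in sorted(ann["homolog_calls"].items()):
            if call["status"] != "rejected" and pid in record.proteins:
                families[call["role"]].append(
                    (f"{entry.genome_id}|{pid}", record.proteins[pid].residues)
                )
        for role in TREE_FAMILIES:
            if role in ("LuxI", "LuxR"):
                continue
            for pid in ann["component_inventory"].get(role, []):
                if pid in record.proteins:
                    families[role].append(
                        (f"{entry.genome_id}|{pid}", record.proteins[pid].residues)
                    )

    tree_dir = config.out_dir / "trees"
    tree_dir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for role in TREE_FAMILIES:
        members = families[role]
        if len(members) < config.min_family_size:
            continue
        try:
            msa = phylo.progressive_msa(
                members, gap_open=config.gap_open, gap_extend=config.gap_extend
            )
            dres = phylo.build_distance_matrix(msa)
            dropped: list[str] = []
            if dres.has_failures:
                dropped = dres.failed_sequence_ids()
                msa = msa.drop(dropped)
                if msa.n_sequences < 3:
                    summary[role] = {"skipped": "too few sequences after drops",
                                     "dropped": dropped}
                    continue
                dres = phylo.build_distance_matrix(msa)
            boot = phylo.bootstrap_supports(
                msa, config.bootstrap_replicates, config.seed
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"family {role}, stage tree: {exc}") from exc
        phylo.write_fasta_msa(msa, tree_dir / f"{role}.aln.faa")
        phylo.write_phylip(dres, tree_dir / f"{role}.dist.phylip")
        phylo.write_newick(boot.tree, tree_dir / f"{role}.nwk")
        summary[role] = {
            "n_members": len(members),
            "dropped_no_common_sites": dropped,
            "bootstrap_replicates": boot.replicates,
            "bootstrap_failed": boot.failed_count,
            "bootstrap_successful": boot.successful,
        }
    _write_json(tree_dir / "summary.json", summary)


def stage_neighborhood(config: PipelineConfig) -> None:
    for entry in read_manifest(config.manifest):
        ann = _read_annotations(config, entry.genome_id)
        try:
            record, _, _ = _load_bundle(entry)
            maps = []
            for feature_id in ann["accepted_features"]:
                nmap = neighborhood.extract_context(
                    record, feature_id, window_bp=config.window_bp
                )
                nmap = neighborhood.flag_keywords(nmap, config.keywords)
                maps.append(nmap)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(
                f"genome {entry.genome_id}, stage neighborhood: {exc}"
            ) from exc
        out = config.out_dir / "neighborhoods"
        out.mkdir(parents=True, exist_ok=True)
        _write_json(
            out / f"{entry.genome_id}.json", [m.to_dict() for m in maps]
        )
        if maps:
            frames = [m.to_bed_frame() for m in maps]
            import pandas as pd

            pd.concat(frames, ignore_index=True).to_csv(
                out / f"{entry.genome_id}.bed.tsv", sep="\t", index=False
            )


def stage_report(config: PipelineConfig) -> None:
    entries = read_manifest(config.manifest)
    ko_tables = {}
    genus_map = {}
    inventories = []
    for entry in entries:
        ko_tables[entry.genome_id] = genome_io.read_ko_assignments(entry.kos)
        genus_map[entry.genome_id] = entry.genus
        ann = _read_annotations(config, entry.genome_id)
        inventories.append(ann["system_inventory"])

    report_dir = config.out_dir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)

    matrix = ko_inventory.presence_matrix(ko_tables)
    sharing = ko_inventory.genus_sharing(matrix, genus_map)
    _write_json(report_dir / "ko_sharing.json", sharing.to_dict())
    sharing.to_frame().to_csv(report_dir / "ko_sharing.tsv", sep="\t", index=False)
    matrix.data.astype(int).to_csv(report_dir / "ko_presence.tsv", sep="\t")

    rows = []
    for inv in inventories:
        rows.append(
            {
                "genome_id": inv["genome_id"],
                "ai1": inv["ai1"]["status"],
                "ai1_pairs": inv["ai1"]["pairs"],
                "ai1_solos": len(inv["ai1"]["luxI_solos"]) + len(inv["ai1"]["luxR_solos"]),
                "ai3_qseEF_pairs": inv["ai3"]["pairs"],
                "ai3_orphans": len(inv["ai3"]["orphans"]),
                "dsf_tier": inv["dsf"]["tier"],
                "qq_ahlD": inv["qq_ahlD"]["count"],
                "qq_ahlD_questionable": sum(
                    1 for v in inv["qq_ahlD"]["validity"].values()
                    if v == "questionable"
                ),
                "ai2_lsrB_only": inv["ai2_lsrB_only"],
                "extras": ";".join(inv["extras"]),
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(
        report_dir / "cohort_systems.tsv", sep="\t", index=False
    )

    log_lines = [
        "qsmine pipeline run log",
        f"manifest: {config.manifest.name}",
        f"genomes: {len(entries)}",
        f"pfam_gate_e_value: {config.pfam_gate_e_value}",
        f"max_gap_bp: {config.max_gap}",
        f"max_intervening_genes: {config.max_intervening}",
        f"neighborhood_window_bp: {config.window_bp}",
        f"keywords: {','.join(config.keywords)}",
        f"gap_open: {config.gap_open}",
        f"gap_extend: {config.gap_extend}",
        f"min_family_size: {config.min_family_size}",
        f"bootstrap_replicates: {config.bootstrap_replicates}",
        f"seed: {config.seed}",
    ]
    (report_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")


_STAGE_FUNCS = {
    "annotate": stage_annotate,
    "tree": stage_tree,
    "neighborhood": stage_neighborhood,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Run the requested stages in canonical order; returns a small summary."""
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
    for stage in STAGES:
        if stage in stages:
            _STAGE_FUNCS[stage](config)
    entries = read_manifest(config.manifest)
    return {
        "genomes": [e.genome_id for e in entries],
        "out_dir": str(config.out_dir),
        "stages": [s for s in STAGES if s in stages],
    }
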