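"""Scoring pipeline output against a synthetic cohort's truth ledger.

Builds comparable item sets (component roles and counts, pair/solo relations,
DSF tiers, AhlD validity and conservation flags, homolog-call statuses,
neighborhood keyword flags) from both the truth ledger and a pipeline output
directory, and reports precision/recall over them. On a zero-noise cohort with
complete evidence tables both should be exactly 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .synthetic_data import TruthLedger

_CONSERVATION_FLAGS = ("motif_absent", "truncated")


def _truth_items(ledger: TruthLedger) -> set[tuple]:
    items: set[tuple] = set()
    for gid, truth in ledger.per_genome.items():
        inv = truth["system_inventory"]
        items.add((gid, "ai1_status", inv["ai1"]["status"]))
        items.add((gid, "ai1_pairs", inv["ai1"]["pairs"]))
        for fid in inv["ai1"]["luxI_solos"]:
            items.add((gid, "luxI_solo", fid))
        for fid in inv["ai1"]["luxR_solos"]:
            items.add((gid, "luxR_solo", fid))
        items.add((gid, "qseE_count", inv["ai3"]["qseE"]))
        items.add((gid, "qseF_count", inv["ai3"]["qseF"]))
        items.add((gid, "qseEF_pairs", inv["ai3"]["pairs"]))
        items.add((gid, "qse_orphans", inv["ai3"]["orphans_count"]))
        items.add((gid, "dsf_tier", inv["dsf"]["tier"]))
        for comp in inv["dsf"]["missing"]:
            items.add((gid, "dsf_missing", comp))
        items.add((gid, "ahld_count", inv["qq_ahlD"]["count"]))
        for pid, validity in inv["qq_ahlD"]["validity"].items():
            items.add((gid, "ahld_validity", pid, validity))
        items.add((gid, "lsrB_only", inv["ai2_lsrB_only"]))
        for extra in inv["extras"]:
            items.add((gid, "extra", extra))
        for rel in truth["pair_relations"]:
            items.add((gid, "relation", rel["relation"], rel["luxI"], rel["luxR"]))
        for pid, call in truth["homolog_calls"].items():
            items.add(
                (gid, "homolog", pid, call["role"], call["status"],
                 tuple(sorted(call["flags"])))
            )
        for pid, cons in truth["conservation"].items():
            flags = tuple(sorted(set(cons["flags"]) & set(_CONSERVATION_FLAGS)))
            items.add((gid, "conservation", pid, flags))
        for nf in truth["neighborhood_flags"]:
            items.add((gid, "neighbor_flag", nf["focal"], nf["feature"], nf["side"]))
    return items


def _predicted_items(out_dir: Path, ledger: TruthLedger) -> set[tuple]:
    items: set[tuple] = set()
    for gid, truth in ledger.per_genome.items():
        ann = json.loads((out_dir / "genomes" / gid / "annotations.json").read_text())
        inv = ann["system_inventory"]
        items.add((gid, "ai1_status", inv["ai1"]["status"]))
        items.add((gid, "ai1_pairs", inv["ai1"]["pairs"]))
        for fid in inv["ai1"]["luxI_solos"]:
            items.add((gid, "luxI_solo", fid))
        for fid in inv["ai1"]["luxR_solos"]:
            items.add((gid, "luxR_solo", fid))
        items.add((gid, "qseE_count", inv["ai3"]["qseE"]))
        items.add((gid, "qseF_count", inv["ai3"]["qseF"]))
        items.add((gid, "qseEF_pairs", inv["ai3"]["pairs"]))
        items.add((gid, "qse_orphans", len(inv["ai3"]["orphans"])))
        items.add((gid, "dsf_tier", inv["dsf"]["tier"]))
        for comp in inv["dsf"]["missing"]:
            items.add((gid, "dsf_missing", comp))
        items.add((gid, "ahld_count", inv["qq_ahlD"]["count"]))
        for pid, validity in inv["qq_ahlD"]["validity"].items():
            items.add((gid, "ahld_validity", pid, validity))
        items.add((gid, "lsrB_only", inv["ai2_lsrB_only"]))
        for extra in inv["extras"]:
            items.add((gid, "extra", extra))
        for rel in ann["pair_calls"]:
            items.add(
                (gid, "relation", rel["relation"], rel["luxI_feature"],
                 rel["luxR_feature"])
            )
        for pid, call in ann["homolog_calls"].items():
            items.add(
                (gid, "homolog", pid, call["role"], call["status"],
                 tuple(sorted(call["flags"])))
            )
        # conservation flags only for the proteins the truth has expectations on
        for pid in truth["conservation"]:
            report = ann["conservation"].get(pid, {"flags": []})
            flags = tuple(sorted(set(report["flags"]) & set(_CONSERVATION_FLAGS)))
            items.add((gid, "conservation", pid, flags))
        npath = out_dir / "neighborhoods" / f"{gid}.json"
        if npath.exists():
            for nmap in json.loads(npath.read_text()):
                for fl in nmap["flags"]:
                    items.add(
                        (gid, "neighbor_flag", nmap["focal"], fl["feature_id"],
                         fl["side"])
                    )
    return items


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    n_truth_items: int
    n_predicted_items: int
    missed: list[tuple]
    spurious: list[tuple]


def compare_to_truth(out_dir: str | Path, ledger: TruthLedger) -> RecoveryScore:
    """Precision/recall of pipeline output items against the truth ledger."""
    truth = _truth_items(ledger)
    predicted = _predicted_items(Path(out_dir), ledger)
    hit = truth & predicted
    return RecoveryScore(
        precision=len(hit) / len(predicted) if predicted else 0.0,
        recall=len(hit) / len(truth) if truth else 0.0,
        n_truth_items=len(truth),
        n_predicted_items=len(predicted),
        missed=sorted(truth - predicted),
        spurious=sorted(predicted - truth),
    )
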