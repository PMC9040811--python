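"""KO-based quorum-sensing inventory: presence/absence and genus-level sharing.

Maps per-protein KEGG Orthology assignments onto the packaged 77-entry QS
pathway reference, builds a genome × KO boolean presence matrix, and computes
genus-level Venn-style sharing (which KOs are found in every genus, which are
genus-exclusive, and every region in between).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .genome_io import KOAssignment
from .resources import KOReferenceEntry, load_ko_reference

logger = logging.getLogger(__name__)


@dataclass
class PresenceMatrix:
    """Boolean genome × KO matrix over the packaged reference KO set."""

    data: pd.DataFrame
    ignored_counts: dict[str, int] = field(default_factory=dict)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def ko_ids(self) -> list[str]:
        return list(self.data.columns)

    def kos_present(self, genome_id: str) -> set[str]:
        row = self.data.loc[genome_id]
        return set(row.index[row])


def presence_matrix(
    ko_tables: Mapping[str, Iterable[KOAssignment]],
    reference: list[KOReferenceEntry] | None = None,
) -> PresenceMatrix:
    """Build the presence matrix from per-genome KO assignment tables.

    A cell (genome, KO) is true iff at least one protein of that genome is
    assigned that KO and the KO belongs to the reference. Assignments outside
    the reference are ignored with a logged per-genome count, never an error.
    """
    reference = reference if reference is not None else load_ko_reference()
    ref_ids = [e.ko_id for e in reference]
    ref_set = set(ref_ids)
    rows = {}
    ignored: dict[str, int] = {}
    for genome_id, table in ko_tables.items():
        if genome_id in rows:
            raise ValueError(f"duplicate genome_id {genome_id!r}")
        present = set()
        n_ignored = 0
        for a in table:
            if a.ko_id in ref_set:
                present.add(a.ko_id)
            else:
                n_ignored += 1
        rows[genome_id] = [k in present for k in ref_ids]
        ignored[genome_id] = n_ignored
        if n_ignored:
            logger.info(
                "genome %s: %d KO assignments outside the reference ignored",
                genome_id,
                n_ignored,
            )
    data = pd.DataFrame.from_dict(rows, orient="index", columns=ref_ids)
    return PresenceMatrix(data=data.astype(bool), ignored_counts=ignored)


def shared_percentage(shared_count: int, reference_size: int = 77) -> tuple[float, int]:
    """Percentage of the KO reference shared, as (one-decimal pct, nearest int)."""
    pct = shared_count / reference_size * 100.0
    return round(pct, 1), round(pct)


@dataclass
class SharingReport:
    """Genus-level KO sharing: Venn regions over genera plus summary counts."""

    genera: list[str]
    #: Venn region -> KO ids: keys are frozensets of genus names; the value is
    #: the set of KOs present in >=1 genome of every genus in the key and in
    #: no genome of any genus outside it.
    regions: dict[frozenset, set[str]]
    per_genus_totals: dict[str, int]
    all_shared_count: int
    all_shared_pct: float
    all_shared_pct_rounded: int
    reference_size: int

    def region_count(self, genera: Iterable[str]) -> int:
        return len(self.regions.get(frozenset(genera), set()))

    def to_dict(self) -> dict:
        return {
            "genera": self.genera,
            "regions": {
                "+".join(sorted(k)): sorted(v) for k, v in self.regions.items()
            },
            "per_genus_totals": self.per_genus_totals,
            "all_shared_count": self.all_shared_count,
            "all_shared_pct": self.all_shared_pct,
            "all_shared_pct_rounded": self.all_shared_pct_rounded,
            "reference_size": self.reference_size,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "+".join(sorted(k)), "n_kos": len(v), "kos": ",".join(sorted(v))}
            for k, v in sorted(self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        return pd.DataFrame(rows, columns=["region", "n_kos", "kos"])


def genus_sharing(
    matrix: PresenceMatrix, genome_to_genus: Mapping[str, str]
) -> SharingReport:
    """Venn-style sharing of reference KOs between genera (strains pooled).

    A KO counts for a genus when any genome of that genus carries it. Every
    non-empty genus subset S gets a region holding the KOs present in all
    genera of S and absent from all other genera; the regions partition the
    observed KOs.
    """
    missing = [g for g in matrix.genome_ids if g not in genome_to_genus]
    if missing:
        raise KeyError(f"genomes missing from the genus map: {missing}")
    genera = sorted({genome_to_genus[g] for g in matrix.genome_ids})
    if not genera:
        raise ValueError("at least one genus required")

    genus_kos: dict[str, set[str]] = {g: set() for g in genera}
    for genome_id in matrix.genome_ids:
        genus_kos[genome_to_genus[genome_id]] |= matrix.kos_present(genome_id)

    regions: dict[frozenset, set[str]] = {}
    for r in range(1, len(genera) + 1):
        for subset in itertools.combinations(genera, r):
            inside = set.intersection(*(genus_kos[g] for g in subset))
            for other in genera:
                if other not in subset:
                    inside -= genus_kos[other]
            regions[frozenset(subset)] = inside

    all_region = regions[frozenset(genera)]
    pct, pct_rounded = shared_percentage(len(all_region), len(matrix.ko_ids))
    return SharingReport(
        genera=genera,
        regions=regions,
        per_genus_totals={g: len(genus_kos[g]) for g in genera},
        all_shared_count=len(all_region),
        all_shared_pct=pct,
        all_shared_pct_rounded=pct_rounded,
        reference_size=len(matrix.ko_ids),
    )
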