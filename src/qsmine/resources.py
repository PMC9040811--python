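"""Loaders for the packaged reference resources (TSV/YAML under ``resources/``)."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _importlib_resources

import pandas as pd
import yaml


class ResourceIntegrityError(RuntimeError):
    """A packaged resource fails its integrity contract."""


def _resource_path(name: str):
    return _importlib_resources.files("qsmine").joinpath("resources", name)


def _read_tsv(name: str, columns: list[str]) -> pd.DataFrame:
    with _importlib_resources.as_file(_resource_path(name)) as path:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=columns, dtype=str
        )
    return df.fillna("")


@dataclass(frozen=True)
class KOReferenceEntry:
    ko_id: str
    protein_name: str
    cog_ids: tuple[str, ...]
    definition: str


def load_ko_reference() -> list[KOReferenceEntry]:
    """The packaged 77-entry reference of quorum-sensing pathway KOs (ko02024)."""
    df = _read_tsv("ko_reference.tsv", ["ko_id", "protein_name", "cog_ids", "definition"])
    entries = [
        KOReferenceEntry(
            ko_id=row.ko_id,
            protein_name=row.protein_name,
            cog_ids=tuple(c for c in row.cog_ids.split(",") if c),
            definition=row.definition,
        )
        for row in df.itertuples()
    ]
    if len(entries) != 77:
        raise ResourceIntegrityError(
            f"KO reference must hold 77 entries, found {len(entries)}"
        )
    ids = [e.ko_id for e in entries]
    if len(set(ids)) != len(ids):
        raise ResourceIntegrityError("KO reference contains duplicate ko_ids")
    if any(not e.definition for e in entries):
        raise ResourceIntegrityError("KO reference contains empty definitions")
    return entries


def ko_reference_lookup(ko_id: str) -> KOReferenceEntry | None:
    """Single-entry lookup; returns None when the KO is outside the reference."""
    for entry in load_ko_reference():
        if entry.ko_id == ko_id:
            return entry
    return None


@dataclass(frozen=True)
class RoleCatalogEntry:
    ko_id: str
    component: str
    system: str


def load_role_catalog() -> list[RoleCatalogEntry]:
    """KO → QS/QQ component-role catalog (LuxI/LuxR, QseE/F, Rpf set, AhlD...)."""
    df = _read_tsv("qs_role_catalog.tsv", ["ko_id", "component", "system"])
    return [RoleCatalogEntry(r.ko_id, r.component, r.system) for r in df.itertuples()]


def load_strain_census() -> dict[str, int]:
    """Genome counts per genus for the acidophile study cohort."""
    df = _read_tsv("strain_census.tsv", ["genus", "n_genomes"])
    return {r.genus: int(r.n_genomes) for r in df.itertuples()}


def load_profiles_yaml() -> dict:
    """Raw parse of the packaged conservation profiles/motifs resource."""
    with _importlib_resources.as_file(
        _resource_path("conservation_profiles.yaml")
    ) as path:
        data = yaml.safe_load(path.read_text())
    if "profiles" not in data or "motifs" not in data:
        raise ResourceIntegrityError("conservation_profiles.yaml missing sections")
    return data
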