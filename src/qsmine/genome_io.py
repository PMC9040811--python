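"""Genome bundles: annotated replicons, protein sequences, and evidence tables.

A *genome bundle* is the on-disk unit the pipeline consumes for one genome:
a protein FASTA, a GFF3 file with gene coordinates, and two evidence tables
(domain hits and KO assignments) produced upstream by domain/orthology
annotation. GFF3 is the single coordinate authority (1-based, inclusive);
FASTA headers carry only the protein identifier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable
from urllib.parse import quote, unquote

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguous residue; accepted everywhere, mismatches every expected residue.
AMBIGUOUS = "X"
_VALID_RESIDUES = AMINO_ACIDS | {AMBIGUOUS}

KO_PATTERN = re.compile(r"^K\d{5}$")

DOMAIN_HIT_COLUMNS = ("protein_id", "namespace", "domain_id", "start", "end", "e_value")


class MalformedInputError(ValueError):
    """Raised when an input file violates the bundle contract."""


@dataclass(frozen=True)
class Replicon:
    replicon_id: str
    length: int
    circular: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise MalformedInputError(
                f"replicon {self.replicon_id!r}: length must be > 0, got {self.length}"
            )


@dataclass(frozen=True)
class GeneFeature:
    """A protein-coding gene on a replicon, 1-based inclusive coordinates."""

    feature_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    locus_tag: str = ""
    product: str = ""
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise MalformedInputError(
                f"feature {self.feature_id!r}: require 1 <= start <= end, "
                f"got start={self.start}, end={self.end}"
            )
        if self.strand not in ("+", "-"):
            raise MalformedInputError(
                f"feature {self.feature_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinSeq:
    protein_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise MalformedInputError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise MalformedInputError(
                f"protein {self.protein_id!r}: invalid residues {sorted(bad)} "
                "(uppercase 20-letter alphabet plus X required)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainHit:
    """One row of an InterProScan-style domain-hit table."""

    protein_id: str
    namespace: str
    domain_id: str
    hit_start: int
    hit_end: int
    e_value: float
    flagged: bool = False  # True when e_value exceeded the caller's threshold

    def __post_init__(self) -> None:
        if self.hit_start > self.hit_end:
            raise MalformedInputError(
                f"domain hit {self.domain_id} on {self.protein_id}: start > end"
            )
        if self.e_value < 0:
            raise MalformedInputError(
                f"domain hit {self.domain_id} on {self.protein_id}: negative e-value"
            )


@dataclass(frozen=True)
class KOAssignment:
    protein_id: str
    ko_id: str

    def __post_init__(self) -> None:
        if not KO_PATTERN.match(self.ko_id):
            raise MalformedInputError(
                f"protein {self.protein_id!r}: malformed KO id {self.ko_id!r}"
            )


@dataclass
class GenomeRecord:
    """An annotated genome: replicons, gene features, protein sequences."""

    genome_id: str
    genus: str = ""
    species: str = ""
    strain: str = ""
    replicons: list[Replicon] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)
    proteins: dict[str, ProteinSeq] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_id = {r.replicon_id: r for r in self.replicons}
        if len(by_id) != len(self.replicons):
            raise MalformedInputError(f"{self.genome_id}: duplicate replicon ids")
        seen: set[str] = set()
        for f in self.features:
            if f.feature_id in seen:
                raise MalformedInputError(
                    f"{self.genome_id}: duplicate feature_id {f.feature_id!r}"
                )
            seen.add(f.feature_id)
            rep = by_id.get(f.replicon_id)
            if rep is None:
                raise MalformedInputError(
                    f"{self.genome_id}: feature {f.feature_id!r} references "
                    f"unknown replicon {f.replicon_id!r}"
                )
            if f.end > rep.length:
                raise MalformedInputError(
                    f"{self.genome_id}: feature {f.feature_id!r} end {f.end} "
                    f"exceeds replicon length {rep.length}"
                )

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r
        raise KeyError(replicon_id)

    def feature(self, feature_id: str) -> GeneFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def feature_for_protein(self, protein_id: str) -> GeneFeature:
        for f in self.features:
            if f.protein_id == protein_id:
                return f
        raise KeyError(protein_id)

    def features_on(self, replicon_id: str) -> list[GeneFeature]:
        return sorted(
            (f for f in self.features if f.replicon_id == replicon_id),
            key=lambda f: (f.start, f.end, f.feature_id),
        )


# --- GFF3 ------------------------------------------------------------------

_ATTR_SAFE = "".join(
    c for c in map(chr, range(33, 127)) if c not in "%;=&,\t"
)


def _encode_attr(value: str) -> str:
    return quote(value, safe=_ATTR_SAFE + " ")


def _parse_attrs(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise MalformedInputError(f"malformed GFF3 attribute {part!r}")
        key, _, val = part.partition("=")
        attrs[key] = unquote(val)
    return attrs


def read_genome_bundle(
    fasta_path: str | Path,
    gff3_path: str | Path,
    *,
    genome_id: str | None = None,
    genus: str | None = None,
    species: str | None = None,
    strain: str | None = None,
) -> GenomeRecord:
    """Read a protein FASTA + GFF3 pair into a :class:`GenomeRecord`.

    The GFF3 file must open with a ``##gff-version 3`` directive and declare
    every replicon with a ``##sequence-region`` directive. Genome metadata is
    taken from ``#!genome-id`` / ``#!genus`` / ``#!species`` / ``#!strain``
    pragmas; keyword arguments override the pragmas. Circular replicons are
    declared with ``region`` feature rows carrying ``Is_circular=true``.
    """
    gff3_path = Path(gff3_path)
    lines = gff3_path.read_text().splitlines()
    if not lines or not lines[0].startswith("##gff-version 3"):
        raise MalformedInputError(f"{gff3_path}: missing '##gff-version 3' directive")

    meta = {"genome-id": None, "genus": "", "species": "", "strain": ""}
    replicons: dict[str, dict] = {}
    features: list[GeneFeature] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line.startswith("#!"):
            key, _, val = line[2:].partition(" ")
            if key in meta:
                meta[key] = val.strip()
            continue
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) != 4:
                raise MalformedInputError(f"{gff3_path}:{lineno}: bad sequence-region")
            replicons[parts[1]] = {"length": int(parts[3]), "circular": False}
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise MalformedInputError(f"{gff3_path}:{lineno}: expected 9 columns")
        seqid, _source, ftype, start, end, _score, strand, _phase, attr_text = cols
        attrs = _parse_attrs(attr_text)
        if ftype == "region":
            if seqid in replicons and attrs.get("Is_circular", "").lower() == "true":
                replicons[seqid]["circular"] = True
            continue
        if ftype not in ("gene", "CDS"):
            continue
        if ftype == "gene":
            # CDS rows carry the coordinates and attributes we use; bare gene
            # rows (no CDS child in this bundle convention) are skipped.
            continue
        features.append(
            GeneFeature(
                feature_id=attrs.get("ID", f"feature_{lineno}"),
                replicon_id=seqid,
                start=int(start),
                end=int(end),
                strand=strand,
                locus_tag=attrs.get("locus_tag", ""),
                product=attrs.get("product", ""),
                protein_id=attrs.get("protein_id") or None,
            )
        )

    proteins: dict[str, ProteinSeq] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in proteins:
            raise MalformedInputError(f"{fasta_path}: duplicate protein id {rec.id!r}")
        proteins[rec.id] = ProteinSeq(rec.id, str(rec.seq).upper())

    record = GenomeRecord(
        genome_id=genome_id or meta["genome-id"] or gff3_path.stem,
        genus=genus if genus is not None else meta["genus"],
        species=species if species is not None else meta["species"],
        strain=strain if strain is not None else meta["strain"],
        replicons=[
            Replicon(rid, spec["length"], spec["circular"])
            for rid, spec in replicons.items()
        ],
        features=features,
        proteins=proteins,
    )
    for feat in record.features:
        if feat.protein_id is not None and feat.protein_id not in proteins:
            raise MalformedInputError(
                f"{record.genome_id}: feature {feat.feature_id!r} references "
                f"protein {feat.protein_id!r} absent from the FASTA"
            )
    return record


def write_genome_bundle(
    record: GenomeRecord, fasta_path: str | Path, gff3_path: str | Path
) -> None:
    """Write ``record`` as a protein FASTA + GFF3 pair (inverse of the reader)."""
    out = ["##gff-version 3"]
    out.append(f"#!genome-id {record.genome_id}")
    for key in ("genus", "species", "strain"):
        val = getattr(record, key)
        if val:
            out.append(f"#!{key} {val}")
    for rep in record.replicons:
        out.append(f"##sequence-region {rep.replicon_id} 1 {rep.length}")
    for rep in record.replicons:
        circ = "true" if rep.circular else "false"
        out.append(
            "\t".join(
                [
                    rep.replicon_id,
                    "qsmine",
                    "region",
                    "1",
                    str(rep.length),
                    ".",
                    "+",
                    ".",
                    f"ID=region_{rep.replicon_id};Is_circular={circ}",
                ]
            )
        )
    for f in record.features:
        attrs = [f"ID={_encode_attr(f.feature_id)}"]
        if f.locus_tag:
            attrs.append(f"locus_tag={_encode_attr(f.locus_tag)}")
        if f.product:
            attrs.append(f"product={_encode_attr(f.product)}")
        if f.protein_id:
            attrs.append(f"protein_id={_encode_attr(f.protein_id)}")
        out.append(
            "\t".join(
                [
                    f.replicon_id,
                    "qsmine",
                    "CDS",
                    str(f.start),
                    str(f.end),
                    ".",
                    f.strand,
                    "0",
                    ";".join(attrs),
                ]
            )
        )
    Path(gff3_path).write_text("\n".join(out) + "\n")

    seqs = [
        SeqRecord(Seq(p.residues), id=p.protein_id, description="")
        for p in record.proteins.values()
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


# --- Evidence tables -------------------------------------------------------


def read_domain_hits(
    tsv_path: str | Path, e_value_threshold: float | None = None
) -> list[DomainHit]:
    """Read a domain-hit TSV.

    Rows whose e-value exceeds ``e_value_threshold`` are retained but marked
    ``flagged=True`` — nothing is silently dropped; filtering is the
    classifier's decision.
    """
    tsv_path = Path(tsv_path)
    try:
        df = pd.read_csv(
            tsv_path, sep="\t", header=None, names=DOMAIN_HIT_COLUMNS, comment="#",
            dtype=str,
        )
    except pd.errors.EmptyDataError:
        return []
    hits: list[DomainHit] = []
    for idx, row in df.iterrows():
        try:
            e_value = float(row["e_value"])
        except (TypeError, ValueError):
            raise MalformedInputError(
                f"{tsv_path}: row {idx + 1}: unparseable e_value {row['e_value']!r}"
            ) from None
        flagged = e_value_threshold is not None and e_value > e_value_threshold
        hits.append(
            DomainHit(
                protein_id=row["protein_id"],
                namespace=row["namespace"],
                domain_id=row["domain_id"],
                hit_start=int(row["start"]),
                hit_end=int(row["end"]),
                e_value=e_value,
                flagged=flagged,
            )
        )
    return hits


def write_domain_hits(hits: Iterable[DomainHit], tsv_path: str | Path) -> None:
    rows = [
        (h.protein_id, h.namespace, h.domain_id, h.hit_start, h.hit_end, h.e_value)
        for h in hits
    ]
    pd.DataFrame(rows, columns=DOMAIN_HIT_COLUMNS).to_csv(
        tsv_path, sep="\t", header=False, index=False
    )


def read_ko_assignments(tsv_path: str | Path) -> list[KOAssignment]:
    """Read a two-column protein→KO TSV; duplicate assignments are an error."""
    tsv_path = Path(tsv_path)
    try:
        df = pd.read_csv(
            tsv_path, sep="\t", header=None, names=["protein_id", "ko_id"],
            comment="#", dtype=str,
        )
    except pd.errors.EmptyDataError:
        return []
    seen: set[str] = set()
    out: list[KOAssignment] = []
    for idx, row in df.iterrows():
        pid = row["protein_id"]
        if pid in seen:
            raise MalformedInputError(
                f"{tsv_path}: row {idx + 1}: duplicate KO assignment for {pid!r}"
            )
        seen.add(pid)
        out.append(KOAssignment(pid, row["ko_id"]))
    return out


def write_ko_assignments(
    assignments: Iterable[KOAssignment], tsv_path: str | Path
) -> None:
    rows = [(a.protein_id, a.ko_id) for a in assignments]
    pd.DataFrame(rows, columns=["protein_id", "ko_id"]).to_csv(
        tsv_path, sep="\t", header=False, index=False
    )


def hits_by_protein(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    grouped: dict[str, list[DomainHit]] = {}
    for h in hits:
        grouped.setdefault(h.protein_id, []).append(h)
    return grouped
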