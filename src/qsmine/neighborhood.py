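"""Gene-neighborhood extraction around focal QS genes.

Extracts the genomic context (default 5 kbp on each side of the focal gene's
boundaries) and flags mobile-element-associated products by keyword, since a
transposase or integrase next to a LuxI/LuxR solo suggests the homolog arrived
by transposition. Upstream/downstream is defined relative to the focal gene's
strand, not replicon coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .genome_io import GeneFeature, GenomeRecord

DEFAULT_WINDOW_BP = 5000

DEFAULT_KEYWORDS = (
    "transposase",
    "mobile element",
    "integrase",
    "recombinase",
    "transposon",
)


@dataclass(frozen=True)
class NeighborhoodEntry:
    feature: GeneFeature
    offset: int  # feature.start - focal.start, in bp (replicon coordinates)
    strand: str
    overlap_bp: int


@dataclass(frozen=True)
class KeywordFlag:
    keyword: str
    feature_id: str
    side: str  # "upstream", "downstream", "overlapping" (focal-strand relative)


@dataclass
class NeighborhoodMap:
    genome_id: str
    focal: GeneFeature
    window: tuple[int, int]  # clipped replicon coordinates (may wrap if circular)
    entries: list[NeighborhoodEntry]
    flags: list[KeywordFlag] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "focal": self.focal.feature_id,
            "window": list(self.window),
            "entries": [
                {
                    "feature_id": e.feature.feature_id,
                    "start": e.feature.start,
                    "end": e.feature.end,
                    "strand": e.strand,
                    "offset": e.offset,
                    "overlap_bp": e.overlap_bp,
                    "product": e.feature.product,
                }
                for e in self.entries
            ],
            "flags": [
                {"keyword": f.keyword, "feature_id": f.feature_id, "side": f.side}
                for f in self.flags
            ],
        }

    def to_bed_frame(self) -> pd.DataFrame:
        """BED-like table: 0-based half-open intervals (start-1, end)."""
        rows = [
            {
                "replicon": e.feature.replicon_id,
                "start": e.feature.start - 1,
                "end": e.feature.end,
                "name": e.feature.feature_id,
                "strand": e.strand,
                "product": e.feature.product,
            }
            for e in self.entries
        ]
        return pd.DataFrame(
            rows, columns=["replicon", "start", "end", "name", "strand", "product"]
        )


def _intervals_overlap(a1: int, a2: int, b1: int, b2: int) -> int:
    return max(0, min(a2, b2) - max(a1, b1) + 1)


def extract_context(
    genome: GenomeRecord, focal_feature_id: str, window_bp: int = DEFAULT_WINDOW_BP
) -> NeighborhoodMap:
    """Extract the window [focal.start - window_bp, focal.end + window_bp].

    The window is clipped to the replicon; it wraps around the origin only when
    the replicon is circular. Features partially overlapping the window are
    included with their overlap length.
    """
    focal = genome.feature(focal_feature_id)  # KeyError if unknown
    rep = genome.replicon(focal.replicon_id)
    raw_left = focal.start - window_bp
    raw_right = focal.end + window_bp

    # The window as a list of linear intervals on [1, length].
    intervals: list[tuple[int, int]] = []
    if rep.circular and (raw_left < 1 or raw_right > rep.length):
        if raw_right - raw_left + 1 >= rep.length:
            intervals = [(1, rep.length)]
        else:
            lo = (raw_left - 1) % rep.length + 1
            hi = (raw_right - 1) % rep.length + 1
            if lo <= hi:
                intervals = [(lo, hi)]
            else:
                intervals = [(lo, rep.length), (1, hi)]
        window = (raw_left, raw_right)
    else:
        lo, hi = max(1, raw_left), min(rep.length, raw_right)
        intervals = [(lo, hi)]
        window = (lo, hi)

    entries: list[NeighborhoodEntry] = []
    for feat in genome.features_on(focal.replicon_id):
        overlap = sum(
            _intervals_overlap(feat.start, feat.end, lo, hi) for lo, hi in intervals
        )
        if overlap < 1:
            continue
        offset = feat.start - focal.start
        if rep.circular:
            # report the signed offset of smallest magnitude around the circle
            alt = offset - rep.length if offset > 0 else offset + rep.length
            if abs(alt) < abs(offset):
                offset = alt
        entries.append(
            NeighborhoodEntry(
                feature=feat, offset=offset, strand=feat.strand, overlap_bp=overlap
            )
        )
    entries.sort(key=lambda e: (e.feature.start, e.feature.end, e.feature.feature_id))
    return NeighborhoodMap(
        genome_id=genome.genome_id, focal=focal, window=window, entries=entries
    )


def _side_of(focal: GeneFeature, feat: GeneFeature) -> str:
    if feat.end < focal.start:
        before = True
    elif feat.start > focal.end:
        before = False
    else:
        return "overlapping"
    # "Upstream" is 5' of the focal gene on its own strand.
    if focal.strand == "+":
        return "upstream" if before else "downstream"
    return "downstream" if before else "upstream"


def flag_keywords(
    nmap: NeighborhoodMap, keywords: tuple[str, ...] = DEFAULT_KEYWORDS
) -> NeighborhoodMap:
    """Case-insensitive substring match of keywords against entry products.

    The focal gene itself is not flagged. Each flag records which side of the
    focal gene (relative to its strand) the matching feature lies on.
    """
    flags: list[KeywordFlag] = []
    for entry in nmap.entries:
        if entry.feature.feature_id == nmap.focal.feature_id:
            continue
        product = entry.feature.product.lower()
        for kw in keywords:
            if kw.lower() in product:
                flags.append(
                    KeywordFlag(
                        keyword=kw,
                        feature_id=entry.feature.feature_id,
                        side=_side_of(nmap.focal, entry.feature),
                    )
                )
    return replace(nmap, flags=flags)
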