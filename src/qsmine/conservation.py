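"""Key-residue and motif conservation checks for QS/QQ protein candidates.

Implements optimal global affine-gap pairwise alignment, mapping of reference
coordinates through an alignment, key-residue profiles (e.g. the LuxI
active-site residues R23/F27/W33/..., the LuxR autoinducer-binding and
DNA-binding residues), and exhaustive spaced-motif scanning (the AhlD
zinc-metallohydrolase HXHXDH...H...D signature and block motifs such as
TPGHTPGH).

Conventions: residue positions are 1-based; the ambiguous residue X never
matches an expected residue and scores 0 against everything in alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from ._gotoh import gotoh_align
from .resources import load_profiles_yaml

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
GAP = "-"
#: Alphabet used for alignment scoring: 20 residues, X, then the gap symbol.
SCORING_ALPHABET = ALPHABET + GAP

DEFAULT_GAP_OPEN = 6.0
DEFAULT_GAP_EXTEND = 1.0


@lru_cache(maxsize=1)
def default_substitution_matrix() -> np.ndarray:
    """BLOSUM62 over :data:`SCORING_ALPHABET`; X and the gap symbol score 0."""
    blosum = substitution_matrices.load("BLOSUM62")
    size = len(SCORING_ALPHABET)
    mat = np.zeros((size, size))
    for i, a in enumerate(ALPHABET[:-1]):
        for j, b in enumerate(ALPHABET[:-1]):
            mat[i, j] = blosum[a][b]
    return mat


def encode_sequence(seq: str) -> np.ndarray:
    try:
        return np.array([SCORING_ALPHABET.index(c) for c in seq], dtype=np.int64)
    except ValueError:
        bad = sorted(set(seq) - set(SCORING_ALPHABET))
        raise ValueError(f"sequence contains invalid symbols {bad}") from None


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of sequence A (reference) against sequence B."""

    seq_a: str
    seq_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)


def align_global(
    seq_a: str,
    seq_b: str,
    matrix: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment (Gotoh) of two protein sequences.

    A gap of length k costs ``gap_open + k * gap_extend``. Traceback ties are
    resolved deterministically (match/mismatch, then gap in A, then gap in B).
    """
    if not seq_a or not seq_b:
        raise ValueError("align_global requires non-empty sequences")
    mat = matrix if matrix is not None else default_substitution_matrix()
    ia = encode_sequence(seq_a)
    ib = encode_sequence(seq_b)
    score = mat[np.ix_(ia, ib)]
    path, best = gotoh_align(score, gap_open, gap_extend)
    rows_a: list[str] = []
    rows_b: list[str] = []
    for i, j in path:
        rows_a.append(seq_a[i] if i is not None else GAP)
        rows_b.append(seq_b[j] if j is not None else GAP)
    return PairwiseAlignment(seq_a, seq_b, "".join(rows_a), "".join(rows_b), best)


def map_reference_positions(
    alignment: PairwiseAlignment, positions: list[int]
) -> dict[int, int | None]:
    """Map 1-based reference (sequence A) positions to candidate positions.

    A reference position aligned to a gap in the candidate maps to ``None``.
    Positions outside the reference length raise ``ValueError``.
    """
    ref_len = len(alignment.seq_a)
    for pos in positions:
        if not (1 <= pos <= ref_len):
            raise ValueError(f"reference position {pos} outside 1..{ref_len}")
    wanted = set(positions)
    mapping: dict[int, int | None] = {}
    a_pos = b_pos = 0
    for ca, cb in zip(alignment.aligned_a, alignment.aligned_b):
        if ca != GAP:
            a_pos += 1
        if cb != GAP:
            b_pos += 1
        if ca != GAP and a_pos in wanted:
            mapping[a_pos] = b_pos if cb != GAP else None
    return mapping


# --- Residue profiles --------------------------------------------------------


@dataclass(frozen=True)
class KeyPosition:
    position: int  # 1-based on the profile reference
    residue: str
    group: str = ""


@dataclass(frozen=True)
class ResidueProfile:
    role: str
    reference_id: str
    reference_seq: str
    key_positions: tuple[KeyPosition, ...]

    def __post_init__(self) -> None:
        for kp in self.key_positions:
            if not (1 <= kp.position <= len(self.reference_seq)):
                raise ValueError(
                    f"profile {self.role}: key position {kp.position} out of range"
                )
            found = self.reference_seq[kp.position - 1]
            if found != kp.residue:
                raise ValueError(
                    f"profile {self.role}: reference has {found} at position "
                    f"{kp.position}, expected {kp.residue}"
                )


@dataclass(frozen=True)
class ResidueMatch:
    position: int
    expected: str
    observed: str | None  # None when the position is gapped or truncated away
    matched: bool
    candidate_position: int | None = None


@dataclass
class ConservationReport:
    protein_id: str
    role: str
    residue_matches: list[ResidueMatch] = field(default_factory=list)
    motif_hits: dict[str, list] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    identity: float | None = None

    @property
    def matched_fraction(self) -> float | None:
        if not self.residue_matches:
            return None
        return sum(m.matched for m in self.residue_matches) / len(self.residue_matches)

    def to_dict(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "role": self.role,
            "residue_matches": [
                {
                    "position": m.position,
                    "expected": m.expected,
                    "observed": m.observed,
                    "matched": m.matched,
                    "candidate_position": m.candidate_position,
                }
                for m in self.residue_matches
            ],
            "motif_hits": {
                k: [list(h.block_starts) if isinstance(h, SpacedMotifHit) else
                    [h.position, h.distance] for h in v]
                for k, v in self.motif_hits.items()
            },
            "flags": sorted(self.flags),
            "identity": self.identity,
            "matched_fraction": self.matched_fraction,
        }


def check_key_residues(
    protein_id: str,
    candidate_seq: str,
    profile: ResidueProfile,
    matrix: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    low_identity_threshold: float = 0.25,
) -> ConservationReport:
    """Align a candidate to the profile reference and check every key residue.

    A key position matches iff the aligned candidate residue equals the
    expected residue (X never matches). Key positions beyond the last
    reference position aligned to any candidate residue are reported with
    ``observed=None`` and set the ``truncated`` flag.
    """
    aln = align_global(
        profile.reference_seq, candidate_seq, matrix, gap_open, gap_extend
    )
    positions = [kp.position for kp in profile.key_positions]
    mapping = map_reference_positions(aln, positions) if positions else {}

    # Last reference position covered by the candidate (not a terminal gap).
    last_covered = 0
    a_pos = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != GAP:
            a_pos += 1
            if cb != GAP:
                last_covered = a_pos

    report = ConservationReport(protein_id=protein_id, role=profile.role)
    for kp in profile.key_positions:
        cand_pos = mapping.get(kp.position)
        if cand_pos is None:
            observed = None
            matched = False
        else:
            observed = candidate_seq[cand_pos - 1]
            matched = observed == kp.residue and observed != "X"
        report.residue_matches.append(
            ResidueMatch(kp.position, kp.residue, observed, matched, cand_pos)
        )
        if kp.position > last_covered:
            report.flags.add("truncated")

    both = [
        (a, b)
        for a, b in zip(aln.aligned_a, aln.aligned_b)
        if a != GAP and b != GAP
    ]
    if both:
        report.identity = sum(a == b for a, b in both) / len(both)
        if report.identity < low_identity_threshold:
            report.flags.add("low_identity")
    return report


def load_profiles() -> dict[str, ResidueProfile]:
    """Packaged residue profiles keyed by family name (luxi, luxr, rpff, ...)."""
    data = load_profiles_yaml()
    profiles: dict[str, ResidueProfile] = {}
    for name, spec in data["profiles"].items():
        seq = "".join(spec["reference_seq"].split())
        profiles[name] = ResidueProfile(
            role=spec["role"],
            reference_id=spec["reference_id"],
            reference_seq=seq,
            key_positions=tuple(
                KeyPosition(kp["position"], kp["residue"], kp.get("group", ""))
                for kp in spec["key_positions"]
            ),
        )
    return profiles


# --- Motif scanning ----------------------------------------------------------


@dataclass(frozen=True)
class SpacedMotif:
    """Ordered residue blocks separated by bounded spacer windows.

    ``blocks`` are patterns over the residue alphabet where X is a wildcard;
    ``spacers[k]`` is the (min, max) count of residues allowed between block k
    and block k+1; ``max_mismatches[k]`` bounds the Hamming mismatches allowed
    in block k.
    """

    motif_id: str
    blocks: tuple[str, ...]
    spacers: tuple[tuple[int, int], ...]
    max_mismatches: tuple[int, ...]
    anchor_positions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("spaced motif needs at least one block")
        if len(self.spacers) != len(self.blocks) - 1:
            raise ValueError("need one spacer window per adjacent block pair")
        if len(self.max_mismatches) != len(self.blocks):
            raise ValueError("need one mismatch budget per block")
        for lo, hi in self.spacers:
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid spacer window ({lo}, {hi})")


@dataclass(frozen=True)
class SpacedMotifHit:
    block_starts: tuple[int, ...]  # 1-based start of each block

    @property
    def span(self) -> tuple[int, int]:
        return self.block_starts[0], self.block_starts[-1]


@dataclass(frozen=True)
class SpacedMotifScan:
    hits: tuple[SpacedMotifHit, ...]
    truncated: bool
    motif_absent: bool


def _block_matches(seq: str, pattern: str, start0: int, max_mm: int) -> bool:
    """Hamming match of ``pattern`` at 0-based ``start0``; pattern X is a
    wildcard, a sequence X matches nothing else."""
    mm = 0
    for k, pc in enumerate(pattern):
        sc = seq[start0 + k]
        if pc == "X":
            continue
        if sc != pc or sc == "X":
            mm += 1
            if mm > max_mm:
                return False
    return True


def _block_starts(seq: str, pattern: str, max_mm: int, lo0: int, hi0: int) -> list[int]:
    """All 0-based starts in [lo0, hi0] where the block matches (exhaustive)."""
    last = min(hi0, len(seq) - len(pattern))
    return [
        s for s in range(max(lo0, 0), last + 1) if _block_matches(seq, pattern, s, max_mm)
    ]


def scan_spaced_motif(seq: str, motif: SpacedMotif) -> SpacedMotifScan:
    """Exhaustively scan for a spaced motif; report all non-overlapping hits.

    Truncation is distinguished from absence: if a partial match chain ran out
    of sequence (the sequence ends inside a spacer window or before the next
    block could fit) and no complete hit exists, the scan is ``truncated``
    rather than ``motif_absent``.
    """
    n = len(seq)
    complete: list[tuple[int, ...]] = []
    truncated_partial = False

    def extend(chain: tuple[int, ...]) -> None:
        nonlocal truncated_partial
        k = len(chain)
        if k == len(motif.blocks):
            complete.append(chain)
            return
        prev_end0 = chain[-1] + len(motif.blocks[k - 1])  # 0-based exclusive end
        lo, hi = motif.spacers[k - 1]
        lo0, hi0 = prev_end0 + lo, prev_end0 + hi
        if hi0 + len(motif.blocks[k]) > n:
            truncated_partial = True
        for s in _block_starts(seq, motif.blocks[k], motif.max_mismatches[k], lo0, hi0):
            extend(chain + (s,))

    for s0 in _block_starts(seq, motif.blocks[0], motif.max_mismatches[0], 0, n):
        extend((s0,))

    # Greedy left-to-right selection of non-overlapping complete chains.
    selected: list[SpacedMotifHit] = []
    occupied_until = -1
    for chain in sorted(complete):
        if chain[0] > occupied_until:
            selected.append(SpacedMotifHit(tuple(s + 1 for s in chain)))
            occupied_until = chain[-1] + len(motif.blocks[-1]) - 1
    hits = tuple(selected)
    truncated = not hits and truncated_partial
    return SpacedMotifScan(
        hits=hits, truncated=truncated, motif_absent=not hits and not truncated
    )


@dataclass(frozen=True)
class BlockMotifHit:
    position: int  # 1-based
    distance: int


def scan_block_motif(seq: str, pattern: str, max_mismatches: int = 0) -> list[BlockMotifHit]:
    """All positions where the pattern matches within a Hamming budget.

    Pattern X is a wildcard; sequence X never matches a concrete pattern
    residue. Hits are sorted by position (then distance).
    """
    hits: list[BlockMotifHit] = []
    for s in range(len(seq) - len(pattern) + 1):
        mm = 0
        ok = True
        for k, pc in enumerate(pattern):
            if pc == "X":
                continue
            sc = seq[s + k]
            if sc != pc or sc == "X":
                mm += 1
                if mm > max_mismatches:
                    ok = False
                    break
        if ok:
            hits.append(BlockMotifHit(s + 1, mm))
    return sorted(hits, key=lambda h: (h.position, h.distance))


def load_motifs() -> dict[str, SpacedMotif | dict]:
    """Packaged motif definitions; spaced motifs as :class:`SpacedMotif`,
    block motifs as plain dicts with ``pattern`` and ``max_mismatches``."""
    data = load_profiles_yaml()
    motifs: dict[str, SpacedMotif | dict] = {}
    for name, spec in data["motifs"].items():
        if spec["kind"] == "spaced":
            motifs[name] = SpacedMotif(
                motif_id=name,
                blocks=tuple(spec["blocks"]),
                spacers=tuple((int(lo), int(hi)) for lo, hi in spec["spacers"]),
                max_mismatches=tuple(spec["max_mismatches"]),
                anchor_positions=tuple(spec["anchor_positions"])
                if spec.get("anchor_positions")
                else None,
            )
        else:
            motifs[name] = {
                "kind": "block",
                "pattern": spec["pattern"],
                "max_mismatches": int(spec.get("max_mismatches", 0)),
                "anchor_position": spec.get("anchor_position"),
            }
    return motifs


def ahld_conservation_report(
    protein_id: str,
    candidate_seq: str,
    profiles: dict[str, ResidueProfile] | None = None,
    motifs: dict | None = None,
) -> ConservationReport:
    """Full AhlD check: zinc-coordination residues, the spaced
    HXHXDH...H...D signature, and the TPGHTPGH block motif.

    ``motif_absent`` / ``truncated`` flags from the spaced-motif scan are
    merged into the report, which is what downgrades the QQ call's validity.
    """
    profiles = profiles or load_profiles()
    motifs = motifs or load_motifs()
    report = check_key_residues(protein_id, candidate_seq, profiles["ahld"])
    spaced = motifs["ahld_zinc_hydrolase"]
    scan = scan_spaced_motif(candidate_seq, spaced)
    report.motif_hits[spaced.motif_id] = list(scan.hits)
    if scan.motif_absent:
        report.flags.add("motif_absent")
    if scan.truncated:
        report.flags.add("truncated")
    block = motifs["ahld_tpgh"]
    report.motif_hits["ahld_tpgh"] = scan_block_motif(
        candidate_seq, block["pattern"], block["max_mismatches"]
    )
    return report
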