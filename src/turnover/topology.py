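"""Membrane-topology parsing and extraluminal domain sizing.

TMHMM long-format output assigns every residue stretch of a membrane
protein to ``inside``, ``outside`` or ``TMhelix``. For a nuclear-envelope
membrane protein, one of the two non-membrane sides faces the ER lumen and
the other faces the nucleo-/cytoplasm; the *extraluminal* domain size — the
total residues outside the lumen — is the quantity compared against
half-life when asking whether bulky nucleoplasmic domains slow turnover.

TMHMM's inside/outside labels do not map reliably onto lumen versus
nucleoplasm (tail-anchored proteins in particular can be annotated either
way), so the luminal side is supplied per protein by the caller rather
than inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import yaml

from .errors import ConfigurationError, ValidationError

SIDE_A = "side_A"   # TMHMM "inside"
SIDE_B = "side_B"   # TMHMM "outside"
MEMBRANE = "membrane"

_LOCATION_BY_TMHMM = {"inside": SIDE_A, "outside": SIDE_B, "TMhelix": MEMBRANE}


@dataclass(frozen=True)
class TopologySegment:
    """One contiguous residue stretch (1-based, inclusive coordinates)."""

    start: int
    end: int
    location: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"segment coordinates must satisfy 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )
        if self.location not in (SIDE_A, SIDE_B, MEMBRANE):
            raise ValidationError(f"unknown segment location {self.location!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TopologyAnnotation:
    """Full topology of one protein: segments tiling [1, length].

    ``luminal_side`` (side_A or side_B) is unset after parsing and must be
    assigned before extraluminal sizing.
    """

    protein_id: str
    length: int
    segments: tuple[TopologySegment, ...]
    luminal_side: str | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError(f"{self.protein_id}: no topology segments")
        ordered = sorted(self.segments, key=lambda s: s.start)
        pos = 1
        for seg in ordered:
            if seg.start != pos:
                kind = "overlap" if seg.start < pos else "gap"
                raise ValidationError(
                    f"{self.protein_id}: topology segments do not tile the "
                    f"sequence ({kind} at residue {min(seg.start, pos)})"
                )
            pos = seg.end + 1
        if pos - 1 != self.length:
            raise ValidationError(
                f"{self.protein_id}: segments cover [1, {pos - 1}] but protein "
                f"length is {self.length}"
            )
        sides = [s.location for s in ordered if s.location != MEMBRANE]
        # membrane passes must alternate the facing side
        blocks: list[str] = []
        for seg in ordered:
            if seg.location == MEMBRANE:
                continue
            blocks.append(seg.location)
        for a, b in zip(blocks, blocks[1:]):
            if a == b:
                raise ValidationError(
                    f"{self.protein_id}: consecutive non-membrane segments on "
                    f"the same side ({a}); topology does not alternate"
                )
        if self.luminal_side not in (None, SIDE_A, SIDE_B):
            raise ValidationError(
                f"{self.protein_id}: luminal_side must be side_A or side_B"
            )

    def with_luminal_side(self, side: str) -> "TopologyAnnotation":
        if side not in (SIDE_A, SIDE_B):
            raise ConfigurationError(
                f"luminal side must be {SIDE_A!r} or {SIDE_B!r}, got {side!r}"
            )
        return replace(self, luminal_side=side)

    def membrane_residues(self) -> int:
        return sum(s.length for s in self.segments if s.location == MEMBRANE)


def parse_tmhmm(path: str | Path) -> list[TopologyAnnotation]:
    """Parse TMHMM long-format output into topology annotations.

    Expected data lines look like ``Q61029  TMHMM2.0  inside  1  70``;
    ``#`` comment lines are ignored. Each protein's segments must tile its
    sequence without gaps or overlaps.
    """
    per_protein: dict[str, list[TopologySegment]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValidationError(
                    f"{path}:{lineno}: expected 5 whitespace-separated fields, "
                    f"got {len(parts)}: {line!r}"
                )
            protein_id, _method, label, start, end = parts
            if label not in _LOCATION_BY_TMHMM:
                raise ValidationError(
                    f"{path}:{lineno}: unknown topology label {label!r}"
                )
            segment = TopologySegment(int(start), int(end), _LOCATION_BY_TMHMM[label])
            if protein_id not in per_protein:
                per_protein[protein_id] = []
                order.append(protein_id)
            per_protein[protein_id].append(segment)
    annotations = []
    for protein_id in order:
        segments = tuple(sorted(per_protein[protein_id], key=lambda s: s.start))
        length = max(s.end for s in segments)
        annotations.append(
            TopologyAnnotation(protein_id=protein_id, length=length, segments=segments)
        )
    return annotations


def extraluminal_size(annotation: TopologyAnnotation) -> int:
    """Total residues in non-membrane segments facing away from the lumen."""
    if annotation.luminal_side is None:
        raise ConfigurationError(
            f"{annotation.protein_id}: luminal_side must be assigned before "
            f"extraluminal sizing (use with_luminal_side)"
        )
    return sum(
        s.length
        for s in annotation.segments
        if s.location != MEMBRANE and s.location != annotation.luminal_side
    )


def load_orientation(path: str | Path) -> dict[str, str]:
    """Read a YAML mapping ``protein_id: side_A|side_B`` of luminal sides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"orientation file {path} must be a mapping")
    for protein, side in raw.items():
        if side not in (SIDE_A, SIDE_B):
            raise ConfigurationError(
                f"orientation for {protein} must be {SIDE_A!r} or {SIDE_B!r}, "
                f"got {side!r}"
            )
    return dict(raw)
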