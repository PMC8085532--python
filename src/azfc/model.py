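"""Reference model of the AZFc ampliconic region of the human Y chromosome.

The AZFc (azoospermia factor c) region on Yq is built almost entirely from
six families of near-identical duplicated sequences ("amplicons"): blue (b),
teal (t), green (g), red (r), yellow (y) and gray (Gr).  On the reference
chromosome the families are present in 4, 2, 3, 4, 2 and 2 copies
respectively, interleaved with two single-copy stretches — the large P3
palindrome spacer between t1 and t2 (which hosts the forensic Y-STR DYS448)
and a single copy of Inverted Repeat 1 (IR1) between b2 and g1.  The
multi-copy Y-STR DYF387S1 sits inside the two yellow amplicons.

This module holds that structure as a validated, ordered segment list
(:class:`ReferenceMap`) loaded from a BED-like text fixture, together with a
gene-family dosage map (PRY, RBMY, BPY, DAZ, CDY hosted by b, t, g, r, y)
and the 1-Mb single-copy interval used to normalise sequencing depth.

Coordinates are 0-based half-open internally; the bundled fixture uses
GRCh37 chrY coordinates distilled from published AZFc maps (segment lengths
are plausible but synthetic: the fixture is built to satisfy the region's
structural constraints — segment order, family copy counts, a 3.5-Mb
b2→b4 span and a 1.6-Mb b1→b3 span — not to reproduce any published
base-pair coordinate list).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "AMPLICON_FAMILIES",
    "REFERENCE_COPY_COUNTS",
    "Segment",
    "Interval",
    "GeneFamily",
    "CopyNumberVector",
    "ReferenceMap",
    "MapValidationError",
    "load_reference_map",
    "write_reference_map",
    "default_reference_map",
    "reference_copy_vector",
]

#: The six amplicon families, proximal-to-distal order of first appearance.
AMPLICON_FAMILIES: tuple[str, ...] = ("b", "t", "g", "r", "y", "Gr")

#: Reference copy count per family (the denominators of normalised-depth ratios).
REFERENCE_COPY_COUNTS: dict[str, int] = {"b": 4, "t": 2, "g": 3, "r": 4, "y": 2, "Gr": 2}

#: Expected proximal->distal order of segment ids on the reference chromosome.
REFERENCE_SEGMENT_ORDER: tuple[str, ...] = (
    "Gr1", "b1", "t1", "P3_spacer", "t2", "b2", "IR1",
    "g1", "r1", "r2", "b3", "y1", "g2", "r3", "r4", "g3", "y2", "b4", "Gr2",
)


class MapValidationError(ValueError):
    """Raised when a reference map violates a structural invariant."""


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise MapValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} has end <= start"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Segment:
    """One amplicon copy, spacer or unique segment of the region model.

    ``family`` is an amplicon family name (b, t, g, r, y, Gr) or the special
    labels ``"spacer"`` / ``"unique"`` for single-copy stretches.
    """

    id: str
    family: str
    interval: Interval
    orientation: int = +1

    def __post_init__(self) -> None:
        if self.orientation not in (+1, -1):
            raise MapValidationError(f"segment {self.id}: orientation must be +1/-1")


@dataclass(frozen=True)
class GeneFamily:
    """Dosage model for one AZFc multi-copy gene family.

    Total copy number = ``copies_per_segment`` x (host amplicon family copy
    count) + ``external_constant_copies`` (copies outside the modelled
    region, unaffected by AZFc rearrangements; RBMY has four such copies,
    giving its reference total of six).
    """

    name: str
    host_family: str
    copies_per_segment: int = 1
    external_constant_copies: int = 0


#: Reference gene-family hosts: PRY/b, RBMY/t, BPY/g, DAZ/r, CDY/y.
DEFAULT_GENE_FAMILIES: dict[str, GeneFamily] = {}


@dataclass(frozen=True)
class CopyNumberVector:
    """Integer copies per amplicon family plus P3-spacer presence.

    This is the object the depth-based caller produces and the NAHR scenario
    search consumes.
    """

    b: int
    t: int
    g: int
    r: int
    y: int
    Gr: int
    spacer: int

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value < 0:
                raise ValueError(f"copy count for {name} is negative: {value}")

    def as_dict(self) -> dict[str, int]:
        return {
            "b": self.b, "t": self.t, "g": self.g, "r": self.r,
            "y": self.y, "Gr": self.Gr, "spacer": self.spacer,
        }

    def as_tuple(self) -> tuple[int, ...]:
        return (self.b, self.t, self.g, self.r, self.y, self.Gr, self.spacer)

    def __getitem__(self, family: str) -> int:
        return self.as_dict()[family]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "CopyNumberVector":
        missing = {*AMPLICON_FAMILIES, "spacer"} - set(mapping)
        if missing:
            raise KeyError(f"copy-number vector missing entries: {sorted(missing)}")
        return cls(**{k: int(mapping[k]) for k in (*AMPLICON_FAMILIES, "spacer")})


@dataclass(frozen=True)
class ReferenceMap:
    """Validated, ordered AZFc segment model.

    Attributes
    ----------
    segments:
        Amplicon copies, the P3 spacer and unique segments, sorted by start,
        pairwise non-overlapping.
    normalization_interval:
        A ~1-Mb single-copy chrY interval used to normalise read depth;
        must not overlap any segment.
    str_anchors:
        Y-STR name -> ids of the host segment(s) (DYS448 -> P3_spacer,
        DYF387S1 -> y1 and y2).
    gene_families:
        Gene family name -> :class:`GeneFamily` dosage model.
    """

    segments: tuple[Segment, ...]
    normalization_interval: Interval
    str_anchors: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    gene_families: Mapping[str, GeneFamily] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- queries -------------------------------------------------------

    def segment(self, segment_id: str) -> Segment:
        for seg in self.segments:
            if seg.id == segment_id:
                return seg
        raise KeyError(f"no segment with id {segment_id!r}")

    def family_segments(self, family: str) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.family == family)

    def family_intervals(self, family: str) -> tuple[Interval, ...]:
        return tuple(s.interval for s in self.family_segments(family))

    def all_intervals(self) -> tuple[Interval, ...]:
        return tuple(s.interval for s in self.segments) + (self.normalization_interval,)

    def region_span(self) -> Interval:
        """The full modelled region (first segment start to last segment end)."""
        return Interval(
            self.segments[0].interval.chrom,
            self.segments[0].interval.start,
            self.segments[-1].interval.end,
        )

    def family_counts(self) -> dict[str, int]:
        counts = {f: 0 for f in AMPLICON_FAMILIES}
        for seg in self.segments:
            if seg.family in counts:
                counts[seg.family] += 1
        return counts

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        if not self.segments:
            raise MapValidationError("reference map has no segments")
        prev = None
        for seg in self.segments:
            if prev is not None:
                if seg.interval.start < prev.interval.start:
                    raise MapValidationError(
                        f"segment {seg.id} is out of order (starts before {prev.id})"
                    )
                if seg.interval.overlaps(prev.interval):
                    raise MapValidationError(
                        f"segment {seg.id} overlaps segment {prev.id}"
                    )
            prev = seg
        counts = self.family_counts()
        for family, expected in REFERENCE_COPY_COUNTS.items():
            if counts[family] != expected:
                raise MapValidationError(
                    f"family {family} has {counts[family]} segments, expected {expected}"
                )
        spacers = [s for s in self.segments if s.family == "spacer"]
        if len(spacers) != 1:
            raise MapValidationError(
                f"expected exactly one P3 spacer segment, found {len(spacers)}"
            )
        known = set(AMPLICON_FAMILIES) | {"spacer", "unique"}
        for seg in self.segments:
            if seg.family not in known:
                raise MapValidationError(
                    f"segment {seg.id} has unknown family {seg.family!r}"
                )
        for seg in self.segments:
            if seg.interval.overlaps(self.normalization_interval):
                raise MapValidationError(
                    f"normalization interval overlaps segment {seg.id}"
                )
        # normalization-interval length is not checked here: toy-scaled maps
        # shrink it along with the segments (the bundled fixture is 1 Mb)
        for str_name, hosts in self.str_anchors.items():
            for host in hosts:
                try:
                    self.segment(host)
                except KeyError:
                    raise MapValidationError(
                        f"STR {str_name} anchored to unknown segment {host!r}"
                    ) from None
        if "DYS448" in self.str_anchors:
            hosts = self.str_anchors["DYS448"]
            if any(self.segment(h).family != "spacer" for h in hosts):
                raise MapValidationError("DYS448 anchor must lie in the P3 spacer")
        if "DYF387S1" in self.str_anchors:
            hosts = self.str_anchors["DYF387S1"]
            if any(self.segment(h).family != "y" for h in hosts):
                raise MapValidationError("DYF387S1 anchors must lie in y segments")


# ---------------------------------------------------------------------------
# I/O


def _parse_bed_line(line: str, lineno: int) -> tuple[str, int, int, str, str, int]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 6:
        parts = line.split()
    if len(parts) != 6:
        raise MapValidationError(
            f"line {lineno}: expected 6 columns (chrom start end id family strand), "
            f"got {len(parts)}"
        )
    chrom, start, end, seg_id, family, strand = parts
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise MapValidationError(f"line {lineno}: non-integer coordinate") from exc
    orientation = +1 if strand == "+" else -1 if strand == "-" else None
    if orientation is None:
        raise MapValidationError(f"line {lineno}: strand must be '+' or '-'")
    return chrom, start_i, end_i, seg_id, family, orientation


def load_reference_map(
    path: str | Path,
    gene_map_path: str | Path | None = None,
    str_anchors_path: str | Path | None = None,
) -> ReferenceMap:
    """Load and validate a reference map from a 6-column BED-like file.

    Columns: chrom, start, end, id, family, strand (0-based half-open).
    A row with family ``norm`` declares the single-copy normalization
    interval instead of a segment.  Gene-family and STR-anchor sidecars are
    JSON; when omitted the bundled defaults are used.
    """
    segments: list[Segment] = []
    norm: Interval | None = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, seg_id, family, orientation = _parse_bed_line(line, lineno)
            if family == "norm":
                norm = Interval(chrom, start, end)
            else:
                segments.append(
                    Segment(seg_id, family, Interval(chrom, start, end), orientation)
                )
    if norm is None:
        raise MapValidationError(
            "no normalization interval (row with family 'norm') in map file"
        )
    segments.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    gene_families = _load_gene_families(gene_map_path)
    str_anchors = _load_str_anchors(str_anchors_path)
    return ReferenceMap(tuple(segments), norm, str_anchors, gene_families)


def _load_gene_families(path: str | Path | None) -> dict[str, GeneFamily]:
    if path is None:
        raw = json.loads(
            resources.files("azfc.data").joinpath("gene_families.json").read_text()
        )
    else:
        raw = json.loads(Path(path).read_text())
    return {
        name: GeneFamily(
            name=name,
            host_family=spec["host_family"],
            copies_per_segment=int(spec.get("copies_per_segment", 1)),
            external_constant_copies=int(spec.get("external_constant_copies", 0)),
        )
        for name, spec in raw.items()
    }


def _load_str_anchors(path: str | Path | None) -> dict[str, tuple[str, ...]]:
    if path is None:
        raw = json.loads(
            resources.files("azfc.data").joinpath("str_anchors.json").read_text()
        )
    else:
        raw = json.loads(Path(path).read_text())
    return {name: tuple(hosts) for name, hosts in raw.items()}


def write_reference_map(refmap: ReferenceMap, path: str | Path) -> None:
    """Write a map back to the 6-column BED-like format read by the loader."""
    with open(path, "w") as handle:
        for seg in refmap.segments:
            strand = "+" if seg.orientation > 0 else "-"
            handle.write(
                f"{seg.interval.chrom}\t{seg.interval.start}\t{seg.interval.end}\t"
                f"{seg.id}\t{seg.family}\t{strand}\n"
            )
        ni = refmap.normalization_interval
        handle.write(f"{ni.chrom}\t{ni.start}\t{ni.end}\tsingle_copy_norm\tnorm\t+\n")


def default_reference_map() -> ReferenceMap:
    """The bundled GRCh37 chrY AZFc fixture."""
    with resources.as_file(resources.files("azfc.data").joinpath("azfc_map.bed")) as p:
        return load_reference_map(p)


def reference_copy_vector(refmap: ReferenceMap) -> CopyNumberVector:
    """Copy-number vector of the reference structure itself.

    For the bundled fixture this is (b=4, t=2, g=3, r=4, y=2, Gr=2,
    spacer=1) — the denominators of the normalised-depth ratios.
    """
    counts = refmap.family_counts()
    spacer = sum(1 for s in refmap.segments if s.family == "spacer")
    return CopyNumberVector(spacer=spacer, **counts)
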