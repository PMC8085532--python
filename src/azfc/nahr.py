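"""Enumeration of NAHR rearrangement scenarios explaining a copy-number vector.

Non-allelic homologous recombination (NAHR) between near-identical amplicon
copies rearranges the AZFc: exchange between misaligned *sister chromatids*
(interchromatidic) produces reciprocal deletion and duplication products,
while looping-out within a single chromatid (intrachromatidic) produces a
deletion only.  Both act between *direct* repeats of the same family; the
recombined copy survives as a hybrid (e.g. "b1/b3") that still counts as
one copy of its family and remains a functional substrate for further NAHR.

Given an observed copy-number vector (families + P3-spacer presence), the
search replays every ordered sequence of up to ``max_events`` events from
the reference structure and reports all minimal-length sequences whose
final vector matches, annotated with per-event genomic spans, gene-family
dosages and the Y-STR copy counts they imply (DYS448 in the spacer,
DYF387S1 in the yellow copies).  An empty result means the vector is not
NAHR-reachable within the event budget.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .model import (
    AMPLICON_FAMILIES,
    CopyNumberVector,
    GeneFamily,
    ReferenceMap,
)

__all__ = [
    "Occurrence",
    "ChromosomeStructure",
    "NAHREvent",
    "Scenario",
    "enumerate_events",
    "apply_event",
    "sister_products",
    "search_scenarios",
    "scenario_span_lengths",
    "gene_dosage",
    "str_copy_counts",
    "write_scenarios",
]

MAX_EVENTS_HARD_LIMIT = 3

DELETION = "deletion"
DUPLICATION = "duplication"
INTRA = "intrachromatidic"
INTER = "interchromatidic"


@dataclass(frozen=True)
class Occurrence:
    """One segment occurrence on a (possibly rearranged) chromosome.

    ``label`` is unique within a structure: original segment ids ("b3"),
    duplicated copies ("b3@2"), hybrids ("b4/b2").  ``sources`` records the
    reference segment id(s) the occurrence derives from; ``anchor`` is the
    reference-projected start coordinate used for span lengths (hybrids
    resolve to their first-listed source's coordinate).
    """

    label: str
    family: str
    orientation: int
    sources: tuple[str, ...]
    anchor: int

    @property
    def is_hybrid(self) -> bool:
        return len(self.sources) > 1


@dataclass(frozen=True)
class ChromosomeStructure:
    """Ordered occurrence list for one chromosome."""

    occurrences: tuple[Occurrence, ...]

    @classmethod
    def from_reference(cls, refmap: ReferenceMap) -> "ChromosomeStructure":
        return cls(
            tuple(
                Occurrence(
                    label=seg.id,
                    family=seg.family,
                    orientation=seg.orientation,
                    sources=(seg.id,),
                    anchor=seg.interval.start,
                )
                for seg in refmap.segments
            )
        )

    def index_of(self, label: str) -> int:
        for i, occ in enumerate(self.occurrences):
            if occ.label == label:
                return i
        raise KeyError(f"no occurrence labelled {label!r} in structure")

    def copy_vector(self) -> CopyNumberVector:
        counts = {f: 0 for f in AMPLICON_FAMILIES}
        spacer = 0
        for occ in self.occurrences:
            if occ.family in counts:
                counts[occ.family] += 1
            elif occ.family == "spacer":
                spacer += 1
        return CopyNumberVector(spacer=spacer, **counts)

    def canonical(self) -> tuple[tuple[str, int], ...]:
        """Family/orientation sequence; hybrids reduce to their family.

        Copy-number observables cannot distinguish finer structure, so two
        structures with equal canonical forms are observationally identical.
        """
        return tuple((occ.family, occ.orientation) for occ in self.occurrences)

    def total_length(self, refmap: ReferenceMap) -> int:
        """Total modelled length: sum of source-segment lengths (hybrids count once)."""
        total = 0
        for occ in self.occurrences:
            total += len(refmap.segment(occ.sources[0]).interval)
        return total


@dataclass(frozen=True)
class NAHREvent:
    """One NAHR exchange between two direct repeats of the same family.

    ``left`` must lie strictly proximal of ``right``.  Duplications arise
    only from interchromatidic exchange; deletions from either mechanism.
    """

    kind: str  # deletion | duplication
    mechanism: str  # intrachromatidic | interchromatidic
    left: str  # occurrence label
    right: str

    def __post_init__(self) -> None:
        if self.kind not in (DELETION, DUPLICATION):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.mechanism not in (INTRA, INTER):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.kind == DUPLICATION and self.mechanism == INTRA:
            raise ValueError("duplications require interchromatidic exchange")

    def signature(self) -> tuple[str, str, str, str]:
        return (self.kind, self.mechanism, self.left, self.right)

    def __str__(self) -> str:  # e.g. "dup(b2/b4, interchromatidic)"
        short = "dup" if self.kind == DUPLICATION else "del"
        return f"{short}({self.left}/{self.right}, {self.mechanism})"


def enumerate_events(structure: ChromosomeStructure) -> list[NAHREvent]:
    """All NAHR events definable on ``structure``.

    For every ordered pair of same-family, same-orientation amplicon
    occurrences (direct repeats): deletion by either mechanism, duplication
    by interchromatidic exchange only.
    """
    events: list[NAHREvent] = []
    occs = structure.occurrences
    for i, j in itertools.combinations(range(len(occs)), 2):
        a, b = occs[i], occs[j]
        if a.family not in AMPLICON_FAMILIES:
            continue
        if a.family != b.family or a.orientation != b.orientation:
            continue
        events.append(NAHREvent(DELETION, INTRA, a.label, b.label))
        events.append(NAHREvent(DELETION, INTER, a.label, b.label))
        events.append(NAHREvent(DUPLICATION, INTER, a.label, b.label))
    return events


def _hybrid(first: Occurrence, second: Occurrence) -> Occurrence:
    """Hybrid copy from an exchange; anchored at its first-listed source."""
    return Occurrence(
        label=f"{first.label}/{second.label}",
        family=first.family,
        orientation=first.orientation,
        sources=first.sources + second.sources,
        anchor=first.anchor,
    )


def _relabel(occ: Occurrence, generation: int) -> Occurrence:
    base = re.sub(r"@\d+", "", occ.label)
    return Occurrence(
        label=f"{base}@{generation}",
        family=occ.family,
        orientation=occ.orientation,
        sources=occ.sources,
        anchor=occ.anchor,
    )


def apply_event(
    structure: ChromosomeStructure, event: NAHREvent
) -> ChromosomeStructure:
    """Replay one event, returning the product chromosome.

    Deletion: occurrences strictly between left and right are removed and
    the pair collapses to one hybrid "left/right".  Duplication: the
    intervening span is present twice around a new hybrid "right/left"
    (one extra family copy): ... left, span, hybrid, span-copy, right, ...
    """
    occs = structure.occurrences
    i = structure.index_of(event.left)
    j = structure.index_of(event.right)
    if i >= j:
        raise ValueError(f"event {event} is not left-before-right in this structure")
    left, right = occs[i], occs[j]
    if left.family != right.family or left.orientation != right.orientation:
        raise ValueError(f"event {event} endpoints are not direct repeats")
    if event.kind == DELETION:
        new = occs[:i] + (_hybrid(left, right),) + occs[j + 1 :]
    else:
        between = occs[i + 1 : j]
        generation = 1 + max(
            (
                int(m)
                for o in occs
                for m in re.findall(r"@(\d+)", o.label)
            ),
            default=0,
        )
        between_copy = tuple(_relabel(o, generation) for o in between)
        new = (
            occs[: i + 1]
            + between
            + (_hybrid(right, left),)
            + between_copy
            + occs[j:]
        )
    return ChromosomeStructure(new)


def sister_products(
    structure: ChromosomeStructure, event: NAHREvent
) -> tuple[ChromosomeStructure, ChromosomeStructure]:
    """Both reciprocal products of an interchromatidic unequal exchange.

    Returns (deletion product, duplication product); for every family the
    two products' copy counts sum to twice the parent's.
    """
    if event.mechanism != INTER:
        raise ValueError(
            "only interchromatidic exchange yields a reciprocal duplication product"
        )
    deletion = apply_event(
        structure, NAHREvent(DELETION, INTER, event.left, event.right)
    )
    duplication = apply_event(
        structure, NAHREvent(DUPLICATION, INTER, event.left, event.right)
    )
    return deletion, duplication


# ---------------------------------------------------------------------------
# scenario search


@dataclass(frozen=True)
class Scenario:
    """An ordered NAHR event sequence with its observable consequences."""

    events: tuple[NAHREvent, ...]
    final_structure: ChromosomeStructure
    final_vector: CopyNumberVector
    spans_bp: tuple[int, ...]
    gene_dosage: Mapping[str, int]
    str_copies: Mapping[str, int]
    concurrent_capable: bool | None = None

    def replay(self, refmap: ReferenceMap) -> ChromosomeStructure:
        structure = ChromosomeStructure.from_reference(refmap)
        for event in self.events:
            structure = apply_event(structure, event)
        return structure


def _event_span(structure: ChromosomeStructure, event: NAHREvent) -> int:
    left = structure.occurrences[structure.index_of(event.left)]
    right = structure.occurrences[structure.index_of(event.right)]
    return abs(right.anchor - left.anchor)


def _concurrent_capable(
    reference: ChromosomeStructure, events: Sequence[NAHREvent]
) -> bool | None:
    """Could the pair have happened simultaneously on the starting structure?

    True when every event's endpoints already exist (as direct repeats) on
    the reference structure — copy-number data cannot distinguish
    simultaneity from succession for such pairs.  None for non-pairs.
    """
    if len(events) != 2:
        return None
    labels = {
        occ.label: (occ.family, occ.orientation) for occ in reference.occurrences
    }
    for event in events:
        if event.left not in labels or event.right not in labels:
            return False
        if labels[event.left] != labels[event.right]:
            return False
    return True


def search_scenarios(
    refmap: ReferenceMap,
    observed: CopyNumberVector,
    max_events: int = 2,
) -> list[Scenario]:
    """Breadth-first search for minimal NAHR event sequences matching ``observed``.

    Replays every ordered sequence of events from the reference structure,
    sharing expansion work between histories that reach an identical
    structure, and returns *all* sequences of minimal length whose final
    copy-number vector (families + spacer presence) equals ``observed``.
    Sequences differing only in mechanism are distinct scenarios.  An empty
    list means the vector is unexplained within ``max_events``.
    """
    if max_events > MAX_EVENTS_HARD_LIMIT:
        raise ValueError(
            f"max_events={max_events} exceeds the hard limit "
            f"({MAX_EVENTS_HARD_LIMIT}); the search grows factorially"
        )
    reference = ChromosomeStructure.from_reference(refmap)
    genes = refmap.gene_families

    def finalize(
        events: tuple[NAHREvent, ...], structure: ChromosomeStructure
    ) -> Scenario:
        spans = []
        replay = reference
        for event in events:
            spans.append(_event_span(replay, event))
            replay = apply_event(replay, event)
        vector = structure.copy_vector()
        return Scenario(
            events=events,
            final_structure=structure,
            final_vector=vector,
            spans_bp=tuple(spans),
            gene_dosage=gene_dosage(vector, genes),
            str_copies=str_copy_counts(structure, refmap),
            concurrent_capable=_concurrent_capable(reference, events),
        )

    def matches_observed(vector: CopyNumberVector) -> bool:
        # families compared exactly; the spacer as presence (0/1)
        return all(
            vector[f] == observed[f] for f in AMPLICON_FAMILIES
        ) and (vector.spacer > 0) == (observed.spacer > 0)

    # states: exact occurrence-label tuple -> (structure, histories reaching it)
    frontier: dict[tuple[str, ...], tuple[ChromosomeStructure, list[tuple[NAHREvent, ...]]]]
    frontier = {tuple(o.label for o in reference.occurrences): (reference, [()])}
    matches: list[Scenario] = []
    for depth in range(max_events + 1):
        for structure, histories in frontier.values():
            if matches_observed(structure.copy_vector()):
                matches.extend(finalize(events, structure) for events in histories)
        if matches or depth == max_events:
            break
        next_frontier: dict[
            tuple[str, ...], tuple[ChromosomeStructure, list[tuple[NAHREvent, ...]]]
        ] = {}
        for structure, histories in frontier.values():
            for event in enumerate_events(structure):
                child = apply_event(structure, event)
                key = tuple(o.label for o in child.occurrences)
                entry = next_frontier.setdefault(key, (child, []))
                entry[1].extend(h + (event,) for h in histories)
        frontier = next_frontier
    return matches


def scenario_span_lengths(scenario: Scenario, refmap: ReferenceMap) -> tuple[int, ...]:
    """Per-event genomic span (bp) between the exchanged copies' anchors."""
    structure = ChromosomeStructure.from_reference(refmap)
    spans = []
    for event in scenario.events:
        spans.append(_event_span(structure, event))
        structure = apply_event(structure, event)
    return tuple(spans)


def gene_dosage(
    vector: CopyNumberVector, genes: Mapping[str, GeneFamily]
) -> dict[str, int]:
    """Per-gene-family total copies implied by an amplicon copy-number vector.

    count = copies_per_host_segment x host family copies + external constant
    copies (e.g. RBMY keeps four copies outside the modelled region, so a
    chromosome with zero teal copies still carries four RBMY).
    """
    dosage: dict[str, int] = {}
    for name, gene in genes.items():
        if gene.host_family not in AMPLICON_FAMILIES:
            raise KeyError(f"gene family {name} hosted by unknown family "
                           f"{gene.host_family!r}")
        dosage[name] = (
            gene.copies_per_segment * vector[gene.host_family]
            + gene.external_constant_copies
        )
    return dosage


def str_copy_counts(
    structure_or_vector: ChromosomeStructure | CopyNumberVector,
    refmap: ReferenceMap,
) -> dict[str, int]:
    """Copies of each anchored Y-STR implied by a structure or vector.

    An STR is carried once per copy of its host segment's family (DYS448 by
    the P3 spacer, DYF387S1 by each yellow copy), so a deleted spacer means
    a null allele and four yellow copies a tetrallelic pattern.
    """
    if isinstance(structure_or_vector, ChromosomeStructure):
        vector = structure_or_vector.copy_vector()
    else:
        vector = structure_or_vector
    counts: dict[str, int] = {}
    for str_name, hosts in refmap.str_anchors.items():
        host_families = {refmap.segment(h).family for h in hosts}
        if len(host_families) != 1:
            raise ValueError(f"STR {str_name} anchored to mixed families")
        family = host_families.pop()
        counts[str_name] = vector["spacer"] if family == "spacer" else vector[family]
    return counts


def write_scenarios(scenarios: Sequence[Scenario], path: str | Path) -> None:
    """Serialise scenarios as JSON (events, spans, dosages, STR counts)."""
    payload = [
        {
            "events": [
                {
                    "kind": e.kind,
                    "mechanism": e.mechanism,
                    "left": e.left,
                    "right": e.right,
                }
                for e in sc.events
            ],
            "final_vector": sc.final_vector.as_dict(),
            "spans_bp": list(sc.spans_bp),
            "gene_dosage": dict(sc.gene_dosage),
            "str_copies": dict(sc.str_copies),
            "concurrent_capable": sc.concurrent_capable,
        }
        for sc in scenarios
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")
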