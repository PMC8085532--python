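"""Amplicon copy-number calling from sequencing read depth.

Reads in the AZFc multi-mapping families pile up on the reference copies, so
the mean depth over a family, divided by the mean depth over a 1-Mb
single-copy region of the same chromosome, is proportional to the family's
total copy number: a sample with the reference copy count shows a
normalised depth of 1, one extra copy of a two-copy family shows 1.5, and
so on.  Copies are called by midpoint thresholding between consecutive
expected values k/ref — e.g. for a two-copy family, one copy is called for
normalised depth in [0.25, 0.75) and zero copies below 0.25.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .model import (
    AMPLICON_FAMILIES,
    CopyNumberVector,
    Interval,
    ReferenceMap,
)

__all__ = [
    "DepthProfile",
    "CNVCall",
    "read_depth_table",
    "write_depth_table",
    "mean_depth",
    "normalized_depth",
    "expected_normalized_depth",
    "calling_thresholds",
    "call_copy_number",
    "call_all",
    "call_from_normalized",
    "write_calls",
]


class DepthParseError(ValueError):
    """Malformed row in a depth table."""


@dataclass
class DepthProfile:
    """Per-base depth over a declared set of intervals for one sample.

    Depth is stored as one array per declared interval; querying a position
    outside the declared intervals is an error.
    """

    sample_id: str
    arrays: dict[Interval, np.ndarray]

    def declared_intervals(self) -> tuple[Interval, ...]:
        return tuple(self.arrays)

    def values(self, interval: Interval) -> np.ndarray:
        """Per-base depth over ``interval`` (must be covered by declared intervals)."""
        pieces: list[np.ndarray] = []
        covered = interval.start
        for declared in sorted(
            (d for d in self.arrays if d.chrom == interval.chrom),
            key=lambda d: d.start,
        ):
            if declared.end <= covered or declared.start >= interval.end:
                continue
            if declared.start > covered:
                break  # gap in coverage
            lo = covered - declared.start
            hi = min(interval.end, declared.end) - declared.start
            pieces.append(self.arrays[declared][lo:hi])
            covered = declared.end
            if covered >= interval.end:
                break
        if covered < interval.end:
            raise KeyError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} is not "
                f"covered by the profile's declared intervals"
            )
        return np.concatenate(pieces) if len(pieces) != 1 else pieces[0]


def _merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of intervals so every base is counted once."""
    merged: list[Interval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(Interval(iv.chrom, iv.start, iv.end))
    return merged


def read_depth_table(
    path: str | Path,
    intervals: Sequence[Interval],
    sample_id: str | None = None,
    missing_as_zero: bool = True,
) -> DepthProfile:
    """Read per-base depth from a text table into the requested intervals.

    Two dialects are auto-detected per row: three columns
    (chrom, 1-based position, depth) or four-column bedGraph
    (chrom, 0-based start, end, depth).  Rows outside the requested
    intervals are ignored; positions inside a requested interval that have
    no row are depth 0 by default (the usual convention for depth dumps
    that omit zero rows) or NaN with ``missing_as_zero=False``.
    """
    intervals = _merge_intervals(intervals)
    fill = 0.0 if missing_as_zero else np.nan
    arrays = {iv: np.full(len(iv), fill) for iv in intervals}
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    unknown_chroms: set[str] = set()

    def deposit(chrom: str, start: int, end: int, depth: float, lineno: int) -> None:
        if chrom not in by_chrom:
            unknown_chroms.add(chrom)
            return
        if depth < 0:
            raise DepthParseError(f"line {lineno}: negative depth {depth}")
        for iv in by_chrom[chrom]:
            lo, hi = max(start, iv.start), min(end, iv.end)
            if lo < hi:
                arrays[iv][lo - iv.start : hi - iv.start] = depth

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            try:
                if len(parts) == 3:
                    chrom, pos, depth = parts[0], int(parts[1]), float(parts[2])
                    deposit(chrom, pos - 1, pos, depth, lineno)  # 1-based -> 0-based
                elif len(parts) == 4:
                    chrom, start, end, depth = (
                        parts[0], int(parts[1]), int(parts[2]), float(parts[3]),
                    )
                    deposit(chrom, start, end, depth, lineno)
                else:
                    raise ValueError(f"{len(parts)} columns")
            except DepthParseError:
                raise
            except ValueError as exc:
                raise DepthParseError(f"line {lineno}: malformed depth row ({exc})") from None
    if unknown_chroms:
        warnings.warn(
            f"skipped rows on chromosomes outside the requested intervals: "
            f"{sorted(unknown_chroms)}",
            stacklevel=2,
        )
    if sample_id is None:
        sample_id = Path(path).stem
    return DepthProfile(sample_id, arrays)


def write_depth_table(
    profile: DepthProfile, path: str | Path, dialect: str = "bedgraph"
) -> None:
    """Write a profile as bedGraph (run-length, default) or per-base rows."""
    with open(path, "w") as handle:
        for iv in sorted(profile.arrays, key=lambda i: (i.chrom, i.start)):
            vals = profile.arrays[iv]
            if dialect == "perbase":
                for offset, v in enumerate(vals):
                    handle.write(f"{iv.chrom}\t{iv.start + offset + 1}\t{v:g}\n")
            elif dialect == "bedgraph":
                # merge runs of equal depth
                change = np.flatnonzero(np.diff(vals)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(vals)]))
                for s, e in zip(starts, ends):
                    handle.write(
                        f"{iv.chrom}\t{iv.start + s}\t{iv.start + e}\t{vals[s]:g}\n"
                    )
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# depth statistics


def mean_depth(profile: DepthProfile, intervals: Sequence[Interval]) -> float:
    """Arithmetic mean per-base depth over the union of ``intervals``."""
    merged = _merge_intervals(intervals)
    if not merged:
        raise ValueError("mean_depth called with an empty interval set")
    values = np.concatenate([profile.values(iv) for iv in merged])
    return float(np.mean(values))


def normalized_depth(
    profile: DepthProfile,
    family_intervals: Sequence[Interval],
    normalization_interval: Interval,
) -> float:
    """Mean depth over all copies of a family / mean depth over the single-copy region."""
    norm = mean_depth(profile, [normalization_interval])
    if norm <= 0:
        raise ValueError(
            "single-copy normalization region has zero mean depth (degenerate control)"
        )
    return mean_depth(profile, family_intervals) / norm


def expected_normalized_depth(k: int, ref: int) -> float:
    """Expected normalised depth for ``k`` copies at reference count ``ref`` (= k/ref)."""
    if ref < 1:
        raise ValueError("reference copy count must be >= 1")
    if k < 0:
        raise ValueError("copy count must be >= 0")
    return k / ref


def calling_thresholds(ref: int, k_max: int | None = None) -> list[float]:
    """Midpoint thresholds between consecutive expected normalised depths.

    Element ``i`` is the boundary between the call ``i`` and ``i+1`` copies,
    i.e. (i + 0.5)/ref; for ref=2 the first two thresholds are 0.25 and 0.75.
    """
    if k_max is None:
        k_max = 3 * ref
    return [
        (expected_normalized_depth(k, ref) + expected_normalized_depth(k + 1, ref)) / 2
        for k in range(k_max)
    ]


def call_copy_number(nd: float, ref: int, k_max: int | None = None) -> int:
    """Call integer copies from a normalised depth by midpoint thresholding.

    ``k`` is called when nd lies in [(k-0.5)/ref, (k+0.5)/ref) — half-open,
    lower-inclusive.  Values at or above (k_max+0.5)/ref clamp to ``k_max``
    with a warning (k_max defaults to 3x the reference count).
    """
    if nd < 0:
        raise ValueError(f"normalized depth must be >= 0, got {nd}")
    if ref < 1:
        raise ValueError("reference copy count must be >= 1")
    if k_max is None:
        k_max = 3 * ref
    k = int(np.floor(nd * ref + 0.5))
    if k > k_max:
        warnings.warn(
            f"normalized depth {nd} implies {k} copies; clamped to k_max={k_max}",
            stacklevel=2,
        )
        k = k_max
    return k


@dataclass(frozen=True)
class CNVCall:
    """One family's call: normalised depth, reference count and accepted interval."""

    family: str
    normalized_depth: float
    reference_count: int
    called_copies: int
    lower_bound: float
    upper_bound: float


def _call_with_bounds(family: str, nd: float, ref: int, k_max: int | None) -> CNVCall:
    k = call_copy_number(nd, ref, k_max)
    lower = max(0.0, (k - 0.5) / ref)
    upper = (k + 0.5) / ref
    return CNVCall(family, nd, ref, k, lower, upper)


def call_all(
    profile: DepthProfile,
    refmap: ReferenceMap,
    k_max: int | None = None,
) -> tuple[list[CNVCall], CopyNumberVector]:
    """Call every amplicon family plus the P3 spacer for one sample.

    Returns the per-family calls and the assembled copy-number vector, the
    input to the NAHR scenario search.
    """
    calls: list[CNVCall] = []
    counts: dict[str, int] = {}
    for family in AMPLICON_FAMILIES:
        nd = normalized_depth(
            profile, refmap.family_intervals(family), refmap.normalization_interval
        )
        ref = len(refmap.family_segments(family))
        call = _call_with_bounds(family, nd, ref, k_max)
        calls.append(call)
        counts[family] = call.called_copies
    spacer_intervals = [s.interval for s in refmap.segments if s.family == "spacer"]
    nd = normalized_depth(profile, spacer_intervals, refmap.normalization_interval)
    call = _call_with_bounds("spacer", nd, 1, k_max)
    calls.append(call)
    counts["spacer"] = call.called_copies
    return calls, CopyNumberVector.from_mapping(counts)


def call_from_normalized(
    values: Mapping[str, float],
    refmap: ReferenceMap | None = None,
    k_max: int | None = None,
) -> CopyNumberVector:
    """Call a copy-number vector directly from printed normalised depths.

    ``values`` maps each family (and ``"spacer"``) to its normalised depth;
    reference counts come from ``refmap`` (bundled fixture by default).
    Bypasses the depth computation — useful for published tables.
    """
    refs = (
        {f: len(refmap.family_segments(f)) for f in AMPLICON_FAMILIES}
        if refmap is not None
        else {"b": 4, "t": 2, "g": 3, "r": 4, "y": 2, "Gr": 2}
    )
    refs["spacer"] = 1
    missing = set(refs) - set(values)
    if missing:
        raise KeyError(f"missing normalized depths for: {sorted(missing)}")
    counts = {
        name: call_copy_number(values[name], refs[name], k_max) for name in refs
    }
    return CopyNumberVector.from_mapping(counts)


def write_calls(
    calls: Sequence[CNVCall],
    vector: CopyNumberVector,
    calls_path: str | Path,
    vector_path: str | Path | None = None,
) -> None:
    """Write calls as TSV and (optionally) the vector as JSON."""
    with open(calls_path, "w") as handle:
        handle.write("family\tnormalized_depth\tref_count\tcalled_copies\n")
        for call in calls:
            handle.write(
                f"{call.family}\t{call.normalized_depth:.4f}\t"
                f"{call.reference_count}\t{call.called_copies}\n"
            )
    if vector_path is not None:
        Path(vector_path).write_text(json.dumps(vector.as_dict(), indent=1) + "\n")
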