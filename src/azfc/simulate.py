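"""Synthetic inputs: depth profiles under multi-mapping collapse, toy-scaled
reference maps, and Y-STR haplotypes evolved under the stepwise mutation model.

Depth model.  Short reads from near-identical amplicon copies co-align to
the reference copies of their family, so the per-base expected depth over a
family's reference segments is base_coverage x (sample copies / reference
copies); the spacer and unique/normalization segments carry base_coverage x
(their own presence).  Counting noise is Poisson per base (real data are
somewhat overdispersed; a negative-binomial option is exposed through
``dispersion``).  Default base coverage is 38.7x, a typical whole-genome
sequencing depth for this kind of study.

Haplotype model.  Each lineage evolves independently from a founder: per
generation and locus a mutation occurs with the locus rate and shifts the
allele by +/-1 with equal probability (strict single-step symmetric SMM).

Both simulators are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dating import DEFAULT_PANEL, Haplotype, default_mutation_rates
from .depth import DepthProfile
from .model import (
    AMPLICON_FAMILIES,
    CopyNumberVector,
    Interval,
    ReferenceMap,
    Segment,
    default_reference_map,
)

__all__ = [
    "DepthSimSpec",
    "simulate_depth",
    "make_toy_map",
    "default_founder",
    "simulate_star",
    "simulate_nested",
]

logger = logging.getLogger(__name__)

#: Typical WGS depth used as the default simulated coverage.
DEFAULT_COVERAGE = 38.7


@dataclass(frozen=True)
class DepthSimSpec:
    """Specification for one simulated depth profile.

    ``base_coverage`` is the haploid single-copy mean depth; ``noise`` is
    ``"poisson"`` or ``"none"`` (exact expectations, useful as a noiseless
    oracle); ``dispersion`` > 0 switches Poisson to negative binomial with
    variance mean*(1+dispersion*mean).
    """

    map: ReferenceMap
    vector: CopyNumberVector
    base_coverage: float = DEFAULT_COVERAGE
    noise: str = "poisson"
    seed: int = 0
    dispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.base_coverage <= 0:
            raise ValueError("base_coverage must be > 0")
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def _expected_multiplier(segment: Segment, vector: CopyNumberVector,
                         refmap: ReferenceMap) -> float:
    if segment.family in AMPLICON_FAMILIES:
        ref = len(refmap.family_segments(segment.family))
        return vector[segment.family] / ref
    if segment.family == "spacer":
        return float(vector.spacer)
    return 1.0  # unique sequence


def simulate_depth(spec: DepthSimSpec, sample_id: str = "sim") -> DepthProfile:
    """Simulate a per-base depth profile for a copy-number vector.

    Every base of a family's reference segments gets expectation
    base_coverage x (family copies / reference copies) — the multi-mapping
    collapse of reads from all copies onto the reference copies — and the
    normalization interval gets base_coverage.
    """
    rng = np.random.default_rng(spec.seed)
    arrays: dict[Interval, np.ndarray] = {}

    def draw(mean: float, n: int) -> np.ndarray:
        if spec.noise == "none":
            return np.full(n, mean)
        if spec.dispersion > 0:
            # NB with variance mean*(1+dispersion*mean)
            if mean == 0:
                return np.zeros(n)
            r = 1.0 / spec.dispersion
            p = r / (r + mean)
            return rng.negative_binomial(r, p, size=n).astype(float)
        return rng.poisson(mean, size=n).astype(float)

    for segment in spec.map.segments:
        mean = spec.base_coverage * _expected_multiplier(segment, spec.vector, spec.map)
        arrays[segment.interval] = draw(mean, len(segment.interval))
    ni = spec.map.normalization_interval
    arrays[ni] = draw(spec.base_coverage, len(ni))
    return DepthProfile(sample_id, arrays)


def make_toy_map(
    scale: float, refmap: ReferenceMap | None = None, min_segment_bp: int = 100
) -> ReferenceMap:
    """Rescale all map coordinates by ``scale`` for fast desk-scale tests.

    Order, family counts and span ratios are preserved; the copy-number
    vector of the map is scale-invariant.  Segments that would shrink below
    ``min_segment_bp`` raise an error.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    if refmap is None:
        refmap = default_reference_map()

    def rescale(iv: Interval) -> Interval:
        start, end = round(iv.start * scale), round(iv.end * scale)
        if end - start < min_segment_bp:
            raise ValueError(
                f"scale {scale} shrinks {iv.chrom}:{iv.start}-{iv.end} below "
                f"{min_segment_bp} bp"
            )
        return Interval(iv.chrom, start, end)

    segments = tuple(
        Segment(s.id, s.family, rescale(s.interval), s.orientation)
        for s in refmap.segments
    )
    return ReferenceMap(
        segments,
        rescale(refmap.normalization_interval),
        refmap.str_anchors,
        refmap.gene_families,
    )


# ---------------------------------------------------------------------------
# Y-STR haplotype simulation


def default_founder(panel: Sequence[str] | None = None) -> Haplotype:
    """A plausible founder haplotype: mid-range repeat counts per panel locus."""
    typical = {
        "DYS19": 14, "DYS389I": 13, "DYS390": 24, "DYS391": 10, "DYS392": 13,
        "DYS393": 13, "DYS437": 15, "DYS438": 12, "DYS439": 12, "DYS456": 15,
        "DYS458": 16, "DYS460": 11, "DYS481": 22, "DYS533": 12, "DYS635": 23,
        "YGATAH4": 12,
    }
    if panel is None:
        panel = DEFAULT_PANEL
    return Haplotype("founder", {locus: typical.get(locus, 14) for locus in panel})


def _evolve(
    alleles: np.ndarray,
    generations: int,
    rates: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve an (n_lineages, n_loci) allele matrix for ``generations``."""
    alleles = alleles.copy()
    for _ in range(generations):
        mutate = rng.random(alleles.shape) < rates
        step = rng.choice((-1, 1), size=alleles.shape)
        alleles = alleles + mutate * step
        hit_zero = alleles <= 0
        if hit_zero.any():
            # reflect: an allele cannot shrink past one repeat
            logger.warning(
                "%d allele(s) reflected off the one-repeat boundary",
                int(hit_zero.sum()),
            )
            alleles[hit_zero] += 2
    return alleles


def _rate_vector(
    rates: Mapping[str, float] | None, panel: Sequence[str]
) -> np.ndarray:
    if rates is None:
        rates = default_mutation_rates()
    missing = [locus for locus in panel if locus not in rates]
    if missing:
        raise KeyError(f"mutation-rate table lacks loci: {missing}")
    return np.array([rates[locus] for locus in panel], dtype=float)


def simulate_star(
    founder: Haplotype | None = None,
    n_tips: int = 4,
    generations: int = 20,
    rates: Mapping[str, float] | None = None,
    seed: int = 0,
    panel: Sequence[str] | None = None,
) -> list[Haplotype]:
    """Evolve ``n_tips`` independent lineages from a founder (star genealogy).

    Under this topology E[per-locus squared distance from the founder] is
    rate x generations, the identity the ASD clock inverts.
    """
    if panel is None:
        panel = DEFAULT_PANEL
    if founder is None:
        founder = default_founder(panel)
    if generations < 0:
        raise ValueError("generations must be >= 0")
    rng = np.random.default_rng(seed)
    rate_vec = _rate_vector(rates, panel)
    start = np.tile([founder[locus] for locus in panel], (n_tips, 1))
    tips = _evolve(start, generations, rate_vec, rng)
    return [
        Haplotype(f"tip{i}", dict(zip(panel, row))) for i, row in enumerate(tips)
    ]


def simulate_nested(
    founder: Haplotype | None = None,
    n_clusters: int = 2,
    tips_per_cluster: int = 4,
    stem_generations: int = 80,
    tip_generations: int = 20,
    rates: Mapping[str, float] | None = None,
    seed: int = 0,
    panel: Sequence[str] | None = None,
) -> dict[str, list[Haplotype]]:
    """Two-level genealogy: cluster founders diverge from the root, tips from them.

    Each cluster founder evolves ``stem_generations`` from the root founder,
    then ``tips_per_cluster`` lineages evolve ``tip_generations`` from it.
    Tips of one cluster coalesce at tip_generations; tips of different
    clusters at stem + tip generations, so inner cluster ages should come
    out smaller than the age of the whole sample.
    """
    if panel is None:
        panel = DEFAULT_PANEL
    if founder is None:
        founder = default_founder(panel)
    rng = np.random.default_rng(seed)
    rate_vec = _rate_vector(rates, panel)
    root = np.array([[founder[locus] for locus in panel]])
    clusters: dict[str, list[Haplotype]] = {}
    for c in range(n_clusters):
        stem = _evolve(root, stem_generations, rate_vec, rng)
        tips = _evolve(
            np.tile(stem, (tips_per_cluster, 1)), tip_generations, rate_vec, rng
        )
        clusters[f"cluster{c}"] = [
            Haplotype(f"c{c}_tip{i}", dict(zip(panel, row)))
            for i, row in enumerate(tips)
        ]
    return clusters
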