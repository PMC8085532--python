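"""Coalescence dating of Y-STR haplotype clusters by average squared distance.

Under the single-step stepwise mutation model a microsatellite drifts from
its founder allele by +/-1 repeat per mutation, so the expected squared
distance from the founder after G generations at mutation rate mu is mu*G
per locus.  Averaging the squared distance over loci (ASD) and dividing by
the mean per-locus mutation rate therefore estimates the age of a cluster
in generations:

    ASD = mean_l mean_i (a_il - f_l)^2 ,    t = ASD / mu_bar

with f the founder (here: modal) haplotype.  Times are reported in years
via an explicit generation interval (default 25 y), with a standard error
from the across-locus dispersion of the per-locus age estimates.

The default panel holds the 16 moderately mutating single-copy loci of the
Yfiler Plus kit (the multi-copy loci DYS385a/b and DYF387S1, the compound
DYS389II, DYS448 — deleted in the chromosomes this package models — and
the five rapidly mutating loci are excluded).  The bundled rate table
compiles published father–son germline estimates for those 16 loci; its
mean is 3.18e-3 mutations per locus per generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PANEL",
    "RAPIDLY_MUTATING_LOCI",
    "Haplotype",
    "ASDResult",
    "AgeEstimate",
    "load_mutation_rates",
    "default_mutation_rates",
    "read_haplotypes",
    "write_haplotypes",
    "modal_haplotype",
    "asd",
    "mean_rate",
    "coalescence_time",
    "date_cluster",
]

#: Rapidly mutating Yfiler Plus loci, excluded from clock calculations.
RAPIDLY_MUTATING_LOCI: tuple[str, ...] = (
    "DYS449", "DYS518", "DYS570", "DYS576", "DYS627",
)

#: The 16-locus dating panel (Yfiler Plus minus multi-copy/compound/RM loci
#: and DYS448).
DEFAULT_PANEL: tuple[str, ...] = (
    "DYS19", "DYS389I", "DYS390", "DYS391", "DYS392", "DYS393",
    "DYS437", "DYS438", "DYS439", "DYS456", "DYS458", "DYS460",
    "DYS481", "DYS533", "DYS635", "YGATAH4",
)


@dataclass(frozen=True)
class Haplotype:
    """A Y-STR haplotype: sample id plus locus -> integer repeat count.

    Microvariant (non-integer) alleles are rejected: squared distances in
    repeat units are undefined for partial repeats.
    """

    sample_id: str
    alleles: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for locus, allele in self.alleles.items():
            if isinstance(allele, float) and not float(allele).is_integer():
                raise ValueError(
                    f"{self.sample_id}: microvariant allele {allele} at {locus}; "
                    f"only integer repeat counts are supported"
                )
            allele = int(allele)
            if allele <= 0:
                raise ValueError(
                    f"{self.sample_id}: non-positive allele {allele} at {locus}"
                )
            clean[locus] = allele
        object.__setattr__(self, "alleles", clean)

    def __getitem__(self, locus: str) -> int:
        return self.alleles[locus]


class ASDResult(NamedTuple):
    """ASD averaged over loci plus the per-locus mean squared distances."""

    asd: float
    per_locus: dict[str, float]
    n_haplotypes: int


@dataclass(frozen=True)
class AgeEstimate:
    """A cluster age: ASD, generations, years and an across-locus SE."""

    asd: float
    t_generations: float
    t_years: float
    se_years: float
    n_haplotypes: int
    n_loci: int
    generation_years: float


# ---------------------------------------------------------------------------
# rates and haplotype I/O


def load_mutation_rates(path: str | Path) -> dict[str, float]:
    """Load a locus -> per-generation mutation-rate table from TSV."""
    frame = pd.read_csv(path, sep="\t")
    frame.columns = [c.strip() for c in frame.columns]
    locus_col, rate_col = frame.columns[:2]
    rates = dict(zip(frame[locus_col].astype(str), frame[rate_col].astype(float)))
    bad = [locus for locus, rate in rates.items() if rate <= 0]
    if bad:
        raise ValueError(f"non-positive mutation rates for loci: {bad}")
    return rates


def default_mutation_rates() -> dict[str, float]:
    """The bundled 16-locus germline rate table (panel mean 3.18e-3)."""
    with resources.as_file(
        resources.files("azfc.data").joinpath("ystr_mutation_rates.tsv")
    ) as path:
        return load_mutation_rates(path)


def read_haplotypes(path: str | Path) -> list[Haplotype]:
    """Read haplotypes from CSV/TSV: one row per sample, columns = loci."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep)
    id_col = frame.columns[0]
    loci = list(frame.columns[1:])
    return [
        Haplotype(str(row[id_col]), {locus: row[locus] for locus in loci})
        for _, row in frame.iterrows()
    ]


def write_haplotypes(haplotypes: Sequence[Haplotype], path: str | Path) -> None:
    loci = sorted({locus for h in haplotypes for locus in h.alleles})
    frame = pd.DataFrame(
        [
            {"sample_id": h.sample_id, **{l: h.alleles[l] for l in loci}}
            for h in haplotypes
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# core statistics


def _shared_panel(
    haplotypes: Sequence[Haplotype], panel: Sequence[str] | None
) -> tuple[str, ...]:
    if not haplotypes:
        raise ValueError("no haplotypes supplied")
    if panel is None:
        panel = DEFAULT_PANEL
    for h in haplotypes:
        missing = [locus for locus in panel if locus not in h.alleles]
        if missing:
            raise KeyError(f"{h.sample_id} lacks panel loci: {missing}")
    return tuple(panel)


def modal_haplotype(
    haplotypes: Sequence[Haplotype], panel: Sequence[str] | None = None
) -> Haplotype:
    """Per-locus modal allele vector, the founder estimate of a cluster.

    Ties are broken by minimising the total squared distance to all
    haplotypes, then by taking the smaller allele.
    """
    panel = _shared_panel(haplotypes, panel)
    alleles: dict[str, int] = {}
    for locus in panel:
        observed = [h[locus] for h in haplotypes]
        counts: dict[int, int] = {}
        for a in observed:
            counts[a] = counts.get(a, 0) + 1
        top = max(counts.values())
        candidates = sorted(a for a, c in counts.items() if c == top)
        if len(candidates) > 1:
            sq = {a: sum((x - a) ** 2 for x in observed) for a in candidates}
            best = min(sq.values())
            candidates = sorted(a for a in candidates if sq[a] == best)
        alleles[locus] = candidates[0]
    return Haplotype("modal", alleles)


def asd(
    haplotypes: Sequence[Haplotype],
    founder: Haplotype,
    panel: Sequence[str] | None = None,
) -> ASDResult:
    """Average squared distance of haplotypes from a founder.

    per_locus[l] = mean over haplotypes of (allele - founder allele)^2;
    asd = mean over panel loci of per_locus.
    """
    panel = _shared_panel(haplotypes, panel)
    missing = [locus for locus in panel if locus not in founder.alleles]
    if missing:
        raise KeyError(f"founder lacks panel loci: {missing}")
    per_locus = {
        locus: float(
            np.mean([(h[locus] - founder[locus]) ** 2 for h in haplotypes])
        )
        for locus in panel
    }
    return ASDResult(
        asd=float(np.mean(list(per_locus.values()))),
        per_locus=per_locus,
        n_haplotypes=len(haplotypes),
    )


def mean_rate(
    rates: Mapping[str, float], panel: Sequence[str] | None = None
) -> float:
    """Arithmetic mean mutation rate over the panel loci."""
    if panel is None:
        panel = DEFAULT_PANEL
    missing = [locus for locus in panel if locus not in rates]
    if missing:
        raise KeyError(f"mutation-rate table lacks panel loci: {missing}")
    return float(np.mean([rates[locus] for locus in panel]))


def coalescence_time(
    asd_result: ASDResult,
    rate: float,
    generation_years: float = 25.0,
) -> AgeEstimate:
    """Convert an ASD into an age: t = ASD / rate generations.

    The standard error is the across-locus standard deviation (ddof=1) of
    the per-locus age estimates divided by sqrt(n_loci), scaled to years —
    an implementation convention for the dispersion of the locus clock, not
    a sampling-theory variance.
    """
    if rate <= 0:
        raise ValueError("mean mutation rate must be > 0")
    t_generations = asd_result.asd / rate
    per_locus_t = np.array(list(asd_result.per_locus.values())) / rate
    n_loci = len(per_locus_t)
    se_gen = (
        float(np.std(per_locus_t, ddof=1)) / math.sqrt(n_loci) if n_loci > 1 else 0.0
    )
    return AgeEstimate(
        asd=asd_result.asd,
        t_generations=t_generations,
        t_years=t_generations * generation_years,
        se_years=se_gen * generation_years,
        n_haplotypes=asd_result.n_haplotypes,
        n_loci=n_loci,
        generation_years=generation_years,
    )


def date_cluster(
    haplotypes: Sequence[Haplotype],
    cluster_ids: Iterable[str],
    rates: Mapping[str, float] | None = None,
    panel: Sequence[str] | None = None,
    generation_years: float = 25.0,
    founder: Haplotype | None = None,
) -> AgeEstimate:
    """Date one haplotype cluster: modal founder -> ASD -> coalescence time.

    ``cluster_ids`` selects the member haplotypes by sample id; the founder
    defaults to the cluster's modal haplotype but may be supplied (e.g. the
    modal haplotype of a larger clade when dating an upstream node).
    """
    by_id = {h.sample_id: h for h in haplotypes}
    cluster_ids = list(cluster_ids)
    unknown = [i for i in cluster_ids if i not in by_id]
    if unknown:
        raise KeyError(f"unknown sample ids in cluster: {unknown}")
    members = [by_id[i] for i in cluster_ids]
    if rates is None:
        rates = default_mutation_rates()
    if founder is None:
        founder = modal_haplotype(members, panel)
    result = asd(members, founder, panel)
    rate = mean_rate(rates, panel)
    return coalescence_time(result, rate, generation_years)
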