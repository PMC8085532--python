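# azfc

Read-depth copy-number calling, NAHR scenario reconstruction and Y-STR
coalescence dating for the **AZFc** region of the human Y chromosome.

The AZFc (azoospermia factor c) region on Yq is built almost entirely from
six families of near-identical duplicated sequences — the amplicons *b*
(blue, 4 copies), *t* (teal, 2), *g* (green, 3), *r* (red, 4), *y*
(yellow, 2) and *Gr* (gray, 2) — interleaved with the single-copy P3
palindrome spacer (which hosts the forensic Y-STR DYS448) and IR1.  The
multi-copy Y-STR DYF387S1 sits in the two yellow amplicons.  Non-allelic
homologous recombination (NAHR) between direct repeats of a family deletes
or duplicates megabase spans, changing spermatogenesis-gene dosage and
producing unusual forensic Y-STR patterns (null alleles, tri/tetrallelic
peaks).  This package is for geneticists who see such a pattern and want to
work out, from whole-genome sequencing depth alone, what rearrangement
produced it and how old the carrier lineage is.

## What it computes

**Copy-number calling.**  Reads from all copies of an amplicon family
co-align to the reference copies, so with mean depth `d(A)` over a family
and `d(S)` over a 1-Mb single-copy region of the same chromosome the
normalised depth `n = d(A)/d(S)` estimates `k/ref` for `k` sample copies at
reference count `ref`.  Copies are called by midpoint thresholding:
`k` is called when `n ∈ [(k−½)/ref, (k+½)/ref)` — for a two-copy family,
one copy in `[0.25, 0.75)`, zero below `0.25`.  A confirmatory profile view
smooths per-base depth with an exponential moving average (window `n`,
ratio `2/(n+1)`, stepped 1 bp) and divides position-wise by the mean EMA of
control samples.

**NAHR scenario search.**  The region is an ordered list of segment
occurrences.  A deletion between direct repeats removes the intervening
span and fuses the endpoints into a hybrid copy; an interchromatidic
(unequal sister-chromatid) exchange additionally has a reciprocal
duplication product.  Given an observed copy-number vector the search
replays every ordered sequence of up to `max_events` events from the
reference structure and returns all minimal sequences that reproduce it,
with per-event spans, gene-family dosages (PRY, RBMY, BPY, DAZ, CDY hosted
by b, t, g, r, y) and implied Y-STR copy counts.

**ASD dating.**  Under the single-step stepwise mutation model the expected
squared distance of a Y-STR allele from its founder after `G` generations
at rate `μ` is `μG`.  The average squared distance from the cluster's modal
haplotype over a 16-locus panel, divided by the panel's mean rate
(3.18 × 10⁻³ per locus per generation for the bundled table), estimates the
cluster age in generations; years follow from an explicit generation
interval (default 25 y).

## Worked example

```python
from azfc import CopyNumberVector, call_from_normalized, default_reference_map, search_scenarios

refmap = default_reference_map()
measured = {"b": 0.983, "t": 0.076, "g": 1.589, "r": 1.475, "y": 1.962,
            "Gr": 0.966, "spacer": 0.022}
vector = call_from_normalized(measured, refmap)
print(vector.as_dict())
for sc in search_scenarios(refmap, vector, max_events=2):
    print([str(e) for e in sc.events], [f"{s/1e6:.1f} Mb" for s in sc.spans_bp])
```

prints

```
{'b': 4, 't': 0, 'g': 5, 'r': 6, 'y': 4, 'Gr': 2, 'spacer': 0}
['dup(b2/b4, interchromatidic)', 'del(b1/b3, intrachromatidic)'] ['3.5 Mb', '1.6 Mb']
['dup(b2/b4, interchromatidic)', 'del(b1/b3, interchromatidic)'] ['3.5 Mb', '1.6 Mb']
```

The measured depths call a chromosome with both teal copies and the P3
spacer deleted, two extra green and red copies and a doubled yellow family.
Exactly two minimal event sequences explain it — a 3.5-Mb b2/b4 duplication
followed (or accompanied, on sister chromatids) by a 1.6-Mb b1/b3 deletion;
no deletion-first ordering is possible.  The scenario objects also report
the consequences: RBMY drops from six to four copies, BPY/DAZ/CDY gain two
each, PRY is unchanged, DYS448 is nulled and DYF387S1 becomes tetrallelic.

The `examples/` directory holds one short script per capability
(depth calling, EMA profiling, scenario search, dating), each printing the
numbers it computes with a note on what they mean.  A thin CLI wraps the
same functions: `azfc call-cnv`, `azfc ema`, `azfc infer-nahr`,
`azfc date-cluster`, `azfc simulate-depth`, `azfc simulate-haplotypes`.

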