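"""NAHR event algebra and exhaustive scenario search.

The search is cross-checked against an independent brute-force oracle that
enumerates every ordered event sequence with its own minimal structure
representation (plain tuples, no shared code with the package).
"""

import itertools
import re

import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from azfc.model import CopyNumberVector
from azfc.nahr import (
    ChromosomeStructure,
    NAHREvent,
    apply_event,
    enumerate_events,
    gene_dosage,
    scenario_span_lengths,
    search_scenarios,
    sister_products,
    str_copy_counts,
)

FAMILIES = ("b", "t", "g", "r", "y", "Gr")


# ---------------------------------------------------------------------------
# independent oracle: structures are tuples of (label, family, orientation)


def oracle_reference(refmap):
    return tuple((s.id, s.family, s.orientation) for s in refmap.segments)


def oracle_events(structure):
    events = []
    for i, j in itertools.combinations(range(len(structure)), 2):
        (_, fam_a, ori_a), (_, fam_b, ori_b) = structure[i], structure[j]
        if fam_a in FAMILIES and fam_a == fam_b and ori_a == ori_b:
            events.append(("deletion", "intrachromatidic", i, j))
            events.append(("deletion", "interchromatidic", i, j))
            events.append(("duplication", "interchromatidic", i, j))
    return events


def oracle_apply(structure, event):
    kind, _, i, j = event
    left, right = structure[i], structure[j]
    if kind == "deletion":
        hybrid = (f"{left[0]}/{right[0]}", left[1], left[2])
        return structure[:i] + (hybrid,) + structure[j + 1 :]
    hybrid = (f"{right[0]}/{left[0]}", left[1], left[2])
    between = structure[i + 1 : j]
    copies = tuple((f"{lab}#", fam, ori) for lab, fam, ori in between)
    return structure[: i + 1] + between + (hybrid,) + copies + structure[j:]


def oracle_vector(structure):
    counts = {f: 0 for f in FAMILIES}
    spacer = 0
    for _, family, _ in structure:
        if family in counts:
            counts[family] += 1
        elif family == "spacer":
            spacer += 1
    return (*(counts[f] for f in FAMILIES), spacer)


def oracle_search(refmap, observed, max_events):
    """All minimal event sequences whose final vector matches ``observed``."""
    target = observed.as_tuple()

    def matches(structure):
        vec = oracle_vector(structure)
        return vec[:6] == target[:6] and (vec[6] > 0) == (target[6] > 0)

    frontier = [((), oracle_reference(refmap))]
    for depth in range(max_events + 1):
        found = [seq for seq, s in frontier if matches(s)]
        if found or depth == max_events:
            return found
        frontier = [
            (seq + ((kind, mech, s[i][0], s[j][0]),), oracle_apply(s, (kind, mech, i, j)))
            for seq, s in frontier
            for kind, mech, i, j in oracle_events(s)
        ]
    return []


def strip_copies(label):
    return re.sub(r"[@#]\d*", "", label)


def signature(events):
    return tuple(
        (e.kind, e.mechanism, strip_copies(e.left), strip_copies(e.right))
        for e in events
    )


# ---------------------------------------------------------------------------


class TestEnumerateEvents:
    def test_four_direct_copies_give_eighteen_events(self, refmap):
        # the red family: four copies, all in the same orientation -> C(4,2)=6
        # pairs x (del-intra, del-inter, dup-inter)
        structure = ChromosomeStructure.from_reference(refmap)
        r_events = [e for e in enumerate_events(structure) if e.left.startswith("r")]
        assert len(r_events) == 18

    def test_opposite_orientation_copies_do_not_pair(self, refmap):
        # b1/b3 are direct to each other, b2/b4 to each other, but the two
        # pairs are mutually inverted: no b1/b2, b1/b4, b2/b3, b3/b4 events
        structure = ChromosomeStructure.from_reference(refmap)
        b_pairs = {
            (e.left, e.right)
            for e in enumerate_events(structure)
            if e.left.startswith("b")
        }
        assert b_pairs == {("b1", "b3"), ("b2", "b4")}

    def test_single_remaining_copy_has_no_events(self, refmap):
        structure = ChromosomeStructure.from_reference(refmap)
        after = apply_event(
            structure, NAHREvent("deletion", "intrachromatidic", "b1", "b3")
        )
        assert not any(
            e for e in enumerate_events(after) if e.left.split("/")[0].startswith("b")
        )

    def test_matches_oracle_on_reference(self, refmap):
        structure = ChromosomeStructure.from_reference(refmap)
        ours = enumerate_events(structure)
        theirs = oracle_events(oracle_reference(refmap))
        assert len(ours) == len(theirs)


class TestApplyEvent:
    def test_duplication_b2_b4_family_counts(self, refmap):
        structure = ChromosomeStructure.from_reference(refmap)
        product = apply_event(
            structure, NAHREvent("duplication", "interchromatidic", "b2", "b4")
        )
        assert product.copy_vector().as_tuple() == (6, 2, 6, 8, 4, 2, 1)

    def test_deletion_b1_b3_after_duplication_gives_observed_vector(
        self, refmap, rearranged_vector
    ):
        structure = ChromosomeStructure.from_reference(refmap)
        product = apply_event(
            structure, NAHREvent("duplication", "interchromatidic", "b2", "b4")
        )
        product = apply_event(
            product, NAHREvent("deletion", "interchromatidic", "b1", "b3")
        )
        assert product.copy_vector() == rearranged_vector

    def test_deletion_between_adjacent_copies_leaves_single_hybrid(self, refmap):
        structure = ChromosomeStructure.from_reference(refmap)
        product = apply_event(
            structure, NAHREvent("deletion", "intrachromatidic", "r3", "r4")
        )
        assert len(product.occurrences) == len(structure.occurrences) - 1
        hybrid = product.occurrences[product.index_of("r3/r4")]
        assert hybrid.family == "r" and hybrid.is_hybrid

    def test_stale_occurrence_id_raises(self, refmap):
        structure = ChromosomeStructure.from_reference(refmap)
        after = apply_event(
            structure, NAHREvent("deletion", "intrachromatidic", "b1", "b3")
        )
        with pytest.raises(KeyError, match="b2"):
            apply_event(after, NAHREvent("deletion", "intrachromatidic", "b2", "b4"))

    def test_hybrid_is_usable_substrate_for_further_events(self, refmap):
        structure = ChromosomeStructure.from_reference(refmap)
        after = apply_event(
            structure, NAHREvent("deletion", "interchromatidic", "r1", "r2")
        )
        labels = [e.left for e in enumerate_events(after)] + [
            e.right for e in enumerate_events(after)
        ]
        assert "r1/r2" in labels


class TestSisterProducts:
    def test_b2_b4_exchange_products(self, refmap):
        structure = ChromosomeStructure.from_reference(refmap)
        deleted, duplicated = sister_products(
            structure, NAHREvent("duplication", "interchromatidic", "b2", "b4")
        )
        assert duplicated.copy_vector().as_tuple() == (6, 2, 6, 8, 4, 2, 1)
        # deletion product loses the whole b2..b4 interior; b1 plus the
        # b2/b4 hybrid are the only blue copies left
        assert deleted.copy_vector().as_tuple() == (2, 2, 0, 0, 0, 2, 1)

    def test_intrachromatidic_event_raises(self, refmap):
        structure = ChromosomeStructure.from_reference(refmap)
        with pytest.raises(ValueError, match="interchromatidic"):
            sister_products(
                structure, NAHREvent("deletion", "intrachromatidic", "b1", "b3")
            )

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_conservation_of_family_counts(self, refmap, data):
        """del product + dup product = 2 x parent, for every family."""
        structure = ChromosomeStructure.from_reference(refmap)
        # optionally pre-apply one random event so parents vary
        first = data.draw(
            st.sampled_from(enumerate_events(structure)), label="first_event"
        )
        parent = apply_event(structure, first)
        inter = [e for e in enumerate_events(parent) if e.mechanism == "interchromatidic"]
        assume(inter)
        event = data.draw(st.sampled_from(inter), label="exchange")
        deleted, duplicated = sister_products(parent, event)
        pv, dv, uv = (
            parent.copy_vector(), deleted.copy_vector(), duplicated.copy_vector()
        )
        for family in (*FAMILIES, "spacer"):
            assert dv[family] + uv[family] == 2 * pv[family]

    def test_spacer_in_both_products_iff_outside_span(self, refmap):
        structure = ChromosomeStructure.from_reference(refmap)
        # spacer inside the b1..b3 span: lost from the deletion product
        deleted, duplicated = sister_products(
            structure, NAHREvent("deletion", "interchromatidic", "b1", "b3")
        )
        assert deleted.copy_vector().spacer == 0
        assert duplicated.copy_vector().spacer == 2
        # spacer outside the r3..r4 span: present once in both
        deleted, duplicated = sister_products(
            structure, NAHREvent("deletion", "interchromatidic", "r3", "r4")
        )
        assert deleted.copy_vector().spacer == 1
        assert duplicated.copy_vector().spacer == 1


class TestSearchScenarios:
    def test_reference_vector_yields_single_empty_scenario(self, refmap,
                                                           reference_vector):
        scenarios = search_scenarios(refmap, reference_vector, max_events=2)
        assert len(scenarios) == 1
        assert scenarios[0].events == ()

    def test_observed_vector_gives_dup_then_del_only(self, refmap,
                                                     rearranged_vector):
        scenarios = search_scenarios(refmap, rearranged_vector, max_events=2)
        signatures = {signature(sc.events) for sc in scenarios}
        assert signatures == {
            (
                ("duplication", "interchromatidic", "b2", "b4"),
                ("deletion", "intrachromatidic", "b1", "b3"),
            ),
            (
                ("duplication", "interchromatidic", "b2", "b4"),
                ("deletion", "interchromatidic", "b1", "b3"),
            ),
        }
        assert all(sc.events[0].kind == "duplication" for sc in scenarios)
        assert all(sc.concurrent_capable for sc in scenarios)

    def test_deletion_first_cannot_be_followed_by_duplication(self, refmap):
        structure = ChromosomeStructure.from_reference(refmap)
        after_del = apply_event(
            structure, NAHREvent("deletion", "interchromatidic", "b1", "b3")
        )
        kinds = {
            (e.kind, e.left.split("/")[0][0]) for e in enumerate_events(after_del)
        }
        assert ("duplication", "b") not in kinds

    def test_doubled_y_alone_is_unreachable_in_two_events(self, refmap):
        observed = CopyNumberVector(4, 2, 3, 4, 4, 2, 1)
        assert search_scenarios(refmap, observed, max_events=2) == []

    @pytest.mark.parametrize(
        "observed",
        [
            CopyNumberVector(4, 0, 5, 6, 4, 2, 0),
            CopyNumberVector(4, 2, 3, 4, 4, 2, 1),
            CopyNumberVector(3, 0, 0, 0, 0, 2, 0),
            CopyNumberVector(6, 2, 6, 8, 4, 2, 1),
            CopyNumberVector(4, 2, 3, 3, 2, 2, 1),
        ],
        ids=["observed", "y-doubled", "b2b4-del-product", "b2b4-dup", "r-del"],
    )
    def test_search_equals_brute_force_oracle(self, refmap, observed):
        ours = {
            signature(sc.events)
            for sc in search_scenarios(refmap, observed, max_events=2)
        }
        theirs = {
            tuple((k, m, strip_copies(l), strip_copies(r)) for k, m, l, r in seq)
            for seq in oracle_search(refmap, observed, max_events=2)
        }
        assert ours == theirs

    def test_replay_reproduces_final_structure(self, refmap, rearranged_vector):
        for sc in search_scenarios(refmap, rearranged_vector, max_events=2):
            replayed = sc.replay(refmap)
            assert replayed.canonical() == sc.final_structure.canonical()
            assert replayed.copy_vector() == sc.final_vector

    def test_length_changes_by_event_span(self, refmap):
        structure = ChromosomeStructure.from_reference(refmap)
        event = NAHREvent("duplication", "interchromatidic", "b2", "b4")
        product = apply_event(structure, event)
        # duplication strictly grows the modelled content
        assert len(product.occurrences) > len(structure.occurrences)
        deletion = apply_event(
            structure, NAHREvent("deletion", "interchromatidic", "b1", "b3")
        )
        assert len(deletion.occurrences) < len(structure.occurrences)

    def test_max_events_above_hard_limit_raises(self, refmap, reference_vector):
        with pytest.raises(ValueError, match="hard limit"):
            search_scenarios(refmap, reference_vector, max_events=4)


class TestSpansDosagesAndSTRs:
    def test_scenario_spans_match_fixture_distances(self, refmap,
                                                    rearranged_vector):
        for sc in search_scenarios(refmap, rearranged_vector, max_events=2):
            spans = scenario_span_lengths(sc, refmap)
            assert spans == sc.spans_bp
            assert spans[0] == 3_500_000  # duplication
            assert spans[1] == 1_600_000  # deletion

    def test_span_between_adjacent_zero_gap_copies(self, refmap):
        structure = ChromosomeStructure.from_reference(refmap)
        scenarios = search_scenarios(
            refmap, CopyNumberVector(4, 2, 3, 3, 2, 2, 1), max_events=2
        )
        r3 = refmap.segment("r3").interval
        for sc in scenarios:
            if signature(sc.events)[0][2:] == ("r3", "r4"):
                assert sc.spans_bp[0] == len(r3)

    def test_reference_gene_dosage(self, refmap, reference_vector):
        dosage = gene_dosage(reference_vector, refmap.gene_families)
        assert dosage == {"PRY": 4, "RBMY": 6, "BPY": 3, "DAZ": 4, "CDY": 2}

    def test_rearranged_gene_dosage(self, refmap, rearranged_vector):
        dosage = gene_dosage(rearranged_vector, refmap.gene_families)
        assert dosage == {"PRY": 4, "RBMY": 4, "BPY": 5, "DAZ": 6, "CDY": 4}

    def test_all_zero_vector_keeps_only_external_copies(self, refmap):
        dosage = gene_dosage(
            CopyNumberVector(0, 0, 0, 0, 0, 0, 0), refmap.gene_families
        )
        assert dosage == {"PRY": 0, "RBMY": 4, "BPY": 0, "DAZ": 0, "CDY": 0}

    def test_reference_str_counts(self, refmap):
        structure = ChromosomeStructure.from_reference(refmap)
        assert str_copy_counts(structure, refmap) == {"DYS448": 1, "DYF387S1": 2}

    def test_rearranged_str_counts_null_allele_and_tetrallelic(
        self, refmap, rearranged_vector
    ):
        scenarios = search_scenarios(refmap, rearranged_vector, max_events=2)
        for sc in scenarios:
            assert sc.str_copies == {"DYS448": 0, "DYF387S1": 4}

    def test_teal_deletion_removes_spacer_but_not_y(self, refmap):
        structure = ChromosomeStructure.from_reference(refmap)
        after = apply_event(
            structure, NAHREvent("deletion", "intrachromatidic", "t1", "t2")
        )
        assert str_copy_counts(after, refmap) == {"DYS448": 0, "DYF387S1": 2}
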