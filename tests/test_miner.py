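"""Element mining: structural detection, homology recovery, classification."""

import itertools

import numpy as np
import pytest

import ltrtrace as lt
from ltrtrace.errors import DegenerateSequenceError
from ltrtrace.miner import CATEGORIES, HitGeometry, MinerParams
from ltrtrace.seqcore import reverse_complement


def _by_span(annotations):
    return {(a.start, a.end): a for a in annotations}


class TestDetectIntact:
    def test_zero_age_recall_and_exact_coordinates(self, zero_age_sim):
        anns = lt.detect_intact_elements(zero_age_sim.genome, zero_age_sim.model)
        truth = {
            (t.start, t.end): t
            for t in zero_age_sim.truth
            if t.category == "intact_with_tsd"
        }
        found = _by_span(anns)
        assert set(truth) <= set(found)
        for span, t in truth.items():
            a = found[span]
            assert a.category == "intact_with_tsd"
            assert a.tsd_seq == t.tsd_seq
            assert a.ltr5 == t.ltr5 and a.ltr3 == t.ltr3
            assert a.termini == t.termini
            assert a.pbs_ok and a.ppt_ok

    def test_random_genome_yields_nothing(self):
        rng = np.random.default_rng(123)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100_000))
        anns = lt.detect_intact_elements({"chr1": seq}, lt.ElementModel())
        assert anns == []

    def test_broken_tsd_gives_intact_no_tsd(self, zero_age_sim):
        t = next(x for x in zero_age_sim.truth if x.category == "intact_with_tsd")
        seq = zero_age_sim.genome[t.chrom]
        s0 = t.start - 1
        # corrupt the upstream TSD copy so the 5-mers no longer match
        old = seq[s0 - 5]
        new = "A" if old != "A" else "C"
        mutated = seq[: s0 - 5] + new + seq[s0 - 4 :]
        anns = lt.detect_intact_elements({t.chrom: mutated}, zero_age_sim.model)
        hit = [a for a in anns if abs(a.start - t.start) < 30 and abs(a.end - t.end) < 30]
        assert len(hit) == 1
        assert hit[0].category == "intact_no_tsd"
        assert hit[0].tsd_seq is None

    def test_no_overlapping_annotations(self, zero_age_sim):
        anns = lt.mine_genome(zero_age_sim.genome, zero_age_sim.model)
        params = MinerParams()
        for a, b in itertools.combinations(anns, 2):
            if a.chrom != b.chrom:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start) + 1
            assert ov <= params.merge_tolerance

    def test_empty_genome_raises(self):
        with pytest.raises(DegenerateSequenceError):
            lt.detect_intact_elements({"c": ""}, lt.ElementModel())


class TestHomologyRecovery:
    def test_solo_and_truncated_recovered(self, zero_age_sim):
        intact = lt.detect_intact_elements(zero_age_sim.genome, zero_age_sim.model)
        extra = lt.recover_by_homology(zero_age_sim.genome, zero_age_sim.model, intact)
        got = {(a.start, a.end): a.category for a in extra}
        for t in zero_age_sim.truth:
            if t.category == "solo_with_tsd":
                assert got.get((t.start, t.end)) == "solo_with_tsd"
            elif t.category.startswith("trunc"):
                match = [
                    c for (s, e), c in got.items()
                    if abs(s - t.start) <= 15 and abs(e - t.end) <= 15
                ]
                assert match == [t.category]

    def test_internal_only_fragment_is_trunc_bothdel(self, zero_age_sim):
        model = zero_age_sim.model
        rng = np.random.default_rng(9)
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 40_000))
        frag = model.internal_consensus[100:3000]
        genome = {"c": bg[:20_000] + frag + bg[20_000:]}
        anns = lt.recover_by_homology(genome, model, [])
        assert len(anns) == 1
        assert anns[0].category == "trunc_bothdel"
        assert anns[0].ltr5 is None and anns[0].ltr3 is None

    def test_reverse_strand_solo(self, zero_age_sim):
        model = zero_age_sim.model
        rng = np.random.default_rng(10)
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 30_000))
        tsd = "GATCA"
        insert = tsd + reverse_complement(model.ltr_consensus) + tsd
        genome = {"c": bg[:15_000] + insert + bg[15_000:]}
        anns = lt.recover_by_homology(genome, model, [])
        assert len(anns) == 1
        assert anns[0].strand == "-"
        assert anns[0].category.startswith("solo")


class TestClassification:
    def test_mapping_is_total_and_deterministic(self):
        states = ("complete", "partial", "absent")
        for l5, l3, internal, tsd in itertools.product(states, states, (True, False), (True, False)):
            geom = HitGeometry(l5, l3, internal, tsd)
            if l5 == l3 == "absent" and not internal:
                with pytest.raises(ValueError):
                    lt.classify_structure(geom)
                continue
            cat = lt.classify_structure(geom)
            assert cat in CATEGORIES + ("unresolved",)
            assert cat == lt.classify_structure(geom)

    @pytest.mark.parametrize(
        "geom,expected",
        [
            (HitGeometry("complete", "complete", True, True), "intact_with_tsd"),
            (HitGeometry("complete", "complete", True, False), "intact_no_tsd"),
            (HitGeometry("complete", "absent", False, True), "solo_with_tsd"),
            (HitGeometry("complete", "partial", True, False), "trunc_3del"),
            (HitGeometry("partial", "complete", True, True), "trunc_5del"),
            (HitGeometry("absent", "absent", True, False), "trunc_bothdel"),
            (HitGeometry("complete", "complete", False, True), "unresolved"),
        ],
    )
    def test_specific_geometries(self, geom, expected):
        assert lt.classify_structure(geom) == expected


class TestSummaries:
    def test_published_style_counts_total(self):
        counts = dict(
            zip(
                CATEGORIES,
                (180, 12, 10, 7, 67, 45, 33),
            )
        )
        summary = lt.summary_from_counts(counts)
        assert summary.total == 354
        assert summary.solo_to_intact_ratio == round(10 / 180, 2)

    def test_ratio_denominator_switch(self):
        counts = {"intact_with_tsd": 180, "intact_no_tsd": 12, "solo_with_tsd": 10}
        assert lt.summary_from_counts(counts, "intact_all").solo_to_intact_ratio == round(
            10 / 192, 2
        )

    def test_empty_counts_ratio_na(self):
        summary = lt.summary_from_counts({})
        assert summary.total == 0
        assert summary.solo_to_intact_ratio is None

    def test_summary_matches_annotation_list(self, zero_age_sim):
        anns = lt.mine_genome(zero_age_sim.genome, zero_age_sim.model)
        summary = lt.summarize_structures(anns)
        assert summary.total == len(anns) - summary.unresolved


class TestTerminiCensus:
    def test_counts_planted_termini(self, zero_age_sim):
        anns = lt.detect_intact_elements(zero_age_sim.genome, zero_age_sim.model)
        census = lt.termini_census(anns)
        n_intact = sum(1 for t in zero_age_sim.truth if t.category.startswith("intact"))
        assert census == {"TA..CA": n_intact}

    def test_mixed_termini_counted_separately(self):
        anns = [
            lt.LtrElementAnnotation("e1", "c", 1, 100, termini="TA..CA"),
            lt.LtrElementAnnotation("e2", "c", 200, 300, termini="TG..CA"),
            lt.LtrElementAnnotation("e3", "c", 400, 500, termini="TA..CG"),
            lt.LtrElementAnnotation("e4", "c", 600, 700, termini="TA..CA"),
            lt.LtrElementAnnotation("e5", "c", 800, 900, termini="??..CA"),
        ]
        census = lt.termini_census(anns)
        assert census == {"TA..CA": 2, "TG..CA": 1, "TA..CG": 1}
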