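"""Registry arithmetic, leave-one-out selection, scoring, class means."""

import warnings

import numpy as np
import pandas as pd
import pytest

from gh9class import profiles, synthetic
from gh9class.profiles import (
    AlignmentError, ClassMeanTriple, DegenerateScoreError, ProfileRegistry,
    RegistryError, SearchConfig, TrainingSequence,
)


class TestRegistryArithmetic:
    def test_published_training_counts(self):
        """n = (6, 16, 4) gives 12/32/8 leave-one-out profiles, 60 total."""
        reg = ProfileRegistry.from_training_counts(6, 16, 4)
        counts = reg.counts()
        assert counts[("loocv", "A")] == 12
        assert counts[("loocv", "B")] == 32
        assert counts[("loocv", "C")] == 8
        assert counts[("generic", "X")] == 2
        assert sum(counts[("class", c)] for c in "ABC") == 6
        assert len(reg.profiles) == 60

    def test_symmetric_counts(self):
        reg = ProfileRegistry.from_training_counts(3, 3, 3)
        assert sum(v for (s, _), v in reg.counts().items() if s == "loocv") == 18

    def test_single_member_class_rejected(self):
        with pytest.raises(RegistryError):
            ProfileRegistry.from_training_counts(1, 3, 3)

    def test_duplicate_ids_rejected(self):
        p = profiles.ProfileHMM("dup", "generic", "X", "1D")
        q = profiles.ProfileHMM("dup", "generic", "X", "3D")
        with pytest.raises(RegistryError):
            ProfileRegistry([p, q])


class TestSelectLoocv:
    @pytest.mark.parametrize("cls,retained,frac", [
        ("A", 42, 0.72), ("B", 22, 0.38), ("C", 46, 0.79),
    ])
    def test_published_retained_counts_and_fractions(self, cls, retained, frac):
        reg = ProfileRegistry.from_training_counts(6, 16, 4)
        uid = reg.select("loocv", cls)[0].excluded_uid
        sel = profiles.select_loocv(uid, cls, reg)
        assert len(sel.retained_profile_ids) == retained
        assert round(sel.delta_fraction, 2) == frac

    @pytest.mark.parametrize("n", [(3, 3, 3), (2, 5, 3), (4, 2, 6)])
    def test_equals_brute_force_enumeration(self, n):
        """Selection matches filtering 'excluded_uid = target or other class'."""
        reg = ProfileRegistry.from_training_counts(*n)
        for cls in "ABC":
            for target in {p.excluded_uid for p in reg.select("loocv", cls)}:
                sel = profiles.select_loocv(target, cls, reg)
                brute = sorted(
                    p.profile_id for p in reg.select("loocv")
                    if p.class_label != cls or p.excluded_uid == target)
                assert list(sel.retained_profile_ids) == brute
                assert sel.delta_fraction == len(brute) / reg.n_class_specific()

    def test_symmetric_counts_give_fourteen(self):
        reg = ProfileRegistry.from_training_counts(3, 3, 3)
        for cls in "ABC":
            uid = reg.select("loocv", cls)[0].excluded_uid
            assert len(profiles.select_loocv(uid, cls, reg).retained_profile_ids) == 14

    def test_unknown_target_raises(self):
        reg = ProfileRegistry.from_training_counts(3, 3, 3)
        with pytest.raises(KeyError):
            profiles.select_loocv("nope", "A", reg)


def make_row(registry, values):
    cols = [p.profile_id for p in registry.scoring_profiles()]
    row = pd.Series(np.nan, index=cols, name="seq")
    for pid, v in values.items():
        row[pid] = v
    return row


class TestClassMeans:
    def test_generic_mean_of_identical_pair(self):
        reg = ProfileRegistry.from_training_counts(2, 2, 2)
        row = make_row(reg, {"cls-A-1d": 300.0, "cls-A-3d": 300.0,
                             "cls-B-1d": 410.0, "cls-B-3d": 390.0,
                             "cls-C-1d": 100.0, "cls-C-3d": 200.0})
        t = profiles.class_means(row, reg, "generic")
        assert t.hmm_a == 300.0 and t.hmm_b == 400.0 and t.hmm_c == 150.0
        assert t.side_means["B"] == (410.0, 390.0)

    def test_column_order_invariance(self):
        reg = ProfileRegistry.from_training_counts(2, 2, 2)
        vals = {"cls-A-1d": 1.0, "cls-A-3d": 3.0, "cls-B-1d": 5.0,
                "cls-B-3d": 7.0, "cls-C-1d": 9.0, "cls-C-3d": 11.0}
        row = make_row(reg, vals)
        shuffled = row[list(reversed(row.index))]
        a = profiles.class_means(row, reg, "generic")
        b = profiles.class_means(shuffled, reg, "generic")
        assert a.as_dict() == b.as_dict()

    def test_loocv_contributing_counts_match_selection(self):
        """A class-C target averages 2 own-pair, 12 class-A, 32 class-B scores."""
        reg = ProfileRegistry.from_training_counts(6, 16, 4)
        uid = reg.select("loocv", "C")[0].excluded_uid
        sel = profiles.select_loocv(uid, "C", reg)
        row = pd.Series(100.0, index=[p.profile_id for p in reg.scoring_profiles()],
                        name=uid)
        t = profiles.class_means(row, reg, "loocv", sel)
        assert len(t.contributing["A"]) == 12
        assert len(t.contributing["B"]) == 32
        assert len(t.contributing["C"]) == 2

    def test_missing_whole_class_is_degenerate(self):
        reg = ProfileRegistry.from_training_counts(2, 2, 2)
        row = make_row(reg, {"cls-A-1d": 1.0, "cls-A-3d": 3.0,
                             "cls-B-1d": 5.0, "cls-B-3d": 7.0})
        with pytest.raises(DegenerateScoreError):
            profiles.class_means(row, reg, "generic")

    def test_partial_missing_zeroed_with_warning(self):
        reg = ProfileRegistry.from_training_counts(2, 2, 2)
        row = make_row(reg, {"cls-A-1d": 100.0, "cls-B-1d": 5.0, "cls-B-3d": 7.0,
                             "cls-C-1d": 9.0, "cls-C-3d": 11.0})
        with pytest.warns(UserWarning, match="missing"):
            t = profiles.class_means(row, reg, "generic")
        assert t.hmm_a == 50.0  # (100 + 0) / 2

    def test_loocv_requires_selection(self):
        reg = ProfileRegistry.from_training_counts(2, 2, 2)
        row = make_row(reg, {})
        with pytest.raises(ValueError):
            profiles.class_means(row, reg, "loocv")


class TestMaxClass:
    @pytest.mark.parametrize("means,label,amb", [
        ((300.0, 250.0, 200.0), "A", False),
        ((100.0, 400.0, 395.0), "B", False),
        ((100.0, 200.0, 200.0), None, True),
    ])
    def test_strict_maximum_with_tie_flag(self, means, label, amb):
        t = ClassMeanTriple(*means, "generic", {}, {})
        res = profiles.max_class(t)
        assert res.label == label and res.ambiguous is amb


class TestEngineBacked:
    """Profile building and scoring through the HMM engine."""

    def test_gapless_alignment_model_length_bounded(self):
        rows = [(f"s{i}", "MKVLLTAGHGLEWKDFARNQ" * 2 + "DEKLMNPQRS") for i in range(4)]
        p = profiles.build_profile(rows, "toy", "generic", "X", "1D")
        assert 0 < p.model_length <= 50

    def test_ragged_or_tiny_alignment_rejected(self):
        with pytest.raises(AlignmentError):
            profiles.build_profile([("a", "MKV"), ("b", "MK")], "x", "class", "A", "1D")
        with pytest.raises(AlignmentError):
            profiles.build_profile([("a", "MKV")], "x", "class", "A", "1D")

    def test_registry_structure_from_family(self, small_family, small_registry):
        spec, records, _ = small_family
        small_registry.validate_structure({c: 4 for c in "ABC"})
        assert len(small_registry.profiles) == 2 + 6 + 2 * 12

    def test_profiles_score_own_members_at_class_threshold(self, small_family,
                                                           small_registry):
        _, records, _ = small_family
        seqs = {r.uid: r.residues for r in records}
        table = profiles.score_profiles(seqs, small_registry, SearchConfig())
        for cls in "ABC":
            pid = f"cls-{cls}-1d"
            members = [r.uid for r in records if r.class_label == cls]
            assert table.loc[members, pid].notna().all()

    def test_screen_retains_family_and_drops_random_negatives(
            self, small_family, small_registry, rng):
        _, records, _ = small_family
        seqs = {r.uid: r.residues for r in records}
        negatives = {f"neg{i}": "".join(rng.choice(list(synthetic.AA20), 100))
                     for i in range(5)}
        hits = profiles.screen_homologs({**seqs, **negatives}, small_registry,
                                        SearchConfig())
        assert {r.uid for r in records} <= hits
        assert not hits & set(negatives)

    def test_screen_empty_proteome(self, small_registry):
        assert profiles.screen_homologs({}, small_registry, SearchConfig()) == set()

    def test_scoring_is_deterministic(self, small_family, small_registry):
        _, records, _ = small_family
        seqs = {r.uid: r.residues for r in records[:3]}
        t1 = profiles.score_profiles(seqs, small_registry)
        t2 = profiles.score_profiles(seqs, small_registry)
        pd.testing.assert_frame_equal(t1, t2)

    def test_best_region_score_is_max_over_domains(self, small_family,
                                                   small_registry):
        """A duplicated-architecture query yields multiple domains; the
        table cell equals the largest domain score reported by the engine."""
        import pyhmmer
        _, records, _ = small_family
        rec = records[0]
        dup = {"dup": rec.residues + "GGGGGGGGGG" + rec.residues}
        profile = small_registry.by_id("cls-A-1d")
        alphabet = pyhmmer.easel.Alphabet.amino()
        block = pyhmmer.easel.DigitalSequenceBlock(alphabet, [
            pyhmmer.easel.TextSequence(name=b"dup",
                                       sequence=dup["dup"]).digitize(alphabet)])
        pipe = pyhmmer.plan7.Pipeline(alphabet,
                                      background=pyhmmer.plan7.Background(alphabet),
                                      E=1e-6, domE=1e-6)
        hits = pipe.search_hmm(profile.hmm, block)
        domain_scores = [d.score for h in hits for d in h.domains]
        assert len(domain_scores) >= 2  # engine saw both copies
        table = profiles.score_profiles(dup, small_registry)
        assert table.loc["dup", "cls-A-1d"] == pytest.approx(max(domain_scores))

    def test_no_hit_cell_is_missing(self, small_registry, rng):
        junk = {"junk": "".join(rng.choice(list("PGKD"), 60))}
        table = profiles.score_profiles(junk, small_registry)
        assert table.loc["junk"].isna().all()


class TestTrainingSequenceValidation:
    def test_alphabet_and_label_checks(self):
        with pytest.raises(ValueError):
            TrainingSequence("u1", "D", "MKV")
        with pytest.raises(ValueError):
            TrainingSequence("u1", "A", "MKV7")
        with pytest.raises(ValueError):
            TrainingSequence("u1", "A", "")
        assert TrainingSequence("u1", "A", "MKVX").residues == "MKVX"


class TestSearchConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            SearchConfig(e_class=10.0, e_generic=1e-6)
        cfg = SearchConfig()
        assert cfg.e_class == pytest.approx(1e-6)
        assert cfg.e_generic == pytest.approx(10.0)
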