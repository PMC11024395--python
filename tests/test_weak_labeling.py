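"""The eight labeling functions, negation handling, and the vote matrix."""

import numpy as np
import pytest

from wearsurv.corpus import ClinicalNote, LabeledNote, segment_and_tag
from wearsurv.lexicons import find_term_mentions
from wearsurv.weak_labeling import (
    ABSTAIN,
    N_LFS,
    NEGATION_TRIGGERS,
    POSITIVE,
    VoteMatrix,
    apply_lfs_to_note,
    assemble_vote_matrix,
    detect_negation,
    lf_apply,
    lf_empirical_metrics,
)


def af_mentions_in(text, af_lex):
    return find_term_mentions(text, af_lex)


class TestDetectNegation:
    def test_explicit_trigger_before_term(self, af_lex):
        text = "Apple Watch showed no afib"
        (ann,) = segment_and_tag(text)
        (m,) = af_mentions_in(text, af_lex)
        assert detect_negation(ann, m) is True

    def test_no_trigger(self, af_lex):
        text = "Apple Watch showed afib"
        (ann,) = segment_and_tag(text)
        (m,) = af_mentions_in(text, af_lex)
        assert detect_negation(ann, m) is False

    def test_conjunction_resets_negation(self, af_lex):
        text = "no symptoms but afib present"
        (ann,) = segment_and_tag(text)
        (m,) = af_mentions_in(text, af_lex)
        assert detect_negation(ann, m) is False

    def test_bigram_trigger(self, af_lex):
        text = "negative for afib today"
        (ann,) = segment_and_tag(text)
        (m,) = af_mentions_in(text, af_lex)
        assert detect_negation(ann, m) is True

    def test_randomized_orderings_match_positional_scan(self, af_lex):
        # brute force: trigger token strictly before the AF term within the
        # sentence, with no reset word in between or after the trigger
        rng = np.random.default_rng(0)
        fillers = ["patient", "states", "mild", "symptoms", "today"]
        for _ in range(40):
            words = list(rng.permutation(fillers[: int(rng.integers(2, 5))]))
            pos = int(rng.integers(0, len(words) + 1))
            trigger = str(rng.choice(list(NEGATION_TRIGGERS)))
            if rng.random() < 0.5:
                words.insert(pos, trigger)
            words.append("afib")
            if rng.random() < 0.3:
                reset_at = int(rng.integers(0, len(words) - 1))
                words.insert(reset_at, "however")
            text = " ".join(words)
            (ann,) = segment_and_tag(text)
            mention = af_mentions_in(text, af_lex)[-1]
            toks = [t.surface.lower() for t in ann.tokens if t.start < mention.start]
            expected = False
            for t in toks:
                if t in NEGATION_TRIGGERS:
                    expected = True
                elif t in ("but", "however"):
                    expected = False
            assert detect_negation(ann, mention) is expected, text

    def test_mention_outside_sentence_rejected(self, af_lex):
        text = "First sentence here. Apple Watch showed afib."
        anns = segment_and_tag(text)
        (m,) = af_mentions_in(text, af_lex)
        with pytest.raises(ValueError):
            detect_negation(anns[0], m)


TABLE1_EXAMPLES = {
    1: "AF and wearable and notification",
    2: "AF noted on wearable",
    3: "Wearable notified AF",
    4: "Observed wearable showing AF",
    5: "Received AF from wearable",
    6: "Got notification from wearable of AF",
    7: "Notified on wearable of AF",
    8: "Per wearable, patient had AF",
}


class TestLfApply:
    @pytest.mark.parametrize("lf_id,text", list(TABLE1_EXAMPLES.items()))
    def test_canonical_example_fires_its_lf(self, lf_id, text):
        row = apply_lfs_to_note(text)
        assert row[lf_id - 1] == POSITIVE, (lf_id, text, row)

    def test_lf2_abstains_on_lf3_example(self):
        row = apply_lfs_to_note("Wearable notified AF")
        assert row[2 - 1] == ABSTAIN and row[3 - 1] == POSITIVE

    def test_negated_sentence_abstains_everywhere(self):
        row = apply_lfs_to_note("Apple Watch showed no afib")
        assert (row == ABSTAIN).all()

    def test_negation_suppression_property(self):
        # wrapping the AF term of any firing sentence with "no " silences all LFs
        for text in TABLE1_EXAMPLES.values():
            negated = text.replace("AF", "no AF")
            assert (apply_lfs_to_note(negated) == ABSTAIN).all(), negated

    def test_pattern_containment_lf1_is_weakest(self):
        # every grammatical pattern (LF2-8) implies the dictionary condition
        for lf_id, text in TABLE1_EXAMPLES.items():
            if lf_id == 1:
                continue
            row = apply_lfs_to_note(text)
            assert row[0] == POSITIVE, (lf_id, text)

    def test_gap_tolerance_bounds(self):
        inside = "AF was noted this morning on his Apple Watch"
        assert apply_lfs_to_note(inside)[2 - 1] == POSITIVE
        far = "AF one two three four five six seven noted on Apple Watch"
        assert apply_lfs_to_note(far)[2 - 1] == ABSTAIN
        assert apply_lfs_to_note(far, gap=10)[2 - 1] == POSITIVE

    def test_unknown_lf_id_rejected(self, event_lex, wearable_lex, af_lex):
        text = "AF noted on wearable"
        (ann,) = segment_and_tag(text)
        with pytest.raises(ValueError):
            lf_apply(9, ann, find_term_mentions(text, wearable_lex),
                     find_term_mentions(text, af_lex), event_lex)

    def test_deterministic_votes(self):
        text = "Got notification from smart watch of a-fib. Plan reviewed."
        assert (apply_lfs_to_note(text) == apply_lfs_to_note(text)).all()


class TestAssembleVoteMatrix:
    def test_single_candidate_sentence_row(self, note_factory):
        note = note_factory(text="Wearable notified AF.")
        m = assemble_vote_matrix([note])
        assert m.votes[0, 3 - 1] == POSITIVE
        assert m.note_ids == ["N1"]

    def test_note_without_af_is_all_abstain(self, note_factory):
        note = note_factory(text="Fitbit battery replaced today.")
        m = assemble_vote_matrix([note])
        assert (m.votes[0] == ABSTAIN).all()

    def test_or_reduction_over_sentences(self):
        # note-level vote equals the OR of per-sentence votes (LF2-8) plus the
        # note-scope dictionary rule
        texts = [
            "Routine visit. AF noted on wearable. Plan unchanged.",
            "Wearable notified AF. Received AF from wearable.",
            "No afib on Apple Watch. Per wearable, patient had AF.",
        ]
        notes = [ClinicalNote(f"N{i}", "P1", "2020-01-01", t) for i, t in enumerate(texts)]
        matrix = assemble_vote_matrix(notes)
        for i, text in enumerate(texts):
            sent_rows = [apply_lfs_to_note(part + ".")
                         for part in text.split(". ")]
            expected_27 = np.maximum.reduce([r[1:] for r in sent_rows])
            assert (matrix.votes[i, 1:] == expected_27).all(), text

    def test_rows_follow_input_order(self, note_factory):
        notes = [note_factory(note_id=f"N{i}") for i in range(4)]
        m = assemble_vote_matrix(notes)
        assert m.note_ids == [f"N{i}" for i in range(4)]

    def test_frame_round_trip(self, note_factory):
        m = assemble_vote_matrix([note_factory(text="AF noted on wearable")])
        again = VoteMatrix.from_frame(m.to_frame())
        assert again.note_ids == m.note_ids and (again.votes == m.votes).all()

    def test_vote_domain_enforced(self):
        with pytest.raises(ValueError):
            VoteMatrix(["a"], np.full((1, N_LFS), 2))


class TestLfEmpiricalMetrics:
    def _matrix(self, votes):
        votes = np.asarray(votes)
        return VoteMatrix([f"n{i}" for i in range(votes.shape[0])], votes)

    def test_perfect_lf(self):
        votes = np.zeros((4, N_LFS), dtype=int)
        votes[:2, 0] = POSITIVE
        gold = [LabeledNote(f"n{i}", 1 if i < 2 else 0, "test") for i in range(4)]
        metrics = lf_empirical_metrics(self._matrix(votes), gold)
        assert metrics.loc["lf1", "precision"] == 1.0
        assert metrics.loc["lf1", "recall"] == 1.0

    def test_footnote_formula_arithmetic(self):
        # TP=3, FP=1 -> precision 0.75
        votes = np.zeros((6, N_LFS), dtype=int)
        votes[:4, 0] = POSITIVE
        gold = [LabeledNote(f"n{i}", 1 if i in (0, 1, 2, 5) else 0, "test")
                for i in range(6)]
        metrics = lf_empirical_metrics(self._matrix(votes), gold)
        assert metrics.loc["lf1", "precision"] == pytest.approx(0.75)
        assert metrics.loc["lf1", "recall"] == pytest.approx(3 / 4)

    def test_random_grids_match_confusion_oracle(self):
        rng = np.random.default_rng(3)
        votes = (rng.random((50, N_LFS)) < 0.3).astype(int)
        y = (rng.random(50) < 0.4).astype(int)
        gold = [LabeledNote(f"n{i}", int(y[i]), "test") for i in range(50)]
        metrics = lf_empirical_metrics(self._matrix(votes), gold)
        for j in range(N_LFS):
            pred = votes[:, j]
            tp = int(((pred == 1) & (y == 1)).sum())
            fp = int(((pred == 1) & (y == 0)).sum())
            fn = int(((pred == 0) & (y == 1)).sum())
            tn = int(((pred == 0) & (y == 0)).sum())
            row = metrics.loc[f"lf{j+1}"]
            assert row["precision"] == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
            assert row["recall"] == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)
            assert row["accuracy"] == pytest.approx((tp + tn) / 50)

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            lf_empirical_metrics(self._matrix(np.zeros((2, N_LFS), dtype=int)), [])
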