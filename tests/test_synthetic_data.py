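"""Generator determinism, moment recovery, and planted-defect detection."""

import numpy as np
import pandas as pd
import pytest

from ambignorm import dominance as dom
from ambignorm import nlm_metrics as nm
from ambignorm import synthetic_data as syn
from ambignorm._common import ConfigError


class TestAssociateStudy:
    def test_config_rejects_invalid_probabilities(self):
        with pytest.raises(ConfigError):
            syn.AssociateStudyConfig(
                n_words=1, n_participants=5, true_sense_probs=(0.6, 0.6)
            )
        with pytest.raises(ConfigError):
            syn.AssociateStudyConfig(
                n_words=1, n_participants=5, true_sense_probs=(0.5, 0.5),
                rater_coverage=1.5,
            )

    def test_degenerate_mixture_yields_single_sense(self):
        cfg = syn.AssociateStudyConfig(
            n_words=2, n_participants=10, true_sense_probs=(1.0,), seed=0
        )
        study = syn.simulate_associate_study(cfg)
        assert (study.truth["sense"] == 1).all()

    def test_response_counts_per_participant(self):
        cfg = syn.AssociateStudyConfig(
            n_words=3, n_participants=7, true_sense_probs=(0.5, 0.5), seed=1
        )
        study = syn.simulate_associate_study(cfg)
        counts = study.responses.groupby(["participant_id", "word"]).size()
        assert (counts == cfg.responses_per_participant).all()
        assert counts.size == 21

    def test_balanced_mixture_drives_dominance_to_zero(self):
        cfg = syn.AssociateStudyConfig(
            n_words=1, n_participants=5000, true_sense_probs=(0.5, 0.5), seed=1
        )
        study = syn.simulate_associate_study(cfg)
        # oracle: direct tally of the generated latent senses
        tally_truth = study.truth["sense"].value_counts(normalize=True)
        assert abs(tally_truth.max() - tally_truth.min()) < 0.05
        rec = dom.dominance_score(
            dom.tally_sense_assignments(study.assignments, 2, word="WORD001")
        )
        assert rec.score < 0.05

    def test_perfect_raters_give_perfect_reliability(self):
        cfg = syn.AssociateStudyConfig(
            n_words=2, n_participants=30, true_sense_probs=(0.5, 0.5),
            rater_coverage=1.0, rater_agreement=1.0, seed=3,
        )
        study = syn.simulate_associate_study(cfg)
        cov, cons = dom.interrater_reliability(study.assignments)
        assert (cov, cons) == (1.0, 1.0)

    def test_coverage_and_agreement_rates_recovered(self):
        cfg = syn.AssociateStudyConfig(
            n_words=4, n_participants=400, true_sense_probs=(0.5, 0.5), seed=5
        )
        study = syn.simulate_associate_study(cfg)
        cov, cons = dom.interrater_reliability(study.assignments)
        n = len(study.responses)
        assert cov == pytest.approx(0.757, abs=3 * np.sqrt(0.757 * 0.243 / n))
        n_both = int(round(cov * n))
        assert cons == pytest.approx(
            0.949, abs=3 * np.sqrt(0.949 * 0.051 / n_both)
        )

    def test_seeded_determinism(self):
        cfg = syn.AssociateStudyConfig(
            n_words=2, n_participants=10, true_sense_probs=(0.7, 0.3), seed=9
        )
        a, b = syn.simulate_associate_study(cfg), syn.simulate_associate_study(cfg)
        pd.testing.assert_frame_equal(a.responses, b.responses)
        pd.testing.assert_frame_equal(a.assignments, b.assignments)


class TestRatingStudy:
    def test_zero_noise_integer_means_reproduced_exactly(self):
        means = dict(zip(syn.CONDITIONS, (2.0, 3.0, 5.0, 6.0)))
        sds = dict.fromkeys(syn.CONDITIONS, 0.0)
        cfg = syn.RatingStudyConfig(
            condition_means=means, condition_item_sds=sds, within_item_sd=0.0,
            items_per_condition=3, n_participants=4, seed=0,
        )
        study = syn.simulate_rating_study(cfg)
        merged = study.ratings.merge(study.items, on="item")
        assert (merged["rating"] == merged["condition"].map(means)).all()

    def test_ratings_are_integers_on_scale(self, rating_study):
        r = rating_study.ratings["rating"]
        assert r.dtype.kind == "i"
        assert r.between(1, 7).all()

    def test_condition_means_recovered_within_three_se(self, rating_study):
        merged = rating_study.ratings.merge(rating_study.items, on="item")
        genuine = merged[~merged["participant_id"].isin(rating_study.flat_raters)]
        item_means = genuine.groupby(["condition", "item"])["rating"].mean()
        cfg = syn.RatingStudyConfig()
        for cond in syn.CONDITIONS:
            vals = item_means[cond]
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert vals.mean() == pytest.approx(
                cfg.condition_means[cond], abs=3 * se
            )

    def test_flat_raters_are_flat(self, rating_study):
        merged = rating_study.ratings.merge(rating_study.items, on="item")
        for pid in rating_study.flat_raters:
            own = merged[merged["participant_id"] == pid]
            by_cond = own.groupby("condition")["rating"].mean()
            assert abs(by_cond["Homonym"] - by_cond["Unambiguous"]) <= 0.5

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            syn.RatingStudyConfig(items_per_condition=0)
        with pytest.raises(ConfigError):
            syn.RatingStudyConfig(within_item_sd=-1)

    def test_seeded_determinism(self):
        cfg = syn.RatingStudyConfig(items_per_condition=4, n_participants=5, seed=2)
        a, b = syn.simulate_rating_study(cfg), syn.simulate_rating_study(cfg)
        pd.testing.assert_frame_equal(a.ratings, b.ratings)


def test_latent_mean_calibration_removes_discretization_bias():
    # near the scale floor the naive clamp+round inflates the mean; the
    # calibrated latent mean restores it
    rng = np.random.default_rng(0)
    target, sd = 1.63, 1.2
    m = syn._latent_mean_for_target(target, sd)
    draws = np.clip(np.rint(rng.normal(m, sd, size=200_000)), 1, 7)
    assert draws.mean() == pytest.approx(target, abs=0.01)
    naive = np.clip(np.rint(rng.normal(target, sd, size=200_000)), 1, 7)
    assert naive.mean() > target + 0.15


class TestZeugmaItems:
    def test_counts_and_span_integrity(self):
        items = syn.generate_zeugma_items(1, seed=0)
        assert len(items) == 4
        for it in items:
            a, b = it.anaphor_span
            assert it.sentence[a:b] == it.anaphor_text
            assert " " not in it.anaphor_text

    def test_multiword_fraction_plants_filterable_items(self):
        items = syn.generate_zeugma_items(40, seed=3, multiword_fraction=0.1)
        n_multi = sum(" " in it.anaphor_text for it in items)
        assert 8 <= n_multi <= 24  # 160 items, expectation 16
        again = syn.generate_zeugma_items(40, seed=3, multiword_fraction=0.1)
        assert n_multi == sum(" " in it.anaphor_text for it in again)

    def test_blends_ordered_by_condition(self, zeugma_items):
        by_cond = {}
        for it in zeugma_items:
            by_cond.setdefault(it.condition, []).append(it.sense_blend)
        assert max(by_cond["Homonym"]) < min(by_cond["IrregularPolyseme"])
        assert max(by_cond["IrregularPolyseme"]) < min(by_cond["RegularPolyseme"])
        assert max(by_cond["RegularPolyseme"]) < min(by_cond["Unambiguous"])

    def test_ratings_for_items_track_blend(self, zeugma_items):
        study = syn.simulate_ratings_for_zeugma_items(
            zeugma_items, n_participants=30, seed=1
        )
        merged = study.ratings.groupby("item")["rating"].mean()
        blends = pd.Series({it.item: it.sense_blend for it in zeugma_items})
        r = np.corrcoef(merged[blends.index], blends)[0, 1]
        assert r > 0.95


class TestToyEncoder:
    def test_identical_meaning_gives_zero_distance_every_layer(self):
        items = syn.generate_zeugma_items(2, seed=1)
        blended = [
            nm.ZeugmaItem(**{**vars(it), "sense_blend": 1.0}) for it in items
        ]
        enc = syn.make_toy_encoder(
            syn.ToyEncoderConfig(n_layers=4, dim=16, seed=0), blended
        )
        for it in blended:
            tok = enc.tokenize(it.sentence)
            vecs = enc.layer_vectors(it.sentence)
            for layer in range(4):
                u = nm.span_embedding(vecs[layer], tok, it.target_span)
                v = nm.span_embedding(vecs[layer], tok, it.anaphor_span)
                assert nm.cosine_distance(u, v) == pytest.approx(0.0, abs=1e-9)

    def test_distance_strictly_decreasing_in_blend(self):
        base = syn.generate_zeugma_items(1, seed=1)[0]
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        # one geometry per sentence, so pad each copy to a distinct key
        items = []
        for i, blend in enumerate(grid):
            sent = base.sentence + " " * i  # distinct key, same spans
            items.append(
                nm.ZeugmaItem(
                    item=f"g{i}", sentence=sent, target_span=base.target_span,
                    anaphor_span=base.anaphor_span, anaphor_text=base.anaphor_text,
                    condition=base.condition, sense_blend=blend,
                )
            )
        enc = syn.make_toy_encoder(
            syn.ToyEncoderConfig(n_layers=12, dim=32, seed=2), items
        )
        dists = []
        for it in items:
            tok = enc.tokenize(it.sentence)
            vecs = enc.layer_vectors(it.sentence)
            u = nm.span_embedding(vecs[11], tok, it.target_span)
            v = nm.span_embedding(vecs[11], tok, it.anaphor_span)
            dists.append(nm.cosine_distance(u, v))
        assert all(a > b for a, b in zip(dists, dists[1:]))

    def test_masked_probability_increasing_in_blend(self, zeugma_items, toy_encoder):
        pairs = sorted(
            (it.sense_blend, toy_encoder.masked_probability(
                it.sentence, it.anaphor_span, it.anaphor_text))
            for it in zeugma_items
        )
        probs = [p for _, p in pairs]
        assert all(a <= b for a, b in zip(probs, probs[1:]))

    def test_byte_identical_vectors_for_same_seed(self, zeugma_items):
        cfg = syn.ToyEncoderConfig(n_layers=3, dim=24, seed=5)
        e1 = syn.make_toy_encoder(cfg, zeugma_items)
        e2 = syn.make_toy_encoder(cfg, zeugma_items)
        s = zeugma_items[0].sentence
        assert e1.layer_vectors(s).tobytes() == e2.layer_vectors(s).tobytes()

    def test_out_of_vocabulary_token_raises(self, toy_encoder):
        with pytest.raises(syn.OutOfVocabularyError):
            toy_encoder.tokenize("The xylophone was heavy.")
        with pytest.raises(syn.OutOfVocabularyError):
            toy_encoder.masked_probability("The old bark.", (8, 12), "xylophone")

    def test_long_words_split_into_subtokens(self):
        enc = syn.make_toy_encoder(
            syn.ToyEncoderConfig(
                n_layers=1, dim=8, seed=0,
                vocab=("the", "lighthouse", "was", "tall"),
            )
        )
        sent = "The lighthouse was tall."
        tok = enc.tokenize(sent)
        assert any(t.startswith("##") for t in tok.subtokens)
        # alignment covers each word's characters exactly once
        covered = sorted(
            i for a, b in tok.spans for i in range(a, b)
        )
        expected = sorted(
            i for w_start, w in _word_offsets(sent) for i in range(w_start, w_start + len(w))
        )
        assert covered == expected


def _word_offsets(sentence):
    pos = 0
    for chunk in sentence.split():
        start = sentence.index(chunk, pos)
        pos = start + len(chunk)
        yield start, chunk
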