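"""Synthetic norming studies and a deterministic toy contextual encoder.

Generators for the three kinds of input the analyses consume:

* an associate-norming study — participants produce two free associates per
  ambiguous word, drawn from a latent per-word sense mixture, and two raters
  classify each response by sense with configurable coverage and agreement;
* a similarity-rating study — items in four ambiguity conditions receive
  integer 1-7 ratings whose item means are drawn from per-condition
  distributions, with optional planted "flat" raters who ignore item type;
* zeugmatic sentences with marked target and anaphor spans, plus a toy
  encoder whose geometry tracks a planted ground-truth sense similarity
  (``sense_blend``): cosine distance between target and anaphor vectors
  decreases, and the masked probability of the anaphor increases,
  monotonically in the blend.

Every generator is deterministic for a fixed (config, seed) and draws from
its own independent RNG stream, so adding one generator to a script does not
perturb the output of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ambignorm._common import CONDITIONS, ConfigError
from ambignorm.nlm_metrics import Tokenization, ZeugmaItem

# distinct stream tags so each generator owns an independent RNG stream
_STREAM_ASSOCIATE = 11
_STREAM_RATING = 22
_STREAM_ENCODER = 33
_STREAM_ZEUGMA = 44


class OutOfVocabularyError(KeyError):
    """A token was not found in the toy encoder's vocabulary."""


def _crc(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


# ---------------------------------------------------------------------------
# associate-norming study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociateStudyConfig:
    """Design of a simulated free-association dominance norming.

    ``true_sense_probs`` is either one probability vector over 2-5 latent
    senses (shared by every word) or one vector per word.  ``rater_coverage``
    is the probability a response is classified by both raters (the study's
    observed rate was 0.757); ``rater_agreement`` is the probability the
    second rater's label matches the first (observed 0.949).
    """

    n_words: int
    n_participants: int
    true_sense_probs: Sequence[float] | Sequence[Sequence[float]]
    responses_per_participant: int = 2
    rater_coverage: float = 0.757
    rater_agreement: float = 0.949
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_words <= 0 or self.n_participants <= 0:
            raise ConfigError("counts must be positive")
        if self.responses_per_participant <= 0:
            raise ConfigError("responses_per_participant must be positive")
        for name, rate in (("rater_coverage", self.rater_coverage),
                           ("rater_agreement", self.rater_agreement)):
            if not (0.0 <= rate <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {rate}")
        for probs in self.per_word_probs():
            p = np.asarray(probs, dtype=float)
            if not (1 <= p.size <= 5):
                raise ConfigError("each word needs 1-5 latent senses")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
                raise ConfigError(f"invalid probability vector {probs}")

    def per_word_probs(self) -> list[tuple[float, ...]]:
        first = self.true_sense_probs[0]
        if isinstance(first, (int, float)):
            shared = tuple(float(x) for x in self.true_sense_probs)  # type: ignore[arg-type]
            return [shared] * self.n_words
        vecs = [tuple(float(x) for x in v) for v in self.true_sense_probs]  # type: ignore[union-attr]
        if len(vecs) != self.n_words:
            raise ConfigError(
                f"got {len(vecs)} probability vectors for {self.n_words} words"
            )
        return vecs


@dataclass(frozen=True)
class AssociateStudy:
    """Output of :func:`simulate_associate_study`.

    ``responses``: participant_id, word, slot, response.
    ``assignments``: rater_id, participant_id, word, slot, label (1..K).
    ``truth``: participant_id, word, slot, sense — the latent labels.
    """

    responses: pd.DataFrame
    assignments: pd.DataFrame
    truth: pd.DataFrame


def simulate_associate_study(config: AssociateStudyConfig) -> AssociateStudy:
    """Simulate a two-response free-association norming with dual raters.

    Each participant contributes exactly ``responses_per_participant``
    responses per word, with the latent sense of each response drawn i.i.d.
    from the word's sense mixture.  Rater 1's label always matches the
    latent sense; when a response is double-labeled (probability
    ``rater_coverage``) the second rater agrees with probability
    ``rater_agreement`` and otherwise picks uniformly among the other
    senses.  Single-labeled responses are attributed to a uniformly chosen
    rater.
    """
    rng = np.random.default_rng([_STREAM_ASSOCIATE, config.seed])
    probs = config.per_word_probs()
    words = [f"WORD{i:03d}" for i in range(1, config.n_words + 1)]
    participants = [f"P{i:04d}" for i in range(1, config.n_participants + 1)]

    resp_rows, assign_rows, truth_rows = [], [], []
    for word, p in zip(words, probs):
        k = len(p)
        senses = np.arange(1, k + 1)
        for pid in participants:
            drawn = rng.choice(senses, size=config.responses_per_participant, p=p)
            for slot, sense in enumerate(drawn, start=1):
                sense = int(sense)
                resp_rows.append(
                    (pid, word, slot, f"assoc_{word.lower()}_s{sense}")
                )
                truth_rows.append((pid, word, slot, sense))
                both = rng.random() < config.rater_coverage
                if both:
                    if k > 1 and rng.random() >= config.rater_agreement:
                        others = senses[senses != sense]
                        second = int(rng.choice(others))
                    else:
                        second = sense
                    assign_rows.append(("R1", pid, word, slot, sense))
                    assign_rows.append(("R2", pid, word, slot, second))
                else:
                    rater = "R1" if rng.random() < 0.5 else "R2"
                    assign_rows.append((rater, pid, word, slot, sense))

    return AssociateStudy(
        responses=pd.DataFrame(
            resp_rows, columns=["participant_id", "word", "slot", "response"]
        ),
        assignments=pd.DataFrame(
            assign_rows,
            columns=["rater_id", "participant_id", "word", "slot", "label"],
        ),
        truth=pd.DataFrame(
            truth_rows, columns=["participant_id", "word", "slot", "sense"]
        ),
    )


# ---------------------------------------------------------------------------
# similarity-rating study
# ---------------------------------------------------------------------------

_DEFAULT_CONDITION_MEANS = dict(zip(CONDITIONS, (1.63, 2.57, 4.96, 6.28)))
_DEFAULT_CONDITION_SDS = dict(zip(CONDITIONS, (0.33, 1.14, 1.27, 0.44)))


@dataclass(frozen=True)
class RatingStudyConfig:
    """Design of a simulated zeugma similarity-rating study.

    Item means per condition are drawn from Normal(mean, sd) and clamped to
    the 1-7 scale; individual ratings are integer discretizations of a
    Gaussian around the item mean with SD ``within_item_sd``.  Planted flat
    raters (``n_flat_raters``, added on top of ``n_participants``) rate
    every item near the scale midpoint regardless of condition, which the
    downstream exclusion rule should catch.
    """

    condition_means: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONDITION_MEANS)
    )
    condition_item_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONDITION_SDS)
    )
    within_item_sd: float = 1.2
    items_per_condition: int = 80
    n_participants: int = 88
    n_flat_raters: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.items_per_condition <= 0:
            raise ConfigError("items_per_condition must be positive")
        if self.n_participants <= 0 or self.n_flat_raters < 0:
            raise ConfigError("participant counts invalid")
        if self.within_item_sd < 0:
            raise ConfigError("within_item_sd must be >= 0")
        for cond, m in self.condition_means.items():
            if not (1.0 <= m <= 7.0):
                raise ConfigError(f"mean for {cond} outside [1, 7]: {m}")
        for cond, s in self.condition_item_sds.items():
            if s < 0:
                raise ConfigError(f"SD for {cond} negative: {s}")
        if set(self.condition_means) != set(self.condition_item_sds):
            raise ConfigError("condition_means and condition_item_sds disagree")


@dataclass(frozen=True)
class RatingStudy:
    """Output of :func:`simulate_rating_study`.

    ``ratings``: participant_id, item, rating (int 1-7).
    ``items``: item, condition, true_mean, sentence.
    ``flat_raters``: participant ids of the planted uncooperative raters.
    """

    ratings: pd.DataFrame
    items: pd.DataFrame
    flat_raters: tuple[str, ...]


def _latent_mean_for_target(target: float, sd: float) -> float:
    """Latent Gaussian mean whose rounded, clamped draw has mean ``target``.

    round(clamp(N(m, sd), 1, 7)) shifts the mean toward the scale midpoint
    near the boundaries; solving E[rating] = target for m removes that bias
    so the discretized ratings are mean-faithful to the item mean.
    """
    if sd == 0.0:
        return target

    grid = np.arange(1, 8)

    def expected(m: float) -> float:
        upper = stats.norm.cdf((grid + 0.5 - m) / sd)
        upper[-1] = 1.0
        lower = np.concatenate(([0.0], upper[:-1]))
        return float(np.dot(grid, upper - lower))

    lo, hi = -30.0 * max(sd, 1.0), 30.0 * max(sd, 1.0)
    if target <= expected(lo):
        return lo
    if target >= expected(hi):
        return hi
    return float(optimize.brentq(lambda m: expected(m) - target, lo, hi, xtol=1e-10))


def _discretize(values: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(values), 1, 7).astype(int)


def simulate_rating_study(config: RatingStudyConfig) -> RatingStudy:
    """Simulate participant x item similarity ratings on the 1-7 scale."""
    rng = np.random.default_rng([_STREAM_RATING, config.seed])
    conditions = sorted(config.condition_means)

    item_rows = []
    idx = 0
    for cond in conditions:
        mu, sd = config.condition_means[cond], config.condition_item_sds[cond]
        true_means = np.clip(
            rng.normal(mu, sd, size=config.items_per_condition), 1.0, 7.0
        )
        for tm in true_means:
            idx += 1
            item_rows.append((f"I{idx:03d}", cond, float(tm)))
    items = pd.DataFrame(item_rows, columns=["item", "condition", "true_mean"])

    genuine = [f"S{i:03d}" for i in range(1, config.n_participants + 1)]
    flat = [
        f"FLAT{i:02d}" for i in range(1, config.n_flat_raters + 1)
    ]

    latent = {
        row.item: _latent_mean_for_target(row.true_mean, config.within_item_sd)
        for row in items.itertuples()
    }

    rows = []
    for pid in genuine:
        for row in items.itertuples():
            if config.within_item_sd == 0.0:
                rating = int(_discretize(np.array([row.true_mean]))[0])
            else:
                draw = rng.normal(latent[row.item], config.within_item_sd)
                rating = int(_discretize(np.array([draw]))[0])
            rows.append((pid, row.item, rating))
    for pid in flat:
        draws = rng.normal(4.0, 0.2, size=len(items))
        for row, d in zip(items.itertuples(), draws):
            rows.append((pid, row.item, int(_discretize(np.array([d]))[0])))

    return RatingStudy(
        ratings=pd.DataFrame(rows, columns=["participant_id", "item", "rating"]),
        items=items,
        flat_raters=tuple(flat),
    )


def simulate_ratings_for_zeugma_items(
    items: Sequence["ZeugmaItem"],
    n_participants: int = 88,
    within_item_sd: float = 1.2,
    n_flat_raters: int = 0,
    seed: int = 0,
) -> RatingStudy:
    """Similarity ratings for zeugma items, driven by their planted blends.

    The ground-truth item mean is the planted sense similarity mapped onto
    the rating scale, ``1 + 6 * sense_blend``, so human-side item means and
    encoder-side geometry share a single latent similarity.  Rating noise
    and flat raters behave as in :func:`simulate_rating_study`.
    """
    if n_participants <= 0 or n_flat_raters < 0 or within_item_sd < 0:
        raise ConfigError("invalid rating parameters")
    rng = np.random.default_rng([_STREAM_RATING, seed, 2])
    rows_items = []
    for it in items:
        if it.sense_blend is None:
            raise ConfigError(f"item {it.item} has no planted sense_blend")
        rows_items.append((it.item, it.condition, 1.0 + 6.0 * it.sense_blend))
    item_df = pd.DataFrame(rows_items, columns=["item", "condition", "true_mean"])

    latent = {
        row.item: _latent_mean_for_target(row.true_mean, within_item_sd)
        for row in item_df.itertuples()
    }
    genuine = [f"S{i:03d}" for i in range(1, n_participants + 1)]
    flat = [f"FLAT{i:02d}" for i in range(1, n_flat_raters + 1)]
    rows = []
    for pid in genuine:
        for row in item_df.itertuples():
            if within_item_sd == 0.0:
                rating = int(_discretize(np.array([row.true_mean]))[0])
            else:
                draw = rng.normal(latent[row.item], within_item_sd)
                rating = int(_discretize(np.array([draw]))[0])
            rows.append((pid, row.item, rating))
    for pid in flat:
        draws = rng.normal(4.0, 0.2, size=len(item_df))
        for row, d in zip(item_df.itertuples(), draws):
            rows.append((pid, row.item, int(_discretize(np.array([d]))[0])))
    return RatingStudy(
        ratings=pd.DataFrame(rows, columns=["participant_id", "item", "rating"]),
        items=item_df,
        flat_raters=tuple(flat),
    )


# ---------------------------------------------------------------------------
# zeugma items
# ---------------------------------------------------------------------------

# planted sense-similarity ranges per condition: homonyms have the most
# distant meanings, unambiguous words essentially a single meaning
_BLEND_RANGES = {
    "Homonym": (0.02, 0.22),
    "IrregularPolyseme": (0.25, 0.48),
    "RegularPolyseme": (0.55, 0.80),
    "Unambiguous": (0.85, 1.00),
}

_TARGET_POOL = (
    "bark bat mold glass press cone file pitch bank seal match note ring "
    "table board letter plant spring scale bill yard chest organ crane palm "
    "fence light train coach staff band pool park bolt deck duck iron key lap "
    "jam"
).split()

_ADJS = ("old", "rough", "bright", "quiet", "heavy", "small", "sturdy", "pale")
_AGENTS = ("farmer", "singer", "child", "vendor", "student", "sailor")
_VERBS = ("needed", "wanted", "noticed", "described")
# single-word anaphoric referring expressions; varied so the anaphor can
# serve as a random-intercept grouping factor downstream
_ANAPHORS = ("one", "it", "some", "this")


def generate_zeugma_items(
    n_per_condition: int,
    seed: int = 0,
    multiword_fraction: float = 0.0,
) -> list[ZeugmaItem]:
    """Build zeugmatic sentences with marked target and anaphor spans.

    Each sentence introduces the target word and later refers back to it
    with a single-word anaphor drawn from a small pool, joined by a bare
    conjunction.  A seeded
    fraction of items instead receives the multiword anaphor "a lot" to
    exercise the downstream exclusion filter.  Spans are 0-based half-open
    character offsets; each item carries its planted ``sense_blend``.
    """
    if n_per_condition <= 0:
        raise ConfigError("n_per_condition must be positive")
    if not (0.0 <= multiword_fraction <= 1.0):
        raise ConfigError("multiword_fraction must be in [0, 1]")
    rng = np.random.default_rng([_STREAM_ZEUGMA, seed])

    items: list[ZeugmaItem] = []
    counter = 0
    for cond in CONDITIONS:
        lo, hi = _BLEND_RANGES[cond]
        for j in range(n_per_condition):
            counter += 1
            base = _TARGET_POOL[(counter - 1) % len(_TARGET_POOL)]
            cycle = (counter - 1) // len(_TARGET_POOL)
            target = base if cycle == 0 else f"{base}{cycle + 1}"
            adj = _ADJS[int(rng.integers(len(_ADJS)))]
            agent = _AGENTS[int(rng.integers(len(_AGENTS)))]
            verb = _VERBS[int(rng.integers(len(_VERBS)))]
            if rng.random() < multiword_fraction:
                anaphor = "a lot"
            else:
                anaphor = _ANAPHORS[int(rng.integers(len(_ANAPHORS)))]
            blend = float(rng.uniform(lo, hi))

            prefix = f"The {adj} "
            mid = f" was heavy and the {agent} {verb} "
            sentence = f"{prefix}{target}{mid}{anaphor}."
            t0 = len(prefix)
            a0 = t0 + len(target) + len(mid)
            items.append(
                ZeugmaItem(
                    item=f"Z{counter:03d}",
                    sentence=sentence,
                    target_span=(t0, t0 + len(target)),
                    anaphor_span=(a0, a0 + len(anaphor)),
                    anaphor_text=anaphor,
                    condition=cond,
                    sense_blend=blend,
                )
            )
    return items


# ---------------------------------------------------------------------------
# toy contextual encoder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyEncoderConfig:
    """Geometry of the deterministic toy encoder.

    Defaults mirror a base-size bidirectional transformer (12 layers, 768
    hidden units) but any L >= 1, d >= 2 is accepted; small dims keep tests
    fast.  ``vocab`` extends the vocabulary beyond the words of the items
    the encoder is built over.  ``subword_split_len``: words strictly longer
    than this split deterministically into two subtokens, emulating
    WordPiece decomposition.
    """

    n_layers: int = 12
    dim: int = 768
    vocab: tuple[str, ...] = ()
    subword_split_len: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ConfigError("n_layers must be >= 1")
        if self.dim < 2:
            raise ConfigError("dim must be >= 2")
        if self.subword_split_len < 2:
            raise ConfigError("subword_split_len must be >= 2")


_PUNCT = ".,;:!?"


@dataclass(frozen=True)
class _ItemGeometry:
    target_span: tuple[int, int]
    anaphor_span: tuple[int, int]
    blend: float


class ToyEncoder:
    """Deterministic test double satisfying the contextual-encoder contract.

    Word vectors are seeded unit Gaussians per (word, layer).  For sentences
    the encoder was built over, the anaphor's vector is a spherical
    interpolation between the target word's vector and an orthogonal
    direction, at angle ``(1 - sense_blend) * pi/2``, so the cosine distance
    between target and anaphor is exactly ``1 - cos(angle)`` in every layer:
    0 at blend 1, 1 at blend 0, strictly decreasing in the blend.  The
    masked probability of the anaphor token rises linearly in the blend, so
    surprisal falls monotonically.
    """

    #: floor/ceiling of the planted anaphor probability
    _P_LO, _P_HI = 0.02, 0.98

    def __init__(self, config: ToyEncoderConfig, items: Sequence[ZeugmaItem] = ()):
        self.config = config
        self.n_layers = config.n_layers
        self.dim = config.dim
        self._geometry: dict[str, _ItemGeometry] = {}
        vocab = {w.lower() for w in config.vocab}
        for it in items:
            if it.sense_blend is None:
                raise ConfigError(f"item {it.item} has no planted sense_blend")
            self._geometry[it.sentence] = _ItemGeometry(
                it.target_span, it.anaphor_span, it.sense_blend
            )
            for tok in it.sentence.split():
                vocab.add(tok.strip(_PUNCT).lower())
        vocab.discard("")
        self._vocab = frozenset(vocab)

    @property
    def vocab(self) -> frozenset[str]:
        return self._vocab

    # -- tokenization -----------------------------------------------------

    def tokenize(self, sentence: str) -> Tokenization:
        subtokens: list[str] = []
        spans: list[tuple[int, int]] = []
        pos = 0
        for chunk in sentence.split():
            start = sentence.index(chunk, pos)
            pos = start + len(chunk)
            word = chunk.rstrip(_PUNCT)
            trailing = chunk[len(word):]
            if word:
                if word.strip(_PUNCT).lower() not in self._vocab:
                    raise OutOfVocabularyError(word)
                if len(word) > self.config.subword_split_len:
                    cut = (len(word) + 1) // 2
                    subtokens.append(word[:cut])
                    spans.append((start, start + cut))
                    subtokens.append("##" + word[cut:])
                    spans.append((start + cut, start + len(word)))
                else:
                    subtokens.append(word)
                    spans.append((start, start + len(word)))
            for k, ch in enumerate(trailing):
                off = start + len(word) + k
                subtokens.append(ch)
                spans.append((off, off + 1))
        return Tokenization(tuple(subtokens), tuple(spans))

    # -- vectors ----------------------------------------------------------

    def _word_vector(self, word: str, layer: int) -> np.ndarray:
        rng = np.random.default_rng(
            [_STREAM_ENCODER, self.config.seed, layer, _crc(word.lower())]
        )
        v = rng.standard_normal(self.dim)
        return v / np.linalg.norm(v)

    def _orthonormal_to(self, u: np.ndarray, tag: str, layer: int) -> np.ndarray:
        rng = np.random.default_rng(
            [_STREAM_ENCODER, self.config.seed, 7_000 + layer, _crc(tag)]
        )
        w = rng.standard_normal(self.dim)
        w -= np.dot(w, u) * u
        return w / np.linalg.norm(w)

    def layer_vectors(self, sentence: str) -> np.ndarray:
        tok = self.tokenize(sentence)
        geom = self._geometry.get(sentence)
        out = np.empty((self.n_layers, len(tok.subtokens), self.dim))
        for layer in range(1, self.n_layers + 1):
            for i, (sub, span) in enumerate(zip(tok.subtokens, tok.spans)):
                out[layer - 1, i] = self._word_vector(sub.lstrip("#"), layer)
            if geom is not None:
                t_idx = tok.covering(geom.target_span)
                a_idx = tok.covering(geom.anaphor_span)
                word = sentence[geom.target_span[0]:geom.target_span[1]]
                u = self._word_vector(word, layer)
                w = self._orthonormal_to(u, sentence, layer)
                angle = (1.0 - geom.blend) * np.pi / 2.0
                v = np.cos(angle) * u + np.sin(angle) * w
                # identical vectors across a word's subtokens keep the span
                # mean equal to the planted direction
                out[layer - 1, t_idx] = u
                out[layer - 1, a_idx] = v
        return out

    # -- masked prediction -------------------------------------------------

    def masked_probability(
        self, sentence: str, span: tuple[int, int], candidate: str
    ) -> float:
        cand = candidate.strip(_PUNCT).lower()
        if cand not in self._vocab:
            raise OutOfVocabularyError(candidate)
        geom = self._geometry.get(sentence)
        if geom is not None and span == geom.anaphor_span:
            planted = sentence[span[0]:span[1]].strip(_PUNCT).lower()
            p_planted = self._P_LO + (self._P_HI - self._P_LO) * geom.blend
            if cand == planted:
                return p_planted
            return (1.0 - p_planted) / max(len(self._vocab), 2)
        # unknown context: deterministic pseudo-probability
        h = _crc(f"{sentence}|{span}|{cand}|{self.config.seed}") / 2**32
        return (0.01 + 0.98 * h) / max(len(self._vocab), 2)


def make_toy_encoder(
    config: ToyEncoderConfig, items: Sequence[ZeugmaItem] = ()
) -> ToyEncoder:
    """Construct a :class:`ToyEncoder` over the given zeugma items.

    The encoder's vocabulary is the union of ``config.vocab`` and the words
    of the item sentences; tokens outside it raise
    :class:`OutOfVocabularyError`.
    """
    return ToyEncoder(config, items)
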