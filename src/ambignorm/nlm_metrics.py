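"""Encoder-derived similarity metrics for zeugmatic sentences.

Each zeugma item pairs a target word with a later anaphoric referring
expression (e.g. "one") whose interpretation forces a second sense of the
target.  Two measures quantify how far apart an encoder places the two
mentions:

* per-layer cosine distance ``d_cos(l) = 1 - cos(u_l, v_l)`` between the
  contextualized vectors of the target word and the anaphor, where a word
  split into several subtokens is represented by the unweighted mean of its
  subtoken vectors;
* masked-anaphor surprisal ``s = -log p``, the negative log probability the
  encoder assigns to the anaphor token when its position is masked.

Items whose anaphor spans multiple words are excluded before metric
computation, and per-layer Pearson correlations relate the metrics to human
item-mean similarity ratings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from scipy import stats


class AlignmentError(ValueError):
    """A character span maps to zero subtokens."""


class EncoderContractError(ValueError):
    """An encoder returned a value outside its documented contract."""


@dataclass(frozen=True)
class ZeugmaItem:
    """One zeugmatic sentence with marked target-word and anaphor spans.

    Spans are 0-based, half-open character intervals into ``sentence``.
    ``sense_blend`` is the planted ground-truth sense similarity carried by
    synthetic items (1 = the two mentions share a meaning exactly); it is
    ``None`` for items of unknown provenance.
    """

    item: str
    sentence: str
    target_span: tuple[int, int]
    anaphor_span: tuple[int, int]
    anaphor_text: str
    condition: str
    sense_blend: float | None = None

    def __post_init__(self) -> None:
        for name, (a, b) in (("target_span", self.target_span),
                             ("anaphor_span", self.anaphor_span)):
            if not (0 <= a < b <= len(self.sentence)):
                raise ValueError(f"{name} {(a, b)} outside sentence bounds")
        ta, tb = self.target_span
        aa, ab = self.anaphor_span
        if max(ta, aa) < min(tb, ab):
            raise ValueError("target and anaphor spans overlap")
        if self.sentence[aa:ab] != self.anaphor_text:
            raise ValueError(
                f"anaphor_text {self.anaphor_text!r} does not match "
                f"sentence[{aa}:{ab}] = {self.sentence[aa:ab]!r}"
            )

    @property
    def target_text(self) -> str:
        a, b = self.target_span
        return self.sentence[a:b]


@dataclass(frozen=True)
class Tokenization:
    """Subtokens of a sentence with per-subtoken character spans.

    Together the spans cover every character of every whitespace-delimited
    word exactly once (whitespace itself is not covered).
    """

    subtokens: tuple[str, ...]
    spans: tuple[tuple[int, int], ...]

    def covering(self, span: tuple[int, int]) -> list[int]:
        """Indices of subtokens overlapping the half-open character span."""
        a, b = span
        return [i for i, (x, y) in enumerate(self.spans) if max(a, x) < min(b, y)]


@runtime_checkable
class EncoderInterface(Protocol):
    """Contract any contextual encoder must satisfy.

    ``n_layers`` (L >= 1) and ``dim`` (d >= 1) describe the stack;
    ``layer_vectors`` returns one vector of dimension d per subtoken for
    each layer 1..L; ``masked_probability`` returns the model probability in
    (0, 1] of ``candidate`` filling the masked character span.
    """

    n_layers: int
    dim: int

    def tokenize(self, sentence: str) -> Tokenization: ...

    def layer_vectors(self, sentence: str) -> np.ndarray:
        """Array of shape (n_layers, n_subtokens, dim)."""
        ...

    def masked_probability(
        self, sentence: str, span: tuple[int, int], candidate: str
    ) -> float: ...


def filter_multiword_anaphors(
    items: Sequence[ZeugmaItem],
) -> tuple[list[ZeugmaItem], list[ZeugmaItem]]:
    """Drop items whose anaphoric expression contains more than one word.

    A multiword anaphor (e.g. "a lot") has no single maskable position, so
    such items are removed before surprisal computation.  Detection is by
    internal whitespace in ``anaphor_text``.  Idempotent.

    Returns ``(retained, removed)``.
    """
    retained, removed = [], []
    for it in items:
        (removed if len(it.anaphor_text.strip().split()) > 1 else retained).append(it)
    return retained, removed


def span_embedding(
    layer_vecs: np.ndarray, tokenization: Tokenization, span: tuple[int, int]
) -> np.ndarray:
    """Unweighted mean of the subtoken vectors covering a character span.

    ``layer_vecs`` holds one row per subtoken (shape ``(n_subtokens, dim)``);
    for a span covered by a single subtoken this is that subtoken's vector
    unchanged.
    """
    idx = tokenization.covering(span)
    if not idx:
        raise AlignmentError(f"span {span} maps to no subtoken")
    return np.asarray(layer_vecs)[idx].mean(axis=0)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """``1 - u.v / (|u||v|)``; scale-invariant, symmetric, in [0, 2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance undefined for a zero vector")
    d = 1.0 - float(np.dot(u, v) / (nu * nv))
    # clip numerical spill just past the analytic range
    return min(2.0, max(0.0, d))


def anaphor_surprisal(
    encoder: EncoderInterface, item: ZeugmaItem, base: str = "e"
) -> float:
    """Surprisal of the anaphor at its masked position.

    The anaphor position is masked and the encoder's probability of the
    observed anaphor token filling it is converted to ``-log p``.  ``base``
    is ``"e"`` (nats, default) or ``"2"`` (bits); ``s = 0`` iff ``p = 1``.
    """
    if len(item.anaphor_text.strip().split()) > 1:
        raise ValueError(
            f"item {item.item!r} has a multiword anaphor; filter first"
        )
    p = encoder.masked_probability(item.sentence, item.anaphor_span, item.anaphor_text)
    if not (0.0 < p <= 1.0):
        raise EncoderContractError(f"encoder probability {p} outside (0, 1]")
    if base == "e":
        return -math.log(p)
    if base == "2":
        return -math.log2(p)
    raise ValueError(f"unsupported log base {base!r}")


def compute_item_metrics(
    encoder: EncoderInterface,
    items: Iterable[ZeugmaItem],
    base: str = "e",
) -> pd.DataFrame:
    """Cosine distances (all layers) and surprisal for each item.

    Returns a long-format frame with columns ``item``, ``condition``,
    ``layer`` (1..L), ``d_cos`` and ``surprisal`` (surprisal repeated across
    a given item's layers for convenient joining).
    """
    rows = []
    for it in items:
        tok = encoder.tokenize(it.sentence)
        vecs = np.asarray(encoder.layer_vectors(it.sentence))
        s = anaphor_surprisal(encoder, it, base=base)
        for layer in range(1, encoder.n_layers + 1):
            lv = vecs[layer - 1]
            u = span_embedding(lv, tok, it.target_span)
            v = span_embedding(lv, tok, it.anaphor_span)
            rows.append(
                {
                    "item": it.item,
                    "condition": it.condition,
                    "layer": layer,
                    "d_cos": cosine_distance(u, v),
                    "surprisal": s,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LayerCorrelation:
    layer: int
    r: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class LayerCorrelationSweep:
    per_layer: tuple[LayerCorrelation, ...] = field(default_factory=tuple)

    @property
    def strongest_layer(self) -> int:
        """Layer with the largest |r|."""
        best = max(self.per_layer, key=lambda c: abs(c.r))
        return best.layer

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.per_layer])


def layer_correlations(
    metrics: pd.DataFrame, item_means: Mapping[str, float] | pd.Series
) -> LayerCorrelationSweep:
    """Pearson r between cosine distance and human item means, per layer.

    The 95% CI uses the Fisher z transform, ``z = atanh(r)`` with standard
    error ``1/sqrt(n - 3)``.  Items are joined on identifier; layers with
    fewer than 4 paired observations or zero variance in either variable
    raise ``ValueError``.
    """
    means = pd.Series(item_means, dtype=float)
    out = []
    for layer, grp in metrics.groupby("layer"):
        joined = grp.set_index("item")["d_cos"].to_frame().join(
            means.rename("mean_similarity"), how="inner"
        )
        n = len(joined)
        if n < 4:
            raise ValueError(f"layer {layer}: only {n} paired observations (< 4)")
        x = joined["d_cos"].to_numpy()
        y = joined["mean_similarity"].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"layer {layer}: zero variance, r undefined")
        r, _ = stats.pearsonr(x, y)
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        half = stats.norm.ppf(0.975) / math.sqrt(n - 3)
        # clipping at |r| ~ 1 can push a bound fractionally inside r itself
        ci_low = min(float(np.tanh(z - half)), float(r))
        ci_high = max(float(np.tanh(z + half)), float(r))
        out.append(
            LayerCorrelation(
                layer=int(layer), r=float(r), ci_low=ci_low, ci_high=ci_high, n=n,
            )
        )
    return LayerCorrelationSweep(per_layer=tuple(sorted(out, key=lambda c: c.layer)))
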