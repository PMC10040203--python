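"""Shared constants and small helpers used across the norming modules."""

from __future__ import annotations

#: Ambiguity conditions, in alphabetical order.  Alphabetical order matters
#: downstream: treatment coding in the mixed models takes the first level
#: (Homonym) as the reference, matching R's default contrasts.
CONDITIONS: tuple[str, ...] = (
    "Homonym",
    "IrregularPolyseme",
    "RegularPolyseme",
    "Unambiguous",
)

#: Sentinel sense label for responses a rater judged to match multiple,
#: undifferentiable, or none of the candidate definitions.  Such ratings are
#: excluded from sense tallies and from the classified-response denominator.
OTHER: int = 0


class ConfigError(ValueError):
    """Raised when a study/generator configuration violates an invariant."""
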