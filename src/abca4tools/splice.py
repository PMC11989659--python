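"""In-silico splice-effect calls for non-canonical intronic variants.

Two lines of evidence are combined, mirroring how clinical variant
pipelines filter SpliceAI and MaxEntScan output:

* the maximum of the four SpliceAI delta scores (acceptor gain/loss,
  donor gain/loss), thresholded at >= 0.2 by default; and
* the MaxEntScan score difference ``variant - reference`` which, for a
  variant lying within a functional donor/acceptor site, indicates loss
  of the site when strictly negative.

Computing the scores themselves (running SpliceAI or MaxEntScan) is out
of scope; they arrive via the splice-score table.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Optional

__all__ = [
    "SpliceEffect",
    "DeltaChannel",
    "SplicePrediction",
    "SpliceCall",
    "delta_maxent",
    "call_splice_effect",
    "DEFAULT_DELTA_THRESHOLD",
]

#: SpliceAI delta score at or above which a gain/loss is called.
DEFAULT_DELTA_THRESHOLD = 0.2


class DeltaChannel(str, enum.Enum):
    ACCEPTOR_GAIN = "acceptor_gain"
    ACCEPTOR_LOSS = "acceptor_loss"
    DONOR_GAIN = "donor_gain"
    DONOR_LOSS = "donor_loss"


_LOSS_CHANNELS = frozenset({DeltaChannel.ACCEPTOR_LOSS, DeltaChannel.DONOR_LOSS})
# fixed evaluation order makes argmax tie-breaking deterministic
_CHANNEL_ORDER = (
    DeltaChannel.ACCEPTOR_GAIN,
    DeltaChannel.ACCEPTOR_LOSS,
    DeltaChannel.DONOR_GAIN,
    DeltaChannel.DONOR_LOSS,
)


class SpliceEffect(str, enum.Enum):
    LOSS_OF_SITE = "loss_of_site"
    GAIN_OF_SITE = "gain_of_site"
    NO_PREDICTED_EFFECT = "no_predicted_effect"


def delta_maxent(reference: Optional[float], variant: Optional[float]) -> float:
    """MaxEntScan score difference, ``variant - reference``.

    Raises :class:`ValueError` when either score is absent — an absent
    score must never silently read as zero, since zero has meaning here.
    """
    if reference is None or variant is None or \
            (isinstance(reference, float) and math.isnan(reference)) or \
            (isinstance(variant, float) and math.isnan(variant)):
        raise ValueError("delta MaxEnt not computable: missing score")
    return variant - reference


@dataclass(frozen=True)
class SplicePrediction:
    """Per-variant splice scores as read from the score table.

    ``delta_scores`` maps each :class:`DeltaChannel` to a fraction in
    [0, 1]; missing channels count as 0.  The MaxEntScan difference may
    be given either as the reference/variant pair or directly via
    ``maxent_delta`` (published tables often print only the difference).
    ``prior_severe_phenotype`` records prior literature evidence of a
    severe phenotype for this variant, which clinical practice accepts
    as deleterious evidence for intronic variants of unclear impact.
    """

    delta_scores: Mapping[DeltaChannel, float]
    delta_positions: Mapping[DeltaChannel, int] = None  # type: ignore[assignment]
    maxent_reference: Optional[float] = None
    maxent_variant: Optional[float] = None
    maxent_delta: Optional[float] = None
    prior_severe_phenotype: bool = False

    def __post_init__(self) -> None:
        for channel, value in self.delta_scores.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(
                    f"delta score for {channel} out of [0, 1]: {value}"
                )
        if self.delta_positions is None:
            object.__setattr__(self, "delta_positions", {})

    def delta(self, channel: DeltaChannel) -> float:
        return float(self.delta_scores.get(channel, 0.0))

    @property
    def delta_maxent(self) -> Optional[float]:
        """The MaxEntScan difference, or None when not computable."""
        if self.maxent_delta is not None:
            return self.maxent_delta
        if self.maxent_reference is None or self.maxent_variant is None:
            return None
        return delta_maxent(self.maxent_reference, self.maxent_variant)


@dataclass(frozen=True)
class SpliceCall:
    effect: SpliceEffect
    dominant_channel: DeltaChannel
    delta_max: float
    delta_maxent: Optional[float] = None

    @property
    def is_effect(self) -> bool:
        return self.effect is not SpliceEffect.NO_PREDICTED_EFFECT


def call_splice_effect(
    prediction: SplicePrediction,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    in_functional_site: bool = False,
) -> SpliceCall:
    """Call a splice-site gain/loss from in-silico scores.

    The dominant channel is the arg-max of the four delta scores (ties
    broken in fixed channel order).  A loss is called when the dominant
    channel is a loss channel and its score is at or above
    ``delta_threshold``, or when the variant lies within a functional
    splice site and the MaxEntScan difference is strictly negative; a
    gain is called symmetrically (a positive MaxEnt difference within a
    functional site is not treated as a gain — site strengthening is not
    site creation).  Otherwise there is no predicted effect.
    """
    if not (0.0 < delta_threshold < 1.0):
        raise ValueError(f"delta_threshold must be in (0, 1): {delta_threshold}")

    dominant = max(_CHANNEL_ORDER, key=prediction.delta)
    delta_max = prediction.delta(dominant)
    dme = prediction.delta_maxent

    effect = SpliceEffect.NO_PREDICTED_EFFECT
    if delta_max >= delta_threshold:
        effect = (SpliceEffect.LOSS_OF_SITE if dominant in _LOSS_CHANNELS
                  else SpliceEffect.GAIN_OF_SITE)
    elif in_functional_site and dme is not None and dme < 0:
        effect = SpliceEffect.LOSS_OF_SITE
    return SpliceCall(effect=effect, dominant_channel=dominant,
                      delta_max=delta_max, delta_maxent=dme)
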