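"""Insertion fitness effects and the per-generation TE lifecycle.

A TE landing inside a gene draws one of four fitness-effect classes —
lethal, deleterious, neutral or beneficial — from a fixed categorical
distribution.  Lethal and deleterious rates are fixed at 30% and 20%; the
beneficial probability BP is the experimental variable, and the neutral
rate absorbs the remainder.  A deleterious or beneficial hit changes the
host's survival likelihood once, by a multiplicative factor of magnitude
``mutation_effect`` (optionally scaled by a uniform draw); the change is
inherited but never re-applied in descendants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .genome import Genome, SiteKind


class EffectClass(Enum):
    LETHAL = "LETHAL"
    DELETERIOUS = "DELETERIOUS"
    NEUTRAL = "NEUTRAL"
    BENEFICIAL = "BENEFICIAL"


class MagnitudeMode(Enum):
    """How the effect magnitude Delta is drawn from mutation_effect Me."""

    UNIFORM = "uniform"  # Delta = Me * U(0,1)
    FIXED = "fixed"      # Delta = Me


_ORDER = (EffectClass.LETHAL, EffectClass.DELETERIOUS,
          EffectClass.NEUTRAL, EffectClass.BENEFICIAL)


@dataclass(frozen=True)
class EffectModel:
    """Categorical insertion-effect distribution plus effect magnitude."""

    p_lethal: float
    p_deleterious: float
    p_neutral: float
    p_beneficial: float
    mutation_effect: float
    magnitude_mode: MagnitudeMode = MagnitudeMode.UNIFORM

    def __post_init__(self):
        ps = (self.p_lethal, self.p_deleterious, self.p_neutral, self.p_beneficial)
        if any(p < 0 for p in ps):
            raise ValueError(f"negative class probability in {ps}")
        if abs(sum(ps) - 1.0) > 1e-12:
            raise ValueError(f"class probabilities sum to {sum(ps)}, not 1")
        if self.mutation_effect < 0:
            raise ValueError("mutation_effect must be >= 0")

    @property
    def probabilities(self) -> tuple[float, float, float, float]:
        """(lethal, deleterious, neutral, beneficial)."""
        return (self.p_lethal, self.p_deleterious, self.p_neutral,
                self.p_beneficial)


def make_effect_model(bp: float, mutation_effect: float,
                      p_lethal: float = 0.30, p_deleterious: float = 0.20,
                      magnitude_mode: MagnitudeMode = MagnitudeMode.UNIFORM,
                      ) -> EffectModel:
    """Build the effect model for a given beneficial probability BP.

    Lethal and deleterious rates default to the fixed 30%/20%; the neutral
    rate is derived so the four classes total 1.  BP large enough to drive
    the neutral rate negative (BP > 0.5 under the defaults) is rejected.
    """
    p_neutral = 1.0 - p_lethal - p_deleterious - bp
    if bp < 0 or p_neutral < -1e-12:
        raise ValueError(
            f"beneficial probability {bp} leaves neutral rate {p_neutral} < 0")
    return EffectModel(p_lethal, p_deleterious, max(p_neutral, 0.0), bp,
                       mutation_effect, magnitude_mode)


def draw_effect(model: EffectModel, rng: np.random.Generator) -> EffectClass:
    """One categorical draw of an insertion's fitness-effect class."""
    u = rng.random()
    acc = 0.0
    for cls, p in zip(_ORDER, model.probabilities):
        acc += p
        if u < acc:
            return cls
    return EffectClass.BENEFICIAL


def draw_effects(model: EffectModel, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorized ``draw_effect``: n class indices into
    (LETHAL, DELETERIOUS, NEUTRAL, BENEFICIAL)."""
    edges = np.cumsum(model.probabilities)
    return np.searchsorted(edges, rng.random(n), side="right")


def apply_insertion_effect(likelihood: float, effect: EffectClass,
                           model: EffectModel,
                           rng: np.random.Generator) -> tuple[float, bool]:
    """Apply one genic hit to a host's survival likelihood L.

    Returns ``(new_likelihood, lethal_flag)``.  Neutral hits leave L alone;
    beneficial/deleterious hits scale it by (1 +/- Delta) exactly once;
    a lethal hit flags the host dead without touching L.
    """
    if likelihood < 0:
        raise ValueError("survival likelihood must be >= 0")
    if effect is EffectClass.LETHAL:
        return likelihood, True
    if effect is EffectClass.NEUTRAL:
        return likelihood, False
    delta = model.mutation_effect
    if model.magnitude_mode is MagnitudeMode.UNIFORM:
        delta *= rng.random()
    if effect is EffectClass.BENEFICIAL:
        return likelihood * (1.0 + delta), False
    return likelihood * (1.0 - delta), False


@dataclass(frozen=True)
class TERates:
    """Per-TE per-generation lifecycle probabilities."""

    excision_rate: float  # probability a copy transposes this generation
    death_rate: float     # probability a copy dies this generation
    progeny: int          # new copies produced per transposition event

    def __post_init__(self):
        if not (0 <= self.excision_rate <= 1 and 0 <= self.death_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.progeny < 1:
            raise ValueError("progeny must be >= 1")


@dataclass
class TranspositionEvent:
    """One logged lifecycle event (death, or an insertion of a new copy)."""

    te_id: int
    kind: str                      # "death" | "insertion"
    site: Optional[SiteKind] = None
    effect: Optional[EffectClass] = None
    delta_l: float = 0.0


@dataclass
class StepResult:
    likelihood: float
    lethal: bool
    events: list[TranspositionEvent] = field(default_factory=list)


def transpose_step(genome: Genome, likelihood: float, rates: TERates,
                   effect_model: EffectModel, insertion_bias: float,
                   rng: np.random.Generator,
                   dead_te_retains_bp: bool = True,
                   inactivate_nested_target: bool = False,
                   log_events: bool = False) -> StepResult:
    """Run one generation of the TE lifecycle on a genome, in place.

    Event order is fixed for reproducibility: each active copy first risks
    death (exclusive — a dying copy does not transpose), then transposes
    with the excision rate, producing ``progeny`` new copies.  Each new copy
    samples an insertion site under the bias; genic landings draw an effect
    class and apply it to the host likelihood.  A lethal hit marks the host
    dead but the step completes so the event log is whole.
    """
    ids = genome.active_te_ids()
    result = StepResult(likelihood=likelihood, lethal=False)
    if not ids:
        return result
    u = rng.random(len(ids))
    dies = u < rates.death_rate
    moves = ~dies & (u < rates.death_rate
                     + (1.0 - rates.death_rate) * rates.excision_rate)
    for te_id, d in zip(ids, dies):
        if d:
            if dead_te_retains_bp:
                genome.deactivate_te(te_id)
            else:
                genome.remove_te(te_id)
            if log_events:
                result.events.append(TranspositionEvent(te_id, "death"))
    for te_id, m in zip(ids, moves):
        if not m or te_id not in genome.tes:
            continue
        for _ in range(rates.progeny):
            pos = genome.sample_insertion_site(insertion_bias, rng)
            site = genome.classify_site(pos)
            new_id = genome.insert_te(pos)
            dl = 0.0
            effect = None
            if site.kind is SiteKind.WITHIN_TE and inactivate_nested_target:
                genome.tes[site.te_id].active = False
            if site.kind is SiteKind.GENIC:
                effect = draw_effect(effect_model, rng)
                new_l, lethal = apply_insertion_effect(
                    result.likelihood, effect, effect_model, rng)
                dl = new_l - result.likelihood
                result.likelihood = new_l
                result.lethal = result.lethal or lethal
            if log_events:
                result.events.append(TranspositionEvent(
                    new_id, "insertion", site=site.kind, effect=effect,
                    delta_l=dl))
    return result
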