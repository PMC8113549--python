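"""Generative model of annotated zebra finch song.

The generator emits annotation logs — not audio — with the statistical
structure the sequence statistics assume: bouts of repeated introductory
notes followed by 2+ renditions of a stereotyped motif, run-length
distributed syllable repetition at designated positions, and per-rendition
pitch drawn around a per-syllable mean with a configurable coefficient of
variation.  Knockdown- or stimulation-like phenotypes (repeat inflation,
syllable omission, insertion of de novo syllables, pitch shifts) are
injected as :class:`EffectSpec` step changes, so parameter-recovery tests
can compare pipeline estimates against analytic expectations.

Repeat counts (renditions beyond the first in a run) follow a pluggable
distribution per element:

* ``geometric(p)`` — memoryless repeat/advance choice, mean (1-p)/p and
  variance (1-p)/p^2.  The minimal "motor loop" model, but the analytic
  repetition d' between two geometric conditions is bounded above by
  sqrt(2), because the mean and SD both scale as 1/p.
* ``poisson(lam)`` — mean = variance = lam.  Under-dispersed relative to a
  geometric with the same mean, which is what lets injected effects reach
  the d' ~ 2 regime reported for strong repetition phenotypes.

Timing respects the segmentation thresholds it is meant to exercise:
within-bout gaps stay under 100 ms (no spurious song boundaries) and
inter-bout gaps exceed 500 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from ..annotations import Recording, SyllableEvent
from ..sequence import VocalElement, as_element, dprime_from_moments

__all__ = [
    "RepeatDist",
    "geometric",
    "poisson",
    "SongModel",
    "EffectSpec",
    "default_model",
    "apply_effect",
    "generate_recording",
    "expected_repetition_dprime",
    "poisson_rate_for_dprime",
]


@dataclass(frozen=True)
class RepeatDist:
    """Distribution of per-run repeat counts (renditions beyond the first)."""

    kind: str  # "geometric" | "poisson"
    param: float

    def __post_init__(self) -> None:
        if self.kind == "geometric":
            if not 0 < self.param <= 1:
                raise ValueError("geometric parameter must be in (0, 1]")
        elif self.kind == "poisson":
            if self.param < 0:
                raise ValueError("poisson rate must be >= 0")
        else:
            raise ValueError(f"unknown repeat distribution '{self.kind}'")

    @property
    def mean(self) -> float:
        if self.kind == "geometric":
            return (1.0 - self.param) / self.param
        return self.param

    @property
    def variance(self) -> float:
        if self.kind == "geometric":
            return (1.0 - self.param) / self.param**2
        return self.param

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "geometric":
            return int(rng.geometric(self.param)) - 1
        return int(rng.poisson(self.param))


def geometric(p: float) -> RepeatDist:
    return RepeatDist("geometric", p)


def poisson(lam: float) -> RepeatDist:
    return RepeatDist("poisson", lam)


@dataclass(frozen=True)
class SongModel:
    """Parameterization of the synthetic song generator.

    Parameters
    ----------
    motif : tuple of str
        The stereotyped syllable sequence.
    intro_label : str
        Label of the introductory note that precedes the first motif.
    repeats : mapping of element -> RepeatDist
        Repeat-count distribution for repeat-eligible elements.  Each
        element draws one run per bout, at its first occurrence (the intro
        run, or the element's position in the first motif), which keeps the
        analytic d' of injected effects exact.
    omission_prob : mapping of syllable -> probability
        Per-motif probability that the syllable is dropped.
    insertion_prob : float
        Per-motif probability that the novel syllable is inserted at a
        uniformly chosen interior position.
    novel_label : str
        Label used for de novo inserted syllables; must be outside the
        baseline repertoire so additions are detectable by identity.
    motifs_per_bout : (low, high)
        Inclusive range of motif renditions per bout.
    pitch_mean : mapping of syllable -> Hz; pitch_cv : fractional CV.
    entropy_mean : mapping or None; entropy_cv : fractional CV of Wiener
        entropy (entropy is negative; the CV applies to its magnitude).
    syllable_duration, within_gap, inter_bout_gap : (low, high) seconds,
        uniform.  ``within_gap`` must stay below the 100 ms boundary rule
        and ``inter_bout_gap`` above the 500 ms bout rule.
    """

    motif: tuple[str, ...] = ("a", "b", "c", "d")
    intro_label: str = "i"
    repeats: Mapping[VocalElement, RepeatDist] = field(
        default_factory=lambda: {("i",): geometric(0.5), ("d",): geometric(0.9)}
    )
    omission_prob: Mapping[str, float] = field(default_factory=dict)
    insertion_prob: float = 0.0
    novel_label: str = "x1"
    motifs_per_bout: tuple[int, int] = (2, 4)
    pitch_mean: Mapping[str, float] = field(default_factory=dict)
    pitch_cv: float = 0.015
    entropy_mean: Mapping[str, float] = field(default_factory=dict)
    entropy_cv: float = 0.107
    syllable_duration: tuple[float, float] = (0.06, 0.12)
    within_gap: tuple[float, float] = (0.01, 0.06)
    inter_bout_gap: tuple[float, float] = (0.8, 2.0)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "repeats",
            {as_element(k): v for k, v in dict(self.repeats).items()},
        )
        if not self.motif:
            raise ValueError("motif must be non-empty")
        for s, w in self.omission_prob.items():
            if not 0 <= w <= 1:
                raise ValueError(f"omission probability for '{s}' out of [0,1]")
        if not 0 <= self.insertion_prob <= 1:
            raise ValueError("insertion probability out of [0,1]")
        if self.novel_label in self.repertoire:
            raise ValueError("novel label must be outside the baseline repertoire")
        lo, hi = self.motifs_per_bout
        if not (1 <= lo <= hi):
            raise ValueError("motifs_per_bout must satisfy 1 <= low <= high")
        if self.within_gap[1] >= 0.1:
            raise ValueError("within-bout gaps must stay below the 100 ms boundary")
        if self.inter_bout_gap[0] <= 0.5:
            raise ValueError("inter-bout gaps must exceed the 500 ms bout rule")

    @property
    def repertoire(self) -> set[str]:
        return set(self.motif) | {self.intro_label}

    def pitch_for(self, label: str) -> float:
        if label in self.pitch_mean:
            return self.pitch_mean[label]
        # deterministic fallback spread over a plausible zebra finch range
        return 500.0 + 90.0 * (sum(map(ord, label)) % 13)

    def entropy_for(self, label: str) -> float:
        return self.entropy_mean.get(label, -2.5)

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "motif": list(self.motif),
            "intro_label": self.intro_label,
            "repeats": {
                " ".join(k): {"kind": v.kind, "param": v.param}
                for k, v in self.repeats.items()
            },
            "omission_prob": dict(self.omission_prob),
            "insertion_prob": self.insertion_prob,
            "novel_label": self.novel_label,
            "motifs_per_bout": list(self.motifs_per_bout),
            "pitch_mean": dict(self.pitch_mean),
            "pitch_cv": self.pitch_cv,
            "entropy_mean": dict(self.entropy_mean),
            "entropy_cv": self.entropy_cv,
            "syllable_duration": list(self.syllable_duration),
            "within_gap": list(self.within_gap),
            "inter_bout_gap": list(self.inter_bout_gap),
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SongModel":
        doc = yaml.safe_load(text)
        doc["motif"] = tuple(doc["motif"])
        doc["repeats"] = {
            tuple(k.split()): RepeatDist(v["kind"], v["param"])
            for k, v in doc.get("repeats", {}).items()
        }
        for key in ("motifs_per_bout", "syllable_duration", "within_gap", "inter_bout_gap"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def default_model(**overrides) -> SongModel:
    """A typical four-syllable motif with repeated intro and end syllables."""
    base = dict(
        motif=("a", "b", "c", "d"),
        intro_label="i",
        repeats={("i",): geometric(0.5), ("d",): geometric(0.9)},
        pitch_mean={"i": 520.0, "a": 650.0, "b": 980.0, "c": 1430.0, "d": 760.0},
    )
    base.update(overrides)
    return SongModel(**base)


@dataclass(frozen=True)
class EffectSpec:
    """A step change applied to a song model (knockdown/stimulation-like).

    ``repeat`` replaces the repeat distribution of ``element``;
    ``omission_delta`` adds to per-syllable omission probabilities;
    ``insertion_delta`` adds to the novel-syllable insertion probability;
    ``pitch_shift_sd`` shifts per-syllable mean pitch in units of the
    syllable's baseline SD (cv * mean).
    """

    element: str | Sequence[str] | None = None
    repeat: RepeatDist | None = None
    omission_delta: Mapping[str, float] = field(default_factory=dict)
    insertion_delta: float = 0.0
    pitch_shift_sd: Mapping[str, float] = field(default_factory=dict)


def apply_effect(model: SongModel, effect: EffectSpec) -> SongModel:
    """Return a new model with the effect applied; the input is unchanged."""
    changes: dict = {}
    if effect.repeat is not None:
        if effect.element is None:
            raise ValueError("an element is required to change its repeats")
        repeats = dict(model.repeats)
        repeats[as_element(effect.element)] = effect.repeat
        changes["repeats"] = repeats
    if effect.omission_delta:
        om = dict(model.omission_prob)
        for s, d in effect.omission_delta.items():
            om[s] = om.get(s, 0.0) + d
            if not 0 <= om[s] <= 1:
                raise ValueError(f"omission probability for '{s}' out of [0,1]")
        changes["omission_prob"] = om
    if effect.insertion_delta:
        p = model.insertion_prob + effect.insertion_delta
        if not 0 <= p <= 1:
            raise ValueError("insertion probability out of [0,1]")
        changes["insertion_prob"] = p
    if effect.pitch_shift_sd:
        pitch = dict(model.pitch_mean)
        for s, shift in effect.pitch_shift_sd.items():
            mu = model.pitch_for(s)
            pitch[s] = mu + shift * model.pitch_cv * mu
        changes["pitch_mean"] = pitch
    return replace(model, **changes) if changes else model


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _bout_tokens(model: SongModel, rng: np.random.Generator) -> list[str]:
    tokens: list[str] = []
    drawn: set[VocalElement] = set()

    def maybe_repeat(element: VocalElement) -> None:
        """Append extra renditions after the element's first run this bout."""
        dist = model.repeats.get(element)
        if dist is None or element in drawn:
            return
        drawn.add(element)
        for _ in range(dist.sample(rng)):
            tokens.extend(element)

    intro = (model.intro_label,)
    tokens.append(model.intro_label)
    maybe_repeat(intro)

    n_motifs = int(rng.integers(model.motifs_per_bout[0], model.motifs_per_bout[1] + 1))
    L = len(model.motif)
    for _ in range(n_motifs):
        insert_at = -1
        if model.insertion_prob > 0 and rng.random() < model.insertion_prob:
            insert_at = int(rng.integers(1, L)) if L > 1 else 1
        pos_in_motif = 0
        for s in model.motif:
            if pos_in_motif == insert_at:
                tokens.append(model.novel_label)
            pos_in_motif += 1
            if rng.random() < model.omission_prob.get(s, 0.0):
                continue
            tokens.append(s)
            # single-syllable repeat-eligible elements anchored at this spot
            maybe_repeat((s,))
        # multi-syllable elements repeat after their first full occurrence
        for element in model.repeats:
            if len(element) > 1 and element not in drawn:
                k = len(element)
                for start in range(len(tokens) - k + 1):
                    if tuple(tokens[start : start + k]) == element:
                        if start + k == len(tokens):
                            maybe_repeat(element)
                        break
    return tokens


def generate_recording(
    model: SongModel,
    n_bouts: int,
    seed: int,
    recording_id: str = "sim",
    timepoint: str = "baseline",
) -> Recording:
    """Generate an annotated recording of ``n_bouts`` song bouts.

    Deterministic for a fixed seed; each bout consumes an independent
    substream spawned from the seed, so bout k is reproducible regardless
    of how many bouts are requested.
    """
    if n_bouts < 1:
        raise ValueError("n_bouts must be >= 1")
    substreams = np.random.SeedSequence(seed).spawn(n_bouts + 1)
    clock_rng = np.random.default_rng(substreams[0])
    events: list[SyllableEvent] = []
    t = 0.5
    for b in range(n_bouts):
        rng = np.random.default_rng(substreams[b + 1])
        for k, label in enumerate(_bout_tokens(model, rng)):
            if k > 0:
                t += clock_rng.uniform(*model.within_gap)
            dur = clock_rng.uniform(*model.syllable_duration)
            mu = model.pitch_for(label)
            pitch = rng.normal(mu, model.pitch_cv * mu)
            emu = model.entropy_for(label)
            entropy = rng.normal(emu, model.entropy_cv * abs(emu))
            events.append(SyllableEvent(label, t, t + dur, pitch, entropy))
            t += dur
        t += clock_rng.uniform(*model.inter_bout_gap)
    return Recording(recording_id, events, timepoint=timepoint)


# ---------------------------------------------------------------------------
# Analytic expectations
# ---------------------------------------------------------------------------


def expected_repetition_dprime(
    model_b: SongModel, model_i: SongModel, element: str | Sequence[str]
) -> float:
    """Closed-form repetition d' between two models for one element.

    Valid because each model draws exactly one repeat run per bout for the
    element, so per-bout counts follow the element's repeat distribution
    directly.
    """
    element = as_element(element)
    try:
        db = model_b.repeats[element]
        di = model_i.repeats[element]
    except KeyError as exc:
        raise ValueError(
            f"element {element} has no repeat distribution in both models"
        ) from exc
    return dprime_from_moments(di.mean, di.variance, db.mean, db.variance)


def poisson_rate_for_dprime(baseline: RepeatDist, target: float) -> float:
    """Poisson repeat rate that yields an analytic d' of ``target``.

    Solves sqrt(2)(lam - m_b) = target * sqrt(lam + v_b) for lam >= m_b
    (target >= 0), where m_b, v_b are the baseline repeat moments.
    """
    if target < 0:
        raise ValueError("target d' must be >= 0 for a rate above baseline")
    mb, vb = baseline.mean, baseline.variance
    if target == 0:
        return mb
    # 2(lam - mb)^2 = t^2 (lam + vb)  ->  2 lam^2 - (4 mb + t^2) lam + (2 mb^2 - t^2 vb) = 0
    t2 = target**2
    a, b, c = 2.0, -(4.0 * mb + t2), 2.0 * mb**2 - t2 * vb
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("no real Poisson rate reaches that d'")
    lam = (-b + math.sqrt(disc)) / (2 * a)
    return lam
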