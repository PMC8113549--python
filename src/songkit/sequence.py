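"""Repetition, d-prime, transition-matrix and variability statistics.

The central quantity is the per-bout repeat count of a *vocal element* (a
single syllable or a short multi-syllable unit): the total number of
consecutively repeated renditions of the element within a song bout, not
counting the first rendition of each run.  Day-to-day changes in repetition
(or in any per-rendition feature such as pitch) are expressed with the
standardized effect size

    d' = sqrt(2) * (n_i - n_b) / sqrt(sigma_i^2 + sigma_b^2)

where ``n`` and ``sigma^2`` are the mean and sample variance of the per-bout
counts (or per-rendition features) on day *i* and the baseline day *b*.
When the two variances are equal, d' is the change in units of SD.

Syllable-to-syllable transition structure is summarised as a first-order
transition matrix over syllable labels plus the song-boundary token ``"/"``
(inserted wherever the silent gap exceeds 100 ms and at recording edges,
after removal of isolated calls).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    Recording,
    SegmentationConfig,
    SongBout,
    drop_isolated_calls,
)

__all__ = [
    "BOUNDARY",
    "as_element",
    "count_repeats",
    "max_run_repeats",
    "select_repeating_elements",
    "RepetitionSeries",
    "repetition_series",
    "DPrimeResult",
    "dprime",
    "dprime_from_moments",
    "PitchShiftResult",
    "pitch_shift_dprime",
    "coefficient_of_variation",
    "TransitionMatrix",
    "transition_matrix",
    "transition_matrix_from_streams",
    "prune_rare_states",
    "difference_matrix",
    "percent_bouts_with_change",
]

#: Token marking a song boundary (silence > 100 ms or a recording edge).
BOUNDARY = "/"

VocalElement = tuple[str, ...]


class DegenerateVarianceError(ValueError):
    """Both variances are zero but the means differ: d' is undefined."""


def as_element(element: str | Sequence[str]) -> VocalElement:
    """Normalize an element given as a string or token sequence to a tuple."""
    if isinstance(element, str):
        element = (element,)
    element = tuple(element)
    if not element or any(not t for t in element):
        raise ValueError("vocal element must be a non-empty sequence of tokens")
    return element


def _iter_runs(labels: Sequence[str], element: VocalElement):
    """Yield lengths of maximal runs of back-to-back element occurrences.

    Occurrences are tiled greedily left to right without overlap, the unique
    tiling consistent with "consecutively repeated".
    """
    k = len(element)
    n = len(labels)
    i = 0
    while i <= n - k:
        if tuple(labels[i : i + k]) == element:
            run = 1
            j = i + k
            while j <= n - k and tuple(labels[j : j + k]) == element:
                run += 1
                j += k
            yield run
            i = j
        else:
            i += 1


def count_repeats(bout_labels: Sequence[str], element: str | Sequence[str]) -> int:
    """Total consecutive repeats of ``element`` in a bout's label sequence.

    Each maximal run of ``k`` back-to-back renditions contributes ``k - 1``
    (the first rendition of a run is not a repeat).

    >>> count_repeats("i i i a b c i i".split(), "i")
    3
    >>> count_repeats(["h", "h'", "h", "h'", "a"], ("h", "h'"))
    1
    """
    element = as_element(element)
    return sum(run - 1 for run in _iter_runs(bout_labels, element))


def max_run_repeats(bout_labels: Sequence[str], element: str | Sequence[str]) -> int:
    """Largest single-run repeat count (run length - 1) of ``element``."""
    element = as_element(element)
    return max((run - 1 for run in _iter_runs(bout_labels, element)), default=0)


def _is_periodic(element: VocalElement) -> bool:
    """True if the element is itself a repetition of a shorter unit."""
    k = len(element)
    for p in range(1, k):
        if k % p == 0 and element == element[:p] * (k // p):
            return True
    return False


def select_repeating_elements(
    bouts: Sequence[SongBout | Sequence[str]],
    min_repeats: int = 2,
    max_element_len: int = 3,
) -> list[VocalElement]:
    """Find vocal elements observed to repeat ``min_repeats``+ times in a run.

    Scans all 1..``max_element_len``-token windows of every bout and keeps
    elements whose maximum single-run repeat count reaches ``min_repeats``
    (i.e. run length >= min_repeats + 1) in at least one bout.  Periodic
    multi-token windows (e.g. ("a", "a")) are skipped — the underlying unit
    is already reported.
    """
    found: dict[VocalElement, int] = {}
    for bout in bouts:
        labels = bout.label_sequence if isinstance(bout, SongBout) else list(bout)
        for k in range(1, max_element_len + 1):
            seen: set[VocalElement] = set()
            for start in range(0, len(labels) - k + 1):
                element = tuple(labels[start : start + k])
                if element in seen or (k > 1 and _is_periodic(element)):
                    continue
                seen.add(element)
                best = max_run_repeats(labels, element)
                if best > found.get(element, 0):
                    found[element] = best
    return sorted(
        (e for e, best in found.items() if best >= min_repeats),
        key=lambda e: (len(e), e),
    )


# ---------------------------------------------------------------------------
# d-prime
# ---------------------------------------------------------------------------


@dataclass
class RepetitionSeries:
    """Per-bout repeat counts of one vocal element on one day."""

    element: VocalElement
    day: str
    per_bout_counts: list[int]

    def __post_init__(self) -> None:
        self.element = as_element(self.element)
        if len(self.per_bout_counts) < 2:
            raise ValueError(
                "need at least 2 bouts for a repetition series "
                f"(got {len(self.per_bout_counts)})"
            )
        if any(c < 0 for c in self.per_bout_counts):
            raise ValueError("repeat counts must be non-negative")

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_bout_counts))

    @property
    def variance(self) -> float:
        """Sample variance (n-1 denominator)."""
        return float(np.var(self.per_bout_counts, ddof=1))

    @property
    def n_bouts(self) -> int:
        return len(self.per_bout_counts)


def repetition_series(
    bouts: Sequence[SongBout | Sequence[str]],
    element: str | Sequence[str],
    day: str = "baseline",
) -> RepetitionSeries:
    """Count repeats of ``element`` in every bout of one day."""
    element = as_element(element)
    counts = []
    for bout in bouts:
        labels = bout.label_sequence if isinstance(bout, SongBout) else list(bout)
        counts.append(count_repeats(labels, element))
    return RepetitionSeries(element, day, counts)


@dataclass(frozen=True)
class DPrimeResult:
    """Signed d' between a comparison day and baseline, with components."""

    value: float
    day_i: str
    day_b: str
    mean_i: float
    var_i: float
    mean_b: float
    var_b: float

    def __float__(self) -> float:
        return self.value


def dprime_from_moments(
    mean_i: float, var_i: float, mean_b: float, var_b: float
) -> float:
    """d' = sqrt(2) (mean_i - mean_b) / sqrt(var_i + var_b).

    Returns 0 when both variances vanish and the means agree; raises
    :class:`DegenerateVarianceError` when they vanish but the means differ.
    """
    if var_i < 0 or var_b < 0:
        raise ValueError("variances must be non-negative")
    denom = var_i + var_b
    if denom == 0:
        if mean_i == mean_b:
            return 0.0
        raise DegenerateVarianceError(
            "zero variance on both days with unequal means "
            f"({mean_i} vs {mean_b}): d' is infinite"
        )
    return math.sqrt(2.0) * (mean_i - mean_b) / math.sqrt(denom)


def dprime(series_i: RepetitionSeries, series_b: RepetitionSeries) -> DPrimeResult:
    """Standardized change in per-bout repeats between day i and baseline.

    Positive values mean more repetition on day *i* than at baseline.
    """
    value = dprime_from_moments(
        series_i.mean, series_i.variance, series_b.mean, series_b.variance
    )
    return DPrimeResult(
        value=value,
        day_i=series_i.day,
        day_b=series_b.day,
        mean_i=series_i.mean,
        var_i=series_i.variance,
        mean_b=series_b.mean,
        var_b=series_b.variance,
    )


@dataclass(frozen=True)
class PitchShiftResult:
    """Absolute pitch-change effect size and the learning-criterion flag."""

    value: float  # |d'|
    signed: float
    learned: bool
    learning_criterion: float


def pitch_shift_dprime(
    features_i: Sequence[float],
    features_b: Sequence[float],
    learning_criterion: float = 0.75,
) -> PitchShiftResult:
    """|d'| of a per-rendition feature (pitch) between two days.

    The flag is set when |d'| exceeds ``learning_criterion`` (default 0.75,
    the criterion for a significant pitch change).
    """
    if len(features_i) < 2 or len(features_b) < 2:
        raise ValueError("need at least 2 renditions per day")
    signed = dprime_from_moments(
        float(np.mean(features_i)),
        float(np.var(features_i, ddof=1)),
        float(np.mean(features_b)),
        float(np.var(features_b, ddof=1)),
    )
    return PitchShiftResult(
        value=abs(signed),
        signed=signed,
        learned=abs(signed) > learning_criterion,
        learning_criterion=learning_criterion,
    )


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV in percent: 100 * sample SD / |mean|."""
    if len(values) < 2:
        raise ValueError("need at least 2 values for a CV")
    mean = float(np.mean(values))
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * float(np.std(values, ddof=1)) / abs(mean)


# ---------------------------------------------------------------------------
# Transition matrices
# ---------------------------------------------------------------------------


@dataclass
class TransitionMatrix:
    """First-order transition counts/probabilities over syllable labels + "/".

    ``streams`` keeps the boundary-marked token streams the matrix was
    tallied from, so rare states can be pruned by *re-tallying* rather than
    renormalizing (pruned-state probability mass is not redistributed
    arbitrarily).
    """

    counts: pd.DataFrame
    streams: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.counts.columns):
            raise ValueError("transition counts must be square and aligned")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("transition counts must be non-negative")
        if BOUNDARY in self.counts.index and self.counts.loc[BOUNDARY, BOUNDARY] != 0:
            raise ValueError('the boundary token "/" cannot self-transition')

    @property
    def states(self) -> list[str]:
        return list(self.counts.index)

    @property
    def probabilities(self) -> pd.DataFrame:
        """Row-normalized transition probabilities (all-zero rows stay zero)."""
        arr = self.counts.to_numpy(dtype=float)
        sums = arr.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(sums > 0, arr / np.where(sums == 0, 1, sums), 0.0)
        return pd.DataFrame(probs, index=self.counts.index, columns=self.counts.columns)

    @property
    def n_transitions(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_tsv(self, path) -> None:
        self.probabilities.to_csv(path, sep="\t")


def _order_states(labels: Iterable[str]) -> list[str]:
    syl = sorted({s for s in labels if s != BOUNDARY})
    return syl + [BOUNDARY]


def transition_matrix_from_streams(streams: Sequence[Sequence[str]]) -> TransitionMatrix:
    """Tally all adjacent (state, next state) pairs in boundary-marked streams."""
    pairs: list[tuple[str, str]] = []
    clean_streams: list[list[str]] = []
    for stream in streams:
        # collapse any accidental double boundaries
        toks: list[str] = []
        for t in stream:
            if t == BOUNDARY and toks and toks[-1] == BOUNDARY:
                continue
            toks.append(t)
        clean_streams.append(toks)
        pairs.extend(zip(toks[:-1], toks[1:]))
    if not pairs:
        raise ValueError("no transitions to tally")
    states = _order_states(t for s in clean_streams for t in s)
    counts = pd.DataFrame(0, index=states, columns=states, dtype=int)
    for a, b in pairs:
        counts.loc[a, b] += 1
    return TransitionMatrix(counts, clean_streams)


def _boundary_stream(rec: Recording, cfg: SegmentationConfig) -> list[str]:
    events = drop_isolated_calls(rec.events, cfg)
    stream = [BOUNDARY]
    for i, e in enumerate(events):
        if i > 0 and e.onset - events[i - 1].offset > cfg.boundary_gap:
            stream.append(BOUNDARY)
        stream.append(e.label)
    stream.append(BOUNDARY)
    return stream if len(stream) > 2 else []


def transition_matrix(
    recordings: Recording | Sequence[Recording],
    cfg: SegmentationConfig | None = None,
) -> TransitionMatrix:
    """Syllable transition matrix from one or more recordings.

    Isolated calls are removed, ``"/"`` is inserted at every silent gap over
    ``cfg.boundary_gap`` (100 ms) and at the recording edges, and every
    adjacent pair is tallied.
    """
    cfg = cfg or SegmentationConfig()
    if isinstance(recordings, Recording):
        recordings = [recordings]
    streams = [s for rec in recordings if (s := _boundary_stream(rec, cfg))]
    return transition_matrix_from_streams(streams)


def _bout_presence_fraction(
    bouts: Sequence[SongBout | Sequence[str]], label: str
) -> float:
    seqs = [
        b.label_sequence if isinstance(b, SongBout) else list(b) for b in bouts
    ]
    if not seqs:
        return 0.0
    return sum(label in s for s in seqs) / len(seqs)


def prune_rare_states(
    tm: TransitionMatrix,
    bouts_by_timepoint: Mapping[str, Sequence[SongBout | Sequence[str]]],
    min_bout_fraction: float = 0.20,
) -> TransitionMatrix:
    """Drop syllables present in under 20% of bouts at any timepoint.

    The surviving matrix is re-tallied from the stored streams with pruned
    labels removed, rather than renormalized, so no probability mass is
    silently reassigned.  The boundary token is never pruned.
    """
    syllables = [s for s in tm.states if s != BOUNDARY]
    pruned = {
        s
        for s in syllables
        if any(
            _bout_presence_fraction(bouts, s) < min_bout_fraction
            for bouts in bouts_by_timepoint.values()
        )
    }
    if len(pruned) == len(syllables):
        raise ValueError("pruning removed every syllable state")
    if not pruned:
        return TransitionMatrix(tm.counts.copy(), [list(s) for s in tm.streams])
    new_streams = [
        [t for t in stream if t not in pruned] for stream in tm.streams
    ]
    return transition_matrix_from_streams(new_streams)


def difference_matrix(
    baseline: TransitionMatrix,
    comparison: TransitionMatrix,
    flip: bool = False,
) -> pd.DataFrame:
    """Baseline-minus-comparison transition probability differences.

    States missing from one matrix contribute all-zero rows/columns; set
    ``flip`` to report comparison - baseline instead.
    """
    sb, sc = set(baseline.states), set(comparison.states)
    if not (sb & sc):
        raise ValueError("transition matrices share no states")
    states = _order_states(sb | sc)
    pb = baseline.probabilities.reindex(index=states, columns=states, fill_value=0.0)
    pc = comparison.probabilities.reindex(index=states, columns=states, fill_value=0.0)
    diff = pb - pc
    return -diff if flip else diff


def percent_bouts_with_change(
    flags: Sequence[bool],
    sampled_bouts: int = 30,
    seed: int | np.random.Generator = 0,
) -> float:
    """Percent of a seeded 30-bout sample exhibiting a change.

    ``flags`` holds one boolean per available bout.  If fewer than
    ``sampled_bouts`` bouts are available, all are used (with a warning).
    """
    if len(flags) == 0:
        raise ValueError("no bouts available")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    flags_arr = np.asarray(flags, dtype=bool)
    if len(flags_arr) < sampled_bouts:
        warnings.warn(
            f"only {len(flags_arr)} bouts available; using all", stacklevel=2
        )
        sample = flags_arr
    else:
        idx = rng.choice(len(flags_arr), size=sampled_bouts, replace=False)
        sample = flags_arr[idx]
    return 100.0 * float(sample.mean())
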