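"""Classification of syntax changes against a baseline motif template.

A bird's baseline motif is a stereotyped ordered sequence of syllables.
After a manipulation, three kinds of change are scored in each song bout:

* **omissions** — template syllables dropped from a motif rendition;
* **additions** — de novo syllables (labels absent from the baseline
  repertoire) inserted into a motif;
* **new transitions** — adjacent syllable pairs not observed at baseline.

A bout counts as *syntax-altered* only when an edit falls in the interior of
the motif: omissions and additions at the beginning or end of a motif are
recorded but are, by definition, not syntax alterations.

Because repetition is quantified separately (see :mod:`songkit.sequence`),
maximal runs of repeated elements are collapsed to a single rendition before
alignment, so repetition never masquerades as insertion.  Motif renditions
are matched to the template by global alignment with unit mismatch/indel
costs; among co-optimal alignments the one whose deletions fall leftmost is
used.  The number of motif renditions per bout is chosen to minimize the
alignment cost (ties favour fewer renditions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotations import SongBout
from .sequence import VocalElement, select_repeating_elements

__all__ = [
    "MotifTemplate",
    "SyntaxChangeReport",
    "BoutSyntax",
    "collapse_runs",
    "align_to_template",
    "classify_bout",
    "classify_syntax_changes",
]


@dataclass(frozen=True)
class MotifTemplate:
    """Baseline motif (ordered syllable labels) plus introductory labels."""

    motif: tuple[str, ...]
    intro_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("motif template must be non-empty")
        interior = set(self.motif[1:-1])
        if interior & self.intro_labels:
            raise ValueError(
                "intro labels must be disjoint from the motif interior: "
                f"{sorted(interior & self.intro_labels)}"
            )

    @classmethod
    def from_string(cls, spec: str, intro: str = "") -> "MotifTemplate":
        """Parse ``"a,b,c,d"`` (or space-separated) motif specs."""
        sep = "," if "," in spec else None
        motif = tuple(t for t in spec.replace(",", " ").split() if t)
        intro_labels = frozenset(t for t in intro.replace(",", " ").split() if t)
        del sep
        return cls(motif, intro_labels)


def collapse_runs(
    tokens: Sequence[str], elements: Sequence[VocalElement] = ()
) -> list[str]:
    """Collapse maximal runs of repeated elements to a single rendition.

    Runs of a single token are always collapsed; runs of the supplied
    multi-token elements (longest first, greedy, non-overlapping) are
    collapsed as well.
    """
    multi = sorted((e for e in elements if len(e) > 1), key=len, reverse=True)
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for element in multi:
            k = len(element)
            if tuple(tokens[i : i + k]) == element:
                j = i + k
                while tuple(tokens[j : j + k]) == element:
                    j += k
                out.extend(element)
                i = j
                matched = True
                break
        if matched:
            continue
        tok = tokens[i]
        out.append(tok)
        while i < n and tokens[i] == tok:
            i += 1
    return out


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

# Alignment ops: ("match"|"sub", template_pos, obs_pos), ("del", template_pos),
# ("ins", template_pos_before_which, obs_pos)


def _needleman_wunsch(ref: Sequence[str], obs: Sequence[str]):
    """Global alignment, cost 0 match / 1 mismatch / 1 indel.

    Backtracking prefers diagonal, then insertion, then deletion, which
    pushes co-optimal deletions to the leftmost position.
    """
    n, m = len(ref), len(obs)
    D = np.zeros((n + 1, m + 1), dtype=np.int32)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = D[i - 1, j - 1] + (ref[i - 1] != obs[j - 1])
            D[i, j] = min(sub, D[i - 1, j] + 1, D[i, j - 1] + 1)
    ops = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (ref[i - 1] != obs[j - 1]):
            ops.append(
                ("match" if ref[i - 1] == obs[j - 1] else "sub", i - 1, j - 1)
            )
            i, j = i - 1, j - 1
        elif j > 0 and D[i, j] == D[i, j - 1] + 1:
            ops.append(("ins", i, j - 1))
            j -= 1
        else:
            ops.append(("del", i - 1))
            i -= 1
    ops.reverse()
    return int(D[n, m]), ops


def align_to_template(
    template: Sequence[str], observed: Sequence[str], max_copies: int | None = None
):
    """Align an observed motif-region sequence to 1+ template renditions.

    Returns ``(n_copies, cost, ops)`` for the rendition count minimizing the
    global alignment cost (ties resolved toward fewer renditions).  Template
    positions in the ops index into the concatenated reference; divide by
    ``len(template)`` for the copy and position within the motif.
    """
    if not template:
        raise ValueError("empty template")
    L = len(template)
    if max_copies is None:
        max_copies = max(1, -(-len(observed) // L) + 1)
    best = None
    for m in range(1, max_copies + 1):
        cost, ops = _needleman_wunsch(list(template) * m, observed)
        if best is None or cost < best[1]:
            best = (m, cost, ops)
    return best


@dataclass
class BoutSyntax:
    """Per-bout classification of motif edits."""

    n_motifs: int = 0
    alignment_cost: int = 0
    omissions: list[tuple[str, int, int, bool]] = field(default_factory=list)
    #: (label, motif index, position in motif, interior?)
    additions: list[tuple[str, int, int, bool]] = field(default_factory=list)
    insertions_existing: list[tuple[str, int, int, bool]] = field(default_factory=list)
    new_transitions: list[tuple[str, str]] = field(default_factory=list)
    syntax_altered: bool = False

    @property
    def has_omission(self) -> bool:
        return bool(self.omissions)

    @property
    def has_addition(self) -> bool:
        return bool(self.additions)


def classify_bout(
    template: MotifTemplate,
    bout_tokens: Sequence[str],
    baseline_pairs: set[tuple[str, str]],
    baseline_repertoire: set[str],
    collapse_elements: Sequence[VocalElement] = (),
) -> BoutSyntax:
    """Classify one bout's motif region against the baseline template."""
    collapsed = collapse_runs(list(bout_tokens), collapse_elements)
    # strip leading introductory elements; they are not part of the motif
    start = 0
    while start < len(collapsed) and collapsed[start] in template.intro_labels:
        start += 1
    motif_region = collapsed[start:]
    result = BoutSyntax()
    if not motif_region:
        return result
    ref_motif = collapse_runs(list(template.motif), collapse_elements)
    L = len(ref_motif)
    m, cost, ops = align_to_template(ref_motif, motif_region)
    result.n_motifs = m
    result.alignment_cost = cost

    def record(kind_list, label, tpos, interior):
        kind_list.append((label, tpos // L, tpos % L, interior))

    interior_edit = False
    for op in ops:
        if op[0] == "match":
            continue
        if op[0] == "del":
            tpos = op[1]
            interior = 0 < tpos % L < L - 1
            record(result.omissions, ref_motif[tpos % L], tpos, interior)
            interior_edit |= interior
        elif op[0] == "ins":
            tpos, opos = op[1], op[2]
            label = motif_region[opos]
            interior = tpos % L != 0
            if label not in baseline_repertoire:
                record(result.additions, label, tpos, interior)
            else:
                record(result.insertions_existing, label, tpos, interior)
            interior_edit |= interior
        else:  # substitution = omission + insertion at the same spot
            tpos, opos = op[1], op[2]
            interior = 0 < tpos % L < L - 1
            record(result.omissions, ref_motif[tpos % L], tpos, interior)
            label = motif_region[opos]
            if label not in baseline_repertoire:
                record(result.additions, label, tpos, interior)
            else:
                record(result.insertions_existing, label, tpos, interior)
            interior_edit |= interior

    result.new_transitions = sorted(
        {
            pair
            for pair in zip(motif_region[:-1], motif_region[1:])
            if pair not in baseline_pairs
        }
    )
    result.syntax_altered = interior_edit
    return result


@dataclass
class SyntaxChangeReport:
    """Aggregate syntax-change report over a sample of song bouts."""

    template: MotifTemplate
    n_bouts_sampled: int
    per_bout: list[BoutSyntax]
    new_transitions: list[tuple[str, str]]
    omissions: list[tuple[str, int]]  # (label, position in motif)
    additions: list[tuple[str, int]]
    pct_bouts_syntax_altered: float
    pct_bouts_with_omission: float
    pct_bouts_with_addition: float


def _bout_labels(bout: SongBout | Sequence[str]) -> list[str]:
    return bout.label_sequence if isinstance(bout, SongBout) else list(bout)


def classify_syntax_changes(
    template: MotifTemplate,
    baseline_bouts: Sequence[SongBout | Sequence[str]],
    post_bouts: Sequence[SongBout | Sequence[str]],
    sampled_bouts: int = 30,
    seed: int = 0,
    collapse_elements: Sequence[VocalElement] | None = None,
) -> SyntaxChangeReport:
    """Score omissions, additions and new transitions in post bouts.

    Baseline bouts define the observed transition pairs and the syllable
    repertoire.  ``sampled_bouts`` post bouts (default 30) are drawn with a
    seeded uniform sample without replacement; if fewer are available all
    are used.  Repeat-eligible multi-syllable elements are auto-detected
    from the pooled bouts unless ``collapse_elements`` is given.
    """
    if not post_bouts:
        raise ValueError("post_bouts must be non-empty")
    base_seqs = [_bout_labels(b) for b in baseline_bouts]
    post_seqs = [_bout_labels(b) for b in post_bouts]
    if collapse_elements is None:
        collapse_elements = [
            e
            for e in select_repeating_elements(
                base_seqs + post_seqs, min_repeats=1, max_element_len=3
            )
            if len(e) > 1
        ]
    base_collapsed = [collapse_runs(s, collapse_elements) for s in base_seqs]
    baseline_pairs = {
        pair for s in base_collapsed for pair in zip(s[:-1], s[1:])
    }
    # template-adjacent pairs are baseline structure even if a given baseline
    # sample happens not to exhibit them
    ref_motif = collapse_runs(list(template.motif), collapse_elements)
    baseline_pairs.update(zip(ref_motif[:-1], ref_motif[1:]))
    baseline_repertoire = (
        {t for s in base_seqs for t in s}
        | set(template.motif)
        | set(template.intro_labels)
    )

    rng = np.random.default_rng(seed)
    if len(post_seqs) < sampled_bouts:
        if len(post_seqs) != sampled_bouts:
            warnings.warn(
                f"only {len(post_seqs)} bouts available; using all", stacklevel=2
            )
        sample = post_seqs
    else:
        idx = rng.choice(len(post_seqs), size=sampled_bouts, replace=False)
        sample = [post_seqs[i] for i in sorted(idx)]

    per_bout = [
        classify_bout(
            template, seq, baseline_pairs, baseline_repertoire, collapse_elements
        )
        for seq in sample
    ]
    n = len(per_bout)
    return SyntaxChangeReport(
        template=template,
        n_bouts_sampled=n,
        per_bout=per_bout,
        new_transitions=sorted({t for b in per_bout for t in b.new_transitions}),
        omissions=sorted({(lab, pos) for b in per_bout for lab, _, pos, _ in b.omissions}),
        additions=sorted({(lab, pos) for b in per_bout for lab, _, pos, _ in b.additions}),
        pct_bouts_syntax_altered=100.0 * sum(b.syntax_altered for b in per_bout) / n,
        pct_bouts_with_omission=100.0 * sum(b.has_omission for b in per_bout) / n,
        pct_bouts_with_addition=100.0 * sum(b.has_addition for b in per_bout) / n,
    )
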