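"""Guide-pool analytics on amplicon reads.

The amplicon has fixed structure, so instead of a general-purpose aligner the
reads are anchored on the two constant flanks (allowing a configurable number
of mismatches per anchor) and all internal coordinates follow by offset
arithmetic.  Reads failing the anchoring, placed ambiguously, carrying an
indel (wrong inter-anchor length) or exceeding the outside-guide mismatch
budget are dropped with an explicit reason; the surviving guide regions feed
diversity, per-position base preference, mismatch-distribution and
enrichment-tracking summaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .io import ReadRecord
from .library import BASES, GuideLibrarySpec

__all__ = [
    "DropReason",
    "MatchResult",
    "GuidePoolProfile",
    "EmptyPoolError",
    "match_read",
    "qc_filter",
    "chance_mismatch_threshold",
    "profile_pool",
    "analyze_reads",
    "rank_guides",
    "track_enrichment",
    "plot_profile",
]


class DropReason(str, Enum):
    NONE = "none"
    UNANCHORED = "unanchored"
    MULTI_ANCHOR = "multi_anchor"
    INDEL = "indel"
    TOO_MANY_MISMATCHES = "too_many_mismatches"


class EmptyPoolError(ValueError):
    """Raised when a profile is requested for an empty guide list."""


@dataclass
class MatchResult:
    anchored: bool
    anchor_multiplicity: int
    has_indel: bool
    mismatches_outside_guide: int
    guide_sequence: str | None
    drop_reason: DropReason


def _hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N never matches."""
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def _find_anchor(seq: str, anchor: str, max_mismatches: int) -> list[tuple[int, int]]:
    """All placements of ``anchor`` in ``seq`` within the mismatch budget.

    Returns (start, n_mismatches) pairs.
    """
    L, A = len(seq), len(anchor)
    hits = []
    for start in range(L - A + 1):
        mm = _hamming(seq[start : start + A], anchor)
        if mm <= max_mismatches:
            hits.append((start, mm))
    return hits


def match_read(
    read: ReadRecord,
    spec: GuideLibrarySpec,
    max_anchor_mismatches: int = 1,
) -> MatchResult:
    """Anchor a read on the constant flanks and extract its guide region.

    More than one valid flank-pair placement maps to the multi-mapping drop;
    a wrong inter-anchor length flags an indel; otherwise the guide is read
    off by fixed offsets and mismatches against the reference are counted
    everywhere outside the guide window (flanks included).
    """
    seq = read.sequence
    hits5 = _find_anchor(seq, spec.flank_5, max_anchor_mismatches)
    hits3 = _find_anchor(seq, spec.flank_3, max_anchor_mismatches)
    pairs = [
        (s5, m5, s3, m3)
        for s5, m5 in hits5
        for s3, m3 in hits3
        if s3 >= s5 + len(spec.flank_5)
    ]
    if not pairs:
        return MatchResult(False, 0, False, 0, None, DropReason.UNANCHORED)
    if len(pairs) > 1:
        return MatchResult(True, len(pairs), False, 0, None, DropReason.MULTI_ANCHOR)
    s5, m5, s3, m3 = pairs[0]
    inner = seq[s5 + len(spec.flank_5) : s3]
    expected = spec.target_sequence + spec.loop_sequence
    expected_len = len(expected) + spec.guide_length
    if len(inner) != expected_len:
        return MatchResult(True, 1, True, 0, None, DropReason.INDEL)
    guide = inner[len(expected) :]
    outside = _hamming(inner[: len(expected)], expected) + m5 + m3
    if any(b == "N" for b in guide):
        # an N in the guide is uninterpretable for profiling; treat as indel-free
        # pass-through (N handling happens downstream in the profile)
        pass
    return MatchResult(True, 1, False, outside, guide, DropReason.NONE)


def qc_filter(
    match: MatchResult, max_outside_mismatches: int = 6
) -> tuple[bool, DropReason]:
    """Keep/drop decision: any anchoring failure, or > threshold mismatches
    outside the guide region (default 6, the chance bound at 0.1% error)."""
    if match.drop_reason is not DropReason.NONE:
        return False, match.drop_reason
    if match.mismatches_outside_guide > max_outside_mismatches:
        return False, DropReason.TOO_MANY_MISMATCHES
    return True, DropReason.NONE


def chance_mismatch_threshold(
    error_rate: float, n_sites: int, n_reads: int
) -> int:
    """Smallest m with expected reads exceeding m errors below one.

    I.e. min m such that n_reads * P[Binomial(n_sites, e) > m] < 1 -- the
    rationale behind the "more than six mismatches" filter.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    if n_sites < 0 or n_reads < 1:
        raise ValueError("n_sites must be >= 0 and n_reads >= 1")
    for m in range(n_sites + 1):
        if n_reads * stats.binom.sf(m, n_sites, error_rate) < 1.0:
            return m
    return n_sites


@dataclass
class GuidePoolProfile:
    """Per-round summary of a guide pool."""

    round_id: str
    n_input_reads: int
    n_passing_reads: int
    drop_tally: dict[str, int]
    base_frequency_matrix: pd.DataFrame  # rows A/C/G/T, columns by label
    mismatch_histogram: np.ndarray  # counts by mismatches vs perfect complement
    position0_tally: dict[str, int]  # C-vs-T (and stray A/G/N) at label 0
    distinct_fraction: float
    singleton_fraction: float
    ranked_guides: pd.DataFrame  # guide, count, frequency, rank
    guide_counts: Counter = field(repr=False, default_factory=Counter)


def rank_guides(guides: list[str] | Counter, top_k: int | None = None) -> pd.DataFrame:
    """Count-descending guide table; ties break lexicographically."""
    counts = guides if isinstance(guides, Counter) else Counter(guides)
    total = sum(counts.values())
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        items = items[:top_k]
    return pd.DataFrame(
        {
            "guide": [g for g, _ in items],
            "count": [c for _, c in items],
            "frequency": [c / total for _, c in items],
            "rank": np.arange(1, len(items) + 1),
        }
    )


def profile_pool(
    guides: list[str],
    spec: GuideLibrarySpec,
    round_id: str = "round",
    top_k: int = 10,
    drop_tally: dict[str, int] | None = None,
    n_input_reads: int | None = None,
) -> GuidePoolProfile:
    """Summarise a list of guide sequences.

    Mismatches are counted against the perfectly complementary guide with
    label 0 excluded (its designed C/T split is tallied separately); N bases
    count as mismatches and are excluded from base-frequency numerators.
    """
    if not guides:
        raise EmptyPoolError("cannot profile an empty guide list")
    L = spec.guide_length
    if any(len(g) != L for g in guides):
        raise ValueError("all guides must have the spec's guide length")
    labels = spec.coords.labels()
    perfect = spec.perfect_guide
    i0 = spec.coords.label_to_guide_index(0)

    arr = np.frombuffer("".join(guides).encode(), dtype=np.uint8).reshape(len(guides), L)
    ref = np.frombuffer(perfect.encode(), dtype=np.uint8)
    mismatch_mat = arr != ref[None, :]
    n_mat = arr == ord("N")
    mismatch_mat = mismatch_mat | n_mat
    mm_counts = mismatch_mat.sum(axis=1) - mismatch_mat[:, i0]
    hist = np.bincount(mm_counts, minlength=L)  # label 0 excluded -> max L-1

    # base-frequency matrix, N excluded and columns renormalized
    freq = pd.DataFrame(0.0, index=list(BASES), columns=labels)
    for label in labels:
        col = arr[:, spec.coords.label_to_guide_index(label)]
        tot = 0
        for b in BASES:
            n = int((col == ord(b)).sum())
            freq.loc[b, label] = n
            tot += n
        if tot > 0:
            freq[label] /= tot

    p0 = Counter(chr(c) for c in arr[:, i0])
    counts = Counter(guides)
    n = len(guides)
    distinct_fraction = len(counts) / n
    singleton_fraction = sum(1 for c in counts.values() if c == 1) / n

    return GuidePoolProfile(
        round_id=round_id,
        n_input_reads=n if n_input_reads is None else n_input_reads,
        n_passing_reads=n,
        drop_tally=dict(drop_tally or {}),
        base_frequency_matrix=freq,
        mismatch_histogram=hist,
        position0_tally=dict(p0),
        distinct_fraction=distinct_fraction,
        singleton_fraction=singleton_fraction,
        ranked_guides=rank_guides(counts, top_k=top_k),
        guide_counts=counts,
    )


def analyze_reads(
    reads,
    spec: GuideLibrarySpec,
    round_id: str = "round",
    max_anchor_mismatches: int = 1,
    max_outside_mismatches: int = 6,
    top_k: int = 10,
) -> GuidePoolProfile:
    """Full read-level pipeline: anchor, filter, extract guides, profile."""
    tally = Counter()
    guides = []
    n_input = 0
    for read in reads:
        n_input += 1
        m = match_read(read, spec, max_anchor_mismatches)
        keep, reason = qc_filter(m, max_outside_mismatches)
        if keep:
            guides.append(m.guide_sequence)
        else:
            tally[reason.value] += 1
    if not guides:
        raise EmptyPoolError(
            f"no reads passed filtering out of {n_input} (drops: {dict(tally)})"
        )
    return profile_pool(
        guides,
        spec,
        round_id=round_id,
        top_k=top_k,
        drop_tally=dict(tally),
        n_input_reads=n_input,
    )


def track_enrichment(
    profiles: list[GuidePoolProfile],
    sequences: list[str] | None = None,
    top_k: int = 10,
) -> pd.DataFrame:
    """Per-sequence frequency trajectory across rounds.

    Default tracked set: the final round's top-k guides.  Rows are sequences,
    columns round ids, entries frequencies (zero where absent).
    """
    if not profiles:
        raise ValueError("no profiles given")
    if sequences is None:
        sequences = list(profiles[-1].ranked_guides["guide"].head(top_k))
    data = {
        p.round_id: [
            p.guide_counts.get(s, 0) / p.n_passing_reads for s in sequences
        ]
        for p in profiles
    }
    return pd.DataFrame(data, index=sequences)


def plot_profile(profile: GuidePoolProfile, ax=None):
    """Stacked per-position base-frequency bars (a logo-style rendering)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    mat = profile.base_frequency_matrix
    bottom = np.zeros(mat.shape[1])
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    for base in BASES:
        vals = mat.loc[base].to_numpy()
        ax.bar(mat.columns, vals, bottom=bottom, label=base, color=colors[base])
        bottom += vals
    ax.set_xlabel("position (0 = opposite the edited A)")
    ax.set_ylabel("base frequency")
    ax.set_title(profile.round_id)
    ax.legend(ncol=4, fontsize=8)
    return ax
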