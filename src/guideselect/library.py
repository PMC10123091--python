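"""Hairpin construct geometry and the statistics of the doped guide library.

The selection substrate is a single molecule laid out 5'->3' as

    flank_5 | target | loop | guide | flank_3

where the *guide* region is the antisense of the *target* region, synthesised
with a 91:3:3:3 doping scheme (91% complementary base, 3% each alternative)
at every position except the one opposite the edited adenosine, which is an
equimolar C:T mix.  The edited A sits at the centre of the odd-length target.

Coordinates follow the sequence-logo convention: a guide base carries the
target-relative label of the base it pairs with, label 0 being the position
opposite the edited A and labels increasing 5'->3' along the *target*
(so they run high->low along the guide itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_DOWN, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BASES",
    "COMPLEMENT",
    "AVOGADRO",
    "complement",
    "reverse_complement",
    "CoordinateMap",
    "GuideLibrarySpec",
    "ReactionArithmetic",
    "demo_library_spec",
    "sequence_space_size",
    "format_scientific",
    "mismatch_count_distribution",
    "molecules_in_reaction",
    "expected_position_profile",
]

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
AVOGADRO = 6.02214076e23  # mol^-1 (exact SI value)


def complement(base: str) -> str:
    return COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class CoordinateMap:
    """Bijection between guide string indices and target-relative labels.

    For a guide of odd length ``L`` with centre ``c = (L - 1) // 2``:

    * guide index ``i`` (0-based, 5'->3' along the guide) pairs with the
      target base labelled ``c - i``;
    * label ``0`` is the guide base opposite the edited adenosine;
    * labels run ``-c .. +c`` and increase 5'->3' along the target.
    """

    def __init__(self, guide_length: int):
        if guide_length < 1 or guide_length % 2 == 0:
            raise ValueError("guide_length must be odd and positive")
        self.guide_length = guide_length
        self.center = (guide_length - 1) // 2

    def labels(self) -> list[int]:
        """Labels ordered as the logo axis (-c .. +c)."""
        return list(range(-self.center, self.center + 1))

    def guide_index_to_label(self, i: int) -> int:
        if not 0 <= i < self.guide_length:
            raise IndexError(f"guide index {i} out of range")
        return self.center - i

    def label_to_guide_index(self, label: int) -> int:
        if abs(label) > self.center:
            raise IndexError(f"label {label} out of range")
        return self.center - label

    def label_to_target_index(self, label: int) -> int:
        if abs(label) > self.center:
            raise IndexError(f"label {label} out of range")
        return self.center + label


def _validate_distribution(dist: dict[str, float], where: str) -> None:
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"base distribution at {where} sums to {total}, not 1")
    for b, p in dist.items():
        if b not in BASES:
            raise ValueError(f"unknown base {b!r} at {where}")
        if p < 0:
            raise ValueError(f"negative probability at {where}")


@dataclass
class GuideLibrarySpec:
    """Layout and per-position sampling design of the randomized guide pool.

    ``randomized_positions`` and ``special_positions`` are keyed by
    target-relative labels; together they must cover every guide coordinate,
    with label 0 always special (the C:T internal control).
    """

    target_sequence: str
    loop_sequence: str
    flank_5: str
    flank_3: str
    doping: float = 0.91  # weight of the complementary base at doped positions
    special_positions: dict[int, dict[str, float]] = field(
        default_factory=lambda: {0: {"C": 0.5, "T": 0.5}}
    )
    edited_site_offset: int = 0  # target-relative label of the edited A

    def __post_init__(self) -> None:
        L = len(self.target_sequence)
        if L < 1 or L % 2 == 0:
            raise ValueError("target_sequence must have odd length")
        for name in ("target_sequence", "loop_sequence", "flank_5", "flank_3"):
            seq = getattr(self, name)
            if any(b not in BASES for b in seq):
                raise ValueError(f"{name} must be DNA over ACGT")
        self.coords = CoordinateMap(L)
        if self.target_sequence[self.coords.center] != "A":
            raise ValueError("the central target base must be the edited A")
        if self.edited_site_offset != 0:
            raise ValueError("the edited A is at label 0 by convention")
        if 0 not in self.special_positions:
            raise ValueError("label 0 must carry an explicit base distribution")
        if not 0.25 <= self.doping <= 1.0:
            raise ValueError("doping weight must be in [0.25, 1]")
        for label, dist in self.special_positions.items():
            if abs(label) > self.coords.center:
                raise ValueError(f"special position {label} outside the guide")
            _validate_distribution(dist, f"label {label}")

    # -- derived geometry ---------------------------------------------------

    @property
    def guide_length(self) -> int:
        return len(self.target_sequence)

    @property
    def randomized_positions(self) -> list[int]:
        """Doped labels: every guide coordinate not listed as special."""
        return [l for l in self.coords.labels() if l not in self.special_positions]

    @property
    def perfect_guide(self) -> str:
        """The fully complementary guide (T opposite the edited A)."""
        return reverse_complement(self.target_sequence)

    @property
    def control_guide(self) -> str:
        """Perfect complement with the canonical A/C mismatch at label 0."""
        g = list(self.perfect_guide)
        g[self.coords.label_to_guide_index(0)] = "C"
        return "".join(g)

    @property
    def construct_length(self) -> int:
        return (
            len(self.flank_5)
            + len(self.target_sequence)
            + len(self.loop_sequence)
            + self.guide_length
            + len(self.flank_3)
        )

    def reference_construct(self, guide: str | None = None) -> str:
        """Full amplicon with the given guide (default: perfect complement)."""
        g = self.perfect_guide if guide is None else guide
        if len(g) != self.guide_length:
            raise ValueError("guide length does not match the spec")
        return self.flank_5 + self.target_sequence + self.loop_sequence + g + self.flank_3

    def guide_slice(self) -> slice:
        """Position of the guide region within the full construct."""
        start = len(self.flank_5) + len(self.target_sequence) + len(self.loop_sequence)
        return slice(start, start + self.guide_length)

    def position_distribution(self, label: int) -> dict[str, float]:
        """Design sampling distribution of the guide base at a label."""
        if label in self.special_positions:
            return dict(self.special_positions[label])
        comp = COMPLEMENT[self.target_sequence[self.coords.label_to_target_index(label)]]
        other = (1.0 - self.doping) / 3.0
        return {b: (self.doping if b == comp else other) for b in BASES}

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "target_sequence": self.target_sequence,
            "loop_sequence": self.loop_sequence,
            "flank_5": self.flank_5,
            "flank_3": self.flank_3,
            "doping": self.doping,
            "special_positions": {
                str(k): dict(v) for k, v in self.special_positions.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GuideLibrarySpec":
        special = {
            int(k): {b: float(p) for b, p in v.items()}
            for k, v in d.get("special_positions", {"0": {"C": 0.5, "T": 0.5}}).items()
        }
        return cls(
            target_sequence=d["target_sequence"],
            loop_sequence=d["loop_sequence"],
            flank_5=d["flank_5"],
            flank_3=d["flank_3"],
            doping=float(d.get("doping", 0.91)),
            special_positions=special,
        )


@dataclass
class ReactionArithmetic:
    """Substrate amount in the in vitro editing reaction (defaults: 2.25 nM in 50 ul)."""

    substrate_concentration: float = 2.25e-9  # molar
    reaction_volume: float = 50e-6  # liters

    def __post_init__(self) -> None:
        if self.substrate_concentration <= 0 or self.reaction_volume <= 0:
            raise ValueError("concentration and volume must be strictly positive")


# Synthetic stand-ins for the eGFP-W58X target context (the published
# construct sequences live in a supplement): a central TAG premature stop
# with the ADAR-preferred 5'-T / 3'-G neighbours, no other A in the target,
# a 25 nt connector loop and 20 nt primer flanks.
_DEMO_TARGET_CORE = "GCCGTCCTG" + "TAG" + "GGTGCTGCC"  # 21 nt, A at index 10
_DEMO_TARGET_EXT5 = "CTGGC"
_DEMO_TARGET_EXT3 = "TGCTG"
_DEMO_LOOP = "TTCGGTTCTCGGCTTCGGTTCTCGG"  # 25 nt
_DEMO_FLANK_5 = "AGCGTGTAGGTCGACCTGCA"  # 20 nt
_DEMO_FLANK_3 = "TGCCGGTCGTGCGGTTCGCG"  # 20 nt


def demo_library_spec(guide_length: int = 21) -> GuideLibrarySpec:
    """A ready-made synthetic library spec (21 or 31 nt guide).

    The sequences are synthetic stand-ins with the geometry of the real
    construct: edited A centred in a TAG codon, 25 nt loop, 20 nt flanks.
    """
    if guide_length == 21:
        target = _DEMO_TARGET_CORE
    elif guide_length == 31:
        target = _DEMO_TARGET_EXT5 + _DEMO_TARGET_CORE + _DEMO_TARGET_EXT3
    else:
        raise ValueError("demo spec supports guide_length 21 or 31")
    return GuideLibrarySpec(
        target_sequence=target,
        loop_sequence=_DEMO_LOOP,
        flank_5=_DEMO_FLANK_5,
        flank_3=_DEMO_FLANK_3,
    )


# -- design arithmetic ------------------------------------------------------


def sequence_space_size(n_random_positions: int, alphabet_size: int = 4) -> int:
    """Exact count of sequence variants over the randomized positions."""
    if n_random_positions < 0:
        raise ValueError("n_random_positions must be non-negative")
    if alphabet_size < 1:
        raise ValueError("alphabet_size must be positive")
    return alphabet_size**n_random_positions


def format_scientific(
    value: float | int, sig_figs: int = 3, mode: str = "truncate"
) -> str:
    """Render a positive number in scientific notation at ``sig_figs``.

    ``mode='truncate'`` drops trailing digits (how 6.775e10 was printed as
    6.7e10); ``mode='round'`` rounds half up (how 1.0995e12 became 1.10e12).
    Returns strings like ``'6.7e+10'``.
    """
    if value <= 0:
        raise ValueError("only positive values are supported")
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    if mode not in ("truncate", "round"):
        raise ValueError("mode must be 'truncate' or 'round'")
    d = Decimal(str(value)) if not isinstance(value, int) else Decimal(value)
    exponent = int(math.floor(Decimal(d).adjusted()))
    mantissa = d.scaleb(-exponent)
    quant = Decimal(1).scaleb(-(sig_figs - 1))
    rounding = ROUND_DOWN if mode == "truncate" else ROUND_HALF_UP
    mantissa = mantissa.quantize(quant, rounding=rounding)
    if mantissa >= 10:  # rounding overflow, e.g. 9.99 -> 10.0
        mantissa = (mantissa / 10).quantize(quant, rounding=rounding)
        exponent += 1
    return f"{mantissa}e{exponent:+d}"


@dataclass
class MismatchDistribution:
    """Binomial mismatch-count model of a doped library."""

    n_positions: int
    p_mismatch: float
    pmf: np.ndarray
    cdf: np.ndarray

    def prob_at_most(self, k: int) -> float:
        return float(self.cdf[min(k, self.n_positions)]) if k >= 0 else 0.0


def mismatch_count_distribution(
    n_positions: int, p_mismatch: float
) -> MismatchDistribution:
    """Distribution of per-molecule mismatch counts under doped synthesis.

    For the 91:3:3:3 scheme ``p_mismatch = 0.09``; ``n_positions`` excludes
    the fixed C/T position opposite the edited A.
    """
    if not 0.0 <= p_mismatch <= 1.0:
        raise ValueError("p_mismatch must be in [0, 1]")
    if n_positions < 0:
        raise ValueError("n_positions must be non-negative")
    k = np.arange(n_positions + 1)
    pmf = stats.binom.pmf(k, n_positions, p_mismatch)
    cdf = stats.binom.cdf(k, n_positions, p_mismatch)
    return MismatchDistribution(n_positions, p_mismatch, pmf, cdf)


def molecules_in_reaction(arith: ReactionArithmetic | None = None) -> float:
    """Total substrate molecules: concentration x volume x Avogadro."""
    arith = arith or ReactionArithmetic()
    return arith.substrate_concentration * arith.reaction_volume * AVOGADRO


def expected_position_profile(spec: GuideLibrarySpec) -> pd.DataFrame:
    """Design base-sampling matrix (rows A/C/G/T, columns by label).

    Columns are ordered along the logo axis (-c .. +c) and each sums to 1.
    """
    labels = spec.coords.labels()
    mat = pd.DataFrame(0.0, index=list(BASES), columns=labels)
    for label in labels:
        for b, p in spec.position_distribution(label).items():
            mat.loc[b, label] = p
    return mat
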