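"""In-silico model of the selection assay and generators for every pipeline input.

The campaign loop mirrors the bench workflow: a doped guide pool is edited by
ADAR at a chosen enzyme level, allele-specific (ARMS) PCR keeps the edited
molecules, and the surviving guides are resampled back up to the working pool
size to seed the next round.  Editing probability per molecule comes from a
pluggable :class:`EditingModel`; the default fitness surface is an invented
per-position factor table (the assay paper does not specify one) chosen so
that a C opposite the edited A is required and one distal mismatch is
advantageous -- enough structure to reproduce the qualitative selection
signatures (position-0 C sweep, decline of the perfectly complementary
control guide).

Also here: FASTQ read simulation with substitution errors and UMIs, and
closed-form kinetic / dose-response series generators.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io import ReadRecord
from .library import BASES, COMPLEMENT, GuideLibrarySpec

__all__ = [
    "SimulatedPool",
    "EditingModel",
    "default_editing_model",
    "SelectionConfig",
    "ReadSimConfig",
    "SelectionExtinctionError",
    "RoundResult",
    "CampaignResult",
    "sample_initial_pool",
    "run_selection_round",
    "run_campaign",
    "pool_to_reads",
    "simulate_editing_amplicon",
    "simulate_site_counts",
    "KineticSeries",
    "DoseSeries",
    "simulate_kinetics",
    "simulate_dose_response",
    "PAPER_TIME_GRID",
]

_CODE = {b: i for i, b in enumerate(BASES)}

#: Sampling grid of the single-turnover kinetics experiments (minutes).
PAPER_TIME_GRID = np.array([0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 120.0])


def _encode(guides: list[str]) -> np.ndarray:
    """(n, L) uint8 matrix of base codes (A=0, C=1, G=2, T=3)."""
    if not guides:
        return np.zeros((0, 0), dtype=np.uint8)
    arr = np.frombuffer("".join(guides).encode(), dtype=np.uint8)
    arr = arr.reshape(len(guides), len(guides[0]))
    out = np.zeros_like(arr)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


def _decode(codes: np.ndarray) -> list[str]:
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return [bytes(row).decode() for row in lut[codes]]


class SelectionExtinctionError(RuntimeError):
    """Raised when a selection step leaves no surviving molecules."""


@dataclass
class SimulatedPool:
    """Multiset of guide sequences with molecule counts."""

    counts: Counter
    round_index: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("molecule counts must be positive")

    @property
    def total_molecules(self) -> int:
        return sum(self.counts.values())

    def frequency(self, guide: str) -> float:
        total = self.total_molecules
        return self.counts.get(guide, 0) / total if total else 0.0

    def guides(self) -> list[str]:
        return list(self.counts)

    def expand(self) -> list[str]:
        """One entry per molecule (order deterministic by insertion)."""
        return [g for g, c in self.counts.items() for _ in range(c)]


class EditingModel:
    """Maps (guide, enzyme level) to a per-molecule editing probability.

    ``p = clamp(p_max * s(g) * E / (E + k_half), 0, 1)`` where ``s(g)`` in
    [0, 1] is a guide score.  Scores come from a per-position multiplicative
    factor table (4 x guide_length, guide-index order), or a user-supplied
    lookup of guide -> score.
    """

    def __init__(
        self,
        factor_matrix: np.ndarray | None = None,
        score_lookup: dict[str, float] | None = None,
        p_max: float = 0.9,
        k_half: float = 1.0,
    ):
        if (factor_matrix is None) == (score_lookup is None):
            raise ValueError("provide exactly one of factor_matrix / score_lookup")
        if factor_matrix is not None:
            factor_matrix = np.asarray(factor_matrix, dtype=float)
            if factor_matrix.shape[0] != 4:
                raise ValueError("factor_matrix must be 4 x guide_length")
            if (factor_matrix < 0).any() or (factor_matrix > 1).any():
                raise ValueError("factors must lie in [0, 1]")
        self.factor_matrix = factor_matrix
        self.score_lookup = score_lookup
        self.p_max = float(p_max)
        self.k_half = float(k_half)

    def scores(self, guides: list[str]) -> np.ndarray:
        if self.factor_matrix is not None:
            codes = _encode(guides)
            cols = np.arange(codes.shape[1])
            per_pos = self.factor_matrix[codes, cols[None, :]]
            return per_pos.prod(axis=1)
        return np.array([self.score_lookup.get(g, 0.0) for g in guides])

    def probabilities(self, guides: list[str], enzyme_level: float) -> np.ndarray:
        if enzyme_level < 0:
            raise ValueError("enzyme_level must be non-negative")
        if enzyme_level == 0.0:
            sat = 0.0
        else:
            sat = enzyme_level / (enzyme_level + self.k_half)
        return np.clip(self.p_max * self.scores(guides) * sat, 0.0, 1.0)

    def probability(self, guide: str, enzyme_level: float) -> float:
        return float(self.probabilities([guide], enzyme_level)[0])


def default_editing_model(
    spec: GuideLibrarySpec,
    core_labels: tuple[int, ...] = (-1, 1, 2, 3),
    core_penalty: float = 0.1,
    outer_penalty: float = 0.95,
    preferred_label: int = 10,
    preferred_base: str = "T",
    preferred_complement_factor: float = 0.3,
    t_at_zero: float = 0.02,
    p_max: float = 0.9,
    k_half: float = 1.0,
) -> EditingModel:
    """The invented default fitness surface, as a per-position factor table.

    * label 0: C scores 1.0, T scores ``t_at_zero``, A/G score 0 (editing
      requires the canonical A/C mismatch; the T half of the synthesis mix
      is strongly counter-selected);
    * core labels near the editing site: any mismatch multiplies by
      ``core_penalty`` (duplex formation next to the target A is required);
    * one distal ``preferred_label`` (clipped into range): the preferred
      mismatch base scores 1.0 while the complementary base scores
      ``preferred_complement_factor`` -- this is what displaces the
      perfectly complementary control during selection;
    * everywhere else: mismatches carry the mild ``outer_penalty``.
    """
    L = spec.guide_length
    c = spec.coords.center
    pref = max(-c, min(c, preferred_label))
    mat = np.ones((4, L))
    for label in spec.coords.labels():
        i = spec.coords.label_to_guide_index(label)
        comp = COMPLEMENT[spec.target_sequence[spec.coords.label_to_target_index(label)]]
        if label == 0:
            for b in BASES:
                mat[_CODE[b], i] = {"C": 1.0, "T": t_at_zero}.get(b, 0.0)
        elif label == pref:
            for b in BASES:
                if b == preferred_base:
                    mat[_CODE[b], i] = 1.0
                else:
                    mat[_CODE[b], i] = preferred_complement_factor
        elif label in core_labels:
            for b in BASES:
                mat[_CODE[b], i] = 1.0 if b == comp else core_penalty
        else:
            for b in BASES:
                mat[_CODE[b], i] = 1.0 if b == comp else outer_penalty
    return EditingModel(factor_matrix=mat, p_max=p_max, k_half=k_half)


@dataclass
class SelectionConfig:
    """Parameters of one selection campaign."""

    spec: GuideLibrarySpec
    n_rounds: int = 9
    pool_size: int = 100_000
    enzyme_levels: tuple[float, ...] = (0.03125, 0.125, 0.5, 2.0, 8.0, 40.0)
    selection_enzyme_level: float = 0.5  # the stringent level used for ARMS selection
    arms_leak: float = 0.0  # probability an unedited molecule survives selection
    pcr_substitution_rate: float = 0.0  # per base, per regeneration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if not 0.0 <= self.arms_leak <= 1.0:
            raise ValueError("arms_leak must be in [0, 1]")
        if not 0.0 <= self.pcr_substitution_rate < 1.0:
            raise ValueError("pcr_substitution_rate must be in [0, 1)")


@dataclass
class ReadSimConfig:
    """Read-level simulation knobs."""

    substitution_rate: float = 0.001
    indel_rate: float = 0.0  # per read, for exercising the indel filter
    umi_length: int = 6
    reads_per_molecule: int = 1
    phred_quality: int = 30
    umi_collision_free: bool = False  # idealized tagging: sample UMIs w/o replacement
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be in [0, 1]")
        if self.umi_length < 0 or self.reads_per_molecule < 1:
            raise ValueError("invalid umi_length or reads_per_molecule")


# -- pool generation and the selection operator -----------------------------


def sample_initial_pool(
    spec: GuideLibrarySpec,
    n_molecules: int,
    seed: int | np.random.Generator = 0,
    bias: dict[int, dict[str, float]] | None = None,
) -> SimulatedPool:
    """Draw an i.i.d. pool from the per-position design distributions.

    ``bias`` optionally overrides the distribution at given labels, to mimic
    synthesis skew away from the nominal 91:3:3:3.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    L = spec.guide_length
    codes = np.empty((n_molecules, L), dtype=np.uint8)
    for label in spec.coords.labels():
        dist = spec.position_distribution(label)
        if bias and label in bias:
            dist = bias[label]
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"bias distribution at {label} sums to {total}")
        p = np.array([dist.get(b, 0.0) for b in BASES])
        i = spec.coords.label_to_guide_index(label)
        codes[:, i] = rng.choice(4, size=n_molecules, p=p)
    return SimulatedPool(Counter(_decode(codes)), round_index=0)


@dataclass
class RoundResult:
    edited_fraction: float
    selected: SimulatedPool
    regenerated: SimulatedPool


def _apply_pcr_errors(
    counts: Counter, rate: float, rng: np.random.Generator
) -> Counter:
    """Per-base substitution during regeneration (skipped when rate is 0)."""
    if rate == 0.0:
        return counts
    guides = list(counts)
    out: Counter = Counter()
    for g in guides:
        n = counts[g]
        L = len(g)
        p_any = 1.0 - (1.0 - rate) ** L
        n_mut = rng.binomial(n, p_any)
        out[g] += n - n_mut
        for _ in range(n_mut):
            pos = rng.integers(L)
            alt = [b for b in BASES if b != g[pos]]
            mutated = g[:pos] + alt[rng.integers(3)] + g[pos + 1 :]
            out[mutated] += 1
    out = Counter({g: c for g, c in out.items() if c > 0})
    return out


def run_selection_round(
    pool: SimulatedPool,
    model: EditingModel,
    enzyme_level: float,
    config: SelectionConfig,
    rng: np.random.Generator | None = None,
) -> RoundResult:
    """One edit -> select -> regenerate cycle.

    Each molecule is edited with probability ``model(guide, enzyme_level)``;
    selection keeps edited molecules plus unedited ones with probability
    ``arms_leak``; regeneration multinomially resamples the survivors back
    to ``config.pool_size`` (PCR amplification), applying
    ``pcr_substitution_rate`` per base.
    """
    if pool.total_molecules == 0:
        raise ValueError("input pool is empty")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    guides = pool.guides()
    counts = np.array([pool.counts[g] for g in guides])
    probs = model.probabilities(guides, enzyme_level)
    edited = rng.binomial(counts, probs)
    edited_fraction = float(edited.sum() / counts.sum())
    survivors = edited.copy()
    if config.arms_leak > 0.0:
        survivors = survivors + rng.binomial(counts - edited, config.arms_leak)
    if survivors.sum() == 0:
        raise SelectionExtinctionError(
            f"no molecules survived selection at enzyme level {enzyme_level}"
        )
    selected = SimulatedPool(
        Counter({g: int(c) for g, c in zip(guides, survivors) if c > 0}),
        round_index=pool.round_index,
    )
    # PCR regeneration: multinomial resampling with replacement to pool_size
    weights = survivors / survivors.sum()
    resampled = rng.multinomial(config.pool_size, weights)
    regen_counts = Counter({g: int(c) for g, c in zip(guides, resampled) if c > 0})
    regen_counts = _apply_pcr_errors(regen_counts, config.pcr_substitution_rate, rng)
    regenerated = SimulatedPool(regen_counts, round_index=pool.round_index + 1)
    return RoundResult(edited_fraction, selected, regenerated)


@dataclass
class RoundRecord:
    round_index: int
    pool: SimulatedPool  # regenerated pool entering the next round
    selection_edited_fraction: float
    readout_edited_fraction: dict[float, float] = field(default_factory=dict)


@dataclass
class CampaignResult:
    config: SelectionConfig
    initial_pool: SimulatedPool
    rounds: list[RoundRecord]

    def pools(self) -> list[SimulatedPool]:
        """Round 0 input followed by the pool after each round."""
        return [self.initial_pool] + [r.pool for r in self.rounds]


def _expected_edited_fraction(
    pool: SimulatedPool, model: EditingModel, enzyme_level: float
) -> float:
    """Pool-weighted mean editing probability (the non-selective PCR readout)."""
    guides = pool.guides()
    counts = np.array([pool.counts[g] for g in guides], dtype=float)
    probs = model.probabilities(guides, enzyme_level)
    return float((counts * probs).sum() / counts.sum())


def run_campaign(
    config: SelectionConfig,
    model: EditingModel,
    initial_pool: SimulatedPool | None = None,
) -> CampaignResult:
    """Iterate selection rounds, recording per-round pools and editing readouts.

    The per-round readout reports the expected pool-level editing at every
    configured enzyme level (the serial-dilution monitoring of the assay);
    the stochastic selection step runs at ``selection_enzyme_level``.
    """
    rng = np.random.default_rng(config.seed)
    pool = initial_pool or sample_initial_pool(
        config.spec, config.pool_size, seed=rng
    )
    rounds: list[RoundRecord] = []
    current = pool
    for _ in range(config.n_rounds):
        readout = {
            lvl: _expected_edited_fraction(current, model, lvl)
            for lvl in config.enzyme_levels
        }
        res = run_selection_round(
            current, model, config.selection_enzyme_level, config, rng
        )
        rounds.append(
            RoundRecord(
                round_index=res.regenerated.round_index,
                pool=res.regenerated,
                selection_edited_fraction=res.edited_fraction,
                readout_edited_fraction=readout,
            )
        )
        current = res.regenerated
    return CampaignResult(config, pool, rounds)


# -- read simulation --------------------------------------------------------


def _inject_substitutions(
    seqs: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. substitution errors on an (n, L) code matrix."""
    if rate == 0.0:
        return seqs
    mask = rng.random(seqs.shape) < rate
    shifts = rng.integers(1, 4, size=mask.sum()).astype(np.uint8)
    out = seqs.copy()
    out[mask] = (out[mask] + shifts) % 4
    return out


def pool_to_reads(
    pool: SimulatedPool,
    spec: GuideLibrarySpec,
    readsim: ReadSimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[ReadRecord]:
    """Emit one full-construct amplicon read per pool molecule.

    Reads are flank_5 + target + loop + guide + flank_3 with i.i.d.
    substitution errors; ``indel_rate`` optionally deletes or duplicates one
    base per read so the indel filter can be exercised.
    """
    readsim = readsim or ReadSimConfig()
    rng = np.random.default_rng(readsim.seed) if rng is None else rng
    constructs = [spec.reference_construct(g) for g in pool.expand()]
    codes = _encode(constructs)
    codes = _inject_substitutions(codes, readsim.substitution_rate, rng)
    seqs = _decode(codes)
    qual = chr(33 + readsim.phred_quality)
    reads = []
    for i, s in enumerate(seqs):
        if readsim.indel_rate > 0.0 and rng.random() < readsim.indel_rate:
            pos = int(rng.integers(len(s)))
            if rng.random() < 0.5:
                s = s[:pos] + s[pos + 1 :]  # deletion
            else:
                s = s[:pos] + s[pos] + s[pos:]  # single-base duplication
        reads.append(
            ReadRecord(f"sim_r{pool.round_index}_{i}", s, qual * len(s))
        )
    return reads


def _sample_umis(
    n: int, length: int, collision_free: bool, rng: np.random.Generator
) -> list[str]:
    if length == 0:
        return [""] * n
    space = 4**length
    if collision_free:
        if n > space:
            raise ValueError("more molecules than distinct UMIs")
        idx = rng.choice(space, size=n, replace=False)
    else:
        idx = rng.integers(space, size=n)
    umis = []
    for v in idx:
        v = int(v)
        umis.append("".join(BASES[(v >> (2 * k)) & 3] for k in range(length)))
    return umis


def simulate_editing_amplicon(
    reference: str,
    true_editing: float,
    n_molecules: int,
    readsim: ReadSimConfig | None = None,
    target_site: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadRecord], int]:
    """UMI-tagged amplicon reads from a partially edited molecule population.

    Each molecule is independently edited (A->G at ``target_site``, default
    the central position) with probability ``true_editing``, tagged with a
    random UMI, and sequenced ``reads_per_molecule`` times under the
    substitution error model.  Returns the reads and the true number of
    edited molecules.
    """
    if not 0.0 <= true_editing <= 1.0:
        raise ValueError("true_editing must be in [0, 1]")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    readsim = readsim or ReadSimConfig()
    rng = np.random.default_rng(readsim.seed) if rng is None else rng
    site = len(reference) // 2 if target_site is None else target_site
    if reference[site] != "A":
        raise ValueError(f"reference base at target site {site} is not A")
    edited_flags = rng.random(n_molecules) < true_editing
    n_edited = int(edited_flags.sum())
    umis = _sample_umis(n_molecules, readsim.umi_length, readsim.umi_collision_free, rng)
    edited_seq = reference[:site] + "G" + reference[site + 1 :]
    molecules = [edited_seq if e else reference for e in edited_flags]
    payloads = np.repeat(
        _encode(molecules), readsim.reads_per_molecule, axis=0
    )
    payloads = _inject_substitutions(payloads, readsim.substitution_rate, rng)
    seqs = _decode(payloads)
    qual = chr(33 + readsim.phred_quality)
    reads = []
    k = 0
    for m, umi in enumerate(umis):
        for _ in range(readsim.reads_per_molecule):
            s = umi + seqs[k]
            reads.append(ReadRecord(f"umi_read_{k}", s, qual * len(s)))
            k += 1
    return reads, n_edited


def simulate_site_counts(
    reference: str,
    true_editing: float,
    coverage: int,
    error_rate: float,
    target_site: int | None = None,
    rng: int | np.random.Generator = 0,
):
    """Per-position base counts over deduplicated molecules, skipping reads.

    Fast counts-level equivalent of simulate + quantify for calibration
    studies: every position draws ``coverage`` bases from (1 - e) reference
    plus e/3 per alternative; the target site additionally carries
    ``true_editing`` A->G conversion before errors.
    """
    from .editing import SiteBaseCounts  # local import to avoid a cycle

    rng = np.random.default_rng(rng)
    site = len(reference) // 2 if target_site is None else target_site
    if reference[site] != "A":
        raise ValueError("reference base at target site is not A")
    counts = np.zeros((len(reference), 5), dtype=int)  # A C G T N
    for pos, ref_base in enumerate(reference):
        if pos == site:
            n_ed = rng.binomial(coverage, true_editing)
            for true_base, n in (("G", n_ed), ("A", coverage - n_ed)):
                counts[pos] += _error_multinomial(true_base, n, error_rate, rng)
        else:
            counts[pos] += _error_multinomial(ref_base, coverage, error_rate, rng)
    return SiteBaseCounts(
        reference=reference, counts=counts, target_site=site
    )


def _error_multinomial(
    true_base: str, n: int, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    p = np.full(5, 0.0)
    for b in BASES:
        p[_CODE[b]] = error_rate / 3.0
    p[_CODE[true_base]] = 1.0 - error_rate
    return rng.multinomial(n, p)


# -- kinetics and dose-response series --------------------------------------


@dataclass
class KineticSeries:
    """Editing time course: times (strictly increasing) x replicate values."""

    times: np.ndarray
    values: np.ndarray  # shape (n_reps, n_times), fractions in [0, 1]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if (self.times < 0).any() or (np.diff(self.times) <= 0).any():
            raise ValueError("times must be non-negative and strictly increasing")
        if self.values.shape[1] != self.times.size:
            raise ValueError("values shape does not match times")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("editing fractions must lie in [0, 1]")

    @property
    def n_reps(self) -> int:
        return self.values.shape[0]


@dataclass
class DoseSeries:
    """Dose-response measurements: doses (nM, increasing) x replicate values."""

    doses: np.ndarray
    values: np.ndarray  # shape (n_reps, n_doses)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if (self.doses <= 0).any() or (np.diff(self.doses) <= 0).any():
            raise ValueError("doses must be positive and strictly increasing")
        if self.values.shape[1] != self.doses.size:
            raise ValueError("values shape does not match doses")

    @property
    def n_reps(self) -> int:
        return self.values.shape[0]


def one_phase_association(t: np.ndarray, emax: float, k: float) -> np.ndarray:
    """E(t) = Emax (1 - exp(-k t))."""
    return emax * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


def four_pl(dose: np.ndarray, bottom: float, top: float, hill: float, ec50: float) -> np.ndarray:
    """Four-parameter logistic response."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / dose) ** hill)


def simulate_kinetics(
    emax: float,
    k: float,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    n_reps: int = 1,
    seed: int = 0,
) -> KineticSeries:
    """One-phase association time course plus Gaussian noise, clamped to [0, 1]."""
    times = PAPER_TIME_GRID if times is None else np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    clean = one_phase_association(times, emax, k)
    values = clean[None, :] + rng.normal(0.0, noise_sd, size=(n_reps, times.size))
    return KineticSeries(times, np.clip(values, 0.0, 1.0))


def simulate_dose_response(
    bottom: float,
    top: float,
    hill: float,
    ec50: float,
    doses: np.ndarray | None = None,
    noise_sd: float = 0.0,
    n_reps: int = 1,
    seed: int = 0,
) -> DoseSeries:
    """4PL dose-response series plus Gaussian noise.

    Default dose grid spans 0.07 - 300 nM (3-fold steps), the assay's range.
    """
    if doses is None:
        doses = 0.07 * 3.0 ** np.arange(8)  # 0.07 .. ~153, capped at 300
        doses = np.append(doses, 300.0)
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    clean = four_pl(doses, bottom, top, hill, ec50)
    values = clean[None, :] + rng.normal(0.0, noise_sd, size=(n_reps, doses.size))
    return DoseSeries(doses, values)
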