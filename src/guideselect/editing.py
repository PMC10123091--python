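"""A-to-I editing quantification from UMI-tagged amplicon reads.

Reads are collapsed to molecules by directional UMI clustering (a less
abundant tag merges into a neighbour within a Hamming threshold when the
neighbour's count is at least ``2n - 1``), each cluster votes a per-position
consensus (ties become N), and editing at the target adenosine is the
deduplicated G/(G + A) ratio.  Significance comes from an empirical p-value:
the per-position error frequencies across the rest of the amplicon form a
background distribution, a Gaussian KDE is fitted to it, and the p-value is
the KDE's upper-tail mass at the observed editing fraction (renormalized to
[0, 1], floored at 1/(n_background + 1)).  A rank-based alternative is
provided since the KDE construction involves choices (kernel, bandwidth,
support handling) that other implementations may make differently.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import ReadRecord
from .library import BASES

__all__ = [
    "UMIRead",
    "SiteBaseCounts",
    "EditingCall",
    "InsufficientBackgroundError",
    "ZeroCoverageError",
    "extract_umi",
    "dedup_umis",
    "count_bases",
    "editing_fraction",
    "empirical_pvalue",
    "normalize_to_max",
    "quantify_editing",
]

_COL = {b: i for i, b in enumerate(BASES + "N")}


class ZeroCoverageError(ValueError):
    """No A or G coverage at the target site."""


class InsufficientBackgroundError(ValueError):
    """Too few covered non-target positions to build an error background."""


@dataclass
class UMIRead:
    umi: str
    payload: str
    read_id: str


def extract_umi(read: ReadRecord, umi_length: int = 6) -> UMIRead | None:
    """Split the leading ``umi_length`` bases off as the molecular tag.

    Returns None (drop) when the read is shorter than the tag.
    """
    if umi_length < 0:
        raise ValueError("umi_length must be non-negative")
    if len(read.sequence) < umi_length:
        return None
    return UMIRead(read.sequence[:umi_length], read.sequence[umi_length:], read.id)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _consensus(payloads: list[str]) -> str:
    """Per-position majority vote; ties vote N."""
    if len(payloads) == 1:
        return payloads[0]
    arr = np.frombuffer("".join(payloads).encode(), dtype=np.uint8).reshape(
        len(payloads), len(payloads[0])
    )
    out = []
    for col in arr.T:
        cnt = Counter(col)
        best = cnt.most_common()
        if len(best) > 1 and best[0][1] == best[1][1]:
            out.append("N")
        else:
            out.append(chr(best[0][0]))
    return "".join(out)


def dedup_umis(
    reads: list[UMIRead], hamming_threshold: int = 1
) -> list[str]:
    """Collapse reads to one consensus payload per inferred molecule.

    Directional clustering: UMIs are visited in decreasing count order; a
    tag ``u`` merges into an already-kept, more abundant tag ``v`` when
    ``Hamming(u, v) <= hamming_threshold`` and ``count(v) >= 2*count(u) - 1``.
    Threshold 0 degenerates to exact-UMI grouping.  Payloads must share one
    length (fixed-structure amplicon); odd-length payloads are dropped.
    """
    if not reads:
        return []
    by_len = Counter(len(r.payload) for r in reads)
    plen = by_len.most_common(1)[0][0]
    groups: dict[str, list[str]] = defaultdict(list)
    for r in reads:
        if len(r.payload) == plen:
            groups[r.umi].append(r.payload)
    if not groups:
        return []
    # decreasing count, lexicographic tie-break for determinism
    order = sorted(groups, key=lambda u: (-len(groups[u]), u))
    cluster_of: dict[str, str] = {}
    kept: list[str] = []
    for u in order:
        n_u = len(groups[u])
        merged = False
        if hamming_threshold > 0:
            for v in kept:
                if (
                    len(groups[v]) >= 2 * n_u - 1
                    and _hamming(u, v) <= hamming_threshold
                ):
                    cluster_of[u] = cluster_of[v]
                    merged = True
                    break
        if not merged:
            cluster_of[u] = u
            kept.append(u)
    clusters: dict[str, list[str]] = defaultdict(list)
    for u, root in cluster_of.items():
        clusters[root].extend(groups[u])
    return [_consensus(clusters[root]) for root in sorted(clusters)]


@dataclass
class SiteBaseCounts:
    """Per-position A/C/G/T/N tallies over consensus molecules."""

    reference: str
    counts: np.ndarray  # shape (len(reference), 5), columns A C G T N
    target_site: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.reference), 5):
            raise ValueError("counts must be (reference length, 5)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not 0 <= self.target_site < len(self.reference):
            raise ValueError("target_site outside the reference")

    def base_count(self, position: int, base: str) -> int:
        return int(self.counts[position, _COL[base]])


def count_bases(
    payloads: list[str], reference: str, target_site: int | None = None
) -> SiteBaseCounts:
    """Tally consensus bases per reference position."""
    site = len(reference) // 2 if target_site is None else target_site
    counts = np.zeros((len(reference), 5), dtype=int)
    for p in payloads:
        if len(p) != len(reference):
            raise ValueError("payload length does not match the reference")
        for pos, b in enumerate(p):
            counts[pos, _COL.get(b, _COL["N"])] += 1
    return SiteBaseCounts(reference=reference, counts=counts, target_site=site)


def editing_fraction(counts: SiteBaseCounts) -> float:
    """G/(G + A) at the target site; C, T and N are excluded from the ratio."""
    a = counts.base_count(counts.target_site, "A")
    g = counts.base_count(counts.target_site, "G")
    if a + g == 0:
        raise ZeroCoverageError("no A or G coverage at the target site")
    return g / (a + g)


def _background_error_frequencies(
    counts: SiteBaseCounts, a_sites_only: bool = False
) -> np.ndarray:
    """Per-position non-reference frequency at covered non-target positions.

    With ``a_sites_only`` the background is restricted to reference-A
    positions and to the A->G error channel, mirroring the editing statistic.
    """
    freqs = []
    for pos, ref_base in enumerate(counts.reference):
        if pos == counts.target_site:
            continue
        row = counts.counts[pos, :4]
        total = int(row.sum())
        if total == 0:
            continue
        if ref_base not in "ACGT":
            continue
        if a_sites_only:
            if ref_base != "A":
                continue
            a, g = row[_COL["A"]], row[_COL["G"]]
            if a + g == 0:
                continue
            freqs.append(g / (a + g))
        else:
            freqs.append((total - row[_COL[ref_base]]) / total)
    return np.asarray(freqs, dtype=float)


def empirical_pvalue(
    counts: SiteBaseCounts,
    min_background: int = 20,
    method: str = "kde",
    a_sites_only: bool = False,
) -> tuple[float, dict]:
    """Empirical p-value of the observed editing against amplicon errors.

    ``method='kde'``: Gaussian KDE (Scott bandwidth) over the background
    error frequencies; p is the KDE mass above the observed editing fraction
    renormalized over [0, 1].  ``method='rank'``: (1 + #background >= obs) /
    (n + 1).  Both are floored at 1/(n_background + 1).  Returns
    (p, background summary).
    """
    if method not in ("kde", "rank"):
        raise ValueError("method must be 'kde' or 'rank'")
    obs = editing_fraction(counts)
    bg = _background_error_frequencies(counts, a_sites_only=a_sites_only)
    n = bg.size
    if n < min_background:
        raise InsufficientBackgroundError(
            f"only {n} covered background positions (need >= {min_background})"
        )
    floor = 1.0 / (n + 1)
    info = {
        "n_background": int(n),
        "background_mean": float(bg.mean()),
        "background_max": float(bg.max()),
        "observed": float(obs),
        "method": method,
    }
    if method == "rank" or np.ptp(bg) == 0.0:
        # degenerate background (e.g. error-free data) falls back to ranking
        p = (1 + int((bg >= obs).sum())) / (n + 1)
        info["method"] = "rank"
    else:
        kde = stats.gaussian_kde(bg)  # Scott's rule by default
        upper = float(kde.integrate_box_1d(obs, 1.0))
        support = float(kde.integrate_box_1d(0.0, 1.0))
        p = upper / support if support > 0 else 0.0
    p = min(1.0, max(p, floor))
    info["p_value"] = float(p)
    return float(p), info


@dataclass
class EditingCall:
    """Editing level at the target site with its empirical significance."""

    editing_fraction: float
    coverage: int  # G + A consensus molecules at the target site
    empirical_p: float
    n_molecules: int
    background: dict = field(default_factory=dict)


def quantify_editing(
    reads,
    reference: str,
    target_site: int | None = None,
    umi_length: int = 6,
    hamming_threshold: int = 1,
    min_background: int = 20,
    method: str = "kde",
    a_sites_only: bool = False,
) -> EditingCall:
    """End-to-end quantification: extract UMIs, dedup, count, call editing."""
    umi_reads = []
    for r in reads:
        u = extract_umi(r, umi_length)
        if u is not None and len(u.payload) == len(reference):
            umi_reads.append(u)
    if not umi_reads:
        raise ZeroCoverageError("no usable reads after UMI extraction")
    payloads = dedup_umis(umi_reads, hamming_threshold=hamming_threshold)
    counts = count_bases(payloads, reference, target_site=target_site)
    frac = editing_fraction(counts)
    p, info = empirical_pvalue(
        counts, min_background=min_background, method=method, a_sites_only=a_sites_only
    )
    site = counts.target_site
    cov = counts.base_count(site, "A") + counts.base_count(site, "G")
    return EditingCall(
        editing_fraction=frac,
        coverage=cov,
        empirical_p=p,
        n_molecules=len(payloads),
        background=info,
    )


def normalize_to_max(series) -> tuple[np.ndarray, bool]:
    """Divide by the series maximum (the round-comparison normalization).

    Returns (normalized, flagged); an all-zero series comes back unchanged
    with the flag set.
    """
    arr = np.asarray(series, dtype=float)
    m = arr.max() if arr.size else 0.0
    if m == 0.0:
        return arr.copy(), True
    return arr / m, False
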