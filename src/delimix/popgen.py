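"""Per-locus summary statistics computed before any inference.

Covers the usual pre-flight table for a multilocus alignment panel:
alignment length, variable-site count, haplotype count, the Hudson–Kaplan
lower bound on recombination events (four-gamete test), and Fu & Li's F*
neutrality statistic with significance assessed against a coalescent-
simulated null rather than interpolated critical-value tables.

Missing data policy: gap ('-') and ambiguous ('N') characters are treated
as missing, excluded per pairwise comparison for distances, and never
counted as a distinct allele for variable-site or four-gamete purposes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .formats import LocusAlignment

_MISSING = frozenset(b"-N")


def _site_matrix(aln: LocusAlignment) -> tuple[np.ndarray, np.ndarray]:
    """(codes, observed-mask) arrays; missing = gap or N."""
    mat = aln.matrix()
    obs = (mat != ord("-")) & (mat != ord("N"))
    return mat, obs


def count_variable_sites(aln: LocusAlignment) -> int:
    """Number of columns with >= 2 distinct non-missing bases."""
    mat, obs = _site_matrix(aln)
    n_var = 0
    for j in range(mat.shape[1]):
        col = mat[obs[:, j], j]
        if col.size and np.unique(col).size >= 2:
            n_var += 1
    return n_var


def collapse_haplotypes(aln: LocusAlignment) -> dict[str, list[str]]:
    """Partition gene copies by exact sequence identity.

    Returns haplotype sequence -> list of copy ids (insertion order
    preserved).  The haplotype count is the number of keys; a reduced
    haplotype alignment for tree building is available via
    :func:`haplotype_alignment`.
    """
    out: dict[str, list[str]] = {}
    for cid, seq in zip(aln.copy_ids, aln.sequences):
        out.setdefault(seq, []).append(cid)
    return out


def haplotype_alignment(aln: LocusAlignment) -> tuple[LocusAlignment, dict[str, list[str]]]:
    """Reduced one-row-per-haplotype alignment plus haplotype -> copies map."""
    part = collapse_haplotypes(aln)
    names = [f"hap{i+1:03d}" for i in range(len(part))]
    reduced = LocusAlignment(
        aln.name + "_haps", names, list(part.keys()), ploidy=1,
        inheritance=aln.inheritance,
    )
    return reduced, dict(zip(names, part.values()))


# ---------------------------------------------------------------------------
# minimum recombination events (Hudson & Kaplan four-gamete bound)
# ---------------------------------------------------------------------------


def _biallelic_sites(aln: LocusAlignment) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Columns with exactly two non-missing alleles, as 0/1 codes.

    Sites with more than two alleles are skipped (four-gamete logic is
    defined for biallelic pairs).  Returns (site indices, binary matrix,
    observed mask) with one column per retained site.
    """
    mat, obs = _site_matrix(aln)
    sites: list[int] = []
    cols: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        vals = np.unique(col[obs[:, j]])
        if vals.size != 2:
            continue
        sites.append(j)
        cols.append((col == vals[1]).astype(np.int8))
        masks.append(obs[:, j])
    if not sites:
        return [], np.empty((mat.shape[0], 0), np.int8), np.empty(
            (mat.shape[0], 0), bool
        )
    return sites, np.stack(cols, axis=1), np.stack(masks, axis=1)


def incompatible_pairs(aln: LocusAlignment) -> list[tuple[int, int]]:
    """All site pairs exhibiting all four gametes (original column indices)."""
    sites, binm, mask = _biallelic_sites(aln)
    pairs: list[tuple[int, int]] = []
    for a in range(len(sites)):
        for b in range(a + 1, len(sites)):
            both = mask[:, a] & mask[:, b]
            combos = set(
                zip(binm[both, a].tolist(), binm[both, b].tolist())
            )
            if len(combos) == 4:
                pairs.append((sites[a], sites[b]))
    return pairs


def min_recombination_rm(aln: LocusAlignment) -> int:
    """Hudson–Kaplan lower bound Rm on the number of recombination events.

    Each incompatible site pair (i, j) requires a recombination event in
    the open interval (i, j); Rm is the size of a maximal set of pairwise
    disjoint such intervals, found by the classic earliest-right-endpoint
    greedy sweep.
    """
    intervals = sorted(incompatible_pairs(aln), key=lambda p: p[1])
    rm = 0
    last_right = -1
    for left, right in intervals:
        if left >= last_right:  # open intervals: (i, j) and (j, k) are disjoint
            rm += 1
            last_right = right
    return rm


# ---------------------------------------------------------------------------
# Fu & Li's F*
# ---------------------------------------------------------------------------


@dataclass
class FuLiFStar:
    statistic: float | None
    p_value: float | None
    significant: bool | None
    n: int
    s: int
    applicable: bool = True


def _segregating_and_singletons(aln: LocusAlignment) -> tuple[int, int, float]:
    """(S, folded singleton count, mean pairwise differences pi)."""
    mat, obs = _site_matrix(aln)
    s = 0
    eta_s = 0
    pi_sum = 0.0
    for j in range(mat.shape[1]):
        col = mat[obs[:, j], j]
        vals, counts = np.unique(col, return_counts=True)
        if vals.size < 2:
            continue
        s += 1
        eta_s += int((counts == 1).sum())
        m = counts.sum()
        if m >= 2:
            same = (counts * (counts - 1) / 2.0).sum()
            pi_sum += 1.0 - same / (m * (m - 1) / 2.0)
    # pi on the per-site pairwise-complete scale, summed over sites
    return s, eta_s, pi_sum


def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def fu_li_f_star_statistic(n: int, s: int, eta_s: int, pi: float) -> float:
    """Fu & Li's F* from sample size, segregating sites, singletons and pi.

    Uses the corrected variance coefficients in common use (the
    Simonsen–Churchill–Aquadro parameterization)::

        F* = (pi - ((n-1)/n) * eta_s) / sqrt(u* S + v* S^2)
    """
    if n < 4:
        raise ValueError("F* requires n >= 4 gene copies")
    if s < 1:
        raise ValueError("F* undefined with no segregating sites")
    a_n = _harmonic(n)
    b_n = _harmonic(n, 2)
    a_n1 = _harmonic(n + 1)
    v = (
        (2 * n**3 + 110 * n**2 - 255 * n + 153) / (9 * n**2 * (n - 1))
        + 2 * (n - 1) * a_n / n**2
        - 8 * b_n / n
    ) / (a_n**2 + b_n)
    u = (
        (4 * n**2 + 19 * n + 3 - 12 * (n + 1) * a_n1) / (3 * n * (n - 1))
    ) / a_n - v
    denom = np.sqrt(u * s + v * s * s)
    return float((pi - (n - 1) / n * eta_s) / denom)


def _simulate_null_stats(n: int, s: int, n_sims: int, rng: np.random.Generator) -> np.ndarray:
    """F* under the neutral coalescent at sample size n, conditioned on S.

    Simulates Kingman genealogies, drops exactly S mutations proportionally
    to branch length, and recomputes the statistic with the same folded
    singleton definition used on data.
    """
    out = np.empty(n_sims)
    n_pairs = n * (n - 1) / 2.0
    for r in range(n_sims):
        # track per-lineage active time and descendant counts
        alive = list(range(n))
        k = n
        lengths = {i: 0.0 for i in range(n)}
        node_desc = {i: 1 for i in range(n)}
        next_id = n
        while k > 1:
            t_k = rng.exponential(2.0 / (k * (k - 1)))
            for node in alive:
                lengths[node] += t_k
            i, j = rng.choice(k, size=2, replace=False)
            a, b = alive[i], alive[j]
            merged = next_id
            next_id += 1
            node_desc[merged] = node_desc[a] + node_desc[b]
            lengths[merged] = 0.0
            alive = [x for x in alive if x not in (a, b)]
            alive.append(merged)
            k -= 1
        per_class = np.zeros(n)
        for node, ln in lengths.items():
            d = node_desc[node]
            if d < n:
                per_class[d] += ln
        total = per_class.sum()
        muts = rng.multinomial(s, per_class / total)
        eta_s = int(muts[1] + (muts[n - 1] if n - 1 >= 1 else 0))
        d_arr = np.arange(n)
        pi = float((muts * d_arr * (n - d_arr)).sum() / n_pairs)
        out[r] = fu_li_f_star_statistic(n, s, eta_s, pi)
    return out


@lru_cache(maxsize=256)
def _null_band(n: int, s: int, n_sims: int, seed: int, alpha: float) -> tuple[float, float, tuple[float, ...]]:
    rng = np.random.default_rng([seed, n, s])
    stats = _simulate_null_stats(n, s, n_sims, rng)
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi), tuple(np.sort(stats))


def fu_li_f_star(
    aln: LocusAlignment,
    n_sims: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> FuLiFStar:
    """Fu & Li's F* with a simulated two-sided significance band.

    Returns a not-applicable sentinel when there are no segregating sites;
    raises for fewer than 4 gene copies.
    """
    n = aln.n_copies
    if n < 4:
        raise ValueError("F* requires an alignment of at least 4 gene copies")
    s, eta_s, pi = _segregating_and_singletons(aln)
    if s == 0:
        return FuLiFStar(None, None, None, n, 0, applicable=False)
    stat = fu_li_f_star_statistic(n, s, eta_s, pi)
    lo, hi, sorted_stats = _null_band(n, s, n_sims, seed, alpha)
    arr = np.asarray(sorted_stats)
    p_low = (np.searchsorted(arr, stat, side="right")) / arr.size
    p = float(2 * min(p_low, 1 - p_low) + 1.0 / arr.size)
    p = min(p, 1.0)
    return FuLiFStar(stat, p, bool(stat < lo or stat > hi), n, s)


# ---------------------------------------------------------------------------
# per-locus summary
# ---------------------------------------------------------------------------


@dataclass
class LocusSummary:
    locus: str
    length: int
    variable_sites: int
    n_haplotypes: int
    rm: int
    f_star: float | None
    f_star_significant: bool | None

    def __post_init__(self) -> None:
        assert 0 <= self.variable_sites <= self.length
        assert self.rm >= 0


def summarize_locus(
    aln: LocusAlignment, f_star_sims: int = 2000, seed: int = 0
) -> LocusSummary:
    """Compute the full per-locus summary row (Size, Variable Sites,
    No. of Haplotypes, Rm, F*)."""
    fstar = (
        fu_li_f_star(aln, n_sims=f_star_sims, seed=seed)
        if aln.n_copies >= 4
        else FuLiFStar(None, None, None, aln.n_copies, 0, applicable=False)
    )
    return LocusSummary(
        locus=aln.name,
        length=aln.length,
        variable_sites=count_variable_sites(aln),
        n_haplotypes=len(collapse_haplotypes(aln)),
        rm=min_recombination_rm(aln),
        f_star=fstar.statistic,
        f_star_significant=fstar.significant,
    )
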