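"""Niche overlap, permutation tests, and niche-dynamics indices.

The comparisons operate on the gridded E-space densities built by
:mod:`nichedyn.espace`:

* Schoener's D between two normalized occupancy grids,
  ``D = 1 - 0.5 * sum |p1 - p2|`` (0 = no overlap, 1 = identical);
* the niche **equivalency** test (pooled occurrences randomly re-split)
  and **similarity** test (one range's density randomly relocated within
  the other's background), each one-sided with alternatives "greater"
  (more equivalent/similar than chance) and "lower";
* the niche-dynamics indices expansion / stability / unfilling on the
  100% occurrence-density outline.

Permutation p-values use the (r + 1) / (n + 1) convention, so they are
never zero; at the default 100 repetitions the floor is 1/101.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .espace import EnvSpace, NicheDensity, _grid_density

#: dynamics indices above this value are flagged ecologically relevant
RELEVANCE_THRESHOLD = 0.1


def _occupancy_grid(z, policy: str = "corrected") -> np.ndarray:
    if isinstance(z, NicheDensity):
        z = z.occupancy(policy)
    z = np.asarray(z, dtype=float)
    if (z < 0).any():
        raise ValueError("occupancy grid must be non-negative")
    total = z.sum()
    if total <= 0:
        raise ValueError("occupancy grid has zero mass")
    return z / total


def schoener_d(z1, z2, policy: str = "corrected") -> float:
    """Schoener's D between two occupancy grids on the same grid."""
    p1 = _occupancy_grid(z1, policy)
    p2 = _occupancy_grid(z2, policy)
    if p1.shape != p2.shape:
        raise ValueError("densities live on different grids")
    return float(1.0 - 0.5 * np.abs(p1 - p2).sum())


def _pvalue(null: np.ndarray, observed: float, alternative: str) -> float:
    null = np.asarray(null, dtype=float)
    if alternative == "greater":
        r = int((null >= observed - 1e-12).sum())
    elif alternative == "lower":
        r = int((null <= observed + 1e-12).sum())
    else:
        raise ValueError("alternative must be 'greater' or 'lower'")
    return (r + 1) / (null.size + 1)


@dataclass
class PermutationResult:
    d_obs: float
    null: np.ndarray
    p_greater: float
    p_lower: float
    n_reps: int
    seed: int


def _corrected(z_occ: np.ndarray, z_avail: np.ndarray,
               avail_floor: float = 1e-6) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(z_avail > avail_floor * z_avail.max(), z_occ / z_avail, 0.0)
    total = z.sum()
    return z / total if total > 0 else z


def _rebuild(occ_scores: np.ndarray, template: NicheDensity, space: EnvSpace,
             policy: str) -> np.ndarray:
    """Occurrence density of a permuted score set against a range's fixed
    availability grid.

    The bandwidth is re-estimated from the permuted sample (not copied
    from the template): the observed densities use bandwidths estimated
    from their own samples, so the null must too, or the permutation
    distribution is not exchangeable with the observed statistic.
    """
    z_occ, _ = _grid_density(occ_scores, space, bandwidth=None)
    if policy == "raw":
        return z_occ
    return _corrected(z_occ, template.z_avail)


def equivalency_test(occ_scores1: np.ndarray, occ_scores2: np.ndarray,
                     dens1: NicheDensity, dens2: NicheDensity,
                     space: EnvSpace, n_reps: int = 100, seed: int = 0,
                     policy: str = "raw") -> PermutationResult:
    """Niche equivalency: are the two occurrence sets interchangeable?

    The pooled occurrence scores are randomly re-split into the original
    sample sizes (without replacement); both densities are rebuilt against
    their own range's availability and D recomputed.  Under "greater" a
    small p supports niches more equivalent than chance; under "lower",
    less equivalent (a niche shift).

    The default policy here is "raw", unlike the reporting of D itself:
    the availability correction clips each density to its own range's
    background, so when the two backgrounds do not overlap in E-space
    both the observed and every permuted D degenerate to 0 and the test
    loses all power.  The uncorrected densities keep the null
    informative; pass ``policy="corrected"`` to override.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    occ_scores1 = np.atleast_2d(occ_scores1)
    occ_scores2 = np.atleast_2d(occ_scores2)
    n1, n2 = len(occ_scores1), len(occ_scores2)
    if min(n1, n2) < 2:
        raise ValueError("each range needs at least 2 occurrences")
    d_obs = schoener_d(dens1, dens2, policy)
    pooled = np.vstack([occ_scores1, occ_scores2])
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(n1 + n2)
        g1 = _rebuild(pooled[perm[:n1]], dens1, space, policy)
        g2 = _rebuild(pooled[perm[n1:]], dens2, space, policy)
        d = 1.0 - 0.5 * np.abs(g1 / g1.sum() - g2 / g2.sum()).sum()
        null[r] = float(min(max(d, 0.0), 1.0))
    return PermutationResult(
        d_obs=d_obs, null=null,
        p_greater=_pvalue(null, d_obs, "greater"),
        p_lower=_pvalue(null, d_obs, "lower"),
        n_reps=n_reps, seed=seed,
    )


def _shift_density(z: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Translate a grid by integer offsets, zero-filling the exposed
    margin (no wrap-around: mass pushed off the grid is lost)."""
    out = np.zeros_like(z)
    si, sj = shift
    ni, nj = z.shape
    i0, i1 = max(0, si), min(ni, ni + si)
    j0, j1 = max(0, sj), min(nj, nj + sj)
    out[i0:i1, j0:j1] = z[i0 - si:i1 - si, j0 - sj:j1 - sj]
    return out


def similarity_test(dens1: NicheDensity, dens2: NicheDensity,
                    space: EnvSpace, n_reps: int = 100, seed: int = 0,
                    policy: str = "raw", max_retries: int = 100
                    ) -> PermutationResult:
    """Niche similarity: is range 1's niche more (or less) similar to
    range 2's than to a niche placed at random within range 2's
    background?

    Each repetition translates range 2's occurrence density so its
    centroid sits on a randomly chosen available cell of range 2, clips
    it to the available cells, renormalizes, and recomputes D against
    range 1's observed density.  The default policy is "raw" for the
    same reason as in :func:`equivalency_test`.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    d_obs = schoener_d(dens1, dens2, policy)
    avail2 = dens2.z_avail > 0
    if not avail2.any():
        raise ValueError("range 2 has an empty background")
    cells = np.argwhere(avail2)
    z2 = dens2.z_occ_raw
    total = z2.sum()
    ci = (np.arange(z2.shape[0]) @ z2.sum(axis=1)) / total
    cj = (np.arange(z2.shape[1]) @ z2.sum(axis=0)) / total
    rng = np.random.default_rng(seed)
    p1 = _occupancy_grid(dens1, policy)
    null = np.empty(n_reps)
    for r in range(n_reps):
        for _attempt in range(max_retries):
            ti, tj = cells[rng.integers(len(cells))]
            shifted = _shift_density(z2, (int(round(ti - ci)), int(round(tj - cj))))
            shifted = np.where(avail2, shifted, 0.0)
            if shifted.sum() > 0:
                break
        else:
            raise RuntimeError("could not place the simulated niche on the background")
        sim = _corrected(shifted, dens2.z_avail) if policy == "corrected" \
            else shifted / shifted.sum()
        d = 1.0 - 0.5 * np.abs(p1 - sim / sim.sum()).sum()
        null[r] = float(min(max(d, 0.0), 1.0))
    return PermutationResult(
        d_obs=d_obs, null=null,
        p_greater=_pvalue(null, d_obs, "greater"),
        p_lower=_pvalue(null, d_obs, "lower"),
        n_reps=n_reps, seed=seed,
    )


def niche_dynamics(dens1: NicheDensity, dens2: NicheDensity,
                   analog_policy: str = "intersection",
                   policy: str = "corrected") -> tuple[float, float, float]:
    """Expansion, stability, and unfilling for an ordered pair (1 -> 2).

    On the analog climate mask (by default the intersection of both
    ranges' available climates): stability is the proportion of range 1's
    occurrence density lying on cells occupied by range 2; expansion the
    complementary proportion on cells not occupied by range 2; unfilling
    the proportion of range 2's density on cells not occupied by range 1.
    Occupancy is judged at the 100% occurrence-density outline.
    """
    if dens1.z_avail.shape != dens2.z_avail.shape:
        raise ValueError("densities live on different grids")
    if analog_policy == "intersection":
        A = (dens1.z_avail > 0) & (dens2.z_avail > 0)
    elif analog_policy == "full-grid":
        A = np.ones_like(dens1.z_avail, dtype=bool)
    else:
        raise ValueError("analog_policy must be 'intersection' or 'full-grid'")
    M1 = dens1.occupied_mask_100 & A
    M2 = dens2.occupied_mask_100 & A
    if not M1.any() or not M2.any():
        raise ValueError("empty occupancy mask on the analog climate")
    p1 = np.where(A, dens1.occupancy(policy), 0.0)
    p2 = np.where(A, dens2.occupancy(policy), 0.0)
    if p1.sum() <= 0 or p2.sum() <= 0:
        raise ValueError("no occupancy mass on the analog climate")
    p1 /= p1.sum()
    p2 /= p2.sum()
    stability = float(p1[M2].sum())
    expansion = 1.0 - stability
    unfilling = float(p2[~M1].sum())
    return expansion, stability, unfilling


@dataclass
class NicheComparison:
    """Full comparison record for an ordered range pair (1 -> 2)."""

    pair: tuple[str, str]
    D_obs: float
    equivalency_p_lower: float
    equivalency_p_greater: float
    similarity_p_lower: float
    similarity_p_greater: float
    expansion: float
    stability: float
    unfilling: float
    n_permutations: int
    analog_mask_policy: str
    seed: int

    @property
    def expansion_relevant(self) -> bool:
        return self.expansion > RELEVANCE_THRESHOLD

    @property
    def stability_relevant(self) -> bool:
        return self.stability > RELEVANCE_THRESHOLD

    @property
    def unfilling_relevant(self) -> bool:
        return self.unfilling > RELEVANCE_THRESHOLD


def compare_pair(label1: str, label2: str, occ_scores: dict, densities: dict,
                 space: EnvSpace, n_reps: int = 100, seed: int = 0,
                 policy: str = "corrected", test_policy: str = "raw",
                 analog_policy: str = "intersection") -> NicheComparison:
    """Run overlap, both permutation tests, and dynamics for one ordered
    pair of ranges.

    ``policy`` governs the reported D and the dynamics indices;
    ``test_policy`` governs the occupancy grids inside the permutation
    tests (see :func:`equivalency_test` for why they differ).
    """
    d1, d2 = densities[label1], densities[label2]
    eq = equivalency_test(occ_scores[label1], occ_scores[label2], d1, d2,
                          space, n_reps=n_reps, seed=seed, policy=test_policy)
    sim = similarity_test(d1, d2, space, n_reps=n_reps, seed=seed + 1,
                          policy=test_policy)
    expansion, stability, unfilling = niche_dynamics(
        d1, d2, analog_policy=analog_policy, policy=policy)
    return NicheComparison(
        pair=(label1, label2),
        D_obs=schoener_d(d1, d2, policy),
        equivalency_p_lower=eq.p_lower,
        equivalency_p_greater=eq.p_greater,
        similarity_p_lower=sim.p_lower,
        similarity_p_greater=sim.p_greater,
        expansion=expansion,
        stability=stability,
        unfilling=unfilling,
        n_permutations=n_reps,
        analog_mask_policy=analog_policy,
        seed=seed,
    )


__all__ = [
    "RELEVANCE_THRESHOLD", "PermutationResult", "NicheComparison",
    "schoener_d", "equivalency_test", "similarity_test", "niche_dynamics",
    "compare_pair",
]
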