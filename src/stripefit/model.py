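"""Analytic scrunching model of unidirectional loop extrusion.

A condensin binds a fixed loading site at rate ``k_b``, anchors one leg there
and translocates the other along the chromosome at speed ``v_e`` until it
unbinds at rate ``k_u``.  Only two combinations of these rates are
identifiable from stationary contact data:

* the processivity ``p = v_e / k_u`` — the mean loop size extruded in the
  absence of obstacles, and
* the density ``d = k_b / (k_b + k_u)`` — the stationary probability that an
  extruder is bound and holding a loop.

The stationary loop-size distribution is exponential with mean ``p``; a
roadblock at distance ``l_i`` that engages the extruder with probability
``alpha_i`` truncates that distribution and piles the truncated mass into an
atom at ``l_i``.  A Gaussian-polymer contact model then converts the loop-size
distribution into the expected 4C-like contact profile of the loading site,
``P(s) = (1 - d) P0(s) + d * sum_l rho(l) P(s, l)``, whose ratio to the
loop-free background ``P0(s) = A s^(-gamma)`` is the quantity compared with
Hi-C stripe data.

All distributions live on a uniform genomic grid (default 1 kb, the Hi-C bin
size).  The continuous part of each distribution stores exact integral bin
masses of the truncated exponential, and every truncation tail is carried as
an exact point mass, so normalization holds to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExtrusionParams",
    "Roadblock",
    "RoadblockSet",
    "LoopSizeDistribution",
    "free_loop_density",
    "blocked_loop_density",
    "composite_loop_density",
    "contact_p0",
    "contact_with_loop",
    "predict_contact_profile",
    "predict_ratio_profile",
]

# Loop-size support is capped at this multiple of the processivity when no
# chromosome end is given; the exponential tail beyond it (< 5e-5 of the mass)
# is carried as a terminal atom.
TRUNCATION_FACTOR = 10.0


@dataclass(frozen=True)
class ExtrusionParams:
    """Identifiable parameters of the scrunching model.

    Parameters
    ----------
    processivity_p:
        Mean loop size extruded before unbinding, in kb (``v_e / k_u``).
    density_d:
        Stationary probability that an extruder is bound at the loading
        site (``k_b / (k_b + k_u)``).
    gamma:
        Contact-decay exponent of the polymer background; 1.5 for an ideal
        (Gaussian) chain, smaller for more compact chromatin.
    amplitude_A:
        Multiplicative constant of the contact model.  Cancels from ratio
        profiles everywhere except at loop-closure atoms.
    """

    processivity_p: float
    density_d: float
    gamma: float = 1.5
    amplitude_A: float = 1.0

    def __post_init__(self) -> None:
        if not self.processivity_p > 0:
            raise ValueError(f"processivity_p must be > 0, got {self.processivity_p}")
        if not 0.0 <= self.density_d <= 1.0:
            raise ValueError(f"density_d must be in [0, 1], got {self.density_d}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not self.amplitude_A > 0:
            raise ValueError(f"amplitude_A must be > 0, got {self.amplitude_A}")


@dataclass(frozen=True)
class Roadblock:
    """A cis-acting extrusion obstacle.

    ``position_l`` is the genomic distance (kb) from the loading site along
    the extrusion direction.  ``pause_alpha`` is the probability that an
    extruder engages (stops at) the block; a non-engaged block is transparent.
    ``domain_width`` > 0 models a diffuse obstacle: the actual barrier is
    placed uniformly at random within ``position_l +/- domain_width / 2``.
    """

    position_l: float
    pause_alpha: float
    domain_width: float = 0.0

    def __post_init__(self) -> None:
        if not self.position_l > 0:
            raise ValueError(f"position_l must be > 0, got {self.position_l}")
        if not 0.0 <= self.pause_alpha <= 1.0:
            raise ValueError(f"pause_alpha must be in [0, 1], got {self.pause_alpha}")
        if self.domain_width < 0:
            raise ValueError(f"domain_width must be >= 0, got {self.domain_width}")
        if self.position_l - self.domain_width / 2 <= 0:
            raise ValueError("domain extends to or past the loading site")

    @property
    def domain_start(self) -> float:
        return self.position_l - self.domain_width / 2

    @property
    def domain_end(self) -> float:
        return self.position_l + self.domain_width / 2


@dataclass(frozen=True)
class RoadblockSet:
    """Ordered roadblocks along the extrusion direction.

    ``terminal_position`` (kb), when given, is the chromosome-arm end treated
    as an absolute block: extrusion can never proceed past it.
    """

    blocks: tuple[Roadblock, ...] = ()
    terminal_position: float | None = None

    def __init__(
        self,
        blocks: "tuple[Roadblock, ...] | list[Roadblock]" = (),
        terminal_position: float | None = None,
    ) -> None:
        object.__setattr__(self, "blocks", tuple(blocks))
        object.__setattr__(self, "terminal_position", terminal_position)
        positions = [b.position_l for b in self.blocks]
        if any(b2 <= b1 for b1, b2 in zip(positions, positions[1:])):
            raise ValueError("roadblock positions must be strictly increasing")
        for b1, b2 in zip(self.blocks, self.blocks[1:]):
            if b1.domain_end > b2.domain_start:
                raise ValueError(
                    f"roadblock domains overlap: [{b1.domain_start}, {b1.domain_end}]"
                    f" and [{b2.domain_start}, {b2.domain_end}]"
                )
        if terminal_position is not None:
            if not terminal_position > 0:
                raise ValueError("terminal_position must be > 0")
            if self.blocks and self.blocks[-1].domain_end > terminal_position:
                raise ValueError("last roadblock lies beyond the terminal position")

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)


NO_BLOCKS = RoadblockSet()


@dataclass
class LoopSizeDistribution:
    """Mixed discrete/continuous distribution of extruded loop sizes.

    ``grid`` holds uniformly spaced loop sizes (integer multiples of
    ``bin_width``); ``continuous_density`` is the per-kb density of the
    continuous part at each grid point (bin mass / bin width); ``atoms`` maps
    loop size (kb) to point mass.  Atoms always lie on the grid.
    """

    bin_width: float
    grid: np.ndarray
    continuous_density: np.ndarray
    atoms: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.continuous_density = np.asarray(self.continuous_density, dtype=float)
        if self.grid.shape != self.continuous_density.shape:
            raise ValueError("grid and continuous_density must have equal length")
        if np.any(self.continuous_density < -1e-12):
            raise ValueError("negative continuous density")
        if any(m < -1e-12 for m in self.atoms.values()):
            raise ValueError("negative atom mass")

    @property
    def total_mass(self) -> float:
        return float(self.continuous_density.sum() * self.bin_width + sum(self.atoms.values()))

    def masses(self) -> np.ndarray:
        """Per-grid-point probability mass, atoms folded onto their bin."""
        m = self.continuous_density * self.bin_width
        for pos, mass in self.atoms.items():
            idx = int(round(pos / self.bin_width)) - 1
            if not 0 <= idx < len(m) or abs(pos - self.grid[idx]) > 1e-6 * self.bin_width:
                raise ValueError(f"atom at {pos} kb is off the grid")
            m[idx] += mass
        return m

    def density_at(self, l: float) -> float:
        """Continuous density at the grid point nearest ``l`` (atoms excluded)."""
        idx = int(round(l / self.bin_width)) - 1
        if not 0 <= idx < len(self.grid):
            return 0.0
        return float(self.continuous_density[idx])

    def cdf(self, x: np.ndarray | float) -> np.ndarray:
        """CDF evaluated at ``x`` (right-continuous), treating each grid bin's
        mass as concentrated at the grid point."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        m = self.masses()
        cum = np.concatenate([[0.0], np.cumsum(m)])
        idx = np.clip(np.floor(x / self.bin_width + 1e-9).astype(int), 0, len(m))
        return cum[idx]

    def ks_distance(self, samples: np.ndarray) -> float:
        """Kolmogorov-Smirnov distance to an empirical sample.

        Samples are binned with the distribution's own convention (bin ``k``
        covers ``((k - 1/2) dl, (k + 1/2) dl]``, the sliver below half a bin
        folded into the first bin) so that the comparison is between two
        distributions on the same discrete support.
        """
        samples = np.asarray(samples, dtype=float)
        m = self.masses()
        edges = np.concatenate(
            [[0.0], (np.arange(1, len(m)) + 0.5) * self.bin_width, [np.inf]]
        )
        counts, _ = np.histogram(samples, bins=edges)
        emp = np.cumsum(counts) / samples.size
        model = np.cumsum(m) / self.total_mass
        return float(np.max(np.abs(emp - model)))


def _exp_cdf(x: np.ndarray | float, p: float) -> np.ndarray | float:
    return -np.expm1(-np.asarray(x, dtype=float) / p)


def _truncated_exponential(p: float, cut: float, bin_width: float) -> LoopSizeDistribution:
    """Exponential(mean p) truncated at ``cut``: exact bin masses on the grid
    ``bin_width, 2*bin_width, ..., cut`` plus the tail ``e^(-cut/p)`` as an
    atom at ``cut``.

    Bin ``k`` covers ``((k - 1/2) dl, (k + 1/2) dl]``; the first bin absorbs
    ``(0, dl/2]`` and the last continuous bin ends exactly at ``cut``, so the
    total mass is exactly 1.
    """
    if p <= 0:
        raise ValueError(f"processivity must be > 0, got {p}")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    n = int(round(cut / bin_width))
    if n < 1 or abs(n * bin_width - cut) > 1e-6 * bin_width:
        raise ValueError(f"cut ({cut}) must be a positive multiple of bin_width ({bin_width})")
    grid = bin_width * np.arange(1, n + 1)
    edges = np.concatenate([[0.0], (np.arange(1, n) + 0.5) * bin_width, [cut]])
    mass = np.diff(_exp_cdf(edges, p))
    dist = LoopSizeDistribution(
        bin_width=bin_width,
        grid=grid,
        continuous_density=mass / bin_width,
        atoms={float(cut): math.exp(-cut / p)},
    )
    return dist


def free_loop_density(
    params: ExtrusionParams, max_l: float | None = None, bin_width: float = 1.0
) -> LoopSizeDistribution:
    """Loop-size distribution without roadblocks: Exponential(mean p).

    The support is truncated at ``max_l`` (default ``10 p``, rounded to the
    grid); the truncated tail becomes a terminal atom, modelling the
    chromosome-arm end as absorbing.
    """
    p = params.processivity_p
    if max_l is None:
        max_l = TRUNCATION_FACTOR * p
    max_l = max(bin_width, round(max_l / bin_width)) * bin_width
    return _truncated_exponential(p, max_l, bin_width)


def blocked_loop_density(
    params: ExtrusionParams,
    block_position: float,
    max_l: float | None = None,
    bin_width: float = 1.0,
) -> LoopSizeDistribution:
    """Loop-size distribution with an engaged (impermeable) roadblock.

    The exponential is cut at the block: density ``(1/p) e^(-l/p)`` below the
    block position, an atom of mass ``e^(-l_i/p)`` exactly at it (extruders
    that reached the block and are held there), nothing beyond.
    """
    if block_position <= 0:
        raise ValueError(f"block_position must be > 0, got {block_position}")
    cut = block_position
    if max_l is not None:
        cut = min(cut, max_l)
    cut = max(bin_width, round(cut / bin_width)) * bin_width
    return _truncated_exponential(params.processivity_p, cut, bin_width)


def _mixture(components: list[tuple[float, LoopSizeDistribution]], bin_width: float) -> LoopSizeDistribution:
    n = max(len(c.grid) for _, c in components)
    grid = bin_width * np.arange(1, n + 1)
    density = np.zeros(n)
    atoms: dict[float, float] = {}
    for w, comp in components:
        if w == 0.0:
            continue
        density[: len(comp.grid)] += w * comp.continuous_density
        for pos, mass in comp.atoms.items():
            atoms[pos] = atoms.get(pos, 0.0) + w * mass
    return LoopSizeDistribution(bin_width, grid, density, atoms)


def _composite_fixed_positions(
    params: ExtrusionParams,
    positions: list[float],
    alphas: list[float],
    max_l: float,
    bin_width: float,
) -> LoopSizeDistribution:
    components: list[tuple[float, LoopSizeDistribution]] = []
    survival = 1.0
    for pos, alpha in zip(positions, alphas):
        if pos >= max_l:
            break  # blocks beyond the support can never be reached
        weight = survival * alpha
        if weight > 0:
            components.append(
                (weight, blocked_loop_density(params, pos, max_l, bin_width))
            )
        survival *= 1.0 - alpha
    if survival > 0:
        components.append((survival, free_loop_density(params, max_l, bin_width)))
    return _mixture(components, bin_width)


def composite_loop_density(
    params: ExtrusionParams,
    blocks: RoadblockSet = NO_BLOCKS,
    max_l: float | None = None,
    bin_width: float = 1.0,
) -> LoopSizeDistribution:
    """Loop-size distribution under an ordered set of partial roadblocks.

    The result is the mixture of the free distribution, weighted by the
    probability ``prod_k (1 - alpha_k)`` of passing every block, and one
    blocked distribution per roadblock ``i`` weighted by
    ``prod_{k<i} (1 - alpha_k) * alpha_i`` (pass every earlier block, engage
    this one).  Domain blocks are averaged over every grid-point placement of
    the barrier inside the domain, each configuration evaluated in full and
    then meaned.
    """
    p = params.processivity_p
    if max_l is None:
        max_l = TRUNCATION_FACTOR * p
    if blocks.terminal_position is not None:
        max_l = min(max_l, blocks.terminal_position)
    max_l = max(bin_width, round(max_l / bin_width)) * bin_width

    snap = lambda x: max(bin_width, round(x / bin_width)) * bin_width
    # enumerate barrier placements for each domain block
    placements: list[list[float]] = []
    alphas = [b.pause_alpha for b in blocks]
    for b in blocks:
        if b.domain_width > 0:
            lo = int(np.ceil((b.domain_start - 1e-9) / bin_width))
            hi = int(np.floor((b.domain_end + 1e-9) / bin_width))
            pts = [k * bin_width for k in range(max(lo, 1), hi + 1)]
            placements.append(pts if pts else [snap(b.position_l)])
        else:
            placements.append([snap(b.position_l)])

    configs: list[list[float]] = [[]]
    for pts in placements:
        configs = [c + [pt] for c in configs for pt in pts]

    dists = [
        _composite_fixed_positions(params, cfg, alphas, max_l, bin_width)
        for cfg in configs
    ]
    if len(dists) == 1:
        return dists[0]
    return _mixture([(1.0 / len(dists), d) for d in dists], bin_width)


def contact_p0(s: np.ndarray | float, params: ExtrusionParams) -> np.ndarray | float:
    """Gaussian-polymer background contact frequency ``A s^(-gamma)``."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr <= 0):
        raise ValueError("genomic distance s must be > 0")
    out = params.amplitude_A * s_arr ** (-params.gamma)
    return out if np.ndim(s) else float(out)


def contact_with_loop(
    s: np.ndarray | float, l: float, params: ExtrusionParams
) -> np.ndarray | float:
    """Contact frequency of the loading site with a point at distance ``s``
    given a fixed extruded loop of size ``l``.

    Inside the loop the two anchors are joined, so the effective Gaussian
    variance is ``s (l - s) / l`` (two chain segments in parallel); at the
    loop closure point ``s = l`` the contact is 1 by definition; beyond the
    loop the intervening chain is shortened by ``l``.
    """
    if l <= 0:
        raise ValueError("loop size l must be > 0")
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr <= 0):
        raise ValueError("genomic distance s must be > 0")
    A, g = params.amplitude_A, params.gamma
    inside = s_arr < l
    beyond = s_arr > l
    eff = np.where(inside, s_arr * (l - s_arr) / l, np.where(beyond, s_arr - l, 1.0))
    out = np.where(np.isclose(s_arr, l), 1.0, A * np.abs(eff) ** (-g))
    return out if np.ndim(s) else float(out)


def _loop_contact_kernel(
    s_grid: np.ndarray,
    l_grid: np.ndarray,
    params: ExtrusionParams,
    bin_width: float = 1.0,
) -> np.ndarray:
    """Matrix ``K[i, j] = P(s_i | loop of size l_j)`` per the piecewise
    Gaussian contact model, with the ``s = l`` entries set to 1.

    Effective separations are floored at one bin: the within-loop expression
    ``s (l - s) / l`` drops below the grid resolution for bins adjacent to
    the loop closure, where the continuum contact would exceed the closure
    contact itself.
    """
    S = s_grid[:, None]
    L = l_grid[None, :]
    A, g = params.amplitude_A, params.gamma
    equal = np.isclose(S, L, rtol=0.0, atol=1e-6)
    inside = (S < L) & ~equal
    eff = np.where(inside, S * (L - S) / np.maximum(L, 1e-300), S - L)
    eff = np.where(equal, 1.0, np.maximum(np.abs(eff), bin_width))
    K = A * eff ** (-g)
    K[equal.nonzero()] = 1.0
    return K


def stripe_component(
    params: ExtrusionParams,
    blocks: RoadblockSet = NO_BLOCKS,
    s_grid: np.ndarray | None = None,
    bin_width: float | None = None,
) -> np.ndarray:
    """Loop-averaged contact term ``E(s) = sum_l rho(l) P(s, l)`` of the
    profile mixture, independent of the density ``d``."""
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.size == 0:
        raise ValueError("s_grid is empty")
    if bin_width is None:
        bin_width = float(s_grid[0])
    dist = composite_loop_density(params, blocks, bin_width=bin_width)
    m = dist.masses()
    K = _loop_contact_kernel(s_grid, dist.grid, params, bin_width)
    return K @ m


def predict_contact_profile(
    params: ExtrusionParams,
    blocks: RoadblockSet = NO_BLOCKS,
    s_grid: np.ndarray | list | None = None,
):
    """Expected 4C-like contact profile of the loading site.

    ``P(s) = (1 - d) P0(s) + d sum_l rho(l) P(s, l)``, the sum running over
    the discretized loop-size distribution (loop-closure atoms contribute
    their mass times a contact of exactly 1 at ``s = l``).
    """
    from .profiles import ContactProfile

    if s_grid is None:
        raise ValueError("s_grid is required")
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.size == 0:
        raise ValueError("s_grid is empty")
    d = params.density_d
    p0 = contact_p0(s_grid, params)
    values = (1.0 - d) * p0
    if d > 0:
        values = values + d * stripe_component(params, blocks, s_grid)
    return ContactProfile(distances=s_grid, values=np.asarray(values, dtype=float))


def predict_ratio_profile(
    params: ExtrusionParams,
    blocks: RoadblockSet = NO_BLOCKS,
    s_grid: np.ndarray | list | None = None,
):
    """Predicted stripe enrichment ``P(s) / P0(s)``.

    Equals 1 everywhere when ``d = 0`` and is bounded below by ``1 - d``.
    The amplitude ``A`` cancels except at loop-closure atom bins, where the
    contact is pinned to 1 rather than scaled by ``A``.
    """
    from .profiles import RatioProfile

    profile = predict_contact_profile(params, blocks, s_grid)
    p0 = contact_p0(profile.distances, params)
    return RatioProfile(distances=profile.distances, values=profile.values / p0)
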