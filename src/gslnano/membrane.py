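"""Nanodomain-structured bilayer patches and fluorescent-probe placement.

The membrane is idealised as a flat periodic square patch of side ``L`` (nm)
carrying ``N`` identical non-overlapping circular nanodomains of radius ``R``
covering an area fraction ``A``.  Domains are registered across the two
leaflets (the same lateral discs apply to both), and donor/acceptor probes
partition between the domain and bulk phases according to a partition
coefficient ``K``: the probability of finding a probe inside a domain is

    p_in = K*A / (K*A + (1 - A))

All lengths are nm; lateral coordinates live on the half-open torus
``[0, L) x [0, L)``.  Cross-leaflet probe pairs are separated by an
additional out-of-plane distance (the bilayer separation) added in
quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "DomainModel",
    "DomainConfiguration",
    "ProbeConfiguration",
    "PlacementError",
    "place_domains",
    "place_probes",
    "pair_distance",
    "coverage_estimate",
]

#: Hard upper bound on the domain area fraction for which disc placement is
#: guaranteed to converge (comfortably above the highest fitted coverages,
#: e.g. 61% for GM3 in pure DOPC).
MAX_AREA_FRACTION = 0.65


class PlacementError(RuntimeError):
    """Raised when a non-overlapping disc configuration cannot be built."""


def _minimum_image(delta: np.ndarray, box_length: float) -> np.ndarray:
    """Wrap lateral displacement(s) into the minimum-image convention."""
    return delta - box_length * np.round(delta / box_length)


@dataclass(frozen=True)
class DomainModel:
    """Nanodomain geometry and probe partitioning for one membrane state.

    Parameters
    ----------
    radius_nm : float
        Nanodomain radius R (nm).
    area_fraction : float
        Membrane area fraction A covered by nanodomains, in [0, 0.65].
    box_length_nm : float
        Side of the periodic simulation patch.  Must be at least 10 R when
        domains are present (finite-size control).
    bilayer_separation_nm : float
        Out-of-plane distance between the two leaflet planes carrying the
        probes.
    partition_donor, partition_acceptor : float
        Partition coefficients K of the donor/acceptor probes into the
        domain phase (K = 1 means no preference).
    """

    radius_nm: float
    area_fraction: float
    box_length_nm: float
    bilayer_separation_nm: float = 4.0
    partition_donor: float = 1.0
    partition_acceptor: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.area_fraction <= MAX_AREA_FRACTION):
            raise ValueError(
                f"area_fraction must lie in [0, {MAX_AREA_FRACTION}]; "
                f"got {self.area_fraction}"
            )
        if self.area_fraction > 0.0 and self.radius_nm <= 0.0:
            raise ValueError("radius_nm must be > 0 when area_fraction > 0")
        if self.box_length_nm <= 0.0:
            raise ValueError("box_length_nm must be positive")
        if self.area_fraction > 0.0 and self.box_length_nm < 10.0 * self.radius_nm:
            raise ValueError(
                "box_length_nm must be at least 10x radius_nm "
                f"({10 * self.radius_nm:g} nm) to control finite-size effects"
            )
        if self.bilayer_separation_nm < 0.0:
            raise ValueError("bilayer_separation_nm must be >= 0")
        if self.partition_donor < 0.0 or self.partition_acceptor < 0.0:
            raise ValueError("partition coefficients must be >= 0")

    @property
    def n_domains(self) -> int:
        """Disc count N = round(A L^2 / (pi R^2)); 0 when A = 0."""
        if self.area_fraction == 0.0:
            return 0
        return int(
            round(
                self.area_fraction
                * self.box_length_nm**2
                / (np.pi * self.radius_nm**2)
            )
        )


@dataclass(frozen=True)
class DomainConfiguration:
    """A realised set of non-overlapping nanodomain discs on the torus."""

    centers: np.ndarray  # (N, 2) nm
    radius_nm: float
    box_length_nm: float

    @property
    def n_domains(self) -> int:
        return len(self.centers)

    @property
    def area_fraction(self) -> float:
        """Exact covered fraction (discs never overlap)."""
        return self.n_domains * np.pi * self.radius_nm**2 / self.box_length_nm**2

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which lateral points lie inside any disc."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.n_domains == 0:
            return np.zeros(len(points), dtype=bool)
        tree = cKDTree(self.centers % self.box_length_nm, boxsize=self.box_length_nm)
        dist, _ = tree.query(points % self.box_length_nm, k=1)
        return dist <= self.radius_nm

    def validate(self) -> None:
        """Raise if any two disc centers are closer than 2R (torus metric)."""
        if self.n_domains < 2:
            return
        tree = cKDTree(self.centers % self.box_length_nm, boxsize=self.box_length_nm)
        pairs = tree.query_pairs(2.0 * self.radius_nm * (1.0 - 1e-12))
        if pairs:
            raise PlacementError(f"{len(pairs)} overlapping disc pair(s) present")


@dataclass(frozen=True)
class ProbeConfiguration:
    """Donor/acceptor lateral positions, leaflet labels and domain flags."""

    donor_xy: np.ndarray            # (N_D, 2) nm
    donor_leaflet: np.ndarray       # (N_D,) in {0, 1}
    donor_in_domain: np.ndarray     # (N_D,) bool
    acceptor_xy: np.ndarray         # (N_A, 2) nm
    acceptor_leaflet: np.ndarray    # (N_A,) in {0, 1}
    acceptor_in_domain: np.ndarray  # (N_A,) bool
    box_length_nm: float
    bilayer_separation_nm: float = 4.0
    domain_config: DomainConfiguration | None = field(default=None, repr=False)

    @property
    def n_donors(self) -> int:
        return len(self.donor_xy)

    @property
    def n_acceptors(self) -> int:
        return len(self.acceptor_xy)


def partition_probability(partition_coefficient: float, area_fraction: float) -> float:
    """p_in = K*A / (K*A + (1 - A)) — probability a probe sits in a domain."""
    k, a = float(partition_coefficient), float(area_fraction)
    denom = k * a + (1.0 - a)
    if denom == 0.0:
        raise ValueError(
            "degenerate partitioning: K=0 with A=1 leaves no admissible region"
        )
    return k * a / denom


def place_domains(model: DomainModel, seed: int) -> DomainConfiguration:
    """Place ``model.n_domains`` non-overlapping discs under periodic boundaries.

    Discs are initialised uniformly at random (overlaps allowed) and then
    relaxed: every overlapping pair is pushed apart along its minimum-image
    axis until the configuration is overlap-free.  This converges well past
    the ~55% jamming limit of sequential adsorption, covering the full
    supported range A <= 0.65.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = model.n_domains
    L = model.box_length_nm
    R = model.radius_nm
    if n == 0:
        return DomainConfiguration(np.empty((0, 2)), R, L)
    centers = rng.uniform(0.0, L, size=(n, 2))
    target = 2.0 * R
    max_iter = 5000
    for _ in range(max_iter):
        tree = cKDTree(centers, boxsize=L)
        pairs = np.array(sorted(tree.query_pairs(target)), dtype=int)
        if len(pairs) == 0:
            cfg = DomainConfiguration(centers, R, L)
            cfg.validate()
            return cfg
        i, j = pairs[:, 0], pairs[:, 1]
        delta = _minimum_image(centers[i] - centers[j], L)
        dist = np.linalg.norm(delta, axis=1)
        # coincident centers: separate along a random axis
        bad = dist < 1e-9
        if np.any(bad):
            delta[bad] = rng.normal(size=(bad.sum(), 2))
            dist[bad] = np.linalg.norm(delta[bad], axis=1)
        push = (0.5 * (target - dist) + 0.05 * R) / dist
        disp = delta * push[:, None]
        move = np.zeros_like(centers)
        np.add.at(move, i, disp)
        np.add.at(move, j, -disp)
        centers = (centers + move) % L
    achievable = MAX_AREA_FRACTION
    raise PlacementError(
        f"could not place {n} discs of radius {R} nm at area fraction "
        f"{model.area_fraction:.3f} within {max_iter} relaxation sweeps; "
        f"coverages up to about {achievable:.2f} are achievable"
    )


def _sample_phase_points(
    config: DomainConfiguration,
    inside: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample lateral positions uniformly within the requested phase."""
    n = len(inside)
    L = config.box_length_nm
    out = np.empty((n, 2))
    n_in = int(inside.sum())
    if n_in and config.n_domains == 0:
        raise PlacementError("probes assigned to the domain phase but no domains exist")
    if n_in:
        # uniform over the union of discs: pick a disc, then a point in it
        disc = rng.integers(0, config.n_domains, size=n_in)
        r = config.radius_nm * np.sqrt(rng.uniform(size=n_in))
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n_in)
        pts = config.centers[disc] + np.c_[r * np.cos(theta), r * np.sin(theta)]
        out[inside] = pts % L
    n_out = n - n_in
    if n_out:
        # rejection sampling against the discs
        idx = np.flatnonzero(~inside)
        remaining = idx
        for _ in range(1000):
            if len(remaining) == 0:
                break
            cand = rng.uniform(0.0, L, size=(len(remaining), 2))
            ok = ~config.contains(cand)
            out[remaining[ok]] = cand[ok]
            remaining = remaining[~ok]
        else:  # pragma: no cover - A <= 0.65 leaves >= 35% free area
            raise PlacementError("bulk-phase rejection sampling failed to converge")
    return out


def place_probes(
    config: DomainConfiguration,
    n_donors: int,
    n_acceptors: int,
    partition_donor: float = 1.0,
    partition_acceptor: float = 1.0,
    seed: int = 0,
    r_min_nm: float = 0.0,
    bilayer_separation_nm: float = 4.0,
) -> ProbeConfiguration:
    """Scatter donors and acceptors over the patch with phase partitioning.

    Each probe independently lands in the domain phase with probability
    ``p_in = K*A/(K*A + 1 - A)`` (A = realised covered fraction) and is
    placed uniformly within its phase.  Probes are split 50/50 between the
    two leaflets; domains are in register, so the same discs apply to both.
    When ``r_min_nm`` > 0, acceptors closer than ``r_min_nm`` (3-D distance,
    bilayer separation included) to any donor are resampled, emulating the
    probes' excluded volume.
    """
    if n_donors <= 0 or n_acceptors <= 0:
        raise ValueError("probe counts must be positive")
    rng = np.random.default_rng(seed)
    a = config.area_fraction
    p_d = partition_probability(partition_donor, a)
    p_a = partition_probability(partition_acceptor, a)

    d_in = rng.uniform(size=n_donors) < p_d
    a_in = rng.uniform(size=n_acceptors) < p_a
    donor_xy = _sample_phase_points(config, d_in, rng)
    acceptor_xy = _sample_phase_points(config, a_in, rng)

    def _half_split(n: int) -> np.ndarray:
        lab = np.zeros(n, dtype=np.int8)
        lab[n // 2:] = 1
        return lab[rng.permutation(n)]

    donor_leaflet = _half_split(n_donors)
    acceptor_leaflet = _half_split(n_acceptors)

    if r_min_nm > 0.0:
        dz = bilayer_separation_nm
        for _ in range(200):
            too_close = _acceptors_within(
                donor_xy, donor_leaflet, acceptor_xy, acceptor_leaflet,
                config.box_length_nm, dz, r_min_nm,
            )
            if not np.any(too_close):
                break
            n_bad = int(too_close.sum())
            a_in_bad = rng.uniform(size=n_bad) < p_a
            acceptor_xy[too_close] = _sample_phase_points(config, a_in_bad, rng)
            a_in[too_close] = a_in_bad
        else:
            raise PlacementError(
                "could not satisfy the donor-acceptor exclusion distance "
                f"r_min={r_min_nm} nm by resampling"
            )

    return ProbeConfiguration(
        donor_xy=donor_xy,
        donor_leaflet=donor_leaflet,
        donor_in_domain=config.contains(donor_xy),
        acceptor_xy=acceptor_xy,
        acceptor_leaflet=acceptor_leaflet,
        acceptor_in_domain=config.contains(acceptor_xy),
        box_length_nm=config.box_length_nm,
        bilayer_separation_nm=bilayer_separation_nm,
        domain_config=config,
    )


def _acceptors_within(
    donor_xy: np.ndarray,
    donor_leaflet: np.ndarray,
    acceptor_xy: np.ndarray,
    acceptor_leaflet: np.ndarray,
    box_length: float,
    dz: float,
    r_min: float,
) -> np.ndarray:
    """Mask of acceptors with 3-D distance < r_min to at least one donor."""
    mask = np.zeros(len(acceptor_xy), dtype=bool)
    d_tree = cKDTree(donor_xy % box_length, boxsize=box_length)
    a_tree = cKDTree(acceptor_xy % box_length, boxsize=box_length)
    # lateral prefilter at r_min (a cross-leaflet pair at lateral distance
    # <= r_min has 3-D distance >= dz, so it only matters when dz < r_min)
    pairs = a_tree.query_ball_tree(d_tree, r_min * (1.0 + 1e-12))
    for ia, donors in enumerate(pairs):
        if not donors:
            continue
        same = donor_leaflet[donors] == acceptor_leaflet[ia]
        if np.any(same):
            lat = _minimum_image(
                donor_xy[np.asarray(donors)[same]] - acceptor_xy[ia], box_length
            )
            if np.any(np.linalg.norm(lat, axis=1) < r_min):
                mask[ia] = True
                continue
        if dz < r_min and np.any(~same):
            lat = _minimum_image(
                donor_xy[np.asarray(donors)[~same]] - acceptor_xy[ia], box_length
            )
            d3 = np.sqrt(np.linalg.norm(lat, axis=1) ** 2 + dz**2)
            if np.any(d3 < r_min):
                mask[ia] = True
    return mask


def pair_distance(
    p_xy,
    p_leaflet: int,
    q_xy,
    q_leaflet: int,
    box_length: float,
    bilayer_separation: float,
) -> float:
    """Donor-acceptor distance with minimum image and leaflet offset.

    Lateral separation uses the minimum-image convention on the torus;
    probes on opposite leaflets add the bilayer separation in quadrature:
    ``d = sqrt(d_lat^2 + dz^2)``.
    """
    delta = _minimum_image(np.asarray(p_xy, float) - np.asarray(q_xy, float), box_length)
    d_lat2 = float(delta @ delta)
    if p_leaflet == q_leaflet:
        return float(np.sqrt(d_lat2))
    return float(np.sqrt(d_lat2 + bilayer_separation**2))


def coverage_estimate(config: DomainConfiguration, n_grid: int = 256) -> float:
    """Grid-sampled covered-area fraction (diagnostic; placement is exact)."""
    x = (np.arange(n_grid) + 0.5) * config.box_length_nm / n_grid
    gx, gy = np.meshgrid(x, x)
    pts = np.c_[gx.ravel(), gy.ravel()]
    return float(config.contains(pts).mean())
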