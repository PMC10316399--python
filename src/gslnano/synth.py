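"""Desk-scale synthetic inputs: TCSPC decay cohorts and membrane fixtures.

Two families of generators, both pure functions of (parameters, seed):

* Poisson photon-count TCSPC decays produced by the forward MC-FRET model,
  organised in cohorts of 5-10 GUVs per lipid composition with GUV-to-GUV
  variability in the generating nanodomain state — emulating the
  per-vesicle measurements the inverse analysis consumes.

* Small membrane coordinate fixtures with hydrogen bonds planted at ideal
  geometry, decoy pairs that must NOT be detected, and a topology with
  charges and Lennard-Jones parameters, so that every downstream table
  (bond counts per moiety, pair energies, water contacts) has an exactly
  known ground truth.  The fixture geometry is synthetic bookkeeping
  scaffolding, not a physical membrane structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fret import DecayCurve, FretParameters, default_time_grid, nanodomain_decay
from .hbond import (
    COULOMB_KJ_NM_E2,
    SPECIES_MOIETIES,
    MoietyMap,
    Topology,
)
from .inference import DEFAULT_PROBE_DENSITY, _box_length
from .membrane import DomainModel

__all__ = [
    "Scenario",
    "make_tcspc",
    "make_guv_cohort",
    "make_membrane_fixture",
    "FixtureError",
]


class FixtureError(ValueError):
    """Raised when a requested fixture cannot be packed into its box."""


@dataclass(frozen=True)
class Scenario:
    """One synthetic GUV cohort: composition label + generating domain state.

    Defaults encode the study conditions: cohorts of 8 vesicles (5-10 were
    imaged per composition), 1e5 photons per decay, 10% relative GUV-to-GUV
    spread on the radius and 0.05 absolute spread on the coverage
    (truncated at the physical bounds), probes at 0.5 mol% per species with
    a domain partition coefficient of 20 (the labelled ganglioside is itself
    the domain-forming species, so nearly all of it sits inside the domains).
    """

    label: str
    radius_nm: float
    area_fraction: float
    rel_sd_radius: float = 0.10
    sd_area: float = 0.05
    n_guvs: int = 8
    counts_per_decay: int = 100_000
    seed: int = 0
    background_fraction: float = 0.01
    probe_density_per_nm2: float = DEFAULT_PROBE_DENSITY
    partition_donor: float = 20.0
    partition_acceptor: float = 20.0
    bilayer_separation_nm: float = 4.0
    n_realizations: int = 8

    def __post_init__(self) -> None:
        if self.n_guvs < 1:
            raise ValueError("n_guvs must be >= 1")
        if self.counts_per_decay <= 0:
            raise ValueError("counts_per_decay must be positive")
        if self.rel_sd_radius < 0 or self.sd_area < 0:
            raise ValueError("variability must be >= 0")


def make_tcspc(
    model_decay: DecayCurve,
    total_counts: int,
    background_fraction: float = 0.0,
    seed: int = 0,
) -> DecayCurve:
    """Poissonian TCSPC measurement of a normalised model decay.

    Expected counts per channel are proportional to
    ``(1 - bf) * F_k / sum F + bf / n_channels`` scaled to ``total_counts``;
    each channel is drawn independently Poisson.  Deterministic given seed.
    """
    if model_decay.intensity is None:
        raise ValueError("make_tcspc needs a normalised model decay")
    if total_counts < 1:
        raise ValueError("total_counts must be >= 1")
    if background_fraction < 0:
        raise ValueError("background_fraction must be >= 0")
    rng = np.random.default_rng(seed)
    f = model_decay.intensity
    shape = (1.0 - background_fraction) * f / f.sum() + background_fraction / len(f)
    expected = total_counts * shape
    counts = rng.poisson(expected)
    return DecayCurve(
        time_ns=model_decay.time_ns,
        counts=counts,
        channel_width_ns=model_decay.channel_width_ns,
        metadata={
            **model_decay.metadata,
            "total_counts": int(total_counts),
            "background_fraction": float(background_fraction),
            "tcspc_seed": int(seed),
        },
    )


def make_guv_cohort(
    scenario: Scenario,
    params: FretParameters,
    time_grid: np.ndarray | None = None,
) -> tuple[list[DecayCurve], dict]:
    """Generate one decay per GUV plus a ground-truth manifest.

    Each GUV draws its own generating (R, A) — the scenario values jittered
    by the stated variability, truncated at the physical bounds — simulates
    the ensemble decay and converts it to Poisson photon counts.  The
    manifest records the per-GUV truth so recovery can be scored without
    re-reading generator internals.
    """
    if time_grid is None:
        time_grid = default_time_grid(params)
    decays: list[DecayCurve] = []
    guvs = []
    for g in range(scenario.n_guvs):
        ss = np.random.SeedSequence(scenario.seed, spawn_key=(g,))
        s_jit, s_sim, s_poi = (s & 0x7FFFFFFF for s in ss.generate_state(3))
        rng = np.random.default_rng(int(s_jit))
        if scenario.area_fraction > 0:
            r_true = scenario.radius_nm * max(
                0.2, 1.0 + scenario.rel_sd_radius * rng.standard_normal()
            )
            a_true = float(
                np.clip(
                    scenario.area_fraction + scenario.sd_area * rng.standard_normal(),
                    0.02,
                    0.65,
                )
            )
        else:
            r_true, a_true = scenario.radius_nm, 0.0
        box = _box_length(r_true if a_true > 0 else 0.0, params)
        model = DomainModel(
            radius_nm=r_true if a_true > 0 else 1.0,
            area_fraction=a_true,
            box_length_nm=box,
            bilayer_separation_nm=scenario.bilayer_separation_nm,
            partition_donor=scenario.partition_donor,
            partition_acceptor=scenario.partition_acceptor,
        )
        clean = nanodomain_decay(
            model,
            params,
            acceptor_density_per_leaflet_nm2=scenario.probe_density_per_nm2,
            n_configs=scenario.n_realizations,
            seed=int(s_sim),
            time_grid=time_grid,
        )
        measured = make_tcspc(
            clean,
            scenario.counts_per_decay,
            scenario.background_fraction,
            seed=int(s_poi),
        )
        guv_id = f"{scenario.label}-guv{g:02d}"
        measured.metadata["guv_id"] = guv_id
        decays.append(measured)
        guvs.append(
            {
                "guv_id": guv_id,
                "radius_true_nm": float(r_true),
                "area_true": float(a_true),
                "counts": int(measured.counts.sum()),
            }
        )
    manifest = {
        "label": scenario.label,
        "radius_nm": scenario.radius_nm,
        "area_fraction": scenario.area_fraction,
        "n_guvs": scenario.n_guvs,
        "seed": scenario.seed,
        "params": {
            "forster_radius_nm": params.forster_radius_nm,
            "donor_lifetime_ns": params.donor_lifetime_ns,
            "r_min_nm": params.r_min_nm,
        },
        "partition_donor": scenario.partition_donor,
        "partition_acceptor": scenario.partition_acceptor,
        "probe_density_per_nm2": scenario.probe_density_per_nm2,
        "bilayer_separation_nm": scenario.bilayer_separation_nm,
        "background_fraction": scenario.background_fraction,
        "guvs": guvs,
        "truth_mean_radius_nm": float(np.mean([g["radius_true_nm"] for g in guvs])),
        "truth_mean_area": float(np.mean([g["area_true"] for g in guvs])),
    }
    return decays, manifest


# ---------------------------------------------------------------------------
# membrane coordinate fixtures with planted hydrogen bonds
# ---------------------------------------------------------------------------

_CHARGE = {"O": -0.5, "H": 0.3, "C": 0.15, "N": -0.4}
_SIGMA = {"O": 0.30, "H": 0.10, "C": 0.34, "N": 0.325}
_EPSILON = {"O": 0.65, "H": 0.065, "C": 0.36, "N": 0.71}

_OO_BOND_NM = 0.28       # planted donor-acceptor distance (ideal geometry)
_OH_NM = 0.10            # donor-hydrogen distance
_SITE_SPACING_NM = 1.5   # spacing of bond sites; > cutoff + planted extent


class _FixtureBuilder:
    def __init__(self) -> None:
        self.pos: list[np.ndarray] = []
        self.element: list[str] = []
        self.mol: list[int] = []
        self.species: list[str] = []
        self.moiety: list[str] = []
        self.bonds: list[tuple[int, int]] = []

    def add(self, pos, element, mol, species, moiety) -> int:
        self.pos.append(np.asarray(pos, float))
        self.element.append(element)
        self.mol.append(mol)
        self.species.append(species)
        self.moiety.append(moiety)
        return len(self.pos) - 1


def _site_grid(n: int, box: np.ndarray, z: float, spacing: float, margin: float = 0.8):
    """n points on a square grid in the plane z=const; error if they don't fit."""
    per_row = int((box[0] - 2 * margin) // spacing) + 1
    n_rows = int(np.ceil(n / max(per_row, 1)))
    if per_row < 1 or margin + (n_rows - 1) * spacing > box[1] - margin:
        raise FixtureError(
            f"cannot pack {n} sites at {spacing} nm spacing into box {box[:2]}"
        )
    pts = []
    for k in range(n):
        i, j = divmod(k, per_row)
        pts.append(np.array([margin + j * spacing, margin + i * spacing, z]))
    return pts


def make_membrane_fixture(
    n_gsl: int,
    species: str,
    planted_bonds: list[tuple[str, str, int]],
    n_water: int = 0,
    box: float | np.ndarray = 12.0,
    seed: int = 0,
    n_decoys: int = 4,
) -> tuple[np.ndarray, Topology, MoietyMap, dict]:
    """Build a single-frame fixture with exactly known hydrogen bonds.

    ``planted_bonds`` lists ``(donor_moiety, acceptor_moiety, count)``; a
    moiety of ``"water"`` puts that end on a water molecule.  Every planted
    bond is an O-H...O triple at ideal geometry (O-O 0.28 nm, collinear);
    ``n_decoys`` additional donor/acceptor pairs violate either the distance
    (O-O 0.45 nm) or the angle (~90 deg) criterion and must not be detected.
    The returned ground truth lists the planted triples, the per-moiety-pair
    counts, and every molecule-pair energy within the 1.2 nm cutoff computed
    by direct all-pairs summation.

    The geometry is synthetic bookkeeping scaffolding: atoms of one GSL are
    scattered over bond sites and a backbone grid, not arranged as a lipid.
    """
    if species not in SPECIES_MOIETIES:
        raise ValueError(f"unknown GSL species {species!r}")
    allowed = set(SPECIES_MOIETIES[species]) | {"Cer", "water"}
    for m1, m2, cnt in planted_bonds:
        for m in (m1, m2):
            if m not in allowed:
                raise FixtureError(
                    f"moiety {m!r} not admissible for species {species}"
                )
        if cnt < 0:
            raise FixtureError("planted bond counts must be >= 0")
    gsl_gsl = [b for b in planted_bonds if "water" not in (b[0], b[1])]
    if gsl_gsl and n_gsl < 2:
        raise FixtureError("GSL-GSL bonds need at least 2 GSL molecules")
    if any("water" in (b[0], b[1]) for b in planted_bonds) and n_gsl < 1:
        raise FixtureError("GSL-water bonds need at least 1 GSL molecule")

    box = np.asarray(box, float) * np.ones(3) if np.ndim(box) == 0 else np.asarray(box, float)
    rng = np.random.default_rng(seed)
    b = _FixtureBuilder()
    z_mid = box[2] / 2.0

    n_sites = sum(c for _, _, c in planted_bonds) + n_decoys
    sites = _site_grid(max(n_sites, 1), box, z_mid, _SITE_SPACING_NM)
    site_iter = iter(sites)

    gsl_mols = list(range(n_gsl))
    next_mol = n_gsl

    planted_triples: list[tuple[int, int, int]] = []
    moiety_pair_counts: dict[tuple[str, str], int] = {}
    pair_cursor = 0

    def _new_water(o_pos: np.ndarray, h_dir: np.ndarray | None) -> tuple[int, int]:
        """Water molecule at o_pos; returns (mol_id, O index).

        ``h_dir`` — unit vector along which the *bonding* hydrogen points
        (donor water); None puts both hydrogens on the far side (acceptor
        water).
        """
        nonlocal next_mol
        mid = next_mol
        next_mol += 1
        o = b.add(o_pos, "O", mid, "water", "water")
        if h_dir is not None:
            h1 = b.add(o_pos + _OH_NM * h_dir, "H", mid, "water", "water")
            away = np.array([-h_dir[0], 0.6, 0.0])
            away /= np.linalg.norm(away)
            h2 = b.add(o_pos + _OH_NM * away, "H", mid, "water", "water")
        else:
            for dy in (0.06, -0.06):
                off = np.array([0.08, dy, 0.0])
                off /= np.linalg.norm(off) / _OH_NM
                b.bonds.append((o, b.add(o_pos + off, "H", mid, "water", "water")))
            return mid, o
        b.bonds.append((o, h1))
        b.bonds.append((o, h2))
        return mid, o

    ex = np.array([1.0, 0.0, 0.0])
    for m_don, m_acc, count in planted_bonds:
        for _ in range(count):
            site = next(site_iter)
            d_pos = site - 0.5 * _OO_BOND_NM * ex
            a_pos = site + 0.5 * _OO_BOND_NM * ex
            # donor end
            if m_don == "water":
                _, d_idx = _new_water(d_pos, h_dir=ex)
                h_idx = d_idx + 1
            else:
                mol_d = gsl_mols[pair_cursor % n_gsl]
                d_idx = b.add(d_pos, "O", mol_d, species, m_don)
                h_idx = b.add(d_pos + _OH_NM * ex, "H", mol_d, species, m_don)
                b.bonds.append((d_idx, h_idx))
            # acceptor end
            if m_acc == "water":
                _, a_idx = _new_water(a_pos, h_dir=None)
            else:
                mol_a = gsl_mols[(pair_cursor + 1) % n_gsl]
                a_idx = b.add(a_pos, "O", mol_a, species, m_acc)
            planted_triples.append((d_idx, h_idx, a_idx))
            key = (m_don, m_acc)
            moiety_pair_counts[key] = moiety_pair_counts.get(key, 0) + 1
            pair_cursor += 1

    # decoys: alternate distance violations and angle violations
    first_moiety = SPECIES_MOIETIES[species][0]
    for k in range(n_decoys):
        site = next(site_iter)
        mol_d = gsl_mols[k % n_gsl]
        mol_a = gsl_mols[(k + 1) % n_gsl] if n_gsl > 1 else mol_d
        if k % 2 == 0:  # beyond the distance cutoff (O-O 0.45 nm)
            d_idx = b.add(site - 0.225 * ex, "O", mol_d, species, first_moiety)
            h_idx = b.add(site - 0.125 * ex, "H", mol_d, species, first_moiety)
            a_idx = b.add(site + 0.225 * ex, "O", mol_a, species, first_moiety)
        else:  # inside the distance cutoff but H at ~90 deg
            d_idx = b.add(site - 0.15 * ex, "O", mol_d, species, first_moiety)
            h_idx = b.add(site - np.array([0.15, -0.10, 0.0]), "H", mol_d, species, first_moiety)
            a_idx = b.add(site + 0.15 * ex, "O", mol_a, species, first_moiety)
        b.bonds.append((d_idx, h_idx))

    # backbone carbons: one per moiety per GSL (completes the moiety map,
    # carbon cannot hydrogen bond); separate plane above the site plane
    backbone_moieties = SPECIES_MOIETIES[species] + ("Cer",)
    n_backbone = n_gsl * len(backbone_moieties)
    for i, pos in enumerate(_site_grid(n_backbone, box, z_mid + 1.0, 0.8)):
        g, m = divmod(i, len(backbone_moieties))
        b.add(pos, "C", gsl_mols[g], species, backbone_moieties[m])

    # free water, well away from everything (no accidental bonds)
    if n_water > 0:
        for pos in _site_grid(n_water, box, z_mid - 2.0, 0.6):
            _new_water(pos, h_dir=None)

    coords = np.array(b.pos)
    atoms = pd.DataFrame(
        {
            "element": b.element,
            "charge_e": [_CHARGE[e] for e in b.element],
            "sigma_nm": [_SIGMA[e] for e in b.element],
            "epsilon_kj_mol": [_EPSILON[e] for e in b.element],
            "mol_id": b.mol,
            "species": b.species,
        }
    )
    # neutralise each molecule exactly (keeps the integer-net-charge invariant)
    for mid, idx in atoms.groupby("mol_id").groups.items():
        net = atoms.loc[idx, "charge_e"].sum()
        atoms.loc[idx[0], "charge_e"] -= net
    topology = Topology(atoms=atoms, bonds=np.array(b.bonds).reshape(-1, 2))
    moiety_map = MoietyMap(labels=pd.Series(b.moiety))

    ground_truth = {
        "hbonds": [list(t) for t in planted_triples],
        "n_hbonds": len(planted_triples),
        "moiety_pair_counts": {f"{k[0]}|{k[1]}": v for k, v in moiety_pair_counts.items()},
        "pair_energies": _direct_pair_energies(coords, box, atoms, cutoff_nm=1.2),
        "n_gsl": n_gsl,
        "species": species,
        "seed": int(seed),
    }
    return coords, topology, moiety_map, ground_truth


def _direct_pair_energies(
    coords: np.ndarray, box: np.ndarray, atoms: pd.DataFrame, cutoff_nm: float
) -> dict[str, float]:
    """All intermolecular molecule-pair energies by direct O(N^2) summation.

    Independent of the analysis path (no neighbour search): plain broadcast
    of the Coulomb + Lennard-Jones pair formula under minimum image.
    """
    q = atoms["charge_e"].to_numpy()
    sig = atoms["sigma_nm"].to_numpy()
    eps = atoms["epsilon_kj_mol"].to_numpy()
    mol = atoms["mol_id"].to_numpy()
    delta = coords[:, None, :] - coords[None, :, :]
    delta -= box * np.round(delta / box)
    r = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))
    np.fill_diagonal(r, np.inf)
    sij = 0.5 * (sig[:, None] + sig[None, :])
    eij = np.sqrt(eps[:, None] * eps[None, :])
    with np.errstate(over="ignore"):
        sr6 = (sij / r) ** 6
        e = COULOMB_KJ_NM_E2 * q[:, None] * q[None, :] / r + 4.0 * eij * (sr6**2 - sr6)
    mask = (r <= cutoff_nm) & (mol[:, None] != mol[None, :])
    out: dict[str, float] = {}
    ii, jj = np.nonzero(mask)
    for i, j in zip(ii, jj):
        if mol[i] < mol[j]:
            key = f"{mol[i]}|{mol[j]}"
            out[key] = out.get(key, 0.0) + float(e[i, j])
    return out
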