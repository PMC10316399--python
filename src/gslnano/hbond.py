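"""Hydrogen-bond bookkeeping and pairwise interaction energies for membranes.

Operates on membrane configurations (coordinates in nm plus an orthorhombic
periodic box) described by a :class:`Topology` (elements, partial charges,
Lennard-Jones parameters, molecule ids, species) and a :class:`MoietyMap`
assigning each atom to a named sugar unit of the glycosphingolipid (GSL)
headgroup — Glc1, Gal2, Sia3, GalNAc4, Gal5, Sia6 — or to Cer, headgroup,
water or other.

The analyses mirror the standard questions asked of GSL bilayer simulations:
how many hydrogen bonds does each sugar moiety mediate between neighbouring
GSLs, how strongly does a GSL interact with its GSL/DOPC/SM/cholesterol
partners (totals and per-partner normalised values), how many bonds does the
headgroup make with water, and where along the membrane normal does each
moiety sit (partial density profiles).

Hydrogen bonds use the common geometric criterion: donor-acceptor distance
<= 0.35 nm and hydrogen-donor-acceptor angle <= 30 deg, both configurable.
Energies are plain-cutoff Coulomb + Lennard-Jones with Lorentz-Berthelot
combination rules; no reciprocal-space (Ewald) term, since a per-pair
decomposition is only well defined for direct-space interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Topology",
    "MoietyMap",
    "HBondCriterion",
    "HBondTable",
    "EnergyTable",
    "detect_hbonds",
    "moiety_hbond_table",
    "headgroup_water_hbonds",
    "pair_interaction_energy",
    "molecular_pair_energies",
    "energy_summary",
    "percent_energy_change",
    "density_profile",
]

#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_KJ_NM_E2 = 138.935458

SUGAR_MOIETIES = ("Glc1", "Gal2", "Sia3", "GalNAc4", "Gal5", "Sia6")
SIA_MOIETIES = ("Sia3", "Sia6")

#: sugar composition of the supported GSL species (innermost to terminal)
SPECIES_MOIETIES: dict[str, tuple[str, ...]] = {
    "GD1a": ("Glc1", "Gal2", "Sia3", "GalNAc4", "Gal5", "Sia6"),
    "GM1": ("Glc1", "Gal2", "Sia3", "GalNAc4", "Gal5"),
    "GM2": ("Glc1", "Gal2", "Sia3", "GalNAc4"),
    "GM3": ("Glc1", "Gal2", "Sia3"),
    "asialoGM1": ("Glc1", "Gal2", "GalNAc4", "Gal5"),
}

_NON_GSL_SPECIES = {"water", "DOPC", "SM", "Chol"}

ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06,
}


@dataclass
class Topology:
    """Per-atom force-field bookkeeping plus the intramolecular bond list.

    ``atoms`` columns: element, charge_e, sigma_nm, epsilon_kj_mol, mol_id,
    species.  ``bonds`` is an (n_bonds, 2) integer array of atom indices;
    bonds must connect atoms of the same molecule, and each molecule's net
    charge must be within 1e-6 e of an integer.
    """

    atoms: pd.DataFrame
    bonds: np.ndarray

    def __post_init__(self) -> None:
        required = {"element", "charge_e", "sigma_nm", "epsilon_kj_mol", "mol_id", "species"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise ValueError(f"topology atoms table lacks columns: {sorted(missing)}")
        self.atoms = self.atoms.reset_index(drop=True)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        mol = self.atoms["mol_id"].to_numpy()
        if len(self.bonds) and np.any(mol[self.bonds[:, 0]] != mol[self.bonds[:, 1]]):
            raise ValueError("bonds must connect atoms of the same molecule")
        net = self.atoms.groupby("mol_id")["charge_e"].sum()
        off = net[np.abs(net - np.round(net)) > 1e-6]
        if len(off):
            raise ValueError(
                f"non-integer net charge on molecule(s) {list(off.index[:5])}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def molecule_species(self) -> pd.Series:
        return self.atoms.groupby("mol_id")["species"].first()

    def bonded_hydrogens(self) -> dict[int, list[int]]:
        """heavy atom index -> indices of hydrogens bonded to it."""
        elements = self.atoms["element"].to_numpy()
        out: dict[int, list[int]] = {}
        seen_h: set[int] = set()
        for a, b in self.bonds:
            ea, eb = elements[a], elements[b]
            if ea == "H" and eb != "H":
                out.setdefault(int(b), []).append(int(a))
                seen_h.add(int(a))
            elif eb == "H" and ea != "H":
                out.setdefault(int(a), []).append(int(b))
                seen_h.add(int(b))
        orphan = set(np.flatnonzero(elements == "H")) - seen_h
        if orphan:
            raise ValueError(
                f"hydrogen atom {sorted(orphan)[0]} is not bonded to any heavy "
                "atom; donors cannot be resolved"
            )
        return out


@dataclass
class MoietyMap:
    """Atom index -> moiety label (sugar unit, Cer, headgroup, water, other)."""

    labels: pd.Series

    VALID = set(SUGAR_MOIETIES) | {"Cer", "headgroup", "water", "other"}

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels).reset_index(drop=True).astype(str)
        bad = set(self.labels.unique()) - self.VALID
        if bad:
            raise ValueError(f"unknown moiety label(s): {sorted(bad)}")

    def validate_against(self, topology: Topology) -> None:
        """Check labels are consistent with each molecule's species."""
        if len(self.labels) != topology.n_atoms:
            raise ValueError("moiety map length does not match topology")
        species = topology.atoms["species"].to_numpy()
        labels = self.labels.to_numpy()
        for sp, allowed in SPECIES_MOIETIES.items():
            mask = species == sp
            ok = set(allowed) | {"Cer", "headgroup", "other"}
            bad = set(labels[mask]) - ok
            if bad:
                raise ValueError(
                    f"moiety label(s) {sorted(bad)} not admissible on species {sp}"
                )
        if np.any((species == "water") & (labels != "water")):
            raise ValueError("water atoms must carry the 'water' moiety label")

    def headgroup_mask(self) -> np.ndarray:
        """Sugar-headgroup atoms: union of the sugar moieties (+ 'headgroup')."""
        return self.labels.isin(set(SUGAR_MOIETIES) | {"headgroup"}).to_numpy()


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition (distance + angle at the donor)."""

    max_donor_acceptor_nm: float = 0.35
    max_angle_deg: float = 30.0
    donor_elements: tuple[str, ...] = ("N", "O")
    acceptor_elements: tuple[str, ...] = ("N", "O")

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_nm <= 0:
            raise ValueError("max_donor_acceptor_nm must be > 0")
        if not (0 < self.max_angle_deg <= 90):
            raise ValueError("max_angle_deg must lie in (0, 90]")


@dataclass(frozen=True)
class HBondTable:
    """Per species x moiety hydrogen-bond averages (bonds per GSL molecule)."""

    mean: pd.DataFrame     # species x moiety
    se: pd.DataFrame       # block standard errors, same shape
    total: pd.Series       # per species; equals mean.sum(axis=1) pre-rounding
    sm_sm: float           # SM-SM bonds per SM molecule (NaN if no SM)
    n_frames: int
    criterion: HBondCriterion


@dataclass(frozen=True)
class EnergyTable:
    """Per pair-class totals and per-partner normalised interaction energies."""

    table: pd.DataFrame  # index: pair class; columns: total_kj_mol, n_partners, normalized_kj_mol
    cutoff_nm: float
    partner_min_fraction: float


def _wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.mod(coords, box)


def _min_image_vec(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def detect_hbonds(
    coords: np.ndarray,
    box: np.ndarray,
    topology: Topology,
    criterion: HBondCriterion | None = None,
    exclude_intramolecular: bool = True,
) -> np.ndarray:
    """All (donor, hydrogen, acceptor) triples satisfying the criterion.

    Donors are N/O atoms carrying at least one bonded hydrogen; acceptors
    are N/O atoms.  Neighbour search is a periodic k-d tree under the
    minimum-image convention.  Returns an (n, 3) integer array sorted by
    (donor, hydrogen, acceptor).
    """
    if criterion is None:
        criterion = HBondCriterion()
    coords = np.asarray(coords, float)
    if coords.shape != (topology.n_atoms, 3):
        raise ValueError("frame does not match topology atom count")
    box = np.asarray(box, float)
    elements = topology.atoms["element"].to_numpy()
    mol = topology.atoms["mol_id"].to_numpy()
    donor_h = topology.bonded_hydrogens()
    donors = [a for a in donor_h if elements[a] in criterion.donor_elements]
    acceptors = np.flatnonzero(np.isin(elements, criterion.acceptor_elements))
    if not donors or len(acceptors) == 0:
        return np.empty((0, 3), dtype=int)

    wrapped = _wrap(coords, box)
    tree = cKDTree(wrapped[acceptors], boxsize=box)
    cos_max = np.cos(np.deg2rad(criterion.max_angle_deg))
    found: list[tuple[int, int, int]] = []
    neigh = tree.query_ball_point(
        wrapped[donors], criterion.max_donor_acceptor_nm * (1 + 1e-12)
    )
    for d, idx in zip(donors, neigh):
        if not idx:
            continue
        acc = acceptors[np.asarray(idx)]
        acc = acc[acc != d]
        if exclude_intramolecular:
            acc = acc[mol[acc] != mol[d]]
        if len(acc) == 0:
            continue
        da = _min_image_vec(coords[acc] - coords[d], box)
        da_norm = np.linalg.norm(da, axis=1)
        keep = da_norm <= criterion.max_donor_acceptor_nm * (1 + 1e-12)
        acc, da, da_norm = acc[keep], da[keep], da_norm[keep]
        for h in donor_h[d]:
            dh = _min_image_vec(coords[h] - coords[d], box)
            dh_norm = np.linalg.norm(dh)
            if dh_norm == 0:
                continue
            cosang = (da @ dh) / (da_norm * dh_norm)
            for a, c in zip(acc, cosang):
                if a != h and c >= cos_max - 1e-12:
                    found.append((int(d), int(h), int(a)))
    if not found:
        return np.empty((0, 3), dtype=int)
    out = np.array(sorted(found), dtype=int)
    return out


def _block_se(per_frame: np.ndarray, block_count: int) -> np.ndarray:
    """SE of the mean from contiguous block averages along axis 0."""
    per_frame = np.atleast_2d(np.asarray(per_frame, float))
    n = per_frame.shape[0]
    block_count = max(1, min(block_count, n))
    if block_count == 1:
        return np.zeros(per_frame.shape[1])
    edges = np.linspace(0, n, block_count + 1).astype(int)
    blocks = np.array(
        [per_frame[lo:hi].mean(axis=0) for lo, hi in zip(edges[:-1], edges[1:])]
    )
    return blocks.std(axis=0, ddof=1) / np.sqrt(block_count)


def _gsl_species_of(topology: Topology, gsl_species) -> list[str]:
    if gsl_species is not None:
        return list(gsl_species)
    present = set(topology.atoms["species"].unique())
    return sorted(present - _NON_GSL_SPECIES)


def moiety_hbond_table(
    frames: np.ndarray,
    box: np.ndarray,
    topology: Topology,
    moiety_map: MoietyMap,
    criterion: HBondCriterion | None = None,
    block_count: int = 5,
    gsl_species: list[str] | None = None,
) -> HBondTable:
    """Average GSL-GSL hydrogen bonds per GSL molecule, split by sugar moiety.

    Each intermolecular GSL-GSL bond contributes 0.5 to the moiety of its
    donor atom and 0.5 to the moiety of its acceptor atom, so the moiety
    columns sum exactly to the total bonds per molecule.  Standard errors
    come from block averaging over ``block_count`` contiguous frame blocks.
    The SM-SM bond count per SM molecule is reported alongside as the
    sphingomyelin reference.
    """
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    species_by_mol = topology.molecule_species()
    gsls = _gsl_species_of(topology, gsl_species)
    if not gsls:
        raise ValueError("no GSL molecules in the topology")
    mol = topology.atoms["mol_id"].to_numpy()
    atom_species = topology.atoms["species"].to_numpy()
    labels = moiety_map.labels.to_numpy()
    n_mol_per_species = {
        sp: int((species_by_mol == sp).sum()) for sp in gsls + ["SM"]
    }

    moieties = [m for m in SUGAR_MOIETIES + ("Cer", "headgroup", "other")]
    per_frame = {sp: np.zeros((len(frames), len(moieties))) for sp in gsls}
    sm_per_frame = np.zeros(len(frames))
    m_index = {m: i for i, m in enumerate(moieties)}

    for f, frame in enumerate(frames):
        bonds = detect_hbonds(frame, box, topology, criterion, exclude_intramolecular=True)
        for d, _h, a in bonds:
            sp_d, sp_a = atom_species[d], atom_species[a]
            if sp_d in gsls and sp_a in gsls:
                per_frame[sp_d][f, m_index[labels[d]]] += 0.5
                per_frame[sp_a][f, m_index[labels[a]]] += 0.5
            elif sp_d == "SM" and sp_a == "SM":
                sm_per_frame[f] += 1.0

    mean_rows, se_rows = {}, {}
    for sp in gsls:
        per_mol = per_frame[sp] / max(n_mol_per_species[sp], 1)
        mean_rows[sp] = per_mol.mean(axis=0)
        se_rows[sp] = _block_se(per_mol, block_count)
    mean = pd.DataFrame(mean_rows, index=moieties).T
    se = pd.DataFrame(se_rows, index=moieties).T
    sm_n = n_mol_per_species.get("SM", 0)
    sm_sm = float(sm_per_frame.mean() / sm_n) if sm_n else float("nan")
    return HBondTable(
        mean=mean,
        se=se,
        total=mean.sum(axis=1),
        sm_sm=sm_sm,
        n_frames=len(frames),
        criterion=criterion or HBondCriterion(),
    )


def headgroup_water_hbonds(
    frames: np.ndarray,
    box: np.ndarray,
    topology: Topology,
    moiety_map: MoietyMap,
    criterion: HBondCriterion | None = None,
    mode: str = "nanodomain",
    isolated_mol_id: int | None = None,
    block_count: int = 5,
    gsl_species: list[str] | None = None,
) -> pd.DataFrame:
    """Headgroup-water hydrogen bonds per GSL molecule, with the Sia share.

    Counts bonds between sugar-headgroup atoms and water (either donation
    direction); for each species reports the headgroup total and each sialic
    moiety's count together with its percentage of the headgroup total.
    ``mode='nanodomain'`` averages over all GSL molecules; ``mode='isolated'``
    restricts the count to one designated molecule (``isolated_mol_id``).
    With no water present, counts are zero and fractions are reported as
    missing (NaN).
    """
    if mode not in ("nanodomain", "isolated"):
        raise ValueError("mode must be 'nanodomain' or 'isolated'")
    if mode == "isolated" and isolated_mol_id is None:
        raise ValueError("isolated mode requires a designated molecule id")
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    gsls = _gsl_species_of(topology, gsl_species)
    atom_species = topology.atoms["species"].to_numpy()
    mol = topology.atoms["mol_id"].to_numpy()
    labels = moiety_map.labels.to_numpy()
    head = moiety_map.headgroup_mask()
    species_by_mol = topology.molecule_species()

    if mode == "isolated":
        denom = {sp: (1 if species_by_mol.get(isolated_mol_id) == sp else 0) for sp in gsls}
    else:
        denom = {sp: int((species_by_mol == sp).sum()) for sp in gsls}

    keys = [(sp, m) for sp in gsls for m in ("headgroup",) + SIA_MOIETIES]
    k_index = {k: i for i, k in enumerate(keys)}
    per_frame = np.zeros((len(frames), len(keys)))
    for f, frame in enumerate(frames):
        bonds = detect_hbonds(frame, box, topology, criterion, exclude_intramolecular=True)
        for d, _h, a in bonds:
            for g_end, w_end in ((d, a), (a, d)):
                if atom_species[w_end] == "water" and head[g_end]:
                    sp = atom_species[g_end]
                    if sp not in gsls:
                        continue
                    if mode == "isolated" and mol[g_end] != isolated_mol_id:
                        continue
                    per_frame[f, k_index[(sp, "headgroup")]] += 1.0
                    if labels[g_end] in SIA_MOIETIES:
                        per_frame[f, k_index[(sp, labels[g_end])]] += 1.0
    rows = []
    se_all = _block_se(per_frame, block_count)
    for sp in gsls:
        if denom[sp] == 0:
            continue
        hg = per_frame[:, k_index[(sp, "headgroup")]].mean() / denom[sp]
        hg_se = se_all[k_index[(sp, "headgroup")]] / denom[sp]
        rows.append(
            {"species": sp, "moiety": "headgroup", "bonds_per_gsl": hg,
             "se": hg_se, "sia_fraction_pct": float("nan")}
        )
        for m in SIA_MOIETIES:
            if m not in SPECIES_MOIETIES.get(sp, SUGAR_MOIETIES):
                continue
            v = per_frame[:, k_index[(sp, m)]].mean() / denom[sp]
            frac = 100.0 * v / hg if hg > 0 else float("nan")
            rows.append(
                {"species": sp, "moiety": m, "bonds_per_gsl": v,
                 "se": se_all[k_index[(sp, m)]] / denom[sp],
                 "sia_fraction_pct": frac}
            )
    return pd.DataFrame(rows)


def sia_fraction_percent(sia_bonds: float, headgroup_bonds: float) -> float:
    """Share (%) of headgroup-water bonds mediated by one sialic moiety."""
    if headgroup_bonds <= 0:
        raise ValueError("headgroup bond count must be positive")
    return 100.0 * sia_bonds / headgroup_bonds


def pair_interaction_energy(
    coords: np.ndarray,
    box: np.ndarray,
    topology: Topology,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff_nm: float = 1.2,
) -> float:
    """Coulomb + Lennard-Jones energy (kJ/mol) between two disjoint groups.

    E = sum over cross pairs within the cutoff of
    f q_i q_j / r + 4 eps_ij [(sig_ij/r)^12 - (sig_ij/r)^6], with
    Lorentz-Berthelot combination rules, plain cutoff and minimum image.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")
    coords = np.asarray(coords, float)
    box = np.asarray(box, float)
    q = topology.atoms["charge_e"].to_numpy()
    sig = topology.atoms["sigma_nm"].to_numpy()
    eps = topology.atoms["epsilon_kj_mol"].to_numpy()

    wrapped = _wrap(coords, box)
    tree_b = cKDTree(wrapped[group_b], boxsize=box)
    neigh = tree_b.query_ball_point(wrapped[group_a], cutoff_nm)
    e_total = 0.0
    for ia, idx in zip(group_a, neigh):
        if not idx:
            continue
        jb = group_b[np.asarray(idx)]
        delta = _min_image_vec(coords[jb] - coords[ia], box)
        r = np.linalg.norm(delta, axis=1)
        keep = r <= cutoff_nm
        jb, r = jb[keep], r[keep]
        if np.any(r < 1e-3):
            raise ValueError(
                f"overlapping atoms (r < 1e-3 nm) between atom {ia} and "
                f"atom {jb[np.argmin(r)]}"
            )
        sij = 0.5 * (sig[ia] + sig[jb])
        eij = np.sqrt(eps[ia] * eps[jb])
        sr6 = (sij / r) ** 6
        e_total += float(
            np.sum(COULOMB_KJ_NM_E2 * q[ia] * q[jb] / r + 4.0 * eij * (sr6**2 - sr6))
        )
    return e_total


def molecular_pair_energies(
    frames: np.ndarray,
    box: np.ndarray,
    topology: Topology,
    cutoff_nm: float = 1.2,
    gsl_species: list[str] | None = None,
    moiety_map: MoietyMap | None = None,
    gsl_side: str = "molecule",
) -> pd.DataFrame:
    """Frame-averaged GSL-partner energies and contact fractions.

    One row per (GSL molecule, partner molecule) pair that comes within the
    cutoff in at least one frame.  ``gsl_side='headgroup'`` restricts the
    GSL side to sugar-headgroup atoms (requires ``moiety_map``);
    ``'molecule'`` uses all atoms.  The partner side always uses whole
    molecules.
    """
    if gsl_side not in ("molecule", "headgroup"):
        raise ValueError("gsl_side must be 'molecule' or 'headgroup'")
    if gsl_side == "headgroup" and moiety_map is None:
        raise ValueError("gsl_side='headgroup' requires a moiety map")
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    mol = topology.atoms["mol_id"].to_numpy()
    species_by_mol = topology.molecule_species()
    gsls = _gsl_species_of(topology, gsl_species)
    gsl_mols = species_by_mol.index[species_by_mol.isin(gsls)].to_numpy()
    records: dict[tuple[int, int], dict] = {}
    for frame in frames:
        for g in gsl_mols:
            sel = mol == g
            if gsl_side == "headgroup":
                sel = sel & moiety_map.headgroup_mask()
            g_idx = np.flatnonzero(sel)
            other_idx = np.flatnonzero(mol != g)
            # contact + energy per partner molecule
            wrapped = _wrap(frame, box)
            tree = cKDTree(wrapped[other_idx], boxsize=np.asarray(box, float))
            neigh = tree.query_ball_point(wrapped[g_idx], cutoff_nm)
            partner_atoms: dict[int, list[tuple[int, np.ndarray]]] = {}
            e_by_partner: dict[int, float] = {}
            q = topology.atoms["charge_e"].to_numpy()
            sig = topology.atoms["sigma_nm"].to_numpy()
            eps = topology.atoms["epsilon_kj_mol"].to_numpy()
            for ia, idx in zip(g_idx, neigh):
                if not idx:
                    continue
                jb = other_idx[np.asarray(idx)]
                delta = _min_image_vec(frame[jb] - frame[ia], np.asarray(box, float))
                r = np.linalg.norm(delta, axis=1)
                keep = r <= cutoff_nm
                jb, r = jb[keep], r[keep]
                if np.any(r < 1e-3):
                    raise ValueError("overlapping atoms in energy evaluation")
                sij = 0.5 * (sig[ia] + sig[jb])
                eij = np.sqrt(eps[ia] * eps[jb])
                sr6 = (sij / r) ** 6
                e = COULOMB_KJ_NM_E2 * q[ia] * q[jb] / r + 4.0 * eij * (sr6**2 - sr6)
                for pm in np.unique(mol[jb]):
                    e_by_partner[pm] = e_by_partner.get(pm, 0.0) + float(
                        e[mol[jb] == pm].sum()
                    )
            for pm, e in e_by_partner.items():
                key = (int(g), int(pm))
                rec = records.setdefault(
                    key,
                    {
                        "gsl_mol": int(g),
                        "partner_mol": int(pm),
                        "gsl_species": species_by_mol[g],
                        "partner_species": species_by_mol[pm],
                        "frames_in_contact": 0,
                        "energy_sum": 0.0,
                    },
                )
                rec["frames_in_contact"] += 1
                rec["energy_sum"] += e
    rows = []
    for rec in records.values():
        rows.append(
            {
                **{k: rec[k] for k in ("gsl_mol", "partner_mol", "gsl_species", "partner_species")},
                "contact_fraction": rec["frames_in_contact"] / len(frames),
                "mean_energy_kj_mol": rec["energy_sum"] / len(frames),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gsl_mol", "partner_mol", "gsl_species", "partner_species",
            "contact_fraction", "mean_energy_kj_mol",
        ],
    )


def energy_summary(
    pair_energies: pd.DataFrame,
    partner_min_fraction: float = 0.5,
    cutoff_nm: float = 1.2,
) -> EnergyTable:
    """Aggregate per-pair energies into per-class totals and normalised values.

    An "interacting partner" is a molecule in contact (>= 1 atom pair within
    the cutoff) in at least ``partner_min_fraction`` of the frames.  Classes
    are GSL/GSL (partner is any GSL species) and GSL/<species> for bulk
    lipids.  ``normalized = total / partner count`` exactly; classes with no
    partner report a missing (NaN) normalised value.
    """
    if pair_energies.empty:
        raise ValueError("no pair energies supplied")
    df = pair_energies[pair_energies["contact_fraction"] >= partner_min_fraction]
    gsl_species = set(pair_energies["gsl_species"].unique())
    n_gsl = pair_energies["gsl_mol"].nunique()

    def _pair_class(partner_species: str) -> str:
        return "GSL/GSL" if partner_species in gsl_species else f"GSL/{partner_species}"

    classes = sorted({_pair_class(s) for s in pair_energies["partner_species"].unique()})
    rows = {}
    for cls in classes:
        sub = df[df["partner_species"].map(_pair_class) == cls]
        total = sub["mean_energy_kj_mol"].sum() / n_gsl
        n_partners = len(sub) / n_gsl
        rows[cls] = {
            "total_kj_mol": total,
            "n_partners": n_partners,
            "normalized_kj_mol": total / n_partners if n_partners > 0 else float("nan"),
        }
    return EnergyTable(
        table=pd.DataFrame(rows).T,
        cutoff_nm=cutoff_nm,
        partner_min_fraction=partner_min_fraction,
    )


def percent_energy_change(e_ref: float, e_new: float) -> float:
    """Percent increase in interaction-energy magnitude, 100(|E_new|-|E_ref|)/|E_ref|.

    Returned unrounded; report layers round to the nearest integer.
    """
    if e_ref == 0:
        raise ValueError("reference energy must be nonzero")
    return 100.0 * (abs(e_new) - abs(e_ref)) / abs(e_ref)


def density_profile(
    frames: np.ndarray,
    box: np.ndarray,
    selection: np.ndarray,
    axis: str = "z",
    n_bins: int = 100,
    weights: str = "number",
    normalization: str = "peak",
    topology: Topology | None = None,
) -> pd.DataFrame:
    """Partial density of a selection along one box axis, frame averaged.

    ``weights='number'`` counts atoms; ``'mass'`` weighs by atomic mass
    (requires ``topology``).  The un-normalised profile is a linear density
    (per nm) whose integral over the axis recovers the selection's
    count/mass per frame; ``normalization='peak'`` rescales to unit maximum.
    """
    if axis not in ("x", "y", "z"):
        raise ValueError("axis must be one of x, y, z")
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    if normalization not in ("peak", "none"):
        raise ValueError("normalization must be 'peak' or 'none'")
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    ax = "xyz".index(axis)
    length = float(np.asarray(box, float)[ax])
    edges = np.linspace(0.0, length, n_bins + 1)
    width = edges[1] - edges[0]
    if weights == "mass":
        if topology is None:
            raise ValueError("mass weighting requires a topology")
        w = topology.atoms["element"].map(ATOMIC_MASS).to_numpy()[selection]
    elif weights == "number":
        w = np.ones(selection.size)
    else:
        raise ValueError("weights must be 'number' or 'mass'")
    hist = np.zeros(n_bins)
    for frame in frames:
        x = np.mod(frame[selection, ax], length)
        h, _ = np.histogram(x, bins=edges, weights=w)
        hist += h
    profile = hist / len(frames) / width
    if normalization == "peak" and profile.max() > 0:
        profile = profile / profile.max()
    return pd.DataFrame(
        {
            "bin_center_nm": 0.5 * (edges[:-1] + edges[1:]),
            "density": profile,
        }
    )
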