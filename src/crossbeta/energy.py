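"""MM/GB-SA-style interface interaction energies and growth-mode analysis.

The interaction energy of two halves of an oligomer is
E_int = [E_MM + G_GB + gamma * SASA](complex) - (part A) - (part B),
with E_MM the Coulomb + Lennard-Jones molecular-mechanics energy, G_GB the
generalized-Born polar solvation free energy (OBC-II effective radii:
pairwise descreening with tanh rescaling), and a surface-area nonpolar
term.  Negative values are stabilizing.  Two segmentation planes define
the two growth modes: *elongation* splits a single-layer protofilament at
its longitudinal midpoint, *thickening* splits a protofilament pair into
its two layers across the CC-interface.  The crossover analysis locates
the oligomer size at which thickening overtakes elongation.

The packaged per-atom parameter table is a minimal, redistributable set
for the reduced atom representation (charges summing to the per-residue
formal charges, generic LJ well depths and Born radii by element); it is
deliberately not a biomolecular force field, and absolute energies are not
comparable to force-field MM/GBSA values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .model import (
    Assembly,
    Ensemble,
    ValidationError,
)

COULOMB_K = 332.0636  # kcal/mol * A / e^2

#: Backbone / generic partial charges (e); each plain residue sums to 0.
#: Moderate amide dipoles keep the GB desolvation penalty of burying the
#: one-atom-thick sheet faces commensurate with the united-atom dispersion
#: that stands in for full side-chain packing.
_BACKBONE_CHARGE = {"N": -0.40, "H": 0.30, "CA": 0.10, "C": 0.50,
                    "O": -0.50, "CB": 0.0, "CH3": 0.0, "SCT": 0.0}
#: Formal-charge carriers of the reduced representation, by (seq, atom).
_SPECIAL_CHARGE = {
    (11, "CB"): -1.0,   # E11 carboxylate (tip not modelled)
    (16, "CB"): +1.0,   # K16 ammonium (tip not modelled)
    (22, "CB"): -1.0,   # E22 carboxylate
    (23, "CG"): +0.30,  # D23 carboxylate, explicit tip
    (23, "OD1"): -0.65,
    (23, "OD2"): -0.65,
    (28, "NZ"): +1.0,   # K28 ammonium, explicit tip
    (42, "O"): -0.75,   # free C-terminal carboxylate, split over O/OXT
    (42, "OXT"): -0.75,
}

#: Lennard-Jones (sigma A, epsilon kcal/mol) by element.
_LJ_BY_ELEMENT = {"C": (3.40, 0.086), "N": (3.25, 0.170),
                  "O": (2.96, 0.210), "H": (1.07, 0.0157)}
#: United-atom wells: CB and the SCT pseudo-atom each absorb a whole side
#: chain's dispersion (residue-level contact wells, not atomic epsilons).
_LJ_BY_NAME = {"CB": (3.90, 0.35), "SCT": (3.60, 2.20)}

#: Intrinsic Born/SASA radii (A) by element.
_RADIUS_BY_ELEMENT = {"C": 1.70, "N": 1.55, "O": 1.50, "H": 1.20}
_RADIUS_PSEUDO = 2.20


@dataclass
class ParamSet:
    """Energetic model parameters.

    ``dielectric_solute``/``dielectric_solvent`` are the GB interior and
    exterior dielectrics; ``gamma_sasa`` (kcal/(mol*A^2)) scales the
    nonpolar surface term; ``obc_params`` are the OBC-II tanh-rescaling
    coefficients (alpha, beta, gamma) with the standard 0.09 A radius
    offset; ``screen`` is the universal descreening scale.
    """

    dielectric_solute: float = 1.0
    dielectric_solvent: float = 78.5
    gamma_sasa: float = 0.0072
    obc_params: tuple[float, float, float] = (1.0, 0.8, 4.85)
    gb_offset: float = 0.09
    screen: float = 0.8
    salt_conc_m: float = 0.15
    sasa_probe: float = 1.4
    sasa_points: int = 960

    @property
    def kappa(self) -> float:
        """Debye screening constant (1/A) at the configured monovalent
        salt concentration, with the customary 0.73 empirical scaling of
        salt-dependent GB."""
        if self.salt_conc_m <= 0:
            return 0.0
        return 0.73 * np.sqrt(self.salt_conc_m) / 3.04

    def validate(self) -> None:
        if self.dielectric_solute < 1 or self.dielectric_solvent < 1:
            raise ValidationError("dielectrics must be >= 1")
        if self.salt_conc_m < 0:
            raise ValidationError("salt concentration must be >= 0")


def assign_params(assembly: Assembly,
                  params: Optional[ParamSet] = None) -> Assembly:
    """Assign partial charges, LJ parameters and intrinsic radii in place.

    Every atom must resolve against the packaged table; per-chain charges
    sum to the chain formal charge (-2 e).  Returns the same assembly.
    """
    params = params or ParamSet()
    params.validate()
    for _li, _chain, res, atom in assembly.iter_atoms():
        key = (res.seq_index, atom.name)
        if key in _SPECIAL_CHARGE:
            atom.partial_charge = _SPECIAL_CHARGE[key]
        elif atom.name in _BACKBONE_CHARGE:
            atom.partial_charge = _BACKBONE_CHARGE[atom.name]
        else:
            raise ValidationError(
                f"unparametrized atom {atom.name!r} in residue "
                f"{res.aa_code}{res.seq_index}")
        if atom.name in _LJ_BY_NAME:
            atom.lj_params = _LJ_BY_NAME[atom.name]
            atom.radius = (_RADIUS_PSEUDO if atom.name == "SCT"
                           else _RADIUS_BY_ELEMENT.get(atom.element, 1.7))
        else:
            if atom.element not in _LJ_BY_ELEMENT:
                raise ValidationError(
                    f"no LJ parameters for element {atom.element!r} "
                    f"(atom {atom.name})")
            atom.lj_params = _LJ_BY_ELEMENT[atom.element]
            atom.radius = _RADIUS_BY_ELEMENT[atom.element]
    return assembly


def _atom_arrays(assembly: Assembly,
                 chain_ids: Optional[Iterable[str]] = None):
    """(coords, q, sigma, eps, radius) arrays for a chain subset."""
    wanted = set(chain_ids) if chain_ids is not None else None
    coords, q, sig, eps, rad = [], [], [], [], []
    for _li, chain, res, atom in assembly.iter_atoms():
        if wanted is not None and chain.chain_id not in wanted:
            continue
        if atom.partial_charge is None or atom.lj_params is None \
                or atom.radius is None:
            raise ValidationError(
                "atoms are unparametrized; call assign_params first")
        coords.append(atom.coord)
        q.append(atom.partial_charge)
        sig.append(atom.lj_params[0])
        eps.append(atom.lj_params[1])
        rad.append(atom.radius)
    if not coords:
        raise ValidationError("chain selection matches no atoms")
    return (np.array(coords), np.array(q), np.array(sig),
            np.array(eps), np.array(rad))


def mm_energy(assembly: Assembly, part_a: Sequence[str],
              part_b: Sequence[str],
              block: int = 2000) -> tuple[float, float]:
    """Cross-part molecular-mechanics energies (kcal/mol).

    Coulomb 332.0636 q_i q_j / r and LJ 4 eps [(sig/r)^12 - (sig/r)^6]
    with Lorentz-Berthelot combination, summed over all atom pairs with
    one atom in each part; no cutoff (finite systems).
    """
    xa, qa, sa, ea, _ = _atom_arrays(assembly, part_a)
    xb, qb, sb, eb, _ = _atom_arrays(assembly, part_b)
    e_coul = 0.0
    e_lj = 0.0
    for i0 in range(0, len(xa), block):
        i1 = min(i0 + block, len(xa))
        r = cdist(xa[i0:i1], xb)
        if (r < 0.1).any():
            ii, jj = np.argwhere(r < 0.1)[0]
            raise ValidationError(
                f"near-singular atom pair at r={r[ii, jj]:.3f} A "
                f"(part A atom {i0 + ii}, part B atom {jj})")
        e_coul += COULOMB_K * (qa[i0:i1, None] * qb[None, :] / r).sum()
        sig = 0.5 * (sa[i0:i1, None] + sb[None, :])
        eps = np.sqrt(ea[i0:i1, None] * eb[None, :])
        x6 = (sig / r) ** 6
        e_lj += (4.0 * eps * (x6 ** 2 - x6)).sum()
    return float(e_coul), float(e_lj)


def effective_born_radii(coords: np.ndarray, radii: np.ndarray,
                         params: Optional[ParamSet] = None,
                         block: int = 512) -> np.ndarray:
    """OBC-II effective Born radii.

    Pairwise HCT descreening integrals with a universal screening factor,
    rescaled through the OBC tanh function with coefficients
    (alpha, beta, gamma) = (1.0, 0.8, 4.85) and intrinsic radii reduced by
    the 0.09 A offset.
    """
    params = params or ParamSet()
    rho = radii - params.gb_offset
    if (rho <= 0).any():
        bad = int(np.argmax(rho <= 0))
        raise ValidationError(
            f"atom {bad}: intrinsic radius {radii[bad]:.2f} A does not "
            f"exceed the GB offset")
    rho_s = params.screen * rho
    n = len(coords)
    integral = np.zeros(n)
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        r = cdist(coords[i0:i1], coords)
        rho_i = rho[i0:i1, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = r + rho_s[None, :]
            l = np.maximum(np.abs(r - rho_s[None, :]), rho_i)
            term = 0.5 * (1.0 / l - 1.0 / u
                          + (rho_s[None, :] ** 2 - r ** 2) / (4.0 * r)
                          * (1.0 / l ** 2 - 1.0 / u ** 2)
                          + np.log(l / u) / (2.0 * r))
            # engulfed-donor correction: atom i inside neighbor's sphere
            engulfed = rho_i < (rho_s[None, :] - r)
            term = term + np.where(engulfed, 2.0 * (1.0 / rho_i - 1.0 / l),
                                   0.0)
        term[u <= rho_i] = 0.0  # neighbor buried inside atom i
        idx = np.arange(i0, i1)
        term[idx - i0, idx] = 0.0  # no self-descreening
        integral[i0:i1] = np.nansum(term, axis=1)
    psi = integral * rho
    alpha, beta, gamma = params.obc_params
    scale = np.tanh(alpha * psi - beta * psi ** 2 + gamma * psi ** 3)
    inv_reff = 1.0 / rho - scale / radii
    if (inv_reff <= 0).any():
        bad = int(np.argmax(inv_reff <= 0))
        raise ValidationError(
            f"non-positive effective Born radius for atom {bad}")
    return 1.0 / inv_reff


def gb_polar_energy(assembly: Assembly,
                    chain_ids: Optional[Iterable[str]] = None,
                    params: Optional[ParamSet] = None,
                    block: int = 512) -> float:
    """Generalized-Born polar solvation free energy (kcal/mol).

    Delta G = -1/2 * 332.0636 * (1/eps_in - 1/eps_out) * sum_ij q_i q_j /
    f_GB with f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j))); the sum
    runs over all ordered pairs including i = j (Born self terms).
    """
    params = params or ParamSet()
    coords, q, _sig, _eps, radii = _atom_arrays(assembly, chain_ids)
    return gb_polar_energy_arrays(coords, q, radii, params, block=block)


def gb_polar_energy_arrays(coords: np.ndarray, charges: np.ndarray,
                           radii: np.ndarray,
                           params: Optional[ParamSet] = None,
                           block: int = 512) -> float:
    """GB polar energy from bare coordinate/charge/radius arrays."""
    params = params or ParamSet()
    coords = np.atleast_2d(np.asarray(coords, float))
    q = np.asarray(charges, float)
    radii = np.asarray(radii, float)
    reff = effective_born_radii(coords, radii, params, block=block)
    kappa = params.kappa
    total = 0.0
    for i0 in range(0, len(coords), block):
        i1 = min(i0 + block, len(coords))
        r2 = cdist(coords[i0:i1], coords) ** 2
        rr = reff[i0:i1, None] * reff[None, :]
        f = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
        # salt-dependent GB: the solvent term is Debye-screened
        pref = (1.0 / params.dielectric_solute
                - np.exp(-kappa * f) / params.dielectric_solvent)
        total += (pref * q[i0:i1, None] * q[None, :] / f).sum()
    return float(-0.5 * COULOMB_K * total)


def sasa(assembly: Assembly,
         chain_ids: Optional[Iterable[str]] = None,
         probe: float = 1.4,
         n_points: int = 960) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area (A^2).

    Returns (per-atom areas, total).  ``n_points`` sphere points per atom
    (>= 960 by default) on a golden-spiral lattice.
    """
    coords, _q, _sig, _eps, radii = _atom_arrays(assembly, chain_ids)
    return sasa_arrays(coords, radii, probe, n_points)


def sasa_arrays(coords: np.ndarray, radii: np.ndarray,
                probe: float = 1.4,
                n_points: int = 960) -> tuple[np.ndarray, float]:
    """Shrake-Rupley SASA from bare coordinate/radius arrays."""
    from scipy.spatial import cKDTree

    from .shape import fibonacci_sphere

    coords = np.atleast_2d(np.asarray(coords, float))
    radii = np.asarray(radii, float)
    ext = radii + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    areas = np.zeros(len(coords))
    max_ext = ext.max()
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i],
                                                  ext[i] + max_ext)
                 if j != i]
        keep = np.ones(n_points, dtype=bool)
        for j in neigh:
            keep &= np.linalg.norm(pts - coords[j], axis=1) >= ext[j]
        areas[i] = keep.mean() * 4.0 * np.pi * ext[i] ** 2
    return areas, float(areas.sum())


@dataclass
class Segmentation:
    """A bipartition of an assembly's chains along a growth-mode plane.

    ``elongation`` splits a single layer at its longitudinal midpoint
    (requires an even chain count -- the segmentation is symmetric);
    ``thickening`` splits a pair into its two layers.
    """

    mode: str
    part_a: tuple[str, ...]
    part_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("elongation", "thickening"):
            raise ValidationError(f"unknown segmentation mode {self.mode!r}")
        if set(self.part_a) & set(self.part_b):
            raise ValidationError("segmentation parts must be disjoint")

    def validate_for(self, assembly: Assembly) -> None:
        ids = {c.chain_id for c in assembly.all_chains()}
        if set(self.part_a) | set(self.part_b) != ids:
            raise ValidationError(
                "segmentation parts must cover all chains")

    @classmethod
    def elongation(cls, assembly: Assembly) -> "Segmentation":
        if assembly.topology != "protofilament":
            raise ValidationError(
                "elongation segmentation applies to single-layer "
                "protofilaments")
        chains = assembly.layers[0]
        if len(chains) % 2:
            raise ValidationError(
                f"elongation requires an even chain count for a symmetric "
                f"segmentation (got {len(chains)})")
        half = len(chains) // 2
        return cls(mode="elongation",
                   part_a=tuple(c.chain_id for c in chains[:half]),
                   part_b=tuple(c.chain_id for c in chains[half:]))

    @classmethod
    def thickening(cls, assembly: Assembly) -> "Segmentation":
        if assembly.topology != "pair" or len(assembly.layers) != 2:
            raise ValidationError(
                "thickening segmentation applies to protofilament pairs")
        return cls(mode="thickening",
                   part_a=tuple(c.chain_id for c in assembly.layers[0]),
                   part_b=tuple(c.chain_id for c in assembly.layers[1]))


@dataclass
class EnergyDecomposition:
    """Interface interaction energy and its components (kcal/mol)."""

    e_coulomb: float
    e_lj: float
    g_gb: float
    g_sasa: float
    e_total: float = field(init=False)
    e_interaction: float = field(init=False)

    def __post_init__(self) -> None:
        self.e_total = self.e_coulomb + self.e_lj + self.g_gb + self.g_sasa
        self.e_interaction = self.e_total


def interaction_energy(ensemble: Ensemble, seg: Segmentation,
                       window_ps: Optional[float] = None,
                       params: Optional[ParamSet] = None,
                       include_gb: bool = True,
                       include_sasa: bool = True) -> EnergyDecomposition:
    """Ensemble-mean interface interaction energy across a segmentation.

    Per frame, E_int = [E_MM + G_GB + gamma * SASA](complex) - (A) - (B);
    the molecular-mechanics part reduces to the cross-part pair sums.
    Frames inside the trailing ``window_ps`` (default: the full duration)
    are weighted uniformly.  Negative values are stabilizing.
    """
    params = params or ParamSet()
    assign_params(ensemble.template, params)
    seg.validate_for(ensemble.template)
    if window_ps is None:
        mask = np.ones(ensemble.n_frames, dtype=bool)
    else:
        mask = ensemble.trailing_window(window_ps)
    comps = []
    for k in np.flatnonzero(mask):
        frame = ensemble.frame(k)
        coul, lj = mm_energy(frame, seg.part_a, seg.part_b)
        gb = 0.0
        if include_gb:
            gb = (gb_polar_energy(frame, None, params)
                  - gb_polar_energy(frame, seg.part_a, params)
                  - gb_polar_energy(frame, seg.part_b, params))
        sas = 0.0
        if include_sasa:
            sas = params.gamma_sasa * (
                sasa(frame, None, params.sasa_probe, params.sasa_points)[1]
                - sasa(frame, seg.part_a, params.sasa_probe,
                       params.sasa_points)[1]
                - sasa(frame, seg.part_b, params.sasa_probe,
                       params.sasa_points)[1])
        comps.append((coul, lj, gb, sas))
    arr = np.array(comps)
    mean = arr.mean(axis=0)
    return EnergyDecomposition(e_coulomb=float(mean[0]), e_lj=float(mean[1]),
                               g_gb=float(mean[2]), g_sasa=float(mean[3]))


@dataclass
class CrossoverResult:
    """Outcome of the elongation-vs-thickening size comparison.

    ``crossover_n`` is the (interpolated) total monomer count at which the
    thickening interaction energy becomes more negative than elongation;
    None when no crossover occurs in the sampled range.
    """

    crossover_n: Optional[float]
    verdict: str
    table: "object"  # pandas DataFrame: size, e_elong, e_thick, favored


def crossover_analysis(results: dict[int, tuple[float, float]]
                       ) -> CrossoverResult:
    """Locate the growth-mode crossover from per-size energies.

    ``results`` maps total monomer count N to (E_elongation, E_thickening)
    in kcal/mol.  The crossover is the smallest N at which
    E_thick(N) < E_elong(N) (more negative = favored), linearly
    interpolated between the bracketing sizes.
    """
    import pandas as pd

    if len(results) < 2:
        raise ValidationError(
            "crossover analysis needs energies for at least 2 sizes")
    sizes = sorted(results)
    f = np.array([results[n][1] - results[n][0] for n in sizes])
    rows = [{"size": n, "e_elong": results[n][0], "e_thick": results[n][1],
             "favored": "pair" if fv < 0 else
             ("tie" if fv == 0 else "protofilament")}
            for n, fv in zip(sizes, f)]
    table = pd.DataFrame(rows)
    below = np.flatnonzero(f < 0)
    if len(below) == 0:
        return CrossoverResult(
            crossover_n=None,
            verdict=f"no crossover in range {sizes[0]}-{sizes[-1]}",
            table=table)
    i = int(below[0])
    if i == 0:
        n_star = float(sizes[0])
    else:
        n0, n1 = sizes[i - 1], sizes[i]
        f0, f1 = f[i - 1], f[i]
        n_star = n0 + f0 * (n1 - n0) / (f0 - f1)
    from math import ceil, isclose
    n_from = (int(round(n_star)) if isclose(n_star, round(n_star),
                                            abs_tol=1e-9)
              else ceil(n_star))
    return CrossoverResult(
        crossover_n=float(n_star),
        verdict=f"pair favored at N >= {n_from}",
        table=table)
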