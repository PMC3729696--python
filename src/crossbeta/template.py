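"""Idealized U-shaped Abeta(9-42) template chain.

The template emulates the sheet-turn-sheet fold of a fibrillar Abeta chain:
an N-terminal beta-strand (G9-F19), a turn carrying the D23/K28 salt-bridge
groups, and a C-terminal beta-strand (I32-A42) running antiparallel to the
first within the chain, so that in-register stacking of copies along the
growth axis produces two parallel beta-sheets.

Construction strategy
---------------------
The per-residue rise of the strands is derived from the requested backbone
dihedrals by building a short poly-alanine segment in internal coordinates
(standard bond lengths and angles) and measuring its helical rise.  The
chain is then laid out as an idealized planar pleated trace: two
antiparallel legs in the xy-plane joined by a circular cap, with the
peptide-unit atoms (C, O, N, H) rebuilt between consecutive CA positions by
an exact triangle solve at standard bond lengths, and carbonyls alternating
along +/-z (the growth axis) so that stacked copies at ~4.8 A spacing form
the canonical parallel-sheet hydrogen-bond ladder.  Dihedral requests whose
implied rise cannot close the peptide-unit triangle raise a construction
error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ACE_CODE,
    ACE_INDEX,
    FIRST_RESIDUE,
    LAST_RESIDUE,
    SIDECHAIN_TIP_LENGTH,
    AtomRecord,
    ChainModel,
    ConstructionError,
    ResidueRecord,
    ValidationError,
    one_letter,
    validate_chain,
)

# Standard backbone internal coordinates (Engh-Huber averages).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7

#: Virtual CA-CA bond length of a trans peptide, A.
CA_CA_VIRTUAL = 3.80

# D23 carboxylate tip geometry: CG along the side-chain direction, the two
# carboxylate oxygens splayed about it.
D23_CG_LENGTH = 2.43
D23_OD_LENGTH = 1.25
D23_OD_SPLAY_DEG = 50.0
#: Reach of the K28 ammonium nitrogen from CA, A.
K28_NZ_LENGTH = 4.90

#: Index of the last residue on the outgoing (N-side) leg.  Residues
#: OUT_LEG_END+1 .. RETURN_LEG_START-1 sit on the connecting cap arc.
OUT_LEG_END = 24
RETURN_LEG_START = 28


@dataclass
class TemplateParams:
    """Geometry of the idealized template chain.

    ``strand_phi``/``strand_psi`` are the backbone dihedrals of the beta
    regions (degrees, defaults -139/+135); the three residue ranges must
    partition 9-42; ``salt_bridge_gap`` is the target minimum distance
    between the D23 carboxylate oxygens and the K28 ammonium nitrogen (A).
    """

    strand_phi: float = -139.0
    strand_psi: float = 135.0
    n_sheet_range: tuple[int, int] = (9, 19)
    c_sheet_range: tuple[int, int] = (32, 42)
    turn_range: tuple[int, int] = (20, 31)
    salt_bridge_gap: float = 3.5

    def validate(self) -> None:
        if self.salt_bridge_gap <= 0:
            raise ValidationError("salt_bridge_gap must be > 0")
        spans = sorted([self.n_sheet_range, self.turn_range,
                        self.c_sheet_range])
        covered: list[int] = []
        for lo, hi in spans:
            if lo > hi:
                raise ValidationError(f"range {lo}-{hi} is inverted")
            covered.extend(range(lo, hi + 1))
        if covered != list(range(FIRST_RESIDUE, LAST_RESIDUE + 1)):
            raise ValidationError(
                "sheet and turn ranges must partition residues 9-42 "
                "without overlap")


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()


def _nerf_extend(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                 bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.deg2rad(180.0 - angle_deg)
    tor = np.deg2rad(torsion_deg)
    d2 = bond * np.array([np.cos(ang),
                          np.sin(ang) * np.cos(tor),
                          np.sin(ang) * np.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def strand_rise_per_residue(phi: float, psi: float, n_res: int = 12) -> float:
    """Helical rise per residue (A) of a poly-backbone with fixed (phi, psi).

    Built in internal coordinates with standard bond geometry and omega=180,
    the CA trace of the repeating conformation advances by a fixed distance
    along its helical axis per residue; that distance is returned.
    """
    # seed triad: N, CA, C of residue 0 in an arbitrary frame
    coords = {
        ("N", 0): np.array([0.0, 0.0, 0.0]),
        ("CA", 0): np.array([BOND_N_CA, 0.0, 0.0]),
    }
    c0 = coords[("CA", 0)] + BOND_CA_C * np.array(
        [np.cos(np.deg2rad(180 - ANGLE_N_CA_C)),
         np.sin(np.deg2rad(180 - ANGLE_N_CA_C)), 0.0])
    coords[("C", 0)] = c0
    for i in range(1, n_res):
        coords[("N", i)] = _nerf_extend(
            coords[("N", i - 1)], coords[("CA", i - 1)], coords[("C", i - 1)],
            BOND_C_N, ANGLE_CA_C_N, psi)
        coords[("CA", i)] = _nerf_extend(
            coords[("CA", i - 1)], coords[("C", i - 1)], coords[("N", i)],
            BOND_N_CA, ANGLE_C_N_CA, 180.0)  # omega
        coords[("C", i)] = _nerf_extend(
            coords[("C", i - 1)], coords[("N", i)], coords[("CA", i)],
            BOND_CA_C, ANGLE_N_CA_C, phi)
    cas = np.array([coords[("CA", i)] for i in range(n_res)])
    # helical axis = dominant principal direction of the CA trace
    centered = cas - cas.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    rises = np.abs(np.diff(np.sort(proj)))
    return float(np.mean(rises))


def _peptide_triangle(length: float) -> tuple[float, float]:
    """Offsets (x1, h) placing C and N between two CA positions ``length``
    apart with |CA-C| = 1.525, |C-N| = 1.329, |N-CA'| = 1.458.

    C sits at x1 along the CA->CA' axis and h perpendicular to it; N sits at
    x1 + 1.329 along and h perpendicular.  Raises ConstructionError when the
    triangle cannot close (CA spacing implied by the dihedrals too long or
    too short).
    """
    a = length - BOND_C_N
    if a <= 0:
        raise ConstructionError(
            f"CA spacing {length:.2f} A too short for a trans peptide unit")
    x1 = (BOND_CA_C ** 2 - BOND_N_CA ** 2 + a ** 2) / (2 * a)
    h_sq = BOND_CA_C ** 2 - x1 ** 2
    if h_sq <= 1e-4:
        raise ConstructionError(
            f"infeasible backbone geometry: CA spacing {length:.2f} A "
            f"cannot close the peptide-unit triangle")
    return x1, float(np.sqrt(h_sq))


def _cap_arc(p_start: np.ndarray, p_end: np.ndarray, n_points: int,
             bulge_dir: np.ndarray) -> np.ndarray:
    """Equally spaced intermediate points on a circular arc joining two CA
    positions, bulging toward ``bulge_dir``, with ~3.8 A spacing."""
    from scipy.optimize import brentq

    chord_v = p_end - p_start
    chord = np.linalg.norm(chord_v)
    n_seg = n_points + 1
    target = CA_CA_VIRTUAL

    def gap(theta: float) -> float:
        # chord of full arc vs chord of one segment for central angle theta
        return 2 * np.sin(theta / 2) / (2 * np.sin(theta / (2 * n_seg))) \
            - chord / target

    try:
        theta = brentq(gap, 1e-3, 2 * np.pi - 1e-3)
    except ValueError as exc:  # no bulged arc fits
        raise ConstructionError(
            f"turn cap cannot span {chord:.1f} A with {n_points} residues"
        ) from exc
    radius = chord / (2 * np.sin(theta / 2))
    mid = 0.5 * (p_start + p_end)
    # center displaced from the chord midpoint opposite the bulge
    perp = bulge_dir - (bulge_dir @ chord_v) * chord_v / chord ** 2
    perp = perp / np.linalg.norm(perp)
    h = radius * np.cos(theta / 2)
    center = mid - h * perp
    ang0 = np.arctan2(*((p_start - center)[[1, 0]]))
    ang1 = np.arctan2(*((p_end - center)[[1, 0]]))
    s1 = ang1 - ang0
    if s1 > np.pi:
        s1 -= 2 * np.pi
    elif s1 <= -np.pi:
        s1 += 2 * np.pi
    s2 = s1 - np.sign(s1) * 2 * np.pi if s1 != 0 else 2 * np.pi
    # of the two arcs joining the endpoints, take the one bulging the
    # requested way (its midpoint lies on the +perp side of the chord)
    best, sweep = -np.inf, s1
    for cand in (s1, s2):
        mid_pt = center + radius * np.array(
            [np.cos(ang0 + cand / 2), np.sin(ang0 + cand / 2), 0.0])
        score = (mid_pt - mid) @ perp
        if score > best:
            best, sweep = score, cand
    pts = []
    for k in range(1, n_points + 1):
        ang = ang0 + sweep * k / n_seg
        pts.append(center + radius * np.array([np.cos(ang), np.sin(ang), 0.0]))
    return np.array(pts)


def _ca_trace(params: TemplateParams) -> tuple[np.ndarray, float, float]:
    """CA positions for virtual indices 8..43 plus (rise d, pleat delta)."""
    d = strand_rise_per_residue(params.strand_phi, params.strand_psi)
    if d < 2.6:
        raise ConstructionError(
            f"dihedrals ({params.strand_phi:.0f}, {params.strand_psi:.0f}) "
            f"imply a rise of {d:.2f} A/residue -- too compressed for an "
            f"extended beta-strand; the U-shaped layout is infeasible")
    if d >= CA_CA_VIRTUAL - 0.05:
        d = CA_CA_VIRTUAL - 0.05
    pleat = np.sqrt(CA_CA_VIRTUAL ** 2 - d ** 2) / 2.0

    # sheet separation solved so the D23/K28 tips meet at salt_bridge_gap
    od_x_offset = D23_OD_LENGTH * np.sin(np.deg2rad(D23_OD_SPLAY_DEG))
    if params.salt_bridge_gap <= od_x_offset:
        raise ConstructionError(
            f"salt_bridge_gap {params.salt_bridge_gap:.2f} A unreachable: "
            f"below the carboxylate splay offset {od_x_offset:.2f} A")
    reach_d = D23_CG_LENGTH + D23_OD_LENGTH * np.cos(
        np.deg2rad(D23_OD_SPLAY_DEG))
    dy = np.sqrt(params.salt_bridge_gap ** 2 - od_x_offset ** 2)
    width = reach_d + K28_NZ_LENGTH + 2 * pleat + dy
    if width < 6.0:
        raise ConstructionError(
            f"implied sheet separation {width:.1f} A too small; "
            f"legs would clash")

    trace = np.zeros((LAST_RESIDUE + 2 - ACE_INDEX, 3))  # indices 8..43

    def idx(i: int) -> int:
        return i - ACE_INDEX

    for i in range(ACE_INDEX, OUT_LEG_END + 1):  # 8..24, +x direction
        trace[idx(i)] = ((i - FIRST_RESIDUE) * d,
                         width / 2 + pleat * (-1) ** i, 0.0)
    for i in range(RETURN_LEG_START, LAST_RESIDUE + 2):  # 28..43, -x direction
        trace[idx(i)] = ((LAST_RESIDUE - i) * d,
                         -width / 2 + pleat * (-1) ** i, 0.0)
    cap = _cap_arc(trace[idx(OUT_LEG_END)], trace[idx(RETURN_LEG_START)],
                   RETURN_LEG_START - OUT_LEG_END - 1,
                   bulge_dir=np.array([1.0, 0.0, 0.0]))
    for k, i in enumerate(range(OUT_LEG_END + 1, RETURN_LEG_START)):
        trace[idx(i)] = cap[k]
    return trace, d, pleat


def _sidechain_dir(i: int, on_out_leg: bool) -> np.ndarray:
    """Unit direction of the side chain of residue i (perpendicular to the
    strand, alternating with residue parity).  Odd residues on the out leg
    and even residues on the return leg point into the U interior."""
    del on_out_leg  # the parity rule is leg-independent for this layout
    return np.array([0.0, (-1) ** i * 1.0, 0.0])


def make_template_chain(params: TemplateParams | None = None,
                        chain_id: str = "A") -> ChainModel:
    """Build the idealized acetyl-capped Abeta(9-42) template chain.

    The result passes all ChainModel invariants (35 residue units, full
    backbone with amide hydrogens, D23 OD1/OD2 and K28 NZ present) and its
    D23-K28 tip distance equals ``params.salt_bridge_gap`` within 0.5 A.
    """
    params = params or TemplateParams()
    params.validate()
    trace, _d, _pleat = _ca_trace(params)

    def ca(i: int) -> np.ndarray:
        return trace[i - ACE_INDEX]

    # peptide-unit atoms between consecutive trace points
    unit_atoms: dict[int, dict[str, np.ndarray]] = {}
    for i in range(ACE_INDEX, LAST_RESIDUE + 1):  # unit i -> i+1
        p0, p1 = ca(i), ca(i + 1)
        seg = p1 - p0
        length = np.linalg.norm(seg)
        along = seg / length
        x1, h = _peptide_triangle(length)
        if OUT_LEG_END < i < RETURN_LEG_START - 1:
            # turn-cap peptide planes lie in the sheet plane: stacked
            # turns do not form the parallel hydrogen-bond ladder
            perp = np.cross(np.array([0.0, 0.0, 1.0]), along)
            perp = perp / np.linalg.norm(perp) * (-1.0) ** i
        else:
            perp = np.array([0.0, 0.0, (-1.0) ** i])
        c_pos = p0 + x1 * along + h * perp
        o_pos = c_pos + BOND_C_O * perp
        n_pos = p0 + (x1 + BOND_C_N) * along + h * perp
        h_pos = n_pos - BOND_N_H * perp
        unit_atoms[i] = {"C": c_pos, "O": o_pos, "N": n_pos, "H": h_pos}

    residues: list[ResidueRecord] = []
    # acetyl cap: methyl carbon at the virtual CA(8) position, C/O from unit 8
    residues.append(ResidueRecord(aa_code=ACE_CODE, seq_index=ACE_INDEX, atoms=[
        AtomRecord("CH3", "C", ca(ACE_INDEX)),
        AtomRecord("C", "C", unit_atoms[ACE_INDEX]["C"]),
        AtomRecord("O", "O", unit_atoms[ACE_INDEX]["O"]),
    ]))

    for i in range(FIRST_RESIDUE, LAST_RESIDUE + 1):
        aa = one_letter(i)
        on_out = i <= OUT_LEG_END
        atoms = [
            AtomRecord("N", "N", unit_atoms[i - 1]["N"]),
            AtomRecord("H", "H", unit_atoms[i - 1]["H"]),
            AtomRecord("CA", "C", ca(i)),
            AtomRecord("C", "C", unit_atoms[i]["C"]),
            AtomRecord("O", "O", unit_atoms[i]["O"]),
        ]
        s_dir = _sidechain_dir(i, on_out)
        if aa != "G":
            atoms.append(AtomRecord("CB", "C", ca(i) + BOND_CA_CB * s_dir))
        if i == 23:  # Asp carboxylate tip
            cg = ca(i) + D23_CG_LENGTH * s_dir
            splay = np.deg2rad(D23_OD_SPLAY_DEG)
            x_hat = np.array([1.0, 0.0, 0.0])
            atoms.append(AtomRecord("CG", "C", cg))
            atoms.append(AtomRecord(
                "OD1", "O",
                cg + D23_OD_LENGTH * (np.cos(splay) * s_dir + np.sin(splay) * x_hat)))
            atoms.append(AtomRecord(
                "OD2", "O",
                cg + D23_OD_LENGTH * (np.cos(splay) * s_dir - np.sin(splay) * x_hat)))
        if i == 28:  # Lys ammonium tip
            atoms.append(AtomRecord("NZ", "N", ca(i) + K28_NZ_LENGTH * s_dir))
        if i in SIDECHAIN_TIP_LENGTH:
            atoms.append(AtomRecord(
                "SCT", "C", ca(i) + SIDECHAIN_TIP_LENGTH[i] * s_dir))
        if i == LAST_RESIDUE:  # free C-terminal carboxylate
            c_pos = unit_atoms[i]["C"]
            perp = np.array([0.0, 0.0, (-1.0) ** i])
            atoms.append(AtomRecord("OXT", "O", c_pos - BOND_C_O * perp))
        residues.append(ResidueRecord(aa_code=aa, seq_index=i, atoms=atoms))

    chain = ChainModel(chain_id=chain_id, residues=residues)
    validate_chain(chain)

    # contract: the built salt bridge must hit the requested gap
    d23 = chain.residue(23)
    k28 = chain.residue(28)
    nz = k28.atom("NZ").coord
    gap = min(np.linalg.norm(d23.atom(n).coord - nz) for n in ("OD1", "OD2"))
    if abs(gap - params.salt_bridge_gap) > 0.5:
        raise ConstructionError(
            f"salt bridge gap {gap:.2f} A misses target "
            f"{params.salt_bridge_gap:.2f} A by more than 0.5 A")
    return chain
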