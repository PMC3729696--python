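"""Geometric observables: twist angle, adjacent-monomer angle, RMSD.

The total twist of a stacked beta-sheet is measured as the signed dihedral
of the CA atoms of V18 and V24 of the second and the penultimate monomer;
the adjacent-monomer angle is the angle between the V18->V24 position
vectors of consecutive chains.  Twist series are unwrapped across frames
(nearest-branch continuation) so cumulative twists beyond +/-180 degrees
are tracked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .model import Assembly, Ensemble, ValidationError


class NotDefinedError(ValueError):
    """The observable is undefined for this assembly size."""


def signed_dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                    p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def _twist_points(assembly: Assembly, layer: int) -> list[np.ndarray]:
    chains = assembly.layers[layer]
    n = len(chains)
    if n < 4:
        raise NotDefinedError(
            f"twist angle requires >= 4 chains in the layer (got {n}); "
            f"tiny oligomers are excluded from angle analysis")
    second, penult = chains[1], chains[n - 2]
    return [second.residue(18).atom("CA").coord,
            second.residue(24).atom("CA").coord,
            penult.residue(24).atom("CA").coord,
            penult.residue(18).atom("CA").coord]


def total_twist_angle(assembly: Assembly, layer: int = 0) -> float:
    """Total twist (degrees) of one layer.

    Signed dihedral of CA(V18, chain 2), CA(V24, chain 2),
    CA(V24, chain n-1), CA(V18, chain n-1) (1-based stacking indices);
    a right-handed rotation about the growth axis is positive, and a
    freshly built untwisted stack measures 0.
    """
    p = _twist_points(assembly, layer)
    raw = signed_dihedral(*p)
    # orient the sign convention: positive = right-handed about growth_axis
    b1 = p[2] - p[1]
    if b1 @ assembly.growth_axis < 0:
        raw = -raw
    return raw


def adjacent_monomer_angle(assembly: Assembly, layer: int = 0,
                           i: int = 0) -> float:
    """Angle (degrees, in [0, 180]) between the V18->V24 vectors of
    chains i and i+1 of a layer (0-based)."""
    chains = assembly.layers[layer]
    if not 0 <= i < len(chains) - 1:
        raise IndexError(
            f"chain index {i} out of range for {len(chains)} chains")

    def v(chain) -> np.ndarray:
        return (chain.residue(24).atom("CA").coord
                - chain.residue(18).atom("CA").coord)

    a, b = v(chains[i]), v(chains[i + 1])
    cosang = (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def mean_adjacent_angle(assembly: Assembly, layer: int = 0) -> float:
    chains = assembly.layers[layer]
    if len(chains) < 2:
        raise NotDefinedError("adjacent angle needs >= 2 chains")
    return float(np.mean([adjacent_monomer_angle(assembly, layer, i)
                          for i in range(len(chains) - 1)]))


@dataclass
class AngleSeries:
    """Per-frame angle values (degrees) with a trailing-window mean."""

    per_frame: np.ndarray
    times: np.ndarray
    window_ps: float
    mean_last_window: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_frame = np.asarray(self.per_frame, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.per_frame) != len(self.times):
            raise ValidationError("series and times lengths differ")
        self.mean_last_window = summarize_angles(self, self.window_ps)


def summarize_angles(series: "AngleSeries", window_ps: float) -> float:
    """Arithmetic mean of the frames inside the trailing time window
    (frames with time > t_end - window)."""
    if window_ps <= 0:
        raise ValidationError("window must be positive")
    t_end = series.times[-1]
    span = series.times[-1] - series.times[0]
    if window_ps >= span and len(series.times) > 1:
        window_ps = span + 1e-9  # window equal to (or beyond) full duration
    mask = series.times > t_end - window_ps
    if len(series.times) == 1:
        mask = np.array([True])
    if not mask.any():
        raise ValidationError("trailing window contains no frames")
    return float(series.per_frame[mask].mean())


@dataclass
class RmsdSeries:
    """Per-frame RMSD (A) relative to a reference frame."""

    per_frame: np.ndarray
    times: np.ndarray
    selection: str = "backbone"

    def __post_init__(self) -> None:
        self.per_frame = np.asarray(self.per_frame, dtype=float)
        if np.any(self.per_frame < -1e-12):
            raise ValidationError("RMSD values must be non-negative")


_BACKBONE = ("N", "CA", "C", "O")


def _selection_coords(assembly: Assembly, selection) -> np.ndarray:
    if callable(selection):
        keep = selection
    elif selection == "backbone":
        def keep(res, atom):
            return atom.name in _BACKBONE
    elif selection == "ca":
        def keep(res, atom):
            return atom.name == "CA"
    elif selection == "all":
        def keep(res, atom):
            return True
    else:
        raise ValidationError(f"unknown selection {selection!r}")
    coords = [a.coord for _, _, r, a in assembly.iter_atoms() if keep(r, a)]
    if not coords:
        raise ValidationError("selection matches no atoms")
    return np.array(coords)


def _selection_mask(assembly: Assembly, selection) -> np.ndarray:
    full = assembly.coords()
    sel = _selection_coords(assembly, selection)
    # build mask by re-running the predicate in canonical order
    if callable(selection):
        keep = selection
    elif selection == "backbone":
        def keep(res, atom):
            return atom.name in _BACKBONE
    elif selection == "ca":
        def keep(res, atom):
            return atom.name == "CA"
    else:
        def keep(res, atom):
            return True
    mask = np.array([keep(r, a) for _, _, r, a in assembly.iter_atoms()])
    assert mask.sum() == len(sel) and len(mask) == len(full)
    return mask


def rmsd(frame: Assembly, reference: Assembly, selection="backbone",
         superpose: bool = True) -> float:
    """RMSD (A) between two structures over an atom selection.

    With ``superpose`` (default) the minimal RMSD after optimal rigid
    superposition (Kabsch) is returned; otherwise the direct coordinate
    RMSD.
    """
    x = _selection_coords(frame, selection)
    y = _selection_coords(reference, selection)
    if x.shape != y.shape:
        raise ValidationError(
            f"selection resolves to {len(x)} vs {len(y)} atoms")
    if not superpose:
        return float(np.sqrt(((x - y) ** 2).sum(axis=1).mean()))
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    _, rssd = Rotation.align_vectors(yc, xc)
    return float(rssd / np.sqrt(len(x)))


def rmsd_series(ensemble: Ensemble, selection="backbone",
                reference_frame: int = 0, superpose: bool = True
                ) -> RmsdSeries:
    """RMSD of every frame to a reference frame (default: the starting
    structure)."""
    mask = _selection_mask(ensemble.template, selection)
    ref = ensemble.coords[reference_frame][mask]
    refc = ref - ref.mean(axis=0)
    out = np.empty(ensemble.n_frames)
    for k in range(ensemble.n_frames):
        x = ensemble.coords[k][mask]
        if superpose:
            xc = x - x.mean(axis=0)
            _, rssd = Rotation.align_vectors(refc, xc)
            out[k] = rssd / np.sqrt(len(x))
        else:
            out[k] = np.sqrt(((x - ref) ** 2).sum(axis=1).mean())
    return RmsdSeries(per_frame=out, times=ensemble.times.copy(),
                      selection=str(selection))


def twist_series(ensemble: Ensemble, layer: int = 0,
                 window_ps: Optional[float] = None) -> AngleSeries:
    """Unwrapped per-frame total twist of a layer.

    Consecutive frames are continued on the nearest branch (|delta| < 180
    degrees), so cumulative twists beyond +/-180 are tracked -- large
    stacks can report totals past 300 degrees.
    """
    tmpl = ensemble.template
    # flat indices of the four dihedral-defining CA atoms
    wanted = {}
    chains = tmpl.layers[layer]
    n = len(chains)
    if n < 4:
        raise NotDefinedError("twist series requires >= 4 chains")
    targets = {(chains[1].chain_id, 18): 0, (chains[1].chain_id, 24): 1,
               (chains[n - 2].chain_id, 24): 2, (chains[n - 2].chain_id, 18): 3}
    for flat, (_li, c, r, a) in enumerate(tmpl.iter_atoms()):
        key = (c.chain_id, r.seq_index)
        if key in targets and a.name == "CA":
            wanted[targets[key]] = flat
    idx = [wanted[k] for k in range(4)]
    raw = np.empty(ensemble.n_frames)
    sign_flip = ((tmpl.layers[layer][n - 2].residue(24).atom("CA").coord
                  - tmpl.layers[layer][1].residue(24).atom("CA").coord)
                 @ tmpl.growth_axis) < 0
    for k in range(ensemble.n_frames):
        c = ensemble.coords[k]
        val = signed_dihedral(c[idx[0]], c[idx[1]], c[idx[2]], c[idx[3]])
        raw[k] = -val if sign_flip else val
    unwrapped = np.degrees(np.unwrap(np.radians(raw)))
    if window_ps is None:
        window_ps = max(float(ensemble.times[-1] - ensemble.times[0]), 1.0)
    return AngleSeries(per_frame=unwrapped, times=ensemble.times.copy(),
                       window_ps=window_ps)


def adjacent_angle_series(ensemble: Ensemble, layer: int = 0,
                          window_ps: Optional[float] = None) -> AngleSeries:
    """Per-frame mean adjacent-monomer angle of a layer."""
    vals = np.empty(ensemble.n_frames)
    for k in range(ensemble.n_frames):
        vals[k] = mean_adjacent_angle(ensemble.frame(k), layer)
    if window_ps is None:
        window_ps = max(float(ensemble.times[-1] - ensemble.times[0]), 1.0)
    return AngleSeries(per_frame=vals, times=ensemble.times.copy(),
                       window_ps=window_ps)


def estimate_twist_rate(ensemble: Ensemble, layer: int = 0) -> float:
    """Per-monomer twist (degrees) recovered from the final-frame total
    twist: the unwrapped total divided by the number of stacking steps
    between the second and penultimate chains (n - 3)."""
    n = len(ensemble.template.layers[layer])
    series = twist_series(ensemble, layer)
    return float(series.per_frame[-1] / (n - 3))


def expected_twist_oracle(twist_per_monomer: float, n_chains: int) -> float:
    """Independent rotation-matrix oracle for the imposed total twist.

    Composes the per-chain rotations explicitly: the V18->V24 vector of
    chain n-1 is the chain-2 vector rotated by (n-3) * twist_per_monomer
    about the growth axis, so the measured dihedral equals that cumulative
    angle.  Kept free of the dihedral code path on purpose.
    """
    if n_chains < 4:
        raise NotDefinedError("oracle undefined below 4 chains")
    return twist_per_monomer * (n_chains - 3)
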