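"""Salt bridges and beta-sheet content.

Salt bridges are monitored via the distance between the D23 carboxylate
oxygens (OD1/OD2) and the K28 ammonium nitrogen (NZ) with a 4.2 A cutoff,
both within a chain (intramolecular) and between adjacent chains of a
layer (intermolecular, D23 of chain i with K28 of chain i+1, toward the
growth end).

Beta-sheet content is computed from backbone hydrogen bonds under the
Kabsch-Sander electrostatic criterion (the algorithm behind DSSP):
E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) kcal/mol, a bond
being recorded when E < -0.5 kcal/mol.  A residue is counted as parallel
beta-sheet when it closes the Kabsch-Sander parallel-bridge pattern with a
residue on another chain.  Amide hydrogens are reconstructed geometrically
(bisector convention, 1.01 A) when a structure lacks them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .model import (
    ACE_INDEX,
    Assembly,
    Ensemble,
    ResidueRecord,
    ValidationError,
)

#: Donor-acceptor distance criterion for the D23-K28 salt bridge, A.
SALT_BRIDGE_CUTOFF = 4.2

#: Kabsch-Sander coupling constant: q1*q2*f = 0.42*0.20*332 kcal/mol*A.
KS_COUPLING = 0.084 * 332.0
#: Bond threshold, kcal/mol.
KS_THRESHOLD = -0.5
#: Clamp value for overlapping atoms, kcal/mol.
KS_CLAMP = -9.9

N_SHEET_WINDOW = (9, 19)
C_SHEET_WINDOW = (32, 42)


@dataclass
class SaltBridgeRecord:
    """One D23-K28 contact; ``kind`` is ``intra`` or ``inter``."""

    donor_chain: str  # chain carrying K28 (the ammonium donor)
    acceptor_chain: str  # chain carrying D23 (the carboxylate acceptor)
    kind: str
    min_distance: float
    present: bool

    def __post_init__(self) -> None:
        if self.kind not in ("intra", "inter"):
            raise ValidationError(f"unknown salt-bridge kind {self.kind!r}")
        if self.kind == "intra" and self.donor_chain != self.acceptor_chain:
            raise ValidationError("intra record must stay within one chain")


def _bridge_distance(d23: ResidueRecord, k28: ResidueRecord) -> float:
    nz = k28.atom("NZ").coord
    return min(float(np.linalg.norm(d23.atom(n).coord - nz))
               for n in ("OD1", "OD2"))


def detect_salt_bridges(assembly: Assembly,
                        cutoff: float = SALT_BRIDGE_CUTOFF
                        ) -> list[SaltBridgeRecord]:
    """All intra- and intermolecular D23-K28 salt-bridge records.

    Every chain yields an intra record; every adjacent chain pair (i, i+1)
    within a layer yields an inter record (D23 of i, K28 of i+1).  The
    distance is the minimum over the two carboxylate oxygens; ``present``
    uses a closed cutoff (d <= cutoff).
    """
    records: list[SaltBridgeRecord] = []
    for layer in assembly.layers:
        for chain in layer:
            d = _bridge_distance(chain.residue(23), chain.residue(28))
            records.append(SaltBridgeRecord(
                donor_chain=chain.chain_id, acceptor_chain=chain.chain_id,
                kind="intra", min_distance=d, present=d <= cutoff))
        for a, b in zip(layer, layer[1:]):
            d = _bridge_distance(a.residue(23), b.residue(28))
            records.append(SaltBridgeRecord(
                donor_chain=b.chain_id, acceptor_chain=a.chain_id,
                kind="inter", min_distance=d, present=d <= cutoff))
    return records


def salt_bridge_occupancy(ensemble: Ensemble,
                          cutoff: float = SALT_BRIDGE_CUTOFF):
    """Fraction of frames each salt-bridge contact is present.

    Returns a pandas DataFrame with one row per (acceptor_chain,
    donor_chain, kind) and an ``occupancy`` column in [0, 1]; frames are
    weighted equally.
    """
    import pandas as pd

    if ensemble.n_frames < 1:
        raise ValidationError("occupancy needs at least one frame")
    counts: dict[tuple[str, str, str], int] = {}
    for k in range(ensemble.n_frames):
        for rec in detect_salt_bridges(ensemble.frame(k), cutoff):
            key = (rec.acceptor_chain, rec.donor_chain, rec.kind)
            counts[key] = counts.get(key, 0) + int(rec.present)
    rows = [{"acceptor_chain": a, "donor_chain": d, "kind": kind,
             "occupancy": c / ensemble.n_frames}
            for (a, d, kind), c in sorted(counts.items())]
    return pd.DataFrame(rows)


def _amide_h(res: ResidueRecord, prev_c: Optional[np.ndarray]) -> Optional[np.ndarray]:
    """Amide H position: explicit if present, else reconstructed on the
    bisector of the C(prev)->N and CA->N directions at 1.01 A."""
    if res.has_atom("H"):
        return res.atom("H").coord
    if prev_c is None or not res.has_atom("N") or not res.has_atom("CA"):
        return None
    n = res.atom("N").coord
    u = n - prev_c
    v = n - res.atom("CA").coord
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    b = u + v
    nb = np.linalg.norm(b)
    if nb < 1e-8:
        return None
    return n + 1.01 * b / nb


def kabsch_sander_energy(donor_res: ResidueRecord,
                         acceptor_res: ResidueRecord,
                         donor_prev_c: Optional[np.ndarray] = None
                         ) -> float:
    """Kabsch-Sander hydrogen-bond energy (kcal/mol) of the backbone
    N-H (donor) ... O=C (acceptor) interaction.

    ``donor_prev_c`` is the carbonyl-carbon position of the residue
    preceding the donor, used to reconstruct a missing amide hydrogen.
    Overlapping geometries (any distance < 0.5 A) clamp to -9.9.
    """
    n = donor_res.atom("N").coord
    h = _amide_h(donor_res, donor_prev_c)
    if h is None:
        raise ValidationError(
            f"cannot place amide H of residue {donor_res.seq_index}")
    c = acceptor_res.atom("C").coord
    o = acceptor_res.atom("O").coord
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return KS_CLAMP
    return float(KS_COUPLING * (1.0 / r_on + 1.0 / r_ch
                                - 1.0 / r_oh - 1.0 / r_cn))


@dataclass
class HBond:
    """A recorded backbone hydrogen bond CO(acceptor) -> NH(donor)."""

    donor: tuple[str, int]
    acceptor: tuple[str, int]
    energy: float

    def __post_init__(self) -> None:
        if not self.energy < KS_THRESHOLD:
            raise ValidationError(
                f"recorded H-bond must have E < {KS_THRESHOLD} kcal/mol")


def interchain_hbonds(assembly: Assembly,
                      prefilter_cutoff: float = 5.2) -> list[HBond]:
    """All inter-chain backbone H-bonds under the Kabsch-Sander criterion.

    Bonds are directional: the acceptor contributes C=O, the donor N-H.
    Intra-chain bonds are not collected (the parallel-bridge patterns only
    consume cross-chain bonds).
    """
    donors = []  # (chain_id, seq, residue, prev_c)
    acceptors = []
    for chain in assembly.all_chains():
        prev_c = None
        for res in chain.residues:
            if res.seq_index != ACE_INDEX and res.has_atom("N"):
                donors.append((chain.chain_id, res.seq_index, res, prev_c))
            if res.has_atom("C") and res.has_atom("O"):
                acceptors.append((chain.chain_id, res.seq_index, res))
            prev_c = res.atom("C").coord if res.has_atom("C") else None
    if not donors or not acceptors:
        return []
    n_pos = np.array([d[2].atom("N").coord for d in donors])
    o_pos = np.array([a[2].atom("O").coord for a in acceptors])
    tree = cKDTree(o_pos)
    bonds: list[HBond] = []
    for di, (dchain, dseq, dres, dprev) in enumerate(donors):
        for ai in tree.query_ball_point(n_pos[di], prefilter_cutoff):
            achain, aseq, ares = acceptors[ai]
            if achain == dchain:
                continue
            e = kabsch_sander_energy(dres, ares, donor_prev_c=dprev)
            if e < KS_THRESHOLD:
                bonds.append(HBond(donor=(dchain, dseq),
                                   acceptor=(achain, aseq), energy=e))
    return bonds


def _parallel_bridge_flags(assembly: Assembly) -> dict[tuple[str, int], bool]:
    """Per (chain, residue) flag: closes a Kabsch-Sander parallel bridge
    with some residue j on another chain, i.e.
    Hbond(j-1 -> i) and Hbond(i -> j+1), or
    Hbond(i-1 -> j) and Hbond(j -> i+1),
    where Hbond(a -> b) means C=O of a bonds N-H of b."""
    out: dict[tuple[str, int], set[tuple[str, int]]] = {}
    inn: dict[tuple[str, int], set[tuple[str, int]]] = {}
    for b in interchain_hbonds(assembly):
        out.setdefault(b.acceptor, set()).add(b.donor)  # CO(a) -> NH(b)
        inn.setdefault(b.donor, set()).add(b.acceptor)

    flags: dict[tuple[str, int], bool] = {}
    for chain in assembly.all_chains():
        for res in chain.residues:
            if res.seq_index == ACE_INDEX:
                continue
            i = (chain.chain_id, res.seq_index)
            im = (i[0], i[1] - 1)
            ip = (i[0], i[1] + 1)
            flag = False
            # pattern 1: Hbond(j-1 -> i) and Hbond(i -> j+1)
            for jm in inn.get(i, ()):
                if jm[0] == i[0]:
                    continue
                if (jm[0], jm[1] + 2) in out.get(i, ()):
                    flag = True
                    break
            # pattern 2: Hbond(i-1 -> j) and Hbond(j -> i+1)
            if not flag:
                for j in out.get(im, ()):
                    if j[0] == i[0]:
                        continue
                    if ip in out.get(j, ()):
                        flag = True
                        break
            flags[i] = flag
    return flags


@dataclass
class BetaContent:
    """Parallel beta-sheet content of an ensemble.

    ``per_residue`` maps the Abeta seq index to the fraction of
    (frame, chain) observations in a parallel bridge; ``window_means``
    holds the whole-chain, N-sheet (9-19) and C-sheet (32-42) means.
    """

    per_residue: dict[int, float]
    window_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for idx, frac in self.per_residue.items():
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(
                    f"fraction {frac} for residue {idx} outside [0, 1]")

    @staticmethod
    def _window_mean(per_residue: dict[int, float],
                     window: tuple[int, int]) -> float:
        vals = [f for i, f in per_residue.items()
                if window[0] <= i <= window[1]]
        return float(np.mean(vals)) if vals else 0.0


def parallel_beta_content(ensemble: Ensemble) -> BetaContent:
    """Mean parallel beta-sheet content over an ensemble.

    Residue fractions average over frames and over the chains of the
    assembly; window means cover the whole chain, the N-terminal sheet
    (G9-F19) and the C-terminal sheet (I32-A42).  A single-chain assembly
    has no inter-chain bridges and returns all zeros with a warning.
    """
    tmpl = ensemble.template
    seq_indices = [r.seq_index for r in tmpl.all_chains()[0].residues
                   if r.seq_index != ACE_INDEX]
    if tmpl.n_chains < 2:
        warnings.warn("single chain: parallel beta content is zero",
                      stacklevel=2)
        per_res = {i: 0.0 for i in seq_indices}
    else:
        sums = {i: 0.0 for i in seq_indices}
        n_obs = 0
        for k in range(ensemble.n_frames):
            flags = _parallel_bridge_flags(ensemble.frame(k))
            n_obs += tmpl.n_chains
            for (chain_id, seq), val in flags.items():
                sums[seq] += float(val)
        per_res = {i: sums[i] / n_obs for i in seq_indices}
    means = {
        "whole": BetaContent._window_mean(per_res, (9, 42)),
        "n_sheet": BetaContent._window_mean(per_res, N_SHEET_WINDOW),
        "c_sheet": BetaContent._window_mean(per_res, C_SHEET_WINDOW),
    }
    return BetaContent(per_residue=per_res, window_means=means)
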