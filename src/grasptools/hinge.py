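"""Open/closed domain-motion analysis for tandem PDZ structures.

Given two conformations of a two-domain protein, the pipeline:

1. superposes the structures on the CA atoms of the first (anchor)
   domain with a least-squares rigid fit (Kabsch, proper rotation);
2. reports the RMSD of the second (mobile) domain in that frame, with
   no second fit — this measures how far the domain has swung;
3. extracts the effective hinge rotation as the best-fit rigid rotation
   carrying the mobile domain from one state to the other,
   theta = arccos((tr(R) - 1)/2), with the axis from R's unit
   eigenvector.

An anisotropic elastic-network model (CA nodes, unit springs inside a
distance cutoff) provides low-frequency normal modes, and their overlap
with the open->closed displacement identifies which collective motion
carries the transition.
"""

from __future__ import annotations

import io
import urllib.request
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import eigh

import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

__all__ = [
    "StructureModel",
    "DomainDefinition",
    "HingeResult",
    "ModeOverlap",
    "read_structure",
    "fetch_pdb",
    "match_common_ca",
    "superpose",
    "rotation_angle_axis",
    "hinge_metrics",
    "enm_modes",
    "mode_overlap",
]


@dataclass
class StructureModel:
    """CA-level structure: parallel arrays of chain, residue and coordinates."""

    chain: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    coords: np.ndarray            # (N, 3) angstroms
    source: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")

    def select_chain(self, chain_id: str) -> "StructureModel":
        keep = self.chain == chain_id
        if not keep.any():
            raise ValueError(f"chain {chain_id!r} not present; have {sorted(set(self.chain))}")
        return StructureModel(
            self.chain[keep], self.res_id[keep], self.res_name[keep], self.coords[keep],
            source=self.source,
        )


@dataclass
class DomainDefinition:
    """Inclusive residue-number windows of the two domains.

    Defaults match the tandem-PDZ construct boundaries: PDZ1 residues
    2-107, PDZ2 residues 108-208.
    """

    pdz1_range: tuple[int, int] = (2, 107)
    pdz2_range: tuple[int, int] = (108, 208)

    def __post_init__(self) -> None:
        a, b = self.pdz1_range, self.pdz2_range
        if a[0] > a[1] or b[0] > b[1] or not (a[1] < b[0] or b[1] < a[0]):
            raise ValueError("domain residue ranges must be ordered and disjoint")


@dataclass
class HingeResult:
    rmsd_pdz2_A: float
    rotation_deg: float
    rotation_axis: np.ndarray
    n_matched_atoms: int


@dataclass
class ModeOverlap:
    mode_rank: int                # 1 = lowest nonzero frequency
    frequency_sq: float
    overlap: float


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

def _model_from_atoms(atoms, source: str) -> StructureModel:
    atoms = atoms[~struc.filter_solvent(atoms)]
    atoms = atoms[struc.filter_amino_acids(atoms)]
    ca = atoms[atoms.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValueError(f"no CA atoms found in {source}")
    # one CA per (chain, residue): keep the first after altloc resolution
    seen: set[tuple[str, int]] = set()
    keep = np.zeros(ca.array_length(), dtype=bool)
    for i in range(ca.array_length()):
        key = (str(ca.chain_id[i]), int(ca.res_id[i]))
        if key not in seen:
            seen.add(key)
            keep[i] = True
    ca = ca[keep]
    return StructureModel(
        chain=np.asarray(ca.chain_id, dtype=object),
        res_id=np.asarray(ca.res_id, dtype=int),
        res_name=np.asarray(ca.res_name, dtype=object),
        coords=np.asarray(ca.coord, dtype=float),
        source=source,
    )


def read_structure(path: str | Path) -> StructureModel:
    """Read CA atoms from a PDB file.

    Alternate locations are resolved to the highest-occupancy copy,
    waters are dropped, and residues lacking a CA are skipped.  A
    malformed file raises with the offending line number when it can be
    identified.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6].strip() in {"ATOM", "HETATM"} and len(line.rstrip("\n")) < 54:
            raise ValueError(f"{path}: malformed coordinate record at line {lineno}")
    try:
        pdb = pdbio.PDBFile.read(io.StringIO(text))
        atoms = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises several parse error types
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc
    return _model_from_atoms(atoms, source=str(path))


def fetch_pdb(pdb_id: str, out_dir: str | Path, timeout: float = 30.0) -> Path:
    """Download a PDB entry from RCSB to ``out_dir`` (requires network)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dest = out_dir / f"{pdb_id.upper()}.pdb"
    if not dest.exists():
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            dest.write_bytes(resp.read())
    return dest


# ---------------------------------------------------------------------------
# residue matching and superposition
# ---------------------------------------------------------------------------

def _domain_coords(model: StructureModel, rng: tuple[int, int]) -> dict[int, np.ndarray]:
    lo, hi = rng
    sel = (model.res_id >= lo) & (model.res_id <= hi)
    return {int(r): c for r, c in zip(model.res_id[sel], model.coords[sel])}


def match_common_ca(
    a: StructureModel, b: StructureModel, dom: DomainDefinition
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pair CA coordinates present in both models, per domain.

    Crystal structures routinely have unresolved residues, so pairing is
    restricted to residue numbers resolved in both models within each
    domain window.  Fewer than 3 common residues in a domain raises.
    """
    out = {}
    for name, rng in (("pdz1", dom.pdz1_range), ("pdz2", dom.pdz2_range)):
        ca_a = _domain_coords(a, rng)
        ca_b = _domain_coords(b, rng)
        common = sorted(set(ca_a) & set(ca_b))
        if len(common) < 3:
            raise ValueError(
                f"only {len(common)} common residues in domain {name} ({rng}); need >= 3"
            )
        out[name] = (
            np.array([ca_a[r] for r in common]),
            np.array([ca_b[r] for r in common]),
        )
    return out


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition (Kabsch) of paired point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the
    rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("need matched point sets with at least 3 points")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) point set: rotation ill-defined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def rotation_angle_axis(rot: np.ndarray) -> tuple[float, np.ndarray]:
    """Angle (deg, in [0, 180]) and unit axis of a proper rotation matrix."""
    cos_th = (np.trace(rot) - 1.0) / 2.0
    angle = float(np.degrees(np.arccos(np.clip(cos_th, -1.0, 1.0))))
    w, v = np.linalg.eig(rot)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    axis = axis / np.linalg.norm(axis)
    # orient the axis so the rotation about it is by +angle
    sin_part = np.array([rot[2, 1] - rot[1, 2], rot[0, 2] - rot[2, 0], rot[1, 0] - rot[0, 1]])
    if np.dot(sin_part, axis) < 0:
        axis = -axis
    return angle, axis


def hinge_metrics(a: StructureModel, b: StructureModel, dom: DomainDefinition | None = None) -> HingeResult:
    """Inter-domain hinge metrics between two conformations.

    Structure ``b`` is superposed onto ``a`` using domain-1 CA atoms
    only; the domain-2 RMSD is then measured directly in that frame (no
    second fit), and the effective hinge rotation is the best-fit rigid
    rotation mapping domain 2 of ``a`` onto domain 2 of ``b``.
    """
    dom = dom or DomainDefinition()
    pairs = match_common_ca(a, b, dom)
    d1_a, d1_b = pairs["pdz1"]
    d2_a, d2_b = pairs["pdz2"]

    rot1, trans1, _ = superpose(d1_b, d1_a)        # bring b into a's frame
    d2_b_in_a = d2_b @ rot1.T + trans1
    rmsd_pdz2 = float(np.sqrt(np.mean(np.sum((d2_b_in_a - d2_a) ** 2, axis=1))))

    rot2, _, _ = superpose(d2_a, d2_b_in_a)        # hinge rotation in the anchor frame
    angle, axis = rotation_angle_axis(rot2)
    return HingeResult(
        rmsd_pdz2_A=rmsd_pdz2,
        rotation_deg=angle,
        rotation_axis=axis,
        n_matched_atoms=d1_a.shape[0] + d2_a.shape[0],
    )


# ---------------------------------------------------------------------------
# elastic-network normal modes
# ---------------------------------------------------------------------------

def _anm_hessian(coords: np.ndarray, cutoff_A: float) -> np.ndarray:
    n = coords.shape[0]
    hess = np.zeros((3 * n, 3 * n))
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    contact = (dist > 0) & (dist <= cutoff_A)
    for i in range(n):
        for j in range(i + 1, n):
            if not contact[i, j]:
                continue
            d = diff[i, j]
            block = -np.outer(d, d) / (dist[i, j] ** 2)
            hess[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            hess[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
            hess[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
            hess[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return hess


def enm_modes(coords: np.ndarray, cutoff_A: float = 10.0, n_modes: int = 3):
    """Lowest nonzero-frequency modes of an anisotropic network model.

    Unit springs connect CA pairs within ``cutoff_A``.  The six
    rigid-body modes (near-zero eigenvalues) are removed by the
    magnitude gap; the next ``n_modes`` orthonormal modes are returned
    as ``(modes, frequencies_sq)`` with ``modes[k]`` of shape (N, 3).

    A disconnected contact graph (stray eigenvalues in the rigid-body
    band) raises with a suggestion to increase the cutoff.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 atoms for normal modes")
    hess = _anm_hessian(coords, cutoff_A)
    vals, vecs = eigh(hess)
    tol = max(vals.max(), 1.0) * 1e-9
    n_zero = int(np.sum(vals < tol))
    # a 3D body has 6 rigid modes (5 if collinear); extra zeros mean the
    # spring network is split into disconnected pieces
    if n_zero > 6:
        raise ValueError(
            f"{n_zero} zero modes found (at most 6 rigid-body modes expected): "
            f"contact graph is disconnected at cutoff {cutoff_A} A; increase the cutoff"
        )
    first = n_zero
    last = min(first + n_modes, 3 * n)
    modes = [vecs[:, k].reshape(n, 3) for k in range(first, last)]
    return modes, vals[first:last]


def mode_overlap(modes, displacement: np.ndarray, frequencies_sq=None) -> list[ModeOverlap]:
    """Normalized projections of a displacement onto each mode.

    ``overlap_k = |<m_k, dr>| / (|m_k| |dr|)``; the displacement is the
    matched closed-minus-open CA difference after anchor-domain
    superposition.
    """
    disp = np.asarray(displacement, dtype=float).ravel()
    norm = np.linalg.norm(disp)
    if norm == 0:
        raise ValueError("zero displacement: overlap undefined")
    out = []
    for k, m in enumerate(modes):
        mv = np.asarray(m, dtype=float).ravel()
        if mv.size != disp.size:
            raise ValueError("mode and displacement dimensions differ")
        overlap = float(abs(mv @ disp) / (np.linalg.norm(mv) * norm))
        freq = float(frequencies_sq[k]) if frequencies_sq is not None else float("nan")
        out.append(ModeOverlap(mode_rank=k + 1, frequency_sq=freq, overlap=overlap))
    return out
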