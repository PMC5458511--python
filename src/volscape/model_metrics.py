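"""Atomic-model analyses: segment B-factor truncation and ring geometry.

Two map-quality-driven analyses of a deposited atomic model:

* **Segment B-factor classification** — chains are cut into consecutive
  windows of five residues; the mean atomic B-factor of each window decides
  how much structural detail the local density supports: side chains are kept
  only below 110 A^2, windows between 110 and 150 A^2 (inclusive) are
  truncated to poly-alanine, and windows above 150 A^2 are removed entirely.
* **Ring hexagon angles** — six labeled C-alpha atoms around a hexameric
  ATPase ring are projected onto a plane and connected into a closed hexagon;
  the inner angle at each vertex measures how far the ring deviates from
  perfect six-fold symmetry (120 degrees everywhere).

Models are read and written with gemmi (PDB and mmCIF).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "read_model",
    "write_model",
    "SegmentReport",
    "Segment",
    "RingReport",
    "segment_bfactor_classify",
    "apply_truncation",
    "ring_hexagon_angles",
]

FULL, POLY_ALA, REMOVED = "full_side_chains", "poly_ala", "removed"
_BACKBONE_PLUS_CB = {"N", "CA", "C", "O", "CB"}


def read_model(path) -> gemmi.Structure:
    """Read a PDB or mmCIF model (format from the file contents/extension)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def write_model(structure: gemmi.Structure, path) -> None:
    """Write in the format implied by the extension (.pdb or .cif/.mmcif)."""
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        structure.make_mmcif_document().write_file(str(path))
    else:
        structure.write_pdb(str(path))


@dataclass
class Segment:
    chain: str
    start: int  # residue seqid
    end: int
    n_residues: int
    mean_b: float
    klass: str


@dataclass
class SegmentReport:
    segments: list[Segment]
    window: int
    t_full: float
    t_poly_ala: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.segments])

    def counts(self) -> dict:
        out = {FULL: 0, POLY_ALA: 0, REMOVED: 0}
        for s in self.segments:
            out[s.klass] += 1
        return out


def _classify(mean_b: float, t_full: float, t_poly: float) -> str:
    # boundary rule: exactly t_full or t_poly -> poly_ala ("between" inclusive)
    if mean_b < t_full:
        return FULL
    if mean_b <= t_poly:
        return POLY_ALA
    return REMOVED


def segment_bfactor_classify(
    structure: gemmi.Structure,
    window: int = 5,
    t_full: float = 110.0,
    t_poly_ala: float = 150.0,
) -> SegmentReport:
    """Classify non-overlapping residue windows by mean atomic B-factor.

    Windows of ``window`` consecutive residues start from each chain's first
    modeled residue; a trailing shorter window is classified by its own mean.
    The mean runs over every atom in the window.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    segments = []
    model = structure[0]
    for chain in model:
        residues = list(chain)
        if not residues or all(len(r) == 0 for r in residues):
            continue
        for i in range(0, len(residues), window):
            chunk = residues[i : i + window]
            bvals = [a.b_iso for r in chunk for a in r]
            if not bvals:
                continue
            mean_b = float(np.mean(bvals))
            segments.append(
                Segment(
                    chain=chain.name,
                    start=chunk[0].seqid.num,
                    end=chunk[-1].seqid.num,
                    n_residues=len(chunk),
                    mean_b=mean_b,
                    klass=_classify(mean_b, t_full, t_poly_ala),
                )
            )
    return SegmentReport(segments, window, t_full, t_poly_ala)


def apply_truncation(structure: gemmi.Structure, report: SegmentReport) -> gemmi.Structure:
    """Enforce a segment report on a copy of the model.

    Full segments are untouched; poly-alanine segments keep N/CA/C/O/CB and
    are renamed ALA (glycine keeps no CB, having none); removed segments are
    deleted.
    """
    st = structure.clone()
    lookup: dict[str, list[Segment]] = {}
    for seg in report.segments:
        lookup.setdefault(seg.chain, []).append(seg)

    def seg_of(chain_name: str, seqid: int) -> Segment | None:
        return next(
            (s for s in lookup.get(chain_name, []) if s.start <= seqid <= s.end), None
        )

    model = st[0]
    for chain in model:
        for i in range(len(chain) - 1, -1, -1):
            res = chain[i]
            seg = seg_of(chain.name, res.seqid.num)
            if seg is None or seg.klass == FULL:
                continue
            if seg.klass == REMOVED:
                del chain[i]
                continue
            doomed = [(a.name, a.altloc) for a in res if a.name not in _BACKBONE_PLUS_CB]
            for name, altloc in doomed:
                res.remove_atom(name, altloc if altloc else "*")
            res.name = "ALA"
    st.remove_empty_chains()
    st.setup_entities()
    return st


@dataclass
class RingReport:
    labels: list[tuple[str, int, str]]
    points: np.ndarray  # (6, 3) original Calpha coordinates, A
    projected: np.ndarray  # (6, 2) coordinates in the ring plane
    inner_angles: np.ndarray  # (6,) degrees
    max_deviation: float  # max |angle - 120| degrees

    @property
    def angle_sum(self) -> float:
        return float(self.inner_angles.sum())


def _atom_position(structure: gemmi.Structure, chain: str, seqid: int, atom: str) -> np.ndarray:
    model = structure[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise KeyError(f"no chain {chain!r} in the model")
    for res in ch:
        if res.seqid.num == seqid:
            a = res.find_atom(atom, "*")
            if a is None:
                raise KeyError(f"atom {atom} missing in {chain}/{res.name} {seqid}")
            return np.array([a.pos.x, a.pos.y, a.pos.z])
    raise KeyError(f"no residue {seqid} in chain {chain}")


def ring_hexagon_angles(
    structure: gemmi.Structure,
    selections: list[tuple[str, int, str]],
    axis=None,
) -> RingReport:
    """Inner angles of the hexagon through six labeled C-alpha atoms.

    Points are projected onto the least-squares plane (or the plane normal to
    ``axis`` if given), connected in the given subunit order, and the interior
    angle at each vertex is computed from the adjacent edges. Reflex vertices
    of non-convex rings report angles above 180 degrees, using the polygon's
    signed area for orientation; a convex hexagon's angles sum to 720.
    """
    if len(selections) != 6:
        raise ValueError("exactly six (chain, residue, atom) selections required")
    pts = np.array([_atom_position(structure, *sel) for sel in selections])
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if axis is not None:
        normal = np.asarray(axis, dtype=float)
        normal = normal / np.linalg.norm(normal)
        u = np.cross(normal, [1.0, 0.0, 0.0])
        if np.linalg.norm(u) < 1e-8:
            u = np.cross(normal, [0.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(normal, u)
        basis = np.stack([u, v])
    else:
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[1] < 1e-9:
            raise ValueError("degenerate ring: points are collinear")
        basis = vt[:2]
    p2 = centered @ basis.T
    if np.linalg.matrix_rank(p2 - p2.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("degenerate ring: projected points are collinear")
    # signed area fixes the traversal orientation so reflex angles exceed 180
    x, y = p2[:, 0], p2[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    orient = -1.0 if area2 > 0 else 1.0
    angles = np.empty(6)
    for i in range(6):
        a, b, c = p2[(i - 1) % 6], p2[i], p2[(i + 1) % 6]
        e1, e2 = a - b, c - b
        cross = e1[0] * e2[1] - e1[1] * e2[0]
        dot = e1 @ e2
        ang = np.degrees(np.arctan2(orient * cross, dot))
        if ang < 0:
            ang += 360.0
        angles[i] = ang
    return RingReport(
        labels=list(selections),
        points=pts,
        projected=p2,
        inner_angles=angles,
        max_deviation=float(np.max(np.abs(angles - 120.0))),
    )
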