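"""Conformer ensembles, trajectory subsampling, ring superposition and dihedrals.

An ensemble is an ordered set of conformers (Cartesian coordinates, Å) with
normalized population weights p_i.  The paramagnetic center is attached to
each conformer by least-squares (Kabsch) superposition of a glucose-ring
template onto the reducing-end ring, after which a fixed metal-offset vector
expressed in the template frame is carried along.  Glycosidic torsion angles
are computed as signed IUPAC dihedrals.

Multi-model PDB files (MODEL/ENDMDL) are read and written through biotite;
residue labels are mapped to 3-letter PDB chemical-component codes on write
and back on read.  The lanthanide position is stored as a HETATM named "LN".
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .torsions import TorsionSeries, wrap_deg

__all__ = [
    "Conformer",
    "Ensemble",
    "RingTemplate",
    "RigidTransform",
    "LinkageDefinition",
    "DEFAULT_GM2_LINKAGES",
    "read_ensemble",
    "write_ensemble",
    "subsample_plan",
    "SubsamplePlan",
    "kabsch",
    "superpose_ring",
    "place_metal",
    "dihedral",
    "glycosidic_torsions",
    "read_linkage_definitions",
    "write_torsion_table",
    "read_torsion_table",
]

#: residue-label ↔ PDB chemical-component code mapping used on write/read
_RES_TO_PDB = {"Glc": "GLC", "Gal": "GAL", "GalNAc": "NGA", "Neu5Ac": "SIA"}
_PDB_TO_RES = {v: k for k, v in _RES_TO_PDB.items()}

_METAL_ATOM = "LN"
_METAL_RES = "LN"


@dataclass
class Conformer:
    """Labelled Cartesian coordinates (Å) of one conformer.

    ``labels`` holds (residue_label, atom_label) pairs, unique within the
    conformer; ``coords`` is the matching (N, 3) array.  ``metal_position``
    is set by :func:`place_metal`.
    """

    labels: list[tuple[str, str]]
    coords: np.ndarray
    metal_position: np.ndarray | None = None
    _index: dict[tuple[str, str], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.labels), 3):
            raise ValueError("coords must be (n_atoms, 3) matching labels")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        self._index = {}
        for i, key in enumerate(self.labels):
            if key in self._index:
                raise ValueError(f"duplicate atom {key}")
            self._index[key] = i
        if self.metal_position is not None:
            self.metal_position = np.asarray(self.metal_position, dtype=float)
            if self.metal_position.shape != (3,):
                raise ValueError("metal_position must be a 3-vector")

    def index(self, residue: str, atom: str) -> int:
        try:
            return self._index[(residue, atom)]
        except KeyError:
            raise KeyError(f"atom {atom!r} of residue {residue!r} not present") from None

    def position(self, residue: str, atom: str) -> np.ndarray:
        return self.coords[self.index(residue, atom)]

    def with_metal(self, metal_position: np.ndarray) -> "Conformer":
        return Conformer(list(self.labels), self.coords.copy(),
                         np.asarray(metal_position, dtype=float))


@dataclass
class Ensemble:
    """Ordered conformers with normalized population weights p_i."""

    conformers: list[Conformer]
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.conformers) < 1:
            raise ValueError("ensemble needs at least one conformer")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.conformers),):
            raise ValueError("one weight per conformer required")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")

    @classmethod
    def uniform(cls, conformers: list[Conformer]) -> "Ensemble":
        n = len(conformers)
        return cls(conformers, np.full(n, 1.0 / n))

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass
class RingTemplate:
    """Six-atom ring template plus a metal offset in the template frame.

    ``atom_labels`` name the ring atoms of ``residue_label`` used for the
    superposition (default: the glucose ring C1, C2, C3, C4, C5, O5);
    ``metal_offset`` is the lanthanide position in the template frame (Å).
    """

    atom_labels: list[str]
    coords: np.ndarray
    metal_offset: np.ndarray
    residue_label: str = "Glc"

    def __post_init__(self) -> None:
        if len(self.atom_labels) != 6:
            raise ValueError("ring template requires exactly six atoms")
        self.coords = np.asarray(self.coords, dtype=float)
        self.metal_offset = np.asarray(self.metal_offset, dtype=float)
        if self.coords.shape != (6, 3) or self.metal_offset.shape != (3,):
            raise ValueError("template coords must be (6,3), offset (3,)")
        c = self.coords - self.coords.mean(axis=0)
        if np.linalg.matrix_rank(c, tol=1e-8) < 2:
            raise ValueError("template atoms are collinear")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "residue_label": self.residue_label,
            "atom_labels": self.atom_labels,
            "coords": self.coords.tolist(),
            "metal_offset": self.metal_offset.tolist(),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RingTemplate":
        d = json.loads(Path(path).read_text())
        return cls(
            atom_labels=list(d["atom_labels"]),
            coords=np.asarray(d["coords"], dtype=float),
            metal_offset=np.asarray(d["metal_offset"], dtype=float),
            residue_label=d.get("residue_label", "Glc"),
        )


@dataclass
class RigidTransform:
    """Proper rigid transform x ↦ R x + t with the superposition RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# multi-model PDB I/O (biotite)

def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB (one MODEL per conformer)."""
    import biotite.structure as struc
    from biotite.structure.io import pdb as bpdb

    first = ensemble.conformers[0]
    for k, c in enumerate(ensemble.conformers):
        if c.labels != first.labels:
            raise ValueError(f"conformer {k} has a different atom set")
    has_metal = [c.metal_position is not None for c in ensemble.conformers]
    if any(has_metal) and not all(has_metal):
        raise ValueError("metal must be set on all conformers or none")
    with_metal = all(has_metal)

    labels = list(first.labels)
    res_ids, res_names, atom_names, elements = [], [], [], []
    rid, prev = 0, None
    for res, atom in labels:
        if res != prev:
            rid += 1
            prev = res
        res_ids.append(rid)
        res_names.append(_RES_TO_PDB.get(res, res[:3].upper()))
        atom_names.append(atom)
        elements.append(atom[0].upper())
    if with_metal:
        res_ids.append(rid + 1)
        res_names.append(_METAL_RES)
        atom_names.append(_METAL_ATOM)
        elements.append("LA")

    n_atoms = len(atom_names)
    stack = struc.AtomArrayStack(len(ensemble), n_atoms)
    stack.chain_id = np.full(n_atoms, "A")
    stack.res_id = np.asarray(res_ids)
    stack.res_name = np.asarray(res_names)
    stack.atom_name = np.asarray(atom_names)
    stack.element = np.asarray(elements)
    stack.hetero = np.asarray([False] * len(labels) + [True] * int(with_metal))
    coords = np.stack([
        np.vstack([c.coords, c.metal_position]) if with_metal else c.coords
        for c in ensemble.conformers
    ])
    stack.coord = coords
    f = bpdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def read_ensemble(path: str | Path) -> Ensemble:
    """Read a multi-model PDB into an Ensemble with uniform weights 1/N.

    Models must share one atom set in one order; a model with missing or
    extra atoms is a validation error.  A HETATM named "LN" is interpreted
    as the lanthanide position.
    """
    from biotite.structure.io import pdb as bpdb

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    f = bpdb.PDBFile.read(str(path))
    n_models = f.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no models found")
    try:
        stack = f.get_structure(model=None)
    except Exception as exc:  # biotite raises on inconsistent atom sets
        raise ValueError(f"{path}: inconsistent models ({exc})") from exc

    metal_mask = stack.atom_name == _METAL_ATOM
    labels = [
        (_PDB_TO_RES.get(rn, rn), an)
        for rn, an in zip(stack.res_name[~metal_mask], stack.atom_name[~metal_mask])
    ]
    conformers = []
    for m in range(stack.stack_depth()):
        coords = stack.coord[m]
        metal = coords[metal_mask][0] if metal_mask.any() else None
        conformers.append(Conformer(list(labels), coords[~metal_mask], metal))
    return Ensemble.uniform(conformers)


# ---------------------------------------------------------------------------
# trajectory subsampling

@dataclass
class SubsamplePlan:
    """Retained snapshot indices per run (0-based, post-discard) and total."""

    count: int
    indices: list[np.ndarray]


def subsample_plan(
    n_runs: int,
    run_length_ps: int,
    snapshot_interval_ps: int,
    discard_ps: int,
    stride_snapshots: int,
) -> SubsamplePlan:
    """Plan equal-interval extraction of conformers from repeated MD runs.

    Each run of ``run_length_ps`` records a snapshot every
    ``snapshot_interval_ps``; the first ``discard_ps`` of each run are
    discarded (equilibration) and every ``stride_snapshots``-th remaining
    snapshot is retained (the last of each stride block, so the count is
    n_runs × floor(((run_length − discard)/interval)/stride)).
    """
    for name, v in (("n_runs", n_runs), ("run_length_ps", run_length_ps),
                    ("snapshot_interval_ps", snapshot_interval_ps),
                    ("stride_snapshots", stride_snapshots)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if discard_ps < 0 or discard_ps >= run_length_ps:
        raise ValueError("discard_ps must be in [0, run_length_ps)")
    per_run = (run_length_ps - discard_ps) // snapshot_interval_ps
    idx = np.arange(stride_snapshots - 1, per_run, stride_snapshots)
    return SubsamplePlan(count=n_runs * idx.size,
                         indices=[idx.copy() for _ in range(n_runs)])


# ---------------------------------------------------------------------------
# rigid superposition and metal placement

def kabsch(from_points: np.ndarray, to_points: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping one point set onto another.

    Standard Kabsch algorithm (SVD of the covariance, sign of the smallest
    singular vector flipped if the rotation would be improper).
    """
    P = np.asarray(from_points, dtype=float)
    Q = np.asarray(to_points, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    resid = P @ R.T + t - Q
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(R, t, rmsd)


def superpose_ring(
    conformer: Conformer,
    template: RingTemplate,
    rmsd_warn_threshold: float = 0.5,
) -> RigidTransform:
    """Superpose the ring template onto the conformer's reducing-end ring.

    All six template atom labels must exist in the conformer's
    ``template.residue_label`` residue; an RMSD above the threshold flags a
    distorted ring with a warning (the transform is still returned).
    """
    try:
        ring = np.array([
            conformer.position(template.residue_label, a)
            for a in template.atom_labels
        ])
    except KeyError as exc:
        raise ValueError(f"ring atom missing for superposition: {exc}") from exc
    tf = kabsch(template.coords, ring)
    if tf.rmsd > rmsd_warn_threshold:
        warnings.warn(
            f"ring superposition rmsd {tf.rmsd:.3f} Å exceeds "
            f"{rmsd_warn_threshold} Å; conformer flagged"
        )
    return tf


def place_metal(conformer: Conformer, template: RingTemplate) -> Conformer:
    """Attach the lanthanide: transform the template metal offset onto the
    conformer via the ring superposition and store it as ``metal_position``."""
    tf = superpose_ring(conformer, template)
    return conformer.with_metal(tf.apply(template.metal_offset))


# ---------------------------------------------------------------------------
# dihedrals and glycosidic torsions

def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC dihedral p1-p2-p3-p4 in degrees, range (−180, 180].

    Sign follows the right-hand rule about the p2→p3 axis (clockwise positive
    looking from p2 to p3); cis = 0°, trans = 180°.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-10:
            raise ValueError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear points: dihedral undefined")
    y = float(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)))
    x = float(n1 @ n2)
    ang = math.degrees(math.atan2(y, x))
    return float(wrap_deg(ang))


@dataclass(frozen=True)
class LinkageDefinition:
    """Named (Φ, ψ) atom quadruples; each atom is (residue_label, atom_label)."""

    name: str
    phi: tuple[tuple[str, str], ...]
    psi: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.phi) != 4 or len(self.psi) != 4:
            raise ValueError("phi and psi each need four atoms")


#: GM2 tetrasaccharide linkage torsions.  Hexose-hexose linkages use
#: Φ = H1–C1–O'4–C'4, ψ = C1–O'4–C'4–H'4; the sialyl linkage uses
#: Φ = C1–C2–O'3–C'3, ψ = C2–O'3–C'3–H'3 (primed atoms on the inner residue).
DEFAULT_GM2_LINKAGES: tuple[LinkageDefinition, ...] = (
    LinkageDefinition(
        "GalNAc-Gal",
        phi=(("GalNAc", "H1"), ("GalNAc", "C1"), ("Gal", "O4"), ("Gal", "C4")),
        psi=(("GalNAc", "C1"), ("Gal", "O4"), ("Gal", "C4"), ("Gal", "H4")),
    ),
    LinkageDefinition(
        "Neu5Ac-Gal",
        phi=(("Neu5Ac", "C1"), ("Neu5Ac", "C2"), ("Gal", "O3"), ("Gal", "C3")),
        psi=(("Neu5Ac", "C2"), ("Gal", "O3"), ("Gal", "C3"), ("Gal", "H3")),
    ),
    LinkageDefinition(
        "Gal-Glc",
        phi=(("Gal", "H1"), ("Gal", "C1"), ("Glc", "O4"), ("Glc", "C4")),
        psi=(("Gal", "C1"), ("Glc", "O4"), ("Glc", "C4"), ("Glc", "H4")),
    ),
)


def read_linkage_definitions(path: str | Path) -> tuple[LinkageDefinition, ...]:
    """Load linkage definitions from JSON: a list of
    {"name": ..., "phi": [[res, atom] × 4], "psi": [[res, atom] × 4]}."""
    data = json.loads(Path(path).read_text())
    return tuple(
        LinkageDefinition(
            name=d["name"],
            phi=tuple((r, a) for r, a in d["phi"]),
            psi=tuple((r, a) for r, a in d["psi"]),
        )
        for d in data
    )


def glycosidic_torsions(
    ensemble: Ensemble,
    definitions: tuple[LinkageDefinition, ...] = DEFAULT_GM2_LINKAGES,
) -> dict[str, TorsionSeries]:
    """Per-conformer (Φ, ψ) series for each defined glycosidic linkage."""
    out: dict[str, TorsionSeries] = {}
    for link in definitions:
        phis = np.empty(len(ensemble))
        psis = np.empty(len(ensemble))
        for i, conf in enumerate(ensemble.conformers):
            try:
                pts_phi = [conf.position(r, a) for r, a in link.phi]
                pts_psi = [conf.position(r, a) for r, a in link.psi]
            except KeyError as exc:
                raise ValueError(
                    f"linkage {link.name!r}, conformer {i}: {exc}"
                ) from exc
            phis[i] = dihedral(*pts_phi)
            psis[i] = dihedral(*pts_psi)
        out[link.name] = TorsionSeries(link.name, phis, psis)
    return out


def write_torsion_table(series: dict[str, TorsionSeries], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for name, ts in series.items():
        for i in range(len(ts)):
            rows.append({
                "conformer_index": i, "linkage": name,
                "phi_deg": repr(float(ts.phi_deg[i])),
                "psi_deg": repr(float(ts.psi_deg[i])),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_torsion_table(path: str | Path) -> dict[str, TorsionSeries]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = {}
    for name, grp in df.groupby("linkage", sort=False):
        grp = grp.sort_values("conformer_index")
        out[str(name)] = TorsionSeries(
            str(name), grp["phi_deg"].to_numpy(float), grp["psi_deg"].to_numpy(float)
        )
    return out
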