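"""Synthetic GM2-tetrasaccharide ensembles and PCS datasets with known truth.

The experimental analysis validates an MD-derived conformational ensemble
against lanthanide-induced PCSs; the trajectories behind it are not
deposited.  This module stands in for them: it generates tetrasaccharide
conformers whose three glycosidic linkages sample configurable wrapped-
Gaussian (Φ, ψ) mixtures — defaulting to the cluster statistics reported for
the GM2 glycan — articulates idealized rigid pyranose fragments so the
requested torsions are reproduced exactly by the built coordinates, places
the lanthanide by glucose-ring alignment, and simulates observed PCSs from a
known ground-truth Δχ tensor with additive Gaussian noise.  Every stage of
the real pipeline can therefore be tested against known truth.

All randomness is driven by explicit integer seeds; identical inputs give
bitwise-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import (
    Conformer,
    Ensemble,
    RingTemplate,
    dihedral,
    place_metal,
)
from .pcs import ChiTensor, ensemble_pcs
from .shift_tables import Nucleus, PCSMeasurement, ResonanceAssignment
from .torsions import TorsionSeries, wrap_deg

__all__ = [
    "MixtureComponent",
    "LinkageMixture",
    "GM2_MIXTURES",
    "GeneratorConfig",
    "sample_torsions",
    "build_conformer",
    "fragment_templates",
    "default_ring_template",
    "default_nuclei",
    "generate_ensemble",
    "simulate_pcs",
]

_BOND_CO = 1.41          # glycosidic C–O bond length, Å
_ANGLE_COC = 109.47      # tetrahedral angle at the glycosidic oxygen, deg
_RING_CC = 1.52          # ring C–C bond length, Å
_BOND_CH = 1.09          # C–H bond length, Å


# ---------------------------------------------------------------------------
# torsion mixtures

@dataclass(frozen=True)
class MixtureComponent:
    """One wrapped-Gaussian (Φ, ψ) cluster: means, SDs (deg) and weight."""

    mean_phi_deg: float
    mean_psi_deg: float
    sd_phi_deg: float
    sd_psi_deg: float
    weight: float

    def __post_init__(self) -> None:
        if self.sd_phi_deg <= 0 or self.sd_psi_deg <= 0:
            raise ValueError("component SDs must be positive")
        if self.weight <= 0:
            raise ValueError("component weights must be positive")


@dataclass(frozen=True)
class LinkageMixture:
    """Wrapped-Gaussian mixture over (Φ, ψ) for one glycosidic linkage."""

    components: tuple[MixtureComponent, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {total}")

    @classmethod
    def of(cls, *comps: tuple[float, float, float, float, float]) -> "LinkageMixture":
        return cls(tuple(MixtureComponent(*c) for c in comps))


#: Default study conditions: the (Φ, ψ) cluster statistics reported for the
#: GM2 tetrasaccharide's three linkages (circular mean ± SD, degrees).  The
#: source reports no cluster populations; the weights below order the
#: clusters as reported, major first (sialyl linkage: the (−174, −32)
#: cluster is described as the major one, (−69, −6) as metastable).
GM2_MIXTURES: dict[str, LinkageMixture] = {
    "GalNAc-Gal": LinkageMixture.of((30.0, 17.0, 12.0, 13.0, 1.0)),
    "Neu5Ac-Gal": LinkageMixture.of(
        (-174.0, -32.0, 11.0, 11.0, 0.65),
        (-69.0, -6.0, 10.0, 14.0, 0.35),
    ),
    "Gal-Glc": LinkageMixture.of(
        (-34.0, -32.0, 15.0, 17.0, 0.50),
        (40.0, -4.0, 11.0, 20.0, 0.30),
        (37.0, -167.0, 21.0, 19.0, 0.20),
    ),
}


def sample_torsions(
    mixture: LinkageMixture, n: int, seed: int | np.random.Generator,
    name: str = "linkage",
) -> TorsionSeries:
    """Draw n (Φ, ψ) pairs: component by weight, then independent wrapped
    Gaussians in Φ and ψ.  Reproducible per seed."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    weights = np.array([c.weight for c in mixture.components])
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    mphi = np.array([c.mean_phi_deg for c in mixture.components])[comp]
    mpsi = np.array([c.mean_psi_deg for c in mixture.components])[comp]
    sphi = np.array([c.sd_phi_deg for c in mixture.components])[comp]
    spsi = np.array([c.sd_psi_deg for c in mixture.components])[comp]
    phi = wrap_deg(rng.normal(mphi, sphi))
    psi = wrap_deg(rng.normal(mpsi, spsi))
    return TorsionSeries(name, phi, psi)


# ---------------------------------------------------------------------------
# rigid fragments

def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def _chair_ring() -> np.ndarray:
    """Idealized ⁴C₁-like six-membered ring: alternating ±z pucker."""
    h = 0.25
    rho = math.sqrt(_RING_CC**2 - 4 * h * h)  # adjacent distance = _RING_CC
    pts = []
    for i in range(6):
        a = math.radians(60.0 * i)
        pts.append([rho * math.cos(a), rho * math.sin(a), h * (-1) ** i])
    return np.array(pts)


def _substituent_dirs(ring: np.ndarray, i: int) -> tuple[np.ndarray, np.ndarray]:
    """(axial-like, equatorial-like) unit directions at ring atom i."""
    p = ring[i]
    u = _normalize(ring[(i - 1) % 6] - p)
    v = _normalize(ring[(i + 1) % 6] - p)
    bisector = _normalize(u + v)
    normal = _normalize(np.cross(u, v))
    if normal[2] < 0:
        normal = -normal
    ax = normal * (-1.0) ** i
    eq = _normalize(-bisector - 0.45 * ax)
    return ax, eq


def _hexose_fragment() -> dict[str, np.ndarray]:
    """Idealized hexopyranose: ring C1..C5+O5, H1..H5, O3/O4, C6+H6a/H6b,
    and a virtual anomeric-oxygen direction O1v used for articulation."""
    ring = _chair_ring()
    names = ["C1", "C2", "C3", "C4", "C5", "O5"]
    atoms = {n: ring[i] for i, n in enumerate(names)}
    for i, n in enumerate(names[:5]):  # carbons only
        ax, eq = _substituent_dirs(ring, i)
        num = n[1:]
        atoms[f"H{num}"] = ring[i] + _BOND_CH * ax
        if n == "C1":
            atoms["O1v"] = ring[i] + _BOND_CO * eq
        elif n in ("C3", "C4"):
            atoms[f"O{num}"] = ring[i] + 1.43 * eq
        elif n == "C5":
            c6 = ring[i] + _RING_CC * eq
            atoms["C6"] = c6
            d = _normalize(c6 - ring[i])
            perp = _normalize(np.cross(d, [0.0, 0.0, 1.0]))
            atoms["H6a"] = c6 + _BOND_CH * _normalize(d + 0.9 * perp)
            atoms["H6b"] = c6 + _BOND_CH * _normalize(d - 0.9 * perp)
    return atoms


def _neu5ac_fragment() -> dict[str, np.ndarray]:
    """Simplified N-acetylneuraminic acid: ring C2..C6+O6 with the carboxyl
    carbon C1 on C2, ring protons, and the C7–C9 glycerol arm.  Chemically
    approximate; geometrically exact for the atoms the pipeline touches."""
    ring = _chair_ring()
    names = ["C2", "C3", "C4", "C5", "C6", "O6"]
    atoms = {n: ring[i] for i, n in enumerate(names)}
    for i, n in enumerate(names[:5]):
        ax, eq = _substituent_dirs(ring, i)
        num = n[1:]
        if n == "C2":
            atoms["C1"] = ring[i] + _RING_CC * ax
            atoms["O2v"] = ring[i] + _BOND_CO * eq
        elif n == "C3":
            atoms["H3a"] = ring[i] + _BOND_CH * ax
            atoms["H3b"] = ring[i] + _BOND_CH * eq
        elif n in ("C4", "C5"):
            atoms[f"H{num}"] = ring[i] + _BOND_CH * ax
        elif n == "C6":
            atoms["H6"] = ring[i] + _BOND_CH * ax
            c7 = ring[i] + _RING_CC * eq
            atoms["C7"] = c7
            d = _normalize(c7 - ring[i])
            e = _normalize(d + np.array([0.0, 0.0, 0.8]))
            c8 = c7 + _RING_CC * e
            atoms["C8"] = c8
            g = _normalize(e + np.array([0.5, 0.0, 0.0]))
            c9 = c8 + _RING_CC * g
            atoms["C9"] = c9
            perp = _normalize(np.cross(d, e))
            atoms["H7"] = c7 + _BOND_CH * perp
            atoms["H8"] = c8 + _BOND_CH * perp
            atoms["H9a"] = c9 + _BOND_CH * perp
            atoms["H9b"] = c9 - _BOND_CH * perp
    return atoms


def fragment_templates() -> dict[str, dict[str, np.ndarray]]:
    """Rigid per-residue coordinate templates (Å) for the four residues.

    Atoms named "O1v"/"O2v" are virtual: they mark the direction of the
    anomeric substituent used to articulate the glycosidic linkage and are
    dropped from built conformers.
    """
    hexose = _hexose_fragment()
    return {
        "Glc": {k: v.copy() for k, v in hexose.items()},
        "Gal": {k: v.copy() for k, v in hexose.items()},
        "GalNAc": {k: v.copy() for k, v in hexose.items()},
        "Neu5Ac": _neu5ac_fragment(),
    }


def default_ring_template(metal_distance: float = 8.0) -> RingTemplate:
    """Glucose-ring template with the lanthanide offset on the anomeric side.

    The tag is attached at the reducing end; the averaged metal position is
    modelled ``metal_distance`` Å from the ring centroid along the direction
    of the anomeric substituent.  The published averaged tag coordinates are
    not available, so the offset is configurable.
    """
    glc = _hexose_fragment()
    labels = ["C1", "C2", "C3", "C4", "C5", "O5"]
    coords = np.array([glc[a] for a in labels])
    centroid = coords.mean(axis=0)
    direction = _normalize(glc["O1v"] - centroid)
    return RingTemplate(
        atom_labels=labels,
        coords=coords,
        metal_offset=centroid + metal_distance * direction,
        residue_label="Glc",
    )


# ---------------------------------------------------------------------------
# articulation

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          dist: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |d−c| = dist, angle(d,c,b) = angle_deg and
    dihedral(d,c,b,a) = torsion_deg (natural-extension reference frame)."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = _normalize(c - b)
    n = _normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = dist * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(chi),
         math.sin(theta) * math.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _rotation_between(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking direction u to direction w."""
    a, b = _normalize(u), _normalize(w)
    v = np.cross(a, b)
    cos = float(a @ b)
    if cos < -1.0 + 1e-12:
        # antiparallel: rotate pi about any axis perpendicular to a
        axis = _normalize(np.cross(a, [1.0, 0.0, 0.0])
                          if abs(a[0]) < 0.9 else np.cross(a, [0.0, 1.0, 0.0]))
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + cos)


def _axis_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = _normalize(axis)
    t = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)


#: linkage topology: (linkage name, parent residue, (O, C, H) parent atoms,
#: child residue, (A, B, virtual-O) child atoms) — A–B–O–C is Φ, B–O–C–H is ψ.
_TOPOLOGY = (
    ("Gal-Glc", "Glc", ("O4", "C4", "H4"), "Gal", ("H1", "C1", "O1v")),
    ("GalNAc-Gal", "Gal", ("O4", "C4", "H4"), "GalNAc", ("H1", "C1", "O1v")),
    ("Neu5Ac-Gal", "Gal", ("O3", "C3", "H3"), "Neu5Ac", ("C1", "C2", "O2v")),
)

_RESIDUE_ORDER = ("Glc", "Gal", "GalNAc", "Neu5Ac")


def _place_child(
    child: dict[str, np.ndarray],
    a_label: str,
    b_label: str,
    ov_label: str,
    o_pos: np.ndarray,
    c_pos: np.ndarray,
    h_pos: np.ndarray,
    phi: float,
    psi: float,
) -> dict[str, np.ndarray]:
    """Rigidly place a child residue so that dihedral(A,B,O,C) = Φ and
    dihedral(B,O,C,H) = ψ, with a 1.41 Å B–O bond and tetrahedral B–O–C."""
    b_target = _nerf(h_pos, c_pos, o_pos, _BOND_CO, _ANGLE_COC, psi)
    R1 = _rotation_between(child[ov_label] - child[b_label], o_pos - b_target)
    origin = child[b_label]
    placed = {k: R1 @ (v - origin) + b_target for k, v in child.items()}
    current = dihedral(placed[a_label], b_target, o_pos, c_pos)
    delta = wrap_deg(phi - current)
    axis = o_pos - b_target
    for attempt_angle in (delta, -delta):
        R2 = _axis_rotation(axis, float(attempt_angle))
        cand = {k: R2 @ (v - b_target) + b_target for k, v in placed.items()}
        got = dihedral(cand[a_label], b_target, o_pos, c_pos)
        if abs(wrap_deg(got - phi)) < 1e-7:
            return cand
    raise RuntimeError("torsion placement failed to converge")  # pragma: no cover


def build_conformer(
    torsions: dict[str, tuple[float, float]],
    templates: dict[str, dict[str, np.ndarray]] | None = None,
) -> Conformer:
    """Articulate the four rigid residue fragments at the requested torsions.

    ``torsions`` maps each linkage name to its (Φ, ψ) in degrees.  The
    glycosidic dihedrals of the returned coordinates, recomputed with
    :func:`glycopcs.geometry.dihedral`, equal the requested values within
    1e-6 degrees.  Deterministic: identical inputs give identical coordinates.
    """
    templates = templates if templates is not None else fragment_templates()
    placed: dict[str, dict[str, np.ndarray]] = {
        "Glc": {k: v.copy() for k, v in templates["Glc"].items()}
    }
    for name, parent, (o, c, h), child_res, (a, b, ov) in _TOPOLOGY:
        if name not in torsions:
            raise ValueError(f"missing torsions for linkage {name!r}")
        phi, psi = torsions[name]
        par = placed[parent]
        child = templates[child_res]
        for lbl, frag, res in ((o, par, parent), (c, par, parent),
                               (h, par, parent), (a, child, child_res),
                               (b, child, child_res), (ov, child, child_res)):
            if lbl not in frag:
                raise ValueError(f"template {res!r} lacks linkage atom {lbl!r}")
        placed[child_res] = _place_child(
            {k: v.copy() for k, v in child.items()},
            a, b, ov, par[o], par[c], par[h], phi, psi,
        )

    labels: list[tuple[str, str]] = []
    coords: list[np.ndarray] = []
    for res in _RESIDUE_ORDER:
        for atom in sorted(placed[res]):
            if atom.endswith("v"):  # virtual articulation atoms
                continue
            labels.append((res, atom))
            coords.append(placed[res][atom])
    return Conformer(labels, np.array(coords))


# ---------------------------------------------------------------------------
# full generator

def _default_truth_tensor() -> ChiTensor:
    return ChiTensor.from_principal(-20.0, -5.0)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic ensemble.

    Defaults emulate the reported analysis: 2000 conformers (uniform weight
    0.0005), the printed (Φ, ψ) cluster mixtures, a ground-truth tensor of
    Δχ_ax = −20, Δχ_rh = −5 (10⁻³² m³; placeholder magnitudes — the actual
    tag Δχ values are unpublished) and 0.01 ppm additive PCS noise.
    """

    n_conformers: int = 2000
    mixtures: dict[str, LinkageMixture] = field(
        default_factory=lambda: dict(GM2_MIXTURES))
    ground_truth_tensor: ChiTensor = field(default_factory=_default_truth_tensor)
    noise_sd_ppm: float = 0.01
    seed: int = 0
    metal_template: RingTemplate = field(default_factory=default_ring_template)

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be ≥ 1")
        if self.noise_sd_ppm < 0:
            raise ValueError("noise_sd_ppm must be non-negative")
        missing = {name for name, *_ in _TOPOLOGY} - set(self.mixtures)
        if missing:
            raise ValueError(f"mixtures missing for linkage(s) {sorted(missing)}")


def generate_ensemble(
    config: GeneratorConfig, out_prefix: str | Path | None = None
) -> tuple[Ensemble, dict]:
    """Generate the synthetic ensemble and its ground-truth record.

    Torsions are drawn per linkage from the configured mixtures, conformers
    articulated and the metal placed by glucose-ring alignment; weights are
    uniform 1/N.  With ``out_prefix`` the ensemble is written as
    ``<prefix>.pdb`` and the ground truth as ``<prefix>_truth.json``.
    """
    ss = np.random.SeedSequence(config.seed)
    link_names = [name for name, *_ in _TOPOLOGY]
    child_seeds = ss.spawn(len(link_names))
    series = {
        name: sample_torsions(
            config.mixtures[name], config.n_conformers,
            np.random.default_rng(s), name=name,
        )
        for name, s in zip(link_names, child_seeds)
    }
    templates = fragment_templates()
    conformers = []
    for i in range(config.n_conformers):
        torsions = {
            name: (float(series[name].phi_deg[i]), float(series[name].psi_deg[i]))
            for name in link_names
        }
        conf = build_conformer(torsions, templates)
        conformers.append(place_metal(conf, config.metal_template))
    ensemble = Ensemble.uniform(conformers)

    truth = {
        "seed": config.seed,
        "n_conformers": config.n_conformers,
        "noise_sd_ppm": config.noise_sd_ppm,
        "tensor": config.ground_truth_tensor.to_dict(),
        "tensor_note": (
            "synthetic placeholder magnitudes; the experimental tag's "
            "Δχ values are unpublished"
        ),
        "mixtures": {
            name: [
                {
                    "mean_phi_deg": c.mean_phi_deg, "mean_psi_deg": c.mean_psi_deg,
                    "sd_phi_deg": c.sd_phi_deg, "sd_psi_deg": c.sd_psi_deg,
                    "weight": c.weight,
                }
                for c in mix.components
            ]
            for name, mix in config.mixtures.items()
        },
    }
    if out_prefix is not None:
        from .geometry import write_ensemble

        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_ensemble(ensemble, prefix.with_suffix(".pdb"))
        Path(f"{prefix}_truth.json").write_text(json.dumps(truth, indent=2))
    return ensemble, truth


def default_nuclei(
    conformer: Conformer, max_n: int | None = None
) -> list[ResonanceAssignment]:
    """Deterministic nucleus selection: every C/H atom of the conformer,
    ordered by residue (reducing end outward) then atom label, optionally
    truncated to the first ``max_n``."""
    res_rank = {r: i for i, r in enumerate(_RESIDUE_ORDER)}
    picks = [
        (res_rank.get(res, 99), atom, res)
        for res, atom in conformer.labels
        if atom[0] in "CH"
    ]
    picks.sort()
    out = [
        ResonanceAssignment(
            res, atom, Nucleus.C13 if atom.startswith("C") else Nucleus.H1
        )
        for _, atom, res in picks
    ]
    return out[:max_n] if max_n is not None else out


def simulate_pcs(
    ensemble: Ensemble,
    tensor: ChiTensor,
    nuclei: Sequence[ResonanceAssignment],
    noise_sd_ppm: float,
    seed: int,
    paramagnetic_metal: str = "Tm",
    diamagnetic_metal: str = "La",
) -> list[PCSMeasurement]:
    """Simulated observed PCSs: ensemble forward model plus N(0, sd²) noise."""
    if noise_sd_ppm < 0:
        raise ValueError("noise_sd_ppm must be non-negative")
    preds = ensemble_pcs(ensemble, tensor, nuclei)
    values = np.array([p.delta_delta_calc_ppm for p in preds])
    if noise_sd_ppm > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd_ppm, values.size)
    return [
        PCSMeasurement(
            assignment=a,
            paramagnetic_metal=paramagnetic_metal,
            diamagnetic_metal=diamagnetic_metal,
            delta_delta_ppm=float(v),
        )
        for a, v in zip(nuclei, values)
    ]
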