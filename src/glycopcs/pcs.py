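"""Pseudocontact-shift forward model, Δχ tensor algebra and Q-factor.

The PCS of a nucleus at polar position (r, θ, φ) relative to the metal center
and the principal frame of the magnetic-susceptibility anisotropy tensor is

    Δδ[ppm] = 10⁴/(12π r³) · [Δχ_ax (3cos²θ − 1) + (3/2) Δχ_rh sin²θ cos2φ]

with r in Å and Δχ in 10⁻³² m³ (the standard unit convention making the three
units consistent).  The frame-independent form is the quadratic contraction

    Δδ[ppm] = 10⁴/(4π) · vᵀ χ v / r⁵ ,   v = r_nucleus − r_metal,

linear in the five independent components of the traceless symmetric χ.
Ensemble predictions are population-weighted sums over conformers, and
agreement with observation is scored by Q = rms(Δδ_calc − Δδ_obs)/rms(Δδ_obs).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import Ensemble
from .shift_tables import Nucleus, PCSMeasurement, ResonanceAssignment

__all__ = [
    "PREFACTOR_POLAR",
    "PREFACTOR_CARTESIAN",
    "ChiTensor",
    "PrincipalView",
    "PolarPosition",
    "PCSPrediction",
    "pcs_polar",
    "pcs_cartesian",
    "pcs_basis",
    "ensemble_pcs",
    "q_factor",
    "tensor_to_principal",
    "write_predictions",
    "read_predictions",
]

#: 10⁴/(12π): ppm prefactor of the polar form (r in Å, Δχ in 1e-32 m³).
PREFACTOR_POLAR = 1.0e4 / (12.0 * math.pi)
#: 10⁴/(4π): ppm prefactor of the Cartesian quadratic form.
PREFACTOR_CARTESIAN = 1.0e4 / (4.0 * math.pi)


@dataclass(frozen=True)
class PolarPosition:
    """Nucleus position in the tensor principal frame: r (Å), θ, φ (deg)."""

    r: float
    theta_deg: float
    phi_deg: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be positive")
        if not 0.0 <= self.theta_deg <= 180.0:
            raise ValueError("theta must lie in [0, 180] degrees")


@dataclass(frozen=True)
class PrincipalView:
    """Principal-frame parameters: Δχ_ax, Δχ_rh (1e-32 m³), ZYZ Euler (deg)."""

    delta_chi_ax: float
    delta_chi_rh: float
    euler_zyz_deg: tuple[float, float, float]


@dataclass(frozen=True)
class PCSPrediction:
    """Back-calculated PCS (ppm) for one assignment."""

    assignment: ResonanceAssignment
    delta_delta_calc_ppm: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_delta_calc_ppm):
            raise ValueError("predicted PCS must be finite")


class ChiTensor:
    """Traceless symmetric magnetic-susceptibility anisotropy tensor.

    Stored as the Cartesian 3×3 matrix in units of 10⁻³² m³ (five independent
    components).  Constructed from components, from the principal-frame view,
    or from a full matrix (validated symmetric and traceless).
    """

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("tensor must be 3x3")
        scale = max(1.0, float(np.abs(m).max()))
        if np.abs(m - m.T).max() > 1e-9 * scale:
            raise ValueError("tensor must be symmetric")
        if abs(np.trace(m)) > 1e-9 * scale:
            raise ValueError("tensor must be traceless")
        m = 0.5 * (m + m.T)
        m = m - np.eye(3) * (np.trace(m) / 3.0)  # exact to rounding
        self.matrix = m

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_components(cls, xx: float, yy: float, xy: float,
                        xz: float, yz: float) -> "ChiTensor":
        """Build from the five independent components (zz = −xx − yy)."""
        zz = -(xx + yy)
        return cls(np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]]))

    @classmethod
    def from_principal(
        cls,
        delta_chi_ax: float,
        delta_chi_rh: float,
        euler_zyz_deg: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "ChiTensor":
        """Build from (Δχ_ax, Δχ_rh) and a ZYZ Euler rotation of the frame."""
        chi_zz = 2.0 * delta_chi_ax / 3.0
        chi_xx = -chi_zz / 2.0 + delta_chi_rh / 2.0
        chi_yy = -chi_zz / 2.0 - delta_chi_rh / 2.0
        D = np.diag([chi_xx, chi_yy, chi_zz])
        R = Rotation.from_euler("ZYZ", list(euler_zyz_deg), degrees=True).as_matrix()
        return cls(R @ D @ R.T)

    # -- views --------------------------------------------------------------
    @property
    def components(self) -> np.ndarray:
        """The five independent components (xx, yy, xy, xz, yz)."""
        m = self.matrix
        return np.array([m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2]])

    def principal(self) -> PrincipalView:
        """Eigendecompose into (Δχ_ax, Δχ_rh, ZYZ Euler angles).

        Eigenvalues are assigned |χ_zz| ≥ |χ_yy| ≥ |χ_xx| (ties broken by
        descending signed value); Δχ_ax = χ_zz − (χ_xx + χ_yy)/2 and
        Δχ_rh = χ_xx − χ_yy.  Eigenvectors are oriented deterministically
        (first nonzero component positive, right-handed frame).
        """
        vals, vecs = np.linalg.eigh(self.matrix)
        order = sorted(range(3), key=lambda i: (-abs(vals[i]), -vals[i]))
        iz, iy, ix = order[0], order[1], order[2]
        vx, vy = vecs[:, ix].copy(), vecs[:, iy].copy()
        for v in (vx, vy):
            nz = np.nonzero(np.abs(v) > 1e-12)[0]
            if nz.size and v[nz[0]] < 0:
                v *= -1.0
        vz = np.cross(vx, vy)
        R = np.column_stack([vx, vy, vz])
        import warnings

        with warnings.catch_warnings():
            # ZYZ is gimbal-degenerate for axial tensors; the default choice
            # (third angle zero) is fine — any azimuth is equivalent there.
            warnings.simplefilter("ignore", UserWarning)
            euler = Rotation.from_matrix(R).as_euler("ZYZ", degrees=True)
        ax = float(vals[iz] - 0.5 * (vals[ix] + vals[iy]))
        rh = float(vals[ix] - vals[iy])
        return PrincipalView(ax, rh, tuple(float(e) for e in euler))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        m = self.matrix
        p = self.principal()
        return {
            "cartesian_1e-32_m3": {
                "xx": m[0, 0], "yy": m[1, 1], "zz": m[2, 2],
                "xy": m[0, 1], "xz": m[0, 2], "yz": m[1, 2],
            },
            "principal": {
                "delta_chi_ax": p.delta_chi_ax,
                "delta_chi_rh": p.delta_chi_rh,
                "euler_zyz_deg": list(p.euler_zyz_deg),
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChiTensor":
        d = json.loads(Path(path).read_text())
        c = d["cartesian_1e-32_m3"]
        return cls.from_components(c["xx"], c["yy"], c["xy"], c["xz"], c["yz"])

    def __repr__(self) -> str:
        p = self.principal()
        return (f"ChiTensor(delta_chi_ax={p.delta_chi_ax:.4g}, "
                f"delta_chi_rh={p.delta_chi_rh:.4g})")


def pcs_polar(
    pos: PolarPosition | None = None,
    delta_chi_ax: float = 0.0,
    delta_chi_rh: float = 0.0,
    *,
    r: float | None = None,
    theta_deg: float | None = None,
    phi_deg: float | None = None,
) -> float:
    """PCS (ppm) from a polar position in the tensor principal frame.

    Accepts either a :class:`PolarPosition` or explicit r/theta/phi keywords.
    """
    if pos is None:
        pos = PolarPosition(r, theta_deg, phi_deg)
    th = math.radians(pos.theta_deg)
    ph = math.radians(pos.phi_deg)
    ang = (delta_chi_ax * (3.0 * math.cos(th) ** 2 - 1.0)
           + 1.5 * delta_chi_rh * math.sin(th) ** 2 * math.cos(2.0 * ph))
    return PREFACTOR_POLAR / pos.r**3 * ang


def pcs_basis(v: np.ndarray) -> np.ndarray:
    """Geometric coefficients of the five tensor components (xx, yy, xy, xz, yz).

    ``v`` is the metal→nucleus vector (Å), or an (..., 3) array of them;
    the contraction ``pcs_basis(v) @ tensor.components`` equals the PCS in ppm.
    """
    v = np.asarray(v, dtype=float)
    x, y, z = v[..., 0], v[..., 1], v[..., 2]
    r2 = x * x + y * y + z * z
    if np.any(r2 < 1e-12):
        raise ValueError("nucleus coincides with the metal position")
    f = PREFACTOR_CARTESIAN / r2**2.5
    return np.stack(
        [f * (x * x - z * z), f * (y * y - z * z),
         f * 2 * x * y, f * 2 * x * z, f * 2 * y * z],
        axis=-1,
    )


def pcs_cartesian(
    nucleus_position: np.ndarray,
    metal_position: np.ndarray,
    tensor: ChiTensor,
) -> float | np.ndarray:
    """PCS (ppm) from Cartesian positions (Å); frame-independent form.

    ``nucleus_position`` may be a single 3-vector or an (N, 3) array.
    """
    v = np.asarray(nucleus_position, dtype=float) - np.asarray(
        metal_position, dtype=float
    )
    out = pcs_basis(v) @ tensor.components
    return float(out) if out.ndim == 0 else out


def ensemble_pcs(
    ensemble: Ensemble,
    tensor: ChiTensor,
    nuclei: Sequence[ResonanceAssignment],
) -> list[PCSPrediction]:
    """Population-weighted PCS predictions: Δδ_calc = Σᵢ pᵢ Δδ(conformer i)."""
    total = np.zeros(len(nuclei))
    for i, (conf, w) in enumerate(zip(ensemble.conformers, ensemble.weights)):
        if conf.metal_position is None:
            raise ValueError(f"conformer {i} has no metal position")
        pos = np.array([
            conf.position(a.residue_label, a.atom_label) for a in nuclei
        ])
        total += w * pcs_cartesian(pos, conf.metal_position, tensor)
    return [
        PCSPrediction(a, float(d)) for a, d in zip(nuclei, total)
    ]


def q_factor(
    obs: Sequence[PCSMeasurement], calc: Sequence[PCSPrediction]
) -> float:
    """Q = rms(Δδ_calc − Δδ_obs) / rms(Δδ_obs) over matched assignments."""
    cmap = {p.assignment: p.delta_delta_calc_ppm for p in calc}
    pairs = [(m.delta_delta_ppm, cmap[m.assignment])
             for m in obs if m.assignment in cmap]
    if not pairs:
        raise ValueError("no matched assignments between observed and calculated")
    o = np.array([p[0] for p in pairs])
    c = np.array([p[1] for p in pairs])
    rms_obs = float(np.sqrt(np.mean(o**2)))
    if rms_obs == 0.0:
        raise ValueError("all observed PCSs are zero; Q undefined")
    return float(np.sqrt(np.mean((c - o) ** 2)) / rms_obs)


def tensor_to_principal(tensor: ChiTensor) -> PrincipalView:
    """Principal-frame view (Δχ_ax, Δχ_rh, ZYZ Euler angles) of a tensor."""
    return tensor.principal()


def write_predictions(
    predictions: Sequence[PCSPrediction], path: str | Path
) -> None:
    import pandas as pd

    pd.DataFrame([
        {
            "residue": p.assignment.residue_label,
            "atom": p.assignment.atom_label,
            "nucleus": p.assignment.nucleus.value,
            "pcs_calc_ppm": repr(p.delta_delta_calc_ppm),
        }
        for p in predictions
    ]).to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> list[PCSPrediction]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        PCSPrediction(
            ResonanceAssignment(
                str(r["residue"]).strip(), str(r["atom"]).strip(),
                Nucleus.parse(r["nucleus"]),
            ),
            float(r["pcs_calc_ppm"]),
        )
        for _, r in df.iterrows()
    ]
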