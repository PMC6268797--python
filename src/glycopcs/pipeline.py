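"""End-to-end orchestration: extract → ensemble → metal → fit → Q → clusters.

A single JSON configuration drives the whole analysis; each stage logs under
a stage-scoped prefix, writes its table/JSON outputs into the configured
output directory, and contributes to a run report (Q-factor, fitted tensor,
cluster summaries, file manifest with SHA-256 checksums, per-stage timing).
Runs are deterministic given (config, seed): two runs produce byte-identical
reports apart from the timing block.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .fit import FitResult, fit_tensor
from .geometry import (
    DEFAULT_GM2_LINKAGES,
    Ensemble,
    RingTemplate,
    glycosidic_torsions,
    place_metal,
    read_ensemble,
    read_linkage_definitions,
    write_ensemble,
    write_torsion_table,
)
from .pcs import ensemble_pcs, q_factor, write_predictions
from .shift_tables import (
    compute_pcs,
    read_pcs_table,
    read_shift_table,
    write_pcs_table,
)
from .synthetic import (
    GeneratorConfig,
    default_nuclei,
    default_ring_template,
    generate_ensemble,
    simulate_pcs,
)
from .torsions import find_clusters

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Validated run configuration.

    Exactly one ensemble source is used: an existing multi-model PDB
    (``ensemble_pdb``) or the synthetic generator (``generator``).  Observed
    PCSs for the tensor fit come from ``obs_pcs`` (a PCS table), from the
    extracted shift tables (``fit_obs="extracted"``), or are simulated from
    the generator's ground truth (``fit_obs="simulate"``, the closure
    configuration).
    """

    outdir: Path
    seed: int = 0
    dia_table: Path | None = None
    para_table: Path | None = None
    obs_pcs: Path | None = None
    fit_obs: str = "simulate"
    ensemble_pdb: Path | None = None
    generator: GeneratorConfig | None = None
    template: RingTemplate = field(default_factory=default_ring_template)
    linkages: tuple = DEFAULT_GM2_LINKAGES
    cluster_bin_deg: float = 5.0
    min_peak_fraction: float = 0.02
    noise_sd_ppm: float | None = None
    n_fit_nuclei: int = 30
    write_ensemble_pdb: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.fit_obs not in {"simulate", "extracted", "table"}:
            raise ValueError(f"invalid fit_obs {self.fit_obs!r}")
        for name in ("dia_table", "para_table", "obs_pcs", "ensemble_pdb"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise ValueError(f"{name} path does not exist: {p}")
        if self.ensemble_pdb is None and self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)
        if (self.dia_table is None) != (self.para_table is None):
            raise ValueError("dia_table and para_table must be given together")
        if self.fit_obs == "extracted" and self.dia_table is None:
            raise ValueError('fit_obs="extracted" requires shift tables')
        if self.fit_obs == "table" and self.obs_pcs is None:
            raise ValueError('fit_obs="table" requires obs_pcs')
        if self.fit_obs == "simulate" and self.generator is None:
            raise ValueError('fit_obs="simulate" requires the generator')

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        gen = None
        if "generator" in d:
            g = dict(d.pop("generator"))
            from .pcs import ChiTensor

            if "ground_truth_tensor" in g:
                t = g["ground_truth_tensor"]
                g["ground_truth_tensor"] = ChiTensor.from_principal(
                    t["delta_chi_ax"], t["delta_chi_rh"],
                    t.get("euler_zyz_deg", (0.0, 0.0, 0.0)),
                )
            gen = GeneratorConfig(**g)
        if "template" in d:
            d["template"] = RingTemplate.from_json(d.pop("template_path")) \
                if "template_path" in d else RingTemplate(**d.pop("template"))
        if "linkages_path" in d:
            d["linkages"] = read_linkage_definitions(d.pop("linkages_path"))
        return cls(generator=gen, **d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return (and write) the run report."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed}
    timing: dict[str, float] = {}
    manifest: dict[str, str] = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            logger.info("[%s] start", name)
            try:
                result = fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
            timing[name] = time.perf_counter() - t0
            logger.info("[%s] done (%.2f s)", name, timing[name])
            return result
        return wrap

    # -- extract observed PCSs from paired shift tables ---------------------
    extracted = None
    if config.dia_table is not None:
        def _extract():
            dia = read_shift_table(config.dia_table)
            para = read_shift_table(config.para_table)
            pcs = compute_pcs(dia, para)
            path = out / "pcs_observed.tsv"
            write_pcs_table(pcs, path)
            manifest[path.name] = _sha256(path)
            return pcs
        extracted = stage("extract")(_extract)
        report["n_extracted_pcs"] = len(extracted)

    # -- ensemble -----------------------------------------------------------
    def _ensemble() -> Ensemble:
        if config.ensemble_pdb is not None:
            ens = read_ensemble(config.ensemble_pdb)
            if any(c.metal_position is None for c in ens.conformers):
                ens = Ensemble(
                    [place_metal(c, config.template) for c in ens.conformers],
                    ens.weights,
                )
            return ens
        ens, truth = generate_ensemble(config.generator)
        tpath = out / "ensemble_truth.json"
        tpath.write_text(json.dumps(truth, indent=2, sort_keys=True))
        manifest[tpath.name] = _sha256(tpath)
        if config.write_ensemble_pdb:
            epath = out / "ensemble.pdb"
            write_ensemble(ens, epath)
            manifest[epath.name] = _sha256(epath)
        return ens

    ensemble = stage("ensemble")(_ensemble)
    report["n_conformers"] = len(ensemble)
    report["conformer_weight"] = float(ensemble.weights[0])

    # -- observations for the tensor fit ------------------------------------
    def _observations():
        if config.fit_obs == "table":
            return read_pcs_table(config.obs_pcs)
        if config.fit_obs == "extracted":
            return extracted
        noise = (config.noise_sd_ppm if config.noise_sd_ppm is not None
                 else config.generator.noise_sd_ppm)
        nuclei = default_nuclei(ensemble.conformers[0], config.n_fit_nuclei)
        return simulate_pcs(
            ensemble, config.generator.ground_truth_tensor, nuclei,
            noise, config.seed,
        )

    obs = stage("observations")(_observations)
    report["n_fit_obs"] = len(obs)

    # -- tensor fit, back-calculation, Q ------------------------------------
    def _fit() -> FitResult:
        res = fit_tensor(ensemble, obs)
        tpath = out / "fitted_tensor.json"
        res.tensor.to_json(tpath)
        manifest[tpath.name] = _sha256(tpath)
        return res

    fitres = stage("fit")(_fit)
    p = fitres.tensor.principal()
    report["fit"] = {
        "q": fitres.q,
        "n_obs": fitres.n_obs,
        "condition_number": fitres.condition_number,
        "delta_chi_ax": p.delta_chi_ax,
        "delta_chi_rh": p.delta_chi_rh,
    }

    def _backcalc():
        nuclei = [m.assignment for m in obs]
        preds = ensemble_pcs(ensemble, fitres.tensor, nuclei)
        path = out / "pcs_calculated.tsv"
        write_predictions(preds, path)
        manifest[path.name] = _sha256(path)
        return preds

    preds = stage("backcalc")(_backcalc)
    report["q"] = q_factor(obs, preds)

    # -- torsions and clusters ----------------------------------------------
    def _torsions():
        series = glycosidic_torsions(ensemble, config.linkages)
        path = out / "torsions.tsv"
        write_torsion_table(series, path)
        manifest[path.name] = _sha256(path)
        return series

    series = stage("torsions")(_torsions)

    def _cluster():
        result = {}
        for name, ts in series.items():
            r = find_clusters(
                ts, bin_deg=config.cluster_bin_deg,
                min_peak_fraction=config.min_peak_fraction,
            )
            result[name] = {
                "n_clusters": len(r.clusters),
                "unassigned_fraction": r.unassigned_fraction,
                "clusters": [c.as_dict() for c in r.clusters],
            }
        path = out / "clusters.json"
        path.write_text(json.dumps(result, indent=2, sort_keys=True))
        manifest[path.name] = _sha256(path)
        return result

    report["clusters"] = stage("cluster")(_cluster)
    report["manifest"] = manifest
    report["timing_s"] = timing

    rpath = out / "report.json"
    rpath.write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("report written to %s (Q = %.3g)", rpath, report["q"])
    return report
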