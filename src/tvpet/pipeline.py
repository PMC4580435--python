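"""End-to-end pipeline driver: simulate -> rebin -> reconstruct -> evaluate.

A pipeline config is a plain dict (typically loaded from JSON).  Any
contiguous suffix of the stage chain may be requested; later stages read
the artifacts written by earlier ones (or pre-existing files), so a
reconstruct-only run on an externally provided sinogram container works.
Every artifact header carries the accumulated provenance chain, and a rerun
with the same config and seed produces byte-identical outputs.
"""

from __future__ import annotations

import os
from typing import Dict, List

import numpy as np
import pandas as pd

from . import containers
from .bosvs import SolverConfig, bosvs_reconstruct
from .core import ObliqueSinogramSet, Sinogram2D, as_sinogram_stack
from .dfrecon import df_reconstruct
from .fore import RebinConfig, rebin_fore, rebin_ssrb
from .metrics import all_region_mask, bias, pooled_variance, variance
from .synthetic import (
    PhantomSpec,
    apply_counting_noise,
    default_geometry,
    forward_project,
    make_oblique_set,
    make_phantom,
    preset_spec,
)

__all__ = ["run_pipeline", "DependencyError", "STAGES"]

STAGES = ("simulate", "rebin", "reconstruct", "evaluate")


class DependencyError(RuntimeError):
    """An upstream artifact required by a stage is missing."""


def _require(path: str, stage: str) -> str:
    if not os.path.exists(path):
        raise DependencyError(
            f"stage {stage!r} needs missing artifact {path!r}; run the "
            "upstream stage or provide the file"
        )
    return path


def _phantom_spec(config: dict) -> PhantomSpec:
    sim = config.get("simulate", {})
    if "phantom_spec" in sim:
        return PhantomSpec.from_dict(sim["phantom_spec"])
    preset = sim.get("phantom", "brain_like")
    kwargs = {}
    if "grid_size" in sim:
        kwargs["grid_size"] = int(sim["grid_size"])
    return preset_spec(preset, **kwargs)


def run_pipeline(config: dict, outdir: str) -> Dict[str, str]:
    """Execute the configured stage chain; returns artifact paths.

    ``config`` keys: ``stages`` (list, a contiguous suffix of
    simulate/rebin/reconstruct/evaluate), ``seed``, and per-stage parameter
    blocks ``simulate`` / ``rebin`` / ``reconstruct`` / ``evaluate``.
    """
    stages = list(config.get("stages", STAGES))
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    order = [STAGES.index(s) for s in stages]
    if any(b <= a for a, b in zip(order, order[1:])):
        raise ValueError(
            "stages must follow the order simulate -> rebin -> reconstruct "
            "-> evaluate"
        )

    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 0))
    prov: List[dict] = [{"step": "config", "seed": seed}]
    paths = {
        "truth": os.path.join(outdir, "truth.img"),
        "oblique": os.path.join(outdir, "oblique.sino"),
        "sinogram": os.path.join(outdir, "sinogram.sino"),
        "recon_df": os.path.join(outdir, "recon_df.img"),
        "recon_bosvs": os.path.join(outdir, "recon_bosvs.img"),
        "report": os.path.join(outdir, "report.csv"),
    }
    artifacts: Dict[str, str] = {}

    if "simulate" in stages:
        sim = config.get("simulate", {})
        spec = _phantom_spec(config)
        truth = make_phantom(spec)
        geometry = default_geometry(
            spec.grid_size,
            n_s=sim.get("n_s"),
            n_phi=sim.get("n_phi"),
            n_rings=int(sim.get("n_rings", 4)),
            delta_values=tuple(sim.get("delta_values", (0.0,))),
        )
        step = {
            "step": "simulate",
            "phantom": spec.preset_name or "custom",
            "grid_size": spec.grid_size,
            "counts": sim.get("counts"),
            "seed": seed,
        }
        prov = prov + [step]
        containers.write_image(truth, paths["truth"], provenance=prov)
        artifacts["truth"] = paths["truth"]
        if len(geometry.delta_values) > 1:
            volume = np.repeat(truth.values[:, :, None], geometry.n_slices, axis=2)
            obset = make_oblique_set(volume, geometry)
            if sim.get("counts"):
                obset = apply_counting_noise(
                    obset, float(sim["counts"]), seed, preserve_scale=True
                )
            containers.write_sinogram(obset, paths["oblique"], provenance=prov)
            artifacts["oblique"] = paths["oblique"]
        else:
            sino = forward_project(truth, geometry)
            if sim.get("counts"):
                sino = apply_counting_noise(
                    sino, float(sim["counts"]), seed, preserve_scale=True
                )
            containers.write_sinogram(sino, paths["sinogram"], provenance=prov)
            artifacts["sinogram"] = paths["sinogram"]

    if "rebin" in stages:
        reb = config.get("rebin", {})
        src = reb.get("input") or artifacts.get("oblique") or paths["oblique"]
        obset = containers.read_sinogram(_require(src, "rebin"))
        if not isinstance(obset, ObliqueSinogramSet):
            raise DependencyError("rebin expects a 4-axis oblique container")
        method = reb.get("method", "fore")
        if method == "fore":
            cfg = RebinConfig(
                omega_limit=int(reb.get("omega_limit", 1)),
                k_limit=int(reb.get("k_limit", 1)),
                delta_max=float(reb.get("delta_max", np.inf)),
            )
            stack = rebin_fore(obset, cfg)
        elif method == "ssrb":
            stack = rebin_ssrb(obset, delta_max=float(reb.get("delta_max", np.inf)))
        else:
            raise ValueError(f"unknown rebin method {method!r}")
        prov = prov + [{"step": "rebin", "method": method}]
        mid = stack[len(stack) // 2]
        containers.write_sinogram(mid, paths["sinogram"], provenance=prov)
        artifacts["sinogram"] = paths["sinogram"]

    if "reconstruct" in stages:
        rec = config.get("reconstruct", {})
        src = rec.get("input") or artifacts.get("sinogram") or paths["sinogram"]
        sino = containers.read_sinogram(_require(src, "reconstruct"))
        if isinstance(sino, ObliqueSinogramSet):
            sino = as_sinogram_stack(sino)[sino.n_z // 2]
        grid = int(rec.get("grid_size", sino.n_s))
        pad = int(rec.get("pad_factor", 4))
        methods = rec.get("methods", ["df", "bosvs"])
        prov = prov + [{"step": "reconstruct", "grid_size": grid, "pad": pad,
                        "methods": list(methods)}]
        if "df" in methods:
            img = df_reconstruct(sino, grid, pad)
            containers.write_image(img, paths["recon_df"], provenance=prov)
            artifacts["recon_df"] = paths["recon_df"]
        if "bosvs" in methods:
            cfg = SolverConfig(
                alpha=float(rec.get("alpha", 1.5)),
                beta=float(rec.get("beta", 10.0)),
                delta_init=float(rec.get("delta_init", 0.8)),
                max_iter=int(rec.get("max_iter", 100)),
            )
            img, history = bosvs_reconstruct(sino, cfg, grid, pad)
            containers.write_image(img, paths["recon_bosvs"], provenance=prov)
            artifacts["recon_bosvs"] = paths["recon_bosvs"]
            pd.DataFrame(history).to_csv(
                os.path.join(outdir, "bosvs_history.csv"), index=False
            )
            artifacts["history"] = os.path.join(outdir, "bosvs_history.csv")

    if "evaluate" in stages:
        ev = config.get("evaluate", {})
        truth_path = ev.get("truth") or artifacts.get("truth") or paths["truth"]
        truth = containers.read_image(_require(truth_path, "evaluate"))
        mask = all_region_mask(truth)
        rows = []
        for method in ("df", "bosvs"):
            key = f"recon_{method}"
            path = ev.get(key) or artifacts.get(key) or paths[key]
            if not os.path.exists(path):
                continue
            img = containers.read_image(path)
            rows.append(
                {
                    "method": method,
                    "region": "all",
                    "bias": bias(img, truth, mask),
                    "variance": pooled_variance(img, truth, mask),
                }
            )
            if truth.roi_map is not None:
                for rid in np.unique(truth.roi_map):
                    if rid <= 0:
                        continue
                    m = truth.roi_map == rid
                    rows.append(
                        {
                            "method": method,
                            "region": int(rid),
                            "bias": bias(img, truth, m),
                            "variance": variance(img, truth, m),
                        }
                    )
        if not rows:
            raise DependencyError("evaluate found no reconstruction artifacts")
        pd.DataFrame(rows).to_csv(paths["report"], index=False)
        artifacts["report"] = paths["report"]

    return artifacts
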