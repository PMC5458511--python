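"""End-to-end driver: align -> PCA -> landscape, plus fixture presets."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .align import align_ensemble
from .config import RunConfig
from .eigenvolumes import fit_pca
from .landscape import build_landscape, find_minima_and_barrier
from .synthetic import (
    EnergyFunctionSpec,
    default_masks,
    default_phantom_spec,
    make_class_ensemble,
    make_two_state_particles,
    render_phantom,
    write_ensemble,
    write_particles,
)
from .volume_io import read_map, read_mask, write_map, write_mask

__all__ = ["run_pipeline", "make_fixtures", "PipelineError", "FIXTURE_PRESETS"]

logger = logging.getLogger(__name__)

# ground-truth rotated fractions for the mixture presets: the three measured
# conditions (control, Oprozomib, Epoxomicin); rotation states 0 and 25 deg
MIXTURE_FRACTIONS = {
    "two_state_mixture_dmso": 0.41,
    "two_state_mixture_oprozomib": 0.13,
    "two_state_mixture_epoxomicin": 0.25,
}
ROTATED_THETA, NONROTATED_THETA = 25.0, 0.0

FIXTURE_PRESETS = ("flat", "harmonic", "double_well") + tuple(MIXTURE_FRACTIONS)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            logger.info("stage %s finished in %.1f s", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute align -> PCA -> landscape -> barrier and write all artifacts.

    Outputs land in ``outdir/run-<config hash>`` so different configurations
    never collide; every artifact directory carries the config hash and seed
    in ``summary.json``. Reruns with the same config and seed are
    byte-identical.
    """
    chash = config.config_hash()
    outdir = Path(config.outdir) / f"run-{chash}"
    outdir.mkdir(parents=True, exist_ok=True)

    reference = read_map(config.reference)
    cp_mask = read_mask(config.cp_mask)
    pca_mask = read_mask(config.pca_mask)

    aligned = _stage("align")(align_ensemble)(
        config.manifest,
        reference,
        cp_mask,
        angular_range=config.align.angular_range,
        angular_step=config.align.angular_step,
        shift_range=config.align.shift_range,
    )
    rows = []
    for cid, t, s in zip(aligned.class_ids, aligned.transforms, aligned.scores):
        r = t.matrix.ravel()
        rows.append(
            {"class_id": cid, **{f"r{i}{j}": r[3 * i + j] for i in range(3) for j in range(3)},
             "tx": t.translation[0], "ty": t.translation[1], "tz": t.translation[2],
             "score": s}
        )
    pd.DataFrame(rows).to_csv(outdir / "transforms.tsv", sep="\t", index=False, float_format="%.6g")
    for cid, vol in zip(aligned.class_ids, aligned.volumes):
        write_map(vol, outdir / f"aligned_class_{int(cid):03d}.mrc")

    decomp = _stage("pca")(fit_pca)(
        aligned, pca_mask, config.pca.n_components, config.pca.count_weighted
    )
    for k, ev in enumerate(decomp.eigenvolumes):
        write_map(ev, outdir / f"eigenvolume_{k + 1}.mrc")
    write_map(decomp.mean_volume, outdir / "mean_volume.mrc")
    coeff_cols = {f"c{k + 1}": decomp.coefficients[:, k] for k in range(decomp.n_components)}
    pd.DataFrame(
        {"class_id": aligned.class_ids, **coeff_cols, "n_particles": aligned.counts}
    ).to_csv(outdir / "coefficients.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        {"component": np.arange(1, decomp.n_components + 1),
         "eigenvalue": decomp.eigenvalues,
         "explained_variance_fraction": decomp.eigenvalues / decomp.total_variance}
    ).to_csv(outdir / "eigenvalues.tsv", sep="\t", index=False, float_format="%.6g")

    k1, k2 = config.landscape.components
    if decomp.n_components < 2:
        raise PipelineError("landscape", ValueError("need at least 2 PCA components"))
    scape = _stage("landscape")(build_landscape)(
        decomp.coefficients,
        aligned.counts,
        components=(k1, k2),
        bins=config.landscape.bins,
        smoothing_sigma=config.landscape.smoothing_sigma,
        cap_empty=config.landscape.cap_empty,
    )
    _write_landscape(scape, outdir)
    report = _stage("barrier")(find_minima_and_barrier)(scape)
    barrier = {
        "minima": [{"bin": list(b), "energy_kT": e} for b, e in report.minima[:20]],
        "n_minima": len(report.minima),
        "barrier_height_kT": None
        if report.barrier_height is None
        else (None if np.isinf(report.barrier_height) else report.barrier_height),
        "disconnected": report.disconnected,
    }
    (outdir / "barrier.json").write_text(json.dumps(barrier, indent=2, sort_keys=True))
    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "n_classes": int(len(aligned.volumes)),
        "total_particles": int(aligned.counts.sum()),
        "explained_variance_fraction": [
            float(v) for v in decomp.eigenvalues / decomp.total_variance
        ],
        "barrier": barrier,
        "outdir": str(outdir),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _write_landscape(scape, outdir: Path) -> None:
    nx, ny = scape.energy.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pd.DataFrame(
        {
            "bin_x": ii.ravel(),
            "bin_y": jj.ravel(),
            "center_x": ((scape.edges_x[:-1] + scape.edges_x[1:]) / 2)[ii.ravel()],
            "center_y": ((scape.edges_y[:-1] + scape.edges_y[1:]) / 2)[jj.ravel()],
            "occupancy": scape.occupancy.ravel(),
            "energy_kT": scape.energy.ravel(),
        }
    ).to_csv(outdir / "landscape.tsv", sep="\t", index=False, float_format="%.6g")
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.pcolormesh(scape.edges_x, scape.edges_y, scape.energy.T, cmap="viridis")
        fig.colorbar(im, ax=ax, label="free energy (kT)")
        ax.set_xlabel(f"eigenvolume coefficient {scape.components[0] + 1}")
        ax.set_ylabel(f"eigenvolume coefficient {scape.components[1] + 1}")
        fig.tight_layout()
        fig.savefig(outdir / "landscape.png", dpi=120, metadata={"Software": "volscape"})
        plt.close(fig)
    except Exception as exc:  # plotting must never sink a run
        logger.warning("could not render landscape.png: %s", exc)


def make_fixtures(preset: str, outdir, seed: int = 0, **overrides) -> Path:
    """Generate a named synthetic dataset under ``outdir``.

    Class-ensemble presets (``flat``, ``harmonic``, ``double_well``) write a
    map-per-class tree with a TSV manifest plus reference and CP/RP masks,
    directly consumable by the alignment stage. Mixture presets write a
    two-state particle stack with truth labels and the two reference maps;
    their ground-truth rotated fractions are the three measured conditions
    (41% control / 13% Oprozomib / 25% Epoxomicin) at a 25-degree separation.
    """
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose one of {FIXTURE_PRESETS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = default_phantom_spec(
        box=overrides.get("box", 48), voxel_size=overrides.get("voxel_size", 4.0), seed=seed
    )
    cp_mask, rp_mask = default_masks(spec)
    if preset in MIXTURE_FRACTIONS:
        particles = make_two_state_particles(
            spec,
            theta_states=(ROTATED_THETA, NONROTATED_THETA),
            fraction_state0=MIXTURE_FRACTIONS[preset],
            n_particles=overrides.get("n_particles", 400),
            snr=overrides.get("snr", 2.0),
            seed=seed,
        )
        truth = write_particles(particles, outdir)
        write_map(render_phantom(spec, ROTATED_THETA), outdir / "ref_rotated.mrc")
        write_map(render_phantom(spec, NONROTATED_THETA), outdir / "ref_nonrotated.mrc")
        return truth
    efun = {
        "flat": EnergyFunctionSpec(kind="flat"),
        "harmonic": EnergyFunctionSpec(kind="harmonic", stiffness=0.02, center=0.0),
        "double_well": EnergyFunctionSpec(
            kind="double_well_barrier", well_centers=(-15.0, 15.0), barrier_height=3.0
        ),
    }[preset]
    ens = make_class_ensemble(
        spec,
        efun,
        n_classes=overrides.get("n_classes", 21),
        total_particles=overrides.get("total_particles", 100_000),
        seed=seed,
    )
    manifest = write_ensemble(ens, outdir)
    write_map(render_phantom(spec, 0.0), outdir / "reference.mrc")
    write_mask(cp_mask, outdir / "cp_mask.mrc")
    write_mask(rp_mask, outdir / "rp_mask.mrc")
    return manifest
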