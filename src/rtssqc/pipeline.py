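"""End-to-end experiment orchestration.

Generates (or loads) reference/test pairs, applies named perturbation
sequences that stand in for contour-editing systems, cleans both members
of every comparison, and computes the displacement summary plus the full
measure suite over the tolerance sweep — both against the original test
contour (expected-identity comparison) and against the reference, with the
original-vs-reference baseline alongside.
"""
from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .displacement import DisplacementSummary, displacement_summary
from .errors import AnalysisError, ConfigError
from .model import ImageGrid, Structure
from .preprocess import clean_structure
from .similarity_mesh import TriangleMesh, structure_to_mesh, surface_measures
from .similarity_polygon import MeasureSet, ToleranceSpec, distances_2d, napl_sweep, vdsc
from .synthetic import (
    PerturbationConfig,
    ShapeSpec,
    make_dataset1,
    make_multi_region,
    perturb,
    preset_systems,
    snap_size_to_slice_lattice,
)

log = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    grid_dx: float = 1.0
    grid_dy: float = 1.0
    grid_dz: float = 2.5
    offset: tuple[float, float, float] = (5.0, 0.0, 0.0)
    cube_size: float = 50.0
    octa_half_diagonal: float = 50.0
    dense_spacing: float = 1.0
    include_multi_region: bool = True
    systems: dict[str, list[PerturbationConfig]] | None = None  # None -> presets
    tolerances: ToleranceSpec = field(default_factory=ToleranceSpec)
    clean: bool = True
    include_mesh: bool = True
    seed: int = 0
    pairs: list[tuple[Structure, Structure]] | None = None  # overrides generation

    def validate(self) -> None:
        if self.systems is not None and not self.systems:
            raise ConfigError("at least one perturbation sequence is required")
        if not self.tolerances.fractions_of_voxel:
            raise ConfigError("tolerance sweep must not be empty")


@dataclass
class ResultsTable:
    """Rows keyed by (structure, simulated system), plus cumulative curves."""

    summary: pd.DataFrame
    long: pd.DataFrame  # per-tolerance long form
    curves: pd.DataFrame
    manifest: dict
    errors: list[dict] = field(default_factory=list)


def compute_measures(
    reference: Structure,
    test: Structure,
    grid: ImageGrid,
    tolerances: ToleranceSpec = ToleranceSpec(),
    include_mesh: bool = True,
    mesh_reference: TriangleMesh | None = None,
    mesh_test: TriangleMesh | None = None,
) -> MeasureSet:
    """The full measure suite for one (reference, test) pair.

    ``mesh_reference`` / ``mesh_test`` allow reusing already-extracted
    meshes across comparisons.
    """
    z_tol = grid.dz / 10.0
    tol_mm = tolerances.resolved_mm(grid)
    napl_map = dict(
        zip(tolerances.fractions_of_voxel, napl_sweep(reference, test, tol_mm, z_tol=z_tol))
    )
    dice = vdsc(reference, test, grid, z_tol=z_tol)
    d2 = distances_2d(reference, test, z_tol=z_tol)
    if include_mesh:
        ma = mesh_reference if mesh_reference is not None else structure_to_mesh(reference, grid)
        mb = mesh_test if mesh_test is not None else structure_to_mesh(test, grid)
        sdsc_mm, mean3d = surface_measures(ma, mb, tol_mm)
        sdsc_map = dict(zip(tolerances.fractions_of_voxel, sdsc_mm.values()))
    else:
        sdsc_map = {frac: float("nan") for frac in tolerances.fractions_of_voxel}
        mean3d = float("nan")
    return MeasureSet(
        napl=napl_map,
        vdsc=dice,
        hd2d_mm=d2.hd2d_mm,
        hd95_2d_mm=d2.hd95_2d_mm,
        hd50_2d_mm=d2.hd50_2d_mm,
        msd2d_mm=d2.msd2d_mm,
        sdsc=sdsc_map,
        msd3d_mm=mean3d,
    )


def _pairs_and_grid(cfg: ExperimentConfig) -> tuple[list[tuple[Structure, Structure]], ImageGrid]:
    if cfg.pairs is not None:
        pairs = cfg.pairs
    else:
        pairs = make_dataset1(
            offset=cfg.offset,
            dz=cfg.grid_dz,
            cube_size=cfg.cube_size,
            octa_half_diagonal=cfg.octa_half_diagonal,
            dense_spacing=cfg.dense_spacing,
        )
        if cfg.include_multi_region:
            spec = ShapeSpec(
                "multi_region",
                size=snap_size_to_slice_lattice(0.6 * cfg.cube_size, cfg.grid_dz),
                dz=cfg.grid_dz,
                separation=0.8 * cfg.cube_size,
            )
            ref = make_multi_region(spec)
            ref.name = "MultiRegion"
            pairs = pairs + [(ref, ref.translated(*cfg.offset))]
    everything = [s for pair in pairs for s in pair]
    grid = ImageGrid.covering(everything, cfg.grid_dx, cfg.grid_dy, cfg.grid_dz, pad_voxels=4)
    return pairs, grid


def run_experiment(cfg: ExperimentConfig) -> ResultsTable:
    """Run every (pair, system) cell of the experiment.

    Per-row errors are recorded and the run continues; partial results are
    valid output.  Deterministic under a fixed config and seed.
    """
    cfg.validate()
    pairs, grid = _pairs_and_grid(cfg)
    systems = cfg.systems if cfg.systems is not None else preset_systems(grid)
    fractions = cfg.tolerances.fractions_of_voxel

    rows: list[dict] = []
    long_rows: list[dict] = []
    curve_rows: list[dict] = []
    errors: list[dict] = []

    for ref, test in pairs:
        ref_c = clean_structure(ref) if cfg.clean else ref
        test_c = clean_structure(test) if cfg.clean else test
        try:
            mesh_ref = structure_to_mesh(ref_c, grid) if cfg.include_mesh else None
            mesh_test = structure_to_mesh(test_c, grid) if cfg.include_mesh else None
            baseline = compute_measures(
                ref_c, test_c, grid, cfg.tolerances, cfg.include_mesh, mesh_ref, mesh_test
            )
        except AnalysisError as exc:
            errors.append({"structure": ref.name, "system": "<baseline>", "error": str(exc)})
            log.error("baseline for %s failed: %s", ref.name, exc)
            continue
        for system_name, configs in systems.items():
            try:
                reexport = perturb(test, configs)
                reexport_c = clean_structure(reexport) if cfg.clean else reexport
                disp = displacement_summary(test_c, reexport_c, grid)
                mesh_reexp = structure_to_mesh(reexport_c, grid) if cfg.include_mesh else None
                vs_orig = compute_measures(
                    test_c, reexport_c, grid, cfg.tolerances, cfg.include_mesh,
                    mesh_test, mesh_reexp,
                )
                vs_ref = compute_measures(
                    ref_c, reexport_c, grid, cfg.tolerances, cfg.include_mesh,
                    mesh_ref, mesh_reexp,
                )
            except (AnalysisError, ConfigError) as exc:
                errors.append({"structure": ref.name, "system": system_name, "error": str(exc)})
                log.error("%s / %s failed: %s", ref.name, system_name, exc)
                continue
            rows.append(
                _summary_row(ref.name, system_name, disp, baseline, vs_orig, vs_ref)
            )
            long_rows.extend(
                _long_rows(ref.name, system_name, fractions, baseline, vs_orig, vs_ref)
            )
            for voxels, frac in disp.cumulative:
                curve_rows.append(
                    {
                        "structure": ref.name,
                        "system": system_name,
                        "distance_voxels": voxels,
                        "fraction": frac,
                    }
                )

    manifest = {
        "generated": datetime.datetime.now().isoformat(timespec="seconds"),
        "seed": cfg.seed,
        "grid": grid.to_dict(),
        "offset": list(cfg.offset),
        "tolerance_fractions": list(fractions),
        "systems": {
            name: [c.describe() for c in configs] for name, configs in systems.items()
        },
        "n_pairs": len(pairs),
        "clean": cfg.clean,
        "include_mesh": cfg.include_mesh,
    }
    return ResultsTable(
        summary=pd.DataFrame(rows),
        long=pd.DataFrame(long_rows),
        curves=pd.DataFrame(curve_rows),
        manifest=manifest,
        errors=errors,
    )


def _summary_row(
    structure: str,
    system: str,
    disp: DisplacementSummary,
    baseline: MeasureSet,
    vs_orig: MeasureSet,
    vs_ref: MeasureSet,
) -> dict:
    row = {
        "structure": structure,
        "system": system,
        "mean_mm": disp.mean_mm,
        "max_mm": disp.max_mm,
        "n_vertices_original": disp.n_vertices_original,
        "n_vertices_reexported": disp.n_vertices_reexported,
        "n_unmatched_vertices": disp.n_unmatched_vertices,
        "topology_changed": disp.topology_changed,
    }
    for label, ms in (("vs_orig", vs_orig), ("vs_ref", vs_ref), ("baseline", baseline)):
        for key, value in ms.as_row().items():
            row[f"{key}_{label}"] = value
    return row


def _long_rows(
    structure: str,
    system: str,
    fractions: tuple[float, ...],
    baseline: MeasureSet,
    vs_orig: MeasureSet,
    vs_ref: MeasureSet,
) -> list[dict]:
    out = []
    for frac in fractions:
        out.append(
            {
                "structure": structure,
                "system": system,
                "tolerance_fraction": frac,
                "napl_vs_orig": vs_orig.napl[frac],
                "napl_vs_ref": vs_ref.napl[frac],
                "napl_baseline": baseline.napl[frac],
                "sdsc_vs_orig": vs_orig.sdsc[frac],
                "sdsc_vs_ref": vs_ref.sdsc[frac],
                "sdsc_baseline": baseline.sdsc[frac],
            }
        )
    return out


def write_report(table: ResultsTable, outdir, plots: bool = False) -> list[Path]:
    """CSV report files (plus optional cumulative-curve plots).

    Column order is stable and timestamps appear only in the manifest, so
    re-running the same config yields byte-identical CSVs.
    """
    if table.summary.empty:
        raise AnalysisError("results table is empty; nothing to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in (
        ("summary.csv", table.summary),
        ("measures_by_tolerance.csv", table.long),
        ("cumulative_curves.csv", table.curves),
    ):
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)
    manifest_path = outdir / "manifest.json"
    manifest = dict(table.manifest)
    if table.errors:
        manifest["row_errors"] = table.errors
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    written.append(manifest_path)
    if plots:
        written.extend(_plot_curves(table, outdir))
    return written


def _plot_curves(table: ResultsTable, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for structure, sub in table.curves.groupby("structure"):
        fig, ax = plt.subplots(figsize=(6, 4))
        for system, curve in sub.groupby("system"):
            order = np.argsort(curve["distance_voxels"].to_numpy())
            ax.plot(
                curve["distance_voxels"].to_numpy()[order],
                100 * curve["fraction"].to_numpy()[order],
                label=system,
                drawstyle="steps-post",
            )
        ax.set_xlabel("distance / in-plane voxel size")
        ax.set_ylabel("% of original vertices within distance")
        ax.set_title(structure)
        ax.legend(fontsize=7)
        path = outdir / f"curve_{structure.replace(' ', '_')}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
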