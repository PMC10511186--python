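"""End-to-end pipeline: phantom → segment → enhance → measure → age.

Each stage is a thin orchestration over the library modules; a run is
driven by a single :class:`PipelineConfig`, writes every artifact under
``output_dir``, and records a manifest (file checksums + parameters) so
identical config and seed reproduce identical results.  A single seed
feeds all stochastic stages through derived per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import breadth, demographics, phantom, relief, volume
from .mesh import read_obj, write_obj

log = logging.getLogger("creasemetry")

_STAGE_STREAMS = {"phantom": 0, "measure": 1}


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "creasemetry_run"
    phantom: dict | None = field(default_factory=dict)
    segment: dict = field(default_factory=dict)
    enhance: dict = field(default_factory=dict)
    measure: dict = field(default_factory=dict)
    age: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "phantom": self.phantom,
            "segment": self.segment,
            "enhance": self.enhance,
            "measure": self.measure,
            "age": self.age,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the run seed."""
    child = np.random.SeedSequence(seed, spawn_key=(_STAGE_STREAMS[stage],))
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))


def file_checksum(path) -> str:
    """SHA-256 of a file's content.

    ``.npz`` archives are hashed over their member arrays (sorted by
    name) rather than raw bytes, so container metadata cannot perturb
    the checksum.
    """
    path = Path(path)
    h = hashlib.sha256()
    if path.suffix == ".npz":
        with np.load(path) as z:
            for key in sorted(z.files):
                arr = np.ascontiguousarray(z[key])
                h.update(key.encode())
                h.update(str(arr.dtype).encode())
                h.update(str(arr.shape).encode())
                h.update(arr.tobytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def validate_table(path) -> dict:
    """Schema check for an observed-MCB table; lists all violations."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path)
    violations: list[str] = []
    for col in demographics.REQUIRED_COLUMNS:
        if col not in df.columns:
            violations.append(f"missing column: {col}")
    if "mcb_o_mm" in df.columns:
        bad = df.index[~(pd.to_numeric(df["mcb_o_mm"], errors="coerce") > 0)]
        for i in bad:
            violations.append(f"row {i}: mcb_o_mm must be positive")
    if "area_mm2" in df.columns:
        bad = df.index[~(pd.to_numeric(df["area_mm2"], errors="coerce") > 0)]
        for i in bad:
            violations.append(f"row {i}: area_mm2 must be positive")
    if "definition" in df.columns:
        bad = df.index[~df["definition"].isin(["kamp", "penrose"])]
        for i in bad:
            violations.append(f"row {i}: definition must be kamp or penrose")
    return {"path": str(path), "n_rows": len(df), "violations": violations,
            "valid": not violations}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Stage order: phantom (optional, when no input stack/mesh is given) →
    segment → enhance → measure → age.  On a stage failure the run halts
    with the failing stage named; artifacts already written are kept.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    config.to_yaml(out / "config.yaml")
    manifest["files"]["config.yaml"] = file_checksum(out / "config.yaml")

    truth = None
    # --- phantom -----------------------------------------------------------
    if config.phantom is not None:
        try:
            spec = phantom.PhantomSpec(
                **{**config.phantom, "seed": stage_seed(config.seed, "phantom")}
            )
            stack, truth = phantom.make_voxel_phantom(spec)
            volume.write_stack(stack, out / "phantom.tif")
            phantom.write_truth(truth, out / "truth.json")
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("phantom", exc) from exc
        manifest["stages"]["phantom"] = {
            "true_breadth_mm": truth.true_breadth_mm,
            "n_voxels": int(stack.intensities.size),
        }
        manifest["files"]["phantom.tif"] = file_checksum(out / "phantom.tif")
        manifest["files"]["truth.json"] = file_checksum(out / "truth.json")
        stack_path = out / "phantom.tif"
        voxel_mm = spec.voxel_mm
    else:
        stack_path = config.segment.get("input")
        if not stack_path or not Path(stack_path).exists():
            raise StageError(
                "segment",
                FileNotFoundError(
                    "no input stack: phantom stage disabled and "
                    f"segment.input={stack_path!r} not found"
                ),
            )
        voxel_mm = float(config.segment.get("voxel_mm", 0.025))

    # --- segment -----------------------------------------------------------
    try:
        stack = volume.read_stack(stack_path, voxel_mm=voxel_mm)
        trim = config.segment.get("trim", (0, 0))
        if any(trim):
            stack = volume.trim_slices(stack, *trim)
        binary = volume.otsu_threshold(
            stack, mode=config.segment.get("mode", "per_slice")
        )
        binary = volume.clean_binary(
            binary,
            min_island_voxels=int(config.segment.get("min_island_voxels", 27)),
            smooth_radius_voxels=int(
                config.segment.get("smooth_radius_voxels", 1)
            ),
        )
        mesh = volume.extract_mesh(binary)
        write_obj(mesh, out / "mesh.obj")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("segment", exc) from exc
    manifest["stages"]["segment"] = {
        "n_faces": mesh.n_faces,
        "material_fraction": float(binary.labels.mean()),
    }
    manifest["files"]["mesh.obj"] = file_checksum(out / "mesh.obj")

    # --- enhance -----------------------------------------------------------
    try:
        if "crop_lo" in config.enhance:
            region = relief.BoxRegion(
                np.asarray(config.enhance["crop_lo"], float),
                np.asarray(config.enhance["crop_hi"], float),
            )
        elif truth is not None and truth.crop_lo is not None:
            region = relief.BoxRegion(truth.crop_lo, truth.crop_hi)
        else:
            raise ValueError("no crop region configured and no phantom truth")
        roi = relief.crop_roi(mesh, region)
        patch = relief.fit_surface(roi)
        patch = relief.invert_cast(patch)
        relief.save_patch(patch, out / "patch.npz")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("enhance", exc) from exc
    manifest["stages"]["enhance"] = {
        "n_points": len(patch.points),
        "residual_rms_mm": float(np.sqrt(np.mean(patch.residuals**2))),
        "polarity": patch.polarity,
    }
    manifest["files"]["patch.npz"] = file_checksum(out / "patch.npz")

    # --- measure -----------------------------------------------------------
    try:
        n_lines = int(config.measure.get("n_lines", 3))
        if "lines" in config.measure:
            lines = [
                breadth.MeasurementLine(
                    origin=np.asarray(rec["origin"], float),
                    direction=np.asarray(rec["direction"], float),
                    length=float(rec["length"]),
                )
                for rec in config.measure["lines"]
            ]
        elif truth is not None:
            lines = phantom.transect_lines(
                truth, n_lines=n_lines, seed=stage_seed(config.seed, "measure")
            )
        else:
            raise ValueError("no measurement lines configured")
        definitions = config.measure.get("definitions", ["kamp", "penrose"])
        area = volume.mesh_area(roi)
        records = []
        for definition in definitions:
            m = breadth.measure_impression(patch, lines, definition)
            for run, (value, line) in enumerate(zip(m.run_values, m.lines), 1):
                records.append(
                    {
                        "label": "phantom",
                        "definition": definition,
                        "run": run,
                        "breadth_mm": value,
                        "crease_count": m.mean_crease_count,
                        "span_mm": m.span_mm,
                        "mcb_mm": m.mcb,
                    }
                )
        runs_df = pd.DataFrame(records)
        runs_df.to_csv(out / "measure.csv", index=False)
        mcb_df = pd.DataFrame(
            [
                {
                    "label": "phantom",
                    "area_mm2": area,
                    "definition": d,
                    "mcb_o_mm": runs_df[runs_df.definition == d].mcb_mm.iloc[0],
                }
                for d in definitions
            ]
        )
        mcb_df.to_csv(out / "mcb.csv", index=False)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("measure", exc) from exc
    manifest["stages"]["measure"] = {
        d: float(mcb_df[mcb_df.definition == d].mcb_o_mm.iloc[0])
        for d in definitions
    }
    manifest["files"]["measure.csv"] = file_checksum(out / "measure.csv")
    manifest["files"]["mcb.csv"] = file_checksum(out / "mcb.csv")

    # --- age ---------------------------------------------------------------
    try:
        report = demographics.build_report(
            mcb_df,
            shrinkages=config.age.get(
                "ts", list(demographics.DEFAULT_SHRINKAGES)
            ),
        )
        report.to_csv(out / "report.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(orient="records"), fh, indent=1)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("age", exc) from exc
    manifest["files"]["report.csv"] = file_checksum(out / "report.csv")
    manifest["files"]["report.json"] = file_checksum(out / "report.json")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
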