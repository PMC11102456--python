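"""On-disk layout for cohorts, models and pipeline artifacts.

Tables are plain TSV with headers; dense run matrices live in HDF5
containers; models and manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .model import RidgeModel
from .synth.cohort import Cohort, CohortConfig, GroundTruth, RestingRun, Subject, TaskRun
from .synth.design import Block, BlockDesign
from .synth.registry import default_registry
from .synth.surface import SurfaceModel

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_model",
    "read_model",
    "sha256_of",
]


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_design(design: BlockDesign, path: Path) -> None:
    pd.DataFrame(
        [
            {"condition": b.condition, "onset_s": b.onset, "duration_s": b.duration}
            for b in design.blocks
        ]
    ).to_csv(path, sep="\t", index=False)


def _read_design(path: Path, tr: float) -> BlockDesign:
    df = pd.read_csv(path, sep="\t")
    blocks = [Block(r.condition, float(r.onset_s), float(r.duration_s)) for r in df.itertuples()]
    total = sum(b.duration for b in blocks)
    return BlockDesign(blocks=blocks, tr=tr, n_volumes=int(round(total / tr)))


def write_cohort(cohort: Cohort, out_dir: "str | Path") -> Path:
    """Persist a cohort as the documented directory layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cohort.config), fh, sort_keys=True)

    tab = cohort.surface.table
    tab[["vertex", "hemi", "x", "y", "z", "curvature", "thickness"]].to_csv(
        out / "surface.tsv", sep="\t", index=False
    )
    tab[["vertex", "parcel"]].to_csv(out / "parcels.tsv", sep="\t", index=False)
    tab.loc[tab["search_space"] != "", ["vertex", "search_space"]].to_csv(
        out / "searchspaces.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "froi": e.froi_id, "name": e.name, "hemisphere": e.hemisphere,
                "category": e.category, "contrast_category": e.contrast_category,
                "search_space": e.search_space,
            }
            for e in cohort.registry
        ]
    ).to_csv(out / "registry.tsv", sep="\t", index=False)

    if cohort.subjects:
        coupling = {k: v.tolist() for k, v in cohort.subjects[0].ground_truth.coupling.items()}
        (out / "coupling.json").write_text(json.dumps(coupling))

    for subj in cohort.subjects:
        sdir = out / subj.subject_id
        sdir.mkdir(exist_ok=True)
        with h5py.File(sdir / "rest.h5", "w") as f:
            f.create_dataset("signal", data=subj.rest.signal, track_times=False)
            f.create_dataset("fd", data=subj.rest.fd, track_times=False)
            f.attrs["tr"] = subj.rest.tr
        for i, run in enumerate(subj.task_runs, start=1):
            with h5py.File(sdir / f"task_run{i}.h5", "w") as f:
                f.create_dataset("signal", data=run.signal, track_times=False)
                f.create_dataset("motion", data=run.motion, track_times=False)
                f.create_dataset("movement", data=run.movement, track_times=False)
            _write_design(run.design, sdir / f"design_run{i}.tsv")
        gt = subj.ground_truth
        (sdir / "ground_truth.json").write_text(
            json.dumps(
                {
                    "amplitude": gt.amplitude.tolist(),
                    "froi_vertices": {k: v.tolist() for k, v in gt.froi_vertices.items()},
                    "centers": {k: v.tolist() for k, v in gt.centers.items()},
                }
            )
        )
    return out


def read_cohort(in_dir: "str | Path") -> Cohort:
    src = Path(in_dir)
    cfg = CohortConfig(**yaml.safe_load((src / "config.yaml").read_text()))
    registry = default_registry()

    surface_tab = pd.read_csv(src / "surface.tsv", sep="\t")
    parcels = pd.read_csv(src / "parcels.tsv", sep="\t")
    spaces = pd.read_csv(src / "searchspaces.tsv", sep="\t")
    tab = surface_tab.merge(parcels, on="vertex").merge(spaces, on="vertex", how="left")
    tab["search_space"] = tab["search_space"].fillna("")
    surface = SurfaceModel(table=tab, n_parcels=cfg.n_parcels, registry=registry)

    coupling_raw = json.loads((src / "coupling.json").read_text())
    coupling = {k: np.asarray(v) for k, v in coupling_raw.items()}

    subjects = []
    for sdir in sorted(src.glob("sub-*")):
        gt_raw = json.loads((sdir / "ground_truth.json").read_text())
        gt = GroundTruth(
            amplitude=np.asarray(gt_raw["amplitude"]),
            froi_vertices={k: np.asarray(v, dtype=int) for k, v in gt_raw["froi_vertices"].items()},
            coupling=coupling,
            centers={k: np.asarray(v) for k, v in gt_raw["centers"].items()},
        )
        with h5py.File(sdir / "rest.h5", "r") as f:
            rest = RestingRun(signal=f["signal"][()], fd=f["fd"][()], tr=float(f.attrs["tr"]))
        runs = []
        for i in (1, 2):
            design = _read_design(sdir / f"design_run{i}.tsv", cfg.tr)
            with h5py.File(sdir / f"task_run{i}.h5", "r") as f:
                runs.append(
                    TaskRun(
                        signal=f["signal"][()],
                        design=design,
                        motion=f["motion"][()],
                        movement=f["movement"][()],
                    )
                )
        subjects.append(Subject(sdir.name, gt, rest, tuple(runs)))
    return Cohort(config=cfg, surface=surface, registry=registry, subjects=subjects)


def write_model(model: RidgeModel, path: "str | Path") -> None:
    """Serialize a ridge model as JSON keyed by column name."""
    payload = {
        "froi_id": model.froi_id,
        "lam": model.lam,
        "intercept": model.intercept,
        "weights": dict(zip(model.columns, model.weights.tolist())),
        "mean": dict(zip(model.columns, model.mean.tolist())),
        "sd": dict(zip(model.columns, model.sd.tolist())),
        "dropped_columns": list(model.dropped_columns),
        "training_subjects": list(model.training_subjects),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model(path: "str | Path") -> RidgeModel:
    raw = json.loads(Path(path).read_text())
    cols = tuple(raw["weights"])
    return RidgeModel(
        weights=np.asarray([raw["weights"][c] for c in cols]),
        intercept=float(raw["intercept"]),
        lam=float(raw["lam"]),
        mean=np.asarray([raw["mean"][c] for c in cols]),
        sd=np.asarray([raw["sd"][c] for c in cols]),
        columns=cols,
        dropped_columns=tuple(raw["dropped_columns"]),
        froi_id=raw["froi_id"],
        training_subjects=tuple(raw["training_subjects"]),
    )
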