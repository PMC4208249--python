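"""Plain-text persistence: dataset manifests, recordings, matrices, models.

All numeric payloads are delimited text (CSV); all metadata is JSON, so a
dataset or fitted model can be inspected with a text editor and diffed.  A
dataset on disk is one CSV per measurement (rows = time samples, columns =
sensors) plus a ``manifest.json`` tying files to labels, stimulus timing and
the sensor-to-material map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SensorArrayRecording
from .discriminant import DiscriminantModel
from .eigenodour import EigenOdourModel
from .svm import KernelSpec, MulticlassSVMModel

__all__ = [
    "DatasetManifest", "ManifestError",
    "read_manifest", "write_manifest",
    "read_recording", "write_recording",
    "load_dataset", "write_dataset",
    "write_matrix", "read_matrix",
    "save_eigenodour_model", "load_eigenodour_model",
    "save_discriminant_model", "load_discriminant_model",
    "save_svm_model", "load_svm_model",
]


class ManifestError(ValueError):
    pass


@dataclass
class ManifestEntry:
    path: str
    label: str
    stimulus_onset: int = 100
    stimulus_end: int = 650


@dataclass
class DatasetManifest:
    """Index of a dataset: per-measurement files, labels and timing."""

    entries: list[ManifestEntry]
    sample_interval: float = 1.0
    n_sensors: int = 0
    material_map: list[int] = field(default_factory=list)
    provenance: str = "external"

    def labels(self) -> list[str]:
        return [e.label for e in self.entries]


def _validate(manifest: DatasetManifest, base: Path, check_files: bool) -> None:
    if manifest.n_sensors <= 0:
        raise ManifestError("n_sensors must be positive")
    if manifest.material_map and len(manifest.material_map) != manifest.n_sensors:
        raise ManifestError(
            f"material_map has {len(manifest.material_map)} entries for "
            f"{manifest.n_sensors} sensors"
        )
    for e in manifest.entries:
        if not e.label:
            raise ManifestError(f"entry {e.path!r} has an empty label")
        if check_files and not (base / e.path).exists():
            raise ManifestError(f"recording file missing: {base / e.path}")


def write_manifest(manifest: DatasetManifest, path) -> Path:
    path = Path(path)
    payload = {
        "sample_interval": manifest.sample_interval,
        "n_sensors": manifest.n_sensors,
        "material_map": list(map(int, manifest.material_map)),
        "provenance": manifest.provenance,
        "entries": [
            {"path": e.path, "label": e.label,
             "stimulus_onset": e.stimulus_onset,
             "stimulus_end": e.stimulus_end}
            for e in manifest.entries
        ],
    }
    _validate(manifest, path.parent, check_files=False)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1) + "\n")
    return path


def read_manifest(path, check_files: bool = True) -> DatasetManifest:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ManifestError(f"cannot read manifest {path}: {exc}") from exc
    for key in ("sample_interval", "n_sensors", "entries"):
        if key not in payload:
            raise ManifestError(f"manifest {path} is missing field {key!r}")
    manifest = DatasetManifest(
        entries=[ManifestEntry(**e) for e in payload["entries"]],
        sample_interval=payload["sample_interval"],
        n_sensors=payload["n_sensors"],
        material_map=payload.get("material_map", []),
        provenance=payload.get("provenance", "external"),
    )
    _validate(manifest, path.parent, check_files=check_files)
    return manifest


def write_recording(recording: SensorArrayRecording, path) -> Path:
    """Write the T x N resistance grid as headerless CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(recording.resistance).to_csv(
        path, header=False, index=False, float_format="%.8g"
    )
    return path


def read_recording(
    path, manifest: DatasetManifest, entry: ManifestEntry
) -> SensorArrayRecording:
    values = pd.read_csv(path, header=None, dtype=float).to_numpy()
    if values.shape[1] != manifest.n_sensors:
        raise ManifestError(
            f"{path}: {values.shape[1]} sensors, manifest says "
            f"{manifest.n_sensors}"
        )
    return SensorArrayRecording(
        resistance=values,
        sample_interval=manifest.sample_interval,
        stimulus_onset=entry.stimulus_onset,
        stimulus_end=entry.stimulus_end,
        label=entry.label,
        material_map=np.array(manifest.material_map)
        if manifest.material_map else None,
    )


def write_dataset(recordings, labels, out_dir, provenance="simulated") -> Path:
    """Persist recordings as CSVs + manifest.json; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    n_sensors = recordings[0].n_sensors if recordings else 0
    for j, (rec, lab) in enumerate(zip(recordings, labels, strict=True)):
        name = f"measurement_{j:03d}.csv"
        write_recording(rec, out_dir / name)
        entries.append(ManifestEntry(
            path=name, label=lab,
            stimulus_onset=rec.stimulus_onset,
            stimulus_end=rec.stimulus_end,
        ))
    first = recordings[0] if recordings else None
    manifest = DatasetManifest(
        entries=entries,
        sample_interval=first.sample_interval if first else 1.0,
        n_sensors=n_sensors if n_sensors else 1,
        material_map=(
            list(map(int, first.material_map))
            if first is not None and first.material_map is not None else []
        ),
        provenance=provenance,
    )
    return write_manifest(manifest, out_dir / "manifest.json")


def load_dataset(manifest_path) -> tuple[list[SensorArrayRecording], list[str]]:
    """Load every recording referenced by a manifest."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    recordings = [
        read_recording(base / e.path, manifest, e) for e in manifest.entries
    ]
    return recordings, manifest.labels()


def write_matrix(values: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(np.atleast_2d(values)).to_csv(
        path, header=False, index=False, float_format="%.17g"
    )
    return path


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path, header=None, dtype=float).to_numpy()


# --- model serialization: directory of JSON metadata + CSV matrices -------

def save_eigenodour_model(model: EigenOdourModel, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "kind": "eigenodour",
        "n_components": int(model.n_components),
        "eigenvalues": model.eigenvalues.tolist(),
        "spectrum": model.spectrum.tolist(),
        "sign_convention": "largest-magnitude coefficient positive",
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=1) + "\n")
    write_matrix(model.mean, out_dir / "mean.csv")
    write_matrix(model.basis, out_dir / "basis.csv")
    write_matrix(model.gram_eigenvectors, out_dir / "gram_eigenvectors.csv")
    return out_dir


def load_eigenodour_model(in_dir) -> EigenOdourModel:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "meta.json").read_text())
    return EigenOdourModel(
        mean=read_matrix(in_dir / "mean.csv").ravel(),
        eigenvalues=np.array(meta["eigenvalues"]),
        basis=read_matrix(in_dir / "basis.csv"),
        gram_eigenvectors=read_matrix(in_dir / "gram_eigenvectors.csv"),
        spectrum=np.array(meta["spectrum"]),
        n_components=int(meta["n_components"]),
    )


def save_discriminant_model(model: DiscriminantModel, out_dir) -> Path:
    out_dir = Path(out_dir)
    save_eigenodour_model(model.eigen, out_dir / "eigen")
    meta = {
        "kind": "discriminant",
        "class_labels": list(model.class_labels),
        "class_counts": model.class_counts.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=1) + "\n")
    for name, mat in (
        ("class_means", model.class_means), ("global_mean", model.global_mean),
        ("s_b", model.s_b), ("s_w", model.s_w), ("s_t", model.s_t),
        ("w_lda", model.w_lda), ("w_opt", model.w_opt),
    ):
        write_matrix(mat, out_dir / f"{name}.csv")
    return out_dir


def load_discriminant_model(in_dir) -> DiscriminantModel:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "meta.json").read_text())
    return DiscriminantModel(
        class_labels=meta["class_labels"],
        class_means=read_matrix(in_dir / "class_means.csv"),
        global_mean=read_matrix(in_dir / "global_mean.csv").ravel(),
        class_counts=np.array(meta["class_counts"]),
        s_b=read_matrix(in_dir / "s_b.csv"),
        s_w=read_matrix(in_dir / "s_w.csv"),
        s_t=read_matrix(in_dir / "s_t.csv"),
        w_lda=read_matrix(in_dir / "w_lda.csv"),
        w_opt=read_matrix(in_dir / "w_opt.csv"),
        eigenvalues=np.array(meta["eigenvalues"]),
        eigen=load_eigenodour_model(in_dir / "eigen"),
    )


def save_svm_model(model: MulticlassSVMModel, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "kind": "crammer-singer-svm",
        "class_labels": list(model.class_labels),
        "penalty": model.penalty,
        "kernel": {"name": model.kernel.name, "gamma": model.kernel.gamma,
                   "bias": model.kernel.bias},
        "y": model.y.tolist(),
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=1) + "\n")
    write_matrix(model.alpha, out_dir / "alpha.csv")
    write_matrix(model.training_points, out_dir / "training_points.csv")
    return out_dir


def load_svm_model(in_dir) -> MulticlassSVMModel:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "meta.json").read_text())
    return MulticlassSVMModel(
        alpha=read_matrix(in_dir / "alpha.csv"),
        training_points=read_matrix(in_dir / "training_points.csv"),
        y=np.array(meta["y"], dtype=int),
        class_labels=meta["class_labels"],
        penalty=meta["penalty"],
        kernel=KernelSpec(meta["kernel"]["name"], meta["kernel"]["gamma"],
                          meta["kernel"].get("bias", 1.0)),
    )
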