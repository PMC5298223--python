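"""File interchange: NIfTI volumes, electrode tables, trial tables,
HDF5 recordings, scaling tables, phantom configs, VTK meshes, STL surfaces."""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .fem import HexMesh
from .gridfit import TriSurface
from .phantom import (
    CylinderDefect,
    ElectrodeSet,
    LabeledVolume,
    PhantomSpec,
    Recording,
    SawLine,
    ScalingTable,
    TrialSet,
)

__all__ = [
    "save_volume_nifti", "load_volume_nifti",
    "save_electrodes_tsv", "load_electrodes_tsv",
    "save_trials_csv", "load_trials_csv",
    "save_recording_h5", "load_recording_h5",
    "save_scaling_csv", "load_scaling_csv",
    "save_phantom_spec", "load_phantom_spec",
    "save_conductivity_table", "load_conductivity_table",
    "save_amplitudes_csv", "save_spectra_h5", "load_spectra_h5",
    "save_mesh_vtk", "save_surface_stl",
]


def save_volume_nifti(volume: LabeledVolume, path) -> None:
    affine = np.diag([volume.spacing_mm] * 3 + [1.0])
    affine[:3, 3] = volume.origin_mm + 0.5 * volume.spacing_mm
    img = nib.Nifti1Image(volume.labels.astype(np.int16), affine)
    nib.save(img, str(path))


def load_volume_nifti(path) -> LabeledVolume:
    img = nib.load(str(path))
    affine = img.affine
    spacing = float(affine[0, 0])
    origin = affine[:3, 3] - 0.5 * spacing
    return LabeledVolume(np.asarray(img.dataobj, dtype=np.int16), spacing, origin)


def save_electrodes_tsv(electrodes: ElectrodeSet, path) -> None:
    df = pd.DataFrame({
        "label": electrodes.labels,
        "x_mm": electrodes.positions_mm[:, 0],
        "y_mm": electrodes.positions_mm[:, 1],
        "z_mm": electrodes.positions_mm[:, 2],
        "kind": electrodes.kinds,
    })
    df.to_csv(path, sep="\t", index=False)


def load_electrodes_tsv(path, reference: str = "CAR") -> ElectrodeSet:
    df = pd.read_csv(path, sep="\t")
    return ElectrodeSet(
        df["label"].astype(str).tolist(),
        df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        df["kind"].astype(str).tolist(),
        reference,
    )


def save_trials_csv(trials: TrialSet, path) -> None:
    pd.DataFrame({
        "onset_s": trials.onsets_s,
        "end_s": trials.ends_s,
        "center_s": trials.centers_s,
        "baseline_start_s": trials.baseline_starts_s,
    }).to_csv(path, index=False)


def load_trials_csv(path, baseline_duration_s: float = 0.2) -> TrialSet:
    df = pd.read_csv(path)
    return TrialSet(
        df["onset_s"].to_numpy(float),
        df["end_s"].to_numpy(float),
        df["baseline_start_s"].to_numpy(float),
        baseline_duration_s,
    )


def save_recording_h5(recording: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("samples_uv", data=recording.samples_uv)
        d.attrs["rate_hz"] = recording.rate_hz
        d.attrs["band_hz"] = list(recording.band_hz)
        d.attrs["channel_labels"] = [s.encode() for s in recording.channel_labels]
        if recording.seed is not None:
            d.attrs["seed"] = recording.seed


def load_recording_h5(path) -> Recording:
    with h5py.File(path, "r") as f:
        d = f["samples_uv"]
        return Recording(
            float(d.attrs["rate_hz"]),
            d[()],
            [s.decode() if isinstance(s, bytes) else str(s)
             for s in d.attrs["channel_labels"]],
            band_hz=tuple(d.attrs["band_hz"]),
            seed=int(d.attrs["seed"]) if "seed" in d.attrs else None,
        )


def save_scaling_csv(table: ScalingTable, path) -> None:
    pd.DataFrame({
        "condition": table.conditions,
        "amplitude_uv": [table[c] for c in table.conditions],
    }).to_csv(path, index=False)


def load_scaling_csv(path) -> ScalingTable:
    df = pd.read_csv(path)
    return ScalingTable(dict(zip(df["condition"], df["amplitude_uv"].astype(float))))


def save_phantom_spec(spec: PhantomSpec, path) -> None:
    d = {
        "spacing_mm": spec.spacing_mm,
        "radii_mm": list(spec.radii_mm),
        "muscle_direction": list(spec.muscle_direction),
        "muscle_half_angle_deg": spec.muscle_half_angle_deg,
        "pterygoid_half_angle_deg": spec.pterygoid_half_angle_deg,
        "burr_holes": [
            {"direction": list(b.direction), "diameter_mm": b.diameter_mm}
            for b in spec.burr_holes
        ],
        "saw_lines": [
            {"start_direction": list(s.start_direction),
             "end_direction": list(s.end_direction),
             "width_mm": s.width_mm}
            for s in spec.saw_lines
        ],
        "foramen": (
            None if spec.foramen is None
            else {"direction": list(spec.foramen.direction),
                  "diameter_mm": spec.foramen.diameter_mm}
        ),
        "grid_rows": spec.grid_rows,
        "grid_cols": spec.grid_cols,
        "grid_pitch_mm": spec.grid_pitch_mm,
        "contact_diameter_mm": spec.contact_diameter_mm,
        "grid_direction": list(spec.grid_direction),
        "grid_thickness_voxels": spec.grid_thickness_voxels,
        "grid_gap_voxels": spec.grid_gap_voxels,
        "grid_margin_mm": spec.grid_margin_mm,
        "n_scalp_electrodes": spec.n_scalp_electrodes,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_phantom_spec(path) -> PhantomSpec:
    d = yaml.safe_load(Path(path).read_text())
    return PhantomSpec(
        spacing_mm=d["spacing_mm"],
        radii_mm=tuple(d["radii_mm"]),
        muscle_direction=tuple(d["muscle_direction"]),
        muscle_half_angle_deg=d["muscle_half_angle_deg"],
        pterygoid_half_angle_deg=d["pterygoid_half_angle_deg"],
        burr_holes=tuple(
            CylinderDefect(tuple(b["direction"]), b["diameter_mm"])
            for b in d["burr_holes"]
        ),
        saw_lines=tuple(
            SawLine(tuple(s["start_direction"]), tuple(s["end_direction"]),
                    s["width_mm"])
            for s in d["saw_lines"]
        ),
        foramen=(
            None if d["foramen"] is None
            else CylinderDefect(tuple(d["foramen"]["direction"]),
                                d["foramen"]["diameter_mm"])
        ),
        grid_rows=d["grid_rows"],
        grid_cols=d["grid_cols"],
        grid_pitch_mm=d["grid_pitch_mm"],
        contact_diameter_mm=d["contact_diameter_mm"],
        grid_direction=tuple(d["grid_direction"]),
        grid_thickness_voxels=d["grid_thickness_voxels"],
        grid_gap_voxels=d.get("grid_gap_voxels", 0),
        grid_margin_mm=d["grid_margin_mm"],
        n_scalp_electrodes=d["n_scalp_electrodes"],
    )


def save_conductivity_table(table, path) -> None:
    """Tissue-name -> sigma (S/m) config file; values round-trip exactly."""
    from .labels import Tissue

    d = {Tissue(t).name.lower(): float(v) for t, v in table.sigma.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_conductivity_table(path):
    from .fem import ConductivityTable
    from .labels import Tissue

    d = yaml.safe_load(Path(path).read_text())
    return ConductivityTable({Tissue[k.upper()]: float(v) for k, v in d.items()})


def save_amplitudes_csv(amplitudes_uv: np.ndarray, channel_labels, path) -> None:
    """Long-format (trial, channel, amplitude_uv) table."""
    n_tr, n_ch = amplitudes_uv.shape
    pd.DataFrame({
        "trial": np.repeat(np.arange(n_tr), n_ch),
        "channel": list(channel_labels) * n_tr,
        "amplitude_uv": amplitudes_uv.ravel(),
    }).to_csv(path, index=False)


def save_spectra_h5(spectra, path, mask: np.ndarray | None = None) -> None:
    """Relative spectra (and optional significance mask) with axis metadata."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("log10_relative_power", data=spectra.values)
        d.attrs["axes"] = ["channel", "trial", "time", "frequency"]
        f.create_dataset("times_s", data=spectra.times_s)
        f.create_dataset("freqs_hz", data=spectra.freqs_hz)
        d.attrs["baseline_reduce"] = spectra.baseline_reduce
        if spectra.channel_labels:
            d.attrs["channel_labels"] = [s.encode() for s in spectra.channel_labels]
        if mask is not None:
            f.create_dataset("significance_mask", data=mask.astype(np.uint8))


def load_spectra_h5(path):
    from .signals import RelativeSpectra

    with h5py.File(path, "r") as f:
        d = f["log10_relative_power"]
        labels = [
            s.decode() if isinstance(s, bytes) else str(s)
            for s in d.attrs.get("channel_labels", [])
        ]
        sp = RelativeSpectra(d[()], f["times_s"][()], f["freqs_hz"][()],
                             channel_labels=labels,
                             baseline_reduce=str(d.attrs["baseline_reduce"]))
        mask = (f["significance_mask"][()].astype(bool)
                if "significance_mask" in f else None)
    return sp, mask


def save_mesh_vtk(mesh: HexMesh, path) -> None:
    """Legacy ASCII VTK unstructured grid (hexahedra with tissue labels)."""
    lines = [
        "# vtk DataFile Version 3.0",
        "hexahedral head mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} float",
    ]
    for p in mesh.node_coords_mm:
        lines.append(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}")
    lines.append(f"CELLS {mesh.n_elems} {mesh.n_elems * 9}")
    for e in mesh.elems:
        lines.append("8 " + " ".join(map(str, e)))
    lines.append(f"CELL_TYPES {mesh.n_elems}")
    lines.extend(["12"] * mesh.n_elems)     # VTK_HEXAHEDRON
    lines.append(f"CELL_DATA {mesh.n_elems}")
    lines.append("SCALARS tissue int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(int(t)) for t in mesh.elem_labels)
    Path(path).write_text("\n".join(lines) + "\n")


def save_surface_stl(surface: TriSurface, path) -> None:
    import trimesh

    trimesh.Trimesh(vertices=surface.vertices,
                    faces=surface.triangles).export(str(path))
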