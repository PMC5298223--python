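"""Parametric head phantom: labeled volumes, electrodes, chewing recordings.

The phantom is a concentric-sphere head (white/gray/CSF/skull/scalp shells)
with the structures that drive extra-to-intracranial EMG propagation:

* an extracranial *temporal-muscle* compartment (angular sector of the
  soft-tissue shell) and a small *pterygoid* compartment at the skull base,
* CSF-filled craniotomy defects (burr-hole cylinders and a saw-line slot),
* a skull-base *foramen* channel of intermediate conductivity,
* a face-sealed insulating *grid patch* on the gray/CSF interface carrying
  a lattice of subdural contacts.

Three head-model variants are derived from one specification:

==== ==========================================
HM1  defects + insulating grid (implanted head)
HM2  insulating grid only (defects closed)
HM3  neither (the healthy head)
==== ==========================================

All randomness is explicit: stochastic operations take a seed and never
touch global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._seal import find_leaks, is_sealed
from .labels import Tissue
from .study import CONDITION_AMPLITUDES_UV, MEAN_ATTENUATION

__all__ = [
    "CylinderDefect",
    "SawLine",
    "PhantomSpec",
    "LabeledVolume",
    "ElectrodeSet",
    "Recording",
    "TrialSet",
    "RecordingParams",
    "ScalingTable",
    "build_phantom",
    "place_electrodes",
    "generate_recording",
    "default_scaling_table",
]


# --------------------------------------------------------------------------
# specification dataclasses
# --------------------------------------------------------------------------

def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return v / n


@dataclass(frozen=True)
class CylinderDefect:
    """Cylindrical channel through the skull, axis through the head center."""

    direction: tuple[float, float, float]
    diameter_mm: float

    def axis(self) -> np.ndarray:
        return _unit(self.direction)


@dataclass(frozen=True)
class SawLine:
    """Great-circle slot in the skull between two surface directions."""

    start_direction: tuple[float, float, float]
    end_direction: tuple[float, float, float]
    width_mm: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric description of the phantom head.

    ``radii_mm`` are the outer radii of the white, gray, CSF, skull and
    scalp shells and must be strictly increasing.  Default voxel spacing is
    2 mm (isotropic).  The grid patch sits on the gray/CSF interface facing
    ``grid_direction``; burr holes use the clinically typical 12 and 16 mm
    diameters and the foramen channel 1-7 mm.

    The default layout mirrors the implanted-patient situation: the muscle
    compartment is lateral (+x), the grid supero-lateral (offset ~40 deg
    from the muscle, as a fronto-parietal grid sits away from the temporal
    muscle), and the craniotomy defects lie along the grid's far (superior)
    edge.  ``grid_gap_voxels`` can lift the patch off the cortex to leave a
    CSF film beneath it.
    """

    spacing_mm: float = 2.0
    radii_mm: tuple[float, float, float, float, float] = (66.0, 78.0, 82.0, 88.0, 94.0)
    muscle_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    muscle_half_angle_deg: float = 40.0
    pterygoid_half_angle_deg: float = 14.0
    burr_holes: tuple[CylinderDefect, ...] = (
        CylinderDefect((0.40, 0.30, 0.87), 12.0),
        CylinderDefect((0.40, -0.30, 0.87), 16.0),
    )
    saw_lines: tuple[SawLine, ...] = (
        SawLine((0.40, 0.30, 0.87), (0.40, -0.30, 0.87), 3.0),
    )
    foramen: CylinderDefect | None = CylinderDefect((0.76, 0.0, -0.65), 4.0)
    grid_rows: int = 4
    grid_cols: int = 4
    grid_pitch_mm: float = 10.0
    contact_diameter_mm: float = 4.0
    grid_direction: tuple[float, float, float] = (0.766, 0.0, 0.643)
    grid_thickness_voxels: int = 1
    grid_gap_voxels: int = 0
    grid_margin_mm: float = 6.0
    n_scalp_electrodes: int = 19

    def __post_init__(self):
        r = self.radii_mm
        if not all(r[i] < r[i + 1] for i in range(len(r) - 1)):
            raise ValueError("shell radii must be strictly increasing")
        if self.spacing_mm <= 0:
            raise ValueError("voxel spacing must be positive")
        for bh in self.burr_holes:
            if not 1.0 <= bh.diameter_mm <= 30.0:
                raise ValueError("burr-hole diameter out of range")
        if self.foramen is not None and not 1.0 <= self.foramen.diameter_mm <= 7.0:
            raise ValueError("foramen diameter must lie in [1, 7] mm")

    # convenience radii -----------------------------------------------------
    @property
    def r_white(self) -> float:
        return self.radii_mm[0]

    @property
    def r_gray(self) -> float:
        return self.radii_mm[1]

    @property
    def r_csf(self) -> float:
        return self.radii_mm[2]

    @property
    def r_skull(self) -> float:
        return self.radii_mm[3]

    @property
    def r_scalp(self) -> float:
        return self.radii_mm[4]

    @property
    def grid_contact_radius_mm(self) -> float:
        """Radius of the subdural contact lattice: the patch's inner face."""
        return self.r_gray + self.grid_gap_voxels * self.spacing_mm

    def grid_cap_angle_rad(self) -> float:
        half_diag = 0.5 * self.grid_pitch_mm * math.hypot(
            self.grid_rows - 1, self.grid_cols - 1
        )
        return (half_diag + self.grid_margin_mm) / self.grid_contact_radius_mm

    def muscle_center(self) -> np.ndarray:
        """Belly of the temporal-muscle compartment (mm)."""
        r = 0.5 * (self.r_skull + self.r_scalp)
        return r * _unit(self.muscle_direction)

    def muscle_superior_point(self) -> np.ndarray:
        """Thin superior part of the muscle, toward the top of the sector."""
        r = 0.5 * (self.r_skull + self.r_scalp)
        ang = math.radians(0.8 * self.muscle_half_angle_deg)
        d = _unit(self.muscle_direction)
        up = np.array([0.0, 0.0, 1.0])
        t = _unit(up - np.dot(up, d) * d)
        return r * (math.cos(ang) * d + math.sin(ang) * t)

    def pterygoid_center(self) -> np.ndarray:
        """Pterygoid compartment just outside the foramen mouth (mm)."""
        if self.foramen is None:
            raise ValueError("phantom has no foramen channel")
        r = self.r_skull + 0.25 * (self.r_scalp - self.r_skull)
        return r * self.foramen.axis()


# --------------------------------------------------------------------------
# volume containers
# --------------------------------------------------------------------------

@dataclass
class LabeledVolume:
    """Integer tissue labels on a regular isotropic voxel grid.

    Voxel centers sit at ``origin + (index + 0.5) * spacing``; lattice nodes
    (used by the FEM mesh) at ``origin + index * spacing``.
    """

    labels: np.ndarray           # int16, shape (nx, ny, nz)
    spacing_mm: float
    origin_mm: np.ndarray        # (3,)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int16)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        valid = {int(t) for t in Tissue}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"unknown label codes: {sorted(present - valid)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ax = [
            self.origin_mm[d] + (np.arange(self.labels.shape[d]) + 0.5) * self.spacing_mm
            for d in range(3)
        ]
        return np.meshgrid(*ax, indexing="ij")

    def count(self, tissue: Tissue) -> int:
        return int(np.count_nonzero(self.labels == int(tissue)))

    def label_at(self, point_mm) -> Tissue:
        idx = np.floor((np.asarray(point_mm, float) - self.origin_mm) / self.spacing_mm)
        idx = idx.astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            return Tissue.BACKGROUND
        return Tissue(int(self.labels[tuple(idx)]))


@dataclass
class ElectrodeSet:
    """Named electrode contacts with positions (mm) and kinds."""

    labels: list[str]
    positions_mm: np.ndarray     # (n, 3)
    kinds: list[str]             # "scalp" | "subdural"
    reference: str = "CAR"

    def __post_init__(self):
        self.positions_mm = np.atleast_2d(np.asarray(self.positions_mm, float))
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("electrode labels must be unique")
        if self.positions_mm.shape[0] != len(self.labels):
            raise ValueError("labels/positions length mismatch")
        if not set(self.kinds) <= {"scalp", "subdural"}:
            raise ValueError("electrode kind must be 'scalp' or 'subdural'")

    def select(self, kind: str) -> "ElectrodeSet":
        keep = [i for i, k in enumerate(self.kinds) if k == kind]
        return ElectrodeSet(
            [self.labels[i] for i in keep],
            self.positions_mm[keep],
            [self.kinds[i] for i in keep],
            self.reference,
        )

    def __len__(self) -> int:
        return len(self.labels)


# --------------------------------------------------------------------------
# phantom construction
# --------------------------------------------------------------------------

def _great_circle_mask(dirs: np.ndarray, a: np.ndarray, b: np.ndarray,
                       half_angle: float) -> np.ndarray:
    """Unit directions within ``half_angle`` of the arc from ``a`` to ``b``."""
    n = np.cross(a, b)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-12:
        raise ValueError("saw-line endpoints are collinear")
    n = n / n_norm
    off_plane = np.abs(np.arcsin(np.clip(dirs @ n, -1.0, 1.0)))
    # in-plane position between the endpoints
    t_a = np.cross(n, a)
    arc = math.atan2(np.dot(np.cross(a, b), n), np.dot(a, b))
    ang = np.arctan2(dirs @ t_a, dirs @ a)
    within = (ang >= -half_angle) & (ang <= arc + half_angle)
    return (off_plane <= half_angle) & within


def _seal_grid_patch(labels: np.ndarray, spec: PhantomSpec) -> None:
    """Add CSF-side voxels until the insulator patch is face-sealed."""
    for _ in range(30):
        mask = labels == int(Tissue.GRID_INSULATOR)
        leaks = find_leaks(mask)
        if not leaks:
            return
        for a, b in leaks:
            diff_axes = [d for d in range(3) if a[d] != b[d]]
            candidates = []
            for ax in diff_axes:
                c = list(a)
                c[ax] = b[ax]
                candidates.append(tuple(c))
            # prefer converting a CSF voxel (stay on the outer side of the
            # interface); fall back to any non-gray voxel
            chosen = None
            for c in candidates:
                if labels[c] == int(Tissue.CSF):
                    chosen = c
                    break
            if chosen is None:
                for c in candidates:
                    if labels[c] != int(Tissue.GRAY):
                        chosen = c
                        break
            if chosen is None:
                chosen = candidates[0]
            labels[chosen] = int(Tissue.GRID_INSULATOR)
    if not is_sealed(labels == int(Tissue.GRID_INSULATOR)):
        raise RuntimeError("grid patch could not be face-sealed")


def _build_full_labels(spec: PhantomSpec) -> np.ndarray:
    h = spec.spacing_mm
    half_extent = spec.r_scalp + 2.0 * h
    n = int(math.ceil(2.0 * half_extent / h))
    origin = -0.5 * n * h * np.ones(3)
    ax = origin[0] + (np.arange(n) + 0.5) * h
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    R = np.sqrt(X**2 + Y**2 + Z**2)
    labels = np.zeros((n, n, n), dtype=np.int16)

    shells = [
        (spec.r_white, Tissue.WHITE),
        (spec.r_gray, Tissue.GRAY),
        (spec.r_csf, Tissue.CSF),
        (spec.r_skull, Tissue.SKULL),
        (spec.r_scalp, Tissue.SOFT_TISSUE),
    ]
    prev = 0.0
    for r_out, tissue in shells:
        labels[(R >= prev) & (R < r_out)] = int(tissue)
        prev = r_out

    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.stack([X, Y, Z], axis=-1) / R[..., None]
    dirs[R == 0] = 0.0

    def _cos_to(direction):
        return dirs @ _unit(direction)

    soft = labels == int(Tissue.SOFT_TISSUE)
    # temporal muscle sector
    cosm = _cos_to(spec.muscle_direction)
    labels[soft & (cosm >= math.cos(math.radians(spec.muscle_half_angle_deg)))] = int(
        Tissue.MUSCLE
    )
    # pterygoid compartment around the foramen mouth
    if spec.foramen is not None:
        cosp = _cos_to(spec.foramen.direction)
        soft = labels == int(Tissue.SOFT_TISSUE)
        labels[
            soft & (cosp >= math.cos(math.radians(spec.pterygoid_half_angle_deg)))
        ] = int(Tissue.MUSCLE)

    skull = labels == int(Tissue.SKULL)
    pts = np.stack([X, Y, Z], axis=-1)

    def _cylinder_mask(defect: CylinderDefect):
        axis = defect.axis()
        along = pts @ axis
        perp = np.sqrt(np.maximum(R**2 - along**2, 0.0))
        return (perp <= 0.5 * defect.diameter_mm) & (along > 0)

    for bh in spec.burr_holes:
        m = skull & _cylinder_mask(bh)
        if not m.any():
            raise ValueError(
                f"burr hole {bh} does not intersect the skull shell"
            )
        labels[m] = int(Tissue.DEFECT_FILL)
        skull = labels == int(Tissue.SKULL)

    r_mid_skull = 0.5 * (spec.r_csf + spec.r_skull)
    for sl in spec.saw_lines:
        half_ang = 0.5 * sl.width_mm / r_mid_skull
        m = skull & _great_circle_mask(
            dirs.reshape(-1, 3), _unit(sl.start_direction), _unit(sl.end_direction),
            half_ang,
        ).reshape(labels.shape)
        if not m.any():
            raise ValueError(f"saw line {sl} does not intersect the skull shell")
        labels[m] = int(Tissue.DEFECT_FILL)
        skull = labels == int(Tissue.SKULL)

    if spec.foramen is not None:
        m = skull & _cylinder_mask(spec.foramen)
        if not m.any():
            raise ValueError("foramen channel does not intersect the skull shell")
        labels[m] = int(Tissue.FORAMEN_FILL)

    # insulating grid patch: spherical-cap shell on the gray/CSF interface
    if spec.grid_rows >= 2 and spec.grid_cols >= 2:
        cosg = _cos_to(spec.grid_direction)
        cap = cosg >= math.cos(spec.grid_cap_angle_rad())
        r_in = spec.r_gray + spec.grid_gap_voxels * h
        shell = (R >= r_in) & (R < r_in + spec.grid_thickness_voxels * h)
        patch = cap & shell & (labels == int(Tissue.CSF))
        if not patch.any():
            raise ValueError("grid patch does not rasterize onto the interface")
        labels[patch] = int(Tissue.GRID_INSULATOR)
        _seal_grid_patch(labels, spec)

    return labels


def build_phantom(spec: PhantomSpec, variant: str = "HM1") -> LabeledVolume:
    """Build the labeled head volume for one head-model variant.

    HM1 carries craniotomy defects and the insulating grid, HM2 only the
    grid (defects relabeled to skull), HM3 neither (defects to skull, grid
    to CSF).  All other voxels are identical across the variants.
    """
    if variant not in {"HM1", "HM2", "HM3"}:
        raise ValueError(f"unknown head-model variant {variant!r}")
    labels = _build_full_labels(spec)
    if variant in {"HM2", "HM3"}:
        labels[labels == int(Tissue.DEFECT_FILL)] = int(Tissue.SKULL)
    if variant == "HM3":
        labels[labels == int(Tissue.GRID_INSULATOR)] = int(Tissue.CSF)
    n = labels.shape[0]
    origin = -0.5 * n * spec.spacing_mm * np.ones(3)
    return LabeledVolume(labels, spec.spacing_mm, origin)


def layered_sphere_volume(
    radii_mm,
    tissues,
    spacing_mm: float = 2.0,
) -> LabeledVolume:
    """Concentric-shell sphere volume (validation geometry).

    ``radii_mm`` are ascending outer shell radii and ``tissues`` the label
    per shell, innermost first.
    """
    radii = np.asarray(radii_mm, float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    if len(radii) != len(tissues):
        raise ValueError("need one tissue per shell")
    h = spacing_mm
    n = int(math.ceil(2.0 * (radii[-1] + h) / h))
    origin = -0.5 * n * h * np.ones(3)
    ax = origin[0] + (np.arange(n) + 0.5) * h
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    R = np.sqrt(X**2 + Y**2 + Z**2)
    labels = np.zeros((n, n, n), dtype=np.int16)
    prev = 0.0
    for r_out, tissue in zip(radii, tissues):
        labels[(R >= prev) & (R < r_out)] = int(tissue)
        prev = r_out
    return LabeledVolume(labels, h, origin)


# --------------------------------------------------------------------------
# electrodes
# --------------------------------------------------------------------------

def _tangent_frame(direction) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = _unit(direction)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(helper, d))
    v = np.cross(d, u)
    return d, u, v


def subdural_lattice(spec: PhantomSpec) -> np.ndarray:
    """rows x cols contact centers at fixed pitch on the gray/CSF interface.

    Lattice offsets live in the azimuthal-equidistant chart around the grid
    direction, so along-row/along-column geodesic spacing equals the pitch.
    """
    d, u, v = _tangent_frame(spec.grid_direction)
    r = spec.grid_contact_radius_mm
    rows, cols = spec.grid_rows, spec.grid_cols
    out = np.empty((rows * cols, 3))
    k = 0
    for i in range(rows):
        for j in range(cols):
            a = (i - (rows - 1) / 2.0) * spec.grid_pitch_mm
            b = (j - (cols - 1) / 2.0) * spec.grid_pitch_mm
            rho = math.hypot(a, b)
            if rho == 0:
                out[k] = r * d
            else:
                bearing = math.atan2(b, a)
                t = math.cos(bearing) * u + math.sin(bearing) * v
                out[k] = r * (math.cos(rho / r) * d + math.sin(rho / r) * t)
            k += 1
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(1.0 - z**2)
    theta = phi * i
    return np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)


def place_electrodes(spec: PhantomSpec, volume: LabeledVolume,
                     n_scalp: int | None = None) -> ElectrodeSet:
    """Subdural lattice on the grid patch plus quasi-uniform scalp contacts."""
    n_scalp = spec.n_scalp_electrodes if n_scalp is None else n_scalp
    labels: list[str] = []
    positions: list[np.ndarray] = []
    kinds: list[str] = []

    if spec.grid_rows >= 2 and spec.grid_cols >= 2:
        if spec.grid_cap_angle_rad() > 0.5 * math.pi:
            raise ValueError("requested lattice exceeds the grid patch extent")
        lattice = subdural_lattice(spec)
        for k, p in enumerate(lattice):
            labels.append(f"G{k + 1:02d}")
            positions.append(p)
            kinds.append("subdural")

    if n_scalp > 0:
        for k, d in enumerate(_fibonacci_sphere(n_scalp)):
            labels.append(f"E{k + 1:02d}")
            positions.append(spec.r_scalp * d)
            kinds.append("scalp")

    if not labels:
        raise ValueError("no electrodes requested")
    return ElectrodeSet(labels, np.array(positions), kinds)


# --------------------------------------------------------------------------
# recordings
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordingParams:
    """Generative settings for synthetic chewing recordings.

    Defaults emulate the acquisition and physiology of the modeled study:
    1024 Hz sampling with a 1-344 Hz acquisition band, broadband 30-500 Hz
    EMG bursts repeating at ~1.2 Hz under a sharp-onset envelope (10 ms
    rise, exponential decay), ~30 uV scalp burst amplitude and a mean
    scalp-to-intracranial attenuation factor of 5.5.
    """

    duration_s: float = 60.0
    rate_hz: float = 1024.0
    rep_rate_hz: float = 1.2
    burst_duration_s: float = 0.35
    emg_band_hz: tuple[float, float] = (30.0, 500.0)
    scalp_burst_amplitude_uv: float = 30.0
    attenuation: float = MEAN_ATTENUATION
    background_rms_uv: float = 8.0
    ecog_background_rms_uv: float = 4.0
    rise_time_s: float = 0.010
    background_exponent: float = 2.0
    band_hz: tuple[float, float] = (1.0, 344.0)


@dataclass
class Recording:
    """Multichannel time series in microvolt."""

    rate_hz: float
    samples_uv: np.ndarray       # (n_channels, n_samples)
    channel_labels: list[str]
    band_hz: tuple[float, float] = (1.0, 344.0)
    seed: int | None = None

    def __post_init__(self):
        self.samples_uv = np.atleast_2d(np.asarray(self.samples_uv, float))
        if not np.all(np.isfinite(self.samples_uv)):
            raise ValueError("recording contains non-finite samples")
        if self.rate_hz <= 2.0 * self.band_hz[1]:
            raise ValueError("sampling rate must exceed twice the low-pass limit")
        if self.samples_uv.shape[0] != len(self.channel_labels):
            raise ValueError("channel count mismatch")

    @property
    def n_channels(self) -> int:
        return self.samples_uv.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples_uv.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class TrialSet:
    """Chewing-event annotations: EMG onset/end, center, baseline windows.

    The event center is the arithmetic mean of EMG onset and end and defines
    the 0-s time point of each trial.  Each baseline window (200 ms by
    default) is centered in the silent gap preceding the event.
    """

    onsets_s: np.ndarray
    ends_s: np.ndarray
    baseline_starts_s: np.ndarray
    baseline_duration_s: float = 0.2

    def __post_init__(self):
        self.onsets_s = np.asarray(self.onsets_s, float)
        self.ends_s = np.asarray(self.ends_s, float)
        self.baseline_starts_s = np.asarray(self.baseline_starts_s, float)
        if np.any(self.ends_s <= self.onsets_s):
            raise ValueError("every event must end after its onset")
        c = self.centers_s
        if np.any(np.diff(c) <= 0):
            raise ValueError("event centers must be strictly increasing")
        b0 = self.baseline_starts_s
        b1 = b0 + self.baseline_duration_s
        overlap = (b0 < self.ends_s) & (b1 > self.onsets_s)
        # a baseline may not overlap its own event window
        if np.any(overlap):
            raise ValueError("baseline windows overlap event windows")

    @property
    def centers_s(self) -> np.ndarray:
        return 0.5 * (self.onsets_s + self.ends_s)

    def __len__(self) -> int:
        return len(self.onsets_s)


@dataclass
class ScalingTable:
    """Mean scalp chewing amplitude per food condition, microvolt."""

    amplitudes_uv: dict[str, float]

    def __post_init__(self):
        if any(v <= 0 for v in self.amplitudes_uv.values()):
            raise ValueError("scaling amplitudes must be positive")

    def __getitem__(self, condition: str) -> float:
        return self.amplitudes_uv[condition]

    @property
    def conditions(self) -> list[str]:
        return list(self.amplitudes_uv)


def default_scaling_table() -> ScalingTable:
    """The six-condition noninvasive scaling table (yoghurt ... licorice)."""
    return ScalingTable(dict(CONDITION_AMPLITUDES_UV))


def _bandpass_noise(rng: np.random.Generator, n: int, rate: float,
                    band: tuple[float, float]) -> np.ndarray:
    from scipy.signal import butter, sosfiltfilt

    lo, hi = band
    hi = min(hi, 0.499 * rate)
    sos = butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = rng.standard_normal(n + 2048)
    y = sosfiltfilt(sos, x)[1024:-1024]
    s = np.std(y)
    return y / s if s > 0 else y


def _one_over_f_noise(rng: np.random.Generator, n: int, rms: float,
                      exponent: float = 2.0) -> np.ndarray:
    """Background noise with power spectrum ~ 1/f**exponent.

    The default exponent of 2 matches the steep high-frequency roll-off of
    ongoing EEG/ECoG background, leaving little power above the 100 Hz
    high-pass of the burst-amplitude statistic.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    with np.errstate(divide="ignore"):
        shape = np.where(f > 0, (f[1] / f) ** (exponent / 2.0), 0.0)
    y = np.fft.irfft(spec * shape, n=n)
    s = np.std(y)
    return rms * y / s if s > 0 else y


def _burst_envelope(n: int, rate: float, rise_s: float) -> np.ndarray:
    t = np.arange(n) / rate
    n_rise = max(int(round(rise_s * rate)), 1)
    env = np.exp(-t / (t[-1] / 2.5 if n > 1 else 1.0))
    ramp = np.ones(n)
    ramp[:n_rise] = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_rise) / n_rise))
    return env * ramp


def _distance_gains(positions: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Inverse-square distance mixing weights, normalized to median 1."""
    d = np.linalg.norm(positions - source, axis=1)
    d = np.maximum(d, 1.0)
    w = 1.0 / d**2
    return w / np.median(w)


def generate_recording(
    electrodes: ElectrodeSet,
    spec: PhantomSpec | None = None,
    params: RecordingParams | None = None,
    seed: int = 0,
) -> tuple[Recording, TrialSet]:
    """Synthesize a chewing recording with ground-truth event annotations.

    Chewing bursts are band-limited (30-500 Hz) Gaussian noise under a
    sharp-rise/exponential-decay envelope, repeated at the configured rate
    with mild jitter.  Every channel receives the burst through
    inverse-square distance mixing from the muscle compartment; subdural
    channels receive it attenuated by ``params.attenuation`` and carry
    independent 1/f background.  The same seed always reproduces the same
    recording bit-for-bit.
    """
    spec = spec or PhantomSpec()
    params = params or RecordingParams()
    rate = params.rate_hz
    if not 0.0 < params.rep_rate_hz < 0.5 * rate:
        raise ValueError("repetition rate out of range")
    if params.rep_rate_hz * params.burst_duration_s >= 1.0:
        raise ValueError("bursts longer than the repetition interval")
    n = int(round(params.duration_s * rate))
    rng = np.random.default_rng(seed)

    interval = 1.0 / params.rep_rate_hz
    margin = 2.5
    if params.duration_s < 2 * margin + 2 * interval:
        raise ValueError("duration too short for at least two events")
    onsets = []
    t = margin + 0.2 * interval * rng.random()
    while t + params.burst_duration_s < params.duration_s - margin:
        onsets.append(t)
        t += max(interval * (1.0 + 0.1 * rng.standard_normal()),
                 params.burst_duration_s + 0.25)
    onsets = np.array(onsets)
    ends = onsets + params.burst_duration_s

    n_burst = int(round(params.burst_duration_s * rate))
    envelope = _burst_envelope(n_burst, rate, params.rise_time_s)

    # common burst drive (per event, fresh carrier)
    drive = np.zeros(n)
    for on in onsets:
        i0 = int(round(on * rate))
        carrier = _bandpass_noise(rng, n_burst, rate, params.emg_band_hz)
        drive[i0:i0 + n_burst] += envelope * carrier

    muscle = spec.muscle_center()
    pos = electrodes.positions_mm
    kinds = np.array(electrodes.kinds)
    gains = np.zeros(len(electrodes))
    scale = np.zeros(len(electrodes))
    for kind, amp in (
        ("scalp", params.scalp_burst_amplitude_uv),
        ("subdural", params.scalp_burst_amplitude_uv / params.attenuation),
    ):
        m = kinds == kind
        if m.any():
            gains[m] = _distance_gains(pos[m], muscle)
            scale[m] = amp

    samples = np.empty((len(electrodes), n))
    for c in range(len(electrodes)):
        rms = (params.background_rms_uv if kinds[c] == "scalp"
               else params.ecog_background_rms_uv)
        samples[c] = scale[c] * gains[c] * drive + _one_over_f_noise(
            rng, n, rms, params.background_exponent)

    rec = Recording(rate, samples, list(electrodes.labels),
                    band_hz=params.band_hz, seed=seed)

    # pre-event baselines centered in the silent gap before each event
    prev_end = np.concatenate([[0.0], ends[:-1]])
    gap_mid = 0.5 * (prev_end + onsets)
    baseline_starts = gap_mid - 0.1
    trials = TrialSet(onsets, ends, baseline_starts)
    return rec, trials
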