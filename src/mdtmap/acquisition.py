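"""Forward simulation of a rotated thick-slice multi-shell acquisition.

The protocol images an anisotropic stack — fine in-plane resolution, thick
slices — and repeats it at several rotations of the stack frame about the
anterior-posterior (world y) axis. Each stack measurement is modeled as

    y = D B R x

where R resamples the isotropic source volume onto the rotated stack frame
(tri-linear), B convolves along the stack's slice axis with the slice
profile (Gaussian or boxcar, FWHM/width = slice thickness, unit DC gain),
and D decimates onto the coarse stack grid. The three factors are fused into
one sparse matrix per (source grid, stack) pair: row = stack voxel, built
from profile taps along the slice normal, each tap tri-linearly interpolated
in the source grid. The exact adjoint is the sparse transpose, which is what
the super-resolution solver requires.

Noise is applied per acquired repetition (magnitude/Rician), matching a real
acquisition; averaging over repetitions happens afterwards and by default
removes the rectified noise floor using the second-moment identity
E[M^2] = s^2 + 2 sigma^2 of the Rician distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .grids import Grid
from .phantom import PhantomVolume
from .signal import BTensorProtocol, add_rician_noise

__all__ = [
    "StackGeometry",
    "LowResStackSet",
    "build_stack_grid",
    "build_sampling_operator",
    "sample_stack",
    "simulate_session",
    "average_repetitions",
    "denoise",
    "correct_distortion",
]

_AXIS_INDEX = {"LR": 0, "AP": 1, "SI": 2}


@dataclass(frozen=True)
class StackGeometry:
    """Geometry of one thick-slice stack and its rotation scheme.

    ``rotation_angles`` (degrees, in [0, 180)) place the slice-select axis;
    the in-plane axis parallel to the rotation axis is unaffected by the
    rotation. The slice profile has FWHM (Gaussian) or width (boxcar) equal
    to the slice thickness and unit DC gain.
    """

    in_plane_mm: tuple[float, float] = (1.53, 1.53)
    slice_thickness_mm: float = 5.2
    rotation_axis: str = "AP"
    rotation_angles_deg: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
    slice_profile: str = "gaussian"

    def __post_init__(self) -> None:
        if self.rotation_axis not in _AXIS_INDEX:
            raise ValueError(f"rotation_axis must be one of {sorted(_AXIS_INDEX)}")
        if self.slice_profile not in ("gaussian", "boxcar"):
            raise ValueError("slice_profile must be 'gaussian' or 'boxcar'")
        if self.slice_thickness_mm < max(self.in_plane_mm) - 1e-9:
            raise ValueError("slice thickness must be >= in-plane spacing")
        if len(self.rotation_angles_deg) < 1:
            raise ValueError("at least one rotation angle required")
        for a in self.rotation_angles_deg:
            if not (0.0 <= a < 180.0):
                raise ValueError(f"angles must lie in [0, 180), got {a}")
        object.__setattr__(
            self, "rotation_angles_deg", tuple(float(a) for a in self.rotation_angles_deg)
        )
        object.__setattr__(
            self, "in_plane_mm", tuple(float(v) for v in self.in_plane_mm)
        )

    @property
    def n_rotations(self) -> int:
        return len(self.rotation_angles_deg)

    def rotation_matrix(self, angle_deg: float) -> np.ndarray:
        """World-space rotation of the stack frame about the rotation axis."""
        t = np.deg2rad(angle_deg)
        c, s = np.cos(t), np.sin(t)
        ax = _AXIS_INDEX[self.rotation_axis]
        other = [i for i in range(3) if i != ax]
        r = np.eye(3)
        r[other[0], other[0]] = c
        r[other[0], other[1]] = -s
        r[other[1], other[0]] = s
        r[other[1], other[1]] = c
        return r

    def to_dict(self) -> dict:
        return {
            "in_plane_mm": list(self.in_plane_mm),
            "slice_thickness_mm": self.slice_thickness_mm,
            "rotation_axis": self.rotation_axis,
            "rotation_angles_deg": list(self.rotation_angles_deg),
            "slice_profile": self.slice_profile,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StackGeometry":
        return cls(
            in_plane_mm=tuple(d.get("in_plane_mm", (1.53, 1.53))),
            slice_thickness_mm=float(d.get("slice_thickness_mm", 5.2)),
            rotation_axis=d.get("rotation_axis", "AP"),
            rotation_angles_deg=tuple(d.get("rotation_angles_deg",
                                            (0, 30, 60, 90, 120, 150))),
            slice_profile=d.get("slice_profile", "gaussian"),
        )


def build_stack_grid(source: Grid, geometry: StackGeometry, angle_deg: float) -> Grid:
    """Stack grid (shape + affine) covering the source field of view.

    The stack frame has axes (in-plane-1, in-plane-2, slice-select) obtained
    by rotating the world axes; spacings are the in-plane spacings and the
    slice thickness. The slice direction is padded by half a slice so the
    profile support covers the source volume edge.
    """
    rot = geometry.rotation_matrix(angle_deg)
    # column order: two in-plane axes then slice axis; the axis parallel to
    # the rotation axis is in-plane axis 2
    ax = _AXIS_INDEX[geometry.rotation_axis]
    inplane_world = [i for i in range(3) if i != ax]
    dirs = np.column_stack(
        [rot[:, inplane_world[0]], rot[:, ax], rot[:, inplane_world[1]]]
    )
    spacing = np.array(
        [geometry.in_plane_mm[0], geometry.in_plane_mm[1], geometry.slice_thickness_mm]
    )
    corners = source.corners_world()
    local = corners @ dirs  # coordinates of corners in the stack frame
    lo, hi = local.min(axis=0), local.max(axis=0)
    shape = np.maximum(np.ceil((hi - lo) / spacing - 1e-9).astype(int), 1)
    # pad the slice axis by whole slices so the profile support covers the
    # source edge; whole-voxel padding keeps center alignment with the source
    shape[2] += 2 * int(np.ceil(geometry.slice_thickness_mm / (2.0 * spacing[2])))
    # center the grid on the FOV center
    center = (lo + hi) / 2.0
    origin_local = center - (shape - 1) / 2.0 * spacing
    affine = np.eye(4)
    affine[:3, :3] = dirs * spacing[None, :]
    affine[:3, 3] = dirs @ origin_local
    return Grid(tuple(shape), affine)


def _profile_taps(geometry: StackGeometry, source_spacing_min: float):
    """Discrete slice-profile taps (offsets mm, weights summing to 1)."""
    w = geometry.slice_thickness_mm
    if geometry.slice_profile == "boxcar":
        n = max(1, int(round(w / source_spacing_min)))
        offsets = (np.arange(n) - (n - 1) / 2.0) * (w / n)
        weights = np.full(n, 1.0 / n)
    else:
        sigma = w / np.sqrt(8.0 * np.log(2.0))  # FWHM -> sigma
        step = min(source_spacing_min, sigma)
        k = int(np.ceil(2.5 * sigma / step))
        offsets = np.arange(-k, k + 1) * step
        weights = np.exp(-0.5 * (offsets / sigma) ** 2)
        weights /= weights.sum()
    return offsets, weights


def build_sampling_operator(
    source: Grid, stack: Grid, geometry: StackGeometry
) -> sp.csr_matrix:
    """Sparse forward operator mapping a source volume to one stack.

    Shape ``(stack.n_voxels, source.n_voxels)`` with both volumes flattened
    in C order. Samples outside the source grid contribute zero
    (zero-padding boundary).
    """
    slice_dir = stack.axes[:, 2]
    offsets, weights = _profile_taps(geometry, float(source.spacing.min()))
    centers = stack.voxel_centers()  # (n_stack, 3)

    n_stack, n_src = stack.n_voxels, source.n_voxels
    src_shape = np.asarray(source.shape)
    rows_all, cols_all, vals_all = [], [], []
    for off, wgt in zip(offsets, weights):
        pts = centers + off * slice_dir[None, :]
        vox = source.world_to_voxel(pts)
        base = np.floor(vox).astype(np.int64)
        frac = vox - base
        for corner in range(8):
            bits = np.array([(corner >> a) & 1 for a in range(3)])
            idx = base + bits[None, :]
            w_tri = np.prod(np.where(bits[None, :], frac, 1.0 - frac), axis=1)
            ok = np.all((idx >= 0) & (idx < src_shape[None, :]), axis=1)
            ok &= w_tri > 0
            if not ok.any():
                continue
            flat = (idx[ok, 0] * src_shape[1] + idx[ok, 1]) * src_shape[2] + idx[ok, 2]
            rows_all.append(np.nonzero(ok)[0])
            cols_all.append(flat)
            vals_all.append(wgt * w_tri[ok])
    mat = sp.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n_stack, n_src),
    )
    return mat.tocsr()


def sample_stack(
    volume: np.ndarray,
    source_grid: Grid,
    geometry: StackGeometry,
    angle_deg: float,
    operator: Optional[sp.csr_matrix] = None,
):
    """Forward-sample one rotated thick-slice stack from an isotropic volume.

    Returns ``(stack_volume, stack_grid)``. A precomputed ``operator`` (from
    :func:`build_sampling_operator` for the same geometry/angle) may be
    passed to skip rebuilding it.
    """
    if not (0.0 <= angle_deg < 180.0):
        raise ValueError(f"angle must lie in [0, 180), got {angle_deg}")
    vol = np.asarray(volume, dtype=float)
    if vol.shape != source_grid.shape:
        raise ValueError("volume shape does not match its grid")
    if not np.isfinite(vol).all():
        raise ValueError("volume must be finite")
    stack_grid = build_stack_grid(source_grid, geometry, angle_deg)
    if operator is None:
        operator = build_sampling_operator(source_grid, stack_grid, geometry)
    y = operator @ vol.ravel()
    return y.reshape(stack_grid.shape), stack_grid


@dataclass
class LowResStackSet:
    """Simulated/acquired stacks indexed by (rotation, shell, repetition).

    ``volumes[i_rot][i_shell]`` is an array of shape ``(n_reps, *stack_shape)``
    for rotation ``i_rot`` and shell ``i_shell``. Geometry, protocol, the
    noise sigma and the seed used to generate the data travel with it.
    """

    volumes: list[list[np.ndarray]]
    stack_grids: list[Grid]
    protocol: BTensorProtocol
    geometry: StackGeometry
    noise_sigma: float = 0.0
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.volumes) != self.geometry.n_rotations:
            raise ValueError("one volume list per rotation required")
        for i_rot, per_shell in enumerate(self.volumes):
            if len(per_shell) != len(self.protocol.shells):
                raise ValueError("one array per shell required")
            for i_sh, arr in enumerate(per_shell):
                if arr.shape[1:] != self.stack_grids[i_rot].shape:
                    raise ValueError(
                        f"stack shape mismatch at rotation {i_rot}, shell {i_sh}"
                    )

    @property
    def n_volumes(self) -> int:
        return sum(arr.shape[0] for per_shell in self.volumes for arr in per_shell)

    @property
    def repetitions(self) -> tuple[int, ...]:
        return tuple(arr.shape[0] for arr in self.volumes[0])

    def shell_stacks(self, i_shell: int) -> list[tuple[np.ndarray, Grid]]:
        """Per-rotation (repetition-axis) arrays and grids for one shell."""
        return [
            (self.volumes[i_rot][i_shell], self.stack_grids[i_rot])
            for i_rot in range(self.geometry.n_rotations)
        ]

    # -- persistence: one 4-D NIfTI per rotation + JSON manifest -----------

    def save(self, directory) -> None:
        from .nifti import write_nifti

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i_rot, per_shell in enumerate(self.volumes):
            stacked = np.concatenate(per_shell, axis=0)  # (total_reps, x, y, z)
            write_nifti(
                directory / f"stacks_rot{i_rot:02d}.nii",
                np.moveaxis(stacked, 0, -1),
                self.stack_grids[i_rot].affine,
                description="dMRI stack volumes (unitless signal)",
            )
        manifest = {
            "protocol": self.protocol.to_dict(),
            "geometry": self.geometry.to_dict(),
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "repetitions": list(self.repetitions),
            "n_volumes": self.n_volumes,
            # reserved for acquisition-specific companions not simulated here
            "phase_encoding_reversed": None,
            "meta": self.meta,
        }
        (directory / "stacks.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "LowResStackSet":
        from .nifti import read_nifti

        directory = Path(directory)
        manifest = json.loads((directory / "stacks.json").read_text())
        protocol = BTensorProtocol.from_dict(manifest["protocol"])
        geometry = StackGeometry.from_dict(manifest["geometry"])
        reps = manifest["repetitions"]
        volumes, grids = [], []
        for i_rot in range(geometry.n_rotations):
            data, affine = read_nifti(directory / f"stacks_rot{i_rot:02d}.nii")
            data = np.moveaxis(data, -1, 0)
            if data.shape[0] != sum(reps):
                raise ValueError(
                    f"rotation {i_rot}: expected {sum(reps)} volumes, "
                    f"found {data.shape[0]}"
                )
            grids.append(Grid(data.shape[1:], affine))
            per_shell, start = [], 0
            for r in reps:
                per_shell.append(np.ascontiguousarray(data[start : start + r]))
                start += r
            volumes.append(per_shell)
        return cls(
            volumes=volumes,
            stack_grids=grids,
            protocol=protocol,
            geometry=geometry,
            noise_sigma=float(manifest.get("noise_sigma", 0.0)),
            seed=manifest.get("seed"),
            meta=manifest.get("meta", {}),
        )


def simulate_session(
    p: PhantomVolume,
    protocol: BTensorProtocol,
    geometry: StackGeometry,
    sigma: float = 0.0,
    seed: Optional[int] = None,
) -> LowResStackSet:
    """Simulate a full session: rotations x shells x repetitions.

    For each shell the noiseless spherical-encoding signal volume is
    evaluated once from the phantom's mixtures, forward-sampled through each
    rotation's stack operator, and independently Rician-corrupted per
    repetition. Deterministic under a fixed ``seed``.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    for shell in protocol.shells:
        if shell.shape != "spherical":
            raise ValueError("session simulation supports spherical encoding only")
    rng = np.random.default_rng(seed)
    shell_signals = [p.shell_signal(s.b) for s in protocol.shells]

    volumes: list[list[np.ndarray]] = []
    grids: list[Grid] = []
    for angle in geometry.rotation_angles_deg:
        stack_grid = build_stack_grid(p.grid, geometry, angle)
        op = build_sampling_operator(p.grid, stack_grid, geometry)
        per_shell = []
        for shell, sig in zip(protocol.shells, shell_signals):
            clean = (op @ sig.ravel()).reshape(stack_grid.shape)
            reps = np.empty((shell.repetitions,) + stack_grid.shape)
            for r in range(shell.repetitions):
                reps[r] = add_rician_noise(clean, sigma, rng)
            per_shell.append(reps)
        volumes.append(per_shell)
        grids.append(stack_grid)
    return LowResStackSet(
        volumes=volumes,
        stack_grids=grids,
        protocol=protocol,
        geometry=geometry,
        noise_sigma=sigma,
        seed=seed,
    )


def average_repetitions(
    s: LowResStackSet, method: str = "auto", sigma: Optional[float] = None
) -> LowResStackSet:
    """Collapse repetitions to one volume per (rotation, shell).

    Methods
    -------
    ``"mean"``
        Arithmetic mean of the magnitude volumes. Retains the Rician bias
        E[M] > s at low signal (the rectified noise floor).
    ``"rician_corrected"``
        Second-moment average ``sqrt(max(mean(M^2) - 2 sigma^2, 0))``, which
        is unbiased in the squared signal (E[M^2] = s^2 + 2 sigma^2) and so
        removes the noise floor that would otherwise bias the high-b shells
        toward lower apparent diffusivity. Requires a noise sigma (argument
        or the set's recorded value).
    ``"auto"``
        ``rician_corrected`` when a positive sigma is known, else ``mean``.
    """
    if method not in ("auto", "mean", "rician_corrected"):
        raise ValueError(f"unknown averaging method {method!r}")
    sig = s.noise_sigma if sigma is None else sigma
    if method == "auto":
        method = "rician_corrected" if sig and sig > 0 else "mean"
    if method == "rician_corrected" and not (sig and sig > 0):
        raise ValueError("rician_corrected averaging requires a positive sigma")

    volumes = []
    for per_shell in s.volumes:
        out_shell = []
        for arr in per_shell:
            if arr.shape[0] < 1:
                raise ValueError("missing repetitions")
            if method == "mean":
                avg = arr.mean(axis=0)
            else:
                avg = np.sqrt(np.maximum((arr**2).mean(axis=0) - 2.0 * sig**2, 0.0))
            out_shell.append(avg[None])
        volumes.append(out_shell)
    meta = dict(s.meta)
    meta["effective_repetitions"] = list(s.repetitions)
    meta["averaging_method"] = method
    return LowResStackSet(
        volumes=volumes,
        stack_grids=s.stack_grids,
        protocol=s.protocol,
        geometry=s.geometry,
        noise_sigma=s.noise_sigma,
        seed=s.seed,
        meta=meta,
    )


def denoise(s: LowResStackSet, method: str = "none") -> LowResStackSet:
    """Denoising hook. Only ``"none"`` (identity) is implemented; random
    noise is instead controlled through repetitions and the noise-floor
    corrected average."""
    if method != "none":
        raise NotImplementedError(f"denoising method {method!r} not implemented")
    return s


def correct_distortion(s: LowResStackSet, method: str = "none") -> LowResStackSet:
    """Distortion-correction hook. The simulator introduces no susceptibility
    or eddy distortions, so only the identity method ``"none"`` exists."""
    if method != "none":
        raise NotImplementedError(f"distortion method {method!r} not implemented")
    return s
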