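"""Digital brain phantoms with partial-volume boundaries and ground truth.

The phantom is a concentric "head": outer background (air), a CSF rim with
sulcal invaginations, a cortical ribbon, a white-matter core containing
periventricular CSF (two lateral ventricles) and optional iron-rich deep
nuclei. Voxels on class boundaries carry fractional occupancies computed by
supersampled point classification, so partial-volume mixing — the phenomenon
the tissue-diffusivity estimator must be robust to — is present by
construction.

Each tissue class has a per-voxel mean-diffusivity map (initialized to a
class default and editable by lesion insertion) so that focal diffusivity
changes can be written into the anatomy without disturbing the fractions.

The ground-truth target is the *CSF-excluded* tissue-weighted mean
diffusivity: in a voxel mixing cortex, white matter and CSF, the truth is the
fraction-weighted mean MD of the non-CSF compartments only. This is exactly
the quantity a CSF-suppressed two-shell estimate is supposed to recover; the
ground-truth map is therefore invariant to the CSF fraction at fixed tissue
composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .grids import Grid, centered_grid
from .signal import FREE_WATER_DIFFUSIVITY

__all__ = [
    "TISSUE_CLASSES",
    "DEFAULT_DIFFUSIVITIES",
    "PhantomVolume",
    "LesionSpec",
    "build_phantom",
    "insert_lesion",
    "ground_truth_tissue_md",
]

#: Non-background classes, in label order. CSF is excluded from ground truth.
TISSUE_CLASSES = ("csf", "cortex", "white_matter", "deep_nuclei")

#: Default class mean diffusivities, um^2/ms.
DEFAULT_DIFFUSIVITIES = {
    "csf": FREE_WATER_DIFFUSIVITY,
    "cortex": 0.8,
    "white_matter": 0.7,
    "deep_nuclei": 0.7,
}

#: MD below this is unphysical for parenchyma; lesions may not cross it.
MIN_TISSUE_MD = 0.05

#: Voxels whose non-CSF fraction falls below this carry no usable tissue
#: signal; they are flagged invalid in ground-truth and bias reports.
MIN_TISSUE_FRACTION = 0.05


@dataclass
class LesionSpec:
    """A spherical focal diffusivity change.

    ``kind`` selects which classes are affected by default:
    ``focal_hyperintense`` shifts cortex MD by ``+delta_md`` (a cortical
    malformation read-out), ``tumor`` shifts cortex and white matter by
    ``+delta_md``, ``ischemia`` shifts its targets by ``-delta_md``
    (cytotoxic restriction). ``target_classes`` overrides the default set.
    """

    kind: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    delta_md: float
    target_classes: Optional[tuple[str, ...]] = None

    _DEFAULT_TARGETS = {
        "focal_hyperintense": ("cortex",),
        "tumor": ("cortex", "white_matter"),
        "ischemia": ("cortex", "white_matter"),
    }

    def __post_init__(self) -> None:
        if self.kind not in self._DEFAULT_TARGETS:
            raise ValueError(
                f"kind must be one of {sorted(self._DEFAULT_TARGETS)}, got {self.kind}"
            )
        if not (self.radius_mm > 0):
            raise ValueError("radius_mm must be positive")
        if self.target_classes is None:
            self.target_classes = self._DEFAULT_TARGETS[self.kind]
        unknown = set(self.target_classes) - set(TISSUE_CLASSES)
        if unknown:
            raise ValueError(f"unknown target classes: {sorted(unknown)}")

    @property
    def signed_delta(self) -> float:
        return -abs(self.delta_md) if self.kind == "ischemia" else self.delta_md

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "center_mm": list(self.center_mm),
            "radius_mm": self.radius_mm,
            "delta_md": self.delta_md,
            "target_classes": list(self.target_classes),
        }


@dataclass
class PhantomVolume:
    """Labeled digital head: per-class fraction maps and MD maps on a grid."""

    grid: Grid
    fractions: dict[str, np.ndarray]
    md_maps: dict[str, np.ndarray]
    lesions: list[LesionSpec] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in TISSUE_CLASSES:
            if name not in self.fractions or name not in self.md_maps:
                raise ValueError(f"missing maps for class {name!r}")
            if self.fractions[name].shape != self.grid.shape:
                raise ValueError(f"fraction map shape mismatch for {name!r}")
        total = self.total_fraction()
        if total.min() < -1e-9 or total.max() > 1.0 + 1e-6:
            raise ValueError("per-voxel fractions must lie in [0, 1]")

    def total_fraction(self) -> np.ndarray:
        return sum(self.fractions[c] for c in TISSUE_CLASSES)

    def tissue_fraction(self) -> np.ndarray:
        """Non-CSF, non-background fraction per voxel."""
        return sum(self.fractions[c] for c in TISSUE_CLASSES if c != "csf")

    def csf_fraction(self) -> np.ndarray:
        return self.fractions["csf"]

    def head_mask(self) -> np.ndarray:
        return self.total_fraction() > 0.5

    def copy(self) -> "PhantomVolume":
        return PhantomVolume(
            grid=self.grid,
            fractions={c: v.copy() for c, v in self.fractions.items()},
            md_maps={c: v.copy() for c, v in self.md_maps.items()},
            lesions=list(self.lesions),
            params=dict(self.params),
        )

    def shell_signal(self, b: float) -> np.ndarray:
        """Noiseless spherical-encoding signal volume at b-value ``b``.

        Vectorized form of :func:`mdtmap.signal.mixture_signal` over the
        whole grid; background contributes zero signal.
        """
        out = np.zeros(self.grid.shape)
        for c in TISSUE_CLASSES:
            out += self.fractions[c] * np.exp(-b * self.md_maps[c] * 1e-3)
        return out

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        """Write fraction maps as one 4-D NIfTI + MD maps + JSON manifest."""
        from .nifti import write_nifti

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        frac4d = np.stack([self.fractions[c] for c in TISSUE_CLASSES], axis=-1)
        md4d = np.stack([self.md_maps[c] for c in TISSUE_CLASSES], axis=-1)
        write_nifti(directory / "fractions.nii", frac4d, self.grid.affine,
                    description="class fractions (unitless)")
        write_nifti(directory / "md_maps.nii", md4d, self.grid.affine,
                    description="class MD maps (um^2/ms)")
        manifest = {
            "classes": list(TISSUE_CLASSES),
            "lesions": [l.to_dict() for l in self.lesions],
            "params": self.params,
        }
        (directory / "phantom.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "PhantomVolume":
        from .nifti import read_nifti

        directory = Path(directory)
        manifest = json.loads((directory / "phantom.json").read_text())
        frac4d, affine = read_nifti(directory / "fractions.nii")
        md4d, _ = read_nifti(directory / "md_maps.nii")
        classes = manifest["classes"]
        grid = Grid(frac4d.shape[:3], affine)
        return cls(
            grid=grid,
            fractions={c: np.ascontiguousarray(frac4d[..., i]) for i, c in enumerate(classes)},
            md_maps={c: np.ascontiguousarray(md4d[..., i]) for i, c in enumerate(classes)},
            lesions=[LesionSpec(**l) for l in manifest.get("lesions", [])],
            params=manifest.get("params", {}),
        )


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

_BACKGROUND = 0
_LABELS = {name: i + 1 for i, name in enumerate(TISSUE_CLASSES)}


def _classify_points(pts: np.ndarray, geo: dict) -> np.ndarray:
    """Label world-space points with the concentric head anatomy.

    Order of precedence: outside head -> background; ventricles -> CSF;
    deep nuclei; sulcally modulated outer CSF rim; cortical ribbon; else WM.
    """
    r = np.linalg.norm(pts, axis=-1)
    labels = np.full(pts.shape[0], _BACKGROUND, dtype=np.int8)

    inside = r <= geo["head_radius"]
    labels[inside] = _LABELS["white_matter"]

    # sulcal modulation of the CSF rim: Gaussian invaginations of the rim
    # into the cortex at fixed azimuths around the rotation (AP, y) axis;
    # wedge width is angular (arc length taken at the head surface) so the
    # cuts narrow toward the axis like real sulci
    phi = np.arctan2(pts[:, 2], pts[:, 0])
    n_sulci = geo["n_sulci"]
    if n_sulci > 0 and geo["sulcal_width"] > 0:
        centers = geo["sulcus_phase"] + 2 * np.pi * np.arange(n_sulci) / n_sulci
        d = np.abs(((phi[:, None] - centers[None, :]) + np.pi) % (2 * np.pi) - np.pi)
        arc = d.min(axis=1) * geo["head_radius"]
        bump = np.exp(-((arc / geo["sulcal_width"]) ** 2))
    else:
        bump = np.zeros_like(r)
    rim = geo["rim_width"] + geo["sulcal_depth"] * bump

    cortex_outer = geo["head_radius"] - rim
    cortex_inner = cortex_outer - geo["ribbon_thickness"]
    labels[inside & (r > cortex_outer)] = _LABELS["csf"]
    labels[inside & (r <= cortex_outer) & (r > cortex_inner)] = _LABELS["cortex"]

    for c in geo["nucleus_centers"]:
        near = np.linalg.norm(pts - np.asarray(c), axis=-1) <= geo["nucleus_radius"]
        labels[near & (labels == _LABELS["white_matter"])] = _LABELS["deep_nuclei"]

    for c in geo["ventricle_centers"]:
        near = np.linalg.norm(pts - np.asarray(c), axis=-1) <= geo["ventricle_radius"]
        labels[near & inside] = _LABELS["csf"]

    return labels


def build_phantom(
    shape=(48, 48, 48),
    spacing: float = 1.0,
    *,
    head_radius_mm: Optional[float] = None,
    rim_width_mm: float = 1.5,
    ribbon_thickness_mm: float = 4.0,
    sulcal_width_mm: float = 2.0,
    n_sulci: int = 6,
    ventricle_radius_mm: Optional[float] = None,
    deep_nuclei: bool = True,
    diffusivities: Optional[dict[str, float]] = None,
    supersample: int = 3,
) -> PhantomVolume:
    """Build a concentric digital head phantom with anti-aliased boundaries.

    Parameters are in millimetres. ``head_radius_mm`` and
    ``ventricle_radius_mm`` default to fractions of the field of view so the
    anatomy scales with the grid. Boundary voxels receive fractional class
    occupancies from ``supersample``^3 point classifications per voxel.

    Default class diffusivities: cortex 0.8, white matter 0.7, CSF 3.0,
    deep nuclei 0.7 um^2/ms.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    grid = centered_grid(shape, spacing)
    if min(grid.shape) < 16:
        raise ValueError("phantom grid must be at least 16^3")
    if ribbon_thickness_mm < spacing:
        raise ValueError("cortical ribbon must be at least one voxel thick")

    fov_half = min(s * sp for s, sp in zip(grid.shape, [spacing] * 3)) / 2.0
    head_radius = head_radius_mm if head_radius_mm is not None else 0.92 * fov_half
    ventricle_radius = (
        ventricle_radius_mm if ventricle_radius_mm is not None else 0.18 * head_radius
    )
    v_off = 0.22 * head_radius
    nucleus_radius = 0.11 * head_radius
    n_off = 0.48 * head_radius
    geo = {
        "head_radius": head_radius,
        "rim_width": rim_width_mm,
        "ribbon_thickness": ribbon_thickness_mm,
        "sulcal_width": sulcal_width_mm,
        "sulcal_depth": ribbon_thickness_mm + rim_width_mm,
        "n_sulci": int(n_sulci),
        "sulcus_phase": np.pi / n_sulci if n_sulci else 0.0,
        "ventricle_radius": ventricle_radius,
        "ventricle_centers": [(-v_off, 0.0, 0.0), (v_off, 0.0, 0.0)],
        "nucleus_radius": nucleus_radius if deep_nuclei else 0.0,
        "nucleus_centers": [(-n_off, 0.0, 0.0), (n_off, 0.0, 0.0)] if deep_nuclei else [],
    }
    if head_radius - rim_width_mm - ribbon_thickness_mm <= v_off + ventricle_radius:
        raise ValueError("geometry leaves no white-matter core")

    # supersampled occupancy: classify s^3 points per voxel, count labels
    s = supersample
    offsets = (np.arange(s) + 0.5) / s - 0.5
    sub = np.stack(np.meshgrid(offsets, offsets, offsets, indexing="ij"), axis=-1)
    sub = sub.reshape(-1, 3)  # (s^3, 3) in voxel units

    idx = np.indices(grid.shape).reshape(3, -1).T.astype(float)
    counts = np.zeros((len(TISSUE_CLASSES) + 1, grid.n_voxels), dtype=np.int32)
    for off in sub:
        pts = grid.voxel_to_world(idx + off)
        lab = _classify_points(pts, geo)
        for li in range(len(TISSUE_CLASSES) + 1):
            counts[li] += lab == li

    fractions = {
        name: (counts[_LABELS[name]] / s**3).reshape(grid.shape)
        for name in TISSUE_CLASSES
    }
    if fractions["white_matter"].sum() == 0:
        raise ValueError("geometry leaves no white-matter core")

    md_defaults = dict(DEFAULT_DIFFUSIVITIES)
    if diffusivities:
        md_defaults.update(diffusivities)
    md_maps = {
        name: np.full(grid.shape, float(md_defaults[name]))
        for name in TISSUE_CLASSES
    }
    params = {
        "shape": list(grid.shape),
        "spacing_mm": spacing,
        "supersample": s,
        "diffusivities": {k: float(v) for k, v in md_defaults.items()},
        **{k: (list(v) if isinstance(v, (list, tuple)) else float(v))
           for k, v in geo.items()
           if k in ("head_radius", "rim_width", "ribbon_thickness", "sulcal_width",
                    "ventricle_radius")},
    }
    return PhantomVolume(grid=grid, fractions=fractions, md_maps=md_maps, params=params)


def insert_lesion(p: PhantomVolume, lesion: LesionSpec) -> PhantomVolume:
    """Return a copy of ``p`` with the lesion's MD shift applied.

    The shift acts on the MD maps of the lesion's target classes inside the
    sphere; class fractions are untouched, so the lesion changes diffusivity,
    not anatomy. Ground truth updates automatically since it is derived from
    the current maps.
    """
    centers = p.grid.voxel_centers().reshape(*p.grid.shape, 3)
    dist = np.linalg.norm(centers - np.asarray(lesion.center_mm), axis=-1)
    inside = dist <= lesion.radius_mm
    if not inside.any():
        raise ValueError("lesion lies wholly outside the volume")

    out = p.copy()
    delta = lesion.signed_delta
    for cls in lesion.target_classes:
        shifted = out.md_maps[cls][inside] + delta
        if delta != 0 and (shifted <= MIN_TISSUE_MD).any():
            raise ValueError(
                f"lesion drives {cls} MD to <= {MIN_TISSUE_MD} um^2/ms"
            )
        out.md_maps[cls][inside] = shifted
    out.lesions.append(replace(lesion))
    return out


def ground_truth_tissue_md(p: PhantomVolume):
    """CSF-excluded tissue-weighted mean diffusivity, with validity mask.

    Per voxel: ``sum_c f_c * md_c / sum_c f_c`` over non-CSF tissue classes.
    Voxels with total tissue fraction below 0.05 (pure CSF, background) are
    invalid and set to NaN.

    Returns
    -------
    (values, valid): MD map in um^2/ms and boolean validity mask.
    """
    num = np.zeros(p.grid.shape)
    den = np.zeros(p.grid.shape)
    for c in TISSUE_CLASSES:
        if c == "csf":
            continue
        num += p.fractions[c] * p.md_maps[c]
        den += p.fractions[c]
    valid = den >= MIN_TISSUE_FRACTION
    values = np.full(p.grid.shape, np.nan)
    values[valid] = num[valid] / den[valid]
    return values, valid
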