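"""Synthetic multimodal MRI phantom with known rim+/rim- lesions.

The phantom emulates the image features that drive paramagnetic-rim
classification, on a geometry simple enough that every downstream stage can
be checked against the construction itself:

* lesions are randomly oriented ellipsoids, hyperintense on the FLAIR-like
  channel;
* rim+ lesions additionally carry a closed one-shell rim at the lesion
  boundary — hypointense on the phase-like channel (configurable sign) and
  attenuated on the T2*-magnitude-like channel — obtained by subtracting a
  morphologically eroded core from the lesion mask;
* rim-shaped phase artefacts can be placed with no FLAIR counterpart,
  mimicking the rim-like intensity artefacts that confound visual rating;
* confluent lesion pairs, additive Gaussian noise and a smooth low-order
  polynomial bias field are optional.

This is an intensity phantom, not a physical MR simulation: there is no
k-space, no Bloch dynamics and no anatomical realism.  Contrast magnitudes
are free parameters of the generator, not claims about tissue.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .volume import VolumeSet, save_volume_set, save_mask

#: minimum lesion volume retained by the candidate-exclusion stage; the
#: generator guarantees every rim+ lesion exceeds it so none is filtered out.
MIN_RIM_POS_VOLUME_MM3 = 12.3

SIX_CONN = ndimage.generate_binary_structure(3, 1)


class PlacementError(RuntimeError):
    """Raised when lesions cannot be placed after bounded retries."""


@dataclass
class ModalityContrast:
    """Piecewise-constant intensity levels for one synthetic contrast."""
    background: float
    lesion: float
    rim_shell: float


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 0.65
    n_rim_pos: int = 5
    n_rim_neg: int = 20
    n_artefacts: int = 2
    lesion_radius_range_mm: tuple[float, float] = (2.0, 4.0)
    rim_thickness_mm: float = 0.8
    contrast: dict[str, ModalityContrast] = field(default_factory=lambda: {
        "flair": ModalityContrast(background=100.0, lesion=180.0,
                                  rim_shell=180.0),
        "t2star": ModalityContrast(background=100.0, lesion=90.0,
                                   rim_shell=55.0),
        "phase": ModalityContrast(background=0.0, lesion=0.0,
                                  rim_shell=-40.0),
    })
    rim_sign: int = -1                 # hypointense rim on phase by default
    noise_sd: float = 0.0
    bias_field_amplitude: float = 0.0
    confluence_probability: float = 0.0
    min_separation_mm: float = 10.0
    edge_margin_vox: int = 10
    max_placement_retries: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (("n_rim_pos", self.n_rim_pos),
                          ("n_rim_neg", self.n_rim_neg),
                          ("n_artefacts", self.n_artefacts)):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rim_thickness_mm <= 0:
            raise ValueError("rim_thickness_mm must be positive")
        if any(s < 64 for s in self.grid_shape):
            raise ValueError("grid_shape must be at least 64 voxels per axis")
        lo, hi = self.lesion_radius_range_mm
        if not 0 < lo <= hi:
            raise ValueError("lesion_radius_range_mm must satisfy 0 < lo <= hi")
        # an ellipsoid with all semi-axes at the minimum radius must clear
        # the size filter even after discretisation losses
        if 4.0 / 3.0 * np.pi * lo ** 3 < 1.2 * MIN_RIM_POS_VOLUME_MM3:
            raise ValueError(
                "minimum lesion radius too small: rim+ lesions could fall "
                f"under the {MIN_RIM_POS_VOLUME_MM3} mm^3 size filter")
        if not 0.0 <= self.confluence_probability <= 1.0:
            raise ValueError("confluence_probability must be in [0, 1]")

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PhantomConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "contrast" in d:
            d["contrast"] = {k: ModalityContrast(**v)
                             for k, v in d["contrast"].items()}
        for key in ("grid_shape", "lesion_radius_range_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Construction record of one phantom volume."""
    lesion_labels: np.ndarray          # int array, one label per placed lesion
    rim_plus_mask: np.ndarray          # bool, union of rim+ lesion voxels
    artefact_mask: np.ndarray          # bool, rim-shaped phase artefacts
    region_masks: dict[str, np.ndarray]
    table: pd.DataFrame                # one row per placed lesion

    @property
    def lesion_mask(self) -> np.ndarray:
        return self.lesion_labels > 0


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _ellipsoid_mask(shape: Sequence[int], center: np.ndarray,
                    semi_axes_vox: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Boolean mask of a rotated ellipsoid, rasterised on the voxel grid."""
    r_max = int(np.ceil(semi_axes_vox.max())) + 1
    lo = np.maximum(np.floor(center).astype(int) - r_max, 0)
    hi = np.minimum(np.floor(center).astype(int) + r_max + 1, shape)
    grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)],
                        indexing="ij")
    pts = np.stack([g - c for g, c in zip(grids, center)], axis=-1)
    local = pts @ rot                          # rotate into ellipsoid frame
    inside = np.sum((local / semi_axes_vox) ** 2, axis=-1) <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = inside
    return mask


def _rim_shell(lesion: np.ndarray, thickness_vox: int) -> np.ndarray:
    """Shell of the lesion boundary: lesion minus its eroded core."""
    core = ndimage.binary_erosion(lesion, structure=SIX_CONN,
                                  iterations=max(1, thickness_vox))
    return lesion & ~core


def _polynomial_bias_field(shape: Sequence[int],
                           rng: np.random.Generator) -> np.ndarray:
    """Smooth random field in [-1, 1] from a second-order polynomial."""
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    basis = [zz, yy, xx, zz * yy, zz * xx, yy * xx,
             zz ** 2, yy ** 2, xx ** 2]
    coeff = rng.uniform(-1.0, 1.0, size=len(basis))
    fld = sum(c * b for c, b in zip(coeff, basis))
    m = np.abs(fld).max()
    return fld / m if m > 0 else fld


def _make_region_masks(shape: Sequence[int]) -> dict[str, np.ndarray]:
    """Schematic anatomy: a central ventricle blob, a cortical shell just
    inside the brain boundary, a small deep-gray nucleus, residual WM."""
    shape = tuple(shape)
    center = (np.array(shape) - 1) / 2.0
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum(((g - c) / (0.46 * s)) ** 2
             for g, c, s in zip((zz, yy, xx), center, shape))
    brain = d2 <= 1.0
    inner = ndimage.binary_erosion(brain, structure=SIX_CONN, iterations=3)
    cortex = brain & ~inner
    d2v = sum(((g - c) / (0.10 * s)) ** 2
              for g, c, s in zip((zz, yy, xx), center, shape))
    ventricles = d2v <= 1.0
    dg_center = center + np.array(shape) * np.array([0.18, 0.0, 0.0])
    d2g = sum(((g - c) / (0.06 * s)) ** 2
              for g, c, s in zip((zz, yy, xx), dg_center, shape))
    deep_gray = (d2g <= 1.0) & ~ventricles
    wm = inner & ~ventricles & ~deep_gray
    return {"brain": brain, "cortex": cortex, "ventricles": ventricles,
            "deep_gray": deep_gray, "white_matter": wm}


def generate_phantom(config: PhantomConfig) -> tuple[VolumeSet, GroundTruth]:
    """Generate one synthetic patient volume with known ground truth.

    Deterministic given ``config.seed``.  Raises :class:`PlacementError`
    when the requested lesion count cannot be placed with the configured
    separation after ``max_placement_retries`` attempts per lesion.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    sp = config.spacing_mm
    vox_vol = sp ** 3
    thick_vox = max(1, round(config.rim_thickness_mm / sp))
    min_sep_vox = config.min_separation_mm / sp

    vols = {name: np.full(shape, c.background, dtype=np.float32)
            for name, c in config.contrast.items()}
    lesion_labels = np.zeros(shape, dtype=np.int32)
    rim_plus_mask = np.zeros(shape, dtype=bool)
    artefact_mask = np.zeros(shape, dtype=bool)
    regions = _make_region_masks(shape)

    # class sequence is shuffled so lesion ids carry no class information
    classes = ["rim+"] * config.n_rim_pos + ["rim-"] * config.n_rim_neg
    rng.shuffle(classes)

    margin = config.edge_margin_vox + int(
        np.ceil(config.lesion_radius_range_mm[1] / sp)) + thick_vox
    lo_bound = np.full(3, margin, dtype=float)
    hi_bound = np.array(shape, dtype=float) - margin
    if np.any(hi_bound <= lo_bound):
        raise PlacementError("grid too small for the configured lesion radii")

    rows: list[dict] = []
    centers: list[np.ndarray] = []

    def sample_center() -> np.ndarray:
        return rng.uniform(lo_bound, hi_bound)

    def place_one(cls: str, lesion_id: int) -> None:
        confluent_with = None
        for _ in range(config.max_placement_retries):
            semi_mm = rng.uniform(*config.lesion_radius_range_mm, size=3)
            rot = _random_rotation(rng)
            if (centers and config.confluence_probability > 0
                    and rng.random() < config.confluence_probability):
                # deliberately overlap a previously placed lesion
                j = int(rng.integers(len(centers)))
                offset = rng.normal(size=3)
                offset *= (semi_mm.mean() / sp) / np.linalg.norm(offset)
                center = np.clip(centers[j] + offset, lo_bound, hi_bound)
                confluent_with = rows[j]["lesion_id"]
            else:
                center = sample_center()
                confluent_with = None
                dists = [np.linalg.norm(center - c) for c in centers]
                if dists and min(dists) < min_sep_vox:
                    continue
            mask = _ellipsoid_mask(shape, center, semi_mm / sp, rot)
            n_vox = int(mask.sum())
            if n_vox == 0:
                continue
            if cls == "rim+":
                if n_vox * vox_vol <= MIN_RIM_POS_VOLUME_MM3:
                    continue
                shell = _rim_shell(mask, thick_vox)
                core = mask & ~shell
                if not core.any() or not shell.any():
                    continue
            # paint intensities
            for name, c in config.contrast.items():
                vols[name][mask] = c.lesion
            if cls == "rim+":
                for name, c in config.contrast.items():
                    shell_val = c.rim_shell
                    if name == "phase":
                        shell_val = (abs(c.rim_shell - c.background)
                                     * config.rim_sign + c.background)
                    vols[name][shell] = shell_val
                rim_plus_mask[shell | core] = True
            lesion_labels[mask] = lesion_id
            centers.append(center)
            com = np.argwhere(mask).mean(axis=0)
            region = _region_of_point(com, regions)
            rows.append({
                "lesion_id": lesion_id, "class": cls, "n_voxels": n_vox,
                "volume_mm3": n_vox * vox_vol,
                "center_x": com[0], "center_y": com[1], "center_z": com[2],
                "region": region,
                "confluent_with": confluent_with,
            })
            return
        raise PlacementError(
            f"could not place lesion {lesion_id} ({cls}) after "
            f"{config.max_placement_retries} retries")

    for i, cls in enumerate(classes, start=1):
        place_one(cls, i)

    # rim-shaped artefacts: phase ring with no FLAIR lesion
    for k in range(config.n_artefacts):
        for _ in range(config.max_placement_retries):
            center = sample_center()
            dists = [np.linalg.norm(center - c) for c in centers]
            if dists and min(dists) < min_sep_vox:
                continue
            semi_mm = rng.uniform(*config.lesion_radius_range_mm, size=3)
            rot = _random_rotation(rng)
            mask = _ellipsoid_mask(shape, center, semi_mm / sp, rot)
            if not mask.any():
                continue
            ring = _rim_shell(mask, thick_vox)
            if not ring.any():
                continue
            pc = config.contrast["phase"]
            vols["phase"][ring] = (abs(pc.rim_shell - pc.background)
                                   * config.rim_sign + pc.background)
            if "t2star" in vols:
                tc = config.contrast["t2star"]
                vols["t2star"][ring] = (tc.background + tc.rim_shell) / 2.0
            artefact_mask |= ring
            centers.append(center)
            break
        else:
            raise PlacementError(f"could not place artefact {k}")

    if config.bias_field_amplitude > 0:
        fld = _polynomial_bias_field(shape, rng)
        for name in vols:
            if name == "phase":
                continue        # bias fields are a magnitude-image phenomenon
            vols[name] *= (1.0 + config.bias_field_amplitude * fld
                           ).astype(np.float32)
    if config.noise_sd > 0:
        for name in vols:
            vols[name] += rng.normal(0.0, config.noise_sd,
                                     size=shape).astype(np.float32)

    cols = ["lesion_id", "class", "n_voxels", "volume_mm3",
            "center_x", "center_y", "center_z", "region", "confluent_with"]
    table = pd.DataFrame(rows, columns=cols)
    vs = VolumeSet(modalities=vols, spacing_mm=sp)
    gt = GroundTruth(lesion_labels=lesion_labels, rim_plus_mask=rim_plus_mask,
                     artefact_mask=artefact_mask, region_masks=regions,
                     table=table)
    return vs, gt


def _region_of_point(pt: np.ndarray, regions: dict[str, np.ndarray]) -> str:
    idx = tuple(np.round(pt).astype(int))
    for name in ("ventricles", "deep_gray", "cortex", "white_matter"):
        if name in regions and regions[name][idx]:
            return name
    return "other"


def generate_cohort(base_config: PhantomConfig, n_patients: int,
                    sites: Sequence[str] = ("siteA", "siteB"),
                    seed: int = 0) -> list[tuple[VolumeSet, GroundTruth]]:
    """Generate a multi-patient, multi-site cohort.

    Each patient reuses ``base_config`` with a per-patient seed derived from
    ``seed``; patients alternate between sites.  Patient and site ids are
    stamped onto the returned :class:`VolumeSet` objects.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_patients):
        cfg_dict = asdict(base_config)
        cfg_dict["contrast"] = {k: ModalityContrast(**v)
                                for k, v in cfg_dict["contrast"].items()}
        for key in ("grid_shape", "lesion_radius_range_mm"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg_dict["seed"] = int(rng.integers(2 ** 31 - 1))
        vs, gt = generate_phantom(PhantomConfig(**cfg_dict))
        vs.patient_id = f"P{i:03d}"
        vs.site_id = sites[i % len(sites)]
        out.append((vs, gt))
    return out


def save_phantom(vs: VolumeSet, gt: GroundTruth, out_dir: str,
                 config: PhantomConfig | None = None) -> None:
    """Persist a phantom: NIfTI volumes and masks, CSV table, YAML config."""
    os.makedirs(out_dir, exist_ok=True)
    save_volume_set(vs, out_dir)
    save_mask(gt.lesion_labels, vs.spacing_mm,
              os.path.join(out_dir, "lesion_labels.nii.gz"), vs.affine)
    save_mask(gt.rim_plus_mask, vs.spacing_mm,
              os.path.join(out_dir, "rim_plus_mask.nii.gz"), vs.affine)
    save_mask(gt.artefact_mask, vs.spacing_mm,
              os.path.join(out_dir, "artefact_mask.nii.gz"), vs.affine)
    for name, m in gt.region_masks.items():
        save_mask(m, vs.spacing_mm,
                  os.path.join(out_dir, f"region_{name}.nii.gz"), vs.affine)
    gt.table.to_csv(os.path.join(out_dir, "lesions.csv"), index=False)
    if config is not None:
        config.to_yaml(os.path.join(out_dir, "phantom.yaml"))
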