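"""Synthetic paired CT / perfusion-SPECT patients with labelled regions.

Clinical perfusion SPECT/CT cohorts for this problem are not publicly
deposited, so every pipeline stage is exercised on digital phantoms that
emulate the six tissue-pattern classes:

* two ellipsoidal lungs of aerated-parenchyma CT density inside a soft
  tissue body on an air background;
* a smooth perfusion field over the lungs with Poisson counting noise;
* peripheral wedge-shaped perfusion defects with *untouched* CT — the
  pulmonary-embolism signature (PE CT values are drawn from the same
  distribution as healthy lung, by construction);
* consolidated blobs with raised CT and preserved perfusion (pneumonia);
* blobs with raised CT and reduced perfusion (the abnormal-CT/low-perfusion
  extra category);
* focal hotspot voxels at many times the lung count level, the tracer
  artifact that motivates percentile rather than max normalization.

The SPECT volume is emitted on a coarser grid, misaligned from the CT by a
known affine, so resizing and mask registration are genuinely exercised;
the true transform is returned for closing the loop in tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocess import AffineTransform3D
from .sampling import enumerate_window_samples
from .volume_io import (
    Modality,
    RoiAnnotation,
    TissueClass,
    Units,
    Volume3D,
    rois_from_label_array,
    write_volume,
)

__all__ = ["PhantomSpec", "PhantomPatient", "generate_phantom_patient", "generate_cohort"]


@dataclass
class PhantomSpec:
    """Geometry, intensity models and artifact settings of the phantom.

    CT statistics are (mean, sd) in HU; SPECT levels are counts. The PE
    multiplier scales the perfusion field inside defect wedges (<= 0.3 so
    defects are unambiguous); pneumonia CT sits >= 300 HU above healthy
    parenchyma while its perfusion is preserved.
    """

    shape: tuple[int, int, int] = (18, 64, 64)  # CT grid (Z, Y, X)
    spacing: tuple[float, float, float] = (3.0, 1.25, 1.25)
    native_spect_shape: tuple[int, int, int] = (10, 32, 32)

    ct_background: tuple[float, float] = (-1015.0, 4.0)
    ct_body: tuple[float, float] = (40.0, 20.0)
    ct_lung: tuple[float, float] = (-800.0, 60.0)
    ct_pneumonia: tuple[float, float] = (-450.0, 80.0)
    ct_abnormal: tuple[float, float] = (-420.0, 80.0)

    spect_lung_level: float = 120.0
    spect_body_level: float = 6.0
    spect_background_level: float = 0.5
    spect_field_variation: float = 0.35  # relative amplitude of the smooth field
    pe_multiplier: float = 0.15
    abnormal_multiplier: float = 0.2
    hotspot_count_range: tuple[int, int] = (1, 3)
    hotspot_amp_range: tuple[float, float] = (30.0, 60.0)  # x lung mean counts

    n_pe_wedges: int = 2
    n_pneumonia: int = 2
    n_abnormal: int = 1
    n_healthy_rois: int = 3
    n_background_rois: int = 2
    n_body_rois: int = 2

    max_translation: float = 2.5  # voxels, in-plane misalignment
    max_slice_shift: float = 1.0
    scale_range: tuple[float, float] = (0.98, 1.04)
    max_attempts: int = 200

    def __post_init__(self) -> None:
        if self.pe_multiplier > 0.3:
            raise ValueError("PE perfusion multiplier must be <= 0.3")
        if self.ct_pneumonia[0] - self.ct_lung[0] < 300:
            raise ValueError("pneumonia CT mean must be >= 300 HU above healthy lung")


@dataclass
class PhantomPatient:
    patient_id: str
    ct: Volume3D
    spect_native: Volume3D  # coarse, misaligned — the pipeline's input
    spect_true: Volume3D  # on the CT grid, for reference/debugging
    labels: np.ndarray  # int8 label volume on the CT grid
    rois: list[RoiAnnotation]
    true_transform: AffineTransform3D  # maps misaligned CT-grid coords -> true


def _ellipsoid(shape, center, half_axes) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    az, ay, ax = half_axes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
    return yy**2 + xx**2 <= radius**2


def _place_disk(allowed: np.ndarray, radius: int, rng) -> tuple[int, int] | None:
    """A centre such that the full disk fits inside the allowed region."""
    safe = ndimage.binary_erosion(allowed, structure=_disk(radius + 1))
    coords = np.argwhere(safe)
    if len(coords) == 0:
        return None
    r, c = coords[rng.integers(len(coords))]
    return int(r), int(c)


def _smooth_field(shape, rng, sigma=4.0) -> np.ndarray:
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=(1.0, sigma, sigma))
    s = smooth.std()
    return smooth / s if s > 0 else smooth


def generate_phantom_patient(
    spec: PhantomSpec, seed: int, patient_id: str | None = None
) -> PhantomPatient:
    """One synthetic patient; bit-identical output for identical seeds."""
    rng = np.random.default_rng(seed)
    if patient_id is None:
        patient_id = f"phantom_{seed:08d}"
    nz, ny, nx = spec.shape

    body = _ellipsoid(spec.shape, (nz / 2 - 0.5, ny / 2, nx / 2), (nz / 2, 0.43 * ny, 0.46 * nx))
    lung_centers = [
        (nz / 2 - 0.5, ny / 2, 0.30 * nx),
        (nz / 2 - 0.5, ny / 2, 0.70 * nx),
    ]
    lung_axes = (0.42 * nz, 0.24 * ny, 0.19 * nx)
    lungs = [_ellipsoid(spec.shape, c, lung_axes) & body for c in lung_centers]
    lung = lungs[0] | lungs[1]
    # airway bridge joining the lungs (as the trachea/main bronchi do at
    # parenchymal thresholds), so the lungs form one connected component
    zc_b = int(nz / 2) - 1
    yc_b = int(ny / 2)
    bridge = np.zeros(spec.shape, dtype=bool)
    bridge[zc_b : zc_b + 2, yc_b - 1 : yc_b + 2, int(0.30 * nx) : int(0.70 * nx) + 1] = True
    bridge &= body
    lung |= bridge

    # ---- CT -------------------------------------------------------------
    ct = rng.normal(*spec.ct_background, size=spec.shape)
    ct[body] = rng.normal(*spec.ct_body, size=int(body.sum()))
    ct[lung] = rng.normal(*spec.ct_lung, size=int(lung.sum()))

    # ---- lesions ---------------------------------------------------------
    lesion = np.zeros(spec.shape, dtype=bool)
    labels = np.zeros(spec.shape, dtype=np.int8)
    zc = nz // 2
    annot_slices = [z for z in range(zc - 2, zc + 3) if 0 <= z < nz]

    # PE wedges: peripheral angular sectors of a lung, CT untouched
    pe_mask = np.zeros(spec.shape, dtype=bool)
    for w in range(spec.n_pe_wedges):
        side = w % 2
        _, cy, cx = lung_centers[side]
        ang0 = rng.uniform(0, 2 * np.pi)
        width = np.deg2rad(rng.uniform(55, 80))
        yy, xx = np.mgrid[:ny, :nx]
        theta = np.arctan2((yy - cy) / lung_axes[1], (xx - cx) / lung_axes[2])
        in_angle = np.mod(theta - ang0, 2 * np.pi) <= width
        r_norm = np.sqrt(((yy - cy) / lung_axes[1]) ** 2 + ((xx - cx) / lung_axes[2]) ** 2)
        sector2d = in_angle & (r_norm >= 0.35)
        for z in annot_slices:
            pe_mask[z] |= sector2d & lungs[side][z]
    pe_mask &= ~lesion
    lesion |= ndimage.binary_dilation(pe_mask, iterations=2)

    def _place_blob():
        for attempt in range(spec.max_attempts):
            z = int(rng.integers(annot_slices[0], annot_slices[-1] + 1))
            allowed = lung[z] & ~ndimage.binary_dilation(lesion[z], iterations=1)
            # shrink the target radius if placement keeps failing
            if attempt < spec.max_attempts // 2:
                radius = int(rng.integers(4, 6))
            elif attempt < 3 * spec.max_attempts // 4:
                radius = 4
            else:
                radius = 3
            center = _place_disk(allowed, radius, rng)
            if center is None:
                continue
            blob = np.zeros(spec.shape, dtype=bool)
            z_half = int(rng.integers(1, 3))
            for dz in range(-z_half, z_half + 1):
                zi = z + dz
                if 0 <= zi < nz:
                    shrink = max(2, int(round(radius * np.sqrt(max(0.0, 1 - (dz / (z_half + 0.5)) ** 2)))))
                    d = _disk(shrink)
                    r0, c0 = center
                    rr = slice(r0 - shrink, r0 + shrink + 1)
                    cc = slice(c0 - shrink, c0 + shrink + 1)
                    if rr.start < 0 or cc.start < 0 or rr.stop > ny or cc.stop > nx:
                        continue
                    blob[zi, rr, cc] |= d
            blob &= lung
            if blob.sum() < 20:
                continue
            return blob
        raise RuntimeError(
            f"could not place a lesion after {spec.max_attempts} attempts"
        )

    pneumonia_mask = np.zeros(spec.shape, dtype=bool)
    for _ in range(spec.n_pneumonia):
        blob = _place_blob()
        pneumonia_mask |= blob
        lesion |= ndimage.binary_dilation(blob, iterations=2)
    abnormal_mask = np.zeros(spec.shape, dtype=bool)
    for _ in range(spec.n_abnormal):
        blob = _place_blob()
        abnormal_mask |= blob
        lesion |= ndimage.binary_dilation(blob, iterations=2)

    ct[pneumonia_mask] = rng.normal(*spec.ct_pneumonia, size=int(pneumonia_mask.sum()))
    ct[abnormal_mask] = rng.normal(*spec.ct_abnormal, size=int(abnormal_mask.sum()))
    ct = np.clip(ct, -1090.0, 1500.0)

    # ---- SPECT -----------------------------------------------------------
    field = np.full(spec.shape, spec.spect_background_level)
    field[body] = spec.spect_body_level
    lung_field = spec.spect_lung_level * (
        1.0 + spec.spect_field_variation * _smooth_field(spec.shape, rng)
    )
    field[lung] = np.clip(lung_field[lung], 0.25 * spec.spect_lung_level, None)
    field[pe_mask] *= spec.pe_multiplier
    field[abnormal_mask] *= spec.abnormal_multiplier

    n_hot = int(rng.integers(spec.hotspot_count_range[0], spec.hotspot_count_range[1] + 1))
    lung_mean = float(field[lung].mean())
    hot_candidates = np.argwhere(lung & ~pe_mask & ~abnormal_mask)
    for _ in range(n_hot):
        z, y, x = hot_candidates[rng.integers(len(hot_candidates))]
        field[z, y, x] = rng.uniform(*spec.hotspot_amp_range) * lung_mean

    spect_true_counts = rng.poisson(field).astype(float)

    # ---- misaligned native grid -----------------------------------------
    s = rng.uniform(*spec.scale_range)
    t_inplane = rng.uniform(-spec.max_translation, spec.max_translation, size=2)
    t_z = rng.uniform(-spec.max_slice_shift, spec.max_slice_shift)
    center = np.array([(nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2])
    linear = np.diag([s, s, s])
    translation = center - linear @ center + np.array([t_z, *t_inplane])
    true_transform = AffineTransform3D(linear, translation)

    mz, my, mx = spec.native_spect_shape
    axes = [np.linspace(0, spec.shape[k] - 1, spec.native_spect_shape[k]) for k in range(3)]
    gz, gy, gx = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gz.ravel(), gy.ravel(), gx.ravel()])
    warped = linear @ pts + translation[:, None]
    native_field = ndimage.map_coordinates(field, warped, order=1, mode="constant", cval=0.0)
    native_counts = rng.poisson(native_field.reshape(spec.native_spect_shape)).astype(float)

    native_spacing = tuple(
        spec.spacing[k] * (spec.shape[k] - 1) / (spec.native_spect_shape[k] - 1)
        for k in range(3)
    )

    # ---- labels ----------------------------------------------------------
    lesion_any = pe_mask | pneumonia_mask | abnormal_mask
    for z in annot_slices:
        labels[z][pe_mask[z]] = TissueClass.PE
        labels[z][pneumonia_mask[z]] = TissueClass.PNEUMONIA
        labels[z][abnormal_mask[z]] = TissueClass.ABNORMAL_CT_LOW_PERF

    placed_healthy = 0
    for attempt in range(spec.max_attempts):
        if placed_healthy >= spec.n_healthy_rois:
            break
        z = int(rng.integers(annot_slices[0], annot_slices[-1] + 1))
        sep = 3 if attempt < spec.max_attempts // 2 else 1
        radius = 5 if attempt < spec.max_attempts // 2 else 4
        allowed = lung[z] & ~ndimage.binary_dilation(lesion_any[z], iterations=sep) & (labels[z] == 0)
        center = _place_disk(allowed, radius, rng)
        if center is None:
            continue
        d = _disk(radius)
        r0, c0 = center
        labels[z, r0 - radius : r0 + radius + 1, c0 - radius : c0 + radius + 1][d] = TissueClass.HEALTHY
        placed_healthy += 1
    if placed_healthy == 0:
        raise RuntimeError("could not place any healthy ROI")

    for cls, n_rois, region in (
        (TissueClass.BACKGROUND, spec.n_background_rois, ~ndimage.binary_dilation(body, iterations=3)),
        (TissueClass.BODY_TISSUE, spec.n_body_rois, body & ~ndimage.binary_dilation(lung, iterations=2)),
    ):
        placed = 0
        for _ in range(spec.max_attempts):
            if placed >= n_rois:
                break
            z = int(rng.integers(annot_slices[0], annot_slices[-1] + 1))
            allowed = region[z] & (labels[z] == 0)
            center = _place_disk(allowed, 4, rng)
            if center is None:
                continue
            d = _disk(4)
            r0, c0 = center
            labels[z, r0 - 4 : r0 + 5, c0 - 4 : c0 + 5][d] = cls
            placed += 1
        if placed == 0:
            raise RuntimeError(f"could not place any ROI of class {cls.name}")

    rois = rois_from_label_array(labels, patient_id=patient_id)

    ct_vol = Volume3D(ct, spec.spacing, Modality.CT, Units.HU)
    spect_true_vol = Volume3D(spect_true_counts, spec.spacing, Modality.SPECT, Units.COUNTS)
    spect_native_vol = Volume3D(native_counts, native_spacing, Modality.SPECT, Units.COUNTS)
    return PhantomPatient(
        patient_id=patient_id,
        ct=ct_vol,
        spect_native=spect_native_vol,
        spect_true=spect_true_vol,
        labels=labels,
        rois=rois,
        true_transform=true_transform,
    )


def generate_cohort(
    spec: PhantomSpec,
    n_patients: int,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[PhantomPatient], dict]:
    """Independent phantom patients with per-patient derived seeds.

    The manifest records, per patient and tissue class, the number of ROIs
    and the number of valid window samples at sides 3 and 5. If ``out_dir``
    is given, NIfTI volumes, label volumes and the manifest are written
    there (one subdirectory per patient).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    master = np.random.default_rng(seed)
    patients = []
    manifest: dict = {"seed": seed, "n_patients": n_patients, "patients": {}}
    for i in range(n_patients):
        child_seed = int(master.integers(2**31))
        pid = f"p{i:03d}"
        patient = generate_phantom_patient(spec, child_seed, patient_id=pid)
        patients.append(patient)
        per_class: dict = {}
        for roi in patient.rois:
            entry = per_class.setdefault(
                roi.label.name, {"n_rois": 0, "n_samples_3": 0, "n_samples_5": 0}
            )
            entry["n_rois"] += 1
            entry["n_samples_3"] += len(enumerate_window_samples(roi, 3))
            entry["n_samples_5"] += len(enumerate_window_samples(roi, 5))
        manifest["patients"][pid] = {"seed": child_seed, "classes": per_class}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for patient in patients:
            pdir = out_dir / patient.patient_id
            pdir.mkdir(exist_ok=True)
            write_volume(patient.ct, pdir / "ct.nii")
            write_volume(patient.spect_native, pdir / "spect.nii")
            label_vol = Volume3D(
                patient.labels.astype(float), patient.ct.spacing, Modality.CT, Units.HU
            )
            write_volume(label_vol, pdir / "labels.nii")
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return patients, manifest
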