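"""NIfTI / sidecar / bval-bvec / CSV readers and writers.

All volumes are NIfTI-1 in RAS+ with a diagonal affine built from the voxel
size; acquisition metadata lives in a JSON sidecar
``{echo_times_ms, bvals, bvecs, voxel_size_mm}``.  FSL-style plain-text
bval/bvec files are also accepted.  Paired volumes are checked for a shared
grid (shape + affine) before any computation.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import Acquisition, PhantomTruth


def affine_from_voxel_size(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_nifti(data: np.ndarray, path, voxel_size=None, affine=None) -> Path:
    if affine is None:
        affine = affine_from_voxel_size(voxel_size or (1.0, 1.0, 1.0))
    img = nib.Nifti1Image(np.asarray(data), affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def check_same_grid(*paths_or_imgs) -> None:
    """Raise if the named volumes disagree in shape (first 3 dims) or affine."""
    ref_shape = ref_aff = ref_name = None
    for item in paths_or_imgs:
        img = nib.load(str(item))
        shape, aff = img.shape[:3], img.affine
        if ref_shape is None:
            ref_shape, ref_aff, ref_name = shape, aff, item
        elif shape != ref_shape or not np.allclose(aff, ref_aff):
            raise ValueError(
                f"grid mismatch between {ref_name} and {item}: "
                f"{ref_shape} vs {shape}")


def write_sidecar(path, acquisition: Acquisition, voxel_size) -> Path:
    payload = {
        "echo_times_ms": acquisition.echo_times.tolist(),
        "bvals": acquisition.bvals.tolist(),
        "bvecs": acquisition.bvecs.tolist(),
        "voxel_size_mm": list(voxel_size),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_sidecar(path) -> tuple[Acquisition, tuple]:
    d = json.loads(Path(path).read_text())
    acq = Acquisition(np.asarray(d["echo_times_ms"], float),
                      np.asarray(d["bvals"], float),
                      np.asarray(d["bvecs"], float))
    return acq, tuple(d["voxel_size_mm"])


def write_bval_bvec(prefix, bvals, bvecs) -> tuple[Path, Path]:
    """FSL convention: one row of b-values; bvecs as 3 rows of components."""
    prefix = Path(prefix)
    bval_path = prefix.with_suffix(".bval")
    bvec_path = prefix.with_suffix(".bvec")
    bval_path.write_text(" ".join(f"{b:g}" for b in bvals) + "\n")
    lines = [" ".join(f"{v:.10g}" for v in np.asarray(bvecs)[:, i])
             for i in range(3)]
    bvec_path.write_text("\n".join(lines) + "\n")
    return bval_path, bvec_path


def read_bval_bvec(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(
            f"bvec shape {bvecs.shape} does not match {bvals.size} b-values")
    return bvals, bvecs


def write_subject(outdir, subject) -> Path:
    """Serialize one simulated subject (volumes, masks, truth, sidecar)."""
    outdir = Path(outdir) / subject.subject_id
    outdir.mkdir(parents=True, exist_ok=True)
    vs = subject.truth.voxel_size
    save_nifti(subject.multi_echo, outdir / "mecho.nii.gz", vs)
    save_nifti(subject.dwi, outdir / "dwi.nii.gz", vs)
    t = subject.truth
    save_nifti(t.label_volume.astype(np.int16), outdir / "truth_labels.nii.gz", vs)
    for name, mask in [("placenta", t.placental_mask),
                       ("chorion", t.chorion_mask), ("basal", t.basal_mask),
                       ("lesion", t.lesion_mask), ("brain", t.brain_mask)]:
        save_nifti(mask.astype(np.uint8), outdir / f"mask_{name}.nii.gz", vs)
    write_sidecar(outdir / "sidecar.json", subject.acquisition, vs)
    meta = {
        "subject_id": subject.subject_id,
        "ga_mri_weeks": subject.ga_mri_weeks,
        "ga_delivery_weeks": subject.ga_delivery_weeks,
        "group": subject.group,
        "seed": int(t.seed),
        "true_compartment_t2star": subject.true_compartment_t2star,
        "true_brain_t2star": subject.true_brain_t2star,
        "true_params": {
            name: {"mean": spec.mean.tolist(), "cov": spec.cov.tolist(),
                   "volume_fraction": spec.volume_fraction}
            for name, spec in t.true_params.items()},
    }
    (outdir / "truth.json").write_text(json.dumps(meta, indent=1))
    return outdir


def load_subject(subdir):
    """Load a serialized subject back into arrays + metadata dict."""
    subdir = Path(subdir)
    check_same_grid(subdir / "mecho.nii.gz", subdir / "dwi.nii.gz",
                    subdir / "mask_placenta.nii.gz")
    mecho, _ = load_nifti(subdir / "mecho.nii.gz")
    dwi, _ = load_nifti(subdir / "dwi.nii.gz")
    acq, voxel_size = read_sidecar(subdir / "sidecar.json")
    if mecho.shape[-1] != acq.echo_times.size:
        raise ValueError(f"{subdir}: echo count does not match sidecar")
    if dwi.shape[-1] != acq.bvals.size:
        raise ValueError(f"{subdir}: DWI volume count does not match sidecar")
    masks = {name: load_nifti(subdir / f"mask_{name}.nii.gz")[0].astype(bool)
             for name in ("placenta", "chorion", "basal", "lesion", "brain")}
    meta = json.loads((subdir / "truth.json").read_text())
    return mecho, dwi, acq, voxel_size, masks, meta


def load_phantom_truth(subdir) -> PhantomTruth | None:
    """Reload the label volume and masks (generative feature maps are not
    serialized; use in-memory truth for voxel-level oracles)."""
    subdir = Path(subdir)
    labels, _ = load_nifti(subdir / "truth_labels.nii.gz")
    masks = {name: load_nifti(subdir / f"mask_{name}.nii.gz")[0].astype(bool)
             for name in ("placenta", "chorion", "basal", "lesion", "brain")}
    meta = json.loads((subdir / "truth.json").read_text())
    shape = labels.shape
    return PhantomTruth(
        label_volume=np.asarray(labels, np.int16),
        lesion_mask=masks["lesion"], chorion_mask=masks["chorion"],
        basal_mask=masks["basal"], placental_mask=masks["placenta"],
        brain_mask=masks["brain"], ga_weeks=meta["ga_mri_weeks"],
        ga_delivery_weeks=meta["ga_delivery_weeks"], true_params={},
        voxel_size=tuple(json.loads((subdir / "sidecar.json").read_text())
                         ["voxel_size_mm"]),
        seed=meta.get("seed", 0),
        true_features=np.zeros(shape + (5,)), true_s0=np.zeros(shape),
        true_tensor=np.zeros(shape + (3, 3)))
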