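"""Disk formats: TIFF stacks with JSON sidecars, CSV tables, manifests.

A rendered stack is stored as one single-channel TIFF per channel role
plus a ``stack.json`` sidecar carrying the voxel spacing (um, z/y/x) and
the role -> filename map.  Channel roles are always declared in the
sidecar, never inferred from intensities.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import BinaryMask, ImageVolume, InvalidParameterError, LeakinessResult
from .phantom import PhantomTruth

SIDECAR_NAME = "stack.json"
TRUTH_NAME = "truth.json"
TRUTH_MASK_NAME = "truth_vessel_mask.tif"


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_stack(
    out_dir: str | Path,
    channels: dict[str, ImageVolume],
    truth: PhantomTruth | None = None,
) -> dict:
    """Write channels (and optional truth) to a directory; returns a
    manifest of file names and SHA-256 hashes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not channels:
        raise InvalidParameterError("no channels to write")
    spacing = next(iter(channels.values())).spacing
    sidecar = {"spacing_um_zyx": list(spacing), "channels": {}}
    files = []
    for role, vol in sorted(channels.items()):
        fname = f"{role}.tif"
        tifffile.imwrite(out / fname, vol.values.astype(np.float32))
        sidecar["channels"][role] = fname
        files.append(fname)
    (out / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    files.append(SIDECAR_NAME)

    if truth is not None:
        tifffile.imwrite(
            out / TRUTH_MASK_NAME, truth.vessel_mask.values.astype(np.uint8)
        )
        truth_doc = {
            "leak_fraction": truth.leak_fraction,
            "inside_mass": truth.inside_mass,
            "outside_mass": truth.outside_mass,
            "segment_diameters_um": truth.segment_diameters_um,
            "hypoxia_h_max": truth.hypoxia_h_max,
            "hypoxia_lambda_um": truth.hypoxia_lambda_um,
            "halo_decay_um": truth.halo_decay_um,
            "cell_positions_um": truth.cell_positions_um.tolist(),
            "seed": truth.seed,
            "vessel_mask_file": TRUTH_MASK_NAME,
        }
        (out / TRUTH_NAME).write_text(json.dumps(truth_doc, indent=2))
        files.extend([TRUTH_MASK_NAME, TRUTH_NAME])

    manifest = {f: sha256_of(out / f) for f in sorted(files)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_stack(in_dir: str | Path) -> dict[str, ImageVolume]:
    """Load a stack directory written by :func:`write_stack`."""
    src = Path(in_dir)
    sidecar_path = src / SIDECAR_NAME
    if not sidecar_path.exists():
        raise InvalidParameterError(f"no {SIDECAR_NAME} sidecar in {src}")
    sidecar = json.loads(sidecar_path.read_text())
    spacing = tuple(sidecar["spacing_um_zyx"])
    channels = {}
    for role, fname in sidecar["channels"].items():
        values = tifffile.imread(src / fname).astype(float)
        channels[role] = ImageVolume(values, spacing=spacing, role=role)
    return channels


def read_truth(in_dir: str | Path) -> PhantomTruth:
    src = Path(in_dir)
    doc = json.loads((src / TRUTH_NAME).read_text())
    sidecar = json.loads((src / SIDECAR_NAME).read_text())
    spacing = tuple(sidecar["spacing_um_zyx"])
    mask = tifffile.imread(src / doc["vessel_mask_file"]).astype(bool)
    return PhantomTruth(
        vessel_mask=BinaryMask(mask, spacing=spacing),
        leak_fraction=doc["leak_fraction"],
        inside_mass=doc["inside_mass"],
        outside_mass=doc["outside_mass"],
        segment_diameters_um=doc["segment_diameters_um"],
        hypoxia_h_max=doc["hypoxia_h_max"],
        hypoxia_lambda_um=doc["hypoxia_lambda_um"],
        halo_decay_um=doc["halo_decay_um"],
        cell_positions_um=np.asarray(doc["cell_positions_um"], dtype=float).reshape(
            -1, 3
        ),
        seed=doc["seed"],
    )


def write_leakiness_csv(path: str | Path, results: list[LeakinessResult]) -> None:
    df = pd.DataFrame(
        {
            "timepoint_min": [r.timepoint for r in results],
            "in_sum": [r.in_sum for r in results],
            "out_sum": [r.out_sum for r in results],
            "ratio": [r.ratio for r in results],
        }
    )
    df.to_csv(path, index=False)
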