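"""Reading and writing masks, sidecars, manifests, and reports.

On disk a visit is a single-channel PNG or TIFF (0 = background,
255 = lesion) plus a JSON sidecar holding the spatial metadata:

.. code-block:: json

    {
      "patient_id": "P001",
      "eye_id": "P001-OD",
      "laterality": "OD",
      "visit_date": "2020-01-01",
      "pixel_size_mm": 0.01,
      "fovea_px": [429.5, 429.5],
      "landmarks_px": [[86.0, 86.0], [86.0, 774.0], [774.0, 172.0]]
    }

A cohort manifest is a CSV with one row per eye:
``patient_id, eye_id, laterality, baseline_mask, baseline_sidecar,
followup_mask, followup_sidecar`` (paths relative to the manifest).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .geometry import SegmentedVisit
from .registration import EyePair, register_pair

logger = logging.getLogger(__name__)

SIDECAR_REQUIRED = (
    "laterality",
    "visit_date",
    "pixel_size_mm",
    "fovea_px",
    "landmarks_px",
)

MANIFEST_COLUMNS = (
    "patient_id",
    "eye_id",
    "laterality",
    "baseline_mask",
    "baseline_sidecar",
    "followup_mask",
    "followup_sidecar",
)

CSV_FLOAT_FORMAT = "%.6g"


@dataclasses.dataclass
class RunConfig:
    """Configuration for an end-to-end run; every default overridable."""

    manifest: str = ""
    output_dir: str = "gaber_out"
    zone_scheme: str = "ring_equal_width"
    exclude_qc: bool = False
    nonlinear_threshold: float = 0.01
    seed: int = 0
    colormap: str = "viridis"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG/TIFF (0/255)."""
    image = Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8))
    image.save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask image; reject anything not strictly 0/255."""
    array = np.asarray(Image.open(path))
    if array.ndim != 2:
        raise ValueError(f"{path}: mask must be single-channel, got {array.shape}")
    offending = int(((array != 0) & (array != 255)).sum())
    if offending:
        raise ValueError(
            f"{path}: mask is not binary — {offending} pixels have "
            "intermediate gray values"
        )
    return array == 255


def write_sidecar(path: str | Path, visit: SegmentedVisit, patient_id: str = "",
                  eye_id: str = "") -> None:
    payload = {
        "patient_id": patient_id,
        "eye_id": eye_id,
        "laterality": visit.laterality,
        "visit_date": visit.visit_date.isoformat(),
        "pixel_size_mm": visit.pixel_size_mm,
        "fovea_px": list(visit.fovea_px),
        "landmarks_px": visit.landmarks_px.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_visit(mask_path: str | Path, sidecar_path: str | Path) -> SegmentedVisit:
    """Load one visit from a mask image and its JSON sidecar."""
    sidecar = json.loads(Path(sidecar_path).read_text())
    for field in SIDECAR_REQUIRED:
        if field not in sidecar:
            raise ValueError(f"{sidecar_path}: sidecar is missing '{field}'")
    mask = read_mask(mask_path)
    return SegmentedVisit(
        mask=mask,
        fovea_px=tuple(sidecar["fovea_px"]),
        landmarks_px=np.asarray(sidecar["landmarks_px"], dtype=float),
        visit_date=datetime.date.fromisoformat(sidecar["visit_date"]),
        laterality=sidecar["laterality"],
        pixel_size_mm=float(sidecar["pixel_size_mm"]),
    )


def write_visit(
    directory: str | Path,
    stem: str,
    visit: SegmentedVisit,
    patient_id: str = "",
    eye_id: str = "",
) -> tuple[Path, Path]:
    """Write mask + sidecar; returns the two paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mask_path = directory / f"{stem}.png"
    sidecar_path = directory / f"{stem}.json"
    write_mask(mask_path, visit.mask)
    write_sidecar(sidecar_path, visit, patient_id=patient_id, eye_id=eye_id)
    return mask_path, sidecar_path


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"{path}: manifest is missing columns {sorted(missing)}")
    return manifest


def load_eye(row: pd.Series, root: str | Path = ".") -> EyePair:
    """Load and register one manifest row into an EyePair."""
    root = Path(root)
    baseline = read_visit(root / row["baseline_mask"], root / row["baseline_sidecar"])
    followup = read_visit(root / row["followup_mask"], root / row["followup_sidecar"])
    return register_pair(
        baseline,
        followup,
        patient_id=row["patient_id"],
        eye_id=row["eye_id"],
    )


def write_csv(path: str | Path, table: pd.DataFrame) -> None:
    """Deterministic CSV: stable column order, fixed float format."""
    table.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def write_run_log(
    path: str | Path,
    config: RunConfig,
    excluded_eyes: list[str],
    extra: dict | None = None,
) -> None:
    payload = {
        "software": "gaber",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "qc_excluded_eyes": sorted(excluded_eyes),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
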