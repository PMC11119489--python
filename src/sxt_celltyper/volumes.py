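"""In-memory container and TIFF I/O for LAC tomogram volumes.

A tomogram is a 3D grid of linear absorption coefficients (LAC, 1/um) with
an isotropic voxel size in nm and a semantic label volume:

    0 = background (outside cell)   2 = nucleus
    1 = cell (cytosol + vesicles)   3 = mitochondria

Volumes are stored as multipage 32-bit float TIFF (LAC) plus uint8 TIFF
(labels) with a JSON sidecar carrying voxel size and cell metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

LABEL_BACKGROUND = 0
LABEL_CELL = 1
LABEL_NUCLEUS = 2
LABEL_MITOCHONDRIA = 3


@dataclass
class TomogramVolume:
    """One cell's LAC voxel grid plus semantic masks.

    Attributes
    ----------
    lac : float32 ndarray, shape (z, y, x)
        Linear absorption coefficients in 1/um; finite and nonnegative.
    voxel_size : float
        Isotropic voxel edge in nm; instrument range is 30-45 nm.
    labels : uint8 ndarray, same shape
        Semantic labels (see module legend).
    """

    lac: np.ndarray
    voxel_size: float
    labels: np.ndarray
    cell_id: str = ""
    cell_class: str | None = None

    def __post_init__(self):
        self.lac = np.asarray(self.lac, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.lac.ndim != 3 or self.lac.shape != self.labels.shape:
            raise ValueError("lac and labels must be 3D arrays of equal shape")
        if not 0 < self.voxel_size <= 100:
            raise ValueError("voxel_size must be in (0, 100] nm")
        if not np.all(np.isfinite(self.lac)) or self.lac.min() < 0:
            raise ValueError("LAC values must be finite and >= 0")
        # the label legend makes nucleus voxels part of the cell region by
        # construction; the structural violation we can still detect is a
        # nucleus with no cell body around it at all
        if (self.labels == LABEL_NUCLEUS).any() and not (self.labels == LABEL_CELL).any():
            raise ValueError("nucleus mask present without any cell mask around it")

    def cell_mask(self) -> np.ndarray:
        return self.labels != LABEL_BACKGROUND

    def nucleus_mask(self) -> np.ndarray:
        return self.labels == LABEL_NUCLEUS

    def mitochondria_mask(self) -> np.ndarray:
        return self.labels == LABEL_MITOCHONDRIA

    @property
    def voxel_volume_um3(self) -> float:
        return (self.voxel_size * 1e-3) ** 3

    # -- I/O ---------------------------------------------------------------
    def save(self, directory: str | Path) -> dict:
        """Write lac/label TIFFs and a JSON sidecar; returns file paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = self.cell_id or "volume"
        paths = {
            "lac": directory / f"{stem}_lac.tif",
            "labels": directory / f"{stem}_labels.tif",
            "meta": directory / f"{stem}_meta.json",
        }
        tifffile.imwrite(paths["lac"], self.lac)
        tifffile.imwrite(paths["labels"], self.labels)
        paths["meta"].write_text(
            json.dumps(
                {
                    "voxel_size_nm": self.voxel_size,
                    "cell_id": self.cell_id,
                    "cell_class": self.cell_class,
                    "label_legend": {
                        "0": "background",
                        "1": "cell",
                        "2": "nucleus",
                        "3": "mitochondria",
                    },
                },
                indent=2,
            )
        )
        return {k: str(v) for k, v in paths.items()}

    @classmethod
    def load(cls, directory: str | Path, cell_id: str) -> "TomogramVolume":
        directory = Path(directory)
        meta = json.loads((directory / f"{cell_id}_meta.json").read_text())
        return cls(
            lac=tifffile.imread(directory / f"{cell_id}_lac.tif"),
            labels=tifffile.imread(directory / f"{cell_id}_labels.tif"),
            voxel_size=meta["voxel_size_nm"],
            cell_id=meta["cell_id"],
            cell_class=meta.get("cell_class"),
        )
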