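"""Core data containers shared across the pipeline.

Everything is a plain dataclass wrapping numpy arrays; NIfTI serialization
lives in :mod:`hypoconn.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

BLOCK_LABELS = ("baseline", "post10", "post45")
DIETS = ("normocaloric", "hypercaloric")


@dataclass(frozen=True)
class VolumeGeometry:
    """3D sampling grid: array shape, voxel size in mm and voxel->world affine."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        if self.affine is None:
            aff = np.diag(list(self.voxel_size_mm) + [1.0])
            object.__setattr__(self, "affine", aff)
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4) or abs(np.linalg.det(aff)) < 1e-12:
                raise ValueError("affine must be an invertible 4x4 matrix")
            object.__setattr__(self, "affine", aff)

    def matches(self, other: "VolumeGeometry") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


@dataclass(frozen=True)
class BlockDesign:
    """Design of one measurement session: three blocks around glucose ingestion."""

    n_timepoints_per_block: int
    tr_seconds: float
    session_id: str
    subject_id: str = "sub-01"
    diet: Optional[str] = None
    block_labels: tuple[str, ...] = BLOCK_LABELS

    def __post_init__(self):
        if tuple(self.block_labels) != BLOCK_LABELS:
            raise ValueError(
                f"blocks must be exactly {BLOCK_LABELS} in order, got {self.block_labels}"
            )
        if self.n_timepoints_per_block < 8:
            raise ValueError("need at least 8 timepoints per block")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.diet is not None and self.diet not in DIETS:
            raise ValueError(f"diet must be one of {DIETS} or None, got {self.diet!r}")

    @property
    def n_blocks(self) -> int:
        return len(self.block_labels)


@dataclass
class BoldBlock:
    """One 4D BOLD time series (a single ~9-minute block of one session)."""

    data: np.ndarray  # (nx, ny, nz, T)
    geometry: VolumeGeometry
    design: BlockDesign
    block_label: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BoldBlock data must be 4D")
        if self.data.shape[:3] != tuple(self.geometry.shape):
            raise ValueError("data spatial shape does not match geometry")
        if self.data.shape[3] != self.design.n_timepoints_per_block:
            raise ValueError("number of timepoints does not match design")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldBlock data contains NaN/Inf")
        if self.block_label not in self.design.block_labels:
            raise ValueError(f"unknown block label {self.block_label!r}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "BoldBlock":
        return BoldBlock(data=data, geometry=self.geometry, design=self.design,
                         block_label=self.block_label)


@dataclass
class TissuePriors:
    """Probabilistic gray-matter / white-matter / CSF maps on one geometry."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    geometry: VolumeGeometry

    def __post_init__(self):
        for name in ("gm", "wm", "csf"):
            vol = np.asarray(getattr(self, name), dtype=float)
            if vol.shape != tuple(self.geometry.shape):
                raise ValueError(f"{name} shape does not match geometry")
            if vol.min() < 0 or vol.max() > 1:
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
            setattr(self, name, vol)
        if np.any(self.gm + self.wm + self.csf > 1 + 1e-6):
            raise ValueError("tissue probabilities sum above 1")


@dataclass
class GroundTruth:
    """What the simulator planted: maps, time courses, per-block amplitudes.

    ``component_maps`` are unit-norm over mask voxels.  ``amplitude_multipliers``
    has shape (K, n_blocks); a value above 1 in the third block encodes the
    planted post-glucose coupling increase.
    """

    component_maps: np.ndarray          # (K, n_mask_voxels), unit L2 norm rows
    component_timecourses: dict         # session_id -> (n_blocks, K, T)
    amplitude_multipliers: np.ndarray   # (K, n_blocks), > 0
    noise_sigma: float
    baseline_mean: float
    drift_spec: dict
    mask: np.ndarray                    # boolean volume
    geometry: VolumeGeometry
    component_scales: np.ndarray = field(default=None)  # per-component signal scale
    support_masks: np.ndarray = field(default=None)     # (K, n_mask_voxels) boolean
    csf_artifact: Optional[dict] = None

    def __post_init__(self):
        self.component_maps = np.asarray(self.component_maps, dtype=float)
        self.amplitude_multipliers = np.asarray(self.amplitude_multipliers, dtype=float)
        if self.component_maps.ndim != 2 or self.component_maps.shape[0] < 1:
            raise ValueError("need at least one component map")
        if np.any(self.amplitude_multipliers <= 0):
            raise ValueError("amplitude multipliers must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        K = self.component_maps.shape[0]
        if K > 1:
            c = np.corrcoef(self.component_maps)
            off = np.abs(c[~np.eye(K, dtype=bool)])
            if np.any(off >= 0.95):
                raise ValueError("component maps are too similar (|r| >= 0.95)")

    @property
    def n_components(self) -> int:
        return self.component_maps.shape[0]


@dataclass
class StudyDataset:
    """A complete simulated study: sessions x blocks of BOLD data plus truth."""

    blocks: dict                 # (session_id, block_label) -> BoldBlock
    designs: list                # list of BlockDesign, one per session
    truth: GroundTruth
    priors: TissuePriors
    mask: np.ndarray

    def session_ids(self) -> list[str]:
        return [d.session_id for d in self.designs]

    def blocks_in_order(self) -> list[BoldBlock]:
        """All blocks, session-major then block order."""
        out = []
        for d in self.designs:
            for lab in d.block_labels:
                out.append(self.blocks[(d.session_id, lab)])
        return out
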