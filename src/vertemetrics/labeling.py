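"""Vertebra instance labeling from a binary bone volume.

A scan is binarized to bone/non-bone, split into 26-connected
components, and the components are named by walking the lumbar (and, if
needed, thoracic) sequence upward from a seed — by default the first
vertebra above the sacrum, the sacrum itself being recognized as the
most inferior component.  Part labels are attached per instance by
masking a congruent part-label volume; part segmentation of real scans
is not computed here and must be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import LabelVolume, VoxelVolume

__all__ = [
    "VertebraInstance",
    "NAME_SEQUENCE",
    "binarize",
    "split_instances",
    "name_vertebrae",
    "attach_parts",
]

# inferior -> superior naming order above the sacrum
NAME_SEQUENCE = ["L5", "L4", "L3", "L2", "L1"] + [f"T{i}" for i in range(12, 0, -1)]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(eq=False)
class VertebraInstance:
    """One connected bone component, optionally named and part-labeled.

    ``mask`` is cropped to the component's bounding box (its origin keeps
    world coordinates consistent with the source grid).
    """

    name: str | None
    mask: VoxelVolume
    parts: LabelVolume | None = None

    @property
    def centroid(self) -> np.ndarray:
        idx = np.argwhere(self.mask.data > 0)
        return self.mask.index_to_world(idx.mean(axis=0))

    @property
    def voxel_count(self) -> int:
        return int(self.mask.data.sum())

    def contains_point(self, xyz) -> bool:
        idx = np.rint(self.mask.world_to_index(xyz)).astype(int)
        if (idx < 0).any() or (idx >= np.asarray(self.mask.shape)).any():
            return False
        return bool(self.mask.data[tuple(idx)])


def binarize(volume: VoxelVolume, threshold: float = 0.5) -> VoxelVolume:
    """Classify each voxel as bone (value >= threshold) or non-bone."""
    return VoxelVolume(
        (volume.data >= threshold).astype(np.uint8), volume.spacing, volume.origin
    )


def split_instances(bone: VoxelVolume, min_size: int = 100) -> list[VertebraInstance]:
    """26-connected components of a binary volume as unnamed instances.

    Components smaller than ``min_size`` voxels are dropped as rasterization
    or segmentation specks.  Instances come back sorted by inferior-to-
    superior centroid.
    """
    if not bone.is_binary():
        raise ValueError("split_instances expects a binary volume")
    if not bone.data.any():
        raise ValueError("bone volume is empty")
    lab, n = ndimage.label(bone.data, structure=_CONN26)
    instances = []
    slices = ndimage.find_objects(lab)
    for i, slc in enumerate(slices, start=1):
        sub = (lab[slc] == i).astype(np.uint8)
        if sub.sum() < min_size:
            continue
        origin = bone.index_to_world([s.start for s in slc])
        instances.append(
            VertebraInstance(None, VoxelVolume(sub, bone.spacing, tuple(origin)))
        )
    if not instances:
        raise ValueError(f"no component reaches the minimum size of {min_size} voxels")
    instances.sort(key=lambda inst: inst.centroid[2])
    return instances


def name_vertebrae(
    instances: list[VertebraInstance],
    seed_name: str = "L5",
    seed_point=None,
) -> list[VertebraInstance]:
    """Assign vertebra names upward (and downward) from a seed.

    The sacrum is the instance with the most inferior centroid unless a
    ``seed_point`` (world mm) pins ``seed_name`` to a specific instance;
    the remaining non-sacrum instances, ordered by SI centroid, get
    consecutive names from the standard sequence.  Naming is invariant to
    the input order of ``instances``.
    """
    if not instances:
        raise ValueError("no instances to name")
    if seed_name not in NAME_SEQUENCE:
        raise ValueError(f"unknown seed name {seed_name!r}")
    inst = sorted(instances, key=lambda i: i.centroid[2])

    if len(inst) == 1 and seed_point is None:
        # a single component cannot be split into sacrum + vertebra;
        # treat it as the seed vertebra
        inst[0].name = seed_name
        return inst

    sacrum, rest = inst[0], inst[1:]
    if seed_point is not None:
        hits = [i for i, v in enumerate(inst) if v.contains_point(seed_point)]
        if not hits:
            raise ValueError(f"seed point {seed_point} lies inside no instance")
        seeded = inst[hits[0]]
        if seeded is sacrum:
            # the seed names the lowest component; no separate sacrum
            sacrum, rest = None, inst
            seed_idx = 0
        else:
            seed_idx = next(i for i, v in enumerate(rest) if v is seeded)
    else:
        seed_idx = 0

    p = NAME_SEQUENCE.index(seed_name)
    lo, hi = p - seed_idx, p - seed_idx + len(rest) - 1
    if lo < 0 or hi >= len(NAME_SEQUENCE):
        raise ValueError(
            f"cannot name {len(rest)} vertebrae around seed {seed_name!r}: "
            "sequence exhausted"
        )
    if sacrum is not None:
        sacrum.name = "sacrum"
    for k, v in enumerate(rest):
        v.name = NAME_SEQUENCE[p + (k - seed_idx)]
    names = [v.name for v in inst]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate names assigned: {names}")
    return inst


def attach_parts(
    instance: VertebraInstance, parts: LabelVolume
) -> tuple[VertebraInstance, int]:
    """Restrict a part-label volume to one instance's mask.

    ``parts`` must live on a grid congruent with the instance's source grid
    (same spacing, origins offset by whole voxels).  Part voxels outside
    the instance mask are dropped; their count is returned alongside the
    updated instance.
    """
    mask = instance.mask
    if not np.allclose(parts.spacing, mask.spacing, atol=1e-6):
        raise ValueError(
            f"part grid spacing {parts.spacing} does not match instance spacing {mask.spacing}"
        )
    off = (np.asarray(mask.origin) - np.asarray(parts.origin)) / np.asarray(mask.spacing)
    off_i = np.rint(off).astype(int)
    if not np.allclose(off, off_i, atol=1e-4):
        raise ValueError("part grid is not aligned with the instance grid")

    sub = np.zeros(mask.shape, dtype=parts.data.dtype)
    src_lo = np.maximum(off_i, 0)
    src_hi = np.minimum(off_i + np.asarray(mask.shape), parts.data.shape)
    dst_lo = src_lo - off_i
    dst_hi = src_hi - off_i
    if (src_hi > src_lo).all():
        sub[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = parts.data[
            src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
        ]
    outside = int(((sub > 0) & (mask.data == 0)).sum())
    sub[mask.data == 0] = 0
    present = set(np.unique(sub).tolist()) - {0}
    table = {k: v for k, v in parts.labels.items() if k in present}
    instance.parts = LabelVolume(sub, mask.spacing, mask.origin, labels=table)
    return instance, outside
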