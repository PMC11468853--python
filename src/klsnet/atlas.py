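"""Atlas handling and per-ROI gray-matter value extraction.

A parcellation atlas assigns every voxel an integer region label (0 =
background).  Given a subject's voxelwise gray-matter (GM) volume map and a
co-registered atlas volume on the same grid, this module pulls out, for each
region, the vector of GM values at that region's voxels.  Those per-region
value distributions are the raw material for the morphological similarity
network built in :mod:`klsnet.density`.

No resampling is performed here: the caller must supply volumes that already
share a grid (spatial normalisation belongs to the upstream VBM pipeline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AtlasSpec",
    "SubjectParcellation",
    "EmptyRegionError",
    "GridMismatchError",
    "extract_roi_values",
    "load_volume",
]


class GridMismatchError(ValueError):
    """GM map and atlas volume do not share the same voxel grid."""


class EmptyRegionError(ValueError):
    """An atlas region contains no voxels in the label volume."""


@dataclass(frozen=True)
class AtlasSpec:
    """Ordered list of region labels and names defining the network nodes.

    The canonical whole-brain parcellation used for GM morphological networks
    is the 116-region AAL atlas (90 cerebral + 26 cerebellar regions), but any
    positive-integer labelling works.
    """

    region_ids: tuple[int, ...]
    region_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        ids = tuple(int(i) for i in self.region_ids)
        if len(ids) == 0:
            raise ValueError("atlas must define at least one region")
        if any(i <= 0 for i in ids):
            raise ValueError("region ids must be strictly positive")
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        names = self.region_names
        if not names:
            names = tuple(f"region_{i}" for i in ids)
        if len(names) != len(ids):
            raise ValueError("region_names must parallel region_ids")
        object.__setattr__(self, "region_ids", ids)
        object.__setattr__(self, "region_names", tuple(str(n) for n in names))

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def name_of(self, region_id: int) -> str:
        return self.region_names[self.region_ids.index(region_id)]

    @classmethod
    def from_table(cls, path: str | Path, sep: str | None = None) -> "AtlasSpec":
        """Read a two-column delimited file of (id, name) rows.

        The delimiter is sniffed (tab/comma/whitespace) unless given.
        """
        df = pd.read_csv(path, sep=sep, engine="python", header=None,
                         comment="#", names=["id", "name"])
        return cls(tuple(df["id"].astype(int)), tuple(df["name"].astype(str)))

    def to_table(self, path: str | Path) -> None:
        pd.DataFrame({"id": self.region_ids, "name": self.region_names}).to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class SubjectParcellation:
    """Per-region vectors of GM voxel values for one subject."""

    subject_id: str
    values: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for rid, v in self.values.items():
            arr = np.asarray(v, dtype=float).ravel()
            if arr.size == 0:
                raise EmptyRegionError(f"region {rid} has no voxels")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"region {rid} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"region {rid} contains negative GM values")
            clean[int(rid)] = arr
        self.values = clean

    @property
    def region_ids(self) -> tuple[int, ...]:
        return tuple(self.values.keys())

    @property
    def voxel_counts(self) -> dict[int, int]:
        return {rid: int(v.size) for rid, v in self.values.items()}

    def pooled_values(self) -> np.ndarray:
        return np.concatenate(list(self.values.values()))

    # -- on-disk round trip (delimited text; one row per region) ------------

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for rid, v in self.values.items():
            rows.append("\t".join([str(rid)] + [repr(float(x)) for x in v]))
        Path(path).write_text("\n".join(rows) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, subject_id: str | None = None) -> "SubjectParcellation":
        values: dict[int, np.ndarray] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            values[int(parts[0])] = np.array([float(x) for x in parts[1:]])
        return cls(subject_id or Path(path).stem, values)


def load_volume(path: str | Path) -> np.ndarray:
    """Load a NIfTI volume as a float array (squeezing trailing singletons)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return np.squeeze(data)


def extract_roi_values(
    gm_map: np.ndarray | str | Path,
    atlas: np.ndarray | str | Path,
    spec: AtlasSpec,
    subject_id: str = "subject",
) -> SubjectParcellation:
    """Extract each region's GM voxel values from a volume pair.

    Parameters
    ----------
    gm_map
        3-D array of (modulated) GM volume values, or path to a NIfTI file.
    atlas
        3-D integer label volume on the same grid, or path to a NIfTI file.
    spec
        Regions to extract.  Atlas labels not listed in ``spec`` are ignored
        with a logged warning; a listed region with zero voxels raises
        :class:`EmptyRegionError`.

    Values are gathered in C-order voxel-scan order, which is deterministic;
    downstream kernel density estimation is order-invariant anyway.
    """
    if not isinstance(gm_map, np.ndarray):
        gm_map = load_volume(gm_map)
    if not isinstance(atlas, np.ndarray):
        atlas = load_volume(atlas)
    atlas = np.asarray(atlas)
    if not np.issubdtype(atlas.dtype, np.integer):
        rounded = np.rint(atlas)
        if not np.allclose(atlas, rounded, atol=1e-6):
            raise ValueError("atlas volume contains non-integer labels")
        atlas = rounded.astype(int)
    if gm_map.shape != atlas.shape:
        raise GridMismatchError(
            f"gm_map grid {gm_map.shape} != atlas grid {atlas.shape}"
        )

    present = set(np.unique(atlas).tolist()) - {0}
    unknown = present - set(spec.region_ids)
    if unknown:
        logger.warning(
            "atlas contains %d label(s) not in the spec (ignored): %s",
            len(unknown), sorted(unknown)[:10],
        )

    values: dict[int, np.ndarray] = {}
    for rid in spec.region_ids:
        mask = atlas == rid
        if not mask.any():
            raise EmptyRegionError(
                f"region {rid} ({spec.name_of(rid)}) has no voxels in the atlas volume"
            )
        values[rid] = np.asarray(gm_map)[mask].astype(float)
    return SubjectParcellation(subject_id, values)
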