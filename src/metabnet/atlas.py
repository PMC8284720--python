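"""Region atlas, regional-uptake tables, and ROI quantification.

Every network in this package lives on a fixed, ordered node space defined
by a :class:`RegionAtlas`.  The packaged default is a 96-region bilateral
parcellation of the rat brain (48 structures x 2 hemispheres) in the style
of the Schwarz atlas commonly used for rodent PET; only the label list and
its order matter downstream — no stereotaxic geometry is carried.

Regional uptake is stored per condition as an :class:`UptakeTable`
(subjects x regions).  Values are standardized uptake values divided by the
whole-brain mean (SUV ratio), so a value of 1.0 means "average brain
uptake".  ROI means can be extracted from already-registered 3-D volumes
paired with an integer label volume; spatial normalization itself is out of
scope here.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

HEMISPHERES = ("L", "R", "midline")

_ATLAS_COLUMNS = ("region_id", "name", "abbreviation", "hemisphere")


@dataclass(frozen=True)
class Region:
    """One parcellation unit: positive integer label plus naming metadata."""

    region_id: int
    name: str
    abbreviation: str
    hemisphere: str

    def __post_init__(self) -> None:
        if self.region_id <= 0:
            raise ValueError(f"region_id must be positive, got {self.region_id}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}"
            )


class RegionAtlas:
    """Ordered collection of regions fixing node identity and node order.

    The order of ``regions`` is the column order of every uptake table and
    the row/column order of every correlation matrix and adjacency matrix
    built from it.
    """

    def __init__(self, regions: Iterable[Region]):
        self.regions: tuple[Region, ...] = tuple(regions)
        if not self.regions:
            raise ValueError("atlas must contain at least one region")
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate region_ids in atlas: {dupes}")
        abbrs = [r.abbreviation for r in self.regions]
        if len(set(abbrs)) != len(abbrs):
            dupes = sorted({a for a in abbrs if abbrs.count(a) > 1})
            raise ValueError(f"duplicate abbreviations in atlas: {dupes}")
        self._abbr_index = {r.abbreviation: i for i, r in enumerate(self.regions)}

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(r.abbreviation for r in self.regions)

    @property
    def region_ids(self) -> np.ndarray:
        return np.array([r.region_id for r in self.regions], dtype=int)

    def index_of(self, abbreviation: str) -> int:
        try:
            return self._abbr_index[abbreviation]
        except KeyError:
            raise KeyError(
                f"region {abbreviation!r} is not in the atlas"
            ) from None

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionAtlas) and self.regions == other.regions

    def __repr__(self) -> str:
        return f"RegionAtlas(n_regions={self.n_regions})"

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionAtlas":
        missing = [c for c in _ATLAS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        return cls(
            Region(int(row.region_id), str(row.name_), str(row.abbreviation), str(row.hemisphere))
            for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionAtlas":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.region_id for r in self.regions],
                "name": [r.name for r in self.regions],
                "abbreviation": [r.abbreviation for r in self.regions],
                "hemisphere": [r.hemisphere for r in self.regions],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def default(cls) -> "RegionAtlas":
        """The packaged 96-region bilateral rat parcellation."""
        global _DEFAULT_ATLAS
        if _DEFAULT_ATLAS is None:
            ref = importlib.resources.files("metabnet.data").joinpath("atlas96.csv")
            with importlib.resources.as_file(ref) as p:
                _DEFAULT_ATLAS = cls.from_csv(p)
        return _DEFAULT_ATLAS


_DEFAULT_ATLAS: RegionAtlas | None = None


@dataclass
class UptakeTable:
    """Whole-brain-normalized regional uptake for one condition.

    ``values[s, r]`` is the SUV ratio of subject ``s`` in region ``r``;
    columns follow ``atlas`` order exactly.
    """

    condition: str
    subject_ids: tuple[str, ...]
    values: np.ndarray
    atlas: RegionAtlas

    def __post_init__(self) -> None:
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        if len(set(self.subject_ids)) != len(self.subject_ids):
            dupes = sorted({s for s in self.subject_ids if self.subject_ids.count(s) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects x regions matrix")
        if self.values.shape != (len(self.subject_ids), self.atlas.n_regions):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {self.atlas.n_regions} regions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("uptake values must all be finite")
        if np.any(self.values <= 0):
            raise ValueError("normalized uptake values must be strictly positive")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.subject_ids, name="subject"),
            columns=self.atlas.abbreviations,
        )

    def column(self, abbreviation: str) -> np.ndarray:
        return self.values[:, self.atlas.index_of(abbreviation)]


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","


def read_uptake_table(
    path: str | Path,
    atlas: RegionAtlas,
    condition: str | None = None,
) -> UptakeTable:
    """Read a delimited subjects x regions table, reordering to atlas order.

    The file must have a subject-identifier column (named ``subject``, or
    the first column) and one column per atlas abbreviation.  Unknown or
    missing region columns raise with the offending names listed.
    """
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    subj_col = "subject" if "subject" in df.columns else df.columns[0]
    region_cols = [c for c in df.columns if c != subj_col]
    wanted = set(atlas.abbreviations)
    unknown = sorted(set(region_cols) - wanted)
    missing = [a for a in atlas.abbreviations if a not in region_cols]
    if missing or unknown:
        parts = []
        if missing:
            parts.append(f"missing atlas columns: {missing}")
        if unknown:
            parts.append(f"unknown columns: {unknown}")
        raise ValueError(f"{path}: " + "; ".join(parts))
    subjects = [str(s) for s in df[subj_col]]
    values = df[list(atlas.abbreviations)].to_numpy(dtype=float)
    return UptakeTable(
        condition=condition if condition is not None else Path(path).stem,
        subject_ids=tuple(subjects),
        values=values,
        atlas=atlas,
    )


def write_uptake_table(table: UptakeTable, path: str | Path) -> None:
    """Write a table such that a read round-trips to full float precision."""
    # 17 significant digits round-trip any IEEE double exactly
    table.to_frame().to_csv(path, sep=_sep_for(path), float_format="%.17g")


@dataclass
class LabeledVolumePair:
    """A registered 3-D uptake volume plus an integer label volume.

    Label 0 is background; positive labels are atlas ``region_id`` values.
    """

    image: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded):
                raise ValueError("label volume must contain integers")
            labels = rounded.astype(int)
        self.labels = labels
        if self.image.shape != self.labels.shape:
            raise ValueError(
                f"image shape {self.image.shape} != labels shape {self.labels.shape}"
            )
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative (0 = background)")


def load_labeled_volume(image_path: str | Path, labels_path: str | Path) -> LabeledVolumePair:
    """Load an image/label NIfTI pair."""
    import nibabel as nib

    image = np.asarray(nib.load(str(image_path)).dataobj, dtype=float)
    labels = np.asarray(nib.load(str(labels_path)).dataobj)
    return LabeledVolumePair(image=image, labels=labels)


def extract_roi_means(
    volume: LabeledVolumePair,
    atlas: RegionAtlas,
    return_counts: bool = False,
):
    """Mean uptake per atlas region, in atlas order; background excluded.

    Raises if any atlas region_id is absent from the label volume, naming
    the region.
    """
    labels = volume.labels.ravel()
    image = volume.image.ravel()
    max_id = int(atlas.region_ids.max())
    sums = np.bincount(labels, weights=image, minlength=max_id + 1)
    counts = np.bincount(labels, minlength=max_id + 1)
    ids = atlas.region_ids
    for region in atlas:
        if region.region_id > len(counts) - 1 or counts[region.region_id] == 0:
            raise ValueError(
                f"region {region.region_id} ({region.abbreviation}) "
                "has no voxels in the label volume"
            )
    roi_counts = counts[ids].astype(int)
    means = sums[ids] / roi_counts
    if return_counts:
        return means, roi_counts
    return means


def normalize_whole_brain(raw_means: np.ndarray, voxel_counts: np.ndarray) -> np.ndarray:
    """Divide regional means by the voxel-count-weighted whole-brain mean.

    The whole-brain mean is taken over all labeled voxels (region means
    weighted by region size), so the weighted mean of the output is exactly
    1.0.  Output is invariant to global rescaling of the raw image.
    """
    raw_means = np.asarray(raw_means, dtype=float)
    voxel_counts = np.asarray(voxel_counts, dtype=float)
    if raw_means.shape != voxel_counts.shape:
        raise ValueError("raw_means and voxel_counts must have the same length")
    if np.any(voxel_counts <= 0):
        raise ValueError("voxel_counts must all be positive")
    whole_brain = float(np.average(raw_means, weights=voxel_counts))
    if not np.isfinite(whole_brain) or whole_brain <= 0:
        raise ValueError(f"whole-brain mean uptake is not positive: {whole_brain}")
    return raw_means / whole_brain


def uptake_from_volumes(
    volumes: Mapping[str, LabeledVolumePair],
    atlas: RegionAtlas,
    condition: str,
) -> UptakeTable:
    """Extract and whole-brain-normalize one row per subject volume."""
    rows = []
    for subject, vol in volumes.items():
        means, counts = extract_roi_means(vol, atlas, return_counts=True)
        rows.append(normalize_whole_brain(means, counts))
    return UptakeTable(
        condition=condition,
        subject_ids=tuple(volumes.keys()),
        values=np.vstack(rows),
        atlas=atlas,
    )
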