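"""Region parcellation and cohort table I/O.

The parcellation is the single source of truth for region ordering: every
matrix produced downstream (connectivity, adjacency, distances) is indexed
by atlas order, and files always refer to regions by abbreviation, never by
index.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Lobe taxonomy: the five anatomically named lobes plus two catch-all
#: categories so that every region of the 90-structure parcellation is
#: assignable (central strip and deep grey nuclei fall outside the five).
LOBES = (
    "Frontal",
    "Temporal",
    "Occipital",
    "Limbic",
    "Parietal",
    "Central",
    "Subcortical-nuclei",
)

#: The five named lobes used for intra-lobe covariation analyses.
NAMED_LOBES = ("Frontal", "Temporal", "Occipital", "Limbic", "Parietal")

HEMISPHERES = ("L", "R")

GROUPS = ("NC", "MCI", "AD")

#: Metadata columns of a cohort file, in canonical order.
COHORT_META_COLUMNS = ("subject_id", "group", "age", "sex", "education", "ref_brainstem")


class AtlasError(ValueError):
    """Raised when a region table fails validation."""


class CohortError(ValueError):
    """Raised when a cohort table fails validation."""


@dataclass(frozen=True)
class Region:
    index: int
    abbreviation: str
    name: str
    hemisphere: str
    lobe: str

    @property
    def stem(self) -> str:
        """Abbreviation without the hemisphere suffix (``PreCG.R`` -> ``PreCG``)."""
        return self.abbreviation.rsplit(".", 1)[0]


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered region parcellation with hemisphere and lobe assignment."""

    regions: tuple[Region, ...]

    @property
    def n(self) -> int:
        return len(self.regions)

    @property
    def abbreviations(self) -> list[str]:
        return [r.abbreviation for r in self.regions]

    def index_of(self, abbreviation: str) -> int:
        try:
            return self._index[abbreviation]
        except KeyError:
            raise AtlasError(f"unknown region abbreviation {abbreviation!r}") from None

    def indices_of(self, abbreviations: Sequence[str]) -> np.ndarray:
        return np.array([self.index_of(a) for a in abbreviations], dtype=int)

    @property
    def _index(self) -> dict[str, int]:
        return {r.abbreviation: r.index for r in self.regions}

    def lobe_indices(self, lobe: str) -> np.ndarray:
        if lobe not in LOBES:
            raise AtlasError(f"unknown lobe {lobe!r}; expected one of {LOBES}")
        return np.array([r.index for r in self.regions if r.lobe == lobe], dtype=int)

    @property
    def lobe_labels(self) -> np.ndarray:
        return np.array([r.lobe for r in self.regions])

    def homologous_pairs(self) -> list[tuple[int, int]]:
        """(left, right) index pairs sharing an abbreviation stem.

        The pairing must be a bijection between hemispheres; a stem with a
        single hemisphere is a validation error caught at load time.
        """
        by_stem: dict[str, dict[str, int]] = {}
        for r in self.regions:
            by_stem.setdefault(r.stem, {})[r.hemisphere] = r.index
        return [(d["L"], d["R"]) for d in by_stem.values()]

    def pair_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of unordered region pairs (i < j, atlas order)."""
        return np.triu_indices(self.n, k=1)


def _validate_atlas(df: pd.DataFrame, expected_n: int | None) -> tuple[Region, ...]:
    required = {"abbreviation", "name", "hemisphere", "lobe"}
    missing = required - set(df.columns)
    if missing:
        raise AtlasError(f"region table missing columns: {sorted(missing)}")
    dup = df["abbreviation"][df["abbreviation"].duplicated()]
    if not dup.empty:
        raise AtlasError(f"duplicate abbreviation(s): {sorted(dup.unique())}")
    regions = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.hemisphere not in HEMISPHERES:
            raise AtlasError(
                f"row {i} ({row.abbreviation}): unknown hemisphere {row.hemisphere!r}"
            )
        if row.lobe not in LOBES:
            raise AtlasError(f"row {i} ({row.abbreviation}): unknown lobe {row.lobe!r}")
        regions.append(Region(i, row.abbreviation, row.name, row.hemisphere, row.lobe))
    if expected_n is not None and len(regions) != expected_n:
        raise AtlasError(f"expected {expected_n} regions, found {len(regions)}")
    # homologous pairing must be a bijection between hemispheres
    by_stem: dict[str, list[Region]] = {}
    for r in regions:
        by_stem.setdefault(r.stem, []).append(r)
    for stem, members in by_stem.items():
        hemis = sorted(m.hemisphere for m in members)
        if hemis != ["L", "R"]:
            raise AtlasError(
                f"stem {stem!r} does not form a left/right homologous pair "
                f"(hemispheres found: {hemis})"
            )
    return tuple(regions)


def load_atlas(path: str | Path = "aal90", expected_n: int | None = None) -> RegionAtlas:
    """Load and validate a region table.

    ``path`` is either a CSV path or the builtin token ``"aal90"`` naming the
    shipped 90-structure parcellation (in which case N is checked to be 90).
    Region order in the file is preserved and becomes the atlas order.
    """
    if str(path) == "aal90":
        with importlib.resources.files("metabonet.data").joinpath("aal90.csv").open() as fh:
            df = pd.read_csv(fh)
        expected_n = 90 if expected_n is None else expected_n
    else:
        df = pd.read_csv(path)
    return RegionAtlas(_validate_atlas(df, expected_n))


@dataclass
class CohortTable:
    """Subjects x regions glucose uptake with per-subject covariates.

    ``cmrgl`` and ``volumes`` columns follow atlas order exactly.
    """

    atlas: RegionAtlas
    subject_ids: list[str]
    group: np.ndarray  # str array, one of GROUPS
    age: np.ndarray  # years
    sex: np.ndarray  # "M"/"F"
    education: np.ndarray  # years
    cmrgl: np.ndarray  # (n_subjects, N), tracer units
    volumes: np.ndarray  # (n_subjects, N), mm^3
    reference_value: np.ndarray  # brainstem mean uptake, > 0

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        N = self.atlas.n
        self.group = np.asarray(self.group, dtype=object)
        self.age = np.asarray(self.age, dtype=float)
        self.education = np.asarray(self.education, dtype=float)
        self.sex = np.asarray(self.sex, dtype=object)
        self.cmrgl = np.asarray(self.cmrgl, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.reference_value = np.asarray(self.reference_value, dtype=float)
        if self.cmrgl.shape != (n, N) or self.volumes.shape != (n, N):
            raise CohortError(
                f"cmrgl/volumes must have shape ({n}, {N}); got "
                f"{self.cmrgl.shape} and {self.volumes.shape}"
            )
        bad = set(self.group) - set(GROUPS)
        if bad:
            raise CohortError(f"unknown group label(s): {sorted(bad)}")
        bad_sex = set(self.sex) - {"M", "F"}
        if bad_sex:
            raise CohortError(f"unknown sex code(s): {sorted(bad_sex)}")
        nonpos = np.flatnonzero(~(self.reference_value > 0))
        if nonpos.size:
            names = [self.subject_ids[i] for i in nonpos[:5]]
            raise CohortError(f"non-positive reference value for subject(s): {names}")
        for arr, label in [
            (self.age, "age"),
            (self.education, "education"),
            (self.cmrgl, "cmrgl"),
            (self.volumes, "volumes"),
            (self.reference_value, "ref_brainstem"),
        ]:
            if not np.all(np.isfinite(arr)):
                raise CohortError(f"missing or non-finite values in {label}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def sex_code(self) -> np.ndarray:
        """Sex coded numerically: M=0, F=1."""
        return (self.sex == "F").astype(float)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CohortTable(
            atlas=self.atlas,
            subject_ids=[self.subject_ids[i] for i in idx],
            group=self.group[idx],
            age=self.age[idx],
            sex=self.sex[idx],
            education=self.education[idx],
            cmrgl=self.cmrgl[idx],
            volumes=self.volumes[idx],
            reference_value=self.reference_value[idx],
        )

    def group_table(self, label: str) -> "CohortTable":
        if label not in set(self.group):
            raise CohortError(f"group {label!r} absent from cohort")
        return self.subset(self.group == label)

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {
            "subject_id": self.subject_ids,
            "group": self.group,
            "age": self.age,
            "sex": self.sex,
            "education": self.education,
            "ref_brainstem": self.reference_value,
        }
        for j, abbr in enumerate(self.atlas.abbreviations):
            data[f"cmrgl_{abbr}"] = self.cmrgl[:, j]
        for j, abbr in enumerate(self.atlas.abbreviations):
            data[f"vol_{abbr}"] = self.volumes[:, j]
        return pd.DataFrame(data)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort table as TSV (``.tsv``) or CSV (anything else)."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    cohort.to_frame().to_csv(path, sep=sep, index=False, float_format="%.12g")


def load_cohort(path: str | Path, atlas: RegionAtlas) -> CohortTable:
    """Load a cohort table, reordering region columns to atlas order.

    The column set must be exactly the metadata columns plus one
    ``cmrgl_<abbr>`` and one ``vol_<abbr>`` column per atlas region.
    """
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep)
    missing_meta = set(COHORT_META_COLUMNS) - set(df.columns)
    if missing_meta:
        raise CohortError(f"cohort file missing metadata columns: {sorted(missing_meta)}")
    missing_regions = [
        c
        for abbr in atlas.abbreviations
        for c in (f"cmrgl_{abbr}", f"vol_{abbr}")
        if c not in df.columns
    ]
    if missing_regions:
        raise CohortError(f"cohort file missing region column(s): {missing_regions}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise CohortError(f"missing values in column(s): {bad}")
    cm_cols = [f"cmrgl_{a}" for a in atlas.abbreviations]
    vol_cols = [f"vol_{a}" for a in atlas.abbreviations]
    for cols in (cm_cols, vol_cols, ["age", "education", "ref_brainstem"]):
        block = df[cols]
        nonnum = [c for c in cols if not np.issubdtype(block[c].dtype, np.number)]
        if nonnum:
            raise CohortError(f"non-numeric values in column(s): {nonnum}")
    return CohortTable(
        atlas=atlas,
        subject_ids=[str(s) for s in df["subject_id"]],
        group=df["group"].to_numpy(),
        age=df["age"].to_numpy(float),
        sex=df["sex"].to_numpy(),
        education=df["education"].to_numpy(float),
        cmrgl=df[cm_cols].to_numpy(float),
        volumes=df[vol_cols].to_numpy(float),
        reference_value=df["ref_brainstem"].to_numpy(float),
    )


def write_matrix(r: np.ndarray, atlas: RegionAtlas, path: str | Path) -> None:
    """Write a square region-by-region matrix as CSV with abbreviation labels."""
    pd.DataFrame(r, index=atlas.abbreviations, columns=atlas.abbreviations).to_csv(path)


def load_matrix(path: str | Path, atlas: RegionAtlas) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    if list(df.columns) != atlas.abbreviations or list(df.index) != atlas.abbreviations:
        df = df.loc[atlas.abbreviations, atlas.abbreviations]
    return df.to_numpy(float)


def write_edge_list(
    edges: Sequence[tuple[int, int]],
    atlas: RegionAtlas,
    path: str | Path,
    weights: Sequence[float] | None = None,
) -> None:
    """Write an edge list TSV: region_a, region_b (a before b in atlas order)."""
    rows = []
    for k, (i, j) in enumerate(edges):
        i, j = (i, j) if i < j else (j, i)
        row = {
            "region_a": atlas.regions[i].abbreviation,
            "region_b": atlas.regions[j].abbreviation,
        }
        if weights is not None:
            row["weight"] = weights[k]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_edge_list(path: str | Path, atlas: RegionAtlas) -> list[tuple[int, int]]:
    df = pd.read_csv(path, sep="\t")
    return [
        tuple(sorted((atlas.index_of(a), atlas.index_of(b))))
        for a, b in zip(df["region_a"], df["region_b"])
    ]
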