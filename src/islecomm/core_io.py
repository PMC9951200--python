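"""Data model and delimited-text I/O for island community data.

The canonical in-memory objects are thin wrappers around pandas
structures:

* :class:`OccurrenceMatrix` — binary species (rows) × islands (columns)
  incidence table.  Every downstream stage (beta diversity, null models,
  ordination) consumes this orientation.
* island attribute tables and taxon maps are plain :class:`pandas.DataFrame`
  objects validated by :func:`read_island_table` / :func:`read_taxon_map`.

Files are UTF-8 delimited text; the delimiter is auto-detected among
comma and tab.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceMatrix",
    "read_occurrence_matrix",
    "write_occurrence_matrix",
    "read_island_table",
    "read_taxon_map",
    "subset_taxon",
    "validate_bundle",
    "ISLAND_COLUMNS",
    "TAXON_CATEGORIES",
]

#: required columns of an island attribute table
ISLAND_COLUMNS = [
    "island_id", "lon", "lat", "area_m2", "elevation_m", "perimeter_m",
    "habitat_richness", "veg_coverage", "isw", "isd_m",
]

#: the five standing taxon categories used throughout the analyses
TAXON_CATEGORIES = (
    "total_bryophytes", "mosses", "liverworts",
    "acrocarpous_mosses", "pleurocarpous_mosses",
)


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Binary species-by-island incidence matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Integer 0/1 values, species as the index, islands as columns.

    Raises
    ------
    ValueError
        If cells are not all 0/1 or labels are duplicated.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at species {self.data.index[i]!r}, "
                f"island {self.data.columns[j]!r}: {values[i, j]!r}"
            )
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate species label: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate island label: {dup!r}")
        object.__setattr__(self, "data", self.data.astype(np.int8))

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def island_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """0/1 array, shape (n_species, n_islands)."""
        return self.data.to_numpy()

    @property
    def n_species(self) -> int:
        return self.data.shape[0]

    @property
    def n_islands(self) -> int:
        return self.data.shape[1]

    def richness(self) -> pd.Series:
        """Species richness per island (column sums)."""
        return self.data.sum(axis=0)

    def occupancy(self) -> pd.Series:
        """Occurrence frequency per species (row sums)."""
        return self.data.sum(axis=1)

    def with_values(self, values: np.ndarray) -> "OccurrenceMatrix":
        """Same labels, new cells (used by the null-model randomizers)."""
        return OccurrenceMatrix(
            pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        )


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=0,
                       encoding="utf-8")


def read_occurrence_matrix(path, orientation: str = "species_rows",
                           blank_is_zero: bool = False) -> OccurrenceMatrix:
    """Read a presence/absence matrix from delimited text.

    Parameters
    ----------
    path : str or pathlib.Path
        CSV/TSV with a header row and a leading label column.
    orientation : {"species_rows", "islands_rows"}
        How the file is laid out.  The returned matrix is always in the
        canonical species-rows orientation.
    blank_is_zero : bool
        Treat empty cells as absences instead of raising.
    """
    if orientation not in ("species_rows", "islands_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = _read_delimited(path)
    if blank_is_zero:
        df = df.fillna(0)
    elif df.isna().any().any():
        row, col = next(
            (r, c) for r in df.index for c in df.columns if pd.isna(df.at[r, c])
        )
        raise ValueError(f"blank cell at row {row!r}, column {col!r} "
                         "(pass blank_is_zero=True to allow)")
    if orientation == "islands_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OccurrenceMatrix(df)


def write_occurrence_matrix(matrix: OccurrenceMatrix, path,
                            sep: str = ",") -> None:
    matrix.data.to_csv(path, sep=sep, encoding="utf-8")


def read_island_table(path) -> pd.DataFrame:
    """Read an island attribute table; returns a frame indexed by island_id.

    Required columns: lon, lat, area_m2, elevation_m, perimeter_m,
    habitat_richness, veg_coverage; isw and isd_m are optional.
    """
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    missing = [c for c in ISLAND_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise ValueError(f"island table missing columns: {missing}")
    df = df.set_index(df["island_id"].astype(str)).drop(columns="island_id")
    _validate_island_frame(df)
    return df


def _validate_island_frame(df: pd.DataFrame) -> None:
    if (df["area_m2"] <= 0).any():
        bad = df.index[df["area_m2"] <= 0].tolist()
        raise ValueError(f"non-positive area for islands {bad}")
    if (df["perimeter_m"] <= 0).any():
        bad = df.index[df["perimeter_m"] <= 0].tolist()
        raise ValueError(f"non-positive perimeter for islands {bad}")
    for col in ("veg_coverage", "isw"):
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")


def read_taxon_map(path) -> pd.DataFrame:
    """Read the species → family / division / growth-form map."""
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    needed = ["species_id", "family", "division", "growth_form"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"taxon map missing columns: {missing}")
    df = df.set_index(df["species_id"].astype(str)).drop(columns="species_id")
    bad_div = set(df["division"]) - {"moss", "liverwort", "hornwort"}
    if bad_div:
        raise ValueError(f"unknown divisions: {sorted(bad_div)}")
    bad_gf = set(df["growth_form"]) - {"acrocarpous", "pleurocarpous",
                                       "not_applicable"}
    if bad_gf:
        raise ValueError(f"unknown growth forms: {sorted(bad_gf)}")
    inconsistent = df[(df["division"] != "moss")
                      & (df["growth_form"] != "not_applicable")]
    if len(inconsistent):
        raise ValueError(
            "growth_form must be not_applicable for non-mosses: "
            f"{inconsistent.index.tolist()}"
        )
    return df


def subset_taxon(matrix: OccurrenceMatrix, taxa: pd.DataFrame,
                 selector: str) -> OccurrenceMatrix:
    """Restrict the matrix rows to one taxon category or one family.

    ``selector`` is one of the five standing categories
    (``total_bryophytes``, ``mosses``, ``liverworts``,
    ``acrocarpous_mosses``, ``pleurocarpous_mosses``) or a family name
    present in ``taxa``.  Islands (columns) are always retained, so a
    family subset may contain empty islands; downstream beta-diversity
    code handles those pairs explicitly.

    The single hornwort division enters only ``total_bryophytes``.
    """
    taxa = taxa.loc[[s for s in matrix.species_ids if s in taxa.index]]
    if selector == "total_bryophytes":
        keep = list(taxa.index)
    elif selector == "mosses":
        keep = list(taxa.index[taxa["division"] == "moss"])
    elif selector == "liverworts":
        keep = list(taxa.index[taxa["division"] == "liverwort"])
    elif selector == "acrocarpous_mosses":
        keep = list(taxa.index[(taxa["division"] == "moss")
                               & (taxa["growth_form"] == "acrocarpous")])
    elif selector == "pleurocarpous_mosses":
        keep = list(taxa.index[(taxa["division"] == "moss")
                               & (taxa["growth_form"] == "pleurocarpous")])
    elif selector in set(taxa["family"]):
        keep = list(taxa.index[taxa["family"] == selector])
    else:
        raise ValueError(f"selector {selector!r} matches no species "
                         "(not a category, not a family)")
    if not keep:
        raise ValueError(f"selector {selector!r} matches zero species")
    return OccurrenceMatrix(matrix.data.loc[keep])


def validate_bundle(matrix: OccurrenceMatrix, islands: pd.DataFrame | None,
                    taxa: pd.DataFrame | None) -> list[str]:
    """Cross-check a matrix / island-table / taxon-map bundle.

    Returns a list of human-readable issue strings; an empty list means
    the bundle is consistent.  This never raises — it is a reporting
    operation used before a pipeline run.
    """
    issues: list[str] = []
    if islands is not None:
        missing = [i for i in matrix.island_ids if i not in islands.index]
        if missing:
            issues.append(f"islands in matrix missing from island table: {missing}")
        extra = [i for i in islands.index if i not in matrix.island_ids]
        if extra:
            issues.append(f"islands in table absent from matrix: {extra}")
    if taxa is not None:
        missing = [s for s in matrix.species_ids if s not in taxa.index]
        if missing:
            issues.append(f"species missing from taxon map: {missing}")
    empty_rows = [s for s, tot in matrix.occupancy().items() if tot == 0]
    if empty_rows:
        issues.append(f"species never observed (all-zero rows): {empty_rows}")
    empty_cols = [i for i, tot in matrix.richness().items() if tot == 0]
    if empty_cols:
        issues.append(f"islands with no records (all-zero columns): {empty_cols}")
    return issues
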