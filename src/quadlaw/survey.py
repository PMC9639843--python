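"""Data model and file I/O for binary quadrat occupancy surveys.

The survey design follows the Binary Method: a transect carries ``n_lquadrats``
large quadrats (L-quadrats), each split into ``m_subquadrats`` small quadrats
(S-quadrats), and each species is scored 1 (present) or 0 (absent) in every
S-quadrat.  Occurrence counts per L-quadrat — the basis of all downstream
statistics — are obtained by summing S-quadrat indicators within an L-quadrat.

Files are delimited text (comma or tab, auto-detected from the ``.csv``/``.tsv``
extension) in one of two layouts:

* **long** — columns ``transect,l_index,s_index,species,present``; by default
  only presence rows need to be listed (field sheets record presences) and
  absent cells are filled with 0.
* **wide** — columns ``transect,l_index,s_index,<one 0/1 column per species>``,
  one row per S-quadrat.

Quadrat indices are 1-based in files, 0-based in memory; the readers and
writers in this module are the only place that mapping occurs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .errors import ConflictError, DesignError, DomainError, FormatError

__all__ = [
    "SurveyDesign",
    "OccurrenceMatrix",
    "SummaryTable",
    "read_occurrence_table",
    "write_occurrence_table",
    "aggregate_counts",
    "read_summary_table",
    "write_summary_table",
]

_LONG_COLUMNS = ("l_index", "s_index", "species", "present")
_CELL_COLUMNS = ("transect", "l_index", "s_index")


@dataclass(frozen=True)
class SurveyDesign:
    """Geometry of one surveyed transect.

    Parameters
    ----------
    n_lquadrats
        Number of L-quadrats along the transect.  At least 2, because the
        occurrence-count variance is taken across L-quadrats.
    m_subquadrats
        Number of S-quadrats inside each L-quadrat (4 for a 25 cm quadrat
        split into 12.5 cm cells).
    transect_id
        Optional label of the transect the design describes.
    """

    n_lquadrats: int
    m_subquadrats: int
    transect_id: str | None = None

    def __post_init__(self) -> None:
        if int(self.n_lquadrats) != self.n_lquadrats or self.n_lquadrats < 2:
            raise DesignError(
                f"n_lquadrats must be an integer >= 2, got {self.n_lquadrats!r}"
            )
        if int(self.m_subquadrats) != self.m_subquadrats or self.m_subquadrats < 2:
            raise DesignError(
                f"m_subquadrats must be an integer >= 2, got {self.m_subquadrats!r}"
            )
        object.__setattr__(self, "n_lquadrats", int(self.n_lquadrats))
        object.__setattr__(self, "m_subquadrats", int(self.m_subquadrats))

    @property
    def n_cells(self) -> int:
        """Total number of S-quadrats on the transect."""
        return self.n_lquadrats * self.m_subquadrats


@dataclass
class OccurrenceMatrix:
    """Binary presence records for every (L-quadrat, S-quadrat, species) cell.

    ``presence`` has shape ``(n_lquadrats, m_subquadrats, n_species)`` with
    values in {0, 1}; species order matches ``species``.
    """

    design: SurveyDesign
    species: list[str]
    presence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.species = list(self.species)
        if len(set(self.species)) != len(self.species):
            raise FormatError("species labels must be unique")
        arr = np.asarray(self.presence)
        expected = (self.design.n_lquadrats, self.design.m_subquadrats, len(self.species))
        if arr.shape != expected:
            raise DesignError(
                f"presence shape {arr.shape} does not match design {expected}"
            )
        if not np.isin(arr, (0, 1)).all():
            raise FormatError("presence values must all be 0 or 1")
        self.presence = arr.astype(np.uint8)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def counts(self) -> pd.DataFrame:
        """Occurrence counts per L-quadrat (rows) and species (columns)."""
        return aggregate_counts(self)


@dataclass
class SummaryTable:
    """Published per-species summary rows: frequency p and heterogeneity δ.

    Mirrors the layout of a printed results table — one row per species with
    its occurrence frequency ``p`` in [0, 1], heterogeneity index ``delta``,
    and optionally the community-relative residual ``epsilon``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = {"species", "p", "delta"} - set(df.columns)
        if missing:
            raise FormatError(f"summary table missing mandatory columns: {sorted(missing)}")
        if len(df) and (df["p"].lt(0).any() or df["p"].gt(1).any()):
            bad = df.loc[(df["p"] < 0) | (df["p"] > 1), "species"].tolist()
            raise DomainError(f"p outside [0, 1] for species {bad}")
        if "abbrev" in df.columns:
            abbrevs = df["abbrev"].dropna()
            if abbrevs.duplicated().any():
                raise FormatError("abbreviations must be unique when present")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def p(self) -> np.ndarray:
        return self.frame["p"].to_numpy(dtype=float)

    @property
    def delta(self) -> np.ndarray:
        return self.frame["delta"].to_numpy(dtype=float)

    @property
    def species(self) -> list[str]:
        return self.frame["species"].tolist()


def _sep_for(source: str | Path | IO[str], sep: str | None) -> str | None:
    """Delimiter from an explicit override or the file extension."""
    if sep is not None:
        return sep
    name = getattr(source, "name", source)
    suffix = Path(str(name)).suffix.lower()
    if suffix == ".tsv":
        return "\t"
    if suffix == ".csv":
        return ","
    return None  # let pandas sniff


def _read_frame(source: str | Path | IO[str], sep: str | None) -> pd.DataFrame:
    sep = _sep_for(source, sep)
    kwargs = {"sep": sep} if sep is not None else {"sep": None, "engine": "python"}
    try:
        return pd.read_csv(source, **kwargs)
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse delimited text: {exc}") from exc


def _check_binary(values: pd.Series, what: str) -> None:
    bad = ~values.isin((0, 1))
    if bad.any():
        row = int(bad.idxmax())
        raise FormatError(
            f"non-binary {what} value {values[row]!r} at input row {row + 2}"
        )


def _select_transect(
    df: pd.DataFrame,
    transect: str | None,
    pool_transects: bool,
) -> tuple[pd.DataFrame, str | None]:
    """Resolve the transect column to a single analysis unit.

    Pooling concatenates transects end to end so their L-quadrats form one
    longer virtual transect; otherwise a file holding several transects needs
    an explicit selection.
    """
    if "transect" not in df.columns:
        return df.assign(transect="T1"), transect
    labels = df["transect"].astype(str)
    df = df.assign(transect=labels)
    unique = labels.unique().tolist()
    if transect is not None:
        if str(transect) not in unique:
            raise DesignError(f"transect {transect!r} not found (file has {unique})")
        return df[df["transect"] == str(transect)].copy(), str(transect)
    if len(unique) <= 1:
        return df, unique[0] if unique else None
    if pool_transects:
        return df, "+".join(unique)
    raise DesignError(
        f"file contains transects {unique}; pass transect=... to select one "
        "or pool_transects=True to pool them"
    )


def read_occurrence_table(
    source: str | Path | IO[str],
    design: SurveyDesign | None = None,
    *,
    transect: str | None = None,
    pool_transects: bool = False,
    strict_zeros: bool = False,
    sep: str | None = None,
) -> OccurrenceMatrix:
    """Read a long- or wide-format presence/absence file.

    Parameters
    ----------
    source
        Path or open text handle of a delimited file (``.csv`` comma,
        ``.tsv`` tab; otherwise sniffed).
    design
        Optional design hint.  When absent the geometry is inferred from the
        maximum 1-based ``l_index``/``s_index`` in the file.
    transect, pool_transects
        Select one transect of a multi-transect file, or pool them into a
        single analysis unit (L-quadrats concatenated).
    strict_zeros
        Long format only: require every absent cell to carry an explicit 0
        row instead of being filled in.

    Returns
    -------
    OccurrenceMatrix
        Validated matrix; species appear in first-encounter order (long) or
        column order (wide).
    """
    df = _read_frame(source, sep)
    is_long = set(_LONG_COLUMNS).issubset(df.columns)
    missing_idx = {"l_index", "s_index"} - set(df.columns)
    if missing_idx:
        raise FormatError(f"missing index columns: {sorted(missing_idx)}")
    df, label = _select_transect(df, transect, pool_transects)

    if is_long:
        return _from_long(df, design, label, strict_zeros)
    return _from_wide(df, design, label)


def _relabel_pooled(df: pd.DataFrame) -> pd.DataFrame:
    """Renumber l_index so pooled transects occupy disjoint L-quadrat ranges."""
    if df["transect"].nunique() <= 1:
        return df
    offset = 0
    parts = []
    for _, part in df.groupby("transect", sort=False):
        part = part.copy()
        span = int(part["l_index"].max())
        part["l_index"] = part["l_index"] + offset
        offset += span
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def _infer_design(df: pd.DataFrame, label: str | None) -> SurveyDesign:
    return SurveyDesign(int(df["l_index"].max()), int(df["s_index"].max()), label)


def _check_indices(df: pd.DataFrame, design: SurveyDesign) -> None:
    if (df["l_index"] < 1).any() or (df["s_index"] < 1).any():
        raise FormatError("l_index and s_index must be 1-based positive integers")
    if (df["l_index"] > design.n_lquadrats).any() or (
        df["s_index"] > design.m_subquadrats
    ).any():
        raise DesignError(
            f"indices exceed design ({design.n_lquadrats} L-quadrats x "
            f"{design.m_subquadrats} S-quadrats)"
        )


def _from_long(
    df: pd.DataFrame,
    design: SurveyDesign | None,
    label: str | None,
    strict_zeros: bool,
) -> OccurrenceMatrix:
    _check_binary(df["present"], "presence")
    df = _relabel_pooled(df)
    if design is None:
        design = _infer_design(df, label)
    _check_indices(df, design)

    dup = df.duplicated(subset=["l_index", "s_index", "species"], keep=False)
    if dup.any():
        conflicts = (
            df[dup]
            .groupby(["l_index", "s_index", "species"])["present"]
            .nunique()
        )
        bad = conflicts[conflicts > 1]
        if len(bad):
            key = bad.index[0]
            raise ConflictError(
                f"conflicting presence values for (l={key[0]}, s={key[1]}, "
                f"species={key[2]!r})"
            )
        df = df.drop_duplicates(subset=["l_index", "s_index", "species"])

    species = list(dict.fromkeys(df["species"]))
    if strict_zeros:
        per_species = df.groupby("species", sort=False).size()
        short = per_species[per_species != design.n_cells]
        if len(short):
            raise FormatError(
                "strict mode requires explicit 0 rows for every cell; species "
                f"{short.index.tolist()} have incomplete records"
            )
    arr = np.zeros((design.n_lquadrats, design.m_subquadrats, len(species)), dtype=np.uint8)
    sp_idx = {s: k for k, s in enumerate(species)}
    li = df["l_index"].to_numpy(dtype=int) - 1
    si = df["s_index"].to_numpy(dtype=int) - 1
    ki = df["species"].map(sp_idx).to_numpy(dtype=int)
    arr[li, si, ki] = df["present"].to_numpy(dtype=np.uint8)
    return OccurrenceMatrix(design, species, arr)


def _from_wide(
    df: pd.DataFrame,
    design: SurveyDesign | None,
    label: str | None,
) -> OccurrenceMatrix:
    species = [c for c in df.columns if c not in _CELL_COLUMNS]
    if not species:
        raise FormatError("wide format file has no species columns")
    df = _relabel_pooled(df)
    if design is None:
        design = _infer_design(df, label)
    _check_indices(df, design)

    if df.duplicated(subset=["l_index", "s_index"]).any():
        raise ConflictError("duplicate (l_index, s_index) rows in wide format file")
    cells_per_l = df.groupby("l_index").size()
    if cells_per_l.nunique() > 1 or len(df) != design.n_cells:
        raise DesignError(
            "ragged S-quadrat counts across L-quadrats: "
            f"{sorted(cells_per_l.unique().tolist())} rows per L-quadrat"
        )
    for col in species:
        _check_binary(df[col], f"presence ({col})")

    arr = np.zeros((design.n_lquadrats, design.m_subquadrats, len(species)), dtype=np.uint8)
    li = df["l_index"].to_numpy(dtype=int) - 1
    si = df["s_index"].to_numpy(dtype=int) - 1
    arr[li, si, :] = df[species].to_numpy(dtype=np.uint8)
    return OccurrenceMatrix(design, species, arr)


def write_occurrence_table(
    matrix: OccurrenceMatrix,
    dest: str | Path | IO[str],
    *,
    layout: str = "wide",
    sparse: bool = True,
    sep: str | None = None,
) -> None:
    """Write a matrix back to delimited text (inverse of the reader).

    Long layout with ``sparse=True`` (the default) lists presence rows only,
    matching how field sheets are transcribed.
    """
    sep = _sep_for(dest, sep) or ","
    design = matrix.design
    tr = design.transect_id if design.transect_id is not None else "T1"
    ll, ss = np.meshgrid(
        np.arange(1, design.n_lquadrats + 1),
        np.arange(1, design.m_subquadrats + 1),
        indexing="ij",
    )
    if layout == "wide":
        df = pd.DataFrame({"transect": tr, "l_index": ll.ravel(), "s_index": ss.ravel()})
        flat = matrix.presence.reshape(design.n_cells, matrix.n_species)
        for k, sp in enumerate(matrix.species):
            df[sp] = flat[:, k]
    elif layout == "long":
        recs = []
        for k, sp in enumerate(matrix.species):
            block = pd.DataFrame(
                {
                    "transect": tr,
                    "l_index": ll.ravel(),
                    "s_index": ss.ravel(),
                    "species": sp,
                    "present": matrix.presence[:, :, k].ravel(),
                }
            )
            recs.append(block)
        df = pd.concat(recs, ignore_index=True)
        if sparse:
            df = df[df["present"] == 1].reset_index(drop=True)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    df.to_csv(dest, sep=sep, index=False)


def aggregate_counts(matrix: OccurrenceMatrix) -> pd.DataFrame:
    """Occurrence counts per L-quadrat: sum S-quadrat indicators within each L.

    Returns a DataFrame of shape ``(n_lquadrats, n_species)``; entry (j, i) is
    the number of S-quadrats of L-quadrat j in which species i is present,
    an integer in [0, m_subquadrats].  Because the input is already binary per
    S-quadrat, tillering shoots or multiple ramets are never re-counted.
    """
    counts = matrix.presence.sum(axis=1)
    return pd.DataFrame(counts, columns=matrix.species)


def read_summary_table(
    source: str | Path | IO[str], *, sep: str | None = None
) -> SummaryTable:
    """Read a published per-species summary (species, abbrev, p, epsilon, delta).

    Mandatory columns: ``species``, ``p``, ``delta``; ``abbrev`` and
    ``epsilon`` are optional.  Row order and numeric precision are preserved.
    """
    df = _read_frame(source, sep)
    return SummaryTable(df)


def write_summary_table(
    table: SummaryTable, dest: str | Path | IO[str], *, sep: str | None = None
) -> None:
    sep = _sep_for(dest, sep) or ","
    table.frame.to_csv(dest, sep=sep, index=False)
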