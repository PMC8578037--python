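"""Tabular input/output.

Reads participant tables and per-participant ROI gray-matter-volume tables
in the wide layout emitted by FreeSurfer's ``asegstats2table`` (rows =
participants, one volume column per structure, volumes in mm^3), and writes
the pipeline's tabular and JSON outputs, including adjacency matrices as
TSV, edge lists and GraphML.

Column matching against the ROI catalog is case- and punctuation-
insensitive and understands FreeSurfer hemisphere prefixes ("Left-Pallidum"
matches the catalog entry ``L_Pallidum``); an explicit alias map (YAML or
JSON, ``{file_column: catalog_name}``) covers anything else.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from .catalog import ROICatalog

__all__ = [
    "ParticipantRecord",
    "ROIVolumeTable",
    "TableError",
    "SchemaError",
    "ParseError",
    "IntegrityError",
    "ValidationError",
    "load_participants",
    "load_volume_table",
    "load_alias_map",
    "load_adjacency",
    "write_table",
    "write_json",
    "write_adjacency",
    "write_edge_list",
    "write_graphml",
    "write_volume_table",
    "write_participants",
]

GROUPS = ("cMDD", "RD", "HC")
GENDERS = ("male", "female")

#: participant columns beyond the identifier; True = required
_PARTICIPANT_COLUMNS = {
    "group": True,
    "gender": True,
    "age": True,
    "icv": True,
    "education": False,
    "hamd17": False,
    "rrs": False,
    "illness_duration": False,
    "illness_remission": False,
}


class TableError(ValueError):
    """Base class for tabular-input failures."""


class SchemaError(TableError):
    """A required column is missing or unmatchable."""


class ParseError(TableError):
    """A cell could not be parsed as the expected type."""


class IntegrityError(TableError):
    """Duplicate identifiers or mismatched participant/volume rows."""


class ValidationError(TableError):
    """A value violates a domain invariant (unknown group, age <= 0, ...)."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's demographic and clinical profile.

    Optional clinical scores are ``None`` when absent from the input —
    absence is flagged, never coerced to zero.
    """

    id: str
    group: str
    gender: str
    age: float
    icv: float
    education: float | None = None
    hamd17: float | None = None
    rrs: float | None = None
    illness_duration: float | None = None
    illness_remission: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"participant {self.id!r}: unknown group {self.group!r} "
                f"(expected one of {GROUPS})"
            )
        if self.gender not in GENDERS:
            raise ValidationError(
                f"participant {self.id!r}: unknown gender {self.gender!r}"
            )
        if not self.age > 0:
            raise ValidationError(f"participant {self.id!r}: age must be > 0")
        if not self.icv > 0:
            raise ValidationError(f"participant {self.id!r}: icv must be > 0")
        if self.hamd17 is not None and self.hamd17 < 0:
            raise ValidationError(f"participant {self.id!r}: hamd17 must be >= 0")


@dataclass
class ROIVolumeTable:
    """Participants with their ROI volumes, columns in catalog order.

    ``participants`` is indexed by participant id; ``volumes`` shares that
    index and has one column per catalog ROI (mm^3, all positive).
    """

    participants: pd.DataFrame
    volumes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.participants.index.equals(self.volumes.index):
            raise IntegrityError("participant and volume tables have different ids")
        if self.volumes.isna().any().any():
            raise IntegrityError("volume table contains missing cells")
        if (self.volumes.to_numpy() <= 0).any():
            bad = self.volumes.columns[(self.volumes <= 0).any()].tolist()
            raise ValidationError(f"non-positive volumes in ROIs: {bad}")

    @property
    def roi_names(self) -> list[str]:
        return list(self.volumes.columns)

    @property
    def n_participants(self) -> int:
        return len(self.volumes)

    def groups(self) -> pd.Series:
        return self.participants["group"]

    def select_groups(self, groups: Iterable[str]) -> "ROIVolumeTable":
        mask = self.participants["group"].isin(list(groups))
        return ROIVolumeTable(self.participants[mask], self.volumes[mask])

    @classmethod
    def from_records(
        cls, records: list[ParticipantRecord], volumes: pd.DataFrame
    ) -> "ROIVolumeTable":
        part = records_to_frame(records)
        vols = volumes.loc[part.index]
        return cls(part, vols)


def records_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Participant records as a DataFrame indexed by id."""
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise IntegrityError("duplicate participant ids")
    df = pd.DataFrame([dataclasses.asdict(r) for r in records]).set_index("id")
    return df


def frame_to_records(df: pd.DataFrame) -> list[ParticipantRecord]:
    records = []
    for pid, row in df.iterrows():
        kwargs: dict[str, Any] = {"id": str(pid)}
        for col, required in _PARTICIPANT_COLUMNS.items():
            val = row.get(col)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                if required:
                    raise SchemaError(f"participant {pid!r}: missing {col}")
                kwargs[col] = None
            else:
                kwargs[col] = val
        records.append(ParticipantRecord(**kwargs))
    return records


# ---------------------------------------------------------------------------
# readers


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a tab- or comma-delimited text file with a header row."""
    return pd.read_csv(path, sep=None, engine="python")


def _normalize(name: str) -> str:
    """Canonical key for ROI-column matching.

    Lowercase, punctuation stripped, with FreeSurfer hemisphere prefixes
    ("left-", "right-") folded to the catalog's single-letter form.
    """
    key = re.sub(r"[^0-9a-z]", "", name.lower())
    if key.startswith("left"):
        key = "l" + key[len("left"):]
    elif key.startswith("right"):
        key = "r" + key[len("right"):]
    return key


_ID_COLUMN_ALIASES = {"id", "participantid", "subject", "subjectid", "measurevolume"}
_ICV_ALIASES = {"icv", "etiv", "estimatedtotalintracranialvol"}


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Load a ``{file_column: catalog_name}`` alias map from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError("alias map must be a mapping of column -> catalog name")
    return {str(k): str(v) for k, v in data.items()}


def load_participants(path: str | Path) -> list[ParticipantRecord]:
    """Load and validate a participant table (delimited text, header row)."""
    df = _read_delimited(path)
    cols = {_normalize(c): c for c in df.columns}
    id_col = next((cols[k] for k in cols if k in _ID_COLUMN_ALIASES), None)
    if id_col is None:
        raise SchemaError("participant table has no id column")
    missing = [c for c, req in _PARTICIPANT_COLUMNS.items() if req and c not in cols]
    if missing:
        raise SchemaError(f"participant table missing required columns: {missing}")

    records = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        pid = str(row[id_col])
        if pid in seen:
            raise IntegrityError(f"duplicate participant id {pid!r}")
        seen.add(pid)
        kwargs: dict[str, Any] = {"id": pid}
        for col, required in _PARTICIPANT_COLUMNS.items():
            if col not in cols:
                kwargs[col] = None
                continue
            val = row[cols[col]]
            if pd.isna(val) or (isinstance(val, str) and not val.strip()):
                if required:
                    raise ValidationError(f"row {i}: missing {col}")
                kwargs[col] = None
            elif col in ("group", "gender"):
                kwargs[col] = str(val).strip()
            else:
                try:
                    kwargs[col] = float(val)
                except (TypeError, ValueError) as exc:
                    raise ParseError(f"row {i}, column {col!r}: non-numeric {val!r}") from exc
        records.append(ParticipantRecord(**kwargs))
    return records


def load_volume_table(
    path: str | Path,
    catalog: ROICatalog,
    *,
    roi_names: list[str] | None = None,
    aliases: dict[str, str] | None = None,
    participants: list[ParticipantRecord] | None = None,
) -> ROIVolumeTable:
    """Load an asegstats2table-style wide volume table.

    Columns are matched to catalog names case-insensitively with
    FreeSurfer-prefix folding plus the optional ``aliases`` map, then
    reordered to catalog order.  ``roi_names`` restricts the expected
    column set to a catalog subset (reduced catalogs used by small
    synthetic cohorts).  Rows with any missing volume are rejected with a
    report listing them.  When ``participants`` is given, rows are aligned
    to it by id; otherwise a minimal participant frame (id + ICV, if the
    file carries an ICV column) is attached.
    """
    expected = catalog.subset(roi_names) if roi_names is not None else catalog.names
    df = _read_delimited(path)

    alias_norm = {_normalize(k): v for k, v in (aliases or {}).items()}
    col_by_key: dict[str, str] = {}
    for col in df.columns:
        key = _normalize(col)
        if key in alias_norm:
            key = _normalize(alias_norm[key])
        if key in col_by_key:
            raise SchemaError(f"columns {col_by_key[key]!r} and {col!r} both match key {key!r}")
        col_by_key[key] = col

    id_col = next((col_by_key[k] for k in _ID_COLUMN_ALIASES if k in col_by_key), None)
    if id_col is None:
        raise SchemaError("volume table has no id column")
    icv_col = next((col_by_key[k] for k in _ICV_ALIASES if k in col_by_key), None)

    matched: dict[str, str] = {}
    unmatched: list[str] = []
    for roi in expected:
        key = _normalize(roi)
        if key in col_by_key:
            matched[roi] = col_by_key[key]
        else:
            unmatched.append(roi)
    if unmatched:
        raise SchemaError(f"volume table missing ROI columns: {', '.join(unmatched)}")

    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].tolist()
        raise IntegrityError(f"duplicate participant ids in volume table: {dups}")

    vols = df[[matched[r] for r in expected]].copy()
    vols.columns = expected
    for col in expected:
        try:
            vols[col] = pd.to_numeric(vols[col], errors="raise")
        except (TypeError, ValueError) as exc:
            bad = vols[pd.to_numeric(vols[col], errors="coerce").isna()].index.tolist()
            raise ParseError(f"non-numeric volume in column {col!r}, rows {bad}") from exc
    vols.index = pd.Index(ids, name="id")

    # listwise deletion of incomplete rows, with a report
    incomplete = vols.index[vols.isna().any(axis=1)].tolist()
    if incomplete:
        import warnings

        warnings.warn(
            f"dropping {len(incomplete)} participants with missing volumes: {incomplete}",
            stacklevel=2,
        )
        vols = vols.drop(index=incomplete)

    if participants is not None:
        part = records_to_frame(participants)
        missing_ids = sorted(set(vols.index) - set(part.index))
        if missing_ids:
            raise IntegrityError(f"volume rows without participant records: {missing_ids}")
        part = part.loc[[i for i in part.index if i in set(vols.index)]]
        vols = vols.loc[part.index]
    else:
        part = pd.DataFrame(index=vols.index)
        part["icv"] = (
            pd.to_numeric(df.set_index(ids)[icv_col], errors="coerce").loc[vols.index]
            if icv_col
            else np.nan
        )
    return ROIVolumeTable(part, vols)


# ---------------------------------------------------------------------------
# writers


def write_table(df: pd.DataFrame, path: str | Path, *, index: bool = True) -> None:
    """Write a DataFrame as TSV (UTF-8, header row)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_json(obj: Any, path: str | Path) -> None:
    """Write a result object as pretty-printed JSON (dataclasses unwrapped)."""

    def default(o: Any):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="index")
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def write_volume_table(table: ROIVolumeTable, path: str | Path) -> None:
    """Write volumes (plus the participants' ICV column) as TSV."""
    out = table.volumes.copy()
    if "icv" in table.participants.columns:
        out.insert(0, "ICV", table.participants["icv"])
    write_table(out, path)


def write_participants(records: list[ParticipantRecord], path: str | Path) -> None:
    write_table(records_to_frame(records), path)


def _adjacency_frame(adjacency: np.ndarray, labels: list[str]) -> pd.DataFrame:
    return pd.DataFrame(np.asarray(adjacency, dtype=int), index=labels, columns=labels)


def write_adjacency(adjacency: np.ndarray, labels: list[str], path: str | Path) -> None:
    """Write a 0/1 adjacency matrix as a labelled TSV."""
    write_table(_adjacency_frame(adjacency, labels), path)


def load_adjacency(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise SchemaError("adjacency TSV row and column labels differ")
    return df.to_numpy(dtype=np.uint8), list(df.columns)


def write_edge_list(adjacency: np.ndarray, labels: list[str], path: str | Path) -> None:
    """Write the upper-triangle edges as a two-column TSV of ROI names."""
    a = np.asarray(adjacency)
    ii, jj = np.nonzero(np.triu(a, k=1))
    df = pd.DataFrame({"source": [labels[i] for i in ii], "target": [labels[j] for j in jj]})
    write_table(df, path, index=False)


def write_graphml(adjacency: np.ndarray, labels: list[str], path: str | Path) -> None:
    import networkx as nx

    g = nx.from_numpy_array(np.asarray(adjacency))
    nx.relabel_nodes(g, dict(enumerate(labels)), copy=False)
    for _, _, d in g.edges(data=True):
        d.clear()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, path)
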