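"""Reading and writing LFQ intensity tables, experimental designs and call reports.

Input tables follow the MaxQuant ``proteinGroups.txt`` convention: one row per
protein group, a ``Protein IDs`` column, one intensity column per sample and a
raw intensity of 0 (or an empty cell) meaning "not detected".  Internally all
intensities are log2-transformed and missingness is carried as NaN — never as
0.0 — so that downstream arithmetic cannot silently absorb a non-detection.

The experimental design (which samples belong to which cell line, which lines
are baits, which single line is the leader negative control, and which bait
pairs are "related" and therefore excluded from each other's control sets) is
read from a small YAML/JSON config.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MISSING",
    "IntensityTable",
    "Line",
    "ExperimentDesign",
    "DesignError",
    "TableError",
    "read_protein_groups",
    "write_protein_groups",
    "read_design",
    "write_design",
    "read_annotation",
    "write_calls",
]

#: the internal missing-value marker for "protein not detected in this sample"
MISSING = float("nan")

ID_COLUMN = "Protein IDs"
DESCRIPTION_COLUMN = "Protein names"
FLAG_COLUMNS = ("Reverse", "Potential contaminant")

DESIGN_SCHEMA_VERSION = 1


class TableError(ValueError):
    """Raised when an intensity table violates its contract."""


class DesignError(ValueError):
    """Raised when an experimental-design config violates its contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class IntensityTable:
    """Proteins x samples log2 LFQ intensities with explicit missingness.

    ``data`` is indexed by unique protein accession, one column per sample;
    values are log2 intensities, NaN marks "not detected".  ``meta`` optionally
    carries a per-protein description string.
    """

    data: pd.DataFrame
    meta: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.data.index
        if len(idx) == 0 or idx.has_duplicates or (idx.astype(str) == "").any():
            raise TableError("protein ids must be unique and non-empty")
        cols = self.data.columns
        if len(cols) == 0 or cols.has_duplicates:
            raise TableError("sample ids must be unique and non-empty")
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise TableError("non-missing intensities must be finite")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def values_for(self, protein_id: str, sample_ids: list[str]) -> np.ndarray:
        """Log2 values (NaN = missing) for one protein across the given samples."""
        return self.data.loc[protein_id, sample_ids].to_numpy(dtype=float)

    def matrix(self, sample_ids: list[str]) -> np.ndarray:
        """Proteins x samples log2 matrix restricted to the given samples."""
        return self.data[sample_ids].to_numpy(dtype=float)

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(self.data.to_csv(sep="\t", float_format="%.10g").encode())
        return h.hexdigest()


@dataclass(frozen=True)
class Line:
    """One cell line: a bait construct or the leader negative control."""

    name: str
    role: str  # "bait" | "negative_control"
    samples: tuple[str, ...]


@dataclass
class ExperimentDesign:
    """Sample-to-line map with bait roles and related-bait exclusions."""

    lines: list[Line]
    related: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lines:
            raise DesignError("design declares no lines")
        names = [ln.name for ln in self.lines]
        if len(set(names)) != len(names):
            raise DesignError("line names must be unique")
        seen: dict[str, str] = {}
        for ln in self.lines:
            if ln.role not in ("bait", "negative_control"):
                raise DesignError(f"line {ln.name!r}: unknown role {ln.role!r}")
            if len(ln.samples) < 2:
                raise DesignError(
                    f"line {ln.name!r} has {len(ln.samples)} replicate(s); at least 2 required"
                )
            for s in ln.samples:
                if s in seen:
                    raise DesignError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {ln.name!r}"
                    )
                seen[s] = ln.name
        controls = [ln.name for ln in self.lines if ln.role == "negative_control"]
        if len(controls) != 1:
            raise DesignError(
                f"exactly one negative_control line required, found {len(controls)}"
            )
        baits = set(self.bait_names)
        for a, partners in self.related.items():
            if a not in baits:
                raise DesignError(f"related entry for non-bait line {a!r}")
            for b in partners:
                if b == a:
                    raise DesignError(f"line {a!r} declared related to itself")
                if b not in baits:
                    raise DesignError(f"related partner {b!r} is not a bait line")
                if a not in self.related.get(b, frozenset()):
                    raise DesignError(
                        f"related pairs must be symmetric: {a!r}->{b!r} lacks inverse"
                    )

    @property
    def bait_names(self) -> list[str]:
        return [ln.name for ln in self.lines if ln.role == "bait"]

    @property
    def negative_control_line(self) -> str:
        return next(ln.name for ln in self.lines if ln.role == "negative_control")

    @property
    def sample_ids(self) -> list[str]:
        return [s for ln in self.lines for s in ln.samples]

    def samples_of(self, line_name: str) -> list[str]:
        for ln in self.lines:
            if ln.name == line_name:
                return list(ln.samples)
        raise DesignError(f"unknown line {line_name!r}")

    def related_to(self, bait: str) -> frozenset[str]:
        return self.related.get(bait, frozenset())


# ---------------------------------------------------------------------------
# protein-groups tables
# ---------------------------------------------------------------------------

def _resolve_column(sample: str, columns: set[str], column_map: dict[str, str] | None) -> str:
    if column_map and sample in column_map:
        col = column_map[sample]
        if col not in columns:
            raise TableError(
                f"mapped column {col!r} for sample {sample!r} not found in table"
            )
        return col
    if sample in columns:
        return sample
    maxquant = f"Intensity {sample}"
    if maxquant in columns:
        return maxquant
    raise TableError(f"no intensity column found for designed sample {sample!r}")


def read_protein_groups(
    path,
    design: ExperimentDesign,
    column_map: dict[str, str] | None = None,
    drop_flagged: bool = True,
) -> IntensityTable:
    """Read a proteinGroups-style TSV into a log2 :class:`IntensityTable`.

    Raw intensities are log2-transformed; a raw 0 or an empty cell becomes the
    missing marker.  Rows flagged "+" in a ``Reverse`` or ``Potential
    contaminant`` column are dropped when ``drop_flagged`` (and such columns
    exist).  Every sample declared in ``design`` must resolve to exactly one
    column — by ``column_map``, by exact name, or by the MaxQuant
    ``Intensity <sample>`` convention.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if ID_COLUMN not in raw.columns:
        raise TableError(f"table lacks the {ID_COLUMN!r} column")

    if drop_flagged:
        for flag in FLAG_COLUMNS:
            if flag in raw.columns:
                raw = raw[raw[flag].str.strip() != "+"]

    ids = raw[ID_COLUMN].str.strip()
    dup = ids[ids.duplicated()]
    if len(dup):
        raise TableError(f"duplicate protein id {dup.iloc[0]!r}")

    columns = set(raw.columns)
    out = {}
    for sample in design.sample_ids:
        col = _resolve_column(sample, columns, column_map)
        cells = raw[col].str.strip()
        vals = np.full(len(cells), np.nan)
        for i, cell in enumerate(cells):
            if cell == "":
                continue
            try:
                v = float(cell)
            except ValueError:
                raise TableError(
                    f"non-numeric intensity {cell!r} at row {ids.iloc[i]!r}, column {col!r}"
                ) from None
            if v < 0 or not math.isfinite(v):
                raise TableError(
                    f"invalid raw intensity {v} at row {ids.iloc[i]!r}, column {col!r}"
                )
            if v > 0:  # raw 0 = not detected, never log2(0)
                vals[i] = math.log2(v)
        out[sample] = vals

    data = pd.DataFrame(out, index=pd.Index(ids, name="protein_id"))
    meta = None
    if DESCRIPTION_COLUMN in raw.columns:
        meta = pd.Series(raw[DESCRIPTION_COLUMN].to_numpy(), index=data.index)
    return IntensityTable(data=data, meta=meta)


def write_protein_groups(table: IntensityTable, path) -> None:
    """Write a table back to proteinGroups-style TSV (linear scale, 0 = missing)."""
    linear = np.power(2.0, table.data.to_numpy(dtype=float))
    linear = np.where(np.isnan(linear), 0.0, linear)
    out = pd.DataFrame(linear, index=table.data.index, columns=table.data.columns)
    out.insert(0, ID_COLUMN, table.data.index)
    if table.meta is not None:
        out.insert(1, DESCRIPTION_COLUMN, table.meta.to_numpy())
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# design configs
# ---------------------------------------------------------------------------

def read_design(path) -> ExperimentDesign:
    """Read and validate an experimental-design YAML/JSON config.

    Schema (version 1)::

        schema: 1
        lines:
          - {name: ZapE1, role: bait, samples: [ZapE1_a, ZapE1_b, ZapE1_c]}
          - {name: IscU_leader, role: negative_control, samples: [...]}
        related:
          - [ZapE1, ZapE2]

    Any invariant violation (zero or multiple negative controls, a sample in
    two lines, an asymmetric related pair, <2 replicates) is a hard error.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return design_from_dict(cfg)


def design_from_dict(cfg: dict) -> ExperimentDesign:
    if not isinstance(cfg, dict) or "lines" not in cfg:
        raise DesignError("design config must be a mapping with a 'lines' entry")
    schema = cfg.get("schema", DESIGN_SCHEMA_VERSION)
    if schema != DESIGN_SCHEMA_VERSION:
        raise DesignError(f"unsupported design schema version {schema!r}")
    lines = []
    for entry in cfg["lines"]:
        try:
            lines.append(
                Line(
                    name=str(entry["name"]),
                    role=str(entry.get("role", "bait")),
                    samples=tuple(str(s) for s in entry["samples"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise DesignError(f"malformed line entry {entry!r}") from exc
    related: dict[str, set[str]] = {}
    for pair in cfg.get("related", []) or []:
        if len(pair) != 2:
            raise DesignError(f"related entry {pair!r} is not a pair")
        a, b = (str(pair[0]), str(pair[1]))
        related.setdefault(a, set()).add(b)
        related.setdefault(b, set()).add(a)
    return ExperimentDesign(
        lines=lines, related={k: frozenset(v) for k, v in related.items()}
    )


def design_to_dict(design: ExperimentDesign) -> dict:
    pairs = sorted(
        {tuple(sorted((a, b))) for a, bs in design.related.items() for b in bs}
    )
    return {
        "schema": DESIGN_SCHEMA_VERSION,
        "lines": [
            {"name": ln.name, "role": ln.role, "samples": list(ln.samples)}
            for ln in design.lines
        ],
        "related": [list(p) for p in pairs],
    }


def write_design(design: ExperimentDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    """Read a prior-evidence annotation TSV.

    Expected columns: ``protein_id`` plus any of ``prior_localized``,
    ``in_importome`` (1/0, true/false) and ``targeting_prob`` (fraction in
    [0,1], blank allowed).  Returns a DataFrame indexed by unique protein id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    if "protein_id" not in df.columns:
        raise TableError("annotation table lacks a 'protein_id' column")
    if df["protein_id"].duplicated().any():
        raise TableError("annotation table has duplicate protein ids")
    df = df.set_index("protein_id")
    for col in ("prior_localized", "in_importome"):
        if col in df.columns:
            df[col] = (
                df[col].astype(str).str.strip().str.lower().isin(("1", "true", "+", "yes"))
            )
        else:
            df[col] = False
    if "targeting_prob" in df.columns:
        tp = pd.to_numeric(df["targeting_prob"], errors="coerce")
        bad = tp.dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise TableError("targeting_prob values must lie in [0, 1]")
        df["targeting_prob"] = tp
    else:
        df["targeting_prob"] = np.nan
    return df


# ---------------------------------------------------------------------------
# call reports
# ---------------------------------------------------------------------------

def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "+" if v else ""
    if isinstance(v, float):
        if math.isnan(v):
            return "-"  # enrichment could not be calculated
        if math.isinf(v):
            return "inf"
        return f"{v:.6g}"
    return str(v)


def write_calls(
    calls,
    path,
    annotation: pd.DataFrame | None = None,
    strong_threshold: float = 100.0,
) -> None:
    """Write interactor or proteome calls as a deterministic TSV report.

    Column order is fixed by the first call's ``report_row`` keys.  For
    interactor rows the ``strong`` column is (re)computed here: a call is
    strong when it is exclusive or mean-enriched more than
    ``strong_threshold`` (default 100x, the highlight convention).  An empty
    call list yields a header-only file with the generic columns.
    """
    rows = []
    for call in calls:
        row = call.report_row()
        if "mean_fc" in row and "status" in row:
            row["strong"] = row["status"] != "rejected" and (
                row["status"] == "exclusive" or row["mean_fc"] > strong_threshold
            )
        if annotation is not None:
            pid = row["protein_id"]
            if pid in annotation.index:
                ann = annotation.loc[pid]
                row["prior_localized"] = bool(ann["prior_localized"])
                row["in_importome"] = bool(ann["in_importome"])
                row["targeting_prob"] = float(ann["targeting_prob"])
            else:
                row["prior_localized"] = False
                row["in_importome"] = False
                row["targeting_prob"] = float("nan")
        rows.append(row)

    if rows:
        columns = list(rows[0].keys())
    else:
        columns = ["protein_id", "status", "strong"]
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c)) for c in columns) + "\n")


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
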