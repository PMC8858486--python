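"""Readers and writers for 3D genome models, feature annotations, regulon
tables, gene lists and result tables.

Conventions
-----------
* The 3D model is a delimited text table with one anchor point per row:
  chromosome, genomic position (bp), x, y, z.  Column order, separator and
  header handling are configurable through :class:`ModelDialect` because
  published model tables differ in layout.
* Feature annotations are read from GFF3 (1-based inclusive, kept as is)
  or BED (0-based half-open, converted to 1-based inclusive on read).
* Regulon tables are TSV with columns ``tf``, ``target``, ``evidence``;
  evidence strings are mapped case-insensitively onto the three canonical
  classes ``binding`` / ``expression`` / ``both``.
* Feature and target identifiers are matched exactly after uppercasing,
  so all readers normalise identifiers to uppercase.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, ParseError, ValidationError

EVIDENCE_CLASSES = ("binding", "expression", "both")

#: Default case-insensitive evidence synonyms; extend via the
#: ``synonyms`` argument of :func:`read_regulons`.
DEFAULT_EVIDENCE_SYNONYMS = {
    "binding": "binding",
    "binding evidence": "binding",
    "dna binding": "binding",
    "expression": "expression",
    "expression evidence": "expression",
    "both": "both",
    "binding and expression": "both",
    "binding & expression": "both",
}


# ---------------------------------------------------------------------------
# 3D model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelDialect:
    """Layout of a 3D model table.

    ``order`` gives the positional indices of (chromosome, position, x, y, z)
    when the file has no usable header; ``names`` overrides it with column
    names when a header is present.  ``header`` may be True, False or None
    (auto-detect: the first row is a header if its position/coordinate
    fields are not numeric).
    """

    order: tuple[int, int, int, int, int] = (0, 1, 2, 3, 4)
    names: tuple[str, str, str, str, str] | None = None
    sep: str = "\t"
    header: bool | None = None


@dataclass
class Model3D:
    """Per-chromosome ordered anchor points of a 3D genome model.

    ``anchors`` has columns (chromosome, position, x, y, z), sorted by
    chromosome then position, with strictly increasing positions within each
    chromosome.  ``report`` records what validation did to the raw file.
    """

    anchors: pd.DataFrame
    report: dict = field(default_factory=dict)

    def __post_init__(self):
        self._paths: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.anchors["chromosome"]))

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def path(self, chromosome: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (positions, coords) for one chromosome: a (k,) int array of
        bp positions and a (k, 3) float array of x,y,z."""
        if chromosome not in self._paths:
            sub = self.anchors[self.anchors["chromosome"] == chromosome]
            if sub.empty:
                raise KeyError(chromosome)
            self._paths[chromosome] = (
                sub["position"].to_numpy(dtype=np.int64),
                sub[["x", "y", "z"]].to_numpy(dtype=np.float64),
            )
        return self._paths[chromosome]

    def validate(self) -> None:
        for chrom in self.chromosomes:
            pos, xyz = self.path(chrom)
            if len(pos) < 2:
                raise ValidationError(
                    f"chromosome {chrom!r} has {len(pos)} anchor(s); >= 2 required"
                )
            if not np.all(np.diff(pos) > 0):
                raise ValidationError(
                    f"anchor positions on chromosome {chrom!r} are not strictly increasing"
                )
            if not np.all(np.isfinite(xyz)):
                raise ValidationError(
                    f"non-finite coordinates on chromosome {chrom!r}"
                )


def read_model3d(path: str | Path, dialect: ModelDialect | None = None) -> Model3D:
    """Read a 3D model table.

    Rows are grouped by chromosome and sorted by genomic position; duplicate
    (chromosome, position) rows are collapsed by averaging their coordinates.
    The returned model carries a validation report (rows read, rows collapsed,
    chromosomes found).
    """
    dialect = dialect or ModelDialect()
    try:
        raw = pd.read_csv(path, sep=dialect.sep, header=None, comment="#",
                          dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty model file") from None

    has_header = dialect.header
    if dialect.names is not None:
        has_header = True

    if has_header is None:
        first = raw.iloc[0]
        numeric_cols = dialect.order[1:]
        try:
            for c in numeric_cols:
                float(first.iloc[c])
            has_header = False
        except (ValueError, IndexError):
            has_header = True

    if has_header:
        header = [str(v) for v in raw.iloc[0]]
        raw = raw.iloc[1:].reset_index(drop=True)
        if dialect.names is not None:
            try:
                cols = [header.index(n) for n in dialect.names]
            except ValueError as exc:
                raise FormatError(f"{path}: missing column: {exc}") from None
        else:
            cols = list(dialect.order)
    else:
        cols = list(dialect.order)

    if raw.shape[1] <= max(cols):
        raise FormatError(
            f"{path}: expected at least {max(cols) + 1} columns, found {raw.shape[1]}"
        )

    df = raw.iloc[:, cols].copy()
    df.columns = ["chromosome", "position", "x", "y", "z"]
    rows_read = len(df)

    for col in ("position", "x", "y", "z"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col!r}",
                line=row + 1 + int(has_header),
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ParseError(f"{path}: missing value in column {col!r}",
                             line=row + 1 + int(has_header))
        df[col] = converted
    if not np.all(np.isfinite(df[["x", "y", "z"]].to_numpy(dtype=float))):
        raise ValidationError(f"{path}: non-finite coordinate value")

    df["position"] = df["position"].astype(np.int64)
    # collapse duplicate (chromosome, position) anchors by averaging; this is
    # deterministic and independent of row order
    grouped = (
        df.groupby(["chromosome", "position"], as_index=False, sort=True)
        .mean(numeric_only=True)
    )
    rows_collapsed = rows_read - len(grouped)
    grouped = grouped.sort_values(["chromosome", "position"], kind="mergesort")
    grouped = grouped[["chromosome", "position", "x", "y", "z"]].reset_index(drop=True)

    model = Model3D(
        anchors=grouped,
        report={
            "rows_read": rows_read,
            "rows_collapsed": rows_collapsed,
            "chromosomes": sorted(grouped["chromosome"].unique().tolist()),
        },
    )
    model.validate()
    return model


def write_model3d(model: Model3D, path: str | Path, dialect: ModelDialect | None = None) -> None:
    """Write a model in the default dialect (tab-separated, with header)."""
    sep = (dialect or ModelDialect()).sep
    model.anchors.to_csv(path, sep=sep, index=False,
                         columns=["chromosome", "position", "x", "y", "z"])


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Genomic features to place on the model.

    ``records`` has columns (feature_id, chromosome, start, end,
    feature_class, strand); coordinates are 1-based inclusive; feature ids
    are uppercased and unique.  Strand is carried but never used for
    placement.
    """

    records: pd.DataFrame
    report: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.records.copy()
        df["feature_id"] = df["feature_id"].astype(str).str.upper()
        dup = df["feature_id"].duplicated()
        n_dup = int(dup.sum())
        if n_dup:
            df = df[~dup]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["end"] < df["start"]).any():
            bad = df[df["end"] < df["start"]].iloc[0]
            raise ValidationError(
                f"feature {bad['feature_id']}: end ({bad['end']}) < start ({bad['start']})"
            )
        self.records = df.reset_index(drop=True)
        self.report = dict(self.report)
        self.report.setdefault("duplicate_ids_dropped", n_dup)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return self.records["feature_id"].tolist()


def _read_features_gff3(path: str | Path, feature_class: str | Sequence[str] | None):
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    keep = None
    if feature_class is not None:
        keep = {feature_class} if isinstance(feature_class, str) else set(feature_class)
    rows = []
    for f in db.all_features():
        if keep is not None and f.featuretype not in keep:
            continue
        fid = (f.attributes.get("ID") or f.attributes.get("Name")
               or f.attributes.get("gene_id") or [f.id])[0]
        rows.append((fid, f.seqid, f.start, f.end, f.featuretype, f.strand or "."))
    return rows


def _read_features_bed(path: str | Path, feature_class):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: BED line needs >= 4 fields", line=lineno)
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}: non-integer BED coordinate", line=lineno) from None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            # BED is 0-based half-open; internal convention is 1-based inclusive
            rows.append((name, chrom, start_i + 1, end_i,
                         feature_class if isinstance(feature_class, str) else "region",
                         strand))
    return rows


def read_features(path: str | Path, format: str = "gff3",
                  feature_class: str | Sequence[str] | None = None) -> FeatureTable:
    """Read features from GFF3 or BED into a unified 1-based inclusive table.

    ``feature_class`` filters GFF3 records by type (e.g. ``"gene"``); for BED
    it only labels the records (BED carries no type column).
    """
    fmt = format.lower()
    if fmt == "gff3":
        rows = _read_features_gff3(path, feature_class)
    elif fmt == "bed":
        rows = _read_features_bed(path, feature_class)
    else:
        raise FormatError(f"unknown feature format: {format!r}")
    if not rows:
        raise FormatError(f"{path}: no usable feature records")
    df = pd.DataFrame(rows, columns=["feature_id", "chromosome", "start",
                                     "end", "feature_class", "strand"])
    return FeatureTable(records=df, report={"format": fmt, "rows_read": len(rows)})


def write_features_gff3(features: FeatureTable, path: str | Path,
                        source: str = "coloc3d") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in features.records.itertuples(index=False):
            fh.write(
                f"{rec.chromosome}\t{source}\t{rec.feature_class}\t{rec.start}\t"
                f"{rec.end}\t.\t{rec.strand}\t.\tID={rec.feature_id}\n"
            )


# ---------------------------------------------------------------------------
# Regulons and gene lists
# ---------------------------------------------------------------------------

@dataclass
class RegulonSet:
    """TF -> target associations with an evidence class.

    ``records`` has columns (tf, target, evidence) with evidence one of
    ``binding`` / ``expression`` / ``both``; (tf, target, evidence) triples
    are unique.  ``rejects`` collects rows whose evidence string could not
    be mapped.
    """

    records: pd.DataFrame
    rejects: pd.DataFrame | None = None
    report: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.records.copy()
        df["tf"] = df["tf"].astype(str).str.upper()
        df["target"] = df["target"].astype(str).str.upper()
        bad = ~df["evidence"].isin(EVIDENCE_CLASSES)
        if bad.any():
            raise ValidationError(
                f"unknown evidence class {df['evidence'][bad].iloc[0]!r}"
            )
        df = df.drop_duplicates(["tf", "target", "evidence"]).reset_index(drop=True)
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def tfs(self) -> list[str]:
        return sorted(self.records["tf"].unique().tolist())

    def targets_of(self, tf: str) -> list[str]:
        sub = self.records[self.records["tf"] == tf.upper()]
        return sorted(sub["target"].unique().tolist())

    def summary(self) -> dict:
        return {
            "n_tfs": int(self.records["tf"].nunique()),
            "n_targets": int(self.records["target"].nunique()),
            "n_associations": int(len(self.records.drop_duplicates(["tf", "target"]))),
        }


def read_regulons(path: str | Path, synonyms: dict[str, str] | None = None) -> RegulonSet:
    """Read a TF/target/evidence TSV into a deduplicated :class:`RegulonSet`.

    Evidence strings are matched case-insensitively against the synonym
    table; rows with unknown evidence go into the ``rejects`` frame rather
    than being silently dropped.
    """
    syn = dict(DEFAULT_EVIDENCE_SYNONYMS)
    if synonyms:
        syn.update({k.lower(): v for k, v in synonyms.items()})
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no parsable rows") from None
    lower = {c.lower(): c for c in df.columns}
    if not {"tf", "target", "evidence"} <= set(lower):
        # headerless fallback: assume (tf, target, evidence) column order
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, header=None)
        if df.shape[1] < 3:
            raise FormatError(f"{path}: expected columns tf, target, evidence")
        df = df.iloc[:, :3]
        df.columns = ["tf", "target", "evidence"]
    else:
        df = df.rename(columns={lower["tf"]: "tf", lower["target"]: "target",
                                lower["evidence"]: "evidence"})
        df = df[["tf", "target", "evidence"]]
    df = df.dropna(subset=["tf", "target", "evidence"])
    if df.empty:
        raise FormatError(f"{path}: no parsable rows")
    mapped = df["evidence"].astype(str).str.strip().str.lower().map(syn)
    rejects = df[mapped.isna()].copy()
    kept = df[mapped.notna()].copy()
    kept["evidence"] = mapped[mapped.notna()]
    if kept.empty:
        raise FormatError(f"{path}: no rows with a recognised evidence class")
    return RegulonSet(
        records=kept.reset_index(drop=True),
        rejects=rejects.reset_index(drop=True) if len(rejects) else None,
        report={"rows_read": len(df), "rows_rejected": int(len(rejects))},
    )


def write_regulons(regulons: RegulonSet, path: str | Path) -> None:
    regulons.records.to_csv(path, sep="\t", index=False,
                            columns=["tf", "target", "evidence"])


def filter_regulons_by_evidence(regulons: RegulonSet,
                                keep: Iterable[str]) -> RegulonSet:
    """Keep only associations whose evidence class is in ``keep``.

    The result's report states the distinct TF count, distinct target count
    and association count of the filtered set (the quantities usually quoted
    when an evidence filter is applied).
    """
    keep = {k.lower() for k in keep}
    if not keep:
        raise ParameterError("keep must name at least one evidence class")
    unknown = keep - set(EVIDENCE_CLASSES)
    if unknown:
        raise ParameterError(f"unknown evidence class(es): {sorted(unknown)}")
    sub = regulons.records[regulons.records["evidence"].isin(keep)]
    result = RegulonSet(records=sub.reset_index(drop=True))
    result.report = result.summary()
    return result


@dataclass
class GeneList:
    """An ordered, duplicate-free list of feature identifiers."""

    ids: list[str]
    label: str = "genes"

    def __post_init__(self):
        seen: dict[str, None] = {}
        for g in self.ids:
            seen.setdefault(str(g).upper())
        if not seen:
            raise ValidationError("gene list is empty")
        self.ids = list(seen)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)


def read_gene_list(path: str | Path, label: str | None = None) -> GeneList:
    """Read one identifier per line; '#' starts a comment."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    if not ids:
        raise FormatError(f"{path}: empty gene list")
    return GeneList(ids=ids, label=label or Path(path).stem)


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["tf", "n_targets", "n_pairs", "ks", "pval", "pval_adjusted",
                  "direction"]


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a per-module result table as TSV with the canonical columns."""
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise FormatError(f"result table missing columns: {missing}")
    results.to_csv(path, sep="\t", index=False, columns=RESULT_COLUMNS,
                   float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
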