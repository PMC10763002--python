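"""Readers and writers for all on-disk pipeline artifacts.

On-disk dialect: UTF-8 TSV with a header row; list-valued cells (a case's
drugs or adverse-event terms, a drug's target genes) are pipe-delimited
within the cell. Gene sets use the standard GMT format. This fixes a single
contract for inputs whose real-world dumps (spontaneous-report extracts,
drug-annotation exports) vary widely in layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

CASE_COLUMNS = ["case_id", "report_date", "sex", "country", "qualification",
                "drugs", "events"]

# accepted raw sex codes -> normalized; FAERS-style numeric codes 1=male 2=female
SEX_CODES = {"m": "male", "male": "male", "1": "male",
             "f": "female", "female": "female", "2": "female"}


class SchemaError(ValueError):
    """An input file does not match its declared schema."""


def normalize_sex(raw: object) -> str:
    return SEX_CODES.get(str(raw).strip().lower(), "unknown")


def _split_cell(cell: object) -> frozenset:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    items = [t.strip() for t in str(cell).split("|")]
    return frozenset(t for t in items if t)


def _join_cell(items) -> str:
    return "|".join(sorted(items))


def _require_columns(df: pd.DataFrame, required: list, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# case reports
# ---------------------------------------------------------------------------

def read_case_table(path) -> pd.DataFrame:
    """Read a case-report table (one row per spontaneous report).

    Returns a DataFrame with normalized sex codes, parsed ISO dates
    (unparseable -> NaT, logged) and frozenset-valued `drugs`/`events`
    columns. Rows with empty drug or event lists are retained here and
    removed by the filter stage.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, CASE_COLUMNS, path)
    df = df[CASE_COLUMNS].copy()
    df["sex"] = df["sex"].map(normalize_sex)
    dates = pd.to_datetime(df["report_date"], format="ISO8601", errors="coerce")
    n_bad = int(dates.isna().sum() - df["report_date"].isna().sum())
    if n_bad:
        log.warning("%s: %d unparseable report dates set to unknown", path, n_bad)
    df["report_date"] = dates
    df["drugs"] = df["drugs"].map(_split_cell)
    df["events"] = df["events"].map(_split_cell)
    df["qualification"] = df["qualification"].fillna("").str.strip()
    log.info("%s: read %d case reports", path, len(df))
    return df


def write_case_table(cases: pd.DataFrame, path) -> None:
    out = cases.copy()
    out["drugs"] = out["drugs"].map(_join_cell)
    out["events"] = out["events"].map(_join_cell)
    out["report_date"] = pd.to_datetime(out["report_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# adverse-event term hierarchy
# ---------------------------------------------------------------------------

@dataclass
class TermHierarchy:
    """Lower-level term -> preferred term -> system-organ class mappings."""

    lower_to_preferred: dict
    preferred_to_soc: dict  # preferred term -> set of organ-class terms

    def __post_init__(self) -> None:
        for pt, socs in self.preferred_to_soc.items():
            if not socs:
                raise SchemaError(f"preferred term {pt!r} has no organ class")


def read_term_hierarchy(path) -> TermHierarchy:
    """TSV columns: lower_level_term, preferred_term, system_organ_class."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["lower_level_term", "preferred_term",
                          "system_organ_class"], path)
    lower = {}
    for llt, pt in zip(df["lower_level_term"], df["preferred_term"]):
        if llt in lower and lower[llt] != pt:
            raise SchemaError(
                f"{path}: lower-level term {llt!r} maps to multiple preferred terms")
        lower[llt] = pt
    soc: dict = {}
    for pt, s in zip(df["preferred_term"], df["system_organ_class"]):
        soc.setdefault(pt, set()).add(s)
    return TermHierarchy(lower_to_preferred=lower, preferred_to_soc=soc)


def write_term_hierarchy(h: TermHierarchy, path) -> None:
    rows = []
    for llt, pt in sorted(h.lower_to_preferred.items()):
        for s in sorted(h.preferred_to_soc.get(pt, {"unspecified"})):
            rows.append((llt, pt, s))
    pd.DataFrame(rows, columns=["lower_level_term", "preferred_term",
                                "system_organ_class"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# drug annotations
# ---------------------------------------------------------------------------

ANNOTATION_FIELDS = ["targets", "enzymes", "transporters", "carriers"]


def read_drug_annotations(path) -> dict:
    """TSV columns: drug_id, targets, enzymes[, transporters, carriers].

    Returns drug id -> {field: frozenset of gene symbols}.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["drug_id", "targets", "enzymes"], path)
    if df["drug_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate drug ids")
    table = {}
    for _, row in df.iterrows():
        table[row["drug_id"]] = {
            f: _split_cell(row[f]) if f in df.columns else frozenset()
            for f in ANNOTATION_FIELDS
        }
    return table


def write_drug_annotations(annotations: dict, path) -> None:
    rows = [
        {"drug_id": d, **{f: _join_cell(fields.get(f, ())) for f in ANNOTATION_FIELDS}}
        for d, fields in sorted(annotations.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions."""

    sets: dict = field(default_factory=dict)  # name -> set of genes
    descriptions: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> set:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Standard GMT: name TAB description TAB gene TAB gene ..."""
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields_ = line.split("\t")
            if len(fields_) < 3:
                raise SchemaError(f"{path}:{i}: GMT line has < 3 fields")
            name, desc = fields_[0], fields_[1]
            if name in coll.sets:
                raise SchemaError(f"{path}:{i}: duplicate gene-set name {name!r}")
            genes = {g for g in fields_[2:] if g}
            coll.sets[name] = genes
            coll.descriptions[name] = desc
    if not coll.sets:
        log.warning("%s: empty GMT file", path)
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in coll.sets:
            genes = sorted(coll.sets[name])
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path) -> pd.DataFrame:
    """TSV columns: source, target, weight. Empty weight -> 1.0 (prior edges
    are presence/absence), logged."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    _require_columns(df, ["source", "target", "weight"], path)
    if df["weight"].isna().any():
        log.warning("%s: %d empty weights set to 1.0", path,
                    int(df["weight"].isna().sum()))
        df["weight"] = df["weight"].fillna(1.0)
    try:
        df["weight"] = df["weight"].astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric weight: {exc}") from exc
    if not np.isfinite(df["weight"]).all():
        raise SchemaError(f"{path}: non-finite weights")
    if df.duplicated(["source", "target"]).any():
        raise SchemaError(f"{path}: duplicate (source, target) pairs")
    return df.reset_index(drop=True)


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.12g")


def rescale_interaction_scores(edges: pd.DataFrame, divisor: float = 1000.0,
                               threshold: float = 0.7) -> pd.DataFrame:
    """Rescale raw interaction scores and keep high-confidence edges.

    Scores are divided by `divisor` and rows with rescaled weight <=
    `threshold` are removed (strict >), matching the convention of dividing
    0-1000 confidence scores by 1000 and keeping interactions above 0.7.
    """
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    if (edges["weight"] < 0).any():
        raise ValueError("interaction scores must be non-negative")
    out = edges.copy()
    out["weight"] = out["weight"] / divisor
    return out[out["weight"] > threshold].reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression data
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ["sample_id", "subject_id", "sex", "tissue", "rin",
                  "ischemic_time", "age"]


@dataclass
class ExpressionData:
    """Gene x sample count matrix plus per-sample metadata."""

    counts: pd.DataFrame           # genes as rows, samples as columns
    samples: pd.DataFrame          # indexed by sample_id

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise SchemaError("count columns and sample metadata are misaligned")
        if (self.counts.values < 0).any():
            raise SchemaError("negative counts")
        if self.counts.index.duplicated().any():
            raise SchemaError("duplicate gene ids")

    def subset(self, sample_ids) -> "ExpressionData":
        sample_ids = list(sample_ids)
        return ExpressionData(self.counts[sample_ids],
                              self.samples.loc[sample_ids])


def read_expression(counts_path, metadata_path) -> ExpressionData:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str,
                                                       "subject_id": str})
    _require_columns(meta, SAMPLE_COLUMNS, metadata_path)
    meta = meta.set_index("sample_id")
    meta["sex"] = meta["sex"].map(normalize_sex)
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise SchemaError(f"{metadata_path}: no metadata for samples {missing[:5]}")
    return ExpressionData(counts=counts, samples=meta.loc[counts.columns])


def write_expression(data: ExpressionData, counts_path, metadata_path) -> None:
    data.counts.to_csv(counts_path, sep="\t", float_format="%.12g")
    data.samples.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# matrices and config
# ---------------------------------------------------------------------------

def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", float_format="%.12g")


def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
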