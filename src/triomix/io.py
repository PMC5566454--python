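"""Data model and file readers/writers.

All tabular formats are plain text: TSV matrices (first column = feature
ids, header row = sample ids, ``NA`` as the missing token), a CSV sample
sheet, BED-like gene models with an extra exonic-length column, and GMT
gene-set collections. Coordinates follow the BED convention: 0-based,
half-open intervals; probe positions are single-base 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATUSES = ("intact", "degraded")
COHORTS = ("discovery", "replication_knee", "replication_hip")
PROBE_FEATURES = ("TSS200", "TSS1500", "5UTR", "1stExon", "Body", "3UTR", "intergenic")

__all__ = [
    "SampleSheet",
    "GeneSetCollection",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_matrix",
    "write_matrix",
    "read_probe_manifest",
    "write_probe_manifest",
    "read_gene_models",
    "write_gene_models",
    "read_gmt",
    "write_gmt",
]


@dataclass
class SampleSheet:
    """Pairing of each patient's intact and degraded sample.

    Wraps a DataFrame with columns ``sample_id``, ``patient_id``,
    ``status`` (intact/degraded) and ``cohort``. Within each cohort every
    patient has exactly one sample of each status.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "patient_id", "status", "cohort"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        bad_status = set(t["status"]) - set(STATUSES)
        if bad_status:
            raise ValueError(f"unknown status values: {sorted(bad_status)}")
        bad_cohort = set(t["cohort"]) - set(COHORTS)
        if bad_cohort:
            raise ValueError(f"unknown cohort values: {sorted(bad_cohort)}")
        for (cohort, patient), grp in t.groupby(["cohort", "patient_id"]):
            counts = grp["status"].value_counts()
            if counts.get("intact", 0) != 1 or counts.get("degraded", 0) != 1:
                raise ValueError(
                    f"patient {patient!r} in cohort {cohort!r} must have exactly "
                    "one intact and one degraded sample"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def pairs(self, cohort: str | None = None) -> pd.DataFrame:
        """One row per patient with ``intact`` and ``degraded`` sample ids."""
        t = self.table
        if cohort is not None:
            t = t[t["cohort"] == cohort]
        wide = t.pivot(index="patient_id", columns="status", values="sample_id")
        return wide[["intact", "degraded"]].reset_index()

    def n_patients(self, cohort: str | None = None) -> int:
        return len(self.pairs(cohort))


@dataclass
class GeneSetCollection:
    """Ordered, named gene sets (KEGG/Reactome/GO-style), read from GMT."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def restricted(self, universe: set[str], min_size: int = 1) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets below ``min_size``.

        Genes outside the universe are ignored with a logged count.
        """
        out: dict[str, frozenset[str]] = {}
        n_dropped_genes = 0
        n_dropped_sets = 0
        for name, genes in self.sets.items():
            kept = frozenset(genes & universe)
            n_dropped_genes += len(genes) - len(kept)
            if len(kept) >= min_size:
                out[name] = kept
            else:
                n_dropped_sets += 1
        if n_dropped_genes or n_dropped_sets:
            logger.info(
                "restricted gene sets to universe: %d genes outside universe, "
                "%d sets below size %d dropped",
                n_dropped_genes, n_dropped_sets, min_size,
            )
        return GeneSetCollection(out, self.source)


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, dtype=str))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, index=False)


def _check_beta(values: pd.DataFrame) -> None:
    arr = values.to_numpy(dtype=float)
    bad = (arr < 0) | (arr > 1) | np.isnan(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"beta value out of [0,1] (or missing) at probe "
            f"{values.index[i]!r}, sample {values.columns[j]!r}: {arr[i, j]!r}"
        )


def _check_counts(values: pd.DataFrame) -> None:
    arr = values.to_numpy(dtype=float)
    bad = np.isnan(arr) | (arr < 0) | (arr != np.floor(arr))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"count must be a non-negative integer at gene "
            f"{values.index[i]!r}, sample {values.columns[j]!r}: {arr[i, j]!r}"
        )


def _check_protein(values: pd.DataFrame) -> None:
    arr = values.to_numpy(dtype=float)
    bad = ~np.isnan(arr) & (arr <= 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"protein abundance must be positive where present at "
            f"{values.index[i]!r}, sample {values.columns[j]!r}: {arr[i, j]!r}"
        )


_VALIDATORS = {"beta": _check_beta, "counts": _check_counts, "protein": _check_protein}


def validate_matrix(values: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Enforce the per-layer matrix invariants; returns the matrix."""
    if kind not in _VALIDATORS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r}")
    _VALIDATORS[kind](values)
    if kind == "counts":
        return values.astype(np.int64)
    return values.astype(float)


def read_matrix(path, kind: str) -> pd.DataFrame:
    """Read a features-by-samples TSV matrix of the given kind.

    ``kind`` is one of ``beta`` (values in [0,1], complete), ``counts``
    (non-negative integers, complete) or ``protein`` (positive, ``NA``
    allowed). The returned DataFrame is indexed by feature id.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    return validate_matrix(df, kind)


def write_matrix(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", na_rep="NA")


_MANIFEST_COLS = ["probe_id", "chrom", "pos", "gene", "feature"]


def read_probe_manifest(path) -> pd.DataFrame:
    """Probe manifest TSV: probe_id, chrom, pos (0-based), gene, feature."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "gene": str},
                     na_values=[], keep_default_na=False)
    missing = [c for c in _MANIFEST_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"probe manifest missing columns: {missing}")
    return validate_probe_manifest(df)


def validate_probe_manifest(df: pd.DataFrame) -> pd.DataFrame:
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id {dup!r}")
    if len(df) and (df["pos"].astype(int) < 0).any():
        raise ValueError("probe positions must be >= 0")
    bad = set(df["feature"]) - set(PROBE_FEATURES)
    if bad:
        raise ValueError(f"unknown probe feature annotations: {sorted(bad)}")
    return df


def write_probe_manifest(df: pd.DataFrame, path) -> None:
    df[_MANIFEST_COLS].to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> pd.DataFrame:
    """Gene models as 6-column BED plus a summed exonic length column.

    Columns: chrom, start, end (0-based half-open), gene_id, score
    (ignored), strand, length.
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand", "length"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    return validate_gene_models(df)


def validate_gene_models(df: pd.DataFrame) -> pd.DataFrame:
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    if len(df) and not (df["start"] < df["end"]).all():
        bad = df.loc[~(df["start"] < df["end"]), "gene_id"].iloc[0]
        raise ValueError(f"gene {bad!r} has start >= end")
    if len(df) and not (df["length"] > 0).all():
        bad = df.loc[~(df["length"] > 0), "gene_id"].iloc[0]
        raise ValueError(f"gene {bad!r} has non-positive length")
    if len(df) and not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    return df


def write_gene_models(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "score" not in out.columns:
        out["score"] = 0
    out[["chrom", "start", "end", "gene_id", "score", "strand", "length"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_gmt(path, source: str = "") -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, tab-separated genes.

    Duplicate genes within a set are de-duplicated (logged); sets with no
    genes are skipped with a warning; a duplicated set name is an error.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed GMT line")
            name = parts[0]
            genes = [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            if not genes:
                logger.warning("%s:%d: gene set %r is empty, skipped", path, lineno, name)
                continue
            uniq = frozenset(genes)
            if len(uniq) < len(genes):
                logger.warning(
                    "%s:%d: %d duplicate genes de-duplicated in set %r",
                    path, lineno, len(genes) - len(uniq), name,
                )
            sets[name] = uniq
    return GeneSetCollection(sets, source)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, collection.source or "na", *sorted(genes)]) + "\n")
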