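"""Cohort ingestion and age-indexed multimorbidity network construction.

A cohort is a long-form table of (patient, disease, onset age) records.  Two
diseases are linked at age ``t`` when at least one patient carries both by
that age, which yields one undirected graph snapshot per year of age over a
fixed node universe (the disease catalog).  The model consumes the binary
adjacency; patient co-occurrence counts are kept as edge weights for reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_PATIENT_COLS = ("patient_id", "patient", "pid")
_DISEASE_COLS = ("disease", "disease_id", "disease_name")
_AGE_COLS = ("onset_age", "age")


class CohortFormatError(ValueError):
    """The cohort file is missing a required column."""


class CatalogError(ValueError):
    """Disease identifiers or names do not match the catalog."""


@dataclass(frozen=True)
class DiseaseCatalog:
    """Ordered disease universe; ids are implicit positions 0..n-1.

    The catalog fixes the node set of every snapshot: diseases that have no
    comorbid partner at early ages stay as isolated nodes so that adjacency
    matrices are conformable across the whole age axis.
    """

    names: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise CatalogError("disease names must be unique")
        if not self.names:
            raise CatalogError("catalog is empty")

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise CatalogError(f"unknown disease name: {name!r}") from None

    def content_hash(self) -> str:
        return hashlib.sha1("\n".join(self.names).encode()).hexdigest()[:12]

    @classmethod
    def from_csv(cls, path) -> "DiseaseCatalog":
        df = pd.read_csv(path, sep=None, engine="python")
        cols = {c.lower(): c for c in df.columns}
        if "id" not in cols or "name" not in cols:
            raise CohortFormatError("catalog file must have columns 'id' and 'name'")
        df = df.sort_values(cols["id"])
        ids = df[cols["id"]].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise CatalogError("catalog ids must be contiguous 0..n-1")
        return cls(tuple(str(x) for x in df[cols["name"]]))

    def to_csv(self, path) -> None:
        pd.DataFrame({"id": range(self.n), "name": self.names}).to_csv(path, index=False)


@dataclass
class CohortTable:
    """Filtered long-form (patient_id, disease_id, onset_age) records."""

    records: list[tuple[str, int, int]]
    n_dropped_records_age: int = 0
    n_dropped_patients_single: int = 0

    @property
    def n_records(self) -> int:
        return len(self.records)

    def patients(self) -> dict[str, dict[int, int]]:
        """patient -> {disease_id: onset_age}, earliest onset wins."""
        out: dict[str, dict[int, int]] = {}
        for pid, did, age in self.records:
            seen = out.setdefault(pid, {})
            if did not in seen or age < seen[did]:
                seen[did] = age
        return out

    @property
    def n_patients(self) -> int:
        return len({pid for pid, _, _ in self.records})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["patient_id", "disease_id", "onset_age"])


@dataclass(frozen=True)
class GraphSnapshot:
    """One age's comorbidity graph: binary adjacency + patient-count weights."""

    age: int
    adjacency: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        a, w = self.adjacency, self.weights
        if a.shape != w.shape or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency and weights must be square and congruent")
        if not np.array_equal(a, a.T) or not np.array_equal(w, w.T):
            raise ValueError(f"snapshot at age {self.age} is not symmetric")
        if np.any(np.diag(a)) or np.any(np.diag(w)):
            raise ValueError(f"snapshot at age {self.age} has nonzero diagonal")
        if not np.array_equal(a, (w >= 1).astype(a.dtype)):
            raise ValueError("adjacency must equal (weights >= 1)")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return set(zip(i.tolist(), j.tolist()))


@dataclass
class SnapshotSequence:
    """Ordered yearly snapshots covering [age_min, age_max]."""

    snapshots: list[GraphSnapshot]
    age_min: int
    age_max: int
    mode: str = "cumulative"

    def __post_init__(self):
        ages = [s.age for s in self.snapshots]
        if ages != list(range(self.age_min, self.age_max + 1)):
            raise ValueError("snapshot ages must be consecutive and cover [age_min, age_max]")

    @property
    def ages(self) -> list[int]:
        return [s.age for s in self.snapshots]

    @property
    def n_nodes(self) -> int:
        return self.snapshots[0].n_nodes

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def snapshot_at(self, age: int) -> GraphSnapshot:
        if not self.age_min <= age <= self.age_max:
            raise KeyError(f"age {age} outside [{self.age_min}, {self.age_max}]")
        return self.snapshots[age - self.age_min]

    # -- plain-text round-trip -------------------------------------------
    def to_dir(self, path, catalog: DiseaseCatalog | None = None) -> None:
        """Write one edge-list TSV per age plus a JSON manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for snap in self.snapshots:
            i, j = np.nonzero(np.triu(snap.weights, k=1))
            df = pd.DataFrame({"src_id": i, "dst_id": j,
                               "weight": snap.weights[i, j].astype(int)})
            df.to_csv(path / f"age_{snap.age}.tsv", sep="\t", index=False)
        manifest = {
            "age_min": self.age_min,
            "age_max": self.age_max,
            "mode": self.mode,
            "n_nodes": self.n_nodes,
            "catalog_hash": catalog.content_hash() if catalog else None,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def from_dir(cls, path) -> "SnapshotSequence":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        n = manifest["n_nodes"]
        snaps = []
        for age in range(manifest["age_min"], manifest["age_max"] + 1):
            df = pd.read_csv(path / f"age_{age}.tsv", sep="\t")
            w = np.zeros((n, n), dtype=np.int64)
            for src, dst, weight in df.itertuples(index=False):
                w[src, dst] = w[dst, src] = weight
            snaps.append(GraphSnapshot(age=age, adjacency=(w >= 1).astype(np.int64), weights=w))
        return cls(snaps, manifest["age_min"], manifest["age_max"], manifest["mode"])


def _resolve_column(df: pd.DataFrame, candidates: tuple[str, ...], what: str) -> str:
    lower = {c.lower(): c for c in df.columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    raise CohortFormatError(
        f"cohort file has no {what} column (expected one of {', '.join(candidates)})"
    )


def load_cohort(path, catalog: DiseaseCatalog, age_min: int = 45,
                age_max: int = 90) -> CohortTable:
    """Read a delimited cohort file, map diseases to catalog ids, and filter.

    Filtering drops records with onset outside [age_min, age_max] and then
    patients left with fewer than two distinct diseases (multimorbidity
    requires at least two).  An ``onset_age`` column is preferred; a plain
    ``age`` column is accepted and interpreted as the onset age of every
    disease record of that patient.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        logger.warning("cohort file %s has no records", path)
        return CohortTable(records=[])
    pcol = _resolve_column(df, _PATIENT_COLS, "patient id")
    dcol = _resolve_column(df, _DISEASE_COLS, "disease")
    acol = _resolve_column(df, _AGE_COLS, "onset age")
    if acol.lower() == "age":
        logger.info("no onset_age column; using 'age' as onset for all records")

    disease_vals = df[dcol]
    if pd.api.types.is_numeric_dtype(disease_vals):
        ids = disease_vals.astype(int)
        bad = sorted(set(ids[(ids < 0) | (ids >= catalog.n)]))
        if bad:
            raise CatalogError(f"disease ids outside catalog range: {bad}")
    else:
        unknown = sorted(set(disease_vals) - set(catalog.names))
        if unknown:
            raise CatalogError(f"unknown disease names: {unknown}")
        ids = disease_vals.map({name: i for i, name in enumerate(catalog.names)})

    ages = df[acol].astype(int)
    in_range = (ages >= age_min) & (ages <= age_max)
    n_dropped_age = int((~in_range).sum())

    records: dict[str, dict[int, int]] = {}
    for pid, did, age, ok in zip(df[pcol].astype(str), ids, ages, in_range):
        if not ok:
            continue
        seen = records.setdefault(pid, {})
        did = int(did)
        if did not in seen or age < seen[did]:
            seen[did] = int(age)

    multimorbid = {p: d for p, d in records.items() if len(d) >= 2}
    n_dropped_single = len(records) - len(multimorbid)
    flat = [(pid, did, age) for pid, dd in multimorbid.items() for did, age in sorted(dd.items())]
    logger.info("loaded %d records for %d patients (dropped %d out-of-range records, "
                "%d patients with <2 diseases)", len(flat), len(multimorbid),
                n_dropped_age, n_dropped_single)
    return CohortTable(records=flat, n_dropped_records_age=n_dropped_age,
                       n_dropped_patients_single=n_dropped_single)


def build_snapshots(cohort: CohortTable, catalog: DiseaseCatalog, age_min: int = 45,
                    age_max: int = 90, mode: str = "cumulative") -> SnapshotSequence:
    """Build the yearly snapshot sequence from a filtered cohort.

    cumulative: weight[i, j] at age t = number of patients with both onsets
    <= t (edges persist once formed).  incident: only pairs whose later onset
    equals t are counted at t.
    """
    if mode not in ("cumulative", "incident"):
        raise ValueError(f"mode must be 'cumulative' or 'incident', got {mode!r}")
    if age_min >= age_max:
        raise ValueError("age_min must be < age_max")
    n = catalog.n
    n_ages = age_max - age_min + 1
    incident = np.zeros((n_ages, n, n), dtype=np.int64)
    for dd in cohort.patients().values():
        items = sorted(dd.items())
        for a, (di, ai) in enumerate(items):
            for dj, aj in items[a + 1:]:
                pair_age = max(ai, aj)
                if age_min <= pair_age <= age_max:
                    incident[pair_age - age_min, di, dj] += 1
                    incident[pair_age - age_min, dj, di] += 1
    weights = np.cumsum(incident, axis=0) if mode == "cumulative" else incident
    snaps = [GraphSnapshot(age=age_min + k,
                           adjacency=(weights[k] >= 1).astype(np.int64),
                           weights=weights[k])
             for k in range(n_ages)]
    return SnapshotSequence(snaps, age_min, age_max, mode)


def prevalence_table(cohort: CohortTable, catalog: DiseaseCatalog) -> pd.DataFrame:
    """Per-disease patient counts and percent of cohort, sorted descending."""
    n_patients = cohort.n_patients
    if n_patients == 0:
        return pd.DataFrame(columns=["disease", "n_patients", "percent"])
    counts = np.zeros(catalog.n, dtype=np.int64)
    for dd in cohort.patients().values():
        for did in dd:
            counts[did] += 1
    df = pd.DataFrame({"disease": catalog.names, "n_patients": counts})
    df["percent"] = (100.0 * df["n_patients"] / n_patients).round(2)
    return (df.sort_values(["n_patients", "disease"], ascending=[False, True])
              .reset_index(drop=True))


def prevalence_from_counts(counts: dict[str, int], cohort_size: int) -> pd.DataFrame:
    """Recompute prevalence percentages from published per-disease counts."""
    df = pd.DataFrame({"disease": list(counts), "n_patients": list(counts.values())})
    df["percent"] = (100.0 * df["n_patients"] / cohort_size).round(2)
    return (df.sort_values(["n_patients", "disease"], ascending=[False, True])
              .reset_index(drop=True))
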