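"""Data model and file I/O shared by every analysis stage.

Count tables are always oriented samples x taxa. TSV files declare the
orientation through the first header cell (``sample_id`` when samples are in
rows, ``taxon_id`` when the file is transposed); BIOM-style JSON follows the
BIOM v1 convention of observations (taxa) in rows and is transposed on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
TREATMENTS = ("control", "drought")
TOLERANCE_CLASSES = ("tolerant", "sensitive", "bulk")

#: strings treated as "no annotation at this rank" in taxonomy input
UNANNOTATED_TOKENS = {"", "na", "nan", "none", "unclassified", "unassigned", "uncultured"}


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class CountTable:
    """Integer ASV counts, samples in rows and taxa in columns."""

    sample_ids: list
    taxon_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise ValueError(
                    "non-integer count at sample "
                    f"{self.sample_ids[bad[0]]!r}, taxon {self.taxon_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                "negative count at sample "
                f"{self.sample_ids[bad[0]]!r}, taxon {self.taxon_ids[bad[1]]!r}"
            )
        totals = counts.sum(axis=1)
        if np.any(totals == 0):
            empty = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise ValueError(f"samples with zero total counts: {empty}")
        self.counts = counts.astype(np.int64)

    @property
    def shape(self):
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def select_taxa(self, taxon_ids) -> "CountTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return CountTable(list(self.sample_ids), list(taxon_ids), self.counts[:, idx])

    def select_samples(self, sample_ids) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(sample_ids), list(self.taxon_ids), self.counts[idx, :])

    def __eq__(self, other):
        return (
            isinstance(other, CountTable)
            and self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class RelativeAbundanceTable:
    """Per-sample relative abundances; every row sums to one."""

    sample_ids: list
    taxon_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError("value matrix shape does not match ids")
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("relative abundances must lie in [0, 1]")
        if not np.allclose(values.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("relative abundance rows must sum to 1 within 1e-9")
        self.values = values

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def select_samples(self, sample_ids) -> "RelativeAbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return RelativeAbundanceTable(list(sample_ids), list(self.taxon_ids), self.values[idx, :])


@dataclass
class StudyDesign:
    """Per-sample factors: ecotype, treatment, tolerance class, replicate."""

    frame: pd.DataFrame

    REQUIRED = ("ecotype", "treatment", "tolerance_class", "replicate")

    def __post_init__(self):
        f = self.frame
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids in design: {dup}")
        missing = [c for c in self.REQUIRED if c not in f.columns]
        if missing:
            raise ValueError(f"design missing columns: {missing}")
        bad_treat = set(f["treatment"]) - set(TREATMENTS)
        if bad_treat:
            raise ValueError(f"unknown treatments: {sorted(bad_treat)}")
        bad_tol = set(f["tolerance_class"]) - set(TOLERANCE_CLASSES)
        if bad_tol:
            raise ValueError(f"unknown tolerance classes: {sorted(bad_tol)}")
        if (f["replicate"].astype(int) < 1).any():
            raise ValueError("replicate numbers must be >= 1")
        self.frame = f.copy()
        self.frame.index = self.frame.index.astype(str)
        self.frame["replicate"] = self.frame["replicate"].astype(int)

    @property
    def sample_ids(self):
        return list(self.frame.index)

    def samples_for(self, ecotype=None, treatment=None, tolerance_class=None):
        mask = pd.Series(True, index=self.frame.index)
        if ecotype is not None:
            mask &= self.frame["ecotype"] == ecotype
        if treatment is not None:
            mask &= self.frame["treatment"] == treatment
        if tolerance_class is not None:
            mask &= self.frame["tolerance_class"] == tolerance_class
        return list(self.frame.index[mask])

    def ecotypes(self, include_bulk=False):
        order = []
        for e, tol in zip(self.frame["ecotype"], self.frame["tolerance_class"]):
            if not include_bulk and tol == "bulk":
                continue
            if e not in order:
                order.append(e)
        return order

    def tolerance_of(self, ecotype: str) -> str:
        vals = set(self.frame.loc[self.frame["ecotype"] == ecotype, "tolerance_class"])
        if len(vals) != 1:
            raise ValueError(f"ecotype {ecotype!r} has inconsistent tolerance class: {vals}")
        return vals.pop()

    def validate_with(self, table: CountTable) -> None:
        """Check the one-row-per-sample and >=2-replicate invariants."""
        missing = [s for s in table.sample_ids if s not in self.frame.index]
        if missing:
            raise ValueError(f"samples without design rows: {missing}")
        sub = self.frame.loc[table.sample_ids]
        sizes = sub.groupby(["ecotype", "treatment"]).size()
        small = sizes[sizes < 2]
        if len(small):
            raise ValueError(f"groups with fewer than 2 replicates: {small.to_dict()}")


@dataclass
class TaxonomyTable:
    """Taxon id -> seven-rank lineage with sentinel labels for missing ranks.

    A taxon unannotated at the requested rank is displayed as
    ``<lowest annotated parent>_<rank initial>`` (e.g. an unannotated genus
    under family Oxalobacteraceae becomes ``Oxalobacteraceae_g``).
    """

    frame: pd.DataFrame
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        f = self.frame
        if f.index.has_duplicates:
            raise ValueError("duplicate taxon ids in taxonomy")
        for rank in RANKS[:-1]:  # species optional
            if rank not in f.columns:
                raise ValueError(f"taxonomy missing rank column: {rank}")
        if "species" not in f.columns:
            f = f.assign(species="")
        self.frame = f.fillna("").astype(str)
        self.frame.index = self.frame.index.astype(str)

    @staticmethod
    def _annotated(value: str) -> bool:
        return value.strip().lower() not in UNANNOTATED_TOKENS

    def label_at(self, taxon_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank: {rank!r}")
        key = (taxon_id, rank)
        if key in self._cache:
            return self._cache[key]
        row = self.frame.loc[taxon_id]
        value = row[rank]
        if self._annotated(value):
            label = value.strip()
        else:
            parent = "unclassified"
            for upper in RANKS[: RANKS.index(rank)][::-1]:
                if self._annotated(row[upper]):
                    parent = row[upper].strip()
                    break
            label = f"{parent}_{rank[0]}"
        self._cache[key] = label
        return label

    def labels_at(self, taxon_ids, rank: str):
        return [self.label_at(t, rank) for t in taxon_ids]


def to_relative_abundance(table: CountTable) -> RelativeAbundanceTable:
    """Divide each sample row by its total."""
    totals = table.counts.sum(axis=1)
    if np.any(totals == 0):
        empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"samples with zero totals cannot be normalized: {empty}")
    values = table.counts / totals[:, None]
    return RelativeAbundanceTable(list(table.sample_ids), list(table.taxon_ids), values)


def filter_singletons(table: CountTable) -> CountTable:
    """Drop taxa present (count > 0) in at most one sample; order preserved."""
    prevalence = (table.counts > 0).sum(axis=0)
    keep = prevalence >= 2
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    return CountTable(list(table.sample_ids), taxa, table.counts[:, keep])


def aggregate_to_rank(table: CountTable, taxonomy: TaxonomyTable, rank: str) -> CountTable:
    """Sum counts of taxa sharing a rank label; per-sample totals conserved."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank: {rank!r}")
    labels = taxonomy.labels_at(table.taxon_ids, rank)
    order: list = []
    index: dict = {}
    for lab in labels:
        if lab not in index:
            index[lab] = len(order)
            order.append(lab)
    out = np.zeros((len(table.sample_ids), len(order)), dtype=np.int64)
    for col, lab in enumerate(labels):
        out[:, index[lab]] += table.counts[:, col]
    return CountTable(list(table.sample_ids), order, out)


# ---------------------------------------------------------------------------
# File I/O


def _infer_format(path: str, fmt):
    if fmt is not None:
        return fmt
    p = str(path).lower()
    if p.endswith(".json") or p.endswith(".biom"):
        return "biom-json"
    return "tsv"


def read_count_table(path, format=None) -> CountTable:
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        head = str(frame.index.name or "").strip().lower()
        if head == "taxon_id":
            frame = frame.T
        elif head not in {"sample_id", ""}:
            raise ValueError(
                f"count table header must start with 'sample_id' or 'taxon_id', got {head!r}"
            )
        values = np.empty(frame.shape, dtype=np.int64)
        for j, taxon in enumerate(frame.columns):
            col = frame.iloc[:, j]
            for i, raw in enumerate(col):
                try:
                    v = int(raw)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-integer count {raw!r} at sample {frame.index[i]!r}, "
                        f"taxon {taxon!r}"
                    ) from None
                if v < 0:
                    raise ValueError(
                        f"negative count {v} at sample {frame.index[i]!r}, taxon {taxon!r}"
                    )
                values[i, j] = v
        return CountTable(list(frame.index), list(frame.columns), values)
    if fmt == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        n_taxa, n_samples = doc["shape"]
        mat = np.zeros((n_taxa, n_samples), dtype=np.int64)
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat[:] = np.asarray(doc["data"])
        return CountTable(samples, taxa, mat.T)
    raise ValueError(f"unknown count table format: {fmt!r}")


def write_count_table(table: CountTable, path, format=None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        frame = table.to_frame()
        frame.index.name = "sample_id"
        frame.to_csv(path, sep="\t")
    elif fmt == "biom-json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "type": "OTU table",
            "matrix_type": "dense",
            "shape": [len(table.taxon_ids), len(table.sample_ids)],
            "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.T.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown count table format: {fmt!r}")


def read_design(path) -> StudyDesign:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    frame.index = frame.index.astype(str)
    return StudyDesign(frame)


def write_design(design: StudyDesign, path) -> None:
    f = design.frame.copy()
    f.index.name = "sample_id"
    f.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    frame.index = frame.index.astype(str)
    return TaxonomyTable(frame)


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    f = taxonomy.frame.copy()
    f.index.name = "taxon_id"
    f.to_csv(path, sep="\t")


def run_pipeline(config, output_dir=None):
    """Execute the full analysis chain; see :mod:`core_responder.pipeline`."""
    from .pipeline import run_pipeline as _run

    return _run(config, output_dir=output_dir)
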