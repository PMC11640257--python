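"""Reading, writing and validation of expression matrices and run artifacts.

The on-disk contract is deliberately minimal: an expression matrix is
delimited text (comma or tab) with a header row of gene identifiers and a
leading sample-identifier column, samples in rows and genes in columns; labels
live in a two-column companion file mapping sample id to a binary class
(0 = no cancer, 1 = cancer). Gene subsets are one identifier per line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class DatasetFormatError(ValueError):
    """Malformed matrix or labels file (duplicates, missing values...)."""


class LabelAlignmentError(ValueError):
    """A sample in the matrix has no label (or vice versa)."""


class LabelValueError(ValueError):
    """A label outside {0, 1}."""


@dataclass
class ExpressionDataset:
    """A labeled sample x gene expression matrix.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per matrix row.
    gene_ids : list of str
        Unique gene identifiers, one per matrix column.
    values : ndarray of shape (n_samples, n_genes)
        Expression values in arbitrary units; no missing entries.
    labels : ndarray of int, shape (n_samples,)
        Binary class per sample, 0 = "No Cancer", 1 = "Cancer". Both
        classes must be present.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n_s, n_g = self.values.shape
        if len(self.sample_ids) != n_s:
            raise DatasetFormatError(
                f"{len(self.sample_ids)} sample ids for {n_s} matrix rows"
            )
        if len(self.gene_ids) != n_g:
            raise DatasetFormatError(
                f"{len(self.gene_ids)} gene ids for {n_g} matrix columns"
            )
        if len(set(self.gene_ids)) != n_g:
            dupes = _duplicates(self.gene_ids)
            raise DatasetFormatError(f"duplicate gene ids: {sorted(dupes)}")
        if len(set(self.sample_ids)) != n_s:
            dupes = _duplicates(self.sample_ids)
            raise DatasetFormatError(f"duplicate sample ids: {sorted(dupes)}")
        if self.labels.shape != (n_s,):
            raise DatasetFormatError("labels length does not match sample count")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise LabelValueError(f"labels must be 0 or 1, got {sorted(bad)}")
        if len(np.unique(self.labels)) < 2:
            raise LabelValueError("both classes (0 and 1) must be present")
        if np.isnan(self.values).any():
            raise DatasetFormatError("expression matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Column indices for the given gene ids, in the given order."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"gene {exc.args[0]!r} not in dataset") from exc

    def subset_values(self, subset: "GeneSubset") -> np.ndarray:
        """The value matrix restricted to the subset's genes (subset order)."""
        return self.values[:, self.gene_index(subset.gene_ids)]


@dataclass
class GeneSubset:
    """An ordered list of gene ids together with the stage that produced it."""

    gene_ids: list[str]
    source_stage: str = "manual"  # one of {"filter", "pso", "manual"}

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("gene subset must be non-empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene subset contains duplicates")
        if self.source_stage not in {"filter", "pso", "manual"}:
            raise ValueError(f"unknown source_stage {self.source_stage!r}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        (dup if it in seen else seen).add(it)
    return dup


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def load_dataset(
    matrix_path: str | Path,
    labels_path: str | Path,
    *,
    delimiter: str | None = None,
    transpose: bool = False,
    impute_missing: bool = False,
) -> ExpressionDataset:
    """Load and validate a labeled expression dataset.

    Parameters
    ----------
    matrix_path, labels_path
        Matrix file (header = gene ids, first column = sample id) and
        two-column labels file (sample_id, label in {0, 1}).
    delimiter
        Field separator; auto-detected between tab and comma when None.
    transpose
        Set when the matrix file is gene-major (rows = genes).
    impute_missing
        Replace missing entries by the per-gene mean instead of failing.
        A gene with no observed value at all still fails.

    Labels are aligned to the matrix rows *by sample id*, never by file
    order, so permuting label-file rows does not change the result.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    sep = delimiter or _detect_delimiter(matrix_path)
    # check the raw header before pandas de-duplicates repeated names
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if not transpose and len(set(header)) != len(header):
        raise DatasetFormatError(
            f"duplicate gene ids in {matrix_path.name}: {sorted(_duplicates(header))}"
        )
    frame = pd.read_csv(
        matrix_path, sep=sep, index_col=0, dtype={0: str},
        float_precision="round_trip",
    )
    if transpose:
        frame = frame.T
    gene_ids = [str(g) for g in frame.columns]
    sample_ids = [str(s) for s in frame.index]
    if len(set(gene_ids)) != len(gene_ids):
        raise DatasetFormatError(
            f"duplicate gene ids in {matrix_path.name}: {sorted(_duplicates(gene_ids))}"
        )
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        if not impute_missing:
            n_bad = int(np.isnan(values).sum())
            raise DatasetFormatError(
                f"{matrix_path.name} has {n_bad} missing entries "
                "(pass impute_missing=True for per-gene mean imputation)"
            )
        col_mean = np.nanmean(values, axis=0)
        if np.isnan(col_mean).any():
            raise DatasetFormatError("a gene column has no observed values")
        idx = np.where(np.isnan(values))
        values[idx] = col_mean[idx[1]]

    label_map = _read_labels(labels_path, delimiter)
    missing = [s for s in sample_ids if s not in label_map]
    if missing:
        raise LabelAlignmentError(
            f"samples missing from {labels_path.name}: {missing}"
        )
    labels = np.array([label_map[s] for s in sample_ids], dtype=int)
    return ExpressionDataset(sample_ids, gene_ids, values, labels)


def _read_labels(path: Path, delimiter: str | None) -> dict[str, int]:
    sep = delimiter or _detect_delimiter(path)
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if raw.shape[1] != 2:
        raise DatasetFormatError(
            f"labels file {path.name} must have exactly two columns"
        )
    rows = raw.values.tolist()
    # tolerate a header row such as "sample_id,label"
    if rows and not _is_binary(rows[0][1]):
        rows = rows[1:]
    out: dict[str, int] = {}
    for sid, lab in rows:
        sid = str(sid).strip()
        if not _is_binary(lab):
            raise LabelValueError(
                f"label for sample {sid!r} must be 0 or 1, got {lab!r}"
            )
        if sid in out:
            raise DatasetFormatError(f"duplicate sample id {sid!r} in labels file")
        out[sid] = int(lab)
    return out


def _is_binary(token: object) -> bool:
    try:
        return int(str(token).strip()) in (0, 1)
    except (TypeError, ValueError):
        return False


def write_dataset(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    labels_path: str | Path,
    *,
    delimiter: str = ",",
) -> None:
    """Write the matrix and labels files in the layout load_dataset reads.

    Values are written with full repr precision so a write/load round trip
    reproduces the matrix exactly.
    """
    frame = pd.DataFrame(
        dataset.values, index=dataset.sample_ids, columns=dataset.gene_ids
    )
    frame.index.name = "sample_id"
    frame.to_csv(matrix_path, sep=delimiter, float_format=None)
    with open(labels_path, "w") as fh:
        fh.write("sample_id%slabel\n" % delimiter)
        for sid, lab in zip(dataset.sample_ids, dataset.labels):
            fh.write(f"{sid}{delimiter}{int(lab)}\n")


def read_gene_subset(path: str | Path, source_stage: str = "manual") -> GeneSubset:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return GeneSubset([ln for ln in lines if ln], source_stage=source_stage)


def write_gene_subset(subset: GeneSubset, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in subset.gene_ids))


def write_report(report, subset: GeneSubset, out_dir: str | Path) -> set[Path]:
    """Write a full evaluation report as plain-text artifacts.

    Produces ``genes.txt`` (one id per line), ``metrics.json`` (metrics and
    the per-run accuracy summary), ``roc.tsv`` / ``pr.tsv`` (two-column
    curve point sets) and ``runs.tsv``. Output is byte-stable: identical
    inputs always give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not report.roc_points or not report.pr_points:
        raise ValueError("report has empty curve point sets; refusing to write")

    written: set[Path] = set()

    genes = out_dir / "genes.txt"
    write_gene_subset(subset, genes)
    written.add(genes)

    cm = report.confusion
    payload = {
        "n_genes_selected": len(subset),
        "confusion": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
        "accuracy": report.accuracy,
        "precision": report.precision,
        "recall": report.recall,
        "f_score": report.f_score,
        "auc_roc": report.auc_roc,
        "runs": {
            "best": report.best,
            "average": report.average,
            "worst": report.worst,
            "n_runs": len(report.per_run_accuracies),
        },
    }
    metrics = out_dir / "metrics.json"
    metrics.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    written.add(metrics)

    for name, points, header in (
        ("roc.tsv", report.roc_points, "fpr\ttpr"),
        ("pr.tsv", report.pr_points, "recall\tprecision"),
    ):
        path = out_dir / name
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for a, b in points:
                fh.write(f"{a!r}\t{b!r}\n")
        written.add(path)

    runs = out_dir / "runs.tsv"
    with open(runs, "w") as fh:
        fh.write("run\tloocv_accuracy\n")
        for i, acc in enumerate(report.per_run_accuracies):
            fh.write(f"{i}\t{acc!r}\n")
    written.add(runs)
    return written
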