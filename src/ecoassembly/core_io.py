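"""Data model and I/O for taxon-by-sample count tables.

The central object is :class:`CommunityMatrix`: an integer taxa x samples
count table aligned with per-sample metadata (treatment, replicate,
timepoint).  Everything downstream — null models, ordination, indicator
statistics, association networks — consumes this object or the
:class:`RelativeAbundanceMatrix` produced by total-sum scaling (TSS).

Counts are validated on construction: non-negative integers, unique taxon
and sample identifiers, metadata covering every sample exactly once, and no
all-zero samples (all-zero taxa are allowed but flagged).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("treatment", "replicate", "timepoint")

__all__ = [
    "CommunityMatrix",
    "RelativeAbundanceMatrix",
    "QpcrRecord",
    "read_community",
    "write_community",
    "read_qpcr",
    "tss_normalize",
    "normalize_qpcr",
    "rolling_mean",
]


@dataclass
class CommunityMatrix:
    """Integer taxa x samples count table plus aligned sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon id with one column per sample; values
        are non-negative integers (read counts).
    metadata
        DataFrame indexed by sample id with columns ``treatment``,
        ``replicate`` and ``timepoint`` (numeric, e.g. hours).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.metadata = self.metadata.copy()
        self._validate()

    def _validate(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(values < 0):
            raise ValueError("negative counts are not permitted")
        if not np.allclose(values, np.round(values)):
            raise ValueError(
                "counts must be integers (use strict=False in read_community "
                "to allow rounding)"
            )
        self.counts = self.counts.astype(np.int64)
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing for sample(s): {sorted(missing)}")
        extra_cols = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if extra_cols:
            raise ValueError(f"metadata lacks required column(s): {extra_cols}")
        if self.metadata.index.duplicated().any():
            dups = self.metadata.index[self.metadata.index.duplicated()].tolist()
            raise ValueError(f"duplicate metadata rows for sample(s): {dups}")
        # canonical axis names so round-trips compare equal
        self.counts.index.name = "taxon"
        self.counts.columns.name = None
        self.metadata.index.name = "sample"
        # align metadata to sample order, drop rows for absent samples
        self.metadata = self.metadata.loc[list(self.counts.columns)]
        self.metadata["timepoint"] = pd.to_numeric(self.metadata["timepoint"])
        zero_samples = self.counts.columns[self.counts.sum(axis=0) == 0].tolist()
        if zero_samples:
            raise ValueError(f"all-zero sample(s) not permitted: {zero_samples}")
        zero_taxa = self.counts.index[self.counts.sum(axis=1) == 0]
        if len(zero_taxa):
            logger.warning("%d all-zero taxa present (kept)", len(zero_taxa))

    @property
    def taxa_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_taxa(self, taxa: list[str], drop_empty_samples: bool = True) -> "CommunityMatrix":
        """Restrict to *taxa*; optionally drop samples left with zero total."""
        sub = self.counts.loc[list(taxa)]
        keep = sub.columns[sub.sum(axis=0) > 0] if drop_empty_samples else sub.columns
        dropped = set(sub.columns) - set(keep)
        if dropped:
            logger.warning("dropping %d empty sample(s) after taxon subset", len(dropped))
        return CommunityMatrix(sub[keep], self.metadata.loc[list(keep)])

    def subset_samples(self, samples: list[str]) -> "CommunityMatrix":
        return CommunityMatrix(self.counts[list(samples)], self.metadata.loc[list(samples)])


@dataclass
class RelativeAbundanceMatrix:
    """TSS-normalised proportions with the same axes as a CommunityMatrix."""

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each sample column must sum to 1")

    @property
    def taxa_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class QpcrRecord:
    """One qPCR quantification with its internal-standard recovery.

    ``measured_16s_copies`` is the raw 16S copy number (copies/ml);
    ``spiked_egfp_copies`` and ``recovered_egfp_copies`` quantify the
    plasmid internal standard added before DNA extraction, whose recovery
    ratio corrects for extraction efficiency.
    """

    sample_id: str
    measured_16s_copies: float
    spiked_egfp_copies: float
    recovered_egfp_copies: float


def _looks_like_json(path: Path) -> bool:
    with open(path) as fh:
        head = fh.read(64).lstrip()
    return head.startswith("{")


def _read_biom_json(path: Path) -> pd.DataFrame:
    """Minimal BIOM-style JSON reader (dense or sparse 'data')."""
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    return pd.DataFrame(mat, index=taxa, columns=samples)


def read_community(
    table_path: str | Path,
    metadata_path: str | Path,
    *,
    strict: bool = True,
) -> CommunityMatrix:
    """Load a count table (TSV or BIOM-style JSON) with its metadata.

    The TSV orientation (taxa rows vs sample rows) is auto-detected by
    matching identifiers against the metadata ``sample`` column; if both
    or neither orientation matches, loading fails rather than guessing.

    With ``strict=False`` decimal values are rounded half-to-even (and the
    rounding logged); by default non-integer counts are an error.
    """
    table_path, metadata_path = Path(table_path), Path(metadata_path)
    meta = pd.read_csv(metadata_path, sep="\t", comment="#")
    if "sample" not in meta.columns:
        raise ValueError("metadata must have a 'sample' column")
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata lacks required column(s): {missing_cols}")
    meta = meta.set_index("sample")

    if _looks_like_json(table_path):
        table = _read_biom_json(table_path)
    else:
        table = pd.read_csv(table_path, sep="\t", comment="#", index_col=0)

    sample_set = set(meta.index)
    cols_match = set(table.columns) <= sample_set
    rows_match = set(table.index) <= sample_set
    if cols_match and not rows_match:
        pass
    elif rows_match and not cols_match:
        table = table.T
    elif cols_match and rows_match:
        raise ValueError("ambiguous table orientation: both axes match metadata sample ids")
    else:
        unmatched = sorted(set(table.columns) - sample_set)
        raise ValueError(f"metadata missing for sample(s): {unmatched}")

    values = table.apply(pd.to_numeric, errors="raise")
    arr = values.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative counts in table")
    if not np.allclose(arr, np.round(arr)):
        if strict:
            raise ValueError("non-integer counts (pass strict=False to round)")
        n_rounded = int(np.sum(~np.isclose(arr, np.round(arr))))
        logger.info("rounded %d non-integer counts half-to-even", n_rounded)
        values = values.round(0)
    return CommunityMatrix(values, meta)


def write_community(cm: CommunityMatrix, table_path: str | Path, metadata_path: str | Path) -> None:
    """Write the count table and metadata back out as plain TSV."""
    Path(table_path).parent.mkdir(parents=True, exist_ok=True)
    out = cm.counts.copy()
    out.index.name = "taxon"
    out.to_csv(table_path, sep="\t")
    meta = cm.metadata.copy()
    meta.index.name = "sample"
    meta.to_csv(metadata_path, sep="\t")


def read_qpcr(path: str | Path) -> list[QpcrRecord]:
    """Read a qPCR table (sample, measured_16s_copies, spiked_egfp_copies,
    recovered_egfp_copies)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "measured_16s_copies", "spiked_egfp_copies", "recovered_egfp_copies"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table lacks column(s): {sorted(missing)}")
    return [
        QpcrRecord(
            sample_id=str(r["sample"]),
            measured_16s_copies=float(r["measured_16s_copies"]),
            spiked_egfp_copies=float(r["spiked_egfp_copies"]),
            recovered_egfp_copies=float(r["recovered_egfp_copies"]),
        )
        for _, r in df.iterrows()
    ]


def tss_normalize(cm: CommunityMatrix) -> RelativeAbundanceMatrix:
    """Total-sum scaling: divide each sample column by its total count."""
    totals = cm.counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"zero-sum sample(s): {bad}")
    return RelativeAbundanceMatrix(cm.counts / totals, cm.metadata)


def normalize_qpcr(rec: QpcrRecord) -> float:
    """Extraction-efficiency-corrected 16S copy number (copies/ml).

    The spiked internal-standard plasmid is quantified alongside the 16S
    target; the correction multiplies the measured copies by
    spiked/recovered.  Volume scaling, if any, is left to the caller.
    """
    if rec.recovered_egfp_copies <= 0:
        raise ValueError("recovered_egfp_copies must be positive")
    if rec.measured_16s_copies <= 0 or rec.spiked_egfp_copies <= 0:
        raise ValueError("qPCR quantities must be positive")
    return rec.measured_16s_copies * (rec.spiked_egfp_copies / rec.recovered_egfp_copies)


def rolling_mean(series, window: int) -> np.ndarray:
    """Centered moving average with truncated windows at the edges.

    Keeps the output the same length as the input: near the boundaries the
    average is taken over the part of the window that exists.
    """
    if window <= 0:
        raise ValueError("window must be a positive integer")
    x = pd.Series(np.asarray(series, dtype=float))
    if window > len(x):
        raise ValueError("window exceeds series length")
    return x.rolling(window, center=True, min_periods=1).mean().to_numpy()
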