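"""Barcode x sample UMI count matrix with sample metadata and annotations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["mouse", "compartment", "timepoint_months", "replicate", "sorted_cells", "gfp_fraction"]
GROUP_KEYS = ["mouse", "compartment", "timepoint_months"]


@dataclass
class BarcodeCountMatrix:
    """UMI counts per barcode (rows) and sample (columns).

    ``samples`` is indexed by sample id and carries mouse, compartment,
    timepoint_months, replicate, sorted_cells and gfp_fraction;
    ``annotations`` (optional) is indexed by barcode and carries the
    per-barcode recombination annotation and, once computed, P_gen.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.samples.index):
            missing = set(self.counts.columns) ^ set(self.samples.index)
            if missing:
                raise ValueError(f"counts columns and samples index disagree: {sorted(missing)[:5]}")
            self.samples = self.samples.loc[self.counts.columns]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.annotations is not None:
            self.annotations = self.annotations.reindex(self.counts.index)

    @property
    def barcodes(self) -> pd.Index:
        return self.counts.index

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[0]

    def fractions(self) -> pd.DataFrame:
        """Per-sample barcode fractions (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise ValueError(f"cannot normalize all-zero sample(s): {bad}")
        return self.counts / totals

    def asinh_fractions(self, cofactor: float = 1.0) -> pd.DataFrame:
        """Hyperbolic-arcsine transformed fractions, asinh(f / cofactor)."""
        return np.arcsinh(self.fractions() / cofactor)

    def subset_barcodes(self, barcodes) -> "BarcodeCountMatrix":
        ann = self.annotations.loc[barcodes] if self.annotations is not None else None
        return BarcodeCountMatrix(self.counts.loc[barcodes], self.samples.copy(), ann)

    def subset_samples(self, sample_ids) -> "BarcodeCountMatrix":
        return BarcodeCountMatrix(
            self.counts[list(sample_ids)], self.samples.loc[list(sample_ids)],
            self.annotations.copy() if self.annotations is not None else None,
        )

    def biological_groups(self) -> dict[tuple, list[str]]:
        """Sample ids grouped by (mouse, compartment, timepoint)."""
        groups: dict[tuple, list[str]] = {}
        for sid, row in self.samples.iterrows():
            groups.setdefault(tuple(row[k] for k in GROUP_KEYS), []).append(sid)
        return groups

    # -- I/O -----------------------------------------------------------------

    def to_tsv(self, counts_path, samples_path, annotations_path=None) -> None:
        self.counts.rename_axis("barcode").to_csv(counts_path, sep="\t")
        self.samples.rename_axis("sample_id").to_csv(samples_path, sep="\t")
        if annotations_path is not None and self.annotations is not None:
            self.annotations.rename_axis("barcode").to_csv(annotations_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, samples_path, annotations_path=None) -> "BarcodeCountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="barcode")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        ann = pd.read_csv(annotations_path, sep="\t", index_col="barcode") if annotations_path else None
        return cls(counts, samples, ann)


def concat_matrices(matrices: list[BarcodeCountMatrix]) -> BarcodeCountMatrix:
    """Outer-join several matrices on barcodes (missing entries are 0)."""
    counts = pd.concat([m.counts for m in matrices], axis=1).fillna(0).astype(int)
    samples = pd.concat([m.samples for m in matrices], axis=0)
    anns = [m.annotations for m in matrices if m.annotations is not None]
    ann = None
    if anns:
        ann = pd.concat(anns, axis=0)
        ann = ann[~ann.index.duplicated(keep="first")]
    return BarcodeCountMatrix(counts, samples, ann)
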