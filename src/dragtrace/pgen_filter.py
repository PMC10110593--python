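"""Recurrence filtering by generation probability.

Barcodes that the recombination machinery produces with high probability
recur independently in different cells (and different mice), so they cannot
be used as clonal marks.  Barcodes are scored with P_gen and only those
below a cutoff (default 1e-4, strict inequality) are retained for clonal
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .matrix import BarcodeCountMatrix
from .model import GenerativeModel
from .pgen import compute_pgen_many
from .reference import CassetteReference

DEFAULT_PGEN_THRESHOLD = 1e-4


@dataclass
class PgenReport:
    threshold: float
    n_input: int
    n_retained: int
    fraction_retained: float
    fraction_mouse_unique: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def annotate_pgen(
    matrix: BarcodeCountMatrix, model: GenerativeModel, reference: CassetteReference
) -> BarcodeCountMatrix:
    """Add a ``pgen`` column to the matrix annotations (cached per unique
    barcode; unproducible barcodes get pgen 0 and are flagged)."""
    barcodes = list(matrix.barcodes)
    pgen = compute_pgen_many(model, reference, barcodes)
    ann = matrix.annotations.copy() if matrix.annotations is not None else pd.DataFrame(index=matrix.barcodes)
    ann["pgen"] = pgen
    ann["unproducible"] = pgen == 0.0
    return BarcodeCountMatrix(matrix.counts.copy(), matrix.samples.copy(), ann)


def filter_by_pgen(
    matrix: BarcodeCountMatrix, threshold: float = DEFAULT_PGEN_THRESHOLD
) -> tuple[BarcodeCountMatrix, PgenReport]:
    """Retain barcodes with pgen strictly below ``threshold``."""
    if matrix.annotations is None or "pgen" not in matrix.annotations:
        raise ValueError("matrix has no pgen annotation; run annotate_pgen first")
    pgen = matrix.annotations["pgen"]
    keep = matrix.barcodes[pgen < threshold]
    retained = matrix.subset_barcodes(keep)
    frac_unique = None
    if "mouse" in matrix.samples.columns and len(keep):
        frac_unique = cross_mouse_uniqueness(retained)
    report = PgenReport(
        threshold=threshold,
        n_input=matrix.n_barcodes,
        n_retained=len(keep),
        fraction_retained=(len(keep) / matrix.n_barcodes) if matrix.n_barcodes else 0.0,
        fraction_mouse_unique=frac_unique,
    )
    return retained, report


def recurrence_probability(pgen: float, n_events: int) -> float:
    """Probability a barcode arises independently at least twice among
    ``n_events`` recombination events (binomial tail at >= 2)."""
    if not 0.0 <= pgen <= 1.0:
        raise ValueError("pgen must lie in [0, 1]")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if n_events < 2 or pgen == 0.0:
        return 0.0
    q = 1.0 - pgen
    return float(1.0 - q**n_events - n_events * pgen * q ** (n_events - 1))


def cross_mouse_uniqueness(matrix: BarcodeCountMatrix) -> float:
    """Fraction of barcodes detected in exactly one mouse.

    Computed over the union of barcodes with a nonzero count anywhere;
    uniqueness is exact sequence identity.
    """
    mice = matrix.samples["mouse"]
    present = matrix.counts > 0
    n_mice_per_barcode = (
        present.T.groupby(mice).any().sum(axis=0)
    )
    detected = n_mice_per_barcode[n_mice_per_barcode > 0]
    if detected.empty:
        return float("nan")
    return float((detected == 1).mean())


def cross_mouse_uniqueness_by_mouse(matrices: dict[str, BarcodeCountMatrix]) -> float:
    """Same statistic from per-mouse matrices keyed by mouse id."""
    seen: dict[str, set] = {}
    for mouse, m in matrices.items():
        det = set(m.barcodes[(m.counts > 0).any(axis=1)])
        for b in det:
            seen.setdefault(b, set()).add(mouse)
    if not seen:
        return float("nan")
    return float(np.mean([len(v) == 1 for v in seen.values()]))
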