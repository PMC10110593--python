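"""Clonal fate classification, clone sizes, and diversity estimation.

Fate classes are the nonempty subsets of {HSPC, MP, M} in which a barcode is
detected after filtering.  Clone sizes convert per-sample barcode fractions
into cell numbers using sorted cell counts.  Diversity is estimated by
incidence-based chao2 richness (with a labeling-efficiency correction to
total clone numbers), Simpson-family indices, and Renyi entropy profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .matrix import BarcodeCountMatrix
from .simulate import COMPARTMENTS


@dataclass(frozen=True)
class DiversityEstimate:
    index: str
    value: float
    q: float | None = None
    labeling_corrected: bool = False


# -- fate classes ------------------------------------------------------------


def classify_fates(
    matrix: BarcodeCountMatrix, compartments=COMPARTMENTS
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-barcode fate class and per-class summaries for one mouse.

    A barcode's class is the set of compartments with a nonzero retained
    count.  The summary reports, per class, the percentage of barcodes and
    the percentage of each compartment's total normalized abundance
    contributed by the class (contributions per compartment sum to 100).
    """
    comp_of = matrix.samples["compartment"]
    missing = [c for c in compartments if c not in set(comp_of)]
    if missing:
        raise ValueError(f"matrix lacks compartment column(s): {missing}")
    present = pd.DataFrame(
        {comp: (matrix.counts.loc[:, comp_of == comp].sum(axis=1) > 0) for comp in compartments}
    )
    classes = present.apply(
        lambda row: "+".join([c for c in compartments if row[c]]) if row.any() else "",
        axis=1,
    )
    classes = classes[classes != ""]
    frac = matrix.fractions()
    comp_frac = {
        comp: frac.loc[:, comp_of == comp].mean(axis=1) for comp in compartments
    }
    class_names = [
        "+".join(c)
        for r in range(1, len(compartments) + 1)
        for c in _subsets(compartments, r)
    ]
    rows = []
    n_total = len(classes)
    for name in class_names:
        in_class = classes.index[classes == name]
        row = {
            "fate_class": name,
            "n_barcodes": len(in_class),
            "pct_barcodes": 100.0 * len(in_class) / n_total if n_total else 0.0,
        }
        for comp in compartments:
            total = comp_frac[comp].sum()
            row[f"pct_{comp}_output"] = (
                100.0 * comp_frac[comp].loc[in_class].sum() / total if total > 0 else 0.0
            )
        rows.append(row)
    return classes, pd.DataFrame(rows).set_index("fate_class")


def _subsets(items, r):
    from itertools import combinations

    return combinations(items, r)


# -- clone sizes -------------------------------------------------------------


def clone_sizes(matrix: BarcodeCountMatrix, scale_by_labeling: bool = False) -> pd.DataFrame:
    """Cells per clone per sample: fraction x sorted cell count.

    With ``scale_by_labeling`` the per-sample GFP+ fraction divides the
    result, extrapolating from the sorted (labeled) population to the whole
    compartment.
    """
    if "sorted_cells" not in matrix.samples.columns or matrix.samples["sorted_cells"].isna().any():
        raise ValueError("every sample needs a sorted_cells count")
    frac = matrix.fractions()
    sizes = frac * matrix.samples["sorted_cells"].astype(float)
    if scale_by_labeling:
        gfp = matrix.samples["gfp_fraction"].astype(float)
        if gfp.isna().any() or (gfp <= 0).any():
            raise ValueError("scale_by_labeling requires positive gfp_fraction for every sample")
        sizes = sizes / gfp
    return sizes


# -- chao2 richness ----------------------------------------------------------


def chao2(
    incidence,
    labeling_fraction: float | None = None,
    form: str = "auto",
) -> DiversityEstimate:
    """Incidence-based chao2 richness over ``m`` sampling units.

    ``incidence`` is a barcodes x units table (nonzero = detected; the PCR
    duplicates are the default sampling units).  The classic estimator
    ``S_obs + ((m-1)/m) * Q1^2 / (2 Q2)`` is used when doubletons exist; the
    bias-corrected form ``S_obs + ((m-1)/m) * Q1 (Q1-1) / (2 (Q2+1))`` when
    ``Q2 = 0`` (or on request).  ``labeling_fraction`` divides the estimate
    to extrapolate labeled richness to total clone numbers.
    """
    inc = np.asarray(incidence, dtype=float) > 0
    if inc.ndim != 2 or inc.shape[1] < 2:
        raise ValueError("chao2 needs an incidence matrix with m >= 2 sampling units")
    m = inc.shape[1]
    units_per_barcode = inc.sum(axis=1)
    s_obs = int((units_per_barcode > 0).sum())
    q1 = int((units_per_barcode == 1).sum())
    q2 = int((units_per_barcode == 2).sum())
    return chao2_from_counts(s_obs, q1, q2, m, labeling_fraction=labeling_fraction, form=form)


def chao2_from_counts(
    s_obs: int,
    q1: int,
    q2: int,
    m: int,
    labeling_fraction: float | None = None,
    form: str = "auto",
) -> DiversityEstimate:
    """chao2 directly from observed richness and singleton/doubleton counts."""
    if m < 2:
        raise ValueError("chao2 needs m >= 2 sampling units")
    if form not in ("auto", "classic", "bias_corrected"):
        raise ValueError(f"unknown chao2 form {form!r}")
    use_classic = form == "classic" or (form == "auto" and q2 > 0)
    if use_classic:
        if q2 == 0:
            raise ValueError("classic chao2 undefined with Q2 = 0; use form='bias_corrected'")
        est = s_obs + (m - 1) / m * q1**2 / (2.0 * q2)
    else:
        est = s_obs + (m - 1) / m * q1 * (q1 - 1) / (2.0 * (q2 + 1))
    corrected = labeling_fraction is not None
    if corrected:
        if not 0.0 < labeling_fraction <= 1.0:
            raise ValueError("labeling_fraction must lie in (0, 1]")
        est = est / labeling_fraction
    return DiversityEstimate(index="chao2", value=float(est), labeling_corrected=corrected)


def replicate_incidence(matrix: BarcodeCountMatrix, mouse, compartment, timepoint=None) -> pd.DataFrame:
    """Incidence table over the PCR replicates of one biological sample."""
    sel = (matrix.samples["mouse"] == mouse) & (matrix.samples["compartment"] == compartment)
    if timepoint is not None:
        sel &= matrix.samples["timepoint_months"] == timepoint
    sids = matrix.samples.index[sel]
    if len(sids) < 2:
        raise ValueError("need >= 2 replicate samples for an incidence table")
    return (matrix.counts[list(sids)] > 0).astype(int)


# -- Renyi / Simpson diversity ----------------------------------------------


def renyi_entropy(p: np.ndarray, q: float) -> float:
    """Renyi entropy H_q of an abundance vector (natural log)."""
    p = p[p > 0]
    if q == 1.0:
        return float(-np.sum(p * np.log(p)))
    if np.isinf(q):
        return float(-np.log(p.max()))
    return float(np.log(np.sum(p**q)) / (1.0 - q))


def _normalize(abundances) -> np.ndarray:
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("abundances sum to zero")
    if abs(total - 1.0) > 1e-9:
        warnings.warn("abundances do not sum to 1; normalizing", stacklevel=3)
        p = p / total
    return p


def simpson_indices(abundances) -> dict[str, float]:
    """Simpson concentration, Gini-Simpson and inverse Simpson."""
    p = _normalize(abundances)
    lam = float(np.sum(p**2))
    return {
        "simpson_concentration": lam,
        "gini_simpson": 1.0 - lam,
        "inverse_simpson": 1.0 / lam,
    }


def diversity_profile(abundances, q_values=(0.0, 0.5, 1.0, 2.0, 4.0, np.inf)) -> pd.DataFrame:
    """Renyi entropy profile plus Simpson-family indices.

    Returns a long-format table of (index, q, value); Renyi entropies are
    non-increasing in q, with H_0 = log richness and exp(H_2) equal to the
    inverse Simpson index.
    """
    p = _normalize(abundances)
    rows = [
        {"index": "renyi", "q": float(q), "value": renyi_entropy(p, float(q))} for q in q_values
    ]
    rows.append({"index": "richness", "q": None, "value": float((p > 0).sum())})
    for name, val in simpson_indices(p).items():
        rows.append({"index": name, "q": None, "value": val})
    return pd.DataFrame(rows)


def diversity_table(matrix: BarcodeCountMatrix, q_values=(0.0, 0.5, 1.0, 2.0, 4.0)) -> pd.DataFrame:
    """Diversity profile per sample of a count matrix (long format)."""
    frames = []
    frac = matrix.fractions()
    for sid in frac.columns:
        prof = diversity_profile(frac[sid].to_numpy(), q_values)
        prof.insert(0, "sample_id", sid)
        frames.append(prof)
    return pd.concat(frames, ignore_index=True)
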