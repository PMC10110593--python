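"""Ground-truthed synthetic data emulating the deposited raw sequencing.

Three generators:

* :func:`simulate_clone_population` — clones with heavy-tailed (log-normal)
  compartment sizes, fate classes over {HSPC, MP, M}, GFP labeling, and
  barcodes drawn from the generative recombination model;
* :func:`simulate_reads` — UMI-tagged single-end reads for one sorted
  sample: cells sampled without replacement, split over PCR replicates,
  UMIs per cell and reads per UMI Poisson-distributed, per-base
  substitution errors; every emitted read is accounted for in a truth
  table;
* :func:`simulate_timecourse` / :func:`simulate_diversity_observations` —
  longitudinal blood samples whose expected clonal diversity follows a
  piecewise log-linear (breakpoint) trajectory with a per-mouse random
  intercept.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import ReadLayout
from .matrix import BarcodeCountMatrix
from .model import GenerativeModel
from .recombination import sample_recombinations
from .reference import NT_ALPHABET, CassetteReference

COMPARTMENTS = ("HSPC", "MP", "M")

#: Default barcode-class proportions.  The triple-positive class matches the
#: observed 13.7% of barcodes shared across HSPC, MP and myeloid cells; the
#: HSPC+M class (without MP) is absent, as observed; the remainder is spread
#: over the other classes in plausible proportions.
DEFAULT_CLASS_PROPORTIONS = {
    "HSPC": 0.20,
    "MP": 0.08,
    "M": 0.15,
    "HSPC+MP": 0.10,
    "HSPC+M": 0.0,
    "MP+M": 0.333,
    "HSPC+MP+M": 0.137,
}


def class_members(fate_class: str) -> tuple[str, ...]:
    return tuple(fate_class.split("+"))


@dataclass
class Clone:
    clone_id: str
    barcode: str
    fate_class: str
    cells: dict  # compartment -> cell count; 0 exactly outside the fate class
    gfp_labeled: bool


@dataclass
class ClonePopulation:
    """Synthetic ground truth: clones, their sizes and labeling."""

    clones: list
    labeling_efficiency: float

    def __post_init__(self) -> None:
        if not 0.0 < self.labeling_efficiency <= 1.0:
            raise ValueError("labeling_efficiency must lie in (0, 1]")
        for clone in self.clones:
            members = set(class_members(clone.fate_class))
            for comp in COMPARTMENTS:
                present = clone.cells.get(comp, 0) > 0
                if present != (comp in members):
                    raise ValueError(
                        f"clone {clone.clone_id}: cells inconsistent with fate class {clone.fate_class}"
                    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "clone_id": c.clone_id,
                    "barcode": c.barcode,
                    "fate_class": c.fate_class,
                    "gfp_labeled": c.gfp_labeled,
                    **{comp: c.cells.get(comp, 0) for comp in COMPARTMENTS},
                }
                for c in self.clones
            ]
        )

    def labeled_clones(self, compartment: str) -> list:
        return [c for c in self.clones if c.gfp_labeled and c.cells.get(compartment, 0) > 0]


def simulate_clone_population(
    n_clones: int,
    model: GenerativeModel,
    reference: CassetteReference,
    rng: np.random.Generator,
    class_proportions: dict | None = None,
    size_median: float = 1000.0,
    size_sigma_log10: float = 0.5,
    labeling_efficiency: float = 0.5,
    allow_collisions: bool = False,
) -> ClonePopulation:
    """Draw a clone population with model-generated barcodes.

    Compartment sizes are log-normal (median ``size_median`` cells, log10
    scale sd ``size_sigma_log10``), spanning roughly 100-10,000 cells at the
    defaults.  Barcodes are resampled on exact collision unless
    ``allow_collisions`` is set (recurrent-barcode simulation).
    """
    props = dict(DEFAULT_CLASS_PROPORTIONS if class_proportions is None else class_proportions)
    names = list(props)
    pvec = np.array([props[k] for k in names], dtype=float)
    if abs(pvec.sum() - 1.0) > 1e-9 or (pvec < 0).any():
        raise ValueError("class proportions must be nonnegative and sum to 1")
    if n_clones == 0:
        return ClonePopulation(clones=[], labeling_efficiency=labeling_efficiency)

    _, barcodes = sample_recombinations(model, reference, n_clones, rng)
    if not allow_collisions:
        seen = set()
        for i, bc in enumerate(barcodes):
            while bc in seen:
                _, (bc,) = sample_recombinations(model, reference, 1, rng)
            seen.add(bc)
            barcodes[i] = bc
    classes = rng.choice(len(names), size=n_clones, p=pvec)
    labeled = rng.random(n_clones) < labeling_efficiency
    clones = []
    for i in range(n_clones):
        fate = names[classes[i]]
        members = class_members(fate)
        cells = {}
        for comp in members:
            log10_size = np.log10(size_median) + size_sigma_log10 * rng.standard_normal()
            cells[comp] = max(1, int(round(10.0 ** log10_size)))
        clones.append(
            Clone(
                clone_id=f"clone{i:05d}",
                barcode=barcodes[i],
                fate_class=fate,
                cells=cells,
                gfp_labeled=bool(labeled[i]),
            )
        )
    return ClonePopulation(clones=clones, labeling_efficiency=labeling_efficiency)


# -- read simulation ---------------------------------------------------------


@dataclass(frozen=True)
class SampleSpec:
    """One sorted biological sample to sequence."""

    sample_id: str
    mouse: str
    compartment: str
    timepoint_months: float
    cells_sampled: int
    pcr_replicates: int = 2
    umis_per_cell: float = 1.0
    reads_per_umi: float = 3.0
    seq_error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.cells_sampled < 0:
            raise ValueError("cells_sampled must be >= 0")
        if self.pcr_replicates < 1:
            raise ValueError("pcr_replicates must be >= 1")
        if not 0.0 <= self.seq_error_rate <= 1.0:
            raise ValueError("seq_error_rate must lie in [0, 1]")

    def replicate_ids(self) -> list[str]:
        return [f"{self.sample_id}_R{r + 1}" for r in range(self.pcr_replicates)]


_LETTERS = np.frombuffer(NT_ALPHABET.encode(), dtype=np.uint8)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(NT_ALPHABET):
    _CODE[ord(_c)] = _i


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply per-base substitution errors to an array of base codes."""
    if rate <= 0 or codes.size == 0:
        return codes
    hit = rng.random(codes.shape) < rate
    n_hit = int(hit.sum())
    if n_hit:
        codes = codes.copy()
        # substitute with one of the three other bases, uniformly
        codes[hit] = (codes[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return codes


def simulate_reads(
    population: ClonePopulation,
    spec: SampleSpec,
    layout: ReadLayout,
    rng: np.random.Generator,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Simulate UMI-tagged reads for one sample.

    Cells are drawn without replacement from the GFP+ clones of the sample's
    compartment (multivariate hypergeometric on clone sizes), each cell's
    molecules go to one PCR replicate, each cell yields ``Poisson(u)+1``
    UMIs and each UMI ``Poisson(r)+1`` reads.  Returns reads keyed by
    replicate sample id, plus a truth table whose emitted-read sums match
    the returned records exactly.
    """
    clones = population.labeled_clones(spec.compartment)
    sizes = np.array([c.cells[spec.compartment] for c in clones], dtype=np.int64)
    total = int(sizes.sum())
    if spec.cells_sampled > total:
        raise ValueError(
            f"cells_sampled={spec.cells_sampled} exceeds GFP+ {spec.compartment} population ({total})"
        )
    sampled = (
        rng.multivariate_hypergeometric(sizes, spec.cells_sampled)
        if clones
        else np.zeros(0, dtype=np.int64)
    )
    rep_ids = spec.replicate_ids()
    reads_out: dict[str, list[tuple[str, str]]] = {rid: [] for rid in rep_ids}
    truth_rows = []
    anchor_codes = _CODE[np.frombuffer(layout.anchor.encode(), dtype=np.uint8)]
    serial = 0
    for ci, clone in enumerate(clones):
        n_cells = int(sampled[ci]) if sampled.size else 0
        if n_cells == 0:
            continue
        split = rng.multinomial(n_cells, np.full(spec.pcr_replicates, 1.0 / spec.pcr_replicates))
        bc_codes = _CODE[np.frombuffer(clone.barcode.encode(), dtype=np.uint8)]
        for r, cells_r in enumerate(split):
            if cells_r == 0:
                continue
            n_umis = int(cells_r + rng.poisson(spec.umis_per_cell * cells_r))
            reads_per = 1 + rng.poisson(spec.reads_per_umi, size=n_umis)
            n_reads = int(reads_per.sum())
            umi_codes = rng.integers(0, 4, size=(n_umis, layout.umi_length), dtype=np.int8)
            # expand UMIs to reads and assemble UMI+anchor+barcode
            umi_rep = np.repeat(umi_codes, reads_per, axis=0)
            body = np.concatenate([anchor_codes, bc_codes]).astype(np.int8)
            mat = np.concatenate(
                [umi_rep, np.broadcast_to(body, (n_reads, body.size))], axis=1
            )
            mat = _mutate(mat, spec.seq_error_rate, rng)
            chars = _LETTERS[mat]
            rid = rep_ids[r]
            for row in chars:
                reads_out[rid].append((f"{rid}:{serial}", row.tobytes().decode()))
                serial += 1
            truth_rows.append(
                {
                    "sample_id": rid,
                    "mouse": spec.mouse,
                    "compartment": spec.compartment,
                    "timepoint_months": spec.timepoint_months,
                    "replicate": r + 1,
                    "clone_id": clone.clone_id,
                    "barcode": clone.barcode,
                    "cells": int(cells_r),
                    "umis": n_umis,
                    "reads": n_reads,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample_id", "mouse", "compartment", "timepoint_months", "replicate",
            "clone_id", "barcode", "cells", "umis", "reads",
        ],
    )
    return reads_out, truth


def sample_metadata(spec: SampleSpec, gfp_fraction: float | None = None) -> pd.DataFrame:
    """Per-replicate sample-sheet rows for a simulated sample."""
    rows = {
        rid: {
            "mouse": spec.mouse,
            "compartment": spec.compartment,
            "timepoint_months": spec.timepoint_months,
            "replicate": r + 1,
            "sorted_cells": spec.cells_sampled,
            "gfp_fraction": gfp_fraction if gfp_fraction is not None else np.nan,
        }
        for r, rid in enumerate(spec.replicate_ids())
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) records as FASTQ (gzipped if path ends in .gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# -- longitudinal diversity dynamics ----------------------------------------


@dataclass(frozen=True)
class BreakpointDynamics:
    """Piecewise log-linear trajectory of expected clonal diversity.

    ``log mu_it = intercept + u_i + slope_before * t + slope_change * max(0, t - breakpoint)``
    with a per-mouse random intercept ``u_i ~ N(0, mouse_sd**2)`` and
    gamma-distributed observations of shape ``gamma_shape`` around ``mu_it``.
    Defaults mimic the observed blood trajectory: diversity declines for the
    first ~7 months after induction and rises linearly afterwards.
    """

    intercept: float = 5.8  # log expected diversity at t=0, median mouse
    slope_before: float = -0.15  # per month
    slope_change: float = 0.25  # slope after breakpoint = -0.15 + 0.25 = +0.10
    breakpoint: float = 7.0  # months post-induction
    mouse_sd: float = 0.3
    gamma_shape: float = 50.0

    def mean(self, t, u: float = 0.0) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.exp(
            self.intercept + u + self.slope_before * t + self.slope_change * np.maximum(0.0, t - self.breakpoint)
        )


def simulate_diversity_observations(
    dynamics: BreakpointDynamics,
    n_mice: int,
    timepoints,
    replicates: int = 2,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Long-format gamma-distributed diversity observations (mouse, t, replicate, y)."""
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for i in range(n_mice):
        u = dynamics.mouse_sd * rng.standard_normal()
        for t in timepoints:
            mu = float(dynamics.mean(t, u))
            for r in range(replicates):
                y = rng.gamma(dynamics.gamma_shape, mu / dynamics.gamma_shape)
                rows.append({"mouse": f"m{i + 1}", "t": float(t), "replicate": r + 1, "y": y})
    return pd.DataFrame(rows)


def simulate_timecourse(
    dynamics: BreakpointDynamics,
    n_mice: int,
    timepoints,
    model: GenerativeModel,
    reference: CassetteReference,
    rng: np.random.Generator,
    capture: float = 0.05,
    replicates: int = 2,
    depth: float = 200.0,
) -> tuple[BarcodeCountMatrix, pd.DataFrame]:
    """Longitudinal blood barcode matrices following a breakpoint trajectory.

    Each mouse carries a pool of barcoded clones; at each timepoint the
    number of clones active in blood follows the dynamics mean (Poisson
    realization), clone abundances are Dirichlet, and each PCR replicate
    captures each active clone independently with probability ``capture``
    (count 1 + Poisson(depth * abundance) when captured).  Returns the
    combined count matrix and a truth table (mouse, t, mu, n_active).
    """
    if not 0.0 < capture <= 1.0:
        raise ValueError("capture must lie in (0, 1]")
    timepoints = [float(t) for t in timepoints]
    max_mu = 0.0
    u_vals = dynamics.mouse_sd * rng.standard_normal(n_mice)
    for u in u_vals:
        max_mu = max(max_mu, float(np.max(dynamics.mean(timepoints, u))))
    pool_size = max(10, int(3 * max_mu))
    cols = {}
    meta = {}
    truth_rows = []
    for i in range(n_mice):
        mouse = f"m{i + 1}"
        _, pool = sample_recombinations(model, reference, pool_size, rng)
        pool = list(dict.fromkeys(pool))  # drop exact collisions within a mouse
        for t in timepoints:
            mu = float(dynamics.mean(t, u_vals[i]))
            n_active = min(len(pool), max(1, int(rng.poisson(mu))))
            active_idx = rng.choice(len(pool), size=n_active, replace=False)
            weights = rng.dirichlet(np.ones(n_active))
            for r in range(replicates):
                captured = rng.random(n_active) < capture
                counts = np.where(captured, 1 + rng.poisson(depth * weights), 0)
                sid = f"{mouse}|blood-M|t{t}|R{r + 1}"
                cols[sid] = {pool[k]: int(c) for k, c in zip(active_idx, counts) if c > 0}
                meta[sid] = {
                    "mouse": mouse,
                    "compartment": "blood-M",
                    "timepoint_months": t,
                    "replicate": r + 1,
                    "sorted_cells": np.nan,
                    "gfp_fraction": np.nan,
                }
            truth_rows.append({"mouse": mouse, "t": t, "mu": mu, "n_active": n_active})
    all_barcodes = sorted(set().union(*[set(c) for c in cols.values()]))
    counts = pd.DataFrame(
        {sid: [cols[sid].get(b, 0) for b in all_barcodes] for sid in cols},
        index=pd.Index(all_barcodes, name="barcode"),
        dtype=int,
    )
    samples = pd.DataFrame.from_dict(meta, orient="index")
    samples.index.name = "sample_id"
    return BarcodeCountMatrix(counts, samples), pd.DataFrame(truth_rows)
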