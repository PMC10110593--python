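"""Barcode calling: UMI extraction, per-UMI consensus, annotation, filtering.

The read architecture is ``UMI + constant anchor + recombined barcode
region``.  Reads are grouped by UMI, collapsed to a per-UMI consensus
(position-wise majority vote; ties discard the group so that barcode
identity stays exact), annotated against the cassette by the most
parsimonious recombination scenario, and tabulated into a barcode x sample
UMI count matrix.  Detection filtering requires a minimum UMI count in every
PCR replicate of a biological sample before replicates are summed.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .matrix import BarcodeCountMatrix
from .model import Bounds
from .recombination import RecombinationScenario, _side_windows, d_variants
from .reference import DEFAULT_LCONST, CassetteReference

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadLayout:
    """Positions of UMI, anchor and barcode region within a read."""

    umi_length: int = 8
    anchor: str = DEFAULT_LCONST
    anchor_max_mismatch: int = 1
    barcode_end: int | None = None  # None: barcode region runs to the read end

    def __post_init__(self) -> None:
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")

    @property
    def barcode_start(self) -> int:
        return self.umi_length + len(self.anchor)


class ExtractResult(NamedTuple):
    ok: bool
    umi: str
    insert: str
    reason: str


def extract_umi(read: str, layout: ReadLayout) -> ExtractResult:
    """Split a read into UMI and barcode insert; reject bad anchors."""
    end = layout.barcode_end if layout.barcode_end is not None else len(read)
    if len(read) < layout.barcode_start + 1 or end > len(read):
        return ExtractResult(False, "", "", "too_short")
    umi = read[: layout.umi_length]
    anchor_obs = read[layout.umi_length : layout.barcode_start]
    mism = sum(1 for x, y in zip(anchor_obs, layout.anchor) if x != y)
    if mism > layout.anchor_max_mismatch:
        return ExtractResult(False, umi, "", "anchor_mismatch")
    return ExtractResult(True, umi, read[layout.barcode_start : end], "")


def consensus_by_umi(
    groups: dict[str, list[str]], min_reads: int = 2
) -> tuple[dict[str, tuple[str, int]], dict[str, int]]:
    """Position-wise majority-vote consensus per UMI group.

    Groups with fewer than ``min_reads`` reads are dropped, as are groups
    with a tied vote at any position (conservative: barcode identity must be
    exact).  Reads whose length differs from the group's modal length are
    ignored in the vote.  Returns (consensus per UMI, QC tallies).
    """
    out: dict[str, tuple[str, int]] = {}
    qc = {"low_support": 0, "tie_discarded": 0, "accepted": 0}
    for umi, reads in groups.items():
        if len(reads) < min_reads:
            qc["low_support"] += 1
            continue
        lengths = Counter(len(r) for r in reads)
        modal_len = max(lengths, key=lambda k: (lengths[k], -k))
        votes = [r for r in reads if len(r) == modal_len]
        if len(votes) < min_reads:
            qc["low_support"] += 1
            continue
        cons = []
        tied = False
        for pos in range(modal_len):
            tally = Counter(r[pos] for r in votes)
            ranked = tally.most_common(2)
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                tied = True
                break
            cons.append(ranked[0][0])
        if tied:
            qc["tie_discarded"] += 1
            continue
        out[umi] = ("".join(cons), len(votes))
        qc["accepted"] += 1
    return out, qc


class BarcodeCall(NamedTuple):
    barcode: str
    inverted: bool
    del_v: int
    del_d5: int
    del_d3: int
    del_j: int
    n_ins_vd: int
    n_ins_dj: int


class CallRejection(NamedTuple):
    reason: str


def call_barcode(
    consensus: str,
    reference: CassetteReference,
    bounds: Bounds,
    min_v_match: int | None = None,
    min_j_match: int | None = None,
) -> BarcodeCall | CallRejection:
    """Annotate a consensus sequence with its parsimony recombination scenario.

    The chosen annotation maximizes total germline retention (minimal total
    trimming); ties are broken by fewer inserted nucleotides, then by
    lexicographic scenario order.  Sequences without a sufficient germline V
    prefix / J suffix match, containing N, or inconsistent with every
    in-bounds scenario are rejected with a reason code.
    """
    if set(consensus) - set("ACGT"):
        return CallRejection("ambiguous_base")
    if min_v_match is None:
        min_v_match = len(reference.v_seq) - bounds.max_del_v
    if min_j_match is None:
        min_j_match = len(reference.j_seq) - bounds.max_del_j
    a_vals, b_vals = _side_windows(reference, consensus, bounds)
    if not a_vals or (a_vals[-1] < min_v_match):
        return CallRejection("v_anchor")
    if not b_vals or (b_vals[-1] < min_j_match):
        return CallRejection("j_anchor")
    n = len(consensus)
    a_min, a_max = a_vals[0], a_vals[-1]
    y_min, y_max = n - b_vals[-1], n - b_vals[0]
    vlen, jlen = len(reference.v_seq), len(reference.j_seq)
    best: tuple | None = None
    for inverted, d5, d3, core in d_variants(reference, bounds):
        k = len(core)
        start = a_min
        while start <= y_max - k:
            if k:
                s = consensus.find(core, start, y_max)
                if s == -1:
                    break
            else:
                s = start
            e = s + k
            a_hi = min(a_max, s)
            y_lo = max(y_min, e)
            if a_hi >= max(a_min, s - bounds.max_ins) and y_lo <= min(y_max, e + bounds.max_ins):
                sc = RecombinationScenario(
                    inverted=inverted,
                    del_v=vlen - a_hi,
                    del_d5=d5,
                    del_d3=d3,
                    del_j=jlen - (n - y_lo),
                    ins_vd=consensus[a_hi:s],
                    ins_dj=consensus[e:y_lo],
                )
                key = (sc.total_deletions, sc.total_insertions, sc)
                if best is None or key < best:
                    best = key
            start = s + 1
    if best is None:
        return CallRejection("unannotatable")
    sc = best[2]
    return BarcodeCall(
        barcode=consensus,
        inverted=sc.inverted,
        del_v=sc.del_v,
        del_d5=sc.del_d5,
        del_d3=sc.del_d3,
        del_j=sc.del_j,
        n_ins_vd=len(sc.ins_vd),
        n_ins_dj=len(sc.ins_dj),
    )


# -- per-sample processing ---------------------------------------------------


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTQ(.gz) file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header[1:].split()[0], seq


def call_sample(
    reads: Iterable[tuple[str, str]],
    layout: ReadLayout,
    reference: CassetteReference,
    bounds: Bounds,
    min_reads: int = 2,
) -> tuple[list[BarcodeCall], dict]:
    """Process one sample's reads to per-UMI barcode calls plus QC tallies."""
    groups: dict[str, list[str]] = defaultdict(list)
    qc: dict[str, int] = Counter()
    for _, seq in reads:
        res = extract_umi(seq, layout)
        if not res.ok:
            qc[f"read_rejected_{res.reason}"] += 1
            continue
        qc["reads_extracted"] += 1
        groups[res.umi].append(res.insert)
    consensuses, cons_qc = consensus_by_umi(groups, min_reads=min_reads)
    qc.update({f"umi_{k}": v for k, v in cons_qc.items()})
    call_cache: dict[str, BarcodeCall | CallRejection] = {}
    calls: list[BarcodeCall] = []
    for umi, (cons, support) in consensuses.items():
        call = call_cache.get(cons)
        if call is None:
            call = call_barcode(cons, reference, bounds)
            call_cache[cons] = call
        if isinstance(call, CallRejection):
            qc[f"umi_rejected_{call.reason}"] += 1
        else:
            calls.append(call)
    qc["umis_called"] = len(calls)
    return calls, dict(qc)


def build_matrix(
    calls_by_sample: dict[str, list[BarcodeCall]], samples: pd.DataFrame
) -> BarcodeCountMatrix:
    """Tabulate per-UMI calls into a barcode x sample UMI count matrix."""
    sample_ids = list(samples.index)
    counters = {sid: Counter(c.barcode for c in calls_by_sample.get(sid, [])) for sid in sample_ids}
    barcodes = sorted(set().union(*[set(c) for c in counters.values()]) if counters else set())
    counts = pd.DataFrame(
        {sid: [counters[sid].get(b, 0) for b in barcodes] for sid in sample_ids},
        index=pd.Index(barcodes, name="barcode"),
        dtype=int,
    )
    ann_rows: dict[str, BarcodeCall] = {}
    for calls in calls_by_sample.values():
        for c in calls:
            ann_rows.setdefault(c.barcode, c)
    ann = pd.DataFrame(
        [
            {
                "inverted": c.inverted,
                "del_v": c.del_v,
                "del_d5": c.del_d5,
                "del_d3": c.del_d3,
                "del_j": c.del_j,
                "n_ins_vd": c.n_ins_vd,
                "n_ins_dj": c.n_ins_dj,
            }
            for c in (ann_rows[b] for b in barcodes)
        ],
        index=pd.Index(barcodes, name="barcode"),
    ) if barcodes else None
    return BarcodeCountMatrix(counts, samples.copy(), ann)


def filter_matrix(
    matrix: BarcodeCountMatrix, min_umis: int = 3, require_both_replicates: bool = True
) -> tuple[BarcodeCountMatrix, dict]:
    """Detection filter: per biological sample, keep a barcode only if it has
    at least ``min_umis`` UMIs in every PCR replicate (when required), then
    sum replicates into one column per biological sample."""
    groups = matrix.biological_groups()
    new_cols = {}
    meta_rows = {}
    report = {"groups": {}, "retained_barcodes": 0, "dropped_entries": 0}
    for key, sids in groups.items():
        sub = matrix.counts[sids]
        if require_both_replicates and len(sids) >= 2:
            keep = (sub >= min_umis).all(axis=1)
        else:
            keep = (sub.max(axis=1) >= min_umis) if min_umis else (sub.sum(axis=1) > 0)
        summed = sub.sum(axis=1).where(keep, 0)
        gid = f"{key[0]}|{key[1]}|t{key[2]}"
        new_cols[gid] = summed
        first = matrix.samples.loc[sids[0]]
        meta_rows[gid] = {
            "mouse": key[0],
            "compartment": key[1],
            "timepoint_months": key[2],
            "replicate": "pooled",
            "sorted_cells": first.get("sorted_cells", np.nan),
            "gfp_fraction": first.get("gfp_fraction", np.nan),
        }
        n_detected = int((sub.sum(axis=1) > 0).sum())
        n_kept = int(keep.sum())
        report["groups"][gid] = {"detected": n_detected, "retained": n_kept, "n_replicates": len(sids)}
        report["dropped_entries"] += n_detected - n_kept
    counts = pd.DataFrame(new_cols)
    counts = counts[(counts > 0).any(axis=1)]
    counts.index.name = "barcode"
    samples = pd.DataFrame.from_dict(meta_rows, orient="index")
    samples.index.name = "sample_id"
    ann = matrix.annotations.loc[counts.index] if matrix.annotations is not None else None
    report["retained_barcodes"] = counts.shape[0]
    return BarcodeCountMatrix(counts.astype(int), samples, ann), report


def normalize_and_transform(
    matrix: BarcodeCountMatrix, cofactor: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample fractions and arcsinh-transformed fractions."""
    frac = matrix.fractions()
    return frac, np.arcsinh(frac / cofactor)


def replicate_concordance(matrix: BarcodeCountMatrix, cofactor: float = 1.0) -> pd.DataFrame:
    """Jaccard overlap and Pearson correlation (on arcsinh fractions) between
    the two PCR replicates of each biological sample."""
    rows = []
    for key, sids in matrix.biological_groups().items():
        if len(sids) != 2:
            logger.warning("replicate_concordance: skipping %s (%d replicate(s))", key, len(sids))
            continue
        a, b = matrix.counts[sids[0]], matrix.counts[sids[1]]
        det_a, det_b = set(a.index[a > 0]), set(b.index[b > 0])
        union = det_a | det_b
        if not union:
            continue
        overlap = len(det_a & det_b) / len(union)
        ta = np.arcsinh((a / a.sum() if a.sum() else a).loc[sorted(union)] / cofactor)
        tb = np.arcsinh((b / b.sum() if b.sum() else b).loc[sorted(union)] / cofactor)
        r = float(_stats.pearsonr(ta, tb)[0]) if len(union) > 1 else np.nan
        rows.append(
            {
                "mouse": key[0],
                "compartment": key[1],
                "timepoint_months": key[2],
                "overlap": overlap,
                "correlation": r,
                "n_union": len(union),
            }
        )
    return pd.DataFrame(rows)
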