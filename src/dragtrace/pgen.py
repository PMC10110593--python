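"""Generation probability (P_gen) and expectation-maximization model fitting.

P_gen of a barcode is the total probability of all recombination scenarios
that realize it.  Explicit enumeration of scenarios is exponential in the
junction ambiguity, so the engine factorizes the sum: for a fixed placement
of the (trimmed, possibly inverted) D core inside the sequence, the V-side
choices (V trim + left insertion) and J-side choices (J trim + right
insertion) are independent and can be pre-summed per junction position.
The same factorization yields exact expected sufficient statistics for the
EM E-step without materializing scenarios.
"""

from __future__ import annotations

import logging
from array import array
from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import Bounds, GenerativeModel, uniform_model
from .reference import NT_INDEX, CassetteReference
from .recombination import _side_windows, d_variants, enumerate_scenarios, scenario_probability

logger = logging.getLogger(__name__)


# -- static (model-independent) consistency structure ------------------------


@dataclass
class _Combos:
    inv: np.ndarray  # int8, per combo
    d5: np.ndarray  # int64
    d3: np.ndarray  # int64
    core_groups: dict  # core string -> list of combo indices


def _build_combos(reference: CassetteReference, bounds: Bounds) -> _Combos:
    variants = d_variants(reference, bounds)
    inv = np.array([int(v[0]) for v in variants], dtype=np.int8)
    d5 = np.array([v[1] for v in variants], dtype=np.int64)
    d3 = np.array([v[2] for v in variants], dtype=np.int64)
    groups: dict[str, list[int]] = {}
    for idx, (_, _, _, core) in enumerate(variants):
        groups.setdefault(core, []).append(idx)
    return _Combos(inv=inv, d5=d5, d3=d3, core_groups=groups)


@dataclass
class _Workspace:
    """Flat per-sequence structure shared by the P_gen and E-step kernels."""

    codes: np.ndarray
    seq_off: np.ndarray
    a_flat: np.ndarray
    a_off: np.ndarray
    b_flat: np.ndarray
    b_off: np.ndarray
    m_combo: np.ndarray
    m_s: np.ndarray
    m_e: np.ndarray
    m_off: np.ndarray
    producible: np.ndarray  # bool per input sequence


def _encode(sequence: str) -> np.ndarray | None:
    codes = np.empty(len(sequence), dtype=np.int8)
    for i, ch in enumerate(sequence):
        idx = NT_INDEX.get(ch)
        if idx is None:
            return None
        codes[i] = idx
    return codes


def _build_workspace(
    reference: CassetteReference, sequences: list[str], bounds: Bounds, combos: _Combos
) -> _Workspace:
    codes_flat = array("b")
    seq_off = array("q", [0])
    a_flat = array("q")
    a_off = array("q", [0])
    b_flat = array("q")
    b_off = array("q", [0])
    m_combo = array("q")
    m_s = array("q")
    m_e = array("q")
    m_off = array("q", [0])
    producible = np.zeros(len(sequences), dtype=bool)
    max_ins = bounds.max_ins

    for si, seq in enumerate(sequences):
        codes = _encode(seq)
        ok = codes is not None
        a_vals: list[int] = []
        b_vals: list[int] = []
        if ok:
            a_vals, b_vals = _side_windows(reference, seq, bounds)
            ok = bool(a_vals) and bool(b_vals)
        n_match = 0
        if ok:
            n = len(seq)
            a_min, a_max = a_vals[0], a_vals[-1]
            y_min, y_max = n - b_vals[-1], n - b_vals[0]
            smin, smax = a_min, min(a_max + max_ins, y_max)
            emin, emax = max(y_min - max_ins, a_min), y_max
            for core, ids in combos.core_groups.items():
                k = len(core)
                if k == 0:
                    lo, hi = max(smin, emin), min(smax, emax)
                    for s in range(lo, hi + 1):
                        for c in ids:
                            m_combo.append(c)
                            m_s.append(s)
                            m_e.append(s)
                            n_match += 1
                else:
                    start = smin
                    while True:
                        s = seq.find(core, start, emax)
                        if s == -1 or s > smax:
                            break
                        e = s + k
                        if e >= emin:
                            for c in ids:
                                m_combo.append(c)
                                m_s.append(s)
                                m_e.append(e)
                                n_match += 1
                        start = s + 1
        if ok and n_match > 0:
            producible[si] = True
            codes_flat.extend(codes.tolist())
            a_flat.extend(a_vals)
            b_flat.extend(b_vals)
        else:
            # roll back any matches appended for a sequence later found dead
            del m_combo[m_off[-1] :]
            del m_s[m_off[-1] :]
            del m_e[m_off[-1] :]
        seq_off.append(len(codes_flat))
        a_off.append(len(a_flat))
        b_off.append(len(b_flat))
        m_off.append(len(m_combo))

    as_np = lambda arr, dt: np.frombuffer(arr, dtype=dt).copy() if len(arr) else np.empty(0, dtype=dt)
    return _Workspace(
        codes=as_np(codes_flat, np.int8),
        seq_off=np.asarray(seq_off, dtype=np.int64),
        a_flat=np.asarray(a_flat, dtype=np.int64) if len(a_flat) else np.empty(0, dtype=np.int64),
        a_off=np.asarray(a_off, dtype=np.int64),
        b_flat=np.asarray(b_flat, dtype=np.int64) if len(b_flat) else np.empty(0, dtype=np.int64),
        b_off=np.asarray(b_off, dtype=np.int64),
        m_combo=np.asarray(m_combo, dtype=np.int64) if len(m_combo) else np.empty(0, dtype=np.int64),
        m_s=np.asarray(m_s, dtype=np.int64) if len(m_s) else np.empty(0, dtype=np.int64),
        m_e=np.asarray(m_e, dtype=np.int64) if len(m_e) else np.empty(0, dtype=np.int64),
        m_off=np.asarray(m_off, dtype=np.int64),
        producible=producible,
    )


# -- numba kernel ------------------------------------------------------------


@njit(cache=True)
def _engine(
    codes,
    seq_off,
    a_flat,
    a_off,
    b_flat,
    b_off,
    m_combo,
    m_s,
    m_e,
    m_off,
    weights,
    c_inv,
    c_d5,
    c_d3,
    vlen,
    jlen,
    max_ins,
    p_del_v,
    p_d5,
    p_d3,
    p_del_j,
    p_ins1,
    p_ins2,
    p_nt,
    p_inv,
    compute_stats,
    cnt_del_v,
    cnt_d5,
    cnt_d3,
    cnt_del_j,
    cnt_ins1,
    cnt_ins2,
    cnt_nt,
    cnt_inv,
    pgen_out,
):
    n_seq = seq_off.size - 1
    n_combo = c_inv.size
    w_combo = np.empty(n_combo)
    for c in range(n_combo):
        w = p_inv if c_inv[c] == 1 else 1.0 - p_inv
        w_combo[c] = w * p_d5[c_d5[c]] * p_d3[c_d3[c]]

    n_max = 0
    for i in range(n_seq):
        n = seq_off[i + 1] - seq_off[i]
        if n > n_max:
            n_max = n

    clog = np.zeros(n_max + 1)
    cbase = np.zeros((4, n_max + 1))
    Lw = np.zeros(n_max + 1)
    Rw = np.zeros(n_max + 1)
    GL = np.zeros(n_max + 1)
    GR = np.zeros(n_max + 1)
    loc_d5 = np.zeros(p_d5.size)
    loc_d3 = np.zeros(p_d3.size)

    loglik = 0.0
    for i in range(n_seq):
        o = seq_off[i]
        n = seq_off[i + 1] - o
        if m_off[i + 1] == m_off[i]:
            pgen_out[i] = 0.0
            continue
        for t in range(n):
            b = codes[o + t]
            clog[t + 1] = clog[t] + np.log(p_nt[b])
            for k in range(4):
                cbase[k, t + 1] = cbase[k, t]
            cbase[b, t + 1] += 1.0
        for t in range(n + 1):
            Lw[t] = 0.0
            Rw[t] = 0.0
            GL[t] = 0.0
            GR[t] = 0.0
        # V side: prefix length a, left-insertion length l1
        for ai in range(a_off[i], a_off[i + 1]):
            a = a_flat[ai]
            base = p_del_v[vlen - a]
            lmax = max_ins
            if n - a < lmax:
                lmax = n - a
            for l1 in range(lmax + 1):
                s = a + l1
                Lw[s] += base * p_ins1[l1] * np.exp(clog[s] - clog[a])
        # J side: suffix length b, right-insertion length l2
        for bi in range(b_off[i], b_off[i + 1]):
            bct = b_flat[bi]
            y = n - bct
            base = p_del_j[jlen - bct]
            lmax = max_ins
            if y < lmax:
                lmax = y
            for l2 in range(lmax + 1):
                e = y - l2
                Rw[e] += base * p_ins2[l2] * np.exp(clog[y] - clog[e])
        # D placements
        P = 0.0
        inv0 = 0.0
        inv1 = 0.0
        for mi in range(m_off[i], m_off[i + 1]):
            c = m_combo[mi]
            s = m_s[mi]
            e = m_e[mi]
            part = w_combo[c] * Rw[e]
            contrib = part * Lw[s]
            P += contrib
            if compute_stats:
                GL[s] += part
                GR[e] += w_combo[c] * Lw[s]
                if c_inv[c] == 1:
                    inv1 += contrib
                else:
                    inv0 += contrib
                loc_d5[c_d5[c]] += contrib
                loc_d3[c_d3[c]] += contrib
        pgen_out[i] = P
        if P <= 0.0:
            if compute_stats:
                for k in range(p_d5.size):
                    loc_d5[k] = 0.0
                for k in range(p_d3.size):
                    loc_d3[k] = 0.0
            continue
        loglik += weights[i] * np.log(P)
        if not compute_stats:
            continue
        scale = weights[i] / P
        cnt_inv[0] += inv0 * scale
        cnt_inv[1] += inv1 * scale
        for k in range(p_d5.size):
            cnt_d5[k] += loc_d5[k] * scale
            loc_d5[k] = 0.0
        for k in range(p_d3.size):
            cnt_d3[k] += loc_d3[k] * scale
            loc_d3[k] = 0.0
        # posterior V-side statistics
        for ai in range(a_off[i], a_off[i + 1]):
            a = a_flat[ai]
            base = p_del_v[vlen - a]
            lmax = max_ins
            if n - a < lmax:
                lmax = n - a
            for l1 in range(lmax + 1):
                s = a + l1
                g = GL[s]
                if g > 0.0:
                    t = base * p_ins1[l1] * np.exp(clog[s] - clog[a]) * g * scale
                    cnt_del_v[vlen - a] += t
                    cnt_ins1[l1] += t
                    for k in range(4):
                        cnt_nt[k] += t * (cbase[k, s] - cbase[k, a])
        # posterior J-side statistics
        for bi in range(b_off[i], b_off[i + 1]):
            bct = b_flat[bi]
            y = n - bct
            base = p_del_j[jlen - bct]
            lmax = max_ins
            if y < lmax:
                lmax = y
            for l2 in range(lmax + 1):
                e = y - l2
                g = GR[e]
                if g > 0.0:
                    t = base * p_ins2[l2] * np.exp(clog[y] - clog[e]) * g * scale
                    cnt_del_j[jlen - bct] += t
                    cnt_ins2[l2] += t
                    for k in range(4):
                        cnt_nt[k] += t * (cbase[k, y] - cbase[k, e])
    return loglik


def _run_engine(
    ws: _Workspace,
    combos: _Combos,
    model: GenerativeModel,
    reference: CassetteReference,
    max_ins: int,
    weights: np.ndarray,
    compute_stats: bool,
):
    n_seq = ws.seq_off.size - 1
    cnt = {
        "del_v": np.zeros(model.p_del_v.size),
        "d5": np.zeros(model.p_del_d5.size),
        "d3": np.zeros(model.p_del_d3.size),
        "del_j": np.zeros(model.p_del_j.size),
        "ins1": np.zeros(model.p_ins_vd.size),
        "ins2": np.zeros(model.p_ins_dj.size),
        "nt": np.zeros(4),
        "inv": np.zeros(2),
    }
    pgen = np.zeros(n_seq)
    loglik = _engine(
        ws.codes,
        ws.seq_off,
        ws.a_flat,
        ws.a_off,
        ws.b_flat,
        ws.b_off,
        ws.m_combo,
        ws.m_s,
        ws.m_e,
        ws.m_off,
        weights,
        combos.inv,
        combos.d5,
        combos.d3,
        len(reference.v_seq),
        len(reference.j_seq),
        max_ins,
        model.p_del_v,
        model.p_del_d5,
        model.p_del_d3,
        model.p_del_j,
        model.p_ins_vd,
        model.p_ins_dj,
        model.p_nt,
        model.p_inv,
        compute_stats,
        cnt["del_v"],
        cnt["d5"],
        cnt["d3"],
        cnt["del_j"],
        cnt["ins1"],
        cnt["ins2"],
        cnt["nt"],
        cnt["inv"],
        pgen,
    )
    return loglik, pgen, cnt


# -- public API --------------------------------------------------------------


def compute_pgen_many(
    model: GenerativeModel,
    reference: CassetteReference,
    sequences,
    bounds: Bounds | None = None,
) -> np.ndarray:
    """Exact P_gen for each sequence (factorized sum over all scenarios)."""
    sequences = list(sequences)
    model.validate_against(reference)
    if bounds is None:
        bounds = model.bounds
    bounds.validate_against(reference)
    combos = _build_combos(reference, bounds)
    ws = _build_workspace(reference, sequences, bounds, combos)
    weights = np.ones(len(sequences))
    _, pgen, _ = _run_engine(ws, combos, model, reference, bounds.max_ins, weights, False)
    return pgen


def compute_pgen(
    model: GenerativeModel,
    reference: CassetteReference,
    sequence: str,
    bounds: Bounds | None = None,
    method: str = "factorized",
) -> float:
    """P_gen of one sequence.

    ``method='factorized'`` uses the junction-factorized engine;
    ``method='enumerate'`` sums ``scenario_probability`` over the explicit
    scenario set (exponentially slower; retained as an independent check).
    """
    if method == "enumerate":
        if bounds is None:
            bounds = model.bounds
        return float(
            sum(scenario_probability(model, sc) for sc in enumerate_scenarios(reference, sequence, bounds))
        )
    if method != "factorized":
        raise ValueError(f"unknown method {method!r}")
    return float(compute_pgen_many(model, reference, [sequence], bounds=bounds)[0])


@dataclass
class EMResult:
    """Outcome of EM fitting; ``model`` holds the fitted parameters."""

    model: GenerativeModel
    loglik_history: np.ndarray  # data log-likelihood at the start of each iteration
    objective_history: np.ndarray  # penalized objective (loglik + Dirichlet prior terms)
    n_sequences: int
    n_excluded: int
    n_iter: int
    converged: bool


def _m_step(counts: np.ndarray, pseudo: float) -> np.ndarray:
    out = counts + pseudo
    return out / out.sum()


def _param_vector(model: GenerativeModel) -> np.ndarray:
    return np.concatenate(
        [
            model.p_del_v,
            model.p_del_d5,
            model.p_del_d3,
            model.p_del_j,
            model.p_ins_vd,
            model.p_ins_dj,
            model.p_nt,
            [model.p_inv],
        ]
    )


def _log_prior(model: GenerativeModel, pseudo: float) -> float:
    if pseudo == 0.0:
        return 0.0
    with np.errstate(divide="ignore"):
        terms = [
            np.sum(pseudo * np.log(arr))
            for arr in (
                model.p_del_v,
                model.p_del_d5,
                model.p_del_d3,
                model.p_del_j,
                model.p_ins_vd,
                model.p_ins_dj,
                model.p_nt,
            )
        ]
    inv = pseudo * (np.log(model.p_inv) + np.log(1.0 - model.p_inv)) if 0 < model.p_inv < 1 else -np.inf
    return float(sum(terms) + inv)


def fit_model(
    sequences,
    reference: CassetteReference,
    bounds: Bounds | None = None,
    init: GenerativeModel | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    pseudocount: float = 0.5,
) -> EMResult:
    """Fit the generative model to observed barcode sequences by EM.

    E-step: each scenario consistent with a sequence is weighted by its
    normalized probability under the current model (computed exactly via the
    factorized engine).  M-step: each categorical is set to the expected-count
    empirical distribution with ``pseudocount`` added per category (MAP-EM
    under a symmetric Dirichlet prior; the penalized objective is guaranteed
    non-decreasing, and the data log-likelihood is recorded per iteration).

    Sequences with no consistent scenario are excluded with a logged warning;
    if no sequence is producible a ``ValueError`` is raised.  Duplicate
    sequences are collapsed to weighted unique sequences internally.
    """
    sequences = list(sequences)
    if bounds is None:
        bounds = Bounds.default(reference)
    bounds.validate_against(reference)
    if init is None:
        init = uniform_model(bounds)
    init.validate_against(reference)

    uniq: dict[str, int] = {}
    for s in sequences:
        uniq[s] = uniq.get(s, 0) + 1
    uniq_seqs = list(uniq.keys())
    weights = np.array([uniq[s] for s in uniq_seqs], dtype=float)

    combos = _build_combos(reference, bounds)
    ws = _build_workspace(reference, uniq_seqs, bounds, combos)
    n_excluded = int(weights[~ws.producible].sum())
    if n_excluded:
        logger.warning("fit_model: excluded %d sequence(s) with no consistent scenario", n_excluded)
    if not ws.producible.any():
        raise ValueError("no input sequence is producible under the given reference and bounds")
    weights = weights * ws.producible  # dead sequences contribute nothing

    model = init
    loglik_hist = []
    obj_hist = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        loglik, _, cnt = _run_engine(ws, combos, model, reference, bounds.max_ins, weights, True)
        loglik_hist.append(loglik)
        obj_hist.append(loglik + _log_prior(model, pseudocount))
        n_tot = cnt["inv"].sum()
        new = GenerativeModel(
            p_del_v=_m_step(cnt["del_v"], pseudocount),
            p_del_d5=_m_step(cnt["d5"], pseudocount),
            p_del_d3=_m_step(cnt["d3"], pseudocount),
            p_del_j=_m_step(cnt["del_j"], pseudocount),
            p_ins_vd=_m_step(cnt["ins1"], pseudocount),
            p_ins_dj=_m_step(cnt["ins2"], pseudocount),
            p_nt=_m_step(cnt["nt"], pseudocount),
            p_inv=float((cnt["inv"][1] + pseudocount) / (n_tot + 2 * pseudocount)),
        )
        delta = float(np.max(np.abs(_param_vector(new) - _param_vector(model))))
        model = new
        if delta < tol:
            converged = True
            break
    final_loglik, _, _ = _run_engine(ws, combos, model, reference, bounds.max_ins, weights, False)
    loglik_hist.append(final_loglik)
    obj_hist.append(final_loglik + _log_prior(model, pseudocount))
    return EMResult(
        model=model,
        loglik_history=np.array(loglik_hist),
        objective_history=np.array(obj_hist),
        n_sequences=len(sequences),
        n_excluded=n_excluded,
        n_iter=n_iter,
        converged=converged,
    )
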