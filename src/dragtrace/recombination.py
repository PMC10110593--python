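"""Recombination scenarios: realization, probability, enumeration, sampling.

A scenario fully specifies one recombination event: whether the D segment is
inverted, how many bases are trimmed at each of the four sites, and the
untemplated strings inserted at the two junctions.  ``realize_scenario`` maps
a scenario deterministically to a barcode sequence; ``enumerate_scenarios``
inverts that map (a sequence is typically consistent with many scenarios
because inserted bases may coincide with germline ends).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .model import Bounds, GenerativeModel
from .reference import NT_ALPHABET, NT_INDEX, CassetteReference


class RecombinationScenario(NamedTuple):
    inverted: bool
    del_v: int
    del_d5: int
    del_d3: int
    del_j: int
    ins_vd: str
    ins_dj: str

    @property
    def total_deletions(self) -> int:
        return self.del_v + self.del_d5 + self.del_d3 + self.del_j

    @property
    def total_insertions(self) -> int:
        return len(self.ins_vd) + len(self.ins_dj)


def _check_scenario(reference: CassetteReference, scenario: RecombinationScenario) -> None:
    if min(scenario.del_v, scenario.del_d5, scenario.del_d3, scenario.del_j) < 0:
        raise ValueError("trim counts must be nonnegative")
    if scenario.del_v > len(reference.v_seq):
        raise ValueError("del_v exceeds V length")
    if scenario.del_j > len(reference.j_seq):
        raise ValueError("del_j exceeds J length")
    if scenario.del_d5 + scenario.del_d3 > len(reference.d_seq):
        raise ValueError("del_d5 + del_d3 exceeds D length")


def realize_scenario(reference: CassetteReference, scenario: RecombinationScenario) -> str:
    """Deterministic barcode sequence produced by a scenario.

    The V segment is trimmed at its 3' end, J at its 5' end, and D (after
    optional reverse-complement) at both ends in the post-orientation frame;
    junction insertions are placed between the trimmed segments.
    """
    _check_scenario(reference, scenario)
    v = reference.v_seq[: len(reference.v_seq) - scenario.del_v]
    d = reference.d_revcomp if scenario.inverted else reference.d_seq
    d = d[scenario.del_d5 : len(d) - scenario.del_d3]
    j = reference.j_seq[scenario.del_j :]
    return v + scenario.ins_vd + d + scenario.ins_dj + j


def scenario_probability(model: GenerativeModel, scenario: RecombinationScenario) -> float:
    """Product-form probability of a scenario under the model.

    Scenarios outside the model support (trim or insertion length beyond the
    categorical array, or an inserted character off the alphabet) have
    probability 0.
    """
    p = model.p_inv if scenario.inverted else 1.0 - model.p_inv
    for arr, k in (
        (model.p_del_v, scenario.del_v),
        (model.p_del_d5, scenario.del_d5),
        (model.p_del_d3, scenario.del_d3),
        (model.p_del_j, scenario.del_j),
        (model.p_ins_vd, len(scenario.ins_vd)),
        (model.p_ins_dj, len(scenario.ins_dj)),
    ):
        if k < 0 or k >= arr.size:
            return 0.0
        p *= arr[k]
    for base in scenario.ins_vd + scenario.ins_dj:
        idx = NT_INDEX.get(base)
        if idx is None:
            return 0.0
        p *= model.p_nt[idx]
    return float(p)


# -- consistency structure shared with the P_gen engine ----------------------


def longest_prefix_match(sequence: str, segment: str) -> int:
    n = min(len(sequence), len(segment))
    for i in range(n):
        if sequence[i] != segment[i]:
            return i
    return n


def longest_suffix_match(sequence: str, segment: str) -> int:
    n = min(len(sequence), len(segment))
    for i in range(1, n + 1):
        if sequence[-i] != segment[-i]:
            return i - 1
    return n


def d_variants(reference: CassetteReference, bounds: Bounds) -> list[tuple[bool, int, int, str]]:
    """All (inverted, del_d5, del_d3, trimmed core) combinations in bounds."""
    out = []
    dlen = len(reference.d_seq)
    for inverted, d in ((False, reference.d_seq), (True, reference.d_revcomp)):
        for d5 in range(min(bounds.max_del_d5, dlen) + 1):
            for d3 in range(min(bounds.max_del_d3, dlen - d5) + 1):
                out.append((inverted, d5, d3, d[d5 : dlen - d3]))
    return out


def _side_windows(reference: CassetteReference, sequence: str, bounds: Bounds):
    """Valid V-prefix lengths ``a`` and J-suffix lengths ``b`` for a sequence."""
    n = len(sequence)
    lv = longest_prefix_match(sequence, reference.v_seq)
    lj = longest_suffix_match(sequence, reference.j_seq)
    a_lo = max(0, len(reference.v_seq) - bounds.max_del_v)
    b_lo = max(0, len(reference.j_seq) - bounds.max_del_j)
    a_vals = [a for a in range(a_lo, lv + 1) if a <= n]
    b_vals = [b for b in range(b_lo, lj + 1) if b <= n]
    return a_vals, b_vals


def enumerate_scenarios(
    reference: CassetteReference, sequence: str, bounds: Bounds
) -> list[RecombinationScenario]:
    """All scenarios within bounds whose realization equals ``sequence``.

    Returns a lexicographically sorted list (fields in declaration order).
    An unproducible sequence yields an empty list.
    """
    if set(sequence) - set(NT_ALPHABET):
        return []
    n = len(sequence)
    a_vals, b_vals = _side_windows(reference, sequence, bounds)
    if not a_vals or not b_vals:
        return []
    a_set = set(a_vals)
    b_set = set(b_vals)
    a_min = a_vals[0]
    y_max = n - b_vals[0]
    vlen, jlen = len(reference.v_seq), len(reference.j_seq)
    found: list[RecombinationScenario] = []
    for inverted, d5, d3, core in d_variants(reference, bounds):
        k = len(core)
        # candidate D placements [s, s+k) inside the feasible middle window
        for s in range(a_min, y_max - k + 1):
            if k and sequence.find(core, s, s + k) != s:
                continue
            e = s + k
            for a in range(max(a_min, s - bounds.max_ins), s + 1):
                if a not in a_set:
                    continue
                for y in range(e, min(y_max, e + bounds.max_ins) + 1):
                    if (n - y) not in b_set:
                        continue
                    found.append(
                        RecombinationScenario(
                            inverted=inverted,
                            del_v=vlen - a,
                            del_d5=d5,
                            del_d3=d3,
                            del_j=jlen - (n - y),
                            ins_vd=sequence[a:s],
                            ins_dj=sequence[e:y],
                        )
                    )
    found.sort()
    return found


# -- forward sampling --------------------------------------------------------


def _sample_counts(rng: np.random.Generator, p: np.ndarray, n: int) -> np.ndarray:
    return rng.choice(p.size, size=n, p=p)


def sample_recombinations(
    model: GenerativeModel,
    reference: CassetteReference,
    n: int,
    rng: np.random.Generator,
) -> tuple[list[RecombinationScenario], list[str]]:
    """Draw ``n`` independent recombination events; vectorized over draws."""
    model.validate_against(reference)
    inv = rng.random(n) < model.p_inv
    del_v = _sample_counts(rng, model.p_del_v, n)
    del_d5 = _sample_counts(rng, model.p_del_d5, n)
    del_d3 = _sample_counts(rng, model.p_del_d3, n)
    del_j = _sample_counts(rng, model.p_del_j, n)
    len_vd = _sample_counts(rng, model.p_ins_vd, n)
    len_dj = _sample_counts(rng, model.p_ins_dj, n)
    total_ins = int(len_vd.sum() + len_dj.sum())
    bases = rng.choice(4, size=total_ins, p=model.p_nt)
    letters = np.array(list(NT_ALPHABET))
    scenarios: list[RecombinationScenario] = []
    sequences: list[str] = []
    pos = 0
    for i in range(n):
        l1, l2 = int(len_vd[i]), int(len_dj[i])
        ins_vd = "".join(letters[bases[pos : pos + l1]])
        pos += l1
        ins_dj = "".join(letters[bases[pos : pos + l2]])
        pos += l2
        sc = RecombinationScenario(
            inverted=bool(inv[i]),
            del_v=int(del_v[i]),
            del_d5=int(del_d5[i]),
            del_d3=int(del_d3[i]),
            del_j=int(del_j[i]),
            ins_vd=ins_vd,
            ins_dj=ins_dj,
        )
        scenarios.append(sc)
        sequences.append(realize_scenario(reference, sc))
    return scenarios, sequences


def sample_recombination(
    model: GenerativeModel, reference: CassetteReference, rng: np.random.Generator
) -> tuple[RecombinationScenario, str]:
    """Draw a single recombination event (scenario, realized sequence)."""
    scenarios, sequences = sample_recombinations(model, reference, 1, rng)
    return scenarios[0], sequences[0]
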