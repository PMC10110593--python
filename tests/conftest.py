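"""Shared fixtures: micro cassettes with exhaustively enumerable scenario
spaces, the default full-size cassette/model, and brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from dragtrace.model import Bounds, GenerativeModel, default_model, truncated_geometric
from dragtrace.recombination import RecombinationScenario, realize_scenario, scenario_probability
from dragtrace.reference import CassetteReference, default_reference


@pytest.fixture(scope="session")
def micro_ref() -> CassetteReference:
    return CassetteReference(v_seq="ACGTA", d_seq="AGT", j_seq="GCAAT", left_const="AA", right_const="TT")


@pytest.fixture(scope="session")
def micro_bounds() -> Bounds:
    return Bounds(max_del_v=2, max_del_d5=1, max_del_d3=2, max_del_j=2, max_ins=2)


@pytest.fixture(scope="session")
def micro_model() -> GenerativeModel:
    return GenerativeModel(
        p_del_v=truncated_geometric(0.5, 2),
        p_del_d5=truncated_geometric(0.6, 1),
        p_del_d3=truncated_geometric(0.4, 2),
        p_del_j=truncated_geometric(0.5, 2),
        p_ins_vd=truncated_geometric(0.5, 2),
        p_ins_dj=truncated_geometric(0.55, 2),
        p_nt=[0.2, 0.3, 0.3, 0.2],
        p_inv=0.12,
    )


def brute_force_pgen_table(
    reference: CassetteReference, model: GenerativeModel, bounds: Bounds
) -> dict[str, float]:
    """Independent oracle: enumerate every scenario within bounds by direct
    product iteration and accumulate probability per realized sequence."""
    table: dict[str, float] = {}
    ins_space = [
        "".join(t)
        for ln in range(bounds.max_ins + 1)
        for t in itertools.product("ACGT", repeat=ln)
    ]
    for inverted in (False, True):
        for del_v in range(bounds.max_del_v + 1):
            for del_d5 in range(bounds.max_del_d5 + 1):
                for del_d3 in range(bounds.max_del_d3 + 1):
                    if del_d5 + del_d3 > len(reference.d_seq):
                        continue
                    for del_j in range(bounds.max_del_j + 1):
                        for ins_vd in ins_space:
                            for ins_dj in ins_space:
                                sc = RecombinationScenario(
                                    inverted, del_v, del_d5, del_d3, del_j, ins_vd, ins_dj
                                )
                                p = scenario_probability(model, sc)
                                if p > 0:
                                    seq = realize_scenario(reference, sc)
                                    table[seq] = table.get(seq, 0.0) + p
    return table


@pytest.fixture(scope="session")
def micro_pgen_table(micro_ref, micro_model, micro_bounds) -> dict[str, float]:
    return brute_force_pgen_table(micro_ref, micro_model, micro_bounds)


@pytest.fixture(scope="session")
def full_ref() -> CassetteReference:
    return default_reference()


@pytest.fixture(scope="session")
def full_model(full_ref) -> GenerativeModel:
    return default_model(full_ref)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
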