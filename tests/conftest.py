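"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from semgo import decompose, parse_obo
from semgo.fixtures import make_fixture_ontology
from semgo.ranker import REL_ORDER, SCOPE_ORDER, WeightConfig
from semgo.search_engine import FrequencyVector

# A hand-written 10-stanza OBO: 4 cellular components (one obsolete),
# 3 molecular functions, 3 biological processes.
TINY_OBO = """\
format-version: 1.2

[Term]
id: T:0001
name: alpha compartment
namespace: cellular_component

[Term]
id: T:0002
name: beta compartment
namespace: cellular_component
synonym: "beta sac" EXACT []
is_a: T:0001 ! alpha compartment

[Term]
id: T:0003
name: gamma compartment
namespace: cellular_component
relationship: part_of T:0001 ! alpha compartment

[Term]
id: T:0004
name: delta compartment
namespace: cellular_component
is_obsolete: true

[Term]
id: T:0005
name: alpha activity
namespace: molecular_function
synonym: "alpha catalysis" NARROW []
synonym: "broad alpha work" BROAD []

[Term]
id: T:0006
name: beta activity
namespace: molecular_function
relationship: regulates T:0005 ! alpha activity

[Term]
id: T:0007
name: gamma activity
namespace: molecular_function
relationship: has_part T:0005 ! alpha activity

[Term]
id: T:0008
name: alpha pathway
namespace: biological_process
synonym: "alpha cascade" RELATED []

[Term]
id: T:0009
name: beta pathway
namespace: biological_process
is_a: T:0008 ! alpha pathway

[Term]
id: T:0010
name: gamma pathway
namespace: biological_process
relationship: part_of T:0008 ! alpha pathway
"""


@pytest.fixture()
def tiny_terms():
    return parse_obo(TINY_OBO)


@pytest.fixture()
def tiny_store(tiny_terms):
    return decompose(tiny_terms)


@pytest.fixture()
def core_obo():
    """Fixture ontology holding exactly the hand-coded GO concept records."""
    return make_fixture_ontology()


@pytest.fixture()
def core_store(core_obo):
    return decompose(parse_obo(core_obo))


# -- independent oracles -----------------------------------------------------


def brute_count(text: str, surface: str) -> int:
    """Character-window occurrence oracle, independent of the implementation."""
    t, s = text.lower(), surface.lower()
    n = 0
    for i in range(len(t) - len(s) + 1):
        if t[i : i + len(s)] != s:
            continue
        pre = i == 0 or not t[i - 1].isalnum()
        post = i + len(s) == len(t) or not t[i + len(s)].isalnum()
        if pre and post:
            n += 1
    return n


def brute_rank(vec: FrequencyVector, w: WeightConfig) -> float:
    """Term-by-term weighted-sum oracle for the ranking formula."""
    syn_w = dict(zip(SCOPE_ORDER, w.w_syn))
    rel_w = dict(zip(REL_ORDER, w.w_rel))
    total = w.w_t * vec.t_cc + w.w_t * vec.t_mf + w.w_t * vec.t_bp
    for lst in (vec.s_cc, vec.s_mf, vec.s_bp):
        for scope, freq in lst:
            total += syn_w[scope] * freq
    for lst in (vec.r_cc, vec.r_mf, vec.r_bp):
        for rtype, freq in lst:
            total += rel_w[rtype] * freq
    return total


def random_vector(rng: random.Random) -> FrequencyVector:
    def class_list(classes):
        return [
            (rng.choice(classes), rng.randint(0, 9))
            for _ in range(rng.randint(0, 4))
        ]

    return FrequencyVector(
        t_cc=rng.randint(0, 9),
        t_mf=rng.randint(0, 9),
        t_bp=rng.randint(0, 9),
        r_cc=class_list(REL_ORDER),
        r_mf=class_list(REL_ORDER),
        r_bp=class_list(REL_ORDER),
        s_cc=class_list(SCOPE_ORDER),
        s_mf=class_list(SCOPE_ORDER),
        s_bp=class_list(SCOPE_ORDER),
    )


def random_weights(rng: random.Random) -> WeightConfig:
    return WeightConfig(
        w_t=round(rng.uniform(0, 20), 3),
        w_syn=tuple(round(rng.uniform(0, 20), 3) for _ in range(4)),
        w_rel=tuple(round(rng.uniform(0, 20), 3) for _ in range(4)),
    )
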