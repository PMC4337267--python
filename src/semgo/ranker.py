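"""Weighted document ranking.

Each retrieved document is scored with the weighted sum

    D_Rank = W_T * (T_cc + T_mf + T_bp)
           + sum_i S_i * W_syn(i)
           + sum_j R_j * W_rel(j)

where the T slots are the asserted-term frequencies, S_i collects synonym
frequencies by scope class (1=NARROW, 2=EXACT, 3=RELATED, 4=BROAD) across
all three subontologies, and R_j collects relation frequencies by type
(1=is_a, 2=has_part, 3=part_of, 4=regulates).  W_T is a single weight shared
by all three term slots — the formula multiplies it by their sum.

The default weights encode the priority ladder: the asserted term itself
outranks any synonym, and any synonym outranks any relation, with strict
descent inside each class quadruple:

    W_T=10 > NARROW=8 > EXACT=7 > RELATED=6 > BROAD=5
         > is_a=4 > has_part=3 > part_of=2 > regulates=1

Scores are plain floats; there is deliberately no TF-IDF/BM25 or length
normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .search_engine import FrequencyVector, ResultRecord

#: Synonym scope classes in weight-index order W_syn(1..4).
SCOPE_ORDER = ("NARROW", "EXACT", "RELATED", "BROAD")
#: Relation type classes in weight-index order W_rel(1..4).
REL_ORDER = ("is_a", "has_part", "part_of", "regulates")

#: Weight-file / override keys.
_SYN_KEYS = tuple(f"w_syn_{s.lower()}" for s in SCOPE_ORDER)
_REL_KEYS = tuple(f"w_rel_{r}" for r in REL_ORDER)
VALID_KEYS = ("w_t",) + _SYN_KEYS + _REL_KEYS


class UnknownWeightClassError(ValueError):
    """A frequency vector carries a scope or relation type with no weight."""


@dataclass(frozen=True)
class WeightConfig:
    """Ranking weights: one shared term weight plus the two class quadruples."""

    w_t: float = 10.0
    w_syn: tuple[float, float, float, float] = (8.0, 7.0, 6.0, 5.0)
    w_rel: tuple[float, float, float, float] = (4.0, 3.0, 2.0, 1.0)

    def __post_init__(self):
        for w in (self.w_t, *self.w_syn, *self.w_rel):
            if not math.isfinite(w) or w < 0:
                raise ValueError(f"weights must be finite and >= 0, got {w!r}")

    def syn_weight(self, scope: str) -> float:
        try:
            return self.w_syn[SCOPE_ORDER.index(scope)]
        except ValueError:
            raise UnknownWeightClassError(f"unknown synonym scope {scope!r}") from None

    def rel_weight(self, rel_type: str) -> float:
        try:
            return self.w_rel[REL_ORDER.index(rel_type)]
        except ValueError:
            raise UnknownWeightClassError(
                f"unknown relation type {rel_type!r}"
            ) from None

    def as_dict(self) -> dict[str, float]:
        out = {"w_t": self.w_t}
        out.update(zip(_SYN_KEYS, self.w_syn))
        out.update(zip(_REL_KEYS, self.w_rel))
        return out


def default_weights(**overrides: float) -> WeightConfig:
    """The system default weights, optionally overridden key by key.

    Recognized keys: ``w_t``, ``w_syn_narrow``, ``w_syn_exact``,
    ``w_syn_related``, ``w_syn_broad``, ``w_rel_is_a``, ``w_rel_has_part``,
    ``w_rel_part_of``, ``w_rel_regulates``.
    """
    unknown = set(overrides) - set(VALID_KEYS)
    if unknown:
        raise ValueError(f"unknown weight key(s): {sorted(unknown)}")
    base = WeightConfig().as_dict()
    base.update(overrides)
    return WeightConfig(
        w_t=float(base["w_t"]),
        w_syn=tuple(float(base[k]) for k in _SYN_KEYS),
        w_rel=tuple(float(base[k]) for k in _REL_KEYS),
    )


def load_weights(path: str | Path) -> WeightConfig:
    """Read a key/value weight file (``key = value`` or ``key<TAB>value``,
    ``#`` comments); unspecified keys keep their defaults."""
    overrides: dict[str, float] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, _, value = line.partition("=")
        else:
            key, _, value = line.partition("\t")
        key, value = key.strip(), value.strip()
        if not value:
            raise ValueError(f"malformed weight line: {raw!r}")
        overrides[key] = float(value)
    return default_weights(**overrides)


def compute_rank(vector: FrequencyVector, weights: WeightConfig) -> float:
    """Score one document's frequency vector.

    Unknown scope or relation classes raise
    :class:`UnknownWeightClassError` — they are never silently dropped.
    """
    total = weights.w_t * (vector.t_cc + vector.t_mf + vector.t_bp)
    for lst in (vector.s_cc, vector.s_mf, vector.s_bp):
        for scope, freq in lst:
            total += freq * weights.syn_weight(scope)
    for lst in (vector.r_cc, vector.r_mf, vector.r_bp):
        for rel_type, freq in lst:
            total += freq * weights.rel_weight(rel_type)
    return total


@dataclass(frozen=True)
class RankedResult:
    paper_id: str
    d_rank: float


def rank_results(
    records: Sequence[ResultRecord], weights: WeightConfig | None = None
) -> list[RankedResult]:
    """Score every record and sort from higher to lower D_Rank.

    Ties (compared after rounding to 1e-9, so platform float noise cannot
    reorder them) break by ascending paper_id; the output is deterministic
    and drops no documents.
    """
    weights = weights or default_weights()
    ranked = [
        RankedResult(rec.paper_id, compute_rank(rec.vector, weights))
        for rec in records
    ]
    return sorted(ranked, key=lambda r: (-round(r.d_rank, 9), r.paper_id))
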