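"""Matched-pair cohort design, pair-preserving splits, and imbalance sweeps.

The audit keeps the two protected groups comparable by pairing each group-B
subject with a group-A subject of the same sex and nearly the same age
(|gap| <= 1 year), splitting at the pair level so both members of a pair
land in the same partition, and building training subsets with controlled
group imbalance from fixed per-group pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "MatchedPair",
    "MatchResult",
    "ImbalanceSplit",
    "match_pairs",
    "split_pairs",
    "imbalance_subsets",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = (1.0, 0.75, 0.5, 0.25, 0.0)

MAX_AGE_GAP = 1.0  # years


@dataclass(frozen=True)
class MatchedPair:
    subject_a: str  # group-A member
    subject_b: str  # group-B member
    age_gap: float  # age(A) - age(B), |gap| <= 1

    def __post_init__(self):
        if abs(self.age_gap) > MAX_AGE_GAP + 1e-9:
            raise ValueError("age gap exceeds matching tolerance")


@dataclass
class MatchResult:
    pairs: List[MatchedPair]
    unmatched: List[str]  # subject ids excluded from the paired design


@dataclass
class ImbalanceSplit:
    """One training composition in the imbalance sweep: a fraction_b of the
    (constant-size) training set drawn from group B, the rest from group A;
    the test set is fixed across all fractions."""

    fraction_b: float
    train_a: List[str]
    train_b: List[str]
    test_ids: List[str] = field(default_factory=list)

    @property
    def train_ids(self) -> List[str]:
        return list(self.train_a) + list(self.train_b)


def _records(cohort) -> List[Tuple[str, str, str, float]]:
    """(id, group, sex, age) per subject, from a Cohort or a DataFrame."""
    if hasattr(cohort, "subjects"):
        return [
            (s.subject_id, s.group, s.covariates.sex, s.covariates.age)
            for s in cohort.subjects
        ]
    return [
        (r.subject_id, r.group, r.sex, float(r.age))
        for r in cohort.itertuples(index=False)
    ]


def match_pairs(cohort, seed: int = 0) -> MatchResult:
    """Greedy nearest-age matching of group-B subjects to group-A subjects
    within sex.

    B subjects are processed in age order; each takes the still-available A
    candidate of the same sex with the smallest |age gap|, provided the gap
    is within +/-1 year.  Ties among equally close candidates are broken by
    a seeded shuffle.  Subjects that cannot be matched are reported and
    excluded.
    """
    recs = _records(cohort)
    groups = {g: [r for r in recs if r[1] == g] for g in ("A", "B")}
    if not groups["A"] or not groups["B"]:
        raise ValueError("both groups must be present to match pairs")

    rng = np.random.default_rng(seed)
    pairs: List[MatchedPair] = []
    unmatched: List[str] = []

    for sex in ("M", "F"):
        cand = [r for r in groups["A"] if r[2] == sex]
        rng.shuffle(cand)  # seeded tie-break among equal gaps
        cand.sort(key=lambda r: r[3])
        used = [False] * len(cand)
        b_subjects = sorted(
            (r for r in groups["B"] if r[2] == sex), key=lambda r: r[3]
        )
        for b in b_subjects:
            best_j, best_gap = -1, np.inf
            for j, a in enumerate(cand):
                if used[j]:
                    continue
                gap = abs(a[3] - b[3])
                if gap < best_gap - 1e-12:
                    best_j, best_gap = j, gap
            if best_j >= 0 and best_gap <= MAX_AGE_GAP + 1e-9:
                used[best_j] = True
                a = cand[best_j]
                pairs.append(
                    MatchedPair(subject_a=a[0], subject_b=b[0], age_gap=a[3] - b[3])
                )
            else:
                unmatched.append(b[0])
        unmatched.extend(a[0] for j, a in enumerate(cand) if not used[j])

    return MatchResult(pairs=pairs, unmatched=unmatched)


def split_pairs(
    pairs: Sequence[MatchedPair], n_test_pairs: int, seed: int = 0
) -> Tuple[List[str], List[str]]:
    """Random pair-level train/test split; both members of a pair always
    fall in the same partition.  Returns (train_ids, test_ids)."""
    if n_test_pairs >= len(pairs):
        raise ValueError("n_test_pairs must be smaller than the number of pairs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    test_idx = set(order[:n_test_pairs].tolist())
    train_ids, test_ids = [], []
    for i, p in enumerate(pairs):
        target = test_ids if i in test_idx else train_ids
        target.extend([p.subject_a, p.subject_b])
    return train_ids, test_ids


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def imbalance_subsets(
    train_ids_by_group: Mapping[str, Sequence[str]],
    fractions: Iterable[float] = DEFAULT_FRACTIONS,
    pool_per_group: int | None = None,
    seed: int = 0,
    test_ids: Sequence[str] = (),
) -> List[ImbalanceSplit]:
    """Build nested training subsets with varying group-B fraction.

    Each fraction f yields round(f * pool) group-B subjects (half-away-from-
    zero rounding) and pool - that group-A subjects, so the total training
    size is constant.  One seeded permutation per group is drawn once and
    subsets take its prefix, so compositions are nested across fractions.
    """
    ids_a = list(train_ids_by_group["A"])
    ids_b = list(train_ids_by_group["B"])
    pool = pool_per_group if pool_per_group is not None else min(len(ids_a), len(ids_b))
    if pool > len(ids_a) or pool > len(ids_b):
        raise ValueError("pool_per_group exceeds available ids")
    rng = np.random.default_rng(seed)
    perm_a = [ids_a[i] for i in rng.permutation(len(ids_a))]
    perm_b = [ids_b[i] for i in rng.permutation(len(ids_b))]

    splits = []
    for f in fractions:
        if not (0.0 <= f <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        n_b = _round_half_away(f * pool)
        n_a = pool - n_b
        splits.append(
            ImbalanceSplit(
                fraction_b=float(f),
                train_a=perm_a[:n_a],
                train_b=perm_b[:n_b],
                test_ids=list(test_ids),
            )
        )
    return splits
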