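"""Training / validation / testing split stratified by integer BMI.

The cohort is partitioned so that each integer-BMI stratum is spread across
the subsets with the training subset holding roughly twice the subjects of
the validation or testing subset (a 2:1:1 tendency), while the global subset
sizes are hit exactly.  BMI values in the study data are integers; real
values are rounded to the nearest integer for stratification only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .imaging_io import SubjectRecord


@dataclass
class CohortSplit:
    """Disjoint train/validation/test subject-id lists plus provenance."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    sizes: tuple[int, int, int]
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split subsets overlap")
        actual = (len(self.train_ids), len(self.val_ids), len(self.test_ids))
        if actual != tuple(self.sizes):
            raise ValueError(f"split sizes {actual} != configured {tuple(self.sizes)}")

    @property
    def all_ids(self) -> list[str]:
        return self.train_ids + self.val_ids + self.test_ids

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "sizes": list(self.sizes),
                    "train_ids": self.train_ids,
                    "val_ids": self.val_ids,
                    "test_ids": self.test_ids,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSplit":
        d = json.loads(Path(path).read_text())
        return cls(d["train_ids"], d["val_ids"], d["test_ids"],
                   tuple(d["sizes"]), d["seed"])


def _randomized_quota(counts: np.ndarray, total: int, rng: np.random.Generator) -> np.ndarray:
    """Integer allocation proportional to ``counts`` summing to ``total``.

    Each stratum receives floor(count * total / sum) and the remaining slots
    go to a seeded random draw among strata with nonzero fractional part, so
    every allocation is within one of its exact quota.
    """
    n = counts.sum()
    if total == 0 or n == 0:
        return np.zeros_like(counts)
    quota = counts * total / n
    alloc = np.floor(quota).astype(int)
    frac = quota - alloc
    short = total - alloc.sum()
    if short:
        eligible = np.flatnonzero(frac > 1e-12)
        picks = rng.choice(eligible, size=short, replace=False)
        alloc[picks] += 1
    return alloc


def stratified_split(
    subjects: Sequence[SubjectRecord],
    sizes: tuple[int, int, int] = (80, 40, 40),
    seed: int = 0,
) -> CohortSplit:
    """Partition subjects into train/val/test with homogeneous BMI strata.

    Within each integer-BMI stratum of size c the training subset receives
    floor(c/2) or ceil(c/2) subjects (for the default half-sized training
    subset) and the remainder is split as evenly as possible between
    validation and testing; leftover slots are assigned by seeded random
    draw subject to the exact global sizes.  Deterministic for a fixed seed.
    """
    n_tr, n_val, n_te = sizes
    if n_tr + n_val + n_te != len(subjects):
        raise ValueError(
            f"sizes {sizes} sum to {n_tr + n_val + n_te}, cohort has {len(subjects)}"
        )
    rng = np.random.default_rng(seed)

    strata: dict[int, list[str]] = {}
    for s in subjects:
        strata.setdefault(int(round(s.bmi)), []).append(s.subject_id)
    keys = sorted(strata)
    counts = np.array([len(strata[k]) for k in keys])

    train_alloc = _randomized_quota(counts, n_tr, rng)
    rest = counts - train_alloc
    val_alloc = _randomized_quota(rest, n_val, rng)
    test_alloc = rest - val_alloc
    if (test_alloc < 0).any() or test_alloc.sum() != n_te:
        raise ValueError("infeasible split sizes for the given strata")

    train, val, test = [], [], []
    for k, t, v in zip(keys, train_alloc, val_alloc):
        ids = list(strata[k])
        rng.shuffle(ids)
        train.extend(ids[:t])
        val.extend(ids[t : t + v])
        test.extend(ids[t + v :])
    return CohortSplit(train, val, test, (n_tr, n_val, n_te), seed)
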