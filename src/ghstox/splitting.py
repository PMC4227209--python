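"""Stratified training/test split preserving class proportions.

Each class contributes floor((1 - test_fraction) * class_size) members to
the training set, chosen uniformly at random under the given seed; the
remainder goes to the test set.  The floor convention (not rounding) is
what makes an 80/20 split of class sizes (103, 171, 162) come out as
train (82, 136, 129) and test (21, 35, 33).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np


class SplitError(ValueError):
    pass


@dataclass
class SplitAssignment:
    train_ids: list[str]
    test_ids: list[str]
    train_counts: dict[int, int]
    test_counts: dict[int, int]

    def to_dict(self) -> dict:
        return {
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "train_counts": {str(k): v for k, v in sorted(self.train_counts.items())},
            "test_counts": {str(k): v for k, v in sorted(self.test_counts.items())},
        }

    def save(self, directory: str | Path, prefix: str = "split") -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        train_path = directory / f"{prefix}_train_ids.txt"
        test_path = directory / f"{prefix}_test_ids.txt"
        train_path.write_text("\n".join(self.train_ids) + "\n")
        test_path.write_text("\n".join(self.test_ids) + "\n")
        return train_path, test_path


def stratified_split(
    ids: Sequence[str],
    labels: Sequence[int],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> SplitAssignment:
    """Split ids into train/test keeping per-class proportions.

    Every class needs at least 2 members so both sides can be non-trivial.
    Membership is seed-dependent; per-class counts are not.
    """
    if not 0 < test_fraction < 1:
        raise SplitError(f"test_fraction must be in (0, 1), got {test_fraction}")
    ids = list(ids)
    y = np.asarray(labels, dtype=int)
    if len(ids) != len(y):
        raise SplitError("ids/labels length mismatch")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    train_counts: dict[int, int] = {}
    test_counts: dict[int, int] = {}
    for cls in sorted(set(y.tolist())):
        members = np.flatnonzero(y == cls)
        n_g = members.size
        if n_g < 2:
            raise SplitError(f"class {cls} has only {n_g} member(s); need >= 2")
        n_train = math.floor((1 - test_fraction) * n_g)
        perm = rng.permutation(n_g)
        chosen = set(members[perm[:n_train]].tolist())
        train_idx.extend(i for i in members.tolist() if i in chosen)
        test_idx.extend(i for i in members.tolist() if i not in chosen)
        train_counts[cls] = n_train
        test_counts[cls] = n_g - n_train
    train_idx.sort()
    test_idx.sort()
    return SplitAssignment(
        train_ids=[ids[i] for i in train_idx],
        test_ids=[ids[i] for i in test_idx],
        train_counts=train_counts,
        test_counts=test_counts,
    )


def load_split(train_path: str | Path, test_path: str | Path) -> tuple[list[str], list[str]]:
    train = [ln for ln in Path(train_path).read_text().splitlines() if ln.strip()]
    test = [ln for ln in Path(test_path).read_text().splitlines() if ln.strip()]
    overlap = set(train) & set(test)
    if overlap:
        raise SplitError(f"ids appear in both sets: {sorted(overlap)[:5]}")
    return train, test
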