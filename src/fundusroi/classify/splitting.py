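"""Greedy iterative stratification for the multi-label train/validation split.

Each class's positives are divided between the two splits as close to the
requested ratio as the multi-label structure allows; the all-negative
(Normal) images are stratified as their own pseudo-class so the derived
Normal state is represented on both sides.
"""
from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from ..types import DISEASES


def split_dataset(
    manifest: pd.DataFrame, ratio: float = 0.9, seed: int = 0
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Split a manifest into (train, val), stratifying per-class positives.

    ``ratio`` is the train share. Every class present must have at least two
    positive images (otherwise one split would necessarily lose the class).
    The two frames are disjoint and exhaustive.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    labels = manifest[list(DISEASES)].to_numpy(dtype=int)
    pos_counts = labels.sum(axis=0)
    for name, count in zip(DISEASES, pos_counts):
        if count == 1:
            raise ValueError(f"class {name!r} has < 2 positive images")

    n = len(manifest)
    # normal pseudo-class column so all-negative images are stratified too
    work = np.column_stack([labels, (labels.sum(axis=1) == 0).astype(int)])
    n_labels = work.shape[1]
    desired_train = work.sum(axis=0) * ratio
    desired_val = work.sum(axis=0) * (1.0 - ratio)
    placed_train = np.zeros(n_labels)
    placed_val = np.zeros(n_labels)

    rng = np.random.default_rng(seed)
    remaining = set(range(n))
    assignment = np.full(n, -1, dtype=int)   # 0 = train, 1 = val

    while remaining:
        remaining_counts = work[list(sorted(remaining))].sum(axis=0)
        active = np.flatnonzero(remaining_counts > 0)
        if active.size == 0:
            # images with no active label (impossible given the pseudo-class,
            # but keep the loop total): assign by global desire
            for i in sorted(remaining):
                assignment[i] = 0 if placed_train.sum() / max(ratio, 1e-9) <= \
                    placed_val.sum() / max(1 - ratio, 1e-9) else 1
            break
        # rarest active label first
        label = active[np.argmin(remaining_counts[active])]
        members = [i for i in sorted(remaining) if work[i, label] == 1]
        rng.shuffle(members)
        for i in members:
            # split with the greater remaining desire for THIS label; break
            # ties on total remaining desire over the image's labels, then by
            # a ratio-weighted coin
            want_train = desired_train[label] - placed_train[label]
            want_val = desired_val[label] - placed_val[label]
            if not np.isclose(want_train, want_val):
                split = 0 if want_train > want_val else 1
            else:
                lab_idx = np.flatnonzero(work[i])
                tot_train = (desired_train[lab_idx] - placed_train[lab_idx]).sum()
                tot_val = (desired_val[lab_idx] - placed_val[lab_idx]).sum()
                if not np.isclose(tot_train, tot_val):
                    split = 0 if tot_train > tot_val else 1
                else:
                    split = 0 if rng.random() < ratio else 1
            assignment[i] = split
            if split == 0:
                placed_train += work[i]
            else:
                placed_val += work[i]
            remaining.discard(i)

    train = manifest.iloc[np.flatnonzero(assignment == 0)].reset_index(drop=True)
    val = manifest.iloc[np.flatnonzero(assignment == 1)].reset_index(drop=True)
    return train, val
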