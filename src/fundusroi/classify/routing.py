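"""Label routing between the three region branches and probability assembly."""
from __future__ import annotations

from typing import Dict, Mapping, Tuple

import numpy as np

from ..types import DISEASES, LabelVector

#: branch id -> ordered target labels
BRANCH_TARGETS: Dict[str, Tuple[str, ...]] = {
    "od_gs": ("gs",),
    "mac_erm_amd": ("erm", "amd"),
    "full_dr_rb_rvo": ("dr", "rb", "rvo"),
    "baseline_full6": DISEASES,
}

#: branch id -> which ROISet member it consumes
BRANCH_REGION: Dict[str, str] = {
    "od_gs": "od_roi",
    "mac_erm_amd": "macula_roi",
    "full_dr_rb_rvo": "full",
    "baseline_full6": "full",
}

BRANCH_IDS = tuple(BRANCH_TARGETS)

ROUTED_BRANCHES = ("od_gs", "mac_erm_amd", "full_dr_rb_rvo")


def partition_labels(
    labels: LabelVector,
) -> Tuple[int, Tuple[int, int], Tuple[int, int, int]]:
    """Route a label vector to the three branches:
    (gs,), (erm, amd), (dr, rb, rvo)."""
    return (
        labels.gs,
        (labels.erm, labels.amd),
        (labels.dr, labels.rb, labels.rvo),
    )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def predict_assemble(branch_outputs: Mapping[str, np.ndarray]) -> np.ndarray:
    """Assemble six-disease probabilities from raw branch logits.

    ``branch_outputs`` maps branch id to per-image logits: shape (n, 2) for
    ``od_gs`` (background/disease two-class head -> softmax probability of the
    disease class) and (n, k) for the sigmoid multi-target branches. Returns
    an (n, 6) probability matrix in canonical disease order.
    """
    for branch in ROUTED_BRANCHES:
        if branch not in branch_outputs:
            raise KeyError(f"missing output for branch {branch!r}")
    gs_logits = np.atleast_2d(np.asarray(branch_outputs["od_gs"], dtype=float))
    mac_logits = np.atleast_2d(np.asarray(branch_outputs["mac_erm_amd"], dtype=float))
    full_logits = np.atleast_2d(np.asarray(branch_outputs["full_dr_rb_rvo"], dtype=float))
    if gs_logits.shape[1] != 2:
        raise ValueError("od_gs branch must emit two-class logits")
    n = gs_logits.shape[0]
    out = np.empty((n, len(DISEASES)), dtype=float)
    p = {
        "gs": _softmax(gs_logits)[:, 1],
        "erm": _sigmoid(mac_logits[:, 0]),
        "amd": _sigmoid(mac_logits[:, 1]),
        "dr": _sigmoid(full_logits[:, 0]),
        "rb": _sigmoid(full_logits[:, 1]),
        "rvo": _sigmoid(full_logits[:, 2]),
    }
    for j, name in enumerate(DISEASES):
        out[:, j] = p[name]
    return out
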