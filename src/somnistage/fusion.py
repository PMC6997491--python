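"""Two-network decision fusion.

The three-epoch-context network (model 3) is the primary classifier, but the
two-epoch network (model 2) is stronger on deep sleep.  Fusion therefore
re-examines only samples model 3 called N2 or N3: for those, the final label
comes from whichever network is more confident (larger maximum probability),
with ties going to model 3.  Every other sample keeps model 3's label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N2, N3 = 2, 3


@dataclass
class FusionDecision:
    """Final label for one epoch, with both probability vectors kept for audit."""

    final_label: int
    source: str  # "model-3" or "model-2"
    p3: np.ndarray | None
    p2: np.ndarray | None


def _check_vector(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (5,):
        raise ValueError(f"{name} must be a length-5 probability vector, got shape {p.shape}")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} must be nonnegative and sum to 1 (got sum {p.sum():.8f})")
    return p


def fuse(p3, p2) -> FusionDecision:
    """Fuse one epoch's probability vectors from the two networks.

    If model 3's argmax is not N2/N3 its label stands.  Otherwise the label
    is the argmax of whichever vector attains the larger maximum probability;
    equal maxima resolve to model 3.
    """
    p3 = _check_vector(p3, "p3")
    p2 = _check_vector(p2, "p2")
    label3 = int(np.argmax(p3))
    if label3 not in (N2, N3):
        return FusionDecision(label3, "model-3", p3, p2)
    if p2.max() > p3.max():
        return FusionDecision(int(np.argmax(p2)), "model-2", p3, p2)
    return FusionDecision(label3, "model-3", p3, p2)


def fuse_series(
    proba3: np.ndarray,
    epochs3: np.ndarray,
    proba2: np.ndarray,
    epochs2: np.ndarray,
) -> pd.DataFrame:
    """Fuse epoch-aligned probability series from the two networks.

    Epochs present in only one series (night edges: the deeper-context model
    starts later) fall back to the single available model, flagged in the
    ``source`` column as ``model-3-only``/``model-2-only``.  Returns a frame
    with columns ``epoch``, ``label``, ``source``.
    """
    epochs3 = np.asarray(epochs3, dtype=int)
    epochs2 = np.asarray(epochs2, dtype=int)
    if len(epochs3) != len(proba3) or len(epochs2) != len(proba2):
        raise ValueError("probability arrays and epoch indices must align")
    m3 = {int(e): np.asarray(proba3[i]) for i, e in enumerate(epochs3)}
    m2 = {int(e): np.asarray(proba2[i]) for i, e in enumerate(epochs2)}
    rows = []
    for e in sorted(set(m3) | set(m2)):
        if e in m3 and e in m2:
            d = fuse(m3[e], m2[e])
            rows.append((e, d.final_label, d.source))
        elif e in m3:
            rows.append((e, int(np.argmax(_check_vector(m3[e], "p3"))), "model-3-only"))
        else:
            rows.append((e, int(np.argmax(_check_vector(m2[e], "p2"))), "model-2-only"))
    return pd.DataFrame(rows, columns=["epoch", "label", "source"])


def read_proba_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an epoch-indexed CSV of five class-probability columns."""
    df = pd.read_csv(path)
    cols = [f"p{k}" for k in range(5)]
    if "epoch" not in df.columns or any(c not in df.columns for c in cols):
        raise ValueError("probability CSV needs columns epoch, p0..p4")
    return df[cols].to_numpy(dtype=float), df["epoch"].to_numpy(dtype=int)


def write_proba_csv(proba: np.ndarray, epochs: np.ndarray, path) -> None:
    df = pd.DataFrame(np.asarray(proba, dtype=float), columns=[f"p{k}" for k in range(5)])
    df.insert(0, "epoch", np.asarray(epochs, dtype=int))
    df.to_csv(path, index=False)
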