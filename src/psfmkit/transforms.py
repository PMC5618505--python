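"""Fixed-length feature vectors from variable-length profiles.

Four transformations map an ``L x 20`` PSFM ``P`` to a fixed-length vector:

* **RPT** (residue probing): profile rows are grouped by the query residue
  at each position; ``e[k, j] = sum_{i : R_i = A_k} P[i, j]``.  Features are
  the flattened ``e / L`` (400 values) followed by the 20 amino-acid
  composition values (column means of the profile).  Dimension 420.
* **EDT** (evolutionary difference): for each separation ``d = 1..D`` and
  ordered residue pair ``(x, y)``,
  ``f(x, y | d) = mean_i (P[i, x] - P[i+d, y])^2``.  Dimension ``400 D``.
* **DBT** (distance bigram): for each ``d = 0..D`` and ordered pair,
  ``f(x, y | d) = mean_i P[i, x] * P[i+d, y]``.  The ``d = 0`` block is the
  profile's amino-acid pair composition at the same position.  Dimension
  ``400 (D + 1)``.
* **TT** (trigram): ``f(x, y, z) = sum_i P[i, x] P[i+1, y] P[i+2, z]`` over
  consecutive triples, unnormalized, so values grow with ``L``.  Dimension
  8000.

Feature ordering is deterministic: separation ``d`` outermost (ascending),
then the first residue, then the second (both in canonical order);
trigrams are ordered ``x`` outermost, then ``y``, then ``z``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .profile_io import AA_TO_INDEX, CANONICAL_ORDER, PSFM, LabeledDataset, ProteinSequence

METHODS = ("rpt", "edt", "dbt", "tt")

#: Operating points used for the published benchmark results (per method:
#: maximum separation D where applicable, SVM cost c and RBF width g).
PAPER_PRESETS: dict[str, dict[str, float | int | None]] = {
    "rpt": {"D": None, "c": 2.0**4, "g": 2.0**6},
    "edt": {"D": 7, "c": 2.0**9, "g": 2.0**-2},
    "dbt": {"D": 4, "c": 2.0**3, "g": 2.0**5},
    "tt": {"D": None, "c": 2.0**5, "g": 2.0**-9},
}

DEFAULT_D = {"edt": 7, "dbt": 4}


class TransformError(ValueError):
    """Raised for inputs a transformation cannot accept."""


@dataclass
class FeatureVector:
    """An ordered numeric feature vector with parallel labels."""

    values: np.ndarray
    method: str
    D: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = dimension(self.method, self.D)
        if self.values.shape != (expected,):
            raise TransformError(
                f"{self.method} vector must have length {expected}, "
                f"got {self.values.shape}"
            )

    @property
    def omega(self) -> int:
        return int(self.values.size)

    @property
    def names(self) -> list[str]:
        return feature_names(self.method, self.D)


def dimension(method: str, D: int | None = None) -> int:
    """Feature-vector length Ω for a method (and max separation D)."""
    if method == "rpt":
        return 420
    if method == "tt":
        return 8000
    if method == "edt":
        if D is None or D < 1:
            raise TransformError("edt requires D >= 1")
        return 400 * D
    if method == "dbt":
        if D is None or D < 0:
            raise TransformError("dbt requires D >= 0")
        return 400 * (D + 1)
    raise TransformError(f"unknown method {method!r}")


@lru_cache(maxsize=None)
def _pair_names() -> tuple[str, ...]:
    return tuple(x + y for x in CANONICAL_ORDER for y in CANONICAL_ORDER)


@lru_cache(maxsize=None)
def feature_names(method: str, D: int | None = None) -> list[str]:
    """Deterministic human-readable labels, parallel to the feature order."""
    pairs = _pair_names()
    if method == "rpt":
        probe = [f"probe{x}:col{y}" for x in CANONICAL_ORDER for y in CANONICAL_ORDER]
        return probe + [f"aac:{x}" for x in CANONICAL_ORDER]
    if method == "edt":
        dimension("edt", D)
        return [f"d{d}:{p}" for d in range(1, D + 1) for p in pairs]
    if method == "dbt":
        dimension("dbt", D)
        return [f"d{d}:{p}" for d in range(0, D + 1) for p in pairs]
    if method == "tt":
        return [x + y + z for x in CANONICAL_ORDER for y in CANONICAL_ORDER
                for z in CANONICAL_ORDER]
    raise TransformError(f"unknown method {method!r}")


def feature_name(method: str, index: int, D: int | None = None) -> str:
    names = feature_names(method, D)
    if not 0 <= index < len(names):
        raise TransformError(
            f"{method} feature index {index} out of range [0, {len(names)})"
        )
    return names[index]


# ---------------------------------------------------------------------------
# The four transformations
# ---------------------------------------------------------------------------

def rpt(psfm: PSFM, seq: ProteinSequence | str | None = None) -> FeatureVector:
    """Residue probing transformation (dimension 420).

    Positions are grouped by the query residue ("probe"); within each group
    the profile columns are summed, giving a 20 x 20 matrix ``e`` whose
    entries sum to ``L``.  Features are ``e / L`` flattened row-major over
    (probe, column), followed by the 20-dimensional amino-acid composition
    (column means of the profile).  Probes absent from the sequence
    contribute all-zero rows.
    """
    residues = _resolve_sequence(psfm, seq)
    L = psfm.length
    e = np.zeros((20, 20))
    for i, aa in enumerate(residues):
        k = AA_TO_INDEX.get(aa)
        if k is None:
            raise TransformError(
                f"{psfm.id}: nonstandard residue {aa!r} at position {i + 1}"
            )
        e[k] += psfm.matrix[i]
    aac = psfm.matrix.mean(axis=0)
    return FeatureVector(np.concatenate([(e / L).ravel(), aac]), "rpt")


def edt(psfm: PSFM, D: int = 7) -> FeatureVector:
    """Evolutionary difference transformation (dimension 400 D).

    The feature for pair ``(x, y)`` at separation ``d`` is the mean squared
    difference between column ``x`` and column ``y`` shifted by ``d``
    positions — the non-co-occurrence of the two residues at that distance.
    """
    L = psfm.length
    if not 1 <= D <= L - 1:
        raise TransformError(
            f"{psfm.id}: sequence too short for distance D={D} (L={L})"
        )
    P = psfm.matrix
    blocks = []
    for d in range(1, D + 1):
        # direct squared differences: exact zeros when columns coincide
        diff = P[: L - d, :, None] - P[d:, None, :]
        blocks.append((diff**2).sum(axis=0).ravel() / (L - d))
    return FeatureVector(np.concatenate(blocks), "edt", D)


def dbt(psfm: PSFM, D: int = 4) -> FeatureVector:
    """Distance bigram transformation (dimension 400 (D + 1)).

    The feature for pair ``(x, y)`` at separation ``d`` is the
    length-normalized sum of products ``P[i, x] * P[i+d, y]`` — the
    expected frequency of the bigram at that distance under the profile.
    ``d = 0`` (same-position products) is included; its diagonal carries
    the amino-acid composition signal.
    """
    L = psfm.length
    if not 0 <= D <= L - 1:
        raise TransformError(
            f"{psfm.id}: sequence too short for distance D={D} (L={L})"
        )
    P = psfm.matrix
    blocks = []
    for d in range(0, D + 1):
        cross = P[: L - d].T @ P[d:]
        blocks.append(cross.ravel() / (L - d))
    return FeatureVector(np.concatenate(blocks), "dbt", D)


def tt(psfm: PSFM) -> FeatureVector:
    """Trigram transformation (dimension 8000, unnormalized).

    ``f(x, y, z)`` sums the profile products over all consecutive position
    triples; values therefore scale with sequence length.
    """
    L = psfm.length
    if L < 3:
        raise TransformError(f"{psfm.id}: trigram transform requires L >= 3 (L={L})")
    P = psfm.matrix
    cube = np.einsum("ix,iy,iz->xyz", P[:-2], P[1:-1], P[2:])
    return FeatureVector(cube.ravel(), "tt")


def transform(psfm: PSFM, method: str, D: int | None = None) -> FeatureVector:
    """Dispatch to one of the four transformations by name."""
    if method == "rpt":
        return rpt(psfm)
    if method == "edt":
        return edt(psfm, D if D is not None else DEFAULT_D["edt"])
    if method == "dbt":
        return dbt(psfm, D if D is not None else DEFAULT_D["dbt"])
    if method == "tt":
        return tt(psfm)
    raise TransformError(f"unknown method {method!r}")


def feature_matrix(
    dataset: LabeledDataset, method: str, D: int | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix, label vector and ids for a labeled dataset."""
    rows = [transform(p, method, D).values for p in dataset.psfms]
    return np.vstack(rows), dataset.labels, dataset.ids


def feature_frame(
    dataset: LabeledDataset, method: str, D: int | None = None
) -> pd.DataFrame:
    """Feature table indexed by id with named feature columns."""
    X, _, ids = feature_matrix(dataset, method, D)
    return pd.DataFrame(X, index=pd.Index(ids, name="id"),
                        columns=feature_names(method, D))


def _resolve_sequence(psfm: PSFM, seq: ProteinSequence | str | None) -> str:
    if seq is None:
        if psfm.sequence is None:
            raise TransformError(
                f"{psfm.id}: residue probing needs the query sequence and the "
                "profile carries none"
            )
        seq = psfm.sequence
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    if len(residues) != psfm.length:
        raise TransformError(
            f"{psfm.id}: sequence length {len(residues)} does not match "
            f"profile length {psfm.length}"
        )
    return residues
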