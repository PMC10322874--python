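"""Glycan niche width and overlap statistics on proportion vectors.

Given a taxon's proportions ``p_j`` of degradative CAZyme family abundance:

* Levins niche width ``B = 1 / sum_j p_j**2`` (inverse Simpson
  concentration), in ``[1, n]``;
* standardized Levins width ``B_A = (B - 1) / (n - 1)`` in ``[0, 1]``, where
  ``n`` is the dataset-wide number of predicted degradative families;
* Shannon-Wiener evenness ``B_i = -sum_j p_j ln p_j`` (natural log,
  ``0 ln 0 = 0``), in ``[0, ln n]``;
* Morisita-Horn overlap between two taxa,
  ``O = 2 sum_j p_aj p_bj / (sum_j p_aj**2 + sum_j p_bj**2)``, 1 for
  identical profiles and 0 for disjoint family support.

Inputs must sum to 1 within 1e-6 (they are then renormalized internally to
remove accumulated float error).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "levins_B",
    "levins_standardized",
    "shannon",
    "morisita_horn",
    "NicheMetrics",
    "niche_metrics",
    "overlap_matrix",
]

#: tolerance on |sum(p) - 1| before an input is rejected as non-normalized
NORMALIZATION_TOL = 1e-6


def _as_proportions(p, name: str = "p") -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D proportion vector")
    if np.any(arr < 0):
        raise ValueError(f"{name} has negative entries")
    total = arr.sum()
    if abs(total - 1.0) > NORMALIZATION_TOL:
        raise ValueError(f"{name} is not normalized: sum = {total!r}")
    return arr / total


def levins_B(p) -> float:
    """Levins niche width ``1 / sum p_j**2``; 1 for a specialist on a single
    family, ``len(p)`` for a perfectly even generalist."""
    arr = _as_proportions(p)
    return float(1.0 / np.sum(arr * arr))


def levins_standardized(p, n: int) -> float:
    """Standardized Levins width ``(B - 1) / (n - 1)`` on the 0-1 scale.

    ``n`` is the total number of degradative CAZyme families predicted in the
    dataset (not just those present in this taxon).
    """
    if n < 2:
        raise ValueError(f"standardization requires n >= 2 families, got n={n}")
    return (levins_B(p) - 1.0) / (n - 1.0)


def shannon(p) -> float:
    """Shannon-Wiener evenness ``-sum p ln p`` with the ``0 ln 0 = 0``
    convention (natural logarithm)."""
    arr = _as_proportions(p)
    nz = arr[arr > 0]
    return float(-np.sum(nz * np.log(nz)))


def morisita_horn(p_a, p_b) -> float:
    """Morisita-Horn overlap of two proportion vectors on the same family
    index; symmetric, 1 iff identical, 0 iff supports are disjoint."""
    a = _as_proportions(p_a, "p_a")
    b = _as_proportions(p_b, "p_b")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size} families")
    denom = np.sum(a * a) + np.sum(b * b)
    return float(2.0 * np.sum(a * b) / denom)


@dataclass(frozen=True)
class NicheMetrics:
    """Niche width summary for one proportion vector within an ``n``-family
    dataset."""

    B: float
    B_A: float
    B_i: float
    n: int


def niche_metrics(p, n: int) -> NicheMetrics:
    return NicheMetrics(B=levins_B(p), B_A=levins_standardized(p, n), B_i=shannon(p), n=n)


def overlap_matrix(profiles: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Pairwise Morisita-Horn overlap for a set of taxon abundance profiles.

    Profiles (family -> abundance Series, raw RPKM or proportions) are
    aligned on the union of their families with zeros for absent families,
    normalized, and compared pairwise. The result is symmetric with a unit
    diagonal; use ``io_tables.write_matrix(..., layout="table1_style")`` for
    the printed lower-triangle convention.
    """
    if len(profiles) < 2:
        raise ValueError("overlap_matrix requires at least 2 profiles")
    aligned = pd.DataFrame(profiles).fillna(0.0).T  # taxa x union-of-families
    totals = aligned.sum(axis=1)
    if (totals <= 0).any():
        empty = list(totals.index[totals <= 0])
        raise ValueError(f"profiles with zero total abundance have no niche: {empty}")
    P = aligned.div(totals, axis=0).to_numpy()
    sq = (P * P).sum(axis=1)
    cross = P @ P.T
    O = 2.0 * cross / (sq[:, None] + sq[None, :])
    np.fill_diagonal(O, 1.0)
    labels = list(aligned.index)
    return pd.DataFrame(O, index=labels, columns=labels)
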