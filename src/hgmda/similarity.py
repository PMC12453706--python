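"""Gaussian interaction profile (GIP) kernel similarity and feature fusion.

Each entity's interaction profile is its binary row (microbes) or column
(diseases) of the association matrix.  Similarity between two entities is a
Gaussian of the squared Euclidean distance between their profiles, with the
bandwidth normalised by the mean squared profile norm (the van Laarhoven
convention used throughout the GIP-kernel literature):

    S[i, j] = exp(-gamma * ||p_i - p_j||^2),
    gamma   = gamma_prime / ((1/n) * sum_i ||p_i||^2)

The kernel matrix doubles as structural node features; when a static feature
matrix is available it is concatenated in front of the kernel columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import StaticFeatures

__all__ = ["SimilarityProfile", "gip_kernel", "fuse_features", "DegenerateBandwidthError"]


class DegenerateBandwidthError(ValueError):
    """All interaction profiles are zero, so no bandwidth can be estimated.

    Pass ``identity_fallback=True`` to return the identity matrix instead
    (every entity similar only to itself).
    """


@dataclass
class SimilarityProfile:
    """Fused node representation for one entity type.

    ``S`` is the symmetric similarity matrix; ``X`` the feature matrix fed to
    graph construction and the network (static features, if any, concatenated
    with the similarity columns).
    """

    entity_names: list[str]
    S: np.ndarray
    X: np.ndarray


def gip_kernel(
    profiles: np.ndarray,
    gamma_prime: float = 1.0,
    identity_fallback: bool = False,
) -> np.ndarray:
    """GIP kernel matrix of a binary profile matrix (one profile per row).

    Entities with an all-zero profile carry no interaction information; their
    row/column is set to the indicator at their own index (self-similarity 1,
    zero elsewhere) rather than propagating a meaningless constant.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2:
        raise ValueError("profiles must be a 2-D matrix")
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    sq_norms = (P ** 2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0.0:
        if identity_fallback:
            return np.eye(P.shape[0])
        raise DegenerateBandwidthError(
            "all interaction profiles are zero; pass identity_fallback=True "
            "to use the identity similarity matrix"
        )
    gamma = gamma_prime / mean_sq
    # ||p_i - p_j||^2 = ||p_i||^2 + ||p_j||^2 - 2 p_i . p_j
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (P @ P.T)
    np.maximum(d2, 0.0, out=d2)
    S = np.exp(-gamma * d2)
    S = 0.5 * (S + S.T)
    zero = sq_norms == 0.0
    if zero.any():
        S[zero, :] = 0.0
        S[:, zero] = 0.0
        S[zero, zero] = 1.0
    return S


def fuse_features(
    static: StaticFeatures | None,
    gip: np.ndarray,
    entity_names: list[str] | None = None,
    mode: str = "concat",
) -> SimilarityProfile:
    """Combine static features with the GIP kernel into node representations.

    ``mode='concat'`` (default) sets ``X = [static.F | gip]`` so both sources
    are preserved exactly; ``mode='mean-where-defined'`` averages the kernel
    with a min-max-rescaled static block of matching width when present.
    Without static features, ``X`` is the kernel itself.
    """
    gip = np.asarray(gip, dtype=float)
    n = gip.shape[0]
    if entity_names is None:
        entity_names = (
            list(static.entity_names) if static is not None
            else [f"entity_{i}" for i in range(n)]
        )
    if static is None:
        return SimilarityProfile(list(entity_names), gip, gip.copy())
    if static.F.shape[0] != n:
        raise ValueError(
            f"static features have {static.F.shape[0]} rows, similarity has {n}"
        )
    if mode == "concat":
        X = np.hstack([static.F, gip])
    elif mode == "mean-where-defined":
        F = static.F
        span = F.max() - F.min()
        F01 = (F - F.min()) / span if span > 0 else np.zeros_like(F)
        if F01.shape[1] == n:
            X = 0.5 * (F01 + gip)
        else:  # widths differ: keep both, rescaled static first
            X = np.hstack([F01, gip])
    else:
        raise ValueError(f"unknown fusion mode: {mode!r}")
    return SimilarityProfile(list(entity_names), gip, X)


def export_profile_tsv(profile: SimilarityProfile, s_path=None, x_path=None) -> None:
    """Write S and/or X as dense TSV with entity-name row headers."""
    if s_path is not None:
        pd.DataFrame(profile.S, index=profile.entity_names,
                     columns=profile.entity_names).to_csv(s_path, sep="\t")
    if x_path is not None:
        pd.DataFrame(profile.X, index=profile.entity_names).to_csv(x_path, sep="\t")
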