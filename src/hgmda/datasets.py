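"""Association tables, static features, synthetic benchmarks and pair sampling.

The supervision signal for microbe-disease link prediction is a sparse binary
matrix ``A`` (microbes x diseases) assembled from curated association tables
such as HMDAD or Disbiome exports.  This module reads and cleans those tables,
loads optional per-entity static feature matrices, generates synthetic
benchmark matrices with planted block structure, and draws class-balanced
positive/negative training pairs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AssociationDataset",
    "StaticFeatures",
    "PairSample",
    "SyntheticDataset",
    "load_association_table",
    "save_association_table",
    "load_static_features",
    "generate_synthetic_dataset",
    "build_balanced_pairs",
]

logger = logging.getLogger("hgmda")

_HEADER_TOKENS = {
    "microbe", "microbes", "microbe_name", "taxon", "taxa", "organism",
    "disease", "diseases", "disease_name", "condition", "phenotype",
}


class DatasetError(ValueError):
    """Raised for malformed or empty association inputs."""


class SamplingError(ValueError):
    """Raised when a requested negative sample cannot be drawn."""


@dataclass
class AssociationDataset:
    """A named bipartite binary association matrix.

    ``A[i, j] == 1`` iff an association between ``microbe_names[i]`` and
    ``disease_names[j]`` is recorded.  Names are unique per axis.
    """

    microbe_names: list[str]
    disease_names: list[str]
    A: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.A = np.asarray(self.A)
        if self.A.shape != (len(self.microbe_names), len(self.disease_names)):
            raise DatasetError(
                f"matrix shape {self.A.shape} does not match name counts "
                f"({len(self.microbe_names)}, {len(self.disease_names)})"
            )
        if not np.isin(self.A, (0, 1)).all():
            raise DatasetError("association matrix must be binary")
        for axis, names in (("microbe", self.microbe_names), ("disease", self.disease_names)):
            if len(set(names)) != len(names):
                raise DatasetError(f"duplicate {axis} names")

    @property
    def n_microbes(self) -> int:
        return len(self.microbe_names)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_names)

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    @property
    def density(self) -> float:
        return self.n_associations / self.A.size

    def microbe_index(self, name: str) -> int:
        try:
            return self.microbe_names.index(name)
        except ValueError:
            raise KeyError(f"unknown microbe: {name!r}") from None

    def disease_index(self, name: str) -> int:
        try:
            return self.disease_names.index(name)
        except ValueError:
            raise KeyError(f"unknown disease: {name!r}") from None

    def summary(self) -> dict:
        return {
            "n_microbes": self.n_microbes,
            "n_diseases": self.n_diseases,
            "n_associations": self.n_associations,
            "density": self.density,
            "provenance": self.provenance,
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


@dataclass
class StaticFeatures:
    """A real-valued feature matrix aligned to an ordered entity-name list."""

    entity_names: list[str]
    F: np.ndarray

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape[0] != len(self.entity_names):
            raise DatasetError("feature row count does not match entity count")
        if not np.isfinite(self.F).all():
            raise DatasetError("static features contain non-finite values")


@dataclass(frozen=True)
class PairSample:
    """One supervised (microbe, disease, label) training/evaluation unit."""

    microbe_index: int
    disease_index: int
    label: int


@dataclass
class SyntheticDataset:
    """A planted-block benchmark: the dataset plus its ground-truth groups."""

    dataset: AssociationDataset
    microbe_blocks: np.ndarray = field(default_factory=lambda: np.array([]))
    disease_blocks: np.ndarray = field(default_factory=lambda: np.array([]))


def _looks_like_header(fields: list[str]) -> bool:
    return any(f.strip().lower() in _HEADER_TOKENS for f in fields[:2])


def load_association_table(path, delimiter: str = "\t") -> AssociationDataset:
    """Read a two-column (microbe, disease) table into a binary matrix.

    Names are stripped of surrounding whitespace and matched case-sensitively;
    duplicate pairs collapse to a single 1-entry.  A header row is recognised
    when its first cells match common column names (microbe/disease/taxon/...).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"association table not found: {path}")
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(delimiter)
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 2:
                raise DatasetError(f"line {lineno}: expected >=2 fields, got {len(fields)}")
            m, d = fields[0].strip(), fields[1].strip()
            if not m or not d:
                raise DatasetError(f"line {lineno}: empty microbe or disease name")
            pairs.append((m, d))
    if not pairs:
        raise DatasetError(f"no association rows in {path}")

    microbe_names = list(dict.fromkeys(m for m, _ in pairs))
    disease_names = list(dict.fromkeys(d for _, d in pairs))
    mi = {n: i for i, n in enumerate(microbe_names)}
    di = {n: i for i, n in enumerate(disease_names)}
    A = np.zeros((len(microbe_names), len(disease_names)), dtype=np.int8)
    for m, d in pairs:
        A[mi[m], di[d]] = 1
    n_unique = len(set(pairs))
    ds = AssociationDataset(microbe_names, disease_names, A, provenance=str(path))
    assert ds.n_associations == n_unique
    logger.info("loaded %s: %d microbes x %d diseases, %d associations",
                path.name, ds.n_microbes, ds.n_diseases, ds.n_associations)
    return ds


def save_association_table(dataset: AssociationDataset, path, delimiter: str = "\t") -> None:
    """Write the 1-entries back as a (microbe, disease) table; round-trips load."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"microbe{delimiter}disease\n")
        rows, cols = np.nonzero(dataset.A)
        for i, j in zip(rows, cols):
            fh.write(f"{dataset.microbe_names[i]}{delimiter}{dataset.disease_names[j]}\n")


def save_matrix_tsv(dataset: AssociationDataset, path) -> None:
    """Export the dense binary matrix as TSV with name headers."""
    df = pd.DataFrame(dataset.A, index=dataset.microbe_names, columns=dataset.disease_names)
    df.to_csv(path, sep="\t")


def load_static_features(path, entity_names: list[str], delimiter: str = "\t") -> StaticFeatures:
    """Load a numeric feature matrix and align its rows to ``entity_names``.

    The file may carry a leading name column (detected when the first field of
    the first data row is non-numeric); otherwise rows are taken in order.
    Entities missing from the file get all-zero rows, counted in a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature file not found: {path}")
    raw = pd.read_csv(path, sep=delimiter, header=None, dtype=str,
                      skip_blank_lines=True, comment="#")

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except (TypeError, ValueError):
            return False

    labeled = not _is_number(str(raw.iloc[0, 0]))
    if labeled:
        labels = [str(v).strip() for v in raw.iloc[:, 0]]
        body = raw.iloc[:, 1:]
    else:
        labels = None
        body = raw

    values = np.empty(body.shape, dtype=float)
    for r in range(body.shape[0]):
        for c in range(body.shape[1]):
            tok = body.iloc[r, c]
            try:
                values[r, c] = float(tok)
            except (TypeError, ValueError):
                raise DatasetError(
                    f"non-numeric value {tok!r} at row {r + 1}, column {c + 1} of {path}"
                ) from None

    n, d = len(entity_names), values.shape[1]
    F = np.zeros((n, d))
    if labels is None:
        if values.shape[0] > n:
            raise DatasetError(f"{values.shape[0]} feature rows for {n} entities")
        F[: values.shape[0]] = values
        missing = n - values.shape[0]
    else:
        by_label = {lab: values[i] for i, lab in enumerate(labels)}
        missing = 0
        for i, name in enumerate(entity_names):
            if name in by_label:
                F[i] = by_label[name]
            else:
                missing += 1
    if missing:
        logger.warning("%d of %d entities missing from %s; filled with zero rows",
                       missing, n, path.name)
    return StaticFeatures(list(entity_names), F)


def generate_synthetic_dataset(
    n_microbes: int,
    n_diseases: int,
    n_blocks: int,
    p_in: float,
    p_out: float,
    seed: int,
) -> SyntheticDataset:
    """Sample a bipartite association matrix with planted block structure.

    Microbes and diseases are each assigned round-robin to ``n_blocks`` groups
    (entity ``i`` belongs to group ``i mod n_blocks``, so group sizes and the
    expected density have closed forms).  A cell whose microbe and disease
    share a group is Bernoulli(``p_in``); all others Bernoulli(``p_out``).
    With ``p_in >> p_out`` this gives the clustered association pattern that
    interaction-profile similarity, KNN graphs and K-means hyperedges can
    recover; with ``p_in == p_out`` there is no recoverable signal.
    """
    if n_blocks > min(n_microbes, n_diseases) or n_blocks < 1:
        raise ValueError("n_blocks must be in [1, min(n_microbes, n_diseases)]")
    if not (0.0 <= p_out < p_in <= 1.0) and not (p_in == p_out and 0 <= p_in <= 1):
        raise ValueError("require 0 <= p_out < p_in <= 1 (or p_in == p_out for the null)")
    rng = np.random.default_rng(seed)
    mb = np.arange(n_microbes) % n_blocks
    db = np.arange(n_diseases) % n_blocks
    same = mb[:, None] == db[None, :]
    P = np.where(same, p_in, p_out)
    A = (rng.random((n_microbes, n_diseases)) < P).astype(np.int8)
    ds = AssociationDataset(
        [f"microbe_{i}" for i in range(n_microbes)],
        [f"disease_{j}" for j in range(n_diseases)],
        A,
        provenance=f"synthetic(blocks={n_blocks}, p_in={p_in}, p_out={p_out}, seed={seed})",
    )
    return SyntheticDataset(ds, mb, db)


def build_balanced_pairs(
    dataset: AssociationDataset, ratio: float = 1.0, seed: int = 0
) -> list[PairSample]:
    """All positive pairs plus ``ceil(ratio * n_pos)`` sampled negatives.

    Negatives are drawn uniformly without replacement from the zero entries of
    ``A`` (unverified pairs treated as negatives).  Deterministic under seed.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    pos = np.argwhere(np.asarray(dataset.A) == 1)
    neg = np.argwhere(np.asarray(dataset.A) == 0)
    if len(pos) == 0:
        raise SamplingError("dataset has no positive associations")
    n_neg = math.ceil(ratio * len(pos))
    if n_neg > len(neg):
        raise SamplingError(
            f"requested {n_neg} negatives but only {len(neg)} zero entries exist"
        )
    rng = np.random.default_rng(seed)
    chosen = neg[rng.choice(len(neg), size=n_neg, replace=False)]
    samples = [PairSample(int(i), int(j), 1) for i, j in pos]
    samples += [PairSample(int(i), int(j), 0) for i, j in chosen]
    return samples
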