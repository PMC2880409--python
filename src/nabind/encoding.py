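"""Windowed instance encoding for residue-wise classification.

Each data instance is a window of ``w`` consecutive residues (default 11)
centred on the target residue, encoded as the concatenation of per-residue
feature blocks.  Within a block the order is fixed:

    [H, K, M]                                 (3 values, group ``hkm``)
    [H̄, σ_H, K̄, σ_K, M̄, σ_M]                 (6 values, group ``descriptors``)
    [20 logistic-scaled PSSM scores]          (20 values, group ``pssm``)

so with all groups active and w = 11 the vector has 11 × 29 = 319 entries,
all in [0, 1].

Two extraction modes exist.  ``training`` yields the n − w + 1 fully
interior windows, replicating the construction used to fit classifiers.
``prediction`` yields one window per residue (n windows), padding past the
termini with all-zero blocks so every residue of a query receives a score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureTable
from .profiles import ConservationProfile, PSSMProfile
from .structure import LabeledSequence

logger = logging.getLogger(__name__)

GROUP_WIDTHS = {"hkm": 3, "descriptors": 6, "pssm": 20}
GROUP_ORDER = ("hkm", "descriptors", "pssm")
DEFAULT_WINDOW = 11


class EncodingError(ValueError):
    pass


def normalize_groups(groups) -> tuple[str, ...]:
    """Canonical ordered tuple of active feature groups."""
    alias = {"desc": "descriptors", "hkm": "hkm", "descriptors": "descriptors",
             "pssm": "pssm"}
    seen = set()
    for g in groups:
        g = alias.get(str(g).lower())
        if g is None:
            raise EncodingError(f"unknown feature group: {groups}")
        seen.add(g)
    return tuple(g for g in GROUP_ORDER if g in seen)


def block_width(groups) -> int:
    return sum(GROUP_WIDTHS[g] for g in normalize_groups(groups))


@dataclass
class SequenceProfiles:
    """Everything needed to encode one sequence's residues."""

    sequence: str
    table: FeatureTable
    conservation: ConservationProfile | None = None
    pssm: PSSMProfile | None = None

    def __post_init__(self) -> None:
        self._block_cache: dict[tuple[str, ...], np.ndarray] = {}

    def block_matrix(self, groups) -> np.ndarray:
        """(n, width) matrix of per-residue feature blocks, computed once."""
        groups = normalize_groups(groups)
        cached = self._block_cache.get(groups)
        if cached is not None:
            return cached
        n = len(self.sequence)
        parts = []
        if "hkm" in groups:
            parts.append(
                np.array([self.table.vector(aa, scaled=True)
                          for aa in self.sequence])
            )
        if "descriptors" in groups:
            if self.conservation is None or len(self.conservation) < n:
                raise EncodingError(
                    "conservation descriptors missing or shorter than sequence"
                )
            parts.append(self.conservation.scaled()[:n])
        if "pssm" in groups:
            if self.pssm is None or len(self.pssm) < n:
                raise EncodingError("PSSM missing or shorter than sequence")
            parts.append(self.pssm.scaled[:n])
        matrix = np.hstack(parts)
        self._block_cache[groups] = matrix
        return matrix

    def residue_block(self, pos: int, groups: tuple[str, ...]) -> np.ndarray:
        """Feature block for the residue at 0-based ``pos``."""
        groups = normalize_groups(groups)
        if pos >= len(self.sequence):
            raise EncodingError(f"no profile for position {pos + 1}")
        return self.block_matrix(groups)[pos]


@dataclass
class EncodingDescriptor:
    """Identifies an encoding scheme; must match between train and predict."""

    window: int = DEFAULT_WINDOW
    groups: tuple[str, ...] = GROUP_ORDER

    def __post_init__(self) -> None:
        self.groups = normalize_groups(self.groups)
        if self.window < 1 or self.window % 2 == 0:
            raise EncodingError(f"window must be odd and >= 1, got {self.window}")

    @property
    def vector_length(self) -> int:
        return self.window * block_width(self.groups)

    def to_dict(self) -> dict:
        return {"window": self.window, "groups": list(self.groups),
                "vector_length": self.vector_length}

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingDescriptor":
        return cls(window=d["window"], groups=tuple(d["groups"]))


def extract_instances(
    labeled_seq: LabeledSequence,
    w: int = DEFAULT_WINDOW,
    mode: str = "training",
) -> list[tuple[list[int | None], int, int]]:
    """Enumerate windows as (positions, target position, label) triples.

    ``positions`` holds 0-based residue indices, with ``None`` marking a
    padding slot (prediction mode only).  Training mode emits the
    max(0, n − w + 1) interior windows; prediction mode emits one window
    per residue.
    """
    if w < 1 or w % 2 == 0:
        raise EncodingError(f"window must be odd and >= 1, got {w}")
    n = len(labeled_seq.sequence)
    half = w // 2
    out = []
    if mode == "training":
        if n < w:
            logger.warning(
                "%s: length %d < window %d, no training instances",
                labeled_seq.id, n, w,
            )
            return []
        for center in range(half, n - half):
            positions = list(range(center - half, center + half + 1))
            out.append((positions, center, int(labeled_seq.labels[center])))
    elif mode == "prediction":
        for center in range(n):
            positions = [
                p if 0 <= p < n else None
                for p in range(center - half, center + half + 1)
            ]
            out.append((positions, center, int(labeled_seq.labels[center])))
    else:
        raise EncodingError(f"mode must be 'training' or 'prediction': {mode}")
    return out


def encode_window(
    positions: list[int | None],
    profiles: SequenceProfiles,
    groups,
) -> np.ndarray:
    """Concatenate per-residue blocks left to right; pads are all-zero."""
    groups = normalize_groups(groups)
    width = block_width(groups)
    matrix = profiles.block_matrix(groups)
    blocks = []
    for pos in positions:
        if pos is None:
            blocks.append(np.zeros(width))
        else:
            if pos >= matrix.shape[0]:
                raise EncodingError(f"no profile for position {pos + 1}")
            blocks.append(matrix[pos])
    return np.concatenate(blocks)


@dataclass
class InstanceSet:
    """Encoded instance matrix with labels and provenance."""

    X: np.ndarray  # (m, d) in [0, 1]
    y: np.ndarray  # ±1
    sequence_ids: list[str]
    positions: np.ndarray  # 0-based target residue positions
    descriptor: EncodingDescriptor = field(default_factory=EncodingDescriptor)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.positions = np.asarray(self.positions, dtype=int)
        m = self.X.shape[0]
        if not (len(self.y) == len(self.sequence_ids) == len(self.positions) == m):
            raise EncodingError("inconsistent instance-set lengths")
        if m and self.X.shape[1] != self.descriptor.vector_length:
            raise EncodingError(
                f"vector length {self.X.shape[1]} != descriptor "
                f"{self.descriptor.vector_length}"
            )

    def __len__(self) -> int:
        return self.X.shape[0]

    def save(self, prefix: str | Path) -> None:
        """Dense TSV matrix plus a JSON sidecar describing the layout."""
        prefix = Path(prefix)
        with open(prefix.with_suffix(".tsv"), "w") as fh:
            for i in range(len(self)):
                fields = [self.sequence_ids[i], str(self.positions[i]),
                          str(self.y[i])]
                fields += [f"{v:.6f}" for v in self.X[i]]
                fh.write("\t".join(fields) + "\n")
        sidecar = {
            "descriptor": self.descriptor.to_dict(),
            "columns": ["sequence_id", "position", "label"]
            + [f"f{j}" for j in range(self.descriptor.vector_length)],
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "InstanceSet":
        prefix = Path(prefix)
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        descriptor = EncodingDescriptor.from_dict(sidecar["descriptor"])
        ids, positions, labels, rows = [], [], [], []
        for line in open(prefix.with_suffix(".tsv")):
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            positions.append(int(parts[1]))
            labels.append(int(parts[2]))
            rows.append([float(v) for v in parts[3:]])
        X = np.array(rows) if rows else np.empty((0, descriptor.vector_length))
        return cls(X, np.array(labels), ids, np.array(positions), descriptor)


def encode_dataset(
    labeled_seqs: list[LabeledSequence],
    profiles_by_id: dict[str, SequenceProfiles],
    descriptor: EncodingDescriptor | None = None,
    mode: str = "training",
) -> InstanceSet:
    """Window and encode a whole dataset into one instance matrix."""
    descriptor = descriptor or EncodingDescriptor()
    X, y, ids, positions = [], [], [], []
    for rec in labeled_seqs:
        profiles = profiles_by_id[rec.id]
        for window_positions, center, label in extract_instances(
            rec, w=descriptor.window, mode=mode
        ):
            X.append(encode_window(window_positions, profiles, descriptor.groups))
            y.append(label)
            ids.append(rec.id)
            positions.append(center)
    X = np.array(X) if X else np.empty((0, descriptor.vector_length))
    return InstanceSet(X, np.array(y, dtype=int), ids,
                       np.array(positions, dtype=int), descriptor)
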