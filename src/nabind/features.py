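"""Per-residue biochemical features used for input encoding.

Three scalar properties describe each amino acid: the hydrophobicity index
(feature ``H``, Kyte–Doolittle scale), the side-chain pKa (feature ``K``,
0.0 for residues without an ionizable side chain) and the monoisotopic
residue mass in daltons (feature ``M``).  The default table ships as a
tab-separated data file so an alternative scale can be swapped in without
touching code.

All downstream encoding uses min-max scaled values in [0, 1]; the scaling
bounds are always computed over the 20 standard amino acids, so the
extremes of each feature map to exactly 0 and 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

FEATURE_NAMES = ("H", "K", "M")

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / rare codes folded onto the 'X' mean row.
_AMBIGUOUS = set("BZJUO")


class DegenerateFeatureError(ValueError):
    """A feature column is constant and cannot be min-max scaled."""


class InvalidResidueError(ValueError):
    """Residue code is not a letter."""


@dataclass(frozen=True)
class FeatureTable:
    """Mapping amino-acid letter -> (H, K, M), raw and min-max scaled.

    ``raw`` covers the 20 standard amino acids plus 'X'; any other letter
    is resolved to 'X' at lookup time.  ``bounds`` holds the (min, max) of
    each feature over the standard amino acids and defines the scaling.
    """

    raw: dict[str, tuple[float, float, float]]
    bounds: dict[str, tuple[float, float]] = field(init=False)

    def __post_init__(self) -> None:
        missing = [a for a in STANDARD_AA if a not in self.raw]
        if missing:
            raise ValueError(f"feature table incomplete, missing {missing}")
        bounds = {}
        for j, name in enumerate(FEATURE_NAMES):
            vals = [self.raw[a][j] for a in STANDARD_AA]
            lo, hi = min(vals), max(vals)
            if hi == lo:
                raise DegenerateFeatureError(
                    f"feature {name} is constant ({lo}); cannot scale"
                )
            bounds[name] = (lo, hi)
        object.__setattr__(self, "bounds", bounds)
        if "X" not in self.raw:
            means = tuple(
                float(np.mean([self.raw[a][j] for a in STANDARD_AA]))
                for j in range(3)
            )
            self.raw["X"] = means

    def resolve(self, aa: str) -> str:
        if not (isinstance(aa, str) and len(aa) == 1 and aa.isalpha()):
            raise InvalidResidueError(f"not an amino-acid letter: {aa!r}")
        aa = aa.upper()
        if aa in self.raw and aa not in _AMBIGUOUS:
            return aa
        return "X"

    def vector(self, aa: str, scaled: bool = True) -> np.ndarray:
        """Return the (H, K, M) triple for ``aa``.

        Unknown or ambiguous letters (X, B, Z, J, U, O, ...) return the
        per-feature mean over the standard amino acids.
        """
        vals = np.asarray(self.raw[self.resolve(aa)], dtype=float)
        if scaled:
            vals = np.array(
                [self.scale_value(name, v) for name, v in zip(FEATURE_NAMES, vals)]
            )
        return vals

    def value(self, aa: str, feature: str, scaled: bool = False) -> float:
        j = FEATURE_NAMES.index(feature)
        return float(self.vector(aa, scaled=scaled)[j])

    def scale_value(self, feature: str, value: float) -> float:
        """Affine map of a raw feature value onto the table's [0, 1] range."""
        lo, hi = self.bounds[feature]
        return (value - lo) / (hi - lo)

    def feature_range(self, feature: str) -> float:
        lo, hi = self.bounds[feature]
        return hi - lo

    @property
    def scaled(self) -> dict[str, tuple[float, float, float]]:
        return {
            a: tuple(self.vector(a, scaled=True)) for a in self.raw
        }


def normalize_table(raw: dict[str, tuple[float, float, float]]) -> dict[str, tuple[float, float, float]]:
    """Min-max scale each feature column of ``raw`` independently to [0, 1].

    Scaling bounds come from the 20 standard amino acids; the map is
    strictly monotone per feature, hence rank-preserving, and idempotent
    once values already span [0, 1].
    """
    table = FeatureTable(raw=dict(raw))
    return table.scaled


def residue_feature_vector(aa: str, table: FeatureTable, scaled: bool = True) -> np.ndarray:
    """(H, K, M) for one residue letter; total over A-Z (unknowns -> means)."""
    return table.vector(aa, scaled=scaled)


def load_feature_table(path: str | Path | None = None) -> FeatureTable:
    """Load a feature table from a 4-column TSV (letter, H, K, M).

    With no ``path``, the packaged default table is used.
    """
    if path is None:
        source = resources.files("nabind.data").joinpath("features.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    raw: dict[str, tuple[float, float, float]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("letter"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"feature table line {lineno}: expected 4 columns")
        letter = parts[0].strip().upper()
        raw[letter] = (float(parts[1]), float(parts[2]), float(parts[3]))
    return FeatureTable(raw=raw)
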