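"""Evolutionary information: PSSM parsing and conservation descriptors.

Two kinds of evolutionary features are produced for a query sequence:

* the 20 per-position PSSM substitution scores from a PSI-BLAST profile
  search, squashed to (0, 1) with a logistic transform, and
* three conservation descriptors — for each biochemical feature
  X in {H, K, M}, the mean and population standard deviation of X over
  the residues aligned to each query position in the query's homologues
  (the query itself is always included, so every column is non-empty).

The homologue search itself is external: precomputed PSSM files, aligned
FASTA alignments, or tabular pairwise alignments are accepted everywhere,
and :func:`run_psiblast` is only a convenience wrapper.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .features import FEATURE_NAMES, STANDARD_AA, FeatureTable

_GAP_CHARS = set("-.")
_EXCLUDED = set("BZJUOX*")  # no single defined feature value


class PSSMFormatError(ValueError):
    """Malformed ASCII PSSM file."""


class AlignmentConsistencyError(ValueError):
    """Alignment does not match the query sequence."""


class PsiBlastUnavailableError(RuntimeError):
    """The external psiblast executable or database is missing."""


@dataclass
class PSSMProfile:
    """Per-position PSI-BLAST substitution scores for a query sequence."""

    query_id: str
    alphabet: str  # 20 letters, column order as emitted by the search tool
    scores: np.ndarray  # (n, 20) integers
    query: str = ""  # query residue letters, one per row, when known

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise PSSMFormatError(
                f"PSSM must be (n, 20), got {self.scores.shape}"
            )

    def __len__(self) -> int:
        return self.scores.shape[0]

    @property
    def scaled(self) -> np.ndarray:
        """Logistic squashing of raw scores into (0, 1), order-preserving."""
        return scale_pssm_scores(self.scores)


def scale_pssm_scores(raw):
    """1 / (1 + exp(-raw)): strictly increasing, 0 maps to 0.5."""
    return 1.0 / (1.0 + np.exp(-np.asarray(raw, dtype=float)))


def read_pssm(path: str | Path) -> PSSMProfile:
    """Parse an ASCII PSSM matrix file (psiblast ``-out_ascii_pssm``).

    Rows are query positions; the first 20 numeric columns of each row are
    the substitution scores, in the alphabet order given by the header line.
    """
    lines = Path(path).read_text().splitlines()
    alphabet = None
    rows, letters = [], []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        parts = stripped.split()
        if alphabet is None:
            # header: 40 single letters (20 score cols + 20 frequency cols),
            # or 20 in handwritten fixtures
            if len(parts) >= 20 and all(len(p) == 1 and p.isalpha() for p in parts[:20]):
                alphabet = "".join(parts[:20])
            continue
        if not parts[0].isdigit():
            continue  # footer (K/lambda statistics)
        if len(parts) < 22 or len(parts[1]) != 1:
            raise PSSMFormatError(f"{path}, line {lineno}: malformed PSSM row")
        try:
            scores = [int(x) for x in parts[2:22]]
        except ValueError as exc:
            raise PSSMFormatError(
                f"{path}, line {lineno}: non-integer score ({exc})"
            ) from exc
        rows.append(scores)
        letters.append(parts[1])
    if alphabet is None or not rows:
        raise PSSMFormatError(f"{path}: no PSSM matrix found")
    return PSSMProfile(
        query_id=Path(path).stem, alphabet=alphabet,
        scores=np.array(rows, dtype=int), query="".join(letters),
    )


@dataclass
class ColumnObservations:
    """Residue letters observed at each query position (query included)."""

    query: str
    columns: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.columns) != len(self.query):
            raise AlignmentConsistencyError(
                f"{len(self.columns)} columns vs query length {len(self.query)}"
            )
        for i, col in enumerate(self.columns):
            if not col:
                raise AlignmentConsistencyError(f"empty column at position {i + 1}")

    def counts(self) -> np.ndarray:
        return np.array([len(c) for c in self.columns])


@dataclass
class PairwiseHit:
    """One local alignment of a homologue onto the query.

    Coordinates are 1-based inclusive on the unaligned sequences; ``qseq``
    and ``sseq`` are the aligned (gapped) texts.  ``score`` breaks ties when
    one homologue has several overlapping HSPs (higher wins; omitted scores
    fall back to file order).
    """

    query_id: str
    subject_id: str
    qstart: int
    qend: int
    sstart: int
    send: int
    qseq: str
    sseq: str
    score: float = 0.0


def read_pairwise_tab(path: str | Path) -> list[PairwiseHit]:
    """Read tabular pairwise alignments (8 columns, optional 9th = score)."""
    hits = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        # skip comments and non-tabular chatter (e.g. convergence markers)
        if not line.strip() or line.startswith("#") or "\t" not in line:
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 8:
            raise ValueError(f"{path}, line {lineno}: expected >=8 columns")
        hits.append(
            PairwiseHit(
                parts[0], parts[1], int(parts[2]), int(parts[3]),
                int(parts[4]), int(parts[5]), parts[6], parts[7],
                float(parts[8]) if len(parts) > 8 else 0.0,
            )
        )
    return hits


def _observe(col: list[str], letter: str) -> None:
    letter = letter.upper()
    if letter in _GAP_CHARS or letter in _EXCLUDED:
        return
    if letter in STANDARD_AA:
        col.append(letter)


def build_column_observations(
    query: str,
    msa=None,
    pairwise: list[PairwiseHit] | None = None,
) -> ColumnObservations:
    """Collect, per query position, the query residue plus aligned homologue
    residues.

    ``msa`` is an aligned-FASTA path or Bio.Align alignment whose FIRST
    record is the query; ``pairwise`` is a list of local alignments in query
    coordinates.  Gaps and ambiguity codes never contribute; for pairwise
    input, each homologue contributes at most one residue per position (its
    best-scoring alignment covering that position), and positions outside
    all of a homologue's alignments get nothing from it.
    """
    query = query.upper()
    columns: list[list[str]] = [[aa] for aa in query]

    if msa is not None and pairwise is not None:
        raise ValueError("give either an MSA or pairwise alignments, not both")

    if msa is not None:
        if isinstance(msa, (str, Path)):
            msa = AlignIO.read(str(msa), "fasta")
        rows = [str(rec.seq).upper() for rec in msa]
        if not rows:
            raise AlignmentConsistencyError("empty alignment")
        aligned_query = rows[0]
        if aligned_query.replace("-", "").replace(".", "") != query:
            raise AlignmentConsistencyError(
                "first alignment record does not match the query sequence"
            )
        qpos = -1
        for col_idx, qchar in enumerate(aligned_query):
            if qchar in _GAP_CHARS:
                continue
            qpos += 1
            for row in rows[1:]:
                _observe(columns[qpos], row[col_idx])

    elif pairwise is not None:
        by_subject: dict[str, list[PairwiseHit]] = {}
        for order, hit in enumerate(pairwise):
            by_subject.setdefault(hit.subject_id, []).append(hit)
        for subject_hits in by_subject.values():
            # best score first; stable sort keeps file order on ties
            subject_hits = sorted(subject_hits, key=lambda h: -h.score)
            claimed: dict[int, str] = {}
            for hit in subject_hits:
                degapped = hit.qseq.replace("-", "")
                if degapped != query[hit.qstart - 1:hit.qend]:
                    raise AlignmentConsistencyError(
                        f"{hit.subject_id}: aligned query text does not match "
                        f"query[{hit.qstart}:{hit.qend}]"
                    )
                qpos = hit.qstart - 2  # advanced before use
                for qchar, schar in zip(hit.qseq, hit.sseq):
                    if qchar in _GAP_CHARS:
                        continue
                    qpos += 1
                    if qpos not in claimed:
                        claimed[qpos] = schar
            for qpos, schar in claimed.items():
                _observe(columns[qpos], schar)

    return ColumnObservations(query=query, columns=columns)


def column_feature_stats(
    observations: list[str], feature: str, table: FeatureTable
) -> tuple[float, float]:
    """Mean and population standard deviation of one feature over a column."""
    if not observations:
        raise AlignmentConsistencyError("empty column")
    values = np.array([table.value(aa, feature) for aa in observations])
    mean = float(values.mean())
    sd = float(np.sqrt(np.mean((values - mean) ** 2)))
    return mean, sd


@dataclass
class ConservationProfile:
    """Per-position conservation descriptors H̄±σ, K̄±σ, M̄±σ.

    ``means`` and ``sds`` are (n, 3) arrays of raw feature units in column
    order (H, K, M); ``scaled()`` maps means with the same per-feature
    min-max bounds as single-residue encoding and divides each σ by the
    feature's raw range, so descriptor values are commensurate with the
    [0, 1] single-residue features.
    """

    query_id: str
    means: np.ndarray
    sds: np.ndarray
    table: FeatureTable = field(repr=False)

    def __len__(self) -> int:
        return self.means.shape[0]

    def scaled(self) -> np.ndarray:
        """(n, 6) array: [H̄, σ_H, K̄, σ_K, M̄, σ_M] per position, in [0, 1]."""
        n = len(self)
        out = np.empty((n, 6))
        for j, name in enumerate(FEATURE_NAMES):
            rng = self.table.feature_range(name)
            out[:, 2 * j] = [self.table.scale_value(name, v) for v in self.means[:, j]]
            out[:, 2 * j + 1] = self.sds[:, j] / rng
        return np.clip(out, 0.0, 1.0)


def conservation_profile(
    obs: ColumnObservations, table: FeatureTable, query_id: str = "query"
) -> ConservationProfile:
    n = len(obs.query)
    means = np.empty((n, 3))
    sds = np.empty((n, 3))
    for i, col in enumerate(obs.columns):
        for j, name in enumerate(FEATURE_NAMES):
            means[i, j], sds[i, j] = column_feature_stats(col, name, table)
    return ConservationProfile(query_id, means, sds, table)


def run_psiblast(
    query_fasta: str | Path,
    database: str | Path,
    out_prefix: str | Path,
    iterations: int = 3,
    evalue: float = 1e-5,
    executable: str = "psiblast",
) -> tuple[Path, Path]:
    """Run a profile search: ``iterations`` rounds at inclusion E <= ``evalue``.

    Writes ``<prefix>.pssm`` (ASCII PSSM) and ``<prefix>.tab`` (tabular
    pairwise alignments readable by :func:`read_pairwise_tab`).  Entirely
    optional: every downstream step also accepts precomputed files.
    """
    if shutil.which(executable) is None:
        raise PsiBlastUnavailableError(
            f"{executable} not found on PATH; supply precomputed PSSM/alignment "
            "files instead"
        )
    out_prefix = Path(out_prefix)
    pssm_path = out_prefix.with_suffix(".pssm")
    tab_path = out_prefix.with_suffix(".tab")
    cmd = [
        executable,
        "-query", str(query_fasta),
        "-db", str(database),
        "-num_iterations", str(iterations),
        "-evalue", str(evalue),
        "-inclusion_ethresh", str(evalue),
        "-out_ascii_pssm", str(pssm_path),
        "-outfmt", "6 qseqid sseqid qstart qend sstart send qseq sseq bitscore",
        "-out", str(tab_path),
    ]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise PsiBlastUnavailableError(
            f"psiblast failed (is the database formatted?): {proc.stderr.strip()}"
        )
    return pssm_path, tab_path


def write_profile_tsv(
    path: str | Path,
    pssm: PSSMProfile | None,
    conservation: ConservationProfile | None,
) -> None:
    """One row per query position: 20 scaled PSSM values + 6 descriptors."""
    n = len(pssm) if pssm is not None else len(conservation)
    pssm_block = pssm.scaled if pssm is not None else None
    cons_block = conservation.scaled() if conservation is not None else None
    with open(path, "w") as fh:
        header = ["position"]
        if pssm is not None:
            header += [f"pssm_{a}" for a in pssm.alphabet]
        if conservation is not None:
            header += ["H_mean", "H_sd", "K_mean", "K_sd", "M_mean", "M_sd"]
        fh.write("\t".join(header) + "\n")
        for i in range(n):
            row = [str(i + 1)]
            if pssm_block is not None:
                row += [f"{v:.6f}" for v in pssm_block[i]]
            if cons_block is not None:
                row += [f"{v:.6f}" for v in cons_block[i]]
            fh.write("\t".join(row) + "\n")
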