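"""Sequence and profile input/output.

A position specific frequency matrix (PSFM) describes a protein of length
``L`` as an ``L x 20`` row-stochastic matrix: entry ``(i, j)`` is the
occurrence probability of amino acid ``j`` at sequence position ``i`` in the
multiple alignment the profile was derived from, and every row sums to 1.

Columns are kept in a single canonical order everywhere in this package:
alphabetical one-letter codes, ``ACDEFGHIKLMNPQRSTVWY``.  Files produced by
PSI-BLAST use a different residue order; the parser remaps on ingest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

#: Canonical amino-acid column order used for every feature index downstream.
CANONICAL_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX = {aa: i for i, aa in enumerate(CANONICAL_ORDER)}

#: Nonstandard letters optionally treated like 'X' by the strict filter.
AMBIGUOUS_LETTERS = frozenset("BZUO")

ROW_SUM_TOLERANCE = 1e-3


class ProfileError(ValueError):
    """Raised for malformed sequence or profile inputs."""


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ProfileError("sequence id must be nonempty")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class PSFM:
    """An ``L x 20`` row-stochastic profile in canonical column order.

    Parameters
    ----------
    id : str
        Identifier of the underlying protein.
    matrix : ndarray of shape (L, 20)
        Per-position amino-acid frequencies; each row sums to 1.
    source : {"psiblast", "plain", "onehot", "synthetic"}
        Where the profile came from.
    sequence : str, optional
        The query (or pseudo-) sequence, required by the residue-probing
        transformation which groups profile rows by query residue.
    """

    id: str
    matrix: np.ndarray
    source: str = "plain"
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ProfileError(
                f"{self.id}: PSFM must have 20 columns, got shape {self.matrix.shape}"
            )
        if self.matrix.shape[0] < 1:
            raise ProfileError(f"{self.id}: PSFM must have at least one row")
        if self.sequence is not None and len(self.sequence) != self.matrix.shape[0]:
            raise ProfileError(
                f"{self.id}: sequence length {len(self.sequence)} does not match "
                f"profile length {self.matrix.shape[0]}"
            )

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    def pseudo_sequence(self) -> str:
        """Most probable residue per position (argmax of each row)."""
        return "".join(CANONICAL_ORDER[j] for j in self.matrix.argmax(axis=1))


@dataclass
class LabeledDataset:
    """Profiles paired with binary labels (1 = positive class)."""

    items: list[tuple[str, PSFM, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [i for i, _, _ in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ProfileError(f"duplicate ids in dataset: {dupes}")
        for i, _, y in self.items:
            if y not in (0, 1):
                raise ProfileError(f"{i}: label must be 0 or 1, got {y!r}")

    @property
    def ids(self) -> list[str]:
        return [i for i, _, _ in self.items]

    @property
    def labels(self) -> np.ndarray:
        return np.array([y for _, _, y in self.items], dtype=int)

    @property
    def psfms(self) -> list[PSFM]:
        return [p for _, p, _ in self.items]

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum()) if self.items else 0

    @property
    def n_neg(self) -> int:
        return len(self.items) - self.n_pos

    def __len__(self) -> int:
        return len(self.items)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.items[i] for i in indices])


# ---------------------------------------------------------------------------
# FASTA and sequence-level filtering
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Sequences are uppercased and whitespace-stripped.  A record with an
    empty sequence is a parse error naming the record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).replace(" ", "").replace("\t", "").upper()
        if not seq:
            raise ProfileError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append(ProteinSequence(id=rec.id, residues=seq))
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for start in range(0, len(s.residues), 60):
                fh.write(s.residues[start : start + 60] + "\n")


def filter_sequences(
    seqs: Sequence[ProteinSequence],
    min_len: int = 50,
    strict: bool = False,
) -> tuple[list[ProteinSequence], list[tuple[ProteinSequence, str]]]:
    """Apply the benchmark-construction sequence filters.

    Sequences shorter than ``min_len`` residues or containing the
    undetermined-residue character 'X' are removed.  With ``strict=True``
    the rarer ambiguity codes B, Z, U, O are treated like 'X' as well.

    Returns
    -------
    (kept, removed)
        ``removed`` pairs each rejected sequence with a reason string.
    """
    bad_letters = {"X"} | (set(AMBIGUOUS_LETTERS) if strict else set())
    kept: list[ProteinSequence] = []
    removed: list[tuple[ProteinSequence, str]] = []
    for s in seqs:
        if s.length < min_len:
            removed.append((s, f"length {s.length} < {min_len}"))
            continue
        hit = next((c for c in s.residues if c in bad_letters), None)
        if hit is not None:
            removed.append((s, f"contains ambiguous residue {hit!r}"))
            continue
        kept.append(s)
    return kept, removed


# ---------------------------------------------------------------------------
# PSFM construction and validation
# ---------------------------------------------------------------------------

def validate_psfm(
    matrix: np.ndarray | Sequence[Sequence[float]],
    id: str = "psfm",
    source: str = "plain",
    sequence: str | None = None,
) -> PSFM:
    """Validate a numeric matrix as a PSFM and renormalize its rows.

    Accepts a rectangular matrix with exactly 20 columns, entries in
    ``[0, 1]`` and row sums within ``1e-3`` of 1 (integer-percentage
    profiles round); rows are then renormalized to sum exactly 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != 20:
        raise ProfileError(f"{id}: expected an L x 20 matrix, got shape {m.shape}")
    if not np.isfinite(m).all():
        row = int(np.flatnonzero(~np.isfinite(m).all(axis=1))[0])
        raise ProfileError(f"{id}: non-finite entry in row {row}")
    bad = (m < 0) | (m > 1)
    if bad.any():
        row = int(np.flatnonzero(bad.any(axis=1))[0])
        raise ProfileError(f"{id}: entry outside [0, 1] in row {row}")
    sums = m.sum(axis=1)
    off = np.abs(sums - 1.0) > ROW_SUM_TOLERANCE
    if off.any():
        row = int(np.flatnonzero(off)[0])
        raise ProfileError(
            f"{id}: row {row} sums to {sums[row]:.6g}, outside tolerance "
            f"{ROW_SUM_TOLERANCE} of 1"
        )
    m = m / sums[:, None]
    return PSFM(id=id, matrix=m, source=source, sequence=sequence)


def onehot_psfm(seq: ProteinSequence) -> PSFM:
    """Profile-free fallback: row ``i`` is the indicator of residue ``R_i``."""
    m = np.zeros((seq.length, 20))
    for i, aa in enumerate(seq.residues):
        j = AA_TO_INDEX.get(aa)
        if j is None:
            raise ProfileError(
                f"{seq.id}: nonstandard residue {aa!r} at position {i + 1}"
            )
        m[i, j] = 1.0
    return PSFM(id=seq.id, matrix=m, source="onehot", sequence=seq.residues)


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM parsing
# ---------------------------------------------------------------------------

def parse_psiblast_pssm(path: str | Path, id: str | None = None) -> PSFM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into a PSFM.

    The file carries two 20-column blocks per position: log-odds scores and
    weighted observed percentages.  The PSFM is built from the second block
    divided by 100 — it is the block with frequency semantics (rows of the
    profile must sum to 1).  Columns are remapped from the file's header
    order to the canonical order.  Positions whose twenty percentages are
    all zero (no alignment evidence) fall back to the one-hot row of the
    query residue, keeping every row stochastic.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_cols: list[str] | None = None
    header_lineno = 0
    for lineno, line in enumerate(lines, start=1):
        toks = line.split()
        if len(toks) == 40 and all(len(t) == 1 and t.isalpha() for t in toks):
            unknown = [t for t in toks if t.upper() not in AA_TO_INDEX]
            if unknown:
                raise ProfileError(
                    f"{path.name}:{lineno}: unknown residue letter(s) "
                    f"{unknown} in PSSM header"
                )
            header_cols = [t.upper() for t in toks]
            header_lineno = lineno
            break
    if header_cols is None:
        raise ProfileError(f"{path.name}: no 40-column PSSM header line found")

    # Column j of the percentages block maps to canonical index perm[j].
    perm = np.array([AA_TO_INDEX[a] for a in header_cols[20:]], dtype=int)

    rows: list[np.ndarray] = []
    residues: list[str] = []
    for lineno, line in enumerate(
        lines[header_lineno:], start=header_lineno + 1
    ):
        toks = line.split()
        if not toks:
            continue
        if not toks[0].isdigit():
            break  # footer (Lambda/K statistics) ends the table
        if len(toks) < 42:
            raise ProfileError(
                f"{path.name}:{lineno}: expected at least 42 columns, got {len(toks)}"
            )
        residue = toks[1].upper()
        try:
            percents = np.array([float(t) for t in toks[22:42]])
        except ValueError as exc:
            raise ProfileError(f"{path.name}:{lineno}: non-numeric cell ({exc})")
        if percents.sum() == 0:
            if residue not in AA_TO_INDEX:
                raise ProfileError(
                    f"{path.name}:{lineno}: all-zero row with nonstandard "
                    f"query residue {residue!r}"
                )
            row = np.zeros(20)
            row[AA_TO_INDEX[residue]] = 1.0
        else:
            row = np.zeros(20)
            row[perm] = percents / 100.0
        rows.append(row)
        residues.append(residue)

    if not rows:
        raise ProfileError(f"{path.name}: PSSM table contains no position rows")

    matrix = np.vstack(rows)
    matrix = matrix / matrix.sum(axis=1, keepdims=True)
    seq = "".join(residues)
    return PSFM(
        id=id or path.stem,
        matrix=matrix,
        source="psiblast",
        sequence=seq if re.fullmatch(f"[{CANONICAL_ORDER}]+", seq) else None,
    )


# ---------------------------------------------------------------------------
# Plain whitespace-delimited profile format
# ---------------------------------------------------------------------------

def read_plain_profile(path: str | Path, id: str | None = None) -> PSFM:
    """Read a plain profile: '#' comment lines, then L lines of 20 floats.

    A comment line ``# sequence: <residues>`` restores the query sequence.
    """
    path = Path(path)
    sequence: str | None = None
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*sequence:\s*(\S+)", line)
            if m:
                sequence = m.group(1)
            continue
        toks = line.split()
        if len(toks) != 20:
            raise ProfileError(
                f"{path.name}:{lineno}: expected 20 values, got {len(toks)}"
            )
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise ProfileError(f"{path.name}:{lineno}: non-numeric cell ({exc})")
    if not rows:
        raise ProfileError(f"{path.name}: profile file contains no data rows")
    return validate_psfm(rows, id=id or path.stem, source="plain", sequence=sequence)


def write_plain_profile(psfm: PSFM, path: str | Path) -> None:
    """Write a PSFM in the plain format; round-trips to 1e-9 per element."""
    with open(path, "w") as fh:
        fh.write(f"# columns: {' '.join(CANONICAL_ORDER)}\n")
        if psfm.sequence is not None:
            fh.write(f"# sequence: {psfm.sequence}\n")
        for row in psfm.matrix:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Labels and dataset assembly
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of ``id<TAB>{0|1}`` (header line optional)."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ProfileError(f"labels line {lineno}: expected 2 columns")
        sid, lab = parts
        if lineno == 1 and lab not in ("0", "1"):
            continue  # header row
        if lab not in ("0", "1"):
            raise ProfileError(f"labels line {lineno}: label must be 0 or 1")
        if sid in labels:
            raise ProfileError(f"labels line {lineno}: duplicate id {sid!r}")
        labels[sid] = int(lab)
    return labels


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")


def load_dataset(profile_dir: str | Path, labels_path: str | Path) -> LabeledDataset:
    """Assemble a LabeledDataset from a directory of plain profiles + labels."""
    profile_dir = Path(profile_dir)
    labels = read_labels(labels_path)
    items = []
    for sid, lab in labels.items():
        candidates = [profile_dir / f"{sid}.profile", profile_dir / f"{sid}.pssm"]
        found = next((p for p in candidates if p.exists()), None)
        if found is None:
            raise ProfileError(f"no profile file for id {sid!r} in {profile_dir}")
        psfm = (
            read_plain_profile(found, id=sid)
            if found.suffix == ".profile"
            else parse_psiblast_pssm(found, id=sid)
        )
        items.append((sid, psfm, lab))
    return LabeledDataset(items)
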