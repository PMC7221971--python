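"""Per-protein sequence descriptors: graph-energy profiles and dipeptide composition.

A protein of length n is encoded as a 20 x n adjacency profile whose column j
is the substitution-matrix column of the residue at position j (in the fixed
physicochemical basis of :mod:`graphppi.alphabet`). A length-20 window slides
along the profile one residue at a time, producing n - 19 sub-matrices, each
read as the biadjacency matrix of a bipartite graph on 20 + 20 vertices. The
energy of that graph — the sum of the absolute eigenvalues of its full
adjacency [[0, M], [M^T, 0]] — equals twice the sum of the singular values
of M, which is how it is computed here.

Two substitution matrices give the two spectral descriptors:

* the *unit* matrix (identity in the physicochemical basis) gives the
  physicochemical graph-energy profile (PGE);
* a real-valued amino-acid contact-energy matrix gives the contact
  graph-energy profile (CGE).

Each profile is fixed at 200 entries: windows beyond the sequence are
zero-padded (sequences shorter than 219 residues yield fewer than 200
windows), and longer sequences are truncated to their first 200 windows.
The third descriptor is the 400-entry dipeptide composition
f_mn = N_mn / (L - 1), counting ordered adjacent residue pairs. The fused
feature is the concatenation [PGE; CGE; dipeptide], 800 entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .alphabet import AA_INDEX, N_AA, PHYSICOCHEMICAL_ORDER
from .sequence_io import ProteinRecord

logger = logging.getLogger(__name__)

WINDOW: int = 20
N_WINDOWS: int = 200
DIPEPTIDE_DIM: int = N_AA * N_AA
FUSED_DIM: int = 2 * N_WINDOWS + DIPEPTIDE_DIM


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A 20 x 20 real matrix indexed by the physicochemical residue ordering."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_AA, N_AA):
            raise ValueError(f"substitution matrix must be 20x20, got {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("substitution matrix contains non-finite entries")
        object.__setattr__(self, "values", v)

    @classmethod
    def unit(cls) -> "SubstitutionMatrix":
        """The unit substitution matrix: identity in the ordering basis."""
        return cls(name="unit", values=np.eye(N_AA))


def load_contact_matrix(path: str | Path) -> SubstitutionMatrix:
    """Load a 20 x 20 contact-energy matrix from labelled delimited text.

    The file must carry one-letter residue codes as header row and first
    column; rows/columns are permuted into the internal physicochemical
    basis regardless of the file's own ordering.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str).str.strip().str.upper()
    df.columns = df.columns.astype(str).str.strip().str.upper()
    order = list(PHYSICOCHEMICAL_ORDER)
    missing = set(order) - set(df.index) | set(order) - set(df.columns)
    if df.shape != (N_AA, N_AA):
        raise ValueError(f"contact matrix must be 20x20, got {df.shape} in {path}")
    if missing:
        raise ValueError(f"contact matrix {path}: missing residue labels {sorted(missing)}")
    values = df.loc[order, order].to_numpy(dtype=float)
    return SubstitutionMatrix(name="contact", values=values)


def default_contact_matrix() -> SubstitutionMatrix:
    """The packaged contact-energy fixture.

    This is a synthetic stand-in: a deterministic symmetric matrix on the
    scale of statistical contact energies, shipped so the pipeline runs
    with no external downloads. Substitute a real contact-energy matrix
    via :func:`load_contact_matrix` for biological work.
    """
    ref = resources.files("graphppi.data") / "contact_energy_synthetic.tsv"
    with resources.as_file(ref) as path:
        return load_contact_matrix(path)


def encode_adjacency(record: ProteinRecord, matrix: SubstitutionMatrix) -> np.ndarray:
    """Build the 20 x n adjacency profile of *record* under *matrix*.

    Column j is the matrix column of residue j; residues outside the
    canonical alphabet (possible under the "zero" residue policy)
    contribute an all-zero column.
    """
    n = record.length
    profile = np.zeros((N_AA, n))
    for j, aa in enumerate(record.seq):
        t = AA_INDEX.get(aa)
        if t is not None:
            profile[:, j] = matrix.values[:, t]
    return profile


def window_energy(mk: np.ndarray) -> float:
    """Graph energy of the bipartite graph with biadjacency matrix *mk*.

    Equals the sum of absolute eigenvalues of the (2w x 2w) symmetric
    adjacency [[0, mk], [mk^T, 0]], i.e. twice the nuclear norm of mk.
    """
    mk = np.asarray(mk, dtype=float)
    if not np.isfinite(mk).all():
        raise ValueError("window matrix contains non-finite entries")
    return 2.0 * float(np.linalg.svd(mk, compute_uv=False).sum())


def energy_profile(
    record: ProteinRecord,
    matrix: SubstitutionMatrix,
    n_windows: int = N_WINDOWS,
    window: int = WINDOW,
) -> np.ndarray:
    """Sliding-window graph-energy vector of fixed length *n_windows*.

    Entry k is the energy of the window starting at residue k+1; entries
    past the last available window are exactly zero (zero-padding), and
    sequences longer than n_windows + window - 1 are truncated to their
    first n_windows windows.
    """
    out = np.zeros(n_windows)
    n = record.length
    if n < window:
        logger.warning(
            "protein %s: length %d < window %d, energy profile all-zero",
            record.id, n, window,
        )
        return out
    profile = encode_adjacency(record, matrix)
    k = min(n - window + 1, n_windows)
    # (20, k_total, window) -> (k, window, 20) stacks for one batched SVD
    wins = sliding_window_view(profile, window, axis=1)[:, :k, :]
    stack = np.moveaxis(wins, 1, 0)
    out[:k] = 2.0 * np.linalg.svd(stack, compute_uv=False).sum(axis=1)
    return out


def dipeptide_composition(record: ProteinRecord) -> np.ndarray:
    """400-entry dipeptide frequency vector f_mn = N_mn / (L - 1).

    N_mn counts ordered adjacent pairs (residue m followed by residue n);
    the flat index is 20*m + n in the physicochemical basis. Pairs with a
    non-canonical member are skipped (counts only; the denominator stays
    L - 1). Single-residue sequences yield the all-zero vector.
    """
    out = np.zeros(DIPEPTIDE_DIM)
    length = record.length
    if length < 2:
        logger.warning("protein %s: length < 2, dipeptide vector all-zero", record.id)
        return out
    for a, b in zip(record.seq, record.seq[1:]):
        m = AA_INDEX.get(a)
        n = AA_INDEX.get(b)
        if m is not None and n is not None:
            out[N_AA * m + n] += 1.0
    return out / (length - 1)


def fuse(
    record: ProteinRecord,
    unit: SubstitutionMatrix,
    contact: SubstitutionMatrix,
    n_windows: int = N_WINDOWS,
    include_dipeptide: bool = True,
) -> np.ndarray:
    """Fused per-protein descriptor [PGE; CGE; dipeptide]."""
    parts = [
        energy_profile(record, unit, n_windows=n_windows),
        energy_profile(record, contact, n_windows=n_windows),
    ]
    if include_dipeptide:
        parts.append(dipeptide_composition(record))
    return np.concatenate(parts)


def feature_table(
    records: dict[str, ProteinRecord],
    unit: SubstitutionMatrix | None = None,
    contact: SubstitutionMatrix | None = None,
    n_windows: int = N_WINDOWS,
) -> pd.DataFrame:
    """Fused features for every protein, one row per id.

    Columns are named pge_001..pge_200, cge_001..cge_200 and dp_<m><n>.
    """
    unit = unit or SubstitutionMatrix.unit()
    contact = contact if contact is not None else default_contact_matrix()
    rows = {pid: fuse(rec, unit, contact, n_windows=n_windows) for pid, rec in records.items()}
    cols = (
        [f"pge_{k + 1:03d}" for k in range(n_windows)]
        + [f"cge_{k + 1:03d}" for k in range(n_windows)]
        + [f"dp_{a}{b}" for a in PHYSICOCHEMICAL_ORDER for b in PHYSICOCHEMICAL_ORDER]
    )
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
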