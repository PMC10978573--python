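"""Position-specific scoring matrices over IMGT (or plain integer) positions."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclasses.dataclass
class Pssm:
    """Per-position amino-acid probability table.

    ``positions`` are external labels (IMGT positions such as ``"42"`` or
    ``"111A"``, or plain indices for unaligned corpora); ``matrix`` has one
    row per position, each a probability vector over the 20 canonical
    residues in alphabetical order; ``support`` counts the observations
    behind each row.
    """

    label: str
    positions: list[str]
    matrix: np.ndarray  # (n_positions, 20), rows sum to 1
    support: np.ndarray | None = None  # (n_positions,)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape != (len(self.positions), 20):
            raise ValueError("PSSM matrix must be (n_positions, 20)")
        if np.any(self.matrix < 0):
            raise ValueError("PSSM rows must be non-negative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PSSM rows must each sum to 1")
        if self.support is not None:
            self.support = np.asarray(self.support)
            if np.any(self.support < 1):
                raise ValueError("PSSM support must be >= 1 wherever a row exists")

    @property
    def index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.positions)}

    def row(self, position: str) -> np.ndarray:
        return self.matrix[self.index[position]]

    def consensus(self) -> str:
        """Modal residue at every position (ties broken alphabetically)."""
        return "".join(AMINO_ACIDS[int(np.argmax(row))] for row in self.matrix)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.positions, columns=list(AMINO_ACIDS))

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.insert(0, "position", df.index)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "pssm") -> "Pssm":
        df = pd.read_csv(path)
        positions = [str(p) for p in df["position"]]
        matrix = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
        return cls(label=label, positions=positions, matrix=matrix)


def random_pssm(length: int, seed: int, concentration: float = 0.5,
                label: str = "random") -> Pssm:
    """Dirichlet-sampled PSSM; low concentration gives peaked, realistic rows."""
    rng = np.random.default_rng(seed)
    matrix = rng.dirichlet([concentration] * 20, size=length)
    return Pssm(label=label, positions=[str(i + 1) for i in range(length)],
                matrix=matrix, support=np.ones(length, dtype=int))


def sample_from_pssm(pssm: Pssm, n: int, seed: int) -> list[str]:
    """Draw ``n`` i.i.d. sequences, residues sampled independently per position."""
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    L = len(pssm.positions)
    # one multinomial draw per (sequence, position)
    cum = np.cumsum(pssm.matrix, axis=1)
    cum[:, -1] = 1.0
    u = rng.random((n, L))
    idx = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    aa = np.array(list(AMINO_ACIDS))
    return ["".join(row) for row in aa[idx]]
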