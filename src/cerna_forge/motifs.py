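"""Transcription-factor motif definitions: IUPAC consensus strings and PWMs.

Two text inputs are supported: a MEME-minimal motif file (``MOTIF`` blocks
with a ``letter-probability matrix``) and a plain consensus file of
``name<TAB>IUPAC`` lines. Both load into :class:`Motif`, which scores a
window as sum of log2(p_base / 0.25) (consensus strings are expanded to a
uniform PWM over their allowed bases).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .errors import FormatError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# probability granted to a base outside the PWM's support, so log-odds stay finite
_PSEUDO = 1e-3


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Motif:
    """A motif as a 4 x width probability matrix (rows A, C, G, T).

    ``consensus`` is kept when the motif came from an IUPAC string, for
    exact-match reporting.
    """

    motif_id: str
    pwm: np.ndarray
    consensus: str | None = None

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[0] != 4:
            raise FormatError(f"{self.motif_id}: PWM must be 4 x width")
        sums = self.pwm.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-3):
            raise FormatError(f"{self.motif_id}: PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.pwm.shape[1]

    def log_odds(self, background: float = 0.25) -> np.ndarray:
        p = np.maximum(self.pwm, _PSEUDO)
        return np.log2(p / background)

    def max_score(self, background: float = 0.25) -> float:
        return float(self.log_odds(background).max(axis=0).sum())

    def score(self, window: str, background: float = 0.25) -> float:
        if len(window) != self.width:
            raise ValueError("window length must equal motif width")
        lo = self.log_odds(background)
        total = 0.0
        for j, base in enumerate(window):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                return -math.inf
            total += lo[idx, j]
        return total

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str) -> "Motif":
        consensus = consensus.upper()
        bad = [c for c in consensus if c not in IUPAC]
        if bad:
            raise FormatError(f"{motif_id}: non-IUPAC characters {bad}")
        pwm = np.zeros((4, len(consensus)))
        for j, code in enumerate(consensus):
            allowed = IUPAC[code]
            for base in allowed:
                pwm[_BASE_INDEX[base], j] = 1.0 / len(allowed)
        return cls(motif_id, pwm, consensus=consensus)

    def to_regex(self) -> "re.Pattern[str]":
        if self.consensus is None:
            raise ValueError("only consensus motifs expand to a regex")
        return re.compile("".join(f"[{IUPAC[c]}]" for c in self.consensus))


def read_meme_minimal(path) -> list[Motif]:
    """Parse the MEME minimal motif format (letter-probability matrices)."""
    motifs: list[Motif] = []
    name: str | None = None
    rows: list[list[float]] = []
    expecting_matrix = False

    def flush():
        nonlocal name, rows
        if name is not None:
            if not rows:
                raise FormatError(f"motif {name!r} has no probability matrix")
            motifs.append(Motif(name, np.array(rows).T))
        name, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                parts = line.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}: MOTIF line without a name")
                name = parts[1]
                expecting_matrix = False
            elif line.startswith("letter-probability matrix"):
                expecting_matrix = True
            elif expecting_matrix and line and name is not None:
                try:
                    vals = [float(x) for x in line.split()]
                except ValueError:
                    expecting_matrix = False
                    continue
                if len(vals) != 4:
                    raise FormatError(f"{path}: matrix row with {len(vals)} columns")
                rows.append(vals)
    flush()
    return motifs


def write_meme_minimal(motifs, path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n"
            )
            for col in m.pwm.T:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


def read_consensus_file(path) -> list[Motif]:
    """Plain ``name<TAB>IUPAC`` lines -> consensus motifs."""
    motifs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'name<TAB>consensus'")
            motifs.append(Motif.from_consensus(parts[0], parts[1]))
    return motifs
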