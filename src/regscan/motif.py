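"""Position frequency / weight matrices built from top-scoring PBM sites.

The array probes carry fixed-length binding sites that are pre-aligned by
design, so the motif is obtained by straight column counting over the k
highest-z sites (default k=25) rather than by EM-style discovery.  The matrix
is exposed in probability (PFM), log-odds (PWM, bits) and per-column
information-content forms, and round-trips through MEME minimal text format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import DNA_ALPHABET, check_dna

BASE_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}
UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass
class PositionMatrix:
    """A DNA motif: 4 x width base probabilities plus a background composition.

    Rows are ordered A, C, G, T.  ``pseudocount`` records the total
    background-apportioned pseudocount used at construction; ``n_sites`` the
    number of aligned sites counted.
    """

    frequencies: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 0.0
    n_sites: int = 0

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.frequencies.ndim != 2 or self.frequencies.shape[0] != 4:
            raise ValueError("frequencies must be a 4 x width matrix (rows A,C,G,T)")
        if self.background.shape != (4,):
            raise ValueError("background must be a length-4 vector")
        if not np.allclose(self.frequencies.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("every frequency column must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if np.any(self.background <= 0):
            raise ValueError("background entries must be positive")
        if self.pseudocount > 0 and np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be positive when pseudocount > 0")

    @property
    def width(self) -> int:
        return self.frequencies.shape[1]

    def consensus(self) -> str:
        return "".join(DNA_ALPHABET[i] for i in self.frequencies.argmax(axis=0))


def select_top_sites(profile, k: int = 25) -> list[str]:
    """The k non-background sequences with the highest z-scores.

    Ties in z are broken by ascending lexicographic sequence order so the
    selection is deterministic.
    """
    fg = profile.z[~profile.is_background]
    if k > len(fg):
        raise ValueError(f"requested top {k} sites but only {len(fg)} non-background sequences")
    order = sorted(fg.items(), key=lambda item: (-item[1], item[0]))
    return [seq for seq, _ in order[:k]]


def build_pfm(
    sites: Sequence[str],
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
) -> PositionMatrix:
    """Count aligned equal-length sites into a PositionMatrix.

    frequencies[b][j] = (count(b, j) + pseudocount * background[b]) / (n + pseudocount)
    """
    if len(sites) == 0:
        raise ValueError("need at least one site")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("sites must all have the same length")
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, dtype=float)
    counts = np.zeros((4, width))
    for s in sites:
        check_dna(s)
        for j, base in enumerate(s):
            counts[BASE_INDEX[base], j] += 1
    freqs = (counts + pseudocount * bg[:, None]) / (len(sites) + pseudocount)
    return PositionMatrix(freqs, bg, pseudocount=pseudocount, n_sites=len(sites))


def pfm_to_pwm(pfm: PositionMatrix) -> np.ndarray:
    """Log-odds matrix in bits: log2(frequency / background)."""
    if np.any(pfm.frequencies <= 0):
        raise ValueError("zero frequencies: rebuild the PFM with a positive pseudocount")
    return np.log2(pfm.frequencies / pfm.background[:, None])


def information_content(pfm: PositionMatrix) -> np.ndarray:
    """Per-column information content in bits, relative to the background.

    IC_j = sum_b f[b][j] log2(f[b][j] / background[b]); with a uniform
    background this is 2 minus the column entropy.
    """
    f = pfm.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f / pfm.background[:, None]), 0.0)
    return terms.sum(axis=0)


def reverse_complement_pfm(pfm: PositionMatrix) -> PositionMatrix:
    # reversing both axes maps (base, position) -> (complement, mirrored position)
    return PositionMatrix(
        pfm.frequencies[::-1, ::-1].copy(),
        pfm.background[::-1].copy(),
        pseudocount=pfm.pseudocount,
        n_sites=pfm.n_sites,
    )


def max_score(pwm: np.ndarray) -> float:
    return float(pwm.max(axis=0).sum())


def score_sequence(pwm: np.ndarray, seq: str) -> float:
    """Log-odds score of one sequence of exactly the motif width."""
    if len(seq) != pwm.shape[1]:
        raise ValueError("sequence length must equal motif width")
    return float(sum(pwm[BASE_INDEX[b], j] for j, b in enumerate(seq)))


def sample_sites(pfm: PositionMatrix, n: int, rng: np.random.Generator) -> list[str]:
    """Draw n sites column-independently from the PFM probabilities."""
    cols = [rng.choice(4, size=n, p=pfm.frequencies[:, j] / pfm.frequencies[:, j].sum())
            for j in range(pfm.width)]
    stacked = np.stack(cols, axis=1)
    return ["".join(DNA_ALPHABET[i] for i in row) for row in stacked]


# ---------------------------------------------------------------------------
# MEME minimal motif format (version 4 text)

def write_meme(pfm: PositionMatrix, path: str | Path, name: str = "motif1") -> None:
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {p:.6f}" for b, p in zip(DNA_ALPHABET, pfm.background)),
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {pfm.width} nsites= {max(pfm.n_sites, 1)} E= 0",
    ]
    for j in range(pfm.width):
        lines.append(" ".join(f"{pfm.frequencies[b, j]:.6f}" for b in range(4)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_meme(path: str | Path) -> PositionMatrix:
    """Parse the first motif from a MEME minimal-format file."""
    lines = Path(path).read_text().splitlines()
    background = UNIFORM_BACKGROUND.copy()
    rows: list[list[float]] = []
    n_sites = 0
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            tokens = lines[i + 1].split()
            background = np.array([float(tokens[2 * k + 1]) for k in range(4)])
            i += 2
            continue
        if line.startswith("letter-probability matrix"):
            fields = dict(zip(line.split()[2::2], line.split()[3::2]))
            width = int(fields["w="])
            n_sites = int(float(fields.get("nsites=", 0)))
            for j in range(1, width + 1):
                rows.append([float(x) for x in lines[i + j].split()[:4]])
            break
        i += 1
    if not rows:
        raise ValueError(f"no letter-probability matrix found in {path}")
    freqs = np.array(rows).T
    freqs = freqs / freqs.sum(axis=0, keepdims=True)  # guard printed rounding
    return PositionMatrix(freqs, background, pseudocount=0.0, n_sites=n_sites)
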