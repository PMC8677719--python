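"""Strand-aware upstream window extraction and exact-p-value motif scanning.

Windows of (default) 500 bp immediately upstream of each TSS are extracted
reading 5'->3' toward the TSS, then every offset on both strands is scored
with the motif's log-odds matrix.  P-values are exact under the i.i.d.
background model, computed by dynamic programming over a discretized score
grid; a position is a hit when its p-value is at or below the threshold
(default 1e-4, the FIMO default).  When both strands pass at one offset the
site is counted once.

Coordinates are 0-based half-open internally; GFF3 input is converted from
1-based closed, BED is native.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import reverse_complement
from .motif import PositionMatrix, pfm_to_pwm

log = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# score assigned to ambiguity codes: effectively -inf on the integer grid
_N_PENALTY = -(10**9)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    tss: int  # 0-based genomic coordinate of the transcription start base

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be non-negative")


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    sequence: str
    genomic_start: int  # 0-based half-open on the + genome strand
    genomic_end: int
    strand: str
    contig: str = ""


@dataclass(frozen=True)
class SiteHit:
    gene_id: str
    offset: int          # 0-based start of the site within the window
    strand_of_hit: str   # relative to the window
    score: float         # log-odds, bits
    p_value: float


@dataclass
class ScanResult:
    hits: dict[str, list[SiteHit]]
    counts: dict[str, int] = field(default_factory=dict)
    threshold_p: float = 1e-4

    def __post_init__(self):
        if not self.counts:
            self.counts = {g: len(h) for g, h in self.hits.items()}
        for g, h in self.hits.items():
            if self.counts[g] != len(h):
                raise ValueError(f"count for {g} does not match its hit list")


# ---------------------------------------------------------------------------
# gene model input

def read_gff3_genes(path: str | Path, feature: str = "gene") -> list[GeneModel]:
    """Gene models from GFF3 ``gene`` records; the TSS is the strand-aware
    5' end of the feature (1-based closed converted to 0-based)."""
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2] != feature:
            continue
        contig, start, end, strand = f[0], int(f[3]), int(f[4]), f[6]
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        gene_id = attrs.get("ID") or attrs.get("Name") or f"{contig}:{start}-{end}"
        tss = start - 1 if strand == "+" else end - 1
        genes.append(GeneModel(gene_id, contig, strand, tss))
    return genes


def read_bed6_genes(path: str | Path) -> list[GeneModel]:
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        contig, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        tss = start if strand == "+" else end - 1
        genes.append(GeneModel(name, contig, strand, tss))
    return genes


# ---------------------------------------------------------------------------
# window extraction

def extract_upstream(
    genome: Mapping[str, str] | str | Path,
    genes: Iterable[GeneModel],
    window: int = 500,
) -> list[PromoterWindow]:
    """Extract the ``window`` bp upstream of each TSS, 5'->3' toward the TSS.

    + strand genes take genomic [tss-window, tss); - strand genes take
    (tss, tss+window] reverse-complemented.  Windows truncated at contig
    edges are kept (with a log record); empty windows are skipped with a
    warning.
    """
    if not isinstance(genome, Mapping):
        import pyfaidx
        genome = pyfaidx.Fasta(str(genome), as_raw=True, sequence_always_upper=True)
    windows = []
    for gene in genes:
        if gene.contig not in genome:
            raise KeyError(f"contig {gene.contig!r} for gene {gene.gene_id} not in genome")
        contig_seq = genome[gene.contig]
        length = len(contig_seq)
        if gene.strand == "+":
            start, end = max(0, gene.tss - window), min(gene.tss, length)
        else:
            start, end = max(0, gene.tss + 1), min(gene.tss + 1 + window, length)
        if end <= start:
            log.warning("gene %s: empty upstream window, skipped", gene.gene_id)
            continue
        seq = str(contig_seq[start:end]).upper()
        if gene.strand == "-":
            seq = reverse_complement(seq)
        if end - start < window:
            log.info("gene %s: window truncated to %d bp at contig edge",
                     gene.gene_id, end - start)
        windows.append(PromoterWindow(gene.gene_id, seq, start, end, gene.strand,
                                      contig=gene.contig))
    return windows


# ---------------------------------------------------------------------------
# exact null score distribution

class ScoreDistribution:
    """Exact distribution of PWM scores of i.i.d. background sequences.

    Matrix entries are rounded onto a grid of ``bins`` steps spanning the
    achievable score range and the distribution of the integer total is built
    by dynamic programming over positions; the same rounding is applied to
    query scores so p-values and hit calls are mutually consistent.  The
    discretization error on any total score is at most width x step / 2.
    """

    def __init__(self, pwm: np.ndarray, background: np.ndarray, bins: int = 1000):
        if bins < 2:
            raise ValueError("bins must be >= 2")
        pwm = np.asarray(pwm, dtype=float)
        if not np.all(np.isfinite(pwm)):
            raise ValueError("PWM entries must be finite")
        background = np.asarray(background, dtype=float)
        self.width = pwm.shape[1]
        smin = pwm.min(axis=0).sum()
        smax = pwm.max(axis=0).sum()
        span = smax - smin
        self.step = span / bins if span > 0 else 1.0
        self.int_pwm = np.rint(pwm / self.step).astype(np.int64)
        # dist[i] = P(partial score == offset + i); support grows column by column
        dist = np.array([1.0])
        offset = 0
        for j in range(self.width):
            col = self.int_pwm[:, j]
            cmin, cmax = int(col.min()), int(col.max())
            new = np.zeros(len(dist) + cmax - cmin)
            for b in range(4):
                shift = int(col[b]) - cmin
                new[shift:shift + len(dist)] += dist * background[b]
            offset += cmin
            dist = new
        self.kmin, self.kmax = offset, offset + len(dist) - 1
        self.pmf = dist
        # tail[i] = P(S_int >= kmin + i)
        self.tail = np.cumsum(dist[::-1])[::-1]

    def quantize(self, score: float) -> int:
        return int(np.rint(score / self.step))

    def pvalue_int(self, k: int) -> float:
        if k <= self.kmin:
            return 1.0
        if k > self.kmax:
            return float(self.tail[-1])
        return float(self.tail[k - self.kmin])

    def pvalue(self, score: float) -> float:
        """P(S >= score) under the background model (grid-rounded)."""
        return self.pvalue_int(self.quantize(score))

    def score_threshold(self, p: float) -> int | None:
        """Smallest integer grid score whose tail probability is <= p."""
        idx = np.searchsorted(-self.tail, -p)  # tail is non-increasing
        while idx < len(self.tail) and self.tail[idx] > p:
            idx += 1
        if idx >= len(self.tail):
            return None
        return self.kmin + idx


# ---------------------------------------------------------------------------
# scanning

def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, 4) for c in seq), dtype=np.int64, count=len(seq))


def _int_scores(codes: np.ndarray, int_pwm: np.ndarray) -> np.ndarray:
    """Integer-grid scores at every offset (vectorized sliding window)."""
    w = int_pwm.shape[1]
    padded = np.vstack([int_pwm, np.full((1, w), _N_PENALTY, dtype=np.int64)])
    wins = np.lib.stride_tricks.sliding_window_view(codes, w)
    return padded[wins, np.arange(w)].sum(axis=1)


def scan_windows(
    windows: Sequence[PromoterWindow],
    pfm: PositionMatrix,
    threshold_p: float = 1e-4,
    bins: int = 1000,
) -> ScanResult:
    """Score every offset of every window on both strands; a hit is a
    position with exact p-value <= threshold_p.  Both-strand passes at one
    offset are counted once (the better-scoring strand is reported)."""
    pwm = pfm_to_pwm(pfm)
    pwm_rc = pwm[::-1, ::-1]
    bg = pfm.background
    # the minus-strand statistic scores the forward sequence with the
    # reverse-complement matrix; the sequence is still drawn from ``bg``
    dist_f = ScoreDistribution(pwm, bg, bins=bins)
    dist_r = ScoreDistribution(pwm_rc, bg, bins=bins)
    w = pfm.width
    hits: dict[str, list[SiteHit]] = {}
    for win in windows:
        gene_hits: list[SiteHit] = []
        if len(win.sequence) < w:
            log.warning("gene %s: window shorter than motif width, 0 hits", win.gene_id)
            hits[win.gene_id] = gene_hits
            continue
        codes = _encode(win.sequence)
        k_f = _int_scores(codes, dist_f.int_pwm)
        k_r = _int_scores(codes, dist_r.int_pwm)
        for off in range(len(k_f)):
            p_f = dist_f.pvalue_int(int(k_f[off])) if k_f[off] > _N_PENALTY // 2 else 1.0
            p_r = dist_r.pvalue_int(int(k_r[off])) if k_r[off] > _N_PENALTY // 2 else 1.0
            hit_f = p_f <= threshold_p
            hit_r = p_r <= threshold_p
            if not (hit_f or hit_r):
                continue
            if hit_f and (not hit_r or p_f <= p_r):
                strand, p, score = "+", p_f, float(k_f[off] * dist_f.step)
            else:
                strand, p, score = "-", p_r, float(k_r[off] * dist_r.step)
            gene_hits.append(SiteHit(win.gene_id, off, strand, score, p))
        hits[win.gene_id] = gene_hits
    return ScanResult(hits=hits, threshold_p=threshold_p)


def genes_with_sites(result: ScanResult, min_sites: int = 1) -> tuple[set[str], dict[int, int]]:
    """Genes with at least ``min_sites`` hits plus the histogram of nonzero
    per-gene site counts."""
    selected = {g for g, c in result.counts.items() if c >= min_sites}
    histogram = dict(Counter(c for c in result.counts.values() if c > 0))
    return selected, histogram


# ---------------------------------------------------------------------------
# output

def hits_to_bed(result: ScanResult, windows: Sequence[PromoterWindow],
                motif_width: int, path: str | Path) -> None:
    """Write hits as BED6 in genomic coordinates; score column is -log10 p."""
    by_gene = {w.gene_id: w for w in windows}
    lines = []
    for gene_id, gene_hits in sorted(result.hits.items()):
        win = by_gene[gene_id]
        for h in gene_hits:
            if win.strand == "+":
                gstart = win.genomic_start + h.offset
                gstrand = h.strand_of_hit
            else:
                gstart = win.genomic_end - h.offset - motif_width
                gstrand = "+" if h.strand_of_hit == "-" else "-"
            score = -np.log10(max(h.p_value, 1e-300))
            contig = win.contig or gene_id
            lines.append(f"{contig}\t{gstart}\t{gstart + motif_width}"
                         f"\t{gene_id}\t{score:.3f}\t{gstrand}")
    Path(path).write_text("".join(line + "\n" for line in lines))


def counts_to_tsv(result: ScanResult, path: str | Path) -> None:
    df = pd.DataFrame(sorted(result.counts.items()), columns=["gene_id", "n_sites"])
    df.to_csv(path, sep="\t", index=False)
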