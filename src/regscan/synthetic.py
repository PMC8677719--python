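"""Seeded synthetic inputs with the statistical structure each pipeline stage
assumes, plus ground-truth records for recovery tests.

Four generators share one SimConfig and one root seed (child RNG streams are
derived per stage, so regenerating one input never perturbs another):

* PBM probe tables: 36-bp probes, 8 replicate probes per unique sequence per
  replicate array.  Bound probes carry a site sampled from a hidden truth
  motif centered in the probe; their log-fluorescence is
  baseline + affinity_scale * max(0, best log-odds of the truth motif over
  the probe) + Normal(0, noise_sd).  Background probes get baseline + noise.
* Three-stage FPKM tables with a planted driver gene at exact configured
  fold ratios, a configurable fraction of strictly stage-increasing
  (concordant) genes, shuffled-order rest, replicate-level lognormal noise
  and zero-inflated gene x stage cells (all replicates zeroed).
* Promoter sequences (one contig per gene, both strands) with 0-4
  non-overlapping consensus implants per gene inside the upstream window,
  written as FASTA + GFF3/BED6 so window extraction recovers the implants.
* A gene-category map with one category enriched among concordant genes by a
  configurable odds multiplier.

Default sizes mirror the study scale: 2592 bound / 1159 background probe
sequences, 8 replicate probes, 2 arrays, a 10-bp truth motif, 8674 genes in
three stages (driver folds 2.3 and 5.0), 500-bp promoters.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from .expression import DEFAULT_STAGE_ORDER
from .motif import (BASE_INDEX, PositionMatrix, build_pfm, pfm_to_pwm,
                    sample_sites, score_sequence)
from .scan import GeneModel

PROBE_LENGTH = 36          # fixed PBM probe design, site centered
_KB_CONSENSUS = "GGGAATTCCC"  # palindromic kB site used as the truth consensus


@dataclass
class SimConfig:
    """All knobs of the synthetic-data generators, with study-scale defaults."""

    seed: int = 0
    # PBM
    n_bound_probes: int = 2592
    n_background_probes: int = 1159
    probe_replicates: int = 8
    n_arrays: int = 2
    truth_motif_width: int = 10
    affinity_scale: float = 0.5     # log-fluorescence per bit of log-odds
    noise_sd: float = 0.2           # sd of log-fluorescence / log-FPKM noise
    baseline_log_fluorescence: float = 7.0
    # expression
    n_genes: int = 8674
    stage_names: tuple[str, ...] = DEFAULT_STAGE_ORDER
    expression_replicates: int = 3
    driver_folds: tuple[float, float] = (2.3, 5.0)
    concordant_fraction: float = 0.155
    zero_inflation: float = 0.05
    # promoters
    promoter_length: int = 500
    sites_per_gene_range: tuple[int, int] = (0, 4)
    # categories
    n_categories: int = 20
    category_size_range: tuple[int, int] = (40, 80)
    enriched_category_effect: float = 5.0

    def __post_init__(self):
        counts = dict(n_bound_probes=self.n_bound_probes,
                      n_background_probes=self.n_background_probes,
                      probe_replicates=self.probe_replicates,
                      n_arrays=self.n_arrays,
                      truth_motif_width=self.truth_motif_width,
                      n_genes=self.n_genes,
                      expression_replicates=self.expression_replicates,
                      promoter_length=self.promoter_length,
                      n_categories=self.n_categories)
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.probe_replicates < 2:
            raise ValueError("probe_replicates must be >= 2")
        for name in ("concordant_fraction", "zero_inflation"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        f1, f2 = self.driver_folds
        if not (f1 > 1 and f2 > f1):
            raise ValueError("driver_folds must be > 1 and strictly increasing")
        if len(self.stage_names) != 3:
            raise ValueError("exactly 3 stage names required")
        lo, hi = self.sites_per_gene_range
        if lo < 0 or hi < lo:
            raise ValueError("sites_per_gene_range must be a non-negative interval")
        if self.truth_motif_width > PROBE_LENGTH:
            raise ValueError("truth_motif_width exceeds the probe length")


@dataclass
class TruthRecord:
    """Ground truth for recovery tests; generators fill their own fields."""

    truth_pfm: PositionMatrix | None = None
    concordant_gene_ids: set[str] = field(default_factory=set)
    driver_gene_id: str | None = None
    implanted_sites: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    enriched_category_id: str | None = None

    def merge(self, other: "TruthRecord") -> "TruthRecord":
        return TruthRecord(
            truth_pfm=other.truth_pfm or self.truth_pfm,
            concordant_gene_ids=self.concordant_gene_ids | other.concordant_gene_ids,
            driver_gene_id=other.driver_gene_id or self.driver_gene_id,
            implanted_sites={**self.implanted_sites, **other.implanted_sites},
            enriched_category_id=other.enriched_category_id or self.enriched_category_id,
        )

    def to_json(self, path: str | Path) -> None:
        obj = {
            "truth_pfm": None if self.truth_pfm is None else {
                "frequencies": self.truth_pfm.frequencies.tolist(),
                "background": self.truth_pfm.background.tolist(),
                "pseudocount": self.truth_pfm.pseudocount,
                "n_sites": self.truth_pfm.n_sites,
            },
            "concordant_gene_ids": sorted(self.concordant_gene_ids),
            "driver_gene_id": self.driver_gene_id,
            "implanted_sites": {g: [[o, s] for o, s in v]
                                for g, v in self.implanted_sites.items()},
            "enriched_category_id": self.enriched_category_id,
        }
        io.write_json(obj, path)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        obj = io.read_json(path)
        pfm = None
        if obj.get("truth_pfm"):
            t = obj["truth_pfm"]
            pfm = PositionMatrix(np.array(t["frequencies"]), np.array(t["background"]),
                                 pseudocount=t["pseudocount"], n_sites=t["n_sites"])
        return cls(
            truth_pfm=pfm,
            concordant_gene_ids=set(obj["concordant_gene_ids"]),
            driver_gene_id=obj["driver_gene_id"],
            implanted_sites={g: [(int(o), s) for o, s in v]
                             for g, v in obj["implanted_sites"].items()},
            enriched_category_id=obj["enriched_category_id"],
        )


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent per-stage RNG stream derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(stream.encode())]))


def truth_motif(width: int, consensus_weight: float = 0.85) -> PositionMatrix:
    """The hidden motif governing bound-probe signal: the kB palindrome
    GGGAATTCCC (tiled or trimmed to ``width``) with ``consensus_weight`` on
    the consensus base per column and the rest spread evenly."""
    consensus = (_KB_CONSENSUS * (width // len(_KB_CONSENSUS) + 1))[:width]
    freqs = np.full((4, width), (1 - consensus_weight) / 3)
    for j, base in enumerate(consensus):
        freqs[BASE_INDEX[base], j] = consensus_weight
    return PositionMatrix(freqs, n_sites=0, pseudocount=0.0)


def _random_dna(rng: np.random.Generator, length: int,
                composition: np.ndarray | None = None) -> str:
    p = composition if composition is not None else np.full(4, 0.25)
    return "".join(io.DNA_ALPHABET[i] for i in rng.choice(4, size=length, p=p))


def _best_log_odds(pwm: np.ndarray, seq: str) -> float:
    """Max log-odds of the motif over all offsets and both strands."""
    w = pwm.shape[1]
    rc = io.reverse_complement(seq)
    best = -np.inf
    for s in (seq, rc):
        for off in range(len(s) - w + 1):
            best = max(best, score_sequence(pwm, s[off:off + w]))
    return best


# ---------------------------------------------------------------------------
# PBM

def simulate_pbm(config: SimConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Probe tables for all replicate arrays plus the truth motif.

    Returns one tidy table (columns probe_id, sequence, replicate, array,
    fluorescence, is_background) holding every array; each unique sequence
    appears ``probe_replicates`` times per array.
    """
    rng = child_rng(config.seed, "pbm")
    pfm = truth_motif(config.truth_motif_width)
    pwm = pfm_to_pwm(pfm)
    w = config.truth_motif_width
    flank = (PROBE_LENGTH - w) // 2

    sequences, affinities, is_bg = [], [], []
    sites = sample_sites(pfm, config.n_bound_probes, rng)
    for site in sites:
        left = _random_dna(rng, flank)
        right = _random_dna(rng, PROBE_LENGTH - flank - w)
        seq = left + site + right
        sequences.append(seq)
        affinities.append(max(0.0, _best_log_odds(pwm, seq)))
        is_bg.append(False)
    for _ in range(config.n_background_probes):
        seq = _random_dna(rng, PROBE_LENGTH)
        sequences.append(seq)
        affinities.append(max(0.0, _best_log_odds(pwm, seq)))
        is_bg.append(True)

    rows = []
    base = config.baseline_log_fluorescence
    for i, (seq, aff, bg) in enumerate(zip(sequences, affinities, is_bg)):
        signal = base + (config.affinity_scale * aff if not bg else 0.0)
        for array in range(config.n_arrays):
            noise = rng.normal(0.0, config.noise_sd, size=config.probe_replicates) \
                if config.noise_sd > 0 else np.zeros(config.probe_replicates)
            for rep in range(config.probe_replicates):
                rows.append((f"p{i:05d}_r{rep}", seq, rep, array,
                             float(np.exp(signal + noise[rep])), bg))
    table = pd.DataFrame(rows, columns=io.PROBE_COLUMNS)
    return table, TruthRecord(truth_pfm=pfm)


# ---------------------------------------------------------------------------
# expression

def simulate_expression(config: SimConfig) -> tuple["pd.DataFrame", TruthRecord]:
    """Three-stage FPKM table (long format) with planted structure.

    Concordant genes get strictly increasing stage means; the driver gene's
    means sit at exact ratios (1, driver_folds[0], driver_folds[1]);
    the rest get a stage ordering that is never strictly increasing.
    zero_inflation of gene x stage cells is zeroed across all replicates;
    zero-inflated concordant genes are removed from the truth concordant set
    (the filter cannot recover them by construction).
    """
    if config.expression_replicates < 2:
        raise ValueError("need at least 2 replicates per stage")
    rng = child_rng(config.seed, "expression")
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]
    n_conc = max(1, round(config.concordant_fraction * n))
    conc_idx = set(rng.choice(n, size=n_conc, replace=False).tolist())
    driver_idx = min(conc_idx)
    driver = genes[driver_idx]

    base = np.exp(rng.normal(np.log(10.0), 1.0, size=n))  # per-gene FPKM scale
    means = np.empty((n, 3))
    noninc_perms = [p for p in
                    ([0, 2, 1], [1, 0, 2], [1, 2, 0], [2, 0, 1], [2, 1, 0])]
    for i in range(n):
        if i == driver_idx:
            means[i] = base[i] * np.array([1.0, *config.driver_folds])
        elif i in conc_idx:
            steps = rng.uniform(1.3, 3.0, size=2)
            means[i] = base[i] * np.array([1.0, steps[0], steps[0] * steps[1]])
        else:
            steps = rng.uniform(1.3, 3.0, size=2)
            tri = base[i] * np.array([1.0, steps[0], steps[0] * steps[1]])
            perm = noninc_perms[rng.integers(len(noninc_perms))]
            means[i] = tri[perm]

    # zero inflation: whole gene x stage cells, driver exempt
    zero_mask = rng.random((n, 3)) < config.zero_inflation
    zero_mask[driver_idx] = False
    means[zero_mask] = 0.0

    truth_conc = {genes[i] for i in conc_idx if not zero_mask[i].any()}

    reps = config.expression_replicates
    noise = (np.exp(rng.normal(0.0, config.noise_sd, size=(n, 3, reps)))
             if config.noise_sd > 0 else np.ones((n, 3, reps)))
    values = means[:, :, None] * noise
    records = []
    for i, gene in enumerate(genes):
        for s, stage in enumerate(config.stage_names):
            for r in range(reps):
                records.append((gene, stage, r, float(values[i, s, r])))
    table = pd.DataFrame(records, columns=io.EXPRESSION_COLUMNS)
    return table, TruthRecord(concordant_gene_ids=truth_conc, driver_gene_id=driver)


# ---------------------------------------------------------------------------
# promoters

def simulate_promoters(
    config: SimConfig,
    pfm: PositionMatrix | None = None,
    gene_ids: Sequence[str] | None = None,
) -> tuple[dict[str, str], list[GeneModel], TruthRecord]:
    """Genome (one contig per gene), gene models and implanted-site truth.

    Each gene receives a uniform-composition promoter of
    ``promoter_length`` bp with 0-4 (``sites_per_gene_range``) non-overlapping
    implants of the motif consensus at random offsets and strands; offsets
    are recorded in window coordinates (0 = far end, window reads 5'->3'
    toward the TSS) so that extract_upstream recovers them directly.
    """
    rng = child_rng(config.seed, "promoters")
    pfm = pfm or truth_motif(config.truth_motif_width)
    w = pfm.width
    consensus = pfm.consensus()
    lo, hi = config.sites_per_gene_range
    L = config.promoter_length
    if hi * w > L:
        raise ValueError("maximum implant count x motif width exceeds promoter_length")
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]

    body_len, pad = 60, 10
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    implanted: dict[str, list[tuple[int, str]]] = {}
    for gene in gene_ids:
        promoter = list(_random_dna(rng, L))
        n_sites = int(rng.integers(lo, hi + 1))
        offsets: list[int] = []
        attempts = 0
        while len(offsets) < n_sites:
            cand = int(rng.integers(0, L - w + 1))
            if all(abs(cand - o) >= w for o in offsets):
                offsets.append(cand)
            attempts += 1
            if attempts > 1000:
                raise RuntimeError("could not place non-overlapping implants")
        sites = []
        for off in sorted(offsets):
            strand = "+" if rng.random() < 0.5 else "-"
            insert = consensus if strand == "+" else io.reverse_complement(consensus)
            promoter[off:off + w] = insert
            sites.append((off, strand))
        implanted[gene] = sites
        pseq = "".join(promoter)
        body = _random_dna(rng, body_len)
        gene_strand = "+" if rng.random() < 0.5 else "-"
        left = _random_dna(rng, pad)
        right = _random_dna(rng, pad)
        contig = f"chr_{gene}"
        if gene_strand == "+":
            # [pad][promoter][TSS + body][pad]; upstream [tss-L, tss) == promoter
            genome[contig] = left + pseq + body + right
            tss = pad + L
        else:
            # upstream (tss, tss+L] reverse-complements back to the promoter;
            # revcomp(pseq + body) lays out revcomp(body) | revcomp(pseq)
            genome[contig] = left + io.reverse_complement(pseq + body) + right
            tss = pad + body_len - 1
        models.append(GeneModel(gene, contig, gene_strand, tss))
    return genome, models, TruthRecord(implanted_sites=implanted)


def write_gene_models(models: Sequence[GeneModel], gff3_path: str | Path,
                      bed_path: str | Path | None = None,
                      body_length: int = 60) -> None:
    """Write gene models as GFF3 (1-based closed) and optionally BED6."""
    gff_lines = ["##gff-version 3"]
    bed_lines = []
    for m in models:
        if m.strand == "+":
            start0, end0 = m.tss, m.tss + body_length
        else:
            start0, end0 = m.tss - body_length + 1, m.tss + 1
        gff_lines.append(f"{m.contig}\tregscan\tgene\t{start0 + 1}\t{end0}\t.\t"
                         f"{m.strand}\t.\tID={m.gene_id}")
        bed_lines.append(f"{m.contig}\t{start0}\t{end0}\t{m.gene_id}\t0\t{m.strand}")
    Path(gff3_path).write_text("".join(line + "\n" for line in gff_lines))
    if bed_path is not None:
        Path(bed_path).write_text("".join(line + "\n" for line in bed_lines))


# ---------------------------------------------------------------------------
# categories

def simulate_categories(config: SimConfig, truth: TruthRecord,
                        gene_ids: Sequence[str] | None = None
                        ) -> tuple[pd.DataFrame, TruthRecord]:
    """Random gene categories plus one enriched among concordant genes.

    The enriched category samples members with selection odds multiplied by
    ``enriched_category_effect`` for truth-concordant genes; effect 1 makes
    it exchangeable with the null categories.
    """
    rng = child_rng(config.seed, "categories")
    if gene_ids is None:
        gene_ids = sorted(truth.concordant_gene_ids) if truth.concordant_gene_ids else \
            [f"g{i:05d}" for i in range(config.n_genes)]
        if len(gene_ids) < config.n_genes:
            gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    genes = np.array(gene_ids)
    n = len(genes)
    lo, hi = config.category_size_range
    hi = min(hi, n)
    lo = min(lo, hi)
    rows = []
    for c in range(config.n_categories):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n, size=size, replace=False)
        rows.extend((genes[i], f"C{c:03d}") for i in members)
    # enriched category: weighted sampling without replacement
    conc = np.isin(genes, sorted(truth.concordant_gene_ids))
    weights = np.where(conc, config.enriched_category_effect, 1.0).astype(float)
    size = int(rng.integers(lo, hi + 1))
    p = weights / weights.sum()
    members = rng.choice(n, size=size, replace=False, p=p)
    enriched_id = f"C{config.n_categories:03d}"
    rows.extend((genes[i], enriched_id) for i in members)
    table = pd.DataFrame(rows, columns=io.CATEGORY_COLUMNS)
    return table, TruthRecord(enriched_category_id=enriched_id)


# ---------------------------------------------------------------------------
# bundle

def simulate_bundle(config: SimConfig, outdir: str | Path) -> TruthRecord:
    """Write every synthetic input the pipeline consumes into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probes, truth = simulate_pbm(config)
    io.write_probe_table(probes, outdir / "probes.tsv")
    expr, t_expr = simulate_expression(config)
    truth = truth.merge(t_expr)
    io.write_expression_table(expr, outdir / "expression.tsv")
    gene_ids = sorted(expr["gene_id"].unique())
    genome, models, t_prom = simulate_promoters(config, truth.truth_pfm, gene_ids)
    truth = truth.merge(t_prom)
    io.write_fasta(genome, outdir / "genome.fa")
    write_gene_models(models, outdir / "genes.gff3", outdir / "genes.bed")
    cats, t_cat = simulate_categories(config, truth, gene_ids)
    truth = truth.merge(t_cat)
    io.write_category_map(cats, outdir / "categories.tsv")
    truth.to_json(outdir / "truth.json")
    config_dict = dataclasses.asdict(config)
    io.write_json(config_dict, outdir / "sim_config.json")
    return truth
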