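"""Synthetic inputs with known ground truth for every pipeline stage.

The study conditions emulated here follow the source experiment's design:
two sheep populations (purebred STH as the low-fat control, the Suffolk
cross SFK x STH as the group of interest), six animals per group for
expression work, cohorts of 25/30 for genotyping, and a biallelic SNP near
allele frequency 0.5. Where the design leaves a knob unstated (read length,
negative-binomial dispersion, blob geometry) a realistic default is fixed
once in SimConfig.

Every generator is a pure function of its SimConfig: the same seed yields
byte-identical outputs, and a truth table accompanies each dataset so that
downstream sensitivity/specificity can be scored exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .read_qc import ReadRecord

if TYPE_CHECKING:
    from .expression import ExpressionMatrix
    from .geneset import GeneSet
    from .popgen import GenotypeCounts

# Fixed 13-mer used as the "sequencing joint" contaminant (the universal
# Illumina adapter prefix).
ADAPTER_13MER = "AGATCGGAAGAGC"

__all__ = [
    "SimConfig",
    "ADAPTER_13MER",
    "simulate_fastq",
    "simulate_counts",
    "simulate_genotypes",
    "simulate_image_pair",
    "simulate_gene_sets",
    "simulate_ct_table",
    "simulate_cds",
]


@dataclass(frozen=True)
class SimConfig:
    """Knobs for all generators; rates are fractions in [0, 1]."""

    seed: int = 0
    # reads
    n_reads: int = 1000
    read_length: int = 100
    adapter_rate: float = 0.05
    n_rate: float = 0.05
    lowq_rate: float = 0.05
    # expression
    n_genes: int = 2000
    n_samples_per_group: int = 6
    n_de: int = 50
    de_log2fc: float = 2.0
    dispersion: float = 0.05
    # genotyping
    allele_freq: float = 0.48
    cohort_n: int = 25
    # imaging
    coloc_rho: float = 0.8
    image_size: int = 256

    def __post_init__(self) -> None:
        for name in ("adapter_rate", "n_rate", "lowq_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.adapter_rate + self.n_rate + self.lowq_rate > 1.0:
            raise ValueError("contamination rates sum to more than 1")
        for name in ("n_reads",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("read_length", "n_genes", "n_samples_per_group", "cohort_n", "image_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.n_de <= self.n_genes:
            raise ValueError("n_de must be between 0 and n_genes")
        if self.dispersion < 0:
            raise ValueError("negative dispersion")
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele_freq must be strictly inside (0, 1)")
        if not -1.0 <= self.coloc_rho <= 1.0:
            raise ValueError("coloc_rho must be in [-1, 1]")


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    # Independent substream per generator so enabling one stage never
    # perturbs another stage's draws. crc32 is stable across processes
    # (str.hash is salted per interpreter).
    return np.random.default_rng([cfg.seed, zlib.crc32(stream.encode())])


def _random_bases(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _clean_read(rng: np.random.Generator, length: int, adapter: str) -> tuple[str, list[int]]:
    while True:
        bases = _random_bases(rng, length)
        if adapter not in bases:
            break
    quals = rng.integers(30, 41, size=length).tolist()
    return bases, quals


def simulate_fastq(cfg: SimConfig, adapter: str = ADAPTER_13MER) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Reads with planted contamination plus a per-read truth table.

    Each read is independently assigned a label with probabilities
    (adapter_rate, n_rate, lowq_rate, remainder clean) and then built to
    violate exactly the labeled rule: adapter reads contain the adapter
    verbatim; high-N reads carry strictly more than 10% N; low-quality
    reads have Phred <= 20 at strictly more than half their bases; clean
    reads violate none of the rules. Zero reads requested yields empty
    outputs.
    """
    rng = _rng(cfg, "fastq")
    L = cfg.read_length
    labels = ("adapter", "highN", "lowQ", "clean")
    probs = (
        cfg.adapter_rate,
        cfg.n_rate,
        cfg.lowq_rate,
        1.0 - cfg.adapter_rate - cfg.n_rate - cfg.lowq_rate,
    )
    reads: list[ReadRecord] = []
    rows = []
    for i in range(cfg.n_reads):
        label = labels[rng.choice(4, p=probs)]
        bases, quals = _clean_read(rng, L, adapter)
        if label == "adapter":
            pos = int(rng.integers(0, L - len(adapter) + 1))
            bases = bases[:pos] + adapter + bases[pos + len(adapter):]
        elif label == "highN":
            # strictly more than 10% N: between floor(L/10)+1 and 2L/10 sites
            k = int(rng.integers(L // 10 + 1, max(L // 5, L // 10 + 2)))
            sites = rng.choice(L, size=k, replace=False)
            arr = list(bases)
            for s in sites:
                arr[s] = "N"
            bases = "".join(arr)
            if adapter in bases:  # N substitution cannot create the adapter, but be safe
                arr[int(sites[0])] = "N"
                bases = "".join(arr)
        elif label == "lowQ":
            k = int(rng.integers(L // 2 + 1, L + 1))
            sites = rng.choice(L, size=k, replace=False)
            for s in sites:
                quals[s] = int(rng.integers(2, 21))
        read_id = f"read_{i:06d}"
        reads.append(ReadRecord(read_id, bases, tuple(int(q) for q in quals)))
        rows.append({"read_id": read_id, "label": label})
    truth = pd.DataFrame(rows, columns=["read_id", "label"])
    return reads, truth


def simulate_counts(cfg: SimConfig) -> tuple["ExpressionMatrix", pd.DataFrame]:
    """Negative-binomial count matrix with planted fold changes.

    Baseline per-gene means are log-normal; the first ``n_de`` genes (after
    a deterministic shuffle) are scaled by 2**de_log2fc in the SFK x STH
    group relative to the STH control. Counts are NB with
    var = mu + dispersion * mu**2; dispersion = 0 degenerates to Poisson.
    Returns the matrix (with gene lengths and group labels) and a truth
    table with one row per gene (is_de, true_log2fc).
    """
    from .expression import ExpressionMatrix  # local import to avoid a cycle

    rng = _rng(cfg, "counts")
    genes = [f"gene_{i:05d}" for i in range(cfg.n_genes)]
    lengths = pd.Series(rng.integers(500, 3001, size=cfg.n_genes), index=genes, name="length")
    base_mu = np.exp(rng.normal(np.log(200.0), 1.0, size=cfg.n_genes))

    de_idx = rng.permutation(cfg.n_genes)[: cfg.n_de]
    fold = np.ones(cfg.n_genes)
    fold[de_idx] = 2.0 ** cfg.de_log2fc

    groups = {}
    cols = {}
    for g, label, mult in (("STH", "STH", np.ones(cfg.n_genes)), ("SFKxSTH", "SFKxSTH", fold)):
        for s in range(cfg.n_samples_per_group):
            name = f"{label}_{s + 1}"
            mu = base_mu * mult
            if cfg.dispersion == 0.0:
                counts = rng.poisson(mu)
            else:
                r = 1.0 / cfg.dispersion
                counts = rng.negative_binomial(r, r / (r + mu))
            cols[name] = counts
            groups[name] = label
    values = pd.DataFrame(cols, index=genes)
    is_de = np.zeros(cfg.n_genes, dtype=bool)
    is_de[de_idx] = True
    truth = pd.DataFrame(
        {"gene": genes, "is_de": is_de, "true_log2fc": np.where(is_de, cfg.de_log2fc, 0.0)}
    )
    matrix = ExpressionMatrix(values=values, groups=pd.Series(groups), lengths=lengths, units="counts")
    return matrix, truth


def simulate_genotypes(cfg: SimConfig, locus: str = "simSNP", population: str = "sim") -> "GenotypeCounts":
    """Draw cohort_n individuals with Hardy-Weinberg genotype probabilities
    (p^2, 2pq, q^2) at allele frequency p = allele_freq."""
    from .popgen import GenotypeCounts  # local import to avoid a cycle

    rng = _rng(cfg, "genotypes")
    p = cfg.allele_freq
    q = 1.0 - p
    n_aa, n_ab, n_bb = rng.multinomial(cfg.cohort_n, [p * p, 2 * p * q, q * q])
    return GenotypeCounts(locus, population, int(n_aa), int(n_ab), int(n_bb))


def simulate_image_pair(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-channel 8-bit image pair with a target foreground correlation.

    The foreground mask is a union of random elliptical "adipocyte" blobs
    on a zero background. Within the mask, pixel pairs are built from a
    bivariate normal with correlation coloc_rho and mapped affinely to
    intensities in [30, 225], so at |rho| = 1 channel 2 is an exact affine
    function of channel 1. Returns (channel1, channel2, mask).
    """
    from skimage.draw import ellipse

    rng = _rng(cfg, "image")
    size = cfg.image_size
    mask = np.zeros((size, size), dtype=bool)
    n_blobs = max(6, size // 40)
    for _ in range(n_blobs):
        r, c = rng.integers(0, size, size=2)
        r_rad = int(rng.integers(size // 16, size // 6))
        c_rad = int(rng.integers(size // 16, size // 6))
        rr, cc = ellipse(r, c, r_rad, c_rad, shape=mask.shape, rotation=rng.uniform(0, np.pi))
        mask[rr, cc] = True

    n_fg = int(mask.sum())
    rho = cfg.coloc_rho
    z1 = rng.standard_normal(n_fg)
    if abs(rho) == 1.0:
        z2 = np.sign(rho) * z1
    else:
        z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n_fg)

    def to_u8(z: np.ndarray) -> np.ndarray:
        return np.clip(128.0 + 35.0 * z, 30, 225).astype(np.uint8)

    ch1 = np.zeros((size, size), dtype=np.uint8)
    ch2 = np.zeros((size, size), dtype=np.uint8)
    ch1[mask] = to_u8(z1)
    ch2[mask] = to_u8(z2)
    return ch1, ch2, mask


def simulate_gene_sets(
    cfg: SimConfig,
    truth: pd.DataFrame,
    n_lipid_terms: int = 8,
    n_background_terms: int = 12,
    term_size: int = 40,
) -> list["GeneSet"]:
    """GMT-style annotation with lipid-named terms enriched in planted DEGs.

    Lipid terms draw roughly half their members from the true DEG list so
    the enrichment stage has signal; background terms sample the whole gene
    universe uniformly.
    """
    from .geneset import GeneSet  # local import to avoid a cycle

    rng = _rng(cfg, "genesets")
    genes = truth["gene"].to_numpy()
    de_genes = truth.loc[truth["is_de"], "gene"].to_numpy()
    lipid_stems = [
        "lipid metabolic process",
        "fatty acid biosynthesis",
        "adipocyte differentiation",
        "lipid storage",
        "long-chain fatty acid transport",
        "adipose tissue development",
        "triglyceride catabolic process",
        "lipid droplet organization",
    ]
    sets: list[GeneSet] = []
    for t in range(n_lipid_terms):
        n_from_de = min(term_size // 2, len(de_genes))
        members = np.concatenate(
            [
                rng.choice(de_genes, size=n_from_de, replace=False) if n_from_de else [],
                rng.choice(genes, size=term_size - n_from_de, replace=False),
            ]
        )
        name = lipid_stems[t % len(lipid_stems)] + (f" variant {t // len(lipid_stems) + 1}" if t >= len(lipid_stems) else "")
        sets.append(GeneSet(f"GO:L{t:04d}", name, "BP", frozenset(members)))
    for t in range(n_background_terms):
        members = rng.choice(genes, size=term_size, replace=False)
        sets.append(GeneSet(f"GO:B{t:04d}", f"housekeeping process {t}", "BP", frozenset(members)))
    return sets


def simulate_ct_table(
    cfg: SimConfig,
    target: str = "PIK3R1",
    reference: str = "GAPDH",
    true_fold: float = 4.0,
    n_replicates: int = 3,
    ct_sd: float = 0.15,
) -> pd.DataFrame:
    """Triplicate qPCR Ct table for two groups with a known fold change.

    The SFK x STH group's target expression is ``true_fold`` times the STH
    calibrator's, i.e. its target Ct is lower by log2(true_fold) cycles;
    the reference gene is flat. Gaussian cycle noise (sd ``ct_sd``) on every
    well emulates pipetting/instrument variation.
    """
    rng = _rng(cfg, "qpcr")
    rows = []
    for group, shift in (("STH", 0.0), ("SFKxSTH", -np.log2(true_fold))):
        for s in range(cfg.n_samples_per_group):
            sample = f"{group}_{s + 1}"
            base_ref = 16.0 + rng.normal(0, 0.3)
            for gene, ct0 in ((reference, base_ref), (target, base_ref + 6.0 + shift)):
                for rep in range(n_replicates):
                    rows.append(
                        {
                            "sample": sample,
                            "group": group,
                            "gene": gene,
                            "replicate": rep + 1,
                            "ct": ct0 + rng.normal(0, ct_sd),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_cds(cfg: SimConfig, n_codons: int = 150) -> str:
    """Random in-frame CDS (start codon, no internal stops, trailing stop)
    containing at least one glutamate codon so the E->U edit is applicable."""
    rng = _rng(cfg, "cds")
    sense = [c for c in _all_codons() if c not in ("TAA", "TAG", "TGA")]
    codons = ["ATG"] + [sense[int(i)] for i in rng.integers(0, len(sense), size=n_codons - 2)]
    if not any(c in ("GAA", "GAG") for c in codons):
        codons[1] = "GAA"
    codons.append("TAA")
    return "".join(codons)


def _all_codons() -> list[str]:
    return [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
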