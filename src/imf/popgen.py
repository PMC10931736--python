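"""Marker-evaluation statistics for a biallelic SNP.

For each population with genotype counts (n_AA, n_AB, n_BB) at one locus,
computes allele frequencies, observed/expected homo- and heterozygosity,
effective allele number Ne = 1/(p^2+q^2), Botstein polymorphism information
content PIC = 1 - (p^2+q^2) - 2 p^2 q^2, and a Hardy-Weinberg-equilibrium
goodness-of-fit chi-square.

Two computation conventions are exposed:

``exact``
    Allele frequency p = (2 n_AA + n_AB) / (2n); all downstream statistics
    from the unrounded p. The statistically standard path; default for new
    data.

``paper_rounded``
    Genotype frequencies are rounded half-up to two decimals first, then
    p = f_AA + f_AB/2 is rounded half-up to two decimals and q = 1 - p;
    Ne is truncated (not rounded) to two decimals. This cascade matches how
    spreadsheet-era livestock diversity tables are built and is required to
    reproduce published reports computed that way.

The HWE chi-square compares observed genotype counts with (n p^2, 2npq,
n q^2). The statistically correct reference distribution for a biallelic
locus with p estimated from the data is chi-square with df=1 (three genotype
classes, minus one constraint, minus one estimated allele frequency); df=2
(categories minus one, ignoring the estimated frequency) is also exposed
because many published tables use it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Literal, Sequence

import pandas as pd
from scipy import stats

Convention = Literal["exact", "paper_rounded"]

__all__ = [
    "GenotypeCounts",
    "DiversityStats",
    "allele_freqs",
    "heterozygosity",
    "effective_alleles",
    "pic_botstein",
    "hwe_chisq",
    "diversity_stats",
    "table_report",
    "load_table1_fixture",
]


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _truncate(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_DOWN))


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one biallelic locus in one population.

    A is the reference allele (e.g. C), B the alternate (e.g. T):
    n_aa homozygous reference, n_ab heterozygous, n_bb homozygous alternate.
    """

    locus: str
    population: str
    n_aa: int
    n_ab: int
    n_bb: int

    def __post_init__(self) -> None:
        if min(self.n_aa, self.n_ab, self.n_bb) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.n == 0:
            raise ValueError(f"population {self.population!r} has zero individuals")

    @property
    def n(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb

    def pooled_with(self, other: "GenotypeCounts", population: str = "All") -> "GenotypeCounts":
        return GenotypeCounts(
            self.locus,
            population,
            self.n_aa + other.n_aa,
            self.n_ab + other.n_ab,
            self.n_bb + other.n_bb,
        )


@dataclass(frozen=True)
class DiversityStats:
    """Full statistics bundle for one locus/population."""

    locus: str
    population: str
    n: int
    p: float
    q: float
    geno_freqs: tuple[float, float, float]
    ho_obs: float
    he_obs: float
    hom_exp: float
    het_exp: float
    ne: float
    pic: float
    x2: float
    pval: float
    df: int
    convention: str


def allele_freqs(g: GenotypeCounts, convention: Convention = "exact") -> tuple[float, float]:
    """Reference/alternate allele frequencies (p, q)."""
    if convention == "exact":
        p = (2 * g.n_aa + g.n_ab) / (2 * g.n)
    elif convention == "paper_rounded":
        f_aa = _round_half_up(g.n_aa / g.n)
        f_ab = _round_half_up(g.n_ab / g.n)
        p = _round_half_up(f_aa + f_ab / 2)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return p, 1.0 - p


def heterozygosity(
    g: GenotypeCounts, convention: Convention = "exact"
) -> tuple[float, float, float, float]:
    """(ho_obs, he_obs, hom_exp, het_exp).

    Observed values are genotype-count proportions; expected values come
    from the convention's allele frequency: hom_exp = p^2 + q^2,
    het_exp = 1 - hom_exp = 2pq.
    """
    p, q = allele_freqs(g, convention)
    ho_obs = (g.n_aa + g.n_bb) / g.n
    he_obs = g.n_ab / g.n
    hom_exp = p * p + q * q
    return ho_obs, he_obs, hom_exp, 1.0 - hom_exp


def effective_alleles(
    p: float, q: float, rounding: Literal["none", "truncate2"] = "none"
) -> float:
    """Effective allele number Ne = 1/(p^2 + q^2); 1 <= Ne <= 2 for biallelic."""
    ne = 1.0 / (p * p + q * q)
    return _truncate(ne) if rounding == "truncate2" else ne


def pic_botstein(p: float, q: float) -> float:
    """Biallelic Botstein PIC = 1 - (p^2+q^2) - 2 p^2 q^2; maximum 0.375 at p=0.5."""
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def hwe_chisq(
    g: GenotypeCounts, convention: Convention = "exact", df: int = 1
) -> tuple[float, float]:
    """Hardy-Weinberg goodness-of-fit chi-square and upper-tail p-value.

    Expected counts are (n p^2, 2npq, n q^2) with the convention's p.
    df=1 is the statistical default (allele frequency estimated from the
    sample); df=2 is the published-table compatibility mode.
    """
    if df not in (1, 2):
        raise ValueError("df must be 1 or 2")
    p, q = allele_freqs(g, convention)
    n = g.n
    observed = (g.n_aa, g.n_ab, g.n_bb)
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    x2 = 0.0
    for obs, exp in zip(observed, expected):
        if exp == 0.0:
            if obs > 0:
                return math.inf, 0.0
            continue
        x2 += (obs - exp) ** 2 / exp
    return x2, float(stats.chi2.sf(x2, df))


def diversity_stats(
    g: GenotypeCounts, convention: Convention = "exact", df: int = 1
) -> DiversityStats:
    """All marker statistics for one population."""
    p, q = allele_freqs(g, convention)
    ho_obs, he_obs, hom_exp, het_exp = heterozygosity(g, convention)
    ne = effective_alleles(p, q, "truncate2" if convention == "paper_rounded" else "none")
    x2, pval = hwe_chisq(g, convention, df)
    return DiversityStats(
        locus=g.locus,
        population=g.population,
        n=g.n,
        p=p,
        q=q,
        geno_freqs=(g.n_aa / g.n, g.n_ab / g.n, g.n_bb / g.n),
        ho_obs=ho_obs,
        he_obs=he_obs,
        hom_exp=hom_exp,
        het_exp=het_exp,
        ne=ne,
        pic=pic_botstein(p, q),
        x2=x2,
        pval=pval,
        df=df,
        convention=convention,
    )


def table_report(
    populations: Sequence[GenotypeCounts],
    convention: Convention = "paper_rounded",
    df: int = 2,
    pooled_label: str = "All",
) -> pd.DataFrame:
    """Per-population report plus a pooled row from summed genotype counts.

    Values are printed at the precision livestock diversity tables use:
    frequencies and chi-square to 2 dp (half-up), Ne per the convention.
    With a single population no pooled row is added.
    """
    pops = list(populations)
    if not pops:
        raise ValueError("at least one population required")
    rows = list(pops)
    if len(pops) > 1:
        pooled = pops[0]
        for g in pops[1:]:
            pooled = pooled.pooled_with(g, pooled_label)
        rows.append(pooled)

    records = []
    for g in rows:
        s = diversity_stats(g, convention, df)
        records.append(
            {
                "locus": s.locus,
                "population": s.population,
                "n": s.n,
                "n_AA": g.n_aa,
                "n_AB": g.n_ab,
                "n_BB": g.n_bb,
                "f_AA": _round_half_up(s.geno_freqs[0]),
                "f_AB": _round_half_up(s.geno_freqs[1]),
                "f_BB": _round_half_up(s.geno_freqs[2]),
                "p": _round_half_up(s.p),
                "q": _round_half_up(s.q),
                "ho_obs": _round_half_up(s.ho_obs),
                "he_obs": _round_half_up(s.he_obs),
                "hom_exp": _round_half_up(s.hom_exp),
                "het_exp": _round_half_up(s.het_exp),
                "Ne": s.ne if convention == "paper_rounded" else _round_half_up(s.ne),
                "PIC": _round_half_up(s.pic),
                "X2": _round_half_up(s.x2),
                "P": _round_half_up(s.pval),
            }
        )
    return pd.DataFrame.from_records(records)


def load_table1_fixture() -> list[GenotypeCounts]:
    """Packaged genotype counts for the PIK3R1 C1146T locus: purebred
    Small-tail Han (STH, n=25) and the Suffolk x STH F1 cross (n=30)."""
    with resources.files("imf.data").joinpath("table1_genotypes.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        GenotypeCounts(r.locus, r.population, int(r.n_AA), int(r.n_AB), int(r.n_BB))
        for r in df.itertuples()
    ]


def genotype_counts_from_csv(path) -> list[GenotypeCounts]:
    """Read a genotype-count CSV with columns locus, population, n_AA, n_AB, n_BB."""
    df = pd.read_csv(path)
    return [
        GenotypeCounts(r.locus, r.population, int(r.n_AA), int(r.n_AB), int(r.n_BB))
        for r in df.itertuples()
    ]
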