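"""Carrier-model recoding of serotonin-related genotypes and genotype-level QC.

Five variants are analysed under a carrier model (>=1 copy of the index allele
vs. homozygote reference):

* ``rs6265`` (*BDNF* val66met, G/A): met (A) carriers vs. val/val.
* ``httlpr`` (*SLC6A4* 5-HTTLPR, L/S) combined with the adjacent triallelic
  A/G SNP (rs25531; also printed as rs23351 in some sources — treated as one
  locus here): the G allele rides only on L alleles, and an L_G allele is
  functionally S-like, so S' carriers (>=1 S or L_G) are contrasted with
  L_A/L_A homozygotes.
* ``rs6295`` (*HTR1A*, C/G): G carriers vs. CC.
* ``rs7333412`` (*HTR2A*, A/G): G carriers vs. AA.
* ``rs1137070`` (*MAOA*, C/T, X-linked): T carriers vs. CC; hemizygous males
  carry a single allele and are carriers iff that allele is T.

QC helpers: a Pearson 1-df chi-square Hardy-Weinberg test (females only for
the X-linked variant) and a 2x2 chi-square comparing male vs. female allele
frequencies at the X-linked locus.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RawGenotype",
    "recode_5httlpr",
    "dichotomize_carrier",
    "hwe_test",
    "xlinked_allele_freq_test",
    "recode_genotype_table",
    "CARRIER_ALLELE",
    "ALLELE_ALPHABET",
    "TRIALLELIC_ALIASES",
]

#: the triallelic SNP adjacent to 5-HTTLPR appears under two rs numbers in the
#: source literature; both aliases resolve to the same A/G locus.
TRIALLELIC_ALIASES = ("rs25531", "rs23351")

ALLELE_ALPHABET = {
    "rs6265": frozenset("GA"),
    "httlpr": frozenset("LS"),
    "httlpr_snp": frozenset("AG"),
    "rs6295": frozenset("CG"),
    "rs7333412": frozenset("AG"),
    "rs1137070": frozenset("CT"),
}

#: index ("carrier") allele per dichotomized variant
CARRIER_ALLELE = {
    "rs6265": "A",  # met
    "rs6295": "G",
    "rs7333412": "G",
    "rs1137070": "T",
}

# convenience aliases accepted on input for rs6265
_RS6265_ALIASES = {"VAL": "G", "MET": "A"}

HweResult = namedtuple("HweResult", ["statistic", "pvalue"])
Chi2Result = namedtuple("Chi2Result", ["statistic", "pvalue"])


@dataclass(frozen=True)
class RawGenotype:
    """A raw genotype call; ``allele2`` is None for hemizygous males."""

    variant_id: str
    allele1: str
    allele2: str | None = None

    @property
    def alleles(self) -> tuple[str, ...]:
        if self.allele2 is None:
            return (self.allele1,)
        return (self.allele1, self.allele2)


def _split(genotype, variant_id: str) -> tuple[str, ...]:
    """Normalize a genotype given as RawGenotype, 'X/Y' string, 'X', or tuple."""
    if isinstance(genotype, RawGenotype):
        alleles = genotype.alleles
    elif isinstance(genotype, str):
        alleles = tuple(a.strip() for a in genotype.split("/") if a.strip())
    else:
        alleles = tuple(genotype)
    if not 1 <= len(alleles) <= 2:
        raise ValueError(f"{variant_id}: expected 1 or 2 alleles, got {alleles!r}")
    out = []
    for a in alleles:
        a = str(a).upper()
        if variant_id == "rs6265":
            a = _RS6265_ALIASES.get(a, a)
        if a not in ALLELE_ALPHABET[variant_id]:
            raise ValueError(
                f"illegal allele {a!r} for {variant_id}; legal: "
                f"{sorted(ALLELE_ALPHABET[variant_id])}"
            )
        out.append(a)
    return tuple(out)


def recode_5httlpr(lpr, triallelic) -> int:
    """S'-carrier indicator from the 5-HTTLPR / triallelic-SNP diplotype.

    Returns 1 iff the diplotype carries at least one S allele or one L_G
    allele (G allele of the triallelic SNP on an L background); 0 iff the
    diplotype is L_A/L_A. The G allele attaches only to L alleles, so a G on
    an S/S background is an inconsistent haplotype and is rejected.

    Parameters
    ----------
    lpr : str | tuple | RawGenotype
        Biallelic L/S call, e.g. ``"L/S"``.
    triallelic : str | tuple | RawGenotype
        A/G call of the adjacent SNP (rs25531/rs23351), e.g. ``"A/G"``.
    """
    lpr_alleles = _split(lpr, "httlpr")
    snp_alleles = _split(triallelic, "httlpr_snp")
    if len(lpr_alleles) != 2 or len(snp_alleles) != 2:
        raise ValueError("5-HTTLPR recoding requires two alleles at each locus")
    n_l = sum(a == "L" for a in lpr_alleles)
    n_g = sum(a == "G" for a in snp_alleles)
    if n_g > n_l:
        raise ValueError(
            f"inconsistent haplotype: {n_g} G allele(s) of the triallelic SNP "
            f"but only {n_l} L allele(s) to carry them "
            f"(lpr={'/'.join(lpr_alleles)}, snp={'/'.join(snp_alleles)})"
        )
    has_s = "S" in lpr_alleles
    has_lg = n_g >= 1
    return int(has_s or has_lg)


def dichotomize_carrier(variant_id: str, genotype) -> int:
    """Binary carrier indicator for the simple biallelic variants.

    ``rs1137070`` is X-linked: hemizygous males may pass a single allele, in
    which case the indicator is the identity of that allele.
    """
    if variant_id not in CARRIER_ALLELE:
        raise ValueError(
            f"unknown variant {variant_id!r}; expected one of {sorted(CARRIER_ALLELE)}"
        )
    alleles = _split(genotype, variant_id)
    if len(alleles) == 1 and variant_id != "rs1137070":
        raise ValueError(f"{variant_id} is autosomal; two alleles required")
    return int(CARRIER_ALLELE[variant_id] in alleles)


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> HweResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg genotype proportions.

    Observed genotype counts are compared with expectations at the sample
    allele frequency (no continuity correction, no exact test). For the
    X-linked ``rs1137070`` pass female genotypes only. A monomorphic sample
    yields a defined p = 1 with a warning.
    """
    counts = np.asarray([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if np.any(counts < 0) or not np.all(counts == np.round(counts)):
        raise ValueError("genotype counts must be non-negative integers")
    n = counts.sum()
    if n <= 0:
        raise ValueError("no genotypes supplied")
    q = (counts[1] + 2 * counts[2]) / (2 * n)  # alt allele frequency
    if q == 0.0 or q == 1.0:
        warnings.warn("monomorphic sample: Hardy-Weinberg test is degenerate, p = 1")
        return HweResult(0.0, 1.0)
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    statistic = float(np.sum((counts - expected) ** 2 / expected))
    return HweResult(statistic, float(stats.chi2.sf(statistic, df=1)))


def xlinked_allele_freq_test(male_allele_counts, female_allele_counts) -> Chi2Result:
    """2x2 chi-square homogeneity test of allele frequencies between sexes.

    Males contribute one allele each (hemizygous), females two. Inputs are
    ``(n_ref, n_alt)`` allele counts per sex.
    """
    male = np.asarray(male_allele_counts, dtype=float)
    female = np.asarray(female_allele_counts, dtype=float)
    if male.shape != (2,) or female.shape != (2,):
        raise ValueError("allele counts must be (n_ref, n_alt) pairs")
    if male.sum() == 0 or female.sum() == 0:
        raise ValueError("zero alleles observed in one sex")
    table = np.vstack([male, female])
    if np.any(table.sum(axis=0) == 0):
        # one allele absent in both sexes: frequencies are trivially equal
        return Chi2Result(0.0, 1.0)
    res = stats.chi2_contingency(table, correction=False)
    return Chi2Result(float(res.statistic), float(res.pvalue))


def recode_genotype_table(df: pd.DataFrame) -> pd.DataFrame:
    """Recode a raw genotype block into the five carrier-coded columns.

    Expects columns ``rs6265, httlpr, httlpr_snp, rs6295, rs7333412,
    rs1137070`` holding genotype strings (``"L/S"``; hemizygous males at
    rs1137070 may hold a single allele). Missing genotypes are rejected.
    Returns a DataFrame with columns ``httlpr, rs6295, rs7333412, rs1137070,
    rs6265`` of 0/1 carrier indicators, indexed like the input.
    """
    required = ["rs6265", "httlpr", "httlpr_snp", "rs6295", "rs7333412", "rs1137070"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"raw genotype block missing columns: {missing}")
    if df[required].isna().any().any():
        bad = df.index[df[required].isna().any(axis=1)].tolist()
        raise ValueError(f"missing genotype calls for rows {bad}; imputation is not supported")
    out = pd.DataFrame(index=df.index)
    out["httlpr"] = [
        recode_5httlpr(lpr, snp) for lpr, snp in zip(df["httlpr"], df["httlpr_snp"])
    ]
    for variant in ("rs6295", "rs7333412", "rs1137070", "rs6265"):
        out[variant] = [dichotomize_carrier(variant, g) for g in df[variant]]
    return out
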