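"""Genotype coding and Hardy-Weinberg testing for the three candidate loci.

Three variants are coded into analysis categories:

* **MAOA-uVNTR** (X-linked promoter repeat; alleles 3.5/4.5/5.5/6.5
  repeats).  Men are hemizygous: one allele, 4.5 -> MAOA-H (high
  expression), 3.5 -> MAOA-L.  Women carry two alleles; because X
  inactivation makes heterozygotes' expressed allele unknowable, only
  homozygotes are coded (4.5/4.5 -> H, 3.5/3.5 -> L) and 3.5/4.5
  heterozygotes are excluded.  The rare 5.5 and 6.5 alleles exclude their
  carriers in either sex.
* **OXTR rs53576** (SNP): unordered A/G genotypes GG, GA, AA.
* **AVPR1a RS3** (microsatellite): allele lengths 324-356 bp binned into
  Short (324-341 bp) and Long (342-356 bp), giving Short/Short,
  Short/Long, Long/Long.

Hardy-Weinberg equilibrium is checked with the 1-df Pearson chi-square
(no continuity correction) on the three diploid genotype classes of a
biallelic system.  MAOA, being X-linked, is only testable in women and on
the pre-exclusion genotype table (a table purged of heterozygotes cannot
be in HWE by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MAOA_ALLELES = (3.5, 4.5, 5.5, 6.5)
RS3_MIN_BP, RS3_SHORT_MAX_BP, RS3_MAX_BP = 324, 341, 356

EXCLUDED = "excluded"
VARIANTS = ("maoa", "oxtr", "avpr1a")

MAOA_LEVELS = ("L", "H")
OXTR_LEVELS = ("AA", "GA", "GG")
RS3_LEVELS = ("Long/Long", "Short/Long", "Short/Short")

GENOTYPE_LEVELS = {"maoa": MAOA_LEVELS, "oxtr": OXTR_LEVELS, "avpr1a": RS3_LEVELS}

__all__ = [
    "EXCLUDED",
    "VARIANTS",
    "GENOTYPE_LEVELS",
    "RawGenotype",
    "CodedGenotypes",
    "HWEResult",
    "code_maoa",
    "code_oxtr",
    "bin_rs3",
    "code_rs3",
    "code_genotypes",
    "genotype_count_table",
    "hwe_test",
    "maoa_female_hwe_counts",
]


@dataclass(frozen=True)
class RawGenotype:
    """One subject's raw genotype calls.

    ``maoa_repeats`` holds one allele for men (X hemizygosity) and two for
    women.  ``rs3_lengths_bp`` are fragment lengths in base pairs.
    """

    sex: str  # "female" | "male"
    maoa_repeats: tuple[float, ...]
    oxtr_alleles: tuple[str, str]
    rs3_lengths_bp: tuple[int, int]

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        expected = 2 if self.sex == "female" else 1
        if len(self.maoa_repeats) != expected:
            raise ValueError(
                f"{self.sex} subjects carry exactly {expected} MAOA allele(s), "
                f"got {len(self.maoa_repeats)}"
            )


@dataclass(frozen=True)
class CodedGenotypes:
    """Analysis-ready labels after exclusion/binning rules."""

    maoa: str  # "H" | "L" | "excluded"
    oxtr: str  # "GG" | "GA" | "AA"
    avpr1a: str  # "Short/Short" | "Short/Long" | "Long/Long" | "excluded"


def code_maoa(raw: RawGenotype) -> str:
    """MAOA-H / MAOA-L / excluded under the hemizygosity and rarity rules."""
    for a in raw.maoa_repeats:
        if a not in MAOA_ALLELES:
            raise ValueError(f"unknown MAOA repeat allele {a!r}")
    if any(a in (5.5, 6.5) for a in raw.maoa_repeats):
        return EXCLUDED
    if raw.sex == "male":
        return "H" if raw.maoa_repeats[0] == 4.5 else "L"
    a1, a2 = raw.maoa_repeats
    if a1 != a2:  # heterozygous women: expressed allele unknowable
        return EXCLUDED
    return "H" if a1 == 4.5 else "L"


def code_oxtr(alleles: Sequence[str]) -> str:
    """Unordered A/G pair -> GG / GA / AA (AG and GA coincide)."""
    pair = tuple(sorted(str(a).upper() for a in alleles))
    if len(pair) != 2 or any(a not in ("A", "G") for a in pair):
        raise ValueError(f"OXTR alleles must be two of A/G, got {alleles!r}")
    return {("A", "A"): "AA", ("A", "G"): "GA", ("G", "G"): "GG"}[pair]


def bin_rs3(length_bp: int) -> str:
    """Short (324-341 bp, inclusive) vs Long (342-356 bp, inclusive)."""
    length_bp = int(length_bp)
    if not RS3_MIN_BP <= length_bp <= RS3_MAX_BP:
        raise ValueError(
            f"RS3 allele length {length_bp} bp outside the observed support "
            f"[{RS3_MIN_BP}, {RS3_MAX_BP}]"
        )
    return "Short" if length_bp <= RS3_SHORT_MAX_BP else "Long"


def code_rs3(lengths_bp: Sequence[int]) -> str:
    """Pair of RS3 lengths -> Short/Short, Short/Long, Long/Long, or
    ``excluded`` when either allele lies outside the observed length range."""
    if len(lengths_bp) != 2:
        raise ValueError("RS3 genotype needs exactly two allele lengths")
    try:
        bins = frozenset(bin_rs3(l) for l in lengths_bp)
    except ValueError:
        return EXCLUDED
    if bins == {"Short"}:
        return "Short/Short"
    if bins == {"Long"}:
        return "Long/Long"
    return "Short/Long"


def code_genotypes(raw: RawGenotype) -> CodedGenotypes:
    return CodedGenotypes(
        maoa=code_maoa(raw),
        oxtr=code_oxtr(raw.oxtr_alleles),
        avpr1a=code_rs3(raw.rs3_lengths_bp),
    )


def genotype_count_table(
    coded: pd.DataFrame,
    variant: str,
    stratify_by_sex: bool = False,
) -> pd.Series | pd.DataFrame:
    """Counts per genotype class, excluded subjects dropped.

    ``coded`` needs a ``sex`` column plus one column per variant.  Returns
    a Series indexed by genotype level, or a level x sex DataFrame when
    stratified (pooled counts are then the row sums).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    levels = list(GENOTYPE_LEVELS[variant])
    kept = coded[coded[variant] != EXCLUDED]
    if kept.empty:
        raise ValueError(f"no subjects remain for {variant} after exclusions")
    if stratify_by_sex:
        table = (
            kept.groupby(["sex", variant], observed=True)
            .size()
            .unstack("sex", fill_value=0)
            .reindex(levels, fill_value=0)
        )
        return table
    return kept[variant].value_counts().reindex(levels, fill_value=0)


@dataclass(frozen=True)
class HWEResult:
    """Pearson chi-square HWE test on one biallelic locus."""

    chi2: float
    df: int
    p: float
    observed: tuple[float, float, float]
    expected: tuple[float, float, float]
    allele_freq: float  # frequency of the first homozygote's allele
    degenerate: bool = False


def hwe_test(genotype_counts: Sequence[float]) -> HWEResult:
    """1-df Pearson chi-square HWE test, counts ordered (hom1, het, hom2).

    The allele frequency is estimated from the genotype counts; expected
    counts are n*(p^2, 2pq, q^2).  No continuity correction.  A
    monomorphic sample is degenerate: chi2 = 0 by convention.
    """
    obs = np.asarray(genotype_counts, dtype=float)
    if obs.shape != (3,):
        raise ValueError("need exactly three genotype counts (hom1, het, hom2)")
    if (obs < 0).any():
        raise ValueError("genotype counts must be nonnegative")
    n = obs.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p_hat = (2 * obs[0] + obs[1]) / (2 * n)
    q_hat = 1.0 - p_hat
    expected = n * np.array([p_hat**2, 2 * p_hat * q_hat, q_hat**2])
    if p_hat in (0.0, 1.0):
        return HWEResult(
            chi2=0.0, df=1, p=1.0,
            observed=tuple(obs), expected=tuple(expected),
            allele_freq=float(p_hat), degenerate=True,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs - expected) ** 2 / expected
    chi2 = float(np.nansum(terms))
    return HWEResult(
        chi2=chi2,
        df=1,
        p=float(stats.chi2.sf(chi2, 1)),
        observed=tuple(obs),
        expected=tuple(expected),
        allele_freq=float(p_hat),
    )


def maoa_female_hwe_counts(raws: Iterable[RawGenotype]) -> tuple[int, int, int]:
    """(L/L, L/H, H/H) counts among women, *before* heterozygote exclusion.

    HWE for the X-linked MAOA locus is only testable in women; male
    (hemizygous) records raise.  Carriers of the rare 5.5/6.5 alleles are
    dropped, heterozygous 3.5/4.5 women are kept — a genotype table purged
    of heterozygotes cannot meaningfully be tested for HWE.
    """
    ll = lh = hh = 0
    for raw in raws:
        if raw.sex != "female":
            raise ValueError(
                "MAOA HWE is only defined for women (men are hemizygous)"
            )
        if any(a in (5.5, 6.5) for a in raw.maoa_repeats):
            continue
        n_low = sum(1 for a in raw.maoa_repeats if a == 3.5)
        if n_low == 2:
            ll += 1
        elif n_low == 1:
            lh += 1
        else:
            hh += 1
    return ll, lh, hh
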