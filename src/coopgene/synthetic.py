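"""Synthetic cohorts with the statistical structure the analysis assumes.

Subjects are drawn with (a) genotypes sampled allele-wise under
Hardy-Weinberg equilibrium -- two independent alleles per autosomal locus,
one MAOA allele for men (X hemizygosity), two for women -- and (b) a
contingent schedule drawn from one of five behavioral archetypes:

* ``CC``     noisy line through the origin with slope beta in (0, 1]; a
             slope below one is the "selfish bias" real conditional
             cooperators show (mean schedules fall below the diagonal).
* ``HS``     noisy tent: contributions rise to a peak and then fall.
* ``FR``     contributions never exceed a small ceiling.
* ``UNCOND`` constant high contribution (unconditional cooperation).
* ``MISC``   seeded arbitrary entries: genuinely unclassifiable plans.

Default mixture weights follow the pooled strategy distribution of a
188-subject study cohort (~49% CC, ~12% HS, ~10% FR, ~29% other, of which
three subjects were unconditional cooperators); default allele frequencies
match that cohort's genotype tables.  An optional *planted effect* tilts
the archetype weights multiplicatively for chosen genotype levels, giving
a ground truth for power and recovery simulations.

Uninformed contributions are generated by evaluating each subject's own
schedule at a seeded "belief" about others' average contribution, so
uninformed behavior mixes strategy with expectations, as it does in real
strategy-method data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genetics import RawGenotype, code_genotypes
from .pgg import ContingentSchedule, SCHEDULE_LEN

ARCHETYPES = ("CC", "HS", "FR", "UNCOND", "MISC")

DEFAULT_WEIGHTS = {
    "CC": 92 / 188,
    "HS": 22 / 188,
    "FR": 18 / 188,
    "UNCOND": 3 / 188,
    "MISC": 53 / 188,
}

DEFAULT_MAOA_FREQS = {3.5: 0.56, 4.5: 0.42, 5.5: 0.015, 6.5: 0.005}

# RS3 allele lengths (bp) with a Short (<=341) allele frequency of 0.56,
# close to the 0.557 of the study cohort's pooled genotype counts.
DEFAULT_RS3_FREQS = {
    327: 0.10, 329: 0.14, 331: 0.12, 333: 0.10, 335: 0.07, 337: 0.03,
    343: 0.12, 345: 0.14, 347: 0.09, 349: 0.05, 351: 0.03, 353: 0.01,
}

CSV_COLUMNS = (
    ["id", "sex", "uninformed"]
    + [f"c{i}" for i in range(SCHEDULE_LEN)]
    + ["maoa_a1", "maoa_a2", "oxtr_a1", "oxtr_a2", "rs3_a1_bp", "rs3_a2_bp"]
)

__all__ = [
    "ARCHETYPES",
    "DEFAULT_WEIGHTS",
    "CSV_COLUMNS",
    "ArchetypeSpec",
    "CohortSpec",
    "draw_genotypes",
    "draw_schedule",
    "generate_cohort",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """One schedule-generating archetype with its shape parameters.

    Only the parameters relevant to ``kind`` are read.  ``noise`` is the
    half-width of the entrywise integer jitter (entries are clipped back to
    the valid range afterwards; FR entries to [0, ceiling]).
    """

    kind: str
    slope: float = 1.0       # CC
    intercept: float = 0.0   # CC
    peak: int = 10           # HS
    height: int = 20         # HS
    ceiling: int = 4         # FR
    constant: int = 20       # UNCOND
    noise: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ARCHETYPES:
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if self.noise < 0:
            raise ValueError("noise must be nonnegative")


def _random_archetype(kind: str, rng: np.random.Generator, noise: int) -> ArchetypeSpec:
    """Subject-level parameter draw for one archetype kind."""
    if kind == "CC":
        return ArchetypeSpec("CC", slope=float(rng.uniform(0.6, 1.0)), noise=noise)
    if kind == "HS":
        return ArchetypeSpec(
            "HS",
            peak=int(rng.integers(8, 14)),
            height=int(rng.integers(12, 21)),
            noise=noise,
        )
    if kind == "FR":
        return ArchetypeSpec("FR", ceiling=int(rng.integers(0, 5)), noise=noise)
    if kind == "UNCOND":
        return ArchetypeSpec("UNCOND", constant=20, noise=noise)
    return ArchetypeSpec("MISC", noise=noise)


def draw_schedule(archetype: ArchetypeSpec, rng: np.random.Generator) -> ContingentSchedule:
    """Draw one 21-entry schedule from an archetype."""
    x = np.arange(SCHEDULE_LEN)
    if archetype.kind == "CC":
        base = np.round(archetype.slope * x + archetype.intercept)
    elif archetype.kind == "HS":
        p, h = archetype.peak, archetype.height
        rise = h * x / p if p > 0 else np.full_like(x, h, dtype=float)
        fall = h * (20 - x) / (20 - p) if p < 20 else np.full_like(x, h, dtype=float)
        base = np.round(np.where(x <= p, rise, fall))
    elif archetype.kind == "FR":
        base = rng.integers(0, archetype.ceiling + 1, SCHEDULE_LEN)
    elif archetype.kind == "UNCOND":
        base = np.full(SCHEDULE_LEN, archetype.constant)
    else:  # MISC
        base = rng.integers(0, 21, SCHEDULE_LEN)
    if archetype.noise > 0:
        base = base + rng.integers(-archetype.noise, archetype.noise + 1, SCHEDULE_LEN)
    top = archetype.ceiling if archetype.kind == "FR" else 20
    entries = np.clip(base, 0, top).astype(int)
    return ContingentSchedule(tuple(entries))


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to draw a cohort.

    ``effect`` optionally plants genotype -> strategy structure: a mapping
    variant -> genotype level -> archetype kind -> multiplicative tilt on
    that subject's archetype weights (renormalized).  With no effect,
    genotype and strategy are independent by construction.
    """

    n: int = 188
    female_fraction: float = 107 / 188
    archetype_weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    maoa_allele_freqs: dict = field(default_factory=lambda: dict(DEFAULT_MAOA_FREQS))
    oxtr_a_freq: float = 121 / 364
    rs3_length_freqs: dict = field(default_factory=lambda: dict(DEFAULT_RS3_FREQS))
    effect: Optional[dict] = None
    noise: int = 1
    belief_p: float = 0.45  # uninformed belief ~ Binomial(20, belief_p)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0, 1]")
        for name, freqs in (
            ("archetype_weights", self.archetype_weights),
            ("maoa_allele_freqs", self.maoa_allele_freqs),
            ("rs3_length_freqs", self.rs3_length_freqs),
        ):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
        if not 0 <= self.oxtr_a_freq <= 1:
            raise ValueError("oxtr_a_freq must lie in [0, 1]")


def _draw_alleles(freqs: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    keys = np.array(list(freqs.keys()))
    probs = np.array([freqs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), size=size, p=probs)]


def draw_genotypes(spec: CohortSpec, rng: Optional[np.random.Generator] = None) -> list[RawGenotype]:
    """Seeded genotype draws for a cohort, in HWE by construction."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_female = int(round(spec.n * spec.female_fraction))
    sexes = np.array(["female"] * n_female + ["male"] * (spec.n - n_female))
    rng.shuffle(sexes)
    out = []
    for sex in sexes:
        n_maoa = 2 if sex == "female" else 1
        maoa = tuple(float(a) for a in _draw_alleles(spec.maoa_allele_freqs, n_maoa, rng))
        oxtr = tuple(
            "A" if rng.random() < spec.oxtr_a_freq else "G" for _ in range(2)
        )
        rs3 = tuple(int(l) for l in _draw_alleles(spec.rs3_length_freqs, 2, rng))
        out.append(
            RawGenotype(sex=str(sex), maoa_repeats=maoa, oxtr_alleles=oxtr,
                        rs3_lengths_bp=rs3)
        )
    return out


def _tilted_weights(spec: CohortSpec, raw: RawGenotype) -> np.ndarray:
    weights = np.array([spec.archetype_weights.get(k, 0.0) for k in ARCHETYPES])
    if spec.effect:
        coded = code_genotypes(raw)
        level_of = {"maoa": coded.maoa, "oxtr": coded.oxtr, "avpr1a": coded.avpr1a}
        for variant, per_level in spec.effect.items():
            tilt = per_level.get(level_of[variant])
            if tilt:
                for i, kind in enumerate(ARCHETYPES):
                    weights[i] *= tilt.get(kind, 1.0)
    return weights / weights.sum()


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a full subject table in the CSV column layout the pipeline reads.

    Men have an empty ``maoa_a2`` field.  Same spec (including seed) gives
    an identical table.
    """
    rng = np.random.default_rng(spec.seed)
    raws = draw_genotypes(spec, rng)
    rows = []
    for i, raw in enumerate(raws):
        weights = _tilted_weights(spec, raw)
        kind = ARCHETYPES[rng.choice(len(ARCHETYPES), p=weights)]
        arch = _random_archetype(kind, rng, spec.noise)
        schedule = draw_schedule(arch, rng)
        belief = int(rng.binomial(20, spec.belief_p))
        uninformed = schedule[belief]
        row = {
            "id": f"S{i + 1:04d}",
            "sex": raw.sex,
            "uninformed": uninformed,
        }
        row.update({f"c{j}": schedule[j] for j in range(SCHEDULE_LEN)})
        row["maoa_a1"] = raw.maoa_repeats[0]
        row["maoa_a2"] = raw.maoa_repeats[1] if len(raw.maoa_repeats) == 2 else np.nan
        row["oxtr_a1"], row["oxtr_a2"] = raw.oxtr_alleles
        row["rs3_a1_bp"], row["rs3_a2_bp"] = raw.rs3_lengths_bp
        rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS)
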