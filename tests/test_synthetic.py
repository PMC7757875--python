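"""Synthetic cohort generator: determinism, HWE structure, recovery."""

import numpy as np
import pandas as pd
import pytest

from coopgene.classifier import classify
from coopgene.genetics import code_genotypes
from coopgene.synthetic import (
    ArchetypeSpec,
    CohortSpec,
    draw_genotypes,
    draw_schedule,
    generate_cohort,
)


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        a = generate_cohort(CohortSpec(n=50, seed=9))
        b = generate_cohort(CohortSpec(n=50, seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortSpec(n=50, seed=9))
        b = generate_cohort(CohortSpec(n=50, seed=10))
        assert not a.equals(b)


class TestGenotypeDraws:
    def test_fixed_maoa_allele_codes_all_low(self):
        spec = CohortSpec(n=40, maoa_allele_freqs={3.5: 1.0}, seed=1)
        raws = draw_genotypes(spec)
        assert all(code_genotypes(r).maoa == "L" for r in raws)

    def test_hemizygosity(self):
        raws = draw_genotypes(CohortSpec(n=60, seed=2))
        for r in raws:
            assert len(r.maoa_repeats) == (2 if r.sex == "female" else 1)

    def test_oxtr_converges_to_hwe_proportions(self):
        """At A-allele frequency 0.33 the genotype proportions approach
        (0.1089, 0.4422, 0.4489) by the law of large numbers."""
        spec = CohortSpec(n=50_000, oxtr_a_freq=0.33, seed=3)
        raws = draw_genotypes(spec)
        codes = [code_genotypes(r).oxtr for r in raws]
        n = len(codes)
        props = {g: codes.count(g) / n for g in ("AA", "GA", "GG")}
        assert props["AA"] == pytest.approx(0.33**2, abs=0.01)
        assert props["GA"] == pytest.approx(2 * 0.33 * 0.67, abs=0.01)
        assert props["GG"] == pytest.approx(0.67**2, abs=0.01)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortSpec(maoa_allele_freqs={3.5: 0.5, 4.5: 0.4})


class TestSchedules:
    @pytest.mark.parametrize(
        "arch, expected",
        [
            (ArchetypeSpec("CC", slope=1.0, noise=0), "CC"),
            (ArchetypeSpec("CC", slope=0.5, noise=0), "CC"),
            (ArchetypeSpec("FR", ceiling=0, noise=0), "FR"),
            (ArchetypeSpec("FR", ceiling=4, noise=2), "FR"),
            (ArchetypeSpec("HS", peak=10, height=20, noise=0), "HS"),
            (ArchetypeSpec("HS", peak=6, height=10, noise=0), "HS"),
            (ArchetypeSpec("HS", peak=13, height=14, noise=0), "HS"),
            (ArchetypeSpec("UNCOND", constant=20, noise=0), "OT"),
        ],
    )
    def test_zero_noise_archetypes_recover_their_label(self, arch, expected, rng):
        sched = draw_schedule(arch, rng)
        assert classify(sched).label == expected

    def test_identity_from_perfect_cc(self, rng):
        sched = draw_schedule(ArchetypeSpec("CC", slope=1.0, noise=0), rng)
        assert sched.entries == tuple(range(21))

    def test_fr_ceiling_respected_under_noise(self, rng):
        for _ in range(20):
            sched = draw_schedule(ArchetypeSpec("FR", ceiling=3, noise=2), rng)
            assert max(sched.entries) <= 3

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ArchetypeSpec("XX")


class TestCohortGeneration:
    def test_round_trip_through_csv(self, tmp_path):
        from coopgene.io import read_subjects, write_subjects

        table = generate_cohort(CohortSpec(n=40, seed=4))
        path = tmp_path / "subjects.csv"
        write_subjects(table, path)
        records, diagnostics = read_subjects(path)
        assert diagnostics == []
        assert len(records) == 40
        reread = pd.read_csv(path, dtype={"id": str})
        for j, rec in enumerate(records):
            row = table.iloc[j]
            assert rec.id == row["id"] and rec.sex == row["sex"]
            assert rec.uninformed == row["uninformed"]
            assert rec.schedule.entries == tuple(
                int(row[f"c{k}"]) for k in range(21)
            )
        pd.testing.assert_frame_equal(
            reread.astype(str), table.astype(str)
        )

    def test_uninformed_is_own_schedule_at_some_belief(self):
        table = generate_cohort(CohortSpec(n=100, seed=5))
        for _, row in table.iterrows():
            entries = [int(row[f"c{k}"]) for k in range(21)]
            assert row["uninformed"] in entries

    def test_sex_split_matches_fraction(self):
        table = generate_cohort(CohortSpec(n=188, seed=6))
        assert (table["sex"] == "female").sum() == 107

    def test_null_cohort_has_independent_genotype_and_strategy(self):
        """Without a planted effect, strategy x genotype Fisher p-values stay
        conservative-to-uniform across seeded replicates."""
        from coopgene.association import fisher_exact
        from coopgene.classifier import classify_cohort
        from coopgene.pgg import ContingentSchedule

        ps = []
        for seed in range(15):
            table = generate_cohort(CohortSpec(n=120, seed=200 + seed))
            scheds = [
                ContingentSchedule(tuple(int(r[f"c{k}"]) for k in range(21)))
                for _, r in table.iterrows()
            ]
            labels = [c.label for c in classify_cohort(scheds).calls]
            oxtr = [
                code_genotypes(r).oxtr
                for r in draw_genotypes(CohortSpec(n=120, seed=200 + seed))
            ]
            tab = pd.crosstab(pd.Series(labels), pd.Series(oxtr))
            tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
            ps.append(fisher_exact(tab.to_numpy()).p)
        ps = np.array(ps)
        assert (ps <= 0.05).mean() <= 0.2
        assert ps.mean() > 0.3

    def test_planted_effect_shifts_strategy_mix(self):
        """A strong CC tilt for OXTR GG carriers produces a visibly higher
        CC share among GG subjects."""
        effect = {"oxtr": {"GG": {"CC": 6.0}}}
        table = generate_cohort(CohortSpec(n=2000, seed=8, effect=effect))
        from coopgene.classifier import classify_cohort
        from coopgene.pgg import ContingentSchedule

        scheds = [
            ContingentSchedule(tuple(int(r[f"c{k}"]) for k in range(21)))
            for _, r in table.iterrows()
        ]
        labels = np.array([c.label for c in classify_cohort(scheds).calls])
        oxtr = np.array(
            [
                code_genotypes(r).oxtr
                for r in draw_genotypes(CohortSpec(n=2000, seed=8, effect=effect))
            ]
        )
        cc_gg = (labels[oxtr == "GG"] == "CC").mean()
        cc_other = (labels[oxtr != "GG"] == "CC").mean()
        assert cc_gg > cc_other + 0.15
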