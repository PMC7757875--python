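"""End-to-end orchestration: read/simulate -> code -> classify -> battery.

Every number in the report bundle is computed by exactly one operation in
one module; the orchestrator only moves data and serializes.  Outputs are
deterministic: the same config and seed produce byte-identical files
(floats are serialized at fixed precision).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import BatteryConfig, fisher_exact, run_battery
from .classifier import (
    LABELS,
    ClassifierConfig,
    average_profile,
    calls_to_frame,
    classify_cohort,
)
from .genetics import (
    EXCLUDED,
    RawGenotype,
    VARIANTS,
    genotype_count_table,
    hwe_test,
    maoa_female_hwe_counts,
)
from .io import analysis_frame, read_subjects, write_subjects
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger("coopgene")

FLOAT_FORMAT = "%.6f"

__all__ = ["PipelineConfig", "load_config", "run"]


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline settings: exactly one of input_path / synthetic must be set."""

    input_path: Optional[str] = None
    synthetic: Optional[CohortSpec] = None
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    battery: BatteryConfig = field(default_factory=BatteryConfig)
    seed: int = 0
    pooled: bool = False  # add a sexes-pooled battery stratum (off by default)

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of input_path / synthetic must be provided"
            )


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    seed = int(cfg.get("seed", 0))
    synthetic = None
    if "synthetic" in cfg:
        syn = dict(cfg["synthetic"])
        syn.setdefault("seed", seed)
        synthetic = CohortSpec(**syn)
    classifier = ClassifierConfig(**cfg.get("classifier", {}))
    battery_kwargs = dict(cfg.get("battery", {}))
    battery_kwargs.setdefault("seed", seed)
    battery = BatteryConfig(**battery_kwargs)
    return PipelineConfig(
        input_path=cfg.get("input"),
        synthetic=synthetic,
        classifier=classifier,
        battery=battery,
        seed=seed,
        pooled=bool(cfg.get("pooled", False)),
    )


def _json_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 6)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _json_ready(obj.tolist())
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_json_ready(payload), indent=2, sort_keys=True) + "\n")


def _records_from_frame(df: pd.DataFrame, tmpdir: Path):
    # round-trip through the canonical CSV so synthetic and file inputs
    # take the identical validation path
    csv_path = tmpdir / "_subjects.csv"
    write_subjects(df, csv_path)
    records, diagnostics = read_subjects(csv_path)
    csv_path.unlink()
    return records, diagnostics


def _hwe_payload(records) -> dict:
    """HWE for the autosomal loci on the pooled sample and for MAOA in women
    (pre-exclusion female genotype table)."""
    coded = pd.DataFrame(
        {
            "sex": [r.sex for r in records],
            "oxtr": [r.coded().oxtr for r in records],
            "avpr1a": [r.coded().avpr1a for r in records],
        }
    )
    payload = {}
    for variant in ("oxtr", "avpr1a"):
        try:
            counts = genotype_count_table(coded, variant)
        except ValueError:
            payload[variant] = {"note": "no subjects after exclusions"}
            continue
        res = hwe_test(tuple(counts.to_numpy()))
        payload[variant] = {
            "classes": list(counts.index),
            "observed": list(res.observed),
            "expected": list(res.expected),
            "chi2": res.chi2,
            "df": res.df,
            "p": res.p,
            "degenerate": res.degenerate,
        }
    female_raws = [
        RawGenotype(
            sex="female",
            maoa_repeats=r.maoa_repeats,
            oxtr_alleles=r.oxtr_alleles or ("A", "A"),
            rs3_lengths_bp=r.rs3_lengths_bp or (330, 330),
        )
        for r in records
        if r.sex == "female" and r.maoa_repeats is not None
    ]
    if female_raws:
        ll, lh, hh = maoa_female_hwe_counts(female_raws)
        if ll + lh + hh > 0:
            res = hwe_test((ll, lh, hh))
            payload["maoa_female"] = {
                "classes": ["L/L", "L/H", "H/H"],
                "observed": list(res.observed),
                "expected": list(res.expected),
                "chi2": res.chi2,
                "df": res.df,
                "p": res.p,
                "degenerate": res.degenerate,
            }
    return payload


def run(config: PipelineConfig, out_dir) -> dict:
    """Run the pipeline and write the report bundle into ``out_dir``.

    Returns a dict of in-memory results keyed like the files written.
    Partial outputs are removed if any stage fails.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_tsv(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written.append(path)

    def emit_json(name: str, payload) -> None:
        path = out / name
        _write_json(path, payload)
        written.append(path)

    try:
        if config.synthetic is not None:
            spec = config.synthetic
            if spec.seed is None:
                spec = CohortSpec(**{**spec.__dict__, "seed": config.seed})
            table = generate_cohort(spec)
            records, diagnostics = _records_from_frame(table, out)
        else:
            records, diagnostics = read_subjects(config.input_path)
        for msg in diagnostics:
            logger.warning("rejected row: %s", msg)

        # classification
        dist = classify_cohort((r.schedule for r in records), config.classifier)
        calls = list(dist.calls)
        emit_tsv("strategy_calls.tsv", calls_to_frame([r.id for r in records], calls))

        # strategy distribution, overall and by sex
        rows = [
            {"stratum": "all", "n": dist.n,
             **{lab: dist.percentages[lab] for lab in LABELS}}
        ]
        sex_tables = {}
        for sex in ("female", "male"):
            labels = [c.label for r, c in zip(records, calls) if r.sex == sex]
            if not labels:
                continue
            counts = {lab: labels.count(lab) for lab in LABELS}
            n = len(labels)
            sex_tables[sex] = [counts[lab] for lab in LABELS]
            rows.append(
                {"stratum": sex, "n": n,
                 **{lab: round(100.0 * counts[lab] / n, 2) for lab in LABELS}}
            )
        dist_df = pd.DataFrame(rows)
        emit_tsv("strategy_distribution.tsv", dist_df)

        # sex-difference Fisher test on the strategy x sex table
        sex_fisher = None
        if len(sex_tables) == 2:
            table_sx = np.array(
                [sex_tables["female"], sex_tables["male"]]
            ).T  # strategies x sexes
            keep = table_sx.sum(axis=1) > 0
            res = fisher_exact(
                table_sx[keep],
                budget=config.battery.fisher_budget,
                mc_draws=config.battery.fisher_mc_draws,
                rng=np.random.default_rng(config.seed),
            )
            sex_fisher = {"p": res.p, "method": res.method}

        # association battery
        frame = analysis_frame(records, calls)
        battery_cfg = config.battery
        if battery_cfg.seed is None:
            battery_cfg = BatteryConfig(**{**battery_cfg.__dict__, "seed": config.seed})
        report = run_battery(frame, battery_cfg)
        emit_tsv("association.tsv", report.tests)

        # per-genotype strategy distributions (plot-ready)
        geno_rows = []
        for sex in ("female", "male"):
            sub = frame[frame["sex"] == sex]
            for variant in VARIANTS:
                kept = sub[sub[variant] != EXCLUDED]
                for level, grp in kept.groupby(variant, observed=True):
                    counts = grp["strategy"].value_counts()
                    n = len(grp)
                    geno_rows.append(
                        {"sex": sex, "variant": variant, "genotype": level, "n": n,
                         **{lab: round(100.0 * counts.get(lab, 0) / n, 2)
                            for lab in LABELS}}
                    )
        emit_tsv("genotype_distributions.tsv", pd.DataFrame(geno_rows))

        # average strategy profiles per label (and per genotype for plots)
        profiles = average_profile(calls, [r.schedule for r in records])
        prof_rows = [
            {"group": lab, **{f"c{j}": prof[j] for j in range(21)}}
            for lab, prof in profiles.items()
        ]
        for sex in ("female", "male"):
            sub = frame[frame["sex"] == sex]
            for variant in VARIANTS:
                kept = sub[sub[variant] != EXCLUDED]
                for level, grp in kept.groupby(variant, observed=True):
                    scheds = np.array(
                        [records[i].schedule.as_array() for i in grp.index]
                    )
                    mean = scheds.mean(axis=0)
                    prof_rows.append(
                        {"group": f"{sex}:{variant}:{level}",
                         **{f"c{j}": mean[j] for j in range(21)}}
                    )
        emit_tsv("average_profiles.tsv", pd.DataFrame(prof_rows))

        # HWE
        hwe_payload = _hwe_payload(records)
        emit_json("hwe.json", hwe_payload)

        # association report JSON
        assoc_payload = {
            "families": {
                name: {
                    "m": fam.m,
                    "family_alpha": fam.family_alpha,
                    "per_test_alpha": fam.per_test_alpha,
                    "per_test_alpha_printed": fam.per_test_alpha_printed,
                }
                for name, fam in report.families.items()
            },
            "n_tests": int(len(report.tests)),
            "n_significant": report.n_significant,
            "sex_difference_fisher": sex_fisher,
            "skipped": report.skipped,
        }
        emit_json("association.json", assoc_payload)

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "n_subjects": len(records),
            "n_rejected_rows": len(diagnostics),
            "classifier": {
                "fr_fraction": config.classifier.fr_fraction,
                "fr_ceiling_tokens": config.classifier.fr_ceiling_tokens,
                "alpha": config.classifier.alpha,
                "min_segment": config.classifier.min_segment,
                "two_sided": config.classifier.two_sided,
            },
            "battery": {
                "bootstrap_reps": battery_cfg.bootstrap_reps,
                "fisher_mc_draws": battery_cfg.fisher_mc_draws,
                "seed": battery_cfg.seed,
            },
            "input": config.input_path or "synthetic",
        }
        emit_json("manifest.json", manifest)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    return {
        "records": records,
        "calls": calls,
        "distribution": dist,
        "frame": frame,
        "report": report,
        "hwe": hwe_payload,
        "sex_difference_fisher": sex_fisher,
    }
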