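"""Study-level simulation: one call per scenario.

Two entry points:

* :func:`simulate_analysis_dataset` — the fast path used by
  parameter-recovery replicates: cohort, genotypes, exposures and the
  derived phenotype table, skipping the raw-signal channels (traces,
  qPCR plates, methylation) that the association models never touch.
* :func:`simulate_study` — the full emission: every raw input the
  downstream pipeline stages consume, writable to disk with
  :func:`write_study` in the plain-text formats the CLI reads back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ..config import ScenarioConfig
from ..ltl import build_ltl_measures
from .cohort import TruthRecord, generate_cohort
from .methylation import generate_methylation
from .qpcr import generate_qpcr_plates
from .vascular import generate_vascular_raw, simulate_derived_phenotypes

__all__ = ["SimulatedStudy", "simulate_analysis_dataset", "simulate_study", "write_study"]


def simulate_analysis_dataset(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """(cohort, dosages, weights, derived phenotypes, truth) for one
    replicate, with measured LTL entering as the latent value."""
    cohort, dosages, weights, truth = generate_cohort(config)
    phenotypes = simulate_derived_phenotypes(cohort, truth, config)
    return cohort, dosages, weights, phenotypes, truth


@dataclass
class SimulatedStudy:
    config: ScenarioConfig
    cohort: pd.DataFrame
    dosages: pd.DataFrame
    weights: pd.DataFrame
    truth: TruthRecord
    vascular_raw: pd.DataFrame
    traces: dict[str, pd.DataFrame]
    derived: pd.DataFrame
    qpcr_plates: pd.DataFrame
    ts_true: pd.Series
    methylation: pd.DataFrame
    cpg_map: pd.DataFrame


def simulate_study(
    config: ScenarioConfig,
    methylation_exposure: str = "measured",
    with_traces: bool = True,
) -> SimulatedStudy:
    """Generate every raw input of the full pipeline for one scenario."""
    cohort, dosages, weights, truth = generate_cohort(config)
    raw, traces, derived = generate_vascular_raw(cohort, truth, config, with_traces=with_traces)
    plate_of = {
        pid: f"P{batch[1:]}" for pid, batch in zip(cohort["participant_id"], cohort["batch"])
    }
    plates, ts_true = generate_qpcr_plates(
        truth.latent_ltl, config, sample_ids=cohort["participant_id"].tolist(), plate_of=plate_of
    )
    betas, cpg_map = generate_methylation(
        cohort, truth.exposures[methylation_exposure], config, truth=truth
    )
    return SimulatedStudy(
        config=config,
        cohort=cohort,
        dosages=dosages,
        weights=weights,
        truth=truth,
        vascular_raw=raw,
        traces=traces,
        derived=derived,
        qpcr_plates=plates,
        ts_true=ts_true,
        methylation=betas,
        cpg_map=cpg_map,
    )


def ltl_measures_from_study(study: SimulatedStudy, panels=None) -> pd.DataFrame:
    """Exposure table for a simulated study (latent LTL as measured)."""
    from ..ltl import PANELS

    return build_ltl_measures(
        study.cohort, study.dosages, study.weights, study.truth.latent_ltl,
        panels=panels or PANELS,
    )


def write_study(study: SimulatedStudy, out_dir) -> Path:
    """Write the study to ``out_dir`` in plain-text formats.

    Emits cohort.csv, dosages.tsv (participants × variants with a
    header row of variant ids), weights.tsv, qpcr_plates.tsv,
    vascular_raw.csv, traces/<participant>.csv, methylation.tsv
    (CpG rows), cpg_map.tsv and truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.cohort.to_csv(out / "cohort.csv", index=False)
    dosages = study.dosages.copy()
    dosages.insert(0, "participant_id", study.cohort["participant_id"].to_numpy())
    dosages.to_csv(out / "dosages.tsv", sep="\t", index=False)
    study.weights.to_csv(out / "weights.tsv", sep="\t", index=False)
    study.qpcr_plates.to_csv(out / "qpcr_plates.tsv", sep="\t", index=False)
    study.vascular_raw.to_csv(out / "vascular_raw.csv", index=False)
    trace_dir = out / "traces"
    trace_dir.mkdir(exist_ok=True)
    for pid, trace in study.traces.items():
        trace.to_csv(trace_dir / f"{pid}.csv", index=False)
    study.methylation.to_csv(out / "methylation.tsv", sep="\t")
    study.cpg_map.to_csv(out / "cpg_map.tsv", sep="\t", index=False)
    truth = {
        "planted_effects": {f"{e}:{o}": v for (e, o), v in study.truth.planted_effects.items()},
        "causal_cpg_ids": study.truth.causal_cpg_ids,
        "causal_cpg_effects": study.truth.causal_cpg_effects,
        "latent_ltl": [float(x) for x in study.truth.latent_ltl],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return out
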