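"""Config-driven end-to-end orchestration.

``run_all`` executes simulate -> preprocess -> peaks -> classify ->
diffpeaks -> clinstats in the fixed methods order, writing each stage's
output plus a reproducibility manifest (config hash, fanned-out seeds, and
record counts) into a run directory. A rerun with the same config reproduces
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import classify as _classify
from . import clinstats as _clinstats
from . import diffpeaks as _diffpeaks
from . import peaks as _peaks
from . import preprocess as _preprocess
from . import spectra_io as _io
from . import synthetic_data as _synth

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "preprocess", "peaks", "classify", "diffpeaks", "clinstats")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run.

    ``stages`` must list the canonical stage order (a reordered list is
    rejected at validation — the preprocessing chain's order is part of the
    method). ``seed`` is the single global seed; per-stage streams are fanned
    out by stable hashing so stages can be rerun in isolation.
    """

    synthetic: _synth.SyntheticConfig = field(default_factory=_synth.SyntheticConfig)
    preprocess: _preprocess.PreprocessParams = field(default_factory=_preprocess.PreprocessParams)
    svm: _classify.SvmConfig = field(default_factory=_classify.SvmConfig)
    snr_threshold: float = 3.0
    window_ppm: float = 2000.0
    integration: str = "max"
    peaks_from: str = "all"  # "all" | "study_only"
    n_study_per_class: tuple = (21, 20)
    fc_line: float = 1.0
    p_line: float = 0.05
    diff_unit: str = "spot"
    clinical_n: tuple = (31, 30, 10)  # (LGP, FA, HGP) cohort sizes
    seed: int = 0
    stages: tuple = STAGE_ORDER

    def __post_init__(self) -> None:
        if tuple(self.stages) != STAGE_ORDER:
            raise ValueError(
                f"stages must follow the fixed order {STAGE_ORDER}; got {tuple(self.stages)}"
            )
        if self.peaks_from not in ("all", "study_only"):
            raise ValueError("peaks_from must be 'all' or 'study_only'")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            sd = dict(d["synthetic"])
            if "effect_compartments" in sd:
                sd["effect_compartments"] = tuple(sd["effect_compartments"])
            d["synthetic"] = _synth.SyntheticConfig(**sd)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = _preprocess.PreprocessParams(**d["preprocess"])
        if "svm" in d and isinstance(d["svm"], dict):
            sv = dict(d["svm"])
            if "cost_grid" in sv:
                sv["cost_grid"] = tuple(sv["cost_grid"])
            d["svm"] = _classify.SvmConfig(**sv)
        for key in ("n_study_per_class", "clinical_n", "stages"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("n_study_per_class", "clinical_n", "stages"):
            d[key] = list(d[key])
        d["synthetic"]["effect_compartments"] = list(d["synthetic"]["effect_compartments"])
        d["svm"]["cost_grid"] = list(d["svm"]["cost_grid"])
        return d


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan a global seed out to a per-stage stream by stable hashing."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_all(config: RunConfig, out_dir) -> dict:
    """Run every stage in order; returns the manifest (also written to disk).

    Outputs in ``out_dir``: the peak matrix (delimited text), preprocessing
    report, per-compartment classification and volcano reports, clinical and
    IHC tables with their summary, the ground-truth sidecar, and
    ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGE_ORDER},
        "stages": {},
        "warnings": [],
    }

    def record(stage, t0, **counts):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **counts}

    try:
        # -- simulate ------------------------------------------------------
        t0 = time.time()
        synth_cfg = dataclasses.replace(config.synthetic, seed=stage_seed(config.seed, "simulate"))
        dataset, truth = _synth.generate_dataset(synth_cfg)
        truth.to_json(out / "ground_truth.json")
        record("simulate", t0, n_spectra=len(dataset.spectra), n_cases=len(dataset.case_ids))

        # -- preprocess ----------------------------------------------------
        t0 = time.time()
        processed, pre_report = _preprocess.run_chain(dataset.spectra, config.preprocess)
        with open(out / "preprocess_report.json", "w") as fh:
            json.dump(pre_report, fh, indent=1, default=str)
        if pre_report["identity_flagged"]:
            manifest["warnings"].append(
                f"{len(pre_report['identity_flagged'])} spectra kept an identity warp"
            )
        if pre_report["tic"]["rejects"]:
            manifest["warnings"].append(
                f"{len(pre_report['tic']['rejects'])} zero-TIC spectra rejected"
            )
        record("preprocess", t0, n_spectra=len(processed))

        # -- classify: split first so peak picking can honor peaks_from ----
        split = _classify.split_dataset(
            _io.ProfileDataset(spectra=processed, partition=dict(dataset.partition)),
            config.n_study_per_class,
            seed=stage_seed(config.seed, "classify"),
        )

        # -- peaks ---------------------------------------------------------
        t0 = time.time()
        if config.peaks_from == "study_only":
            pool = [s for s in split.spectra if split.partition[s.case_id] == "study"]
        else:
            pool = split.spectra
        mean = _peaks.mean_spectrum(pool)
        peaklist = _peaks.detect_peaks(mean, snr_threshold=config.snr_threshold)
        matrix = _peaks.build_peak_matrix(
            split.spectra, peaklist, window_ppm=config.window_ppm, integration=config.integration
        )
        _io.write_peak_matrix(matrix, out / "peak_matrix.csv")
        record("peaks", t0, n_peaks=len(peaklist), n_rows=matrix.n_spectra)

        # -- classify ------------------------------------------------------
        t0 = time.time()
        truth_map = truth.true_class_by_case
        svm_cfg = dataclasses.replace(config.svm, seed=stage_seed(config.seed, "classify"))
        classification = {}
        for compartment in ("epithelial", "stromal"):
            classification[compartment] = _classify.classify_validation(
                matrix, split.partition, truth_map, svm_cfg, compartment=compartment
            )
        with open(out / "classification_report.json", "w") as fh:
            json.dump(classification, fh, indent=1, default=str)
        record(
            "classify", t0,
            n_study=sum(v == "study" for v in split.partition.values()),
            n_validation=sum(v == "validation" for v in split.partition.values()),
        )

        # -- diffpeaks (study set, per compartment) ------------------------
        t0 = time.time()
        study_cases = [c for c, p in split.partition.items() if p == "study"]
        volcano = {}
        for compartment in ("epithelial", "stromal"):
            sub = matrix.subset(matrix.rows_for(case_ids=study_cases, compartment=compartment))
            v = _diffpeaks.volcano_stats(
                sub, fc_line=config.fc_line, p_line=config.p_line, unit=config.diff_unit
            )
            _diffpeaks.volcano_table(v).to_csv(out / f"volcano_{compartment}.csv", index=False)
            volcano[compartment] = {k: v[k] for k in
                                    ("n_peaks", "n_past_fc_line", "n_significant_raw", "n_past_both")}
        record("diffpeaks", t0, **{f"n_peaks_{c}": volcano[c]["n_peaks"] for c in volcano})

        # -- clinstats -----------------------------------------------------
        t0 = time.time()
        n_lgp, n_fa, n_hgp = config.clinical_n
        cseed = stage_seed(config.seed, "clinstats")
        clinical = _synth.generate_clinical_table(n_lgp, n_fa, seed=cseed)
        ihc = _synth.generate_ihc_table(n_fa, n_lgp, n_hgp, seed=cseed + 1)
        _io.write_clinical_table(clinical, out / "clinical.csv")
        _io.write_ihc_table(ihc, out / "ihc.csv")
        summary = _clinstats.summarize_groups(clinical, ihc)
        with open(out / "clinical_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=lambda o: getattr(o, "__dict__", str(o)))
        record("clinstats", t0, n_clinical=len(clinical), n_ihc=len(ihc))
    except Exception as exc:
        stage = next((s for s in STAGE_ORDER if s not in manifest["stages"]), "unknown")
        manifest["failed_stage"] = stage
        manifest["partial_results"] = True
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["classification"] = {
        c: {
            "overall_accuracy": classification[c]["overall_accuracy"],
            "tuned_cost": classification[c]["tuned_cost"],
            "n_fully_consistent": classification[c]["n_fully_consistent"],
        }
        for c in classification
    }
    manifest["volcano"] = volcano
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
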